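"""Paired-domain alignment handling.

A :class:`PairedMSA` is a multiple sequence alignment of a two-domain
protein in which one row is the sequence of the reference structure and
the alignment columns belonging to each structural domain are recorded
explicitly.  All coevolution scores in this package operate on the
inter-domain column pairs of such an object.

The module covers reading (FASTA / Stockholm), sanitising non-standard
residue symbols to gaps, reduced-alphabet transformation, column
eligibility masking (ungapped, entropy > 0) and deterministic
subsampling of sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import AlignIO

from .errors import (
    DomainRangeError,
    InconsistentSpecError,
    MissingReferenceError,
    RaggedAlignmentError,
    SubsampleError,
    UnknownSymbolError,
)

#: the 20 standard amino acids, one-letter codes
AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: gap symbol used internally; "." in input is normalised to this
GAP = "-"

_AA20_SET = frozenset(AA20)


@dataclass(frozen=True)
class AlphabetMap:
    """Total mapping from the 20 standard amino acids to category symbols."""

    mapping: Mapping[str, str]
    name: str = "custom"

    def __post_init__(self) -> None:
        missing = _AA20_SET - set(self.mapping)
        if missing:
            raise UnknownSymbolError(
                f"alphabet map {self.name!r} lacks entries for {sorted(missing)}"
            )

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.mapping.values())))


def _reduced_seven() -> AlphabetMap:
    # Physiochemical 7-category grouping: Small, Hydrophobic, Negatively
    # charged, Aromatic, Polar, Favoured positive (R/H), Disfavoured
    # positive (K); lysine is split out because it is rare at interfaces.
    groups = {
        "S": "SGAP",   # Small
        "H": "VMILC",  # Hydrophobic
        "N": "DE",     # Negatively charged
        "A": "FYW",    # Aromatic
        "P": "QTN",    # Polar
        "F": "RH",     # Favoured positively-charged
        "D": "K",      # Disfavoured positively-charged
    }
    mapping = {aa: cat for cat, members in groups.items() for aa in members}
    return AlphabetMap(mapping=mapping, name="reduced7")


#: the default 7-category physiochemical reduced alphabet
REDUCED_ALPHABET = _reduced_seven()


@dataclass(frozen=True)
class PairedMSA:
    """Alignment of a two-domain protein with explicit domain columns.

    Parameters
    ----------
    sequences:
        Equal-length aligned rows (uppercase, ``-`` gaps after sanitising).
    ids:
        One identifier per row.
    reference_index:
        Row index of the reference-structure sequence.
    domain1_cols, domain2_cols:
        Disjoint, ordered 0-based alignment columns covering each domain
        of the reference sequence.
    domain1_start, domain2_start:
        1-based residue number of the first residue of each domain on the
        reference sequence, so columns can be mapped back to residues.
    """

    sequences: tuple[str, ...]
    ids: tuple[str, ...]
    reference_index: int
    domain1_cols: tuple[int, ...]
    domain2_cols: tuple[int, ...]
    domain1_start: int = 1
    domain2_start: int = 1
    id: str = ""

    def __post_init__(self) -> None:
        if not self.sequences:
            raise RaggedAlignmentError("alignment has no sequences")
        length = len(self.sequences[0])
        if any(len(s) != length for s in self.sequences):
            raise RaggedAlignmentError("sequences differ in length")
        if len(self.ids) != len(self.sequences):
            raise RaggedAlignmentError("ids and sequences differ in count")
        if not 0 <= self.reference_index < len(self.sequences):
            raise MissingReferenceError(
                f"reference index {self.reference_index} out of range"
            )
        d1, d2 = set(self.domain1_cols), set(self.domain2_cols)
        if d1 & d2:
            raise DomainRangeError("domain column sets overlap")
        for c in d1 | d2:
            if not 0 <= c < length:
                raise DomainRangeError(f"domain column {c} outside alignment")
        ref = self.sequences[self.reference_index]
        if any(ref[c] == GAP for c in d1 | d2):
            raise DomainRangeError("reference row is gapped inside a domain")

    # -- basic properties -------------------------------------------------

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])

    @property
    def reference(self) -> str:
        return self.sequences[self.reference_index]

    @property
    def domain_cols(self) -> tuple[int, ...]:
        return tuple(self.domain1_cols) + tuple(self.domain2_cols)

    def domain_of(self, col: int) -> int:
        """1 or 2 for a domain column, 0 otherwise."""
        if col in set(self.domain1_cols):
            return 1
        if col in set(self.domain2_cols):
            return 2
        return 0

    def column(self, col: int) -> str:
        """The alignment column as a string, one symbol per row."""
        return "".join(s[col] for s in self.sequences)

    def to_array(self) -> np.ndarray:
        """(n_sequences, n_columns) array of single characters."""
        return np.array([list(s) for s in self.sequences], dtype="U1")

    def column_residue(self, col: int) -> tuple[int, int]:
        """Map a domain column to (domain, 1-based reference residue number)."""
        for cols, start, dom in (
            (self.domain1_cols, self.domain1_start, 1),
            (self.domain2_cols, self.domain2_start, 2),
        ):
            if col in cols:
                return dom, start + cols.index(col)
        raise DomainRangeError(f"column {col} belongs to neither domain")

    def residue_column(self, domain: int, resnum: int) -> int:
        """Map (domain, 1-based residue number) to its alignment column."""
        cols, start = (
            (self.domain1_cols, self.domain1_start)
            if domain == 1
            else (self.domain2_cols, self.domain2_start)
        )
        idx = resnum - start
        if not 0 <= idx < len(cols):
            raise DomainRangeError(
                f"residue {resnum} outside domain {domain} range"
            )
        return cols[idx]


@dataclass(frozen=True)
class ColumnMask:
    """Per-column eligibility for scoring.

    ``reason`` is one of ``ok`` (eligible), ``non_reference`` (outside the
    domain columns), ``gapped`` (>=1 gap in any row) or ``zero_entropy``
    (fully conserved).
    """

    eligible: np.ndarray  # bool, per column
    reason: tuple[str, ...]

    def __post_init__(self) -> None:
        for ok, why in zip(self.eligible, self.reason):
            if ok != (why == "ok"):
                raise InconsistentSpecError("mask eligibility/reason mismatch")

    def eligible_cols(self, cols: Iterable[int]) -> tuple[int, ...]:
        return tuple(c for c in cols if self.eligible[c])


# ---------------------------------------------------------------------------
# reading / writing


def _walk_reference(ref_row: str, start: int, end: int) -> tuple[int, ...]:
    """Alignment columns of reference residues ``start..end`` (1-based incl.)."""
    cols: list[int] = []
    resnum = 0
    for col, sym in enumerate(ref_row):
        if sym == GAP:
            continue
        resnum += 1
        if start <= resnum <= end:
            cols.append(col)
    if resnum < end:
        raise DomainRangeError(
            f"range {start}-{end} extends beyond the {resnum}-residue reference"
        )
    return tuple(cols)


def read_alignment(
    path: str | Path,
    format: str = "fasta",
    *,
    domain1_range: tuple[int, int],
    domain2_range: tuple[int, int],
    reference_id: str,
    id: str = "",
) -> PairedMSA:
    """Read a paired-domain alignment from a FASTA or Stockholm file.

    Domain ranges are 1-based inclusive residue numbers on the reference
    sequence (the ``D1 / D2`` convention of structure-derived domain
    tables); columns are derived by walking the reference row past gaps.
    """
    if format not in {"fasta", "stockholm"}:
        raise ValueError(f"unsupported alignment format {format!r}")
    try:
        aln = AlignIO.read(str(path), format)
    except ValueError as exc:
        if "length" in str(exc).lower():
            raise RaggedAlignmentError(f"{path}: {exc}") from None
        raise
    ids = tuple(rec.id for rec in aln)
    sequences = tuple(
        str(rec.seq).upper().replace(".", GAP) for rec in aln
    )
    if len({len(s) for s in sequences}) > 1:
        raise RaggedAlignmentError(f"{path}: sequences differ in length")
    try:
        ref_index = ids.index(reference_id)
    except ValueError:
        raise MissingReferenceError(
            f"reference id {reference_id!r} not found in {path}"
        ) from None
    for lo, hi, name in (*domain1_range, "domain1"), (*domain2_range, "domain2"):
        if lo < 1 or hi < lo:
            raise DomainRangeError(f"{name} range ({lo}, {hi}) is not a valid "
                                   "1-based inclusive interval")
    ref_row = sequences[ref_index]
    d1 = _walk_reference(ref_row, *domain1_range)
    d2 = _walk_reference(ref_row, *domain2_range)
    return PairedMSA(
        sequences=sequences,
        ids=ids,
        reference_index=ref_index,
        domain1_cols=d1,
        domain2_cols=d2,
        domain1_start=domain1_range[0],
        domain2_start=domain2_range[0],
        id=id or Path(path).stem,
    )


def write_fasta(msa: PairedMSA, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in zip(msa.ids, msa.sequences):
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# transformations


def sanitize(msa: PairedMSA) -> PairedMSA:
    """Replace every non-standard residue symbol with a gap.

    Lowercase is normalised to uppercase first; then any symbol outside
    the 20 standard amino acids (B, Z, X, ``*``, ``?``, U, O, ...) becomes
    a gap, because such sequencing ambiguities carry no usable covariation
    signal.  Idempotent; row count and length are unchanged.
    """
    table = {c: (c if c in _AA20_SET else GAP) for c in set("".join(msa.sequences).upper())}
    cleaned = tuple(
        "".join(table[c] for c in seq.upper()) for seq in msa.sequences
    )
    return replace(msa, sequences=cleaned)


def reduce_alphabet(msa: PairedMSA, amap: AlphabetMap = REDUCED_ALPHABET) -> PairedMSA:
    """Rewrite every residue as its physiochemical category symbol.

    Gaps are preserved.  Raises :class:`UnknownSymbolError` on symbols the
    map does not cover (i.e. if :func:`sanitize` was skipped).
    """
    out: list[str] = []
    for seq in msa.sequences:
        try:
            out.append(
                "".join(GAP if c == GAP else amap.mapping[c] for c in seq)
            )
        except KeyError as exc:
            raise UnknownSymbolError(
                f"symbol {exc.args[0]!r} not covered by alphabet map "
                f"{amap.name!r}; run sanitize() first"
            ) from None
    return replace(msa, sequences=tuple(out))


def build_mask(msa: PairedMSA) -> ColumnMask:
    """Flag each column eligible or not for scoring.

    A column is eligible iff it belongs to one of the two domains, carries
    no gap in any row, and is not fully conserved (entropy > 0).  Fully
    conserved columns always yield a mutual information of exactly zero
    with any partner, so they are filtered here once and for all.
    """
    domain_cols = set(msa.domain_cols)
    eligible = np.zeros(msa.n_columns, dtype=bool)
    reason: list[str] = []
    arr = msa.to_array()
    for col in range(msa.n_columns):
        if col not in domain_cols:
            reason.append("non_reference")
            continue
        column = arr[:, col]
        if (column == GAP).any():
            reason.append("gapped")
        elif (column == column[0]).all():
            reason.append("zero_entropy")
        else:
            reason.append("ok")
            eligible[col] = True
    return ColumnMask(eligible=eligible, reason=tuple(reason))


def subsample(msa: PairedMSA, fraction: float, seed: int) -> PairedMSA:
    """Random sub-alignment of ``floor(fraction * n)`` rows, reference kept.

    The reference row is retained unconditionally (structure annotations
    must stay mappable); the remaining ``floor(fraction*n) - 1`` rows are
    drawn uniformly without replacement from the other sequences.
    Deterministic for a given seed.  Column count is unchanged.
    """
    if not 0 < fraction <= 1:
        raise SubsampleError(f"fraction {fraction} outside (0, 1]")
    n = msa.n_sequences
    k = int(np.floor(fraction * n + 1e-9))  # guard: 0.7*180 != 126 in FP
    if k < 2:
        raise SubsampleError(f"subsample of {k} sequences is too small")
    rng = np.random.default_rng(seed)
    others = [i for i in range(n) if i != msa.reference_index]
    chosen = rng.choice(len(others), size=k - 1, replace=False)
    rows = [msa.reference_index] + sorted(others[i] for i in chosen)
    return replace(
        msa,
        sequences=tuple(msa.sequences[i] for i in rows),
        ids=tuple(msa.ids[i] for i in rows),
        reference_index=0,
    )
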