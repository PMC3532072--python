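"""Synthetic paired-domain alignments with planted ground truth.

The generator emulates the statistical structure that mutual-information
contact prediction assumes: independent background columns, pairs (or
triples) of columns whose symbols covary with a controllable coupling
strength, fully conserved columns, gapped columns, and a consistent set
of structural annotations (surface/buried accessibility, inter-domain
contact geometry, within-domain patch pairs) realised as one-atom
point coordinates that satisfy the planted distance constraints exactly.

Couplings are bijection mixtures: with probability equal to the coupling
a row's second symbol is a fixed random bijection of the first,
otherwise it is drawn independently.  An optional phylogenetic-noise
mode assigns rows to two clades, each with its own ancestral sequence,
and resamples sites independently at the given rate; the shared clade
identity then correlates otherwise-independent columns, creating the
background signal the product- and pattern-similarity corrections are
designed to suppress.  (A single shared ancestor would not do this:
with one ancestor the columns remain independent across rows.)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import InconsistentSpecError
from .msa import AA20, GAP, PairedMSA
from .structure import DistanceMap, ResidueAnnotation, min_atom_distances

#: planted accessibility (%) for surface / buried residues and the
#: in-complex value of contact residues
SURFACE_ACCESS = 30.0
BURIED_ACCESS = 2.0
CONTACT_COMPLEX_ACCESS = 18.0
#: planted distance (A) between a contact pair / patch pair of residues
CLOSE_DISTANCE = 4.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic paired-domain alignment.

    Columns are 0-based alignment columns; domain 1 occupies columns
    ``0 .. len1-1`` (residues 1..len1), domain 2 columns
    ``len1 .. len1+len2-1`` (residues len1+1 .. len1+len2).
    """

    n_sequences: int = 500
    len1: int = 30
    len2: int = 30
    alphabet_size: int = 20
    coupled_pairs: tuple[tuple[int, int, float], ...] = ()
    coupled_triples: tuple[tuple[int, int, int, float], ...] = ()
    conserved_cols: tuple[int, ...] = ()
    gapped_cols: tuple[int, ...] = ()
    surface_fraction: float = 0.7
    contact_cols: tuple[int, ...] = ()
    patch_pairs: tuple[tuple[int, int], ...] = ()
    phylo_noise: float = 0.0
    seed: int = 0
    id: str = "synthetic"

    @property
    def n_columns(self) -> int:
        return self.len1 + self.len2

    @property
    def domain1_cols(self) -> tuple[int, ...]:
        return tuple(range(self.len1))

    @property
    def domain2_cols(self) -> tuple[int, ...]:
        return tuple(range(self.len1, self.len1 + self.len2))

    def domain_of(self, col: int) -> int:
        return 1 if col < self.len1 else 2

    def column_resnum(self, col: int) -> int:
        # global residue numbering across both domains, 1-based
        return col + 1

    def __post_init__(self) -> None:
        if self.n_sequences < 2 or self.len1 < 1 or self.len2 < 1:
            raise InconsistentSpecError("lengths and counts must be positive")
        if not 2 <= self.alphabet_size <= 20:
            raise InconsistentSpecError("alphabet_size must be in 2..20")
        planted: list[int] = []
        for c1, c2, cpl in self.coupled_pairs:
            planted += [c1, c2]
            if not 0 <= cpl <= 1:
                raise InconsistentSpecError(f"coupling {cpl} outside [0,1]")
            if self.domain_of(c1) == self.domain_of(c2):
                raise InconsistentSpecError(
                    f"coupled pair ({c1},{c2}) is not inter-domain")
        for j, k, l, cpl in self.coupled_triples:
            planted += [j, k, l]
            if not 0 <= cpl <= 1:
                raise InconsistentSpecError(f"coupling {cpl} outside [0,1]")
        if len(planted) != len(set(planted)):
            raise InconsistentSpecError("coupled columns must be distinct")
        clash = set(planted) & (set(self.conserved_cols) | set(self.gapped_cols))
        if clash:
            raise InconsistentSpecError(
                f"columns {sorted(clash)} both coupled and conserved/gapped")
        for col in (*planted, *self.conserved_cols, *self.gapped_cols,
                    *self.contact_cols):
            if not 0 <= col < self.n_columns:
                raise InconsistentSpecError(f"column {col} out of range")
        for a, b in self.patch_pairs:
            if self.domain_of(a) != self.domain_of(b) or a == b:
                raise InconsistentSpecError(
                    f"patch pair ({a},{b}) must be two distinct same-domain columns")
        if not 0 <= self.surface_fraction <= 1:
            raise InconsistentSpecError("surface_fraction outside [0,1]")


def generate_msa(spec: SyntheticSpec) -> PairedMSA:
    """Draw the alignment described by ``spec``; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    n, length = spec.n_sequences, spec.n_columns
    alphabet = np.array(list(AA20[: spec.alphabet_size]), dtype="U1")
    m = len(alphabet)

    def uniform(size):
        return rng.integers(0, m, size=size)

    if spec.phylo_noise > 0:
        # two clades, each a star around its own ancestral sequence
        ancestors = uniform((2, length))
        clade = rng.integers(0, 2, size=n)
        codes = ancestors[clade].copy()
        resample = rng.random((n, length)) < spec.phylo_noise
        codes[resample] = uniform(int(resample.sum()))
    else:
        codes = uniform((n, length))

    for c1, c2, coupling in spec.coupled_pairs:
        codes[:, c1] = uniform(n)
        perm = rng.permutation(m)
        linked = rng.random(n) < coupling
        codes[linked, c2] = perm[codes[linked, c1]]
        codes[~linked, c2] = uniform(int((~linked).sum()))

    for j, k, l, coupling in spec.coupled_triples:
        codes[:, j] = uniform(n)
        perm_k, perm_l = rng.permutation(m), rng.permutation(m)
        linked = rng.random(n) < coupling
        codes[linked, k] = perm_k[codes[linked, j]]
        codes[linked, l] = perm_l[codes[linked, j]]
        codes[~linked, k] = uniform(int((~linked).sum()))
        codes[~linked, l] = uniform(int((~linked).sum()))

    for col in spec.conserved_cols:
        codes[:, col] = rng.integers(0, m)

    arr = alphabet[codes]
    for col in spec.gapped_cols:
        # reference row (0) must stay ungapped inside the domains
        row = int(rng.integers(1, n))
        arr[row, col] = GAP

    sequences = tuple("".join(row) for row in arr)
    ids = ("ref",) + tuple(f"seq{i}" for i in range(1, n))
    return PairedMSA(
        sequences=sequences, ids=ids, reference_index=0,
        domain1_cols=spec.domain1_cols, domain2_cols=spec.domain2_cols,
        domain1_start=1, domain2_start=spec.len1 + 1, id=spec.id,
    )


def _plant_coordinates(spec: SyntheticSpec, surface: set[int]
                       ) -> dict[tuple[int, int], np.ndarray]:
    """One-atom coordinates satisfying the planted distance constraints.

    Non-contact residues of the two domains sit on two widely separated
    lines; each contact is moved into a private pocket 4 A from its
    partner; patch pairs are co-located 4 A apart within their domain.
    """
    pos: dict[tuple[int, int], np.ndarray] = {}
    for col in range(spec.n_columns):
        res = spec.column_resnum(col)
        dom = spec.domain_of(col)
        base_y = 0.0 if dom == 1 else 1000.0
        pos[(dom, res)] = np.array([10.0 * res, base_y, 0.0])

    d1_contacts = [c for c in spec.contact_cols if spec.domain_of(c) == 1]
    d2_contacts = [c for c in spec.contact_cols if spec.domain_of(c) == 2]
    pocket = 0
    for c1, c2 in zip(d1_contacts, d2_contacts):
        x = 2000.0 + 100.0 * pocket
        pos[(1, spec.column_resnum(c1))] = np.array([x, 500.0, 0.0])
        pos[(2, spec.column_resnum(c2))] = np.array([x, 500.0 + CLOSE_DISTANCE, 0.0])
        pocket += 1
    # leftover contacts pair with a non-contact partner residue that is
    # buried or accessibility-stable, so the partner stays non-contact
    leftovers = d1_contacts[len(d2_contacts):] + d2_contacts[len(d1_contacts):]
    for col in leftovers:
        dom = spec.domain_of(col)
        other = 2 if dom == 1 else 1
        other_cols = (spec.domain2_cols if other == 2 else spec.domain1_cols)
        candidates = [c for c in other_cols if c not in spec.contact_cols]
        buried = [c for c in candidates if c not in surface]
        partner = (buried or candidates)[0]
        x = 5000.0 + 100.0 * pocket
        pos[(dom, spec.column_resnum(col))] = np.array([x, 500.0, 0.0])
        pos[(other, spec.column_resnum(partner))] = np.array(
            [x, 500.0 + CLOSE_DISTANCE, 0.0])
        pocket += 1

    for a, b in spec.patch_pairs:
        dom = spec.domain_of(a)
        ra, rb = spec.column_resnum(a), spec.column_resnum(b)
        if a in spec.contact_cols and b in spec.contact_cols:
            raise InconsistentSpecError(
                f"patch pair ({a},{b}): both members are contacts")
        if b in spec.contact_cols:  # keep the contact anchor fixed
            ra, rb = rb, ra
        pos[(dom, rb)] = pos[(dom, ra)] + np.array([0.0, 0.0, CLOSE_DISTANCE])
    return pos


def generate_annotations(spec: SyntheticSpec, msa: PairedMSA
                         ) -> tuple[list[ResidueAnnotation], DistanceMap,
                                    dict[tuple[int, int], np.ndarray]]:
    """Planted annotations + distance map consistent with the spec.

    Returns (annotations with columns attached, distance map, one-atom
    coordinates).  Exactly the planted contact columns satisfy all three
    contact criteria; surface membership covers ``surface_fraction`` of
    each domain's residues and always includes the planted contacts.
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 1)))
    surface: set[int] = set(spec.contact_cols)
    for dom_cols in (spec.domain1_cols, spec.domain2_cols):
        want = int(round(spec.surface_fraction * len(dom_cols)))
        have = [c for c in dom_cols if c in surface]
        extra = [c for c in dom_cols if c not in surface]
        n_extra = max(0, want - len(have))
        if n_extra > len(extra):
            raise InconsistentSpecError("surface_fraction too large for contacts")
        chosen = rng.choice(len(extra), size=n_extra, replace=False)
        surface.update(extra[i] for i in chosen)

    coords = _plant_coordinates(spec, surface)
    dmap = min_atom_distances(coords)

    annotations = []
    for col in range(spec.n_columns):
        dom = spec.domain_of(col)
        res = spec.column_resnum(col)
        iso = SURFACE_ACCESS if col in surface else BURIED_ACCESS
        cplx = CONTACT_COMPLEX_ACCESS if col in spec.contact_cols else iso
        annotations.append(ResidueAnnotation(
            domain=dom, resnum=res,
            rel_access_isolated=iso, rel_access_complex=cplx,
            surface=col in surface, contact=col in spec.contact_cols,
            column=col,
        ))
    return annotations, dmap, coords


# ---------------------------------------------------------------------------
# fixture materialisation


def write_pdb(coords: dict[tuple[int, int], np.ndarray],
              path: str | Path) -> None:
    """Write the one-atom-per-residue coordinates as a minimal PDB file."""
    lines = []
    serial = 0
    for (dom, res) in sorted(coords, key=lambda k: k[1]):
        for xyz in np.atleast_2d(coords[(dom, res)]):
            serial += 1
            x, y, z = (float(v) for v in xyz)
            lines.append(
                f"ATOM  {serial:5d}  CA  ALA A{res:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_fixture(spec: SyntheticSpec, directory: str | Path
                  ) -> dict[str, Path]:
    """Materialise FASTA + annotation TSV + PDB for one spec."""
    from .msa import write_fasta
    from .structure import write_annotations

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    msa = generate_msa(spec)
    annotations, _, coords = generate_annotations(spec, msa)
    paths = {
        "fasta": directory / f"{spec.id}.fasta",
        "annotations": directory / f"{spec.id}.annotations.tsv",
        "pdb": directory / f"{spec.id}.pdb",
    }
    write_fasta(msa, paths["fasta"])
    write_annotations(annotations, paths["annotations"])
    write_pdb(coords, paths["pdb"])
    return paths
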