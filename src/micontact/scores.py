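"""Mutual-information coevolution scores between domain columns.

Implemented variants, each over the eligible inter-domain column pairs
(or patch triples) of a :class:`~micontact.msa.PairedMSA`:

``MI``
    plug-in mutual information H(J) + H(K) - H(J;K), natural log.
``MIp``
    MI minus the average product correction APC(J;K) =
    mean_MI(J) * mean_MI(K) / mean_MI, which suppresses background
    (entropic and phylogenetic) signal shared by whole columns.
``MIc``
    MI minus the normalised coevolutionary pattern similarity NCPS,
    where CPS(J;K) is the mean over third columns L of
    MI(J;L) * MI(K;L) and the normaliser is the square root of the mean
    CPS over the inter-domain pairs.
``MI3D`` / ``MIp3D``
    total correlation of a domain-1 column J with a spatial "patch" pair
    of domain-2 columns (K, L) whose reference residues lie < 4.5 A
    apart, and its product-of-means APC3D correction.

Raw scores of exactly zero are removed before any mean or
standardisation is computed: they arise from conserved or effectively
independent columns and carry no covariation evidence.  Every surviving
table is z-scored over its own entries (sample sd), so scores are
comparable across alignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .entropy import column_entropy, entropy_from_counts, joint_entropy
from .errors import (
    DegenerateStandardizationError,
    IneligibleColumnError,
    NoSurvivingPairsError,
    ZeroMeanError,
)
from .msa import GAP, ColumnMask, PairedMSA

#: raw scores with magnitude at or below this are treated as exactly zero
ZERO_TOL = 1e-12

#: default same-patch distance cutoff in Angstroms (strict <)
PATCH_CUTOFF = 4.5

Key = tuple  # (J, K) column pair or (J, K, L) column triple


@dataclass(frozen=True)
class PairScoreTable:
    """Raw + standardised scores for surviving inter-domain keys.

    ``excluded`` maps removed keys to a reason (``zero_mi`` or
    ``ineligible_column``).  Standardised values are z-scores over the
    surviving entries of this table only.
    """

    variant: str
    entries: Mapping[Key, float]
    standardized: Mapping[Key, float]
    excluded: Mapping[Key, str]
    mean: float
    sd: float

    def columns(self) -> tuple[int, ...]:
        out: set[int] = set()
        for key in self.entries:
            out.update(key)
        return tuple(sorted(out))

    def scores_for_column(self, col: int) -> list[float]:
        """Standardised scores of every surviving key involving ``col``."""
        return [s for key, s in self.standardized.items() if col in key]

    def to_frame(self, msa: PairedMSA | None = None) -> pd.DataFrame:
        rows = []
        for key, raw in self.entries.items():
            row: dict = {"variant": self.variant, "raw": raw,
                         "standardized": self.standardized[key]}
            for slot, col in zip("JKL", key):
                row[f"col_{slot}"] = col
                if msa is not None:
                    dom, res = msa.column_residue(col)
                    row[f"res_{slot}"] = res
                    row[f"domain_{slot}"] = dom
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class PatchTriplets:
    """(J, K, L) column triples with K < L a same-patch domain pair."""

    triples: tuple[tuple[int, int, int], ...]


# ---------------------------------------------------------------------------
# elementary scores on raw columns


def _snap(value: float) -> float:
    # clamp FP negatives, collapse numerically-zero scores to exact 0
    return 0.0 if value <= ZERO_TOL else float(value)


def mi(col_j: Sequence[str], col_k: Sequence[str]) -> float:
    """Plug-in mutual information of two row-paired columns, nats."""
    return _snap(column_entropy(col_j) + column_entropy(col_k)
                 - joint_entropy(col_j, col_k))


def mi3d(col_j: Sequence[str], col_k: Sequence[str], col_l: Sequence[str]) -> float:
    """Total correlation of three row-paired columns, nats.

    sum over joint states of P(j,k,l) log [P(j,k,l) / (P(j)P(k)P(l))],
    equal to H(J) + H(K) + H(L) - H(J;K;L); non-negative.
    """
    triples = [a + b + c for a, b, c in zip(col_j, col_k, col_l)]
    _, counts = np.unique(np.asarray(triples), return_counts=True)
    h_joint = entropy_from_counts(counts)
    return _snap(column_entropy(col_j) + column_entropy(col_k)
                 + column_entropy(col_l) - h_joint)


def apc(raw: Mapping[Key, float], j: int, k: int) -> float:
    """Average product correction mean_MI(j) * mean_MI(k) / mean_MI.

    Means are over the surviving pairs of ``raw`` containing the column
    (for the per-column means) and over all surviving pairs (overall).
    """
    j_vals = [v for key, v in raw.items() if j in key]
    k_vals = [v for key, v in raw.items() if k in key]
    if not j_vals or not k_vals or not raw:
        raise NoSurvivingPairsError(f"no surviving pairs for columns {j}, {k}")
    overall = float(np.mean(list(raw.values())))
    if overall == 0.0:
        raise ZeroMeanError("overall mean MI is zero")
    return float(np.mean(j_vals)) * float(np.mean(k_vals)) / overall


def cps(mi_values: Mapping[frozenset, float] | Mapping[Key, float],
        j: int, k: int, columns: Iterable[int]) -> float:
    """Coevolutionary pattern similarity: mean over third columns L of
    MI(j;L) * MI(k;L), L ranging over ``columns`` minus {j, k}."""
    def get(a: int, b: int) -> float:
        try:
            return mi_values[(a, b)]  # type: ignore[index]
        except (KeyError, TypeError):
            pass
        try:
            return mi_values[(b, a)]  # type: ignore[index]
        except (KeyError, TypeError):
            return mi_values[frozenset((a, b))]  # type: ignore[index]

    ls = [l for l in columns if l not in (j, k)]
    if not ls:
        raise NoSurvivingPairsError(f"no admissible third column for ({j},{k})")
    return float(np.mean([get(j, l) * get(k, l) for l in ls]))


def standardize_scores(raw: Mapping[Key, float]) -> tuple[dict[Key, float], float, float]:
    """Z-score a table over its own entries (sample sd); returns
    (standardized, mean, sd)."""
    if len(raw) < 2:
        raise DegenerateStandardizationError(
            f"{len(raw)} surviving entries; need at least 2 to standardise"
        )
    values = np.array(list(raw.values()), dtype=float)
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    if sd == 0.0:
        raise DegenerateStandardizationError("all surviving scores identical")
    return ({key: (v - mean) / sd for key, v in raw.items()}, mean, sd)


# ---------------------------------------------------------------------------
# fast encoded column machinery


class _Encoded:
    """Integer-coded eligible columns of one alignment."""

    def __init__(self, msa: PairedMSA, mask: ColumnMask):
        arr = msa.to_array()
        self.codes: dict[int, np.ndarray] = {}
        self.nstates: dict[int, int] = {}
        self.entropy: dict[int, float] = {}
        for col in range(msa.n_columns):
            if not mask.eligible[col]:
                continue
            _, inv = np.unique(arr[:, col], return_inverse=True)
            self.codes[col] = inv
            self.nstates[col] = int(inv.max()) + 1
            self.entropy[col] = entropy_from_counts(np.bincount(inv))
        self.d1 = mask.eligible_cols(msa.domain1_cols)
        self.d2 = mask.eligible_cols(msa.domain2_cols)

    def require(self, *cols: int) -> None:
        for c in cols:
            if c not in self.codes:
                raise IneligibleColumnError(f"column {c} is not eligible")

    def mi(self, j: int, k: int) -> float:
        self.require(j, k)
        joint = self.codes[j] * self.nstates[k] + self.codes[k]
        h_jk = entropy_from_counts(np.bincount(joint))
        return _snap(self.entropy[j] + self.entropy[k] - h_jk)

    def mi3d(self, j: int, k: int, l: int) -> float:
        self.require(j, k, l)
        joint = (self.codes[j] * self.nstates[k] + self.codes[k]
                 ) * self.nstates[l] + self.codes[l]
        h = entropy_from_counts(np.bincount(joint))
        return _snap(self.entropy[j] + self.entropy[k] + self.entropy[l] - h)

    def mi_matrix(self, columns: Sequence[int]) -> np.ndarray:
        """Symmetric plug-in MI matrix over the given columns (diag 0)."""
        n = len(columns)
        m = np.zeros((n, n))
        for a in range(n):
            for b in range(a + 1, n):
                m[a, b] = m[b, a] = self.mi(columns[a], columns[b])
        return m


# ---------------------------------------------------------------------------
# score tables


def _finalize(variant: str, raw: dict[Key, float],
              excluded: dict[Key, str]) -> PairScoreTable:
    if not raw:
        raise NoSurvivingPairsError(f"{variant}: every pair was excluded")
    std, mean, sd = standardize_scores(raw)
    return PairScoreTable(variant=variant, entries=raw, standardized=std,
                          excluded=excluded, mean=mean, sd=sd)


def _raw_inter_mi(enc: _Encoded) -> tuple[dict[Key, float], dict[Key, str]]:
    raw: dict[Key, float] = {}
    excluded: dict[Key, str] = {}
    for j in enc.d1:
        for k in enc.d2:
            value = enc.mi(j, k)
            if value == 0.0:
                excluded[(j, k)] = "zero_mi"
            else:
                raw[(j, k)] = value
    return raw, excluded


def mi_table(msa: PairedMSA, mask: ColumnMask) -> PairScoreTable:
    """Raw + standardised MI for every surviving inter-domain pair."""
    enc = _Encoded(msa, mask)
    if not enc.d1 or not enc.d2:
        raise NoSurvivingPairsError("a domain has no eligible columns")
    raw, excluded = _raw_inter_mi(enc)
    return _finalize("MI", raw, excluded)


def mip_table(msa: PairedMSA, mask: ColumnMask) -> PairScoreTable:
    """MIp = MI - APC over surviving inter-domain pairs.

    Zero-MI pairs are removed before the APC means are computed.
    """
    enc = _Encoded(msa, mask)
    if not enc.d1 or not enc.d2:
        raise NoSurvivingPairsError("a domain has no eligible columns")
    raw_mi, excluded = _raw_inter_mi(enc)
    if not raw_mi:
        raise NoSurvivingPairsError("MIp: every pair was excluded")
    raw = {key: raw_mi[key] - apc(raw_mi, *key) for key in raw_mi}
    return _finalize("MIp", raw, excluded)


def mic_table(msa: PairedMSA, mask: ColumnMask,
              cps_l_scope: str = "all") -> PairScoreTable:
    """MIc = MI - NCPS over surviving inter-domain pairs.

    CPS needs MI(J;L) and MI(K;L) for third columns L; with
    ``cps_l_scope="all"`` (default) L runs over every eligible column of
    both domains and the full (intra + inter) MI matrix is used, with
    n = total eligible columns in the Eq.-style 1/(n-2) average.  With
    ``"opposite_only"`` L is restricted to the eligible columns of the
    domain opposite J (minus K).  The NCPS normaliser is the square root
    of the mean CPS over the surviving inter-domain pairs in both cases.
    """
    if cps_l_scope not in {"all", "opposite_only"}:
        raise ValueError(f"unknown cps_l_scope {cps_l_scope!r}")
    enc = _Encoded(msa, mask)
    d1, d2 = enc.d1, enc.d2
    if not d1 or not d2:
        raise NoSurvivingPairsError("a domain has no eligible columns")
    columns = list(d1) + list(d2)
    index = {c: i for i, c in enumerate(columns)}
    m = enc.mi_matrix(columns)

    raw_mi, excluded = _raw_inter_mi(enc)
    if not raw_mi:
        raise NoSurvivingPairsError("MIc: every pair was excluded")

    prod = m @ m  # prod[a,b] = sum_L m[a,L] m[L,b]; diagonal of m is 0
    n_all = len(columns)
    cps_values: dict[Key, float] = {}
    for (j, k) in raw_mi:
        a, b = index[j], index[k]
        if cps_l_scope == "all":
            if n_all < 3:
                raise NoSurvivingPairsError("need >= 3 eligible columns for CPS")
            cps_values[(j, k)] = prod[a, b] / (n_all - 2)
        else:
            ls = [index[l] for l in d2 if l != k]
            if not ls:
                raise NoSurvivingPairsError("no admissible third column")
            cps_values[(j, k)] = float(
                np.mean(m[a, ls] * m[b, ls])
            )
    mean_cps = float(np.mean(list(cps_values.values())))
    if mean_cps <= 0.0:
        raise ZeroMeanError("mean inter-domain CPS is zero")
    ncps = {key: v / np.sqrt(mean_cps) for key, v in cps_values.items()}
    raw = {key: raw_mi[key] - ncps[key] for key in raw_mi}
    return _finalize("MIc", raw, excluded)


def enumerate_patch_triplets(
    msa: PairedMSA,
    mask: ColumnMask,
    intra_col_distances: Mapping[tuple[int, int], float],
    cutoff: float = PATCH_CUTOFF,
) -> PatchTriplets:
    """All (J, K, L) with J eligible in one domain and (K, L) an eligible
    same-patch pair (reference residues strictly closer than ``cutoff``)
    in the other domain.

    ``intra_col_distances`` maps unordered same-domain column pairs to the
    minimum inter-atomic distance of their reference residues (see
    :func:`micontact.structure.column_distances`).
    """
    d1 = set(mask.eligible_cols(msa.domain1_cols))
    d2 = set(mask.eligible_cols(msa.domain2_cols))
    triples: list[tuple[int, int, int]] = []
    for (a, b), dist in intra_col_distances.items():
        if not dist < cutoff:
            continue
        k, l = min(a, b), max(a, b)
        if k in d2 and l in d2:
            js = d1
        elif k in d1 and l in d1:
            js = d2
        else:
            continue
        triples.extend((j, k, l) for j in sorted(js))
    return PatchTriplets(triples=tuple(sorted(triples)))


def mi3d_table(msa: PairedMSA, mask: ColumnMask,
               triples: PatchTriplets) -> PairScoreTable:
    """Raw + standardised MI3D for every surviving patch triple."""
    enc = _Encoded(msa, mask)
    raw: dict[Key, float] = {}
    excluded: dict[Key, str] = {}
    for j, k, l in triples.triples:
        value = enc.mi3d(j, k, l)
        if value == 0.0:
            excluded[(j, k, l)] = "zero_mi"
        else:
            raw[(j, k, l)] = value
    return _finalize("MI3D", raw, excluded)


def apc3d(raw: Mapping[Key, float], j: int, k: int, l: int) -> float:
    """Product-of-means correction mean(j)*mean(k)*mean(l) / mean.

    Per-column means run over the surviving triples containing the column
    (in the J slot for the first-domain column, in either patch slot for
    the other two, which form an unordered pair).
    """
    def col_mean(col: int) -> float:
        vals = [v for key, v in raw.items() if col in key]
        if not vals:
            raise NoSurvivingPairsError(f"no surviving triples for column {col}")
        return float(np.mean(vals))

    overall = float(np.mean(list(raw.values())))
    if overall == 0.0:
        raise ZeroMeanError("overall mean MI3D is zero")
    return col_mean(j) * col_mean(k) * col_mean(l) / overall


def mip3d_table(msa: PairedMSA, mask: ColumnMask,
                triples: PatchTriplets) -> PairScoreTable:
    """MIp3D = MI3D - APC3D over surviving patch triples."""
    enc = _Encoded(msa, mask)
    raw_3d: dict[Key, float] = {}
    excluded: dict[Key, str] = {}
    for j, k, l in triples.triples:
        value = enc.mi3d(j, k, l)
        if value == 0.0:
            excluded[(j, k, l)] = "zero_mi"
        else:
            raw_3d[(j, k, l)] = value
    if not raw_3d:
        raise NoSurvivingPairsError("MIp3D: every triple was excluded")
    raw = {key: raw_3d[key] - apc3d(raw_3d, *key) for key in raw_3d}
    return _finalize("MIp3D", raw, excluded)


VARIANTS = ("MI", "MIp", "MIc", "MI3D", "MIp3D")


def score_table(msa: PairedMSA, mask: ColumnMask, variant: str,
                triples: PatchTriplets | None = None,
                cps_l_scope: str = "all") -> PairScoreTable:
    """Dispatch to the table builder for ``variant`` (see :data:`VARIANTS`).

    Reduced-alphabet variants are obtained by scoring a reduced alignment
    (:func:`micontact.msa.reduce_alphabet`) with the same builders.
    """
    if variant == "MI":
        return mi_table(msa, mask)
    if variant == "MIp":
        return mip_table(msa, mask)
    if variant == "MIc":
        return mic_table(msa, mask, cps_l_scope=cps_l_scope)
    if variant in {"MI3D", "MIp3D"}:
        if triples is None:
            raise ValueError(f"{variant} requires patch triples "
                             "(coordinates of the reference structure)")
        builder = mi3d_table if variant == "MI3D" else mip3d_table
        return builder(msa, mask, triples)
    raise ValueError(f"unknown variant {variant!r}")


# ---------------------------------------------------------------------------
# diagnostics


def zero_mi_diagnostic(msa: PairedMSA) -> tuple[float, float]:
    """(fraction of zero-entropy columns, fraction of zero-MI pairs).

    Both fractions are over the *ungapped* domain columns / inter-domain
    column pairs, with zero-entropy columns deliberately retained, so the
    direct effect of conserved columns on the zero-MI pair rate is
    visible (pairing any column with a fully conserved one yields MI 0).
    """
    arr = msa.to_array()

    def ungapped(cols: Iterable[int]) -> list[int]:
        return [c for c in cols if not (arr[:, c] == GAP).any()]

    d1, d2 = ungapped(msa.domain1_cols), ungapped(msa.domain2_cols)
    if not d1 or not d2:
        raise NoSurvivingPairsError("no ungapped columns in a domain")
    cols = d1 + d2
    codes, nstates, ent = {}, {}, {}
    for c in cols:
        _, inv = np.unique(arr[:, c], return_inverse=True)
        codes[c], nstates[c] = inv, int(inv.max()) + 1
        ent[c] = entropy_from_counts(np.bincount(inv))
    zero_cols = sum(1 for c in cols if ent[c] == 0.0)
    n_zero_pairs = 0
    for j in d1:
        for k in d2:
            joint = codes[j] * nstates[k] + codes[k]
            h_jk = entropy_from_counts(np.bincount(joint))
            if _snap(ent[j] + ent[k] - h_jk) == 0.0:
                n_zero_pairs += 1
    return zero_cols / len(cols), n_zero_pairs / (len(d1) * len(d2))
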