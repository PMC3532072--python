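"""Shannon entropies of alignment columns, in nats.

Column probabilities are plain empirical frequencies (no pseudocounts);
natural logarithms are used throughout so values are comparable across
mutual-information studies.  Per-alignment standardisation turns raw
entropies into z-scores over the eligible columns, using the sample
(n-1) standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    ColumnLengthMismatchError,
    DegenerateStandardizationError,
    EmptyColumnError,
)
from .msa import ColumnMask, PairedMSA


def _counts(column: Sequence[str]) -> np.ndarray:
    if len(column) == 0:
        raise EmptyColumnError("entropy of an empty column is undefined")
    _, counts = np.unique(np.asarray(list(column), dtype="U1"), return_counts=True)
    return counts


def entropy_from_counts(counts: np.ndarray) -> float:
    """-sum p log p with 0 log 0 := 0, for a vector of symbol counts."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n <= 0:
        raise EmptyColumnError("entropy of an empty column is undefined")
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def column_entropy(column: Sequence[str]) -> float:
    """Entropy of one alignment column (symbols as observed, nats)."""
    return entropy_from_counts(_counts(column))


def joint_entropy(col_j: Sequence[str], col_k: Sequence[str]) -> float:
    """Entropy of the empirical joint distribution of two row-paired columns."""
    if len(col_j) != len(col_k):
        raise ColumnLengthMismatchError(
            f"columns of length {len(col_j)} and {len(col_k)}"
        )
    pairs = [a + b for a, b in zip(col_j, col_k)]
    _, counts = np.unique(np.asarray(pairs), return_counts=True)
    return entropy_from_counts(counts)


@dataclass(frozen=True)
class EntropyProfile:
    """Raw and standardised per-column entropies of one alignment."""

    raw: np.ndarray           # nats; NaN for columns outside the mask
    standardized: np.ndarray  # z-scores; NaN for columns outside the mask
    mean: float
    sd: float

    def to_frame(self, msa: PairedMSA, mask: ColumnMask) -> pd.DataFrame:
        """Tabular export: column index, domain, eligibility, entropies."""
        rows = []
        for col in range(len(self.raw)):
            rows.append(
                {
                    "column": col,
                    "domain": msa.domain_of(col),
                    "reason": mask.reason[col],
                    "entropy": self.raw[col],
                    "entropy_std": self.standardized[col],
                }
            )
        return pd.DataFrame(rows)


def column_entropies(msa: PairedMSA) -> np.ndarray:
    """Raw entropy of every alignment column (gap treated as a symbol)."""
    arr = msa.to_array()
    return np.array(
        [entropy_from_counts(np.unique(arr[:, c], return_counts=True)[1])
         for c in range(msa.n_columns)]
    )


def standardize_entropies(raw: np.ndarray, mask: ColumnMask) -> EntropyProfile:
    """Z-score raw entropies over the eligible columns of one alignment.

    The mean and sample (n-1) standard deviation are computed over all
    eligible columns of the alignment combined; standardised values are
    defined only for those columns (NaN elsewhere).
    """
    raw = np.asarray(raw, dtype=float)
    elig = np.asarray(mask.eligible, dtype=bool)
    values = raw[elig]
    if values.size < 2:
        raise DegenerateStandardizationError(
            f"{values.size} eligible column(s); need at least 2"
        )
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    if sd == 0.0:
        raise DegenerateStandardizationError("all eligible entropies identical")
    out_raw = np.where(elig, raw, np.nan)
    std = np.where(elig, (raw - mean) / sd, np.nan)
    return EntropyProfile(raw=out_raw, standardized=std, mean=mean, sd=sd)


def entropy_profile(msa: PairedMSA, mask: ColumnMask) -> EntropyProfile:
    """Convenience: raw + standardised entropies for one alignment."""
    return standardize_entropies(column_entropies(msa), mask)
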