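"""Residue-level scoring and classifier evaluation.

A column-pair score table is collapsed to per-residue scores (by default
the maximum standardised score the residue's column achieves with any
partner), which are then evaluated as a binary classifier of contact
vs. non-contact surface residues (or surface vs. buried residues) with
precision-recall curves over percentile cutoffs, Matthews correlation
coefficients, subsampling stability, and a binomial top-k enrichment
test for single case studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .errors import EvaluationError, StabilityGateError
from .msa import ColumnMask, PairedMSA, build_mask, subsample
from .scores import PairScoreTable, PatchTriplets, score_table
from .structure import ResidueAnnotation


@dataclass(frozen=True)
class ResidueScore:
    domain: int
    resnum: int
    column: int
    score: float
    variant: str
    surface: bool
    contact: bool


@dataclass(frozen=True)
class PROCCurve:
    """Precision/recall over percentile score cutoffs.

    ``points`` is ordered by rising cutoff; the first point is the
    all-inclusive cutoff, where precision equals the baseline prevalence
    and recall is 1.
    """

    points: tuple[tuple[float, float, float], ...]  # (percentile, precision, recall)
    baseline: float
    positives: int
    total: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points,
                            columns=["percentile", "precision", "recall"])


@dataclass(frozen=True)
class StabilityResult:
    variant: str
    precisions: tuple[float, ...]  # one per subsample replicate
    mean: float
    sd: float
    stderr: float


@dataclass(frozen=True)
class TopKTestResult:
    k: int
    hits: int
    n_candidates: int
    n_positives: int
    expected: float
    p_value: float


def prevalence(n_positives: int, n_total: int) -> float:
    """Positive prevalence n_positives / n_total, the random-guess
    precision baseline of a P-ROC plot."""
    if n_total <= 0 or not 0 <= n_positives <= n_total:
        raise EvaluationError(f"bad counts {n_positives}/{n_total}")
    return n_positives / n_total


# ---------------------------------------------------------------------------
# residue scores


def residue_scores(
    table: PairScoreTable,
    annotations: Iterable[ResidueAnnotation],
    aggregation: str = "max",
) -> list[ResidueScore]:
    """Per-residue aggregated standardised scores.

    Each annotated residue receives the max (default) or mean of the
    standardised scores over all surviving pairs/triples containing its
    alignment column (any slot for triples).  Residues whose column
    appears in no surviving entry are dropped.
    """
    if aggregation not in {"max", "mean"}:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    if not table.entries:
        raise EvaluationError("empty score table")
    by_col: dict[int, list[float]] = {}
    for key, s in table.standardized.items():
        for col in key:
            by_col.setdefault(col, []).append(s)
    agg: Callable[[list[float]], float] = max if aggregation == "max" else \
        lambda v: float(np.mean(v))
    out = []
    for ann in annotations:
        if ann.column is None:
            raise EvaluationError(
                f"residue {(ann.domain, ann.resnum)} has no column; run "
                "annotate_columns first"
            )
        scores = by_col.get(ann.column)
        if scores is None:
            continue  # excluded column (gap / zero entropy / zero MI)
        out.append(ResidueScore(
            domain=ann.domain, resnum=ann.resnum, column=ann.column,
            score=agg(scores), variant=table.variant,
            surface=bool(ann.surface), contact=bool(ann.contact),
        ))
    return out


def _task_arrays(scores: Sequence[ResidueScore], task: str
                 ) -> tuple[np.ndarray, np.ndarray]:
    if task == "contact_vs_noncontact_surface":
        pool = [r for r in scores if r.surface]
        labels = np.array([r.contact for r in pool], dtype=bool)
    elif task == "surface_vs_buried":
        pool = list(scores)
        labels = np.array([r.surface for r in pool], dtype=bool)
    else:
        raise ValueError(f"unknown task {task!r}")
    values = np.array([r.score for r in pool], dtype=float)
    if values.size == 0 or labels.all() or not labels.any():
        raise EvaluationError(f"task {task}: need both classes present")
    return values, labels


def _confusion(values: np.ndarray, labels: np.ndarray, cutoff: float
               ) -> tuple[int, int, int, int]:
    pred = values >= cutoff
    tp = int((pred & labels).sum())
    fp = int((pred & ~labels).sum())
    fn = int((~pred & labels).sum())
    tn = int((~pred & ~labels).sum())
    return tp, fp, fn, tn


def _percentile_cutoffs(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # 1st..100th percentile grid plus an explicit all-inclusive cutoff
    percentiles = np.concatenate(([0.0], np.arange(1.0, 101.0)))
    return percentiles, np.percentile(values, percentiles)


def proc_curve(scores: Sequence[ResidueScore],
               task: str = "contact_vs_noncontact_surface") -> PROCCurve:
    """Precision-recall curve over percentile cutoffs of the scores.

    At each cutoff a residue scoring >= the cutoff is predicted positive.
    Tasks: ``contact_vs_noncontact_surface`` (positives = contacts,
    restricted to surface residues) or ``surface_vs_buried`` (positives =
    surface, all residues).
    """
    values, labels = _task_arrays(scores, task)
    percentiles, cutoffs = _percentile_cutoffs(values)
    n_pos = int(labels.sum())
    points = []
    for pct, cut in zip(percentiles, cutoffs):
        tp, fp, fn, _ = _confusion(values, labels, cut)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn)
        points.append((float(pct), precision, recall))
    return PROCCurve(points=tuple(points),
                     baseline=prevalence(n_pos, len(labels)),
                     positives=n_pos, total=len(labels))


def precision_at_recall(curve: PROCCurve, target_recall: float) -> float:
    """Precision at the highest cutoff whose recall still reaches the
    target (step convention, no interpolation)."""
    best = None
    for _, precision, recall in curve.points:
        if recall >= target_recall:
            best = precision  # points are ordered by rising cutoff
    if best is None:
        raise EvaluationError(f"no cutoff reaches recall {target_recall}")
    return best


def mcc_curve(scores: Sequence[ResidueScore],
              task: str = "contact_vs_noncontact_surface"
              ) -> tuple[np.ndarray, np.ndarray]:
    """(percentiles, MCC at each percentile cutoff); MCC set to 0 when a
    denominator factor vanishes."""
    values, labels = _task_arrays(scores, task)
    percentiles, cutoffs = _percentile_cutoffs(values)
    out = []
    for cut in cutoffs:
        tp, fp, fn, tn = _confusion(values, labels, cut)
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / np.sqrt(denom)
        out.append(mcc)
    return percentiles, np.array(out)


# ---------------------------------------------------------------------------
# subsampling stability


def stability_run(
    msa: PairedMSA,
    annotations: Sequence[ResidueAnnotation],
    variant: str,
    *,
    fraction: float = 0.7,
    n_reps: int = 100,
    seed: int = 0,
    target_recall: float = 0.2,
    aggregation: str = "max",
    triples: PatchTriplets | None = None,
    cps_l_scope: str = "all",
    min_sequences: int = 200,
    enforce_gate: bool = True,
) -> StabilityResult:
    """Replicate subsample -> rescore -> precision at ``target_recall``.

    Each replicate keeps ``fraction`` of the sequences (reference always
    retained), rebuilds the eligibility mask, recomputes the variant
    table and the contact-vs-non-contact precision at the target recall.
    The >= ``min_sequences`` gate ensures subsamples stay above the
    commonly recommended 125-sequence minimum for stable MI estimates.
    """
    if enforce_gate and msa.n_sequences < min_sequences:
        raise StabilityGateError(
            f"{msa.n_sequences} sequences < required {min_sequences}"
        )
    seeds = np.random.SeedSequence(seed).spawn(n_reps)
    precisions = []
    for ss in seeds:
        rep_seed = int(ss.generate_state(1)[0] % (2**31))
        sub = subsample(msa, fraction, rep_seed)
        mask = build_mask(sub)
        table = score_table(sub, mask, variant, triples=triples,
                            cps_l_scope=cps_l_scope)
        rs = residue_scores(table, annotations, aggregation)
        curve = proc_curve(rs, "contact_vs_noncontact_surface")
        precisions.append(precision_at_recall(curve, target_recall))
    arr = np.array(precisions)
    return StabilityResult(
        variant=variant,
        precisions=tuple(precisions),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        stderr=float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0,
    )


# ---------------------------------------------------------------------------
# case-study binomial test


def binomial_topk_test(candidates: Sequence[ResidueScore], k: int,
                       tie_policy: str = "expand") -> TopKTestResult:
    """Contacts among the top-k scored candidates vs. a binomial null.

    Under no score-contact relationship the hit count is
    Binomial(k, n_positives / n_candidates); the p-value is the upper
    tail P(X >= hits).  Ties at the k-th score either expand the
    selection (default, with a warning) or are truncated deterministically
    by (domain, column) order.
    """
    if k <= 0:
        raise EvaluationError("k must be positive")
    if not candidates:
        raise EvaluationError("empty candidate set")
    if k > len(candidates):
        raise EvaluationError(f"k={k} exceeds {len(candidates)} candidates")
    if tie_policy not in {"expand", "truncate"}:
        raise ValueError(f"unknown tie policy {tie_policy!r}")
    ordered = sorted(candidates,
                     key=lambda r: (-r.score, r.domain, r.column))
    kth_score = ordered[k - 1].score
    n_tied_selected = sum(1 for r in ordered[:k] if r.score == kth_score)
    n_tied_total = sum(1 for r in ordered if r.score == kth_score)
    if n_tied_total > n_tied_selected and tie_policy == "expand":
        k_eff = k + (n_tied_total - n_tied_selected)
        warnings.warn(
            f"{n_tied_total} candidates tie at the k-th score; "
            f"selection expanded to {k_eff}", stacklevel=2)
    else:
        k_eff = k
    selected = ordered[:k_eff]
    hits = sum(1 for r in selected if r.contact)
    n_cand, n_pos = len(candidates), sum(1 for r in candidates if r.contact)
    p = n_pos / n_cand
    return TopKTestResult(
        k=k_eff, hits=hits, n_candidates=n_cand, n_positives=n_pos,
        expected=k_eff * p,
        p_value=float(binom.sf(hits - 1, k_eff, p)),
    )
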