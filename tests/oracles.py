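"""Brute-force plug-in oracle for the score formulas.

Deliberately independent of the package internals: pure-python loops
over dictionaries with math.log, re-deriving eligibility, every entropy,
MI variant and standardisation from first principles.  Used to pin the
fast implementations to 1e-12 on small alignments.
"""

from __future__ import annotations

import math
from collections import Counter
from statistics import mean, stdev

GAP = "-"


def entropy_oracle(symbols) -> float:
    n = len(symbols)
    return -sum((c / n) * math.log(c / n) for c in Counter(symbols).values())


def joint_entropy_oracle(*columns) -> float:
    return entropy_oracle(list(zip(*columns)))


def mi_oracle(col_j, col_k) -> float:
    v = entropy_oracle(col_j) + entropy_oracle(col_k) - joint_entropy_oracle(col_j, col_k)
    return 0.0 if v <= 1e-12 else v


def mi3d_oracle(col_j, col_k, col_l) -> float:
    # direct triple sum over P(j,k,l) log [P(j,k,l)/(P(j)P(k)P(l))]
    n = len(col_j)
    pj = {s: c / n for s, c in Counter(col_j).items()}
    pk = {s: c / n for s, c in Counter(col_k).items()}
    pl = {s: c / n for s, c in Counter(col_l).items()}
    pjkl = {s: c / n for s, c in Counter(zip(col_j, col_k, col_l)).items()}
    v = sum(p * math.log(p / (pj[a] * pk[b] * pl[c]))
            for (a, b, c), p in pjkl.items())
    return 0.0 if v <= 1e-12 else v


def eligible_columns_oracle(msa):
    """Re-derive eligibility: domain column, ungapped, not conserved."""
    out = []
    for col in msa.domain_cols:
        column = [s[col] for s in msa.sequences]
        if GAP in column:
            continue
        if len(set(column)) == 1:
            continue
        out.append(col)
    return out


def standardize_oracle(values: dict) -> dict:
    m, s = mean(values.values()), stdev(values.values())
    return {k: (v - m) / s for k, v in values.items()}


def _column(msa, col):
    return [s[col] for s in msa.sequences]


def inter_mi_oracle(msa):
    """Surviving inter-domain MI pairs (zero-MI removed)."""
    elig = set(eligible_columns_oracle(msa))
    out = {}
    for j in msa.domain1_cols:
        for k in msa.domain2_cols:
            if j in elig and k in elig:
                v = mi_oracle(_column(msa, j), _column(msa, k))
                if v != 0.0:
                    out[(j, k)] = v
    return out


def mip_oracle(msa):
    raw = inter_mi_oracle(msa)
    overall = mean(raw.values())
    out = {}
    for (j, k), v in raw.items():
        mj = mean(x for key, x in raw.items() if j in key)
        mk = mean(x for key, x in raw.items() if k in key)
        out[(j, k)] = v - mj * mk / overall
    return out


def mic_oracle(msa):
    """MIc with L over all eligible columns of both domains (full matrix)."""
    elig = eligible_columns_oracle(msa)
    full = {}
    for i, a in enumerate(elig):
        for b in elig[i + 1:]:
            full[(a, b)] = full[(b, a)] = mi_oracle(_column(msa, a), _column(msa, b))
    raw = inter_mi_oracle(msa)
    n = len(elig)
    cps = {}
    for (j, k) in raw:
        ls = [l for l in elig if l not in (j, k)]
        cps[(j, k)] = sum(full[(j, l)] * full[(k, l)] for l in ls) / (n - 2)
    mean_cps = mean(cps.values())
    return {key: raw[key] - cps[key] / math.sqrt(mean_cps) for key in raw}


def mi3d_triples_oracle(msa, triples):
    out = {}
    for j, k, l in triples:
        v = mi3d_oracle(_column(msa, j), _column(msa, k), _column(msa, l))
        if v != 0.0:
            out[(j, k, l)] = v
    return out


def mip3d_oracle(msa, triples):
    raw = mi3d_triples_oracle(msa, triples)
    overall = mean(raw.values())
    out = {}
    for (j, k, l), v in raw.items():
        mj = mean(x for key, x in raw.items() if j in key)
        mk = mean(x for key, x in raw.items() if k in key)
        ml = mean(x for key, x in raw.items() if l in key)
        out[(j, k, l)] = v - mj * mk * ml / overall
    return out


def binom_upper_tail_oracle(hits: int, k: int, p: float) -> float:
    return sum(math.comb(k, i) * p**i * (1 - p) ** (k - i)
               for i in range(hits, k + 1))
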