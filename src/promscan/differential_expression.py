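"""Two-group differential expression for per-TSS count matrices.

The test is a conditional negative-binomial exact test with a single common
dispersion, in the classic style of count-based RNA expression testing:

1. library sizes are TMM-normalized (trimmed mean of M-values),
2. counts are scaled to a common effective library size (the geometric mean
   of the effective sizes) and rounded, so replicates are exchangeable,
3. per row, group sums are compared conditionally on their total: under a
   shared negative-binomial mean and the given dispersion, the probability of
   a split at least as extreme as observed is computed from the two group-sum
   distributions, two-sided by doubling the smaller tail (capped at 1),
4. Benjamini-Hochberg step-up controls FDR over the tested rows.

Rows failing the expression filter (fewer than ``min_samples`` samples at
``min_cpm`` in both groups) are called NOT_EXPRESSED and excluded from
testing and from the FDR correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DeResult",
    "tmm_factors",
    "estimate_common_dispersion",
    "nb_exact_test",
    "bh_fdr",
    "call_status",
    "run_de",
]

STATUS = ("UP", "DOWN", "UNCHANGED", "NOT_EXPRESSED")


@dataclass
class DeResult:
    tss_id: str
    cpm_a: float
    cpm_b: float
    log2_fc: float
    p_value: Optional[float]
    fdr: Optional[float] = None
    status: Optional[str] = None


# ---------------------------------------------------------------------------
# TMM normalization


def tmm_factors(
    counts: np.ndarray,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> np.ndarray:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    The reference sample is the one whose 75th-percentile CPM is closest to
    the mean 75th-percentile. M (log ratio) and A (log abundance) values are
    computed on rows positive in both samples; the top/bottom ``trim_m`` of M
    and ``trim_a`` of A are discarded and the remaining M are averaged with
    inverse-variance (delta method) weights.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a counts matrix with >= 2 samples")
    lib = x.sum(axis=0)
    for j, l in enumerate(lib):
        if l == 0:
            raise ValueError(f"sample {j} has all-zero counts")
    uq = np.array(
        [np.quantile(x[:, j][x[:, j] > 0], 0.75) / lib[j] for j in range(x.shape[1])]
    )
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(x.shape[1])
    for j in range(x.shape[1]):
        if j == ref:
            continue
        ok = (x[:, j] > 0) & (x[:, ref] > 0)
        if not np.any(ok):
            continue
        yj, yr = x[ok, j], x[ok, ref]
        m = np.log2((yj / lib[j]) / (yr / lib[ref]))
        a = 0.5 * np.log2((yj / lib[j]) * (yr / lib[ref]))
        w = 1.0 / ((lib[j] - yj) / (lib[j] * yj) + (lib[ref] - yr) / (lib[ref] * yr))
        # doubly trimmed mean
        finite = np.isfinite(m) & np.isfinite(a) & np.isfinite(w)
        m, a, w = m[finite], a[finite], w[finite]
        if len(m) == 0:
            continue
        lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not np.any(keep):
            keep = np.ones_like(m, dtype=bool)
        factors[j] = 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
    # normalize to geometric mean 1
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


# ---------------------------------------------------------------------------
# Dispersion


def estimate_common_dispersion(
    counts: np.ndarray, groups: Sequence[str]
) -> float:
    """Pooled method-of-moments NB dispersion after library-size scaling.

    Counts are scaled to the mean library size, then for every row and group
    the sample mean and variance contribute to the pooled estimate
    ``phi = sum(var - mean) / sum(mean^2)`` (regression through the origin of
    the NB variance law var = mu + phi*mu^2), floored at 0.
    """
    x = np.asarray(counts, dtype=float)
    groups = np.asarray(groups)
    if x.shape[0] == 1:
        warnings.warn("single-row input: dispersion estimate is low-information")
    lib = x.sum(axis=0)
    lib = np.where(lib == 0, 1.0, lib)
    scaled = x / lib * lib.mean()
    num = 0.0
    den = 0.0
    for g in np.unique(groups):
        sub = scaled[:, groups == g]
        if sub.shape[1] < 2:
            continue
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        num += float(np.sum(v[ok] - m[ok]))
        den += float(np.sum(m[ok] ** 2))
    if den == 0:
        return 0.0
    return max(0.0, num / den)


# ---------------------------------------------------------------------------
# Exact test


def _group_sum_pmf(total: int, n: int, mu: float, dispersion: float) -> np.ndarray:
    """pmf of a sum of n iid NB(mu, dispersion) at 0..total.

    The sum of n iid NB with mean mu and dispersion phi is NB with mean n*mu
    and dispersion phi/n. dispersion 0 degenerates to Poisson.
    """
    k = np.arange(total + 1)
    if dispersion == 0.0:
        return stats.poisson.pmf(k, n * mu)
    size = n / dispersion  # NB "number of successes" r = 1/(phi/n)
    p = size / (size + n * mu)
    return stats.nbinom.pmf(k, size, p)


def _exact_p(
    sum_a: int, sum_b: int, n_a: int, n_b: int, dispersion: float
) -> float:
    """Conditional two-sided exact p for a group-sum split."""
    total = sum_a + sum_b
    if total == 0:
        return 1.0
    mu = total / (n_a + n_b)
    pmf_a = _group_sum_pmf(total, n_a, mu, dispersion)
    pmf_b = _group_sum_pmf(total, n_b, mu, dispersion)
    joint = pmf_a * pmf_b[::-1]  # P(A=k, B=total-k), k = 0..total
    denom = joint.sum()
    if denom <= 0:
        return 1.0
    cond = joint / denom
    lower = float(cond[: sum_a + 1].sum())
    upper = float(cond[sum_a:].sum())
    return min(1.0, 2.0 * min(lower, upper))


def nb_exact_test(
    counts: np.ndarray,
    groups: Sequence[str],
    dispersion: float,
    row_ids: Optional[Sequence[str]] = None,
    lib_sizes: Optional[np.ndarray] = None,
    norm_factors: Optional[np.ndarray] = None,
) -> List[DeResult]:
    """Row-wise conditional NB exact test between the two groups.

    Counts are first scaled (and rounded) to the geometric mean of effective
    library sizes so that replicates within and across groups share a common
    mean under the null.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    x = np.asarray(counts, dtype=float)
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups.tolist()))
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    mask_a = groups == labels[0]
    mask_b = groups == labels[1]
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("each group needs >= 2 samples")

    lib = x.sum(axis=0) if lib_sizes is None else np.asarray(lib_sizes, float)
    nf = np.ones(x.shape[1]) if norm_factors is None else np.asarray(norm_factors)
    eff = lib * nf
    common = float(np.exp(np.mean(np.log(eff))))
    pseudo = np.rint(x / eff * common).astype(np.int64)

    cpm = x / eff * 1e6
    cpm_a = cpm[:, mask_a].mean(axis=1)
    cpm_b = cpm[:, mask_b].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2((cpm_b + 0.5 * 1e6 / common) / (cpm_a + 0.5 * 1e6 / common))

    ids = list(row_ids) if row_ids is not None else [str(i) for i in range(len(x))]
    results = []
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    for i in range(x.shape[0]):
        sa = int(pseudo[i, mask_a].sum())
        sb = int(pseudo[i, mask_b].sum())
        p = _exact_p(sa, sb, n_a, n_b, dispersion)
        results.append(
            DeResult(
                tss_id=ids[i],
                cpm_a=float(cpm_a[i]),
                cpm_b=float(cpm_b[i]),
                log2_fc=float(lfc[i]),
                p_value=p,
            )
        )
    return results


# ---------------------------------------------------------------------------
# BH-FDR and status calls


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    if n == 0:
        return np.array([])
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def call_status(
    results: Sequence[DeResult],
    counts: np.ndarray,
    groups: Sequence[str],
    alpha: float = 0.05,
    min_cpm: float = 1.0,
    min_samples: int = 2,
    lib_sizes: Optional[np.ndarray] = None,
    norm_factors: Optional[np.ndarray] = None,
) -> List[DeResult]:
    """Apply the expression filter, BH-FDR over tested rows, and status calls.

    NOT_EXPRESSED: fewer than ``min_samples`` samples reach ``min_cpm`` in
    both groups (such rows are excluded from the FDR correction). Otherwise
    UP/DOWN by log2FC sign when fdr < alpha, else UNCHANGED.
    """
    x = np.asarray(counts, dtype=float)
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups.tolist()))
    mask_a = groups == labels[0]
    mask_b = groups == labels[1]
    lib = x.sum(axis=0) if lib_sizes is None else np.asarray(lib_sizes, float)
    nf = np.ones(x.shape[1]) if norm_factors is None else np.asarray(norm_factors)
    cpm = x / (lib * nf) * 1e6

    expressed = np.zeros(x.shape[0], dtype=bool)
    for i in range(x.shape[0]):
        ok_a = int(np.sum(cpm[i, mask_a] >= min_cpm))
        ok_b = int(np.sum(cpm[i, mask_b] >= min_cpm))
        expressed[i] = (ok_a >= min_samples) or (ok_b >= min_samples)

    tested_idx = [i for i in range(len(results)) if expressed[i]]
    fdr = bh_fdr([results[i].p_value for i in tested_idx])
    out = list(results)
    for rank, i in enumerate(tested_idx):
        r = out[i]
        r.fdr = float(fdr[rank])
        if r.fdr < alpha:
            r.status = "UP" if r.log2_fc > 0 else "DOWN"
        else:
            r.status = "UNCHANGED"
    for i in range(len(out)):
        if not expressed[i]:
            out[i].fdr = None
            out[i].p_value = out[i].p_value  # p retained for transparency
            out[i].status = "NOT_EXPRESSED"
    return out


def run_de(
    counts: np.ndarray,
    groups: Sequence[str],
    row_ids: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
    min_cpm: float = 1.0,
    min_samples: int = 2,
    dispersion: Optional[float] = None,
) -> pd.DataFrame:
    """Full two-group pipeline: TMM, dispersion, exact test, FDR, status."""
    x = np.asarray(counts, dtype=float)
    nf = tmm_factors(x)
    lib = x.sum(axis=0)
    if dispersion is None:
        dispersion = estimate_common_dispersion(x, groups)
    results = nb_exact_test(
        x, groups, dispersion, row_ids=row_ids, lib_sizes=lib, norm_factors=nf
    )
    results = call_status(
        results,
        x,
        groups,
        alpha=alpha,
        min_cpm=min_cpm,
        min_samples=min_samples,
        lib_sizes=lib,
        norm_factors=nf,
    )
    return pd.DataFrame(
        {
            "tss_id": [r.tss_id for r in results],
            "cpm_a": [r.cpm_a for r in results],
            "cpm_b": [r.cpm_b for r in results],
            "log2_fc": [r.log2_fc for r in results],
            "p_value": [r.p_value for r in results],
            "fdr": [r.fdr for r in results],
            "status": [r.status for r in results],
        }
    )
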