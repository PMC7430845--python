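"""Cross-model bookkeeping statistics: percentage tables, rank tests, ECDFs,
Z-score matrices, and annotation-based isoform-diversity counts."""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import TranscriptModel

__all__ = [
    "round_half_up",
    "mann_whitney_u",
    "ecdf_table",
    "zscore_matrix",
    "crosstab_percentages",
    "isoform_diversity",
    "IsoformDiversity",
]


def round_half_up(x: float, decimals: int) -> float:
    """Decimal half-up rounding (0.5 rounds away from zero), as in printed
    percentage tables; numpy/python banker's rounding would differ."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Mann-Whitney U

EXACT_LIMIT = 12  # pooled size at or below which the exact null is enumerated


def mann_whitney_u(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> Tuple[float, float]:
    """Two-sided Mann-Whitney U with midranks.

    Exact p by full enumeration of label assignments when the pooled sample
    size is at most 12 (valid with ties); otherwise the normal approximation
    with tie and continuity corrections. Returns (U of sample_a, p).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        n_a = len(a)
        return n_a * len(b) / 2.0, 1.0

    ranks = stats.rankdata(pooled)  # midranks
    n_a, n_b = len(a), len(b)
    u_a = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)

    if n_a + n_b <= EXACT_LIMIT:
        # enumerate all C(n, n_a) assignments of the pooled values to group A
        mean_u = n_a * n_b / 2.0
        obs_dev = abs(u_a - mean_u)
        n_total = n_a + n_b
        count = 0
        total = 0
        for combo in itertools.combinations(range(n_total), n_a):
            u = float(ranks[list(combo)].sum() - n_a * (n_a + 1) / 2.0)
            total += 1
            if abs(u - mean_u) >= obs_dev - 1e-9:
                count += 1
        return u_a, count / total

    # normal approximation with tie correction
    _, counts = np.unique(pooled, return_counts=True)
    n = n_a + n_b
    tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
    sigma2 = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return u_a, 1.0
    mean_u = n_a * n_b / 2.0
    z = (abs(u_a - mean_u) - 0.5) / math.sqrt(sigma2)  # continuity correction
    p = 2.0 * stats.norm.sf(max(z, 0.0))
    return u_a, min(p, 1.0)


# ---------------------------------------------------------------------------
# ECDF


def ecdf_table(
    values_by_class: Mapping[str, Sequence[float]],
    log10_transform: bool = True,
    zero_policy: str = "exclude",
    pseudo_value: Optional[float] = None,
) -> pd.DataFrame:
    """Empirical CDF per class, on log10 values by default.

    Zeros are excluded (with their count recorded in the ``n_zero_excluded``
    column) unless ``zero_policy='offset'``, in which case ``pseudo_value`` is
    added before the log.
    """
    rows: List[pd.DataFrame] = []
    for label, values in values_by_class.items():
        v = np.asarray(values, dtype=float)
        if np.any(v < 0):
            raise ValueError("ECDF values must be >= 0")
        n_zero = 0
        if log10_transform:
            if zero_policy == "offset":
                if pseudo_value is None or pseudo_value <= 0:
                    raise ValueError("offset policy needs a positive pseudo_value")
                v = v + pseudo_value
            else:
                n_zero = int(np.sum(v == 0))
                v = v[v > 0]
            v = np.log10(v)
        if len(v) == 0:
            continue
        v = np.sort(v)
        frac = np.arange(1, len(v) + 1) / len(v)
        rows.append(
            pd.DataFrame(
                {
                    "class": label,
                    "value": v,
                    "cumulative_fraction": frac,
                    "n_zero_excluded": n_zero,
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["class", "value", "cumulative_fraction", "n_zero_excluded"]
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Z-scores


def zscore_matrix(
    counts_by_sample: np.ndarray, row_ids: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Per-row Z-scores (population sd); constant rows map to all zeros and
    are flagged in the ``constant`` column."""
    x = np.asarray(counts_by_sample, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 samples")
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)  # population sd
    constant = (sd[:, 0] == 0.0)
    safe_sd = np.where(sd == 0.0, 1.0, sd)
    z = (x - mean) / safe_sd
    z[constant, :] = 0.0
    df = pd.DataFrame(z)
    df.insert(0, "row_id", list(row_ids) if row_ids is not None else range(len(df)))
    df["constant"] = constant
    return df


# ---------------------------------------------------------------------------
# Percentage cross-tabs


def crosstab_percentages(
    set_sizes: Mapping[str, Tuple[int, int]], decimals: int = 1
) -> pd.DataFrame:
    """Percentages from (numerator, denominator) pairs at a stated printed
    precision, using half-up rounding."""
    rows = []
    for label, (num, den) in set_sizes.items():
        if den <= 0:
            raise ValueError(f"{label}: denominator must be positive")
        if num > den:
            raise ValueError(f"{label}: numerator {num} exceeds denominator {den}")
        rows.append(
            {
                "label": label,
                "count": num,
                "denominator": den,
                "percent": round_half_up(100.0 * num / den, decimals),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Isoform diversity


@dataclass(frozen=True)
class IsoformDiversity:
    gene_id: str
    n_distinct_tss: int
    n_distinct_cds: int
    multi_tss: bool
    multi_cds: bool


def isoform_diversity(
    transcripts: Iterable[TranscriptModel], tss_merge_distance: int = 0
) -> List[IsoformDiversity]:
    """Per-gene counts of distinct annotated TSS positions and distinct
    coding sequences.

    TSS positions within ``tss_merge_distance`` bp of each other (chained,
    same strand) merge into one; the default 0 counts exactly distinct
    positions. Distinct CDS counts ignore transcripts with an empty cds_key.
    """
    by_gene: Dict[str, List[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    out = []
    for gene_id in sorted(by_gene):
        ts = by_gene[gene_id]
        n_tss = 0
        for strand in ("+", "-", "."):
            positions = sorted(
                {t.tss_position for t in ts if t.span.strand == strand}
            )
            if not positions:
                continue
            n = 1
            for prev, cur in zip(positions, positions[1:]):
                if cur - prev > tss_merge_distance:
                    n += 1
            n_tss += n
        cds = {t.cds_key for t in ts if t.cds_key}
        out.append(
            IsoformDiversity(
                gene_id=gene_id,
                n_distinct_tss=n_tss,
                n_distinct_cds=len(cds),
                multi_tss=n_tss >= 2,
                multi_cds=len(cds) >= 2,
            )
        )
    return out
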