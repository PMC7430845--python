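"""Tau tissue-specificity scores over a multi-tissue expression matrix.

Tau for a profile x over n tissues is

    tau = sum_i (1 - x_hat_i) / (n - 1),   x_hat_i = x_i / max(x)

so 0 means equal (ubiquitous) expression and 1 means expression confined to a
single tissue. By default expression is transformed to log2(CPM + 1) before
scoring, which tempers the weight of the dominant tissue; raw mode is
available (``log_transform=False``). All-zero profiles cannot be scored and
are excluded with a reason code.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["TauResult", "tau_score", "tau_table", "normalized_tissue_components"]


@dataclass(frozen=True)
class TauResult:
    tss_id: str
    tau: float
    argmax_tissue: str
    x_hat: np.ndarray  # normalized profile, max component = 1
    excluded_reason: Optional[str] = None


def _to_cpm(counts: np.ndarray, library_sizes: Optional[np.ndarray]) -> np.ndarray:
    if library_sizes is None:
        return counts.astype(float)
    lib = np.asarray(library_sizes, dtype=float)
    lib = np.where(lib == 0, 1.0, lib)
    return counts / lib * 1e6


def tau_score(
    profile: Sequence[float],
    tissues: Optional[Sequence[str]] = None,
    log_transform: bool = True,
    tss_id: str = "",
) -> TauResult:
    """Tau of one expression profile (CPM scale).

    The transform (default log2(CPM+1)) is applied before normalizing by the
    maximum; tau is guaranteed to lie in [0, 1].
    """
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("profile must be 1-D with >= 2 tissues")
    if np.any(x < 0):
        raise ValueError("expression must be >= 0")
    names = list(tissues) if tissues is not None else [str(i) for i in range(len(x))]
    if len(names) != len(x):
        raise ValueError("tissue names must match profile length")
    if np.all(x == 0):
        return TauResult(
            tss_id=tss_id,
            tau=float("nan"),
            argmax_tissue="",
            x_hat=np.zeros_like(x),
            excluded_reason="all_zero",
        )
    t = np.log2(x + 1.0) if log_transform else x
    x_hat = t / t.max()
    n = len(x)
    tau = float(np.sum(1.0 - x_hat) / (n - 1))
    return TauResult(
        tss_id=tss_id,
        tau=tau,
        argmax_tissue=names[int(np.argmax(t))],
        x_hat=x_hat,
    )


def tau_table(
    counts: pd.DataFrame,
    library_sizes: Optional[np.ndarray] = None,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Tau per row of a TSS x tissue count matrix.

    Returns columns tau, argmax_tissue, excluded_reason plus one ``xhat_*``
    column per tissue. Rows with all-zero expression carry NaN tau.
    """
    cpm = _to_cpm(counts.to_numpy(dtype=float), library_sizes)
    rows = []
    for i, tss_id in enumerate(counts.index):
        res = tau_score(
            cpm[i], tissues=counts.columns, log_transform=log_transform,
            tss_id=str(tss_id),
        )
        row = {
            "tss_id": res.tss_id,
            "tau": res.tau,
            "argmax_tissue": res.argmax_tissue,
            "excluded_reason": res.excluded_reason,
        }
        row.update({f"xhat_{t}": v for t, v in zip(counts.columns, res.x_hat)})
        rows.append(row)
    return pd.DataFrame(rows).set_index("tss_id")


def normalized_tissue_components(
    tau_results: pd.DataFrame, classes: Optional[pd.Series] = None
) -> pd.DataFrame:
    """Per-tissue distribution summaries of the normalized components x_hat.

    Given the output of :func:`tau_table` (optionally with a class label per
    TSS), reports median and 5th/95th percentiles of x_hat per tissue (per
    class when given).
    """
    xhat_cols = [c for c in tau_results.columns if c.startswith("xhat_")]
    scored = tau_results[tau_results["excluded_reason"].isna()]
    if classes is None:
        groups = {"all": scored}
    else:
        groups = {
            str(label): scored.loc[scored.index.intersection(idx)]
            for label, idx in classes.groupby(classes).groups.items()
        }
    rows = []
    for label, sub in groups.items():
        if len(sub) == 0:
            continue
        for col in xhat_cols:
            v = sub[col].to_numpy()
            rows.append(
                {
                    "class": label,
                    "tissue": col[len("xhat_"):],
                    "median": float(np.median(v)),
                    "p05": float(np.percentile(v, 5)),
                    "p95": float(np.percentile(v, 95)),
                    "n": len(v),
                }
            )
    return pd.DataFrame(rows)
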