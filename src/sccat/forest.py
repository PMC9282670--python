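"""Per-item effect sizes between label groups, as forest-plot data.

Each item column is first standardised to mean 0, SD 1 over the whole
cohort, then the standardised mean difference (SMD, Cohen's d with pooled
SD) between the cancer and non-cancer groups is computed with its
normal-approximation 95% CI.  Positive SMD means the cancer group scores
higher.  Cochran's Q with inverse-variance weights tests heterogeneity of
the 30 effects.  The pre-standardisation is affinely redundant for an SMD
but kept because it defines the plotted scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .item_bank import ItemBank

__all__ = [
    "SmdRecord",
    "ForestSummary",
    "smd_per_item",
    "heterogeneity",
    "forest_summary",
    "export_forest",
]

Z_95 = 1.96


@dataclass(frozen=True)
class SmdRecord:
    item_id: int
    smd: float
    se_smd: float
    ci_low: float
    ci_high: float
    weight: float  # inverse variance
    text: str = ""


@dataclass
class ForestSummary:
    records: list[SmdRecord]
    heterogeneity_q: float
    q_df: int
    q_pvalue: float
    pooled_smd: float = field(default=float("nan"))


def _cohens_d(x1: np.ndarray, x0: np.ndarray) -> tuple[float, float]:
    """Pooled-SD standardised mean difference and its SE."""
    n1, n0 = len(x1), len(x0)
    s1, s0 = x1.var(ddof=1), x0.var(ddof=1)
    pooled = math.sqrt(((n1 - 1) * s1 + (n0 - 1) * s0) / (n1 + n0 - 2))
    if pooled == 0:
        raise ValueError("degenerate groups: zero pooled SD")
    d = (x1.mean() - x0.mean()) / pooled
    se = math.sqrt((n1 + n0) / (n1 * n0) + d**2 / (2 * (n1 + n0)))
    return d, se


def smd_per_item(cohort: Cohort, bank: ItemBank | None = None) -> list[SmdRecord]:
    """SMD (cancer minus non-cancer) per item, on the z-scored columns."""
    y = cohort.labels
    if not (np.any(y == 1) and np.any(y == 0)):
        raise ValueError("both label groups must be non-empty")
    records = []
    for j in range(cohort.n_items):
        col = cohort.responses[:, j].astype(float)
        sd = col.std(ddof=1)
        z = (col - col.mean()) / sd if sd > 0 else col - col.mean()
        d, se = _cohens_d(z[y == 1], z[y == 0])
        records.append(
            SmdRecord(
                item_id=j + 1,
                smd=d,
                se_smd=se,
                ci_low=d - Z_95 * se,
                ci_high=d + Z_95 * se,
                weight=1.0 / se**2,
                text=bank[j + 1].text if bank is not None else "",
            )
        )
    return records


def heterogeneity(records: list[SmdRecord]) -> tuple[float, int, float]:
    """Cochran's Q over the item effects: Q, df, chi-square p-value."""
    if len(records) < 2:
        raise ValueError("heterogeneity needs at least 2 records")
    d = np.array([r.smd for r in records])
    w = np.array([r.weight for r in records])
    pooled = float(np.sum(w * d) / np.sum(w))
    q = float(np.sum(w * (d - pooled) ** 2))
    df = len(records) - 1
    p = float(stats.chi2.sf(q, df))
    return q, df, p


def forest_summary(cohort: Cohort, bank: ItemBank | None = None) -> ForestSummary:
    """Full forest-plot summary: per-item SMDs plus the heterogeneity test."""
    records = smd_per_item(cohort, bank)
    q, df, p = heterogeneity(records)
    d = np.array([r.smd for r in records])
    w = np.array([r.weight for r in records])
    return ForestSummary(
        records=records,
        heterogeneity_q=q,
        q_df=df,
        q_pvalue=p,
        pooled_smd=float(np.sum(w * d) / np.sum(w)),
    )


def export_forest(
    summary: ForestSummary, path: str | Path, plot_path: str | Path | None = None
) -> None:
    """Write forest CSV (ordered by item_id) and the heterogeneity JSON
    sidecar; optionally render a static forest plot."""
    path = Path(path)
    rows = [
        {
            "item_id": r.item_id,
            "text": r.text,
            "smd": r.smd,
            "se": r.se_smd,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "weight": r.weight,
        }
        for r in sorted(summary.records, key=lambda r: r.item_id)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(
            {
                "heterogeneity_q": summary.heterogeneity_q,
                "q_df": summary.q_df,
                "q_pvalue": summary.q_pvalue,
                "pooled_smd": summary.pooled_smd,
            },
            fh,
            indent=1,
        )
    if plot_path is not None:
        _plot_forest(summary, plot_path)


def _plot_forest(summary: ForestSummary, plot_path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    recs = sorted(summary.records, key=lambda r: r.item_id, reverse=True)
    ys = np.arange(len(recs))
    fig, ax = plt.subplots(figsize=(6, 0.28 * len(recs) + 1.5))
    for y, r in zip(ys, recs):
        ax.plot([r.ci_low, r.ci_high], [y, y], color="0.3", lw=1)
        ax.plot(r.smd, y, "s", color="green", ms=5)
    ax.axvline(0.0, color="k", lw=0.8, ls="--")
    ax.set_yticks(ys)
    ax.set_yticklabels([f"item {r.item_id}" for r in recs], fontsize=7)
    ax.set_xlabel("standardized mean difference (cancer - non-cancer)")
    ax.set_title(f"Q = {summary.heterogeneity_q:.1f}, df = {summary.q_df}, p = {summary.q_pvalue:.3g}")
    fig.tight_layout()
    fig.savefig(plot_path, dpi=150)
    plt.close(fig)
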