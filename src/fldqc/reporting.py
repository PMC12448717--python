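"""QC-table assembly, threshold filtering, and FLD density plotting.

The QC table holds one row per barcode with the periodicity score and the
companion metrics; filter rules are simple per-metric bounds whose
conjunction defines the retained cell set. When a reference barcode list
(e.g. the set retained by an independent pipeline) is supplied, the report
also carries reference coverage (retained ∩ reference / |reference|) and
exclusivity (retained cells absent from the reference).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fragments import FLDHistogram

__all__ = [
    "FilterRule",
    "FilterReport",
    "build_qc_table",
    "apply_filters",
    "write_qc_table",
    "read_qc_table",
    "group_mean_fld",
    "plot_fld_density",
]


@dataclass(frozen=True)
class FilterRule:
    """Keep cells with lower <= metric <= upper (either bound optional).

    The periodicity score needs only a lower bound; metrics with
    non-linear behaviour (mNSC) typically need both.
    """

    metric: str
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self):
        if self.lower is None and self.upper is None:
            raise ValueError("rule needs at least one bound")
        if self.lower is not None and self.upper is not None and self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")

    def mask(self, values: pd.Series) -> pd.Series:
        ok = pd.Series(True, index=values.index)
        if self.lower is not None:
            ok &= values >= self.lower
        if self.upper is not None:
            ok &= values <= self.upper
        return ok.fillna(False)


@dataclass(frozen=True)
class FilterReport:
    n_total: int
    n_retained: int
    reference_coverage: float | None = None  # |retained ∩ ref| / |ref|
    n_exclusive: int | None = None  # retained cells not in the reference


def build_qc_table(
    scores: Mapping[str, "object"] | None = None,
    metrics: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Merge per-barcode score results and the metric table into one QC
    table indexed by barcode."""
    parts = []
    if scores is not None:
        parts.append(
            pd.DataFrame.from_dict(
                {
                    bc: {
                        "fld_score": r.fld_score,
                        "n_fragments_used": r.n_fragments_used,
                        "downsampled": r.downsampled,
                        "flag": r.flag,
                    }
                    for bc, r in scores.items()
                },
                orient="index",
            )
        )
    if metrics is not None:
        parts.append(metrics)
    if not parts:
        raise ValueError("nothing to assemble")
    df = parts[0]
    for p in parts[1:]:
        df = df.join(p, how="outer")
    df.index.name = "barcode"
    return df


def apply_filters(
    table: pd.DataFrame,
    rules: Sequence[FilterRule],
    reference: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Mark each cell pass/fail per rule and overall.

    Adds one boolean ``pass_<metric>`` column per rule and ``pass_all``
    (their conjunction; all-True with no rules). Rule order is
    irrelevant. Cells with NaN in a filtered metric fail that rule.
    """
    out = table.copy()
    overall = pd.Series(True, index=out.index)
    for rule in rules:
        if rule.metric not in out.columns:
            raise KeyError(f"unknown metric {rule.metric!r}")
        col = rule.mask(out[rule.metric])
        out[f"pass_{rule.metric}"] = col
        overall &= col
    out["pass_all"] = overall
    retained = set(out.index[overall])
    coverage = None
    n_exclusive = None
    if reference is not None:
        ref = set(reference)
        coverage = len(retained & ref) / len(ref) if ref else math.nan
        n_exclusive = len(retained - ref)
    report = FilterReport(len(out), len(retained), coverage, n_exclusive)
    return out, report


def write_qc_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t")


def read_qc_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="barcode")
    if "flag" in df.columns:
        df["flag"] = df["flag"].fillna("")
    return df


def group_mean_fld(
    histograms: Mapping[str, FLDHistogram], barcodes: Sequence[str]
) -> np.ndarray:
    """Mean of per-cell normalized (unit-sum) fragment length histograms.

    Cells with zero fragments contribute a zero curve.
    """
    if len(barcodes) == 0:
        raise ValueError("empty group")
    curves = []
    for bc in barcodes:
        h = histograms[bc]
        total = h.total
        curves.append(h.counts / total if total > 0 else np.zeros_like(h.counts, dtype=float))
    return np.mean(curves, axis=0)


def plot_fld_density(
    histograms: Mapping[str, FLDHistogram],
    groups: Mapping[str, str],
    path: str | Path,
    *,
    max_cells_per_group: int = 200,
) -> Path:
    """Per-group FLD density plot: individual normalized cell curves at low
    alpha plus the group mean overlay. Deterministic for fixed inputs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = sorted(set(groups.values()))
    if not labels:
        raise ValueError("no groups to plot")
    members = {
        lab: [bc for bc, g in groups.items() if g == lab] for lab in labels
    }
    for lab, bcs in members.items():
        if not bcs:
            raise ValueError(f"empty group {lab!r}")
    fig, axes = plt.subplots(
        len(labels), 1, figsize=(7, 2.6 * len(labels)), squeeze=False, sharex=True
    )
    for ax, lab in zip(axes[:, 0], labels):
        bcs = members[lab][:max_cells_per_group]
        for bc in bcs:
            h = histograms[bc]
            if h.total > 0:
                ax.plot(h.counts / h.total, color="steelblue", alpha=0.08, lw=0.6)
        mean_curve = group_mean_fld(histograms, members[lab])
        ax.plot(mean_curve, color="crimson", lw=1.5, label="group mean")
        ax.set_ylabel("density")
        ax.set_title(f"{lab} (n={len(members[lab])})", fontsize=9)
        ax.legend(frameon=False, fontsize=8)
    axes[-1, 0].set_xlabel("fragment length (bp)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
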