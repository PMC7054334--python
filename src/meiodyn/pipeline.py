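"""End-to-end orchestration: simulate -> dynamics -> NDR -> report.

The pipeline chains the analysis modules the way the study design dictates:
de novo/common split of the target stage against premeiotic prior stages,
hotspot association, presence matrix over the four classification stages,
turnover classification; and, on the NOMe side, depth filtering, NDR
calling, TSS-proximal/distal annotation, hotspot-NDR partition and
accessibility ratios.  Sex chromosomes are dropped by default at this level
(the data model keeps them).

No multiple-testing correction is applied anywhere: significance uses the
fixed thresholds of the underlying definitions (chi-square P <= 1e-10 for
NDR windows; peak-caller cutoffs are applied upstream of this package).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import GenomeLayout, GenomicInterval, PeakSet, StageOrder
from .nome import (
    CytosineTable,
    accessibility_ratio,
    call_ndrs,
    classify_ndr,
    genome_background,
    hotspot_ndr_partition,
)
from .peak_dynamics import (
    DynamicsReport,
    build_presence_matrix,
    classify_dynamics,
    hotspot_associated,
    split_de_novo,
)

__all__ = [
    "PRIOR_STAGES_DEFAULT",
    "run_dynamics",
    "run_ndr",
    "compare_groups",
    "write_report",
]

#: Premeiotic stages used as the prior set for the de novo split.  Peaks
#: appearing at leptotene and persisting into mid-zygotene still count as
#: de novo at mid-zygotene: "previous stages" means the spermatogonia /
#: preleptotene series, not earlier prophase-I substages.
PRIOR_STAGES_DEFAULT = ("Undiff", "A1", "B", "mpL")

CLASSIFICATION_STAGES = ("L", "mZ", "lZ", "e1P")


@dataclass
class DynamicsSection:
    """Dynamics half of the summary report."""

    n_target: int
    n_de_novo: int
    n_common: int
    n_hotspot_associated: int
    class_counts: dict[str, int]
    report: DynamicsReport


def _maybe_autosomes(ps: PeakSet, autosomes_only: bool) -> PeakSet:
    return ps.restrict_to_autosomes() if autosomes_only else ps


def run_dynamics(
    stage_series: Mapping[str, PeakSet],
    hotspots: PeakSet,
    target_stage: str = "mZ",
    prior_stages: Sequence[str] = PRIOR_STAGES_DEFAULT,
    classification_stages: Sequence[str] = CLASSIFICATION_STAGES,
    order: StageOrder | None = None,
    autosomes_only: bool = True,
    min_bp: int = 1,
) -> DynamicsSection:
    """De novo split -> hotspot association -> presence matrix -> classes."""
    order = order or StageOrder()
    series = {s: _maybe_autosomes(ps, autosomes_only) for s, ps in stage_series.items()}
    hotspots = _maybe_autosomes(hotspots, autosomes_only)
    prior = [s for s in prior_stages if s in series]
    de_novo, common = split_de_novo(series, target_stage, prior, order=order,
                                    min_bp=min_bp)
    assoc, _ = hotspot_associated(de_novo, hotspots, min_bp=min_bp)
    matrix = build_presence_matrix(assoc, series, list(classification_stages),
                                   order=order, min_bp=min_bp)
    labels = classify_dynamics(matrix)
    report = DynamicsReport.from_labels(assoc, labels)
    return DynamicsSection(
        n_target=len(series[target_stage]),
        n_de_novo=len(de_novo),
        n_common=len(common),
        n_hotspot_associated=len(assoc),
        class_counts=report.class_counts,
        report=report,
    )


@dataclass
class NdrSection:
    """NOMe half of the summary report."""

    background_level: float
    n_ndrs: int
    n_proximal: int
    n_distal: int
    hotspot_partition: dict
    accessibility: dict
    ndrs: pd.DataFrame


def run_ndr(
    table: CytosineTable,
    layout: GenomeLayout,
    tss: pd.DataFrame | None,
    hotspots: PeakSet,
    depth_cutoff: int = 3,
    p_max: float = 1e-10,
    min_sites: int = 6,
    min_len: int = 141,
    tss_flank: int = 1500,
    autosomes_only: bool = True,
) -> NdrSection:
    """Depth filter -> NDR calling -> proximal/distal -> hotspot partition."""
    filtered = table.depth_filter(depth_cutoff)
    if autosomes_only:
        auto = set(layout.autosomes())
        filtered = CytosineTable(filtered.df[filtered.df["chrom"].isin(auto)],
                                 depth_filtered_at=depth_cutoff)
        hotspots = hotspots.restrict_to_autosomes()
    bg = genome_background(filtered, "GCH")
    ndrs = call_ndrs(filtered, layout, p_max=p_max, min_sites=min_sites,
                     min_len=min_len)
    if tss is not None and len(tss):
        ndrs = classify_ndr(ndrs, tss, flank=tss_flank)
    else:
        import warnings
        warnings.warn("no TSS annotation: NDRs left unclassified")
        ndrs = ndrs.copy()
        ndrs["class"] = "unclassified"
    partition = hotspot_ndr_partition(list(hotspots), ndrs)
    ratios = accessibility_ratio(list(hotspots), filtered)
    defined = ratios[~np.isnan(ratios)]
    accessibility = {
        "n_regions": int(len(ratios)),
        "n_defined": int(len(defined)),
        "median_ratio": float(np.median(defined)) if len(defined) else float("nan"),
        "mean_ratio": float(np.mean(defined)) if len(defined) else float("nan"),
    }
    return NdrSection(
        background_level=bg.mean_level,
        n_ndrs=len(ndrs),
        n_proximal=int((ndrs["class"] == "proximal").sum()) if len(ndrs) else 0,
        n_distal=int((ndrs["class"] == "distal").sum()) if len(ndrs) else 0,
        hotspot_partition=partition,
        accessibility=accessibility,
        ndrs=ndrs,
    )


def compare_groups(
    values_by_class: Mapping[str, Sequence[float]] | np.ndarray,
    test: str = "t_test",
) -> tuple[float, float]:
    """Routine two-group comparison statistics.

    ``t_test``: unpaired two-sample t-test on exactly two groups of values
    (two-tailed).  ``fisher``: Fisher's exact test on a 2x2 count table.
    Degenerate zero-variance identical groups are reported with p = 1.
    """
    if test == "fisher":
        table = np.asarray(values_by_class)
        if table.shape != (2, 2):
            raise ValueError("fisher test needs a 2x2 table")
        odds, p = stats.fisher_exact(table)
        return float(odds), float(p)
    if test != "t_test":
        raise ValueError(f"unknown test {test!r}")
    groups = list(values_by_class.values())
    if len(groups) != 2:
        raise ValueError("t_test compares exactly two groups")
    a, b = (np.asarray(g, dtype=float) for g in groups)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    if np.var(a) == 0 and np.var(b) == 0:
        # degenerate variance: identical constants are indistinguishable
        return (0.0, 1.0) if np.mean(a) == np.mean(b) else (float("inf"), 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def write_report(
    out_path: str | Path,
    dynamics: DynamicsSection | None = None,
    ndr: NdrSection | None = None,
    extra: Mapping | None = None,
) -> dict:
    """Assemble the JSON summary report; every fraction keeps its n."""
    report: dict = {}
    if dynamics is not None:
        report["dynamics"] = {
            "n_target": dynamics.n_target,
            "n_de_novo": dynamics.n_de_novo,
            "n_common": dynamics.n_common,
            "n_hotspot_associated": dynamics.n_hotspot_associated,
            "class_counts": dynamics.class_counts,
        }
    if ndr is not None:
        report["ndr"] = {
            "background_gch_level": ndr.background_level,
            "n_ndrs": ndr.n_ndrs,
            "n_proximal": ndr.n_proximal,
            "n_distal": ndr.n_distal,
            "hotspot_partition": ndr.hotspot_partition,
            "accessibility": ndr.accessibility,
        }
    if extra:
        report.update(extra)
    with open(out_path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
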