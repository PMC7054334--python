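"""Stage-comparative peak classification for meiotic recombination hotspots.

The central object is the presence matrix: for each reference peak (a
hotspot-associated mid-zygotene H3K4me3 peak), a boolean per prophase-I stage
saying whether any peak called at that stage overlaps it.  The time of
appearance and disappearance across leptotene (L), mid-zygotene (mZ),
late-zygotene (lZ) and early 1-pachytene (e1P) assigns each peak one of four
turnover classes:

=============  ==  ==  ==  ===
class           L  mZ  lZ  e1P
=============  ==  ==  ==  ===
early_forming   1   1   *   *
fast_turnover   0   1   0   0
slow_turnover   0   1   1   0
persistent      0   1   1   1
=============  ==  ==  ==  ===

Any other pattern (e.g. disappearing then reappearing) is ``unclassified``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import (
    GenomeLayout,
    GenomicInterval,
    PeakSet,
    StageOrder,
    width,
)
from .signal import SignalTrack, region_mean_density

__all__ = [
    "DYNAMICS_CLASSES",
    "PresenceMatrix",
    "DynamicsReport",
    "split_de_novo",
    "hotspot_associated",
    "build_presence_matrix",
    "classify_dynamics",
    "h3k9me2_dip",
    "fisher_overlap_test",
    "overlap_summary",
]

DYNAMICS_CLASSES = ("early_forming", "fast_turnover", "slow_turnover", "persistent")

#: Stages the four-class taxonomy is defined over, in order.
CLASSIFICATION_STAGES = ("L", "mZ", "lZ", "e1P")


@dataclass
class PresenceMatrix:
    """Reference peaks x ordered stages -> boolean presence.

    ``values[i, j]`` is True iff reference peak ``i`` overlaps (>= min_bp) any
    peak called at stage ``stages[j]``.
    """

    reference: PeakSet
    stages: tuple[str, ...]
    values: np.ndarray  # (n_peaks, n_stages) bool

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.reference), len(self.stages)):
            raise ValueError(
                f"presence matrix shape {self.values.shape} does not match "
                f"{len(self.reference)} peaks x {len(self.stages)} stages"
            )

    def column(self, stage: str) -> np.ndarray:
        return self.values[:, self.stages.index(stage)]


def split_de_novo(
    stage_series: Mapping[str, PeakSet],
    target_stage: str,
    prior_stages: Sequence[str],
    order: StageOrder | None = None,
    min_bp: int = 1,
) -> tuple[PeakSet, PeakSet]:
    """Partition the target stage's peaks into de novo and common sets.

    A peak is *de novo* when it overlaps no peak of the same mark at any of
    the listed prior stages; the rest are *common* (present at some prior
    stage).  ``prior_stages`` must all be strictly earlier than
    ``target_stage`` in the stage order.
    """
    order = order or StageOrder()
    if target_stage not in stage_series:
        raise KeyError(f"target stage {target_stage!r} missing from series")
    for s in prior_stages:
        if s not in stage_series:
            raise KeyError(f"prior stage {s!r} missing from series")
        if not order.is_earlier(s, target_stage):
            raise ValueError(
                f"prior stage {s!r} is not strictly earlier than {target_stage!r}"
            )
    target = stage_series[target_stage]
    in_prior = np.zeros(len(target), dtype=bool)
    for s in prior_stages:
        in_prior |= stage_series[s].presence_of(target.intervals, min_bp=min_bp)
    de_novo = target.subset(np.flatnonzero(~in_prior))
    common = target.subset(np.flatnonzero(in_prior))
    return de_novo, common


def hotspot_associated(
    peaks: PeakSet, hotspots: PeakSet, min_bp: int = 1
) -> tuple[PeakSet, dict[int, list[int]]]:
    """Subset of ``peaks`` overlapping at least one DSB hotspot.

    Returns the subset plus an association map from index-in-subset to the
    hotspot indices it overlaps.  An empty hotspot set yields an empty subset.
    """
    if len(hotspots) == 0:
        import warnings
        warnings.warn("empty hotspot set: no peaks are hotspot-associated")
        return peaks.subset([]), {}
    keep: list[int] = []
    assoc: dict[int, list[int]] = {}
    for i, iv in enumerate(peaks):
        hits = hotspots.overlapping_indices(iv, min_bp=min_bp)
        if len(hits):
            assoc[len(keep)] = [int(h) for h in hits]
            keep.append(i)
    return peaks.subset(keep), assoc


def build_presence_matrix(
    reference: PeakSet,
    stage_series: Mapping[str, PeakSet],
    stages: Sequence[str],
    order: StageOrder | None = None,
    min_bp: int = 1,
) -> PresenceMatrix:
    """Boolean presence of each reference peak at each requested stage."""
    order = order or StageOrder()
    idx = [order.index(s) for s in stages]
    if idx != sorted(idx):
        raise ValueError(f"stages {stages} are not in stage order")
    cols = []
    for s in stages:
        if s not in stage_series:
            raise KeyError(f"stage {s!r} missing from series")
        cols.append(stage_series[s].presence_of(reference.intervals, min_bp=min_bp))
    values = (
        np.stack(cols, axis=1) if cols else np.zeros((len(reference), 0), dtype=bool)
    )
    return PresenceMatrix(reference=reference, stages=tuple(stages), values=values)


def classify_dynamics(matrix: PresenceMatrix) -> np.ndarray:
    """Assign each hotspot-associated mid-zygotene peak a turnover class.

    Requires the four classification stages (L, mZ, lZ, e1P) as columns and
    every row present at mZ.  Returns an object array of labels; patterns not
    matching any of the four classes are ``unclassified``.
    """
    for s in CLASSIFICATION_STAGES:
        if s not in matrix.stages:
            raise ValueError(f"presence matrix lacks stage {s!r}")
    L = matrix.column("L")
    mZ = matrix.column("mZ")
    lZ = matrix.column("lZ")
    e1P = matrix.column("e1P")
    if not mZ.all():
        raise ValueError(
            "classification requires every reference peak present at mid-zygotene"
        )
    labels = np.full(len(L), "unclassified", dtype=object)
    labels[L] = "early_forming"
    labels[~L & ~lZ & ~e1P] = "fast_turnover"
    labels[~L & lZ & ~e1P] = "slow_turnover"
    labels[~L & lZ & e1P] = "persistent"
    return labels


@dataclass
class DynamicsReport:
    """Per-peak labels plus per-class count / width / score summaries."""

    labels: pd.DataFrame  # chrom, start, end, name, width, label
    class_counts: dict[str, int]

    @classmethod
    def from_labels(cls, reference: PeakSet, labels: np.ndarray) -> "DynamicsReport":
        df = pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in reference],
                "start": [iv.start for iv in reference],
                "end": [iv.end for iv in reference],
                "name": [iv.name for iv in reference],
                "score": [iv.score for iv in reference],
                "width": [width(iv) for iv in reference],
                "label": labels,
            }
        )
        counts = {c: int((labels == c).sum()) for c in DYNAMICS_CLASSES}
        counts["unclassified"] = int((labels == "unclassified").sum())
        assert sum(counts.values()) == len(labels)
        return cls(labels=df, class_counts=counts)

    def class_widths(self) -> dict[str, np.ndarray]:
        return {
            c: self.labels.loc[self.labels["label"] == c, "width"].to_numpy()
            for c in DYNAMICS_CLASSES
        }


def h3k9me2_dip(
    hotspots: PeakSet,
    track: SignalTrack,
    ratio_threshold: float = 0.5,
    flank_multiple: int = 2,
) -> tuple[PeakSet, pd.DataFrame]:
    """Hotspots whose interior signal is depleted relative to their flanks.

    For a hotspot of width ``w`` the flanks are ``[start - flank_multiple*w,
    start)`` and ``[end, end + flank_multiple*w)``, clipped at chromosome
    ends (the truncated span is used).  The hotspot is a dip when
    ``inside_mean / mean(flank_means) < ratio_threshold``.  Hotspots whose
    flanks are entirely off-chromosome, or whose flank signal is zero, are
    skipped (ratio undefined).
    """
    rows = []
    keep = []
    for i, hs in enumerate(hotspots):
        w = width(hs)
        L = track.layout[hs.chrom]
        inside = region_mean_density(track, hs)
        flank_means = []
        ls, le = hs.start - flank_multiple * w, hs.start
        rs, re = hs.end, hs.end + flank_multiple * w
        for fs, fe in ((ls, le), (rs, re)):
            fs_c, fe_c = max(fs, 0), min(fe, L)
            if fs_c < fe_c:
                flank_means.append(
                    region_mean_density(track, GenomicInterval(hs.chrom, fs_c, fe_c))
                )
        if not flank_means:
            continue  # both flanks off-chromosome: skip
        flank = float(np.mean(flank_means))
        if flank == 0:
            continue  # undefined ratio
        ratio = inside / flank
        is_dip = ratio < ratio_threshold
        rows.append(
            {
                "chrom": hs.chrom, "start": hs.start, "end": hs.end,
                "inside_mean": inside, "flank_mean": flank,
                "ratio": ratio, "is_dip": is_dip,
            }
        )
        if is_dip:
            keep.append(i)
    table = pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "inside_mean", "flank_mean", "ratio", "is_dip",
    ])
    return hotspots.subset(keep), table


def _bins_hit(peaks: PeakSet, layout: GenomeLayout, bin_size: int) -> dict[str, np.ndarray]:
    hit = {
        c: np.zeros(-(-layout[c] // bin_size), dtype=bool) for c in layout.chroms
    }
    for iv in peaks:
        b0 = iv.start // bin_size
        b1 = (iv.end - 1) // bin_size
        hit[iv.chrom][b0: b1 + 1] = True
    return hit


def fisher_overlap_test(
    set_a: PeakSet,
    set_b: PeakSet,
    layout: GenomeLayout,
    bin_size: int = 1000,
) -> tuple[float, float, np.ndarray]:
    """Fisher's exact test for spatial association of two peak sets.

    The genome is tiled into non-overlapping ``bin_size`` bins; each bin is
    scored for overlap with A and with B, and the 2x2 bin counts
    ``[[both, A only], [B only, neither]]`` are tested (two-sided).  Returns
    (odds ratio, p-value, table).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if len(set_a) == 0 or len(set_b) == 0:
        raise ValueError("fisher_overlap_test requires two non-empty sets")
    hit_a = _bins_hit(set_a, layout, bin_size)
    hit_b = _bins_hit(set_b, layout, bin_size)
    both = a_only = b_only = neither = 0
    for c in layout.chroms:
        a, b = hit_a[c], hit_b[c]
        both += int((a & b).sum())
        a_only += int((a & ~b).sum())
        b_only += int((~a & b).sum())
        neither += int((~a & ~b).sum())
    table = np.array([[both, a_only], [b_only, neither]])
    odds_ratio, p_value = stats.fisher_exact(table, alternative="two-sided")
    return float(odds_ratio), float(p_value), table


def overlap_summary(sets: Sequence[PeakSet]) -> dict[str, int]:
    """Venn-style intersection-class counts for 2-3 peak sets.

    The first set is the reference universe: each of its peaks is assigned a
    membership pattern, e.g. ``"110"`` for a reference peak overlapping
    something in set 2 but nothing in set 3 (the reference bit is always 1).
    Counts are keyed by pattern; patterns absent from the data are reported
    as zero.
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError("overlap_summary supports 2 or 3 sets")
    n = len(sets)
    from itertools import product
    counts = {
        "1" + "".join(bits): 0 for bits in product("01", repeat=n - 1)
    }
    for iv in sets[0]:
        bits = "1" + "".join(
            "1" if sets[j].overlaps_any(iv) else "0" for j in range(1, n)
        )
        counts[bits] += 1
    return counts
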