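"""Binned coverage tracks, spike-in normalization, and region-anchored matrices.

Fragments are single-end style records (chrom, 5' position, strand) extended
3'-ward to a fixed length (default 150 bp, the average sonicated chromatin
size).  Coverage is accumulated at base resolution and re-binned, so a
fragment contributes exactly its clipped length in bp to the track: partial
bins receive fractional mass and total track mass is conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_model import GenomeLayout, GenomicInterval

__all__ = [
    "SignalTrack",
    "coverage_from_fragments",
    "spike_factors",
    "matrix_around",
    "mean_profile",
    "region_mean_density",
    "read_fragments",
    "write_fragments",
]


@dataclass
class SignalTrack:
    """Per-chromosome dense bin vectors at a fixed bin size.

    ``bins[chrom][i]`` covers ``[i*bin_size, (i+1)*bin_size)``; the last bin
    may be partial.  Values are non-negative coverage mass (bp of fragment
    overlap per bin, possibly rescaled by a spike-in factor).
    """

    layout: GenomeLayout
    bin_size: int = 50
    bins: dict[str, np.ndarray] = field(default_factory=dict)
    norm_factor: float = 1.0
    label: str | None = None

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for chrom in self.layout.chroms:
            n = -(-self.layout[chrom] // self.bin_size)  # ceil division
            if chrom not in self.bins:
                self.bins[chrom] = np.zeros(n)
            elif len(self.bins[chrom]) != n:
                raise ValueError(
                    f"{chrom}: expected {n} bins, got {len(self.bins[chrom])}"
                )

    def scale(self, factor: float) -> "SignalTrack":
        """Return a copy with every bin multiplied by ``factor``."""
        return SignalTrack(
            layout=self.layout,
            bin_size=self.bin_size,
            bins={c: v * factor for c, v in self.bins.items()},
            norm_factor=self.norm_factor * factor,
            label=self.label,
        )

    def total_mass(self) -> float:
        return float(sum(v.sum() for v in self.bins.values()))

    # -- bedGraph ----------------------------------------------------------

    def to_bedgraph(self, path: str | Path) -> None:
        """Write the track as bedGraph, merging equal-valued adjacent bins."""
        with open(path, "w") as fh:
            for chrom in self.layout.chroms:
                vals = self.bins[chrom]
                L = self.layout[chrom]
                if len(vals) == 0:
                    continue
                change = np.flatnonzero(np.diff(vals)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [len(vals)]))
                for s, e in zip(starts, ends):
                    v = vals[s]
                    if v == 0:
                        continue
                    fh.write(
                        f"{chrom}\t{s * self.bin_size}\t{min(e * self.bin_size, L)}\t{v:.17g}\n"
                    )

    @classmethod
    def from_bedgraph(
        cls, path: str | Path, layout: GenomeLayout, bin_size: int = 50,
        label: str | None = None,
    ) -> "SignalTrack":
        """Read a bedGraph whose runs are aligned to ``bin_size`` boundaries."""
        track = cls(layout=layout, bin_size=bin_size, label=label)
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                chrom, s, e, v = line.split("\t")
                start, end, val = int(s), int(e), float(v)
                if chrom not in layout:
                    raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                if start % bin_size:
                    raise ValueError(
                        f"{path}:{lineno}: run start {start} not aligned to bin size {bin_size}"
                    )
                b0 = start // bin_size
                b1 = -(-end // bin_size)
                track.bins[chrom][b0:b1] = val
        return track


def read_fragments(path: str | Path) -> pd.DataFrame:
    """Fragment-table TSV (chrom, 5' position, strand) -> DataFrame."""
    df = pd.read_csv(path, sep="\t", names=["chrom", "pos", "strand"],
                     dtype={"chrom": str, "pos": np.int64, "strand": str},
                     comment="#")
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"{path}: invalid strand values {df.loc[bad, 'strand'].unique()}")
    return df


def write_fragments(frags: pd.DataFrame, path: str | Path) -> None:
    frags.to_csv(path, sep="\t", header=False, index=False,
                 columns=["chrom", "pos", "strand"])


def coverage_from_fragments(
    frags: pd.DataFrame,
    layout: GenomeLayout,
    extension: int = 150,
    bin_size: int = 50,
    label: str | None = None,
) -> tuple[SignalTrack, int]:
    """Extend each fragment 3'-ward and accumulate binned coverage.

    A + strand record at ``pos`` covers ``[pos, pos+extension)``; a - strand
    record covers ``(pos-extension, pos]`` i.e. ``[pos-extension+1, pos+1)``.
    Spans are clipped at chromosome ends.  Returns the track and the number of
    rejected records (5' position off-chromosome).
    """
    if extension <= 0:
        raise ValueError("extension must be positive")
    track = SignalTrack(layout=layout, bin_size=bin_size, label=label)
    rejected = 0
    for chrom, sub in frags.groupby("chrom", sort=False):
        if chrom not in layout:
            rejected += len(sub)
            continue
        L = layout[chrom]
        pos = sub["pos"].to_numpy()
        plus = (sub["strand"] == "+").to_numpy()
        ok = (pos >= 0) & (pos < L)
        rejected += int((~ok).sum())
        pos, plus = pos[ok], plus[ok]
        starts = np.where(plus, pos, pos - extension + 1)
        ends = np.where(plus, pos + extension, pos + 1)
        starts = np.clip(starts, 0, L)
        ends = np.clip(ends, 0, L)
        # per-base difference array, then sum bases into bins
        diff = np.zeros(L + 1)
        np.add.at(diff, starts, 1.0)
        np.add.at(diff, ends, -1.0)
        per_base = np.cumsum(diff[:-1])
        nbins = len(track.bins[chrom])
        pad = nbins * bin_size - L
        if pad:
            per_base = np.concatenate((per_base, np.zeros(pad)))
        track.bins[chrom] = per_base.reshape(nbins, bin_size).sum(axis=1)
    return track, rejected


def spike_factors(spike_counts: Mapping[str, int]) -> dict[str, float]:
    """Per-sample normalization factors from exogenous spike-in read counts.

    ``factor_s = min(counts) / counts_s``: the sample with fewest spike reads
    keeps factor 1 and every other sample is scaled down, so spike-derived
    signal totals are equalized across samples.
    """
    if not spike_counts:
        raise ValueError("no spike counts given")
    for label, c in spike_counts.items():
        if c <= 0:
            raise ValueError(f"spike count for {label!r} must be positive, got {c}")
    lo = min(spike_counts.values())
    return {label: lo / c for label, c in spike_counts.items()}


def _per_base_values(track: SignalTrack, chrom: str, start: int, end: int) -> np.ndarray:
    """Track bin values expanded to base resolution over [start, end).

    Bases outside the chromosome are NaN (missing, not zero).
    """
    L = track.layout[chrom]
    out = np.full(end - start, np.nan)
    lo, hi = max(start, 0), min(end, L)
    if lo >= hi:
        return out
    base_idx = np.arange(lo, hi)
    out[lo - start: hi - start] = track.bins[chrom][base_idx // track.bin_size]
    return out


def matrix_around(
    regions: Sequence[GenomicInterval],
    track: SignalTrack,
    flank: int = 5000,
    bin_size: int = 50,
    rank_scores: Sequence[float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Region-center-anchored signal matrix (rows = regions, cols = 2*flank/bin).

    Row r holds the mean track value in each ``bin_size`` column across
    ``center(region r) +/- flank``.  Columns falling (even partly) off the
    chromosome are NaN.  If ``rank_scores`` is given, rows are ordered by
    descending score (ties keep input order); the returned index array maps
    matrix rows back to input regions.
    """
    if flank % bin_size:
        raise ValueError(f"bin size {bin_size} does not divide flank {flank}")
    ncols = 2 * flank // bin_size
    rows = []
    for iv in regions:
        c = iv.center
        vals = _per_base_values(track, iv.chrom, c - flank, c + flank)
        rows.append(vals.reshape(ncols, bin_size).mean(axis=1))  # NaN-propagating
    mat = np.asarray(rows).reshape(len(regions), ncols)
    order = np.arange(len(regions))
    if rank_scores is not None:
        if len(rank_scores) != len(regions):
            raise ValueError("rank_scores length must equal region count")
        order = np.argsort(-np.asarray(rank_scores, dtype=float), kind="stable")
        mat = mat[order]
    return mat, order


def mean_profile(matrix: np.ndarray) -> np.ndarray:
    """Column means over non-missing entries; all-missing columns stay NaN."""
    if matrix.shape[0] < 1:
        raise ValueError("matrix needs at least one row")
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        return np.nanmean(matrix, axis=0)


def region_mean_density(track: SignalTrack, interval: GenomicInterval) -> float:
    """Length-weighted mean of bin values over the interval (clipped).

    Returns NaN when the interval is entirely off-chromosome after clipping.
    """
    L = track.layout[interval.chrom]
    lo, hi = max(interval.start, 0), min(interval.end, L)
    if lo >= hi:
        return float("nan")
    vals = track.bins[interval.chrom]
    b0, b1 = lo // track.bin_size, (hi - 1) // track.bin_size
    total = 0.0
    for b in range(b0, b1 + 1):
        seg = min(hi, (b + 1) * track.bin_size) - max(lo, b * track.bin_size)
        total += vals[b] * seg
    return total / (hi - lo)
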