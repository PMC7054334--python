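"""NOMe-seq analytics: cytosine contexts, methylation levels, NDR calling.

In a NOMe-seq experiment an exogenous GpC methyltransferase (M.CviPI)
methylates cytosines in accessible chromatin, so GCH methylation reports
accessibility while WCG methylation reports endogenous CpG methylation.
GCG/CCG sites are ambiguous between the two signals and are excluded.

Nucleosome-depleted regions (NDRs) are called by sliding a 100-bp window at
a 20-bp step across depth-filtered GCH sites, testing each window's pooled
methylated/unmethylated read counts against the whole-genome background by a
chi-square test (one-sided: only windows whose mean site level exceeds the
genome mean can be significant), merging significant windows, and keeping
merged regions with min window p <= 1e-10, more than 5 GCH sites and width
greater than 140 bp.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import GenomeLayout, GenomicInterval

__all__ = [
    "classify_context",
    "CytosineTable",
    "site_level",
    "genome_background",
    "scan_and_test",
    "call_ndrs",
    "classify_ndr",
    "region_level",
    "accessibility_ratio",
    "hotspot_ndr_partition",
]

_WCG_UP = {"A", "T"}
_GCH_DOWN = {"A", "C", "T"}


def classify_context(upstream_base: str, c_base: str, downstream_base: str) -> str:
    """Trinucleotide context of a cytosine: ``WCG``, ``GCH`` or ``other``.

    WCG = ACG/TCG (endogenous CpG methylation); GCH = GCA/GCC/GCT
    (accessibility).  GCG matches neither and is ``other``.  Bases must be
    strand-resolved so the middle base is literally C.
    """
    for b in (upstream_base, c_base, downstream_base):
        if b not in {"A", "C", "G", "T", "N"}:
            raise ValueError(f"invalid base {b!r}")
    if c_base != "C":
        raise ValueError(f"middle base must be C, got {c_base!r}")
    if upstream_base in _WCG_UP and downstream_base == "G":
        return "WCG"
    if upstream_base == "G" and downstream_base in _GCH_DOWN:
        return "GCH"
    return "other"


def site_level(meth_reads: int, total_reads: int) -> float:
    """Per-site methylation level: methylated reads / all detected reads."""
    if total_reads <= 0:
        raise ValueError("site has no reads; depth filtering should exclude it")
    if not 0 <= meth_reads <= total_reads:
        raise ValueError(f"invalid counts meth={meth_reads} total={total_reads}")
    return meth_reads / total_reads


class CytosineTable:
    """Per-site WCG/GCH methylated/total read counts, 0-based positions.

    Backed by a DataFrame with columns ``chrom, pos, strand, context, meth,
    total``.  Duplicate (chrom, pos, context) records are merged by summing
    counts (replicate merging).  ``depth_filter`` returns a copy retaining
    sites at or above the read-depth cutoff.
    """

    COLUMNS = ("chrom", "pos", "strand", "context", "meth", "total")

    def __init__(self, df: pd.DataFrame, depth_filtered_at: int | None = None):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"cytosine table missing columns {sorted(missing)}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        if (df["meth"] > df["total"]).any() or (df["meth"] < 0).any():
            raise ValueError("need 0 <= meth <= total for every site")
        # merge duplicate site records (replicates) by summing counts
        if df.duplicated(subset=["chrom", "pos", "context"]).any():
            df = (
                df.groupby(["chrom", "pos", "context"], as_index=False)
                .agg({"strand": "first", "meth": "sum", "total": "sum"})
                .loc[:, list(self.COLUMNS)]
            )
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        self.df = df
        self.depth_filtered_at = depth_filtered_at

    def __len__(self) -> int:
        return len(self.df)

    def depth_filter(self, min_depth: int = 3) -> "CytosineTable":
        out = CytosineTable(self.df[self.df["total"] >= min_depth])
        out.depth_filtered_at = min_depth
        return out

    def context_sites(self, context: str) -> pd.DataFrame:
        return self.df[self.df["context"] == context]

    def merge(self, other: "CytosineTable") -> "CytosineTable":
        """Merge replicate tables by summing counts per site."""
        return CytosineTable(pd.concat([self.df, other.df], ignore_index=True))

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CytosineTable":
        """Read a cytosine-report-style TSV.

        Columns: chrom, 1-based position, strand, meth count, unmeth count,
        context — where context is either WCG/GCH/other or a trinucleotide
        (classified on the fly).  Positions convert to 0-based.
        """
        raw = pd.read_csv(
            path, sep="\t", comment="#",
            names=["chrom", "pos1", "strand", "meth", "unmeth", "context"],
            dtype={"chrom": str, "pos1": np.int64, "strand": str,
                   "meth": np.int64, "unmeth": np.int64, "context": str},
        )
        ctx = raw["context"]
        tri = (ctx.str.len() == 3) & ~ctx.isin(["WCG", "GCH"])
        if tri.any():
            ctx = ctx.where(
                ~tri,
                ctx[tri].map(lambda t: classify_context(t[0], t[1], t[2])),
            )
        df = pd.DataFrame(
            {
                "chrom": raw["chrom"],
                "pos": raw["pos1"] - 1,
                "strand": raw["strand"],
                "context": ctx,
                "meth": raw["meth"],
                "total": raw["meth"] + raw["unmeth"],
            }
        )
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        out = pd.DataFrame(
            {
                "chrom": self.df["chrom"],
                "pos1": self.df["pos"] + 1,
                "strand": self.df["strand"],
                "meth": self.df["meth"],
                "unmeth": self.df["total"] - self.df["meth"],
                "context": self.df["context"],
            }
        )
        out.to_csv(path, sep="\t", header=False, index=False)


@dataclass(frozen=True)
class Background:
    """Whole-genome pooled counts and mean site level for one context."""

    meth: int
    total: int
    mean_level: float
    n_sites: int


def genome_background(table: CytosineTable, context: str = "GCH") -> Background:
    """Pooled counts and unweighted mean site level over all sites of a context."""
    sites = table.context_sites(context)
    if len(sites) == 0:
        raise ValueError(f"no {context} sites in table")
    levels = sites["meth"].to_numpy() / sites["total"].to_numpy()
    # sequential (cumsum-style) summation keeps whole-genome-as-region
    # levels bit-identical to this mean
    return Background(
        meth=int(sites["meth"].sum()),
        total=int(sites["total"].sum()),
        mean_level=float(np.cumsum(levels)[-1] / len(levels)),
        n_sites=len(sites),
    )


def _chi2_p_one_sided(
    win_meth: np.ndarray,
    win_total: np.ndarray,
    win_mean: np.ndarray,
    bg: Background,
) -> np.ndarray:
    """Vectorized 2x2 chi-square p (df=1, no continuity correction).

    Table: [[win_meth, win_unmeth], [bg_meth, bg_unmeth]].  Windows with no
    reads, degenerate margins, or mean site level <= the genome mean get
    p = 1 (the NDR definition is one-sided: *higher* than background).
    """
    a = win_meth.astype(float)
    b = (win_total - win_meth).astype(float)
    c = float(bg.meth)
    d = float(bg.total - bg.meth)
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    p = stats.chi2.sf(chi2, df=1)
    bad = (win_total == 0) | (r1 * r2 * c1 * c2 == 0)
    p = np.where(bad, 1.0, p)
    p = np.where(win_mean <= bg.mean_level, 1.0, p)
    return p


def scan_and_test(
    table: CytosineTable,
    layout: GenomeLayout,
    win: int = 100,
    step: int = 20,
    background: Background | None = None,
    context: str = "GCH",
) -> pd.DataFrame:
    """Slide a window across each chromosome and chi-square-test each window.

    Windows start at 0, step, 2*step, ... and span ``[start, start+win)``
    clipped at the chromosome end.  Returns one row per window: chrom, start,
    end, n_sites, meth, total, mean_level (NaN when empty), pvalue.
    """
    bg = background or genome_background(table, context)
    sites_all = table.context_sites(context)
    frames = []
    for chrom in layout.chroms:
        L = layout[chrom]
        sub = sites_all[sites_all["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        meth = sub["meth"].to_numpy()
        total = sub["total"].to_numpy()
        lev = np.divide(meth, total, out=np.zeros_like(meth, dtype=float),
                        where=total > 0)
        starts = np.arange(0, L, step)
        ends = np.minimum(starts + win, L)
        i0 = np.searchsorted(pos, starts, side="left")
        i1 = np.searchsorted(pos, ends, side="left")
        cm = np.concatenate(([0], np.cumsum(meth)))
        ct = np.concatenate(([0], np.cumsum(total)))
        cl = np.concatenate(([0.0], np.cumsum(lev)))
        n_sites = i1 - i0
        w_meth = cm[i1] - cm[i0]
        w_total = ct[i1] - ct[i0]
        with np.errstate(invalid="ignore"):
            w_mean = np.where(n_sites > 0, (cl[i1] - cl[i0]) / np.maximum(n_sites, 1),
                              np.nan)
        p = _chi2_p_one_sided(w_meth, w_total,
                              np.where(n_sites > 0, w_mean, -np.inf), bg)
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": ends,
            "n_sites": n_sites, "meth": w_meth, "total": w_total,
            "mean_level": w_mean, "pvalue": p,
        }))
    return pd.concat(frames, ignore_index=True)


def call_ndrs(
    table: CytosineTable,
    layout: GenomeLayout,
    p_max: float = 1e-10,
    min_sites: int = 6,
    min_len: int = 141,
    win: int = 100,
    step: int = 20,
    background: Background | None = None,
    context: str = "GCH",
) -> pd.DataFrame:
    """Call nucleosome-depleted regions from a depth-filtered cytosine table.

    Significant windows (p <= p_max) that overlap or abut are merged; merged
    regions are kept iff they hold at least ``min_sites`` GCH sites (default
    6, realizing "more than 5") and span at least ``min_len`` bp (default
    141, realizing "greater than 140").  Returns a DataFrame with columns
    chrom, start, end, n_sites, mean_level, min_p.
    """
    windows = scan_and_test(table, layout, win=win, step=step,
                            background=background, context=context)
    sig = windows[windows["pvalue"] <= p_max]
    sites_all = table.context_sites(context)
    rows = []
    for chrom, sub in sig.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        pos = sites_all.loc[sites_all["chrom"] == chrom, "pos"].to_numpy()
        meth = sites_all.loc[sites_all["chrom"] == chrom, "meth"].to_numpy()
        total = sites_all.loc[sites_all["chrom"] == chrom, "total"].to_numpy()
        cur_s = cur_e = None
        cur_p = 1.0
        merged: list[tuple[int, int, float]] = []
        for s, e, p in zip(sub["start"], sub["end"], sub["pvalue"]):
            if cur_s is None:
                cur_s, cur_e, cur_p = s, e, p
            elif s <= cur_e:  # overlapping or bookended
                cur_e = max(cur_e, e)
                cur_p = min(cur_p, p)
            else:
                merged.append((cur_s, cur_e, cur_p))
                cur_s, cur_e, cur_p = s, e, p
        if cur_s is not None:
            merged.append((cur_s, cur_e, cur_p))
        for s, e, p in merged:
            inside = (pos >= s) & (pos < e)
            n = int(inside.sum())
            if n < min_sites or (e - s) < min_len:
                continue
            lv = meth[inside] / total[inside]
            rows.append({
                "chrom": chrom, "start": int(s), "end": int(e),
                "n_sites": n, "mean_level": float(lv.mean()), "min_p": float(p),
            })
    return pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "n_sites", "mean_level", "min_p",
    ])


def classify_ndr(
    ndrs: pd.DataFrame,
    tss: Sequence[tuple[str, int]] | pd.DataFrame,
    flank: int = 1500,
) -> pd.DataFrame:
    """Annotate NDRs as TSS-proximal or distal.

    Proximal = within ``flank`` bp (inclusive) of any TSS position, i.e. the
    NDR touches the closed window ``[tss - flank, tss + flank]``; symmetric,
    so strand-agnostic.  An empty TSS set labels everything distal (with a
    warning).
    """
    out = ndrs.copy()
    if isinstance(tss, pd.DataFrame):
        tss_list = list(zip(tss["chrom"], tss["pos"]))
    else:
        tss_list = list(tss)
    if not tss_list:
        import warnings
        warnings.warn("empty TSS set: all NDRs labeled distal")
        out["class"] = "distal"
        return out
    by_chrom: dict[str, np.ndarray] = {}
    for chrom, pos in tss_list:
        by_chrom.setdefault(chrom, []).append(pos)  # type: ignore[arg-type]
    by_chrom = {c: np.sort(np.asarray(v)) for c, v in by_chrom.items()}
    labels = []
    for chrom, s, e in zip(out["chrom"], out["start"], out["end"]):
        positions = by_chrom.get(chrom)
        if positions is None:
            labels.append("distal")
            continue
        # coordinate gap from [s, e) to the nearest TSS; 0 if a TSS falls
        # inside.  Using the end *coordinate* keeps the boundary rule
        # symmetric: an NDR edge exactly `flank` bp away is proximal.
        left = positions[positions < s]
        right = positions[positions >= e]
        inside = len(positions) - len(left) - len(right) > 0
        d = 0 if inside else min(
            s - left[-1] if len(left) else np.inf,
            (right[0] - e) if len(right) else np.inf,
        )
        labels.append("proximal" if d <= flank else "distal")
    out["class"] = labels
    return out


def region_level(
    region: GenomicInterval,
    table: CytosineTable,
    context: str = "GCH",
    min_sites: int = 3,
) -> float:
    """Unweighted mean site level inside a region; NaN below ``min_sites``.

    Only regions with at least three GCH (or WCG) sites are considered; an
    undefined level propagates as NaN, never as zero.
    """
    sites = table.context_sites(context)
    sub = sites[
        (sites["chrom"] == region.chrom)
        & (sites["pos"] >= region.start)
        & (sites["pos"] < region.end)
    ]
    if len(sub) < min_sites:
        return float("nan")
    lv = sub["meth"].to_numpy() / sub["total"].to_numpy()
    return float(np.cumsum(lv)[-1] / len(lv))


def accessibility_ratio(
    regions: Sequence[GenomicInterval],
    table: CytosineTable,
    context: str = "GCH",
    min_sites: int = 3,
) -> np.ndarray:
    """Per-region accessibility relative to the whole genome.

    ratio = region mean GCH level / genome mean GCH level.  Regions with an
    undefined level yield NaN.
    """
    bg = genome_background(table, context)
    if bg.mean_level == 0:
        raise ValueError("genome background level is zero; ratio undefined")
    sites = table.context_sites(context)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in sites.groupby("chrom"):
        pos = sub["pos"].to_numpy()
        lev = sub["meth"].to_numpy() / sub["total"].to_numpy()
        by_chrom[chrom] = (pos, np.concatenate(([0.0], np.cumsum(lev))))
    out = np.full(len(regions), np.nan)
    for i, r in enumerate(regions):
        if r.chrom not in by_chrom:
            continue
        pos, cum = by_chrom[r.chrom]
        i0 = np.searchsorted(pos, r.start, side="left")
        i1 = np.searchsorted(pos, r.end, side="left")
        if i1 - i0 >= min_sites:
            out[i] = (cum[i1] - cum[i0]) / (i1 - i0) / bg.mean_level
    return out


def hotspot_ndr_partition(
    hotspots: Iterable[GenomicInterval],
    ndrs: pd.DataFrame,
) -> dict:
    """Partition DSB hotspots by whether their center base lies inside an NDR.

    Returns counts and fractions for within/outside, and — when the NDR
    table carries a ``class`` column — the proximal/distal split of the
    within-NDR hotspots.
    """
    hotspots = list(hotspots)
    n = len(hotspots)
    within = 0
    prox = dist = 0
    has_class = "class" in ndrs.columns
    by_chrom = {c: sub for c, sub in ndrs.groupby("chrom")} if len(ndrs) else {}
    for hs in hotspots:
        sub = by_chrom.get(hs.chrom)
        if sub is None:
            continue
        center = hs.center
        hit = sub[(sub["start"] <= center) & (center < sub["end"])]
        if len(hit):
            within += 1
            if has_class:
                if (hit["class"] == "proximal").any():
                    prox += 1
                else:
                    dist += 1
    out = {
        "n_hotspots": n,
        "within_ndr": within,
        "outside_ndr": n - within,
        "fraction_within": within / n if n else float("nan"),
    }
    if has_class:
        out["within_proximal"] = prox
        out["within_distal"] = dist
    return out
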