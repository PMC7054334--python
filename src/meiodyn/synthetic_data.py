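"""Seeded miniature-genome simulator with planted ground truth.

Emulates the data shapes of a stage-resolved meiotic epigenome study:

* a small multi-chromosome genome with TSS annotation;
* DSB hotspots with heavy-tailed (gamma) strengths;
* a stage series of H3K4me3 peak sets realizing the four turnover classes
  (early-forming, fast-turnover, slow-turnover, persistent) on hotspots,
  plus common promoter peaks present at every stage and non-hotspot de novo
  distractors;
* NOMe-seq cytosine tables with planted NDRs (elevated GCH methylation over
  a low background) and an endogenous WCG background;
* fragment sets concentrated in peaks proportional to strength, with
  per-sample spike-in counts.

Default counts per dynamics class follow the study-scale class ratio
(roughly 2700:2369:1036:4032) scaled down 100x; class width means are
ordered early_forming > persistent > slow_turnover > fast_turnover, echoing
the reported ~2 kb (early-forming) down to <1 kb (fast-turnover) widths.

Feature coordinates are drawn from a shared grid of well-separated slots so
planted features never collide; every component uses its own RNG stream
split from the master seed, so adding one component never perturbs another.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .genome_model import (
    STAGES,
    GenomeLayout,
    GenomicInterval,
    PeakSet,
    read_bed,
    write_bed,
)
from .nome import CytosineTable
from .signal import read_fragments, write_fragments

__all__ = [
    "SimConfig",
    "SimBundle",
    "simulate_genome",
    "simulate_stage_peaks",
    "simulate_nome",
    "simulate_signal",
    "simulate_bundle",
    "write_bundle",
    "load_bundle",
]

#: Stages at which class peaks appear, per class.
CLASS_STAGES = {
    "early_forming": ("L", "mZ", "lZ", "e1P"),
    "fast_turnover": ("mZ",),
    "slow_turnover": ("mZ", "lZ"),
    "persistent": ("mZ", "lZ", "e1P"),
}

#: Premeiotic stages: common promoter peaks exist here, class peaks do not.
PREMEIOTIC_STAGES = ("Undiff", "A1", "B", "mpL")


@dataclass
class SimConfig:
    """All knobs of the simulator; ``seed`` is mandatory.

    Width means (bp) are ordered early_forming > persistent > slow_turnover >
    fast_turnover.  GCH levels are Beta-distributed around the given means;
    depth is ``depth_min + Poisson(depth_mean - depth_min)``.
    """

    seed: int
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 2_000_000, "chr3": 2_000_000}
    )
    # dynamics classes (100x scale-down of the study-scale class ratio)
    n_early_forming: int = 27
    n_fast_turnover: int = 24
    n_slow_turnover: int = 10
    n_persistent: int = 40
    n_common: int = 30
    n_tss: int = 60
    n_hotspots: int = 150
    n_distractors: int = 40
    width_means: dict[str, float] = field(
        default_factory=lambda: {
            "early_forming": 2000.0,
            "persistent": 1400.0,
            "slow_turnover": 1100.0,
            "fast_turnover": 800.0,
        }
    )
    width_cv: float = 0.15
    common_width: float = 1500.0
    hotspot_width: int = 300
    strength_shape: float = 0.8   # gamma shape < 1: heavy-tailed strengths
    strength_scale: float = 10.0
    stage_jitter: int = 40        # per-stage coordinate jitter of peak edges (bp)
    # NOMe
    n_ndrs: int = 40
    ndr_width: int = 400
    gch_inside: float = 0.5
    gch_outside: float = 0.05
    beta_concentration: float = 50.0
    wcg_background: float = 0.75
    site_spacing: int = 10
    wcg_spacing: int = 50
    depth_mean: float = 10.0
    depth_min: int = 3
    # signal
    fragments_per_stage: int = 40_000
    noise_fraction: float = 0.1
    spike_mean: int = 10_000
    extension: int = 150

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_early_forming", "n_fast_turnover", "n_slow_turnover",
                     "n_persistent", "n_common", "n_tss", "n_hotspots",
                     "n_distractors", "n_ndrs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("gch_inside", "gch_outside", "wcg_background",
                     "noise_fraction"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1), got {v}")

    @property
    def class_counts(self) -> dict[str, int]:
        return {
            "early_forming": self.n_early_forming,
            "fast_turnover": self.n_fast_turnover,
            "slow_turnover": self.n_slow_turnover,
            "persistent": self.n_persistent,
        }

    def rng(self, component: str) -> np.random.Generator:
        """Independent RNG stream for one component, split from the seed."""
        h = int.from_bytes(hashlib.sha256(component.encode()).digest()[:4], "big")
        return np.random.default_rng([self.seed, h])

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        return cls(**d)


def _slot_grid(config: SimConfig, layout: GenomeLayout, rng: np.random.Generator,
               n_slots: int, spacing: int) -> list[tuple[str, int]]:
    """``n_slots`` well-separated center positions across the genome."""
    candidates: list[tuple[str, int]] = []
    for chrom in layout.chroms:
        L = layout[chrom]
        for c in range(spacing, L - spacing, spacing):
            candidates.append((chrom, c))
    if n_slots > len(candidates):
        raise ValueError(
            f"genome too small: {n_slots} features requested, "
            f"{len(candidates)} slots available at spacing {spacing}"
        )
    idx = rng.choice(len(candidates), size=n_slots, replace=False)
    return [candidates[i] for i in sorted(idx)]


def simulate_genome(config: SimConfig) -> tuple[GenomeLayout, pd.DataFrame]:
    """Genome layout plus a TSS table (chrom, pos, strand), seeded.

    TSS positions come from the shared slot grid, so they never collide with
    hotspots or distractor peaks drawn later from the same grid partition.
    """
    layout = GenomeLayout(dict(config.chrom_sizes))
    slots = _all_slots(config, layout)
    rng = config.rng("genome")
    tss_slots = slots["tss"]
    strands = rng.choice(["+", "-"], size=len(tss_slots))
    tss = pd.DataFrame(
        {
            "chrom": [c for c, _ in tss_slots],
            "pos": [p for _, p in tss_slots],
            "strand": strands,
        }
    )
    return layout, tss


def _all_slots(config: SimConfig, layout: GenomeLayout) -> dict[str, list[tuple[str, int]]]:
    """Partition one deterministic slot grid among feature families.

    Slot spacing leaves room for the widest peak plus jitter on both sides
    of each center, so features in different slots cannot overlap.
    """
    max_half = max(
        max(config.width_means.values()) * (1 + 4 * config.width_cv) / 2,
        config.common_width * (1 + 4 * config.width_cv) / 2,
        config.ndr_width,
        config.hotspot_width,
    )
    spacing = int(2 * (max_half + config.stage_jitter) + 200)
    n_total = config.n_hotspots + config.n_tss + config.n_distractors + config.n_ndrs
    rng = config.rng("slots")
    slots = _slot_grid(config, layout, rng, n_total, spacing)
    perm = rng.permutation(n_total)
    out: dict[str, list[tuple[str, int]]] = {}
    i = 0
    for name, n in (
        ("hotspots", config.n_hotspots),
        ("tss", config.n_tss),
        ("distractors", config.n_distractors),
        ("ndrs", config.n_ndrs),
    ):
        out[name] = sorted(slots[j] for j in perm[i: i + n])
        i += n
    return out


def simulate_hotspots(config: SimConfig, layout: GenomeLayout) -> tuple[PeakSet, pd.DataFrame]:
    """DSB hotspot intervals with heavy-tailed planted strengths."""
    rng = config.rng("hotspots")
    slots = _all_slots(config, layout)["hotspots"]
    strengths = rng.gamma(config.strength_shape, config.strength_scale,
                          size=len(slots))
    strengths = np.maximum(strengths, 0.05)
    ivs = []
    rows = []
    for i, ((chrom, center), s) in enumerate(zip(slots, strengths)):
        half = config.hotspot_width // 2
        iv = GenomicInterval(chrom, center - half, center + half,
                             name=f"hs{i}", score=float(s))
        ivs.append(iv)
        rows.append({"hotspot_id": f"hs{i}", "chrom": chrom,
                     "start": iv.start, "end": iv.end, "strength": float(s)})
    return PeakSet(ivs, layout), pd.DataFrame(rows)


def _draw_width(rng: np.random.Generator, mean: float, cv: float) -> int:
    w = rng.normal(mean, cv * mean)
    return max(int(round(w)), 150)


def simulate_stage_peaks(
    config: SimConfig,
    layout: GenomeLayout,
    hotspots: PeakSet,
    tss: pd.DataFrame,
) -> tuple[dict[str, PeakSet], pd.DataFrame]:
    """Per-stage H3K4me3 peak sets realizing the planted turnover classes.

    Class peaks sit on hotspots and appear at the stages their class
    dictates; common promoter peaks sit on TSS at every stage; distractor
    de novo peaks (non-hotspot) appear from leptotene onward.  Returns the
    stage series and a truth table (peak id, class, mid-zygotene
    coordinates, hotspot id).
    """
    counts = config.class_counts
    n_class = sum(counts.values())
    if n_class > len(hotspots):
        raise ValueError(
            f"{n_class} class peaks requested but only {len(hotspots)} hotspots"
        )
    rng = config.rng("peaks")
    order = rng.permutation(len(hotspots))
    assignment: list[tuple[int, str]] = []
    i = 0
    for cls, n in counts.items():
        for j in range(n):
            assignment.append((int(order[i]), cls))
            i += 1
    slots = _all_slots(config, layout)
    stage_ivs: dict[str, list[GenomicInterval]] = {s: [] for s in STAGES}
    truth_rows = []
    for k, (hs_idx, cls) in enumerate(assignment):
        hs = hotspots[hs_idx]
        center = hs.center
        w = _draw_width(rng, config.width_means[cls], config.width_cv)
        mz_iv = None
        for stage in CLASS_STAGES[cls]:
            jitter_s = int(rng.integers(-config.stage_jitter, config.stage_jitter + 1))
            jitter_e = int(rng.integers(-config.stage_jitter, config.stage_jitter + 1))
            s = max(center - w // 2 + jitter_s, 0)
            e = min(center + w // 2 + jitter_e, layout[hs.chrom])
            iv = GenomicInterval(hs.chrom, s, e, name=f"pk{k}_{stage}",
                                 score=hs.score)
            stage_ivs[stage].append(iv)
            if stage == "mZ":
                mz_iv = iv
        assert mz_iv is not None
        truth_rows.append({
            "peak_id": f"pk{k}", "class": cls, "chrom": mz_iv.chrom,
            "start": mz_iv.start, "end": mz_iv.end,
            "hotspot_id": hs.name, "strength": hs.score,
        })
    # common promoter peaks: all stages, centered on TSS
    for k, (chrom, pos) in enumerate(
        zip(tss["chrom"].head(config.n_common), tss["pos"].head(config.n_common))
    ):
        w = _draw_width(rng, config.common_width, config.width_cv)
        for stage in STAGES:
            jitter_s = int(rng.integers(-config.stage_jitter, config.stage_jitter + 1))
            jitter_e = int(rng.integers(-config.stage_jitter, config.stage_jitter + 1))
            s = max(pos - w // 2 + jitter_s, 0)
            e = min(pos + w // 2 + jitter_e, layout[chrom])
            stage_ivs[stage].append(
                GenomicInterval(chrom, s, e, name=f"common{k}_{stage}", score=1.0)
            )
    # distractors: non-hotspot de novo peaks at the meiotic stages
    for k, (chrom, center) in enumerate(slots["distractors"]):
        w = _draw_width(rng, config.width_means["fast_turnover"], config.width_cv)
        for stage in ("L", "mZ"):
            jitter_s = int(rng.integers(-config.stage_jitter, config.stage_jitter + 1))
            jitter_e = int(rng.integers(-config.stage_jitter, config.stage_jitter + 1))
            s = max(center - w // 2 + jitter_s, 0)
            e = min(center + w // 2 + jitter_e, layout[chrom])
            stage_ivs[stage].append(
                GenomicInterval(chrom, s, e, name=f"dn{k}_{stage}", score=0.5)
            )
    series = {
        stage: PeakSet(ivs, layout, mark="H3K4me3", stage=stage)
        for stage, ivs in stage_ivs.items()
    }
    return series, pd.DataFrame(truth_rows)


def simulate_nome(
    config: SimConfig,
    layout: GenomeLayout,
    ndr_truth: pd.DataFrame | None = None,
    accessible_regions: pd.DataFrame | None = None,
    inside_level: float | None = None,
) -> tuple[CytosineTable, pd.DataFrame]:
    """Cytosine table with planted accessible regions over a low background.

    By default the planted regions are NDR slots of ``ndr_width`` bp at GCH
    level ``gch_inside``; alternatively pass explicit ``accessible_regions``
    (chrom, start, end) and an ``inside_level``.  GCH sites sit every
    ``site_spacing`` bp, WCG sites every ``wcg_spacing`` bp at the endogenous
    background.  Overlapping planted regions are merged in the returned
    truth.  Per-site level ~ Beta(mean, concentration); reads ~
    Binomial(depth, level) with depth >= ``depth_min``.
    """
    rng = config.rng("nome")
    if accessible_regions is None:
        slots = _all_slots(config, layout)["ndrs"]
        half = config.ndr_width // 2
        accessible_regions = pd.DataFrame(
            {
                "chrom": [c for c, _ in slots],
                "start": [p - half for _, p in slots],
                "end": [p + half for _, p in slots],
            }
        )
        inside_level = config.gch_inside if inside_level is None else inside_level
    elif inside_level is None:
        raise ValueError("inside_level required with explicit accessible_regions")
    truth = _merge_regions(accessible_regions)
    k = config.beta_concentration
    rows = []
    for chrom in layout.chroms:
        L = layout[chrom]
        sub = truth[truth["chrom"] == chrom]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        # GCH sites
        pos = np.arange(config.site_spacing, L, config.site_spacing)
        j = np.searchsorted(starts, pos, side="right") - 1
        inside = (j >= 0) & (pos < ends[np.clip(j, 0, max(len(ends) - 1, 0))]) \
            if len(ends) else np.zeros(len(pos), dtype=bool)
        mean = np.where(inside, inside_level, config.gch_outside)
        level = rng.beta(mean * k, (1 - mean) * k)
        depth = config.depth_min + rng.poisson(
            max(config.depth_mean - config.depth_min, 0), size=len(pos)
        )
        meth = rng.binomial(depth, level)
        strand = rng.choice(["+", "-"], size=len(pos))
        rows.append(pd.DataFrame({
            "chrom": chrom, "pos": pos, "strand": strand, "context": "GCH",
            "meth": meth, "total": depth,
        }))
        # WCG sites at the endogenous background (offset to avoid GCH positions)
        wpos = np.arange(config.wcg_spacing + 1, L, config.wcg_spacing)
        wlevel = rng.beta(config.wcg_background * k,
                          (1 - config.wcg_background) * k, size=len(wpos))
        wdepth = config.depth_min + rng.poisson(
            max(config.depth_mean - config.depth_min, 0), size=len(wpos)
        )
        wmeth = rng.binomial(wdepth, wlevel)
        wstrand = rng.choice(["+", "-"], size=len(wpos))
        rows.append(pd.DataFrame({
            "chrom": chrom, "pos": wpos, "strand": wstrand, "context": "WCG",
            "meth": wmeth, "total": wdepth,
        }))
    table = CytosineTable(pd.concat(rows, ignore_index=True))
    return table, truth


def _merge_regions(regions: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/bookended intervals per chromosome."""
    out = []
    for chrom, sub in regions.groupby("chrom"):
        sub = sub.sort_values("start")
        cur_s = cur_e = None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append({"chrom": chrom, "start": cur_s, "end": cur_e})
                cur_s, cur_e = s, e
        if cur_s is not None:
            out.append({"chrom": chrom, "start": cur_s, "end": cur_e})
    return (
        pd.DataFrame(out, columns=["chrom", "start", "end"])
        .sort_values(["chrom", "start"])
        .reset_index(drop=True)
    )


def simulate_signal(
    peak_sets: Mapping[str, PeakSet],
    config: SimConfig,
    layout: GenomeLayout,
) -> tuple[dict[str, pd.DataFrame], dict[str, int]]:
    """Fragment sets per stage plus per-sample spike-in counts.

    Fragments are drawn inside peaks with probability proportional to peak
    strength (score), over a uniform genomic background at
    ``noise_fraction``.  Spike counts are Poisson around ``spike_mean``.
    """
    rng = config.rng("signal")
    chroms = list(layout.chroms)
    sizes = np.array([layout[c] for c in chroms], dtype=float)
    frags: dict[str, pd.DataFrame] = {}
    spikes: dict[str, int] = {}
    for stage, peaks in peak_sets.items():
        n = config.fragments_per_stage
        n_noise = rng.binomial(n, config.noise_fraction) if len(peaks) else n
        recs_chrom: list[str] = []
        recs_pos: list[int] = []
        # uniform background
        ci = rng.choice(len(chroms), size=n_noise, p=sizes / sizes.sum())
        for idx in ci:
            recs_chrom.append(chroms[idx])
        recs_pos.extend(
            int(rng.integers(0, layout[chroms[idx]])) for idx in ci
        )
        # peak-concentrated fragments
        n_peak = n - n_noise
        if len(peaks) and n_peak:
            scores = np.array(
                [iv.score if iv.score is not None else 1.0 for iv in peaks]
            )
            scores = np.maximum(scores, 1e-6)
            pick = rng.choice(len(peaks), size=n_peak, p=scores / scores.sum())
            for idx in pick:
                iv = peaks[int(idx)]
                recs_chrom.append(iv.chrom)
                recs_pos.append(int(rng.integers(iv.start, iv.end)))
        strand = rng.choice(["+", "-"], size=len(recs_pos))
        df = pd.DataFrame({"chrom": recs_chrom, "pos": recs_pos, "strand": strand})
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        frags[stage] = df
        spikes[stage] = int(max(rng.poisson(config.spike_mean), 1))
    return frags, spikes


@dataclass
class SimBundle:
    """Everything one simulation run produced, including planted truth."""

    config: SimConfig
    layout: GenomeLayout
    tss: pd.DataFrame
    hotspots: PeakSet
    hotspot_truth: pd.DataFrame
    stage_peaks: dict[str, PeakSet]
    peak_truth: pd.DataFrame
    nome_table: CytosineTable
    ndr_truth: pd.DataFrame
    fragments: dict[str, pd.DataFrame]
    spike_counts: dict[str, int]


def simulate_bundle(config: SimConfig) -> SimBundle:
    """Run every simulator component under one seed."""
    layout, tss = simulate_genome(config)
    hotspots, hotspot_truth = simulate_hotspots(config, layout)
    stage_peaks, peak_truth = simulate_stage_peaks(config, layout, hotspots, tss)
    nome_table, ndr_truth = simulate_nome(config, layout)
    fragments, spike_counts = simulate_signal(stage_peaks, config, layout)
    return SimBundle(
        config=config, layout=layout, tss=tss,
        hotspots=hotspots, hotspot_truth=hotspot_truth,
        stage_peaks=stage_peaks, peak_truth=peak_truth,
        nome_table=nome_table, ndr_truth=ndr_truth,
        fragments=fragments, spike_counts=spike_counts,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_bundle(bundle: SimBundle, out_dir: str | Path) -> Path:
    """Write the bundle as plain-text files plus a checksum manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "chrom.sizes", "w") as fh:
        for c in bundle.layout.chroms:
            fh.write(f"{c}\t{bundle.layout[c]}\n")
    bundle.tss.to_csv(out / "tss.tsv", sep="\t", index=False)
    write_bed(bundle.hotspots, out / "hotspots.bed")
    bundle.hotspot_truth.to_csv(out / "hotspot_truth.tsv", sep="\t", index=False)
    for stage, ps in bundle.stage_peaks.items():
        write_bed(ps, out / f"peaks_{stage}.bed")
    bundle.peak_truth.to_csv(out / "peak_truth.tsv", sep="\t", index=False)
    bundle.nome_table.to_tsv(out / "cytosine.tsv")
    bundle.ndr_truth.to_csv(out / "ndr_truth.tsv", sep="\t", index=False)
    for stage, df in bundle.fragments.items():
        write_fragments(df, out / f"fragments_{stage}.tsv")
    with open(out / "spike_counts.json", "w") as fh:
        json.dump(bundle.spike_counts, fh, indent=1, sort_keys=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(bundle.config.to_dict(), fh, sort_keys=True)
    manifest = {
        p.name: _sha256(p) for p in sorted(out.iterdir())
        if p.name != "manifest.json"
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out


def verify_manifest(bundle_dir: str | Path) -> bool:
    """True iff every file matches its recorded checksum."""
    out = Path(bundle_dir)
    with open(out / "manifest.json") as fh:
        manifest = json.load(fh)
    return all(_sha256(out / name) == digest for name, digest in manifest.items())


def load_bundle(bundle_dir: str | Path) -> SimBundle:
    """Re-read a written bundle into live objects."""
    out = Path(bundle_dir)
    with open(out / "config.yaml") as fh:
        config = SimConfig.from_dict(yaml.safe_load(fh))
    from .genome_model import read_chrom_sizes
    layout = read_chrom_sizes(out / "chrom.sizes")
    tss = pd.read_csv(out / "tss.tsv", sep="\t")
    hotspots = read_bed(out / "hotspots.bed", layout)
    hotspot_truth = pd.read_csv(out / "hotspot_truth.tsv", sep="\t")
    stage_peaks = {}
    for p in sorted(out.glob("peaks_*.bed")):
        stage = p.stem.removeprefix("peaks_")
        stage_peaks[stage] = read_bed(p, layout, mark="H3K4me3", stage=stage)
    peak_truth = pd.read_csv(out / "peak_truth.tsv", sep="\t")
    nome_table = CytosineTable.from_tsv(out / "cytosine.tsv")
    ndr_truth = pd.read_csv(out / "ndr_truth.tsv", sep="\t")
    fragments = {
        p.stem.removeprefix("fragments_"): read_fragments(p)
        for p in sorted(out.glob("fragments_*.tsv"))
    }
    with open(out / "spike_counts.json") as fh:
        spike_counts = {k: int(v) for k, v in json.load(fh).items()}
    return SimBundle(
        config=config, layout=layout, tss=tss,
        hotspots=hotspots, hotspot_truth=hotspot_truth,
        stage_peaks=stage_peaks, peak_truth=peak_truth,
        nome_table=nome_table, ndr_truth=ndr_truth,
        fragments=fragments, spike_counts=spike_counts,
    )
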