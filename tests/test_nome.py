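"""Cytosine contexts, methylation levels, and the windowed chi-square NDR caller."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from meiodyn.genome_model import GenomeLayout, GenomicInterval
from meiodyn.nome import (
    Background,
    CytosineTable,
    accessibility_ratio,
    call_ndrs,
    classify_context,
    classify_ndr,
    genome_background,
    hotspot_ndr_partition,
    region_level,
    scan_and_test,
    site_level,
)


# ---------------------------------------------------------------------------
# contexts and levels
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("up,down,expected", [
    ("A", "G", "WCG"), ("T", "G", "WCG"),
    ("G", "A", "GCH"), ("G", "C", "GCH"), ("G", "T", "GCH"),
    ("G", "G", "other"),   # GCG is ambiguous and excluded from both lists
    ("C", "G", "other"),   # CCG likewise
    ("A", "A", "other"),
])
def test_classify_context(up, down, expected):
    assert classify_context(up, "C", down) == expected


def test_classify_context_requires_cytosine():
    with pytest.raises(ValueError):
        classify_context("A", "G", "G")
    with pytest.raises(ValueError):
        classify_context("Q", "C", "G")


def test_site_level():
    assert site_level(3, 4) == 0.75
    assert site_level(0, 5) == 0.0
    with pytest.raises(ValueError):
        site_level(1, 0)
    with pytest.raises(ValueError):
        site_level(5, 4)


def _table(rows):
    return CytosineTable(pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "meth", "total"]))


def test_depth_filter_keeps_3x_sites():
    t = _table([
        ("chr1", 10, "+", "GCH", 1, 2),
        ("chr1", 20, "+", "GCH", 2, 3),
        ("chr1", 30, "+", "GCH", 5, 9),
    ])
    f = t.depth_filter(3)
    assert len(f) == 2 and (f.df["total"] >= 3).all()
    assert f.depth_filtered_at == 3


def test_replicate_merge_sums_counts():
    a = _table([("chr1", 10, "+", "GCH", 1, 2)])
    b = _table([("chr1", 10, "+", "GCH", 2, 3)])
    m = a.merge(b)
    assert len(m) == 1
    assert m.df.iloc[0]["meth"] == 3 and m.df.iloc[0]["total"] == 5


def test_genome_background_mean_and_pools():
    t = _table([
        ("chr1", 10, "+", "GCH", 1, 5),   # level 0.2
        ("chr1", 20, "+", "GCH", 2, 5),   # level 0.4
        ("chr1", 30, "+", "WCG", 5, 5),
    ])
    bg = genome_background(t, "GCH")
    assert bg.mean_level == pytest.approx(0.3)
    assert (bg.meth, bg.total, bg.n_sites) == (3, 10, 2)
    with pytest.raises(ValueError):
        genome_background(_table([]), "GCH")


def test_cytosine_tsv_roundtrip(tmp_path):
    t = _table([
        ("chr1", 9, "+", "GCH", 3, 7),
        ("chr1", 41, "-", "WCG", 2, 4),
    ])
    p = tmp_path / "cg.tsv"
    t.to_tsv(p)
    back = CytosineTable.from_tsv(p)
    pd.testing.assert_frame_equal(back.df, t.df)


def test_from_tsv_classifies_trinucleotides(tmp_path):
    p = tmp_path / "tri.tsv"
    p.write_text("chr1\t10\t+\t3\t1\tACG\nchr1\t20\t+\t1\t3\tGCT\nchr1\t30\t+\t1\t1\tGCG\n")
    t = CytosineTable.from_tsv(p)
    assert list(t.df["context"]) == ["WCG", "GCH", "other"]
    assert list(t.df["pos"]) == [9, 19, 29]  # converted to 0-based


# ---------------------------------------------------------------------------
# window scan
# ---------------------------------------------------------------------------

def _grid_table(layout, level_fn, spacing=10, depth=10):
    """Deterministic table: one GCH site every `spacing` bp at given level."""
    rows = []
    for chrom in layout.chroms:
        for pos in range(spacing, layout[chrom], spacing):
            lv = level_fn(chrom, pos)
            rows.append((chrom, pos, "+", "GCH", int(round(lv * depth)), depth))
    return _table(rows)


def test_scan_window_geometry():
    lay = GenomeLayout({"chr1": 300})
    t = _grid_table(lay, lambda c, p: 0.1)
    win = scan_and_test(t, lay, win=100, step=20)
    assert list(win["start"][:3]) == [0, 20, 40]
    assert win["end"].max() == 300
    assert (win["end"] - win["start"] <= 100).all()


def test_scan_chi2_matches_direct_formula():
    """Window p equals scipy's chi-square on the same pooled 2x2 table."""
    lay = GenomeLayout({"chr1": 2000})
    t = _grid_table(lay, lambda c, p: 0.6 if 500 <= p < 600 else 0.05)
    bg = genome_background(t, "GCH")
    win = scan_and_test(t, lay)
    row = win[(win["start"] == 500)].iloc[0]
    table = np.array([
        [row["meth"], row["total"] - row["meth"]],
        [bg.meth, bg.total - bg.meth],
    ])
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    assert row["pvalue"] == pytest.approx(p, rel=1e-9)
    assert row["pvalue"] < 1e-10


def test_scan_one_sided_gate():
    """Windows at or below the genome mean level always get p = 1."""
    lay = GenomeLayout({"chr1": 1000})
    t = _grid_table(lay, lambda c, p: 0.25)  # flat: every window equals background
    win = scan_and_test(t, lay)
    assert (win["pvalue"] == 1.0).all()


def test_scan_empty_windows_flagged():
    lay = GenomeLayout({"chr1": 1000})
    t = _table([("chr1", 500, "+", "GCH", 5, 10),
                ("chr1", 510, "+", "GCH", 9, 10)])
    win = scan_and_test(t, lay)
    empty = win[win["n_sites"] == 0]
    assert len(empty) > 0
    assert (empty["pvalue"] == 1.0).all()
    assert empty["mean_level"].isna().all()


# ---------------------------------------------------------------------------
# NDR calling
# ---------------------------------------------------------------------------

def _ndr_oracle(table, layout, p_max=1e-10, min_sites=6, min_len=141,
                win=100, step=20):
    """Brute-force reference: enumerate every window, test, merge, filter."""
    sites = table.context_sites("GCH")
    levels = sites["meth"].to_numpy() / sites["total"].to_numpy()
    bg_meth = int(sites["meth"].sum())
    bg_total = int(sites["total"].sum())
    bg_mean = levels.sum() / len(levels)
    out = []
    for chrom in layout.chroms:
        sub = sites[sites["chrom"] == chrom]
        sig = []
        for start in range(0, layout[chrom], step):
            end = min(start + win, layout[chrom])
            w = sub[(sub["pos"] >= start) & (sub["pos"] < end)]
            if len(w) == 0:
                continue
            w_meth, w_total = int(w["meth"].sum()), int(w["total"].sum())
            w_mean = (w["meth"] / w["total"]).mean()
            if w_total == 0 or w_mean <= bg_mean:
                continue
            tab = np.array([[w_meth, w_total - w_meth],
                            [bg_meth, bg_total - bg_meth]])
            if (tab.sum(0) == 0).any() or (tab.sum(1) == 0).any():
                continue
            _, p, _, _ = stats.chi2_contingency(tab, correction=False)
            if p <= p_max:
                sig.append((start, end, p))
        # merge overlapping/bookended significant windows
        merged = []
        for s, e, p in sig:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
                merged[-1][2] = min(merged[-1][2], p)
            else:
                merged.append([s, e, p])
        for s, e, p in merged:
            w = sub[(sub["pos"] >= s) & (sub["pos"] < e)]
            if len(w) >= min_sites and (e - s) >= min_len:
                out.append((chrom, s, e, len(w), p))
    return out


def _random_table(rng, layout, ndr_regions, inside=0.5, outside=0.05,
                  spacing=10, depth_mean=10):
    rows = []
    for chrom in layout.chroms:
        for pos in range(spacing, layout[chrom], spacing):
            lv = outside
            for (c, s, e) in ndr_regions:
                if c == chrom and s <= pos < e:
                    lv = inside
                    break
            depth = 3 + rng.poisson(depth_mean - 3)
            meth = rng.binomial(depth, lv)
            rows.append((chrom, pos, "+", "GCH", meth, depth))
    return _table(rows)


def test_call_ndrs_matches_brute_force_oracle():
    """Record-identical to full window enumeration on a random 100-kb table."""
    lay = GenomeLayout({"chr1": 60_000, "chr2": 40_000})
    rng = np.random.default_rng(17)
    regions = [("chr1", 10_000, 10_400), ("chr1", 30_000, 30_250),
               ("chr2", 5_000, 5_600)]
    t = _random_table(rng, lay, regions)
    called = call_ndrs(t, lay)
    expected = _ndr_oracle(t, lay)
    got = [(r.chrom, r.start, r.end, r.n_sites) for r in called.itertuples()]
    assert got == [(c, s, e, n) for c, s, e, n, _ in expected]
    for rec, (_, _, _, _, p) in zip(called.itertuples(), expected):
        assert rec.min_p == pytest.approx(p, rel=1e-9)


def test_call_ndrs_null_background():
    lay = GenomeLayout({"chr1": 50_000})
    rng = np.random.default_rng(23)
    t = _random_table(rng, lay, [])
    assert len(call_ndrs(t, lay)) == 0


def test_call_ndrs_rejects_small_regions():
    """A significant region of width 120 bp or with only 5 sites is rejected."""
    lay = GenomeLayout({"chr1": 10_000})
    # single very hot 100-bp window: merged region is at most 100+2*20 wide
    # with sites only inside 100 bp -> check both knives separately
    rows = [("chr1", p, "+", "GCH", 0, 10) for p in range(10, 10_000, 10)
            if not 5000 <= p < 5100]
    rows += [("chr1", p, "+", "GCH", 10, 10) for p in range(5000, 5100, 10)]
    t = _table(rows)
    # default thresholds: region built from windows covering [4920, 5200)
    default = call_ndrs(t, lay)
    strict_len = call_ndrs(t, lay, min_len=10_000)
    assert len(strict_len) == 0
    strict_sites = call_ndrs(t, lay, min_sites=1000)
    assert len(strict_sites) == 0
    if len(default):
        assert (default["n_sites"] > 5).all()
        assert ((default["end"] - default["start"]) > 140).all()


def test_call_ndrs_pmax_monotone():
    """Tightening p_max can only shrink the NDR set (subset relation)."""
    lay = GenomeLayout({"chr1": 60_000})
    rng = np.random.default_rng(29)
    regions = [("chr1", s, s + 400) for s in range(5_000, 55_000, 10_000)]
    t = _random_table(rng, lay, regions, inside=0.35)
    loose = call_ndrs(t, lay, p_max=1e-6)
    tight = call_ndrs(t, lay, p_max=1e-20)
    loose_spans = {(r.chrom, r.start, r.end) for r in loose.itertuples()}
    for r in tight.itertuples():
        # every tight NDR lies within some loose NDR
        assert any(c == r.chrom and s <= r.start and r.end <= e
                   for c, s, e in loose_spans)


def test_every_emitted_ndr_satisfies_all_criteria():
    lay = GenomeLayout({"chr1": 60_000})
    rng = np.random.default_rng(31)
    regions = [("chr1", s, s + 400) for s in range(5_000, 55_000, 7_000)]
    t = _random_table(rng, lay, regions)
    ndrs = call_ndrs(t, lay)
    assert len(ndrs) > 0
    assert (ndrs["min_p"] <= 1e-10).all()
    assert (ndrs["n_sites"] > 5).all()
    assert ((ndrs["end"] - ndrs["start"]) > 140).all()


# ---------------------------------------------------------------------------
# proximal/distal, region levels, partition
# ---------------------------------------------------------------------------

def _ndr_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


@pytest.mark.parametrize("start,end,expected", [
    (4000, 4400, "proximal"),    # 0.6-1.0 kb from the TSS at 5000
    (7000, 7400, "distal"),      # nearest TSS 2.0 kb away
    (6500, 6700, "proximal"),    # start edge exactly 1.5 kb away: inclusive
    (2000, 3500, "proximal"),    # end edge exactly 1.5 kb away: inclusive
])
def test_classify_ndr_boundaries(start, end, expected):
    ndrs = _ndr_frame([("chr1", start, end)])
    out = classify_ndr(ndrs, [("chr1", 5000)])
    assert out["class"].iloc[0] == expected


def test_classify_ndr_empty_tss_warns():
    with pytest.warns(UserWarning):
        out = classify_ndr(_ndr_frame([("chr1", 0, 200)]), [])
    assert (out["class"] == "distal").all()


def test_region_level_and_min_sites():
    t = _table([
        ("chr1", 10, "+", "GCH", 1, 5),
        ("chr1", 20, "+", "GCH", 2, 5),
        ("chr1", 30, "+", "GCH", 3, 5),
    ])
    r = GenomicInterval("chr1", 0, 100)
    assert region_level(r, t) == pytest.approx(0.4)
    assert np.isnan(region_level(GenomicInterval("chr1", 0, 25), t))  # 2 sites


def test_region_level_site_order_invariant():
    rows = [("chr1", p, "+", "GCH", p % 5, 5) for p in (50, 10, 30, 10, 50)]
    t = _table(rows)  # duplicates merged, order normalized
    r = GenomicInterval("chr1", 0, 100)
    t2 = _table(list(reversed(rows)))
    assert region_level(r, t) == region_level(r, t2)


def test_accessibility_ratio_identity_and_scaling():
    lay_rows = [("chr1", p, "+", "GCH", (p // 10) % 6, 10)
                for p in range(10, 5000, 10)]
    t = _table(lay_rows)
    whole = GenomicInterval("chr1", 0, 5000)
    assert accessibility_ratio([whole], t)[0] == 1.0
    # region at level 0.10 over genome background computed from the table
    t2 = _table([("chr1", 10, "+", "GCH", 1, 10),
                 ("chr1", 20, "+", "GCH", 0, 10),
                 ("chr1", 30, "+", "GCH", 2, 10),
                 ("chr1", 1000, "+", "GCH", 1, 10),
                 ("chr1", 1010, "+", "GCH", 0, 10),
                 ("chr1", 1020, "+", "GCH", 2, 10)])
    bg = genome_background(t2, "GCH")
    r = accessibility_ratio([GenomicInterval("chr1", 0, 100)], t2)[0]
    assert r == pytest.approx(0.1 / bg.mean_level)


def test_hotspot_ndr_partition_center_rule():
    ndrs = classify_ndr(_ndr_frame([("chr1", 1000, 2000)]), [("chr1", 50_000)])
    assert (ndrs["class"] == "distal").all()
    hotspots = [
        GenomicInterval("chr1", 1400, 1600),   # center 1500: inside
        GenomicInterval("chr1", 1900, 2300),   # center 2100: outside
        GenomicInterval("chr1", 30_000, 30_200),
    ]
    out = hotspot_ndr_partition(hotspots, ndrs)
    assert out["within_ndr"] == 1 and out["outside_ndr"] == 2
    assert out["fraction_within"] == pytest.approx(1 / 3)
    assert out["within_distal"] == 1 and out["within_proximal"] == 0


def test_hotspot_ndr_partition_no_ndrs():
    out = hotspot_ndr_partition([GenomicInterval("chr1", 0, 100)],
                                _ndr_frame([]))
    assert out["within_ndr"] == 0 and out["fraction_within"] == 0.0
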