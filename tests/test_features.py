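"""OCR classification, signal arithmetic, differential gates and enhancers."""

import numpy as np
import pandas as pd
import pytest

from chromarch.features import (
    call_enhancers,
    classify_histone_cases,
    classify_ocrs,
    deg_call,
    differential_enhancers,
    differential_regions,
    metaprofile,
    peak_enrichment,
    track_mean,
)
from conftest import regions


GENE = pd.DataFrame(
    {"chrom": ["chr1"], "start": [10_000], "end": [20_000],
     "strand": ["+"], "gene_id": ["g1"]}
)


def constant_track(value, n_steps=200, step=500):
    pos = np.arange(n_steps) * step
    return pd.DataFrame(
        {"chrom": "chr1", "start": pos, "end": pos + step, "value": value}
    )


# ---------------------------------------------------------------------------
# OCR locality
# ---------------------------------------------------------------------------

def test_ocr_window_arithmetic_plus_strand():
    peaks = regions("chr1", (6_000, 6_500), (9_500, 10_200), (19_000, 22_000))
    calls = classify_ocrs(peaks, GENE)
    # window is [7,000, 20,000): peak ending at 6,500 is distal
    assert calls["locality"].tolist() == ["distal", "local", "local"]


def test_ocr_window_arithmetic_minus_strand():
    gene = GENE.assign(strand="-")
    # minus-strand window is [10,000, 23,000)
    peaks = regions("chr1", (6_000, 9_900), (22_000, 22_500), (23_100, 24_000))
    calls = classify_ocrs(peaks, gene)
    assert calls["locality"].tolist() == ["distal", "local", "distal"]


def test_empty_gene_list_makes_all_distal():
    peaks = regions("chr1", (0, 500), (1_000, 1_500))
    calls = classify_ocrs(peaks, GENE.head(0))
    assert (calls["locality"] == "distal").all()


def test_ocr_local_fraction_on_synthetic_truth(default_truth, default_config):
    calls = classify_ocrs(default_truth.peaks["ATAC"]["a"], default_truth.genes)
    frac = (calls["locality"] == "local").mean()
    p = default_config.atac_local_fraction
    se = np.sqrt(p * (1 - p) / len(calls))
    assert abs(frac - p) < max(4 * se, 0.03)


# ---------------------------------------------------------------------------
# Signal arithmetic
# ---------------------------------------------------------------------------

def test_peak_enrichment_is_signal_minus_background():
    sig = constant_track(5.0)
    bg = constant_track(2.0)
    assert peak_enrichment(sig, bg, "chr1", 1_000, 3_000) == pytest.approx(3.0)
    assert peak_enrichment(sig, sig, "chr1", 1_000, 3_000) == pytest.approx(0.0)


def test_track_mean_errors_outside_coverage():
    with pytest.raises(ValueError):
        track_mean(constant_track(1.0), "chrX", 0, 100)
    with pytest.raises(ValueError):
        track_mean(constant_track(1.0), "chr1", 100, 100)


# ---------------------------------------------------------------------------
# Differential regions
# ---------------------------------------------------------------------------

def test_identical_tables_give_no_significant_regions():
    rng = np.random.default_rng(0)
    n = 200
    counts = rng.poisson(50, size=(n, 2))
    dr = differential_regions(
        regions("chr1", *[(i * 1000, i * 1000 + 500) for i in range(n)]),
        counts, counts, [1e6, 1e6], [1e6, 1e6],
    )
    assert dr["significant"].sum() == 0


def test_log2fc_arithmetic_with_pseudocount():
    reg = regions("chr1", (0, 500))
    dr = differential_regions(
        reg, np.array([[100, 100]]), np.array([[12, 13]]),
        [1e6, 1e6], [1e6, 1e6],
    )
    assert dr.loc[0, "log2fc"] == pytest.approx(np.log2(101 / 13.5))


def test_single_replicate_poisson_branch():
    reg = regions("chr1", (0, 500), (1000, 1500))
    dr = differential_regions(
        reg, np.array([[400], [50]]), np.array([[50], [50]]), [1e6], [1e6]
    )
    assert dr.loc[0, "significant"]
    assert dr.loc[0, "direction"] == "A-enriched"
    assert not dr.loc[1, "significant"]


def test_null_type_one_error_controlled():
    for seed in range(3):
        rng = np.random.default_rng(seed)
        n = 1000
        lam = rng.uniform(20, 200, n)
        ca = rng.poisson(lam[:, None], (n, 2))
        cb = rng.poisson(lam[:, None], (n, 2))
        dr = differential_regions(
            regions("chr1", *[(i * 1000, i * 1000 + 500) for i in range(n)]),
            ca, cb, [1e6, 1e6], [1e6, 1e6],
        )
        frac = (dr["p_value"] < 0.05).mean()
        assert frac <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n)
        assert dr["significant"].mean() <= 0.05


def test_zero_library_size_rejected():
    with pytest.raises(ValueError):
        differential_regions(
            regions("chr1", (0, 500)), np.array([[1]]), np.array([[1]]), [0], [1e6]
        )


# ---------------------------------------------------------------------------
# DEG calling
# ---------------------------------------------------------------------------

def make_expression(rng, n, fold=1.0, n_deg=0, sigma=0.25, n_reps=3):
    base = np.exp(rng.normal(2.0, 1.0, n))
    mean_a = base.copy()
    mean_b = base.copy()
    mean_b[:n_deg] = mean_a[:n_deg] * fold
    tab = pd.DataFrame({"gene_id": [f"g{i}" for i in range(n)]})
    for cond, mean in (("a", mean_a), ("b", mean_b)):
        for r in range(n_reps):
            tab[f"{cond}_{r+1}"] = mean * np.exp(rng.normal(0, sigma, n))
    return tab


def test_deg_null_false_positive_rate():
    for seed in range(3):
        tab = make_expression(np.random.default_rng(seed), 2000)
        deg = deg_call(tab, ["a_1", "a_2", "a_3"], ["b_1", "b_2", "b_3"])
        fpr = (deg["call"] != "ns").mean()
        assert fpr <= 0.01 + 2 * np.sqrt(0.01 * 0.99 / 2000)


def test_deg_recovers_planted_four_fold_effects():
    tab = make_expression(np.random.default_rng(42), 2000, fold=4.0, n_deg=200)
    deg = deg_call(tab, ["a_1", "a_2", "a_3"], ["b_1", "b_2", "b_3"])
    called = deg["call"] != "ns"
    truth = np.zeros(2000, bool)
    truth[:200] = True
    assert (called & truth).sum() / truth.sum() >= 0.9
    assert (called & ~truth).sum() / max(called.sum(), 1) <= 0.05
    assert (deg.loc[truth & called.to_numpy(), "call"] == "B-enriched").all()


def test_expression_classes_and_identical_means():
    tab = pd.DataFrame(
        {
            "gene_id": ["hi", "lo"],
            "a_1": [118.0, 0.5], "a_2": [122.0, 0.5],
            "b_1": [121.0, 0.2], "b_2": [119.0, 0.2],
        }
    )
    deg = deg_call(tab, ["a_1", "a_2"], ["b_1", "b_2"])
    assert deg.loc[0, "call"] == "ns"
    assert deg.loc[0, "class_a"] == "high" and deg.loc[0, "class_b"] == "high"
    assert deg.loc[1, "class_a"] == "non-expressed"
    assert deg.loc[1, "class_b"] == "non-expressed"


def test_deg_requires_replicates():
    tab = pd.DataFrame({"gene_id": ["g"], "a_1": [1.0], "b_1": [1.0]})
    with pytest.raises(ValueError):
        deg_call(tab, ["a_1"], ["b_1"])


# ---------------------------------------------------------------------------
# Histone cases and enhancers
# ---------------------------------------------------------------------------

def test_histone_case_definitions():
    reg = regions("chr1", (0, 1000), (2000, 3000), (4000, 5000), (6000, 7000))
    peaksets = {
        "H3K27me3": regions("chr1", (0, 1000)),
        "H3K4me3": regions("chr1", (4000, 5000)),
        "H3K9ac": regions("chr1", (4000, 5000), (6000, 7000)),
    }
    cased = classify_histone_cases(reg, peaksets)
    assert cased["case"].tolist() == ["Case1", "Case2", "Case3", "Case4"]


def test_histone_case_conflict_precedence():
    reg = regions("chr1", (0, 1000))
    # K27 covers the whole region, active marks cover less -> Case1
    cased = classify_histone_cases(
        reg,
        {
            "H3K27me3": regions("chr1", (0, 1000)),
            "H3K4me3": regions("chr1", (0, 300)),
            "H3K9ac": regions("chr1", (0, 300)),
        },
    )
    assert cased["case"].tolist() == ["Case1"]
    # active marks dominate coverage -> Case3
    cased2 = classify_histone_cases(
        reg,
        {
            "H3K27me3": regions("chr1", (0, 100)),
            "H3K4me3": regions("chr1", (0, 1000)),
            "H3K9ac": regions("chr1", (0, 1000)),
        },
    )
    assert cased2["case"].tolist() == ["Case3"]


def test_enhancers_exclude_promoter_windows():
    reg = regions("chr1", (8_000, 9_000), (50_000, 51_000))
    peaksets = {"H3K9ac": regions("chr1", (8_000, 9_000), (50_000, 51_000))}
    cased = classify_histone_cases(reg, peaksets)
    enh = call_enhancers(cased, GENE)  # promoter window [7,000, 13,000)
    assert enh["start"].tolist() == [50_000]
    # invariant: never overlaps any +/-3 kb TSS window
    from chromarch.genome import overlaps_any, promoter_windows

    windows = promoter_windows(GENE, 3000, 3000)
    assert not overlaps_any(enh, windows).any()


def test_differential_enhancers_carry_mark_status():
    enh = regions("chr1", (50_000, 51_000))
    dr = regions("chr1", (50_200, 50_800))
    dr["log2fc"] = [2.0]
    dr["q_value"] = [0.001]
    dr["significant"] = [True]
    dr["direction"] = ["B-enriched"]
    out = differential_enhancers(enh, {"H3K9ac": dr})
    assert out["H3K9ac_status"].tolist() == ["B-gain"]


# ---------------------------------------------------------------------------
# Metaprofiles
# ---------------------------------------------------------------------------

def test_metaprofile_constant_track_is_flat():
    track = constant_track(3.0)
    anchors = pd.DataFrame({"chrom": ["chr1"], "pos": [50_000], "strand": ["+"]})
    mat, mean = metaprofile(track, anchors, flank_bp=2000, bin_bp=100)
    assert np.allclose(mean, 3.0)


def test_metaprofile_strand_flip_mirrors_asymmetric_bump():
    pos = np.arange(0, 100_000, 100)
    val = np.where((pos >= 50_000) & (pos < 51_000), 9.0, 1.0)
    track = pd.DataFrame(
        {"chrom": "chr1", "start": pos, "end": pos + 100, "value": val}
    )
    plus = pd.DataFrame({"chrom": ["chr1"], "pos": [50_000], "strand": ["+"]})
    minus = plus.assign(strand="-")
    _, prof_plus = metaprofile(track, plus, flank_bp=2000, bin_bp=100)
    _, prof_minus = metaprofile(track, minus, flank_bp=2000, bin_bp=100)
    assert np.allclose(prof_minus, prof_plus[::-1])


def test_metaprofile_excludes_edge_anchors_from_means():
    track = constant_track(2.0)
    anchors = pd.DataFrame(
        {"chrom": ["chr1", "chr1"], "pos": [500, 50_000], "strand": ["+", "+"]}
    )
    mat, mean = metaprofile(track, anchors, flank_bp=2000, bin_bp=100)
    assert np.isnan(mat[0]).any()
    assert np.allclose(mean, 2.0)
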