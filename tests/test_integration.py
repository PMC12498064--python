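"""Cross-layer linking: dOCR-gene loops, TFBS categories, controls, arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from chromarch.integration import (
    active_docr_loop_rate,
    classify_docr_activity,
    docr_gene_loops,
    enhancer_gene_links,
    genes_in_switched_bins,
    percent_change,
    percentage,
    pooled_percentage,
    shifted_controls,
    tfbs_loop_categories,
)
from chromarch.loops import Loop, classify_loops
from conftest import regions


def mkloop(s1, s2, width=10_000, chrom="chr1"):
    return Loop(chrom, s1, s1 + width, s2, s2 + width, width, 1.0, 0.01)


def random_fixture(rng, span=5_000_000):
    genes = pd.DataFrame({"chrom": "chr1", "start": rng.integers(0, span, 25)})
    genes["end"] = genes["start"] + rng.integers(2_000, 8_000, 25)
    genes["strand"] = np.where(rng.random(25) < 0.5, "+", "-")
    genes["gene_id"] = [f"g{i}" for i in range(25)]
    loops = []
    for _ in range(20):
        s1 = int(rng.integers(0, span - 1_200_000))
        loops.append(mkloop(s1, s1 + int(rng.integers(200_000, 1_000_000))))
    ocrs = pd.DataFrame({"chrom": "chr1", "start": rng.integers(0, span, 60)})
    ocrs["end"] = ocrs["start"] + 400
    ocrs["locality"] = np.where(rng.random(60) < 0.7, "distal", "local")
    return genes, loops, ocrs


# ---------------------------------------------------------------------------
# Reporting arithmetic (worked examples from printed counts)
# ---------------------------------------------------------------------------

def test_pooled_anchoring_rate_from_printed_counts():
    assert pooled_percentage([(223, 6_455), (487, 10_878)]) == 4.1


def test_active_docr_participation_from_printed_counts():
    assert percentage(12, 964) == 1.2
    assert percentage(15, 1_057) == 1.4  # the quotient the printed counts give


def test_percent_change_arithmetic():
    assert percent_change(16.2, 30.7) == 89.5
    assert percent_change(10.0, 10.0) == 0.0
    assert percent_change(10.0, 5.0) == -50.0
    with pytest.raises(ValueError):
        percent_change(0.0, 5.0)


@given(
    st.floats(0.1, 1e4, allow_nan=False),
    st.floats(0.0, 1e4, allow_nan=False),
)
def test_percent_change_sign_and_inverse(control, treatment):
    pc = percent_change(control, treatment, decimals=6)
    assert (pc >= 0) == (treatment >= control)
    assert pc == pytest.approx(
        100 * (treatment - control) / control, abs=1e-4
    )


# ---------------------------------------------------------------------------
# dOCR-gene loops
# ---------------------------------------------------------------------------

def brute_force_links(loops, classes, ocrs, genes):
    """Independent O(anchors x dOCRs) enumeration."""
    docrs = ocrs[ocrs["locality"] == "distal"].reset_index(drop=True)
    out = []
    for loop, cls in zip(loops, classes):
        if cls != "intergenic-gene":
            continue
        anchors = [(loop.start1, loop.end1), (loop.start2, loop.end2)]
        genic = [
            any(gs < e and ge > s for gs, ge in zip(genes["start"], genes["end"]))
            for s, e in anchors
        ]
        inter = anchors[0] if not genic[0] else anchors[1]
        hit = sorted(
            i for i, (ds, de) in enumerate(zip(docrs["start"], docrs["end"]))
            if ds < inter[1] and de > inter[0]
        )
        if hit:
            out.append((inter, tuple(hit)))
    return out


def test_docr_gene_loops_matches_brute_force_on_random_fixtures():
    for seed in range(30):
        rng = np.random.default_rng(seed)
        genes, loops, ocrs = random_fixture(rng)
        classes = classify_loops(loops, genes)
        links, frac = docr_gene_loops(loops, classes, ocrs, genes)
        oracle = brute_force_links(loops, classes, ocrs, genes)
        got = [((l.intergenic_anchor[1], l.intergenic_anchor[2]),
                tuple(l.docr_indices)) for l in links]
        assert got == oracle
        n_ig = sum(1 for c in classes if c == "intergenic-gene")
        if n_ig:
            assert frac == pytest.approx(round(100 * len(oracle) / n_ig, 1))


def test_docr_gene_loops_no_docrs_gives_zero_fraction():
    rng = np.random.default_rng(1)
    genes, loops, ocrs = random_fixture(rng)
    ocrs["locality"] = "local"
    classes = classify_loops(loops, genes)
    links, frac = docr_gene_loops(loops, classes, ocrs, genes)
    assert links == [] and frac == 0.0


# ---------------------------------------------------------------------------
# dOCR activity
# ---------------------------------------------------------------------------

def diffregion(span, direction):
    df = regions("chr1", span)
    df["log2fc"] = 2.0 if direction == "A-enriched" else -2.0
    df["q_value"] = 1e-4
    df["significant"] = True
    df["direction"] = direction
    return df


EMPTY_DR = diffregion((0, 1), "A-enriched").head(0)


def test_docr_activity_rules():
    docrs = regions("chr1", (10_000, 10_400), (50_000, 50_400), (90_000, 90_400))
    atac = diffregion((10_100, 10_300), "A-enriched")
    # weaker K27 in B == K27 A-enriched -> B-active; 1 kb away, 2 kb flank
    k27 = diffregion((51_400, 52_000), "A-enriched")
    out = classify_docr_activity(docrs, atac, k27, flank_bp=2000)
    assert out["activity"].tolist() == ["A-active", "B-active", "static"]


def test_docr_activity_conflict_is_static():
    docrs = regions("chr1", (10_000, 10_400))
    atac = diffregion((10_000, 10_400), "A-enriched")  # more open in A
    k27 = diffregion((10_000, 10_400), "A-enriched")   # weaker K27 in B
    out = classify_docr_activity(docrs, atac, k27)
    # ATAC evidence says A-active, K27 evidence says B-active -> conflict
    assert out["activity"].tolist() == ["static"]
    assert out["conflict"].tolist() == [True]


def test_docr_activity_antisymmetric_under_label_swap():
    rng = np.random.default_rng(2)
    docrs = regions("chr1", *[(int(s), int(s) + 400)
                              for s in rng.integers(0, 1_000_000, 30)])
    atac = pd.concat(
        [diffregion((int(s), int(s) + 300), d) for s, d in zip(
            rng.integers(0, 1_000_000, 10),
            np.where(rng.random(10) < 0.5, "A-enriched", "B-enriched"),
        )],
        ignore_index=True,
    )
    swapped = atac.copy()
    swapped["direction"] = np.where(
        atac["direction"] == "A-enriched", "B-enriched", "A-enriched"
    )
    fwd = classify_docr_activity(docrs, atac, EMPTY_DR)
    rev = classify_docr_activity(docrs, swapped, EMPTY_DR)
    mapping = {"A-active": "B-active", "B-active": "A-active", "static": "static"}
    assert rev["activity"].tolist() == [mapping[a] for a in fwd["activity"]]


def test_active_docr_loop_rate_counts():
    docrs = regions("chr1", (0, 400), (1_000, 1_400), (2_000, 2_400))
    docrs["activity"] = ["A-active", "A-active", "static"]
    link = type("L", (), {})()
    link.docr_indices = [0]
    assert active_docr_loop_rate(docrs, [link], "a") == 50.0
    link2 = type("L", (), {})()
    link2.docr_indices = [0, 1]
    assert active_docr_loop_rate(docrs, [link, link2], "a") == 100.0
    with pytest.raises(ValueError):
        active_docr_loop_rate(docrs, [], "b")


# ---------------------------------------------------------------------------
# TFBS categories and enhancer links
# ---------------------------------------------------------------------------

def test_tfbs_categories_hand_enumeration():
    from chromarch.integration import DocrGeneLink

    link = DocrGeneLink(
        mkloop(100_000, 500_000), ("chr1", 100_000, 110_000),
        ("chr1", 500_000, 510_000), [0], ["g1"],
    )
    sites = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": [101_000, 501_000, 102_000, 900_000],
            "end": [101_010, 501_010, 102_010, 900_010],
            "motif_id": ["M1", "M1", "M2", "M2"],
        }
    )
    out = tfbs_loop_categories(sites, [link]).set_index("motif_id")
    # M1 on both anchors -> Joint; M2 only on the dOCR anchor; off-anchor
    # occurrences are not counted
    assert out.loc["M1", "joint_tfbs"] == 1
    assert out.loc["M1", "docr_tfbs"] == 0 and out.loc["M1", "local_tfbs"] == 0
    assert out.loc["M2", "docr_tfbs"] == 1 and out.loc["M2", "joint_tfbs"] == 0
    row = out.loc["M2"]
    assert row["docr_tfbs"] + row["local_tfbs"] + row["joint_tfbs"] == 1


def test_enhancer_gene_links_match_brute_force():
    for seed in range(30):
        rng = np.random.default_rng(100 + seed)
        genes, loops, _ = random_fixture(rng)
        enh = pd.DataFrame({"chrom": "chr1", "start": rng.integers(0, 5_000_000, 15)})
        enh["end"] = enh["start"] + 1_000
        got = enhancer_gene_links(enh, loops, genes, promoter_bp=3000)
        # oracle: triple loop over enhancers x loops x promoters
        proms = []
        for _, g in genes.iterrows():
            tss = g["start"] if g["strand"] == "+" else g["end"]
            lo, hi = (tss - 3000, tss) if g["strand"] == "+" else (tss, tss + 3000)
            proms.append((max(lo, 0), hi, g["gene_id"]))
        expected = set()
        for _, e in enh.iterrows():
            for loop in loops:
                anchors = [(loop.start1, loop.end1), (loop.start2, loop.end2)]
                for side in (0, 1):
                    s, t = anchors[side]
                    if e["start"] < t and e["end"] > s:
                        ps, pt = anchors[1 - side]
                        for lo, hi, gid in proms:
                            if lo < pt and hi > ps:
                                expected.add((e["start"], gid))
        found = set(zip(got.get("enhancer_start", []), got.get("gene_id", [])))
        assert found == expected


def test_genes_in_switched_bins_enumeration():
    switch = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1"],
            "start": [0, 100_000],
            "end": [100_000, 200_000],
            "pattern": ["B2A", "A2A"],
        }
    )
    genes = pd.DataFrame(
        {
            "chrom": ["chr1"] * 3,
            "start": [10_000, 50_000, 150_000],
            "end": [20_000, 60_000, 160_000],
            "strand": ["+"] * 3,
            "gene_id": ["d1", "d2", "d3"],
        }
    )
    degs = pd.DataFrame(
        {"gene_id": ["d1", "d2", "d3"], "call": ["A-enriched", "B-enriched", "A-enriched"]}
    )
    out = genes_in_switched_bins(switch, genes, degs)
    assert sorted(out["gene_id"]) == ["d1", "d2"]  # d3 is in an A2A bin
    none = genes_in_switched_bins(switch.assign(pattern="A2A"), genes, degs)
    assert len(none) == 0


# ---------------------------------------------------------------------------
# Shifted controls
# ---------------------------------------------------------------------------

def test_shifted_controls_preserve_widths_and_stay_on_chromosome():
    rng = np.random.default_rng(0)
    docrs = regions(
        "chr1", *[(int(s), int(s) + int(w)) for s, w in zip(
            rng.integers(0, 9_000_000, 50), rng.integers(200, 2_000, 50)
        )]
    )
    sizes = {"chr1": 10_000_000}
    ctrl = shifted_controls(docrs, sizes, seed=5)
    assert len(ctrl) == len(docrs)
    w0 = sorted((docrs["end"] - docrs["start"]).tolist())
    w1 = sorted((ctrl["end"] - ctrl["start"]).tolist())
    assert w0 == w1
    assert (ctrl["start"] >= 0).all()
    assert (ctrl["end"] <= sizes["chr1"]).all()
    ctrl2 = shifted_controls(docrs, sizes, seed=6)
    assert not ctrl.equals(ctrl2)
    assert ctrl.equals(shifted_controls(docrs, sizes, seed=5))
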