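"""Loop calling, multi-resolution merging, comparison, classing and APA."""

import numpy as np
import pandas as pd
import pytest

from chromarch.contacts import ContactMap, balance, observed_over_expected
from chromarch.loops import (
    Loop,
    apa,
    call_loops,
    classify_loops,
    compare_loops,
    merge_resolutions,
)
from conftest import prebalanced, toy_contact_map


def mkloop(s1, s2, width=10_000, res=10_000, score=1.0, chrom="chr1"):
    return Loop(chrom, s1, s1 + width, s2, s2 + width, res, score, 0.01)


def test_loop_anchor_ordering_enforced():
    with pytest.raises(ValueError):
        Loop("chr1", 50_000, 60_000, 20_000, 30_000, 10_000, 1.0, 0.1)


def test_uniform_matrix_yields_no_calls_in_most_seeds():
    hits = 0
    for seed in range(40):
        rng = np.random.default_rng(seed)
        n = 120
        upper = rng.poisson(np.triu(np.full((n, n), 8.0)))
        mat = upper + np.triu(upper, 1).T
        cmap = balance(toy_contact_map(mat, resolution=20_000))
        if call_loops(cmap, max_dist_bp=1_000_000):
            hits += 1
    assert hits / 40 <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / 40)


def test_single_planted_pixel_is_called_exactly():
    rng = np.random.default_rng(3)
    n = 150
    idx = np.arange(n)
    s = np.maximum(np.abs(idx[:, None] - idx[None, :]), 1.0)
    lam = 200.0 / s
    lam[40, 90] = lam[90, 40] = lam[40, 90] * 20
    upper = rng.poisson(np.triu(lam))
    mat = upper + np.triu(upper, 1).T
    cmap = balance(toy_contact_map(mat, resolution=20_000))
    calls = call_loops(cmap, max_dist_bp=2_000_000)
    assert len(calls) == 1
    assert calls[0].start1 // 20_000 == 40
    assert calls[0].start2 // 20_000 == 90


def test_planted_loop_recovery_multiresolution(loop_depth_config):
    """Merged 10+20-kb calls recover planted loops at +-1 bin tolerance."""
    import dataclasses

    from chromarch.synthetic import make_genome, simulate_contacts

    def center(l):
        return ((l.start1 + l.end1) // 2, (l.start2 + l.end2) // 2)

    tp = fn = matched = ncalled = 0
    for seed in (1, 2):
        base = dataclasses.replace(loop_depth_config, seed=seed)
        truth = make_genome(base)
        sets = {}
        for res in (10_000, 20_000):
            cfg = base.at_resolution(res)
            cmap = balance(simulate_contacts(truth, cfg, "a"))
            sets[res] = call_loops(cmap)
        merged = merge_resolutions(sets)
        ncalled += len(merged)
        keep = truth.loops["status"].isin(["shared", "a_only"])
        pix_bp = {
            c: [
                (r["start1"] + 5_000, r["start2"] + 5_000)
                for _, r in truth.loops[keep & (truth.loops["chrom"] == c)].iterrows()
            ]
            for c in truth.chromsizes
        }
        for chrom, planted in pix_bp.items():
            calls = [l for l in merged if l.chrom == chrom]
            for p1, p2 in planted:
                if any(
                    abs(center(l)[0] - p1) <= l.resolution
                    and abs(center(l)[1] - p2) <= l.resolution
                    for l in calls
                ):
                    tp += 1
                else:
                    fn += 1
            for l in calls:
                if any(
                    abs(center(l)[0] - p1) <= l.resolution
                    and abs(center(l)[1] - p2) <= l.resolution
                    for p1, p2 in planted
                ):
                    matched += 1
    assert tp / (tp + fn) >= 0.8
    assert matched / ncalled >= 0.8


def test_merge_keeps_finest_resolution():
    fine = mkloop(100_000, 500_000, res=5_000, width=5_000, score=2.0)
    mid = mkloop(100_000, 500_000, res=10_000, width=10_000, score=5.0)
    coarse = mkloop(100_000, 500_000, res=20_000, width=20_000, score=9.0)
    merged = merge_resolutions({5_000: [fine], 10_000: [mid], 20_000: [coarse]})
    assert len(merged) == 1
    assert merged[0].resolution == 5_000


def test_merge_preserves_disjoint_calls():
    a = mkloop(100_000, 500_000, res=5_000, width=5_000)
    b = mkloop(900_000, 1_500_000, res=20_000, width=20_000)
    merged = merge_resolutions({5_000: [a], 20_000: [b]})
    assert len(merged) == 2


def test_merge_output_has_no_mutually_overlapping_pairs():
    rng = np.random.default_rng(0)
    for _ in range(20):
        sets = {}
        for res in (5_000, 10_000, 20_000):
            loops = []
            for _ in range(12):
                s1 = int(rng.integers(0, 80)) * 10_000
                s2 = s1 + int(rng.integers(20, 60)) * 10_000
                loops.append(mkloop(s1, s2, width=res, res=res,
                                    score=float(rng.random())))
            sets[res] = loops
        merged = merge_resolutions(sets)
        assert len(merged) <= sum(len(v) for v in sets.values())
        from chromarch.loops import _anchors_overlap

        for i, x in enumerate(merged):
            for y in merged[i + 1:]:
                assert not _anchors_overlap(x, y)


def test_compare_loops_interval_arithmetic():
    a = [mkloop(100_000, 500_000)]
    # 3-kb shift on 10-kb anchors: reciprocal overlap 0.7 >= 0.5 -> common
    b_common = [mkloop(103_000, 503_000)]
    cmp1 = compare_loops(a, b_common, f=0.5, slop_bp=40_000)
    assert len(cmp1.common) == 1 and not cmp1.a_specific and not cmp1.b_specific
    # 60-kb shift on one anchor: f fails and exceeds the 40-kb slop
    b_far = [mkloop(100_000, 560_000)]
    cmp2 = compare_loops(a, b_far, f=0.5, slop_bp=40_000)
    assert not cmp2.common
    assert len(cmp2.a_specific) == 1 and len(cmp2.b_specific) == 1


def test_compare_loops_identity_and_symmetry():
    loops = [mkloop(100_000, 500_000), mkloop(700_000, 1_200_000, score=3.0)]
    self_cmp = compare_loops(loops, loops)
    assert len(self_cmp.common) == 2
    assert not self_cmp.a_specific and not self_cmp.b_specific
    other = [mkloop(100_000, 500_000), mkloop(2_000_000, 2_500_000)]
    fwd = compare_loops(loops, other)
    rev = compare_loops(other, loops)
    assert {(l1.start1, l2.start1) for l1, l2 in fwd.common} == {
        (l2.start1, l1.start1) for l1, l2 in rev.common
    }
    assert [l.start1 for l in fwd.a_specific] == [l.start1 for l in rev.b_specific]


def test_classify_loops_matches_brute_force():
    rng = np.random.default_rng(5)
    genes = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": rng.integers(0, 3_000_000, 40),
        }
    )
    genes["end"] = genes["start"] + rng.integers(1000, 5000, 40)
    genes["strand"] = "+"
    genes["gene_id"] = [f"g{i}" for i in range(40)]
    loops = []
    for _ in range(30):
        s1 = int(rng.integers(0, 2_000_000))
        loops.append(mkloop(s1, s1 + int(rng.integers(100_000, 900_000))))
    got = classify_loops(loops, genes)
    for loop, cls in zip(loops, got):
        genic = []
        for s, e in ((loop.start1, loop.end1), (loop.start2, loop.end2)):
            genic.append(
                any(gs < e and ge > s for gs, ge in zip(genes["start"], genes["end"]))
            )
        n = sum(genic)
        assert cls == ["intergenic-intergenic", "intergenic-gene", "gene-gene"][n]


def test_classify_loops_gene_desert_and_empty():
    genes = pd.DataFrame(
        {"chrom": ["chr1"], "start": [5_000_000], "end": [5_010_000],
         "strand": ["+"], "gene_id": ["g"]}
    )
    loops = [mkloop(100_000, 500_000)]
    assert classify_loops(loops, genes) == ["intergenic-intergenic"]
    loops2 = [mkloop(4_995_000, 5_500_000)]
    assert classify_loops(loops2, genes) == ["intergenic-gene"]


def test_apa_uniform_oe_scores_one():
    from chromarch.contacts import MatrixBundle

    n = 100
    oe = MatrixBundle(10_000, {"chr1": n * 10_000}, {"chr1": np.ones((n, n))})
    loops = [mkloop(200_000, 600_000)]
    pileup, score, used = apa(oe, loops, flank_bins=5)
    assert used == 1
    assert np.allclose(pileup, 1.0)
    assert score == pytest.approx(1.0)


def test_apa_planted_and_shifted_controls(loop_depth_config):
    from chromarch.synthetic import make_genome, simulate_contacts

    truth = make_genome(loop_depth_config)
    cmap = balance(simulate_contacts(truth, loop_depth_config, "a"))
    oe = observed_over_expected(cmap)
    res = 20_000
    true_loops = []
    for _, r in truth.loops[truth.loops["status"].isin(["shared", "a_only"])].iterrows():
        i, j = r["start1"] // res, r["start2"] // res
        true_loops.append(mkloop(i * res, j * res, width=res, res=res, chrom=r["chrom"]))
    _, score, used = apa(oe, true_loops)
    assert used >= 20
    assert score > 1.0
    rng = np.random.default_rng(0)
    ctrl_scores = []
    for _ in range(20):
        ctrl = []
        for l in true_loops:
            shift = int(rng.integers(25, 60)) * res
            if l.start2 + shift + res < cmap.chromsizes[l.chrom]:
                ctrl.append(mkloop(l.start1 + shift, l.start2 + shift,
                                   width=res, res=res, chrom=l.chrom))
        ctrl_scores.append(apa(oe, ctrl)[1])
    mean, sd = np.mean(ctrl_scores), np.std(ctrl_scores)
    assert abs(mean - 1.0) <= 2 * sd
    assert score > mean + 2 * sd
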