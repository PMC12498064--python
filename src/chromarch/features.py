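"""Open-chromatin, histone-mark, enhancer and expression-level analyses.

Conventions used throughout:

* an OCR is **local** iff it overlaps (>= 1 bp) the strand-aware window from
  3 kb upstream of a gene's TSS through its TTS; everything else is distal;
* differential regions gate at |log2 fold enrichment| > 0.5 and FDR < 0.05;
* differentially expressed genes gate at q < 0.01 and fold change > 1.5,
  with expression classes FPKM > 100 (high) and FPKM < 1 (non-expressed);
* histone four-case classification: Case1 strong H3K27me3, Case2 all weak,
  Case3 strong H3K4me3 + H3K9ac, Case4 strong H3K9ac; putative enhancers
  are Case3/Case4 regions outside every +/-3 kb TSS promoter window.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import (
    as_regions,
    coverage_fraction,
    genes_frame,
    local_windows,
    overlap_pairs,
    overlaps_any,
    promoter_windows,
)

__all__ = [
    "classify_ocrs",
    "peak_enrichment",
    "differential_regions",
    "deg_call",
    "classify_histone_cases",
    "call_enhancers",
    "differential_enhancers",
    "metaprofile",
    "track_mean",
]

DAR_LOG2FC = 0.5
DAR_FDR = 0.05
DEG_Q = 0.01
DEG_FC = 1.5
FPKM_HIGH = 100.0
FPKM_NONEXPRESSED = 1.0
PROMOTER_BP = 3000


# ---------------------------------------------------------------------------
# OCR locality
# ---------------------------------------------------------------------------

def classify_ocrs(peaks: pd.DataFrame, genes: pd.DataFrame,
                  upstream_bp: int = PROMOTER_BP) -> pd.DataFrame:
    """Label each peak local (genic TSS-3kb..TTS window) or distal."""
    peaks = as_regions(peaks).reset_index(drop=True)
    out = peaks.copy()
    if len(genes):
        windows = local_windows(genes, upstream_bp=upstream_bp)
        local = overlaps_any(peaks, windows)
    else:
        local = np.zeros(len(peaks), dtype=bool)
    out["locality"] = np.where(local, "local", "distal")
    return out


# ---------------------------------------------------------------------------
# Signal tracks
# ---------------------------------------------------------------------------

def track_mean(track: pd.DataFrame, chrom: str, start: int, end: int) -> float:
    """Mean per-base value of a bedGraph over [start, end); gaps count as 0."""
    if end <= start:
        raise ValueError("empty region")
    t = track[track["chrom"] == chrom]
    if len(t) == 0:
        raise ValueError(f"track does not cover chromosome {chrom!r}")
    s = np.maximum(t["start"].to_numpy(), start)
    e = np.minimum(t["end"].to_numpy(), end)
    ov = np.clip(e - s, 0, None)
    return float((ov * t["value"].to_numpy()).sum() / (end - start))


def peak_enrichment(signal_track: pd.DataFrame, background_track: pd.DataFrame,
                    chrom: str, start: int, end: int) -> float:
    """Enrichment = mean per-base signal minus mean per-base background."""
    return track_mean(signal_track, chrom, start, end) - track_mean(
        background_track, chrom, start, end
    )


# ---------------------------------------------------------------------------
# Differential testing
# ---------------------------------------------------------------------------

def moderated_ttest(
    la: np.ndarray, lb: np.ndarray, prior_df: float = 20.0
) -> np.ndarray:
    """Two-sample t-test with empirical-Bayes variance moderation.

    Per-feature pooled variances are shrunk toward their global mean with
    ``prior_df`` pseudo-degrees of freedom (the limma idea): with a handful
    of replicates per condition, borrowing strength across features is what
    makes genome-wide differential calls at strict FDR feasible at all.
    Returns two-sided p-values.
    """
    la = np.asarray(la, dtype=float)
    lb = np.asarray(lb, dtype=float)
    na, nb = la.shape[1], lb.shape[1]
    df_g = na + nb - 2
    va = la.var(axis=1, ddof=1)
    vb = lb.var(axis=1, ddof=1)
    s2 = ((na - 1) * va + (nb - 1) * vb) / df_g
    s2_0 = float(np.mean(s2[np.isfinite(s2)])) if np.isfinite(s2).any() else 0.0
    s2_post = (prior_df * s2_0 + df_g * s2) / (prior_df + df_g)
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (la.mean(axis=1) - lb.mean(axis=1)) / se
    p = 2.0 * stats.t.sf(np.abs(t), df=prior_df + df_g)
    return np.where(np.isfinite(p), p, 1.0)

def differential_regions(
    regions: pd.DataFrame,
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    libsizes_a: np.ndarray,
    libsizes_b: np.ndarray,
    log2fc_threshold: float = DAR_LOG2FC,
    fdr: float = DAR_FDR,
) -> pd.DataFrame:
    """Differential enrichment over fixed consensus regions.

    Counts are scaled to CPM; log2FC uses a pseudocount of 1.  With >= 2
    replicates per condition the p-value is a moderated t-test on log2 CPM
    (see :func:`moderated_ttest`); with single replicates it is an exact
    equal-rate Poisson (binomial) test on the summed counts.  Significance:
    |log2FC| > threshold and BH FDR < ``fdr``.
    """
    counts_a = np.atleast_2d(np.asarray(counts_a, dtype=float))
    counts_b = np.atleast_2d(np.asarray(counts_b, dtype=float))
    libs_a = np.asarray(libsizes_a, dtype=float)
    libs_b = np.asarray(libsizes_b, dtype=float)
    if (libs_a <= 0).any() or (libs_b <= 0).any():
        raise ValueError("library sizes must be positive")
    cpm_a = counts_a / libs_a[None, :] * 1e6
    cpm_b = counts_b / libs_b[None, :] * 1e6
    mean_a = cpm_a.mean(axis=1)
    mean_b = cpm_b.mean(axis=1)
    log2fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))
    n_a, n_b = counts_a.shape[1], counts_b.shape[1]
    if n_a >= 2 and n_b >= 2:
        p = moderated_ttest(np.log2(cpm_a + 1.0), np.log2(cpm_b + 1.0))
    else:
        tot_a = counts_a.sum(axis=1)
        tot_b = counts_b.sum(axis=1)
        frac = libs_a.sum() / (libs_a.sum() + libs_b.sum())
        p = np.array([
            stats.binomtest(int(ka), int(ka + kb), frac).pvalue if ka + kb > 0 else 1.0
            for ka, kb in zip(tot_a, tot_b)
        ])
    q = multipletests(p, method="fdr_bh")[1]
    out = as_regions(regions).reset_index(drop=True).copy()
    out["log2fc"] = log2fc
    out["p_value"] = p
    out["q_value"] = q
    out["significant"] = (np.abs(log2fc) > log2fc_threshold) & (q < fdr)
    out["direction"] = np.where(
        out["significant"], np.where(log2fc > 0, "A-enriched", "B-enriched"), "ns"
    )
    return out


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

def _expression_class(mean_fpkm: np.ndarray) -> np.ndarray:
    return np.where(
        mean_fpkm > FPKM_HIGH, "high",
        np.where(mean_fpkm < FPKM_NONEXPRESSED, "non-expressed", "expressed"),
    )


def deg_call(
    expression: pd.DataFrame,
    cond_a_cols: list[str],
    cond_b_cols: list[str],
    q_threshold: float = DEG_Q,
    fc_threshold: float = DEG_FC,
    pseudo: float = 0.01,
) -> pd.DataFrame:
    """Differential expression with fold-change and q-value gates.

    FC is the larger-over-smaller ratio of condition mean FPKM (pseudocount
    ``pseudo``); p from a moderated t-test on log FPKM, BH-corrected.  A gene is
    called A-/B-enriched iff q < ``q_threshold`` and FC > ``fc_threshold``.
    Expression classes use the condition-mean cutoffs (>100 high, <1
    non-expressed).
    """
    if len(cond_a_cols) < 2 or len(cond_b_cols) < 2:
        raise ValueError("deg_call needs >= 2 replicates per condition")
    fa = expression[cond_a_cols].to_numpy(dtype=float)
    fb = expression[cond_b_cols].to_numpy(dtype=float)
    mean_a = fa.mean(axis=1)
    mean_b = fb.mean(axis=1)
    ratio = (mean_a + pseudo) / (mean_b + pseudo)
    fc = np.maximum(ratio, 1.0 / ratio)
    p = moderated_ttest(np.log2(fa + pseudo), np.log2(fb + pseudo))
    q = multipletests(p, method="fdr_bh")[1]
    called = (q < q_threshold) & (fc > fc_threshold)
    out = pd.DataFrame({
        "gene_id": expression["gene_id"],
        "mean_a": mean_a,
        "mean_b": mean_b,
        "fold_change": fc,
        "p_value": p,
        "q_value": q,
        "call": np.where(called, np.where(ratio > 1, "A-enriched", "B-enriched"), "ns"),
        "class_a": _expression_class(mean_a),
        "class_b": _expression_class(mean_b),
    })
    return out


# ---------------------------------------------------------------------------
# Histone cases and enhancers
# ---------------------------------------------------------------------------

def classify_histone_cases(
    regions: pd.DataFrame, peaksets: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Four-case histone classification of regions.

    "Strong" means the region overlaps a called peak of that mark.  Mixed
    repressive/active states resolve by covered fraction: if the H3K27me3
    coverage of the region is >= the larger active-mark coverage the region
    is Case1, otherwise Case3/Case4 by the active-mark combination.  A
    strong-H3K4me3-only region carries no H3K9ac evidence and falls to
    Case2 (conservative: not called an enhancer).
    """
    regions = as_regions(regions).reset_index(drop=True)
    k4 = peaksets.get("H3K4me3", regions.head(0))
    k9 = peaksets.get("H3K9ac", regions.head(0))
    k27 = peaksets.get("H3K27me3", regions.head(0))
    f4 = coverage_fraction(regions, k4) if len(k4) else np.zeros(len(regions))
    f9 = coverage_fraction(regions, k9) if len(k9) else np.zeros(len(regions))
    f27 = coverage_fraction(regions, k27) if len(k27) else np.zeros(len(regions))
    s4, s9, s27 = f4 > 0, f9 > 0, f27 > 0
    case = np.full(len(regions), "Case2", dtype=object)
    active_frac = np.maximum(f4, f9)
    for i in range(len(regions)):
        if s27[i] and f27[i] >= active_frac[i]:
            case[i] = "Case1"
        elif s4[i] and s9[i]:
            case[i] = "Case3"
        elif s9[i]:
            case[i] = "Case4"
        elif s27[i]:
            case[i] = "Case1"
    out = regions.copy()
    out["case"] = case
    out["k4_frac"] = f4
    out["k9_frac"] = f9
    out["k27_frac"] = f27
    return out


def call_enhancers(
    cased_regions: pd.DataFrame, genes: pd.DataFrame,
    promoter_bp: int = PROMOTER_BP,
) -> pd.DataFrame:
    """Putative enhancers: Case3/Case4 regions outside all TSS +/-3 kb windows."""
    cand = cased_regions[cased_regions["case"].isin(["Case3", "Case4"])].reset_index(drop=True)
    if len(genes) and len(cand):
        windows = promoter_windows(genes, upstream_bp=promoter_bp, downstream_bp=promoter_bp)
        keep = ~overlaps_any(cand, windows)
        cand = cand[keep].reset_index(drop=True)
    return cand


def differential_enhancers(
    enhancers: pd.DataFrame, diffregions_by_mark: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Per-mark gain/loss status of enhancers from differential regions.

    For each mark, an enhancer overlapping an A-enriched (resp. B-enriched)
    significant region is flagged ``A-gain`` (resp. ``B-gain``) for that
    mark; otherwise ``static``.
    """
    out = enhancers.reset_index(drop=True).copy()
    for mark, dr in diffregions_by_mark.items():
        status = np.full(len(out), "static", dtype=object)
        sig = dr[dr["significant"]].reset_index(drop=True)
        if len(sig) and len(out):
            pairs = overlap_pairs(out, sig)
            for _, pr in pairs.iterrows():
                d = sig.loc[int(pr["t_idx"]), "direction"]
                status[int(pr["q_idx"])] = "A-gain" if d == "A-enriched" else "B-gain"
        out[f"{mark}_status"] = status
    return out


# ---------------------------------------------------------------------------
# Metaprofiles
# ---------------------------------------------------------------------------

def metaprofile(
    track: pd.DataFrame,
    anchors: pd.DataFrame,
    flank_bp: int = 3000,
    bin_bp: int = 50,
    chromsizes: dict[str, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-anchor binned signal around anchor points, strand-flipped.

    ``anchors`` needs ``chrom`` and ``pos`` columns (``strand`` optional).
    Anchors too close to a chromosome edge are NA-padded and dropped from
    the column means.  Returns ``(matrix, mean_profile)``.
    """
    n_bins_side = flank_bp // bin_bp
    n_cols = 2 * n_bins_side
    mat = np.full((len(anchors), n_cols), np.nan)
    for r, (_, anc) in enumerate(anchors.iterrows()):
        chrom, pos = anc["chrom"], int(anc["pos"])
        lo = pos - flank_bp
        hi = pos + flank_bp
        limit = chromsizes.get(chrom) if chromsizes else None
        vals = np.full(n_cols, np.nan)
        for k in range(n_cols):
            s = lo + k * bin_bp
            e = s + bin_bp
            if s < 0 or (limit is not None and e > limit):
                continue
            vals[k] = track_mean(track, chrom, s, e)
        if anc.get("strand", "+") == "-":
            vals = vals[::-1]
        mat[r] = vals
    complete = ~np.isnan(mat).any(axis=1)
    mean = np.nanmean(mat[complete], axis=0) if complete.any() else np.full(n_cols, np.nan)
    return mat, mean
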