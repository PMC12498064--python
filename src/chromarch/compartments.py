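"""A/B compartment calling, switch classification and saddle analysis.

Compartments come from the leading eigenvector of the per-chromosome Pearson
correlation matrix of O/E contacts, oriented so that PC1 correlates
positively with gene density (gene-dense regions are compartment A).  Switch
patterns between two conditions are the usual A2A/A2B/B2A/B2B labels.  The
saddle sorts bins by PC1, trims the quantile range, and averages cis O/E by
quantile pair; compartment strength is read off the 20% corners:

    x = top(A-A) / bottom(A-B)        y = top(B-B) / bottom(A-B)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contacts import ContactMap, MatrixBundle, observed_over_expected

__all__ = [
    "CompartmentTrack",
    "SwitchTable",
    "SaddleResult",
    "call_compartments",
    "classify_switches",
    "saddle",
    "compartment_summary",
]

PATTERNS = ("A2A", "A2B", "B2A", "B2B")


@dataclass
class CompartmentTrack:
    """Per-bin PC1 loading and A/B label at one resolution."""

    resolution: int
    chromsizes: dict[str, int]
    pc1: dict[str, np.ndarray]     # NaN on masked bins
    labels: dict[str, np.ndarray]  # "A"/"B"/"NA"

    def frame(self) -> pd.DataFrame:
        rows = []
        for chrom in self.pc1:
            n = len(self.pc1[chrom])
            starts = np.arange(n) * self.resolution
            rows.append(pd.DataFrame({
                "chrom": chrom,
                "start": starts,
                "end": np.minimum(starts + self.resolution, self.chromsizes[chrom]),
                "pc1": self.pc1[chrom],
                "label": self.labels[chrom],
            }))
        return pd.concat(rows, ignore_index=True)


@dataclass
class SwitchTable:
    """Per-bin switch pattern between two conditions plus pattern counts."""

    resolution: int
    patterns: dict[str, np.ndarray]  # per-chrom array of A2A/A2B/B2A/B2B/NA
    counts: dict[str, int]

    def frame(self) -> pd.DataFrame:
        rows = []
        for chrom, pat in self.patterns.items():
            starts = np.arange(len(pat)) * self.resolution
            rows.append(pd.DataFrame({
                "chrom": chrom, "start": starts,
                "end": starts + self.resolution, "pattern": pat,
            }))
        return pd.concat(rows, ignore_index=True)


@dataclass
class SaddleResult:
    matrix: np.ndarray       # Q x Q mean O/E by PC1 quantile pair
    strength_x: float        # top(A-A)/bottom(A-B)
    strength_y: float        # top(B-B)/bottom(A-B)
    qrange: tuple[float, float]
    n_quantiles: int


def _leading_eigvec(corr: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(corr)
    return vecs[:, -1]


def call_compartments(
    cmap: ContactMap,
    gene_density: dict[str, np.ndarray],
    min_bins: int = 10,
    oe: MatrixBundle | None = None,
) -> CompartmentTrack:
    """Call A/B compartments per chromosome from a balanced map.

    ``gene_density`` maps chromosome -> per-bin gene counts used to orient
    the eigenvector (A = gene dense = PC1 > 0).  Chromosomes with fewer than
    ``min_bins`` unmasked bins come back all-NA with a warning.
    """
    if oe is None:
        oe = observed_over_expected(cmap)
    pc1_out, lab_out = {}, {}
    for chrom in cmap.chroms:
        n = cmap.n_bins(chrom)
        pc1 = np.full(n, np.nan)
        labels = np.array(["NA"] * n, dtype=object)
        good = ~cmap.bad_bins[chrom]
        if good.sum() < min_bins:
            warnings.warn(f"call_compartments: {chrom} has <{min_bins} usable bins")
            pc1_out[chrom], lab_out[chrom] = pc1, labels
            continue
        sub = oe.data[chrom][np.ix_(good, good)]
        sub = np.where(np.isfinite(sub), sub, 1.0)
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(sub)
        corr = np.where(np.isfinite(corr), corr, 0.0)
        vec = _leading_eigvec(corr)
        dens = np.asarray(gene_density[chrom], dtype=float)[good]
        if np.std(vec) > 0 and np.std(dens) > 0:
            r = np.corrcoef(vec, dens)[0, 1]
            if np.isfinite(r) and r < 0:
                vec = -vec
        pc1[good] = vec
        labels[good] = np.where(vec > 0, "A", np.where(vec < 0, "B", "NA"))
        pc1_out[chrom], lab_out[chrom] = pc1, labels
    return CompartmentTrack(cmap.resolution, dict(cmap.chromsizes), pc1_out, lab_out)


def gene_density_per_bin(genes: pd.DataFrame, chromsizes, binsize: int) -> dict[str, np.ndarray]:
    """Count gene starts per bin — the orientation covariate for PC1."""
    out = {}
    for chrom, length in chromsizes.items():
        n = -(-length // binsize)
        dens = np.zeros(n)
        g = genes[genes["chrom"] == chrom]
        if len(g):
            idx = np.clip(g["start"].to_numpy() // binsize, 0, n - 1)
            np.add.at(dens, idx, 1.0)
        out[chrom] = dens
    return out


def classify_switches(track_a: CompartmentTrack, track_b: CompartmentTrack) -> SwitchTable:
    """Per-bin A2A/A2B/B2A/B2B pattern (first condition -> second)."""
    if (track_a.resolution != track_b.resolution
            or dict(track_a.chromsizes) != dict(track_b.chromsizes)):
        raise ValueError("classify_switches: tracks have different bin tables")
    patterns = {}
    counts = {p: 0 for p in PATTERNS}
    counts["NA"] = 0
    for chrom in track_a.labels:
        la, lb = track_a.labels[chrom], track_b.labels[chrom]
        pat = np.array(["NA"] * len(la), dtype=object)
        ok = (la != "NA") & (lb != "NA")
        pat[ok] = np.char.add(np.char.add(la[ok].astype(str), "2"), lb[ok].astype(str))
        patterns[chrom] = pat
        vals, n = np.unique(pat, return_counts=True)
        for v, k in zip(vals, n):
            counts[v] = counts.get(v, 0) + int(k)
    for p in PATTERNS:
        counts.setdefault(p, 0)
    return SwitchTable(track_a.resolution, patterns, counts)


def saddle(
    cmap: ContactMap,
    track: CompartmentTrack,
    qrange: tuple[float, float] = (0.02, 0.98),
    n_quantiles: int = 10,
    corner_frac: float = 0.2,
    oe: MatrixBundle | None = None,
) -> SaddleResult:
    """PC1-sorted cis O/E saddle and corner-ratio compartment strengths.

    Bins are ranked by PC1 genome-wide, trimmed to ``qrange``, and divided
    into ``n_quantiles`` equal-occupancy groups.  Strengths use the top
    ``corner_frac`` of ranked bins on each side: x = AA-corner / AB-corner,
    y = BB-corner / AB-corner.
    """
    if oe is None:
        oe = observed_over_expected(cmap)
    pooled = np.concatenate([track.pc1[c] for c in cmap.chroms])
    finite = pooled[np.isfinite(pooled)]
    if len(finite) < n_quantiles:
        raise ValueError("saddle: not enough PC1 values")
    if np.all(finite == finite[0]):
        raise ValueError("saddle: PC1 is constant (degenerate)")
    lo, hi = np.quantile(finite, qrange)
    # per-chromosome quantile assignment against genome-wide edges
    kept = finite[(finite >= lo) & (finite <= hi)]
    edges = np.quantile(kept, np.linspace(0, 1, n_quantiles + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    sums = np.zeros((n_quantiles, n_quantiles))
    cnts = np.zeros((n_quantiles, n_quantiles))
    a_cut = np.quantile(kept, 1 - corner_frac)
    b_cut = np.quantile(kept, corner_frac)
    aa = ab = bb = 0.0
    n_aa = n_ab = n_bb = 0
    for chrom in cmap.chroms:
        pc1 = track.pc1[chrom]
        keep = np.isfinite(pc1) & (pc1 >= lo) & (pc1 <= hi)
        idx = np.flatnonzero(keep)
        if len(idx) == 0:
            continue
        q = np.searchsorted(edges, pc1[idx], side="right") - 1
        q = np.clip(q, 0, n_quantiles - 1)
        sub = oe.data[chrom][np.ix_(idx, idx)]
        valid = np.isfinite(sub)
        vals = np.where(valid, sub, 0.0)
        np.add.at(sums, (q[:, None].repeat(len(q), 1), q[None, :].repeat(len(q), 0)), vals)
        np.add.at(cnts, (q[:, None].repeat(len(q), 1), q[None, :].repeat(len(q), 0)), valid)
        is_a = pc1[idx] >= a_cut
        is_b = pc1[idx] <= b_cut
        for mask1, mask2, which in ((is_a, is_a, "aa"), (is_b, is_b, "bb"), (is_a, is_b, "ab")):
            block = sub[np.ix_(mask1, mask2)]
            v = block[np.isfinite(block)]
            if which == "aa":
                aa += v.sum(); n_aa += len(v)
            elif which == "bb":
                bb += v.sum(); n_bb += len(v)
            else:
                ab += v.sum(); n_ab += len(v)
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    mat = (mat + mat.T) / 2
    if n_ab == 0 or ab == 0:
        raise ValueError("saddle: empty A-B corner")
    x = (aa / max(n_aa, 1)) / (ab / n_ab)
    y = (bb / max(n_bb, 1)) / (ab / n_ab)
    return SaddleResult(mat, float(x), float(y), qrange, n_quantiles)


def segment_lengths(track: CompartmentTrack) -> pd.DataFrame:
    """Maximal same-label runs per chromosome (bins and bp)."""
    rows = []
    for chrom, lab in track.labels.items():
        start = 0
        for i in range(1, len(lab) + 1):
            if i == len(lab) or lab[i] != lab[start]:
                rows.append((chrom, lab[start], start, i, i - start))
                start = i
    df = pd.DataFrame(rows, columns=["chrom", "label", "start_bin", "end_bin", "n_bins"])
    df["length_bp"] = df["n_bins"] * track.resolution
    return df


def compartment_summary(
    track: CompartmentTrack,
    switch: SwitchTable | None = None,
    genes: pd.DataFrame | None = None,
    gc_track: dict[str, np.ndarray] | None = None,
    expression: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-category (A/B or switch-pattern) summaries of gene count/GC/FPKM.

    ``expression`` needs ``gene_id`` plus a ``mean_fpkm`` column.  Returns
    one row per category with mean per-bin gene count, mean GC fraction and
    mean FPKM of overlapping genes.
    """
    frame = track.frame()
    if switch is not None:
        frame["category"] = np.concatenate(
            [switch.patterns[c] for c in track.labels]
        )
    else:
        frame["category"] = frame["label"]
    if gc_track is not None:
        frame["gc"] = np.concatenate([np.asarray(gc_track[c], float) for c in track.labels])
    gene_count = np.zeros(len(frame))
    fpkm_sum = np.zeros(len(frame))
    fpkm_n = np.zeros(len(frame))
    if genes is not None and len(genes):
        from .genome import overlap_pairs

        pairs = overlap_pairs(frame[["chrom", "start", "end"]], genes)
        np.add.at(gene_count, pairs["q_idx"].to_numpy(), 1.0)
        if expression is not None:
            fp = genes.reset_index(drop=True).merge(expression, on="gene_id", how="left")
            vals = fp["mean_fpkm"].to_numpy()[pairs["t_idx"].to_numpy()]
            ok = np.isfinite(vals)
            np.add.at(fpkm_sum, pairs["q_idx"].to_numpy()[ok], vals[ok])
            np.add.at(fpkm_n, pairs["q_idx"].to_numpy()[ok], 1.0)
    frame["gene_count"] = gene_count
    with np.errstate(invalid="ignore", divide="ignore"):
        frame["mean_fpkm"] = np.where(fpkm_n > 0, fpkm_sum / np.maximum(fpkm_n, 1), np.nan)
    agg = {"gene_count": ("gene_count", "mean")}
    if gc_track is not None:
        agg["gc"] = ("gc", "mean")
    agg["mean_fpkm"] = ("mean_fpkm", "mean")
    agg["n_bins"] = ("gene_count", "size")
    return frame.groupby("category").agg(**agg).reset_index()
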