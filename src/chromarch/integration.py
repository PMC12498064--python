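"""Cross-layer linking of compartments, loops, open chromatin and expression.

The central object is the dOCR-gene link: an intergenic-gene loop whose
intergenic anchor contains at least one distal OCR, tying a putative distal
regulatory element to the gene(s) on the partner anchor.  Around it sit the
bookkeeping operations the comparative analysis needs: switch-bin x DEG
association, dOCR activity classing from differential accessibility and
flanking H3K27me3, TFBS anchor categories, enhancer-gene links through loop
anchors, randomly shifted control regions, and small reporting arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import as_regions, overlap_pairs, overlaps_any, promoter_windows
from .loops import Loop

__all__ = [
    "DocrGeneLink",
    "genes_in_switched_bins",
    "docr_gene_loops",
    "classify_docr_activity",
    "active_docr_loop_rate",
    "tfbs_loop_categories",
    "enhancer_gene_links",
    "shifted_controls",
    "percent_change",
    "percentage",
    "pooled_percentage",
]


@dataclass
class DocrGeneLink:
    loop: Loop
    intergenic_anchor: tuple[str, int, int]
    gene_anchor: tuple[str, int, int]
    docr_indices: list[int]      # positional indices into the dOCR frame
    gene_ids: list[str]


def percentage(part: float, whole: float, decimals: int = 1) -> float:
    """100 * part/whole, rounded for reporting."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    return round(100.0 * part / whole, decimals)


def pooled_percentage(counts: list[tuple[float, float]], decimals: int = 1) -> float:
    """Pooled percentage over (part, whole) pairs, e.g. per-tissue counts."""
    part = sum(c[0] for c in counts)
    whole = sum(c[1] for c in counts)
    return percentage(part, whole, decimals)


def percent_change(control_mean: float, treatment_mean: float, decimals: int = 1) -> float:
    """Signed percent change of the treatment mean relative to control."""
    if control_mean <= 0:
        raise ValueError("control_mean must be positive")
    return round(100.0 * (treatment_mean - control_mean) / control_mean, decimals)


# ---------------------------------------------------------------------------
# Compartment switches x expression
# ---------------------------------------------------------------------------

def genes_in_switched_bins(
    switch_frame: pd.DataFrame, genes: pd.DataFrame, deg_table: pd.DataFrame
) -> pd.DataFrame:
    """DEGs overlapping A2B/B2A switched bins, with their switch pattern.

    ``switch_frame`` is the per-bin frame from
    :meth:`compartments.SwitchTable.frame`.
    """
    switched = switch_frame[switch_frame["pattern"].isin(["A2B", "B2A"])].reset_index(drop=True)
    degs = deg_table[deg_table["call"] != "ns"]
    g = genes.reset_index(drop=True)
    g_deg = g[g["gene_id"].isin(degs["gene_id"])].reset_index(drop=True)
    if len(switched) == 0 or len(g_deg) == 0:
        return pd.DataFrame(columns=["gene_id", "pattern", "chrom", "start", "end"])
    pairs = overlap_pairs(g_deg, switched)
    rows = []
    for _, pr in pairs.iterrows():
        gene = g_deg.iloc[int(pr["q_idx"])]
        bin_ = switched.iloc[int(pr["t_idx"])]
        rows.append((gene["gene_id"], bin_["pattern"], gene["chrom"],
                     gene["start"], gene["end"]))
    out = pd.DataFrame(rows, columns=["gene_id", "pattern", "chrom", "start", "end"])
    return out.drop_duplicates(subset=["gene_id", "pattern"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# dOCR-gene loops
# ---------------------------------------------------------------------------

def docr_gene_loops(
    loops: list[Loop],
    loop_classes: list[str],
    ocr_calls: pd.DataFrame,
    genes: pd.DataFrame,
    gene_anchor_mode: str = "body_or_promoter",
    promoter_bp: int = 3000,
) -> tuple[list[DocrGeneLink], float]:
    """Link distal OCRs to genes through intergenic-gene loops.

    Restricted to loops classed ``intergenic-gene``; a link requires >= 1
    distal OCR overlapping the intergenic anchor.  Linked genes are those
    whose body (or, by default, body-or-promoter) overlaps the gene anchor.
    Returns the link list and the anchored fraction: 100 x linked intergenic
    anchors / all intergenic anchors.
    """
    docrs = ocr_calls[ocr_calls["locality"] == "distal"].reset_index(drop=True)
    g = genes.reset_index(drop=True)
    if gene_anchor_mode == "body_or_promoter":
        prom = promoter_windows(g, upstream_bp=promoter_bp, downstream_bp=0)
        gene_regions = pd.concat(
            [g[["chrom", "start", "end", "gene_id"]], prom], ignore_index=True
        )
    elif gene_anchor_mode == "body":
        gene_regions = g[["chrom", "start", "end", "gene_id"]]
    else:
        raise ValueError(f"unknown gene_anchor_mode {gene_anchor_mode!r}")
    links: list[DocrGeneLink] = []
    n_intergenic_anchors = 0
    n_linked = 0
    gene_bodies = g[["chrom", "start", "end"]]
    for loop, cls in zip(loops, loop_classes):
        if cls != "intergenic-gene":
            continue
        anchors = [
            (loop.chrom, loop.start1, loop.end1),
            (loop.chrom, loop.start2, loop.end2),
        ]
        genic = [
            bool(overlaps_any(
                pd.DataFrame([a], columns=["chrom", "start", "end"]), gene_bodies
            )[0])
            for a in anchors
        ]
        if genic[0] == genic[1]:
            continue  # classing and bodies disagree only on degenerate input
        inter = anchors[0] if not genic[0] else anchors[1]
        gene_anchor = anchors[1] if not genic[0] else anchors[0]
        n_intergenic_anchors += 1
        inter_df = pd.DataFrame([inter], columns=["chrom", "start", "end"])
        dpairs = overlap_pairs(inter_df, docrs)
        if len(dpairs) == 0:
            continue
        n_linked += 1
        gpairs = overlap_pairs(
            pd.DataFrame([gene_anchor], columns=["chrom", "start", "end"]),
            gene_regions,
        )
        gene_ids = sorted(
            set(gene_regions.iloc[gpairs["t_idx"]]["gene_id"])
        ) if len(gpairs) else []
        links.append(DocrGeneLink(
            loop, inter, gene_anchor,
            sorted(dpairs["t_idx"].astype(int).tolist()), gene_ids,
        ))
    fraction = percentage(n_linked, n_intergenic_anchors) if n_intergenic_anchors else 0.0
    return links, fraction


def classify_docr_activity(
    docrs: pd.DataFrame,
    atac_diffregions: pd.DataFrame,
    k27_diffregions: pd.DataFrame,
    flank_bp: int = 2000,
) -> pd.DataFrame:
    """Condition-activity labels for distal OCRs.

    A dOCR is A-active iff it overlaps an A-enriched differential ATAC
    region, or overlaps/flanks (within ``flank_bp``) a B-enriched (i.e.
    A-depleted) differential H3K27me3 region — more open and/or weaker
    repression in condition A.  Symmetric for B; evidence in both
    directions -> static with a conflict flag.
    """
    docrs = as_regions(docrs).reset_index(drop=True)
    out = docrs.copy()
    a_vote = np.zeros(len(docrs), dtype=bool)
    b_vote = np.zeros(len(docrs), dtype=bool)
    atac_sig = atac_diffregions[atac_diffregions["significant"]]
    for direction, vote in (("A-enriched", a_vote), ("B-enriched", b_vote)):
        sub = atac_sig[atac_sig["direction"] == direction]
        if len(sub):
            vote |= overlaps_any(docrs, sub)
    k27_sig = k27_diffregions[k27_diffregions["significant"]].copy()
    if len(k27_sig):
        k27_sig["start"] = np.maximum(k27_sig["start"] - flank_bp, 0)
        k27_sig["end"] = k27_sig["end"] + flank_bp
        # weaker K27 in A == K27 B-enriched -> A-active
        for direction, vote in (("B-enriched", a_vote), ("A-enriched", b_vote)):
            sub = k27_sig[k27_sig["direction"] == direction]
            if len(sub):
                vote |= overlaps_any(docrs, sub)
    activity = np.where(
        a_vote & b_vote, "static",
        np.where(a_vote, "A-active", np.where(b_vote, "B-active", "static")),
    )
    out["activity"] = activity
    out["conflict"] = a_vote & b_vote
    return out


def active_docr_loop_rate(
    docr_activity: pd.DataFrame, links: list[DocrGeneLink], condition: str
) -> float:
    """Percent of condition-active dOCRs that appear in >= 1 dOCR-gene link."""
    label = {"a": "A-active", "b": "B-active"}[condition]
    active_idx = set(np.flatnonzero((docr_activity["activity"] == label).to_numpy()))
    if not active_idx:
        raise ValueError(f"no {label} dOCRs; rate undefined")
    linked = set()
    for link in links:
        linked.update(link.docr_indices)
    return percentage(len(active_idx & linked), len(active_idx))


# ---------------------------------------------------------------------------
# TFBS categories and enhancer-gene links
# ---------------------------------------------------------------------------

def tfbs_loop_categories(
    motif_sites: pd.DataFrame, links: list[DocrGeneLink]
) -> pd.DataFrame:
    """Classify motif occurrences on dOCR-gene loop anchors per motif.

    Per motif and link: sites only on the dOCR (intergenic) anchor -> dOCR
    TFBS; only on the gene anchor -> Local TFBS; on both -> Joint TFBS.
    Returns per-motif counts and percentages.
    """
    motif_sites = motif_sites.reset_index(drop=True)
    if "motif_id" not in motif_sites.columns:
        raise ValueError("motif_sites needs a motif_id column")
    records = []
    for li, link in enumerate(links):
        for side, (chrom, start, end) in (
            ("docr", link.intergenic_anchor), ("gene", link.gene_anchor)
        ):
            anchor = pd.DataFrame([(chrom, start, end)], columns=["chrom", "start", "end"])
            pairs = overlap_pairs(anchor, motif_sites)
            for t in pairs["t_idx"]:
                records.append((li, motif_sites.loc[int(t), "motif_id"], side))
    if not records:
        return pd.DataFrame(columns=["motif_id", "docr_tfbs", "local_tfbs", "joint_tfbs"])
    rec = pd.DataFrame(records, columns=["link", "motif_id", "side"])
    rows = []
    for motif, grp in rec.groupby("motif_id"):
        docr = local = joint = 0
        for _, g in grp.groupby("link"):
            sides = set(g["side"])
            if sides == {"docr", "gene"}:
                joint += 1
            elif sides == {"docr"}:
                docr += 1
            else:
                local += 1
        rows.append((motif, docr, local, joint))
    out = pd.DataFrame(rows, columns=["motif_id", "docr_tfbs", "local_tfbs", "joint_tfbs"])
    tot = out[["docr_tfbs", "local_tfbs", "joint_tfbs"]].sum(axis=1)
    for col in ("docr_tfbs", "local_tfbs", "joint_tfbs"):
        out[f"{col}_pct"] = 100.0 * out[col] / tot
    return out


def enhancer_gene_links(
    enhancers: pd.DataFrame,
    loops: list[Loop],
    genes: pd.DataFrame,
    promoter_bp: int = 3000,
) -> pd.DataFrame:
    """Link differential enhancers to genes through loop anchors.

    An enhancer overlapping one anchor of a loop is linked to every gene
    whose promoter overlaps the partner anchor; any gain/loss status columns
    on the enhancer frame propagate to the links.
    """
    enhancers = as_regions(enhancers).reset_index(drop=True)
    prom = promoter_windows(genes, upstream_bp=promoter_bp, downstream_bp=0)
    status_cols = [c for c in enhancers.columns if c.endswith("_status")]
    rows = []
    for li, loop in enumerate(loops):
        anchors = [
            (loop.chrom, loop.start1, loop.end1),
            (loop.chrom, loop.start2, loop.end2),
        ]
        for side in (0, 1):
            a = pd.DataFrame([anchors[side]], columns=["chrom", "start", "end"])
            epairs = overlap_pairs(a, enhancers)
            if len(epairs) == 0:
                continue
            partner = pd.DataFrame([anchors[1 - side]], columns=["chrom", "start", "end"])
            ppairs = overlap_pairs(partner, prom)
            if len(ppairs) == 0:
                continue
            for e in epairs["t_idx"]:
                enh = enhancers.iloc[int(e)]
                for t in ppairs["t_idx"]:
                    row = {
                        "loop_index": li,
                        "enhancer_chrom": enh["chrom"],
                        "enhancer_start": int(enh["start"]),
                        "enhancer_end": int(enh["end"]),
                        "gene_id": prom.loc[int(t), "gene_id"],
                    }
                    for c in status_cols:
                        row[c] = enh[c]
                    rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out = out.drop_duplicates(
            subset=["enhancer_chrom", "enhancer_start", "enhancer_end", "gene_id"]
        ).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Shifted controls
# ---------------------------------------------------------------------------

def shifted_controls(
    docrs: pd.DataFrame,
    chromsizes: dict[str, int],
    seed: int,
    max_shift_bp: int = 500_000,
) -> pd.DataFrame:
    """Randomly shifted copies of the dOCRs (same count and widths).

    Each region gets an independent uniform shift in +/-``max_shift_bp``;
    off-chromosome shifts are resampled.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    docrs = as_regions(docrs).reset_index(drop=True)
    rows = []
    for _, r in docrs.iterrows():
        length = int(chromsizes[r["chrom"]])
        width = int(r["end"] - r["start"])
        for _ in range(1000):
            shift = int(rng.integers(-max_shift_bp, max_shift_bp + 1))
            s = int(r["start"]) + shift
            if 0 <= s and s + width <= length:
                rows.append((r["chrom"], s, s + width))
                break
        else:
            rows.append((r["chrom"], int(r["start"]), int(r["end"])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])
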