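"""Paired-condition multi-omic simulator with fully known planted truth.

The generator lays out, in base-pair coordinates, a genome with:

* plaid A/B compartment blocks (geometric block lengths, signs +/-1), a
  configurable number of which flip sign between the two conditions;
* a TAD segmentation per condition, with planted merge/split edits;
* punctate loops (10-kb anchors), some gained/lost between conditions;
* gene models placed preferentially inside A (+1) blocks so the
  gene-density orientation of compartment eigenvectors is recoverable;
* ATAC/histone peak sets and bedGraph-style signal tracks co-located with
  the planted states, and an expression table coupled to them.

Contact counts follow a Poisson model around the expected intensity

    Lambda_ij = depth * norm * s^-alpha * (1 + delta*e_i*e_j)
                * tad_boost^[same TAD] * loop_boost^[anchor pixel]

which keeps every downstream statistic checkable in closed form.  All
randomness flows from ``SimConfig.seed`` through stable per-stage streams,
so identical configs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .contacts import ContactMap
from .genome import derive_seed, local_windows, n_bins

__all__ = [
    "SimConfig",
    "ArchitectureTruth",
    "make_genome",
    "simulate_contacts",
    "simulate_interaction_pairs",
    "simulate_tracks",
    "simulate_expression",
    "simulate_peak_counts",
]

COMPARTMENT_UNIT_BP = 200_000  # compartment blocks are laid on this grid
TAD_UNIT_BP = 40_000           # TAD boundaries are laid on this grid
LOOP_ANCHOR_BP = 10_000        # loop anchors are this wide, on this grid


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the paired-condition simulator.

    Defaults give two 20-Mb chromosomes at a total expected depth of 5e6
    read pairs — small enough to analyse on a laptop, deep enough that
    compartments, TADs and loops are all recoverable.
    """

    n_chroms: int = 2
    chrom_length_bp: int = 20_000_000
    bin_size_bp: int = 40_000
    decay_exponent: float = 1.0
    compartment_delta: float = 0.4
    tad_boost: float = 2.0
    loop_boost: float = 4.0
    n_flipped_blocks: int = 3
    tad_edits: tuple[str, ...] = ("merge", "merge", "split")
    loop_edits: tuple[str, ...] = ("gain", "loss")
    n_loops: int = 30
    sequencing_depth: float = 5_000_000
    trans_fraction: float = 0.05
    block_mean_bp: int = 1_000_000
    tad_min_bp: int = 320_000
    tad_max_bp: int = 800_000
    loop_min_sep_bp: int = 300_000
    loop_max_sep_bp: int = 1_500_000
    n_genes: int = 2000
    gene_in_a_prob: float = 0.8
    atac_local_fraction: float = 0.174
    n_local_peaks: int = 300
    conditional_distal_fraction: float = 0.1
    deg_fraction: float = 0.1
    deg_effect: float = 4.0
    expression_sigma: float = 0.25
    track_step_bp: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.chrom_length_bp <= 0:
            raise ValueError("chrom_length_bp must be positive")
        if self.chrom_length_bp % self.bin_size_bp != 0:
            raise ValueError("bin_size_bp must divide chrom_length_bp")
        if not (0 <= self.compartment_delta < 1):
            raise ValueError("compartment_delta must be in [0, 1)")
        if self.tad_boost < 1 or self.loop_boost < 1:
            raise ValueError("boost multipliers must be >= 1")
        bad = [e for e in self.tad_edits if e not in ("merge", "split")]
        bad += [e for e in self.loop_edits if e not in ("gain", "loss")]
        if bad:
            raise ValueError(f"unknown edits {bad}")

    @property
    def chromsizes(self) -> dict[str, int]:
        return {f"chr{i+1}": self.chrom_length_bp for i in range(self.n_chroms)}

    def at_resolution(self, bin_size_bp: int) -> "SimConfig":
        """Same study conditions re-binned at a different resolution."""
        return replace(self, bin_size_bp=bin_size_bp)


@dataclass
class ArchitectureTruth:
    """Complete planted truth for one simulated genome pair."""

    chromsizes: dict[str, int]
    blocks: pd.DataFrame          # chrom start end sign_a sign_b flipped
    tads: dict[str, pd.DataFrame]  # condition -> chrom start end
    tad_edits: list[dict]
    loops: pd.DataFrame           # chrom start1 end1 start2 end2 status
    genes: pd.DataFrame           # chrom start end strand gene_id active
    expression: pd.DataFrame      # gene_id mean_a mean_b is_deg direction
    peaks: dict[str, dict[str, pd.DataFrame]]  # mark -> condition -> BED

    def compartment_sign(self, chrom: str, binsize: int) -> np.ndarray:
        """Per-bin +/-1 sign matrix (rows: condition a then b)."""
        nb = n_bins(self.chromsizes[chrom], binsize)
        mid = np.arange(nb) * binsize + binsize // 2
        blk = self.blocks[self.blocks["chrom"] == chrom]
        idx = np.searchsorted(blk["end"].to_numpy(), mid, side="right")
        idx = np.clip(idx, 0, len(blk) - 1)
        return np.vstack(
            [blk["sign_a"].to_numpy()[idx], blk["sign_b"].to_numpy()[idx]]
        )

    def flipped_bins(self, chrom: str, binsize: int) -> np.ndarray:
        signs = self.compartment_sign(chrom, binsize)
        return signs[0] != signs[1]

    def tad_boundaries(self, condition: str, chrom: str, binsize: int) -> np.ndarray:
        """Internal boundary bin indices (domain start positions / binsize)."""
        t = self.tads[condition]
        t = t[t["chrom"] == chrom]
        starts = t["start"].to_numpy()[1:]  # internal boundaries only
        return np.unique(starts // binsize)

    def loop_pixels(self, condition: str, chrom: str, binsize: int) -> np.ndarray:
        keep = {"a": ("shared", "a_only"), "b": ("shared", "b_only")}[condition]
        lp = self.loops[(self.loops["chrom"] == chrom) & self.loops["status"].isin(keep)]
        i = (lp["start1"].to_numpy() + LOOP_ANCHOR_BP // 2) // binsize
        j = (lp["start2"].to_numpy() + LOOP_ANCHOR_BP // 2) // binsize
        return np.stack([i, j], axis=1).astype(np.int64) if len(lp) else np.empty((0, 2), np.int64)


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------

def _layout_blocks(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Contiguous alternating-sign compartment blocks with geometric lengths."""
    mean_units = max(3, cfg.block_mean_bp // COMPARTMENT_UNIT_BP)
    min_units = 2
    rows = []
    for chrom, length in cfg.chromsizes.items():
        total_units = length // COMPARTMENT_UNIT_BP
        pos = 0
        sign = int(rng.choice([-1, 1]))
        while pos < total_units:
            units = min_units + rng.geometric(1.0 / (mean_units - min_units))
            units = min(units, total_units - pos)
            rows.append((chrom, pos * COMPARTMENT_UNIT_BP, (pos + units) * COMPARTMENT_UNIT_BP, sign))
            pos += units
            sign = -sign
    blocks = pd.DataFrame(rows, columns=["chrom", "start", "end", "sign_a"])
    blocks["sign_b"] = blocks["sign_a"]
    blocks["flipped"] = False
    # flip whole, pairwise non-adjacent blocks so A2B/B2A runs are unambiguous
    n_flip = min(cfg.n_flipped_blocks, len(blocks) // 3)
    candidates = list(range(1, len(blocks) - 1))
    rng.shuffle(candidates)
    chosen: list[int] = []
    for c in candidates:
        if len(chosen) == n_flip:
            break
        if all(abs(c - k) >= 2 for k in chosen):
            chosen.append(c)
    for c in chosen:
        blocks.loc[c, "sign_b"] = -blocks.loc[c, "sign_a"]
        blocks.loc[c, "flipped"] = True
    return blocks


def _layout_tads(cfg: SimConfig, blocks: pd.DataFrame,
                 rng: np.random.Generator) -> tuple[dict, list]:
    """TADs nested within compartment blocks (TAD cuts refine block edges).

    Compartment transitions are insulation discontinuities of their own, so
    keeping block edges on TAD boundaries makes the planted truth complete:
    every structural break in the expected matrix is a recorded boundary.
    """
    lo = max(2, cfg.tad_min_bp // TAD_UNIT_BP)
    hi = max(lo + 1, cfg.tad_max_bp // TAD_UNIT_BP)
    rows = []
    for _, blk in blocks.iterrows():
        rem = (int(blk["end"]) - int(blk["start"])) // TAD_UNIT_BP
        pos = int(blk["start"]) // TAD_UNIT_BP
        while rem > 0:
            if rem < 2 * lo:
                size = rem
            else:
                size = int(rng.integers(lo, min(hi, rem - lo) + 1))
            rows.append((blk["chrom"], pos * TAD_UNIT_BP, (pos + size) * TAD_UNIT_BP))
            pos += size
            rem -= size
    tads_a = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    tads_b = tads_a.copy()
    edits: list[dict] = []
    touched: set[int] = set()
    for kind in cfg.tad_edits:
        if kind == "merge":
            # remove one internal boundary in condition b
            for _ in range(100):
                i = int(rng.integers(0, len(tads_b) - 1))
                nxt = i + 1
                if (
                    i in touched or nxt in touched
                    or tads_b.iloc[i]["chrom"] != tads_b.iloc[nxt]["chrom"]
                ):
                    continue
                edits.append({"kind": "merge", "chrom": tads_b.iloc[i]["chrom"],
                              "boundary_bp": int(tads_b.iloc[nxt]["start"])})
                tads_b.loc[tads_b.index[i], "end"] = tads_b.iloc[nxt]["end"]
                tads_b = tads_b.drop(tads_b.index[nxt]).reset_index(drop=True)
                touched.add(i)
                break
        else:  # split
            for _ in range(100):
                i = int(rng.integers(0, len(tads_b)))
                row = tads_b.iloc[i]
                size = (row["end"] - row["start"]) // TAD_UNIT_BP
                if i in touched or size < 2 * lo:
                    continue
                mid = row["start"] + (size // 2) * TAD_UNIT_BP
                edits.append({"kind": "split", "chrom": row["chrom"],
                              "boundary_bp": int(mid)})
                new = pd.DataFrame(
                    [
                        (row["chrom"], row["start"], mid),
                        (row["chrom"], mid, row["end"]),
                    ],
                    columns=["chrom", "start", "end"],
                )
                tads_b = pd.concat(
                    [tads_b.iloc[:i], new, tads_b.iloc[i + 1:]], ignore_index=True
                )
                touched.update({i, i + 1})
                break
    return {"a": tads_a, "b": tads_b}, edits


def _layout_loops(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    chroms = list(cfg.chromsizes)
    rows = []
    statuses = ["shared"] * (cfg.n_loops - len(cfg.loop_edits))
    statuses += ["b_only" if e == "gain" else "a_only" for e in cfg.loop_edits]
    rng.shuffle(statuses)
    for status in statuses[: cfg.n_loops]:
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        length = cfg.chromsizes[chrom]
        for _ in range(200):
            sep = int(rng.integers(cfg.loop_min_sep_bp, cfg.loop_max_sep_bp + 1))
            sep = (sep // LOOP_ANCHOR_BP) * LOOP_ANCHOR_BP
            a1 = int(rng.integers(0, (length - sep) // LOOP_ANCHOR_BP)) * LOOP_ANCHOR_BP
            a2 = a1 + sep
            if a2 + LOOP_ANCHOR_BP > length:
                continue
            clash = any(
                r[0] == chrom and abs(r[1] - a1) < 3 * LOOP_ANCHOR_BP
                and abs(r[3] - a2) < 3 * LOOP_ANCHOR_BP
                for r in rows
            )
            if not clash:
                rows.append((chrom, a1, a1 + LOOP_ANCHOR_BP, a2, a2 + LOOP_ANCHOR_BP, status))
                break
    return pd.DataFrame(
        rows, columns=["chrom", "start1", "end1", "start2", "end2", "status"]
    )


def _layout_genes(cfg: SimConfig, blocks: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Place genes preferentially in +1 (A) blocks of condition a."""
    chroms = list(cfg.chromsizes)
    lengths = np.array([cfg.chromsizes[c] for c in chroms], dtype=float)
    per_chrom = np.round(cfg.n_genes * lengths / lengths.sum()).astype(int)
    rows = []
    gid = 0
    for chrom, n_g in zip(chroms, per_chrom):
        blk = blocks[blocks["chrom"] == chrom]
        a_blocks = blk[blk["sign_a"] > 0]
        b_blocks = blk[blk["sign_a"] < 0]
        for _ in range(n_g):
            use_a = (rng.random() < cfg.gene_in_a_prob) and len(a_blocks) > 0
            pool = a_blocks if use_a else (b_blocks if len(b_blocks) else a_blocks)
            row = pool.iloc[int(rng.integers(0, len(pool)))]
            glen = int(rng.integers(1000, 5001))
            lo, hi = int(row["start"]), int(row["end"]) - glen
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((chrom, start, start + glen, strand, f"gene{gid:05d}",
                         bool(row["sign_a"] > 0)))
            gid += 1
    g = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "gene_id", "active"])
    return g.sort_values(["chrom", "start"]).reset_index(drop=True)


def _plant_expression(cfg: SimConfig, genes: pd.DataFrame, blocks: pd.DataFrame,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Planted per-condition mean FPKM; DEGs coupled to flipped blocks."""
    n = len(genes)
    base = np.where(
        genes["active"].to_numpy(),
        np.exp(rng.normal(np.log(20.0), 0.8, size=n)),
        np.exp(rng.normal(np.log(0.3), 0.6, size=n)),
    )
    mean_a = base.copy()
    mean_b = base.copy()
    is_deg = np.zeros(n, dtype=bool)
    direction = np.array([""] * n, dtype=object)
    # genes inside flipped blocks follow the activity flip: B2A -> up in b, A2B -> up in a
    flipped = blocks[blocks["flipped"]]
    if len(flipped):
        from .genome import overlap_pairs

        pairs = overlap_pairs(genes, flipped.reset_index(drop=True))
        for _, pr in pairs.iterrows():
            gi = int(pr["q_idx"])
            bl = flipped.reset_index(drop=True).iloc[int(pr["t_idx"])]
            is_deg[gi] = True
            if bl["sign_b"] > 0:  # B2A: activated in condition b
                direction[gi] = "b"
                mean_b[gi] = max(mean_b[gi], 1.0) * cfg.deg_effect
            else:
                direction[gi] = "a"
                mean_a[gi] = max(mean_a[gi], 1.0) * cfg.deg_effect
    # additional random DEGs up to the configured fraction
    target = int(cfg.deg_fraction * n)
    extra = max(0, target - int(is_deg.sum()))
    free = np.flatnonzero(~is_deg)
    rng.shuffle(free)
    for gi in free[:extra]:
        is_deg[gi] = True
        if rng.random() < 0.5:
            direction[gi] = "a"
            mean_a[gi] = max(mean_a[gi], 1.0) * cfg.deg_effect
        else:
            direction[gi] = "b"
            mean_b[gi] = max(mean_b[gi], 1.0) * cfg.deg_effect
    return pd.DataFrame(
        {
            "gene_id": genes["gene_id"],
            "mean_a": mean_a,
            "mean_b": mean_b,
            "is_deg": is_deg,
            "direction": direction,
        }
    )


def _plant_peaks(cfg: SimConfig, genes: pd.DataFrame, blocks: pd.DataFrame,
                 expression: pd.DataFrame, rng: np.random.Generator) -> dict:
    """ATAC + histone peak sets per condition, co-located with planted states."""
    expr = expression.set_index("gene_id")
    peaks: dict[str, dict[str, list]] = {
        m: {"a": [], "b": []} for m in ("ATAC", "H3K4me3", "H3K9ac", "H3K27me3")
    }

    def add(mark, cond, chrom, start, end, name):
        peaks[mark][cond].append((chrom, max(0, int(start)), int(end), name))

    # promoter (local) ATAC + active histone marks over condition-active genes
    active_idx = genes.index[genes["active"]].to_numpy()
    rng.shuffle(active_idx)
    sampled = active_idx[: cfg.n_local_peaks]
    for gi in sampled:
        g = genes.loc[gi]
        mean_a = expr.loc[g["gene_id"], "mean_a"]
        mean_b = expr.loc[g["gene_id"], "mean_b"]
        tss = g["start"] if g["strand"] == "+" else g["end"]
        for cond, mean in (("a", mean_a), ("b", mean_b)):
            if mean >= 1.0:
                add("ATAC", cond, g["chrom"], tss - 200, tss + 300, f"locATAC_{g['gene_id']}")
                add("H3K4me3", cond, g["chrom"], tss - 500, tss + 1000, f"K4_{g['gene_id']}")
                add("H3K9ac", cond, g["chrom"], tss - 500, tss + 1000, f"K9_{g['gene_id']}")
    # repressive H3K27me3 over per-condition B blocks
    for cond, col in (("a", "sign_a"), ("b", "sign_b")):
        for _, blk in blocks[blocks[col] < 0].iterrows():
            add("H3K27me3", cond, blk["chrom"], blk["start"], blk["end"],
                f"K27_{blk['chrom']}_{blk['start']}")
    # distal ATAC peaks outside all genic local windows
    n_local = len(sampled)
    n_distal = max(1, int(round(n_local / cfg.atac_local_fraction)) - n_local)
    windows = local_windows(genes, chromsizes=cfg.chromsizes)
    win_by_chrom = {c: g_ for c, g_ in windows.groupby("chrom", sort=False)}
    chroms = list(cfg.chromsizes)
    n_cond = int(round(cfg.conditional_distal_fraction * n_distal))
    statuses = ["a_only"] * n_cond + ["b_only"] * n_cond
    statuses += ["shared"] * (n_distal - len(statuses))
    rng.shuffle(statuses)
    placed = 0
    for status in statuses:
        for _ in range(200):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            start = int(rng.integers(0, cfg.chromsizes[chrom] - 400))
            end = start + 400
            win = win_by_chrom.get(chrom)
            if win is not None and (
                (win["start"].to_numpy() < end) & (win["end"].to_numpy() > start)
            ).any():
                continue
            name = f"dATAC{placed:05d}_{status}"
            conds = {"shared": ("a", "b"), "a_only": ("a",), "b_only": ("b",)}[status]
            for cond in conds:
                add("ATAC", cond, chrom, start, end, name)
                # condition-specific distal sites double as planted enhancer
                # gains: K9ac (and for half of them K4me3) in the same condition
                if status != "shared":
                    add("H3K9ac", cond, chrom, start - 200, end + 200, f"enh{name}")
                    if placed % 2 == 0:
                        add("H3K4me3", cond, chrom, start - 200, end + 200, f"enhK4{name}")
            placed += 1
            break
    out: dict[str, dict[str, pd.DataFrame]] = {}
    for mark, by_cond in peaks.items():
        out[mark] = {}
        for cond, rows in by_cond.items():
            df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
            out[mark][cond] = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    return out


def make_genome(config: SimConfig) -> ArchitectureTruth:
    """Lay out the full planted architecture for both conditions."""
    rng = np.random.default_rng(derive_seed(config.seed, "genome"))
    blocks = _layout_blocks(config, rng)
    tads, tad_edits = _layout_tads(config, blocks, rng)
    loops = _layout_loops(config, rng)
    genes = _layout_genes(config, blocks, rng)
    expression = _plant_expression(config, genes, blocks, rng)
    peaks = _plant_peaks(config, genes, blocks, expression, rng)
    return ArchitectureTruth(
        chromsizes=config.chromsizes,
        blocks=blocks,
        tads=tads,
        tad_edits=tad_edits,
        loops=loops,
        genes=genes,
        expression=expression,
        peaks=peaks,
    )


# ---------------------------------------------------------------------------
# Contact simulation
# ---------------------------------------------------------------------------

def _expected_matrix(truth: ArchitectureTruth, config: SimConfig, condition: str,
                     chrom: str) -> np.ndarray:
    """Unnormalised expected intensity B_ij for one chromosome."""
    binsize = config.bin_size_bp
    nb = n_bins(truth.chromsizes[chrom], binsize)
    idx = np.arange(nb)
    sep = np.abs(idx[:, None] - idx[None, :]).astype(float)
    s_eff = np.maximum(sep, 1.0)
    base = s_eff ** (-config.decay_exponent)
    signs = truth.compartment_sign(chrom, binsize)
    e = signs[0] if condition == "a" else signs[1]
    base = base * (1.0 + config.compartment_delta * np.outer(e, e))
    # same-TAD boost
    tads = truth.tads[condition]
    tads = tads[tads["chrom"] == chrom]
    tad_id = np.full(nb, -1)
    for k, (_, row) in enumerate(tads.iterrows()):
        b0 = int(row["start"]) // binsize
        b1 = -(-int(row["end"]) // binsize)
        tad_id[b0:b1] = k
    same = (tad_id[:, None] == tad_id[None, :]) & (tad_id[:, None] >= 0)
    base = base * np.where(same, config.tad_boost, 1.0)
    # loop anchor pixels
    for i, j in truth.loop_pixels(condition, chrom, binsize):
        if 0 <= i < nb and 0 <= j < nb:
            base[i, j] *= config.loop_boost
            base[j, i] *= config.loop_boost
    return base


def simulate_contacts(truth: ArchitectureTruth, config: SimConfig, condition: str) -> ContactMap:
    """Poisson-sample a symmetric cis contact map at ``config.bin_size_bp``.

    Expected upper-triangle total (incl. diagonal) is
    ``sequencing_depth * (1 - trans_fraction)``.
    """
    if condition not in ("a", "b"):
        raise ValueError("condition must be 'a' or 'b'")
    bases = {c: _expected_matrix(truth, config, condition, c) for c in truth.chromsizes}
    total = sum(np.triu(b).sum() for b in bases.values())
    scale = config.sequencing_depth * (1.0 - config.trans_fraction) / total
    if scale * max(b.max() for b in bases.values()) > 1e12:
        raise OverflowError("sequencing_depth too large for Poisson sampling")
    rng = np.random.default_rng(
        derive_seed(config.seed, "contacts", condition, config.bin_size_bp)
    )
    counts = {}
    for chrom, b in bases.items():
        lam = np.triu(scale * b)
        upper = rng.poisson(lam)
        counts[chrom] = upper + np.triu(upper, 1).T
    return ContactMap(
        resolution=config.bin_size_bp,
        chromsizes=dict(truth.chromsizes),
        counts=counts,
    )


def simulate_interaction_pairs(truth: ArchitectureTruth, config: SimConfig,
                               condition: str, n_pairs: int = 2000) -> pd.DataFrame:
    """Labelled interval-pair list with a uniform trans background.

    Cis pairs are drawn on one chromosome, trans pairs across two distinct
    chromosomes at rate ``trans_fraction``; the ``label`` column records the
    planted class for exact-recovery tests.
    """
    rng = np.random.default_rng(derive_seed(config.seed, "pairs", condition))
    chroms = list(truth.chromsizes)
    rows = []
    for _ in range(n_pairs):
        trans = rng.random() < config.trans_fraction and len(chroms) > 1
        if trans:
            c1, c2 = rng.choice(len(chroms), size=2, replace=False)
        else:
            c1 = c2 = int(rng.integers(0, len(chroms)))
        s1 = int(rng.integers(0, truth.chromsizes[chroms[c1]] - LOOP_ANCHOR_BP))
        s2 = int(rng.integers(0, truth.chromsizes[chroms[c2]] - LOOP_ANCHOR_BP))
        rows.append(
            (chroms[c1], s1, s1 + LOOP_ANCHOR_BP, chroms[c2], s2, s2 + LOOP_ANCHOR_BP,
             "trans" if trans else "cis")
        )
    return pd.DataFrame(
        rows, columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2", "label"]
    )


# ---------------------------------------------------------------------------
# Tracks, expression, region counts
# ---------------------------------------------------------------------------

NOISE_FLOOR = 0.45
PEAK_AMPLITUDE = 8.0


def simulate_tracks(truth: ArchitectureTruth, config: SimConfig, condition: str) -> dict:
    """Peak sets plus bedGraph signal tracks for one condition.

    Returns ``{"peaks": {mark: BED frame}, "tracks": {mark: bedGraph frame},
    "methylation": bedGraph frame}``.  Every planted peak is covered by
    signal above the noise floor; the methylation track dips inside ATAC
    peaks (open chromatin is hypomethylated).
    """
    rng = np.random.default_rng(derive_seed(config.seed, "tracks", condition))
    step = config.track_step_bp
    tracks: dict[str, pd.DataFrame] = {}
    peaks_out: dict[str, pd.DataFrame] = {}
    meth_rows = []
    for mark in ("ATAC", "H3K4me3", "H3K9ac", "H3K27me3"):
        pk = truth.peaks[mark][condition]
        peaks_out[mark] = pk.copy()
        rows = []
        for chrom, length in truth.chromsizes.items():
            n_steps = length // step
            pos = np.arange(n_steps) * step
            sig = NOISE_FLOOR * 0.6 + rng.random(n_steps) * NOISE_FLOOR * 0.6
            for _, p in pk[pk["chrom"] == chrom].iterrows():
                center = (p["start"] + p["end"]) / 2
                width = max(p["end"] - p["start"], step)
                lo = max(0, int((p["start"] - width) // step))
                hi = min(n_steps, int((p["end"] + width) // step) + 1)
                x = pos[lo:hi] + step / 2
                sig[lo:hi] += PEAK_AMPLITUDE * np.exp(-((x - center) ** 2) / (2 * width**2))
            rows.append(pd.DataFrame(
                {"chrom": chrom, "start": pos, "end": pos + step, "value": sig}
            ))
        tracks[mark] = pd.concat(rows, ignore_index=True)
    # methylation: high baseline, hypomethylated in open chromatin
    atac = truth.peaks["ATAC"][condition]
    for chrom, length in truth.chromsizes.items():
        n_steps = length // step
        pos = np.arange(n_steps) * step
        m = 0.75 + rng.random(n_steps) * 0.1
        for _, p in atac[atac["chrom"] == chrom].iterrows():
            lo, hi = int(p["start"] // step), min(n_steps, int(p["end"] // step) + 1)
            m[lo:hi] = 0.1
        meth_rows.append(pd.DataFrame(
            {"chrom": chrom, "start": pos, "end": pos + step, "value": m}
        ))
    return {
        "peaks": peaks_out,
        "tracks": tracks,
        "methylation": pd.concat(meth_rows, ignore_index=True),
    }


def simulate_expression(truth: ArchitectureTruth, config: SimConfig, n_reps: int = 3) -> pd.DataFrame:
    """Replicate FPKM table: lognormal noise around the planted means.

    Columns ``a_1..a_n, b_1..b_n``; planted DEGs carry the configured fold
    change in their ``direction`` condition.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = np.random.default_rng(derive_seed(config.seed, "expression"))
    expr = truth.expression
    out = {"gene_id": expr["gene_id"]}
    for cond in ("a", "b"):
        mean = expr[f"mean_{cond}"].to_numpy()
        for r in range(n_reps):
            noise = rng.normal(0.0, config.expression_sigma, size=len(expr))
            out[f"{cond}_{r+1}"] = mean * np.exp(noise)
    return pd.DataFrame(out)


def simulate_peak_counts(
    truth: ArchitectureTruth,
    config: SimConfig,
    regions: pd.DataFrame,
    n_reps: int = 2,
    base_rate: float = 20.0,
    open_boost: float = 8.0,
) -> dict[str, np.ndarray]:
    """Replicate ATAC read counts over consensus regions, per condition.

    A region overlapping a condition's planted ATAC peak set counts at
    ``base_rate * open_boost``, otherwise at ``base_rate``; counts are
    Poisson.  Returns ``{"a": (n_regions, n_reps), "b": ...}``.
    """
    from .genome import overlaps_any

    rng = np.random.default_rng(derive_seed(config.seed, "peak_counts"))
    out = {}
    for cond in ("a", "b"):
        open_ = overlaps_any(regions, truth.peaks["ATAC"][cond])
        lam = np.where(open_, base_rate * open_boost, base_rate)
        out[cond] = rng.poisson(lam[:, None], size=(len(regions), n_reps))
    return out
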