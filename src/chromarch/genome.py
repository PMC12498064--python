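"""Genomic coordinate primitives shared across the package.

All coordinates are 0-based half-open: bin ``i`` at resolution ``r`` covers
``[i*r, (i+1)*r)``.  Interval sets are plain :class:`pandas.DataFrame` objects
with at least ``chrom``, ``start`` and ``end`` columns, mirroring BED.
"""

from __future__ import annotations

import hashlib
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

BED_COLUMNS = ["chrom", "start", "end"]


def derive_seed(seed: int, *tokens) -> int:
    """Fan a global seed out to a stage-specific seed (< 2**31).

    Stable across runs and platforms: the stream label is hashed with
    SHA-256, never with Python's randomized ``hash``.
    """
    label = ":".join([str(int(seed))] + [str(t) for t in tokens])
    digest = hashlib.sha256(label.encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31 - 1)


def make_bin_table(chromsizes: Mapping[str, int], binsize: int) -> pd.DataFrame:
    """Tile each chromosome with fixed-size bins (last bin clipped)."""
    rows = []
    for chrom, length in chromsizes.items():
        n = -(-int(length) // int(binsize))
        starts = np.arange(n, dtype=np.int64) * binsize
        ends = np.minimum(starts + binsize, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def n_bins(length_bp: int, binsize: int) -> int:
    return -(-int(length_bp) // int(binsize))


def as_regions(df: pd.DataFrame) -> pd.DataFrame:
    """Validate/coerce a region frame: required columns, integer coords."""
    missing = [c for c in BED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"region frame missing columns {missing}")
    out = df.copy()
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    if (out["end"] < out["start"]).any():
        raise ValueError("region with end < start")
    return out


def _overlap_pairs_1d(
    qs: np.ndarray, qe: np.ndarray, ts: np.ndarray, te: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs (qi, ti) with qs[qi] < te[ti] and qe[qi] > ts[ti]."""
    nq, nt = len(qs), len(ts)
    if nq == 0 or nt == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    hit = (qs[:, None] < te[None, :]) & (qe[:, None] > ts[None, :])
    qi, ti = np.nonzero(hit)
    return qi.astype(np.int64), ti.astype(np.int64)


def overlap_pairs(query: pd.DataFrame, target: pd.DataFrame) -> pd.DataFrame:
    """All overlapping (query, target) index pairs on matching chromosomes.

    Returns a frame with columns ``q_idx``, ``t_idx``, ``overlap_bp`` holding
    positional indices into the two inputs.
    """
    query = as_regions(query).reset_index(drop=True)
    target = as_regions(target).reset_index(drop=True)
    out_q, out_t, out_bp = [], [], []
    t_by_chrom = {c: g for c, g in target.groupby("chrom", sort=False)}
    for chrom, q in query.groupby("chrom", sort=False):
        t = t_by_chrom.get(chrom)
        if t is None:
            continue
        qi, ti = _overlap_pairs_1d(
            q["start"].to_numpy(), q["end"].to_numpy(),
            t["start"].to_numpy(), t["end"].to_numpy(),
        )
        if len(qi) == 0:
            continue
        qpos = q.index.to_numpy()[qi]
        tpos = t.index.to_numpy()[ti]
        ov = (
            np.minimum(q["end"].to_numpy()[qi], t["end"].to_numpy()[ti])
            - np.maximum(q["start"].to_numpy()[qi], t["start"].to_numpy()[ti])
        )
        out_q.append(qpos)
        out_t.append(tpos)
        out_bp.append(ov)
    if not out_q:
        return pd.DataFrame({"q_idx": [], "t_idx": [], "overlap_bp": []}).astype(np.int64)
    return pd.DataFrame(
        {
            "q_idx": np.concatenate(out_q),
            "t_idx": np.concatenate(out_t),
            "overlap_bp": np.concatenate(out_bp),
        }
    )


def overlaps_any(query: pd.DataFrame, target: pd.DataFrame) -> np.ndarray:
    """Boolean per query row: does it overlap >=1 bp of any target region?"""
    query = as_regions(query)
    flags = np.zeros(len(query), dtype=bool)
    pairs = overlap_pairs(query, target)
    if len(pairs):
        flags[np.unique(pairs["q_idx"].to_numpy())] = True
    return flags


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union of intervals per chromosome (sorted, non-overlapping output)."""
    df = as_regions(df)
    rows = []
    for chrom, g in df.groupby("chrom", sort=False):
        g = g.sort_values("start")
        starts, ends = [], []
        for s, e in zip(g["start"], g["end"]):
            if starts and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    if not rows:
        return df.head(0)
    return pd.concat(rows, ignore_index=True)


def coverage_fraction(query: pd.DataFrame, target: pd.DataFrame) -> np.ndarray:
    """Fraction of each query interval covered by the union of targets."""
    query = as_regions(query).reset_index(drop=True)
    merged = merge_intervals(target) if len(target) else target
    covered = np.zeros(len(query), dtype=float)
    if len(merged):
        pairs = overlap_pairs(query, merged)
        if len(pairs):
            np.add.at(covered, pairs["q_idx"].to_numpy(), pairs["overlap_bp"].to_numpy())
    widths = (query["end"] - query["start"]).to_numpy().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(widths > 0, covered / widths, 0.0)
    return frac


def genes_frame(genes: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene-model frame and derive TSS/TTS (strand-aware)."""
    g = as_regions(genes)
    for col in ("strand", "gene_id"):
        if col not in g.columns:
            raise ValueError(f"gene frame missing column {col!r}")
    bad = ~g["strand"].isin(["+", "-"])
    if bad.any():
        g = g.copy()
        g.loc[bad, "strand"] = "+"
    g = g.copy()
    plus = g["strand"] == "+"
    g["tss"] = np.where(plus, g["start"], g["end"])
    g["tts"] = np.where(plus, g["end"], g["start"])
    return g


def promoter_windows(
    genes: pd.DataFrame,
    upstream_bp: int = 3000,
    downstream_bp: int = 0,
    chromsizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Strand-aware promoter windows around each TSS, clipped to chromosomes.

    ``upstream_bp=3000, downstream_bp=0`` gives the classic 3-kb upstream
    promoter; ``3000, 3000`` gives the +/-3 kb TSS exclusion window.
    """
    g = genes_frame(genes)
    plus = (g["strand"] == "+").to_numpy()
    tss = g["tss"].to_numpy()
    start = np.where(plus, tss - upstream_bp, tss - downstream_bp)
    end = np.where(plus, tss + downstream_bp, tss + upstream_bp)
    start = np.maximum(start, 0)
    out = pd.DataFrame(
        {"chrom": g["chrom"], "start": start, "end": end, "gene_id": g["gene_id"]}
    )
    if chromsizes is not None:
        lim = out["chrom"].map(chromsizes).to_numpy()
        out["end"] = np.minimum(out["end"].to_numpy(), lim)
    return out


def local_windows(
    genes: pd.DataFrame, upstream_bp: int = 3000,
    chromsizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Genic "local" windows: TSS - upstream_bp through the TTS (strand-aware)."""
    g = genes_frame(genes)
    plus = (g["strand"] == "+").to_numpy()
    start = np.where(plus, g["start"].to_numpy() - upstream_bp, g["start"].to_numpy())
    end = np.where(plus, g["end"].to_numpy(), g["end"].to_numpy() + upstream_bp)
    start = np.maximum(start, 0)
    out = pd.DataFrame(
        {"chrom": g["chrom"], "start": start, "end": end, "gene_id": g["gene_id"]}
    )
    if chromsizes is not None:
        lim = out["chrom"].map(chromsizes).to_numpy()
        out["end"] = np.minimum(out["end"].to_numpy(), lim)
    return out
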