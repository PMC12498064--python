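"""Plain-text interchange formats: BED, bedGraph, BEDPE, GFF-lite TSV.

Everything is tab-separated and uncompressed; contact matrices have their
own sparse-triple format in :mod:`chromarch.contacts`.
"""

from __future__ import annotations

import pandas as pd

from .loops import Loop, loops_frame


def write_bed(df: pd.DataFrame, path, extra_cols: list[str] | None = None) -> None:
    cols = ["chrom", "start", "end"] + [c for c in (extra_cols or []) if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, names: list[str] | None = None) -> pd.DataFrame:
    base = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = (names or base)[: df.shape[1]]
    return df


def write_bedgraph(track: pd.DataFrame, path) -> None:
    track[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bedgraph(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"]
    )


def write_bedpe(loops: list[Loop], path) -> None:
    df = loops_frame(loops)
    df["name"] = [f"loop{i}" for i in range(len(df))]
    df[["chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "score"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bedpe(path, resolution: int | None = None) -> list[Loop]:
    df = pd.read_csv(path, sep="\t", header=None)
    loops = []
    for _, r in df.iterrows():
        width = int(r[2] - r[1])
        loops.append(Loop(
            chrom=str(r[0]), start1=int(r[1]), end1=int(r[2]),
            start2=int(r[4]), end2=int(r[5]),
            resolution=resolution or width,
            score=float(r[7]) if len(r) > 7 else 0.0,
            q_value=float("nan"),
        ))
    return loops


def write_genes(genes: pd.DataFrame, path) -> None:
    genes[["chrom", "start", "end", "strand", "gene_id"]].to_csv(
        path, sep="\t", index=False
    )


def read_genes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
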