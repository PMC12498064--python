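"""Config-driven end-to-end pipeline over a simulated condition pair.

Stages: simulate -> balance -> compartments + saddle -> differential matrix
-> TADs -> loops -> chromatin features -> integration.  Every threshold is
carried in :class:`PipelineConfig` (defaults follow common practice for this
kind of tissue comparison: insulation threshold 0.1 with ignore-diags 2 and
bad-bin distance 5, loop reciprocal fraction 0.5 with 40-kb slop, TAD
stability 75%, DAR |log2FC| > 0.5 at FDR 0.05, DEG q < 0.01 at FC > 1.5,
promoter 3 kb) and is echoed into the output manifest, so a rerun with the
same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compartments as cmod
from . import contacts as ct
from . import domains as dmod
from . import features as fmod
from . import integration as imod
from . import io as cio
from . import loops as lmod
from .genome import derive_seed
from .synthetic import (
    ArchitectureTruth,
    SimConfig,
    make_genome,
    simulate_contacts,
    simulate_expression,
    simulate_peak_counts,
    simulate_tracks,
)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    compartment_res: int = 100_000
    tad_res: int = 40_000
    loop_res: tuple[int, ...] = (10_000, 20_000)
    window_bins: int = 10
    ignore_diags: int = 2
    insulation_threshold: float = 0.1
    min_dist_bad_bin: int = 5
    boundary_tol_bins: int = 1
    loop_fdr: float = 0.05
    loop_max_dist_bp: int = 2_000_000
    loop_f: float = 0.5
    loop_slop_bp: int = 40_000
    dar_log2fc: float = 0.5
    dar_fdr: float = 0.05
    deg_q: float = 0.01
    deg_fc: float = 1.5
    promoter_bp: int = 3000
    n_reps: int = 3

    @property
    def seed(self) -> int:
        return self.sim.seed


def load_config(path) -> PipelineConfig:
    """Load a YAML config; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim_raw = raw.pop("sim", {})
    sim_fields = {f.name for f in dataclasses.fields(SimConfig)}
    bad = set(sim_raw) - sim_fields
    pipe_fields = {f.name for f in dataclasses.fields(PipelineConfig)} - {"sim"}
    bad |= set(raw) - pipe_fields
    if bad:
        raise ValueError(f"unknown config keys: {sorted(bad)}")
    if "tad_edits" in sim_raw:
        sim_raw["tad_edits"] = tuple(sim_raw["tad_edits"])
    if "loop_edits" in sim_raw:
        sim_raw["loop_edits"] = tuple(sim_raw["loop_edits"])
    if "loop_res" in raw:
        raw["loop_res"] = tuple(raw["loop_res"])
    return PipelineConfig(sim=SimConfig(**sim_raw), **raw)


def _compartment_stage(cfg: PipelineConfig, truth: ArchitectureTruth) -> dict:
    sim = cfg.sim.at_resolution(cfg.compartment_res)
    dens = cmod.gene_density_per_bin(truth.genes, truth.chromsizes, cfg.compartment_res)
    out = {}
    zs = {}
    for cond in ("a", "b"):
        cmap = ct.balance(simulate_contacts(truth, sim, cond))
        oe = ct.observed_over_expected(cmap)
        track = cmod.call_compartments(cmap, dens, oe=oe)
        out[f"track_{cond}"] = track
        out[f"saddle_{cond}"] = cmod.saddle(cmap, track, oe=oe)
        zs[cond] = ct.zscore(cmap)
    out["switches"] = cmod.classify_switches(out["track_a"], out["track_b"])
    out["difference"] = ct.difference(zs["a"], zs["b"])
    return out


def _tad_stage(cfg: PipelineConfig, truth: ArchitectureTruth) -> dict:
    sim = cfg.sim.at_resolution(cfg.tad_res)
    out = {}
    for cond in ("a", "b"):
        cmap = ct.balance(simulate_contacts(truth, sim, cond))
        track = dmod.insulation_track(cmap, cfg.window_bins, cfg.ignore_diags)
        bounds = dmod.call_boundaries(
            track, cfg.insulation_threshold, cfg.min_dist_bad_bin
        )
        out[f"insulation_{cond}"] = track
        out[f"boundaries_{cond}"] = bounds
        out[f"tads_{cond}"] = dmod.derive_tads(bounds, truth.chromsizes, cfg.tad_res)
    shared, a_spec, b_spec = dmod.compare_boundaries(
        out["boundaries_a"], out["boundaries_b"], cfg.boundary_tol_bins
    )
    out["boundary_comparison"] = {
        "shared": len(shared), "a_specific": len(a_spec), "b_specific": len(b_spec)
    }
    out["tad_changes"] = dmod.classify_tad_changes(out["tads_a"], out["tads_b"])
    return out


def _loop_stage(cfg: PipelineConfig, truth: ArchitectureTruth) -> dict:
    out = {}
    for cond in ("a", "b"):
        per_res = {}
        for res in cfg.loop_res:
            sim = cfg.sim.at_resolution(res)
            cmap = ct.balance(simulate_contacts(truth, sim, cond))
            per_res[res] = lmod.call_loops(
                cmap, max_dist_bp=cfg.loop_max_dist_bp, fdr=cfg.loop_fdr
            )
            if res == min(cfg.loop_res):
                out[f"oe_{cond}"] = ct.observed_over_expected(cmap)
        out[f"loops_{cond}"] = lmod.merge_resolutions(per_res)
    out["comparison"] = lmod.compare_loops(
        out["loops_a"], out["loops_b"], f=cfg.loop_f, slop_bp=cfg.loop_slop_bp
    )
    for cond in ("a", "b"):
        out[f"classes_{cond}"] = lmod.classify_loops(out[f"loops_{cond}"], truth.genes)
    return out


def _feature_stage(cfg: PipelineConfig, truth: ArchitectureTruth) -> dict:
    out = {}
    tracks = {c: simulate_tracks(truth, cfg.sim, c) for c in ("a", "b")}
    out["tracks"] = tracks
    for cond in ("a", "b"):
        out[f"ocrs_{cond}"] = fmod.classify_ocrs(
            tracks[cond]["peaks"]["ATAC"], truth.genes, upstream_bp=cfg.promoter_bp
        )
    expr = simulate_expression(truth, cfg.sim, n_reps=cfg.n_reps)
    a_cols = [c for c in expr.columns if c.startswith("a_")]
    b_cols = [c for c in expr.columns if c.startswith("b_")]
    out["expression"] = expr
    out["degs"] = fmod.deg_call(
        expr, a_cols, b_cols, q_threshold=cfg.deg_q, fc_threshold=cfg.deg_fc
    )
    # differential accessibility / repression over the consensus peak sets
    from .genome import merge_intervals

    diffs = {}
    for mark in ("ATAC", "H3K27me3"):
        consensus = merge_intervals(pd.concat(
            [tracks["a"]["peaks"][mark], tracks["b"]["peaks"][mark]], ignore_index=True
        ))
        counts = simulate_peak_counts(truth, cfg.sim, consensus, n_reps=2) if mark == "ATAC" \
            else _k27_counts(truth, cfg.sim, consensus)
        libs = np.full(2, 1e6)
        diffs[mark] = fmod.differential_regions(
            consensus, counts["a"], counts["b"], libs, libs,
            log2fc_threshold=cfg.dar_log2fc, fdr=cfg.dar_fdr,
        )
    out["diffregions"] = diffs
    # histone cases and enhancers per condition
    for cond in ("a", "b"):
        peaksets = {m: tracks[cond]["peaks"][m] for m in ("H3K4me3", "H3K9ac", "H3K27me3")}
        regions = out[f"ocrs_{cond}"][["chrom", "start", "end"]]
        cased = fmod.classify_histone_cases(regions, peaksets)
        out[f"cases_{cond}"] = cased
        enh = fmod.call_enhancers(cased, truth.genes, promoter_bp=cfg.promoter_bp)
        out[f"enhancers_{cond}"] = fmod.differential_enhancers(enh, diffs)
    return out


def _k27_counts(truth: ArchitectureTruth, sim: SimConfig, regions: pd.DataFrame) -> dict:
    """Replicate K27 counts: regions covered by a condition's planted K27 run hot."""
    from .genome import overlaps_any

    rng = np.random.default_rng(derive_seed(sim.seed, "k27_counts"))
    out = {}
    for cond in ("a", "b"):
        hot = overlaps_any(regions, truth.peaks["H3K27me3"][cond])
        lam = np.where(hot, 120.0, 15.0)
        out[cond] = rng.poisson(lam[:, None], size=(len(regions), 2))
    return out


def _integration_stage(cfg: PipelineConfig, truth: ArchitectureTruth,
                       comp: dict, loops: dict, feats: dict) -> dict:
    out = {}
    out["switch_degs"] = imod.genes_in_switched_bins(
        comp["switches"].frame(), truth.genes, feats["degs"]
    )
    for cond in ("a", "b"):
        links, frac = imod.docr_gene_loops(
            loops[f"loops_{cond}"], loops[f"classes_{cond}"],
            feats[f"ocrs_{cond}"], truth.genes, promoter_bp=cfg.promoter_bp,
        )
        out[f"links_{cond}"] = links
        out[f"anchored_fraction_{cond}"] = frac
        docrs = feats[f"ocrs_{cond}"][feats[f"ocrs_{cond}"]["locality"] == "distal"]
        activity = imod.classify_docr_activity(
            docrs, feats["diffregions"]["ATAC"], feats["diffregions"]["H3K27me3"]
        )
        out[f"docr_activity_{cond}"] = activity
        out[f"controls_{cond}"] = imod.shifted_controls(
            docrs, truth.chromsizes, derive_seed(cfg.seed, "controls", cond)
        )
        out[f"enhancer_links_{cond}"] = imod.enhancer_gene_links(
            feats[f"enhancers_{cond}"], loops[f"loops_{cond}"], truth.genes,
            promoter_bp=cfg.promoter_bp,
        )
    return out


def _write_outputs(outdir: Path, cfg: PipelineConfig, results: dict) -> list[str]:
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def save(name: str, fn) -> None:
        path = outdir / name
        fn(path)
        written.append(name)

    comp, tads, loops, feats, integ = (
        results["compartments"], results["tads"], results["loops"],
        results["features"], results["integration"],
    )
    for cond in ("a", "b"):
        track = comp[f"track_{cond}"]
        save(f"compartments_{cond}.tsv", lambda p, t=track: t.frame().to_csv(p, sep="\t", index=False))
        sad = comp[f"saddle_{cond}"]
        save(f"saddle_{cond}.json", lambda p, s=sad: Path(p).write_text(json.dumps(
            {"strength_x": s.strength_x, "strength_y": s.strength_y,
             "qrange": list(s.qrange), "n_quantiles": s.n_quantiles}, indent=2)))
        save(f"insulation_{cond}.bedgraph", lambda p, t=tads[f"insulation_{cond}"]:
             cio.write_bedgraph(t.frame().rename(columns={"insulation": "value"}).fillna(0.0), p))
        bounds = tads[f"boundaries_{cond}"]
        save(f"boundaries_{cond}.bed", lambda p, b=bounds, r=cfg.tad_res: pd.DataFrame(
            [(x.chrom, x.bin * r, (x.bin + 1) * r, f"boundary{i}", x.strength)
             for i, x in enumerate(b)],
            columns=["chrom", "start", "end", "name", "score"],
        ).to_csv(p, sep="\t", header=False, index=False))
        save(f"tads_{cond}.bed", lambda p, t=tads[f"tads_{cond}"]:
             cio.write_bed(t.frame_bp(), p))
        save(f"loops_{cond}.bedpe", lambda p, l=loops[f"loops_{cond}"]: cio.write_bedpe(l, p))
        save(f"ocrs_{cond}.tsv", lambda p, o=feats[f"ocrs_{cond}"]: o.to_csv(p, sep="\t", index=False))
        save(f"enhancers_{cond}.tsv", lambda p, e=feats[f"enhancers_{cond}"]: e.to_csv(p, sep="\t", index=False))
        save(f"docr_activity_{cond}.tsv", lambda p, d=integ[f"docr_activity_{cond}"]: d.to_csv(p, sep="\t", index=False))
    save("switches.tsv", lambda p: comp["switches"].frame().to_csv(p, sep="\t", index=False))
    save("tad_changes.tsv", lambda p: tads["tad_changes"].to_csv(p, sep="\t", index=False))
    save("degs.tsv", lambda p: feats["degs"].to_csv(p, sep="\t", index=False))
    save("switch_degs.tsv", lambda p: integ["switch_degs"].to_csv(p, sep="\t", index=False))
    comparison = loops["comparison"]
    save("loop_comparison.tsv", lambda p: pd.DataFrame({
        "set": ["common", "a_specific", "b_specific", "a_ambiguous", "b_ambiguous"],
        "count": [len(comparison.common), len(comparison.a_specific),
                  len(comparison.b_specific), len(comparison.a_ambiguous),
                  len(comparison.b_ambiguous)],
    }).to_csv(p, sep="\t", index=False))
    return written


def run_pipeline(cfg: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run the full comparative analysis on one simulated condition pair.

    Returns the in-memory result bundle; when ``outdir`` is given, writes
    the per-stage tables plus a manifest of parameters and outputs.
    """
    truth = make_genome(cfg.sim)
    results: dict = {"truth": truth}
    results["compartments"] = _compartment_stage(cfg, truth)
    results["tads"] = _tad_stage(cfg, truth)
    results["loops"] = _loop_stage(cfg, truth)
    results["features"] = _feature_stage(cfg, truth)
    results["integration"] = _integration_stage(
        cfg, truth, results["compartments"], results["loops"], results["features"]
    )
    if outdir is not None:
        outdir = Path(outdir)
        written = _write_outputs(outdir, cfg, results)
        manifest = {
            "parameters": {
                **{f.name: getattr(cfg, f.name) for f in dataclasses.fields(cfg)
                   if f.name != "sim"},
                "sim": dataclasses.asdict(cfg.sim),
            },
            "outputs": sorted(written),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=list))
    return results
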