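"""End-to-end orchestration: simulate inputs, then quantify, compare,
filter, titrate, and call copy number, writing plain TSV/JSON artifacts per
stage so any stage can be rerun or audited standalone."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from . import cnv as cnv_mod
from . import consensus as cons
from . import simulate as sim
from . import titration as titr
from .cohort import pearson_correlation, summarize_groups, wilcoxon_rank_sum
from .electropherogram import compute_sample_quant

logger = logging.getLogger("cfpipe")

__all__ = ["RunConfig", "ConfigError", "validate_config", "run", "config_hash"]


class _Base(BaseModel):
    model_config = ConfigDict(extra="forbid")


class StageToggles(_Base):
    quantify: bool = True
    cohort: bool = True
    variants: bool = True
    titration: bool = True
    cnv: bool = True


class TraceParams(_Base):
    total_ng: float = Field(80.0, gt=0)
    fractions: tuple[float, float, float, float] = (0.82, 0.10, 0.05, 0.03)
    eluate_volumes_ul: tuple[float, float, float, float] = sim.DEFAULT_ELUATE_VOLUMES_UL
    plasma_volume_ml: float = Field(sim.DEFAULT_PLASMA_VOLUME_ML, gt=0)
    gdna_total_ng: float = Field(0.0, ge=0)
    purity_threshold_pg_per_ul: float = Field(50.0, gt=0)


class VariantParams(_Base):
    min_callers: int = Field(2, ge=1)
    min_depth: int = Field(10, ge=0)
    min_vaf: float = Field(0.05, ge=0, le=1)
    min_alt_reads: int = Field(8, ge=0)
    max_germline_alt: int = Field(0, ge=0)
    max_pop_af: float = Field(1e-4, ge=0, le=1)


class TitrationParams(_Base):
    start_depth: int = Field(147, ge=1)
    reduction: float = Field(0.2, gt=0, lt=1)
    steps: int = Field(4, ge=1)


class CnvParams(_Base):
    min_bins: int = Field(10, ge=2)
    penalty: float = Field(12.0, gt=0)
    tumor_fraction: float = Field(0.25, ge=0, lt=1)


class RunConfig(_Base):
    seed: int = 0
    stages: StageToggles = StageToggles()
    trace: TraceParams = TraceParams()
    variants: VariantParams = VariantParams()
    titration: TitrationParams = TitrationParams()
    cnv: CnvParams = CnvParams()


class ConfigError(ValueError):
    """Raised with path-addressed messages when a config is invalid."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


def validate_config(raw: dict | None) -> RunConfig:
    """Fill defaults and validate; unknown keys are rejected."""
    try:
        return RunConfig.model_validate(raw or {})
    except ValidationError as e:
        msgs = [
            f"{'.'.join(str(p) for p in err['loc']) or '<root>'}: {err['msg']}"
            for err in e.errors()
        ]
        raise ConfigError(msgs) from None


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the enabled stages and write their artifacts under
    ``outdir``. Deterministic per config; the report records the config
    hash and package version."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    seeds = {name: child for name, child in zip(
        ("quantify", "cohort", "variants", "titration", "cnv"), root.spawn(5))}
    report: dict = {
        "config_hash": config_hash(config),
        "version": __version__,
        "stages": {},
    }

    if config.stages.quantify:
        logger.info("stage quantify")
        d = outdir / "quantify"
        d.mkdir(exist_ok=True)
        tp = config.trace
        traces = sim.gen_elution_series(
            tp.total_ng, tp.fractions, tp.eluate_volumes_ul,
            seed=seeds["quantify"], gdna_total_ng=tp.gdna_total_ng,
            plasma_volume_ml=tp.plasma_volume_ml,
        )
        from .electropherogram import write_trace_csv

        for t in traces:
            write_trace_csv(t, d / f"trace_eluate{t.eluate_index}.csv")
        quant = compute_sample_quant(traces)
        _write_json(d / "sample_quant.json", quant.to_dict())
        report["stages"]["quantify"] = {
            "cfdna_ng_per_ml_plasma": quant.cfdna_ng_per_ml_plasma,
            "purity": quant.purity,
            "first_elution_pct": quant.first_elution_pct,
        }

    if config.stages.cohort:
        logger.info("stage cohort")
        d = outdir / "cohort"
        d.mkdir(exist_ok=True)
        table = sim.gen_cohort(sim.CohortSpec(), seeds["cohort"])
        table.to_csv(d / "cohort.tsv", sep="\t", index=False)
        summary = summarize_groups(table)
        summary.to_csv(d / "group_summary.tsv", sep="\t", index=False)
        mcrpc = table[table["group"] == "mCRPC"]
        healthy = table[table["group"] == "healthy"]
        w = wilcoxon_rank_sum(
            mcrpc["concentration_ng_per_ml"], healthy["concentration_ng_per_ml"]
        )
        r, p = pearson_correlation(
            mcrpc["mean_fragment_size_bp"], mcrpc["concentration_ng_per_ml"]
        )
        stats_out = {
            "wilcoxon_mcrpc_vs_healthy": {"W": w.statistic, "p": w.pvalue, "method": w.method},
            "pearson_size_vs_conc_mcrpc": {"r": r, "p": p},
        }
        _write_json(d / "stats.json", stats_out)
        report["stages"]["cohort"] = stats_out

    if config.stages.variants:
        logger.info("stage variants")
        d = outdir / "variants"
        d.mkdir(exist_ok=True)
        bundle = sim.gen_callsets(sim.CallsetSpec(), seeds["variants"])
        bundle.write(d / "inputs")
        vp = config.variants
        params = cons.FilterParams(
            min_callers=vp.min_callers, min_depth=vp.min_depth,
            min_vaf=vp.min_vaf, min_alt_reads=vp.min_alt_reads,
            max_germline_alt=vp.max_germline_alt, max_pop_af=vp.max_pop_af,
        )
        annotations = cons.annotations_from_frames(bundle.annotations, bundle.germline)
        passing, audit = cons.filter_callset(bundle.callsets, annotations, params)
        audit.to_csv(d / "audit.tsv", sep="\t", index=False)
        cons.write_passing_vcf(passing, d / "passing.vcf")
        report["stages"]["variants"] = {
            "n_candidates": int(len(audit)),
            "n_passing": len(passing),
        }

    if config.stages.titration:
        logger.info("stage titration")
        d = outdir / "titration"
        d.mkdir(exist_ok=True)
        tp = config.titration
        schedule = titr.downsample_schedule(tp.start_depth, tp.reduction, tp.steps)
        spec = sim.CallsetSpec(depth=tp.start_depth)
        rng = np.random.default_rng(seeds["titration"])
        tracks = {
            f"{v.chrom}:{v.pos}{v.ref}>{v.alt}": (
                int(rng.binomial(tp.start_depth, v.vaf)), tp.start_depth)
            for v in spec.true_variants
        }
        table = titr.vaf_across_depths(tracks, schedule, rng,
                                       min_reads=config.variants.min_alt_reads)
        table.to_csv(d / "allele_tracks.tsv", sep="\t", index=False)
        _write_json(d / "schedule.json", {
            "start_depth": schedule.start_depth,
            "depths": list(schedule.depths),
        })
        report["stages"]["titration"] = {
            "depths": list(schedule.depths),
            "n_detected_at_lowest": int(
                table[table["depth"] == schedule.depths[-1]]["detected"].sum()
            ),
        }

    if config.stages.cnv:
        logger.info("stage cnv")
        d = outdir / "cnv"
        d.mkdir(exist_ok=True)
        cp = config.cnv
        spec = sim.ProfileSpec(tumor_fraction=cp.tumor_fraction)
        tumor, normal = sim.gen_bin_profile(spec, seeds["cnv"])
        cnv_mod.write_bins_tsv(tumor, d / "tumor_bins.tsv")
        cnv_mod.write_bins_tsv(normal, d / "normal_bins.tsv")
        lr = cnv_mod.normalize_bins(tumor, normal)
        segments = cnv_mod.segment_profile(lr, min_bins=cp.min_bins, penalty=cp.penalty)
        estimate, fitted = cnv_mod.estimate_tf(
            segments, bin_noise_sd=cnv_mod.estimate_noise_sd(lr)
        )
        cnv_mod.write_segments_tsv(fitted, d / "segments.tsv")
        cnv_mod.write_summary_json(estimate, d / "summary.json")
        report["stages"]["cnv"] = {
            "tumor_fraction": estimate.tumor_fraction,
            "frac_genome_subclonal": estimate.frac_genome_subclonal,
            "n_segments": len(fitted),
        }

    _write_json(outdir / "report.json", report)
    return report
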