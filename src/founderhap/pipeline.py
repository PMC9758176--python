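"""Pipeline orchestration: simulate -> ibd -> classify -> popgen -> flux.

A single structured-text (YAML) config with one block per stage drives
the run; stages absent from the config are skipped. All outputs are
written under one prefix and summarized in a JSON report carrying run
metadata (seed, config digest). Re-running with the same config and seed
reproduces every numeric output bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path

import yaml

from . import flux as fluxmod
from . import popgen as popmod
from .haplotype import DEFAULT_RULE, HaplotypeRule, classify_diplotype, haplotype_frequencies
from .ibd import StreakParams, multiway_shared_segments, segment_span_kb
from .matrix import GenotypeMatrix
from .simulate import (
    FounderSpec,
    PanelSite,
    SampleSpec,
    SimulationConfig,
    founder_demo_config,
    panel_truth,
    simulate_genotypes,
)
from .vcfio import read_vcf, write_calls_tsv, write_segments_bed, write_segments_tsv, write_vcf

log = logging.getLogger("founderhap")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineReport:
    seed: int
    config_digest: str
    timestamp: str
    stages: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config_digest": self.config_digest,
            "timestamp": self.timestamp,
            "stages": self.stages,
            "outputs": self.outputs,
        }


def _digest(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def load_config(path: str | PathLike) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("pipeline config must be a mapping")
    return cfg


def _sim_config_from_block(block: dict, seed: int) -> SimulationConfig:
    if block.get("demo"):
        kwargs = {
            k: block[k]
            for k in ("n_sites", "genotype_error_rate", "missing_rate")
            if k in block
        }
        return founder_demo_config(seed, **kwargs)
    chromosome, lo, hi = block["region"]
    return SimulationConfig(
        seed=seed,
        region=(str(chromosome), int(lo), int(hi)),
        n_sites=int(block["n_sites"]),
        panel_sites=tuple(PanelSite(**ps) for ps in block.get("panel_sites", [])),
        founders=tuple(
            FounderSpec(
                label=f["label"],
                planted_span=tuple(f["planted_span"]),
                marker_pattern={int(k): v for k, v in f.get("marker_pattern", {}).items()},
                risk=f.get("risk", True),
            )
            for f in block.get("founders", [])
        ),
        samples=tuple(SampleSpec(**s) for s in block.get("samples", [])),
        genotype_error_rate=float(block.get("genotype_error_rate", 0.0)),
        missing_rate=float(block.get("missing_rate", 0.0)),
        alt_freq_overrides={
            int(k): float(v) for k, v in block.get("alt_freq_overrides", {}).items()
        },
        forced_genotypes=tuple(
            (s, int(p), int(c)) for s, p, c in block.get("forced_genotypes", [])
        ),
        exclude_zones=tuple(tuple(z) for z in block.get("exclude_zones", [])),
    )


def demo_config(seed: int = 1) -> dict:
    """Bundled demo: the two-founder, four-homozygote synthetic scenario."""
    return {
        "seed": seed,
        "simulate": {"demo": True, "n_sites": 1200},
        "ibd": {
            "groups": [["P1", "P2"], ["P3", "H1"]],
            "max_mismatches": 0,
            "min_markers": 150,
            "min_span_bp": 100_000,
        },
        "classify": {},
        "popgen": {
            "population_n": popmod.DEFAULT_POPULATION_N,
            "counts": [
                {"variant_label": "c.620A>T", "alt_alleles": 22, "total_alleles": 13_686},
                {"variant_label": "c.1807G>C", "alt_alleles": 12, "total_alleles": 13_686},
            ],
            "observed": {"c.620A>T": 3, "c.1807G>C": 92},
            "freq_overrides": {"c.1807G>C": 0.00089},
            "cohort_table": {
                "total_patient_alleles": 730,
                "rows": [
                    {
                        "variant_label": "c.1807G>C",
                        "patient_alleles": 318,
                        "homozygous_alleles": 184,
                        "compound_het_alleles": 134,
                    },
                    {
                        "variant_label": "c.620A>T",
                        "patient_alleles": 185,
                        "homozygous_alleles": 6,
                        "compound_het_alleles": 179,
                    },
                ],
            },
        },
        "flux": {
            "dimers": [["WT", "WT"], ["D207V", "D207V"], ["D207V", "catalytic"]]
        },
    }


def run_pipeline(config: dict | str | PathLike, out_prefix: str | PathLike) -> PipelineReport:
    """Execute the configured stages in dependency order.

    Stage outputs are written under ``out_prefix``; a stage failure raises
    :class:`PipelineError` naming the stage, with earlier outputs retained
    on disk.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    seed = int(config.get("seed", 0))
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    report = PipelineReport(
        seed=seed,
        config_digest=_digest(config),
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    gm: GenotypeMatrix | None = None

    if "simulate" in config:
        stage = "simulate"
        try:
            sim_cfg = _sim_config_from_block(config[stage] or {}, seed)
            gm = simulate_genotypes(sim_cfg)
            vcf_path = f"{prefix}.vcf"
            write_vcf(gm, vcf_path)
            truth_path = f"{prefix}.truth.json"
            with open(truth_path, "w") as fh:
                json.dump(panel_truth(sim_cfg), fh, indent=1)
            report.outputs["vcf"] = vcf_path
            report.outputs["truth"] = truth_path
            report.stages[stage] = {
                "n_samples": gm.n_samples,
                "n_sites": gm.n_sites,
            }
            log.info("[simulate] %d samples x %d sites", gm.n_samples, gm.n_sites)
        except Exception as e:  # noqa: BLE001 - re-raised with stage name
            raise PipelineError(stage, e) from e

    def _matrix_for(block: dict) -> GenotypeMatrix:
        if block.get("vcf"):
            return read_vcf(block["vcf"])
        if gm is None:
            raise ValueError("no VCF given and no simulate stage configured")
        return gm

    if "ibd" in config:
        stage = "ibd"
        try:
            block = config[stage] or {}
            m = _matrix_for(block)
            params = StreakParams(
                max_mismatches=int(block.get("max_mismatches", 0)),
                min_markers=int(block.get("min_markers", 100)),
                min_span_bp=int(block.get("min_span_bp", 100_000)),
            )
            groups = block.get("groups") or []
            segs = []
            for group in groups:
                segs.extend(multiway_shared_segments(m, list(group), params))
            write_segments_bed(segs, f"{prefix}.ibd.bed")
            write_segments_tsv(segs, f"{prefix}.ibd.tsv")
            report.outputs["ibd_bed"] = f"{prefix}.ibd.bed"
            report.outputs["ibd_tsv"] = f"{prefix}.ibd.tsv"
            report.stages[stage] = {
                "segments": [
                    {
                        "pair": list(s.pair),
                        "chromosome": s.chromosome,
                        "start": s.start,
                        "end": s.end,
                        "span_kb": segment_span_kb(s),
                        "n_markers": s.n_markers,
                    }
                    for s in segs
                ]
            }
            log.info("[ibd] %d segment(s)", len(segs))
        except Exception as e:
            raise PipelineError(stage, e) from e

    if "classify" in config:
        stage = "classify"
        try:
            block = config[stage] or {}
            m = _matrix_for(block)
            rule = DEFAULT_RULE
            if block.get("rule"):
                with open(block["rule"]) as fh:
                    rd = yaml.safe_load(fh)
                rule = HaplotypeRule(
                    chromosome=str(rd.get("chromosome", "9")),
                    discriminating_sites=tuple(rd["discriminating_sites"]),
                    risk_site=int(rd["risk_site"]),
                    alpha_pattern=tuple(rd["alpha_pattern"]),
                    beta_pattern=tuple(rd["beta_pattern"]),
                    background_pattern=tuple(rd["background_pattern"]),
                    risk_ref=rd.get("risk_ref", "T"),
                    risk_alt=rd.get("risk_alt", "A"),
                )
            which = block.get("samples") or m.samples
            calls = []
            for s in which:
                g = m.genotypes_at(s, rule.panel_sites, rule.chromosome)
                calls.append(classify_diplotype(g, rule, sample=s))
            write_calls_tsv(calls, f"{prefix}.calls.tsv")
            freqs = haplotype_frequencies(calls, stratum=block.get("stratum", "all"))
            with open(f"{prefix}.haplotype_freqs.json", "w") as fh:
                json.dump(freqs, fh, indent=1)
            report.outputs["calls"] = f"{prefix}.calls.tsv"
            report.outputs["haplotype_freqs"] = f"{prefix}.haplotype_freqs.json"
            report.stages[stage] = {
                "calls": {c.sample: c.diplotype for c in calls},
                "frequencies": freqs,
            }
            log.info("[classify] %d call(s)", len(calls))
        except Exception as e:
            raise PipelineError(stage, e) from e

    if "popgen" in config:
        stage = "popgen"
        try:
            block = config[stage] or {}
            counts = [popmod.AlleleCount(**c) for c in block.get("counts", [])]
            table = None
            if "cohort_table" in block:
                import pandas as pd

                tb = block["cohort_table"]
                table = popmod.CohortAlleleTable(
                    rows=pd.DataFrame(tb["rows"]),
                    total_patient_alleles=int(tb["total_patient_alleles"]),
                )
            rep = popmod.cohort_report(
                counts,
                observed={k: int(v) for k, v in block.get("observed", {}).items()},
                table=table,
                population_n=int(
                    block.get("population_n", popmod.DEFAULT_POPULATION_N)
                ),
                freq_overrides={
                    k: float(v) for k, v in block.get("freq_overrides", {}).items()
                },
            )
            with open(f"{prefix}.popgen.json", "w") as fh:
                json.dump(rep, fh, indent=1)
            report.outputs["popgen"] = f"{prefix}.popgen.json"
            report.stages[stage] = rep
            log.info("[popgen] %d variant(s)", len(rep))
        except Exception as e:
            raise PipelineError(stage, e) from e

    if "flux" in config:
        stage = "flux"
        try:
            block = config[stage] or {}
            results = {}
            for label1, label2 in block.get("dimers", []):
                model = fluxmod.dimer_from_presets(label1, label2)
                results[f"{label1}/{label2}"] = fluxmod.dimer_production(model).as_dict()
            with open(f"{prefix}.flux.json", "w") as fh:
                json.dump(results, fh, indent=1)
            report.outputs["flux"] = f"{prefix}.flux.json"
            report.stages[stage] = results
            log.info("[flux] %d dimer(s)", len(results))
        except Exception as e:
            raise PipelineError(stage, e) from e

    with open(f"{prefix}.report.json", "w") as fh:
        json.dump(report.as_dict(), fh, indent=1)
    report.outputs["report"] = f"{prefix}.report.json"
    return report
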