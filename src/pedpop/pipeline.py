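"""End-to-end pipeline: simulate (or ingest) -> identify -> relatedness ->
pedigree -> population estimates -> experiments -> JSON report."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .estimators import (
    CreelRosenblattModel,
    DAM_MORTALITY,
    FS_THRESHOLD,
    RarefactionModel,
    SIRE_MORTALITY,
)
from .experiments import (
    dyad_completeness,
    edge_subsets,
    make_cre_engine,
    sampling_intensity_sweep,
)
from .genotyping import identify_individuals
from .panel import default_panel
from .parentage import ParentageConfig, ParentageModel
from .relatedness import allele_frequencies, lr_matrix
from .simulate import SampleSet, SimConfig, collect_samples, simulate_population

logger = logging.getLogger("pedpop")

REPORT_SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Flat per-stage configuration; every stochastic stage's seed derives
    deterministically from the master seed."""

    seed: int = 0
    samples_csv: str | None = None  # ingest instead of simulating
    output_dir: str = "pedpop_out"
    simulate: dict = field(default_factory=dict)  # SimConfig overrides
    min_loci: int = 70
    max_mismatch: int = 2
    min_overlap: int = 40
    parentage: dict = field(default_factory=dict)  # ParentageConfig overrides
    strategy: str = "nonbreeder_fraction"
    m_f: float = DAM_MORTALITY
    m_m: float = SIRE_MORTALITY
    fs_threshold: float = FS_THRESHOLD
    rarefaction_iters: int = 100
    run_experiments: bool = False
    sweep_levels: list = field(default_factory=lambda: [0.2, 0.4, 0.6])
    sweep_reps: int = 3
    edges_n: int = 20

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)


def _child_seed(master: int, label: str) -> int:
    digest = hashlib.sha256(f"{master}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return (and write) the JSON report."""
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "manifest": {
            "package_version": __version__,
            "seed": config.seed,
            "config": {
                k: v
                for k, v in dataclasses.asdict(config).items()
                if k != "output_dir"
            },
        },
        "stages": {},
    }

    def stage(name):
        logger.info("stage %s", name)
        return time.time()

    # ---- simulate or ingest ------------------------------------------------
    ts = stage("samples")
    try:
        if config.samples_csv:
            sample_set = SampleSet.from_csv(config.samples_csv)
            report["stages"]["samples"] = {
                "source": "ingested",
                "path": str(config.samples_csv),
                "n_samples": len(sample_set),
            }
            pop = None
        else:
            sim = SimConfig(**{"seed": config.seed, **config.simulate})
            pop = simulate_population(sim)
            if pop.extinct:
                raise PipelineError("samples", "simulated population went extinct")
            sample_set = collect_samples(pop, sim)
            pop.pedigree_to_csv(outdir / "true_pedigree.csv")
            report["stages"]["samples"] = {
                "source": "simulated",
                "n_alive": len(pop.alive_ids),
                "n_samples": len(sample_set),
            }
        sample_set.to_csv(outdir / "samples.csv")
    except PipelineError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError("samples", str(exc)) from exc
    report["stages"]["samples"]["seconds"] = round(time.time() - ts, 3)

    # ---- identification ----------------------------------------------------
    ts = stage("identify")
    try:
        table = identify_individuals(
            sample_set,
            min_loci=config.min_loci,
            max_mismatch=config.max_mismatch,
            min_overlap=config.min_overlap,
        )
        table.to_csv(outdir / "individuals.csv")
    except Exception as exc:
        raise PipelineError("identify", str(exc)) from exc
    report["stages"]["identify"] = {
        "n_individuals": len(table),
        "n_female": int(np.sum(table.sex == "F")),
        "n_male": int(np.sum(table.sex == "M")),
        "seconds": round(time.time() - ts, 3),
    }

    # ---- relatedness -------------------------------------------------------
    ts = stage("relatedness")
    try:
        freqs = allele_frequencies(table.genotypes)
        rel = lr_matrix(table, freqs)
        rel.to_csv(outdir / "relatedness.csv")
    except Exception as exc:
        raise PipelineError("relatedness", str(exc)) from exc
    report["stages"]["relatedness"] = {
        "n_pairs": int(len(table) * (len(table) - 1) // 2),
        "seconds": round(time.time() - ts, 3),
    }

    # ---- pedigree ----------------------------------------------------------
    ts = stage("pedigree")
    try:
        pcfg = ParentageConfig(**config.parentage)
        ped = ParentageModel(table, freqs).fit(pcfg)
        ped.to_csv(outdir / "pedigree.csv")
    except Exception as exc:
        raise PipelineError("pedigree", str(exc)) from exc
    assert ped.n_triads + ped.n_dyads + ped.n_unassigned == ped.n_s
    report["stages"]["pedigree"] = {
        "n_s": ped.n_s,
        "n_triads": ped.n_triads,
        "n_dyads": ped.n_dyads,
        "n_unassigned": ped.n_unassigned,
        "b_s": ped.b_s,
        "breeder_proportion": round(ped.breeder_proportion, 4)
        if ped.n_s
        else None,
        "dam_sire_ratio": None
        if not np.isfinite(ped.dam_sire_ratio)
        else round(ped.dam_sire_ratio, 4),
        "seconds": round(time.time() - ts, 3),
    }

    # ---- estimates ---------------------------------------------------------
    ts = stage("estimates")
    try:
        cre = CreelRosenblattModel(
            ped, rel, m_f=config.m_f, m_m=config.m_m, fs_threshold=config.fs_threshold
        ).fit(strategy=config.strategy)
        # map each QC-passed sample to its matched individual, preserving
        # the collection order of the sample stream
        member_map = {
            sid: ind_id
            for ind_id, sids in zip(table.ids, table.members or [])
            for sid in sids
        }
        seq = [
            member_map[s.sample_id]
            for s in sample_set.samples
            if s.sample_id in member_map
        ]
        rare = RarefactionModel(seq).fit(
            n_iter=config.rarefaction_iters, seed=_child_seed(config.seed, "rarefaction")
        )
    except Exception as exc:
        raise PipelineError("estimates", str(exc)) from exc
    report["stages"]["estimates"] = {
        "cre": cre.to_dict(),
        "rarefaction": {
            "mean_a": round(rare.mean_a, 2),
            "n_converged": rare.n_converged,
            "n_samples": rare.n_samples,
            "n_unique": rare.n_unique,
        },
        "seconds": round(time.time() - ts, 3),
    }
    with open(outdir / "cre.json", "w") as fh:
        json.dump(cre.to_dict(), fh, indent=2, sort_keys=True)

    # ---- experiments (optional) -------------------------------------------
    if config.run_experiments:
        ts = stage("experiments")
        try:
            engine = make_cre_engine(
                ParentageConfig(**config.parentage),
                strategy=config.strategy,
                m_f=config.m_f,
                m_m=config.m_m,
            )
            sweep = sampling_intensity_sweep(
                table,
                engine,
                n_ref=len(table),
                levels=config.sweep_levels,
                n_reps=config.sweep_reps,
                seed=_child_seed(config.seed, "sweep"),
            )
            sweep.to_frame().to_csv(outdir / "sweep.csv", index=False)
            edges = edge_subsets(table, min(config.edges_n, len(table)))
            completeness = {
                name: round(
                    dyad_completeness(subset, ped.assignments), 4
                )
                for name, subset in edges.subsets.items()
            }
        except Exception as exc:
            raise PipelineError("experiments", str(exc)) from exc
        report["stages"]["experiments"] = {
            "sweep": sweep.to_frame().to_dict(orient="records"),
            "edge_completeness": completeness,
            "seconds": round(time.time() - ts, 3),
        }

    report["seconds_total"] = round(time.time() - t0, 3)
    with open(outdir / "report.json", "w") as fh:
        json.dump(_strip_times(report), fh, indent=2, sort_keys=True)
    return report


def _strip_times(obj):
    if isinstance(obj, dict):
        return {
            k: _strip_times(v)
            for k, v in obj.items()
            if k not in ("seconds", "seconds_total")
        }
    if isinstance(obj, list):
        return [_strip_times(v) for v in obj]
    return obj
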