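"""End-to-end driver: simulation -> PMF -> energetics -> affinity correlation.

Per scenario (a shielding value standing for a complex variant), the pipeline
runs restrained equilibration + steered pulls, estimates the endpoint rupture
PMF with bootstrap errors, and computes the near-probe water RDF with the
exclusion zone tied to the shielding.  If a per-bond endpoint table is
supplied instead (``endpoints_tsv``), the simulation stage is skipped and the
energetics layer (ΣPMF, relative values, error propagation) is built from it;
an optional per-complex ΔG_bin table adds the ΣPMF-vs-affinity regression.

The report is deterministic under a fixed config: same config text -> byte
identical report body (no timestamps).  Every output file carries the config
hash and seed in its header comments.  Stage failures abort with the stage
name; partial outputs written so far are left in place.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig, config_hash
from .energetics import build_energetics_table, correlate_with_affinity
from .io import write_pmf_profile, write_rdf_profile, write_work_profiles
from .pmf import bootstrap_errors, endpoint_value
from .simulate import generate_work_ensemble, sample_solvent_frames
from .solvation import RDFConfig, compute_rdf

__all__ = ["PipelineReport", "PipelineError", "run_pipeline"]

logger = logging.getLogger("glueforce")

_SEED_MOD = 2_147_483_647


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineReport:
    """All numbers produced by one pipeline run, with provenance."""

    provenance: dict
    scenarios: dict
    energetics: dict | None = None
    correlation: dict | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _configure_logging(quiet: bool) -> None:
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("[%(name)s] %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(logging.WARNING if quiet else logging.INFO)


def _scenario_stage(cfg: RunConfig, outdir: Path, meta: dict) -> dict:
    results = {}
    rdf_cfg = RDFConfig()
    for k, label in enumerate(sorted(cfg.scenarios)):
        shielding = float(cfg.scenarios[label])
        t0 = time.perf_counter()
        model = cfg.landscape.with_shielding(shielding)
        protocol = replace(
            cfg.protocol, seed=(cfg.seed + 100_000 * k) % _SEED_MOD
        )
        ensemble = generate_work_ensemble(
            model, protocol, cfg.restraint, stage1_ns=cfg.stage1_ns
        )
        profile = bootstrap_errors(
            ensemble, n_boot=cfg.n_boot, seed=(cfg.seed + 7 + k) % _SEED_MOD
        )
        value, sd = endpoint_value(profile, end=protocol.end_distance)
        entry = {
            "shielding": shielding,
            "n_traj": ensemble.n_traj,
            "endpoint_pmf_kcal_mol": round(value, 6),
            "endpoint_sd_kcal_mol": round(sd, 6),
            "mean_work_end_kcal_mol": round(float(ensemble.works[:, -1].mean()), 6),
            "min_work_end_kcal_mol": round(float(ensemble.works[:, -1].min()), 6),
        }
        write_work_profiles(
            outdir / f"work_{label}.tsv", ensemble, meta=meta, coarsen=100
        )
        write_pmf_profile(outdir / f"pmf_{label}.tsv", profile, meta=meta)
        if cfg.rdf_frames > 0:
            frames = sample_solvent_frames(
                cfg.rdf_frames,
                exclusion_radius=cfg.rdf_exclusion_radius,
                exclusion_prob=shielding,
                seed=(cfg.seed + 13 + k) % _SEED_MOD,
            )
            rdf = compute_rdf(frames, rdf_cfg)
            near = rdf.r < cfg.rdf_exclusion_radius
            entry["rdf_mean_g_near"] = round(float(rdf.g[near].mean()), 6)
            write_rdf_profile(outdir / f"rdf_{label}.tsv", rdf, meta=meta)
        results[label] = entry
        logger.info(
            "scenario %s (shielding %.2f): endpoint %.3f ± %.3f kcal/mol [%.1f s]",
            label,
            shielding,
            value,
            sd,
            time.perf_counter() - t0,
        )
    return results


def _energetics_stage(cfg: RunConfig) -> dict:
    records = pd.read_csv(cfg.endpoints_tsv, sep="\t", comment="#")
    table = build_energetics_table(records, reference=cfg.reference)
    totals = table.totals
    return {
        "reference": table.reference,
        "sum_pmf_kcal_mol": {
            c: round(float(totals.loc[c, "sum_pmf_kcal_mol"]), 6)
            for c in totals.index
        },
        "sum_sd_kcal_mol": {
            c: round(float(totals.loc[c, "sd_kcal_mol"]), 6) for c in totals.index
        },
        "rel_kcal_mol": {
            c: round(float(totals.loc[c, "rel_kcal_mol"]), 6) for c in totals.index
        },
        "rel_sd_kcal_mol": {
            c: round(float(totals.loc[c, "rel_sd_kcal_mol"]), 6)
            for c in totals.index
        },
        "mismatched_printed_totals": list(table.mismatches),
    }


def _correlation_stage(cfg: RunConfig, energetics: dict) -> dict:
    affinity = pd.read_csv(cfg.affinity_tsv, sep="\t", comment="#")
    dg = affinity.set_index("complex")["dg_bin_kcal_mol"]
    totals = pd.Series(energetics["sum_pmf_kcal_mol"])
    fit = correlate_with_affinity(totals, dg)
    return {
        "slope": round(fit.slope, 6),
        "intercept": round(fit.intercept, 6),
        "r_squared": round(fit.r_squared, 6),
        "n": fit.n,
    }


def run_pipeline(cfg: RunConfig) -> PipelineReport:
    """Execute the configured pipeline and write its outputs under ``cfg.outdir``.

    Deterministic under a fixed config; the returned report is also written to
    ``report.json``.
    """
    _configure_logging(cfg.quiet)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    meta = {"config_hash": chash, "seed": cfg.seed}
    (outdir / "config.txt").write_text(cfg.to_text())

    provenance = {"config_hash": chash, "seed": cfg.seed, "version": __version__}
    scenarios: dict = {}
    energetics = correlation = None

    def _run(stage: str, fn, *args):
        t0 = time.perf_counter()
        try:
            out = fn(*args)
        except Exception as exc:  # preserve partial outputs, name the stage
            report = PipelineReport(
                provenance=provenance,
                scenarios=scenarios,
                energetics=energetics,
                correlation=correlation,
            )
            (outdir / "report_partial.json").write_text(report.to_json() + "\n")
            raise PipelineError(stage, exc) from exc
        logger.info("stage %s done [%.1f s]", stage, time.perf_counter() - t0)
        return out

    if cfg.endpoints_tsv:
        energetics = _run("energetics", _energetics_stage, cfg)
        if cfg.affinity_tsv:
            correlation = _run("correlation", _correlation_stage, cfg, energetics)
    else:
        scenarios = _run("simulation", _scenario_stage, cfg, outdir, meta)

    report = PipelineReport(
        provenance=provenance,
        scenarios=scenarios,
        energetics=energetics,
        correlation=correlation,
    )
    (outdir / "report.json").write_text(report.to_json() + "\n")
    return report
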