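"""End-to-end orchestration: simulate -> stage 1 -> standardise -> pool -> priors.

``run_pipeline`` executes the requested stages against a programme of
synthetic trials, writing per-stage artifacts (CSV trial tables, JSON
exports, JSON/CSV pooled summaries, a Student-t prior) plus a machine-
readable manifest recording the master seed, configuration, and SHA-256
hashes of every artifact.  Reruns with the same configuration reproduce the
artifacts byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import io as cio
from .cohorts import (
    COPD_PROFILE,
    DIABETES_PROFILE,
    HYPERTENSION_PROFILE,
    CohortProfile,
    GroundTruth,
    TrialDesign,
    generate_program,
)
from .mcid import McidRegistry, standardize
from .meta import (
    MCMCConfig,
    MetaResult,
    meta_analyse,
    meta_input_from_exports,
    pool_ratio_scale,
)
from .priors import GroupEstimate, fit_student_t, hierarchical_prediction
from .report import forest_table
from .stage1 import INTERACTION_LABELS, AnalysisSpec, fit_program

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "demo_designs", "builtin_profiles"]


def builtin_profiles() -> dict[str, CohortProfile]:
    return {
        "diabetes": DIABETES_PROFILE,
        "hypertension": HYPERTENSION_PROFILE,
        "copd": COPD_PROFILE,
    }


@dataclass
class RunConfig:
    """Full pipeline configuration; serialised alongside every run."""

    out_dir: Path
    seed: int = 0
    families: tuple[str, ...] = ("age_sex", "comorbidity_count")
    effects_threshold: int = 5
    sensitivity: bool = False
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    registry: McidRegistry = field(default_factory=McidRegistry.example)
    designs: Sequence[tuple[TrialDesign, CohortProfile]] = ()
    fit_priors: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path, out_dir=None) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        profiles = builtin_profiles()
        for name, p in (raw.get("profiles") or {}).items():
            profiles[name] = CohortProfile(indication=name, **p)
        designs = []
        for d in raw.get("trials", []):
            profile = profiles[d["indication"]]
            truth = GroundTruth(**(d.get("truth") or {}))
            designs.append(
                (
                    TrialDesign(
                        trial_id=d["trial_id"],
                        indication=d["indication"],
                        comparison=d["comparison"],
                        outcome_name=d["outcome_name"],
                        outcome_family=d.get("outcome_family", "continuous"),
                        direction=d.get("direction", "higher_worse"),
                        mcid=float(d["mcid"]),
                        n=int(d["n"]),
                        truth=truth,
                    ),
                    profile,
                )
            )
        mcmc = MCMCConfig(**(raw.get("mcmc") or {}))
        registry = McidRegistry.example()
        for row in raw.get("mcid_registry", []):
            from .mcid import McidEntry

            registry.add(
                row["indication"],
                row["outcome"],
                McidEntry(float(row["mcid"]), row["direction"], row.get("source", "")),
            )
        return cls(
            out_dir=Path(out_dir or raw.get("out_dir", "comorbmeta_run")),
            seed=int(raw.get("seed", 0)),
            families=tuple(raw.get("families", ("age_sex", "comorbidity_count"))),
            effects_threshold=int(raw.get("effects_threshold", 5)),
            sensitivity=bool(raw.get("sensitivity", False)),
            mcmc=mcmc,
            registry=registry,
            designs=designs,
            fit_priors=bool(raw.get("fit_priors", True)),
        )


def demo_designs(
    n_per_trial: int = 400, gamma_count: float = 0.0
) -> list[tuple[TrialDesign, CohortProfile]]:
    """A small three-indication demo programme (12 trials).

    Diabetes contributes 5 trials on one comparison (so its group pools with
    random effects under the default threshold), hypertension 4 and COPD 3
    (fixed effects).  All trials are null for interactions unless
    ``gamma_count`` is set.
    """
    designs: list[tuple[TrialDesign, CohortProfile]] = []

    def add(prefix, k, profile, comparison, outcome, direction, mcid, truth):
        for i in range(k):
            designs.append(
                (
                    TrialDesign(
                        trial_id=f"{prefix}{i + 1:02d}",
                        indication=profile.indication,
                        comparison=comparison,
                        outcome_name=outcome,
                        outcome_family="continuous",
                        direction=direction,
                        mcid=mcid,
                        n=n_per_trial,
                        truth=truth,
                    ),
                    profile,
                )
            )

    dia_truth = GroundTruth(
        beta0=-4.0, beta_base=0.6, beta_age=0.5, beta_sex=0.3,
        delta=-8.0, gamma_count=gamma_count, sigma=8.0,
    )
    htn_truth = GroundTruth(
        beta0=-10.0, beta_base=0.5, beta_age=1.0, beta_sex=0.5,
        delta=-6.0, gamma_count=gamma_count, sigma=12.0,
    )
    copd_truth = GroundTruth(
        beta0=0.05, beta_base=0.8, beta_age=-0.05, beta_sex=0.02,
        delta=0.12, gamma_count=-gamma_count, sigma=0.3,
    )
    add("DIA", 5, DIABETES_PROFILE, "sglt2_vs_placebo", "hba1c", "higher_worse", 4.0, dia_truth)
    add("HTN", 4, HYPERTENSION_PROFILE, "arb_vs_placebo", "sbp", "higher_worse", 5.0, htn_truth)
    add("CPD", 3, COPD_PROFILE, "laba_vs_placebo", "fev1", "higher_better", 0.1, copd_truth)
    return designs


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all requested stages; returns (and writes) the run manifest.

    Any stage failure writes a FAILED marker naming the stage and re-raises,
    leaving earlier artifacts in place for inspection.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    t0 = time.time()
    artifacts: dict[str, str] = {}
    stage = "configure"
    try:
        designs = list(config.designs) or demo_designs()
        design_map = {d.trial_id: d for d, _ in designs}

        stage = "simulate"
        tables, sim_manifest = generate_program(designs, seed=config.seed)
        trial_dir = out / "trials"
        trial_dir.mkdir(exist_ok=True)
        for trial_id, table in tables.items():
            cio.write_trial_table(table, trial_dir / f"{trial_id}.csv")
            artifacts[f"trials/{trial_id}.csv"] = _sha256(trial_dir / f"{trial_id}.csv")
        cio.write_manifest(sim_manifest, out / "simulation_manifest.json")
        artifacts["simulation_manifest.json"] = _sha256(out / "simulation_manifest.json")

        stage = "stage1"
        exports, failures = [], []
        for ofam in sorted({d.outcome_family for d, _ in designs}):
            sub = {tid: tab for tid, tab in tables.items()
                   if design_map[tid].outcome_family == ofam}
            specs = [AnalysisSpec(family=f, outcome_family=ofam) for f in config.families]
            exp, fails = fit_program(sub, specs, designs=design_map)
            exports.extend(exp)
            failures.extend(fails)
        cio.write_exports(exports, out / "stage1_exports.json")
        artifacts["stage1_exports.json"] = _sha256(out / "stage1_exports.json")
        if failures:
            cio.write_manifest({"failures": failures}, out / "stage1_failures.json")

        stage = "standardize"
        std_exports = [standardize(e, config.registry) for e in exports]
        cio.write_exports(std_exports, out / "standardized_exports.json")
        artifacts["standardized_exports.json"] = _sha256(out / "standardized_exports.json")

        stage = "meta"
        groups: dict[tuple[str, str], list] = {}
        for e in std_exports:
            groups.setdefault((e.indication, e.comparison), []).append(e)
        results: list[MetaResult] = []
        seed_stream = np.random.SeedSequence(config.seed).generate_state(2 * len(groups) + 4)
        gi = 0
        for (ind, comp), grp in sorted(groups.items()):
            for family in config.families:
                labels = INTERACTION_LABELS.get(family)
                if labels is None:
                    continue
                fam_exports = [e for e in grp if e.spec.family == family]
                if not fam_exports:
                    continue
                minput = meta_input_from_exports(fam_exports, labels)
                pool = (
                    pool_ratio_scale
                    if fam_exports[0].family in ("count", "binary")
                    else meta_analyse
                )
                results.append(
                    pool(
                        minput,
                        effects_model="auto",
                        mcmc=config.mcmc,
                        seed=int(seed_stream[gi] % (2**31)),
                        sensitivity=config.sensitivity,
                        threshold=config.effects_threshold,
                    )
                )
                gi += 1
        cio.write_meta_results(results, out / "meta_results.json")
        artifacts["meta_results.json"] = _sha256(out / "meta_results.json")

        stage = "report"
        table = forest_table(results, std_exports)
        table.to_csv(out / "forest_table.csv", index=False)
        artifacts["forest_table.csv"] = _sha256(out / "forest_table.csv")

        prior_payload = None
        count_label = INTERACTION_LABELS["comorbidity_count"][0]
        conditions = {e.indication for e in std_exports if count_label in e.labels}
        if config.fit_priors and len(conditions) >= 2:
            stage = "priors"
            data = [
                GroupEstimate(
                    condition=e.indication,
                    comparison=e.comparison,
                    trial_id=e.trial_id,
                    estimate=e.coef(count_label),
                    se=e.coef_se(count_label),
                )
                for e in std_exports
                if count_label in e.labels and e.family == "continuous"
            ]
            samples = hierarchical_prediction(
                data, seed=int(seed_stream[-1] % (2**31)), mcmc=config.mcmc
            )
            prior, goodness = fit_student_t(samples)
            prior_payload = {"prior": prior.to_dict(), "goodness": goodness}
            (out / "tprior.json").write_text(json.dumps(prior_payload, indent=2) + "\n")
            artifacts["tprior.json"] = _sha256(out / "tprior.json")

        stage = "manifest"
        manifest = {
            "seed": config.seed,
            "families": list(config.families),
            "effects_threshold": config.effects_threshold,
            "sensitivity": config.sensitivity,
            "mcmc": asdict(config.mcmc),
            "n_trials": len(designs),
            "n_groups": len(groups),
            "stage1_failures": len(failures),
            "artifacts": artifacts,
            "tprior": prior_payload,
            "elapsed_s": round(time.time() - t0, 2),
        }
        cio.write_manifest(manifest, out / "run_manifest.json")
        return manifest
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        logger.error("pipeline failed at stage %s: %s", stage, exc)
        raise
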