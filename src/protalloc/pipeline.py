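"""End-to-end analysis pipeline: synthetic data -> utilization -> prediction
-> segmentation -> evolution -> shifts.

A single config (YAML-compatible nested dict) drives all stages.  A global
seed spawns per-stage, per-condition substreams keyed by stage name, so
inserting a stage does not perturb another stage's draws.  All stage
outputs are plain TSV/JSON; a manifest records the seed, a config hash and
the artefacts written.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping, Optional

import numpy as np
import pandas as pd

from . import expression, segmentation, shifts, synthetic, utilization
from .model import Environment, MEModel, apply_turnover, load_model, save_model
from .prediction import PredictionConfig, prediction_report
from .solver import min_protein_demand
from .synthetic import ConditionSpec, StrainSpec, ToyModelConfig, batch_environment

logger = logging.getLogger(__name__)

__all__ = ["default_config", "load_config", "run_pipeline", "stage_seed"]

STAGES = (
    "data",
    "utilization",
    "segmentation",
    "turnover",
    "prediction",
    "shifts",
)


def stage_seed(seed: int, *names: str) -> int:
    """Derive a reproducible sub-seed keyed by stage (and condition) names."""
    key = tuple(zlib.crc32(n.encode()) for n in names)
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=key)
    return int(ss.generate_state(1)[0] % (2**31))


def default_config(seed: int = 0) -> dict:
    """Default synthetic study: 3 carbon / 2 nitrogen toy, 6 conditions.

    The condition panel emulates the structure of the 16-environment
    proteomics design at toy scale: carbon-source batch cultures,
    glucose-analogue-limited chemostats and a stress condition, with
    planted unused fractions rising (and turnover falling) toward slower
    growth.
    """
    return {
        "seed": seed,
        "model": {"synthetic": {}},
        "conditions": [
            {"id": "c1_batch", "carbon": "c1", "unused_fraction": 0.10, "turnover": 1.0},
            {"id": "c2_batch", "carbon": "c2", "unused_fraction": 0.25, "turnover": 0.75},
            {"id": "c3_batch", "carbon": "c3", "unused_fraction": 0.30, "turnover": 0.60},
            {
                "id": "chemostat_010",
                "carbon": "c1",
                "unused_fraction": 0.45,
                "turnover": 0.50,
                "mu": 0.10,
                "kind": "chemostat",
            },
            {
                "id": "chemostat_020",
                "carbon": "c1",
                "unused_fraction": 0.35,
                "turnover": 0.55,
                "mu": 0.20,
                "kind": "chemostat",
            },
            {
                "id": "stress_heat",
                "carbon": "c1",
                "unused_fraction": 0.25,
                "turnover": 0.65,
                "kcat_scale": 0.8,
                "kind": "stress",
            },
        ],
        "proteomics": {"synthetic": {"noise_sd": 0.0}},
        "transcriptomics": {
            "synthetic": {
                "mu_wt": 0.45,
                "unused_fraction_wt": 0.2,
                "strains": [
                    {"id": "ev1", "mu": 0.6, "delta_utilized": 0.10},
                    {"id": "ev2", "mu": 0.6, "delta_utilized": 0.05},
                    {
                        "id": "ev3",
                        "mu": 0.6,
                        "delta_utilized": -0.02,
                        "ribosome_factor": 0.7,
                    },
                ],
            }
        },
        "sampler": {"n_samples": 100, "log10_mean": 1.11, "log10_variance": 1.31},
        "reference_condition": "c1_batch",
        "panel": {"base_sources": {"C": "EX_c1", "N": "EX_n1"}},
        "shifts": {
            "pre_condition": "c2_batch",
            "post_condition": "c1_batch",
            "supplementation": {
                "limit_exchange": "EX_c1",
                "limit_factor": 0.5,
                "supplement": "EX_c2",
                "control_supplement": "EX_n2",
            },
        },
    }


def load_config(path: str | Path) -> dict:
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh)


def _condition_specs(config: Mapping) -> list[ConditionSpec]:
    return [ConditionSpec(**c) for c in config["conditions"]]


def _build_model(config: Mapping) -> MEModel:
    spec = config["model"]
    if "path" in spec:
        return load_model(spec["path"])
    toy = ToyModelConfig(**spec.get("synthetic", {}), seed=config.get("seed", 0))
    return synthetic.make_toy_model(toy)


def _condition_env(model: MEModel, cond: ConditionSpec) -> Environment:
    return batch_environment(model, cond.carbon, cond.nitrogen)


def _json_default(obj: Any):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (frozenset, set)):
        return sorted(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _write_json(payload, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=1, sort_keys=True, default=_json_default) + "\n")


def run_pipeline(config: Mapping, outdir: str | Path) -> dict:
    """Execute all stages; write artefacts under ``outdir``; return the bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    written: list[str] = []
    bundle: dict[str, Any] = {"seed": seed}

    def emit(name: str, payload=None, frame: Optional[pd.DataFrame] = None) -> None:
        path = outdir / name
        if frame is not None:
            frame.to_csv(path, sep="\t")
        else:
            _write_json(payload, path)
        written.append(name)

    # ---- stage: data ---------------------------------------------------
    model = _build_model(config)
    save_model(model, outdir / "model.json")
    written.append("model.json")
    conditions = _condition_specs(config)
    prot_cfg = config.get("proteomics", {})
    if "synthetic" in prot_cfg:
        table, truth = synthetic.make_proteomics(
            model,
            conditions,
            seed=stage_seed(seed, "data", "proteomics"),
            **prot_cfg["synthetic"],
        )
        emit("truth.json", asdict(truth))
    else:
        table = expression.read_abundance_table(
            prot_cfg["path"], prot_cfg.get("growth_rates")
        )
        truth = None
    expression.write_abundance_table(
        table, outdir / "abundance.tsv", outdir / "growth_rates.tsv"
    )
    written += ["abundance.tsv", "growth_rates.tsv"]
    mass_fractions = expression.to_mass_fractions(table)
    emit("mass_fractions.tsv", frame=mass_fractions)
    bundle.update(model=model, abundance=table, truth=truth, mass_fractions=mass_fractions)

    # ---- stage: utilization -------------------------------------------
    sampler_cfg = dict(config.get("sampler", {}))
    scope = frozenset(model.modeled_protein_ids) & set(mass_fractions.index)
    condition_sets: dict[str, list[frozenset[str]]] = {}
    for cond in conditions:
        cmodel = synthetic._condition_model(model, cond)
        env = _condition_env(model, cond)
        sconf = utilization.SamplerConfig(
            seed=stage_seed(seed, "utilization", cond.id), **sampler_cfg
        )
        samples = utilization.sample_kcats(cmodel, sconf)
        condition_sets[cond.id] = utilization.utilized_sets(cmodel, env, samples)
    distributions = utilization.unutilized_distribution(
        mass_fractions, condition_sets, scope
    )
    sample_rows = []
    for cond_id, dist in distributions.items():
        for k in range(len(dist.utilized)):
            sample_rows.append(
                {
                    "condition": cond_id,
                    "sample": k,
                    "utilized_fraction": dist.utilized[k],
                    "unutilized_fraction": dist.unutilized[k],
                }
            )
    emit(
        "utilization_samples.tsv",
        frame=pd.DataFrame(sample_rows).set_index("condition"),
    )
    emit(
        "utilization_summary.json",
        {c: d.summary for c, d in distributions.items()},
    )
    bundle.update(condition_sets=condition_sets, distributions=distributions)

    # ---- stage: segmentation ------------------------------------------
    panel_cfg = config.get("panel", {})
    panel = segmentation.enumerate_environments(
        model, panel_cfg.get("base_sources", {"C": "EX_c1", "N": "EX_n1"})
    )
    segments = segmentation.classify_proteome(model, panel)
    labels = segments.labels()
    emit(
        "segments.tsv",
        frame=pd.DataFrame(
            {"labels": {p: ";".join(v) for p, v in labels.items()}}
        ).rename_axis("protein"),
    )
    seg_masses = segmentation.segment_masses(segments, mass_fractions, condition_sets)
    emit("segment_masses.tsv", frame=seg_masses.masses.rename_axis("condition"))
    growth = table.growth_rates
    trends = {}
    for seg_name in seg_masses.masses.columns:
        try:
            trends[seg_name] = asdict(
                segmentation.growth_trend(seg_masses.masses[seg_name], growth)
            )
        except Exception as exc:  # degenerate panels
            trends[seg_name] = {"error": str(exc)}
    emit("segment_trends.json", trends)
    emit(
        "utilized_noncore.json",
        {c: v for c, v in seg_masses.utilized_noncore.items()},
    )
    bundle.update(panel=panel, segments=segments, segment_masses=seg_masses, trends=trends)

    # ---- stage: turnover ----------------------------------------------
    demands = {}
    for cond in conditions:
        cmodel = synthetic._condition_model(model, cond)
        env = _condition_env(model, cond)
        demands[cond.id] = min_protein_demand(cmodel, env, float(growth[cond.id]))
    turnover = utilization.turnover_ratios(
        demands, mass_fractions, scope=set(segments.core)
    )
    emit("turnover_relative.tsv", frame=turnover.relative.rename_axis("protein"))
    emit("turnover_ratio.tsv", frame=turnover.ratio.rename_axis("protein"))
    emit(
        "turnover_condition_mean.tsv",
        frame=turnover.condition_mean.rename_axis("condition"),
    )
    max_unused = {c: demands[c].max_unused_fraction for c in demands}
    emit("max_unused_fraction.json", max_unused)
    bundle.update(demands=demands, turnover=turnover, max_unused=max_unused)

    # ---- stage: prediction --------------------------------------------
    reference = config.get("reference_condition", conditions[0].id)
    phi_unused = {
        c: float(np.median(d.unutilized)) for c, d in distributions.items()
    }
    rho = {c: float(turnover.condition_mean.loc[c, "mean"]) for c in demands}
    pconf = PredictionConfig(
        reference_condition=reference,
        phi_unused=phi_unused,
        rho=rho,
        mu_measured={c: float(growth[c]) for c in growth.index},
    )
    envs = {cond.id: _condition_env(model, cond) for cond in conditions}
    cond_models = {
        cond.id: synthetic._condition_model(model, cond) for cond in conditions
    }
    # condition-specific modifiers (stress kcat scale) are part of the model
    from .prediction import calibrate_tau, predict_growth

    tau_ref = calibrate_tau(
        cond_models[reference],
        envs[reference],
        pconf.mu_measured[reference],
        phi_unused[reference],
    )
    pred_full: dict[str, float] = {}
    pred_fixed: dict[str, float] = {}
    for cond in conditions:
        cid = cond.id
        tau_c = tau_ref * rho[cid] / rho[reference]
        pred_full[cid] = predict_growth(
            cond_models[cid], envs[cid], phi_unused[cid], tau_c
        )
        pred_fixed[cid] = predict_growth(
            cond_models[cid], envs[cid], phi_unused[reference], tau_ref
        )
    report_full = prediction_report(pred_full, pconf.mu_measured)
    report_fixed = prediction_report(pred_fixed, pconf.mu_measured)
    pred_frame = pd.DataFrame(
        {
            "mu_measured": pd.Series(pconf.mu_measured),
            "mu_predicted": pd.Series(pred_full),
            "mu_predicted_reference_fixed": pd.Series(pred_fixed),
        }
    ).rename_axis("condition")
    emit("predictions.tsv", frame=pred_frame)
    emit(
        "prediction_report.json",
        {
            "tau_ref": tau_ref,
            "per_condition": {
                "pearson_r": report_full.pearson_r,
                "sd_predicted": report_full.sample_sd_predicted,
                "sd_measured": report_full.sample_sd_measured,
            },
            "reference_fixed": {
                "pearson_r": report_fixed.pearson_r,
                "sd_predicted": report_fixed.sample_sd_predicted,
                "sd_measured": report_fixed.sample_sd_measured,
            },
        },
    )
    bundle.update(
        prediction_config=pconf,
        tau_ref=tau_ref,
        predictions=pred_frame,
        report_full=report_full,
        report_fixed=report_fixed,
    )

    # ---- stage: evolution (optional) ----------------------------------
    trans_cfg = config.get("transcriptomics")
    if trans_cfg:
        syn = trans_cfg.get("synthetic")
        ref_env = envs[reference]
        if syn is not None:
            strains = [StrainSpec(**s) for s in syn.get("strains", [])]
            ttable, ttruth = synthetic.make_transcriptomics(
                model,
                ref_env,
                syn.get("mu_wt", 0.45),
                strains,
                unused_fraction_wt=syn.get("unused_fraction_wt", 0.2),
                noise_sd=syn.get("noise_sd", 0.0),
                seed=stage_seed(seed, "evolution", "transcriptomics"),
            )
            emit("transcriptome_truth.json", ttruth)
        else:
            ttable = expression.read_transcriptome_table(
                trans_cfg["path"], trans_cfg.get("growth_rates")
            )
        expression.write_transcriptome_table(ttable, outdir / "fpkm.tsv")
        written.append("fpkm.tsv")
        fractions = expression.transcriptome_fractions(ttable)
        ref_sets = condition_sets[reference]
        deltas = {
            strain: expression.utilized_transcriptome_change(
                fractions["wt"], fractions[strain], ref_sets
            )
            for strain in fractions.columns
            if strain != "wt"
        }
        emit(
            "utilized_transcriptome_change.tsv",
            frame=pd.DataFrame(deltas).rename_axis("sample"),
        )
        strain_demands = {
            strain: min_protein_demand(
                model, ref_env, float(ttable.growth_rates[strain])
            )
            for strain in fractions.columns
        }
        change, medians, _ = expression.evolved_turnover_change(
            fractions, strain_demands, wild_type="wt", scope=set(segments.core)
        )
        emit("turnover_change.tsv", frame=change.rename_axis("protein"))
        emit("turnover_change_median.json", medians.to_dict())
        bundle.update(
            transcriptome=ttable,
            transcriptome_fractions=fractions,
            delta_utilized=deltas,
            turnover_change=change,
            turnover_change_median=medians,
        )

    # ---- stage: shifts -------------------------------------------------
    shift_cfg = config.get("shifts", {})
    by_id = {c.id: c for c in conditions}
    pre_id = shift_cfg.get("pre_condition", conditions[1].id if len(conditions) > 1 else conditions[0].id)
    post_id = shift_cfg.get("post_condition", reference)
    pre_cond, post_cond = by_id[pre_id], by_id[post_id]
    core_scope = frozenset(segments.core)
    mu_pre_meas = float(growth[pre_id])
    shift_out = {}
    tau_pre = rho[pre_id] / rho[reference] * (tau_ref or 1.0)
    tau_post = rho[post_id] / rho[reference] * (tau_ref or 1.0)
    for label, tau in (("turnover_pre_shift", tau_pre), ("turnover_post_shift", tau_post)):
        scenario = shifts.ShiftScenario(
            env_pre=envs[pre_id],
            env_post=envs[post_id],
            turnover_pre=min(tau, 1.0),
            mu_pre=mu_pre_meas,
            constrained_scope=core_scope,
        )
        res = shifts.simulate_upshift(model, scenario)
        shift_out[label] = {
            "tau_pre": min(tau, 1.0),
            "mu_pre": res.mu_pre,
            "mu_instantaneous": res.mu_instantaneous,
            "binding_constraints": res.binding_constraints,
        }
    supp = shift_cfg.get("supplementation")
    if supp:
        base_env = envs[post_id]
        limit_ex = supp["limit_exchange"]
        base_sol_mu = float(growth[post_id])
        bound = supp.get(
            "limit_bound", supp.get("limit_factor", 0.5) * max(base_sol_mu, 0.1)
        )
        for key, ex in (
            ("supplement", supp.get("supplement")),
            ("control_supplement", supp.get("control_supplement")),
        ):
            if ex is None:
                continue
            mu_lim, mu_sup = shifts.simulate_supplementation(
                model, base_env, {limit_ex: bound}, ex
            )
            shift_out[key] = {
                "exchange": ex,
                "mu_limited": mu_lim,
                "mu_supplemented": mu_sup,
                "benefit": mu_sup - mu_lim,
            }
    emit("shifts.json", shift_out)
    bundle["shifts"] = shift_out

    # ---- manifest ------------------------------------------------------
    canonical = json.dumps(config, sort_keys=True, default=_json_default)
    manifest = {
        "seed": seed,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "stages": list(STAGES) + (["evolution"] if trans_cfg else []),
        "outputs": sorted(set(written)),
    }
    _write_json(manifest, outdir / "manifest.json")
    bundle["manifest"] = manifest
    return bundle
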