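"""End-to-end analysis: fit -> predict at quartile means -> CI -> summary.

For every age group x food group the pipeline selects the model variant,
fits the two-part model, predicts intake at the four population meat
quartile means for each sex, attaches parametric-bootstrap intervals, and
summarizes the association with meat consumption as the relative difference
(Q4 - Q1) / (age-sex group mean observed intake).  Everything is driven by
one config and one master seed; reruns with the same config are
bit-identical, and per-food-group RNG substreams keep results independent
of which other food groups are in the batch.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._rng import substream
from .model import FitResult, SeparationError, fit as fit_model
from .prediction import CovariateProfile, predict_intake, relative_difference
from .preprocessing import build_meat_quartiles, descriptive_table, energy_standardize
from .synthetic import RecallDataset
from .uncertainty import bootstrap_ci

__all__ = ["AnalysisConfig", "run_analysis", "validate_dataset"]

log = logging.getLogger("twopart_intake")


@dataclass
class AnalysisConfig:
    """Configuration of one full analysis run."""

    data_csv: str | None = None
    truth_json: str | None = None
    output_dir: str = "results"
    food_groups: list[str] | None = None      # default: all groups in data
    variant: str = "auto"
    quartile_basis: str = "person"
    n_draws: int = 10_000
    n_boot: int = 1000
    nodes: int = 15
    discordant_floor: float = 0.02
    seed: int = 0
    compute_ci: bool = True

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


def validate_dataset(data) -> dict:
    """Schema and consistency checks on a recall table (path or DataFrame).

    Returns a report dict with ``n_rows`` and a list of ``violations``;
    an empty list means the dataset is analysis-ready.
    """
    if not isinstance(data, pd.DataFrame):
        data = pd.read_csv(data)
    violations: list[dict] = []
    missing = set(RecallDataset.COLUMNS) - set(data.columns)
    if missing:
        violations.append({"check": "schema",
                           "detail": f"missing columns {sorted(missing)}"})
        return {"n_rows": len(data), "violations": violations}

    dup = data.duplicated(["participant_id", "day", "food_group"])
    for i in data.index[dup][:20]:
        violations.append({"check": "duplicate_participant_day",
                           "detail": f"row {i}: duplicated participant-day for its food group"})
    neg = data.index[data["grams"] < 0]
    for i in neg[:20]:
        violations.append({"check": "negative_grams", "detail": f"row {i}"})
    bad_kcal = data.index[~(data["kcal"] > 0) | data["kcal"].isna()]
    for i in bad_kcal[:20]:
        violations.append({"check": "nonpositive_energy", "detail": f"row {i}"})
    # covariates must be constant within participant
    for col in ("sex", "age_group"):
        varying = data.groupby("participant_id")[col].nunique()
        for pid in varying.index[varying > 1][:20]:
            violations.append({"check": "covariate_varies_within_participant",
                               "detail": f"participant {pid}: {col}"})
    return {"n_rows": len(data), "violations": violations}


def _fit_with_fallback(sub: pd.DataFrame, cfg: AnalysisConfig) -> FitResult:
    """Fit both parts; on separation, pin the degenerate part and fit the
    other alone rather than aborting the food-group loop."""
    try:
        return fit_model(sub, variant=cfg.variant, nodes=cfg.nodes,
                         discordant_floor=cfg.discordant_floor)
    except SeparationError as exc:
        parts = "amount" if "every recall day" in str(exc) else "probability"
        log.warning("separation: falling back to single-part (%s) fit", parts)
        return fit_model(sub, variant="uncorrelated", parts=parts,
                         nodes=cfg.nodes)


def run_analysis(config: AnalysisConfig,
                 dataset: RecallDataset | None = None) -> dict:
    """Run the full analysis; returns the result bundle and writes it to
    ``config.output_dir`` (fit JSONs per age group, prediction/CI tables,
    relative-difference long table, manifest with seeds and variant
    reasons)."""
    t0 = time.time()
    if dataset is None:
        if config.data_csv is None:
            raise ValueError("config.data_csv is required when no dataset is passed")
        dataset = RecallDataset.from_csv(config.data_csv, config.truth_json)
    data = dataset.data

    report = validate_dataset(data)
    if report["violations"]:
        raise ValueError(f"dataset failed validation: {report['violations'][:5]}")

    food_groups = config.food_groups or dataset.food_groups
    age_groups = list(pd.unique(data["age_group"]))
    quartile_spec, quartile_labels = build_meat_quartiles(
        data, basis=config.quartile_basis)

    # observed mean energy-standardized intake per age-sex group & food group
    obs = data.copy()
    obs["g_per_2000"] = energy_standardize(obs["grams"], obs["kcal"])
    group_means = obs.groupby(["age_group", "sex", "food_group"])["g_per_2000"].mean()

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    fits: dict[tuple[str, str], FitResult] = {}
    pred_rows, ci_rows, rel_rows, failures = [], [], [], []

    for age in age_groups:
        age_dir = out_dir / f"age_{age}"
        age_dir.mkdir(exist_ok=True)
        for fg in food_groups:
            sub = data[(data["age_group"] == age) & (data["food_group"] == fg)]
            t_fg = time.time()
            try:
                res = _fit_with_fallback(sub, config)
            except Exception as exc:  # noqa: BLE001 - batch must continue
                log.error("fit failed for age %s, food group %s: %s", age, fg, exc)
                failures.append({"age_group": age, "food_group": fg,
                                 "error": str(exc)})
                continue
            fits[(age, fg)] = res
            res.to_json(age_dir / f"fit_{fg}.json")
            log.info("age %s / %s: variant=%s converged=%s (%.1fs)",
                     age, fg, res.variant, res.converged, time.time() - t_fg)

            # common random numbers across the 8 profiles of this food group
            rng = substream(config.seed, "predict", str(age), fg)
            std_normals = rng.standard_normal((config.n_draws, 2))
            preds: dict[tuple[int, int], float] = {}
            for sex in (0, 1):
                for q in (1, 2, 3, 4):
                    profile = CovariateProfile(
                        exposure=quartile_spec.quartile_means[q - 1], sex=sex)
                    pred = predict_intake(res, profile, n_draws=config.n_draws,
                                          standard_normals=std_normals)
                    preds[(sex, q)] = pred.intake
                    pred_rows.append({
                        "age_group": age, "food_group": fg, "sex": sex,
                        "meat_quartile": q, "exposure": profile.exposure,
                        "probability": pred.probability, "amount": pred.amount,
                        "intake": pred.intake, "mc_se": pred.mc_se,
                    })
                    if config.compute_ci and res.converged:
                        ci = bootstrap_ci(
                            res, profile, n_boot=config.n_boot,
                            n_draws=config.n_draws,
                            seed=substream(config.seed, "ci", str(age), fg,
                                           sex, q).integers(2**31))
                        ci_rows.append({
                            "age_group": age, "food_group": fg, "sex": sex,
                            "meat_quartile": q, "intake": ci.point,
                            "lower": ci.lower, "upper": ci.upper,
                        })
            for sex in (0, 1):
                gm = group_means.get((age, sex, fg), np.nan)
                rel = (relative_difference(preds[(sex, 4)], preds[(sex, 1)], gm)
                       if gm and gm > 0 else np.nan)
                rel_rows.append({
                    "age_group": age, "food_group": fg, "sex": sex,
                    "intake_q1": preds[(sex, 1)], "intake_q4": preds[(sex, 4)],
                    "group_mean": gm, "relative_difference": rel,
                })

    predictions = pd.DataFrame(pred_rows)
    intervals = pd.DataFrame(ci_rows)
    relative = pd.DataFrame(rel_rows)
    descriptives = descriptive_table(data, quartile_labels)

    predictions.to_csv(out_dir / "predictions.csv", index=False)
    intervals.to_csv(out_dir / "intervals.csv", index=False)
    relative.to_csv(out_dir / "relative_differences.csv", index=False)
    descriptives.to_csv(out_dir / "descriptives.csv", index=False)
    with open(out_dir / "quartiles.json", "w") as fh:
        json.dump({"cutpoints": list(quartile_spec.cutpoints),
                   "quartile_means": list(quartile_spec.quartile_means),
                   "basis": quartile_spec.basis}, fh, indent=1)

    digest = hashlib.sha256()
    for frame in (predictions, intervals, relative, descriptives):
        digest.update(frame.round(10).to_csv(index=False).encode())
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "variants": {f"{age}/{fg}": {"variant": r.variant,
                                     "reason": r.variant_reason,
                                     "parts": r.parts,
                                     "converged": bool(r.converged)}
                     for (age, fg), r in fits.items()},
        "failures": failures,
        "output_hash": digest.hexdigest(),
        "wall_time_s": round(time.time() - t0, 2),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)

    return {"fits": fits, "predictions": predictions, "intervals": intervals,
            "relative_differences": relative, "descriptives": descriptives,
            "quartiles": quartile_spec, "manifest": manifest}
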