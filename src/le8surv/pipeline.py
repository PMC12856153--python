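"""End-to-end orchestration of the study pipeline.

Stage order mirrors the analysis plan: simulate (or ingest) -> LE8
scoring -> endpoint derivation -> rate tables + Kaplan-Meier -> Cox
models (Models 1-3; quartile, linear, penalised spline) -> proportional-
hazards diagnostics -> moderation LRTs -> PAF/PIF -> sensitivity
analyses (2-year landmark, Fine-Gray competing risk).  Each stage writes
CSV artefacts into the output directory and logs progress; a stage
failure aborts downstream stages but preserves earlier outputs.  Every
run emits ``manifest.json`` (config hash, seed, package version).

All p-values are reported raw at the conventional 0.05 threshold; no
multiplicity correction is applied.  Rows missing any LE8 input are
dropped with counts logged (complete-case rule).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortSpec, generate_cohort
from .cox import (
    ModelSpec,
    SplineSpec,
    fine_gray,
    fit_cox,
    fit_cox_pspline,
    hr_curve,
    lrt_interaction,
    schoenfeld_test,
)
from .errors import LE8SurvError, ParameterError
from .impact import COMPONENT_THRESHOLDS, Scenario, component_pif, paf, pif
from .outcomes import (
    ALL_CAUSE_MORTALITY,
    MACE,
    derive_survival,
    km_curve,
    landmark_filter,
    rate_table,
)
from .scoring import COMPONENTS, score_cohort

logger = logging.getLogger("le8surv")

LE8_INPUT_COLUMNS = (
    "smoking_status",
    "bmi_kg_m2",
    "sbp_mmHg",
    "dbp_mmHg",
    "met_min_week",
    "sleep_hours",
    "non_hdl_mmol_l",
    "hba1c_mmol_mol",
)


@dataclass
class RunConfig:
    """Pipeline configuration.

    Either ``cohort_csv``/``diagnoses_csv`` point at ingestable tables,
    or a synthetic cohort of ``n_participants`` is simulated.
    """

    outdir: str = "le8surv_run"
    seed: int = 0
    n_participants: int = 23758
    cohort_csv: str | None = None
    diagnoses_csv: str | None = None
    horizon_years: float = 10.0
    landmark_years: float = 2.0
    endpoints: tuple = ("all_cause_mortality", "mace")
    adjustments: tuple = ("model1", "model2", "model3")
    spline_target_df: float = 4.0
    bootstrap_mode: str = "fast"  # "refit" for reported CIs, "fast" for speed
    bootstrap_reps: int = 200
    fine_gray_max_n: int = 5000  # subsample cap for the competing-risk stage
    moderators: tuple = ("age_group", "female", "multimorbidity")
    plots: bool = False
    verbosity: str = "INFO"

    def validate(self) -> None:
        if not (0 < self.landmark_years < self.horizon_years):
            raise ParameterError("landmark_years must lie in (0, horizon_years)")
        if self.n_participants <= 0:
            raise ParameterError("n_participants must be > 0")
        if self.bootstrap_reps < 100:
            raise ParameterError("bootstrap_reps must be >= 100")


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a dict of artefact paths and
    in-memory results."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "stages_completed": [],
    }
    results: dict = {"outdir": str(outdir)}

    def _finish(stage, err=None):
        if err is None:
            manifest["stages_completed"].append(stage)
        else:
            manifest["failed_stage"] = {"stage": stage, "error": str(err)}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    try:
        stage = "simulate"
        if config.cohort_csv:
            cohort = pd.read_csv(config.cohort_csv)
            diagnoses = pd.read_csv(config.diagnoses_csv)
        else:
            spec = CohortSpec(
                n_participants=config.n_participants,
                seed=config.seed,
                horizon_years=config.horizon_years,
            )
            cohort, diagnoses = generate_cohort(spec)
        n0 = len(cohort)
        complete = cohort.dropna(subset=[c for c in LE8_INPUT_COLUMNS])
        dropped = n0 - len(complete)
        if dropped:
            logger.info("complete-case rule: dropped %d rows missing LE8 inputs", dropped)
        manifest["n_complete_case"] = len(complete)
        manifest["n_dropped_missing"] = dropped
        cohort = complete.reset_index(drop=True)
        cohort.to_csv(outdir / "cohort.csv", index=False)
        diagnoses.to_csv(outdir / "diagnoses.csv", index=False)
        _finish(stage)

        stage = "score"
        scores = score_cohort(cohort)
        scores.to_csv(outdir / "scored.csv", index=False)
        results["scores"] = scores
        _finish(stage)

        baseline = _baseline_table(cohort, scores)
        baseline.to_csv(outdir / "baseline_by_quartile.csv")

        merged_cov = cohort.merge(scores[["id", "composite", "quartile"]], on="id")
        merged_cov["multimorbidity"] = (
            merged_cov[[f"comorb_{c}" for c in (
                "stroke", "mi", "chronic_coronary", "heart_failure",
                "type2_diabetes", "depression")]].sum(axis=1) >= 1
        ).astype(int)
        merged_cov["age_group"] = (
            merged_cov["age_years"] >= merged_cov["age_years"].median()
        ).astype(int)

        endpoint_defs = {"all_cause_mortality": ALL_CAUSE_MORTALITY, "mace": MACE}
        results["fits"] = {}
        results["impact"] = {}
        for ep_name in config.endpoints:
            ep = endpoint_defs[ep_name]
            stage = f"derive_{ep_name}"
            surv = derive_survival(cohort, diagnoses, ep, config.horizon_years)
            data = surv.merge(merged_cov, on="id")
            _finish(stage)

            stage = f"rates_{ep_name}"
            rates = rate_table(data)
            rates.to_csv(outdir / f"rates_{ep_name}.csv", index=False)
            results[f"rates_{ep_name}"] = rates
            km_frames = []
            for q in ("Q1", "Q2", "Q3", "Q4"):
                km = km_curve(data, group=q)
                km["quartile"] = q
                km_frames.append(km)
            pd.concat(km_frames).to_csv(outdir / f"km_{ep_name}.csv", index=False)
            if config.plots:
                from .plots import plot_km_by_quartile

                plot_km_by_quartile(
                    data, outdir / f"km_{ep_name}.png", title=ep_name
                )
            _finish(stage)

            stage = f"cox_{ep_name}"
            fit_rows = []
            for adj in config.adjustments:
                for form in ("quartile", "linear"):
                    mspec = ModelSpec(adjustment=adj, exposure_form=form)
                    fit = fit_cox(data, mspec)
                    summ = fit.summary().reset_index(names="term")
                    summ.insert(0, "model", adj)
                    summ.insert(1, "form", form)
                    fit_rows.append(summ)
                    results["fits"][(ep_name, adj, form)] = fit
            pd.concat(fit_rows).to_csv(outdir / f"cox_{ep_name}.csv", index=False)
            sfit = fit_cox_pspline(
                data,
                spec=SplineSpec(target_df=config.spline_target_df),
                adjustment=ModelSpec(adjustment="model3", exposure_form="none"),
            )
            results["fits"][(ep_name, "model3", "pspline")] = sfit
            curve = hr_curve(sfit)
            curve.to_csv(outdir / f"hr_curve_{ep_name}.csv", index=False)
            if config.plots:
                from .plots import plot_hr_curve

                plot_hr_curve(sfit, outdir / f"hr_curve_{ep_name}.png", title=ep_name)
            meta = {
                "smoothing": sfit.smoothing,
                "effective_df": sfit.effective_df,
                "linear_coef": sfit.linear_coef,
                "se_linear": sfit.se_linear,
                "note": "linear_coef is the least-squares linear trend of the "
                "penalised-spline curve over the sample exposures",
            }
            (outdir / f"spline_meta_{ep_name}.json").write_text(
                json.dumps(meta, indent=2)
            )
            _finish(stage)

            stage = f"diagnostics_{ep_name}"
            zph = schoenfeld_test(data, results["fits"][(ep_name, "model3", "quartile")])
            zph.to_csv(outdir / f"schoenfeld_{ep_name}.csv")
            _finish(stage)

            stage = f"moderation_{ep_name}"
            mod_rows = []
            for mod in config.moderators:
                try:
                    lrt = lrt_interaction(
                        data,
                        moderator=mod,
                        spec=SplineSpec(target_df=config.spline_target_df),
                        adjustment=ModelSpec(adjustment="model2", exposure_form="none"),
                    )
                    mod_rows.append(
                        {
                            "moderator": mod,
                            "chi_square": lrt.chi_square,
                            "df": lrt.df,
                            "p_value": lrt.p_value,
                            "significant_0.05": lrt.p_value < 0.05,
                        }
                    )
                except LE8SurvError as exc:
                    mod_rows.append({"moderator": mod, "error": str(exc)})
            pd.DataFrame(mod_rows).to_csv(
                outdir / f"moderation_{ep_name}.csv", index=False
            )
            _finish(stage)

            stage = f"impact_{ep_name}"
            x = data["composite"].to_numpy()
            paf_res = paf(
                sfit, x, bootstrap=config.bootstrap_mode,
                reps=config.bootstrap_reps, seed=config.seed, refit_data=data,
                spline_spec=SplineSpec(target_df=config.spline_target_df),
            )
            pif_res = pif(
                sfit, x, Scenario(), bootstrap=config.bootstrap_mode,
                reps=config.bootstrap_reps, seed=config.seed, refit_data=data,
                spline_spec=SplineSpec(target_df=config.spline_target_df),
            )
            scored_in = scores[scores["id"].isin(data["id"])]
            comp_rows = []
            for comp in COMPONENTS:
                cres = component_pif(
                    scored_in, sfit, comp,
                    bootstrap="fast", reps=config.bootstrap_reps, seed=config.seed,
                )
                comp_rows.append(
                    {
                        "component": comp,
                        "pif_pct": 100 * cres.estimate,
                        "ci_low_pct": 100 * cres.ci_low,
                        "ci_high_pct": 100 * cres.ci_high,
                        "threshold": COMPONENT_THRESHOLDS[comp],
                        "n_eligible": cres.n_eligible,
                    }
                )
            impact_df = pd.DataFrame(comp_rows).sort_values(
                "pif_pct", ascending=False
            )
            impact_df.to_csv(outdir / f"component_pif_{ep_name}.csv", index=False)
            summary = pd.DataFrame(
                [
                    {"measure": "PAF", "estimate_pct": 100 * paf_res.estimate,
                     "ci_low_pct": 100 * paf_res.ci_low,
                     "ci_high_pct": 100 * paf_res.ci_high,
                     "caveat": paf_res.caveat},
                    {"measure": "PIF", "estimate_pct": 100 * pif_res.estimate,
                     "ci_low_pct": 100 * pif_res.ci_low,
                     "ci_high_pct": 100 * pif_res.ci_high,
                     "caveat": pif_res.caveat},
                ]
            )
            summary.to_csv(outdir / f"impact_{ep_name}.csv", index=False)
            results["impact"][ep_name] = {
                "paf": paf_res, "pif": pif_res, "components": impact_df,
            }
            _finish(stage)

            stage = f"landmark_{ep_name}"
            lm = landmark_filter(data, config.landmark_years, config.horizon_years)
            lm_fit = fit_cox(lm, ModelSpec(adjustment="model3", exposure_form="quartile"))
            lm_fit.summary().to_csv(outdir / f"landmark_cox_{ep_name}.csv")
            results["fits"][(ep_name, "landmark", "quartile")] = lm_fit
            _finish(stage)

        if "mace" in config.endpoints:
            stage = "fine_gray_mace"
            surv = derive_survival(cohort, diagnoses, MACE, config.horizon_years)
            data = surv.merge(merged_cov, on="id")
            if len(data) > config.fine_gray_max_n:
                rng = np.random.default_rng(config.seed)
                data = data.iloc[
                    rng.choice(len(data), config.fine_gray_max_n, replace=False)
                ].reset_index(drop=True)
            fg = fine_gray(data, ModelSpec(exposure_form="quartile", ties="breslow"))
            fg.summary().to_csv(outdir / "fine_gray_mace.csv")
            results["fits"][("mace", "fine_gray", "quartile")] = fg
            _finish(stage)
    except LE8SurvError as exc:
        logger.error("stage %s failed: %s", stage, exc)
        _finish(stage, err=exc)
        raise

    return results


def _baseline_table(cohort: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    """Baseline characteristics by LE8 quartile (means/SDs and percents)."""
    df = cohort.merge(scores[["id", "quartile"]], on="id")
    cont = {
        "age_years": "Baseline age (years)",
        "townsend": "Deprivation index",
        "bmi_kg_m2": "BMI",
        "sbp_mmHg": "SBP",
        "dbp_mmHg": "DBP",
        "met_min_week": "Physical activity (MET-min/week)",
        "hba1c_mmol_mol": "HbA1c (mmol/mol)",
    }
    rows = {}
    g = df.groupby("quartile", observed=False)
    rows["n"] = g.size()
    for col, label in cont.items():
        rows[f"{label}, mean"] = g[col].mean()
        rows[f"{label}, sd"] = g[col].std()
    rows["Female (%)"] = 100 * g["female"].mean()
    for status in ("current", "former", "never"):
        rows[f"Smoking {status} (%)"] = 100 * g["smoking_status"].apply(
            lambda s, status=status: (s == status).mean()
        )
    for med in ("on_antihypertensive", "on_lipid_lowering", "on_glucose_lowering"):
        rows[f"{med} (%)"] = 100 * g[med].mean()
    return pd.DataFrame(rows).T
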