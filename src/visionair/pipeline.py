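"""End-to-end pipeline: generate/ingest -> encode -> select -> explain ->
counterfactual, with seeded determinism and on-disk run artifacts.

Every random operation's seed derives deterministically from the single run
seed, so a rerun of the same config reproduces the data artifacts
byte-for-byte (stage wall times live in the manifest's ``timings`` entry,
which is excluded from the config hash and from determinism comparisons).
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .counterfactual import (
    DEFAULT_STRATA,
    counterfactual_ucva,
    exposure_gradient,
    exposure_subgroup,
    scenario_report,
)
from .metrics import evaluate, reports_to_frame
from .models import default_candidates, fit_candidates, select_best, split_cohort
from .schema import derive_labels, encode_features, load_schema, read_cohort, validate_cohort, write_cohort
from .shapley import beeswarm_export, exact_shap, mean_abs_shap, sampled_shap
from .subgroups import group_contribution_shares, partial_dependence, subgroup_average_explanation, waterfall_export
from .synthetic import generate_cohort, load_generative_spec

__all__ = ["RunConfig", "run_pipeline", "summarize_run", "ALL_STAGES"]

ALL_STAGES = (
    "load",
    "validate",
    "encode",
    "split",
    "fit",
    "select",
    "explain",
    "subgroups",
    "pd",
    "scenario",
    "gradient",
)


class ShapSettings(BaseModel):
    estimator: Literal["sampled", "exact"] = "sampled"
    background_size: int = Field(default=100, ge=1)
    n_permutations: int = Field(default=32, ge=2)
    max_instances: int = Field(default=500, ge=1)
    exact_cutoff: int = Field(default=12, ge=1)


class ScenarioSettings(BaseModel):
    scenarios: dict[str, list[str]] = {
        "no2_only": ["no2"],
        "pm25_only": ["pm25"],
        "both": ["no2", "pm25"],
    }
    quantile: float = Field(default=0.20, gt=0, lt=1)
    t: int = Field(default=500, ge=1)
    n_bins: int = Field(default=20, ge=2)
    gradient_t: int = Field(default=50, ge=1)
    gradient_pollutants: list[str] = ["no2", "pm25"]


class CandidateSettings(BaseModel):
    roster: list[str] = ["gbm", "random_forest", "ridge"]
    hyperparams: dict[str, dict] = {}


class RunConfig(BaseModel):
    """Configuration for a full pipeline run."""

    input_path: str | None = None  # CSV cohort; None -> synthetic generator
    generator: str = "default"
    n: int = Field(default=5000, ge=0)
    seed: int = 0
    split_fraction: float = Field(default=0.8, gt=0, lt=1)
    candidates: CandidateSettings = CandidateSettings()
    shap: ShapSettings = ShapSettings()
    subgroup_strata: list[str] = list(DEFAULT_STRATA)
    pd_features: list[str] = [
        "school_type",
        "parental_myopia",
        "sleep_duration",
        "homework_hour",
        "no2",
        "pm25",
        "ndvi",
    ]
    scenario: ScenarioSettings = ScenarioSettings()
    outdir: str = "visionair_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = self.model_dump()
        payload.pop("outdir", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _stage_seeds(seed: int) -> dict[str, int]:
    names = ("split", "background", "shap", "scenario", "gradient", "generate")
    ss = np.random.SeedSequence(seed)
    return {
        name: int(child.generate_state(1)[0] & 0x7FFFFFFF)
        for name, child in zip(names, ss.spawn(len(names)))
    }


def run_pipeline(config: RunConfig, stages=None) -> dict:
    """Execute the pipeline, writing artifacts to ``config.outdir``.

    Returns the manifest dict. Any stage failure aborts with the stage name;
    artifacts of completed stages are preserved.
    """
    stages = tuple(stages) if stages is not None else ALL_STAGES
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    schema = load_schema()
    seeds = _stage_seeds(config.seed)
    artifacts: list[str] = []
    timings: dict[str, float] = {}
    state: dict = {}

    def emit(name: str, frame: pd.DataFrame) -> None:
        frame.to_csv(outdir / name, index=False)
        artifacts.append(name)

    def stage(name):
        return name in stages

    current = "load"
    try:
        t0 = time.perf_counter()
        if config.input_path is not None:
            table = read_cohort(config.input_path, schema)
        else:
            spec = load_generative_spec(config.generator, n=config.n, seed=seeds["generate"])
            table = generate_cohort(spec)
            state["generative_spec"] = spec
        table = table.set_index(pd.Index(table["id"], name="row_id"), drop=False)
        state["table"] = table
        write_cohort(table.reset_index(drop=True), outdir / "cohort.csv", schema)
        artifacts.append("cohort.csv")
        labels = derive_labels(table)
        state["labels"] = labels
        timings["load"] = time.perf_counter() - t0

        if stage("validate"):
            current = "validate"
            t0 = time.perf_counter()
            report = validate_cohort(table, schema)
            emit("validation.csv", report.to_frame())
            timings["validate"] = time.perf_counter() - t0

        current = "encode"
        t0 = time.perf_counter()
        fm = encode_features(table, schema=schema)
        X, y = fm.X, table["ucva"]
        state["features"] = fm
        timings["encode"] = time.perf_counter() - t0

        current = "split"
        t0 = time.perf_counter()
        train_X, test_X = split_cohort(X, config.split_fraction, seeds["split"])
        y_train, y_test = y.loc[train_X.index], y.loc[test_X.index]
        timings["split"] = time.perf_counter() - t0

        if stage("fit"):
            current = "fit"
            t0 = time.perf_counter()
            roster = [
                c
                for c in default_candidates(
                    categorical_features=fm.categorical,
                    random_state=config.seed,
                    hyperparams=config.candidates.hyperparams,
                )
                if c.name in config.candidates.roster
            ]
            fitted = fit_candidates(train_X, y_train, roster)
            reports = []
            for m in fitted:
                reports.append(evaluate(m, train_X, y_train, split="train", name=m.name))
                reports.append(evaluate(m, test_X, y_test, split="test", name=m.name))
            emit("fit_reports.csv", reports_to_frame(reports))
            state["fitted"] = {m.name: m for m in fitted}
            state["reports"] = reports
            timings["fit"] = time.perf_counter() - t0

        if stage("select") and "fitted" in state:
            current = "select"
            best_name = select_best(state["reports"])
            best = state["fitted"][best_name]
            state["best"] = best
            best_test = next(
                r for r in state["reports"] if r.model == best_name and r.split == "test"
            )
            with open(outdir / "selected_model.json", "w") as fh:
                json.dump({"selected": best_name, "test": best_test.to_dict()}, fh, indent=2, sort_keys=True)
            artifacts.append("selected_model.json")

        if stage("explain") and "best" in state:
            current = "explain"
            t0 = time.perf_counter()
            rng = np.random.default_rng(seeds["background"])
            bg_idx = rng.choice(
                len(train_X), size=min(config.shap.background_size, len(train_X)), replace=False
            )
            background = train_X.iloc[np.sort(bg_idx)]
            inst = X.iloc[: config.shap.max_instances]
            if config.shap.estimator == "exact" and X.shape[1] <= config.shap.exact_cutoff:
                expl = exact_shap(state["best"], inst, background, exact_cutoff=config.shap.exact_cutoff)
            else:
                expl = sampled_shap(
                    state["best"], inst, background,
                    n_permutations=config.shap.n_permutations, seed=seeds["shap"],
                )
            state["explanations"] = expl
            emit("explanations.csv", expl.to_frame())
            emit("global_importance.csv", mean_abs_shap(expl).to_frame())
            emit("beeswarm.csv", beeswarm_export(expl, table.loc[expl.ids, schema.predictors]))
            timings["explain"] = time.perf_counter() - t0

        if stage("subgroups") and "explanations" in state:
            current = "subgroups"
            t0 = time.perf_counter()
            expl = state["explanations"]
            sub_labels = labels.loc[expl.ids]
            sub_frames, share_payload, wf_frames = [], {}, []
            for stratum in config.subgroup_strata:
                if stratum == "all":
                    member_ids = expl.ids
                else:
                    from .counterfactual import stratum_mask

                    member_ids = expl.ids[stratum_mask(sub_labels, stratum).to_numpy()]
                if len(member_ids) == 0:
                    warnings.warn(f"stratum {stratum!r} empty among explained instances")
                    continue
                sub = subgroup_average_explanation(expl, member_ids, label=stratum)
                frame = sub.mean_contribution.rename("mean_contribution").reset_index()
                frame.columns = ["feature", "mean_contribution"]
                frame.insert(0, "subgroup", stratum)
                frame["k"] = sub.k
                frame["phi0"] = sub.phi0
                frame["mean_prediction"] = sub.mean_prediction
                sub_frames.append(frame)
                shares = group_contribution_shares(sub, state["features"].groups)
                share_payload[stratum] = {
                    g: {
                        "share_pct": round(row["share_pct"], 4),
                        "net_contribution": round(row["net_contribution"], 6),
                        "sign": int(row["sign"]),
                    }
                    for g, row in shares.iterrows()
                }
                wf = waterfall_export(sub)
                wf.insert(0, "subgroup", stratum)
                wf_frames.append(wf)
            emit("subgroup_explanations.csv", pd.concat(sub_frames, ignore_index=True))
            emit("waterfall.csv", pd.concat(wf_frames, ignore_index=True))
            with open(outdir / "group_shares.json", "w") as fh:
                json.dump(share_payload, fh, indent=2, sort_keys=True)
            artifacts.append("group_shares.json")
            timings["subgroups"] = time.perf_counter() - t0

        if stage("pd") and "best" in state:
            current = "pd"
            t0 = time.perf_counter()
            fm = state["features"]
            curves = []
            for feat in config.pd_features:
                if feat not in X.columns:
                    continue
                is_cat = feat in fm.categorical
                curve = partial_dependence(state["best"], X, feat, categorical=is_cat)
                curve.insert(0, "feature", feat)
                if is_cat:
                    lv = fm.levels[feat]
                    curve["level"] = [
                        lv[int(v)] if 0 <= int(v) < len(lv) else "missing"
                        for v in curve["value"]
                    ]
                else:
                    curve["level"] = ""
                curves.append(curve)
            emit("pd_curves.csv", pd.concat(curves, ignore_index=True))
            timings["pd"] = time.perf_counter() - t0

        if stage("scenario") and "best" in state:
            current = "scenario"
            t0 = time.perf_counter()
            summaries, hists = [], []
            for name, pols in config.scenario.scenarios.items():
                pool = exposure_subgroup(X, pols, config.scenario.quantile)
                res = counterfactual_ucva(
                    state["best"], X, pols, pool,
                    t=config.scenario.t, seed=seeds["scenario"], scenario=name,
                )
                emit(f"scenario_{name}.csv", res.to_frame())
                rep = scenario_report(res, labels, strata=config.subgroup_strata)
                summary = rep.summary.copy()
                summary.insert(0, "scenario", name)
                summaries.append(summary)
                hist = rep.histograms.copy()
                hist.insert(0, "scenario", name)
                hists.append(hist)
                state.setdefault("scenario_results", {})[name] = res
            emit("scenario_summary.csv", pd.concat(summaries, ignore_index=True))
            emit("scenario_histograms.csv", pd.concat(hists, ignore_index=True))
            timings["scenario"] = time.perf_counter() - t0

        if stage("gradient") and "best" in state:
            current = "gradient"
            t0 = time.perf_counter()
            grads, slopes = [], []
            for pol in config.scenario.gradient_pollutants:
                g, s = exposure_gradient(
                    state["best"], X, pol, labels,
                    n_bins=config.scenario.n_bins,
                    strata=("all", "primary", "senior"),
                    t=config.scenario.gradient_t,
                    seed=seeds["gradient"],
                )
                g.insert(0, "pollutant", pol)
                s.insert(0, "pollutant", pol)
                grads.append(g)
                slopes.append(s)
            emit("gradient.csv", pd.concat(grads, ignore_index=True))
            emit("gradient_slopes.csv", pd.concat(slopes, ignore_index=True))
            timings["gradient"] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    import sklearn

    manifest = {
        "config": config.model_dump(),
        "config_hash": config.config_hash(),
        "versions": {
            "visionair": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "artifacts": sorted(artifacts),
        "timings": {k: round(v, 3) for k, v in timings.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["_state"] = state
    return manifest


def summarize_run(artifact_dir: str | Path) -> str:
    """Human-readable run summary from an artifact directory."""
    outdir = Path(artifact_dir)
    manifest_path = outdir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {outdir}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    lines = [f"visionair run {manifest['config_hash']}"]
    sel_path = outdir / "selected_model.json"
    if sel_path.exists():
        with open(sel_path) as fh:
            sel = json.load(fh)
        t = sel["test"]
        lines.append(
            f"selected model: {sel['selected']} "
            f"(test rmse={t['rmse']:.4f}, rmse_s={t['rmse_s']:.4f}, "
            f"rmse_u={t['rmse_u']:.4f}, d={t['d']:.4f}, n={t['n']})"
        )
    gi_path = outdir / "global_importance.csv"
    if gi_path.exists():
        gi = pd.read_csv(gi_path).head(5)
        lines.append("top features by mean |SHAP|:")
        for _, row in gi.iterrows():
            lines.append(f"  {row['feature']}: {row['mean_abs_shap']:.4f}")
    ss_path = outdir / "scenario_summary.csv"
    if ss_path.exists():
        ss = pd.read_csv(ss_path)
        lines.append("clean-air scenario deltas (chart units):")
        for _, row in ss.iterrows():
            lines.append(
                f"  {row['scenario']:>9s} | {row['stratum']:>13s}: "
                f"{row['mean_baseline']:.4f} -> {row['mean_counterfactual']:.4f} "
                f"(delta {row['mean_delta']:+.4f}, n={int(row['n'])})"
            )
    return "\n".join(lines)
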