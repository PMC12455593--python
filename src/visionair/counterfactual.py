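"""Clean-air counterfactual scenarios by donor-pool resampling.

The donor pool is the lowest-exposure 20% of the cohort (ties included; for
joint scenarios, rows in the lowest 20% of either pollutant's own
marginal). For each individual, the intervened pollutant value(s) are
replaced by uniform draws (with replacement) from donor rows — joint draws
take the (NO2, PM2.5) pair from a single donor row, preserving pollutant
covariance — the model re-predicts, and the counterfactual UCVA is the
average over t iterations. All other features keep their observed values;
the baseline is the model prediction on observed features.

Each individual gets an independent random substream derived from the
global seed and its id, so results are stable under row reordering.

The exposure gradient segments the pollutant into equal-frequency bins and
uses each bin in turn as the donor pool, yielding mean counterfactual UCVA
per bin and stratum plus a least-squares slope of UCVA against the bin-mean
pollutant level.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScenarioResult",
    "ScenarioReport",
    "exposure_subgroup",
    "counterfactual_ucva",
    "scenario_report",
    "exposure_gradient",
    "stratum_mask",
]

DEFAULT_STRATA = ("all", "primary", "senior", "school_myopia", "high_myopia")


def exposure_subgroup(
    table: pd.DataFrame, pollutants: list[str], quantile: float = 0.20
) -> pd.Index:
    """Donor pool: rows at or below each pollutant's empirical quantile.

    Single pollutant: value <= its 20th percentile (ties included). Several
    pollutants: union of each pollutant's own low tail.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    if not pollutants:
        raise ValueError("need at least one pollutant")
    mask = pd.Series(False, index=table.index)
    for pol in pollutants:
        vals = pd.to_numeric(table[pol], errors="coerce")
        cut = vals.quantile(quantile, interpolation="lower")
        mask |= vals <= cut
    pool = table.index[mask]
    if len(pool) == 0:
        raise ValueError("empty donor pool (degenerate pollutant distribution)")
    return pool


@dataclass
class ScenarioResult:
    """Per-individual counterfactual predictions for one scenario."""

    scenario: str
    baseline: pd.Series
    counterfactual: pd.Series
    t: int
    seed: int
    donor_summary: dict = field(default_factory=dict)

    @property
    def delta(self) -> pd.Series:
        return self.counterfactual - self.baseline

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.baseline.index,
                "baseline": self.baseline.to_numpy(),
                "counterfactual": self.counterfactual.to_numpy(),
                "delta": self.delta.to_numpy(),
            }
        )


def _row_seeds(global_seed: int, ids) -> np.ndarray:
    """Stable per-individual substream seeds (order-independent)."""
    return np.array(
        [zlib.crc32(f"{global_seed}:{i}".encode()) & 0x7FFFFFFF for i in ids],
        dtype=np.uint64,
    )


def counterfactual_ucva(
    model,
    X: pd.DataFrame,
    pollutants: list[str],
    donor_pool: pd.Index,
    t: int = 500,
    seed: int = 0,
    scenario: str | None = None,
) -> ScenarioResult:
    """Donor-resampled counterfactual prediction, averaged over t draws."""
    if t < 1:
        raise ValueError("t must be >= 1")
    if len(donor_pool) == 0:
        raise ValueError("donor pool is empty")
    scenario = scenario or "+".join(pollutants)
    baseline = pd.Series(
        np.asarray(model.predict(X), dtype=float), index=X.index, name="baseline"
    )

    present = [p for p in pollutants if p in X.columns]
    absent = [p for p in pollutants if p not in X.columns]
    if absent:
        warnings.warn(
            f"pollutant(s) {absent} not model features; identity result", stacklevel=2
        )
    if not present:
        return ScenarioResult(
            scenario=scenario,
            baseline=baseline,
            counterfactual=baseline.copy(),
            t=t,
            seed=seed,
        )

    donors = X.loc[donor_pool, present].to_numpy(dtype=float)
    n, n_pool = len(X), len(donors)
    # per-individual donor indices: (n, t), one seeded substream per row id
    if n_pool == 1:
        draws = np.zeros((n, 1), dtype=np.int64)
        t_eff = 1  # singleton pool: deterministic, no Monte-Carlo spread
    else:
        seeds = _row_seeds(seed, X.index)
        draws = np.empty((n, t), dtype=np.int64)
        for i, s in enumerate(seeds):
            draws[i] = np.random.default_rng(s).integers(0, n_pool, size=t)
        t_eff = t

    acc = np.zeros(n)
    work = X.copy()
    for j in range(t_eff):
        vals = donors[draws[:, j]]
        for c, pol in enumerate(present):
            work[pol] = vals[:, c]
        acc += np.asarray(model.predict(work), dtype=float)
    counterfactual = pd.Series(acc / t_eff, index=X.index, name="counterfactual")

    donor_summary = {"pool_size": int(n_pool), "pollutants": {}}
    for c, pol in enumerate(present):
        donor_summary["pollutants"][pol] = {
            "cohort_mean": float(X[pol].mean()),
            "cohort_median": float(X[pol].median()),
            "donor_mean": float(donors[:, c].mean()),
            "donor_median": float(np.median(donors[:, c])),
        }
    return ScenarioResult(
        scenario=scenario,
        baseline=baseline,
        counterfactual=counterfactual,
        t=t,
        seed=seed,
        donor_summary=donor_summary,
    )


def stratum_mask(labels: pd.DataFrame, stratum: str) -> pd.Series:
    """Boolean membership for a named stratum of the cohort."""
    if stratum == "all":
        return pd.Series(True, index=labels.index)
    if stratum in ("primary", "senior"):
        return labels["school_level"] == stratum
    if stratum == "school_myopia":
        return labels["myopia_class"] == "school"
    if stratum == "high_myopia":
        return labels["myopia_class"] == "high"
    raise KeyError(f"unknown stratum {stratum!r}")


@dataclass
class ScenarioReport:
    scenario: str
    summary: pd.DataFrame
    histograms: pd.DataFrame


def scenario_report(
    result: ScenarioResult,
    labels: pd.DataFrame,
    strata=DEFAULT_STRATA,
    bin_edges: np.ndarray | None = None,
) -> ScenarioReport:
    """Per-stratum baseline/counterfactual means, deltas, and UCVA histograms."""
    if not labels.index.equals(result.baseline.index):
        labels = labels.loc[result.baseline.index]
    if bin_edges is None:
        bin_edges = np.arange(3.0, 5.4001, 0.1)
    rows, hist_rows = [], []
    for stratum in strata:
        mask = stratum_mask(labels, stratum)
        base = result.baseline[mask]
        cf = result.counterfactual[mask]
        rows.append(
            {
                "stratum": stratum,
                "n": int(mask.sum()),
                "mean_baseline": base.mean(),
                "mean_counterfactual": cf.mean(),
                "mean_delta": (cf - base).mean(),
            }
        )
        h_base, _ = np.histogram(base, bins=bin_edges)
        h_cf, _ = np.histogram(cf, bins=bin_edges)
        hist_rows.append(
            pd.DataFrame(
                {
                    "stratum": stratum,
                    "bin_left": bin_edges[:-1],
                    "bin_right": bin_edges[1:],
                    "baseline_count": h_base,
                    "counterfactual_count": h_cf,
                }
            )
        )
    return ScenarioReport(
        scenario=result.scenario,
        summary=pd.DataFrame(rows),
        histograms=pd.concat(hist_rows, ignore_index=True),
    )


def exposure_gradient(
    model,
    X: pd.DataFrame,
    pollutant: str,
    labels: pd.DataFrame,
    n_bins: int = 20,
    strata=("all", "primary", "senior"),
    t: int = 50,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counterfactual UCVA across an equal-frequency exposure gradient.

    Each of ``n_bins`` quantile bins of the pollutant serves in turn as the
    donor pool; returns (gradient, slopes) where slopes are per-stratum OLS
    slopes of mean counterfactual UCVA on bin-mean pollutant.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    vals = pd.to_numeric(X[pollutant], errors="coerce")
    n_distinct = vals.nunique()
    if n_bins > n_distinct:
        warnings.warn(
            f"n_bins={n_bins} exceeds {n_distinct} distinct values; reducing",
            stacklevel=2,
        )
        n_bins = max(2, n_distinct)
    bins = pd.qcut(vals, q=n_bins, labels=False, duplicates="drop")
    rows = []
    for b in sorted(bins.dropna().unique()):
        pool = X.index[bins == b]
        res = counterfactual_ucva(
            model, X, [pollutant], pool, t=t, seed=seed, scenario=f"{pollutant}_bin{b}"
        )
        bin_mean = float(vals[bins == b].mean())
        for stratum in strata:
            mask = stratum_mask(labels.loc[X.index], stratum)
            rows.append(
                {
                    "bin": int(b),
                    "bin_mean_pollutant": bin_mean,
                    "stratum": stratum,
                    "mean_ucva": float(res.counterfactual[mask].mean()),
                }
            )
    gradient = pd.DataFrame(rows)
    slopes = []
    for stratum in strata:
        sub = gradient[gradient["stratum"] == stratum]
        slope = float(
            np.polyfit(sub["bin_mean_pollutant"], sub["mean_ucva"], deg=1)[0]
        )
        slopes.append({"stratum": stratum, "slope": slope})
    return gradient, pd.DataFrame(slopes)
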