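"""Subgroup-aggregated explanations, contribution shares, waterfall export,
and partial dependence.

A subgroup's average explanation is the per-feature mean of the members'
Shapley contributions; by linearity, the base value plus these means equals
the subgroup's mean model prediction. Contribution shares aggregate the
mean contributions into the Demog / Habit / Environ feature groups: each
group's share is its absolute mean contribution as a percentage of the
total absolute mean contribution, reported with the sign of the group's net
contribution.

Partial dependence is the brute-force marginal: mean prediction over all
rows with one feature pinned to each grid value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .shapley import ExplanationSet, _as_set

__all__ = [
    "SubgroupExplanation",
    "subgroup_average_explanation",
    "group_contribution_shares",
    "waterfall_export",
    "partial_dependence",
]


@dataclass
class SubgroupExplanation:
    """Mean prediction of a subgroup decomposed into feature contributions."""

    label: str
    k: int
    phi0: float
    mean_contribution: pd.Series

    @property
    def mean_prediction(self) -> float:
        """f_bar(D_K) = phi0 + sum of mean contributions."""
        return float(self.phi0 + self.mean_contribution.sum())


def subgroup_average_explanation(
    explanations, membership, label: str = "subgroup"
) -> SubgroupExplanation:
    """Average the per-instance explanations over a subgroup.

    ``membership`` is an iterable of instance ids (or a boolean mask aligned
    with the explanation index). Every member must have an explanation.
    """
    expl: ExplanationSet = _as_set(explanations)
    if isinstance(membership, (pd.Series, np.ndarray)) and getattr(
        membership, "dtype", None
    ) == bool:
        ids = expl.ids[np.asarray(membership)]
    else:
        ids = pd.Index(membership)
    if len(ids) == 0:
        raise ValueError("membership is empty")
    missing = ids.difference(expl.ids)
    if len(missing) > 0:
        raise KeyError(f"members lacking explanations: {list(missing)[:10]}")
    sub = expl.phi.loc[ids]
    return SubgroupExplanation(
        label=label,
        k=len(ids),
        phi0=expl.phi0,
        mean_contribution=sub.mean(axis=0),
    )


def group_contribution_shares(
    sub_expl: SubgroupExplanation, group_map: dict[str, str]
) -> pd.DataFrame:
    """Signed magnitude-shares of the feature groups (percent).

    share(G) = sum_{p in G} |mean contribution p| / total * 100, with the
    sign of the group's summed mean contribution alongside. Absolute shares
    sum to 100.
    """
    contrib = sub_expl.mean_contribution
    unmapped = [f for f in contrib.index if f not in group_map]
    if unmapped:
        raise KeyError(f"features missing from group_map: {unmapped}")
    groups = pd.Series({f: group_map[f] for f in contrib.index})
    abs_by_group = contrib.abs().groupby(groups).sum()
    net_by_group = contrib.groupby(groups).sum()
    total = abs_by_group.sum()
    share = (
        abs_by_group / total * 100.0 if total > 0 else abs_by_group * 0.0
    )
    out = pd.DataFrame(
        {
            "share_pct": share,
            "net_contribution": net_by_group,
            "sign": np.sign(net_by_group).astype(int),
        }
    )
    out.index.name = "group"
    return out


def waterfall_export(sub_expl: SubgroupExplanation) -> pd.DataFrame:
    """Ordered cumulative contribution table for waterfall charts.

    Rows are ordered by descending |mean contribution| starting from the
    base value; the final cumulative value equals the subgroup's mean
    prediction.
    """
    contrib = sub_expl.mean_contribution
    order = contrib.abs().sort_values(ascending=False).index
    rows = [
        {
            "feature": "(base)",
            "contribution": sub_expl.phi0,
            "cumulative": sub_expl.phi0,
            "direction": "base",
        }
    ]
    cum = sub_expl.phi0
    for feat in order:
        c = float(contrib[feat])
        cum += c
        rows.append(
            {
                "feature": feat,
                "contribution": c,
                "cumulative": cum,
                "direction": "up" if c >= 0 else "down",
            }
        )
    return pd.DataFrame(rows)


def partial_dependence(
    model,
    X: pd.DataFrame,
    feature: str,
    grid=None,
    n_points: int = 20,
    percentiles: tuple[float, float] = (0.01, 0.99),
    categorical: bool = False,
) -> pd.DataFrame:
    """Brute-force partial dependence curve with per-point prediction sd.

    Numeric grids default to ``n_points`` equally spaced values between the
    1st and 99th percentiles; categorical grids are the observed level
    codes. Returns a frame (value, mean_prediction, sd_prediction).
    """
    if feature not in X.columns:
        raise KeyError(f"feature {feature!r} not in matrix")
    if grid is None:
        col = X[feature].to_numpy(dtype=float)
        if categorical:
            grid = np.unique(col[~np.isnan(col)])
        else:
            lo, hi = np.nanquantile(col, percentiles)
            grid = np.linspace(lo, hi, n_points)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty grid")
    means, sds = [], []
    work = X.copy()
    for v in grid:
        work[feature] = v
        preds = np.asarray(model.predict(work), dtype=float)
        means.append(preds.mean())
        sds.append(preds.std())
    return pd.DataFrame(
        {"value": grid, "mean_prediction": means, "sd_prediction": sds}
    )
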