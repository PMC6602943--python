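"""Domain scores and the overall AHAH index.

Pipeline: orient each indicator so larger = less healthy, standardise by the
Rankit rank-based inverse-normal transform, average indicators within each
domain with equal weights, rank the domain scores (rank 1 = most
health-promoting), scale ranks to R = rank/N in (0, 1], apply the
exponential transformation

    X = -23 * ln(1 - R * (1 - exp(-100/23)))

which maps R to (0, 100] and puts greater emphasis on the worst-ranked
zones, reducing cancellation between domains, and finally average the three
domain X scores with equal weights into the overall index.  Higher scores
mean LESS healthy throughout; decile 1 is the most health-promoting tenth.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from .errors import ValidationError
from .indicators import (
    DOMAIN_MEMBERS,
    DOMAINS,
    INDICATOR_NAMES,
    SPEC_BY_NAME,
    IndicatorSpec,
    validate_table,
)

__all__ = [
    "orient",
    "rankit",
    "domain_score",
    "exp_transform",
    "ordinal_ranks",
    "decile_from_rank",
    "build_index",
    "construct_index",
    "diagnostics",
    "EXP_SCALE",
    "EXP_RANGE",
]

#: Constants of the exponential rank transform (IMD-2015 style).
EXP_SCALE = 23.0
EXP_RANGE = 100.0
#: 1 - e^(-100/23); X(R) = -23 ln(1 - R * _EXP_COEF).
_EXP_COEF = 1.0 - np.exp(-EXP_RANGE / EXP_SCALE)


def orient(values: pd.Series | np.ndarray, spec: IndicatorSpec) -> pd.Series | np.ndarray:
    """Apply the indicator's health orientation.

    'flip' negates the values (larger raw value was healthier — distance to
    a hazard, green area); 'keep' leaves them unchanged.  After orientation
    a larger value always means less healthy.
    """
    if spec.orientation == "flip":
        return -values
    if spec.orientation == "keep":
        return values
    raise ValidationError(f"unknown orientation '{spec.orientation}' for {spec.name}")


def rankit(values: pd.Series | np.ndarray) -> np.ndarray:
    """Rank-based inverse normal (Rankit) transform.

    score_i = Phi^-1((r_i - 0.5) / n) with ascending average ranks r_i.
    Ties receive average ranks; n = 1 maps to 0.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValidationError("rankit requires a non-empty 1-D input")
    if not np.all(np.isfinite(arr)):
        bad = np.flatnonzero(~np.isfinite(arr))
        labels = (
            [values.index[i] for i in bad[:10]]
            if isinstance(values, pd.Series)
            else bad[:10].tolist()
        )
        raise ValidationError(f"non-finite values at: {labels}")
    ranks = rankdata(arr, method="average")
    return ndtri((ranks - 0.5) / arr.size)


def domain_score(
    scores: pd.DataFrame,
    domain: str,
    weights: Sequence[float] | None = None,
) -> pd.Series:
    """Equal-weight (by default) mean of a domain's Rankit indicator scores."""
    members = DOMAIN_MEMBERS[domain]
    missing = [m for m in members if m not in scores.columns]
    if missing:
        raise ValidationError(f"domain '{domain}' missing indicator(s): {missing}")
    sub = scores[list(members)]
    if weights is None:
        weights = np.ones(len(members))
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (len(members),):
            raise ValidationError(
                f"domain '{domain}' expects {len(members)} weights, got {weights.shape}"
            )
    # divide by the weight sum AFTER the dot product: equal weights then
    # reduce to an exact mean (sum/n), avoiding 1/n rounding artefacts
    return pd.Series(sub.to_numpy() @ weights / weights.sum(), index=sub.index)


def exp_transform(R: float | np.ndarray) -> float | np.ndarray:
    """Exponential rank transform X = -23 ln(1 - R(1 - e^(-100/23))).

    Strictly increasing on (0, 1]; X(1) = 100 exactly (analytically
    -23 ln(e^(-100/23))); X -> 0 as R -> 0.
    """
    arr = np.asarray(R, dtype=float)
    if np.any((arr <= 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValidationError(f"rank fraction outside (0, 1]: {arr[(arr <= 0) | (arr > 1)][:5]}")
    out = -EXP_SCALE * np.log1p(-arr * _EXP_COEF)
    return float(out) if np.isscalar(R) else out


def ordinal_ranks(scores: pd.Series) -> pd.Series:
    """Ascending ordinal ranks 1..N, ties broken by zone_code.

    Ordinal ranking keeps every R = rank/N distinct so deciles partition
    exactly; rank 1 = lowest score = most health-promoting.
    """
    df = pd.DataFrame({"score": scores.to_numpy(), "zone_code": scores.index})
    df = df.sort_values(["score", "zone_code"], kind="mergesort")
    ranks = pd.Series(
        np.arange(1, len(df) + 1), index=df["zone_code"].to_numpy()
    )
    return ranks.reindex(scores.index)


def decile_from_rank(rank: np.ndarray | pd.Series, n: int) -> np.ndarray | pd.Series:
    """Decile 1..10 from ordinal rank; sizes differ by at most one zone."""
    return ((np.asarray(rank) - 1) * 10) // n + 1


def build_index(
    domain_X: pd.DataFrame,
    weights: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Combine the three domain X scores into the overall index.

    index_score = equal-weight mean of the domain X values; index rank and
    deciles follow the same ascending ordinal convention (decile 1 = most
    health-promoting).
    """
    missing = [d for d in DOMAINS if f"{d}_X" not in domain_X.columns]
    if missing:
        raise ValidationError(f"missing domain X column(s): {missing}")
    if domain_X[[f"{d}_X" for d in DOMAINS]].isna().any().any():
        bad = domain_X.index[domain_X.isna().any(axis=1)][:5].tolist()
        raise ValidationError(f"missing domain score for zones: {bad}")
    if weights is None:
        weights = np.ones(len(DOMAINS))
    else:
        weights = np.asarray(weights, dtype=float)
    n = len(domain_X)
    out = domain_X.copy()
    out["index_score"] = (
        out[[f"{d}_X" for d in DOMAINS]].to_numpy() @ weights / weights.sum()
    )
    out["index_rank"] = ordinal_ranks(out["index_score"])
    out["index_decile"] = decile_from_rank(out["index_rank"], n)
    return out


def construct_index(
    table: pd.DataFrame,
    indicator_weights: Mapping[str, Sequence[float]] | None = None,
    domain_weights: Sequence[float] | None = None,
) -> "AHAHResult":
    """Run the full index construction on a zone x 14 indicator table."""
    validate_table(table)
    n = len(table)

    oriented = pd.DataFrame(
        {name: orient(table[name], SPEC_BY_NAME[name]) for name in INDICATOR_NAMES},
        index=table.index,
    )
    rankit_scores = pd.DataFrame(
        {name: rankit(oriented[name]) for name in INDICATOR_NAMES},
        index=table.index,
    )

    domains = pd.DataFrame(index=table.index)
    for d in DOMAINS:
        w = None if indicator_weights is None else indicator_weights.get(d)
        std = domain_score(rankit_scores, d, w)
        rank = ordinal_ranks(std)
        R = rank / n
        domains[f"{d}_std"] = std
        domains[f"{d}_rank"] = rank
        domains[f"{d}_R"] = R
        domains[f"{d}_X"] = exp_transform(R.to_numpy())
        domains[f"{d}_decile"] = decile_from_rank(rank, n)

    index_df = build_index(
        domains[[f"{d}_X" for d in DOMAINS]].copy(), domain_weights
    )
    domains["index_score"] = index_df["index_score"]
    domains["index_rank"] = index_df["index_rank"]
    domains["index_decile"] = index_df["index_decile"]

    # component deciles on ORIENTED values: decile 1 = most health-promoting
    comp_deciles = pd.DataFrame(index=table.index)
    for name in INDICATOR_NAMES:
        comp_deciles[f"{name}_decile"] = decile_from_rank(
            ordinal_ranks(oriented[name]), n
        )

    return AHAHResult(
        table=table,
        oriented=oriented,
        rankit_scores=rankit_scores,
        domains=domains,
        component_deciles=comp_deciles,
    )


class AHAHResult:
    """Outputs of the index construction.

    Attributes
    ----------
    table : the raw zone x 14 indicator table.
    oriented, rankit_scores : intermediate per-indicator frames.
    domains : per-zone domain std/rank/R/X/decile columns plus
        index_score/index_rank/index_decile.
    component_deciles : per-indicator deciles (oriented; 1 = healthiest).
    """

    def __init__(self, table, oriented, rankit_scores, domains, component_deciles):
        self.table = table
        self.oriented = oriented
        self.rankit_scores = rankit_scores
        self.domains = domains
        self.component_deciles = component_deciles

    def index_frame(self) -> pd.DataFrame:
        """The ``ahah_index.csv`` layout (scores increase with unhealthiness)."""
        d = self.domains
        out = pd.DataFrame(index=d.index)
        out["index_score"] = d["index_score"]
        out["index_rank"] = d["index_rank"].astype(int)
        out["index_decile"] = d["index_decile"].astype(int)
        for dom in DOMAINS:
            out[f"{dom}_X"] = d[f"{dom}_X"]
            out[f"{dom}_decile"] = d[f"{dom}_decile"].astype(int)
        return out

    def components_frame(self) -> pd.DataFrame:
        """The ``ahah_components.csv`` layout: 14 measures + 14 deciles."""
        return pd.concat([self.table, self.component_deciles], axis=1)


def diagnostics(
    table: pd.DataFrame,
    result: "AHAHResult | None" = None,
    method: str = "pearson",
) -> pd.DataFrame:
    """Pairwise correlations of the 14 raw indicators.

    Returns the 14x14 correlation matrix (product-moment or rank); if a
    result is supplied, appends an ``index_score`` row/column correlating
    each domain X and the overall index.  Zero-variance columns yield NaN
    cells which writers render as an explicit 'undefined' marker.
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation method '{method}'")
    frame = table.copy()
    if result is not None:
        for dom in DOMAINS:
            frame[f"{dom}_X"] = result.domains[f"{dom}_X"]
        frame["index_score"] = result.domains["index_score"]
    return frame.corr(method=method)
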