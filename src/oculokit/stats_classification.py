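"""Group-level statistics, the >2 SD impairment classifier and ROC
cut-off analysis.

Group comparisons use ordinary least squares on per-trial rows with age
as a covariate and standard errors clustered by participant (repeated
trials per participant are correlated).  Pearson correlations use a
Bonferroni family correction; effect sizes are Cohen's d with pooled
(n-1) SD.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf

__all__ = [
    "GroupModelSpec",
    "GroupModelResult",
    "ROCResult",
    "fit_group_model",
    "interaction_test",
    "pairwise_correlations",
    "cohens_d",
    "classify_impairment",
    "multi_metric_impairment_rate",
    "roc_best_cutoff",
    "WORSE_DIRECTION",
]


# Which side of the control distribution counts as impaired, per metric.
WORSE_DIRECTION: dict[str, str] = {
    "swj_count": "higher",
    "large_intrusive_saccades": "higher",
    "longest_fixation_ms": "lower",
    "time_to_target_ms": "higher",
    "latency_ms": "higher",
    "amplitude_error_deg": "lower",   # more negative = more hypometric
    "peak_velocity": "higher",
    "n_saccades": "higher",
    "pursuit_gain": "lower",
    "pursuit_saccades": "higher",
}


@dataclass
class GroupModelSpec:
    metric_name: str
    covariates: tuple[str, ...] = ("age",)
    factors: tuple[str, ...] = ()            # categorical independent variables
    interactions: tuple[tuple[str, str], ...] = ()
    transform: str = "none"                  # none | sqrt
    cluster_col: str | None = "participant_id"


@dataclass
class GroupModelResult:
    spec: GroupModelSpec
    contrasts: pd.DataFrame     # pair, estimate, se, p
    model: object = field(repr=False, default=None)
    interaction_pvalue: float | None = None
    interaction_contrasts: pd.DataFrame | None = None


@dataclass
class ROCResult:
    metric_name: str
    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float
    direction: str  # 'greater' -> positive class flagged above cutoff


def _build_formula(spec: GroupModelSpec) -> str:
    terms = ["C(group)"]
    terms += [f"C({f})" for f in spec.factors]
    terms += list(spec.covariates)
    for a, b in spec.interactions:
        fa = f"C({a})" if a in ("group",) + tuple(spec.factors) else a
        fb = f"C({b})" if b in ("group",) + tuple(spec.factors) else b
        terms.append(f"{fa}:{fb}")
    return "value ~ " + " + ".join(terms)


def _prepare(rows: pd.DataFrame, spec: GroupModelSpec) -> pd.DataFrame:
    df = rows[rows["metric_name"] == spec.metric_name].copy() if "metric_name" in rows else rows.copy()
    df = df.dropna(subset=["value"])
    if spec.transform == "sqrt":
        if (df["value"] < 0).any():
            raise ValueError("negative values cannot be square-root transformed")
        df["value"] = np.sqrt(df["value"])
    elif spec.transform != "none":
        raise ValueError(f"unknown transform {spec.transform!r}")
    groups = df["group"].unique()
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    counts = df.groupby("group")["value"].count()
    small = counts[counts < 3]
    if len(small):
        raise ValueError(f"groups with fewer than 3 observations: {list(small.index)}")
    return df


def _check_rank(model) -> None:
    exog = model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # name the dependent columns via QR pivoting
        _, r = np.linalg.qr(exog)
        diag = np.abs(np.diag(r))
        tol = diag.max() * 1e-10 if diag.size else 0.0
        bad = [model.exog_names[i] for i in np.flatnonzero(diag <= tol)]
        raise ValueError(f"rank-deficient design; collinear term(s): {bad}")


def _fit(df: pd.DataFrame, formula: str, spec: GroupModelSpec):
    model = smf.ols(formula, data=df)
    _check_rank(model)
    if spec.cluster_col and spec.cluster_col in df and df[spec.cluster_col].nunique() > 1:
        # t-based inference: z-based cluster p-values are anti-conservative
        # at realistic participant counts
        return model.fit(
            cov_type="cluster", cov_kwds={"groups": df[spec.cluster_col]}, use_t=True
        )
    return model.fit()


def _pairwise_group_contrasts(res, df: pd.DataFrame, term: str = "group") -> pd.DataFrame:
    """Pairwise contrasts between levels of a treatment-coded factor."""
    levels = sorted(df[term].unique())
    names = res.model.exog_names
    rows = []
    for g1, g2 in itertools.combinations(levels, 2):
        vec = np.zeros(len(names))
        for g, sign in ((g1, 1.0), (g2, -1.0)):
            col = f"C({term})[T.{g}]"
            if col in names:
                vec[names.index(col)] += sign
            # reference level contributes 0
        tt = res.t_test(vec)
        rows.append({
            "pair": f"{g1} - {g2}",
            "estimate": float(np.atleast_1d(tt.effect)[0]),
            "se": float(np.atleast_1d(tt.sd).ravel()[0]),
            "p": float(np.atleast_1d(tt.pvalue).ravel()[0]),
        })
    return pd.DataFrame(rows)


def fit_group_model(rows: pd.DataFrame, spec: GroupModelSpec) -> GroupModelResult:
    """Linear model of (transformed) metric on group + covariates.

    ``rows`` is a long-format table with at least ``group``, ``value`` and
    the covariate columns.  Returns pairwise group contrasts with
    cluster-robust p-values.
    """
    df = _prepare(rows, spec)
    res = _fit(df, _build_formula(spec), spec)
    contrasts = _pairwise_group_contrasts(res, df)
    return GroupModelResult(spec=spec, contrasts=contrasts, model=res)


def interaction_test(
    rows: pd.DataFrame,
    spec: GroupModelSpec,
    factors: tuple[str, str] = ("group", "condition"),
) -> GroupModelResult:
    """Group model plus an interaction term, with a Wald test on the
    interaction block and post hoc pairwise interaction contrasts."""
    a, b = factors
    df = _prepare(rows, spec)
    cells = df.groupby([a, b]).size().unstack(b)
    if cells.isna().any().any() or (cells == 0).any().any():
        missing = [
            (ia, ib)
            for ia in cells.index
            for ib in cells.columns
            if pd.isna(cells.loc[ia, ib]) or cells.loc[ia, ib] == 0
        ]
        raise ValueError(f"empty design cell(s): {missing}")
    ispec = GroupModelSpec(
        metric_name=spec.metric_name,
        covariates=spec.covariates,
        factors=tuple(f for f in dict.fromkeys(list(spec.factors) + [b]) if f != "group"),
        interactions=spec.interactions + ((a, b),),
        transform=spec.transform,
        cluster_col=spec.cluster_col,
    )
    res = _fit(df, _build_formula(ispec), ispec)
    names = res.model.exog_names
    inter_cols = [n for n in names if ":" in n]
    wald = res.wald_test(
        np.eye(len(names))[[names.index(c) for c in inter_cols]], scalar=True
    )
    # post hoc: pairwise difference-of-differences between group levels
    blevels = sorted(df[b].unique())
    glevels = sorted(df[a].unique())
    rows_out = []
    if len(blevels) == 2:
        for g1, g2 in itertools.combinations(glevels, 2):
            vec = np.zeros(len(names))
            for g, sign in ((g1, 1.0), (g2, -1.0)):
                col = f"C({a})[T.{g}]:C({b})[T.{blevels[1]}]"
                if col in names:
                    vec[names.index(col)] += sign
            if not vec.any():
                continue
            tt = res.t_test(vec)
            rows_out.append({
                "pair": f"{g1} - {g2}",
                "estimate": float(np.atleast_1d(tt.effect)[0]),
                "se": float(np.atleast_1d(tt.sd).ravel()[0]),
                "p": float(np.atleast_1d(tt.pvalue).ravel()[0]),
            })
    return GroupModelResult(
        spec=ispec,
        contrasts=_pairwise_group_contrasts(res, df),
        model=res,
        interaction_pvalue=float(wald.pvalue),
        interaction_contrasts=pd.DataFrame(rows_out),
    )


def pairwise_correlations(
    metrics: pd.DataFrame,
    scores: pd.DataFrame,
    n_tests: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson r between every metric column and every score column.

    Inputs are wide per-participant frames sharing an index.  The
    Bonferroni factor defaults to the number of tests in the family
    (metrics x scores) but may be overridden to widen the family.
    Zero-variance columns yield missing r.
    """
    common = metrics.index.intersection(scores.index)
    m = metrics.loc[common]
    s = scores.loc[common]
    pairs = [(mc, sc) for mc in m.columns for sc in s.columns]
    if n_tests is None:
        n_tests = len(pairs)
    out = []
    for mc, sc in pairs:
        paired = pd.concat([m[mc], s[sc]], axis=1).dropna()
        x, y = paired.iloc[:, 0].to_numpy(), paired.iloc[:, 1].to_numpy()
        if len(paired) < 4 or x.std() == 0 or y.std() == 0:
            r, p = math.nan, math.nan
        else:
            r, p = scipy.stats.pearsonr(x, y)
        p_adj = min(1.0, p * n_tests) if math.isfinite(p) else math.nan
        out.append({
            "metric": mc,
            "score": sc,
            "n": len(paired),
            "r": r,
            "p": p,
            "p_bonferroni": p_adj,
            "significant": bool(p_adj < alpha) if math.isfinite(p_adj) else False,
        })
    return pd.DataFrame(out)


def cohens_d(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Standardized mean difference (a - b) / pooled SD (n-1 pooling).

    Returns NaN when the pooled SD is zero.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        return math.nan
    return float((a.mean() - b.mean()) / math.sqrt(pooled_var))


def classify_impairment(
    participant_metrics: Mapping[str, float],
    control_stats: Mapping[str, tuple[float, float]],
    direction_registry: Mapping[str, str] | None = None,
) -> dict[str, bool]:
    """Flag metrics more than 2 SD worse than control performance.

    ``control_stats`` maps metric -> (mean, SD); the registry declares the
    "worse" side per metric.  The 2 SD bound is strict: a score exactly at
    it is not impaired.  Missing values are never flagged.
    """
    directions = dict(WORSE_DIRECTION if direction_registry is None else direction_registry)
    flags: dict[str, bool] = {}
    for metric, score in participant_metrics.items():
        if metric not in control_stats:
            raise KeyError(f"no control statistics for metric {metric!r}")
        if metric not in directions:
            raise KeyError(f"no worse-direction registered for metric {metric!r}")
        mean, sd = control_stats[metric]
        if score is None or not math.isfinite(score):
            flags[metric] = False
        elif directions[metric] == "higher":
            flags[metric] = score > mean + 2.0 * sd
        elif directions[metric] == "lower":
            flags[metric] = score < mean - 2.0 * sd
        else:
            raise ValueError(f"direction must be 'higher' or 'lower', got {directions[metric]!r}")
    return flags


def multi_metric_impairment_rate(
    flags: pd.DataFrame, metric_family: Sequence[str] | None = None
) -> float:
    """Fraction of participants (rows) impaired on more than one metric
    of the given family (columns)."""
    fam = flags if metric_family is None else flags[list(metric_family)]
    if fam.shape[0] == 0:
        raise ValueError("no participants supplied")
    return float((fam.sum(axis=1) > 1).mean())


def roc_best_cutoff(
    scores: Sequence[float],
    labels: Sequence[bool],
    metric_name: str = "",
) -> ROCResult:
    """Accuracy-maximizing cut-off over all candidate thresholds.

    Candidates are midpoints between adjacent sorted unique scores plus
    -inf/+inf; both directions (positive class above or below cutoff) are
    evaluated.  Ties in accuracy break towards higher sensitivity, then
    towards the 'greater' direction for determinism.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must align")
    finite = np.isfinite(s)
    s, y = s[finite], y[finite]
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be non-empty")
    uniq = np.unique(s)
    cuts = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]))
    best: ROCResult | None = None
    for direction in ("greater", "less"):
        for c in cuts:
            pred = s > c if direction == "greater" else s < c
            tp = int((pred & y).sum())
            tn = int((~pred & ~y).sum())
            sens = tp / n_pos
            spec = tn / n_neg
            acc = (tp + tn) / (n_pos + n_neg)
            cand = ROCResult(
                metric_name=metric_name,
                cutoff=float(c),
                sensitivity=sens,
                specificity=spec,
                accuracy=acc,
                direction=direction,
            )
            if (
                best is None
                or acc > best.accuracy + 1e-12
                or (abs(acc - best.accuracy) <= 1e-12 and sens > best.sensitivity + 1e-12)
            ):
                best = cand
    return best
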