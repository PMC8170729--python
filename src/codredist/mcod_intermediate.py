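"""Redistribution proportions for intermediate-cause garbage from
multiple-cause-of-death data.

Intermediate causes (sepsis, heart failure, acute kidney injury, ...) sit in
the causal chain between the true underlying cause and death, and are
frequently miscoded as the underlying cause.  Certificates that *do* carry a
valid underlying cause reveal how often each underlying cause involves the
intermediate cause, which is enough to rebuild a plausible target
distribution for the miscoded deaths:

1. tag certificates with a non-garbage underlying cause for presence of the
   intermediate cause's codes (Part I only for sepsis, Parts I and II for
   the others) and aggregate to per-stratum fractions;
2. trim the target-cause list -- keep the causes covering 80% of
   intermediate-cause-related deaths, then let an L1-penalised regression on
   the remaining causes' indicators decide which of the tail causes carry a
   real signal;
3. fit a binomial-logit fraction model
   ``logit(pi) = b0 + b1*X + b_age + b_sex + gamma_cause``
   with a per-cause random intercept (approximated here by shrunken fixed
   effects -- see :func:`fit_fraction_model`);
4. convert predicted fractions to redistribution proportions by scaling with
   an external cause-specific death envelope and normalising per stratum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold

from ._util import DEFAULT_AGE_GROUPS, STRATUM_COLS, expit
from .causemap import CauseHierarchy, normalize_code, resolve_code
from .datamodel import MultiCauseRecord
from .proportions import ProportionPackage

__all__ = [
    "IntermediateCauseSpec",
    "FractionModel",
    "tag_and_aggregate",
    "trim_targets",
    "fit_fraction_model",
    "build_proportions",
]

AGG_COLS = ["cause_id"] + STRATUM_COLS


@dataclass(frozen=True)
class IntermediateCauseSpec:
    """Which codes flag an intermediate cause and how certificates are read.

    ``include_part2`` is False for sepsis-style causes where only the causal
    chain (Part I) counts, True when Part II contributing conditions count
    as presence too.
    """

    name: str
    code_set: frozenset[str]
    include_part2: bool = True
    covariates: tuple[str, ...] = ("haq",)

    def __post_init__(self):
        if not self.code_set:
            raise ValueError(f"spec {self.name!r} has an empty code set")
        object.__setattr__(self, "code_set", frozenset(normalize_code(c) for c in self.code_set))


def tag_and_aggregate(
    records: Sequence[MultiCauseRecord],
    spec: IntermediateCauseSpec,
    hierarchy: CauseHierarchy,
) -> pd.DataFrame:
    """Per (underlying cause, age, sex, location, year): total certificates
    and certificates tagged with the intermediate cause.

    Certificates whose underlying code resolves to garbage are excluded --
    they carry no usable underlying-cause label.
    """
    rows = []
    for r in records:
        res = resolve_code(r.underlying_code, hierarchy, unknown="residual")
        if res.is_garbage:
            continue
        codes = {normalize_code(c) for c in r.part1_codes}
        if spec.include_part2:
            codes |= {normalize_code(c) for c in r.part2_codes}
        tagged = bool(codes & spec.code_set)
        rows.append((res.dest, r.location, r.year, r.age_group, r.sex, 1, int(tagged)))
    if not rows:
        warnings.warn(f"no eligible certificates for intermediate cause {spec.name!r}")
        return pd.DataFrame(columns=AGG_COLS + ["n_deaths", "n_with_intermediate", "fraction"])
    df = pd.DataFrame(rows, columns=AGG_COLS + ["n", "tagged"])
    agg = df.groupby(AGG_COLS, as_index=False).sum()
    agg = agg.rename(columns={"n": "n_deaths", "tagged": "n_with_intermediate"})
    agg["fraction"] = agg["n_with_intermediate"] / agg["n_deaths"]
    return agg


# ---------------------------------------------------------------------------
# target trimming


def _weighted_cv_lasso(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    n_folds: int = 10,
    rule: str = "1se",
    seed: int = 0,
    n_alphas: int = 60,
) -> np.ndarray:
    """Lasso coefficients at a cross-validated penalty.

    Columns are standardised to unit weighted variance before penalisation
    (so rare-cause indicators are not over-penalised relative to common
    ones) and coefficients are returned on the original scale.  The penalty
    grid runs from the smallest all-zero penalty down three decades; fold
    errors are weighted mean squared errors (weights reflect binomial
    precision).  ``rule="min"`` takes the error-minimising penalty;
    ``rule="1se"`` (default, the glmnet convention) takes the largest
    penalty within one standard error of the minimum, which guards against
    retaining noise causes.
    """
    w = np.asarray(w, float)
    wn = w / w.sum()
    xbar = wn @ X
    sd = np.sqrt(wn @ (X - xbar) ** 2)
    sd[sd == 0] = 1.0
    Xs = X / sd
    ybar = float(wn @ y)
    alpha_max = float(np.max(np.abs((Xs - xbar / sd).T @ (w * (y - ybar)))) / w.sum())
    if alpha_max <= 0:
        return np.zeros(X.shape[1])
    alphas = alpha_max * np.logspace(0, -3, n_alphas)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    mse = np.zeros((n_alphas, n_folds))
    for k, (tr, te) in enumerate(kf.split(Xs)):
        las = Lasso(alpha=1.0, warm_start=True, max_iter=10_000)
        for i, a in enumerate(alphas):
            las.set_params(alpha=a)
            las.fit(Xs[tr], y[tr], sample_weight=w[tr])
            r = y[te] - las.predict(Xs[te])
            mse[i, k] = float(np.sum(w[te] * r * r) / np.sum(w[te]))
    mean = mse.mean(axis=1)
    i_min = int(np.argmin(mean))
    if rule == "min":
        i_sel = i_min
    else:
        se = mse.std(axis=1, ddof=1) / np.sqrt(n_folds)
        i_sel = int(np.where(mean <= mean[i_min] + se[i_min])[0].min())
    fit = Lasso(alpha=alphas[i_sel], max_iter=10_000).fit(Xs, y, sample_weight=w)
    return fit.coef_ / sd


def trim_targets(
    agg: pd.DataFrame,
    lasso_folds: int = 10,
    keep_fraction: float = 0.8,
    rule: str = "1se",
    seed: int = 0,
) -> set[str]:
    """Two-step target selection.

    Step 1 ranks underlying causes by intermediate-cause-related deaths and
    keeps the smallest prefix covering ``keep_fraction`` of them (ties with
    the marginal cause are all included).  Step 2 regresses the stratum
    fractions on indicator columns for the remaining tail causes with an L1
    penalty; tail causes with a non-zero coefficient at the cross-validated
    penalty are added back.
    """
    if len(agg) == 0:
        raise ValueError("cannot trim targets from an empty aggregate")
    by_cause = (
        agg.groupby("cause_id")["n_with_intermediate"]
        .sum()
        .sort_values(ascending=False, kind="stable")
    )
    total = float(by_cause.sum())
    if total <= 0:
        warnings.warn("no intermediate-cause-related deaths; keeping all causes")
        return set(by_cause.index)
    cum = by_cause.cumsum() / total
    n_keep = int(np.searchsorted(cum.to_numpy(), keep_fraction) + 1)
    n_keep = min(n_keep, len(by_cause))
    marginal = by_cause.iloc[n_keep - 1]
    keep = set(by_cause.index[by_cause >= marginal])  # include ties with the marginal cause
    bottom = [c for c in by_cause.index if c not in keep]
    if not bottom:
        return keep

    X = np.column_stack([(agg["cause_id"] == c).to_numpy(float) for c in bottom])
    y = agg["fraction"].to_numpy(float)
    w = agg["n_deaths"].to_numpy(float)
    folds = min(lasso_folds, len(agg))
    if folds < lasso_folds:
        warnings.warn(f"only {len(agg)} strata; reducing CV folds to {folds}")
    if folds < 2:
        warnings.warn("not enough strata for cross-validation; skipping LASSO step")
        return keep
    coefs = _weighted_cv_lasso(X, y, w, n_folds=folds, rule=rule, seed=seed)
    keep |= {c for c, b in zip(bottom, coefs) if abs(b) > 1e-10}
    return keep


# ---------------------------------------------------------------------------
# binomial fraction model


@dataclass
class FractionModel:
    """Fitted binomial-logit fraction model.

    Fixed effects: intercept, covariate slopes, categorical age and sex
    effects (first level is the reference).  Per-cause intercepts are
    sum-coded fixed effects shrunk toward zero by an exchangeable
    empirical-Bayes factor -- an approximation to the binomial random
    intercept, flagged in ``diagnostics["approach"]``.  Causes unseen at fit
    time predict with a zero cause effect.
    """

    params: pd.Series
    bse: pd.Series
    cause_effects: dict[str, float]
    raw_cause_effects: dict[str, float]
    cause_se: dict[str, float]
    covariate_names: tuple[str, ...]
    age_levels: tuple[str, ...]
    sex_levels: tuple[str, ...]
    diagnostics: dict = field(default_factory=dict)

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(df), self.params["const"], dtype=float)
        for c in self.covariate_names:
            eta += self.params[f"cov:{c}"] * df[c].to_numpy(float)
        for a in self.age_levels[1:]:
            eta += self.params[f"age:{a}"] * (df["age_group"] == a).to_numpy(float)
        for s in self.sex_levels[1:]:
            eta += self.params[f"sex:{s}"] * (df["sex"] == s).to_numpy(float)
        eta += df["cause_id"].map(lambda c: self.cause_effects.get(c, 0.0)).to_numpy(float)
        return eta

    def predict_fraction(self, df: pd.DataFrame) -> np.ndarray:
        """Predicted intermediate-cause fraction in (0, 1)."""
        return expit(self.linear_predictor(df))


def _ordered_levels(values, vocabulary) -> tuple[str, ...]:
    vocab_order = {v: i for i, v in enumerate(vocabulary)}
    uniq = sorted(set(values), key=lambda v: (vocab_order.get(v, len(vocab_order)), v))
    return tuple(uniq)


def _design_matrix(
    df: pd.DataFrame,
    covariate_names: Sequence[str],
    age_levels: Sequence[str],
    sex_levels: Sequence[str],
    cause_levels: Sequence[str],
) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {"const": np.ones(len(df))}
    for c in covariate_names:
        cols[f"cov:{c}"] = df[c].to_numpy(float)
    for a in age_levels[1:]:
        cols[f"age:{a}"] = (df["age_group"] == a).to_numpy(float)
    for s in sex_levels[1:]:
        cols[f"sex:{s}"] = (df["sex"] == s).to_numpy(float)
    # sum (deviation) coding so the intercept is the grand mean and the
    # implied effect of the last cause is minus the sum of the others
    last = cause_levels[-1]
    for c in cause_levels[:-1]:
        cols[f"cause:{c}"] = (df["cause_id"] == c).to_numpy(float) - (
            df["cause_id"] == last
        ).to_numpy(float)
    return pd.DataFrame(cols, index=df.index)


def fit_fraction_model(
    agg: pd.DataFrame,
    covariates: pd.DataFrame,
    covariate_names: Sequence[str] = ("haq",),
    targets: set[str] | None = None,
    age_vocabulary=DEFAULT_AGE_GROUPS,
) -> FractionModel:
    """Fit the binomial-logit fraction model on the target-restricted aggregate.

    The likelihood is binomial with ``n_deaths`` trials and
    ``n_with_intermediate`` successes per stratum; zero-success strata are
    retained as ordinary binomial observations.
    """
    df = agg if targets is None else agg[agg["cause_id"].isin(targets)]
    df = df.merge(covariates, on=["location", "year"], how="left", validate="many_to_one")
    covariate_names = tuple(covariate_names)
    for c in covariate_names:
        if c not in df.columns or df[c].isna().any():
            raise ValueError(f"covariate {c!r} missing for some (location, year)")
    cause_levels = tuple(sorted(df["cause_id"].unique()))
    age_levels = _ordered_levels(df["age_group"], age_vocabulary)
    sex_levels = tuple(sorted(df["sex"].unique()))
    if len(cause_levels) < 2 or len(age_levels) < 2:
        raise ValueError("fraction model needs at least 2 causes and 2 age groups")

    X = _design_matrix(df, covariate_names, age_levels, sex_levels, cause_levels)
    endog = np.column_stack(
        [df["n_with_intermediate"].to_numpy(float), (df["n_deaths"] - df["n_with_intermediate"]).to_numpy(float)]
    )
    model = sm.GLM(endog, X, family=sm.families.Binomial())
    converged = True
    try:
        fit = model.fit(maxiter=200)
        converged = bool(fit.converged)
    except Exception as exc:  # separation or numerical failure
        warnings.warn(f"binomial GLM failed ({exc}); refitting with a small ridge penalty")
        fit = model.fit_regularized(alpha=1e-6, L1_wt=0.0)
        converged = False

    params = pd.Series(np.asarray(fit.params), index=X.columns)
    try:
        bse = pd.Series(np.asarray(fit.bse), index=X.columns)
        cov = np.asarray(fit.cov_params())
    except Exception:
        bse = pd.Series(np.nan, index=X.columns)
        cov = None

    # recover all k cause effects from the k-1 sum-coded columns
    cause_cols = [f"cause:{c}" for c in cause_levels[:-1]]
    gamma = {c: float(params[f"cause:{c}"]) for c in cause_levels[:-1]}
    gamma[cause_levels[-1]] = -float(sum(gamma.values()))
    gamma_se: dict[str, float] = {}
    if cov is not None:
        idx = [X.columns.get_loc(c) for c in cause_cols]
        sub = cov[np.ix_(idx, idx)]
        for c, i in zip(cause_levels[:-1], range(len(idx))):
            gamma_se[c] = float(np.sqrt(sub[i, i]))
        gamma_se[cause_levels[-1]] = float(np.sqrt(np.ones(len(idx)) @ sub @ np.ones(len(idx))))
    else:
        gamma_se = {c: np.nan for c in cause_levels}

    # exchangeable empirical-Bayes shrinkage toward the grand mean
    g = np.array([gamma[c] for c in cause_levels])
    s2 = np.array([gamma_se[c] ** 2 for c in cause_levels])
    if np.isfinite(s2).all():
        tau2 = max(float(np.var(g, ddof=1) - s2.mean()), 0.0)
        lam = tau2 / (tau2 + s2.mean()) if (tau2 + s2.mean()) > 0 else 1.0
    else:
        lam = 1.0
    shrunk = {c: lam * gamma[c] for c in cause_levels}

    fixed = params.drop(cause_cols)
    return FractionModel(
        params=fixed,
        bse=bse.drop(cause_cols),
        cause_effects=shrunk,
        raw_cause_effects=gamma,
        cause_se=gamma_se,
        covariate_names=covariate_names,
        age_levels=age_levels,
        sex_levels=sex_levels,
        diagnostics={
            "deviance": float(getattr(fit, "deviance", np.nan)),
            "converged": converged,
            "approach": "exchangeable_shrinkage",
            "shrinkage_factor": float(lam),
            "n_strata": int(len(df)),
        },
    )


def build_proportions(
    model: FractionModel,
    covariates: pd.DataFrame,
    envelope: pd.DataFrame,
    group_id: str,
    targets: set[str] | None = None,
) -> ProportionPackage:
    """Predicted fractions x envelope deaths, normalised within stratum.

    ``envelope`` columns: location, year, age_group, sex, cause_id, deaths
    (the external cause-specific death estimates).  Strata whose total
    intermediate-cause-related deaths are zero are omitted with a warning.
    """
    env = envelope if targets is None else envelope[envelope["cause_id"].isin(targets)]
    env = env.merge(covariates, on=["location", "year"], how="left", validate="many_to_one")
    for c in model.covariate_names:
        if c not in env.columns or env[c].isna().any():
            raise ValueError(f"covariate {c!r} missing for some envelope (location, year)")
    out = env[STRATUM_COLS + ["cause_id"]].copy()
    out["intermediate_deaths"] = model.predict_fraction(env) * env["deaths"].to_numpy(float)
    denom = out.groupby(STRATUM_COLS, observed=True)["intermediate_deaths"].transform("sum")
    zero = denom <= 0
    if zero.any():
        n_strata = out.loc[zero, STRATUM_COLS].drop_duplicates().shape[0]
        warnings.warn(f"omitting {n_strata} stratum/strata with zero intermediate-cause deaths")
    out = out[~zero].copy()
    out["proportion"] = out["intermediate_deaths"] / denom[~zero]
    return ProportionPackage(group_id, out[STRATUM_COLS + ["cause_id", "proportion"]])
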