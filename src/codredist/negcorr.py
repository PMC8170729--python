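"""Negative-correlation redistribution for class-4 garbage.

The most specific garbage codes (unspecified stroke, unspecified diabetes,
cancer of unspecified site) shadow a short a-priori list of subtypes, and a
certificate never lists both the vague code and a specific subtype -- so
multiple-cause data cannot help.  Instead, the method exploits the inverse
relationship between the vague code's frequency and its subtypes'
frequencies across strata:

1. model the logit-transformed subtype share (out of non-garbage-coded
   subtype deaths) linearly on mortality-predictive covariates, one
   regression per subtype;
2. regress the residuals on the logit-transformed garbage fraction; a
   non-zero slope means coding practice is leaking subtype deaths into the
   vague code;
3. shift each stratum's prediction by
   ``slope * (logit(counterfactual) - logit(GC_i))`` -- the move from the
   observed garbage fraction to a counterfactual "almost no garbage" world
   (1%, since logit(0) is undefined) along the fitted residual trend;
4. inverse-logit and renormalise over subtypes per stratum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._util import STRATUM_COLS, clamp_proportion, expit, logit
from .causemap import CauseHierarchy, GarbageGroup, resolve_code
from .proportions import ProportionPackage

__all__ = [
    "SubtypeModel",
    "NegCorrAdjustment",
    "build_subtype_dataset",
    "fit_subtype_model",
    "residual_adjustment",
    "adjusted_proportions",
    "DEFAULT_COUNTERFACTUAL_GC",
]

DEFAULT_COUNTERFACTUAL_GC = 0.01
LOGIT_EPS = 1e-4


def build_subtype_dataset(
    deaths: pd.DataFrame,
    group: GarbageGroup,
    hierarchy: CauseHierarchy,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Per stratum: subtype death counts, the garbage count for the group,
    the garbage fraction GC = garbage / (garbage + specific), and covariates.

    Only strata with at least one specific subtype death are usable.
    """
    if not group.target_causes:
        raise ValueError(f"group {group.group_id!r} has no a-priori subtype targets")
    df = deaths.copy()
    res = {c: resolve_code(c, hierarchy, unknown="residual") for c in df["code_or_cause"].unique()}
    df["dest"] = df["code_or_cause"].map(lambda c: res[c].dest)
    df["kind"] = df["code_or_cause"].map(lambda c: res[c].kind)

    sub = df[(df["kind"] == "cause") & df["dest"].isin(group.target_causes)]
    garb = df[(df["kind"] == "garbage") & (df["dest"] == group.group_id)]

    wide = (
        sub.groupby(STRATUM_COLS + ["dest"], observed=True)["deaths"]
        .sum()
        .unstack("dest", fill_value=0.0)
        .reindex(columns=sorted(group.target_causes), fill_value=0.0)
    )
    g = garb.groupby(STRATUM_COLS, observed=True)["deaths"].sum()
    out = wide.reset_index()
    out["garbage_deaths"] = out.set_index(STRATUM_COLS).index.map(g).fillna(0.0).to_numpy()
    out["total_specific"] = wide.sum(axis=1).to_numpy()
    out = out[out["total_specific"] > 0].copy()
    out["gc_fraction"] = out["garbage_deaths"] / (out["garbage_deaths"] + out["total_specific"])
    out = out.merge(covariates, on=["location", "year"], how="left", validate="many_to_one")
    return out.reset_index(drop=True)


@dataclass
class SubtypeModel:
    """Independent per-subtype linear models on logit shares."""

    subtypes: tuple[str, ...]
    covariate_names: tuple[str, ...]
    params: dict[str, pd.Series]  # per subtype: const + covariate slopes
    residuals: dict[str, np.ndarray]
    fitted_logit: dict[str, np.ndarray]
    strata: pd.DataFrame  # stratum keys + gc_fraction, aligned with residuals
    eps: float = LOGIT_EPS

    def predict_logit(self, subtype: str, covariates: pd.DataFrame) -> np.ndarray:
        p = self.params[subtype]
        eta = np.full(len(covariates), p["const"], dtype=float)
        for c in self.covariate_names:
            eta += p[c] * covariates[c].to_numpy(float)
        return eta


def fit_subtype_model(
    data: pd.DataFrame,
    subtypes: tuple[str, ...] | None = None,
    covariate_names: tuple[str, ...] = ("haq",),
    eps: float = LOGIT_EPS,
) -> SubtypeModel:
    """OLS of logit(subtype share of non-garbage subtype deaths) on covariates.

    Shares of exactly 0 or 1 are clamped to [eps, 1-eps] before the logit.
    """
    if subtypes is None:
        key_cols = set(STRATUM_COLS + ["garbage_deaths", "total_specific", "gc_fraction"]) | set(
            covariate_names
        )
        subtypes = tuple(c for c in data.columns if c not in key_cols)
    if len(subtypes) < 2:
        raise ValueError("negative-correlation model needs at least 2 subtypes")
    X = sm.add_constant(data[list(covariate_names)].to_numpy(float))
    names = pd.Index(["const", *covariate_names])
    params, resid, fitted = {}, {}, {}
    for s in subtypes:
        share = clamp_proportion(data[s].to_numpy(float) / data["total_specific"].to_numpy(float), eps)
        y = logit(share)
        fit = sm.OLS(y, X).fit()
        params[s] = pd.Series(fit.params, index=names)
        resid[s] = np.asarray(fit.resid)
        fitted[s] = np.asarray(fit.fittedvalues)
    return SubtypeModel(
        subtypes=tuple(subtypes),
        covariate_names=tuple(covariate_names),
        params=params,
        residuals=resid,
        fitted_logit=fitted,
        strata=data[STRATUM_COLS + ["gc_fraction"]].reset_index(drop=True),
        eps=eps,
    )


@dataclass
class NegCorrAdjustment:
    """Residual-vs-logit(GC) regression and the per-stratum counterfactual shift."""

    slopes: dict[str, float]  # residual-regression slope per subtype
    intercepts: dict[str, float]
    logit_gc: np.ndarray
    counterfactual_gc: float
    adjustments: dict[str, np.ndarray] = field(default_factory=dict)

    def adjustment_for(self, subtype: str, gc_fraction: np.ndarray) -> np.ndarray:
        b1 = self.slopes[subtype]
        gc = clamp_proportion(np.asarray(gc_fraction, float), LOGIT_EPS)
        return b1 * (logit(self.counterfactual_gc) - logit(gc))


def residual_adjustment(
    model: SubtypeModel,
    counterfactual_gc: float = DEFAULT_COUNTERFACTUAL_GC,
) -> NegCorrAdjustment:
    """Regress each subtype's residuals on logit(GC) and derive the shift
    toward the ``counterfactual_gc`` (1% by default) no-garbage world."""
    gc = clamp_proportion(model.strata["gc_fraction"].to_numpy(float), model.eps)
    lgc = logit(gc)
    slopes, intercepts, adjustments = {}, {}, {}
    degenerate = np.allclose(lgc, lgc[0])
    X = sm.add_constant(lgc)
    for s in model.subtypes:
        if degenerate:
            warnings.warn("all garbage fractions identical; residual slope undefined, adjustment 0")
            b0, b1 = float(np.mean(model.residuals[s])), 0.0
        else:
            fit = sm.OLS(model.residuals[s], X).fit()
            b0, b1 = float(fit.params[0]), float(fit.params[1])
        slopes[s] = b1
        intercepts[s] = b0
        adjustments[s] = b1 * (logit(counterfactual_gc) - lgc)
    return NegCorrAdjustment(
        slopes=slopes,
        intercepts=intercepts,
        logit_gc=lgc,
        counterfactual_gc=counterfactual_gc,
        adjustments=adjustments,
    )


def adjusted_proportions(
    model: SubtypeModel,
    adjustment: NegCorrAdjustment | None,
    group_id: str,
    adjust_space: str = "logit",
) -> ProportionPackage:
    """Counterfactual subtype proportions, renormalised per stratum.

    ``adjust_space="logit"`` (default) adds the shift to the fitted logit
    before the inverse transform, which keeps every share inside (0, 1);
    ``"natural"`` adds it to the fitted share directly (clipped at 0).
    """
    rows = []
    n = len(model.strata)
    shares = np.zeros((n, len(model.subtypes)))
    for j, s in enumerate(model.subtypes):
        pred = model.fitted_logit[s]
        adj = adjustment.adjustments[s] if adjustment is not None else np.zeros(n)
        if adjust_space == "logit":
            shares[:, j] = expit(pred + adj)
        elif adjust_space == "natural":
            shares[:, j] = np.clip(expit(pred) + adj, 0.0, None)
        else:
            raise ValueError(f"unknown adjust_space {adjust_space!r}")
    shares = shares / shares.sum(axis=1, keepdims=True)
    for j, s in enumerate(model.subtypes):
        block = model.strata[STRATUM_COLS].copy()
        block["cause_id"] = s
        block["proportion"] = shares[:, j]
        rows.append(block)
    return ProportionPackage(group_id, pd.concat(rows, ignore_index=True))
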