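"""Shared constants and small numeric helpers."""

from __future__ import annotations

import numpy as np
from scipy.special import expit as _expit
from scipy.special import logit as _logit

#: Demographic key identifying a stratum of tabulated deaths.
STRATUM_COLS = ["location", "year", "age_group", "sex"]

SEXES = ["male", "female"]

#: Default closed age-group vocabulary: 20 GBD-style bands.
DEFAULT_AGE_GROUPS = (
    ["<1", "1-4"]
    + [f"{lo}-{lo + 4}" for lo in range(5, 90, 5)]
    + ["90+"]
)


def logit(p):
    return _logit(p)


def expit(x):
    return _expit(x)


def clamp_proportion(p, eps=1e-4):
    """Clamp proportions into [eps, 1-eps] so the logit is finite."""
    return np.clip(p, eps, 1.0 - eps)


def check_age_groups(values, vocabulary):
    unknown = set(values) - set(vocabulary)
    if unknown:
        raise ValueError(f"unknown age group label(s): {sorted(unknown)}")
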