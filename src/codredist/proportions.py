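"""Redistribution proportion packages.

A :class:`ProportionPackage` is the common currency of the four estimation
methods: for one garbage group it holds, per demographic stratum, the share
of that group's deaths going to each target cause.  Shares sum to one within
every stratum.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._util import STRATUM_COLS

__all__ = ["ProportionPackage", "PROPORTION_COLS"]

PROPORTION_COLS = STRATUM_COLS + ["cause_id", "proportion"]


@dataclass
class ProportionPackage:
    group_id: str
    data: pd.DataFrame  # columns: location, year, age_group, sex, cause_id, proportion

    def __post_init__(self) -> None:
        missing = set(PROPORTION_COLS) - set(self.data.columns)
        if missing:
            raise ValueError(f"proportion package missing column(s): {sorted(missing)}")
        self.data = self.data.reset_index(drop=True)
        self.validate()

    def validate(self, tol: float = 1e-9) -> None:
        if len(self.data) == 0:
            return
        p = self.data["proportion"]
        if (p < -tol).any() or (p > 1 + tol).any():
            raise ValueError(f"package {self.group_id!r}: proportions outside [0, 1]")
        sums = self.data.groupby(STRATUM_COLS, observed=True)["proportion"].sum()
        off = sums[(sums - 1.0).abs() > tol]
        if len(off):
            raise ValueError(
                f"package {self.group_id!r}: proportions do not sum to 1 in "
                f"{len(off)} stratum/strata (worst: {off.iloc[0]:.12f})"
            )

    def targets(self) -> list[str]:
        return sorted(self.data["cause_id"].unique())

    def write(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "garbage_group_id", self.group_id)
        out.to_csv(path, index=False, float_format="%.15g")

    @classmethod
    def read(cls, path) -> "ProportionPackage":
        df = pd.read_csv(path, dtype={"location": str, "age_group": str, "sex": str})
        gid = df.pop("garbage_group_id").iloc[0]
        return cls(gid, df)
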