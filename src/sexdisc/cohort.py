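"""Canonical participant-level cohort table.

One row per participant, wide format: demographics, four sexual
indifference-point curves (visual-analog responses on the 0-100 scale, one
column per delay), one monetary curve (indifference amounts in dollars out
of $1000), questionnaire scores, and the number of images selected.  Both
the synthetic generator and the analysis pipeline speak this schema.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import (
    ALL_CONDITIONS,
    DDT_SCHEDULE,
    SDT_SCHEDULE,
    SEXUAL_CONDITIONS,
    IndifferenceCurve,
    normalize_delays,
)

logger = logging.getLogger(__name__)

SCENARIOS = ("positive", "negative", "negative_regret")

DELAYED_AMOUNT = 1000.0  # dollars

DEMOGRAPHIC_COLUMNS = (
    "participant_id",
    "scenario",
    "gender",
    "age",
    "household_size",
    "income_usd",
    "days_since_last_encounter",
    "education",
    "marital_status",
    "employed",
    "image_count",
)

SCORE_COLUMNS = ("hrbs_score", "ztpi_score", "sss_score", "cfc_score")


def sdt_column(condition: str, delay_hours: float) -> str:
    return f"sdt_{condition}_{delay_hours:g}h"


def ddt_column(delay_hours: float) -> str:
    return f"ddt_{delay_hours:g}h"


def sdt_columns(condition: str) -> list[str]:
    return [sdt_column(condition, d) for d in SDT_SCHEDULE.durations]


def ddt_columns() -> list[str]:
    return [ddt_column(d) for d in DDT_SCHEDULE.durations]


def all_columns() -> list[str]:
    cols = list(DEMOGRAPHIC_COLUMNS)
    for cond in SEXUAL_CONDITIONS:
        cols.extend(sdt_columns(cond))
    cols.extend(ddt_columns())
    cols.extend(SCORE_COLUMNS)
    return cols


REQUIRED_COLUMNS = tuple(all_columns())


@dataclass
class CohortTable:
    """Typed wrapper around the canonical wide DataFrame."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"cohort table missing required columns: {missing}")
        bad_scen = set(self.df["scenario"].dropna()) - set(SCENARIOS)
        if bad_scen:
            raise ValueError(f"unknown scenario labels: {sorted(bad_scen)}")
        low_img = self.df["image_count"].dropna() < 2
        if low_img.any():
            raise ValueError(
                f"{int(low_img.sum())} participant(s) with image_count < 2 "
                "(task requires selecting at least two images)"
            )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_per_scenario(self) -> dict[str, int]:
        counts = self.df["scenario"].value_counts()
        return {s: int(counts.get(s, 0)) for s in SCENARIOS}

    def curve(self, participant_id, condition: str) -> IndifferenceCurve:
        """Extract one participant x condition as an IndifferenceCurve."""
        row = self.df.loc[self.df["participant_id"] == participant_id]
        if row.empty:
            raise KeyError(f"no participant {participant_id!r}")
        row = row.iloc[0]
        if condition == "monetary":
            values = tuple(float(row[c]) / DELAYED_AMOUNT for c in ddt_columns())
            return IndifferenceCurve(
                str(participant_id), "monetary", "monetary", DDT_SCHEDULE, values
            )
        values = tuple(float(row[c]) / 100.0 for c in sdt_columns(condition))
        return IndifferenceCurve(str(participant_id), "sexual", condition, SDT_SCHEDULE, values)

    def auc_frame(self, anchor: str = "measured") -> pd.DataFrame:
        """Per-participant AUC for all five conditions (vectorized trapezoid).

        Returns participant_id, scenario, gender plus ``auc_<condition>``
        columns.  A participant with any missing response in a condition
        gets NaN for that condition's AUC (excluded from analyses on it);
        exclusion counts are logged.
        """
        if anchor not in ("measured", "exclude-zero"):
            raise ValueError(f"unknown anchor mode {anchor!r}")
        out = self.df[["participant_id", "scenario", "gender"]].copy()
        x_sdt = normalize_delays(SDT_SCHEDULE)
        for cond in SEXUAL_CONDITIONS:
            vals = self.df[sdt_columns(cond)].to_numpy(dtype=float) / 100.0
            if np.any((vals < -1e-9) | (vals > 1 + 1e-9)):
                raise ValueError(f"VAS values outside [0, 100] in condition {cond}")
            x = x_sdt
            if anchor == "exclude-zero":
                x = (x_sdt[1:] - x_sdt[1]) / (x_sdt[-1] - x_sdt[1])
                vals = vals[:, 1:]
            auc = np.trapezoid(vals, x, axis=1)
            n_missing = int(np.isnan(auc).sum())
            if n_missing:
                logger.info("%s: %d participant(s) excluded (missing responses)", cond, n_missing)
            out[f"auc_{cond}"] = np.clip(auc, 0.0, 1.0)
        # monetary: synthetic anchor (0, 1) prepended before integration
        vals = self.df[ddt_columns()].to_numpy(dtype=float) / DELAYED_AMOUNT
        x = np.concatenate([[0.0], normalize_delays(DDT_SCHEDULE)])
        vals = np.column_stack([np.ones(len(vals)), vals])
        auc = np.trapezoid(vals, x, axis=1)
        n_missing = int(np.isnan(auc).sum())
        if n_missing:
            logger.info("monetary: %d participant(s) excluded (missing responses)", n_missing)
        out["auc_monetary"] = np.clip(auc, 0.0, 1.0)
        return out

    def measures_frame(self, anchor: str = "measured") -> pd.DataFrame:
        """AUC frame joined with questionnaire scores and image count."""
        aucs = self.auc_frame(anchor=anchor)
        extra = self.df[["participant_id", "image_count", *SCORE_COLUMNS]]
        return aucs.merge(extra, on="participant_id", validate="one_to_one")

    def median_indifference_points(self) -> pd.DataFrame:
        """Median normalized indifference point per scenario x condition x delay.

        The tabular analogue of per-scenario median discounting curves.
        """
        records = []
        for cond in ALL_CONDITIONS:
            if cond == "monetary":
                cols = ddt_columns()
                delays = DDT_SCHEDULE.durations
                scale = DELAYED_AMOUNT
            else:
                cols = sdt_columns(cond)
                delays = SDT_SCHEDULE.durations
                scale = 100.0
            med = self.df.groupby("scenario")[cols].median()
            for scenario, row in med.iterrows():
                for delay, col in zip(delays, cols):
                    records.append(
                        {
                            "condition": cond,
                            "scenario": scenario,
                            "delay_hours": delay,
                            "median_value": float(row[col]) / scale,
                        }
                    )
        return pd.DataFrame.from_records(records)

    def write_csv(self, path) -> None:
        self.df.to_csv(path, index=False, columns=list(REQUIRED_COLUMNS))

    @classmethod
    def read_csv(cls, path) -> "CohortTable":
        return cls(pd.read_csv(path))
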