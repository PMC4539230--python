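"""End-to-end orchestration: cohort in, published-analysis tables out.

The pipeline loads a cohort (from the canonical CSV, an adapted external
file, or the synthetic generator), computes per-participant AUCs, and emits
the three analysis tables plus the gender contrast and a demographic
summary:

* table 1 - pairwise scenario comparisons of the AUC distribution per
  partner condition and for monetary discounting (rank-sum Z, 15 rows);
* table 2 - permutation tests for differences in the strength of the
  Spearman correlation between AUC and HRBS across scenarios (12 rows);
* table 3 - Spearman correlations between sexual AUC and the other
  measures, pooled across scenarios (24 rows);
* gender contrast - rank-sum test of AUC by gender per partner condition.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    REQUIRED_COLUMNS,
    SCENARIOS,
    SCORE_COLUMNS,
    CohortTable,
    ddt_columns,
    sdt_columns,
)
from .curves import SEXUAL_CONDITIONS
from .scenarios import render_scenario  # noqa: F401  (re-exported pipeline surface)
from .stats import (
    PermCorrDiffResult,
    median_iqr,
    permutation_corr_diff,
    spearman,
    wilcoxon_rank_sum,
)
from .synthetic_cohort import SimulationConfig, generate_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "ColumnMapping",
    "AnalysisConfig",
    "ReportBundle",
    "read_cohort",
    "read_measures",
    "render_scenario",
    "table1_analysis",
    "table2_analysis",
    "table3_analysis",
    "gender_contrast_analysis",
    "demographics_summary",
    "run_all",
]

# Published-table ordering conventions: rows list the first-named group
# first, and the rank-sum Z follows that group.
PAIR_ORDER = (
    ("negative", "negative_regret"),
    ("positive", "negative"),
    ("positive", "negative_regret"),
)
CONDITION_ORDER = SEXUAL_CONDITIONS + ("monetary",)
MEASURE_ORDER = (
    ("monetary_auc", "auc_monetary"),
    ("ztpi", "ztpi_score"),
    ("image_count", "image_count"),
    ("hrbs", "hrbs_score"),
    ("sss", "sss_score"),
    ("cfc", "cfc_score"),
)


@dataclass
class ColumnMapping:
    """Bridge from an external file's columns to the canonical schema.

    ``columns`` maps canonical names to source names; canonical columns
    already present in the file under their own name need no entry.
    Canonical fields the file genuinely lacks are listed in ``absent``
    (analyses needing them produce flagged rows).  ``vas_scale`` is the
    source value meaning "always wait" (100 for raw VAS, 1 for
    pre-normalized); ``money_scale`` likewise for indifference amounts.
    ``auc_columns`` (condition -> source column) bypasses the AUC stage for
    files that store AUC instead of trial-level responses.
    """

    columns: dict[str, str] = field(default_factory=dict)
    vas_scale: float = 100.0
    money_scale: float = 1000.0
    auc_columns: dict[str, str] = field(default_factory=dict)
    absent: set[str] = field(default_factory=set)
    scenario_labels: dict[str, str] = field(default_factory=dict)  # source -> canonical

    @classmethod
    def from_yaml(cls, path) -> "ColumnMapping":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        if "absent" in d:
            d["absent"] = set(d["absent"])
        return cls(**d)

    def validate(self, source_columns, required) -> None:
        """Every required canonical field must be mapped, present, or absent."""
        source_columns = set(source_columns)
        problems = []
        for canonical in required:
            src = self.columns.get(canonical, canonical)
            if canonical in self.absent:
                continue
            if src not in source_columns:
                problems.append(f"{canonical!r} (source column {src!r} not found)")
        if problems:
            raise ValueError(
                "column mapping leaves required fields unresolved: " + ", ".join(problems)
            )


def _apply_mapping(df: pd.DataFrame, mapping: ColumnMapping, required) -> pd.DataFrame:
    mapping.validate(df.columns, required)
    rename = {src: canon for canon, src in mapping.columns.items() if src in df.columns}
    out = df.rename(columns=rename).copy()
    for col in mapping.absent:
        if col not in out.columns:
            out[col] = np.nan
    if mapping.scenario_labels and "scenario" in out.columns:
        out["scenario"] = out["scenario"].map(lambda s: mapping.scenario_labels.get(s, s))
    return out


def read_cohort(path, mapping: ColumnMapping | None = None) -> CohortTable:
    """Load a trial-level cohort file, adapting columns via ``mapping``.

    Values are rescaled to the canonical units (VAS 0-100, dollars out of
    $1000).  A per-field validation summary (missingness) is logged.
    """
    df = pd.read_csv(path)
    mapping = mapping or ColumnMapping()
    df = _apply_mapping(df, mapping, REQUIRED_COLUMNS)
    vas_cols = [c for cond in SEXUAL_CONDITIONS for c in sdt_columns(cond)]
    if mapping.vas_scale != 100.0:
        df[vas_cols] = df[vas_cols] * (100.0 / mapping.vas_scale)
    if mapping.money_scale != 1000.0:
        df[ddt_columns()] = df[ddt_columns()] * (1000.0 / mapping.money_scale)
    for col in vas_cols + ddt_columns() + list(SCORE_COLUMNS):
        n_missing = int(df[col].isna().sum())
        if n_missing:
            logger.info("column %s: %d missing value(s)", col, n_missing)
    return CohortTable(df)


MEASURES_REQUIRED = ("participant_id", "scenario", "gender") + tuple(
    f"auc_{c}" for c in CONDITION_ORDER
) + ("image_count",) + SCORE_COLUMNS


def read_measures(path, mapping: ColumnMapping | None = None) -> pd.DataFrame:
    """Load a participant-level measures file that already stores AUC.

    Used when a deposited file carries AUC columns rather than trial-level
    responses: the AUC stage is bypassed and the statistical stages run
    unchanged.  ``mapping.auc_columns`` names the source AUC columns.
    """
    df = pd.read_csv(path)
    mapping = mapping or ColumnMapping()
    if mapping.auc_columns:
        mapping = ColumnMapping(
            columns={
                **mapping.columns,
                **{f"auc_{cond}": src for cond, src in mapping.auc_columns.items()},
            },
            absent=mapping.absent,
            scenario_labels=mapping.scenario_labels,
        )
    return _apply_mapping(df, mapping, MEASURES_REQUIRED)


def _as_measures(cohort, anchor: str = "measured") -> pd.DataFrame:
    if isinstance(cohort, CohortTable):
        return cohort.measures_frame(anchor=anchor)
    return cohort


def _stars(p: float, low: float, high: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < high:
        return "**"
    if p < low:
        return "*"
    return ""


def table1_analysis(cohort, anchor: str = "measured") -> pd.DataFrame:
    """Pairwise scenario rank-sum tests per condition (15 rows).

    Rows follow the fixed listing order: for each condition (four partner
    conditions then monetary), the three scenario pairs with the
    first-named group defining the sign of Z.  Empty cells (no valid AUC in
    a group) are flagged, never dropped.
    """
    measures = _as_measures(cohort, anchor)
    rows = []
    for cond in CONDITION_ORDER:
        col = f"auc_{cond}"
        for group_a, group_b in PAIR_ORDER:
            a = measures.loc[measures["scenario"] == group_a, col].dropna().to_numpy()
            b = measures.loc[measures["scenario"] == group_b, col].dropna().to_numpy()
            row = {
                "condition": cond,
                "group_a": group_a,
                "group_b": group_b,
                "n_a": a.size,
                "n_b": b.size,
            }
            if a.size < 2 or b.size < 2:
                row.update(
                    mean_rank_diff=np.nan, z=np.nan, p_two_sided=np.nan,
                    significance="", flagged=True,
                )
            else:
                res = wilcoxon_rank_sum(a, b)
                row.update(
                    mean_rank_diff=res.mean_rank_diff,
                    z=res.z,
                    p_two_sided=res.p_two_sided,
                    significance=_stars(res.p_two_sided, 0.05, 0.001),
                    flagged=False,
                )
            rows.append(row)
    return pd.DataFrame(rows)


def table2_analysis(
    cohort,
    n_resamples: int = 100_000,
    seed: int = 0,
    anchor: str = "measured",
) -> pd.DataFrame:
    """Permutation tests for AUC-HRBS correlation differences (12 rows).

    For each partner condition and scenario pair, the (AUC, HRBS) pairs of
    the two groups are pooled and group labels reshuffled ``n_resamples``
    times.  Each row records its own derived seed, so the full table is
    reproducible from the master seed.
    """
    measures = _as_measures(cohort, anchor)
    master = np.random.default_rng(seed)
    rows = []
    for cond in SEXUAL_CONDITIONS:
        col = f"auc_{cond}"
        for group_a, group_b in PAIR_ORDER:
            sub_a = measures.loc[measures["scenario"] == group_a, [col, "hrbs_score"]].dropna()
            sub_b = measures.loc[measures["scenario"] == group_b, [col, "hrbs_score"]].dropna()
            row_seed = int(master.integers(0, 2**31 - 1))
            row = {
                "condition": cond,
                "group_a": group_a,
                "group_b": group_b,
                "n_a": len(sub_a),
                "n_b": len(sub_b),
            }
            if len(sub_a) < 3 or len(sub_b) < 3:
                row.update(
                    rho_a=np.nan, rho_b=np.nan, observed_diff=np.nan,
                    p_two_sided=np.nan, n_resamples=0, seed=row_seed,
                    n_degenerate=0, significance="", flagged=True,
                )
            else:
                res: PermCorrDiffResult = permutation_corr_diff(
                    sub_a[col], sub_a["hrbs_score"],
                    sub_b[col], sub_b["hrbs_score"],
                    n_resamples=n_resamples,
                    seed=row_seed,
                )
                row.update(
                    rho_a=res.rho_a,
                    rho_b=res.rho_b,
                    observed_diff=res.observed_diff,
                    p_two_sided=res.p_two_sided,
                    n_resamples=res.n_resamples,
                    seed=row_seed,
                    n_degenerate=res.n_degenerate,
                    significance=_stars(res.p_two_sided, 0.05, 0.01),
                    flagged=False,
                )
            rows.append(row)
    return pd.DataFrame(rows)


def table3_analysis(cohort, anchor: str = "measured") -> pd.DataFrame:
    """Spearman correlations of sexual AUC with the other measures (24 rows)."""
    measures = _as_measures(cohort, anchor)
    rows = []
    for cond in SEXUAL_CONDITIONS:
        col = f"auc_{cond}"
        for name, mcol in MEASURE_ORDER:
            sub = measures[[col, mcol]].dropna()
            row = {"condition": cond, "measure": name, "n": len(sub)}
            if len(sub) < 3:
                row.update(rho=np.nan, p_two_sided=np.nan, significance="", flagged=True)
            else:
                res = spearman(sub[col], sub[mcol])
                row.update(
                    rho=res.rho,
                    p_two_sided=res.p_two_sided,
                    significance="" if not res.defined else _stars(res.p_two_sided, 0.05, 0.01),
                    flagged=not res.defined,
                )
            rows.append(row)
    return pd.DataFrame(rows)


def gender_contrast_analysis(cohort, anchor: str = "measured") -> pd.DataFrame:
    """Rank-sum test of AUC by gender per partner condition (males first)."""
    measures = _as_measures(cohort, anchor)
    rows = []
    for cond in SEXUAL_CONDITIONS:
        col = f"auc_{cond}"
        male = measures.loc[measures["gender"] == "male", col].dropna().to_numpy()
        female = measures.loc[measures["gender"] == "female", col].dropna().to_numpy()
        row = {"condition": cond, "group_a": "male", "group_b": "female",
               "n_a": male.size, "n_b": female.size}
        if male.size < 2 or female.size < 2:
            row.update(z=np.nan, p_two_sided=np.nan, significance="", flagged=True)
        else:
            res = wilcoxon_rank_sum(male, female)
            row.update(
                z=res.z, p_two_sided=res.p_two_sided,
                significance=_stars(res.p_two_sided, 0.05, 0.001), flagged=False,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def demographics_summary(cohort: CohortTable) -> pd.DataFrame:
    """Median (IQR) for numeric demographics; proportions for categoricals."""
    df = cohort.df
    rows = []
    for var in ("age", "household_size", "income_usd", "days_since_last_encounter"):
        med, q1, q3 = median_iqr(df[var].dropna())
        rows.append({"variable": var, "kind": "median_iqr",
                     "median": med, "q1": q1, "q3": q3, "proportion": np.nan})
    categorical = {
        "female": (df["gender"] == "female").mean(),
        "some_college_or_more": (df["education"] == "some_college_or_more").mean(),
        "single": (df["marital_status"] == "single").mean(),
        "employed": df["employed"].astype(bool).mean(),
    }
    for var, p in categorical.items():
        rows.append({"variable": var, "kind": "proportion",
                     "median": np.nan, "q1": np.nan, "q3": np.nan, "proportion": float(p)})
    return pd.DataFrame(rows)


@dataclass
class ReportBundle:
    """All emitted tables plus run metadata."""

    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    gender_contrast: pd.DataFrame
    demographics: pd.DataFrame | None
    median_curves: pd.DataFrame | None
    metadata: dict

    EXPECTED_ROWS = {"table1": 15, "table2": 12, "table3": 24, "gender_contrast": 4}

    def __post_init__(self) -> None:
        for name, expected in self.EXPECTED_ROWS.items():
            got = len(getattr(self, name))
            if got != expected:
                raise ValueError(f"{name} must have {expected} rows, got {got}")

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("table1", "table2", "table3", "gender_contrast"):
            getattr(self, name).to_csv(outdir / f"{name}.csv", index=False)
        if self.demographics is not None:
            self.demographics.to_csv(outdir / "demographics.csv", index=False)
        if self.median_curves is not None:
            self.median_curves.to_csv(outdir / "median_indifference_points.csv", index=False)
        with open(outdir / "metadata.json", "w", encoding="utf-8") as fh:
            json.dump(self.metadata, fh, indent=2, default=str)


@dataclass
class AnalysisConfig:
    """Names either an input file (+ mapping) or a simulation config."""

    simulation: SimulationConfig | None = None
    input_csv: str | None = None
    mapping: ColumnMapping | None = None
    measures_input: bool = False  # input stores AUC, bypass the AUC stage
    n_resamples: int = 100_000
    seed: int = 0
    auc_anchor: str = "measured"
    emit_median_curves: bool = True

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.input_csv is None):
            raise ValueError("config must name exactly one of simulation / input_csv")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        if d.get("simulation") is not None:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if d.get("mapping") is not None:
            m = d["mapping"]
            if "absent" in m:
                m["absent"] = set(m["absent"])
            d["mapping"] = ColumnMapping(**m)
        return cls(**d)


def run_all(config: AnalysisConfig, outdir=None) -> ReportBundle:
    """Load or simulate, analyze, and (optionally) write the full bundle."""
    stage = "input"
    try:
        input_digest = None
        cohort: CohortTable | pd.DataFrame
        if config.simulation is not None:
            cohort = generate_cohort(config.simulation)
        elif config.measures_input:
            cohort = read_measures(config.input_csv, config.mapping)
        else:
            cohort = read_cohort(config.input_csv, config.mapping)
        if config.input_csv is not None:
            input_digest = hashlib.sha256(Path(config.input_csv).read_bytes()).hexdigest()

        stage = "table1"
        table1 = table1_analysis(cohort, anchor=config.auc_anchor)
        stage = "table2"
        table2 = table2_analysis(
            cohort, n_resamples=config.n_resamples, seed=config.seed, anchor=config.auc_anchor
        )
        stage = "table3"
        table3 = table3_analysis(cohort, anchor=config.auc_anchor)
        stage = "gender_contrast"
        gender = gender_contrast_analysis(cohort, anchor=config.auc_anchor)
        stage = "demographics"
        is_cohort = isinstance(cohort, CohortTable)
        demographics = demographics_summary(cohort) if is_cohort else None
        median_curves = (
            cohort.median_indifference_points()
            if is_cohort and config.emit_median_curves
            else None
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    measures = _as_measures(cohort, config.auc_anchor)
    metadata = {
        "package_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": config.seed,
        "n_resamples": config.n_resamples,
        "auc_anchor": config.auc_anchor,
        "n_per_scenario": {
            s: int((measures["scenario"] == s).sum()) for s in SCENARIOS
        },
        "input_digest": input_digest,
        "simulation": config.simulation.to_dict() if config.simulation else None,
    }
    bundle = ReportBundle(
        table1=table1,
        table2=table2,
        table3=table3,
        gender_contrast=gender,
        demographics=demographics,
        median_curves=median_curves,
        metadata=metadata,
    )
    if outdir is not None:
        bundle.write(outdir)
    return bundle
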