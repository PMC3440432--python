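"""Cohort orchestration.

Reads a cohort composition table (molar or percent-of-mean dialect), applies
the study's inclusion filters, simulates every retained individual with and
without the protein C pathway, reduces each trace to thrombogram parameters,
and emits group-stratified summary tables plus mean +/- SD envelope curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .kinetics import (
    EXCLUSION_FLAGS,
    FACTOR_SPECIES,
    PHYSIOLOGIC_MEAN,
    PlasmaComposition,
    SimulationConfig,
    SimulationError,
    simulate,
)
from .metrics import compute_metrics, exceeds_control
from .model import ModelDefinition, select_submodel

__all__ = [
    "CohortTable",
    "FilterReport",
    "read_cohort",
    "cohort_to_compositions",
    "apply_inclusion_filters",
    "percent_to_molar",
    "molar_to_percent",
    "run_cohort",
    "summarize_groups",
    "envelope_curves",
    "EXCLUSION_COLUMNS",
    "FACTOR_COLUMNS",
    "METRIC_COLUMNS",
]

log = logging.getLogger(__name__)

FACTOR_COLUMNS = tuple(attr for attr, _, _ in FACTOR_SPECIES)
_FACTOR_BASE = tuple(c.rsplit("_", 1)[0] for c in FACTOR_COLUMNS)  # fII, fV, ...
PERCENT_COLUMNS = tuple(f"{b}_pct" for b in _FACTOR_BASE)
EXCLUSION_COLUMNS = tuple(f"excl_{flag}" for flag in EXCLUSION_FLAGS)
LABEL_COLUMNS = ("sex", "age", "pc_mutation", "pt_g20210a", "thrombosis_history")
METRIC_COLUMNS = ("MaxL_nM", "TMaxL_s", "MaxR_nM_per_s", "TMaxR_s", "AUC_uM_s", "CT_s")
PATHWAYS = ("with_pc", "without_pc")


@dataclass
class FilterReport:
    n_raw: int
    n_retained: int
    removed_by_category: dict[str, int]  # flag occurrences; may double-count
    n_removed: int                       # size of the union of flagged rows

    def __str__(self) -> str:
        cats = ", ".join(f"{k}={v}" for k, v in self.removed_by_category.items())
        return f"{self.n_raw} -> {self.n_retained} retained ({self.n_removed} removed; {cats})"


@dataclass
class CohortTable:
    df: pd.DataFrame
    source: str = "<memory>"
    filter_report: FilterReport | None = None

    def __post_init__(self) -> None:
        if self.df["subject_id"].duplicated().any():
            dup = self.df.loc[self.df["subject_id"].duplicated(), "subject_id"].iloc[0]
            raise ValueError(f"duplicate subject_id {dup!r}")

    def __len__(self) -> int:
        return len(self.df)


def _detect_dialect(columns: list[str]) -> str:
    has_molar = any(c in columns for c in FACTOR_COLUMNS)
    has_pct = any(c in columns for c in PERCENT_COLUMNS)
    if has_molar and has_pct:
        raise ValueError("mixed molar and percent factor columns; supply one dialect")
    if not has_molar and not has_pct:
        raise ValueError("no factor columns found")
    return "percent" if has_pct else "molar"


def read_cohort(path, mean: PlasmaComposition = PHYSIOLOGIC_MEAN) -> CohortTable:
    """Read a cohort CSV; percent-of-mean columns are converted to molar."""
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise ValueError("cohort table needs a subject_id column")
    df["subject_id"] = df["subject_id"].astype(str)
    dialect = _detect_dialect(list(df.columns))
    if dialect == "percent":
        missing = [c for c in PERCENT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"percent dialect missing columns {missing}")
        for pct_col, molar_col in zip(PERCENT_COLUMNS, FACTOR_COLUMNS):
            values = percent_to_molar(
                {molar_col: df[pct_col].to_numpy(dtype=float)}, mean
            )[molar_col]
            df[molar_col] = values
        df = df.drop(columns=list(PERCENT_COLUMNS))
    else:
        missing = [c for c in FACTOR_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"molar dialect missing columns {missing}")
    for col in EXCLUSION_COLUMNS:
        if col not in df.columns:
            df[col] = False
        else:
            df[col] = df[col].fillna(False).astype(bool)
    return CohortTable(df, source=str(path))


def percent_to_molar(percent_values, mean: PlasmaComposition = PHYSIOLOGIC_MEAN):
    """Convert percent-of-mean factor values to molar units.

    ``percent_values`` maps molar column names (``fII_uM`` ...) or bare factor
    names (``fII`` ...) to percentages; 100 maps to the physiologic mean.
    """
    out = {}
    for key, pct in percent_values.items():
        col = key if key in FACTOR_COLUMNS else next(
            (c for c, b in zip(FACTOR_COLUMNS, _FACTOR_BASE) if b == key), None
        )
        if col is None:
            raise ValueError(f"unknown factor {key!r}")
        arr = np.asarray(pct, dtype=float)
        if np.any(arr <= 0):
            raise ValueError(f"{key}: percent values must be > 0")
        out[col] = arr / 100.0 * getattr(mean, col)
    return out


def molar_to_percent(molar_values, mean: PlasmaComposition = PHYSIOLOGIC_MEAN):
    """Inverse of :func:`percent_to_molar` (round-trips to 1e-12 relative)."""
    out = {}
    for col, val in molar_values.items():
        if col not in FACTOR_COLUMNS:
            raise ValueError(f"unknown factor column {col!r}")
        out[col] = np.asarray(val, dtype=float) / getattr(mean, col) * 100.0
    return out


def apply_inclusion_filters(cohort: CohortTable) -> CohortTable:
    """Drop every row with any exclusion flag set.

    A multi-flagged row is removed once but tallied in each of its categories,
    so category tallies may sum to more than the number removed.
    """
    df = cohort.df
    missing = [c for c in EXCLUSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing exclusion-flag columns {missing}")
    flags = df[list(EXCLUSION_COLUMNS)].astype(bool)
    removed_by_category = {
        flag: int(flags[col].sum()) for flag, col in zip(EXCLUSION_FLAGS, EXCLUSION_COLUMNS)
    }
    any_flag = flags.any(axis=1)
    report = FilterReport(
        n_raw=len(df),
        n_retained=int((~any_flag).sum()),
        removed_by_category=removed_by_category,
        n_removed=int(any_flag.sum()),
    )
    log.info("inclusion filters: %s", report)
    return CohortTable(df.loc[~any_flag].reset_index(drop=True), cohort.source, report)


def cohort_to_compositions(cohort: CohortTable) -> list[PlasmaComposition]:
    comps = []
    for row in cohort.df.itertuples(index=False):
        d = row._asdict()
        comps.append(
            PlasmaComposition(
                subject_id=str(d["subject_id"]),
                **{c: float(d[c]) for c in FACTOR_COLUMNS},
                sex=str(d.get("sex", "F")),
                age=float(d.get("age", 45.0)),
                pc_mutation=str(d.get("pc_mutation", "no")),
                pt_g20210a=str(d.get("pt_g20210a", "no")),
                thrombosis_history=str(d.get("thrombosis_history", "none")),
                exclusions=frozenset(
                    f for f, c in zip(EXCLUSION_FLAGS, EXCLUSION_COLUMNS) if d.get(c, False)
                ),
            )
        )
    return comps


def _metrics_row(subject_id: str, pathway: str, tc) -> dict:
    m = compute_metrics(tc.time, tc.thrombin)
    return {
        "subject_id": subject_id,
        "pathway": pathway,
        "MaxL_nM": m.max_level_nM,
        "TMaxL_s": m.t_max_level_s,
        "MaxR_nM_per_s": m.max_rate_nM_s,
        "TMaxR_s": m.t_max_rate_s,
        "AUC_uM_s": m.auc_uM_s,
        "CT_s": m.clot_time_s,
    }


def _row_to_metrics(row) -> "ThrombinMetrics":
    from .metrics import ThrombinMetrics

    return ThrombinMetrics(
        row["MaxL_nM"], row["TMaxL_s"], row["MaxR_nM_per_s"], row["TMaxR_s"],
        row["AUC_uM_s"], row["CT_s"],
    )


def run_cohort(
    cohort: CohortTable,
    model: ModelDefinition,
    config: SimulationConfig = SimulationConfig(),
    *,
    control: PlasmaComposition = PHYSIOLOGIC_MEAN,
    keep_traces: bool = False,
    max_failure_fraction: float = 0.1,
):
    """Simulate each subject with and without the PC pathway.

    Returns ``(metrics_df, traces)``; ``metrics_df`` has two rows per subject
    plus one ``control`` row per pathway, with ``exceeds_*`` flags computed
    against the same-pathway control.  ``traces`` maps pathway ->
    {subject_id -> thrombin trace} (thrombin traces only, kept when
    ``keep_traces``; the control trace is always kept).
    """
    arms = {
        "with_pc": (select_submodel(model, True), config),
        "without_pc": (select_submodel(model, False), replace(config, include_pc=False)),
    }
    rows: list[dict] = []
    traces: dict[str, dict[str, np.ndarray]] = {p: {} for p in PATHWAYS}
    controls = {}
    for pathway, (arm_model, arm_config) in arms.items():
        tc = simulate(arm_model, control, arm_config)
        controls[pathway] = _metrics_row(control.subject_id, pathway, tc)
        traces[pathway][control.subject_id] = tc.thrombin

    comps = cohort_to_compositions(cohort)
    failures: list[tuple[str, str]] = []
    n_total = len(comps) * len(arms)
    for i, comp in enumerate(comps):
        for pathway, (arm_model, arm_config) in arms.items():
            try:
                tc = simulate(arm_model, comp, arm_config)
            except SimulationError as exc:
                log.error("subject %s (%s): %s", comp.subject_id, pathway, exc)
                failures.append((comp.subject_id, str(exc)))
                continue
            rows.append(_metrics_row(comp.subject_id, pathway, tc))
            if keep_traces:
                traces[pathway][comp.subject_id] = tc.thrombin
        log.debug("simulated %d/%d subjects", i + 1, len(comps))
    if n_total and len(failures) > max_failure_fraction * n_total:
        raise SimulationError(
            f"{len(failures)}/{n_total} simulations failed; first: {failures[0]}"
        )

    for pathway in PATHWAYS:
        rows.append({**controls[pathway], "is_control": True})
    df = pd.DataFrame(rows)
    if "is_control" in df.columns:
        df["is_control"] = df["is_control"].notna() & df["is_control"].astype(object).eq(True)
    else:
        df["is_control"] = False

    ctrl_metrics = {p: _row_to_metrics(controls[p]) for p in PATHWAYS}
    for flag in ("MaxL", "MaxR", "AUC", "CT"):
        df[f"exceeds_{flag}"] = [
            exceeds_control(_row_to_metrics(row), ctrl_metrics[row["pathway"]])[flag]
            if not row["is_control"]
            else False
            for _, row in df.iterrows()
        ]
    return df, traces


def summarize_groups(
    metrics_df: pd.DataFrame,
    cohort: CohortTable,
    stratifier: str,
    *,
    by_sex: bool = False,
    pathway: str = "with_pc",
    metrics: tuple[str, ...] = ("CT_s", "MaxR_nM_per_s", "MaxL_nM", "AUC_uM_s"),
) -> pd.DataFrame:
    """Per-group mean (SD) of thrombogram parameters, optionally within sex strata.

    Output layout: one row per (stratum, group, metric) with columns
    stratifier, stratum, group, n, metric, mean, sd, p_value (NaN placeholder
    filled by the statistics stage).
    """
    if stratifier not in cohort.df.columns:
        raise ValueError(f"unknown stratifier {stratifier!r}")
    merged = metrics_df[~metrics_df["is_control"]].query("pathway == @pathway").merge(
        cohort.df[["subject_id", "sex", stratifier]], on="subject_id", how="inner"
    )
    strata = [("all", merged)]
    if by_sex:
        strata += [(sex, merged[merged["sex"] == sex]) for sex in sorted(merged["sex"].unique())]
    rows = []
    for stratum_name, stratum_df in strata:
        for group, gdf in stratum_df.groupby(stratifier, dropna=False):
            for metric in metrics:
                vals = gdf[metric].dropna()
                rows.append(
                    {
                        "stratifier": stratifier,
                        "stratum": stratum_name,
                        "group": group,
                        "n": len(gdf),
                        "metric": metric,
                        "mean": float(vals.mean()) if len(vals) else np.nan,
                        "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                        "p_value": np.nan,
                    }
                )
    return pd.DataFrame(rows)


def envelope_curves(traces_by_group: dict[str, list[np.ndarray]], time: np.ndarray) -> pd.DataFrame:
    """Pointwise mean and SD thrombin trace per group, on the common grid."""
    n = len(time)
    data = {"time_s": np.asarray(time, dtype=float)}
    for group, traces in traces_by_group.items():
        if not traces:
            continue
        arr = np.vstack([np.asarray(t, dtype=float) for t in traces])
        if arr.shape[1] != n:
            raise ValueError(f"group {group!r}: trace length {arr.shape[1]} != grid {n}")
        data[f"{group}_mean_nM"] = arr.mean(axis=0)
        data[f"{group}_sd_nM"] = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros(n)
    return pd.DataFrame(data)
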