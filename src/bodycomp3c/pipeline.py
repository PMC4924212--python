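"""Config-driven pipeline: simulate -> tbw -> compose -> agree -> classify.

Produces per-stage CSVs plus a consolidated report: a cohort summary table
(mean +/- SD and range per variable per method), an agreement block per
compared variable, and a tertile classification block.  Machine-readable
outputs keep full precision; the text report rounds to a configurable number
of decimals (default 1) at presentation time only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .body_composition import (
    METHOD_3C,
    METHOD_BIA,
    compose_cohort,
    paired_variable,
)
from .classification import ClassificationTable, classify, format_table
from .errors import ConfigurationError, SchemaError
from .method_agreement import AgreementSummary, PairedSample, summarize_agreement
from .synthetic_cohort import CohortConfig, generate_cohort, write_cohort

logger = logging.getLogger("bodycomp3c")

VALID_VARIABLES = ("bf_pct", "fm_kg", "ffm_kg", "fmi", "ffmi")

VARIABLE_UNITS = {
    "bf_pct": "%",
    "fm_kg": "kg",
    "ffm_kg": "kg",
    "fmi": "kg/m^2",
    "ffmi": "kg/m^2",
    "bmi": "kg/m^2",
}


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration: either a cohort CSV to load or a simulation."""

    cohort_csv: str | None = None
    simulate: CohortConfig | None = None
    variables: tuple[str, ...] = ("bf_pct", "fm_kg", "ffm_kg")
    n_groups: int = 3
    decimals: int = 1
    exclude_flagged: bool = False
    out_dir: str = "."

    def __post_init__(self) -> None:
        if (self.cohort_csv is None) == (self.simulate is None):
            raise ConfigurationError(
                "exactly one of cohort_csv or simulate must be given"
            )
        bad = [v for v in self.variables if v not in VALID_VARIABLES]
        if bad:
            raise ConfigurationError(
                f"unknown variables {bad}; choose from {VALID_VARIABLES}"
            )
        if self.n_groups < 2:
            raise ConfigurationError("n_groups must be >= 2")


def load_run_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from TOML; a [simulate] table maps to CohortConfig."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    sim = data.pop("simulate", None)
    if sim is not None:
        sim = CohortConfig(**sim)
    if "variables" in data:
        data["variables"] = tuple(data["variables"])
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(simulate=sim, **data)


def load_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Load and validate a cohort CSV (schema errors name the column and file)."""
    df = pd.read_csv(path)
    required = ["id", "weight_kg", "height_cm", "bia_bf_pct", "bv_l"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if not ("tbw_kg" in df.columns or {"nd_kg", "no_kg"} <= set(df.columns)):
        raise SchemaError(f"{path}: need tbw_kg or both nd_kg and no_kg columns")
    for col in ["weight_kg", "height_cm", "bia_bf_pct", "bv_l"]:
        bad = df.index[~np.isfinite(df[col].to_numpy(dtype=float))].tolist()
        if bad:
            raise SchemaError(f"{path}: non-finite {col} at rows {bad}")
    return df


def summary_table(results: pd.DataFrame) -> pd.DataFrame:
    """Mean, SD, min, max per variable per method (cohort characteristics)."""
    rows = []
    for method in (METHOD_BIA, METHOD_3C):
        sub = results[results["method"] == method]
        for var in ["bf_pct", "fm_kg", "ffm_kg", "fmi", "ffmi", "bmi"]:
            x = sub[var].to_numpy(dtype=float)
            rows.append(
                {
                    "method": method,
                    "variable": var,
                    "mean": float(np.mean(x)),
                    "sd": float(np.std(x, ddof=1)),
                    "min": float(np.min(x)),
                    "max": float(np.max(x)),
                }
            )
    return pd.DataFrame(rows)


def agreement_for_variable(results: pd.DataFrame, variable: str) -> AgreementSummary:
    test, ref = paired_variable(results, variable)
    sample = PairedSample(
        variable=variable,
        test_values=test,
        ref_values=ref,
        units=VARIABLE_UNITS.get(variable, ""),
    )
    return summarize_agreement(sample)


def _fmt(x: float, decimals: int) -> str:
    return "nan" if not np.isfinite(x) else f"{x:.{decimals}f}"


def render_report(
    summary: pd.DataFrame,
    agreements: dict[str, AgreementSummary],
    tables: dict[str, ClassificationTable],
    decimals: int = 1,
) -> str:
    """Human-readable consolidated report (rounded at presentation only)."""
    d = decimals
    lines = ["Cohort summary (mean +/- SD, range)", ""]
    for method in (METHOD_BIA, METHOD_3C):
        lines.append(f"  {method}:")
        sub = summary[summary["method"] == method]
        for row in sub.itertuples(index=False):
            lines.append(
                f"    {row.variable:<7} {_fmt(row.mean, d)} +/- {_fmt(row.sd, d)}"
                f"  ({_fmt(row.min, d)}-{_fmt(row.max, d)})"
            )
    lines.append("")
    for var, a in agreements.items():
        lines += [
            f"Agreement for {var} ({a.units}), BIA vs 3C, n={a.n}:",
            f"  mean difference (BIA - 3C): {_fmt(a.mean_diff, d)}"
            f"  (paired t = {_fmt(a.paired_t, 2)}, p = {a.paired_p:.3g})",
            f"  limits of agreement (+/-2SD): {_fmt(a.loa_lower, d)} to"
            f" {_fmt(a.loa_upper, d)} (half-width {_fmt(a.loa_half_width, d)})",
            f"  trend diff~avg: slope {_fmt(a.trend_slope, 3)},"
            f" r = {_fmt(a.trend_r, 3)}, p = {a.trend_p:.3g}",
            f"  Pearson r = {_fmt(a.pearson_r, 3)} (p = {a.pearson_p:.3g})",
            f"  calibration (3C on BIA): y = {_fmt(a.reg_intercept, 3)} +"
            f" {_fmt(a.reg_slope, 3)}x, R^2 = {_fmt(a.reg_r2, 3)},"
            f" SEE = {_fmt(a.reg_see, 2)}",
            "",
        ]
    for var, t in tables.items():
        lines.append(format_table(t, variable=var))
        lines.append("")
    return "\n".join(lines)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline, writing stage outputs under ``config.out_dir``.

    Returns the report as a JSON-serialisable dict; also writes
    ``cohort.csv`` (when simulating), ``results.csv``, ``agreement.json``,
    ``classification.json`` and ``report.txt``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("bodycomp3c %s", __version__)

    if config.simulate is not None:
        cohort = generate_cohort(config.simulate)
        records = cohort.records
        write_cohort(cohort, out / "cohort.csv", out / "cohort_truth.csv")
        logger.info(
            "simulated cohort: n=%d seed=%d", config.simulate.n, config.simulate.seed
        )
    else:
        records = load_cohort_csv(config.cohort_csv)
        logger.info("loaded cohort %s: n=%d rows", config.cohort_csv, len(records))

    results = compose_cohort(records)
    if config.exclude_flagged:
        flagged_ids = set(results.loc[results["flags"] != "", "id"])
        if flagged_ids:
            logger.info("excluding %d flagged subjects", len(flagged_ids))
            results = results[~results["id"].isin(flagged_ids)].reset_index(drop=True)
    results.to_csv(out / "results.csv", index=False)

    summary = summary_table(results)
    summary.to_csv(out / "summary.csv", index=False)

    agreements = {v: agreement_for_variable(results, v) for v in config.variables}
    with open(out / "agreement.json", "w") as fh:
        json.dump(
            {v: dataclasses.asdict(a) for v, a in agreements.items()},
            fh,
            indent=2,
            default=list,
        )

    tables: dict[str, ClassificationTable] = {}
    for var in config.variables:
        test, ref = paired_variable(results, var)
        tables[var] = classify(test, ref, config.n_groups)
    with open(out / "classification.json", "w") as fh:
        json.dump(
            {
                v: {
                    **dataclasses.asdict(t),
                    "offset_counts": {str(k): c for k, c in t.offset_counts.items()},
                }
                for v, t in tables.items()
            },
            fh,
            indent=2,
            default=list,
        )

    text = render_report(summary, agreements, tables, config.decimals)
    (out / "report.txt").write_text(text)
    logger.info("report written to %s", out / "report.txt")

    return {
        "n_subjects": int(results["id"].nunique()),
        "summary": summary.to_dict(orient="records"),
        "agreement": {v: dataclasses.asdict(a) for v, a in agreements.items()},
        "classification": {
            v: {
                **dataclasses.asdict(t),
                "offset_counts": {str(k): c for k, c in t.offset_counts.items()},
            }
            for v, t in tables.items()
        },
    }
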