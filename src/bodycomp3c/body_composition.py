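"""Fat mass, fat-free mass and derived indices under the 3C and BIA methods.

The three-component (3C) model partitions body weight into fat, water and dry
fat-free mass from measured body volume (air-displacement plethysmography) and
total body water (isotope dilution):

    FM (kg) = 2.220 * BV - 0.764 * TBW - 1.465 * BW

with BV in litres, TBW and BW in kg.  Because TBW is measured rather than
assumed, the model is free of the hydration-of-FFM assumption that limits
two-component methods and serves as the criterion here.

The BIA (test) method supplies a body-fat percentage directly; FM is
BF%/100 * weight and FFM the remainder.  Both methods share the derived
indices BMI, FMI and FFMI (mass / height-in-m squared).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, MissingFieldError, SchemaError
from .isotope_tbw import ND_DIVISOR, ND_NO_RATIO_BAND, NO_DIVISOR, tbw_from_spaces

# 3C model coefficients (BV in L, TBW and BW in kg)
C_BV = 2.220
C_TBW = 0.764
C_BW = 1.465

METHOD_BIA = "BIA"
METHOD_3C = "3C"

#: quality-flag threshold: a body-fat percentage above this is physiologically
#: implausible for a healthy pediatric cohort and marks inconsistent inputs
BF_PCT_FLAG_THRESHOLD = 60.0


@dataclass(frozen=True)
class SubjectRecord:
    """One child's measured inputs.

    ``tbw`` may be given directly, or via both dilution spaces ``nd``/``no``
    (kg), from which it is derived.  ``bv`` is the final thoracic-gas-corrected
    body volume in litres.
    """

    id: str
    weight: float  # kg
    height: float  # cm
    sex: str = ""
    age: float = float("nan")  # years
    bia_bf_pct: float | None = None
    bv: float | None = None
    nd: float | None = None
    no: float | None = None
    tbw: float | None = None

    def __post_init__(self) -> None:
        if not self.weight > 0 or not self.height > 0:
            raise DomainError("weight and height must be > 0")
        if self.bia_bf_pct is not None and not 0 < self.bia_bf_pct < 100:
            raise DomainError("bia_bf_pct must lie in (0, 100)")
        if self.bv is not None and not self.bv > 0:
            raise DomainError("bv must be > 0 when present")


@dataclass(frozen=True)
class CompositionResult:
    """FM/FFM/BF% and indices for one subject under one method."""

    method: str
    fm: float  # kg
    ffm: float  # kg
    bf_pct: float
    bmi: float  # kg/m^2
    fmi: float  # kg/m^2
    ffmi: float  # kg/m^2
    flags: tuple[str, ...] = ()


def fm_3c(bv: float, tbw: float, bw: float) -> float:
    """Three-component-model fat mass (kg).

    ``fm = 2.220*bv - 0.764*tbw - 1.465*bw``.  May be negative for mutually
    inconsistent inputs; callers flag rather than clamp.
    """
    if not (bv > 0 and tbw > 0 and bw > 0):
        raise DomainError("bv, tbw and bw must all be > 0")
    return C_BV * bv - C_TBW * tbw - C_BW * bw


def composition_from_bf(
    bf_pct: float, bw: float, height: float, method: str = METHOD_BIA
) -> CompositionResult:
    """Composition from a body-fat percentage (the BIA route).

    FM = BF%/100 * weight; FFM = weight - FM; indices use height in metres.
    """
    if not 0 <= bf_pct < 100:
        raise DomainError("bf_pct must lie in [0, 100)")
    if not (bw > 0 and height > 0):
        raise DomainError("bw and height must be > 0")
    h_m = height / 100.0
    fm = bf_pct / 100.0 * bw
    ffm = bw - fm
    return CompositionResult(
        method=method,
        fm=fm,
        ffm=ffm,
        bf_pct=bf_pct,
        bmi=bw / h_m**2,
        fmi=fm / h_m**2,
        ffmi=ffm / h_m**2,
    )


def composition_3c(record: SubjectRecord) -> CompositionResult:
    """Criterion composition for one subject: TBW -> 3C fat mass -> indices.

    Requires ``bv`` and either ``tbw`` or both dilution spaces.  Negative FM
    or BF% above 60 is flagged on the result, never clamped.
    """
    if record.bv is None:
        raise MissingFieldError(f"subject {record.id!r}: body volume (bv) is missing")
    flags: list[str] = []
    if record.tbw is not None:
        tbw = record.tbw
    elif record.nd is not None and record.no is not None:
        res = tbw_from_spaces(record.nd, record.no)
        tbw = res.tbw
        if res.ratio_flagged:
            flags.append("nd_no_ratio")
    else:
        raise MissingFieldError(
            f"subject {record.id!r}: need tbw or both dilution spaces (nd, no)"
        )
    fm = fm_3c(record.bv, tbw, record.weight)
    ffm = record.weight - fm
    bf_pct = 100.0 * fm / record.weight
    if fm < 0:
        flags.append("negative_fm")
    if bf_pct > BF_PCT_FLAG_THRESHOLD:
        flags.append("implausible_bf_pct")
    h_m = record.height / 100.0
    return CompositionResult(
        method=METHOD_3C,
        fm=fm,
        ffm=ffm,
        bf_pct=bf_pct,
        bmi=record.weight / h_m**2,
        fmi=fm / h_m**2,
        ffmi=ffm / h_m**2,
        flags=tuple(flags),
    )


COHORT_COLUMNS = [
    "id",
    "sex",
    "age_y",
    "weight_kg",
    "height_cm",
    "bia_bf_pct",
    "bv_l",
    "nd_kg",
    "no_kg",
]

RESULT_COLUMNS = [
    "id",
    "method",
    "fm_kg",
    "ffm_kg",
    "bf_pct",
    "fmi",
    "ffmi",
    "bmi",
    "flags",
]


def compose_cohort(records: pd.DataFrame) -> pd.DataFrame:
    """Vectorised two-method composition for a whole cohort.

    Input: the cohort CSV schema (``id, sex, age_y, weight_kg, height_cm,
    bia_bf_pct, bv_l, nd_kg, no_kg``; a ``tbw_kg`` column may replace the two
    dilution spaces).  Output: long format, one row per subject per method,
    with a semicolon-joined ``flags`` column.
    """
    required = ["id", "weight_kg", "height_cm", "bia_bf_pct", "bv_l"]
    missing = [c for c in required if c not in records.columns]
    if missing:
        raise SchemaError(f"cohort table is missing columns: {missing}")

    w = records["weight_kg"].to_numpy(dtype=float)
    h_m = records["height_cm"].to_numpy(dtype=float) / 100.0
    if np.any(w <= 0) or np.any(h_m <= 0):
        bad = records.index[(w <= 0) | (h_m <= 0)].tolist()
        raise DomainError(f"non-positive weight or height at rows {bad}")

    if "tbw_kg" in records.columns:
        tbw = records["tbw_kg"].to_numpy(dtype=float)
        ratio_flag = np.zeros(len(records), dtype=bool)
    elif "nd_kg" in records.columns and "no_kg" in records.columns:
        nd = records["nd_kg"].to_numpy(dtype=float)
        no = records["no_kg"].to_numpy(dtype=float)
        if np.any(nd <= 0) or np.any(no <= 0):
            raise DomainError("dilution spaces must be > 0")
        tbw = (nd / ND_DIVISOR + no / NO_DIVISOR) / 2.0
        ratio = nd / no
        ratio_flag = (ratio < ND_NO_RATIO_BAND[0]) | (ratio > ND_NO_RATIO_BAND[1])
    else:
        raise SchemaError("need tbw_kg or both nd_kg and no_kg columns")

    bv = records["bv_l"].to_numpy(dtype=float)
    bia_bf = records["bia_bf_pct"].to_numpy(dtype=float)

    fm3 = C_BV * bv - C_TBW * tbw - C_BW * w
    ffm3 = w - fm3
    bf3 = 100.0 * fm3 / w
    fm_b = bia_bf / 100.0 * w
    ffm_b = w - fm_b

    def flags_3c(i: int) -> str:
        f = []
        if ratio_flag[i]:
            f.append("nd_no_ratio")
        if fm3[i] < 0:
            f.append("negative_fm")
        if bf3[i] > BF_PCT_FLAG_THRESHOLD:
            f.append("implausible_bf_pct")
        return ";".join(f)

    bia = pd.DataFrame(
        {
            "id": records["id"],
            "method": METHOD_BIA,
            "fm_kg": fm_b,
            "ffm_kg": ffm_b,
            "bf_pct": bia_bf,
            "fmi": fm_b / h_m**2,
            "ffmi": ffm_b / h_m**2,
            "bmi": w / h_m**2,
            "flags": "",
        }
    )
    crit = pd.DataFrame(
        {
            "id": records["id"],
            "method": METHOD_3C,
            "fm_kg": fm3,
            "ffm_kg": ffm3,
            "bf_pct": bf3,
            "fmi": fm3 / h_m**2,
            "ffmi": ffm3 / h_m**2,
            "bmi": w / h_m**2,
            "flags": [flags_3c(i) for i in range(len(records))],
        }
    )
    out = pd.concat([bia, crit], ignore_index=True)
    return out[RESULT_COLUMNS]


def paired_variable(results: pd.DataFrame, variable: str) -> tuple[np.ndarray, np.ndarray]:
    """Extract aligned (BIA, 3C) arrays for one variable from long-format results."""
    if variable not in results.columns:
        raise SchemaError(f"unknown variable {variable!r}")
    wide = results.pivot(index="id", columns="method", values=variable)
    if METHOD_BIA not in wide.columns or METHOD_3C not in wide.columns:
        raise SchemaError("results must contain both BIA and 3C rows")
    wide = wide.dropna()
    return wide[METHOD_BIA].to_numpy(), wide[METHOD_3C].to_numpy()
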