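"""Total body water from doubly-labelled-water urine enrichments.

The tracer protocol: a weighed oral dose of labelled water (deuterium and/or
oxygen-18) equilibrates with the body water pool, then washes out
exponentially through water turnover.  Post-dose urine enrichments (excess
mole fraction of label above the pre-dose baseline) therefore follow

    E(t) = E0 * exp(-k t)

and ordinary least squares on ln E(t) vs t recovers the zero-time enrichment
E0 (back-extrapolated to dosing) and the elimination rate k (per day).

The apparent volume of distribution of each tracer — the dilution space — is
obtained from E0 by the plateau principle: the moles of body water that would
dilute the dose to E0.  Dilution spaces exceed total body water because both
tracers exchange with non-aqueous hydrogen/oxygen; the standard corrections
divide the deuterium space by 1.041 and the oxygen-18 space by 1.007, and TBW
is the average of the two corrected spaces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import DomainError, InsufficientDataError, SchemaError

#: molar mass of water, kg/mol (isotopic differences in dose mass are handled
#: upstream when converting dose grams to moles of labelled water)
WATER_MOLAR_MASS_KG = 0.018015

#: dilution-space-to-TBW divisors for deuterium and oxygen-18
ND_DIVISOR = 1.041
NO_DIVISOR = 1.007

#: plausibility band for the N_D/N_O ratio: 1.039 +/- 3 * 0.008
ND_NO_RATIO_BAND = (1.015, 1.063)

DEUTERIUM = "deuterium"
OXYGEN18 = "oxygen-18"


@dataclass(frozen=True)
class EnrichmentSeries:
    """Post-dose urine enrichments for one subject and one tracer.

    Parameters
    ----------
    isotope:
        ``"deuterium"`` or ``"oxygen-18"``.
    times:
        Sampling times in days since dosing, strictly increasing, >= 2 points.
    enrichments:
        Excess mole fraction of label above the pre-dose baseline
        (dimensionless, strictly positive).
    dose_mol:
        Moles of labelled water administered.
    """

    isotope: str
    times: np.ndarray
    enrichments: np.ndarray
    dose_mol: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        enr = np.asarray(self.enrichments, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "enrichments", enr)
        if self.isotope not in (DEUTERIUM, OXYGEN18):
            raise DomainError(f"unknown isotope label: {self.isotope!r}")
        if times.ndim != 1 or times.shape != enr.shape:
            raise SchemaError("times and enrichments must be 1-D and equal length")
        if len(times) < 2:
            raise InsufficientDataError(
                "at least 2 post-dose enrichment points are required"
            )
        if np.any(np.diff(times) <= 0):
            raise DomainError("sampling times must be strictly increasing")
        if np.any(enr <= 0) or not np.all(np.isfinite(enr)):
            raise DomainError("enrichments must be finite and > 0")
        if not self.dose_mol > 0:
            raise DomainError("dose_mol must be > 0")


@dataclass(frozen=True)
class DilutionResult:
    """Zero-time enrichment, elimination rate and dilution space for one tracer."""

    isotope: str
    e_zero: float
    k: float
    n_space: float  # kg of water

    def __post_init__(self) -> None:
        if not self.e_zero > 0:
            raise DomainError("e_zero must be > 0")
        if not self.n_space > 0:
            raise DomainError("n_space must be > 0")


class TbwResult(NamedTuple):
    """Two-space-average TBW plus the N_D/N_O quality ratio."""

    tbw: float  # kg
    ratio: float  # N_D / N_O, dimensionless
    ratio_flagged: bool  # True when ratio falls outside the 1.039 +/- 3 SD band


def fit_zero_time_enrichment(series: EnrichmentSeries) -> tuple[float, float]:
    """Back-extrapolate the exponential disappearance curve to dosing time.

    Unweighted OLS of ln(enrichment) on time; returns ``(e_zero, k)`` with
    ``e_zero = exp(intercept)`` and ``k = -slope`` (per day).  Exact for
    noiseless exponential data.
    """
    slope, intercept = np.polyfit(series.times, np.log(series.enrichments), 1)
    return float(math.exp(intercept)), float(-slope)


def dilution_space(e_zero: float, dose_mol: float) -> float:
    """Dilution space in kg water from zero-time enrichment and dose.

    Plateau principle: the dose is diluted into ``n_mol`` moles of body water
    such that the label's mole fraction is ``e_zero``, i.e.
    ``n_mol = dose_mol * (1/e_zero - 1)``, converted to kg with the molar
    mass of water.  Strictly decreasing in ``e_zero``.
    """
    if not e_zero > 0 or not dose_mol > 0:
        raise DomainError("e_zero and dose_mol must be > 0")
    if e_zero >= 1:
        raise DomainError("e_zero must be < 1 (excess mole fraction)")
    return dose_mol * (1.0 / e_zero - 1.0) * WATER_MOLAR_MASS_KG


def space_to_e_zero(n_space_kg: float, dose_mol: float) -> float:
    """Inverse of :func:`dilution_space`: enrichment produced by a known space."""
    if not n_space_kg > 0 or not dose_mol > 0:
        raise DomainError("n_space_kg and dose_mol must be > 0")
    n_mol = n_space_kg / WATER_MOLAR_MASS_KG
    return 1.0 / (n_mol / dose_mol + 1.0)


def tbw_from_spaces(n_d: float, n_o: float) -> TbwResult:
    """Average the corrected dilution spaces into total body water (kg).

    ``tbw = (N_D/1.041 + N_O/1.007) / 2``.  The returned ratio ``N_D/N_O`` is
    flagged when it falls outside [1.015, 1.063], i.e. more than 3 SD from the
    physiological 1.039 +/- 0.008.
    """
    if not n_d > 0 or not n_o > 0:
        raise DomainError("dilution spaces must be > 0")
    tbw = (n_d / ND_DIVISOR + n_o / NO_DIVISOR) / 2.0
    ratio = n_d / n_o
    flagged = not (ND_NO_RATIO_BAND[0] <= ratio <= ND_NO_RATIO_BAND[1])
    return TbwResult(tbw=tbw, ratio=ratio, ratio_flagged=flagged)


def process_series(series: EnrichmentSeries) -> DilutionResult:
    """Fit one enrichment series and convert to a dilution space."""
    e_zero, k = fit_zero_time_enrichment(series)
    n_space = dilution_space(e_zero, series.dose_mol)
    return DilutionResult(isotope=series.isotope, e_zero=e_zero, k=k, n_space=n_space)


def synthesize_series(
    n_space_kg: float,
    dose_mol: float,
    k: float,
    times: np.ndarray,
    isotope: str = DEUTERIUM,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> EnrichmentSeries:
    """Generate an enrichment series consistent with a known dilution space.

    The zero-time enrichment is the exact inverse of :func:`dilution_space`,
    so the noiseless fit -> space round trip is an algebraic identity.
    ``noise_sd`` applies multiplicative lognormal noise (sd on the log scale).
    """
    times = np.asarray(times, dtype=float)
    e_zero = space_to_e_zero(n_space_kg, dose_mol)
    enr = e_zero * np.exp(-k * times)
    if noise_sd > 0:
        if rng is None:
            raise DomainError("rng is required when noise_sd > 0")
        enr = enr * np.exp(rng.normal(0.0, noise_sd, size=times.shape))
    return EnrichmentSeries(
        isotope=isotope, times=times, enrichments=enr, dose_mol=dose_mol
    )


ENRICHMENT_COLUMNS = [
    "subject_id",
    "isotope",
    "time_days",
    "excess_mole_fraction",
    "dose_mol",
]


def tbw_table(enrichments: pd.DataFrame) -> pd.DataFrame:
    """Per-subject N_D, N_O, ratio and TBW from a long-format enrichment table.

    Expects columns ``subject_id, isotope, time_days, excess_mole_fraction,
    dose_mol`` with one row per urine sample; both tracers must be present for
    every subject.
    """
    missing = [c for c in ENRICHMENT_COLUMNS if c not in enrichments.columns]
    if missing:
        raise SchemaError(f"enrichment table is missing columns: {missing}")
    rows = []
    for subject_id, sub in enrichments.groupby("subject_id", sort=True):
        spaces: dict[str, DilutionResult] = {}
        for isotope, grp in sub.groupby("isotope"):
            grp = grp.sort_values("time_days")
            dose = float(grp["dose_mol"].iloc[0])
            series = EnrichmentSeries(
                isotope=str(isotope),
                times=grp["time_days"].to_numpy(),
                enrichments=grp["excess_mole_fraction"].to_numpy(),
                dose_mol=dose,
            )
            spaces[str(isotope)] = process_series(series)
        if DEUTERIUM not in spaces or OXYGEN18 not in spaces:
            raise MissingIsotope(subject_id, sorted(spaces))
        res = tbw_from_spaces(spaces[DEUTERIUM].n_space, spaces[OXYGEN18].n_space)
        rows.append(
            {
                "id": subject_id,
                "nd_kg": spaces[DEUTERIUM].n_space,
                "no_kg": spaces[OXYGEN18].n_space,
                "k_d_per_day": spaces[DEUTERIUM].k,
                "k_o_per_day": spaces[OXYGEN18].k,
                "nd_no_ratio": res.ratio,
                "ratio_flagged": res.ratio_flagged,
                "tbw_kg": res.tbw,
            }
        )
    return pd.DataFrame(rows)


class MissingIsotope(SchemaError):
    def __init__(self, subject_id, present):
        super().__init__(
            f"subject {subject_id!r}: need both tracers, found only {present}"
        )
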