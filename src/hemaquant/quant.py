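"""Serial-dilution mass bookkeeping, HAU titers, ELISA curves, exposure dose.

The dilution model: a two-fold (generally f-fold) serial dilution retains a
fixed volume per well, so well n holds ``start_conc * volume / f**(n-1)`` ng
of analyte (well 1 undiluted).  The hemagglutination titer (HAU) is the
reciprocal of the last agglutinating dilution, ``f**(last_positive - 1)``.
Given the smallest detectable analyte amount theta (default 200 ng), the
active-lectin concentration of a powder extract is estimated as theta
divided by the powder mass in the first negative well, scaled to mg per g.

ELISA quantitation fits a linear standard curve (absorbance = a + b*ng) by
ordinary least squares with a t-based 95% CI on the slope, back-calculates
ng per well, and converts to mg analyte per g dry powder.  An exposure dose
is simply concentration times the dry mass consumed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .errors import FitError, QuantitationError

__all__ = [
    "DilutionSeries",
    "HemagglutinationQuant",
    "StandardCurve",
    "ElisaResult",
    "ExposureDose",
    "DEFAULT_THETA_NG",
    "DEFAULT_LLOQ_NG",
    "amount_in_well",
    "hau_from_well",
    "pha_conc_hemagglutination",
    "fit_standard_curve",
    "elisa_conc",
    "exposure_dose",
    "reduction_ratio",
]

#: Smallest analyte amount (ng) producing detectable agglutination.
DEFAULT_THETA_NG = 200.0
#: ELISA lower limit of quantification (ng analyte per well).
DEFAULT_LLOQ_NG = 15.0


@dataclass(frozen=True)
class DilutionSeries:
    """A serial dilution with retained volume.

    ``start_conc_ng_per_ul`` is the concentration loaded into well 1 — of
    purified analyte, or of *powder* for a w/v extract (10% w/v = 100 mg/mL
    = 100,000 ng powder per µL).  100 µL is retained per well after each
    transfer.
    """

    start_conc_ng_per_ul: float
    retained_volume_ul: float = 100.0
    dilution_factor: float = 2.0
    n_wells: int = 12
    first_well_undiluted: bool = True

    def __post_init__(self) -> None:
        if self.start_conc_ng_per_ul <= 0:
            raise ValueError("start concentration must be positive")
        if self.dilution_factor <= 1:
            raise ValueError("dilution factor must exceed 1")
        if self.retained_volume_ul <= 0:
            raise ValueError("retained volume must be positive")
        if self.n_wells < 2:
            raise ValueError("a series needs at least 2 wells")

    @classmethod
    def from_w_over_v(cls, percent_w_v: float, **kwargs) -> "DilutionSeries":
        """Series for a w/v powder extract (10% w/v -> 100,000 ng powder/µL)."""
        return cls(start_conc_ng_per_ul=percent_w_v * 10_000.0, **kwargs)


@dataclass(frozen=True)
class HemagglutinationQuant:
    """Active-lectin concentration estimated from the agglutination endpoint."""

    min_detectable_ng: float
    powder_ng_first_negative: float
    conc_mg_per_g: float
    censored: bool = False  # True when the series never went negative

    @property
    def display(self) -> str:
        prefix = ">=" if self.censored else ""
        return f"{prefix}{self.conc_mg_per_g:.1f} mg/g"


@dataclass(frozen=True)
class StandardCurve:
    """Linear ELISA standard curve, absorbance = intercept + slope * ng."""

    slope_au_per_ng: float
    intercept_au: float
    slope_ci95: tuple[float, float]
    r2: float
    lloq_ng: float
    max_standard_ng: float
    slope_se: float
    df_resid: int


@dataclass(frozen=True)
class ElisaResult:
    """Back-calculated amount and concentration for one sample well."""

    ng_in_well: float
    conc_mg_per_g: float
    flags: tuple[str, ...]

    @property
    def censored_below_lloq(self) -> bool:
        return "below_lloq" in self.flags


@dataclass(frozen=True)
class ExposureDose:
    """Dose = concentration in the food times dry mass consumed."""

    conc_mg_per_g: float
    dry_mass_g: float
    dose_mg: float


def amount_in_well(series: DilutionSeries, well_index: int) -> float:
    """Analyte (or powder) mass in ng present in 1-based well ``well_index``."""
    if not 1 <= well_index <= series.n_wells:
        raise ValueError(
            f"well index {well_index} outside series of {series.n_wells} wells"
        )
    steps = well_index - 1 if series.first_well_undiluted else well_index
    return (
        series.start_conc_ng_per_ul
        * series.retained_volume_ul
        / series.dilution_factor**steps
    )


def hau_from_well(last_positive: int, dilution_factor: float = 2.0) -> float:
    """Titer from the last positive well: ``f ** (last_positive - 1)``."""
    if last_positive < 1:
        raise ValueError("last_positive must be >= 1")
    return float(dilution_factor) ** (last_positive - 1)


def pha_conc_hemagglutination(
    series: DilutionSeries,
    first_negative: int | None,
    theta_ng: float = DEFAULT_THETA_NG,
) -> HemagglutinationQuant:
    """Estimate active lectin in mg per g dry powder from the endpoint.

    The first negative well is the first dilution whose analyte content
    dropped below the minimum detectable amount theta, so
    ``theta / powder_in_first_negative`` bounds the active mass fraction;
    x1000 converts ng/ng to mg/g.  A series that never goes negative is
    right-censored: the estimate uses a hypothetical next dilution step and
    is reported as a lower bound.
    """
    if theta_ng <= 0:
        raise ValueError("theta must be positive")
    if first_negative is None:
        powder = amount_in_well(series, series.n_wells) / series.dilution_factor
        return HemagglutinationQuant(
            min_detectable_ng=theta_ng,
            powder_ng_first_negative=powder,
            conc_mg_per_g=theta_ng / powder * 1000.0,
            censored=True,
        )
    powder = amount_in_well(series, first_negative)
    return HemagglutinationQuant(
        min_detectable_ng=theta_ng,
        powder_ng_first_negative=powder,
        conc_mg_per_g=theta_ng / powder * 1000.0,
    )


def fit_standard_curve(
    amounts_ng: Sequence[float],
    absorbances: Sequence[float],
    lloq_ng: float = DEFAULT_LLOQ_NG,
) -> StandardCurve:
    """Ordinary least-squares standard curve with a 95% CI on the slope.

    Replicates enter the fit individually (they are not averaged per
    amount), which is visible in the residual degrees of freedom of the CI.

    Raises
    ------
    FitError
        Fewer than 3 distinct standard amounts, or all amounts identical.
    """
    x = np.asarray(list(amounts_ng), dtype=float)
    y = np.asarray(list(absorbances), dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise FitError("amounts and absorbances must be equal-length vectors")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise FitError("standard-curve inputs must be finite")
    if np.unique(x).size < 3:
        raise FitError("at least 3 distinct standard amounts are required")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = float(model.rsquared)
    return StandardCurve(
        slope_au_per_ng=float(model.params[1]),
        intercept_au=float(model.params[0]),
        slope_ci95=(float(ci[1, 0]), float(ci[1, 1])),
        r2=r2 if np.isfinite(r2) else 0.0,
        lloq_ng=float(lloq_ng),
        max_standard_ng=float(x.max()),
        slope_se=float(model.bse[1]),
        df_resid=int(model.df_resid),
    )


def elisa_conc(
    absorbance: float,
    curve: StandardCurve,
    dilution_factor: float,
    well_volume_ul: float = 100.0,
    extract_mg_powder_per_ul: float = 0.1,
) -> ElisaResult:
    """Back-calculate mg active lectin per g dry powder from one absorbance.

    ``ng_in_well = (absorbance - intercept) / slope``; the concentration in
    the original extract is ``ng_in_well / well_volume * dilution_factor``,
    and dividing by the powder load (mg powder per µL extract; 0.1 for a 10%
    w/v extract) and by 1000 yields mg analyte per g powder.

    Values below the LLOQ are censored ("below_lloq" flag; the returned
    concentration is the LLOQ-equivalent upper bound, not a measurement).
    Values above the top standard are flagged "above_max_standard" —
    extrapolation is refused as a quantitative result.
    """
    if curve.slope_au_per_ng <= 0:
        raise QuantitationError("standard-curve slope must be positive to quantify")
    if well_volume_ul <= 0 or extract_mg_powder_per_ul <= 0 or dilution_factor <= 0:
        raise ValueError("volumes, powder load and dilution factor must be positive")
    ng = (absorbance - curve.intercept_au) / curve.slope_au_per_ng
    flags: list[str] = []
    if ng < curve.lloq_ng:
        flags.append("below_lloq")
        ng_for_conc = curve.lloq_ng  # upper bound, censored
    elif ng > curve.max_standard_ng:
        flags.append("above_max_standard")
        ng_for_conc = ng
    else:
        ng_for_conc = ng
    conc = (
        ng_for_conc / well_volume_ul * dilution_factor / extract_mg_powder_per_ul / 1000.0
    )
    return ElisaResult(ng_in_well=float(ng), conc_mg_per_g=float(conc), flags=tuple(flags))


def exposure_dose(conc_mg_per_g: float, dry_mass_g: float) -> ExposureDose:
    """Exposure dose in mg: concentration (mg/g dry weight) x dry mass (g)."""
    if conc_mg_per_g < 0 or dry_mass_g < 0:
        raise ValueError("concentration and mass must be non-negative")
    return ExposureDose(
        conc_mg_per_g=conc_mg_per_g,
        dry_mass_g=dry_mass_g,
        dose_mg=conc_mg_per_g * dry_mass_g,
    )


def reduction_ratio(conc_processed: float, conc_raw: float) -> float:
    """Percent of the raw-product concentration remaining after processing."""
    if conc_raw <= 0:
        raise ValueError("raw concentration must be positive")
    if conc_processed < 0:
        raise ValueError("processed concentration must be non-negative")
    return 100.0 * conc_processed / conc_raw
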