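"""Tracer-clamp glucose kinetics, densitometric body composition, hepatic
lipid ratio, and weighted linear calibration for quantitative assays.

Tracer arithmetic uses steady-state dilution: with a constant tracer
infusion F at infusate enrichment E_inf, plasma enrichment E_p at plateau
satisfies  Ra_total = F * (E_inf / E_p - 1), so endogenous production is
the tracer-derived appearance minus any exogenous (infused) glucose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "ClampRecord",
    "DensitometryRecord",
    "CalibrationCurve",
    "GLUCOSE_MW_G_PER_MOL",
    "mg_to_umol",
    "umol_to_mg",
    "basal_egp_steele",
    "clamp_egp_suppressed",
    "rd_clamp",
    "adjust_metric",
    "body_composition",
    "ihl_fraction",
    "fit_calibration",
    "quantify",
    "D_FAT_DEFAULT",
    "DEFAULT_FFM_DENSITY",
]

GLUCOSE_MW_G_PER_MOL = 180.156


def mg_to_umol(mg: float) -> float:
    return mg * 1000.0 / GLUCOSE_MW_G_PER_MOL


def umol_to_mg(umol: float) -> float:
    return umol * GLUCOSE_MW_G_PER_MOL / 1000.0


@dataclass
class ClampRecord:
    """Steady-state tracer and infusion data for one participant-visit.

    Units: F in umol/kg/min (tracer), enrichments in mole percent excess
    (0-100), GIR in mg/kg/min, insulin in mU/L, FFM in kg, glucose in mg/dL.
    """

    tracer_rate_umol_kg_min: float
    infusate_enrichment_mpe: float
    basal_enrichment_mpe: float
    clamp_enrichment_mpe: float | None = None
    gir_mg_kg_min: float = 0.0
    insulin_mU_L: float | None = None
    ffm_kg: float | None = None
    glucose_mg_dl: float | None = None

    def __post_init__(self) -> None:
        if self.tracer_rate_umol_kg_min < 0:
            raise ValueError("tracer infusion rate must be >= 0")
        if not 0 < self.infusate_enrichment_mpe <= 100:
            raise ValueError("infusate enrichment must be in (0, 100] MPE")
        for name, e in (("basal", self.basal_enrichment_mpe), ("clamp", self.clamp_enrichment_mpe)):
            if e is not None and not 0 <= e <= self.infusate_enrichment_mpe:
                raise ValueError(
                    f"{name} plasma enrichment must satisfy 0 <= E_p <= E_inf, got {e}"
                )
        if self.gir_mg_kg_min < 0:
            raise ValueError("glucose infusion rate must be >= 0")
        if self.ffm_kg is not None and self.ffm_kg <= 0:
            raise ValueError("fat-free mass must be positive")
        if self.insulin_mU_L is not None and self.insulin_mU_L <= 0:
            raise ValueError("insulin must be positive")


def basal_egp_steele(rec: ClampRecord) -> float:
    """Basal endogenous glucose production (umol/kg/min), steady state.

    EGP = F * (E_inf / E_p_basal - 1): all non-tracer glucose appearing in
    the accessible pool at plateau is endogenous when nothing is infused.
    """
    if rec.basal_enrichment_mpe <= 0:
        raise ValueError("basal plasma enrichment is zero; no tracer dilution measurable")
    return rec.tracer_rate_umol_kg_min * (
        rec.infusate_enrichment_mpe / rec.basal_enrichment_mpe - 1.0
    )


def _default_suppression_strategy(rec: ClampRecord) -> float:
    """Clamp EGP (umol/kg/min): tracer-derived total Ra minus infused glucose.

    The GIR tracer-correction term is zero under an unlabeled exogenous
    infusate; the strategy is pluggable because the cited method is not
    restated algebraically in the source protocol.
    """
    ra_total = rec.tracer_rate_umol_kg_min * (
        rec.infusate_enrichment_mpe / rec.clamp_enrichment_mpe - 1.0
    )
    return max(0.0, ra_total - mg_to_umol(rec.gir_mg_kg_min))


def clamp_egp_suppressed(
    rec: ClampRecord,
    strategy: Callable[[ClampRecord], float] | None = None,
) -> tuple[float, float | None]:
    """Clamp-phase EGP and its percent suppression from basal.

    Returns ``(egp_clamp_umol_kg_min, suppression_pct)``; suppression is
    None (flagged with a warning) when basal EGP is zero.
    """
    if rec.clamp_enrichment_mpe is None or rec.clamp_enrichment_mpe <= 0:
        raise ValueError("clamp plasma enrichment must be positive")
    egp_basal = basal_egp_steele(rec)
    egp_clamp = (strategy or _default_suppression_strategy)(rec)
    egp_clamp = max(0.0, egp_clamp)
    if egp_basal == 0:
        warnings.warn("basal EGP is zero; suppression undefined")
        return egp_clamp, None
    return egp_clamp, 100.0 * (1.0 - egp_clamp / egp_basal)


def rd_clamp(rec: ClampRecord, strategy=None) -> float:
    """Glucose disposal rate Rd (mg/kg/min) at clamp steady state.

    Appearance equals disposal at plateau: Rd = GIR + EGP_clamp.
    """
    if rec.gir_mg_kg_min < 0:
        raise ValueError("negative glucose infusion rate")
    egp_clamp, _ = clamp_egp_suppressed(rec, strategy)
    return rec.gir_mg_kg_min + umol_to_mg(egp_clamp)


def adjust_metric(value: float, insulin_mU_L: float, ffm_kg: float) -> float:
    """Express a whole-body rate per kg fat-free mass per unit insulin."""
    if insulin_mU_L <= 0 or ffm_kg <= 0:
        raise ValueError("insulin and fat-free mass must be positive")
    return value / (insulin_mU_L * ffm_kg)


D_FAT_DEFAULT = 0.9007  # g/cm3

#: Stage-indexed fat-free-mass densities (g/cm3). The nonpregnant value is
#: the classical two-compartment constant; the pregnancy entries are
#: PLACEHOLDERS standing in for published gestational adjustments, supplied
#: here as a config table and overridable per record.
DEFAULT_FFM_DENSITY = {
    "nonpregnant": 1.100,
    "early": 1.099,
    "late": 1.093,
    "postwean": 1.100,
}


@dataclass
class DensitometryRecord:
    """Air-displacement densitometry inputs for one participant-visit."""

    body_mass_kg: float
    body_volume_L: float
    stage: str = "nonpregnant"
    d_fat: float = D_FAT_DEFAULT
    d_ffm: float | None = None
    ffm_density_table: dict = field(default_factory=lambda: dict(DEFAULT_FFM_DENSITY))

    def __post_init__(self) -> None:
        if self.body_mass_kg <= 0 or self.body_volume_L <= 0:
            raise ValueError("mass and volume must be positive")
        if self.d_ffm is None:
            try:
                self.d_ffm = self.ffm_density_table[self.stage]
            except KeyError:
                raise ValueError(
                    f"stage {self.stage!r} not in FFM density table and no d_ffm given"
                ) from None
        if not self.d_fat < self.d_ffm:
            raise ValueError("fat density must be below fat-free-mass density")


def body_composition(rec: DensitometryRecord) -> tuple[float, float, float]:
    """Two-compartment body composition from whole-body density.

    Db = mass/volume (g/cm3, since kg/L); fat fraction is the linear
    interpolation of 1/Db between the fat and fat-free densities. Returns
    ``(fat_percent, fat_mass_kg, ffm_kg)``; densities outside the physical
    bracket clamp the fraction to [0, 1] with a warning.
    """
    db = rec.body_mass_kg / rec.body_volume_L
    frac = (1.0 / db - 1.0 / rec.d_ffm) / (1.0 / rec.d_fat - 1.0 / rec.d_ffm)
    if not 0.0 <= frac <= 1.0:
        warnings.warn(
            f"body density {db:.4f} g/cm3 outside ({rec.d_fat}, {rec.d_ffm}); clamping"
        )
        frac = min(max(frac, 0.0), 1.0)
    fat_mass = frac * rec.body_mass_kg
    return 100.0 * frac, fat_mass, rec.body_mass_kg - fat_mass


def ihl_fraction(lipid_peak_area: float, water_peak_area: float) -> float:
    """Intrahepatic lipid: primary lipid peak area over water peak area."""
    if water_peak_area <= 0:
        raise ValueError("water peak area must be positive")
    if lipid_peak_area < 0:
        raise ValueError("lipid peak area must be nonnegative")
    return lipid_peak_area / water_peak_area


def ihl_from_series(lipid_areas, water_areas) -> float:
    """Mean of per-acquisition lipid/water ratios over repeated series."""
    lipid = np.asarray(lipid_areas, dtype=float)
    water = np.asarray(water_areas, dtype=float)
    if lipid.shape != water.shape or lipid.size == 0:
        raise ValueError("series must be paired and nonempty")
    return float(np.mean([ihl_fraction(l, w) for l, w in zip(lipid, water)]))


@dataclass(frozen=True)
class CalibrationCurve:
    """Weighted linear calibration: response = slope * conc + intercept."""

    slope: float
    intercept: float
    weighting: str = "1/x"
    range_min: float = 0.0
    range_max: float = np.inf

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be nonzero")
        if not self.range_min < self.range_max:
            raise ValueError("calibration range min must be below max")


def fit_calibration(
    concentrations, responses, weighting: str = "1/x"
) -> CalibrationCurve:
    """Weighted least-squares line through calibration standards.

    ``weighting`` is ``"1/x"`` (weights 1/concentration, the convention for
    heteroscedastic assay responses) or ``"none"``. Requires >= 3 standards;
    1/x weighting requires strictly positive concentrations.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.ndim != 1 or x.shape != y.shape or x.size < 3:
        raise ValueError("need >= 3 paired (concentration, response) standards")
    if np.ptp(x) == 0:
        raise ValueError("standards must span a concentration range")
    if weighting == "1/x":
        if np.any(x <= 0):
            raise ValueError("1/x weighting requires positive concentrations")
        w = 1.0 / x
    elif weighting in ("none", None):
        w = np.ones_like(x)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    # closed-form WLS for a straight line
    sw = w.sum()
    xbar = (w * x).sum() / sw
    ybar = (w * y).sum() / sw
    sxx = (w * (x - xbar) ** 2).sum()
    if sxx == 0:
        raise ValueError("degenerate design: zero weighted variance in x")
    slope = (w * (x - xbar) * (y - ybar)).sum() / sxx
    intercept = ybar - slope * xbar
    return CalibrationCurve(
        slope=slope,
        intercept=intercept,
        weighting=weighting if weighting else "none",
        range_min=float(x.min()),
        range_max=float(x.max()),
    )


def quantify(curve: CalibrationCurve, peak_ratio: float) -> tuple[float, bool]:
    """Back-calculate concentration from a response via the fitted line.

    Returns ``(concentration, in_range)`` where ``in_range`` is False when
    the back-calculated value falls outside the calibration range.
    """
    conc = (peak_ratio - curve.intercept) / curve.slope
    tol = 1e-9 * max(abs(curve.range_min), abs(curve.range_max), 1.0)
    in_range = curve.range_min - tol <= conc <= curve.range_max + tol
    if not in_range:
        warnings.warn(
            f"back-calculated concentration {conc:.4g} outside calibration range "
            f"[{curve.range_min:g}, {curve.range_max:g}]"
        )
    return conc, in_range
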