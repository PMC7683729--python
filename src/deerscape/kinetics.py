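"""Prephenate-dehydratase quantitation and Michaelis-Menten fitting.

The assay follows product (phenylpyruvate) formation by absorbance at
320 nm: concentrations via Beer-Lambert with a molar extinction coefficient
of 17,500 1/(M cm), initial rates from the least-squares slope of product
vs time restricted to < 20% substrate conversion, non-enzymatic (blank)
turnover subtracted.  Rates across substrate concentrations are fit to
v = kcat * E * S / (KM + S) by unweighted nonlinear least squares; standard
errors come from the Jacobian-based covariance at the optimum, and the
catalytic efficiency kcat/KM carries a quadrature-propagated error

    SE(kcat/KM) = (kcat/KM) * sqrt((SE_KM/KM)^2 + (SE_kcat/kcat)^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "AssayConfig",
    "RateSeries",
    "MMFit",
    "EfficiencyEstimate",
    "absorbance_to_concentration",
    "compute_rate",
    "compute_rates",
    "fit_mm",
    "efficiency",
]


@dataclass(frozen=True)
class AssayConfig:
    extinction_coefficient: float = 17_500.0  # 1/(M cm)
    path_length: float = 1.0                  # cm
    max_conversion_fraction: float = 0.20

    def __post_init__(self):
        if self.extinction_coefficient <= 0 or self.path_length <= 0:
            raise ValueError("extinction coefficient and path length must be positive")
        if not 0.0 < self.max_conversion_fraction < 1.0:
            raise ValueError("max conversion fraction must lie in (0, 1)")


def absorbance_to_concentration(a320: float, config: AssayConfig = AssayConfig()) -> float:
    """Beer-Lambert product concentration in uM: c = A / (eps * l)."""
    a320 = np.asarray(a320, dtype=float)
    if np.any(a320 < 0):
        raise ValueError("absorbance must be non-negative")
    c_molar = a320 / (config.extinction_coefficient * config.path_length)
    return c_molar * 1e6


@dataclass
class RateSeries:
    """Blank-corrected initial rates across substrate concentrations."""

    substrate_uM: np.ndarray
    rate: np.ndarray              # product uM per time unit, blank-subtracted
    enzyme_uM: float

    def __post_init__(self):
        self.substrate_uM = np.asarray(self.substrate_uM, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.substrate_uM.shape != self.rate.shape:
            raise ValueError("substrate and rate arrays must match")
        if np.any(self.substrate_uM <= 0):
            raise ValueError("substrate concentrations must be positive")
        if not np.all(np.isfinite(self.rate)):
            raise ValueError("rates must be finite")
        if self.enzyme_uM <= 0:
            raise ValueError("enzyme concentration must be positive")


def _slope(t: np.ndarray, y: np.ndarray) -> float:
    return float(np.polyfit(t, y, 1)[0])


def compute_rate(
    times,
    product_uM,
    substrate0_uM: float,
    blank_product_uM=None,
    config: AssayConfig = AssayConfig(),
) -> tuple[float, int]:
    """Initial rate (uM per time unit) from a product time course.

    Only points with conversion below ``max_conversion_fraction`` of the
    initial substrate enter the regression; the blank (non-enzymatic) slope
    over the same points is subtracted.  Returns (net rate, points used).
    """
    times = np.asarray(times, dtype=float)
    product_uM = np.asarray(product_uM, dtype=float)
    if times.shape != product_uM.shape or len(times) < 2:
        raise ValueError("need at least two matching (time, product) points")
    keep = product_uM <= config.max_conversion_fraction * substrate0_uM
    if keep.sum() < 2:
        raise ValueError(
            "fewer than two points below the conversion threshold; "
            "reduce enzyme or shorten reaction times"
        )
    rate = _slope(times[keep], product_uM[keep])
    if blank_product_uM is not None:
        blank = np.asarray(blank_product_uM, dtype=float)
        if blank.shape != times.shape:
            raise ValueError("blank series must match the time grid")
        rate -= _slope(times[keep], blank[keep])
    return rate, int(keep.sum())


def compute_rates(
    courses: list[dict],
    enzyme_uM: float,
    config: AssayConfig = AssayConfig(),
) -> RateSeries:
    """Build a RateSeries from per-substrate time courses.

    Each course is a mapping with keys ``substrate_uM``, ``times``,
    ``product_uM`` and optionally ``blank_product_uM``.
    """
    subs, rates = [], []
    for course in courses:
        r, _ = compute_rate(
            course["times"],
            course["product_uM"],
            course["substrate_uM"],
            course.get("blank_product_uM"),
            config,
        )
        subs.append(course["substrate_uM"])
        rates.append(r)
    return RateSeries(np.array(subs), np.array(rates), enzyme_uM)


@dataclass(frozen=True)
class MMFit:
    km_uM: float
    km_se: float
    kcat: float      # per time unit of the rate data (1/s for rates in uM/s)
    kcat_se: float

    def __post_init__(self):
        if self.km_uM <= 0 or self.kcat <= 0:
            raise ValueError("point estimates must be positive")
        if self.km_se < 0 or self.kcat_se < 0:
            raise ValueError("standard errors must be non-negative")


def fit_mm(rates: RateSeries) -> MMFit:
    """Unweighted nonlinear least-squares Michaelis-Menten fit.

    v = kcat * E * S / (KM + S); SEs from the Jacobian covariance at the
    optimum.  Warns when KM lands far outside the sampled substrate range.
    """
    S, v, E = rates.substrate_uM, rates.rate, rates.enzyme_uM
    if len(np.unique(S)) < 4:
        raise ValueError("need rates at >= 4 distinct substrate concentrations")

    def model(s, km, kcat):
        return kcat * E * s / (km + s)

    p0 = (float(np.median(S)), float(1.2 * v.max() / E))
    try:
        popt, pcov = optimize.curve_fit(
            model, S, v, p0=p0, bounds=([1e-12, 1e-12], [np.inf, np.inf]),
            x_scale="jac", ftol=1e-14, xtol=1e-14, gtol=1e-14, maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"Michaelis-Menten fit did not converge: {exc}") from None
    km, kcat = float(popt[0]), float(popt[1])
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    if not (S.min() / 10 <= km <= 10 * S.max()):
        warnings.warn(
            f"KM = {km:.3g} uM lies outside [min(S)/10, 10 max(S)]; poorly constrained"
        )
    return MMFit(km, float(se[0]), kcat, float(se[1]))


@dataclass(frozen=True)
class EfficiencyEstimate:
    value: float  # 1/(M s)
    se: float

    def __str__(self) -> str:
        return f"kcat/KM = {self.value:.3g} +/- {self.se:.2g} M^-1 s^-1"


def efficiency(fit: MMFit) -> EfficiencyEstimate:
    """kcat/KM in 1/(M s) with quadrature-propagated standard error."""
    if fit.km_uM == 0:
        raise ValueError("KM must be non-zero")
    km_M = fit.km_uM * 1e-6
    value = fit.kcat / km_M
    rel = np.sqrt((fit.km_se / fit.km_uM) ** 2 + (fit.kcat_se / fit.kcat) ** 2)
    return EfficiencyEstimate(float(value), float(value * rel))
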