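"""Hemoglobin-oxygen binding submodel.

Saturation follows a Hill law

    S_HbO2 = (pO2/p50)^nH / (1 + (pO2/p50)^nH)

whose midpoint p50 and cooperativity nH are not constants: nH rises
smoothly with pO2, and p50 is shifted away from its standard value by
blood pCO2, temperature, erythrocyte pH and 2,3-DPG concentration (the
Bohr and related effects).  The functional forms and coefficients are
the published ones of the Dash-Korman-Bassingthwaighte blood gas model,
which was fitted to several experimental data sets over a wide range of
conditions; they are exposed on :class:`BindingParameters` so they can
be swapped wholesale.

Standard conditions are pCO2 = 40 mmHg, T = 37 degC, pH_rbc = 7.24 and
[2,3-DPG] = 4.65 mM, where p50 = 26.8 mmHg.  Each shift polynomial
evaluates to p50_standard at the standard point, so the shift machinery
is an exact no-op there.

Blood oxygen *content* (ml O2 per ml blood) combines physically
dissolved oxygen (solubility alpha) with hemoglobin-bound oxygen
(capacity at full saturation):

    c(pO2) = alpha * pO2 + c_Hb * S_HbO2(pO2)

The numerical inverse of this strictly monotone function converts an
absolute oxygen amount back into a partial pressure, which is what the
capillary solver needs after each diffusion step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .parameters import PARAMETER_RANGES

__all__ = [
    "BindingParameters",
    "BloodContext",
    "DissociationCurve",
    "OutOfDomainError",
    "hill_coefficient",
    "p50_shifted",
    "saturation",
    "o2_content",
    "pO2_from_content",
    "dissociation_curve_family",
]


class OutOfDomainError(ValueError):
    """Argument outside the range the empirical submodel was fitted for."""


@dataclass(frozen=True)
class BindingParameters:
    """Constants of the Hb-O2 submodel and blood gas carriage.

    ``hill_law_constants`` are (a, b, c) in nH(pO2) = a - b * 10^(-pO2/c).
    Each ``p50_*_coefficients`` tuple holds polynomial coefficients in
    the deviation of its variable from the standard condition (constant
    term first); the four polynomial factors combine multiplicatively,
    normalised by p50_standard.
    """

    p50_standard: float = 26.8  # mmHg
    hill_law_constants: tuple[float, float, float] = (2.82, 1.20, 29.25)
    # polynomials in (x - x_standard); constant term = p50_standard
    p50_ph_coefficients: tuple[float, ...] = (26.8, -25.535, 10.646, -1.764)
    p50_pco2_coefficients: tuple[float, ...] = (26.8, 1.273e-1, 1.083e-4)
    p50_dpg_coefficients: tuple[float, ...] = (26.8, 0.795633533, -0.0196608947)  # per mM
    p50_temperature_coefficients: tuple[float, ...] = (26.8, 1.435, 4.163e-2, 6.86e-4)
    standard_conditions: tuple[float, float, float, float] = (40.0, 37.0, 7.24, 4.65)
    # blood gas carriage (documented package defaults, not printed in the
    # morphometric or binding literature in these exact terms)
    hb_o2_capacity: float = 0.201     # ml O2 / ml blood at S = 1 (1.34 ml/g x 150 g/L)
    o2_solubility: float = 3.1e-5     # ml O2 / (ml blood x mmHg)
    co2_capacitance: float = 8.0e-3   # ml CO2 / (ml blood x mmHg), venous-arterial slope

    def __post_init__(self) -> None:
        if min(self.p50_standard, self.hb_o2_capacity, self.o2_solubility,
               self.co2_capacitance) <= 0:
            raise ValueError("binding constants must be strictly positive")


@dataclass(frozen=True)
class BloodContext:
    """Blood-side conditions the dissociation curve depends on."""

    pCO2: float = 40.0   # mmHg
    temperature: float = 37.0  # degC
    ph_rbc: float = 7.24
    dpg: float = 4.65    # mM


_DOMAIN = {
    "pCO2": PARAMETER_RANGES["blood_pCO2_in"],
    "temperature": PARAMETER_RANGES["blood_temperature"],
    "ph_rbc": PARAMETER_RANGES["ph_rbc"],
    "dpg": PARAMETER_RANGES["dpg_concentration"],
}


def _check_domain(ctx: BloodContext) -> None:
    for name, (lo, hi) in _DOMAIN.items():
        v = getattr(ctx, name)
        if not (lo <= v <= hi):
            raise OutOfDomainError(
                f"{name}={v!r} outside the fitted range [{lo}, {hi}]; "
                "refusing to extrapolate the empirical p50 model"
            )


def hill_coefficient(pO2, b: BindingParameters = BindingParameters()):
    """Cooperativity nH as a smooth, increasing function of pO2."""
    pO2 = np.asarray(pO2, dtype=float)
    if np.any(pO2 < 0):
        raise ValueError("pO2 must be non-negative")
    a, amp, scale = b.hill_law_constants
    return a - amp * 10.0 ** (-pO2 / scale)


def p50_shifted(pCO2: float, temperature: float, ph_rbc: float, dpg: float,
                b: BindingParameters = BindingParameters()) -> float:
    """p50 under the given blood conditions (mmHg).

    Increases with pCO2, temperature and 2,3-DPG, decreases with pH
    (rightward shift of the dissociation curve); exactly p50_standard at
    standard conditions.
    """
    ctx = BloodContext(pCO2, temperature, ph_rbc, dpg)
    _check_domain(ctx)
    std_pco2, std_t, std_ph, std_dpg = b.standard_conditions
    f_ph = np.polynomial.polynomial.polyval(ph_rbc - std_ph, b.p50_ph_coefficients)
    f_co2 = np.polynomial.polynomial.polyval(pCO2 - std_pco2, b.p50_pco2_coefficients)
    f_dpg = np.polynomial.polynomial.polyval(dpg - std_dpg, b.p50_dpg_coefficients)
    f_t = np.polynomial.polynomial.polyval(temperature - std_t, b.p50_temperature_coefficients)
    p50 = f_ph * f_co2 * f_dpg * f_t / b.p50_standard**3
    if p50 <= 0:
        raise OutOfDomainError("shifted p50 is non-positive; conditions outside model domain")
    return float(p50)


def saturation(pO2, p50: float, nH=None, b: BindingParameters = BindingParameters()):
    """Hill saturation S in [0, 1); S(p50) = 0.5 exactly.

    If *nH* is omitted it is evaluated at the local pO2 via
    :func:`hill_coefficient`.
    """
    pO2 = np.asarray(pO2, dtype=float)
    if p50 <= 0:
        raise ValueError("p50 must be positive")
    if nH is None:
        nH = hill_coefficient(pO2, b)
    elif np.any(np.asarray(nH) <= 0):
        raise ValueError("nH must be positive")
    if np.any(pO2 < 0):
        raise ValueError("pO2 must be non-negative")
    ratio = (pO2 / p50) ** nH
    out = ratio / (1.0 + ratio)
    return float(out) if out.ndim == 0 else out


def saturation_at(pO2, ctx: BloodContext, b: BindingParameters = BindingParameters()):
    """Saturation with p50 shifted for the given blood context."""
    p50 = p50_shifted(ctx.pCO2, ctx.temperature, ctx.ph_rbc, ctx.dpg, b)
    return saturation(pO2, p50, b=b)


def o2_content(pO2, ctx: BloodContext, b: BindingParameters = BindingParameters()):
    """Blood O2 content in ml O2 per ml blood (dissolved + Hb-bound)."""
    return b.o2_solubility * np.asarray(pO2, dtype=float) + b.hb_o2_capacity * saturation_at(pO2, ctx, b)


#: upper bracket for the content inversion; far above any physiological pO2
_PO2_MAX = 2000.0


def pO2_from_content(c: float, ctx: BloodContext,
                     b: BindingParameters = BindingParameters()) -> float:
    """Invert :func:`o2_content` by bracketed root finding.

    The content function is strictly increasing, so the root is unique.
    Round-trips pO2 -> content -> pO2 to better than 1e-6 mmHg.
    """
    if c < 0:
        raise ValueError("oxygen content must be non-negative")
    if c == 0:
        return 0.0
    c_max = o2_content(_PO2_MAX, ctx, b)
    if c >= c_max:
        raise ValueError(f"content {c!r} outside attainable range (max {c_max!r})")
    return float(brentq(lambda p: o2_content(p, ctx, b) - c, 0.0, _PO2_MAX,
                        xtol=1e-9, rtol=8.9e-16))


@dataclass(frozen=True)
class DissociationCurve:
    """One oxygen dissociation curve S(pO2) under fixed blood conditions."""

    pO2_grid: np.ndarray
    saturation: np.ndarray
    condition_label: str
    p50: float = field(default=float("nan"))


_VARY_FIELDS = {
    "ph_rbc": "ph_rbc",
    "blood_pCO2": "pCO2",
    "dpg": "dpg",
    "temperature": "temperature",
}


def dissociation_curve_family(vary: str, values, grid=None,
                              b: BindingParameters = BindingParameters()) -> list[DissociationCurve]:
    """Family of dissociation curves varying one blood-side parameter.

    *vary* is one of ``ph_rbc``, ``blood_pCO2``, ``dpg``, ``temperature``;
    all other conditions stay standard.  Curves come back in the order
    of *values*; each is monotone in pO2.
    """
    if vary not in _VARY_FIELDS:
        raise KeyError(f"unknown parameter {vary!r}; choose from {sorted(_VARY_FIELDS)}")
    if grid is None:
        grid = np.linspace(0.0, 150.0, 301)
    grid = np.asarray(grid, dtype=float)
    curves = []
    for v in values:
        ctx = BloodContext(**{_VARY_FIELDS[vary]: float(v)})
        p50 = p50_shifted(ctx.pCO2, ctx.temperature, ctx.ph_rbc, ctx.dpg, b)
        curves.append(DissociationCurve(grid, saturation(grid, p50, b=b),
                                        f"{vary}={v:g}", p50))
    return curves
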