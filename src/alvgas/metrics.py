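"""Derived physiological metrics and parameter sweeps.

Organ-scale extrapolation, the reaction half-time of capillary
oxygenation, the pulmonary diffusing capacity for oxygen

    D_LO2 = VO2 / mean(delta pO2),

and the two analyses built on it: the surface-exposure x capillary-
recruitment sweep (parallel / antiparallel / full grid) and the
reconstruction of D_LO2 as a function of pulmonary blood flow.

The mean alveolar-capillary gradient is, by default, the arithmetic
mean over the equal-time capillary sections of (alveolar pO2 - section
pO2), evaluated at the gradients the sections actually exchanged under
(i.e. their entry states).  With that choice D_LO2 reduces exactly to
the perfused-membrane conductance DMO2 x recruitment - the definition
identity holds to machine precision and is independent of the section
count.  A logarithmic-mean variant is available for comparison but is
numerically fragile once the profile equilibrates (the outlet gradient
underflows), which is why it is not the default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace as _dc_replace

import numpy as np

from .binding import BindingParameters
from .exchange import CapillaryProfile, solve_profile, parcel_trajectory
from .parameters import AlveolusParameters, LungScale

__all__ = [
    "DiffusingCapacityResult",
    "SweepResult",
    "extrapolate_to_lung",
    "weibel_reference_dmo2",
    "reaction_half_time",
    "mean_pressure_gradient",
    "diffusing_capacity",
    "sweep",
    "blood_flow_to_volume",
    "reconstruct_dlo2_vs_flow",
]


def extrapolate_to_lung(per_alveolus_value: float, lung: LungScale | None = None) -> float:
    """Scale a per-alveolus quantity to the whole lung (x n_alveoli)."""
    lung = lung or LungScale()
    return per_alveolus_value * lung.n_alveoli


def weibel_reference_dmo2(lung: LungScale | None = None) -> float:
    """Morphometric whole-lung DMO2 reference, per-kg value x body weight."""
    lung = lung or LungScale()
    return lung.whole_lung_dmo2_per_kg * lung.body_weight


class FlatTrajectoryError(ValueError):
    """No oxygenation occurred; the half-time is undefined."""


def reaction_half_time(trajectory: np.ndarray) -> float:
    """Time at which half of the transit oxygenation is complete.

    *trajectory* is an (m, 3) array of (t, pO2, saturation) rows as
    returned by :func:`alvgas.exchange.parcel_trajectory`.  The half
    level is defined on saturation: the smallest t with
    S(t) >= S0 + (S_end - S0)/2, linearly interpolated between samples.
    """
    trajectory = np.asarray(trajectory, dtype=float)
    if trajectory.ndim != 2 or trajectory.shape[0] < 2:
        raise ValueError("need a trajectory with at least two samples")
    t, sat = trajectory[:, 0], trajectory[:, 2]
    s0, s_end = sat[0], sat[-1]
    if s_end <= s0:
        raise FlatTrajectoryError("final saturation does not exceed initial saturation")
    mid = s0 + 0.5 * (s_end - s0)
    above = np.nonzero(sat >= mid)[0]
    i = above[0]
    if i == 0:
        return float(t[0])
    frac = (mid - sat[i - 1]) / (sat[i] - sat[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


@dataclass(frozen=True)
class DiffusingCapacityResult:
    """D_LO2 and its ingredients for one configuration."""

    vo2_per_alveolus: float      # ml O2/s
    mean_delta_pO2: float        # mmHg
    dlo2_per_alveolus: float     # ml/(mmHg x s)
    dlo2_lung: float             # ml/(mmHg x min), x n_alveoli x 60
    configuration_summary: tuple[float, float]  # (surface exposure, recruitment)


def mean_pressure_gradient(profile: CapillaryProfile, method: str = "arithmetic") -> float:
    """Mean alveolar-capillary pO2 gradient along the capillary (mmHg).

    ``arithmetic`` averages the per-section entry gradients (the ones
    the Fick fluxes were computed from); ``log`` uses the logarithmic
    mean of the inlet and outlet gradients.
    """
    if not profile.sections:
        return profile.alveolar_pO2 - profile.outlet_state.pO2
    dps = np.array([profile.alveolar_pO2 - s.pO2 for s in profile.sections])
    if method == "arithmetic":
        return float(np.mean(dps))
    if method == "log":
        dp_in = dps[0]
        dp_out = profile.alveolar_pO2 - profile.outlet_state.pO2
        if dp_out <= 0 or dp_in <= 0 or dp_in == dp_out:
            return float(dp_in)
        return float((dp_in - dp_out) / math.log(dp_in / dp_out))
    raise ValueError(f"unknown mean method {method!r}")


def diffusing_capacity(p: AlveolusParameters, b: BindingParameters | None = None,
                       lung: LungScale | None = None, n_sections: int = 100,
                       gradient_mean: str = "arithmetic") -> DiffusingCapacityResult:
    """Compute D_LO2 for one configuration from the steady profile."""
    lung = lung or LungScale()
    profile = solve_profile(p, b, n_sections)
    vo2 = profile.total_o2_uptake_rate
    if vo2 == 0.0:
        exposure = p.surface_area / lung.max_surface_area
        recruitment = p.blood_volume / lung.max_bed_volume
        return DiffusingCapacityResult(0.0, profile.alveolar_pO2 - p.blood_pO2_in,
                                       0.0, 0.0, (exposure, recruitment))
    mean_dp = mean_pressure_gradient(profile, gradient_mean)
    assert mean_dp > 0, "nonzero uptake with zero mean gradient is inconsistent"
    dlo2 = vo2 / mean_dp
    return DiffusingCapacityResult(
        vo2_per_alveolus=vo2,
        mean_delta_pO2=mean_dp,
        dlo2_per_alveolus=dlo2,
        dlo2_lung=dlo2 * lung.n_alveoli * 60.0,
        configuration_summary=(p.surface_area / lung.max_surface_area,
                               p.blood_volume / lung.max_bed_volume),
    )


@dataclass(frozen=True)
class SweepResult:
    """D_LO2 over a surface-exposure x recruitment grid or path."""

    exposure_grid: np.ndarray
    recruitment_grid: np.ndarray
    dlo2_matrix: np.ndarray  # ml/(mmHg x min); 2-D for grid mode, 1-D otherwise
    mode: str


def _with_fractions(p: AlveolusParameters, lung: LungScale,
                    exposure: float, recruitment: float) -> AlveolusParameters:
    return _dc_replace(p, surface_area=exposure * lung.max_surface_area,
                       blood_volume=recruitment * lung.max_bed_volume)


def sweep(mode: str, steps, p: AlveolusParameters | None = None,
          b: BindingParameters | None = None, lung: LungScale | None = None,
          n_sections: int = 100) -> SweepResult:
    """Sweep D_LO2 over surface exposure and capillary recruitment.

    ``grid`` fills the full matrix (exposure rows x recruitment
    columns); ``parallel`` walks the diagonal (x, x); ``antiparallel``
    walks (x, 1 - x).  *steps* are fractions in [0, 1], e.g.
    ``numpy.arange(0, 1.001, 0.125)`` for 12.5 % steps.
    """
    p = p or AlveolusParameters()
    lung = lung or LungScale()
    steps = np.asarray(list(steps), dtype=float)
    if np.any((steps < 0) | (steps > 1)):
        raise ValueError("sweep fractions must lie in [0, 1]")

    def dlo2(e: float, r: float) -> float:
        return diffusing_capacity(_with_fractions(p, lung, e, r), b, lung, n_sections).dlo2_lung

    if mode == "grid":
        matrix = np.array([[dlo2(e, r) for r in steps] for e in steps])
        return SweepResult(steps, steps, matrix, mode)
    if mode == "parallel":
        return SweepResult(steps, steps, np.array([dlo2(x, x) for x in steps]), mode)
    if mode == "antiparallel":
        return SweepResult(steps, 1.0 - steps,
                           np.array([dlo2(x, 1.0 - x) for x in steps]), mode)
    raise ValueError(f"unknown sweep mode {mode!r}")


#: um^3 per litre
UM3_PER_L = 1e15


def blood_flow_to_volume(q_lung: float, velocity: float = 1.5,
                         capillary_length: float = 500.0,
                         lung: LungScale | None = None) -> float:
    """Translate pulmonary blood flow into per-alveolus blood volume.

    Blood flow *q_lung* (L/min, whole lung) divided over the alveoli
    and multiplied by the capillary transit time L/v gives the blood
    volume resident in one alveolus, V_b = (Q/N) * L/v, in um^3.
    Values above the maximal bed volume are capped (with a warning):
    the capillary bed cannot recruit beyond 100 %.
    """
    lung = lung or LungScale()
    if velocity <= 0:
        raise ValueError("velocity must be positive")
    if q_lung < 0 or capillary_length <= 0:
        raise ValueError("flow and capillary length must be positive")
    q_per_alv = q_lung * UM3_PER_L / 60.0 / lung.n_alveoli  # um^3/s
    transit = capillary_length / (velocity * 1000.0)        # s
    vb = q_per_alv * transit
    if vb > lung.max_bed_volume:
        warnings.warn(
            f"blood flow {q_lung} L/min implies {vb:.3g} um^3 per alveolus; "
            f"capping at the maximal bed volume {lung.max_bed_volume:.3g} um^3",
            stacklevel=2,
        )
        vb = lung.max_bed_volume
    return vb


def reconstruct_dlo2_vs_flow(q_values, exposure_values, p: AlveolusParameters | None = None,
                             b: BindingParameters | None = None,
                             lung: LungScale | None = None,
                             velocity: float = 1.5, n_sections: int = 100) -> list[dict]:
    """D_LO2 for paired (blood flow, surface exposure) scenarios.

    Each pair is converted to a blood volume via
    :func:`blood_flow_to_volume` (at the stated constant velocity) and
    evaluated with :func:`diffusing_capacity`.  Returns one row per
    pair: ``{"q_l_per_min", "exposure", "blood_volume_um3", "dlo2_lung"}``.
    """
    p = p or AlveolusParameters()
    lung = lung or LungScale()
    q_values = list(q_values)
    exposure_values = list(exposure_values)
    if len(q_values) != len(exposure_values):
        raise ValueError("q_values and exposure_values must have equal length")
    rows = []
    for q, e in zip(q_values, exposure_values):
        vb = blood_flow_to_volume(q, velocity, p.capillary_length, lung)
        cfg = _dc_replace(p, surface_area=e * lung.max_surface_area,
                          blood_volume=vb, blood_flow_velocity=velocity)
        res = diffusing_capacity(cfg, b, lung, n_sections)
        rows.append({"q_l_per_min": q, "exposure": e,
                     "blood_volume_um3": vb, "dlo2_lung": res.dlo2_lung})
    return rows
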