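"""Simulation instances: lifecycle, clock and cumulative oxygen uptake.

An instance couples one parameter set to a solved capillary profile, a
simulation clock and a running total of oxygen taken up.  Because
alveolar gas tensions are fixed between parameter changes, the uptake
rate is stationary and advancing the clock integrates it linearly
(quasi-steady time model); changing parameters re-solves the profile,
so the cumulative-uptake curve is piecewise linear.

Multiple named, colour-tagged instances coexist in an
:class:`InstanceSet` for side-by-side comparison of parameter settings.
Everything here is deterministic and instances are fully isolated
(deep-copy semantics on ``copy``).
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass, field

from .binding import BindingParameters
from .exchange import CapillaryProfile, solve_profile
from .metrics import diffusing_capacity, reaction_half_time
from .parameters import AlveolusParameters, default_parameters

__all__ = ["SimulationInstance", "InstanceSet", "COMPARISON_METRICS"]

_ids = itertools.count(1)

#: colour-blind-safe categorical tags; actual colours are chosen at the
#: plotting boundary
_COLOR_TOKENS = ("C0", "C1", "C2", "C3", "C4", "C5", "C6", "C7")


@dataclass
class SimulationInstance:
    """One live simulation: parameters + clock + cumulative uptake."""

    instance_id: int
    label: str
    color_token: str
    parameters: AlveolusParameters
    binding: BindingParameters
    n_sections: int
    clock: float = 0.0
    cumulative_o2_uptake: float = 0.0   # ml O2 per alveolus
    profile: CapillaryProfile = field(repr=False, default=None)  # type: ignore[assignment]
    _initial_parameters: AlveolusParameters = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.profile is None:
            self.profile = solve_profile(self.parameters, self.binding, self.n_sections)
        if self._initial_parameters is None:
            self._initial_parameters = self.parameters

    # -- state changes ----------------------------------------------------

    def set_parameters(self, params: AlveolusParameters) -> None:
        """Swap parameters and re-solve the profile (recompute-on-write)."""
        self.parameters = params
        self.profile = solve_profile(params, self.binding, self.n_sections)

    def advance(self, dt: float) -> "SimulationInstance":
        """Advance the clock by *dt* seconds, accumulating oxygen uptake."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.clock += dt
        self.cumulative_o2_uptake += self.profile.total_o2_uptake_rate * dt
        return self

    def reset(self) -> None:
        """Restore creation-time parameters; zero clock and uptake."""
        self.clock = 0.0
        self.cumulative_o2_uptake = 0.0
        self.set_parameters(self._initial_parameters)

    # -- outputs ----------------------------------------------------------

    def snapshot_graphs(self) -> dict:
        """The three graph datasets: dissociation curve, saturation along
        the capillary, and the current cumulative-uptake point."""
        from .binding import dissociation_curve_family

        p = self.parameters
        curve = dissociation_curve_family(
            "blood_pCO2", [p.blood_pCO2_in], b=self.binding)[0]
        arrays = self.profile.as_arrays()
        return {
            "color_token": self.color_token,
            "label": self.label,
            "dissociation_curve": curve,
            "saturation_vs_time": (arrays["time_s"], arrays["saturation"]),
            "uptake_vs_time_point": (self.clock, self.cumulative_o2_uptake),
        }

    def metric(self, name: str) -> float:
        if name == "outlet_saturation":
            return self.profile.outlet_state.saturation
        if name == "uptake_rate":
            return self.profile.total_o2_uptake_rate
        if name == "half_time":
            arrays = self.profile.as_arrays()
            import numpy as np

            traj = np.column_stack([arrays["time_s"], arrays["pO2_mmHg"], arrays["saturation"]])
            return reaction_half_time(traj)
        if name == "dlo2_lung":
            return diffusing_capacity(self.parameters, self.binding,
                                      n_sections=self.n_sections).dlo2_lung
        raise KeyError(f"unknown metric {name!r}")


COMPARISON_METRICS = ("outlet_saturation", "uptake_rate", "half_time", "dlo2_lung")


class InstanceSet:
    """Ordered collection of simulation instances with unique ids."""

    def __init__(self, binding: BindingParameters | None = None, n_sections: int = 100):
        self._instances: dict[int, SimulationInstance] = {}
        self._binding = binding or BindingParameters()
        self._n_sections = n_sections

    def __len__(self) -> int:
        return len(self._instances)

    def __iter__(self):
        return iter(self._instances.values())

    def create(self, params: AlveolusParameters | None = None,
               label: str = "instance") -> SimulationInstance:
        params = params if params is not None else default_parameters()
        iid = next(_ids)
        inst = SimulationInstance(
            instance_id=iid,
            label=label,
            color_token=_COLOR_TOKENS[len(self._instances) % len(_COLOR_TOKENS)],
            parameters=params,
            binding=self._binding,
            n_sections=self._n_sections,
        )
        self._instances[iid] = inst
        return inst

    def get(self, instance_id: int) -> SimulationInstance:
        try:
            return self._instances[instance_id]
        except KeyError:
            raise KeyError(f"no instance with id {instance_id}") from None

    def copy(self, instance_id: int, label: str | None = None) -> SimulationInstance:
        """Deep duplicate with a fresh id and zeroed clock/uptake."""
        src = self.get(instance_id)
        iid = next(_ids)
        inst = SimulationInstance(
            instance_id=iid,
            label=label or f"{src.label} (copy)",
            color_token=_COLOR_TOKENS[len(self._instances) % len(_COLOR_TOKENS)],
            parameters=dataclasses.replace(src.parameters),
            binding=src.binding,
            n_sections=src.n_sections,
        )
        self._instances[iid] = inst
        return inst

    def delete(self, instance_id: int) -> None:
        self.get(instance_id)
        del self._instances[instance_id]

    def compare(self, quantity: str = "outlet_saturation") -> list[dict]:
        """One row per instance: id, label, parameter deltas vs defaults
        and the requested metric."""
        if quantity not in COMPARISON_METRICS:
            raise KeyError(f"unknown metric {quantity!r}; choose from {COMPARISON_METRICS}")
        defaults = default_parameters()
        rows = []
        for inst in self:
            deltas = {
                f.name: getattr(inst.parameters, f.name) - getattr(defaults, f.name)
                for f in dataclasses.fields(defaults)
                if getattr(inst.parameters, f.name) != getattr(defaults, f.name)
            }
            rows.append({
                "instance_id": inst.instance_id,
                "label": inst.label,
                "parameter_deltas": deltas,
                quantity: inst.metric(quantity),
            })
        return rows
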