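"""Matplotlib figure builders for the three standard views.

Plots are best-effort conveniences; CSV exports are the authoritative
output.  Colours come from a colour-blind-safe categorical palette keyed
by instance colour tokens.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .binding import BindingParameters, DissociationCurve, dissociation_curve_family
from .exchange import CapillaryProfile
from .metrics import SweepResult

__all__ = [
    "plot_dissociation_panels",
    "plot_saturation_along_capillary",
    "plot_sweep",
]

#: Okabe-Ito palette (colour-blind safe)
PALETTE = {
    "C0": "#0072B2", "C1": "#D55E00", "C2": "#009E73", "C3": "#CC79A7",
    "C4": "#E69F00", "C5": "#56B4E9", "C6": "#F0E442", "C7": "#000000",
}

_PANELS = {
    "ph_rbc": ([6.8, 7.0, 7.24, 7.6], "erythrocyte pH"),
    "blood_pCO2": ([20.0, 40.0, 60.0, 80.0], "blood pCO2 (mmHg)"),
    "dpg": ([1.0, 4.65, 7.0, 10.0], "[2,3]-DPG (mM)"),
    "temperature": ([20.0, 30.0, 37.0, 44.0], "temperature (degC)"),
}


def plot_dissociation_panels(path: str | Path, b: BindingParameters | None = None) -> Path:
    """Four-panel dissociation-curve family (pH, pCO2, DPG, temperature)."""
    b = b or BindingParameters()
    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True, sharey=True)
    for ax, (vary, (values, label)) in zip(axes.ravel(), _PANELS.items()):
        for i, curve in enumerate(dissociation_curve_family(vary, values, b=b)):
            ax.plot(curve.pO2_grid, curve.saturation,
                    color=list(PALETTE.values())[i], label=curve.condition_label)
        ax.set_title(f"varying {label}")
        ax.legend(fontsize=7)
    for ax in axes[-1]:
        ax.set_xlabel("pO2 (mmHg)")
    for ax in axes[:, 0]:
        ax.set_ylabel("S_HbO2")
    fig.tight_layout()
    return _save(fig, path)


def plot_saturation_along_capillary(profiles, path: str | Path, labels=None,
                                    color_tokens=None) -> Path:
    """Saturation versus time-in-capillary, one line per profile."""
    if isinstance(profiles, CapillaryProfile):
        profiles = [profiles]
    labels = labels or [f"instance {i + 1}" for i in range(len(profiles))]
    color_tokens = color_tokens or [f"C{i % 8}" for i in range(len(profiles))]
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for profile, label, token in zip(profiles, labels, color_tokens):
        arrays = profile.as_arrays()
        ax.plot(arrays["time_s"], arrays["saturation"],
                color=PALETTE.get(token, token), label=label)
    ax.set_xlabel("time in capillary (s)")
    ax.set_ylabel("hemoglobin O2 saturation")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    return _save(fig, path)


def plot_sweep(result: SweepResult, path: str | Path) -> Path:
    """Heatmap (grid mode) or line plot (parallel/antiparallel) of D_LO2."""
    fig, ax = plt.subplots(figsize=(6.5, 4.5))
    if result.dlo2_matrix.ndim == 2:
        im = ax.imshow(result.dlo2_matrix, origin="lower", aspect="auto",
                       extent=(result.recruitment_grid[0], result.recruitment_grid[-1],
                               result.exposure_grid[0], result.exposure_grid[-1]))
        fig.colorbar(im, ax=ax, label="D_LO2 (ml/(mmHg x min))")
        ax.set_xlabel("capillary recruitment")
        ax.set_ylabel("surface exposure")
    else:
        ax.plot(result.exposure_grid, result.dlo2_matrix, marker="o",
                color=PALETTE["C0"])
        ax.set_xlabel("surface exposure fraction"
                      + (" (recruitment = 1 - x)" if result.mode == "antiparallel" else ""))
        ax.set_ylabel("D_LO2 (ml/(mmHg x min))")
        ax.set_title(f"{result.mode} sweep")
    fig.tight_layout()
    return _save(fig, path)


def _save(fig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
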