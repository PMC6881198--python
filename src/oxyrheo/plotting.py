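"""Basic diagnostic figures (viscosity rheograms, oxygen relaxation)."""

from __future__ import annotations

from typing import TYPE_CHECKING

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

if TYPE_CHECKING:  # pragma: no cover
    from .oxygen import DiffusionResult
    from .pipeline import PipelineResult

__all__ = ["plot_cohort_rheograms", "plot_oxygen_relaxation"]

_TENSION_COLORS = {92.0: "tab:red", 46.0: "tab:olive", 0.0: "tab:blue"}


def plot_cohort_rheograms(result: "PipelineResult", path) -> None:
    """Effective viscosity vs average shear rate, one panel per sample."""
    samples = list(result.rheograms)
    ncols = min(3, len(samples))
    nrows = (len(samples) + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3 * nrows), squeeze=False)
    for ax, sid in zip(axes.flat, samples):
        for po2, rheo in sorted(result.rheograms[sid].items(), reverse=True):
            color = _TENSION_COLORS.get(po2)
            ax.errorbar(
                rheo.shear_rates,
                rheo.viscosities * 1e3,
                yerr=[p.sd_pa_s * 1e3 for p in rheo.points],
                marker="o",
                ms=3,
                lw=1,
                color=color,
                label=f"{po2:g} mm Hg",
            )
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel("average shear rate (1/s)")
        ax.set_ylabel("effective viscosity (mPa s)")
        ax.set_title(sid, fontsize=9)
        ax.legend(fontsize=7)
    for ax in axes.flat[len(samples):]:
        ax.set_visible(False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_oxygen_relaxation(result: "DiffusionResult", path, probe_z_m=None) -> None:
    """Blood-channel oxygen tension vs time after a gas switch."""
    if probe_z_m is None:
        probe_z_m = result.stack.layer_midpoint("blood")
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(result.t_s, result.probe(probe_z_m), lw=1.5)
    ax.set_xlabel("time after gas switch (s)")
    ax.set_ylabel("blood-channel pO$_2$ (mm Hg)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
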