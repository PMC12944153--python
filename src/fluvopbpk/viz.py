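"""Concentration-time figures with the therapeutic window overlaid."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from . import ivive
from .engine import daily_dose_regimen, simulate_population, steady_state_window
from .population import PopulationSpec, build_population
from .studies import CalibratedModel, TherapeuticWindow

__all__ = ["plot_phenotype_dose"]


def plot_phenotype_dose(
    model: CalibratedModel,
    phenotype: str,
    daily_dose_mg: float,
    path,
    seed: int | None = None,
    ages: tuple[float, float] = (65.0, 98.0),
    n_days: int = 14,
    window: TherapeuticWindow | None = None,
) -> None:
    """Steady-state mean profile with 5th-95th percentile band, saved as PNG."""
    window = window or TherapeuticWindow()
    seed = model.seed if seed is None else seed
    spec = PopulationSpec(
        age_min=ages[0],
        age_max=ages[1],
        prop_female=0.5,
        phenotype_mode=f"uniform_{phenotype}",
        geriatric_flag=True,
        seed=seed,
    )
    pop = build_population(spec, model.config, model.aging)
    cs = ivive.clearances(pop, model.compound)
    regimen = daily_dose_regimen(daily_dose_mg, n_days)
    win = steady_state_window(
        simulate_population(pop, model.compound, cs, regimen, model.settings),
        regimen.interval_h,
        model.settings.ss_convergence_tol,
    )
    fig, ax = plt.subplots(figsize=(5, 3.4))
    ax.fill_between(
        win.times,
        np.percentile(win.conc, 5, axis=0),
        np.percentile(win.conc, 95, axis=0),
        alpha=0.3,
        label="5th-95th percentile",
    )
    ax.plot(win.times, win.conc.mean(axis=0), lw=2, label="mean")
    for y in (window.low_ng_ml, window.high_ng_ml):
        ax.axhline(y, ls="--", color="k", lw=0.8)
    ax.set_xlabel("time within dosing interval (h)")
    ax.set_ylabel("plasma concentration (ng/mL)")
    ax.set_title(f"{phenotype}, {daily_dose_mg:g} mg/day, geriatric steady state")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
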