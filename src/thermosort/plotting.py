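"""Matplotlib views of sweep and swelling results (optional dependency)."""

from __future__ import annotations

import numpy as np


def plot_sorting_sweep(sweep, ax=None):
    """Remaining fractions and separation factor vs B_p, one panel pair."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(1, 2, figsize=(9, 3.5), constrained_layout=True)
    for i, dd in enumerate(sweep.D_d):
        ax[0].errorbar(sweep.B_p, sweep.frac1[i], yerr=sweep.frac1_se[i],
                       marker="o", ms=3, label=f"type 1, $D_d$={dd:g}")
        ax[0].errorbar(sweep.B_p, sweep.frac2[i], yerr=sweep.frac2_se[i],
                       marker="s", ms=3, ls="--", label=f"type 2, $D_d$={dd:g}")
        sf = np.where(sweep.sf_defined[i], sweep.sf[i], np.nan)
        ax[1].plot(sweep.B_p, sf, marker="o", ms=3, label=f"$D_d$={dd:g}")
    ax[0].set_xlabel("$B_p$")
    ax[0].set_ylabel("cells attached (%)")
    ax[1].set_xlabel("$B_p$")
    ax[1].set_ylabel("separation factor")
    for a in ax:
        a.legend(fontsize=7)
    return ax


def plot_swelling_curves(table, ax=None):
    """Swelling ratio vs cross-link fraction, one curve per grafting density."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5), constrained_layout=True)
    for rho_g, grp in table.groupby("rho_g"):
        grp = grp.sort_values("nu_cr")
        ax.errorbar(grp["nu_cr"], grp["ratio"], yerr=grp.get("ratio_se"),
                    marker="o", label=rf"$\rho_g$ = {rho_g:g}")
    ax.set_xlabel(r"cross-link fraction $\nu_{cr}$ (%)")
    ax.set_ylabel("swelling ratio $h_1/h_2$")
    ax.legend()
    return ax
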