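"""Scatter and Bland-Altman plots for paired SUV/SUVR measures."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .agreement import BlandAltmanResult, RegressionResult


def scatter_plot(spect, pet, reg: RegressionResult, label: str, path) -> None:
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(spect, pet, s=12, c="k", alpha=0.7)
    xs = np.linspace(min(spect), max(spect), 50)
    ax.plot(xs, reg.slope * xs + reg.intercept, "r-",
            label=f"y = {reg.slope:.2f}x + {reg.intercept:.2f}, R²={reg.r_squared:.2f}")
    ax.set_xlabel(f"SPECT {label}")
    ax.set_ylabel(f"PET {label}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)


def bland_altman_plot(ba: BlandAltmanResult, label: str, path) -> None:
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(ba.means, ba.differences, s=12, c="k", alpha=0.7)
    ax.axhline(ba.median_diff_pct, color="r", label=f"median {ba.median_diff_pct:.0f}%")
    for v in (ba.loa_low_pct, ba.loa_high_pct):
        ax.axhline(v, color="r", ls=":")
    ax.set_xlabel(f"mean of SPECT and PET {label}")
    ax.set_ylabel(f"difference ({ba.normalization}), %")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)
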