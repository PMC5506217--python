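"""Decorative plots of data, fitted psychometric functions, and the model's
internal components.  Numerical outputs never depend on these."""

from __future__ import annotations

import numpy as np

from .estimation import FitResult
from .gof import active_categories
from .model import judgment_probabilities, mu, predicted_probabilities

__all__ = ["plot_fit", "plot_model_components"]

_CAT_NAMES = {"ternary": ("F", "U", "S"), "2AFC": ("F", "U", "S"),
              "equality": ("F", "same", "different")}
_COLORS = {0: ("tab:blue", "tab:cyan"), 1: ("black", "gray"),
           2: ("tab:red", "lightcoral")}


def _level_grid(levels: np.ndarray) -> np.ndarray:
    lo, hi = levels.min(), levels.max()
    pad = 0.05 * (hi - lo or 1.0)
    return np.linspace(lo - pad, hi + pad, 201)


def plot_fit(result: FitResult, ax=None):
    """Observed response proportions and fitted psychometric functions per
    category and presentation order, with standard/PSE markers."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    levels = result.levels
    grid = _level_grid(levels)
    psi = predicted_probabilities(
        grid, result.sensory, result.boundaries, result.errors,
        result.response_format,
    )
    totals = result.counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        props = np.where(totals > 0, result.counts / totals, np.nan)
    names = _CAT_NAMES[result.response_format]
    for r in active_categories(result.response_format):
        for m in range(2):
            color = _COLORS[r][m]
            ax.plot(grid, psi[m, r], color=color, lw=1.5,
                    label=f"{names[r]}, test {('first', 'second')[m]}")
            ax.plot(levels, props[m, r], "o", color=color, ms=4)
    if not result.sensory.is_detection:
        ax.axvline(result.standard, color="k", ls="--", lw=0.8)
        if result.pse is not None:
            ax.axvline(result.pse, color="k", ls="-", lw=0.8)
    ax.set_xlabel("test level")
    ax.set_ylabel("response probability")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=7, ncol=2)
    return ax


def plot_model_components(result: FitResult, axes=None):
    """Three panels: estimated psychophysical function (with the standard's
    anchor), decision space with the fitted boundaries and the variance-2
    density of the decision variable, and the latent (error-free) judgment
    probabilities."""
    import matplotlib.pyplot as plt
    from scipy.stats import norm

    if axes is None:
        _, axes = plt.subplots(1, 3, figsize=(11, 3.2))
    ax_mu, ax_dec, ax_lat = axes
    grid = _level_grid(result.levels)

    ax_mu.plot(grid, mu(grid, result.sensory.test), color="tab:red")
    if not result.sensory.is_detection:
        ax_mu.plot(result.standard, result.sensory.anchor, "o", color="tab:blue")
    ax_mu.set_xlabel("test level")
    ax_mu.set_ylabel(r"$\mu_t$")
    ax_mu.set_title(
        rf"$\hat\alpha_t$={result.alpha_t:.3g}, $\hat\beta_t$={result.beta_t:.3g}",
        fontsize=9,
    )

    dd = np.linspace(result.delta1 - 5, result.delta2 + 5, 400)
    ax_dec.plot(dd, norm.pdf(dd, scale=np.sqrt(2)), color="k")
    for v, lab in ((result.delta1, r"$\hat\delta_1$"), (result.delta2, r"$\hat\delta_2$")):
        ax_dec.axvline(v, color="tab:orange", ls="--")
        ax_dec.text(v, ax_dec.get_ylim()[1] * 0.9, lab, ha="center", fontsize=9)
    ax_dec.set_xlabel("decision variable D")
    ax_dec.set_ylabel("density")

    for m in (1, 2):
        p = judgment_probabilities(grid, m, result.sensory, result.boundaries)
        for r, comp in enumerate(p):
            ax_lat.plot(grid, comp, color=_COLORS[r][m - 1], lw=1.2)
    ax_lat.set_xlabel("test level")
    ax_lat.set_ylabel("judgment probability")
    ax_lat.set_ylim(-0.02, 1.02)
    return axes
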