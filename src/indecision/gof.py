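"""Goodness-of-fit statistics for a fitted model.

Pearson's X^2 and the likelihood-ratio G^2 are computed over the active
response categories only (3 for ternary data, 2 for the binary formats —
counting the structurally-zero row of binary data would overstate the cell
count and the degrees of freedom).  Degrees of freedom are
``sum over order x level of (C_active - 1) - n_free``; this convention is
reported in the output so users can audit it.  Small-expected-frequency
diagnostics are reported but cells are never collapsed automatically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

__all__ = ["GofReport", "active_categories", "gof_statistics"]


@dataclass(frozen=True)
class GofReport:
    n_cells: int
    n_expected_lt5: int
    n_expected_lt5_obs_nonnull: int
    n_expected_lt1: int
    n_expected_lt1_obs_nonnull: int
    df: int
    X2: float
    p_X2: float
    G2: float
    p_G2: float
    bic: float
    minus2loglik: float


def active_categories(response_format: str) -> list[int]:
    """Indices of the response categories that can carry counts: F/U/S for
    ternary, F/S for 2AFC, U("same")/S("different") for equality."""
    if response_format == "ternary":
        return [0, 1, 2]
    if response_format == "2AFC":
        return [0, 2]
    if response_format == "equality":
        return [1, 2]
    raise ValueError(f"unknown response format {response_format!r}")


def gof_statistics(counts, psi, n_free: int, response_format: str = "ternary") -> GofReport:
    """Compute X^2, G^2, df, p-values, BIC and cell diagnostics.

    Parameters
    ----------
    counts : (2, 3, N) array of observed response counts.
    psi : (2, 3, N) array of fitted response probabilities.
    n_free : number of free parameters of the fitted model.
    response_format : determines the active categories.

    Only (order, level) cells with at least one trial enter the statistics.
    ``0 * log(0/E)`` is taken as 0 in G^2.  If df <= 0 the p-values are NaN
    and a warning is issued, but the statistics are still returned.  The BIC
    uses the total trial count as sample size; the multinomial constant is
    omitted throughout (it cancels in model comparisons).
    """
    counts = np.asarray(counts, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if counts.shape != psi.shape or counts.ndim != 3 or counts.shape[1] != 3:
        raise ValueError("counts and psi must both have shape (2, 3, N)")
    cats = active_categories(response_format)

    obs = counts[:, cats, :]  # (2, C, N)
    prob = psi[:, cats, :]
    totals = counts.sum(axis=1)  # (2, N) trials per order x level
    occupied = totals > 0
    n_occupied = int(occupied.sum())
    C = len(cats)

    expected = prob * totals[:, None, :]
    use = np.broadcast_to(occupied[:, None, :], obs.shape)

    O = obs[use]
    E = expected[use]
    n_cells = O.size

    E_safe = np.maximum(E, 1e-300)
    X2 = float(np.sum((O - E) ** 2 / E_safe))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(O > 0, O * np.log(np.maximum(O, 1e-300) / E_safe), 0.0)
    G2 = float(2.0 * np.sum(terms))

    lt5 = E < 5
    lt1 = E < 1
    report_counts = dict(
        n_expected_lt5=int(lt5.sum()),
        n_expected_lt5_obs_nonnull=int((lt5 & (O > 0)).sum()),
        n_expected_lt1=int(lt1.sum()),
        n_expected_lt1_obs_nonnull=int((lt1 & (O > 0)).sum()),
    )

    df = n_occupied * (C - 1) - int(n_free)
    if df > 0:
        p_X2 = float(chi2.sf(X2, df))
        p_G2 = float(chi2.sf(G2, df))
    else:
        warnings.warn(
            f"non-positive degrees of freedom (df = {df}); p-values undefined",
            stacklevel=2,
        )
        p_X2 = p_G2 = float("nan")

    n_total = float(totals.sum())
    with np.errstate(divide="ignore"):
        ll_terms = np.where(O > 0, O * np.log(np.maximum(prob[use], 1e-12)), 0.0)
    minus2loglik = float(-2.0 * np.sum(ll_terms))
    bic = minus2loglik + n_free * np.log(max(n_total, 1.0))

    return GofReport(
        n_cells=n_cells,
        df=df,
        X2=X2,
        p_X2=p_X2,
        G2=G2,
        p_G2=p_G2,
        bic=float(bic),
        minus2loglik=minus2loglik,
        **report_counts,
    )
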