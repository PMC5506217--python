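"""Maximum-likelihood fitting of the indecision model.

Parameters are estimated by minimizing the multinomial negative
log-likelihood of the 2 (presentation orders) x 3 (response categories) x N
(test levels) count table with a bounded local optimizer (L-BFGS-B) started
from every point of a factorial grid of starting values, returning the best
solution across starts.  Internally the boundaries are parameterized as
(delta1, width) with width = delta2 - delta1 >= 0, so delta1 <= delta2 is a
box constraint; width fixed at 0 yields the classical 2AFC difference model.

The central object is the scikit-learn style estimator
:class:`IndecisionModel`; :func:`fit` and :func:`select_error_model` are the
equivalent functional entry points operating on :class:`Dataset` /
:class:`FitOptions`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Any, Sequence

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import gof as gof_mod
from . import measures as measures_mod
from .model import (
    DETECTION_STANDARD,
    FORMATS,
    DecisionBoundaries,
    ErrorModelSpec,
    ErrorParams,
    OrderErrors,
    PsyFunParams,
    SensoryModel,
    constrain_errors,
    format_constraints,
    mu,
    predicted_probabilities,
)

__all__ = [
    "Dataset",
    "FitOptions",
    "FitResult",
    "ParameterLayout",
    "IndecisionModel",
    "free_parameter_layout",
    "negative_log_likelihood",
    "fit",
    "enumerate_error_models",
    "select_error_model",
    "default_alpha_bounds",
]

PROB_FLOOR = 1e-12  # likelihood floor: zero predicted probability with
# nonzero counts yields a finite, heavily penalized objective


# ---------------------------------------------------------------------------
# Data container


@dataclass
class Dataset:
    """Response counts from one observer in a dual-presentation task.

    ``counts[m, r, i]`` is the number of r in (F, U, S) responses at test
    level ``levels[i]`` when the test was presented in interval ``m + 1``.
    ``standard`` is the standard level; ``-inf`` declares a detection task.
    For ``equality`` data, "same" counts live in the U row and "different"
    counts in the S row (F row structurally zero); for ``2AFC`` data the U
    row is structurally zero.
    """

    levels: np.ndarray
    counts: np.ndarray
    standard: float = DETECTION_STANDARD
    response_format: str = "ternary"

    def __post_init__(self) -> None:
        levels = np.atleast_1d(np.asarray(self.levels, dtype=float))
        counts = np.asarray(self.counts)
        if self.response_format not in FORMATS:
            raise ValueError(
                f"unknown response format {self.response_format!r}; "
                f"expected one of {FORMATS}"
            )
        if levels.ndim != 1 or not np.all(np.isfinite(levels)):
            raise ValueError("levels must be a 1-D vector of finite reals")
        if counts.shape != (2, 3, levels.size):
            raise ValueError(
                f"counts must have shape (2, 3, {levels.size}), got {counts.shape}"
            )
        if np.any(np.asarray(counts, dtype=float) < 0) or np.any(
            np.asarray(counts, dtype=float) != np.round(np.asarray(counts, dtype=float))
        ):
            raise ValueError("counts must be nonnegative integers")
        counts = np.asarray(np.round(np.asarray(counts, dtype=float)), dtype=int)

        # canonicalize: sort levels ascending, merge duplicate levels
        order = np.argsort(levels, kind="stable")
        levels = levels[order]
        counts = counts[:, :, order]
        uniq, inverse = np.unique(levels, return_inverse=True)
        if uniq.size != levels.size:
            merged = np.zeros((2, 3, uniq.size), dtype=int)
            np.add.at(merged.transpose(2, 0, 1), inverse, counts.transpose(2, 0, 1))
            levels, counts = uniq, merged

        # structural-zero validation for binary formats
        zero_row = {"2AFC": (1, "U"), "equality": (0, "F")}.get(self.response_format)
        if zero_row is not None:
            row, name = zero_row
            bad = np.argwhere(counts[:, row, :] > 0)
            if bad.size:
                m, i = bad[0]
                raise ValueError(
                    f"{self.response_format} data must have an all-zero {name} "
                    f"row; nonzero count at order {m + 1}, level {levels[i]:g}"
                )

        self.levels = levels
        self.counts = counts
        self.standard = float(self.standard) if self.standard is not None else DETECTION_STANDARD

        if not self.is_detection and not np.isfinite(self.standard):
            raise ValueError("standard must be finite or -inf (detection)")

    @property
    def is_detection(self) -> bool:
        return np.isneginf(self.standard)

    @property
    def n_levels(self) -> int:
        return self.levels.size

    @property
    def n_trials(self) -> int:
        return int(self.counts.sum())


# ---------------------------------------------------------------------------
# Fitting options and parameter layout


def default_alpha_bounds(levels, detection: bool) -> tuple[float, float]:
    """Search bounds for alpha_t from the test-level range (x1, xN).

    Detection: [3 x1 - 2 xN, xN] — alpha is identifiable and lies near the
    rising portion of the psychometric functions.  Suprathreshold
    discrimination: [3 x1 - 2 xN, 2 x1 - xN] (as far below x1 as xN is above
    x1), keeping mu_t linear over the test range; alpha is unidentifiable
    there and a bound hit is benign.
    """
    levels = np.asarray(levels, dtype=float)
    x1, xN = float(levels.min()), float(levels.max())
    if x1 == xN:
        raise ValueError("alpha bounds require at least two distinct test levels")
    lo = 3.0 * x1 - 2.0 * xN
    return (lo, xN) if detection else (lo, 2.0 * x1 - xN)


@dataclass
class FitOptions:
    """Bounds, starting grids, and model assumptions for a fit.

    ``psyfun_type`` is "same" when a common psychophysical function holds for
    test and standard (the anchor is mu_t(x_s)) and "diff" when the anchor
    mu_s(x_s) is a free parameter.  ``error_model`` is an
    :class:`ErrorModelSpec` (or its label), or ``"best"`` to search all
    enumerated error models.  ``enforce_single_boundary`` fixes
    width = delta2 - delta1 at 0 (classical difference model for 2AFC data).
    Bounds for the eps and kappa parameters are fixed at [0, 1].  Defaults
    for alpha bounds/starts are derived from the data when left as None.
    """

    psyfun_type: str = "same"
    error_model: ErrorModelSpec | str = field(default_factory=ErrorModelSpec)
    selection_criterion: str = "loglik"
    alpha_bounds: tuple[float, float] | None = None
    beta_bounds: tuple[float, float] = (0.01, 1.0)
    delta1_bounds: tuple[float, float] = (-8.0, 2.0)
    width_bounds: tuple[float, float] = (0.0, 12.0)
    anchor_bounds: tuple[float, float] = (1e-6, 100.0)
    alpha_starts: Sequence[float] | None = None
    beta_starts: Sequence[float] = (0.05, 0.15)
    delta1_starts: Sequence[float] = (-4.0, -2.0, -0.5)
    width_starts: Sequence[float] = (5.0,)
    anchor_starts: Sequence[float] | None = None
    eps_start: float = 0.01
    kappa_start: float = 0.5
    enforce_single_boundary: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if self.psyfun_type not in ("same", "diff"):
            raise ValueError("psyfun_type must be 'same' or 'diff'")
        if self.selection_criterion not in ("loglik", "bic"):
            raise ValueError("selection_criterion must be 'loglik' or 'bic'")
        if isinstance(self.error_model, str) and self.error_model != "best":
            self.error_model = ErrorModelSpec.from_label(self.error_model)
        if self.width_bounds[0] < 0:
            raise ValueError("width bounds must be nonnegative")

    def effective_width_bounds(self) -> tuple[float, float]:
        return (0.0, 0.0) if self.enforce_single_boundary else tuple(self.width_bounds)


@dataclass(frozen=True)
class ParamSpec:
    name: str
    bounds: tuple[float, float]
    starts: tuple[float, ...]


_EPS_KAPPA = (("eps_F", "kappa_FU"), ("eps_U", "kappa_UF"), ("eps_S", "kappa_SF"))


class ParameterLayout:
    """Ordered description of the free-parameter vector for one fit.

    Maps a flat parameter vector onto (SensoryModel, DecisionBoundaries,
    ErrorParams); parameters fixed by the response format, by the error-model
    mask, or by degenerate bounds (lb == ub) are never counted as free.
    """

    def __init__(self, d: Dataset, o: FitOptions):
        model = o.error_model
        if isinstance(model, str):
            raise ValueError("error_model must be resolved before layout")
        width_bounds = o.effective_width_bounds()
        width_fixed = width_bounds[0] == width_bounds[1]
        if d.response_format == "equality" and width_fixed and width_bounds[0] == 0.0:
            raise ValueError(
                "same-different data cannot be accounted for with delta1 = "
                "delta2 (no 'same' responses would ever occur)"
            )

        alpha_bounds = tuple(
            o.alpha_bounds
            if o.alpha_bounds is not None
            else default_alpha_bounds(d.levels, d.is_detection)
        )
        alpha_mid = 0.5 * (alpha_bounds[0] + alpha_bounds[1])
        alpha_starts = tuple(o.alpha_starts) if o.alpha_starts is not None else (alpha_mid,)

        self.dataset = d
        self.options = o
        self.model_spec = model
        self.alpha_bounds = alpha_bounds
        self.width_bounds = width_bounds
        self._fixed: dict[str, float] = {}
        self.params: list[ParamSpec] = []

        def add(name, bounds, starts):
            lb, ub = float(bounds[0]), float(bounds[1])
            if lb == ub:
                self._fixed[name] = lb
                return
            starts = tuple(float(np.clip(s, lb, ub)) for s in starts)
            self.params.append(ParamSpec(name, (lb, ub), tuple(dict.fromkeys(starts))))

        add("alpha_t", alpha_bounds, alpha_starts)
        add("beta_t", o.beta_bounds, o.beta_starts)
        self.free_anchor = o.psyfun_type == "diff" and not d.is_detection
        if self.free_anchor:
            if o.anchor_starts is not None:
                anchor_starts = tuple(o.anchor_starts)
            else:
                anchor_starts = tuple(
                    mu(d.standard, PsyFunParams(alpha_mid, b)) for b in o.beta_starts
                )
            add("anchor", o.anchor_bounds, anchor_starts)
        add("delta1", o.delta1_bounds, o.delta1_starts)
        add("width", width_bounds, o.width_starts)
        self.width_zero = width_fixed and width_bounds[0] == 0.0

        fixed_fmt = format_constraints(d.response_format)
        for m in (1, 2):
            mask = model.mask(m)
            for k, (eps_name, kappa_name) in enumerate(_EPS_KAPPA):
                if eps_name == "eps_U" and self.width_zero:
                    # p_U is identically 0: eps_U and kappa_U-F drop out
                    continue
                if eps_name in fixed_fmt:
                    if kappa_name not in fixed_fmt:
                        add(f"{kappa_name}_{m}", (0.0, 1.0), (o.kappa_start,))
                elif mask[k]:
                    add(f"{eps_name}_{m}", (0.0, 1.0), (o.eps_start,))
                    if kappa_name not in fixed_fmt:
                        add(f"{kappa_name}_{m}", (0.0, 1.0), (o.kappa_start,))

    @property
    def n_free(self) -> int:
        return len(self.params)

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.params]

    @property
    def bounds(self) -> list[tuple[float, float]]:
        return [p.bounds for p in self.params]

    def start_grid(self) -> list[np.ndarray]:
        """Factorial combination of per-parameter starting values."""
        return [np.array(pt) for pt in itertools.product(*(p.starts for p in self.params))]

    def build(
        self, theta
    ) -> tuple[SensoryModel, DecisionBoundaries, ErrorParams]:
        theta = np.asarray(theta, dtype=float)
        if theta.size != self.n_free:
            raise ValueError(f"expected {self.n_free} parameters, got {theta.size}")
        vals = dict(self._fixed)
        vals.update(zip(self.names, theta))

        test = PsyFunParams(vals["alpha_t"], vals["beta_t"])
        d = self.dataset
        if d.is_detection:
            s = SensoryModel.detection(test)
        elif self.free_anchor:
            s = SensoryModel.free_anchor(test, d.standard, vals["anchor"])
        else:
            s = SensoryModel.shared(test, d.standard)
        delta1 = vals["delta1"]
        b = DecisionBoundaries(delta1, delta1 + vals["width"])

        orders = []
        for m in (1, 2):
            kw: dict[str, float] = {}
            for eps_name, kappa_name in _EPS_KAPPA:
                for name in (eps_name, kappa_name):
                    v = vals.get(f"{name}_{m}")
                    if v is not None:
                        kw[name] = v
            orders.append(OrderErrors(**kw))
        return s, b, ErrorParams(*orders)


def free_parameter_layout(d: Dataset, o: FitOptions) -> ParameterLayout:
    """Ordered free-parameter vector description for fitting ``d`` under ``o``."""
    return ParameterLayout(d, o)


# ---------------------------------------------------------------------------
# Likelihood and fitting


def _nll(theta, layout: ParameterLayout) -> float:
    d = layout.dataset
    s, b, e = layout.build(theta)
    psi = predicted_probabilities(d.levels, s, b, e, d.response_format)
    return float(-np.sum(d.counts * np.log(np.maximum(psi, PROB_FLOOR))))


def negative_log_likelihood(theta, d: Dataset, o: FitOptions) -> float:
    """Multinomial negative log-likelihood (kernel only; the multinomial
    coefficients are constant in theta and omitted).  Finite for every theta
    within bounds thanks to the probability floor."""
    return _nll(theta, free_parameter_layout(d, o))


@dataclass
class FitResult:
    """Complete record of one fit: estimates, diagnostics, goodness of fit,
    and derived performance measures."""

    label: str
    optimizer: dict[str, Any]
    levels: np.ndarray
    counts: np.ndarray
    response_format: str
    standard: float
    requested_model: str
    fitted_model: str
    selection_criterion: str | None
    psyfun_type: str
    n_free: int
    gof: gof_mod.GofReport
    alpha_bounds: tuple[float, float]
    beta_bounds: tuple[float, float]
    delta1_bounds: tuple[float, float]
    width_bounds: tuple[float, float]
    boundaries_reached: list[str]
    alpha_t: float
    beta_t: float
    anchor: float | None
    mu_t_at_standard: float | None
    delta1: float
    delta2: float
    errors_order1: dict[str, float]
    errors_order2: dict[str, float]
    pse: float | None
    dl_level: float | None
    dl: float | None
    threshold: float | None
    theta: np.ndarray
    param_names: list[str]
    sensory: SensoryModel
    boundaries: DecisionBoundaries
    errors: ErrorParams

    @property
    def minus2loglik(self) -> float:
        return self.gof.minus2loglik

    @property
    def bic(self) -> float:
        return self.gof.bic

    def predicted(self) -> np.ndarray:
        """Fitted response probabilities, 2x3xN."""
        return predicted_probabilities(
            self.levels, self.sensory, self.boundaries, self.errors,
            self.response_format,
        )


def _order_error_record(e: OrderErrors) -> dict[str, float]:
    return {
        "eps_F": e.eps_F, "eps_U": e.eps_U, "eps_S": e.eps_S,
        "kappa_FU": e.kappa_FU, "kappa_FS": e.kappa_FS,
        "kappa_UF": e.kappa_UF, "kappa_US": e.kappa_US,
        "kappa_SF": e.kappa_SF, "kappa_SU": e.kappa_SU,
    }


def _boundary_report(layout: ParameterLayout, vals: dict[str, float]) -> list[str]:
    """Which of the user-bounded parameters sit at a bound.

    A parameter fixed by degenerate bounds (lb == ub) is reported at its
    upper bound — with width fixed at 0 this signals that the data might be
    better fitted with delta2 > delta1 allowed.
    """
    report = []
    named_bounds = {
        "alpha_t": layout.alpha_bounds,
        "beta_t": layout.options.beta_bounds,
        "delta1": layout.options.delta1_bounds,
        "width": layout.width_bounds,
    }
    for name, (lb, ub) in named_bounds.items():
        v = vals.get(name)
        if v is None:
            continue
        if lb == ub:
            report.append(f"{name} at upper bound")
            continue
        tol = max(1e-8, 1e-4 * (ub - lb))
        if v <= lb + tol:
            report.append(f"{name} at lower bound")
        elif v >= ub - tol:
            report.append(f"{name} at upper bound")
    return report


def fit(d: Dataset, o: FitOptions | None = None) -> FitResult:
    """Maximum-likelihood fit of the indecision model to a dataset.

    Runs L-BFGS-B from every point of the factorial start grid and keeps the
    solution with the smallest -2 log L.  Deterministic given the options.
    """
    o = o if o is not None else FitOptions()
    if o.error_model == "best":
        return select_error_model(d, o)
    layout = free_parameter_layout(d, o)

    best = None
    n_starts = 0
    any_success = False
    for x0 in layout.start_grid():
        n_starts += 1
        res = minimize(
            _nll, x0, args=(layout,), method="L-BFGS-B", bounds=layout.bounds
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None:  # zero free parameters: evaluate directly
        best = type("R", (), {})()
        best.x = np.empty(0)
        best.fun = _nll(best.x, layout)
        best.success, best.status, best.nit, best.nfev = True, 0, 0, 1
        any_success = True

    theta = np.asarray(best.x, dtype=float)
    s, b, e_raw = layout.build(theta)
    e = constrain_errors(e_raw, d.response_format)
    psi = predicted_probabilities(d.levels, s, b, e_raw, d.response_format)
    gof = gof_mod.gof_statistics(d.counts, psi, layout.n_free, d.response_format)

    vals = dict(layout._fixed)
    vals.update(zip(layout.names, theta))

    if d.is_detection:
        meas = measures_mod.PerformanceMeasures(
            threshold=measures_mod.detection_threshold(s.test)
        )
        mu_at_std = None
    else:
        meas = measures_mod.performance_measures(s)
        mu_at_std = mu(d.standard, s.test)

    result = FitResult(
        label=o.label,
        optimizer={
            "converged": any_success,
            "status": int(getattr(best, "status", 0)),
            "n_iterations": int(getattr(best, "nit", 0)),
            "n_evaluations": int(getattr(best, "nfev", 0)),
            "n_starts": n_starts,
        },
        levels=d.levels,
        counts=d.counts,
        response_format=d.response_format,
        standard=d.standard,
        requested_model=(
            o.error_model.label
            if isinstance(o.error_model, ErrorModelSpec)
            else str(o.error_model)
        ),
        fitted_model=layout.model_spec.label,
        selection_criterion=None,
        psyfun_type=o.psyfun_type,
        n_free=layout.n_free,
        gof=gof,
        alpha_bounds=layout.alpha_bounds,
        beta_bounds=tuple(o.beta_bounds),
        delta1_bounds=tuple(o.delta1_bounds),
        width_bounds=layout.width_bounds,
        boundaries_reached=_boundary_report(layout, vals),
        alpha_t=float(vals["alpha_t"]),
        beta_t=float(vals["beta_t"]),
        anchor=None if d.is_detection else float(s.anchor),
        mu_t_at_standard=mu_at_std,
        delta1=float(b.delta1),
        delta2=float(b.delta2),
        errors_order1=_order_error_record(e.order1),
        errors_order2=_order_error_record(e.order2),
        pse=meas.pse,
        dl_level=meas.dl_level,
        dl=meas.dl,
        threshold=meas.threshold,
        theta=theta,
        param_names=layout.names,
        sensory=s,
        boundaries=b,
        errors=e,
    )
    return result


# ---------------------------------------------------------------------------
# Error-model enumeration and selection


def enumerate_error_models(response_format: str = "ternary") -> list[ErrorModelSpec]:
    """All error models for a format: 64 for ternary (8 masks per order over
    eps_F/eps_U/eps_S), 16 for each binary format (only the eps's not fixed
    by the format vary)."""
    free_bits = {
        "ternary": (0, 1, 2),
        "2AFC": (0, 2),  # eps_U is format-fixed at 1
        "equality": (1, 2),  # eps_F is format-fixed at 1
    }[response_format] if response_format in FORMATS else None
    if free_bits is None:
        raise ValueError(f"unknown response format {response_format!r}")
    masks = []
    for combo in itertools.product((0, 1), repeat=len(free_bits)):
        mask = [0, 0, 0]
        for bit, v in zip(free_bits, combo):
            mask[bit] = v
        masks.append(tuple(mask))
    masks.sort(key=lambda mk: (sum(mk), mk))
    return [ErrorModelSpec(m1, m2) for m1 in masks for m2 in masks]


def select_error_model(d: Dataset, o: FitOptions | None = None) -> FitResult:
    """Fit every enumerated error model and return the winner under the
    selection criterion (``loglik``: smallest -2 log L; ``bic``: smallest
    BIC).  Ties (within 1e-6) break toward fewest free parameters, then the
    lexicographically smallest model label."""
    o = o if o is not None else FitOptions(error_model="best")
    results: list[FitResult] = []
    for spec in enumerate_error_models(d.response_format):
        results.append(fit(d, replace(o, error_model=spec)))
    key = (lambda r: r.bic) if o.selection_criterion == "bic" else (
        lambda r: r.minus2loglik
    )
    best_val = min(key(r) for r in results)
    candidates = [r for r in results if key(r) <= best_val + 1e-6]
    winner = min(candidates, key=lambda r: (r.n_free, r.fitted_model))
    winner.requested_model = "best"
    winner.selection_criterion = o.selection_criterion
    return winner


# ---------------------------------------------------------------------------
# scikit-learn estimator


class IndecisionModel(BaseEstimator):
    """Scikit-learn style estimator for the indecision model.

    Parameters mirror :class:`FitOptions` plus the dataset-level declarations
    (response format and standard level).  ``fit(X, y)`` takes the test
    levels as ``X`` (shape (N,) or (N, 1)) and the response counts as ``y``
    (shape (2, 3, N)).  Fitted attributes carry a trailing underscore;
    ``result_`` holds the full :class:`FitResult` record.

    Examples
    --------
    >>> est = IndecisionModel(response_format="ternary", standard=-1.0)
    >>> est.fit(levels, counts).delta1_  # doctest: +SKIP
    """

    def __init__(
        self,
        *,
        response_format: str = "ternary",
        standard: float = DETECTION_STANDARD,
        psyfun_type: str = "same",
        error_model: Any = "(0,0)",
        selection_criterion: str = "loglik",
        alpha_bounds: tuple[float, float] | None = None,
        beta_bounds: tuple[float, float] = (0.01, 1.0),
        delta1_bounds: tuple[float, float] = (-8.0, 2.0),
        width_bounds: tuple[float, float] = (0.0, 12.0),
        anchor_bounds: tuple[float, float] = (1e-6, 100.0),
        alpha_starts: Sequence[float] | None = None,
        beta_starts: Sequence[float] = (0.05, 0.15),
        delta1_starts: Sequence[float] = (-4.0, -2.0, -0.5),
        width_starts: Sequence[float] = (5.0,),
        anchor_starts: Sequence[float] | None = None,
        eps_start: float = 0.01,
        kappa_start: float = 0.5,
        enforce_single_boundary: bool = False,
    ):
        self.response_format = response_format
        self.standard = standard
        self.psyfun_type = psyfun_type
        self.error_model = error_model
        self.selection_criterion = selection_criterion
        self.alpha_bounds = alpha_bounds
        self.beta_bounds = beta_bounds
        self.delta1_bounds = delta1_bounds
        self.width_bounds = width_bounds
        self.anchor_bounds = anchor_bounds
        self.alpha_starts = alpha_starts
        self.beta_starts = beta_starts
        self.delta1_starts = delta1_starts
        self.width_starts = width_starts
        self.anchor_starts = anchor_starts
        self.eps_start = eps_start
        self.kappa_start = kappa_start
        self.enforce_single_boundary = enforce_single_boundary

    def _options(self) -> FitOptions:
        model = self.error_model
        if isinstance(model, str) and model != "best":
            model = ErrorModelSpec.from_label(model)
        return FitOptions(
            psyfun_type=self.psyfun_type,
            error_model=model,
            selection_criterion=self.selection_criterion,
            alpha_bounds=self.alpha_bounds,
            beta_bounds=tuple(self.beta_bounds),
            delta1_bounds=tuple(self.delta1_bounds),
            width_bounds=tuple(self.width_bounds),
            anchor_bounds=tuple(self.anchor_bounds),
            alpha_starts=self.alpha_starts,
            beta_starts=tuple(self.beta_starts),
            delta1_starts=tuple(self.delta1_starts),
            width_starts=tuple(self.width_starts),
            anchor_starts=self.anchor_starts,
            eps_start=self.eps_start,
            kappa_start=self.kappa_start,
            enforce_single_boundary=self.enforce_single_boundary,
        )

    def fit(self, X, y) -> "IndecisionModel":
        levels = np.asarray(X, dtype=float).reshape(-1)
        dataset = Dataset(
            levels=levels,
            counts=np.asarray(y),
            standard=self.standard,
            response_format=self.response_format,
        )
        options = self._options()
        if options.error_model == "best":
            result = select_error_model(dataset, options)
        else:
            result = fit(dataset, options)
        self.result_ = result
        self.alpha_ = result.alpha_t
        self.beta_ = result.beta_t
        self.anchor_ = result.anchor
        self.delta1_ = result.delta1
        self.delta2_ = result.delta2
        self.n_free_ = result.n_free
        self.minus2loglik_ = result.minus2loglik
        self.bic_ = result.bic
        self.pse_ = result.pse
        self.dl_ = result.dl
        self.threshold_ = result.threshold
        self.n_features_in_ = 1
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Fitted response probabilities at levels ``X``, shape (2, 3, N)."""
        check_is_fitted(self, "result_")
        levels = np.asarray(X, dtype=float).reshape(-1)
        r = self.result_
        return predicted_probabilities(
            levels, r.sensory, r.boundaries, r.errors, r.response_format
        )

    def score(self, X, y) -> float:
        """Mean log-likelihood per trial of counts ``y`` at levels ``X``."""
        check_is_fitted(self, "result_")
        levels = np.asarray(X, dtype=float).reshape(-1)
        counts = np.asarray(y, dtype=float)
        psi = np.maximum(self.predict_proba(levels), PROB_FLOOR)
        return float(np.sum(counts * np.log(psi)) / max(counts.sum(), 1.0))
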