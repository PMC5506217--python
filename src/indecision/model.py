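"""Forward model: psychophysical function, judgment probabilities, response-error layer.

The indecision model describes an observer who compares two stimuli presented
in sequence (or side by side).  Each stimulus at level ``x`` evokes a sensory
effect that is normally distributed with unit variance around the mean given
by the psychophysical function ``mu``.  The decision variable ``D = S2 - S1``
(variance 2) is partitioned by two boundaries ``delta1 <= delta2`` into three
judgment regions: "first" (F) if ``D < delta1``, "undecided" (U) if
``delta1 < D < delta2``, and "second" (S) if ``D > delta2``.  A response-error
layer (analogous to lapse parameters) maps latent judgments onto overt
responses, and fixed settings of that layer express the classical 2AFC and
same-different response formats as special cases of the ternary model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal

import numpy as np
from scipy.special import ndtr

__all__ = [
    "PsyFunParams",
    "SensoryModel",
    "DecisionBoundaries",
    "OrderErrors",
    "ErrorParams",
    "ErrorModelSpec",
    "ResponseFormat",
    "FORMATS",
    "DETECTION_STANDARD",
    "mu",
    "mu_inverse",
    "judgment_probabilities",
    "error_matrix",
    "apply_error_model",
    "format_constraints",
    "predicted_probabilities",
]

SQRT2 = np.sqrt(2.0)
LOG2 = np.log(2.0)

ResponseFormat = Literal["ternary", "2AFC", "equality"]
FORMATS: tuple[str, ...] = ("ternary", "2AFC", "equality")

#: Sentinel standard level declaring a detection task (null standard).
DETECTION_STANDARD = -np.inf

# Response/judgment category indices used throughout: F=0, U=1, S=2.
CATEGORIES = ("F", "U", "S")


@dataclass(frozen=True)
class PsyFunParams:
    """Location ``alpha`` and scale ``beta`` of the psychophysical function.

    ``mu(x) = log(1 + 2 exp((x - alpha)/beta))`` rises from 0 at low levels to
    an oblique asymptote ``log 2 + (x - alpha)/beta``; ``1/beta`` is the
    asymptotic slope, and ``mu(alpha) = log 3``.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha):
            raise ValueError(f"alpha must be finite, got {self.alpha}")
        if not (np.isfinite(self.beta) and self.beta > 0):
            raise ValueError(f"beta must be a positive real, got {self.beta}")


def mu(x, p: PsyFunParams):
    """Mean sensory effect at stimulus level ``x``.

    Overflow-safe: for large ``(x - alpha)/beta`` the value is computed from
    the oblique-asymptote rearrangement ``t + log 2 + log1p(exp(-t)/2)``.
    """
    x = np.asarray(x, dtype=float)
    t = (x - p.alpha) / p.beta
    out = np.empty_like(t)
    small = t < 30.0
    out[small] = np.log1p(2.0 * np.exp(t[small]))
    big = ~small
    out[big] = t[big] + LOG2 + np.log1p(np.exp(-t[big]) / 2.0)
    return out if out.ndim else float(out)


def mu_inverse(y, p: PsyFunParams):
    """Stimulus level whose mean sensory effect is ``y`` (inverse of :func:`mu`).

    Closed form ``x = alpha + beta * (log(expm1(y)) - log 2)``; valid for
    ``y > 0`` since mu's range is (0, inf).
    """
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("mu_inverse requires y > 0 (mu's range is (0, inf))")
    out = np.empty_like(y)
    small = y < 30.0
    out[small] = p.alpha + p.beta * (np.log(np.expm1(y[small])) - LOG2)
    out[~small] = p.alpha + p.beta * (y[~small] - LOG2)  # expm1(y) ~ e^y
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SensoryModel:
    """Test psychophysical function plus the standard's subjective anchor.

    ``anchor`` is the mean sensory effect of the standard, ``mu_s(x_s)``:
    0 in detection (null standard), ``mu(x_s; test)`` when a common
    psychophysical function is assumed (``shared``), or a free parameter when
    test and standard follow different functions (``free_anchor``).
    """

    test: PsyFunParams
    standard_mode: Literal["detection", "shared", "free_anchor"]
    standard_level: float
    anchor: float

    @classmethod
    def detection(cls, test: PsyFunParams) -> "SensoryModel":
        return cls(test, "detection", DETECTION_STANDARD, 0.0)

    @classmethod
    def shared(cls, test: PsyFunParams, standard_level: float) -> "SensoryModel":
        return cls(test, "shared", standard_level, mu(standard_level, test))

    @classmethod
    def free_anchor(
        cls, test: PsyFunParams, standard_level: float, anchor: float
    ) -> "SensoryModel":
        if anchor <= 0:
            raise ValueError("the anchor mu_s(x_s) must be positive")
        return cls(test, "free_anchor", standard_level, anchor)

    @property
    def is_detection(self) -> bool:
        return self.standard_mode == "detection"

    def __post_init__(self) -> None:
        if self.standard_mode not in ("detection", "shared", "free_anchor"):
            raise ValueError(f"unknown standard_mode {self.standard_mode!r}")
        if self.standard_mode == "detection":
            if self.anchor != 0.0:
                raise ValueError("detection mode requires anchor = 0")
        elif not np.isfinite(self.standard_level):
            raise ValueError("discrimination requires a finite standard level")


@dataclass(frozen=True)
class DecisionBoundaries:
    """Boundaries ``delta1 <= delta2`` partitioning the decision axis.

    Width ``delta2 - delta1 = 0`` is a valid degenerate point: the classical
    2AFC difference model in which U judgments never occur.
    """

    delta1: float
    delta2: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.delta1) and np.isfinite(self.delta2)):
            raise ValueError("boundaries must be finite")
        if self.delta1 > self.delta2:
            raise ValueError(
                f"delta1 ({self.delta1}) must not exceed delta2 ({self.delta2})"
            )

    @property
    def width(self) -> float:
        return self.delta2 - self.delta1


def judgment_probabilities(
    x, order: int, s: SensoryModel, b: DecisionBoundaries
) -> tuple:
    """Latent judgment probabilities (pF, pU, pS) at test level(s) ``x``.

    ``order`` is 1 when the test is presented first (D has mean
    ``mu_s(x_s) - mu_t(x)``) and 2 when it is presented second (mean
    ``mu_t(x) - mu_s(x_s)``); D's variance is 2 in both cases.  pU is
    computed as a difference of two normal CDF values so it can never go
    negative in the tails.
    """
    if order not in (1, 2):
        raise ValueError(f"order must be 1 or 2, got {order}")
    mt = mu(x, s.test)
    mean = s.anchor - mt if order == 1 else mt - s.anchor
    lo = ndtr((b.delta1 - mean) / SQRT2)
    hi = ndtr((b.delta2 - mean) / SQRT2)
    pF = lo
    pU = np.maximum(hi - lo, 0.0)
    pS = 1.0 - hi
    return pF, pU, pS


@dataclass(frozen=True)
class OrderErrors:
    """Response-error layer for one presentation order.

    ``eps_X`` is the probability of misreporting an X judgment; ``kappa_XY``
    the bias toward misreporting X as Y.  Only one kappa per branching point
    is free — the complements ``kappa_FS = 1 - kappa_FU``,
    ``kappa_US = 1 - kappa_UF`` and ``kappa_SU = 1 - kappa_SF`` are derived.
    """

    eps_F: float = 0.0
    eps_U: float = 0.0
    eps_S: float = 0.0
    kappa_FU: float = 0.5
    kappa_UF: float = 0.5
    kappa_SF: float = 0.5

    def __post_init__(self) -> None:
        for name in ("eps_F", "eps_U", "eps_S", "kappa_FU", "kappa_UF", "kappa_SF"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @property
    def kappa_FS(self) -> float:
        return 1.0 - self.kappa_FU

    @property
    def kappa_US(self) -> float:
        return 1.0 - self.kappa_UF

    @property
    def kappa_SU(self) -> float:
        return 1.0 - self.kappa_SF


@dataclass(frozen=True)
class ErrorParams:
    """Per-order error layers (order 1 = test first, order 2 = test second)."""

    order1: OrderErrors = field(default_factory=OrderErrors)
    order2: OrderErrors = field(default_factory=OrderErrors)

    def for_order(self, order: int) -> OrderErrors:
        if order == 1:
            return self.order1
        if order == 2:
            return self.order2
        raise ValueError(f"order must be 1 or 2, got {order}")


def error_matrix(e: OrderErrors) -> np.ndarray:
    """3x3 column-stochastic matrix mapping judgment probabilities to response
    probabilities: ``Psi = M @ p`` with categories ordered (F, U, S)."""
    return np.array(
        [
            [1.0 - e.eps_F, e.eps_U * e.kappa_UF, e.eps_S * e.kappa_SF],
            [e.eps_F * e.kappa_FU, 1.0 - e.eps_U, e.eps_S * e.kappa_SU],
            [e.eps_F * e.kappa_FS, e.eps_U * e.kappa_US, 1.0 - e.eps_S],
        ]
    )


def apply_error_model(p, e: ErrorParams, order: int):
    """Map latent judgment probabilities onto overt response probabilities.

    ``p`` is a (pF, pU, pS) triple (scalars or arrays).  With all eps = 0 the
    output equals the input (no misreports).
    """
    M = error_matrix(e.for_order(order))
    pF, pU, pS = (np.asarray(v, dtype=float) for v in p)
    psi = np.tensordot(M, np.stack([pF, pU, pS]), axes=1)
    return psi[0], psi[1], psi[2]


def format_constraints(f: str) -> dict:
    """Fixed error-layer values implied by a response format.

    2AFC: U judgments are always misreported (guessed) as F or S
    (``eps_U = 1``) and F/S judgments can only be misreported as each other
    (``kappa_FS = 1`` i.e. ``kappa_FU = 0``; ``kappa_SF = 1``).

    Same-different ("equality"): F judgments are always folded into the
    "different" category or mistakenly into "same" (``eps_F = 1``), while U
    and S misreports cross into the other binary category
    (``kappa_US = 1`` i.e. ``kappa_UF = 0``; ``kappa_SU = 1`` i.e.
    ``kappa_SF = 0``).  "Same" counts are carried in the U row and
    "different" counts in the S row; the F row is structurally zero.
    """
    if f == "ternary":
        return {}
    if f == "2AFC":
        return {"eps_U": 1.0, "kappa_FU": 0.0, "kappa_SF": 1.0}
    if f == "equality":
        return {"eps_F": 1.0, "kappa_UF": 0.0, "kappa_SF": 0.0}
    raise ValueError(f"unknown response format {f!r}; expected one of {FORMATS}")


def constrain_errors(e: ErrorParams, f: str) -> ErrorParams:
    """Return ``e`` with the format-fixed values overriding the stored ones."""
    fixed = format_constraints(f)
    if not fixed:
        return e
    return ErrorParams(replace(e.order1, **fixed), replace(e.order2, **fixed))


def predicted_probabilities(
    levels,
    s: SensoryModel,
    b: DecisionBoundaries,
    e: ErrorParams,
    f: str = "ternary",
) -> np.ndarray:
    """Response probabilities as a 2x3xN array (order x {F,U,S} x level).

    Applies the format constraints of :func:`format_constraints` on top of
    ``e`` before the error layer, so binary formats produce their structural
    zero row exactly.
    """
    levels = np.atleast_1d(np.asarray(levels, dtype=float))
    if not np.all(np.isfinite(levels)):
        raise ValueError("test levels must be finite")
    e = constrain_errors(e, f)
    out = np.empty((2, 3, levels.size))
    for m in (1, 2):
        p = judgment_probabilities(levels, m, s, b)
        psi = apply_error_model(p, e, m)
        out[m - 1] = np.stack([np.atleast_1d(c) for c in psi])
    return out


# ---------------------------------------------------------------------------
# Error-model lattice


@dataclass(frozen=True)
class ErrorModelSpec:
    """Which eps parameters are free, per presentation order.

    Each mask is a 3-tuple of 0/1 flags over (eps_F, eps_U, eps_S).  An
    excluded eps is fixed at 0 and its associated kappa leaves the free set.
    There are 8 masks per order, hence 64 combinations for the ternary tree;
    under binary formats only the format-free eps's vary (16 combinations).
    """

    order1: tuple[int, int, int] = (0, 0, 0)
    order2: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        for mask in (self.order1, self.order2):
            if len(mask) != 3 or any(v not in (0, 1) for v in mask):
                raise ValueError(f"mask must be a 3-tuple of 0/1 flags, got {mask}")

    def mask(self, order: int) -> tuple[int, int, int]:
        return self.order1 if order == 1 else self.order2

    @staticmethod
    def _label_one(mask: Iterable[int]) -> str:
        mask = tuple(mask)
        if mask == (0, 0, 0):
            return "0"
        if mask == (1, 1, 1):
            return "1"
        return "".join(c for c, m in zip(CATEGORIES, mask) if m)

    @property
    def label(self) -> str:
        """Model label, anchored at "(0,0)" (no error parameters) and
        "(1,1)" (all of them); partial masks list the included eps's."""
        return f"({self._label_one(self.order1)},{self._label_one(self.order2)})"

    @classmethod
    def from_label(cls, label: str) -> "ErrorModelSpec":
        body = label.strip().strip("()")
        parts = [p.strip() for p in body.split(",")]
        if len(parts) != 2:
            raise ValueError(f"cannot parse error-model label {label!r}")
        masks = []
        for part in parts:
            if part == "0":
                masks.append((0, 0, 0))
            elif part == "1":
                masks.append((1, 1, 1))
            else:
                if not set(part) <= set(CATEGORIES):
                    raise ValueError(f"cannot parse error-model label {label!r}")
                masks.append(tuple(int(c in part) for c in CATEGORIES))
        return cls(masks[0], masks[1])
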