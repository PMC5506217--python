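"""Performance measures derived from fitted psychophysical functions.

PSE, difference limen, and detection threshold are obtained from the
estimated psychophysical functions themselves, not from crossings of the
observable psychometric curves (which are distorted by indecision and by
response errors):

* PSE: the level at which the test's mean sensory effect equals the
  standard's anchor, ``x_PSE = mu_t^{-1}(mu_s(x_s))``.
* DL: the level at which ``Prob(S_t - S_s > 0) = 0.75``, i.e.
  ``x_DL = mu_t^{-1}(mu_s(x_s) + z_0.75 * sqrt(2))``; the classical DL is
  the distance ``x_DL - x_PSE`` and both are reported.
* Detection threshold: the level at which the test's sensory effect exceeds
  the null standard's with probability 0.84,
  ``theta = mu_t^{-1}(z_0.84 * sqrt(2))``.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import norm

from .model import SQRT2, PsyFunParams, SensoryModel, mu_inverse

__all__ = [
    "CriterionLevels",
    "PerformanceMeasures",
    "UndefinedMeasureError",
    "pse",
    "difference_limen",
    "detection_threshold",
    "performance_measures",
]


class UndefinedMeasureError(ValueError):
    """Raised when a measure is undefined for the task at hand (e.g. a PSE
    for detection data, or a detection threshold for discrimination data)."""


@dataclass(frozen=True)
class CriterionLevels:
    """Exceedance-probability criteria defining the DL (default 0.75) and the
    detection threshold (default 0.84); the corresponding unit-normal
    quantiles are exposed as properties."""

    dl_prob: float = 0.75
    threshold_prob: float = 0.84

    def __post_init__(self) -> None:
        for name in ("dl_prob", "threshold_prob"):
            v = getattr(self, name)
            if not (0.5 < v < 1.0):
                raise ValueError(f"{name} must lie in (0.5, 1), got {v}")

    @property
    def z_dl(self) -> float:
        return float(norm.ppf(self.dl_prob))

    @property
    def z_threshold(self) -> float:
        return float(norm.ppf(self.threshold_prob))


@dataclass(frozen=True)
class PerformanceMeasures:
    """PSE/DL (discrimination) or detection threshold (detection); the
    inapplicable entries are None."""

    pse: float | None = None
    dl_level: float | None = None
    dl: float | None = None
    threshold: float | None = None


def pse(s: SensoryModel) -> float:
    """Point of subjective equality: level at which mu_t equals the anchor.

    When a common psychophysical function holds for test and standard this is
    the standard level itself.
    """
    if s.is_detection:
        raise UndefinedMeasureError("the PSE is undefined for detection tasks")
    if s.standard_mode == "shared":
        return float(s.standard_level)  # mu_t = mu_s makes x_PSE = x_s exactly
    return mu_inverse(s.anchor, s.test)


def difference_limen(
    s: SensoryModel, c: CriterionLevels = CriterionLevels()
) -> tuple[float, float]:
    """(dl_level, dl): the level where the test's sensory effect exceeds the
    standard's with probability ``c.dl_prob``, and its distance to the PSE."""
    if s.is_detection:
        raise UndefinedMeasureError("the DL is undefined for detection tasks")
    dl_level = mu_inverse(s.anchor + c.z_dl * SQRT2, s.test)
    return dl_level, dl_level - pse(s)


def detection_threshold(
    p: PsyFunParams, c: CriterionLevels = CriterionLevels()
) -> float:
    """Level where the test's sensory effect exceeds the null standard's with
    probability ``c.threshold_prob`` (``mu(theta) = z * sqrt(2)``, 1.406 at
    the default 0.84 criterion)."""
    return mu_inverse(c.z_threshold * SQRT2, p)


def performance_measures(
    s: SensoryModel, c: CriterionLevels = CriterionLevels()
) -> PerformanceMeasures:
    """All measures applicable to the task encoded in ``s``."""
    if s.is_detection:
        return PerformanceMeasures(threshold=detection_threshold(s.test, c))
    dl_level, dl = difference_limen(s, c)
    return PerformanceMeasures(pse=pse(s), dl_level=dl_level, dl=dl)
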