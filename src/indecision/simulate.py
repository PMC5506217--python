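"""Synthetic response data and the format-comparison recovery study.

Replicates are generated under the conditions of the model's comparative
evaluation: true parameters drawn from uniform distributions
(alpha_t on [-3, -2], beta_t on [0.05, 0.10], delta1 on [-4, -2], delta2 on
[2, 4]; with unequal psychophysical functions the anchor mu_s(x_s) is drawn
on [mu_t(x_s) - 1, mu_t(x_s) + 1]); responses are multinomial draws from the
format-constrained model at 11 test levels spaced 0.1 apart, 40 trials per
level per presentation order.  In detection the central level is the true
alpha_t rounded to the nearest 0.1; in discrimination it is the standard
x_s = -1 (suprathreshold given those parameter ranges).  Under error regime
"model11" the eps's are drawn on [0, 0.02] and the kappas on [0, 1]; under
"model00" all eps's are 0.

True parameters are drawn from a per-replicate substream keyed only by
(seed, replicate), so every scenario sees the same true parameters at a
given replicate index; response noise uses a scenario-specific substream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import Dataset, FitOptions, default_alpha_bounds, fit
from .measures import (
    detection_threshold,
    difference_limen,
    pse as pse_measure,
)
from .model import (
    DETECTION_STANDARD,
    DecisionBoundaries,
    ErrorModelSpec,
    ErrorParams,
    OrderErrors,
    PsyFunParams,
    SensoryModel,
    mu,
    predicted_probabilities,
)

__all__ = [
    "ScenarioSpec",
    "TrueParams",
    "SCENARIOS",
    "draw_true_params",
    "design_levels",
    "build_sensory_model",
    "simulate_responses",
    "recovery_study",
    "summarize_recovery",
]

DISCRIMINATION_STANDARD = -1.0  # suprathreshold given alpha_t in [-3, -2]


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the format-comparison design."""

    task: str  # "detection" | "discrimination"
    response_format: str  # "ternary" | "2AFC" | "equality"
    psyfun_type: str = "same"  # "same" | "diff"
    error_regime: str = "model00"  # "model00" | "model11"
    n_levels: int = 11
    step: float = 0.1
    trials_per_level_per_order: int = 40
    n_replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("detection", "discrimination"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.error_regime not in ("model00", "model11"):
            raise ValueError(f"unknown error regime {self.error_regime!r}")
        if self.n_levels % 2 == 0 or self.n_levels < 1:
            raise ValueError("n_levels must be a positive odd integer")

    @property
    def name(self) -> str:
        parts = [self.response_format, self.task]
        if self.task == "discrimination":
            parts.append(self.psyfun_type)
        return "-".join(parts)


#: The seven scenarios of the format comparison.
SCENARIOS: dict[str, ScenarioSpec] = {
    s.name: s
    for s in (
        ScenarioSpec("detection", "ternary"),
        ScenarioSpec("detection", "2AFC"),
        ScenarioSpec("discrimination", "ternary", "same"),
        ScenarioSpec("discrimination", "2AFC", "same"),
        ScenarioSpec("discrimination", "ternary", "diff"),
        ScenarioSpec("discrimination", "2AFC", "diff"),
        ScenarioSpec("discrimination", "equality", "same"),
    )
}


@dataclass(frozen=True)
class TrueParams:
    """One generating parameter set; the anchor offset and the error layer
    are always drawn so the same draw serves every scenario."""

    alpha_t: float
    beta_t: float
    delta1: float
    delta2: float
    anchor_offset: float  # anchor = mu_t(x_s) + offset when psyfun_type="diff"
    eps: np.ndarray = field(repr=False)  # (2, 3) over (F, U, S)
    kappa: np.ndarray = field(repr=False)  # (2, 3) over (FU, UF, SF)

    @property
    def test(self) -> PsyFunParams:
        return PsyFunParams(self.alpha_t, self.beta_t)

    @property
    def boundaries(self) -> DecisionBoundaries:
        return DecisionBoundaries(self.delta1, self.delta2)

    def errors(self, regime: str) -> ErrorParams:
        eps = self.eps if regime == "model11" else np.zeros((2, 3))
        orders = [
            OrderErrors(
                eps_F=eps[m, 0], eps_U=eps[m, 1], eps_S=eps[m, 2],
                kappa_FU=self.kappa[m, 0],
                kappa_UF=self.kappa[m, 1],
                kappa_SF=self.kappa[m, 2],
            )
            for m in (0, 1)
        ]
        return ErrorParams(*orders)


def draw_true_params(rng: np.random.Generator) -> TrueParams:
    """Draw one replicate's generating parameters (fixed draw order so that
    substream-sharing across scenarios is exact)."""
    return TrueParams(
        alpha_t=rng.uniform(-3.0, -2.0),
        beta_t=rng.uniform(0.05, 0.10),
        delta1=rng.uniform(-4.0, -2.0),
        delta2=rng.uniform(2.0, 4.0),
        anchor_offset=rng.uniform(-1.0, 1.0),
        eps=rng.uniform(0.0, 0.02, size=(2, 3)),
        kappa=rng.uniform(0.0, 1.0, size=(2, 3)),
    )


def design_levels(spec: ScenarioSpec, true: TrueParams) -> np.ndarray:
    """Test-level grid: centered on round(alpha_t / step) * step for
    detection, on the standard level for discrimination; the remaining
    levels move out in steps of ``spec.step`` in each direction."""
    if spec.task == "detection":
        center = np.round(true.alpha_t / spec.step) * spec.step
    else:
        center = DISCRIMINATION_STANDARD
    half = spec.n_levels // 2
    return center + spec.step * np.arange(-half, half + 1)


def build_sensory_model(spec: ScenarioSpec, true: TrueParams) -> SensoryModel:
    if spec.task == "detection":
        return SensoryModel.detection(true.test)
    if spec.psyfun_type == "same":
        return SensoryModel.shared(true.test, DISCRIMINATION_STANDARD)
    anchor = mu(DISCRIMINATION_STANDARD, true.test) + true.anchor_offset
    return SensoryModel.free_anchor(true.test, DISCRIMINATION_STANDARD, anchor)


def simulate_responses(
    levels, true: TrueParams, spec: ScenarioSpec, rng: np.random.Generator
) -> Dataset:
    """Multinomial response counts from the format-constrained model."""
    levels = np.asarray(levels, dtype=float)
    s = build_sensory_model(spec, true)
    psi = predicted_probabilities(
        levels, s, true.boundaries, true.errors(spec.error_regime),
        spec.response_format,
    )
    psi = np.clip(psi, 0.0, None)
    psi /= psi.sum(axis=1, keepdims=True)
    n = spec.trials_per_level_per_order
    counts = np.empty((2, 3, levels.size), dtype=int)
    for m in range(2):
        for i in range(levels.size):
            counts[m, :, i] = rng.multinomial(n, psi[m, :, i])
    standard = (
        DETECTION_STANDARD if spec.task == "detection" else DISCRIMINATION_STANDARD
    )
    return Dataset(levels, counts, standard, spec.response_format)


def _study_fit_options(spec: ScenarioSpec, levels) -> FitOptions:
    mask = (1, 1, 1) if spec.error_regime == "model11" else (0, 0, 0)
    return FitOptions(
        psyfun_type=spec.psyfun_type if spec.task == "discrimination" else "same",
        error_model=ErrorModelSpec(mask, mask),
        alpha_bounds=default_alpha_bounds(levels, spec.task == "detection"),
    )


def _measure_rows(spec: ScenarioSpec, s: SensoryModel) -> dict[str, float]:
    if spec.task == "detection":
        return {"threshold": detection_threshold(s.test)}
    rows = {"dl": difference_limen(s)[1]}
    if spec.psyfun_type == "diff":
        rows["pse"] = pse_measure(s)
    return rows


def recovery_study(spec: ScenarioSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate-and-refit study for one scenario.

    Returns a tidy per-replicate table (columns: replicate, parameter, true,
    estimated) and a per-parameter summary (bias, rmse, correlation, n).
    Replicates whose fit raises are excluded and counted in the summary
    attribute ``n_failed``.
    """
    fmt_code = {"ternary": 1, "2AFC": 2, "equality": 3}[spec.response_format]
    task_code = {"detection": 1, "discrimination": 2}[spec.task]
    rows = []
    n_failed = 0
    for rep in range(spec.n_replicates):
        true = draw_true_params(
            np.random.default_rng(np.random.SeedSequence([spec.seed, rep]))
        )
        levels = design_levels(spec, true)
        noise_rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, rep, fmt_code, task_code])
        )
        data = simulate_responses(levels, true, spec, noise_rng)
        try:
            result = fit(data, _study_fit_options(spec, levels))
        except Exception:
            n_failed += 1
            continue
        true_sensory = build_sensory_model(spec, true)
        est_sensory = result.sensory
        pairs = {
            "alpha_t": (true.alpha_t, result.alpha_t),
            "beta_t": (true.beta_t, result.beta_t),
            "delta1": (true.delta1, result.delta1),
            "delta2": (true.delta2, result.delta2),
        }
        true_meas = _measure_rows(spec, true_sensory)
        est_meas = _measure_rows(spec, est_sensory)
        for name in true_meas:
            pairs[name] = (true_meas[name], est_meas[name])
        for name, (t, e) in pairs.items():
            rows.append(
                {"replicate": rep, "parameter": name, "true": t, "estimated": e}
            )
    table = pd.DataFrame(rows, columns=["replicate", "parameter", "true", "estimated"])
    summary = summarize_recovery(table)
    summary.attrs["n_failed"] = n_failed
    summary.attrs["scenario"] = spec.name
    table.attrs["n_failed"] = n_failed
    table.attrs["scenario"] = spec.name
    return table, summary


def summarize_recovery(table: pd.DataFrame) -> pd.DataFrame:
    """Per-parameter bias, RMSE, and true-vs-estimated correlation."""
    out = []
    for name, grp in table.groupby("parameter", sort=True):
        err = grp["estimated"] - grp["true"]
        if grp["true"].std() > 0 and grp["estimated"].std() > 0:
            corr = float(np.corrcoef(grp["true"], grp["estimated"])[0, 1])
        else:
            corr = float("nan")
        out.append(
            {
                "parameter": name,
                "bias": float(err.mean()),
                "rmse": float(np.sqrt(np.mean(err**2))),
                "correlation": corr,
                "n": int(len(grp)),
            }
        )
    return pd.DataFrame(out, columns=["parameter", "bias", "rmse", "correlation", "n"])
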