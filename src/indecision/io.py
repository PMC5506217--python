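"""Readers and writers for the 7-row data layout and for fit-result records.

Data files are delimited text with as many columns as test levels and seven
rows: row 1 the test levels, rows 2-4 the F/U/S counts with the test
presented first, rows 5-7 the F/U/S counts with the test presented second.
Fields may be separated by commas or whitespace; lines starting with '#' are
comments, and '#key: value' header lines may declare the standard level
(``-inf`` for detection) and the response format.  Explicit function
arguments win over header declarations.

For same-different ("equality") data the "same" counts are stored in the U
rows (3 and 6) and the "different" counts in the S rows (4 and 7); the F
rows are structurally zero.

Fit results serialize to JSON with a stable field order mirroring the
54-field output record of the reference fitting routine.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np

from .estimation import Dataset, FitResult
from .gof import GofReport
from .model import DETECTION_STANDARD

__all__ = [
    "read_dataset",
    "write_dataset",
    "result_to_dict",
    "result_from_dict",
    "write_result",
    "read_result",
]

RESULT_FORMAT_VERSION = 1

_DETECTION_TOKENS = {"-inf", "-infinity", "detection"}


def _parse_header(lines: list[str]) -> dict[str, str]:
    meta = {}
    for line in lines:
        m = re.match(r"#\s*([A-Za-z_]+)\s*[:=]\s*(.+?)\s*$", line)
        if m:
            meta[m.group(1).lower()] = m.group(2)
    return meta


def read_dataset(
    path, standard: float | None = None, response_format: str | None = None
) -> Dataset:
    """Read a 7-row data file.

    ``standard`` and ``response_format`` override any '#standard:' /
    '#format:' header lines.  Levels are sorted ascending (count columns
    permuted accordingly) and duplicate levels are merged by summing counts;
    structural-zero rows are validated against the declared format.
    """
    path = Path(path)
    text = path.read_text()
    comment_lines = [ln for ln in text.splitlines() if ln.lstrip().startswith("#")]
    meta = _parse_header(comment_lines)

    rows: list[list[float]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = re.split(r"[,\s]+", stripped)
        try:
            rows.append([float(f) for f in fields if f])
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: non-numeric field") from exc
    if len(rows) != 7:
        raise ValueError(f"{path}: expected 7 numeric rows, found {len(rows)}")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"{path}: ragged rows (column counts {sorted(widths)})")

    arr = np.array(rows, dtype=float)
    levels = arr[0]
    counts = arr[1:].reshape(2, 3, -1)
    bad = np.argwhere((counts < 0) | (counts != np.round(counts)))
    if bad.size:
        m, r, i = bad[0]
        raise ValueError(
            f"{path}: row {2 + 3 * m + r}, column {i + 1}: counts must be "
            "nonnegative integers"
        )

    if standard is None:
        raw = meta.get("standard")
        if raw is None:
            raise ValueError(
                f"{path}: standard level missing (pass standard= or add a "
                "'#standard: <level>' header; use -inf for detection)"
            )
        standard = (
            DETECTION_STANDARD if raw.lower() in _DETECTION_TOKENS else float(raw)
        )
    if response_format is None:
        response_format = meta.get("format", "ternary")
    if response_format.lower() == "2afc":
        response_format = "2AFC"
    return Dataset(levels, counts.astype(int), standard, response_format)


def write_dataset(d: Dataset, path) -> None:
    """Write a dataset in the 7-row layout with metadata header lines."""
    path = Path(path)
    std = "-inf" if d.is_detection else f"{d.standard:.10g}"
    lines = [
        f"# standard: {std}",
        f"# format: {d.response_format}",
        " ".join(f"{x:.10g}" for x in d.levels),
    ]
    for m in range(2):
        for r in range(3):
            lines.append(" ".join(str(int(c)) for c in d.counts[m, r]))
    path.write_text("\n".join(lines) + "\n")


def result_to_dict(r: FitResult) -> dict:
    """Serialize a fit result with the canonical field order."""
    return {
        "version": RESULT_FORMAT_VERSION,
        "label": r.label,
        "optimizer": dict(r.optimizer),
        "levels": [float(x) for x in r.levels],
        "counts": np.asarray(r.counts).astype(int).tolist(),
        "format": r.response_format,
        "standard": "-inf" if np.isneginf(r.standard) else float(r.standard),
        "requested_model": r.requested_model,
        "fitted_model": r.fitted_model,
        "selection_criterion": r.selection_criterion,
        "type": r.psyfun_type,
        "n_free_parameters": r.n_free,
        "n_cells": r.gof.n_cells,
        "n_expected_lt5": r.gof.n_expected_lt5,
        "n_expected_lt5_obs_nonnull": r.gof.n_expected_lt5_obs_nonnull,
        "n_expected_lt1": r.gof.n_expected_lt1,
        "n_expected_lt1_obs_nonnull": r.gof.n_expected_lt1_obs_nonnull,
        "df": r.gof.df,
        "X2": r.gof.X2,
        "p_X2": r.gof.p_X2,
        "G2": r.gof.G2,
        "p_G2": r.gof.p_G2,
        "BIC": r.gof.bic,
        "minus2loglik": r.gof.minus2loglik,
        "alpha_bounds": list(r.alpha_bounds),
        "beta_bounds": list(r.beta_bounds),
        "delta1_bounds": list(r.delta1_bounds),
        "width_bounds": list(r.width_bounds),
        "boundaries_reached": list(r.boundaries_reached),
        "alpha_t": r.alpha_t,
        "beta_t": r.beta_t,
        "anchor": r.anchor,
        "mu_t_at_standard": r.mu_t_at_standard,
        "delta1": r.delta1,
        "delta2": r.delta2,
        "errors_order1": dict(r.errors_order1),
        "errors_order2": dict(r.errors_order2),
        "PSE": r.pse,
        "DL_level": r.dl_level,
        "DL": r.dl,
        "threshold": r.threshold,
        "theta": [float(v) for v in r.theta],
        "param_names": list(r.param_names),
    }


def result_from_dict(d: dict) -> FitResult:
    """Rebuild a :class:`FitResult` from its serialized form (lossless for
    every reported field; the in-memory model objects are reconstructed)."""
    from .model import (  # local import to avoid cycle noise at module load
        DecisionBoundaries,
        ErrorParams,
        OrderErrors,
        PsyFunParams,
        SensoryModel,
        constrain_errors,
    )

    standard = (
        DETECTION_STANDARD if d["standard"] == "-inf" else float(d["standard"])
    )
    test = PsyFunParams(d["alpha_t"], d["beta_t"])
    if np.isneginf(standard):
        sensory = SensoryModel.detection(test)
    elif d["type"] == "same":
        sensory = SensoryModel.shared(test, standard)
    else:
        sensory = SensoryModel.free_anchor(test, standard, d["anchor"])
    orders = []
    for key in ("errors_order1", "errors_order2"):
        e = d[key]
        orders.append(
            OrderErrors(
                eps_F=e["eps_F"], eps_U=e["eps_U"], eps_S=e["eps_S"],
                kappa_FU=e["kappa_FU"], kappa_UF=e["kappa_UF"],
                kappa_SF=e["kappa_SF"],
            )
        )
    errors = constrain_errors(ErrorParams(*orders), d["format"])
    gof = GofReport(
        n_cells=d["n_cells"],
        n_expected_lt5=d["n_expected_lt5"],
        n_expected_lt5_obs_nonnull=d["n_expected_lt5_obs_nonnull"],
        n_expected_lt1=d["n_expected_lt1"],
        n_expected_lt1_obs_nonnull=d["n_expected_lt1_obs_nonnull"],
        df=d["df"],
        X2=d["X2"],
        p_X2=d["p_X2"],
        G2=d["G2"],
        p_G2=d["p_G2"],
        bic=d["BIC"],
        minus2loglik=d["minus2loglik"],
    )
    return FitResult(
        label=d["label"],
        optimizer=dict(d["optimizer"]),
        levels=np.asarray(d["levels"], dtype=float),
        counts=np.asarray(d["counts"], dtype=int),
        response_format=d["format"],
        standard=standard,
        requested_model=d["requested_model"],
        fitted_model=d["fitted_model"],
        selection_criterion=d["selection_criterion"],
        psyfun_type=d["type"],
        n_free=d["n_free_parameters"],
        gof=gof,
        alpha_bounds=tuple(d["alpha_bounds"]),
        beta_bounds=tuple(d["beta_bounds"]),
        delta1_bounds=tuple(d["delta1_bounds"]),
        width_bounds=tuple(d["width_bounds"]),
        boundaries_reached=list(d["boundaries_reached"]),
        alpha_t=d["alpha_t"],
        beta_t=d["beta_t"],
        anchor=d["anchor"],
        mu_t_at_standard=d["mu_t_at_standard"],
        delta1=d["delta1"],
        delta2=d["delta2"],
        errors_order1=dict(d["errors_order1"]),
        errors_order2=dict(d["errors_order2"]),
        pse=d["PSE"],
        dl_level=d["DL_level"],
        dl=d["DL"],
        threshold=d["threshold"],
        theta=np.asarray(d["theta"], dtype=float),
        param_names=list(d["param_names"]),
        sensory=sensory,
        boundaries=DecisionBoundaries(d["delta1"], d["delta2"]),
        errors=errors,
    )


def write_result(r: FitResult, path) -> None:
    Path(path).write_text(json.dumps(result_to_dict(r), indent=2) + "\n")


def read_result(path) -> FitResult:
    return result_from_dict(json.loads(Path(path).read_text()))
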