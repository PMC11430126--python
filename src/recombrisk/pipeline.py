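"""End-to-end analysis pipeline.

raw assay table → per-line endpoints → mechanistic & empirical fits →
composite H×G calibration → per-line ERR predictions → report.

The composite predictor H×G (percent scale) is inverted to an ERR either
exactly, through the monotone mechanistic composite (default — the linear
calibration leaves a visible systematic error at the top of the panel
range because the composite is convex there), or through the linear
calibration line (printed panel line by default, optionally refit from
lines with a known reference ERR).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .endpoints import compute_endpoints
from .fitting import (
    CorrelationScreen,
    FitError,
    FitResult,
    correlation_screen,
    fit_h_mechanistic,
    fit_linear,
    fit_logistic,
    fit_polynomial,
    smoothed_sem_weights,
)
from .models import (
    DEFAULT_CALIBRATION,
    DEFAULT_G_PARAMS,
    DEFAULT_H_PARAMS,
    GModelParams,
    HModelParams,
    LinearCalibration,
    invert_hg,
    predict_err,
)
from .panel import (
    CellLineRecord,
    Endpoint,
    EndpointSet,
    SyndromeERR,
    read_err_table,
    read_panel,
    reference_err_table,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineReport", "ComparisonResult", "run_pipeline", "compare_to_reference"]


@dataclass
class PipelineReport:
    """Everything the pipeline computed, ready to serialize."""

    endpoint_table: pd.DataFrame
    fit_results: dict[str, FitResult]
    screens: dict[str, CorrelationScreen]
    calibration: LinearCalibration
    predictions: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "calibration": {
                "intercept": self.calibration.intercept,
                "slope": self.calibration.slope,
                "r": None if np.isnan(self.calibration.r) else self.calibration.r,
            },
            "fits": {k: f.to_dict() for k, f in self.fit_results.items()},
            "screens": {
                k: {"r": s.r, "p_value": s.p_value, "verdict": s.verdict}
                for k, s in self.screens.items()
            },
            "predictions": self.predictions.to_dict(orient="records"),
        }

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(self.to_dict(), indent=2, default=float) + "\n")
        self.endpoint_table.to_csv(out / "endpoints.csv", index=False)
        self.predictions.to_csv(out / "predictions.csv", index=False)


@dataclass
class ComparisonResult:
    """Per-syndrome predicted-vs-reference differences and their Pearson r."""

    table: pd.DataFrame
    r: float


def _endpoint_frame(sets: Iterable[EndpointSet]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"line_id": s.line_id, "endpoint": s.endpoint.value, "mean": s.mean, "sem": s.sem, "n": s.n}
            for s in sets
        ],
        columns=["line_id", "endpoint", "mean", "sem", "n"],
    )


def run_pipeline(
    panel: str | Path | Sequence[CellLineRecord],
    reference: str | Path | Sequence[SyndromeERR] | None = None,
    *,
    strict: bool = False,
    predict_method: str = "model",
    refit_calibration: bool = False,
    h_params: HModelParams = DEFAULT_H_PARAMS,
    g_params: GModelParams = DEFAULT_G_PARAMS,
    calibration: LinearCalibration = DEFAULT_CALIBRATION,
    out_dir: str | Path | None = None,
) -> PipelineReport:
    """Run the full analysis on a panel.

    ``panel`` is an assay CSV path or an in-memory list of records;
    ``reference`` a syndrome→ERR table (CSV path, list, or None for the
    packaged literature table). ``predict_method`` is ``"model"`` (exact
    inversion of the mechanistic composite) or ``"calibration"`` (linear
    line; refit from the panel when ``refit_calibration``). Deterministic
    given its inputs; writes report JSON + CSV tables when ``out_dir``.
    """
    if predict_method not in ("model", "calibration"):
        raise ValueError(f"predict_method must be 'model' or 'calibration', got {predict_method!r}")
    if isinstance(panel, (str, Path)):
        records = read_panel(panel)
    else:
        records = list(panel)
    if reference is None:
        ref_table = reference_err_table()
    elif isinstance(reference, (str, Path)):
        ref_table = read_err_table(reference)
    else:
        ref_table = list(reference)
    ref_err = {t.syndrome: t.err for t in ref_table}

    all_sets: list[EndpointSet] = []
    per_line: dict[str, dict[Endpoint, EndpointSet]] = {}
    line_info: dict[str, CellLineRecord] = {}
    for rec in records:
        if rec.line_id in line_info:
            raise ValueError(f"duplicate line_id {rec.line_id!r} in panel")
        line_info[rec.line_id] = rec
        sets = compute_endpoints(rec, strict=strict)
        all_sets.extend(sets)
        per_line[rec.line_id] = {s.endpoint: s for s in sets}

    def points_for(ep: Endpoint) -> list[tuple[float, float]]:
        pts = []
        for lid, eps in per_line.items():
            syn = line_info[lid].syndrome
            if syn not in ref_err:
                logger.warning("line %s: syndrome %s absent from reference table; excluded from fits", lid, syn.value)
                continue
            if ep in eps:
                pts.append((ref_err[syn], eps[ep].mean))
        return pts

    def sems_for(ep: Endpoint) -> list[float]:
        return [
            eps[ep].sem
            for lid, eps in per_line.items()
            if line_info[lid].syndrome in ref_err and ep in eps
        ]

    fits: dict[str, FitResult] = {}
    screens: dict[str, CorrelationScreen] = {}

    def try_fit(name, fn, *args, **kwargs):
        try:
            fits[name] = fn(*args, **kwargs)
        except FitError as exc:
            logger.warning("fit %s skipped: %s", name, exc)

    h_pts = points_for(Endpoint.H)
    g_pts = points_for(Endpoint.G)
    if len(h_pts) >= 3:
        try_fit("H_mechanistic", fit_h_mechanistic, h_pts)
        if len(h_pts) >= 5:
            try_fit("H_poly3", fit_polynomial, h_pts, 3)
    f_pts = points_for(Endpoint.F)
    if len(f_pts) >= 4:
        try_fit("F_poly2", fit_polynomial, f_pts, 2)
    e_pts = points_for(Endpoint.E)
    if len(e_pts) >= 5:
        try_fit("E_poly3", fit_polynomial, e_pts, 3)
    if len(g_pts) >= 4:
        # the logistic's floor and rate live in the low-noise low-mean region;
        # inverse-variance weighting (smoothed) markedly improves their recovery
        g_w = smoothed_sem_weights([p[1] for p in g_pts], sems_for(Endpoint.G))
        try_fit("G_logistic", fit_logistic, g_pts, weights=g_w)

    # composite calibration points: lines with both H and G
    hg_pts = []
    for lid, eps in per_line.items():
        syn = line_info[lid].syndrome
        if Endpoint.H in eps and Endpoint.G in eps and syn in ref_err:
            hg_pts.append((ref_err[syn], eps[Endpoint.H].mean * eps[Endpoint.G].mean / 100.0))
    if len(hg_pts) >= 2:
        try_fit("HG_linear", fit_linear, hg_pts)

    for ep, name in ((Endpoint.FDR, "FDR_vs_err"), (Endpoint.MRE11MAX, "MRE11max_vs_err"), (Endpoint.G1, "G1_vs_err")):
        pts = points_for(ep)
        if len(pts) >= 3:
            screens[name] = correlation_screen(pts)

    cal = calibration
    if refit_calibration:
        if "HG_linear" not in fits or fits["HG_linear"].params is None:
            raise FitError("cannot refit calibration: composite linear fit unavailable")
        cal = fits["HG_linear"].params

    rows = []
    for lid, eps in per_line.items():
        syn = line_info[lid].syndrome
        row = {
            "line_id": lid,
            "syndrome": syn.value,
            "hg_percent": np.nan,
            "predicted_err": np.nan,
            "reference_err": ref_err.get(syn, np.nan),
            "note": "",
        }
        if Endpoint.H not in eps or Endpoint.G not in eps:
            missing = [e.value for e in (Endpoint.H, Endpoint.G) if e not in eps]
            row["note"] = f"excluded: missing endpoint(s) {','.join(missing)}"
            logger.warning("line %s excluded from H*G prediction: missing %s", lid, missing)
        else:
            hg = eps[Endpoint.H].mean * eps[Endpoint.G].mean / 100.0
            row["hg_percent"] = hg
            if predict_method == "model":
                row["predicted_err"] = invert_hg(hg, h_params, g_params)
            else:
                row["predicted_err"] = predict_err(hg, cal)
        rows.append(row)
    predictions = pd.DataFrame(
        rows, columns=["line_id", "syndrome", "hg_percent", "predicted_err", "reference_err", "note"]
    )

    report = PipelineReport(
        endpoint_table=_endpoint_frame(all_sets),
        fit_results=fits,
        screens=screens,
        calibration=cal,
        predictions=predictions,
        provenance={
            "package": "recombrisk",
            "version": __version__,
            "n_lines": len(records),
            "strict": strict,
            "predict_method": predict_method,
            "refit_calibration": refit_calibration,
        },
    )
    if out_dir is not None:
        report.write(out_dir)
    return report


def compare_to_reference(
    report: PipelineReport, ref: Sequence[SyndromeERR]
) -> ComparisonResult:
    """Per-syndrome predicted − reference differences plus their Pearson r.

    Lines without a prediction or without a matching reference syndrome
    are warned about and excluded from r.
    """
    ref_err = {t.syndrome.value: t.err for t in ref}
    rows = []
    for rec in report.predictions.itertuples():
        if rec.syndrome not in ref_err:
            logger.warning("syndrome %s not in reference; excluded from comparison", rec.syndrome)
            continue
        if np.isnan(rec.predicted_err):
            continue
        rows.append(
            {
                "line_id": rec.line_id,
                "syndrome": rec.syndrome,
                "predicted_err": rec.predicted_err,
                "reference_err": ref_err[rec.syndrome],
                "difference": rec.predicted_err - ref_err[rec.syndrome],
            }
        )
    table = pd.DataFrame(
        rows, columns=["line_id", "syndrome", "predicted_err", "reference_err", "difference"]
    )
    if len(table) < 2 or table["reference_err"].nunique() < 2 or table["predicted_err"].nunique() < 2:
        if table.empty:
            logger.warning("empty comparison table")
        r = float("nan")
    else:
        r = float(np.corrcoef(table["predicted_err"], table["reference_err"])[0, 1])
    return ComparisonResult(table=table, r=r)
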