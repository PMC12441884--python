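"""Voxelwise estimation of ADC metrics and microstructural parameters.

Workflow mirrors clinical MR cytometry: per-voxel signals are normalized by
the b=0 acquisition of each sequence (removing T2/TE differences between
sequences), mono-exponential ADCs are fitted per sequence, and the composite
tissue models (IMPULSED / JOINT / EXCHANGE) are fitted by bounded nonlinear
least squares with deterministic Latin-hypercube multi-start.  Per-voxel
estimates are then averaged over the lesion ROI.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .errors import DataError
from .forward_models import (
    D_IN_FIXED,
    MicrostructureParams,
    cellularity,
    exchange_signal,
    impulsed_signal,
)
from .protocol import Protocol, sequence_label

logger = logging.getLogger(__name__)

__all__ = [
    "ADCMetrics",
    "FitConfig",
    "FitResult",
    "LesionFit",
    "MODEL_FREE_PARAMS",
    "fit_adc",
    "compute_delta_adc",
    "fit_voxel",
    "fit_lesion",
    "fit_cohort",
    "normalize_by_b0",
]

#: Free parameters per model; the exchange-incorporating models fix D_in.
MODEL_FREE_PARAMS: dict[str, tuple[str, ...]] = {
    "IMPULSED": ("d", "v_in", "D_in", "D_ex"),
    "JOINT": ("d", "v_in", "D_ex", "k_in"),
    "EXCHANGE": ("d", "v_in", "D_ex", "k_in"),
}

#: Default fitting bounds.  They bracket the parameter ranges reported for
#: breast tumors with margin; v_in is capped just below 1 for the exchange
#: models to keep the detailed-balance closure k_out = k_in v_in/(1-v_in)
#: finite along the optimizer path.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "d": (5.0, 30.0),
    "v_in": (0.0, 1.0),
    "D_in": (0.5, 3.0),
    "D_ex": (0.3, 3.5),
    "k_in": (0.0, 50.0),
}
_V_IN_MAX_EXCHANGE = 0.999


@dataclass
class FitConfig:
    """Configuration of the voxelwise nonlinear fit.

    ``n_starts`` Latin-hypercube initial points are ranked by their residual
    sum of squares and the best ``n_polish`` are refined with trust-region
    reflective least squares.  ``fit_dt`` is the waveform sampling used during
    optimization (ms); forward models are exact for the sampled waveform, so
    this only controls the time-discretization of the protocol.
    """

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    n_starts: int = 16
    n_polish: int = 4
    seed: int = 0
    ftol: float = 1e-10
    xtol: float = 1e-10
    n_modes: int = 20
    fit_dt: float = 0.1
    exclude_low_b: bool = False  # drop b < 0.2 ms/um^2 from ADC fits
    low_b_threshold: float = 0.2


@dataclass
class ADCMetrics:
    """Per-sequence apparent diffusion coefficients (um^2/ms) and their
    diffusion-time dependence Delta-ADC."""

    adc_pgse: float
    adc_25hz: float
    adc_50hz: float
    delta_adc: float = float("nan")


@dataclass
class FitResult:
    """Best multi-start solution for one voxel and one tissue model."""

    model: str
    params: MicrostructureParams
    cellularity: float
    rss: float
    n_starts_used: int
    converged: bool
    bounds_hit: frozenset[str]


@dataclass
class LesionFit:
    """Voxelwise maps plus the ROI summary row for one lesion."""

    lesion_id: str
    maps: dict[str, np.ndarray]
    summary: dict[str, float | str | int]
    n_voxels: int
    n_excluded: int
    n_nonconverged: dict[str, int]
    low_convergence_warning: bool


def fit_adc(b, S) -> float:
    """Least-squares ADC of ln S = -b * ADC (through-origin, clipped at 0).

    Requires at least two distinct b-values including b = 0; signals must be
    strictly positive (noise-floor voxels are the caller's job to exclude).
    """
    b = np.asarray(b, dtype=float)
    S = np.asarray(S, dtype=float)
    if b.shape != S.shape or b.size < 2:
        raise ValueError("b and S must be equal-length vectors of size >= 2")
    if np.unique(b).size < 2 or not np.any(b == 0):
        raise ValueError("need >= 2 distinct b-values including b = 0")
    if not np.all(np.isfinite(S)) or np.any(S <= 0):
        raise DataError("non-positive or non-finite signal in ADC fit")
    denom = float(np.sum(b * b))
    if denom == 0:
        return 0.0
    adc = -float(np.sum(b * np.log(S))) / denom
    return max(adc, 0.0)


def compute_delta_adc(metrics: ADCMetrics, mode: str = "relative") -> float:
    """Diffusion-time dependence of ADC between the 50 Hz OGSE and PGSE.

    relative: (ADC_50Hz - ADC_PGSE) / ADC_PGSE (dimensionless);
    absolute: ADC_50Hz - ADC_PGSE (um^2/ms).  Returns NaN when the relative
    form is undefined (ADC_PGSE = 0).
    """
    if mode == "absolute":
        return metrics.adc_50hz - metrics.adc_pgse
    if mode != "relative":
        raise ValueError(f"unknown delta-ADC mode {mode!r}")
    if metrics.adc_pgse <= 0:
        return float("nan")
    return (metrics.adc_50hz - metrics.adc_pgse) / metrics.adc_pgse


def normalize_by_b0(S, protocol: Protocol):
    """Normalize a voxel's signal vector by the b=0 signal of each sequence.

    Returns (normalized vector, ok flag).  The voxel is flagged bad when any
    b=0 signal is non-positive, any normalized signal exceeds 1.2, or any
    value is non-finite -- the noise-floor/artifact guard.
    """
    S = np.asarray(S, dtype=float)
    if len(S) != len(protocol):
        raise DataError(
            f"signal vector length {len(S)} != protocol acquisitions {len(protocol)}"
        )
    if not np.all(np.isfinite(S)):
        return S, False
    out = np.empty_like(S)
    b_values = protocol.b_values
    for _, idx in protocol.sequence_groups().items():
        idx = np.asarray(idx)
        b0_idx = idx[b_values[idx] == 0]
        s0 = float(np.mean(S[b0_idx]))
        if s0 <= 0:
            return S, False
        out[idx] = S[idx] / s0
    if np.any(out <= 0) or np.any(out > 1.2):
        return out, False
    return out, True


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------


def _model_bounds(model: str, config: FitConfig) -> tuple[np.ndarray, np.ndarray]:
    names = MODEL_FREE_PARAMS[model]
    lo = np.array([config.bounds[p][0] for p in names])
    hi = np.array([config.bounds[p][1] for p in names])
    if model in ("JOINT", "EXCHANGE"):
        j = names.index("v_in")
        hi[j] = min(hi[j], _V_IN_MAX_EXCHANGE)
    return lo, hi


def _make_params(model: str, theta: np.ndarray) -> MicrostructureParams:
    names = MODEL_FREE_PARAMS[model]
    kw = dict(zip(names, (float(v) for v in theta)))
    if model == "IMPULSED":
        kw["k_in"] = 0.0
    else:
        kw["D_in"] = D_IN_FIXED
    return MicrostructureParams(**kw)


def _predict(model: str, theta: np.ndarray, protocol: Protocol,
             n_modes: int) -> np.ndarray:
    params = _make_params(model, theta)
    if model == "IMPULSED":
        return impulsed_signal(params, protocol, n_modes=n_modes)
    return exchange_signal(params, protocol, variant=model, n_modes=n_modes)


class _FitContext:
    """Per-(protocol, config) state reused across voxels: the coarse protocol
    for optimization and the deterministic Latin-hypercube start grid."""

    def __init__(self, protocol: Protocol, config: FitConfig):
        self.config = config
        self.protocol = (
            protocol.resampled(config.fit_dt)
            if config.fit_dt and abs(config.fit_dt - _protocol_dt(protocol)) > 1e-12
            else protocol
        )
        self._starts: dict[str, np.ndarray] = {}

    def starts(self, model: str) -> np.ndarray:
        if model not in self._starts:
            lo, hi = _model_bounds(model, self.config)
            sampler = qmc.LatinHypercube(d=len(lo), seed=self.config.seed)
            u = sampler.random(self.config.n_starts)
            # keep starts strictly inside the box
            self._starts[model] = lo + (0.02 + 0.96 * u) * (hi - lo)
        return self._starts[model]


def _protocol_dt(protocol: Protocol) -> float:
    return next(iter(protocol.waveforms.values())).dt


def make_fit_context(protocol: Protocol, config: FitConfig | None = None) -> _FitContext:
    return _FitContext(protocol, config or FitConfig())


def fit_voxel(S, protocol: Protocol | _FitContext, model: str = "IMPULSED",
              config: FitConfig | None = None) -> FitResult:
    """Bounded multi-start nonlinear least-squares fit of one voxel.

    ``S`` must already be normalized per sequence (b=0 of each sequence = 1).
    Never raises on optimizer failure; a non-converged FitResult is returned
    instead.  NaN or negative signals raise DataError.
    """
    if model not in MODEL_FREE_PARAMS:
        raise ValueError(f"unknown model {model!r}")
    ctx = protocol if isinstance(protocol, _FitContext) else _FitContext(
        protocol, config or FitConfig()
    )
    cfg = ctx.config
    S = np.asarray(S, dtype=float)
    if not np.all(np.isfinite(S)) or np.any(S < 0):
        raise DataError("NaN or negative signals passed to fit_voxel")
    lo, hi = _model_bounds(model, cfg)

    def residuals(theta: np.ndarray) -> np.ndarray:
        return _predict(model, theta, ctx.protocol, cfg.n_modes) - S

    starts = ctx.starts(model)
    rss0 = np.array([float(np.sum(residuals(x) ** 2)) for x in starts])
    order = np.argsort(rss0, kind="stable")[: cfg.n_polish]
    best_x = None
    best_rss = math.inf
    converged = False
    n_used = 0
    for i in order:
        n_used += 1
        try:
            sol = least_squares(
                residuals, starts[i], bounds=(lo, hi), method="trf",
                ftol=cfg.ftol, xtol=cfg.xtol, gtol=1e-10,
            )
        except Exception:  # pragma: no cover - optimizer failure path
            continue
        rss = float(2.0 * sol.cost)
        if rss < best_rss:
            best_rss = rss
            best_x = sol.x
            converged = converged or bool(sol.success)
    if best_x is None:
        i = int(order[0])
        best_x = starts[i]
        best_rss = float(rss0[i])
        converged = False
    span = hi - lo
    names = MODEL_FREE_PARAMS[model]
    hit = frozenset(
        names[j]
        for j in range(len(names))
        if best_x[j] - lo[j] <= 1e-6 * span[j] or hi[j] - best_x[j] <= 1e-6 * span[j]
    )
    params = _make_params(model, best_x)
    return FitResult(
        model=model,
        params=params,
        cellularity=params.cellularity,
        rss=best_rss,
        n_starts_used=n_used,
        converged=converged,
        bounds_hit=hit,
    )


# ---------------------------------------------------------------------------
# Lesion-level fitting
# ---------------------------------------------------------------------------

_MODEL_COLUMN_PARAMS = {
    "IMPULSED": ("d", "v_in", "d_in", "d_ex", "cellularity"),
    "JOINT": ("d", "v_in", "k_in", "d_ex", "cellularity"),
    "EXCHANGE": ("d", "v_in", "k_in", "d_ex", "cellularity"),
}

LABEL_COLUMNS = ("ER", "PR", "HER2", "Ki67")


def metric_columns(models: Sequence[str]) -> list[str]:
    cols = ["adc_pgse", "adc_25hz", "adc_50hz", "delta_adc"]
    for m in models:
        cols += [f"{m.lower()}_{p}" for p in _MODEL_COLUMN_PARAMS[m]]
    return cols


def _adc_metrics(S_norm: np.ndarray, protocol: Protocol,
                 config: FitConfig, mode: str) -> dict[str, float]:
    b_values = protocol.b_values
    out: dict[str, float] = {}
    for wid, idx in protocol.sequence_groups().items():
        idx = np.asarray(idx)
        b = b_values[idx]
        s = S_norm[idx]
        if config.exclude_low_b:
            keep = (b == 0) | (b >= config.low_b_threshold)
            b, s = b[keep], s[keep]
        label = sequence_label(protocol.waveforms[wid])
        out[label] = fit_adc(b, s)
    metrics = ADCMetrics(
        adc_pgse=out.get("adc_pgse", float("nan")),
        adc_25hz=out.get("adc_25hz", float("nan")),
        adc_50hz=out.get("adc_50hz", float("nan")),
    )
    out["delta_adc"] = compute_delta_adc(metrics, mode=mode)
    return out


def _param_value(result: FitResult, param: str) -> float:
    if param == "cellularity":
        return result.cellularity
    attr = {"d": "d", "v_in": "v_in", "k_in": "k_in", "d_ex": "D_ex", "d_in": "D_in"}
    return getattr(result.params, attr[param])


def fit_lesion(
    dataset,
    protocol: Protocol,
    models: Sequence[str] = ("IMPULSED", "JOINT", "EXCHANGE"),
    config: FitConfig | None = None,
    delta_adc_mode: str = "relative",
    context: _FitContext | None = None,
) -> LesionFit:
    """Fit every masked voxel of a lesion and average the metrics over the ROI.

    ``dataset`` needs ``signals`` (n_voxels x n_acquisitions), ``lesion_id``,
    and optionally ``subtype`` / ``labels`` carried into the summary row.  The
    ROI summary is the arithmetic mean over converged voxels of each metric.
    """
    config = config or FitConfig()
    signals = np.asarray(dataset.signals, dtype=float)
    if signals.ndim != 2 or signals.shape[0] == 0:
        raise ValueError("dataset.signals must be a non-empty 2-D array")
    ctx = context or _FitContext(protocol, config)
    n_vox = signals.shape[0]
    adc_cols = ["adc_pgse", "adc_25hz", "adc_50hz", "delta_adc"]
    cols = metric_columns(models)
    maps = {c: np.full(n_vox, np.nan) for c in cols}
    conv = {m: np.zeros(n_vox, dtype=bool) for m in models}
    included = np.zeros(n_vox, dtype=bool)
    n_excluded = 0
    for v in range(n_vox):
        s_norm, ok = normalize_by_b0(signals[v], protocol)
        if not ok:
            n_excluded += 1
            continue
        included[v] = True
        for name, value in _adc_metrics(s_norm, protocol, config, delta_adc_mode).items():
            if name in maps:
                maps[name][v] = value
        for m in models:
            res = fit_voxel(s_norm, ctx, model=m)
            conv[m][v] = res.converged
            for p in _MODEL_COLUMN_PARAMS[m]:
                maps[f"{m.lower()}_{p}"][v] = _param_value(res, p)
    summary: dict = {"lesion_id": dataset.lesion_id}
    summary["subtype"] = getattr(dataset, "subtype", "")
    labels = getattr(dataset, "labels", {}) or {}
    for lab in LABEL_COLUMNS:
        summary[lab] = labels.get(lab, np.nan)
    for c in adc_cols:
        vals = maps[c][included]
        summary[c] = float(np.nanmean(vals)) if vals.size else float("nan")
    n_nonconverged = {}
    low_conv = False
    for m in models:
        use = included & conv[m]
        n_nonconverged[m] = int(np.sum(included) - np.sum(use))
        if np.sum(included) and n_nonconverged[m] > 0.5 * np.sum(included):
            low_conv = True
        for p in _MODEL_COLUMN_PARAMS[m]:
            c = f"{m.lower()}_{p}"
            vals = maps[c][use]
            summary[c] = float(np.mean(vals)) if vals.size else float("nan")
    if low_conv:
        logger.warning("lesion %s: >50%% non-converged voxels", dataset.lesion_id)
    return LesionFit(
        lesion_id=str(dataset.lesion_id),
        maps=maps,
        summary=summary,
        n_voxels=int(np.sum(included)),
        n_excluded=n_excluded,
        n_nonconverged=n_nonconverged,
        low_convergence_warning=low_conv,
    )


def fit_cohort(
    cohort: Iterable,
    protocol: Protocol,
    models: Sequence[str] = ("IMPULSED", "JOINT", "EXCHANGE"),
    config: FitConfig | None = None,
    delta_adc_mode: str = "relative",
) -> pd.DataFrame:
    """ROI-summary table (one row per lesion) for a list of lesion datasets."""
    config = config or FitConfig()
    ctx = _FitContext(protocol, config)
    rows = []
    for ds in cohort:
        fit = fit_lesion(ds, protocol, models=models, config=config,
                         delta_adc_mode=delta_adc_mode, context=ctx)
        rows.append(fit.summary)
    columns = (["lesion_id", "subtype", *LABEL_COLUMNS] + metric_columns(models))
    return pd.DataFrame(rows, columns=columns)
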