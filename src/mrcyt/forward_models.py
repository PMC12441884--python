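"""Forward dMRI signal models for MR cytometry.

Three composite two-compartment tissue models are provided:

* IMPULSED -- impermeable spheres: S = v_in * S_sphere + (1 - v_in) * exp(-b D_ex),
  with the intracellular signal from the Gaussian phase approximation (GPA)
  over the sampled effective gradient waveform.
* JOINT / EXCHANGE -- the same two compartments coupled by transcytolemmal
  water exchange (Karger-type), solved by piecewise-constant matrix-exponential
  propagation at waveform resolution.  The two named variants share one
  forward engine and one default fitting configuration; they differ only in
  provenance (see docs/methods.md).

The GPA log-attenuation for diffusion restricted in a sphere of radius R is

    ln S = -gamma^2 * sum_n B_n * J_n,
    J_n  = int_0^TE g(t) int_0^t g(t') exp(-D_in (alpha_n / R)^2 (t - t')) dt' dt,
    B_n  = 2 (R / alpha_n)^2 / (alpha_n^2 - 2),

where alpha_n are the ascending positive roots of alpha * j1'(alpha) = 0 and
sum_n B_n = R^2 / 5 (the equilibrium position variance along one axis).  The
narrow-pulse long-time limit of this expression is exp(-q^2 R^2 / 5), which
fixes the overall prefactor; the Monte-Carlo random-walk simulator in
synthetic_data provides an independent cross-check of the whole expression.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import spherical_jn

from ._kernels import exchange_propagate, gpa_mode_integrals, gpa_step_sums
from .errors import DegenerateBalanceError, NumericalError
from .protocol import GAMMA, Protocol

__all__ = [
    "MicrostructureParams",
    "SphereEigenmodes",
    "sphere_eigenmodes",
    "sphere_gpa_log_attenuation",
    "hindered_signal",
    "impulsed_signal",
    "exchange_signal",
    "cellularity",
    "D_IN_FIXED",
]

#: Intracellular intrinsic diffusivity fixed during exchange-model fitting
#: (um^2/ms), chosen to stabilize the four-parameter fit.
D_IN_FIXED = 1.56

_MAX_MODES = 80
_TAIL_RTOL = 1e-6


@dataclass(frozen=True)
class MicrostructureParams:
    """Tissue model state: cell diameter d (um), intracellular volume fraction
    v_in, intracellular diffusivity D_in (um^2/ms), apparent extracellular
    diffusivity D_ex (um^2/ms) and intracellular water exchange rate constant
    k_in (1/s; 0 for the impermeable model)."""

    d: float
    v_in: float
    D_ex: float
    D_in: float = D_IN_FIXED
    k_in: float = 0.0

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("cell diameter d must be positive")
        if not 0.0 <= self.v_in <= 1.0:
            raise ValueError("v_in must be in [0, 1]")
        if self.D_in <= 0 or self.D_ex <= 0:
            raise ValueError("diffusivities must be positive")
        if self.k_in < 0:
            raise ValueError("k_in must be non-negative")

    @property
    def cellularity(self) -> float:
        return cellularity(self.v_in, self.d)


@dataclass(frozen=True)
class SphereEigenmodes:
    """First N eigenmodes of restricted diffusion in a sphere of given radius:
    roots alpha_n of alpha * j1'(alpha) = 0 and GPA weights B_n (um^2)."""

    alphas: np.ndarray
    weights: np.ndarray
    radius: float


_ALPHA_CACHE: list[float] = []


def _sphere_alphas(n_modes: int) -> np.ndarray:
    """Ascending positive roots of alpha * j1'(alpha) = 0 (excluding alpha=0)."""
    def f(x: float) -> float:
        return spherical_jn(1, x, derivative=True)

    while len(_ALPHA_CACHE) < n_modes:
        lo = _ALPHA_CACHE[-1] + 1e-6 if _ALPHA_CACHE else 0.5
        x = lo
        found = None
        while x < lo + 20.0:
            if f(x) * f(x + 0.05) < 0:
                found = brentq(f, x, x + 0.05, xtol=1e-14)
                break
            x += 0.05
        if found is None:
            raise NumericalError(
                f"failed to bracket sphere eigenmode {len(_ALPHA_CACHE) + 1}"
            )
        _ALPHA_CACHE.append(float(found))
    return np.array(_ALPHA_CACHE[:n_modes])


def sphere_eigenmodes(n_modes: int = 20, radius: float = 1.0) -> SphereEigenmodes:
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    if radius <= 0:
        raise ValueError("radius must be positive")
    alphas = _sphere_alphas(n_modes)
    weights = 2.0 * (radius / alphas) ** 2 / (alphas**2 - 2.0)
    return SphereEigenmodes(alphas=alphas, weights=weights, radius=radius)


# ---------------------------------------------------------------------------
# Per-protocol precomputation: unit-amplitude waveform arrays.  The GPA double
# integral and all dephasing rates scale with amplitude^2, so each unique
# waveform is characterized once and every acquisition only carries the scalar
# amp2 = b_target / b_unit.
# ---------------------------------------------------------------------------


@dataclass
class _WaveformArrays:
    g_unit: np.ndarray     # waveform at unit peak amplitude
    q2_unit: np.ndarray    # q(t)^2 of the unit waveform (rad^2/um^2)
    dt: float
    b_unit: float          # b-value of the unit waveform


@dataclass
class _ProtocolArrays:
    waveforms: list[_WaveformArrays]
    acqs: list[tuple[int, float, float]]  # (waveform index, amp2, b_target)


def _protocol_arrays(protocol: Protocol) -> _ProtocolArrays:
    cached = getattr(protocol, "_fm_arrays", None)
    if cached is not None:
        return cached
    wf_ids = list(protocol.waveforms)
    index = {wid: i for i, wid in enumerate(wf_ids)}
    wf_arrays = []
    for wid in wf_ids:
        w = protocol.waveforms[wid]
        amp = w.amplitude
        g_unit = w.samples / amp if amp > 0 else np.array(w.samples)
        q = GAMMA * w.dt * (np.cumsum(g_unit) - 0.5 * g_unit)
        q2 = q * q
        wf_arrays.append(
            _WaveformArrays(g_unit=g_unit, q2_unit=q2, dt=w.dt,
                            b_unit=float(np.sum(q2) * w.dt))
        )
    acqs = []
    for wid, wf, b in protocol.scaled_acquisitions():
        i = index[wid]
        b_unit = wf_arrays[i].b_unit
        amp2 = b / b_unit if b > 0 else 0.0
        acqs.append((i, amp2, b))
    arrays = _ProtocolArrays(waveforms=wf_arrays, acqs=acqs)
    protocol._fm_arrays = arrays  # type: ignore[attr-defined]
    return arrays


def _mode_kappas(d: float, D_in: float, n_modes: int):
    radius = 0.5 * d
    modes = sphere_eigenmodes(n_modes, radius)
    kappas = D_in * (modes.alphas / radius) ** 2
    return kappas, modes.weights


def _unit_log_attenuation(wf: _WaveformArrays, d: float, D_in: float,
                          n_modes: int) -> float:
    """ln S of the unit-amplitude waveform, with automatic mode-count growth."""
    n = n_modes
    while True:
        kappas, weights = _mode_kappas(d, D_in, n)
        js = gpa_mode_integrals(wf.g_unit, wf.dt, kappas)
        total = float(np.dot(weights, js))
        tail = abs(weights[-1] * js[-1])
        if total == 0.0 or tail <= _TAIL_RTOL * abs(total):
            return -(GAMMA**2) * total
        if n >= _MAX_MODES:
            raise NumericalError(
                f"GPA eigenmode series not converged at {n} modes (d={d} um)"
            )
        warnings.warn(
            f"GPA series tail {tail:.2e} above tolerance at {n} modes; doubling",
            stacklevel=2,
        )
        n = min(2 * n, _MAX_MODES)


def sphere_gpa_log_attenuation(d: float, D_in: float, waveform,
                               n_modes: int = 20) -> float:
    """GPA log-signal (<= 0) of water restricted in a sphere of diameter d."""
    if d <= 0 or D_in <= 0:
        raise ValueError("d and D_in must be positive")
    amp = waveform.amplitude
    if amp == 0.0:
        return 0.0
    g_unit = waveform.samples / amp
    wf = _WaveformArrays(
        g_unit=g_unit,
        q2_unit=np.zeros(0),
        dt=waveform.dt,
        b_unit=0.0,
    )
    return amp * amp * _unit_log_attenuation(wf, d, D_in, n_modes)


def hindered_signal(D_ex: float, b) -> np.ndarray | float:
    """Mono-exponential extracellular (hindered) signal exp(-b * D_ex)."""
    if D_ex <= 0:
        raise ValueError("D_ex must be positive")
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b must be non-negative")
    out = np.exp(-b * D_ex)
    return out if out.ndim else float(out)


def impulsed_signal(params: MicrostructureParams, protocol: Protocol,
                    n_modes: int = 20) -> np.ndarray:
    """Impermeable-sphere two-compartment signal at every protocol acquisition.

    ``params.k_in`` is ignored (the model assumes no transcytolemmal exchange).
    """
    arrays = _protocol_arrays(protocol)
    ln_unit = [
        _unit_log_attenuation(wf, params.d, params.D_in, n_modes)
        for wf in arrays.waveforms
    ]
    out = np.empty(len(arrays.acqs))
    for j, (i, amp2, _) in enumerate(arrays.acqs):
        b_wf = amp2 * arrays.waveforms[i].b_unit
        s_in = math.exp(amp2 * ln_unit[i])
        s_ex = math.exp(-b_wf * params.D_ex)
        out[j] = params.v_in * s_in + (1.0 - params.v_in) * s_ex
    return out


def exchange_signal(params: MicrostructureParams, protocol: Protocol,
                    variant: str = "EXCHANGE", n_modes: int = 20) -> np.ndarray:
    """Two-compartment signal with transcytolemmal water exchange.

    Solves dM/dt = A(t) M where the intracellular dephasing rate is the
    instantaneous GPA rate of the waveform, the extracellular rate is
    D_ex * q(t)^2, and exchange obeys detailed balance
    k_out = k_in * v_in / (1 - v_in).  ``variant`` names the fitting
    configuration (JOINT or EXCHANGE); both use this engine.
    """
    if variant not in ("JOINT", "EXCHANGE"):
        raise ValueError(f"unknown exchange variant {variant!r}")
    k_in = params.k_in * 1e-3  # 1/s -> 1/ms
    if params.v_in >= 1.0:
        if k_in > 0:
            raise DegenerateBalanceError(
                "v_in = 1 with k_in > 0: no extracellular pool to balance"
            )
        k_out = 0.0
    else:
        k_out = k_in * params.v_in / (1.0 - params.v_in)
    arrays = _protocol_arrays(protocol)
    rate_profiles = []
    for wf in arrays.waveforms:
        kappas, weights = _mode_kappas(params.d, params.D_in, n_modes)
        r = gpa_step_sums(wf.g_unit, wf.dt, kappas, weights)
        rate_profiles.append((GAMMA**2) * r / wf.dt)  # unit-amp intracellular rate
    out = np.empty(len(arrays.acqs))
    for j, (i, amp2, _) in enumerate(arrays.acqs):
        wf = arrays.waveforms[i]
        r_in = amp2 * rate_profiles[i]
        r_ex = amp2 * params.D_ex * wf.q2_unit
        out[j] = exchange_propagate(r_in, r_ex, wf.dt, k_in, k_out, params.v_in)
    return out


def cellularity(v_in: float, d: float) -> float:
    """Cell-density index 2 * (3 v_in / (2 pi) * 100)^(2/3) / d^2.

    Increasing in the intracellular volume fraction, decreasing with the
    square of the cell diameter; a proxy for the number of cells per area.
    """
    if d <= 0:
        raise ValueError("d must be positive")
    if not 0.0 <= v_in <= 1.0:
        raise ValueError("v_in must be in [0, 1]")
    return 2.0 * (3.0 * v_in / (2.0 * math.pi) * 100.0) ** (2.0 / 3.0) / d**2
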