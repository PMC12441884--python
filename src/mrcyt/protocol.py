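"""Gradient waveforms and multi-sequence acquisition protocols.

Pulsed-gradient spin echo (PGSE) probes long diffusion times via two
rectangular effective-gradient lobes of opposite sign; cosine-modulated
oscillating-gradient spin echo (OGSE) probes short effective diffusion times
t_d = 1/(4f).  Both are represented as an *effective* gradient time-course
sampled on a uniform grid, which is what every signal model in the package
integrates over.

Unit conventions (package-wide):
    time            ms
    gradient        mT/m
    b-value         ms/um^2  (1 ms/um^2 = 1000 s/mm^2)
    diffusivity     um^2/ms
    exchange rate   1/s at the API (converted internally)
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .errors import (
    HardwareLimitError,
    InvalidTimingError,
    InvalidWaveformError,
    ProtocolError,
)

#: Proton gyromagnetic ratio, expressed so that q(t) = GAMMA * int g dt is in
#: rad/um with g in mT/m and t in ms (267.513e6 rad s^-1 T^-1 in SI).
GAMMA = 2.67513e-4

#: Per-axis hardware gradient cap of the target scanner class (mT/m).
G_MAX_PER_AXIS = 80.0

#: Effective cap when all three gradient axes are driven together, which is
#: how low-b high-frequency OGSE reaches its nominal b-values in practice.
G_MAX_EFFECTIVE = G_MAX_PER_AXIS * math.sqrt(3.0)

PGSE = "PGSE"
OGSE_COSINE = "OGSE_cosine"

#: Relative tolerance of the refocusing check |int g dt| <= tol * max|g| * TE.
REFOCUS_RTOL = 1e-9


@dataclass(eq=False)
class GradientWaveform:
    """A sampled effective gradient time-course with sequence metadata.

    ``samples[k]`` is the effective gradient amplitude over the step
    ``[k*dt, (k+1)*dt)``.  ``delta`` is the lobe (encoding) duration, ``Delta``
    the leading-edge lobe separation (PGSE only), ``frequency`` the oscillation
    frequency in Hz (0 for PGSE) and ``n_periods`` the number of full periods
    per encoding interval (OGSE only).
    """

    kind: str
    samples: np.ndarray
    dt: float
    delta: float
    Delta: float = 0.0
    frequency: float = 0.0
    n_periods: int = 0
    echo_time: float = 0.0
    t_start: float = 0.0
    gap: float = 0.0
    g_max: float = G_MAX_EFFECTIVE
    nominal_amplitude: float | None = None  # builder amplitude (peak of the
    # analytic envelope; the max midpoint sample can sit slightly below it)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.nominal_amplitude is None:
            self.nominal_amplitude = self.amplitude
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for name in ("delta", "Delta", "frequency", "echo_time", "t_start", "gap"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.amplitude > self.g_max * (1 + 1e-9):
            raise HardwareLimitError(
                f"amplitude {self.amplitude:.2f} mT/m exceeds cap {self.g_max:.2f} mT/m"
            )

    @property
    def amplitude(self) -> float:
        """Peak effective gradient amplitude (mT/m)."""
        return float(np.max(np.abs(self.samples))) if self.samples.size else 0.0

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    def is_refocused(self) -> bool:
        amp = self.amplitude
        if amp == 0.0:
            return True
        residual = abs(float(np.sum(self.samples)) * self.dt)
        return residual <= REFOCUS_RTOL * amp * self.echo_time

    def q_of_t(self) -> np.ndarray:
        """Dephasing q(t) in rad/um at step midpoints (second-order accurate)."""
        return GAMMA * self.dt * (np.cumsum(self.samples) - 0.5 * self.samples)

    def scaled(self, factor: float) -> "GradientWaveform":
        """Return a copy with the amplitude multiplied by ``factor`` >= 0."""
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        return replace(self, samples=self.samples * factor,
                       nominal_amplitude=self.nominal_amplitude * factor)

    def rebuilt(self, dt: float) -> "GradientWaveform":
        """Rebuild the same waveform on a different time grid."""
        if self.kind == PGSE:
            return build_pgse(
                self.delta,
                self.Delta,
                self.nominal_amplitude,
                dt=dt,
                t_start=self.t_start,
                echo_time=self.echo_time,
                g_max=self.g_max,
            )
        return build_ogse_cosine(
            self.frequency,
            self.n_periods,
            self.nominal_amplitude,
            dt=dt,
            t_start=self.t_start,
            gap=self.gap,
            echo_time=self.echo_time,
            g_max=self.g_max,
        )


def _check_grid(value: float, dt: float, rtol: float, what: str) -> int:
    n = int(round(value / dt))
    if n < 1 or abs(n * dt - value) > rtol * value:
        raise ValueError(f"dt={dt} ms does not divide {what}={value} ms to {rtol:.0%}")
    return n


def build_pgse(
    delta: float,
    Delta: float,
    amplitude: float,
    dt: float = 0.005,
    t_start: float = 2.0,
    echo_time: float | None = None,
    g_max: float = G_MAX_EFFECTIVE,
) -> GradientWaveform:
    """Two rectangular effective lobes of opposite sign.

    ``delta`` is the lobe duration and ``Delta`` the leading-edge separation;
    the effective diffusion time is Delta - delta/3.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if delta <= 0 or Delta <= 0:
        raise ValueError("delta and Delta must be positive")
    if delta > Delta:
        raise ValueError(f"delta={delta} must not exceed Delta={Delta}")
    if echo_time is None:
        echo_time = Delta + delta + 2.0 * t_start
    if t_start + Delta + delta > echo_time + 1e-9:
        raise InvalidTimingError(
            f"PGSE lobes (end {t_start + Delta + delta} ms) overflow echo time {echo_time} ms"
        )
    nd = _check_grid(delta, dt, 0.01, "delta")
    i0 = int(round(t_start / dt))
    i1 = int(round((t_start + Delta) / dt))
    n = int(round(echo_time / dt))
    g = np.zeros(n)
    g[i0 : i0 + nd] = amplitude
    g[i1 : i1 + nd] = -amplitude
    return GradientWaveform(
        kind=PGSE,
        samples=g,
        dt=dt,
        delta=delta,
        Delta=Delta,
        echo_time=n * dt,
        t_start=t_start,
        g_max=g_max,
        nominal_amplitude=float(amplitude),
    )


def build_ogse_cosine(
    frequency: float,
    n_periods: int,
    amplitude: float,
    dt: float = 0.005,
    t_start: float = 2.0,
    gap: float = 6.0,
    echo_time: float | None = None,
    g_max: float = G_MAX_EFFECTIVE,
) -> GradientWaveform:
    """Two cosine-modulated encoding intervals of opposite effective sign.

    Each interval holds ``n_periods`` full periods of cos(2 pi f t) so each
    lobe integrates to zero on its own; the gap between the intervals hosts the
    refocusing pulse.  Samples are taken at step midpoints, which keeps the
    refocusing condition exact on the grid.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    if not float(n_periods).is_integer() or n_periods < 1:
        raise ValueError("n_periods must be a positive integer")
    n_periods = int(n_periods)
    if dt > 10.0 / frequency:  # >= 100 samples per period
        raise ValueError(
            f"dt={dt} ms too coarse for {frequency} Hz (need >= 100 samples/period)"
        )
    period = 1000.0 / frequency  # ms
    lobe = n_periods * period
    m = _check_grid(lobe, dt, 1e-6, "the encoding interval")
    if echo_time is None:
        echo_time = 2.0 * t_start + 2.0 * lobe + gap
    if t_start + 2.0 * lobe + gap > echo_time + 1e-9:
        raise InvalidTimingError(
            f"OGSE lobes (end {t_start + 2 * lobe + gap} ms) overflow echo time {echo_time} ms"
        )
    omega = 2.0 * math.pi / period  # rad/ms
    n = int(round(echo_time / dt))
    g = np.zeros(n)
    i0 = int(round(t_start / dt))
    i1 = int(round((t_start + lobe + gap) / dt))
    t_mid = (np.arange(m) + 0.5) * dt
    lobe_samples = amplitude * np.cos(omega * t_mid)
    g[i0 : i0 + m] = lobe_samples
    g[i1 : i1 + m] = -lobe_samples
    return GradientWaveform(
        kind=OGSE_COSINE,
        samples=g,
        dt=dt,
        delta=lobe,
        frequency=frequency,
        n_periods=n_periods,
        echo_time=n * dt,
        t_start=t_start,
        gap=gap,
        g_max=g_max,
        nominal_amplitude=float(amplitude),
    )


def b_value_of(waveform: GradientWaveform) -> float:
    """Diffusion weighting b = gamma^2 int_0^TE (int_0^t g ds)^2 dt in ms/um^2."""
    if not waveform.is_refocused():
        raise InvalidWaveformError("waveform is not refocused (int g dt != 0)")
    q = waveform.q_of_t()
    return float(np.sum(q * q) * waveform.dt)


def effective_diffusion_time(waveform: GradientWaveform) -> float:
    """Effective diffusion time in ms: Delta - delta/3 (PGSE), 1/(4f) (OGSE).

    Note that the 1/(4f) convention for cosine-modulated OGSE gives 5 ms at
    50 Hz and 10 ms at 25 Hz.
    """
    if waveform.kind == PGSE:
        return waveform.Delta - waveform.delta / 3.0
    return 1000.0 / (4.0 * waveform.frequency)


def scale_to_b(waveform: GradientWaveform, target_b: float) -> GradientWaveform:
    """Rescale the amplitude so that b_value_of(result) == target_b."""
    if target_b < 0:
        raise ValueError("target_b must be non-negative")
    if target_b == 0:
        return waveform.scaled(0.0)
    current = b_value_of(waveform)
    if current == 0:
        raise InvalidWaveformError("cannot scale a zero-amplitude waveform to b > 0")
    factor = math.sqrt(target_b / current)
    new_amp = waveform.amplitude * factor
    if new_amp > waveform.g_max * (1 + 1e-9):
        raise HardwareLimitError(
            f"b={target_b} ms/um^2 needs {new_amp:.1f} mT/m "
            f"(cap {waveform.g_max:.1f} mT/m)"
        )
    return waveform.scaled(factor)


@dataclass
class Protocol:
    """Ordered set of (waveform id, b-value) acquisitions over named waveforms.

    Every waveform referenced by an acquisition must also appear with b = 0 at
    least once (the normalization anchor used by the fitting layer).
    """

    waveforms: dict[str, GradientWaveform]
    acquisitions: list[tuple[str, float]]
    _scaled: list | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        seen_b0 = {wid: False for wid in self.waveforms}
        for wid, b in self.acquisitions:
            if wid not in self.waveforms:
                raise ProtocolError(f"acquisition references unknown waveform {wid!r}")
            if b < 0:
                raise ProtocolError(f"negative b-value {b} for waveform {wid!r}")
            if b == 0:
                seen_b0[wid] = True
        used = {wid for wid, _ in self.acquisitions}
        for wid in used:
            if not seen_b0[wid]:
                raise ProtocolError(f"waveform {wid!r} has no b=0 acquisition")

    def __len__(self) -> int:
        return len(self.acquisitions)

    @property
    def b_values(self) -> np.ndarray:
        return np.array([b for _, b in self.acquisitions])

    def scaled_acquisitions(self) -> list[tuple[str, GradientWaveform, float]]:
        """Per-acquisition waveforms with amplitude scaled to the nominal b."""
        if self._scaled is None:
            self._scaled = [
                (wid, scale_to_b(self.waveforms[wid], b), b)
                for wid, b in self.acquisitions
            ]
        return self._scaled

    def sequence_groups(self) -> dict[str, list[int]]:
        """Map waveform id -> acquisition indices, in protocol order."""
        groups: dict[str, list[int]] = {}
        for i, (wid, _) in enumerate(self.acquisitions):
            groups.setdefault(wid, []).append(i)
        return groups

    def resampled(self, dt: float) -> "Protocol":
        """Rebuild every waveform on a grid of width ``dt`` (same acquisitions)."""
        return Protocol(
            waveforms={wid: w.rebuilt(dt) for wid, w in self.waveforms.items()},
            acquisitions=list(self.acquisitions),
        )

    # -- JSON round trip -----------------------------------------------------
    def to_json(self) -> dict:
        wfs = {}
        for wid, w in self.waveforms.items():
            entry: dict = {"kind": w.kind, "amplitude_mT_m": w.nominal_amplitude,
                           "dt_ms": w.dt, "echo_time_ms": w.echo_time,
                           "t_start_ms": w.t_start}
            if w.kind == PGSE:
                entry["delta_ms"] = w.delta
                entry["Delta_ms"] = w.Delta
            else:
                entry["frequency_hz"] = w.frequency
                entry["n_periods"] = w.n_periods
                entry["gap_ms"] = w.gap
            wfs[wid] = entry
        return {
            "acquisitions": [{"waveform": wid, "b": b} for wid, b in self.acquisitions],
            "waveforms": wfs,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "Protocol":
        waveforms = {}
        for wid, e in obj["waveforms"].items():
            kind = e["kind"]
            dt = e.get("dt_ms", 0.005)
            amp = e.get("amplitude_mT_m", 40.0)
            if kind == PGSE:
                waveforms[wid] = build_pgse(
                    e["delta_ms"], e["Delta_ms"], amp, dt=dt,
                    t_start=e.get("t_start_ms", 2.0),
                    echo_time=e.get("echo_time_ms"),
                )
            elif kind == OGSE_COSINE:
                waveforms[wid] = build_ogse_cosine(
                    e["frequency_hz"], e["n_periods"], amp, dt=dt,
                    t_start=e.get("t_start_ms", 2.0), gap=e.get("gap_ms", 6.0),
                    echo_time=e.get("echo_time_ms"),
                )
            else:
                raise ProtocolError(f"unknown waveform kind {kind!r}")
        acquisitions = [(a["waveform"], float(a["b"])) for a in obj["acquisitions"]]
        return cls(waveforms=waveforms, acquisitions=acquisitions)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "Protocol":
        with open(path) as fh:
            return cls.from_json(json.load(fh))


#: Sequence-name resolution used for ADC metric naming.
def sequence_label(waveform: GradientWaveform) -> str:
    if waveform.kind == PGSE:
        return "adc_pgse"
    return f"adc_{waveform.frequency:g}hz"


def default_protocol(dt: float = 0.005) -> Protocol:
    """The three-sequence breast protocol used throughout the package.

    PGSE with t_d = 70 ms (delta 12, Delta 74 ms) at b = {0, 0.25, 0.5, 1.0,
    1.5}; 25 Hz cosine OGSE (one period per lobe) at b = {0, 0.3, 0.6, 1.0};
    50 Hz cosine OGSE (two periods per lobe) at b = {0, 0.25, 0.5} ms/um^2 --
    the 50 Hz ceiling reflects the achievable amplitude at this frequency.
    """
    waveforms = {
        "pgse70": build_pgse(delta=12.0, Delta=74.0, amplitude=40.0, dt=dt),
        "ogse25": build_ogse_cosine(frequency=25.0, n_periods=1, amplitude=60.0, dt=dt),
        "ogse50": build_ogse_cosine(frequency=50.0, n_periods=2, amplitude=60.0, dt=dt),
    }
    acquisitions: list[tuple[str, float]] = []
    for b in (0.0, 0.25, 0.5, 1.0, 1.5):
        acquisitions.append(("pgse70", b))
    for b in (0.0, 0.3, 0.6, 1.0):
        acquisitions.append(("ogse25", b))
    for b in (0.0, 0.25, 0.5):
        acquisitions.append(("ogse50", b))
    return Protocol(waveforms=waveforms, acquisitions=acquisitions)
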