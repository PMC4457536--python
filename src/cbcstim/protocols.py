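"""Stimulus waveforms: monophasic, charge-balanced biphasic, bursts, sinusoids.

A waveform is the time course of the electrode drive in volts.  Because the
volume-conductor problem is linear, the extracellular potential at any point
is (unit-drive field sample) x (waveform value), so waveforms are defined
independently of the field.

Polarity convention: this package follows the source convention of the
modelled implant, where a "cathodic" pulse is the one that depolarizes the
synaptic terminals of a perpendicular bipolar cell.  In the volume-conductor
sign frame used here that corresponds to a positive electrode drive (see
docs/methods.md for the derivation); "anodic" is the opposite sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: sign applied to the amplitude of a cathodic (terminal-depolarizing) phase
CATHODIC_SIGN = +1.0
ANODIC_SIGN = -1.0

_SIGNS = {"cathodic": CATHODIC_SIGN, "anodic": ANODIC_SIGN}


@dataclass(frozen=True)
class StimulusWaveform:
    """Piecewise description of the electrode voltage over time.

    ``segments`` is a list of (duration ms, amplitude V) pieces; a segment may
    instead carry a sinusoid via ``sine_hz`` (amplitude then is the peak
    value).  Evaluation is pure: the waveform is zero outside [0, duration].
    """

    segments: tuple[tuple[float, float], ...]
    label: str = ""
    sine_hz: float | None = None

    def __post_init__(self):
        for dur, _amp in self.segments:
            if dur <= 0:
                raise ValueError("segment durations must be positive")

    @property
    def duration(self) -> float:
        return float(sum(d for d, _ in self.segments))

    def __call__(self, t) -> np.ndarray:
        """Drive voltage at time(s) ``t`` (ms)."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        if self.sine_hz is not None:
            amp = self.segments[0][1]
            inside = (t >= 0) & (t < self.duration)
            out[inside] = amp * np.sin(2e-3 * math.pi * self.sine_hz * t[inside])
            return out
        t0 = 0.0
        for dur, amp in self.segments:
            out[(t >= t0) & (t < t0 + dur)] = amp
            t0 += dur
        return out

    def integral(self) -> float:
        """Signed area in V ms (zero for charge-balanced pulses)."""
        if self.sine_hz is not None:
            period = 1e3 / self.sine_hz
            n_whole = math.floor(self.duration / period)
            rem = self.duration - n_whole * period
            amp = self.segments[0][1]
            w = 2e-3 * math.pi * self.sine_hz
            return amp * (1.0 - math.cos(w * rem)) / w
        return float(sum(d * a for d, a in self.segments))


def monophasic(amplitude: float, width: float, polarity: str = "cathodic",
               label: str | None = None) -> StimulusWaveform:
    """Single rectangular phase of ``width`` ms, signed by polarity."""
    if width <= 0:
        raise ValueError("width must be positive")
    sign = _SIGNS[polarity]
    return StimulusWaveform(
        segments=((width, sign * amplitude),),
        label=label or f"monophasic {polarity} {amplitude} V / {width} ms",
    )


def biphasic(amplitude: float, total_width: float, x: float,
             order: str = "cathodic") -> StimulusWaveform:
    """Charge-balanced biphasic pulse.

    The first phase lasts ``x`` percent of ``total_width`` at the given
    amplitude; the second phase spans the rest with its amplitude scaled by
    x/(100-x) so the two phase areas are equal.  ``order`` names the polarity
    of the first phase ("cathodic" = cathodic-first).
    """
    if not 0 < x < 100:
        raise ValueError("x must lie strictly between 0 and 100 percent")
    if total_width <= 0:
        raise ValueError("total_width must be positive")
    sign = _SIGNS[order]
    w1 = total_width * x / 100.0
    w2 = total_width - w1
    a1 = sign * amplitude
    a2 = -a1 * (x / (100.0 - x))
    return StimulusWaveform(
        segments=((w1, a1), (w2, a2)),
        label=f"biphasic {order}-first x={x}% {amplitude} V / {total_width} ms",
    )


def burst(pulse: StimulusWaveform, n: int, isi: float) -> StimulusWaveform:
    """``n`` copies of a rectangular pulse separated by ``isi`` ms of zero drive."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if isi < 0:
        raise ValueError("isi must be non-negative")
    if pulse.sine_hz is not None:
        raise ValueError("bursts of sinusoids are not supported")
    if n == 1 or isi == 0:
        reps = list(pulse.segments) * n
    else:
        reps = []
        for k in range(n):
            reps.extend(pulse.segments)
            if k < n - 1:
                reps.append((isi, 0.0))
    return StimulusWaveform(segments=tuple(reps),
                            label=f"burst n={n} isi={isi} ms of [{pulse.label}]")


def sinusoid(freq: float, amplitude: float, n_cycles: float = 1.0,
             min_samples_per_cycle: int = 20) -> StimulusWaveform:
    """Sinusoidal drive of ``freq`` Hz lasting ``n_cycles`` periods.

    ``min_samples_per_cycle`` is recorded for integrator step-size checks:
    callers should use dt <= period / min_samples_per_cycle.
    """
    if freq <= 0:
        raise ValueError("freq must be positive")
    duration = n_cycles * 1e3 / freq
    wf = StimulusWaveform(segments=((duration, amplitude),),
                          label=f"sinusoid {freq} Hz {amplitude} V",
                          sine_hz=freq)
    object.__setattr__(wf, "max_dt", 1e3 / freq / min_samples_per_cycle)
    return wf


def from_config(cfg: dict) -> StimulusWaveform:
    """Build a waveform from a config mapping.

    Schema: {type: monophasic|biphasic|burst|sinusoid, amplitude_V, width_ms,
    polarity, x_percent, order, n, isi_ms, freq_Hz, n_cycles}; burst configs
    nest their unit pulse under ``pulse``.
    """
    kind = cfg.get("type")
    if kind == "monophasic":
        return monophasic(cfg["amplitude_V"], cfg["width_ms"],
                          cfg.get("polarity", "cathodic"))
    if kind == "biphasic":
        return biphasic(cfg["amplitude_V"], cfg["width_ms"],
                        cfg["x_percent"], cfg.get("order", "cathodic"))
    if kind == "burst":
        return burst(from_config(cfg["pulse"]), cfg["n"], cfg["isi_ms"])
    if kind == "sinusoid":
        return sinusoid(cfg["freq_Hz"], cfg["amplitude_V"],
                        cfg.get("n_cycles", 1.0))
    raise ValueError(f"unknown waveform type {kind!r}")


def load_protocol(path) -> StimulusWaveform:
    """Read a waveform description from a YAML file."""
    import yaml

    with open(path) as fh:
        return from_config(yaml.safe_load(fh))
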