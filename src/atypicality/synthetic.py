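"""Seeded generators for every signal class the coders and scanner assume.

Typical backgrounds are white Gaussian noise or a Gaussian AR process;
events are planted on top by substitution (variance bursts, power-matched
colored noise, AR regime changes) or superposition (tones, mean shifts).
The flagship fixture is the power-matched colored anomaly: an AR(1)
segment whose marginal variance equals the background's, invisible to any
energy detector but compressible by a linear-prediction coder.

Generation is reproducible: the same scenario (including its seed)
produces bit-identical float64 signals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

_BURN_IN = 1024


@dataclass(frozen=True)
class Event:
    """Planted event: [start, start+length) of a given kind.

    Kinds and parameters:

    - ``variance_burst``: white noise at ``factor`` times the background
      variance (substituted).
    - ``colored_same_variance``: AR(1) with coefficient ``a``, innovation
      power matched so the marginal variance equals the background's
      (substituted).
    - ``tone``: sinusoid with ``freq`` (cycles/sample), ``amplitude`` and
      optional ``phase`` (added).
    - ``mean_shift``: constant ``offset`` (added).
    - ``ar_change``: AR process with ``coeffs`` and ``tau`` innovation
      variance (substituted).
    """

    start: int
    length: int
    kind: str
    params: dict = field(default_factory=dict)

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class Scenario:
    """A reproducible signal recipe: typical background plus events."""

    name: str
    length: int
    typical: tuple = ("white", 1.0)
    events: tuple = ()
    seed: int = 0


def _ar_samples(rng, coeffs, tau, n):
    innov = rng.normal(0.0, math.sqrt(tau), n + _BURN_IN)
    a = np.concatenate([[1.0], -np.asarray(coeffs, dtype=float)])
    return lfilter([1.0], a, innov)[_BURN_IN:]


def _background(rng, typical, n):
    kind = typical[0]
    if kind == "white":
        sigma2 = float(typical[1])
        return rng.normal(0.0, math.sqrt(sigma2), n), sigma2
    if kind == "ar":
        coeffs = np.asarray(typical[1], dtype=float)
        tau = float(typical[2])
        x = _ar_samples(rng, coeffs, tau, n)
        return x, float(np.var(x))
    raise ValueError(f"unknown typical spec {typical!r}")


def generate(scenario: Scenario):
    """Materialize a scenario; returns ``(signal, truth_intervals)``.

    Truth intervals are 0-based half-open ``(start, end)`` pairs, one per
    event, in stream order.
    """
    rng = np.random.default_rng(scenario.seed)
    x, bg_var = _background(rng, scenario.typical, scenario.length)
    last_end = -1
    truth = []
    for ev in sorted(scenario.events, key=lambda e: e.start):
        if ev.start < 0 or ev.end > scenario.length or ev.length <= 0:
            raise ValueError(f"event {ev} out of bounds")
        if ev.start < last_end:
            raise ValueError("events must not overlap")
        last_end = ev.end
        sl = slice(ev.start, ev.end)
        p = ev.params
        if ev.kind == "variance_burst":
            var = bg_var * float(p.get("factor", 16.0))
            x[sl] = rng.normal(0.0, math.sqrt(var), ev.length)
        elif ev.kind == "colored_same_variance":
            a = float(p.get("a", 0.9))
            tau = bg_var * (1.0 - a * a)
            x[sl] = _ar_samples(rng, [a], tau, ev.length)
        elif ev.kind == "tone":
            t = np.arange(ev.length)
            x[sl] += float(p.get("amplitude", 1.0)) * np.sin(
                2.0 * math.pi * float(p["freq"]) * t + float(p.get("phase", 0.0))
            )
        elif ev.kind == "mean_shift":
            x[sl] += float(p["offset"])
        elif ev.kind == "ar_change":
            x[sl] = _ar_samples(rng, p["coeffs"], float(p.get("tau", bg_var)), ev.length)
        else:
            raise ValueError(f"unknown event kind {ev.kind!r}")
        truth.append((ev.start, ev.end))
    return x, truth


def builtin_scenario(name: str, seed: int = 0) -> Scenario:
    """Named study scenarios used by the command line and the test suite.

    - ``false_alarm``: 10^5 samples of unit white noise, no events.
    - ``colored_burst``: a 2048-sample power-matched AR(0.9) segment in
      32768 samples of unit white noise.
    - ``variance_burst``: a 256-sample 16x variance burst in 16384 samples.
    - ``two_bursts``: two well-separated 16x variance bursts.
    - ``whale``: repeated down-swept tones over colored background noise —
      an illustrative miniature of hydrophone transient detection.
    - ``hrv``: slowly-varying Gaussian series with a rhythm anomaly
      (variance burst plus mean shift), a heart-rate-variability stand-in.
    """
    if name == "false_alarm":
        return Scenario("false_alarm", 100_000, ("white", 1.0), (), seed)
    if name == "colored_burst":
        return Scenario(
            "colored_burst",
            32768,
            ("white", 1.0),
            (Event(12000, 2048, "colored_same_variance", {"a": 0.9}),),
            seed,
        )
    if name == "variance_burst":
        return Scenario(
            "variance_burst",
            16384,
            ("white", 1.0),
            (Event(6000, 256, "variance_burst", {"factor": 16.0}),),
            seed,
        )
    if name == "two_bursts":
        return Scenario(
            "two_bursts",
            32768,
            ("white", 1.0),
            (
                Event(5000, 256, "variance_burst", {"factor": 16.0}),
                Event(24000, 256, "variance_burst", {"factor": 16.0}),
            ),
            seed,
        )
    if name == "whale":
        sweeps = tuple(
            Event(s, 512, "tone", {"freq": 0.02 + 0.01 * (k % 3), "amplitude": 2.0})
            for k, s in enumerate(range(8000, 30000, 6000))
        )
        return Scenario("whale", 32768, ("ar", [0.6], 0.64), sweeps, seed)
    if name == "hrv":
        return Scenario(
            "hrv",
            32768,
            ("white", 0.05),
            (
                Event(9000, 512, "variance_burst", {"factor": 12.0}),
                Event(22000, 512, "mean_shift", {"offset": 1.0}),
            ),
            seed,
        )
    raise ValueError(f"unknown scenario {name!r}")
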