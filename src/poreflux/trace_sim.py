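"""Ground-truth-labelled synthetic planar-bilayer current recordings.

Emulates the single-channel acquisition chain used for the pore recordings
(+150 mV holding potential, 20 kHz sampling, 4 kHz low-pass) and the
observed event phenomenology: a mixture of step-like openings (one stable
conductance level), multi-level openings (two or more stable levels within
one opening) and erratic flickering openings, plus a control mode producing
only short liposome-fusion transients.

The step-conductance law is a shifted log-normal whose three parameters are
chosen so that the distribution's median and quartiles equal the reported
summary exactly (median 0.17 nS, IQR 0.12–0.32 nS by default); a plain
two-parameter log-normal cannot hit all three numbers at once because its
quartiles are geometrically symmetric about the median.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import bessel, filtfilt

_Z75 = 0.6744897501960817  # standard normal upper quartile

CLASS_STEP = "step-like"
CLASS_MULTI = "multi-level"
CLASS_ERRATIC = "erratic"
CLASS_FUSION = "fusion"


@dataclass(frozen=True)
class StepConductanceDistribution:
    """Shifted log-normal conductance law: G = shift + LogNormal(mu, sigma)."""

    shift_nS: float
    mu: float
    sigma: float

    @classmethod
    def from_median_iqr(
        cls, median_nS: float, q1_nS: float, q3_nS: float
    ) -> "StepConductanceDistribution":
        """Fit so that the law's median and quartiles match the three inputs.

        The shift solves (med-g)^2 = (q1-g)(q3-g); if the quartiles are
        geometrically symmetric about the median (or the solution is not
        below q1) the shift degenerates to 0 and the median/IQR-ratio
        two-parameter fit is used.
        """
        if not 0 < q1_nS < median_nS < q3_nS:
            raise ValueError("need 0 < Q1 < median < Q3")
        denom = 2.0 * median_nS - q1_nS - q3_nS
        shift = (median_nS**2 - q1_nS * q3_nS) / denom if denom != 0 else -1.0
        if not (0.0 <= shift < q1_nS):
            shift = 0.0
        mu = math.log(median_nS - shift)
        sigma = math.log((q3_nS - shift) / (q1_nS - shift)) / (2.0 * _Z75)
        return cls(shift_nS=shift, mu=mu, sigma=sigma)

    def quantile(self, p: float) -> float:
        from scipy.stats import norm

        return self.shift_nS + math.exp(self.mu + self.sigma * norm.ppf(p))

    @property
    def median_nS(self) -> float:
        return self.shift_nS + math.exp(self.mu)

    @property
    def iqr_nS(self) -> tuple[float, float]:
        return (self.quantile(0.25), self.quantile(0.75))

    #: conductances above this are redrawn — a single channel far above the
    #: nS scale is not physical, and one extreme event would dominate a trace
    truncate_nS: float = 2.5

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        out = self.shift_nS + rng.lognormal(self.mu, self.sigma, size=n)
        for _ in range(100):
            bad = out > self.truncate_nS
            if not bad.any():
                break
            out[bad] = self.shift_nS + rng.lognormal(
                self.mu, self.sigma, size=int(bad.sum())
            )
        return np.minimum(out, self.truncate_nS)


@dataclass(frozen=True)
class TraceProtocol:
    """Acquisition settings and event-mixture parameters of one recording."""

    voltage_mV: float = 150.0
    sampling_hz: float = 20_000.0
    filter_hz: float = 4_000.0
    duration_s: float | None = None   # None: sized to fit the generated events
    baseline_pA: float = 0.0
    noise_sd_pA: float = 2.0
    event_rate_hz: float = 1.0        # reciprocal mean closed gap between events
    n_events: int = 116
    #: probabilities for (step-like, multi-level, erratic)
    mixture: tuple[float, float, float] = (0.55, 0.25, 0.20)
    step_median_nS: float = 0.17
    step_q1_nS: float = 0.12
    step_q3_nS: float = 0.32
    #: log-duration law of step-like openings (s): ln T ~ N(mu, sigma)
    step_dur_mu: float = 0.624
    step_dur_sigma: float = 0.9
    #: per-level extra dwell of multi-level openings: 0.1 s + LogNormal
    multi_dwell_mu: float = -1.2
    multi_dwell_sigma: float = 0.8
    #: control (liposome-fusion) transient durations: ln T ~ N(mu, sigma)
    control_dur_mu: float = -1.036
    control_dur_sigma: float = 1.0
    control_mode: bool = False
    min_gap_s: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.mixture) - 1.0) > 1e-9 or any(m < 0 for m in self.mixture):
            raise ValueError("class mixture must be non-negative and sum to 1")
        if self.filter_hz >= self.sampling_hz / 2.0:
            raise ValueError("filter cutoff must be below the Nyquist frequency")
        if self.sampling_hz <= 0 or self.event_rate_hz <= 0:
            raise ValueError("rates must be positive")
        if self.noise_sd_pA < 0:
            raise ValueError("noise SD must be >= 0")
        if self.n_events < 1:
            raise ValueError("need at least one event")

    def conductance_law(self) -> StepConductanceDistribution:
        return StepConductanceDistribution.from_median_iqr(
            self.step_median_nS, self.step_q1_nS, self.step_q3_nS
        )

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["mixture"] = list(d["mixture"])
        return d


@dataclass
class GroundTruthEvent:
    """A labelled event: a sequence of (conductance, dwell) sub-levels.

    Closed gaps inside an erratic opening are encoded as levels with zero
    conductance.  ``unstable`` marks flickering (erratic) events.
    """

    label: str
    start_s: float
    levels: list[tuple[float, float]]  # (conductance nS, dwell s)
    unstable: bool = False

    @property
    def duration_s(self) -> float:
        return float(sum(d for _, d in self.levels))

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s

    @property
    def open_levels(self) -> list[tuple[float, float]]:
        return [(g, d) for g, d in self.levels if g > 0]


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))
    )


def _draw_event(
    rng: np.random.Generator,
    protocol: TraceProtocol,
    law: StepConductanceDistribution,
) -> GroundTruthEvent:
    if protocol.control_mode:
        g = float(law.sample(rng, 1)[0])
        dur = max(0.012, float(rng.lognormal(
            protocol.control_dur_mu, protocol.control_dur_sigma)))
        return GroundTruthEvent(CLASS_FUSION, 0.0, [(g, dur)])
    u = rng.random()
    p_step, p_multi, _ = protocol.mixture
    if u < p_step:
        g = float(law.sample(rng, 1)[0])
        dur = max(0.012, float(rng.lognormal(
            protocol.step_dur_mu, protocol.step_dur_sigma)))
        return GroundTruthEvent(CLASS_STEP, 0.0, [(g, dur)])
    if u < p_step + p_multi:
        n_levels = int(rng.integers(2, 4))
        levels: list[tuple[float, float]] = []
        prev_g = None
        for _ in range(n_levels):
            for _ in range(100):
                g = float(law.sample(rng, 1)[0])
                if prev_g is None or abs(g - prev_g) >= 0.05:
                    break
            dwell = 0.1 + float(rng.lognormal(
                protocol.multi_dwell_mu, protocol.multi_dwell_sigma))
            levels.append((g, dwell))
            prev_g = g
        return GroundTruthEvent(CLASS_MULTI, 0.0, levels)
    # erratic: a burst of short sub-100-ms flickers separated by brief closures
    n_flick = int(rng.integers(5, 16))
    base = 0.0
    while base < 0.12:  # keep every flicker resolvable above the noise floor
        base = float(law.sample(rng, 1)[0])
    levels = []
    for i in range(n_flick):
        amp = base * float(rng.uniform(0.8, 1.3))
        open_dwell = float(rng.uniform(0.005, 0.060))
        levels.append((amp, open_dwell))
        if i < n_flick - 1:
            levels.append((0.0, float(rng.uniform(0.002, 0.010))))
    return GroundTruthEvent(CLASS_ERRATIC, 0.0, levels, unstable=True)


def generate_events(
    protocol: TraceProtocol, n_events: int | None = None
) -> list[GroundTruthEvent]:
    """Draw a non-overlapping labelled event sequence from the protocol mixture.

    Events are placed sequentially with exponential closed gaps of mean
    1/event_rate (plus a fixed minimum gap), so they never overlap; if the
    protocol fixes a recording duration that cannot hold the drawn events,
    an error is raised.
    """
    n = protocol.n_events if n_events is None else int(n_events)
    rng = _rng(protocol.seed, 0)
    law = protocol.conductance_law()
    events: list[GroundTruthEvent] = []
    t = protocol.min_gap_s + float(rng.exponential(1.0 / protocol.event_rate_hz))
    for _ in range(n):
        ev = _draw_event(rng, protocol, law)
        ev.start_s = t
        events.append(ev)
        t = ev.end_s + protocol.min_gap_s + float(
            rng.exponential(1.0 / protocol.event_rate_hz)
        )
    if protocol.duration_s is not None and events[-1].end_s > protocol.duration_s:
        raise ValueError(
            f"event rate too high: {n} events need "
            f"{events[-1].end_s:.1f} s but the protocol fixes "
            f"{protocol.duration_s:.1f} s"
        )
    return events


@dataclass
class CurrentTrace:
    """A uniformly sampled current recording with its acquisition metadata."""

    samples_pA: np.ndarray
    sampling_hz: float
    protocol: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples_pA = np.asarray(self.samples_pA, dtype=float)
        if not np.all(np.isfinite(self.samples_pA)):
            raise ValueError("trace contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return int(self.samples_pA.size)

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_hz

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_hz


def ideal_trace(
    events: list[GroundTruthEvent], protocol: TraceProtocol
) -> np.ndarray:
    """Noise-free piecewise-constant current (baseline + G*V per sub-level)."""
    if protocol.duration_s is not None:
        dur = protocol.duration_s
    else:
        dur = (events[-1].end_s if events else 0.0) + 0.5
    fs = protocol.sampling_hz
    n = int(round(dur * fs))
    out = np.full(n, protocol.baseline_pA, dtype=float)
    for ev in events:
        if ev.end_s > dur + 1e-9:
            raise ValueError("event extends past the recording duration")
        t = ev.start_s
        for g, dwell in ev.levels:
            i0 = int(round(t * fs))
            i1 = int(round((t + dwell) * fs))
            out[i0:i1] += g * protocol.voltage_mV
            t += dwell
    return out


def render_trace(
    events: list[GroundTruthEvent], protocol: TraceProtocol
) -> CurrentTrace:
    """Render the acquisition chain: ideal current + white noise, then the
    4-pole Bessel-type low-pass at the protocol cutoff (applied zero-phase),
    sampled at the protocol rate.  Seed-deterministic."""
    raw = ideal_trace(events, protocol)
    if protocol.noise_sd_pA > 0:
        rng = _rng(protocol.seed, 1)
        raw = raw + rng.normal(0.0, protocol.noise_sd_pA, size=raw.size)
    b, a = bessel(4, protocol.filter_hz, fs=protocol.sampling_hz, norm="mag")
    filtered = filtfilt(b, a, raw)
    return CurrentTrace(
        samples_pA=filtered,
        sampling_hz=protocol.sampling_hz,
        protocol=protocol.to_dict(),
    )


def sample_step_conductances(protocol: TraceProtocol, n: int) -> np.ndarray:
    """Draw ``n`` step-event conductances directly from the protocol's law."""
    return protocol.conductance_law().sample(_rng(protocol.seed, 2), n)


def sample_durations(
    protocol: TraceProtocol, n: int | None = None
) -> np.ndarray:
    """Draw ``n`` whole-event durations from the protocol's mixture."""
    events = generate_events(protocol, n_events=n)
    return np.array([ev.duration_s for ev in events])
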