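"""Single-channel current-trace idealization and event statistics.

Pipeline: robust baseline/noise estimation from the closed-state samples, a
threshold detector for open events (|current - baseline| > k*sigma with
debounce merging and a minimum duration), half-amplitude edge refinement,
within-event change-point segmentation into sub-levels (binary segmentation
with a BIC-style penalty), three-way classification into step-like /
multi-level / erratic openings, the step-like conductance summary
(median/IQR + histogram), and the long-event duration comparison against a
control group via the Brunner–Munzel test.

All thresholds are declared defaults exposed as keyword arguments: detection
k = 5, minimum event duration 10 ms, debounce gap 15 ms, sub-level stability
= robust SD within 1.5x the trace noise and dwell >= 50 ms, and a 10% budget
of unstable time for a step-like call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from . import stats as _stats
from .trace_sim import CurrentTrace, CLASS_STEP, CLASS_MULTI, CLASS_ERRATIC

#: absolute floors used when the recorded noise is (near) zero
_NOISE_FLOOR_PA = 0.25
_THRESHOLD_FLOOR_PA = 0.5


@dataclass(frozen=True)
class BaselineEstimate:
    baseline_pA: float
    noise_sd_pA: float
    bimodal: bool = False  # no single dominant level; lower mode was chosen

    def __iter__(self):
        yield self.baseline_pA
        yield self.noise_sd_pA


def estimate_baseline(
    trace: CurrentTrace, window_pA: float = 6.0
) -> BaselineEstimate:
    """Robust closed-state location and scale.

    The mode of a kernel-smoothed amplitude histogram locates the dominant
    level; with several comparable modes the lowest-current one is taken as
    the closed state (flagged).  Scale is the median absolute deviation of
    the samples within ``window_pA`` of the mode, scaled by 1.4826.
    """
    s = trace.samples_pA
    if s.size < 1000:
        raise ValueError("baseline estimation needs at least 1000 samples")
    # quantile-clipped histogram range: the closed state is the *lowest*
    # substantial mode, so rare extreme open levels must not set the binning
    lo, hi = np.quantile(s, [0.001, 0.90])
    if hi - lo < 1e-12:
        return BaselineEstimate(float(np.median(s)), 0.0)
    hist, edges = np.histogram(s[(s >= lo) & (s <= hi)], bins=512)
    smooth = gaussian_filter1d(hist.astype(float), sigma=3.0)
    padded = np.concatenate([[0.0], smooth, [0.0]])  # peaks at the range edge count
    peaks, _ = find_peaks(padded, height=0.1 * float(np.max(smooth)))
    peaks = peaks - 1
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(smooth))])
    centers = 0.5 * (edges[:-1] + edges[1:])
    mode = float(centers[peaks[0]])  # peaks are ordered by current; take lowest
    sel = s[np.abs(s - mode) < window_pA]
    if sel.size == 0:
        sel = s
    baseline = float(np.median(sel))
    noise = 1.4826 * float(np.median(np.abs(sel - baseline)))
    return BaselineEstimate(baseline, noise, bimodal=peaks.size > 1)


@dataclass(frozen=True)
class RawEvent:
    """A detected excursion from baseline, before segmentation."""

    start_idx: int
    end_idx: int  # half-open
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def detect_events(
    trace: CurrentTrace,
    baseline_pA: float,
    noise_sd_pA: float,
    threshold_k: float = 5.0,
    min_duration_s: float = 0.010,
    debounce_s: float = 0.015,
) -> list[RawEvent]:
    """Maximal runs with |current - baseline| above k*sigma.

    Runs separated by less than the debounce gap are merged (so brief
    flicker closures stay inside one event); runs shorter than
    ``min_duration_s`` are dropped.  Edges are refined to the half-amplitude
    crossing of each run's plateau, the standard idealization convention.
    """
    if threshold_k <= 0:
        raise ValueError("threshold_k must be positive")
    fs = trace.sampling_hz
    dev = np.abs(trace.samples_pA - baseline_pA)
    thr = threshold_k * noise_sd_pA
    if thr <= 0:
        thr = _THRESHOLD_FLOOR_PA
    above = dev > thr
    if not above.any():
        return []
    d = np.diff(above.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(above.size)
    # debounce: merge runs separated by a short sub-threshold gap
    gap = int(round(debounce_s * fs))
    merged: list[list[int]] = []
    for s0, e0 in zip(starts, ends):
        if merged and s0 - merged[-1][1] < gap:
            merged[-1][1] = e0
        else:
            merged.append([s0, e0])
    out: list[RawEvent] = []
    w_loc = max(4, int(round(0.010 * fs)))  # plateau window for edge levels
    for s0, e0 in merged:
        # refine each edge to the half-amplitude crossing of its *local*
        # plateau (first/last ~10 ms), the standard idealization convention;
        # a global plateau would misplace edges of multi-level events
        half_lo = max(0.5 * float(np.median(dev[s0 : min(e0, s0 + w_loc)])), 0.5 * thr)
        half_hi = max(0.5 * float(np.median(dev[max(s0, e0 - w_loc) : e0])), 0.5 * thr)
        i0, i1 = s0, e0
        while i0 > 0 and dev[i0 - 1] >= half_lo:
            i0 -= 1
        while i0 < i1 - 1 and dev[i0] < half_lo:
            i0 += 1
        while i1 < dev.size and dev[i1] >= half_hi:
            i1 += 1
        while i1 > i0 + 1 and dev[i1 - 1] < half_hi:
            i1 -= 1
        if (i1 - i0) / fs < min_duration_s:
            continue
        out.append(RawEvent(i0, i1, i0 / fs, i1 / fs))
    return out


@dataclass(frozen=True)
class SubLevel:
    """A contiguous constant-current stretch inside one event."""

    start_idx: int
    end_idx: int
    mean_pA: float
    dwell_s: float
    stable: bool
    is_open: bool


def _sse(css: np.ndarray, cs: np.ndarray, i: int, j: int) -> float:
    n = j - i
    s = cs[j] - cs[i]
    return float(css[j] - css[i] - s * s / n)


def segment_levels(
    samples: np.ndarray,
    noise_sd_pA: float,
    sampling_hz: float,
    baseline_pA: float = 0.0,
    min_segment: int = 20,
    penalty_factor: float = 10.0,
    stability_sd_factor: float = 1.5,
    stability_dwell_s: float = 0.050,
    max_segments: int = 64,
) -> list[SubLevel]:
    """Change-point segmentation of an event window into sub-levels.

    Binary segmentation greedily splits at the point minimizing the within-
    segment sum of squares, accepting a split only if it improves the SSE by
    more than a BIC-style penalty (``penalty_factor * sigma^2 * ln n``).
    Adjacent segments with indistinguishable means (< 3 sigma apart) are
    re-merged.  A segment is *stable* iff its robust SD is within
    ``stability_sd_factor`` times the trace noise and it dwells at least
    ``stability_dwell_s``; it is *open* iff its mean deviates from baseline
    by more than 2.5 sigma.
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("window too short to segment")
    sigma = max(noise_sd_pA, _NOISE_FLOOR_PA)
    penalty = penalty_factor * sigma * sigma * float(np.log(n))
    cs = np.concatenate([[0.0], np.cumsum(x)])
    css = np.concatenate([[0.0], np.cumsum(x * x)])

    def best_split(i: int, j: int) -> tuple[float, int]:
        if j - i < 2 * min_segment:
            return -np.inf, -1
        ks = np.arange(i + min_segment, j - min_segment + 1)
        if ks.size == 0:
            return -np.inf, -1
        sl = cs[ks] - cs[i]
        sr = cs[j] - cs[ks]
        nl = ks - i
        nr = j - ks
        cost = (css[j] - css[i]) - sl * sl / nl - sr * sr / nr
        k = int(np.argmin(cost))
        gain = _sse(css, cs, i, j) - float(cost[k])
        return gain, int(ks[k])

    bounds = [0, n]
    candidates = {(0, n): best_split(0, n)}
    while len(bounds) - 1 < max_segments:
        seg, (gain, k) = max(candidates.items(), key=lambda kv: kv[1][0])
        if gain <= penalty or k < 0:
            break
        i, j = seg
        del candidates[seg]
        bounds.append(k)
        bounds.sort()
        candidates[(i, k)] = best_split(i, k)
        candidates[(k, j)] = best_split(k, j)

    # merge adjacent segments whose means are statistically indistinguishable
    bounds = sorted(bounds)
    merged = [bounds[0], bounds[1]]
    for b in bounds[2:]:
        i, j = merged[-2], merged[-1]
        m_prev = (cs[j] - cs[i]) / (j - i)
        m_next = (cs[b] - cs[j]) / (b - j)
        if abs(m_next - m_prev) < 3.0 * sigma:
            merged[-1] = b
        else:
            merged.append(b)

    out: list[SubLevel] = []
    for i, j in zip(merged[:-1], merged[1:]):
        seg = x[i:j]
        mean = float(np.mean(seg))
        robust_sd = 1.4826 * float(np.median(np.abs(seg - np.median(seg))))
        dwell = (j - i) / sampling_hz
        stable = robust_sd <= stability_sd_factor * sigma and dwell >= stability_dwell_s
        is_open = abs(mean - baseline_pA) > 2.5 * sigma
        out.append(SubLevel(i, j, mean, dwell, stable, is_open))
    return out


def classify_event(
    sub_levels: list[SubLevel], noise_sd_pA: float | None = None
) -> str:
    """Three-way event classification from its sub-levels.

    step-like: exactly one distinct stable open level and at most 10% of the
    event in unstable segments; multi-level: two or more *distinct* stable
    conductance states (means more than 4 sigma apart) with the event not
    dominated by unstable time; erratic: everything else (flickering, no
    resolvable stable state structure).
    """
    if not sub_levels:
        raise ValueError("need at least one sub-level")
    if noise_sd_pA is None:
        noise_sd_pA = _NOISE_FLOOR_PA
    sigma = max(noise_sd_pA, _NOISE_FLOOR_PA)
    total = sum(lv.dwell_s for lv in sub_levels)
    stable_open = [lv for lv in sub_levels if lv.stable and lv.is_open]
    unstable_time = sum(lv.dwell_s for lv in sub_levels if not lv.stable)
    # distinct conductance states: cluster stable means to 4 sigma
    distinct: list[float] = []
    for lv in sorted(stable_open, key=lambda l: l.mean_pA):
        if not distinct or abs(lv.mean_pA - distinct[-1]) > 4.0 * sigma:
            distinct.append(lv.mean_pA)
    if len(distinct) >= 2 and unstable_time <= 0.50 * total:
        return CLASS_MULTI
    if len(distinct) == 1 and unstable_time <= 0.10 * total:
        return CLASS_STEP
    return CLASS_ERRATIC


@dataclass
class ChannelEvent:
    """An idealized open-channel event."""

    start_s: float
    end_s: float
    label: str
    mean_open_pA: float          # signed deviation from baseline
    conductance_nS: float
    sub_levels: list[SubLevel] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def n_levels(self) -> int:
        return sum(1 for lv in self.sub_levels if lv.stable and lv.is_open)


def analyze_trace(
    trace: CurrentTrace,
    voltage_mV: float | None = None,
    threshold_k: float = 5.0,
    min_duration_s: float = 0.010,
    debounce_s: float = 0.015,
    baseline: BaselineEstimate | None = None,
) -> tuple[list[ChannelEvent], BaselineEstimate]:
    """Full idealization pipeline: baseline, detection, segmentation, classes.

    For a step-like event the open current is the mean of its single stable
    segment (excluding edge transients); otherwise the dwell-weighted mean
    over open segments.
    """
    if voltage_mV is None:
        v = trace.protocol.get("voltage_mV")
        if v is None:
            raise ValueError("voltage not given and absent from trace metadata")
        voltage_mV = float(v)
    if voltage_mV == 0:
        raise ValueError("conductance undefined at zero voltage")
    if baseline is None:
        baseline = estimate_baseline(trace)
    raw = detect_events(
        trace,
        baseline.baseline_pA,
        baseline.noise_sd_pA,
        threshold_k=threshold_k,
        min_duration_s=min_duration_s,
        debounce_s=debounce_s,
    )
    events: list[ChannelEvent] = []
    for ev in raw:
        window = trace.samples_pA[ev.start_idx : ev.end_idx]
        levels = segment_levels(
            window,
            baseline.noise_sd_pA,
            trace.sampling_hz,
            baseline_pA=baseline.baseline_pA,
        )
        # re-anchor indices to the trace
        levels = [
            SubLevel(
                lv.start_idx + ev.start_idx,
                lv.end_idx + ev.start_idx,
                lv.mean_pA,
                lv.dwell_s,
                lv.stable,
                lv.is_open,
            )
            for lv in levels
        ]
        label = classify_event(levels, baseline.noise_sd_pA)
        stable_open = [lv for lv in levels if lv.stable and lv.is_open]
        if label == CLASS_STEP:
            open_dev = stable_open[0].mean_pA - baseline.baseline_pA
        else:
            opens = [lv for lv in levels if lv.is_open] or levels
            w = np.array([lv.dwell_s for lv in opens])
            m = np.array([lv.mean_pA for lv in opens])
            open_dev = float(np.average(m, weights=w)) - baseline.baseline_pA
        events.append(
            ChannelEvent(
                start_s=ev.start_s,
                end_s=ev.end_s,
                label=label,
                mean_open_pA=open_dev,
                conductance_nS=open_dev / voltage_mV,
                sub_levels=levels,
                flags=["bimodal-baseline"] if baseline.bimodal else [],
            )
        )
    return events, baseline


@dataclass
class ConductanceSummary:
    """Median/IQR and histogram of step-like event conductances."""

    values_nS: np.ndarray
    n: int
    median_nS: float
    q1_nS: float
    q3_nS: float
    hist_edges_nS: np.ndarray
    hist_counts: np.ndarray
    empty: bool = False


def event_conductances(
    events: list[ChannelEvent],
    voltage_mV: float,
    bin_width_nS: float = 0.05,
) -> ConductanceSummary:
    """Step-like conductance cohort: G = mean open deviation / V, summarized
    as median (IQR) with a fixed-width histogram."""
    if voltage_mV == 0:
        raise ValueError("conductance undefined at zero voltage")
    g = np.array(
        [ev.mean_open_pA / voltage_mV for ev in events if ev.label == CLASS_STEP]
    )
    if g.size == 0:
        return ConductanceSummary(
            g, 0, float("nan"), float("nan"), float("nan"),
            np.array([0.0]), np.array([], dtype=int), empty=True,
        )
    med, q1, q3 = _stats.median_iqr(g)
    top = np.ceil(float(np.max(g)) / bin_width_nS) * bin_width_nS
    edges = np.arange(0.0, top + bin_width_nS / 2, bin_width_nS)
    counts, edges = np.histogram(g, bins=edges)
    return ConductanceSummary(
        values_nS=g, n=int(g.size), median_nS=med, q1_nS=q1, q3_nS=q3,
        hist_edges_nS=edges, hist_counts=counts,
    )


def _durations(events) -> np.ndarray:
    return np.array(
        [ev.duration_s if hasattr(ev, "duration_s") else float(ev) for ev in events]
    )


@dataclass
class DurationReport:
    """Long-event fractions and the Brunner–Munzel duration comparison."""

    cutoff_s: float
    n_a: int
    n_b: int
    frac_exceeding_a: float
    frac_exceeding_b: float
    bm: _stats.BMTestResult
    low_power: bool = False


def duration_analysis(
    events_a, events_b, cutoff_s: float = 1.0
) -> DurationReport:
    """Per-group fraction of events exceeding the cutoff (1 s criterion) and a
    two-sided Brunner–Munzel comparison of the duration distributions."""
    da, db = _durations(events_a), _durations(events_b)
    if da.size == 0 or db.size == 0:
        raise ValueError("both groups must be non-empty")
    bm = _stats.brunner_munzel(da, db)
    return DurationReport(
        cutoff_s=cutoff_s,
        n_a=int(da.size),
        n_b=int(db.size),
        frac_exceeding_a=float(np.mean(da > cutoff_s)),
        frac_exceeding_b=float(np.mean(db > cutoff_s)),
        bm=bm,
        low_power=min(da.size, db.size) < 10,
    )
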