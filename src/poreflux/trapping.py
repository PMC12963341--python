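"""Dwell-time (residence) analysis inside the constriction window.

Quantifies the transient anion trapping seen in the wild-type pore lumen:
maximal continuous runs of frames during which an ion's z coordinate lies
inside a defined axial window, summarized per species, and a two-condition
comparison (e.g. wild type vs. the constriction-free double-glycine mutant
surrogate) covering both conduction and trapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pore_sim import IonTrajectory, SPECIES_CL
from . import permeation
from .permeation import ConductanceAggregate, PoreGeometry
from . import stats as _stats


@dataclass(frozen=True)
class DwellEvent:
    """One continuous residence of an ion inside the axial window."""

    ion_id: int
    species: str
    entry_time_ns: float
    exit_time_ns: float   # half-open: first time no longer inside
    duration_ns: float

    def __post_init__(self) -> None:
        if self.duration_ns <= 0:
            raise ValueError("dwell duration must be positive")


def dwell_events(
    traj: IonTrajectory,
    window: tuple[float, float],
    min_duration_ns: float = 0.0,
    gap_frames: int = 0,
) -> list[DwellEvent]:
    """Maximal per-ion runs of frames with z inside ``window``.

    Durations follow the half-open frame convention: a run covering k saved
    frames at save interval dt has duration k*dt (exit is one frame past the
    last inside frame).  Runs separated by at most ``gap_frames`` outside
    frames are merged; runs shorter than ``min_duration_ns`` are discarded.
    """
    w_lo, w_hi = window
    if not w_lo < w_hi:
        raise ValueError("empty dwell window")
    if min_duration_ns < 0:
        raise ValueError("min_duration must be >= 0")
    times = traj.times_ns
    if len(times) > 1:
        save_dt = float(times[1] - times[0])
    else:
        save_dt = 0.0
    inside = (traj.z >= w_lo) & (traj.z < w_hi)  # (F, N)
    events: list[DwellEvent] = []
    for j in range(traj.n_ions):
        col = inside[:, j]
        if not col.any():
            continue
        idx = np.nonzero(col)[0]
        # split where the gap between consecutive inside frames exceeds tolerance
        breaks = np.nonzero(np.diff(idx) > gap_frames + 1)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [idx.size - 1]])
        for s, e in zip(starts, ends):
            first, last = idx[s], idx[e]
            duration = times[last] - times[first] + save_dt
            if duration <= 0 or duration < min_duration_ns:
                continue
            events.append(
                DwellEvent(
                    ion_id=int(traj.ion_ids[j]),
                    species=str(traj.species[j]),
                    entry_time_ns=float(times[first]),
                    exit_time_ns=float(times[first] + duration),
                    duration_ns=float(duration),
                )
            )
    events.sort(key=lambda ev: (ev.entry_time_ns, ev.ion_id))
    return events


def default_window(traj: IonTrajectory) -> tuple[float, float]:
    """Constriction window from the simulation config: trap center +/- half-width."""
    cfg = traj.metadata.get("config", {})
    if "slab_z" not in cfg:
        raise ValueError("trajectory metadata carries no trap geometry")
    z_lo, z_hi = cfg["slab_z"]
    center = cfg.get("trap_center_z_nm")
    if center is None:
        center = 0.5 * (z_lo + z_hi)
    half = cfg.get("trap_half_width_nm", 0.3)
    return (center - half, center + half)


@dataclass
class DwellSummary:
    """Count and duration statistics of a set of dwell events."""

    species: str | None
    count: int
    mean_ns: float      # NaN when count == 0
    median_ns: float
    max_ns: float
    total_occupancy_ns: float
    empty: bool = False


def dwell_summary(
    events: list[DwellEvent], species: str | None = None
) -> DwellSummary:
    """Summary statistics of dwell durations, optionally for one species."""
    durs = np.array(
        [ev.duration_ns for ev in events if species is None or ev.species == species]
    )
    if durs.size == 0:
        nan = float("nan")
        return DwellSummary(species, 0, nan, nan, nan, 0.0, empty=True)
    return DwellSummary(
        species=species,
        count=int(durs.size),
        mean_ns=float(np.mean(durs)),
        median_ns=float(np.median(durs)),
        max_ns=float(np.max(durs)),
        total_occupancy_ns=float(np.sum(durs)),
    )


@dataclass
class TrapComparison:
    """Conduction and trapping contrast between two conditions."""

    labels: tuple[str, str]
    conductance: dict[str, ConductanceAggregate]
    dwell: dict[str, dict[str, DwellSummary]]  # label -> species -> summary
    conductance_difference_nS: float           # b - a
    cl_dwell_ratio: float                      # mean dwell a / mean dwell b
    cl_dwell_ratio_flagged: bool = False       # a condition had zero Cl- dwells
    bm_test: "_stats.BMTestResult | None" = None
    window: tuple[float, float] = (0.0, 0.0)
    voltage_mV: float = 0.0


def compare_conditions(
    trajs_a: list[IonTrajectory],
    trajs_b: list[IonTrajectory],
    labels: tuple[str, str],
    window: tuple[float, float],
    voltage_mV: float,
    geom: PoreGeometry | None = None,
    min_duration_ns: float = 0.0,
    gap_frames: int = 0,
    run_test: bool = False,
) -> TrapComparison:
    """Compare conduction and Cl- trapping between two trajectory sets.

    Both conditions are analyzed with the same window, geometry and voltage
    (mismatched per-trajectory metadata voltages raise).  The Cl- dwell
    ratio is mean(condition a) / mean(condition b); if either side has no
    Cl- dwell events the ratio is returned as inf/NaN and flagged.  A
    Brunner–Munzel test on the pooled Cl- dwell durations is run only on
    request.
    """
    conds: dict[str, ConductanceAggregate] = {}
    dwells: dict[str, dict[str, DwellSummary]] = {}
    all_durs: dict[str, list[float]] = {}
    for label, trajs in zip(labels, (trajs_a, trajs_b)):
        if not trajs:
            raise ValueError(f"condition {label!r} has no trajectories")
        for t in trajs:
            v = t.metadata.get("config", {}).get("voltage_mV")
            if v is not None and float(v) != float(voltage_mV):
                raise ValueError(
                    f"trajectory in condition {label!r} was run at {v} mV, "
                    f"not {voltage_mV} mV"
                )
        ests = [
            permeation.estimate_conductance(t, geom=geom, voltage_mV=voltage_mV)
            for t in trajs
        ]
        conds[label] = permeation.aggregate_replicates(ests)
        evs: list[DwellEvent] = []
        for t in trajs:
            evs.extend(
                dwell_events(
                    t, window, min_duration_ns=min_duration_ns, gap_frames=gap_frames
                )
            )
        per_species = {}
        for sp in sorted({str(s) for t in trajs for s in t.species}):
            per_species[sp] = dwell_summary(evs, species=sp)
        dwells[label] = per_species
        all_durs[label] = [
            ev.duration_ns for ev in evs if ev.species == SPECIES_CL
        ]

    la, lb = labels
    mean_a = dwells[la].get(SPECIES_CL, dwell_summary([], SPECIES_CL)).mean_ns
    mean_b = dwells[lb].get(SPECIES_CL, dwell_summary([], SPECIES_CL)).mean_ns
    flagged = not (np.isfinite(mean_a) and np.isfinite(mean_b))
    if np.isfinite(mean_a) and np.isfinite(mean_b) and mean_b != 0:
        ratio = mean_a / mean_b
    elif np.isfinite(mean_a) and mean_a > 0:
        ratio = float("inf")
    else:
        ratio = float("nan")

    bm = None
    if run_test and len(all_durs[la]) >= 2 and len(all_durs[lb]) >= 2:
        bm = _stats.brunner_munzel(all_durs[la], all_durs[lb])

    return TrapComparison(
        labels=labels,
        conductance=conds,
        dwell=dwells,
        conductance_difference_nS=(
            conds[lb].mean_conductance_nS - conds[la].mean_conductance_nS
        ),
        cl_dwell_ratio=ratio,
        cl_dwell_ratio_flagged=flagged,
        bm_test=bm,
        window=window,
        voltage_mV=voltage_mV,
    )
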