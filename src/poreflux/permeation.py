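"""Directional ion-translocation counting, current/conductance, and RMSD.

The central computation of the MD arm: unwrap periodic z coordinates, detect
complete directional pore traversals with a two-plane hysteresis scheme,
convert productive counts to an ionic current

    I = (N_K + N_Cl) * e / dt

(N_K = K+ crossings in +Z, N_Cl = Cl- crossings in -Z, e the elementary
charge) and to a conductance G = I / V by Ohm's law, then aggregate
replicate runs as mean +/- sample SD.  Wrong-direction crossings are tallied
and reported but never enter N_K/N_Cl, matching the counting equation
literally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import charges_per_ns_to_pA
from .pore_sim import IonTrajectory, SPECIES_K, SPECIES_CL


@dataclass(frozen=True)
class PoreGeometry:
    """Counting planes bounding the membrane/pore span along the pore (Z) axis."""

    z_lo_nm: float
    z_hi_nm: float
    radial_cutoff_nm: float | None = None

    def __post_init__(self) -> None:
        if not self.z_lo_nm < self.z_hi_nm:
            raise ValueError("z_lo must be below z_hi")
        if self.radial_cutoff_nm is not None and self.radial_cutoff_nm <= 0:
            raise ValueError("radial cutoff must be positive if set")

    @classmethod
    def from_trajectory(cls, traj: IonTrajectory) -> "PoreGeometry":
        """Default geometry: the membrane slab faces recorded in the metadata."""
        cfg = traj.metadata.get("config", {})
        if "slab_z" not in cfg:
            raise ValueError("trajectory metadata carries no slab geometry")
        z_lo, z_hi = cfg["slab_z"]
        return cls(z_lo_nm=float(z_lo), z_hi_nm=float(z_hi))


@dataclass(frozen=True)
class CrossingEvent:
    """One completed directional translocation of a single ion."""

    ion_id: int
    species: str
    direction: int  # +1 for +Z, -1 for -Z
    entry_time_ns: float
    exit_time_ns: float
    flagged_sparse: bool = False  # single saved frame jumped past both planes

    def __post_init__(self) -> None:
        if self.direction not in (+1, -1):
            raise ValueError("direction must be +1 or -1")
        if not self.entry_time_ns < self.exit_time_ns:
            raise ValueError("entry time must precede exit time")


def unwrap_z(z_series: np.ndarray, box_z: float) -> np.ndarray:
    """Undo periodic wrapping of a z time series (minimal-image convention).

    Consecutive unwrapped differences have magnitude <= box_z/2; the
    unwrapped value differs from the wrapped one by an integer multiple of
    box_z at every frame.  A single-frame jump of exactly box_z/2 is treated
    as physical motion (no wrap) — the documented tie rule.
    """
    z = np.asarray(z_series, dtype=float)
    if z.size == 0:
        raise ValueError("empty z series")
    if z.ndim == 1:
        z = z[:, None]
        squeeze = True
    else:
        squeeze = False
    dz = np.diff(z, axis=0)
    shift = np.floor(dz / box_z + 0.5)
    # tie rule: |dz| == box_z/2 exactly -> no wrap
    shift[np.abs(np.abs(dz) - box_z / 2.0) == 0.0] = 0.0
    corr = dz - shift * box_z
    out = np.concatenate([z[:1], z[:1] + np.cumsum(corr, axis=0)], axis=0)
    return out[:, 0] if squeeze else out


def wrap_z(z_series: np.ndarray, box_z: float) -> np.ndarray:
    """Wrap a continuous z series back into [0, box_z)."""
    return np.asarray(z_series, dtype=float) % box_z


def detect_crossings(
    traj: IonTrajectory, geom: PoreGeometry | None = None
) -> list[CrossingEvent]:
    """Detect complete directional pore traversals for every ion.

    Uses two-plane hysteresis: an ion arms on leaving one bounding plane's
    reservoir and fires only on reaching the opposite reservoir, so
    dithering around a single plane never counts.  Operates on unwrapped z,
    with the slab repeated periodically, so reservoir recycling across the
    box boundary is never mistaken for a traversal.  Recrossings after a
    completed event count as new events.
    """
    if geom is None:
        geom = PoreGeometry.from_trajectory(traj)
    box_z = traj.box_z
    if geom.z_lo_nm < 0 or geom.z_hi_nm > box_z:
        warnings.warn(
            "counting planes lie outside the trajectory z-range; zero events",
            stacklevel=2,
        )
        return []
    h = geom.z_hi_nm - geom.z_lo_nm
    L = box_z
    times = traj.times_ns
    zu = unwrap_z(traj.z, box_z)  # (F, N)

    radial_ok = None
    if geom.radial_cutoff_nm is not None:
        cx, cy = 0.5 * traj.box[0], 0.5 * traj.box[1]
        r2 = (traj.positions[:, :, 0] - cx) ** 2 + (
            traj.positions[:, :, 1] - cy
        ) ** 2
        radial_ok = r2 <= geom.radial_cutoff_nm**2

    events: list[CrossingEvent] = []
    q = zu - geom.z_lo_nm
    cell = np.floor(q / L).astype(np.int64)
    in_slab = (q - cell * L) < h  # inside some periodic image of the slab
    for j in range(traj.n_ions):
        nz = np.nonzero(~in_slab[:, j])[0]
        if nz.size < 2:
            continue
        r = cell[nz, j]  # reservoir index per non-slab frame
        change = np.nonzero(np.diff(r) != 0)[0]
        for c in change:
            i0, i1 = nz[c], nz[c + 1]
            jump = int(r[c + 1] - r[c])
            if radial_ok is not None and i1 - i0 > 1:
                if not np.all(radial_ok[i0 + 1 : i1, j]):
                    continue  # bypassed outside the radial cutoff
            direction = 1 if jump > 0 else -1
            for _ in range(abs(jump)):
                events.append(
                    CrossingEvent(
                        ion_id=int(traj.ion_ids[j]),
                        species=str(traj.species[j]),
                        direction=direction,
                        entry_time_ns=float(times[i0]),
                        exit_time_ns=float(times[i1]),
                        flagged_sparse=abs(jump) > 1 or i1 == i0 + 1,
                    )
                )
    events.sort(key=lambda e: (e.exit_time_ns, e.ion_id))
    return events


@dataclass(frozen=True)
class DirectionalCounts:
    """Productive and counter-productive crossing tallies."""

    n_k: int          # K+ crossings in +Z (productive)
    n_cl: int         # Cl- crossings in -Z (productive)
    n_k_counter: int  # K+ in -Z, excluded from the counting equation
    n_cl_counter: int # Cl- in +Z, excluded

    def __iter__(self):
        yield self.n_k
        yield self.n_cl


def count_directional(events: list[CrossingEvent]) -> DirectionalCounts:
    """Tally productive crossings (K+ in +Z, Cl- in -Z) per the counting equation.

    Counter-productive crossings are reported separately, never subtracted.
    """
    n_k = n_cl = n_kc = n_clc = 0
    for ev in events:
        if ev.species == SPECIES_K:
            if ev.direction > 0:
                n_k += 1
            else:
                n_kc += 1
        elif ev.species == SPECIES_CL:
            if ev.direction < 0:
                n_cl += 1
            else:
                n_clc += 1
        else:
            raise ValueError(f"unknown species {ev.species!r}")
    return DirectionalCounts(n_k, n_cl, n_kc, n_clc)


def compute_current(n_k: int, n_cl: int, dt_ns: float) -> float:
    """Ionic current in pA: I = (N_K + N_Cl) * e / dt."""
    if dt_ns <= 0:
        raise ValueError("dt must be positive")
    return charges_per_ns_to_pA((n_k + n_cl) / dt_ns)


def compute_conductance(current_pA: float, voltage_mV: float) -> float:
    """Ohm's-law conductance in nS: G = I / V (pA / mV = nS)."""
    if voltage_mV == 0:
        raise ValueError("conductance undefined at zero voltage")
    return current_pA / voltage_mV


@dataclass
class ConductanceEstimate:
    """Counts, current and conductance for one replicate trajectory."""

    counts: DirectionalCounts
    dt_ns: float
    voltage_mV: float
    current_pA: float
    conductance_nS: float

    @property
    def net_current_pA(self) -> float:
        """Signed current including counter-productive crossings (for V=0 checks)."""
        c = self.counts
        net = (c.n_k - c.n_k_counter) + (c.n_cl - c.n_cl_counter)
        return charges_per_ns_to_pA(net / self.dt_ns)


@dataclass
class ConductanceAggregate:
    """Replicate mean +/- sample SD of current and conductance."""

    replicates: list[ConductanceEstimate]
    voltage_mV: float
    mean_current_pA: float
    sd_current_pA: float
    mean_conductance_nS: float
    sd_conductance_nS: float
    n: int
    single_replicate: bool = field(default=False)


def estimate_conductance(
    traj: IonTrajectory,
    geom: PoreGeometry | None = None,
    voltage_mV: float | None = None,
) -> ConductanceEstimate:
    """Full per-replicate pipeline: detect crossings, count, I and G."""
    if geom is None:
        geom = PoreGeometry.from_trajectory(traj)
    if voltage_mV is None:
        cfg = traj.metadata.get("config", {})
        if "voltage_mV" not in cfg:
            raise ValueError("voltage not given and absent from metadata")
        voltage_mV = float(cfg["voltage_mV"])
    events = detect_crossings(traj, geom)
    counts = count_directional(events)
    current = compute_current(counts.n_k, counts.n_cl, traj.duration_ns)
    cond = (
        compute_conductance(current, voltage_mV) if voltage_mV != 0 else float("nan")
    )
    return ConductanceEstimate(
        counts=counts,
        dt_ns=traj.duration_ns,
        voltage_mV=voltage_mV,
        current_pA=current,
        conductance_nS=cond,
    )


def aggregate_replicates(
    estimates: list[ConductanceEstimate],
) -> ConductanceAggregate:
    """Mean and sample SD (n-1 denominator) across replicate estimates."""
    if not estimates:
        raise ValueError("need at least one replicate")
    voltages = {e.voltage_mV for e in estimates}
    if len(voltages) != 1:
        raise ValueError("replicates were run at different voltages")
    currents = np.array([e.current_pA for e in estimates])
    conds = np.array([e.conductance_nS for e in estimates])
    n = len(estimates)
    sd_i = float(np.std(currents, ddof=1)) if n > 1 else 0.0
    sd_g = float(np.std(conds, ddof=1)) if n > 1 else 0.0
    return ConductanceAggregate(
        replicates=list(estimates),
        voltage_mV=voltages.pop(),
        mean_current_pA=float(np.mean(currents)),
        sd_current_pA=sd_i,
        mean_conductance_nS=float(np.mean(conds)),
        sd_conductance_nS=sd_g,
        n=n,
        single_replicate=(n == 1),
    )


def kabsch_rmsd(
    reference: np.ndarray, frame: np.ndarray, superpose: bool = True
) -> float:
    """RMSD between two matched coordinate sets, optionally after optimal
    least-squares superposition (Kabsch algorithm, proper rotation enforced)."""
    ref = np.asarray(reference, dtype=float)
    mob = np.asarray(frame, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("coordinate sets must both have shape (n_atoms, 3)")
    n = ref.shape[0]
    if superpose:
        if n < 3:
            raise ValueError("superposition needs at least 3 atoms")
        ref_c = ref - ref.mean(axis=0)
        mob_c = mob - mob.mean(axis=0)
        h = mob_c.T @ ref_c
        u, _, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(u @ vt))
        diag = np.diag([1.0, 1.0, d])
        rot = u @ diag @ vt
        mob = mob_c @ rot
        ref = ref_c
    diff = mob - ref
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def rmsd_series(
    coords: np.ndarray, reference_frame: int = 0, superpose: bool = True
) -> np.ndarray:
    """Per-frame RMSD of a (frames, atoms, 3) stack against one of its frames."""
    c = np.asarray(coords, dtype=float)
    if c.ndim != 3 or c.shape[0] == 0:
        raise ValueError("need a non-empty (frames, atoms, 3) array")
    if not (-c.shape[0] <= reference_frame < c.shape[0]):
        raise ValueError("reference frame index out of range")
    ref = c[reference_frame]
    return np.array([kabsch_rmsd(ref, frame, superpose=superpose) for frame in c])
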