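from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from poreflux.pore_sim import IonTrajectory

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def traj_from_z(
    z_paths: np.ndarray,
    box_z: float = 100.0,
    species=None,
    save_dt_ns: float = 0.01,
    metadata: dict | None = None,
) -> IonTrajectory:
    """Build a trajectory from bare z paths (frames, ions); x=y=pore axis."""
    z = np.atleast_2d(np.asarray(z_paths, dtype=float))
    if z.shape[0] == 1 and z.ndim == 2 and np.asarray(z_paths).ndim == 1:
        z = z.T  # single ion given as a 1-D series
    f, n = z.shape
    pos = np.empty((f, n, 3))
    pos[:, :, 0] = 3.0
    pos[:, :, 1] = 3.0
    pos[:, :, 2] = z % box_z
    sp = species if species is not None else np.array(["K+"] * n)
    return IonTrajectory(
        times_ns=np.arange(f) * save_dt_ns,
        ion_ids=np.arange(n),
        species=np.asarray(sp),
        positions=pos,
        box=(6.0, 6.0, box_z),
        metadata=metadata or {},
    )


@pytest.fixture
def z_traj_builder():
    return traj_from_z
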