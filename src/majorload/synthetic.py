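"""Synthetic load datasets with known structure, plus an exact cover oracle.

Instrumented-hip recordings of daily activities share a characteristic
shape: within one activity the contact-force direction drifts smoothly
over a small patch of the unit sphere while the magnitude follows a smooth
profile over the movement cycle.  :func:`generate_activity_dataset`
emulates exactly that — a reflected random walk on the sphere inside a
per-activity angular spread, paired with a sinusoidal magnitude profile —
and :func:`daily_activity_specs` provides a nine-activity default whose
layout mirrors a full daily-activity collection (9 activities x 201
samples, forces in percent of body weight, pelvic frame): the three
walking speeds, stair ascent/descent and quiet standing load the joint
along nearby superior-medial directions, while chair rise/sit and knee
bends pull the force direction several tens of degrees away.

:func:`generate_separated_clusters` builds tiny instances whose minimal
cover size is known *by construction*, and :func:`exact_min_cover` is a
brute-force set-cover oracle for cross-checking the heuristic on small
instances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InstanceTooLargeError
from .geometry import Cone, covers, orthonormal_frame, unit
from .load_io import LoadDataset, Units

__all__ = [
    "ClusterSpec",
    "generate_activity_dataset",
    "daily_activity_specs",
    "generate_daily_activity_dataset",
    "generate_separated_clusters",
    "exact_min_cover",
]

#: largest instance the exhaustive oracle accepts
ORACLE_MAX_N = 15


@dataclass(frozen=True)
class ClusterSpec:
    """One activity-like direction cluster.

    ``center`` is the mean direction (unit 3-vector); directions stay
    within ``angular_spread_deg`` of it; magnitudes stay inside
    ``magnitude_range`` (same units as the dataset being built).
    """

    name: str
    center: np.ndarray
    angular_spread_deg: float
    magnitude_range: tuple[float, float]
    n_samples: int = 201

    def __post_init__(self) -> None:
        c = unit(np.asarray(self.center, dtype=float))
        object.__setattr__(self, "center", c)
        if self.angular_spread_deg < 0:
            raise ValueError("angular_spread_deg must be >= 0")
        lo, hi = self.magnitude_range
        if lo > hi:
            raise ValueError("magnitude_range must be (min, max) with min <= max")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


def _cap_point(center: np.ndarray, r_deg: float, phi_rad: float,
               b1: np.ndarray, b2: np.ndarray) -> np.ndarray:
    """Direction at angular radius r from the center, azimuth phi."""
    r = np.radians(r_deg)
    return (np.cos(r) * center
            + np.sin(r) * (np.cos(phi_rad) * b1 + np.sin(phi_rad) * b2))


def _direction_walk(spec: ClusterSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth trajectory inside the spread: a reflected planar random walk
    mapped onto the spherical cap (azimuthal-equidistant chart)."""
    if spec.angular_spread_deg == 0.0:
        return np.tile(spec.center, (n, 1))
    spread = spec.angular_spread_deg
    b1, b2 = orthonormal_frame(spec.center)
    step = spread / 8.0
    p = rng.uniform(-spread / 2, spread / 2, size=2)
    points = np.empty((n, 2))
    for i in range(n):
        p = p + rng.normal(0.0, step, size=2)
        r = float(np.hypot(*p))
        while r > spread:  # reflect at the cap boundary
            p = p * (2.0 * spread / r - 1.0)
            r = float(np.hypot(*p))
        points[i] = p
    radii = np.hypot(points[:, 0], points[:, 1])
    phis = np.arctan2(points[:, 1], points[:, 0])
    return np.array([_cap_point(spec.center, r, phi, b1, b2)
                     for r, phi in zip(radii, phis)])


def _magnitude_profile(spec: ClusterSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth cycle-like magnitude curve inside the spec's range."""
    lo, hi = spec.magnitude_range
    if lo == hi or n == 1:
        return np.full(n, float(hi))
    mid, amp = (lo + hi) / 2.0, (hi - lo) / 2.0
    cycles = rng.uniform(1.0, 3.0)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    t = np.linspace(0.0, 1.0, n)
    return mid + amp * np.sin(2.0 * np.pi * cycles * t + phase)


def generate_activity_dataset(activities: list[ClusterSpec],
                              samples_per_activity: int | None = None,
                              seed: int = 0,
                              units: Units = Units.BW_PERCENT) -> LoadDataset:
    """Build a dataset of smooth per-activity load trajectories.

    ``samples_per_activity`` overrides each spec's ``n_samples`` when
    given.  Reproducible: equal (specs, seed) give byte-identical datasets.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for spec in activities:
        n = samples_per_activity or spec.n_samples
        dirs = _direction_walk(spec, n, rng)
        mags = _magnitude_profile(spec, n, rng)
        vecs = dirs * mags[:, None]
        frames.append(pd.DataFrame({
            "activity": spec.name,
            "sample_index": np.arange(n),
            "fx": vecs[:, 0], "fy": vecs[:, 1], "fz": vecs[:, 2]}))
    return LoadDataset(pd.concat(frames, ignore_index=True), units)


# -- the nine-activity default -------------------------------------------

#: dominant hip-contact direction in the pelvic frame (superior, slightly
#: anterior-lateral), around which the activity clusters are laid out
_GLOBAL_DIRECTION = unit(np.array([228.0, -207.0, 1803.0]))

#: (name, tilt deg from global direction, azimuth deg, spread deg, BW% range)
_DAILY_ACTIVITIES = [
    ("slow walking",       4.0,   0.0,  9.0,  (80.0, 243.0)),
    ("normal walking",     6.0,  40.0, 10.0,  (90.0, 233.0)),
    ("fast walking",       9.0,  80.0, 11.0, (100.0, 250.0)),
    ("walking upstairs",  14.0, 150.0, 10.0,  (90.0, 252.0)),
    ("walking downstairs", 16.0, 230.0, 12.0, (100.0, 260.0)),
    ("standing up",       30.0, 300.0, 12.0,  (50.0, 190.0)),
    ("sitting down",      34.0, 330.0, 12.0,  (40.0, 156.0)),
    ("standing",           8.0, 180.0,  6.0,  (30.0, 100.0)),
    ("knee bending",      28.0,  20.0, 10.0,  (40.0, 143.0)),
]


def daily_activity_specs() -> list[ClusterSpec]:
    """Nine activity clusters emulating a daily-activity collection.

    Walking, stairs and standing cluster within ~16 degrees of the global
    superior-medial load direction; chair rise/sit and knee bending sit
    28-34 degrees away, so load cases derived from walking and stairs alone
    cannot account for them.  Peak magnitudes echo published per-activity
    hip-contact peaks (about 100-260 BW% for locomotion, less for chair
    and standing activities).
    """
    b1, b2 = orthonormal_frame(_GLOBAL_DIRECTION)
    specs = []
    for name, tilt, azim, spread, mags in _DAILY_ACTIVITIES:
        center = _cap_point(_GLOBAL_DIRECTION, tilt, np.radians(azim), b1, b2)
        specs.append(ClusterSpec(name, center, spread, mags))
    return specs


def generate_daily_activity_dataset(seed: int = 0,
                                    samples_per_activity: int = 201) -> LoadDataset:
    """The default synthetic collection: 9 activities x 201 samples in BW%."""
    return generate_activity_dataset(daily_activity_specs(),
                                     samples_per_activity, seed)


# -- separated clusters with a known minimal cover -----------------------

def generate_separated_clusters(k: int, half_apex_deg: float,
                                min_separation_deg: float, jitter_deg: float,
                                seed: int = 0, n_per_cluster: int = 4,
                                magnitude_range: tuple[float, float] = (50.0, 250.0),
                                ) -> tuple[LoadDataset, int]:
    """k direction clusters whose exact minimal cover size is k.

    Construction: cluster points stay within ``jitter_deg`` of their
    center, with ``jitter_deg`` < half-apex angle, so each cluster fits in
    one cone; centers are at least ``min_separation_deg`` apart with
    ``min_separation_deg`` > 2*half_apex + 2*jitter, so points of different
    clusters are more than twice the half-apex angle apart and no single
    cone can touch two clusters.  Hence exactly k cones are necessary and
    sufficient.
    """
    if jitter_deg >= half_apex_deg:
        raise ValueError("jitter_deg must be strictly smaller than the half-apex angle")
    if min_separation_deg <= 2.0 * half_apex_deg + 2.0 * jitter_deg:
        raise ValueError("min_separation_deg must exceed 2*half_apex + 2*jitter")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    centers: list[np.ndarray] = []
    for _ in range(2000):
        v = unit(rng.normal(size=3))
        if all(np.degrees(np.arccos(np.clip(v @ c, -1, 1))) >= min_separation_deg
               for c in centers):
            centers.append(v)
        if len(centers) == k:
            break
    else:
        raise ValueError(
            f"could not place {k} centers at {min_separation_deg} deg separation")
    specs = [ClusterSpec(f"cluster_{i}", c, jitter_deg, magnitude_range,
                         n_per_cluster) for i, c in enumerate(centers)]
    dataset = generate_activity_dataset(specs, seed=int(rng.integers(2**31)))
    return dataset, k


# -- exact brute-force oracle --------------------------------------------

def exact_min_cover(units_in: np.ndarray, half_apex_deg: float,
                    candidate_axes: np.ndarray | None = None,
                    ) -> tuple[int, np.ndarray]:
    """Smallest number of half-apex cones (from a candidate axis set)
    covering all given unit vectors, by exhaustive set-cover search.

    Default candidates are the input vectors themselves plus all pairwise
    angular bisectors — exact relative to that candidate set; the
    separated-cluster fixtures are built so the restriction is harmless
    (every cluster fits in a cone around one of its own members).
    Instances above ``ORACLE_MAX_N`` vectors are refused.
    """
    units_arr = np.atleast_2d(np.asarray(units_in, dtype=float))
    n = units_arr.shape[0]
    if n == 0:
        raise ValueError("oracle needs at least one vector")
    if n > ORACLE_MAX_N:
        raise InstanceTooLargeError(
            f"exact oracle is limited to {ORACLE_MAX_N} vectors, got {n}")
    if candidate_axes is None:
        cands = [units_arr[i] for i in range(n)]
        for i in range(n):
            for j in range(i + 1, n):
                s = units_arr[i] + units_arr[j]
                norm = np.linalg.norm(s)
                if norm > 1e-9:
                    cands.append(s / norm)
        candidate_axes = np.array(cands)
    else:
        candidate_axes = np.atleast_2d(np.asarray(candidate_axes, dtype=float))

    cones = [Cone(unit(ax), half_apex_deg) for ax in candidate_axes]
    cover_sets: dict[frozenset, int] = {}
    for idx, cone in enumerate(cones):
        s = frozenset(np.flatnonzero(covers(cone, units_arr)).tolist())
        if s and s not in cover_sets:
            cover_sets[s] = idx
    # drop sets strictly contained in another candidate's set
    sets = list(cover_sets.items())
    maximal = [(s, i) for s, i in sets
               if not any(s < t for t, _ in sets)]
    universe = frozenset(range(n))
    if frozenset().union(*[s for s, _ in maximal]) != universe:
        raise ValueError("candidate axes cannot cover all input vectors")

    best: list[int] | None = None

    def search(uncovered: frozenset, chosen: list[int]) -> None:
        nonlocal best
        if best is not None and len(chosen) >= len(best):
            return
        if not uncovered:
            best = list(chosen)
            return
        # branch on the hardest element: fewest candidate sets contain it
        elem = min(uncovered,
                   key=lambda e: sum(1 for s, _ in maximal if e in s))
        for s, idx in maximal:
            if elem in s:
                search(uncovered - s, chosen + [idx])

    search(universe, [])
    assert best is not None
    return len(best), candidate_axes[np.array(best, dtype=int)]
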