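"""The two-phase heuristic that turns a cloud of same-origin force vectors
into a small set of *major loads*.

Phase one finds cone axes.  Working on unit directions only, it repeats:

1. take the arithmetic mean of the remaining unit vectors (renormalised);
2. pick the *edge vector* — the remaining direction farthest from that mean;
3. restrict attention to the local set within twice the half-apex angle of
   the edge (no cone containing the edge can reach farther);
4. weight each local direction by a penalty that favours points close to
   the edge:  v = v_min + (1 - v_min) (1 - d_norm)^p,  with d_norm the
   chord distance to the edge normalised by the largest local distance;
5. sweep a candidate cone axis over a (tilt x azimuth) grid around the
   edge — every candidate still covers the edge — and keep the axis whose
   covered set has the largest penalty sum;
6. remove everything the chosen cone covers and loop until nothing is left.

Phase two assigns each cone the maximum magnitude among the samples it
covers, so every recorded load is enveloped both in direction (inside some
cone) and in magnitude (not larger than its cone's representative).

The grid is anchored to the data (azimuth zero lies in the plane spanned
by the edge and the current mean), which makes the whole procedure
equivariant under rotation of the input and deterministic: ties are broken
by smaller tilt, then smaller azimuth, then lower sample index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .exceptions import CoverageViolationError, DegenerateVectorError, EmptyDatasetError
from .geometry import Cone, angle_between, covers, orthonormal_frame, unit
from .load_io import LoadDataset

__all__ = [
    "CoverConfig",
    "MajorLoad",
    "penalty",
    "mean_direction",
    "select_edge_vector",
    "local_candidates",
    "search_best_axis",
    "compute_major_directions",
    "assign_magnitudes",
    "cover",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoverConfig:
    """User parameters of the covering heuristic.

    half_apex_deg
        Angular radius of each covering cone, degrees, in (0, 90).
        Default 10: small enough that one static FE load case per cone is
        representative, large enough to keep the number of cases low.
    penalty_exponent
        Exponent p >= 0 of the penalty function; larger p concentrates the
        weight near the edge vector, which empirically lowers the cone
        count.  Default 6.
    v_min
        Floor of the penalty in (0, 1]: even the farthest local direction
        keeps this weight.  Default 0.1.
    increment_deg
        Step of the tilt/azimuth search grid, degrees.  Default 1.
    mean_degeneracy_tol
        Norm below which the mean of unit vectors counts as degenerate
        (antipodally balanced input).  Default 1e-9.
    """

    half_apex_deg: float = 10.0
    penalty_exponent: float = 6.0
    v_min: float = 0.1
    increment_deg: float = 1.0
    mean_degeneracy_tol: float = 1e-9

    def __post_init__(self) -> None:
        if not 0.0 < self.half_apex_deg < 90.0:
            raise ValueError("half_apex_deg must lie strictly inside (0, 90)")
        if not 0.0 < self.increment_deg <= self.half_apex_deg:
            raise ValueError("increment_deg must lie in (0, half_apex_deg]")
        if not 0.0 < self.v_min <= 1.0:
            raise ValueError("v_min must lie in (0, 1]")
        if self.penalty_exponent < 0.0:
            raise ValueError("penalty_exponent must be >= 0")
        if self.mean_degeneracy_tol <= 0.0:
            raise ValueError("mean_degeneracy_tol must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "CoverConfig":
        """Load a flat key-value config (JSON or YAML) with these fields."""
        import json

        import yaml

        text = Path(path).read_text()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a flat mapping")
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class MajorLoad:
    """A covering cone with its enveloping magnitude.

    ``covered_indices`` are positional sample indices of the dataset the
    cone covers; ``magnitude`` is the maximum resultant magnitude among
    them (in the dataset's units); ``order`` is the discovery rank.
    """

    cone: Cone
    magnitude: float
    covered_indices: tuple[int, ...]
    order: int

    def __post_init__(self) -> None:
        if len(self.covered_indices) == 0:
            raise ValueError("a major load must cover at least one sample")
        if self.magnitude < 0:
            raise ValueError("magnitude must be non-negative")

    @property
    def force_vector(self) -> np.ndarray:
        """Axis scaled to the enveloping magnitude: the static load case."""
        return self.cone.axis * self.magnitude


def penalty(d_norm, v_min: float = 0.1, p: float = 6.0):
    """Penalty weight v = v_min + (1 - v_min) (1 - d_norm)^p.

    ``d_norm`` in [0, 1] is the normalised distance from the edge vector;
    v equals 1 at the edge itself and v_min at the farthest local point.
    Vectorised over ``d_norm``.
    """
    d = np.asarray(d_norm, dtype=float)
    if np.any((d < 0.0) | (d > 1.0)):
        raise ValueError("d_norm must lie in [0, 1]")
    out = v_min + (1.0 - v_min) * (1.0 - d) ** p
    return float(out) if out.ndim == 0 else out


def mean_direction(units: np.ndarray, tol: float = 1e-9) -> np.ndarray | None:
    """Renormalised arithmetic mean of unit vectors; None when degenerate.

    Antipodally balanced inputs cancel: a mean with norm below ``tol``
    carries no direction and is reported as degenerate (None).
    """
    units = np.atleast_2d(np.asarray(units, dtype=float))
    if units.shape[0] == 0:
        raise EmptyDatasetError("mean direction of zero vectors is undefined")
    m = units.mean(axis=0)
    norm = np.linalg.norm(m)
    if norm < tol:
        return None
    return m / norm


def select_edge_vector(units: np.ndarray, mean: np.ndarray | None,
                       magnitudes: np.ndarray | None = None) -> int:
    """Positional index of the edge vector.

    The edge is the unit vector with the largest Euclidean (chord) distance
    from the mean direction; ties break to the lowest index.  With a
    degenerate mean (None) the fallback is the direction of the sample with
    the largest original magnitude, which requires ``magnitudes``.
    """
    units = np.atleast_2d(np.asarray(units, dtype=float))
    if units.shape[0] == 0:
        raise EmptyDatasetError("cannot select an edge vector from zero vectors")
    if mean is None:
        if magnitudes is None:
            raise DegenerateVectorError(
                "mean direction is degenerate and no magnitudes were supplied "
                "for the largest-magnitude fallback")
        return int(np.argmax(magnitudes))
    d = np.linalg.norm(units - np.asarray(mean, dtype=float), axis=1)
    return int(np.argmax(d))


def local_candidates(units: np.ndarray, edge: np.ndarray,
                     half_apex_deg: float) -> np.ndarray:
    """Indices of unit vectors within 2*theta of the edge vector.

    Any cone whose axis stays within theta of the edge can only cover
    directions within 2*theta of it (triangle inequality on the sphere),
    so restricting the search to this local set loses nothing.
    """
    units = np.atleast_2d(np.asarray(units, dtype=float))
    ang = angle_between(units, np.asarray(edge, dtype=float))
    return np.flatnonzero(ang <= 2.0 * half_apex_deg)


def _candidate_axes(edge: np.ndarray, config: CoverConfig,
                    frame_ref: np.ndarray | None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Grid of candidate axes around the edge, with their (tilt, azimuth).

    Tilt runs 0, step, ..., half_apex (inclusive); azimuth runs a full turn
    at the same step.  Tilt 0 contributes a single candidate (the edge).
    Candidates are ordered by (tilt, azimuth), so a first-argmax implements
    the tie-break.
    """
    step = config.increment_deg
    theta = config.half_apex_deg
    n_tilt = int(np.floor(theta / step + 1e-9))
    tilts = step * np.arange(1, n_tilt + 1)
    if tilts.size == 0 or not np.isclose(tilts[-1], theta):
        tilts = np.append(tilts, theta)  # always include the full tilt
    azimuths = step * np.arange(int(np.ceil(360.0 / step)))
    azimuths = azimuths[azimuths < 360.0]
    b1, b2 = orthonormal_frame(edge, frame_ref)
    t_grid, a_grid = np.meshgrid(tilts, azimuths, indexing="ij")
    t = np.concatenate(([0.0], t_grid.ravel()))
    a = np.concatenate(([0.0], a_grid.ravel()))
    tr, ar = np.radians(t), np.radians(a)
    axes = (np.cos(tr)[:, None] * edge[None, :]
            + np.sin(tr)[:, None] * (np.cos(ar)[:, None] * b1[None, :]
                                     + np.sin(ar)[:, None] * b2[None, :]))
    return axes, t, a


def search_best_axis(edge: np.ndarray, local_units: np.ndarray,
                     d_norm: np.ndarray, config: CoverConfig,
                     frame_ref: np.ndarray | None = None) -> Cone:
    """Best-scoring cone on the tilt/azimuth grid around the edge vector.

    Each candidate axis is scored by the sum of penalty weights of the
    local unit vectors it covers; the maximal-score candidate wins, with
    ties broken by smaller tilt, then smaller azimuth.  Every candidate
    covers the edge by construction (tilt <= half-apex angle).
    """
    local_units = np.atleast_2d(np.asarray(local_units, dtype=float))
    if local_units.shape[0] == 0:
        raise EmptyDatasetError("search requires a non-empty local set")
    weights = penalty(d_norm, config.v_min, config.penalty_exponent)
    axes, tilts, azimuths = _candidate_axes(np.asarray(edge, dtype=float),
                                            config, frame_ref)
    # same boundary slack as geometry.covers: candidates at full tilt hold
    # the edge vector exactly on their boundary, and an exact comparison
    # would let 1-ulp noise decide its membership per candidate
    cos_theta = np.cos(np.radians(config.half_apex_deg)) - 1e-12
    covered = local_units @ axes.T >= cos_theta  # (n_local, n_candidates)
    scores = np.atleast_1d(weights) @ covered
    best = int(np.argmax(scores))  # first max == (tilt, azimuth) tie-break
    return Cone(unit(axes[best]), config.half_apex_deg)


def compute_major_directions(dataset: LoadDataset,
                             config: CoverConfig | None = None) -> list[Cone]:
    """Phase one: cone axes covering every nonzero direction of the dataset.

    Returns cones in discovery order.  Terminates in at most n iterations
    because each chosen cone covers at least the edge vector of its round.
    """
    config = config or CoverConfig()
    nonzero = dataset.nonzero_indices()
    if nonzero.size == 0:
        raise EmptyDatasetError("dataset has no nonzero force vectors to cover")
    all_units = unit(dataset.vectors()[nonzero])
    magnitudes = dataset.magnitudes()[nonzero]

    remaining = np.arange(all_units.shape[0])
    cones: list[Cone] = []
    for _ in range(remaining.size):
        units_r = all_units[remaining]
        mean = mean_direction(units_r, config.mean_degeneracy_tol)
        edge_pos = select_edge_vector(units_r, mean, magnitudes[remaining])
        edge = units_r[edge_pos]
        local_pos = local_candidates(units_r, edge, config.half_apex_deg)
        local_units = units_r[local_pos]
        dist = np.linalg.norm(local_units - edge, axis=1)
        d_max = dist.max()
        d_norm = dist / d_max if d_max > 0.0 else np.zeros_like(dist)
        cone = search_best_axis(edge, local_units, d_norm, config, frame_ref=mean)
        covered_mask = covers(cone, units_r)
        if not covered_mask.any():  # numerically impossible; keep the loop safe
            cone = Cone(edge, config.half_apex_deg)
            covered_mask = covers(cone, units_r)
        cones.append(cone)
        remaining = remaining[~covered_mask]
        if remaining.size == 0:
            break
    if remaining.size:
        raise CoverageViolationError(
            f"{remaining.size} direction(s) left uncovered after the iteration bound")
    logger.info("covered %d directions with %d cones (theta=%g deg, p=%g)",
                all_units.shape[0], len(cones), config.half_apex_deg,
                config.penalty_exponent)
    return cones


def assign_magnitudes(cones: Sequence[Cone], dataset: LoadDataset) -> list[MajorLoad]:
    """Phase two: give each cone the maximum magnitude among the samples it
    covers.

    Every sample is attributed to *every* cone that covers it, so the
    envelope property (no covered sample exceeds its cone's magnitude)
    holds unconditionally.  Starting all representatives at the global
    maximum and shrinking each until it meets the largest covered sample
    reaches exactly this fixed point, so the fixed point is computed
    directly.
    """
    vectors = dataset.vectors()
    magnitudes = dataset.magnitudes()
    nonzero = dataset.nonzero_indices()
    covered_any = np.zeros(len(dataset), dtype=bool)
    loads: list[MajorLoad] = []
    for order, cone in enumerate(cones, start=1):
        mask = np.zeros(len(dataset), dtype=bool)
        mask[nonzero] = covers(cone, vectors[nonzero])
        if not mask.any():
            raise CoverageViolationError(f"cone {order} covers no sample")
        covered_any |= mask
        idx = tuple(int(i) for i in np.flatnonzero(mask))
        loads.append(MajorLoad(cone, float(magnitudes[mask].max()), idx, order))
    missing = np.flatnonzero(~covered_any[nonzero])
    if missing.size:
        raise CoverageViolationError(
            f"{missing.size} nonzero sample(s) are covered by no cone")
    return loads


def cover(dataset: LoadDataset, config: CoverConfig | None = None) -> list[MajorLoad]:
    """Run both phases: major-load directions, then enveloping magnitudes.

    Deterministic for a given dataset and config.
    """
    config = config or CoverConfig()
    cones = compute_major_directions(dataset, config)
    return assign_magnitudes(cones, dataset)
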