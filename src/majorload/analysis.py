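"""Coverage reporting, parameter sweeps, and "step zero" prefilters.

These tools answer the question the covering heuristic is built around:
given a set of candidate load cases (cone axes), which recorded loads do
they actually account for?  Literature practice — taking the peak loads of
walking and stair climbing as the FE load cases — can be expressed as a
small axis set and audited against a full daily-activity dataset here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .covering import CoverConfig, cover
from .geometry import Cone, covers
from .load_io import LoadDataset

__all__ = [
    "CoverageReport",
    "coverage_report",
    "parameter_sweep",
    "prefilter_by_magnitude",
    "remove_precovered",
    "plot_coverage",
]


@dataclass(frozen=True)
class CoverageReport:
    """Coverage of a dataset's nonzero samples by a set of cones.

    ``uncovered_indices`` are positional dataset indices;
    ``max_uncovered_magnitude`` is None when everything is covered.
    """

    n_total: int
    n_covered: int
    uncovered_indices: tuple[int, ...]
    max_uncovered_magnitude: float | None

    @property
    def fraction(self) -> float:
        return self.n_covered / self.n_total if self.n_total else 0.0

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_covered": self.n_covered,
            "fraction": self.fraction,
            "uncovered_indices": list(self.uncovered_indices),
            "max_uncovered_magnitude": self.max_uncovered_magnitude,
        }

    def summary(self) -> str:
        lines = [f"covered {self.n_covered} / {self.n_total} nonzero samples "
                 f"({100 * self.fraction:.1f}%)"]
        if self.uncovered_indices:
            lines.append(f"largest uncovered magnitude: "
                         f"{self.max_uncovered_magnitude:.6g}")
        else:
            lines.append("full coverage: no uncovered samples")
        return "\n".join(lines)


def coverage_report(axes: Sequence[Cone], dataset: LoadDataset) -> CoverageReport:
    """Test every nonzero sample of the dataset against every cone."""
    nonzero = dataset.nonzero_indices()
    vectors = dataset.vectors()[nonzero]
    magnitudes = dataset.magnitudes()[nonzero]
    covered = np.zeros(nonzero.size, dtype=bool)
    for cone in axes:
        covered |= covers(cone, vectors)
    uncovered = nonzero[~covered]
    max_unc = float(magnitudes[~covered].max()) if uncovered.size else None
    return CoverageReport(
        n_total=int(nonzero.size),
        n_covered=int(covered.sum()),
        uncovered_indices=tuple(int(i) for i in uncovered),
        max_uncovered_magnitude=max_unc,
    )


def parameter_sweep(dataset: LoadDataset, half_apex_list: Sequence[float],
                    exponent_list: Sequence[float],
                    config: CoverConfig | None = None) -> pd.DataFrame:
    """Major-load count per (half-apex angle, penalty exponent) combination.

    Runs the full heuristic for every grid cell; other parameters are taken
    from ``config``.  No monotonicity in either parameter is claimed — the
    heuristic is not provably monotone — so the result is reported as data,
    one row per combination, suitable for plotting.
    """
    if len(half_apex_list) == 0 or len(exponent_list) == 0:
        raise ValueError("parameter lists must be non-empty")
    base = config or CoverConfig()
    records = []
    for theta in half_apex_list:
        for p in exponent_list:
            cfg = CoverConfig(half_apex_deg=float(theta), penalty_exponent=float(p),
                              v_min=base.v_min,
                              increment_deg=min(base.increment_deg, float(theta)),
                              mean_degeneracy_tol=base.mean_degeneracy_tol)
            records.append({"half_apex_deg": float(theta),
                            "penalty_exponent": float(p),
                            "major_load_count": len(cover(dataset, cfg))})
    return pd.DataFrame.from_records(records)


def prefilter_by_magnitude(dataset: LoadDataset, threshold: float) -> LoadDataset:
    """Step zero: drop samples whose magnitude is not above the threshold.

    Strictly ``magnitude > threshold`` is kept, so boundary samples at
    exactly the threshold are removed; order is preserved.  Idempotent.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    keep = np.flatnonzero(dataset.magnitudes() > threshold)
    return dataset.subset(keep)


def remove_precovered(dataset: LoadDataset, given: Sequence[Cone],
                      magnitudes: Sequence[float] | None = None) -> LoadDataset:
    """Step zero: drop samples already accounted for by given load cases.

    A previously committed load case (stumbling is the classic example —
    enormous magnitude, known direction) removes every sample inside its
    cone.  When per-cone ``magnitudes`` are supplied, a sample is removed
    only if it is directionally covered AND its magnitude does not exceed
    the cone's; without magnitudes, removal is purely directional.
    Idempotent; samples matching no cone are untouched.
    """
    if magnitudes is not None and len(magnitudes) != len(given):
        raise ValueError("magnitudes, when given, must match the cones one-to-one")
    vectors = dataset.vectors()
    mags = dataset.magnitudes()
    nonzero = mags > 0.0
    remove = np.zeros(len(dataset), dtype=bool)
    for k, cone in enumerate(given):
        inside = np.zeros(len(dataset), dtype=bool)
        inside[nonzero] = covers(cone, vectors[nonzero])
        if magnitudes is not None:
            inside &= mags <= float(magnitudes[k])
        remove |= inside
    return dataset.subset(np.flatnonzero(~remove))


def plot_coverage(axes: Sequence[Cone], dataset: LoadDataset, path=None):
    """Scatter the unit-sphere terminal points, coloured covered/uncovered.

    Optional helper (requires matplotlib).  Returns the figure; saves to
    ``path`` when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .geometry import unit as _unit

    report = coverage_report(axes, dataset)
    nonzero = dataset.nonzero_indices()
    units = _unit(dataset.vectors()[nonzero])
    uncovered = np.isin(nonzero, np.asarray(report.uncovered_indices, dtype=int))
    fig = plt.figure(figsize=(6, 6))
    ax3 = fig.add_subplot(projection="3d")
    ax3.scatter(*units[~uncovered].T, s=4, c="tab:green", label="covered")
    if uncovered.any():
        ax3.scatter(*units[uncovered].T, s=6, c="tab:red", label="uncovered")
    for cone in axes:
        ax3.plot(*np.column_stack(([0, 0, 0], cone.axis * 1.1)), c="k", lw=1)
    ax3.set_box_aspect((1, 1, 1))
    ax3.legend(loc="upper left")
    ax3.set_title(f"coverage {100 * report.fraction:.1f}%")
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
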