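"""Multi-position sampling plans, well summaries, CV and subsampling stability.

A well is imaged at a serpentine grid of positions confined to the central
area of the culture (meniscus effects distort the periphery).  Positions are
summarised as mean ± SEM with the coefficient of variation (CV = 100·SD/mean)
for comparing variability between methods, and a seeded subsampling analysis
quantifies how stable those statistics are against the number of positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .heights import ASLMeasurement

__all__ = [
    "SamplingPlan",
    "WellSummary",
    "serpentine_positions",
    "summarize_well",
    "subsample_stability",
    "timecourse",
]


@dataclass(frozen=True)
class SamplingPlan:
    """An ordered serpentine grid of lateral positions.

    ``order`` is the visiting sequence of (row, col) grid indices;
    ``coords`` the matching fractional (x, y) stage coordinates inside the
    unit field, confined to the central ``central_fraction`` of each axis.
    """

    rows: int
    cols: int
    order: tuple[tuple[int, int], ...]
    coords: tuple[tuple[float, float], ...]
    central_fraction: float

    def __post_init__(self) -> None:
        if len(self.order) != self.rows * self.cols:
            raise ValueError("position count must equal rows*cols")
        if len(set(self.order)) != len(self.order):
            raise ValueError("positions must be unique")

    @property
    def n_positions(self) -> int:
        return len(self.order)


def serpentine_positions(rows: int, cols: int, central_fraction: float = 0.6) -> SamplingPlan:
    """Row-major serpentine traversal of a rows × cols grid.

    Even rows run left→right, odd rows right→left, so consecutive positions
    are always adjacent (minimal stage travel).  Grid points are evenly
    spaced inside the central ``central_fraction`` of the unit field.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    if not 0 < central_fraction <= 1:
        raise ValueError("central_fraction must be in (0, 1]")
    lo = 0.5 - central_fraction / 2.0

    def axis(i: int, n: int) -> float:
        return lo + central_fraction * ((i + 0.5) / n)

    order: list[tuple[int, int]] = []
    for r in range(rows):
        cs = range(cols) if r % 2 == 0 else range(cols - 1, -1, -1)
        order.extend((r, c) for c in cs)
    coords = tuple((axis(c, cols), axis(r, rows)) for r, c in order)
    return SamplingPlan(rows=rows, cols=cols, order=tuple(order), coords=coords,
                        central_fraction=central_fraction)


@dataclass(frozen=True)
class WellSummary:
    """Per-well summary of unflagged position heights (µm; CV in percent)."""

    well_id: str
    time_min: float
    method: str
    n_positions: int
    n_flagged: int
    mean: float
    sd: float
    sem: float
    cv: float


def _usable_heights(measurements: list[ASLMeasurement]) -> np.ndarray:
    return np.array([m.asl_height for m in measurements if m.usable])


def summarize_well(measurements: list[ASLMeasurement]) -> WellSummary:
    """Mean/SD/SEM/CV over the usable positions of one well.

    Positions carrying excluding QC flags are dropped (their count is
    reported); clamped-to-zero positions stay in.  At least two usable
    positions are required for a dispersion estimate.
    """
    if not measurements:
        raise InsufficientDataError("no measurements")
    heights = _usable_heights(measurements)
    if heights.size < 2:
        raise InsufficientDataError(
            f"only {heights.size} usable position(s); need >= 2"
        )
    mean = float(heights.mean())
    sd = float(heights.std(ddof=1))
    m0 = measurements[0]
    return WellSummary(
        well_id=m0.well_id,
        time_min=m0.time_min,
        method=m0.method,
        n_positions=int(heights.size),
        n_flagged=len(measurements) - int(heights.size),
        mean=mean,
        sd=sd,
        sem=sd / float(np.sqrt(heights.size)),
        cv=100.0 * sd / mean if mean > 0 else float("nan"),
    )


def subsample_stability(
    measurements: list[ASLMeasurement],
    sizes: list[int],
    n_reps: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Stability of mean/SD/CV against the number of sampled positions.

    For each requested size, ``n_reps`` random without-replacement subsets of
    the usable positions are summarised; the table reports the mean of the
    subset means, SDs and CVs per size.  Seeded and reproducible.
    """
    heights = _usable_heights(measurements)
    if any(s < 2 for s in sizes):
        raise ValueError("subsample sizes must be >= 2")
    if any(s > heights.size for s in sizes):
        raise ValueError(
            f"subsample size exceeds the {heights.size} usable positions"
        )
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        means = np.empty(n_reps)
        sds = np.empty(n_reps)
        for r in range(n_reps):
            sub = rng.choice(heights, size=size, replace=False)
            means[r] = sub.mean()
            sds[r] = sub.std(ddof=1)
        cvs = 100.0 * sds / means
        rows.append(
            {
                "size": size,
                "n_reps": n_reps,
                "mean_of_means": float(means.mean()),
                "mean_sd": float(sds.mean()),
                "mean_cv": float(cvs.mean()),
            }
        )
    return pd.DataFrame(rows)


def timecourse(summaries: list[WellSummary]) -> pd.DataFrame:
    """Time-ordered mean ± SEM trace for one well and method.

    Input summaries must share well_id and method and have unique time
    points; output rows are sorted by time.
    """
    if not summaries:
        raise ValueError("no summaries")
    wells = {s.well_id for s in summaries}
    methods = {s.method for s in summaries}
    if len(wells) > 1 or len(methods) > 1:
        raise ValueError(f"mixed wells {wells} or methods {methods}")
    times = [s.time_min for s in summaries]
    if len(set(times)) != len(times):
        raise ValueError("duplicate time points for the same well")
    df = pd.DataFrame(
        {
            "well_id": [s.well_id for s in summaries],
            "method": [s.method for s in summaries],
            "time_min": times,
            "mean": [s.mean for s in summaries],
            "sem": [s.sem for s in summaries],
            "sd": [s.sd for s in summaries],
            "cv": [s.cv for s in summaries],
            "n_positions": [s.n_positions for s in summaries],
        }
    )
    return df.sort_values("time_min", ignore_index=True)
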