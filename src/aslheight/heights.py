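"""Per-position ASL height by the reflection and fluorescence methods.

Reflection method: ASL height = (z3 − z2), the separation of the
transwell→cell and ASL→air reflection peaks, minus the cell-layer thickness
read from the calcein-AM half-maximum band.  Fluorescence method: ASL height
= the width of the rhodamine-dextran half-maximum band.  Every stage failure
is converted into a QC flag on the measurement — never a silent NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import profiles
from .errors import (
    BoundaryFailureError,
    FitFailureError,
    InsufficientPeaksError,
    MethodUnavailableError,
)
from .phantom import SyntheticScan
from .profiles import (
    DEFAULT_MIN_PROMINENCE,
    DEFAULT_PROFILE_WIDTH,
    DEFAULT_R2_THRESHOLD,
    HalfMaxBounds,
    ReflectionInterfaces,
)

__all__ = [
    "ChannelStack",
    "ASLMeasurement",
    "EXCLUDING_FLAGS",
    "cell_height",
    "asl_height_reflection",
    "asl_height_fluorescence",
    "measure_position",
    "measure_well",
]

#: QC flags that exclude a position from well summaries.  ``negative_clamped``
#: is deliberately NOT here: clamped zeros stay in the mean so that noise at
#: low ASL does not bias well means upward.
EXCLUDING_FLAGS = frozenset(
    {"insufficient_peaks", "fit_failure", "fit_quality", "boundary_failure"}
)


@dataclass
class ChannelStack:
    """A loaded multi-channel XZ stack: role-keyed (n_x, n_z) images."""

    channels: dict[str, np.ndarray]
    z_spacing: float

    def __post_init__(self) -> None:
        if self.z_spacing <= 0:
            raise ValueError("z_spacing must be > 0")
        shapes = {im.shape for im in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")


@dataclass(frozen=True)
class ASLMeasurement:
    """One position's ASL height with its QC provenance."""

    well_id: str
    position_index: int
    time_min: float
    method: str                     # "reflection" | "fluorescence"
    asl_height: float               # µm; NaN when the position failed QC
    cell_height: float = float("nan")   # µm; reflection method only
    z2_calcein_offset: float = float("nan")  # µm; QC metric, z2 − calcein lower bound
    qc_flags: frozenset[str] = field(default_factory=frozenset)

    @property
    def usable(self) -> bool:
        return math.isfinite(self.asl_height) and not (self.qc_flags & EXCLUDING_FLAGS)


def cell_height(calcein_bounds: HalfMaxBounds) -> float:
    """Cell-layer thickness: width of the calcein half-maximum band (µm)."""
    return calcein_bounds.width


def asl_height_reflection(
    interfaces: ReflectionInterfaces,
    calcein_bounds: HalfMaxBounds,
    *,
    clamp: bool = True,
) -> float:
    """Reflection-method ASL height: (z3 − z2) − cell-layer thickness (µm).

    Noise can drive the difference slightly negative; by default it is
    clamped at 0 (callers that need to flag the clamp pass ``clamp=False``
    and handle the sign themselves).
    """
    raw = (interfaces.z3_asl_air - interfaces.z2_transwell_cell) - cell_height(calcein_bounds)
    return max(raw, 0.0) if clamp else raw


def asl_height_fluorescence(rhodamine_bounds: HalfMaxBounds) -> float:
    """Fluorescence-method ASL height: width of the rhodamine band (µm)."""
    return rhodamine_bounds.width


def measure_position(
    scan: SyntheticScan | ChannelStack,
    x_index: int | None = None,
    method: str = "reflection",
    *,
    width: int = DEFAULT_PROFILE_WIDTH,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    well_id: str = "well",
    position_index: int = 0,
    time_min: float = 0.0,
) -> ASLMeasurement:
    """Run the full per-position chain: profile → peaks/bounds → height.

    ``x_index`` defaults to the centre of the lateral field.  A missing
    channel required by ``method`` raises :class:`MethodUnavailableError`
    (a configuration problem); any downstream stage failure instead returns
    a flagged measurement with NaN height so a single bad position cannot
    abort a well.
    """
    if method not in ("reflection", "fluorescence"):
        raise ValueError(f"unknown method {method!r}")
    channels, z_spacing = scan.channels, scan.z_spacing
    needed = {"reflection": ("reflection", "calcein"), "fluorescence": ("rhodamine",)}[method]
    for ch in needed:
        if ch not in channels or channels[ch] is None:
            raise MethodUnavailableError(
                f"{method} method requires the {ch!r} channel, which is missing"
            )
    n_x = channels[needed[0]].shape[0]
    if x_index is None:
        x_index = n_x // 2

    flags: set[str] = set()
    asl = float("nan")
    cell = float("nan")
    z2_offset = float("nan")

    def _profile(ch: str) -> profiles.ZProfile:
        return profiles.extract_profile(
            channels[ch], x_index, width, z_spacing=z_spacing, channel=ch
        )

    if method == "reflection":
        try:
            peaks = profiles.detect_reflection_peaks(_profile("reflection"), min_prominence)
            interfaces = profiles.classify_interfaces(peaks)
        except InsufficientPeaksError:
            flags.add("insufficient_peaks")
            interfaces = None
        except FitFailureError:
            flags.add("fit_failure")
            interfaces = None
        if interfaces is not None and interfaces.min_r_squared < r2_threshold:
            flags.add("fit_quality")
        try:
            bounds = profiles.half_max_bounds(_profile("calcein"))
        except BoundaryFailureError:
            flags.add("boundary_failure")
            bounds = None
        if interfaces is not None and bounds is not None:
            cell = cell_height(bounds)
            z2_offset = interfaces.z2_transwell_cell - bounds.z_lower
            raw = asl_height_reflection(interfaces, bounds, clamp=False)
            if raw < 0:
                flags.add("negative_clamped")
                raw = 0.0
            asl = raw
    else:
        try:
            bounds = profiles.half_max_bounds(_profile("rhodamine"))
            asl = asl_height_fluorescence(bounds)
        except BoundaryFailureError:
            flags.add("boundary_failure")

    return ASLMeasurement(
        well_id=well_id,
        position_index=position_index,
        time_min=time_min,
        method=method,
        asl_height=asl,
        cell_height=cell,
        z2_calcein_offset=z2_offset,
        qc_flags=frozenset(flags),
    )


def measure_well(
    scans: list[SyntheticScan | ChannelStack],
    method: str = "reflection",
    *,
    well_id: str = "well",
    time_min: float = 0.0,
    **kwargs,
) -> list[ASLMeasurement]:
    """Measure every position (scan) of one well with shared settings."""
    return [
        measure_position(
            scan,
            method=method,
            well_id=well_id,
            position_index=i,
            time_min=time_min,
            **kwargs,
        )
        for i, scan in enumerate(scans)
    ]
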