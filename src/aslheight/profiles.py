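"""Axial line profiles: extraction, reflection-peak fitting, half-max edges.

An XZ scan is reduced to one intensity-vs-depth trace per lateral position by
averaging a few neighbouring columns.  Reflection peaks are located with a
prominence-thresholded candidate search and refined to sub-pixel depth by
least-squares Gaussian fits; fluorescence bands (cell layer, ASL) are
delimited by the depths where the profile crosses half of its plateau level,
located by linear interpolation between samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .errors import BoundaryFailureError, FitFailureError, InsufficientPeaksError

__all__ = [
    "ZProfile",
    "PeakFit",
    "HalfMaxBounds",
    "ReflectionInterfaces",
    "extract_profile",
    "fit_gaussian_peak",
    "detect_reflection_peaks",
    "classify_interfaces",
    "half_max_bounds",
]

#: Default lateral averaging window (columns) for profile extraction.
DEFAULT_PROFILE_WIDTH = 5
#: Default half-width (µm) of the Gaussian fit window around a candidate peak.
DEFAULT_FIT_HALFWIDTH = 2.0
#: Default peak prominence threshold, as a fraction of the profile maximum.
DEFAULT_MIN_PROMINENCE = 0.1
#: Fits with r² below this are flagged by QC downstream.
DEFAULT_R2_THRESHOLD = 0.9


@dataclass(frozen=True)
class ZProfile:
    """An axial intensity trace from one lateral position of an XZ scan."""

    intensities: np.ndarray
    z_spacing: float
    channel: str = "reflection"
    x_position: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "intensities", np.asarray(self.intensities, dtype=float))
        if self.intensities.ndim != 1 or self.intensities.size < 8:
            raise ValueError("profile must be 1-D with at least 8 samples")
        if self.z_spacing <= 0:
            raise ValueError("z_spacing must be > 0")

    @property
    def z(self) -> np.ndarray:
        """Depth grid in µm."""
        return np.arange(self.intensities.size) * self.z_spacing

    @property
    def depth(self) -> float:
        return (self.intensities.size - 1) * self.z_spacing


@dataclass(frozen=True)
class PeakFit:
    """A Gaussian + constant-baseline fit to one reflection peak."""

    center: float          # µm
    sigma: float           # µm
    amplitude: float
    baseline: float
    r_squared: float
    prominence: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")


@dataclass(frozen=True)
class HalfMaxBounds:
    """Half-maximum boundaries of a fluorescence band, in µm."""

    z_lower: float
    z_upper: float
    reference_level: float

    def __post_init__(self) -> None:
        if self.z_upper < self.z_lower:
            raise ValueError("z_upper must be >= z_lower")

    @property
    def width(self) -> float:
        return self.z_upper - self.z_lower


@dataclass(frozen=True)
class ReflectionInterfaces:
    """The three classified reflection interfaces of one profile."""

    z1_medium_transwell: float
    z2_transwell_cell: float
    z3_asl_air: float
    peaks: tuple[PeakFit, PeakFit, PeakFit] = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not (self.z1_medium_transwell < self.z2_transwell_cell < self.z3_asl_air):
            raise ValueError("interfaces must satisfy z1 < z2 < z3")

    @property
    def min_r_squared(self) -> float:
        if not self.peaks:
            return float("nan")
        return min(p.r_squared for p in self.peaks)


def extract_profile(
    image: np.ndarray,
    x_index: int,
    width: int = DEFAULT_PROFILE_WIDTH,
    *,
    z_spacing: float,
    channel: str = "reflection",
) -> ZProfile:
    """Average ``width`` columns centred on ``x_index`` into one Z profile.

    ``image`` has shape (n_x, n_z).  The window must lie entirely inside the
    image; use width 1 for an exact column copy.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D (x, z)")
    if width < 1:
        raise ValueError("width must be >= 1")
    lo = x_index - (width - 1) // 2
    hi = lo + width
    if lo < 0 or hi > image.shape[0]:
        raise IndexError(
            f"window [{lo}, {hi}) outside image with {image.shape[0]} columns"
        )
    trace = image[lo:hi].mean(axis=0)
    return ZProfile(trace, z_spacing=z_spacing, channel=channel, x_position=x_index)


def _gaussian(z: np.ndarray, amp: float, mu: float, sig: float, base: float) -> np.ndarray:
    return amp * np.exp(-((z - mu) ** 2) / (2.0 * sig**2)) + base


def fit_gaussian_peak(
    profile: ZProfile,
    window_center: float,
    window_halfwidth: float = DEFAULT_FIT_HALFWIDTH,
    *,
    prominence: float = 0.0,
) -> PeakFit:
    """Least-squares Gaussian + constant baseline fit inside a depth window.

    Returns the sub-pixel peak position with the fit's r²; quality gating
    (e.g. r² < 0.9) is left to the caller's QC policy.

    Raises
    ------
    FitFailureError
        If the window holds fewer than 5 samples, contains no local maximum,
        or the optimiser does not converge.
    """
    z = profile.z
    y = profile.intensities
    mask = np.abs(z - window_center) <= window_halfwidth
    if mask.sum() < 5:
        raise FitFailureError(
            f"fit window ±{window_halfwidth} µm around {window_center} µm has "
            f"{int(mask.sum())} samples (< 5)"
        )
    zw, yw = z[mask], y[mask]
    # normalise intensities so optimiser tolerances are scale-free: the fit
    # (and hence the centre) is then invariant to global intensity scaling
    y_scale = float(np.max(np.abs(yw)))
    if y_scale <= 0:
        raise FitFailureError("window is empty; no peak to fit")
    yw = yw / y_scale
    base0 = float(yw.min())
    amp0 = float(yw.max() - base0)
    if amp0 <= 0:
        raise FitFailureError("window is flat; no peak to fit")
    mu0 = float(zw[np.argmax(yw)])
    sig0 = max(window_halfwidth / 4.0, profile.z_spacing)
    try:
        popt, _ = curve_fit(
            _gaussian,
            zw,
            yw,
            p0=(amp0, mu0, sig0, base0),
            bounds=(
                (0.0, zw[0], profile.z_spacing / 10.0, -np.inf),
                (np.inf, zw[-1], 4.0 * window_halfwidth, np.inf),
            ),
            maxfev=5000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(f"Gaussian fit failed near {window_center} µm: {exc}") from exc
    amp, mu, sig, base = (float(v) for v in popt)
    resid = yw - _gaussian(zw, *popt)
    ss_tot = float(np.sum((yw - yw.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return PeakFit(center=mu, sigma=sig, amplitude=amp * y_scale,
                   baseline=base * y_scale, r_squared=r2, prominence=prominence)


def detect_reflection_peaks(
    profile: ZProfile,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    window_halfwidth: float = DEFAULT_FIT_HALFWIDTH,
) -> list[PeakFit]:
    """Find reflection peaks above a prominence threshold and refine each fit.

    Candidates are local maxima whose prominence exceeds
    ``min_prominence × max(profile)``; each is refined by
    :func:`fit_gaussian_peak` and the fits are returned sorted by depth.

    Raises
    ------
    InsufficientPeaksError
        If fewer than three candidates survive the threshold — such a
        position is flagged and excluded from the well mean downstream.
    """
    y = profile.intensities
    thresh = min_prominence * float(y.max())
    idx, props = find_peaks(y, prominence=thresh)
    if idx.size < 3:
        raise InsufficientPeaksError(
            f"found {idx.size} reflection peak(s), need 3 (channel "
            f"{profile.channel}, x={profile.x_position})"
        )
    fits = []
    for i, prom in zip(idx, props["prominences"]):
        try:
            fits.append(
                fit_gaussian_peak(
                    profile,
                    window_center=float(i * profile.z_spacing),
                    window_halfwidth=window_halfwidth,
                    prominence=float(prom),
                )
            )
        except FitFailureError:
            # an unfittable spurious candidate (noise bump) is dropped; the
            # three real interfaces must still be fittable
            continue
    if len(fits) < 3:
        raise InsufficientPeaksError(
            f"only {len(fits)} of {idx.size} peak candidates could be fitted"
        )
    fits.sort(key=lambda p: p.center)
    return fits


def classify_interfaces(peaks: list[PeakFit]) -> ReflectionInterfaces:
    """Assign the three most prominent peaks to interfaces by depth order.

    With more than three peaks, the three of greatest prominence are kept
    (ties broken toward shallower depth); the survivors are labelled
    z1 < z2 < z3.
    """
    if len(peaks) < 3:
        raise InsufficientPeaksError(f"need >= 3 peaks to classify, got {len(peaks)}")
    ranked = sorted(peaks, key=lambda p: (-p.prominence, p.center))[:3]
    z1, z2, z3 = sorted(ranked, key=lambda p: p.center)
    return ReflectionInterfaces(
        z1_medium_transwell=z1.center,
        z2_transwell_cell=z2.center,
        z3_asl_air=z3.center,
        peaks=(z1, z2, z3),
    )


def _cross_left(z: np.ndarray, ysub: np.ndarray, start: int, half: float) -> float:
    """Walk left from ``start`` to the first half-level crossing; interpolate."""
    for i in range(start, -1, -1):
        if ysub[i] < half:
            frac = (half - ysub[i]) / (ysub[i + 1] - ysub[i])
            return float(z[i] + frac * (z[i + 1] - z[i]))
    raise BoundaryFailureError("no half-maximum crossing on the lower side")


def _cross_right(z: np.ndarray, ysub: np.ndarray, start: int, half: float) -> float:
    for i in range(start, ysub.size):
        if ysub[i] < half:
            frac = (ysub[i - 1] - half) / (ysub[i - 1] - ysub[i])
            return float(z[i - 1] + frac * (z[i] - z[i - 1]))
    raise BoundaryFailureError("no half-maximum crossing on the upper side")


def half_max_bounds(profile: ZProfile) -> HalfMaxBounds:
    """Half-maximum boundaries of the dominant fluorescence band.

    The baseline is the 5th percentile of the profile.  The band is the
    contiguous run of samples above baseline + 10 % of the peak excursion
    that contains the global maximum.  The plateau reference level is the
    median of band samples at or above 0.8 × the band's 95th percentile —
    a core-plateau median that is unbiased under symmetric noise and robust
    to the bright rim sometimes seen at the air interface.  Bounds are the
    half-level crossings on either side of the band, linearly interpolated
    between samples.

    Raises
    ------
    BoundaryFailureError
        If the profile has no band above baseline or a half-level crossing
        is missing on either side.
    """
    z = profile.z
    y = profile.intensities
    baseline = float(np.percentile(y, 5))
    ysub = y - baseline
    peak = float(ysub.max())
    if peak <= 0:
        raise BoundaryFailureError("profile has no signal above baseline")
    imax = int(np.argmax(ysub))
    band_thresh = 0.1 * peak
    lo = imax
    while lo > 0 and ysub[lo - 1] > band_thresh:
        lo -= 1
    hi = imax
    while hi < ysub.size - 1 and ysub[hi + 1] > band_thresh:
        hi += 1
    band = ysub[lo : hi + 1]
    robust_max = float(np.percentile(band, 95))
    core = band[band >= 0.8 * robust_max]
    reference = float(np.median(core))
    half = reference / 2.0
    z_lower = _cross_left(z, ysub, imax, half)
    z_upper = _cross_right(z, ysub, imax, half)
    return HalfMaxBounds(z_lower=z_lower, z_upper=z_upper, reference_level=reference)
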