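"""Synthetic XZ confocal scan generator with known ground truth.

The forward model emulates a confocal microscope imaging an air–liquid
interface airway culture through the transwell from below.  Along the optical
axis the beam crosses, in order: immersion medium, the transwell membrane, the
epithelial cell layer, the airway surface liquid (ASL) and air.  At each
refractive-index step a fraction of the light given by the normal-incidence
Fresnel law is reflected, so the reflection channel of an XZ scan shows three
axial peaks:

    (1) medium -> transwell        at depth z1
    (2) transwell -> cell layer    at depth z2
    (3) ASL -> air                 at depth z3

(the transwell->cell and cell->ASL steps are weak and merged into peak 2 /
ignored, matching what the instrument resolves).  Fluorescence channels are
plateau bands: calcein-AM stains the cell layer [z2, z2 + cell height] and
rhodamine dextran labels the ASL [z2 + cell height, z3].  Peaks and band
edges are blurred by a Gaussian axial PSF and corrupted by additive detector
noise; interfaces may tilt linearly across the lateral field and shift
between the positions of a multi-position well.

Depth coordinates increase from the transwell toward the air interface, with
depth 0 at the first stack plane.  All lengths are in micrometres.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .errors import GeometryError, InvalidIndexError

__all__ = [
    "DEFAULT_REFRACTIVE_INDICES",
    "PhantomConfig",
    "PhantomTruth",
    "SyntheticScan",
    "fresnel_reflectance",
    "render_scan",
    "render_well",
    "relaxation_height",
    "volume_challenge_series",
]

#: Default refractive indices of the media the beam crosses.  The transwell
#: membrane (polyester) is optically dense; the FEP support film under the
#: sample is index-matched to water and therefore contributes no interface.
DEFAULT_REFRACTIVE_INDICES: dict[str, float] = {
    "medium": 1.33,
    "transwell": 1.58,
    "cell": 1.37,
    "asl": 1.34,
    "air": 1.00,
}


def fresnel_reflectance(n1: float, n2: float) -> float:
    """Normal-incidence Fresnel power reflectance of an n1|n2 interface.

    R = ((n1 - n2) / (n1 + n2))**2 — symmetric in its arguments, zero when
    the indices match and always < 1.

    Raises
    ------
    InvalidIndexError
        If either index is below 1.0 (non-physical for the media involved).
    """
    if n1 < 1.0 or n2 < 1.0:
        raise InvalidIndexError(f"refractive indices must be >= 1.0, got ({n1}, {n2})")
    return float(((n1 - n2) / (n1 + n2)) ** 2)


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, optics and acquisition parameters of a simulated scan.

    Lengths in µm.  ``noise_gaussian_sd`` is expressed as a fraction of the
    brightest structure in each channel (the strongest reflection peak, or
    the fluorescence plateau).  ``tilt`` is the total interface-depth drift
    across the lateral field; ``position_offset_sd`` is the standard
    deviation of the random whole-profile depth shift between the positions
    of a well.
    """

    z_spacing: float = 0.2
    n_z: int = 320
    n_x: int = 64
    transwell_top_z: float = 15.0
    transwell_thickness: float = 10.0
    cell_height: float = 15.0
    asl_height: float = 7.0
    refractive_indices: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REFRACTIVE_INDICES)
    )
    psf_sigma_axial: float = 0.7
    noise_gaussian_sd: float = 0.05
    tilt: float = 0.0
    position_offset_sd: float = 0.5
    n_positions: int = 15
    include_rhodamine: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.z_spacing <= 0:
            raise ValueError("z_spacing must be > 0")
        if self.n_z < 8 or self.n_x < 1:
            raise ValueError("stack must have n_z >= 8 and n_x >= 1")
        for name in ("transwell_top_z", "transwell_thickness", "cell_height",
                     "asl_height", "psf_sigma_axial"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.transwell_top_z < self.transwell_thickness:
            raise GeometryError("transwell_top_z must be >= transwell_thickness")
        idx = self.refractive_indices
        missing = {"medium", "transwell", "cell", "asl", "air"} - set(idx)
        if missing:
            raise ValueError(f"refractive_indices missing {sorted(missing)}")
        for name, n in idx.items():
            if n < 1.0:
                raise InvalidIndexError(f"refractive index {name}={n} < 1.0")
        needed = (self.transwell_top_z + self.cell_height + self.asl_height
                  + 3.0 * self.psf_sigma_axial)
        if self.n_z * self.z_spacing <= needed:
            raise GeometryError(
                f"stack depth {self.n_z * self.z_spacing:.1f} µm too shallow for "
                f"geometry requiring > {needed:.1f} µm"
            )

    @property
    def interface_depths(self) -> tuple[float, float, float]:
        """Nominal (z1, z2, z3) before tilt or position offsets."""
        z2 = self.transwell_top_z
        z1 = z2 - self.transwell_thickness
        z3 = z2 + self.cell_height + self.asl_height
        return (z1, z2, z3)

    def peak_amplitudes(self) -> tuple[float, float, float]:
        """Fresnel reflectances of the three imaged interfaces."""
        n = self.refractive_indices
        return (
            fresnel_reflectance(n["medium"], n["transwell"]),
            fresnel_reflectance(n["transwell"], n["cell"]),
            fresnel_reflectance(n["asl"], n["air"]),
        )


@dataclass(frozen=True)
class PhantomTruth:
    """Ground-truth geometry of one rendered position (the test oracle)."""

    z1: float
    z2: float
    z3: float
    true_cell_height: float
    true_asl_height: float
    position_offset: float = 0.0

    def __post_init__(self) -> None:
        if not (self.z1 < self.z2 <= self.z3):
            raise ValueError("interface depths must satisfy z1 < z2 <= z3")


@dataclass
class SyntheticScan:
    """One simulated XZ scan: per-channel (n_x, n_z) images plus the truth."""

    reflection_image: np.ndarray
    calcein_image: np.ndarray
    rhodamine_image: np.ndarray | None
    truth: PhantomTruth
    config: PhantomConfig

    @property
    def z_spacing(self) -> float:
        return self.config.z_spacing

    @property
    def channels(self) -> dict[str, np.ndarray]:
        out = {"reflection": self.reflection_image, "calcein": self.calcein_image}
        if self.rhodamine_image is not None:
            out["rhodamine"] = self.rhodamine_image
        return out


def _blurred_band(z: np.ndarray, lo: np.ndarray, hi: np.ndarray, sigma: float) -> np.ndarray:
    """Unit plateau over [lo, hi] convolved with a Gaussian of width sigma."""
    if sigma <= 0:
        return ((z >= lo) & (z < hi)).astype(float)
    s = sigma * np.sqrt(2.0)
    return 0.5 * (erf((z - lo) / s) - erf((z - hi) / s))


def render_scan(
    config: PhantomConfig,
    seed: int | None = None,
    *,
    position_offset: float = 0.0,
    rng: np.random.Generator | None = None,
) -> SyntheticScan:
    """Render one XZ scan of the phantom.

    The reflection channel is the sum of three Gaussian-blurred impulse lines
    at the interface depths with Fresnel amplitudes; fluorescence channels
    are blurred plateaus.  Additive Gaussian noise (sd = ``noise_gaussian_sd``
    × the channel's brightest amplitude) is applied and negative intensities
    are clipped to zero, as a non-negative detector would.  With the same
    seed the output is bit-identical.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)

    z = np.arange(config.n_z) * config.z_spacing  # (n_z,)
    x = np.arange(config.n_x, dtype=float)
    if config.n_x > 1:
        tilt_per_col = config.tilt * (x / (config.n_x - 1) - 0.5)
    else:
        tilt_per_col = np.zeros(1)
    offset = (position_offset + tilt_per_col)[:, None]  # (n_x, 1)

    z1, z2, z3 = config.interface_depths
    amps = config.peak_amplitudes()
    sigma = config.psf_sigma_axial

    refl = np.zeros((config.n_x, config.n_z))
    for zk, ak in zip((z1, z2, z3), amps):
        refl += ak * np.exp(-((z[None, :] - (zk + offset)) ** 2) / (2.0 * sigma**2))

    cal = _blurred_band(z[None, :], z2 + offset, z2 + config.cell_height + offset, sigma)
    rho = None
    if config.include_rhodamine:
        rho = _blurred_band(z[None, :], z2 + config.cell_height + offset, z3 + offset, sigma)

    if config.noise_gaussian_sd > 0:
        refl = refl + rng.normal(0.0, config.noise_gaussian_sd * max(amps), refl.shape)
        cal = cal + rng.normal(0.0, config.noise_gaussian_sd, cal.shape)
        if rho is not None:
            rho = rho + rng.normal(0.0, config.noise_gaussian_sd, rho.shape)
    refl = np.clip(refl, 0.0, None)
    cal = np.clip(cal, 0.0, None)
    if rho is not None:
        rho = np.clip(rho, 0.0, None)

    truth = PhantomTruth(
        z1=z1 + position_offset,
        z2=z2 + position_offset,
        z3=z3 + position_offset,
        true_cell_height=config.cell_height,
        true_asl_height=config.asl_height,
        position_offset=position_offset,
    )
    return SyntheticScan(refl, cal, rho, truth, config)


def render_well(config: PhantomConfig, seed: int | None = None) -> list[SyntheticScan]:
    """Render ``config.n_positions`` scans of one well.

    Each position receives an independent Gaussian depth offset
    (sd = ``position_offset_sd``) and an independent noise realisation, all
    drawn from a single seeded generator so a well is reproducible as a unit.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    offsets = rng.normal(0.0, config.position_offset_sd, config.n_positions)
    return [render_scan(config, position_offset=float(off), rng=rng) for off in offsets]


def relaxation_height(initial: float, steady: float, tau: float, t: float) -> float:
    """ASL height t minutes after a volume challenge.

    Excess apical liquid is reabsorbed toward the steady state with
    first-order kinetics:  h(t) = steady + (initial - steady) * exp(-t/tau).
    This exponential is a simulation convention for the phantom; real
    absorption curves need not be single-exponential.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if t < 0:
        raise ValueError("time must be >= 0")
    return steady + (initial - steady) * float(np.exp(-t / tau))


def volume_challenge_series(
    config: PhantomConfig,
    initial_height: float,
    steady_height: float,
    tau: float,
    times: list[float],
    seed: int | None = None,
) -> list[SyntheticScan]:
    """Render one scan per time point of a post-challenge relaxation series.

    The true ASL height follows :func:`relaxation_height`; geometry and noise
    parameters are taken from ``config`` (its ``asl_height`` is overridden).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    scans = []
    for t in times:
        h = relaxation_height(initial_height, steady_height, tau, t)
        cfg_t = dataclasses.replace(config, asl_height=h)
        scans.append(render_scan(cfg_t, rng=rng))
    return scans
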