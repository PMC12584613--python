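"""Ground-truth spectrum generator for the gas-solid interface system.

The generator emulates confocal Raman spectra measured on the surface of a
solidified seawater medium under a nitrogen headspace held at constant
pressure, so that the N2 stretching band at 2,332 cm^-1 provides a
constant internal standard.  Scenes are built from:

* a band table of Gaussian components (N2 internal standard, the sulfate
  S-O stretch at 980 cm^-1, the S8 S-S vibration at 470 cm^-1, and
  carotenoid bands including the polyene C=C stretch at 1,523 cm^-1 plus
  a companion band at 1,005 cm^-1 that deliberately overlaps the sulfate
  fitting window),
* a polynomial baseline,
* additive i.i.d. Gaussian noise on CCD counts, and
* optional single-channel cosmic-ray spikes.

Every generator is deterministic under a fixed seed, and the analytic
band-area bookkeeping is exact: a Gaussian with height h and full width
at half maximum w has area h * w * sqrt(pi / (4 ln 2)).  Calibration
series are constructed so that the true sulfate-to-N2 area ratio at
concentration C is exactly ``CAL_SLOPE * C + CAL_INTERCEPT``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ramanquant.errors import ArgumentError
from ramanquant.io import SpectralMap, Spectrum

__all__ = [
    "Band",
    "SceneTruth",
    "KineticProfile",
    "GAUSS_AREA_FACTOR",
    "CAL_SLOPE",
    "CAL_INTERCEPT",
    "CAL_RANGE",
    "NOISE_SD_MID",
    "NOISE_SD_LOW",
    "default_axis",
    "gaussian_profile",
    "band_area",
    "default_interface_bands",
    "simulate_spectrum",
    "simulate_calibration_series",
    "simulate_map",
    "simulate_timecourse",
    "simulate_silicon",
    "logistic_concentration",
]

#: analytic area of a unit-height, unit-FWHM Gaussian: sqrt(pi / (4 ln 2))
GAUSS_AREA_FACTOR = math.sqrt(math.pi / (4.0 * math.log(2.0)))

#: calibration line relating sulfate-to-N2 area ratio to concentration
#: (mmol/L); the generator builds calibration scenes on this line exactly.
CAL_SLOPE = 0.01802
CAL_INTERCEPT = -0.04239
#: validity range of the calibration model, mmol/L, at 0.3 MPa N2.
CAL_RANGE = (25.0, 75.0)

# Fixed internal-standard band: the N2 headspace pressure is held constant,
# so the band has constant height by design.
_N2_CENTER = 2332.0
_N2_FWHM = 10.0
_N2_HEIGHT = 2000.0

_SULFATE_CENTER = 980.0
_SULFATE_FWHM = 8.0

_S8_CENTER = 470.0
_S8_FWHM = 10.0
_S8_HEIGHT_UNIT = 800.0

# Carotenoid band set: the polyene C=C stretch at 1,523 plus the standard
# companion bands near 1,005 and 1,157 cm^-1; the 1,005 band overlaps the
# sulfate fitting window to exercise deconvolution.
_CAROTENOID_BANDS = (
    (1005.0, 12.0, 300.0),
    (1157.0, 12.0, 500.0),
    (1523.0, 14.0, 1000.0),
)

#: per-channel noise SD (CCD counts) that produces ~0.5% relative SD in
#: the pipeline-fitted sulfate peak area at mid-range concentration
#: (50 mmol/L); Monte Carlo calibrated, see docs/methods.md.
NOISE_SD_MID = 12.5
#: as above for the ~0.1% area-error regime.
NOISE_SD_LOW = 2.5

#: default mild baseline for interface scenes (counts; ascending powers).
DEFAULT_BASELINE = (30.0, 0.004)


def default_axis(lo: float = 200.0, hi: float = 2500.0, step: float = 1.0) -> np.ndarray:
    """Default wavenumber axis: 200-2,500 cm^-1 at 1 cm^-1 spacing.

    The instrument's spectral resolution is 3 cm^-1; sampling at 1 cm^-1
    oversamples by ~3x and keeps multi-component fits well conditioned.
    """
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


@dataclass(frozen=True)
class Band:
    """A parametric Gaussian component of a spectrum."""

    name: str
    center: float
    fwhm: float
    height: float

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ArgumentError(f"band {self.name!r}: fwhm must be > 0")
        if self.height < 0:
            raise ArgumentError(f"band {self.name!r}: height must be >= 0")

    @property
    def area(self) -> float:
        """Analytic Gaussian area, height * fwhm * sqrt(pi/(4 ln 2))."""
        return self.height * self.fwhm * GAUSS_AREA_FACTOR


def gaussian_profile(axis: np.ndarray, center: float, fwhm: float, height: float) -> np.ndarray:
    """Gaussian in FWHM parameterisation: h * exp(-4 ln2 (v-c)^2 / w^2)."""
    return height * np.exp(-4.0 * math.log(2.0) * ((axis - center) / fwhm) ** 2)


def band_area(height: float, fwhm: float) -> float:
    """Analytic area of a Gaussian band."""
    return height * fwhm * GAUSS_AREA_FACTOR


@dataclass
class SceneTruth:
    """Ground truth for one simulated spectrum.

    ``baseline_coeffs`` are polynomial coefficients in ascending powers of
    the wavenumber; ``spike_spec`` lists (channel index, magnitude) pairs
    of cosmic-ray spikes added after noise.
    """

    bands: list[Band] = field(default_factory=list)
    baseline_coeffs: tuple[float, ...] = ()
    noise_sd: float = 0.0
    spike_spec: list[tuple[int, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ArgumentError("noise_sd must be >= 0")


def simulate_spectrum(truth: SceneTruth, axis: np.ndarray | None = None) -> Spectrum:
    """Render a SceneTruth on a wavenumber axis.

    intensity = sum of Gaussian bands + polynomial baseline
    + N(0, noise_sd) noise + cosmic-ray spikes; bit-identical for a
    fixed seed.
    """
    if axis is None:
        axis = default_axis()
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or np.any(np.diff(axis) <= 0):
        raise ArgumentError("axis must be 1-D and strictly increasing")
    lo, hi = axis[0], axis[-1]
    for b in truth.bands:
        if not (lo <= b.center <= hi):
            raise ArgumentError(
                f"band {b.name!r} center {b.center} outside axis span [{lo}, {hi}]"
            )
    y = np.zeros_like(axis)
    for b in truth.bands:
        y += gaussian_profile(axis, b.center, b.fwhm, b.height)
    if truth.baseline_coeffs:
        y += np.polynomial.polynomial.polyval(axis, list(truth.baseline_coeffs))
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        y = y + rng.normal(0.0, truth.noise_sd, size=axis.shape)
    for idx, mag in truth.spike_spec:
        if not (0 <= idx < len(axis)):
            raise ArgumentError(f"spike channel {idx} outside axis bounds")
        y[idx] += mag
    return Spectrum(axis, y, {"synthetic": True, "seed": truth.seed})


def default_interface_bands(
    sulfate_conc: float,
    carotenoid_level: float = 0.0,
    s8_level: float = 0.0,
) -> list[Band]:
    """Band table for a gas-solid interface scene.

    The N2 internal standard has fixed height; the sulfate band height is
    set so that the analytic sulfate-to-N2 area ratio equals
    ``CAL_SLOPE * sulfate_conc + CAL_INTERCEPT`` (clipped at zero).  S8
    and carotenoid bands scale linearly with their level arguments; at
    level 0 they are omitted.
    """
    if not (0.0 <= sulfate_conc <= 100.0):
        raise ArgumentError("sulfate_conc must be within [0, 100] mmol/L")
    if carotenoid_level < 0 or s8_level < 0:
        raise ArgumentError("band levels must be >= 0")
    bands = [Band("N2", _N2_CENTER, _N2_FWHM, _N2_HEIGHT)]
    ratio = max(0.0, CAL_SLOPE * sulfate_conc + CAL_INTERCEPT)
    if ratio > 0:
        n2_area = band_area(_N2_HEIGHT, _N2_FWHM)
        height = ratio * n2_area / (_SULFATE_FWHM * GAUSS_AREA_FACTOR)
        bands.append(Band("sulfate", _SULFATE_CENTER, _SULFATE_FWHM, height))
    if s8_level > 0:
        bands.append(Band("S8", _S8_CENTER, _S8_FWHM, _S8_HEIGHT_UNIT * s8_level))
    if carotenoid_level > 0:
        for center, fwhm, unit_height in _CAROTENOID_BANDS:
            bands.append(
                Band(
                    f"carotenoid-{center:.0f}",
                    center,
                    fwhm,
                    unit_height * carotenoid_level,
                )
            )
    return bands


def _child_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def simulate_calibration_series(
    concs: list[float],
    replicates: int = 3,
    noise_sd: float = NOISE_SD_MID,
    seed: int = 42,
    baseline_coeffs: tuple[float, ...] = DEFAULT_BASELINE,
    spike_probability: float = 0.3,
    axis: np.ndarray | None = None,
) -> list[tuple[float, Spectrum]]:
    """Simulate a sulfate calibration series at the gas-solid interface.

    One spectrum per (concentration, replicate); replicate seeds are
    derived deterministically from the master seed.  Each spectrum may
    carry a cosmic-ray spike (probability ``spike_probability``) so the
    despiking step of the pipeline is exercised.  Concentrations outside
    the 25-75 mmol/L validity range are generated with a warning recorded
    in the spectrum metadata, not rejected.
    """
    if replicates < 1:
        raise ArgumentError("replicates must be >= 1")
    if axis is None:
        axis = default_axis()
    master = np.random.default_rng(seed)
    out: list[tuple[float, Spectrum]] = []
    for conc in concs:
        for rep in range(replicates):
            sub_seed = _child_seed(master)
            sub = np.random.default_rng(sub_seed)
            spikes: list[tuple[int, float]] = []
            if sub.random() < spike_probability:
                idx = int(sub.integers(0, len(axis)))
                mag = float(sub.uniform(2000.0, 8000.0))
                spikes.append((idx, mag))
            truth = SceneTruth(
                bands=default_interface_bands(conc),
                baseline_coeffs=baseline_coeffs,
                noise_sd=noise_sd,
                spike_spec=spikes,
                seed=sub_seed,
            )
            s = simulate_spectrum(truth, axis)
            s.meta.update(
                {
                    "concentration_mmol_L": float(conc),
                    "replicate": rep,
                    "true_ratio": max(0.0, CAL_SLOPE * conc + CAL_INTERCEPT),
                }
            )
            if not (CAL_RANGE[0] <= conc <= CAL_RANGE[1]):
                s.meta["warning"] = (
                    f"concentration {conc} mmol/L outside calibration range "
                    f"{CAL_RANGE[0]}-{CAL_RANGE[1]}"
                )
            out.append((float(conc), s))
    return out


def simulate_map(
    shape: tuple[int, int],
    colony_radius: float,
    truth_inside: SceneTruth,
    truth_outside: SceneTruth,
    seed: int = 7,
    step: float = 25.0,
    axis: np.ndarray | None = None,
) -> tuple[SpectralMap, np.ndarray]:
    """Simulate a colony scene: a disc of colony spectra in a background.

    Nodes within ``colony_radius`` (um) of the grid centre use the
    ``truth_inside`` band table; others ``truth_outside``.  Per-node noise
    seeds derive from the master seed.  Returns the map and the boolean
    colony mask (True inside the disc).  The default 25 um step matches
    typical colony mapping step sizes (20-30 um).
    """
    if colony_radius <= 0:
        raise ArgumentError("colony_radius must be > 0")
    ny, nx = shape
    if ny < 1 or nx < 1:
        raise ArgumentError("map shape must be at least 1x1")
    if axis is None:
        axis = default_axis()
    xs = step * np.arange(nx)
    ys = step * np.arange(ny)
    cx, cy = xs.mean(), ys.mean()
    gx, gy = np.meshgrid(xs, ys)
    half_extent = min(xs[-1] - cx, ys[-1] - cy) if (nx > 1 and ny > 1) else 0.0
    if colony_radius > half_extent + step / 2:
        raise ArgumentError(
            f"colony disc (radius {colony_radius} um) does not fit inside the grid"
        )
    mask = (gx - cx) ** 2 + (gy - cy) ** 2 <= colony_radius**2
    master = np.random.default_rng(seed)
    cube = np.empty((ny, nx, len(axis)))
    for iy in range(ny):
        for ix in range(nx):
            truth = truth_inside if mask[iy, ix] else truth_outside
            node_truth = replace(truth, seed=_child_seed(master))
            cube[iy, ix] = simulate_spectrum(node_truth, axis).intensity
    smap = SpectralMap(
        xs, ys, axis, cube, {"synthetic": True, "seed": seed, "step_um": step}
    )
    return smap, mask


@dataclass(frozen=True)
class KineticProfile:
    """Logistic sulfate-production kinetics at the colony surface.

    c(t) = c0 + (c_max - c0) / (1 + exp(-rate * light_factor * (t - t_mid)))

    ``light_factor`` multiplies the rate; dark cultivation slows sulfate
    production, so dark profiles use a factor < 1.
    """

    c0: float = 30.0
    c_max: float = 70.0
    t_mid: float = 40.0
    rate: float = 0.15
    light_factor: float = 1.0

    def __post_init__(self) -> None:
        if not (CAL_RANGE[0] <= self.c0 < self.c_max <= CAL_RANGE[1]):
            raise ArgumentError(
                f"require {CAL_RANGE[0]} <= c0 < c_max <= {CAL_RANGE[1]}"
            )
        if self.rate <= 0:
            raise ArgumentError("rate must be > 0")
        if not (0 < self.light_factor <= 1):
            raise ArgumentError("light_factor must be in (0, 1]")


def logistic_concentration(profile: KineticProfile, t: float | np.ndarray) -> np.ndarray:
    """Evaluate the logistic concentration curve at time(s) t (hours)."""
    from scipy.special import expit  # overflow-safe sigmoid

    k = profile.rate * profile.light_factor
    return profile.c0 + (profile.c_max - profile.c0) * expit(
        k * (np.asarray(t, dtype=float) - profile.t_mid)
    )


def simulate_timecourse(
    profile: KineticProfile,
    times: list[float],
    replicates: int = 3,
    noise_sd: float = NOISE_SD_MID,
    seed: int = 11,
    baseline_coeffs: tuple[float, ...] = DEFAULT_BASELINE,
    axis: np.ndarray | None = None,
) -> list[tuple[float, list[Spectrum]]]:
    """Simulate timed replicate acquisitions along a kinetic profile.

    Sulfate concentration follows the logistic curve; each time point gets
    ``replicates`` interface spectra built via the default band table.
    """
    times = list(times)
    if any(b < a for a, b in zip(times, times[1:])):
        raise ArgumentError("times must be nondecreasing")
    if replicates < 1:
        raise ArgumentError("replicates must be >= 1")
    if axis is None:
        axis = default_axis()
    master = np.random.default_rng(seed)
    out: list[tuple[float, list[Spectrum]]] = []
    for t in times:
        conc = float(logistic_concentration(profile, t))
        reps = []
        for rep in range(replicates):
            truth = SceneTruth(
                bands=default_interface_bands(conc),
                baseline_coeffs=baseline_coeffs,
                noise_sd=noise_sd,
                seed=_child_seed(master),
            )
            s = simulate_spectrum(truth, axis)
            s.meta.update(
                {"time_h": float(t), "replicate": rep, "true_conc_mmol_L": conc}
            )
            reps.append(s)
        out.append((float(t), reps))
    return out


def simulate_silicon(
    axis_offset: float = 0.0,
    height: float = 3000.0,
    fwhm: float = 6.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    axis: np.ndarray | None = None,
) -> Spectrum:
    """Simulate a single-crystal silicon reference spectrum.

    The silicon band sits at 520 cm^-1 in truth; a miscalibrated axis is
    emulated by shifting the *apparent* band centre by ``axis_offset``
    (an instrument whose axis reads high by +3 shows the band at 523).
    """
    if axis is None:
        axis = default_axis(300.0, 700.0)
    truth = SceneTruth(
        bands=[Band("silicon", 520.0 + axis_offset, fwhm, height)],
        noise_sd=noise_sd,
        seed=seed,
    )
    s = simulate_spectrum(truth, axis)
    s.meta["axis_offset_true"] = float(axis_offset)
    return s
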