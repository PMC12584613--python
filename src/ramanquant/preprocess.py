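"""Spectral preprocessing: despiking, baseline, wavenumber calibration, averaging.

The processing order is fixed to despike -> baseline -> (optional)
wavenumber correction -> average: cosmic-ray spikes corrupt baseline
estimates, so they are removed first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from ramanquant.errors import ArgumentError, CalibrationError
from ramanquant.io import Spectrum

__all__ = [
    "BaselineResult",
    "WavenumberShift",
    "remove_cosmic_rays",
    "correct_baseline",
    "calibrate_wavenumber",
    "average_spectra",
]


@dataclass
class BaselineResult:
    """Additive decomposition of a spectrum into corrected signal + baseline.

    Invariant: ``corrected.intensity + baseline`` equals the input
    intensity elementwise, exactly.
    """

    corrected: Spectrum
    baseline: np.ndarray
    params: dict


@dataclass
class WavenumberShift:
    """Estimated wavenumber-axis offset from the silicon reference.

    ``offset`` is the fitted silicon band centre minus 520 cm^-1; a
    correctly calibrated axis yields offset 0.
    """

    offset: float
    reference_center_found: float

    def __post_init__(self) -> None:
        if abs(self.offset) >= 50:
            raise CalibrationError(
                f"implausible wavenumber offset {self.offset:+.1f} cm^-1 (|offset| "
                "must be < 50); check the silicon reference spectrum"
            )


_MAX_SPIKE_WIDTH = 2  # channels; cosmic rays hit 1-2 CCD columns


def _local_diff_scale(
    absd: np.ndarray, j_in: int, j_out: int, radius: int, floor: float
) -> float:
    """Robust local scale of the first-difference series around a jump pair.

    Median |diff| over ``radius`` diffs on each side of the pair, the
    pair itself and its immediate neighbours excluded; floored by the
    global noise scale so flat noiseless regions do not divide by zero.
    """
    lo = max(0, j_in - 1 - radius)
    hi = min(len(absd), j_out + 2 + radius)
    keep = np.r_[lo : max(lo, j_in - 1), min(hi, j_out + 2) : hi]
    vals = absd[keep]
    local = float(np.median(vals)) if vals.size else 0.0
    return max(local, floor)


def remove_cosmic_rays(
    s: Spectrum, window: int = 5, z_thresh: float = 8.0
) -> tuple[Spectrum, list[int]]:
    """Detect and repair cosmic-ray spikes; returns (despiked, spike indices).

    A cosmic-ray spike is an impulse 1-2 channels wide: a large jump up
    in the first-difference series followed immediately by a large jump
    down (or vice versa for negative artefacts).  Both jumps are scored
    robustly — modified-z style — against the median |difference| of the
    surrounding channels, so a spike riding on a band slope is still an
    outlier relative to the slope, while genuine Raman bands (which rise
    and fall over many channels, being ~3x oversampled at the 3 cm^-1
    instrument resolution) never look impulse-like.  Smooth noiseless
    spectra pass through untouched.  Flagged channels are replaced by the
    median of the surrounding window, spike channels excluded.
    """
    if window < 3 or window % 2 == 0:
        raise ArgumentError("window must be odd and >= 3")
    if z_thresh <= 0:
        raise ArgumentError("z_thresh must be > 0")
    n = len(s)
    if n < window:
        raise ArgumentError(f"spectrum of {n} channels shorter than window {window}")
    y = s.intensity.copy()
    spike_channels: set[int] = set()
    # iterate: repairing one channel of a multi-channel artefact exposes
    # the next (e.g. two adjacent spikes of unequal magnitude)
    for _ in range(4):
        found = _find_spikes(y, window, z_thresh)
        new = found - spike_channels
        if not new:
            break
        spike_channels |= new
        _repair(y, sorted(spike_channels), window)

    spikes = sorted(spike_channels)
    if not spikes:
        return s.copy(), []
    # final repair from the pristine input, so earlier provisional
    # replacements do not leak into the result
    y = s.intensity.copy()
    _repair(y, spikes, window)
    out = s.copy(intensity=y)
    out.meta["despiked_channels"] = spikes
    return out, spikes


def _find_spikes(y: np.ndarray, window: int, z_thresh: float) -> set[int]:
    """One detection pass: channels bounded by an opposite-sign jump pair."""
    d = np.diff(y)
    absd = np.abs(d)
    # global robust noise scale of the differences; tiny absolute floor
    # guards the noiseless limit.
    floor = max(float(np.median(absd)), 1e-9 * max(1.0, float(absd.max(initial=1.0))))
    found: set[int] = set()
    for j_in in np.nonzero(absd > z_thresh * floor)[0]:
        for width in range(1, _MAX_SPIKE_WIDTH + 1):
            j_out = j_in + width
            if j_out >= len(d):
                break
            if d[j_in] * d[j_out] >= 0:
                continue
            scale = _local_diff_scale(absd, j_in, j_out, radius=2 * window, floor=floor)
            if min(absd[j_in], absd[j_out]) > z_thresh * scale:
                found.update(range(j_in + 1, j_in + 1 + width))
                break
    return found


def _repair(y: np.ndarray, spikes: list[int], window: int) -> None:
    """Replace spike channels in place by the median of clean neighbours."""
    n = len(y)
    half = window // 2
    spike_set = set(spikes)
    for i in spikes:
        k = half
        neighbors: list[float] = []
        while not neighbors:
            lo, hi = max(0, i - k), min(n, i + k + 1)
            neighbors = [y[j] for j in range(lo, hi) if j not in spike_set]
            k += 1
        y[i] = float(np.median(neighbors))


def _exact_split(y: np.ndarray, b_raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split y into (corrected, baseline) with corrected + baseline == y bit-exactly.

    The fitted baseline is adjusted by at most one ulp per channel so the
    additive decomposition holds under floating-point rounding.
    """
    corrected = y - b_raw
    baseline = y - corrected
    for _ in range(4):
        s = corrected + baseline
        bad = s != y
        if not bad.any():
            return corrected, baseline
        over = bad & (s > y)
        under = bad & (s < y)
        baseline[over] = np.nextafter(baseline[over], -np.inf)
        baseline[under] = np.nextafter(baseline[under], np.inf)
    # channels where y is at the edge of the floating-point range (e.g.
    # subnormal band-tail values) admit no exact two-float split against
    # an O(1) baseline; there the baseline is set to zero and the full
    # value stays in the corrected trace.
    bad = (corrected + baseline) != y
    corrected[bad] = y[bad]
    baseline[bad] = 0.0
    return corrected, baseline


def _als_baseline(y: np.ndarray, lam: float, p: float, niter: int) -> np.ndarray:
    """Asymmetric-least-squares (Whittaker) baseline of Eilers & Boelens.

    Minimises sum w_i (y_i - z_i)^2 + lam * sum (Delta^2 z)^2 with
    asymmetric weights w_i = p above the baseline and 1-p below.
    """
    n = len(y)
    d = sparse.diags([1.0, -2.0, 1.0], [0, -1, -2], shape=(n, n - 2))
    dtd = lam * (d @ d.T)
    w = np.ones(n)
    z = y
    for _ in range(niter):
        ws = sparse.diags(w)
        z = spsolve((ws + dtd).tocsc(), w * y)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return np.asarray(z)


def _poly_baseline(
    x: np.ndarray, y: np.ndarray, degree: int, niter: int = 50
) -> np.ndarray:
    """Iteratively clipped polynomial baseline (modified polyfit).

    Peaks are excluded by repeatedly fitting and clipping the working
    signal to min(y, fit) until the fit stabilises.
    """
    xc = (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)
    work = y.copy()
    fit = np.zeros_like(y)
    for _ in range(niter):
        coeffs = np.polynomial.polynomial.polyfit(xc, work, degree)
        new_fit = np.polynomial.polynomial.polyval(xc, coeffs)
        clipped = np.minimum(work, new_fit)
        if np.allclose(new_fit, fit, rtol=1e-10, atol=1e-12):
            fit = new_fit
            break
        fit, work = new_fit, clipped
    return fit


def correct_baseline(
    s: Spectrum, method: str = "asymmetric-least-squares", **params
) -> BaselineResult:
    """Estimate and subtract the smooth background under the Raman bands.

    Methods
    -------
    ``asymmetric-least-squares`` (default)
        Whittaker smoother with asymmetric weighting; params ``lam``
        (smoothness, > 0, default 1e5), ``p`` (asymmetry in (0, 1),
        default 0.001), ``niter`` (default 10).  The small asymmetry
        keeps the residual baseline under strong bands below 1e-3 of
        the band height.
    ``polynomial``
        Iteratively clipped polynomial; param ``degree`` (<= 6, default 3).

    The decomposition is exactly additive: corrected + baseline == input.
    """
    if method in ("asymmetric-least-squares", "als", "asls"):
        lam = float(params.pop("lam", 1e5))
        p = float(params.pop("p", 0.001))
        niter = int(params.pop("niter", 10))
        if params:
            raise ArgumentError(f"unknown ALS parameters: {sorted(params)}")
        if lam <= 0:
            raise ArgumentError("ALS smoothness lam must be > 0")
        if not (0 < p < 1):
            raise ArgumentError("ALS asymmetry p must be in (0, 1)")
        baseline = _als_baseline(s.intensity, lam, p, niter)
        used = {"method": "asymmetric-least-squares", "lam": lam, "p": p, "niter": niter}
    elif method == "polynomial":
        degree = int(params.pop("degree", 3))
        if params:
            raise ArgumentError(f"unknown polynomial parameters: {sorted(params)}")
        if not (0 <= degree <= 6):
            raise ArgumentError("polynomial degree must be in [0, 6]")
        baseline = _poly_baseline(s.wavenumber, s.intensity, degree)
        used = {"method": "polynomial", "degree": degree}
    else:
        raise ArgumentError(
            f"unknown baseline method {method!r}; choose "
            "'asymmetric-least-squares' or 'polynomial'"
        )
    corr_arr, baseline = _exact_split(s.intensity, np.asarray(baseline))
    corrected = s.copy(intensity=corr_arr)
    corrected.meta["baseline"] = used
    return BaselineResult(corrected=corrected, baseline=baseline, params=used)


def calibrate_wavenumber(
    s: Spectrum, silicon: Spectrum, search_window: tuple[float, float] = (470.0, 570.0)
) -> tuple[WavenumberShift, Spectrum]:
    """Correct the wavenumber axis against the 520 cm^-1 silicon reference.

    The dominant band of the silicon spectrum is fitted inside
    ``search_window``; the offset (fitted centre - 520) is subtracted
    from the axis of ``s``.  Applying the correction twice is a no-op:
    the second fitted offset is 0.
    """
    from ramanquant.peakfit import fit_peaks  # local import, avoids cycle

    sl = silicon.window_slice(*search_window)
    seg = silicon.intensity[sl]
    if seg.size < 8:
        raise CalibrationError(
            f"silicon spectrum has too few channels in {search_window}"
        )
    # demand a real band: peak must stand clearly above the window edges
    edge = min(seg[0], seg[-1])
    if seg.max() - edge <= 10 * max(1.0, abs(edge)) * 1e-3 and seg.max() - edge < 5:
        raise CalibrationError("no silicon band found in the search window")
    peaks = fit_peaks(silicon, window=search_window, n_components=1)
    center = peaks[0].center
    shift = WavenumberShift(offset=center - 520.0, reference_center_found=center)
    corrected = Spectrum(
        s.wavenumber - shift.offset,
        s.intensity.copy(),
        {**s.meta, "wavenumber_offset_applied": shift.offset},
    )
    return shift, corrected


def average_spectra(spectra: list[Spectrum]) -> tuple[Spectrum, np.ndarray]:
    """Elementwise mean and sample SD of replicate spectra on one axis.

    Replicates acquired at distinct positions are summed and averaged to
    a representative spectrum; the per-channel sample SD (ddof = 1)
    tracks replicate scatter.  Metadata records the replicate count.
    """
    if len(spectra) < 2:
        raise ArgumentError("need at least 2 spectra to average")
    axis = spectra[0].wavenumber
    for i, sp in enumerate(spectra[1:], start=1):
        if len(sp) != len(axis) or not np.array_equal(sp.wavenumber, axis):
            raise ArgumentError(f"spectrum {i} has a mismatched wavenumber axis")
    stack = np.vstack([sp.intensity for sp in spectra])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    out = Spectrum(axis.copy(), mean, {"n_averaged": len(spectra)})
    return out, sd
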