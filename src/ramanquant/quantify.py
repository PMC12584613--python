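"""Internal-standard ratio quantification and linear calibration.

The Raman intensity of a band scales with concentration but also with
excitation power, scattering cross-section and instrument response.  For
two substances measured in the same spectrum these nuisance factors
cancel in the peak-area ratio:

    A_a / A_b = (C_a / C_b) * (F_a / F_b)

where A is the fitted peak area, C the concentration and F the
quantification factor (cross-section times instrument response).  With
the N2 headspace held at constant pressure, C_b and F_a/F_b are constant
and the sulfate-to-N2 area ratio is linear in sulfate concentration:

    A_SO4 / A_N2 = k * C_SO4 + b

k and b are estimated by ordinary least squares from a calibration
series; concentration is then predicted by algebraic inversion.  The
individual cross-sections and instrument factors are never estimated —
only their product, absorbed into k.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from ramanquant.errors import ArgumentError, QuantificationError
from ramanquant.io import Spectrum
from ramanquant.peakfit import fit_peaks
from ramanquant.synthetic import Band

__all__ = [
    "SULFATE_WINDOW",
    "N2_WINDOW",
    "CalibrationModel",
    "ConcentrationEstimate",
    "compute_ratio",
    "fit_calibration",
    "predict_concentration",
]

#: default fit window for the sulfate S-O stretch (980 cm^-1), wide
#: enough to cover the overlapping carotenoid band near 1,005 cm^-1.
SULFATE_WINDOW = (930.0, 1030.0)
#: default fit window for the N2 internal standard (2,332 cm^-1).
N2_WINDOW = (2280.0, 2380.0)

_MODEL_SCHEMA_VERSION = 1


@dataclass
class CalibrationModel:
    """Linear model of analyte-to-standard area ratio vs concentration.

    ``slope`` has units (mmol/L)^-1 and absorbs the quantification-factor
    ratio divided by the (fixed) internal-standard amount; the optional
    ``f_ratio_times_invCb`` field records it explicitly for documentation.
    """

    slope: float
    intercept: float
    r_squared: float
    conc_range: tuple[float, float]
    analyte_band: dict = field(
        default_factory=lambda: {"name": "sulfate", "window": SULFATE_WINDOW}
    )
    standard_band: dict = field(
        default_factory=lambda: {"name": "N2", "window": N2_WINDOW}
    )
    condition: str = "N2 headspace at 0.3 MPa"
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ArgumentError("calibration slope must be nonzero")
        if not (0.0 <= self.r_squared <= 1.0):
            raise ArgumentError("r_squared must be in [0, 1]")
        lo, hi = self.conc_range
        if not lo < hi:
            raise ArgumentError("conc_range must satisfy lo < hi")

    @property
    def f_ratio_times_invCb(self) -> float:
        """The quantification-factor ratio scaled by 1/C_standard (== slope)."""
        return self.slope

    def to_json(self, path: str | Path) -> None:
        doc = {
            "schema_version": _MODEL_SCHEMA_VERSION,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "conc_range": list(self.conc_range),
            "analyte_band": {
                "name": self.analyte_band["name"],
                "window": list(self.analyte_band["window"]),
            },
            "standard_band": {
                "name": self.standard_band["name"],
                "window": list(self.standard_band["window"]),
            },
            "condition": self.condition,
            "n_points": self.n_points,
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        doc = json.loads(Path(path).read_text())
        version = doc.pop("schema_version", None)
        if version != _MODEL_SCHEMA_VERSION:
            raise ArgumentError(
                f"unsupported calibration model schema version {version!r}"
            )
        doc["conc_range"] = tuple(doc["conc_range"])
        doc["analyte_band"]["window"] = tuple(doc["analyte_band"]["window"])
        doc["standard_band"]["window"] = tuple(doc["standard_band"]["window"])
        return cls(**doc)


@dataclass
class ConcentrationEstimate:
    """A predicted concentration with replicate scatter and range flag."""

    value: float
    sd: float
    n_replicates: int
    extrapolated: bool
    ratio: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ArgumentError("sd must be >= 0")


def compute_ratio(
    s: Spectrum,
    analyte_window: tuple[float, float] = SULFATE_WINDOW,
    is_window: tuple[float, float] = N2_WINDOW,
    analyte_components: int = 1,
    analyte_init: list[Band] | None = None,
    analyte_center: float = 980.0,
    fit_seed: int = 0,
) -> float:
    """Fitted analyte-to-internal-standard peak-area ratio for one spectrum.

    Both areas come from windowed Gaussian fits.  With
    ``analyte_components`` = 2 the analyte window is deconvolved and the
    component nearest ``analyte_center`` (980 cm^-1, the sulfate S-O
    stretch) is taken as the analyte; the other is the carotenoid-overlap
    component.  Raises :class:`QuantificationError` if the
    internal-standard area vanishes — the N2 band being absent means the
    constant-pressure headspace assumption is violated.
    """
    analyte_peaks = fit_peaks(
        s, analyte_window, n_components=analyte_components, init=analyte_init,
        seed=fit_seed,
    )
    analyte = min(analyte_peaks, key=lambda p: abs(p.center - analyte_center))
    is_peaks = fit_peaks(s, is_window, n_components=1, seed=fit_seed)
    a_is = is_peaks[0].area
    if a_is <= 0 or not np.isfinite(a_is):
        raise QuantificationError(
            "internal-standard band area vanished: no N2 band in the "
            f"window {is_window} (constant-pressure headspace assumption violated)"
        )
    return analyte.area / a_is


def fit_calibration(points: list[tuple[float, float]]) -> CalibrationModel:
    """Ordinary least squares of area ratio on concentration.

    ``points`` are (concentration mmol/L, ratio) pairs — all replicate
    points enter the regression individually.  Requires at least 3
    distinct concentrations; the model's validity range is the span of
    the calibration concentrations.
    """
    if len(points) < 3:
        raise ArgumentError("need at least 3 calibration points")
    conc = np.asarray([p[0] for p in points], dtype=float)
    ratio = np.asarray([p[1] for p in points], dtype=float)
    if len(np.unique(conc)) < 3:
        raise ArgumentError("need at least 3 distinct concentrations")
    if np.var(conc) == 0:
        raise ArgumentError("zero concentration variance: degenerate design")
    res = stats.linregress(conc, ratio)
    return CalibrationModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        conc_range=(float(conc.min()), float(conc.max())),
        n_points=len(points),
    )


def predict_concentration(
    ratio: float,
    model: CalibrationModel,
    replicate_ratios: list[float] | None = None,
) -> ConcentrationEstimate:
    """Invert the calibration line: C = (ratio - b) / k.

    When replicate ratios are given, a concentration is computed per
    replicate and the estimate is their mean with sample SD — replicate
    aggregation happens on the quantity of interest, not on the ratios.
    Estimates outside the model's validity range are flagged as
    extrapolated (a warning, not an error: time-course concentrations may
    drift out of range).
    """
    if replicate_ratios:
        values = np.asarray(
            [(r - model.intercept) / model.slope for r in replicate_ratios]
        )
        value = float(values.mean())
        sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
        n = len(values)
        used_ratio = float(np.mean(replicate_ratios))
    else:
        value = (ratio - model.intercept) / model.slope
        sd = 0.0
        n = 1
        used_ratio = ratio
    lo, hi = model.conc_range
    return ConcentrationEstimate(
        value=value,
        sd=sd,
        n_replicates=n,
        extrapolated=not (lo <= value <= hi),
        ratio=used_ratio,
    )
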