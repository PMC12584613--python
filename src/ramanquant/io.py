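"""Plain-text spectrum and spectral-map formats.

A :class:`Spectrum` is stored as a two-column CSV with header
``wavenumber,intensity`` plus an optional JSON metadata sidecar
``<path>.meta.json`` carrying the acquisition record (label, position,
integration time, accumulations, laser power, timestamp).

A :class:`SpectralMap` is stored as a long-format CSV with columns
``x,y,wavenumber,intensity``; the rectangular grid is inferred from the
unique sorted x and y coordinates and every node must share one
wavenumber axis.  Rows are written row-major by ascending y then x so
that output files are byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ramanquant.errors import FormatError, ParseError

__all__ = [
    "Spectrum",
    "SpectralMap",
    "read_spectrum",
    "write_spectrum",
    "read_map",
    "write_map",
]


def _validate_axis(wavenumber: np.ndarray, intensity: np.ndarray) -> None:
    if wavenumber.ndim != 1 or intensity.ndim != 1:
        raise FormatError("wavenumber and intensity must be one-dimensional")
    if len(wavenumber) != len(intensity):
        raise FormatError(
            f"length mismatch: {len(wavenumber)} wavenumbers vs "
            f"{len(intensity)} intensities"
        )
    if len(wavenumber) < 2:
        raise FormatError("a spectrum needs at least 2 channels")
    diffs = np.diff(wavenumber)
    bad = np.nonzero(diffs <= 0)[0]
    if bad.size:
        i = int(bad[0])
        raise FormatError(
            f"wavenumber axis not strictly increasing at index {i + 1} "
            f"({wavenumber[i + 1]:g} after {wavenumber[i]:g})"
        )
    if not np.all(np.isfinite(wavenumber)):
        raise FormatError("non-finite wavenumber value")
    if not np.all(np.isfinite(intensity)):
        i = int(np.nonzero(~np.isfinite(intensity))[0][0])
        raise FormatError(f"non-finite intensity at index {i}")


@dataclass
class Spectrum:
    """One wavenumber-indexed intensity trace with acquisition metadata.

    Parameters
    ----------
    wavenumber
        Strictly increasing Raman shifts in cm^-1.
    intensity
        CCD counts, same length as ``wavenumber``.  Stored as floating
        point: averaged replicate spectra are non-integer.
    meta
        Free-form acquisition record (label, position in um, integration
        time in s, accumulations, laser power in mW, timestamp in h).
    """

    wavenumber: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        _validate_axis(self.wavenumber, self.intensity)

    def __len__(self) -> int:
        return len(self.wavenumber)

    def copy(self, intensity: np.ndarray | None = None, **meta_updates) -> "Spectrum":
        """Return a copy, optionally replacing the intensity trace."""
        meta = dict(self.meta)
        meta.update(meta_updates)
        return Spectrum(
            self.wavenumber.copy(),
            self.intensity.copy() if intensity is None else np.asarray(intensity, float),
            meta,
        )

    def window_slice(self, lo: float, hi: float) -> slice:
        """Index slice covering wavenumbers in [lo, hi]."""
        i0, i1 = np.searchsorted(self.wavenumber, [lo, hi])
        if self.wavenumber[min(i1, len(self) - 1)] == hi:
            i1 += 1
        return slice(int(i0), int(min(i1, len(self))))


@dataclass
class SpectralMap:
    """Gridded spectra sharing one wavenumber axis.

    ``cube`` has shape ``(len(ys), len(xs), len(wavenumber))`` with axis
    order (row = y, column = x).  Grid coordinates are in micrometres and
    must have a constant positive step.
    """

    xs: np.ndarray
    ys: np.ndarray
    wavenumber: np.ndarray
    cube: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.xs = np.asarray(self.xs, dtype=float)
        self.ys = np.asarray(self.ys, dtype=float)
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        self.cube = np.asarray(self.cube, dtype=float)
        for name, coords in (("x", self.xs), ("y", self.ys)):
            if coords.ndim != 1 or len(coords) < 1:
                raise FormatError(f"{name} grid must be a non-empty 1-D array")
            if len(coords) > 1:
                steps = np.diff(coords)
                if np.any(steps <= 0):
                    raise FormatError(f"{name} grid not strictly increasing")
                if not np.allclose(steps, steps[0], rtol=1e-8, atol=1e-9):
                    raise FormatError(f"{name} grid step is not constant")
        if self.cube.shape != (len(self.ys), len(self.xs), len(self.wavenumber)):
            raise FormatError(
                f"cube shape {self.cube.shape} does not match grid "
                f"({len(self.ys)}, {len(self.xs)}, {len(self.wavenumber)})"
            )
        _validate_axis(self.wavenumber, self.cube[0, 0])
        if not np.all(np.isfinite(self.cube)):
            raise FormatError("non-finite intensity in map cube")

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.ys), len(self.xs))

    def spectrum_at(self, iy: int, ix: int) -> Spectrum:
        return Spectrum(
            self.wavenumber.copy(),
            self.cube[iy, ix].copy(),
            {"x": float(self.xs[ix]), "y": float(self.ys[iy])},
        )


# %.17g guarantees exact float64 round-trip through text
_FLOAT_FMT = "%.17g"


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write ``wavenumber,intensity`` CSV plus JSON sidecar if meta is non-empty."""
    path = Path(path)
    df = pd.DataFrame(
        {"wavenumber": spectrum.wavenumber, "intensity": spectrum.intensity}
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    if spectrum.meta:
        sidecar = path.with_name(path.name + ".meta.json")
        sidecar.write_text(json.dumps(spectrum.meta, indent=1, sort_keys=True) + "\n")


def _read_numeric_csv(path: Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    got = [c.strip() for c in df.columns]
    if got != columns:
        raise FormatError(
            f"{path}: expected header {','.join(columns)!r}, got {','.join(got)!r}"
        )
    out = {}
    for col in columns:
        try:
            # astype uses a correctly-rounded parser (unlike to_numeric),
            # preserving the %.17g round-trip guarantee
            out[col] = df[col].astype(np.float64).to_numpy()
        except (ValueError, TypeError):
            for i, cell in enumerate(df[col]):
                try:
                    float(cell)
                except (ValueError, TypeError):
                    # +2: 1-based numbering plus header row
                    raise ParseError(
                        f"{path}: non-numeric value {cell!r} in column {col!r}",
                        line=i + 2,
                    ) from None
            raise
        if np.isnan(out[col]).any():
            line = int(np.nonzero(np.isnan(out[col]))[0][0]) + 2
            raise ParseError(f"{path}: empty cell in column {col!r}", line=line)
    return pd.DataFrame(out)


def read_spectrum(path: str | Path) -> Spectrum:
    """Read a spectrum CSV; a missing metadata sidecar yields empty metadata."""
    path = Path(path)
    df = _read_numeric_csv(path, ["wavenumber", "intensity"])
    sidecar = path.with_name(path.name + ".meta.json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return Spectrum(df["wavenumber"].to_numpy(), df["intensity"].to_numpy(), meta)


def write_map(smap: SpectralMap, path: str | Path) -> None:
    """Write a long-format ``x,y,wavenumber,intensity`` CSV, row-major by y then x."""
    path = Path(path)
    ny, nx = smap.shape
    nw = len(smap.wavenumber)
    x_col = np.repeat(np.tile(smap.xs, ny), nw)
    y_col = np.repeat(smap.ys, nx * nw)
    w_col = np.tile(smap.wavenumber, ny * nx)
    i_col = smap.cube.reshape(-1)
    df = pd.DataFrame(
        {"x": x_col, "y": y_col, "wavenumber": w_col, "intensity": i_col}
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    if smap.meta:
        sidecar = path.with_name(path.name + ".meta.json")
        sidecar.write_text(json.dumps(smap.meta, indent=1, sort_keys=True) + "\n")


def read_map(path: str | Path) -> SpectralMap:
    """Read a long-format map CSV, inferring the grid from unique sorted x, y.

    Raises :class:`FormatError` naming the first missing (x, y) node if the
    grid is incomplete, and rejects nodes whose wavenumber axis differs
    from the shared one.
    """
    path = Path(path)
    df = _read_numeric_csv(path, ["x", "y", "wavenumber", "intensity"])
    xs = np.unique(df["x"].to_numpy())
    ys = np.unique(df["y"].to_numpy())
    axis = np.unique(df["wavenumber"].to_numpy())
    nw = len(axis)
    cube = np.full((len(ys), len(xs), nw), np.nan)
    x_idx = np.searchsorted(xs, df["x"].to_numpy())
    y_idx = np.searchsorted(ys, df["y"].to_numpy())
    w_idx = np.searchsorted(axis, df["wavenumber"].to_numpy())
    cube[y_idx, x_idx, w_idx] = df["intensity"].to_numpy()
    missing = np.isnan(cube).any(axis=2)
    if missing.any():
        nodes = [
            f"(x={xs[ix]:g}, y={ys[iy]:g})"
            for iy, ix in zip(*np.nonzero(missing))
        ]
        raise FormatError(f"{path}: incomplete grid, missing nodes {', '.join(nodes)}")
    sidecar = path.with_name(path.name + ".meta.json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return SpectralMap(xs, ys, axis, cube, meta)
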