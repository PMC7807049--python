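"""Emission-spectrum container and preprocessing primitives.

A :class:`Spectrum` is one autofluorescence measurement: an intensity
(arbitrary units) sampled on a strictly increasing wavelength grid (nm).
Measurements play one of three roles in the pipeline:

``cell``
    autofluorescence of a single cell inside an imaging well,
``background``
    the imaging solution alone, measured on a clean region of the same
    coverslip (several per well; their pointwise mean is subtracted),
``reference``
    a pure fluorophore solution used to train the spectral library.
"""

from __future__ import annotations

import dataclasses
import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import savgol_filter

#: wavelength window that encloses the emission of all four endogenous
#: fluorophores considered here (NADH free/bound, FAD, lipopigment)
DEFAULT_RANGE_NM = (400.0, 850.0)

#: Savitzky-Golay smoothing defaults: short enough to preserve emission
#: peak shape on a 1 nm grid, long enough to suppress shot-like noise
SMOOTH_WINDOW = 11
SMOOTH_ORDER = 3

ROLES = ("cell", "background", "reference")


@dataclass
class Spectrum:
    """One emission measurement on a wavelength grid.

    Parameters
    ----------
    wavelengths_nm : array-like
        Strictly increasing wavelengths in nm, length >= 2.
    intensities : array-like
        Same-length intensities in arbitrary units; must be finite.
    meta : dict
        Free-form metadata. Conventional keys: ``sample_id``, ``donor``,
        ``passage`` (``"E"``, ``"S"`` or ``"n/a"``), ``role``.
    """

    wavelengths_nm: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths_nm.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("wavelengths and intensities must be 1-D")
        if self.wavelengths_nm.size != self.intensities.size:
            raise ValueError(
                f"length mismatch: {self.wavelengths_nm.size} wavelengths vs "
                f"{self.intensities.size} intensities"
            )
        if self.wavelengths_nm.size < 2:
            raise ValueError("a spectrum needs at least 2 samples")
        if not np.all(np.diff(self.wavelengths_nm) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.wavelengths_nm)):
            raise ValueError("non-finite wavelength")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("non-finite intensity")
        role = self.meta.get("role")
        if role is not None and role not in ROLES:
            raise ValueError(f"unknown role {role!r}; expected one of {ROLES}")

    # -- basic calculus ---------------------------------------------------

    @property
    def n(self) -> int:
        return self.wavelengths_nm.size

    def integral(self) -> float:
        """Trapezoidal integral over the grid (a.u. * nm)."""
        return float(np.trapezoid(self.intensities, self.wavelengths_nm))

    def copy(self, **meta_updates) -> "Spectrum":
        meta = dict(self.meta)
        meta.update(meta_updates)
        return Spectrum(self.wavelengths_nm.copy(), self.intensities.copy(), meta)

    # -- grid operations --------------------------------------------------

    def crop(self, range_nm: tuple[float, float] = DEFAULT_RANGE_NM) -> "Spectrum":
        """Restrict to wavelengths inside ``range_nm`` (inclusive)."""
        lo, hi = range_nm
        mask = (self.wavelengths_nm >= lo) & (self.wavelengths_nm <= hi)
        if mask.sum() < 2:
            raise ValueError(
                f"spectrum covers [{self.wavelengths_nm[0]:g}, "
                f"{self.wavelengths_nm[-1]:g}] nm; fewer than 2 points fall in "
                f"[{lo:g}, {hi:g}] nm"
            )
        return Spectrum(self.wavelengths_nm[mask], self.intensities[mask], dict(self.meta))

    def resample(self, grid_nm: np.ndarray) -> "Spectrum":
        """Linear interpolation onto ``grid_nm``; extrapolation is refused."""
        grid_nm = np.asarray(grid_nm, dtype=float)
        if grid_nm[0] < self.wavelengths_nm[0] - 1e-9 or grid_nm[-1] > self.wavelengths_nm[-1] + 1e-9:
            raise ValueError(
                f"cannot resample: target grid [{grid_nm[0]:g}, {grid_nm[-1]:g}] nm "
                f"extends beyond measured range [{self.wavelengths_nm[0]:g}, "
                f"{self.wavelengths_nm[-1]:g}] nm (extrapolation forbidden)"
            )
        vals = np.interp(grid_nm, self.wavelengths_nm, self.intensities)
        return Spectrum(grid_nm, vals, dict(self.meta))

    # -- serialisation ----------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        Path(path).write_text(self.to_csv_string())

    def to_csv_string(self) -> str:
        buf = io.StringIO()
        for key in sorted(self.meta):
            buf.write(f"# {key}={self.meta[key]}\n")
        buf.write("wavelength_nm,intensity\n")
        for w, i in zip(self.wavelengths_nm, self.intensities):
            buf.write(f"{float(w)!r},{float(i)!r}\n")
        return buf.getvalue()

    @classmethod
    def from_csv(cls, path: str | Path) -> "Spectrum":
        return cls.from_csv_string(Path(path).read_text())

    @classmethod
    def from_csv_string(cls, text: str) -> "Spectrum":
        meta: dict = {}
        wl: list[float] = []
        inten: list[float] = []
        header_seen = False
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            if not header_seen:
                cols = [c.strip() for c in line.split(",")]
                if cols[:2] != ["wavelength_nm", "intensity"]:
                    raise ValueError(
                        f"bad spectra CSV header {cols!r}; expected "
                        "['wavelength_nm', 'intensity']"
                    )
                header_seen = True
                continue
            w, _, i = line.partition(",")
            wl.append(float(w))
            inten.append(float(i))
        if not header_seen:
            raise ValueError("spectra CSV has no header line")
        return cls(np.array(wl), np.array(inten), meta)


def common_grid(spectra: list[Spectrum]) -> np.ndarray:
    """Densest grid covered by every spectrum (error if overlap is empty)."""
    lo = max(s.wavelengths_nm[0] for s in spectra)
    hi = min(s.wavelengths_nm[-1] for s in spectra)
    if hi <= lo:
        raise ValueError("spectra have no overlapping wavelength range")
    step = min(float(np.min(np.diff(s.wavelengths_nm))) for s in spectra)
    n = int(np.floor((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


def mean_background(backgrounds: list[Spectrum], grid_nm: np.ndarray) -> np.ndarray:
    """Pointwise mean of background spectra, interpolated onto ``grid_nm``."""
    if not backgrounds:
        raise ValueError("at least one background spectrum is required")
    stack = np.stack([b.resample(grid_nm).intensities for b in backgrounds])
    return stack.mean(axis=0)


def smooth(values: np.ndarray, window: int = SMOOTH_WINDOW, order: int = SMOOTH_ORDER) -> np.ndarray:
    """Savitzky-Golay smoothing; window shrinks (odd) for very short inputs."""
    n = values.size
    win = min(window, n if n % 2 == 1 else n - 1)
    if win <= order:
        return values.copy()
    return savgol_filter(values, window_length=win, polyorder=order)


def subtract_background(
    cell: Spectrum,
    backgrounds: list[Spectrum],
    clip: bool = True,
) -> Spectrum:
    """Subtract the mean background from a cell/reference spectrum."""
    bg = mean_background(backgrounds, cell.wavelengths_nm)
    vals = cell.intensities - bg
    if clip:
        vals = np.clip(vals, 0.0, None)
    return Spectrum(cell.wavelengths_nm, vals, dict(cell.meta))
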