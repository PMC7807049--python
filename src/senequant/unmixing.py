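"""Non-negative linear unmixing of cell autofluorescence spectra.

Each background-corrected cell spectrum I(lambda) is decomposed as

    I(lambda) = sum_k  a_k * S_k(lambda) + residual,    a_k >= 0,

where S_k are the unit-peak library components (NADH free/bound, FAD,
lipopigment) and the coefficients a solve the non-negative least-squares
problem. Per cell we tabulate, for every component, the peak value of its
fitted contribution and the integral ("sum of intensities") under it, plus
the model-free total autofluorescence (integral of the corrected spectrum).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .library import SpectralLibrary
from .spectra import DEFAULT_RANGE_NM, Spectrum, mean_background, smooth


@dataclass
class UnmixingResult:
    """Per-cell decomposition summary.

    coefficients
        non-negative component loadings a_k (a.u., per unit-peak shape)
    peak_value
        max over the domain of a_k * S_k(lambda), per component
    integrated_intensity
        trapezoidal integral of a_k * S_k(lambda) (a.u. * nm), per component
    total_autofluorescence
        integral of the corrected spectrum itself (model-free)
    residual_l2, r_squared
        fit diagnostics; r_squared is uncentered (no-intercept convention)
    """

    component_names: list[str]
    coefficients: np.ndarray
    peak_value: np.ndarray
    integrated_intensity: np.ndarray
    total_autofluorescence: float
    residual_l2: float
    r_squared: float
    meta: dict = field(default_factory=dict)

    def coefficient(self, name: str) -> float:
        return float(self.coefficients[self.component_names.index(name)])

    def integral(self, name: str) -> float:
        return float(self.integrated_intensity[self.component_names.index(name)])

    def peak(self, name: str) -> float:
        return float(self.peak_value[self.component_names.index(name)])


def preprocess(
    cell: Spectrum,
    backgrounds: list[Spectrum],
    range_nm: tuple[float, float] = DEFAULT_RANGE_NM,
) -> Spectrum:
    """Background-correct, crop, smooth and clip one cell spectrum.

    The pointwise mean of the background spectra is subtracted, the grid
    is cropped to ``range_nm``, the signal is Savitzky-Golay smoothed and
    negative excursions are clipped to zero.
    """
    if not backgrounds:
        raise ValueError("at least one background spectrum is required")
    lo, hi = range_nm
    if cell.wavelengths_nm[0] > lo + 1e-9 or cell.wavelengths_nm[-1] < hi - 1e-9:
        raise ValueError(
            f"cell spectrum covers [{cell.wavelengths_nm[0]:g}, "
            f"{cell.wavelengths_nm[-1]:g}] nm and does not span the requested "
            f"range [{lo:g}, {hi:g}] nm"
        )
    cropped = cell.crop(range_nm)
    bg = mean_background(backgrounds, cropped.wavelengths_nm)
    vals = np.clip(smooth(cropped.intensities - bg), 0.0, None)
    out = Spectrum(cropped.wavelengths_nm, vals, dict(cell.meta))
    out.meta["preprocessed"] = True
    return out


def unmix(corrected: Spectrum, library: SpectralLibrary) -> UnmixingResult:
    """Non-negative least-squares decomposition of one corrected spectrum."""
    wl = corrected.wavelengths_nm
    if wl.size < len(library):
        raise ValueError(
            f"underdetermined: {wl.size} grid points for {len(library)} components"
        )
    D = library.design_matrix(wl)
    y = corrected.intensities
    coeffs, rnorm = nnls(D, y)
    contributions = D * coeffs  # (n_wl, k)
    peak_value = contributions.max(axis=0)
    integrated = np.trapezoid(contributions, wl, axis=0)
    total_af = float(np.trapezoid(y, wl))
    ss_raw = float(np.dot(y, y))
    r2 = 1.0 - rnorm**2 / ss_raw if ss_raw > 0 else 1.0
    return UnmixingResult(
        component_names=list(library.names),
        coefficients=coeffs,
        peak_value=peak_value,
        integrated_intensity=integrated,
        total_autofluorescence=total_af,
        residual_l2=float(rnorm),
        r_squared=float(r2),
        meta=dict(corrected.meta),
    )


def summarize_cells(
    results: list[UnmixingResult], metric: str = "total_af"
) -> tuple[float, float, float]:
    """(mean, sample sd, n) of a per-cell metric over a sample of cells.

    ``metric`` is ``"total_af"`` or ``"<kind>:<component>"`` with kind one
    of ``coefficient``, ``integral``, ``peak`` — e.g. ``"integral:lipopigment"``
    is the lipopigment autofluorescence per cell. sd is 0 by convention
    for a single cell.
    """
    if not results:
        raise ValueError("no unmixing results to summarise")
    values = np.array([_metric_value(r, metric) for r in results])
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return float(values.mean()), sd, float(values.size)


def _metric_value(result: UnmixingResult, metric: str) -> float:
    if metric == "total_af":
        return result.total_autofluorescence
    kind, _, name = metric.partition(":")
    if not name:
        raise ValueError(f"bad metric {metric!r}: expected 'total_af' or 'kind:component'")
    getter = {"coefficient": result.coefficient, "integral": result.integral, "peak": result.peak}
    if kind not in getter:
        raise ValueError(f"unknown metric kind {kind!r}")
    return getter[kind](name)


def results_to_frame(results: list[UnmixingResult]) -> pd.DataFrame:
    """Tidy per-cell results table (one row per measurement)."""
    rows = []
    for r in results:
        row = {
            "sample_id": r.meta.get("sample_id", ""),
            "donor": r.meta.get("donor", ""),
            "passage": r.meta.get("passage", ""),
        }
        for i, name in enumerate(r.component_names):
            row[f"coefficient_{name}"] = r.coefficients[i]
            row[f"peak_{name}"] = r.peak_value[i]
            row[f"integral_{name}"] = r.integrated_intensity[i]
        row["total_af"] = r.total_autofluorescence
        row["residual_l2"] = r.residual_l2
        row["r_squared"] = r.r_squared
        rows.append(row)
    return pd.DataFrame(rows)


class SpectralUnmixer:
    """Scikit-learn style transformer around the NNLS decomposition.

    Parameters
    ----------
    library : SpectralLibrary
        Trained component library.

    After :meth:`fit` (which binds the wavelength grid), :meth:`transform`
    maps an (n_spectra, n_wavelengths) intensity matrix to the
    (n_spectra, n_components) non-negative coefficient matrix.

    Fitted attributes: ``wavelengths_``, ``components_`` (the design
    matrix, components in rows), ``component_names_``.
    """

    def __init__(self, library: SpectralLibrary):
        self.library = library

    def get_params(self, deep: bool = True) -> dict:
        return {"library": self.library}

    def set_params(self, **params) -> "SpectralUnmixer":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"invalid parameter {key!r} for SpectralUnmixer")
            setattr(self, key, value)
        return self

    def fit(self, X, y=None, wavelengths_nm: np.ndarray | None = None) -> "SpectralUnmixer":
        """Bind the wavelength grid (defaults to 1 nm over the library domain)."""
        if wavelengths_nm is None:
            lo, hi = self.library.domain
            wavelengths_nm = np.arange(lo, hi + 0.5)
        self.wavelengths_ = np.asarray(wavelengths_nm, dtype=float)
        if self.wavelengths_.size < len(self.library):
            raise ValueError("underdetermined: fewer grid points than components")
        self.components_ = self.library.design_matrix(self.wavelengths_).T
        self.component_names_ = list(self.library.names)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "components_"):
            raise ValueError("SpectralUnmixer is not fitted; call fit() first")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.wavelengths_.size:
            raise ValueError(
                f"X has {X.shape[1]} wavelengths, expected {self.wavelengths_.size}"
            )
        D = self.components_.T
        return np.stack([nnls(D, row)[0] for row in X])

    def fit_transform(self, X, y=None, **fit_kwargs) -> np.ndarray:
        return self.fit(X, y, **fit_kwargs).transform(X)


def write_results_csv(results: list[UnmixingResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, index=False)
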