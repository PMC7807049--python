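"""Spectral component library: training, residual learning, persistence.

The decomposition of a cell's autofluorescence uses four endogenous
fluorophore components: free and protein-bound NADH, FAD, and lipopigment
(lipofuscin-like granules that accumulate in non-proliferating cells).
Each component is modelled as a sum of 1-3 Gaussians in wavelength,
unit-peak normalised over the working domain.

The first three components are trained from reference solutions
(:func:`fit_component`); the lipopigment component has no clean reference
solution and is instead learned from the unmixing residuals of spectra of
known-senescent cells (:func:`learn_residual_component`). Fitted parameters
are persisted as versioned JSON "library files".
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

from .spectra import DEFAULT_RANGE_NM, Spectrum, common_grid, mean_background, smooth

LIBRARY_FORMAT_VERSION = 1

#: resolution used to locate/normalise component peaks (nm)
_PEAK_GRID_STEP = 0.1

COMPONENT_NAMES = ("NADH_free", "NADH_bound", "FAD", "lipopigment")


def _gaussian_sum(wl: np.ndarray, params: np.ndarray) -> np.ndarray:
    """Sum of Gaussians; params is a flat (center, width, amplitude)*k array."""
    out = np.zeros_like(wl, dtype=float)
    for c, w, a in params.reshape(-1, 3):
        out += a * np.exp(-0.5 * ((wl - c) / w) ** 2)
    return out


@dataclass
class SpectralComponent:
    """Unit-peak emission shape of one fluorophore.

    ``gaussians`` is a list of ``(center_nm, width_nm, amplitude)`` triples;
    the evaluated maximum over the domain equals 1 (within 1e-6).
    """

    name: str
    gaussians: list[tuple[float, float, float]]
    domain: tuple[float, float] = DEFAULT_RANGE_NM
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.gaussians:
            raise ValueError("a component needs at least one Gaussian term")
        for c, w, a in self.gaussians:
            if w <= 0:
                raise ValueError(f"non-positive Gaussian width {w}")
            if a < 0:
                raise ValueError(f"negative Gaussian amplitude {a}")
        peak = self.peak_height()
        if abs(peak - 1.0) > 1e-6:
            raise ValueError(
                f"component {self.name!r} is not unit-peak normalised "
                f"(max = {peak:.8g}); build it with from_raw_gaussians()"
            )

    @classmethod
    def from_raw_gaussians(
        cls,
        name: str,
        gaussians: list[tuple[float, float, float]],
        domain: tuple[float, float] = DEFAULT_RANGE_NM,
        provenance: dict | None = None,
    ) -> "SpectralComponent":
        """Build a component, rescaling amplitudes to unit peak."""
        params = np.asarray(gaussians, dtype=float).reshape(-1)
        grid = _dense_grid(domain)
        peak = float(_gaussian_sum(grid, params).max())
        if peak <= 0:
            raise ValueError("component evaluates to zero everywhere on the domain")
        scaled = [(float(c), float(w), float(a / peak)) for c, w, a in np.asarray(gaussians, float)]
        return cls(name, scaled, domain, provenance or {})

    def evaluate(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths_nm, dtype=float)
        return _gaussian_sum(wl, np.asarray(self.gaussians, float).reshape(-1))

    def peak_height(self) -> float:
        return float(self.evaluate(_dense_grid(self.domain)).max())

    def peak_wavelength(self) -> float:
        grid = _dense_grid(self.domain)
        return float(grid[np.argmax(self.evaluate(grid))])


def _dense_grid(domain: tuple[float, float]) -> np.ndarray:
    lo, hi = domain
    n = int(round((hi - lo) / _PEAK_GRID_STEP)) + 1
    return np.linspace(lo, hi, n)


@dataclass
class SpectralLibrary:
    """Ordered collection of unit-peak spectral components."""

    components: list[SpectralComponent]
    domain: tuple[float, float] = DEFAULT_RANGE_NM
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate component names in library: {names}")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.components]

    def __len__(self) -> int:
        return len(self.components)

    def __getitem__(self, name: str) -> SpectralComponent:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(name)

    def design_matrix(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        """Component shapes evaluated on a grid, shape (n_wavelengths, n_components)."""
        return np.column_stack([c.evaluate(wavelengths_nm) for c in self.components])

    def with_component(self, component: SpectralComponent) -> "SpectralLibrary":
        return SpectralLibrary(
            self.components + [component], self.domain, dict(self.provenance)
        )

    def subset(self, names: list[str]) -> "SpectralLibrary":
        return SpectralLibrary([self[n] for n in names], self.domain, dict(self.provenance))

    # -- persistence ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "version": LIBRARY_FORMAT_VERSION,
            "domain": list(self.domain),
            "provenance": self.provenance,
            "components": [
                {
                    "name": c.name,
                    "gaussians": [
                        {"center_nm": g[0], "width_nm": g[1], "amplitude": g[2]}
                        for g in c.gaussians
                    ],
                    "provenance": c.provenance,
                }
                for c in self.components
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SpectralLibrary":
        version = data.get("version")
        if version != LIBRARY_FORMAT_VERSION:
            raise ValueError(
                f"unsupported library file version {version!r} "
                f"(this reader handles version {LIBRARY_FORMAT_VERSION})"
            )
        for key in ("domain", "components"):
            if key not in data:
                raise ValueError(f"library file missing required field {key!r}")
        domain = tuple(float(x) for x in data["domain"])
        comps = []
        for entry in data["components"]:
            gaussians = [
                (float(g["center_nm"]), float(g["width_nm"]), float(g["amplitude"]))
                for g in entry["gaussians"]
            ]
            comps.append(
                SpectralComponent(
                    entry["name"], gaussians, domain, entry.get("provenance", {})
                )
            )
        return cls(comps, domain, data.get("provenance", {}))


def save_library(library: SpectralLibrary, path: str | Path) -> None:
    """Write a library file (versioned JSON; floats round-trip bit-exactly)."""
    Path(path).write_text(json.dumps(library.to_dict(), indent=2) + "\n")


def load_library(path: str | Path) -> SpectralLibrary:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"not a valid library file: {exc}") from exc
    return SpectralLibrary.from_dict(data)


# ---------------------------------------------------------------------------
# Gaussian-sum fitting
# ---------------------------------------------------------------------------


def fit_gaussian_sum(
    wl: np.ndarray,
    y: np.ndarray,
    max_gaussians: int = 3,
    r2_stop: float = 0.9995,
) -> tuple[np.ndarray, float]:
    """Least-squares fit of y(wl) by <= max_gaussians Gaussian terms.

    Greedy initialisation: terms are added at the running residual's peak,
    then all terms are refined jointly with bounded least squares
    (amplitudes >= 0, widths in [2, 400] nm).

    Returns (flat parameter array, R^2 about the mean).
    """
    if y.max() <= 0:
        raise ValueError("no signal")
    span = wl[-1] - wl[0]
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    params = np.empty(0)
    residual = y.copy()
    best: tuple[np.ndarray, float] = (params, -np.inf)
    for _ in range(max_gaussians):
        if residual.max() <= 0.005 * y.max():
            break
        i_pk = int(np.argmax(residual))
        c0, a0 = wl[i_pk], residual[i_pk]
        w0 = _half_max_width(wl, residual, i_pk)
        p0 = np.concatenate([params, [c0, w0, a0]])
        k = p0.size // 3
        lb = np.tile([wl[0] - 0.2 * span, 2.0, 0.0], k)
        ub = np.tile([wl[-1] + 0.2 * span, 400.0, np.inf], k)
        sol = least_squares(
            lambda p: _gaussian_sum(wl, p) - y,
            np.clip(p0, lb, ub),
            bounds=(lb, ub),
            method="trf",
        )
        params = sol.x
        residual = y - _gaussian_sum(wl, params)
        r2 = 1.0 - float(np.sum(residual**2)) / ss_tot if ss_tot > 0 else 1.0
        if r2 > best[1]:
            best = (params.copy(), r2)
        if r2 >= r2_stop:
            break
    return best


def _half_max_width(wl: np.ndarray, y: np.ndarray, i_pk: int) -> float:
    """Gaussian sigma estimated from the half-maximum width around a peak."""
    half = y[i_pk] / 2.0
    i_lo = i_pk
    while i_lo > 0 and y[i_lo] > half:
        i_lo -= 1
    i_hi = i_pk
    while i_hi < y.size - 1 and y[i_hi] > half:
        i_hi += 1
    fwhm = wl[i_hi] - wl[i_lo]
    if fwhm <= 0:
        return 0.05 * (wl[-1] - wl[0])
    return float(fwhm / 2.3548)


# ---------------------------------------------------------------------------
# Library training
# ---------------------------------------------------------------------------


def fit_component(
    reference_spectra: list[Spectrum],
    background_spectra: list[Spectrum],
    name: str,
    max_gaussians: int = 3,
    domain: tuple[float, float] = DEFAULT_RANGE_NM,
) -> SpectralComponent:
    """Train one library component from reference-solution spectra.

    The references are resampled to a common grid, background-corrected
    (mean of the provided background spectra), averaged, smoothed
    (Savitzky-Golay) and clipped at zero, then fitted by a sum of at most
    ``max_gaussians`` Gaussians and unit-peak normalised. The fit R^2 is
    stored in the component's provenance.
    """
    if not reference_spectra:
        raise ValueError("at least one reference spectrum is required")
    grid = common_grid(reference_spectra)
    grid = grid[(grid >= domain[0]) & (grid <= domain[1])]
    if grid.size < 10:
        raise ValueError("reference spectra barely overlap the working domain")
    stack = np.stack([s.resample(grid).intensities for s in reference_spectra])
    y = stack.mean(axis=0)
    if background_spectra:
        y = y - mean_background(background_spectra, grid)
    y = np.clip(y, 0.0, None)
    y = np.clip(smooth(y), 0.0, None)
    if y.max() <= 0:
        raise ValueError("no signal: background-corrected reference is zero everywhere")
    params, r2 = fit_gaussian_sum(grid, y, max_gaussians=max_gaussians)
    return SpectralComponent.from_raw_gaussians(
        name,
        [tuple(t) for t in params.reshape(-1, 3)],
        domain,
        provenance={
            "trained_from": f"{len(reference_spectra)} reference spectra",
            "fit_r_squared": r2,
        },
    )


def learn_residual_component(
    senescent_spectra: list[Spectrum],
    background_spectra: list[Spectrum],
    library3: SpectralLibrary,
    name: str = "lipopigment",
    max_gaussians: int = 3,
    min_residual_frac: float = 1e-3,
) -> SpectralComponent:
    """Learn the lipopigment component from senescent-cell residuals.

    Each senescent-cell spectrum is background-corrected and unmixed
    against the three trained components with non-negative coefficients;
    the per-wavelength residuals are averaged, floored at zero and
    smoothed. That one-pass residual under-states the fourth emission
    wherever it overlaps the trained components (the overlap is absorbed
    into their coefficients), so it serves as the initialiser of a joint
    refinement: the Gaussian parameters of the fourth component are
    estimated by variable-projection least squares, re-solving the
    per-spectrum non-negative coefficients at every trial shape. The
    parametric Gaussian form is what makes the shape identifiable — a
    Gaussian sum cannot silently trade intensity with the trained
    components the way a free-form shape can. Gaussian terms are added
    one at a time (up to ``max_gaussians``) until the fit stops
    improving.

    Raises ``ValueError("no residual component detectable")`` when the
    mean residual carries no signal above ``min_residual_frac`` of the
    corrected spectra's peak.
    """
    from .unmixing import preprocess  # local import to avoid a cycle

    if len(library3) != 3:
        raise ValueError(
            f"expected a 3-component trained library, got {len(library3)} components"
        )
    if len(senescent_spectra) < 5:
        raise ValueError("at least 5 senescent spectra are required")

    corrected = [
        preprocess(s, background_spectra, range_nm=library3.domain)
        for s in senescent_spectra
    ]
    grid = corrected[0].wavelengths_nm
    Y = np.stack([c.resample(grid).intensities for c in corrected])
    D3 = library3.design_matrix(grid)

    resid = Y - _nnls_rows(D3, Y) @ D3.T
    shape0 = np.clip(smooth(np.clip(resid.mean(axis=0), 0.0, None)), 0.0, None)
    if shape0.max() <= min_residual_frac * max(Y.max(), 1e-300):
        raise ValueError("no residual component detectable")

    params, ssr = _fit_shared_component(grid, Y, D3, shape0, max_gaussians)
    return SpectralComponent.from_raw_gaussians(
        name,
        [tuple(t) for t in params.reshape(-1, 3)],
        library3.domain,
        provenance={
            "trained_from": f"residuals of {len(senescent_spectra)} senescent-cell spectra",
            "joint_fit_ssr": ssr,
        },
    )


def _fit_shared_component(
    grid: np.ndarray,
    Y: np.ndarray,
    D3: np.ndarray,
    shape0: np.ndarray,
    max_gaussians: int,
    improve_tol: float = 0.02,
) -> tuple[np.ndarray, float]:
    """Variable-projection fit of one shared Gaussian-sum component.

    For trial Gaussian parameters theta the per-spectrum coefficients are
    the NNLS solution against [D3, G(theta)]; theta minimises the pooled
    squared residual. Terms are added greedily; a new term is kept only
    while it improves the pooled SSR by more than ``improve_tol``
    (relative), which keeps the component as parsimonious as the data
    demand.
    """
    span = grid[-1] - grid[0]

    def pooled_residual(theta: np.ndarray) -> np.ndarray:
        g = _gaussian_sum(grid, theta)
        peak = g.max()
        if peak <= 0:
            return Y.reshape(-1)
        D4 = np.column_stack([D3, g / peak])
        A = _nnls_rows(D4, Y)
        return (Y - A @ D4.T).reshape(-1)

    best_params: np.ndarray | None = None
    best_ssr = np.inf
    theta = np.empty(0)
    current_shape = shape0
    for k in range(1, max_gaussians + 1):
        seed_fit, _ = fit_gaussian_sum(grid, current_shape, max_gaussians=1)
        theta0 = np.concatenate([theta, seed_fit])
        lb = np.tile([grid[0] - 0.2 * span, 5.0, 0.0], k)
        ub = np.tile([grid[-1] + 0.2 * span, 400.0, np.inf], k)
        sol = least_squares(
            pooled_residual,
            np.clip(theta0, lb + 1e-9, ub - 1e-9),
            bounds=(lb, ub),
            method="trf",
            x_scale="jac",
        )
        ssr = float(2.0 * sol.cost)
        if best_params is not None and ssr > best_ssr * (1.0 - improve_tol):
            break
        best_params, best_ssr = sol.x.copy(), ssr
        theta = sol.x
        # residual left unexplained, to seed the next Gaussian term
        g = _gaussian_sum(grid, theta)
        D4 = np.column_stack([D3, g / g.max()])
        A = _nnls_rows(D4, Y)
        current_shape = np.clip((Y - A @ D4.T).mean(axis=0), 0.0, None)
        if current_shape.max() <= 1e-12 * max(Y.max(), 1e-300) or best_ssr <= 1e-16 * np.sum(Y**2):
            break
    assert best_params is not None
    return best_params, best_ssr


def _nnls_rows(D: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Non-negative least squares of each row of Y against columns of D."""
    from scipy.optimize import nnls

    return np.stack([nnls(D, y)[0] for y in Y])


# ---------------------------------------------------------------------------
# Default truth library (used by the synthetic generator)
# ---------------------------------------------------------------------------


def make_default_library_truth() -> SpectralLibrary:
    """Ground-truth four-component library used for simulation.

    Centers: NADH_bound 440 nm, NADH_free 460 nm (literature-typical
    emission maxima for bound/free NADH), FAD 525 nm, and a broad
    two-Gaussian lipopigment band spanning roughly 450-700 nm. All
    shapes are unit-peak normalised on the 400-850 nm domain.
    """
    comps = [
        SpectralComponent.from_raw_gaussians("NADH_free", [(460.0, 45.0, 1.0)]),
        SpectralComponent.from_raw_gaussians("NADH_bound", [(440.0, 33.0, 1.0)]),
        SpectralComponent.from_raw_gaussians("FAD", [(525.0, 38.0, 1.0)]),
        SpectralComponent.from_raw_gaussians(
            "lipopigment", [(540.0, 60.0, 1.0), (620.0, 70.0, 0.55)]
        ),
    ]
    return SpectralLibrary(
        comps,
        DEFAULT_RANGE_NM,
        provenance={
            "source": "synthetic ground truth",
            "created": datetime.date(2026, 1, 1).isoformat(),
        },
    )
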