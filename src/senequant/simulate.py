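"""Synthetic cohort generator: the forward model of the whole study.

Emulates, per donor, everything the analysis consumes:

* per-cell autofluorescence emission spectra on a 400-850 nm grid, built
  as non-negative mixtures of the four fluorophore shapes plus a smooth
  low-amplitude background and additive Gaussian noise, with five
  background-only measurements per sample;
* flow-cytometry event tables (FSC, FL1) drawn lognormal per channel,
  with a low-FSC debris subpopulation mixed in;
* binomial beta-galactosidase positive counts per stained well;
* a multi-passage growth curve with an exponentially declining doubling
  rate, so early (cPD near 6) and senescent (< 1 PD per week) passages
  exist.

Donors share the configured early-to-senescent shifts but differ in an
overall "senescent burden" factor that jointly scales their
beta-galactosidase probabilities, spectral baselines and (damped) flow
medians — emulating the strong inter-donor heterogeneity real hMSC
cohorts show. A :class:`TruthRecord` carrying every latent quantity is
emitted alongside each dataset so parameter recovery is testable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cytometry import FlowSample
from .growth import BgalCount, GrowthCurve, PassageRecord
from .library import SpectralLibrary, make_default_library_truth
from .spectra import Spectrum

PASSAGES = ("E", "S")

#: default wavelength grid: 400-850 nm at 1 nm steps
def default_grid() -> np.ndarray:
    return np.arange(400.0, 851.0)


@dataclass
class CohortConfig:
    """Study conditions for one synthetic donor cohort.

    Defaults mirror the study design: six donors, at least ten cell
    spectra per passage per donor with five background measurements
    each, 1e5 flow events, beta-gal wells of at least 200 counted cells,
    a doubling of the lipopigment abundance from E to S, a 1.3-fold FSC
    median shift, and beta-gal positivity rising from 10% to 60%.
    """

    n_donors: int = 6
    cells_per_group: int = 10
    n_backgrounds: int = 5
    spectra_noise_sd: float = 0.01      # fraction of the peak signal
    background_level: float = 0.05      # a.u.
    background_noise_sd: float = 0.02   # fraction of background_level
    # per-component mean abundances, order = truth library order
    # (NADH_free, NADH_bound, FAD, lipopigment)
    true_abundances_E: tuple = (1.0, 0.8, 0.6, 0.5)
    true_abundances_S: tuple = (1.0, 0.8, 0.6, 1.0)
    abundance_cv: float = 0.05          # per-cell lognormal dispersion
    donor_sigma: float = 0.15           # donor-level burden lognormal sigma
    # flow: lognormal (median, sigma) per channel
    flow_params_E: dict = field(default_factory=lambda: {"FSC": (400.0, 0.35), "FL1": (150.0, 0.5)})
    flow_params_S: dict = field(default_factory=lambda: {"FSC": (520.0, 0.35), "FL1": (450.0, 0.5)})
    debris_fraction: float = 0.05
    debris_params: dict = field(default_factory=lambda: {"FSC": (30.0, 0.25), "FL1": (20.0, 0.4)})
    n_events: int = 100_000
    # beta-gal staining
    bgal_prob_E: float = 0.10
    bgal_prob_S: float = 0.60
    cells_counted_bgal: int = 200
    n_wells: int = 3
    # growth curve
    growth_seed_count: float = 1.2e5
    growth_pd0: float = 3.3             # PD of the first passage
    growth_decay: float = 0.15          # per-passage exponential decline
    growth_days: float = 7.0
    growth_pd_noise_sd: float = 0.03
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_donors < 1 or self.cells_per_group < 1 or self.n_events < 1:
            raise ValueError("counts must be >= 1")
        for p in (self.bgal_prob_E, self.bgal_prob_S, self.debris_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability/fraction {p} outside [0, 1]")
        if self.debris_fraction >= 1.0:
            raise ValueError("debris_fraction must be < 1")
        for a in (*self.true_abundances_E, *self.true_abundances_S):
            if a < 0:
                raise ValueError("abundances must be non-negative")
        if self.cells_counted_bgal < 1 or self.n_wells < 1:
            raise ValueError("counting parameters must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("true_abundances_E", "true_abundances_S"):
            if key in data:
                data[key] = tuple(data[key])
        for key in ("flow_params_E", "flow_params_S", "debris_params"):
            if key in data:
                data[key] = {ch: tuple(v) for ch, v in data[key].items()}
        return cls(**data)


@dataclass
class TruthRecord:
    """Latent quantities behind a generated cohort (for recovery tests)."""

    rng_seed: int
    component_names: list[str]
    donor_burden: dict[str, float]
    # (donor, passage) -> per-cell abundance matrix (n_cells, n_components)
    cell_abundances: dict[tuple[str, str], np.ndarray]
    # metric -> donor -> true S/E fold of the population mean
    true_folds: dict[str, dict[str, float]]
    bgal_probs: dict[str, dict[str, float]]        # donor -> {"E": p, "S": p}
    growth_indices: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        data = {
            "rng_seed": self.rng_seed,
            "component_names": self.component_names,
            "donor_burden": self.donor_burden,
            "cell_abundances": {
                f"{d}/{p}": arr.tolist() for (d, p), arr in self.cell_abundances.items()
            },
            "true_folds": self.true_folds,
            "bgal_probs": self.bgal_probs,
            "growth_indices": self.growth_indices,
        }
        Path(path).write_text(json.dumps(data, indent=1) + "\n")


@dataclass
class DonorData:
    donor: str
    spectra: dict       # passage -> list[Spectrum] (cells)
    backgrounds: dict   # passage -> list[Spectrum]
    flow: dict          # passage -> FlowSample
    bgal: dict          # passage -> list[BgalCount]
    growth: GrowthCurve


@dataclass
class CohortBundle:
    config: CohortConfig
    library: SpectralLibrary
    donors: list[DonorData]

    def write_dir(self, out: str | Path) -> None:
        """Dump the bundle as plain-text files (CSV per measurement)."""
        out = Path(out)
        for dd in self.donors:
            base = out / dd.donor
            for passage in PASSAGES:
                d = base / passage
                d.mkdir(parents=True, exist_ok=True)
                for i, s in enumerate(dd.spectra[passage]):
                    s.to_csv(d / f"cell_{i:03d}.csv")
                for i, b in enumerate(dd.backgrounds[passage]):
                    b.to_csv(d / f"background_{i:03d}.csv")
                dd.flow[passage].to_csv(d / "flow.csv")
                pd.DataFrame(
                    {
                        "well": [c.well for c in dd.bgal[passage]],
                        "positive": [c.positive for c in dd.bgal[passage]],
                        "total": [c.total for c in dd.bgal[passage]],
                    }
                ).to_csv(d / "bgal.csv", index=False)
            base.mkdir(parents=True, exist_ok=True)
            dd.growth.to_frame().to_csv(base / "growth.csv", index=False)


# ---------------------------------------------------------------------------
# elementary generators
# ---------------------------------------------------------------------------


def generate_background_spectrum(
    grid_nm: np.ndarray,
    level: float,
    rng: np.random.Generator,
    noise_sd: float = 0.02,
    meta: dict | None = None,
) -> Spectrum:
    """Smooth low-amplitude imaging-solution spectrum plus noise."""
    shape = level * (1.0 + 0.3 * np.exp(-0.5 * ((grid_nm - 480.0) / 120.0) ** 2))
    noise = rng.normal(0.0, noise_sd * level, size=grid_nm.size) if level > 0 else 0.0
    m = {"role": "background"}
    m.update(meta or {})
    return Spectrum(grid_nm, shape + noise, m)


def generate_cell_spectrum(
    library: SpectralLibrary,
    abundances,
    noise_sd: float,
    background: Spectrum,
    rng: np.random.Generator,
    meta: dict | None = None,
) -> Spectrum:
    """Forward model of one cell measurement.

    intensities = sum_k a_k S_k(lambda) + background(lambda) + noise,
    with Gaussian noise of sd ``noise_sd`` times the peak signal.
    """
    a = np.asarray(abundances, dtype=float)
    if a.size != len(library):
        raise ValueError(f"expected {len(library)} abundances, got {a.size}")
    if (a < 0).any():
        raise ValueError("abundances must be non-negative")
    wl = background.wavelengths_nm
    signal = library.design_matrix(wl) @ a + background.intensities
    peak = float(np.abs(signal).max())
    if noise_sd > 0 and peak > 0:
        signal = signal + rng.normal(0.0, noise_sd * peak, size=wl.size)
    m = {"role": "cell"}
    m.update(meta or {})
    return Spectrum(wl, signal, m)


def generate_flow_sample(
    n_events: int,
    params: dict,
    debris_fraction: float,
    rng: np.random.Generator,
    debris_params: dict | None = None,
    meta: dict | None = None,
) -> FlowSample:
    """Lognormal FSC/FL1 events with an optional low-FSC debris fraction.

    ``params`` maps channel -> (median, sigma); the lognormal median is
    its scale parameter, so configured median ratios between samples are
    exactly the population median ratios. True event labels
    (cell/debris) are retained in a ``label`` column.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if debris_params is None:
        debris_params = {"FSC": (30.0, 0.25), "FL1": (20.0, 0.4)}
    n_debris = int(rng.binomial(n_events, debris_fraction)) if debris_fraction > 0 else 0
    n_cells = n_events - n_debris
    cols = {}
    for ch in ("FSC", "FL1"):
        med, sigma = params[ch]
        dmed, dsigma = debris_params[ch]
        cells = med * np.exp(sigma * rng.standard_normal(n_cells))
        debris = dmed * np.exp(dsigma * rng.standard_normal(n_debris))
        cols[ch] = np.concatenate([cells, debris])
    labels = np.array(["cell"] * n_cells + ["debris"] * n_debris)
    order = rng.permutation(n_events)
    events = pd.DataFrame(
        {"FSC": cols["FSC"][order], "FL1": cols["FL1"][order], "label": labels[order]}
    )
    return FlowSample(events, meta=dict(meta or {}))


def generate_growth_curve(
    rng: np.random.Generator,
    seed_count: float = 1.2e5,
    pd0: float = 3.3,
    decay: float = 0.15,
    days: float = 7.0,
    pd_noise_sd: float = 0.03,
    max_passages: int = 40,
    meta: dict | None = None,
) -> GrowthCurve:
    """Serial-passage record with exponentially declining doubling rate."""
    records = []
    for p in range(max_passages):
        pd_true = pd0 * np.exp(-decay * p)
        pd_obs = max(pd_true * (1.0 + pd_noise_sd * rng.standard_normal()), 0.05)
        harvested = max(round(seed_count * 2.0**pd_obs), 1)
        records.append(PassageRecord(p + 1, seed_count, harvested, days))
        if pd_obs < 0.8:  # well past the < 1 PD / week senescence threshold
            break
    return GrowthCurve(records, dict(meta or {}))


# ---------------------------------------------------------------------------
# whole cohort
# ---------------------------------------------------------------------------


def generate_cohort(config: CohortConfig) -> tuple[CohortBundle, TruthRecord]:
    """Generate a full multi-donor dataset bundle plus its truth record.

    Fully reproducible: the same config (including ``rng_seed``) yields a
    byte-identical bundle.
    """
    rng = np.random.default_rng(config.rng_seed)
    library = make_default_library_truth()
    grid = default_grid()
    names = list(library.names)
    aE = np.asarray(config.true_abundances_E, float)
    aS = np.asarray(config.true_abundances_S, float)
    integrals = np.trapezoid(library.design_matrix(grid), grid, axis=0)

    donors: list[DonorData] = []
    truth = TruthRecord(
        rng_seed=config.rng_seed,
        component_names=names,
        donor_burden={},
        cell_abundances={},
        true_folds={m: {} for m in ("lipopigment_mean", "total_af_mean", "fsc_mean", "c12fdg_mean", "bgal_pct")},
        bgal_probs={},
    )

    lip = names.index("lipopigment")
    for d in range(config.n_donors):
        donor = f"donor_{d + 1}"
        burden = float(np.exp(config.donor_sigma * rng.standard_normal()))
        truth.donor_burden[donor] = burden
        spectra: dict = {}
        backgrounds: dict = {}
        flow: dict = {}
        bgal: dict = {}
        p_by_passage = {}
        for passage, base_a, flow_params, bgal_p in (
            ("E", aE, config.flow_params_E, config.bgal_prob_E),
            ("S", aS, config.flow_params_S, config.bgal_prob_S),
        ):
            mean_a = base_a * burden
            # per-cell abundances: lognormal around the donor-passage mean
            cv = config.abundance_cv
            if cv > 0:
                sig = np.sqrt(np.log1p(cv**2))
                cells_a = mean_a * np.exp(
                    sig * rng.standard_normal((config.cells_per_group, mean_a.size))
                    - sig**2 / 2.0
                )
            else:
                cells_a = np.tile(mean_a, (config.cells_per_group, 1))
            truth.cell_abundances[(donor, passage)] = cells_a

            bgs = [
                generate_background_spectrum(
                    grid, config.background_level, rng, config.background_noise_sd,
                    meta={"donor": donor, "passage": passage, "sample_id": f"bg_{i}"},
                )
                for i in range(config.n_backgrounds)
            ]
            bg_truth = generate_background_spectrum(
                grid, config.background_level, np.random.default_rng(0), noise_sd=0.0
            )
            cells = [
                generate_cell_spectrum(
                    library, cells_a[i], config.spectra_noise_sd, bg_truth, rng,
                    meta={"donor": donor, "passage": passage, "sample_id": f"cell_{i}"},
                )
                for i in range(config.cells_per_group)
            ]
            spectra[passage] = cells
            backgrounds[passage] = bgs

            fp = {ch: (med * burden**0.5, sigma) for ch, (med, sigma) in flow_params.items()}
            flow[passage] = generate_flow_sample(
                config.n_events, fp, config.debris_fraction, rng,
                debris_params=config.debris_params,
                meta={"donor": donor, "passage": passage, "stain": "C12FDG"},
            )

            p = min(bgal_p * burden, 0.98)
            p_by_passage[passage] = p
            bgal[passage] = [
                BgalCount(
                    int(rng.binomial(config.cells_counted_bgal, p)),
                    config.cells_counted_bgal,
                    well=f"{donor}_{passage}_w{w}",
                )
                for w in range(config.n_wells)
            ]

        growth = generate_growth_curve(
            rng,
            seed_count=config.growth_seed_count,
            pd0=config.growth_pd0,
            decay=config.growth_decay,
            days=config.growth_days,
            pd_noise_sd=config.growth_pd_noise_sd,
            meta={"donor": donor},
        )
        donors.append(DonorData(donor, spectra, backgrounds, flow, bgal, growth))

        truth.bgal_probs[donor] = dict(p_by_passage)
        truth.true_folds["lipopigment_mean"][donor] = float(aS[lip] / aE[lip])
        # background is subtracted during preprocessing, so the true total-AF
        # fold is the ratio of summed component integrals
        truth.true_folds["total_af_mean"][donor] = float(
            (integrals @ aS) / (integrals @ aE)
        )
        truth.true_folds["fsc_mean"][donor] = float(
            config.flow_params_S["FSC"][0] / config.flow_params_E["FSC"][0]
        )
        truth.true_folds["c12fdg_mean"][donor] = float(
            config.flow_params_S["FL1"][0] / config.flow_params_E["FL1"][0]
        )
        truth.true_folds["bgal_pct"][donor] = float(p_by_passage["S"] / p_by_passage["E"])

    return CohortBundle(config, library, donors), truth
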