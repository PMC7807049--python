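"""Benchmarking statistics: fold differences, Welch tests, Spearman ranks.

Every candidate senescence metric (C12FDG mean, FSC mean, total
autofluorescence mean, lipopigment autofluorescence mean, ...) is judged
three ways against the early (E) / senescent (S) passage design:

* per-donor fold difference S/E of the metric's sample means, and the
  (min, max) range of those folds across donors;
* a per-donor one-tailed Welch (unequal-variance) t-test of S > E on the
  per-cell (or per-event / per-well) raw values, annotated with the usual
  star labels (*** p<=0.001, ** p<=0.01, * p<=0.05, ns);
* Spearman rank correlation of the metric's donor-passage means against
  the beta-galactosidase percentage benchmark over all E and S points
  jointly (two points per donor).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def p_to_stars(p: float) -> str:
    for threshold, label in STAR_THRESHOLDS:
        if p <= threshold:
            return label
    return "ns"


# ---------------------------------------------------------------------------
# fold differences
# ---------------------------------------------------------------------------


def fold_difference(e_mean: float, s_mean: float) -> float:
    """Senescent-over-early ratio of sample means; may be < 1 (reversal)."""
    if e_mean <= 0:
        raise ValueError(f"early-passage mean must be > 0, got {e_mean}")
    return s_mean / e_mean


def fold_range(folds) -> tuple[float, float]:
    """(min, max) of per-donor fold differences."""
    folds = list(folds)
    if not folds:
        raise ValueError("no fold differences given")
    return (min(folds), max(folds))


# ---------------------------------------------------------------------------
# Welch one-tailed test
# ---------------------------------------------------------------------------


@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    stars: str


def welch_one_tailed(e_values, s_values, alternative: str = "greater") -> WelchResult:
    """One-tailed Welch (unequal-variance) t-test of S vs E.

    ``alternative="greater"`` tests the a-priori hypothesis that the
    senescent mean exceeds the early mean: t = (mean_S - mean_E) /
    sqrt(s_S^2/n_S + s_E^2/n_E), with Welch-Satterthwaite degrees of
    freedom, and p the upper-tail probability of t. Degenerate zero
    variance with equal means yields t = 0, p = 0.5.
    """
    e = np.asarray(e_values, dtype=float)
    s = np.asarray(s_values, dtype=float)
    if e.size < 2 or s.size < 2:
        raise ValueError(f"each group needs n >= 2 (got {e.size} and {s.size})")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    ve, vs = e.var(ddof=1), s.var(ddof=1)
    se2 = vs / s.size + ve / e.size
    diff = s.mean() - e.mean()
    if se2 == 0.0:
        if diff == 0.0:
            return WelchResult(0.0, float(e.size + s.size - 2), 0.5, "ns")
        t = math.inf if diff > 0 else -math.inf
        df = float(e.size + s.size - 2)
    else:
        t = diff / math.sqrt(se2)
        # Welch-Satterthwaite, computed on variance fractions to avoid
        # under/overflow of se2**2 at extreme scales
        fs = (vs / s.size) / se2
        fe = (ve / e.size) / se2
        df = 1.0 / (fs**2 / (s.size - 1) + fe**2 / (e.size - 1))
    if alternative == "greater":
        p = float(stats.t.sf(t, df))
    else:
        p = float(stats.t.cdf(t, df))
    return WelchResult(float(t), float(df), p, p_to_stars(p))


# ---------------------------------------------------------------------------
# Spearman correlation with exact small-sample p
# ---------------------------------------------------------------------------

_EXACT_N_MAX = 9


@dataclass
class SpearmanResult:
    r: float
    p: float
    method: str  # "exact-permutation" | "t-approx" | "undefined"

    @property
    def defined(self) -> bool:
        return self.method != "undefined"


def spearman(x, y, alternative: str = "two-sided") -> SpearmanResult:
    """Spearman rank correlation with an exact permutation p at small n.

    r is the Pearson correlation of mid-ranks (ties averaged). For
    n <= 9 the p-value enumerates all n! rank permutations exactly;
    for larger n the usual t approximation with df = n - 2 is used.
    Constant input leaves r undefined (flagged via ``method``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired (equal length)")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman r undefined", stacklevel=2)
        return SpearmanResult(float("nan"), float("nan"), "undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    r = float(np.corrcoef(rx, ry)[0, 1])
    if n <= _EXACT_N_MAX:
        p = _exact_permutation_p(rx, ry, r, alternative)
        return SpearmanResult(r, p, "exact-permutation")
    t = r * math.sqrt((n - 2) / max(1.0 - r * r, 1e-300))
    if alternative == "two-sided":
        p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    elif alternative == "greater":
        p = float(stats.t.sf(t, n - 2))
    elif alternative == "less":
        p = float(stats.t.cdf(t, n - 2))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return SpearmanResult(r, min(p, 1.0), "t-approx")


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, r_obs: float, alternative: str) -> float:
    """Enumerate all n! orderings of one rank vector (ties kept as mid-ranks)."""
    n = rx.size
    perms = np.array(list(itertools.permutations(ry)))
    xc = rx - rx.mean()
    pc = perms - ry.mean()
    denom = np.linalg.norm(xc) * np.linalg.norm(pc[0])
    r_all = pc @ xc / denom
    eps = 1e-12
    if alternative == "two-sided":
        count = np.count_nonzero(np.abs(r_all) >= abs(r_obs) - eps)
    elif alternative == "greater":
        count = np.count_nonzero(r_all >= r_obs - eps)
    elif alternative == "less":
        count = np.count_nonzero(r_all <= r_obs + eps)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return count / len(r_all)


# ---------------------------------------------------------------------------
# donor metric table and report
# ---------------------------------------------------------------------------

PASSAGES = ("E", "S")


@dataclass
class DonorMetricTable:
    """Per-(donor, passage) metric summaries plus raw per-cell values.

    ``summary`` has columns donor, passage, metric, mean, sd, n; ``raw``
    maps (donor, passage, metric) to the per-observation value array
    (needed for the Welch tests).
    """

    summary: pd.DataFrame
    raw: dict[tuple[str, str, str], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"donor", "passage", "metric", "mean", "sd", "n"}
        missing = required - set(self.summary.columns)
        if missing:
            raise ValueError(f"summary table missing columns {sorted(missing)}")

    @property
    def metrics(self) -> list[str]:
        return sorted(self.summary["metric"].unique())

    @property
    def donors(self) -> list[str]:
        return sorted(self.summary["donor"].unique())

    def mean_of(self, donor: str, passage: str, metric: str) -> float:
        sel = self.summary[
            (self.summary["donor"] == donor)
            & (self.summary["passage"] == passage)
            & (self.summary["metric"] == metric)
        ]
        if len(sel) != 1:
            raise KeyError(f"no unique row for ({donor}, {passage}, {metric})")
        return float(sel["mean"].iloc[0])

    def add(self, donor: str, passage: str, metric: str, values) -> None:
        """Append one (donor, passage, metric) cell from raw values."""
        values = np.asarray(values, dtype=float)
        sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
        row = pd.DataFrame(
            [
                {
                    "donor": donor,
                    "passage": passage,
                    "metric": metric,
                    "mean": float(values.mean()),
                    "sd": sd,
                    "n": int(values.size),
                }
            ]
        )
        if self.summary.empty:
            self.summary = row
        else:
            self.summary = pd.concat([self.summary, row], ignore_index=True)
        self.raw[(donor, passage, metric)] = values

    @classmethod
    def empty(cls) -> "DonorMetricTable":
        return cls(pd.DataFrame(columns=["donor", "passage", "metric", "mean", "sd", "n"]))


@dataclass
class BenchmarkReport:
    """Fold differences, Welch tests and benchmark correlations, per metric."""

    folds: dict[str, dict[str, float]]            # metric -> donor -> S/E fold
    fold_ranges: dict[str, tuple[float, float]]   # metric -> (min, max)
    welch: dict[str, dict[str, WelchResult]]      # metric -> donor -> test
    correlations: dict[str, SpearmanResult]       # metric -> rho vs benchmark
    benchmark_metric: str
    excluded_donors: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "benchmark_metric": self.benchmark_metric,
            "excluded_donors": self.excluded_donors,
            "fold_ranges": {m: list(r) for m, r in self.fold_ranges.items()},
            "folds": self.folds,
            "welch": {
                m: {
                    d: {"t": w.t, "df": w.df, "p": w.p, "stars": w.stars}
                    for d, w in per_donor.items()
                }
                for m, per_donor in self.welch.items()
            },
            "correlations": {
                m: {"r": c.r, "p": c.p, "method": c.method}
                for m, c in self.correlations.items()
            },
        }

    def folds_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": m, "donor": d, "fold": f}
            for m, per_donor in self.folds.items()
            for d, f in per_donor.items()
        ]
        return pd.DataFrame(rows)


def build_report(
    table: DonorMetricTable, benchmark_metric: str = "bgal_pct"
) -> BenchmarkReport:
    """Assemble the full benchmarking report from a donor metric table.

    Donors lacking an E or S row for a metric are excluded from that
    metric's folds and tests (with a warning). Correlations pool all
    (donor, passage) mean points of a metric against the benchmark
    metric's points — two per donor.
    """
    if benchmark_metric not in table.metrics:
        raise ValueError(
            f"benchmark metric {benchmark_metric!r} absent from table "
            f"(metrics: {table.metrics})"
        )
    folds: dict[str, dict[str, float]] = {}
    fold_ranges: dict[str, tuple[float, float]] = {}
    welch: dict[str, dict[str, WelchResult]] = {}
    excluded: set[str] = set()

    for metric in table.metrics:
        folds[metric] = {}
        welch[metric] = {}
        for donor in table.donors:
            try:
                e_mean = table.mean_of(donor, "E", metric)
                s_mean = table.mean_of(donor, "S", metric)
            except KeyError:
                warnings.warn(
                    f"donor {donor!r} lacks an E or S row for {metric!r}; excluded",
                    stacklevel=2,
                )
                excluded.add(donor)
                continue
            folds[metric][donor] = fold_difference(e_mean, s_mean)
            e_raw = table.raw.get((donor, "E", metric))
            s_raw = table.raw.get((donor, "S", metric))
            if e_raw is not None and s_raw is not None and e_raw.size > 1 and s_raw.size > 1:
                welch[metric][donor] = welch_one_tailed(e_raw, s_raw)
        if folds[metric]:
            fold_ranges[metric] = fold_range(folds[metric].values())

    correlations: dict[str, SpearmanResult] = {}
    bench_points: dict[tuple[str, str], float] = {}
    for donor in table.donors:
        for passage in PASSAGES:
            try:
                bench_points[(donor, passage)] = table.mean_of(donor, passage, benchmark_metric)
            except KeyError:
                continue
    for metric in table.metrics:
        xs, ys = [], []
        for key, bench_value in bench_points.items():
            try:
                ys.append(table.mean_of(key[0], key[1], metric))
            except KeyError:
                continue
            xs.append(bench_value)
        if len(xs) >= 3:
            correlations[metric] = spearman(xs, ys)

    return BenchmarkReport(
        folds=folds,
        fold_ranges=fold_ranges,
        welch=welch,
        correlations=correlations,
        benchmark_metric=benchmark_metric,
        excluded_donors=sorted(excluded),
    )
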