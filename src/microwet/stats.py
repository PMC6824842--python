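"""Statistical summaries of droplet and aggregate tables.

Droplet areas on drying surfaces span four decades, so every summary here
bins on a log10 scale.  The module provides:

* number-density size distributions (counts per mm² per log bin, mean ± SEM
  across fields of view);
* power-law exponent fits for the droplet-area density p(A) ∝ A**γ, either
  by least squares on log-binned densities (``logbin_ls``, the form in
  which such distributions are usually plotted) or by maximum likelihood on
  the truncated continuous power law (``truncated_mle``);
* binned mean ± SEM curves (droplet area vs cell-covered area, survival vs
  droplet size), 2D survival grids over (aggregate size, droplet size);
* an area-weighted binomial logistic regression separating the
  contributions of droplet size and aggregate size to survival;
* population-fraction-above-size curves and pooled overall survival.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from scipy import stats as sps

__all__ = [
    "BinSpec",
    "BinnedCurve",
    "PowerLawFit",
    "ContributionModel",
    "size_distribution",
    "fit_power_law",
    "binned_mean_curve",
    "survival_vs_droplet_size",
    "population_by_droplet_size",
    "survival_2d",
    "fit_contribution",
    "population_above_size",
    "overall_survival",
]


class FitError(ValueError):
    """Raised when a fit is requested on degenerate input."""


@dataclass(frozen=True)
class BinSpec:
    """Strictly increasing bin edges on a log10 area scale (µm²)."""

    edges: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        object.__setattr__(self, "edges", edges)
        if edges.ndim != 1 or len(edges) < 2:
            raise ValueError("need at least 2 edges")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("edges must be strictly increasing")

    @classmethod
    def log_spaced(cls, lo: float, hi: float, n_bins: int) -> "BinSpec":
        """n_bins bins with edges evenly spaced on the log scale."""
        if not 0 < lo < hi:
            raise ValueError(f"need 0 < lo < hi, got [{lo}, {hi}]")
        return cls(np.logspace(np.log10(lo), np.log10(hi), n_bins + 1))

    @classmethod
    def default_droplet_bins(cls) -> "BinSpec":
        """Decades 10^0..10^5 µm², two bins per decade."""
        return cls.log_spaced(1.0, 1e5, 10)

    @property
    def centers(self) -> np.ndarray:
        """Geometric means of adjacent edges."""
        return np.sqrt(self.edges[:-1] * self.edges[1:])

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def index(self, x: np.ndarray) -> np.ndarray:
        """Bin index per value; -1 for values outside [edges[0], edges[-1]]."""
        x = np.asarray(x, dtype=float)
        idx = np.searchsorted(self.edges, x, side="right") - 1
        idx[x == self.edges[-1]] = self.n_bins - 1  # closed last bin
        idx[(x < self.edges[0]) | (x > self.edges[-1])] = -1
        return idx


@dataclass
class BinnedCurve:
    """Per-bin mean ± SEM with occupancy; empty bins carry NaN and n = 0."""

    bin_centers: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_center": self.bin_centers, "mean": self.mean,
            "sem": self.sem, "n": self.n,
        })


@dataclass(frozen=True)
class PowerLawFit:
    """Fitted density exponent γ of p(A) ∝ A**γ on [xmin, xmax]."""

    gamma: float
    stderr: float
    method: str
    xmin: float
    xmax: Optional[float]
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "method": self.method, "gamma": self.gamma, "stderr": self.stderr,
            "xmin": self.xmin, "xmax": self.xmax, "n": self.n,
        }])


@dataclass(frozen=True)
class ContributionModel:
    """Area-weighted logistic regression of survival on standardized
    log10(droplet area) and log10(aggregate area)."""

    beta_droplet: float
    beta_aggregate: float
    se_droplet: float
    se_aggregate: float
    intercept: float
    n: int
    separated: bool = False

    @property
    def droplet_dominates(self) -> bool:
        return abs(self.beta_droplet) > abs(self.beta_aggregate)


def _sem(x: np.ndarray) -> float:
    """Standard error of the mean; 0 for a single observation."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        return 0.0
    return float(np.std(x, ddof=1) / np.sqrt(len(x)))


# ---------------------------------------------------------------------------
# size distribution & power-law fits
# ---------------------------------------------------------------------------

def size_distribution(
    droplets: pd.DataFrame,
    scanned_area_mm2: float,
    bins: BinSpec,
    area_col: str = "droplet_area_um2",
) -> pd.DataFrame:
    """Droplet counts per mm² of surface per size bin.

    ``scanned_area_mm2`` is the area of one field of view ('repeat'); with
    several fields present the per-field densities are averaged and the SEM
    across fields reported, mirroring replicate surface sections.
    """
    if scanned_area_mm2 <= 0:
        raise ValueError("scanned_area_mm2 must be > 0")
    areas = droplets[area_col].to_numpy(dtype=float)
    fields = droplets["repeat"].to_numpy() if "repeat" in droplets else np.zeros(len(areas))
    uniq = np.unique(fields)
    per_field = np.zeros((len(uniq), bins.n_bins))
    for k, f in enumerate(uniq):
        idx = bins.index(areas[fields == f])
        counts = np.bincount(idx[idx >= 0], minlength=bins.n_bins)
        per_field[k] = counts / scanned_area_mm2
    if len(uniq) == 0:
        per_field = np.zeros((1, bins.n_bins))
    mean = per_field.mean(axis=0)
    sem = np.array([_sem(per_field[:, j]) for j in range(bins.n_bins)])
    total = (per_field * scanned_area_mm2).sum(axis=0).astype(int)
    return pd.DataFrame({
        "bin_center": bins.centers, "bin_lo": bins.edges[:-1], "bin_hi": bins.edges[1:],
        "count_per_mm2": mean, "sem": sem, "n": total,
    })


def fit_power_law(
    areas: Sequence[float],
    method: str = "logbin_ls",
    xmin: float = 10.0,
    xmax: Optional[float] = None,
    n_bins: int = 12,
) -> PowerLawFit:
    """Fit the density exponent γ of p(A) ∝ A**γ.

    ``logbin_ls``: least-squares slope of log10(count density) against
    log10(bin center) over log-spaced bins of [xmin, xmax] — the estimator
    implied by plotting a binned size distribution on log-log axes.

    ``truncated_mle``: maximum likelihood for the continuous power law
    truncated to [xmin, xmax]; with ``xmax=None`` this reduces to the
    closed-form Hill estimator γ̂ = −(1 + n / Σ ln(xᵢ/xmin)).  Standard
    errors come from the regression formula and the observed information,
    respectively.
    """
    x = np.asarray(areas, dtype=float)
    x = x[np.isfinite(x) & (x >= xmin)]
    if xmax is not None:
        x = x[x <= xmax]
    n = len(x)
    if n < 2:
        raise FitError(f"need >= 2 areas in range, got {n}")
    if np.ptp(x) == 0:
        raise FitError("all areas identical; exponent undefined")

    if method == "truncated_mle":
        s = np.log(x / xmin).sum()
        if xmax is None:
            gamma = -(1.0 + n / s)
            stderr = abs(gamma + 1.0) / np.sqrt(n)
            return PowerLawFit(gamma, stderr, method, xmin, xmax, n)
        logratio = np.log(xmax / xmin)

        def negll(g: float) -> float:
            g1 = g + 1.0
            if abs(g1) < 1e-9:
                logc = -np.log(logratio)
            else:
                logc = np.log(abs(g1)) - np.log(abs(xmax**g1 - xmin**g1))
            return -(n * logc + g * np.log(x).sum())

        res = optimize.minimize_scalar(negll, bounds=(-6.0, 4.0), method="bounded")
        gamma = float(res.x)
        # observed information via central second difference of the negative
        # log-likelihood
        h = 1e-4
        d2 = (negll(gamma + h) - 2 * negll(gamma) + negll(gamma - h)) / h**2
        stderr = float(1.0 / np.sqrt(d2)) if d2 > 0 else np.nan
        return PowerLawFit(gamma, stderr, method, xmin, xmax, n)

    if method == "logbin_ls":
        hi = xmax if xmax is not None else float(x.max())
        bins = BinSpec.log_spaced(xmin, hi, n_bins)
        counts, _ = np.histogram(x, bins=bins.edges)
        widths = np.diff(bins.edges)
        keep = counts > 0
        if keep.sum() < 2:
            raise FitError("fewer than 2 occupied bins; cannot fit slope")
        logx = np.log10(bins.centers[keep])
        logy = np.log10(counts[keep] / widths[keep])
        fit = sps.linregress(logx, logy)
        return PowerLawFit(float(fit.slope), float(fit.stderr), method, xmin, xmax, n)

    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# binned curves
# ---------------------------------------------------------------------------

def binned_mean_curve(
    x: Sequence[float], y: Sequence[float], bins: BinSpec
) -> BinnedCurve:
    """Mean ± SEM of y per log bin of x (SEM over the observations in each
    bin)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    idx = bins.index(x)
    mean = np.full(bins.n_bins, np.nan)
    sem = np.full(bins.n_bins, np.nan)
    n = np.zeros(bins.n_bins, dtype=int)
    for b in range(bins.n_bins):
        vals = y[idx == b]
        n[b] = len(vals)
        if len(vals):
            mean[b] = vals.mean()
            sem[b] = _sem(vals)
    return BinnedCurve(bins.centers, mean, sem, n)


def survival_vs_droplet_size(
    droplets: pd.DataFrame, bins: BinSpec, pooled: bool = False
) -> BinnedCurve:
    """Fraction of live cells as a function of droplet size.

    Default: the per-droplet survival live/(live+dead) averaged over the
    droplets in each bin (each droplet is one observation, with SEM over
    droplets).  ``pooled=True`` instead returns the area-pooled ratio
    Σlive/Σ(live+dead) per bin (SEM undefined, NaN).
    Droplets with no cells are excluded.
    """
    d = droplets[droplets["cell_area_um2"] > 0]
    if len(d) == 0:
        warnings.warn("no droplets with cells; empty survival curve")
        return BinnedCurve(
            bins.centers, np.full(bins.n_bins, np.nan),
            np.full(bins.n_bins, np.nan), np.zeros(bins.n_bins, dtype=int),
        )
    if not pooled:
        surv = d["live_area_um2"] / d["cell_area_um2"]
        return binned_mean_curve(d["droplet_area_um2"], surv, bins)
    idx = bins.index(d["droplet_area_um2"].to_numpy(dtype=float))
    mean = np.full(bins.n_bins, np.nan)
    n = np.zeros(bins.n_bins, dtype=int)
    for b in range(bins.n_bins):
        sel = idx == b
        n[b] = int(sel.sum())
        tot = d.loc[sel, "cell_area_um2"].sum()
        if tot > 0:
            mean[b] = d.loc[sel, "live_area_um2"].sum() / tot
    return BinnedCurve(bins.centers, mean, np.full(bins.n_bins, np.nan), n)


def population_by_droplet_size(
    droplets: pd.DataFrame, bins: BinSpec, scanned_area_mm2: float = 1.0
) -> pd.DataFrame:
    """Live and dead cell-covered area per droplet-size bin, per mm².

    The stacked live/dead totals conserve the grand total cell area.
    """
    idx = bins.index(droplets["droplet_area_um2"].to_numpy(dtype=float))
    live = np.zeros(bins.n_bins)
    dead = np.zeros(bins.n_bins)
    for b in range(bins.n_bins):
        sel = idx == b
        live[b] = droplets.loc[sel, "live_area_um2"].sum()
        dead[b] = droplets.loc[sel, "dead_area_um2"].sum()
    return pd.DataFrame({
        "bin_center": bins.centers,
        "live_area_per_mm2": live / scanned_area_mm2,
        "dead_area_per_mm2": dead / scanned_area_mm2,
    })


def survival_2d(
    aggregates: pd.DataFrame, droplet_bins: BinSpec, aggregate_bins: BinSpec
) -> dict[str, np.ndarray]:
    """Mean survival, SEM and count per (aggregate-size, droplet-size) bin.

    Rows index aggregate-size bins, columns droplet-size bins; only objects
    with a host droplet and at least some cell area enter.
    """
    a = aggregates.dropna(subset=["droplet_area_um2", "survival_rate"])
    gi = aggregate_bins.index(a["aggregate_area_um2"].to_numpy(dtype=float))
    di = droplet_bins.index(a["droplet_area_um2"].to_numpy(dtype=float))
    surv = a["survival_rate"].to_numpy(dtype=float)
    shape = (aggregate_bins.n_bins, droplet_bins.n_bins)
    mean = np.full(shape, np.nan)
    sem = np.full(shape, np.nan)
    n = np.zeros(shape, dtype=int)
    for r in range(shape[0]):
        for c in range(shape[1]):
            vals = surv[(gi == r) & (di == c)]
            n[r, c] = len(vals)
            if len(vals):
                mean[r, c] = vals.mean()
                sem[r, c] = _sem(vals)
    return {
        "mean": mean, "sem": sem, "n": n,
        "aggregate_bin_centers": aggregate_bins.centers,
        "droplet_bin_centers": droplet_bins.centers,
    }


def fit_contribution(aggregates: pd.DataFrame) -> ContributionModel:
    """Separate the contributions of droplet size and aggregate size to
    survival.

    Fits a binomial logistic regression of the per-object live fraction on
    standardized log10(droplet area) and log10(aggregate area), weighting
    each object by its total cell area (live + dead), so that "events" are
    area units — area being the proxy for cell number.  Perfect separation
    is flagged and resolved by an L2-regularized refit (standard errors then
    unavailable).
    """
    a = aggregates.dropna(subset=["droplet_area_um2", "aggregate_area_um2"])
    a = a[(a["live_area_um2"] + a["dead_area_um2"]) > 0]
    if len(a) < 2:
        raise FitError(f"need >= 2 usable records, got {len(a)}")

    logd = np.log10(a["droplet_area_um2"].to_numpy(dtype=float))
    loga = np.log10(a["aggregate_area_um2"].to_numpy(dtype=float))
    if np.ptp(logd) == 0 or np.ptp(loga) == 0:
        raise FitError("degenerate predictors: no variation in size")
    zd = (logd - logd.mean()) / logd.std(ddof=0)
    za = (loga - loga.mean()) / loga.std(ddof=0)
    X = sm.add_constant(np.column_stack([zd, za]))
    total = (a["live_area_um2"] + a["dead_area_um2"]).to_numpy(dtype=float)
    frac = a["live_area_um2"].to_numpy(dtype=float) / total

    model = sm.GLM(frac, X, family=sm.families.Binomial(), freq_weights=total)
    separated = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            res = model.fit()
        params, bse = res.params, res.bse
        if not np.all(np.isfinite(bse)) or np.any(np.abs(params[1:]) > 50):
            raise RuntimeError("separation suspected")
    except Exception:
        separated = True
        res = model.fit_regularized(alpha=1e-4, L1_wt=0.0)
        params = res.params
        bse = np.full(3, np.nan)

    return ContributionModel(
        beta_droplet=float(params[1]), beta_aggregate=float(params[2]),
        se_droplet=float(bse[1]), se_aggregate=float(bse[2]),
        intercept=float(params[0]), n=len(a), separated=separated,
    )


def population_above_size(
    droplets: pd.DataFrame, thresholds: Optional[np.ndarray] = None
) -> pd.DataFrame:
    """Fraction of the population (by cell-covered area) residing in droplets
    at least as large as each threshold.

    Default thresholds: 100 log-spaced values from 10^1.5 µm² to the largest
    droplet present.  The curve is non-increasing and starts at ≤ 1.
    """
    total = droplets["cell_area_um2"].sum()
    if total <= 0:
        raise ValueError("total cell area is zero")
    areas = droplets["droplet_area_um2"].to_numpy(dtype=float)
    cell = droplets["cell_area_um2"].to_numpy(dtype=float)
    if thresholds is None:
        hi = float(areas.max())
        thresholds = np.logspace(1.5, np.log10(hi), 100)
    thresholds = np.asarray(thresholds, dtype=float)
    frac = np.array([cell[areas >= t].sum() / total for t in thresholds])
    return pd.DataFrame({"threshold_um2": thresholds, "fraction_above": frac})


def overall_survival(records: pd.DataFrame) -> float:
    """Pooled survival Σ live / Σ (live + dead) over all rows.

    Accepts any table with live_area_um2/dead_area_um2 columns — droplet
    records, aggregate records (including dry objects), or their
    concatenation.
    """
    live = records["live_area_um2"].sum()
    dead = records["dead_area_um2"].sum()
    if live + dead <= 0:
        raise ValueError("total cell area is zero")
    return float(live / (live + dead))
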