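"""Empirical semivariograms and theoretical variogram models.

The semivariogram gamma(h) is the central spatial-dependence descriptor of
geostatistics: half the expected squared difference between field values at
two locations separated by lag distance h.  This module estimates it from
scattered well data (method-of-moments, pair-by-pair), evaluates the three
classical bounded models (spherical, exponential, Gaussian) and fits them to
an empirical variogram by pair-count-weighted nonlinear least squares.

Conventions
-----------
* gamma(0) == 0 exactly: the nugget applies only for h > 0, which makes
  ordinary kriging an exact interpolator at sampled locations.
* The exponential and Gaussian models use the "practical range" form, i.e.
  gamma reaches ~95% of the sill at h = a (the 3h/a parameterisation).
* Values are normally log10 concentrations, so semivariance carries
  (log10 ug/L)^2 units; distances are planar meters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist

VARIOGRAM_KINDS = ("spherical", "exponential", "gaussian")


class VariogramFitError(RuntimeError):
    """Raised when weighted least squares cannot fit a variogram model.

    Carries the best parameters seen so far in ``best_model``.
    """

    def __init__(self, message: str, best_model: "VariogramModel | None" = None):
        super().__init__(message)
        self.best_model = best_model


@dataclass(frozen=True)
class VariogramModel:
    """A bounded variogram model gamma(h) with nugget / partial sill / range.

    Parameters
    ----------
    kind : {"spherical", "exponential", "gaussian"}
    nugget : float
        Discontinuity at the origin, c0 >= 0 (micro-scale variance plus
        measurement error).
    partial_sill : float
        Spatially structured variance c > 0; total sill is ``nugget +
        partial_sill``.
    range_ : float
        Distance a > 0 (m) beyond which correlation is negligible.
    """

    kind: str
    nugget: float
    partial_sill: float
    range_: float

    def __post_init__(self):
        if self.kind not in VARIOGRAM_KINDS:
            raise ValueError(f"unknown variogram kind {self.kind!r}")
        if not (self.nugget >= 0):
            raise ValueError(f"nugget must be >= 0, got {self.nugget}")
        if not (self.partial_sill > 0):
            raise ValueError(f"partial sill must be > 0, got {self.partial_sill}")
        if not (self.range_ > 0):
            raise ValueError(f"range must be > 0, got {self.range_}")
        if not np.isfinite(self.nugget + self.partial_sill):
            raise ValueError("sill must be finite")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def __call__(self, h):
        return model_gamma(self, h)

    def covariance(self, h):
        """Covariance C(h) of the second-order stationary field implied by
        this variogram: C(0) = c0 + c, and C(h) = c - (gamma(h) - c0) for
        h > 0 (the nugget is uncorrelated at any positive lag)."""
        h = np.asarray(h, dtype=float)
        cov = self.partial_sill - (model_gamma(self, h) - self.nugget)
        return np.where(h == 0.0, self.nugget + self.partial_sill, cov)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "nugget": self.nugget,
            "partial_sill": self.partial_sill,
            "range": self.range_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VariogramModel":
        return cls(d["kind"], d["nugget"], d["partial_sill"], d["range"])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "VariogramModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def model_gamma(model: VariogramModel, h):
    """Evaluate the theoretical semivariance gamma(h).

    ``h`` may be a scalar or array of nonnegative distances (m).  Returns 0
    at h == 0 by convention (exact-interpolation nugget handling).
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("lag distance h must be >= 0")
    c0, c, a = model.nugget, model.partial_sill, model.range_
    if model.kind == "spherical":
        r = np.minimum(h / a, 1.0)
        g = c0 + c * (1.5 * r - 0.5 * r**3)
    elif model.kind == "exponential":
        g = c0 + c * (1.0 - np.exp(-3.0 * h / a))
    else:  # gaussian
        g = c0 + c * (1.0 - np.exp(-((3.0 * h / a) ** 2)))
    g = np.where(h == 0.0, 0.0, g)
    return g if g.ndim else float(g)


@dataclass(frozen=True)
class EmpiricalVariogram:
    """Method-of-moments semivariogram estimate on distance bins.

    gamma_hat(h) = (1 / 2N(h)) * sum over the N(h) pairs in the bin of the
    squared value difference; every unordered pair is counted once.
    """

    lag_centers: np.ndarray  # mean pair distance per retained bin (m)
    gamma: np.ndarray        # semivariance per bin
    pair_counts: np.ndarray  # N(h) per bin

    def __post_init__(self):
        lc = np.asarray(self.lag_centers, float)
        g = np.asarray(self.gamma, float)
        n = np.asarray(self.pair_counts)
        if not (len(lc) == len(g) == len(n)):
            raise ValueError("lag_centers, gamma, pair_counts must align")
        if np.any(g < 0):
            raise ValueError("semivariance must be >= 0")
        if np.any(n < 1):
            raise ValueError("each reported bin needs >= 1 pair")
        if np.any(np.diff(lc) <= 0):
            raise ValueError("lag_centers must be strictly increasing")
        object.__setattr__(self, "lag_centers", lc)
        object.__setattr__(self, "gamma", g)
        object.__setattr__(self, "pair_counts", np.asarray(n, int))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"lag_m": self.lag_centers, "gamma": self.gamma, "n_pairs": self.pair_counts}
        )


def empirical_semivariogram(
    xy: np.ndarray,
    values: np.ndarray,
    bin_width: float | None = None,
    max_lag: float | None = None,
    min_pairs: int = 30,
) -> EmpiricalVariogram:
    """Estimate the semivariogram of ``values`` observed at planar ``xy``.

    Parameters
    ----------
    xy : (n, 2) array of planar coordinates in meters.
    values : (n,) array, normally log10 concentrations.
    bin_width : lag bin width (m); default ``max_lag / 15``.
    max_lag : largest lag considered; default half the maximum pairwise
        distance (beyond that, pairs are few and the estimate unstable).
    min_pairs : bins with fewer pairs are dropped.

    Zero-distance pairs (duplicate locations) are excluded: they estimate
    the nugget, not any positive-lag bin.
    """
    xy = np.asarray(xy, dtype=float)
    values = np.asarray(values, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("xy must be (n, 2)")
    if len(xy) < 2:
        raise ValueError("need at least two wells")
    d = pdist(xy)
    sq = pdist(values[:, None], metric="sqeuclidean")
    if max_lag is None:
        max_lag = 0.5 * float(d.max())
        if max_lag <= 0:
            raise ValueError("all wells at identical locations")
    if bin_width is None:
        bin_width = max_lag / 15.0
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    keep = (d > 0) & (d <= max_lag)
    if not keep.any():
        raise ValueError(
            f"no pairs with 0 < distance <= max_lag={max_lag:g} m; increase max_lag"
        )
    d, sq = d[keep], sq[keep]
    nbins = int(np.ceil(max_lag / bin_width))
    idx = np.minimum((d / bin_width).astype(int), nbins - 1)
    counts = np.bincount(idx, minlength=nbins)
    sums = np.bincount(idx, weights=sq, minlength=nbins)
    dmean = np.bincount(idx, weights=d, minlength=nbins)
    ok = counts >= max(1, min_pairs)
    if not ok.any():
        raise ValueError("no lag bin reaches min_pairs; relax binning parameters")
    counts, sums, dmean = counts[ok], sums[ok], dmean[ok]
    return EmpiricalVariogram(
        lag_centers=dmean / counts,
        gamma=sums / (2.0 * counts),
        pair_counts=counts,
    )


@dataclass(frozen=True)
class VariogramFit:
    """Result of fitting a theoretical model to an empirical variogram."""

    model: VariogramModel
    weighted_sse: float
    n_bins: int
    range_identifiable: bool = True
    starts_tried: int = field(default=1, compare=False)


def fit_model(
    emp: EmpiricalVariogram,
    kind: str = "exponential",
    n_starts: int = 5,
) -> VariogramFit:
    """Fit a variogram model by pair-count-weighted nonlinear least squares.

    The objective is sum_k w_k (gamma_model(h_k) - gamma_hat_k)^2 with
    w_k proportional to the pair count N(h_k) (weights are normalised, so the
    fit is invariant to scaling all counts by a common factor).  A trust-region
    solver is restarted from ``n_starts`` range values spread log-uniformly
    across the lag span to avoid nugget/range local minima.

    A flat empirical variogram (all gamma equal) makes the range
    unidentifiable; the returned fit then carries the constant as the sill
    with ``range_identifiable=False``.
    """
    if kind not in VARIOGRAM_KINDS:
        raise ValueError(f"unknown variogram kind {kind!r}")
    h = emp.lag_centers
    g = emp.gamma
    if len(h) < 4:
        raise ValueError("need >= 4 usable lag bins to fit a variogram")
    w = emp.pair_counts / emp.pair_counts.mean()
    sw = np.sqrt(w)

    if np.ptp(g) < 1e-12 * max(1.0, abs(g[0])):
        const = float(g[0])
        model = VariogramModel(kind, 0.0, max(const, 1e-12), float(h[-1]))
        return VariogramFit(model, 0.0, len(h), range_identifiable=False)

    gmax = float(g.max())
    tiny = 1e-10 * gmax

    def resid(p):
        m = VariogramModel(kind, p[0], max(p[1], tiny), max(p[2], 1e-9))
        return sw * (model_gamma(m, h) - g)

    lo = np.array([0.0, tiny, 1e-9])
    hi = np.array([gmax * 2.0 + tiny, gmax * 3.0, h[-1] * 100.0])
    best = None
    best_cost = np.inf
    starts = np.geomspace(max(h[0], 1e-6), h[-1] * 4.0, n_starts)
    c0_init = max(float(g[0]) * 0.5, tiny)
    for a0 in starts:
        x0 = np.array([c0_init, max(gmax - c0_init, 10 * tiny), a0])
        try:
            res = least_squares(resid, x0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if res.cost < best_cost:
            best_cost = res.cost
            best = res
    if best is None:
        raise VariogramFitError(f"no {kind} variogram start converged", None)
    c0, c, a = best.x
    model = VariogramModel(kind, float(c0), float(max(c, tiny)), float(a))
    wsse = float(2.0 * best_cost)  # least_squares cost = 0.5 * sum r^2
    if not best.success:
        raise VariogramFitError(
            f"{kind} variogram fit did not converge (status {best.status})", model
        )
    return VariogramFit(model, wsse, len(h), starts_tried=n_starts)
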