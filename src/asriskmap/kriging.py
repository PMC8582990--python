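"""Ordinary kriging (OK): best linear unbiased spatial prediction.

The OK estimate at a target location x0 is Z*(x0) = sum_i lambda_i Z(x_i),
with weights solving the augmented semivariogram system

    [ Gamma  1 ] [ lambda ]   [ gamma0 ]
    [ 1^T    0 ] [ mu     ] = [ 1      ]

where Gamma_ij = gamma(|x_i - x_j|), gamma0_i = gamma(|x_i - x0|) and mu is
the Lagrange multiplier enforcing sum lambda_i = 1 (unbiasedness).  With the
gamma(0) = 0 convention the predictor is exact at sampled locations.

All samples enter the system (global neighborhood): at survey scale (a few
hundred wells) the dense solve is trivial, and a search neighborhood would
only add a discontinuity to the map.  Prediction over a grid factorizes the
left-hand side once and back-substitutes all cell centers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import lu_factor, lu_solve

from .variogram import VariogramModel, model_gamma


class KrigingError(RuntimeError):
    pass


@dataclass(frozen=True)
class KrigingResult:
    """OK prediction at one location."""

    estimate: float               # Z*(x0), log10 concentration
    weights: np.ndarray           # lambda_i, sum to 1
    lagrange_multiplier: float    # mu
    kriging_variance: float       # model-based error variance, >= 0


def _dedupe(xy: np.ndarray, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average samples sharing exact coordinates (duplicates make the OK
    system singular; household wells can share a recorded location)."""
    df = pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1], "z": z})
    g = df.groupby(["x", "y"], sort=False, as_index=False)["z"].mean()
    if len(g) < len(df):
        warnings.warn(
            f"averaged {len(df) - len(g)} duplicate-coordinate sample(s) before kriging",
            stacklevel=3,
        )
    return g[["x", "y"]].to_numpy(), g["z"].to_numpy()


def _ok_lhs(xy: np.ndarray, model: VariogramModel) -> np.ndarray:
    n = len(xy)
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
    a = np.empty((n + 1, n + 1))
    a[:n, :n] = model_gamma(model, d)
    a[n, :n] = a[:n, n] = 1.0
    a[n, n] = 0.0
    return a


def _factorize(a: np.ndarray, model: VariogramModel):
    n = a.shape[0] - 1
    for jitter in (0.0, 1e-12, 1e-9):
        aj = a.copy()
        aj[np.arange(n), np.arange(n)] += jitter
        try:
            lu, piv = lu_factor(aj)
            if np.any(np.abs(np.diag(lu)) < 1e-300):
                continue
            return lu, piv
        except Exception:
            continue
    raise KrigingError(
        "ordinary kriging system singular after regularization — duplicate or "
        f"collinear sample configuration under variogram {model.to_dict()}"
    )


def ok_predict(samples, target, model: VariogramModel) -> KrigingResult:
    """Ordinary-kriging prediction at a single target location.

    ``samples`` is an (n, 3) array-like of (x, y, z) rows; z is normally a
    log10 concentration.  Duplicate coordinates are averaged first.
    """
    s = np.asarray(samples, dtype=float)
    if s.ndim != 2 or s.shape[1] != 3:
        raise ValueError("samples must be (n, 3) rows of (x, y, z)")
    if len(s) < 1:
        raise ValueError("need at least one sample")
    xy, z = _dedupe(s[:, :2], s[:, 2])
    est, var, w, mu = _predict_many(xy, z, np.asarray(target, float)[None, :], model)
    return KrigingResult(
        estimate=float(est[0]),
        weights=w[:, 0],
        lagrange_multiplier=float(mu[0]),
        kriging_variance=float(var[0]),
    )


def _predict_many(xy, z, targets, model):
    n = len(xy)
    lu_piv = _factorize(_ok_lhs(xy, model), model)
    d0 = np.linalg.norm(xy[:, None, :] - targets[None, :, :], axis=-1)  # (n, m)
    rhs = np.vstack([model_gamma(model, d0), np.ones((1, len(targets)))])
    sol = lu_solve(lu_piv, rhs)  # (n+1, m)
    w, mu = sol[:n], sol[n]
    est = w.T @ z
    var = np.einsum("nm,nm->m", w, model_gamma(model, d0)) + mu
    var = np.where((var < 0) & (var > -1e-8), 0.0, var)
    return est, var, w, mu


def ok_predict_points(samples, targets, model: VariogramModel):
    """Vectorized OK at many targets; returns (estimates, kriging variances).

    One factorization of the sample system serves every target.
    """
    s = np.asarray(samples, dtype=float)
    xy, z = _dedupe(s[:, :2], s[:, 2])
    targets = np.asarray(targets, dtype=float)
    est, var, _, _ = _predict_many(xy, z, targets, model)
    return est, var


def ok_map(samples, grid, model: VariogramModel):
    """Krige every cell center of ``grid``; returns a ConcentrationGrid with
    ``log10_est`` (log10 ug/L), back-transformed ``conc_ugL`` and
    ``kriging_variance`` layers."""
    from .grids import ConcentrationGrid

    cx, cy = grid.cell_centers()
    targets = np.column_stack([cx.ravel(), cy.ravel()])
    est, var = ok_predict_points(samples, targets, model)
    shape = cx.shape
    g = ConcentrationGrid(grid)
    g.add_layer("log10_est", est.reshape(shape))
    g.add_layer("conc_ugL", (10.0 ** est).reshape(shape))
    g.add_layer("kriging_variance", var.reshape(shape))
    return g
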