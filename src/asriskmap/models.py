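"""Model / Results interface over the two spatial interpolators.

Mirrors the fit-then-inspect workflow of mainstream statistical packages:
a model object is built from a well table, ``fit()`` returns a results
object carrying the estimates and diagnostics, and ``summary()`` renders a
readable table.  Prediction and mapping hang off the results.

>>> model = KrigingModel(wells)                      # doctest: +SKIP
>>> res = model.fit()
>>> print(res.summary())
>>> grid_est = res.predict_grid(make_grid(wells))
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import kriging, variogram
from .bpnn import NetworkSpec, TrainConfig, TrainedNetwork, fit_network
from .grids import ConcentrationGrid, GridSpec
from .preprocess import log_transform
from .synthetic import validate_wells


def _table(title: str, rows: list[tuple[str, str]]) -> str:
    width = max(len(k) for k, _ in rows) + 2
    lines = [title, "=" * max(len(title), width + 18)]
    lines += [f"{k:<{width}}{v}" for k, v in rows]
    return "\n".join(lines)


class KrigingModel:
    """Ordinary kriging of log10 concentration with a fitted variogram.

    Parameters
    ----------
    wells : DataFrame with columns ``well_id, x, y, conc_ugL, censored``.
    kind : variogram model family, default "exponential".
    """

    def __init__(self, wells: pd.DataFrame, kind: str = "exponential"):
        self.wells = validate_wells(wells)
        self.kind = kind
        self.endog = log_transform(wells["conc_ugL"])
        self.exog = wells[["x", "y"]].to_numpy(float)

    @classmethod
    def from_csv(cls, path, kind: str = "exponential") -> "KrigingModel":
        from .grids import read_wells

        return cls(read_wells(path), kind)

    def fit(self, bin_width=None, max_lag=None, min_pairs: int = 30) -> "KrigingResults":
        emp = variogram.empirical_semivariogram(
            self.exog, self.endog, bin_width=bin_width, max_lag=max_lag,
            min_pairs=min_pairs,
        )
        vfit = variogram.fit_model(emp, self.kind)
        return KrigingResults(self, emp, vfit)


@dataclass
class KrigingResults:
    """Fitted variogram plus the kriging predictor built on it."""

    model: KrigingModel
    empirical: variogram.EmpiricalVariogram
    vfit: variogram.VariogramFit

    @property
    def variogram_model(self) -> variogram.VariogramModel:
        return self.vfit.model

    @property
    def params(self) -> pd.Series:
        vm = self.vfit.model
        return pd.Series(
            {"nugget": vm.nugget, "partial_sill": vm.partial_sill,
             "range_m": vm.range_},
            name=vm.kind,
        )

    def predict(self, targets, return_variance: bool = False):
        """OK estimate of log10 concentration at (m, 2) target coordinates."""
        samples = np.column_stack([self.model.exog, self.model.endog])
        est, var = kriging.ok_predict_points(samples, targets, self.vfit.model)
        return (est, var) if return_variance else est

    def predict_grid(self, grid: GridSpec) -> ConcentrationGrid:
        samples = np.column_stack([self.model.exog, self.model.endog])
        return kriging.ok_map(samples, grid, self.vfit.model)

    def summary(self) -> str:
        vm = self.vfit.model
        rows = [
            ("Model:", f"ordinary kriging ({vm.kind} variogram)"),
            ("No. wells:", str(len(self.model.wells))),
            ("Nugget c0:", f"{vm.nugget:.6g} (log10 ug/L)^2"),
            ("Partial sill c:", f"{vm.partial_sill:.6g} (log10 ug/L)^2"),
            ("Sill c0+c:", f"{vm.sill:.6g} (log10 ug/L)^2"),
            ("Range a:", f"{vm.range_:.6g} m"),
            ("Weighted SSE:", f"{self.vfit.weighted_sse:.6g}"),
            ("Lag bins used:", str(self.vfit.n_bins)),
            ("Range identifiable:", str(self.vfit.range_identifiable)),
        ]
        return _table("Ordinary Kriging Results", rows)

    def plot_variogram(self, ax=None):
        """Empirical semivariogram with the fitted curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        emp = self.empirical
        ax.plot(emp.lag_centers, emp.gamma, "o", label="empirical")
        h = np.linspace(0, emp.lag_centers[-1], 200)
        ax.plot(h, variogram.model_gamma(self.vfit.model, h), "-",
                label=f"{self.vfit.model.kind} fit")
        ax.set_xlabel("lag h (m)")
        ax.set_ylabel(r"$\gamma(h)$ (log10 ug/L)$^2$")
        ax.legend()
        return ax


class NeuralFieldModel:
    """Coordinate-to-log10-concentration network regressor.

    Parameters
    ----------
    wells : DataFrame with the standard well schema.
    layer_sizes : network structure, default (2, 10, 10, 1).
    config : LM training configuration.
    """

    def __init__(self, wells: pd.DataFrame, layer_sizes=(2, 10, 10, 1),
                 config: TrainConfig = TrainConfig()):
        self.wells = validate_wells(wells)
        self.spec = NetworkSpec(tuple(layer_sizes))
        self.config = config
        self.endog = log_transform(wells["conc_ugL"])
        self.exog = wells[["x", "y"]].to_numpy(float)

    @classmethod
    def from_csv(cls, path, layer_sizes=(2, 10, 10, 1),
                 config: TrainConfig = TrainConfig()) -> "NeuralFieldModel":
        from .grids import read_wells

        return cls(read_wells(path), layer_sizes, config)

    def fit(self, restarts: int = 3, seed: int | None = None) -> "NeuralFieldResults":
        cfg = self.config
        if seed is not None:
            from dataclasses import replace

            cfg = replace(cfg, seed=seed)
        net = fit_network(self.exog, self.endog, self.spec, cfg, restarts=restarts)
        return NeuralFieldResults(self, net)


@dataclass
class NeuralFieldResults:
    model: NeuralFieldModel
    network: TrainedNetwork

    @property
    def history(self):
        return self.network.history

    def predict(self, targets) -> np.ndarray:
        """Network estimate of log10 concentration at raw coordinates."""
        return self.network.predict(targets)

    def predict_grid(self, grid: GridSpec) -> ConcentrationGrid:
        cx, cy = grid.cell_centers()
        est = self.predict(np.column_stack([cx.ravel(), cy.ravel()]))
        g = ConcentrationGrid(grid)
        g.add_layer("log10_est", est.reshape(cx.shape))
        g.add_layer("conc_ugL", (10.0 ** est).reshape(cx.shape))
        return g

    def summary(self) -> str:
        h = self.network.history
        rows = [
            ("Model:", f"BPNN {self.model.spec} (tanh hidden, linear output)"),
            ("No. wells:", str(len(self.model.wells))),
            ("Training:", "Levenberg-Marquardt, full batch"),
            ("Final training mse:", f"{h.final_mse:.6g} (log10 ug/L)^2"),
            ("Epochs:", str(h.n_epochs)),
            ("Converged (mse goal):", str(h.converged)),
            ("mse goal:", f"{self.model.config.mse_goal:g}"),
        ]
        return _table("Neural Field Regression Results", rows)
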