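"""Ordinary kriging of soil properties to quadrat centers and PCA to a
fertility axis (PC1).

The variogram families supported are spherical and exponential, both with a
nugget. Kriging uses a global neighbourhood by default (every sample weighs
in at every target), which is exact and cheap at desk-scale sample counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

from plotcarbon.core_data import SOIL_PROPERTIES, PlotGrid

DEFAULT_ORIENT_POSITIVE = ["total_n", "organic_matter", "water_content"]


@dataclass
class VariogramModel:
    """Fitted isotropic semivariogram gamma(h).

    gamma(0) = 0 by convention; the nugget applies for h > 0.
    """

    family: str
    nugget: float
    psill: float
    range_: float
    bins: np.ndarray = field(default=None, repr=False)
    gamma_hat: np.ndarray = field(default=None, repr=False)
    pair_counts: np.ndarray = field(default=None, repr=False)
    weighted_sse: float = float("nan")

    def __post_init__(self):
        if self.family not in ("spherical", "exponential"):
            raise ValueError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0 or self.psill <= 0 or self.range_ <= 0:
            raise ValueError("require nugget >= 0, partial sill > 0, range > 0")

    @property
    def sill(self) -> float:
        return self.nugget + self.psill

    def __call__(self, h) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        g = _gamma(h, self.family, self.nugget, self.psill, self.range_)
        return g

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "nugget": float(self.nugget),
            "psill": float(self.psill),
            "range": float(self.range_),
            "weighted_sse": float(self.weighted_sse),
        }


def _gamma(h, family, nugget, psill, rng):
    h = np.asarray(h, dtype=float)
    out = np.zeros_like(h)
    pos = h > 0
    if family == "spherical":
        hr = np.minimum(h[pos] / rng, 1.0)
        out[pos] = nugget + psill * (1.5 * hr - 0.5 * hr**3)
    else:  # exponential; rng is the practical range (gamma ~ 95% sill there)
        out[pos] = nugget + psill * (1.0 - np.exp(-3.0 * h[pos] / rng))
    return out


def empirical_variogram(
    coords: np.ndarray,
    values: np.ndarray,
    n_bins: int = 15,
    max_lag: float | None = None,
) -> pd.DataFrame:
    """Binned empirical semivariogram.

    gamma_hat(h_k) is the mean of 0.5*(z_i - z_j)^2 over sample pairs whose
    separation falls in lag bin k. Empty bins are dropped with a warning.

    Returns a DataFrame with columns ``lag`` (bin midpoint), ``gamma``,
    ``n_pairs``.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError(f"need at least 2 samples for a variogram, got {n}")
    if n < 10:
        warnings.warn(f"only {n} samples; empirical variogram will be noisy", stacklevel=2)
    iu = np.triu_indices(n, k=1)
    d = cdist(coords, coords)[iu]
    sv = 0.5 * (values[:, None] - values[None, :])[iu] ** 2
    if max_lag is None:
        max_lag = d.max() / 2.0
    keep = (d > 0) & (d <= max_lag)
    d, sv = d[keep], sv[keep]
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    idx = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    rows = []
    n_empty = 0
    for k in range(n_bins):
        in_bin = idx == k
        cnt = int(in_bin.sum())
        if cnt == 0:
            n_empty += 1
            continue
        rows.append(
            {"lag": 0.5 * (edges[k] + edges[k + 1]), "gamma": sv[in_bin].mean(), "n_pairs": cnt}
        )
    if n_empty:
        warnings.warn(f"{n_empty} empty lag bin(s) dropped", stacklevel=2)
    return pd.DataFrame(rows)


def fit_variogram(binned: pd.DataFrame, family: str = "spherical") -> VariogramModel:
    """Weighted least-squares fit of a variogram model to binned semivariances.

    Residuals are weighted by sqrt(pair count). A flat empirical variogram
    drives the range to its upper bound, which is reported with a warning.
    """
    if len(binned) < 3:
        raise ValueError("need at least 3 nonempty lag bins to fit a variogram")
    lags = binned["lag"].to_numpy(float)
    gammas = binned["gamma"].to_numpy(float)
    counts = binned["n_pairs"].to_numpy(float)
    w = np.sqrt(counts)
    gmax = max(gammas.max(), 1e-12)
    lmax = lags.max()

    def resid(theta):
        nugget, psill, rng = theta
        return w * (_gamma(lags, family, nugget, psill, rng) - gammas)

    x0 = np.array([0.1 * gmax, 0.9 * gmax, 0.5 * lmax])
    lower = np.array([0.0, 1e-10 * gmax, 1e-3 * lmax])
    upper = np.array([2.0 * gmax, 3.0 * gmax, 4.0 * lmax])
    sol = least_squares(resid, x0, bounds=(lower, upper))
    if not sol.success:
        raise RuntimeError(f"variogram fit did not converge: {sol.message}")
    nugget, psill, rng = sol.x
    if (
        rng >= 0.999 * upper[2]
        or rng <= 1.05 * lags.min()
        or psill <= max(2.0 * lower[1], 1e-6 * gmax)
    ):
        warnings.warn(
            "degenerate variogram fit: range estimate outside the resolvable "
            "lag window (flat empirical variogram?)",
            stacklevel=2,
        )
    model = VariogramModel(family, nugget, psill, rng)
    model.bins = lags
    model.gamma_hat = gammas
    model.pair_counts = counts
    model.weighted_sse = float(np.sum(resid(sol.x) ** 2))
    return model


def _dedupe(coords: np.ndarray, values: np.ndarray):
    """Average values at duplicate sample locations (singular system guard)."""
    key = [tuple(np.round(c, 9)) for c in coords]
    df = pd.DataFrame({"key": key, "v": values, "x": coords[:, 0], "y": coords[:, 1]})
    if df["key"].duplicated().any():
        warnings.warn("duplicate sample locations averaged before kriging", stacklevel=3)
        agg = df.groupby("key", sort=False).mean(numeric_only=True)
        return agg[["x", "y"]].to_numpy(), agg["v"].to_numpy()
    return coords, values


def ordinary_krige(
    coords: np.ndarray,
    values: np.ndarray,
    model: VariogramModel,
    targets: np.ndarray,
    return_weights: bool = False,
):
    """Ordinary kriging of point samples to target locations.

    Solves, for each target, the semivariance system augmented with the
    unbiasedness constraint (Lagrange multiplier); the resulting weights sum
    to 1 and predictions are exact at sample locations.

    Returns ``(predictions, kriging_variances)`` and, if requested, the
    (n_targets, n_samples) weight matrix.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    targets = np.asarray(targets, dtype=float)
    coords, values = _dedupe(coords, values)
    n = len(values)

    A = np.empty((n + 1, n + 1))
    A[:n, :n] = model(cdist(coords, coords))
    A[n, :n] = 1.0
    A[:n, n] = 1.0
    A[n, n] = 0.0

    B = np.empty((n + 1, len(targets)))
    g0 = model(cdist(coords, targets))
    B[:n] = g0
    B[n] = 1.0

    sol = np.linalg.solve(A, B)
    weights = sol[:n]  # (n_samples, n_targets)
    mu = sol[n]
    preds = weights.T @ values
    krig_var = np.maximum(np.sum(weights * g0, axis=0) + mu, 0.0)
    if return_weights:
        return preds, krig_var, weights.T
    return preds, krig_var


def krige_property_to_quadrats(
    samples: pd.DataFrame,
    prop: str,
    grid: PlotGrid,
    family: str = "spherical",
    n_bins: int = 15,
) -> tuple[np.ndarray, VariogramModel]:
    """Fit a variogram for one soil property and krige it to quadrat centers."""
    coords = samples[["x", "y"]].to_numpy(float)
    values = samples[prop].to_numpy(float)
    max_lag = 0.5 * np.hypot(grid.plot_width, grid.plot_height)
    emp = empirical_variogram(coords, values, n_bins=n_bins, max_lag=max_lag)
    model = fit_variogram(emp, family=family)
    preds, _ = ordinary_krige(coords, values, model, grid.centers())
    return preds, model


def krige_all_properties(
    samples: pd.DataFrame,
    grid: PlotGrid,
    family: str = "spherical",
    properties: list[str] = SOIL_PROPERTIES,
) -> tuple[pd.DataFrame, dict[str, VariogramModel]]:
    """Krige every soil property to quadrat centers.

    Returns (per-quadrat property table indexed by quadrat_id, fitted models).
    """
    out = {}
    models = {}
    for prop in properties:
        out[prop], models[prop] = krige_property_to_quadrats(
            samples, prop, grid, family=family
        )
    table = pd.DataFrame(out, index=pd.Index(range(grid.n_quadrats), name="quadrat_id"))
    return table, models


@dataclass
class PCAResult:
    scores: pd.DataFrame           # quadrat x component
    loadings: pd.DataFrame         # variable x component
    explained_variance_ratio: np.ndarray

    @property
    def pc1(self) -> pd.Series:
        return self.scores["PC1"]


def soil_pca(
    table: pd.DataFrame,
    orient_positive: list[str] = DEFAULT_ORIENT_POSITIVE,
) -> PCAResult:
    """PCA of z-scored soil properties, PC1 oriented toward fertility.

    PC1's sign is flipped if needed so that the mean loading over
    ``orient_positive`` (default: total N, organic matter, water content) is
    positive — high PC1 then means high fertility.
    """
    if len(table) < 2:
        raise ValueError("PCA needs at least 2 quadrats")
    if table.isna().any().any():
        raise ValueError("soil table has missing values")
    std = table.std(ddof=1)
    dead = std[std == 0].index.tolist()
    if dead:
        raise ValueError(f"zero-variance soil column(s): {dead}")
    z = (table - table.mean()) / std
    pca = PCA()
    scores = pca.fit_transform(z.to_numpy())
    loadings = pca.components_.T  # variable x component
    names = [f"PC{k + 1}" for k in range(scores.shape[1])]
    scores = pd.DataFrame(scores, index=table.index, columns=names)
    loadings = pd.DataFrame(loadings, index=table.columns, columns=names)

    orient = [c for c in orient_positive if c in loadings.index]
    if orient and loadings.loc[orient, "PC1"].mean() < 0:
        scores["PC1"] = -scores["PC1"]
        loadings["PC1"] = -loadings["PC1"]
    return PCAResult(scores, loadings, pca.explained_variance_ratio_)
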