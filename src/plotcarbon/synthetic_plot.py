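"""Seeded generator of complete synthetic plots with known ground truth.

Stands in for an undeposited forest census: terrain, a ~30 m soil sampling
design with satellite points, a species pool with correlated traits, and a
stem map whose species occurrences respond to terrain convexity and a latent
soil-fertility field through configured log-odds coefficients. Every stage
is deterministic under a fixed seed, and the realized coefficients are
recorded so downstream estimates can be checked against truth.

Spatially autocorrelated surfaces are sums of randomly placed Gaussian
kernels (an analytic, seedable stand-in for a Gaussian-process draw whose
variogram is still well-behaved for kriging).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from plotcarbon import terrain as terrain_mod
from plotcarbon.core_data import SOIL_PROPERTIES, TRAIT_NAMES, ElevationGrid, PlotGrid

# Fixed loadings mapping the scalar latent fertility field to the nine soil
# properties: positive for nutrients / organic matter / water, sign of pH
# configurable via pH_loading.
_BASE_SOIL_MEANS = {
    "total_n": 1.2, "total_p": 0.30, "total_k": 20.0,
    "avail_n": 0.12, "avail_p": 0.004, "avail_k": 0.08,
    "organic_matter": 35.0, "water_content": 22.0, "ph": 4.2,
}
_BASE_SOIL_LOADINGS = {
    "total_n": 0.35, "total_p": 0.08, "total_k": 4.0,
    "avail_n": 0.035, "avail_p": 0.0012, "avail_k": 0.02,
    "organic_matter": 10.0, "water_content": 4.5, "ph": -0.25,
}


@dataclass
class TraitConfig:
    """Marginal lognormal means/CVs per trait and a log-scale correlation."""

    means: dict = field(
        default_factory=lambda: {
            "la": 45.0, "sla": 150.0, "ldmc": 0.38, "wd": 0.55, "max_dbh": 30.0
        }
    )
    cvs: dict = field(
        default_factory=lambda: {
            "la": 0.9, "sla": 0.35, "ldmc": 0.15, "wd": 0.25, "max_dbh": 0.8
        }
    )
    # correlation among log-traits, order TRAIT_NAMES; default: acquisitive
    # LA-SLA go together and trade off against LDMC/WD
    correlation: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [1.00, 0.40, -0.30, -0.30, 0.10],
                [0.40, 1.00, -0.50, -0.40, 0.00],
                [-0.30, -0.50, 1.00, 0.40, 0.00],
                [-0.30, -0.40, 0.40, 1.00, 0.20],
                [0.10, 0.00, 0.00, 0.20, 1.00],
            ]
        )
    )


@dataclass
class SyntheticConfig:
    """Everything needed to realize one synthetic plot."""

    plot_width: float = 400.0
    plot_height: float = 500.0
    quadrat_size: float = 20.0
    n_species: int = 40

    # terrain
    n_hills: int = 6
    hill_height: float = 80.0
    hill_width: float = 120.0
    terrain_noise_amp: float = 8.0
    terrain_noise_kernels: int = 40
    terrain_noise_width: float = 40.0
    alt_min: float = 230.0
    alt_max: float = 470.0

    # soil sampling design and latent fertility field
    soil_grid_spacing: float = 30.0
    satellite_distances: tuple = (2.0, 5.0, 15.0)
    n_satellites: int = 2
    fertility_kernels: int = 25
    fertility_range: float = 100.0
    soil_noise_cv: float = 0.10
    ph_loading: float = -0.25

    # species pool
    traits: TraitConfig = field(default_factory=TraitConfig)

    # habitat filtering: per-species log-odds of occurrence per SD of
    # convexity / fertility. Either explicit arrays (n_species,) or a
    # coupling {"trait": name, "strength": s} giving beta_j = s * z(trait_j).
    beta_conv: object = 0.0
    beta_soil: object = 0.0
    base_occupancy: float = 0.25      # occurrence probability at average habitat
    mean_stems_per_occurrence: float = 4.0
    dbh_weibull_shape: float = 0.9
    dbh_weibull_scale: float = 4.0

    seed: int = 0

    def grid(self) -> PlotGrid:
        return PlotGrid(self.plot_width, self.plot_height, self.quadrat_size)


@dataclass
class GroundTruth:
    """Realized generator state sufficient to predict downstream signs."""

    beta_conv: np.ndarray            # per-species log-odds per SD convexity
    beta_soil: np.ndarray            # per-species log-odds per SD fertility
    fertility_quadrat: np.ndarray    # latent fertility at quadrat centers (z)
    convexity_quadrat: np.ndarray    # convexity used for placement (z-scored)
    species_ids: list
    seed: int

    def to_dict(self) -> dict:
        return {
            "beta_conv": np.asarray(self.beta_conv).tolist(),
            "beta_soil": np.asarray(self.beta_soil).tolist(),
            "fertility_quadrat": np.asarray(self.fertility_quadrat).tolist(),
            "convexity_quadrat": np.asarray(self.convexity_quadrat).tolist(),
            "species_ids": list(self.species_ids),
            "seed": self.seed,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


class _KernelField:
    """Sum of Gaussian kernels: an analytic random smooth surface."""

    def __init__(self, rng, width, height, n_kernels, kernel_width, amplitude):
        self.cx = rng.uniform(-0.2 * width, 1.2 * width, n_kernels)
        self.cy = rng.uniform(-0.2 * height, 1.2 * height, n_kernels)
        self.amp = rng.normal(0.0, amplitude, n_kernels)
        self.w = kernel_width

    def __call__(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)[..., None]
        y = np.asarray(y, dtype=float)[..., None]
        d2 = (x - self.cx) ** 2 + (y - self.cy) ** 2
        return np.sum(self.amp * np.exp(-0.5 * d2 / self.w**2), axis=-1)


def generate_terrain(cfg: SyntheticConfig, seed: int | None = None) -> ElevationGrid:
    """Analytic hill-plus-noise surface sampled at corners and centers.

    Corner and center altitudes are evaluated from the same surface, then
    affinely rescaled so corner altitudes span [alt_min, alt_max].
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    grid = cfg.grid()

    hills = None
    if cfg.n_hills > 0:
        hills = {
            "cx": rng.uniform(0, cfg.plot_width, cfg.n_hills),
            "cy": rng.uniform(0, cfg.plot_height, cfg.n_hills),
            "h": rng.uniform(0.4, 1.0, cfg.n_hills) * cfg.hill_height,
            "w": rng.uniform(0.6, 1.4, cfg.n_hills) * cfg.hill_width,
        }
    noise = None
    if cfg.terrain_noise_amp > 0:
        noise = _KernelField(
            rng, cfg.plot_width, cfg.plot_height,
            cfg.terrain_noise_kernels, cfg.terrain_noise_width, cfg.terrain_noise_amp,
        )

    def surface(x, y):
        z = np.zeros(np.broadcast(np.asarray(x), np.asarray(y)).shape, dtype=float)
        if hills is not None:
            xx = np.asarray(x, dtype=float)[..., None]
            yy = np.asarray(y, dtype=float)[..., None]
            d2 = (xx - hills["cx"]) ** 2 + (yy - hills["cy"]) ** 2
            z = z + np.sum(hills["h"] * np.exp(-0.5 * d2 / hills["w"] ** 2), axis=-1)
        if noise is not None:
            z = z + noise(x, y)
        return z

    s = grid.quadrat_size
    ix = np.arange(grid.n_qx + 1) * s
    jy = np.arange(grid.n_qy + 1) * s
    gx, gy = np.meshgrid(ix, jy)
    corners = surface(gx, gy)

    ctr = grid.centers()
    centers = surface(ctr[:, 0], ctr[:, 1]).reshape(grid.n_qy, grid.n_qx)

    lo, hi = corners.min(), corners.max()
    if hi > lo:
        scale = (cfg.alt_max - cfg.alt_min) / (hi - lo)
        corners = cfg.alt_min + (corners - lo) * scale
        centers = cfg.alt_min + (centers - lo) * scale
    else:  # flat surface
        corners = np.full_like(corners, cfg.alt_min)
        centers = np.full_like(centers, cfg.alt_min)
    return ElevationGrid(grid, corners, centers)


def _fertility_field(cfg: SyntheticConfig, rng) -> _KernelField:
    return _KernelField(
        rng, cfg.plot_width, cfg.plot_height,
        cfg.fertility_kernels, cfg.fertility_range / 2.0, 1.0,
    )


def generate_soil_samples(
    cfg: SyntheticConfig, seed: int | None = None
) -> tuple[pd.DataFrame, _KernelField]:
    """Soil sampling design plus correlated property values.

    Base points sit on a ``soil_grid_spacing`` lattice (offset half a
    spacing from the origin); each gets ``n_satellites`` satellites at a
    distance drawn from ``satellite_distances`` in a uniform random compass
    direction, clipped into the plot. The nine properties are fixed
    loadings on a smooth latent fertility field plus independent noise.

    Returns (sample table, latent fertility field).
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    sp = cfg.soil_grid_spacing
    bx = np.arange(sp / 2, cfg.plot_width, sp)
    by = np.arange(sp / 2, cfg.plot_height, sp)
    gx, gy = np.meshgrid(bx, by)
    base = np.column_stack([gx.ravel(), gy.ravel()])

    pts = [base]
    for _ in range(cfg.n_satellites):
        dist = rng.choice(np.asarray(cfg.satellite_distances, dtype=float), len(base))
        theta = rng.uniform(0, 2 * np.pi, len(base))
        sat = base + np.column_stack([dist * np.cos(theta), dist * np.sin(theta)])
        pts.append(sat)
    xy = np.vstack(pts)
    eps = 1e-6
    xy[:, 0] = np.clip(xy[:, 0], 0.0, cfg.plot_width - eps)
    xy[:, 1] = np.clip(xy[:, 1], 0.0, cfg.plot_height - eps)

    fert = _fertility_field(cfg, rng)
    f = fert(xy[:, 0], xy[:, 1])
    fsd = f.std()
    fz = (f - f.mean()) / fsd if fsd > 0 else np.zeros_like(f)

    data = {"sample_id": [f"S{i:04d}" for i in range(len(xy))], "x": xy[:, 0], "y": xy[:, 1]}
    for prop in SOIL_PROPERTIES:
        mean = _BASE_SOIL_MEANS[prop]
        loading = cfg.ph_loading if prop == "ph" else _BASE_SOIL_LOADINGS[prop]
        noise = rng.normal(0.0, cfg.soil_noise_cv * abs(mean), len(xy))
        data[prop] = mean + loading * fz + noise
    return pd.DataFrame(data), fert


def generate_species_pool(cfg: SyntheticConfig, seed: int | None = None) -> pd.DataFrame:
    """Species pool with positive, correlated traits.

    Traits are multivariate lognormal: a Gaussian copula on the log scale
    with the configured correlation matrix and marginal mean/CV per trait.
    LDMC is capped just below 1 to respect its ratio definition.
    """
    if cfg.n_species < 1:
        raise ValueError("n_species must be >= 1")
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    tc = cfg.traits
    corr = np.asarray(tc.correlation, dtype=float)
    if corr.shape != (5, 5) or not np.allclose(corr, corr.T):
        raise ValueError("trait correlation must be a symmetric 5x5 matrix")
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() <= 1e-10:
        raise ValueError("trait correlation matrix is not positive-definite")

    sigmas = np.array(
        [np.sqrt(np.log(1.0 + tc.cvs[t] ** 2)) for t in TRAIT_NAMES]
    )
    mus = np.array(
        [np.log(tc.means[t]) - 0.5 * sigmas[k] ** 2 for k, t in enumerate(TRAIT_NAMES)]
    )
    cov = corr * np.outer(sigmas, sigmas)
    logs = rng.multivariate_normal(mus, cov, size=cfg.n_species, method="cholesky")
    vals = np.exp(logs)
    vals[:, TRAIT_NAMES.index("ldmc")] = np.minimum(
        vals[:, TRAIT_NAMES.index("ldmc")], 0.99
    )
    vals[:, TRAIT_NAMES.index("max_dbh")] = np.maximum(
        vals[:, TRAIT_NAMES.index("max_dbh")], 2.0
    )
    pool = pd.DataFrame(vals, columns=TRAIT_NAMES)
    pool.insert(0, "species_id", [f"sp{i:03d}" for i in range(cfg.n_species)])
    return pool


def _resolve_beta(spec, pool: pd.DataFrame, n_species: int) -> np.ndarray:
    """Expand a beta spec (scalar | array | trait coupling) to per-species."""
    if isinstance(spec, dict):
        trait = spec["trait"]
        strength = float(spec["strength"])
        x = pool[trait].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        return strength * z
    arr = np.asarray(spec, dtype=float)
    if arr.ndim == 0:
        return np.full(n_species, float(arr))
    if arr.shape != (n_species,):
        raise ValueError("per-species beta array has wrong length")
    return arr


def _truncated_weibull(rng, shape, scale, lo, hi, size):
    """Inverse-CDF sample of a Weibull truncated to [lo, hi)."""
    lo = np.broadcast_to(np.asarray(lo, dtype=float), (size,))
    hi = np.broadcast_to(np.asarray(hi, dtype=float), (size,))
    F = lambda x: 1.0 - np.exp(-((x / scale) ** shape))
    u = rng.uniform(F(lo), np.maximum(F(hi), F(lo) + 1e-12))
    u = np.clip(u, 1e-12, 1 - 1e-12)
    return scale * (-np.log1p(-u)) ** (1.0 / shape)


def generate_stem_map(
    elev: ElevationGrid,
    fertility: _KernelField,
    pool: pd.DataFrame,
    cfg: SyntheticConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Place stems quadrat by quadrat under logistic habitat filtering.

    Per quadrat q and species j the occurrence probability is
    logit^-1( logit(base_occupancy) + beta_conv_j * conv_z(q)
              + beta_soil_j * fert_z(q) ); occupied cells draw
    1 + Poisson(mean_stems_per_occurrence - 1) stems, each with a DBH from
    a species-specific Weibull truncated to [1 cm, max_dbh].
    """
    rng = np.random.default_rng(cfg.seed + 3 if seed is None else seed)
    grid = cfg.grid()
    n_sp = len(pool)
    nq = grid.n_quadrats

    conv = terrain_mod.convexity(elev)["convexity"].to_numpy()
    csd = conv.std(ddof=1)
    conv_z = (conv - conv.mean()) / csd if csd > 0 else np.zeros_like(conv)

    ctr = grid.centers()
    f = fertility(ctr[:, 0], ctr[:, 1])
    fsd = f.std(ddof=1)
    fert_z = (f - f.mean()) / fsd if fsd > 0 else np.zeros_like(f)

    b_conv = _resolve_beta(cfg.beta_conv, pool, n_sp)
    b_soil = _resolve_beta(cfg.beta_soil, pool, n_sp)

    logit0 = np.log(cfg.base_occupancy / (1.0 - cfg.base_occupancy))
    eta = logit0 + np.outer(conv_z, b_conv) + np.outer(fert_z, b_soil)  # (nq, nsp)
    p_occ = 1.0 / (1.0 + np.exp(-eta))

    occ = rng.uniform(size=(nq, n_sp)) < p_occ
    counts = np.zeros((nq, n_sp), dtype=int)
    lam = max(cfg.mean_stems_per_occurrence - 1.0, 0.0)
    counts[occ] = 1 + rng.poisson(lam, size=int(occ.sum()))

    q_idx, s_idx = np.nonzero(counts)
    reps = counts[q_idx, s_idx]
    stem_q = np.repeat(q_idx, reps)
    stem_s = np.repeat(s_idx, reps)
    n_stems = len(stem_q)

    qrow, qcol = grid.rowcol(stem_q)
    s = grid.quadrat_size
    x = (qcol + rng.uniform(size=n_stems)) * s
    y = (qrow + rng.uniform(size=n_stems)) * s

    max_dbh = pool["max_dbh"].to_numpy(dtype=float)[stem_s]
    dbh = _truncated_weibull(
        rng, cfg.dbh_weibull_shape, cfg.dbh_weibull_scale, 1.0, max_dbh, n_stems
    )
    dbh = np.clip(dbh, 1.0, max_dbh)

    stems = pd.DataFrame(
        {
            "stem_id": [f"t{i:06d}" for i in range(n_stems)],
            "x": np.minimum(x, grid.plot_width - 1e-9),
            "y": np.minimum(y, grid.plot_height - 1e-9),
            "species_id": pool["species_id"].to_numpy()[stem_s],
            "dbh": dbh,
        }
    )
    truth = GroundTruth(
        beta_conv=b_conv,
        beta_soil=b_soil,
        fertility_quadrat=fert_z,
        convexity_quadrat=conv_z,
        species_ids=pool["species_id"].tolist(),
        seed=cfg.seed if seed is None else seed,
    )
    return stems, truth


def generate_plot(cfg: SyntheticConfig):
    """Realize a full plot: terrain, soils, pool, stems, ground truth."""
    elev = generate_terrain(cfg)
    soils, fert = generate_soil_samples(cfg)
    pool = generate_species_pool(cfg)
    stems, truth = generate_stem_map(elev, fert, pool, cfg)
    return elev, soils, pool, stems, truth


def config_from_dict(d: dict) -> SyntheticConfig:
    """Build a SyntheticConfig from a plain (e.g. YAML-loaded) mapping."""
    d = dict(d)
    tc = d.pop("traits", None)
    cfg_fields = {f.name for f in dataclasses.fields(SyntheticConfig)}
    unknown = set(d) - cfg_fields
    if unknown:
        raise ValueError(f"unknown synthetic-config key(s): {sorted(unknown)}")
    if tc is not None:
        tc = dict(tc)
        if "correlation" in tc:
            tc["correlation"] = np.asarray(tc["correlation"], dtype=float)
        d["traits"] = TraitConfig(**tc)
    return SyntheticConfig(**d)
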