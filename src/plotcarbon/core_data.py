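"""Data model, file I/O, quadrat assignment and community-matrix construction.

Coordinate convention: the plot is the half-open rectangle
[0, width) x [0, height); quadrats tile it in half-open cells
[k*s, (k+1)*s) so every in-bounds point belongs to exactly one quadrat.
Quadrat ids are row-major from the origin: id = col + n_qx * row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STEM_COLUMNS = ["stem_id", "x", "y", "species_id", "dbh"]
TRAIT_COLUMNS = ["species_id", "la", "sla", "ldmc", "wd", "max_dbh"]
TRAIT_NAMES = ["la", "sla", "ldmc", "wd", "max_dbh"]
SOIL_PROPERTIES = [
    "total_n", "total_p", "total_k",
    "avail_n", "avail_p", "avail_k",
    "organic_matter", "water_content", "ph",
]

DBH_CENSUS_MIN_CM = 1.0


class FormatError(ValueError):
    """A file is structurally unusable (e.g. missing a required column)."""


class ValidationError(ValueError):
    """A record violates a data invariant."""


@dataclass(frozen=True)
class PlotGrid:
    """Regular quadrat grid over a rectangular plot.

    Parameters
    ----------
    plot_width, plot_height : float
        Plot dimensions in metres (x spans width, y spans height).
    quadrat_size : float
        Side of the square quadrats in metres (default 20).
    """

    plot_width: float
    plot_height: float
    quadrat_size: float = 20.0

    def __post_init__(self) -> None:
        if self.plot_width <= 0 or self.plot_height <= 0 or self.quadrat_size <= 0:
            raise ValueError("plot dimensions and quadrat size must be positive")
        for dim, name in ((self.plot_width, "plot_width"), (self.plot_height, "plot_height")):
            n = dim / self.quadrat_size
            if abs(n - round(n)) > 1e-9:
                raise ValueError(
                    f"{name}={dim} is not divisible by quadrat_size={self.quadrat_size}"
                )

    @property
    def n_qx(self) -> int:
        return round(self.plot_width / self.quadrat_size)

    @property
    def n_qy(self) -> int:
        return round(self.plot_height / self.quadrat_size)

    @property
    def n_quadrats(self) -> int:
        return self.n_qx * self.n_qy

    @property
    def quadrat_area_ha(self) -> float:
        return self.quadrat_size**2 / 10_000.0

    def quadrat_id(self, row: np.ndarray | int, col: np.ndarray | int):
        """Linear id from (row, col); row indexes y, col indexes x."""
        return np.asarray(col) + self.n_qx * np.asarray(row)

    def rowcol(self, quadrat_id: np.ndarray | int):
        qid = np.asarray(quadrat_id)
        return qid // self.n_qx, qid % self.n_qx

    def centers(self) -> np.ndarray:
        """(n_quadrats, 2) array of quadrat-center coordinates, id order."""
        s = self.quadrat_size
        cols = np.arange(self.n_qx)
        rows = np.arange(self.n_qy)
        cc, rr = np.meshgrid(cols, rows)
        return np.column_stack([(cc.ravel() + 0.5) * s, (rr.ravel() + 0.5) * s])


@dataclass
class ElevationGrid:
    """Corner-lattice altitudes with optional quadrat-center altitudes.

    ``corners[j, i]`` is the altitude (m) at lattice node (x = i*s, y = j*s),
    shape (n_qy + 1, n_qx + 1). ``centers[row, col]``, if given, holds the
    measured/generated altitude at each quadrat center, shape (n_qy, n_qx).
    """

    grid: PlotGrid
    corners: np.ndarray
    centers: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.corners = np.asarray(self.corners, dtype=float)
        expected = (self.grid.n_qy + 1, self.grid.n_qx + 1)
        if self.corners.shape != expected:
            raise ValueError(
                f"corner lattice shape {self.corners.shape} != expected {expected}"
            )
        if not np.all(np.isfinite(self.corners)):
            raise ValidationError("corner lattice contains non-finite altitudes")
        if self.centers is not None:
            self.centers = np.asarray(self.centers, dtype=float)
            if self.centers.shape != (self.grid.n_qy, self.grid.n_qx):
                raise ValueError("center altitude shape does not match quadrat grid")
            if not np.all(np.isfinite(self.centers)):
                raise ValidationError("center altitudes contain non-finite values")


@dataclass
class ValidationReport:
    """Row-level rejections from stem-table reading, by reason."""

    below_census_threshold: pd.DataFrame = field(default_factory=pd.DataFrame)
    out_of_bounds: pd.DataFrame = field(default_factory=pd.DataFrame)
    invalid_values: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_rejected(self) -> int:
        return (
            len(self.below_census_threshold)
            + len(self.out_of_bounds)
            + len(self.invalid_values)
        )


def read_stem_table(path, grid: PlotGrid | None = None):
    """Read and validate a stem table CSV.

    Columns: stem_id,x,y,species_id,dbh. Rows with dbh below the 1 cm census
    threshold, non-numeric fields, or (when ``grid`` is given) coordinates
    outside the half-open plot bounds are rejected and reported.

    Returns
    -------
    (stems, report) : (pandas.DataFrame, ValidationReport)
    """
    raw = pd.read_csv(path, dtype={"stem_id": str, "species_id": str})
    missing = [c for c in STEM_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"stem table missing required column(s): {missing}")
    raw = raw[list(raw.columns)]
    report = ValidationReport()

    numeric = raw.copy()
    for col in ("x", "y", "dbh"):
        numeric[col] = pd.to_numeric(numeric[col], errors="coerce")
    bad_numeric = numeric[["x", "y", "dbh"]].isna().any(axis=1)
    bad_species = numeric["species_id"].isna() | (numeric["species_id"].astype(str).str.strip() == "")
    invalid = bad_numeric | bad_species
    report.invalid_values = raw.loc[invalid]
    stems = numeric.loc[~invalid].copy()

    below = stems["dbh"] < DBH_CENSUS_MIN_CM
    report.below_census_threshold = stems.loc[below]
    stems = stems.loc[~below]

    if grid is not None:
        oob = (
            (stems["x"] < 0)
            | (stems["x"] >= grid.plot_width)
            | (stems["y"] < 0)
            | (stems["y"] >= grid.plot_height)
        )
        report.out_of_bounds = stems.loc[oob]
        stems = stems.loc[~oob]

    return stems.reset_index(drop=True), report


def write_stem_table(stems: pd.DataFrame, path) -> None:
    stems[[c for c in STEM_COLUMNS if c in stems.columns]].to_csv(path, index=False)


def read_trait_table(path) -> pd.DataFrame:
    """Read the per-species trait table (la, sla, ldmc, wd, max_dbh)."""
    traits = pd.read_csv(path, dtype={"species_id": str})
    missing = [c for c in TRAIT_COLUMNS if c not in traits.columns]
    if missing:
        raise FormatError(f"trait table missing required column(s): {missing}")
    if traits["species_id"].duplicated().any():
        dupes = traits.loc[traits["species_id"].duplicated(), "species_id"].tolist()
        raise ValidationError(f"duplicate species in trait table: {dupes}")
    vals = traits[TRAIT_NAMES].to_numpy(dtype=float)
    if not np.all(vals > 0):
        raise ValidationError("trait values must all be positive")
    if (traits["ldmc"] > 1).any():
        raise ValidationError("ldmc (dry mass / fresh mass) cannot exceed 1")
    return traits.reset_index(drop=True)


def write_trait_table(traits: pd.DataFrame, path) -> None:
    traits[TRAIT_COLUMNS].to_csv(path, index=False)


def read_elevation(path, grid: PlotGrid, centers_path=None) -> ElevationGrid:
    """Read corner altitudes (columns i,j,altitude) and optional centers
    (columns row,col,altitude) into an ElevationGrid."""
    df = pd.read_csv(path)
    for col in ("i", "j", "altitude"):
        if col not in df.columns:
            raise FormatError(f"elevation file missing column {col!r}")
    corners = np.full((grid.n_qy + 1, grid.n_qx + 1), np.nan)
    corners[df["j"].to_numpy(int), df["i"].to_numpy(int)] = df["altitude"].to_numpy(float)
    if np.isnan(corners).any():
        n = int(np.isnan(corners).sum())
        raise ValidationError(f"elevation lattice incomplete: {n} corner(s) missing")
    centers = None
    if centers_path is not None:
        cdf = pd.read_csv(centers_path)
        centers = np.full((grid.n_qy, grid.n_qx), np.nan)
        centers[cdf["row"].to_numpy(int), cdf["col"].to_numpy(int)] = cdf[
            "altitude"
        ].to_numpy(float)
        if np.isnan(centers).any():
            raise ValidationError("center-altitude table incomplete")
    return ElevationGrid(grid, corners, centers)


def write_elevation(elev: ElevationGrid, path, centers_path=None) -> None:
    jj, ii = np.indices(elev.corners.shape)
    pd.DataFrame(
        {"i": ii.ravel(), "j": jj.ravel(), "altitude": elev.corners.ravel()}
    ).to_csv(path, index=False)
    if centers_path is not None and elev.centers is not None:
        rr, cc = np.indices(elev.centers.shape)
        pd.DataFrame(
            {"row": rr.ravel(), "col": cc.ravel(), "altitude": elev.centers.ravel()}
        ).to_csv(centers_path, index=False)


def read_soil_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str})
    required = ["sample_id", "x", "y"] + SOIL_PROPERTIES
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"soil sample table missing column(s): {missing}")
    return df


def assign_quadrats(stems: pd.DataFrame, grid: PlotGrid) -> pd.DataFrame:
    """Assign every stem to its quadrat by floor division of coordinates.

    Adds ``qrow``, ``qcol`` and linear ``quadrat_id`` columns. Raises
    ValidationError naming the offending stems if any coordinate falls
    outside [0, width) x [0, height).
    """
    x = stems["x"].to_numpy(dtype=float)
    y = stems["y"].to_numpy(dtype=float)
    oob = (x < 0) | (x >= grid.plot_width) | (y < 0) | (y >= grid.plot_height)
    if oob.any():
        bad = stems.loc[oob, "stem_id"].tolist()[:20]
        raise ValidationError(f"stems outside plot bounds: {bad}")
    out = stems.copy()
    out["qcol"] = np.floor(x / grid.quadrat_size).astype(int)
    out["qrow"] = np.floor(y / grid.quadrat_size).astype(int)
    out["quadrat_id"] = grid.quadrat_id(out["qrow"].to_numpy(), out["qcol"].to_numpy())
    return out


def community_matrix(stems: pd.DataFrame, grid: PlotGrid | None = None) -> pd.DataFrame:
    """Quadrat x species stem-count matrix.

    With ``grid`` supplied, all quadrats appear as rows (empty quadrats are
    all-zero); otherwise only quadrats holding at least one stem appear.
    """
    if "quadrat_id" not in stems.columns:
        raise ValueError("stems must carry quadrat_id; call assign_quadrats first")
    mat = (
        stems.groupby(["quadrat_id", "species_id"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    if grid is not None:
        mat = mat.reindex(range(grid.n_quadrats), fill_value=0)
    mat.columns.name = "species_id"
    mat.index.name = "quadrat_id"
    return mat.astype(int)
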