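"""Per-stem aboveground biomass (moist-forest allometry in DBH and wood
density) and per-quadrat aboveground carbon storage in Mg C ha^-1."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from plotcarbon.core_data import PlotGrid

#: moist-forest allometry coefficients for AGB(kg) = WD * exp(poly(ln DBH))
_A0, _A1, _A2, _A3 = -1.499, 2.148, 0.207, -0.0281

DEFAULT_CARBON_FRACTION = 0.5


def agb_moist(dbh, wd):
    """Aboveground biomass (kg) of a stem from the moist-forest allometry.

    AGB = WD * exp(-1.499 + 2.148 ln D + 0.207 (ln D)^2 - 0.0281 (ln D)^3)

    with DBH in cm and wood density WD in g cm^-3. Linear in WD and
    strictly increasing in DBH over the census range.
    """
    dbh = np.asarray(dbh, dtype=float)
    wd = np.asarray(wd, dtype=float)
    if np.any(dbh <= 0) or np.any(wd <= 0):
        raise ValueError("dbh and wd must be positive")
    ln_d = np.log(dbh)
    out = wd * np.exp(_A0 + _A1 * ln_d + _A2 * ln_d**2 + _A3 * ln_d**3)
    return float(out) if out.ndim == 0 else out


@dataclass
class CarbonResult:
    stem_agb: pd.Series            # kg, indexed like the stem table
    quadrat_agb: pd.Series         # kg summed per quadrat
    c_storage: pd.Series           # Mg C ha^-1 per quadrat
    carbon_fraction: float
    imputed_wd: float | None       # WD used for trait-missing species, if any
    imputed_species: list


def quadrat_carbon(
    stems: pd.DataFrame,
    traits: pd.DataFrame,
    grid: PlotGrid,
    carbon_fraction: float = DEFAULT_CARBON_FRACTION,
    impute_wd: bool = True,
) -> CarbonResult:
    """Quadrat aboveground carbon storage.

    C(q) [Mg C ha^-1] = sum of stem AGB (kg) in q  x  carbon_fraction
    / 1000 / quadrat area (ha). Stems of species without a measured wood
    density get the plot-abundance-weighted mean WD when ``impute_wd`` is
    on; otherwise the missing species are reported in an error.
    """
    if "quadrat_id" not in stems.columns:
        raise ValueError("stems must carry quadrat_id; call assign_quadrats first")
    if not 0 < carbon_fraction <= 1:
        raise ValueError("carbon_fraction must be in (0, 1]")

    wd_map = traits.set_index("species_id")["wd"]
    wd = stems["species_id"].map(wd_map)
    missing = wd.isna()
    imputed_species: list = []
    imputed_wd = None
    if missing.any():
        imputed_species = sorted(stems.loc[missing, "species_id"].unique())
        if not impute_wd:
            raise ValueError(
                f"no wood density for species {imputed_species} and imputation disabled"
            )
        # abundance-weighted plot mean over trait-covered stems
        imputed_wd = float(wd[~missing].mean())
        wd = wd.fillna(imputed_wd)
        warnings.warn(
            f"imputed WD={imputed_wd:.3f} g/cm3 for {len(imputed_species)} species",
            stacklevel=2,
        )

    agb = pd.Series(
        agb_moist(stems["dbh"].to_numpy(), wd.to_numpy()),
        index=stems.index,
        name="agb_kg",
    )
    quadrat_agb = (
        agb.groupby(stems["quadrat_id"]).sum().reindex(range(grid.n_quadrats), fill_value=0.0)
    )
    quadrat_agb.index.name = "quadrat_id"
    c_storage = quadrat_agb * carbon_fraction / 1000.0 / grid.quadrat_area_ha
    c_storage.name = "c_storage"
    return CarbonResult(
        stem_agb=agb,
        quadrat_agb=quadrat_agb.rename("agb_kg"),
        c_storage=c_storage,
        carbon_fraction=carbon_fraction,
        imputed_wd=imputed_wd,
        imputed_species=imputed_species,
    )
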