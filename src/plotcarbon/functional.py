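"""Functional dominance (community-weighted means) and functional dispersion.

CWM_i = sum_j a_j x_ij / sum_j a_j, the abundance-weighted mean trait value
of the species present in a quadrat. FDis is the abundance-weighted mean
distance z_j of species to the abundance-weighted trait centroid c:

    c_i = sum_j a_j x_ij / sum_j a_j
    FDis = sum_j a_j z_j / sum_j a_j,   z_j = || x_j - c ||

Abundance is the stem count (never basal area or biomass, to keep trait
structure independent of the carbon response). Species missing from the
trait table are excluded from both indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from plotcarbon.core_data import TRAIT_NAMES


@dataclass
class FDisResult:
    """Per-quadrat dispersion values plus the pieces used to compute them."""

    values: pd.Series               # FDis per quadrat
    centroids: pd.DataFrame         # quadrat x trait weighted centroid
    richness: pd.Series             # trait-covered species with a_j > 0
    trait_set: tuple
    standardize: str                # "none" | "zscore" | "range"


def _align(community: pd.DataFrame, traits: pd.DataFrame, trait_cols):
    """Restrict the community matrix to trait-covered species and return
    (abundance array, trait-value matrix) in matching species order."""
    covered = [s for s in community.columns if s in set(traits["species_id"])]
    sub = community[covered]
    tmat = (
        traits.set_index("species_id")
        .loc[covered, list(trait_cols)]
        .to_numpy(dtype=float)
    )
    return sub.to_numpy(dtype=float), tmat, covered


def _standardize(tmat: np.ndarray, mode: str) -> np.ndarray:
    if mode == "none":
        return tmat
    if mode == "zscore":
        sd = tmat.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        return (tmat - tmat.mean(axis=0)) / sd
    if mode == "range":  # Gower-style range scaling over the species pool
        rng = tmat.max(axis=0) - tmat.min(axis=0)
        rng[rng == 0] = 1.0
        return (tmat - tmat.min(axis=0)) / rng
    raise ValueError(f"unknown standardization mode {mode!r}")


def weighted_centroid(abundances: np.ndarray, trait_matrix: np.ndarray) -> np.ndarray:
    """Abundance-weighted centroid c of species trait vectors."""
    a = np.asarray(abundances, dtype=float)
    x = np.atleast_2d(np.asarray(trait_matrix, dtype=float))
    if x.shape[0] != a.shape[0]:
        x = x.T
    total = a.sum()
    if total <= 0:
        raise ValueError("centroid undefined: all abundances are zero")
    return (a @ x) / total


def cwm(community: pd.DataFrame, traits: pd.DataFrame, trait: str) -> pd.Series:
    """Community-weighted mean of one trait per quadrat.

    Quadrats with no trait-covered stems get NaN (with a warning) and are
    excluded downstream.
    """
    if trait not in TRAIT_NAMES:
        raise ValueError(f"unknown trait {trait!r}; expected one of {TRAIT_NAMES}")
    ab, tmat, _ = _align(community, traits, [trait])
    totals = ab.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (ab @ tmat[:, 0]) / totals
    n_empty = int((totals == 0).sum())
    if n_empty:
        warnings.warn(
            f"{n_empty} quadrat(s) with no trait-covered stems -> CWM is NaN",
            stacklevel=2,
        )
    return pd.Series(out, index=community.index, name=f"{trait}_cwm")


def fdis(
    community: pd.DataFrame,
    traits: pd.DataFrame,
    trait_set,
    standardize: str = "none",
) -> FDisResult:
    """Functional dispersion per quadrat over the given trait set.

    With a single trait and ``standardize="none"`` this is the
    abundance-weighted mean absolute deviation from the weighted mean.
    Standardization statistics (z-score or range) are computed over the full
    species pool in the trait table, not per quadrat.
    """
    trait_set = tuple(trait_set)
    if not trait_set:
        raise ValueError("trait_set must not be empty")
    ab, tmat, covered = _align(community, traits, trait_set)
    tmat = _standardize(tmat, standardize)
    totals = ab.sum(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        centroids = (ab @ tmat) / totals[:, None]       # quadrat x trait
        # z[q, j] = distance of species j to quadrat q's centroid
        diff = tmat[None, :, :] - centroids[:, None, :]
        z = np.sqrt(np.sum(diff**2, axis=2))
        values = np.sum(ab * z, axis=1) / totals

    richness = (ab > 0).sum(axis=1)
    values[(totals > 0) & (richness <= 1)] = 0.0        # single species -> 0
    n_empty = int((totals == 0).sum())
    if n_empty:
        warnings.warn(
            f"{n_empty} quadrat(s) with no trait-covered stems -> FDis is NaN",
            stacklevel=2,
        )
    name = "_".join(trait_set) + "_fdis" if len(trait_set) == 1 else "multi_fdis"
    return FDisResult(
        values=pd.Series(values, index=community.index, name=name),
        centroids=pd.DataFrame(centroids, index=community.index, columns=trait_set),
        richness=pd.Series(richness, index=community.index, name="richness"),
        trait_set=trait_set,
        standardize=standardize,
    )


def multivariate_fdis(community: pd.DataFrame, traits: pd.DataFrame) -> FDisResult:
    """FDis over all five traits, z-scored across the species pool."""
    return fdis(community, traits, TRAIT_NAMES, standardize="zscore")
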