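"""Standardized seed-production summaries with CV-based weights.

Individual standardized production (ISP, g seed per m² of tree basal
area) averages a tree's posterior mean fecundities over years with
weights w = f̂/s (the inverse coefficient of variation): low, noisy
estimates matter less than large, precise ones.  Species (SSP), group
(GSP) and community (CSP, per ha of forest floor) summaries aggregate
ISP upward.  The seeds-per-gram benchmark converts the trade-off
regression intercept into expected seeds per m² basal area for a
1-g-seeded species, with a second-order Taylor correction for intercept
uncertainty.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import basal_area

__all__ = [
    "tree_isp",
    "isp_table",
    "species_ssp",
    "group_gsp",
    "plot_csp",
    "seeds_per_gram_benchmark",
    "worked_example_production",
]

log = logging.getLogger(__name__)

LN10 = math.log(10.0)


def _cv_weights(fhat: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Inverse-CV weights w = f̂/s.  Years with f̂ = 0 get weight 0;
    s = 0 with f̂ > 0 gets the 99th percentile of the finite weights
    (the weight is unbounded as s → 0)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(fhat > 0, fhat / se, 0.0)
    inf_mask = ~np.isfinite(w)
    finite = w[np.isfinite(w) & (w > 0)]
    cap = np.percentile(finite, 99) if len(finite) else 1.0
    w[inf_mask] = cap
    return w


def tree_isp(
    posterior_rows: pd.DataFrame, seed_mass: float, basal_area_m2: float
) -> tuple[float, float]:
    """ISP for one tree from its tree-year posterior rows
    (columns fhat, se): (m/b)·Σw f̂/Σw with w = f̂/s.

    Returns (ISP in g·m⁻², tree-level CV = s_tree/f̂_tree of the
    weighted mean).  Raises if every year is degenerate (all f̂ = 0).
    """
    if seed_mass <= 0:
        raise ValueError("seed mass must be positive")
    if basal_area_m2 <= 0:
        raise ValueError("basal area must be positive")
    fhat = posterior_rows["fhat"].to_numpy(dtype=float)
    se = posterior_rows["se"].to_numpy(dtype=float)
    w = _cv_weights(fhat, se)
    if w.sum() == 0:
        raise ValueError("all years degenerate (fhat = 0); ISP undefined")
    fbar = float(np.sum(w * fhat) / np.sum(w))
    # uncertainty of the weighted mean, from the per-year standard errors
    s_tree = float(np.sqrt(np.sum((w * se) ** 2)) / np.sum(w))
    isp = seed_mass / basal_area_m2 * fbar
    cv = s_tree / fbar if fbar > 0 else np.nan
    return isp, cv


def isp_table(
    posterior: pd.DataFrame,
    trees,
    seed_mass: dict[str, float],
    maturity_threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-tree ISP over all trees with a usable posterior.

    Only trees whose posterior maturation probability exceeds the
    threshold in at least one year are included (the analysis concerns
    mature trees); excluded or degenerate trees are logged, not raised.

    Returns columns tree_id, species, stand_id, plot_area_ha, isp, cv,
    weight (= 1/cv), n_years, sum_se2 (Σ_t s²_t, for group SEs).
    """
    by_id = {t.tree_id: t for t in trees}
    rows = []
    for tree_id, grp in posterior.groupby("tree_id", sort=True):
        tree = by_id.get(str(tree_id))
        if tree is None:
            log.info("tree %s absent from inventory; skipped", tree_id)
            continue
        if "maturity_prob" in grp.columns and not (
            grp["maturity_prob"] > maturity_threshold
        ).any():
            log.info("tree %s never exceeds maturity threshold; excluded", tree_id)
            continue
        m = seed_mass.get(tree.species)
        if m is None:
            log.info("tree %s: no seed mass for %s; excluded", tree_id, tree.species)
            continue
        last_year = int(grp["year"].max())
        b = basal_area(tree.diameter_by_year[last_year]) if tree.diameter_by_year else None
        try:
            isp, cv = tree_isp(grp, m, b)
        except ValueError as e:
            log.info("tree %s excluded: %s", tree_id, e)
            continue
        rows.append(
            {
                "tree_id": str(tree_id),
                "species": tree.species,
                "stand_id": tree.stand_id,
                "plot_area_ha": tree.plot_area,
                "isp": isp,
                "cv": cv,
                "weight": (1.0 / cv) if cv and np.isfinite(cv) and cv > 0 else np.nan,
                "n_years": len(grp),
                "sum_se2": float(np.sum(grp["se"].to_numpy() ** 2)),
            }
        )
    return pd.DataFrame(rows)


def _fill_weights(tab: pd.DataFrame) -> np.ndarray:
    w = tab["weight"].to_numpy(dtype=float)
    finite = w[np.isfinite(w) & (w > 0)]
    cap = np.percentile(finite, 99) if len(finite) else 1.0
    return np.where(np.isfinite(w) & (w > 0), w, cap)


def species_ssp(isp: pd.DataFrame) -> pd.DataFrame:
    """Species seed production: inverse-CV-weighted mean of ISP over the
    trees of each species.  Species with no eligible tree are absent
    (logged).  Downstream analyses use log10(SSP)."""
    rows = []
    for sp, grp in isp.groupby("species", sort=True):
        if len(grp) == 0:
            log.info("species %s: no eligible trees", sp)
            continue
        w = _fill_weights(grp)
        ssp = float(np.sum(w * grp["isp"].to_numpy()) / np.sum(w))
        rows.append({"species": str(sp), "ssp": ssp, "n_trees": len(grp)})
    return pd.DataFrame(rows)


def group_gsp(isp: pd.DataFrame, membership: dict[str, str]) -> pd.DataFrame:
    """Group seed production with uncertainty.

    ``membership`` maps species to a group label (e.g. angiosperm /
    gymnosperm, Pinales, Fagales, fleshy-fruited, other).  GSP is the
    weighted mean of member ISP; its standard error is
    (1/n_k)·sqrt(Σ_t s²) with n_k the number of tree-year observations
    in the group.  An empty group is an error.
    """
    tab = isp.copy()
    tab["group"] = tab["species"].map(membership)
    if tab["group"].isna().any():
        missing = sorted(tab.loc[tab["group"].isna(), "species"].unique())
        raise ValueError(f"species without group membership: {missing}")
    rows = []
    for g, grp in tab.groupby("group", sort=True):
        if len(grp) == 0:
            raise ValueError(f"group {g} is empty")
        w = _fill_weights(grp)
        gsp = float(np.sum(w * grp["isp"].to_numpy()) / np.sum(w))
        n_k = int(grp["n_years"].sum())
        se = math.sqrt(float(grp["sum_se2"].sum())) / n_k
        rows.append({"group": str(g), "gsp": gsp, "se": se, "n": n_k})
    return pd.DataFrame(rows)


def plot_csp(isp: pd.DataFrame) -> pd.DataFrame:
    """Community seed production per plot: CSP_j = (1/A_j)·Σ ISP over
    the plot's trees, in g per ha of forest floor.  Plots without a
    known area are skipped with a log entry."""
    rows = []
    for stand, grp in isp.groupby("stand_id", sort=True):
        area = grp["plot_area_ha"].dropna().unique()
        if len(area) == 0:
            log.info("plot %s: missing area; skipped", stand)
            continue
        rows.append(
            {
                "stand_id": str(stand),
                "csp": float(grp["isp"].sum() / area[0]),
                "plot_area_ha": float(area[0]),
                "n_trees": len(grp),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# benchmark conversions from the trade-off regression


def seeds_per_gram_benchmark(
    alpha_hat: float, s_alpha: float
) -> tuple[float, float]:
    """Expected seeds per m² basal area for a 1-g-seeded species.

    For intercept estimate α̂ with standard error s_α on the log10
    scale, two Taylor terms give
    E(10^α) ≈ 10^α̂·(1 + s_α²l²/2) ± 10^α̂·s_α·l with l = ln 10.
    Returns (expectation, half-width).
    """
    if s_alpha < 0:
        raise ValueError("s_alpha must be nonnegative")
    scale = 10.0**alpha_hat
    return scale * (1.0 + (s_alpha * LN10) ** 2 / 2.0), scale * s_alpha * LN10


@dataclass
class WorkedYield:
    seed_mass_yield_g: float
    seed_number: float


def worked_example_production(
    diameter_cm: float,
    seed_mass_g: float,
    alpha_hat: float = 4.29,
    beta_hat: float = 0.546,
    s_alpha: float = 0.065,
) -> WorkedYield:
    """Annual seed-mass yield and seed number for a tree of given
    diameter and species seed mass, from the fitted power law
    SSP = E(10^α)·m^β g·m⁻² times basal area π(d/200)² m².

    The intercept uses the Taylor-corrected expectation of 10^α (see
    :func:`seeds_per_gram_benchmark`); pass ``s_alpha=0`` for the plain
    plug-in power law.
    """
    if seed_mass_g <= 0:
        raise ValueError("seed mass must be positive")
    if diameter_cm <= 0:
        raise ValueError("diameter must be positive")
    expectation, _ = seeds_per_gram_benchmark(alpha_hat, s_alpha)
    ssp = expectation * seed_mass_g**beta_hat  # g per m² basal area
    ba = math.pi * (diameter_cm / 200.0) ** 2
    yield_g = ssp * ba
    return WorkedYield(seed_mass_yield_g=yield_g, seed_number=yield_g / seed_mass_g)
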