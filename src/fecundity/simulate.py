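"""Forward generative model for tree fecundity worlds.

Generates inventories, latent maturation/fecundity trajectories,
seed-trap counts, crop counts, phylogenies and traits with the
statistical structure the inference model assumes:

* size-dependent absorbing maturation (probit hazard in diameter),
* log-linear conditional fecundity with lognormal individual effects,
  quasi-synchronous year effects shared within species × ecoregion
  groups, and lognormal process noise,
* a fat-tailed (2Dt) seed shadow onto point traps with Poisson counts,
  optionally identified only to genus,
* beta-binomial crop counts around a reported crop-fraction estimate,
* Brownian-motion traits on a random phylogeny with tunable λ.

Every stage takes an explicit numpy Generator; stages draw from
independent child streams spawned from one root seed so that, e.g.,
adding trees does not perturb trap-count draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import TrapRecord, TreeRecord, CropCountRecord
from .phylo import lambda_transform, phylo_covariance, simulate_phylogeny

__all__ = [
    "StandConfig",
    "GenerativeParams",
    "LatentTruth",
    "simulate_stand",
    "place_traps",
    "simulate_maturation",
    "simulate_fecundity",
    "dispersal_kernel",
    "simulate_trap_counts",
    "simulate_crop_counts",
    "simulate_phylogeny",
    "simulate_trait",
    "simulate_world",
    "World",
]


@dataclass
class StandConfig:
    """One simulated stand: layout, species pool, habitat and climate."""

    n_trees: int = 50
    n_years: int = 10
    start_year: int = 2001
    stand_id: str = "S1"
    ecoregion: str = "R1"
    plot_area_ha: float = 1.0
    extent_m: float = 100.0
    species_probs: dict[str, float] = field(
        default_factory=lambda: {"Alpha_one": 1.0}
    )
    cec: float = 15.0                 # cmol(+)/kg, constant within stand
    temp_mean: float = 10.0           # °C site mean
    temp_anomaly_sd: float = 1.0
    moisture_mean: float = 200.0      # mm site-mean deficit
    moisture_anomaly_sd: float = 40.0
    slope_deg: float = 10.0
    aspect_deg: float = 180.0
    diameter_init_mean_cm: float = 25.0
    diameter_init_sd_log: float = 0.35
    diameter_min_cm: float = 5.0
    diameter_max_cm: float = 120.0
    growth_cm_yr: float = 0.3


@dataclass
class GenerativeParams:
    """Parameters of the generative model.

    ``beta_psi`` maps covariate names (matching covariate-table columns,
    plus ``"intercept"``) to log-scale fixed effects; per-species values
    via ``beta_psi_by_species``.  Maturation is a probit hazard
    Φ(β0 + β1·d) applied while immature.  ``kernel_scale`` is the 2Dt
    scale u in m².
    """

    beta_rho: tuple[float, float] = (-3.0, 0.15)
    beta_psi: dict[str, float] = field(
        default_factory=lambda: {"intercept": 6.0, "diameter_cm": 0.02}
    )
    beta_psi_by_species: dict[str, dict[str, float]] | None = None
    tau_ind: float = 0.3
    tau_yr: float = 0.5
    sigma: float = 0.4
    kernel_scale: float = 100.0
    nu: float = 50.0                  # beta-binomial concentration
    genus_id_prob: float = 0.0
    seed_mass: dict[str, float] = field(default_factory=dict)
    seeds_per_structure: float = 1.0
    genus_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.tau_ind, self.tau_yr, self.sigma) < 0:
            raise ValueError("standard deviations must be nonnegative")
        if self.kernel_scale <= 0:
            raise ValueError("kernel scale must be positive")

    def psi_coefs(self, species: str) -> dict[str, float]:
        if self.beta_psi_by_species and species in self.beta_psi_by_species:
            return self.beta_psi_by_species[species]
        return self.beta_psi

    def genus(self, species: str) -> str:
        return self.genus_of.get(species, species.split("_")[0])


@dataclass
class LatentTruth:
    """Latent truth per tree-year: maturation state ρ, conditional
    fecundity ψ and realized fecundity f = ρψ, plus the drawn random
    effects (for test oracles)."""

    table: pd.DataFrame   # tree_id, species, stand_id, group, year, mature, log_psi, psi, fecundity
    ind_effects: dict[str, float]
    year_effects: dict[tuple[str, int], float]


def simulate_stand(
    config: StandConfig, rng: np.random.Generator
) -> tuple[list[TreeRecord], pd.DataFrame]:
    """Simulate one stand's inventory and covariate table.

    Diameters grow monotonically; shade class follows local crowding
    (neighbour count within 15 m mapped to quantile classes 1..5); CEC is
    constant within the stand; climate anomalies are centered per site.
    """
    if config.n_trees < 1:
        raise ValueError("n_trees must be at least 1")
    n, T = config.n_trees, config.n_years
    years = np.arange(config.start_year, config.start_year + T)
    xy = rng.uniform(0, config.extent_m, size=(n, 2))
    species_names = list(config.species_probs)
    probs = np.array([config.species_probs[s] for s in species_names], dtype=float)
    probs /= probs.sum()
    species = rng.choice(species_names, size=n, p=probs)

    d0 = np.clip(
        config.diameter_init_mean_cm
        * np.exp(rng.normal(0, config.diameter_init_sd_log, n)),
        config.diameter_min_cm,
        config.diameter_max_cm,
    )
    growth = np.clip(rng.normal(config.growth_cm_yr, 0.1 * config.growth_cm_yr, n), 0.0, None)

    # crowding → shade: more close neighbours, deeper shade
    dist = np.hypot(xy[:, 0][:, None] - xy[:, 0], xy[:, 1][:, None] - xy[:, 1])
    crowding = (dist < 15.0).sum(axis=1) - 1
    ranks = pd.Series(crowding).rank(method="average", pct=True).to_numpy()
    shade = np.minimum(5, 1 + (ranks * 5).astype(int))

    t_anom = rng.normal(0, config.temp_anomaly_sd, T)
    t_anom -= t_anom.mean()
    m_anom = rng.normal(0, config.moisture_anomaly_sd, T)
    m_anom -= m_anom.mean()
    from .io import terrain_vector

    u1, u2, u3 = terrain_vector(config.slope_deg, config.aspect_deg)

    trees: list[TreeRecord] = []
    rows = []
    for i in range(n):
        diam = {int(y): float(d0[i] + growth[i] * k) for k, y in enumerate(years)}
        trees.append(
            TreeRecord(
                tree_id=f"{config.stand_id}-t{i + 1}",
                species=str(species[i]),
                genus=str(species[i]).split("_")[0],
                stand_id=config.stand_id,
                x=float(xy[i, 0]),
                y=float(xy[i, 1]),
                plot_area=config.plot_area_ha,
                diameter_by_year=diam,
                shade_by_year={int(y): int(shade[i]) for y in years},
            )
        )
        for k, y in enumerate(years):
            rows.append(
                {
                    "tree_id": trees[-1].tree_id,
                    "species": str(species[i]),
                    "stand_id": config.stand_id,
                    "ecoregion": config.ecoregion,
                    "year": int(y),
                    "intercept": 1.0,
                    "diameter_cm": diam[int(y)],
                    "diameter_cm_sq": diam[int(y)] ** 2,
                    "shade": int(shade[i]),
                    "cec": config.cec,
                    "t_site_mean": config.temp_mean,
                    "t_anomaly": float(t_anom[k]),
                    "m_site_mean": config.moisture_mean,
                    "m_anomaly": float(m_anom[k]),
                    "u1": u1,
                    "u2": u2,
                    "u3": u3,
                }
            )
    return trees, pd.DataFrame(rows)


def place_traps(
    config: StandConfig,
    n_traps: int,
    rng: np.random.Generator,
    collection_area: float = 0.5,
) -> list[TrapRecord]:
    """Scatter seed traps uniformly over the stand."""
    xy = rng.uniform(0, config.extent_m, size=(n_traps, 2))
    return [
        TrapRecord(
            trap_id=f"{config.stand_id}-trap{i + 1}",
            stand_id=config.stand_id,
            x=float(xy[i, 0]),
            y=float(xy[i, 1]),
            collection_area=collection_area,
        )
        for i in range(n_traps)
    ]


def simulate_maturation(
    trees: list[TreeRecord],
    params: GenerativeParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Absorbing maturation: while immature, the per-year transition
    probability is Φ(β0 + β1·d); once mature, always mature."""
    b0, b1 = params.beta_rho
    rows = []
    for tree in trees:
        mature = 0
        for year in tree.years:
            if not mature:
                p = norm.cdf(b0 + b1 * tree.diameter_by_year[year])
                if rng.random() < p:
                    mature = 1
            rows.append({"tree_id": tree.tree_id, "year": year, "mature": mature})
    return pd.DataFrame(rows)


def simulate_fecundity(
    trees: list[TreeRecord],
    states: pd.DataFrame,
    covariates: pd.DataFrame,
    params: GenerativeParams,
    rng: np.random.Generator,
) -> LatentTruth:
    """Conditional fecundity: log ψ = x'β + individual effect + year
    effect (shared within species × ecoregion group, centered within
    group) + Normal(0, σ²) noise; realized fecundity f = ρψ."""
    cov = covariates.merge(states, on=["tree_id", "year"], how="left", validate="1:1")
    if cov["mature"].isna().any():
        raise ValueError("maturation states missing for some tree-years")
    cov = cov.copy()
    cov["group"] = cov["species"].astype(str) + ":" + cov["ecoregion"].astype(str)

    # linear predictor from named coefficients
    eta = np.zeros(len(cov))
    needed: set[str] = set()
    for sp in cov["species"].unique():
        needed |= set(params.psi_coefs(sp))
    missing = [c for c in needed if c != "intercept" and c not in cov.columns]
    if missing:
        raise ValueError(f"design matrix incomplete; missing covariates {missing}")
    for sp, idx in cov.groupby("species").groups.items():
        coefs = params.psi_coefs(str(sp))
        sub = cov.loc[idx]
        e = np.zeros(len(sub))
        for name, beta in coefs.items():
            e += beta * (1.0 if name == "intercept" else sub[name].to_numpy())
        eta[cov.index.get_indexer(idx)] = e

    tree_ids = sorted({t.tree_id for t in trees})
    ind = {tid: float(rng.normal(0, params.tau_ind)) for tid in tree_ids}

    year_eff: dict[tuple[str, int], float] = {}
    for group, sub in cov.groupby("group"):
        yrs = sorted(sub["year"].unique())
        draws = rng.normal(0, params.tau_yr, len(yrs))
        draws -= draws.mean()  # centered within group
        for y, g in zip(yrs, draws):
            year_eff[(str(group), int(y))] = float(g)

    eps = rng.normal(0, params.sigma, len(cov))
    log_psi = (
        eta
        + cov["tree_id"].map(ind).to_numpy()
        + np.array([year_eff[(g, int(y))] for g, y in zip(cov["group"], cov["year"])])
        + eps
    )
    psi = np.exp(log_psi)
    out = cov[["tree_id", "species", "stand_id", "group", "year", "mature"]].copy()
    out["log_psi"] = log_psi
    out["psi"] = psi
    out["fecundity"] = out["mature"].to_numpy() * psi
    return LatentTruth(table=out, ind_effects=ind, year_effects=year_eff)


def dispersal_kernel(distance, u: float):
    """Isotropic 2Dt seed-shadow density (per m²) with shape p = 1:
    k(r) = u / (π (u + r²)²).  Integrates to one over the plane;
    k(0) = 1/(πu)."""
    if u <= 0:
        raise ValueError("kernel scale must be positive")
    r = np.asarray(distance, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance must be nonnegative")
    return u / (math.pi * (u + r**2) ** 2)


def _trap_intensities(
    trees: list[TreeRecord],
    truth: pd.DataFrame,
    traps: list[TrapRecord],
    kernel_scale: float,
) -> pd.DataFrame:
    """Expected seeds per trap-year-species: area · Σ_trees f · k(dist)."""
    tree_by_id = {t.tree_id: t for t in trees}
    rows = []
    for trap in traps:
        stand_trees = [t for t in trees if t.stand_id == trap.stand_id]
        k = {
            t.tree_id: dispersal_kernel(
                math.hypot(t.x - trap.x, t.y - trap.y), kernel_scale
            )
            for t in stand_trees
        }
        sub = truth[truth["tree_id"].isin(k.keys())]
        for (year, species), grp in sub.groupby(["year", "species"]):
            lam = trap.collection_area * sum(
                f * k[tid] for tid, f in zip(grp["tree_id"], grp["fecundity"])
            )
            rows.append(
                {
                    "trap_id": trap.trap_id,
                    "year": int(year),
                    "species": str(species),
                    "genus": tree_by_id[grp["tree_id"].iloc[0]].genus,
                    "intensity": lam,
                }
            )
    return pd.DataFrame(rows)


def simulate_trap_counts(
    trees: list[TreeRecord],
    truth: LatentTruth,
    traps: list[TrapRecord],
    params: GenerativeParams,
    rng: np.random.Generator,
) -> list[TrapRecord]:
    """Poisson seed counts in traps under the 2Dt seed shadow.

    With probability ``genus_id_prob`` a (trap, year, genus) count is
    recorded at genus level with congeneric intensities summed.  Traps
    outside the bounding box of their stand's trees trigger a warning.
    """
    import warnings

    for trap in traps:
        xs = [t.x for t in trees if t.stand_id == trap.stand_id]
        ys = [t.y for t in trees if t.stand_id == trap.stand_id]
        if xs and not (
            min(xs) <= trap.x <= max(xs) and min(ys) <= trap.y <= max(ys)
        ):
            warnings.warn(
                f"trap {trap.trap_id} outside the bounding box of stand "
                f"{trap.stand_id}", stacklevel=2
            )
    intens = _trap_intensities(trees, truth.table, traps, params.kernel_scale)
    out = [
        TrapRecord(
            trap_id=tr.trap_id,
            stand_id=tr.stand_id,
            x=tr.x,
            y=tr.y,
            collection_area=tr.collection_area,
            counts_by_year={},
        )
        for tr in traps
    ]
    by_id = {tr.trap_id: tr for tr in out}
    for (trap_id, year, genus), grp in intens.groupby(["trap_id", "year", "genus"]):
        rec = by_id[trap_id]
        if rng.random() < params.genus_id_prob:
            lam = grp["intensity"].sum()
            rec.counts_by_year[(int(year), str(genus), "genus")] = int(
                rng.poisson(lam)
            )
        else:
            for _, r in grp.iterrows():
                rec.counts_by_year[(int(year), str(r["species"]), "species")] = int(
                    rng.poisson(r["intensity"])
                )
    return out


def simulate_crop_counts(
    truth: LatentTruth,
    params: GenerativeParams,
    rng: np.random.Generator,
    crop_fraction: float = 0.5,
    observation_prob: float = 1.0,
) -> list[CropCountRecord]:
    """Beta-binomial crop counts: the realized observed fraction φ is
    Beta(νφ̂, ν(1−φ̂)) around the reported estimate φ̂, and
    structures_counted ~ Binomial(f, φ) with f the (rounded) true
    fecundity."""
    if not (0.0 < crop_fraction <= 1.0):
        raise ValueError(f"crop fraction estimate {crop_fraction} outside (0, 1]")
    out = []
    for _, row in truth.table.iterrows():
        if observation_prob < 1.0 and rng.random() >= observation_prob:
            continue
        f = int(round(row["fecundity"] / params.seeds_per_structure))
        if crop_fraction >= 1.0:
            phi = 1.0
        else:
            phi = rng.beta(
                params.nu * crop_fraction, params.nu * (1.0 - crop_fraction)
            )
        out.append(
            CropCountRecord(
                tree_id=str(row["tree_id"]),
                year=int(row["year"]),
                structures_counted=int(rng.binomial(f, phi)) if f > 0 else 0,
                crop_fraction_estimate=crop_fraction,
            )
        )
    return out


def simulate_trait(
    tree,
    lam: float,
    sigma_bm: float,
    rng: np.random.Generator,
    root_value: float = 0.0,
) -> pd.Series:
    """Tip values under λ-scaled Brownian motion: multivariate normal
    with covariance σ²_BM · C_λ (off-diagonals of the BM covariance
    multiplied by λ)."""
    C, labels = phylo_covariance(tree)
    cov = sigma_bm**2 * lambda_transform(C, lam)
    # covariance is PD for λ in [0,1] on trees with positive terminal branches
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(len(labels)))
    vals = root_value + L @ rng.standard_normal(len(labels))
    return pd.Series(vals, index=labels)


@dataclass
class World:
    """A fully simulated study system: everything the pipeline consumes."""

    trees: list[TreeRecord]
    covariates: pd.DataFrame
    truth: LatentTruth
    traps: list[TrapRecord]
    crop_counts: list[CropCountRecord]
    params: GenerativeParams
    config: StandConfig


def simulate_world(
    config: StandConfig,
    params: GenerativeParams,
    rng: np.random.Generator | int,
    n_traps: int = 5,
    crop_fraction: float = 0.5,
    crop_observation_prob: float = 0.5,
) -> World:
    """Run the full generative pipeline for one stand with independent
    child streams per stage."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    streams = rng.spawn(5)
    trees, cov = simulate_stand(config, streams[0])
    states = simulate_maturation(trees, params, streams[1])
    truth = simulate_fecundity(trees, states, cov, params, streams[2])
    traps = place_traps(config, n_traps, streams[3])
    traps = simulate_trap_counts(trees, truth, traps, params, streams[3])
    crops = simulate_crop_counts(
        truth, params, streams[4],
        crop_fraction=crop_fraction,
        observation_prob=crop_observation_prob,
    )
    return World(trees, cov, truth, traps, crops, params, config)
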