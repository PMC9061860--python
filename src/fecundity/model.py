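"""Hierarchical Bayesian state-space inference of maturation and fecundity.

For each tree-year the expected fecundity is f = ρψ: an absorbing
maturation state ρ with probit hazard Φ(β0 + β1·d) while immature, and
conditional fecundity log ψ = x'β + individual effect + year effect +
Normal(0, σ²) noise, with year effects shared within species × ecoregion
groups.  Observations enter through two data models:

* seed traps: count ~ Poisson(area · Σ_trees f·k(dist)) under a 2Dt
  dispersal kernel, with genus-level counts pooling congeneric trees;
* crop counts: structures ~ beta-binomial around the reported fraction
  of the crop observed, concentration ν.

Sampling is Metropolis-within-Gibbs: latent log ψ by adaptive random
walk (adaptation frozen after burn-in), maturation histories by exact
per-tree enumeration over the first-mature year, probit coefficients by
Albert–Chib augmentation, the Gaussian linear layer and variances by
conjugate updates.  One parameter block per species; congeners are
coupled only through the shared trap likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import RunConfig
from .io import TrapRecord, TreeRecord, CropCountRecord
from .simulate import dispersal_kernel

__all__ = [
    "DesignInfo",
    "build_design",
    "trap_log_likelihood",
    "crop_log_likelihood",
    "poisson_logpmf",
    "betabinom_logpmf",
    "GibbsSampler",
    "sample_maturation",
    "sample_fecundity_effects",
    "FitResult",
    "fit",
    "dic",
]

_LOG_F_CAP = 60.0  # caps exp(log psi) to keep Poisson terms finite


def _expf(x: float) -> float:
    return math.exp(x if x < _LOG_F_CAP else _LOG_F_CAP)


DEFAULT_DESIGN = [
    "intercept",
    "diameter_cm",
    "diameter_cm_sq",
    "shade",
    "cec",
    "t_site_mean",
    "t_anomaly",
    "m_site_mean",
    "m_anomaly",
    "u1",
    "u2",
    "u3",
]


# ---------------------------------------------------------------------------
# design matrices


@dataclass
class DesignInfo:
    """Standardized design matrix with stored transforms.

    Continuous columns are centered and scaled; coefficients fitted on
    the standardized scale convert back with :meth:`to_original`.
    """

    columns: list[str]
    X: np.ndarray
    means: np.ndarray
    sds: np.ndarray

    def to_original(self, beta_std: np.ndarray) -> np.ndarray:
        """Coefficients on the raw covariate scale from standardized-scale
        coefficients (intercept absorbs the centering shifts)."""
        beta = np.asarray(beta_std, dtype=float).copy()
        out = beta / self.sds
        if "intercept" in self.columns:
            i0 = self.columns.index("intercept")
            shift = sum(
                beta[j] * self.means[j] / self.sds[j]
                for j in range(len(self.columns))
                if j != i0
            )
            out[i0] = beta[i0] - shift
        return out

    def to_standardized(self, beta_orig: np.ndarray) -> np.ndarray:
        beta = np.asarray(beta_orig, dtype=float)
        out = beta * self.sds
        if "intercept" in self.columns:
            i0 = self.columns.index("intercept")
            shift = sum(
                beta[j] * self.means[j]
                for j in range(len(self.columns))
                if j != i0
            )
            out[i0] = beta[i0] + shift
        return out


def build_design(
    covariates: pd.DataFrame, columns: Sequence[str] | None = None
) -> DesignInfo:
    """Assemble and standardize the fixed-effects design matrix.

    Quadratic diameter is squared *before* standardization.  Raises if
    the design is rank-deficient, naming the collinear columns.
    """
    if columns is None:
        columns = [c for c in DEFAULT_DESIGN if c in covariates.columns]
    columns = list(columns)
    raw = np.empty((len(covariates), len(columns)))
    for j, c in enumerate(columns):
        if c == "intercept":
            raw[:, j] = 1.0
        else:
            if c not in covariates.columns:
                raise ValueError(f"covariate column {c!r} missing")
            raw[:, j] = covariates[c].to_numpy(dtype=float)
    means = raw.mean(axis=0)
    sds = raw.std(axis=0)
    for j, c in enumerate(columns):
        if c == "intercept" or sds[j] == 0:
            means[j] = 0.0
            sds[j] = 1.0
    X = (raw - means) / sds

    rank = np.linalg.matrix_rank(X)
    if rank < len(columns):
        # name offenders via QR pivoting on correlations
        _, R = np.linalg.qr(X)
        bad = [columns[j] for j in range(len(columns)) if abs(R[j, j]) < 1e-8]
        raise ValueError(f"design matrix rank-deficient; collinear columns {bad}")
    return DesignInfo(columns=columns, X=X, means=means, sds=sds)


# ---------------------------------------------------------------------------
# data-model log pmfs (scalar fast paths used inside the sampler)


def poisson_logpmf(y: int, mu: float) -> float:
    if mu <= 0.0:
        return 0.0 if y == 0 else -math.inf
    return y * math.log(mu) - mu - math.lgamma(y + 1)


def betabinom_logpmf(y: int, n: int, phat: float, nu: float) -> float:
    """Beta-binomial log pmf with mean fraction ``phat`` and
    concentration ``nu``; y > n has zero mass, never an exception."""
    if y < 0 or y > n:
        return -math.inf
    if phat >= 1.0:
        return 0.0 if y == n else -math.inf
    a = nu * phat
    b = nu * (1.0 - phat)
    if nu > 1e6:
        # near-binomial regime: lgamma differences cancel catastrophically,
        # so evaluate the gamma ratios as exact products of integer offsets
        out = math.lgamma(n + 1) - math.lgamma(y + 1) - math.lgamma(n - y + 1)
        out += sum(math.log(a + i) for i in range(y))
        out += sum(math.log(b + i) for i in range(n - y))
        out -= sum(math.log(a + b + i) for i in range(n))
        return out
    return (
        math.lgamma(n + 1)
        - math.lgamma(y + 1)
        - math.lgamma(n - y + 1)
        + math.lgamma(y + a)
        + math.lgamma(n - y + b)
        - math.lgamma(n + a + b)
        + math.lgamma(a + b)
        - math.lgamma(a)
        - math.lgamma(b)
    )


def trap_log_likelihood(
    fecundity: pd.DataFrame,
    trees: list[TreeRecord],
    traps: list[TrapRecord],
    kernel_scale: float,
) -> float:
    """Poisson log likelihood of all trap counts given per-tree-year
    fecundities (columns tree_id, year, fecundity).

    Intensity for a (trap, year, taxon) count is
    area · Σ_trees f · k(dist), the sum over trees of that species, or
    over congeneric trees for genus-level counts.  Zero intensity with a
    positive count yields −inf.
    """
    f = {
        (str(t), int(y)): float(v)
        for t, y, v in zip(
            fecundity["tree_id"], fecundity["year"], fecundity["fecundity"]
        )
    }
    total = 0.0
    for trap in traps:
        stand_trees = [t for t in trees if t.stand_id == trap.stand_id]
        kern = {
            t.tree_id: trap.collection_area
            * float(dispersal_kernel(math.hypot(t.x - trap.x, t.y - trap.y), kernel_scale))
            for t in stand_trees
        }
        for (year, taxon, level), y in trap.counts_by_year.items():
            if level == "genus":
                members = [t for t in stand_trees if t.genus == taxon]
            else:
                members = [t for t in stand_trees if t.species == taxon]
            mu = sum(
                kern[t.tree_id] * f.get((t.tree_id, year), 0.0) for t in members
            )
            total += poisson_logpmf(int(y), mu)
            if total == -math.inf:
                return -math.inf
    return total


def crop_log_likelihood(
    fecundity: pd.DataFrame,
    crop_counts: list[CropCountRecord],
    nu: float,
    seeds_per_structure: float = 1.0,
) -> float:
    """Beta-binomial log likelihood of crop counts given fecundities.
    An observed count exceeding the (rounded) fecundity contributes
    −inf, never silently dropped."""
    f = {
        (str(t), int(y)): float(v)
        for t, y, v in zip(
            fecundity["tree_id"], fecundity["year"], fecundity["fecundity"]
        )
    }
    total = 0.0
    for c in crop_counts:
        n = int(round(f.get((c.tree_id, c.year), 0.0) / seeds_per_structure))
        total += betabinom_logpmf(
            c.structures_counted, n, c.crop_fraction_estimate, nu
        )
        if total == -math.inf:
            return -math.inf
    return total


# ---------------------------------------------------------------------------
# sampler


@dataclass
class _TrapObs:
    y: np.ndarray          # counts, length J
    rows: list[np.ndarray]  # contributing flat-row indices per obs
    w: list[np.ndarray]     # area·k(dist) weights per obs


@dataclass
class FitResult:
    posterior: pd.DataFrame          # tree_id, year, fhat, se, cv, maturity_prob, ess
    samples: dict                    # parameter draws, shape (chains, draws, ...)
    diagnostics: dict                # rhat per fixed effect, convergence flag
    design: DesignInfo
    species: list[str]
    deviance: np.ndarray             # (chains, draws) deviance samples
    deviance_at_mean: float
    flat: pd.DataFrame               # tree_id, year, species, group per flat row


class GibbsSampler:
    """One-chain sampler state over a prepared dataset.

    The flat tree-year table is sorted by (tree, year); ``mat_time[i]``
    is the index (into tree i's year list) of the first mature year,
    with T_i meaning "not within the window".  Maturity is absorbing by
    construction of this parameterization.
    """

    def __init__(
        self,
        trees: list[TreeRecord],
        covariates: pd.DataFrame,
        traps: list[TrapRecord],
        crop_counts: list[CropCountRecord],
        design: DesignInfo | None,
        config: RunConfig,
        rng: np.random.Generator,
        design_columns: Sequence[str] | None = None,
    ):
        self.config = config
        self.rng = rng
        self.trees = trees
        cov = covariates.sort_values(["tree_id", "year"], kind="mergesort").reset_index(
            drop=True
        )
        self.flat = cov
        self.design = design if design is not None else build_design(cov, design_columns)
        if design is not None and len(design.X) != len(cov):
            raise ValueError("design rows do not match covariate rows")
        self.X = self.design.X
        self.M, self.p = self.X.shape

        self.tree_ids = sorted({t.tree_id for t in trees})
        self.tree_index = {t: i for i, t in enumerate(self.tree_ids)}
        self.row_tree = cov["tree_id"].map(self.tree_index).to_numpy()
        self.row_year = cov["year"].to_numpy(dtype=int)
        self.row_diam = cov["diameter_cm"].to_numpy(dtype=float)

        self.species = sorted(cov["species"].astype(str).unique())
        self.sp_index = {s: i for i, s in enumerate(self.species)}
        self.row_sp = cov["species"].astype(str).map(self.sp_index).to_numpy()
        self.n_sp = len(self.species)
        tree_sp = {}
        for t in trees:
            tree_sp[self.tree_index[t.tree_id]] = self.sp_index[str(t.species)]
        self.tree_species = np.array([tree_sp[i] for i in range(len(self.tree_ids))])

        if "ecoregion" in cov.columns:
            grp = cov["species"].astype(str) + ":" + cov["ecoregion"].astype(str)
        else:
            grp = cov["species"].astype(str)
        gy = grp + "@" + cov["year"].astype(str)
        self.gy_labels = sorted(gy.unique())
        gy_ix = {g: i for i, g in enumerate(self.gy_labels)}
        self.row_gy = gy.map(gy_ix).to_numpy()
        self.n_gy = len(self.gy_labels)
        self.gy_species = np.array(
            [self.sp_index[g.split(":")[0]] for g in self.gy_labels]
        )

        # per-tree contiguous row ranges
        self.tree_rows: list[np.ndarray] = [None] * len(self.tree_ids)
        for i in range(len(self.tree_ids)):
            self.tree_rows[i] = np.flatnonzero(self.row_tree == i)

        self._row_of = {
            (self.tree_ids[self.row_tree[m]], int(self.row_year[m])): m
            for m in range(self.M)
        }
        self._index_observations(traps, crop_counts)

        # --- state
        pr = config.priors
        self.beta = np.zeros((self.n_sp, self.p))
        self.b_ind = np.zeros(len(self.tree_ids))
        self.gamma = np.zeros(self.n_gy)
        self.sigma2 = np.full(self.n_sp, 0.25)
        self.tau_ind2 = np.full(self.n_sp, 0.25)
        self.tau_yr2 = np.full(self.n_sp, 0.25)
        self.beta_rho = np.tile(np.array([-1.0, 0.05]), (self.n_sp, 1))
        self.prior_beta_var = pr.fixed_effect_sd**2
        self.prior_rho_var = pr.maturation_sd**2
        self.ig_a = pr.variance_shape
        self.ig_b = pr.variance_scale

        # known-mature constraints from crop counts / inventory flags
        key_rows = self._row_of
        self.known_by = np.full(len(self.tree_ids), np.iinfo(np.int32).max)
        for c in crop_counts:
            if c.structures_counted > 0 and (c.tree_id, c.year) in key_rows:
                i = self.tree_index[c.tree_id]
                pos = int(np.searchsorted(self.row_year[self.tree_rows[i]], c.year))
                self.known_by[i] = min(self.known_by[i], pos)
        for t in trees:
            if t.first_observed_mature_year is not None:
                i = self.tree_index[t.tree_id]
                yrs = self.row_year[self.tree_rows[i]]
                pos = int(np.searchsorted(yrs, t.first_observed_mature_year))
                self.known_by[i] = min(self.known_by[i], pos)

        # initial maturation: mature from the constraint year, else from
        # a prior draw of the hazard path
        self.mat_time = np.empty(len(self.tree_ids), dtype=int)
        for i in range(len(self.tree_ids)):
            Ti = len(self.tree_rows[i])
            self.mat_time[i] = min(self.known_by[i], Ti)
        self.mature = np.zeros(self.M, dtype=bool)
        for i in range(len(self.tree_ids)):
            self.mature[self.tree_rows[i][self.mat_time[i]:]] = True

        # latent log ψ initialized near the data: crude per-tree scale
        self.log_psi = np.full(self.M, 1.0)
        self.f = np.where(self.mature, np.exp(self.log_psi), 0.0)
        self._refresh_intensities()

        self.step = np.full(self.M, 0.5)
        self._acc = np.zeros(self.M)
        self._try = np.zeros(self.M)
        self.kernel_scale = config.kernel_scale_m2
        self.nu = config.crop_concentration

    # -- observation indexing -------------------------------------------------

    def _index_observations(self, traps, crop_counts):
        tree_by_id = {t.tree_id: t for t in self.trees}
        obs_y, obs_rows, obs_w = [], [], []
        u = self.config.kernel_scale_m2
        for trap in traps:
            stand = [t for t in self.trees if t.stand_id == trap.stand_id]
            kern = {
                t.tree_id: trap.collection_area
                * float(
                    dispersal_kernel(
                        math.hypot(t.x - trap.x, t.y - trap.y), u
                    )
                )
                for t in stand
            }
            for (year, taxon, level), y in sorted(trap.counts_by_year.items()):
                if level == "genus":
                    members = [t for t in stand if t.genus == taxon]
                else:
                    members = [t for t in stand if t.species == taxon]
                rows, ws = [], []
                for t in members:
                    m = self._row_lookup(t.tree_id, year)
                    if m is not None:
                        rows.append(m)
                        ws.append(kern[t.tree_id])
                if rows:
                    obs_y.append(int(y))
                    obs_rows.append(np.array(rows))
                    obs_w.append(np.array(ws))
        self.trap_obs = _TrapObs(
            y=np.array(obs_y, dtype=int), rows=obs_rows, w=obs_w
        )
        # reverse index: per flat row, (obs index, weight) pairs
        self.row_obs: list[list[tuple[int, float]]] = [[] for _ in range(self.M)]
        for j, (rows, ws) in enumerate(zip(obs_rows, obs_w)):
            for m, w in zip(rows, ws):
                self.row_obs[m].append((j, float(w)))
        # crop observations per row
        self.row_crop: list[list[tuple[int, float]]] = [[] for _ in range(self.M)]
        for c in crop_counts:
            m = self._row_lookup(c.tree_id, c.year)
            if m is not None:
                self.row_crop[m].append(
                    (int(c.structures_counted), float(c.crop_fraction_estimate))
                )
        self.has_data = np.array(
            [bool(self.row_obs[m]) or bool(self.row_crop[m]) for m in range(self.M)]
        )

    def _row_lookup(self, tree_id: str, year: int):
        if tree_id not in self.tree_index:
            return None
        return self._row_of.get((tree_id, int(year)))

    def _refresh_intensities(self):
        self.mu = np.array(
            [
                float(np.dot(w, self.f[rows]))
                for rows, w in zip(self.trap_obs.rows, self.trap_obs.w)
            ]
        )

    # -- conditional means ----------------------------------------------------

    def _prior_mean(self, rows) -> np.ndarray:
        return (
            np.einsum("ij,ij->i", self.X[rows], self.beta[self.row_sp[rows]])
            + self.b_ind[self.row_tree[rows]]
            + self.gamma[self.row_gy[rows]]
        )

    # -- updates ---------------------------------------------------------------

    def update_log_psi(self, adapt: bool = False):
        """Single-site adaptive random-walk Metropolis on latent log ψ
        for mature tree-years with data; exact Gibbs (prior draw) where
        no observation touches the tree-year."""
        rng = self.rng
        rows = np.flatnonzero(self.mature)
        means = self._prior_mean(rows)
        sig = np.sqrt(self.sigma2[self.row_sp[rows]])
        z = rng.standard_normal(len(rows))
        u_log = np.log(rng.random(len(rows)))
        for k in range(len(rows)):
            m = int(rows[k])
            mean_m, sd_m = means[k], sig[k]
            if not self.has_data[m]:
                self.log_psi[m] = mean_m + sd_m * z[k]
                self.f[m] = _expf(self.log_psi[m])
                continue
            cur = self.log_psi[m]
            prop = cur + self.step[m] * z[k]
            f_cur, f_prop = self.f[m], _expf(prop)
            delta = -0.5 * ((prop - mean_m) ** 2 - (cur - mean_m) ** 2) / sd_m**2
            for j, w in self.row_obs[m]:
                mu_old = self.mu[j]
                mu_new = mu_old + w * (f_prop - f_cur)
                y = int(self.trap_obs.y[j])
                delta += poisson_logpmf(y, mu_new) - poisson_logpmf(y, mu_old)
            for y, phat in self.row_crop[m]:
                delta += betabinom_logpmf(
                    y, int(round(f_prop)), phat, self.nu
                ) - betabinom_logpmf(y, int(round(f_cur)), phat, self.nu)
            self._try[m] += 1
            if u_log[k] < delta:
                self.log_psi[m] = prop
                self.f[m] = f_prop
                for j, w in self.row_obs[m]:
                    self.mu[j] += w * (f_prop - f_cur)
                self._acc[m] += 1
        if adapt:
            self._adapt_steps()

    def _adapt_steps(self):
        tried = self._try > 0
        if not tried.any():
            return
        rate = np.where(tried, self._acc / np.maximum(self._try, 1), 0.44)
        self.step[tried] *= np.exp(np.clip(rate[tried] - 0.44, -0.5, 0.5))
        self.step = np.clip(self.step, 1e-3, 10.0)
        self._acc[:] = 0
        self._try[:] = 0

    def _hazards(self, i: int) -> np.ndarray:
        b0, b1 = self.beta_rho[self.tree_species[i]]
        d = self.row_diam[self.tree_rows[i]]
        return norm.cdf(b0 + b1 * d)

    def _all_hazards(self) -> np.ndarray:
        """Per-row transition probability Φ(β0 + β1·d), vectorized."""
        eta = (
            self.beta_rho[self.row_sp, 0]
            + self.beta_rho[self.row_sp, 1] * self.row_diam
        )
        return norm.cdf(eta)

    def maturation_log_prior(self, i: int) -> np.ndarray:
        """Log prior over first-mature index m ∈ {0..T} (T = never)."""
        p = np.clip(self._hazards(i), 1e-12, 1 - 1e-12)
        T = len(p)
        out = np.empty(T + 1)
        log1mp = np.log1p(-p)
        cum = np.concatenate([[0.0], np.cumsum(log1mp)])
        out[:T] = cum[:T] + np.log(p)
        out[T] = cum[T]
        return out

    def update_maturation(self):
        """Exact Gibbs draw of each tree's first-mature year by
        enumeration; immature years force f = 0 in both data models."""
        rng = self.rng
        # refresh latents on all currently-immature rows in one draw
        cold_all = np.flatnonzero(~self.mature)
        if len(cold_all):
            mm = self._prior_mean(cold_all)
            sd = np.sqrt(self.sigma2[self.row_sp[cold_all]])
            self.log_psi[cold_all] = mm + sd * rng.standard_normal(len(cold_all))
        hazard = np.clip(self._all_hazards(), 1e-12, 1 - 1e-12)
        for i in range(len(self.tree_ids)):
            if self.known_by[i] == 0:
                continue  # observed mature from the first year; no freedom
            rows = self.tree_rows[i]
            T = len(rows)
            p = hazard[rows]
            log1mp = np.log1p(-p)
            cum = np.concatenate([[0.0], np.cumsum(log1mp)])
            lp = np.empty(T + 1)
            lp[:T] = cum[:T] + np.log(p)
            lp[T] = cum[T]
            lim = min(self.known_by[i], T)
            lp[lim + 1:] = -np.inf

            # per-year log likelihood with the tree fertile vs sterile
            ll_on = np.zeros(T)
            ll_off = np.zeros(T)
            for t in range(T):
                m = int(rows[t])
                ft = _expf(self.log_psi[m])
                cur_on = self.mature[m]
                for j, w in self.row_obs[m]:
                    base = self.mu[j] - (w * self.f[m] if cur_on else 0.0)
                    y = int(self.trap_obs.y[j])
                    ll_on[t] += poisson_logpmf(y, base + w * ft)
                    ll_off[t] += poisson_logpmf(y, base)
                for y, phat in self.row_crop[m]:
                    ll_on[t] += betabinom_logpmf(y, int(round(ft)), phat, self.nu)
                    ll_off[t] += betabinom_logpmf(y, 0, phat, self.nu)
            prefix = np.concatenate([[0.0], np.cumsum(ll_off)])  # years before m
            suffix = np.concatenate([np.cumsum(ll_on[::-1])[::-1], [0.0]])
            logp = lp + prefix + suffix
            mx = logp.max()
            if not np.isfinite(mx):  # no candidate with support: keep state
                continue
            prob = np.exp(logp - mx)
            prob /= prob.sum()
            new_m = int(rng.choice(T + 1, p=prob))
            old_m = int(self.mat_time[i])
            if new_m != old_m:
                lo, hi = min(new_m, old_m), max(new_m, old_m)
                for t in range(lo, hi):
                    m = int(rows[t])
                    turning_on = new_m < old_m
                    ft = _expf(self.log_psi[m])
                    for j, w in self.row_obs[m]:
                        self.mu[j] += w * (ft if turning_on else -self.f[m])
                    self.mature[m] = turning_on
                    self.f[m] = ft if turning_on else 0.0
                self.mat_time[i] = new_m
            # keep f consistent for freshly drawn latents on mature rows
            on = rows[self.mat_time[i]:]
            self.f[on] = np.exp(np.minimum(self.log_psi[on], _LOG_F_CAP))

    def update_maturation_coefs(self):
        """Albert–Chib probit update of (β0, β1) per species from the
        at-risk transition events (years while immature, outcome =
        transition)."""
        rng = self.rng
        for s in range(self.n_sp):
            ds, ys = [], []
            for i in np.flatnonzero(self.tree_species == s):
                rows = self.tree_rows[i]
                T = len(rows)
                mt = int(self.mat_time[i])
                if self.known_by[i] == 0:
                    continue  # never at risk in-window
                for t in range(min(mt + 1, T)):
                    ds.append(self.row_diam[rows[t]])
                    ys.append(1 if t == mt else 0)
            if not ds:
                continue
            D = np.column_stack([np.ones(len(ds)), np.array(ds)])
            yv = np.array(ys)
            eta = D @ self.beta_rho[s]
            # truncated-normal latent draws
            u = rng.random(len(ds))
            lo = norm.cdf(-eta)
            cdf = np.where(yv == 1, lo + u * (1 - lo), u * lo)
            zlat = eta + norm.ppf(np.clip(cdf, 1e-12, 1 - 1e-12))
            prec = D.T @ D + np.eye(2) / self.prior_rho_var
            V = np.linalg.inv(prec)
            mean = V @ (D.T @ zlat)
            self.beta_rho[s] = rng.multivariate_normal(mean, V)

    def sample_beta(self):
        """Conjugate Gaussian draw of the fixed effects per species given
        the latent log ψ, individual and year effects, and σ²."""
        rng = self.rng
        live = self.mature
        for s in range(self.n_sp):
            sel = live & (self.row_sp == s)
            rows = np.flatnonzero(sel)
            resid_target = (
                self.log_psi[rows]
                - self.b_ind[self.row_tree[rows]]
                - self.gamma[self.row_gy[rows]]
            )
            Xs = self.X[rows]
            s2 = self.sigma2[s]
            prec = Xs.T @ Xs / s2 + np.eye(self.p) / self.prior_beta_var
            V = np.linalg.inv(prec)
            mean = V @ (Xs.T @ resid_target / s2)
            self.beta[s] = rng.multivariate_normal(mean, V)

    def sample_random_effects(self):
        """Conjugate draws of individual and group-year effects."""
        rng = self.rng
        live = self.mature
        xb = np.einsum("ij,ij->i", self.X, self.beta[self.row_sp])

        # individual effects
        for i in range(len(self.tree_ids)):
            s = self.tree_species[i]
            rows = self.tree_rows[i][self.mature[self.tree_rows[i]]]
            t2 = self.tau_ind2[s]
            if len(rows) == 0:
                self.b_ind[i] = rng.normal(0.0, math.sqrt(t2))
                continue
            s2 = self.sigma2[s]
            r = self.log_psi[rows] - xb[rows] - self.gamma[self.row_gy[rows]]
            prec = len(rows) / s2 + 1.0 / t2
            mean = r.sum() / s2 / prec
            self.b_ind[i] = rng.normal(mean, math.sqrt(1.0 / prec))

        # group-year effects
        r_all = self.log_psi - xb - self.b_ind[self.row_tree]
        for g in range(self.n_gy):
            s = self.gy_species[g]
            rows = np.flatnonzero(live & (self.row_gy == g))
            t2 = self.tau_yr2[s]
            if len(rows) == 0:
                self.gamma[g] = rng.normal(0.0, math.sqrt(t2))
                continue
            s2 = self.sigma2[s]
            prec = len(rows) / s2 + 1.0 / t2
            mean = r_all[rows].sum() / s2 / prec
            self.gamma[g] = rng.normal(mean, math.sqrt(1.0 / prec))

    def sample_variances(self):
        """Inverse-gamma conjugate draws of σ², τ_ind², τ_yr² per species."""
        rng = self.rng
        live = self.mature
        xb = np.einsum("ij,ij->i", self.X, self.beta[self.row_sp])
        resid = (
            self.log_psi
            - xb
            - self.b_ind[self.row_tree]
            - self.gamma[self.row_gy]
        )
        for s in range(self.n_sp):
            rows = np.flatnonzero(live & (self.row_sp == s))
            a = self.ig_a + 0.5 * len(rows)
            b = self.ig_b + 0.5 * float(np.sum(resid[rows] ** 2))
            self.sigma2[s] = 1.0 / rng.gamma(a, 1.0 / b)
            ii = np.flatnonzero(self.tree_species == s)
            a = self.ig_a + 0.5 * len(ii)
            b = self.ig_b + 0.5 * float(np.sum(self.b_ind[ii] ** 2))
            self.tau_ind2[s] = 1.0 / rng.gamma(a, 1.0 / b)
            gg = np.flatnonzero(self.gy_species == s)
            a = self.ig_a + 0.5 * len(gg)
            b = self.ig_b + 0.5 * float(np.sum(self.gamma[gg] ** 2))
            self.tau_yr2[s] = 1.0 / rng.gamma(a, 1.0 / b)

    def update_effects(self):
        """Conjugate updates for the whole Gaussian linear layer: fixed
        effects, random effects, then variances.  Only mature tree-years
        contribute."""
        self.sample_beta()
        self.sample_random_effects()
        self.sample_variances()

    def log_likelihood(self) -> float:
        """Joint data log likelihood at the current state."""
        total = 0.0
        for j in range(len(self.trap_obs.y)):
            total += poisson_logpmf(int(self.trap_obs.y[j]), float(self.mu[j]))
        for m in range(self.M):
            for y, phat in self.row_crop[m]:
                total += betabinom_logpmf(y, int(round(self.f[m])), phat, self.nu)
        return total

    def sweep(self, adapt: bool = False):
        self.update_log_psi(adapt=adapt)
        self.update_maturation()
        self.update_maturation_coefs()
        self.update_effects()

    def initialize(self):
        """Crude data-driven initialization, jittered per chain."""
        rng = self.rng
        # rough fecundity scale from crop counts where present
        for m in range(self.M):
            guess = None
            for y, phat in self.row_crop[m]:
                guess = max(guess or 0.0, y / max(phat, 1e-3))
            if guess is not None and guess > 0:
                self.log_psi[m] = math.log(guess)
            else:
                self.log_psi[m] = rng.normal(3.0, 1.0)
        self.beta[:, :] = 0.0
        if "intercept" in self.design.columns:
            i0 = self.design.columns.index("intercept")
            live = self.log_psi[self.mature]
            base = float(np.mean(live)) if len(live) else 3.0
            self.beta[:, i0] = base + rng.normal(0, 0.5)
        self.f = np.where(self.mature, np.exp(self.log_psi), 0.0)
        self._refresh_intensities()


def sample_maturation(sampler: GibbsSampler) -> np.ndarray:
    """One maturation sweep; returns the per-row maturity indicator."""
    sampler.update_maturation()
    return sampler.mature.copy()


def sample_fecundity_effects(sampler: GibbsSampler) -> dict:
    """One linear-layer sweep; returns the updated parameter blocks."""
    sampler.update_effects()
    return {
        "beta": sampler.beta.copy(),
        "b_ind": sampler.b_ind.copy(),
        "gamma": sampler.gamma.copy(),
        "sigma2": sampler.sigma2.copy(),
    }


# ---------------------------------------------------------------------------
# fit


def fit(
    trees: list[TreeRecord],
    covariates: pd.DataFrame,
    traps: list[TrapRecord],
    crop_counts: list[CropCountRecord],
    config: RunConfig | None = None,
    design_columns: Sequence[str] | None = None,
    rng: np.random.Generator | int | None = None,
) -> FitResult:
    """Fit the state-space model by MCMC and summarize per-tree-year
    fecundity posteriors.

    Runs ``config.mcmc.chains`` (≥ 2 recommended) chains and reports the
    Gelman–Rubin diagnostic per fixed effect.  Non-convergence is
    flagged in the diagnostics, never auto-rerun.  The returned
    ``posterior`` table has f̂ = posterior mean of ρψ, its posterior sd,
    and CV = s/f̂ (finite only where f̂ > 0).
    """
    if not traps and not crop_counts:
        raise ValueError("need at least one observation type (traps or crop counts)")
    config = config or RunConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    n_chains = max(1, config.mcmc.chains)
    chain_rngs = rng.spawn(n_chains)

    design = build_design(
        covariates.sort_values(["tree_id", "year"], kind="mergesort").reset_index(
            drop=True
        ),
        design_columns,
    )

    keep = (config.mcmc.iterations - config.mcmc.burn_in) // config.mcmc.thin
    if keep < 1:
        raise ValueError("no retained iterations after burn-in/thinning")

    all_beta = None
    all_f = None
    all_var = None
    all_rho = None
    all_dev = np.empty((n_chains, keep))

    sampler0 = None
    for c in range(n_chains):
        s = GibbsSampler(
            trees, covariates, traps, crop_counts, design, config, chain_rngs[c]
        )
        if sampler0 is None:
            sampler0 = s
            all_beta = np.empty((n_chains, keep, s.n_sp, s.p))
            all_f = np.empty((n_chains, keep, s.M))
            all_var = np.empty((n_chains, keep, s.n_sp, 3))
            all_rho = np.empty((n_chains, keep, s.n_sp, 2))
        s.initialize()
        k = 0
        for it in range(config.mcmc.iterations):
            burn = it < config.mcmc.burn_in
            s.sweep(adapt=burn and (it % 25 == 24))
            if not burn and (it - config.mcmc.burn_in) % config.mcmc.thin == 0:
                if k < keep:
                    all_beta[c, k] = s.beta
                    all_f[c, k] = s.f
                    all_var[c, k, :, 0] = s.sigma2
                    all_var[c, k, :, 1] = s.tau_ind2
                    all_var[c, k, :, 2] = s.tau_yr2
                    all_rho[c, k] = s.beta_rho
                    all_dev[c, k] = -2.0 * s.log_likelihood()
                    k += 1

    # diagnostics on fixed effects (standardized scale)
    import arviz as az

    rhat = {}
    for sidx, sp in enumerate(sampler0.species):
        for j, col in enumerate(design.columns):
            chains = all_beta[:, :, sidx, j]
            rhat[f"{sp}:{col}"] = (
                float(az.rhat(az.convert_to_dataset(chains))["x"].values)
                if n_chains > 1
                else float("nan")
            )
    converged = all(
        (np.isnan(v) or v < 1.1) for v in rhat.values()
    )

    fhat = all_f.reshape(-1, sampler0.M).mean(axis=0)
    se = all_f.reshape(-1, sampler0.M).std(axis=0, ddof=1)
    mat_prob = (all_f.reshape(-1, sampler0.M) > 0).mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(fhat > 0, se / fhat, np.nan)
    try:
        ess = az.ess(az.convert_to_dataset(all_f))["x"].values
    except Exception:
        ess = np.full(sampler0.M, np.nan)

    flat = sampler0.flat
    posterior = pd.DataFrame(
        {
            "tree_id": flat["tree_id"],
            "species": flat["species"],
            "stand_id": flat.get("stand_id"),
            "year": flat["year"],
            "fhat": fhat,
            "se": se,
            "cv": cv,
            "maturity_prob": mat_prob,
            "ess": ess,
        }
    )

    # plug-in deviance at posterior-mean fecundities for DIC
    mean_tab = pd.DataFrame(
        {"tree_id": flat["tree_id"], "year": flat["year"], "fecundity": fhat}
    )
    ll_mean = trap_log_likelihood(
        mean_tab, trees, traps, config.kernel_scale_m2
    ) + crop_log_likelihood(mean_tab, crop_counts, config.crop_concentration)

    samples = {
        "beta_std": all_beta,
        "beta_orig": np.stack(
            [
                [design.to_original(all_beta[c, k, sidx]) for sidx in range(sampler0.n_sp)]
                for c in range(n_chains)
                for k in range(keep)
            ]
        ).reshape(n_chains, keep, sampler0.n_sp, sampler0.p),
        "variances": all_var,
        "beta_rho": all_rho,
        "f": all_f,
    }
    return FitResult(
        posterior=posterior,
        samples=samples,
        diagnostics={"rhat": rhat, "converged": bool(converged)},
        design=design,
        species=sampler0.species,
        deviance=all_dev,
        deviance_at_mean=-2.0 * ll_mean,
        flat=flat[["tree_id", "year", "species"]],
    )


def dic(result: FitResult) -> float:
    """Deviance information criterion DIC = D̄ + pD with
    pD = D̄ − D(θ̄) evaluated at the posterior-mean fecundities."""
    dev = result.deviance.ravel()
    if len(dev) < 10:
        raise ValueError("need at least 10 retained samples for DIC")
    dbar = float(dev.mean())
    pd_eff = dbar - result.deviance_at_mean
    return dbar + pd_eff
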