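"""Generative-model oracles: maturation hazard, fecundity structure,
dispersal kernel, trap and crop observation models, phylogenetic traits."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from fecundity.io import TrapRecord
from fecundity.phylo import phylo_covariance, simulate_phylogeny
from fecundity.simulate import (
    GenerativeParams,
    LatentTruth,
    StandConfig,
    dispersal_kernel,
    place_traps,
    simulate_crop_counts,
    simulate_fecundity,
    simulate_maturation,
    simulate_stand,
    simulate_trait,
    simulate_trap_counts,
    simulate_world,
)


# ---------------------------------------------------------------------------
# stand generation


def test_stand_minimal_and_errors(rng):
    trees, cov = simulate_stand(StandConfig(n_trees=1, n_years=1), rng)
    assert len(trees) == 1 and len(cov) == 1
    with pytest.raises(ValueError):
        simulate_stand(StandConfig(n_trees=0), rng)


def test_stand_diameters_within_bounds_and_growing(rng):
    cfg = StandConfig(n_trees=200, n_years=8, diameter_min_cm=5, diameter_max_cm=120)
    trees, cov = simulate_stand(cfg, rng)
    d = cov["diameter_cm"]
    assert d.min() >= cfg.diameter_min_cm and d.max() <= cfg.diameter_max_cm + 8
    for t in trees:
        ds = [t.diameter_by_year[y] for y in t.years]
        assert all(b >= a for a, b in zip(ds, ds[1:]))


def test_stand_cec_varies_only_between_stands(rng):
    t1, c1 = simulate_stand(StandConfig(stand_id="S1", cec=5.0), rng)
    t2, c2 = simulate_stand(StandConfig(stand_id="S2", cec=30.0), rng)
    assert c1["cec"].nunique() == 1 and c2["cec"].nunique() == 1
    assert set(c1["cec"]) == {5.0} and set(c2["cec"]) == {30.0}


def test_stand_anomalies_centered(rng):
    _, cov = simulate_stand(StandConfig(n_trees=30, n_years=12), rng)
    per_year = cov.groupby("year")[["t_anomaly", "m_anomaly"]].first()
    assert per_year["t_anomaly"].mean() == pytest.approx(0.0, abs=1e-10)
    assert per_year["m_anomaly"].mean() == pytest.approx(0.0, abs=1e-10)


# ---------------------------------------------------------------------------
# maturation


def test_maturation_immediate_when_hazard_saturates(rng):
    trees, _ = simulate_stand(StandConfig(n_trees=50, n_years=3), rng)
    par = GenerativeParams(beta_rho=(50.0, 0.0))
    states = simulate_maturation(trees, par, rng)
    first = states[states["year"] == states["year"].min()]
    assert (first["mature"] == 1).all()


def test_maturation_is_absorbing(rng):
    trees, _ = simulate_stand(StandConfig(n_trees=100, n_years=10), rng)
    states = simulate_maturation(trees, GenerativeParams(beta_rho=(-1.5, 0.05)), rng)
    for _, grp in states.groupby("tree_id"):
        m = grp.sort_values("year")["mature"].to_numpy()
        assert (np.diff(m) >= 0).all()


def test_first_maturation_time_is_geometric(rng):
    """At constant diameter the first-maturation year is geometric with
    success probability Φ(η); check the empirical pmf at 10,000 trees."""
    n, T, d = 10_000, 8, 30.0
    cfg = StandConfig(
        n_trees=n, n_years=T, diameter_init_mean_cm=d,
        diameter_init_sd_log=0.0, growth_cm_yr=0.0,
    )
    trees, _ = simulate_stand(cfg, rng)
    b0, b1 = -2.0, 0.05
    p = float(norm.cdf(b0 + b1 * d))
    states = simulate_maturation(trees, GenerativeParams(beta_rho=(b0, b1)), rng)
    first = (
        states[states["mature"] == 1].groupby("tree_id")["year"].min()
        - states["year"].min()
    )
    for k in range(4):
        expected = (1 - p) ** k * p
        observed = (first == k).mean() * len(first) / n
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) < 4 * se


# ---------------------------------------------------------------------------
# conditional fecundity


def _zero_noise_params(**kw):
    return GenerativeParams(tau_ind=0.0, tau_yr=0.0, sigma=0.0, **kw)


def test_fecundity_deterministic_when_noise_off(rng):
    trees, cov = simulate_stand(StandConfig(n_trees=30, n_years=5), rng)
    par = _zero_noise_params(
        beta_rho=(50.0, 0.0), beta_psi={"intercept": 2.0, "diameter_cm": 0.1}
    )
    states = simulate_maturation(trees, par, rng)
    truth = simulate_fecundity(trees, states, cov, par, rng)
    expected = np.exp(2.0 + 0.1 * cov.sort_index()["diameter_cm"])
    merged = cov.merge(truth.table, on=["tree_id", "year"])
    assert np.allclose(
        merged["psi"], np.exp(2.0 + 0.1 * merged["diameter_cm"]), rtol=1e-12
    )
    assert (merged.loc[merged["mature"] == 0, "fecundity"] == 0).all()


def test_fecundity_unit_when_all_zero(rng):
    trees, cov = simulate_stand(StandConfig(n_trees=10, n_years=3), rng)
    par = _zero_noise_params(beta_rho=(50.0, 0.0), beta_psi={"intercept": 0.0})
    states = simulate_maturation(trees, par, rng)
    truth = simulate_fecundity(trees, states, cov, par, rng)
    assert np.allclose(truth.table["psi"], 1.0)


def test_fecundity_missing_covariate_raises(rng):
    trees, cov = simulate_stand(StandConfig(n_trees=5, n_years=2), rng)
    par = GenerativeParams(beta_psi={"intercept": 1.0, "no_such_column": 2.0})
    states = simulate_maturation(trees, par, rng)
    with pytest.raises(ValueError, match="no_such_column"):
        simulate_fecundity(trees, states, cov, par, rng)


def test_year_effects_drive_synchrony(rng):
    """Large τ_yr and small σ makes log f nearly perfectly correlated
    between trees of the same species × region group (masting)."""
    cfg = StandConfig(n_trees=500, n_years=12)
    par = GenerativeParams(
        beta_rho=(50.0, 0.0),
        beta_psi={"intercept": 4.0},
        tau_ind=0.0,
        tau_yr=2.0,
        sigma=0.05,
    )
    trees, cov = simulate_stand(cfg, rng)
    states = simulate_maturation(trees, par, rng)
    truth = simulate_fecundity(trees, states, cov, par, rng)
    wide = truth.table.pivot(index="year", columns="tree_id", values="log_psi")
    sub = wide.iloc[:, :40]
    corr = sub.corr().to_numpy()
    off = corr[np.triu_indices_from(corr, k=1)]
    assert off.mean() > 0.95


def test_cec_coefficient_scales_fecundity(rng):
    """Raising CEC by one unit multiplies ψ by exp(β_cec) when the same
    noise stream is used (paired simulation)."""
    cfg = StandConfig(n_trees=50, n_years=4)
    par = GenerativeParams(
        beta_rho=(50.0, 0.0), beta_psi={"intercept": 1.0, "cec": 0.08}
    )
    trees, cov = simulate_stand(cfg, rng)
    states = simulate_maturation(trees, par, np.random.default_rng(1))
    t1 = simulate_fecundity(trees, states, cov, par, np.random.default_rng(5))
    cov2 = cov.copy()
    cov2["cec"] = cov2["cec"] + 1.0
    t2 = simulate_fecundity(trees, states, cov2, par, np.random.default_rng(5))
    ratio = t2.table["psi"].to_numpy() / t1.table["psi"].to_numpy()
    assert np.allclose(ratio, math.exp(0.08), rtol=1e-10)


# ---------------------------------------------------------------------------
# dispersal kernel


def test_kernel_closed_form_at_zero():
    u = 60.0
    assert dispersal_kernel(0.0, u) == pytest.approx(1.0 / (math.pi * u))


def test_kernel_integrates_to_one():
    u = 45.0
    total, err = quad(lambda r: 2 * math.pi * r * dispersal_kernel(r, u), 0, np.inf)
    assert total == pytest.approx(1.0, abs=1e-6)


def test_kernel_monotone_and_errors():
    r = np.linspace(0, 500, 2000)
    k = dispersal_kernel(r, 80.0)
    assert (np.diff(k) <= 0).all()
    with pytest.raises(ValueError):
        dispersal_kernel(1.0, 0.0)
    with pytest.raises(ValueError):
        dispersal_kernel(-1.0, 10.0)


# ---------------------------------------------------------------------------
# trap counts


def _single_tree_world(f_value, rng, n_years=1):
    cfg = StandConfig(n_trees=1, n_years=n_years, extent_m=10.0)
    trees, cov = simulate_stand(cfg, rng)
    rows = []
    for y in trees[0].years:
        rows.append(
            {
                "tree_id": trees[0].tree_id,
                "species": trees[0].species,
                "stand_id": "S1",
                "group": "g",
                "year": y,
                "mature": 1,
                "log_psi": math.log(f_value) if f_value > 0 else -np.inf,
                "psi": f_value,
                "fecundity": f_value,
            }
        )
    truth = LatentTruth(pd.DataFrame(rows), {}, {})
    return trees, truth


def test_trap_intensity_single_tree_closed_form(rng):
    trees, truth = _single_tree_world(1000.0, rng)
    t = trees[0]
    trap = TrapRecord("p", "S1", t.x + 0.1, t.y, 0.5)
    par = GenerativeParams(kernel_scale=70.0)
    lam = 0.5 * 1000.0 * float(dispersal_kernel(0.1, 70.0))
    reps = 10_000
    rng2 = np.random.default_rng(3)
    counts = []
    for _ in range(200):
        recs = simulate_trap_counts(trees, truth, [trap], par, rng2)
        counts.extend(recs[0].counts_by_year.values())
    counts = np.asarray(counts, dtype=float)
    assert counts.mean() == pytest.approx(lam, abs=4 * math.sqrt(lam / len(counts)))


def test_trap_counts_zero_when_sterile(rng):
    trees, truth = _single_tree_world(0.0, rng, n_years=3)
    traps = place_traps(StandConfig(n_trees=1, extent_m=10.0), 4, rng)
    recs = simulate_trap_counts(trees, truth, traps, GenerativeParams(), rng)
    assert all(v == 0 for r in recs for v in r.counts_by_year.values())


def test_trap_count_moments_match_poisson_intensity(rng):
    """Replicated draws of one trap-year have mean ≈ variance ≈ λ."""
    trees, truth = _single_tree_world(800.0, rng)
    t = trees[0]
    trap = TrapRecord("p", "S1", t.x + 3.0, t.y, 0.5)
    par = GenerativeParams(kernel_scale=60.0)
    lam = 0.5 * 800.0 * float(dispersal_kernel(3.0, 60.0))
    rng2 = np.random.default_rng(11)
    draws = np.array(
        [
            list(simulate_trap_counts(trees, truth, [trap], par, rng2)[0]
                 .counts_by_year.values())[0]
            for _ in range(3000)
        ],
        dtype=float,
    )
    n = len(draws)
    assert draws.mean() == pytest.approx(lam, abs=4 * math.sqrt(lam / n))
    assert draws.var() == pytest.approx(lam, rel=0.15)


def test_genus_level_counts_pool_congeners(rng):
    cfg = StandConfig(
        n_trees=40, n_years=2,
        species_probs={"Quercus_alba": 0.5, "Quercus_rubra": 0.5},
    )
    trees, cov = simulate_stand(cfg, rng)
    par = GenerativeParams(
        beta_rho=(50.0, 0.0), beta_psi={"intercept": 5.0}, genus_id_prob=1.0
    )
    states = simulate_maturation(trees, par, rng)
    truth = simulate_fecundity(trees, states, cov, par, rng)
    traps = place_traps(cfg, 3, rng)
    recs = simulate_trap_counts(trees, truth, traps, par, rng)
    levels = {k[2] for r in recs for k in r.counts_by_year}
    taxa = {k[1] for r in recs for k in r.counts_by_year}
    assert levels == {"genus"}
    assert taxa == {"Quercus"}


# ---------------------------------------------------------------------------
# crop counts


def _truth_rows(f, n):
    rows = [
        {
            "tree_id": "t1", "species": "A", "stand_id": "S1", "group": "g",
            "year": 2000 + i, "mature": 1, "log_psi": 0.0, "psi": f,
            "fecundity": f,
        }
        for i in range(n)
    ]
    return LatentTruth(pd.DataFrame(rows), {}, {})


def test_crop_counts_exact_when_full_crop_observed(rng):
    truth = _truth_rows(137.0, 5)
    recs = simulate_crop_counts(truth, GenerativeParams(), rng, crop_fraction=1.0)
    assert [r.structures_counted for r in recs] == [137] * 5


def test_crop_counts_zero_fecundity(rng):
    truth = _truth_rows(0.0, 3)
    recs = simulate_crop_counts(truth, GenerativeParams(), rng, crop_fraction=0.4)
    assert all(r.structures_counted == 0 for r in recs)


def test_crop_counts_marginal_mean(rng):
    """Law of total expectation: E(count) = f·φ̂ marginally over the
    beta-distributed observed fraction."""
    f, phat, reps = 200.0, 0.35, 10_000
    truth = _truth_rows(f, reps)
    recs = simulate_crop_counts(
        truth, GenerativeParams(nu=20.0), rng, crop_fraction=phat
    )
    counts = np.array([r.structures_counted for r in recs], dtype=float)
    # var(count) inflated by the beta mixing; use empirical se
    se = counts.std() / math.sqrt(reps)
    assert counts.mean() == pytest.approx(f * phat, abs=4 * se)


def test_crop_fraction_validation(rng):
    truth = _truth_rows(10.0, 1)
    with pytest.raises(ValueError):
        simulate_crop_counts(truth, GenerativeParams(), rng, crop_fraction=0.0)
    with pytest.raises(ValueError):
        simulate_crop_counts(truth, GenerativeParams(), rng, crop_fraction=1.2)


# ---------------------------------------------------------------------------
# phylogeny and traits


def test_phylogeny_simulation_basics(rng):
    tree = simulate_phylogeny(50, rng)
    assert len(tree.leaf_nodes()) == 50
    depths = [l.distance_from_root() for l in tree.leaf_node_iter()]
    assert max(depths) == pytest.approx(1.0, rel=1e-9)
    assert min(e.length for e in tree.preorder_edge_iter() if e.length is not None) > 0
    with pytest.raises(ValueError):
        simulate_phylogeny(2, rng)


def test_trait_lambda_zero_is_iid(rng):
    """λ = 0 on an ultrametric tree gives i.i.d. tips: off-diagonal
    sample correlations are near zero."""
    tree = simulate_phylogeny(8, rng)
    draws = np.array([simulate_trait(tree, 0.0, 1.0, rng).to_numpy() for _ in range(4000)])
    corr = np.corrcoef(draws.T)
    off = corr[np.triu_indices_from(corr, k=1)]
    assert np.abs(off).max() < 0.08
    assert draws.var(axis=0) == pytest.approx(np.ones(8), rel=0.15)


def test_trait_sister_covariance_closed_form(rng):
    """For a sister pair with shared path length s, cov = λσ²s."""
    import dendropy

    tree = dendropy.Tree.get(data="(A:1,(B:0.4,C:0.4):0.6);", schema="newick")
    for lam in (0.3, 1.0):
        draws = np.array(
            [simulate_trait(tree, lam, 1.5, rng).to_numpy() for _ in range(6000)]
        )
        labels = list(simulate_trait(tree, lam, 1.5, rng).index)
        b, c = labels.index("B"), labels.index("C")
        cov_bc = np.cov(draws[:, b], draws[:, c])[0, 1]
        assert cov_bc == pytest.approx(lam * 1.5**2 * 0.6, abs=0.12)


def test_trait_lambda_validation(rng):
    tree = simulate_phylogeny(5, rng)
    with pytest.raises(ValueError):
        simulate_trait(tree, 1.5, 1.0, rng)


def test_bm_covariance_ordering_sisters_vs_distant(rng):
    """Under plain BM, sister tips covary more than distant tips."""
    tree = simulate_phylogeny(12, rng)
    C, labels = phylo_covariance(tree)
    draws = np.array([simulate_trait(tree, 1.0, 1.0, rng).to_numpy() for _ in range(1000)])
    S = np.cov(draws.T)
    iu = np.triu_indices_from(C, k=1)
    hi = np.argsort(C[iu])[-5:]   # most shared history
    lo = np.argsort(C[iu])[:5]
    assert S[iu][hi].mean() > S[iu][lo].mean()


# ---------------------------------------------------------------------------
# full world invariants


def test_world_absorbing_and_budget(small_world):
    tab = small_world.truth.table
    for _, grp in tab.groupby("tree_id"):
        m = grp.sort_values("year")["mature"].to_numpy()
        assert (np.diff(m) >= 0).all()
        assert (grp.loc[grp["mature"] == 0, "fecundity"] == 0).all()
    # expected seeds captured by traps cannot exceed production times
    # the best-case per-trap interception probability
    total_f = tab["fecundity"].sum()
    kmax = float(dispersal_kernel(0.0, small_world.params.kernel_scale))
    cap = total_f * sum(t.collection_area for t in small_world.traps) * kmax
    exp_caught = sum(
        sum(t.counts_by_year.values()) for t in small_world.traps
    )
    assert exp_caught <= max(cap, 1.0) * 1.5 + 50


def test_world_reproducible_by_seed():
    cfg = StandConfig(n_trees=8, n_years=4)
    par = GenerativeParams()
    w1 = simulate_world(cfg, par, 9, n_traps=3)
    w2 = simulate_world(cfg, par, 9, n_traps=3)
    pd.testing.assert_frame_equal(w1.truth.table, w2.truth.table)
    assert [t.counts_by_year for t in w1.traps] == [t.counts_by_year for t in w2.traps]
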