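"""Simulate a complete study system: a mapped stand, latent maturation
and fecundity, seed-trap counts under a 2Dt seed shadow, and crop
counts with observation error."""

from fecundity.simulate import GenerativeParams, StandConfig, simulate_world

config = StandConfig(n_trees=30, n_years=8, extent_m=80, cec=18.0)
params = GenerativeParams(
    beta_rho=(-2.0, 0.1),                       # probit maturation vs diameter (cm)
    beta_psi={"intercept": 6.0, "diameter_cm": 0.03},
    tau_ind=0.3,                                # sd of per-tree log-fecundity effects
    tau_yr=0.5,                                 # sd of shared year (masting) effects
    sigma=0.4,                                  # residual process sd on log psi
    kernel_scale=80.0,                          # 2Dt dispersal scale u (m^2)
)
world = simulate_world(config, params, rng=42, n_traps=6, crop_fraction=0.5)

truth = world.truth.table
mature = truth[truth["mature"] == 1]
print(f"{len(world.trees)} trees over {config.n_years} years; "
      f"{truth['mature'].mean():.0%} of tree-years mature")
print(f"median fecundity of mature tree-years: {mature['fecundity'].median():,.0f} seeds")
total_trapped = sum(sum(t.counts_by_year.values()) for t in world.traps)
print(f"seeds collected across {len(world.traps)} traps: {total_trapped}")
print(f"crop-count observations: {len(world.crop_counts)}")
# The trap total is far below production: each 0.5-m2 trap intercepts only
# the seed shadow integrated over its area, which is the signal the
# state-space model inverts to recover per-tree fecundity.
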