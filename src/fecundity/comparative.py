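"""Species-level comparative analyses.

* Seed size–number trade-off: OLS of log10 SSP on log10 seed mass
  (with the seed-number slope β − 1 against the strict-trade-off null
  of −1), optionally with order × seed-size interactions.
* Phylogenetic signal: maximum-likelihood Pagel's λ, profiling out the
  root mean and the Brownian rate.
* Phylogenetic regression: GLS under the λ-transformed Brownian
  covariance with λ estimated jointly by ML.
* Ancestral states: GLS/ML reconstruction of internal-node values.
* Soil-fertility responses: per-species β_cec with eligibility rules
  and predicted response curves; community-level CSP-vs-CEC regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .phylo import lambda_transform, node_covariance, phylo_covariance

__all__ = [
    "TradeoffFit",
    "fit_tradeoff",
    "fit_tradeoff_by_order",
    "PhyloSignalResult",
    "pagels_lambda",
    "PhyloGLSResult",
    "phylo_regression",
    "ancestral_states",
    "extract_cec_responses",
    "percent_negative",
    "csp_fertility_regression",
]


# ---------------------------------------------------------------------------
# trade-off regressions


@dataclass
class TradeoffFit:
    """Fitted log10 SSP = α + β·log10 m regression.

    ``number_slope`` is β − 1, the slope of log10 seed number per basal
    area on log10 seed mass (a strict size–number trade-off predicts
    −1, i.e. β = 0).
    """

    alpha: float
    beta: float
    se_alpha: float
    se_beta: float
    r2: float
    p_value: float
    n: int
    number_slope: float
    per_order: dict[str, dict[str, float]] = field(default_factory=dict)
    results: object = None

    def confint_beta(self, level: float = 0.95):
        ci = self.results.conf_int(alpha=1 - level)
        return float(ci[1, 0]), float(ci[1, 1])


def _tradeoff_frame(ssp: pd.DataFrame, traits) -> pd.DataFrame:
    if not isinstance(traits, pd.DataFrame):
        traits = pd.DataFrame(
            [{"species": t.species, "seed_mass_g": t.seed_mass} for t in traits]
        )
    df = ssp.merge(traits[["species", "seed_mass_g"]], on="species", how="inner")
    bad = (df["ssp"] <= 0) | (df["seed_mass_g"] <= 0)
    if bad.any():
        import logging

        logging.getLogger(__name__).info(
            "excluding %d species with nonpositive SSP or seed mass", bad.sum()
        )
        df = df[~bad]
    df = df.copy()
    df["log_ssp"] = np.log10(df["ssp"])
    df["log_m"] = np.log10(df["seed_mass_g"])
    return df


def fit_tradeoff(ssp: pd.DataFrame, traits) -> TradeoffFit:
    """OLS of log10 SSP on log10 seed mass across species."""
    df = _tradeoff_frame(ssp, traits)
    if len(df) < 3:
        raise ValueError("need at least 3 species with positive SSP and seed mass")
    X = sm.add_constant(df["log_m"].to_numpy())
    res = sm.OLS(df["log_ssp"].to_numpy(), X).fit()
    return TradeoffFit(
        alpha=float(res.params[0]),
        beta=float(res.params[1]),
        se_alpha=float(res.bse[0]),
        se_beta=float(res.bse[1]),
        r2=float(res.rsquared),
        p_value=float(res.pvalues[1]),
        n=len(df),
        number_slope=float(res.params[1]) - 1.0,
        results=res,
    )


def fit_tradeoff_by_order(
    ssp: pd.DataFrame, traits, orders: dict[str, str], min_per_order: int = 3
) -> TradeoffFit:
    """Trade-off regression with taxonomic order as a factor and an
    order × seed-size interaction; orders with fewer than
    ``min_per_order`` species are pooled into "other"."""
    df = _tradeoff_frame(ssp, traits)
    df["order"] = df["species"].map(orders).fillna("other")
    counts = df["order"].value_counts()
    small = counts[counts < min_per_order].index
    df.loc[df["order"].isin(small), "order"] = "other"
    levels = sorted(df["order"].unique())
    ref = levels[0]
    cols = ["intercept", "log_m"]
    X = [np.ones(len(df)), df["log_m"].to_numpy()]
    for lev in levels[1:]:
        ind = (df["order"] == lev).astype(float).to_numpy()
        X.append(ind)
        X.append(ind * df["log_m"].to_numpy())
        cols += [f"order[{lev}]", f"order[{lev}]:log_m"]
    Xm = np.column_stack(X)
    res = sm.OLS(df["log_ssp"].to_numpy(), Xm).fit()
    params = dict(zip(cols, res.params))
    per_order = {}
    for lev in levels:
        a = params["intercept"] + params.get(f"order[{lev}]", 0.0)
        b = params["log_m"] + params.get(f"order[{lev}]:log_m", 0.0)
        per_order[lev] = {"alpha": float(a), "beta": float(b)}
    fit0 = TradeoffFit(
        alpha=float(params["intercept"]),
        beta=float(params["log_m"]),
        se_alpha=float(res.bse[0]),
        se_beta=float(res.bse[1]),
        r2=float(res.rsquared),
        p_value=float(res.pvalues[1]),
        n=len(df),
        number_slope=float(params["log_m"]) - 1.0,
        per_order=per_order,
        results=res,
    )
    fit0.design_columns = cols
    fit0.reference_order = ref
    return fit0


# ---------------------------------------------------------------------------
# phylogenetic signal and regression


def _match_tree(tree: dendropy.Tree, values: pd.Series):
    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    usable = [s for s in values.index if s in labels and np.isfinite(values[s])]
    if len(usable) < len(labels):
        tree = tree.clone(depth=1)
        tree.retain_taxa_with_labels(usable)
    C, order = phylo_covariance(tree)
    y = values.loc[order].to_numpy(dtype=float)
    return tree, C, order, y


def _profile_loglik(y: np.ndarray, V: np.ndarray, X: np.ndarray):
    """ML log-likelihood of y ~ N(Xb, σ²V) profiling b and σ²."""
    n = len(y)
    L = np.linalg.cholesky(V)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    Xi = np.linalg.solve(L, X)
    yi = np.linalg.solve(L, y)
    b, *_ = np.linalg.lstsq(Xi, yi, rcond=None)
    r = yi - Xi @ b
    s2 = float(r @ r) / n
    ll = -0.5 * (n * math.log(2 * math.pi * s2) + logdet + n)
    return ll, b, s2, Xi, yi


@dataclass
class PhyloSignalResult:
    lambda_hat: float
    loglik: float
    loglik0: float
    p_value: float
    n_tips: int
    sigma2: float
    root_mean: float


def pagels_lambda(tree: dendropy.Tree, values: pd.Series) -> PhyloSignalResult:
    """ML estimate of Pagel's λ ∈ [0, 1] for a continuous trait.

    The likelihood is multivariate normal with covariance σ²C_λ, where
    C_λ scales the off-diagonal Brownian covariance by λ; root mean and
    σ² are profiled out.  The p-value is the χ²₁ likelihood-ratio test
    against λ = 0 (independence across species).
    """
    tree, C, order, y = _match_tree(tree, values)
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 usable tips")
    X = np.ones((n, 1))

    def nll(lam: float) -> float:
        ll, *_ = _profile_loglik(y, lambda_transform(C, lam), X)
        return -ll

    res = minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-6})
    candidates = [(float(res.x), -res.fun), (0.0, -nll(0.0)), (1.0, -nll(1.0))]
    lam_hat, ll_hat = max(candidates, key=lambda t: t[1])
    ll0 = -nll(0.0)
    stat = max(0.0, 2.0 * (ll_hat - ll0))
    ll_best, b, s2, _, _ = _profile_loglik(y, lambda_transform(C, lam_hat), X)
    return PhyloSignalResult(
        lambda_hat=lam_hat,
        loglik=ll_hat,
        loglik0=ll0,
        p_value=float(chi2.sf(stat, 1)),
        n_tips=n,
        sigma2=s2,
        root_mean=float(b[0]),
    )


@dataclass
class PhyloGLSResult:
    params: pd.Series
    bse: pd.Series
    lambda_hat: float
    loglik: float
    n: int
    sigma2: float


def phylo_regression(
    y: pd.Series,
    X: pd.DataFrame,
    tree: dendropy.Tree,
    lam: float | None = None,
) -> PhyloGLSResult:
    """Phylogenetic generalized least squares of y on X.

    Residual covariance is the λ-transformed Brownian matrix; λ is
    estimated jointly by ML unless fixed.  Complete cases only; the
    tree is pruned to the used tips.  Collinear predictors raise,
    naming the columns.
    """
    df = X.copy()
    df["__y"] = y
    df = df.dropna()
    series = df["__y"]
    tree, C, order, yv = _match_tree(tree, series)
    df = df.loc[order]
    names = ["intercept"] + list(X.columns)
    Xm = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(float) for c in X.columns])
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        _, R = np.linalg.qr(Xm)
        bad = [names[j] for j in range(Xm.shape[1]) if abs(R[j, j]) < 1e-8]
        raise ValueError(f"collinear predictors: {bad}")

    def nll(l):
        ll, *_ = _profile_loglik(yv, lambda_transform(C, l), Xm)
        return -ll

    if lam is None:
        res = minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                              options={"xatol": 1e-6})
        candidates = [(float(res.x), -res.fun), (0.0, -nll(0.0)), (1.0, -nll(1.0))]
        lam, ll = max(candidates, key=lambda t: t[1])
    ll, b, s2, Xi, _ = _profile_loglik(yv, lambda_transform(C, lam), Xm)
    n, p = Xm.shape
    s2_unbiased = s2 * n / (n - p)
    cov_b = s2_unbiased * np.linalg.inv(Xi.T @ Xi)
    return PhyloGLSResult(
        params=pd.Series(b, index=names),
        bse=pd.Series(np.sqrt(np.diag(cov_b)), index=names),
        lambda_hat=float(lam),
        loglik=float(ll),
        n=n,
        sigma2=s2,
    )


def ancestral_states(tree: dendropy.Tree, values: pd.Series) -> pd.Series:
    """GLS/ML ancestral-state estimates for a continuous trait under
    Brownian motion.

    Internal nodes get the conditional expectation given the tips; the
    root estimate equals the GLS mean.  Internal nodes are labeled
    node1.. in preorder where unlabeled; the returned Series is indexed
    by those labels.
    """
    C_all, nodes, tip_names = node_covariance(tree)
    k = len(tip_names)
    y = values.loc[tip_names].to_numpy(dtype=float)
    Ctt = C_all[:k, :k]
    Cat = C_all[k:, :k]
    one = np.ones(k)
    Ci = np.linalg.inv(Ctt + 1e-12 * np.eye(k))
    mu = float(one @ Ci @ y / (one @ Ci @ one))
    anc = mu + Cat @ Ci @ (y - mu)
    labels = []
    for idx, node in enumerate(nodes[k:]):
        if node.label is None:
            node.label = f"node{idx + 1}"
        labels.append(node.label)
        node.ancestral_state = float(anc[idx])
    return pd.Series(anc, index=labels)


# ---------------------------------------------------------------------------
# soil-fertility responses


def extract_cec_responses(
    fits: pd.DataFrame,
    data: pd.DataFrame,
    min_span: float = 10.0,
    min_sites: int = 3,
    coef_tables: dict[str, dict[str, float]] | None = None,
    cec_points: int = 25,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Per-species soil-fertility responses β_cec with eligibility.

    ``fits`` has columns species, beta_cec, se.  A species is eligible
    when its observed CEC span in ``data`` (columns species, stand_id,
    cec) reaches ``min_span`` cmol(+)/kg over at least ``min_sites``
    distinct sites; ineligible species are flagged with a reason, never
    dropped.  When per-species coefficient tables are given, a
    predicted fecundity-vs-CEC curve is produced holding the other
    covariates at reference values (half of the species' maximum
    diameter, shade class 3, site-mean climate), monotone in the
    direction of β_cec's sign.
    """
    rows = []
    curves: dict[str, pd.DataFrame] = {}
    for _, r in fits.iterrows():
        sp = str(r["species"])
        sub = data[data["species"] == sp]
        span = float(sub["cec"].max() - sub["cec"].min()) if len(sub) else 0.0
        n_sites = int(sub["stand_id"].nunique()) if len(sub) else 0
        if n_sites < min_sites:
            eligible, reason = False, f"only {n_sites} site(s)"
        elif span < min_span:
            eligible, reason = False, f"CEC span {span:.1f} < {min_span}"
        else:
            eligible, reason = True, ""
        beta = float(r["beta_cec"])
        rows.append(
            {
                "species": sp,
                "beta_cec": beta,
                "se": float(r.get("se", np.nan)),
                "sign": int(np.sign(beta)),
                "eligible": eligible,
                "reason": reason,
                "cec_span": span,
                "n_sites": n_sites,
            }
        )
        if eligible and coef_tables and sp in coef_tables and len(sub):
            coefs = coef_tables[sp]
            grid = np.linspace(sub["cec"].min(), sub["cec"].max(), cec_points)
            d_ref = 0.5 * float(sub["diameter_cm"].max()) if "diameter_cm" in sub else 0.0
            ref = {
                "intercept": 1.0,
                "diameter_cm": d_ref,
                "diameter_cm_sq": d_ref**2,
                "shade": 3.0,
            }
            for c in ("t_site_mean", "m_site_mean", "t_anomaly", "m_anomaly",
                      "u1", "u2", "u3"):
                ref[c] = float(sub[c].mean()) if c in sub else 0.0
            base = sum(
                coefs.get(name, 0.0) * val for name, val in ref.items()
            )
            log_psi = base + coefs.get("cec", beta) * grid
            curves[sp] = pd.DataFrame({"cec": grid, "psi": np.exp(log_psi)})
    return pd.DataFrame(rows), curves


def percent_negative(responses: pd.DataFrame, membership: dict[str, str]) -> pd.Series:
    """Percentage of eligible species with negative β_cec per group."""
    tab = responses[responses["eligible"]].copy()
    tab["group"] = tab["species"].map(membership)
    return tab.groupby("group")["sign"].apply(lambda s: 100.0 * (s < 0).mean())


def csp_fertility_regression(csp: pd.DataFrame, level: float = 0.95):
    """OLS of log10 CSP on plot CEC across inventory plots.

    Returns (slope, se, p_value, (ci_lo, ci_hi), results).  Requires at
    least 3 plots.
    """
    if len(csp) < 3:
        raise ValueError("need at least 3 plots with CSP and CEC")
    y = np.log10(csp["csp"].to_numpy(dtype=float))
    X = sm.add_constant(csp["cec"].to_numpy(dtype=float))
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=1 - level)
    return (
        float(res.params[1]),
        float(res.bse[1]),
        float(res.pvalues[1]),
        (float(ci[1, 0]), float(ci[1, 1])),
        res,
    )
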