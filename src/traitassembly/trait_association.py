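"""Trait-trait relationships.

Two complementary views of how leaf traits covary:

* :func:`phylo_correlation` — a phylogeny-aware correlation between species
  means.  Each trait is modeled as a lambda-rescaled Brownian process with a
  measurement-error diagonal (the squared standard errors of the species
  means); the cross-trait evolutionary covariance is then estimated by
  maximum likelihood and tested with a likelihood-ratio test against zero
  covariance.  With a star phylogeny and zero standard errors this reduces
  exactly to the ordinary Pearson correlation.
* :func:`spearman_matrix` — rank correlations at the individual level,
  pooled across species or within each sufficiently sampled species.
  p-values are reported raw and Holm-adjusted side by side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from statsmodels.stats.multitest import multipletests

from .core_io import Phylogeny, SpeciesTraitMatrix, TraitTable
from .synthetic_data import lambda_transform

__all__ = [
    "PhyloCorrelationResult",
    "phylo_correlation",
    "spearman_matrix",
    "phylo_correlation_matrix",
]


@dataclass
class PhyloCorrelationResult:
    coefficient: float
    p_value: float
    n_species: int
    lambda_a: float
    lambda_b: float
    sigma2_a: float
    sigma2_b: float
    loglik: float
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Univariate lambda fit with measurement error
# ---------------------------------------------------------------------------


def _gls_profile(V: np.ndarray, x: np.ndarray) -> tuple[float, float, float]:
    """Profile the mean out under covariance V; return (loglik, mu, quad)."""
    n = x.size
    cho = linalg.cho_factor(V)
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    Vinv1 = linalg.cho_solve(cho, np.ones(n))
    mu = float(Vinv1 @ x) / float(np.ones(n) @ Vinv1)
    r = x - mu
    q = float(r @ linalg.cho_solve(cho, r))
    ll = -0.5 * (n * math.log(2 * math.pi) + logdet + q)
    return ll, mu, q


def _fit_lambda_me(
    x: np.ndarray, C: np.ndarray, se2: np.ndarray, lam_max: float
) -> tuple[float, float, float, float]:
    """ML fit of (lambda, sigma2) for one trait with measurement-error
    diagonal; returns (lambda, sigma2, mu, loglik)."""
    n = x.size

    def nll(params: np.ndarray) -> float:
        lam, logs2 = params
        V = math.exp(logs2) * lambda_transform(C, lam) + np.diag(se2)
        try:
            ll, _, _ = _gls_profile(V, x)
        except linalg.LinAlgError:
            return 1e10
        return -ll

    s2_init = max(np.var(x, ddof=1), 1e-8)
    best = None
    for lam0 in (0.2, 0.8):
        res = optimize.minimize(
            nll,
            x0=np.array([lam0, math.log(s2_init)]),
            method="L-BFGS-B",
            bounds=[(0.0, lam_max), (math.log(s2_init) - 12, math.log(s2_init) + 6)],
        )
        if best is None or res.fun < best.fun:
            best = res
    lam, logs2 = best.x
    s2 = math.exp(logs2)
    V = s2 * lambda_transform(C, lam) + np.diag(se2)
    ll, mu, _ = _gls_profile(V, x)
    return float(lam), float(s2), float(mu), float(ll)


# ---------------------------------------------------------------------------
# Bivariate evolutionary correlation
# ---------------------------------------------------------------------------


def _bivariate_nll(
    params: np.ndarray,
    xa: np.ndarray,
    xb: np.ndarray,
    Ca: np.ndarray,
    Cb: np.ndarray,
    Cab: np.ndarray,
    se2a: np.ndarray,
    se2b: np.ndarray,
) -> float:
    logs2a, logs2b, z = params
    s2a, s2b = math.exp(logs2a), math.exp(logs2b)
    rho = math.tanh(z)
    n = xa.size
    V = np.empty((2 * n, 2 * n))
    V[:n, :n] = s2a * Ca + np.diag(se2a)
    V[n:, n:] = s2b * Cb + np.diag(se2b)
    V[:n, n:] = rho * math.sqrt(s2a * s2b) * Cab
    V[n:, :n] = V[:n, n:].T
    try:
        cho = linalg.cho_factor(V)
    except linalg.LinAlgError:
        return 1e10
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    # GLS means: block design, one intercept per trait
    X = np.zeros((2 * n, 2))
    X[:n, 0] = 1.0
    X[n:, 1] = 1.0
    y = np.concatenate([xa, xb])
    Vinv_X = linalg.cho_solve(cho, X)
    beta = np.linalg.solve(X.T @ Vinv_X, Vinv_X.T @ y)
    r = y - X @ beta
    q = float(r @ linalg.cho_solve(cho, r))
    return 0.5 * (2 * n * math.log(2 * math.pi) + logdet + q)


def phylo_correlation(
    mean_a: pd.Series,
    se_a: pd.Series,
    mean_b: pd.Series,
    se_b: pd.Series,
    phylogeny: Phylogeny,
) -> PhyloCorrelationResult:
    """Evolutionary correlation between two traits under lambda-GLS with
    measurement error.

    Each trait's marginal covariance is sigma2 * C(lambda_hat) + diag(SE^2)
    with lambda fitted per trait; the cross block is
    rho * sigma_a * sigma_b * C(sqrt(lambda_a * lambda_b)).  (sigma2_a,
    sigma2_b, rho) are then jointly re-estimated by ML, and rho is tested
    with a 1-df likelihood-ratio test against rho = 0.
    """
    common = sorted(set(mean_a.dropna().index) & set(mean_b.dropna().index) & set(phylogeny.labels))
    if len(common) < 5:
        raise ValueError(f"need >= 5 species shared by both traits and the tree, got {len(common)}")
    phylo = phylogeny.prune_to(common) if set(phylogeny.labels) != set(common) else phylogeny
    order = phylo.labels
    xa = mean_a.reindex(order).to_numpy(dtype=float)
    xb = mean_b.reindex(order).to_numpy(dtype=float)
    se2a = se_a.reindex(order).fillna(0.0).to_numpy(dtype=float) ** 2
    se2b = se_b.reindex(order).fillna(0.0).to_numpy(dtype=float) ** 2
    C = phylo.vcv().to_numpy()
    from .phylo_signal import lambda_max as _lmax

    lmax = min(_lmax(phylo), 1.0)
    lam_a, s2a0, _, _ = _fit_lambda_me(xa, C, se2a, lmax)
    lam_b, s2b0, _, _ = _fit_lambda_me(xb, C, se2b, lmax)
    Ca = lambda_transform(C, lam_a)
    Cb = lambda_transform(C, lam_b)
    Cab = lambda_transform(C, math.sqrt(lam_a * lam_b))

    args = (xa, xb, Ca, Cb, Cab, se2a, se2b)
    x0 = np.array([math.log(max(s2a0, 1e-10)), math.log(max(s2b0, 1e-10)), 0.0])
    bounds = [(x0[0] - 10, x0[0] + 6), (x0[1] - 10, x0[1] + 6), (-6.0, 6.0)]
    opts = {"ftol": 1e-15, "gtol": 1e-12, "maxfun": 5000}
    res = optimize.minimize(_bivariate_nll, x0, args=args, method="L-BFGS-B",
                            bounds=bounds, options=opts)
    # polish: Nelder-Mead is insensitive to the flat-gradient finish of
    # L-BFGS-B and pins the optimum to high precision
    res = optimize.minimize(_bivariate_nll, res.x, args=args, method="Nelder-Mead",
                            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 4000})
    res0 = optimize.minimize(
        lambda p: _bivariate_nll(np.array([p[0], p[1], 0.0]), *args),
        x0[:2], method="L-BFGS-B", bounds=bounds[:2], options=opts,
    )
    ll1, ll0 = -float(res.fun), -float(res0.fun)
    rho = math.tanh(res.x[2])
    lr = max(0.0, 2.0 * (ll1 - ll0))
    p = float(stats.chi2.sf(lr, df=1))
    return PhyloCorrelationResult(
        coefficient=float(rho),
        p_value=p,
        n_species=len(common),
        lambda_a=lam_a,
        lambda_b=lam_b,
        sigma2_a=float(math.exp(res.x[0])),
        sigma2_b=float(math.exp(res.x[1])),
        loglik=ll1,
        extra={"loglik_rho0": ll0},
    )


def phylo_correlation_matrix(stm: SpeciesTraitMatrix, phylogeny: Phylogeny) -> pd.DataFrame:
    """All pairwise evolutionary correlations; tidy long table."""
    rows = []
    for a, b in combinations(stm.traits, 2):
        try:
            r = phylo_correlation(stm.mean[a], stm.se[a], stm.mean[b], stm.se[b], phylogeny)
            rows.append({"trait_a": a, "trait_b": b, "level": "species_phylo",
                         "coefficient": r.coefficient, "p_value": r.p_value,
                         "n": r.n_species, "note": ""})
        except (ValueError, RuntimeError) as exc:
            rows.append({"trait_a": a, "trait_b": b, "level": "species_phylo",
                         "coefficient": np.nan, "p_value": np.nan, "n": 0, "note": str(exc)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Spearman correlations at the individual level
# ---------------------------------------------------------------------------


def _spearman_long(df: pd.DataFrame, traits: list[str], level: str, species: str | None) -> list[dict]:
    rows = []
    for a, b in combinations(traits, 2):
        sub = df[[a, b]].dropna()
        n = len(sub)
        if n < 3:
            rows.append({"trait_a": a, "trait_b": b, "level": level, "species": species,
                         "coefficient": np.nan, "p_value": np.nan, "n": n,
                         "note": "fewer than 3 complete pairs"})
            continue
        if sub[a].nunique() < 2 or sub[b].nunique() < 2:
            rows.append({"trait_a": a, "trait_b": b, "level": level, "species": species,
                         "coefficient": np.nan, "p_value": np.nan, "n": n,
                         "note": "all-tied ranks (zero rank variance)"})
            continue
        r, p = stats.spearmanr(sub[a], sub[b])
        rows.append({"trait_a": a, "trait_b": b, "level": level, "species": species,
                     "coefficient": float(r), "p_value": float(p), "n": n, "note": ""})
    return rows


def spearman_matrix(
    traits: TraitTable,
    scope: str = "pooled",
    columns: list[str] | None = None,
    min_n: int = 5,
) -> pd.DataFrame:
    """Spearman rank correlations among traits at the individual level.

    ``scope='pooled'`` uses all individuals together; ``scope='per_species'``
    returns one set of pairwise correlations per species with at least
    ``min_n`` individuals.  Raw and Holm-adjusted p-values are both
    reported.
    """
    cols = columns or list(traits.trait_columns)
    if scope == "pooled":
        rows = _spearman_long(traits.data, cols, "individuals_pooled", None)
    elif scope == "per_species":
        rows = []
        for sp, grp in traits.data.groupby("species"):
            if len(grp) < min_n:
                continue
            rows.extend(_spearman_long(grp, cols, "within_species", sp))
    else:
        raise ValueError("scope must be 'pooled' or 'per_species'")
    out = pd.DataFrame(rows)
    if len(out):
        ok = out["p_value"].notna()
        adj = np.full(len(out), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(out.loc[ok, "p_value"], method="holm")[1]
        out["p_holm"] = adj
    return out
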