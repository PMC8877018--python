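"""Phylogenetic-signal indices for species-mean traits.

Two families of indices are provided, mirroring the usual multi-method
comparison:

* autocorrelation indices — Moran's I on a phylogenetic proximity matrix
  (default 1/patristic distance, row-normalized) and Abouheif's C_mean
  (Moran's I on the node-degree path-product proximity);
* model-based indices — Blomberg's K and K* (variance-ratio statistics
  standardized to 1 under Brownian motion) and Pagel's lambda (maximum
  likelihood on the lambda-rescaled Brownian covariance).

Permutation indices get two-sided p-values from tip-label shuffles with the
add-one rule p = (#more-extreme + 1)/(n_perm + 1); lambda gets a
likelihood-ratio test against lambda = 0 (chi-square, 1 df).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .core_io import Phylogeny

__all__ = [
    "SignalResult",
    "morans_i",
    "abouheif_cmean",
    "blomberg_k",
    "pagel_lambda",
    "signal_battery",
]


@dataclass
class SignalResult:
    index_name: str
    statistic: float
    p_value: float
    n_species: int
    n_permutations: int = 0
    ultrametric: bool = True
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value out of range: {self.p_value}")


def _aligned(trait: pd.Series, phylogeny: Phylogeny) -> np.ndarray:
    missing = set(phylogeny.labels) - set(trait.index)
    if missing:
        raise ValueError(f"trait missing values for tips: {sorted(missing)}")
    return trait.reindex(phylogeny.labels).to_numpy(dtype=float)


def _two_sided_perm_p(obs: float, null: np.ndarray) -> float:
    n = null.size
    lo = (np.sum(null <= obs) + 1) / (n + 1)
    hi = (np.sum(null >= obs) + 1) / (n + 1)
    return min(1.0, 2.0 * min(lo, hi))


# ---------------------------------------------------------------------------
# Moran-type autocorrelation indices
# ---------------------------------------------------------------------------


def _moran_stat(z: np.ndarray, W: np.ndarray) -> float:
    n = z.size
    s0 = W.sum()
    return float(n / s0 * (z @ W @ z) / (z @ z))


def proximity_matrix(phylogeny: Phylogeny, mode: str = "patristic") -> np.ndarray:
    """Phylogenetic proximity W (zero diagonal, row-normalized).

    ``patristic``: w_ij = 1/d_ij for patristic distance d.  ``abouheif``:
    the node-degree path-product proximity.
    """
    if mode == "patristic":
        D = phylogeny.patristic_distances().to_numpy()
        with np.errstate(divide="ignore"):
            W = 1.0 / D
        np.fill_diagonal(W, 0.0)
    elif mode == "abouheif":
        W = phylogeny.abouheif_proximity().to_numpy()
    else:
        raise ValueError(f"unknown proximity mode {mode!r}")
    rs = W.sum(axis=1, keepdims=True)
    return W / rs


def _moran_like(
    trait: pd.Series,
    phylogeny: Phylogeny,
    W: np.ndarray,
    name: str,
    n_perm: int,
    seed,
) -> SignalResult:
    x = _aligned(trait, phylogeny)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 species")
    z = x - x.mean()
    if np.allclose(z, 0.0):
        raise ValueError("trait has zero variance")
    obs = _moran_stat(z, W)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        zp = rng.permutation(z)
        null[b] = _moran_stat(zp, W)
    return SignalResult(
        index_name=name,
        statistic=obs,
        p_value=_two_sided_perm_p(obs, null),
        n_species=n,
        n_permutations=n_perm,
        ultrametric=phylogeny.is_ultrametric,
        extra={"null_mean": float(null.mean()), "null_sd": float(null.std(ddof=1))},
    )


def morans_i(
    trait: pd.Series,
    phylogeny: Phylogeny,
    weights_mode: str = "patristic",
    n_perm: int = 999,
    seed: int | None = 0,
) -> SignalResult:
    """Moran's I with a phylogenetic proximity matrix and permutation test."""
    W = proximity_matrix(phylogeny, weights_mode)
    return _moran_like(trait, phylogeny, W, "MoranI", n_perm, seed)


def abouheif_cmean(
    trait: pd.Series,
    phylogeny: Phylogeny,
    n_perm: int = 999,
    seed: int | None = 0,
) -> SignalResult:
    """Abouheif's C_mean: Moran's I on the path-product proximity matrix."""
    W = proximity_matrix(phylogeny, "abouheif")
    return _moran_like(trait, phylogeny, W, "AbouheifCmean", n_perm, seed)


# ---------------------------------------------------------------------------
# Blomberg's K / K*
# ---------------------------------------------------------------------------


def blomberg_k(
    trait: pd.Series,
    phylogeny: Phylogeny,
    variant: str = "K",
    n_perm: int = 999,
    seed: int | None = 0,
) -> SignalResult:
    """Blomberg's K (or K*): observed MSE0/MSE standardized by its Brownian
    expectation, with a two-sided tip-shuffle permutation test.

    MSE is the generalized-least-squares mean squared error under the
    Brownian covariance C; MSE0 is the ordinary mean squared deviation from
    the phylogenetically corrected mean (K) or the arithmetic mean (K*).
    Both ratios have expectation 1 under Brownian motion.
    """
    if variant not in ("K", "Kstar"):
        raise ValueError("variant must be 'K' or 'Kstar'")
    x = _aligned(trait, phylogeny)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 species")
    C = phylogeny.vcv().to_numpy()
    try:
        cho = linalg.cho_factor(C)
    except linalg.LinAlgError as exc:
        raise ValueError(f"singular Brownian covariance (duplicate zero-length tips?): {exc}")
    Cinv1 = linalg.cho_solve(cho, np.ones(n))
    s1 = float(np.ones(n) @ Cinv1)  # 1' C^-1 1

    if variant == "K":
        expected = (np.trace(C) - n / s1) / (n - 1)
    else:
        expected = (np.trace(C) - C.sum() / n) / (n - 1)

    def ratio(v: np.ndarray) -> float:
        ahat = float(Cinv1 @ v) / s1
        r = v - ahat
        mse = float(r @ linalg.cho_solve(cho, r)) / (n - 1)
        if variant == "K":
            mse0 = float(r @ r) / (n - 1)
        else:
            d = v - v.mean()
            mse0 = float(d @ d) / (n - 1)
        return mse0 / mse

    obs = ratio(x) / expected
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = ratio(rng.permutation(x)) / expected
    # n_perm = 0 computes the statistic only (no test)
    return SignalResult(
        index_name="BlombergK" if variant == "K" else "BlombergKstar",
        statistic=float(obs),
        p_value=_two_sided_perm_p(obs, null) if n_perm else math.nan,
        n_species=n,
        n_permutations=n_perm,
        ultrametric=phylogeny.is_ultrametric,
        extra={"null_mean": float(null.mean()), "null_sd": float(null.std(ddof=1))} if n_perm > 1 else {},
    )


# ---------------------------------------------------------------------------
# Pagel's lambda
# ---------------------------------------------------------------------------


def _lambda_loglik(x: np.ndarray, C: np.ndarray, lam: float) -> float:
    """Profile log-likelihood of lambda (mu and sigma2 profiled out)."""
    n = x.size
    Cl = lam * C
    np.fill_diagonal(Cl, np.diag(C))
    try:
        cho = linalg.cho_factor(Cl)
    except linalg.LinAlgError:
        return -math.inf
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    Cinv1 = linalg.cho_solve(cho, np.ones(n))
    mu = float(Cinv1 @ x) / float(np.ones(n) @ Cinv1)
    r = x - mu
    q = float(r @ linalg.cho_solve(cho, r))
    sigma2 = q / n
    return -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)


def lambda_max(phylogeny: Phylogeny) -> float:
    """Largest lambda keeping C(lambda) positive-definite; for an ultrametric
    tree this is depth / (deepest internal-node depth)."""
    C = phylogeny.vcv().to_numpy()
    off = C.copy()
    np.fill_diagonal(off, -np.inf)
    deepest = off.max()
    if deepest <= 0:
        return 1.0
    return float(phylogeny.depth / deepest)


def pagel_lambda(trait: pd.Series, phylogeny: Phylogeny) -> SignalResult:
    """ML estimate of Pagel's lambda with a likelihood-ratio test vs 0."""
    x = _aligned(trait, phylogeny)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 species")
    C = phylogeny.vcv().to_numpy()
    # stay strictly inside the positive-definite region
    lmax = lambda_max(phylogeny) * (1.0 - 1e-8)

    res = optimize.minimize_scalar(
        lambda lam: -_lambda_loglik(x, C, lam),
        bounds=(0.0, lmax),
        method="bounded",
        options={"xatol": 1e-6},
    )
    if not res.success:
        raise RuntimeError(
            f"lambda optimization failed (bounds [0, {lmax:.4g}]): {res.message}"
        )
    lam_hat = float(res.x)
    ll1 = -float(res.fun)
    # the optimizer avoids the exact boundaries; snap if an endpoint is better
    for edge in (0.0, lmax):
        ll_edge = _lambda_loglik(x, C, edge)
        if ll_edge > ll1:
            lam_hat, ll1 = edge, ll_edge
    ll0 = _lambda_loglik(x, C, 0.0)
    lr = max(0.0, 2.0 * (ll1 - ll0))
    p = float(stats.chi2.sf(lr, df=1))
    return SignalResult(
        index_name="PagelLambda",
        statistic=lam_hat,
        p_value=p,
        n_species=n,
        n_permutations=0,
        ultrametric=phylogeny.is_ultrametric,
        extra={"loglik": ll1, "loglik_lambda0": ll0, "lambda_max": lmax},
    )


# ---------------------------------------------------------------------------
# Convenience battery
# ---------------------------------------------------------------------------


def signal_battery(
    trait_means: pd.DataFrame,
    phylogeny: Phylogeny,
    indices: tuple[str, ...] = ("MoranI", "AbouheifCmean", "BlombergK", "BlombergKstar", "PagelLambda"),
    n_perm: int = 999,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Run the selected indices for every trait column; tidy long table."""
    phylo = phylogeny.prune_to(list(trait_means.index)) if set(phylogeny.labels) != set(trait_means.index) else phylogeny
    rows = []
    ss = np.random.SeedSequence(seed)
    for t_i, trait in enumerate(trait_means.columns):
        col = trait_means[trait].dropna()
        sub = phylo.prune_to(list(col.index)) if set(col.index) != set(phylo.labels) else phylo
        for i_i, name in enumerate(indices):
            child = np.random.default_rng(np.random.SeedSequence([0 if seed is None else seed, t_i, i_i]))
            try:
                if name == "MoranI":
                    r = morans_i(col, sub, n_perm=n_perm, seed=child)
                elif name == "AbouheifCmean":
                    r = abouheif_cmean(col, sub, n_perm=n_perm, seed=child)
                elif name == "BlombergK":
                    r = blomberg_k(col, sub, "K", n_perm=n_perm, seed=child)
                elif name == "BlombergKstar":
                    r = blomberg_k(col, sub, "Kstar", n_perm=n_perm, seed=child)
                elif name == "PagelLambda":
                    r = pagel_lambda(col, sub)
                else:
                    raise ValueError(f"unknown index {name!r}")
            except ValueError as exc:
                rows.append({"trait": trait, "index": name, "statistic": np.nan,
                             "p_value": np.nan, "n_species": len(col), "note": str(exc)})
                continue
            rows.append({
                "trait": trait, "index": r.index_name, "statistic": r.statistic,
                "p_value": r.p_value, "n_species": r.n_species, "note": "",
            })
    return pd.DataFrame(rows)
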