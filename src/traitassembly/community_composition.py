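"""Functional composition of communities.

Community-weighted means (CWM = sum of relative abundance x species mean
trait), one-way ANOVA contrasts between habitat classes, non-metric
multidimensional scaling of individuals in trait space (Kruskal stress-1,
reported on a 0-100 scale), and a PERMANOVA-style Monte Carlo test of the
separation of group centroids in the ordination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import smacof

from .core_io import CommunityMatrix, SpeciesTraitMatrix, TraitTable, select_abundant_species

__all__ = [
    "cwm",
    "cwm_table",
    "one_way_anova",
    "group_summary",
    "OrdinationResult",
    "nmds",
    "centroid_test",
    "kruskal_stress",
]


# ---------------------------------------------------------------------------
# Community-weighted means
# ---------------------------------------------------------------------------


def cwm(
    community_row: pd.Series,
    species_trait_means: pd.DataFrame,
    species_subset: list[str] | None = None,
) -> pd.Series:
    """CWM per trait for one site: sum_i W_i * X_i with W renormalized over
    the retained species subset."""
    subset = list(species_subset) if species_subset is not None else list(community_row.index)
    if not subset:
        raise ValueError("empty species subset")
    ab = community_row.reindex(subset).astype(float)
    if (ab <= 0).any() or ab.isna().any():
        bad = list(ab.index[(ab <= 0) | ab.isna()])
        raise ValueError(f"subset species with non-positive abundance: {bad}")
    missing = [s for s in subset if s not in species_trait_means.index]
    if missing:
        raise ValueError(f"no trait means for subset species: {missing}")
    X = species_trait_means.loc[subset]
    if X.isna().any().any():
        bad = [(s, t) for s in subset for t in X.columns if pd.isna(X.loc[s, t])]
        raise ValueError(f"missing trait mean for subset species: {bad[:5]}")
    w = ab / ab.sum()
    return X.mul(w, axis=0).sum(axis=0)


def cwm_table(
    community: CommunityMatrix,
    stm: SpeciesTraitMatrix,
    threshold: float = 0.70,
) -> pd.DataFrame:
    """Site-level CWM table using the abundance-based (70%-rule) subset of
    each community; adds the number of species used per site."""
    rows = {}
    n_used = {}
    for site in community.sites:
        row = community.data.loc[site]
        subset = select_abundant_species(row, threshold)
        subset = [s for s in subset if s in stm.mean.index]
        rows[site] = cwm(row, stm.mean, subset)
        n_used[site] = len(subset)
    out = pd.DataFrame(rows).T
    out.index.name = "site"
    out["n_species"] = pd.Series(n_used)
    return out


# ---------------------------------------------------------------------------
# ANOVA and group summaries
# ---------------------------------------------------------------------------


def one_way_anova(group_a, group_b) -> tuple[float, float]:
    """Classical one-way F between two groups with (1, nA+nB-2) df.

    Degenerate cases: identical group means give F = 0, p = 1; zero pooled
    within-group variance with unequal means gives F = inf, p = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    grand = np.concatenate([a, b]).mean()
    ssb = a.size * (a.mean() - grand) ** 2 + b.size * (b.mean() - grand) ** 2
    ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    df2 = a.size + b.size - 2
    if ssw == 0.0:
        return (0.0, 1.0) if ssb == 0.0 else (math.inf, 0.0)
    F = ssb / (ssw / df2)
    return float(F), float(stats.f.sf(F, 1, df2))


def group_summary(values: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Per-group mean and SD (n-1 denominator)."""
    df = pd.DataFrame({"value": values, "group": groups})
    g = df.groupby("group")["value"]
    return pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1), "n": g.count()})


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------


def kruskal_stress(dissim: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration, as a fraction in [0, 1].

    Disparities are the isotonic (monotone) regression of configuration
    distances on the rank order of the input dissimilarities.
    """
    d_conf = pdist(coords)
    order = np.argsort(dissim, kind="stable")
    fitted = isotonic_regression(d_conf[order]).x
    d_hat = np.empty_like(d_conf)
    d_hat[order] = fitted
    denom = float((d_conf**2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d_conf - d_hat) ** 2).sum() / denom))


def _classical_mds(D: np.ndarray, k: int) -> np.ndarray:
    """Torgerson scaling used as the first NMDS start."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(G)
    idx = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[idx], 0.0, None)
    return vecs[:, idx] * np.sqrt(lam)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # individuals x k, plus id columns if known
    stress: float  # Kruskal stress-1 on the 0-100 scale
    converged: bool
    n_restarts: int
    site_centroids: pd.DataFrame | None = None
    habitat_centroids: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)


def nmds(
    individuals: TraitTable | pd.DataFrame,
    k: int = 2,
    n_restarts: int = 4,
    max_iter: int = 300,
    seed: int | None = 0,
    columns: list[str] | None = None,
) -> OrdinationResult:
    """Non-metric MDS of individuals in trait space.

    Traits are z-score normalized, dissimilarities are Euclidean, and the
    configuration minimizes Kruskal stress-1 by SMACOF with monotone
    (pool-adjacent-violators) regression.  The first restart starts from
    classical metric scaling, the rest from random configurations; the best
    configuration is returned with its stress on the 0-100 scale.
    """
    if isinstance(individuals, TraitTable):
        cols = columns or list(individuals.trait_columns)
        df = individuals.data
    else:
        df = individuals
        cols = columns or [c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])]
    complete = df.dropna(subset=cols)
    X = complete[cols].to_numpy(dtype=float)
    if X.shape[0] < max(3, k + 1):
        raise ValueError(f"need at least {max(3, k + 1)} complete individuals")
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    dissim = pdist(Z)
    Dsq = squareform(dissim)

    rng = np.random.default_rng(seed)
    best = None
    for r in range(n_restarts):
        init = _classical_mds(Dsq, k) if r == 0 else rng.standard_normal((X.shape[0], k))
        coords, _, n_it = smacof(
            Dsq,
            metric=False,
            n_components=k,
            init=init,
            n_init=1,
            max_iter=max_iter,
            eps=1e-9,
            normalized_stress=True,
            return_n_iter=True,
        )
        s1 = kruskal_stress(dissim, coords)
        if best is None or s1 < best[0]:
            best = (s1, coords, n_it)
    stress1, coords, n_it = best
    coords = coords - coords.mean(axis=0)

    out = pd.DataFrame(coords, columns=[f"axis{i+1}" for i in range(k)], index=complete.index)
    site_cent = hab_cent = None
    if "site" in complete.columns:
        out.insert(0, "site", complete["site"])
        site_cent = out.groupby("site")[[f"axis{i+1}" for i in range(k)]].mean()
    if "habitat" in complete.columns:
        out.insert(1 if "site" in out.columns else 0, "habitat", complete["habitat"])
        hab_cent = out.groupby("habitat")[[f"axis{i+1}" for i in range(k)]].mean()
    return OrdinationResult(
        coordinates=out,
        stress=100.0 * stress1,
        converged=n_it < max_iter,
        n_restarts=n_restarts,
        site_centroids=site_cent,
        habitat_centroids=hab_cent,
        extra={"n_individuals": X.shape[0], "k": k},
    )


# ---------------------------------------------------------------------------
# Centroid permutation test
# ---------------------------------------------------------------------------


def _centroid_r2(coords: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    grand = coords.mean(axis=0)
    ss_total = float(((coords - grand) ** 2).sum())
    if ss_total == 0:
        return 0.0
    ss_between = 0.0
    for g in range(n_groups):
        pts = coords[codes == g]
        if pts.size:
            ss_between += pts.shape[0] * float(((pts.mean(axis=0) - grand) ** 2).sum())
    return ss_between / ss_total


def centroid_test(
    coordinates: np.ndarray | pd.DataFrame,
    labels,
    n_perm: int = 999,
    seed: int | None = 0,
) -> tuple[float, float]:
    """Monte Carlo test of group-centroid separation in an ordination.

    The statistic is the PERMANOVA-style r^2 = SS(between centroids) /
    SS(total); the p-value is the add-one-corrected fraction of label
    permutations reaching an r^2 at least as large.
    """
    coords = np.asarray(coordinates, dtype=float)
    codes, uniques = pd.factorize(pd.Series(list(labels)))
    if len(uniques) < 2:
        raise ValueError("need at least 2 groups")
    obs = _centroid_r2(coords, codes, len(uniques))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if _centroid_r2(coords, rng.permutation(codes), len(uniques)) >= obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return float(obs), float(p)
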