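"""Trait-environment association through abundance: the fourth-corner
permutation test and (extended) RLQ three-table ordination.

The three tables are the site x environment matrix R, the site x species
abundance matrix L, and the species x trait matrix Q.  The fourth-corner
statistic r_P for an (environment variable, trait) pair is the
abundance-weighted Pearson correlation over the inflated table that has one
row per individual occurrence, pairing the site's environment value with
the species' trait value.  Significance comes from permuting whole site
rows of L (``model='sites'``), whole species columns (``model='species'``),
or taking the larger p of the two sequential tests (``model='combined'``).

RLQ finds axes of maximal co-inertia between the environment and trait
spaces, linked by the correspondence-analysis row/column weights of L.  The
extended variant appends a block of phylogenetic eigenvectors (principal
coordinates of the square-root patristic distance) to the trait block, and
splits each species' score on the first axis into a trait-based and a
phylogeny-based contribution that sum exactly to the global score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import CommunityMatrix, EnvMatrix, Phylogeny, SpeciesTraitMatrix

__all__ = [
    "FourthCornerResult",
    "RLQResult",
    "fourth_corner",
    "rlq",
    "extended_rlq",
    "phylo_eigenvectors",
]


def _as_df(x, kind):
    if isinstance(x, (CommunityMatrix, EnvMatrix)):
        return x.data
    if isinstance(x, SpeciesTraitMatrix):
        return x.mean
    return x


def _weights(L: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Correspondence-analysis weights from L: P = L/total, site weights r,
    species weights c."""
    total = L.sum()
    if total <= 0:
        raise ValueError("community matrix has no individuals")
    P = L / total
    return P, P.sum(axis=1), P.sum(axis=0)


def _standardize(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted z-scores column-wise; constant columns raise."""
    mean = w @ X
    Xc = X - mean
    var = w @ (Xc**2)
    if np.any(var <= 0):
        bad = np.flatnonzero(var <= 0)
        raise ValueError(f"constant column(s) at index {bad.tolist()} cannot be standardized")
    return Xc / np.sqrt(var)


# ---------------------------------------------------------------------------
# Fourth-corner
# ---------------------------------------------------------------------------


@dataclass
class FourthCornerResult:
    table: pd.DataFrame  # env, trait, r, p_value, model, n_perm

    def matrix(self, column: str = "r") -> pd.DataFrame:
        return self.table.pivot(index="env", columns="trait", values=column)


def _fc_matrix(R: np.ndarray, Q: np.ndarray, P: np.ndarray, r: np.ndarray, c: np.ndarray) -> np.ndarray:
    """All-pairs fourth-corner correlations: Rs' (P - r c') Qs, equal to the
    abundance-weighted Pearson correlation on the inflated table."""
    Rs = _standardize(R, r)
    Qs = _standardize(Q, c)
    return Rs.T @ (P - np.outer(r, c)) @ Qs


def fourth_corner(
    R: EnvMatrix | pd.DataFrame,
    L: CommunityMatrix | pd.DataFrame,
    Q: SpeciesTraitMatrix | pd.DataFrame,
    model: str = "sites",
    n_perm: int = 999,
    seed: int | None = 0,
) -> FourthCornerResult:
    """Fourth-corner test for every (environment variable, trait) pair."""
    Rdf, Ldf, Qdf = _as_df(R, "R"), _as_df(L, "L"), _as_df(Q, "Q")
    Qdf = Qdf.loc[[s for s in Ldf.columns if s in Qdf.index]]
    Ldf = Ldf[Qdf.index]
    Rdf = Rdf.loc[Ldf.index]
    if model not in ("sites", "species", "combined"):
        raise ValueError("model must be 'sites', 'species' or 'combined'")

    Lm = Ldf.to_numpy(dtype=float)
    P, r, c = _weights(Lm)
    Rm, Qm = Rdf.to_numpy(dtype=float), Qdf.to_numpy(dtype=float)

    # drop constant columns up front, reported as undefined
    dropped = []
    keep_R = []
    for j, name in enumerate(Rdf.columns):
        (keep_R if np.ptp(Rm[:, j]) > 0 else dropped).append((j, name, "env"))
    keep_Q = []
    for j, name in enumerate(Qdf.columns):
        (keep_Q if np.ptp(Qm[:, j]) > 0 else dropped).append((j, name, "trait"))
    iR = [j for j, *_ in keep_R]
    iQ = [j for j, *_ in keep_Q]
    obs = _fc_matrix(Rm[:, iR], Qm[:, iQ], P, r, c)

    def null_counts(which: str) -> tuple[np.ndarray, np.ndarray]:
        # per-scheme stream: 'combined' reproduces exactly the p-values of
        # the two sequential tests run with the same seed
        rng = np.random.default_rng(
            np.random.SeedSequence([0 if seed is None else seed, 0 if which == "sites" else 1]))
        lo = np.zeros_like(obs)
        hi = np.zeros_like(obs)
        for _ in range(n_perm):
            if which == "sites":
                perm = rng.permutation(Lm.shape[0])
                Pp, rp, cp = _weights(Lm[perm])
                stat = _fc_matrix(Rm[:, iR], Qm[:, iQ], Pp, rp, cp)
            else:
                perm = rng.permutation(Lm.shape[1])
                Pp, rp, cp = _weights(Lm[:, perm])
                stat = _fc_matrix(Rm[:, iR], Qm[:, iQ][perm], Pp, rp, cp)
        # note: permuting L rows against fixed R == permuting site assignments
            lo += stat <= obs
            hi += stat >= obs
        return lo, hi

    def pvals(which: str) -> np.ndarray:
        lo, hi = null_counts(which)
        return np.minimum(1.0, 2.0 * np.minimum(lo + 1, hi + 1) / (n_perm + 1))

    if model == "combined":
        p = np.maximum(pvals("sites"), pvals("species"))
    else:
        p = pvals(model)

    rows = []
    env_names = [name for _, name, _ in keep_R]
    trait_names = [name for _, name, _ in keep_Q]
    for i, e in enumerate(env_names):
        for j, t in enumerate(trait_names):
            rows.append({"env": e, "trait": t, "r": float(obs[i, j]),
                         "p_value": float(p[i, j]), "model": model, "n_perm": n_perm,
                         "note": ""})
    for _, name, kind in dropped:
        partner = trait_names if kind == "env" else env_names
        for other in partner:
            e, t = (name, other) if kind == "env" else (other, name)
            rows.append({"env": e, "trait": t, "r": np.nan, "p_value": np.nan,
                         "model": model, "n_perm": n_perm,
                         "note": f"constant {kind} column; correlation undefined"})
    return FourthCornerResult(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# RLQ
# ---------------------------------------------------------------------------


@dataclass
class RLQResult:
    eigenvalues: np.ndarray
    percent: np.ndarray  # percent of total co-inertia per axis
    total_coinertia: float
    env_loadings: pd.DataFrame  # env variables x axes (orthonormal)
    trait_loadings: pd.DataFrame  # traits (+ phylo axes) x axes (orthonormal)
    site_scores: pd.DataFrame
    species_scores: pd.DataFrame
    # extended variant only: axis-1 score decomposition per species
    global_scores: pd.Series | None = None
    trait_based: pd.Series | None = None
    phylogeny_based: pd.Series | None = None
    extra: dict = field(default_factory=dict)


def _rlq_core(Rdf: pd.DataFrame, Ldf: pd.DataFrame, Bdf: pd.DataFrame) -> RLQResult:
    Lm = Ldf.to_numpy(dtype=float)
    P, r, c = _weights(Lm)
    Rs = _standardize(Rdf.to_numpy(dtype=float), r)
    Bs = _standardize(Bdf.to_numpy(dtype=float), c)
    M = Rs.T @ (P - np.outer(r, c)) @ Bs
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    tol = max(M.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    k = int(np.sum(s > tol))
    U, s, V = U[:, :k], s[:k], Vt[:k].T
    eig = s**2
    total = float((M**2).sum())
    axes = [f"axis{i+1}" for i in range(k)]
    return RLQResult(
        eigenvalues=eig,
        percent=100.0 * eig / total if total > 0 else np.zeros_like(eig),
        total_coinertia=total,
        env_loadings=pd.DataFrame(U, index=Rdf.columns, columns=axes),
        trait_loadings=pd.DataFrame(V, index=Bdf.columns, columns=axes),
        site_scores=pd.DataFrame(Rs @ U, index=Rdf.index, columns=axes),
        species_scores=pd.DataFrame(Bs @ V, index=Bdf.index, columns=axes),
        extra={"site_weights": r, "species_weights": c},
    )


def rlq(
    R: EnvMatrix | pd.DataFrame,
    L: CommunityMatrix | pd.DataFrame,
    Q: SpeciesTraitMatrix | pd.DataFrame,
) -> RLQResult:
    """RLQ ordination of environment against traits linked by abundance."""
    Rdf, Ldf, Qdf = _as_df(R, "R"), _as_df(L, "L"), _as_df(Q, "Q")
    Qdf = Qdf.loc[[s for s in Ldf.columns if s in Qdf.index]]
    Ldf = Ldf[Qdf.index]
    Rdf = Rdf.loc[Ldf.index]
    return _rlq_core(Rdf, Ldf, Qdf)


# ---------------------------------------------------------------------------
# Extended RLQ with a phylogenetic block
# ---------------------------------------------------------------------------


def phylo_eigenvectors(
    phylogeny: Phylogeny,
    species: list[str],
    min_representation: float = 0.95,
) -> pd.DataFrame:
    """Species x eigenvector encoding of the phylogeny: principal
    coordinates of the square-root patristic distance, axes retained until
    they represent at least ``min_representation`` of the positive
    eigenvalue mass."""
    phylo = phylogeny.prune_to(species) if set(phylogeny.labels) != set(species) else phylogeny
    D = np.sqrt(phylo.patristic_distances().loc[species, species].to_numpy())
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(vals.max(), 0) * 1e-10
    vals, vecs = vals[pos], vecs[:, pos]
    if vals.size == 0:
        return pd.DataFrame(index=species)
    cum = np.cumsum(vals) / vals.sum()
    k = int(np.searchsorted(cum, min_representation) + 1)
    coords = vecs[:, :k] * np.sqrt(vals[:k])
    return pd.DataFrame(coords, index=species, columns=[f"phylo{i+1}" for i in range(k)])


def extended_rlq(
    R: EnvMatrix | pd.DataFrame,
    L: CommunityMatrix | pd.DataFrame,
    Q: SpeciesTraitMatrix | pd.DataFrame,
    phylogeny: Phylogeny,
    min_representation: float = 0.95,
) -> RLQResult:
    """RLQ on the column blocks [traits | phylogenetic eigenvectors], with
    the axis-1 species scores decomposed into trait-based and
    phylogeny-based parts (global = trait.based + phylogeny.based)."""
    Rdf, Ldf, Qdf = _as_df(R, "R"), _as_df(L, "L"), _as_df(Q, "Q")
    Qdf = Qdf.loc[[s for s in Ldf.columns if s in Qdf.index]]
    Ldf = Ldf[Qdf.index]
    Rdf = Rdf.loc[Ldf.index]
    missing = set(Qdf.index) - set(phylogeny.labels)
    if missing:
        raise ValueError(f"tree does not cover species: {sorted(missing)}")
    Pdf = phylo_eigenvectors(phylogeny, list(Qdf.index), min_representation)
    B = pd.concat([Qdf, Pdf], axis=1)
    res = _rlq_core(Rdf, Ldf, B)

    q = Qdf.shape[1]
    Lm = Ldf.to_numpy(dtype=float)
    _, _, c = _weights(Lm)
    Bs = _standardize(B.to_numpy(dtype=float), c)
    v1 = res.trait_loadings.iloc[:, 0].to_numpy()
    trait_part = Bs[:, :q] @ v1[:q]
    phylo_part = Bs[:, q:] @ v1[q:]
    res.global_scores = pd.Series(trait_part + phylo_part, index=B.index, name="global.scores")
    res.trait_based = pd.Series(trait_part, index=B.index, name="trait.based")
    res.phylogeny_based = pd.Series(phylo_part, index=B.index, name="phylogeny.based")
    res.extra["n_phylo_axes"] = Pdf.shape[1]
    return res
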