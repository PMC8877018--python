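"""Synthetic phylogenies, traits, environments and filtered communities.

The generator produces datasets with the statistical structure the analysis
assumes, with known ground truth, so every stage is testable without field
data:

* a pure-birth (Yule) ultrametric phylogeny conditioned on its tip count;
* species mean traits evolved under Brownian motion with a tunable Pagel
  lambda (lambda = 1 is plain BM, lambda = 0 makes tips independent);
* individuals drawn around species means with Gaussian intraspecific noise;
* site communities assembled under a configurable Gaussian external filter
  (membership probability decays with the distance between a species' mean
  and the site's environmental optimum) and a minimum-spacing internal
  filter (of two admitted species closer than the spacing on the filter
  trait, the lower-probability one is dropped).

Everything is deterministic given ``seed``; sub-streams are derived with
:class:`numpy.random.SeedSequence` so the phylogeny, trait and assembly
stages draw from independent streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    TRAITS,
    CommunityMatrix,
    EnvMatrix,
    Phylogeny,
    TraitTable,
    write_community_matrix,
    write_env_matrix,
    write_trait_table,
)

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "AssemblyError",
    "simulate_phylogeny",
    "simulate_traits",
    "assemble_communities",
    "generate_dataset",
    "write_dataset",
]


class AssemblyError(RuntimeError):
    """No species passes the external filter for some site."""


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults emulate a desk-scale version of an
    eight-site, two-habitat tropical dry forest survey.

    ``n_sites`` defaults to 8 (four secondary-forest and four old-growth
    sites); ``n_species`` and ``n_individuals_per_site`` are scaled-down
    analogues of the regional pool.  ``sigma2`` is the Brownian rate (trait
    variance per Myr); ``lambda_signal`` interpolates the off-diagonal
    phylogenetic covariance.  ``external_filter_sd`` is the width of the
    Gaussian trait-optimum filter (smaller = stronger; ``inf`` disables);
    ``internal_filter`` is the minimum spacing between admitted species
    means on the filter trait (0 disables).
    """

    n_species: int = 30
    n_sites: int = 8
    n_individuals_per_site: int = 40
    birth_rate: float = 1.0
    sigma2: float = 1.0
    lambda_signal: float = 1.0
    root_value: float = 0.0
    intraspecific_sd: float = 0.5
    env_gradient: tuple[float, ...] | None = None  # per-site optima
    external_filter_sd: float = math.inf
    internal_filter: float = 0.0
    n_traits: int = len(TRAITS)
    # generic names: simulated traits live on the unconstrained Brownian
    # scale (think log-transformed), so concentration-style nonnegativity
    # does not apply to them
    trait_names: tuple[str, ...] = tuple(f"trait{i + 1}" for i in range(len(TRAITS)))
    trait_correlation: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2 or self.n_sites < 2 or self.n_individuals_per_site < 2:
            raise ValueError("all counts must be >= 2")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        if not 0.0 <= self.lambda_signal <= 1.0:
            raise ValueError("lambda_signal must be in [0, 1]")
        if not self.external_filter_sd > 0:
            raise ValueError("external_filter_sd must be > 0 (use inf to disable)")
        self.trait_names = tuple(self.trait_names)[: self.n_traits]

    def site_optima(self) -> np.ndarray:
        if self.env_gradient is not None:
            opt = np.asarray(self.env_gradient, dtype=float)
            if opt.size != self.n_sites:
                raise ValueError("env_gradient must have one optimum per site")
            return opt
        # default gradient spans +-1.5 regional trait SD around the root value
        half = 1.5 * math.sqrt(max(self.sigma2, 1e-12))
        return self.root_value + np.linspace(-half, half, self.n_sites)


@dataclass
class SyntheticDataset:
    phylogeny: Phylogeny
    true_species_means: pd.DataFrame  # species x trait
    traits: TraitTable
    community: CommunityMatrix
    env: EnvMatrix
    config: SimulationConfig


# ---------------------------------------------------------------------------
# Phylogeny simulation
# ---------------------------------------------------------------------------


def simulate_phylogeny(
    n_species: int, birth_rate: float = 1.0, seed: int | np.random.Generator = 0
) -> Phylogeny:
    """Pure-birth ultrametric tree conditioned on ``n_species`` extant tips.

    Lineages split at exponential waiting times with total rate
    ``k * birth_rate`` for ``k`` extant lineages; after the last split the
    tree is grown for one further exponential hold so terminal branches have
    positive length.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # each active lineage: (birth_time, node_id); tree stored as child lists
    children: dict[int, list[int]] = {}
    birth: dict[int, float] = {0: 0.0}
    active = [0]
    next_id = 1
    t = 0.0
    while len(active) < n_species:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        i = int(rng.integers(k))
        parent = active.pop(i)
        kids = [next_id, next_id + 1]
        next_id += 2
        for c in kids:
            birth[c] = t
        children[parent] = kids
        active.extend(kids)
    t_end = t + rng.exponential(1.0 / (n_species * birth_rate))

    width = len(str(n_species))
    tip_iter = iter(range(n_species))

    # an internal node's edge runs from its parent's split time to its own
    def _newick(node: int, parent_split: float) -> str:
        if node in children:
            split_t = birth[children[node][0]]
            a, b = children[node]
            sub = f"({_newick(a, split_t)},{_newick(b, split_t)})"
            return f"{sub}:{split_t - parent_split:.10f}"
        label = f"sp{next(tip_iter) + 1:0{width}d}"
        return f"{label}:{t_end - parent_split:.10f}"

    root_split = birth[children[0][0]]
    a, b = children[0]
    newick = f"({_newick(a, root_split)},{_newick(b, root_split)}):0.0;"
    return Phylogeny.from_newick(newick)


# ---------------------------------------------------------------------------
# Trait evolution
# ---------------------------------------------------------------------------


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Pagel's lambda transform: rescale off-diagonal entries of C by lam."""
    Cl = lam * C
    np.fill_diagonal(Cl, np.diag(C))
    return Cl


def simulate_traits(
    phylogeny: Phylogeny,
    sigma2: float = 1.0,
    lambda_signal: float = 1.0,
    root_value: float = 0.0,
    seed: int | np.random.Generator = 0,
    n_traits: int = 1,
    trait_names: tuple[str, ...] | None = None,
    trait_correlation: np.ndarray | None = None,
) -> pd.DataFrame:
    """Species mean traits from the multivariate normal N(root, sigma2*C(lambda)).

    Traits are independent of one another unless ``trait_correlation`` (a
    positive-definite correlation matrix across traits) is supplied.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = phylogeny.labels
    names = list(trait_names) if trait_names is not None else [f"trait{i+1}" for i in range(n_traits)]
    n = len(labels)
    if sigma2 == 0:
        return pd.DataFrame(np.full((n, n_traits), root_value), index=labels, columns=names)
    C = lambda_transform(phylogeny.vcv().to_numpy(), lambda_signal)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(n))
    Z = rng.standard_normal((n, n_traits))
    if trait_correlation is not None:
        R = np.asarray(trait_correlation, dtype=float)
        if R.shape != (n_traits, n_traits):
            raise ValueError("trait_correlation must be n_traits x n_traits")
        Z = Z @ np.linalg.cholesky(R).T
    X = root_value + math.sqrt(sigma2) * (L @ Z)
    return pd.DataFrame(X, index=labels, columns=names)


# ---------------------------------------------------------------------------
# Community assembly
# ---------------------------------------------------------------------------


def _admit_species(
    means: np.ndarray, logp: np.ndarray, spacing: float, labels: list[str]
) -> np.ndarray:
    """Greedy minimum-spacing internal filter: walk species in decreasing
    admission probability and drop any candidate whose filter-trait mean is
    within ``spacing`` of an already admitted species."""
    order = sorted(range(len(labels)), key=lambda i: (-logp[i], labels[i]))
    admitted: list[int] = []
    for i in order:
        if not np.isfinite(logp[i]):
            continue
        if all(abs(means[i] - means[j]) >= spacing for j in admitted):
            admitted.append(i)
    return np.array(sorted(admitted), dtype=int)


def assemble_communities(
    species_means: pd.DataFrame,
    env_gradient: np.ndarray,
    external_filter_sd: float = math.inf,
    internal_filter: float = 0.0,
    n_individuals_per_site: int = 40,
    intraspecific_sd: float = 0.5,
    seed: int | np.random.Generator = 0,
    filter_trait: str | None = None,
    site_names: list[str] | None = None,
    habitats: list[str] | None = None,
) -> tuple[CommunityMatrix, TraitTable]:
    """Sample site communities and their individuals.

    Species enter a site with probability proportional to
    ``exp(-(mean - optimum)^2 / (2 * external_filter_sd^2))`` evaluated on
    the filter trait (the first trait column by default).  With
    ``internal_filter > 0`` the greedy spacing rule thins the admitted set.
    Individuals are drawn as Normal(species mean, intraspecific_sd) for
    every trait column.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    species = list(species_means.index)
    traits = list(species_means.columns)
    ft = filter_trait or traits[0]
    fmeans = species_means[ft].to_numpy(dtype=float)
    optima = np.asarray(env_gradient, dtype=float)
    n_sites = optima.size
    site_names = site_names or [f"site{i+1}" for i in range(n_sites)]
    if habitats is None:
        habitats = ["SEF" if i < n_sites // 2 else "OGF" for i in range(n_sites)]

    counts = np.zeros((n_sites, len(species)), dtype=int)
    rows: list[dict] = []
    for s in range(n_sites):
        if math.isinf(external_filter_sd):
            logp = np.zeros(len(species))
        else:
            with np.errstate(divide="ignore"):
                logp = -((fmeans - optima[s]) ** 2) / (2.0 * external_filter_sd**2)
        if internal_filter > 0:
            keep = _admit_species(fmeans, logp, internal_filter, species)
        else:
            keep = np.flatnonzero(np.isfinite(logp))
        if keep.size == 0 or not np.isfinite(logp[keep]).any():
            raise AssemblyError(
                f"external filter admits no species at site {site_names[s]!r} "
                f"(optimum {optima[s]:.3g}, sd {external_filter_sd:.3g})"
            )
        lp = logp[keep] - logp[keep].max()
        p = np.exp(lp)
        p /= p.sum()
        draw = rng.multinomial(n_individuals_per_site, p)
        counts[s, keep] = draw
        for sp_i, k in zip(keep, draw):
            if k == 0:
                continue
            noise = rng.normal(0.0, intraspecific_sd, size=(k, len(traits)))
            vals = species_means.iloc[sp_i].to_numpy(dtype=float)[None, :] + noise
            for ind in range(k):
                rec = {
                    "site": site_names[s],
                    "habitat": habitats[s],
                    "species": species[sp_i],
                    "individual": f"{site_names[s]}_{species[sp_i]}_{ind+1}",
                }
                rec.update({t: vals[ind, j] for j, t in enumerate(traits)})
                rows.append(rec)

    community = CommunityMatrix(pd.DataFrame(counts, index=site_names, columns=species))
    cols = ["site", "habitat", "species", "individual", *traits]
    table = TraitTable(pd.DataFrame(rows, columns=cols))
    return community, table


# ---------------------------------------------------------------------------
# Full-dataset generation
# ---------------------------------------------------------------------------


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a full synthetic dataset (tree, means, individuals, L, R)."""
    ss = np.random.SeedSequence(config.seed)
    rng_tree, rng_traits, rng_comm, rng_env = (np.random.default_rng(s) for s in ss.spawn(4))

    phylo = simulate_phylogeny(config.n_species, config.birth_rate, rng_tree)
    means = simulate_traits(
        phylo,
        sigma2=config.sigma2,
        lambda_signal=config.lambda_signal,
        root_value=config.root_value,
        seed=rng_traits,
        n_traits=config.n_traits,
        trait_names=config.trait_names,
        trait_correlation=config.trait_correlation,
    )
    optima = config.site_optima()
    community, traits = assemble_communities(
        means,
        optima,
        external_filter_sd=config.external_filter_sd,
        internal_filter=config.internal_filter,
        n_individuals_per_site=config.n_individuals_per_site,
        intraspecific_sd=config.intraspecific_sd,
        seed=rng_comm,
    )
    # environment: the filter optimum itself plus correlated and pure-noise
    # covariates, mimicking a multi-variable site-level logger/soil table
    n_sites = config.n_sites
    env = pd.DataFrame(
        {
            "env_filter": optima,
            "env_correlated": optima + rng_env.normal(0, 0.25 * (np.ptp(optima) + 1e-9), n_sites),
            "env_noise": rng_env.normal(0.0, 1.0, n_sites),
        },
        index=community.sites,
    )
    return SyntheticDataset(
        phylogeny=phylo,
        true_species_means=means,
        traits=traits,
        community=community,
        env=EnvMatrix(env),
        config=config,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Serialize a dataset to tsv/newick files; returns the paths written."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "traits": out / "traits.tsv",
        "community": out / "community.tsv",
        "env": out / "env.tsv",
        "tree": out / "tree.nwk",
        "truth": out / "truth.tsv",
    }
    write_trait_table(ds.traits, paths["traits"])
    write_community_matrix(ds.community, paths["community"])
    write_env_matrix(ds.env, paths["env"])
    paths["tree"].write_text(ds.phylogeny.to_newick() + "\n")
    ds.true_species_means.to_csv(paths["truth"], sep="\t")
    return paths
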