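"""Domain types, readers/writers, validation, and the abundance-based
species-selection rule shared by all analysis stages.

The data model mirrors a three-table community-ecology study design:

* an individual-level trait table (one row per sampled individual, with
  site, habitat, species and individual labels plus leaf traits),
* a site x species abundance matrix (``L``),
* a site x environment matrix (``R``),
* a species x mean-trait matrix with standard errors (``Q``),
* a rooted, (near-)ultrametric phylogeny over the species pool.

Tabular files are UTF-8 delimited text; the delimiter is chosen from the
extension (``.csv`` -> comma, anything else -> tab).  Empty cells and the
literal string ``NA`` are treated as missing.  Sample statistics use the
n-1 denominator throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "TRAITS",
    "ID_COLS",
    "HABITATS",
    "ValidationError",
    "TraitTable",
    "CommunityMatrix",
    "EnvMatrix",
    "SpeciesTraitMatrix",
    "Phylogeny",
    "read_trait_table",
    "write_trait_table",
    "read_community_matrix",
    "write_community_matrix",
    "read_env_matrix",
    "write_env_matrix",
    "read_newick",
    "select_abundant_species",
    "species_means",
]

#: Canonical trait column names, in the order they are reported.
TRAITS = ("phenols", "tannins", "flavonoids", "chlorophyll", "sla", "ld", "lfm")

#: Identifier columns of the individual-level trait table.
ID_COLS = ("site", "habitat", "species", "individual")

#: Habitat classes: secondary forest and old-growth forest.
HABITATS = ("SEF", "OGF")

#: Traits that must be non-negative where present.
_NONNEGATIVE = ("phenols", "tannins", "flavonoids")
#: Traits that must be strictly positive where present.
_POSITIVE = ("sla", "ld")

#: Relative tolerance for the ultrametricity check on root-to-tip depths.
ULTRAMETRIC_RTOL = 1e-6


class ValidationError(ValueError):
    """An input table or tree violates a structural invariant."""


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


# ---------------------------------------------------------------------------
# TraitTable
# ---------------------------------------------------------------------------


@dataclass
class TraitTable:
    """Individual-level trait records.

    ``data`` has the identifier columns :data:`ID_COLS` plus one column per
    measured trait; trait cells may be missing (NaN).  Each trait is analyzed
    downstream on its own complete subset of individuals; no imputation is
    performed.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in ID_COLS if c not in df.columns]
        if missing:
            raise ValidationError(f"trait table missing required columns: {missing}")
        self.trait_columns = tuple(c for c in df.columns if c not in ID_COLS)
        dup = df.duplicated(subset=["site", "species", "individual"])
        if dup.any():
            row = int(np.flatnonzero(dup.to_numpy())[0])
            raise ValidationError(
                f"duplicate (site, species, individual) key at row {row}: "
                f"{tuple(df.iloc[row][['site', 'species', 'individual']])}"
            )
        for col in self.trait_columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad_lo = 0.0 if col in _NONNEGATIVE else None
            if col in _NONNEGATIVE:
                bad = vals < 0
            elif col in _POSITIVE:
                bad = vals <= 0
            else:
                continue
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValidationError(
                    f"invalid value {vals.iloc[row]!r} in column {col!r} at row {row}"
                    + ("" if bad_lo is None else " (must be > 0)" if col in _POSITIVE else " (must be >= 0)")
                )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def species(self) -> list[str]:
        return sorted(self.data["species"].unique())

    @property
    def sites(self) -> list[str]:
        return sorted(self.data["site"].unique())

    def subset_species(self, species: list[str]) -> "TraitTable":
        return TraitTable(self.data[self.data["species"].isin(set(species))].reset_index(drop=True))

    def subset_sites(self, sites: list[str]) -> "TraitTable":
        return TraitTable(self.data[self.data["site"].isin(set(sites))].reset_index(drop=True))


def read_trait_table(path: str | Path) -> TraitTable:
    """Read an individual-level trait table from delimited text."""
    df = pd.read_csv(path, sep=_sep_for(path), na_values=["NA", ""])
    for c in ID_COLS:
        if c in df.columns:
            df[c] = df[c].astype(str)
    for c in df.columns:
        if c not in ID_COLS:
            df[c] = pd.to_numeric(df[c], errors="raise")
    return TraitTable(df)


def write_trait_table(table: TraitTable, path: str | Path) -> None:
    table.data.to_csv(path, sep=_sep_for(path), index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# CommunityMatrix / EnvMatrix
# ---------------------------------------------------------------------------


@dataclass
class CommunityMatrix:
    """Site x species abundance matrix (matrix ``L``); non-negative counts."""

    data: pd.DataFrame  # index: sites, columns: species

    def __post_init__(self) -> None:
        arr = self.data.to_numpy()
        if (arr < 0).any():
            raise ValidationError("community matrix has negative abundances")
        self.data = self.data.astype(int)

    @property
    def sites(self) -> list[str]:
        return list(self.data.index)

    @property
    def species(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class EnvMatrix:
    """Site x environmental-variable matrix (matrix ``R``)."""

    data: pd.DataFrame  # index: sites, columns: variables

    @property
    def sites(self) -> list[str]:
        return list(self.data.index)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)


def read_community_matrix(path: str | Path) -> CommunityMatrix:
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    return CommunityMatrix(df)


def write_community_matrix(cm: CommunityMatrix, path: str | Path) -> None:
    cm.data.to_csv(path, sep=_sep_for(path))


def read_env_matrix(path: str | Path) -> EnvMatrix:
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, na_values=["NA", ""])
    df.index = df.index.astype(str)
    return EnvMatrix(df)


def write_env_matrix(em: EnvMatrix, path: str | Path) -> None:
    em.data.to_csv(path, sep=_sep_for(path), na_rep="NA")


# ---------------------------------------------------------------------------
# SpeciesTraitMatrix
# ---------------------------------------------------------------------------


@dataclass
class SpeciesTraitMatrix:
    """Species x trait means with standard errors of the mean (matrix ``Q``).

    ``mean``/``se``/``n`` are aligned DataFrames (species index, trait
    columns).  SE = sample SD / sqrt(n) with the n-1 denominator; species
    represented by a single individual get SE = 0 and are flagged in
    ``single_individual``.
    """

    mean: pd.DataFrame
    se: pd.DataFrame
    n: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.se.to_numpy() < 0).any():
            raise ValidationError("negative standard error in species trait matrix")

    @property
    def species(self) -> list[str]:
        return list(self.mean.index)

    @property
    def traits(self) -> list[str]:
        return list(self.mean.columns)

    @property
    def single_individual(self) -> pd.DataFrame:
        return self.n == 1


def species_means(traits: TraitTable, columns: tuple[str, ...] | None = None) -> SpeciesTraitMatrix:
    """Aggregate an individual-level table to species means, SEs and counts.

    Each trait uses its own complete subset of individuals.  A species whose
    individuals all have the trait missing gets NaN mean, NaN SE and n = 0.
    """
    cols = list(columns) if columns is not None else list(traits.trait_columns)
    g = traits.data.groupby("species")[cols]
    mean = g.mean()
    n = g.count()
    sd = g.std(ddof=1)
    se = sd / np.sqrt(n)
    se = se.where(n >= 2, 0.0)
    se = se.where(n >= 1)  # keep NaN where no observations at all
    return SpeciesTraitMatrix(mean=mean, se=se, n=n)


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------


class Phylogeny:
    """A rooted tree over the species pool, branch lengths in Myr.

    Wraps a :class:`dendropy.Tree` and exposes the matrices the comparative
    methods need: patristic distances and the Brownian-motion covariance
    matrix ``C`` (shared root-to-MRCA path lengths).  Trees whose
    root-to-tip depths differ by more than a relative tolerance are accepted
    with ``is_ultrametric = False`` and a warning; indices that assume
    ultrametricity carry that flag through to their results.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self.labels: list[str] = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("duplicate tip labels in tree")
        self._depths = self._tip_depths()
        depths = np.array([self._depths[t] for t in self.labels])
        self.depth = float(depths.max())
        scale = self.depth if self.depth > 0 else 1.0
        self.is_ultrametric = bool((depths.max() - depths.min()) <= ULTRAMETRIC_RTOL * scale)
        if not self.is_ultrametric:
            warnings.warn(
                "tree is not ultrametric within tolerance; "
                "signal indices will flag this", stacklevel=2,
            )
        self._vcv: pd.DataFrame | None = None
        self._patristic: pd.DataFrame | None = None

    # -- construction --------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise ValidationError(f"unparseable Newick: {exc}") from exc
        return cls(tree)

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", unquoted_underscores=True).strip()

    # -- internals -----------------------------------------------------

    def _tip_depths(self) -> dict[str, float]:
        depths: dict[str, float] = {}
        for node in self.tree.preorder_node_iter():
            parent = node.parent_node
            base = 0.0 if parent is None else parent._root_dist
            node._root_dist = base + (node.edge.length or 0.0)
            if node.is_leaf():
                depths[node.taxon.label] = node._root_dist
        return depths

    # -- matrices ------------------------------------------------------

    def vcv(self) -> pd.DataFrame:
        """Brownian covariance matrix C: C_ij = root-to-MRCA(i,j) path length."""
        if self._vcv is None:
            idx = {t: i for i, t in enumerate(self.labels)}
            n = len(self.labels)
            C = np.zeros((n, n))
            for node in self.tree.postorder_node_iter():
                if node.is_leaf():
                    node._leafset = [idx[node.taxon.label]]
                    C[node._leafset[0], node._leafset[0]] = node._root_dist
                else:
                    kids = [c._leafset for c in node.child_nodes()]
                    for a in range(len(kids)):
                        for b in range(a + 1, len(kids)):
                            for i in kids[a]:
                                for j in kids[b]:
                                    C[i, j] = C[j, i] = node._root_dist
                    node._leafset = [i for k in kids for i in k]
            self._vcv = pd.DataFrame(C, index=self.labels, columns=self.labels)
        return self._vcv.copy()

    def patristic_distances(self) -> pd.DataFrame:
        """Tip-to-tip path-length (patristic) distance matrix."""
        if self._patristic is None:
            C = self.vcv().to_numpy()
            d = np.diag(C)
            # d(i,j) = depth_i + depth_j - 2 * depth of MRCA
            D = d[:, None] + d[None, :] - 2.0 * C
            np.fill_diagonal(D, 0.0)
            self._patristic = pd.DataFrame(D, index=self.labels, columns=self.labels)
        return self._patristic.copy()

    def patristic_distance(self, a: str, b: str) -> float:
        return float(self.patristic_distances().loc[a, b])

    def prune_to(self, species: list[str]) -> "Phylogeny":
        keep = set(species)
        missing = keep - set(self.labels)
        if missing:
            raise ValidationError(f"species missing from tree: {sorted(missing)}")
        tree = self.tree.clone(depth=1)
        tree.retain_taxa_with_labels(sorted(keep))
        return Phylogeny(tree)

    # -- node bookkeeping for Abouheif proximities ---------------------

    def abouheif_proximity(self) -> pd.DataFrame:
        """Abouheif proximity: 1 / product of direct-descendant counts over
        the internal nodes on the path between two tips (MRCA included)."""
        idx = {t: i for i, t in enumerate(self.labels)}
        n = len(self.labels)
        A = np.zeros((n, n))
        # path_prod[tip] = product of dd over internal nodes strictly between
        # tip and the current ancestor (exclusive of the ancestor itself)
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                node._paths = {idx[node.taxon.label]: 1.0}
            else:
                dd = len(node.child_nodes())
                kids = [c._paths for c in node.child_nodes()]
                for a in range(len(kids)):
                    for b in range(a + 1, len(kids)):
                        for i, pi in kids[a].items():
                            for j, pj in kids[b].items():
                                # dd of the MRCA enters once; inner nodes already counted
                                A[i, j] = A[j, i] = 1.0 / (pi * pj * dd)
                node._paths = {}
                for c in node.child_nodes():
                    for i, p in c._paths.items():
                        node._paths[i] = p * dd
        return pd.DataFrame(A, index=self.labels, columns=self.labels)


def read_newick(path: str | Path) -> Phylogeny:
    """Read a Newick tree file with branch lengths."""
    return Phylogeny.from_newick(Path(path).read_text())


# ---------------------------------------------------------------------------
# Abundance-based species selection
# ---------------------------------------------------------------------------


def select_abundant_species(
    community_row: pd.Series, threshold: float = 0.70
) -> list[str]:
    """Most abundant species jointly representing at least ``threshold`` of
    the individuals in one site.

    Species are ranked by descending abundance (ties broken by species
    label); the smallest prefix whose cumulative relative abundance reaches
    the threshold (inclusive, per "at least 70%") is returned.  The output
    is independent of the input species order.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    total = community_row.sum()
    if total <= 0:
        raise ValidationError("all-zero abundance row")
    order = sorted(community_row.items(), key=lambda kv: (-kv[1], kv[0]))
    picked: list[str] = []
    cum = 0.0
    for sp, count in order:
        if count <= 0:
            break
        picked.append(sp)
        cum += count
        if cum / total >= threshold:
            break
    return picked
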