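"""T-statistics: trait-variance ratios across organizational levels, with
permutation null models and standardized effect sizes.

The framework decomposes the variance of an individual-level trait into
components at nested levels — individuals within populations (sigma2_IP),
individuals within communities (sigma2_IC), individuals in the regional
pool (sigma2_IR), population means within communities (sigma2_PC) and
within the region (sigma2_PR) — and forms three diagnostic ratios:

* ``T_IP/IC = sigma2_IP / sigma2_IC`` — interspecific niche packing; low
  values mean local intraspecific variation is narrow relative to the
  community spread (internal filtering / reduced overlap).
* ``T_IC/IR = sigma2_IC / sigma2_IR`` — external filtering on individuals;
  values near 0 mean the community admits a narrow slice of the regional
  trait range.
* ``T_PC/PR = sigma2_PC / sigma2_PR`` — the same contrast at the level of
  population means.

A "population" is the set of individuals of one species in one site.  Each
ratio has its own permutation null model ("local", "regional.ind",
"regional.pop"); observed values are located within the null by a
standardized effect size SES = (T_obs - T_null)/T_SDnull and a two-sided
permutation p-value.  All sample variances use the n-1 denominator;
sigma2_IP pools per-population sample variances with an unweighted mean
over populations with >= 2 individuals (a size-weighted variant, which
satisfies the exact law-of-total-variance identity against sigma2_IC, is
available behind ``weighted=True``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import TraitTable

__all__ = [
    "VarianceComponents",
    "TStatResult",
    "variance_components",
    "t_statistics",
    "null_local",
    "null_regional_ind",
    "null_regional_pop",
    "ses_and_p",
    "tstats_for_dataset",
    "habitat_contrast",
]

NULL_MODELS = {"T_IP_IC": "local", "T_IC_IR": "regional.ind", "T_PC_PR": "regional.pop"}


@dataclass
class VarianceComponents:
    sigma2_IP: float
    sigma2_IC: float
    sigma2_IR: float
    sigma2_PC: float
    sigma2_PR: float
    # size-weighted within/between parts of sigma2_IC (law of total variance)
    sigma2_IP_weighted: float = math.nan
    sigma2_PC_weighted: float = math.nan
    notes: list = field(default_factory=list)


@dataclass
class TStatResult:
    trait: str
    community: str
    statistic: str  # T_IP_IC | T_IC_IR | T_PC_PR
    t_obs: float
    null_mean: float
    null_sd: float
    ses: float
    p_value: float
    null_model: str
    n_perm: int
    null_distribution: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Variance components
# ---------------------------------------------------------------------------


def _pop_stats(values: np.ndarray, pops: np.ndarray):
    """Per-population n, mean, sample variance (NaN where n < 2)."""
    codes, uniq = pd.factorize(pd.Series(pops))
    n = np.bincount(codes, minlength=len(uniq)).astype(float)
    s = np.bincount(codes, weights=values, minlength=len(uniq))
    ss = np.bincount(codes, weights=values**2, minlength=len(uniq))
    mean = s / n
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (ss - n * mean**2) / (n - 1)
    var[n < 2] = np.nan
    var = np.clip(var, 0.0, None)
    return n, mean, var


def variance_components(
    traits: TraitTable,
    trait: str,
    community: str | list[str],
    region: list[str] | None = None,
) -> VarianceComponents:
    """Variance components for one trait in one community against the
    regional pool (all sites by default)."""
    df = traits.data.dropna(subset=[trait])
    sites = [community] if isinstance(community, str) else list(community)
    reg = df if region is None else df[df["site"].isin(set(region))]
    com = reg[reg["site"].isin(set(sites))]
    if len(com) < 2:
        raise ValueError(f"need >= 2 individuals in community {community!r}")
    notes: list[str] = []

    v_com = com[trait].to_numpy(dtype=float)
    pops_com = (com["site"] + "//" + com["species"]).to_numpy()
    n_c, mean_c, var_c = _pop_stats(v_com, pops_com)

    ok = ~np.isnan(var_c)
    if ok.any():
        sigma2_IP = float(var_c[ok].mean())
    else:
        sigma2_IP = math.nan
        notes.append("no population with >= 2 individuals; sigma2_IP undefined")
    sigma2_IC = float(np.var(v_com, ddof=1))
    if len(mean_c) >= 2:
        sigma2_PC = float(np.var(mean_c, ddof=1))
    else:
        sigma2_PC = math.nan
        notes.append("single population in community; sigma2_PC undefined")

    v_reg = reg[trait].to_numpy(dtype=float)
    pops_reg = (reg["site"] + "//" + reg["species"]).to_numpy()
    _, mean_r, _ = _pop_stats(v_reg, pops_reg)
    sigma2_IR = float(np.var(v_reg, ddof=1)) if len(v_reg) >= 2 else math.nan
    sigma2_PR = float(np.var(mean_r, ddof=1)) if len(mean_r) >= 2 else math.nan

    # size-weighted decomposition: within + between == sigma2_IC exactly
    N = v_com.size
    w_ip = float(np.nansum((n_c - 1) * np.nan_to_num(var_c)) / (N - 1))
    w_pc = float((n_c * (mean_c - v_com.mean()) ** 2).sum() / (N - 1))

    return VarianceComponents(
        sigma2_IP=sigma2_IP,
        sigma2_IC=sigma2_IC,
        sigma2_IR=sigma2_IR,
        sigma2_PC=sigma2_PC,
        sigma2_PR=sigma2_PR,
        sigma2_IP_weighted=w_ip,
        sigma2_PC_weighted=w_pc,
        notes=notes,
    )


def t_statistics(components: VarianceComponents, weighted: bool = False) -> dict[str, float]:
    """The three ratios; NaN (with a note) where a denominator is zero or a
    component is undefined."""
    ip = components.sigma2_IP_weighted if weighted else components.sigma2_IP
    pc = components.sigma2_PC_weighted if weighted else components.sigma2_PC

    def ratio(num: float, den: float) -> float:
        if math.isnan(num) or math.isnan(den) or den == 0:
            return math.nan
        return num / den

    return {
        "T_IP_IC": ratio(ip, components.sigma2_IC),
        "T_IC_IR": ratio(components.sigma2_IC, components.sigma2_IR),
        "T_PC_PR": ratio(pc, components.sigma2_PR),
    }


# ---------------------------------------------------------------------------
# Null models (vectorized over permutations)
# ---------------------------------------------------------------------------


def _perm_matrix(values: np.ndarray, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """n_perm independent permutations of ``values`` as rows."""
    tiled = np.tile(values, (n_perm, 1))
    return rng.permuted(tiled, axis=1)


def _t_ip_ic_rows(V: np.ndarray, pops: np.ndarray) -> np.ndarray:
    """T_IP/IC per row of a (n_perm, N) value matrix with fixed population
    structure (unweighted sigma2_IP pooling)."""
    codes, uniq = pd.factorize(pd.Series(pops))
    P = len(uniq)
    Z = np.zeros((V.shape[1], P))
    Z[np.arange(V.shape[1]), codes] = 1.0
    n = Z.sum(axis=0)
    S = V @ Z
    SS = (V**2) @ Z
    mean = S / n
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (SS - n * mean**2) / (n - 1)
    keep = n >= 2
    sigma2_ip = np.clip(var[:, keep], 0.0, None).mean(axis=1) if keep.any() else np.full(V.shape[0], np.nan)
    sigma2_ic = V.var(axis=1, ddof=1)
    return sigma2_ip / sigma2_ic


def null_local(
    traits: TraitTable,
    trait: str,
    community: str,
    n_perm: int = 999,
    seed: int | None = 0,
) -> np.ndarray:
    """Null distribution of T_IP/IC: trait values permuted among individuals
    within the community, species composition (population sizes) fixed."""
    df = traits.data.dropna(subset=[trait])
    com = df[df["site"] == community]
    if len(com) < 2:
        raise ValueError(f"need >= 2 individuals in community {community!r}")
    values = com[trait].to_numpy(dtype=float)
    pops = (com["site"] + "//" + com["species"]).to_numpy()
    rng = np.random.default_rng(seed)
    V = _perm_matrix(values, n_perm, rng)
    return _t_ip_ic_rows(V, pops)


def null_regional_ind(
    traits: TraitTable,
    trait: str,
    n_perm: int = 999,
    seed: int | None = 0,
    communities: list[str] | None = None,
    strict: bool = True,
) -> dict[str, np.ndarray]:
    """Null distributions of T_IC/IR per community: trait values permuted
    across all individuals in the region, community sizes fixed.

    With ``strict=False`` a degenerate community (< 2 individuals) yields
    an all-NaN null instead of raising.
    """
    df = traits.data.dropna(subset=[trait])
    if communities is None:
        communities = sorted(df["site"].unique())
    values = df[trait].to_numpy(dtype=float)
    sigma2_ir = float(np.var(values, ddof=1))
    site = df["site"].to_numpy()
    rng = np.random.default_rng(seed)
    V = _perm_matrix(values, n_perm, rng)
    out = {}
    for c in communities:
        mask = site == c
        if mask.sum() < 2:
            if strict:
                raise ValueError(f"need >= 2 individuals in community {c!r}")
            out[c] = np.full(n_perm, np.nan)
            continue
        out[c] = V[:, mask].var(axis=1, ddof=1) / sigma2_ir
    return out


def null_regional_pop(
    traits: TraitTable,
    trait: str,
    n_perm: int = 999,
    seed: int | None = 0,
    communities: list[str] | None = None,
    strict: bool = True,
) -> dict[str, np.ndarray]:
    """Null distributions of T_PC/PR per community: population mean trait
    values permuted across the regional population pool, the number of
    populations per community fixed.

    With ``strict=False`` a degenerate community (< 2 populations) yields
    an all-NaN null instead of raising.
    """
    df = traits.data.dropna(subset=[trait])
    if communities is None:
        communities = sorted(df["site"].unique())
    pop_means = df.groupby(["site", "species"])[trait].mean()
    values = pop_means.to_numpy(dtype=float)
    sigma2_pr = float(np.var(values, ddof=1))
    site = pop_means.index.get_level_values("site").to_numpy()
    rng = np.random.default_rng(seed)
    V = _perm_matrix(values, n_perm, rng)
    out = {}
    for c in communities:
        mask = site == c
        if mask.sum() < 2:
            if strict:
                raise ValueError(f"need >= 2 populations in community {c!r}")
            out[c] = np.full(n_perm, np.nan)
            continue
        out[c] = V[:, mask].var(axis=1, ddof=1) / sigma2_pr
    return out


# ---------------------------------------------------------------------------
# SES and p-values
# ---------------------------------------------------------------------------


def ses_and_p(t_obs: float, null: np.ndarray) -> tuple[float, float]:
    """Standardized effect size and two-sided add-one permutation p.

    SES = (T_obs - null mean)/null SD; p = 2 * min(P(null <= obs),
    P(null >= obs)) with the add-one correction, capped at 1.  A degenerate
    null (SD = 0) yields SES = NaN and a p computed from exact ties.
    """
    null = np.asarray(null, dtype=float)
    null = null[~np.isnan(null)]
    if null.size == 0 or math.isnan(t_obs):
        return math.nan, math.nan
    mean = float(null.mean())
    sd = float(null.std(ddof=1)) if null.size > 1 else 0.0
    ses = (t_obs - mean) / sd if sd > 0 else math.nan
    n = null.size
    lo = (np.sum(null <= t_obs) + 1) / (n + 1)
    hi = (np.sum(null >= t_obs) + 1) / (n + 1)
    p = min(1.0, 2.0 * min(lo, hi))
    return float(ses), float(p)


# ---------------------------------------------------------------------------
# Whole-dataset driver
# ---------------------------------------------------------------------------


def tstats_for_dataset(
    traits: TraitTable,
    columns: list[str] | None = None,
    n_perm: int = 999,
    seed: int | None = 0,
    weighted: bool = False,
    keep_null: bool = False,
) -> pd.DataFrame:
    """All three T-statistics with their null models for every trait x
    community; tidy long table with T_obs, null mean/SD, SES and p."""
    cols = columns or list(traits.trait_columns)
    sites = sorted(traits.data["site"].unique())
    records = []
    for t_i, trait in enumerate(cols):
        base = 0 if seed is None else seed
        nulls_ic = null_regional_ind(traits, trait, n_perm, np.random.default_rng(np.random.SeedSequence([base, t_i, 1])), strict=False)
        nulls_pc = null_regional_pop(traits, trait, n_perm, np.random.default_rng(np.random.SeedSequence([base, t_i, 2])), strict=False)
        for s_i, site in enumerate(sites):
            comp = variance_components(traits, trait, site)
            tstats = t_statistics(comp, weighted=weighted)
            try:
                null_ip = null_local(
                    traits, trait, site, n_perm,
                    np.random.default_rng(np.random.SeedSequence([base, t_i, 0, s_i])),
                )
            except ValueError:
                null_ip = np.full(n_perm, np.nan)
            for stat, null in (
                ("T_IP_IC", null_ip),
                ("T_IC_IR", nulls_ic[site]),
                ("T_PC_PR", nulls_pc[site]),
            ):
                ses, p = ses_and_p(tstats[stat], null)
                finite = null[np.isfinite(null)]
                records.append({
                    "trait": trait, "community": site, "statistic": stat,
                    "t_obs": tstats[stat],
                    "null_mean": float(finite.mean()) if finite.size else math.nan,
                    "null_sd": float(finite.std(ddof=1)) if finite.size > 1 else math.nan,
                    "ses": ses,
                    "p_value": p, "null_model": NULL_MODELS[stat], "n_perm": n_perm,
                    **({"null": null} if keep_null else {}),
                })
    return pd.DataFrame(records)


def habitat_contrast(results: pd.DataFrame, habitats: pd.Series) -> pd.DataFrame:
    """One-way ANOVA of per-community SES between the two habitat classes,
    for each trait x statistic."""
    from .community_composition import one_way_anova

    hab = habitats.astype(str)
    classes = sorted(hab.unique())
    if len(classes) != 2:
        raise ValueError("habitat contrast needs exactly 2 habitat classes")
    rows = []
    for (trait, stat), grp in results.groupby(["trait", "statistic"]):
        ses = grp.set_index("community")["ses"].dropna()
        a = ses[hab.reindex(ses.index) == classes[0]]
        b = ses[hab.reindex(ses.index) == classes[1]]
        if len(a) < 2 or len(b) < 2:
            rows.append({"trait": trait, "statistic": stat, "F": np.nan, "p_value": np.nan})
            continue
        F, p = one_way_anova(a, b)
        rows.append({"trait": trait, "statistic": stat, "F": F, "p_value": p})
    return pd.DataFrame(rows)
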