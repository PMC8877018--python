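"""End-to-end orchestration: run every analysis stage from a single config.

The pipeline sequences species selection -> species means -> phylogenetic
signal -> trait correlations -> CWM/NMDS/habitat ANOVA -> T-statistics ->
fourth-corner/RLQ, writing one tidy table per stage plus a machine-readable
summary and a run log.  A single global seed is fanned out per stage with a
counter-based scheme (SeedSequence([seed, stage_index])) so toggling one
stage never changes another stage's random stream.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_io import (
    read_community_matrix,
    read_env_matrix,
    read_newick,
    read_trait_table,
    select_abundant_species,
    species_means,
)
from .synthetic_data import SimulationConfig, generate_dataset, write_dataset

logger = logging.getLogger("traitassembly")

ALL_STAGES = ("signal", "correlations", "composition", "tstats", "fourthcorner")
# fixed per-stage seed counters; independent of which stages are toggled on
_STAGE_SEED = {name: i for i, name in enumerate(ALL_STAGES)}


def setup_logging(logfile: Path | None = None, level: int = logging.INFO) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


@dataclass
class PipelineConfig:
    """Inputs are either four file paths or a simulation block, not neither."""

    traits: str | None = None
    community: str | None = None
    env: str | None = None
    tree: str | None = None
    simulation: SimulationConfig | None = None
    abundance_threshold: float = 0.70
    n_perm: int = 999
    seed: int = 0
    output_dir: str = "traitassembly_out"
    stages: tuple[str, ...] = ALL_STAGES
    fourth_corner_model: str = "sites"

    def __post_init__(self) -> None:
        has_paths = self.traits is not None
        if not has_paths and self.simulation is None:
            raise ValueError("config needs input paths or a simulation block")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulation", None)
        if sim is not None:
            sim = SimulationConfig(**sim)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(simulation=sim, **raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            sim = dataclasses.asdict(self.simulation)
            sim.pop("trait_correlation", None)
            sim["trait_names"] = list(sim["trait_names"])
            if sim["env_gradient"] is not None:
                sim["env_gradient"] = list(sim["env_gradient"])
            d["simulation"] = sim  # yaml renders inf as `.inf` natively
        d["stages"] = list(self.stages)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _stage_seed(config: PipelineConfig, stage: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([config.seed, _STAGE_SEED[stage]])


def _load_inputs(config: PipelineConfig, outdir: Path):
    if config.simulation is not None:
        ds = generate_dataset(config.simulation)
        write_dataset(ds, outdir / "synthetic_input")
        return ds.traits, ds.community, ds.env, ds.phylogeny
    traits = read_trait_table(config.traits)
    community = read_community_matrix(config.community) if config.community else None
    env = read_env_matrix(config.env) if config.env else None
    tree = read_newick(config.tree) if config.tree else None
    return traits, community, env, tree


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns a summary dict (also written
    to ``summary.json`` in the output directory)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    setup_logging(outdir / "run.log")
    logger.info("traitassembly %s starting; seed=%d stages=%s", __version__, config.seed, config.stages)
    config.to_yaml(outdir / "config.yaml")

    summary: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    traits, community, env, tree = _load_inputs(config, outdir)

    # species selection + species means feed every later stage
    stage = "select"
    try:
        if community is not None:
            retained = sorted({
                sp
                for site in community.sites
                for sp in select_abundant_species(community.data.loc[site], config.abundance_threshold)
            })
            traits_sel = traits.subset_species(retained)
        else:
            retained = traits.species
            traits_sel = traits
        stm = species_means(traits_sel)
        stm.mean.to_csv(outdir / "species_means.tsv", sep="\t")
        summary["n_species_retained"] = len(retained)
        summary["n_individuals"] = len(traits_sel)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    if "signal" in config.stages:
        stage = "signal"
        try:
            if tree is None:
                raise ValueError("signal stage needs a tree")
            from .phylo_signal import signal_battery

            sig = signal_battery(
                stm.mean.dropna(how="any"), tree, n_perm=config.n_perm,
                seed=int(_stage_seed(config, stage).generate_state(1)[0] % (2**31)),
            )
            sig.to_csv(outdir / "signal.tsv", sep="\t", index=False)
            summary["stages"][stage] = {"rows": len(sig)}
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    if "correlations" in config.stages:
        stage = "correlations"
        try:
            from .trait_association import phylo_correlation_matrix, spearman_matrix

            pooled = spearman_matrix(traits_sel, scope="pooled")
            per_sp = spearman_matrix(traits_sel, scope="per_species")
            tables = [pooled, per_sp]
            if tree is not None:
                tables.append(phylo_correlation_matrix(stm, tree))
            corr = pd.concat(tables, ignore_index=True)
            corr.to_csv(outdir / "correlations.tsv", sep="\t", index=False)
            summary["stages"][stage] = {"rows": len(corr)}
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    if "composition" in config.stages:
        stage = "composition"
        try:
            from .community_composition import centroid_test, cwm_table, nmds, one_way_anova

            seed = int(_stage_seed(config, stage).generate_state(1)[0] % (2**31))
            out = {}
            if community is not None:
                cwms = cwm_table(community, stm, config.abundance_threshold)
                cwms.to_csv(outdir / "cwm.tsv", sep="\t")
                hab = traits.data.drop_duplicates("site").set_index("site")["habitat"]
                rows = []
                for trait in stm.traits:
                    groups = cwms[trait].groupby(hab.reindex(cwms.index))
                    vals = {g: v.to_numpy() for g, v in groups}
                    if len(vals) == 2 and all(len(v) >= 2 for v in vals.values()):
                        F, p = one_way_anova(*vals.values())
                        rows.append({"trait": trait, "F": F, "p_value": p})
                pd.DataFrame(rows).to_csv(outdir / "cwm_anova.tsv", sep="\t", index=False)
                out["cwm_sites"] = len(cwms)
            ord_res = nmds(traits_sel, seed=seed)
            ord_res.coordinates.to_csv(outdir / "ordination.tsv", sep="\t")
            coords = ord_res.coordinates[[c for c in ord_res.coordinates.columns if c.startswith("axis")]]
            cent = {}
            for label_col in ("site", "habitat"):
                if label_col in ord_res.coordinates.columns:
                    r2, p = centroid_test(coords, ord_res.coordinates[label_col],
                                          n_perm=config.n_perm, seed=seed)
                    cent[label_col] = {"r2": r2, "p": p}
            out.update({"stress": ord_res.stress, "centroid_tests": cent})
            summary["stages"][stage] = out
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    if "tstats" in config.stages:
        stage = "tstats"
        try:
            from .assembly_tstats import habitat_contrast, tstats_for_dataset

            seed = int(_stage_seed(config, stage).generate_state(1)[0] % (2**31))
            ts = tstats_for_dataset(traits_sel, n_perm=config.n_perm, seed=seed)
            ts.to_csv(outdir / "tstats.tsv", sep="\t", index=False)
            hab = traits.data.drop_duplicates("site").set_index("site")["habitat"]
            if hab.nunique() == 2:
                hc = habitat_contrast(ts, hab)
                hc.to_csv(outdir / "tstats_habitat_anova.tsv", sep="\t", index=False)
            summary["stages"][stage] = {"rows": len(ts)}
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    if "fourthcorner" in config.stages:
        stage = "fourthcorner"
        try:
            if community is None or env is None:
                raise ValueError("fourthcorner stage needs community and env matrices")
            from .env_association import extended_rlq, fourth_corner, rlq

            seed = int(_stage_seed(config, stage).generate_state(1)[0] % (2**31))
            fc = fourth_corner(env, community, stm, model=config.fourth_corner_model,
                               n_perm=config.n_perm, seed=seed)
            fc.table.to_csv(outdir / "fourth_corner.tsv", sep="\t", index=False)
            q = stm.mean.dropna(how="any")
            res = rlq(env, community, q)
            axis_summary = pd.DataFrame({
                "eigenvalue": res.eigenvalues, "percent": res.percent,
            })
            if tree is not None:
                ext = extended_rlq(env, community, q, tree)
                dec = pd.DataFrame({
                    "global.scores": ext.global_scores,
                    "trait.based": ext.trait_based,
                    "phylogeny.based": ext.phylogeny_based,
                })
                dec.to_csv(outdir / "rlq_species_scores.tsv", sep="\t")
            axis_summary.to_csv(outdir / "rlq_axes.tsv", sep="\t", index=False)
            summary["stages"][stage] = {
                "pairs": len(fc.table),
                "axis1_percent": float(res.percent[0]) if len(res.percent) else math.nan,
            }
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline finished; outputs in %s", outdir)
    return summary
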