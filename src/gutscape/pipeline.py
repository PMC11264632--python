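"""End-to-end orchestration: load → rarefy → diversity → enterotype →
assembly → environmental association, from one validated config.

Every stage derives its own random seed from the master seed, so enabling or
disabling one stage never changes another stage's results. All intermediates
are plain TSV; a JSON manifest records parameters, seeds, library versions
and dropped-sample accounting so a run can be reproduced from the manifest
alone.
"""

from __future__ import annotations

import dataclasses
import difflib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_model import (AnalysisBundle, align_inputs, read_feature_table,
                         read_metadata, read_taxonomy, read_tree)
from . import assembly as assembly_mod
from . import diversity as diversity_mod
from . import enterotype as enterotype_mod
from . import env_assoc as env_mod

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated settings for a full run."""

    table: str = ""
    tree: str = ""
    metadata: str = ""
    taxonomy: str = ""
    output_dir: str = "gutscape_out"
    rarefaction_depth: int = 4530
    seed: int = 0
    n_permutations: int = 999
    n_randomizations: int = 1000
    abundance_weighted: bool = True
    enterotype_subset: dict = field(default_factory=dict)  # column -> value
    k_max: int = 6
    stages: tuple = ("diversity", "enterotype", "assembly", "env_assoc")

    def __post_init__(self) -> None:
        if self.rarefaction_depth < 1:
            raise ValueError("rarefaction_depth must be >= 1")
        unknown = set(self.stages) - {"diversity", "enterotype", "assembly",
                                      "env_assoc"}
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        return (int(self.seed) ^ zlib.crc32(stage.encode())) % (2**31)


def validate_config(path) -> PipelineConfig:
    """Load a YAML config file into a typed PipelineConfig.

    Unknown keys are rejected with a nearest-match suggestion; defaults
    filled in for absent keys are logged.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    valid = {f.name for f in dataclasses.fields(PipelineConfig)}
    for key in raw:
        if key not in valid:
            hint = difflib.get_close_matches(key, valid, n=1)
            suggestion = f" (did you mean {hint[0]!r}?)" if hint else ""
            raise ValueError(f"{path}: unknown config key {key!r}{suggestion}")
    for name in sorted(valid - set(raw)):
        default = getattr(PipelineConfig, name, None)
        logger.info("config: %s not set, using default %r", name, default)
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    return PipelineConfig(**raw)


def load_bundle(config: PipelineConfig) -> AnalysisBundle:
    need_tree = "assembly" in config.stages or "diversity" in config.stages
    for name in ("table", "metadata"):
        if not getattr(config, name):
            raise ValueError(f"config: {name} path is required")
    if need_tree and not config.tree:
        raise ValueError("config: tree path is required for the phylogenetic "
                         "stages (diversity, assembly)")
    table = read_feature_table(config.table)
    tree = read_tree(config.tree, expected_taxa=table.taxon_ids) if config.tree else None
    meta = read_metadata(config.metadata)
    tax = read_taxonomy(config.taxonomy) if config.taxonomy else None
    return align_inputs(table, tree, meta, tax, require_tree=need_tree)


def run_pipeline(config: PipelineConfig,
                 bundle: AnalysisBundle | None = None) -> dict:
    """Execute all configured stages; returns the result dictionary.

    All stage outputs are also written as TSVs under ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if bundle is None:
        bundle = load_bundle(config)
    results: dict = {}
    manifest = {
        "gutscape_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "stage_seeds": {s: config.stage_seed(s) for s in config.stages},
        "dropped_samples": bundle.dropped_samples,
        "dropped_taxa": bundle.dropped_taxa,
        "pruned_tips": bundle.pruned_tips,
    }

    rarefied = diversity_mod.rarefy(bundle.table, config.rarefaction_depth,
                                    seed=config.stage_seed("rarefy"))
    meta = bundle.metadata.loc[rarefied.sample_ids]
    manifest["samples_after_rarefaction"] = len(rarefied.sample_ids)

    if "diversity" in config.stages:
        seed = config.stage_seed("diversity")
        alpha = diversity_mod.alpha_diversity(rarefied, bundle.tree)
        alpha.to_csv(out / "alpha_diversity.tsv", sep="\t")
        dm = diversity_mod.bray_curtis(rarefied)
        pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
            out / "bray_curtis.tsv", sep="\t")
        perm = {
            level: diversity_mod.permanova(dm, meta[level],
                                           n_perm=config.n_permutations,
                                           seed=seed)
            for level in ("province", "site")
        }
        pd.DataFrame(perm).T.to_csv(out / "permanova.tsv", sep="\t")
        results["diversity"] = {"alpha": alpha, "bray_curtis": dm,
                                "permanova": perm}

    if "enterotype" in config.stages and bundle.taxonomy is not None:
        seed = config.stage_seed("enterotype")
        sub_ids = list(rarefied.sample_ids)
        for col, val in config.enterotype_subset.items():
            sub_ids = [s for s in sub_ids if meta.loc[s, col] == val]
        sub = rarefied.filter_samples(sub_ids)
        profiles = enterotype_mod.collapse_to_genus(sub, bundle.taxonomy)
        model = enterotype_mod.find_enterotypes(profiles, k_max=config.k_max,
                                                seed=seed)
        model.labels.to_csv(out / "enterotype_labels.tsv", sep="\t")
        pd.DataFrame({"CH": model.ch_by_k,
                      "silhouette": model.silhouette_by_k}).to_csv(
            out / "enterotype_indices.tsv", sep="\t")
        model.pcoa_scores.to_csv(out / "enterotype_pcoa.tsv", sep="\t")
        contrasts = enterotype_mod.compare_enterotypes(profiles, model.labels)
        contrasts.to_csv(out / "enterotype_contrasts.tsv", sep="\t")
        results["enterotype"] = {"model": model, "contrasts": contrasts,
                                 "profiles": profiles}

    if "assembly" in config.stages:
        seed = config.stage_seed("assembly")
        null_cfg = assembly_mod.NullModelConfig(
            n_randomizations=config.n_randomizations, seed=seed,
            abundance_weighted=config.abundance_weighted)
        asm = assembly_mod.partition_assembly(rarefied, bundle.tree, meta,
                                              null_cfg)
        asm.pairs.to_csv(out / "assembly_pairs.tsv", sep="\t", index=False)
        frac = pd.DataFrame({c: f.fractions for c, f in asm.fractions.items()})
        frac.to_csv(out / "assembly_fractions.tsv", sep="\t")
        shift = assembly_mod.compare_fractions(asm.fractions["between_site"],
                                               asm.fractions["within_site"])
        shift.to_csv(out / "assembly_site_shift.tsv", sep="\t")
        results["assembly"] = {"result": asm, "site_shift": shift}

    if "env_assoc" in config.stages:
        seed = config.stage_seed("env_assoc")
        env = env_mod.env_table(meta)
        vif = env_mod.vif_screen(env)
        vif.to_csv(out / "env_vif.tsv", sep="\t")
        dm = results.get("diversity", {}).get("bray_curtis")
        if dm is None:
            dm = diversity_mod.bray_curtis(rarefied)
        screen = env_mod.marginal_adonis_screen(dm, env,
                                                n_perm=config.n_permutations,
                                                seed=seed)
        screen.to_csv(out / "env_adonis_screen.tsv", sep="\t")
        alpha = results.get("diversity", {}).get("alpha")
        if alpha is None:
            alpha = diversity_mod.alpha_diversity(rarefied, bundle.tree)
        glms = {}
        for var in env.columns:
            glms[var] = {
                "chao1": env_mod.glm_alpha(alpha["chao1"], env[var], "poisson"),
                "faith_pd": (env_mod.glm_alpha(alpha["faith_pd"], env[var],
                                               "gaussian")
                             if "faith_pd" in alpha else None),
            }
        glm_rows = []
        for var, fits in glms.items():
            for index, fit in fits.items():
                if fit is not None:
                    glm_rows.append({"variable": var, "index": index,
                                     "slope": fit.slope, "p": fit.slope_p})
        pd.DataFrame(glm_rows).to_csv(out / "env_glm.tsv", sep="\t",
                                      index=False)
        ddr = env_mod.ddr_fit(dm, meta, n_perm=config.n_permutations,
                              seed=seed)
        occupied = rarefied.counts.sum(axis=1) > 0
        cca_table = rarefied.filter_taxa(
            [t for t, keep in zip(rarefied.taxon_ids, occupied) if keep])
        cca_res = env_mod.cca(cca_table, env)
        cca_p = env_mod.cca_permutation_test(cca_res,
                                             n_perm=config.n_permutations,
                                             seed=seed)
        fit = env_mod.envfit(cca_res.site_scores.iloc[:, :2], env,
                             n_perm=config.n_permutations, seed=seed)
        fit.to_csv(out / "env_envfit.tsv", sep="\t")
        cca_res.biplot_scores.to_csv(out / "cca_biplot.tsv", sep="\t")
        cca_res.site_scores.to_csv(out / "cca_sites.tsv", sep="\t")
        results["env_assoc"] = {"vif": vif, "screen": screen, "glm": glms,
                                "ddr": ddr, "cca": cca_res,
                                "cca_test": cca_p, "envfit": fit}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    results["manifest"] = manifest
    return results
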