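"""End-to-end pipeline: simulate -> gwas -> meta -> clump -> grs -> phewas
-> mr -> network, with a JSON manifest of every artifact.

The run is deterministic given the configuration seed: the manifest records
the master seed and the sha256 of each written file, so identical configs
produce identical manifests for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import gwas, grs, io, mr, network, phewas
from .config import PipelineConfig, SimulationConfig, TwoSampleConfig
from .simulate import simulate_cohort, simulate_two_sample

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full chain and return the manifest dict (also written to
    ``<out_dir>/manifest.json``). Any stage failure aborts with the stage
    name; artifacts written before the failure are retained."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = config.simulation
    if sim_cfg.seed != config.seed:
        sim_cfg = SimulationConfig.from_dict({**sim_cfg.to_dict(), "seed": config.seed})
    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}

    def _record(stage: str, **files: Path) -> None:
        manifest["stages"][stage] = {k: str(p) for k, p in files.items()}
        for p in files.values():
            manifest["files"][str(p)] = _sha256(Path(p))

    stage = "simulate"
    try:
        genotypes, covariates, trait, true_betas, phe = simulate_cohort(sim_cfg)
        io.write_genotypes(genotypes, out / "dosages.tsv", out / "variants.tsv")
        io.write_covariates(covariates, out / "covariates.csv")
        io.write_trait(trait, out / "trait.csv")
        io.write_phecodes(phe, out / "phecodes.csv", out / "phecode_meta.csv")
        _record(stage, dosages=out / "dosages.tsv", variants=out / "variants.tsv",
                covariates=out / "covariates.csv", trait=out / "trait.csv",
                phecodes=out / "phecodes.csv", phecode_meta=out / "phecode_meta.csv")

        stage = "gwas"
        resid = gwas.residualize_trait(trait, covariates)
        y = gwas.inverse_normal_transform(resid)
        assoc = gwas.run_gwas(genotypes, y)
        io.write_summary_stats(assoc, out / "gwas.tsv")
        _record(stage, summary=out / "gwas.tsv")

        stage = "meta"
        meta = gwas.meta_analyze([assoc])
        io.write_summary_stats(meta, out / "meta.tsv")
        _record(stage, summary=out / "meta.tsv")

        stage = "clump"
        loci = gwas.select_independent_snps(
            meta, genotypes, p_threshold=config.p_threshold,
            r2_threshold=config.r2_threshold, locus_window=config.locus_window)
        clump_df = loci.accepted
        io.write_summary_stats(clump_df, out / "independent_snps.tsv")
        _record(stage, snps=out / "independent_snps.tsv")

        stage = "grs"
        # external weights: the true simulated effects stand in for an
        # external discovery meta-analysis (betas on the standardized scale)
        external = genotypes.variants.copy()
        external["beta"] = true_betas.to_numpy()
        external["se"] = 1.0
        external["p"] = 1.0
        external["n"] = sim_cfg.n_individuals
        if len(clump_df):
            weights = grs.build_weights(loci, external)
        else:
            weights = pd.DataFrame(columns=["snp", "ea", "weight"])
        score = grs.compute_grs(genotypes, weights)
        io.write_weights(weights, out / "grs_weights.tsv")
        pd.DataFrame({"individual_id": genotypes.individual_ids, "grs": score}).to_csv(
            out / "grs.csv", index=False)
        _record(stage, weights=out / "grs_weights.tsv", scores=out / "grs.csv")

        stage = "phewas"
        filtered = phewas.filter_phecodes(phe, config.min_cases, config.min_controls)
        results_df = pd.DataFrame()
        if filtered.codes:
            z = phewas.standardize_bmi(trait)
            results_df = phewas.run_phewas(z, filtered, covariates)
            thr = phewas.bonferroni_threshold(len(filtered.codes))
            results_df["significant"] = (~results_df["flagged"]) & (results_df["p"] < thr)
        results_df.to_csv(out / "phewas.tsv", sep="\t", index=False)
        _record(stage, results=out / "phewas.tsv")

        stage = "mr"
        mr_df = pd.DataFrame()
        associated: list[str] = []
        if filtered.codes and score.std() > 0:
            mr_results = mr.grs_mr(score, trait, filtered, covariates)
            mr_df = pd.DataFrame([r.to_dict() for r in mr_results])
            thr = phewas.bonferroni_threshold(len(filtered.codes))
            mr_df["significant"] = (~mr_df["flagged"]) & (mr_df["p"] < thr)
            associated = mr_df.loc[mr_df["significant"], "outcome"].tolist()
        mr_df.to_csv(out / "mr.tsv", sep="\t", index=False)
        burden_codes = associated if associated else []
        burden, trend_p = phewas.disease_burden(phe, burden_codes, trait)
        burden["trend_p"] = trend_p
        burden.to_csv(out / "burden.csv", index=False)
        _record(stage, results=out / "mr.tsv", burden=out / "burden.csv")

        stage = "network"
        net_summary = {"n_nodes": 0, "n_edges": 0, "n_communities": 0}
        if len(associated) >= 2:
            rolled = network.rollup_phecodes(phe, associated)
            if len(rolled.codes) >= 2:
                net = network.build_network(rolled, phi_min=config.phi_min,
                                            alpha=config.alpha, adjust=config.adjust_method)
                labels = network.detect_communities(net, seed=config.seed)
                if net.n_edges > 0:
                    network.community_significance(net, labels, n_null=config.n_null,
                                                   seed=config.seed)
                io.write_network(net, out / "network.graphml", out / "edges.tsv",
                                 out / "communities.csv")
                net_summary = {"n_nodes": net.n_nodes, "n_edges": net.n_edges,
                               "n_communities": len(set(labels.values()))}
                _record(stage, graphml=out / "network.graphml", edges=out / "edges.tsv",
                        communities=out / "communities.csv")
        if "network" not in manifest["stages"]:
            logger.info("network stage: fewer than 2 associated codes; nothing to build")
            manifest["stages"]["network"] = {}
        manifest["network_summary"] = net_summary
    except Exception as exc:  # noqa: BLE001 - abort must name the stage
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
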