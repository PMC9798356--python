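"""Plain-text file formats for every pipeline artifact.

Everything is TSV/CSV/JSON with documented headers: a dosage matrix TSV
(header row = variant ids, first column = individual id) plus a variant
metadata TSV; covariates, trait and phecode statuses as CSV; association
summaries in the interchange TSV schema (snp, chr, pos, ea, oa, eaf, beta,
se, p, n); two-sample summaries as TSV (snp, beta_exp, se_exp, beta_out,
se_out); the network as GraphML plus an edge-list TSV. Floats are written
with 15 significant digits so round-trips are lossless at that precision.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import ASSOC_COLUMNS, DiseaseNetwork, GenotypeMatrix, PhecodeTable

logger = logging.getLogger(__name__)

__all__ = [
    "write_genotypes", "read_genotypes",
    "write_covariates", "read_covariates",
    "write_trait", "read_trait",
    "write_phecodes", "read_phecodes",
    "write_summary_stats", "read_summary_stats",
    "write_two_sample", "read_two_sample",
    "write_weights", "read_weights",
    "write_network",
]

_FLOAT_FMT = "%.15g"


def write_genotypes(genotypes: GenotypeMatrix, dosage_path: str | Path, variants_path: str | Path) -> None:
    df = pd.DataFrame(genotypes.dosages, columns=genotypes.variants["snp"],
                      index=genotypes.individual_ids)
    df.index.name = "individual_id"
    df.to_csv(dosage_path, sep="\t", float_format=_FLOAT_FMT)
    genotypes.variants.to_csv(variants_path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_genotypes(dosage_path: str | Path, variants_path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(dosage_path, sep="\t", index_col="individual_id")
    variants = pd.read_csv(variants_path, sep="\t")
    return GenotypeMatrix(dosages=df.to_numpy(dtype=float), variants=variants,
                          individual_ids=[str(i) for i in df.index])


def write_covariates(cov: pd.DataFrame, path: str | Path) -> None:
    out = cov.copy()
    out.index.name = "individual_id"
    out.to_csv(path, float_format=_FLOAT_FMT)


def read_covariates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="individual_id")


def write_trait(trait: pd.DataFrame, path: str | Path) -> None:
    out = trait.copy()
    out.index.name = "individual_id"
    out.to_csv(path, float_format=_FLOAT_FMT)


def read_trait(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="individual_id")


def write_phecodes(phecodes: PhecodeTable, status_path: str | Path, meta_path: str | Path) -> None:
    out = phecodes.status.copy()
    out.index.name = "individual_id"
    out.to_csv(status_path)
    phecodes.meta.to_csv(meta_path, index=False)


def read_phecodes(status_path: str | Path, meta_path: str | Path) -> PhecodeTable:
    status = pd.read_csv(status_path, index_col="individual_id")
    status.columns = [str(c) for c in status.columns]
    meta = pd.read_csv(meta_path, dtype={"code": str}).fillna("")
    return PhecodeTable(status=status, meta=meta)


def write_summary_stats(assoc: pd.DataFrame, path: str | Path) -> None:
    assoc.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT,
                 columns=[c for c in ASSOC_COLUMNS if c in assoc.columns])


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    """Read the association interchange TSV; malformed rows are rejected
    with their line numbers logged, a missing required column raises."""
    raw = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ASSOC_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"summary statistics file missing required column(s): {missing}")
    numeric = {"chr": int, "pos": int, "eaf": float, "beta": float, "se": float,
               "p": float, "n": int}
    rows, bad = [], []
    for k, row in raw.iterrows():
        try:
            rec = {"snp": str(row["snp"]), "ea": str(row["ea"]), "oa": str(row["oa"])}
            for col, typ in numeric.items():
                rec[col] = typ(float(row[col]))
            if rec["se"] <= 0 or not (0 < rec["p"] <= 1):
                raise ValueError
            rows.append(rec)
        except (ValueError, TypeError):
            bad.append(k + 2)  # 1-based line number incl. header
    if bad:
        logger.info("read_summary_stats: rejected %d malformed row(s) at lines %s",
                    len(bad), bad[:20])
    return pd.DataFrame(rows, columns=ASSOC_COLUMNS)


def write_two_sample(data: pd.DataFrame, path: str | Path) -> None:
    data.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT,
                columns=["snp", "beta_exp", "se_exp", "beta_out", "se_out"])


def read_two_sample(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = ["snp", "beta_exp", "se_exp", "beta_out", "se_out"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"two-sample file missing required column(s): {missing}")
    return df


def write_weights(weights: pd.DataFrame, path: str | Path) -> None:
    weights.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_weights(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("snp", "ea", "weight") if c not in df.columns]
    if missing:
        raise ValueError(f"weights file missing required column(s): {missing}")
    return df


def write_network(net: DiseaseNetwork, graphml_path: str | Path, edges_path: str | Path,
                  communities_path: str | Path | None = None) -> None:
    nx.write_graphml(net.graph, graphml_path)
    net.edges.to_csv(edges_path, sep="\t", index=False, float_format=_FLOAT_FMT,
                     columns=["code_i", "code_j", "phi", "p_adj"])
    if communities_path is not None and net.communities:
        from .network import hub_stats

        hubs = hub_stats(net)
        hubs["community_p"] = hubs["community"].map(net.community_p) if net.community_p else np.nan
        hubs.to_csv(communities_path, index=False, float_format=_FLOAT_FMT)
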