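"""In-memory containers shared across the pipeline.

Tabular data (association summaries, PheWAS results, weights) travel as
pandas DataFrames with documented column schemas; the containers here wrap
the pieces that need to stay together (dosages + variant metadata, disease
status matrix + code metadata, clumped loci, MR estimates, the comorbidity
graph).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PhecodeTable",
    "Locus",
    "LocusSet",
    "MRResult",
    "DiseaseNetwork",
    "ASSOC_COLUMNS",
]

#: interchange schema for per-variant association summaries
ASSOC_COLUMNS = ["snp", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "p", "n"]


@dataclass
class GenotypeMatrix:
    """Additive dosage matrix (individuals x variants) plus variant metadata.

    ``variants`` columns: snp, chr, pos (1-based), ea (effect allele),
    oa (other allele), eaf (effect-allele frequency used to simulate).
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    individual_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x variants)")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("variant metadata length does not match dosage columns")
        if not self.individual_ids:
            self.individual_ids = [f"id{i:06d}" for i in range(self.dosages.shape[0])]
        self._index = {s: j for j, s in enumerate(self.variants["snp"])}

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def column(self, snp: str) -> np.ndarray:
        """Dosage vector for one variant id."""
        try:
            return self.dosages[:, self._index[snp]]
        except KeyError:
            raise KeyError(f"variant {snp!r} not present in genotype matrix") from None

    def columns(self, snps) -> np.ndarray:
        missing = [s for s in snps if s not in self._index]
        if missing:
            raise KeyError(f"variants missing from genotype matrix: {missing[:10]}")
        idx = [self._index[s] for s in snps]
        return self.dosages[:, idx]


@dataclass
class PhecodeTable:
    """Binary case/control status per individual and phecode.

    ``status``: DataFrame indexed by individual id with one 0/1 column per
    dotted phecode string. ``meta``: DataFrame with columns code,
    description, disease_group (one row per code).
    """

    status: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.status.to_numpy()
        if vals.size and not np.isin(vals, [0, 1]).all():
            raise ValueError("phecode statuses must be binary 0/1")
        self.meta = self.meta.set_index("code", drop=False) if "code" in self.meta.columns else self.meta

    @property
    def codes(self) -> list[str]:
        return list(self.status.columns)

    def counts(self) -> pd.DataFrame:
        """Cases/controls per code."""
        n = len(self.status)
        cases = self.status.sum(axis=0).astype(int)
        return pd.DataFrame(
            {"code": self.status.columns, "n_cases": cases.values, "n_controls": n - cases.values}
        )


@dataclass
class Locus:
    lead: pd.Series
    secondaries: pd.DataFrame
    chrom: int
    start: int
    end: int
    novel: bool | None = None

    @property
    def span(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def n_snps(self) -> int:
        return 1 + len(self.secondaries)


@dataclass
class LocusSet:
    loci: list[Locus]
    accepted: pd.DataFrame  # all accepted independent SNPs (assoc schema)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_independent_snps(self) -> int:
        return len(self.accepted)

    @property
    def n_novel(self) -> int:
        return sum(1 for l in self.loci if l.novel)


@dataclass
class MRResult:
    """One causal estimate: log-OR per SD of the exposure, with Wald SE."""

    outcome: str
    estimator: str
    beta: float
    se: float
    p: float
    n_variants: int = 0
    egger_intercept: float | None = None
    egger_intercept_p: float | None = None
    first_stage_f: float | None = None
    weak_instrument: bool = False
    flagged: bool = False

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci(self) -> tuple[float, float]:
        return (float(np.exp(self.beta - 1.96 * self.se)), float(np.exp(self.beta + 1.96 * self.se)))

    def to_dict(self) -> dict:
        lo, hi = self.ci
        return {
            "outcome": self.outcome,
            "estimator": self.estimator,
            "beta": self.beta,
            "se": self.se,
            "p": self.p,
            "or": self.odds_ratio,
            "ci_low": lo,
            "ci_high": hi,
            "n_variants": self.n_variants,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_p": self.egger_intercept_p,
            "first_stage_f": self.first_stage_f,
            "weak_instrument": self.weak_instrument,
            "flagged": self.flagged,
        }


@dataclass
class DiseaseNetwork:
    """phi-correlation comorbidity network over 3-digit codes.

    ``edges`` columns: code_i, code_j, c_ij, p_i, p_j, n, phi, t_stat,
    p_raw, p_adj (only retained edges). ``graph`` is the networkx Graph of
    retained edges; ``communities`` maps node -> integer label (filled by
    community detection); ``community_p`` maps label -> permutation p.
    """

    graph: "object"
    edges: pd.DataFrame
    all_pairs: pd.DataFrame
    node_groups: dict[str, str] = field(default_factory=dict)
    communities: dict[str, int] = field(default_factory=dict)
    community_p: dict[int, float] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()
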