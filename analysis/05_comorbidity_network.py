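#!/usr/bin/env python
"""Disease comorbidity network over the MR-associated phecodes.

Rolls the MR-associated dotted codes up to their 3-digit parents, scores
every pair by phi-correlation, keeps edges with BH-adjusted p < 0.05 and
phi >= 0.2, detects Louvain communities, tests each against a
degree-preserving rewiring null, and ranks hub diagnoses by degree and
cross-community reach. Run 01-04 first.
"""

from pathlib import Path

import pandas as pd

from bmiphenet import io
from bmiphenet.network import (
    build_network,
    community_significance,
    detect_communities,
    hub_stats,
    rollup_phecodes,
)
from bmiphenet.phewas import bonferroni_threshold

ROOT = Path(__file__).resolve().parent.parent / "results"
COHORT = ROOT / "cohort"
OUT = ROOT / "network"
SEED = 2022


def main() -> None:
    phecodes = io.read_phecodes(COHORT / "phecodes.csv", COHORT / "phecode_meta.csv")
    associated = pd.read_csv(ROOT / "phewas_mr" / "mr_associated_codes.csv",
                             dtype=str)["phecode"].tolist()
    if len(associated) < 2:
        print("fewer than 2 MR-associated codes: no network to build")
        return

    rolled = rollup_phecodes(phecodes, associated)
    net = build_network(rolled, phi_min=0.2, alpha=0.05, adjust="bh")
    labels = detect_communities(net, seed=SEED)
    n_comm = len(set(labels.values()))
    pvals = community_significance(net, labels, n_null=1000, seed=SEED) if net.n_edges else {}
    thr = bonferroni_threshold(max(n_comm, 1))
    hubs = hub_stats(net, labels)

    OUT.mkdir(parents=True, exist_ok=True)
    io.write_network(net, OUT / "network.graphml", OUT / "edges.tsv",
                     OUT / "communities.csv")
    hubs.to_csv(OUT / "hubs.csv", index=False)

    print(f"{len(associated)} MR-associated codes -> {len(rolled.codes)} "
          f"3-digit codes; network keeps {net.n_nodes} nodes and "
          f"{net.n_edges} edges (phi >= 0.2, adjusted p < 0.05)")
    print(f"{n_comm} Louvain communities; significance threshold "
          f"0.05/{n_comm} = {thr:.3g}")
    for lab in sorted(set(labels.values())):
        members = sorted(v for v, l in labels.items() if l == lab)
        p = pvals.get(lab, float("nan"))
        flag = "significant" if p < thr else "not significant"
        print(f"    community {lab}: {members} (p = {p:.3g}, {flag})")
    print("top hubs:")
    for row in hubs.head(5).itertuples(index=False):
        print(f"    {row.code:>6}: degree {row.degree}, community {row.community}, "
              f"reaches {row.cross_links} other communities")
    print(f"tables written to {OUT}")


if __name__ == "__main__":
    main()
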