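"""Signed co-expression network, modules, hubs and DEG enrichment.

Builds the signed adjacency ((1+r)/2)^5 on log2(RPKM+1), reports the
scale-free fit at beta=5, cuts TOM-dissimilarity modules (static cut,
minimum size 30), thresholds edges at weight > 0.43, calls hubs with > 50
connections, and tests each module for one-sided Fisher over-representation
of both DEG sets.

Reads results/data/ and results/expression/, writes results/network/.
"""

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from kskpipe import expression, network, simulate

DATA = Path("results/data")
EXPR = Path("results/expression")
OUT = Path("results/network")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    counts = pd.read_csv(DATA / "counts.tsv", sep="\t", index_col=0)
    lengths = pd.read_csv(DATA / "gene_lengths.tsv", sep="\t", index_col=0).iloc[:, 0]
    truth = simulate.count_truth_from_json((DATA / "count_truth.json").read_text())
    expr = np.log2(expression.rpkm(counts, lengths) + 1.0)

    net = network.signed_adjacency(expr, beta=5.0)
    r2, mean_k = network.scale_free_fit(net)
    print(f"signed network at beta=5: scale-free R^2 = {r2:.3f}, mean k = {mean_k:.1f}")

    mods = network.detect_modules(net)
    genes = list(expr.index)
    tl = [truth.module_assignments_true.get(g, 0) for g in genes]
    pl = [mods.assignments[g] for g in genes]
    mg = [i for i, t in enumerate(tl) if t > 0]
    ari = adjusted_rand_score([tl[i] for i in mg], [pl[i] for i in mg])
    print(f"{mods.n_modules()} modules (>= 30 genes); ARI vs planted modules = {ari:.3f}")
    pd.DataFrame({"gene": genes, "module": pl}).to_csv(OUT / "modules.tsv", sep="\t", index=False)

    edges = network.edge_list(net, weight_min=0.43)
    edges.to_csv(OUT / "edges.tsv", sep="\t", index=False, float_format="%.6g")
    hubs = network.hub_genes(edges, min_connections=50)
    (OUT / "hubs.txt").write_text("".join(f"{g}\n" for g in hubs))
    print(f"{len(edges)} edges above weight 0.43; {len(hubs)} hub genes (> 50 connections)")

    rows = []
    for deg_name in ("comparison1", "comparison2"):
        deg = set()
        for d in ("up", "down"):
            deg |= set((EXPR / f"{deg_name}_{d}.txt").read_text().split())
        for mid in sorted({m for m in pl if m > 0}):
            e = network.module_enrichment(mods.module_genes(mid), deg, set(genes), mid)
            rows.append({"deg_set": deg_name} | dataclasses.asdict(e))
    enr = pd.DataFrame(rows)
    enr.to_csv(OUT / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
    best = enr.loc[enr["log10_p"].idxmin()]
    print(f"strongest module enrichment: module {best['module_id']} for {best['deg_set']} "
          f"(overlap {best['overlap']}, log10 p = {best['log10_p']:.2f})")
    (OUT / "summary.json").write_text(json.dumps(
        {"r2": r2, "n_modules": mods.n_modules(), "ari_module_genes": ari,
         "n_edges": len(edges), "hubs": hubs}, indent=1))


if __name__ == "__main__":
    main()
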