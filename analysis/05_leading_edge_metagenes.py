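#!/usr/bin/env python
"""Metagene analysis of the mouse leading edges.

Builds the binary occurrence matrix of leading-edge genes across the sets
enriched at FDR < 0.01 in the mouse screen, cuts the average-linkage
dendrogram (1 - Pearson distance) into two metagenes, and annotates each
cluster by hypergeometric over-representation against the annotation terms
(universe = all ortholog-mappable platform genes, in human symbols).
"""

from pathlib import Path

import pandas as pd

from xsmono import cross_species, gsea, io_formats, metagenes

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "benchmark"
RESULTS = ROOT / "results"


def _load_results(path):
    df = pd.read_csv(path, sep="\t")
    return [
        gsea.GseaResult(
            set_name=row["set"], es=row["es"], nes=row["nes"], p_value=row["p"],
            fdr_q=row["q"], leading_edge=str(row["leading_edge"]).split(","),
            size=int(row["size"]), n_dropped=0, n_perm=1000, scheme="gene_set",
        )
        for _, row in df.iterrows()
    ]


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    results = _load_results(DATA / "gsea_mouse.tsv")
    occ = metagenes.occurrence_matrix(results, q_max=0.01)
    occ.to_csv(DATA / "occurrence_mouse.tsv", sep="\t")
    clusters = metagenes.cluster_metagenes(occ, k=2)
    print(f"occurrence matrix: {occ.shape[0]} genes x {occ.shape[1]} sets")
    print(f"metagene sizes at k=2: {[len(c) for c in clusters.clusters]}")

    with open(RESULTS / "metagene_clusters.tsv", "w", encoding="utf-8") as fh:
        fh.write("gene\tcluster\n")
        for i, cl in enumerate(clusters.clusters):
            for g in cl:
                fh.write(f"{g}\t{i}\n")

    omap = io_formats.read_ortholog_map(DATA / "orthologs.tsv")
    annotation = io_formats.read_gmt(DATA / "annotation.gmt")
    mouse_matrix_genes = pd.read_csv(DATA / "mouse_matrix.tsv", sep="\t", usecols=[0])
    universe_mapped, _ = cross_species.map_orthologs(mouse_matrix_genes.iloc[:, 0], omap)
    universe = sorted(set(universe_mapped))
    blocks = []
    for i, cl in enumerate(clusters.clusters):
        mapped, _ = cross_species.map_orthologs(cl, omap)
        mapped = sorted(set(mapped) & set(universe))
        if not mapped:
            continue
        res = metagenes.overrepresentation(mapped, annotation, universe)
        res.insert(0, "cluster", i)
        blocks.append(res)
        top = res.iloc[0]
        print(f"cluster {i} ({len(cl)} genes): top term {top['term']} "
              f"(k={top['k']}/{top['K']}, q={top['q']:.2g})")
    pd.concat(blocks, ignore_index=True).to_csv(
        RESULTS / "overrepresentation.tsv", sep="\t", index=False
    )


if __name__ == "__main__":
    main()
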