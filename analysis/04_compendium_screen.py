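#!/usr/bin/env python
"""Compendium screen in both species, shared sets, representation.

Screens the 200-set compendium against each species' ranked list (1,000
gene-set permutations per set), intersects the positively enriched sets at
FDR < 0.01, and counts how often each gene appears in the shared sets'
leading edges in either species (Spearman-scored). Full GSEA tables go to
scratch/benchmark/; shared sets and the representation table to results/.
"""

from pathlib import Path

from xsmono import cross_species, gsea, io_formats

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "benchmark"
RESULTS = ROOT / "results"
SEEDS = {"mouse": 202, "human": 303}


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    omap = io_formats.read_ortholog_map(DATA / "orthologs.tsv")
    compendium = io_formats.read_gmt(DATA / "compendium.gmt")
    mouse_comp, _ = cross_species.translate_collection(
        compendium, omap.inverse(), fallback=str.title
    )
    common = sorted(set(mouse_comp.names()) & set(compendium.names()))
    results = {}
    for species, coll in (("mouse", mouse_comp.subset(common)),
                          ("human", compendium.subset(common))):
        ranked = io_formats.read_rnk(DATA / f"ranked_{species}.rnk")
        res = gsea.gsea_test(ranked, coll, scheme="gene_set", n_perm=1000,
                             seed=SEEDS[species])
        results[species] = res
        gsea.results_table(res).to_csv(DATA / f"gsea_{species}.tsv", sep="\t", index=False)
        n_sig = sum(1 for r in res if r.es > 0 and r.fdr_q < 0.01)
        print(f"{species}: {n_sig}/{len(res)} sets positively enriched at FDR<0.01")

    shared = cross_species.shared_enriched_sets(results["mouse"], results["human"], q_max=0.01)
    (RESULTS / "shared_sets.tsv").write_text(
        "set\n" + "".join(s + "\n" for s in shared), encoding="utf-8"
    )
    print(f"{len(shared)} sets enriched in both species")

    rep_table, (rho, r2, p) = cross_species.leading_edge_representation(
        shared, results["mouse"], results["human"], omap
    )
    rep_table.to_csv(RESULTS / "representation.tsv", sep="\t", index=False)
    print(f"leading-edge representation over {len(rep_table)} genes: "
          f"rho={rho:.3f} (r^2={r2:.3f}, p={p:.2g})")
    print(f"most represented (human): {', '.join(rep_table['gene'].head(5))}")


if __name__ == "__main__":
    main()
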