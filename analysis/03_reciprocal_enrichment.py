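#!/usr/bin/env python
"""Reciprocal cross-species signature enrichment.

Tests the mouse top-200 up-signature (ortholog-translated) against the
human ranked list and vice versa, with 10,000 gene-set permutations per
direction. A conserved response shows positive enrichment with small p in
both directions.
"""

import json
from pathlib import Path

from xsmono import cross_species, diffexp, io_formats

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "benchmark"
RESULTS = ROOT / "results"
SEED = 101


def main() -> None:
    ranked = {s: io_formats.read_rnk(DATA / f"ranked_{s}.rnk") for s in ("mouse", "human")}
    sigs = {
        s: diffexp.GeneSignature(
            (DATA / f"signature_{s}.txt").read_text(encoding="utf-8").split(), source_species=s
        )
        for s in ("mouse", "human")
    }
    omap = io_formats.read_ortholog_map(DATA / "orthologs.tsv")
    recip = cross_species.reciprocal_enrichment(
        sigs["mouse"], ranked["human"], sigs["human"], ranked["mouse"],
        omap, n_perm=10_000, seed=SEED,
    )
    block = {
        direction: {"es": r.es, "nes": r.nes, "p": r.p_value,
                    "leading_edge_size": len(r.leading_edge), "size": r.size}
        for direction, r in (
            ("mouse_in_human", recip.mouse_in_human),
            ("human_in_mouse", recip.human_in_mouse),
        )
    }
    block["mapping_stats"] = recip.mapping_stats
    block["seed"] = SEED
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "reciprocal.json").write_text(json.dumps(block, indent=2, sort_keys=True) + "\n",
                                             encoding="utf-8")
    for d in ("mouse_in_human", "human_in_mouse"):
        print(f"{d}: ES={block[d]['es']:.3f}, NES={block[d]['nes']:.2f}, p={block[d]['p']:.2g}")
    print("conserved up-regulation" if recip.significant(0.001) else "no conserved signal")


if __name__ == "__main__":
    main()
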