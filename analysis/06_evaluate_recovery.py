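#!/usr/bin/env python
"""Score every pipeline stage against the planted truth.

Compares the signatures, shared-set screen and leading edges produced by
scripts 02-05 with the modules and loaded sets planted by script 01, and
writes the recovery metrics table.
"""

import json
from pathlib import Path

import pandas as pd

from xsmono import diffexp, simulate
from xsmono.diffexp import GeneSignature

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "benchmark"
RESULTS = ROOT / "results"


def main() -> None:
    raw = json.loads((DATA / "truth.json").read_text(encoding="utf-8"))
    truth = simulate.SyntheticTruth(
        conserved_pairs=[tuple(p) for p in raw["conserved_pairs"]],
        mouse_specific=raw["mouse_specific"],
        human_specific=raw["human_specific"],
        loaded_set_names=raw["loaded_set_names"],
        random_set_names=raw["random_set_names"],
        module_term_names=[], mouse_effects={}, human_effects={},
    )
    sigs = {
        s: GeneSignature((DATA / f"signature_{s}.txt").read_text().split(), source_species=s)
        for s in ("mouse", "human")
    }
    shared = pd.read_csv(RESULTS / "shared_sets.tsv", sep="\t")["set"].tolist()
    rep = pd.read_csv(RESULTS / "representation.tsv", sep="\t")
    rho, _, _ = diffexp.spearman_r2(rep["count_human"], rep["count_mouse"])
    gsea_h = pd.read_csv(DATA / "gsea_human.tsv", sep="\t")
    le_genes = sorted(
        {g for _, row in gsea_h.iterrows() if row["set"] in set(shared)
         for g in str(row["leading_edge"]).split(",")}
    )
    metrics = simulate.evaluate_recovery(
        truth, mouse_signature=sigs["mouse"], human_signature=sigs["human"],
        shared_sets=shared, leading_edge_genes=le_genes, representation_rho=rho,
    )
    with open(RESULTS / "recovery.tsv", "w", encoding="utf-8") as fh:
        fh.write("metric\tvalue\n")
        for key in sorted(metrics):
            fh.write(f"{key}\t{metrics[key]:.6g}\n")
            print(f"{key}: {metrics[key]:.3g}")


if __name__ == "__main__":
    main()
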