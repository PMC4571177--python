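#!/usr/bin/env python
"""Per-species differential expression, ranking and 200-gene signatures.

Reads the benchmark cohorts, runs the pooled t-test per gene, counts
significant genes under both threshold profiles (FC>1.5/p<0.05 and
FC>2/p<0.01), and writes the signal-to-noise ranked lists plus the top-200
up-signatures used by every later stage. Full DE tables and RNK files go to
scratch/benchmark/; the count summary to results/.
"""

from pathlib import Path

from xsmono import diffexp, io_formats

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "benchmark"
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = ["species\tprofile\tfc_min\tp_max\tn_up\tn_down"]
    for species in ("mouse", "human"):
        matrix = io_formats.read_expression_matrix(
            DATA / f"{species}_matrix.tsv", DATA / f"{species}_groups.tsv"
        )
        table = diffexp.de_test(matrix)
        table.to_csv(DATA / f"de_{species}.tsv", sep="\t")
        for profile, (fc_min, p_max) in diffexp.DE_PROFILES.items():
            up, down = diffexp.de_filter(table, fc_min, p_max)
            rows.append(f"{species}\t{profile}\t{fc_min}\t{p_max}\t{len(up)}\t{len(down)}")
            print(f"{species} [{profile}] FC>{fc_min}, p<{p_max}: {len(up)} up, {len(down)} down")
        ranked = diffexp.rank_genes(matrix)
        io_formats.write_rnk(ranked, DATA / f"ranked_{species}.rnk")
        signature = diffexp.select_signature(ranked, 200, source_species=species)
        (DATA / f"signature_{species}.txt").write_text(
            "\n".join(signature.genes) + "\n", encoding="utf-8"
        )
    (RESULTS / "de_counts.tsv").write_text("\n".join(rows) + "\n", encoding="utf-8")
    print(f"summary -> {RESULTS / 'de_counts.tsv'}")


if __name__ == "__main__":
    main()
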