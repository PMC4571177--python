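"""Config-driven orchestration of the full cross-species analysis.

Stages: simulate (or load inputs) -> differential expression and ranking in
each species -> top-n up-signatures -> reciprocal signature enrichment ->
compendium screen in both species -> shared enriched sets -> leading-edge
representation -> occurrence matrix -> metagene clustering -> per-cluster
over-representation -> JSON summary. Every intermediate artifact is written
in the formats of :mod:`xsmono.io_formats`; the summary is byte-identical
across reruns of the same config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import cross_species, diffexp, gsea, io_formats, metagenes, simulate

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs, loadable from a single YAML file.

    Either ``simulate`` (a :class:`~xsmono.simulate.SyntheticConfig`
    parameter block) or ``inputs`` (paths to on-disk artifacts) must be
    given. Thresholds default to the study's named values: 200-gene
    signatures, compendium significance at FDR < 0.25, leading-edge screen
    at FDR < 0.01, "figure3" DE profile (FC > 2, p < 0.01), two metagenes.
    """

    out_dir: str
    seed: int = 0
    simulate: dict | None = None
    inputs: dict | None = None
    de_profile: str = "figure3"
    metric: str = "signal_to_noise"
    signature_n: int = 200
    ortholog_policy: str = "table_only"
    exponent: float = 1.0
    reciprocal_n_perm: int = 10_000
    compendium_n_perm: int = 1000
    compendium_scheme: str = "gene_set"
    compendium_fdr: float = 0.25
    leading_edge_fdr: float = 0.01
    cluster_k: int = 2
    cluster_linkage: str = "average"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("config needs exactly one of 'simulate' or 'inputs'")
        if self.de_profile not in diffexp.DE_PROFILES:
            raise ValueError(f"unknown de_profile {self.de_profile!r}")
        if self.inputs is not None:
            required = ["mouse_matrix", "mouse_groups", "human_matrix", "human_groups",
                        "gmt", "ortholog_map"]
            for key in required:
                if key not in self.inputs:
                    raise ValueError(f"inputs block missing {key!r}")
                if not Path(self.inputs[key]).exists():
                    raise ValueError(f"input file not found: {key} = {self.inputs[key]}")
            if "annotation_gmt" in self.inputs and not Path(self.inputs["annotation_gmt"]).exists():
                raise ValueError(f"input file not found: annotation_gmt")


def _load_inputs(cfg: PipelineConfig):
    inp = cfg.inputs
    mouse = io_formats.read_expression_matrix(inp["mouse_matrix"], inp["mouse_groups"])
    human = io_formats.read_expression_matrix(inp["human_matrix"], inp["human_groups"])
    compendium = io_formats.read_gmt(inp["gmt"])
    omap = io_formats.read_ortholog_map(inp["ortholog_map"])
    annotation = io_formats.read_gmt(inp["annotation_gmt"]) if "annotation_gmt" in inp else None
    return mouse, human, compendium, omap, annotation, None


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage, writing artifacts and ``summary.json`` to
    ``config.out_dir``; returns that directory. Per-stage seeds are derived
    deterministically from ``config.seed``."""
    cfg = config
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_record = dataclasses.asdict(cfg)
    cfg_record.pop("out_dir")  # run location is not part of the analysis
    summary: dict = {"seed": cfg.seed, "config": cfg_record}

    def stage(name):
        def wrap(fn, *args, **kw):
            try:
                return fn(*args, **kw)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrap

    # --- stage 1: inputs -------------------------------------------------
    truth = None
    if cfg.simulate is not None:
        sim_params = dict(cfg.simulate)
        sim_params.setdefault("seed", cfg.seed)
        scfg = simulate.SyntheticConfig(**sim_params)
        study = stage("simulate")(simulate.simulate_two_species, scfg)
        mouse, human = study.mouse, study.human
        compendium, omap, annotation = study.compendium, study.orthologs, study.annotation
        truth = study.truth
        io_formats.write_expression_matrix(mouse, out / "mouse_matrix.tsv", out / "mouse_groups.tsv")
        io_formats.write_expression_matrix(human, out / "human_matrix.tsv", out / "human_groups.tsv")
        io_formats.write_gmt(compendium, out / "compendium.gmt")
        io_formats.write_gmt(annotation, out / "annotation.gmt")
        io_formats.write_ortholog_map(omap, out / "orthologs.tsv")
        summary["simulate"] = {
            "n_genes": scfg.n_genes,
            "mouse_samples": mouse.n_samples,
            "human_samples": human.n_samples,
            "n_sets": len(compendium),
            "conserved_module_size": scfg.conserved_module_size,
        }
    else:
        mouse, human, compendium, omap, annotation, truth = stage("load_inputs")(_load_inputs, cfg)
        summary["inputs"] = {k: str(v) for k, v in cfg.inputs.items()}

    # --- stage 2: differential expression --------------------------------
    fc_min, p_max = diffexp.DE_PROFILES[cfg.de_profile]
    de_block = {}
    tables = {}
    for name, matrix in (("mouse", mouse), ("human", human)):
        table = stage("de_test")(diffexp.de_test, matrix)
        tables[name] = table
        up, down = diffexp.de_filter(table, fc_min, p_max)
        table.to_csv(out / f"de_{name}.tsv", sep="\t")
        de_block[name] = {"profile": cfg.de_profile, "n_up": len(up), "n_down": len(down),
                          "n_genes": len(table)}
        log.info("DE %s: %d up / %d down of %d genes (%s)", name, len(up), len(down),
                 len(table), cfg.de_profile)
    summary["differential_expression"] = de_block

    # --- stage 3: ranking and signatures ---------------------------------
    ranked = {}
    signatures = {}
    for name, matrix in (("mouse", mouse), ("human", human)):
        rl = stage("rank_genes")(diffexp.rank_genes, matrix, cfg.metric)
        ranked[name] = rl
        io_formats.write_rnk(rl, out / f"ranked_{name}.rnk")
        signatures[name] = diffexp.select_signature(rl, cfg.signature_n, source_species=name)
        (out / f"signature_{name}.txt").write_text(
            "\n".join(signatures[name].genes) + "\n", encoding="utf-8"
        )
    summary["signatures"] = {
        "n": cfg.signature_n,
        "metric": cfg.metric,
        "mouse_top5": signatures["mouse"].genes[:5],
        "human_top5": signatures["human"].genes[:5],
    }

    # --- stage 4: reciprocal enrichment ----------------------------------
    recip = stage("reciprocal_enrichment")(
        cross_species.reciprocal_enrichment,
        signatures["mouse"], ranked["human"], signatures["human"], ranked["mouse"],
        omap, policy=cfg.ortholog_policy, n_perm=cfg.reciprocal_n_perm,
        seed=cfg.seed + 11, exponent=cfg.exponent,
    )
    recip_block = {
        direction: {"es": r.es, "nes": r.nes, "p": r.p_value, "q": r.fdr_q, "size": r.size}
        for direction, r in (
            ("mouse_in_human", recip.mouse_in_human),
            ("human_in_mouse", recip.human_in_mouse),
        )
    }
    recip_block["mapping_stats"] = recip.mapping_stats
    recip_block["significant_0.05"] = recip.significant(0.05)
    (out / "reciprocal.json").write_text(
        json.dumps(recip_block, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    summary["reciprocal_enrichment"] = recip_block

    # --- stage 5: compendium screen + shared sets ------------------------
    mouse_compendium, _ = cross_species.translate_collection(
        compendium, omap.inverse(), policy=cfg.ortholog_policy, fallback=str.title
    )
    common = sorted(set(mouse_compendium.names()) & set(compendium.names()))
    results = {}
    for name, rl, coll, offset in (
        ("mouse", ranked["mouse"], mouse_compendium.subset(common), 23),
        ("human", ranked["human"], compendium.subset(common), 29),
    ):
        res = stage("compendium_screen")(
            gsea.gsea_test, rl, coll, scheme=cfg.compendium_scheme,
            n_perm=cfg.compendium_n_perm, seed=cfg.seed + offset, exponent=cfg.exponent,
        )
        results[name] = res
        gsea.results_table(res).to_csv(out / f"gsea_{name}.tsv", sep="\t", index=False)
    shared = stage("shared_enriched_sets")(
        cross_species.shared_enriched_sets,
        results["mouse"], results["human"], q_max=cfg.leading_edge_fdr,
    )
    (out / "shared_sets.tsv").write_text(
        "set\n" + "".join(s + "\n" for s in shared), encoding="utf-8"
    )
    sig_at_025 = {
        name: sum(1 for r in res if r.es > 0 and r.fdr_q < cfg.compendium_fdr)
        for name, res in results.items()
    }
    summary["compendium_screen"] = {
        "n_sets_tested": len(common),
        "n_perm": cfg.compendium_n_perm,
        "significant_fdr_0.25": sig_at_025,
        "shared_fdr_threshold": cfg.leading_edge_fdr,
        "n_shared": len(shared),
    }

    # --- stage 6: leading-edge representation ----------------------------
    if len(shared) > 0:
        rep_table, (rho, r2, rep_p) = stage("leading_edge_representation")(
            cross_species.leading_edge_representation,
            shared, results["mouse"], results["human"], omap, policy=cfg.ortholog_policy,
        )
        rep_table.to_csv(out / "representation.tsv", sep="\t", index=False)
        summary["representation"] = {
            "n_genes": int(len(rep_table)),
            "spearman_rho": rho,
            "r_squared": r2,
            "p": rep_p,
            "top5_human": rep_table["gene"].head(5).tolist(),
        }
    else:
        summary["representation"] = {"n_genes": 0}

    # --- stage 7: metagenes + over-representation ------------------------
    mouse_sig_results = [r for r in results["mouse"] if r.fdr_q < cfg.leading_edge_fdr]
    if mouse_sig_results:
        occ = metagenes.occurrence_matrix(results["mouse"], q_max=cfg.leading_edge_fdr)
        occ.to_csv(out / "occurrence_mouse.tsv", sep="\t")
        clusters = metagenes.cluster_metagenes(occ, linkage=cfg.cluster_linkage, k=cfg.cluster_k)
        with open(out / "clusters.tsv", "w", encoding="utf-8") as fh:
            fh.write("gene\tcluster\n")
            for i, cl in enumerate(clusters.clusters):
                for g in cl:
                    fh.write(f"{g}\t{i}\n")
        meta_block = {"k": cfg.cluster_k, "cluster_sizes": [len(c) for c in clusters.clusters]}
        if annotation is not None:
            # universe = every gene on the (mouse) platform, in human space
            universe_mapped, _ = cross_species.map_orthologs(
                mouse.gene_ids, omap, policy=cfg.ortholog_policy
            )
            universe = sorted(set(universe_mapped))
            over_rows = []
            top_terms = {}
            for i, cl in enumerate(clusters.clusters):
                mapped, _ = cross_species.map_orthologs(cl, omap, policy=cfg.ortholog_policy)
                mapped = sorted(set(mapped) & set(universe))
                if len(mapped) == 0:
                    continue
                res = metagenes.overrepresentation(mapped, annotation, universe)
                res.insert(0, "cluster", i)
                over_rows.append(res)
                top_terms[str(i)] = res.iloc[0]["term"]
            if over_rows:
                import pandas as pd

                pd.concat(over_rows, ignore_index=True).to_csv(
                    out / "overrepresentation.tsv", sep="\t", index=False
                )
                meta_block["top_terms"] = top_terms
        summary["metagenes"] = meta_block
    else:
        summary["metagenes"] = {"k": cfg.cluster_k, "cluster_sizes": []}

    # --- stage 8: recovery vs planted truth ------------------------------
    if truth is not None:
        le_genes = sorted(
            {g for name in shared for g in
             next(r for r in results["human"] if r.set_name == name).leading_edge}
        )
        metrics = simulate.evaluate_recovery(
            truth,
            mouse_signature=signatures["mouse"],
            human_signature=signatures["human"],
            shared_sets=shared,
            leading_edge_genes=le_genes,
            representation_rho=summary["representation"].get("spearman_rho"),
        )
        with open(out / "recovery.tsv", "w", encoding="utf-8") as fh:
            fh.write("metric\tvalue\n")
            for key in sorted(metrics):
                fh.write(f"{key}\t{metrics[key]:.6g}\n")
        summary["recovery"] = {k: metrics[k] for k in sorted(metrics)}

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=str) + "\n", encoding="utf-8"
    )
    return out
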