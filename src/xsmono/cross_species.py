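"""Cross-species conservation analysis.

Translates gene signatures through an ortholog table, tests each species'
up-regulated signature for enrichment in the other species' ranked list
(reciprocal enrichment), screens a shared gene-set compendium in both
species to find sets enriched in both, and compares how often each gene
appears in the leading edges of those shared sets (representation), scored
by Spearman correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexp import GeneSignature, spearman_r2
from .gsea import GseaResult, gsea_test
from .io_formats import GeneSetCollection, OrthologMap, RankedList

__all__ = [
    "ReciprocalEnrichment",
    "map_orthologs",
    "translate_collection",
    "reciprocal_enrichment",
    "shared_enriched_sets",
    "leading_edge_representation",
]

log = logging.getLogger(__name__)

POLICIES = ("table_only", "table_then_casefold")


def map_orthologs(
    genes,
    omap: OrthologMap,
    policy: str = "table_only",
    fallback=str.upper,
) -> tuple[list[str], list[str]]:
    """Order-preserving translation of gene symbols through an ortholog table.

    Under ``table_then_casefold`` a symbol absent from the table is
    translated by ``fallback`` (uppercase by default — the mouse->human
    symbol convention; pass ``str.title`` for the reverse direction). Two
    sources collapsing onto one target keep the first occurrence and log
    the collision. Returns (mapped, unmapped); unmapped symbols are
    reported, never silently dropped.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; choose from {POLICIES}")
    mapped: list[str] = []
    unmapped: list[str] = []
    seen: dict[str, str] = {}
    for g in genes:
        target = omap.get(g)
        if target is None and policy == "table_then_casefold":
            target = fallback(g)
        if target is None:
            unmapped.append(g)
            continue
        if target in seen:
            log.warning("ortholog collision: %r and %r both map to %r; keeping first",
                        seen[target], g, target)
            continue
        seen[target] = g
        mapped.append(target)
    return mapped, unmapped


def translate_collection(
    collection: GeneSetCollection,
    omap: OrthologMap,
    policy: str = "table_only",
    fallback=str.upper,
) -> tuple[GeneSetCollection, dict[str, dict[str, int]]]:
    """Translate every set of a collection into the target symbol space.

    Sets whose members are entirely untranslatable are dropped. Returns the
    translated collection and per-set counts of mapped/unmapped members.
    """
    sets: dict[str, tuple[str, list[str]]] = {}
    stats: dict[str, dict[str, int]] = {}
    for name in collection.names():
        mapped, unmapped = map_orthologs(collection.genes(name), omap, policy, fallback)
        stats[name] = {"mapped": len(mapped), "unmapped": len(unmapped)}
        if mapped:
            sets[name] = (collection.description(name), mapped)
    return GeneSetCollection(sets), stats


@dataclass
class ReciprocalEnrichment:
    """Both directions of the cross-species signature test."""

    mouse_in_human: GseaResult
    human_in_mouse: GseaResult
    mapping_stats: dict[str, int] = field(default_factory=dict)

    def significant(self, alpha: float = 0.05) -> bool:
        """Conserved up-regulation: positive enrichment at ``alpha`` in both
        directions."""
        return all(
            r.es > 0 and r.p_value <= alpha for r in (self.mouse_in_human, self.human_in_mouse)
        )


def _one_direction(
    signature: GeneSignature,
    ranked: RankedList,
    omap: OrthologMap,
    policy: str,
    fallback,
    name: str,
    n_perm: int,
    seed,
    exponent: float,
) -> tuple[GseaResult, dict[str, int]]:
    mapped, unmapped = map_orthologs(signature.genes, omap, policy, fallback)
    if len(mapped) < 0.5 * len(signature):
        raise ValueError(
            f"only {len(mapped)}/{len(signature)} signature genes mappable; "
            "provide a more complete ortholog table"
        )
    present = [g for g in mapped if g in set(ranked.genes)]
    collection = GeneSetCollection.from_dict({name: present or mapped}, "cross-species signature")
    (result,) = gsea_test(
        ranked, collection, scheme="gene_set", n_perm=n_perm, seed=seed, exponent=exponent
    )
    stats = {
        "signature_size": len(signature),
        "mapped": len(mapped),
        "unmapped": len(unmapped),
        "present_in_target": len(present),
    }
    return result, stats


def reciprocal_enrichment(
    sig_mouse: GeneSignature,
    ranked_human: RankedList,
    sig_human: GeneSignature,
    ranked_mouse: RankedList,
    omap: OrthologMap,
    policy: str = "table_only",
    n_perm: int = 10_000,
    seed: int | None = None,
    exponent: float = 1.0,
) -> ReciprocalEnrichment:
    """Test each species' up-signature in the other species' ranked list.

    ``omap`` maps mouse symbols to human; the reverse direction uses its
    inverse (title-case fallback under the casefold policy). The signature
    is a single fixed gene set, so significance uses gene-set permutation.
    """
    m2h, m2h_stats = _one_direction(
        sig_mouse, ranked_human, omap, policy, str.upper,
        "MOUSE_UP_SIGNATURE", n_perm, seed, exponent,
    )
    h2m, h2m_stats = _one_direction(
        sig_human, ranked_mouse, omap.inverse(), policy, str.title,
        "HUMAN_UP_SIGNATURE", n_perm, None if seed is None else seed + 1, exponent,
    )
    stats = {f"mouse_in_human_{k}": v for k, v in m2h_stats.items()}
    stats.update({f"human_in_mouse_{k}": v for k, v in h2m_stats.items()})
    return ReciprocalEnrichment(mouse_in_human=m2h, human_in_mouse=h2m, mapping_stats=stats)


def shared_enriched_sets(
    results_mouse: list[GseaResult],
    results_human: list[GseaResult],
    q_max: float = 0.01,
) -> list[str]:
    """Names of sets positively enriched (es > 0, fdr_q < q_max) in both
    species, in lexicographic order.

    Both result lists must cover the same collection; a set present in only
    one is an error (screen both species against the same translated
    compendium first).
    """
    by_m = {r.set_name: r for r in results_mouse}
    by_h = {r.set_name: r for r in results_human}
    if set(by_m) != set(by_h):
        only = sorted(set(by_m).symmetric_difference(by_h))
        raise ValueError(f"result collections mismatch; e.g. {only[:5]}")
    shared = [
        name
        for name in sorted(by_m)
        if by_m[name].es > 0 and by_m[name].fdr_q < q_max
        and by_h[name].es > 0 and by_h[name].fdr_q < q_max
    ]
    return shared


def leading_edge_representation(
    shared: list[str],
    results_mouse: list[GseaResult],
    results_human: list[GseaResult],
    omap: OrthologMap,
    policy: str = "table_only",
) -> tuple[pd.DataFrame, tuple[float, float, float]]:
    """Per-gene leading-edge occurrence counts over the shared enriched sets.

    Counts live in the human symbol space (mouse leading edges are
    translated; untranslatable genes fall back per policy or are dropped
    with a log entry). The table is ranked from most to least represented
    in the human data (ties by ascending symbol). Spearman rho/r2/p are
    computed over the union of represented genes, zero-filling a gene's
    count in the species where it never appears, so divergence counts
    against the correlation as much as conservation counts for it.
    """
    by_m = {r.set_name: r for r in results_mouse}
    by_h = {r.set_name: r for r in results_human}
    counts_h: dict[str, int] = {}
    counts_m: dict[str, int] = {}
    for name in shared:
        for g in set(by_h[name].leading_edge):
            counts_h[g] = counts_h.get(g, 0) + 1
        mapped, unmapped = map_orthologs(sorted(set(by_m[name].leading_edge)), omap, policy)
        if unmapped:
            log.info("set %s: %d leading-edge genes untranslatable", name, len(unmapped))
        for g in mapped:
            counts_m[g] = counts_m.get(g, 0) + 1
    union = sorted(set(counts_h) | set(counts_m))
    if len(union) < 3:
        raise ValueError("correlation undefined: fewer than 3 represented genes")
    table = pd.DataFrame(
        {
            "gene": union,
            "count_human": [counts_h.get(g, 0) for g in union],
            "count_mouse": [counts_m.get(g, 0) for g in union],
        }
    ).sort_values(["count_human", "gene"], ascending=[False, True], ignore_index=True)
    rho, r2, p = spearman_r2(table["count_human"].to_numpy(), table["count_mouse"].to_numpy())
    return table, (rho, r2, p)
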