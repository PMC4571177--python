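"""Readers and writers for every on-disk artifact the pipeline touches.

Formats
-------
- expression TSV: genes x samples, header row of sample ids, first column
  gene symbols (first header cell ignored)
- groups TSV: header ``sample<TAB>group``, one row per sample, exactly two
  distinct group labels
- GMT (Broad dialect): ``name<TAB>description<TAB>gene<TAB>gene...``
- RNK: two columns, gene symbol and numeric score
- ortholog TSV: two columns, source symbol and target symbol

All files are tab-separated UTF-8 with "." decimals and no quoting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "OrthologMap",
    "RankedList",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_groups",
    "write_groups",
    "read_gmt",
    "write_gmt",
    "read_rnk",
    "write_rnk",
    "read_ortholog_map",
    "write_ortholog_map",
    "collapse_duplicates",
]

#: group labels conventionally naming the perturbed/treatment condition,
#: used when the caller does not name the treatment group explicitly
_TREATMENT_ALIASES = frozenset({"ami", "mi", "case", "treated", "treatment", "disease"})


@dataclass
class ExpressionMatrix:
    """Dense log2 expression grid (genes x samples) with a two-group design.

    Parameters
    ----------
    gene_ids : list of str
        Unique gene symbols, one per row.
    sample_ids : list of str
        Unique sample identifiers, one per column.
    values : ndarray of shape (n_genes, n_samples)
        Finite log2 intensities.
    groups : dict
        Maps every sample id to one of exactly two group labels.
    treatment : str, optional
        Which of the two labels is the perturbed condition. If omitted it
        is inferred from a small alias list ("ami", "case", ...); an
        unrecognisable design raises.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    groups: dict[str, str]
    treatment: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_ids; collapse them first (max-mean rule)")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_ids")
        if not np.all(np.isfinite(self.values)):
            g, s = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at gene {self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
            )
        missing = [s for s in self.sample_ids if s not in self.groups]
        if missing:
            raise ValueError(f"sample {missing[0]!r} missing from groups file")
        labels = sorted({self.groups[s] for s in self.sample_ids})
        if len(labels) != 2:
            raise ValueError(f"exactly two groups required, found {len(labels)}: {labels}")
        counts = {lab: sum(self.groups[s] == lab for s in self.sample_ids) for lab in labels}
        for lab, n in counts.items():
            if n < 2:
                raise ValueError(f"group {lab!r} has {n} sample(s); at least 2 required")
        if self.treatment is None:
            hits = [lab for lab in labels if lab.casefold() in _TREATMENT_ALIASES]
            if len(hits) != 1:
                raise ValueError(
                    f"cannot infer treatment group from labels {labels}; pass treatment="
                )
            self.treatment = hits[0]
        elif self.treatment not in labels:
            raise ValueError(f"treatment label {self.treatment!r} not among groups {labels}")

    @property
    def control(self) -> str:
        """The non-treatment group label."""
        labels = {self.groups[s] for s in self.sample_ids}
        (other,) = labels - {self.treatment}
        return other

    def group_columns(self, label: str) -> np.ndarray:
        """Column indices of the samples carrying ``label``."""
        return np.array(
            [i for i, s in enumerate(self.sample_ids) if self.groups[s] == label], dtype=int
        )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class GeneSetCollection:
    """Named gene sets with free-text descriptions (the GMT payload)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, genes) in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def genes(self, name: str) -> list[str]:
        return list(self.sets[name][1])

    def description(self, name: str) -> str:
        return self.sets[name][0]

    def subset(self, names) -> "GeneSetCollection":
        return GeneSetCollection({n: self.sets[n] for n in names})

    @classmethod
    def from_dict(cls, mapping: dict[str, list[str]], description: str = "") -> "GeneSetCollection":
        return cls({name: (description, list(genes)) for name, genes in mapping.items()})


@dataclass
class OrthologMap:
    """One-way gene-symbol translation table (e.g. mouse -> human).

    The mapping is a function: each source symbol has exactly one target.
    """

    pairs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for src, dst in self.pairs.items():
            if not src or not dst:
                raise ValueError("empty symbol in ortholog map")

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.pairs

    def get(self, symbol: str):
        return self.pairs.get(symbol)

    def inverse(self) -> "OrthologMap":
        """Target->source map; on collisions the first source wins (logged)."""
        inv: dict[str, str] = {}
        for src, dst in self.pairs.items():
            if dst in inv:
                warnings.warn(
                    f"ortholog inverse collision on {dst!r}: keeping {inv[dst]!r}, dropping {src!r}"
                )
                continue
            inv[dst] = src
        return OrthologMap(inv)


@dataclass
class RankedList:
    """Genes ordered by a differential metric, the substrate of enrichment.

    Scores are non-increasing; ties are broken by ascending lexicographic
    symbol so output is deterministic across platforms.
    """

    genes: list[str]
    scores: np.ndarray
    metric_name: str = "score"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != self.scores.size:
            raise ValueError("genes and scores differ in length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene symbols in ranked list")
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("scores must be non-increasing; use RankedList.from_scores")

    @classmethod
    def from_scores(cls, genes, scores, metric_name: str = "score") -> "RankedList":
        """Sort descending by score, ties by ascending symbol."""
        genes = list(genes)
        scores = np.asarray(scores, dtype=float)
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate gene symbols in ranked list")
        order = np.lexsort((np.asarray(genes, dtype=object), -scores))
        return cls([genes[i] for i in order], scores[order], metric_name)

    def __len__(self) -> int:
        return len(self.genes)

    def position(self) -> dict[str, int]:
        """Map gene -> 0-based rank position."""
        return {g: i for i, g in enumerate(self.genes)}


# ---------------------------------------------------------------------------
# expression matrices


def collapse_duplicates(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate gene symbols keeping the row with the highest mean.

    Standard max-mean probe collapse for array data; idempotent. Row order
    of the surviving rows is preserved.
    """
    if df.index.is_unique:
        return df
    means = df.mean(axis=1).to_numpy()
    keep = np.ones(len(df), dtype=bool)
    best: dict[str, int] = {}
    for i, sym in enumerate(df.index):
        j = best.get(sym)
        if j is None:
            best[sym] = i
        elif means[i] > means[j]:
            keep[j] = False
            best[sym] = i
        else:
            keep[i] = False
    return df.loc[keep]


def read_groups(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample", "group"]:
        raise ValueError(f"groups file must have header 'sample<TAB>group', got {list(df.columns)}")
    if df["sample"].duplicated().any():
        dup = df["sample"][df["sample"].duplicated()].iloc[0]
        raise ValueError(f"sample {dup!r} listed twice in groups file")
    return dict(zip(df["sample"], df["group"]))


def write_groups(groups: dict[str, str], path) -> None:
    pd.DataFrame({"sample": list(groups), "group": list(groups.values())}).to_csv(
        path, sep="\t", index=False
    )


def read_expression_matrix(path, groups_path, treatment: str | None = None) -> ExpressionMatrix:
    """Load a genes x samples TSV plus its two-group sample annotation.

    Duplicate gene symbols are collapsed by the max-mean rule; any
    non-numeric cell raises with its row/column coordinates.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    num = raw.apply(pd.to_numeric, errors="coerce")
    bad = num.isna()
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at gene {raw.index[g]!r}, sample {raw.columns[s]!r}: "
            f"{raw.iloc[g, s]!r}"
        )
    num = collapse_duplicates(num)
    groups = read_groups(groups_path)
    missing = [s for s in num.columns if s not in groups]
    if missing:
        raise ValueError(f"sample {missing[0]!r} missing from groups file")
    return ExpressionMatrix(
        gene_ids=list(num.index),
        sample_ids=list(num.columns),
        values=num.to_numpy(dtype=float),
        groups={s: groups[s] for s in num.columns},
        treatment=treatment,
    )


def write_expression_matrix(matrix: ExpressionMatrix, path, groups_path=None) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.gene_ids, columns=matrix.sample_ids)
    df.index.name = "gene"
    df.to_csv(path, sep="\t")
    if groups_path is not None:
        write_groups({s: matrix.groups[s] for s in matrix.sample_ids}, groups_path)


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: expected >=3 tab-separated fields")
            name, desc, *genes = fields
            if name in sets:
                raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
            seen: list[str] = []
            for g in genes:
                if g and g not in seen:
                    seen.append(g)
            if not seen:
                raise ValueError(f"GMT line {lineno}: set {name!r} has no genes")
            sets[name] = (desc, seen)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, (desc, genes) in collection.sets.items():
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# RNK


def read_rnk(path, metric_name: str = "score") -> RankedList:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] != 2:
        raise ValueError(f"RNK file must have exactly 2 columns, got {df.shape[1]}")
    genes = df[0].tolist()
    if len(set(genes)) != len(genes):
        dup = df[0][df[0].duplicated()].iloc[0]
        raise ValueError(f"duplicate symbol {dup!r} in RNK file")
    scores = []
    for i, raw in enumerate(df[1]):
        try:
            scores.append(float(raw))  # exact round-trip parse
        except (TypeError, ValueError):
            raise ValueError(f"non-numeric score {raw!r} for gene {genes[i]!r}") from None
    return RankedList.from_scores(genes, np.array(scores), metric_name)


def write_rnk(ranked: RankedList, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g, s in zip(ranked.genes, ranked.scores):
            fh.write(f"{g}\t{s:.17g}\n")


# ---------------------------------------------------------------------------
# ortholog maps


def read_ortholog_map(path) -> OrthologMap:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"ortholog map must have exactly 2 columns, got {df.shape[1]}")
    pairs: dict[str, str] = {}
    for src, dst in zip(df[0], df[1]):
        if src in pairs and pairs[src] != dst:
            raise ValueError(f"conflicting targets for source symbol {src!r}")
        pairs[src] = dst
    return OrthologMap(pairs)


def write_ortholog_map(omap: OrthologMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for src, dst in omap.pairs.items():
            fh.write(f"{src}\t{dst}\n")
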