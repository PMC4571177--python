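"""Two-group differential expression, gene ranking and signatures.

Inputs are log2 intensities, so the fold change of a gene is
``2 ** (mean_treatment - mean_control)`` and the test is a pooled-variance
(Student) two-sample t by default, with Welch available behind a flag.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix, RankedList

__all__ = [
    "DE_PROFILES",
    "GeneSignature",
    "RankedList",
    "de_test",
    "de_filter",
    "rank_genes",
    "select_signature",
    "spearman_r2",
]

#: named (fold-change, p) threshold profiles: a permissive screen and the
#: stricter cut used for headline differential gene counts
DE_PROFILES: dict[str, tuple[float, float]] = {
    "methods": (1.5, 0.05),
    "figure3": (2.0, 0.01),
}

RANK_METRICS = ("signal_to_noise", "log2fc", "t_stat")


@dataclass
class GeneSignature:
    """Top-n most up-regulated genes of one condition, rank order preserved."""

    genes: list[str]
    source_species: str = ""
    direction: str = "up"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("empty signature forbidden")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature genes must be unique")

    def __len__(self) -> int:
        return len(self.genes)


def _group_arrays(matrix: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(control block, treatment block) of the expression grid."""
    c = matrix.values[:, matrix.group_columns(matrix.control)]
    t = matrix.values[:, matrix.group_columns(matrix.treatment)]
    return c, t


def de_test(matrix: ExpressionMatrix, equal_var: bool = True) -> pd.DataFrame:
    """Per-gene two-sample t-test of treatment vs control.

    Returns a DataFrame indexed by gene with columns ``log2fc`` (treatment
    mean minus control mean), ``fold_change`` (linear, ``2**log2fc``),
    ``t_stat``, ``p_value`` (two-tailed) and ``zero_variance`` (True where
    the pooled variance vanished and the statistic was set by convention:
    equal means -> t=0, p=1; unequal means -> p=0).
    """
    x1, x2 = _group_arrays(matrix)
    n1, n2 = x1.shape[1], x2.shape[1]
    if min(n1, n2) < 2:
        raise ValueError("each group needs at least 2 samples")
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1, v2 = x1.var(axis=1, ddof=1), x2.var(axis=1, ddof=1)
    diff = m2 - m1
    if equal_var:
        df = np.full_like(diff, n1 + n2 - 2)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    else:
        se2 = v1 / n1 + v2 / n2
        se = np.sqrt(se2)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)))
        df = np.where(np.isfinite(df), df, 1.0)
    degenerate = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, 0.0, diff / np.where(degenerate, 1.0, se))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    # zero pooled variance: equal means are an exact null, unequal means an
    # infinitely confident difference
    t = np.where(degenerate & (diff != 0), np.where(diff > 0, np.inf, -np.inf), t)
    p = np.where(degenerate, np.where(diff == 0, 1.0, 0.0), p)
    return pd.DataFrame(
        {
            "log2fc": diff,
            "fold_change": np.exp2(diff),
            "t_stat": t,
            "p_value": p,
            "zero_variance": degenerate,
        },
        index=pd.Index(matrix.gene_ids, name="gene"),
    )


def de_filter(
    table: pd.DataFrame, fc_min: float = 2.0, p_max: float = 0.01
) -> tuple[list[str], list[str]]:
    """Significant up- and down-regulated gene lists at strict thresholds.

    up: fold_change > fc_min and p < p_max; down: fold_change < 1/fc_min
    and p < p_max. Both inequalities are strict.
    """
    if not fc_min > 1:
        raise ValueError("fc_min must exceed 1 (linear fold change)")
    if not 0 < p_max <= 1:
        raise ValueError("p_max must lie in (0, 1]")
    sig = table["p_value"] < p_max
    up = table.index[sig & (table["fold_change"] > fc_min)].tolist()
    down = table.index[sig & (table["fold_change"] < 1.0 / fc_min)].tolist()
    return up, down


def signal_to_noise(
    matrix: ExpressionMatrix, sd_floor_frac: float = 0.2, sd_floor_abs: float = 0.2
) -> np.ndarray:
    """(mu_t - mu_c) / (sigma_c + sigma_t) with each sigma floored at
    max(sigma, sd_floor_frac*|mu|, sd_floor_abs), the established convention
    for this metric on array data; keeps constant genes finite."""
    x1, x2 = _group_arrays(matrix)
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    s1 = np.maximum.reduce([x1.std(axis=1, ddof=1), sd_floor_frac * np.abs(m1),
                            np.full_like(m1, sd_floor_abs)])
    s2 = np.maximum.reduce([x2.std(axis=1, ddof=1), sd_floor_frac * np.abs(m2),
                            np.full_like(m2, sd_floor_abs)])
    return (m2 - m1) / (s1 + s2)


def rank_genes(matrix: ExpressionMatrix, metric: str = "signal_to_noise") -> RankedList:
    """Rank all genes by a two-group differential metric, descending.

    Metrics: ``signal_to_noise`` (floored), ``log2fc``, ``t_stat``.
    Ties break by ascending symbol.
    """
    if metric == "signal_to_noise":
        scores = signal_to_noise(matrix)
    elif metric in ("log2fc", "t_stat"):
        table = de_test(matrix)
        scores = table[metric].to_numpy()
        scores = np.nan_to_num(scores, posinf=np.finfo(float).max, neginf=-np.finfo(float).max)
    else:
        raise ValueError(f"unknown metric {metric!r}; choose from {RANK_METRICS}")
    return RankedList.from_scores(matrix.gene_ids, scores, metric)


def select_signature(ranked: RankedList, n: int = 200, source_species: str = "") -> GeneSignature:
    """The first ``n`` genes of the ranked list, order preserved."""
    if not 0 < n <= len(ranked):
        raise ValueError(f"signature size {n} outside 1..{len(ranked)}")
    return GeneSignature(list(ranked.genes[:n]), source_species=source_species)


def _rank_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def spearman_r2(x, y) -> tuple[float, float, float]:
    """Spearman rho, its square (variance explained) and a two-tailed p.

    rho is the Pearson correlation of mid-ranks. The p-value uses the
    t-approximation for n >= 10 and exhaustive enumeration of all rank
    permutations for smaller n, where the approximation is poor.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors differ in length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _rank_rho(rx, ry)
    if n >= 10:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * stats.t.sf(abs(t), n - 2))
    else:
        target = abs(rho) - 1e-12
        hits = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if abs(_rank_rho(rx, ry[list(perm)])) >= target:
                hits += 1
        p = hits / total
    return rho, rho * rho, p
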