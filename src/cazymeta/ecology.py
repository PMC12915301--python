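"""Community-level summaries: richness partitions, diversity, dissimilarity,
correlations, habitat comparisons and expressing fractions.

Rank statistics go through scipy (Spearman with the t-approximation,
Mann-Whitney with exact enumeration for small groups); the diversity and
dissimilarity formulas are the standard ones (inverse Simpson 1/sum p^2,
Bray-Curtis sum|x-y| / sum(x+y)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import CazymeAnnotation

__all__ = [
    "SubstrateActivity",
    "richness_partition",
    "inverse_simpson",
    "bray_curtis",
    "spearman",
    "rank_sum_compare",
    "expressing_fraction",
]


@dataclass(frozen=True)
class SubstrateActivity:
    """Populations encoding vs expressing genes for one substrate/habitat."""

    substrate: str
    habitat: str
    n_present: int  # MAGs present and encoding >= 1 gene for the substrate
    n_expressing: int  # of those, MAGs with >= 1 expressed gene
    fraction: Optional[float]  # n_expressing / n_present, None when n_present=0
    above_half: Optional[bool]  # classification against the slope-0.5 line

    def __post_init__(self) -> None:
        if not (0 <= self.n_expressing <= self.n_present):
            raise ValueError("need 0 <= n_expressing <= n_present")


def richness_partition(
    water: set[str], sediment: set[str]
) -> tuple[int, int, int]:
    """(water-only, sediment-only, shared) distinct-family counts."""
    return (len(water - sediment), len(sediment - water), len(water & sediment))


def inverse_simpson(abundances: Sequence[float]) -> float:
    """1 / sum(p_i^2) for relative abundances p; errors on an all-zero vector."""
    x = np.asarray(abundances, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("inverse Simpson undefined for an all-zero vector")
    p = x / total
    return float(1.0 / np.sum(p**2))


def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """sum|x-y| / sum(x+y) between two non-negative abundance vectors."""
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("abundances must be non-negative")
    denom = (a + b).sum()
    if denom <= 0:
        raise ValueError("both vectors are all-zero")
    return float(np.abs(a - b).sum() / denom)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    Two-sided p from the t-approximation. Errors on n < 3 or a constant
    input (rho undefined).
    """
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(a) < 3:
        raise ValueError("need n >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("Spearman rho undefined for a constant vector")
    res = stats.spearmanr(a, b)
    return float(res.statistic), float(res.pvalue)


def rank_sum_compare(
    a: Sequence[float], b: Sequence[float], exact_max_n: int = 8
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparison of two samples.

    Exact enumeration when both groups have <= ``exact_max_n`` observations
    and the pooled data is tie-free; otherwise the normal approximation with
    tie and continuity corrections. Returns (U for the first sample,
    two-sided p).
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (tie_free and x.size <= exact_max_n and y.size <= exact_max_n) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def expressing_fraction(
    presence: pd.DataFrame,
    expressed: pd.DataFrame,
    annotations: Mapping[str, CazymeAnnotation],
    gene_genome: Mapping[str, str],
    genome_habitat: Mapping[str, str],
    sample_habitat: Mapping[str, str],
) -> list[SubstrateActivity]:
    """Per (substrate, habitat) population counts behind the slope-0.5 plot.

    A MAG counts as present for a habitat when present in >= 1 of that
    habitat's samples; as expressing a substrate when >= 1 of its genes for
    the substrate is expressed in >= 1 of those samples.
    """
    habitats = sorted(set(sample_habitat.values()))
    hab_samples = {
        h: [s for s in presence.columns if sample_habitat.get(s) == h] for h in habitats
    }
    # substrate -> genome -> gene ids
    sub_genes: dict[str, dict[str, list[str]]] = {}
    for gene_id, ann in annotations.items():
        genome = gene_genome.get(gene_id)
        if genome is None:
            continue
        for sub in ann.substrates:
            sub_genes.setdefault(sub, {}).setdefault(genome, []).append(gene_id)
    out: list[SubstrateActivity] = []
    for sub in sorted(sub_genes):
        for hab in habitats:
            samples = hab_samples[hab]
            if not samples:
                continue
            n_present = 0
            n_expressing = 0
            for genome, genes in sub_genes[sub].items():
                if genome_habitat.get(genome) != hab:
                    continue
                if genome not in presence.index:
                    continue
                if not presence.loc[genome, samples].any():
                    continue
                n_present += 1
                gene_rows = [g for g in genes if g in expressed.index]
                if gene_rows and expressed.loc[gene_rows, samples].to_numpy().any():
                    n_expressing += 1
            fraction = n_expressing / n_present if n_present else None
            out.append(
                SubstrateActivity(
                    substrate=sub,
                    habitat=hab,
                    n_present=n_present,
                    n_expressing=n_expressing,
                    fraction=fraction,
                    above_half=(fraction > 0.5) if fraction is not None else None,
                )
            )
    return out
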