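"""MAG presence, transcript filtering, TPM and per-capita expression.

The quantification conventions: populations (MAGs) count as present in a
sample when reads cover at least 10% of the genome (length-weighted over
contigs); gene counts below five read pairs are zeroed before
normalisation; TPM is computed per sample over all genes in the table;
per-capita expression divides a genome's summed TPM by its mean
fold-coverage in the same sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import CazymeAnnotation
from .io_formats import GenomeQuality

__all__ = [
    "MIN_COMPLETENESS",
    "MAX_CONTAMINATION",
    "BREADTH_MIN",
    "MIN_READ_PAIRS",
    "ExpressionTable",
    "filter_genome_quality",
    "genome_coverage",
    "genome_presence",
    "filter_counts",
    "expressed_flags",
    "tpm_normalize",
    "build_expression_table",
    "per_capita",
    "aggregate_tpm",
]

MIN_COMPLETENESS = 50.0
MAX_CONTAMINATION = 5.0
#: fraction of genome positions that must be covered for presence
BREADTH_MIN = 0.10
#: genes with fewer mapped read pairs than this are zeroed per sample
MIN_READ_PAIRS = 5


@dataclass(frozen=True)
class ExpressionTable:
    """Bundled gene x sample count, TPM and expression-flag matrices."""

    counts: pd.DataFrame  # raw integer read pairs
    filtered: pd.DataFrame  # counts after the read-pair floor
    tpm: pd.DataFrame
    expressed: pd.DataFrame  # boolean


def filter_genome_quality(
    qualities: Iterable[GenomeQuality],
    min_comp: float = MIN_COMPLETENESS,
    max_cont: float = MAX_CONTAMINATION,
) -> set[str]:
    """Genomes with completeness >= min_comp and contamination <= max_cont."""
    return {
        q.genome_id
        for q in qualities
        if q.completeness >= min_comp and q.contamination <= max_cont
    }


def genome_coverage(
    contig_cov: pd.DataFrame, contig_genome: Mapping[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Roll per-contig coverage up to genomes.

    ``contig_cov`` is the long table (contig_id, sample_id, depth, breadth,
    length). Returns (breadth, depth) genome x sample frames, both as
    contig-length-weighted means.
    """
    df = contig_cov.copy()
    unknown = set(df["contig_id"]) - set(contig_genome)
    if unknown:
        raise KeyError(f"contigs without genome assignment: {sorted(unknown)[:5]}")
    if df["length"].isna().any() or (df["length"] <= 0).any():
        raise ValueError("every contig needs a positive length")
    df["genome_id"] = df["contig_id"].map(contig_genome)
    df["wb"] = df["breadth"] * df["length"]
    df["wd"] = df["depth"] * df["length"]
    g = df.groupby(["genome_id", "sample_id"])
    tot = g["length"].sum()
    breadth = (g["wb"].sum() / tot).unstack(fill_value=0.0)
    depth = (g["wd"].sum() / tot).unstack(fill_value=0.0)
    return breadth, depth


def genome_presence(
    contig_cov: pd.DataFrame,
    contig_genome: Mapping[str, str],
    breadth_min: float = BREADTH_MIN,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(presence booleans, genome breadth); present iff breadth >= breadth_min."""
    breadth, _ = genome_coverage(contig_cov, contig_genome)
    return breadth >= breadth_min, breadth


def filter_counts(counts: pd.DataFrame, min_pairs: int = MIN_READ_PAIRS) -> pd.DataFrame:
    """Zero every cell with fewer than ``min_pairs`` read pairs (cell-wise)."""
    arr = counts.to_numpy()
    if arr.size and not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be integers (read pairs)")
    out = counts.copy()
    out[out < min_pairs] = 0
    return out


def expressed_flags(counts: pd.DataFrame, min_pairs: int = MIN_READ_PAIRS) -> pd.DataFrame:
    """Gene x sample booleans: expressed iff raw count >= min_pairs."""
    return counts >= min_pairs


def tpm_normalize(counts: pd.DataFrame, gene_lengths_nt: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million per sample column.

    rate_g = count_g / (length_g / 1000); tpm_g = 1e6 * rate_g / sum(rates).
    The denominator runs over every gene in the table. All-zero columns stay
    zero. Counts should already be floor-filtered.
    """
    missing = counts.index.difference(gene_lengths_nt.index)
    if len(missing):
        raise KeyError(f"genes without length: {list(missing[:5])}")
    lengths = gene_lengths_nt.loc[counts.index].astype(float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.div(lengths / 1000.0, axis=0)
    colsum = rate.sum(axis=0)
    tpm = rate.mul(1e6).div(colsum.where(colsum > 0, 1.0), axis=1)
    tpm.loc[:, colsum == 0] = 0.0
    return tpm


def build_expression_table(
    counts: pd.DataFrame,
    gene_lengths_nt: pd.Series,
    min_pairs: int = MIN_READ_PAIRS,
) -> ExpressionTable:
    """Floor-filter, normalise and flag in the fixed pipeline order."""
    filtered = filter_counts(counts, min_pairs)
    return ExpressionTable(
        counts=counts,
        filtered=filtered,
        tpm=tpm_normalize(filtered, gene_lengths_nt),
        expressed=expressed_flags(counts, min_pairs),
    )


def per_capita(tpm_by_genome: pd.DataFrame, depth: pd.DataFrame) -> pd.DataFrame:
    """Genome-summed TPM divided by genome mean depth; depth 0 -> NaN."""
    depth_aligned = depth.reindex(index=tpm_by_genome.index, columns=tpm_by_genome.columns)
    return tpm_by_genome / depth_aligned.where(depth_aligned > 0)


def aggregate_tpm(
    tpm: pd.DataFrame,
    annotations: Mapping[str, CazymeAnnotation],
    gene_genome: Mapping[str, str],
    by: str = "ec",
) -> pd.DataFrame:
    """Long table of TPM summed within (key, genome, sample).

    ``by`` is one of ec / family / substrate / gene. A multi-valued gene
    (two ECs, say) contributes its full TPM under each of its keys. Genes
    whose key set is empty, or which lack an annotation when one is needed,
    are dropped (their number is in ``.attrs['n_dropped']``).
    """
    if by not in ("ec", "family", "substrate", "gene"):
        raise ValueError(f"unknown grouping {by!r}")
    records = []
    dropped = 0
    for gene_id in tpm.index:
        genome = gene_genome.get(gene_id)
        if genome is None:
            dropped += 1
            continue
        if by == "gene":
            keys: Sequence[str] = (gene_id,)
        else:
            ann = annotations.get(gene_id)
            if ann is None:
                dropped += 1
                continue
            keys = sorted(
                ann.ec_numbers if by == "ec" else
                ann.families if by == "family" else
                ann.substrates
            )
            if not keys:
                dropped += 1
                continue
        row = tpm.loc[gene_id]
        for key in keys:
            for sample, value in row.items():
                records.append((key, genome, sample, value))
    out = pd.DataFrame(records, columns=[by, "genome_id", "sample_id", "tpm"])
    out = (
        out.groupby([by, "genome_id", "sample_id"], as_index=False)["tpm"].sum()
        if len(out)
        else out
    )
    out.attrs["n_dropped"] = dropped
    return out
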