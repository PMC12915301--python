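"""CAZy family assignment from HMM domain hits.

Raw profile matches are filtered on independent-domain E-value and profile
coverage, then reduced to a non-overlapping set per gene: of any pair of
retained matches, the query-coordinate overlap may not exceed half the
shorter alignment. Genes whose hits survive carry the set of matching CAZy
families (a gene can belong to several families, e.g. GH13 + CBM48).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .io_formats import DomainHit

__all__ = [
    "EcSource",
    "CazymeAnnotation",
    "E_MAX",
    "COV_MIN",
    "filter_hits",
    "resolve_overlaps",
    "annotate_genes",
]

#: dbCAN HMM acceptance thresholds: independent-domain E-value strictly below
#: 1e-18 and profile coverage of at least 35%.
E_MAX = 1e-18
COV_MIN = 0.35


class EcSource(str, Enum):
    """Which rule of the EC-assignment cascade fired (NONE if none did)."""

    RULE1 = "RULE1"
    RULE2 = "RULE2"
    RULE3 = "RULE3"
    RULE4 = "RULE4"
    NONE = "NONE"


@dataclass(frozen=True)
class CazymeAnnotation:
    """Per-gene CAZy families with (later-assigned) ECs and substrates."""

    gene_id: str
    families: frozenset[str]
    ec_numbers: frozenset[str] = frozenset()
    ec_source: EcSource = EcSource.NONE
    substrates: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.families:
            raise ValueError(f"gene {self.gene_id}: families must be non-empty")
        if (self.ec_source is EcSource.NONE) != (not self.ec_numbers):
            raise ValueError(
                f"gene {self.gene_id}: ec_source NONE must coincide with empty ECs"
            )

    def with_ecs(self, ecs: frozenset[str], source: EcSource) -> "CazymeAnnotation":
        return replace(self, ec_numbers=ecs, ec_source=source)

    def with_substrates(self, substrates: frozenset[str]) -> "CazymeAnnotation":
        return replace(self, substrates=substrates)


def filter_hits(
    hits: Iterable[DomainHit], e_max: float = E_MAX, cov_min: float = COV_MIN
) -> list[DomainHit]:
    """Retain hits with i_evalue < e_max and profile coverage >= cov_min."""
    return [h for h in hits if h.i_evalue < e_max and h.hmm_coverage >= cov_min]


def _priority_key(h: DomainHit):
    # better E-value first, then longer alignment, then stable label order
    return (h.i_evalue, -h.ali_length, h.family, h.ali_from)


def _overlap(a: DomainHit, b: DomainHit) -> int:
    return max(0, min(a.ali_to, b.ali_to) - max(a.ali_from, b.ali_from) + 1)


def _compatible(a: DomainHit, b: DomainHit) -> bool:
    """Pair is retained together iff overlap <= 50% of the shorter alignment."""
    return _overlap(a, b) <= 0.5 * min(a.ali_length, b.ali_length)


def resolve_overlaps(hits: Sequence[DomainHit]) -> list[DomainHit]:
    """Greedy non-overlapping selection for one gene's hits.

    Candidates are ranked by (i_evalue asc, alignment length desc, family,
    ali_from) and accepted greedily when they overlap every already-accepted
    hit by at most 50% of the shorter of the two alignments (strictly more
    than half is a clash). Output is sorted by query start. Idempotent.
    """
    if not hits:
        return []
    gene_ids = {h.gene_id for h in hits}
    if len(gene_ids) > 1:
        raise ValueError(f"resolve_overlaps expects one gene, got {sorted(gene_ids)}")
    accepted: list[DomainHit] = []
    for h in sorted(hits, key=_priority_key):
        if all(_compatible(h, a) for a in accepted):
            accepted.append(h)
    accepted.sort(key=lambda h: (h.ali_from, h.ali_to, h.family))
    return accepted


def annotate_genes(
    hits: Iterable[DomainHit],
    e_max: float = E_MAX,
    cov_min: float = COV_MIN,
) -> dict[str, CazymeAnnotation]:
    """Filter then overlap-resolve hits per gene; build family annotations.

    Genes with no surviving hit are absent from the result. ECs and
    substrates start empty (assigned by the downstream cascade).
    """
    by_gene: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_gene.setdefault(h.gene_id, []).append(h)
    out: dict[str, CazymeAnnotation] = {}
    for gene_id, gene_hits in by_gene.items():
        surviving = resolve_overlaps(filter_hits(gene_hits, e_max, cov_min))
        if surviving:
            out[gene_id] = CazymeAnnotation(
                gene_id=gene_id, families=frozenset(h.family for h in surviving)
            )
    return out


def surviving_hits(
    hits: Iterable[DomainHit],
    e_max: float = E_MAX,
    cov_min: float = COV_MIN,
) -> dict[str, list[DomainHit]]:
    """Per-gene hits after the filter -> overlap-resolution pipeline."""
    by_gene: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_gene.setdefault(h.gene_id, []).append(h)
    return {
        g: kept
        for g, gh in by_gene.items()
        if (kept := resolve_overlaps(filter_hits(gh, e_max, cov_min)))
    }
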