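"""EC-number assignment for CAZyme genes by a four-rule cascade.

Evidence comes from four independent annotation routes, consulted strictly
in order; the first route that yields at least one EC wins:

1. curated EC metadata on surviving subfamily (dbCAN-sub) HMM hits;
2. DRAM-derived KO annotations whose ECs agree with the gene's CAZy
   family's curated EC list;
3. sequence hits against characterised CAZy proteins (CAZyDB) of the same
   family that carry ECs;
4. BLAST-derived KEGG KO annotations, checked for family agreement as in
   rule 2.

Genes failing all four keep an empty EC set.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from .annotation import (
    COV_MIN,
    E_MAX,
    CazymeAnnotation,
    EcSource,
    filter_hits,
    resolve_overlaps,
)
from .io_formats import AlignmentHit, DomainHit, KoAnnotation, KoSource, ReferenceMaps

__all__ = [
    "CAZYDB_E_MAX",
    "CAZYDB_PID_MIN",
    "CAZYDB_QCOV_MIN",
    "filter_dbcansub",
    "filter_cazydb",
    "assign_ec",
    "assign_ec_all",
]

#: CAZyDB sequence-hit thresholds: E strictly below 1e-102, percent identity
#: and query coverage at least 35% / 70% (both boundaries inclusive).
CAZYDB_E_MAX = 1e-102
CAZYDB_PID_MIN = 35.0
CAZYDB_QCOV_MIN = 70.0


def filter_dbcansub(
    hits: Sequence[DomainHit], e_max: float = E_MAX, cov_min: float = COV_MIN
) -> list[DomainHit]:
    """Filter subfamily HMM hits with the same criteria as the family HMMs.

    Accepts hits over many genes; the <=50%-overlap resolution is applied
    per gene.
    """
    by_gene: dict[str, list[DomainHit]] = {}
    for h in filter_hits(hits, e_max, cov_min):
        by_gene.setdefault(h.gene_id, []).append(h)
    out: list[DomainHit] = []
    for gene_id in by_gene:
        out.extend(resolve_overlaps(by_gene[gene_id]))
    return out


def filter_cazydb(
    hits: Iterable[AlignmentHit],
    e_max: float = CAZYDB_E_MAX,
    pid_min: float = CAZYDB_PID_MIN,
    qcov_min: float = CAZYDB_QCOV_MIN,
) -> list[AlignmentHit]:
    """Retain hits with evalue < e_max, pident >= pid_min, qcov >= qcov_min.

    A NaN query coverage (file without the qcovhsp column) fails the filter.
    """
    return [
        h for h in hits if h.evalue < e_max and h.pident >= pid_min and h.qcov >= qcov_min
    ]


def _ko_family_agreement(
    kos: Iterable[KoAnnotation],
    source: KoSource,
    families: frozenset[str],
    family_ec_map: Mapping[str, frozenset[str]],
) -> frozenset[str]:
    """ECs carried by KOs of `source` that also appear under any gene family."""
    family_ecs: set[str] = set()
    for fam in families:
        family_ecs |= family_ec_map.get(fam, frozenset())
    agreed: set[str] = set()
    for ko in kos:
        if ko.source is source:
            agreed |= ko.ec_numbers & family_ecs
    return frozenset(agreed)


def assign_ec(
    ann: CazymeAnnotation,
    sub_hits: Sequence[DomainHit],
    dram_kos: Sequence[KoAnnotation],
    cazydb_hits: Sequence[AlignmentHit],
    kegg_kos: Sequence[KoAnnotation],
    maps: ReferenceMaps,
) -> CazymeAnnotation:
    """Apply the cascade to one gene; inputs must be pre-filtered.

    Rules are evaluated strictly in order 1..4 and evaluation stops at the
    first rule producing a non-empty EC set; ``ec_source`` records the
    firing rule. When a rule yields several ECs all are kept.
    """
    # rule 1: curated subfamily metadata
    rule1 = frozenset().union(*(h.ec_numbers for h in sub_hits)) if sub_hits else frozenset()
    if rule1:
        return ann.with_ecs(rule1, EcSource.RULE1)
    # rule 2: DRAM KO ECs agreeing with the family's curated list
    rule2 = _ko_family_agreement(dram_kos, KoSource.DRAM, ann.families, maps.family_ec_map)
    if rule2:
        return ann.with_ecs(rule2, EcSource.RULE2)
    # rule 3: characterised same-family CAZyDB hits carrying ECs
    rule3: set[str] = set()
    for h in cazydb_hits:
        if h.subject_family in ann.families and h.subject_ec:
            rule3 |= h.subject_ec
    if rule3:
        return ann.with_ecs(frozenset(rule3), EcSource.RULE3)
    # rule 4: KEGG-BLAST KOs, same agreement check as rule 2
    rule4 = _ko_family_agreement(kegg_kos, KoSource.KEGG_BLAST, ann.families, maps.family_ec_map)
    if rule4:
        return ann.with_ecs(rule4, EcSource.RULE4)
    return ann.with_ecs(frozenset(), EcSource.NONE)


def assign_ec_all(
    annotations: Mapping[str, CazymeAnnotation],
    sub_hits: Sequence[DomainHit],
    dram_kos: Sequence[KoAnnotation],
    cazydb_hits: Sequence[AlignmentHit],
    kegg_kos: Sequence[KoAnnotation],
    maps: ReferenceMaps,
) -> dict[str, CazymeAnnotation]:
    """Vectorised convenience: run the cascade for every annotated gene.

    Raw evidence may span all genes; subfamily and CAZyDB hits are filtered
    here (rule-1 hits with the HMM criteria, rule-3 hits with the CAZyDB
    criteria) and grouped per gene.
    """
    sub_by_gene: dict[str, list[DomainHit]] = {}
    for h in filter_dbcansub(sub_hits):
        sub_by_gene.setdefault(h.gene_id, []).append(h)
    caz_by_gene: dict[str, list[AlignmentHit]] = {}
    for h in filter_cazydb(cazydb_hits):
        caz_by_gene.setdefault(h.query_id, []).append(h)
    dram_by_gene: dict[str, list[KoAnnotation]] = {}
    for k in dram_kos:
        dram_by_gene.setdefault(k.gene_id, []).append(k)
    kegg_by_gene: dict[str, list[KoAnnotation]] = {}
    for k in kegg_kos:
        kegg_by_gene.setdefault(k.gene_id, []).append(k)
    return {
        g: assign_ec(
            ann,
            sub_by_gene.get(g, []),
            dram_by_gene.get(g, []),
            caz_by_gene.get(g, []),
            kegg_by_gene.get(g, []),
            maps,
        )
        for g, ann in annotations.items()
    }
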