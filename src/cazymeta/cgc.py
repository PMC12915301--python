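"""CAZyme-gene-cluster (CGC) detection and substrate prediction.

A CGC is a contiguous stretch of genes on one contig containing at least
one CAZyme gene and at least one other signature gene (transcription
factor, signal-transduction protein, or transporter), where consecutive
signature genes are separated by at most two non-signature genes. In
Bacteroidota such loci are the polysaccharide utilization loci (PULs).

Cluster substrates are predicted two ways: by homology to a reference PUL
database ranked on summed bitscores (method B), and by majority voting
over the member genes' own substrate predictions (method C).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Mapping, Optional, Sequence, Union

from .annotation import CazymeAnnotation
from .io_formats import AlignmentHit, DomainHit, GeneRecord, ReferenceMaps, Role

__all__ = [
    "CGC",
    "MAX_GAP",
    "VOTE_MIN",
    "TF_STP_E_MAX",
    "TF_STP_COV_MIN",
    "TCDB_E_MAX",
    "TCDB_QCOV_MIN",
    "TCDOMS_E_MAX",
    "PUL_E_MAX",
    "filter_signature_hmm",
    "filter_tcdb",
    "filter_tcdoms",
    "classify_signature",
    "cluster_spans",
    "find_cgcs",
    "predict_cgc_substrate_homology",
    "predict_cgc_substrate_voting",
    "count_gene_pairs",
]

#: at most this many non-signature genes may separate consecutive signature
#: genes inside one cluster
MAX_GAP = 2
#: minimum votes for a method-C substrate call
VOTE_MIN = 2

# signature-evidence thresholds (dbCAN3-style defaults, config-exposed)
TF_STP_E_MAX = 1e-4
TF_STP_COV_MIN = 0.35
TCDB_E_MAX = 1e-10
TCDB_QCOV_MIN = 35.0
TCDOMS_E_MAX = 1e-4

#: PUL homology hits must beat this E-value (method B)
PUL_E_MAX = 1e-102

_SIGNATURE_OTHER = {Role.TF, Role.STP, Role.TRANSPORTER}


@dataclass(frozen=True)
class CGC:
    """A detected cluster spanning contig gene indices start..end inclusive."""

    cgc_id: str
    contig_id: str
    start_index: int
    end_index: int
    members: tuple[tuple[str, Role], ...]  # (gene_id, role), contig order
    substrate_B: Optional[tuple[str, str, float]] = None  # (substrate, pul_id, sum)
    substrate_C: Optional[tuple[tuple[str, ...], int]] = None  # (substrates, votes)

    def __post_init__(self) -> None:
        roles = [r for _, r in self.members]
        if Role.CAZYME not in roles or not any(r in _SIGNATURE_OTHER for r in roles):
            raise ValueError(
                f"CGC {self.cgc_id} must contain a CAZyme and another signature gene"
            )

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.members)


# ---------------------------------------------------------------------------
# Signature-gene classification
# ---------------------------------------------------------------------------


def filter_signature_hmm(
    hits: Iterable[DomainHit],
    e_max: float = TF_STP_E_MAX,
    cov_min: float = TF_STP_COV_MIN,
) -> list[DomainHit]:
    """TF/STP HMM evidence filter."""
    return [h for h in hits if h.i_evalue < e_max and h.hmm_coverage >= cov_min]


def filter_tcdb(
    hits: Iterable[AlignmentHit],
    e_max: float = TCDB_E_MAX,
    qcov_min: float = TCDB_QCOV_MIN,
) -> list[AlignmentHit]:
    """Transporter (TCDB DIAMOND) evidence filter; E-value bound inclusive."""
    return [h for h in hits if h.evalue <= e_max and h.qcov >= qcov_min]


def filter_tcdoms(hits: Iterable[DomainHit], e_max: float = TCDOMS_E_MAX) -> list[DomainHit]:
    """Transporter domain (tcDoms HMM) evidence filter."""
    return [h for h in hits if h.i_evalue < e_max]


def classify_signature(
    genes: Sequence[GeneRecord],
    tf_hits: Sequence[DomainHit],
    stp_hits: Sequence[DomainHit],
    tcdb_hits: Sequence[AlignmentHit],
    tcdoms_hits: Sequence[DomainHit],
    cazyme_ids: set[str],
) -> list[GeneRecord]:
    """Assign one role per gene with precedence CAZYME > TRANSPORTER > TF > STP.

    Hit lists must be pre-filtered (see the filter_* helpers). Genes with no
    evidence keep role NULL.
    """
    tf_ids = {h.gene_id for h in tf_hits}
    stp_ids = {h.gene_id for h in stp_hits}
    tc_ids = {h.query_id for h in tcdb_hits} | {h.gene_id for h in tcdoms_hits}
    out: list[GeneRecord] = []
    for g in genes:
        if g.gene_id in cazyme_ids:
            role = Role.CAZYME
        elif g.gene_id in tc_ids:
            role = Role.TRANSPORTER
        elif g.gene_id in tf_ids:
            role = Role.TF
        elif g.gene_id in stp_ids:
            role = Role.STP
        else:
            role = Role.NULL
        out.append(g.with_role(role))
    return out


# ---------------------------------------------------------------------------
# Cluster detection
# ---------------------------------------------------------------------------


def cluster_spans(roles: Sequence[Role], max_gap: int = MAX_GAP) -> list[tuple[int, int]]:
    """Valid cluster spans (start, end inclusive) over a contig's role string.

    Consecutive signature (non-NULL) genes chain when at most ``max_gap``
    NULL genes intervene; a maximal chain qualifies iff it holds >= 1 CAZyme
    and >= 1 other signature role. Spans run signature-to-signature.
    """
    sig = [i for i, r in enumerate(roles) if r is not Role.NULL]
    spans: list[tuple[int, int]] = []
    if not sig:
        return spans
    chain_start = 0
    for k in range(1, len(sig) + 1):
        if k == len(sig) or sig[k] - sig[k - 1] - 1 > max_gap:
            chain = sig[chain_start:k]
            chain_roles = {roles[i] for i in chain}
            if Role.CAZYME in chain_roles and chain_roles & _SIGNATURE_OTHER:
                spans.append((chain[0], chain[-1]))
            chain_start = k
    return spans


def find_cgcs(
    contig_genes: Sequence[GeneRecord], max_gap: int = MAX_GAP
) -> list[CGC]:
    """Detect CGCs on one contig's genes (sorted by index, roles assigned)."""
    if not contig_genes:
        return []
    contigs = {g.contig_id for g in contig_genes}
    if len(contigs) > 1:
        raise ValueError(f"find_cgcs expects one contig, got {sorted(contigs)}")
    indices = [g.index_on_contig for g in contig_genes]
    if indices != sorted(indices) or len(set(indices)) != len(indices):
        raise ValueError("contig genes must be sorted by index_on_contig")
    contig_id = contig_genes[0].contig_id
    # positions in the local list, which may start at a nonzero contig index
    roles = [g.role for g in contig_genes]
    cgcs: list[CGC] = []
    for n, (i, j) in enumerate(cluster_spans(roles, max_gap)):
        members = tuple((g.gene_id, g.role) for g in contig_genes[i : j + 1])
        cgcs.append(
            CGC(
                cgc_id=f"{contig_id}|cgc{n + 1}",
                contig_id=contig_id,
                start_index=contig_genes[i].index_on_contig,
                end_index=contig_genes[j].index_on_contig,
                members=members,
            )
        )
    return cgcs


def find_cgcs_all(
    genes: Sequence[GeneRecord], max_gap: int = MAX_GAP
) -> list[CGC]:
    """Detect CGCs across many contigs; contig boundaries terminate chains."""
    by_contig: dict[str, list[GeneRecord]] = {}
    order: list[str] = []
    for g in genes:
        if g.contig_id not in by_contig:
            order.append(g.contig_id)
        by_contig.setdefault(g.contig_id, []).append(g)
    out: list[CGC] = []
    for contig in order:
        contig_genes = sorted(by_contig[contig], key=lambda g: g.index_on_contig)
        out.extend(find_cgcs(contig_genes, max_gap))
    return out


# ---------------------------------------------------------------------------
# Substrate prediction
# ---------------------------------------------------------------------------


def predict_cgc_substrate_homology(
    cgc: CGC,
    pul_hits: Sequence[AlignmentHit],
    maps: ReferenceMaps,
    e_max: float = PUL_E_MAX,
) -> Optional[tuple[str, str, float]]:
    """Method B: rank candidate reference PULs by summed member bitscores.

    Hits with E >= e_max are dropped; only the best hit per (member gene,
    PUL) pair contributes to the sum, preventing multi-HSP double counting.
    A PUL is eligible only when the matched subject proteins include a
    CAZyme and at least one other signature role. Ties break on pul_id.
    """
    member_set = set(cgc.gene_ids)
    subject_info: dict[str, tuple[str, Role]] = {}
    for pid, entry in maps.pul_db.items():
        for subject_id, role in entry.members:
            subject_info[subject_id] = (pid, role)
    best: dict[tuple[str, str], float] = {}  # (query, pul) -> best bitscore
    matched_roles: dict[str, set[Role]] = {}
    for h in pul_hits:
        if h.query_id not in member_set:
            raise ValueError(f"hit query {h.query_id!r} is not a member of {cgc.cgc_id}")
        if not (h.evalue < e_max):
            continue
        pul_id = h.subject_pul_id
        role = h.subject_role
        if pul_id is None and h.subject_id in subject_info:
            pul_id, role = subject_info[h.subject_id]
        elif role is None and h.subject_id in subject_info:
            role = subject_info[h.subject_id][1]
        if pul_id is None or pul_id not in maps.pul_db:
            continue
        key = (h.query_id, pul_id)
        if h.bitscore > best.get(key, -math.inf):
            best[key] = h.bitscore
        if role is not None:
            matched_roles.setdefault(pul_id, set()).add(role)
    sums: dict[str, float] = {}
    for (_, pul_id), score in best.items():
        sums[pul_id] = sums.get(pul_id, 0.0) + score
    eligible = [
        pid
        for pid in sums
        if Role.CAZYME in matched_roles.get(pid, set())
        and matched_roles.get(pid, set()) & _SIGNATURE_OTHER
    ]
    if not eligible:
        return None
    winner = min(eligible, key=lambda pid: (-sums[pid], pid))
    return (maps.pul_db[winner].substrate, winner, sums[winner])


def predict_cgc_substrate_voting(
    cgc: CGC,
    annotations: Mapping[str, CazymeAnnotation],
    vote_min: int = VOTE_MIN,
) -> Optional[tuple[tuple[str, ...], int]]:
    """Method C: each member gene votes once per distinct substrate it carries.

    Substrate(s) with the maximal tally win if the tally reaches ``vote_min``;
    ties return all co-winners sorted.
    """
    votes: dict[str, int] = {}
    for gene_id in cgc.gene_ids:
        ann = annotations.get(gene_id)
        if ann is None:
            continue
        for sub in ann.substrates:
            votes[sub] = votes.get(sub, 0) + 1
    if not votes:
        return None
    top = max(votes.values())
    if top < vote_min:
        return None
    winners = tuple(sorted(s for s, v in votes.items() if v == top))
    return (winners, top)


def annotate_cgc_substrates(
    cgcs: Sequence[CGC],
    pul_hits: Sequence[AlignmentHit],
    annotations: Mapping[str, CazymeAnnotation],
    maps: ReferenceMaps,
    e_max: float = PUL_E_MAX,
    vote_min: int = VOTE_MIN,
) -> list[CGC]:
    """Attach method-B and method-C substrate calls to every cluster."""
    hits_by_gene: dict[str, list[AlignmentHit]] = {}
    for h in pul_hits:
        hits_by_gene.setdefault(h.query_id, []).append(h)
    out = []
    for c in cgcs:
        member_hits = [h for g in c.gene_ids for h in hits_by_gene.get(g, [])]
        out.append(
            replace(
                c,
                substrate_B=predict_cgc_substrate_homology(c, member_hits, maps, e_max),
                substrate_C=predict_cgc_substrate_voting(c, annotations, vote_min),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Gene-pair tallies (susCD-style counts)
# ---------------------------------------------------------------------------

Predicate = Union[str, Callable[[str], bool]]


def count_gene_pairs(
    cgcs: Sequence[CGC],
    annotations: Mapping[str, CazymeAnnotation],
    pair_spec: tuple[Predicate, Predicate],
) -> int:
    """Count adjacent member-gene pairs matching the two predicates.

    A predicate is either a CAZy family label (gene qualifies when the label
    is among its annotated families) or a callable on the gene id. Adjacency
    means consecutive positions in the cluster span (indices differ by 1);
    either orientation qualifies and each adjacent pair counts once.
    """

    def matches(pred: Predicate, gene_id: str) -> bool:
        if callable(pred):
            return bool(pred(gene_id))
        ann = annotations.get(gene_id)
        return ann is not None and pred in ann.families

    pred_a, pred_b = pair_spec
    n = 0
    for c in cgcs:
        ids = c.gene_ids
        for g1, g2 in zip(ids, ids[1:]):
            if (matches(pred_a, g1) and matches(pred_b, g2)) or (
                matches(pred_b, g1) and matches(pred_a, g2)
            ):
                n += 1
    return n
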