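"""Seeded generator of a full mock estuary study with a ground-truth ledger.

The generator emits every table the pipeline consumes — gene tables, HMM
domain tables with true and decoy hits, subfamily/KO/CAZyDB/PUL evidence,
signature-gene hits, reference maps, per-contig coverage and gene x sample
read-pair counts — together with a ledger recording the planted truth
(families, ECs, substrates, roles, cluster spans and substrates, presence
and expression states). No sequences are emitted, only identifiers,
coordinates and hit statistics.

Planted margins are deliberate: true domain hits sit at least a decade
below the E-value threshold with >= 0.40 profile coverage, decoys at least
a decade above it (or with coverage <= 0.30), so threshold behaviour is
deterministic rather than distributional.

One RNG stream per fixture type, all derived from the master seed, so
adding a fixture type never perturbs existing ones.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .io_formats import (
    AlignmentHit,
    DomainHit,
    GeneRecord,
    KoAnnotation,
    KoSource,
    PulEntry,
    ReferenceMaps,
    Role,
    write_blast_tab,
    write_coverage_table,
    write_domtblout,
    write_family_ec_map,
    write_gene_table,
    write_ko_table,
    write_matrix,
    write_pul_db,
    write_substrate_map,
)

__all__ = ["SimConfig", "TruthLedger", "SyntheticStudy", "generate", "scenario_estuary"]

HABITATS = ("water", "sediment")


class SimulationError(ValueError):
    """Raised for infeasible generator configurations."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the mock community.

    ``p_cazyme`` and ``expression_prob`` may be a single float or a
    per-habitat mapping (expression additionally per substrate).
    """

    seed: int = 0
    n_genomes_per_habitat: int = 10
    n_samples_per_habitat: int = 3
    contigs_per_genome: tuple[int, int] = (2, 4)
    genes_per_contig: tuple[int, int] = (8, 20)
    gene_length_nt: tuple[int, int] = (300, 2400)
    n_substrates: int = 8
    n_families: int = 24
    p_cazyme: Union[float, Mapping[str, float]] = 0.20
    p_multi_family: float = 0.10
    n_planted_cgcs: int = 10
    n_decoy_cgcs: int = 10
    decoy_rate: float = 0.5
    expression_prob: Union[float, Mapping] = 0.7
    p_housekeeping: float = 0.7
    p_present: float = 0.9
    count_model: tuple[float, float, float] = (80.0, 0.2, 10.0)  # mean_expr, mean_silent, dispersion
    noise_free: bool = False
    core_substrate: Optional[str] = None
    route_probs: tuple[float, float, float, float, float] = (0.55, 0.15, 0.10, 0.10, 0.10)

    def __post_init__(self) -> None:
        for name in ("contigs_per_genome", "genes_per_contig", "gene_length_nt"):
            lo, hi = getattr(self, name)
            if lo <= 0 or lo > hi:
                raise SimulationError(f"{name} range ({lo}, {hi}) is empty or non-positive")
        probs = [self.p_multi_family, self.p_housekeeping, self.p_present, self.decoy_rate]
        probs += list(self.route_probs)
        for h in HABITATS:
            probs.append(self.cazyme_prob(h))
        if any(p < 0 for p in probs) or any(
            p > 1 for p in probs if p is not self.decoy_rate
        ):
            raise SimulationError("probabilities must lie in [0, 1]")
        if abs(sum(self.route_probs) - 1.0) > 1e-9:
            raise SimulationError("route_probs must sum to 1")
        if self.n_genomes_per_habitat <= 0 or self.n_samples_per_habitat <= 0:
            raise SimulationError("need at least one genome and one sample per habitat")
        if self.n_substrates <= 0 or self.n_families < 4:
            raise SimulationError("need >= 1 substrate and >= 4 families")
        # a planted cluster needs room: up to 5 signature genes with 2-gene
        # gaps plus flanking padding
        if (self.n_planted_cgcs or self.n_decoy_cgcs) and self.genes_per_contig[1] < 8:
            raise SimulationError("planted clusters do not fit in genes_per_contig")

    def cazyme_prob(self, habitat: str) -> float:
        if isinstance(self.p_cazyme, Mapping):
            return float(self.p_cazyme[habitat])
        return float(self.p_cazyme)

    def expr_prob(self, habitat: str, substrate: str) -> float:
        ep = self.expression_prob
        if isinstance(ep, Mapping):
            v = ep[habitat]
            if isinstance(v, Mapping):
                return float(v.get(substrate, v.get("default", 0.5)))
            return float(v)
        return float(ep)


@dataclass(frozen=True)
class GeneTruth:
    families: frozenset[str]
    ec_numbers: frozenset[str]
    substrates: frozenset[str]
    role: Role


@dataclass(frozen=True)
class CgcTruth:
    contig_id: str
    start_index: int
    end_index: int
    substrate: str
    pul_id: str
    n_cazyme: int


@dataclass
class TruthLedger:
    """Planted ground truth for every emitted entity."""

    genes: dict[str, GeneTruth] = field(default_factory=dict)
    cgcs: list[CgcTruth] = field(default_factory=list)
    expression: dict[tuple[str, str], bool] = field(default_factory=dict)  # (gene, sample)
    presence: dict[tuple[str, str], bool] = field(default_factory=dict)  # (genome, sample)

    def cazyme_gene_ids(self) -> set[str]:
        return {g for g, t in self.genes.items() if t.families}

    def frames(self) -> dict[str, pd.DataFrame]:
        gene_rows = [
            {
                "gene_id": g,
                "families": ",".join(sorted(t.families)),
                "ec_numbers": ",".join(sorted(t.ec_numbers)),
                "substrates": ",".join(sorted(t.substrates)),
                "role": t.role.value,
            }
            for g, t in sorted(self.genes.items())
        ]
        cgc_rows = [
            {
                "contig_id": c.contig_id,
                "start_index": c.start_index,
                "end_index": c.end_index,
                "substrate": c.substrate,
                "pul_id": c.pul_id,
                "n_cazyme": c.n_cazyme,
            }
            for c in self.cgcs
        ]
        expr_rows = [
            {"gene_id": g, "sample_id": s, "expressed": int(v)}
            for (g, s), v in sorted(self.expression.items())
        ]
        pres_rows = [
            {"genome_id": g, "sample_id": s, "present": int(v)}
            for (g, s), v in sorted(self.presence.items())
        ]
        return {
            "truth_genes": pd.DataFrame(gene_rows),
            "truth_cgcs": pd.DataFrame(cgc_rows),
            "truth_expression": pd.DataFrame(expr_rows),
            "truth_presence": pd.DataFrame(pres_rows),
        }


@dataclass
class SyntheticStudy:
    """In-memory fixture set plus the ground-truth ledger."""

    config: SimConfig
    genes: list[GeneRecord]
    genomes: pd.DataFrame  # genome_id, habitat, completeness, contamination
    samples: pd.DataFrame  # sample_id, habitat
    dbcan_hits: list[DomainHit]
    sub_hits: list[DomainHit]  # subfamily hits, EC metadata attached
    subfamily_ecs: dict[str, frozenset[str]]
    tf_hits: list[DomainHit]
    stp_hits: list[DomainHit]
    tcdoms_hits: list[DomainHit]
    tcdb_hits: list[AlignmentHit]
    cazydb_hits: list[AlignmentHit]
    pul_hits: list[AlignmentHit]
    dram_kos: list[KoAnnotation]
    kegg_kos: list[KoAnnotation]
    maps: ReferenceMaps
    coverage: pd.DataFrame  # contig_id, sample_id, depth, breadth, length
    counts: pd.DataFrame  # gene x sample
    contig_lengths: dict[str, int]
    ledger: TruthLedger

    @property
    def gene_lengths(self) -> pd.Series:
        return pd.Series({g.gene_id: g.length_nt for g in self.genes})

    @property
    def gene_genome(self) -> dict[str, str]:
        return {g.gene_id: g.genome_id for g in self.genes}

    @property
    def contig_genome(self) -> dict[str, str]:
        return {g.contig_id: g.genome_id for g in self.genes}

    @property
    def genome_habitat(self) -> dict[str, str]:
        return dict(zip(self.genomes["genome_id"], self.genomes["habitat"]))

    @property
    def sample_habitat(self) -> dict[str, str]:
        return dict(zip(self.samples["sample_id"], self.samples["habitat"]))

    def write(self, out_dir: str | Path) -> dict:
        """Emit every fixture file plus ledger TSVs and a checksum manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_gene_table(self.genes, out / "genes.tsv")
        self.genomes.to_csv(out / "genomes.tsv", sep="\t", index=False)
        self.samples.to_csv(out / "samples.tsv", sep="\t", index=False)
        write_domtblout(self.dbcan_hits, out / "dbcan_hmm.domtbl")
        write_domtblout(self.sub_hits, out / "dbcan_sub.domtbl")
        write_family_ec_map(self.subfamily_ecs, out / "subfamily_ec_map.tsv")
        write_domtblout(self.tf_hits, out / "tf.domtbl")
        write_domtblout(self.stp_hits, out / "stp.domtbl")
        write_domtblout(self.tcdoms_hits, out / "tcdoms.domtbl")
        write_blast_tab(self.tcdb_hits, out / "tcdb.tsv")
        write_blast_tab(self.cazydb_hits, out / "cazydb.tsv")
        with open(out / "cazydb_meta.tsv", "w") as fh:
            fh.write("subject_id\tec_numbers\tfamily\tpul_id\trole\n")
            seen = set()
            for h in self.cazydb_hits:
                if h.subject_id in seen:
                    continue
                seen.add(h.subject_id)
                fh.write(
                    f"{h.subject_id}\t{','.join(sorted(h.subject_ec))}\t"
                    f"{h.subject_family or ''}\t\t\n"
                )
        write_blast_tab(self.pul_hits, out / "pul_hits.tsv")
        with open(out / "pul_meta.tsv", "w") as fh:
            fh.write("subject_id\tec_numbers\tfamily\tpul_id\trole\n")
            for pid in sorted(self.maps.pul_db):
                for subject_id, role in self.maps.pul_db[pid].members:
                    fh.write(f"{subject_id}\t\t\t{pid}\t{role.value}\n")
        write_ko_table(self.dram_kos, out / "dram_ko.tsv")
        write_ko_table(self.kegg_kos, out / "kegg_ko.tsv")
        write_family_ec_map(self.maps.family_ec_map, out / "family_ec_map.tsv")
        write_substrate_map(self.maps.substrate_map, out / "substrate_map.tsv")
        write_pul_db(self.maps.pul_db, out / "pul_db.tsv")
        write_coverage_table(self.coverage, out / "coverage.tsv")
        write_matrix(self.counts, out / "counts.tsv")
        for name, frame in self.ledger.frames().items():
            frame.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        manifest = {"seed": self.config.seed, "files": {}}
        for path in sorted(out.glob("*.tsv")) + sorted(out.glob("*.domtbl")):
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            manifest["files"][path.name] = digest
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest


# ---------------------------------------------------------------------------
# Reference vocabulary
# ---------------------------------------------------------------------------


def _build_references(cfg: SimConfig) -> tuple[list[str], dict[str, list[str]], ReferenceMaps, list[str]]:
    """Family pools, family->EC map, (family, EC)->substrate map, PUL db."""
    n = cfg.n_families
    n_gh = max(2, int(round(n * 0.5)))
    rest = n - n_gh
    classes = ["PL", "CE", "CBM", "GT", "AA"]
    families = [f"GH{i + 1}" for i in range(n_gh)]
    for i in range(rest):
        families.append(f"{classes[i % len(classes)]}{i // len(classes) + 1}")
    substrates = [f"S{i + 1:02d}" for i in range(cfg.n_substrates)]
    fam_ec: dict[str, frozenset[str]] = {}
    sub_map: dict[tuple[str, str], frozenset[str]] = {}
    for i, fam in enumerate(families):
        ecs = {f"3.2.1.{i + 1}"}
        if i % 4 == 0:
            ecs.add(f"3.2.1.{100 + i}")
        fam_ec[fam] = frozenset(ecs)
        # degradative classes map to a substrate; GT/AA stay unmapped
        if not fam.startswith(("GT", "AA")):
            sub = substrates[i % cfg.n_substrates]
            for ec in ecs:
                sub_map[(fam, ec)] = frozenset({sub})
    pul_db: dict[str, PulEntry] = {}
    for i, sub in enumerate(substrates):
        pid = f"PUL{i + 1:03d}"
        pul_db[pid] = PulEntry(
            pid,
            sub,
            ((f"{pid}_caz", Role.CAZYME), (f"{pid}_tc", Role.TRANSPORTER)),
        )
    # sediment draws on the full pool; water on a GH-poorer subset
    pools = {
        "sediment": families,
        "water": families[n_gh // 2 :],
    }
    maps = ReferenceMaps(fam_ec, sub_map, pul_db)
    return families, pools, maps, substrates


def _substrate_families(
    maps: ReferenceMaps, substrates: list[str]
) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {s: [] for s in substrates}
    for (fam, _ec), subs in maps.substrate_map.items():
        for s in subs:
            if fam not in out[s]:
                out[s].append(fam)
    return out


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Negative binomial with the given mean and size/dispersion parameter."""
    if mean <= 0:
        return 0
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


class _Builder:
    def __init__(self, cfg: SimConfig):
        self.cfg = cfg
        ss = np.random.SeedSequence(cfg.seed)
        streams = ss.spawn(8)
        self.rng_layout = np.random.default_rng(streams[0])
        self.rng_hits = np.random.default_rng(streams[1])
        self.rng_decoy = np.random.default_rng(streams[2])
        self.rng_cgc = np.random.default_rng(streams[3])
        self.rng_cov = np.random.default_rng(streams[4])
        self.rng_counts = np.random.default_rng(streams[5])
        self.rng_expr = np.random.default_rng(streams[6])
        self.rng_qual = np.random.default_rng(streams[7])

        self.families, self.pools, self.maps, self.substrates = _build_references(cfg)
        self.sub_fams = _substrate_families(self.maps, self.substrates)
        self.ledger = TruthLedger()
        self.genes: list[GeneRecord] = []
        self.dbcan: list[DomainHit] = []
        self.sub_hits: list[DomainHit] = []
        self.subfamily_ecs: dict[str, frozenset[str]] = {}
        self.tf: list[DomainHit] = []
        self.stp: list[DomainHit] = []
        self.tcdoms: list[DomainHit] = []
        self.tcdb: list[AlignmentHit] = []
        self.cazydb: list[AlignmentHit] = []
        self.pul_hits: list[AlignmentHit] = []
        self.dram: list[KoAnnotation] = []
        self.kegg: list[KoAnnotation] = []
        self.contig_lengths: dict[str, int] = {}
        self._gene_n = 0

    # -- primitives -----------------------------------------------------

    def _new_contig(self, genome_id: str, k: int) -> str:
        return f"{genome_id}_c{k}"

    def _add_gene(
        self, contig_id: str, genome_id: str, idx: int, cursor: int
    ) -> tuple[GeneRecord, int]:
        cfg = self.cfg
        rng = self.rng_layout
        gap = int(rng.integers(20, 201))
        length = int(rng.integers(cfg.gene_length_nt[0], cfg.gene_length_nt[1] + 1))
        length -= length % 3
        length = max(length, 300)
        start = cursor + gap
        end = start + length - 1
        self._gene_n += 1
        gene = GeneRecord(
            gene_id=f"g{self._gene_n:06d}",
            contig_id=contig_id,
            genome_id=genome_id,
            index_on_contig=idx,
            start=start,
            end=end,
            strand="+" if rng.random() < 0.5 else "-",
            has_signal_peptide=bool(rng.random() < 0.3),
        )
        self.genes.append(gene)
        return gene, end

    def _true_domain_hit(
        self,
        gene: GeneRecord,
        family: str,
        window: Optional[tuple[int, int]] = None,
    ) -> DomainHit:
        """E at least a decade under 1e-18, coverage in [0.40, 1.0].

        ``window`` restricts the protein alignment to a 1-based aa interval
        so that multi-domain genes get non-overlapping matches.
        """
        rng = self.rng_hits
        hmm_len = int(rng.integers(80, 401))
        cov = rng.uniform(0.40, 1.0)
        span = max(1, min(hmm_len, int(round(cov * hmm_len))))
        span = max(span, int(np.ceil(0.40 * hmm_len)))
        hmm_from = int(rng.integers(1, hmm_len - span + 2))
        aa = gene.length_nt // 3
        lo, hi = window if window is not None else (1, aa)
        ali_span = min(span, hi - lo + 1)
        ali_from = lo + int(rng.integers(0, (hi - lo + 1) - ali_span + 1))
        return DomainHit(
            gene_id=gene.gene_id,
            family=family,
            hmm_length=hmm_len,
            hmm_from=hmm_from,
            hmm_to=hmm_from + span - 1,
            ali_from=ali_from,
            ali_to=ali_from + ali_span - 1,
            i_evalue=float(10 ** -rng.uniform(19.0, 40.0)),
            score=float(rng.uniform(80, 500)),
        )

    def _decoy_domain_hit(self, gene: GeneRecord) -> DomainHit:
        """Fails the thresholds by construction: E >= 1e-17 or coverage <= 0.30."""
        rng = self.rng_decoy
        family = self.families[int(rng.integers(len(self.families)))]
        hmm_len = int(rng.integers(80, 401))
        if rng.random() < 0.5:  # E-value decoy
            evalue = float(10 ** -rng.uniform(5.0, 17.0))
            cov = rng.uniform(0.40, 0.95)
        else:  # coverage decoy
            evalue = float(10 ** -rng.uniform(19.0, 40.0))
            cov = rng.uniform(0.05, 0.30)
        span = max(1, min(hmm_len, int(cov * hmm_len)))
        hmm_from = int(rng.integers(1, hmm_len - span + 2))
        aa = max(1, gene.length_nt // 3)
        ali_span = min(span, aa)
        ali_from = int(rng.integers(1, max(1, aa - ali_span + 1) + 1))
        return DomainHit(
            gene_id=gene.gene_id,
            family=family,
            hmm_length=hmm_len,
            hmm_from=hmm_from,
            hmm_to=hmm_from + span - 1,
            ali_from=ali_from,
            ali_to=ali_from + ali_span - 1,
            i_evalue=evalue,
            score=float(rng.uniform(10, 60)),
        )

    def _emit_ec_evidence(
        self,
        gene: GeneRecord,
        families: list[str],
        route: int,
        windows: list[tuple[int, int]],
    ) -> frozenset[str]:
        """Plant the evidence for the chosen cascade route; return true ECs."""
        ecs = frozenset().union(*(self.maps.family_ec_map[f] for f in families))
        rng = self.rng_hits
        if route == 1:
            for fam, window in zip(families, windows):
                subfam = f"{fam}_sub1"
                self.subfamily_ecs[subfam] = self.maps.family_ec_map[fam]
                base = self._true_domain_hit(gene, subfam, window)
                self.sub_hits.append(
                    dataclasses.replace(base, ec_numbers=self.maps.family_ec_map[fam])
                )
            # a conflicting lower-priority candidate exercises precedence
            if rng.random() < 0.3:
                self.cazydb.append(
                    AlignmentHit(
                        query_id=gene.gene_id,
                        subject_id=f"ref_{families[0]}_alt",
                        pident=float(rng.uniform(40, 90)),
                        qcov=float(rng.uniform(75, 99)),
                        evalue=float(10 ** -rng.uniform(110, 180)),
                        bitscore=float(rng.uniform(300, 900)),
                        subject_ec=frozenset({"9.9.9.9"}),
                        subject_family=families[0],
                    )
                )
        elif route == 2:
            self.dram.append(
                KoAnnotation(gene.gene_id, f"K{rng.integers(10000, 20000):05d}", ecs, KoSource.DRAM)
            )
        elif route == 3:
            for fam in families:
                self.cazydb.append(
                    AlignmentHit(
                        query_id=gene.gene_id,
                        subject_id=f"ref_{fam}",
                        pident=float(rng.uniform(40, 90)),
                        qcov=float(rng.uniform(75, 99)),
                        evalue=float(10 ** -rng.uniform(110, 180)),
                        bitscore=float(rng.uniform(300, 900)),
                        subject_ec=self.maps.family_ec_map[fam],
                        subject_family=fam,
                    )
                )
        elif route == 4:
            self.kegg.append(
                KoAnnotation(
                    gene.gene_id, f"K{rng.integers(20000, 30000):05d}", ecs, KoSource.KEGG_BLAST
                )
            )
        else:  # no EC evidence
            return frozenset()
        return ecs

    def _plant_cazyme(
        self, gene: GeneRecord, habitat: str, family: Optional[str] = None, route: Optional[int] = None
    ) -> GeneTruth:
        rng = self.rng_hits
        pool = self.pools[habitat]
        families = [family or pool[int(rng.integers(len(pool)))]]
        if family is None and rng.random() < self.cfg.p_multi_family:
            extra = pool[int(rng.integers(len(pool)))]
            if extra not in families:
                families.append(extra)
        # disjoint protein windows keep multi-domain matches non-overlapping
        aa = gene.length_nt // 3
        k = len(families)
        windows = [
            (1 + i * (aa // k), (i + 1) * (aa // k) if i < k - 1 else aa)
            for i in range(k)
        ]
        for fam, window in zip(families, windows):
            self.dbcan.append(self._true_domain_hit(gene, fam, window))
        if route is None:
            route = 1 + int(
                rng.choice(5, p=np.asarray(self.cfg.route_probs, dtype=float))
            )
        ecs = self._emit_ec_evidence(gene, families, route, windows)
        subs: set[str] = set()
        for fam in families:
            for ec in ecs:
                subs |= self.maps.substrate_map.get((fam, ec), frozenset())
        truth = GeneTruth(frozenset(families), ecs, frozenset(subs), Role.CAZYME)
        self.ledger.genes[gene.gene_id] = truth
        return truth

    def _plant_signature(self, gene: GeneRecord, role: Role) -> None:
        rng = self.rng_cgc
        if role is Role.TRANSPORTER:
            self.tcdb.append(
                AlignmentHit(
                    query_id=gene.gene_id,
                    subject_id=f"tcdb_{rng.integers(1, 500)}",
                    pident=float(rng.uniform(40, 90)),
                    qcov=float(rng.uniform(50, 99)),
                    evalue=float(10 ** -rng.uniform(12.0, 60.0)),
                    bitscore=float(rng.uniform(100, 600)),
                )
            )
        else:
            hmm_len = int(rng.integers(60, 200))
            span = max(int(np.ceil(0.5 * hmm_len)), 1)
            aa = max(span, gene.length_nt // 3)
            hit = DomainHit(
                gene_id=gene.gene_id,
                family="TF_dom" if role is Role.TF else "STP_dom",
                hmm_length=hmm_len,
                hmm_from=1,
                hmm_to=span,
                ali_from=1,
                ali_to=min(span, aa),
                i_evalue=float(10 ** -rng.uniform(6.0, 30.0)),
                score=float(rng.uniform(30, 200)),
            )
            (self.tf if role is Role.TF else self.stp).append(hit)
        self.ledger.genes[gene.gene_id] = GeneTruth(
            frozenset(), frozenset(), frozenset(), role
        )

    def _plant_null(self, gene: GeneRecord) -> None:
        self.ledger.genes[gene.gene_id] = GeneTruth(
            frozenset(), frozenset(), frozenset(), Role.NULL
        )

    # -- contig builders -------------------------------------------------

    def build_background_contig(self, genome_id: str, habitat: str, k: int) -> None:
        cfg = self.cfg
        contig = self._new_contig(genome_id, k)
        n_genes = int(self.rng_layout.integers(cfg.genes_per_contig[0], cfg.genes_per_contig[1] + 1))
        cursor = 0
        for idx in range(n_genes):
            gene, cursor = self._add_gene(contig, genome_id, idx, cursor)
            if self.rng_hits.random() < cfg.cazyme_prob(habitat):
                self._plant_cazyme(gene, habitat)
            else:
                self._plant_null(gene)
        self.contig_lengths[contig] = cursor + 100

    def build_core_contig(self, genome_id: str, habitat: str, k: int) -> None:
        """One guaranteed single-substrate gene for the core substrate."""
        cfg = self.cfg
        contig = self._new_contig(genome_id, k)
        gene, cursor = self._add_gene(contig, genome_id, 0, 0)
        pool = set(self.pools[habitat])
        fams = [f for f in self.sub_fams[cfg.core_substrate] if f in pool]
        fams = fams or self.sub_fams[cfg.core_substrate]
        fam = fams[int(self.rng_hits.integers(len(fams)))]
        self._plant_cazyme(gene, habitat, family=fam, route=1)
        self.contig_lengths[contig] = cursor + 100

    def build_cluster_contig(
        self, genome_id: str, habitat: str, k: int, decoy: bool
    ) -> None:
        """A dedicated contig holding one planted cluster (or decoy)."""
        rng = self.rng_cgc
        contig = self._new_contig(genome_id, k)
        # substrates and families drawn within the habitat's family pool
        pool = set(self.pools[habitat])
        eligible = [
            s for s in self.substrates if any(f in pool for f in self.sub_fams[s])
        ]
        substrate = eligible[int(rng.integers(len(eligible)))]
        fams = [f for f in self.sub_fams[substrate] if f in pool]
        other_roles = [Role.TRANSPORTER, Role.TF, Role.STP]
        if not decoy:
            sig_roles = [Role.CAZYME, Role.CAZYME, other_roles[int(rng.integers(3))]]
            for _ in range(int(rng.integers(0, 3))):
                sig_roles.append(
                    [Role.CAZYME, Role.TRANSPORTER, Role.TF, Role.STP][int(rng.integers(4))]
                )
            rng.shuffle(sig_roles)
            gaps = [int(rng.integers(0, 3)) for _ in range(len(sig_roles) - 1)]
        elif rng.random() < 0.5:  # gap-3 decoy: chain breaks
            sig_roles = [Role.CAZYME, other_roles[int(rng.integers(3))]]
            gaps = [3]
        else:  # no-other-signature decoy
            sig_roles = [Role.CAZYME, Role.CAZYME]
            gaps = [int(rng.integers(0, 3))]
        layout: list[Optional[Role]] = [None, None]  # leading padding
        for i, role in enumerate(sig_roles):
            layout.append(role)
            if i < len(gaps):
                layout.extend([None] * gaps[i])
        layout.extend([None, None])
        cursor = 0
        sig_indices: list[int] = []
        caz_members: list[GeneRecord] = []
        other_members: list[GeneRecord] = []
        for idx, role in enumerate(layout):
            gene, cursor = self._add_gene(contig, genome_id, idx, cursor)
            if role is None:
                self._plant_null(gene)
                continue
            sig_indices.append(idx)
            if role is Role.CAZYME:
                fam = fams[int(self.rng_hits.integers(len(fams)))]
                self._plant_cazyme(gene, habitat, family=fam, route=1)
                caz_members.append(gene)
            else:
                self._plant_signature(gene, role)
                other_members.append(gene)
        self.contig_lengths[contig] = cursor + 100
        if decoy:
            return
        # homology evidence toward the matching reference PUL
        pul_id = f"PUL{self.substrates.index(substrate) + 1:03d}"
        for member, subject in (
            (caz_members[0], f"{pul_id}_caz"),
            ((other_members or caz_members)[0], f"{pul_id}_tc"),
        ):
            self.pul_hits.append(
                AlignmentHit(
                    query_id=member.gene_id,
                    subject_id=subject,
                    pident=float(rng.uniform(40, 95)),
                    qcov=float(rng.uniform(60, 99)),
                    evalue=float(10 ** -rng.uniform(110.0, 180.0)),
                    bitscore=float(rng.uniform(300, 800)),
                )
            )
        if rng.random() < 0.3 and len(caz_members) > 1:
            # strong but ineligible distractor: only a CAZyme matches
            wrong = f"PUL{int(rng.integers(len(self.substrates))) + 1:03d}"
            if wrong != pul_id:
                self.pul_hits.append(
                    AlignmentHit(
                        query_id=caz_members[1].gene_id,
                        subject_id=f"{wrong}_caz",
                        pident=50.0,
                        qcov=90.0,
                        evalue=1e-150,
                        bitscore=2000.0,
                    )
                )
        self.ledger.cgcs.append(
            CgcTruth(
                contig_id=contig,
                start_index=sig_indices[0],
                end_index=sig_indices[-1],
                substrate=substrate,
                pul_id=pul_id,
                n_cazyme=len(caz_members),
            )
        )

    # -- coverage / expression / counts ----------------------------------

    def build_samples(self) -> pd.DataFrame:
        rows = [
            {"sample_id": f"{hab}_s{i + 1}", "habitat": hab}
            for hab in HABITATS
            for i in range(self.cfg.n_samples_per_habitat)
        ]
        return pd.DataFrame(rows)

    def build_coverage_and_counts(
        self, genomes: pd.DataFrame, samples: pd.DataFrame
    ) -> tuple[pd.DataFrame, pd.DataFrame]:
        cfg = self.cfg
        mean_expr, mean_silent, disp = cfg.count_model
        genome_habitat = dict(zip(genomes["genome_id"], genomes["habitat"]))
        contigs_by_genome: dict[str, list[str]] = {}
        for g in self.genes:
            if g.contig_id not in contigs_by_genome.setdefault(g.genome_id, []):
                contigs_by_genome[g.genome_id].append(g.contig_id)
        genes_by_genome: dict[str, list[GeneRecord]] = {}
        for g in self.genes:
            genes_by_genome.setdefault(g.genome_id, []).append(g)

        # habitat-level expression state, one draw per (genome, substrate)
        expr_state: dict[tuple[str, str], bool] = {}
        hk_state: dict[str, bool] = {}
        for genome, habitat in genome_habitat.items():
            for sub in self.substrates:
                expr_state[(genome, sub)] = bool(
                    self.rng_expr.random() < cfg.expr_prob(habitat, sub)
                )
            for g in genes_by_genome.get(genome, []):
                hk_state[g.gene_id] = bool(self.rng_expr.random() < cfg.p_housekeeping)

        cov_rows = []
        count_cols: dict[str, np.ndarray] = {}
        gene_ids = [g.gene_id for g in self.genes]
        gene_pos = {g: i for i, g in enumerate(gene_ids)}
        for _, sample in samples.iterrows():
            sid, s_hab = sample["sample_id"], sample["habitat"]
            col = np.zeros(len(gene_ids), dtype=int)
            for genome, habitat in genome_habitat.items():
                own = habitat == s_hab
                present = own and bool(self.rng_cov.random() < cfg.p_present)
                self.ledger.presence[(genome, sid)] = present
                if cfg.noise_free:
                    breadth = 0.8 if present else 0.0
                    depth = 20.0 if present else 0.0
                else:
                    if present:
                        breadth = float(self.rng_cov.uniform(0.30, 0.95))
                        depth = float(self.rng_cov.uniform(5.0, 50.0))
                    else:
                        breadth = float(self.rng_cov.uniform(0.0, 0.05))
                        depth = float(breadth * self.rng_cov.uniform(0.5, 2.0))
                        if breadth == 0.0:
                            depth = 0.0
                for contig in contigs_by_genome.get(genome, []):
                    cov_rows.append(
                        {
                            "contig_id": contig,
                            "sample_id": sid,
                            "depth": depth,
                            "breadth": breadth,
                            "length": self.contig_lengths[contig],
                        }
                    )
                for g in genes_by_genome.get(genome, []):
                    truth = self.ledger.genes[g.gene_id]
                    if not present:
                        expressed = False
                    elif truth.substrates:
                        primary = min(truth.substrates)
                        expressed = expr_state[(genome, primary)]
                    else:
                        expressed = hk_state[g.gene_id]
                    self.ledger.expression[(g.gene_id, sid)] = expressed
                    if cfg.noise_free:
                        count = max(5, int(round(mean_expr))) if expressed else 0
                    else:
                        count = (
                            _nb_draw(self.rng_counts, mean_expr, disp)
                            if expressed
                            else _nb_draw(self.rng_counts, mean_silent, disp)
                        )
                    col[gene_pos[g.gene_id]] = count
            count_cols[sid] = col
        coverage = pd.DataFrame(cov_rows)
        counts = pd.DataFrame(count_cols, index=pd.Index(gene_ids, name="gene_id"))
        return coverage, counts

    def build_genomes(self) -> pd.DataFrame:
        rows = []
        for hab in HABITATS:
            prefix = "W" if hab == "water" else "D"
            for i in range(self.cfg.n_genomes_per_habitat):
                rows.append(
                    {
                        "genome_id": f"{prefix}{i + 1:03d}",
                        "habitat": hab,
                        "completeness": float(self.rng_qual.uniform(60, 100)),
                        "contamination": float(self.rng_qual.uniform(0, 4)),
                    }
                )
        return pd.DataFrame(rows)

    def add_decoy_hits(self) -> None:
        if self.cfg.decoy_rate <= 0:
            return
        for gene in self.genes:
            for _ in range(int(self.rng_decoy.poisson(self.cfg.decoy_rate))):
                self.dbcan.append(self._decoy_domain_hit(gene))


def generate(config: SimConfig) -> SyntheticStudy:
    """Build the full deterministic fixture set and its truth ledger."""
    if config.core_substrate is not None:
        valid = {f"S{i + 1:02d}" for i in range(config.n_substrates)}
        if config.core_substrate not in valid:
            raise SimulationError(f"core_substrate {config.core_substrate!r} not in {sorted(valid)}")
    b = _Builder(config)
    genomes = b.build_genomes()
    samples = b.build_samples()
    # distribute planted clusters and decoys round-robin over genomes
    genome_list = list(zip(genomes["genome_id"], genomes["habitat"]))
    cluster_counter: dict[str, int] = {g: 0 for g, _ in genome_list}
    plan: list[tuple[str, str, bool]] = []
    for j in range(config.n_planted_cgcs):
        g, h = genome_list[j % len(genome_list)]
        plan.append((g, h, False))
    for j in range(config.n_decoy_cgcs):
        g, h = genome_list[(j + config.n_planted_cgcs) % len(genome_list)]
        plan.append((g, h, True))
    next_contig: dict[str, int] = {}
    for genome_id, habitat in genome_list:
        n_bg = int(
            b.rng_layout.integers(config.contigs_per_genome[0], config.contigs_per_genome[1] + 1)
        )
        k = 1
        for _ in range(n_bg):
            b.build_background_contig(genome_id, habitat, k)
            k += 1
        if config.core_substrate is not None:
            b.build_core_contig(genome_id, habitat, k)
            k += 1
        next_contig[genome_id] = k
    for genome_id, habitat, decoy in plan:
        b.build_cluster_contig(genome_id, habitat, next_contig[genome_id], decoy)
        next_contig[genome_id] += 1
    b.add_decoy_hits()
    coverage, counts = b.build_coverage_and_counts(genomes, samples)
    return SyntheticStudy(
        config=config,
        genes=b.genes,
        genomes=genomes,
        samples=samples,
        dbcan_hits=b.dbcan,
        sub_hits=b.sub_hits,
        subfamily_ecs=b.subfamily_ecs,
        tf_hits=b.tf,
        stp_hits=b.stp,
        tcdoms_hits=b.tcdoms,
        tcdb_hits=b.tcdb,
        cazydb_hits=b.cazydb,
        pul_hits=b.pul_hits,
        dram_kos=b.dram,
        kegg_kos=b.kegg,
        maps=b.maps,
        coverage=coverage,
        counts=counts,
        contig_lengths=b.contig_lengths,
        ledger=b.ledger,
    )


def scenario_estuary(
    seed: int,
    n_genomes_per_habitat: int = 25,
    noise_free: bool = False,
    **overrides,
) -> SimConfig:
    """Estuary-like study conditions: sediment communities encode CAZymes
    more densely (and over a larger family pool), water communities express
    a larger fraction of the substrates they encode."""
    params = dict(
        seed=seed,
        n_genomes_per_habitat=n_genomes_per_habitat,
        n_samples_per_habitat=3,
        p_cazyme={"water": 0.15, "sediment": 0.30},
        expression_prob={"water": 0.85, "sediment": 0.45},
        n_planted_cgcs=max(4, n_genomes_per_habitat // 3),
        n_decoy_cgcs=max(4, n_genomes_per_habitat // 3),
        decoy_rate=0.5,
        noise_free=noise_free,
    )
    params.update(overrides)
    return SimConfig(**params)
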