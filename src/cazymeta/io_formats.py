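"""Readers and writers for every external table the pipeline touches.

Domain types defined here (:class:`DomainHit`, :class:`AlignmentHit`,
:class:`GeneRecord`, :class:`GenomeQuality`, :class:`ReferenceMaps`) are the
only currency downstream modules accept; parsing and serialisation stay in
this module.

Conventions
-----------
* All coordinates are 1-based inclusive (HMMER / GFF convention).
* HMMER per-domain tables (``domtblout``) are read in ``hmmsearch``
  orientation by default: the profile is the query, the protein the target.
* BLAST/DIAMOND tabular files are outfmt-6
  (``qseqid sseqid pident length mismatch gapopen qstart qend sstart send
  evalue bitscore``) with an optional 13th ``qcovhsp`` column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "DomainHit",
    "AlignmentHit",
    "GeneRecord",
    "GenomeQuality",
    "KoAnnotation",
    "KoSource",
    "PulEntry",
    "ReferenceMaps",
    "Role",
    "ParseError",
    "read_domtblout",
    "write_domtblout",
    "attach_subfamily_ecs",
    "read_blast_tab",
    "write_blast_tab",
    "read_subject_metadata",
    "read_gene_table",
    "write_gene_table",
    "read_matrix",
    "write_matrix",
    "read_genome_table",
    "read_ko_table",
    "write_ko_table",
    "read_family_ec_map",
    "write_family_ec_map",
    "read_substrate_map",
    "write_substrate_map",
    "read_pul_db",
    "write_pul_db",
    "read_coverage_table",
    "write_coverage_table",
]


class ParseError(ValueError):
    """Raised when an input table is malformed; carries the line number."""


class Role(str, Enum):
    """Signature-gene role used by CGC detection."""

    CAZYME = "CAZYME"
    TRANSPORTER = "TRANSPORTER"
    TF = "TF"
    STP = "STP"
    NULL = "NULL"


class KoSource(str, Enum):
    DRAM = "DRAM"
    KEGG_BLAST = "KEGG_BLAST"


@dataclass(frozen=True)
class DomainHit:
    """One HMM-profile match on one gene.

    ``ec_numbers`` is empty for plain dbCAN hits; dbCAN-sub subfamily hits
    carry their curated EC metadata here (see :func:`attach_subfamily_ecs`).
    """

    gene_id: str
    family: str
    hmm_length: int
    hmm_from: int
    hmm_to: int
    ali_from: int
    ali_to: int
    i_evalue: float
    score: float
    ec_numbers: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.hmm_length <= 0:
            raise ValueError(f"hmm_length must be positive, got {self.hmm_length}")
        if not (1 <= self.hmm_from <= self.hmm_to <= self.hmm_length):
            raise ValueError(
                f"invalid profile coordinates {self.hmm_from}..{self.hmm_to} "
                f"on profile of length {self.hmm_length}"
            )
        if not (1 <= self.ali_from <= self.ali_to):
            raise ValueError(f"invalid query coordinates {self.ali_from}..{self.ali_to}")
        if self.i_evalue < 0:
            raise ValueError(f"i_evalue must be non-negative, got {self.i_evalue}")

    @property
    def hmm_coverage(self) -> float:
        """Fraction of the HMM profile covered by this match."""
        return (self.hmm_to - self.hmm_from + 1) / self.hmm_length

    @property
    def ali_length(self) -> int:
        return self.ali_to - self.ali_from + 1


@dataclass(frozen=True)
class AlignmentHit:
    """One DIAMOND/BLAST pairwise hit with optional subject metadata."""

    query_id: str
    subject_id: str
    pident: float
    qcov: float  # percent; NaN when the file had no qcovhsp column
    evalue: float
    bitscore: float
    subject_ec: frozenset[str] = frozenset()
    subject_family: Optional[str] = None
    subject_pul_id: Optional[str] = None
    subject_role: Optional[Role] = None

    def __post_init__(self) -> None:
        if not (0 <= self.pident <= 100):
            raise ValueError(f"pident out of range: {self.pident}")
        if not math.isnan(self.qcov) and not (0 <= self.qcov <= 100):
            raise ValueError(f"qcov out of range: {self.qcov}")
        if self.evalue < 0:
            raise ValueError(f"evalue must be non-negative, got {self.evalue}")


@dataclass(frozen=True)
class GeneRecord:
    """A gene with contig/genome membership and contig order index."""

    gene_id: str
    contig_id: str
    genome_id: str
    index_on_contig: int
    start: int
    end: int
    strand: str
    has_signal_peptide: bool = False
    role: Role = Role.NULL

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1

    def with_role(self, role: Role) -> "GeneRecord":
        return replace(self, role=role)


@dataclass(frozen=True)
class GenomeQuality:
    genome_id: str
    completeness: float
    contamination: float

    def __post_init__(self) -> None:
        if not (0 <= self.completeness <= 100):
            raise ValueError(f"completeness out of range: {self.completeness}")
        if not (0 <= self.contamination <= 100):
            raise ValueError(f"contamination out of range: {self.contamination}")


@dataclass(frozen=True)
class KoAnnotation:
    gene_id: str
    ko_id: str
    ec_numbers: frozenset[str]
    source: KoSource


@dataclass(frozen=True)
class PulEntry:
    """One reference polysaccharide utilization locus."""

    pul_id: str
    substrate: str
    members: tuple[tuple[str, Role], ...]  # (subject protein id, role)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"PUL {self.pul_id} has no members")


@dataclass(frozen=True)
class ReferenceMaps:
    """Curated lookup tables: family->ECs, (family, EC)->substrates, PUL db."""

    family_ec_map: Mapping[str, frozenset[str]]
    substrate_map: Mapping[tuple[str, str], frozenset[str]]
    pul_db: Mapping[str, PulEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for fam, _ec in self.substrate_map:
            if fam not in self.family_ec_map:
                raise ValueError(
                    f"substrate_map family {fam!r} absent from family_ec_map"
                )


# ---------------------------------------------------------------------------
# HMMER per-domain tables
# ---------------------------------------------------------------------------

_DOMTBL_NCOL = 22  # columns before the free-text description


def _strip_hmm(name: str) -> str:
    return name[:-4] if name.endswith(".hmm") else name


def read_domtblout(path: str | Path, *, query_is_profile: bool = True) -> list[DomainHit]:
    """Parse a HMMER per-domain table into :class:`DomainHit` records.

    With ``query_is_profile=True`` (the ``hmmsearch`` orientation) the query
    name column is the profile/family and the target is the protein; pass
    ``False`` for ``hmmscan`` output. A trailing ``.hmm`` on the profile name
    is stripped.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split(None, _DOMTBL_NCOL)
            if len(parts) < _DOMTBL_NCOL:
                raise ParseError(
                    f"{path}:{lineno}: expected >= {_DOMTBL_NCOL} columns, got {len(parts)}"
                )
            try:
                if query_is_profile:
                    gene_id, family = parts[0], _strip_hmm(parts[3])
                    hmm_length = int(parts[5])
                else:
                    gene_id, family = parts[3], _strip_hmm(parts[0])
                    hmm_length = int(parts[2])
                hit = DomainHit(
                    gene_id=gene_id,
                    family=family,
                    hmm_length=hmm_length,
                    hmm_from=int(parts[15]),
                    hmm_to=int(parts[16]),
                    ali_from=int(parts[17]),
                    ali_to=int(parts[18]),
                    i_evalue=float(parts[12]),
                    score=float(parts[13]),
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_domtblout(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write hits in the HMMER per-domain column order (hmmsearch orientation)."""
    with open(path, "w") as fh:
        fh.write("# target name - tlen query name - qlen E-value score bias "
                 "# of c-Evalue i-Evalue score bias hmm_from hmm_to ali_from "
                 "ali_to env_from env_to acc description\n")
        for h in hits:
            tlen = h.ali_to  # protein length is not modelled; upper bound
            fh.write(
                f"{h.gene_id} - {tlen} {h.family} - {h.hmm_length} "
                f"{h.i_evalue:.12g} {h.score:.12g} 0.0 1 1 "
                f"{h.i_evalue:.12g} {h.i_evalue:.12g} {h.score:.12g} 0.0 "
                f"{h.hmm_from} {h.hmm_to} {h.ali_from} {h.ali_to} "
                f"{h.ali_from} {h.ali_to} 0.90 -\n"
            )


def attach_subfamily_ecs(
    hits: Sequence[DomainHit], subfamily_ecs: Mapping[str, Iterable[str]]
) -> list[DomainHit]:
    """Attach curated subfamily EC metadata to hits by profile name."""
    out = []
    for h in hits:
        ecs = frozenset(subfamily_ecs.get(h.family, ()))
        out.append(replace(h, ec_numbers=ecs) if ecs else h)
    return out


# ---------------------------------------------------------------------------
# BLAST/DIAMOND tabular
# ---------------------------------------------------------------------------


def read_subject_metadata(path: str | Path) -> dict[str, dict]:
    """Read a subject side table: subject_id, ec_numbers, family, pul_id, role.

    Empty cells mean "no metadata". ``ec_numbers`` is comma-joined.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    meta: dict[str, dict] = {}
    for row in df.itertuples(index=False):
        meta[row.subject_id] = {
            "ec_numbers": frozenset(e for e in str(getattr(row, "ec_numbers", "")).split(",") if e),
            "family": getattr(row, "family", "") or None,
            "pul_id": getattr(row, "pul_id", "") or None,
            "role": Role(getattr(row, "role")) if getattr(row, "role", "") else None,
        }
    return meta


def read_blast_tab(
    path: str | Path,
    metadata: Optional[Mapping[str, Mapping]] = None,
    *,
    strict: bool = False,
) -> list[AlignmentHit]:
    """Parse outfmt-6 TSV; join subject metadata where available.

    In strict mode every subject must appear in ``metadata``; the default is
    lenient because public database dumps are incomplete.
    """
    hits: list[AlignmentHit] = []
    missing: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 12:
                raise ParseError(f"{path}:{lineno}: expected >= 12 columns, got {len(parts)}")
            try:
                qcov = float(parts[12]) if len(parts) > 12 and parts[12] != "" else float("nan")
                meta = (metadata or {}).get(parts[1])
                if metadata is not None and meta is None:
                    missing.append(parts[1])
                    meta = {}
                meta = meta or {}
                hits.append(
                    AlignmentHit(
                        query_id=parts[0],
                        subject_id=parts[1],
                        pident=float(parts[2]),
                        qcov=qcov,
                        evalue=float(parts[10]),
                        bitscore=float(parts[11]),
                        subject_ec=frozenset(meta.get("ec_numbers", ())),
                        subject_family=meta.get("family"),
                        subject_pul_id=meta.get("pul_id"),
                        subject_role=meta.get("role"),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if strict and missing:
        raise ParseError(f"{path}: subjects missing from metadata: {sorted(set(missing))}")
    return hits


def write_blast_tab(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            alen = 100  # placeholder alignment stats; not consumed downstream
            qcov = "" if math.isnan(h.qcov) else f"{h.qcov:.12g}"
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pident:.12g}\t{alen}\t0\t0\t"
                f"1\t{alen}\t1\t{alen}\t{h.evalue:.12g}\t{h.bitscore:.12g}\t{qcov}\n"
            )


# ---------------------------------------------------------------------------
# Gene tables
# ---------------------------------------------------------------------------

_GENE_COLS = ["gene_id", "contig_id", "genome_id", "start", "end", "strand", "signal_peptide"]


def _index_genes(rows: list[dict]) -> list[GeneRecord]:
    """Assign 0-based contig order by ascending (start, end, gene_id)."""
    seen: set[str] = set()
    for r in rows:
        if r["gene_id"] in seen:
            raise ParseError(f"duplicate gene_id {r['gene_id']!r}")
        seen.add(r["gene_id"])
    genes: list[GeneRecord] = []
    by_contig: dict[str, list[dict]] = {}
    contig_order: list[str] = []
    for r in rows:
        if r["contig_id"] not in by_contig:
            contig_order.append(r["contig_id"])
        by_contig.setdefault(r["contig_id"], []).append(r)
    for contig in contig_order:
        ordered = sorted(by_contig[contig], key=lambda r: (r["start"], r["end"], r["gene_id"]))
        for idx, r in enumerate(ordered):
            genes.append(
                GeneRecord(
                    gene_id=r["gene_id"],
                    contig_id=r["contig_id"],
                    genome_id=r["genome_id"],
                    index_on_contig=idx,
                    start=r["start"],
                    end=r["end"],
                    strand=r["strand"],
                    has_signal_peptide=r["signal_peptide"],
                )
            )
    return genes


def _parse_gff_attrs(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read genes from GFF3 or the 7-column TSV exchange format.

    TSV columns: gene_id, contig_id, genome_id, start, end, strand,
    signal_peptide (0/1 or true/false). GFF3 rows of type gene/CDS are used;
    attributes ``ID``, ``genome_id`` and ``signal_peptide`` are honoured.
    ``index_on_contig`` is assigned by ascending start within each contig,
    ties broken by end then gene_id.
    """
    path = Path(path)
    rows: list[dict] = []
    with open(path) as fh:
        first = fh.readline()
        is_gff = first.startswith("##gff-version") or path.suffix in (".gff", ".gff3")
        fh.seek(0)
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                if is_gff:
                    if len(parts) != 9:
                        raise ParseError(f"{path}:{lineno}: expected 9 GFF columns")
                    if parts[2] not in ("gene", "CDS"):
                        continue
                    attrs = _parse_gff_attrs(parts[8])
                    if "ID" not in attrs:
                        raise ParseError(f"{path}:{lineno}: GFF row lacks ID attribute")
                    rows.append(
                        {
                            "gene_id": attrs["ID"],
                            "contig_id": parts[0],
                            "genome_id": attrs.get("genome_id", ""),
                            "start": int(parts[3]),
                            "end": int(parts[4]),
                            "strand": parts[6],
                            "signal_peptide": attrs.get("signal_peptide", "").lower()
                            in ("1", "true", "yes"),
                        }
                    )
                else:
                    if parts == _GENE_COLS:  # header
                        continue
                    if len(parts) != 7:
                        raise ParseError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
                    rows.append(
                        {
                            "gene_id": parts[0],
                            "contig_id": parts[1],
                            "genome_id": parts[2],
                            "start": int(parts[3]),
                            "end": int(parts[4]),
                            "strand": parts[5],
                            "signal_peptide": parts[6].lower() in ("1", "true", "yes"),
                        }
                    )
                if rows and rows[-1]["start"] > rows[-1]["end"]:
                    raise ParseError(
                        f"{path}:{lineno}: start > end for gene {rows[-1]['gene_id']}"
                    )
            except ParseError:
                raise
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return _index_genes(rows)


def write_gene_table(genes: Iterable[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_COLS) + "\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.contig_id}\t{g.genome_id}\t{g.start}\t{g.end}\t"
                f"{g.strand}\t{int(g.has_signal_peptide)}\n"
            )


# ---------------------------------------------------------------------------
# Matrices and long tables
# ---------------------------------------------------------------------------


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a row-ID x sample-ID TSV of non-negative reals.

    Missing cells and negative values are errors; no silent zero-fill.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        bad = [str(c) for c in df.columns[df.isna().any()]]
        raise ParseError(f"{path}: missing cells in columns {bad}")
    if df.size and (df.to_numpy() < 0).any():
        raise ParseError(f"{path}: negative values are not allowed")
    df.columns = df.columns.astype(str)
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_genome_table(path: str | Path) -> pd.DataFrame:
    """Genome metadata: genome_id, habitat, completeness, contamination."""
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str, "habitat": str})
    for col in ("genome_id", "completeness", "contamination"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    # validates bounds
    for row in df.itertuples(index=False):
        GenomeQuality(row.genome_id, float(row.completeness), float(row.contamination))
    return df


def read_coverage_table(path: str | Path) -> pd.DataFrame:
    """Long per-contig coverage: contig_id, sample_id, depth, breadth, length."""
    df = pd.read_csv(path, sep="\t", dtype={"contig_id": str, "sample_id": str})
    required = {"contig_id", "sample_id", "depth", "breadth", "length"}
    if missing := required - set(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if (df["depth"] < 0).any() or ((df["breadth"] < 0) | (df["breadth"] > 1)).any():
        raise ParseError(f"{path}: depth must be >= 0 and breadth in [0, 1]")
    return df


def write_coverage_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# KO tables and reference maps
# ---------------------------------------------------------------------------


def read_ko_table(path: str | Path, source: KoSource) -> list[KoAnnotation]:
    """KO annotations: gene_id, ko_id, ec_numbers (comma-joined, may be empty)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        KoAnnotation(
            gene_id=row.gene_id,
            ko_id=row.ko_id,
            ec_numbers=frozenset(e for e in row.ec_numbers.split(",") if e),
            source=source,
        )
        for row in df.itertuples(index=False)
    ]


def write_ko_table(kos: Iterable[KoAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tko_id\tec_numbers\n")
        for k in kos:
            fh.write(f"{k.gene_id}\t{k.ko_id}\t{','.join(sorted(k.ec_numbers))}\n")


def read_family_ec_map(path: str | Path) -> dict[str, frozenset[str]]:
    """family -> set of EC strings; one (family, ec) pair per row."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.family, set()).add(row.ec)
    return {k: frozenset(v) for k, v in out.items()}


def write_family_ec_map(fam_ec: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("family\tec\n")
        for fam in sorted(fam_ec):
            for ec in sorted(fam_ec[fam]):
                fh.write(f"{fam}\t{ec}\n")


def read_substrate_map(path: str | Path) -> dict[tuple[str, str], frozenset[str]]:
    """(family, ec) -> set of substrate categories; one triple per row."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[tuple[str, str], set[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault((row.family, row.ec), set()).add(row.substrate)
    return {k: frozenset(v) for k, v in out.items()}


def write_substrate_map(
    smap: Mapping[tuple[str, str], Iterable[str]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("family\tec\tsubstrate\n")
        for (fam, ec) in sorted(smap):
            for sub in sorted(smap[(fam, ec)]):
                fh.write(f"{fam}\t{ec}\t{sub}\n")


def read_pul_db(path: str | Path) -> dict[str, PulEntry]:
    """PUL reference: pul_id, substrate, subject_id, role; one member per row."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    members: dict[str, list[tuple[str, Role]]] = {}
    substrate: dict[str, str] = {}
    order: list[str] = []
    for row in df.itertuples(index=False):
        if row.pul_id not in members:
            order.append(row.pul_id)
        members.setdefault(row.pul_id, []).append((row.subject_id, Role(row.role)))
        substrate[row.pul_id] = row.substrate
    return {
        pid: PulEntry(pid, substrate[pid], tuple(members[pid])) for pid in order
    }


def write_pul_db(pul_db: Mapping[str, PulEntry], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pul_id\tsubstrate\tsubject_id\trole\n")
        for pid in sorted(pul_db):
            entry = pul_db[pid]
            for subject_id, role in entry.members:
                fh.write(f"{pid}\t{entry.substrate}\t{subject_id}\t{role.value}\n")
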