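"""End-to-end orchestration: annotate -> EC -> substrates -> CGC -> quant -> stats.

Two entry points: :func:`run_study` executes the whole chain on in-memory
inputs (as produced by :mod:`cazymeta.simulate` or assembled from the
io_formats readers) and returns a :class:`PipelineResult`;
:func:`run_pipeline` reads a fixture directory laid out with the
conventional file names, runs the chain, and writes every stage's TSV
outputs plus a JSON run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import __version__
from .annotation import COV_MIN, E_MAX, CazymeAnnotation, annotate_genes
from .cgc import (
    CGC,
    MAX_GAP,
    PUL_E_MAX,
    TCDB_E_MAX,
    TCDB_QCOV_MIN,
    TF_STP_COV_MIN,
    TF_STP_E_MAX,
    VOTE_MIN,
    annotate_cgc_substrates,
    classify_signature,
    filter_signature_hmm,
    filter_tcdb,
    filter_tcdoms,
    find_cgcs_all,
)
from .ec import CAZYDB_E_MAX, CAZYDB_PID_MIN, CAZYDB_QCOV_MIN, assign_ec_all
from .ecology import SubstrateActivity, expressing_fraction
from .io_formats import (
    AlignmentHit,
    DomainHit,
    GeneRecord,
    GenomeQuality,
    KoAnnotation,
    KoSource,
    ReferenceMaps,
    attach_subfamily_ecs,
    read_blast_tab,
    read_coverage_table,
    read_domtblout,
    read_family_ec_map,
    read_gene_table,
    read_genome_table,
    read_ko_table,
    read_matrix,
    read_pul_db,
    read_subject_metadata,
    read_substrate_map,
)
from .quant import (
    BREADTH_MIN,
    MIN_READ_PAIRS,
    ExpressionTable,
    aggregate_tpm,
    build_expression_table,
    filter_genome_quality,
    genome_coverage,
    per_capita,
)
from .substrates import predict_all_substrates

__all__ = ["RunConfig", "PipelineResult", "StudyInputs", "run_study", "run_pipeline", "load_inputs"]


class ConfigError(ValueError):
    """Bad or missing run configuration."""


@dataclass(frozen=True)
class RunConfig:
    """Every threshold knob of the pipeline with its default."""

    input_dir: str = "."
    output_dir: str = "out"
    e_max: float = E_MAX
    cov_min: float = COV_MIN
    cazydb_e_max: float = CAZYDB_E_MAX
    cazydb_pid_min: float = CAZYDB_PID_MIN
    cazydb_qcov_min: float = CAZYDB_QCOV_MIN
    breadth_min: float = BREADTH_MIN
    min_pairs: int = MIN_READ_PAIRS
    cgc_max_gap: int = MAX_GAP
    cgc_vote_min: int = VOTE_MIN
    tf_stp_e_max: float = TF_STP_E_MAX
    tf_stp_cov_min: float = TF_STP_COV_MIN
    tcdb_e_max: float = TCDB_E_MAX
    tcdb_qcov_min: float = TCDB_QCOV_MIN
    pul_e_max: float = PUL_E_MAX
    min_completeness: float = 50.0
    max_contamination: float = 5.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        raw.update(overrides)
        return cls(**raw)


@dataclass
class StudyInputs:
    """Everything the pipeline consumes, already parsed."""

    genes: list[GeneRecord]
    genomes: pd.DataFrame
    samples: pd.DataFrame
    dbcan_hits: list[DomainHit]
    sub_hits: list[DomainHit]
    tf_hits: list[DomainHit]
    stp_hits: list[DomainHit]
    tcdoms_hits: list[DomainHit]
    tcdb_hits: list[AlignmentHit]
    cazydb_hits: list[AlignmentHit]
    pul_hits: list[AlignmentHit]
    dram_kos: list[KoAnnotation]
    kegg_kos: list[KoAnnotation]
    maps: ReferenceMaps
    coverage: pd.DataFrame
    counts: pd.DataFrame


@dataclass
class PipelineResult:
    annotations: dict[str, CazymeAnnotation]  # families+ECs+substrates
    cgcs: list[CGC]
    retained_genomes: set[str]
    presence: pd.DataFrame
    breadth: pd.DataFrame
    depth: pd.DataFrame
    expression: ExpressionTable
    tpm_by_genome: pd.DataFrame
    per_capita: pd.DataFrame
    activity: list[SubstrateActivity]
    aggregates: dict[str, pd.DataFrame] = field(default_factory=dict)


def _study_to_inputs(study) -> StudyInputs:
    return StudyInputs(
        genes=study.genes,
        genomes=study.genomes,
        samples=study.samples,
        dbcan_hits=study.dbcan_hits,
        sub_hits=study.sub_hits,
        tf_hits=study.tf_hits,
        stp_hits=study.stp_hits,
        tcdoms_hits=study.tcdoms_hits,
        tcdb_hits=study.tcdb_hits,
        cazydb_hits=study.cazydb_hits,
        pul_hits=study.pul_hits,
        dram_kos=study.dram_kos,
        kegg_kos=study.kegg_kos,
        maps=study.maps,
        coverage=study.coverage,
        counts=study.counts,
    )


def run_study(inputs, config: Optional[RunConfig] = None) -> PipelineResult:
    """Execute the full analysis chain on parsed inputs.

    ``inputs`` is a :class:`StudyInputs` or a
    :class:`~cazymeta.simulate.SyntheticStudy`.
    """
    cfg = config or RunConfig()
    if not isinstance(inputs, StudyInputs):
        inputs = _study_to_inputs(inputs)

    # stage 1: CAZy family annotation
    annotations = annotate_genes(inputs.dbcan_hits, cfg.e_max, cfg.cov_min)

    # stage 2: EC cascade
    annotations = assign_ec_all(
        annotations,
        inputs.sub_hits,
        inputs.dram_kos,
        inputs.cazydb_hits,
        inputs.kegg_kos,
        inputs.maps,
    )

    # stage 3: substrates
    annotations = predict_all_substrates(annotations, inputs.maps)

    # stage 4: CGC detection + substrate prediction
    roled = classify_signature(
        inputs.genes,
        filter_signature_hmm(inputs.tf_hits, cfg.tf_stp_e_max, cfg.tf_stp_cov_min),
        filter_signature_hmm(inputs.stp_hits, cfg.tf_stp_e_max, cfg.tf_stp_cov_min),
        filter_tcdb(inputs.tcdb_hits, cfg.tcdb_e_max, cfg.tcdb_qcov_min),
        filter_tcdoms(inputs.tcdoms_hits),
        set(annotations),
    )
    cgcs = find_cgcs_all(roled, cfg.cgc_max_gap)
    cgcs = annotate_cgc_substrates(
        cgcs, inputs.pul_hits, annotations, inputs.maps, cfg.pul_e_max, cfg.cgc_vote_min
    )

    # stage 5: quantification, restricted to quality-filtered genomes
    qualities = [
        GenomeQuality(r.genome_id, float(r.completeness), float(r.contamination))
        for r in inputs.genomes.itertuples(index=False)
    ]
    retained = filter_genome_quality(qualities, cfg.min_completeness, cfg.max_contamination)
    contig_genome = {g.contig_id: g.genome_id for g in inputs.genes}
    gene_genome = {g.gene_id: g.genome_id for g in inputs.genes}
    cov = inputs.coverage[inputs.coverage["contig_id"].map(contig_genome).isin(retained)]
    breadth, depth = genome_coverage(cov, contig_genome)
    presence = breadth >= cfg.breadth_min
    keep_genes = [g for g in inputs.counts.index if gene_genome.get(g) in retained]
    counts = inputs.counts.loc[keep_genes]
    lengths = pd.Series({g.gene_id: g.length_nt for g in inputs.genes})
    expression = build_expression_table(counts, lengths, cfg.min_pairs)
    tpm_gene = aggregate_tpm(expression.tpm, annotations, gene_genome, by="gene")
    tpm_by_genome = (
        tpm_gene.groupby(["genome_id", "sample_id"])["tpm"].sum().unstack(fill_value=0.0)
        if len(tpm_gene)
        else pd.DataFrame()
    )
    pc = per_capita(tpm_by_genome, depth) if len(tpm_by_genome) else pd.DataFrame()

    # stage 6: ecology summaries
    genome_habitat = dict(zip(inputs.genomes["genome_id"], inputs.genomes["habitat"]))
    sample_habitat = dict(zip(inputs.samples["sample_id"], inputs.samples["habitat"]))
    activity = expressing_fraction(
        presence, expression.expressed, annotations, gene_genome, genome_habitat, sample_habitat
    )
    aggregates = {
        by: aggregate_tpm(expression.tpm, annotations, gene_genome, by=by)
        for by in ("ec", "family", "substrate")
    }
    return PipelineResult(
        annotations=annotations,
        cgcs=cgcs,
        retained_genomes=retained,
        presence=presence,
        breadth=breadth,
        depth=depth,
        expression=expression,
        tpm_by_genome=tpm_by_genome,
        per_capita=pc,
        activity=activity,
        aggregates=aggregates,
    )


# ---------------------------------------------------------------------------
# Directory-based run
# ---------------------------------------------------------------------------

_REQUIRED_FILES = [
    "genes.tsv",
    "genomes.tsv",
    "samples.tsv",
    "dbcan_hmm.domtbl",
    "family_ec_map.tsv",
    "substrate_map.tsv",
    "coverage.tsv",
    "counts.tsv",
]


def load_inputs(input_dir: str | Path) -> StudyInputs:
    """Read a fixture directory laid out with the conventional file names."""
    d = Path(input_dir)
    missing = [f for f in _REQUIRED_FILES if not (d / f).exists()]
    if missing:
        raise ConfigError(f"{d}: missing required input files: {missing}")

    def opt_dom(name: str) -> list[DomainHit]:
        return read_domtblout(d / name) if (d / name).exists() else []

    def opt_blast(name: str, meta_name: Optional[str] = None) -> list[AlignmentHit]:
        if not (d / name).exists():
            return []
        meta = (
            read_subject_metadata(d / meta_name)
            if meta_name and (d / meta_name).exists()
            else None
        )
        return read_blast_tab(d / name, meta)

    sub_hits = opt_dom("dbcan_sub.domtbl")
    if (d / "subfamily_ec_map.tsv").exists():
        sub_hits = attach_subfamily_ecs(sub_hits, read_family_ec_map(d / "subfamily_ec_map.tsv"))
    samples = pd.read_csv(d / "samples.tsv", sep="\t", dtype=str)
    pul_db = read_pul_db(d / "pul_db.tsv") if (d / "pul_db.tsv").exists() else {}
    maps = ReferenceMaps(
        read_family_ec_map(d / "family_ec_map.tsv"),
        read_substrate_map(d / "substrate_map.tsv"),
        pul_db,
    )
    return StudyInputs(
        genes=read_gene_table(d / "genes.tsv"),
        genomes=read_genome_table(d / "genomes.tsv"),
        samples=samples,
        dbcan_hits=read_domtblout(d / "dbcan_hmm.domtbl"),
        sub_hits=sub_hits,
        tf_hits=opt_dom("tf.domtbl"),
        stp_hits=opt_dom("stp.domtbl"),
        tcdoms_hits=opt_dom("tcdoms.domtbl"),
        tcdb_hits=opt_blast("tcdb.tsv"),
        cazydb_hits=opt_blast("cazydb.tsv", "cazydb_meta.tsv"),
        pul_hits=opt_blast("pul_hits.tsv", "pul_meta.tsv"),
        dram_kos=(
            read_ko_table(d / "dram_ko.tsv", KoSource.DRAM)
            if (d / "dram_ko.tsv").exists()
            else []
        ),
        kegg_kos=(
            read_ko_table(d / "kegg_ko.tsv", KoSource.KEGG_BLAST)
            if (d / "kegg_ko.tsv").exists()
            else []
        ),
        maps=maps,
        coverage=read_coverage_table(d / "coverage.tsv"),
        counts=read_matrix(d / "counts.tsv"),
    )


def write_outputs(result: PipelineResult, out_dir: str | Path) -> dict:
    """Serialise every stage's tables; returns the run manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ann_rows = [
        {
            "gene_id": g,
            "families": ",".join(sorted(a.families)),
            "ec_numbers": ",".join(sorted(a.ec_numbers)),
            "ec_source": a.ec_source.value,
            "substrates": ",".join(sorted(a.substrates)),
        }
        for g, a in sorted(result.annotations.items())
    ]
    pd.DataFrame(ann_rows).to_csv(out / "annotations.tsv", sep="\t", index=False)
    cgc_rows, member_rows = [], []
    for c in result.cgcs:
        b = c.substrate_B
        v = c.substrate_C
        cgc_rows.append(
            {
                "cgc_id": c.cgc_id,
                "contig_id": c.contig_id,
                "start_index": c.start_index,
                "end_index": c.end_index,
                "roles": ",".join(r.value for _, r in c.members),
                "substrate_B": b[0] if b else "",
                "pul_id": b[1] if b else "",
                "summed_bitscore": b[2] if b else "",
                "substrate_C": ",".join(v[0]) if v else "",
                "votes": v[1] if v else "",
            }
        )
        for gene_id, role in c.members:
            member_rows.append({"cgc_id": c.cgc_id, "gene_id": gene_id, "role": role.value})
    pd.DataFrame(cgc_rows).to_csv(out / "cgcs.tsv", sep="\t", index=False)
    pd.DataFrame(member_rows).to_csv(out / "cgc_members.tsv", sep="\t", index=False)
    result.expression.tpm.to_csv(out / "tpm.tsv", sep="\t")
    result.presence.astype(int).to_csv(out / "presence.tsv", sep="\t")
    result.per_capita.to_csv(out / "per_capita.tsv", sep="\t")
    for by, frame in result.aggregates.items():
        frame.to_csv(out / f"tpm_by_{by}.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "substrate": a.substrate,
                "habitat": a.habitat,
                "n_present": a.n_present,
                "n_expressing": a.n_expressing,
                "fraction": "" if a.fraction is None else a.fraction,
                "above_half": "" if a.above_half is None else int(a.above_half),
            }
            for a in result.activity
        ]
    ).to_csv(out / "substrate_activity.tsv", sep="\t", index=False)
    manifest = {
        "version": __version__,
        "row_counts": {
            "annotations": len(result.annotations),
            "cgcs": len(result.cgcs),
            "retained_genomes": len(result.retained_genomes),
            "activity": len(result.activity),
        },
        "files": {},
    }
    for path in sorted(out.glob("*.tsv")):
        manifest["files"][path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def run_pipeline(config: RunConfig) -> Path:
    """Load, run and serialise; returns the output directory path."""
    inputs = load_inputs(config.input_dir)
    result = run_study(inputs, config)
    manifest = dict(write_outputs(result, config.output_dir))
    manifest["config"] = dataclasses.asdict(config)
    with open(Path(config.output_dir) / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return Path(config.output_dir)
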