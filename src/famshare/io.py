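"""Readers and writers for the plain-text formats the pipeline touches.

All tabular files are TSV with a header row, UTF-8, ``.`` as decimal
separator.  Genomes travel as FASTA with record ids ``genome_id|contig_id``
plus a metadata sidecar ``genomes.tsv``.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cohort import (
    AnnotationRecord,
    DistanceMatrix,
    FamilyCohort,
    GeneModel,
    GenomeAsset,
    Role,
    Sample,
    Sex,
    SNVProfile,
    SNVSite,
    validate_abundance,
)

GENOME_META_COLUMNS = [
    "genome_id",
    "sample_id",
    "species_label",
    "completeness",
    "contamination",
]

METADATA_COLUMNS = [
    "sample_id",
    "family_id",
    "role",
    "ethnicity",
    "sex",
    "age",
    "region",
]

# fixed float formatting keeps write->read->write byte-identical
_FLOAT_FMT = "%.10g"


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")
    return df


# ---------------------------------------------------------------------------
# genomes

def read_genomes(path_or_dir) -> list[GenomeAsset]:
    """Read a genome bundle: ``genomes.fasta`` + ``genomes.tsv`` sidecar.

    ``path_or_dir`` may be the directory or the FASTA path itself.
    Sequences are uppercased; ``N`` is allowed.
    """
    path = Path(path_or_dir)
    if path.is_dir():
        fasta, meta = path / "genomes.fasta", path / "genomes.tsv"
    else:
        fasta, meta = path, path.with_suffix(".tsv")
    if not fasta.exists():
        raise FileNotFoundError(f"FASTA file {fasta} not found")
    if not meta.exists():
        raise FileNotFoundError(f"metadata sidecar {meta} not found")

    contigs_by_genome: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(fasta), "fasta"):
        if "|" in rec.id:
            genome_id, contig_id = rec.id.split("|", 1)
        else:
            genome_id, contig_id = rec.id, rec.id
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{fasta}: record {rec.id} has an empty sequence")
        contigs_by_genome.setdefault(genome_id, {})[contig_id] = seq

    mdf = _read_tsv(meta, GENOME_META_COLUMNS)
    genomes = []
    for row in mdf.itertuples(index=False):
        gid = row.genome_id
        if gid not in contigs_by_genome:
            raise ValueError(
                f"{meta}: metadata row for {gid!r} has no FASTA record"
            )
        genomes.append(
            GenomeAsset(
                genome_id=gid,
                sample_id=row.sample_id,
                species_label=row.species_label,
                contigs=contigs_by_genome.pop(gid),
                completeness=float(row.completeness),
                contamination=float(row.contamination),
            )
        )
    if contigs_by_genome:
        orphans = sorted(contigs_by_genome)
        raise ValueError(f"{fasta}: records without metadata rows: {orphans}")
    return genomes


def write_genomes(genomes: list[GenomeAsset], out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = [
        SeqRecord(Seq(seq), id=f"{g.genome_id}|{cid}", description="")
        for g in genomes
        for cid, seq in g.contigs.items()
    ]
    SeqIO.write(records, str(out / "genomes.fasta"), "fasta")
    pd.DataFrame(
        {
            "genome_id": [g.genome_id for g in genomes],
            "sample_id": [g.sample_id for g in genomes],
            "species_label": [g.species_label for g in genomes],
            "completeness": [g.completeness for g in genomes],
            "contamination": [g.contamination for g in genomes],
        }
    ).to_csv(out / "genomes.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# metadata

def read_metadata(path) -> FamilyCohort:
    """Read the sample metadata TSV into a FamilyCohort."""
    df = _read_tsv(path, METADATA_COLUMNS)
    allowed_roles = [r.value for r in Role]
    samples = []
    for row in df.itertuples(index=False):
        if row.role not in allowed_roles:
            raise ValueError(
                f"{path}: unknown role {row.role!r} for {row.sample_id}; "
                f"allowed values: {allowed_roles}"
            )
        samples.append(
            Sample(
                sample_id=row.sample_id,
                family_id=row.family_id,
                role=Role(row.role),
                ethnicity=row.ethnicity,
                sex=Sex(row.sex),
                age=float(row.age),
                region=row.region,
            )
        )
    return FamilyCohort(samples)


def write_metadata(cohort: FamilyCohort, path) -> None:
    cohort.to_frame().to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# abundance / read counts

def read_abundance(path) -> pd.DataFrame:
    """Sample x taxon matrix; first column is sample_id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return validate_abundance(df)


def write_abundance(matrix: pd.DataFrame, path) -> None:
    validate_abundance(matrix)
    matrix.to_csv(path, sep="\t", index_label="sample_id", float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# distance matrices

def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return DistanceMatrix.from_frame(df)


def write_distance_matrix(dist: DistanceMatrix, path) -> None:
    dist.to_frame().to_csv(path, sep="\t", index_label="id", float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# SNVs

SNV_COLUMNS = [
    "genome_id",
    "contig",
    "position",
    "ref_allele",
    "count_A",
    "count_C",
    "count_G",
    "count_T",
]


def read_snv(path) -> list[SNVProfile]:
    df = _read_tsv(path, SNV_COLUMNS)
    profiles: dict[str, list[SNVSite]] = {}
    for row in df.itertuples(index=False):
        counts = {
            b: int(getattr(row, f"count_{b}"))
            for b in "ACGT"
            if int(getattr(row, f"count_{b}")) > 0
        }
        site = SNVSite(
            contig=row.contig,
            position=int(row.position),
            ref_allele=row.ref_allele,
            allele_counts=counts,
        )
        if site.total < 1:
            raise ValueError(
                f"{path}: site {row.contig}:{row.position} has zero total count"
            )
        profiles.setdefault(row.genome_id, []).append(site)
    return [SNVProfile(gid, sites) for gid, sites in profiles.items()]


def write_snv(profiles: list[SNVProfile], path) -> None:
    rows = []
    for p in profiles:
        for s in p.sites:
            rows.append(
                {
                    "genome_id": p.genome_id,
                    "contig": s.contig,
                    "position": s.position,
                    "ref_allele": s.ref_allele,
                    **{f"count_{b}": s.allele_counts.get(b, 0) for b in "ACGT"},
                }
            )
    pd.DataFrame(rows, columns=SNV_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene models & annotations

GENE_COLUMNS = ["gene_id", "contig", "start", "end", "strand"]


def read_genes(path) -> list[GeneModel]:
    df = _read_tsv(path, GENE_COLUMNS)
    return [
        GeneModel(
            gene_id=row.gene_id,
            contig=row.contig,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
        )
        for row in df.itertuples(index=False)
    ]


def write_genes(genes: list[GeneModel], path) -> None:
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "contig": [g.contig for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "strand": [g.strand for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


ANNOTATION_COLUMNS = ["gene_id", "annotation_type", "label"]


def read_annotations(path) -> list[AnnotationRecord]:
    df = _read_tsv(path, ANNOTATION_COLUMNS)
    return [
        AnnotationRecord(row.gene_id, row.annotation_type, row.label)
        for row in df.itertuples(index=False)
    ]


def write_annotations(records: list[AnnotationRecord], path) -> None:
    pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "annotation_type": [r.annotation_type for r in records],
            "label": [r.label for r in records],
        }
    ).to_csv(path, sep="\t", index=False)
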