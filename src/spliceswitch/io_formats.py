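"""Readers and writers for the external formats the pipeline touches.

All genomic intervals are 0-based half-open internally; GTF I/O converts
from/to the 1-based inclusive convention at the boundary. Protein residue
coordinates (domain tables) stay 1-based inclusive, as is conventional.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class ValidationError(ValueError):
    """Raised when an input file or in-memory object violates a contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

Interval = tuple[int, int]


@dataclass
class TranscriptModel:
    """Exon structure of one transcript.

    ``exons`` are 0-based half-open intervals, sorted ascending and disjoint.
    ``cds`` optionally holds the coding intervals in the same convention.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds: list[Interval] | None = None
    biotype: str = "protein_coding"
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: transcript has zero exons")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        prev_end = None
        for a, b in self.exons:
            if a >= b:
                raise ValidationError(
                    f"{self.transcript_id}: empty or inverted exon [{a},{b})"
                )
            if prev_end is not None and a < prev_end:
                raise ValidationError(f"{self.transcript_id}: overlapping exons")
            prev_end = b

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(b - a for a, b in self.cds) if self.cds else 0

    def contains_exon(self, exon: Interval) -> bool:
        return tuple(exon) in {tuple(e) for e in self.exons}


@dataclass
class GeneModel:
    gene_id: str
    transcripts: list[TranscriptModel]

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> Interval:
        return (
            min(t.span[0] for t in self.transcripts),
            max(t.span[1] for t in self.transcripts),
        )


class ExpressionMatrix:
    """Isoform x sample TPM table plus an isoform->gene mapping."""

    def __init__(self, tpm: pd.DataFrame, isoform_to_gene: dict[str, str]):
        values = tpm.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValidationError("expression matrix contains non-finite values")
        if (values < 0).any():
            raise ValidationError("expression matrix contains negative TPM")
        if tpm.index.duplicated().any():
            dups = tpm.index[tpm.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicated isoform rows: {dups}")
        orphans = [i for i in tpm.index if i not in isoform_to_gene]
        if orphans:
            raise ValidationError(f"isoforms absent from gene map: {orphans}")
        self.tpm = tpm.astype(float)
        self.isoform_to_gene = dict(isoform_to_gene)

    @property
    def isoform_ids(self) -> list[str]:
        return list(self.tpm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.tpm.columns)

    def gene_isoforms(self, gene_id: str) -> list[str]:
        return [i for i in self.tpm.index if self.isoform_to_gene[i] == gene_id]

    def value(self, isoform_id: str, sample_id: str) -> float:
        return float(self.tpm.at[isoform_id, sample_id])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ExpressionMatrix)
            and self.tpm.equals(other.tpm)
            and self.isoform_to_gene == other.isoform_to_gene
        )


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    patient_id: str
    condition: str  # "Baseline" or "DP"


class SampleSheet:
    """Sample -> patient/condition mapping with the matched-pair invariant:
    every patient contributing a DP sample has exactly one Baseline sample."""

    CONDITIONS = ("Baseline", "DP")

    def __init__(self, records: list[SampleRecord]):
        ids = [r.sample_id for r in records]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample_id in sample sheet")
        for r in records:
            if r.condition not in self.CONDITIONS:
                raise ValidationError(
                    f"unknown condition {r.condition!r} for sample {r.sample_id}"
                )
        baselines: dict[str, list[str]] = {}
        for r in records:
            if r.condition == "Baseline":
                baselines.setdefault(r.patient_id, []).append(r.sample_id)
        for r in records:
            if r.condition == "DP":
                n = len(baselines.get(r.patient_id, []))
                if n != 1:
                    raise ValidationError(
                        f"patient {r.patient_id} has {n} Baseline samples "
                        f"(DP sample {r.sample_id} needs exactly one)"
                    )
        self.records = list(records)

    @property
    def samples(self) -> list[str]:
        return [r.sample_id for r in self.records]

    def by_condition(self, condition: str) -> list[SampleRecord]:
        return [r for r in self.records if r.condition == condition]

    def baseline_of(self, patient_id: str) -> str:
        for r in self.records:
            if r.patient_id == patient_id and r.condition == "Baseline":
                return r.sample_id
        raise KeyError(patient_id)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SampleSheet) and self.records == other.records


@dataclass(frozen=True)
class DomainAnnotation:
    """Pfam-style domain interval on a protein, 1-based inclusive residues."""

    protein_id: str
    domain_name: str
    start_aa: int
    end_aa: int

    def __post_init__(self) -> None:
        if not (1 <= self.start_aa <= self.end_aa):
            raise ValidationError(
                f"{self.protein_id}/{self.domain_name}: bad residue interval "
                f"[{self.start_aa},{self.end_aa}]"
            )

    @property
    def length(self) -> int:
        return self.end_aa - self.start_aa + 1


@dataclass(frozen=True)
class BindingSite:
    """One RBP binding site (CLIP-derived), BED-style half-open interval."""

    rbp_name: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    target_gene: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"binding site {self.rbp_name} [{self.start},{self.end}): start >= end"
            )


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str, lineno: int) -> dict[str, str]:
    attrs = dict(_ATTR_RE.findall(attr_field))
    if "gene_id" not in attrs or "transcript_id" not in attrs:
        raise ValidationError(
            f"GTF line {lineno}: attribute string lacks gene_id/transcript_id: "
            f"{attr_field!r}"
        )
    return attrs


def read_gtf(path) -> list[GeneModel]:
    """Parse exon (and CDS) features into per-gene transcript models.

    GTF 1-based inclusive coordinates become 0-based half-open; exons are
    sorted ascending per transcript. Unknown attributes are preserved.
    """
    exon_rows: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValidationError(f"GTF line {lineno}: expected 9 fields")
            chrom, _source, feature, start, end, _score, strand, _frame, attr = fields[:9]
            if feature not in ("exon", "CDS"):
                continue
            attrs = _parse_attributes(attr, lineno)
            tid = attrs["transcript_id"]
            try:
                iv = (int(start) - 1, int(end))
            except ValueError as exc:
                raise ValidationError(f"GTF line {lineno}: bad coordinates") from exc
            rec = exon_rows.setdefault(
                tid,
                {
                    "gene_id": attrs["gene_id"],
                    "chrom": chrom,
                    "strand": strand,
                    "exons": [],
                    "cds": [],
                    "attrs": attrs,
                },
            )
            if tid not in order:
                order.append(tid)
            rec[("exons" if feature == "exon" else "cds")].append(iv)
    genes: dict[str, list[TranscriptModel]] = {}
    gene_order: list[str] = []
    for tid in order:
        rec = exon_rows[tid]
        if not rec["exons"]:
            raise ValidationError(f"transcript {tid} has zero exon features")
        biotype = rec["attrs"].get(
            "transcript_biotype", rec["attrs"].get("gene_biotype", "protein_coding")
        )
        tm = TranscriptModel(
            transcript_id=tid,
            gene_id=rec["gene_id"],
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=rec["exons"],
            cds=sorted(rec["cds"]) or None,
            biotype=biotype,
            attributes={
                k: v
                for k, v in rec["attrs"].items()
                if k not in ("gene_id", "transcript_id")
            },
        )
        if rec["gene_id"] not in genes:
            gene_order.append(rec["gene_id"])
        genes.setdefault(rec["gene_id"], []).append(tm)
    return [GeneModel(g, genes[g]) for g in gene_order]


def write_gtf(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for gene in genes:
            for t in gene.transcripts:
                base = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; ' \
                       f'transcript_biotype "{t.biotype}";'
                extra = "".join(
                    f' {k} "{v}";'
                    for k, v in t.attributes.items()
                    if k != "transcript_biotype"
                )
                attrs = base + extra
                for a, b in t.exons:
                    fh.write(
                        f"{t.chrom}\tspliceswitch\texon\t{a + 1}\t{b}\t.\t{t.strand}\t.\t{attrs}\n"
                    )
                for a, b in t.cds or []:
                    fh.write(
                        f"{t.chrom}\tspliceswitch\tCDS\t{a + 1}\t{b}\t.\t{t.strand}\t.\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# expression matrix / sample sheet
# ---------------------------------------------------------------------------

def read_expression_matrix(path, gene_map: dict[str, str]) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValidationError("expression matrix contains missing values")
    return ExpressionMatrix(df, gene_map)


def write_expression_matrix(expr: ExpressionMatrix, path) -> None:
    df = expr.tpm.copy()
    df.index.name = "isoform_id"
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "patient_id", "condition"}
    if not required.issubset(df.columns):
        raise ValidationError(f"sample sheet needs columns {sorted(required)}")
    records = [
        SampleRecord(r.sample_id, r.patient_id, r.condition)
        for r in df.itertuples(index=False)
    ]
    return SampleSheet(records)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    pd.DataFrame(
        [(r.sample_id, r.patient_id, r.condition) for r in sheet.records],
        columns=["sample_id", "patient_id", "condition"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA / GMT / BED / domain TSV
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise ValidationError(f"empty sequence for {rec.id}")
        seqs[rec.id] = seq
    return seqs


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_gmt(path) -> list[tuple[str, set[str]]]:
    sets: list[tuple[str, set[str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValidationError(f"GMT line {lineno}: empty gene set")
            sets.append((parts[0], set(parts[2:])))
    return sets


def write_gmt(sets: list[tuple[str, set[str]]], path) -> None:
    with open(path, "w") as fh:
        for name, members in sets:
            fh.write("\t".join([name, "na"] + sorted(members)) + "\n")


def read_bed_sites(path) -> list[BindingSite]:
    sites: list[BindingSite] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValidationError(f"BED line {lineno}: need >=4 columns")
            chrom, start, end, name = parts[:4]
            strand = parts[5] if len(parts) >= 6 else "."
            target = parts[6] if len(parts) >= 7 else None
            sites.append(BindingSite(name, chrom, int(start), int(end), strand, target))
    return sites


def write_bed_sites(sites: list[BindingSite], path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            cols = [s.chrom, str(s.start), str(s.end), s.rbp_name, "0", s.strand]
            if s.target_gene is not None:
                cols.append(s.target_gene)
            fh.write("\t".join(cols) + "\n")


def read_domains(path) -> list[DomainAnnotation]:
    df = pd.read_csv(path, sep="\t")
    return [
        DomainAnnotation(r.protein_id, r.domain_name, int(r.start_aa), int(r.end_aa))
        for r in df.itertuples(index=False)
    ]


def write_domains(domains: list[DomainAnnotation], path) -> None:
    pd.DataFrame(
        [(d.protein_id, d.domain_name, d.start_aa, d.end_aa) for d in domains],
        columns=["protein_id", "domain_name", "start_aa", "end_aa"],
    ).to_csv(path, sep="\t", index=False)
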