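"""Ground-truthed synthetic cohorts with the matched-pair design of a
baseline / disease-progression (DP) biopsy study.

The generator emulates a cohort of 21 patients, each contributing one
pre-treatment Baseline biopsy and 1-3 DP biopsies (44 DP total). A configurable
fraction of genes carries a programmed reciprocal exon-skip switch: an
"inclusion" isoform (cassette exon present, 43 aa in-frame by default) rises in
manifesting DP samples while its "skip" sibling falls, mirroring the
AKT2-206 / AKT2-210 pattern. A driver RNA-binding protein's expression follows
the same per-sample latent switch-activity factor that determines which DP
samples manifest, so the downstream RBP screen has a recoverable signal.

Manifestation model: each DP sample s gets a latent activity a_s ~ N(0,1);
each switch gene manifests in exactly round(penetrance x n_DP) DP samples,
chosen as the top-scoring samples under a_s plus gene-specific jitter. The
per-gene manifestation count is therefore deterministic given the config,
while manifesting samples overlap across genes through a_s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io_formats import (
    BindingSite,
    DomainAnnotation,
    ExpressionMatrix,
    GeneModel,
    SampleRecord,
    SampleSheet,
    TranscriptModel,
    ValidationError,
    write_bed_sites,
    write_domains,
    write_expression_matrix,
    write_fasta,
    write_gmt,
    write_gtf,
)

AA_ALPHABET = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class SimulationConfig:
    """Study-design parameters of the simulated cohort."""

    n_patients: int = 21
    n_dp_samples: int = 44
    max_dp_per_patient: int = 3
    n_genes: int = 400
    isoforms_per_gene: tuple[int, int] = (2, 5)
    switch_gene_fraction: float = 0.1
    switch_penetrance: float = 0.5
    effect_size: float = 4.0
    cassette_aa: int = 43
    baseline_log_tpm_mean: float = 3.5
    baseline_log_tpm_sd: float = 0.8
    switch_min_tpm: float = 15.0
    noise_sd: float = 0.25
    rbp_coupling: float = 0.8
    n_rbps: int = 10
    decoy_anticorr_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("switch_gene_fraction", "switch_penetrance", "decoy_anticorr_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0,1], got {v}")
        if self.effect_size <= 1:
            raise ValidationError("effect_size must be > 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        lo, hi = self.isoforms_per_gene
        if lo < 2:
            raise ValidationError("isoforms_per_gene minimum must be >= 2 "
                                  "(switch genes need an inclusion and a skip isoform)")
        if hi < lo:
            raise ValidationError("isoforms_per_gene range inverted")
        if self.n_dp_samples > self.n_patients * self.max_dp_per_patient:
            raise ValidationError("n_dp_samples exceeds patients x max_dp_per_patient")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "isoforms_per_gene" in data:
            data["isoforms_per_gene"] = tuple(data["isoforms_per_gene"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["isoforms_per_gene"] = list(self.isoforms_per_gene)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @property
    def n_switch_genes(self) -> int:
        return int(round(self.n_genes * self.switch_gene_fraction))


@dataclass
class AnnotationBundle:
    genes: list[GeneModel]
    proteins: dict[str, str]                      # transcript_id -> aa sequence
    domains: list[DomainAnnotation]
    sites: list[BindingSite]
    gene_sets: list[tuple[str, set[str]]]
    switch_genes: list[str]
    skipped_exon: dict[str, tuple[int, int]]      # switch gene -> cassette interval
    switch_isoforms: dict[str, tuple[str, str]]   # gene -> (inclusion_id, skip_id)
    driver_rbp: str
    rbp_genes: list[str]                          # RBP gene ids (one isoform each)
    anticorr_decoys: list[str]


@dataclass
class GroundTruth:
    switch_genes: set[str]
    manifestations: pd.DataFrame  # columns: gene_id, dp_sample, manifested
    driver_rbp: str
    skipped_exon: dict[str, tuple[int, int]]


@dataclass
class CohortBundle:
    config: SimulationConfig
    annotation: AnnotationBundle
    expression: ExpressionMatrix
    sheet: SampleSheet
    truth: GroundTruth


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _aa_block(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(AA_ALPHABET, size=n))


def _make_switch_gene(gene_id: str, chrom: str, start: int, cassette_aa: int,
                      rng: np.random.Generator):
    """Inclusion/skip isoform pair differing by one in-frame cassette exon.

    Exon lengths are multiples of 3 so the cassette's translated block is
    exactly ``cassette_aa`` residues; a domain interval straddles the encoded
    peptide so skipping truncates the domain.
    """
    aa_lens = [int(rng.integers(60, 120)), cassette_aa, int(rng.integers(60, 120))]
    intron = lambda: int(rng.integers(20, 60)) * 3
    exons = []
    pos = start
    for aa in aa_lens:
        exons.append((pos, pos + 3 * aa))
        pos = exons[-1][1] + intron()
    inc_id, skip_id = f"{gene_id}-201", f"{gene_id}-202"
    strand = "+" if rng.random() < 0.5 else "-"
    inc = TranscriptModel(inc_id, gene_id, chrom, strand, exons,
                          cds=list(exons), biotype="protein_coding")
    skip = TranscriptModel(skip_id, gene_id, chrom, strand,
                           [exons[0], exons[2]],
                           cds=[exons[0], exons[2]], biotype="protein_coding")
    blocks = [_aa_block(rng, aa) for aa in aa_lens]
    inc_prot = "".join(blocks)
    skip_prot = blocks[0] + blocks[2]
    # domain overlapping the cassette peptide: skipping truncates it
    cass_start = aa_lens[0] + 1                   # 1-based first cassette residue
    dom_start = max(1, cass_start - int(rng.integers(5, 20)))
    dom_end = min(len(inc_prot), cass_start + cassette_aa - 1 + int(rng.integers(5, 20)))
    domain = DomainAnnotation(inc_id, f"Kinase_dom_{gene_id}", dom_start, dom_end)
    return (GeneModel(gene_id, [inc, skip]),
            {inc_id: inc_prot, skip_id: skip_prot},
            [domain], exons[1], (inc_id, skip_id), pos)


_DECOY_MODES = ("SE", "RI", "A5SS", "A3SS", "MXE")


def _make_decoy_gene(gene_id: str, chrom: str, start: int, n_isoforms: int,
                     rng: np.random.Generator):
    """Gene with a reference isoform plus variants covering the five event
    modes; protein sequences share per-codon residues so isoform differences
    are contiguous blocks."""
    n_exons = int(rng.integers(4, 8))
    strand = "+" if rng.random() < 0.5 else "-"
    exons = []
    pos = start
    for _ in range(n_exons):
        aa = int(rng.integers(20, 60))
        exons.append((pos, pos + 3 * aa))
        pos = exons[-1][1] + int(rng.integers(40, 80)) * 3
    gene_end = pos
    # shared residue per genomic codon, covering room for MXE/A5SS variants
    codon0 = start // 3
    codons = _aa_block(rng, (gene_end - start) // 3 + 200)

    def protein(ex_list):
        out = []
        for a, b in ex_list:
            out.append(codons[a // 3 - codon0: b // 3 - codon0])
        return "".join(out)

    ref = TranscriptModel(f"{gene_id}-201", gene_id, chrom, strand, exons,
                          cds=list(exons), biotype="protein_coding")
    transcripts = [ref]
    proteins = {ref.transcript_id: protein(exons)}
    modes = list(rng.permutation(_DECOY_MODES))
    for k in range(n_isoforms - 1):
        mode = modes[k % len(modes)]
        ex = [tuple(e) for e in exons]
        i = int(rng.integers(1, n_exons - 1))    # internal exon index
        if mode == "SE":
            ex.pop(i)
        elif mode == "RI":
            ex[i] = (ex[i][0], ex[i + 1][1])
            ex.pop(i + 1)
        elif mode == "A5SS":                      # shift the right boundary
            shift = 3 * int(rng.integers(3, 12))
            ex[i] = (ex[i][0], ex[i][1] + shift)
        elif mode == "A3SS":                      # shift the left boundary
            shift = 3 * int(rng.integers(3, 12))
            ex[i] = (ex[i][0] + shift, ex[i][1])
        else:                                     # MXE: replace exon i
            gap_start = ex[i][1]
            alt_len = 3 * int(rng.integers(15, 30))
            alt_start = gap_start + 15
            ex[i] = (alt_start, alt_start + alt_len)
        tid = f"{gene_id}-{202 + k}"
        coding = rng.random() > 0.2
        transcripts.append(TranscriptModel(
            tid, gene_id, chrom, strand, ex,
            cds=list(ex) if coding else None,
            biotype="protein_coding" if coding else "processed_transcript"))
        if coding:
            proteins[tid] = protein(ex)
    return GeneModel(gene_id, transcripts), proteins, gene_end


def simulate_annotation(config: SimulationConfig) -> AnnotationBundle:
    rng = np.random.default_rng(config.seed)
    genes: list[GeneModel] = []
    proteins: dict[str, str] = {}
    domains: list[DomainAnnotation] = []
    skipped_exon: dict[str, tuple[int, int]] = {}
    switch_isoforms: dict[str, tuple[str, str]] = {}

    n_switch = config.n_switch_genes
    switch_genes = [f"SWG{i:04d}" for i in range(1, n_switch + 1)]
    decoy_genes = [f"DCG{i:04d}" for i in range(1, config.n_genes - n_switch + 1)]

    pos = 3000
    for gid in switch_genes:
        gm, prots, doms, cassette, pair, end = _make_switch_gene(
            gid, "chr1", pos, config.cassette_aa, rng)
        genes.append(gm)
        proteins.update(prots)
        domains.extend(doms)
        skipped_exon[gid] = cassette
        switch_isoforms[gid] = pair
        pos = end + 3000

    lo, hi = config.isoforms_per_gene
    anticorr: list[str] = []
    for gid in decoy_genes:
        n_iso = int(rng.integers(lo, hi + 1))
        gm, prots, end = _make_decoy_gene(gid, "chr1", pos, n_iso, rng)
        genes.append(gm)
        proteins.update(prots)
        if rng.random() < config.decoy_anticorr_fraction:
            anticorr.append(gid)
        # occasional decoy domain, away from any programmed deletion signal
        if rng.random() < 0.5 and gm.transcripts[0].transcript_id in prots:
            plen = len(prots[gm.transcripts[0].transcript_id])
            if plen > 40:
                a = int(rng.integers(1, plen - 30))
                domains.append(DomainAnnotation(
                    gm.transcripts[0].transcript_id,
                    f"Dom_{gid}", a, min(plen, a + int(rng.integers(20, 60)))))
        pos = end + 3000

    # RBP genes: single-isoform loci on chr2
    rbp_genes = [f"RBP{i:02d}" for i in range(1, config.n_rbps + 1)]
    driver = str(rng.choice(rbp_genes))
    rpos = 3000
    for rid in rbp_genes:
        aa = int(rng.integers(100, 200))
        t = TranscriptModel(f"{rid}-201", rid, "chr2", "+",
                            [(rpos, rpos + 3 * aa)], cds=[(rpos, rpos + 3 * aa)])
        genes.append(GeneModel(rid, [t]))
        proteins[t.transcript_id] = _aa_block(rng, aa)
        rpos += 3 * aa + 3000

    # binding sites: driver covers every switch-gene locus; others random
    gene_span = {g.gene_id: (g.chrom, g.strand, *g.span) for g in genes}
    sites: list[BindingSite] = []
    for gid in switch_genes:
        chrom, strand, a, b = gene_span[gid]
        for _ in range(int(rng.integers(2, 5))):
            s = int(rng.integers(a, b - 20))
            sites.append(BindingSite(driver, chrom, s, s + 20, strand, gid))
    target_pool = switch_genes + decoy_genes
    for rid in rbp_genes:
        if rid == driver:
            continue
        for gid in rng.choice(target_pool, size=int(rng.integers(3, 8)), replace=False):
            chrom, strand, a, b = gene_span[gid]
            s = int(rng.integers(a, b - 20))
            sites.append(BindingSite(rid, chrom, s, s + 20, strand, str(gid)))

    # gene sets: one set enriched in switch genes + random background sets
    all_gids = switch_genes + decoy_genes
    enriched = set(rng.choice(switch_genes, size=max(1, int(0.8 * n_switch)),
                              replace=False).tolist())
    enriched |= set(rng.choice(decoy_genes, size=max(1, n_switch // 4),
                               replace=False).tolist())
    gene_sets = [("PATHWAY_SWITCH_SIGNALING", enriched)]
    for j in range(4):
        size = min(int(rng.integers(20, 60)), len(all_gids))
        gene_sets.append((f"PATHWAY_RANDOM_{j + 1}",
                          set(rng.choice(all_gids, size=size, replace=False).tolist())))

    return AnnotationBundle(genes, proteins, domains, sites, gene_sets,
                            switch_genes, skipped_exon, switch_isoforms,
                            driver, rbp_genes, anticorr)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _allocate_samples(config: SimulationConfig, rng: np.random.Generator) -> SampleSheet:
    patients = [f"P{i:02d}" for i in range(1, config.n_patients + 1)]
    records = [SampleRecord(f"{p}_B", p, "Baseline") for p in patients]
    counts = {p: 1 for p in patients}            # every patient has >=1 DP
    extra = config.n_dp_samples - config.n_patients
    eligible = list(patients)
    while extra > 0:
        p = str(rng.choice(eligible))
        counts[p] += 1
        if counts[p] >= config.max_dp_per_patient:
            eligible.remove(p)
        extra -= 1
    for p in patients:
        for k in range(1, counts[p] + 1):
            records.append(SampleRecord(f"{p}_DP{k}", p, "DP"))
    return SampleSheet(records)


def simulate_expression(config: SimulationConfig, annotation: AnnotationBundle
                        ) -> tuple[ExpressionMatrix, SampleSheet, GroundTruth]:
    rng = np.random.default_rng(config.seed + 1)
    sheet = _allocate_samples(config, rng)
    samples = sheet.samples
    dp_samples = [r.sample_id for r in sheet.by_condition("DP")]
    n_dp = len(dp_samples)

    isoforms = [t.transcript_id for g in annotation.genes for t in g.transcripts]
    gene_map = {t.transcript_id: g.gene_id
                for g in annotation.genes for t in g.transcripts}

    # per-DP-sample latent switch activity drives manifestation AND the RBP
    activity = pd.Series(rng.normal(size=n_dp), index=dp_samples)

    n_manifest = int(round(config.switch_penetrance * n_dp))
    rows = []
    manifest: dict[str, set[str]] = {}
    for gid in annotation.switch_genes:
        score = activity + rng.normal(scale=0.7, size=n_dp)
        chosen = set(score.nlargest(n_manifest).index)
        manifest[gid] = chosen
        for s in dp_samples:
            rows.append((gid, s, s in chosen))
    manifestations = pd.DataFrame(rows, columns=["gene_id", "dp_sample", "manifested"])

    base_log = pd.Series(
        rng.normal(config.baseline_log_tpm_mean, config.baseline_log_tpm_sd,
                   size=len(isoforms)),
        index=isoforms)
    # a switch between isoforms below the abundance detection filter is not a
    # switch the assay defines; programmed switch pairs are kept expressed
    floor = np.log(config.switch_min_tpm)
    for gid in annotation.switch_genes:
        for iso in annotation.switch_isoforms[gid]:
            base_log[iso] = max(float(base_log[iso]), floor)

    log_tpm = pd.DataFrame(
        np.add.outer(base_log.to_numpy(), np.zeros(len(samples))),
        index=isoforms, columns=samples)

    if config.noise_sd > 0:
        noise = rng.normal(scale=config.noise_sd, size=log_tpm.shape)
        # anti-correlated decoy isoform pairs: shared noise, opposite signs
        iso_pos = {iso: i for i, iso in enumerate(isoforms)}
        for gid in annotation.anticorr_decoys:
            pair = [iso for iso in isoforms if gene_map[iso] == gid][:2]
            if len(pair) == 2:
                shared = rng.normal(scale=config.noise_sd, size=len(samples))
                noise[iso_pos[pair[0]]] = shared + rng.normal(
                    scale=0.3 * config.noise_sd, size=len(samples))
                noise[iso_pos[pair[1]]] = -shared + rng.normal(
                    scale=0.3 * config.noise_sd, size=len(samples))
        log_tpm += noise

    log_effect = np.log(config.effect_size)
    for gid in annotation.switch_genes:
        inc, skip = annotation.switch_isoforms[gid]
        for s in manifest[gid]:
            log_tpm.at[inc, s] += log_effect
            log_tpm.at[skip, s] -= log_effect

    # driver RBP follows the latent activity in DP samples
    driver_iso = f"{annotation.driver_rbp}-201"
    if config.rbp_coupling > 0:
        for s in dp_samples:
            log_tpm.at[driver_iso, s] += config.rbp_coupling * float(activity[s])

    expr = ExpressionMatrix(np.exp(log_tpm), gene_map)
    truth = GroundTruth(set(annotation.switch_genes), manifestations,
                        annotation.driver_rbp, dict(annotation.skipped_exon))
    return expr, sheet, truth


def simulate_cohort(config: SimulationConfig) -> CohortBundle:
    annotation = simulate_annotation(config)
    expr, sheet, truth = simulate_expression(config, annotation)
    return CohortBundle(config, annotation, expr, sheet, truth)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_cohort(bundle: CohortBundle, directory) -> dict[str, Path]:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "gtf": d / "annotation.gtf",
        "expression": d / "expression.tsv",
        "sample_sheet": d / "sample_sheet.tsv",
        "proteins": d / "proteins.fasta",
        "domains": d / "domains.tsv",
        "sites": d / "rbp_sites.bed",
        "gene_sets": d / "gene_sets.gmt",
        "truth": d / "truth.tsv",
        "config": d / "config.yaml",
    }
    ann = bundle.annotation
    write_gtf(ann.genes, paths["gtf"])
    write_expression_matrix(bundle.expression, paths["expression"])
    from .io_formats import write_sample_sheet
    write_sample_sheet(bundle.sheet, paths["sample_sheet"])
    write_fasta(ann.proteins, paths["proteins"])
    write_domains(ann.domains, paths["domains"])
    write_bed_sites(ann.sites, paths["sites"])
    write_gmt(ann.gene_sets, paths["gene_sets"])
    truth = bundle.truth.manifestations.copy()
    truth["driver_rbp"] = bundle.truth.driver_rbp
    truth["cassette_start"] = truth["gene_id"].map(
        {g: iv[0] for g, iv in bundle.truth.skipped_exon.items()})
    truth["cassette_end"] = truth["gene_id"].map(
        {g: iv[1] for g, iv in bundle.truth.skipped_exon.items()})
    truth.to_csv(paths["truth"], sep="\t", index=False)
    bundle.config.to_yaml(paths["config"])
    return paths
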