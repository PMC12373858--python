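"""Reciprocal within-gene isoform switch detection, fold-change/PSI
correlation, and protein-domain impact annotation.

A "switch" is the pattern where one isoform of a gene rises while a sibling
isoform falls in the same patient-matched biopsy pair. It is operationalised
as (i) a negative Pearson correlation between the two isoforms' per-pair
log2 fold-change vectors, (ii) opposite-signed recurrence concordance
surviving the up/down-difference filter, (iii) opposite-signed paired t-tests
on log2 abundance, and (iv) at least one pair with co-occurring reciprocal
directional calls. The co-occurrence count over all pairs gives the
"switch in X% of biopsies" statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats

from .dei_screen import (
    DEICall,
    PairedComparison,
    RecurrenceRecord,
    concordance_filter,
    paired_group_test,
    per_pair_log2fc,
    recurrence,
)
from .enrichment import bh_fdr
from .io_formats import (
    DomainAnnotation,
    ExpressionMatrix,
    GeneModel,
    ValidationError,
)

logger = logging.getLogger(__name__)


@dataclass
class SwitchCall:
    gene_id: str
    up_isoform: str
    down_isoform: str
    n_reciprocal_pairs: int
    n_pairs: int
    pearson_r: float
    p_value: float


@dataclass
class CorrelationResult:
    x_label: str
    y_label: str
    r: float
    p: float
    n: int


@dataclass
class DiffSegment:
    kind: str  # deletion | insertion | substitution
    principal_interval: tuple[int, int]   # 1-based inclusive on principal
    alternative_interval: tuple[int, int]

    @property
    def length(self) -> int:
        a, b = (
            self.alternative_interval
            if self.kind == "insertion"
            else self.principal_interval
        )
        return b - a + 1


@dataclass
class ProteinDiff:
    principal_id: str
    alternative_id: str
    segments: list[DiffSegment]
    frameshift: bool = False


@dataclass
class DomainImpact:
    alternative_id: str
    domain_name: str
    status: str  # lost | truncated | intact
    overlap_aa: int


# ---------------------------------------------------------------------------
# switch detection
# ---------------------------------------------------------------------------

def switch_candidates(
    gene: GeneModel,
    expr: ExpressionMatrix,
    calls: list[DEICall],
    pairs: list[PairedComparison],
    min_abs_r: float = 0.5,
    max_p: float = 0.05,
    pseudocount: float = 0.1,
) -> list[SwitchCall]:
    """Ordered isoform pairs of one gene with anti-correlated per-pair
    log2FC vectors. Constant vectors make the correlation undefined and the
    pair is skipped with a logged reason."""
    if len(pairs) < 3:
        return []
    iso_ids = [
        t.transcript_id for t in gene.transcripts if t.transcript_id in expr.tpm.index
    ]
    vectors = {
        iso: per_pair_log2fc(expr, iso, pairs, pseudocount) for iso in iso_ids
    }
    up_calls: dict[str, set[str]] = {}
    down_calls: dict[str, set[str]] = {}
    for c in calls:
        if c.isoform_id in vectors:
            (up_calls if c.direction == "up" else down_calls).setdefault(
                c.isoform_id, set()
            ).add(c.dp_sample)
    out: list[SwitchCall] = []
    for a in iso_ids:
        for b in iso_ids:
            if a >= b:
                continue
            va, vb = vectors[a], vectors[b]
            const_a = bool(np.all(va == va[0]))
            const_b = bool(np.all(vb == vb[0]))
            if const_a and const_b and va[0] * vb[0] < 0:
                # perfectly reciprocal constant shift: the noise-free limit of
                # an exact switch; treated as r -> -1
                r, p = -1.0, 0.0
            elif const_a or const_b:
                logger.debug(
                    "%s: constant log2FC vector for (%s,%s); correlation undefined",
                    gene.gene_id, a, b,
                )
                continue
            else:
                r, p = stats.pearsonr(va, vb)
            if r < 0 and abs(r) >= min_abs_r and p <= max_p:
                for up, down in ((a, b), (b, a)):
                    n_rec = len(
                        up_calls.get(up, set()) & down_calls.get(down, set())
                    )
                    out.append(
                        SwitchCall(
                            gene.gene_id, up, down, n_rec, len(pairs),
                            float(r), float(p),
                        )
                    )
    out.sort(key=lambda s: (-s.n_reciprocal_pairs, s.pearson_r, s.up_isoform))
    return out


def detect_switches(
    genes: list[GeneModel],
    expr: ExpressionMatrix,
    pairs: list[PairedComparison],
    calls: list[DEICall],
    min_abs_r: float = 0.5,
    max_p: float = 0.05,
    min_concordance: int = 6,
    paired_alpha: float = 0.05,
    pseudocount: float = 0.1,
) -> list[SwitchCall]:
    """Cohort-level switch calls: at most one call per gene, gated by
    anti-correlation, opposite-signed concordance, opposite-signed paired
    t-tests (BH-corrected across all recurrent isoforms), and at least one
    reciprocal pair."""
    records = {r.isoform_id: r for r in recurrence(calls, pairs)}
    retained = {
        r.isoform_id for r in concordance_filter(list(records.values()), min_concordance)
    }
    # family-wise paired tests: BH across every isoform with >=1 call
    iso_family = sorted(records)
    paired: dict[str, tuple[float, float]] = {
        iso: paired_group_test(expr, iso, pairs, pseudocount) for iso in iso_family
    }
    qvals = bh_fdr([paired[iso][1] for iso in iso_family])
    paired_q = {iso: float(q) for iso, q in zip(iso_family, qvals)}
    out: list[SwitchCall] = []
    for gene in genes:
        for cand in switch_candidates(
            gene, expr, calls, pairs, min_abs_r, max_p, pseudocount
        ):
            if cand.n_reciprocal_pairs < 1:
                continue
            up_rec = records.get(cand.up_isoform)
            down_rec = records.get(cand.down_isoform)
            if (
                up_rec is None or down_rec is None
                or cand.up_isoform not in retained
                or cand.down_isoform not in retained
                or up_rec.concordance <= 0
                or down_rec.concordance >= 0
            ):
                continue
            t_up, _ = paired[cand.up_isoform]
            t_down, _ = paired[cand.down_isoform]
            q_up = paired_q[cand.up_isoform]
            q_down = paired_q[cand.down_isoform]
            if t_up > 0 and q_up <= paired_alpha and t_down < 0 and q_down <= paired_alpha:
                out.append(cand)
                break  # best-ranked candidate per gene
    return out


def reciprocal_recurrence(
    up_isoform: str,
    down_isoform: str,
    calls: list[DEICall],
    pairs: list[PairedComparison],
) -> tuple[int, float]:
    """Pairs where the up isoform has an up call AND the down isoform has a
    down call, with the percentage of all pairs."""
    ups = {c.dp_sample for c in calls if c.isoform_id == up_isoform and c.direction == "up"}
    downs = {
        c.dp_sample for c in calls if c.isoform_id == down_isoform and c.direction == "down"
    }
    n = len(ups & downs)
    return n, 100.0 * n / len(pairs) if pairs else 0.0


def correlate_fc_dpsi(
    x, y, x_label: str = "log2FC", y_label: str = "dPSI"
) -> CorrelationResult:
    """Pearson correlation with pairwise deletion of missing entries; the
    two-sided p-value comes from the t distribution with n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("vectors differ in length")
    mask = ~(np.isnan(x) | np.isnan(y))
    if mask.sum() < 3:
        raise ValidationError("fewer than 3 complete pairs")
    r, p = stats.pearsonr(x[mask], y[mask])
    return CorrelationResult(x_label, y_label, float(r), float(p), int(mask.sum()))


# ---------------------------------------------------------------------------
# principal isoform and protein diff
# ---------------------------------------------------------------------------

def principal_isoform(
    gene: GeneModel, principal_table: dict[str, str] | None = None
) -> str:
    """APPRIS-style principal isoform: taken from the table when provided,
    else longest CDS, ties by longest transcript, then lexicographic id."""
    if principal_table and gene.gene_id in principal_table:
        return principal_table[gene.gene_id]
    return min(
        gene.transcripts,
        key=lambda t: (-t.cds_length, -t.length, t.transcript_id),
    ).transcript_id


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
_aligner.open_gap_score = -11.0
_aligner.extend_gap_score = -1.0


def diff_protein(
    principal_seq: str,
    alternative_seq: str,
    principal_id: str = "principal",
    alternative_id: str = "alternative",
    frameshift_tail_min: int = 10,
) -> ProteinDiff:
    """Segment-level differences between two protein sequences via global
    alignment (BLOSUM62, affine gaps).

    Contiguous gap runs become deletion/insertion segments and mismatch runs
    become substitutions. A substitution run of at least
    ``frameshift_tail_min`` residues extending to the C-terminus is flagged
    as a frameshift (the alternative is then not reconstructable from the
    principal by contiguous in-frame blocks).
    """
    if not principal_seq or not alternative_seq:
        raise ValidationError("empty protein sequence")
    if principal_seq == alternative_seq:
        return ProteinDiff(principal_id, alternative_id, [])
    aln = _aligner.align(principal_seq, alternative_seq)[0]
    p_aln, a_aln = str(aln[0]), str(aln[1])
    segments: list[DiffSegment] = []
    p_pos = a_pos = 0  # residues consumed
    run_kind: str | None = None
    run_start: tuple[int, int] | None = None
    prev_end: tuple[int, int] = (0, 0)

    def close_run(end_p: int, end_a: int) -> None:
        nonlocal run_kind, run_start
        if run_kind is None:
            return
        sp, sa = run_start
        if run_kind == "deletion":
            seg = DiffSegment("deletion", (sp + 1, end_p), (sa + 1, sa))
        elif run_kind == "insertion":
            seg = DiffSegment("insertion", (sp + 1, sp), (sa + 1, end_a))
        else:
            seg = DiffSegment("substitution", (sp + 1, end_p), (sa + 1, end_a))
        segments.append(seg)
        run_kind = None
        run_start = None

    for pc, ac in zip(p_aln, a_aln):
        if pc != "-" and ac == "-":
            kind = "deletion"
        elif pc == "-" and ac != "-":
            kind = "insertion"
        elif pc != ac:
            kind = "substitution"
        else:
            kind = None
        if kind != run_kind:
            close_run(p_pos, a_pos)
            if kind is not None:
                run_start = (p_pos, a_pos)
            run_kind = kind
        if pc != "-":
            p_pos += 1
        if ac != "-":
            a_pos += 1
    close_run(p_pos, a_pos)

    frameshift = any(
        s.kind == "substitution"
        and s.length >= frameshift_tail_min
        and s.principal_interval[1] == len(principal_seq)
        for s in segments
    )
    return ProteinDiff(principal_id, alternative_id, segments, frameshift)


def apply_diff(principal_seq: str, diff: ProteinDiff, alternative_seq: str) -> str:
    """Reconstruct the alternative sequence from the principal plus the
    reported segments (inverse-consistency check)."""
    out: list[str] = []
    p_cursor = 0
    for seg in diff.segments:
        sp, ep = seg.principal_interval
        out.append(principal_seq[p_cursor: sp - 1])
        if seg.kind == "deletion":
            p_cursor = ep
        elif seg.kind == "insertion":
            sa, ea = seg.alternative_interval
            out.append(alternative_seq[sa - 1: ea])
            p_cursor = sp - 1
        else:
            sa, ea = seg.alternative_interval
            out.append(alternative_seq[sa - 1: ea])
            p_cursor = ep
    out.append(principal_seq[p_cursor:])
    return "".join(out)


def domain_impact(
    diff: ProteinDiff, domains: list[DomainAnnotation]
) -> list[DomainImpact]:
    """Per-domain consequence of the protein differences.

    Overlap counts residues of the (principal-coordinate) domain removed by
    deletion segments; a frameshift forces every domain starting at or after
    the first frameshifted residue to be lost.
    """
    fs_start = None
    if diff.frameshift:
        fs_start = min(
            s.principal_interval[0]
            for s in diff.segments
            if s.kind == "substitution"
            and s.length >= 1
        )
    impacts: list[DomainImpact] = []
    for dom in domains:
        if fs_start is not None and dom.start_aa >= fs_start:
            impacts.append(
                DomainImpact(diff.alternative_id, dom.domain_name, "lost", dom.length)
            )
            continue
        overlap = 0
        for seg in diff.segments:
            if seg.kind != "deletion":
                continue
            a, b = seg.principal_interval
            overlap += max(0, min(b, dom.end_aa) - max(a, dom.start_aa) + 1)
        overlap = min(overlap, dom.length)
        status = (
            "lost" if overlap == dom.length else "intact" if overlap == 0 else "truncated"
        )
        impacts.append(DomainImpact(diff.alternative_id, dom.domain_name, status, overlap))
    return impacts


# ---------------------------------------------------------------------------
# functional screening flowchart
# ---------------------------------------------------------------------------

def functional_screen(
    retained: list[RecurrenceRecord],
    genes: list[GeneModel],
    proteins: dict[str, str],
    domains: list[DomainAnnotation],
    gene_sets: list[tuple[str, set[str]]],
    principal_table: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Candidate prioritisation: (1) keep protein-coding isoforms among
    retained differential isoforms; (2) keep those whose principal-relative
    protein diff loses or truncates an annotated domain; (3) attach gene-set
    memberships. Ranked by recurrence, then |concordance|, then isoform id.
    """
    tx_index = {
        t.transcript_id: (g, t) for g in genes for t in g.transcripts
    }
    dom_by_protein: dict[str, list[DomainAnnotation]] = {}
    for d in domains:
        dom_by_protein.setdefault(d.protein_id, []).append(d)
    rows = []
    for rec in retained:
        entry = tx_index.get(rec.isoform_id)
        if entry is None:
            continue
        gene, tx = entry
        if tx.biotype != "protein_coding" or rec.isoform_id not in proteins:
            continue  # stage 1: coding isoforms only
        principal = principal_isoform(gene, principal_table)
        if principal not in proteins:
            continue
        diff = diff_protein(
            proteins[principal], proteins[rec.isoform_id], principal, rec.isoform_id
        )
        impacts = domain_impact(diff, dom_by_protein.get(principal, []))
        hit = [i for i in impacts if i.status in ("lost", "truncated")]
        if not hit:
            continue  # stage 2: domain-impacting isoforms only
        memberships = sorted(
            name for name, members in gene_sets if gene.gene_id in members
        )
        rows.append(
            {
                "isoform_id": rec.isoform_id,
                "gene_id": gene.gene_id,
                "principal_isoform": principal,
                "n_up": rec.n_up,
                "n_down": rec.n_down,
                "recurrence": rec.recurrence,
                "concordance": rec.concordance,
                "impacted_domains": ";".join(
                    f"{i.domain_name}:{i.status}" for i in hit
                ),
                "gene_sets": ";".join(memberships),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "isoform_id", "gene_id", "principal_isoform", "n_up", "n_down",
            "recurrence", "concordance", "impacted_domains", "gene_sets",
        ],
    )
    if not df.empty:
        df = df.sort_values(
            ["recurrence", "concordance", "isoform_id"],
            ascending=[False, False, True],
            key=lambda s: s.abs() if s.name == "concordance" else s,
        ).reset_index(drop=True)
    return df
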