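"""Candidate RNA-binding-protein (RBP) regulators of a target gene's
splicing: binding-site overlap with the gene locus plus expression
correlation between each candidate RBP and the gene's isoforms.

Overlap is computed at the whole-locus level (distal intronic sites count) on
half-open intervals; adjacent intervals never overlap. Correlations default
to expression across all samples, with per-pair log2 fold change as an
alternative scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dei_screen import PairedComparison, per_pair_log2fc
from .io_formats import BindingSite, ExpressionMatrix, GeneModel, ValidationError
from .switch_and_domain import CorrelationResult


@dataclass
class RBPCandidate:
    rbp_name: str
    n_sites_in_gene: int
    correlations: list[CorrelationResult] = field(default_factory=list)

    @property
    def max_abs_r(self) -> float:
        return max((abs(c.r) for c in self.correlations), default=0.0)


def overlapping_rbps(
    gene: GeneModel,
    sites: list[BindingSite],
    strand_mode: str = "ignore",
) -> dict[str, int]:
    """RBPs with at least one binding site intersecting the gene span.

    ``strand_mode='strict'`` additionally requires the site strand to match
    the gene strand ('.' sites never match in strict mode).
    """
    if strand_mode not in ("ignore", "strict"):
        raise ValidationError(f"unknown strand_mode {strand_mode!r}")
    a, b = gene.span
    counts: dict[str, int] = {}
    for s in sites:
        if s.chrom != gene.chrom:
            continue
        if strand_mode == "strict" and s.strand != gene.strand:
            continue
        if s.start < b and a < s.end:  # half-open intersection
            counts[s.rbp_name] = counts.get(s.rbp_name, 0) + 1
    return counts


def rbp_isoform_correlation(
    expr: ExpressionMatrix,
    rbp_isoform: str,
    target_isoforms: list[str],
    pairs: list[PairedComparison] | None = None,
    scope: str = "all_samples",
    pseudocount: float = 0.1,
) -> list[CorrelationResult]:
    """Pearson correlation of an RBP's expression with each target isoform.

    scope='all_samples' correlates TPM across every sample; scope
    'per_pair_log2fc' correlates per-pair log2 fold-change vectors (requires
    ``pairs``).
    """
    if scope == "all_samples":
        x = expr.tpm.loc[rbp_isoform].to_numpy()
        vectors = {t: expr.tpm.loc[t].to_numpy() for t in target_isoforms}
    elif scope == "per_pair_log2fc":
        if pairs is None:
            raise ValidationError("per_pair_log2fc scope requires pairs")
        x = per_pair_log2fc(expr, rbp_isoform, pairs, pseudocount)
        vectors = {
            t: per_pair_log2fc(expr, t, pairs, pseudocount) for t in target_isoforms
        }
    else:
        raise ValidationError(f"unknown scope {scope!r}")
    if len(x) < 3:
        raise ValidationError("need at least 3 observations for correlation")
    out: list[CorrelationResult] = []
    for t, y in vectors.items():
        if np.std(x) == 0 or np.std(y) == 0:
            continue
        r, p = stats.pearsonr(x, y)
        out.append(CorrelationResult(rbp_isoform, t, float(r), float(p), len(x)))
    return out


def screen_rbps(
    gene: GeneModel,
    expr: ExpressionMatrix,
    sites: list[BindingSite],
    rbp_to_isoform: dict[str, str],
    samples: list[str] | None = None,
    strand_mode: str = "ignore",
) -> list[RBPCandidate]:
    """Full screen for one target gene: locus-overlapping RBPs with their
    per-isoform expression correlations (optionally restricted to a sample
    subset, e.g. the DP biopsies)."""
    sub = expr
    if samples is not None:
        from .io_formats import ExpressionMatrix as _EM

        sub = _EM(expr.tpm[samples], expr.isoform_to_gene)
    target_isoforms = [t.transcript_id for t in gene.transcripts
                       if t.transcript_id in sub.tpm.index]
    candidates = []
    for rbp, n_sites in sorted(overlapping_rbps(gene, sites, strand_mode).items()):
        iso = rbp_to_isoform.get(rbp)
        if iso is None or iso not in sub.tpm.index:
            continue
        corrs = rbp_isoform_correlation(sub, iso, target_isoforms)
        candidates.append(RBPCandidate(rbp, n_sites, corrs))
    return candidates


def rank_rbp_candidates(
    candidates: list[RBPCandidate],
    min_abs_r: float = 0.3,
    max_p: float = 0.05,
) -> list[RBPCandidate]:
    """Candidates with |r| >= min_abs_r and p <= max_p for at least one
    isoform, ranked by max |r| descending; ties break by name."""
    passing = [
        c
        for c in candidates
        if any(abs(x.r) >= min_abs_r and x.p <= max_p for x in c.correlations)
    ]
    passing.sort(key=lambda c: (-c.max_abs_r, c.rbp_name))
    return passing
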