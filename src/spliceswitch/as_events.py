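"""Classification of canonical alternative-splicing events from transcript
structures, and abundance-based PSI (percent spliced in) with significance
testing.

Five event modes are recognised from pairwise transcript comparison: skipped
exon (SE), retained intron (RI), alternative 5' splice site (A5SS, donor),
alternative 3' splice site (A3SS, acceptor) and mutually exclusive exons
(MXE). Flank matching requires exact coordinate identity. Donor/acceptor
naming is strand-aware: a right-boundary shift of an exon is a donor (A5SS)
event on the + strand and an acceptor (A3SS) event on the - strand.

PSI is computed from isoform abundances: the TPM of inclusion-supporting
isoforms over the TPM of all isoforms supporting either form — the fraction
of a gene's mRNA containing the inclusion structure — not from junction
reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dei_screen import PairedComparison
from .enrichment import bh_fdr
from .io_formats import ExpressionMatrix, GeneModel, Interval, TranscriptModel

MODES = ("SE", "A5SS", "A3SS", "RI", "MXE")


@dataclass
class ASEvent:
    event_id: str
    gene_id: str
    mode: str
    coordinates: tuple
    inclusion_isoforms: frozenset[str]
    exclusion_isoforms: frozenset[str]


@dataclass
class EventTestResult:
    event_id: str
    gene_id: str
    mode: str
    n_pairs: int
    mean_dpsi: float | None
    p_value: float | None
    q_value: float | None = None
    significant: bool = False
    tested: bool = True


def _consecutive(t: TranscriptModel, *exons: Interval) -> bool:
    """True when ``exons`` appear in t.exons as an adjacent run."""
    ex = [tuple(e) for e in t.exons]
    want = [tuple(e) for e in exons]
    n = len(want)
    return any(ex[i : i + n] == want for i in range(len(ex) - n + 1))


def classify_events(gene: GeneModel) -> list[ASEvent]:
    """All deduplicated pairwise AS events of one gene.

    Support sets contain every gene transcript structurally consistent with
    each form (not just the discovering pair); events whose support sets are
    not both non-empty and disjoint are discarded.
    """
    ts = gene.transcripts
    if len(ts) < 2:
        return []
    strand = gene.strand
    found: dict[tuple, tuple] = {}  # (mode, coords) -> (inc_pred, exc_pred)

    for t1 in ts:
        for t2 in ts:
            if t1 is t2:
                continue
            e1, e2 = t1.exons, t2.exons
            set2 = {tuple(e) for e in e2}
            # SE: internal exon of t1 absent from t2, flanks adjacent in t2
            for i in range(1, len(e1) - 1):
                fl, cas, fr = e1[i - 1], e1[i], e1[i + 1]
                if tuple(cas) not in set2 and _consecutive(t2, fl, fr):
                    coords = (fl, cas, fr)
                    found[("SE", coords)] = (
                        lambda t, fl=fl, cas=cas, fr=fr: _consecutive(t, fl, cas, fr),
                        lambda t, fl=fl, fr=fr, cas=cas: _consecutive(t, fl, fr)
                        and not t.contains_exon(cas),
                    )
            # RI: single exon [a,d) in t1 vs [a,b),[c,d) adjacent in t2
            for a, d in e1:
                for j in range(len(e2) - 1):
                    (a2, b), (c, d2) = e2[j], e2[j + 1]
                    if a2 == a and d2 == d and b < c:
                        coords = (a, b, c, d)
                        found[("RI", coords)] = (
                            lambda t, a=a, d=d: t.contains_exon((a, d)),
                            lambda t, a=a, b=b, c=c, d=d: _consecutive(
                                t, (a, b), (c, d)
                            ),
                        )
            # alt splice sites: shared one boundary, shared flank across intron
            for i in range(len(e1)):
                for j in range(len(e2)):
                    a1, b1 = e1[i]
                    a2, b2 = e2[j]
                    # right-boundary shift (donor on + strand)
                    if a1 == a2 and b1 != b2 and i + 1 < len(e1) and j + 1 < len(e2):
                        if e1[i + 1] == e2[j + 1] and e1[i + 1][0] > max(b1, b2):
                            mode = "A5SS" if strand == "+" else "A3SS"
                            bs, bl = min(b1, b2), max(b1, b2)
                            flank = e1[i + 1]
                            coords = (a1, bs, bl, flank)
                            found[(mode, coords)] = (
                                lambda t, a=a1, bl=bl, fl=flank: _consecutive(
                                    t, (a, bl), fl
                                ),
                                lambda t, a=a1, bs=bs, fl=flank: _consecutive(
                                    t, (a, bs), fl
                                ),
                            )
                    # left-boundary shift (acceptor on + strand)
                    if b1 == b2 and a1 != a2 and i > 0 and j > 0:
                        if e1[i - 1] == e2[j - 1] and e1[i - 1][1] < min(a1, a2):
                            mode = "A3SS" if strand == "+" else "A5SS"
                            al, ashort = min(a1, a2), max(a1, a2)
                            flank = e1[i - 1]
                            coords = (flank, al, ashort, b1)
                            found[(mode, coords)] = (
                                lambda t, fl=flank, al=al, b=b1: _consecutive(
                                    t, fl, (al, b)
                                ),
                                lambda t, fl=flank, a=ashort, b=b1: _consecutive(
                                    t, fl, (a, b)
                                ),
                            )
            # MXE: (L, X, R) in t1 vs (L, Y, R) in t2, X and Y disjoint
            for i in range(1, len(e1) - 1):
                for j in range(1, len(e2) - 1):
                    if e1[i - 1] == e2[j - 1] and e1[i + 1] == e2[j + 1]:
                        x, y = e1[i], e2[j]
                        if x == y or not (x[1] <= y[0] or y[1] <= x[0]):
                            continue
                        first, second = (x, y) if x[0] < y[0] else (y, x)
                        if any(
                            t.contains_exon(first) and t.contains_exon(second)
                            for t in ts
                        ):
                            continue
                        fl, fr = e1[i - 1], e1[i + 1]
                        coords = (fl, first, second, fr)
                        found[("MXE", coords)] = (
                            lambda t, fl=fl, x=first, fr=fr: _consecutive(t, fl, x, fr),
                            lambda t, fl=fl, y=second, fr=fr: _consecutive(t, fl, y, fr),
                        )

    events: list[ASEvent] = []
    for (mode, coords), (inc_pred, exc_pred) in sorted(found.items()):
        inc = frozenset(t.transcript_id for t in ts if inc_pred(t))
        exc = frozenset(t.transcript_id for t in ts if exc_pred(t))
        if not inc or not exc or inc & exc:
            continue
        event_id = f"{gene.gene_id}:{mode}:{_fmt_coords(coords)}"
        events.append(ASEvent(event_id, gene.gene_id, mode, coords, inc, exc))
    return events


def _fmt_coords(coords: tuple) -> str:
    flat: list[str] = []
    for c in coords:
        if isinstance(c, tuple):
            flat.append(f"{c[0]}-{c[1]}")
        else:
            flat.append(str(c))
    return "_".join(flat)


def classify_all(genes: list[GeneModel]) -> list[ASEvent]:
    out: list[ASEvent] = []
    for g in genes:
        out.extend(classify_events(g))
    return out


# ---------------------------------------------------------------------------
# PSI
# ---------------------------------------------------------------------------

def compute_psi(event: ASEvent, expr: ExpressionMatrix) -> pd.Series:
    """Per-sample PSI of one event; NaN marks samples with zero total TPM."""
    inc_ids = [i for i in event.inclusion_isoforms if i in expr.tpm.index]
    exc_ids = [i for i in event.exclusion_isoforms if i in expr.tpm.index]
    inc = expr.tpm.loc[inc_ids].sum(axis=0)
    total = inc + expr.tpm.loc[exc_ids].sum(axis=0)
    psi = inc / total.where(total > 0)
    psi.name = event.event_id
    return psi


def exon_psi(gene: GeneModel, exon: Interval, expr: ExpressionMatrix) -> pd.Series:
    """PSI of an exact exon interval: TPM of gene transcripts carrying the
    exon over the gene's total TPM (the fraction of the gene's mRNA
    containing that exon)."""
    exon = (int(exon[0]), int(exon[1]))
    inc_ids = [t.transcript_id for t in gene.transcripts if t.contains_exon(exon)]
    all_ids = [t.transcript_id for t in gene.transcripts if t.transcript_id in expr.tpm.index]
    inc_ids = [i for i in inc_ids if i in expr.tpm.index]
    inc = expr.tpm.loc[inc_ids].sum(axis=0) if inc_ids else pd.Series(0.0, index=expr.tpm.columns)
    total = expr.tpm.loc[all_ids].sum(axis=0)
    psi = inc / total.where(total > 0)
    psi.name = f"{gene.gene_id}:exon:{exon[0]}-{exon[1]}"
    return psi


def test_events(
    events: list[ASEvent],
    expr: ExpressionMatrix,
    pairs: list[PairedComparison],
    dpsi_min: float = 0.1,
    fdr_alpha: float = 0.05,
    min_pairs: int = 3,
) -> list[EventTestResult]:
    """Paired differential-PSI test per event with BH correction.

    Per pair, dPSI = PSI_DP - PSI_Baseline; events with fewer than
    ``min_pairs`` informative pairs are reported untested rather than given
    p = 1. Significance needs both |mean dPSI| > dpsi_min and q < fdr_alpha.
    """
    results: list[EventTestResult] = []
    tested_idx: list[int] = []
    pvals: list[float] = []
    for ev in events:
        psi = compute_psi(ev, expr)
        deltas = np.array(
            [psi[p.dp_sample] - psi[p.baseline_sample] for p in pairs], dtype=float
        )
        deltas = deltas[~np.isnan(deltas)]
        if len(deltas) < min_pairs:
            results.append(
                EventTestResult(ev.event_id, ev.gene_id, ev.mode, len(deltas),
                                None, None, tested=False)
            )
            continue
        mean = float(deltas.mean())
        sd = deltas.std(ddof=1)
        if np.isclose(sd, 0.0):
            p = 1.0 if math.isclose(mean, 0.0, abs_tol=1e-12) else 0.0
        else:
            p = float(stats.ttest_1samp(deltas, 0.0).pvalue)
        tested_idx.append(len(results))
        pvals.append(p)
        results.append(
            EventTestResult(ev.event_id, ev.gene_id, ev.mode, len(deltas), mean, p)
        )
    if pvals:
        qvals = bh_fdr(np.array(pvals))
        for idx, q in zip(tested_idx, qvals):
            r = results[idx]
            r.q_value = float(q)
            r.significant = abs(r.mean_dpsi) > dpsi_min and r.q_value < fdr_alpha
    return results


def event_mode_distribution(items) -> dict[str, float]:
    """Proportion of each event mode among ``items`` (events or test
    results); proportions sum to 1 over the modes present."""
    modes = [getattr(x, "mode") for x in items]
    if not modes:
        return {}
    counts = pd.Series(modes).value_counts()
    return (counts / counts.sum()).to_dict()
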