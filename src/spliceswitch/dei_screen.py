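"""Per-pair differential isoform calling, recurrence ranking and cohort
summaries for matched Baseline / disease-progression (DP) biopsy designs.

An isoform is evaluated in a patient-matched pair only if it reaches
``tpm_min`` TPM (default 10) in at least one of the two samples; the fold
change FC = DP/Baseline is called differential when |1 - FC| > 0.2, applied on
the raw FC scale (FC < 0.8 or FC > 1.2, deliberately asymmetric). Recurrence
counts the pairs in which an isoform is called up or down, and the concordance
filter keeps isoforms whose up/down counts differ by more than ``min_diff``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix, SampleSheet, ValidationError


@dataclass(frozen=True)
class PairedComparison:
    patient_id: str
    baseline_sample: str
    dp_sample: str


@dataclass(frozen=True)
class DEICall:
    isoform_id: str
    patient_id: str
    dp_sample: str
    fc: float
    log2fc: float
    direction: str  # "up" | "down"


@dataclass
class RecurrenceRecord:
    isoform_id: str
    n_up: int
    n_down: int
    n_pairs: int

    @property
    def concordance(self) -> int:
        return self.n_up - self.n_down

    @property
    def recurrence(self) -> int:
        return max(self.n_up, self.n_down)


def make_pairs(sheet: SampleSheet) -> list[PairedComparison]:
    """One comparison per DP sample, matched to its patient's Baseline."""
    return [
        PairedComparison(r.patient_id, sheet.baseline_of(r.patient_id), r.sample_id)
        for r in sheet.by_condition("DP")
    ]


def call_dei_pair(
    expr: ExpressionMatrix,
    pair: PairedComparison,
    tpm_min: float = 10.0,
    fc_cutoff: float = 0.2,
    pseudocount: float = 0.1,
) -> list[DEICall]:
    """Differential isoform calls for one matched pair.

    With pseudocount 0 and zero baseline TPM the fold change is +inf and is
    treated as an up call, never a division error.
    """
    base = expr.tpm[pair.baseline_sample].to_numpy()
    dp = expr.tpm[pair.dp_sample].to_numpy()
    calls: list[DEICall] = []
    for iso, b, d in zip(expr.isoform_ids, base, dp):
        if max(b, d) < tpm_min:
            continue
        denom = b + pseudocount
        if denom == 0:
            if d + pseudocount == 0:
                continue
            fc = math.inf
        else:
            fc = (d + pseudocount) / denom
        if abs(1.0 - fc) > fc_cutoff:
            calls.append(
                DEICall(
                    iso,
                    pair.patient_id,
                    pair.dp_sample,
                    fc,
                    math.log2(fc) if 0 < fc < math.inf else math.copysign(math.inf, 1),
                    "up" if fc > 1 else "down",
                )
            )
    return calls


def call_dei(
    expr: ExpressionMatrix,
    pairs: list[PairedComparison],
    tpm_min: float = 10.0,
    fc_cutoff: float = 0.2,
    pseudocount: float = 0.1,
) -> list[DEICall]:
    calls: list[DEICall] = []
    for pair in pairs:
        calls.extend(call_dei_pair(expr, pair, tpm_min, fc_cutoff, pseudocount))
    return calls


def recurrence(calls: list[DEICall], pairs: list[PairedComparison]) -> list[RecurrenceRecord]:
    """Per-isoform up/down counts, ranked by recurrence.

    Sort: max(n_up, n_down) descending, ties by concordance descending, then
    isoform_id ascending — fully deterministic.
    """
    n_pairs = len(pairs)
    counts: dict[str, list[int]] = {}
    for c in calls:
        row = counts.setdefault(c.isoform_id, [0, 0])
        row[0 if c.direction == "up" else 1] += 1
    records = [
        RecurrenceRecord(iso, up, down, n_pairs) for iso, (up, down) in counts.items()
    ]
    records.sort(key=lambda r: (-r.recurrence, -r.concordance, r.isoform_id))
    return records


def concordance_filter(
    records: list[RecurrenceRecord], min_diff: int = 6
) -> list[RecurrenceRecord]:
    """Keep isoforms whose |n_up - n_down| strictly exceeds ``min_diff``."""
    return [r for r in records if abs(r.concordance) > min_diff]


def cumulative_recurrence_curve(records: list[RecurrenceRecord]) -> pd.DataFrame:
    """Number of isoforms whose recurrence max(n_up, n_down) >= k, for each k."""
    if not records:
        return pd.DataFrame({"k": [0], "n_isoforms": [0]})
    recs = np.array([r.recurrence for r in records])
    kmax = int(recs.max())
    rows = [(k, int((recs >= k).sum())) for k in range(0, kmax + 1)]
    return pd.DataFrame(rows, columns=["k", "n_isoforms"])


def sharing_stats(
    expr: ExpressionMatrix, sheet: SampleSheet, presence_tpm: float = 1.0
) -> dict[str, float]:
    """Venn-style sharing of detected isoforms between Baseline and DP groups.

    An isoform is present in a group when it reaches ``presence_tpm`` in at
    least one sample of that group.
    """
    base_samples = [r.sample_id for r in sheet.by_condition("Baseline")]
    dp_samples = [r.sample_id for r in sheet.by_condition("DP")]
    in_base = (expr.tpm[base_samples] >= presence_tpm).any(axis=1)
    in_dp = (expr.tpm[dp_samples] >= presence_tpm).any(axis=1)
    n_shared = int((in_base & in_dp).sum())
    n_base_only = int((in_base & ~in_dp).sum())
    n_dp_only = int((~in_base & in_dp).sum())
    total = n_shared + n_base_only + n_dp_only
    return {
        "n_baseline_only": n_base_only,
        "n_dp_only": n_dp_only,
        "n_shared": n_shared,
        "shared_fraction": n_shared / total if total else 0.0,
    }


def normalized_entropy(proportions: np.ndarray) -> float:
    """Shannon entropy of isoform proportions, normalized to [0,1] by log2(m)."""
    p = np.asarray(proportions, dtype=float)
    m = len(p)
    if m < 2:
        raise ValidationError("entropy undefined for fewer than 2 isoforms")
    nz = p[p > 0]
    h = -(nz * np.log2(nz)).sum()
    return float(h / np.log2(m))


def isoform_diversity(
    expr: ExpressionMatrix,
    pseudocount: float = 0.1,
    altered_genes: set[str] | None = None,
):
    """Per-gene, per-sample normalized Shannon entropy of isoform usage.

    Laplace pseudocount is added to each isoform's TPM before computing
    proportions. Single-isoform genes are reported as missing. When
    ``altered_genes`` is given, also returns a Wilcoxon rank-sum comparison of
    mean per-gene diversity between altered and non-altered multi-isoform
    genes.
    """
    gene_map = pd.Series(expr.isoform_to_gene)
    rows = []
    for gene, idx in expr.tpm.groupby(gene_map.reindex(expr.tpm.index)).groups.items():
        sub = expr.tpm.loc[idx]
        if len(sub) < 2:
            continue
        vals = sub.to_numpy() + pseudocount
        props = vals / vals.sum(axis=0, keepdims=True)
        logm = np.log2(len(sub))
        h = -(np.where(props > 0, props * np.log2(props), 0.0)).sum(axis=0) / logm
        for sample, hv in zip(sub.columns, h):
            rows.append((gene, sample, float(hv)))
    div = pd.DataFrame(rows, columns=["gene_id", "sample_id", "entropy"])
    if altered_genes is None:
        return div, None
    mean_h = div.groupby("gene_id")["entropy"].mean()
    a = mean_h[mean_h.index.isin(altered_genes)]
    b = mean_h[~mean_h.index.isin(altered_genes)]
    if len(a) == 0 or len(b) == 0:
        return div, None
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return div, {"statistic": float(stat), "p_value": float(p),
                 "mean_altered": float(a.mean()), "mean_other": float(b.mean())}


def paired_group_test(
    expr: ExpressionMatrix,
    isoform_id: str,
    pairs: list[PairedComparison],
    pseudocount: float = 0.1,
) -> tuple[float, float]:
    """Classical paired t-test on log2(TPM + pseudocount) across matched pairs.

    Zero-variance differences are guarded: t is +/-inf with p = 0 when the
    common difference is nonzero, and t = 0 with p = 1 when it is zero.
    """
    if len(pairs) < 2:
        raise ValidationError("paired test needs at least 2 pairs")
    base = np.array([expr.value(isoform_id, p.baseline_sample) for p in pairs])
    dp = np.array([expr.value(isoform_id, p.dp_sample) for p in pairs])
    diffs = np.log2(dp + pseudocount) - np.log2(base + pseudocount)
    if np.allclose(diffs.std(ddof=1), 0.0):
        mean = diffs.mean()
        if math.isclose(mean, 0.0, abs_tol=1e-12):
            return 0.0, 1.0
        return math.copysign(math.inf, mean), 0.0
    t, p = stats.ttest_rel(np.log2(dp + pseudocount), np.log2(base + pseudocount))
    return float(t), float(p)


def per_pair_log2fc(
    expr: ExpressionMatrix,
    isoform_id: str,
    pairs: list[PairedComparison],
    pseudocount: float = 0.1,
) -> np.ndarray:
    base = np.array([expr.value(isoform_id, p.baseline_sample) for p in pairs])
    dp = np.array([expr.value(isoform_id, p.dp_sample) for p in pairs])
    return np.log2(dp + pseudocount) - np.log2(base + pseudocount)
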