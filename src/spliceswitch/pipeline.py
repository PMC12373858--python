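"""End-to-end orchestration: simulate or load a cohort, run every analysis
stage, and write the report tables with a manifest. Reruns with the same
config and seed produce byte-identical outputs."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .as_events import classify_all, event_mode_distribution, test_events
from .dei_screen import (
    call_dei,
    concordance_filter,
    cumulative_recurrence_curve,
    isoform_diversity,
    make_pairs,
    recurrence,
    sharing_stats,
)
from .enrichment import crossover, ora
from .io_formats import (
    ValidationError,
    read_bed_sites,
    read_domains,
    read_expression_matrix,
    read_fasta,
    read_gmt,
    read_gtf,
    read_sample_sheet,
)
from .rbp_screen import rank_rbp_candidates, screen_rbps
from .switch_and_domain import (
    detect_switches,
    functional_screen,
    reciprocal_recurrence,
)
from .synthetic_data import SimulationConfig, simulate_cohort, write_cohort

logger = logging.getLogger(__name__)


def percent_recurrence(n_events: int, n_total: int) -> float:
    """Percentage with half-up rounding to 2 decimals (the reporting style
    of recurrent-event counts, e.g. 13/44 -> 29.55)."""
    if n_total <= 0:
        raise ValidationError("n_total must be positive")
    if not 0 <= n_events <= n_total:
        raise ValidationError("n_events outside [0, n_total]")
    pct = Decimal(100 * n_events) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class PipelineConfig:
    outdir: str = "spliceswitch_run"
    seed: int = 0
    tpm_min: float = 10.0
    fc_cutoff: float = 0.2
    pseudocount: float = 0.1
    min_concordance: int = 6
    dpsi_min: float = 0.1
    fdr_alpha: float = 0.05
    min_abs_r: float = 0.5
    max_p: float = 0.05
    presence_tpm: float = 1.0
    simulate: SimulationConfig | None = None
    inputs: dict | None = None  # paths: gtf, expression, sample_sheet, ...

    def __post_init__(self) -> None:
        if self.simulate is None and not self.inputs:
            raise ValidationError("config needs either a simulate block or input paths")
        for name, lo, hi in (
            ("fc_cutoff", 0, None), ("dpsi_min", 0, 1), ("fdr_alpha", 0, 1),
            ("max_p", 0, 1), ("min_abs_r", 0, 1),
        ):
            v = getattr(self, name)
            if v < lo or (hi is not None and v > hi):
                raise ValidationError(f"{name}={v} out of range")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        sim = data.pop("simulate", None)
        if sim is not None:
            if "isoforms_per_gene" in sim:
                sim["isoforms_per_gene"] = tuple(sim["isoforms_per_gene"])
            sim = SimulationConfig(**sim)
        return cls(simulate=sim, **data)


def _load_inputs(paths: dict):
    genes = read_gtf(paths["gtf"])
    gene_map = {t.transcript_id: g.gene_id for g in genes for t in g.transcripts}
    expr = read_expression_matrix(paths["expression"], gene_map)
    sheet = read_sample_sheet(paths["sample_sheet"])
    proteins = read_fasta(paths["proteins"]) if "proteins" in paths else {}
    domains = read_domains(paths["domains"]) if "domains" in paths else []
    sites = read_bed_sites(paths["sites"]) if "sites" in paths else []
    gene_sets = read_gmt(paths["gene_sets"]) if "gene_sets" in paths else []
    return genes, expr, sheet, proteins, domains, sites, gene_sets


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute simulate -> dei -> events -> switch -> domains -> enrich ->
    rbp -> report; returns the report bundle and writes every stage output
    under ``config.outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        sim_cfg = config.simulate
        bundle = simulate_cohort(sim_cfg)
        write_cohort(bundle, out / "cohort")
        genes = bundle.annotation.genes
        expr, sheet = bundle.expression, bundle.sheet
        proteins = bundle.annotation.proteins
        domains = bundle.annotation.domains
        sites = bundle.annotation.sites
        gene_sets = bundle.annotation.gene_sets
        truth = bundle.truth
    else:
        genes, expr, sheet, proteins, domains, sites, gene_sets = _load_inputs(
            config.inputs
        )
        truth = None

    pairs = make_pairs(sheet)
    logger.info("pairs: %d (patients %d)", len(pairs),
                len({p.patient_id for p in pairs}))

    # --- differential isoforms -------------------------------------------
    calls = call_dei(expr, pairs, config.tpm_min, config.fc_cutoff, config.pseudocount)
    records = recurrence(calls, pairs)
    retained = concordance_filter(records, config.min_concordance)
    logger.info("dei: %d calls, %d isoforms, %d retained after concordance filter",
                len(calls), len(records), len(retained))
    curve = cumulative_recurrence_curve(records)
    sharing = sharing_stats(expr, sheet, config.presence_tpm)
    altered_genes = {expr.isoform_to_gene[r.isoform_id] for r in retained}
    diversity, diversity_test = isoform_diversity(
        expr, config.pseudocount, altered_genes
    )

    pd.DataFrame(
        [(c.isoform_id, c.patient_id, c.dp_sample, c.fc, c.log2fc, c.direction)
         for c in calls],
        columns=["isoform_id", "patient_id", "dp_sample", "fc", "log2fc", "direction"],
    ).to_csv(out / "dei_calls.tsv", sep="\t", index=False, float_format="%.6g")
    pd.DataFrame(
        [(r.isoform_id, r.n_up, r.n_down, r.n_pairs, r.concordance, r.recurrence)
         for r in records],
        columns=["isoform_id", "n_up", "n_down", "n_pairs", "concordance", "recurrence"],
    ).to_csv(out / "recurrence.tsv", sep="\t", index=False)
    curve.to_csv(out / "cumulative_recurrence.tsv", sep="\t", index=False)
    diversity.to_csv(out / "diversity.tsv", sep="\t", index=False, float_format="%.6g")

    # --- splicing events ---------------------------------------------------
    events = classify_all(genes)
    tests = test_events(events, expr, pairs, config.dpsi_min, config.fdr_alpha)
    significant = [t for t in tests if t.significant]
    logger.info("events: %d classified, %d tested, %d significant",
                len(events), sum(t.tested for t in tests), len(significant))
    pd.DataFrame(
        [(e.event_id, e.gene_id, e.mode,
          ";".join(sorted(e.inclusion_isoforms)), ";".join(sorted(e.exclusion_isoforms)))
         for e in events],
        columns=["event_id", "gene_id", "mode", "inclusion", "exclusion"],
    ).to_csv(out / "events.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(t.event_id, t.gene_id, t.mode, t.n_pairs, t.mean_dpsi, t.p_value,
          t.q_value, t.significant, t.tested) for t in tests],
        columns=["event_id", "gene_id", "mode", "n_pairs", "mean_dpsi",
                 "p_value", "q_value", "significant", "tested"],
    ).to_csv(out / "event_tests.tsv", sep="\t", index=False, float_format="%.6g")

    # --- switches and domain impact ---------------------------------------
    switches = detect_switches(
        genes, expr, pairs, calls,
        config.min_abs_r, config.max_p, config.min_concordance,
        config.max_p, config.pseudocount,
    )
    switch_rows = []
    for s in switches:
        n_rec, pct = reciprocal_recurrence(s.up_isoform, s.down_isoform, calls, pairs)
        switch_rows.append(
            (s.gene_id, s.up_isoform, s.down_isoform, n_rec, s.n_pairs,
             percent_recurrence(n_rec, s.n_pairs), s.pearson_r, s.p_value)
        )
    switches_df = pd.DataFrame(
        switch_rows,
        columns=["gene_id", "up_isoform", "down_isoform", "n_reciprocal_pairs",
                 "n_pairs", "pct_pairs", "pearson_r", "p_value"],
    ).sort_values(["n_reciprocal_pairs", "gene_id"],
                  ascending=[False, True]).reset_index(drop=True)
    switches_df.to_csv(out / "switches.tsv", sep="\t", index=False, float_format="%.6g")
    candidates = functional_screen(retained, genes, proteins, domains, gene_sets)
    candidates.to_csv(out / "functional_candidates.tsv", sep="\t", index=False)
    logger.info("switch: %d calls; screen: %d candidates", len(switches), len(candidates))

    # --- enrichment ---------------------------------------------------------
    universe = {expr.isoform_to_gene[i] for i in expr.isoform_ids}
    dei_genes = {expr.isoform_to_gene[r.isoform_id] for r in retained}
    enr = ora(dei_genes & universe, gene_sets, universe, config.fdr_alpha)
    pd.DataFrame(
        [(r.term, r.k, r.K, r.n, r.N, r.p, r.q) for r in enr],
        columns=["term", "k", "K", "n", "N", "p", "q"],
    ).to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
    cross = crossover(dei_genes, gene_sets, universe)
    pd.DataFrame(cross).to_csv(out / "crossover.tsv", sep="\t", index=False,
                               float_format="%.6g")

    # --- RBP screen on the top switch gene ---------------------------------
    rbp_rows = []
    top_gene = switches_df["gene_id"].iloc[0] if len(switches_df) else None
    if top_gene is not None and sites:
        gene = next(g for g in genes if g.gene_id == top_gene)
        rbp_names = {s.rbp_name for s in sites}
        rbp_to_isoform = {}
        by_gene = {g.gene_id: g for g in genes}
        for name in rbp_names:
            g = by_gene.get(name)
            if g is not None:
                rbp_to_isoform[name] = g.transcripts[0].transcript_id
        cands = screen_rbps(gene, expr, sites, rbp_to_isoform)
        ranked = rank_rbp_candidates(cands, min_abs_r=0.3, max_p=config.max_p)
        for c in ranked:
            rbp_rows.append((top_gene, c.rbp_name, c.n_sites_in_gene, c.max_abs_r))
    pd.DataFrame(
        rbp_rows, columns=["target_gene", "rbp_name", "n_sites", "max_abs_r"]
    ).to_csv(out / "rbp_candidates.tsv", sep="\t", index=False, float_format="%.6g")

    # --- summary ------------------------------------------------------------
    per_pair = pd.DataFrame(
        [(c.dp_sample, c.direction) for c in calls], columns=["dp_sample", "direction"]
    )
    updown = (
        per_pair.groupby(["dp_sample", "direction"]).size().unstack(fill_value=0)
        if len(per_pair)
        else pd.DataFrame()
    )
    report = {
        "n_isoforms": len(expr.isoform_ids),
        "n_genes": len({expr.isoform_to_gene[i] for i in expr.isoform_ids}),
        "n_pairs": len(pairs),
        "n_dei_calls": len(calls),
        "n_dei_isoforms": len(records),
        "n_retained_isoforms": len(retained),
        "sharing": sharing,
        "diversity_test": diversity_test,
        "n_events": len(events),
        "n_significant_events": len(significant),
        "event_mode_distribution": event_mode_distribution(significant),
        "n_switch_genes_called": len(switches),
        "top_switch": switch_rows[0][:6] if switch_rows else None,
        "n_functional_candidates": int(len(candidates)),
    }
    audit_report(report)
    with open(out / "summary.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    updown.to_csv(out / "per_pair_updown.tsv", sep="\t")

    manifest = {
        "package": "spliceswitch",
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "tpm_min": config.tpm_min, "fc_cutoff": config.fc_cutoff,
            "min_concordance": config.min_concordance, "dpsi_min": config.dpsi_min,
            "fdr_alpha": config.fdr_alpha, "min_abs_r": config.min_abs_r,
            "max_p": config.max_p, "pseudocount": config.pseudocount,
            "presence_tpm": config.presence_tpm,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    bundle_out = {
        "report": report, "pairs": pairs, "calls": calls, "records": records,
        "retained": retained, "events": events, "tests": tests,
        "switches": switches, "switches_df": switches_df, "candidates": candidates,
        "enrichment": enr, "crossover": cross, "rbp": rbp_rows, "truth": truth,
        "outdir": out,
    }
    return bundle_out


def audit_report(report: dict) -> None:
    """Internal consistency audit: totals equal sums of their parts."""
    sh = report["sharing"]
    total = sh["n_baseline_only"] + sh["n_dp_only"] + sh["n_shared"]
    if total and abs(sh["shared_fraction"] - sh["n_shared"] / total) > 1e-9:
        raise ValidationError("sharing fraction inconsistent with counts")
    if report["n_retained_isoforms"] > report["n_dei_isoforms"]:
        raise ValidationError("retained isoforms exceed called isoforms")
    dist = report["event_mode_distribution"]
    if dist and abs(sum(dist.values()) - 1.0) > 1e-9:
        raise ValidationError("event mode proportions do not sum to 1")


def switch_performance(bundle: dict) -> dict:
    """Sensitivity and precision of switch calling against ground truth
    (simulated cohorts only)."""
    truth = bundle["truth"]
    if truth is None:
        raise ValidationError("no ground truth available")
    called = {s.gene_id for s in bundle["switches"]}
    tp = len(called & truth.switch_genes)
    fp = len(called - truth.switch_genes)
    fn = len(truth.switch_genes - called)
    return {
        "tp": tp, "fp": fp, "fn": fn,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
    }
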