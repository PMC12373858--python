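import numpy as np
import pandas as pd
import pytest

from spliceswitch.dei_screen import (
    DEICall,
    PairedComparison,
    call_dei,
    concordance_filter,
    make_pairs,
    recurrence,
)
from spliceswitch.io_formats import (
    DomainAnnotation,
    ExpressionMatrix,
    GeneModel,
    TranscriptModel,
    ValidationError,
)
from spliceswitch.switch_and_domain import (
    apply_diff,
    correlate_fc_dpsi,
    detect_switches,
    diff_protein,
    domain_impact,
    functional_screen,
    principal_isoform,
    reciprocal_recurrence,
    switch_candidates,
)


def _two_isoform_gene():
    t1 = TranscriptModel("G-1", "G", "chr1", "+", [(0, 90), (200, 290)])
    t2 = TranscriptModel("G-2", "G", "chr1", "+", [(0, 90)])
    return GeneModel("G", [t1, t2])


def _expr_from_log2fc(v1, v2, n):
    """Expression whose per-pair log2FC (pseudocount 0.1) equals v1/v2."""
    samples = [f"B{i}" for i in range(n)] + [f"D{i}" for i in range(n)]
    base = 10.0
    rows = {
        "G-1": [base] * n + [(base + 0.1) * 2.0 ** x - 0.1 for x in v1],
        "G-2": [base] * n + [(base + 0.1) * 2.0 ** x - 0.1 for x in v2],
    }
    expr = ExpressionMatrix(
        pd.DataFrame(rows, index=samples).T, {"G-1": "G", "G-2": "G"}
    )
    pairs = [PairedComparison(f"P{i}", f"B{i}", f"D{i}") for i in range(n)]
    return expr, pairs


class TestSwitchCandidates:
    def test_exactly_opposite_vectors_give_r_minus_one(self):
        v = np.linspace(-1.5, 1.5, 8)
        expr, pairs = _expr_from_log2fc(v, -v, 8)
        cands = switch_candidates(_two_isoform_gene(), expr, [], pairs)
        assert cands and cands[0].pearson_r == pytest.approx(-1.0)

    def test_independent_noise_yields_no_call(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(20):
            v1, v2 = rng.normal(size=44), rng.normal(size=44)
            expr, pairs = _expr_from_log2fc(v1, v2, 44)
            hits += bool(switch_candidates(_two_isoform_gene(), expr, [], pairs))
        assert hits == 0

    def test_synthetic_switch_pair_strongly_anticorrelated(self, small_cohort):
        from spliceswitch.synthetic_data import SimulationConfig, simulate_cohort

        b = simulate_cohort(SimulationConfig(n_genes=40, seed=3, noise_sd=0.1))
        pairs = make_pairs(b.sheet)
        calls = call_dei(b.expression, pairs)
        gid = sorted(b.truth.switch_genes)[0]
        gene = next(g for g in b.annotation.genes if g.gene_id == gid)
        cands = switch_candidates(gene, b.expression, calls, pairs)
        assert cands and cands[0].pearson_r <= -0.9
        inc, skip = b.annotation.switch_isoforms[gid]
        assert (cands[0].up_isoform, cands[0].down_isoform) == (inc, skip)


class TestReciprocalRecurrence:
    def _calls(self, iso, direction, samples):
        return [DEICall(iso, "P", s, 2.0, 1.0, direction) for s in samples]

    def test_printed_marginals_reproduce_joint_count(self):
        # up in pairs 1..15, down in pairs 3..24 -> joint {3..15} = 13 of 44
        pairs = [PairedComparison("P", "B", f"D{i}") for i in range(1, 45)]
        calls = self._calls("UP", "up", [f"D{i}" for i in range(1, 16)])
        calls += self._calls("DN", "down", [f"D{i}" for i in range(3, 25)])
        n, pct = reciprocal_recurrence("UP", "DN", calls, pairs)
        assert n == 13
        assert pct == pytest.approx(100 * 13 / 44)

    def test_disjoint_and_identical_sets(self):
        pairs = [PairedComparison("P", "B", f"D{i}") for i in range(44)]
        up = self._calls("UP", "up", [f"D{i}" for i in range(5)])
        down = self._calls("DN", "down", [f"D{i}" for i in range(5, 10)])
        assert reciprocal_recurrence("UP", "DN", up + down, pairs)[0] == 0
        down_same = self._calls("DN", "down", [f"D{i}" for i in range(5)])
        n, pct = reciprocal_recurrence("UP", "DN", up + down_same, pairs)
        assert n == 5 and pct == pytest.approx(100 * 5 / 44)

    def test_bounded_by_marginals(self, default_cohort):
        b = default_cohort
        pairs = make_pairs(b.sheet)
        calls = call_dei(b.expression, pairs)
        recs = {r.isoform_id: r for r in recurrence(calls, pairs)}
        for gid in sorted(b.truth.switch_genes)[:10]:
            inc, skip = b.annotation.switch_isoforms[gid]
            n, _ = reciprocal_recurrence(inc, skip, calls, pairs)
            assert n <= min(recs[inc].n_up, recs[skip].n_down)


class TestCorrelation:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        res = correlate_fc_dpsi(x, 2 * x)
        assert res.r == pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        res = correlate_fc_dpsi([1.0, 2.0, 3.0], [1.0, 2.0, 2.0])
        assert res.r == pytest.approx(0.8660, abs=1e-4)

    def test_too_few_complete_pairs(self):
        with pytest.raises(ValidationError, match="fewer than 3"):
            correlate_fc_dpsi([1.0, np.nan, 3.0], [1.0, 2.0, np.nan])

    def test_switch_gene_fc_tracks_exon_psi(self, default_cohort):
        # the inclusion isoform's per-pair log2FC correlates positively with
        # the cassette exon's per-pair delta-PSI
        from spliceswitch.as_events import exon_psi
        from spliceswitch.dei_screen import per_pair_log2fc

        b = default_cohort
        pairs = make_pairs(b.sheet)
        gid = sorted(b.truth.switch_genes)[0]
        gene = next(g for g in b.annotation.genes if g.gene_id == gid)
        inc, _ = b.annotation.switch_isoforms[gid]
        psi = exon_psi(gene, b.truth.skipped_exon[gid], b.expression)
        dpsi = np.array([psi[p.dp_sample] - psi[p.baseline_sample] for p in pairs])
        fc = per_pair_log2fc(b.expression, inc, pairs)
        res = correlate_fc_dpsi(fc, dpsi)
        assert res.r > 0.4 and res.p < 0.05


class TestPrincipalIsoform:
    def _gene(self, cds1, cds2):
        t1 = TranscriptModel("G-1", "G", "chr1", "+", [(0, 2000)], cds=[(0, cds1)])
        t2 = TranscriptModel("G-2", "G", "chr1", "+", [(0, 2000)], cds=[(0, cds2)])
        return GeneModel("G", [t1, t2])

    def test_table_wins(self):
        g = self._gene(900, 1029)
        assert principal_isoform(g, {"G": "G-1"}) == "G-1"

    def test_longest_cds_else_lexicographic(self):
        assert principal_isoform(self._gene(900, 1029)) == "G-2"
        assert principal_isoform(self._gene(900, 900)) == "G-1"


class TestProteinDiff:
    def test_contiguous_43aa_deletion(self):
        rng = np.random.default_rng(1)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        principal = "".join(rng.choice(list(aas), size=481))
        alt = principal[:200] + principal[243:]
        diff = diff_protein(principal, alt)
        assert not diff.frameshift
        dels = [s for s in diff.segments if s.kind == "deletion"]
        assert len(dels) == 1 and dels[0].length == 43
        assert apply_diff(principal, diff, alt) == alt

    def test_identical_sequences(self):
        assert diff_protein("MKTAY", "MKTAY").segments == []

    def test_n_terminal_truncation(self):
        rng = np.random.default_rng(2)
        principal = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=120))
        alt = principal[10:]
        diff = diff_protein(principal, alt)
        dels = [s for s in diff.segments if s.kind == "deletion"]
        assert len(dels) == 1 and dels[0].principal_interval == (1, 10)

    def test_divergent_tail_flags_frameshift(self):
        rng = np.random.default_rng(3)
        principal = "".join(rng.choice(list("ACDEFGH"), size=100))
        alt = principal[:60] + "".join(rng.choice(list("KLMNPQRSTVWY"), size=40))
        diff = diff_protein(principal, alt)
        assert diff.frameshift

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            diff_protein("", "MK")


class TestDomainImpact:
    def _del_diff(self, a, b):
        from spliceswitch.switch_and_domain import DiffSegment, ProteinDiff

        return ProteinDiff("P", "A", [DiffSegment("deletion", (a, b), (a, a - 1))])

    @pytest.mark.parametrize(
        "deletion, domain, status, overlap",
        [
            ((150, 192), (100, 200), "truncated", 43),
            ((300, 320), (100, 200), "intact", 0),
            ((90, 210), (100, 200), "lost", 101),
        ],
    )
    def test_interval_arithmetic(self, deletion, domain, status, overlap):
        (imp,) = domain_impact(
            self._del_diff(*deletion),
            [DomainAnnotation("P", "D", *domain)],
        )
        assert (imp.status, imp.overlap_aa) == (status, overlap)

    def test_frameshift_loses_downstream_domains(self):
        from spliceswitch.switch_and_domain import DiffSegment, ProteinDiff

        diff = ProteinDiff(
            "P", "A",
            [DiffSegment("substitution", (50, 100), (50, 100))],
            frameshift=True,
        )
        imps = domain_impact(
            diff,
            [DomainAnnotation("P", "up", 10, 30), DomainAnnotation("P", "down", 60, 90)],
        )
        by_name = {i.domain_name: i for i in imps}
        assert by_name["down"].status == "lost"
        assert by_name["up"].status == "intact"


class TestDetectAndScreen:
    def test_recovers_planted_switches(self, default_cohort):
        b = default_cohort
        pairs = make_pairs(b.sheet)
        calls = call_dei(b.expression, pairs)
        switches = detect_switches(b.annotation.genes, b.expression, pairs, calls)
        called = {s.gene_id for s in switches}
        tp = len(called & b.truth.switch_genes)
        assert tp / len(b.truth.switch_genes) >= 0.9
        for s in switches:
            if s.gene_id in b.truth.switch_genes:
                assert (s.up_isoform, s.down_isoform) == b.annotation.switch_isoforms[
                    s.gene_id
                ]

    def test_screen_keeps_skip_isoforms_drops_intact_and_noncoding(self, default_cohort):
        b = default_cohort
        pairs = make_pairs(b.sheet)
        calls = call_dei(b.expression, pairs)
        retained = concordance_filter(recurrence(calls, pairs))
        table = functional_screen(
            retained,
            b.annotation.genes,
            b.annotation.proteins,
            b.annotation.domains,
            b.annotation.gene_sets,
        )
        skip_isoforms = {
            b.annotation.switch_isoforms[g][1]
            for g in b.truth.switch_genes
        }
        retained_skips = {r.isoform_id for r in retained} & skip_isoforms
        assert retained_skips  # switches survive the concordance filter
        assert retained_skips <= set(table.isoform_id)
        # non-coding isoforms and principal (diff-free) isoforms are excluded
        coding = {
            t.transcript_id
            for g in b.annotation.genes
            for t in g.transcripts
            if t.biotype == "protein_coding"
        }
        assert set(table.isoform_id) <= coding
        principals = {principal_isoform(g) for g in b.annotation.genes}
        assert not (set(table.isoform_id) & principals)
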