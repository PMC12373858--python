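import numpy as np
import pandas as pd
import pytest

from spliceswitch.as_events import (
    classify_all,
    classify_events,
    compute_psi,
    event_mode_distribution,
    exon_psi,
)
from spliceswitch.as_events import test_events as differential_event_tests
from spliceswitch.dei_screen import PairedComparison, make_pairs
from spliceswitch.io_formats import ExpressionMatrix, GeneModel, TranscriptModel

from conftest import random_gene_model


def gene(strand, *exon_lists, gene_id="G"):
    txs = [
        TranscriptModel(f"{gene_id}-{k}", gene_id, "chr1", strand, ex)
        for k, ex in enumerate(exon_lists)
    ]
    return GeneModel(gene_id, txs)


# ---------------------------------------------------------------------------
# brute-force oracle: enumerate coordinate tuples over the union of exons and
# apply the mode definitions directly
# ---------------------------------------------------------------------------

def oracle_events(g: GeneModel) -> set[tuple]:
    ts = g.transcripts
    strand = g.strand
    exons = sorted({tuple(e) for t in ts for e in t.exons})

    def consec(t, *want):
        ex = [tuple(e) for e in t.exons]
        w = list(want)
        return any(ex[i : i + len(w)] == w for i in range(len(ex) - len(w) + 1))

    def has(t, e):
        return tuple(e) in {tuple(x) for x in t.exons}

    found = set()
    for fl in exons:
        for c in exons:
            for fr in exons:
                if fl[1] <= c[0] and c[1] <= fr[0]:
                    if any(consec(t, fl, c, fr) for t in ts) and any(
                        consec(t, fl, fr) and not has(t, c) for t in ts
                    ):
                        found.add(("SE", (fl, c, fr)))
    for a, d in exons:
        for a2, b in exons:
            for c, d2 in exons:
                if a2 == a and d2 == d and b < c:
                    if any(has(t, (a, d)) for t in ts) and any(
                        consec(t, (a, b), (c, d)) for t in ts
                    ):
                        found.add(("RI", (a, b, c, d)))
    for a, b1 in exons:
        for a2, b2 in exons:
            if a2 == a and b1 < b2:
                for fl in exons:
                    if fl[0] > b2:
                        if any(consec(t, (a, b2), fl) for t in ts) and any(
                            consec(t, (a, b1), fl) for t in ts
                        ):
                            mode = "A5SS" if strand == "+" else "A3SS"
                            found.add((mode, (a, b1, b2, fl)))
    for a1, b in exons:
        for a2, b2 in exons:
            if b2 == b and a1 < a2:
                for fl in exons:
                    if fl[1] < a1:
                        if any(consec(t, fl, (a1, b)) for t in ts) and any(
                            consec(t, fl, (a2, b)) for t in ts
                        ):
                            mode = "A3SS" if strand == "+" else "A5SS"
                            found.add((mode, (fl, a1, a2, b)))
    for xi, x in enumerate(exons):
        for y in exons[xi + 1 :]:
            if x[1] > y[0]:
                continue
            if any(has(t, x) and has(t, y) for t in ts):
                continue
            for fl in exons:
                if fl[1] > x[0]:
                    continue
                for fr in exons:
                    if fr[0] < y[1]:
                        continue
                    if any(consec(t, fl, x, fr) for t in ts) and any(
                        consec(t, fl, y, fr) for t in ts
                    ):
                        found.add(("MXE", (fl, x, y, fr)))
    return found


class TestClassifyEvents:
    def test_forced_se(self):
        g = gene("+", [(100, 200), (300, 400), (500, 600)], [(100, 200), (500, 600)])
        (ev,) = classify_events(g)
        assert ev.mode == "SE"
        assert ev.coordinates[1] == (300, 400)
        assert ev.inclusion_isoforms == {"G-0"} and ev.exclusion_isoforms == {"G-1"}

    def test_forced_ri(self):
        g = gene("+", [(100, 200), (300, 400)], [(100, 400)])
        (ev,) = classify_events(g)
        assert ev.mode == "RI"
        assert ev.coordinates == (100, 200, 300, 400)
        assert ev.inclusion_isoforms == {"G-1"}  # intron retained

    def test_a5ss_a3ss_strand_aware(self):
        plus = gene("+", [(100, 250), (300, 400)], [(100, 200), (300, 400)])
        minus = gene("-", [(100, 250), (300, 400)], [(100, 200), (300, 400)])
        (ev_p,) = classify_events(plus)
        (ev_m,) = classify_events(minus)
        assert ev_p.mode == "A5SS" and ev_m.mode == "A3SS"

    def test_mxe(self):
        g = gene(
            "+",
            [(0, 50), (100, 150), (300, 350)],
            [(0, 50), (200, 250), (300, 350)],
        )
        (ev,) = classify_events(g)
        assert ev.mode == "MXE"
        assert ev.inclusion_isoforms == {"G-0"}  # upstream exon

    def test_single_transcript_gene_yields_nothing(self):
        g = gene("+", [(0, 50), (100, 150)])
        assert classify_events(g) == []

    def test_agrees_with_oracle_on_random_models(self):
        rng = np.random.default_rng(42)
        for i in range(200):
            g = random_gene_model(rng, f"G{i}")
            got = {(e.mode, e.coordinates) for e in classify_events(g)}
            assert got == oracle_events(g), f"model {i}"

    def test_strand_symmetries(self):
        # flipping the strand alone swaps donor/acceptor naming
        # (A5SS<->A3SS); mirroring coordinates AND flipping strand is the
        # reverse-complement of the locus, so every mode is invariant
        rng = np.random.default_rng(7)
        swap = {"A5SS": "A3SS", "A3SS": "A5SS", "SE": "SE", "RI": "RI", "MXE": "MXE"}
        for i in range(60):
            g = random_gene_model(rng, f"G{i}")
            m = max(b for t in g.transcripts for _, b in t.exons) + 10
            other = "-" if g.strand == "+" else "+"
            strand_flipped = GeneModel(
                g.gene_id,
                [
                    TranscriptModel(t.transcript_id, t.gene_id, t.chrom, other,
                                    list(t.exons))
                    for t in g.transcripts
                ],
            )
            revcomp = GeneModel(
                g.gene_id,
                [
                    TranscriptModel(t.transcript_id, t.gene_id, t.chrom, other,
                                    [(m - b, m - a) for a, b in t.exons])
                    for t in g.transcripts
                ],
            )
            orig = sorted(e.mode for e in classify_events(g))
            assert sorted(swap[e.mode] for e in classify_events(strand_flipped)) == orig
            assert sorted(e.mode for e in classify_events(revcomp)) == orig


class TestPsi:
    def _expr(self, inc, exc, samples=("S1",)):
        df = pd.DataFrame({s: [inc, exc] for s in samples}, index=["G-0", "G-1"])
        return ExpressionMatrix(df, {"G-0": "G", "G-1": "G"})

    def test_psi_from_abundance(self):
        g = gene("+", [(100, 200), (300, 400), (500, 600)], [(100, 200), (500, 600)])
        (ev,) = classify_events(g)
        psi = compute_psi(ev, self._expr(30.0, 10.0))
        assert psi["S1"] == pytest.approx(0.75)

    def test_zero_total_is_missing(self):
        g = gene("+", [(100, 200), (300, 400), (500, 600)], [(100, 200), (500, 600)])
        (ev,) = classify_events(g)
        psi = compute_psi(ev, self._expr(0.0, 0.0))
        assert np.isnan(psi["S1"])

    def test_exon_psi_all_isoforms_contain_exon(self):
        g = gene("+", [(100, 200), (500, 600)], [(100, 200), (500, 600), (700, 800)])
        psi = exon_psi(g, (100, 200), self._expr(5.0, 15.0))
        assert psi["S1"] == pytest.approx(1.0)

    def test_psi_bounded_on_cohort(self, small_cohort):
        events = classify_all(small_cohort.annotation.genes)
        for ev in events[:50]:
            psi = compute_psi(ev, small_cohort.expression).dropna()
            assert ((psi >= 0) & (psi <= 1)).all()


class TestEventTests:
    def test_switch_events_significant_mode_is_se(self, nonoise_cohort):
        b = nonoise_cohort
        pairs = make_pairs(b.sheet)
        events = classify_all(b.annotation.genes)
        results = differential_event_tests(events, b.expression, pairs)
        sig = [r for r in results if r.significant]
        assert sig, "no significant events on a fully penetrant cohort"
        dist = event_mode_distribution(sig)
        assert max(dist, key=dist.get) == "SE"
        assert sum(dist.values()) == pytest.approx(1.0)
        sig_genes = {r.gene_id for r in sig}
        assert sig_genes <= b.truth.switch_genes | set()

    def test_magnitude_gate_blocks_small_dpsi(self):
        g = gene("+", [(100, 200), (300, 400), (500, 600)], [(100, 200), (500, 600)])
        (ev,) = classify_events(g)
        # dPSI constant +0.09: p ~ 0 but below the magnitude gate
        samples = [f"B{i}" for i in range(5)] + [f"D{i}" for i in range(5)]
        rows = {"G-0": [50.0] * 5 + [59.0] * 5, "G-1": [50.0] * 5 + [41.0] * 5}
        expr = ExpressionMatrix(
            pd.DataFrame(rows, index=samples).T, {"G-0": "G", "G-1": "G"}
        )
        pairs = [PairedComparison(f"P{i}", f"B{i}", f"D{i}") for i in range(5)]
        (res,) = differential_event_tests([ev], expr, pairs)
        assert res.mean_dpsi == pytest.approx(0.09)
        assert not res.significant

    def test_few_pairs_reported_untested(self):
        g = gene("+", [(100, 200), (300, 400), (500, 600)], [(100, 200), (500, 600)])
        (ev,) = classify_events(g)
        samples = ["B0", "D0", "B1", "D1"]
        expr = ExpressionMatrix(
            pd.DataFrame({"G-0": [10, 20, 10, 20], "G-1": [10, 5, 10, 5]},
                         index=samples).T,
            {"G-0": "G", "G-1": "G"},
        )
        pairs = [PairedComparison(f"P{i}", f"B{i}", f"D{i}") for i in range(2)]
        (res,) = differential_event_tests([ev], expr, pairs)
        assert not res.tested and res.p_value is None

    def test_mode_distribution_basic(self):
        class M:
            def __init__(self, mode):
                self.mode = mode

        dist = event_mode_distribution([M("SE")] * 3 + [M("RI")])
        assert dist == {"SE": 0.75, "RI": 0.25}
        assert event_mode_distribution([]) == {}
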