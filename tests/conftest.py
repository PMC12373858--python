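import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from spliceswitch.io_formats import GeneModel, TranscriptModel
from spliceswitch.synthetic_data import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Compact cohort for module-level tests (fast to generate)."""
    return simulate_cohort(SimulationConfig(n_genes=60, seed=11))


@pytest.fixture(scope="session")
def default_cohort():
    """Cohort at the study-design defaults (400 genes, 40 switch genes,
    21 patients / 44 DP biopsies, effect 4x, noise 0.25, penetrance 0.5)."""
    return simulate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def nonoise_cohort():
    """Noise-free, fully penetrant cohort: every programmed switch manifests
    in every DP sample and abundances carry no noise."""
    return simulate_cohort(
        SimulationConfig(seed=2, noise_sd=0.0, switch_penetrance=1.0)
    )


def random_gene_model(rng: np.random.Generator, gene_id: str = "G") -> GeneModel:
    """Random 2-5 isoform gene over a 3-8 exon backbone, with random exon
    drops, merges, boundary shifts and swapped alternative exons."""
    n_ex = int(rng.integers(3, 9))
    pos = 0
    chain = []
    for _ in range(n_ex):
        start = pos + int(rng.integers(20, 60))
        end = start + int(rng.integers(20, 60))
        chain.append((start, end))
        pos = end
    strand = "+" if rng.random() < 0.5 else "-"
    txs = []
    for k in range(int(rng.integers(2, 6))):
        ex = [list(e) for e in chain]
        for _ in range(int(rng.integers(0, 3))):
            op = rng.choice(["drop", "merge", "right", "left", "swap"])
            i = int(rng.integers(0, len(ex)))
            if op == "drop" and len(ex) > 2 and 0 < i < len(ex) - 1:
                ex.pop(i)
            elif op == "merge" and i < len(ex) - 1:
                ex[i][1] = ex[i + 1][1]
                ex.pop(i + 1)
            elif op == "right" and i < len(ex) - 1:
                gap = ex[i + 1][0] - ex[i][1]
                if gap > 2:
                    ex[i][1] += int(rng.integers(1, gap))
            elif op == "left" and i > 0:
                gap = ex[i][0] - ex[i - 1][1]
                if gap > 2:
                    ex[i][0] -= int(rng.integers(1, gap))
            elif op == "swap" and 0 < i < len(ex) - 1:
                gap = ex[i + 1][0] - ex[i][1]
                if gap > 6:
                    s = ex[i][1] + int(rng.integers(1, gap - 3))
                    e = int(rng.integers(s + 2, ex[i + 1][0]))
                    ex[i] = [s, e]
        txs.append(
            TranscriptModel(f"{gene_id}-{k}", gene_id, "chr1", strand,
                            [tuple(e) for e in ex])
        )
    return GeneModel(gene_id, txs)
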