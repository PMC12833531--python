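import numpy as np
import pytest

from slipscan import FixtureSpec, SLIPPERY_MOTIFS, SequenceRecord, make_fixture, validate_cds


TOY_RNA = "AUGUUUCUGAUAAGGUAA"  # M F L I R *; one UUUC site at nt 3


@pytest.fixture
def toy_cds():
    return validate_cds(SequenceRecord(id="toy", residues=TOY_RNA))


def draw_planted(rng: np.random.Generator, n_codons: int, n_sites: int):
    """Random well-separated (codon_index, motif) pairs for planting."""
    candidates = list(range(1, n_codons - 2))
    rng.shuffle(candidates)
    chosen: list[int] = []
    for c in candidates:
        if len(chosen) == n_sites:
            break
        if all(abs(c - u) >= 2 for u in chosen):
            chosen.append(c)
    assert len(chosen) == n_sites
    motifs = [SLIPPERY_MOTIFS[rng.integers(len(SLIPPERY_MOTIFS))] for _ in chosen]
    return tuple(sorted(zip(chosen, motifs)))


def build_fixture_batch(n_fixtures: int, seed: int):
    """Verified fixtures with 1-10 planted sites each, plus their truth sets."""
    rng = np.random.default_rng(seed)
    batch = []
    for _ in range(n_fixtures):
        n_codons = int(rng.integers(150, 600))
        n_sites = int(rng.integers(1, 11))
        spec = FixtureSpec(
            n_codons=n_codons,
            planted=draw_planted(rng, n_codons, n_sites),
            seed=int(rng.integers(2**31)),
            gc_fraction=float(rng.choice([0.3, 0.5, 0.7])),
        )
        batch.append(make_fixture(spec))
    return batch


@pytest.fixture(scope="session")
def fixture_batch_small():
    """20 planted fixtures for unit/property tests."""
    return build_fixture_batch(20, seed=11)


@pytest.fixture(scope="session")
def fixture_batch_full():
    """200 planted fixtures, the full verification batch."""
    return build_fixture_batch(200, seed=29)
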