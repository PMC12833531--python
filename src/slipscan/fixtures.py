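"""Synthetic coding sequences with planted slippery sites, plus a
brute-force scanning oracle.

The generator emulates the input the scanner sees in practice: a fully
specified CDS (AUG start, terminal stop, no internal stops) with a chosen
GC content, into which slippery motifs are planted at known codon-aligned
positions.  The oracle is a literal sliding-window rescan implemented
independently of :func:`slipscan.core.scan_slippery_sites`, so the two can
be compared as implementation versus specification.
"""
from __future__ import annotations

import itertools

import numpy as np

from .errors import FixtureError
from .model import FixtureSpec, SlipperyMotif, SlipperySite, ValidatedCds
from .seqio import validate_cds
from .model import SequenceRecord

_BASES = "ACGU"
_STOPS = {"UAA", "UAG", "UGA"}
_SENSE_CODONS = [
    "".join(c) for c in itertools.product(_BASES, repeat=3) if "".join(c) not in _STOPS
]

_ORACLE_MOTIFS = frozenset({"UUUU", "UUUC", "AAAG"})

_MAX_ATTEMPTS = 100


def oracle_scan(rna: str, cds_id: str = "") -> list[SlipperySite]:
    """Literal sliding-window slippery-site scan (the test oracle).

    Examines *every* position ``p`` of the string and reports those where
    the 4-mer ``rna[p:p+4]`` is a slippery motif and ``p`` is a codon
    boundary (``p % 3 == 0``).  Windows containing non-ACGU characters
    never match.  Shares no code with the production scanner.
    """
    sites = []
    for p in range(len(rna) - 3):
        if rna[p : p + 4] in _ORACLE_MOTIFS and p % 3 == 0:
            sites.append(
                SlipperySite(
                    cds_id=cds_id,
                    codon_index=p // 3,
                    nt_start=p,
                    motif=SlipperyMotif(rna[p : p + 4]),
                )
            )
    return sites


def _codon_weights(gc_fraction: float) -> np.ndarray:
    """Per-sense-codon sampling weights from independent per-base GC bias."""
    p = {
        "G": gc_fraction / 2,
        "C": gc_fraction / 2,
        "A": (1 - gc_fraction) / 2,
        "U": (1 - gc_fraction) / 2,
    }
    w = np.array([p[a] * p[b] * p[c] for a, b, c in _SENSE_CODONS], dtype=float)
    total = w.sum()
    if total <= 0:
        raise FixtureError(f"gc_fraction {gc_fraction} admits no sense codons")
    return w / total


def _sample_body(rng: np.random.Generator, n: int, weights: np.ndarray) -> list[str]:
    idx = rng.choice(len(_SENSE_CODONS), size=n, p=weights)
    return [_SENSE_CODONS[i] for i in idx]


def generate_random_cds(
    n_codons: int, gc_fraction: float = 0.5, seed: int | np.random.SeedSequence = 0
) -> ValidatedCds:
    """A random CDS (AUG + sense codons + stop) with no motif constraint.

    Slippery sites occur at their natural background rate — the right input
    for scanner-versus-oracle equivalence testing.  Deterministic for a
    fixed seed.
    """
    if n_codons < 3:
        raise FixtureError("n_codons must be >= 3")
    rng = np.random.default_rng(seed)
    weights = _codon_weights(gc_fraction)
    body = _sample_body(rng, n_codons - 2, weights)
    stop = _STOPS_LIST[rng.integers(len(_STOPS_LIST))]
    rna = "AUG" + "".join(body) + stop
    return validate_cds(SequenceRecord(id=f"random_{n_codons}", residues=rna))


_STOPS_LIST = sorted(_STOPS)


def generate_clean_cds(
    n_codons: int, gc_fraction: float = 0.5, seed: int | np.random.SeedSequence = 0
) -> ValidatedCds:
    """A random CDS verified by the oracle to contain zero slippery sites.

    Sampling as in :func:`generate_random_cds`, then offending codons are
    rejection-resampled and the result re-verified until the oracle finds
    nothing; a bounded number of rounds guards against pathological
    parameters (practically unreachable at moderate GC).
    """
    if n_codons < 3:
        raise FixtureError("n_codons must be >= 3")
    rng = np.random.default_rng(seed)
    weights = _codon_weights(gc_fraction)
    body = _sample_body(rng, n_codons - 2, weights)
    stop = _STOPS_LIST[rng.integers(len(_STOPS_LIST))]
    codons = ["AUG"] + body + [stop]
    for _ in range(_MAX_ATTEMPTS):
        rna = "".join(codons)
        hits = oracle_scan(rna)
        if not hits:
            record = SequenceRecord(id=f"clean_{n_codons}", residues=rna)
            return validate_cds(record)
        for site in hits:
            # codon 0 is AUG and can never head a motif; the final stop can
            # never head one either, so site.codon_index indexes the body.
            codons[site.codon_index] = _SENSE_CODONS[
                rng.choice(len(_SENSE_CODONS), p=weights)
            ]
    raise FixtureError(
        f"could not generate a clean CDS of {n_codons} codons "
        f"(gc_fraction={gc_fraction}) in {_MAX_ATTEMPTS} rounds"
    )


def plant_sites(
    cds: ValidatedCds, planted: list[tuple[int, str]]
) -> ValidatedCds:
    """Overwrite codons so each ``(codon_index, motif)`` becomes a slippery site.

    Codon ``c`` becomes ``motif[0:3]`` and the first base of codon ``c+1``
    becomes ``motif[3]``.  Planting positions must be distinct, in range,
    and pairwise non-overlapping (enforced by :class:`FixtureSpec` rules).
    The caller is responsible for verifying no accidental extra sites arose
    at junctions (see :func:`make_fixture`, which regenerates on collision).
    """
    spec = FixtureSpec(n_codons=cds.n_codons, planted=tuple(planted))  # re-validates
    chars = list(cds.rna)
    for c, motif in spec.planted:
        p = 3 * c
        chars[p : p + 3] = motif[:3]
        chars[p + 3] = motif[3]
    record = SequenceRecord(id=cds.id, residues="".join(chars))
    return validate_cds(record)


def make_fixture(spec: FixtureSpec) -> tuple[ValidatedCds, list[SlipperySite]]:
    """Build a verified fixture: clean background + planted sites, exactly.

    Regenerates the background with a derived seed whenever planting
    produces accidental extra sites at a junction (e.g. a planted motif's
    trailing base extending an upstream run), so the planted set is the
    exact truth set.  Deterministic for a fixed spec.
    """
    expected = {(3 * c, m) for c, m in spec.planted}
    for attempt in range(_MAX_ATTEMPTS):
        ss = np.random.SeedSequence([spec.seed, attempt])
        clean = generate_clean_cds(spec.n_codons, spec.gc_fraction, seed=ss)
        planted_cds = plant_sites(clean, list(spec.planted))
        found = oracle_scan(planted_cds.rna, cds_id=planted_cds.id)
        if {(s.nt_start, str(s.motif)) for s in found} == expected:
            truth = sorted(found, key=lambda s: s.nt_start)
            return planted_cds, truth
    raise FixtureError(f"could not realize fixture {spec} without accidental sites")
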