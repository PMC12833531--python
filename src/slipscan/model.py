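"""Domain types shared across the toolkit.

Coordinates are 0-based half-open everywhere in memory; report writers
convert to 1-based closed coordinates at the serialization boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field

#: The +1 slippery motifs scanned for: UUUX with X in {U, C}, plus AAAG.
#: The ribosome decodes the leading homopolymeric codon (UUU or AAA) and can
#: slip forward one nucleotide when the next base extends the run weakly.
SLIPPERY_MOTIFS: tuple[str, ...] = ("UUUU", "UUUC", "AAAG")


@dataclass(frozen=True)
class SlipperyMotif:
    """One of the recognized slippery 4-mers."""

    motif: str

    def __post_init__(self) -> None:
        if self.motif not in SLIPPERY_MOTIFS:
            raise ValueError(f"not a slippery motif: {self.motif!r}")

    @property
    def slipped_base(self) -> str:
        """The 4th base — the one skipped by a +1 slip (U, C, or G)."""
        return self.motif[3]

    def __str__(self) -> str:
        return self.motif


@dataclass(frozen=True)
class SequenceRecord:
    """A raw FASTA entry (residues as read, case and T/U preserved)."""

    id: str
    residues: str
    description: str = ""


@dataclass(frozen=True)
class ValidatedCds:
    """A frame-anchored coding sequence in the RNA alphabet.

    ``rna`` is uppercase with T transliterated to U; codon ``c`` occupies
    positions ``[3c, 3c+3)``.  In non-strict validation IUPAC ambiguity
    codes may remain (listed in ``warnings``); scanners skip any window
    containing one.
    """

    id: str
    rna: str
    n_codons: int
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class SlipperySite:
    """A codon-aligned slippery-motif occurrence (nt_start = 3 * codon_index)."""

    cds_id: str
    codon_index: int
    nt_start: int
    motif: SlipperyMotif

    def __post_init__(self) -> None:
        if self.nt_start != 3 * self.codon_index:
            raise ValueError("site not codon-aligned: nt_start != 3 * codon_index")


@dataclass(frozen=True)
class FrameshiftVariant:
    """The parent CDS with the slipped base deleted.

    Deleting the 4th motif base places everything downstream of the slippery
    codon into the +1 frame, so frame-0 translation of the variant emulates
    the ribosome's post-slip product.
    """

    parent_id: str
    site: SlipperySite
    rna: str


@dataclass(frozen=True)
class FrameshiftProduct:
    """The chimeric peptide a +1 slip at one site would produce."""

    site: SlipperySite
    chimeric_peptide: str
    native_prefix_aa: int
    tail_peptide: str
    tail_len_aa: int
    stop_in_shifted_frame: bool
    classification: str  # null_product | short_tail | long_tail


@dataclass(frozen=True)
class RecodedCds:
    """A synonymously edited CDS with slippery sites removed.

    Each edit is ``(nt_position, old_base, new_base)`` with a 0-based
    position; every edit touches the wobble base of a slippery codon.
    ``residual_sites`` is the scan of the final sequence (empty on
    convergence).
    """

    parent_id: str
    rna: str
    edits: tuple[tuple[int, str, str], ...]
    residual_sites: tuple[SlipperySite, ...]

    @property
    def converged(self) -> bool:
        return not self.residual_sites


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic CDS with planted slippery sites.

    Planted codon indices must be distinct, each below ``n_codons - 1``
    (a motif needs the first base of the following codon), and pairwise at
    least two codons apart so planting windows cannot overlap.
    """

    n_codons: int
    planted: tuple[tuple[int, str], ...] = ()
    seed: int = 0
    gc_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.n_codons < 3:
            raise ValueError("n_codons must be >= 3")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")
        indices = [c for c, _ in self.planted]
        if len(set(indices)) != len(indices):
            raise ValueError("planted codon indices must be distinct")
        for c, motif in self.planted:
            SlipperyMotif(motif)  # validates the motif string
            if not 0 <= c < self.n_codons - 1:
                raise ValueError(f"planted codon index {c} out of range")
        for a, b in zip(sorted(indices), sorted(indices)[1:]):
            if b - a < 2:
                raise ValueError("planting windows overlap: indices must differ by >= 2")
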