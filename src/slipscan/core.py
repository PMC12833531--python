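"""Slippery-site detection and +1 frameshift product prediction.

N1-methylpseudouridine-substituted mRNA has been reported to promote +1
ribosomal frameshifting at slippery sequences.  A +1 slip on a decoded UUU
or AAA codon skips the next nucleotide, so every downstream codon is read
in the +1 frame and the ribosome emits a chimeric protein: the native
N-terminus up to the slippery codon, then an aberrant tail until the first
stop in the shifted frame.

This module finds every codon-aligned slippery motif (UUUU, UUUC, AAAG —
i.e. UUUX with X in {U, C}, plus AAAG), emulates the slip by deleting the
skipped base, translates the resulting chimera, and classifies it by the
length of the shifted tail.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence, Union

from Bio.Data import CodonTable

from .errors import IntegrityError, TranslationError
from .model import (
    FrameshiftProduct,
    FrameshiftVariant,
    SlipperyMotif,
    SlipperySite,
    ValidatedCds,
)
from .seqio import UNAMBIGUOUS_RNA, write_fasta

log = logging.getLogger(__name__)

_STANDARD_TABLE = CodonTable.unambiguous_rna_by_id[1]
_CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)
_STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)

#: Default tail-length threshold (aa) separating short_tail from long_tail.
DEFAULT_MIN_TAIL_AA = 20


def scan_slippery_sites(cds: ValidatedCds) -> list[SlipperySite]:
    """Find every codon-aligned slippery motif in a CDS.

    A window starting at position ``p`` is reported iff ``p`` is a codon
    boundary (``p % 3 == 0``), the window fits (``p + 4 <= len``), and the
    4-mer is UUUU, UUUC or AAAG.  Overlapping poly-U runs yield one site per
    matching codon boundary.  Windows containing ambiguity codes (possible
    in non-strict validation) are skipped.
    """
    rna = cds.rna
    sites: list[SlipperySite] = []
    for codon_index in range(cds.n_codons):
        p = 3 * codon_index
        if p + 4 > len(rna):
            break
        window = rna[p : p + 4]
        if any(ch not in UNAMBIGUOUS_RNA for ch in window):
            log.debug("%s: skipping ambiguous window at nt %d", cds.id, p)
            continue
        head, slipped = window[:3], window[3]
        if (head == "UUU" and slipped in "UC") or (head == "AAA" and slipped == "G"):
            sites.append(
                SlipperySite(
                    cds_id=cds.id,
                    codon_index=codon_index,
                    nt_start=p,
                    motif=SlipperyMotif(window),
                )
            )
    return sites


def build_frameshift_variant(cds: ValidatedCds, site: SlipperySite) -> FrameshiftVariant:
    """Delete the slipped base (position ``nt_start + 3``) from the parent.

    The deletion puts all sequence downstream of the slippery codon into the
    +1 frame, so frame-0 translation of the variant reproduces the product
    of a +1 slip at this site — the emulation contract the product
    prediction relies on.
    """
    rna = cds.rna
    window = rna[site.nt_start : site.nt_start + 4]
    if window != str(site.motif):
        raise IntegrityError(
            f"site motif {site.motif} not found at nt {site.nt_start} of "
            f"{cds.id!r} (saw {window!r})"
        )
    cut = site.nt_start + 3
    return FrameshiftVariant(parent_id=cds.id, site=site, rna=rna[:cut] + rna[cut + 1 :])


def translate(rna: str) -> tuple[str, bool]:
    """Translate frame 0 with the standard genetic code (NCBI table 1).

    Proceeds codon by codon from position 0, halting at the first stop
    codon (returned peptide excludes it, ``stop_found=True``) or at the last
    complete codon (``stop_found=False``); a trailing 1–2 nt remainder is
    ignored.  An ambiguity code inside a translated codon raises
    :class:`TranslationError` with the codon's start position.
    """
    peptide: list[str] = []
    for p in range(0, len(rna) - 2, 3):
        codon = rna[p : p + 3]
        if codon in _STOP_CODONS:
            return "".join(peptide), True
        aa = _CODON_TO_AA.get(codon)
        if aa is None:
            raise TranslationError(
                f"untranslatable codon {codon!r} at position {p}", position=p
            )
        peptide.append(aa)
    return "".join(peptide), False


def classify_tail(tail_len_aa: int, min_tail_aa: int = DEFAULT_MIN_TAIL_AA) -> str:
    if tail_len_aa == 0:
        return "null_product"
    return "short_tail" if tail_len_aa < min_tail_aa else "long_tail"


def predict_frameshift_product(
    cds: ValidatedCds,
    site: SlipperySite,
    min_tail_aa: int = DEFAULT_MIN_TAIL_AA,
) -> FrameshiftProduct:
    """Predict the chimeric protein a +1 slip at ``site`` would produce.

    The chimera is the variant's frame-0 translation to the first stop: a
    native prefix of ``codon_index + 1`` residues (through the slippery
    codon) followed by the +1-frame tail.  Classification by tail length:
    ``null_product`` (slip runs straight into a stop), ``short_tail``
    (< ``min_tail_aa`` residues), ``long_tail`` otherwise.  ``min_tail_aa``
    is a configurable proxy for "could this chimera be a functional/antigenic
    protein"; definitive screening is external homology search on the
    exported peptides.
    """
    if min_tail_aa < 0:
        raise ValueError("min_tail_aa must be >= 0")
    variant = build_frameshift_variant(cds, site)
    peptide, stop_found = translate(variant.rna)
    native_prefix_aa = site.codon_index + 1
    # A premature in-frame stop upstream of the site truncates the peptide
    # inside the "native prefix"; the slip then changes nothing (tail 0).
    tail_peptide = peptide[native_prefix_aa:]
    tail_len_aa = len(tail_peptide)
    return FrameshiftProduct(
        site=site,
        chimeric_peptide=peptide,
        native_prefix_aa=native_prefix_aa,
        tail_peptide=tail_peptide,
        tail_len_aa=tail_len_aa,
        stop_in_shifted_frame=stop_found and len(peptide) >= native_prefix_aa,
        classification=classify_tail(tail_len_aa, min_tail_aa),
    )


def export_putative_peptides(
    products: Sequence[FrameshiftProduct],
    path: Union[str, Path],
) -> None:
    """Write chimeric peptides as FASTA, ready as a BLASTx-style query set.

    Header: ``<cds_id>|site<nt_start 1-based>|<motif>|<classification>``.
    An empty product list yields an empty file and a logged warning.
    """
    if not products:
        log.warning("no frameshift products to export; writing empty FASTA %s", path)
        Path(path).write_text("")
        return
    entries = []
    for product in products:
        s = product.site
        header = f"{s.cds_id}|site{s.nt_start + 1}|{s.motif}|{product.classification}"
        entries.append((header, product.chimeric_peptide))
    write_fasta(entries, path)
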