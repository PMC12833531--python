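"""Synonymous recoding to eliminate slippery sites.

A slippery motif always begins with a homopolymeric codon, UUU (Phe) or
AAA (Lys), each of which has exactly one synonymous partner differing at
the wobble base: UUU→UUC and AAA→AAG.  Editing that single base destroys
the motif (UUCx and AAGx match nothing in the motif set) while provably
preserving the encoded protein.  Because a wobble-position edit at codon
``c`` appears in no scan window other than the one anchored at ``c``, an
edit can never create a new motif elsewhere; convergence in a single round
is expected, and the iterative rescan below is a safety net that surfaces
any residual sites honestly rather than assuming them away.
"""
from __future__ import annotations

import logging

from .core import scan_slippery_sites, translate
from .errors import IntegrityError
from .model import RecodedCds, SlipperySite, ValidatedCds

log = logging.getLogger(__name__)

_WOBBLE_SWAP = {"UUU": "C", "AAA": "G"}  # slippery codon -> replacement wobble base

DEFAULT_MAX_ROUNDS = 5


def recode_site(cds: ValidatedCds, site: SlipperySite) -> str:
    """Return ``cds.rna`` with the slippery codon at ``site`` synonymously edited.

    UUU→UUC for the UUUU/UUUC motifs (Phe preserved), AAA→AAG for AAAG
    (Lys preserved); exactly one base changes, at wobble position
    ``nt_start + 2``.
    """
    rna = cds.rna
    window = rna[site.nt_start : site.nt_start + 4]
    if window != str(site.motif):
        raise IntegrityError(
            f"site motif {site.motif} not found at nt {site.nt_start} of "
            f"{cds.id!r} (saw {window!r})"
        )
    codon = window[:3]
    new_base = _WOBBLE_SWAP[codon]
    pos = site.nt_start + 2
    return rna[:pos] + new_base + rna[pos + 1 :]


def recode_all(cds: ValidatedCds, max_rounds: int = DEFAULT_MAX_ROUNDS) -> RecodedCds:
    """Iteratively scan and recode until no slippery sites remain.

    Each round edits the wobble base of every detected slippery codon, then
    rescans.  Protein identity holds at every round by construction of the
    synonymous swaps.  Non-convergence within ``max_rounds`` is reported via
    ``residual_sites``, never raised.
    """
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    current = cds
    edits: list[tuple[int, str, str]] = []
    for _ in range(max_rounds):
        sites = scan_slippery_sites(current)
        if not sites:
            break
        rna = current.rna
        for site in sites:
            pos = site.nt_start + 2
            old = rna[pos]
            rna = _apply(rna, site)
            edits.append((pos, old, rna[pos]))
        current = ValidatedCds(
            id=cds.id, rna=rna, n_codons=cds.n_codons, warnings=cds.warnings
        )
    residual = tuple(scan_slippery_sites(current))
    if residual:
        log.warning(
            "%s: recoding did not converge in %d round(s); %d residual site(s)",
            cds.id,
            max_rounds,
            len(residual),
        )
    return RecodedCds(
        parent_id=cds.id, rna=current.rna, edits=tuple(edits), residual_sites=residual
    )


def _apply(rna: str, site: SlipperySite) -> str:
    """Apply one wobble edit to an already partially edited string.

    Sites from a single scan never share a wobble position, and earlier
    edits in the round cannot invalidate a later site's codon (each edit is
    confined to its own codon), so re-reading the motif head from the
    current string is safe.
    """
    codon = rna[site.nt_start : site.nt_start + 3]
    pos = site.nt_start + 2
    return rna[:pos] + _WOBBLE_SWAP[codon] + rna[pos + 1 :]


def verify_protein_identity(parent: ValidatedCds, recoded: RecodedCds) -> bool:
    """True iff parent and recoded sequences translate identically."""
    return translate(parent.rna) == translate(recoded.rna)
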