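"""FASTA input/output, alphabet normalization, CDS validation, and reports.

All other modules consume the :class:`~slipscan.model.ValidatedCds` produced
here, which anchors the codon frame: codon ``c`` occupies RNA positions
``[3c, 3c+3)``.  Reports are written 1-based; internal coordinates stay
0-based half-open.
"""
from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .errors import FastaParseError, FrameError, SequenceValidationError
from .model import FrameshiftProduct, SequenceRecord, SlipperyMotif, SlipperySite, ValidatedCds

log = logging.getLogger(__name__)

#: IUPAC nucleotide one-letter codes (DNA or RNA).
IUPAC_NT = frozenset("ACGTURYSWKMBDHVN")
UNAMBIGUOUS_RNA = frozenset("ACGU")
STOP_CODONS = frozenset({"UAA", "UAG", "UGA"})

SITE_COLUMNS = ("cds_id", "codon", "nt_start", "nt_end", "motif", "slipped_base")
PRODUCT_COLUMNS = (
    "cds_id",
    "codon",
    "nt_start",
    "motif",
    "classification",
    "native_prefix_aa",
    "tail_len_aa",
    "stop_in_shifted_frame",
    "chimeric_peptide",
    "tail_peptide",
)


def _check_fasta_structure(path: Path) -> None:
    """Reject FASTA files Bio.SeqIO would silently tolerate."""
    saw_header = False
    last_header_line: int | None = None
    header_has_seq = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                if not header_has_seq:
                    raise FastaParseError("empty FASTA record", line=last_header_line)
                saw_header = True
                last_header_line = lineno
                header_has_seq = False
            else:
                if not saw_header:
                    raise FastaParseError("sequence data before first FASTA header", line=lineno)
                header_has_seq = True
    if saw_header and not header_has_seq:
        raise FastaParseError("empty FASTA record", line=last_header_line)


def read_fasta(path: Union[str, Path]) -> list[SequenceRecord]:
    """Read a (possibly multi-record) FASTA file, order preserved.

    Residues are concatenated across wrapped lines with whitespace removed;
    case and T/U are preserved as read.  Non-IUPAC characters raise
    :class:`SequenceValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_fasta_structure(path)
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).replace(" ", "")
        for i, ch in enumerate(residues):
            if ch.upper() not in IUPAC_NT:
                raise SequenceValidationError(
                    f"record {rec.id!r}: non-IUPAC character {ch!r} at position {i}",
                    position=i,
                )
        records.append(SequenceRecord(id=rec.id, residues=residues, description=rec.description))
    return records


def normalize_to_rna(residues: str) -> str:
    """Uppercase and transliterate T to U; idempotent on valid input."""
    for i, ch in enumerate(residues):
        if ch.upper() not in IUPAC_NT:
            raise SequenceValidationError(
                f"non-IUPAC character {ch!r} at position {i}", position=i
            )
    return residues.upper().replace("T", "U")


def validate_cds(
    record: SequenceRecord,
    strict: bool = False,
    cds_start_offset: int = 0,
) -> ValidatedCds:
    """Normalize a record and anchor its codon frame.

    ``cds_start_offset`` trims a 5' leader (e.g. a UTR) before framing; the
    entry is otherwise assumed to be exactly the CDS.  With a nonzero
    offset, a trailing 1–2 nt partial codon is trimmed with a warning;
    with the default offset a non-multiple-of-three length is an error.

    Length not divisible by three raises :class:`FrameError`.  Ambiguity
    codes raise :class:`SequenceValidationError` in strict mode, otherwise
    they are retained, recorded as a warning, and their scan windows are
    later skipped.  A missing AUG start or terminal stop is always just a
    warning: therapeutic constructs are often supplied as CDS fragments.
    """
    rna = normalize_to_rna(record.residues)
    if cds_start_offset:
        if not 0 <= cds_start_offset < len(rna):
            raise SequenceValidationError(
                f"cds_start_offset {cds_start_offset} outside sequence of length {len(rna)}"
            )
        rna = rna[cds_start_offset:]
    warnings: list[str] = []
    if len(rna) % 3 != 0:
        if cds_start_offset:
            trimmed = len(rna) % 3
            warnings.append(f"trimmed {trimmed} trailing nt to restore frame")
            rna = rna[: len(rna) - trimmed]
        else:
            raise FrameError(
                f"record {record.id!r}: length {len(rna)} is not a multiple of 3"
            )
    if not rna:
        raise FrameError(f"record {record.id!r}: empty coding sequence")
    ambiguous = [i for i, ch in enumerate(rna) if ch not in UNAMBIGUOUS_RNA]
    if ambiguous:
        if strict:
            raise SequenceValidationError(
                f"record {record.id!r}: ambiguity code {rna[ambiguous[0]]!r} "
                f"at position {ambiguous[0]} (strict mode)",
                position=ambiguous[0],
            )
        warnings.append(
            f"{len(ambiguous)} ambiguity code(s) at positions "
            + ",".join(str(i) for i in ambiguous[:10])
            + ("..." if len(ambiguous) > 10 else "")
            + "; overlapping scan windows will be skipped"
        )
    if rna[:3] != "AUG":
        warnings.append("no AUG start codon")
    if rna[-3:] not in STOP_CODONS:
        warnings.append("no terminal stop codon")
    return ValidatedCds(
        id=record.id, rna=rna, n_codons=len(rna) // 3, warnings=tuple(warnings)
    )


# ---------------------------------------------------------------------------
# report serialization


def _site_row(site: SlipperySite) -> dict:
    return {
        "cds_id": site.cds_id,
        "codon": site.codon_index + 1,
        "nt_start": site.nt_start + 1,
        "nt_end": site.nt_start + 4,
        "motif": str(site.motif),
        "slipped_base": site.motif.slipped_base,
    }


def _product_row(product: FrameshiftProduct) -> dict:
    s = product.site
    return {
        "cds_id": s.cds_id,
        "codon": s.codon_index + 1,
        "nt_start": s.nt_start + 1,
        "motif": str(s.motif),
        "classification": product.classification,
        "native_prefix_aa": product.native_prefix_aa,
        "tail_len_aa": product.tail_len_aa,
        "stop_in_shifted_frame": product.stop_in_shifted_frame,
        "chimeric_peptide": product.chimeric_peptide,
        "tail_peptide": product.tail_peptide,
    }


def _site_from_row(row: dict) -> SlipperySite:
    return SlipperySite(
        cds_id=row["cds_id"],
        codon_index=int(row["codon"]) - 1,
        nt_start=int(row["nt_start"]) - 1,
        motif=SlipperyMotif(row["motif"]),
    )


def write_report(
    items: Sequence[Union[SlipperySite, FrameshiftProduct]],
    path: Union[str, Path],
    format: str = "tsv",
    kind: str | None = None,
) -> None:
    """Serialize sites or products to TSV or JSON with 1-based coordinates.

    ``kind`` ("sites" or "products") is inferred from the first element and
    only needs to be given for an empty list (default "sites").  Column
    order is fixed, so identical input yields byte-identical files.
    """
    if kind is None:
        kind = "products" if items and isinstance(items[0], FrameshiftProduct) else "sites"
    if kind not in ("sites", "products"):
        raise ValueError(f"unknown report kind {kind!r}")
    columns = SITE_COLUMNS if kind == "sites" else PRODUCT_COLUMNS
    to_row = _site_row if kind == "sites" else _product_row
    rows = [to_row(item) for item in items]
    path = Path(path)
    if format == "tsv":
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=columns, delimiter="\t", lineterminator="\n")
            writer.writeheader()
            writer.writerows(rows)
    elif format == "json":
        with open(path, "w") as fh:
            json.dump({"kind": kind, "records": rows}, fh, indent=2)
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_site_report(path: Union[str, Path]) -> list[SlipperySite]:
    """Read back a site report (JSON or TSV); inverse of :func:`write_report`."""
    path = Path(path)
    if path.suffix == ".json":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("kind") != "sites":
            raise ValueError(f"{path} is not a site report")
        rows = payload["records"]
    else:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh, delimiter="\t"))
    return [_site_from_row(row) for row in rows]


def write_fasta(
    entries: Iterable[tuple[str, str]],
    path: Union[str, Path],
) -> None:
    """Write ``(header, sequence)`` pairs as FASTA."""
    records = [
        _BioSeqRecord(Seq(seq), id=header, description="") for header, seq in entries
    ]
    SeqIO.write(records, str(Path(path)), "fasta")
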