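# Methods

## Background and model

Therapeutic mRNAs are commonly synthesized with N1-methylpseudouridine
(m1Ψ) in place of uridine. m1Ψ has been reported to promote +1 ribosomal
frameshifting at *slippery sequences*: positions where the ribosome,
having decoded a homopolymeric UUU (Phe) or AAA (Lys) codon, can advance
one extra nucleotide when the following base weakly extends the run. The
motif alphabet scanned here is therefore **UUUX with X ∈ {U, C}, plus
AAAG** — i.e. the 4-mers UUUU, UUUC and AAAG. After a +1 slip every
downstream codon is read in the +1 frame, so the ribosome emits a
*chimeric* protein: the native N-terminus through the slippery codon,
followed by an aberrant tail until the first stop codon in the shifted
frame. For an mRNA therapeutic such a chimera is a potential off-target
antigen, so construct QC asks: where can a slip occur, what would it
produce, and can the sites be designed away?

The toolkit answers those three questions deterministically:

1. **Detection** (`scan_slippery_sites`). A motif is reported only when it
   is *codon-aligned*: its first three bases form a complete codon of the
   CDS frame (`nt_start ≡ 0 (mod 3)`). This is the central interpretive
   decision — +1 slippage is an event on the ribosome's decoded UUU/AAA
   codon, so a 4-mer straddling a codon boundary is not a slip substrate.
   Every codon-aligned window is reported independently, so an extended
   poly-U run yields one site per matching codon boundary. The scan
   considers exactly the stated motif set; AAAX variants other than AAAG
   are deliberately not matched.
2. **Slip emulation** (`build_frameshift_variant`,
   `predict_frameshift_product`). A +1 slip at a site is emulated by
   *deleting* the 4th motif base (the skipped X or G) from the sequence.
   Deletion — not substitution — is what places all downstream sequence
   into the +1 frame; the variant's ordinary frame-0 translation is then
   exactly the chimeric product. Each site gets its own single-deletion
   variant: a ribosome slips once per event, so multi-site combinatorial
   variants are out of scope. The chimera decomposes into a native prefix
   of `codon_index + 1` residues and a shifted tail.
3. **Mitigation** (`recode_all`). The slippery codon is synonymously
   recoded at its wobble base: UUU→UUC (Phe) or AAA→AAG (Lys). The genetic
   code guarantees protein identity, and neither UUCx nor AAGx matches any
   motif — including the UUUC case, whose edit yields the non-motif UUCC.

## Classification of chimeric products

The field has no agreed operational definition of when a frameshift
chimera is a "functional protein"; definitive screening is a translated
homology search (e.g. BLASTx) on the exported peptides, which this toolkit
prepares but does not run. As a deterministic, testable proxy the product
is classified by shifted-tail length `t`:

| class | condition | reading |
|---|---|---|
| `null_product` | t = 0 | the slip runs straight into a stop codon |
| `short_tail` | 0 < t < `min_tail_aa` | a peptide too short to fold a domain |
| `long_tail` | t ≥ `min_tail_aa` | potentially antigenic; screen externally |

`min_tail_aa` defaults to **20 aa** — roughly the minimum length of an
autonomous folded element and a common lower bound for a meaningful
homology hit — and is exposed on the API and CLI (`--min-tail-aa`).
Classification is monotone in the threshold: raising it can only move a
product from `long_tail` toward `null_product`, never the reverse.

## Input contract and coordinates

Input FASTA entries are assumed to be exactly the CDS (the frame anchor
"in-frame" requires). A full transcript with a 5′ UTR can be supplied with
`--cds-start-offset`, which trims the leader; with a nonzero offset a
trailing 1–2 nt partial codon is also trimmed (with a warning), but the
entry must still end at the CDS end — 3′ UTRs are not located
automatically. Lengths not divisible by three are otherwise an error.
T/U and case are normalized to uppercase RNA. IUPAC ambiguity codes are an
error in `--strict` mode; by default they are retained with a warning and
any 4-nt scan window containing one is skipped, since the pipeline
presumes a fully specified construct. A missing AUG start or terminal stop
is only a warning: constructs are often supplied as CDS fragments.

Internally all coordinates are 0-based half-open; every user-facing report
(TSV/JSON, FASTA headers, edit logs) is 1-based. Translation uses the
standard genetic code (NCBI table 1, via Biopython's table), hard-coded:
the intended substrate is human therapeutic mRNA.

## Degenerate inputs and numerical choices

* Sites are emitted sorted by `nt_start`; all outputs are deterministic
  for a fixed input and seed (no timestamps in data files).
* A premature in-frame stop upstream of a site truncates the "native
  prefix" itself; the product's tail is then empty and it is classified
  `null_product` (tail length is floored at zero). This cannot occur on
  the synthetic fixtures, which contain no internal stops.
* `recode_all` iterates scan → edit-every-site → rescan (default 5
  rounds). A wobble edit at codon `c` occurs in no scan window other than
  the one anchored at `c`, so an edit can never create a new motif and the
  loop converges in one round; the iteration is kept as a safety net and
  any residual sites are reported honestly rather than assumed absent.
  Non-convergence is reported, never raised.

## The synthetic-data generator

Fixtures emulate a fully specified therapeutic CDS: an AUG start, a
terminal stop, no internal stops, and background codons drawn uniformly
from the 61 sense codons weighted by an independent per-base GC bias
(`gc_fraction`, default 0.5; tests sweep 0.3/0.5/0.7 to cover U/A-rich and
GC-rich constructs). Two flavours:

* `generate_random_cds` — no motif constraint; slippery sites occur at
  their natural background rate. This is the input for scanner-versus-
  oracle equivalence testing.
* `generate_clean_cds` — verified by the oracle to contain zero sites;
  offending codons are rejection-resampled (bounded rounds). Into a clean
  background, `plant_sites` writes motifs at chosen codon indices (codon
  `c` ← motif head, first base of codon `c+1` ← slipped base);
  `make_fixture` re-verifies with the oracle and regenerates with a
  derived seed if planting created any accidental junction site, so the
  planted set is exactly the truth set.

The *oracle* (`oracle_scan`) is an independent brute-force re-statement of
the motif definition: a literal sliding window over **every** string
position, filtered by `p mod 3 = 0`, sharing no code with the production
scanner. Scanner correctness claims rest on exact set equality against it.

What the generator does **not** emulate: human codon-usage bias, UTRs,
modified-nucleotide chemistry, or any model of slip *probability* — the
toolkit flags possible sites; it does not estimate frameshifting rates.
Passing tests therefore demonstrate that detection, emulation and
recoding are exact string-level operations on any CDS, not that a given
site will measurably frameshift in cells.

## Verification scales

The fixture-driven guarantees are verified at full scale in the test
suite and recomputed by `scripts/acceptance.py`: 1000 random CDSs of
100–2000 codons for oracle equivalence, and 200 planted fixtures of
150–600 codons carrying 1–10 sites each for recovery, frame emulation,
prefix conservation and recoding soundness. The whole suite runs in a few
seconds.

## Known limitations

* Tail-length classification is a proxy; cross-reactivity screening of
  the exported peptides (BLASTx or similar) is a documented external step.
* Only the +1 direction and the three stated motifs are considered; −1
  frameshifting and extended slippery-site grammars are out of scope.
* No kinetics: all sites are treated as equally plausible slip points.
* Synonymous recoding optimizes nothing else (no CAI/GC targets, no
  restriction-site or uridine-depletion awareness).
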