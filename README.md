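# slipscan

Slippery-sequence QC for therapeutic mRNA coding sequences: detect
codon-aligned +1 ribosomal frameshift motifs, predict the chimeric protein
a slip would produce, and synonymously recode the sequence to remove the
risk.

mRNA therapeutics synthesized with N1-methylpseudouridine can undergo +1
ribosomal frameshifting at *slippery sequences* — codon-aligned 4-mers
**UUUX (X = U or C) or AAAG** — producing chimeric proteins with an
aberrant C-terminal tail that may act as off-target antigens. Given a CDS
with codons anchored at positions `3c`, slipscan reports every window
`rna[p:p+4] ∈ {UUUU, UUUC, AAAG}` with `p ≡ 0 (mod 3)`, emulates the +1
slip at each site by deleting the slipped 4th base (placing all downstream
sequence in the +1 frame), translates the chimera

```
chimera = native prefix (codons 0..c, incl. the slippery codon) + shifted tail (to first stop)
```

and classifies it by tail length (`null_product` / `short_tail` /
`long_tail`, threshold `--min-tail-aa`, default 20 aa). Chimeric peptides
are exported as FASTA ready for external BLASTx screening. A recoding step
removes sites by the synonymous wobble edits UUU→UUC (Phe) and AAA→AAG
(Lys), which provably preserve the protein and cannot create new motifs.
See `docs/methods.md` for the model, its assumptions and limitations.

Intended users: groups designing and QC-ing mRNA constructs (CARs,
vaccines, protein replacement) who want a deterministic, testable scan
before committing a sequence to synthesis.

## Worked example

`AUGUUUCUGAUAAGGUAA` encodes MFLIR\*. Scanning:

```bash
$ printf '>toy\nAUGUUUCUGAUAAGGUAA\n' > toy.fasta
$ slipscan scan --input toy.fasta --out out/
INFO scanned 1 record(s): 1 slippery site(s) -> out/sites.tsv
$ cat out/sites.tsv
cds_id  codon   nt_start        nt_end  motif   slipped_base
toy     2       4       7       UUUC    C
```

One site: the UUUC window starting at nt 4 (1-based; codon 2 = UUU). A +1
slip there skips the C, so the ribosome reads `AUG UUU UGA ...`:

```bash
$ slipscan shift --input toy.fasta --out out/
$ cat out/peptides.fasta
>toy|site4|UUUC|null_product
MF
```

The variant `AUGUUUUGAUAAGGUAA` (17 nt) hits a UGA stop immediately after
the slippery codon: chimeric peptide `MF`, shifted tail length 0, class
`null_product` — this slip site cannot yield an aberrant protein.
Recoding removes it anyway with a single synonymous edit:

```bash
$ slipscan recode --input toy.fasta --out out/
$ cat out/edits.tsv
cds_id  nt_position     old_base        new_base
toy     6       U       C
```

giving `AUGUUCCUGAUAAGGUAA`, still MFLIR\*, with zero remaining sites.

Other subcommands: `slipscan simulate` emits synthetic CDS fixtures with
planted sites plus a ground-truth TSV; `--format json`, `--strict`,
`--cds-start-offset` control report format, ambiguity handling and frame
anchoring. The same operations are available as a library
(`slipscan.scan_slippery_sites`, `predict_frameshift_product`,
`recode_all`, ...).

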