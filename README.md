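# bescan

sgRNA design for CRISPR base-editing workflows on user-supplied microbial
genomes. `bescan` scans a target region of an annotated genome for
spacer+PAM candidates, measures each candidate's genome-wide off-target
profile on its 13 bp PAM-proximal seed, simulates deaminase editing
(C→T or A→G) inside a configurable edit window, classifies the resulting
codon changes, and exports the annotated guides as CSV.

## How it works

- **genome_io** — reads GenBank (preferred; CDS features with
  `locus_tag`/`gene`/`protein_id` qualifiers, `join` locations supported)
  or plain FASTA (sequence-only), and resolves target queries: a 1-based
  inclusive base range (`5496473-5567376`), a gene name, a locus tag, or a
  protein ID. Internally everything is 0-based half-open; user-facing
  coordinates are 1-based inclusive.
- **suffix_index** — a suffix array over every contig plus its reverse
  complement (unique sentinels per segment), built with induced sorting
  (SA-IS, linear time). Exact anchor lookup is two binary searches;
  bounded-Hamming search (up to 3 substitutions) walks suffix-array
  intervals with a mismatch budget, which is equivalent to enumerating all
  substitution variants but prunes absent prefixes. `N` in the genome
  matches nothing.
- **guide_finder** — finds PAM sites (IUPAC pattern, default `NGG`) by
  anchor lookup plus degenerate-position validation, extracts 20-nt
  spacers on both strands, and attaches per-seed off-target histograms
  (0–3 mismatches, the guide's own locus excluded once). A
  `--offtarget-require-pam` flag restricts counting to loci with an
  adjacent PAM.
- **base_editor** — computes the edit window (default bases 13–20 upstream
  of the PAM), converts every source base in the window simultaneously on
  the protospacer strand, retranslates every overlapping CDS codon under
  the standard genetic code, and flags guides that change an amino acid
  (`can_edit`) or create a stop codon (`introduces_stop`).
- **reporting / cli** — filter (`all`/`edit`/`stop`), per-gene
  restriction, sorting by off-target histogram, RFC 4180 CSV export.
- **synthetic** — deterministic fixture generator: random genomes with
  planted CDSs, planted guide sites, planted off-target copies at known
  Hamming distances, and planted stop-gain / synonymous-only codon
  layouts, each with a truth table verified at build time by naive
  quadratic oracles (regex PAM scans, sliding-window Hamming scans,
  codon-by-codon retranslation) that share no code with the pipeline.

## CLI

```sh
bescan find --genome genome.gbk --target 5496473-5567376 --mode stop --out guides.csv
bescan find --genome genome.gbk --target actVA --editor abest --window 13:20
bescan find --genome genome.fa --target 1-5000 --editor none   # classic sgRNA design
```

Key options: `--pam NGG`, `--spacer-len 20`, `--seed-len 13`,
`--editor {cbest,abest,none}`, `--window MIN:MAX`,
`--mode {all,edit,stop}`, `--gene LOCUS_TAG`, `--offtarget-require-pam`,
`--out FILE.csv`. Results go to stdout when `--out` is omitted; warnings
and progress go to stderr. Exit codes: 0 success, 2 argument/target
errors, 1 runtime errors.

CSV columns: `contig, start, end, strand, spacer, pam, offtargets_0..3,
genes, aa_changes, introduces_stop` (spacer coordinates 1-based inclusive;
amino-acid changes as `Q74*`-style strings).

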