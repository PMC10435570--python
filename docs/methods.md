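# Methods

## Scope and model

`bemux` implements the computational machinery for one-step multiplex tumor
modeling with base editors: designing sgRNAs that install desired point
mutations with a cytidine (CBE, C→T) or adenine (ABE, A→G) base editor,
predicting the bystander-edit spectrum of each guide, auditing sgRNA
cross-loading between co-delivered editors, scanning coding sequences for
CRISPR-stop opportunities, aggregating targetability over cancer-variant
catalogs, and computing the off-target / mutational-burden statistics used
to assess the safety of a multiplexed editing experiment.

The editing model is deliberately mechanistic and conservative:

* A base editor engages a protospacer delimited by its PAM and deaminates
  substrate bases (C for CBE, A for ABE) on the **protospacer strand** —
  the strand identical to the spacer — because R-loop formation displaces
  that strand single-stranded.  A sense-strand C>T therefore requires a
  sense protospacer with a downstream PAM; a sense G>A requires an
  antisense protospacer.
* Deamination is restricted to the **editing window**, positions 4–8
  (1-based from the protospacer's 5', PAM-distal end).  An extended window
  of 3–9 is available opt-in (`allow_extended`); designs that rely on it
  always carry `OUTSIDE_CORE_WINDOW`/`LOW_POSITION` flags.
* Every substrate base in the window may or may not be converted, so a
  guide with k substrates yields 2^k candidate alleles.  The *headline*
  outcome converts all substrates, matching the empirical pattern that
  clones routinely carry silent co-edits beside the intended change.

## Editor registry

| name       | homolog | PAM    | spacer | window |
|------------|---------|--------|--------|--------|
| SpCas9     | Sp      | NGG    | 20 nt  | 4–8    |
| SpCas9-NG  | Sp      | NG     | 20 nt  | 4–8    |
| SpCas9-NGT | Sp      | NGT    | 20 nt  | 4–8    |
| SpRY       | Sp      | NAN    | 20 nt  | 4–8    |
| SaCas9     | Sa      | NNGRRT | 21 nt  | 4–8    |
| SaKKH      | Sa      | NNNRRT | 21 nt  | 4–8    |

Each PAM variant is registered in both CBE and ABE chemistry.  SpRY is
registered with the narrow NAN motif; broader published SpRY activity can
be configured by the user (PAM, spacer length and windows are plain
`EditorSpec` fields, not hard-coded).  The SpCas9-NG entry carries the
minimal NG pattern; the three-letter NGT convenience entry matches the
common usage for KRAS codon-12 designs.  Sa-family spacers default to
21 nt, Sp-family to 20 nt.  Sa-family CBE guides carry an indel-risk
annotation (elevated indel induction is an observed liability of that
combination); indels are never enumerated as alleles.

Efficiency heuristics are annotations, not filters: `LOW_POSITION` for
targets at protospacer positions 3, 4 or 8; `BAD_CONTEXT` when the
protospacer-strand trinucleotide around a target is ACG;
`OUTSIDE_CORE_WINDOW` for extended-window targets.

## Guide search and outcome enumeration

`find_guides` accepts a coding-level substitution (HGVS-like `c.96C>T`) or
a protein-level request (`p.S45P`, `p.Q1406*`).  Protein requests expand
into every within-codon substitution set reaching any codon of the target
amino acid; a set is designable only if all its substitutions share one
protospacer strand and one chemistry.  This reproduces, e.g., the KRAS
codon-12 asymmetry: from GGT, Ser (AGT) needs one antisense C>T edit while
Asn (AAT) needs two — the two-edit requirement that makes G12N rare.

`enumerate_outcomes` applies chemistry conversions per substrate subset on
the protospacer strand, maps them back to transcript sense, and classifies
each touched codon (silent / missense / nonsense; a stop-to-stop change is
silent, since nonsense requires a non-stop reference codon).  Enumeration
is guarded at 12 substrates (4096 alleles).  CBEs' occasional C>A / C>G
products are enumerated only on request, labelled `rare`, and are never
counted as designable outcomes.

`stop_convertible_codons` derives, by brute force over all 64 codons and
every C>T edit subset on both strands, the closure of codons convertible
to a premature stop: CAA, CAG, CGA (sense) and TGG (antisense), i.e.
exactly the Gln/Arg/Trp residues exploited by CRISPR-stop.  The scanner
reports one site per convertible codon occurrence with all supporting
guides; codons lacking any PAM-supported guide are reported only with
`report_unguided`.

## Multiplex interference

Editors built on the same Cas9 homolog share an sgRNA scaffold, so a
co-delivered opposite-chemistry editor can load a guide and edit the same
window (a CBE guide becomes an ABE substrate-carrier and vice versa).
`check_interference` enumerates, for every panel entry and every delivered
same-homolog opposite-chemistry editor, the cross-chemistry outcome
spectrum at the entry's protospacer — provided the cross editor's own PAM
is present — and grades it `none` (no substrate), `silent_only`, or
`coding`.  Cross-homolog pairs never interfere, which is precisely why
splitting chemistries across homologs (e.g. SaKKH-CBE with SpCas9-ABE)
removes the problem.  `assign_homologs` exploits this with a deterministic
greedy assignment (canonical edit order; score = coding findings, then
efficiency flags, then lexicographic spacer, then editor name).

Genomic guide-vs-guide cross-targeting is not modeled here; it belongs to
the off-target scanner.

## Catalog targetability

`scan_catalog` filters a COSMIC-like catalog to pathogenic rows, asks
`find_guides` per variant and editor under the **core** window (extended
counting is a separate, flagged mode), and aggregates per role: fraction
of targetable variants and fraction of genes with ≥1 targetable variant,
reported to 4 decimals.  Bystander substrates never disqualify a variant.
The catalog format is a thin TSV mapping (gene, role, coding_change,
pathogenic); no external database is bundled, and published database-wide
percentages are not reproduction targets — the scanner's correctness is
established on synthetic catalogs with planted targetable fractions.

## Burden statistics

* **Load comparison** — one-sided Mann–Whitney U (alternative: sequential
  > multiplexed).  For groups of ≤ 8 observations each the p-value is
  computed by full enumeration of all C(n_a+n_b, n_a) labelings with
  midrank tie handling, so small-n results are exact and reproducible:
  completely separated 3-vs-4 groups give p = 1/35 ≈ 0.02857 by
  construction.  Larger groups use the tie-corrected normal approximation.
* **Spectra and refitting** — SNVs are binned into the canonical 96
  trinucleotide channels (pyrimidine-normalized; class-major, context
  lexicographic).  Exposure refitting is non-negative least squares
  against a column-stochastic 96×k signature matrix, reported with the
  reconstruction cosine.  NNLS is exact on noiseless full-rank mixtures;
  at n = 10,000 sampled mutations planted exposures are recovered within
  5% relative error (seed-fixed test).
* **APOBEC proxy** — a mutation is "APOBEC-like" iff its normalized class
  is C>T or C>G with a 5' T (TpC context).  This is a deterministic
  per-mutation stand-in for signature-level attribution, which cannot be
  done per mutation without a probabilistic assignment; the divergence is
  intentional and documented here.
* **Gene-body depletion** — expected in-gene count is n × (covered
  fraction); the score is log2(observed/expected) with an optional
  pseudocount guard, the p-value an exact minimum-likelihood two-sided
  binomial test.  Class-vs-class comparison uses the two-sided Fisher
  exact test; zero-margin tables return p = 1 with a degenerate flag.
* **Rainfall / kataegis** — per-chromosome inter-mutation distances; a
  kataegis call is a maximal run of ≥ 6 mutations with every consecutive
  distance ≤ 1,000 bp.  Both thresholds are configurable; the defaults
  follow common convention.
* **Off-target scan** — brute-force search of both strands for
  spacer-length windows with ≤ 4 mismatches (default) and an adjacent PAM
  (NGG default); each site carries a closed ±200 bp flank clipped to the
  chromosome.  Mutation intersection classifies hits as `in_spacer` or
  `in_flank`.  No bulges or gapped alignments are modeled (mismatch-only
  search).  The scan is O(genome × spacer) and intended for the desk-scale
  synthetic genomes used here, not for whole human genomes.

Intervals are 1-based closed internally; BED-like inputs (0-based
half-open) are converted at the reader boundary.

## Synthetic data

Generators are seeded, deterministic (one named stream per generator, so
adding a generator never shifts another's output) and self-verifying:
every planted construct is re-discovered with the production operations
before the dataset is returned.

* `gen_transcript` plants codons and writes concrete PAM realizations into
  pyrimidine-only (C/T) filler.  No registry PAM can match inside pure C/T
  sequence and it holds no ABE substrate, so plants sit in a controlled
  background; incidental sites created near plant/PAM writes are permitted
  and are enumerated by the production scanners themselves.
* `gen_catalog` plants sense C>T variants at window offset 6 of an NGG
  protospacer for the targetable fraction and transversion variants
  (chemistry-impossible) for the rest.
* `gen_mutation_set` samples 96-channel classes from a signature mixture
  (half the records emitted purine-strand to exercise normalization) and
  positions uniformly over a single synthetic chromosome; with a
  gene-depletion factor f the in-gene per-base rate is exactly f times
  the uniform rate, so the depletion log2 score converges to log2 f.
* `gen_clone_loads` draws log-normal per-clone loads; the defaults are the
  study conditions (3 multiplexed vs 4 sequential clones, group means
  1114 and 3716, CV 0.05).  At this CV the groups are separated with
  overwhelming probability, pinning the exact one-sided p at 1/35.

What the generators do **not** emulate: real human genome composition,
replication-timing or expression covariates of mutation rate, realistic
codon usage, sequencing noise or variant-calling artifacts.  Passing
tests therefore demonstrate algorithmic correctness on controlled inputs,
not performance on real WGS or database data.

## Numerical and design choices

* Exact tests wherever group sizes permit (Mann–Whitney enumeration for
  n ≤ 8 per group; binomial and Fisher by exact methods); approximations
  only beyond, clearly bounded.
* CDS coordinates are 1-based HGVS-style; codon i covers positions
  3i−2..3i after the frame offset; partial CDS fragments are supported via
  `frame_offset` so short planted contexts can be used.
* Sequences containing N are rejected at parse time — window logic is
  undefined on ambiguity codes; IUPAC letters are meaningful only inside
  PAM patterns.
* Problem sizes in tests and in `scripts/acceptance.py` (50-instance
  oracle suites, 10k-mutation refits, 50k-mutation depletion runs, 50 kb
  off-target genomes) were chosen as the smallest sizes at which the
  statistical recoveries are stable; all are package choices and rerun
  end-to-end on every invocation.
* The fold change between group means is reported as the raw ratio of the
  computed means, without rounding conventions.

## Known limitations

* Only substitutions are modeled; indels appear solely as a risk
  annotation on Sa-family CBE guides.
* No learned on-target efficiency scoring, chromatin accessibility, or
  NMD-escape prediction; efficiency flags are rule-based annotations.
* The off-target scanner is exhaustive, not indexed; use dedicated tools
  for genome-scale searches.
* Splice isoforms, UTRs and genome-coordinate liftover are out of scope —
  all coordinates are relative to the user-supplied CDS.
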