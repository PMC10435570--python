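# bemux

Base-editor multiplex design and safety auditing for tumor modeling.

Cytidine and adenine base editors (CBE: C→T via a uracil intermediate;
ABE: A→G via inosine) install point mutations without double-strand
breaks, which makes it possible to engineer several cancer mutations in
one transfection — activating oncogenes, truncating tumor suppressors
with CRISPR-stop, and selecting edited clones functionally.  Doing this
well is a combinatorial design problem: each editor only edits its
substrate base within a small window (protospacer positions 4–8) next to
a homolog-specific PAM (NGG, NG, NGT, NAN, NNGRRT, NNNRRT, ...), every
substrate in the window is a potential bystander edit, and co-delivered
editors that share a Cas9 homolog can cross-load each other's sgRNAs and
edit the same sites with the opposite chemistry.

`bemux` implements that machinery end to end:

* **seqmodel** — CDS/codon/coordinate model, HGVS-like `c.`/`p.` parsing,
  expansion of protein-level requests into codon substitution sets with
  per-edit chemistry.
* **guide_design** — editor registry (Sp/Sa homologs × CBE/ABE), IUPAC PAM
  matching, protospacer enumeration, window-aware guide search on both
  strands, efficiency flags (positions 3/4/8, ACG context, extended
  window).
* **outcomes** — 2^k bystander allele enumeration with per-codon
  consequences, rare C>A/C>G CBE products, CRISPR-stop scanning (the
  CAA/CAG/CGA/TGG → Gln/Arg/Trp closure, derived by brute force).
* **multiplex** — panel assembly, same-homolog cross-chemistry
  interference auditing, homolog assignment, functional selection plans
  (Nutlin-3, Wnt withdrawal, Meki, ...).
* **catalog_scan** — targetable-fraction aggregation over COSMIC-like
  variant catalogs, per role and per editor.
* **burden** — exact small-n Mann–Whitney load comparison, 96-channel
  mutation spectra and NNLS signature refitting, gene-body depletion
  (exact binomial/Fisher), rainfall/kataegis, mismatch-tolerant
  off-target search with ±200 bp flank intersection.
* **synth** — seeded generators with self-verified ground truth for every
  stage (planted editable codons and PAMs, catalogs with known targetable
  fractions, signature-mixture mutation sets, clone load samples).

See `docs/methods.md` for the model, parameter defaults and limitations.

## Worked example

Design guides for KRAS G12S on a codon-12-containing CDS fragment and
compare per-clone mutation loads between engineering strategies:

```python
from bemux import Transcript, find_guides, compare_loads
from bemux.seqmodel import ProteinChange, protein_to_nucleotide_options
from bemux.synth import gen_clone_loads

KRAS = "ATGACTGAATATAAACTTGTGGTAGTTGGAGCTGGTGGCGTAGGCAAGAGTGCC"
t = Transcript("KRAS", KRAS, role="oncogene")

for aa in ("S", "N"):
    best = protein_to_nucleotide_options(ProteinChange(12, "G", aa), t)[0]
    print(f"G12{aa}: codon GGT -> {best.alt_codon}, "
          f"{best.n_edits} edit(s), chemistry {set(best.chemistries)}")

for g in find_guides(ProteinChange(12, "G", "S"), t):
    print(f"{g.editor:14s} {g.strand:9s} spacer {g.spacer} PAM {g.pam_seq} "
          f"targets {sorted(g.target_offsets)} flags {sorted(g.flags)}")

loads, _ = gen_clone_loads(seed=7)
res = compare_loads(loads["multiplexed"], loads["sequential"])
print(f"mean multiplexed {res['mean_multiplexed']:.0f}, "
      f"mean sequential {res['mean_sequential']:.0f}, "
      f"fold {res['fold']:.2f}, one-sided p {res['p_one_sided']:.5f}")
```

Output:

```
G12S: codon GGT -> AGT, 1 edit(s), chemistry {'C→T antisense'}
G12N: codon GGT -> AAT, 2 edit(s), chemistry {'C→T antisense'}
SaKKH-CBE      antisense spacer ACGCCACCAGCTCCAACTACC PAM ACAAGT targets [8] flags ['LOW_POSITION']
SpCas9-NG-CBE  antisense spacer CACCAGCTCCAACTACCACA PAM AG targets [4] flags ['LOW_POSITION']
SpCas9-NGT-CBE antisense spacer CACCAGCTCCAACTACCACA PAM AGT targets [4] flags ['LOW_POSITION']
SpRY-CBE       antisense spacer ACGCCACCAGCTCCAACTAC PAM CAC targets [8] flags ['LOW_POSITION']
SpRY-CBE       antisense spacer GCCACCAGCTCCAACTACCA PAM CAA targets [6] flags []
SpRY-CBE       antisense spacer CCACCAGCTCCAACTACCAC PAM AAG targets [5] flags []
mean multiplexed 1126, mean sequential 3726, fold 3.31, one-sided p 0.02857
```

Reading it: reaching Ser from GGT takes a single antisense C>T edit,
while Asn needs two — which is why G12N is the rarer outcome of a
codon-12 design.  Several editors can place the edit in their window; the
flagged candidates put the target at a low-efficiency protospacer
position, and the unflagged SpRY placements are the preferred designs.
The load comparison is the exact one-sided Mann–Whitney test: three
multiplexed versus four fully separated sequential clones give
p = 1/35 ≈ 0.02857, the smallest value those group sizes allow.

A `bemux` console script exposes the same stages
(`design`, `stopscan`, `panel`, `catalog`, `burden`, `simulate`), e.g.

```sh
bemux --seed 7 --out out/ simulate loads
bemux --out out/ design --edit p.G12S --gene KRAS --fasta cds.fa
```

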