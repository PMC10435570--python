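"""Sequence, codon, coordinate and variant-notation data model.

Conventions used throughout the package:

* Nucleotide sequences are uppercase strings over ``ACGT``; ambiguity
  codes are only meaningful inside PAM patterns, which are handled by
  :mod:`bemux.guide_design`.
* CDS coordinates are 1-based, HGVS ``c.`` style.  Codon ``i`` covers CDS
  positions ``frame_offset + 3i-2 .. frame_offset + 3i``.
* Only substitutions are modeled (single-nucleotide, or several within
  one codon for protein-level requests); indels are out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "NucSeqError",
    "ReferenceMismatchError",
    "ParseError",
    "Transcript",
    "CodingChange",
    "ProteinChange",
    "SubstitutionOption",
    "validate_nucseq",
    "reverse_complement",
    "translate",
    "CODON_TABLE",
    "STOP_CODONS",
    "parse_coding_change",
    "format_coding_change",
    "parse_protein_change",
    "protein_to_nucleotide_options",
    "codons_for_aa",
    "read_transcripts_fasta",
]


class NucSeqError(ValueError):
    """A sequence contains characters outside the ACGT alphabet."""


class ParseError(ValueError):
    """A variant string does not match the supported grammar."""


class ReferenceMismatchError(ValueError):
    """A parsed variant's reference base disagrees with the transcript."""


_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = re.compile(r"^[ACGT]*$")

# 64-entry standard genetic code with stops rendered '*'; built from the
# Biopython table once at import so lookups stay dict-speed.
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TABLE[_stop] = "*"

STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # {TAA, TAG, TGA}

ROLES = ("oncogene", "tsg", "other")


def validate_nucseq(seq: str, what: str = "sequence") -> str:
    """Uppercase and validate a nucleotide string; reject non-ACGT (incl. N)."""
    s = seq.upper()
    if not _VALID.match(s):
        bad = sorted(set(s) - set("ACGT"))
        raise NucSeqError(f"{what} contains non-ACGT characters: {bad}")
    return s


def reverse_complement(seq: str) -> str:
    """Return the 5'->3' reverse complement. Involution on valid input."""
    s = validate_nucseq(seq)
    return s.translate(_COMPLEMENT)[::-1]


def translate(cds_slice: str) -> str:
    """Translate an in-frame CDS slice with the standard code; stop is '*'.

    Raises ``ValueError`` if the length is not a multiple of 3.
    """
    s = validate_nucseq(cds_slice)
    if len(s) % 3:
        raise ValueError(f"length {len(s)} not divisible by 3")
    return "".join(CODON_TABLE[s[i : i + 3]] for i in range(0, len(s), 3))


def codons_for_aa(aa: str) -> list[str]:
    """All codons encoding ``aa`` ('*' for stop), sorted."""
    return sorted(c for c, a in CODON_TABLE.items() if a == aa)


@dataclass(frozen=True)
class Transcript:
    """A gene's CDS with optional flanking context.

    ``frame_offset`` permits partial CDS fragments: the analyzed frame
    starts at CDS position ``frame_offset + 1``.  Flanks extend the
    sequence context available for protospacer/PAM placement without
    contributing codons.
    """

    gene_id: str
    cds: str
    role: str = "other"
    up_flank: str = ""
    down_flank: str = ""
    frame_offset: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "cds", validate_nucseq(self.cds, "cds"))
        object.__setattr__(self, "up_flank", validate_nucseq(self.up_flank, "up_flank"))
        object.__setattr__(
            self, "down_flank", validate_nucseq(self.down_flank, "down_flank")
        )
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if not 0 <= self.frame_offset <= 2:
            raise ValueError("frame_offset must be 0, 1 or 2")
        if (len(self.cds) - self.frame_offset) % 3:
            raise ValueError(
                "cds length minus frame_offset must be a whole number of codons"
            )

    # -- coordinate helpers -------------------------------------------------

    @property
    def n_codons(self) -> int:
        return (len(self.cds) - self.frame_offset) // 3

    @property
    def context(self) -> str:
        """Full sense-strand sequence: up_flank + cds + down_flank."""
        return self.up_flank + self.cds + self.down_flank

    def cds_to_context(self, pos: int) -> int:
        """Map a 1-based CDS position to a 1-based position in ``context``."""
        if not 1 <= pos <= len(self.cds):
            raise IndexError(f"CDS position {pos} out of range 1..{len(self.cds)}")
        return len(self.up_flank) + pos

    def context_to_cds(self, pos: int) -> int | None:
        """Inverse of :meth:`cds_to_context`; None when outside the CDS."""
        p = pos - len(self.up_flank)
        return p if 1 <= p <= len(self.cds) else None

    def codon_span(self, codon_index: int) -> tuple[int, int]:
        """1-based CDS (start, end) of codon ``codon_index`` (1-based)."""
        if not 1 <= codon_index <= self.n_codons:
            raise IndexError(
                f"codon {codon_index} out of range 1..{self.n_codons}"
            )
        start = self.frame_offset + 3 * codon_index - 2
        return start, start + 2

    def codon(self, codon_index: int) -> str:
        start, end = self.codon_span(codon_index)
        return self.cds[start - 1 : end]

    def codon_index_of(self, cds_pos: int) -> int | None:
        """Codon index covering a CDS position; None when out of frame."""
        p = cds_pos - self.frame_offset
        if p < 1 or cds_pos > len(self.cds):
            return None
        idx = (p - 1) // 3 + 1
        return idx if idx <= self.n_codons else None

    def protein(self) -> str:
        return translate(self.cds[self.frame_offset :])


@dataclass(frozen=True, order=True)
class CodingChange:
    """A single-nucleotide substitution in CDS coordinates (HGVS c. style)."""

    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref", validate_nucseq(self.ref, "ref"))
        object.__setattr__(self, "alt", validate_nucseq(self.alt, "alt"))
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("ref and alt must be single bases")
        if self.ref == self.alt:
            raise ParseError(f"ref equals alt ({self.ref}) at position {self.position}")
        if self.position < 1:
            raise ValueError("position must be >= 1")

    def validate_against(self, transcript: Transcript) -> "CodingChange":
        if self.position > len(transcript.cds):
            raise IndexError(
                f"c.{self.position} beyond CDS of length {len(transcript.cds)}"
            )
        actual = transcript.cds[self.position - 1]
        if actual != self.ref:
            raise ReferenceMismatchError(
                f"c.{self.position}: transcript has {actual}, change states {self.ref}"
            )
        return self


@dataclass(frozen=True)
class ProteinChange:
    """A protein-level substitution request, e.g. S45P or Q1406*."""

    residue: int
    ref_aa: str
    alt_aa: str

    def __post_init__(self) -> None:
        if self.residue < 1:
            raise ValueError("residue must be >= 1")
        aas = set(CODON_TABLE.values())
        if self.ref_aa not in aas or self.ref_aa == "*":
            raise ParseError(f"invalid reference amino acid {self.ref_aa!r}")
        if self.alt_aa not in aas:
            raise ParseError(f"invalid target amino acid {self.alt_aa!r}")
        if self.alt_aa == self.ref_aa:
            raise ParseError(f"ref and alt amino acid both {self.ref_aa!r}")

    def validate_against(self, transcript: Transcript) -> "ProteinChange":
        codon = transcript.codon(self.residue)
        actual = CODON_TABLE[codon]
        if actual != self.ref_aa:
            raise ReferenceMismatchError(
                f"residue {self.residue} encodes {actual}, change states {self.ref_aa}"
            )
        return self


_CODING_RE = re.compile(r"^c\.(\d+)\s*([ACGTacgt])\s*>\s*([ACGTacgt])$")
_PROTEIN_RE = re.compile(r"^p\.([A-Za-z])(\d+)([A-Za-z*])$")


def parse_coding_change(text: str, transcript: Transcript | None = None) -> CodingChange:
    """Parse an HGVS-like ``c.<pos><ref>><alt>`` string.

    Whitespace around '>' is tolerated.  When a transcript is supplied the
    reference base is checked against it.
    """
    m = _CODING_RE.match(text.strip())
    if not m:
        raise ParseError(f"cannot parse coding change {text!r}")
    cc = CodingChange(int(m.group(1)), m.group(2).upper(), m.group(3).upper())
    if transcript is not None:
        cc.validate_against(transcript)
    return cc


def format_coding_change(cc: CodingChange) -> str:
    return f"c.{cc.position}{cc.ref}>{cc.alt}"


def parse_protein_change(text: str, transcript: Transcript | None = None) -> ProteinChange:
    """Parse a ``p.<ref_aa><residue><alt_aa>`` string ('*' allowed as alt)."""
    m = _PROTEIN_RE.match(text.strip())
    if not m:
        raise ParseError(f"cannot parse protein change {text!r}")
    pc = ProteinChange(int(m.group(2)), m.group(1).upper(), m.group(3).upper())
    if transcript is not None:
        pc.validate_against(transcript)
    return pc


def parse_edit(text: str, transcript: Transcript | None = None):
    """Parse either a coding-level (c.) or protein-level (p.) edit string."""
    t = text.strip()
    if t.startswith("c."):
        return parse_coding_change(t, transcript)
    if t.startswith("p."):
        return parse_protein_change(t, transcript)
    raise ParseError(f"edit must start with 'c.' or 'p.': {text!r}")


# -- chemistry annotation ---------------------------------------------------

# Sense-strand substitution -> (base-editor chemistry, protospacer strand).
# The deaminase substrate sits on the protospacer strand, so a sense G>A is
# installed by a CBE acting on the antisense strand (antisense C>T).
CHEMISTRY_BY_SUBSTITUTION: dict[tuple[str, str], tuple[str, str]] = {
    ("C", "T"): ("CBE", "sense"),
    ("G", "A"): ("CBE", "antisense"),
    ("A", "G"): ("ABE", "sense"),
    ("T", "C"): ("ABE", "antisense"),
}


def substitution_chemistry(ref: str, alt: str) -> tuple[str, str] | None:
    """(chemistry, protospacer strand) installing sense ref>alt, or None."""
    return CHEMISTRY_BY_SUBSTITUTION.get((ref, alt))


def chemistry_label(ref: str, alt: str) -> str:
    """Human-readable chemistry tag for a sense-strand substitution."""
    hit = substitution_chemistry(ref, alt)
    if hit is None:
        return "other"
    chem, strand = hit
    arrow = "C→T" if chem == "CBE" else "A→G"
    return f"{arrow} {strand}"


@dataclass(frozen=True)
class SubstitutionOption:
    """One way to reach a target amino acid: a set of within-codon edits."""

    alt_codon: str
    changes: tuple[CodingChange, ...]
    chemistries: tuple[str, ...] = field(compare=False, default=())

    @property
    def n_edits(self) -> int:
        return len(self.changes)


def protein_to_nucleotide_options(
    pc: ProteinChange, transcript: Transcript
) -> list[SubstitutionOption]:
    """Enumerate every within-codon substitution set achieving ``pc``.

    One option per codon of the target amino acid, carrying the CDS-level
    changes plus a per-substitution chemistry tag ("C→T sense",
    "A→G antisense", "other", ...).  Sorted by edit count then codon.
    """
    pc.validate_against(transcript)
    start, _ = transcript.codon_span(pc.residue)
    ref_codon = transcript.codon(pc.residue)
    options: list[SubstitutionOption] = []
    for alt_codon in codons_for_aa(pc.alt_aa):
        changes = tuple(
            CodingChange(start + i, ref_codon[i], alt_codon[i])
            for i in range(3)
            if ref_codon[i] != alt_codon[i]
        )
        if not changes:
            continue
        chems = tuple(chemistry_label(c.ref, c.alt) for c in changes)
        options.append(SubstitutionOption(alt_codon, changes, chems))
    options.sort(key=lambda o: (o.n_edits, o.alt_codon))
    return options


# -- FASTA ingestion --------------------------------------------------------

def read_transcripts_fasta(path: str | Path) -> list[Transcript]:
    """Read transcripts from FASTA.

    The record id is parsed as ``gene_id|role|frame_offset`` with role
    defaulting to "other" and frame_offset to 0.  Sequences are uppercased
    and validated strictly (N is rejected).
    """
    transcripts = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        gene_id = parts[0]
        role = parts[1] if len(parts) > 1 and parts[1] else "other"
        frame_offset = int(parts[2]) if len(parts) > 2 and parts[2] else 0
        transcripts.append(
            Transcript(
                gene_id=gene_id,
                cds=str(rec.seq),
                role=role,
                frame_offset=frame_offset,
            )
        )
    return transcripts


def write_transcripts_fasta(transcripts: Iterable[Transcript], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.gene_id}|{t.role}|{t.frame_offset}\n")
            for i in range(0, len(t.cds), 70):
                fh.write(t.cds[i : i + 70] + "\n")
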