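"""Editor registry, PAM matching, protospacer enumeration and guide search.

Coordinate conventions
----------------------
A protospacer lives on one strand of the transcript context (up_flank +
cds + down_flank).  Positions on the sense strand are 1-based 5'->3' in
sense orientation; positions on the antisense strand are 1-based 5'->3'
in antisense orientation, i.e. antisense position ``q`` maps to sense
position ``N - q + 1`` for a context of length ``N``.  The editing window
is counted from the protospacer's 5' (PAM-distal) end; the PAM sits
immediately 3' of the protospacer on the same strand.

The deaminase substrate is the protospacer strand (the strand identical
to the spacer): the R-loop displaces it single-stranded.  A sense C>T
therefore needs a sense-strand protospacer, a sense G>A an antisense one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from bemux.seqmodel import (
    CodingChange,
    ProteinChange,
    SubstitutionOption,
    Transcript,
    protein_to_nucleotide_options,
    reverse_complement,
    substitution_chemistry,
    validate_nucseq,
)

__all__ = [
    "EditorSpec",
    "GuideCandidate",
    "LOW_POSITION",
    "BAD_CONTEXT",
    "OUTSIDE_CORE_WINDOW",
    "IUPAC",
    "default_registry",
    "registry_by_name",
    "match_pam",
    "enumerate_protospacers",
    "find_guides",
    "find_guides_for_changes",
    "efficiency_flags",
]

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

SUBSTRATE_BASE = {"CBE": "C", "ABE": "A"}
PRODUCT_BASE = {"CBE": "T", "ABE": "G"}

# Efficiency-flag labels
LOW_POSITION = "LOW_POSITION"
BAD_CONTEXT = "BAD_CONTEXT"
OUTSIDE_CORE_WINDOW = "OUTSIDE_CORE_WINDOW"

# Protospacer positions where editing runs less efficiently, and the
# disfavoured trinucleotide context around the edited base.
LOW_EFFICIENCY_POSITIONS = frozenset({3, 4, 8})
BAD_TRINUCLEOTIDE = "ACG"


@dataclass(frozen=True)
class EditorSpec:
    """A base editor: Cas9 homolog, deaminase chemistry, PAM and window."""

    name: str
    homolog: str  # "Sp" | "Sa"
    chemistry: str  # "CBE" (C->T) | "ABE" (A->G)
    pam: str
    spacer_len: int
    window: tuple[int, int] = (4, 8)
    extended_window: tuple[int, int] = (3, 9)

    def __post_init__(self) -> None:
        if self.homolog not in ("Sp", "Sa"):
            raise ValueError(f"homolog must be Sp or Sa, got {self.homolog!r}")
        if self.chemistry not in SUBSTRATE_BASE:
            raise ValueError(f"chemistry must be CBE or ABE, got {self.chemistry!r}")
        for ch in self.pam:
            if ch not in IUPAC:
                raise ValueError(f"non-IUPAC letter {ch!r} in PAM {self.pam!r}")
        lo, hi = self.window
        elo, ehi = self.extended_window
        if not (1 <= lo <= hi <= self.spacer_len):
            raise ValueError(f"window {self.window} outside 1..{self.spacer_len}")
        if not (elo <= lo and hi <= ehi and 1 <= elo and ehi <= self.spacer_len):
            raise ValueError("extended_window must contain window within the spacer")

    @property
    def substrate(self) -> str:
        return SUBSTRATE_BASE[self.chemistry]

    @property
    def product(self) -> str:
        return PRODUCT_BASE[self.chemistry]

    def window_positions(self, extended: bool = False) -> range:
        lo, hi = self.extended_window if extended else self.window
        return range(lo, hi + 1)


def default_registry() -> list[EditorSpec]:
    """The stock editor set, each PAM variant in CBE and ABE chemistry.

    Sp-family spacers are 20 nt, Sa-family 21 nt; every entry uses the
    canonical core window [4, 8] with the extended window [3, 9].
    SpCas9-NG is registered with its minimal "NG" PAM plus a convenience
    "NGT" entry matching the 3-letter usage for KRAS G12 designs.
    """
    base = [
        ("SpCas9", "Sp", "NGG", 20),
        ("SpCas9-NG", "Sp", "NG", 20),
        ("SpCas9-NGT", "Sp", "NGT", 20),
        ("SpRY", "Sp", "NAN", 20),
        ("SaCas9", "Sa", "NNGRRT", 21),
        ("SaKKH", "Sa", "NNNRRT", 21),
    ]
    registry = []
    for name, homolog, pam, spacer_len in base:
        for chem in ("CBE", "ABE"):
            registry.append(
                EditorSpec(
                    name=f"{name}-{chem}",
                    homolog=homolog,
                    chemistry=chem,
                    pam=pam,
                    spacer_len=spacer_len,
                )
            )
    return registry


def registry_by_name(registry: Iterable[EditorSpec] | None = None) -> dict[str, EditorSpec]:
    return {e.name: e for e in (registry if registry is not None else default_registry())}


def match_pam(seq: str, pattern: str) -> bool:
    """True iff every base of ``seq`` lies in the IUPAC class of ``pattern``."""
    if len(seq) != len(pattern):
        raise ValueError(f"sequence length {len(seq)} != pattern length {len(pattern)}")
    seq = validate_nucseq(seq, "PAM sequence")
    for base, code in zip(seq, pattern):
        cls = IUPAC.get(code)
        if cls is None:
            raise ValueError(f"non-IUPAC letter {code!r} in pattern {pattern!r}")
        if base not in cls:
            return False
    return True


@dataclass(frozen=True)
class Placement:
    """A protospacer placement on one strand of a context sequence."""

    start: int  # 1-based 5' end of spacer in the strand's own coordinates
    spacer: str
    pam_seq: str


def enumerate_protospacers(strand_seq: str, editor: EditorSpec) -> list[Placement]:
    """All placements where spacer_len bases are immediately followed by a PAM.

    Returned in ascending start order; a sequence shorter than
    spacer_len + len(pam) yields an empty list.
    """
    seq = validate_nucseq(strand_seq)
    L, P = editor.spacer_len, len(editor.pam)
    out = []
    for start0 in range(0, len(seq) - L - P + 1):
        pam_seq = seq[start0 + L : start0 + L + P]
        if match_pam(pam_seq, editor.pam):
            out.append(Placement(start0 + 1, seq[start0 : start0 + L], pam_seq))
    return out


@dataclass(frozen=True)
class GuideCandidate:
    """A protospacer placement that installs a set of desired substitutions.

    ``strand`` is relative to the transcript; ``protospacer_start`` is the
    1-based position of the spacer's 5' end in that strand's coordinates
    over the full context (flanks included).  ``target_offsets`` are the
    window positions carrying the required edits; ``substrate_offsets``
    are all positions in the window in use that hold a substrate base on
    the protospacer strand (targets included).
    """

    editor: str
    spacer: str
    strand: str  # "sense" | "antisense"
    protospacer_start: int
    pam_seq: str
    target_offsets: frozenset[int]
    substrate_offsets: frozenset[int]
    flags: frozenset[str] = frozenset()
    gene_id: str = ""
    changes: tuple[CodingChange, ...] = ()
    alt_codon: str = ""
    indel_risk: bool = False

    def sort_key(self):
        return (self.editor, self.strand, self.protospacer_start, self.spacer)


def _strand_seq(transcript: Transcript, strand: str) -> str:
    ctx = transcript.context
    return ctx if strand == "sense" else reverse_complement(ctx)


def _sense_to_strand(pos: int, strand: str, n: int) -> int:
    return pos if strand == "sense" else n - pos + 1


def efficiency_flags(
    candidate: GuideCandidate, editor: EditorSpec | None = None
) -> frozenset[str]:
    """Heuristic efficiency annotations for a candidate's target offsets.

    * ``LOW_POSITION`` — a target sits at protospacer position 3, 4 or 8,
      where editing runs less efficiently.
    * ``BAD_CONTEXT`` — a target base's protospacer-strand trinucleotide
      (5' base, target, 3' base) is ACG, a disfavoured context.
    * ``OUTSIDE_CORE_WINDOW`` — a target lies outside the core window.
    """
    if editor is None:
        editor = registry_by_name()[candidate.editor]
    flags = set()
    lo, hi = editor.window
    for off in candidate.target_offsets:
        if off in LOW_EFFICIENCY_POSITIONS:
            flags.add(LOW_POSITION)
        if not lo <= off <= hi:
            flags.add(OUTSIDE_CORE_WINDOW)
        if 2 <= off <= len(candidate.spacer) - 1:
            tri = candidate.spacer[off - 2 : off + 1]
            if tri == BAD_TRINUCLEOTIDE:
                flags.add(BAD_CONTEXT)
    return frozenset(flags)


def find_guides_for_changes(
    changes: Sequence[CodingChange],
    transcript: Transcript,
    editors: Iterable[EditorSpec],
    allow_extended: bool = False,
    alt_codon: str = "",
) -> list[GuideCandidate]:
    """Guide candidates installing a set of sense-strand CDS substitutions.

    All substitutions must share one protospacer strand and one chemistry
    (C>T sense and G>A sense cannot be combined); otherwise no candidate
    exists and an empty list is returned.
    """
    if not changes:
        return []
    for c in changes:
        c.validate_against(transcript)

    chem_strand = {substitution_chemistry(c.ref, c.alt) for c in changes}
    if None in chem_strand or len(chem_strand) != 1:
        return []  # mixed or non-transition chemistry: not base-editable
    chemistry, strand = chem_strand.pop()

    ctx = transcript.context
    n = len(ctx)
    strand_seq = _strand_seq(transcript, strand)
    # positions of the required edits in the protospacer strand's coordinates
    edit_pos = sorted(
        _sense_to_strand(transcript.cds_to_context(c.position), strand, n)
        for c in changes
    )

    out: list[GuideCandidate] = []
    for editor in editors:
        if editor.chemistry != chemistry:
            continue
        lo, hi = editor.extended_window if allow_extended else editor.window
        # protospacer start s places strand position q at window offset q-s+1
        starts = range(max(1, edit_pos[-1] - hi + 1), edit_pos[0] - lo + 2)
        for s in starts:
            if s < 1 or s + editor.spacer_len + len(editor.pam) - 1 > n:
                continue
            spacer = strand_seq[s - 1 : s - 1 + editor.spacer_len]
            pam_seq = strand_seq[
                s - 1 + editor.spacer_len : s - 1 + editor.spacer_len + len(editor.pam)
            ]
            if not match_pam(pam_seq, editor.pam):
                continue
            offsets = frozenset(q - s + 1 for q in edit_pos)
            if not all(lo <= o <= hi for o in offsets):
                continue
            substrate_offsets = frozenset(
                o for o in range(lo, hi + 1) if spacer[o - 1] == editor.substrate
            )
            cand = GuideCandidate(
                editor=editor.name,
                spacer=spacer,
                strand=strand,
                protospacer_start=s,
                pam_seq=pam_seq,
                target_offsets=offsets,
                substrate_offsets=substrate_offsets,
                gene_id=transcript.gene_id,
                changes=tuple(sorted(changes)),
                alt_codon=alt_codon,
                indel_risk=(editor.homolog == "Sa" and editor.chemistry == "CBE"),
            )
            cand = replace(cand, flags=efficiency_flags(cand, editor))
            out.append(cand)
    out.sort(key=GuideCandidate.sort_key)
    return out


def find_guides(
    edit: CodingChange | ProteinChange,
    transcript: Transcript,
    editors: Iterable[EditorSpec] | None = None,
    allow_extended: bool = False,
) -> list[GuideCandidate]:
    """Guide candidates for a coding- or protein-level edit request.

    Protein-level edits expand into every within-codon substitution set
    reaching the target amino acid; candidates are returned per option.
    An edit achievable by no registered chemistry yields an empty list.
    """
    editors = list(editors) if editors is not None else default_registry()
    if isinstance(edit, CodingChange):
        return find_guides_for_changes([edit], transcript, editors, allow_extended)
    options = protein_to_nucleotide_options(edit, transcript)
    out: list[GuideCandidate] = []
    for opt in options:
        out.extend(
            find_guides_for_changes(
                list(opt.changes),
                transcript,
                editors,
                allow_extended,
                alt_codon=opt.alt_codon,
            )
        )
    out.sort(key=GuideCandidate.sort_key)
    return out
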