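"""Multi-edit panel assembly, sgRNA interference auditing and selection plans.

When a CBE and an ABE built on the same Cas9 homolog are co-delivered,
each editor can load the other's sgRNAs (the backbones are identical),
so a guide designed for a C>T edit can also receive A>G edits at the
same protospacer, and vice versa.  Splitting chemistries across Cas9
homologs (e.g. SaKKH-CBE with SpCas9-ABE) removes this cross-loading
because Sp and Sa sgRNA scaffolds are mutually incompatible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from bemux.guide_design import (
    EditorSpec,
    GuideCandidate,
    default_registry,
    find_guides,
    match_pam,
    registry_by_name,
)
from bemux.outcomes import EditOutcome, enumerate_outcomes
from bemux.seqmodel import CodingChange, ProteinChange, Transcript, reverse_complement

__all__ = [
    "PanelEntry",
    "Panel",
    "InterferenceFinding",
    "UnsatisfiableEditError",
    "DEFAULT_SELECTION_TABLE",
    "check_interference",
    "assign_homologs",
    "annotate_selection",
]

SEVERITY_ORDER = {"none": 0, "silent_only": 1, "coding": 2}

# Functional selection handles for the common colorectal/hepatocyte drivers.
# Genes without an entry fall back to antibiotic/transfection selection via
# a co-integrated resistance cassette.
DEFAULT_SELECTION_TABLE: dict[str, str] = {
    "APC": "removal of Wnt-Surrogate and Rspo1-conditioned medium",
    "TP53": "addition of Nutlin-3",
    "PIK3CA": "addition of Meki",
    "CTNNB1": "removal of the Wnt activators Chir and R-spondin1, and addition of Nutlin-3",
}
DEFAULT_SELECTION = "antibiotic/transfection selection"


class UnsatisfiableEditError(ValueError):
    """No registered editor can install one of the requested edits."""


@dataclass(frozen=True)
class PanelEntry:
    edit: CodingChange | ProteinChange
    transcript: Transcript
    candidate: GuideCandidate
    editor: str  # editor name; must be in the panel's delivered set


@dataclass
class Panel:
    entries: list[PanelEntry]
    delivered_editors: set[str]

    def __post_init__(self) -> None:
        for e in self.entries:
            if e.editor not in self.delivered_editors:
                raise ValueError(
                    f"entry editor {e.editor!r} not among delivered editors"
                )


@dataclass(frozen=True)
class InterferenceFinding:
    entry_index: int
    cross_editor: str
    cross_outcomes: tuple[EditOutcome, ...]
    severity: str  # none | silent_only | coding


def _cross_candidate(
    entry: PanelEntry, cross: EditorSpec
) -> GuideCandidate | None:
    """The entry's sgRNA as loaded by the opposite-chemistry editor.

    Returns None when the cross editor cannot engage the site (spacer
    length mismatch or its own PAM absent next to the protospacer).
    """
    cand = entry.candidate
    if cross.spacer_len != len(cand.spacer):
        return None
    ctx = entry.transcript.context
    strand_seq = ctx if cand.strand == "sense" else reverse_complement(ctx)
    pam_start = cand.protospacer_start + cross.spacer_len - 1
    pam_seq = strand_seq[pam_start : pam_start + len(cross.pam)]
    if len(pam_seq) != len(cross.pam) or not match_pam(pam_seq, cross.pam):
        return None
    lo, hi = cross.window
    substrate_offsets = frozenset(
        o for o in range(lo, hi + 1) if cand.spacer[o - 1] == cross.substrate
    )
    return replace(
        cand,
        editor=cross.name,
        pam_seq=pam_seq,
        target_offsets=frozenset(),
        substrate_offsets=substrate_offsets,
        flags=frozenset(),
        changes=(),
        alt_codon="",
    )


def check_interference(
    panel: Panel, registry: Iterable[EditorSpec] | None = None
) -> list[InterferenceFinding]:
    """Audit cross-chemistry sgRNA loading within each Cas9 homolog.

    For every entry and every delivered editor sharing the entry's sgRNA
    backbone (same homolog) but opposite chemistry, the cross-chemistry
    outcome spectrum at the entry's protospacer is enumerated.  Severity:
    ``coding`` if any non-identity cross outcome is missense/nonsense,
    ``silent_only`` if all are silent, ``none`` if the window holds no
    cross-chemistry substrate.  Cross-homolog pairs never interfere.
    """
    specs = registry_by_name(registry)
    findings: list[InterferenceFinding] = []
    for i, entry in enumerate(panel.entries):
        own = specs[entry.editor]
        for name in sorted(panel.delivered_editors):
            cross = specs[name]
            if cross.homolog != own.homolog or cross.chemistry == own.chemistry:
                continue
            xcand = _cross_candidate(entry, cross)
            if xcand is None or not xcand.substrate_offsets:
                findings.append(
                    InterferenceFinding(i, cross.name, (), "none")
                )
                continue
            outcomes = tuple(
                o
                for o in enumerate_outcomes(xcand, entry.transcript, registry=registry)
                if o.edited_offsets
            )
            classes = {o.worst_class for o in outcomes}
            if classes & {"missense", "nonsense"}:
                severity = "coding"
            else:
                severity = "silent_only"
            findings.append(
                InterferenceFinding(i, cross.name, outcomes, severity)
            )
    return findings


def _coding_findings(panel: Panel, registry) -> int:
    return sum(
        1 for f in check_interference(panel, registry) if f.severity == "coding"
    )


def assign_homologs(
    edits: Sequence[tuple[str, CodingChange | ProteinChange]],
    transcripts: Mapping[str, Transcript],
    registry: Iterable[EditorSpec] | None = None,
    allow_extended: bool = False,
) -> Panel:
    """Greedy editor/guide assignment minimizing coding interference.

    Edits are processed in a canonical order (gene, edit repr) so the
    result is invariant under permutation of the input list.  For each
    edit every candidate guide is scored by the number of coding-severity
    findings the partial panel would carry, tie-broken by fewer
    efficiency flags, then lexicographic spacer, then editor name.
    """
    reg = list(registry) if registry is not None else default_registry()
    ordered = sorted(edits, key=lambda ge: (ge[0], repr(ge[1])))
    entries: list[PanelEntry] = []
    delivered: set[str] = set()
    for gene, edit in ordered:
        transcript = transcripts[gene]
        candidates = find_guides(edit, transcript, reg, allow_extended=allow_extended)
        if not candidates:
            raise UnsatisfiableEditError(
                f"no registered editor can install {edit!r} in {gene}"
            )
        best = None
        for cand in candidates:
            trial = Panel(
                entries + [PanelEntry(edit, transcript, cand, cand.editor)],
                delivered | {cand.editor},
            )
            score = (
                _coding_findings(trial, reg),
                len(cand.flags),
                cand.spacer,
                cand.editor,
            )
            if best is None or score < best[0]:
                best = (score, cand)
        cand = best[1]
        entries.append(PanelEntry(edit, transcript, cand, cand.editor))
        delivered.add(cand.editor)
    return Panel(entries, delivered)


def annotate_selection(
    panel: Panel, selection_table: Mapping[str, str] | None = None
) -> list[str]:
    """Per-entry functional selection plan.

    Genes absent from the table are annotated with the antibiotic /
    transfection-selection fallback (co-integrated resistance cassette).
    """
    table = DEFAULT_SELECTION_TABLE if selection_table is None else selection_table
    return [
        table.get(entry.transcript.gene_id, DEFAULT_SELECTION)
        for entry in panel.entries
    ]
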