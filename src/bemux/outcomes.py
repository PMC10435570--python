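"""Bystander outcome enumeration and CRISPR-stop site scanning.

A base editor deaminates every substrate base exposed in the editing
window, so each guide induces a spectrum of alleles: one per subset of
substrate positions.  The "headline" outcome edits the full substrate
set, matching the empirical observation that clones routinely carry
silent co-edits alongside the intended change.  CBEs occasionally yield
C>A / C>G products instead of C>T; these are enumerated separately as
labelled "rare" variants and never counted as designable outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from bemux.guide_design import (
    EditorSpec,
    GuideCandidate,
    default_registry,
    find_guides_for_changes,
    registry_by_name,
)
from bemux.seqmodel import (
    CODON_TABLE,
    STOP_CODONS,
    CodingChange,
    Transcript,
)

__all__ = [
    "EditOutcome",
    "Consequence",
    "StopSite",
    "classify_consequence",
    "enumerate_outcomes",
    "stop_convertible_codons",
    "crispr_stop_scan",
    "MAX_SUBSTRATES",
]

MAX_SUBSTRATES = 12  # 2^12 alleles; beyond this, restrict the window

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def classify_consequence(codon_before: str, codon_after: str) -> str:
    """silent / missense / nonsense for one codon substitution.

    Nonsense requires the reference codon not to be a stop already.
    """
    if len(codon_before) != 3 or len(codon_after) != 3:
        raise ValueError("codons must be length 3")
    aa_before = CODON_TABLE[codon_before]
    aa_after = CODON_TABLE[codon_after]
    if aa_before == aa_after:
        return "silent"
    if codon_after in STOP_CODONS and codon_before not in STOP_CODONS:
        return "nonsense"
    return "missense"


@dataclass(frozen=True)
class Consequence:
    codon_index: int
    codon_before: str
    codon_after: str
    consequence: str  # silent | missense | nonsense


@dataclass(frozen=True)
class EditOutcome:
    """One allele: a subset of window substrates converted by the editor."""

    edited_offsets: frozenset[int]
    allele: str  # transcript-sense CDS after applying the edits
    consequences: tuple[Consequence, ...]
    is_headline: bool
    label: str = ""  # "" for canonical chemistry, "rare" for C>A/C>G

    @property
    def worst_class(self) -> str:
        order = {"nonsense": 2, "missense": 1, "silent": 0}
        if not self.consequences:
            return "none"
        return max((c.consequence for c in self.consequences), key=order.get)


def _offset_to_sense(candidate: GuideCandidate, offset: int, n_context: int) -> int:
    """Map a window offset to a 1-based sense position in the context."""
    q = candidate.protospacer_start + offset - 1
    return q if candidate.strand == "sense" else n_context - q + 1


def _sense_edit(candidate: GuideCandidate, editor: EditorSpec, product: str) -> tuple[str, str]:
    """(sense_ref, sense_alt) for one substrate converted to ``product``."""
    if candidate.strand == "sense":
        return editor.substrate, product
    return _COMP[editor.substrate], _COMP[product]


def _apply(
    candidate: GuideCandidate,
    editor: EditorSpec,
    transcript: Transcript,
    products: Mapping[int, str],
) -> tuple[str, tuple[Consequence, ...]]:
    """Apply per-offset products on the protospacer strand; return CDS allele."""
    n = len(transcript.context)
    cds = list(transcript.cds)
    touched: set[int] = set()
    for off, product in products.items():
        sense_pos = _offset_to_sense(candidate, off, n)
        cds_pos = transcript.context_to_cds(sense_pos)
        if cds_pos is None:
            continue  # window reaches into a flank; no coding consequence
        ref, alt = _sense_edit(candidate, editor, product)
        if cds[cds_pos - 1] != ref:
            raise ValueError(
                f"substrate mismatch at c.{cds_pos}: expected {ref}, "
                f"found {cds[cds_pos - 1]}"
            )
        cds[cds_pos - 1] = alt
        idx = transcript.codon_index_of(cds_pos)
        if idx is not None:
            touched.add(idx)
    allele = "".join(cds)
    consequences = []
    for idx in sorted(touched):
        start, end = transcript.codon_span(idx)
        before = transcript.cds[start - 1 : end]
        after = allele[start - 1 : end]
        if before != after:
            consequences.append(
                Consequence(idx, before, after, classify_consequence(before, after))
            )
    return allele, tuple(consequences)


def enumerate_outcomes(
    candidate: GuideCandidate,
    transcript: Transcript,
    include_rare_cbe: bool = False,
    registry: Iterable[EditorSpec] | None = None,
) -> list[EditOutcome]:
    """All 2^k subset alleles for a guide's k window substrates.

    Edits are applied as chemistry conversions on the protospacer strand
    and mapped back to the transcript sense.  With ``include_rare_cbe``
    and a CBE editor, single-substrate C>A and C>G variants of the
    headline allele are appended, labelled "rare".
    """
    editor = registry_by_name(registry)[candidate.editor]
    substrates = sorted(candidate.substrate_offsets)
    if len(substrates) > MAX_SUBSTRATES:
        raise ValueError(
            f"{len(substrates)} substrates in window exceeds the enumeration "
            f"guard ({MAX_SUBSTRATES}); restrict the window"
        )
    full = frozenset(substrates)
    out: list[EditOutcome] = []
    for k in range(len(substrates) + 1):
        for subset in combinations(substrates, k):
            products = {off: editor.product for off in subset}
            allele, cons = _apply(candidate, editor, transcript, products)
            out.append(
                EditOutcome(
                    edited_offsets=frozenset(subset),
                    allele=allele,
                    consequences=cons,
                    is_headline=frozenset(subset) == full,
                )
            )
    if include_rare_cbe and editor.chemistry == "CBE" and substrates:
        for off in substrates:
            for rare_product in ("A", "G"):
                products = {o: editor.product for o in substrates}
                products[off] = rare_product
                allele, cons = _apply(candidate, editor, transcript, products)
                out.append(
                    EditOutcome(
                        edited_offsets=full,
                        allele=allele,
                        consequences=cons,
                        is_headline=False,
                        label="rare",
                    )
                )
    return out


def stop_convertible_codons() -> dict[str, dict[str, list[frozenset[int]]]]:
    """Codons convertible to a stop by C>T editing, found by brute force.

    Tries every non-empty subset of sense-strand C positions (sense C>T)
    and of sense-strand G positions (antisense C>T, i.e. sense G>A) over
    all 64 codons.  Returns codon -> strategy -> list of codon-position
    subsets that land on a stop.  Reference stop codons are excluded.
    """
    result: dict[str, dict[str, list[frozenset[int]]]] = {}
    bases = "ACGT"
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                codon = b1 + b2 + b3
                if codon in STOP_CODONS:
                    continue
                strategies: dict[str, list[frozenset[int]]] = {}
                for strategy, sub, prod in (
                    ("sense_C>T", "C", "T"),
                    ("antisense_C>T", "G", "A"),
                ):
                    positions = [i for i in range(3) if codon[i] == sub]
                    hits = []
                    for k in range(1, len(positions) + 1):
                        for subset in combinations(positions, k):
                            edited = list(codon)
                            for i in subset:
                                edited[i] = prod
                            if "".join(edited) in STOP_CODONS:
                                hits.append(frozenset(i + 1 for i in subset))
                    if hits:
                        strategies[strategy] = sorted(hits, key=sorted)
                if strategies:
                    result[codon] = strategies
    return result


@dataclass(frozen=True)
class StopSite:
    """A codon occurrence convertible to a premature stop by a CBE."""

    codon_index: int
    codon: str
    stop_strategy: str  # "sense_C>T" | "antisense_C>T"
    required_offsets: tuple[frozenset[int], ...]  # stop-reaching codon-position sets
    guides: tuple[GuideCandidate, ...]


def crispr_stop_scan(
    transcript: Transcript,
    editors: Iterable[EditorSpec] | None = None,
    allow_extended: bool = False,
    report_unguided: bool = False,
) -> list[StopSite]:
    """Scan a CDS for codons a CBE can convert into premature stops.

    One site per stop-convertible codon occurrence with at least one
    valid guide; with ``report_unguided`` sites lacking any PAM-supported
    guide are reported with an empty guide list.  ABE entries in the
    editor list are ignored (stop introduction is a CBE strategy).
    """
    editors = list(editors) if editors is not None else default_registry()
    cbes = [e for e in editors if e.chemistry == "CBE"]
    if not cbes:
        raise ValueError("crispr_stop_scan requires at least one CBE editor")
    convertible = stop_convertible_codons()
    sites: list[StopSite] = []
    for idx in range(1, transcript.n_codons + 1):
        codon = transcript.codon(idx)
        strategies = convertible.get(codon)
        if not strategies:
            continue
        start, _ = transcript.codon_span(idx)
        for strategy, subsets in strategies.items():
            guides: list[GuideCandidate] = []
            ref, alt = ("C", "T") if strategy == "sense_C>T" else ("G", "A")
            for subset in subsets:
                changes = [
                    CodingChange(start + pos - 1, ref, alt) for pos in sorted(subset)
                ]
                guides.extend(
                    find_guides_for_changes(
                        changes, transcript, cbes, allow_extended=allow_extended
                    )
                )
            guides = sorted(set(guides), key=GuideCandidate.sort_key)
            if guides or report_unguided:
                sites.append(
                    StopSite(
                        codon_index=idx,
                        codon=codon,
                        stop_strategy=strategy,
                        required_offsets=tuple(subsets),
                        guides=tuple(guides),
                    )
                )
    return sites
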