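"""Variant-catalog targetability aggregation.

Given a COSMIC-like catalog of pathogenic coding variants annotated with
gene roles (oncogene / tumor suppressor), count how many variants — and
how many genes with at least one such variant — have a suitable base
editing guide: a PAM-supported protospacer placing the required edit in
the core editing window with a compatible chemistry.  Bystander edits do
not disqualify a variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from bemux.guide_design import EditorSpec, default_registry, find_guides
from bemux.seqmodel import (
    CodingChange,
    ReferenceMismatchError,
    Transcript,
    parse_coding_change,
)

__all__ = [
    "VariantRecord",
    "RoleSummary",
    "TargetabilityReport",
    "variant_targetable",
    "scan_catalog",
    "read_catalog_tsv",
    "write_catalog_tsv",
]

ROLES = ("oncogene", "tsg")


@dataclass(frozen=True)
class VariantRecord:
    gene_id: str
    role: str  # oncogene | tsg
    change: CodingChange
    pathogenic: bool

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")


@dataclass
class RoleSummary:
    n_pathogenic_variants: int = 0
    n_targetable_variants: int = 0
    n_genes: int = 0
    n_genes_with_any_targetable: int = 0
    per_editor: dict[str, int] = field(default_factory=dict)
    undefined_fractions: bool = False

    @property
    def variant_fraction(self) -> float:
        if self.n_pathogenic_variants == 0:
            return 0.0
        return round(self.n_targetable_variants / self.n_pathogenic_variants, 4)

    @property
    def gene_fraction(self) -> float:
        if self.n_genes == 0:
            return 0.0
        return round(self.n_genes_with_any_targetable / self.n_genes, 4)


@dataclass
class TargetabilityReport:
    by_role: dict[str, RoleSummary]
    skipped: list[str] = field(default_factory=list)  # variants lacking a transcript

    def to_dict(self) -> dict:
        out = {}
        for role, s in self.by_role.items():
            out[role] = {
                "n_pathogenic_variants": s.n_pathogenic_variants,
                "n_targetable_variants": s.n_targetable_variants,
                "variant_fraction": s.variant_fraction,
                "n_genes": s.n_genes,
                "n_genes_with_any_targetable": s.n_genes_with_any_targetable,
                "gene_fraction": s.gene_fraction,
                "per_editor": dict(sorted(s.per_editor.items())),
                "undefined_fractions": s.undefined_fractions,
            }
        out["skipped"] = list(self.skipped)
        return out


def variant_targetable(
    v: VariantRecord,
    transcript: Transcript,
    editors: Iterable[EditorSpec] | None = None,
    allow_extended: bool = False,
) -> dict[str, bool]:
    """Per-editor map: does this editor have a suitable guide for ``v``?

    True for editor E iff a guide exists placing the substitution in E's
    window (core window unless ``allow_extended``) next to a matching
    PAM.  Bystander substrates in the window do not disqualify.
    """
    editors = list(editors) if editors is not None else default_registry()
    result = {}
    for e in editors:
        hits = find_guides(v.change, transcript, [e], allow_extended=allow_extended)
        result[e.name] = bool(hits)
    return result


def scan_catalog(
    catalog: Sequence[VariantRecord],
    transcripts: Mapping[str, Transcript],
    editors: Iterable[EditorSpec] | None = None,
    allow_extended: bool = False,
) -> TargetabilityReport:
    """Aggregate targetability over a pathogenic variant catalog.

    Non-pathogenic rows are filtered first.  A variant counts targetable
    iff at least one editor has a guide; a gene counts iff at least one
    of its pathogenic variants is targetable.  Variants whose gene lacks
    a transcript are skipped with a warning record.
    """
    editors = list(editors) if editors is not None else default_registry()
    report = TargetabilityReport(
        by_role={role: RoleSummary(per_editor={e.name: 0 for e in editors}) for role in ROLES}
    )
    genes: dict[str, set[str]] = {role: set() for role in ROLES}
    genes_targetable: dict[str, set[str]] = {role: set() for role in ROLES}

    for v in catalog:
        if not v.pathogenic:
            continue
        summary = report.by_role[v.role]
        transcript = transcripts.get(v.gene_id)
        if transcript is None:
            report.skipped.append(f"{v.gene_id}: no transcript supplied")
            continue
        try:
            v.change.validate_against(transcript)
        except (ReferenceMismatchError, IndexError) as exc:
            report.skipped.append(f"{v.gene_id}: {exc}")
            continue
        summary.n_pathogenic_variants += 1
        genes[v.role].add(v.gene_id)
        per_editor = variant_targetable(v, transcript, editors, allow_extended)
        if any(per_editor.values()):
            summary.n_targetable_variants += 1
            genes_targetable[v.role].add(v.gene_id)
        for name, hit in per_editor.items():
            if hit:
                summary.per_editor[name] += 1

    for role in ROLES:
        s = report.by_role[role]
        s.n_genes = len(genes[role])
        s.n_genes_with_any_targetable = len(genes_targetable[role])
        if s.n_pathogenic_variants == 0 or s.n_genes == 0:
            s.undefined_fractions = True
    return report


# -- catalog TSV ingestion (thin column mapping; the database is never bundled)

CATALOG_COLUMNS = ["gene", "role", "coding_change", "pathogenic"]


def read_catalog_tsv(path: str | Path) -> list[VariantRecord]:
    """Read a catalog TSV with columns gene, role, coding_change, pathogenic."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(CATALOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"catalog missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            VariantRecord(
                gene_id=str(row.gene),
                role=str(row.role),
                change=parse_coding_change(str(row.coding_change)),
                pathogenic=bool(int(row.pathogenic)),
            )
        )
    return records


def write_catalog_tsv(records: Sequence[VariantRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "gene": [v.gene_id for v in records],
            "role": [v.role for v in records],
            "coding_change": [f"c.{v.change.position}{v.change.ref}>{v.change.alt}" for v in records],
            "pathogenic": [int(v.pathogenic) for v in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)
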