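"""Seeded synthetic-data generators with self-verified ground truth.

Every generator is deterministic under a fixed seed, uses its own named
random stream (so adding a generator never shifts another's output), and
verifies its planted ground truth against the production operations
before returning.  Filler sequence is drawn from a pyrimidine-only
alphabet (C/T): none of the registry PAMs (NGG, NG, NGT, NAN, NNGRRT,
NNNRRT) can match inside pure C/T filler and it contains no ABE
substrate, so planted guides sit in a controlled background.  Residual
incidental sites near plants are permitted; the production scanners
enumerate them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from bemux.burden import IntervalSet, Mutation, SignatureMatrix
from bemux.catalog_scan import VariantRecord, variant_targetable
from bemux.guide_design import (
    IUPAC,
    EditorSpec,
    default_registry,
    find_guides_for_changes,
    registry_by_name,
)
from bemux.seqmodel import CodingChange, Transcript, reverse_complement

__all__ = [
    "GenerationError",
    "PlantSpec",
    "GroundTruth",
    "gen_transcript",
    "gen_catalog",
    "gen_mutation_set",
    "gen_clone_loads",
    "synthetic_signatures",
]

# Independent stream ids per generator; a single user seed fans out into
# (seed, stream) spawn keys so generators never share a stream.
_STREAMS = {"transcript": 1, "catalog": 2, "mutations": 3, "loads": 4, "signatures": 5}

FLANK_LEN = 30
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class GenerationError(ValueError):
    """A plant request cannot be satisfied (overlap, no substrate, bounds)."""


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass(frozen=True)
class PlantSpec:
    """Request to plant a codon with a PAM so a given editor can edit it.

    The codon's editable base (the editor-substrate base on the chosen
    protospacer strand) is placed at ``window_offset`` of a protospacer
    whose PAM is written into the filler.
    """

    codon: str
    codon_index: int
    pam_for: str  # editor name in the registry
    strand: str = "sense"
    window_offset: int = 6


@dataclass
class GroundTruth:
    """Free-form per-generator truth record (plants, flags, exposures...)."""

    data: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.data[key]


def _realize_pam(pattern: str, rng: np.random.Generator) -> str:
    return "".join(sorted(IUPAC[ch])[rng.integers(len(IUPAC[ch]))] for ch in pattern)


def _editable_base_index(codon: str, editor: EditorSpec, strand: str) -> int:
    """0-based index within the sense codon of the editable substrate base."""
    if strand == "sense":
        hits = [i for i, b in enumerate(codon) if b == editor.substrate]
    else:
        want = _COMP[editor.substrate]  # antisense substrate seen on sense
        hits = [i for i, b in enumerate(codon) if b == want]
    if not hits:
        raise GenerationError(
            f"codon {codon} holds no {editor.chemistry} substrate on {strand} strand"
        )
    # pick the substrate closest to the protospacer's 5' end on its strand
    return hits[0] if strand == "sense" else hits[-1]


def _plant_change(codon: str, i: int, editor: EditorSpec, strand: str, cds_pos: int) -> CodingChange:
    if strand == "sense":
        return CodingChange(cds_pos, editor.substrate, editor.product)
    return CodingChange(cds_pos, _COMP[editor.substrate], _COMP[editor.product])


def gen_transcript(
    seed: int,
    n_codons: int,
    plants: Sequence[PlantSpec] = (),
    gene_id: str = "SYNTH1",
    role: str = "other",
    registry: Sequence[EditorSpec] | None = None,
) -> tuple[Transcript, GroundTruth]:
    """Generate a transcript with planted editable codons and PAMs.

    Plants must be mutually non-overlapping; the generator raises
    :class:`GenerationError` when a PAM or codon write collides with a
    previous plant.  Before returning, each plant is re-discovered with
    the production guide search; failure to recover a plant is an error.
    """
    specs = registry_by_name(registry)
    rng = _rng(seed, "transcript")
    cds_len = 3 * n_codons
    n = FLANK_LEN + cds_len + FLANK_LEN
    # pyrimidine filler: PAM-free, ABE-substrate-free background
    seq = [("C", "T")[b] for b in rng.integers(2, size=n)]
    locked: set[int] = set()  # 1-based sense context positions already written

    def write(pos1: int, base: str, why: str) -> None:
        if pos1 < 1 or pos1 > n:
            raise GenerationError(f"{why}: position {pos1} outside context 1..{n}")
        if pos1 in locked and seq[pos1 - 1] != base:
            raise GenerationError(f"{why}: conflicting write at position {pos1}")
        seq[pos1 - 1] = base
        locked.add(pos1)

    # 1) planted codons
    for p in plants:
        if not 1 <= p.codon_index <= n_codons:
            raise GenerationError(f"codon_index {p.codon_index} outside 1..{n_codons}")
        start = FLANK_LEN + 3 * (p.codon_index - 1) + 1
        for i, b in enumerate(p.codon):
            write(start + i, b, f"plant codon {p.codon_index}")

    # 2) PAM placement per plant
    truth_plants = []
    for p in plants:
        editor = specs[p.pam_for]
        i = _editable_base_index(p.codon, editor, p.strand)
        sense_pos = FLANK_LEN + 3 * (p.codon_index - 1) + 1 + i
        q = sense_pos if p.strand == "sense" else n - sense_pos + 1
        s = q - p.window_offset + 1  # protospacer start on its strand
        if s < 1 or s + editor.spacer_len + len(editor.pam) - 1 > n:
            raise GenerationError(
                f"plant at codon {p.codon_index}: protospacer/PAM outside context"
            )
        pam = _realize_pam(editor.pam, rng)
        for j, b in enumerate(pam):
            strand_pos = s + editor.spacer_len + j
            if p.strand == "sense":
                write(strand_pos, b, f"PAM for codon {p.codon_index}")
            else:
                write(n - strand_pos + 1, _COMP[b], f"PAM for codon {p.codon_index}")
        cds_pos = sense_pos - FLANK_LEN
        truth_plants.append(
            {
                "plant": p,
                "editor": editor.name,
                "strand": p.strand,
                "protospacer_start": s,
                "window_offset": p.window_offset,
                "change": _plant_change(p.codon, i, editor, p.strand, cds_pos),
            }
        )

    full = "".join(seq)
    transcript = Transcript(
        gene_id=gene_id,
        cds=full[FLANK_LEN : FLANK_LEN + cds_len],
        role=role,
        up_flank=full[:FLANK_LEN],
        down_flank=full[FLANK_LEN + cds_len :],
    )

    # 3) generation-time oracle: every plant must be recovered by the
    # production guide search at exactly the planted placement.
    for tp in truth_plants:
        editor = specs[tp["editor"]]
        lo, hi = editor.window
        extended = not (lo <= tp["window_offset"] <= hi)
        hits = find_guides_for_changes(
            [tp["change"]], transcript, [editor], allow_extended=extended
        )
        if not any(
            h.protospacer_start == tp["protospacer_start"] and h.strand == tp["strand"]
            for h in hits
        ):
            raise GenerationError(
                f"self-check failed: plant at codon {tp['plant'].codon_index} "
                f"not recovered by find_guides"
            )
    return transcript, GroundTruth({"plants": truth_plants, "seed": seed})


def gen_catalog(
    seed: int,
    n_genes: int,
    n_variants: int,
    frac_targetable: float,
) -> tuple[list[VariantRecord], dict[str, Transcript], GroundTruth]:
    """Generate a variant catalog with a known targetable fraction.

    Targetable variants are sense C>T substitutions planted at window
    offset 6 of an NGG-PAM protospacer (SpCas9-CBE); non-targetable
    variants are C>G transversions, which no transition chemistry can
    install regardless of PAM.  ``round(frac * n)`` variants are made
    targetable; the realized fraction is recorded in the truth object.
    """
    if not 0.0 <= frac_targetable <= 1.0:
        raise ValueError("frac_targetable must be in [0, 1]")
    if n_genes < 1 or n_variants < 1:
        raise ValueError("need at least one gene and one variant")
    rng = _rng(seed, "catalog")
    n_target = round(frac_targetable * n_variants)
    flags = [i < n_target for i in range(n_variants)]
    order = rng.permutation(n_variants)
    flags = [flags[i] for i in order]

    per_gene: dict[int, list[int]] = {g: [] for g in range(n_genes)}
    for i in range(n_variants):
        per_gene[i % n_genes].append(i)

    variants: list[VariantRecord | None] = [None] * n_variants
    transcripts: dict[str, Transcript] = {}
    registry = default_registry()
    for g, idxs in per_gene.items():
        gene = f"GENE{g + 1}"
        role = "oncogene" if g % 2 == 0 else "tsg"
        # one planted codon per targetable variant, spaced 10 codons apart
        plants = []
        slots = {}
        for k, i in enumerate(idxs):
            codon_index = 4 + 10 * k
            slots[i] = codon_index
            if flags[i]:
                plants.append(
                    PlantSpec("CTT", codon_index, "SpCas9-CBE", "sense", 6)
                )
        n_codons = 4 + 10 * len(idxs) + 4
        transcript, truth = gen_transcript(
            seed + g + 1, n_codons, plants, gene_id=gene, role=role
        )
        transcripts[gene] = transcript
        planted = {tp["plant"].codon_index: tp for tp in truth["plants"]}
        for i in idxs:
            codon_index = slots[i]
            if flags[i]:
                change = planted[codon_index]["change"]
            else:
                # C>G transversion at the first C of the slot codon
                start, end = transcript.codon_span(codon_index)
                codon = transcript.codon(codon_index)
                offset = codon.index("C") if "C" in codon else 0
                ref = codon[offset]
                alt = "G" if ref != "G" else "A"
                change = CodingChange(start + offset, ref, alt)
            variants[i] = VariantRecord(gene, role, change, pathogenic=True)

    catalog = [v for v in variants if v is not None]
    # generation-time oracle: planted booleans must match the production check
    for v, flag in zip(catalog, flags):
        hit = any(variant_targetable(v, transcripts[v.gene_id], registry).values())
        if hit != flag:
            raise GenerationError(
                f"self-check failed: {v.gene_id} c.{v.change.position} "
                f"targetable={hit}, planted {flag}"
            )
    realized = sum(flags) / n_variants
    return (
        catalog,
        transcripts,
        GroundTruth(
            {
                "targetable": flags,
                "frac_requested": frac_targetable,
                "frac_realized": realized,
                "seed": seed,
            }
        ),
    )


def synthetic_signatures(seed: int = 0, k: int = 2, concentration: float = 0.5) -> SignatureMatrix:
    """Random non-collinear 96-channel signatures (Dirichlet columns)."""
    rng = _rng(seed, "signatures")
    mat = rng.dirichlet([concentration] * 96, size=k).T
    return SignatureMatrix(mat, [f"SBS-SYN{i + 1}" for i in range(k)])


def gen_mutation_set(
    seed: int,
    n: int,
    exposures: Sequence[float],
    sigs: SignatureMatrix,
    genome_model: IntervalSet,
    gene_depletion: float | None = None,
) -> tuple[list[Mutation], GroundTruth]:
    """Sample SNVs from a signature mixture over a simple genome model.

    Trinucleotide channels are drawn from the mixture profile
    ``sigs @ exposures``; half the records are emitted on the purine
    strand to exercise pyrimidine normalization.  Positions are uniform
    over a single synthetic chromosome of ``total_genome_length`` bases.
    With ``gene_depletion`` f the per-base mutation rate inside the
    gene-body intervals is exactly f times the uniform rate, so the
    observed/expected ratio of the depletion test converges to f.
    """
    exposures = np.asarray(exposures, dtype=float)
    if len(exposures) != sigs.k:
        raise ValueError("one exposure per signature required")
    if not np.isclose(exposures.sum(), 1.0):
        raise ValueError("exposures must sum to 1")
    if gene_depletion is not None and not 0.0 <= gene_depletion <= 1.0:
        raise ValueError("gene_depletion must be in [0, 1]")
    rng = _rng(seed, "mutations")
    truth = GroundTruth(
        {"exposures": exposures.tolist(), "gene_depletion": gene_depletion, "seed": seed}
    )
    if n == 0:
        return [], truth

    from bemux.burden import SBS96_CLASSES  # canonical channel order

    mix = sigs.matrix @ exposures
    mix = mix / mix.sum()
    channels = rng.choice(96, size=n, p=mix)
    flips = rng.random(n) < 0.5
    total = genome_model.total_genome_length
    gene_ivs = genome_model.intervals.get("chr1", [])
    covered = sum(e - s + 1 for s, e in gene_ivs)
    gene_frac = covered / total

    def draw_in_genes() -> int:
        # uniform over the covered gene-body length
        off = int(rng.integers(covered))
        for s, e in gene_ivs:
            span = e - s + 1
            if off < span:
                return s + off
            off -= span
        raise AssertionError("offset beyond covered length")

    def draw_position() -> int:
        if gene_depletion is None:
            return int(rng.integers(1, total + 1))
        # in-gene rate = depletion factor x uniform rate; the remainder
        # of the mass lands uniformly outside the gene bodies
        if rng.random() < gene_depletion * gene_frac:
            return draw_in_genes()
        while True:
            pos = int(rng.integers(1, total + 1))
            if not genome_model.contains("chr1", pos):
                return pos

    mutations = []
    for ch, flip in zip(channels, flips):
        sub, ctx = SBS96_CLASSES[ch]
        ref, alt = sub[0], sub[2]
        context = ctx[0] + ref + ctx[1]
        if flip:
            ref, alt = _COMP[ref], _COMP[alt]
            context = reverse_complement(context)
        mutations.append(Mutation("chr1", draw_position(), ref, alt, context))
    mutations.sort(key=lambda m: m.pos)
    return mutations, truth


def gen_clone_loads(
    seed: int,
    n_multiplex: int = 3,
    n_sequential: int = 4,
    mean_m: float = 1114.0,
    mean_s: float = 3716.0,
    cv: float = 0.05,
) -> tuple[dict[str, list[float]], GroundTruth]:
    """Log-normal per-clone mutation loads for two engineering strategies.

    Defaults mirror the study conditions: 3 multiplexed vs 4 sequential
    clones with group means 1114 and 3716.  At small coefficient of
    variation the groups are completely separated with high probability,
    pinning the exact one-sided Mann–Whitney p at 1/35.
    """
    if n_multiplex < 1 or n_sequential < 1:
        raise ValueError("both group sizes must be >= 1")
    if mean_m <= 0 or mean_s <= 0:
        raise ValueError("group means must be positive")
    rng = _rng(seed, "loads")
    sigma2 = np.log1p(cv**2)
    sigma = float(np.sqrt(sigma2))

    def draw(mean: float, size: int) -> list[float]:
        mu = np.log(mean) - sigma2 / 2
        return [float(x) for x in rng.lognormal(mu, sigma, size=size)]

    loads = {
        "multiplexed": draw(mean_m, n_multiplex),
        "sequential": draw(mean_s, n_sequential),
    }
    truth = GroundTruth(
        {
            "loads": {k: list(v) for k, v in loads.items()},
            "means": (mean_m, mean_s),
            "cv": cv,
            "seed": seed,
        }
    )
    return loads, truth
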