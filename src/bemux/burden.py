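"""Off-target and mutational-burden statistics for base-editing safety audits.

Implements the desk-scale statistical toolkit used to compare engineered
clones: exact Mann–Whitney comparison of per-clone mutation loads,
96-channel single-base-substitution spectra and non-negative
least-squares signature refitting, gene-body depletion tests (exact
binomial and Fisher), rainfall/kataegis detection, and a brute-force
mismatch-tolerant off-target site search with flank intersection.

Exact tests are used wherever group sizes permit: small-n results such
as the one-sided p = 1/35 for fully separated samples of sizes 3 and 4
must be reproducible to the printed digit, which rules out approximate
methods at those sizes.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from itertools import combinations, product
from math import comb, log2, sqrt
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from bemux.guide_design import match_pam
from bemux.seqmodel import reverse_complement, validate_nucseq

__all__ = [
    "Mutation",
    "Profile96",
    "SignatureMatrix",
    "Exposures",
    "IntervalSet",
    "OffTargetSite",
    "SBS96_CLASSES",
    "SBS96_LABELS",
    "normalize_to_pyrimidine",
    "compare_loads",
    "build_profile96",
    "refit_signatures",
    "classify_apobec_like",
    "gene_body_depletion",
    "compare_depletion",
    "rainfall",
    "find_offtarget_sites",
    "intersect_offtargets",
    "read_mutations_tsv",
    "write_mutations_tsv",
    "read_signatures_tsv",
    "write_signatures_tsv",
    "read_intervals_bed",
]

PYRIMIDINE_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"

# Canonical 96-channel order: substitution class major, then flanking
# context lexicographic (5' base, 3' base), COSMIC-style.
SBS96_CLASSES: list[tuple[str, str]] = [
    (sub, five + three)
    for sub in PYRIMIDINE_CLASSES
    for five in _BASES
    for three in _BASES
]
SBS96_LABELS: list[str] = [
    f"{ctx[0]}[{sub}]{ctx[1]}" for sub, ctx in SBS96_CLASSES
]
_CLASS_INDEX = {cls: i for i, cls in enumerate(SBS96_CLASSES)}


@dataclass(frozen=True)
class Mutation:
    """A somatic SNV with its trinucleotide context (ref = middle base)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    context: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref", validate_nucseq(self.ref, "ref"))
        object.__setattr__(self, "alt", validate_nucseq(self.alt, "alt"))
        object.__setattr__(self, "context", validate_nucseq(self.context, "context"))
        if len(self.context) != 3:
            raise ValueError(f"context must be a trinucleotide, got {self.context!r}")
        if self.context[1] != self.ref:
            raise ValueError(
                f"context middle base {self.context[1]} != ref {self.ref}"
            )
        if self.ref == self.alt:
            raise ValueError("ref equals alt")


def normalize_to_pyrimidine(ref: str, alt: str, context: str) -> tuple[str, str]:
    """(substitution class, context) with the reference on the pyrimidine strand.

    Purine-reference mutations are mapped through the reverse complement,
    so G>A at TGT becomes C>T at ACA.
    """
    if ref in "CT":
        return f"{ref}>{alt}", context
    return f"{reverse_complement(ref)}>{reverse_complement(alt)}", reverse_complement(context)


@dataclass
class Profile96:
    """Counts over the canonical 96 trinucleotide substitution channels."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError("Profile96 requires exactly 96 counts")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class SignatureMatrix:
    """96 x k matrix of substitution probabilities, one column per signature."""

    matrix: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 96:
            raise ValueError("signature matrix must be 96 x k")
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("one name per signature column required")
        if (self.matrix < 0).any():
            raise ValueError("signature entries must be non-negative")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("each signature column must sum to 1 (±1e-9)")

    @property
    def k(self) -> int:
        return self.matrix.shape[1]


@dataclass
class Exposures:
    values: np.ndarray
    names: list[str]
    reconstruction_cosine: float | None  # None when the profile is empty

    def as_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.names, self.values)}

    @property
    def proportions(self) -> np.ndarray:
        total = self.values.sum()
        return self.values / total if total > 0 else np.zeros_like(self.values)


# -- group comparison -------------------------------------------------------

def _mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> float:
    """U statistic for the alternative 'b tends larger than a' (ties 0.5)."""
    u = 0.0
    for x in b:
        for y in a:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def exact_mannwhitney_p(a: Sequence[float], b: Sequence[float]) -> float:
    """One-sided exact Mann–Whitney p (alternative: b > a) by enumeration.

    Enumerates all C(n_a+n_b, n_a) group labelings of the pooled sample,
    so ties are handled exactly.  Intended for small groups.
    """
    pooled = list(a) + list(b)
    n_a = len(a)
    observed = _mann_whitney_u(a, b)
    n_ge = 0
    idx = range(len(pooled))
    for a_idx in combinations(idx, n_a):
        a_set = set(a_idx)
        aa = [pooled[i] for i in a_idx]
        bb = [pooled[i] for i in idx if i not in a_set]
        if _mann_whitney_u(aa, bb) >= observed - 1e-12:
            n_ge += 1
    return n_ge / comb(len(pooled), n_a)


def compare_loads(
    multiplexed: Sequence[float],
    sequential: Sequence[float],
    exact_max_n: int = 8,
) -> dict[str, float]:
    """Compare per-clone mutation loads between two engineering strategies.

    One-sided Mann–Whitney U with alternative "sequential > multiplexed":
    exact permutation enumeration when both groups have at most
    ``exact_max_n`` observations (ties handled exactly), tie-corrected
    normal approximation above.  Fully separated groups of sizes 3 and 4
    give the minimal exact p = 1/35 ≈ 0.02857.
    """
    if len(multiplexed) == 0 or len(sequential) == 0:
        raise ValueError("both groups must be non-empty")
    mean_a = float(np.mean(multiplexed))
    mean_b = float(np.mean(sequential))
    if max(len(multiplexed), len(sequential)) <= exact_max_n:
        p = exact_mannwhitney_p(multiplexed, sequential)
    else:
        p = float(
            stats.mannwhitneyu(
                sequential, multiplexed, alternative="greater", method="asymptotic"
            ).pvalue
        )
    return {
        "mean_multiplexed": mean_a,
        "mean_sequential": mean_b,
        "fold": mean_b / mean_a if mean_a > 0 else float("inf"),
        "p_one_sided": p,
    }


# -- spectra and signatures -------------------------------------------------

def build_profile96(mutations: Iterable[Mutation]) -> Profile96:
    """Count mutations into the canonical pyrimidine-normalized 96 channels."""
    counts = np.zeros(96)
    errors = []
    for m in mutations:
        try:
            sub, ctx = normalize_to_pyrimidine(m.ref, m.alt, m.context)
            counts[_CLASS_INDEX[(sub, ctx[0] + ctx[2])]] += 1
        except (KeyError, ValueError) as exc:  # pragma: no cover - guarded upstream
            errors.append(f"{m.chrom}:{m.pos} {exc}")
    if errors:
        raise ValueError("malformed mutation records: " + "; ".join(errors))
    return Profile96(counts)


def refit_signatures(profile: Profile96, sigs: SignatureMatrix) -> Exposures:
    """Non-negative least-squares refit of known signatures to a profile.

    Exposures minimize the squared reconstruction error subject to
    non-negativity; the reconstruction cosine similarity is reported as a
    fit diagnostic (None for an all-zero profile).
    """
    if sigs.k < 1:
        raise ValueError("at least one signature required")
    y = profile.counts
    if y.sum() == 0:
        return Exposures(np.zeros(sigs.k), list(sigs.names), None)
    x, _ = optimize.nnls(sigs.matrix, y)
    recon = sigs.matrix @ x
    denom = np.linalg.norm(y) * np.linalg.norm(recon)
    cosine = float(y @ recon / denom) if denom > 0 else None
    return Exposures(x, list(sigs.names), cosine)


def classify_apobec_like(m: Mutation) -> bool:
    """Deterministic APOBEC-context proxy: C>T or C>G at a TpC site.

    The pyrimidine-normalized substitution must be C>T or C>G with T as
    the 5' flanking base — the context that dominates the APOBEC
    signatures SBS2/SBS13.
    """
    sub, ctx = normalize_to_pyrimidine(m.ref, m.alt, m.context)
    return sub in ("C>T", "C>G") and ctx[0] == "T"


# -- genomic intervals ------------------------------------------------------

@dataclass
class IntervalSet:
    """Sorted, non-overlapping 1-based closed intervals per chromosome."""

    intervals: dict[str, list[tuple[int, int]]]
    total_genome_length: int

    def __post_init__(self) -> None:
        if self.total_genome_length <= 0:
            raise ValueError("total_genome_length must be positive")
        normalized = {}
        for chrom, ivs in self.intervals.items():
            ivs = sorted(ivs)
            merged: list[tuple[int, int]] = []
            for start, end in ivs:
                if start > end or start < 1:
                    raise ValueError(f"invalid interval ({start}, {end}) on {chrom}")
                if merged and start <= merged[-1][1] + 1:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], end))
                else:
                    merged.append((start, end))
            normalized[chrom] = merged
        self.intervals = normalized

    @property
    def covered_length(self) -> int:
        return sum(
            end - start + 1
            for ivs in self.intervals.values()
            for start, end in ivs
        )

    def contains(self, chrom: str, pos: int) -> bool:
        ivs = self.intervals.get(chrom)
        if not ivs:
            return False
        starts = [s for s, _ in ivs]
        i = bisect.bisect_right(starts, pos) - 1
        return i >= 0 and ivs[i][0] <= pos <= ivs[i][1]


def gene_body_depletion(
    mutations: Sequence[Mutation],
    genes: IntervalSet,
    pseudocount: float = 0.0,
) -> dict[str, float]:
    """Depletion of mutations in gene bodies vs. the size expectation.

    Expected in-gene count is n_mutations x (covered length fraction).
    The log2 observed/expected score uses an optional pseudocount to
    guard ±infinity; the p-value is the exact two-sided binomial test
    (minimum-likelihood method).
    """
    if len(mutations) == 0:
        raise ValueError("empty mutation set")
    n = len(mutations)
    frac = genes.covered_length / genes.total_genome_length
    observed = sum(1 for m in mutations if genes.contains(m.chrom, m.pos))
    expected = n * frac
    assert observed <= n
    num = observed + pseudocount
    den = expected + pseudocount
    score = log2(num / den) if num > 0 and den > 0 else float("-inf")
    p = float(stats.binomtest(observed, n, frac, alternative="two-sided").pvalue)
    return {
        "observed": float(observed),
        "expected": float(expected),
        "log2_score": score,
        "p_binomial": p,
    }


def compare_depletion(
    class_a: tuple[int, int], class_b: tuple[int, int]
) -> dict[str, float]:
    """Two-sided Fisher exact test of in-gene proportions between classes.

    ``class_a`` and ``class_b`` are (in_genes, outside_genes) counts.
    A zero-margin table returns p = 1 with a degenerate flag.
    """
    a_in, a_out = class_a
    b_in, b_out = class_b
    if min(a_in, a_out, b_in, b_out) < 0:
        raise ValueError("counts must be non-negative")
    table = [[a_in, a_out], [b_in, b_out]]
    degenerate = (
        a_in + a_out == 0
        or b_in + b_out == 0
        or a_in + b_in == 0
        or a_out + b_out == 0
    )
    if degenerate:
        return {"p_fisher": 1.0, "degenerate": True}
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return {"p_fisher": p, "degenerate": False}


# -- rainfall / kataegis ----------------------------------------------------

@dataclass(frozen=True)
class KataegisCall:
    chrom: str
    start: int
    end: int
    n_mutations: int


def rainfall(
    mutations: Sequence[Mutation],
    min_run: int = 6,
    max_distance: int = 1000,
) -> tuple[dict[str, list[tuple[int, int]]], list[KataegisCall]]:
    """Inter-mutation distances per chromosome plus kataegis calls.

    The distance list holds (pos, distance to the previous mutation on
    the same chromosome); the first mutation of a chromosome has no
    entry.  A kataegis call is a maximal run of at least ``min_run``
    mutations whose consecutive distances are all <= ``max_distance``.
    """
    per_chrom: dict[str, list[int]] = {}
    for m in mutations:
        per_chrom.setdefault(m.chrom, []).append(m.pos)
    distances: dict[str, list[tuple[int, int]]] = {}
    calls: list[KataegisCall] = []
    for chrom in sorted(per_chrom):
        positions = sorted(per_chrom[chrom])
        dl = [
            (positions[i], positions[i] - positions[i - 1])
            for i in range(1, len(positions))
        ]
        distances[chrom] = dl
        run_start = 0
        i = 1
        while i <= len(positions):
            if i == len(positions) or positions[i] - positions[i - 1] > max_distance:
                run_len = i - run_start
                if run_len >= min_run:
                    calls.append(
                        KataegisCall(
                            chrom,
                            positions[run_start],
                            positions[i - 1],
                            run_len,
                        )
                    )
                run_start = i
            i += 1
    return distances, calls


# -- off-target scan --------------------------------------------------------

@dataclass(frozen=True)
class OffTargetSite:
    """A mismatch-tolerant spacer match with adjacent PAM and ±flank."""

    chrom: str
    strand: str  # "+" | "-"
    start: int  # 1-based start of the protospacer span on the + strand
    end: int  # inclusive end of the protospacer span on the + strand
    matched: str  # protospacer-strand sequence at the site
    mismatches: int
    flank_start: int
    flank_end: int


def find_offtarget_sites(
    spacer: str,
    genome: Mapping[str, str],
    max_mismatches: int = 4,
    pam: str = "NGG",
    flank: int = 200,
) -> list[OffTargetSite]:
    """Brute-force scan for near-matches of a spacer next to a PAM.

    Both strands of every chromosome are scanned; a site is any
    spacer-length window with at most ``max_mismatches`` mismatches whose
    immediately 3' bases match the PAM.  Each site carries a ±``flank``
    interval (closed, clipped to the chromosome).
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    spacer = validate_nucseq(spacer, "spacer")
    L, P = len(spacer), len(pam)
    sites: list[OffTargetSite] = []
    for chrom in sorted(genome):
        seq = validate_nucseq(genome[chrom], f"genome[{chrom}]")
        n = len(seq)
        for strand, sseq in (("+", seq), ("-", reverse_complement(seq))):
            for start0 in range(0, n - L - P + 1):
                window = sseq[start0 : start0 + L]
                mm = sum(1 for a, b in zip(window, spacer) if a != b)
                if mm > max_mismatches:
                    continue
                if not match_pam(sseq[start0 + L : start0 + L + P], pam):
                    continue
                if strand == "+":
                    start, end = start0 + 1, start0 + L
                else:
                    start, end = n - (start0 + L) + 1, n - start0
                sites.append(
                    OffTargetSite(
                        chrom=chrom,
                        strand=strand,
                        start=start,
                        end=end,
                        matched=window,
                        mismatches=mm,
                        flank_start=max(1, start - flank),
                        flank_end=min(n, end + flank),
                    )
                )
    sites.sort(key=lambda s: (s.chrom, s.start, s.strand))
    return sites


def intersect_offtargets(
    mutations: Sequence[Mutation], sites: Sequence[OffTargetSite]
) -> list[tuple[Mutation, OffTargetSite, str]]:
    """Mutations overlapping off-target sites, classed in_spacer / in_flank.

    A mutation overlaps when its position falls inside the protospacer
    span (``in_spacer``) or the surrounding closed flank (``in_flank``).
    """
    hits = []
    for m in mutations:
        for s in sites:
            if m.chrom != s.chrom:
                continue
            if s.start <= m.pos <= s.end:
                hits.append((m, s, "in_spacer"))
            elif s.flank_start <= m.pos <= s.flank_end:
                hits.append((m, s, "in_flank"))
    return hits


# -- text I/O ---------------------------------------------------------------

MUTATION_COLUMNS = ["chrom", "pos", "ref", "alt", "context"]


def read_mutations_tsv(path: str | Path) -> list[Mutation]:
    """Read a VCF-lite mutation TSV (chrom, pos, ref, alt, context)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    missing = set(MUTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"mutation table missing columns: {sorted(missing)}")
    return [
        Mutation(str(r.chrom), int(r.pos), str(r.ref), str(r.alt), str(r.context))
        for r in df.itertuples(index=False)
    ]


def write_mutations_tsv(mutations: Sequence[Mutation], path: str | Path) -> None:
    pd.DataFrame(
        {
            "chrom": [m.chrom for m in mutations],
            "pos": [m.pos for m in mutations],
            "ref": [m.ref for m in mutations],
            "alt": [m.alt for m in mutations],
            "context": [m.context for m in mutations],
        }
    ).to_csv(path, sep="\t", index=False)


def read_signatures_tsv(path: str | Path) -> SignatureMatrix:
    """Read a 96 x k signature TSV (row index = channel label, one column/signature)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df = df.loc[SBS96_LABELS]  # enforce canonical channel order
    return SignatureMatrix(df.to_numpy(dtype=float), [str(c) for c in df.columns])


def write_signatures_tsv(sigs: SignatureMatrix, path: str | Path) -> None:
    pd.DataFrame(sigs.matrix, index=SBS96_LABELS, columns=sigs.names).to_csv(
        path, sep="\t", index_label="channel"
    )


def read_intervals_bed(path: str | Path, total_genome_length: int) -> IntervalSet:
    """Read BED-like intervals (0-based half-open on disk) as 1-based closed."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            intervals.setdefault(chrom, []).append((int(start) + 1, int(end)))
    return IntervalSet(intervals, total_genome_length)
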