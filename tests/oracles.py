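"""Independent brute-force oracles used to cross-check the production code.

Everything here is deliberately written in a different style from the
package (string slicing, per-position set membership, full enumeration)
and imports only leaf-level data types, so an error in the production
search logic cannot silently propagate into the expected values.
"""

from __future__ import annotations

from itertools import combinations, product

# Independent IUPAC expansion (not imported from the package)
IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

# Independent hard-coded standard genetic code, TCAG ordering
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_ORDER = "TCAG"
CODON_TABLE_64 = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_ORDER)
    for j, b in enumerate(_ORDER)
    for k, c in enumerate(_ORDER)
}

_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(s: str) -> str:
    return "".join(_RC[c] for c in reversed(s))


def pam_matches(seq: str, pattern: str) -> bool:
    return len(seq) == len(pattern) and all(
        b in IUPAC_SETS[p] for b, p in zip(seq, pattern)
    )


def oracle_placements(strand_seq: str, spacer_len: int, pam: str) -> list[tuple[int, str, str]]:
    """All (start, spacer, pam_seq), 1-based, by naive sliding window."""
    out = []
    for i in range(len(strand_seq)):
        spacer = strand_seq[i : i + spacer_len]
        pam_seq = strand_seq[i + spacer_len : i + spacer_len + len(pam)]
        if len(spacer) == spacer_len and pam_matches(pam_seq, pam):
            out.append((i + 1, spacer, pam_seq))
    return out


# sense-strand substitution -> (chemistry, protospacer strand)
CHEMISTRY = {
    ("C", "T"): ("CBE", "sense"),
    ("G", "A"): ("CBE", "antisense"),
    ("A", "G"): ("ABE", "sense"),
    ("T", "C"): ("ABE", "antisense"),
}


def oracle_guides(
    changes,  # iterable of (cds_pos, ref, alt), sense coordinates
    context: str,
    up_flank_len: int,
    editor,  # bemux EditorSpec (data only: pam, spacer_len, windows, chemistry)
    allow_extended: bool,
) -> set[tuple[str, int]]:
    """Set of (strand, protospacer_start) supporting all changes at once.

    Tries every placement on both strands by brute force and keeps those
    whose PAM matches and whose required edits all sit in the window with
    the editor's chemistry on the protospacer strand.
    """
    changes = list(changes)
    chems = {CHEMISTRY.get((ref, alt)) for _, ref, alt in changes}
    if None in chems or len(chems) != 1:
        return set()
    chemistry, strand = chems.pop()
    if chemistry != editor.chemistry:
        return set()
    n = len(context)
    sseq = context if strand == "sense" else revcomp(context)
    positions = [
        (up_flank_len + p) if strand == "sense" else (n - (up_flank_len + p) + 1)
        for p, _, _ in changes
    ]
    lo, hi = editor.extended_window if allow_extended else editor.window
    hits = set()
    for start, spacer, pam_seq in oracle_placements(sseq, editor.spacer_len, editor.pam):
        offsets = [q - start + 1 for q in positions]
        if all(lo <= o <= hi for o in offsets):
            hits.add((strand, start))
    return hits


def oracle_protein_options(ref_codon: str, alt_aa: str) -> list[tuple[str, tuple]]:
    """All (alt_codon, changed positions 0-based) by scanning the 64 codons."""
    out = []
    for codon, aa in CODON_TABLE_64.items():
        if aa != alt_aa or codon == ref_codon:
            continue
        diffs = tuple(i for i in range(3) if codon[i] != ref_codon[i])
        if diffs:
            out.append((codon, diffs))
    return out


def oracle_stop_codons() -> dict[str, set[str]]:
    """Codons convertible to stop by C>T on either strand, brute force."""
    stops = {"TAA", "TAG", "TGA"}
    result: dict[str, set[str]] = {}
    for codon in ("".join(t) for t in product("ACGT", repeat=3)):
        if codon in stops:
            continue
        for strategy, sub, prod in (("sense_C>T", "C", "T"), ("antisense_C>T", "G", "A")):
            pos = [i for i in range(3) if codon[i] == sub]
            for k in range(1, len(pos) + 1):
                for subset in combinations(pos, k):
                    edited = "".join(
                        prod if i in subset else codon[i] for i in range(3)
                    )
                    if edited in stops:
                        result.setdefault(codon, set()).add(strategy)
    return result


def oracle_translate(cds: str) -> str:
    return "".join(CODON_TABLE_64[cds[i : i + 3]] for i in range(0, len(cds), 3))


def oracle_offtargets(
    spacer: str, genome: dict[str, str], max_mm: int, pam: str
) -> set[tuple[str, str, int]]:
    """Set of (chrom, strand, plus-strand start) near-matches with PAM."""
    L, P = len(spacer), len(pam)
    hits = set()
    for chrom, seq in genome.items():
        n = len(seq)
        for strand in "+-":
            s = seq if strand == "+" else revcomp(seq)
            for i in range(n - L - P + 1):
                mm = sum(a != b for a, b in zip(s[i : i + L], spacer))
                if mm <= max_mm and pam_matches(s[i + L : i + L + P], pam):
                    start = i + 1 if strand == "+" else n - (i + L) + 1
                    hits.add((chrom, strand, start))
    return hits


def oracle_binom_two_sided(k: int, n: int, p: float) -> float:
    """Exact two-sided binomial p by minimum-likelihood enumeration."""
    from math import comb

    pmf = [comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(n + 1)]
    obs = pmf[k]
    return min(1.0, sum(x for x in pmf if x <= obs * (1 + 1e-12)))


def oracle_fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p by hypergeometric enumeration."""
    from math import comb

    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2
    denom = comb(n, col1)
    probs = {}
    for x in range(max(0, col1 - row2), min(row1, col1) + 1):
        probs[x] = comb(row1, x) * comb(row2, col1 - x) / denom
    obs = probs[a]
    return min(1.0, sum(p for p in probs.values() if p <= obs * (1 + 1e-12)))
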