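"""Load comparison, spectra, signature refitting, depletion, kataegis, off-targets."""

from itertools import combinations
from math import comb, isclose

import numpy as np
import pytest

from bemux.burden import (
    IntervalSet,
    Mutation,
    Profile96,
    SignatureMatrix,
    SBS96_CLASSES,
    build_profile96,
    classify_apobec_like,
    compare_depletion,
    compare_loads,
    find_offtarget_sites,
    gene_body_depletion,
    intersect_offtargets,
    normalize_to_pyrimidine,
    rainfall,
    read_intervals_bed,
    read_mutations_tsv,
    read_signatures_tsv,
    refit_signatures,
    write_mutations_tsv,
    write_signatures_tsv,
)
from bemux.synth import synthetic_signatures

from oracles import (
    oracle_binom_two_sided,
    oracle_fisher_two_sided,
    oracle_offtargets,
)


class TestCompareLoads:
    def test_fully_separated_3v4_reproduces_1_over_35(self):
        res = compare_loads([1000, 1150, 1192], [3600, 3700, 3750, 3814])
        assert isclose(res["p_one_sided"], 1 / 35)
        assert round(res["p_one_sided"], 5) == 0.02857
        assert res["mean_multiplexed"] == pytest.approx(1114)
        assert res["mean_sequential"] == pytest.approx(3716)
        assert res["fold"] == pytest.approx(3716 / 1114)

    def test_tied_singletons_give_p_1(self):
        assert compare_loads([5], [5])["p_one_sided"] == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_loads([], [1.0])

    def test_separated_p_equals_combinatorial_minimum_up_to_6(self):
        # fully separated groups: p = 1 / C(n_a + n_b, n_a) for all sizes <= 6
        for n_a in range(1, 7):
            for n_b in range(1, 7):
                a = [float(i) for i in range(n_a)]
                b = [float(100 + i) for i in range(n_b)]
                p = compare_loads(a, b)["p_one_sided"]
                assert isclose(p, 1 / comb(n_a + n_b, n_a)), (n_a, n_b)

    def test_exact_matches_rank_based_permutation_oracle_with_ties(self, rng):
        # independent oracle: U from midranks, permutation null by enumeration
        from scipy.stats import rankdata

        def u_from_ranks(a, b):
            ranks = rankdata(list(a) + list(b))
            r_b = ranks[len(a):].sum()
            return r_b - len(b) * (len(b) + 1) / 2

        for _ in range(10):
            n_a, n_b = int(rng.integers(2, 5)), int(rng.integers(2, 5))
            a = list(rng.integers(0, 4, size=n_a))  # small alphabet forces ties
            b = list(rng.integers(0, 4, size=n_b))
            pooled = a + b
            obs = u_from_ranks(a, b)
            hits = 0
            total = 0
            for a_idx in combinations(range(len(pooled)), n_a):
                aa = [pooled[i] for i in a_idx]
                bb = [pooled[i] for i in range(len(pooled)) if i not in a_idx]
                hits += u_from_ranks(aa, bb) >= obs - 1e-9
                total += 1
            assert compare_loads(a, b)["p_one_sided"] == pytest.approx(hits / total)


class TestProfile96:
    def test_pyrimidine_and_purine_strands_share_a_channel(self):
        m1 = Mutation("chr1", 10, "C", "T", "ACA")
        m2 = Mutation("chr1", 20, "G", "A", "TGT")  # revcomp of the same class
        p = build_profile96([m1, m2])
        idx = SBS96_CLASSES.index(("C>T", "AA"))
        assert p.counts[idx] == 2 and p.total == 2

    def test_counts_are_conserved(self, rng):
        sigs = synthetic_signatures(1)
        from bemux.synth import gen_mutation_set

        genes = IntervalSet({"chr1": [(1, 100)]}, 10_000)
        muts, _ = gen_mutation_set(5, 1000, [0.5, 0.5], sigs, genes)
        assert build_profile96(muts).total == 1000

    def test_context_must_embed_ref(self):
        with pytest.raises(ValueError):
            Mutation("chr1", 1, "C", "T", "ATA")


class TestRefitSignatures:
    def test_pure_column_recovered_exactly(self):
        sigs = synthetic_signatures(2, k=2)
        profile = Profile96(500 * sigs.matrix[:, 0])
        exp = refit_signatures(profile, sigs)
        assert exp.values == pytest.approx([500.0, 0.0], abs=1e-6)
        assert exp.reconstruction_cosine == pytest.approx(1.0)

    def test_noiseless_mixture_recovered_to_1e6(self):
        sigs = synthetic_signatures(3, k=2)
        profile = Profile96(10_000 * (0.6 * sigs.matrix[:, 0] + 0.4 * sigs.matrix[:, 1]))
        exp = refit_signatures(profile, sigs)
        assert exp.proportions == pytest.approx([0.6, 0.4], abs=1e-6)

    def test_zero_profile_flagged(self):
        sigs = synthetic_signatures(4, k=3)
        exp = refit_signatures(Profile96(np.zeros(96)), sigs)
        assert exp.values.tolist() == [0.0, 0.0, 0.0]
        assert exp.reconstruction_cosine is None

    def test_column_normalization_enforced(self):
        with pytest.raises(ValueError):
            SignatureMatrix(np.full((96, 1), 0.5), ["S1"])


class TestApobecClassifier:
    @pytest.mark.parametrize(
        "ref,alt,context,expected",
        [
            ("C", "T", "TCA", True),
            ("C", "G", "TCT", True),
            ("C", "T", "ACG", False),
            ("C", "A", "TCA", False),
            ("G", "A", "TGA", True),  # normalizes to C>T at TCA
        ],
    )
    def test_rule(self, ref, alt, context, expected):
        assert classify_apobec_like(Mutation("chr1", 1, ref, alt, context)) is expected


def uniform_mutations(positions, chrom="chr1"):
    return [Mutation(chrom, p, "C", "T", "ACA") for p in positions]


class TestGeneBodyDepletion:
    def test_point_of_symmetry(self):
        genes = IntervalSet({"chr1": [(1, 400)]}, 1000)
        muts = uniform_mutations(list(range(1, 41)) + list(range(500, 560)))
        res = gene_body_depletion(muts, genes)
        assert res["observed"] == 40 and res["expected"] == 40
        assert res["log2_score"] == 0.0
        assert res["p_binomial"] == pytest.approx(1.0)

    def test_halved_occupancy_scores_minus_one_and_matches_enumeration(self):
        genes = IntervalSet({"chr1": [(1, 400)]}, 1000)
        muts = uniform_mutations(list(range(1, 21)) + list(range(500, 580)))
        res = gene_body_depletion(muts, genes)
        assert res["log2_score"] == pytest.approx(-1.0)
        assert res["p_binomial"] == pytest.approx(oracle_binom_two_sided(20, 100, 0.4))

    def test_empty_mutation_set_rejected(self):
        genes = IntervalSet({"chr1": [(1, 400)]}, 1000)
        with pytest.raises(ValueError, match="empty"):
            gene_body_depletion([], genes)


class TestCompareDepletion:
    def test_identical_proportions(self):
        assert compare_depletion((5, 5), (5, 5))["p_fisher"] == 1.0

    def test_matches_hypergeometric_enumeration(self):
        res = compare_depletion((10, 90), (40, 60))
        assert res["p_fisher"] == pytest.approx(oracle_fisher_two_sided(10, 90, 40, 60))

    def test_extreme_table_smallest_p_for_margins(self):
        res = compare_depletion((0, 10), (10, 0))
        assert res["p_fisher"] == pytest.approx(oracle_fisher_two_sided(0, 10, 10, 0))

    def test_zero_margin_flagged(self):
        res = compare_depletion((0, 0), (3, 4))
        assert res == {"p_fisher": 1.0, "degenerate": True}


class TestRainfall:
    def test_widely_spaced_mutations_no_calls(self):
        muts = uniform_mutations(range(100_000, 1_000_001, 100_000))
        dists, calls = rainfall(muts)
        assert calls == []
        assert all(d == 100_000 for _, d in dists["chr1"])

    def test_planted_run_called_once_with_correct_span(self):
        background = list(range(10_000, 500_001, 10_000))
        run = [700_000 + 500 * i for i in range(6)]
        _, calls = rainfall(uniform_mutations(background + run))
        assert len(calls) == 1
        call = calls[0]
        assert (call.start, call.end, call.n_mutations) == (700_000, 702_500, 6)

    def test_single_mutation_chrom_has_empty_distances(self):
        dists, calls = rainfall(uniform_mutations([50]))
        assert dists["chr1"] == [] and calls == []

    def test_run_of_five_not_called(self):
        run = [1000 + 500 * i for i in range(5)]
        _, calls = rainfall(uniform_mutations(run))
        assert calls == []


class TestOffTargets:
    SPACER = "ACGTACGTACGTACGTACGT"

    def test_perfect_site(self):
        genome = {"chr1": self.SPACER + "AGG"}
        sites = find_offtarget_sites(self.SPACER, genome)
        assert len(sites) == 1
        s = sites[0]
        assert (s.start, s.end, s.mismatches, s.strand) == (1, 20, 0, "+")
        assert s.flank_start == 1 and s.flank_end == 23

    def test_five_mismatches_excluded(self):
        mutated = "TCGTTCGTTCGTTCGTTCGT"  # 5 substitutions
        genome = {"chr1": mutated + "AGG"}
        assert find_offtarget_sites(self.SPACER, genome, max_mismatches=4) == []

    def test_matches_naive_oracle_on_random_genomes(self):
        rng = np.random.default_rng(77)
        for _ in range(3):
            genome = {
                "chrA": "".join("ACGT"[i] for i in rng.integers(4, size=3000)),
                "chrB": "".join("ACGT"[i] for i in rng.integers(4, size=2000)),
            }
            spacer = "".join("ACGT"[i] for i in rng.integers(4, size=20))
            got = {
                (s.chrom, s.strand, s.start)
                for s in find_offtarget_sites(spacer, genome, max_mismatches=4)
            }
            assert got == oracle_offtargets(spacer, genome, 4, "NGG")

    def test_intersection_classes_and_boundary(self):
        genome = {"chr1": "T" * 300 + self.SPACER + "AGG" + "T" * 300}
        (site,) = find_offtarget_sites(self.SPACER, genome)
        assert (site.start, site.end) == (301, 320)
        inside = Mutation("chr1", 310, "C", "T", "ACA")
        downstream_150 = Mutation("chr1", 470, "C", "T", "ACA")
        at_200 = Mutation("chr1", 520, "C", "T", "ACA")
        beyond = Mutation("chr1", 521, "C", "T", "ACA")
        hits = intersect_offtargets([inside, downstream_150, at_200, beyond], [site])
        assert [(m.pos, cls) for m, _, cls in hits] == [
            (310, "in_spacer"),
            (470, "in_flank"),
            (520, "in_flank"),
        ]


class TestTextIO:
    def test_mutation_round_trip(self, tmp_path):
        muts = uniform_mutations([10, 20, 30])
        path = tmp_path / "m.tsv"
        write_mutations_tsv(muts, path)
        assert read_mutations_tsv(path) == muts

    def test_signature_round_trip(self, tmp_path):
        sigs = synthetic_signatures(9, k=3)
        path = tmp_path / "s.tsv"
        write_signatures_tsv(sigs, path)
        back = read_signatures_tsv(path)
        assert back.names == sigs.names
        assert np.allclose(back.matrix, sigs.matrix)

    def test_bed_is_converted_to_1_based_closed(self, tmp_path):
        path = tmp_path / "g.bed"
        path.write_text("chr1\t0\t100\nchr1\t200\t250\n")
        ivs = read_intervals_bed(path, 1000)
        assert ivs.intervals["chr1"] == [(1, 100), (201, 250)]
        assert ivs.covered_length == 150
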