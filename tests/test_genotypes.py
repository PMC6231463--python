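"""Genotype handling: parsing, filtering, individual identification,
diversity indices, P(ID) and the shared-alleles distance."""

import io
import itertools

import numpy as np
import pytest

from landgen.genotypes import (
    GenotypeTable,
    allele_frequencies,
    collapse_individuals,
    diversity_summary,
    dps_distance,
    filter_by_loci,
    probability_of_identity,
    read_genotypes,
)

from conftest import random_table


# -- parsing -----------------------------------------------------------
def _csv(text):
    return io.StringIO(text.strip() + "\n")


class TestReadGenotypes:
    def test_well_formed(self):
        t = read_genotypes(_csv(
            "sample,sex,x,y,La_1,La_2,Lb_1,Lb_2\n"
            "a,F,0,0,100,102,200,200\n"
            "b,M,10,10,100,100,202,204\n"
            "c,F,20,5,102,102,200,204"
        ))
        assert t.n == 3 and t.n_loci == 2
        assert t.locus_names == ["La", "Lb"]
        assert t.sample_id == ["a", "b", "c"]

    def test_half_missing_coerced(self, caplog):
        t = read_genotypes(_csv(
            "sample,sex,x,y,La_1,La_2\na,F,0,0,182,0"
        ))
        assert t.calls[0, 0].tolist() == [0, 0]  # fully missing

    def test_odd_allele_columns(self):
        with pytest.raises(ValueError, match="odd"):
            read_genotypes(_csv(
                "sample,sex,x,y,La_1,La_2,Lb_1\na,F,0,0,1,2,3"
            ))

    def test_duplicate_sample_id(self):
        with pytest.raises(ValueError, match="dup"):
            read_genotypes(_csv(
                "sample,sex,x,y,La_1,La_2\na,F,0,0,1,2\na,M,1,1,3,4"
            ))

    def test_custom_missing_code(self):
        t = read_genotypes(_csv(
            "sample,sex,x,y,La_1,La_2\na,F,0,0,-99,-99"
        ), missing_code=-99)
        assert not t.typed()[0, 0]

    def test_roundtrip(self, toy_table, tmp_path):
        path = tmp_path / "g.csv"
        toy_table.to_csv(path)
        back = read_genotypes(path)
        assert back.sample_id == toy_table.sample_id
        np.testing.assert_array_equal(back.calls, toy_table.calls)


# -- filtering and collapsing ------------------------------------------
class TestFilterCollapse:
    def test_threshold_removes_undertyped(self, toy_table):
        # s3 is typed at 2 of 3 loci
        out = filter_by_loci(toy_table, 3)
        assert "s3" not in out.sample_id and out.n == 4

    def test_zero_threshold_is_identity(self, toy_table):
        assert filter_by_loci(toy_table, 0).sample_id == toy_table.sample_id

    def test_collapse_exact_duplicates(self, toy_table):
        out, mapping = collapse_individuals(toy_table, 0)
        assert mapping["s1"] == mapping["s0"]
        assert out.n == 4

    def test_collapse_mismatch_tolerance(self, toy_table):
        out, mapping = collapse_individuals(toy_table, 1)
        # s2 differs from s0 by one locus: merged at tolerance 1
        assert mapping["s2"] == mapping["s0"]

    def test_collapse_matches_exhaustive_grouping(self, rng):
        """Union-find grouping equals brute-force transitive closure."""
        t = random_table(rng, n=10, n_loci=4, n_alleles=2, missing_rate=0.2)
        for max_mm in (0, 1):
            _, mapping = collapse_individuals(t, max_mm)

            def mism(i, j):
                both = t.typed()[i] & t.typed()[j]
                cnt = 0
                for L in np.flatnonzero(both):
                    a, b = sorted(t.calls[i, L]), sorted(t.calls[j, L])
                    cnt += a != b
                return cnt

            # brute-force closure
            groups = {i: {i} for i in range(t.n)}
            changed = True
            while changed:
                changed = False
                for i, j in itertools.combinations(range(t.n), 2):
                    if mism(i, j) <= max_mm and groups[i] is not groups[j]:
                        merged = groups[i] | groups[j]
                        for k in merged:
                            groups[k] = merged
                        changed = True
            for i, j in itertools.combinations(range(t.n), 2):
                same_bf = groups[i] is groups[j]
                same_uf = mapping[t.sample_id[i]] == mapping[t.sample_id[j]]
                assert same_bf == same_uf

    def test_filter_then_collapse_idempotent(self, rng):
        t = random_table(rng, n=15, missing_rate=0.2)
        once = collapse_individuals(filter_by_loci(t, 3), 0)[0]
        twice = collapse_individuals(filter_by_loci(once, 3), 0)[0]
        assert once.sample_id == twice.sample_id
        np.testing.assert_array_equal(once.calls, twice.calls)

    def test_empty_table(self):
        t = GenotypeTable([], [], np.empty((0, 2)), np.empty((0, 2, 2), int), ["La", "Lb"])
        out, mapping = collapse_individuals(t, 0)
        assert out.n == 0 and mapping == {}


# -- frequencies and diversity -----------------------------------------
class TestFrequencies:
    def test_symmetric_counts(self):
        t = GenotypeTable(["a", "b"], ["F", "F"], np.zeros((2, 2)),
                          np.array([[[1, 2]], [[1, 2]]]), ["L"])
        f = allele_frequencies(t).freqs[0]
        assert f == {1: 0.5, 2: 0.5}

    def test_three_of_four(self):
        t = GenotypeTable(["a", "b"], ["F", "F"], np.zeros((2, 2)),
                          np.array([[[1, 1]], [[1, 2]]]), ["L"])
        f = allele_frequencies(t).freqs[0]
        assert f == {1: 0.75, 2: 0.25}

    def test_missing_excluded_from_denominator(self):
        t = GenotypeTable(["a", "b"], ["F", "F"], np.zeros((2, 2)),
                          np.array([[[1, 2]], [[0, 0]]]), ["L"])
        af = allele_frequencies(t)
        assert af.n_genes[0] == 2

    def test_all_missing_locus_errors(self):
        t = GenotypeTable(["a"], ["F"], np.zeros((1, 2)),
                          np.array([[[0, 0]]]), ["Lbad"])
        with pytest.raises(ValueError, match="Lbad"):
            allele_frequencies(t)


class TestDiversity:
    def test_monomorphic_locus(self):
        t = GenotypeTable(["a", "b"], ["F", "F"], np.zeros((2, 2)),
                          np.array([[[1, 1]], [[1, 1]]]), ["L"])
        d = diversity_summary(t).per_locus.iloc[0]
        assert d["A"] == 1 and d["H_O"] == 0 and d["H_E"] == 0

    def test_single_heterozygote_closed_form(self):
        # n=1: H_O = 1, unbiased H_E = (2/1) * (1 - 0.5) = 1
        t = GenotypeTable(["a"], ["F"], np.zeros((1, 2)),
                          np.array([[[1, 2]]]), ["L"])
        d = diversity_summary(t).per_locus.iloc[0]
        assert d["H_O"] == 1.0
        assert d["H_E"] == pytest.approx(1.0)

    def test_unbiased_correction_vanishes_at_large_n(self, rng):
        n = 10_000
        calls = rng.choice([1, 2, 3], size=(n, 1, 2))
        t = GenotypeTable([f"i{k}" for k in range(n)], ["F"] * n,
                          np.zeros((n, 2)), calls, ["L"])
        he_unb = diversity_summary(t, unbiased=True).mean_he
        he_raw = diversity_summary(t, unbiased=False).mean_he
        assert abs(he_unb - he_raw) < 1e-4


# -- probability of identity -------------------------------------------
def _pid_enumeration(p):
    """Exhaustive genotype-pair enumeration under HWE (unrelated pair)."""
    alleles = list(range(len(p)))
    total = 0.0
    for i, j in itertools.product(alleles, alleles):
        prob = p[i] * p[j]  # ordered genotype
        # probability a second independent individual has same unordered genotype
        if i == j:
            match = p[i] ** 2
        else:
            match = 2 * p[i] * p[j]
        total += prob * match
    return total


def _pidsib_enumeration(p):
    """Full-sib genotype identity by enumerating parental genotypes and
    Mendelian transmissions."""
    alleles = list(range(len(p)))
    total = 0.0
    for m1, m2 in itertools.product(alleles, repeat=2):
        for f1, f2 in itertools.product(alleles, repeat=2):
            p_parents = p[m1] * p[m2] * p[f1] * p[f2]
            match = 0.0
            for a1, b1 in itertools.product((m1, m2), (f1, f2)):
                for a2, b2 in itertools.product((m1, m2), (f1, f2)):
                    if sorted((a1, b1)) == sorted((a2, b2)):
                        match += (0.25) * (0.25)
            total += p_parents * match
    return total


class TestPID:
    def test_biallelic_values(self):
        """p = q = 0.5 gives the textbook 0.375 and 0.59375."""
        from landgen.genotypes import AlleleFrequencies

        af = AlleleFrequencies([{1: 0.5, 2: 0.5}], np.array([100]), ["L"])
        pid, pid_sib = probability_of_identity(af)
        assert pid == pytest.approx(0.375, abs=1e-12)
        assert pid_sib == pytest.approx(0.59375, abs=1e-12)

    @pytest.mark.parametrize("p", [
        [0.5, 0.5],
        [0.7, 0.2, 0.1],
        [0.4, 0.3, 0.2, 0.1],
    ])
    def test_matches_enumeration(self, p):
        from landgen.genotypes import AlleleFrequencies

        af = AlleleFrequencies([{k: v for k, v in enumerate(p)}],
                               np.array([100]), ["L"])
        pid, pid_sib = probability_of_identity(af)
        assert pid == pytest.approx(_pid_enumeration(p), abs=1e-12)
        assert pid_sib == pytest.approx(_pidsib_enumeration(p), abs=1e-12)

    def test_multilocus_product(self):
        from landgen.genotypes import AlleleFrequencies

        one = AlleleFrequencies([{1: 0.5, 2: 0.5}], np.array([10]), ["L1"])
        two = AlleleFrequencies([{1: 0.5, 2: 0.5}] * 2, np.array([10, 10]),
                                ["L1", "L2"])
        assert probability_of_identity(two)[0] == pytest.approx(
            probability_of_identity(one)[0] ** 2, rel=1e-12
        )


# -- Dps ---------------------------------------------------------------
class TestDps:
    def test_identical_genotypes_distance_zero(self, toy_table):
        d = dps_distance(toy_table)
        assert d.values[0, 1] == 0.0

    def test_disjoint_alleles_distance_one(self):
        t = GenotypeTable(["a", "b"], ["F", "F"], np.zeros((2, 2)),
                          np.array([[[1, 2], [5, 6]], [[3, 4], [7, 8]]]),
                          ["L1", "L2"])
        assert dps_distance(t).values[0, 1] == 1.0

    def test_single_locus_half_shared(self):
        # AB vs AC share one allele: distance 1 - 1/2
        t = GenotypeTable(["a", "b"], ["F", "F"], np.zeros((2, 2)),
                          np.array([[[1, 2]], [[1, 3]]]), ["L"])
        assert dps_distance(t).values[0, 1] == pytest.approx(0.5)

    def test_multiplicity_counting(self):
        # AA vs AB: one A matched (multiplicity) -> shared 1 of 2
        t = GenotypeTable(["a", "b"], ["F", "F"], np.zeros((2, 2)),
                          np.array([[[1, 1]], [[1, 2]]]), ["L"])
        assert dps_distance(t).values[0, 1] == pytest.approx(0.5)

    def test_no_cotyped_pair_errors(self):
        t = GenotypeTable(["a", "b"], ["F", "F"], np.zeros((2, 2)),
                          np.array([[[1, 2], [0, 0]], [[0, 0], [3, 4]]]),
                          ["L1", "L2"])
        with pytest.raises(ValueError, match="co-typed"):
            dps_distance(t)

    def test_properties_on_random_tables(self, rng):
        """Symmetric, zero-diagonal, bounded in [0, 1]."""
        for _ in range(10):
            t = random_table(rng)
            d = dps_distance(t).values
            assert np.allclose(d, d.T)
            assert np.all(np.diag(d) == 0)
            assert d.min() >= 0 and d.max() <= 1
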