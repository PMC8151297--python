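import numpy as np
import pytest

import capspop as cp
from capspop.amova import AmovaError, _AmovaData

from conftest import make_gm


def brute_force_ss(gm):
    """Independent oracle: explicit enumeration of allele-copy pairs.

    Per locus, the SS within a group of copies is the sum over all copy
    pairs of the 0/1 mismatch indicator divided by the number of copies in
    the group; levels are total, within-population, within-individual.
    """
    pops = sorted(set(gm.population_labels))

    def group_ss(indices):
        total = 0.0
        for j in range(gm.n_markers):
            copies = []
            for i in indices:
                call = gm.calls[i][j]
                if not call.is_missing:
                    copies.extend(call.alleles)
            if not copies:
                continue
            mismatches = sum(
                copies[a] != copies[b]
                for a in range(len(copies))
                for b in range(a + 1, len(copies))
            )
            total += mismatches / len(copies)
        return total

    ss_total = group_ss(range(gm.n_accessions))
    ss_wp = sum(
        group_ss([i for i, p in enumerate(gm.population_labels) if p == pop])
        for pop in pops
    )
    ss_wi = sum(
        sum(c.is_heterozygous for c in row) / 2.0 for row in gm.calls
    )
    return ss_total - ss_wp, ss_wp - ss_wi, ss_wi


def two_pop_gm(seed, sizes=(3, 3), n_loci=5, fst=0.3):
    cfg = cp.SimulationConfig(
        seed=seed, n_populations=2, population_sizes=sizes, n_admixed=0,
        n_loci=n_loci, monomorphic_fraction=0.0, target_fst=fst, f_excess=0.0,
    )
    return cp.simulate_genotypes(cfg, cp.simulate_allele_frequencies(cfg))


class TestDfStructure:
    def test_41_accessions_3_groups(self):
        cfg = cp.SimulationConfig(
            seed=2, n_populations=3, population_sizes=(14, 14, 13), n_admixed=0,
            monomorphic_fraction=0.0,
        )
        gm = cp.simulate_genotypes(cfg, cp.simulate_allele_frequencies(cfg))
        res = cp.amova_codominant(gm)
        assert [r["df"] for r in res.rows] == [2, 38, 41, 81]

    def test_singleton_population_rejected(self):
        gm = make_gm(
            [["A/A"], ["A/G"], ["G/G"]],
            pops=["P1", "P1", "P2"],
        )
        with pytest.raises(AmovaError, match="at least 2"):
            cp.amova_codominant(gm)

    def test_labels_required(self):
        gm = make_gm([["A/A"], ["G/G"]])
        with pytest.raises(AmovaError, match="labels"):
            cp.amova_codominant(gm)


class TestSumsOfSquares:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_pair_enumeration_oracle(self, seed):
        gm = two_pop_gm(seed, sizes=(4, 4), n_loci=6)
        res = cp.amova_codominant(gm)
        expected = brute_force_ss(gm)
        for row, exp in zip(res.rows, expected):
            assert row["SS"] == pytest.approx(exp, abs=1e-10)

    def test_oracle_with_missing_calls(self):
        cfg = cp.SimulationConfig(
            seed=9, n_populations=2, population_sizes=(4, 4), n_admixed=0,
            n_loci=6, monomorphic_fraction=0.0, target_fst=0.3, f_excess=0.0,
            missing_rate=0.15,
        )
        gm = cp.simulate_genotypes(cfg, cp.simulate_allele_frequencies(cfg))
        res = cp.amova_codominant(gm)
        expected = brute_force_ss(gm)
        for row, exp in zip(res.rows, expected):
            assert row["SS"] == pytest.approx(exp, abs=1e-10)

    def test_ss_additivity(self, synthetic_gm):
        res = cp.amova_codominant(synthetic_gm)
        parts = [r["SS"] for r in res.rows[:3]]
        assert sum(parts) == pytest.approx(res.rows[3]["SS"], abs=1e-8)

    def test_percentages_sum_to_100(self, synthetic_gm):
        res = cp.amova_codominant(synthetic_gm)
        assert sum(r["percent"] for r in res.rows[:3]) == pytest.approx(100.0)

    def test_scale_invariance_locus_duplication(self):
        gm = two_pop_gm(3, sizes=(4, 4), n_loci=6)
        doubled = cp.GenotypeMatrix(
            accession_ids=list(gm.accession_ids),
            marker_ids=gm.marker_ids + [m + "b" for m in gm.marker_ids],
            calls=[row + row for row in gm.calls],
            population_labels=list(gm.population_labels),
        )
        r1, r2 = cp.amova_codominant(gm), cp.amova_codominant(doubled)
        assert r2.rows[3]["SS"] == pytest.approx(2 * r1.rows[3]["SS"])
        assert r2.f_st == pytest.approx(r1.f_st, abs=1e-12)
        for a, b in zip(r1.rows[:3], r2.rows[:3]):
            assert b["percent"] == pytest.approx(a["percent"], abs=1e-9)


class TestFst:
    def test_complete_fixation(self):
        gm = make_gm(
            [["A/A", "C/C"], ["A/A", "C/C"], ["G/G", "T/T"], ["G/G", "T/T"]],
            pops=["P1", "P1", "P2", "P2"],
        )
        res = cp.amova_codominant(gm)
        assert res.f_st == pytest.approx(1.0)
        assert res.rows[0]["percent"] == pytest.approx(100.0)

    def test_panmictic_split_fst_near_zero(self):
        # one HWE population randomly split in two: F_ST ~ 0, p ~ uniform
        fsts, pvals = [], []
        for rep in range(200):
            cfg = cp.SimulationConfig(
                seed=3000 + rep, n_populations=1, population_sizes=(16,),
                n_admixed=0, n_loci=30, monomorphic_fraction=0.0,
                target_fst=0.0, f_excess=0.0,
            )
            gm = cp.simulate_genotypes(cfg, cp.simulate_allele_frequencies(cfg))
            labels = ["P1"] * 8 + ["P2"] * 8
            rng = np.random.default_rng(rep)
            rng.shuffle(labels)
            gm = gm.with_population_labels(labels)
            res = cp.amova_codominant(gm)
            fsts.append(res.f_st)
            pvals.append(cp.permute_fst(gm, res, n_perm=49, seed=rep))
        assert abs(np.mean(fsts)) < 0.02
        assert 0.35 < np.mean(pvals) < 0.65

    def test_missing_calls_logged_count(self):
        data_complete = _AmovaData(two_pop_gm(4, sizes=(3, 3)))
        assert data_complete.n_missing_calls == 0


class TestPermutation:
    def test_p_value_bounds_and_determinism(self):
        gm = two_pop_gm(5, sizes=(5, 5), n_loci=20)
        p1 = cp.permute_fst(gm, n_perm=99, seed=42)
        p2 = cp.permute_fst(gm, n_perm=99, seed=42)
        assert p1 == p2
        assert 1 / 100 <= p1 <= 1.0

    def test_complete_fixation_minimal_p(self):
        # no permutation of whole individuals can exceed F_ST = 1... but any
        # permutation preserving group sizes keeps two fixed groups mixed,
        # so only the identity-like splits reach it; verify via enumeration
        gm = make_gm(
            [["A/A"], ["A/A"], ["G/G"], ["G/G"]],
            pops=["P1", "P1", "P2", "P2"],
        )
        res = cp.amova_codominant(gm)
        assert res.f_st == pytest.approx(1.0)
        from itertools import permutations

        data = _AmovaData(gm)
        hits = 0
        total = 0
        for perm in set(permutations([0, 0, 1, 1])):
            total += 1
            if data.fst(np.array(perm)) >= res.f_st - 1e-12:
                hits += 1
        # 2 of the 6 distinct label arrangements reproduce the fixation split
        assert (hits, total) == (2, 6)
        p = cp.permute_fst(gm, res, n_perm=999, seed=0)
        assert p == pytest.approx(2 / 6, abs=0.06)
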