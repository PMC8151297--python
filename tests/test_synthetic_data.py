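import numpy as np
import pytest
from scipy import stats as sps

import capspop as cp
from capspop.synthetic_data import SimulationError


class TestConfig:
    def test_fst_range_checked(self):
        with pytest.raises(SimulationError):
            cp.SimulationConfig(seed=1, target_fst=1.0)

    def test_sizes_checked(self):
        with pytest.raises(SimulationError):
            cp.SimulationConfig(seed=1, population_sizes=(16, 1))

    def test_default_dimensions(self, default_cfg):
        assert default_cfg.n_individuals == 41
        assert default_cfg.n_loci == 70


class TestSimulateAlleleFrequencies:
    def test_zero_fst_shares_ancestral(self):
        cfg = cp.SimulationConfig(seed=4, target_fst=0.0, monomorphic_fraction=0.0)
        freqs = cp.simulate_allele_frequencies(cfg)
        for k in range(cfg.n_populations):
            assert np.array_equal(freqs.pop_freqs[k], freqs.ancestral)

    def test_balding_nichols_moments(self):
        # p=0.5, F=0.2 -> Beta(2, 2): mean 0.5, variance p(1-p)F = 0.05
        cfg = cp.SimulationConfig(
            seed=5, n_populations=2, population_sizes=(2, 2), n_admixed=0,
            n_loci=5000, monomorphic_fraction=0.0, target_fst=0.2,
            ancestral_freq_range=(0.5, 0.5),
        )
        draws = cp.simulate_allele_frequencies(cfg).pop_freqs.ravel()
        n = draws.size
        se_mean = np.sqrt(0.05 / n)
        assert draws.mean() == pytest.approx(0.5, abs=3 * se_mean)
        # var of Beta(2,2) = 0.05; se of sample variance ~ sqrt(2/n)*var
        assert draws.var() == pytest.approx(0.05, abs=3 * np.sqrt(2 / n) * 0.05)

    def test_monomorphic_count(self, default_freqs):
        assert int(default_freqs.monomorphic.sum()) == 6
        assert np.all(default_freqs.pop_freqs[:, default_freqs.monomorphic] == 1.0)

    def test_ref_alt_differ(self, default_freqs):
        assert all(r != a for r, a in zip(default_freqs.ref_alleles, default_freqs.alt_alleles))


class TestSimulateGenotypes:
    def test_full_homozygote_excess(self):
        cfg = cp.SimulationConfig(seed=6, f_excess=1.0)
        gm = cp.simulate_genotypes(cfg, cp.simulate_allele_frequencies(cfg))
        assert not any(c.is_heterozygous for row in gm.calls for c in row)

    def test_hwe_when_no_excess(self):
        """Chi-square HWE check: nearly all loci non-significant at alpha=0.01."""
        cfg = cp.SimulationConfig(
            seed=7, n_populations=1, population_sizes=(300,), n_admixed=0,
            n_loci=100, monomorphic_fraction=0.0, target_fst=0.0, f_excess=0.0,
        )
        gm = cp.simulate_genotypes(cfg, cp.simulate_allele_frequencies(cfg))
        non_sig = 0
        tested = 0
        for marker in gm.marker_ids:
            calls = [c for c in gm.marker_column(marker) if not c.is_missing]
            spec = cp.allele_frequencies(gm, marker)
            if len(spec.frequencies) < 2:
                continue
            p = max(spec.frequencies.values())
            q = 1 - p
            n = len(calls)
            n_het = sum(c.is_heterozygous for c in calls)
            exp = np.array([p * p, 2 * p * q, q * q]) * n
            hom_major = sum(
                not c.is_heterozygous and spec.frequencies[c.allele_1] == p for c in calls
            )
            obs = np.array([hom_major, n_het, n - n_het - hom_major])
            chi2 = ((obs - exp) ** 2 / np.maximum(exp, 1e-9)).sum()
            tested += 1
            if chi2 < sps.chi2.ppf(0.99, df=1):
                non_sig += 1
        assert tested > 80
        assert non_sig / tested >= 0.95

    def test_determinism(self, default_cfg, default_freqs):
        gm1 = cp.simulate_genotypes(default_cfg, default_freqs)
        gm2 = cp.simulate_genotypes(default_cfg, default_freqs)
        assert gm1.calls == gm2.calls
        assert gm1.population_labels == gm2.population_labels

    def test_population_labels_attached(self, synthetic_gm, default_cfg):
        labels = synthetic_gm.population_labels
        assert labels.count("POP1") == default_cfg.population_sizes[0]
        assert labels.count("Admix") == default_cfg.n_admixed


class TestSimulateCapsPanel:
    def test_all_markers_differential(self, default_cfg, default_freqs, enzymes):
        amps, defs = cp.simulate_caps_panel(default_cfg, default_freqs)
        for amp, d in zip(amps, defs):
            a = cp.assess_caps_marker(amp, enzymes[d.enzyme_name])
            assert a.differential

    def test_amplicon_lengths_within_bounds(self, default_cfg, default_freqs):
        amps, _ = cp.simulate_caps_panel(default_cfg, default_freqs)
        lo, hi = default_cfg.amplicon_length_range
        assert all(lo <= len(a.sequence) <= hi for a in amps)

    def test_end_to_end_digestion_round_trip(
        self, default_cfg, default_freqs, synthetic_gm, enzymes
    ):
        """Genotypes -> fragment patterns -> re-called genotypes, exactly."""
        amps, defs = cp.simulate_caps_panel(default_cfg, default_freqs)
        assessments = {
            d.marker_id: cp.assess_caps_marker(amp, enzymes[d.enzyme_name])
            for amp, d in zip(amps, defs)
        }
        for i, acc in enumerate(synthetic_gm.accession_ids):
            for j, marker in enumerate(synthetic_gm.marker_ids):
                truth = synthetic_gm.calls[i][j]
                if truth.is_missing:
                    continue
                a = assessments[marker]
                if truth.alleles == (a.ref_allele, a.ref_allele):
                    observed = a.ref_pattern
                elif truth.alleles == (a.alt_allele, a.alt_allele):
                    observed = a.alt_pattern
                else:
                    observed = cp.FragmentPattern(sorted(a.het_band_set))
                called = cp.call_genotype_from_fragments(observed, a)
                assert called.call == truth, (acc, marker)

    def test_fasta_round_trip(self, tmp_path, default_cfg, default_freqs):
        from capspop.caps_insilico import read_amplicon_fasta
        from capspop.synthetic_data import write_amplicon_fasta

        amps, defs = cp.simulate_caps_panel(default_cfg, default_freqs)
        path = tmp_path / "amps.fasta"
        write_amplicon_fasta(amps, path)
        back = read_amplicon_fasta(path, {d.marker_id: d for d in defs})
        assert [a.sequence for a in back] == [a.sequence for a in amps]
        assert [a.snp_offset for a in back] == [a.snp_offset for a in amps]


class TestParametricFst:
    def test_identical_frequencies_zero(self):
        cfg = cp.SimulationConfig(seed=12, target_fst=0.0, monomorphic_fraction=0.0)
        freqs = cp.simulate_allele_frequencies(cfg)
        from capspop.synthetic_data import parametric_fst

        assert parametric_fst(freqs) == pytest.approx(0.0, abs=1e-12)

    def test_expectation_matches_nominal_target(self):
        # many loci: realized theta concentrates on the Balding-Nichols F
        from capspop.synthetic_data import parametric_fst

        cfg = cp.SimulationConfig(
            seed=13, n_populations=2, population_sizes=(2, 2), n_admixed=0,
            n_loci=20_000, monomorphic_fraction=0.0, target_fst=0.2,
        )
        freqs = cp.simulate_allele_frequencies(cfg)
        assert parametric_fst(freqs) == pytest.approx(0.2, abs=0.01)


class TestEmpiricalFst:
    @pytest.mark.parametrize("target", [0.05, 0.15, 0.3])
    def test_amova_fst_matches_target_on_large_simulation(self, target):
        # single replicates carry ~0.02-0.03 of locus-sampling noise at
        # L=200, so calibration is asserted on the mean of 5 seeded runs
        ests = []
        for rep in range(5):
            cfg = cp.SimulationConfig(
                seed=int(target * 1000) + rep, n_populations=2,
                population_sizes=(300, 300), n_admixed=0, n_loci=200,
                monomorphic_fraction=0.0, target_fst=target, f_excess=0.0,
            )
            gm = cp.simulate_genotypes(cfg, cp.simulate_allele_frequencies(cfg))
            ests.append(cp.amova_codominant(gm).f_st)
        assert np.mean(ests) == pytest.approx(target, abs=0.02)
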