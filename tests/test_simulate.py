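import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dnmlineage import SimConfig, emit_fixtures, inject_dnms, simulate_reads
from dnmlineage.simulate import (CONTROL_SPECTRUM, FD_SPECTRUM,
                                 TIMING_MISMATCH, TIMING_PGC,
                                 draw_substitution, simulate_inherited_variants,
                                 simulate_study)
from dnmlineage.pedigree import build_pedigree
from dnmlineage.vcfio import read_vcf


class TestSimConfig:
    def test_defaults_are_study_conditions(self):
        cfg = SimConfig()
        assert cfg.lambda_one_fd == pytest.approx(87.6)
        assert cfg.lambda_both_fd == pytest.approx(211.0)
        assert cfg.p_mismatch == pytest.approx(268 / 575)
        assert cfg.depth_mean == 30.0
        assert cfg.spectrum_fd["G:C>A:T"] == pytest.approx(0.354)
        assert cfg.spectrum_control["G:C>A:T"] == pytest.approx(0.53)

    def test_group_selects_f2_mean(self):
        assert SimConfig(group="C").lambda_f2 == pytest.approx(211.0)
        assert SimConfig(group="B").lambda_f2 == pytest.approx(87.6)

    @pytest.mark.parametrize("kwargs", [
        {"p_mismatch": 1.5},
        {"depth_mean": 0},
        {"lambda_one_fd": -1},
        {"spectrum_fd": {"G:C>A:T": 1.0}},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)

    def test_spectra_sum_to_one(self):
        assert sum(CONTROL_SPECTRUM.values()) == pytest.approx(1.0)
        assert sum(FD_SPECTRUM.values()) == pytest.approx(1.0)


class TestInjectDnms:
    def test_zero_rate_gives_empty(self, desk_genome, rng):
        truth = inject_dnms("s", 0.0, 0.5, dict(CONTROL_SPECTRUM),
                            desk_genome, rng)
        assert truth.empty

    def test_all_mismatch_when_p_is_one(self, desk_genome, rng):
        truth = inject_dnms("s", 50, 1.0, dict(CONTROL_SPECTRUM),
                            desk_genome, rng)
        assert (truth["timing"] == TIMING_MISMATCH).all()
        assert (truth["true_vaf"] == 0.25).all()

    def test_timing_labels_encode_true_vaf(self, desk_genome, rng):
        truth = inject_dnms("s", 300, 0.4, dict(FD_SPECTRUM),
                            desk_genome, rng)
        pgc = truth["timing"] == TIMING_PGC
        assert (truth.loc[pgc, "true_vaf"] == 0.5).all()
        assert (truth.loc[~pgc, "true_vaf"] == 0.25).all()

    def test_count_mean_and_variance_poisson(self, desk_genome, rng):
        # over R=1000 replicate samples, mean and variance both ~ lambda
        lam = 87.6
        counts = np.array([
            len(inject_dnms("s", lam, 0.5, dict(FD_SPECTRUM),
                            desk_genome, rng))
            for _ in range(1000)])
        se_mean = np.sqrt(lam / 1000)
        assert abs(counts.mean() - lam) < 3 * se_mean
        # SE of a Poisson variance estimate: sqrt((mu4 - sigma^4)/R),
        # mu4 = lam(1 + 3 lam)
        se_var = np.sqrt((lam * (1 + 3 * lam) - lam ** 2) / 1000)
        assert abs(counts.var(ddof=1) - lam) < 3 * se_var

    def test_mismatch_fraction_matches_p(self, desk_genome, rng):
        p = 268 / 575
        truth = inject_dnms("s", 5000, p, dict(FD_SPECTRUM),
                            desk_genome, rng)
        frac = (truth["timing"] == TIMING_MISMATCH).mean()
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / len(truth))

    def test_error_when_genome_exhausted(self, rng):
        from dnmlineage.genome import GenomeModel
        tiny = GenomeModel(chromosomes=[("chr1", 20)])
        with pytest.raises((ValueError, RuntimeError)):
            inject_dnms("s", 500, 0.5, dict(CONTROL_SPECTRUM), tiny, rng)


class TestSimulateReads:
    def test_zero_vaf_never_yields_alt(self, rng):
        depth, alt = simulate_reads(0.0, 30, rng, size=5000)
        assert (alt == 0).all()
        assert (depth >= 1).all()

    def test_mean_vaf_unbiased_at_half(self, rng):
        depth, alt = simulate_reads(0.5, 30, rng, size=10_000)
        assert abs((alt / depth).mean() - 0.5) < 0.01

    def test_vaf_distribution_matches_binomial(self, rng):
        # chi-square of alt counts at fixed depth 30 vs Binomial(30, 0.5)
        n = 10_000
        alt = rng.binomial(30, 0.5, size=n)
        observed = np.bincount(alt, minlength=31)
        expected = sps.binom.pmf(np.arange(31), 30, 0.5) * n
        keep = expected >= 5
        obs = np.append(observed[keep], observed[~keep].sum())
        exp = np.append(expected[keep], expected[~keep].sum())
        stat = ((obs - exp) ** 2 / exp).sum()
        assert sps.chi2.sf(stat, len(exp) - 1) > 0.01

    def test_tail_beyond_threshold_matches_exact_binomial(self, rng):
        # P(observed VAF >= 0.30 at depth exactly 30, true VAF 0.25)
        alt = rng.binomial(30, 0.25, size=40_000)
        frac = (alt / 30 >= 0.30).mean()
        exact = sps.binom.sf(8, 30, 0.25)  # P(X >= 9)
        assert abs(frac - exact) < 3 * np.sqrt(exact * (1 - exact) / 40_000)

    def test_invalid_vaf_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_reads(1.5, 30, rng)


class TestDrawSubstitution:
    def test_ref_alt_pairs_are_snvs(self, rng):
        refs, alts = draw_substitution(dict(FD_SPECTRUM), rng, 500)
        assert set(refs) <= set("ACGT") and set(alts) <= set("ACGT")
        assert all(r != a for r, a in zip(refs, alts))


class TestInheritedVariants:
    def test_no_founder_sites_gives_empty(self, desk_genome, rng):
        cfg = SimConfig(n_founder_het=0, n_shared_ancestral_snvs=0,
                        n_sibships=1, n_f2_per_sibship=2, n_controls=0)
        ped = build_pedigree(1, 2)
        table = simulate_inherited_variants(ped, cfg, rng)
        assert table.empty

    def test_transmission_frequency_near_half(self, rng):
        # mate -> F2 transmissions: 50 sites x 200 embryos = 10,000 draws
        ped = build_pedigree(1, 200)
        cfg = SimConfig(n_sibships=1, n_f2_per_sibship=200, n_controls=0,
                        n_founder_het=50, n_shared_ancestral_snvs=0)
        table = simulate_inherited_variants(ped, cfg, rng)
        mate = "B1_F1_mate"
        mate_sites = set(map(tuple, table[table["sample_id"] == mate]
                             [["chrom", "pos"]].itertuples(index=False)))
        f2_ids = {s.sample_id for s in ped.generation("F2")}
        carriers = table[table["sample_id"].isin(f2_ids)]
        hits = sum(k in mate_sites for k in
                   carriers[["chrom", "pos"]].itertuples(index=False, name=None))
        rate = hits / (len(mate_sites) * len(f2_ids))
        assert abs(rate - 0.5) < 3 * np.sqrt(0.25 / 10_000)

    def test_ancestral_sites_in_every_sample(self, small_study):
        anc = small_study.inherited.query("origin == 'ancestral'")
        n_samples = len(small_study.pedigree)
        per_site = anc.groupby(["chrom", "pos"])["sample_id"].nunique()
        assert (per_site == n_samples).all()
        assert len(per_site) == small_study.config.n_shared_ancestral_snvs


class TestStudyAndFixtures:
    def test_observation_matrix_covers_all_samples(self, small_study):
        n_sites = small_study.calls[["chrom", "pos"]].drop_duplicates().shape[0]
        counts = small_study.calls.groupby("sample_id").size()
        assert (counts == n_sites).all()

    def test_fixture_round_trip_preserves_records(self, small_study, tmp_path):
        paths = emit_fixtures(small_study, tmp_path / "fx")
        back = read_vcf(paths["vcf"])
        orig = small_study.calls
        merged = orig.merge(back, on=["sample_id", "chrom", "pos", "ref",
                                      "alt"], suffixes=("", "_rt"))
        assert len(merged) == len(orig) == len(back)
        assert (merged["total_depth"] == merged["total_depth_rt"]).all()
        assert (merged["alt_depth"] == merged["alt_depth_rt"]).all()
        assert np.allclose(merged["qual"], merged["qual_rt"], atol=0.01)
        assert np.allclose(merged["mq_alt"], merged["mq_alt_rt"], atol=0.01)

    def test_fixtures_byte_identical_for_same_seed(self, small_config,
                                                   tmp_path):
        digests = []
        for sub in ("a", "b"):
            result = simulate_study(small_config)
            paths = emit_fixtures(result, tmp_path / sub)
            digests.append({k: p.read_bytes() for k, p in paths.items()})
        assert digests[0] == digests[1]

    def test_vcf_coordinates_one_based_bed_zero_based(self, tmp_path,
                                                      toy_genome):
        # cross-format oracle on a 3-variant fixture: a variant at pos p
        # must appear in the VCF at p and overlap BED interval [p-1, p)
        from dnmlineage.vcfio import write_vcf
        from conftest import make_calls
        calls = make_calls([{"pos": 1}, {"pos": 500}, {"pos": 100_000}])
        path = tmp_path / "three.vcf"
        write_vcf(calls, toy_genome, path)
        text = path.read_text()
        for pos in (1, 500, 100_000):
            assert f"chr1\t{pos}\t" in text
        back = read_vcf(path)
        assert sorted(back["pos"]) == [1, 500, 100_000]

    def test_empty_call_set_valid_vcf(self, tmp_path, toy_genome):
        from dnmlineage.vcfio import write_vcf, empty_calls
        path = tmp_path / "empty.vcf"
        write_vcf(empty_calls(), toy_genome, path)
        back = read_vcf(path)
        assert back.empty
        assert path.read_text().startswith("##fileformat=VCF")
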