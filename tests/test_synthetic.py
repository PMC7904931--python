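import numpy as np
import pytest

from lipospec.dipole import compute_rex
from lipospec.io_formats import Compound, LipidSystem
from lipospec.lifetime import DecayModel, convolve_model
from lipospec.synthetic import (
    SpectrumShapeConfig,
    StudyDesign,
    SynthTruth,
    generate_decay,
    generate_excitation_pair,
    generate_polarized_set,
    generate_study,
)


class TestSynthTruth:
    def test_needs_at_least_one_truth_field(self):
        with pytest.raises(ValueError):
            SynthTruth(seed=1)

    def test_taus_must_increase(self):
        with pytest.raises(ValueError):
            SynthTruth(seed=1, truth_taus_ns=(7.0, 3.0))


class TestShapeConfig:
    def test_blank_fraction_capped_at_0p7_percent(self):
        with pytest.raises(ValueError, match="0.7"):
            SpectrumShapeConfig(blank_frac=0.01)


class TestExcitationPair:
    @pytest.mark.parametrize("truth_rex", [1.0, 2.03, 2.20, 3.05])
    def test_zero_noise_ratio_exact(self, truth_rex):
        lab, blank, truth = generate_excitation_pair(
            truth_rex, SpectrumShapeConfig(noise_cv=0.0), seed=3
        )
        assert compute_rex(lab, blank) == pytest.approx(truth_rex, abs=1e-12)
        assert truth.truth_rex == truth_rex

    def test_blank_stays_below_limit(self):
        for seed in range(20):
            lab, blank, _ = generate_excitation_pair(2.2, seed=seed)
            assert blank.intensity.max() <= 0.0072 * lab.intensity.max()

    def test_non_positive_ratio_rejected(self):
        with pytest.raises(ValueError):
            generate_excitation_pair(-1.0, seed=0)

    def test_monte_carlo_mean_recovery(self):
        """Noisy ratios are unbiased: mean over 1000 seeds within 3 SE."""
        cfg = SpectrumShapeConfig(noise_cv=0.01)
        vals = []
        for seed in range(1000):
            lab, blank, _ = generate_excitation_pair(2.5, cfg, seed=seed)
            vals.append(compute_rex(lab, blank))
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 2.5) < 3 * se


class TestPolarizedSet:
    def test_isotropic_equal_components(self):
        pset, _ = generate_polarized_set(0.0, 1.0, scale=500.0, noise_cv=0.0, seed=1)
        np.testing.assert_allclose(pset.I_VV, 500.0)
        np.testing.assert_allclose(pset.I_VH, 500.0)

    def test_component_relations_hold(self):
        pset, _ = generate_polarized_set(0.3, 1.4, scale=1000.0, noise_cv=0.0, seed=1)
        np.testing.assert_allclose(pset.I_VV, 1000.0 * 1.6)
        np.testing.assert_allclose(pset.I_VH, 1000.0 * 0.7 / 1.4)
        np.testing.assert_allclose(pset.I_HV / pset.I_HH, 1.4)

    def test_out_of_range_r_rejected(self):
        with pytest.raises(ValueError):
            generate_polarized_set(1.5, 1.0, seed=0)

    def test_monte_carlo_mean_recovery(self):
        from lipospec.anisotropy import sample_anisotropy

        vals = []
        for seed in range(500):
            pset, _ = generate_polarized_set(0.3, 1.2, noise_cv=0.005, seed=seed)
            vals.append(sample_anisotropy(pset)[0])
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 0.3) < 3 * se


class TestDecayGeneration:
    def test_delta_like_irf_gives_pure_exponential(self):
        h, _ = generate_decay(
            [1.0], [5.0], irf_fwhm_ns=1e-4, n_channels=600, seed=0, poisson=False
        )
        counts = h.counts.astype(float)
        peak = int(np.argmax(counts))
        t = np.arange(len(counts)) * h.channel_width_ns
        tail = slice(peak + 5, peak + 400)
        expected = counts[peak + 5] * np.exp(-(t[tail] - t[peak + 5]) / 5.0)
        np.testing.assert_allclose(counts[tail], expected, rtol=5e-3, atol=1.0)

    def test_expected_total_counts_match_analytic_integral(self):
        """Total expected counts equal scale*sum(alpha_i tau_i)/dt (the
        analytic integral of the scaled model) on a long fine record."""
        alphas, taus = (0.4, 0.6), (2.0, 6.0)
        dt = 0.01
        n = 20000
        h, _ = generate_decay(
            alphas,
            taus,
            irf_fwhm_ns=0.05,
            n_channels=n,
            channel_width_ns=dt,
            target_peak_counts=15000,
            seed=1,
            poisson=False,
        )
        model = DecayModel(alphas=alphas, taus_ns=taus)
        curve = convolve_model(model, h.irf_counts, dt, n)
        scale = 15000 / curve.max()
        analytic = scale * sum(a * t for a, t in zip(alphas, taus)) / dt
        assert h.counts.sum() == pytest.approx(analytic, rel=1e-3)

    def test_poisson_variance_to_mean_near_unity(self):
        """Replicated channel counts obey var/mean ~ 1."""
        reps = [
            generate_decay([0.5, 0.5], [3.0, 7.0], n_channels=1024, seed=s)[0].counts
            for s in range(60)
        ]
        arr = np.asarray(reps, dtype=float)
        mean = arr.mean(axis=0)
        mask = mean > 100
        ratio = (arr.var(axis=0, ddof=1)[mask] / mean[mask]).mean()
        assert ratio == pytest.approx(1.0, abs=0.1)

    def test_short_record_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            generate_decay([1.0], [7.0], n_channels=100, seed=0)

    def test_peak_band_enforced(self):
        with pytest.raises(ValueError, match="band"):
            generate_decay([1.0], [3.0], n_channels=512, target_peak_counts=500, seed=0)

    def test_invalid_simplex_rejected(self):
        with pytest.raises(ValueError, match="simplex"):
            generate_decay([0.7, 0.7], [3.0, 7.0], n_channels=1024, seed=0)


class TestStudyConfig:
    def test_yaml_round_trip_of_design_knobs(self, tmp_path):
        cfg = tmp_path / "design.yaml"
        cfg.write_text(
            "lipid_systems: [popc, popc_chol]\n"
            "compounds: [control, phloretin]\n"
            "n_replicates: 2\n"
            "control_rex: {popc: 2.03, popc_chol: 3.05}\n"
            "delta_psi_mV:\n"
            "  phloretin: {popc: -103, popc_chol: -327}\n"
            "G_factor: 1.1\n"
            "include_decays: false\n"
        )
        design = StudyDesign.from_yaml(cfg)
        assert design.lipid_systems == (LipidSystem.POPC, LipidSystem.POPC_CHOL)
        assert design.n_replicates == 2
        assert design.truth_rex(LipidSystem.POPC, Compound.PHLORETIN) == pytest.approx(
            2.03 - 103 / 365
        )
        assert design.G_factor == 1.1
        assert not design.include_decays


class TestStudy:
    def test_default_design_enumerates_all_conditions(self, default_study):
        manifest, truth = default_study
        rex_truth = truth[truth["quantity"] == "rex"]
        assert len(rex_truth) == 3 * 8 * 3
        assert set(rex_truth["lipid_system"]) == {s.name for s in LipidSystem}
        assert set(rex_truth["compound"]) == {c.name for c in Compound}

    def test_same_design_and_seed_byte_identical(self, tmp_path):
        design = StudyDesign(
            compounds=(Compound.CONTROL, Compound.G8),
            lipid_systems=(LipidSystem.POPC,),
            n_replicates=2,
            include_decays=True,
        )
        generate_study(design, seed=99, out_dir=tmp_path / "a")
        generate_study(design, seed=99, out_dir=tmp_path / "b")
        files_a = sorted(p.name for p in (tmp_path / "a").iterdir())
        files_b = sorted(p.name for p in (tmp_path / "b").iterdir())
        assert files_a == files_b
        for name in files_a:
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_truth_table_recovered_within_3_sd(self, default_study):
        """Joining pipeline output to the truth table recovers every R_ex
        condition mean within 3 SDs of the replicate scatter."""
        from lipospec import pipeline

        manifest, truth = default_study
        per_sample = pipeline.rex_per_sample(manifest)
        rex_truth = truth[truth["quantity"] == "rex"].drop_duplicates(
            subset=["lipid_system", "compound"]
        )
        merged = per_sample.merge(
            rex_truth[["lipid_system", "compound", "truth"]],
            on=["lipid_system", "compound"],
        )
        cv = 0.007  # generator default reading noise
        for (_, _), g in merged.groupby(["lipid_system", "compound"]):
            truth_val = g["truth"].iloc[0]
            sd_noise = np.sqrt(2.0) * cv * truth_val
            assert abs(g["rex"].mean() - truth_val) < 3 * sd_noise
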