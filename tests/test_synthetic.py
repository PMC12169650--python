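"""The synthetic generators: builder inverses, ensembles, probes, hills,
titrations and decays."""

import numpy as np
import pytest

from dnaadapt.conformation import pseudorotation
from dnaadapt.metad import HillsRecord
from dnaadapt.rigidbase import (PairParameters, StepParameters,
                                duplex_parameters)
from dnaadapt.synthetic import (APT_SEQUENCE, CanonicalFormSpec,
                                DoubleWellPotential, DuplexSpec,
                                EnsembleSpec, FlatPotential, ProbeAtomSpec,
                                SugarSpec, build_duplex, build_probe_complex,
                                generate_decay, generate_hills,
                                generate_titration, sample_ensemble)


class TestBuilder:
    def test_canonical_b_is_extractor_fixed_point(self, bform_duplex):
        """Ideal B parameters are recovered exactly after building."""
        pp, sp, _ = duplex_parameters(bform_duplex)
        sp_arr = np.array([s.as_array() for s in sp])
        assert np.abs(sp_arr - [0, 0, 3.38, 0, 0, 36.0]).max() < 1e-6
        assert np.abs(np.array([p.as_array() for p in pp])).max() < 1e-6

    def test_a_form_spec_roundtrip(self):
        a = CanonicalFormSpec.a_form()
        dup = build_duplex("GCGCGCGCGCGC", a.pair, a.step, a.sugar)
        _, sp, _ = duplex_parameters(dup)
        assert sp[5].twist == pytest.approx(32.7, abs=1e-6)
        assert sp[5].rise == pytest.approx(2.56, abs=1e-6)
        assert sp[5].slide == pytest.approx(-1.5, abs=1e-6)
        P, _ = pseudorotation(dup.strand_watson[5])
        assert P == pytest.approx(18.0, abs=5.0)

    def test_parameter_length_mismatch(self):
        with pytest.raises(ValueError, match="11 step"):
            build_duplex(APT_SEQUENCE,
                         step_params=[CanonicalFormSpec.b_form().step] * 5)
        with pytest.raises(ValueError, match="12 pair"):
            build_duplex(APT_SEQUENCE,
                         pair_params=[PairParameters.zero()] * 5)

    def test_bad_sequence_rejected(self):
        with pytest.raises(ValueError, match="A,C,G,T"):
            build_duplex("GCXT")

    def test_impossible_sugar_rejected(self):
        with pytest.raises(ValueError, match="ring closure"):
            build_duplex("GCAT", sugar_specs=SugarSpec(18.0, 170.0, -100.0))


class TestEnsembles:
    def test_reproducible_under_seed(self):
        spec = EnsembleSpec(n_frames=3, seed=42, step_sds={"twist": 3.0})
        a = sample_ensemble(DuplexSpec(), spec)
        b = sample_ensemble(DuplexSpec(), spec)
        assert np.array_equal(a.coordinates, b.coordinates)

    def test_zero_sd_gives_identical_frames(self):
        ens = sample_ensemble(DuplexSpec(), EnsembleSpec(n_frames=3, seed=1))
        assert np.abs(ens.coordinates - ens.coordinates[0]).max() == 0.0

    @pytest.mark.parametrize("rho", [0.0, -0.5])
    def test_adjacent_twist_correlation_recovered(self, rho):
        """Sample Pearson between adjacent step twists matches the target
        within +-0.05 at n=2000 (pooled over the 11 steps)."""
        ens = sample_ensemble(DuplexSpec(), EnsembleSpec(
            n_frames=2000, seed=7, step_sds={"twist": 3.0}, rho_twist=rho))
        tw = ens.step_parameter_draws[:, :, 5]
        x = (tw[:, :-1] - tw[:, :-1].mean(axis=0)).ravel()
        y = (tw[:, 1:] - tw[:, 1:].mean(axis=0)).ravel()
        r = float(x @ y / np.sqrt((x @ x) * (y @ y)))
        assert r == pytest.approx(rho, abs=0.05)

    def test_sample_means_converge_to_spec(self):
        """Per-parameter sample means sit within 3 SE of the spec means."""
        sds = {"twist": 3.0, "roll": 2.0, "rise": 0.2}
        ens = sample_ensemble(DuplexSpec(), EnsembleSpec(
            n_frames=2000, seed=8, step_sds=sds))
        draws = ens.step_parameter_draws
        n = draws.shape[0]
        for k, (name, mean) in enumerate(zip(
                ("shift", "slide", "rise", "tilt", "roll", "twist"),
                (0.0, 0.0, 3.38, 0.0, 0.0, 36.0))):
            sd = sds.get(name, 0.0)
            got = draws[:, :, k].mean()
            assert abs(got - mean) <= max(3.0 * sd / np.sqrt(n), 1e-9), name

    def test_non_positive_definite_covariance_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            sample_ensemble(DuplexSpec(), EnsembleSpec(
                n_frames=2, seed=1, step_sds={"twist": 3.0}, rho_twist=0.9))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError, match="SDs"):
            EnsembleSpec(step_sds={"twist": -1.0})
        with pytest.raises(ValueError, match="rho"):
            EnsembleSpec(rho_twist=1.0)


class TestProbes:
    def test_single_probe_exact_distance(self, bform_duplex):
        cx = build_probe_complex(bform_duplex, [
            ProbeAtomSpec("NE1", "TRP", 109, ("A", 6, "C1'"), 4.0)])
        ne1 = cx.chains["P"][0].atom("NE1").position
        c1 = bform_duplex.strand_watson[5].atom("C1'").position
        assert np.linalg.norm(ne1 - c1) == pytest.approx(4.0, abs=1e-9)

    def test_infeasible_distance(self, bform_duplex):
        with pytest.raises(ValueError, match="infeasible"):
            build_probe_complex(bform_duplex, [
                ProbeAtomSpec("NE1", "TRP", 109, ("A", 6, "C1'"), -1.0)])

    def test_unknown_target(self, bform_duplex):
        with pytest.raises(ValueError, match="not found"):
            build_probe_complex(bform_duplex, [
                ProbeAtomSpec("NE1", "TRP", 109, ("A", 99, "C1'"), 4.0)])


class TestHills:
    def test_zero_duration_empty(self):
        assert generate_hills(FlatPotential(), duration_ns=0.0) == []

    def test_records_carry_deposit_parameters(self):
        hills = generate_hills(FlatPotential(), duration_ns=0.1, seed=1)
        assert len(hills) == 25   # 100 ps / 4 ps stride
        assert all(isinstance(h, HillsRecord) for h in hills)
        assert all(h.sigma == 0.04 and h.height == 0.1 for h in hills)
        assert np.allclose(np.diff([h.time for h in hills]), 4.0)
        lo, hi = np.radians(10.0), np.radians(60.0)
        assert all(lo <= h.center <= hi for h in hills)

    def test_reproducible_under_seed(self):
        a = generate_hills(DoubleWellPotential(), duration_ns=0.5, seed=9)
        b = generate_hills(DoubleWellPotential(), duration_ns=0.5, seed=9)
        assert [(h.time, h.center) for h in a] == [(h.time, h.center) for h in b]

    def test_invalid_parameters(self):
        with pytest.raises(ValueError, match="sigma"):
            generate_hills(FlatPotential(), sigma=0.0, duration_ns=0.1)


class TestTitration:
    def test_half_saturation_at_K(self):
        series = generate_titration(1000.0, 1.38, 100.0, 20.0,
                                    np.array([1000.0]), 0.0)
        assert series.F_obs[0] == pytest.approx(60.0)   # theta = 0.5 exactly

    def test_saturation_limit(self):
        series = generate_titration(1000.0, 2.0, 100.0, 20.0,
                                    np.array([1e9]), 0.0)
        assert series.F_obs[0] == pytest.approx(20.0, abs=1e-3)

    def test_noise_reproducible(self):
        c = np.geomspace(10.0, 1e5, 8)
        a = generate_titration(1000.0, 1.0, 1.2, 0.2, c, 0.02, seed=3)
        b = generate_titration(1000.0, 1.0, 1.2, 0.2, c, 0.02, seed=3)
        assert np.array_equal(a.F_obs, b.F_obs)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            generate_titration(-1.0, 1.0, 1.0, 0.0, np.array([1.0]))
        with pytest.raises(ValueError):
            generate_titration(1.0, 1.0, 1.0, 0.0, np.array([-1.0]))


class TestDecay:
    def test_delta_irf_channel_ratio(self):
        """With a delta-like IRF the noiseless histogram decays as
        exp(-dt/tau) per channel."""
        hist = generate_decay([1.0], [2.0], irf_fwhm_ns=1e-6, dt_ns=0.1,
                              n_channels=256, poisson_noise=False)
        tail = hist.counts[50:150]
        ratios = tail[1:] / tail[:-1]
        assert np.allclose(ratios, np.exp(-0.1 / 2.0), atol=1e-9)

    def test_zero_counts_all_zero(self):
        hist = generate_decay([1.0], [2.0], total_counts=0.0)
        assert np.all(hist.counts == 0)

    def test_poisson_reproducible(self):
        a = generate_decay([0.7, 0.3], [1.0, 4.0], seed=5, n_channels=128)
        b = generate_decay([0.7, 0.3], [1.0, 4.0], seed=5, n_channels=128)
        assert np.array_equal(a.counts, b.counts)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError, match="lifetimes"):
            generate_decay([1.0], [-2.0])
        with pytest.raises(ValueError, match="amplitudes"):
            generate_decay([0.0], [2.0])
        with pytest.raises(ValueError, match="dt"):
            generate_decay([1.0], [2.0], dt_ns=0.0)
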