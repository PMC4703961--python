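"""Generator: IRF shape, photon statistics, scenes and study designs."""

import numpy as np
import pytest

from omiflim import synthetic as syn
from omiflim.segmentation import morphology_metrics
from omiflim.types import DecayParams


class TestMakeIrf:
    @pytest.mark.parametrize("fwhm", [130.0, 260.0, 520.0])
    def test_measured_fwhm_within_one_bin(self, fwhm):
        irf = syn.make_irf(fwhm_ps=fwhm)
        assert abs(irf.measured_fwhm_ps() - fwhm) <= irf.bin_width_ps

    def test_normalized_to_unit_sum(self):
        irf = syn.make_irf(fwhm_ps=333.0, bin_width_ps=30.0, n_bins=128)
        assert abs(irf.samples.sum() - 1.0) <= 1e-9

    def test_delta_like_limit(self):
        # FWHM of one bin width: nearly all mass within three bins
        irf = syn.make_irf(fwhm_ps=48.8)
        order = np.sort(irf.samples)[::-1]
        assert order[:3].sum() >= 0.99

    @pytest.mark.parametrize(
        "kwargs", [dict(fwhm_ps=-1), dict(bin_width_ps=0),
                   dict(n_bins=8), dict(center_fraction=1.5)])
    def test_invalid_parameters_raise(self, kwargs):
        with pytest.raises(ValueError):
            syn.make_irf(**kwargs)


class TestSimulateDecay:
    def test_mean_arrival_matches_first_moment(self, nadh_params):
        # long window so wrap-around is negligible; the analytic photon
        # arrival mean of I(t) = a1 exp(-t/t1) + a2 exp(-t/t2) is
        # (a1 t1^2 + a2 t2^2) / (a1 t1 + a2 t2) = 1.9053 ns here.  The
        # empirical centroid subtracts the IRF centroid; half a bin is added
        # back because discrete convolution of two center-sampled signals
        # reads out half a bin early on the bin-center axis.
        p = nadh_params
        irf = syn.make_irf(n_bins=1024, center_fraction=0.05)
        sim = syn.simulate_decay(p, irf, photon_budget=1e6, seed=11)
        dt = irf.bin_width_ps * 1e-3
        t = (np.arange(irf.n_bins) + 0.5) * dt
        m = float(t @ sim.counts) / sim.counts.sum() \
            - irf.centroid_ps * 1e-3 + dt / 2.0
        oracle = (p.alpha1 * p.tau1**2 + p.alpha2 * p.tau2**2) / (
            p.alpha1 * p.tau1 + p.alpha2 * p.tau2)
        assert abs(oracle - 1.9053) < 1e-3  # frozen closed form
        assert abs(m - oracle) / oracle <= 0.02

    def test_photon_conservation(self, irf, nadh_params):
        sim = syn.simulate_decay(nadh_params, irf, photon_budget=1e6, seed=3)
        assert abs(sim.counts.sum() - 1e6) <= 4.0 * np.sqrt(1e6)

    def test_poisson_dispersion(self, irf, nadh_params):
        # variance/mean per bin over replicates consistent with Poisson
        reps = np.stack([
            syn.simulate_decay(nadh_params, irf, 2000.0, seed=s).counts
            for s in range(1000)
        ])
        mean = reps.mean(axis=0)
        ratio = reps.var(axis=0)[mean >= 5] / mean[mean >= 5]
        assert 0.9 <= ratio.mean() <= 1.1

    def test_wraparound_tail_in_prerise_bins(self, irf):
        # a 3 ns monoexponential in a 12.5 ns window leaves a previous-pulse
        # tail in the pre-rise bins; its photon fraction is the geometric
        # continuation exp(-T/tau) of the decay
        tau, budget = 3.0, 1e6
        p = DecayParams.make(1.0, tau, tau)
        sim = syn.simulate_decay(p, irf, budget, seed=7)
        dt = irf.bin_width_ps * 1e-3
        period = irf.n_bins * dt
        sigma = irf.fwhm_ps / 2.3548 * 1e-3
        cut_ns = irf.centroid_ps * 1e-3 - 4 * sigma
        cut = int(cut_ns / dt)
        assert cut >= 10
        observed = sim.counts[:cut].sum()
        # analytic tail mass in the pre-rise window: a photon seen at
        # position p < cut arrived s = p + T - c after its (previous)
        # excitation, so the window holds the geometric continuation of the
        # decay over s in [T - c, T - c + cut); the one-wrap density is
        # exp(-s/tau) (1 + exp(-T/tau)) normalized over [0, T)
        c_ns = irf.centroid_ps * 1e-3
        a = np.exp(-period / tau)
        e1 = np.exp(-(period - c_ns) / tau)
        e2 = np.exp(-(period - c_ns + cut_ns) / tau)
        frac = (e1 - e2) / (1.0 - a)
        expected = budget * frac
        assert expected > 50
        assert abs(observed - expected) <= 0.1 * expected

    def test_ill_conditioned_lifetime_flagged(self, irf):
        p = DecayParams.make(0.5, 0.4, 70.0)
        with pytest.warns(UserWarning, match="ill-conditioned"):
            sim = syn.simulate_decay(p, irf, 1e4, seed=0)
        assert sim.ill_conditioned

    def test_invalid_budget_raises(self, irf, nadh_params):
        with pytest.raises(ValueError):
            syn.simulate_decay(nadh_params, irf, photon_budget=0.0)


class TestScenes:
    def test_labels_match_cell_count(self, irf):
        scene = syn.random_scene(12, seed=21, image_shape=(128, 128))
        render = syn.render_scene(scene, irf, seed=22)
        assert render.truth_labels.n_cells == 12
        nuc = np.unique(render.truth_labels.nucleus_labels)
        assert (nuc > 0).sum() == 12

    def test_forced_redox_ratio(self, irf):
        scene = syn.random_scene(6, seed=5, image_shape=(96, 96))
        for c in scene.cells:
            c.nadh_rate, c.fad_rate = 1.0, 0.5
        render = syn.render_scene(scene, irf, seed=6)
        assert np.allclose(render.truth_cells["redox_ratio"], 2.0)
        # empirical per-cell ratio from the photon cubes
        for k in render.truth_labels.labels:
            sel = render.truth_labels.cytoplasm_labels == k
            ratio = (render.nadh.counts.sum(axis=2)[sel].mean()
                     / render.fad.counts.sum(axis=2)[sel].mean())
            assert abs(ratio - 2.0) <= 0.1

    def test_default_mean_photons_per_pixel(self, irf):
        # acquisition scale: 5e5 counts/s * 60 s over 256^2 pixels = 457.8
        scene = syn.random_scene(8, seed=9, image_shape=(96, 96))
        render = syn.render_scene(scene, irf, seed=10)
        mean = render.nadh.counts.sum(axis=2).mean()
        assert abs(mean - 457.8) / 457.8 <= 0.10

    def test_nuclei_dimmer_than_cytoplasm(self, irf):
        scene = syn.random_scene(5, seed=13, image_shape=(96, 96))
        render = syn.render_scene(scene, irf, seed=14)
        intensity = render.nadh.counts.sum(axis=2)
        nuc = intensity[render.truth_labels.nucleus_labels > 0].mean()
        cyto = intensity[render.truth_labels.cytoplasm_labels > 0].mean()
        assert nuc < 0.6 * cyto

    def test_overlapping_cells_rejected(self):
        cell = dict(cell_radius=10.0, nucleus_axes=(8.0, 6.0),
                    nucleus_angle=0.0,
                    nadh_params=DecayParams.make(0.75, 0.4, 2.6),
                    fad_params=DecayParams.make(0.6, 0.3, 2.8),
                    nadh_rate=1.0, fad_rate=0.5)
        cells = [syn.CellSpec(center=(30.0, 30.0), **cell),
                 syn.CellSpec(center=(35.0, 30.0), **cell)]
        with pytest.raises(ValueError, match="overlap"):
            syn.SceneSpec(image_shape=(64, 64), cells=cells)

    def test_ground_truth_roundtrip(self, irf):
        # morphology recomputed from the truth maps equals the truth table
        scene = syn.random_scene(7, seed=31, image_shape=(96, 96))
        render = syn.render_scene(scene, irf, seed=32)
        again, n = morphology_metrics(render.truth_labels)
        assert n == 7
        merged = render.truth_cells.merge(again, on="cell_id",
                                          suffixes=("", "_re"))
        for col in ("cell_area_um2", "nucleus_diameter_um", "ncr"):
            assert np.array_equal(merged[col].to_numpy(),
                                  merged[f"{col}_re"].to_numpy())


class TestExperimentDesign:
    def test_null_design_calls_all_none(self):
        design = syn.ExperimentDesign(samples=("S1",),
                                      preparations=("fresh", "flash_frozen"),
                                      seed=1)
        tables = syn.generate_experiment(design)
        assert set(tables.truth_calls["call"]) == {"none"}

    def test_omi_decreasing_effect_called_decrease(self):
        key = ("S1", "flash_frozen", "drug_A", 72)
        design = syn.ExperimentDesign(samples=("S1",), seed=1,
                                      effects={key: (-1.0, -1.0, 1.0)})
        calls = syn.generate_experiment(design).truth_calls
        row = calls[(calls["treatment"] == "drug_A")
                    & (calls["timepoint_hr"] == 72)
                    & (calls["preparation"] == "flash_frozen")]
        assert (row["call"] == "decrease").all()

    def test_seed_reproducibility_byte_identical(self):
        design = syn.ExperimentDesign(samples=("S1",), seed=42)
        a = syn.generate_experiment(design).cells.to_csv(index=False)
        b = syn.generate_experiment(design).cells.to_csv(index=False)
        assert a == b

    def test_missing_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            syn.ExperimentDesign(treatments=("drug_A", "drug_B"))

    def test_records_internally_consistent(self):
        tables = syn.generate_experiment(
            syn.ExperimentDesign(samples=("S1",), seed=2))
        c = tables.cells
        assert np.allclose(
            c["nadh_tau_m"],
            c["nadh_alpha1"] * c["nadh_tau1"]
            + (1 - c["nadh_alpha1"]) * c["nadh_tau2"])
        assert (c["nadh_tau1"] <= c["nadh_tau2"] + 1e-12).all()
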