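"""Synthetic phantom generator: forward models, determinism, cohort statistics."""

import numpy as np
import pytest

from promai import (
    AffineTransform9,
    CohortSpec,
    CorePlan,
    LesionSpec,
    PhantomSpec,
    generate_cohort_specs,
    generate_phantom,
    sample_biopsy_cores,
    simulate_dce_curve,
    simulate_dwi_signal,
)
from promai.phantom import B_VALUES_DEFAULT
from promai.tofts import BiexponentialAif


class TestForwardModels:
    def test_dwi_signal_at_b0_is_s0(self):
        assert simulate_dwi_signal(100.0, 1.0e-3, 0.0) == pytest.approx(100.0)

    def test_dwi_signal_closed_form(self):
        assert simulate_dwi_signal(100.0, 1.0e-3, 800.0) == pytest.approx(
            100.0 * np.exp(-0.8)
        )
        assert simulate_dwi_signal(100.0, 1.0e-3, 800.0) == pytest.approx(
            44.9329, abs=1e-4
        )

    def test_seven_b_value_protocol(self):
        sig = simulate_dwi_signal(100.0, 1.2e-3, B_VALUES_DEFAULT)
        assert sig.shape == (7,)
        assert np.all(np.diff(sig) < 0)  # strictly decreasing for adc > 0
        np.testing.assert_array_equal(
            B_VALUES_DEFAULT, [0, 50, 100, 150, 200, 250, 800]
        )

    def test_dwi_rejects_negative_inputs(self):
        with pytest.raises(ValueError):
            simulate_dwi_signal(-1.0, 1e-3, 0.0)
        with pytest.raises(ValueError):
            simulate_dwi_signal(1.0, -1e-3, 0.0)

    def test_zero_ktrans_gives_zero_concentration(self):
        t = np.arange(30) * 9.9
        ct = simulate_dce_curve(0.0, 0.4, BiexponentialAif(), t)
        np.testing.assert_array_equal(ct, 0.0)

    def test_step_aif_matches_closed_form(self):
        """Quadrature oracle: Ct = Ve c (1 - exp(-kep t)) for a step AIF."""

        class StepAif:
            onset_s = 0.0

            def __call__(self, t):
                return np.full_like(np.asarray(t, dtype=float), 2.0)

        kt, ve = 0.3, 0.4
        t = np.arange(40) * 9.9
        ct = simulate_dce_curve(kt, ve, StepAif(), t)
        closed = ve * 2.0 * (1.0 - np.exp(-(kt / ve) * t / 60.0))
        np.testing.assert_allclose(ct, closed, atol=1e-6)

    def test_dce_rejects_bad_parameters(self):
        t = np.arange(10) * 9.9
        with pytest.raises(ValueError):
            simulate_dce_curve(0.1, 0.0, BiexponentialAif(), t)
        with pytest.raises(ValueError):
            simulate_dce_curve(0.1, 0.4, BiexponentialAif(), t[::-1])


class TestGeneratePhantom:
    def test_bitwise_determinism(self):
        spec = PhantomSpec(seed=21, lesions=[LesionSpec((28, 22, 18), (5, 5, 5), 7)])
        s1, t1 = generate_phantom(spec)
        s2, t2 = generate_phantom(spec)
        np.testing.assert_array_equal(s1.t2w.data, s2.t2w.data)
        for a, b in zip(s1.dwi + s1.dce, s2.dwi + s2.dce):
            np.testing.assert_array_equal(a.data, b.data)
        np.testing.assert_array_equal(t1.labels, t2.labels)

    def test_noiseless_dwi_is_exactly_monoexponential(self, lesion_spec,
                                                      lesion_phantom):
        """Every voxel's decay constant is one of the tissue-table ADCs."""
        study, _ = lesion_phantom
        b = study.b_values[-1]
        s0 = study.dwi[0].data
        adc_vox = -np.log(study.dwi[-1].data / s0) / b
        table_adcs = sorted(p.adc for p in lesion_spec.tissue_table.values())
        dist = np.min(
            np.abs(adc_vox[..., None] - np.asarray(table_adcs)), axis=-1
        )
        assert dist.max() < 1e-12

    def test_lesion_volume_matches_rasterization(self):
        # semi-axes chosen for a 0.8 cm^3 ellipsoid: abc = 3*800/(4 pi)
        r = (3.0 * 800.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
        spec = PhantomSpec(seed=3, lesions=[LesionSpec((25, 22, 18), (r, r, r), 7)])
        _, truth = generate_phantom(spec)
        vox_vol = abs(np.linalg.det(truth.affine[:3, :3]))
        lesion_ml = (truth.labels == 7).sum() * vox_vol / 1000.0
        assert lesion_ml == pytest.approx(0.8, abs=vox_vol * 40 / 1000.0)

    def test_lesion_outside_prostate_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(lesions=[LesionSpec((45.0, 22.0, 18.0), (6, 6, 6), 7)])

    def test_grade_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            LesionSpec((25, 22, 18), (5, 5, 5), 5)

    def test_misregistration_shifts_secondary_anatomy(self):
        base = PhantomSpec(seed=4, noise_sigma_dwi=0.0)
        moved = PhantomSpec(
            seed=4, noise_sigma_dwi=0.0,
            misregistration=AffineTransform9(translation=[4.4, 0.0, 0.0]),
        )
        a, _ = generate_phantom(base)
        b, _ = generate_phantom(moved)
        # anatomy moved by +4.4 mm = 2 DWI voxels along x
        np.testing.assert_allclose(
            b.dwi[0].data[2:], a.dwi[0].data[:-2], atol=1e-9
        )


class TestBiopsyCores:
    def test_core_inside_lesion_reads_its_grade(self, lesion_spec, lesion_phantom):
        _, truth = lesion_phantom
        cores = sample_biopsy_cores(
            truth, lesion_spec, CorePlan(n_cores=16, n_targeted=2), seed=5
        )
        targeted = cores[-2:]
        assert any(c.gleason == 8 for c in targeted)

    def test_core_through_benign_tissue_is_negative(self, lesion_spec,
                                                    lesion_phantom):
        _, truth = lesion_phantom
        spec_nolesion = PhantomSpec(seed=7)
        _, truth0 = generate_phantom(spec_nolesion)
        cores = sample_biopsy_cores(
            truth0, spec_nolesion, CorePlan(n_cores=20, n_targeted=0), seed=6
        )
        assert all(c.gleason == 0 for c in cores)

    def test_short_effective_length_misses_distal_lesion(self):
        """A lesion only in the distal 20% of the throw is missed at 0.7."""
        from promai.phantom import GroundTruth, _core_gleason

        labels = np.ones((40, 40, 12), dtype=int)
        labels[:, 30:, :] = 8  # lesion occupies y >= 30 mm (spacing 1 mm)
        truth = GroundTruth(labels=labels, affine=np.eye(4), true_maps={},
                            misregistration=None)
        entry = np.array([20.0, 13.4, 6.0])
        tip = np.array([20.0, 33.4, 6.0])  # distal 20% inside the lesion
        assert _core_gleason(truth, entry, tip, fraction=1.0) == 8
        assert _core_gleason(truth, entry, tip, fraction=0.7) == 0

    def test_core_count_bounds_enforced(self):
        with pytest.raises(ValueError):
            CorePlan(n_cores=10)
        with pytest.raises(ValueError):
            CorePlan(n_cores=40)

    def test_determinism(self, lesion_spec, lesion_phantom):
        _, truth = lesion_phantom
        a = sample_biopsy_cores(truth, lesion_spec, CorePlan(), seed=9)
        b = sample_biopsy_cores(truth, lesion_spec, CorePlan(), seed=9)
        assert [(c.entry_mm, c.tip_mm, c.gleason, c.effective_fraction) for c in a] \
            == [(c.entry_mm, c.tip_mm, c.gleason, c.effective_fraction) for c in b]


class TestCohort:
    def test_prevalence_over_many_patients(self):
        """Empirical prevalence within +-5 points of the configured 46.7%."""
        cohort = CohortSpec(n_patients=1000)
        specs = generate_cohort_specs(cohort, seed=1234)
        frac = np.mean([bool(spec.lesions) for _, spec, _ in specs])
        assert abs(frac - 0.467) < 0.05

    def test_core_counts_within_protocol_range(self):
        specs = generate_cohort_specs(CohortSpec(n_patients=60), seed=8)
        counts = [plan.n_cores for _, _, plan in specs]
        assert min(counts) >= 16 and max(counts) <= 36
        assert abs(np.mean(counts) - 24) < 2.5

    def test_patient_specs_are_seeded_and_stable(self):
        a = generate_cohort_specs(CohortSpec(n_patients=5), seed=77)
        b = generate_cohort_specs(CohortSpec(n_patients=5), seed=77)
        for (pa, sa, la), (pb, sb, lb) in zip(a, b):
            assert pa == pb and sa.seed == sb.seed and la.n_cores == lb.n_cores
            assert [l.gleason for l in sa.lesions] == [l.gleason for l in sb.lesions]
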