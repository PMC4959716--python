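"""Core profiles, the dual-threshold rule, lesion detection, patient scoring."""

import itertools

import numpy as np
import pytest

from promai.core_eval import (
    BiopsyCore,
    CoreProfile,
    PatientCategory,
    PredictedLesion,
    classify_core,
    cores_from_dataframe,
    cores_to_dataframe,
    detect_lesions,
    extract_core_profile,
    score_patient,
)
from promai.volume import VolumeImage, affine_from_geometry


def _mai_volume(data, spacing=(1.0, 1.0, 1.0)):
    return VolumeImage(data, affine_from_geometry(spacing), modality="MAI")


def _core(entry, tip, cid="c0", gleason=0, frac=1.0):
    return BiopsyCore("p0", cid, tuple(entry), tuple(tip),
                      effective_fraction=frac, gleason=gleason)


class TestExtractProfile:
    def test_constant_region_gives_constant_profile(self):
        vol = _mai_volume(np.full((20, 20, 10), 0.3))
        prof = extract_core_profile(vol, _core((5, 3, 5), (5, 16, 5)))
        assert prof.max_mai == pytest.approx(0.3)
        assert prof.mean_mai == pytest.approx(0.3)
        assert prof.histogram.sum() == prof.samples.size

    def test_half_high_half_low_mean(self):
        data = np.zeros((40, 40, 10))
        data[:, 20:, :] = 0.8  # sharp boundary at y = 19.5 mm
        vol = _mai_volume(data)
        prof = extract_core_profile(vol, _core((20, 9.5, 5), (20, 29.5, 5)),
                                    radius_mm=0.0)
        assert prof.max_mai == pytest.approx(0.8)
        assert prof.mean_mai == pytest.approx(0.4, abs=0.05)

    def test_max_never_below_mean(self):
        rng = np.random.default_rng(0)
        vol = _mai_volume(rng.uniform(0, 1, size=(15, 15, 8)))
        for k in range(10):
            a = rng.uniform(2, 12, size=3)
            b = rng.uniform(2, 12, size=3)
            if np.allclose(a, b):
                continue
            prof = extract_core_profile(vol, _core(a, b, cid=f"c{k}"))
            assert prof.max_mai >= prof.mean_mai - 1e-12

    def test_effective_fraction_truncates_sampling(self):
        data = np.zeros((40, 40, 10))
        data[:, 30:, :] = 1.0
        vol = _mai_volume(data)
        full = extract_core_profile(vol, _core((20, 13.4, 5), (20, 33.4, 5)))
        short = extract_core_profile(
            vol, _core((20, 13.4, 5), (20, 33.4, 5), frac=0.7)
        )
        assert full.max_mai > 0.9
        assert short.max_mai < 0.1  # the distal high region is never reached

    def test_core_outside_volume_rejected(self):
        vol = _mai_volume(np.zeros((10, 10, 5)))
        with pytest.raises(ValueError):
            extract_core_profile(vol, _core((50, 50, 50), (60, 60, 60)))


class TestClassifyCore:
    def _prof(self, mx, mean):
        return CoreProfile("c", np.array([mean]), np.zeros(20), mx, mean)

    @pytest.mark.parametrize(
        "mx,mean,t_mean,expected",
        [
            (0.59, 0.55, 0.2, False),   # max gate fails
            (0.90, 0.19, 0.2, False),   # mean gate fails
            (0.90, 0.25, 0.2, True),    # both gates pass
            (0.60, 0.20, 0.2, True),    # ties count as passing
        ],
    )
    def test_dual_threshold_rule(self, mx, mean, t_mean, expected):
        assert classify_core(self._prof(mx, mean), 0.6, t_mean) is expected

    def test_raising_mean_threshold_never_creates_positives(self):
        rng = np.random.default_rng(1)
        profs = [self._prof(mx, mean * mx)
                 for mx, mean in rng.uniform(0, 1, size=(50, 2))]
        for t1, t2 in [(0.15, 0.2), (0.2, 0.3), (0.3, 0.4)]:
            for p in profs:
                if not classify_core(p, 0.6, t1):
                    assert not classify_core(p, 0.6, t2)

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            classify_core(self._prof(0.5, 0.5), 1.5, 0.2)


class TestDetectLesions:
    def test_empty_map_gives_no_lesions(self):
        vol = _mai_volume(np.zeros((10, 10, 10)))
        assert detect_lesions(vol) == []

    def test_blob_volume_arithmetic(self):
        # 600 voxels at MAI 0.9 with voxel volume 1.68 mm^3 -> 1.008 ml
        data = np.zeros((20, 20, 20))
        data.flat[:0] = 0
        blob = np.zeros((20, 20, 20), dtype=bool)
        blob[2:12, 2:12, 2:8] = True  # 10*10*6 = 600 voxels
        data[blob] = 0.9
        vol = _mai_volume(data, spacing=(0.8, 0.7, 3.0))
        lesions = detect_lesions(vol)
        assert len(lesions) == 1
        assert lesions[0].voxel_count == 600
        assert lesions[0].volume_ml == pytest.approx(1.008)
        assert lesions[0].mean_mai == pytest.approx(0.9)

    def test_small_blob_excluded_by_volume_filter(self):
        data = np.zeros((20, 20, 20))
        data[5:10, 5:10, 5:10] = 0.9  # 125 voxels * 1.68 mm^3 = 0.21 ml
        vol = _mai_volume(data, spacing=(0.8, 0.7, 3.0))
        assert detect_lesions(vol, min_volume_ml=0.5) == []
        assert len(detect_lesions(vol, min_volume_ml=0.2)) == 1

    def test_diagonal_voxels_merge_under_26_connectivity(self):
        data = np.zeros((12, 12, 12))
        data[2:6, 2:6, 2:6] = 0.9
        data[6, 6, 6] = 0.9  # touches the block only diagonally
        vol = _mai_volume(data, spacing=(2.0, 2.0, 2.0))
        lesions = detect_lesions(vol, min_volume_ml=0.0)
        assert len(lesions) == 1
        assert lesions[0].voxel_count == 4**3 + 1


def _lesion(lid):
    return PredictedLesion(
        lesion_id=lid, voxel_count=100, volume_ml=1.0, mean_mai=0.8,
        max_mai=0.9, centroid_mm=(0, 0, 0), component_voxels=np.zeros((1, 3), int),
    )


class TestScorePatient:
    """Exhaustive truth table over the lesion/core evidence combinations."""

    CASES = [
        # (n_lesions, lesion->cores map, core pathologies, core preds, expected)
        (1, {"c0": [1]}, {"c0": 7}, {"c0": True}, "TP"),
        (1, {"c0": [1]}, {"c0": 7}, {"c0": False}, "FP"),
        (1, {"c0": [1]}, {"c0": 0}, {"c0": True}, "FP"),
        (1, {"c0": [1]}, {"c0": 0}, {"c0": False}, "FP"),
        (1, {"c0": []}, {"c0": 0}, {"c0": False}, "TN"),   # lesion unsampled
        (1, {"c0": []}, {"c0": 8}, {"c0": False}, "FN"),   # unsampled + path+
        (0, {"c0": []}, {"c0": 0}, {"c0": False}, "TN"),
        (0, {"c0": []}, {"c0": 6}, {"c0": True}, "FN"),
        (2, {"c0": [1], "c1": [2]}, {"c0": 7, "c1": 0},
         {"c0": True, "c1": True}, "TP"),
        (2, {"c0": [1], "c1": []}, {"c0": 0, "c1": 9},
         {"c0": False, "c1": False}, "FP"),
        (2, {"c0": [], "c1": []}, {"c0": 0, "c1": 0},
         {"c0": False, "c1": False}, "TN"),
        (1, {"c0": [1], "c1": [1]}, {"c0": 0, "c1": 8},
         {"c0": True, "c1": True}, "TP"),
    ]

    @pytest.mark.parametrize("n_lesions,cmap,paths,preds,expected", CASES)
    def test_rule_table(self, n_lesions, cmap, paths, preds, expected):
        lesions = [_lesion(i + 1) for i in range(n_lesions)]
        cores = [
            _core((0, 0, 0), (0, 17, 0), cid=cid, gleason=g)
            for cid, g in paths.items()
        ]
        score = score_patient("p0", lesions, cores, preds, core_lesion_map=cmap)
        assert score.category == PatientCategory(expected)

    def test_total_function_over_random_evidence(self):
        """Every generated evidence combination maps to exactly one category."""
        rng = np.random.default_rng(2)
        for _ in range(200):
            n_les = int(rng.integers(0, 3))
            lesions = [_lesion(i + 1) for i in range(n_les)]
            n_cores = int(rng.integers(1, 5))
            cores, cmap, preds = [], {}, {}
            for k in range(n_cores):
                cid = f"c{k}"
                g = int(rng.choice([0, 0, 6, 7, 8]))
                cores.append(_core((0, 0, 0), (0, 17, 0), cid=cid, gleason=g))
                cmap[cid] = [
                    lid for lid in range(1, n_les + 1) if rng.random() < 0.4
                ]
                preds[cid] = bool(rng.random() < 0.5)
            score = score_patient("p0", lesions, cores, preds, core_lesion_map=cmap)
            assert score.category in PatientCategory

    def test_unknown_lesion_reference_rejected(self):
        with pytest.raises(ValueError):
            score_patient(
                "p0", [_lesion(1)],
                [_core((0, 0, 0), (0, 17, 0), cid="c0", gleason=7)],
                {"c0": True}, core_lesion_map={"c0": [99]},
            )


class TestCoreCsv:
    def test_round_trip(self):
        cores = [
            _core((1, 2, 3), (1, 19, 3), cid="a", gleason=7, frac=0.85),
            _core((4, 5, 6), (4, 22, 6), cid="b", gleason=0, frac=0.5),
        ]
        back = cores_from_dataframe(cores_to_dataframe(cores))
        assert back == cores

    def test_missing_columns_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            cores_from_dataframe(pd.DataFrame({"patient_id": ["p"]}))
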