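"""Biopsy-core evaluation against malignancy-index maps.

Cores are 3D needle segments with recorded entry/tip positions (mm,
patient frame).  Each core's malignancy-index (MAI) profile is sampled
along its effective segment; a core is called positive when both the
profile maximum and mean clear their thresholds (defaults 0.6 and 0.2).
Predicted lesions are connected components of supra-threshold voxels;
patients are scored TP/TN/FP/FN from the lesion/core evidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy.ndimage import label as cc_label
from scipy.ndimage import map_coordinates

from .volume import VolumeImage

__all__ = [
    "BiopsyCore",
    "CoreProfile",
    "PredictedLesion",
    "PatientCategory",
    "PatientScore",
    "extract_core_profile",
    "classify_core",
    "detect_lesions",
    "score_patient",
    "cores_to_dataframe",
    "cores_from_dataframe",
]

PROFILE_BIN_EDGES = np.round(np.arange(0.0, 1.0001, 0.05), 10)


@dataclass(frozen=True)
class BiopsyCore:
    """One biopsy core: a needle segment with its pathology result.

    ``gleason`` is 0 for a cancer-negative core, otherwise the Gleason
    grade (6-10).  ``effective_fraction`` is the fraction of the nominal
    needle throw that actually retrieved tissue, measured from the entry.
    """

    patient_id: str
    core_id: str
    entry_mm: tuple[float, float, float]
    tip_mm: tuple[float, float, float]
    effective_fraction: float = 1.0
    gleason: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.effective_fraction <= 1:
            raise ValueError(
                f"effective_fraction must be in (0,1], got {self.effective_fraction}"
            )
        if self.gleason != 0 and self.gleason not in (6, 7, 8, 9, 10):
            raise ValueError(f"gleason must be 0 or 6..10, got {self.gleason}")
        if np.allclose(self.entry_mm, self.tip_mm):
            raise ValueError("core entry and tip coincide")

    @property
    def pathology_positive(self) -> bool:
        return self.gleason >= 6

    def effective_segment(self) -> tuple[np.ndarray, np.ndarray]:
        """Entry and effective tip (nominal throw truncated from the entry)."""
        a = np.asarray(self.entry_mm, dtype=float)
        b = np.asarray(self.tip_mm, dtype=float)
        return a, a + self.effective_fraction * (b - a)


@dataclass
class CoreProfile:
    """MAI samples along one core with its summary features."""

    core_id: str
    samples: np.ndarray
    histogram: np.ndarray
    max_mai: float
    mean_mai: float

    def __post_init__(self) -> None:
        if self.max_mai < self.mean_mai - 1e-12:
            raise ValueError("profile max must be >= mean")


def _radial_offsets(direction: np.ndarray, radius_mm: float) -> np.ndarray:
    """Four unit offsets perpendicular to the core direction, scaled."""
    d = direction / np.linalg.norm(direction)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, d)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(d, ref)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return radius_mm * np.stack([u, -u, v, -v])


def extract_core_profile(
    mai: VolumeImage,
    core: BiopsyCore,
    step_mm: float = 0.5,
    radius_mm: float = 1.0,
) -> CoreProfile:
    """Sample the MAI map along a core's effective segment.

    Sample points sit every ``step_mm`` along the effective segment; at
    each point the MAI is trilinearly interpolated and averaged over the
    axial point plus four radial offsets at ``radius_mm`` (set
    ``radius_mm=0`` for pure line sampling).  Points outside the volume
    are dropped; raises if none remain.
    """
    a, b = core.effective_segment()
    length = float(np.linalg.norm(b - a))
    n = max(int(np.floor(length / step_mm)) + 1, 2)
    ts = np.linspace(0.0, 1.0, n)
    pts = a[np.newaxis, :] + ts[:, np.newaxis] * (b - a)[np.newaxis, :]
    if radius_mm > 0:
        offs = _radial_offsets(b - a, radius_mm)
        stacks = [pts] + [pts + o for o in offs]
    else:
        stacks = [pts]
    all_pts = np.concatenate(stacks, axis=0)
    vox = mai.world_to_voxel(all_pts)
    vals = map_coordinates(mai.data, vox.T, order=1, mode="constant", cval=np.nan)
    vals = vals.reshape(len(stacks), n)
    # average over the radial bundle per axial position, ignoring
    # out-of-volume offsets; axial positions fully outside are dropped
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        samples = np.nanmean(vals, axis=0)
    samples = samples[np.isfinite(samples)]
    if samples.size == 0:
        raise ValueError(f"core {core.core_id}: no in-volume samples")
    hist, _ = np.histogram(np.clip(samples, 0.0, 1.0), bins=PROFILE_BIN_EDGES)
    return CoreProfile(
        core_id=core.core_id,
        samples=samples,
        histogram=hist,
        max_mai=float(np.max(samples)),
        mean_mai=float(np.mean(samples)),
    )


def classify_core(
    profile: CoreProfile,
    max_threshold: float = 0.6,
    mean_threshold: float = 0.2,
) -> bool:
    """Dual-threshold rule: positive iff max >= t_max and mean >= t_mean.

    The max gate (default 0.6, the lowest biopsy-positive Gleason grade's
    index value) is held fixed; the mean gate is the swept threshold.
    Ties count as passing (>=).
    """
    for name, t in (("max_threshold", max_threshold), ("mean_threshold", mean_threshold)):
        if not 0 <= t <= 1:
            raise ValueError(f"{name} must be in [0,1], got {t}")
    return profile.max_mai >= max_threshold and profile.mean_mai >= mean_threshold


@dataclass
class PredictedLesion:
    lesion_id: int
    voxel_count: int
    volume_ml: float
    mean_mai: float
    max_mai: float
    centroid_mm: tuple[float, float, float]
    component_voxels: np.ndarray  # (N, 3) voxel indices

    def to_dict(self) -> dict:
        return {
            "lesion_id": self.lesion_id,
            "voxel_count": self.voxel_count,
            "volume_ml": self.volume_ml,
            "mean_mai": self.mean_mai,
            "max_mai": self.max_mai,
            "centroid_mm": list(self.centroid_mm),
        }


_CONN26 = np.ones((3, 3, 3), dtype=int)


def detect_lesions(
    mai: VolumeImage,
    mai_threshold: float = 0.6,
    min_volume_ml: float = 0.5,
    mean_mai_min: float = 0.6,
) -> list[PredictedLesion]:
    """Clinically relevant predicted lesions in a MAI map.

    26-connected components of voxels with MAI > ``mai_threshold``; a
    component qualifies iff its mean MAI exceeds ``mean_mai_min`` and its
    volume (voxel count x voxel volume) is at least ``min_volume_ml``.
    """
    if not 0 <= mai_threshold <= 1:
        raise ValueError("mai_threshold must be in [0,1]")
    labeled, n = cc_label(mai.data > mai_threshold, structure=_CONN26)
    vox_ml = mai.voxel_volume_mm3 / 1000.0
    lesions: list[PredictedLesion] = []
    for lid in range(1, n + 1):
        idx = np.argwhere(labeled == lid)
        vals = mai.data[tuple(idx.T)]
        volume_ml = idx.shape[0] * vox_ml
        if float(np.mean(vals)) > mean_mai_min and volume_ml >= min_volume_ml:
            centroid = mai.voxel_to_world(idx.mean(axis=0))
            lesions.append(
                PredictedLesion(
                    lesion_id=len(lesions) + 1,
                    voxel_count=int(idx.shape[0]),
                    volume_ml=float(volume_ml),
                    mean_mai=float(np.mean(vals)),
                    max_mai=float(np.max(vals)),
                    centroid_mm=tuple(np.asarray(centroid, dtype=float)),
                    component_voxels=idx,
                )
            )
    return lesions


class PatientCategory(str, Enum):
    TP = "TP"
    TN = "TN"
    FP = "FP"
    FN = "FN"


@dataclass
class PatientScore:
    patient_id: str
    category: PatientCategory
    evidence: dict = field(default_factory=dict)


def _core_samples_in_lesion(
    mai: VolumeImage, core: BiopsyCore, lesion: PredictedLesion, step_mm: float = 0.5
) -> bool:
    """A core belongs to a lesion if any sample point falls in its component."""
    a, b = core.effective_segment()
    length = float(np.linalg.norm(b - a))
    n = max(int(np.floor(length / step_mm)) + 1, 2)
    ts = np.linspace(0.0, 1.0, n)
    pts = a[np.newaxis, :] + ts[:, np.newaxis] * (b - a)[np.newaxis, :]
    vox = np.round(mai.world_to_voxel(pts)).astype(int)
    comp = {tuple(v) for v in lesion.component_voxels}
    return any(tuple(v) in comp for v in vox)


def score_patient(
    patient_id: str,
    lesions: list[PredictedLesion],
    cores: list[BiopsyCore],
    core_predictions: dict[str, bool],
    mai: VolumeImage | None = None,
    core_lesion_map: dict[str, list[int]] | None = None,
) -> PatientScore:
    """Patient-level TP/TN/FP/FN from lesion and core evidence.

    Lesion level: a predicted lesion is *confirmed* when at least one core
    taken from it is pathology-positive and index-positive; *disproved*
    when cores were taken but none is pathology-positive; *unsampled*
    lesions (no cores taken from them) are excluded from the analysis.

    Patient level, applied to the sampled lesions: at least one confirmed
    lesion -> TP; no lesions and no pathology-positive cores -> TN; no
    lesions but pathology-positive cores -> FN; everything else -> FP.

    Core-to-lesion attribution uses ``core_lesion_map`` (core_id -> lesion
    ids) when given, otherwise geometric membership of the core's sample
    points in the lesion's component (requires ``mai``).
    """
    if core_lesion_map is None:
        if mai is None and lesions:
            raise ValueError("need either core_lesion_map or the MAI map")
        core_lesion_map = {}
        for core in cores:
            ids = [
                les.lesion_id
                for les in lesions
                if _core_samples_in_lesion(mai, core, les)
            ]
            core_lesion_map[core.core_id] = ids
    known = {les.lesion_id for les in lesions}
    for cid, ids in core_lesion_map.items():
        unknown = set(ids) - known
        if unknown:
            raise ValueError(f"core {cid} references unknown lesion ids {unknown}")

    by_core = {c.core_id: c for c in cores}
    confirmed, disproved, unsampled = [], [], []
    for les in lesions:
        core_ids = [
            cid for cid, ids in core_lesion_map.items() if les.lesion_id in ids
        ]
        if not core_ids:
            unsampled.append(les.lesion_id)
            continue
        hits = [
            cid
            for cid in core_ids
            if by_core[cid].pathology_positive and core_predictions.get(cid, False)
        ]
        if hits:
            confirmed.append(les.lesion_id)
        else:
            disproved.append(les.lesion_id)

    pathology_positive_patient = any(c.pathology_positive for c in cores)
    sampled_lesions = bool(confirmed or disproved)
    if confirmed:
        cat = PatientCategory.TP
    elif not sampled_lesions and not pathology_positive_patient:
        cat = PatientCategory.TN
    elif not sampled_lesions and pathology_positive_patient:
        cat = PatientCategory.FN
    else:
        cat = PatientCategory.FP
    return PatientScore(
        patient_id=patient_id,
        category=cat,
        evidence={
            "confirmed_lesions": confirmed,
            "disproved_lesions": disproved,
            "unsampled_lesions": unsampled,
            "pathology_positive": pathology_positive_patient,
        },
    )


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

_CORE_COLUMNS = [
    "patient_id", "core_id",
    "entry_x_mm", "entry_y_mm", "entry_z_mm",
    "tip_x_mm", "tip_y_mm", "tip_z_mm",
    "effective_fraction", "gleason",
]


def cores_to_dataframe(cores: list[BiopsyCore]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": c.patient_id,
            "core_id": c.core_id,
            "entry_x_mm": c.entry_mm[0],
            "entry_y_mm": c.entry_mm[1],
            "entry_z_mm": c.entry_mm[2],
            "tip_x_mm": c.tip_mm[0],
            "tip_y_mm": c.tip_mm[1],
            "tip_z_mm": c.tip_mm[2],
            "effective_fraction": c.effective_fraction,
            "gleason": c.gleason,
        }
        for c in cores
    ]
    return pd.DataFrame(rows, columns=_CORE_COLUMNS)


def cores_from_dataframe(df: pd.DataFrame) -> list[BiopsyCore]:
    missing = set(_CORE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"core table is missing columns: {sorted(missing)}")
    return [
        BiopsyCore(
            patient_id=str(r.patient_id),
            core_id=str(r.core_id),
            entry_mm=(r.entry_x_mm, r.entry_y_mm, r.entry_z_mm),
            tip_mm=(r.tip_x_mm, r.tip_y_mm, r.tip_z_mm),
            effective_fraction=float(r.effective_fraction),
            gleason=int(r.gleason),
        )
        for r in df.itertuples(index=False)
    ]
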