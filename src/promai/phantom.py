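"""Seeded synthetic multiparametric prostate MRI studies with ground truth.

Each phantom is an ellipsoidal prostate with optional ellipsoidal lesions
of Gleason grade 6-10, rendered through the forward models every
downstream stage inverts: a mono-exponential diffusion decay for the DWI
series, the two-compartment Tofts model for the DCE series and a
per-class base intensity for T2W.  Grids, spacings, the seven-b-value
set, the 9.9 s DCE frame interval and the noise levels are all explicit
configuration; an optional misregistration transform displaces the DWI
and DCE world frames so registration can be tested on known truth.

The cohort generator emulates the evaluated study population: 45
patients, 46.7% cancer prevalence, 16-36 biopsy cores per patient
(average 24) and lesions of Gleason 6-9 with a grade-7 mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core_eval import BiopsyCore
from .tofts import BiexponentialAif, tofts_forward
from .transforms import AffineTransform9
from .volume import VolumeImage, affine_from_geometry

__all__ = [
    "TissueClassParams",
    "TISSUE_TABLE_DEFAULT",
    "LesionSpec",
    "PhantomSpec",
    "CorePlan",
    "GroundTruth",
    "MpMriStudy",
    "CohortSpec",
    "simulate_dwi_signal",
    "simulate_dce_curve",
    "generate_phantom",
    "sample_biopsy_cores",
    "generate_cohort_specs",
]

B_VALUES_DEFAULT = np.array([0.0, 50.0, 100.0, 150.0, 200.0, 250.0, 800.0])
LABEL_BACKGROUND = 0
LABEL_BENIGN = 1


@dataclass(frozen=True)
class TissueClassParams:
    """Forward-model parameters of one tissue class."""

    s0_dwi: float      # a.u., DWI signal at b = 0
    adc: float         # mm^2/s
    ktrans: float      # 1/min
    ve: float          # fraction in (0, 1]
    t2w: float         # a.u., T2W base intensity
    s0_dce: float      # a.u., DCE baseline signal

    def __post_init__(self) -> None:
        if not 0 < self.ve <= 1:
            raise ValueError(f"ve must be in (0,1], got {self.ve}")
        if self.adc < 0 or self.ktrans < 0 or self.s0_dwi < 0:
            raise ValueError("tissue parameters must be non-negative")


# One editable table drives every forward model.  Benign peripheral zone:
# high ADC, low Ktrans, bright T2W.  With grade, ADC falls, Ktrans rises
# and T2W darkens - the qualitative pattern malignancy scoring exploits.
TISSUE_TABLE_DEFAULT: dict[int, TissueClassParams] = {
    LABEL_BACKGROUND: TissueClassParams(30.0, 2.2e-3, 0.02, 0.20, 30.0, 80.0),
    LABEL_BENIGN: TissueClassParams(100.0, 1.6e-3, 0.05, 0.25, 100.0, 100.0),
    6: TissueClassParams(95.0, 1.25e-3, 0.12, 0.30, 72.0, 100.0),
    7: TissueClassParams(92.0, 1.05e-3, 0.20, 0.35, 62.0, 100.0),
    8: TissueClassParams(90.0, 0.90e-3, 0.30, 0.40, 54.0, 100.0),
    9: TissueClassParams(88.0, 0.78e-3, 0.42, 0.45, 47.0, 100.0),
    10: TissueClassParams(86.0, 0.68e-3, 0.55, 0.50, 42.0, 100.0),
}


@dataclass(frozen=True)
class LesionSpec:
    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    gleason: int

    def __post_init__(self) -> None:
        if self.gleason not in (6, 7, 8, 9, 10):
            raise ValueError(f"gleason grade must be 6..10, got {self.gleason}")
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ValueError("lesion semi-axes must be positive")

    @property
    def volume_ml(self) -> float:
        a, b, c = self.semi_axes_mm
        return 4.0 / 3.0 * np.pi * a * b * c / 1000.0


@dataclass
class PhantomSpec:
    """Full description of one synthetic patient study.

    Grid shapes and spacings default to a desk-scale field of view with
    the acquisition pixel sizes and slice thicknesses of the emulated
    protocol (T2W 0.8 x 0.7 x 3 mm, DWI 2.2 x 2.2 x 3 mm, DCE
    1.6 x 1.6 x 1.5 mm; DCE frames 9.9 s apart).
    """

    t2w_shape: tuple[int, int, int] = (64, 64, 12)
    t2w_spacing: tuple[float, float, float] = (0.8, 0.7, 3.0)
    dwi_shape: tuple[int, int, int] = (24, 24, 12)
    dwi_spacing: tuple[float, float, float] = (2.2, 2.2, 3.0)
    dce_shape: tuple[int, int, int] = (32, 32, 24)
    dce_spacing: tuple[float, float, float] = (1.6, 1.6, 1.5)
    prostate_center_mm: tuple[float, float, float] = (25.0, 22.0, 18.0)
    prostate_semi_axes_mm: tuple[float, float, float] = (17.0, 14.0, 12.0)
    lesions: list[LesionSpec] = field(default_factory=list)
    tissue_table: dict[int, TissueClassParams] = field(
        default_factory=lambda: dict(TISSUE_TABLE_DEFAULT)
    )
    b_values: np.ndarray = field(default_factory=lambda: B_VALUES_DEFAULT.copy())
    noise_sigma_t2w: float = 2.0
    noise_sigma_dwi: float = 1.0
    noise_sigma_dce: float = 1.0
    # smooth multiplicative heterogeneity riding on the anatomy; it gives
    # registration rotational signal and only modulates baselines, so the
    # ADC and Tofts parameters stay exactly recoverable
    texture_amplitude: float = 0.15
    texture_wavelength_mm: tuple[float, float, float] = (23.0, 19.0, 17.0)
    dce_frame_interval_s: float = 9.9
    dce_n_frames: int = 32
    dce_gain: float = 20.0  # a.u. per mM signal-concentration proportionality
    aif: BiexponentialAif = field(default_factory=BiexponentialAif)
    misregistration: AffineTransform9 | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("t2w_spacing", "dwi_spacing", "dce_spacing"):
            if any(s <= 0 for s in getattr(self, name)):
                raise ValueError(f"{name} must be positive")
        if self.dce_frame_interval_s <= 0 or self.dce_n_frames < 2:
            raise ValueError("need a positive frame interval and >= 2 DCE frames")
        c = np.asarray(self.prostate_center_mm)
        ax = np.asarray(self.prostate_semi_axes_mm)
        for les in self.lesions:
            lc = np.asarray(les.center_mm)
            la = np.asarray(les.semi_axes_mm)
            # all six axis-endpoints of the lesion must be inside the prostate
            for i in range(3):
                for sign in (-1.0, 1.0):
                    p = lc.copy()
                    p[i] += sign * la[i]
                    if np.sum(((p - c) / ax) ** 2) > 1.0:
                        raise ValueError(
                            f"lesion at {les.center_mm} extends outside the prostate"
                        )

    @property
    def prostate_volume_ml(self) -> float:
        a, b, c = self.prostate_semi_axes_mm
        return 4.0 / 3.0 * np.pi * a * b * c / 1000.0

    @property
    def dce_times_s(self) -> np.ndarray:
        return np.arange(self.dce_n_frames) * self.dce_frame_interval_s


@dataclass
class GroundTruth:
    """The simulation's truth on the T2W grid, for recovery tests."""

    labels: np.ndarray          # 0 background, 1 benign, g = lesion grade
    affine: np.ndarray          # T2W grid geometry
    true_maps: dict[str, np.ndarray]
    misregistration: AffineTransform9 | None


@dataclass
class MpMriStudy:
    """One patient's simulated acquisition."""

    patient_id: str
    t2w: VolumeImage
    dwi: list[VolumeImage]
    b_values: np.ndarray
    dce: list[VolumeImage]
    dce_times_s: np.ndarray
    aif: BiexponentialAif
    dce_gain: float


# ---------------------------------------------------------------------------
# Forward models
# ---------------------------------------------------------------------------

def simulate_dwi_signal(
    s0: float | np.ndarray, adc: float | np.ndarray, b: float | np.ndarray
) -> np.ndarray:
    """Mono-exponential DWI signal s0 * exp(-b * adc)."""
    s0 = np.asarray(s0, dtype=float)
    adc = np.asarray(adc, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(s0 < 0) or np.any(adc < 0) or np.any(b < 0):
        raise ValueError("s0, adc and b must all be >= 0")
    return s0 * np.exp(-b * adc)


def simulate_dce_curve(ktrans: float, ve: float, aif, times_s: np.ndarray) -> np.ndarray:
    """Tofts tissue-concentration curve (shared forward model)."""
    return tofts_forward(ktrans, ve, aif, times_s)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _labels_at_points(points_mm: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Tissue class at world points: lesion grade > benign > background."""
    c = np.asarray(spec.prostate_center_mm)
    ax = np.asarray(spec.prostate_semi_axes_mm)
    inside = np.sum(((points_mm - c) / ax) ** 2, axis=-1) <= 1.0
    labels = np.where(inside, LABEL_BENIGN, LABEL_BACKGROUND).astype(int)
    for les in spec.lesions:
        lc = np.asarray(les.center_mm)
        la = np.asarray(les.semi_axes_mm)
        in_les = np.sum(((points_mm - lc) / la) ** 2, axis=-1) <= 1.0
        labels = np.where(in_les, np.maximum(labels, les.gleason), labels)
    return labels


def _grid_world_points(shape: tuple[int, int, int], affine: np.ndarray) -> np.ndarray:
    idx = np.indices(shape, dtype=float).reshape(3, -1).T
    return idx @ affine[:3, :3].T + affine[:3, 3]


def _param_lookup(labels: np.ndarray, table: dict[int, TissueClassParams],
                  attr: str) -> np.ndarray:
    out = np.zeros(labels.shape, dtype=float)
    for cls, params in table.items():
        out[labels == cls] = getattr(params, attr)
    return out


def generate_phantom(
    spec: PhantomSpec, patient_id: str = "phantom"
) -> tuple[MpMriStudy, GroundTruth]:
    """Render one synthetic study plus its ground truth.

    Deterministic: the same spec and seed give bit-identical volumes.  If
    a misregistration transform T is configured, the anatomy rendered in
    the DWI/DCE frames is displaced so that a feature at primary-world
    point p appears at T(p); metadata-only initialization then leaves
    exactly T to be recovered by registration.
    """
    rng = np.random.default_rng(spec.seed)
    aff_t2w = affine_from_geometry(spec.t2w_spacing)
    aff_dwi = affine_from_geometry(spec.dwi_spacing)
    aff_dce = affine_from_geometry(spec.dce_spacing)

    phases = rng.uniform(0.0, 2.0 * np.pi, size=3)

    def _texture(points_mm: np.ndarray) -> np.ndarray:
        """Smooth seeded heterogeneity in the anatomy's own frame."""
        if spec.texture_amplitude == 0.0:
            return np.ones(points_mm.shape[0])
        w = 2.0 * np.pi / np.asarray(spec.texture_wavelength_mm)
        s = np.sin(points_mm * w[np.newaxis, :] + phases[np.newaxis, :])
        return 1.0 + spec.texture_amplitude * s.prod(axis=1)

    # truth on the T2W grid
    pts_t2w = _grid_world_points(spec.t2w_shape, aff_t2w)
    labels = _labels_at_points(pts_t2w, spec).reshape(spec.t2w_shape)
    table = spec.tissue_table
    true_maps = {
        "adc": _param_lookup(labels, table, "adc"),
        "ktrans": _param_lookup(labels, table, "ktrans"),
        "ve": _param_lookup(labels, table, "ve"),
        "t2w": _param_lookup(labels, table, "t2w"),
    }
    true_maps["kep"] = np.where(
        true_maps["ve"] > 0, true_maps["ktrans"] / np.where(true_maps["ve"] > 0,
                                                            true_maps["ve"], 1.0), 0.0
    )

    tex_t2w = _texture(pts_t2w).reshape(spec.t2w_shape)
    t2w_data = true_maps["t2w"] * tex_t2w + rng.normal(
        0.0, spec.noise_sigma_t2w, size=spec.t2w_shape
    )
    t2w = VolumeImage(t2w_data, aff_t2w, modality="T2W")

    # secondary frames: misregistration displaces the rendered anatomy
    inv = (spec.misregistration.inverse_matrix()
           if spec.misregistration is not None else np.eye(4))

    def _labels_on(shape, affine):
        pts = _grid_world_points(shape, affine)
        pts = pts @ inv[:3, :3].T + inv[:3, 3]
        return (_labels_at_points(pts, spec).reshape(shape),
                _texture(pts).reshape(shape))

    labels_dwi, tex_dwi = _labels_on(spec.dwi_shape, aff_dwi)
    s0_dwi = _param_lookup(labels_dwi, table, "s0_dwi") * tex_dwi
    adc_dwi = _param_lookup(labels_dwi, table, "adc")
    dwi = []
    for b in np.asarray(spec.b_values, dtype=float):
        sig = simulate_dwi_signal(s0_dwi, adc_dwi, b)
        sig = sig + rng.normal(0.0, spec.noise_sigma_dwi, size=spec.dwi_shape)
        dwi.append(VolumeImage(sig, aff_dwi, modality=f"DWI_b{b:g}"))

    labels_dce, tex_dce = _labels_on(spec.dce_shape, aff_dce)
    times = spec.dce_times_s
    # per-class concentration curves, then broadcast to voxels
    curves = {
        cls: simulate_dce_curve(p.ktrans, p.ve, spec.aif, times)
        for cls, p in table.items()
    }
    s0_dce = _param_lookup(labels_dce, table, "s0_dce") * tex_dce
    dce = []
    frames = np.zeros(spec.dce_shape + (times.size,))
    for cls, curve in curves.items():
        frames[labels_dce == cls] = spec.dce_gain * curve
    frames += s0_dce[..., np.newaxis]
    frames += rng.normal(0.0, spec.noise_sigma_dce,
                         size=spec.dce_shape + (times.size,))
    for k in range(times.size):
        dce.append(VolumeImage(frames[..., k], aff_dce, modality=f"DCE_f{k:02d}"))

    study = MpMriStudy(
        patient_id=patient_id, t2w=t2w, dwi=dwi,
        b_values=np.asarray(spec.b_values, dtype=float),
        dce=dce, dce_times_s=times, aif=spec.aif, dce_gain=spec.dce_gain,
    )
    truth = GroundTruth(
        labels=labels, affine=aff_t2w, true_maps=true_maps,
        misregistration=spec.misregistration,
    )
    return study, truth


# ---------------------------------------------------------------------------
# Biopsy sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorePlan:
    """How many cores to take and how many of them target lesions."""

    n_cores: int = 24
    n_targeted: int = 2
    nominal_length_mm: float = 17.0
    effective_beta: tuple[float, float] = (8.0, 2.0)  # mean 0.8 shortfall model

    def __post_init__(self) -> None:
        if not 16 <= self.n_cores <= 36:
            raise ValueError(f"core count must be within [16, 36], got {self.n_cores}")
        if self.n_targeted > self.n_cores:
            raise ValueError("cannot target more cores than are taken")


def _core_gleason(truth: GroundTruth, entry: np.ndarray, tip: np.ndarray,
                  fraction: float, step_mm: float = 0.5) -> int:
    """Pathology result: max truth grade along the effective segment."""
    eff_tip = entry + fraction * (tip - entry)
    length = float(np.linalg.norm(eff_tip - entry))
    n = max(int(np.floor(length / step_mm)) + 1, 2)
    ts = np.linspace(0.0, 1.0, n)
    pts = entry[np.newaxis, :] + ts[:, np.newaxis] * (eff_tip - entry)[np.newaxis, :]
    inv = np.linalg.inv(truth.affine)
    vox = np.round(pts @ inv[:3, :3].T + inv[:3, 3]).astype(int)
    shape = np.asarray(truth.labels.shape)
    ok = np.all((vox >= 0) & (vox < shape), axis=1)
    if not np.any(ok):
        raise ValueError("core lies entirely outside the label volume")
    grades = truth.labels[tuple(vox[ok].T)]
    top = int(grades.max(initial=0))
    return top if top >= 6 else 0


def sample_biopsy_cores(
    truth: GroundTruth,
    spec: PhantomSpec,
    plan: CorePlan,
    seed: int,
    patient_id: str = "phantom",
) -> list[BiopsyCore]:
    """Simulate a transperineal template biopsy session.

    Systematic cores enter from below the prostate (-y) on a jittered
    template across its x-z extent and travel the nominal throw in +y;
    targeted cores are aimed so the mid-throw crosses a lesion centre.
    Each core's effective-length fraction is drawn from Beta(8, 2)
    (seeded), truncating the segment from the entry; the pathology result
    is the maximum truth grade along the effective segment, 0 if benign.
    """
    rng = np.random.default_rng(seed)
    c = np.asarray(spec.prostate_center_mm)
    ax = np.asarray(spec.prostate_semi_axes_mm)
    L = plan.nominal_length_mm
    cores: list[BiopsyCore] = []

    n_targeted = min(plan.n_targeted, len(spec.lesions) * 2) if spec.lesions else 0
    targets = []
    for i in range(n_targeted):
        les = spec.lesions[i % len(spec.lesions)]
        targets.append(np.asarray(les.center_mm))
    n_systematic = plan.n_cores - len(targets)

    # systematic template: jittered grid over the prostate's x-z footprint
    n_x = int(np.ceil(np.sqrt(n_systematic)))
    n_z = int(np.ceil(n_systematic / n_x))
    xs = np.linspace(c[0] - 0.8 * ax[0], c[0] + 0.8 * ax[0], n_x)
    zs = np.linspace(c[2] - 0.8 * ax[2], c[2] + 0.8 * ax[2], n_z)
    grid = [(x, z) for z in zs for x in xs][:n_systematic]

    k = 0
    for x, z in grid:
        jitter = rng.normal(0.0, 1.0, size=2)
        mid = np.array([x + jitter[0], c[1], z + jitter[1]])
        entry = mid - np.array([0.0, L / 2.0, 0.0])
        tip = mid + np.array([0.0, L / 2.0, 0.0])
        frac = float(rng.beta(*plan.effective_beta))
        g = _core_gleason(truth, entry, tip, frac)
        cores.append(BiopsyCore(patient_id, f"{patient_id}-c{k:02d}",
                                tuple(entry), tuple(tip), frac, g))
        k += 1
    for tgt in targets:
        jitter = rng.normal(0.0, 0.8, size=3)
        mid = tgt + jitter
        entry = mid - np.array([0.0, L / 2.0, 0.0])
        tip = mid + np.array([0.0, L / 2.0, 0.0])
        frac = float(rng.beta(*plan.effective_beta))
        g = _core_gleason(truth, entry, tip, frac)
        cores.append(BiopsyCore(patient_id, f"{patient_id}-c{k:02d}",
                                tuple(entry), tuple(tip), frac, g))
        k += 1
    return cores


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Study-population configuration for the cohort generator."""

    n_patients: int = 45
    prevalence: float = 0.467
    core_count_range: tuple[int, int] = (16, 32)  # uniform; mean 24
    lesion_grades: tuple[int, ...] = (6, 7, 8, 9)
    lesion_grade_probs: tuple[float, ...] = (0.3, 0.4, 0.2, 0.1)  # grade-7 mode
    lesion_semi_axis_range_mm: tuple[float, float] = (4.0, 8.0)
    max_lesions: int = 2
    n_targeted: int = 2


def generate_cohort_specs(
    cohort: CohortSpec, seed: int, base_spec: PhantomSpec | None = None
) -> list[tuple[str, PhantomSpec, CorePlan]]:
    """Per-patient phantom specs and biopsy plans for a seeded cohort.

    Volumes are not rendered here; pass each spec to
    :func:`generate_phantom` on demand.  Patient cancer status is an
    independent seeded Bernoulli draw at the configured prevalence.
    """
    rng = np.random.default_rng(seed)
    base = base_spec or PhantomSpec()
    out = []
    for i in range(cohort.n_patients):
        pid = f"p{i:03d}"
        positive = bool(rng.random() < cohort.prevalence)
        lesions: list[LesionSpec] = []
        if positive:
            n_les = int(rng.integers(1, cohort.max_lesions + 1))
            for _ in range(n_les):
                grade = int(rng.choice(cohort.lesion_grades,
                                       p=cohort.lesion_grade_probs))
                axes = rng.uniform(*cohort.lesion_semi_axis_range_mm, size=3)
                # place the lesion well inside the prostate
                c = np.asarray(base.prostate_center_mm)
                pa = np.asarray(base.prostate_semi_axes_mm)
                for _attempt in range(50):
                    u = rng.uniform(-0.5, 0.5, size=3)
                    center = c + u * pa
                    cand = LesionSpec(tuple(center), tuple(axes), grade)
                    ok = all(
                        np.sum(((np.asarray(center) + s * axes * e - c) / pa) ** 2) <= 1.0
                        for e in np.eye(3) for s in (-1.0, 1.0)
                    )
                    if ok:
                        lesions.append(cand)
                        break
        spec = replace(base, lesions=lesions,
                       seed=int(rng.integers(0, 2**31 - 1)))
        n_cores = int(rng.integers(cohort.core_count_range[0],
                                   cohort.core_count_range[1] + 1))
        plan = CorePlan(n_cores=n_cores,
                        n_targeted=cohort.n_targeted if lesions else 0)
        out.append((pid, spec, plan))
    return out
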