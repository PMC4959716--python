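"""Kernel-based malignancy-index model: the three-step mapping to MAI.

The Malignancy Attention Index (MAI) maps a five-feature voxel vector
(normalized T2W, ADC, Ktrans, Ve, kep) to a scalar in [0, 1] that is
congruent with Gleason grade.  Three steps:

1. *Preparation transform* - Gaussian radial-basis activations at learned
   kernel centres, weighted into predictor space (an RBF layer).
2. *Linear classification* - a summation layer collapses predictor space
   to one raw malignancy score.
3. *Regularisation* - a monotone piecewise-linear calibration maps raw
   scores to MAI so that Gleason grade g lands at 0.6 + 0.1 (g - 6)
   (grade 6 at 0.6, grade 10 at 1.0) and benign tissue below 0.6.

Training is two-phase and supervised: phase 1 grows kernels dynamically
(error feedback adds a centre at the worst-ranked misordered sample) and
fits the weights to order voxels by label (benign < 6 < ... < 10) under a
pairwise logistic ranking loss; phase 2 freezes the weights and fits the
calibration nodes so class-median raw scores land on the Gleason anchors,
subject to monotonicity.

The estimator follows the scikit-learn protocol (``fit`` /
``decision_function`` / ``predict``, ``get_params`` / ``set_params``),
so it composes with sklearn model selection.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .parametric_maps import ParametricMaps
from .volume import VolumeImage

__all__ = [
    "FEATURE_NAMES",
    "KernelMalignancyModel",
    "assemble_features",
    "raw_malignancy_score",
    "calibrate_to_mai",
    "train_mai_model",
    "compute_mai_map",
    "gleason_anchor",
]

# fixed component order of every feature vector
FEATURE_NAMES = ("t2w_norm", "adc", "ktrans", "ve", "kep")

#: class labels in malignancy order: benign, then Gleason grades
LABEL_BENIGN = 0


def gleason_anchor(label: int, benign_anchor: float = 0.3) -> float:
    """Target MAI for a class: 0.6 + 0.1 (g - 6) for grades, else benign."""
    if label == LABEL_BENIGN:
        return benign_anchor
    if label not in (6, 7, 8, 9, 10):
        raise ValueError(f"label must be 0 or 6..10, got {label}")
    return 0.6 + 0.1 * (label - 6)


def assemble_features(
    maps: ParametricMaps, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix (N, 5) for the masked voxels, in ``FEATURE_NAMES`` order.

    Flagged voxels (failed fits) are excluded; the second return value is
    the boolean volume mask of voxels actually used.  Raises on an empty
    or all-flagged mask.  Features are raw; the model standardizes them
    with its stored constants, exactly once.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != maps.shape:
        raise ValueError("mask shape must match the parameter maps")
    if not mask.any():
        raise ValueError("empty mask")
    used = mask & (maps.flags == 0)
    if not used.any():
        raise ValueError("all masked voxels are flagged; no usable features")
    X = np.column_stack([
        maps.t2w_norm[used], maps.adc[used], maps.ktrans[used],
        maps.ve[used], maps.kep[used],
    ])
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature components")
    return X, used


class KernelMalignancyModel(BaseEstimator):
    """Gaussian-kernel ranking model with monotone Gleason calibration.

    Parameters
    ----------
    max_kernels : int
        Cap on dynamically grown kernels (predictor-space dimension).
    patience : int
        Growth stops after this many rounds without validation
        ranking-error improvement.
    width_scale : float
        Kernel width = width_scale x median pairwise distance of a
        training subsample (standardized space).
    pair_subsample : int
        Ordered label pairs sampled per training round.
    val_fraction : float
        Held-out fraction for the growth stopping rule.
    l2 : float
        Ridge penalty on the projection weights.
    benign_anchor : float
        Calibration target for benign voxels (below the 0.6 cancer floor).
    random_state : int
        Seed for all training randomness; fixed seed gives bit-identical
        models.
    """

    def __init__(
        self,
        max_kernels: int = 64,
        patience: int = 5,
        width_scale: float = 1.0,
        pair_subsample: int = 100_000,
        val_fraction: float = 0.2,
        l2: float = 1e-4,
        benign_anchor: float = 0.3,
        random_state: int = 0,
    ):
        self.max_kernels = max_kernels
        self.patience = patience
        self.width_scale = width_scale
        self.pair_subsample = pair_subsample
        self.val_fraction = val_fraction
        self.l2 = l2
        self.benign_anchor = benign_anchor
        self.random_state = random_state

    # -- internals --------------------------------------------------------
    def _activations(self, Xs: np.ndarray) -> np.ndarray:
        d2 = ((Xs[:, None, :] - self.centers_[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-0.5 * d2 / self.widths_[None, :] ** 2)

    @staticmethod
    def _sample_pairs(y: np.ndarray, n_pairs: int, rng: np.random.Generator
                      ) -> tuple[np.ndarray, np.ndarray]:
        """Seeded sample of (lo, hi) index pairs with y[lo] < y[hi]."""
        order = np.argsort(y, kind="stable")
        ys = y[order]
        # sample pairs uniformly, reject equal labels
        lo, hi = [], []
        need = n_pairs
        for _ in range(8):
            i = rng.integers(0, y.size, size=2 * need)
            j = rng.integers(0, y.size, size=2 * need)
            keep = y[i] != y[j]
            i, j = i[keep], j[keep]
            swap = y[i] > y[j]
            i2 = np.where(swap, j, i)
            j2 = np.where(swap, i, j)
            lo.append(i2)
            hi.append(j2)
            if sum(a.size for a in lo) >= n_pairs:
                break
        del order, ys
        lo_all = np.concatenate(lo)[:n_pairs]
        hi_all = np.concatenate(hi)[:n_pairs]
        if lo_all.size == 0:
            raise ValueError("could not sample ordered pairs (single class?)")
        return lo_all, hi_all

    def _fit_weights(self, phi: np.ndarray, lo: np.ndarray, hi: np.ndarray,
                     w0: np.ndarray) -> np.ndarray:
        """Convex logistic ranking loss over ordered pairs, L-BFGS."""
        D = phi[hi] - phi[lo]  # score diff features; want D @ w > 0

        def fun(w: np.ndarray) -> tuple[float, np.ndarray]:
            m = D @ w
            # log(1 + exp(-m)) stably
            loss = np.logaddexp(0.0, -m).mean() + 0.5 * self.l2 * w @ w
            sig = 1.0 / (1.0 + np.exp(np.clip(m, -500, 500)))
            grad = -(D * sig[:, None]).mean(axis=0) + self.l2 * w
            return float(loss), grad

        res = minimize(fun, w0, jac=True, method="L-BFGS-B",
                       options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-10})
        return res.x

    @staticmethod
    def _ranking_error(scores: np.ndarray, y: np.ndarray,
                       lo: np.ndarray, hi: np.ndarray) -> float:
        return float(np.mean(scores[hi] <= scores[lo]))

    # -- estimator API ----------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "KernelMalignancyModel":
        """Two-phase supervised training.

        ``y`` holds 0 for benign voxels and the Gleason grade (6-10) for
        lesion voxels; at least two distinct classes are required.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be (n_samples, n_features) matching y")
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("need at least 2 distinct label classes")
        bad = set(classes.tolist()) - {0, 6, 7, 8, 9, 10}
        if bad:
            raise ValueError(f"labels must be 0 or 6..10, got extra {sorted(bad)}")

        rng = np.random.default_rng(self.random_state)
        self.feature_mean_ = X.mean(axis=0)
        std = X.std(axis=0)
        self.feature_scale_ = np.where(std > 0, std, 1.0)
        Xs = (X - self.feature_mean_) / self.feature_scale_

        # train / validation split, stratified by shuffling within the pool
        n = Xs.shape[0]
        perm = rng.permutation(n)
        n_val = max(int(self.val_fraction * n), classes.size)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        if np.unique(y[tr_idx]).size < 2 or np.unique(y[val_idx]).size < 2:
            # tiny inputs: fall back to using everything for both roles
            tr_idx = val_idx = np.arange(n)
        Xtr, ytr = Xs[tr_idx], y[tr_idx]
        Xval, yval = Xs[val_idx], y[val_idx]

        # kernel width from the pairwise-distance scale of a subsample
        sub = Xtr[rng.permutation(Xtr.shape[0])[:256]]
        d2 = ((sub[:, None, :] - sub[None, :, :]) ** 2).sum(axis=2)
        med = float(np.median(np.sqrt(d2[d2 > 0]))) if np.any(d2 > 0) else 1.0
        base_width = max(self.width_scale * med, 1e-6)

        # seed kernels: one at each class mean
        centers = [Xtr[ytr == c].mean(axis=0) for c in np.unique(ytr)]
        self.centers_ = np.asarray(centers)
        self.widths_ = np.full(len(centers), base_width)

        pairs_tr = self._sample_pairs(ytr, self.pair_subsample, rng)
        pairs_val = self._sample_pairs(yval, min(self.pair_subsample, 20_000), rng)

        w = np.zeros(self.centers_.shape[0])
        best_err = np.inf
        best_state = None
        stall = 0
        while True:
            phi = self._activations(Xtr)
            w = self._fit_weights(phi, *pairs_tr, np.pad(w, (0, phi.shape[1] - w.size)))
            self.projection_weights_ = w
            val_scores = self._activations(Xval) @ w
            err = self._ranking_error(val_scores, yval, *pairs_val)
            if err < best_err - 1e-6:
                best_err = err
                best_state = (self.centers_.copy(), self.widths_.copy(), w.copy())
                stall = 0
            else:
                stall += 1
            if (stall >= self.patience or err == 0.0
                    or self.centers_.shape[0] >= self.max_kernels):
                break
            # error feedback: add a centre at the worst-ranked misordered
            # training sample (most violated ordered pairs)
            tr_scores = phi @ w
            lo, hi = pairs_tr
            viol = tr_scores[hi] <= tr_scores[lo]
            if not viol.any():
                break
            counts = np.bincount(
                np.concatenate([lo[viol], hi[viol]]), minlength=ytr.size
            )
            worst = int(np.argmax(counts))
            self.centers_ = np.vstack([self.centers_, Xtr[worst]])
            self.widths_ = np.append(self.widths_, base_width)

        if best_state is not None:
            self.centers_, self.widths_, self.projection_weights_ = best_state
        self.linear_weights_ = np.ones(self.centers_.shape[0])  # summation layer
        self.bias_ = 0.0
        self.validation_ranking_error_ = float(best_err)
        self.train_ranking_error_ = self._ranking_error(
            self._activations(Xtr) @ self.projection_weights_, ytr, *pairs_tr
        )
        self.classes_ = classes

        # ---- phase 2: monotone calibration to the Gleason anchors ----
        raw_all = self._raw(Xs)
        medians = np.array([np.median(raw_all[y == c]) for c in classes])
        anchors = np.array([gleason_anchor(int(c), self.benign_anchor)
                            for c in classes])
        # enforce strictly increasing node abscissae (pool-adjacent, then
        # epsilon separation); ordering training should already give this
        medians = np.asarray(_isotonic(medians))
        eps = 1e-9 + 1e-9 * np.abs(medians).max()
        for i in range(1, medians.size):
            if medians[i] <= medians[i - 1]:
                medians[i] = medians[i - 1] + eps
        self.calibration_raw_ = medians
        self.calibration_mai_ = np.clip(anchors, 0.0, 1.0)
        self.n_features_in_ = X.shape[1]
        return self

    def _raw(self, Xs: np.ndarray) -> np.ndarray:
        phi = self._activations(Xs)
        return (phi * self.projection_weights_[None, :]) @ self.linear_weights_ + self.bias_

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Raw malignancy scores (pre-calibration), deterministic."""
        check_is_fitted(self, "centers_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected (n, {self.n_features_in_}) features, got {X.shape}"
            )
        Xs = (X - self.feature_mean_) / self.feature_scale_
        return self._raw(Xs)

    def calibrate(self, raw: np.ndarray) -> np.ndarray:
        """Monotone piecewise-linear map from raw score to MAI in [0, 1]."""
        check_is_fitted(self, "calibration_raw_")
        nodes_x = self.calibration_raw_
        nodes_y = self.calibration_mai_
        if np.any(np.diff(nodes_x) <= 0) or np.any(np.diff(nodes_y) <= 0):
            raise ValueError("calibration nodes must be strictly increasing")
        out = np.interp(np.asarray(raw, dtype=float), nodes_x, nodes_y)
        return np.clip(out, 0.0, 1.0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """MAI in [0, 1] for each feature vector."""
        return self.calibrate(self.decision_function(X))

    # -- serialization ----------------------------------------------------
    def to_json_dict(self) -> dict:
        check_is_fitted(self, "centers_")
        return {
            "format": "promai-model",
            "version": 1,
            "feature_names": list(FEATURE_NAMES[: self.n_features_in_]),
            "params": self.get_params(),
            "feature_mean": self.feature_mean_.tolist(),
            "feature_scale": self.feature_scale_.tolist(),
            "kernel_centers": self.centers_.tolist(),
            "kernel_widths": self.widths_.tolist(),
            "projection_weights": self.projection_weights_.tolist(),
            "linear_weights": self.linear_weights_.tolist(),
            "bias": self.bias_,
            "calibration_raw": self.calibration_raw_.tolist(),
            "calibration_mai": self.calibration_mai_.tolist(),
            "classes": self.classes_.tolist(),
            "train_seed": self.random_state,
            "validation_ranking_error": self.validation_ranking_error_,
            "train_ranking_error": self.train_ranking_error_,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "KernelMalignancyModel":
        if d.get("format") != "promai-model":
            raise ValueError("not a malignancy-model JSON document")
        model = cls(**d["params"])
        model.feature_mean_ = np.asarray(d["feature_mean"], dtype=float)
        model.feature_scale_ = np.asarray(d["feature_scale"], dtype=float)
        model.centers_ = np.asarray(d["kernel_centers"], dtype=float)
        model.widths_ = np.asarray(d["kernel_widths"], dtype=float)
        model.projection_weights_ = np.asarray(d["projection_weights"], dtype=float)
        model.linear_weights_ = np.asarray(d["linear_weights"], dtype=float)
        model.bias_ = float(d["bias"])
        model.calibration_raw_ = np.asarray(d["calibration_raw"], dtype=float)
        model.calibration_mai_ = np.asarray(d["calibration_mai"], dtype=float)
        if np.any(np.diff(model.calibration_raw_) <= 0) or np.any(
            np.diff(model.calibration_mai_) <= 0
        ):
            raise ValueError("calibration nodes must be strictly increasing")
        model.classes_ = np.asarray(d["classes"], dtype=int)
        model.n_features_in_ = model.centers_.shape[1]
        model.validation_ranking_error_ = float(d["validation_ranking_error"])
        model.train_ranking_error_ = float(d["train_ranking_error"])
        return model

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_json_dict(), indent=1))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "KernelMalignancyModel":
        return cls.from_json_dict(json.loads(Path(path).read_text()))


def _isotonic(v: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators for a short increasing sequence."""
    v = list(map(float, v))
    blocks = [[x, 1] for x in v]  # (mean, size)
    out: list[list[float]] = []
    for b in blocks:
        out.append(b)
        while len(out) >= 2 and out[-2][0] > out[-1][0]:
            m2, n2 = out.pop()
            m1, n1 = out.pop()
            out.append([(m1 * n1 + m2 * n2) / (n1 + n2), n1 + n2])
    res = []
    for m, n in out:
        res.extend([m] * n)
    return np.asarray(res)


# ---------------------------------------------------------------------------
# Thin functional wrappers
# ---------------------------------------------------------------------------

def raw_malignancy_score(X: np.ndarray, model: KernelMalignancyModel) -> np.ndarray:
    """Raw (pre-calibration) malignancy score of feature vectors."""
    return model.decision_function(np.atleast_2d(X))


def calibrate_to_mai(raw: np.ndarray | float, model: KernelMalignancyModel):
    """Map raw scores through the monotone calibration to MAI in [0, 1]."""
    out = model.calibrate(raw)
    return float(out) if np.isscalar(raw) else out


def train_mai_model(
    X: np.ndarray, y: np.ndarray, seed: int = 0, **options
) -> KernelMalignancyModel:
    """Train a malignancy model; deterministic for a fixed seed."""
    return KernelMalignancyModel(random_state=seed, **options).fit(X, y)


def compute_mai_map(
    maps: ParametricMaps,
    model: KernelMalignancyModel,
    mask: np.ndarray,
) -> VolumeImage:
    """Per-voxel MAI volume on the T2W grid.

    Scores the masked, unflagged voxels and calibrates to [0, 1]; flagged
    or unmasked voxels get MAI 0.
    """
    X, used = assemble_features(maps, mask)
    mai = np.zeros(maps.shape)
    mai[used] = model.predict(X)
    return VolumeImage(mai, maps.affine.copy(), modality="MAI")
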