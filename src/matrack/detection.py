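"""Blob segmentation and one-class animal classification.

Candidate entities are segmented from each frame with a Laplacian-of-Gaussian
(LoG) band-pass filter whose Gaussian standard deviation ``sigma_log`` sets
the preferred blob scale.  Each entity is summarised by five scalar features
(area and the mean / median / min / max of its member-pixel intensities) and
classified as *animal* or *background* by a one-class Mahalanobis model
trained from a handful of user-marked exemplars.  Because the user only ever
marks positive examples, the classifier is a novelty detector: it learns the
mean and covariance of the marked feature vectors and accepts a query whose
Mahalanobis distance falls below an empirical quantile of the training
distances.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.base import BaseEstimator

FEATURE_NAMES = ("area", "mean", "median", "min", "max")

__all__ = [
    "FEATURE_NAMES",
    "SegmentationParams",
    "Entity",
    "MahalanobisAnimalClassifier",
    "log_kernel",
    "log_filter",
    "segment_entities",
    "fit_classifier",
    "mahalanobis_distance",
    "classify_entity",
    "build_training_set",
    "save_model",
    "load_model",
]


@dataclass
class SegmentationParams:
    """Parameters controlling LoG segmentation.

    Attributes
    ----------
    sigma_log : float
        Standard deviation (px) of the LoG Gaussian; sets the preferred
        blob scale (a bright blob of radius ~ sigma_log*sqrt(2) responds
        maximally).
    binarize_threshold : float
        Fixed scalar threshold applied to the signed LoG response.
    min_area_px : int
        Minimum connected-component area kept (suppresses pixel noise).
    connectivity : int
        4 or 8 pixel connectivity for component labeling.
    invert_polarity : bool
        If True, detect dark blobs on bright background instead of the
        default bright-on-dark.
    """

    sigma_log: float = 3.0
    binarize_threshold: float = 0.02
    min_area_px: int = 3
    connectivity: int = 8
    invert_polarity: bool = False

    def __post_init__(self) -> None:
        if self.sigma_log <= 0:
            raise ValueError("sigma_log must be positive")
        if self.min_area_px < 1:
            raise ValueError("min_area_px must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class Entity:
    """One segmented blob in one frame.

    ``centroid`` is (x, y) in pixels, 0-based, x rightward (column) and
    y downward (row), origin at the top-left corner.  ``features`` is the
    fixed-order 5-vector (area, mean, median, min, max) computed from the
    ORIGINAL image intensities of the member pixels.
    """

    frame_index: int
    centroid: tuple[float, float]
    area_px: int
    features: np.ndarray = field(repr=False)


def log_kernel(sigma: float) -> np.ndarray:
    """Negated Laplacian-of-Gaussian kernel, truncated at radius ceil(4*sigma).

    The kernel is negated so that a bright blob of matched scale produces a
    positive local maximum; its sum is re-centered to exactly zero so that
    constant images map to an identically-zero response.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    radius = int(np.ceil(4.0 * sigma))
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1].astype(float)
    r2 = xx**2 + yy**2
    gauss = np.exp(-r2 / (2.0 * sigma**2))
    kern = -((r2 - 2.0 * sigma**2) / sigma**4) * gauss
    kern -= kern.mean()  # zero-sum: annihilates constants exactly
    return kern


def log_filter(image: np.ndarray, sigma_log: float) -> np.ndarray:
    """Convolve ``image`` with the zero-sum negated LoG kernel.

    Bright blobs of scale ~ sigma_log*sqrt(2) give positive extrema.
    Boundaries are handled by nearest-edge replication, which preserves
    the zero response on constant images.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    kern = log_kernel(sigma_log)
    if min(image.shape) < kern.shape[0]:
        raise ValueError(
            f"image {image.shape} smaller than LoG kernel support {kern.shape}"
        )
    return ndimage.convolve(image, kern, mode="nearest")


def _connectivity_structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)


def segment_entities(
    image: np.ndarray,
    params: SegmentationParams,
    frame_index: int = 0,
) -> list[Entity]:
    """Segment candidate entities from one frame.

    The LoG response is binarized at ``params.binarize_threshold`` and
    connected components with area >= ``min_area_px`` become entities.
    Centroids are unweighted means of member-pixel coordinates; features
    are computed from the original (unfiltered) intensities.
    """
    image = np.asarray(image, dtype=float)
    if image.size and np.ptp(image) == 0 and image.flat[0] > 0:
        warnings.warn("all-saturated frame: no entities segmented", stacklevel=2)
        return []
    response = log_filter(image, params.sigma_log)
    if params.invert_polarity:
        response = -response
    mask = response > params.binarize_threshold
    labels, n_labels = ndimage.label(mask, structure=_connectivity_structure(params.connectivity))
    if n_labels == 0:
        return []
    entities: list[Entity] = []
    objects = ndimage.find_objects(labels)
    for lab, slc in enumerate(objects, start=1):
        member = labels[slc] == lab
        area = int(member.sum())
        if area < params.min_area_px:
            continue
        rows, cols = np.nonzero(member)
        rows = rows + slc[0].start
        cols = cols + slc[1].start
        vals = image[rows, cols]
        features = np.array(
            [area, vals.mean(), np.median(vals), vals.min(), vals.max()],
            dtype=float,
        )
        entities.append(
            Entity(
                frame_index=frame_index,
                centroid=(float(cols.mean()), float(rows.mean())),
                area_px=area,
                features=features,
            )
        )
    return entities


class MahalanobisAnimalClassifier(BaseEstimator):
    """One-class novelty detector over blob features using Mahalanobis distance.

    Fitting estimates the feature mean ``mu_`` and sample covariance
    ``sigma_`` from the (positively labeled) training matrix.  The
    acceptance threshold ``threshold_T_`` is the empirical
    (1 - beta_fnr)-quantile (nearest-rank) of the training Mahalanobis
    distances, so about a fraction ``beta_fnr`` of genuine training
    exemplars fall outside it (the configured false-negative rate).
    A query x is classified as an animal iff D(x) <= threshold_T_,
    with D(x) = sqrt((x - mu)^T Sigma^-1 (x - mu)).

    Parameters
    ----------
    beta_fnr : float
        Target false-negative rate in [0, 1); default 0.01.
    cond_max : float
        Covariance condition number beyond which Tikhonov regularization
        is applied.
    reg_eps : float
        Regularization strength: eps * trace(Sigma)/n added to the diagonal.
    """

    def __init__(self, beta_fnr: float = 0.01, cond_max: float = 1e8, reg_eps: float = 1e-6):
        self.beta_fnr = beta_fnr
        self.cond_max = cond_max
        self.reg_eps = reg_eps

    def fit(self, X: np.ndarray, y=None) -> "MahalanobisAnimalClassifier":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("training set must be a 2-D (m, n) matrix")
        m, n = X.shape
        if m <= n:
            raise ValueError(f"need at least n+1={n + 1} training rows, got {m}")
        if not 0 <= self.beta_fnr < 1:
            raise ValueError("beta_fnr must lie in [0, 1)")
        self.mu_ = X.mean(axis=0)
        sigma = np.cov(X, rowvar=False, ddof=1)
        sigma = np.atleast_2d(sigma)
        self.sigma_ = sigma
        self.sigma_inv_ = self._invert(sigma)
        d = self.mahalanobis(X)
        # nearest-rank quantile: the distance larger than (1-beta)*m samples
        rank = int(np.ceil((1.0 - self.beta_fnr) * m))
        rank = min(max(rank, 1), m)
        self.threshold_T_ = float(np.sort(d)[rank - 1])
        self.n_features_in_ = n
        self.training_distances_ = d
        return self

    def _invert(self, sigma: np.ndarray) -> np.ndarray:
        n = sigma.shape[0]
        cond = np.linalg.cond(sigma)
        if not np.isfinite(cond) or cond > self.cond_max:
            trace = np.trace(sigma)
            scale = trace / n if trace > 0 else 1.0
            warnings.warn(
                "ill-conditioned feature covariance; applying diagonal regularization",
                stacklevel=2,
            )
            sigma = sigma + self.reg_eps * scale * np.eye(n)
            self.sigma_ = sigma
        return np.linalg.inv(sigma)

    def mahalanobis(self, X: np.ndarray) -> np.ndarray:
        """Mahalanobis distance of each row of X from the fitted distribution."""
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.mu_.shape[0]:
            raise ValueError(
                f"expected {self.mu_.shape[0]} features, got {X.shape[1]}"
            )
        diff = X - self.mu_
        d2 = np.einsum("ij,jk,ik->i", diff, self.sigma_inv_, diff)
        return np.sqrt(np.maximum(d2, 0.0))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Boolean array: True where the row is accepted as an animal."""
        return self.mahalanobis(X) <= self.threshold_T_

    def _check_fitted(self) -> None:
        if not hasattr(self, "mu_"):
            raise RuntimeError("classifier is not fitted")


def fit_classifier(train: np.ndarray, beta_fnr: float = 0.01) -> MahalanobisAnimalClassifier:
    """Fit the one-class model on an (m, n) matrix of marked-entity features."""
    return MahalanobisAnimalClassifier(beta_fnr=beta_fnr).fit(train)


def mahalanobis_distance(x: np.ndarray, model: MahalanobisAnimalClassifier) -> float:
    return float(model.mahalanobis(np.asarray(x, dtype=float))[0])


def classify_entity(entity: Entity, model: MahalanobisAnimalClassifier) -> str:
    """Return 'animal' iff the entity's feature distance is within threshold."""
    return "animal" if bool(model.predict(entity.features[None, :])[0]) else "background"


def build_training_set(
    clicks: pd.DataFrame,
    entities_by_frame: dict[int, list[Entity]],
    snap_radius_px: float = 10.0,
) -> np.ndarray:
    """Snap user clicks to segmented entities and collect their features.

    ``clicks`` needs columns frame_index, x_px, y_px (0-based pixels).
    Each click is matched to the nearest entity centroid in its frame
    within ``snap_radius_px``; unmatched clicks are dropped with a warning.
    """
    rows = []
    dropped = 0
    for rec in clicks.itertuples(index=False):
        cands = entities_by_frame.get(int(rec.frame_index), [])
        if not cands:
            dropped += 1
            continue
        pts = np.array([e.centroid for e in cands])
        dist = np.hypot(pts[:, 0] - rec.x_px, pts[:, 1] - rec.y_px)
        k = int(np.argmin(dist))
        if dist[k] <= snap_radius_px:
            rows.append(cands[k].features)
        else:
            dropped += 1
    if dropped:
        warnings.warn(f"{dropped} click(s) had no entity within snap radius", stacklevel=2)
    if not rows:
        raise ValueError("no clicks could be snapped to segmented entities")
    return np.vstack(rows)


def save_model(
    path,
    model: MahalanobisAnimalClassifier,
    seg: SegmentationParams,
) -> None:
    """Serialize a fitted model plus the segmentation settings it was trained with."""
    model._check_fitted()
    payload = {
        "mu": model.mu_.tolist(),
        "sigma": model.sigma_.tolist(),
        "threshold_T": model.threshold_T_,
        "beta_fnr": model.beta_fnr,
        "feature_names": list(FEATURE_NAMES),
        "sigma_log": seg.sigma_log,
        "binarize_threshold": seg.binarize_threshold,
        "min_area_px": seg.min_area_px,
        "connectivity": seg.connectivity,
        "invert_polarity": seg.invert_polarity,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> tuple[MahalanobisAnimalClassifier, SegmentationParams]:
    with open(path) as fh:
        payload = json.load(fh)
    model = MahalanobisAnimalClassifier(beta_fnr=payload["beta_fnr"])
    model.mu_ = np.asarray(payload["mu"], dtype=float)
    model.sigma_ = np.asarray(payload["sigma"], dtype=float)
    model.sigma_inv_ = np.linalg.inv(model.sigma_)
    model.threshold_T_ = float(payload["threshold_T"])
    model.n_features_in_ = model.mu_.shape[0]
    seg = SegmentationParams(
        sigma_log=payload["sigma_log"],
        binarize_threshold=payload["binarize_threshold"],
        min_area_px=payload.get("min_area_px", 3),
        connectivity=payload.get("connectivity", 8),
        invert_polarity=payload.get("invert_polarity", False),
    )
    return model, seg
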