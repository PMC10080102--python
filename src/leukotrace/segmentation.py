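"""Pixel-level semantic segmentation of standardized frames.

Each pixel of an 8-bit frame is classified into one of four classes —
endothelial background, luminal "static" PMN, luminal "probing" PMN, or
transmigrated (abluminal) PMN — by a random forest over a multi-scale
feature bank. Phase contrast renders luminal PMNs bright and rounded and
transmigrated PMNs dark and amorphous, so intensity, edge and ridge
features at several scales carry the class signal. Training uses sparse
ground-truth masks (most pixels unlabeled) with geometric and photometric
augmentation; the forest's out-of-bag error provides an internal accuracy
estimate without a held-out set.
"""

from __future__ import annotations

import pickle
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier

from .io_preprocess import SubStackPlan, VideoStack

UNLABELED = 255

# Multi-scale feature bank: raw intensity, Gaussian blurs, gradient
# magnitudes, difference-of-Gaussians, Hessian eigenvalue pairs.
BLUR_SIGMAS = (1.0, 2.0, 4.0, 8.0, 16.0)
HESSIAN_SIGMAS = (1.0, 2.0, 4.0)
N_FEATURES = 1 + len(BLUR_SIGMAS) * 2 + (len(BLUR_SIGMAS) - 1) + 2 * len(HESSIAN_SIGMAS)


@dataclass(frozen=True)
class ClassScheme:
    """The four-class labeling scheme.

    Classes 1-3 are PMN classes; class 3 is the single abluminal
    (transmigrated) class, classes 1-2 are luminal.
    """

    names: tuple[str, ...] = ("endothelium", "luminal_static_pmn", "luminal_probing_pmn", "transmigrated_pmn")

    ENDOTHELIUM: int = 0
    LUMINAL_STATIC: int = 1
    LUMINAL_PROBING: int = 2
    TRANSMIGRATED: int = 3

    @property
    def n_classes(self) -> int:
        return len(self.names)

    @property
    def pmn_classes(self) -> tuple[int, ...]:
        return (1, 2, 3)

    @property
    def luminal_classes(self) -> tuple[int, ...]:
        return (1, 2)

    @property
    def abluminal_class(self) -> int:
        return 3


SCHEME = ClassScheme()


@dataclass
class SegmentationMap:
    """Per-pixel class labels and vote probabilities for one frame."""

    labels: np.ndarray           # (H, W) uint8 argmax class
    probabilities: np.ndarray    # (n_classes, H, W) float, sums to 1 per pixel
    frame: int = 0

    def __post_init__(self) -> None:
        if self.labels.shape != self.probabilities.shape[1:]:
            raise ValueError("label/probability shape mismatch")


@dataclass
class SegModel:
    """A trained random-forest pixel classifier with its configuration."""

    forest: RandomForestClassifier
    scheme: ClassScheme
    n_features: int
    oob_error: float
    seed: int
    training_meta: dict = field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "SegModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, SegModel):
            raise TypeError(f"{path} does not contain a SegModel")
        return model


def extract_features(frame: np.ndarray) -> np.ndarray:
    """Compute the fixed 21-feature bank for one frame.

    Returns an array of shape (H, W, 21): raw intensity; Gaussian blurs at
    sigma 1,2,4,8,16; gradient magnitude at each sigma; difference-of-
    Gaussians of consecutive sigma pairs; and both Hessian eigenvalues at
    sigma 1,2,4. Borders are handled by reflection; output order is fixed.
    """
    img = np.asarray(frame, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("extract_features expects a single 2-D frame")
    feats = [img]
    blurs = [ndimage.gaussian_filter(img, s, mode="reflect") for s in BLUR_SIGMAS]
    feats.extend(blurs)
    for s in BLUR_SIGMAS:
        gx = ndimage.gaussian_filter(img, s, order=(0, 1), mode="reflect")
        gy = ndimage.gaussian_filter(img, s, order=(1, 0), mode="reflect")
        feats.append(np.hypot(gx, gy))
    for a, b in zip(blurs[:-1], blurs[1:]):
        feats.append(a - b)
    for s in HESSIAN_SIGMAS:
        hrr = ndimage.gaussian_filter(img, s, order=(2, 0), mode="reflect")
        hcc = ndimage.gaussian_filter(img, s, order=(0, 2), mode="reflect")
        hrc = ndimage.gaussian_filter(img, s, order=(1, 1), mode="reflect")
        # closed-form eigenvalues of the symmetric 2x2 Hessian
        tr = 0.5 * (hrr + hcc)
        det = np.sqrt(np.maximum(0.25 * (hrr - hcc) ** 2 + hrc**2, 0.0))
        feats.append(tr + det)
        feats.append(tr - det)
    stack = np.stack(feats, axis=-1)
    if not np.all(np.isfinite(stack)):
        raise FloatingPointError("non-finite feature values")
    return stack


def _augment_pairs(frames, masks, rng):
    """Yield augmented (frame, mask) pairs: flips, 90-degree rotations,
    Gaussian-blur and brightness-jitter copies of each original."""
    for frame, mask in zip(frames, masks):
        yield frame, mask
        yield frame[::-1, :], mask[::-1, :]
        yield frame[:, ::-1], mask[:, ::-1]
        yield np.rot90(frame), np.rot90(mask)
        blurred = ndimage.gaussian_filter(frame.astype(np.float64), 1.0, mode="reflect")
        yield np.clip(np.rint(blurred), 0, 255).astype(np.uint8), mask
        jitter = frame.astype(np.float64) + rng.uniform(-15.0, 15.0)
        yield np.clip(np.rint(jitter), 0, 255).astype(np.uint8), mask


def train_segmenter(
    frames: list[np.ndarray],
    masks: list[np.ndarray],
    seed: int,
    *,
    n_trees: int = 200,
    max_pixels_per_class: int = 10_000,
    augment: bool = True,
    scheme: ClassScheme = SCHEME,
    allow_subset: bool = False,
) -> SegModel:
    """Train the pixel random forest from sparsely labeled masks.

    Masks are uint8 rasters: values 0-3 are class labels, 255 means
    unlabeled (ignored; never a background class). Labeled pixels are
    pooled over all (augmented) frames, capped per class for balance, and
    fed to a 200-tree forest with sqrt-features splits. The model's
    ``oob_error`` is 1 minus the forest's out-of-bag accuracy.
    """
    if len(frames) != len(masks) or not frames:
        raise ValueError("need matching non-empty frame and mask lists")
    rng = np.random.default_rng(seed)
    pairs = _augment_pairs(frames, masks, rng) if augment else zip(frames, masks)

    X_parts: list[np.ndarray] = []
    y_parts: list[np.ndarray] = []
    for frame, mask in pairs:
        mask = np.asarray(mask)
        sel = mask != UNLABELED
        if not sel.any():
            continue
        feats = extract_features(frame)
        X_parts.append(feats[sel])
        y_parts.append(mask[sel].astype(np.int64))
    X = np.concatenate(X_parts)
    y = np.concatenate(y_parts)

    present = np.unique(y)
    missing = [scheme.names[c] for c in range(scheme.n_classes) if c not in present]
    if missing and not allow_subset:
        # allow_subset supports reduced calibration problems (e.g. a
        # two-class toy); the full pipeline requires all four classes
        raise ValueError(f"no labeled training pixels for classes: {', '.join(missing)}")

    keep = np.zeros(len(y), dtype=bool)
    for c in present:
        idx = np.flatnonzero(y == c)
        if len(idx) > max_pixels_per_class:
            idx = rng.choice(idx, size=max_pixels_per_class, replace=False)
        keep[idx] = True
    X, y = X[keep], y[keep]

    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        oob_score=True,
        bootstrap=True,
        random_state=int(seed) % (2**32),
        n_jobs=1,
    )
    forest.fit(X, y)
    return SegModel(
        forest=forest,
        scheme=scheme,
        n_features=X.shape[1],
        oob_error=float(1.0 - forest.oob_score_),
        seed=seed,
        training_meta={
            "n_training_pixels": int(len(y)),
            "per_class": {int(c): int((y == c).sum()) for c in present},
            "n_trees": n_trees,
            "augment": augment,
        },
    )


def segment(model: SegModel, frame: np.ndarray, frame_index: int = 0) -> SegmentationMap:
    """Segment one frame; probabilities are tree-vote fractions.

    Argmax ties break toward the lowest class index (numpy argmax order),
    so the labeling is deterministic.
    """
    feats = extract_features(frame)
    h, w, nf = feats.shape
    if nf != model.n_features:
        raise ValueError(f"feature count {nf} does not match model ({model.n_features})")
    proba = model.forest.predict_proba(feats.reshape(-1, nf))
    # forests trained on a class subset still emit a full 4-class map
    full = np.zeros((h * w, model.scheme.n_classes), dtype=np.float64)
    for j, c in enumerate(model.forest.classes_):
        full[:, int(c)] = proba[:, j]
    labels = np.argmax(full, axis=1).astype(np.uint8)
    return SegmentationMap(
        labels=labels.reshape(h, w),
        probabilities=full.T.reshape(model.scheme.n_classes, h, w),
        frame=frame_index,
    )


def segment_stack_parallel(
    model: SegModel,
    stack: VideoStack,
    plan: SubStackPlan | None = None,
    n_workers: int = 1,
) -> list[SegmentationMap]:
    """Segment every frame of a stack, chunked per the sub-stack plan.

    Output is identical to sequential segmentation regardless of worker
    count: chunks are dispatched to a thread pool and reassembled in frame
    order, and per-frame inference is deterministic.
    """
    if plan is None:
        from .io_preprocess import plan_substacks
        plan = plan_substacks(stack.n_frames, max(n_workers, 1))
    if plan.n_frames and plan.n_frames != stack.n_frames:
        raise ValueError("plan does not cover the stack")
    if not plan.chunk_boundaries:
        return []

    def run_chunk(bounds):
        start, end = bounds
        try:
            return [segment(model, stack.frames[i], frame_index=i) for i in range(start, end)]
        except Exception as exc:  # annotate which chunk failed
            raise RuntimeError(f"segmentation failed in frames [{start}, {end})") from exc

    if n_workers <= 1:
        chunks = [run_chunk(b) for b in plan.chunk_boundaries]
    else:
        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            chunks = list(pool.map(run_chunk, plan.chunk_boundaries))
    return [m for chunk in chunks for m in chunk]
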