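"""Single-vs-multiple classification of PMN detections and cluster counting.

Size or shape alone cannot separate single neutrophils from clusters —
PMN area and geometry vary with activation state — so each detection's
binary mask crop is classified by a compact convolutional network with the
classic LeNet-5 layout: conv(6@5x5) -> pool(2) -> conv(16@5x5) -> pool(2)
-> dense(120) -> dense(84) -> dense(2, softmax). The network is small
enough to train in seconds on one CPU, so it is implemented directly on
NumPy (im2col convolutions, max pooling, Adam, cross-entropy). Crops are
binary masks, not intensities: the decision depends only on segmentation
geometry. Clusters are then counted by dividing their pixel area by the
mean area of same-frame detections classified "single".
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import resize

from .detection import Detection

CROP_SIZE = 32
CLASS_NAMES = ("single", "multiple")


@dataclass
class LabeledCrop:
    """A 32x32 binary mask crop with its single/multiple label."""

    mask: np.ndarray
    label: str

    def __post_init__(self) -> None:
        if self.mask.shape != (CROP_SIZE, CROP_SIZE):
            raise ValueError(f"crop must be {CROP_SIZE}x{CROP_SIZE}")
        if not self.mask.any():
            raise ValueError("crop has no foreground pixels")
        if self.label not in CLASS_NAMES:
            raise ValueError(f"label must be one of {CLASS_NAMES}")


def make_crop(d: Detection, size: int = CROP_SIZE) -> np.ndarray:
    """Render a detection's pixel set as a centered square binary crop.

    The component is placed on a square canvas whose side is the larger
    bounding-box dimension, positioned so the centroid sits at the canvas
    center, then resampled to ``size`` x ``size`` by local averaging and
    re-binarized at 0.5. Integer translations of the component leave the
    crop unchanged.
    """
    coords = np.asarray(d.pixels)
    rmin, cmin = coords.min(axis=0)
    rmax, cmax = coords.max(axis=0)
    h, w = rmax - rmin + 1, cmax - cmin + 1
    side = int(max(h, w))
    # offsets that center the bounding box on the square canvas
    r_off = (side - h) // 2
    c_off = (side - w) // 2
    canvas = np.zeros((side, side), dtype=np.float64)
    canvas[coords[:, 0] - rmin + r_off, coords[:, 1] - cmin + c_off] = 1.0
    if side != size:
        canvas = resize(canvas, (size, size), order=1, anti_aliasing=side > size,
                        preserve_range=True)
    crop = canvas >= 0.5
    if not crop.any():  # keep the invariant for pathological thin shapes
        crop = canvas >= canvas.max()
    return crop


# ---------------------------------------------------------------------------
# network internals


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    # x: (N, C, H, W) -> (N, oh*ow, C*k*k)
    n, c, h, w = x.shape
    win = sliding_window_view(x, (k, k), axis=(2, 3))  # (N, C, oh, ow, k, k)
    oh, ow = win.shape[2], win.shape[3]
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * k * k), oh, ow


class _Conv:
    def __init__(self, c_in, c_out, k, rng):
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.W = rng.normal(0.0, scale, size=(c_out, c_in, k, k))
        self.b = np.zeros(c_out)
        self.k, self.c_in, self.c_out = k, c_in, c_out

    def forward(self, x):
        self._x_shape = x.shape
        cols, oh, ow = _im2col(x, self.k)
        self._cols, self._oh, self._ow = cols, oh, ow
        out = cols @ self.W.reshape(self.c_out, -1).T + self.b
        return out.transpose(0, 2, 1).reshape(x.shape[0], self.c_out, oh, ow)

    def backward(self, dout):
        n = dout.shape[0]
        dmat = dout.reshape(n, self.c_out, -1).transpose(0, 2, 1)  # (N, P, c_out)
        self.dW = np.einsum("npo,npf->of", dmat, self._cols).reshape(self.W.shape)
        self.db = dmat.sum(axis=(0, 1))
        dcols = dmat @ self.W.reshape(self.c_out, -1)  # (N, P, C*k*k)
        dcols = dcols.reshape(n, self._oh, self._ow, self.c_in, self.k, self.k)
        dx = np.zeros(self._x_shape)
        for i in range(self.k):
            for j in range(self.k):
                dx[:, :, i:i + self._oh, j:j + self._ow] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dx

    @property
    def params(self):
        return [("W", self), ("b", self)]


class _MaxPool2:
    def forward(self, x):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        self._arg = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dxr, self._arg[..., None], dout[..., None], axis=-1)
        return dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class _Dense:
    def __init__(self, n_in, n_out, rng):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class _LeNet:
    """conv(6@5x5)-pool-conv(16@5x5)-pool-dense(120)-dense(84)-dense(2)."""

    def __init__(self, seed: int):
        rng = np.random.default_rng(seed)
        self.conv1 = _Conv(1, 6, 5, rng)
        self.pool1 = _MaxPool2()
        self.conv2 = _Conv(6, 16, 5, rng)
        self.pool2 = _MaxPool2()
        self.fc1 = _Dense(16 * 5 * 5, 120, rng)
        self.fc2 = _Dense(120, 84, rng)
        self.fc3 = _Dense(84, 2, rng)
        self.relus = [_ReLU() for _ in range(4)]

    def forward(self, x):
        h = self.relus[0].forward(self.conv1.forward(x))
        h = self.pool1.forward(h)
        h = self.relus[1].forward(self.conv2.forward(h))
        h = self.pool2.forward(h)
        h = h.reshape(x.shape[0], -1)
        h = self.relus[2].forward(self.fc1.forward(h))
        h = self.relus[3].forward(self.fc2.forward(h))
        return self.fc3.forward(h)

    def backward(self, dlogits):
        d = self.fc3.backward(dlogits)
        d = self.fc2.backward(self.relus[3].backward(d))
        d = self.fc1.backward(self.relus[2].backward(d))
        d = d.reshape(d.shape[0], 16, 5, 5)
        d = self.pool2.backward(d)
        d = self.conv2.backward(self.relus[1].backward(d))
        d = self.pool1.backward(d)
        self.conv1.backward(self.relus[0].backward(d))

    def param_layers(self):
        return [self.conv1, self.conv2, self.fc1, self.fc2, self.fc3]

    def predict_proba(self, x):
        logits = self.forward(x)
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)


class _Adam:
    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers, self.lr, self.b1, self.b2, self.eps = layers, lr, beta1, beta2, eps
        self.m = [[np.zeros_like(l.W), np.zeros_like(l.b)] for l in layers]
        self.v = [[np.zeros_like(l.W), np.zeros_like(l.b)] for l in layers]
        self.t = 0

    def step(self):
        self.t += 1
        for i, layer in enumerate(self.layers):
            for j, (p, g) in enumerate([(layer.W, layer.dW), (layer.b, layer.db)]):
                self.m[i][j] = self.b1 * self.m[i][j] + (1 - self.b1) * g
                self.v[i][j] = self.b2 * self.v[i][j] + (1 - self.b2) * g * g
                mhat = self.m[i][j] / (1 - self.b1**self.t)
                vhat = self.v[i][j] / (1 - self.b2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _dihedral(mask: np.ndarray):
    """The 8 flip/90-degree-rotation images of a square mask."""
    out = []
    m = mask
    for _ in range(4):
        out.append(m)
        out.append(m[:, ::-1])
        m = np.rot90(m)
    return out


# ---------------------------------------------------------------------------
# public model


@dataclass
class ClusterModel:
    """Trained single/multiple classifier with its validation error."""

    net: _LeNet
    input_size: int
    classes: tuple[str, str]
    validation_error: float
    training_meta: dict = field(default_factory=dict)

    def predict(self, crops: list[np.ndarray]) -> list[str]:
        x = np.stack([c.astype(np.float64) for c in crops])[:, None]
        proba = self.net.predict_proba(x)
        return [self.classes[i] for i in proba.argmax(axis=1)]

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "ClusterModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, ClusterModel):
            raise TypeError(f"{path} does not contain a ClusterModel")
        return model


def train_cluster_model(
    crops: list[LabeledCrop],
    seed: int,
    *,
    epochs: int = 25,
    batch_size: int = 32,
    lr: float = 1e-3,
    augment: bool = True,
) -> ClusterModel:
    """Train the single/multiple classifier.

    Uses a stratified 80/20 train/validation split, flip and 90-degree
    rotation augmentation of the training portion only, 25 epochs of Adam
    on cross-entropy, and reports ``validation_error`` on the held-out
    crops. Reproducible under a fixed seed.
    """
    labels = np.array([CLASS_NAMES.index(c.label) for c in crops])
    present = set(labels.tolist())
    if present != {0, 1}:
        missing = [CLASS_NAMES[i] for i in (0, 1) if i not in present]
        raise ValueError(f"both classes required for training; missing: {missing}")
    rng = np.random.default_rng(seed)

    train_idx, val_idx = [], []
    for c in (0, 1):
        idx = np.flatnonzero(labels == c)
        idx = rng.permutation(idx)
        n_val = max(1, int(round(0.2 * len(idx))))
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])

    x_train, y_train = [], []
    for i in train_idx:
        views = _dihedral(crops[i].mask) if augment else [crops[i].mask]
        for v in views:
            x_train.append(np.ascontiguousarray(v, dtype=np.float64))
            y_train.append(labels[i])
    x_train = np.stack(x_train)[:, None]
    y_train = np.array(y_train)
    x_val = np.stack([crops[i].mask.astype(np.float64) for i in val_idx])[:, None]
    y_val = np.array([labels[i] for i in val_idx])

    net = _LeNet(seed)
    opt = _Adam(net.param_layers(), lr=lr)
    n = len(y_train)
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            sel = order[start:start + batch_size]
            xb, yb = x_train[sel], y_train[sel]
            logits = net.forward(xb)
            logits = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            proba = e / e.sum(axis=1, keepdims=True)
            dlogits = proba.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            net.backward(dlogits / len(yb))
            opt.step()

    val_pred = net.predict_proba(x_val).argmax(axis=1)
    val_err = float(np.mean(val_pred != y_val))
    return ClusterModel(
        net=net,
        input_size=CROP_SIZE,
        classes=CLASS_NAMES,
        validation_error=val_err,
        training_meta={
            "epochs": epochs, "optimizer": "adam", "lr": lr, "seed": seed,
            "split": "80/20 stratified", "n_train": int(n), "n_val": int(len(y_val)),
            "augment": augment,
        },
    )


def estimate_count(d: Detection, mean_single_area: float) -> int:
    """Estimated cells in a detection: 1 for singles, area division for
    clusters with a floor of 2 (``multiple`` means at least two cells)."""
    if d.single_multi == "single":
        return 1
    if d.single_multi == "multiple":
        if mean_single_area <= 0:
            raise ValueError("mean_single_area must be positive")
        return max(2, int(round(d.area_px / mean_single_area)))
    raise ValueError("detection has no single/multiple label")


def count_frame(detections: list[Detection]) -> int:
    """Total estimated PMNs in one frame."""
    return sum(d.est_count for d in detections)


def annotate_counts(
    detections_by_frame: dict[int, list[Detection]],
    model: ClusterModel,
    fallback_mean_single_area: float | None = None,
) -> dict[int, list[Detection]]:
    """Classify every detection and fill in per-cell count estimates.

    ``mean_single_area`` is the mean area of same-frame detections
    classified single; a frame with no singles falls back to the running
    mean over the trailing 10 frames, then to
    ``fallback_mean_single_area`` (e.g. the training-set mean).
    """
    recent_means: list[float] = []
    for frame in sorted(detections_by_frame):
        dets = detections_by_frame[frame]
        if not dets:
            continue
        preds = model.predict([make_crop(d) for d in dets])
        for d, p in zip(dets, preds):
            d.single_multi = p
        singles = [d.area_px for d in dets if d.single_multi == "single"]
        if singles:
            mean_single = float(np.mean(singles))
            recent_means.append(mean_single)
            recent_means = recent_means[-10:]
        elif recent_means:
            mean_single = float(np.mean(recent_means))
        elif fallback_mean_single_area is not None:
            mean_single = fallback_mean_single_area
        else:
            raise ValueError(
                f"frame {frame}: no single detections and no fallback mean single area"
            )
        for d in dets:
            d.est_count = estimate_count(d, mean_single)
    return detections_by_frame
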