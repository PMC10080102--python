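"""Seeded synthetic phase-contrast video generator with full ground truth.

Emulates the imaging phenomenology of neutrophils trafficking on an
endothelial monolayer: luminal PMNs render as phase-bright rounded discs
with a bright halo rim, "probing" luminal PMNs additionally oscillate
their boundary, and transmigrated PMNs render as darker amorphous blobs
(low-order Fourier boundary perturbation) against a band-limited textured
background. Transmigrating cells blend linearly bright-to-dark over a few
frames (a transmigration event spans ~5 frames / 20 s at 0.25 Hz) and
switch ground-truth state at the half-blend point. Cell motion is an
exactly discretized 2-D Ornstein-Uhlenbeck velocity process with
relaxation time P and per-component stationary variance S^2/2, whose
closed-form MSD equals the persistent-random-walk (Dunn) model with
parameters S and P — so motility parameter-recovery tests are sharp.
Boundaries are reflective, so the population is conserved in every frame.
Every stochastic draw is fixed by the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_preprocess import VideoStack
from .segmentation import SCHEME, ClassScheme
from .tracking import TrackFragment


@dataclass
class SimConfig:
    """Synthetic video scenario.

    Defaults describe the nominal recording: 450 frames at 0.25 Hz.
    ``size`` defaults to 512 so full pipeline tests run in minutes; use
    1024 for full-scale runs. Cell radii are set so single cells comfortably
    exceed the 600-pixel detection noise floor.
    """

    n_frames: int = 450
    frame_interval_s: float = 4.0
    size: int = 512
    n_cells: int = 30
    fraction_transmigrating: float = 0.2
    transmigration_onset_window: tuple[int, int] = (20, 80)
    transmigration_duration: int = 5
    # persistent-random-walk motion, per state
    speed_luminal: float = 0.15        # S, px/s
    persistence_luminal: float = 40.0  # P, s
    speed_abluminal: float = 0.15
    persistence_abluminal: float = 40.0
    immobile_fraction: float = 0.25
    # geometry
    radius_mean: float = 16.5          # px; area ~ 850 px > 600-px noise floor
    radius_sd: float = 1.5
    min_radius: float = 15.0           # imaged PMN size floor: single cells
                                       # always exceed the detection noise area
    boundary_amp: float = 0.22         # abluminal amorphous perturbation
    probing_osc_amp: float = 0.10      # probing boundary oscillation
    # photometry (8-bit scale)
    bg_mean: float = 120.0
    bg_contrast: float = 10.0
    bg_texture_scale: float = 6.0      # px
    luminal_brightness: float = 70.0
    probing_brightness_factor: float = 0.6  # probing PMNs flatten and lose
                                            # phase brightness vs static ones
    rim_brightness: float = 25.0
    abluminal_darkness: float = 45.0
    noise_sd: float = 5.0
    clustering_rate: float = 0.0       # fraction of cells placed in clusters
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_transmigrating", "immobile_fraction", "clustering_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.transmigration_duration < 1:
            raise ValueError("transmigration_duration must be >= 1")
        if self.n_frames < 1 or self.n_cells < 0 or self.size < 32:
            raise ValueError("invalid scenario dimensions")


@dataclass
class GroundTruth:
    """Complete per-frame truth for a simulated stack."""

    masks: np.ndarray            # (T, H, W) uint8, 4-class labels
    cells: pd.DataFrame          # frame, cell_id, x, y, state, cluster_id
    counts: np.ndarray           # per-frame cell count
    transmigrated_fraction: np.ndarray
    config: SimConfig = field(repr=False, default=None)

    def tracks(self) -> list[TrackFragment]:
        """The true trajectories as track fragments (one per cell)."""
        out = []
        for cid, grp in self.cells.groupby("cell_id"):
            grp = grp.sort_values("frame")
            fr = TrackFragment(
                fragment_id=int(cid),
                frames=grp["frame"].tolist(),
                xs=grp["x"].tolist(),
                ys=grp["y"].tolist(),
                states=grp["state"].tolist(),
                det_ids=[-1] * len(grp),
            )
            out.append(fr)
        return out


def _ou_updates(n_steps: int, n_walkers: int, S: float, P: float, dt: float, rng):
    """Exact discrete-time sample of the integrated OU velocity process.

    Returns position increments dx[(step, walker)] and velocities; the
    velocity has per-component stationary variance sigma^2 = S^2/2 and
    relaxation time P, so the 2-D MSD is exactly
    2 S^2 P [t - P(1 - e^(-t/P))].
    """
    sigma2 = S * S / 2.0
    mu = np.exp(-dt / P)
    var_v = sigma2 * (1.0 - mu * mu)
    var_x = 2.0 * sigma2 * P * (dt - 2.0 * P * (1.0 - mu) + 0.5 * P * (1.0 - mu * mu))
    cov_xv = sigma2 * P * (1.0 - mu) ** 2
    var_x = max(var_x, 0.0)
    a = np.sqrt(var_x)
    b = cov_xv / a if a > 0 else 0.0
    c = np.sqrt(max(var_v - b * b, 0.0))
    v = rng.normal(0.0, np.sqrt(sigma2), size=(n_walkers, 2))
    dxs = np.empty((n_steps, n_walkers, 2))
    for k in range(n_steps):
        z1 = rng.standard_normal((n_walkers, 2))
        z2 = rng.standard_normal((n_walkers, 2))
        xi_x = a * z1
        xi_v = b * z1 + c * z2
        dxs[k] = P * (1.0 - mu) * v + xi_x
        v = mu * v + xi_v
    return dxs


def simulate_ou_fragments(
    n_fragments: int,
    n_frames: int,
    S: float,
    P: float,
    frame_interval_s: float = 4.0,
    seed: int = 0,
    state: str = "luminal",
) -> list[TrackFragment]:
    """Unbounded OU-velocity walks as ready-made track fragments.

    Used for motility parameter-recovery studies: the fragments' exact
    ensemble MSD is the Dunn model with the given S and P.
    """
    rng = np.random.default_rng(seed)
    dxs = _ou_updates(n_frames - 1, n_fragments, S, P, frame_interval_s, rng)
    pos = np.concatenate([np.zeros((1, n_fragments, 2)), np.cumsum(dxs, axis=0)])
    frags = []
    for i in range(n_fragments):
        frags.append(TrackFragment(
            fragment_id=i,
            frames=list(range(n_frames)),
            xs=pos[:, i, 0].tolist(),
            ys=pos[:, i, 1].tolist(),
            states=[state] * n_frames,
            det_ids=[-1] * n_frames,
        ))
    return frags


def _place_cells(cfg: SimConfig, radii: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    """Initial positions with optional cluster seeding.

    Clustered cells are placed touching their anchor so connected
    components of the rendered masks contain known multiplicities.
    Raises when the field is too dense to place cells without full overlap.
    """
    margin = radii.max() * 2.0 + 4.0
    lo, hi = margin, cfg.size - margin
    if hi <= lo:
        raise ValueError("field too small for the configured cell size")
    pos = np.zeros((cfg.n_cells, 2))
    cluster_id = np.arange(cfg.n_cells)
    n_clustered = int(round(cfg.clustering_rate * cfg.n_cells))
    placed: list[int] = []
    for i in range(cfg.n_cells):
        attach = placed and i >= cfg.n_cells - n_clustered
        for _ in range(500):
            if attach:
                j = placed[int(rng.integers(len(placed)))]
                ang = rng.uniform(0, 2 * np.pi)
                d = (radii[i] + radii[j]) * rng.uniform(0.75, 0.95)
                cand = pos[j] + d * np.array([np.cos(ang), np.sin(ang)])
                cand = np.clip(cand, lo, hi)
                min_sep_ok = True
                for k in placed:
                    if k == j:
                        continue
                    if np.hypot(*(cand - pos[k])) < 0.8 * (radii[i] + radii[k]):
                        min_sep_ok = False
                        break
                if min_sep_ok:
                    pos[i] = cand
                    cluster_id[i] = cluster_id[j]
                    break
            else:
                cand = rng.uniform(lo, hi, size=2)
                if all(np.hypot(*(cand - pos[k])) > 2.6 * max(radii[i], radii[k]) for k in placed):
                    pos[i] = cand
                    break
        else:
            raise ValueError("over-dense configuration: could not place all cells")
        placed.append(i)
    return pos, cluster_id


def _render_cell(img, mask, x, y, radius, kind, blend, t, cfg: SimConfig, shape_coeffs, scheme: ClassScheme):
    """Draw one cell into the intensity image and truth mask.

    ``blend`` in [0, 1] interpolates bright luminal rendering into dark
    amorphous abluminal rendering; truth class flips past blend 0.5.
    """
    r_max = radius * (1.0 + cfg.boundary_amp * 3 + cfg.probing_osc_amp) + 4.0
    size = img.shape[0]
    r0 = max(int(np.floor(y - r_max)), 0)
    r1 = min(int(np.ceil(y + r_max)) + 1, size)
    c0 = max(int(np.floor(x - r_max)), 0)
    c1 = min(int(np.ceil(x + r_max)) + 1, size)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy = yy - y
    dx = xx - x
    rho = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)

    # angular radius profile
    rb = np.full_like(rho, radius)
    if blend > 0:  # amorphous component grows in as the cell transmigrates
        amorphous = np.zeros_like(theta)
        for k, (amp, phase) in enumerate(shape_coeffs, start=2):
            amorphous += amp * np.cos(k * theta + phase)
        rb = rb * (1.0 + blend * amorphous)
    if kind == "probing" and blend < 1.0:
        rb = rb * (1.0 + cfg.probing_osc_amp * np.cos(3 * theta + 0.35 * t + shape_coeffs[0][1]))

    inside = rho <= rb
    edge = rb - rho
    soft = np.clip(edge / 2.0 + 0.5, 0.0, 1.0)  # 2-px feathered edge
    body = cfg.luminal_brightness * (cfg.probing_brightness_factor if kind == "probing" else 1.0)
    bright = body * soft + cfg.rim_brightness * np.exp(-((rho - rb) / 2.5) ** 2)
    dark = -cfg.abluminal_darkness * soft
    img[r0:r1, c0:c1] += (1.0 - blend) * bright + blend * dark

    if blend > 0.5:
        cls = scheme.TRANSMIGRATED
    elif kind == "probing":
        cls = scheme.LUMINAL_PROBING
    else:
        cls = scheme.LUMINAL_STATIC
    region = mask[r0:r1, c0:c1]
    region[inside] = cls


def simulate(cfg: SimConfig, scheme: ClassScheme = SCHEME) -> tuple[VideoStack, GroundTruth]:
    """Generate a synthetic stack and its complete ground truth."""
    rng = np.random.default_rng(cfg.seed)
    radii = np.clip(rng.normal(cfg.radius_mean, cfg.radius_sd, size=cfg.n_cells),
                    cfg.min_radius, cfg.radius_mean * 1.5)
    pos0, cluster_id = _place_cells(cfg, radii, rng)

    n_trans = int(round(cfg.fraction_transmigrating * cfg.n_cells))
    trans_ids = rng.choice(cfg.n_cells, size=n_trans, replace=False) if n_trans else np.array([], int)
    lo_w, hi_w = cfg.transmigration_onset_window
    hi_w = min(hi_w, max(cfg.n_frames - cfg.transmigration_duration - 1, lo_w + 1))
    onset = np.full(cfg.n_cells, -1)
    if n_trans:
        onset[trans_ids] = rng.integers(lo_w, hi_w + 1, size=n_trans)

    n_immobile = int(round(cfg.immobile_fraction * cfg.n_cells))
    immobile = np.zeros(cfg.n_cells, dtype=bool)
    if n_immobile:
        immobile[rng.choice(cfg.n_cells, size=n_immobile, replace=False)] = True

    # per-cell amorphous shape coefficients (fixed through the video)
    shape_coeffs = [
        [(rng.uniform(0.3, 1.0) * cfg.boundary_amp, rng.uniform(0, 2 * np.pi)) for _ in range(3)]
        for _ in range(cfg.n_cells)
    ]

    # motion: luminal parameters until transmigration completes, then
    # abluminal; approximated by drawing each cell's whole path with the
    # parameters of its majority state (transition is ~5 frames of 450)
    dt = cfg.frame_interval_s
    lum_dx = _ou_updates(cfg.n_frames - 1, cfg.n_cells, cfg.speed_luminal,
                         cfg.persistence_luminal, dt, rng)
    ab_dx = _ou_updates(cfg.n_frames - 1, cfg.n_cells, cfg.speed_abluminal,
                        cfg.persistence_abluminal, dt, rng)

    margin = radii.max() + 3.0
    lo_b, hi_b = margin, cfg.size - margin

    bg = ndimage.gaussian_filter(rng.normal(0.0, 1.0, size=(cfg.size, cfg.size)),
                                 cfg.bg_texture_scale, mode="reflect")
    bg = cfg.bg_mean + cfg.bg_contrast * bg / max(bg.std(), 1e-9)

    frames = np.empty((cfg.n_frames, cfg.size, cfg.size), dtype=np.uint8)
    masks = np.zeros((cfg.n_frames, cfg.size, cfg.size), dtype=np.uint8)
    cell_rows = []
    trans_frac = np.zeros(cfg.n_frames)

    pos = pos0.copy()
    # members of a cluster share their anchor's displacement so clusters persist
    anchor = np.array([np.flatnonzero(cluster_id == cluster_id[i])[0] for i in range(cfg.n_cells)])
    for t in range(cfg.n_frames):
        img = bg.copy()
        mask = masks[t]
        n_ab = 0
        for i in np.argsort(radii):  # draw smaller cells first
            xi, yi = pos[i]
            if onset[i] < 0 or t < onset[i]:
                blend = 0.0
            else:
                blend = min((t - onset[i] + 1) / cfg.transmigration_duration, 1.0)
            state = "abluminal" if blend > 0.5 else "luminal"
            if state == "abluminal":
                n_ab += 1
            kind = "static" if immobile[i] else "probing"
            _render_cell(img, mask, xi, yi, radii[i], kind, blend, t, cfg,
                         shape_coeffs[i], scheme)
            cell_rows.append({
                "frame": t, "cell_id": i, "x": xi, "y": yi,
                "state": state, "cluster_id": int(cluster_id[i]),
            })
        trans_frac[t] = n_ab / cfg.n_cells if cfg.n_cells else 0.0
        if cfg.noise_sd > 0:
            img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
        frames[t] = np.clip(np.rint(img), 0, 255).astype(np.uint8)

        if t < cfg.n_frames - 1:
            for i in range(cfg.n_cells):
                a = anchor[i]
                if immobile[a]:
                    continue
                use_ab = onset[a] >= 0 and t >= onset[a] + cfg.transmigration_duration
                step = ab_dx[t, a] if use_ab else lum_dx[t, a]
                pos[i] = pos[i] + step
            # reflective boundaries (population conservation)
            for i in range(cfg.n_cells):
                for d in range(2):
                    if pos[i, d] < lo_b:
                        pos[i, d] = 2 * lo_b - pos[i, d]
                    elif pos[i, d] > hi_b:
                        pos[i, d] = 2 * hi_b - pos[i, d]

    cells = pd.DataFrame(cell_rows, columns=["frame", "cell_id", "x", "y", "state", "cluster_id"])
    counts = cells.groupby("frame").size().reindex(range(cfg.n_frames), fill_value=0).to_numpy()
    stack = VideoStack(frames, frame_interval_s=cfg.frame_interval_s)
    truth = GroundTruth(masks=masks, cells=cells, counts=counts,
                        transmigrated_fraction=trans_frac, config=cfg)
    return stack, truth


def make_training_fixtures(
    cfg: SimConfig,
    n_label_frames: int = 6,
    n_videos: int = 3,
    max_labeled_per_class: int = 4000,
    n_crops_per_class: int = 800,
):
    """Training substrate for the segmenter and the cluster classifier.

    Returns ``(frames, sparse_masks, crops)``: simulated frames with
    sparsely labeled masks (a random subset of the dense truth per class,
    the rest unlabeled — mimicking manual masking), plus labeled 32x32
    single/multiple binary crops generated from the same cell-shape model.
    Label frames are drawn from ``n_videos`` scenario variants with
    distinct backgrounds and cell placements, as a training set built from
    several recordings would be — a segmenter trained on a single video
    memorizes that video's background texture.
    """
    from dataclasses import replace as dc_replace

    from .classify import CROP_SIZE, LabeledCrop, make_crop
    from .detection import Detection

    rng = np.random.default_rng(cfg.seed + 1)
    n_videos = max(1, min(n_videos, n_label_frames))
    per_video = int(np.ceil(n_label_frames / n_videos))
    frame_sources = []
    for k in range(n_videos):
        vcfg = dc_replace(cfg, seed=cfg.seed + 101 * k)
        v_stack, v_truth = simulate(vcfg)
        for t in np.linspace(0, vcfg.n_frames - 1, per_video).astype(int):
            frame_sources.append((v_stack.frames[t], v_truth.masks[t]))
    frame_sources = frame_sources[:n_label_frames]

    frames, sparse_masks = [], []
    for frame_img, dense in frame_sources:
        sparse = np.full_like(dense, 255)
        # annotators label background around cells (where the phase halo
        # lives), so half the background labels come from the rim band
        rim = ndimage.binary_dilation(dense > 0, iterations=6) & (dense == 0)
        for c in range(4):
            sel_mask = dense == c
            rows, cols = np.nonzero(sel_mask)
            if len(rows) == 0:
                continue
            if c == 0 and rim.any():
                n_rim = min(max_labeled_per_class // 2, int(rim.sum()))
                rr, rc = np.nonzero(rim)
                pick = rng.choice(len(rr), size=n_rim, replace=False)
                sparse[rr[pick], rc[pick]] = 0
                far = sel_mask & ~rim
                fr_, fc_ = np.nonzero(far)
                n_far = min(max_labeled_per_class - n_rim, len(fr_))
                pick = rng.choice(len(fr_), size=n_far, replace=False)
                sparse[fr_[pick], fc_[pick]] = 0
                continue
            if len(rows) > max_labeled_per_class:
                sel = rng.choice(len(rows), size=max_labeled_per_class, replace=False)
                rows, cols = rows[sel], cols[sel]
            sparse[rows, cols] = c
        frames.append(frame_img)
        sparse_masks.append(sparse)

    crops: list[LabeledCrop] = []
    canvas_size = int(cfg.radius_mean * 8)
    for label, n_blobs_choices in (("single", [1]), ("multiple", [2, 2, 3])):
        while sum(c.label == label for c in crops) < n_crops_per_class:
            n_blobs = n_blobs_choices[int(rng.integers(len(n_blobs_choices)))]
            canvas = np.zeros((canvas_size, canvas_size), dtype=bool)
            cx = cy = canvas_size / 2
            centers = [(cx, cy)]
            for b in range(1, n_blobs):
                ang = rng.uniform(0, 2 * np.pi)
                d = cfg.radius_mean * rng.uniform(1.3, 1.8)
                px, py = centers[int(rng.integers(len(centers)))]
                centers.append((px + d * np.cos(ang), py + d * np.sin(ang)))
            for (bx, by) in centers:
                r = float(np.clip(rng.normal(cfg.radius_mean, cfg.radius_sd),
                                  cfg.min_radius, cfg.radius_mean * 1.5))
                yy, xx = np.mgrid[:canvas_size, :canvas_size]
                theta = np.arctan2(yy - by, xx - bx)
                wobble = 1.0 + sum(
                    rng.uniform(0.0, cfg.boundary_amp) * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
                    for k in range(2, 5)
                )
                canvas |= np.hypot(xx - bx, yy - by) <= r * wobble
            coords = np.argwhere(canvas)
            if len(coords) == 0:
                continue
            det = Detection(
                frame=0, det_id=0, pixels=coords, area_px=len(coords),
                centroid=(float(coords[:, 1].mean()), float(coords[:, 0].mean())),
                radius_px=np.sqrt(len(coords) / np.pi),
                class_fractions=(1.0, 0.0, 0.0),
            )
            crop = make_crop(det, CROP_SIZE)
            if crop.any():
                crops.append(LabeledCrop(mask=crop, label=label))
    return frames, sparse_masks, crops
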