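"""Per-fragment motility analytics.

Each sufficiently long track fragment is summarized by its meandering
index (net displacement over path length), its time-averaged mean-squared
displacement (MSD) up to a maximum lag, and the speed S and persistence
time P obtained by fitting the persistent-random-walk (Dunn) model

    MSD(t) = 2 S^2 P [ t - P (1 - exp(-t/P)) ]

to the MSD curve. In the short-time limit (t << P) the model is ballistic,
MSD ~ S^2 t^2; in the long-time limit it is diffusive, MSD ~ 2 S^2 P t.
Group summaries mirror the standard comparisons: all long fragments, the
15 longest, 15 random, luminal vs abluminal by bulk fragment state, and
reactive vs non-reactive by a meandering-index threshold of 0.1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .tracking import TrackFragment

MIN_FIT_FRAMES = 100         # fragments longer than this are fit
DEFAULT_TAU_MAX_S = 120.0
NONREACTIVE_MI = 0.1


@dataclass
class MotilitySummary:
    """Motility metrics for one track fragment."""

    fragment_id: int
    n_frames: int
    speed: float                # px/s (um/s if coordinates were converted)
    persistence: float          # s
    meandering_index: float
    msd_curve: np.ndarray       # (n_lags, 2): lag seconds, MSD px^2
    fit_rss: float
    converged: bool
    bulk_state: str = "luminal"
    group: str = "all_long"


def dunn_msd(t: np.ndarray, S: float, P: float) -> np.ndarray:
    """Persistent-random-walk MSD model, 2 S^2 P [t - P(1 - e^(-t/P))]."""
    t = np.asarray(t, dtype=np.float64)
    return 2.0 * S * S * P * (t - P * (1.0 - np.exp(-t / P)))


def meandering_index(fragment: TrackFragment) -> float:
    """Net displacement divided by total path length; 0 for a zero-length path."""
    if fragment.n_points < 2:
        raise ValueError("meandering index needs at least 2 points")
    x = np.asarray(fragment.xs)
    y = np.asarray(fragment.ys)
    steps = np.hypot(np.diff(x), np.diff(y))
    path = steps.sum()
    if path == 0:
        return 0.0
    disp = float(np.hypot(x[-1] - x[0], y[-1] - y[0]))
    return disp / path


def msd(
    fragment: TrackFragment,
    frame_interval_s: float = 4.0,
    tau_max_s: float = DEFAULT_TAU_MAX_S,
) -> np.ndarray:
    """Time-averaged MSD over all overlapping lag pairs.

    Lags run from one frame up to ``tau_max_s`` (30 lags at 4 s/frame).
    Requires uniformly spaced points (no dropped frames within the
    fragment).
    """
    f = np.asarray(fragment.frames)
    if fragment.n_points < 2:
        raise ValueError("msd needs at least 2 points")
    if not np.all(np.diff(f) == 1):
        raise ValueError("msd requires a gap-free fragment (uniform frame spacing)")
    x = np.asarray(fragment.xs)
    y = np.asarray(fragment.ys)
    max_lag = min(int(tau_max_s / frame_interval_s), fragment.n_points - 1)
    curve = np.empty((max_lag, 2))
    for lag in range(1, max_lag + 1):
        dx = x[lag:] - x[:-lag]
        dy = y[lag:] - y[:-lag]
        curve[lag - 1] = (lag * frame_interval_s, np.mean(dx * dx + dy * dy))
    return curve


def fit_dunn(
    msd_curve: np.ndarray,
    p_starts: tuple[float, ...] = (5.0, 20.0, 80.0, 320.0),
    p_max: float = 1e4,
) -> tuple[float, float, float, bool]:
    """Fit the persistent-random-walk model to an MSD curve.

    Unweighted nonlinear least squares with multistart over the
    persistence initializer; the speed is initialized from the first-lag
    slope (ballistic guess S ~ sqrt(MSD1)/t1). Returns (S, P, rss,
    converged); near-ballistic curves report a persistence at the upper
    bound, flagged converged (the fit is a lower bound on P).
    """
    curve = np.asarray(msd_curve, dtype=np.float64)
    if curve.ndim != 2 or curve.shape[0] < 5:
        raise ValueError("need at least 5 MSD lag points")
    t, m = curve[:, 0], curve[:, 1]
    s0 = max(np.sqrt(max(m[0], 1e-12)) / t[0], 1e-9)

    def residual(theta):
        logS, logP = theta
        return dunn_msd(t, np.exp(logS), np.exp(logP)) - m

    best = None
    for p0 in p_starts:
        try:
            res = least_squares(
                residual,
                x0=[np.log(s0), np.log(p0)],
                bounds=([-30.0, np.log(1e-3)], [30.0, np.log(p_max)]),
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[2]:
            best = (float(np.exp(res.x[0])), float(np.exp(res.x[1])), rss, res.success)
    if best is None:
        return float("nan"), float("nan"), float("nan"), False
    return best


def summarize_fragment(
    fragment: TrackFragment,
    frame_interval_s: float = 4.0,
    tau_max_s: float = DEFAULT_TAU_MAX_S,
    pixel_size_um: float | None = None,
) -> MotilitySummary:
    """Full motility summary (MI, MSD, Dunn fit) for one fragment."""
    curve = msd(fragment, frame_interval_s, tau_max_s)
    if pixel_size_um is not None:
        curve = curve.copy()
        curve[:, 1] *= pixel_size_um**2
    S, P, rss, ok = fit_dunn(curve)
    return MotilitySummary(
        fragment_id=fragment.fragment_id,
        n_frames=fragment.n_points,
        speed=S,
        persistence=P,
        meandering_index=meandering_index(fragment),
        msd_curve=curve,
        fit_rss=rss,
        converged=ok,
        bulk_state=fragment.bulk_state,
    )


def analyze_fragments(
    fragments: list[TrackFragment],
    frame_interval_s: float = 4.0,
    tau_max_s: float = DEFAULT_TAU_MAX_S,
    min_frames: int = MIN_FIT_FRAMES,
    pixel_size_um: float | None = None,
) -> list[MotilitySummary]:
    """Summarize every fragment longer than ``min_frames`` frames.

    Non-convergent fits are kept in the list but flagged; group statistics
    exclude them (with a logged count).
    """
    out = []
    for fr in fragments:
        if fr.n_points <= min_frames:
            continue
        out.append(summarize_fragment(fr, frame_interval_s, tau_max_s, pixel_size_um))
    n_bad = sum(not s.converged for s in out)
    if n_bad:
        warnings.warn(f"{n_bad} fragment fits did not converge; excluded from group stats")
    return out


def group_summaries(
    summaries: list[MotilitySummary],
    manual: list[MotilitySummary] | None = None,
    n_select: int = 15,
    seed: int = 0,
    mi_threshold: float = NONREACTIVE_MI,
) -> pd.DataFrame:
    """Per-group mean +/- SEM of speed, persistence and meandering index.

    Groups: all long fragments, the ``n_select`` longest, ``n_select``
    random (seeded), luminal/abluminal by bulk state, non-reactive
    (MI < ``mi_threshold``) and reactive, plus optional manual tracks.
    """
    ok = [s for s in summaries if s.converged and np.isfinite(s.speed)]
    rng = np.random.default_rng(seed)
    groups: dict[str, list[MotilitySummary]] = {"all_long": ok}
    by_len = sorted(ok, key=lambda s: (-s.n_frames, s.fragment_id))
    groups[f"longest{n_select}"] = by_len[:n_select]
    if len(ok) > n_select:
        idx = rng.choice(len(ok), size=n_select, replace=False)
        groups[f"random{n_select}"] = [ok[i] for i in sorted(idx)]
    else:
        groups[f"random{n_select}"] = list(ok)
    groups["luminal"] = [s for s in ok if s.bulk_state == "luminal"]
    groups["abluminal"] = [s for s in ok if s.bulk_state == "abluminal"]
    groups["nonreactive"] = [s for s in ok if s.meandering_index < mi_threshold]
    groups["reactive"] = [s for s in ok if s.meandering_index >= mi_threshold]
    if manual is not None:
        groups["manual"] = list(manual)

    rows = []
    for name, members in groups.items():
        if not members:
            rows.append({"group": name, "n": 0})
            continue
        vals = {m: np.array([getattr(s, m) for s in members])
                for m in ("speed", "persistence", "meandering_index")}
        row = {"group": name, "n": len(members)}
        for m, v in vals.items():
            row[f"{m}_mean"] = float(v.mean())
            row[f"{m}_sem"] = float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def spider_plot_table(fragments: list[TrackFragment]) -> pd.DataFrame:
    """Origin-shifted (x, y) per fragment for spider-plot rendering."""
    rows = []
    for fr in fragments:
        x0, y0 = fr.xs[0], fr.ys[0]
        for f, x, y in zip(fr.frames, fr.xs, fr.ys):
            rows.append({"fragment_id": fr.fragment_id, "frame": f,
                         "x": x - x0, "y": y - y0})
    return pd.DataFrame(rows, columns=["fragment_id", "frame", "x", "y"])


def summaries_to_frame(summaries: list[MotilitySummary]) -> pd.DataFrame:
    rows = [{
        "fragment_id": s.fragment_id, "group": s.group, "n_frames": s.n_frames,
        "speed": s.speed, "persistence": s.persistence,
        "meandering_index": s.meandering_index, "fit_rss": s.fit_rss,
        "converged": s.converged, "bulk_state": s.bulk_state,
    } for s in summaries]
    return pd.DataFrame(rows, columns=[
        "fragment_id", "group", "n_frames", "speed", "persistence",
        "meandering_index", "fit_rss", "converged", "bulk_state",
    ])
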