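"""Single-nucleus tracking, post-mitotic decay normalization, chase half-lives,
and PCNA-pattern phase-transition timing.

Nuclear abundance after mitosis (or after translation block in a
cycloheximide chase) is modelled as first-order decay, N(t) = N0 e^(-k t),
with half-life t1/2 = ln 2 / k.  Decay is fitted by linear regression of
log abundance on time — closed form, robust for the short 4-point chases this
targets; a nonlinear refinement on the original scale is available.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import optimize, stats


@dataclass
class NucleusTrack:
    """Time series of nuclear MFI for one tracked nucleus."""

    track_id: int
    frames: list[int]
    times: list[float]                  # minutes
    mfi: list[float]
    xy: list[tuple[float, float]] = field(default_factory=list)
    relative_mfi: list[float] | None = None
    pcna_pattern: list[str] | None = None
    phase_boundaries: dict[str, int] | None = None

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class DecayFit:
    """Result of an exponential-decay fit."""

    n0: float
    rate_k: float          # per hour
    half_life: float       # hours; inf when rate_k == 0
    r_squared: float
    n_points: int


def link_tracks(
    per_frame: pd.DataFrame,
    max_disp: float = 20.0,
    frame_col: str = "frame",
    x_col: str = "centroid_x",
    y_col: str = "centroid_y",
    mfi_col: str = "cgas_gfp_mfi_corrected",
    frame_interval_min: float = 5.0,
) -> list[NucleusTrack]:
    """Link per-frame detections into tracks by greedy nearest-centroid matching.

    Frame-to-frame pairs are assigned in order of increasing distance (ties to
    the lower label id); assignments farther than ``max_disp`` pixels start
    new tracks and unmatched tracks terminate.  Every detection joins at most
    one track.
    """
    frames = sorted(per_frame[frame_col].unique())
    tracks: list[NucleusTrack] = []
    active: dict[int, NucleusTrack] = {}  # track index -> track
    next_id = 1

    prev_pos: list[tuple[float, float]] = []
    prev_track: list[int] = []
    for fi, fr in enumerate(frames):
        sub = per_frame[per_frame[frame_col] == fr].sort_values(
            by="cell_id" if "cell_id" in per_frame else x_col
        )
        pos = list(zip(sub[x_col].to_numpy(float), sub[y_col].to_numpy(float)))
        vals = sub[mfi_col].to_numpy(float)
        t = fi * frame_interval_min

        assigned_det = [-1] * len(pos)
        if prev_pos and pos:
            cand = []
            for i, (px, py) in enumerate(prev_pos):
                for j, (x, y) in enumerate(pos):
                    d = math.hypot(px - x, py - y)
                    if d <= max_disp:
                        cand.append((d, i, j))
            cand.sort()
            used_prev: set[int] = set()
            used_det: set[int] = set()
            for d, i, j in cand:
                if i in used_prev or j in used_det:
                    continue
                used_prev.add(i)
                used_det.add(j)
                assigned_det[j] = prev_track[i]
        new_prev_pos, new_prev_track = [], []
        for j, (x, y) in enumerate(pos):
            ti = assigned_det[j]
            if ti < 0:
                tr = NucleusTrack(track_id=next_id, frames=[], times=[], mfi=[], xy=[])
                next_id += 1
                tracks.append(tr)
                ti = len(tracks) - 1
            tr = tracks[ti]
            tr.frames.append(int(fr))
            tr.times.append(t)
            tr.mfi.append(float(vals[j]))
            tr.xy.append((x, y))
            new_prev_pos.append((x, y))
            new_prev_track.append(ti)
        prev_pos, prev_track = new_prev_pos, new_prev_track
    return tracks


def normalize_track(track: NucleusTrack, reference_index: int = 0) -> NucleusTrack:
    """Express a track's MFI relative to a reference frame (default: first).

    The reference frame is the first post-mitotic frame in the live-imaging
    use; ``relative_mfi[reference_index] == 1`` afterwards.
    """
    ref = track.mfi[reference_index]
    if not ref > 0:
        raise ValueError("reference MFI must be positive")
    track.relative_mfi = [v / ref for v in track.mfi]
    return track


def fit_exponential_decay(times, values, refine: bool = False) -> DecayFit:
    """Fit N(t) = N0 e^(-k t) by linear regression of log values on time.

    Requires >= 3 strictly positive values.  A positive trend clamps
    ``rate_k`` to 0 (half-life infinite) with a warning.  ``refine=True``
    runs a nonlinear least-squares pass on the original scale starting from
    the log-space solution.  ``r_squared`` is the log-space coefficient of
    determination.
    """
    t = np.asarray(times, float)
    v = np.asarray(values, float)
    if t.size < 3:
        raise ValueError("need at least 3 points")
    if np.any(v <= 0):
        raise ValueError("values must be positive for a log-space decay fit")
    res = stats.linregress(t, np.log(v))
    k = -res.slope
    n0 = float(np.exp(res.intercept))
    r2 = float(res.rvalue**2)
    if k < 0:
        warnings.warn("series increases with time; clamping rate_k to 0", stacklevel=2)
        k, n0 = 0.0, float(np.exp(np.log(v).mean()))
    elif refine:
        def resid(p):
            return p[0] * np.exp(-p[1] * t) - v
        sol = optimize.least_squares(resid, x0=[n0, k], bounds=([0, 0], [np.inf, np.inf]))
        n0, k = float(sol.x[0]), float(sol.x[1])
    return DecayFit(
        n0=n0,
        rate_k=float(k),
        half_life=math.inf if k == 0 else math.log(2) / k,
        r_squared=r2,
        n_points=int(t.size),
    )


def fit_chase_table(
    table: pd.DataFrame,
    time_col: str = "time_h",
    value_col: str = "abundance",
    by: tuple[str, ...] = ("condition", "replicate"),
) -> pd.DataFrame:
    """Fit a decay per group of a long-format chase table; one row per fit."""
    by = [c for c in by if c in table]
    groups = table.groupby(by) if by else [((), table)]
    rows = []
    for key, sub in groups:
        fit = fit_exponential_decay(sub[time_col], sub[value_col])
        row = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        row.update(
            n0=fit.n0, rate_k=fit.rate_k, half_life_h=fit.half_life,
            r_squared=fit.r_squared, n_points=fit.n_points,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def classify_pcna_pattern(
    pcna_crop: np.ndarray,
    mask: np.ndarray | None = None,
    threshold: float = 1.0,
    min_area: int = 50,
    smooth_sigma: float = 1.0,
) -> tuple[str, float]:
    """Classify a nuclear PCNA crop as 'diffuse' or 'punctate'.

    Replication factories make PCNA dot-like in S phase.  The granularity
    score is (P99 - median) / median of the smoothed in-mask intensities;
    the crop is punctate iff the score strictly exceeds ``threshold``.
    Returns ``(label, score)``.
    """
    img = np.asarray(pcna_crop, float)
    if mask is None:
        mask = np.ones(img.shape, bool)
    if int(mask.sum()) < min_area:
        raise ValueError(f"crop covers fewer than {min_area} pixels")
    sm = ndi.gaussian_filter(img, smooth_sigma)
    vals = sm[mask]
    med = float(np.median(vals))
    if med <= 0:
        return "diffuse", 0.0
    score = (float(np.percentile(vals, 99)) - med) / med
    return ("punctate" if score > threshold else "diffuse"), score


def detect_phase_transitions(
    pattern: list[str], min_run: int = 3
) -> dict[str, int]:
    """Locate G1->S and S->G2 from a per-frame diffuse/punctate sequence.

    G1->S is the first frame opening a run of >= ``min_run`` punctate labels;
    S->G2 is the first frame opening the subsequent run of >= ``min_run``
    diffuse labels.  Shorter flickers are ignored.  Missing transitions are
    simply absent from the result.
    """
    def first_run(labels, value, start):
        run = 0
        for i in range(start, len(labels)):
            run = run + 1 if labels[i] == value else 0
            if run == min_run:
                return i - min_run + 1
        return None

    out: dict[str, int] = {}
    g1s = first_run(pattern, "punctate", 0)
    if g1s is not None:
        out["G1_S"] = g1s
        sg2 = first_run(pattern, "diffuse", g1s + min_run)
        if sg2 is not None:
            out["S_G2"] = sg2
    return out
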