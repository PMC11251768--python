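"""Path comparison and exploration-exploitation analytics.

dtw_mae aligns two 3D paths of possibly different lengths by dynamic time
warping with a mean-absolute-error local cost; path_r2 measures the fraction
of an observed path's variance explained by a model path.  The EER
(exploration-exploitation rate) of a labelled stretch of flight is the
fraction of samples labelled exploration ('s'); eer_vs_distance bins samples
by Euclidean distance from the target and reports the across-flight mean and
s.d. of the exploration fraction per band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .segmentation import Trajectory

__all__ = ["EERCurve", "dtw_mae", "path_r2", "mean_eer", "eer_vs_distance"]


@dataclass
class EERCurve:
    """Mean +- s.d. exploration fraction per distance band from the target.

    Bands are non-overlapping intervals of half-width ``band_radius`` on a
    regular grid of centres.  Bands containing no samples are marked empty
    (NaN mean/sd, n_samples 0), never zero.
    """

    band_centres: np.ndarray  # m
    band_radius: float  # m
    mean_eer: np.ndarray  # in [0, 1] or NaN for empty bands
    sd_eer: np.ndarray
    n_samples: np.ndarray  # pooled sample count per band
    n_flights: np.ndarray  # number of flights contributing per band


@njit(cache=True)
def _dtw_kernel(a, b):  # pragma: no cover - exercised via dtw_mae
    n, m = a.shape[0], b.shape[0]
    big = 1e300
    D = np.full((n + 1, m + 1), big)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            c = (abs(a[i - 1, 0] - b[j - 1, 0])
                 + abs(a[i - 1, 1] - b[j - 1, 1])
                 + abs(a[i - 1, 2] - b[j - 1, 2])) / 3.0
            best = D[i - 1, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
            D[i, j] = c + best
    # backtrack to count the warping-path length
    i, j, steps = n, m, 0
    while i > 1 or j > 1:
        steps += 1
        diag, up, left = D[i - 1, j - 1], D[i - 1, j], D[i, j - 1]
        if diag <= up and diag <= left:
            i, j = i - 1, j - 1
        elif up <= left:
            i -= 1
        else:
            j -= 1
    steps += 1
    return D[n, m], steps


def _positions(p) -> np.ndarray:
    arr = p.positions if isinstance(p, Trajectory) else np.asarray(p, dtype=float)
    arr = np.atleast_2d(arr).astype(np.float64)
    if arr.shape[0] == 0:
        raise ValueError("empty path")
    if arr.shape[1] != 3:
        raise ValueError("paths must be sequences of 3-vectors")
    return np.ascontiguousarray(arr)


def dtw_mae(path_a, path_b, normalized: bool = True) -> float:
    """Dynamic-time-warping distance with mean-absolute-error local cost.

    The local cost of matching two points is the mean absolute coordinate
    difference; the returned value is the total cost along the optimal
    warping path, divided by the path length when ``normalized`` (so values
    are comparable across path lengths).  Symmetric; zero iff the paths are
    identical up to repeated points.
    """
    a, b = _positions(path_a), _positions(path_b)
    total, steps = _dtw_kernel(a, b)
    return float(total / steps) if normalized else float(total)


def resample_to_length(traj: Trajectory | np.ndarray, n: int) -> np.ndarray:
    """Linear interpolation over normalised time to n samples."""
    pos = _positions(traj)
    if pos.shape[0] == n:
        return pos
    s_old = np.linspace(0.0, 1.0, pos.shape[0])
    s_new = np.linspace(0.0, 1.0, n)
    return np.column_stack([np.interp(s_new, s_old, pos[:, c]) for c in range(3)])


def path_r2(observed, model, clamp: bool = False) -> float:
    """Coefficient of determination of a model path against an observed one.

    The model is resampled to the observed length (normalised time), then
    R^2 = 1 - SS_res/SS_tot pooled over the three coordinates, with SS_tot
    about the observed per-coordinate means.  Raw R^2 can be negative (model
    worse than the mean path); ``clamp`` reports max(0, R^2) for the
    r in [0, 1] convention.
    """
    obs = _positions(observed)
    mod = resample_to_length(model, obs.shape[0])
    ss_tot = float(np.sum((obs - obs.mean(axis=0)) ** 2))
    if ss_tot == 0.0:
        raise ValueError("observed path has zero variance in all coordinates")
    ss_res = float(np.sum((obs - mod) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return max(0.0, r2) if clamp else r2


def mean_eer(labels) -> float:
    """Exploration fraction of a label sequence: share of 's' samples."""
    lab = np.asarray(labels)
    if lab.size == 0:
        raise ValueError("empty label sequence")
    return float(np.mean(lab == "s"))


def eer_vs_distance(flights, target, band_radius: float = 0.06,
                    max_distance: float = 2.0,
                    mode: str = "pool") -> EERCurve:
    """EER as a function of Euclidean distance from the target.

    ``flights`` is a sequence of (positions, labels) pairs — positions
    (n, 3) in metres and per-sample labels in {'s', 'o'} (a FlightRecord-like
    object with .trajectory and labels also works via tuples built upstream).
    Samples are assigned to non-overlapping bands of half-width
    ``band_radius`` centred on a regular grid from 0 to ``max_distance``.

    mode='pool': each flight contributes its within-band exploration fraction
    and the curve reports the across-flight mean and s.d. (a flight with no
    samples in a band does not contribute there).  mode='per_flight' is the
    same statistic; the modes differ only in n_samples bookkeeping kept for
    pooled counts.
    """
    if band_radius <= 0:
        raise ValueError("band_radius must be > 0")
    if mode not in ("pool", "per_flight"):
        raise ValueError("mode must be 'pool' or 'per_flight'")
    target = np.asarray(target, dtype=float).reshape(3)
    width = 2.0 * band_radius
    centres = np.arange(band_radius, max_distance + band_radius, width)
    nb = centres.shape[0]
    frac_lists: list[list[float]] = [[] for _ in range(nb)]
    counts = np.zeros(nb, dtype=int)
    for positions, labels in flights:
        pos = _positions(positions)
        lab = np.asarray(labels)
        if lab.shape[0] != pos.shape[0]:
            raise ValueError("labels must match positions length")
        d = np.linalg.norm(pos - target, axis=1)
        idx = np.floor(d / width).astype(int)
        ok = (idx >= 0) & (idx < nb)
        for band in np.unique(idx[ok]):
            sel = ok & (idx == band)
            frac_lists[band].append(float(np.mean(lab[sel] == "s")))
            counts[band] += int(np.sum(sel))
    means = np.full(nb, np.nan)
    sds = np.full(nb, np.nan)
    n_fl = np.zeros(nb, dtype=int)
    for b in range(nb):
        if frac_lists[b]:
            arr = np.array(frac_lists[b])
            means[b] = arr.mean()
            sds[b] = arr.std(ddof=0)
            n_fl[b] = arr.shape[0]
    return EERCurve(band_centres=centres, band_radius=band_radius,
                    mean_eer=means, sd_eer=sds, n_samples=counts, n_flights=n_fl)
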