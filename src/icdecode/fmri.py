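"""fMRI branch: spatial ICA maps, mask features, HRF sampling and a GLM z-map.

The fMRI decoder treats scans as mixtures of spatially independent component
maps.  ICA is run in the *spatial* convention (the data matrix is time x
voxels, components are voxel maps, mixing columns are component time courses).
Component maps are z-scored, thresholded at z >= 2.3 and binarized; held-out
scans are summarised by the mean signal inside each binary mask, sampled at
the scan nearest each event's predicted BOLD peak (onset + HRF peak lag).
Because the paradigm is rapid and self-paced, only events inside a same-label
run of length >= 2 are kept as exemplars (consecutive-trial filter).

A minimal voxelwise OLS GLM (HRF-convolved belief/disbelief regressors plus
intercept, Gaussianized t) provides the contrast z-map that the
interpretation stage compares IC masks against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike, NDArray
from scipy import stats

from .ica import InfomaxICA

__all__ = [
    "HRFParams",
    "sample_hrf",
    "Volume4D",
    "SpatialMap",
    "BinaryMask",
    "spatial_ica",
    "threshold_binarize",
    "mask_mean_timecourse",
    "hrf_peak_sample_times",
    "filter_consecutive_exemplars",
    "glm_zstat",
    "build_fmri_features",
]


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma hemodynamic response.

    Defaults: response peak ~6 s, undershoot ~16 s, dispersions 0.9 s,
    undershoot one sixth of the peak.  ``peak_lag`` is derived by a dense-grid
    argmax of the sampled kernel, never hard-coded.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 0.9
    undershoot_dispersion: float = 0.9
    undershoot_ratio: float = 1.0 / 6.0
    duration: float = 32.0

    @property
    def peak_lag(self) -> float:
        t, h = sample_hrf(self, dt=0.01)
        return float(t[int(np.argmax(h))])


def sample_hrf(params: HRFParams = HRFParams(), dt: float = 0.1
               ) -> tuple[NDArray, NDArray]:
    """Sample the double-gamma HRF on a ``dt`` grid over its support."""
    t = np.arange(0.0, params.duration + dt / 2, dt)
    peak = stats.gamma.pdf(t, params.peak_delay / params.peak_dispersion,
                           scale=params.peak_dispersion)
    under = stats.gamma.pdf(t, params.undershoot_delay / params.undershoot_dispersion,
                            scale=params.undershoot_dispersion)
    h = peak - params.undershoot_ratio * under
    return t, h / h.max()


@dataclass
class Volume4D:
    """4D BOLD series with acquisition metadata."""

    values: NDArray                 # X x Y x Z x T
    TR: float
    affine: NDArray | None = None
    brain_mask: NDArray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4 or self.values.shape[-1] < 2:
            raise ValueError("values must be X x Y x Z x T with T >= 2")
        if self.TR <= 0:
            raise ValueError("TR must be positive")
        if self.affine is None:
            self.affine = np.eye(4)
        if self.brain_mask is None:
            self.brain_mask = np.ones(self.values.shape[:3], dtype=bool)

    @property
    def n_scans(self) -> int:
        return self.values.shape[-1]


@dataclass
class SpatialMap:
    values: NDArray        # X x Y x Z, z units
    kind: str              # "IC" | "GLM-contrast"
    map_id: str


@dataclass
class BinaryMask:
    values: NDArray        # X x Y x Z boolean
    threshold: float
    parent_id: str
    empty: bool = False

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())


# ----------------------------------------------------------------------

def spatial_ica(
    vol: Volume4D,
    K: int = 6,
    seed: int | None = 0,
    scan_subset: NDArray | None = None,
    **ica_kwargs,
) -> tuple[list[SpatialMap], NDArray]:
    """Spatial ICA of a 4D volume into K component maps and time courses.

    The in-mask data are reshaped to time x voxels and decomposed with the
    same Infomax engine as the EEG branch; component activations are the
    voxel maps (z-scored over the brain mask), mixing columns the time
    courses.  ``scan_subset`` restricts the *fit* to those scans (the
    training firewall); maps are z-scored regardless.
    """
    if K > vol.n_scans:
        raise ValueError(f"K={K} exceeds number of scans T={vol.n_scans}")
    mask = vol.brain_mask
    X = vol.values[mask]                      # voxels x T
    fit_X = X if scan_subset is None else X[:, np.asarray(scan_subset)]
    est = InfomaxICA(n_components=K, random_state=seed, **ica_kwargs)
    est.fit(fit_X)                            # samples=voxels, channels=scans
    maps_flat = est.activations_              # K x voxels
    # time courses on the full series: regress each scan onto the maps
    Z = maps_flat - maps_flat.mean(axis=1, keepdims=True)
    tcs, *_ = np.linalg.lstsq(Z.T, X - X.mean(axis=0, keepdims=True), rcond=None)
    tcs = tcs.T                               # T x K

    maps = []
    for k in range(K):
        m = maps_flat[k]
        z = (m - m.mean()) / m.std()
        vol3 = np.zeros(mask.shape)
        vol3[mask] = z
        maps.append(SpatialMap(values=vol3, kind="IC", map_id=f"IC{k}"))
    return maps, tcs


def threshold_binarize(smap: SpatialMap, z_thresh: float = 2.3) -> BinaryMask:
    """Binarize a z map at the (inclusive) threshold ``z >= z_thresh``."""
    vals = np.asarray(smap.values) >= z_thresh
    return BinaryMask(values=vals, threshold=z_thresh, parent_id=smap.map_id,
                      empty=not vals.any())


def mask_mean_timecourse(vol: Volume4D, mask: BinaryMask) -> NDArray:
    """Mean in-mask signal per scan (length-T series)."""
    if mask.values.shape != vol.values.shape[:3]:
        raise ValueError("mask grid does not match volume grid")
    if not mask.values.any():
        raise ValueError("empty mask")
    return vol.values[mask.values].mean(axis=0)


def hrf_peak_sample_times(
    events: pd.DataFrame,
    hrf: HRFParams,
    TR: float,
    n_scans: int | None = None,
) -> tuple[NDArray, NDArray]:
    """Scan index of the predicted BOLD peak for each event.

    ``index_i = round((onset_i + peak_lag) / TR)``.  Returns
    ``(indices, kept_rows)``; events whose peak falls past the scan are
    dropped (their row indices are simply absent from ``kept_rows``).
    """
    lag = hrf.peak_lag
    idx = np.round((events["onset"].to_numpy() + lag) / TR).astype(int)
    keep = idx >= 0
    if n_scans is not None:
        keep &= idx < n_scans
    return idx[keep], np.where(keep)[0]


def filter_consecutive_exemplars(events: pd.DataFrame) -> pd.DataFrame:
    """Keep only events inside a same-label run of length >= 2.

    Event i survives iff its label equals that of its predecessor or its
    successor — isolated labels (which share scans with neighbours of the
    opposite class in the rapid self-paced design) are removed.
    """
    if len(events) == 0:
        raise ValueError("empty event table")
    lab = events["trial_type"].to_numpy()
    prev_same = np.zeros(len(lab), dtype=bool)
    next_same = np.zeros(len(lab), dtype=bool)
    prev_same[1:] = lab[1:] == lab[:-1]
    next_same[:-1] = lab[:-1] == lab[1:]
    return events[prev_same | next_same].copy()


def _convolved_regressor(onsets: NDArray, hrf: HRFParams, TR: float,
                         n_scans: int) -> NDArray:
    dt = 0.1
    _, h = sample_hrf(hrf, dt=dt)
    fine_n = int(np.ceil(n_scans * TR / dt)) + len(h)
    stick = np.zeros(fine_n)
    for onset in onsets:
        j = int(round(onset / dt))
        if 0 <= j < fine_n:
            stick[j] += 1.0
    conv = np.convolve(stick, h)[:fine_n]
    return np.interp(np.arange(n_scans) * TR, np.arange(fine_n) * dt, conv)


def glm_zstat(
    vol: Volume4D,
    events: pd.DataFrame,
    hrf: HRFParams = HRFParams(),
    contrast: str = "B-DB",
) -> SpatialMap:
    """Voxelwise OLS z-map for the belief-vs-disbelief contrast.

    Design: HRF-convolved belief and disbelief stick regressors plus an
    intercept.  The contrast t statistic is Gaussianized through the exact
    survival function, so the null rate of |z| >= 2.3 matches the normal
    tail.
    """
    if contrast not in ("B-DB", "DB-B"):
        raise ValueError("contrast must be 'B-DB' or 'DB-B'")
    for lab in ("B", "DB"):
        if (events["trial_type"] == lab).sum() < 2:
            raise ValueError(f"need >= 2 events of class {lab}")
    T = vol.n_scans
    xb = _convolved_regressor(
        events.loc[events["trial_type"] == "B", "onset"].to_numpy(),
        hrf, vol.TR, T)
    xd = _convolved_regressor(
        events.loc[events["trial_type"] == "DB", "onset"].to_numpy(),
        hrf, vol.TR, T)
    X = np.column_stack([xb, xd, np.ones(T)])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("degenerate design: collinear regressors")
    c = np.array([1.0, -1.0, 0.0]) if contrast == "B-DB" else np.array([-1.0, 1.0, 0.0])

    mask = vol.brain_mask
    Y = vol.values[mask].T                    # T x voxels
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    df = T - np.linalg.matrix_rank(X)
    sigma2 = (resid**2).sum(axis=0) / df
    cvc = float(c @ np.linalg.inv(X.T @ X) @ c)
    se = np.sqrt(sigma2 * cvc)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, (c @ beta) / se, 0.0)
    # Gaussianize via matched tail probabilities (numerically stable per sign)
    z = np.sign(tval) * stats.norm.isf(
        np.clip(stats.t.sf(np.abs(tval), df), 1e-300, 1.0)
    )
    out = np.zeros(mask.shape)
    out[mask] = z
    return SpatialMap(values=out, kind="GLM-contrast", map_id=contrast)


def build_fmri_features(
    timecourses: NDArray,
    sample_indices: NDArray,
    events: pd.DataFrame,
    on_collision: str = "keep",
) -> tuple[NDArray, NDArray, NDArray]:
    """Sample component time courses at each event's BOLD-peak scan.

    ``timecourses`` is T x K (model mixing columns on training data, or
    binarized-mask means on held-out data).  Returns ``(X, y, flags)`` with
    one row per event and one column per component; events mapped to the same
    scan are flagged, and dropped when ``on_collision="drop"``.
    """
    timecourses = np.asarray(timecourses, dtype=float)
    idx = np.asarray(sample_indices, dtype=int)
    if idx.max(initial=-1) >= timecourses.shape[0] or idx.min(initial=0) < 0:
        raise ValueError("sample index outside the scan range")
    if len(idx) != len(events):
        raise ValueError("one sample index per event required")
    uniq, counts = np.unique(idx, return_counts=True)
    collided = np.isin(idx, uniq[counts > 1])
    X = timecourses[idx]
    y = events["trial_type"].to_numpy()
    if on_collision == "drop":
        X, y, collided = X[~collided], y[~collided], collided[~collided]
    return X, y, collided
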