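"""Per-fold feature builders: the glue between raw data and the decoder.

Each builder implements the protocol :func:`icdecode.decode.run_nested_cv`
expects — ``labels``, ``fit(train_idx)`` and ``features(idx, held_out)`` — and
re-fits everything data-dependent (ICA model, wavelet time-point selection,
binary masks) on the training bins of the current outer fold only.  The
fitted objects of the most recent fold are kept as attributes
(``model_``, ``selections_``, ``masks_`` ...) so the train/test firewall can
be checked bit-for-bit from outside.
"""

from __future__ import annotations

import numpy as np
from numpy.typing import NDArray
import pandas as pd

from . import eeg as eegmod
from . import fmri as fmrimod
from .eeg import (BandDef, DEFAULT_BANDS, EpochSet, FeatureTable,
                  WaveletParams, band_power_envelope, build_eeg_features,
                  morlet_spectrogram, select_timepoints)
from .ica import InfomaxICA, project_components
from .fmri import (HRFParams, Volume4D, build_fmri_features,
                   hrf_peak_sample_times, mask_mean_timecourse, spatial_ica,
                   threshold_binarize)

__all__ = ["EEGICBuilder", "EEGBandPowerBuilder", "FMRIICBuilder"]


def _trial_spectrogram_power(data: NDArray, rate: float, freqs: NDArray,
                             params: WaveletParams) -> NDArray:
    """Normalized wavelet power for a trials x channels x time tensor.

    Equivalent to :func:`icdecode.eeg.morlet_spectrogram` per trial, but the
    batch shares one forward FFT of the data across all analysis frequencies
    (the per-fold hot path).  Each (trial, channel, freq) power series is
    divided by its segment mean.
    """
    from scipy.fft import fft, ifft, next_fast_len
    from .eeg import morlet_wavelet

    nt, nc, ns = data.shape
    flat = data.reshape(nt * nc, ns)
    atoms = [morlet_wavelet(f, rate, params.width_cycles) for f in freqs]
    nfft = next_fast_len(ns + max(len(a) for a in atoms) - 1)
    F = fft(flat, nfft, axis=-1)
    power = np.empty((nt * nc, len(freqs), ns))
    for fi, atom in enumerate(atoms):
        kern = atom[::-1].conj()  # convolution with reversed conj = correlation
        coef = ifft(F * fft(kern, nfft), axis=-1)
        start = (len(kern) - 1) // 2  # 'same' alignment
        power[:, fi, :] = np.abs(coef[:, start:start + ns]) ** 2
    power = power.reshape(nt, nc, len(freqs), ns)
    return power / power.mean(axis=-1, keepdims=True)


class EEGICBuilder:
    """IC-feature builder for EEG epochs.

    Per fold: Infomax ICA on the concatenated training trials (square model
    by default), wavelet time-point selection per band on training-trial
    channel spectrograms, then features = power envelope of the projected IC
    activations sampled at t_B / t_DB.
    """

    def __init__(self, epochs: EpochSet, bands: list[str] | None = None,
                 wavelet: WaveletParams = WaveletParams(),
                 n_components: int | None = None, seed: int = 0,
                 envelope_method: str = "hilbert"):
        self.epochs = epochs
        self.band_defs = [DEFAULT_BANDS[b] for b in (bands or ["gamma"])]
        self.wavelet = wavelet
        self.n_components = n_components
        self.seed = seed
        self.envelope_method = envelope_method
        self.model_: InfomaxICA | None = None
        self.selections_: list = []

    @property
    def labels(self) -> NDArray:
        return self.epochs.labels

    def fit(self, train_idx: NDArray) -> "EEGICBuilder":
        ep = self.epochs
        train = ep.data[np.asarray(train_idx)]
        nt, nc, ns = train.shape
        concat = train.transpose(1, 0, 2).reshape(nc, nt * ns)
        est = InfomaxICA(n_components=self.n_components,
                         max_samples=20_000, random_state=self.seed)
        est.fit(concat.T)
        self.model_ = est

        self.selections_ = []
        for band in self.band_defs:
            freqs = band.freqs(self.wavelet.freq_step)
            power = _trial_spectrogram_power(train, ep.sampling_rate, freqs,
                                             self.wavelet)
            sel = select_timepoints(power, ep.labels[train_idx], band, freqs,
                                    ep.times_ms)
            self.selections_.append(sel)
        return self

    def _ic_tensor(self, idx: NDArray) -> NDArray:
        """Project epochs ``idx`` through the frozen model (trials x K x time)."""
        ep = self.epochs
        out = []
        for i in np.asarray(idx):
            out.append(self.model_.transform(ep.data[i].T).T)
        return np.stack(out)

    def features(self, idx: NDArray, held_out: bool = False) -> NDArray:
        ics = self._ic_tensor(idx)
        tables = []
        for sel in self.selections_:
            env = band_power_envelope(ics, self.epochs.sampling_rate, sel.band,
                                      method=self.envelope_method)
            tab = build_eeg_features(env, sel, self.epochs.times_ms,
                                     self.epochs.labels[np.asarray(idx)],
                                     source_kind="ic")
            tables.append(tab.X)
        return np.hstack(tables)

    def feature_meta(self) -> list[dict]:
        """Provenance of the feature columns of the most recent fold."""
        meta = []
        K = self.model_.unmixing_.shape[0]
        for sel in self.selections_:
            for t_ms, tag in ((sel.t_B, "t_B"), (sel.t_DB, "t_DB")):
                for c in range(K):
                    meta.append({
                        "source": f"IC{c}", "band": sel.band.name,
                        "sample_time_ms": float(t_ms), "which": tag,
                        "label": f"IC{c}_{sel.band.name}_{tag}_{t_ms:.0f}ms",
                    })
        return meta


class EEGBandPowerBuilder:
    """Band-power (ERSP) feature builder: no ICA, channel envelopes sampled at
    the per-band discriminative time points.  Stack several bands for the
    "combined" spectral classifier."""

    def __init__(self, epochs: EpochSet, bands: list[str],
                 wavelet: WaveletParams = WaveletParams(), seed: int = 0,
                 envelope_method: str = "hilbert"):
        self.epochs = epochs
        self.band_defs = [DEFAULT_BANDS[b] for b in bands]
        self.wavelet = wavelet
        self.seed = seed
        self.envelope_method = envelope_method
        self.selections_: list = []

    @property
    def labels(self) -> NDArray:
        return self.epochs.labels

    def fit(self, train_idx: NDArray) -> "EEGBandPowerBuilder":
        ep = self.epochs
        train = ep.data[np.asarray(train_idx)]
        self.selections_ = []
        for band in self.band_defs:
            freqs = band.freqs(self.wavelet.freq_step)
            power = _trial_spectrogram_power(train, ep.sampling_rate, freqs,
                                             self.wavelet)
            self.selections_.append(
                select_timepoints(power, ep.labels[train_idx], band, freqs,
                                  ep.times_ms))
        return self

    def features(self, idx: NDArray, held_out: bool = False) -> NDArray:
        ep = self.epochs
        data = ep.data[np.asarray(idx)]
        tables = []
        for sel in self.selections_:
            env = band_power_envelope(data, ep.sampling_rate, sel.band,
                                      method=self.envelope_method)
            tab = build_eeg_features(env, sel, ep.times_ms,
                                     ep.labels[np.asarray(idx)],
                                     source_kind="chan")
            tables.append(tab.X)
        return np.hstack(tables)


class FMRIICBuilder:
    """fMRI IC-feature builder.

    Per fold: spatial ICA fit on all scans *except* the held-out events'
    BOLD-peak scans (±1 TR); training rows are sampled from the model's own
    component time courses, held-out rows from the mean signal inside each
    thresholded, binarized IC map.  When K exceeds ``n_keep``, components are
    ranked by the absolute two-sample t of their training features and the
    top ``n_keep`` kept.
    """

    def __init__(self, vol: Volume4D, events: pd.DataFrame,
                 hrf: HRFParams = HRFParams(), K: int = 6, seed: int = 0,
                 z_thresh: float = 2.3, n_keep: int = 6):
        self.vol = vol
        self.hrf = hrf
        self.K = K
        self.seed = seed
        self.z_thresh = z_thresh
        self.n_keep = n_keep
        events = fmrimod.filter_consecutive_exemplars(events)
        idx, kept = hrf_peak_sample_times(events, hrf, vol.TR, vol.n_scans)
        self.events = events.iloc[kept].reset_index(drop=True)
        self.peak_idx = idx
        self.maps_: list = []
        self.masks_: list = []
        self.timecourses_: NDArray | None = None
        self.kept_components_: list[int] = []

    @property
    def labels(self) -> NDArray:
        return self.events["trial_type"].to_numpy()

    def fit(self, train_idx: NDArray) -> "FMRIICBuilder":
        train_idx = np.asarray(train_idx)
        test_mask = np.ones(len(self.events), dtype=bool)
        test_mask[train_idx] = False
        test_scans = set()
        for i in np.where(test_mask)[0]:
            for d in (-1, 0, 1):
                s = self.peak_idx[i] + d
                if 0 <= s < self.vol.n_scans:
                    test_scans.add(s)
        fit_scans = np.array(sorted(set(range(self.vol.n_scans)) - test_scans))
        maps, tcs = spatial_ica(self.vol, K=self.K, seed=self.seed,
                                scan_subset=fit_scans)
        self.maps_ = maps
        self.timecourses_ = tcs  # T x K (per-scan regression on the maps)
        self.masks_ = []
        for m in maps:
            mask = threshold_binarize(m, self.z_thresh)
            if mask.empty:
                # fall back to the map's top percentile so the pipeline can
                # proceed; the mask stays flagged as empty-at-threshold
                q = np.quantile(m.values, 0.99)
                mask = fmrimod.BinaryMask(values=m.values >= q,
                                          threshold=self.z_thresh,
                                          parent_id=m.map_id, empty=True)
            self.masks_.append(mask)

        # rank components on training features only
        Xtr = self.timecourses_[self.peak_idx[train_idx]]
        ytr = self.labels[train_idx]
        from .decode import rank_features
        order = rank_features(Xtr, ytr)
        self.kept_components_ = sorted(int(c) for c in order[: self.n_keep])
        return self

    def features(self, idx: NDArray, held_out: bool = False) -> NDArray:
        idx = np.asarray(idx)
        if held_out:
            series = np.column_stack([
                mask_mean_timecourse(self.vol, self.masks_[k])
                for k in self.kept_components_
            ])
        else:
            series = self.timecourses_[:, self.kept_components_]
        X, _, _ = build_fmri_features(series, self.peak_idx[idx],
                                      self.events.iloc[idx])
        return X
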