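"""EEG preprocessing, Morlet spectrograms and wavelet-informed features.

The EEG branch of the decoder works on stimulus-locked epochs (default window
-500 to +2500 ms at 250 Hz).  Single-trial features are power values sampled
at two *discriminative time points* per class, found on training trials only:
the (time, channel) pair maximising the band-summed difference of squared
class-mean normalized wavelet power,

    f_B(t, n)  = sum_{freq in band} ( E_B(t, n, freq)^2 - E_DB(t, n, freq)^2 )
    (t_B, n_B) = argmax_{t, n} f_B ,

and symmetrically for disbelief.  Features are then the power envelope of
either independent-component activations or band-limited channel signals,
sampled at t_B and t_DB.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike, NDArray
from scipy import signal

__all__ = [
    "BandDef",
    "DEFAULT_BANDS",
    "WaveletParams",
    "EpochSet",
    "Spectrogram",
    "TimepointSelection",
    "FeatureTable",
    "preprocess_continuous",
    "segment_epochs",
    "baseline_correct",
    "detect_artifacts",
    "morlet_wavelet",
    "morlet_spectrogram",
    "normalize_power",
    "select_timepoints",
    "band_power_envelope",
    "build_eeg_features",
]


@dataclass(frozen=True)
class BandDef:
    name: str
    lo: float
    hi: float

    def __post_init__(self):
        if not 0 <= self.lo < self.hi:
            raise ValueError(f"invalid band {self.name}: [{self.lo}, {self.hi}]")

    def freqs(self, step: float = 1.0) -> NDArray:
        """Integer-step analysis frequencies inside the band (>= 1 Hz)."""
        lo = max(self.lo, step)
        return np.arange(np.ceil(lo / step) * step, self.hi + 1e-9, step)


DEFAULT_BANDS: dict[str, BandDef] = {
    "delta": BandDef("delta", 0.1, 4.0),
    "theta": BandDef("theta", 4.0, 8.0),
    "alpha": BandDef("alpha", 8.0, 12.0),
    "beta": BandDef("beta", 12.0, 20.0),
    "gamma": BandDef("gamma", 20.0, 45.0),
}


@dataclass(frozen=True)
class WaveletParams:
    """Morlet analysis settings: ``width_cycles`` cycles under the Gaussian
    (time-domain SD = cycles / (2 pi f)), 1 Hz frequency step by default."""

    width_cycles: float = 6.0
    freq_step: float = 1.0
    freq_range: tuple[float, float] = (1.0, 45.0)

    def __post_init__(self):
        if self.width_cycles < 3:
            raise ValueError("width_cycles must be >= 3 for practical admissibility")
        if self.freq_step <= 0:
            raise ValueError("freq_step must be positive")


@dataclass
class EpochSet:
    """Labelled trials x channels x time tensor (uV)."""

    data: NDArray
    labels: NDArray
    sampling_rate: float
    t0_offset: float  # ms of the first sample relative to stimulus onset
    channel_ids: list[str] | None = None
    bad_channel_mask: NDArray | None = None  # trials x channels
    bad_trial_mask: NDArray | None = None
    exclusion_reasons: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x time")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must match trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> NDArray:
        return self.t0_offset + 1000.0 * np.arange(self.n_samples) / self.sampling_rate

    def time_index(self, t_ms: float) -> int:
        idx = int(np.argmin(np.abs(self.times_ms - t_ms)))
        if abs(self.times_ms[idx] - t_ms) > 1000.0 / self.sampling_rate:
            raise ValueError(f"time {t_ms} ms outside the epoch window")
        return idx


@dataclass
class Spectrogram:
    power: NDArray            # channels x freqs x time
    freqs: NDArray
    times: NDArray            # ms
    normalization: str = "raw"
    edge_mask: NDArray | None = None  # freqs x time, True where unreliable


@dataclass
class TimepointSelection:
    band: BandDef
    t_B: float
    chan_B: int
    f_B_value: float
    t_DB: float
    chan_DB: int
    f_DB_value: float
    degenerate: bool = False


@dataclass
class FeatureTable:
    """Exemplars x features with labels and per-column provenance."""

    X: NDArray
    y: NDArray
    meta: list[dict]
    fold_provenance: str = ""

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.shape[0] != len(self.y):
            raise ValueError("labels must align with rows")
        if self.X.shape[1] != len(self.meta):
            raise ValueError("meta must cover every feature column")

    def to_tsv(self, path) -> None:
        cols = [m.get("label", f"f{i}") for i, m in enumerate(self.meta)]
        df = pd.DataFrame(self.X, columns=cols)
        df.insert(0, "label", self.y)
        df.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------
# preprocessing

def preprocess_continuous(
    raw: ArrayLike,
    sampling_rate: float,
    lo: float = 0.1,
    hi: float = 100.0,
    notch: float | None = 60.0,
    notch_halfwidth: float = 1.0,
) -> NDArray:
    """Zero-phase band-pass (4th-order Butterworth) plus FFT mains notch.

    ``raw`` is channels x samples.  The high-pass and low-pass stages are
    applied separately (a single band-pass with a ~0.1 Hz lower edge is
    numerically ill-conditioned at EEG rates) with even-reflection padding to
    tame the slow high-pass edge transient.  The notch multiplies spectrum
    bins within ``notch_halfwidth`` of the mains frequency by 0.01 (-40 dB),
    with a cosine taper over a second half-width on each side; being applied
    in the frequency domain it is inherently zero-phase.
    """
    raw = np.asarray(raw, dtype=float)
    nyq = sampling_rate / 2.0
    if hi >= nyq:
        raise ValueError(f"upper edge {hi} Hz violates Nyquist ({nyq} Hz)")
    pad = min(raw.shape[-1] - 1, int(3 * sampling_rate / max(lo, 0.01)))
    sos_hp = signal.butter(4, lo, btype="highpass", fs=sampling_rate,
                           output="sos")
    sos_lp = signal.butter(4, hi, btype="lowpass", fs=sampling_rate,
                           output="sos")
    out = signal.sosfiltfilt(sos_hp, raw, axis=-1, padlen=pad, padtype="even")
    out = signal.sosfiltfilt(sos_lp, out, axis=-1)
    if notch is not None and notch < nyq:
        n = out.shape[-1]
        freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
        dist = np.abs(freqs - notch)
        gain = np.ones_like(freqs)
        stop = 0.01  # -40 dB
        inside = dist <= notch_halfwidth
        ramp = (dist > notch_halfwidth) & (dist <= 2 * notch_halfwidth)
        gain[inside] = stop
        frac = (dist[ramp] - notch_halfwidth) / notch_halfwidth
        gain[ramp] = stop + (1 - stop) * 0.5 * (1 - np.cos(np.pi * frac))
        out = np.fft.irfft(np.fft.rfft(out, axis=-1) * gain, n=n, axis=-1)
    return out


def segment_epochs(
    filtered: ArrayLike,
    sampling_rate: float,
    events: pd.DataFrame,
    pre_ms: float = 500.0,
    post_ms: float = 2500.0,
    channel_ids: list[str] | None = None,
) -> EpochSet:
    """Cut one epoch per event (default 500 ms before to 2500 ms after onset).

    Events whose window overruns the recording are dropped, with the reason
    recorded on the returned :class:`EpochSet`.
    """
    filtered = np.asarray(filtered, dtype=float)
    n_pre = int(round(pre_ms / 1000.0 * sampling_rate))
    n_post = int(round(post_ms / 1000.0 * sampling_rate))
    epochs, labels, reasons = [], [], {}
    for i, row in events.reset_index(drop=True).iterrows():
        center = int(round(row["onset"] * sampling_rate))
        i0, i1 = center - n_pre, center + n_post
        if i0 < 0 or i1 > filtered.shape[1]:
            reasons[i] = "event window outside recording bounds"
            continue
        epochs.append(filtered[:, i0:i1])
        labels.append(row["trial_type"])
    if not epochs:
        raise ValueError("no events produced a complete epoch")
    es = EpochSet(
        data=np.stack(epochs),
        labels=np.asarray(labels),
        sampling_rate=sampling_rate,
        t0_offset=-pre_ms,
        channel_ids=channel_ids,
    )
    es.exclusion_reasons = reasons
    return es


def baseline_correct(epochs: EpochSet, baseline_ms: float = 100.0) -> EpochSet:
    """Subtract the mean over the ``baseline_ms`` window before stimulus onset
    from every trial x channel."""
    t = epochs.times_ms
    win = (t >= -baseline_ms) & (t < 0)
    if not win.any():
        raise ValueError("baseline window not contained in the epoch")
    base = epochs.data[:, :, win].mean(axis=-1, keepdims=True)
    out = EpochSet(
        data=epochs.data - base,
        labels=epochs.labels.copy(),
        sampling_rate=epochs.sampling_rate,
        t0_offset=epochs.t0_offset,
        channel_ids=epochs.channel_ids,
    )
    out.exclusion_reasons = dict(epochs.exclusion_reasons)
    return out


def detect_artifacts(
    epochs: EpochSet,
    blink_slope_uv_per_ms: float = 10.0,
    ma_len: int = 80,
    ma_window: int = 160,
    em_thresh_uv: float = 100.0,
    chan_err_frac: float = 0.20,
    max_bad_chans: int = 10,
) -> tuple[EpochSet, dict]:
    """Flag blink and eye-movement artifacts; data are never modified.

    Per trial x channel: a blink flag when the sample-to-sample slope exceeds
    ``blink_slope_uv_per_ms`` (uV/ms); an eye-movement flag when, within any
    ``ma_window``-sample window, the ``ma_len``-sample moving averages of its
    two halves differ by more than ``em_thresh_uv``.  Channels bad in more
    than ``chan_err_frac`` of trials are excluded dataset-wide; trials with
    more than ``max_bad_chans`` bad channels are excluded.
    """
    if min(blink_slope_uv_per_ms, ma_len, ma_window, em_thresh_uv) <= 0:
        raise ValueError("artifact parameters must be positive")
    data = epochs.data
    nt, nc, ns = data.shape
    dt_ms = 1000.0 / epochs.sampling_rate

    slope = np.abs(np.diff(data, axis=-1)) / dt_ms
    blink = slope.max(axis=-1) >= blink_slope_uv_per_ms

    em = np.zeros((nt, nc), dtype=bool)
    if ns >= ma_window:
        kern = np.ones(ma_len) / ma_len
        # moving average at each start position, for every trial x channel
        ma = signal.fftconvolve(data, kern[None, None, :], mode="valid", axes=-1)
        gap = ma_window - ma_len
        if gap > 0 and ma.shape[-1] > gap:
            step = np.abs(ma[..., gap:] - ma[..., :-gap])
            em = step.max(axis=-1) >= em_thresh_uv

    flags = blink | em
    bad_channels = flags.mean(axis=0) > chan_err_frac
    eff = flags | bad_channels[None, :]
    bad_trials = eff.sum(axis=1) > max_bad_chans

    out = EpochSet(
        data=data,
        labels=epochs.labels.copy(),
        sampling_rate=epochs.sampling_rate,
        t0_offset=epochs.t0_offset,
        channel_ids=epochs.channel_ids,
        bad_channel_mask=flags,
        bad_trial_mask=bad_trials,
    )
    out.exclusion_reasons = dict(epochs.exclusion_reasons)
    report = {
        "n_flagged": int(flags.sum()),
        "n_blink_flags": int(blink.sum()),
        "n_eyemove_flags": int(em.sum()),
        "excluded_channels": np.where(bad_channels)[0].tolist(),
        "excluded_trials": np.where(bad_trials)[0].tolist(),
    }
    return out, report


# ----------------------------------------------------------------------
# Morlet time-frequency analysis

def morlet_wavelet(freq: float, sampling_rate: float,
                   width_cycles: float = 6.0) -> NDArray:
    """Sampled complex Morlet atom at ``freq`` (unit L2 norm).

    Gaussian time SD = width_cycles / (2 pi freq); support truncated at 5 SD.
    """
    sigma_t = width_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(5.0 * sigma_t * sampling_rate))
    t = np.arange(-half, half + 1) / sampling_rate
    atom = np.exp(2j * np.pi * freq * t) * np.exp(-(t**2) / (2 * sigma_t**2))
    return atom / np.linalg.norm(atom)


def morlet_spectrogram(
    x: ArrayLike,
    sampling_rate: float,
    params: WaveletParams = WaveletParams(),
    times_ms: NDArray | None = None,
    freqs: NDArray | None = None,
) -> Spectrogram:
    """Morlet wavelet power of ``x`` (channels x time, or a 1-D signal).

    Power is the squared magnitude of the complex wavelet coefficient at each
    (frequency, time) point; samples within one wavelet SD of either epoch
    edge are flagged unreliable in ``edge_mask``.  ``freqs`` overrides the
    default 1 Hz grid spanning ``params.freq_range`` (e.g. to restrict the
    computation to one band's frequencies).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    nyq = sampling_rate / 2.0
    if freqs is None:
        lo, hi = params.freq_range
        freqs = np.arange(max(lo, params.freq_step), hi + 1e-9, params.freq_step)
    else:
        freqs = np.asarray(freqs, dtype=float)
    if freqs.max() >= nyq:
        raise ValueError("requested frequency is at or above Nyquist")
    nc, ns = x.shape
    power = np.empty((nc, len(freqs), ns))
    edge = np.zeros((len(freqs), ns), dtype=bool)
    for fi, f in enumerate(freqs):
        atom = morlet_wavelet(f, sampling_rate, params.width_cycles)
        coef = signal.fftconvolve(x, atom[None, ::-1].conj(), mode="same",
                                  axes=-1)
        power[:, fi, :] = np.abs(coef) ** 2
        sd_samples = int(np.ceil(params.width_cycles / (2 * np.pi * f)
                                 * sampling_rate))
        edge[fi, :sd_samples] = True
        if sd_samples > 0:
            edge[fi, -sd_samples:] = True
    if times_ms is None:
        times_ms = 1000.0 * np.arange(ns) / sampling_rate
    return Spectrogram(power=power, freqs=freqs, times=np.asarray(times_ms),
                       normalization="raw", edge_mask=edge)


def normalize_power(spec: Spectrogram) -> Spectrogram:
    """Divide each (channel, frequency) power series by its segment mean.

    After normalization the time-mean of every row is 1; applying it twice is
    a no-op.
    """
    mean = spec.power.mean(axis=-1, keepdims=True)
    if np.any(mean == 0):
        raise ValueError("zero mean power row (identically zero signal)")
    return Spectrogram(
        power=spec.power / mean,
        freqs=spec.freqs,
        times=spec.times,
        normalization="segment-mean-divided",
        edge_mask=spec.edge_mask,
    )


def select_timepoints(
    power: NDArray,
    labels: ArrayLike,
    band: BandDef,
    freqs: NDArray,
    times_ms: NDArray,
) -> TimepointSelection:
    """Wavelet-informed discriminative time-point selection on training trials.

    ``power`` is trials x channels x freqs x time (normalized).  The class
    means E_B and E_DB are squared, differenced, summed over the band's
    frequencies, and the (time, channel) maximising the result is returned for
    each class.  Ties break to the earliest time, then the lowest channel
    index, with a degeneracy flag.
    """
    labels = np.asarray(labels)
    in_b = labels == "B"
    in_db = labels == "DB"
    if in_b.sum() < 2 or in_db.sum() < 2:
        raise ValueError("need at least two training trials of each class")
    sel = (freqs >= band.lo) & (freqs <= band.hi)
    if not sel.any():
        raise ValueError(f"no analysis frequencies inside band {band.name}")
    EB = power[in_b][:, :, sel, :].mean(axis=0)    # chan x freq x time
    EDB = power[in_db][:, :, sel, :].mean(axis=0)
    fB = (EB**2 - EDB**2).sum(axis=1)              # chan x time
    fDB = -fB

    def _argmax(f):
        ft = f.T  # time x chan: flat argmax = earliest time, lowest channel
        idx = int(np.argmax(ft))
        t_i, c_i = np.unravel_index(idx, ft.shape)
        degen = (ft == ft.flat[idx]).sum() > 1
        return float(times_ms[t_i]), int(c_i), float(ft.flat[idx]), bool(degen)

    t_B, chan_B, v_B, d1 = _argmax(fB)
    t_DB, chan_DB, v_DB, d2 = _argmax(fDB)
    return TimepointSelection(
        band=band, t_B=t_B, chan_B=chan_B, f_B_value=v_B,
        t_DB=t_DB, chan_DB=chan_DB, f_DB_value=v_DB,
        degenerate=d1 or d2,
    )


# ----------------------------------------------------------------------
# power envelopes and feature assembly

def band_power_envelope(
    data: ArrayLike,
    sampling_rate: float,
    band: BandDef,
    method: str = "square",
) -> NDArray:
    """Power envelope of band-limited signals.

    ``data`` is trials x channels x time (or channels x time).  Each trace is
    band-pass filtered (4th-order zero-phase Butterworth), demeaned, then
    converted to instantaneous power: ``method="square"`` squares the trace;
    ``method="hilbert"`` squares the analytic-signal magnitude (a smooth,
    phase-free version of the same quantity).
    """
    data = np.asarray(data, dtype=float)
    nyq = sampling_rate / 2.0
    if band.hi >= nyq:
        raise ValueError(f"band edge {band.hi} Hz violates Nyquist")
    lo = max(band.lo, 0.05)
    sos = signal.butter(4, [lo, band.hi], btype="bandpass",
                        fs=sampling_rate, output="sos")
    pad = min(data.shape[-1] - 1, int(3 * sampling_rate / lo))
    filt = signal.sosfiltfilt(sos, data, axis=-1, padlen=pad)
    filt = filt - filt.mean(axis=-1, keepdims=True)
    if method == "square":
        return filt**2
    if method == "hilbert":
        return np.abs(signal.hilbert(filt, axis=-1)) ** 2
    raise ValueError(f"unknown envelope method {method!r}")


def build_eeg_features(
    source: NDArray,
    selections: TimepointSelection | list[TimepointSelection],
    times_ms: NDArray,
    labels: ArrayLike,
    source_kind: str = "ic",
    fold_provenance: str = "",
) -> FeatureTable:
    """Sample a source tensor at the discriminative time points.

    ``source`` is trials x channels x time — IC power envelopes or band power
    envelopes.  For every channel (or IC) and every selection, two features
    are produced: the value at t_B and at t_DB.  Stacking the selections of
    several bands yields the "combined" feature set.
    """
    if isinstance(selections, TimepointSelection):
        selections = [selections]
    source = np.asarray(source, dtype=float)
    nt, nc, ns = source.shape
    times_ms = np.asarray(times_ms)
    cols, meta = [], []
    for sel in selections:
        for t_ms, tag in ((sel.t_B, "t_B"), (sel.t_DB, "t_DB")):
            if t_ms < times_ms[0] - 1e-9 or t_ms > times_ms[-1] + 1e-9:
                raise ValueError(f"sample time {t_ms} ms outside the epoch")
            ti = int(np.argmin(np.abs(times_ms - t_ms)))
            for c in range(nc):
                cols.append(source[:, c, ti])
                name = f"IC{c}" if source_kind == "ic" else f"chan{c}"
                meta.append({
                    "source": name,
                    "band": sel.band.name,
                    "sample_time_ms": float(t_ms),
                    "which": tag,
                    "label": f"{name}_{sel.band.name}_{tag}_{t_ms:.0f}ms",
                })
    X = np.column_stack(cols)
    return FeatureTable(X=X, y=np.asarray(labels), meta=meta,
                        fold_provenance=fold_provenance)
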