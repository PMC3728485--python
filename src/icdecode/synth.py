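"""Synthetic EEG and fMRI generators with known ground truth.

No recordings accompany the decoding task this package implements, so every
stage is exercised on simulated data whose generative model is fully known:

* **EEG** — trials are a linear mixture of independent sources plus 1/f and
  white noise.  Discriminative sources emit a Gabor burst (Gaussian-windowed
  sinusoid) at a class-specific latency; the default configuration plants the
  belief burst ~578 ms earlier than the disbelief burst, mirroring the
  latency asymmetry the method is designed to exploit.
* **fMRI** — component spatial maps are isotropic Gaussian blobs (truncated at
  3 SD) whose time courses are HRF-convolved event trains with class-specific
  loadings, plus white noise.
* **Events** — a self-paced schedule: each stimulus follows the previous
  key-press response by a fixed gap (default 0.5 s), with a belief response
  rate of 45.6 % and ~180 trials per session by default.

Ground-truth objects record the mixing matrices, planted latencies and maps so
recovery can be scored exactly, plus a Monte-Carlo ideal-observer accuracy
estimate used to benchmark end-to-end decoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .eeg import BandDef, DEFAULT_BANDS, EpochSet
from .fmri import HRFParams, sample_hrf

__all__ = [
    "SourceSpec",
    "EEGSimConfig",
    "EEGGroundTruth",
    "FMRISimConfig",
    "FMRIGroundTruth",
    "simulate_eeg",
    "simulate_fmri",
    "simulate_event_schedule",
    "default_eeg_sources",
    "estimate_bayes_accuracy",
    "eeg_config_for_bayes",
    "inject_ramp",
    "inject_blink",
]

LABELS = ("B", "DB")


# ----------------------------------------------------------------------
# configuration dataclasses

@dataclass
class SourceSpec:
    """One independent source: a class-locked oscillatory burst.

    ``latency_B``/``latency_DB`` (ms, stimulus-locked) say when the burst
    occurs on trials of each class; ``None`` means the source is silent for
    that class.  ``burst_cycles`` sets the Gaussian window SD as
    ``cycles / (2 pi f)`` so the atom matches the Morlet analysis kernel.
    """

    center_freq: float = 30.0
    band: str = "gamma"
    latency_B: float | None = 600.0
    latency_DB: float | None = None
    burst_cycles: float = 6.0
    amplitude: float = 1.0
    spatial_profile: NDArray | None = None

    def __post_init__(self):
        if self.latency_B is None and self.latency_DB is None:
            raise ValueError("source needs at least one class latency")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")

    @property
    def sigma_ms(self) -> float:
        return 1000.0 * self.burst_cycles / (2.0 * np.pi * self.center_freq)


def default_eeg_sources() -> list[SourceSpec]:
    """Three sources: one discriminative gamma source (belief burst 578 ms
    before the disbelief burst) and two class-indifferent distractors."""
    return [
        SourceSpec(center_freq=30.0, band="gamma", latency_B=600.0,
                   latency_DB=1178.0, amplitude=3.0),
        SourceSpec(center_freq=10.0, band="alpha", latency_B=400.0,
                   latency_DB=400.0, amplitude=2.0),
        SourceSpec(center_freq=6.0, band="theta", latency_B=1500.0,
                   latency_DB=1500.0, amplitude=2.0),
    ]


@dataclass
class EEGSimConfig:
    n_channels: int = 8
    sampling_rate: float = 250.0
    n_trials_per_class: int = 60
    epoch_window: tuple[float, float] = (-500.0, 2500.0)
    sources: list[SourceSpec] = field(default_factory=default_eeg_sources)
    noise_1f_exponent: float = 1.0
    noise_sd: float = 1.0
    pink_fraction: float = 0.5
    seed: int = 0
    # spatial profiles are a property of the (simulated) montage, not of the
    # trial realization: drawn from their own seed so difficulty is stable
    # across trial seeds
    profile_seed: int = 12345

    def validate(self) -> None:
        if self.n_channels < len(self.sources):
            raise ValueError("need at least as many channels as sources")
        nyq = self.sampling_rate / 2.0
        pre, post = self.epoch_window
        for s in self.sources:
            if s.center_freq >= nyq:
                raise ValueError(
                    f"source frequency {s.center_freq} Hz violates Nyquist"
                )
            for lat in (s.latency_B, s.latency_DB):
                if lat is None:
                    continue
                if lat - 3 * s.sigma_ms < pre or lat + 3 * s.sigma_ms > post:
                    raise ValueError(
                        f"burst at {lat} ms (±3 SD = {3 * s.sigma_ms:.0f} ms) "
                        "extends past the epoch window"
                    )

    @property
    def n_samples(self) -> int:
        pre, post = self.epoch_window
        return int(round((post - pre) / 1000.0 * self.sampling_rate))

    @property
    def times_ms(self) -> NDArray:
        pre, _ = self.epoch_window
        return pre + 1000.0 * np.arange(self.n_samples) / self.sampling_rate


@dataclass
class EEGGroundTruth:
    mixing: NDArray                      # channels x sources
    source_timecourses: NDArray          # trials x sources x time
    discriminative_latency_B: float | None
    discriminative_latency_DB: float | None
    bayes_accuracy_estimate: float | None = None


@dataclass
class FMRISimConfig:
    grid: tuple[int, int, int] = (12, 12, 10)
    n_components: int = 3
    blob_centers: list[tuple[float, float, float]] | None = None
    blob_radii: list[float] | None = None
    loadings: list[tuple[float, float]] | None = None  # (B, DB) per component
    TR: float = 2.0
    n_events_per_class: int = 40
    mean_iti: float = 2.5
    class_balance: float = 0.456
    hrf_params: HRFParams = field(default_factory=HRFParams)
    noise_sd: float = 0.1
    # multiplicative trial-to-trial response variability per component; also
    # what makes the K component time courses linearly independent (without
    # it they all live in the 2-D span of the class regressors)
    amplitude_jitter_sd: float = 0.3
    seed: int = 0

    def resolved(self) -> "FMRISimConfig":
        """Fill in default blob geometry / loadings for the component count."""
        cfg = replace(self)
        K = cfg.n_components
        if cfg.blob_centers is None:
            gx, gy, gz = cfg.grid
            # spread blob centers on a ring in the central slice
            ang = 2 * np.pi * np.arange(K) / max(K, 1)
            cx = gx / 2 + (gx / 6.0) * np.cos(ang)
            cy = gy / 2 + (gy / 6.0) * np.sin(ang)
            cfg.blob_centers = [(float(x), float(y), gz / 2) for x, y in zip(cx, cy)]
        if cfg.blob_radii is None:
            cfg.blob_radii = [1.0] * K
        if cfg.loadings is None:
            base = [(1.0, 0.25), (0.25, 1.0), (0.6, 0.6)]
            cfg.loadings = [base[k % 3] for k in range(K)]
        if len(cfg.blob_centers) != K or len(cfg.blob_radii) != K or len(cfg.loadings) != K:
            raise ValueError("blob/loading lists must match n_components")
        if cfg.TR <= 0:
            raise ValueError("TR must be positive")
        for (x, y, z), r in zip(cfg.blob_centers, cfg.blob_radii):
            for c, g in zip((x, y, z), cfg.grid):
                if c - 3 * r < -0.5 or c + 3 * r > g - 0.5:
                    raise ValueError("blob (3 SD support) lies outside the grid")
        return cfg


@dataclass
class FMRIGroundTruth:
    true_maps: NDArray          # K x X x Y x Z
    true_timecourses: NDArray   # K x T
    event_table: pd.DataFrame
    loadings: NDArray           # K x 2 (B, DB)


# ----------------------------------------------------------------------
# event schedules

def simulate_event_schedule(
    n_events: int = 180,
    mean_response_time: float = 2.0,
    post_response_gap: float = 0.5,
    class_balance: float = 0.456,
    seed: int | None = 0,
    response_time_sd: float = 0.4,
    start: float = 10.0,
) -> pd.DataFrame:
    """Self-paced event schedule.

    Each stimulus onset follows the previous response by ``post_response_gap``
    seconds (onset_{i+1} = onset_i + RT_i + gap).  Labels are drawn i.i.d.
    with P(belief) = ``class_balance``; response times are lognormal with the
    given mean and SD (``response_time_sd = 0`` gives a deterministic
    schedule).
    """
    if n_events <= 0:
        raise ValueError("n_events must be positive")
    if not 0.0 < class_balance < 1.0:
        raise ValueError("class_balance must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    if response_time_sd > 0:
        mu = np.log(mean_response_time**2 / np.sqrt(mean_response_time**2 + response_time_sd**2))
        sig = np.sqrt(np.log(1 + response_time_sd**2 / mean_response_time**2))
        rts = rng.lognormal(mu, sig, size=n_events)
    else:
        rts = np.full(n_events, mean_response_time)
    labels = np.where(rng.random(n_events) < class_balance, "B", "DB")
    onsets = start + np.concatenate([[0.0], np.cumsum(rts[:-1] + post_response_gap)])
    return pd.DataFrame(
        {
            "onset": onsets,
            "duration": rts,
            "trial_type": labels,
            "response_time": rts,
        }
    )


# ----------------------------------------------------------------------
# EEG

def _shaped_noise(rng, shape_time: int, n_rows: int, exponent: float,
                  pink_fraction: float, sd: float, rate: float) -> NDArray:
    """1/f^alpha plus white Gaussian noise, unit-SD mix scaled to ``sd``."""
    white = rng.standard_normal((n_rows, shape_time))
    if pink_fraction > 0 and exponent > 0:
        spec = np.fft.rfft(rng.standard_normal((n_rows, shape_time)), axis=-1)
        freqs = np.fft.rfftfreq(shape_time, d=1.0 / rate)
        gain = np.zeros_like(freqs)
        gain[1:] = freqs[1:] ** (-exponent / 2.0)
        pink = np.fft.irfft(spec * gain, n=shape_time, axis=-1)
        pstd = pink.std()
        if pstd > 0:
            pink /= pstd
        mix = pink_fraction * pink + (1 - pink_fraction) * white
    else:
        mix = white
    mstd = mix.std()
    if mstd > 0:
        mix = mix / mstd
    return sd * mix


def _gabor(times_ms: NDArray, freq: float, latency_ms: float,
           sigma_ms: float, amplitude: float, phase: float) -> NDArray:
    t = (times_ms - latency_ms) / 1000.0
    return amplitude * np.exp(-0.5 * (t / (sigma_ms / 1000.0)) ** 2) * np.cos(
        2 * np.pi * freq * t + phase
    )


def simulate_eeg(config: EEGSimConfig) -> tuple[EpochSet, EEGGroundTruth]:
    """Generate labelled EEG epochs as mixing @ sources + noise.

    Returns the :class:`~icdecode.eeg.EpochSet` (trials x channels x time,
    labels balanced per class) and the ground truth (mixing matrix, per-trial
    source time courses, planted discriminative latencies).  Bit-reproducible
    for a given config (the seed lives in the config).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_src = len(config.sources)
    nt = config.n_samples
    times = config.times_ms

    # mixing columns: given profiles or random unit vectors from profile_seed
    prof_rng = np.random.default_rng(config.profile_seed)
    mixing = np.empty((config.n_channels, n_src))
    for j, s in enumerate(config.sources):
        if s.spatial_profile is not None:
            prof = np.asarray(s.spatial_profile, dtype=float)
            if prof.shape != (config.n_channels,):
                raise ValueError("spatial_profile length must equal n_channels")
        else:
            prof = prof_rng.standard_normal(config.n_channels)
        prof = prof / np.linalg.norm(prof)
        mixing[:, j] = prof

    n_per = config.n_trials_per_class
    labels = np.array(["B"] * n_per + ["DB"] * n_per)
    order = rng.permutation(2 * n_per)
    labels = labels[order]

    sources = np.zeros((2 * n_per, n_src, nt))
    for i, lab in enumerate(labels):
        for j, s in enumerate(config.sources):
            lat = s.latency_B if lab == "B" else s.latency_DB
            if lat is None:
                continue
            phase = rng.uniform(0, 2 * np.pi)
            sources[i, j] = _gabor(times, s.center_freq, lat, s.sigma_ms,
                                   s.amplitude, phase)

    data = np.einsum("cs,isn->icn", mixing, sources)
    if config.noise_sd > 0:
        noise = _shaped_noise(
            rng, nt, 2 * n_per * config.n_channels, config.noise_1f_exponent,
            config.pink_fraction, config.noise_sd, config.sampling_rate,
        ).reshape(2 * n_per, config.n_channels, nt)
        data = data + noise

    epochs = EpochSet(
        data=data,
        labels=labels,
        sampling_rate=config.sampling_rate,
        t0_offset=config.epoch_window[0],
        channel_ids=[f"E{c + 1}" for c in range(config.n_channels)],
    )
    disc = [s for s in config.sources
            if s.latency_B != s.latency_DB or s.latency_DB is None or s.latency_B is None]
    truth = EEGGroundTruth(
        mixing=mixing,
        source_timecourses=sources,
        discriminative_latency_B=disc[0].latency_B if disc else None,
        discriminative_latency_DB=disc[0].latency_DB if disc else None,
    )
    return epochs, truth


# ----------------------------------------------------------------------
# ideal-observer accuracy estimate

def _quadrature_energy(data: NDArray, times: NDArray, unmix_row: NDArray,
                       freq: float, latency: float, sigma_ms: float) -> NDArray:
    """|<projected trial, complex Gabor at (freq, latency)>|^2 per trial."""
    proj = np.einsum("c,icn->in", unmix_row, data)
    t = (times - latency) / 1000.0
    atom = np.exp(-0.5 * (t / (sigma_ms / 1000.0)) ** 2) * np.exp(
        2j * np.pi * freq * t
    )
    atom = atom / np.linalg.norm(atom)
    return np.abs(proj @ atom.conj()) ** 2


def estimate_bayes_accuracy(config: EEGSimConfig, n_mc: int = 10_000,
                            seed: int | None = None) -> float:
    """Monte-Carlo ideal-observer accuracy of the generative model.

    Simulates ``n_mc`` fresh trials and classifies each with the quadrature
    matched filter built from the *known* mixing, burst frequency and planted
    latencies (the optimal detector for a random-phase narrowband burst in
    white noise; near-optimal under the 1/f + white mixture).  For sources
    present in only one class the decision threshold is learned on one half of
    the Monte-Carlo sample and accuracy scored on the other half.
    """
    n_per = max(n_mc // 2, 1)
    mc_cfg = replace(config, n_trials_per_class=n_per,
                     seed=(config.seed if seed is None else seed) + 7_777)
    epochs, truth = simulate_eeg(mc_cfg)
    times = mc_cfg.times_ms
    unmix = np.linalg.pinv(truth.mixing)  # sources x channels

    stat = np.zeros(len(epochs.labels))
    for j, s in enumerate(mc_cfg.sources):
        if s.latency_B == s.latency_DB:
            continue
        if s.latency_B is not None:
            stat += _quadrature_energy(epochs.data, times, unmix[j],
                                       s.center_freq, s.latency_B, s.sigma_ms)
        if s.latency_DB is not None:
            stat -= _quadrature_energy(epochs.data, times, unmix[j],
                                       s.center_freq, s.latency_DB, s.sigma_ms)
    y = (epochs.labels == "B")
    half = len(y) // 2
    thr_grid = np.quantile(stat[:half], np.linspace(0.02, 0.98, 97))
    accs = [( (stat[:half] > t) == y[:half]).mean() for t in thr_grid]
    thr = thr_grid[int(np.argmax(accs))]
    return float(((stat[half:] > thr) == y[half:]).mean())


def eeg_config_for_bayes(target: float = 0.90, base: EEGSimConfig | None = None,
                         n_mc: int = 6000, seed: int = 0,
                         tol: float = 0.005) -> EEGSimConfig:
    """Calibrate the discriminative burst amplitude so the Monte-Carlo
    ideal-observer accuracy hits ``target`` (bisection; accuracy is monotone
    in amplitude)."""
    if base is None:
        base = EEGSimConfig(seed=seed)

    def with_amp(a: float) -> EEGSimConfig:
        srcs = [replace(s, amplitude=a if (s.latency_B != s.latency_DB) else s.amplitude)
                for s in base.sources]
        return replace(base, sources=srcs)

    lo, hi = 0.05, 30.0
    acc_lo = estimate_bayes_accuracy(with_amp(lo), n_mc, seed)
    acc_hi = estimate_bayes_accuracy(with_amp(hi), n_mc, seed)
    if not (acc_lo <= target <= acc_hi):
        raise ValueError(
            f"target {target} outside achievable range [{acc_lo:.3f}, {acc_hi:.3f}]"
        )
    for _ in range(25):
        mid = np.sqrt(lo * hi)
        acc = estimate_bayes_accuracy(with_amp(mid), n_mc, seed)
        if abs(acc - target) < tol:
            lo = hi = mid
            break
        if acc < target:
            lo = mid
        else:
            hi = mid
    amp = np.sqrt(lo * hi)
    cfg = with_amp(float(amp))
    return cfg


# ----------------------------------------------------------------------
# fMRI

def _blob(grid: tuple[int, int, int], center, radius: float) -> NDArray:
    gx, gy, gz = grid
    x, y, z = np.meshgrid(np.arange(gx), np.arange(gy), np.arange(gz),
                          indexing="ij")
    d2 = ((x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2)
    m = np.exp(-0.5 * d2 / radius**2)
    m[d2 > (3 * radius) ** 2] = 0.0  # truncate at 3 SD
    return m


def simulate_fmri(config: FMRISimConfig) -> tuple[NDArray, FMRIGroundTruth]:
    """Generate a 4D volume = sum_k map_k x (HRF * event train)_k + noise.

    Component ``k`` responds to belief events with amplitude ``loadings[k][0]``
    and to disbelief events with ``loadings[k][1]``; differential loadings make
    a component class-informative.  Returns the volume (X, Y, Z, T) and the
    ground truth (maps, time courses, event table).
    """
    cfg = config.resolved()
    rng = np.random.default_rng(cfg.seed)

    events = simulate_event_schedule(
        n_events=2 * cfg.n_events_per_class,
        mean_response_time=max(cfg.mean_iti - 0.5, 0.5),
        post_response_gap=0.5,
        class_balance=cfg.class_balance,
        seed=cfg.seed + 101,
    )
    # enforce the configured per-class counts exactly (balanced design)
    lab = np.array(["B"] * cfg.n_events_per_class + ["DB"] * cfg.n_events_per_class)
    events["trial_type"] = lab[rng.permutation(len(lab))]

    hrf_t, hrf_v = sample_hrf(cfg.hrf_params, dt=0.1)
    dur = events["onset"].iloc[-1] + 32.0
    T = int(np.ceil(dur / cfg.TR))
    fine_n = int(np.ceil(dur / 0.1)) + len(hrf_v)

    maps = np.stack([_blob(cfg.grid, c, r)
                     for c, r in zip(cfg.blob_centers, cfg.blob_radii)])
    # reject overlapping components (ground-truth maps must be distinct)
    flat = maps.reshape(cfg.n_components, -1)
    for a in range(cfg.n_components):
        for b in range(a + 1, cfg.n_components):
            ca = flat[a] - flat[a].mean()
            cb = flat[b] - flat[b].mean()
            r = ca @ cb / (np.linalg.norm(ca) * np.linalg.norm(cb) + 1e-300)
            if r >= 0.5:
                raise ValueError(
                    f"blobs {a} and {b} overlap too much (spatial r={r:.2f})"
                )

    loadings = np.asarray(cfg.loadings, dtype=float)
    tcs = np.zeros((cfg.n_components, T))
    scan_times = np.arange(T) * cfg.TR
    for k in range(cfg.n_components):
        stick = np.zeros(fine_n)
        for onset, lab_ in zip(events["onset"], events["trial_type"]):
            amp = loadings[k, 0] if lab_ == "B" else loadings[k, 1]
            if cfg.amplitude_jitter_sd > 0:
                amp *= max(1.0 + cfg.amplitude_jitter_sd * rng.standard_normal(), 0.0)
            stick[int(round(onset / 0.1))] += amp
        conv = np.convolve(stick, hrf_v)[:fine_n]
        tcs[k] = np.interp(scan_times, np.arange(fine_n) * 0.1, conv)

    vol = np.einsum("kxyz,kt->xyzt", maps, tcs)
    if cfg.noise_sd > 0:
        vol = vol + cfg.noise_sd * rng.standard_normal(vol.shape)

    truth = FMRIGroundTruth(
        true_maps=maps, true_timecourses=tcs, event_table=events,
        loadings=loadings,
    )
    return vol, truth


# ----------------------------------------------------------------------
# artifact injectors (test scaffolding for detection thresholds)

def inject_ramp(epochs: EpochSet, trial: int, channel: int,
                slope_uv_per_ms: float, start_ms: float, dur_ms: float) -> EpochSet:
    """Add an eye-movement-like linear ramp to one trial x channel in place."""
    rate = epochs.sampling_rate
    t = epochs.times_ms
    seg = (t >= start_ms) & (t < start_ms + dur_ms)
    ramp = np.zeros_like(t)
    ramp[seg] = slope_uv_per_ms * (t[seg] - start_ms)
    ramp[t >= start_ms + dur_ms] = slope_uv_per_ms * dur_ms
    epochs.data[trial, channel] += ramp
    return epochs


def inject_blink(epochs: EpochSet, trial: int, channel: int,
                 peak_uv: float, center_ms: float, width_ms: float = 100.0) -> EpochSet:
    """Add a blink-like sharp biphasic spike to one trial x channel in place."""
    t = epochs.times_ms
    epochs.data[trial, channel] += peak_uv * np.exp(
        -0.5 * ((t - center_ms) / (width_ms / 4)) ** 2
    )
    return epochs
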