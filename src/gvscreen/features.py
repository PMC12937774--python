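"""The 16 resting-state EEG biomarkers, trial segmentation, and extraction.

All biomarkers are computed on standardized 2 s windows.  Band edges, the
phase-amplitude estimator, the burst rule and the entropy parameters are
configurable through :class:`BiomarkerConfig`; the defaults follow common
conventions in the PD-EEG literature (beta 13-30 Hz, gamma 50-100 Hz,
broadband 1-45 Hz, Tort modulation index with 18 bins, 75th-percentile burst
threshold with a 100 ms minimum duration, ApEn/SampEn with m=2, r=0.2*SD).
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from functools import lru_cache

import numpy as np
from scipy.signal import fftconvolve, firwin, hilbert, welch

# Central electrodes over sensorimotor cortex used for channel averaging.
CENTRAL_CHANNELS = (
    "FC5", "FC1", "FCz", "FC2", "FC6",
    "C3", "Cz", "C4",
    "CP5", "CP1", "CPz", "CP2", "CP6",
)

#: Field order of the feature vector (fixed; grouped by physiological domain).
BIOMARKER_FIELDS = (
    "bg_pac",
    "pt_asym", "rd_ratio",
    "exponent", "offset",
    "abd", "aba", "abe",
    "beta_power", "rel_beta_power",
    "pfd", "hj_mob", "hj_comp", "spec_en", "app_en", "samp_en",
)

#: CSV/report column names matching the published abbreviations.
BIOMARKER_ABBREV = (
    "BG-PAC",
    "PTAsym", "RDRatio",
    "Exponent", "Offset",
    "ABD", "ABA", "ABE",
    "BetaPower", "RelBetaPower",
    "PFD", "HjMob", "HjComp", "SpecEn", "AppEn", "SampEn",
)

N_BIOMARKERS = 16


@dataclass(frozen=True)
class BiomarkerConfig:
    beta_band: tuple[float, float] = (13.0, 30.0)
    gamma_band: tuple[float, float] = (50.0, 100.0)
    total_band: tuple[float, float] = (1.0, 45.0)
    aperiodic_fit_range: tuple[float, float] = (2.0, 40.0)
    pac_n_bins: int = 18
    burst_min_dur_s: float = 0.1
    burst_percentile: float = 75.0
    entropy_m: int = 2
    entropy_r: float = 0.2
    # ApEn/SampEn are O(N^2); computing them on a copy decimated to this rate
    # keeps full-cohort extraction tractable without changing any ordering
    # the features are used for.  Set >= fs to disable.
    entropy_fs: float = 250.0


DEFAULT_CONFIG = BiomarkerConfig()


@dataclass(frozen=True)
class BiomarkerVector:
    bg_pac: float
    pt_asym: float
    rd_ratio: float
    exponent: float
    offset: float
    abd: float
    aba: float
    abe: float
    beta_power: float
    rel_beta_power: float
    pfd: float
    hj_mob: float
    hj_comp: float
    spec_en: float
    app_en: float
    samp_en: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in BIOMARKER_FIELDS])

    @classmethod
    def from_array(cls, arr) -> "BiomarkerVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (N_BIOMARKERS,):
            raise ValueError(f"expected {N_BIOMARKERS} biomarker values, got {arr.shape}")
        return cls(**dict(zip(BIOMARKER_FIELDS, arr.tolist())))


assert tuple(f.name for f in dc_fields(BiomarkerVector)) == BIOMARKER_FIELDS


@dataclass(frozen=True)
class TrialFeatures:
    subject_id: str
    stim_id: int
    pre: BiomarkerVector
    stim: BiomarkerVector
    post: BiomarkerVector


# --------------------------------------------------------------------------
# Filtering helpers
# --------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _fir_taps(fs: float, lo: float, hi: float, n_samples: int) -> np.ndarray:
    # linear-phase FIR spanning ~3 cycles of the band's low edge, capped so
    # filtfilt padding fits inside the window
    numtaps = int(round(3.0 * fs / lo))
    numtaps = min(numtaps, n_samples // 4)
    numtaps = max(numtaps | 1, 31)  # odd, not degenerate
    return firwin(numtaps, [lo, hi], pass_zero=False, fs=fs)


def _apply_fir(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Zero-phase application of a symmetric (linear-phase) FIR along the
    last axis: centered convolution with odd-reflection edge padding.  The
    operation is exactly time-reversal symmetric."""
    pad = taps.size // 2
    xp = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(pad, pad)],
                mode="reflect", reflect_type="odd")
    y = fftconvolve(xp, taps.reshape((1,) * (x.ndim - 1) + (-1,)),
                    mode="same", axes=-1)
    return y[..., pad:-pad] if pad else y


def bandpass(x: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Zero-phase FIR bandpass along the last axis."""
    x = np.asarray(x, dtype=float)
    taps = _fir_taps(float(fs), float(band[0]), float(band[1]), x.shape[-1])
    return _apply_fir(x, taps)


def _welch(x: np.ndarray, fs: float):
    nperseg = min(int(fs), x.shape[-1])
    return welch(x, fs=fs, window="hann", nperseg=nperseg,
                 noverlap=nperseg // 2, axis=-1)


# --------------------------------------------------------------------------
# Segmentation
# --------------------------------------------------------------------------

def segment_trial(data: np.ndarray, fs: float) -> dict[str, list[np.ndarray]]:
    """Split a 9 s trial into pre/stim windows and 4 overlapping post windows.

    ``data`` is (channels, samples) or (samples,).  Windows are half-open
    sample ranges: pre [0,2) s, stim [2,4) s, post [4,6), [5,7), [6,8),
    [7,9) s; each is exactly ``2*fs`` samples.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    fs_i = int(round(fs))
    if data.shape[-1] != 9 * fs_i:
        raise ValueError(
            f"trial must have exactly {9 * fs_i} samples at fs={fs}, "
            f"got {data.shape[-1]}"
        )
    w = 2 * fs_i
    return {
        "pre": [data[:, 0:w]],
        "stim": [data[:, 2 * fs_i:2 * fs_i + w]],
        "post": [data[:, s * fs_i:s * fs_i + w] for s in (4, 5, 6, 7)],
    }


# --------------------------------------------------------------------------
# Individual biomarkers
# --------------------------------------------------------------------------

def band_powers(window: np.ndarray, fs: float,
                cfg: BiomarkerConfig = DEFAULT_CONFIG) -> tuple[float, float]:
    """(beta_power, rel_beta_power) from a Welch PSD."""
    freqs, psd = _welch(np.asarray(window, dtype=float), fs)
    return _band_powers_from_psd(freqs, psd, cfg)


def _band_powers_from_psd(freqs, psd, cfg) -> tuple[float, float]:
    beta = _band_integral(freqs, psd, cfg.beta_band)
    total = _band_integral(freqs, psd, cfg.total_band)
    rel = float(beta / total) if total > 0 else 0.0
    return float(beta), rel


def _band_integral(freqs, psd, band) -> float:
    m = (freqs >= band[0]) & (freqs <= band[1])
    return float(np.trapezoid(psd[..., m], freqs[m], axis=-1))


def mi_from_distribution(mean_amps: np.ndarray) -> float:
    """Tort modulation index of a phase-binned mean-amplitude distribution."""
    mean_amps = np.asarray(mean_amps, dtype=float)
    total = mean_amps.sum()
    if total <= 0:
        return 0.0
    p = mean_amps / total
    nz = p[p > 0]
    h = -float(np.sum(nz * np.log(nz)))
    log_k = np.log(len(mean_amps))
    return float(np.clip((log_k - h) / log_k, 0.0, 1.0))


def tort_mi(window: np.ndarray, fs: float,
            cfg: BiomarkerConfig = DEFAULT_CONFIG) -> float:
    """Beta-gamma phase-amplitude coupling (Tort MI in [0, 1])."""
    window = np.asarray(window, dtype=float)
    phase = np.angle(hilbert(bandpass(window, fs, cfg.beta_band)))
    amp = np.abs(hilbert(bandpass(window, fs, cfg.gamma_band)))
    return _mi_from_phase_amp(phase, amp, cfg.pac_n_bins)


def _mi_from_phase_amp(phase, amp, n_bins) -> float:
    bins = np.minimum(
        ((phase + np.pi) / (2 * np.pi) * n_bins).astype(int), n_bins - 1)
    sums = np.bincount(bins, weights=amp, minlength=n_bins)
    counts = np.bincount(bins, minlength=n_bins)
    mean_amp = np.divide(sums, counts, out=np.zeros(n_bins), where=counts > 0)
    return mi_from_distribution(mean_amp)


def waveform_shape(window: np.ndarray, fs: float,
                   cfg: BiomarkerConfig = DEFAULT_CONFIG) -> tuple[float, float]:
    """(pt_asym, rd_ratio): beta-cycle peak/trough sharpness asymmetry and
    log rise/decay duration ratio, measured on the broadband signal."""
    window = np.asarray(window, dtype=float)
    beta = bandpass(window, fs, cfg.beta_band)
    broad = bandpass(window, fs, cfg.total_band)
    return _shape_from_filtered(beta, broad, fs)


def _shape_from_filtered(beta, broad, fs) -> tuple[float, float]:
    sign = np.sign(beta)
    sign[sign == 0] = 1.0
    flips = np.flatnonzero(sign[1:] != sign[:-1]) + 1
    edges = np.concatenate(([0], flips, [beta.size])).astype(np.int64)
    return _shape_kernel(np.ascontiguousarray(broad), edges,
                         sign[edges[:-1]] > 0)


def _shape_kernel_py(broad: np.ndarray, edges: np.ndarray,
                     positive: np.ndarray) -> tuple[float, float]:
    """Reference implementation of the per-cycle shape metrics."""
    extrema: list[tuple[int, bool]] = []  # (index, is_peak), chronological
    for a, b, pos in zip(edges[:-1], edges[1:], positive):
        if b - a < 2:
            continue
        if pos:
            extrema.append((a + int(np.argmax(broad[a:b])), True))
        else:
            extrema.append((a + int(np.argmin(broad[a:b])), False))
    peaks = [i for i, isp in extrema if isp]
    troughs = [i for i, isp in extrema if not isp]
    if len(peaks) < 3 or len(troughs) < 3:
        return 0.0, 0.0

    d2 = np.abs(np.diff(broad, 2))  # |x[k-1] - 2x[k] + x[k+1]| at k = i+1

    def sharpness(indices: list[int]) -> float:
        # mean |second difference| over samples within +-5 of each extremum
        idx = np.asarray(indices)
        lo = np.maximum(idx - 6, 0)
        hi = np.minimum(idx + 5, d2.size)
        vals = [d2[l:h].mean() for l, h in zip(lo, hi)]
        return float(np.mean(vals))

    ps = sharpness(peaks)
    ts = sharpness(troughs)
    pt = (ps - ts) / (ps + ts) if (ps + ts) > 0 else 0.0

    rises, decays = [], []
    for (i0, p0), (i1, p1) in zip(extrema[:-1], extrema[1:]):
        if p0 == p1:
            continue
        if p1:  # trough -> peak
            rises.append(i1 - i0)
        else:  # peak -> trough
            decays.append(i1 - i0)
    if not rises or not decays:
        return float(pt), 0.0
    rd = float(np.log(np.mean(rises) / np.mean(decays)))
    return float(pt), rd


try:
    from numba import njit as _njit

    @_njit(cache=True)
    def _shape_kernel_numba(broad, edges, positive):  # pragma: no cover
        n_seg = edges.size - 1
        idxs = np.empty(n_seg, dtype=np.int64)
        kinds = np.empty(n_seg, dtype=np.bool_)
        n_ext = 0
        for s in range(n_seg):
            a, b = edges[s], edges[s + 1]
            if b - a < 2:
                continue
            best = a
            if positive[s]:
                for i in range(a + 1, b):
                    if broad[i] > broad[best]:
                        best = i
            else:
                for i in range(a + 1, b):
                    if broad[i] < broad[best]:
                        best = i
            idxs[n_ext] = best
            kinds[n_ext] = positive[s]
            n_ext += 1
        n_peaks = 0
        n_troughs = 0
        for e in range(n_ext):
            if kinds[e]:
                n_peaks += 1
            else:
                n_troughs += 1
        if n_peaks < 3 or n_troughs < 3:
            return 0.0, 0.0

        nd2 = broad.size - 2
        ps = 0.0
        ts = 0.0
        for e in range(n_ext):
            lo = idxs[e] - 6
            if lo < 0:
                lo = 0
            hi = idxs[e] + 5
            if hi > nd2:
                hi = nd2
            acc = 0.0
            for i in range(lo, hi):
                acc += abs(broad[i] - 2.0 * broad[i + 1] + broad[i + 2])
            val = acc / max(hi - lo, 1)
            if kinds[e]:
                ps += val
            else:
                ts += val
        ps /= n_peaks
        ts /= n_troughs
        pt = (ps - ts) / (ps + ts) if (ps + ts) > 0 else 0.0

        rise_sum = 0.0
        n_rises = 0
        decay_sum = 0.0
        n_decays = 0
        for e in range(1, n_ext):
            if kinds[e] == kinds[e - 1]:
                continue
            gap = idxs[e] - idxs[e - 1]
            if kinds[e]:
                rise_sum += gap
                n_rises += 1
            else:
                decay_sum += gap
                n_decays += 1
        if n_rises == 0 or n_decays == 0:
            return pt, 0.0
        rd = np.log((rise_sum / n_rises) / (decay_sum / n_decays))
        return pt, rd

    _shape_kernel = _shape_kernel_numba
except Exception:  # pragma: no cover
    _shape_kernel = _shape_kernel_py


def fit_aperiodic_psd(freqs: np.ndarray, psd: np.ndarray,
                      fit_range: tuple[float, float] = (2.0, 40.0),
                      n_prune_iters: int = 2) -> tuple[float, float]:
    """Peak-pruned straight-line fit of log10(PSD) vs log10(f).

    Returns (exponent, offset) with exponent = -slope and offset the
    intercept at log10 f = 0.  Points more than 1 SD above the current line
    are treated as oscillatory peaks and removed; two prune-refit passes.
    """
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    m = (freqs >= fit_range[0]) & (freqs <= fit_range[1]) & (psd > 0)
    lf, lp = np.log10(freqs[m]), np.log10(psd[m])
    if lf.size < 3:
        return 0.0, 0.0

    def ols(x, y):
        A = np.column_stack([x, np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        return coef  # slope, intercept

    keep = np.ones(lf.size, dtype=bool)
    slope, icpt = ols(lf, lp)
    for _ in range(n_prune_iters):
        resid = lp - (slope * lf + icpt)
        sd = resid[keep].std()
        keep &= resid <= sd
        if keep.sum() < 3:
            break
        slope, icpt = ols(lf[keep], lp[keep])
    return float(-slope), float(icpt)


def aperiodic_fit(window: np.ndarray, fs: float,
                  cfg: BiomarkerConfig = DEFAULT_CONFIG) -> tuple[float, float]:
    freqs, psd = _welch(np.asarray(window, dtype=float), fs)
    return fit_aperiodic_psd(freqs, psd, cfg.aperiodic_fit_range)


def bursts_from_envelope(env: np.ndarray, fs: float, threshold: float,
                         min_dur_s: float = 0.1) -> tuple[float, float, float]:
    """(abd, aba, abe) from a beta amplitude envelope and threshold."""
    if threshold <= 0:
        raise ValueError("burst threshold must be positive")
    env = np.asarray(env, dtype=float)
    above = env > threshold
    if not above.any():
        return 0.0, 0.0, 0.0
    padded = np.concatenate(([False], above, [False]))
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(~padded[1:] & padded[:-1])
    min_len = int(round(min_dur_s * fs))
    durs, amps, energies = [], [], []
    for s, e in zip(starts, ends):
        if e - s < min_len:
            continue
        seg = env[s:e]
        durs.append((e - s) / fs)
        amps.append(seg.max())
        energies.append(float(np.sum(seg ** 2)) / fs)
    if not durs:
        return 0.0, 0.0, 0.0
    return float(np.mean(durs)), float(np.mean(amps)), float(np.mean(energies))


def beta_bursts(window: np.ndarray, fs: float, baseline_threshold: float,
                cfg: BiomarkerConfig = DEFAULT_CONFIG) -> tuple[float, float, float]:
    env = np.abs(hilbert(bandpass(np.asarray(window, dtype=float), fs,
                                  cfg.beta_band)))
    return bursts_from_envelope(env, fs, baseline_threshold, cfg.burst_min_dur_s)


def petrosian_fd(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    n = x.size
    d = np.diff(x)
    n_delta = int(np.sum(d[1:] * d[:-1] < 0))
    return float(np.log10(n) / (np.log10(n) + np.log10(n / (n + 0.4 * n_delta))))


def hjorth_params(x: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    v0 = np.var(x)
    if v0 <= 0:
        return 0.0, 0.0
    d1 = np.diff(x)
    v1 = np.var(d1)
    mob = float(np.sqrt(v1 / v0))
    v2 = np.var(np.diff(d1))
    if v1 <= 0:
        return mob, 0.0
    return mob, float(np.sqrt(v2 / v1) / mob)


def spectral_entropy(window: np.ndarray, fs: float) -> float:
    _, psd = _welch(np.asarray(window, dtype=float), fs)
    return _spec_en_from_psd(psd)


def _spec_en_from_psd(psd) -> float:
    total = psd.sum()
    if total <= 0:
        return 0.0
    p = psd / total
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)) / np.log(psd.size))


@lru_cache(maxsize=16)
def _decim_taps(q: int) -> np.ndarray:
    return firwin(8 * q + 1, 0.8 / q)


def _entropy_signal(x: np.ndarray, fs: float, cfg: BiomarkerConfig) -> np.ndarray:
    """Anti-alias filter + downsample along the last axis (ApEn/SampEn input)."""
    if cfg.entropy_fs >= fs:
        return x
    q = int(round(fs / cfg.entropy_fs))
    if q <= 1:
        return x
    return _apply_fir(x, _decim_taps(q))[..., ::q]


def _entropy_counts_numpy(x: np.ndarray, m: int, r: float):
    """(cm, cm1, B, A): per-template match counts (self included) for orders
    m and m+1, and SampEn pair counts (self excluded, order m restricted to
    the first n-m templates so both orders compare the same pool)."""
    n = x.size
    nm = n - m
    within = np.ones((n - m + 1, n - m + 1), dtype=bool)
    for k in range(m):
        seg = x[k:k + n - m + 1]
        within &= np.abs(seg[:, None] - seg[None, :]) <= r
    cm = within.sum(axis=1)
    last = np.abs(x[m:n][:, None] - x[m:n][None, :]) <= r
    within1 = within[:nm, :nm] & last
    cm1 = within1.sum(axis=1)
    b = int(within[:nm, :nm].sum()) - nm
    a = int(within1.sum()) - nm
    return cm, cm1, b, a


try:  # optional numba fast path for the O(N^2) entropy counts
    from numba import njit

    @njit(cache=True)
    def _entropy_counts_numba(x, m, r):  # pragma: no cover - numba
        n = x.size
        nm = n - m
        cm = np.ones(n - m + 1)
        cm1 = np.ones(nm)
        b = 0
        a = 0
        for i in range(n - m + 1):
            for j in range(i + 1, n - m + 1):
                d = 0.0
                for k in range(m):
                    t = abs(x[i + k] - x[j + k])
                    if t > d:
                        d = t
                        if d > r:
                            break
                if d <= r:
                    cm[i] += 1.0
                    cm[j] += 1.0
                    if j < nm:
                        b += 1
                        if abs(x[i + m] - x[j + m]) <= r:
                            a += 1
                            cm1[i] += 1.0
                            cm1[j] += 1.0
        return cm, cm1, 2 * b, 2 * a

    _entropy_counts = _entropy_counts_numba
except Exception:  # pragma: no cover
    _entropy_counts = _entropy_counts_numpy


def _entropy_pair(x: np.ndarray, m: int, r_frac: float) -> tuple[float, float]:
    """(app_en, samp_en) with Chebyshev distance and r = r_frac * SD."""
    x = np.ascontiguousarray(x, dtype=float)
    sd = x.std()
    if sd <= 0 or x.size < m + 2:
        return 0.0, 0.0
    r = r_frac * sd
    cm, cm1, b, a = _entropy_counts(x, m, r)
    phi_m = float(np.mean(np.log(cm / (x.size - m + 1))))
    phi_m1 = float(np.mean(np.log(cm1 / (x.size - m))))
    app = phi_m - phi_m1
    if b == 0:
        samp = 0.0
    elif a == 0:
        samp = float(np.log(b + 1.0))
    else:
        samp = float(-np.log(a / b))
    return app, samp


def approx_entropy(x: np.ndarray, m: int = 2, r_frac: float = 0.2) -> float:
    return _entropy_pair(np.asarray(x, dtype=float), m, r_frac)[0]


def sample_entropy(x: np.ndarray, m: int = 2, r_frac: float = 0.2) -> float:
    return _entropy_pair(np.asarray(x, dtype=float), m, r_frac)[1]


def complexity_suite(window: np.ndarray, fs: float,
                     cfg: BiomarkerConfig = DEFAULT_CONFIG) -> tuple[float, ...]:
    """(pfd, hj_mob, hj_comp, spec_en, app_en, samp_en)."""
    x = np.asarray(window, dtype=float)
    if np.ptp(x) == 0:
        return 1.0, 0.0, 0.0, 0.0, 0.0, 0.0
    pfd = petrosian_fd(x)
    mob, comp = hjorth_params(x)
    sen = spectral_entropy(x, fs)
    app, samp = _entropy_pair(_entropy_signal(x, fs, cfg), cfg.entropy_m,
                              cfg.entropy_r)
    return pfd, mob, comp, sen, app, samp


# --------------------------------------------------------------------------
# Batched extraction
# --------------------------------------------------------------------------

def compute_vector(window: np.ndarray, fs: float, burst_threshold: float,
                   cfg: BiomarkerConfig = DEFAULT_CONFIG) -> BiomarkerVector:
    """All 16 biomarkers for one 2 s single-channel window."""
    arr = compute_block(np.atleast_2d(np.asarray(window, dtype=float)), fs,
                        np.array([burst_threshold]), cfg)[0]
    return BiomarkerVector.from_array(arr)


def compute_block(windows: np.ndarray, fs: float, burst_thresholds: np.ndarray,
                  cfg: BiomarkerConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Vectorized biomarker computation for a (k, n) stack of windows.

    Filtering, Hilbert transforms and Welch PSDs are batched across rows;
    returns a (k, 16) array in :data:`BIOMARKER_FIELDS` order.
    """
    W = np.asarray(windows, dtype=float)
    if W.ndim != 2:
        raise ValueError("windows must be 2-D (k, n)")
    k, n = W.shape
    thr = np.broadcast_to(np.asarray(burst_thresholds, dtype=float), (k,))

    beta_f = bandpass(W, fs, cfg.beta_band)
    gamma_f = bandpass(W, fs, cfg.gamma_band)
    broad_f = bandpass(W, fs, cfg.total_band)
    beta_an = hilbert(beta_f, axis=-1)
    beta_phase = np.angle(beta_an)
    beta_env = np.abs(beta_an)
    gamma_env = np.abs(hilbert(gamma_f, axis=-1))
    freqs, psd = _welch(W, fs)
    W_ent = _entropy_signal(W, fs, cfg)

    out = np.empty((k, N_BIOMARKERS))
    for i in range(k):
        x = W[i]
        if np.ptp(x) == 0:
            bp, rbp = _band_powers_from_psd(freqs, psd[i], cfg)
            out[i] = [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
                      bp, rbp, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0]
            continue
        mi = _mi_from_phase_amp(beta_phase[i], gamma_env[i], cfg.pac_n_bins)
        pt, rd = _shape_from_filtered(beta_f[i], broad_f[i], fs)
        expo, off = fit_aperiodic_psd(freqs, psd[i], cfg.aperiodic_fit_range)
        abd, aba, abe = bursts_from_envelope(beta_env[i], fs, thr[i],
                                             cfg.burst_min_dur_s)
        bp, rbp = _band_powers_from_psd(freqs, psd[i], cfg)
        pfd = petrosian_fd(x)
        mob, comp = hjorth_params(x)
        sen = _spec_en_from_psd(psd[i])
        app, samp = _entropy_pair(W_ent[i], cfg.entropy_m, cfg.entropy_r)
        out[i] = [mi, pt, rd, expo, off, abd, aba, abe, bp, rbp,
                  pfd, mob, comp, sen, app, samp]
    return out


def burst_thresholds_from_pre_windows(
        pre_windows: np.ndarray, fs: float,
        cfg: BiomarkerConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Per-channel burst thresholds: the configured percentile of the beta
    envelope pooled over a subject's pre-stimulation windows.

    ``pre_windows`` is (n_trials, n_channels, n_samples).
    """
    pw = np.asarray(pre_windows, dtype=float)
    n_tr, n_ch, n = pw.shape
    env = np.abs(hilbert(bandpass(pw.reshape(n_tr * n_ch, n), fs,
                                  cfg.beta_band), axis=-1))
    env = env.reshape(n_tr, n_ch, n).transpose(1, 0, 2).reshape(n_ch, -1)
    return np.percentile(env, cfg.burst_percentile, axis=1)


def extract_features(trial, burst_thresholds: dict[str, float],
                     central_channels=CENTRAL_CHANNELS,
                     cfg: BiomarkerConfig = DEFAULT_CONFIG) -> TrialFeatures:
    """Channel-averaged pre/stim/post biomarker vectors for one trial.

    ``burst_thresholds`` maps channel name -> subject baseline threshold.
    The post vector is the unweighted mean over the four overlapping windows,
    then all vectors are averaged over ``central_channels``.
    """
    missing = [c for c in central_channels if c not in trial.channel_names]
    if missing:
        raise ValueError(f"trial is missing central channels: {missing}")
    ch_idx = [trial.channel_names.index(c) for c in central_channels]
    windows = segment_trial(trial.data, trial.fs)

    thr = np.array([burst_thresholds[c] for c in central_channels])
    n_ch = len(ch_idx)
    stacks, thrs = [], []
    layout = []  # (interval, window_number)
    for interval in ("pre", "stim", "post"):
        for w_i, win in enumerate(windows[interval]):
            stacks.append(win[ch_idx])
            thrs.append(thr)
            layout.append((interval, w_i))
    block = compute_block(np.concatenate(stacks, axis=0), trial.fs,
                          np.concatenate(thrs), cfg)
    block = block.reshape(len(layout), n_ch, N_BIOMARKERS)

    by_interval: dict[str, list[np.ndarray]] = {"pre": [], "stim": [], "post": []}
    for (interval, _), vecs in zip(layout, block):
        by_interval[interval].append(vecs)
    means = {
        interval: np.mean(np.stack(v), axis=(0, 1))
        for interval, v in by_interval.items()
    }
    return TrialFeatures(
        subject_id=trial.subject_id,
        stim_id=trial.stim_id,
        pre=BiomarkerVector.from_array(means["pre"]),
        stim=BiomarkerVector.from_array(means["stim"]),
        post=BiomarkerVector.from_array(means["post"]),
    )


def channelwise_metrics(trial, cfg: BiomarkerConfig = DEFAULT_CONFIG,
                        intervals=("pre", "stim", "post")) -> dict:
    """Per-channel RelBetaPower and PTAsym per interval (for the q-value
    channel maps); post is the mean of the four overlapping windows.

    Returns {interval: {"RelBetaPower": (n_ch,), "PTAsym": (n_ch,)}}.
    """
    windows = segment_trial(trial.data, trial.fs)
    out: dict = {}
    for interval in intervals:
        wins = windows[interval]
        W = np.concatenate(wins, axis=0)
        freqs, psd = _welch(W, trial.fs)
        beta_f = bandpass(W, trial.fs, cfg.beta_band)
        broad_f = bandpass(W, trial.fs, cfg.total_band)
        rbp = np.empty(W.shape[0])
        pta = np.empty(W.shape[0])
        for i in range(W.shape[0]):
            _, rbp[i] = _band_powers_from_psd(freqs, psd[i], cfg)
            pta[i], _ = _shape_from_filtered(beta_f[i], broad_f[i], trial.fs)
        n_ch = wins[0].shape[0]
        rbp = rbp.reshape(len(wins), n_ch).mean(axis=0)
        pta = pta.reshape(len(wins), n_ch).mean(axis=0)
        out[interval] = {"RelBetaPower": rbp, "PTAsym": pta}
    return out
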