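"""Far-field QRS-T removal and analysis windowing.

Unipolar atrial electrograms carry a ventricular far-field deflection at
every heartbeat.  Following the standard template-subtraction approach,
R peaks are detected on a simultaneous surface-ECG reference, the mean
QRS-T complex is computed across all beats, and that template (least-
squares rescaled per beat and per channel by default) is subtracted at
each beat from every basket channel.  The cleaned recording is then cut
into consecutive, non-overlapping analysis windows (default 5 x 10 s).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .recording import MultiChannelRecording


class InsufficientBeatsError(ValueError):
    """Fewer than two usable beats to build a QRS-T template."""


class InsufficientDurationError(ValueError):
    """Recording shorter than the requested window plan."""


# --------------------------------------------------------------------------
# R-peak detection


def detect_r_peaks(
    ecg: np.ndarray,
    fs_hz: float,
    *,
    band_hz: tuple[float, float] = (5.0, 25.0),
    threshold_frac: float = 0.5,
    refractory_ms: float = 250.0,
    rolling_window_s: float = 2.0,
) -> np.ndarray:
    """Detect R peaks on a single-channel ECG.

    Band-pass (5-25 Hz) the signal, take the absolute envelope, and keep
    local maxima exceeding ``threshold_frac`` times the rolling maximum
    of the envelope, with a refractory period that keeps the larger of
    two competing peaks.  Detections are refined to the nearest extremum
    of the raw signal.  Returns strictly increasing sample indices;
    empty (with a warning) when nothing crosses the threshold.
    """
    ecg = np.asarray(ecg, dtype=float)
    if len(ecg) < 2 * fs_hz:
        raise ValueError("need at least 2 s of ECG for R detection")
    sos = signal.butter(2, band_hz, btype="bandpass", fs=fs_hz, output="sos")
    filt = signal.sosfiltfilt(sos, ecg)
    env = np.abs(filt)

    win = max(3, int(rolling_window_s * fs_hz))
    rolling_max = ndimage.maximum_filter1d(env, size=win, mode="nearest")
    threshold = threshold_frac * rolling_max

    refractory = max(1, int(refractory_ms / 1000.0 * fs_hz))
    peaks, _ = signal.find_peaks(env, distance=refractory)
    peaks = peaks[(env[peaks] >= threshold[peaks]) & (env[peaks] > 0)]
    if len(peaks) == 0:
        warnings.warn("no R peaks exceeded the adaptive threshold", stacklevel=2)
        return np.array([], dtype=int)

    # refine to the raw-signal extremum near each envelope peak
    half = max(1, int(0.040 * fs_hz))
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(len(ecg), p + half + 1)
        refined.append(lo + int(np.argmax(np.abs(ecg[lo:hi]))))
    refined = np.unique(refined)

    # re-impose the refractory period after refinement, keeping larger peaks
    order = np.argsort(np.abs(ecg[refined]))[::-1]
    kept: list[int] = []
    for idx in refined[order]:
        if all(abs(idx - j) >= refractory for j in kept):
            kept.append(int(idx))
    return np.array(sorted(kept), dtype=int)


# --------------------------------------------------------------------------
# QRS-T template


@dataclass
class QRSTTemplate:
    """Mean QRS-T complex aligned on the R peak."""

    waveform: np.ndarray
    pre_r_ms: float
    post_r_ms: float
    fs_hz: float

    @property
    def n_pre(self) -> int:
        return int(round(self.pre_r_ms * self.fs_hz / 1000.0))

    @property
    def n_post(self) -> int:
        return int(round(self.post_r_ms * self.fs_hz / 1000.0))

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        expected = self.n_pre + self.n_post + 1
        if len(self.waveform) != expected:
            raise ValueError(
                f"waveform length {len(self.waveform)} != "
                f"round((pre+post)*fs/1000)+1 = {expected}"
            )


def _beat_slices(
    peaks: np.ndarray, n_pre: int, n_post: int, n_samples: int
) -> list[tuple[int, slice]]:
    """Beats whose full template window lies inside the record."""
    out = []
    for r in np.asarray(peaks, dtype=int):
        lo, hi = r - n_pre, r + n_post + 1
        if lo >= 0 and hi <= n_samples:
            out.append((int(r), slice(lo, hi)))
    return out


def build_qrst_template(
    ecg: np.ndarray,
    peaks: np.ndarray,
    pre_r_ms: float = 50.0,
    post_r_ms: float = 400.0,
    fs_hz: float = 977.0,
) -> QRSTTemplate:
    """Mean QRS-T complex over all beats fully inside the recording."""
    ecg = np.asarray(ecg, dtype=float)
    n_pre = int(round(pre_r_ms * fs_hz / 1000.0))
    n_post = int(round(post_r_ms * fs_hz / 1000.0))
    beats = _beat_slices(np.asarray(peaks), n_pre, n_post, len(ecg))
    if len(beats) < 2:
        raise InsufficientBeatsError(
            f"only {len(beats)} usable beats; need at least 2"
        )
    stack = np.stack([ecg[sl] for _, sl in beats])
    return QRSTTemplate(stack.mean(axis=0), pre_r_ms, post_r_ms, fs_hz)


def subtract_qrst(
    series: np.ndarray,
    peaks: np.ndarray,
    template: QRSTTemplate,
    *,
    per_channel_scale: bool = True,
    max_lag_samples: int = 0,
    pool_scale: bool = False,
) -> np.ndarray:
    """Subtract the QRS-T template at each beat from one channel.

    With ``per_channel_scale`` the template is rescaled per beat by a
    least-squares fit to the channel segment (far-field amplitude varies
    strongly across basket electrodes); otherwise it is subtracted as
    is.  ``pool_scale`` replaces the per-beat scales with their median
    across beats — the far-field amplitude at one electrode is nearly
    constant over a recording, and pooling stops atrial signal inside
    the beat window from leaking into each beat's scale estimate.
    ``max_lag_samples`` > 0 additionally searches small per-beat
    alignment shifts of the template inside the fixed beat window,
    compensating sample-level R-detection jitter.  Samples outside every
    beat window are returned bit-identical; beats whose window crosses a
    record edge are skipped.
    """
    series = np.asarray(series, dtype=float)
    out = series.copy()
    peaks = np.asarray(peaks, dtype=int)
    if len(peaks) == 0:
        warnings.warn("no R peaks supplied; returning input unchanged", stacklevel=2)
        return out
    w = template.waveform
    length = len(w)
    pad = max_lag_samples
    wpad = np.concatenate([np.zeros(pad), w, np.zeros(pad)])
    # candidate templates shifted by each lag, all covering the same
    # fixed beat window (edges clipped to zero)
    shifted = [wpad[pad - lag : pad - lag + length]
               for lag in range(-pad, pad + 1)]
    beats = _beat_slices(peaks, template.n_pre, template.n_post, len(series))

    def _fit(seg: np.ndarray, fixed_scale: float | None) -> tuple[float, np.ndarray]:
        best = None
        for wl in shifted:
            denom = float(wl @ wl)
            if fixed_scale is not None:
                a = fixed_scale
            elif per_channel_scale and denom > 0:
                a = float(wl @ seg) / denom
            else:
                a = 1.0
            resid = float(np.sum((seg - a * wl) ** 2))
            if best is None or resid < best[0]:
                best = (resid, a, wl)
        return best[1], best[2]

    pooled: float | None = None
    if pool_scale and per_channel_scale and beats:
        pooled = float(np.median([_fit(series[sl], None)[0] for _, sl in beats]))
    for _, sl in beats:
        a, wl = _fit(series[sl], pooled)
        out[sl] -= a * wl
    return out


def align_peaks_to_template(
    ecg: np.ndarray,
    peaks: np.ndarray,
    template: QRSTTemplate,
    max_lag_samples: int = 5,
) -> np.ndarray:
    """Refine R-peak samples by template matching on the reference ECG.

    Envelope-based detection jitters by a sample or two at the flat top
    of the R wave; the jitter is resolved on the ECG (where the QRS-T
    dwarfs the noise) by picking, per beat, the shift of the template
    that minimizes the least-squares residual.
    """
    ecg = np.asarray(ecg, dtype=float)
    w = template.waveform
    length = len(w)
    out = []
    for r in np.asarray(peaks, dtype=int):
        best = None
        for lag in range(-max_lag_samples, max_lag_samples + 1):
            lo = r + lag - template.n_pre
            if lo < 0 or lo + length > len(ecg):
                continue
            seg = ecg[lo : lo + length]
            a = float(w @ seg) / float(w @ w)
            resid = float(np.sum((seg - a * w) ** 2))
            if best is None or resid < best[0]:
                best = (resid, r + lag)
        out.append(best[1] if best is not None else int(r))
    return np.array(out, dtype=int)


def remove_ventricular_farfield(
    rec: MultiChannelRecording,
    ecg: np.ndarray,
    *,
    pre_r_ms: float = 50.0,
    post_r_ms: float = 400.0,
    per_channel_scale: bool = True,
    max_lag_samples: int = 0,
) -> tuple[MultiChannelRecording, np.ndarray]:
    """Full far-field removal: detect R peaks, build template, subtract.

    The template is built from the reference ECG, beat positions are
    refined by template matching on the ECG (absorbing sample-level
    detection jitter), the template is rebuilt on the refined beats, and
    each basket channel is cleaned with least-squares scaling of that
    template (beat-pooled per channel: the template shape is shared, the
    amplitude is not).  Returns the cleaned recording and the refined
    R-peak sample indices.
    """
    peaks = detect_r_peaks(ecg, rec.fs_hz)
    if len(peaks) < 2:
        warnings.warn("fewer than 2 beats detected; recording left unchanged",
                      stacklevel=2)
        return rec.copy(), peaks
    template = build_qrst_template(ecg, peaks, pre_r_ms, post_r_ms, rec.fs_hz)
    for _ in range(2):  # align beats, then re-estimate with the cleaner template
        peaks = align_peaks_to_template(ecg, peaks, template)
        template = build_qrst_template(ecg, peaks, pre_r_ms, post_r_ms, rec.fs_hz)
    cleaned = np.column_stack([
        subtract_qrst(rec.data[:, c], peaks, template,
                      per_channel_scale=per_channel_scale,
                      max_lag_samples=max_lag_samples,
                      pool_scale=True)
        for c in range(rec.n_channels)
    ])
    return MultiChannelRecording(cleaned, rec.fs_hz, list(rec.labels)), peaks


# --------------------------------------------------------------------------
# windowing


@dataclass
class WindowSet:
    """Consecutive, non-overlapping, equal-length analysis windows."""

    windows: list[np.ndarray]
    window_s: float
    fs_hz: float

    @property
    def n_windows(self) -> int:
        return len(self.windows)


def segment_windows(
    rec: MultiChannelRecording, window_s: float = 10.0, n_windows: int = 5
) -> WindowSet:
    """Cut the first ``n_windows`` windows of ``window_s`` seconds each.

    The remainder of the recording past ``n_windows * window_s`` is
    discarded.  Raises if the recording is too short.
    """
    if n_windows < 1 or window_s <= 0:
        raise ValueError("need n_windows >= 1 and window_s > 0")
    samples_per_window = int(round(window_s * rec.fs_hz))
    needed = samples_per_window * n_windows
    if rec.n_samples < needed:
        raise InsufficientDurationError(
            f"recording has {rec.n_samples} samples; "
            f"{n_windows} x {window_s}s windows need {needed}"
        )
    windows = [
        rec.data[i * samples_per_window : (i + 1) * samples_per_window, :]
        for i in range(n_windows)
    ]
    return WindowSet(windows, window_s, rec.fs_hz)
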