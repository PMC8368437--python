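"""Sensor-space preprocessing: artifact rejection, band decomposition, ictal segmentation.

The analysis bands are the six canonical ranges used for ictal MEG work on
absence epilepsy: delta-range 1-4 Hz (the spike-wave fundamental), 4-8,
8-12 (alpha), 12-30 (beta), 30-80 (gamma) and 80-250 Hz (ripple-band high
frequency oscillations).  Seizure segments are delimited from the first
spike to the offset of the last slow wave and must exceed 3 s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .exceptions import ConfigurationError, EmptyDataError

__all__ = [
    "BandDefinition",
    "CANONICAL_BANDS",
    "SensorRecording",
    "IctalSegment",
    "reject_artifacts",
    "bandpass",
    "detect_ictal_segments",
    "global_field_power",
    "segments_to_tsv",
    "mask_to_json",
]

#: Default peak-amplitude criterion for magnetic artifacts, tesla (6 pT).
ARTIFACT_LIMIT_T = 6e-12

#: Power-line frequency that is notched out whenever a band contains it.
LINE_FREQ_HZ = 50.0


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band ``[lo_hz, hi_hz)`` in hertz."""

    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not (0.0 < self.lo_hz < self.hi_hz):
            raise ConfigurationError(
                f"band {self.name!r}: need 0 < lo < hi, got ({self.lo_hz}, {self.hi_hz})"
            )

    def contains(self, freq_hz: float) -> bool:
        return self.lo_hz < freq_hz < self.hi_hz


#: The canonical six-band decomposition (Hz).
CANONICAL_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("1-4", 1.0, 4.0),
    BandDefinition("4-8", 4.0, 8.0),
    BandDefinition("8-12", 8.0, 12.0),
    BandDefinition("12-30", 12.0, 30.0),
    BandDefinition("30-80", 30.0, 80.0),
    BandDefinition("80-250", 80.0, 250.0),
)


def band_by_name(name: str) -> BandDefinition:
    for b in CANONICAL_BANDS:
        if b.name == name:
            return b
    raise ConfigurationError(f"unknown band {name!r}")


@dataclass
class SensorRecording:
    """Multichannel magnetometer time series.

    data : (n_channels, n_samples) float array, tesla.
    rate_hz : sampling rate, samples per second.
    channel_ids : one label per row of ``data``.
    t0 : time of the first sample, seconds.
    """

    data: np.ndarray
    rate_hz: float
    channel_ids: tuple[str, ...]
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ConfigurationError("data must be 2-D (channels x samples)")
        if self.rate_hz <= 0:
            raise ConfigurationError("rate_hz must be positive")
        self.channel_ids = tuple(str(c) for c in self.channel_ids)
        if len(self.channel_ids) != self.data.shape[0]:
            raise ConfigurationError(
                f"{len(self.channel_ids)} channel ids for {self.data.shape[0]} rows"
            )
        if not np.all(np.isfinite(self.data)):
            raise ConfigurationError("data contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.rate_hz


@dataclass(frozen=True)
class IctalSegment:
    """Half-open sample interval ``[start_sample, end_sample)`` of one seizure."""

    start_sample: int
    end_sample: int
    rate_hz: float

    def __post_init__(self) -> None:
        if self.end_sample <= self.start_sample:
            raise ConfigurationError("segment end must exceed start")

    @property
    def duration_s(self) -> float:
        return (self.end_sample - self.start_sample) / self.rate_hz

    @property
    def start_s(self) -> float:
        return self.start_sample / self.rate_hz

    @property
    def end_s(self) -> float:
        return self.end_sample / self.rate_hz


def reject_artifacts(
    rec: SensorRecording,
    amplitude_limit: float = ARTIFACT_LIMIT_T,
    window_s: float = 1.0,
) -> tuple[SensorRecording, np.ndarray]:
    """Mask windows whose peak absolute field on any channel exceeds the limit.

    The recording is tiled into consecutive non-overlapping windows of
    ``window_s``; a window where any channel exceeds ``amplitude_limit``
    (strictly, matching the ">6 pT" criterion) is marked rejected.  Data are
    left in place; the boolean per-sample mask (True = rejected) is returned
    for audit and is honoured by :func:`detect_ictal_segments`.

    Raises
    ------
    EmptyDataError
        If every window is rejected.
    """
    if window_s <= 0:
        raise ConfigurationError("window_s must be positive")
    win = max(1, int(round(window_s * rec.rate_hz)))
    mask = np.zeros(rec.n_samples, dtype=bool)
    peak = np.max(np.abs(rec.data), axis=0)
    for start in range(0, rec.n_samples, win):
        stop = min(start + win, rec.n_samples)
        if np.max(peak[start:stop]) > amplitude_limit:
            mask[start:stop] = True
    if mask.all():
        raise EmptyDataError(
            "all windows exceed the artifact amplitude limit "
            f"({amplitude_limit:.3g} T); nothing left to analyse"
        )
    return rec, mask


def _band_sos(band: BandDefinition, rate_hz: float, order: int = 4) -> np.ndarray:
    nyq = rate_hz / 2.0
    if band.hi_hz >= nyq:
        raise ConfigurationError(
            f"band {band.name!r} upper edge {band.hi_hz} Hz is not below "
            f"Nyquist ({nyq} Hz)"
        )
    return signal.butter(order, [band.lo_hz, band.hi_hz], btype="bandpass",
                         fs=rate_hz, output="sos")


def bandpass(rec: SensorRecording, band: BandDefinition, order: int = 4) -> SensorRecording:
    """Zero-phase band-pass filter (Butterworth, forward-backward).

    When the band contains the 50 Hz power line, a zero-phase notch is applied
    in addition, so line noise never enters band-limited analyses.
    """
    sos = _band_sos(band, rec.rate_hz, order=order)
    # Pad with three cycles of the low band edge so narrowband edge
    # transients settle before the retained samples.
    padlen = min(rec.n_samples - 1, int(3 * rec.rate_hz / band.lo_hz))
    out = signal.sosfiltfilt(sos, rec.data, axis=-1, padlen=padlen)
    if band.contains(LINE_FREQ_HZ):
        b, a = signal.iirnotch(LINE_FREQ_HZ, Q=30.0, fs=rec.rate_hz)
        out = signal.filtfilt(b, a, out, axis=-1)
    return replace(rec, data=out)


def global_field_power(data: np.ndarray) -> np.ndarray:
    """Root-mean-square field across channels at each sample."""
    return np.sqrt(np.mean(np.square(data), axis=0))


def _clean_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of False (usable) samples as half-open intervals."""
    good = ~mask
    if not good.any():
        return []
    idx = np.flatnonzero(np.diff(good.astype(np.int8)))
    edges = np.concatenate([[0] if good[0] else [], idx + 1, [len(good)] if good[-1] else []])
    edges = edges.astype(int)
    return [(edges[i], edges[i + 1]) for i in range(0, len(edges), 2)]


def detect_ictal_segments(
    rec: SensorRecording,
    min_duration_s: float = 3.0,
    swd_rate_hz: float = 3.0,
    k_mad: float = 10.0,
    bad_mask: np.ndarray | None = None,
) -> list[IctalSegment]:
    """Detect generalized spike-wave runs lasting more than ``min_duration_s``.

    Candidate spikes are peaks of the 1-4 Hz global field power (GFP)
    exceeding ``median + k_mad * MAD`` of the quiet-window baseline.  The
    default ``k_mad = 10`` sits well above the extreme-value tail of the
    baseline GFP (whose MAD is narrow because GFP pools many channels) while
    staying an order of magnitude below typical discharge peaks.  Consecutive spikes whose intervals are
    compatible with ``swd_rate_hz`` +/- 1 Hz form a run; a run whose span
    (first-spike onset to last slow-wave offset) strictly exceeds
    ``min_duration_s`` becomes a segment.  The segment starts where the
    envelope first rises above threshold before the first spike and ends
    where it falls back below threshold after the last spike (the slow-wave
    offset).  Segments never overlap samples flagged in ``bad_mask``.
    """
    if rec.duration_s <= min_duration_s:
        raise ConfigurationError("recording shorter than the minimum segment duration")
    if bad_mask is None:
        bad_mask = np.zeros(rec.n_samples, dtype=bool)

    low = bandpass(rec, BandDefinition("swd", 1.0, min(4.0, rec.rate_hz / 2 - 1e-6)))
    gfp = global_field_power(low.data)
    # Baseline statistics from the quietest quarter of 1-s windows, so the
    # threshold stays anchored to the interictal floor regardless of how much
    # of the recording the discharges occupy.
    win = max(1, int(round(rec.rate_hz)))
    n_win = max(1, gfp.size // win)
    rms = np.array([np.sqrt(np.mean(gfp[i * win:(i + 1) * win] ** 2))
                    for i in range(n_win)])
    quiet = np.argsort(rms)[: max(1, int(np.ceil(0.25 * n_win)))]
    base = np.concatenate([gfp[i * win:(i + 1) * win] for i in quiet])
    med = float(np.median(base))
    mad = float(np.median(np.abs(base - med)))
    thr = med + k_mad * mad
    if mad == 0.0:
        return []

    # Smooth envelope of the GFP for onset/offset placement (0.2 s boxcar).
    w = max(1, int(round(0.2 * rec.rate_hz)))
    env = np.convolve(gfp, np.ones(w) / w, mode="same")

    min_gap = int(rec.rate_hz / (swd_rate_hz + 1.0))
    peaks, _ = signal.find_peaks(gfp, height=thr, distance=min_gap)
    peaks = peaks[~bad_mask[peaks]]
    if peaks.size == 0:
        return []

    lo_int = rec.rate_hz / (swd_rate_hz + 1.0)
    # 10% slack over the slowest admissible cycle absorbs jitter when the
    # detected peak is the slow wave rather than the spike of a cycle.
    hi_int = 1.1 * rec.rate_hz / max(swd_rate_hz - 1.0, 0.5)
    runs: list[list[int]] = [[int(peaks[0])]]
    for p in peaks[1:]:
        gap = p - runs[-1][-1]
        # A gap of two cycles means one spike fell below threshold; tolerate
        # a single missed spike rather than splitting the discharge run.
        if lo_int <= gap <= hi_int or 2 * lo_int <= gap <= 2 * hi_int:
            runs[-1].append(int(p))
        else:
            runs.append([int(p)])
    # The missed-spike tolerance may attach a stray peak at a run's edge;
    # a run must begin and end on consecutive-cycle spikes, so trim edge
    # peaks that only connect through a double-cycle gap.
    for run in runs:
        while len(run) > 1 and not lo_int <= run[1] - run[0] <= hi_int:
            run.pop(0)
        while len(run) > 1 and not lo_int <= run[-1] - run[-2] <= hi_int:
            run.pop()
        # Acausal filter tails of a strong discharge produce small precursor
        # and decay peaks; a run's edge spikes must be commensurate with its
        # body, so trim edge peaks far below the median spike height.
        h_med = float(np.median(gfp[np.asarray(run)]))
        while len(run) > 1 and gfp[run[0]] < 0.3 * h_med:
            run.pop(0)
        while len(run) > 1 and gfp[run[-1]] < 0.3 * h_med:
            run.pop()

    # A genuine discharge lasting min_duration_s at swd_rate_hz +/- 1 carries
    # at least this many suprathreshold spikes; chains of sparse noise peaks
    # linked through the missed-spike tolerance fall short of it, and their
    # median inter-spike interval is not a single discharge cycle.
    min_spikes = max(2, int(np.ceil(min_duration_s * max(swd_rate_hz - 1.0, 0.5))))
    segments: list[IctalSegment] = []
    clean = _clean_runs(bad_mask)
    for run in runs:
        if len(run) < min_spikes:
            continue
        med_gap = float(np.median(np.diff(run)))
        if not lo_int <= med_gap <= hi_int:
            continue
        # Boundary threshold relative to this run's spike height, so the
        # acausal filter skirt of a strong discharge does not stretch the
        # segment into the surrounding baseline.
        thr_walk = max(thr, 0.1 * float(np.median(gfp[np.asarray(run)])))
        # First-spike onset: walk back to where the envelope drops below threshold.
        s = run[0]
        while s > 0 and env[s - 1] >= thr_walk and not bad_mask[s - 1]:
            s -= 1
        # Last slow-wave offset: forward to where the envelope returns below threshold.
        e = run[-1]
        while e < rec.n_samples - 1 and env[e + 1] >= thr_walk and not bad_mask[e + 1]:
            e += 1
        e += 1  # half-open
        # Clip to the clean interval containing the run.
        for c0, c1 in clean:
            if c0 <= run[0] < c1:
                s, e = max(s, c0), min(e, c1)
                break
        segments.append((s, e))
    # Sub-runs of one discharge expand to overlapping spans; merge them.
    segments.sort()
    merged: list[list[int]] = []
    for s, e in segments:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [
        IctalSegment(s, e, rec.rate_hz)
        for s, e in merged
        if (e - s) / rec.rate_hz > min_duration_s
    ]


def segments_to_tsv(segments: list[IctalSegment], path) -> None:
    with open(path, "w") as fh:
        fh.write("start_s\tend_s\tduration_s\n")
        for seg in segments:
            fh.write(f"{seg.start_s:.6f}\t{seg.end_s:.6f}\t{seg.duration_s:.6f}\n")


def mask_to_json(mask: np.ndarray, rate_hz: float, path) -> None:
    """Persist a rejection mask as a list of rejected [start_s, end_s) intervals."""
    runs = _clean_runs(~np.asarray(mask, dtype=bool))
    payload = {
        "rate_hz": rate_hz,
        "rejected_intervals_s": [[s / rate_hz, e / rate_hz] for s, e in runs],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
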