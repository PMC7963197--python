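"""Raw EMG + barbell trace -> phase-normalized, amplitude-normalized envelopes.

The power clean is segmented from the vertical barbell displacement: the lowest
barbell position (plates on the floor in touch-and-go reps) starts the ascendant
phase, the highest position ends it; the descendant phase runs to the next
minimum.  Each analyzed repetition becomes a muscles x 200 matrix (100 points
per phase), amplitude-normalized to a reference recorded at 90% of the 5 RM
load.  The first and last repetitions of every set are discarded.

All filtering is zero-phase (forward-backward Butterworth): timing lags between
muscles and subjects are the analysis outcome, so one-pass filters, which delay
the envelope, are never used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

#: Muscle codes, in recording order: upper trapezius, pectoralis major, biceps
#: brachii, triceps brachii, flexor digitorum superficialis, extensor digitorum
#: communis, latissimus dorsi, erector spinae, rectus abdominis, external
#: oblique, gluteus maximus, vastus lateralis, biceps femoris, semitendinosus,
#: lateral gastrocnemius, tibialis anterior.
MUSCLES = [
    "TS", "PM", "BB", "TB", "FDS", "EDC", "LD", "ES",
    "RA", "OE", "Gmax", "VL", "BF", "ST", "GL", "TA",
]

#: Points per phase-normalized cycle (100 ascendant + 100 descendant).
CYCLE_POINTS = 200
PHASE_SPLIT = 100


@dataclass
class EmgSet:
    """One set of repetitions: raw multichannel EMG plus the barbell trace."""

    emg: np.ndarray            # channels x samples
    fs_emg: float              # Hz
    barbell: np.ndarray        # vertical displacement, mocap rate
    fs_mocap: float            # Hz
    channel_labels: list[str] = field(default_factory=lambda: list(MUSCLES))
    load_pct: float = 0.70     # fraction of the 5 RM load

    def __post_init__(self) -> None:
        self.emg = np.asarray(self.emg, dtype=float)
        self.barbell = np.asarray(self.barbell, dtype=float)
        if self.emg.ndim != 2:
            raise ValueError("emg must be a channels x samples matrix")
        if self.fs_emg <= 900:
            raise ValueError("fs_emg must exceed 900 Hz for the 20-450 Hz band")


@dataclass
class CycleEnvelope:
    """One repetition's phase-normalized envelope matrix (muscles x 200)."""

    values: np.ndarray
    phase_split: int = PHASE_SPLIT

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != CYCLE_POINTS:
            raise ValueError(
                f"cycle envelope must have {CYCLE_POINTS} columns, "
                f"got shape {self.values.shape}"
            )
        if np.any(self.values < 0):
            raise ValueError("cycle envelope entries must be nonnegative")


def _sos_lowpass(cutoff: float, fs: float, order: int = 4) -> np.ndarray:
    return signal.butter(order, cutoff, btype="low", fs=fs, output="sos")


def smooth_barbell(trace: np.ndarray, fs: float, cutoff: float = 8.0,
                   order: int = 4) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass (8 Hz) of the barbell trace."""
    trace = np.asarray(trace, dtype=float)
    sos = _sos_lowpass(cutoff, fs, order)
    # pad beyond the filter's slow tail so the edges stay zero-phase
    padlen = min(int(3 * fs / cutoff), trace.size - 1)
    if trace.size <= 3 * (2 * sos.shape[0] + 1):
        raise ValueError(f"trace too short to filter ({trace.size} samples)")
    return signal.sosfiltfilt(sos, trace, padlen=padlen)


def detect_phases(smoothed: np.ndarray, fs: float | None = None,
                  prominence_frac: float = 0.10) -> list[tuple[int, int, int]]:
    """Segment repetitions from the smoothed barbell displacement.

    Returns ``(asc_start, asc_end, desc_end)`` sample-index triples in temporal
    order: ascendant phase from a displacement minimum to the following
    maximum, descendant phase from that maximum to the next minimum.  Maxima
    are detected with a prominence of `prominence_frac` of the trace range to
    reject jitter extrema; the boundary minima are the argmin between (and
    around) consecutive maxima, so repetitions starting or ending at the trace
    edges are kept.
    """
    x = np.asarray(smoothed, dtype=float)
    rng = x.max() - x.min()
    if rng <= 0:
        raise ValueError("no repetitions detected (constant trace)")
    maxima, _ = signal.find_peaks(x, prominence=prominence_frac * rng)
    if maxima.size == 0:
        raise ValueError("no repetitions detected")
    bounds = []
    edges = np.concatenate(([0], maxima, [x.size - 1]))
    for lo, hi in zip(edges[:-1], edges[1:]):
        seg = x[lo:hi + 1]
        bounds.append(lo + int(np.argmin(seg)))
    reps = []
    for i, m in enumerate(maxima):
        a, b = bounds[i], bounds[i + 1]
        if a < m < b:
            reps.append((a, int(m), b))
    if not reps:
        raise ValueError("no repetitions detected")
    return reps


def emg_envelope(emg: np.ndarray, fs: float, band: tuple[float, float] = (20.0, 450.0),
                 lowpass: float = 12.0, order: int = 4) -> np.ndarray:
    """Linear envelope: 20-450 Hz band-pass, rectification, 12 Hz low-pass.

    Both filters are 4th-order Butterworth applied forward-backward
    (zero-phase); the result is clipped at zero (filtfilt undershoot).
    Accepts a 1-D signal or a channels x samples matrix.
    """
    emg = np.atleast_2d(np.asarray(emg, dtype=float))
    if fs <= 2 * band[1]:
        raise ValueError(f"fs={fs} too low for a {band[1]} Hz band edge")
    sos_bp = signal.butter(order, band, btype="band", fs=fs, output="sos")
    sos_lp = _sos_lowpass(lowpass, fs, order)
    # pad past the slowest pole (the 20 Hz / 12 Hz edges) so both passes
    # stay zero-phase out to the recording edges
    pad_bp = min(int(3 * fs / band[0]), emg.shape[1] - 1)
    pad_lp = min(int(3 * fs / lowpass), emg.shape[1] - 1)
    out = signal.sosfiltfilt(sos_bp, emg, axis=1, padlen=pad_bp)
    out = np.abs(out)
    out = signal.sosfiltfilt(sos_lp, out, axis=1, padlen=pad_lp)
    return np.clip(out, 0.0, None)


def normalization_reference(envelope_90pct: np.ndarray, fs: float,
                            window_s: float = 0.1,
                            labels: list[str] | None = None) -> np.ndarray:
    """Per-muscle amplitude reference from the 90%-5RM set's envelope.

    For each channel, the envelope mean over the 100 ms window centered on the
    global envelope peak (window truncated at recording edges, never padded).
    """
    env = np.atleast_2d(np.asarray(envelope_90pct, dtype=float))
    labels = labels or MUSCLES
    half = int(round(window_s / 2 * fs))
    factors = np.empty(env.shape[0])
    for i, row in enumerate(env):
        if not np.any(row > 0):
            name = labels[i] if i < len(labels) else str(i)
            raise ValueError(f"all-zero envelope for channel {name}")
        peak = int(np.argmax(row))
        lo, hi = max(0, peak - half), min(row.size, peak + half + 1)
        factors[i] = row[lo:hi].mean()
    return factors


def normalize_cycles(envelopes: np.ndarray, phases: list[tuple[int, int, int]],
                     ref: np.ndarray, fs_emg: float,
                     fs_mocap: float) -> list[CycleEnvelope]:
    """Amplitude-normalize and phase-normalize each analyzed repetition.

    Drops the first and last repetitions, divides each channel by its
    reference factor, then linearly resamples the ascendant and descendant
    phases separately to 100 points each.  Phase boundaries come from the
    barbell trace (mocap rate) and are converted to EMG samples by time.
    """
    env = np.atleast_2d(np.asarray(envelopes, dtype=float))
    ref = np.asarray(ref, dtype=float)
    if len(phases) < 3:
        raise ValueError("exclusion leaves no repetitions (< 3 detected)")
    scale = fs_emg / fs_mocap
    cycles = []
    for a, b, c in phases[1:-1]:
        ia = min(int(round(a * scale)), env.shape[1] - 1)
        ib = min(int(round(b * scale)), env.shape[1] - 1)
        ic = min(int(round(c * scale)), env.shape[1] - 1)
        if not (ia < ib < ic):
            raise ValueError("degenerate phase boundaries after rate conversion")
        out = np.empty((env.shape[0], CYCLE_POINTS))
        for (lo, hi), sl in (((ia, ib), slice(0, PHASE_SPLIT)),
                             ((ib, ic), slice(PHASE_SPLIT, CYCLE_POINTS))):
            xp = np.arange(lo, hi + 1, dtype=float)
            xq = np.linspace(lo, hi, PHASE_SPLIT)
            for ch in range(env.shape[0]):
                out[ch, sl] = np.interp(xq, xp, env[ch, lo:hi + 1])
        out /= ref[:, None]
        cycles.append(CycleEnvelope(np.clip(out, 0.0, None)))
    return cycles


def assemble_matrix(cycles: list[CycleEnvelope]) -> np.ndarray:
    """Concatenate cycle envelopes in temporal order into the NMF input E."""
    if not cycles:
        raise ValueError("no cycles to assemble")
    n_ch = {c.values.shape[0] for c in cycles}
    if len(n_ch) != 1:
        raise ValueError(f"inconsistent channel counts across cycles: {n_ch}")
    return np.hstack([c.values for c in cycles])


def process_set(emg_set: EmgSet, ref: np.ndarray) -> list[CycleEnvelope]:
    """Full preprocessing chain for one set: envelope, segmentation, normalization."""
    env = emg_envelope(emg_set.emg, emg_set.fs_emg)
    bar = smooth_barbell(emg_set.barbell, emg_set.fs_mocap)
    phases = detect_phases(bar, emg_set.fs_mocap)
    return normalize_cycles(env, phases, ref, emg_set.fs_emg, emg_set.fs_mocap)
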