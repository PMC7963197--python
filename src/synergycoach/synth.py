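"""Synthetic surface-EMG generator with known synergy ground truth.

No recordings accompany the study this pipeline targets, so every downstream
stage is exercised on simulated data built from the generative model the
analysis assumes: envelopes are ``W @ C`` for a nonnegative muscle-weight
matrix ``W`` (16 muscles x 3 synergies by default) and nonnegative activation
waveforms ``C`` (one 200-point curve per synergy), plus noise.

Two simulated groups mirror the study design: group A ("UNE", untrained) uses
the base weights and unshifted templates; group B ("EXP", trained
weightlifters) activates each synergy with a signed timing offset (defaults
-2.46, -4.60, +1.86 % of cycle) and uses a muscle-weight matrix with the
composition changes reported for trained lifters (synergy #1 shifts load from
latissimus/erector spinae toward vastus lateralis; synergy #3 leans on erector
spinae and latissimus rather than tibialis anterior / vastus lateralis).
Per-subject variability is multiplicative lognormal jitter on the weights,
Gaussian timing jitter, and a lognormal sharpness (power) jitter on the
template shapes; repetitions add small timing jitter and Gaussian noise at a
configurable SNR, clipped at zero.

Timing convention used everywhere in this package: shifts and lags are in % of
the 200-point cycle (1% = 2 points); a positive value means *delayed*.
Template shifts are applied circularly (the movement is cyclic touch-and-go).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .preprocess import CYCLE_POINTS, MUSCLES, CycleEnvelope, EmgSet

GROUP_A_ALIASES = {"A", "UNE", "a", "une"}
GROUP_B_ALIASES = {"B", "EXP", "b", "exp"}

#: Qualitative muscle groupings of the three synergies (untrained group):
#: #1 back + posterior lower limb (hip extension), #2 upper-limb pull,
#: #3 end-of-ascent trunk muscles with VL and TA.
_SYNERGY_MUSCLES = [
    ["TS", "LD", "ES", "Gmax", "BF", "ST", "GL"],
    ["TS", "BB", "TB", "FDS", "EDC"],
    ["RA", "OE", "ES", "PM", "VL", "TA"],
]


@dataclass
class GroundTruth:
    """Generative parameters shared by every simulated subject."""

    W0: np.ndarray                     # muscles x synergies, group A weights
    C0_templates: np.ndarray           # synergies x 200 activation templates
    group_shifts: tuple[float, ...]    # % of cycle, applied to group B (+ = delayed)
    W0_b: np.ndarray | None = None     # group B weights (None -> same as W0)
    weight_jitter_sd: float = 0.25     # lognormal sigma on W entries per subject
    subject_shift_sd: float = 0.75     # per-subject timing jitter, % of cycle
    rep_shift_sd: float = 0.5          # per-repetition timing jitter, % of cycle
    shape_jitter_sd: float = 0.15      # lognormal sigma of per-subject template power
    shape_mod_amp: float = 0.15        # per-subject smooth waveform-modulation depth
    snr_db: float = 8.0                # additive-noise level (np.inf = noise-free)

    def __post_init__(self) -> None:
        self.W0 = np.asarray(self.W0, dtype=float)
        self.C0_templates = np.asarray(self.C0_templates, dtype=float)
        if np.any(self.W0 < 0) or np.any(self.C0_templates < 0):
            raise ValueError("ground-truth weights and templates must be nonnegative")
        if self.C0_templates.shape[1] != CYCLE_POINTS:
            raise ValueError(f"templates must have {CYCLE_POINTS} points per cycle")
        if self.W0.shape[1] != self.C0_templates.shape[0]:
            raise ValueError("W0 and C0_templates disagree on the synergy count")
        if len(self.group_shifts) != self.n_synergies:
            raise ValueError("one group shift per synergy required")
        if self.W0_b is not None:
            self.W0_b = np.asarray(self.W0_b, dtype=float)
            if self.W0_b.shape != self.W0.shape or np.any(self.W0_b < 0):
                raise ValueError("W0_b must match W0's shape and be nonnegative")

    @property
    def n_muscles(self) -> int:
        return self.W0.shape[0]

    @property
    def n_synergies(self) -> int:
        return self.W0.shape[1]

    def weights_for(self, group: str) -> np.ndarray:
        if group in GROUP_A_ALIASES:
            return self.W0
        if group in GROUP_B_ALIASES:
            return self.W0_b if self.W0_b is not None else self.W0
        raise ValueError(f"unknown group {group!r} (expected A/UNE or B/EXP)")


def _gaussian_bump(center: float, width: float) -> np.ndarray:
    t = np.arange(CYCLE_POINTS, dtype=float)
    # circular distance so bumps near the cycle ends wrap smoothly
    d = np.minimum(np.abs(t - center), CYCLE_POINTS - np.abs(t - center))
    return np.exp(-0.5 * (d / width) ** 2)


def make_default_ground_truth(n_muscles: int = 16, n_synergies: int = 3,
                              seed: int = 0, **overrides) -> GroundTruth:
    """Default ground truth: Gaussian-bump templates, grouped muscle loadings.

    With the default 16 muscles / 3 synergies, loadings follow the qualitative
    composition described for the power clean (hip extension, upper-limb pull,
    end-of-ascent trunk burst) and the group-B weight matrix encodes the
    trained-group composition changes.  Other shapes get a block layout.
    Deterministic for a fixed seed.  Keyword overrides set any
    :class:`GroundTruth` parameter (e.g. ``snr_db=np.inf``).
    """
    if not (n_muscles >= n_synergies >= 1):
        raise ValueError("need n_muscles >= n_synergies >= 1")
    rng = np.random.default_rng(seed)

    if n_synergies <= 3:
        # distinct bursts: hip extension early-mid pull, upper-limb pull late
        # in the ascent, trunk burst spanning the turnaround at end-of-ascent
        centers = [30.0, 70.0, 108.0][:n_synergies]
        widths = [18.0, 12.0, 16.0][:n_synergies]
    else:
        centers = list(np.linspace(25.0, 140.0, n_synergies))
        widths = [15.0] * n_synergies
    templates = np.vstack([_gaussian_bump(c, w) for c, w in zip(centers, widths)])

    W0 = 0.05 + 0.10 * rng.random((n_muscles, n_synergies))
    if n_muscles == 16 and n_synergies == 3:
        labels = MUSCLES
        for j, members in enumerate(_SYNERGY_MUSCLES):
            for m in members:
                W0[labels.index(m), j] = 0.75 + 0.25 * rng.random()
        W0_b = W0.copy()
        # trained-group composition: synergy #1 trades LD/ES for VL ...
        W0_b[labels.index("LD"), 0] *= 0.35
        W0_b[labels.index("ES"), 0] *= 0.45
        W0_b[labels.index("VL"), 0] = 0.90
        # ... synergy #3 leans on ES/LD instead of TA/VL
        W0_b[labels.index("TA"), 2] *= 0.30
        W0_b[labels.index("VL"), 2] *= 0.35
        W0_b[labels.index("LD"), 2] = 0.85
        W0_b[labels.index("ES"), 2] = min(1.0, W0_b[labels.index("ES"), 2] * 1.2)
    else:
        for i in range(n_muscles):
            W0[i, (i * n_synergies) // n_muscles] = 0.75 + 0.25 * rng.random()
        W0_b = W0 * rng.lognormal(0.0, 0.35, size=W0.shape)
    W0 /= W0.max(axis=0, keepdims=True)
    W0_b /= W0_b.max(axis=0, keepdims=True)

    shifts = (-2.46, -4.60, 1.86)[:n_synergies]
    if n_synergies > 3:
        shifts = shifts + (0.0,) * (n_synergies - 3)
    params = dict(W0=W0, C0_templates=templates, group_shifts=shifts, W0_b=W0_b)
    params.update(overrides)
    return GroundTruth(**params)


def _pct_to_points(pct: float) -> int:
    return int(round(pct * CYCLE_POINTS / 100.0))


def _smooth_modulation(rng: np.random.Generator, amp: float) -> np.ndarray:
    """Smooth positive modulation curve: 1 + amp * low-order Fourier noise."""
    if amp == 0:
        return np.ones(CYCLE_POINTS)
    t = np.arange(CYCLE_POINTS) / CYCLE_POINTS
    f = np.zeros(CYCLE_POINTS)
    for h in (1, 2, 3):
        a, b = rng.normal(0.0, 1.0 / h, size=2)
        f += a * np.cos(2 * np.pi * h * t) + b * np.sin(2 * np.pi * h * t)
    f /= max(f.std(), 1e-12)
    return np.clip(1.0 + amp * f, 0.05, None)


def _subject_draws(gt: GroundTruth, group: str, rng: np.random.Generator):
    """Subject-level draws: weights, timing offsets (%), shaped templates."""
    W = gt.weights_for(group) * rng.lognormal(0.0, gt.weight_jitter_sd,
                                              size=gt.W0.shape)
    base = np.array(gt.group_shifts) if group in GROUP_B_ALIASES else \
        np.zeros(gt.n_synergies)
    shifts = base + rng.normal(0.0, gt.subject_shift_sd, size=gt.n_synergies)
    powers = rng.lognormal(0.0, gt.shape_jitter_sd, size=gt.n_synergies)
    templates = np.vstack([
        gt.C0_templates[k] ** powers[k] *
        _smooth_modulation(rng, gt.shape_mod_amp)
        for k in range(gt.n_synergies)])
    return W, shifts, templates


def _cycle_activation(templates: np.ndarray, shifts_pct: np.ndarray) -> np.ndarray:
    return np.vstack([np.roll(templates[k], _pct_to_points(shifts_pct[k]))
                      for k in range(templates.shape[0])])


def simulate_subject(gt: GroundTruth, group: str, n_reps: int,
                     seed: int) -> list[CycleEnvelope]:
    """Simulate one subject's analyzed repetitions as phase-normalized envelopes.

    Subject-level draws (weights, timing, template sharpness) are fixed by the
    seed; each repetition adds its own timing jitter and measurement noise at
    ``gt.snr_db``, then clips at zero so envelopes stay valid NMF input.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    W, shifts, templates = _subject_draws(gt, group, rng)
    cycles = []
    for _ in range(n_reps):
        rep_shifts = shifts + rng.normal(0.0, gt.rep_shift_sd, gt.n_synergies)
        E = W @ _cycle_activation(templates, rep_shifts)
        if np.isfinite(gt.snr_db):
            noise_sd = np.sqrt(np.mean(E ** 2)) * 10 ** (-gt.snr_db / 20.0)
            E = E + rng.normal(0.0, noise_sd, size=E.shape)
        cycles.append(CycleEnvelope(np.clip(E, 0.0, None)))
    return cycles


def _barbell_cycle(n_asc: int, n_desc: int, height: float = 1.0) -> np.ndarray:
    up = height * 0.5 * (1.0 - np.cos(np.pi * np.arange(n_asc) / n_asc))
    down = height * 0.5 * (1.0 + np.cos(np.pi * np.arange(n_desc) / n_desc))
    return np.concatenate([up, down])


def simulate_raw_set(gt: GroundTruth, group: str, n_reps: int, fs_emg: float,
                     fs_mocap: float, seed: int, t_asc: float = 0.9,
                     t_desc: float = 1.1, load_pct: float = 0.70) -> EmgSet:
    """Simulate a raw-like set: envelope-modulated EMG carrier + barbell trace.

    Emits ``n_reps + 2`` repetitions so the first/last-repetition exclusion is
    exercised end-to-end.  Each channel's raw signal is a zero-mean 20-450 Hz
    band-limited noise carrier amplitude-modulated by that channel's envelope;
    the barbell trace is a raised-cosine displacement whose minima sit at the
    repetition boundaries and whose maxima mark the ascendant/descendant split.
    The overall amplitude scales with ``load_pct`` so a 90%-load set yields a
    larger normalization reference than the 70% analysis sets.
    """
    if fs_emg <= 900:
        raise ValueError("fs_emg must exceed 900 Hz (20-450 Hz band edge)")
    if fs_mocap <= 16:
        raise ValueError("fs_mocap must exceed 16 Hz")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    total_reps = n_reps + 2
    W, shifts, templates = _subject_draws(gt, group, rng)
    W = W * load_pct

    n_asc = int(round(t_asc * fs_emg))
    n_desc = int(round(t_desc * fs_emg))
    env_parts = []
    for _ in range(total_reps):
        rep_shifts = shifts + rng.normal(0.0, gt.rep_shift_sd, gt.n_synergies)
        cyc = W @ _cycle_activation(templates, rep_shifts)    # muscles x 200
        # expand each phase to its duration at the EMG rate
        asc = np.empty((gt.n_muscles, n_asc))
        desc = np.empty((gt.n_muscles, n_desc))
        xa = np.linspace(0, 99, n_asc)
        xd = np.linspace(100, 199, n_desc)
        for ch in range(gt.n_muscles):
            asc[ch] = np.interp(xa, np.arange(100), cyc[ch, :100])
            desc[ch] = np.interp(xd, np.arange(100, 200), cyc[ch, 100:])
        env_parts.append(np.hstack([asc, desc]))
    envelope = np.hstack(env_parts)

    sos = signal.butter(4, (20.0, 450.0), btype="band", fs=fs_emg, output="sos")
    carrier = signal.sosfilt(sos, rng.standard_normal(envelope.shape), axis=1)
    carrier /= np.sqrt(np.mean(carrier ** 2, axis=1, keepdims=True))
    emg = envelope * carrier
    if np.isfinite(gt.snr_db):
        noise_sd = np.sqrt(np.mean(emg ** 2)) * 10 ** (-gt.snr_db / 20.0)
        emg = emg + rng.normal(0.0, noise_sd, size=emg.shape)

    n_bar = int(round(total_reps * (t_asc + t_desc) * fs_mocap))
    na = int(round(t_asc * fs_mocap))
    nd = int(round(t_desc * fs_mocap))
    one = _barbell_cycle(na, nd)
    barbell = np.tile(one, total_reps)[:n_bar]
    labels = list(MUSCLES)[:gt.n_muscles] if gt.n_muscles <= 16 else \
        [f"ch{i}" for i in range(gt.n_muscles)]
    return EmgSet(emg=emg, fs_emg=fs_emg, barbell=barbell, fs_mocap=fs_mocap,
                  channel_labels=labels, load_pct=load_pct)


def simulate_cohort(gt: GroundTruth, n_a: int, n_b: int, n_reps: int,
                    seed: int) -> tuple[dict[str, list[CycleEnvelope]],
                                        dict[str, str]]:
    """Simulate a two-group cohort of subjects (envelope level).

    Returns ``(cycles_by_subject, group_by_subject)`` with subject ids
    ``U01..`` for group A (untrained) and ``E01..`` for group B (trained).
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=n_a + n_b)
    cycles, groups = {}, {}
    for i in range(n_a):
        sid = f"U{i + 1:02d}"
        cycles[sid] = simulate_subject(gt, "A", n_reps, int(seeds[i]))
        groups[sid] = "UNE"
    for i in range(n_b):
        sid = f"E{i + 1:02d}"
        cycles[sid] = simulate_subject(gt, "B", n_reps, int(seeds[n_a + i]))
        groups[sid] = "EXP"
    return cycles, groups


def with_overrides(gt: GroundTruth, **kwargs) -> GroundTruth:
    """Copy a ground truth with some parameters replaced."""
    return replace(gt, **kwargs)
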