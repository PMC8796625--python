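"""Synthetic pose-feature sessions and EEG traces with known ground truth.

The pose generator emulates the study's acquisition geometry: 30 fps
sessions of ~20 minutes, recorded in ~20 s blocks separated by 1-2 s storage
interruptions.  Dynamics are a switching AR process under a Markov chain;
the state chain runs continuously through gaps (a gap interrupts storage,
not behavior), while observations inside gaps are emitted but masked.

The EEG generator produces 1/f-shaped Gaussian background (low-passed at the
acquisition antialias frequency) with injected sinusoidal bursts whose
band-filtered amplitude is calibrated against the band-filtered background
SD, so detector thresholds expressed in baseline SDs are meaningful by
construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from ._kernels import ar_emit, sample_chain
from .types import ARHMMModel, EEGRecording, FilterSpec, GroundTruth, PoseSession, RippleEvent

logger = logging.getLogger(__name__)

__all__ = [
    "GapSpec",
    "NoiseSpec",
    "EEGEvent",
    "SpikeSpec",
    "build_demo_model",
    "apply_occupancy_multipliers",
    "multiplier_for_occupancy",
    "simulate_arhmm_session",
    "make_cohort",
    "simulate_eeg",
]


@dataclass
class GapSpec:
    """Acquisition-gap structure: ~``block_s`` of recording, then a gap of
    ``gap_s_range`` seconds, repeated over the session."""

    block_s: float = 20.0
    block_jitter_s: float = 1.0
    gap_s_range: tuple[float, float] = (1.0, 2.0)


def _build_valid_mask(T: int, fps: float, gap_spec: GapSpec | None, rng: np.random.Generator) -> np.ndarray:
    mask = np.ones(T, dtype=bool)
    if gap_spec is None:
        return mask
    t = 0
    while t < T:
        block = gap_spec.block_s + rng.uniform(-gap_spec.block_jitter_s, gap_spec.block_jitter_s)
        t += int(round(block * fps))
        if t >= T:
            break
        gap = rng.uniform(*gap_spec.gap_s_range)
        g = int(round(gap * fps))
        mask[t : min(t + g, T)] = False
        t += g
    return mask


def _rotation_matrix(P: int, i: int, j: int, theta: float) -> np.ndarray:
    R = np.eye(P)
    c, s = np.cos(theta), np.sin(theta)
    R[i, i] = c
    R[j, j] = c
    R[i, j] = -s
    R[j, i] = s
    return R


def build_demo_model(
    K: int = 5,
    P: int = 5,
    L: int = 1,
    stickiness: float = 0.95,
    ar_decay: float = 0.9,
    mean_scale: float = 3.0,
    noise_sd: float = 0.3,
) -> ARHMMModel:
    """Deterministically construct a well-separated K-state AR(1) model.

    Each state is a damped rotation around a distinct stationary mean, with
    isotropic Gaussian innovations and a sticky uniform transition matrix
    (stationary occupancy uniform).  Intended as the base model for synthetic
    cohorts; all parameters are explicit so tests can reason about them.
    """
    if L != 1:
        raise NotImplementedError("demo model is first-order AR")
    means = np.zeros((K, P))
    for k in range(K):
        d = k % (2 * P)
        if d < P:
            means[k, d] = mean_scale
        else:
            means[k, d - P] = -mean_scale
    ar = np.zeros((K, 1, P, P))
    intercepts = np.zeros((K, P))
    covs = np.zeros((K, P, P))
    for k in range(K):
        theta = 0.15 + 0.1 * k
        A = ar_decay * _rotation_matrix(P, k % P, (k + 1) % P, theta)
        ar[k, 0] = A
        intercepts[k] = (np.eye(P) - A) @ means[k]
        covs[k] = noise_sd**2 * np.eye(P)
    trans = np.full((K, K), (1.0 - stickiness) / max(K - 1, 1))
    np.fill_diagonal(trans, stickiness if K > 1 else 1.0)
    model = ARHMMModel(
        ar_coefs=ar,
        intercepts=intercepts,
        covariances=covs,
        transition_matrix=trans,
        initial_distribution=np.full(K, 1.0 / K),
    )
    model.validate()
    return model


def apply_occupancy_multipliers(model: ARHMMModel, multipliers: dict[int, float] | np.ndarray) -> ARHMMModel:
    """Scale entry into target states and re-normalize transition rows.

    Multiplying column ``s`` of the transition matrix by ``m < 1`` (followed
    by row re-normalization) reduces how often the chain enters state ``s``
    and thus its stationary occupancy; ``m > 1`` increases it.  Rejects
    effects so extreme that a state becomes (numerically) unreachable.
    """
    K = model.n_states
    mult = np.ones(K)
    if isinstance(multipliers, dict):
        for s, m in multipliers.items():
            mult[s] = m
    else:
        mult = np.asarray(multipliers, dtype=np.float64)
    if (mult <= 0).any():
        raise ValueError("occupancy multipliers must be positive")
    trans = model.transition_matrix * mult[None, :]
    rows = trans.sum(axis=1)
    if (rows <= 0).any():
        raise ValueError("multipliers zero out an entire transition row")
    trans = trans / rows[:, None]
    init = model.initial_distribution * mult
    init = init / init.sum()
    new = ARHMMModel(
        ar_coefs=model.ar_coefs.copy(),
        intercepts=model.intercepts.copy(),
        covariances=model.covariances.copy(),
        transition_matrix=trans,
        initial_distribution=init,
    )
    pi = new.stationary_distribution()
    if (pi < 1e-6).any():
        raise ValueError("effect too extreme: a state becomes unreachable")
    return new


def multiplier_for_occupancy(
    model: ARHMMModel, state: int, target_ratio: float, tol: float = 1e-6
) -> float:
    """Column multiplier that scales ``state``'s stationary occupancy to
    ``target_ratio`` times its baseline value (bisection on the stationary
    distribution).  Column scaling shifts occupancy more than proportionally
    on sticky chains, so e.g. halving occupancy needs a multiplier well
    above 0.5."""
    if not (0 < target_ratio):
        raise ValueError("target_ratio must be positive")
    base = model.stationary_distribution()[state]
    target = target_ratio * base
    if target >= 1.0:
        raise ValueError("target occupancy >= 1 is unreachable")

    def occ(m: float) -> float:
        return apply_occupancy_multipliers(model, {state: m}).stationary_distribution()[state]

    lo, hi = 1e-6, 1.0
    if target_ratio > 1.0:
        hi = 1.0
        while occ(hi) < target:
            hi *= 2.0
            if hi > 1e6:
                raise ValueError("target occupancy unreachable")
        lo = 1.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if occ(mid) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def simulate_arhmm_session(
    model: ARHMMModel,
    minutes: float,
    fps: float = 30.0,
    gap_spec: GapSpec | None = None,
    seed: int = 0,
    animal_id: str = "animal",
    genotype: str = "wt",
) -> tuple[PoseSession, GroundTruth]:
    """Simulate one session from a known switching-AR model.

    The first L frames are drawn from the initial state's stationary
    observation distribution (warm-up); identical seeds give identical
    output.
    """
    if minutes <= 0:
        raise ValueError("minutes must be positive")
    model.validate()
    T = int(round(minutes * 60.0 * fps))
    L = model.ar_order
    if L >= T:
        raise ValueError("AR order exceeds available warm-up frames")
    rng = np.random.default_rng(seed)
    cum_trans = np.cumsum(model.transition_matrix, axis=1)
    cum_init = np.cumsum(model.initial_distribution)
    states = sample_chain(cum_trans, cum_init, rng.uniform(size=T))

    chols = np.linalg.cholesky(model.covariances)
    mean0, cov0 = model.state_stationary_moments(int(states[0]))
    chol0 = np.linalg.cholesky(cov0 + 1e-12 * np.eye(model.n_dims))
    warmup = mean0[None, :] + rng.standard_normal((L, model.n_dims)) @ chol0.T
    noise = rng.standard_normal((T, model.n_dims))
    feats = ar_emit(states, model.ar_coefs, model.intercepts, chols, warmup, noise)
    mask = _build_valid_mask(T, fps, gap_spec, rng)
    session = PoseSession(
        animal_id=animal_id,
        genotype=genotype,
        fps=fps,
        features=feats,
        valid_mask=mask,
        session_minutes=minutes,
    )
    return session, GroundTruth(states=states, model=model)


def make_cohort(
    base_model: ARHMMModel,
    genotype_effects: dict[str, dict[int, float] | np.ndarray | None],
    n_per_genotype: dict[str, int],
    minutes: float = 20.0,
    fps: float = 30.0,
    gap_spec: GapSpec | None = GapSpec(),
    seed: int = 0,
) -> list[tuple[PoseSession, GroundTruth]]:
    """Simulate a multi-genotype cohort with genotype-dependent syllable usage.

    ``genotype_effects`` maps genotype -> occupancy multipliers (None or all
    ones for the reference genotype).  Each animal receives an independent
    child seed derived from ``seed``; group sizes like the study's
    wt 6 / het 10 / hom 5 are just ``n_per_genotype``.
    """
    ss = np.random.SeedSequence(seed)
    models = {}
    for geno in n_per_genotype:
        eff = genotype_effects.get(geno)
        models[geno] = base_model if eff is None else apply_occupancy_multipliers(base_model, eff)
    total = sum(n_per_genotype.values())
    children = ss.spawn(total)
    out = []
    i = 0
    for geno, n in n_per_genotype.items():
        for j in range(n):
            child_seed = int(children[i].generate_state(1)[0] % (2**31 - 1))
            sess, gt = simulate_arhmm_session(
                models[geno],
                minutes=minutes,
                fps=fps,
                gap_spec=gap_spec,
                seed=child_seed,
                animal_id=f"{geno}_{j:02d}",
                genotype=geno,
            )
            out.append((sess, gt))
            i += 1
    return out


# ---------------------------------------------------------------------------
# EEG synthesis
# ---------------------------------------------------------------------------


@dataclass
class NoiseSpec:
    """Background EEG noise: Gaussian, 1/f^slope amplitude spectrum, then
    low-passed at the acquisition antialias frequency, scaled to ``sd`` uV."""

    sd: float = 30.0
    slope: float = 1.0


@dataclass
class EEGEvent:
    """One injected oscillatory burst.

    ``amplitude_ratio`` is the amplitude of the burst's interior oscillations
    in the detection band, in units of the band-filtered background SD.
    """

    time_s: float
    channel: int
    freq_hz: float
    n_cycles: int
    amplitude_ratio: float


@dataclass
class SpikeSpec:
    """Optional sharp biphasic transients (epileptiform-spike stand-ins)."""

    times_s: list[float] = field(default_factory=list)
    channel: int = 0
    amplitude_uv: float = 200.0
    width_ms: float = 30.0


def _burst_waveform(freq_hz: float, n_cycles: int, fs: float, taper_cycles: float = 0.5) -> np.ndarray:
    """Unit-amplitude oscillatory burst: constant amplitude with half-Hann
    (Tukey) tapers of ``taper_cycles`` cycles at each edge.

    The flat interior makes ``amplitude_ratio`` the amplitude of every
    counted oscillation rather than of a single central peak.
    """
    n = int(round(n_cycles / freq_hz * fs))
    t = np.arange(n) / fs
    carrier = np.sin(2 * np.pi * freq_hz * t)
    alpha = min(1.0, 2.0 * taper_cycles / n_cycles)
    win = signal.windows.tukey(n, alpha=alpha)
    return win * carrier


def _shape_background(white: np.ndarray, fs: float, spec: NoiseSpec, antialias: float) -> np.ndarray:
    n = white.shape[-1]
    spec_f = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(f)
    nz = f > 0
    scale[nz] = f[nz] ** (-spec.slope / 2.0)
    scale[0] = scale[1] if n > 1 else 1.0
    shaped = np.fft.irfft(spec_f * scale, n=n, axis=-1)
    if antialias < fs / 2:
        sos = signal.butter(4, antialias, btype="low", fs=fs, output="sos")
        shaped = signal.sosfiltfilt(sos, shaped, axis=-1)
    sd = shaped.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd * spec.sd


def simulate_eeg(
    duration_s: float,
    fs: float = 4000.0,
    channels: int = 1,
    background: NoiseSpec | None = None,
    events: list[EEGEvent] | None = None,
    spikes: SpikeSpec | None = None,
    seed: int = 0,
    antialias_lowpass: float = 2000.0,
    reference_filter: FilterSpec | None = None,
) -> tuple[EEGRecording, GroundTruth]:
    """Synthesize multichannel EEG with injected fast-ripple-like bursts.

    Each event's amplitude is calibrated so that, after band-pass filtering
    with ``reference_filter`` (default: the detection band, 200-550 Hz
    order-2 Butterworth, zero phase), the burst's oscillation amplitude
    equals ``amplitude_ratio`` times the SD of the band-filtered background
    of its channel.  Deterministic given ``seed``.
    """
    from .ripples import bandpass  # local import to avoid cycle

    background = background or NoiseSpec()
    events = list(events or [])
    reference_filter = reference_filter or FilterSpec()
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    if background.sd > 0:
        samples = _shape_background(rng.standard_normal((channels, n)), fs, background, antialias_lowpass)
    else:
        samples = np.zeros((channels, n))

    # band-filtered background per channel (pre-injection); bursts are
    # calibrated against the *local* 250 ms surrounding baseline, the same
    # window convention the detector thresholds against
    if background.sd > 0:
        band_bg = np.stack([bandpass(samples[c], fs, reference_filter) for c in range(channels)])
    else:
        band_bg = np.ones((channels, n))
    half = int(round(0.125 * fs))
    guard = int(round(0.010 * fs))

    def _local_sd(ch: int, start: int, end: int) -> float:
        left = band_bg[ch, max(0, start - guard - half) : max(0, start - guard)]
        right = band_bg[ch, min(n, end + guard) : min(n, end + guard + half)]
        seg = np.concatenate([left, right])
        if seg.size < half:
            seg = band_bg[ch]
        return float(seg.std())

    truth_events: list[RippleEvent] = []
    occupied: dict[int, list[tuple[int, int]]] = {}
    names = [f"E{c + 1:02d}" for c in range(channels)]
    for ev in events:
        if not (0 < ev.freq_hz < fs / 2):
            raise ValueError("event frequency outside (0, fs/2)")
        w = _burst_waveform(ev.freq_hz, ev.n_cycles, fs)
        start = int(round(ev.time_s * fs))
        end = start + w.shape[0]
        if start < 0 or end > n:
            raise ValueError("event extends past trace end")
        for s0, e0 in occupied.get(ev.channel, []):
            if start < e0 and s0 < end:
                raise ValueError("overlapping events on one channel")
        occupied.setdefault(ev.channel, []).append((start, end))
        # gain of the reference filter on this burst, measured empirically
        pad = int(round(0.25 * fs))
        probe = np.zeros(w.shape[0] + 2 * pad)
        probe[pad : pad + w.shape[0]] = w
        gain = np.abs(bandpass(probe, fs, reference_filter)).max()
        amp = ev.amplitude_ratio * _local_sd(ev.channel, start, end) / gain
        # suppress the in-band background under the event so the injected
        # amplitude ratio is exact (calibration fixture, not a superposition
        # model): without this, in-band interference makes the realized
        # ratio a random variable with sd ~0.4 baseline SDs.  The
        # suppression window is flat over the whole burst and tapers one
        # cycle beyond each end.
        pad = int(round(fs / ev.freq_hz))
        s0, e0 = max(0, start - pad), min(n, end + pad)
        win_env = signal.windows.tukey(e0 - s0, alpha=min(1.0, 2.0 * pad / (e0 - s0)))
        # subtracting the *raw* background commutes through any linear
        # detection filter, so the suppression is exact in-band as well
        samples[ev.channel, s0:e0] -= win_env * samples[ev.channel, s0:e0]
        samples[ev.channel, start:end] += amp * w
        truth_events.append(
            RippleEvent(
                channel=names[ev.channel],
                start=start,
                end=end,
                n_oscillations=ev.n_cycles,
                peak_amplitude_ratio=ev.amplitude_ratio,
                frequency_hz=ev.freq_hz,
            )
        )

    if spikes is not None:
        width = spikes.width_ms / 1000.0
        for t0 in spikes.times_s:
            c = int(round(t0 * fs))
            half = int(round(2 * width * fs))
            idx = np.arange(max(0, c - half), min(n, c + half))
            tt = (idx - c) / fs
            # biphasic: first derivative of a Gaussian
            wave = -tt / width * np.exp(0.5 - (tt / width) ** 2 / 2.0)
            samples[spikes.channel, idx] += spikes.amplitude_uv * wave

    rec = EEGRecording(channel_names=names, samples=samples, fs=fs, antialias_lowpass=antialias_lowpass)
    return rec, GroundTruth(events=truth_events)
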