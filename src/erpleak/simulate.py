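"""Synthetic familiarity-experiment EEG sessions.

A session shows a subject six 4-digit codes (tag 1 = the code familiar to the
subject, tags 2..6 = random codes), each repeated ``reps_per_tag`` times in a
constrained random order.  Every presentation yields one epoch of multichannel
EEG.  Familiar codes evoke an extra late positive component (P300-like) over
parietal/occipital electrodes; all codes ride on a common evoked baseline and
on 1/f^alpha + white background noise.  Occasional eye blinks contaminate the
EOG channels and, attenuated, the frontal EEG channels.

The generator is fully deterministic given its seeds, which makes every
downstream stage of the evaluation pipeline testable without recordings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .montage import (
    ALL_CHANNELS,
    EOG_CHANNELS,
    FRONTAL_CHANNELS,
    INFORMATIVE_WEIGHTS,
)

__all__ = [
    "UserProfile",
    "SessionConfig",
    "EpochSet",
    "make_user_profile",
    "simulate_session",
    "simulate_cohort",
]

#: Calibrated defaults: familiarity amplitude (µV) and per-sample noise SD (µV).
#: With the 0.5–30 Hz bandpass and P7+P8 concatenation these yield profiled
#: attacks that recover the familiar code within a few tens of observations,
#: i.e. perceived information in the 0.05–0.2 bit range.
DEFAULT_AMPLITUDE = 7.0
DEFAULT_NOISE_SD = 10.0


@dataclass
class UserProfile:
    """Generative parameters for one subject.

    ``baseline_erp`` is the evoked response common to every code; the
    familiarity component (a temporal Gaussian bump of ``amplitude`` µV,
    centred at ``latency_ms`` with SD ``width_ms``) is added only to tag-1
    epochs, weighted per channel by ``weights``.  ``parasitic_tag`` optionally
    marks a second, unintentionally familiar code which receives the component
    scaled by ``parasitic_scale``.
    """

    user_id: int
    fs: float
    epoch_len: int
    baseline_erp: np.ndarray          # (n_channels, epoch_len), µV
    amplitude: float                  # µV, >= 0
    latency_ms: float
    width_ms: float
    weights: np.ndarray               # (n_channels,)
    parasitic_tag: Optional[int] = None
    parasitic_scale: float = 0.0
    noise_sd: float = DEFAULT_NOISE_SD
    noise_alpha: float = 1.0
    pink_fraction: float = 0.6
    channel_names: Sequence[str] = field(default_factory=lambda: list(ALL_CHANNELS))

    def __post_init__(self) -> None:
        self.baseline_erp = np.asarray(self.baseline_erp, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.amplitude < 0:
            raise ValueError("familiarity amplitude must be >= 0")
        window_ms = 1000.0 * self.epoch_len / self.fs
        if not (0 <= self.latency_ms < window_ms):
            raise ValueError(
                f"latency {self.latency_ms} ms outside epoch window [0, {window_ms}) ms"
            )
        if self.latency_ms + 3 * self.width_ms > window_ms:
            raise ValueError(
                "familiarity component (latency + 3*width) extends beyond the epoch window"
            )
        if not (0.0 <= self.parasitic_scale <= 1.0):
            raise ValueError("parasitic_scale must lie in [0, 1]")
        if self.parasitic_tag is not None and self.parasitic_tag < 2:
            raise ValueError("parasitic_tag must be a non-familiar tag (>= 2)")

    def familiarity_bump(self) -> np.ndarray:
        """Temporal profile of the familiarity component, length ``epoch_len``."""
        t_ms = np.arange(self.epoch_len) * 1000.0 / self.fs
        return self.amplitude * np.exp(
            -0.5 * ((t_ms - self.latency_ms) / self.width_ms) ** 2
        )

    def familiarity_template(self) -> np.ndarray:
        """Channels x samples template added to familiar-code epochs (µV)."""
        return np.outer(self.weights, self.familiarity_bump())

    def to_json(self, path) -> None:
        d = asdict(self)
        d["baseline_erp"] = self.baseline_erp.tolist()
        d["weights"] = self.weights.tolist()
        d["channel_names"] = list(self.channel_names)
        with open(path, "w") as fh:
            json.dump(d, fh)

    @classmethod
    def from_json(cls, path) -> "UserProfile":
        with open(path) as fh:
            d = json.load(fh)
        d["baseline_erp"] = np.asarray(d["baseline_erp"], dtype=float)
        d["weights"] = np.asarray(d["weights"], dtype=float)
        return cls(**d)


@dataclass
class SessionConfig:
    """Acquisition-level parameters of one simulated session."""

    n_tags: int = 6
    reps_per_tag: int = 150
    fs: float = 1000.0
    epoch_len: int = 1000
    soa: float = 1.009                # stimulus onset asynchrony, s
    blink_rate: float = 0.05          # probability of a blink per epoch
    blink_amplitude: float = 250.0    # µV, nominal EOG deflection
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tags < 2:
            raise ValueError("need at least two codes (n_tags >= 2)")
        if self.reps_per_tag < 1:
            raise ValueError("reps_per_tag must be >= 1")
        if self.epoch_len > self.soa * self.fs:
            raise ValueError("epoch_len exceeds the stimulus onset asynchrony window")


@dataclass
class EpochSet:
    """Epoched multichannel signals with their presentation tags.

    ``tags`` are in 1..n_tags with tag 1 the familiar (real-PIN) code.
    ``artifact_truth`` is the simulator's ground truth of blink-contaminated
    epochs (available only for synthetic data).
    """

    data: np.ndarray                  # (n_epochs, n_channels, n_samples), µV
    tags: np.ndarray                  # (n_epochs,), int, 1..n_tags
    user_id: int
    fs: float
    channel_names: Sequence[str]
    artifact_truth: np.ndarray        # (n_epochs,), bool

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.tags = np.asarray(self.tags, dtype=int)
        self.artifact_truth = np.asarray(self.artifact_truth, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("data must be (epochs, channels, samples)")
        n = self.data.shape[0]
        if self.tags.shape != (n,) or self.artifact_truth.shape != (n,):
            raise ValueError("tags/artifact_truth length mismatch with data")
        if n and (self.tags.min() < 1):
            raise ValueError("tags must be >= 1")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def channel_index(self, name: str) -> int:
        try:
            return list(self.channel_names).index(name)
        except ValueError:
            raise KeyError(
                f"unknown channel {name!r}; available: {list(self.channel_names)}"
            ) from None

    def subset(self, keep: np.ndarray) -> "EpochSet":
        """New EpochSet restricted to the epochs selected by ``keep``."""
        return EpochSet(
            data=self.data[keep],
            tags=self.tags[keep],
            user_id=self.user_id,
            fs=self.fs,
            channel_names=list(self.channel_names),
            artifact_truth=self.artifact_truth[keep],
        )

    def subset_channels(self, names: Sequence[str]) -> "EpochSet":
        """New EpochSet restricted to the named channels, in the given order."""
        idx = [self.channel_index(c) for c in names]
        return EpochSet(
            data=self.data[:, idx, :],
            tags=self.tags.copy(),
            user_id=self.user_id,
            fs=self.fs,
            channel_names=list(names),
            artifact_truth=self.artifact_truth.copy(),
        )


def _smooth_baseline(rng: np.random.Generator, n_channels: int, epoch_len: int,
                     scale: float = 1.5, n_harmonics: int = 4) -> np.ndarray:
    """Smooth per-channel evoked baseline: a few random low-frequency cosines."""
    t = np.arange(epoch_len) / epoch_len
    amps = scale * rng.standard_normal((n_channels, n_harmonics)) / np.arange(1, n_harmonics + 1)
    phases = rng.uniform(0, 2 * np.pi, size=(n_channels, n_harmonics))
    k = np.arange(1, n_harmonics + 1)
    arg = 2 * np.pi * k[None, :, None] * t[None, None, :] + phases[:, :, None]
    return (amps[:, :, None] * np.cos(arg)).sum(axis=1)


def make_user_profile(
    seed: int,
    amplitude: float = DEFAULT_AMPLITUDE,
    latency_ms: float = 400.0,
    width_ms: float = 60.0,
    parasitic_tag: Optional[int] = None,
    parasitic_scale: float = 0.5,
    noise_sd: float = DEFAULT_NOISE_SD,
    noise_alpha: float = 1.0,
    fs: float = 1000.0,
    epoch_len: int = 1000,
    user_id: int = 0,
) -> UserProfile:
    """Build a deterministic subject profile.

    The familiarity component's channel weights are concentrated on the
    parietal/occipital electrodes (P7, P8, Pz, O1, O2) with a small seeded
    jitter; all other EEG channels receive near-zero weight and the EOG
    channels none.
    """
    rng = np.random.default_rng(seed)
    n_channels = len(ALL_CHANNELS)
    baseline = _smooth_baseline(rng, n_channels, epoch_len)
    baseline[-len(EOG_CHANNELS):] *= 0.3   # EOG sees little evoked activity

    weights = 0.05 * rng.standard_normal(n_channels)
    for name, w in INFORMATIVE_WEIGHTS.items():
        weights[ALL_CHANNELS.index(name)] = w * (1.0 + 0.1 * rng.standard_normal())
    for name in EOG_CHANNELS:
        weights[ALL_CHANNELS.index(name)] = 0.0

    return UserProfile(
        user_id=user_id,
        fs=fs,
        epoch_len=epoch_len,
        baseline_erp=baseline,
        amplitude=amplitude,
        latency_ms=latency_ms,
        width_ms=width_ms,
        weights=weights,
        parasitic_tag=parasitic_tag,
        parasitic_scale=parasitic_scale if parasitic_tag is not None else 0.0,
        noise_sd=noise_sd,
        noise_alpha=noise_alpha,
    )


def sample_schedule(rng: np.random.Generator, n_tags: int, reps_per_tag: int,
                    min_separation: int = 2, max_restarts: int = 1000) -> np.ndarray:
    """Random tag order with any two equal tags separated by >= ``min_separation``
    other events.

    Sequential constrained sampling: each position draws among the tags that
    still have quota and do not appear in the previous ``min_separation``
    positions, with probability proportional to remaining quota; dead ends
    trigger a restart.
    """
    if n_tags < min_separation + 1:
        raise ValueError(
            f"cannot schedule {n_tags} tags with separation {min_separation}: "
            f"need at least {min_separation + 1} distinct tags"
        )
    n = n_tags * reps_per_tag
    for _ in range(max_restarts):
        counts = np.full(n_tags, reps_per_tag, dtype=int)
        seq = np.empty(n, dtype=int)
        ok = True
        for i in range(n):
            forbidden = set(seq[max(0, i - min_separation):i])
            cand = [t for t in range(1, n_tags + 1)
                    if counts[t - 1] > 0 and t not in forbidden]
            if not cand:
                ok = False
                break
            probs = counts[np.array(cand) - 1].astype(float)
            seq[i] = rng.choice(cand, p=probs / probs.sum())
            counts[seq[i] - 1] -= 1
        if ok:
            return seq
    raise RuntimeError("schedule sampling failed to satisfy the separation constraint")


def _pink_noise(rng: np.random.Generator, shape: tuple, alpha: float) -> np.ndarray:
    """Unit-variance 1/f^alpha noise along the last axis.

    Synthesized directly in the frequency domain (random phases, 1/f^(a/2)
    amplitudes) in single precision — the background noise does not need
    double-precision draws and session generation is dominated by this step.
    """
    L = shape[-1]
    fshape = shape[:-1] + (L // 2 + 1,)
    spec = (rng.standard_normal(fshape, dtype=np.float32)
            + 1j * rng.standard_normal(fshape, dtype=np.float32))
    freqs = np.fft.rfftfreq(L)
    scale = np.zeros(L // 2 + 1, dtype=np.float32)
    scale[1:] = freqs[1:] ** (-alpha / 2.0)
    spec *= scale
    pink = np.fft.irfft(spec, n=L, axis=-1)
    sd = pink.std()
    if sd > 0:
        pink /= sd
    return pink


def _blink_waveform(epoch_len: int, fs: float, onset: int) -> np.ndarray:
    """Stereotyped biphasic blink deflection starting near ``onset`` (samples)."""
    t = np.arange(epoch_len, dtype=float)
    up = np.exp(-0.5 * ((t - onset) / (0.05 * fs)) ** 2)
    down = np.exp(-0.5 * ((t - onset - 0.12 * fs) / (0.07 * fs)) ** 2)
    return up - 0.6 * down


def simulate_session(profile: UserProfile, config: SessionConfig) -> EpochSet:
    """Simulate one full session for ``profile`` under ``config``.

    Returns ``n_tags * reps_per_tag`` epochs: common baseline ERP on every
    epoch, the familiarity component on tag-1 epochs (and a scaled copy on the
    parasitic tag, if any), seeded 1/f^alpha + white noise everywhere, and
    blink artifacts on EOG + frontal channels with probability ``blink_rate``
    per epoch.
    """
    rng = np.random.default_rng(config.seed)
    n_tags, reps = config.n_tags, config.reps_per_tag
    n = n_tags * reps
    n_ch = len(profile.channel_names)
    L = config.epoch_len
    if profile.epoch_len != L or profile.fs != config.fs:
        raise ValueError("profile and config disagree on epoch length / sampling rate")

    tags = sample_schedule(rng, n_tags, reps)

    data = np.empty((n, n_ch, L))
    pf = profile.pink_fraction
    data[:] = profile.noise_sd * pf * _pink_noise(rng, (n, n_ch, L), profile.noise_alpha)
    data += profile.noise_sd * np.sqrt(1 - pf ** 2) * rng.standard_normal(
        (n, n_ch, L), dtype=np.float32)

    data += profile.baseline_erp[None, :, :]
    template = profile.familiarity_template()
    data[tags == 1] += template[None, :, :]
    if profile.parasitic_tag is not None:
        data[tags == profile.parasitic_tag] += profile.parasitic_scale * template[None, :, :]

    blink_mask = rng.random(n) < config.blink_rate
    eog_idx = [profile.channel_names.index(c) for c in EOG_CHANNELS]
    frontal_idx = [profile.channel_names.index(c) for c in FRONTAL_CHANNELS]
    for i in np.flatnonzero(blink_mask):
        onset = rng.integers(int(0.1 * L), int(0.6 * L))
        amp = config.blink_amplitude * rng.uniform(0.7, 1.3)
        wave = amp * _blink_waveform(L, config.fs, onset)
        data[i, eog_idx[0]] += wave
        data[i, eog_idx[1]] += 0.9 * wave
        for ch in frontal_idx:
            data[i, ch] += 0.15 * wave

    return EpochSet(
        data=data,
        tags=tags,
        user_id=profile.user_id,
        fs=config.fs,
        channel_names=list(profile.channel_names),
        artifact_truth=blink_mask,
    )


def simulate_cohort(
    n_users: int,
    seed: int,
    spread: float = 1.0,
    amplitude: float = DEFAULT_AMPLITUDE,
    latency_ms: float = 400.0,
    width_ms: float = 60.0,
    noise_sd: float = DEFAULT_NOISE_SD,
    config: Optional[SessionConfig] = None,
) -> list[tuple[UserProfile, EpochSet]]:
    """Simulate ``n_users`` subjects with user-specific response shapes.

    ``spread`` scales the between-user variability of amplitude, latency,
    width and channel weighting; ``spread=0`` gives every user the same
    generating profile (sessions still differ through noise).
    """
    if n_users < 2:
        raise ValueError("a cohort needs at least 2 users")
    base = config or SessionConfig()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_users)
    out = []
    for u, child in enumerate(children, start=1):
        child_seeds = child.generate_state(3) % (2 ** 31)
        prng = np.random.default_rng(int(child_seeds[0]))
        amp_u = amplitude * float(np.exp(spread * 0.25 * prng.standard_normal()))
        lat_u = latency_ms + spread * float(prng.uniform(-60, 60))
        wid_u = width_ms * (1.0 + spread * 0.2 * float(prng.standard_normal()))
        wid_u = max(wid_u, 20.0)
        profile_seed = int(child_seeds[1]) if spread > 0 else int(
            np.random.SeedSequence(seed).generate_state(1)[0] % (2 ** 31)
        )
        if spread == 0:
            amp_u, lat_u, wid_u = amplitude, latency_ms, width_ms
        profile = make_user_profile(
            seed=profile_seed,
            amplitude=amp_u,
            latency_ms=lat_u,
            width_ms=wid_u,
            noise_sd=noise_sd,
            fs=base.fs,
            epoch_len=base.epoch_len,
            user_id=u,
        )
        cfg = SessionConfig(
            n_tags=base.n_tags,
            reps_per_tag=base.reps_per_tag,
            fs=base.fs,
            epoch_len=base.epoch_len,
            soa=base.soa,
            blink_rate=base.blink_rate,
            blink_amplitude=base.blink_amplitude,
            seed=int(child_seeds[2]),
        )
        out.append((profile, simulate_session(profile, cfg)))
    return out
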