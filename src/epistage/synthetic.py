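"""Stage-labeled surrogate EEG generator.

Real intracranial recordings from the pilocarpine rat model are not publicly
deposited, so the pipeline is exercised on surrogates designed to reproduce
one *qualitative* property of the real data: in the fast-ripple band
(250-500 Hz), signal regularity is stage-dependent. The acute
(status-epilepticus) stage is dominated by large rhythmic discharges and is by
far the most regular; the normal baseline is the most irregular; the chronic
(spontaneous-seizure) stage sits slightly below normal.

Each channel is simulated independently as

    white Gaussian noise + 1/f-shaped noise + Poisson-timed sinusoidal bursts

with the burst carrier inside 250-500 Hz. Stage controls burst density,
amplitude, and the fraction of time occupied by bursts (``regularity``).
Channels share the stage parameters but use independent noise, matching the
downstream graph model which assumes no informative cross-channel structure.

Amplitudes are in nominal microvolts; they are plausible for hippocampal
local field potentials but are not calibrated against any real recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .signal_io import CANONICAL_CHANNELS, Recording, Stage

__all__ = [
    "StageParams",
    "GeneratorConfig",
    "default_stage_params",
    "generate_recording",
    "generate_dataset",
]


@dataclass
class StageParams:
    """Burst/noise parameters controlling band-limited regularity for one stage.

    ``regularity`` is the expected fraction of each second occupied by
    rhythmic bursts; burst duration is ``regularity / burst_rate`` so the
    expected duty cycle equals ``regularity`` when bursts do not overlap.
    """

    stage: Stage
    noise_sd: float = 50.0  # uV, white noise
    pink_sd: float = 15.0  # uV, 1/f-shaped component
    burst_rate: float = 0.0  # bursts per second (Poisson)
    burst_freq: float = 330.0  # Hz, carrier within the fast-ripple band
    burst_amp: float = 0.0  # uV, carrier amplitude
    regularity: float = 0.0  # in [0, 1]

    def __post_init__(self) -> None:
        self.stage = Stage.coerce(self.stage)
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.regularity <= 1.0:
            raise ValueError("regularity must lie in [0, 1]")
        if self.burst_amp > 0 and not 250.0 <= self.burst_freq <= 500.0:
            raise ValueError("burst_freq must lie in the 250-500 Hz band")


def default_stage_params(stage) -> StageParams:
    """Default stage parameters.

    Chosen so that after fast-ripple band extraction the mean sample entropy
    orders normal > chronic > acute, with the normal-chronic gap small
    relative to the normal-acute gap: the acute stage is an almost continuous
    large-amplitude rhythm, the chronic stage a sparse low-amplitude one.
    """
    stage = Stage.coerce(stage)
    if stage is Stage.NORMAL:
        return StageParams(stage=stage)
    if stage is Stage.ACUTE:
        return StageParams(
            stage=stage, burst_rate=8.0, burst_amp=400.0, regularity=0.9
        )
    if stage is Stage.CHRONIC:
        return StageParams(
            stage=stage, burst_rate=2.0, burst_amp=100.0, regularity=0.2
        )
    raise ValueError(f"no default parameters for stage {stage}")


@dataclass
class GeneratorConfig:
    """Geometry and seeding for surrogate recordings.

    Defaults emulate the acquisition protocol the pipeline targets:
    8 channels at 1000 Hz for 600 s (600,000 samples per channel).
    """

    fs: float = 1000.0
    duration: float = 600.0
    n_channels: int = 8
    seed: int = 0
    stage_params: dict = field(default_factory=dict)  # Stage -> StageParams

    def __post_init__(self) -> None:
        n = self.fs * self.duration
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"fs * duration must be an integer sample count, got {n}"
            )
        coerced = {}
        for key, value in self.stage_params.items():
            coerced[Stage.coerce(key)] = value
        self.stage_params = coerced

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))

    def params_for(self, stage) -> StageParams:
        stage = Stage.coerce(stage)
        return self.stage_params.get(stage, default_stage_params(stage))


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f-shaped noise via FFT spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    freqs[0] = freqs[1] if n > 1 else 1.0
    spec /= np.sqrt(freqs)
    pink = np.fft.irfft(spec, n)
    sd = pink.std()
    return pink / sd if sd > 0 else pink


def _burst_train(
    rng: np.random.Generator, p: StageParams, fs: float, n: int
) -> np.ndarray:
    """Poisson-timed sinusoidal bursts with expected duty cycle ``regularity``."""
    out = np.zeros(n)
    if p.burst_amp <= 0 or p.regularity <= 0 or p.burst_rate <= 0:
        return out
    duration = n / fs
    n_bursts = rng.poisson(p.burst_rate * duration)
    burst_len = int(round(p.regularity / p.burst_rate * fs))
    if burst_len < 1 or n_bursts == 0:
        return out
    starts = rng.integers(0, n, size=n_bursts)
    t = np.arange(n) / fs
    for s in np.sort(starts):
        e = min(s + burst_len, n)
        phase = rng.uniform(0, 2 * np.pi)
        out[s:e] = p.burst_amp * np.sin(2 * np.pi * p.burst_freq * t[s:e] + phase)
    return out


def generate_recording(stage, cfg: GeneratorConfig, subject_id: str = "sim") -> Recording:
    """Generate one stage-labeled surrogate recording.

    Deterministic in ``(stage, cfg.seed)``: the per-stage stream is seeded
    from the config seed and the stage's class index.
    """
    stage = Stage.coerce(stage)
    p = cfg.params_for(stage)
    n = cfg.n_samples
    rng = np.random.default_rng([cfg.seed, stage.class_index])
    if cfg.n_channels <= len(CANONICAL_CHANNELS):
        names = CANONICAL_CHANNELS[: cfg.n_channels]
    else:
        names = [f"ch{i}" for i in range(cfg.n_channels)]
    data = np.empty((cfg.n_channels, n))
    for c in range(cfg.n_channels):
        x = p.noise_sd * rng.standard_normal(n)
        if p.pink_sd > 0:
            x += p.pink_sd * _pink_noise(rng, n)
        x += _burst_train(rng, p, cfg.fs, n)
        data[c] = x
    return Recording(
        data, fs=cfg.fs, channel_names=names, stage=stage, subject_id=subject_id
    )


def generate_dataset(
    cfg: GeneratorConfig, recordings_per_stage: int, subject_id: str = "sim"
) -> list[Recording]:
    """Balanced list of recordings: [normal, acute, chronic] x repeats.

    Each repeat derives a distinct seed from ``cfg.seed`` so recordings are
    independent but the whole dataset is reproducible.
    """
    if recordings_per_stage < 1:
        raise ValueError("recordings_per_stage must be >= 1")
    out = []
    for rep in range(recordings_per_stage):
        # derive a per-repeat seed deterministically, keeping it in int range
        rep_seed = int(np.random.default_rng([cfg.seed, rep]).integers(2**31))
        rep_cfg = replace(cfg, seed=rep_seed)
        for stage in (Stage.NORMAL, Stage.ACUTE, Stage.CHRONIC):
            out.append(generate_recording(stage, rep_cfg, subject_id=subject_id))
    return out
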