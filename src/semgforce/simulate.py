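"""Synthetic sEMG / grasp-force recordings with planted ground truth.

The simulator emulates a grasp-force protocol: a subject squeezes a force
sensor for about one second at one of four prompted strength levels, relaxes,
and repeats — 60 actions in total, 15 per level. Surface EMG is modeled as
band-limited zero-mean Gaussian interference noise whose instantaneous
standard deviation (the envelope) grows with the exerted force; per-channel
gains control how informative each electrode position is, and a gain of zero
yields a pure-noise channel. The planted action spans, strength levels and
gains are returned as ground truth so downstream stages can be scored
against them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

from .io import Recording


class ConfigurationError(ValueError):
    """A simulator configuration field is invalid."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic recording.

    Envelope law: the EMG standard deviation on channel ``c`` at time ``t`` is
    ``noise_floor + channel_gains[c] * (force(t)/max_force)**envelope_exponent
    * envelope_scale`` (all in µV). ``envelope_exponent`` defaults to 1 so the
    amplitude–force coupling is linear, the common first-order model for
    isometric grasp.
    """

    n_channels: int = 6
    fs: float = 1000.0
    n_actions: int = 60
    strength_levels: tuple[float, ...] = (0.25, 0.50, 0.75, 1.00)
    actions_per_level: int = 15
    action_duration: float = 1.0
    rest_range: tuple[float, float] = (0.5, 1.5)
    max_force: float = 250.0
    channel_gains: tuple[float, ...] = (1.0, 0.85, 0.7, 0.9, 0.75, 0.0)
    envelope_exponent: float = 1.0
    envelope_scale: float = 300.0
    noise_floor: float = 8.0
    band: tuple[float, float] = (10.0, 450.0)
    level_jitter_sigma: float = 0.08
    ramp_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_channels < 1:
            raise ConfigurationError("n_channels: must be at least 1")
        if self.fs <= 0:
            raise ConfigurationError(f"fs: must be positive, got {self.fs}")
        if self.actions_per_level * len(self.strength_levels) != self.n_actions:
            raise ConfigurationError(
                "n_actions: actions_per_level x |strength_levels| "
                f"({self.actions_per_level} x {len(self.strength_levels)}) "
                f"!= n_actions ({self.n_actions})"
            )
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ConfigurationError(f"band: edges must satisfy 0 < lo < hi, got {self.band}")
        if hi >= self.fs / 2:
            raise ConfigurationError(
                f"band: upper edge {hi} Hz must be below Nyquist ({self.fs / 2} Hz)"
            )
        if len(self.channel_gains) != self.n_channels:
            raise ConfigurationError(
                f"channel_gains: {len(self.channel_gains)} gains for "
                f"{self.n_channels} channels"
            )
        if any(g < 0 for g in self.channel_gains):
            raise ConfigurationError("channel_gains: gains must be non-negative")
        if not any(g > 0 for g in self.channel_gains) and self.noise_floor <= 0:
            raise ConfigurationError(
                "channel_gains: at least one positive gain (or a positive "
                "noise_floor) is required"
            )
        if self.max_force <= 0:
            raise ConfigurationError("max_force: must be positive")
        if self.action_duration <= 0:
            raise ConfigurationError("action_duration: must be positive")
        if not 0 < self.rest_range[0] <= self.rest_range[1]:
            raise ConfigurationError(f"rest_range: invalid range {self.rest_range}")
        if self.noise_floor < 0:
            raise ConfigurationError("noise_floor: must be non-negative")
        if not 0 < self.ramp_fraction < 0.5:
            raise ConfigurationError("ramp_fraction: must lie in (0, 0.5)")

    @property
    def informative_channels(self) -> tuple[int, ...]:
        return tuple(i for i, g in enumerate(self.channel_gains) if g > 0)


def _burst_profile(n: int, ramp_fraction: float) -> np.ndarray:
    # Smooth ramp-plateau-ramp: a Tukey (tapered cosine) window with cosine
    # flanks covering ``ramp_fraction`` of the burst on each side.
    return signal.windows.tukey(n, alpha=2.0 * ramp_fraction)


def generate_recording(cfg: SimConfig) -> tuple[Recording, dict]:
    """Synthesize a recording and its ground-truth sidecar.

    Returns ``(recording, truth)`` where ``truth`` holds one entry per action
    (sample span, prompted level, realized peak force) plus the channel gains.
    Identical configuration (including seed) yields bit-identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    levels = np.repeat(cfg.strength_levels, cfg.actions_per_level)
    order = rng.permutation(cfg.n_actions)
    levels = levels[order]

    n_action = int(round(cfg.action_duration * cfg.fs))
    rest_durations = rng.uniform(*cfg.rest_range, size=cfg.n_actions + 1)
    rest_samples = np.round(rest_durations * cfg.fs).astype(int)

    profile = _burst_profile(n_action, cfg.ramp_fraction)
    jitter = np.exp(rng.normal(0.0, cfg.level_jitter_sigma, size=cfg.n_actions))

    pieces = [np.zeros(rest_samples[0])]
    actions = []
    cursor = rest_samples[0]
    for i in range(cfg.n_actions):
        peak = float(np.clip(levels[i] * jitter[i], 0.0, 1.2)) * cfg.max_force
        pieces.append(peak * profile)
        actions.append(
            {
                "action": i,
                "start": int(cursor),
                "end": int(cursor + n_action),
                "level": float(levels[i]),
                "peak_force": peak,
            }
        )
        cursor += n_action
        pieces.append(np.zeros(rest_samples[i + 1]))
        cursor += rest_samples[i + 1]
    force = np.concatenate(pieces)
    n_total = force.size

    # Band-limited carrier noise per channel, unit RMS, then amplitude
    # modulated by the force-dependent envelope. Zero-phase filtering keeps
    # the carrier aligned with the envelope.
    sos = signal.butter(4, cfg.band, btype="bandpass", fs=cfg.fs, output="sos")
    rel = (force / cfg.max_force) ** cfg.envelope_exponent
    emg = np.empty((n_total, cfg.n_channels))
    for c in range(cfg.n_channels):
        carrier = signal.sosfiltfilt(sos, rng.standard_normal(n_total))
        carrier /= carrier.std()
        sigma_t = cfg.noise_floor + cfg.channel_gains[c] * rel * cfg.envelope_scale
        emg[:, c] = carrier * sigma_t

    rec = Recording(fs=cfg.fs, emg=emg, force=force)
    truth = {
        "actions": actions,
        "channel_gains": list(cfg.channel_gains),
        "informative_channels": [
            rec.channel_labels[i] for i in cfg.informative_channels
        ],
        "max_force": cfg.max_force,
        "seed": cfg.seed,
    }
    return rec, truth
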