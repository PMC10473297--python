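"""Synthetic multi-scan generators with planted co-fluctuation states.

Scans are white noise with single-frame events injected at scheduled
frames: frame = amplitude * mode_k + noise, making each event a rank-1
co-fluctuation spike whose edge pattern recurs whenever state k fires.
Optional two-level planting derives sub-modes from a shared super-mode
plus an orthogonal perturbation, giving a controllable parent-child
correlation.  Circular-shift surrogates rotate each parcel independently,
preserving marginal moments while destroying cross-correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_masks import ParcelTimeSeriesSet

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_state_switching_data",
    "circular_shift_surrogate",
    "generate_censor_mask",
]


@dataclass
class SyntheticConfig:
    """Generator settings for planted state-switching scans."""

    n_parcels: int = 50
    n_frames: int = 400
    n_scans: int = 10
    tr: float = 1.0
    n_states: int = 3
    event_rate: float = 5.0  # expected events per scan per state
    amplitude: float = 3.0
    amplitude_sd: float = 0.0
    noise_sd: float = 0.5
    mode_kind: str = "gaussian"  # or "blocks" (bipartition-style +-1 modes)
    modes: np.ndarray | None = None
    n_super: int = 0  # > 0 plants a two-level hierarchy
    subs_per_super: int = 2
    sub_perturbation: float = 0.8
    min_event_gap_frames: int | None = None
    censor_fraction: float = 0.0
    censor_burst_mean: float = 5.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_states < 1:
            raise ValueError("need n_states >= 1")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.censor_fraction < 1:
            raise ValueError("censor_fraction must lie in [0, 1)")
        if self.n_super:
            self.n_states = self.n_super * self.subs_per_super
        if self.modes is not None:
            self.modes = np.asarray(self.modes, dtype=float)
            if self.modes.shape != (self.n_states, self.n_parcels):
                raise ValueError("modes must be K x N")
            if (np.linalg.norm(self.modes, axis=1) == 0).any():
                raise ValueError("degenerate (zero) mode vector")

    @property
    def event_gap(self) -> int:
        if self.min_event_gap_frames is not None:
            return self.min_event_gap_frames
        return math.ceil(10.0 / self.tr) + 3


@dataclass
class GroundTruth:
    """Planted events and the implied static structure."""

    events: pd.DataFrame  # columns: scan_id, frame, state, amplitude
    frame_states: dict[str, np.ndarray]  # per-scan state id per frame, -1=none
    modes: np.ndarray
    planted_fc: np.ndarray
    state_to_super: np.ndarray | None = None

    def states_at_peaks(
        self, scan_id: str, frames: np.ndarray, tolerance: int = 1
    ) -> np.ndarray:
        """Planted state at (or within ``tolerance`` frames of) each frame."""
        fs = self.frame_states[scan_id]
        out = np.full(len(frames), -1, dtype=int)
        for i, f in enumerate(np.asarray(frames, dtype=int)):
            lo, hi = max(0, f - tolerance), min(fs.shape[0], f + tolerance + 1)
            window = fs[lo:hi]
            hits = window[window >= 0]
            if hits.size:
                out[i] = hits[0]
        return out


def _unit_ms(v: np.ndarray) -> np.ndarray:
    """Scale a vector to unit mean square so amplitude means per-parcel SD."""
    return v / np.sqrt((v**2).mean())


def _draw_modes(cfg: SyntheticConfig, rng: np.random.Generator):
    state_to_super = None
    if cfg.modes is not None:
        modes = np.array([_unit_ms(m) for m in cfg.modes])
        if cfg.n_super:
            state_to_super = np.repeat(
                np.arange(cfg.n_super), cfg.subs_per_super
            )
        return modes, state_to_super

    def base_mode() -> np.ndarray:
        if cfg.mode_kind == "blocks":
            v = np.where(rng.random(cfg.n_parcels) < 0.5, 1.0, -1.0)
            v += 0.1 * rng.standard_normal(cfg.n_parcels)
        elif cfg.mode_kind == "gaussian":
            v = rng.standard_normal(cfg.n_parcels)
        else:
            raise ValueError(f"unknown mode_kind {cfg.mode_kind!r}")
        return _unit_ms(v)

    if not cfg.n_super:
        return np.array([base_mode() for _ in range(cfg.n_states)]), None
    modes = []
    state_to_super = []
    for s in range(cfg.n_super):
        parent = base_mode()
        for _ in range(cfg.subs_per_super):
            pert = rng.standard_normal(cfg.n_parcels)
            pert -= pert @ parent / (parent @ parent) * parent  # orthogonal
            pert = _unit_ms(pert)
            child = _unit_ms(parent + cfg.sub_perturbation * pert)
            modes.append(child)
            state_to_super.append(s)
    return np.array(modes), np.array(state_to_super)


def _schedule_events(
    cfg: SyntheticConfig, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Poisson event counts per state, placed with a minimum frame gap."""
    counts = rng.poisson(cfg.event_rate, size=cfg.n_states)
    total = int(counts.sum())
    gap = cfg.event_gap
    frames: list[int] = []
    margin = 2  # keep events off run edges so peaks have bounding troughs
    attempts = 0
    while len(frames) < total and attempts < 200 * max(total, 1):
        f = int(rng.integers(margin, cfg.n_frames - margin))
        if all(abs(f - g) >= gap for g in frames):
            frames.append(f)
        attempts += 1
    frames = frames[: len(frames)]
    states = np.repeat(np.arange(cfg.n_states), counts)[: len(frames)]
    rng.shuffle(states)
    return list(zip(frames, states.tolist()))


def generate_state_switching_data(
    cfg: SyntheticConfig,
) -> tuple[list[ParcelTimeSeriesSet], GroundTruth]:
    """Emit independent scans plus the ground truth of planted events."""
    rng = np.random.default_rng(cfg.seed)
    modes, state_to_super = _draw_modes(cfg, rng)
    scans = []
    ev_rows = []
    frame_states = {}
    rate_frac = np.zeros(cfg.n_states)
    for s in range(cfg.n_scans):
        scan_id = f"scan{s:03d}"
        x = cfg.noise_sd * rng.standard_normal((cfg.n_frames, cfg.n_parcels))
        fs = np.full(cfg.n_frames, -1, dtype=int)
        for frame, state in _schedule_events(cfg, rng):
            if cfg.amplitude_sd > 0:
                amp = abs(rng.normal(cfg.amplitude, cfg.amplitude_sd))
            else:
                amp = cfg.amplitude
            x[frame] += amp * modes[state]
            fs[frame] = state
            ev_rows.append(
                {
                    "scan_id": scan_id,
                    "frame": frame,
                    "state": int(state),
                    "amplitude": float(amp),
                }
            )
            rate_frac[state] += 1
        censor = generate_censor_mask(
            cfg.n_frames,
            cfg.censor_fraction,
            cfg.censor_burst_mean,
            seed=rng,
        )
        scans.append(
            ParcelTimeSeriesSet(
                data=x, tr=cfg.tr, censor=censor, scan_id=scan_id
            )
        )
        frame_states[scan_id] = fs
    rate_frac /= cfg.n_scans * cfg.n_frames
    cov = cfg.noise_sd**2 * np.eye(cfg.n_parcels)
    for k in range(cfg.n_states):
        cov += rate_frac[k] * cfg.amplitude**2 * np.outer(modes[k], modes[k])
    d = np.sqrt(np.diag(cov))
    planted_fc = cov / np.outer(d, d)
    events = pd.DataFrame(
        ev_rows, columns=["scan_id", "frame", "state", "amplitude"]
    )
    truth = GroundTruth(
        events=events,
        frame_states=frame_states,
        modes=modes,
        planted_fc=planted_fc,
        state_to_super=state_to_super,
    )
    return scans, truth


def circular_shift_surrogate(
    ts: ParcelTimeSeriesSet, seed=None
) -> ParcelTimeSeriesSet:
    """Rotate each parcel independently by a nonzero random offset.

    Per-parcel value multisets (hence marginal moments) are preserved
    exactly; cross-parcel alignment is destroyed.  The censor mask is left
    unshifted.
    """
    t = ts.n_frames
    if t < 2:
        raise ValueError("need T >= 2 to shift")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    offsets = rng.integers(1, t, size=ts.n_parcels)
    shifted = np.empty_like(ts.data)
    for j in range(ts.n_parcels):
        shifted[:, j] = np.roll(ts.data[:, j], int(offsets[j]))
    return ParcelTimeSeriesSet(
        data=shifted,
        tr=ts.tr,
        censor=ts.censor.copy(),
        scan_id=f"{ts.scan_id}_surrogate",
        parcel_ids=list(ts.parcel_ids),
    )


def generate_censor_mask(
    t: int,
    censored_fraction: float,
    burst_length_mean: float = 5.0,
    seed=None,
) -> np.ndarray:
    """Binary mask with censored frames arranged in geometric-length bursts.

    The total censored count is pinned to round(fraction * T) (last burst
    trimmed), so the achieved fraction matches the target up to rounding.
    """
    if not 0 <= censored_fraction < 1:
        raise ValueError("censored_fraction must lie in [0, 1)")
    mask = np.ones(t, dtype=np.uint8)
    target = int(round(censored_fraction * t))
    if target == 0:
        return mask
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    lengths: list[int] = []
    while sum(lengths) < target:
        lengths.append(int(rng.geometric(1.0 / max(burst_length_mean, 1.0))))
    lengths[-1] -= sum(lengths) - target
    if lengths[-1] == 0:
        lengths.pop()
    free = t - target
    gaps = rng.multinomial(free, np.ones(len(lengths) + 1) / (len(lengths) + 1))
    pos = 0
    for gap, burst in zip(gaps, lengths):
        pos += gap
        mask[pos : pos + burst] = 0
        pos += burst
    return mask
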