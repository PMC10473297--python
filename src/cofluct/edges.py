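"""Edge time series, global co-fluctuation amplitude, and peak extraction.

The product of two parcels' z-scored signals at one frame is that frame's
contribution to their Pearson correlation: averaging the edge time series
over frames recovers static functional connectivity exactly.  The global
amplitude R(t) (root mean square over all edges) is segmented trough to
trough; each segment holds one peak whose single-frame co-fluctuation
pattern is extracted after prominence and temporal-separation filtering.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .concordance import concordance_matrix_from_array
from .io_masks import ContiguousRun, ParcelTimeSeriesSet, runs_mask

__all__ = [
    "DegenerateInputError",
    "RMSSeries",
    "PeakSegment",
    "CoFluctuationPattern",
    "zscore_parcels",
    "edge_frame",
    "static_fc",
    "rms_series",
    "detect_peak_segments",
    "extract_peak_patterns",
    "classify_peak_amplitude",
    "offpeak_resampling_test",
    "patterns_to_array",
]

log = logging.getLogger(__name__)


class DegenerateInputError(ValueError):
    """Zero-variance parcel or too few retained frames."""


@dataclass
class RMSSeries:
    """Global co-fluctuation amplitude R(t) over one usable run."""

    values: np.ndarray
    run: ContiguousRun

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.run):
            raise ValueError("RMS length must equal run length")
        if (self.values < 0).any():
            raise ValueError("RMS values must be non-negative")

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class PeakSegment:
    """Trough-to-trough interval with its single peak frame.

    Indices are relative to the run; ``left``/``right`` are the bounding
    trough frames (run endpoints count as boundary troughs).
    """

    run: ContiguousRun
    left: int
    peak: int
    right: int
    peak_rms: float
    relative_rms: float

    def __post_init__(self) -> None:
        if not (self.left < self.peak < self.right):
            raise ValueError("need left < peak < right")
        if self.relative_rms < 0:
            raise ValueError("relative RMS must be >= 0")

    @property
    def global_peak(self) -> int:
        """Peak frame index within the scan."""
        return self.run.start + self.peak


@dataclass
class CoFluctuationPattern:
    """Upper-triangle edge vector at one peak frame (i<j row-major order)."""

    vector: np.ndarray
    scan_id: str
    frame: int
    rms: float
    relative_rms: float
    amplitude_class: str = "unclassified"

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float).ravel()

    @property
    def n_nodes(self) -> int:
        e = self.vector.shape[0]
        n = int(round((1 + math.sqrt(1 + 8 * e)) / 2))
        if n * (n - 1) // 2 != e:
            raise ValueError(f"edge vector length {e} is not N(N-1)/2")
        return n

    def as_matrix(self) -> np.ndarray:
        """Symmetric node x node co-fluctuation matrix, zero diagonal."""
        from scipy.spatial.distance import squareform

        return squareform(self.vector, checks=False)


def zscore_parcels(
    ts: ParcelTimeSeriesSet, runs: list[ContiguousRun]
) -> np.ndarray:
    """Standardize each parcel over the retained (in-run) frames.

    Moments are pooled across all retained frames of the scan (sample std,
    ddof=1).  Frames outside the runs are set to NaN so that accidental use
    downstream is loud.
    """
    mask = runs_mask(runs, ts.n_frames)
    n_ret = int(mask.sum())
    if n_ret < 3:
        raise DegenerateInputError(
            f"scan {ts.scan_id}: only {n_ret} retained frames (< 3)"
        )
    x = ts.data[mask]
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    dead = np.flatnonzero(sd <= 0)
    if dead.size:
        names = [ts.parcel_ids[i] for i in dead[:5]]
        raise DegenerateInputError(
            f"scan {ts.scan_id}: zero-variance parcel(s) {names}"
        )
    z = np.full_like(ts.data, np.nan)
    z[mask] = (x - mu) / sd
    return z


def edge_frame(z_row: np.ndarray) -> np.ndarray:
    """Upper triangle (i<j) of the rank-1 outer product of one z frame."""
    z_row = np.asarray(z_row, dtype=float).ravel()
    iu, ju = np.triu_indices(z_row.shape[0], k=1)
    return z_row[iu] * z_row[ju]


def static_fc(z: np.ndarray, runs: list[ContiguousRun]) -> np.ndarray:
    """Pearson FC as the temporal average of edge co-fluctuations.

    r_ij = (1/(T-1)) sum_t z_i(t) z_j(t) over retained frames, which equals
    the textbook correlation because z-scoring used sample std over the
    same frames.
    """
    mask = runs_mask(runs, z.shape[0])
    zz = z[mask]
    t = zz.shape[0]
    if t < 3:
        raise DegenerateInputError("need >= 3 retained frames for FC")
    r = (zz.T @ zz) / (t - 1)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def rms_series(z: np.ndarray, run: ContiguousRun) -> RMSSeries:
    """R(t) = sqrt(mean over edges of r_ij(t)^2), streamed per frame.

    Uses sum_{i<j} z_i^2 z_j^2 = ((sum z^2)^2 - sum z^4) / 2, so the full
    edge x time matrix is never materialized.
    """
    zz = z[run.start : run.end]
    n = zz.shape[1]
    n_edges = n * (n - 1) // 2
    s2 = (zz**2).sum(axis=1)
    s4 = (zz**4).sum(axis=1)
    ss = np.maximum((s2**2 - s4) / 2.0, 0.0)
    return RMSSeries(np.sqrt(ss / n_edges), run)


def _candidate_segments(r: np.ndarray, run: ContiguousRun) -> list[PeakSegment]:
    """Trough-to-trough segments with their interior maxima (unfiltered)."""
    n = r.shape[0]
    if n < 3:
        log.info("run %s too short for peak detection (%d frames)", run, n)
        return []
    # collapse plateaus so a flat trough still separates segments; the
    # leftmost frame of a flat stretch represents it
    starts = np.concatenate(([0], np.flatnonzero(np.diff(r) != 0) + 1))
    rv = r[starts]
    m = rv.shape[0]
    if m >= 3:
        inner = np.arange(1, m - 1)
        strict = inner[(rv[1:-1] < rv[:-2]) & (rv[1:-1] < rv[2:])]
        minima = starts[strict]
    else:
        minima = np.array([], dtype=int)
    bounds = [0, *minima.tolist(), n - 1]
    out = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a < 2:  # no interior frame
            continue
        peak = a + 1 + int(np.argmax(r[a + 1 : b]))  # leftmost on plateaus
        rel = float(r[peak] - max(r[a], r[b]))
        if rel < 0:
            continue  # boundary frame dominates; not a genuine local max
        out.append(PeakSegment(run, a, peak, b, float(r[peak]), rel))
    return out


def detect_peak_segments(
    rms: RMSSeries,
    tr: float,
    min_relative_rms: float = 0.25,
    min_separation_s: float = 10.0,
    _stats: dict | None = None,
) -> list[PeakSegment]:
    """Segment R(t) at local minima and keep filtered peaks.

    Relative RMS (prominence) is peak height minus the larger bounding
    trough; peaks with relative RMS <= ``min_relative_rms`` are dropped.
    Peaks closer than ceil(min_separation_s / tr) frames are then greedily
    thinned, keeping the larger relative RMS (earlier frame on ties).

    ``_stats``, when given, accumulates funnel counts under keys
    ``segments``, ``after_prominence``, ``after_separation``.
    """
    cands = _candidate_segments(rms.values, rms.run)
    prominent = [s for s in cands if s.relative_rms > min_relative_rms]
    min_sep = math.ceil(min_separation_s / tr)
    kept: list[PeakSegment] = []
    for seg in sorted(prominent, key=lambda s: (-s.relative_rms, s.peak)):
        if all(abs(seg.peak - k.peak) >= min_sep for k in kept):
            kept.append(seg)
    kept.sort(key=lambda s: s.peak)
    if _stats is not None:
        _stats["segments"] = _stats.get("segments", 0) + len(cands)
        _stats["after_prominence"] = (
            _stats.get("after_prominence", 0) + len(prominent)
        )
        _stats["after_separation"] = (
            _stats.get("after_separation", 0) + len(kept)
        )
    return kept


def extract_peak_patterns(
    z: np.ndarray,
    segments: list[PeakSegment],
) -> list[CoFluctuationPattern]:
    """One single-frame co-fluctuation pattern per surviving segment."""
    out = []
    for seg in segments:
        frame = seg.global_peak
        vec = edge_frame(z[frame])
        rms = float(np.sqrt((vec**2).mean()))
        out.append(
            CoFluctuationPattern(
                vector=vec,
                scan_id=seg.run.scan_id,
                frame=frame,
                rms=rms,
                relative_rms=seg.relative_rms,
            )
        )
    return out


def patterns_to_array(patterns: list[CoFluctuationPattern]) -> np.ndarray:
    """Stack pattern edge vectors into a P x E array."""
    if not patterns:
        raise ValueError("no patterns")
    return np.vstack([p.vector for p in patterns])


def classify_peak_amplitude(
    patterns: list[CoFluctuationPattern],
    null_peak_rms: np.ndarray,
    hi_pct: float = 97.5,
    lo_pct: float = 2.5,
) -> list[str]:
    """Label each pattern high / ns / low against a null peak-RMS sample.

    The null is the empirical peak-RMS distribution from decorrelated
    (circular-shift) surrogates.  Patterns above its ``hi_pct`` percentile
    are "high", below ``lo_pct`` are "low", otherwise "ns".  Classes are
    written back onto the patterns and returned.
    """
    null_peak_rms = np.asarray(null_peak_rms, dtype=float).ravel()
    if null_peak_rms.size == 0:
        log.warning("empty null distribution; amplitude classes unassigned")
        for p in patterns:
            p.amplitude_class = "unclassified"
        return [p.amplitude_class for p in patterns]
    hi = np.percentile(null_peak_rms, hi_pct)
    lo = np.percentile(null_peak_rms, lo_pct)
    for p in patterns:
        if p.rms > hi:
            p.amplitude_class = "high"
        elif p.rms < lo:
            p.amplitude_class = "low"
        else:
            p.amplitude_class = "ns"
    return [p.amplitude_class for p in patterns]


def offpeak_resampling_test(
    z: np.ndarray,
    segments: list[PeakSegment],
    patterns: list[CoFluctuationPattern],
    n_resamples: int = 1000,
    seed: int | None = None,
) -> np.ndarray:
    """Probability that off-peak concordance meets or beats the observed.

    Each resample replaces every pattern by the edge vector at a uniformly
    random non-peak interior frame of its own trough-to-trough segment and
    recomputes the concordance matrix; p(i,j) is the fraction of resamples
    whose null concordance >= the observed concordance.  Segments with no
    alternative frame keep their peak (logged).
    """
    if len(segments) != len(patterns):
        raise ValueError("segments and patterns must align")
    rng = np.random.default_rng(seed)
    obs = concordance_matrix_from_array(patterns_to_array(patterns))
    alternatives = []
    for seg in segments:
        alts = [
            seg.run.start + t
            for t in range(seg.left + 1, seg.right)
            if t != seg.peak
        ]
        if not alts:
            log.info("segment %s has no off-peak frame; keeping peak", seg)
            alts = [seg.global_peak]
        alternatives.append(np.array(alts))
    count = np.zeros_like(obs)
    for _ in range(n_resamples):
        frames = [int(rng.choice(a)) for a in alternatives]
        null_x = np.vstack([edge_frame(z[f]) for f in frames])
        null_c = concordance_matrix_from_array(null_x)
        count += null_c >= obs
    p = count / n_resamples
    np.fill_diagonal(p, 1.0)
    return p
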