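"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from cofluct import (
    SyntheticConfig,
    circular_shift_surrogate,
    detect_peak_segments,
    extract_peak_patterns,
    generate_state_switching_data,
    recursive_cluster,
    rms_series,
    segment_usable_runs,
    zscore_parcels,
)
from cofluct.concordance import concordance_matrix_from_array
from cofluct.edges import patterns_to_array

# ---------------------------------------------------------------- oracles


def set_partitions(n):
    """All partitions of n items as restricted-growth label strings."""

    def rec(prefix, maxv):
        if len(prefix) == n:
            yield list(prefix)
            return
        for v in range(maxv + 2):
            yield from rec(prefix + [v], max(maxv, v))

    yield from rec([], -1)


def exhaustive_max_q(b: np.ndarray) -> float:
    """Brute-force maximum modularity over every partition (n <= ~10)."""
    best = -np.inf
    for labs in set_partitions(b.shape[0]):
        labs = np.array(labs)
        q = 0.0
        for c in np.unique(labs):
            idx = np.flatnonzero(labs == c)
            sub = b[np.ix_(idx, idx)]
            q += sub.sum() - np.trace(sub)
        best = max(best, q)
    return float(best)


def lin_concordance_oracle(x, y) -> float:
    """Direct transcription of the concordance formula (population moments)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return 2.0 * cov / (x.var() + y.var() + (x.mean() - y.mean()) ** 2)


# ------------------------------------------------------- pipeline helpers


def extract_patterns_from_scans(scans, tr=1.0, min_relative_rms=0.25,
                                min_separation_s=10.0):
    """Default-parameter peak extraction across a list of scans."""
    patterns = []
    for ts in scans:
        runs = segment_usable_runs(ts)
        if not runs:
            continue
        z = zscore_parcels(ts, runs)
        for run in runs:
            segs = detect_peak_segments(
                rms_series(z, run),
                tr=tr,
                min_relative_rms=min_relative_rms,
                min_separation_s=min_separation_s,
            )
            patterns.extend(extract_peak_patterns(z, segs))
    return patterns


def surrogate_null_levels(seed, n_runs=100, n_perm=1000, **synth_kwargs):
    """Hierarchy depth of the full pipeline on circular-shift surrogates.

    Decorrelation at realistic parcel counts destroys prominent RMS peaks,
    so the surrogate run typically has too few patterns to cluster and the
    hierarchy is the trivial root + empty pair (2 levels).
    """
    kwargs = dict(
        n_parcels=630, n_frames=500, n_scans=5, n_states=3,
        event_rate=6.0, amplitude=1.2, noise_sd=1.0,
    )
    kwargs.update(synth_kwargs)
    scans, _ = generate_state_switching_data(
        SyntheticConfig(seed=seed, **kwargs)
    )
    rng = np.random.default_rng(seed + 10_000)
    patterns = extract_patterns_from_scans(
        [circular_shift_surrogate(ts, seed=rng) for ts in scans]
    )
    if len(patterns) < 2:
        return 2
    conc = concordance_matrix_from_array(patterns_to_array(patterns))
    hier = recursive_cluster(
        conc,
        [p.scan_id for p in patterns],
        n_runs=n_runs,
        n_perm=n_perm,
        seed=seed,
    )
    return hier.n_levels


# --------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def planted_flat():
    """Small flat K=3 simulation with its extracted patterns."""
    cfg = SyntheticConfig(
        n_parcels=40, n_frames=300, n_scans=6, n_states=3,
        event_rate=5.0, amplitude=3.0, noise_sd=0.5, seed=101,
    )
    scans, truth = generate_state_switching_data(cfg)
    patterns = extract_patterns_from_scans(scans)
    return {"cfg": cfg, "scans": scans, "truth": truth, "patterns": patterns}


@pytest.fixture
def rng():
    return np.random.default_rng(0)
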