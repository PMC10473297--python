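"""Run configuration, seed fan-out, and the end-to-end pipeline."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bipartitions as bp
from . import characterize as ch
from . import datareq as dr
from . import edges as ed
from . import hierarchy as hc
from . import io_masks as io
from . import synthetic as sy
from .concordance import concordance_matrix_from_array

__all__ = ["RunConfig", "run_pipeline", "extract_all_peaks"]

log = logging.getLogger(__name__)

# fixed fan-out order for per-stage seeds
_STAGES = ("simulate", "surrogate", "cluster", "offpeak", "datareq")


@dataclass
class RunConfig:
    """All stage parameters; defaults follow the reference analysis."""

    pad_frames: int = 2
    min_run: int = 5
    min_relative_rms: float = 0.25
    min_separation_s: float = 10.0
    hi_pct: float = 97.5
    lo_pct: float = 2.5
    alpha: float = 0.05
    min_size: int = 5
    min_scans: int = 2
    n_louvain_runs: int = 1000
    n_perm: int = 10000
    n_splits: int = 20
    n_systems: int = 4
    seed: int = 0
    out_dir: str = "cofluct_out"
    synthetic: sy.SyntheticConfig = field(default_factory=sy.SyntheticConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["synthetic"].get("modes") is not None:
            d["synthetic"]["modes"] = np.asarray(
                d["synthetic"]["modes"]
            ).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        syn = d.pop("synthetic", {})
        if isinstance(syn, dict):
            syn = sy.SyntheticConfig(**syn)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(synthetic=syn, **d)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RunConfig":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(yaml.safe_load(text))

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed fanned out from the master seed."""
        idx = _STAGES.index(stage)
        state = np.random.SeedSequence(self.seed).generate_state(
            len(_STAGES), dtype=np.uint64
        )
        return int(state[idx])


def extract_all_peaks(
    scans: list[io.ParcelTimeSeriesSet],
    cfg: RunConfig,
    funnel: dict | None = None,
):
    """Censor, z-score, and extract peak patterns across scans.

    Returns ``(patterns, per_scan)`` where ``per_scan`` maps scan_id to a
    dict with the z matrix, runs, segments, and that scan's FC.
    """
    patterns: list[ed.CoFluctuationPattern] = []
    per_scan: dict[str, dict] = {}
    stats = funnel if funnel is not None else {}
    stats.setdefault("n_frames", 0)
    stats.setdefault("n_usable", 0)
    stats.setdefault("n_retained", 0)
    for ts in scans:
        runs = io.segment_usable_runs(
            ts, pad_frames=cfg.pad_frames, min_run=cfg.min_run
        )
        stats["n_frames"] += ts.n_frames
        stats["n_usable"] += int(ts.censor.sum())
        stats["n_retained"] += sum(len(r) for r in runs)
        if not runs:
            per_scan[ts.scan_id] = {"runs": [], "segments": [], "z": None}
            continue
        z = ed.zscore_parcels(ts, runs)
        segments: list[ed.PeakSegment] = []
        for run in runs:
            rms = ed.rms_series(z, run)
            segments.extend(
                ed.detect_peak_segments(
                    rms,
                    tr=ts.tr,
                    min_relative_rms=cfg.min_relative_rms,
                    min_separation_s=cfg.min_separation_s,
                    _stats=stats,
                )
            )
        patterns.extend(ed.extract_peak_patterns(z, segments))
        per_scan[ts.scan_id] = {
            "runs": runs,
            "segments": segments,
            "z": z,
            "fc": ed.static_fc(z, runs),
        }
    return patterns, per_scan


def _null_peak_rms(
    scans: list[io.ParcelTimeSeriesSet], cfg: RunConfig, seed: int
) -> np.ndarray:
    """Peak RMS sample from circular-shift surrogates of every scan."""
    rng = np.random.default_rng(seed)
    vals: list[float] = []
    for ts in scans:
        surr = sy.circular_shift_surrogate(ts, seed=rng)
        runs = io.segment_usable_runs(
            surr, pad_frames=cfg.pad_frames, min_run=cfg.min_run
        )
        if not runs:
            continue
        z = ed.zscore_parcels(surr, runs)
        for run in runs:
            rms = ed.rms_series(z, run)
            for seg in ed.detect_peak_segments(
                rms,
                tr=surr.tr,
                min_relative_rms=0.0,
                min_separation_s=cfg.min_separation_s,
            ):
                vals.append(seg.peak_rms)
    return np.array(vals)


def run_pipeline(cfg: RunConfig, scans=None, systems=None) -> dict:
    """Simulate (or ingest) -> peaks -> concordance -> cluster -> reports.

    When ``scans`` is None the synthetic generator supplies the data.  All
    artifacts are written under ``cfg.out_dir`` tagged with the config
    hash; the returned dict exposes the in-memory results.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    funnel: dict = {}
    truth = None
    if scans is None:
        syn_cfg = dataclasses.replace(
            cfg.synthetic, seed=cfg.stage_seed("simulate")
        )
        scans, truth = sy.generate_state_switching_data(syn_cfg)
        log.info("simulated %d scans (%s)", len(scans), syn_cfg)
    if systems is None:
        n = scans[0].n_parcels
        labels = [f"sys{(i * cfg.n_systems) // n}" for i in range(n)]
        systems = io.SystemPartition(list(scans[0].parcel_ids), labels)

    patterns, per_scan = extract_all_peaks(scans, cfg, funnel=funnel)
    if len(patterns) < max(cfg.min_size, 2):
        raise RuntimeError(
            f"stage 'peaks' failed: only {len(patterns)} patterns"
        )
    null_rms = _null_peak_rms(scans, cfg, cfg.stage_seed("surrogate"))
    classes = ed.classify_peak_amplitude(
        patterns, null_rms, hi_pct=cfg.hi_pct, lo_pct=cfg.lo_pct
    )
    vectors = ed.patterns_to_array(patterns)
    scan_ids = np.array([p.scan_id for p in patterns])
    rms = np.array([p.rms for p in patterns])
    conc = concordance_matrix_from_array(vectors)
    hier = hc.recursive_cluster(
        conc,
        scan_ids,
        alpha=cfg.alpha,
        min_size=cfg.min_size,
        min_scans=cfg.min_scans,
        n_runs=cfg.n_louvain_runs,
        n_perm=cfg.n_perm,
        seed=cfg.stage_seed("cluster"),
    )
    fcs = [d["fc"] for d in per_scan.values() if d.get("fc") is not None]
    fc = np.mean(fcs, axis=0)
    depths = ch.hierarchical_depth(hier)
    curves = {
        mode: ch.depth_fc_curves(vectors, depths, fc, mode=mode)
        for mode in ("level_only", "cumulative", "reverse_cumulative")
    }
    parent_sim = ch.centroid_parent_similarity(hier, vectors)
    level_fracs, comm_stats = ch.cluster_composition(hier, classes, rms)

    tset = bp.enumerate_system_templates(systems)
    bips = np.vstack(
        [
            bp.frame_bipartition(per_scan[p.scan_id]["z"][p.frame])
            for p in patterns
        ]
    )
    match = bp.match_to_templates(bips, tset)

    level2 = hier.level_labels(2) if hier.n_levels >= 2 else None
    datareq_result = None
    if (
        level2 is not None
        and (level2 > 0).any()
        and np.unique(scan_ids).size >= 4
    ):
        datareq_result = dr.split_half_convergence(
            vectors,
            scan_ids,
            level2,
            n_splits=cfg.n_splits,
            seed=cfg.stage_seed("datareq"),
        )

    provenance = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "funnel": funnel,
        "n_patterns": len(patterns),
        "n_levels": hier.n_levels,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1))
    hier.to_json(out / "hierarchy.json")
    pd.DataFrame(
        {
            "scan_id": scan_ids,
            "frame": [p.frame for p in patterns],
            "rms": rms,
            "relative_rms": [p.relative_rms for p in patterns],
            "amplitude_class": classes,
            **{
                f"level{i + 1}": hier.labels[i]
                for i in range(hier.n_levels)
            },
        }
    ).to_csv(out / "patterns_meta.tsv", sep="\t", index=False)
    np.savetxt(out / "pattern_vectors.tsv", vectors, delimiter="\t")
    np.savetxt(out / "concordance.tsv", conc, delimiter="\t")
    parent_sim.to_csv(out / "parent_similarity.tsv", sep="\t", index=False)
    comm_stats.to_csv(out / "community_stats.tsv", sep="\t", index=False)
    level_fracs.to_csv(out / "level_composition.tsv", sep="\t")
    pd.DataFrame(curves).to_csv(out / "depth_fc_curves.tsv", sep="\t")

    funnel_ok = (
        funnel.get("segments", 0)
        >= funnel.get("after_prominence", 0)
        >= funnel.get("after_separation", 0)
    )
    if not funnel_ok:
        raise RuntimeError("peak funnel counts are not nonincreasing")
    log.info(
        "funnel: %d segments -> %d after prominence -> %d after separation",
        funnel.get("segments", 0),
        funnel.get("after_prominence", 0),
        funnel.get("after_separation", 0),
    )
    return {
        "scans": scans,
        "truth": truth,
        "patterns": patterns,
        "vectors": vectors,
        "scan_ids": scan_ids,
        "classes": classes,
        "concordance": conc,
        "hierarchy": hier,
        "fc": fc,
        "depth_fc_curves": curves,
        "parent_similarity": parent_sim,
        "composition": (level_fracs, comm_stats),
        "templates": tset,
        "template_match": match,
        "datareq": datareq_result,
        "funnel": funnel,
        "provenance": provenance,
    }
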