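"""Parcel time-series I/O, censor masks, and usable-run segmentation.

Scans are stored as frames x parcels matrices together with a per-frame
binary censor vector (1 = usable).  Frames neighbouring a censored frame
are removed symmetrically, and surviving stretches shorter than a minimum
length are discarded; every downstream computation operates on the
resulting :class:`ContiguousRun` intervals only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "FormatError",
    "LabelError",
    "ParcelTimeSeriesSet",
    "ContiguousRun",
    "SystemPartition",
    "load_parcel_timeseries",
    "load_censor",
    "segment_usable_runs",
    "runs_mask",
    "load_system_labels",
    "load_manifest",
]


class FormatError(ValueError):
    """Malformed numeric matrix file (ragged, empty, or non-numeric)."""


class LabelError(ValueError):
    """Parcel/system label file inconsistent with the time series."""


@dataclass
class ParcelTimeSeriesSet:
    """One scan: frames x parcels signal, TR, censor mask and identifiers."""

    data: np.ndarray
    tr: float
    censor: np.ndarray | None = None
    scan_id: str = "scan"
    parcel_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D frames x parcels array")
        t, n = self.data.shape
        if t < 1 or n < 2:
            raise ValueError(f"need T >= 1 and N >= 2, got T={t}, N={n}")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.censor is None:
            self.censor = np.ones(t, dtype=np.uint8)
        else:
            self.censor = np.asarray(self.censor).astype(np.uint8).ravel()
            if self.censor.shape[0] != t:
                raise ValueError(
                    f"censor length {self.censor.shape[0]} != T={t}"
                )
            if not np.isin(self.censor, (0, 1)).all():
                raise ValueError("censor must be binary")
        usable = self.censor.astype(bool)
        if not np.isfinite(self.data[usable]).all():
            raise ValueError("non-finite values among usable frames")
        if self.parcel_ids is None:
            self.parcel_ids = [f"p{i}" for i in range(n)]
        elif len(self.parcel_ids) != n:
            raise ValueError("parcel_ids length mismatch")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True, order=True)
class ContiguousRun:
    """Half-open frame interval [start, end) of usable data within a scan."""

    scan_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid run [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def frames(self) -> np.ndarray:
        return np.arange(self.start, self.end)


@dataclass
class SystemPartition:
    """Assignment of every parcel to exactly one named system."""

    parcel_ids: list[str]
    systems: list[str]
    system_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.parcel_ids) != len(self.systems):
            raise LabelError("parcel_ids and systems length mismatch")
        if not self.system_names:
            seen: dict[str, None] = {}
            for s in self.systems:
                seen.setdefault(s, None)
            self.system_names = list(seen)
        if len(self.system_names) < 2:
            raise LabelError("need at least 2 distinct systems")

    @property
    def n_systems(self) -> int:
        return len(self.system_names)

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_ids)

    def indices(self, system: str) -> np.ndarray:
        """Parcel indices belonging to ``system``."""
        return np.array(
            [i for i, s in enumerate(self.systems) if s == system], dtype=int
        )

    def label_codes(self) -> np.ndarray:
        """Integer system code per parcel, in ``system_names`` order."""
        lut = {s: k for k, s in enumerate(self.system_names)}
        return np.array([lut[s] for s in self.systems], dtype=int)


def _parse_delimited_matrix(path: Path) -> np.ndarray:
    text = path.read_text()
    rows: list[list[float]] = []
    width = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        tokens = line.replace(",", "\t").split()
        if width is None:
            width = len(tokens)
        elif len(tokens) != width:
            raise FormatError(
                f"{path}: row {lineno} has {len(tokens)} columns, "
                f"expected {width}"
            )
        vals = []
        for col, tok in enumerate(tokens, start=1):
            try:
                v = float(tok)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric cell at row {lineno}, column {col}: "
                    f"{tok!r}"
                ) from None
            if not np.isfinite(v):
                raise FormatError(
                    f"{path}: non-finite cell at row {lineno}, column {col}: "
                    f"{tok!r}"
                )
            vals.append(v)
        rows.append(vals)
    if not rows:
        raise FormatError(f"{path}: empty matrix file")
    return np.array(rows, dtype=float)


def load_parcel_timeseries(
    path: str | Path,
    layout: str = "frames_by_parcels",
    tr: float = 1.0,
    scan_id: str | None = None,
    censor: np.ndarray | None = None,
) -> ParcelTimeSeriesSet:
    """Read a delimited matrix (or HDF5 container) as one scan.

    ``layout`` declares the on-disk orientation; data are always stored
    frames x parcels.  HDF5 files (suffix .h5/.hdf5) must contain ``/data``
    and may contain ``/censor``.
    """
    path = Path(path)
    if layout not in ("frames_by_parcels", "parcels_by_frames"):
        raise ValueError(f"unknown layout {layout!r}")
    if path.suffix.lower() in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            data = np.asarray(f["data"], dtype=float)
            if censor is None and "censor" in f:
                censor = np.asarray(f["censor"])
    else:
        data = _parse_delimited_matrix(path)
    if layout == "parcels_by_frames":
        data = data.T
    return ParcelTimeSeriesSet(
        data=data,
        tr=tr,
        censor=censor,
        scan_id=scan_id or path.stem,
    )


def load_censor(path: str | Path) -> np.ndarray:
    """Read a one-column binary censor vector (1 = usable frame)."""
    arr = _parse_delimited_matrix(Path(path)).ravel()
    if not np.isin(arr, (0.0, 1.0)).all():
        raise FormatError(f"{path}: censor values must be 0/1")
    return arr.astype(np.uint8)


def segment_usable_runs(
    ts: ParcelTimeSeriesSet,
    pad_frames: int = 2,
    min_run: int = 5,
) -> list[ContiguousRun]:
    """Split a scan into ordered usable runs.

    Frames within ``pad_frames`` of any censored frame (symmetric) are
    removed; remaining maximal contiguous stretches shorter than
    ``min_run`` frames are discarded.  An empty result is legitimate.
    """
    usable = ts.censor.astype(bool).copy()
    bad = np.flatnonzero(~usable)
    t = usable.shape[0]
    for b in bad:
        lo = max(0, b - pad_frames)
        hi = min(t, b + pad_frames + 1)
        usable[lo:hi] = False
    runs: list[ContiguousRun] = []
    start = None
    for i in range(t + 1):
        if i < t and usable[i]:
            if start is None:
                start = i
        elif start is not None:
            if i - start >= min_run:
                runs.append(ContiguousRun(ts.scan_id, start, i))
            start = None
    return runs


def runs_mask(runs: list[ContiguousRun], n_frames: int) -> np.ndarray:
    """Boolean frame mask covering all run intervals."""
    mask = np.zeros(n_frames, dtype=bool)
    for r in runs:
        mask[r.start : r.end] = True
    return mask


def load_system_labels(
    path: str | Path, parcel_ids: list[str]
) -> SystemPartition:
    """Read a two-column (parcel_id, system) file covering every parcel.

    System order follows first appearance in the file.
    """
    path = Path(path)
    mapping: dict[str, str] = {}
    order: dict[str, None] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.replace(",", "\t").split()
        if len(parts) != 2:
            raise LabelError(f"{path}: row {lineno} is not two columns")
        pid, system = parts
        if pid in mapping:
            raise LabelError(f"{path}: duplicate parcel id {pid!r}")
        mapping[pid] = system
        order.setdefault(system, None)
    missing = [p for p in parcel_ids if p not in mapping]
    if missing:
        raise LabelError(f"{path}: missing parcel ids {missing[:5]}")
    unknown = [p for p in mapping if p not in set(parcel_ids)]
    if unknown:
        raise LabelError(f"{path}: unknown parcel ids {unknown[:5]}")
    systems = [mapping[p] for p in parcel_ids]
    names = [s for s in order if s in set(systems)]
    return SystemPartition(list(parcel_ids), systems, names)


def load_manifest(
    path: str | Path,
) -> tuple[list[ParcelTimeSeriesSet], SystemPartition | None]:
    """Read a JSON manifest describing a multi-scan dataset.

    Schema: ``{"scans": [{"path", "tr", "scan_id", "layout"?, "censor"?}],
    "systems": path?}``.  Relative paths resolve against the manifest.
    """
    path = Path(path)
    spec = json.loads(path.read_text())
    base = path.parent
    scans = []
    for entry in spec["scans"]:
        censor = None
        if entry.get("censor"):
            censor = load_censor(base / entry["censor"])
        scans.append(
            load_parcel_timeseries(
                base / entry["path"],
                layout=entry.get("layout", "frames_by_parcels"),
                tr=float(entry.get("tr", 1.0)),
                scan_id=entry.get("scan_id"),
                censor=censor,
            )
        )
    partition = None
    if spec.get("systems"):
        if not scans:
            raise FormatError(f"{path}: systems given but no scans")
        partition = load_system_labels(
            base / spec["systems"], scans[0].parcel_ids
        )
    return scans, partition
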