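"""Reading, writing and temporal preprocessing of node time series.

A :class:`SignalSet` holds one node x time matrix per subject, all sharing
the same node order and sampling interval ``dt`` (seconds per frame, the
fMRI TR). Preprocessing follows the usual resting-state recipe for parcel
time series: discard the first frames (scanner equilibration), then remove
slow drift with a temporal high-pass filter.

Signals are stored as delimited text, one file per subject: a ``node_id``
column followed by one column per frame. Comma or tab delimiters are
auto-detected. The atlas table is a delimited table with columns
``node_id, x, y, z, network_label``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.fft import dct, idct

__all__ = [
    "SignalSet",
    "load_signals",
    "save_signals",
    "load_atlas",
    "save_atlas",
    "validate_atlas",
    "discard_initial_frames",
    "highpass",
]

ATLAS_COLUMNS = ("node_id", "x", "y", "z", "network_label")


@dataclass(frozen=True)
class SignalSet:
    """Per-subject node x time signal matrices with shared node order.

    Parameters
    ----------
    subjects
        Ordered subject identifiers.
    data
        One ``(n_nodes, n_frames)`` float array per subject, aligned with
        ``subjects``. All subjects must share the node count; frame counts
        must match as well (one acquisition protocol).
    node_ids
        Ordered node identifiers shared by every subject.
    dt
        Seconds per frame (TR). Must be positive.
    """

    subjects: tuple[str, ...]
    data: tuple[np.ndarray, ...]
    node_ids: tuple[str, ...]
    dt: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "subjects", tuple(str(s) for s in self.subjects))
        object.__setattr__(self, "node_ids", tuple(str(n) for n in self.node_ids))
        mats = tuple(np.asarray(m, dtype=float) for m in self.data)
        object.__setattr__(self, "data", mats)
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if len(self.subjects) != len(mats):
            raise ValueError("one matrix per subject required")
        if len(set(self.subjects)) != len(self.subjects):
            raise ValueError("duplicate subject ids")
        n_nodes = len(self.node_ids)
        for subj, m in zip(self.subjects, mats):
            if m.ndim != 2 or m.shape[0] != n_nodes:
                raise ValueError(
                    f"subject {subj}: expected {n_nodes} node rows, got shape {m.shape}"
                )
            if not np.isfinite(m).all():
                bad = np.argwhere(~np.isfinite(m))[0]
                raise ValueError(
                    f"subject {subj}: non-finite value at node {self.node_ids[bad[0]]}, "
                    f"frame {bad[1]}"
                )
        frames = {m.shape[1] for m in mats}
        if len(frames) > 1:
            raise ValueError(f"subjects differ in frame count: {sorted(frames)}")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_frames(self) -> int:
        return self.data[0].shape[1] if self.data else 0

    def subject(self, subject_id: str) -> np.ndarray:
        return self.data[self.subjects.index(str(subject_id))]


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        head = fh.readline()
    return "\t" if head.count("\t") > head.count(",") else ","


def load_signals(
    paths: Sequence[str | Path],
    dt: float,
    subjects: Sequence[str] | None = None,
) -> SignalSet:
    """Load one delimited node x time file per subject into a SignalSet.

    The node order of the first file is authoritative; every other file must
    list the same nodes in the same order. Ragged rows, non-numeric cells and
    missing values fail loudly with the offending file and location.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no signal files given")
    if subjects is None:
        subjects = [p.stem for p in paths]
    mats: list[np.ndarray] = []
    node_ids: tuple[str, ...] | None = None
    for path in paths:
        delim = _sniff_delimiter(path)
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh, delimiter=delim))
        if len(rows) < 2:
            raise ValueError(f"{path}: no data rows")
        width = len(rows[0])
        ids, values = [], []
        for i, row in enumerate(rows[1:], start=2):
            if len(row) != width:
                raise ValueError(f"{path}: ragged row {i} ({len(row)} != {width} cells)")
            ids.append(row[0])
            try:
                values.append([float(c) for c in row[1:]])
            except ValueError:
                bad = next(j for j, c in enumerate(row[1:]) if not _is_float(c))
                raise ValueError(
                    f"{path}: non-numeric cell at row {i}, column {bad + 2}: {row[1:][bad]!r}"
                ) from None
        mat = np.asarray(values, dtype=float)
        if np.isnan(mat).any():
            r, c = np.argwhere(np.isnan(mat))[0]
            raise ValueError(f"{path}: missing value at node {ids[r]}, frame {c}")
        if node_ids is None:
            node_ids = tuple(ids)
        elif tuple(ids) != node_ids:
            raise ValueError(f"{path}: node order differs from {paths[0]}")
        mats.append(mat)
    assert node_ids is not None
    return SignalSet(tuple(str(s) for s in subjects), tuple(mats), node_ids, dt)


def _is_float(cell: str) -> bool:
    try:
        float(cell)
    except ValueError:
        return False
    return True


def save_signals(s: SignalSet, out_dir: str | Path, delimiter: str = ",") -> list[Path]:
    """Write one ``<subject>.csv`` per subject (node_id column + frame columns)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for subj, mat in zip(s.subjects, s.data):
        path = out_dir / f"{subj}.csv"
        header = ["node_id"] + [f"f{t}" for t in range(mat.shape[1])]
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter=delimiter)
            w.writerow(header)
            for node, row in zip(s.node_ids, mat):
                w.writerow([node] + [repr(float(v)) for v in row])
        written.append(path)
    return written


def validate_atlas(atlas: pd.DataFrame, signals: SignalSet | None = None) -> pd.DataFrame:
    """Check atlas invariants: required columns, unique node ids, coverage."""
    missing = [c for c in ATLAS_COLUMNS if c not in atlas.columns]
    if missing:
        raise ValueError(f"atlas missing columns: {missing}")
    atlas = atlas.copy()
    atlas["node_id"] = atlas["node_id"].astype(str)
    if atlas["node_id"].duplicated().any():
        dupes = atlas.loc[atlas["node_id"].duplicated(), "node_id"].tolist()
        raise ValueError(f"duplicate atlas node ids: {dupes}")
    if signals is not None:
        absent = set(signals.node_ids) - set(atlas["node_id"])
        if absent:
            raise ValueError(f"signal nodes absent from atlas: {sorted(absent)}")
    return atlas


def load_atlas(path: str | Path, signals: SignalSet | None = None) -> pd.DataFrame:
    path = Path(path)
    atlas = pd.read_csv(path, sep=_sniff_delimiter(path))
    return validate_atlas(atlas, signals)


def save_atlas(atlas: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    validate_atlas(atlas).to_csv(path, index=False)
    return path


def discard_initial_frames(s: SignalSet, n: int = 20) -> SignalSet:
    """Drop the first ``n`` frames of every subject (non-equilibrium frames)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if n >= s.n_frames:
        raise ValueError(f"cannot discard {n} of {s.n_frames} frames")
    if n == 0:
        return s
    return replace(s, data=tuple(m[:, n:] for m in s.data))


def highpass(s: SignalSet, cutoff_hz: float = 0.008) -> SignalSet:
    """Temporal high-pass filter via discrete-cosine-basis removal.

    The DCT-II basis on ``n`` frames has component frequencies
    ``f_k = k / (2 n dt)``. All components with ``f_k < cutoff_hz``
    (including the DC term, so output is zero-mean per node) are removed by
    zeroing their coefficients in the orthonormal DCT domain — a zero-phase
    projection, exact on the finite window.
    """
    nyquist = 1.0 / (2.0 * s.dt)
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyquist} Hz")
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    n = s.n_frames
    freqs = np.arange(n) / (2.0 * n * s.dt)
    kill = freqs < cutoff_hz
    out = []
    for m in s.data:
        coef = dct(m, type=2, norm="ortho", axis=1)
        coef[:, kill] = 0.0
        out.append(idct(coef, type=2, norm="ortho", axis=1))
    return replace(s, data=tuple(out))
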