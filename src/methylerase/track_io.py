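"""Nucleosome annotation tracks and time-course matrices, with TSV round-trip I/O.

Coordinates follow the BED convention (0-based, half-open).  Missing values are
encoded as ``NA`` on disk and ``NaN`` in memory.  Readers reject malformed
input rather than repairing it; error messages name the offending record.

See ``docs/FORMATS.md`` for the on-disk column layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .errors import MatrixValidationError, TrackValidationError

TRACK_COLUMNS = [
    "chrom",
    "start",
    "end",
    "nucleosome_id",
    "replication_time_min",
    "tss_distance_bp",
    "gene",
    "induction_class",
    "heat_induction_log2",
    "alpha_induction_log2",
]


@dataclass
class NucleosomeTrack:
    """Per-nucleosome annotation: interval, replication time, TSS distance, induction."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in TRACK_COLUMNS if c not in df.columns]
        if missing:
            raise TrackValidationError(f"track missing columns: {missing}")
        dup = df["nucleosome_id"][df["nucleosome_id"].duplicated()]
        if len(dup):
            raise TrackValidationError(
                f"duplicate nucleosome_id: {sorted(set(dup))[:5]}"
            )
        bad = df[~(df["start"] < df["end"])]
        if len(bad):
            ids = bad["nucleosome_id"].tolist()[:5]
            raise TrackValidationError(
                f"records with start >= end (0-based half-open intervals): {ids}"
            )
        if not np.isfinite(df["replication_time_min"].to_numpy(float)).all():
            bad_ids = df.loc[
                ~np.isfinite(df["replication_time_min"].to_numpy(float)), "nucleosome_id"
            ].tolist()[:5]
            raise TrackValidationError(f"non-finite replication_time_min: {bad_ids}")
        self.records = df.reset_index(drop=True)

    @property
    def ids(self) -> List[str]:
        return self.records["nucleosome_id"].tolist()

    def __len__(self) -> int:
        return len(self.records)

    def annotation(self, column: str) -> pd.Series:
        """Series of one annotation column indexed by nucleosome_id."""
        return self.records.set_index("nucleosome_id")[column]


@dataclass
class TimeCourseMatrix:
    """Nucleosomes x time points of log2 values plus condition metadata.

    ``segments`` holds the cumulative column counts at segment ends for
    concatenated courses (e.g. ``[19, 38]`` for two 19-point courses); a single
    un-concatenated course has ``segments == [n_times]``.
    """

    ids: List[str]
    times: np.ndarray
    values: np.ndarray
    condition: str = ""
    channel: str = "H3K4me3"
    centered: bool = False
    segments: List[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.ids)) != len(self.ids):
            dup = pd.Index(self.ids)
            raise MatrixValidationError(
                f"duplicate row ids: {sorted(set(dup[dup.duplicated()]))[:5]}"
            )
        if self.values.shape != (len(self.ids), len(self.times)):
            raise MatrixValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.ids)} ids x {len(self.times)} times"
            )
        if not self.segments:
            self.segments = [len(self.times)]
        if self.segments[-1] != len(self.times):
            raise MatrixValidationError(
                f"segment boundaries {self.segments} do not end at {len(self.times)}"
            )
        for seg_lo, seg_hi in self.iter_segments():
            t = self.times[seg_lo:seg_hi]
            if np.any(np.diff(t) <= 0):
                raise MatrixValidationError(
                    "time points must be strictly increasing within each segment"
                )
        if self.centered:
            for seg_lo, seg_hi in self.iter_segments():
                row_means = np.nanmean(self.values[:, seg_lo:seg_hi], axis=1)
                if np.nanmax(np.abs(row_means), initial=0.0) > 1e-9:
                    raise MatrixValidationError(
                        "centered=True but some row mean deviates from 0 by > 1e-9"
                    )

    def iter_segments(self) -> List[Tuple[int, int]]:
        bounds = [0] + list(self.segments)
        return list(zip(bounds[:-1], bounds[1:]))

    @property
    def n_rows(self) -> int:
        return len(self.ids)

    def row(self, nucleosome_id: str) -> np.ndarray:
        return self.values[self.ids.index(nucleosome_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.ids, name="nucleosome_id"),
                            columns=self.times)

    def copy_with(self, **kw) -> "TimeCourseMatrix":
        base = dict(
            ids=list(self.ids), times=self.times.copy(), values=self.values.copy(),
            condition=self.condition, channel=self.channel, centered=self.centered,
            segments=list(self.segments),
        )
        base.update(kw)
        return TimeCourseMatrix(**base)


# ---------------------------------------------------------------------------
# track I/O

def write_track(track: NucleosomeTrack, path: Union[str, Path]) -> None:
    """Write a BED-like TSV (0-based half-open; extra annotation columns)."""
    track.records.to_csv(path, sep="\t", index=False, na_rep="NA",
                         columns=TRACK_COLUMNS)


def read_track(path: Union[str, Path]) -> NucleosomeTrack:
    df = pd.read_csv(path, sep="\t", header=0, na_values=["NA"], keep_default_na=False,
                     dtype={"nucleosome_id": str, "chrom": str, "gene": str,
                            "induction_class": str})
    return NucleosomeTrack(df)


# ---------------------------------------------------------------------------
# matrix I/O
#
# Metadata travels in '#key=value' comment lines before the header so a matrix
# TSV round-trips including its condition/channel/centered/segment state.

def write_matrix(m: TimeCourseMatrix, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write(f"#condition={m.condition}\n")
        fh.write(f"#channel={m.channel}\n")
        fh.write(f"#centered={int(m.centered)}\n")
        fh.write("#segments=" + ",".join(str(s) for s in m.segments) + "\n")
        header = "nucleosome_id\t" + "\t".join(repr(float(t)) for t in m.times)
        fh.write(header + "\n")
        for rid, row in zip(m.ids, m.values):
            cells = ["NA" if not np.isfinite(v) else repr(float(v)) for v in row]
            fh.write(rid + "\t" + "\t".join(cells) + "\n")


def read_matrix(path: Union[str, Path]) -> TimeCourseMatrix:
    # parsed by hand rather than via a DataFrame reader: time columns repeat
    # across concatenation segments (which tabular readers mangle), and the
    # round trip must be bit-exact
    meta = {}
    header: Optional[List[str]] = None
    ids: List[str] = []
    rows: List[List[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                meta[key] = val
                continue
            cells = line.split("\t")
            if header is None:
                header = cells
                continue
            if len(cells) != len(header):
                raise MatrixValidationError(
                    f"line {lineno}: {len(cells)} fields, expected {len(header)}")
            ids.append(cells[0])
            rows.append([float("nan") if c == "NA" else float(c)
                         for c in cells[1:]])
    if header is None:
        raise MatrixValidationError(f"{path}: no header line")
    try:
        times = np.array([float(c) for c in header[1:]])
    except ValueError as exc:
        raise MatrixValidationError(f"non-numeric time column in header: {exc}")
    segments = [int(s) for s in meta.get("segments", "").split(",")] if meta.get(
        "segments") else []
    return TimeCourseMatrix(
        ids=ids,
        times=times,
        values=np.array(rows, dtype=float).reshape(len(ids), len(times)),
        condition=meta.get("condition", ""),
        channel=meta.get("channel", "H3K4me3"),
        centered=bool(int(meta.get("centered", "0"))),
        segments=segments,
    )


# ---------------------------------------------------------------------------

@dataclass
class JoinResult:
    """Matrix restricted to ids present in the track, plus the drop count."""

    matrix: TimeCourseMatrix
    track: NucleosomeTrack
    n_dropped: int
    dropped_ids: List[str]


def join(matrix: TimeCourseMatrix, track: NucleosomeTrack) -> JoinResult:
    """Restrict ``matrix`` to rows annotated in ``track`` (matrix order kept).

    Raises :class:`TrackValidationError` if the id sets are disjoint.
    """
    track_ids = set(track.ids)
    keep = [i for i, rid in enumerate(matrix.ids) if rid in track_ids]
    dropped = [rid for rid in matrix.ids if rid not in track_ids]
    if not keep:
        raise TrackValidationError("matrix and track share no nucleosome ids")
    sub = matrix.copy_with(ids=[matrix.ids[i] for i in keep],
                           values=matrix.values[keep])
    order = {rid: k for k, rid in enumerate(sub.ids)}
    tr = track.records[track.records["nucleosome_id"].isin(order)].copy()
    tr = tr.sort_values("nucleosome_id", key=lambda s: s.map(order))
    return JoinResult(matrix=sub, track=NucleosomeTrack(tr), n_dropped=len(dropped),
                      dropped_ids=dropped)
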