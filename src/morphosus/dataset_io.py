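"""Reading, writing and validation of landmark datasets.

Two interchange formats are supported: the TPS landmark format produced by
the tpsDig family of digitizers (``LM=``/``LM3=``, ``CURVES=``/``POINTS=``,
``ID=``, ``IMAGE=``, ``SCALE=`` records) for 2D dental data, and plain CSV
coordinate tables (columns ``x, y, z`` plus an optional ``role`` column) for
3D bone data.  Specimen metadata (population group, period, wild/domestic
status, skeletal element) comes from a separate CSV keyed by specimen id.

Coordinates are stored exactly as read (TPS uses a bottom-left y origin); an
optional ``flip_y`` flag at read time converts image-convention input, which
matters for outline winding direction but not for Procrustes alignment.
Missing landmarks are not supported: a record with an incomplete coordinate
block is a parse error, never silently imputed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkConfiguration",
    "SpecimenRecord",
    "MorphometricDataset",
    "ProtocolTemplate",
    "TpsParseError",
    "DatasetError",
    "read_tps",
    "write_tps",
    "read_metadata",
    "read_xyz_table",
    "assemble_dataset",
    "validate_dataset",
]

ANATOMICAL = "anatomical"
SEMILANDMARK = "semilandmark"

_ALLOWED_ELEMENTS = ("M2", "M3", "calcaneus", "other")
_ALLOWED_STATUS = ("wild", "domestic", "hybrid", "captive", "unknown")


class TpsParseError(ValueError):
    """Malformed TPS input; message names the record index and line number."""


class DatasetError(ValueError):
    """A dataset violates its structural invariants."""


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One specimen's ordered point set with per-point role tags.

    Parameters
    ----------
    points
        (p, k) array of coordinates, k in {2, 3}, arbitrary consistent units.
    roles
        Length-p tuple of ``"anatomical"`` / ``"semilandmark"`` tags.
    """

    points: np.ndarray
    roles: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] not in (2, 3):
            raise DatasetError(f"points must be (p, k) with k in {{2, 3}}, got {pts.shape}")
        if pts.shape[0] < 3:
            raise DatasetError(f"a configuration needs at least 3 points, got {pts.shape[0]}")
        if not np.all(np.isfinite(pts)):
            raise DatasetError("non-finite coordinate in configuration")
        roles = tuple(self.roles) if self.roles else (ANATOMICAL,) * pts.shape[0]
        if len(roles) != pts.shape[0]:
            raise DatasetError(f"roles length {len(roles)} != point count {pts.shape[0]}")
        bad = set(roles) - {ANATOMICAL, SEMILANDMARK}
        if bad:
            raise DatasetError(f"unknown role tags: {sorted(bad)}")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "roles", roles)

    @property
    def p(self) -> int:
        return self.points.shape[0]

    @property
    def dimension(self) -> int:
        return self.points.shape[1]

    def flat(self) -> np.ndarray:
        """Row-major flattening (x1, y1[, z1], x2, ...)."""
        return self.points.reshape(-1)


@dataclass(frozen=True)
class SpecimenRecord:
    specimen_id: str
    group: str
    configuration: LandmarkConfiguration
    period: str = ""
    status: str = "unknown"
    element: str = "other"

    def __post_init__(self) -> None:
        if self.element not in _ALLOWED_ELEMENTS:
            raise DatasetError(
                f"{self.specimen_id!r}: element {self.element!r} not in {_ALLOWED_ELEMENTS}"
            )
        if self.status not in _ALLOWED_STATUS:
            raise DatasetError(
                f"{self.specimen_id!r}: status {self.status!r} not in {_ALLOWED_STATUS}"
            )


@dataclass(frozen=True)
class MorphometricDataset:
    """A homogeneous sample: all records share element, landmark count and dimension."""

    records: tuple[SpecimenRecord, ...]
    element: str
    p: int = field(default=0)
    k: int = field(default=0)

    def __post_init__(self) -> None:
        records = tuple(self.records)
        if len(records) < 2:
            raise DatasetError("a dataset needs at least 2 records")
        p = records[0].configuration.p
        k = records[0].configuration.dimension
        object.__setattr__(self, "records", records)
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "k", k)
        validate_dataset(self)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def specimen_ids(self) -> list[str]:
        return [r.specimen_id for r in self.records]

    @property
    def groups(self) -> np.ndarray:
        return np.array([r.group for r in self.records])

    def coordinate_matrix(self) -> np.ndarray:
        """(n, k*p) matrix of raw coordinates, row-major per landmark."""
        return np.stack([r.configuration.flat() for r in self.records])

    def configurations(self) -> list[LandmarkConfiguration]:
        return [r.configuration for r in self.records]


def validate_dataset(dataset: MorphometricDataset) -> None:
    """Raise :class:`DatasetError` listing every offending record."""
    p, k = dataset.p, dataset.k
    offenders = [
        f"{r.specimen_id} (p={r.configuration.p}, k={r.configuration.dimension})"
        for r in dataset.records
        if r.configuration.p != p or r.configuration.dimension != k
    ]
    if offenders:
        raise DatasetError(f"heterogeneous configurations: {', '.join(offenders)}")
    mixed = [r.specimen_id for r in dataset.records if r.element != dataset.element]
    if mixed:
        raise DatasetError(f"records with foreign element label: {', '.join(mixed)}")
    seen: dict[str, int] = {}
    for r in dataset.records:
        seen[r.specimen_id] = seen.get(r.specimen_id, 0) + 1
    dupes = [sid for sid, n in seen.items() if n > 1]
    if dupes:
        raise DatasetError(f"duplicate specimen_ids: {', '.join(dupes)}")


@dataclass(frozen=True)
class ProtocolTemplate:
    """Digitizing protocol for one skeletal element: fixed landmarks plus an
    equidistant outline block anchored at one of the landmarks."""

    element: str
    n_anatomical: int
    n_semilandmarks: int
    start_landmark_index: int

    def __post_init__(self) -> None:
        if self.n_anatomical < 1:
            raise DatasetError("n_anatomical must be >= 1")
        if self.n_semilandmarks < 0:
            raise DatasetError("n_semilandmarks must be >= 0")
        if not 0 <= self.start_landmark_index < self.n_anatomical:
            raise DatasetError("start_landmark_index must index an anatomical landmark")

    @property
    def p(self) -> int:
        return self.n_anatomical + self.n_semilandmarks


# ---------------------------------------------------------------------------
# TPS format
# ---------------------------------------------------------------------------

_KEYWORD = re.compile(r"^(LM3?|CURVES|POINTS|ID|IMAGE|SCALE|COMMENT)\s*=\s*(.*)$", re.I)


def _parse_coord_line(line: str, k: int, record_idx: int, lineno: int) -> np.ndarray:
    parts = line.split()
    try:
        vals = [float(v) for v in parts]
    except ValueError:
        raise TpsParseError(
            f"record {record_idx}, line {lineno}: non-numeric coordinate {line!r}"
        ) from None
    if len(vals) != k:
        raise TpsParseError(
            f"record {record_idx}, line {lineno}: expected {k} coordinates, got {len(vals)}"
        )
    return np.array(vals)


def read_tps(
    path: str | Path, *, flip_y: bool = False
) -> list[tuple[str, LandmarkConfiguration, list[np.ndarray]]]:
    """Parse a TPS file into ``(specimen_id, configuration, curves)`` entries.

    Landmarks come from the ``LM=`` block; outline curves (``CURVES=`` /
    ``POINTS=`` blocks) are returned separately, one array per curve, in file
    order.  ``SCALE=`` is applied multiplicatively to landmarks and curves.
    Both ``LM=`` (2D) and ``LM3=`` (3D) headers are accepted; ``IMAGE=`` and
    ``COMMENT=`` lines are opaque.  With ``flip_y`` the y axis is negated,
    converting image-convention (top-left origin) input.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    entries: list[tuple[str, LandmarkConfiguration, list[np.ndarray]]] = []

    i = 0
    record_idx = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        m = _KEYWORD.match(line)
        if not m or m.group(1).upper() not in ("LM", "LM3"):
            raise TpsParseError(f"record {record_idx}, line {i + 1}: expected LM= header, got {line!r}")
        k = 3 if m.group(1).upper() == "LM3" else 2
        try:
            n_lm = int(m.group(2))
        except ValueError:
            raise TpsParseError(f"record {record_idx}, line {i + 1}: bad LM= count {m.group(2)!r}") from None
        if n_lm <= 0:
            raise TpsParseError(f"record {record_idx}, line {i + 1}: LM={n_lm} (must be positive)")
        i += 1

        landmarks = []
        for j in range(n_lm):
            if i >= len(lines) or _KEYWORD.match(lines[i].strip()):
                raise TpsParseError(
                    f"record {record_idx}, line {i + 1}: truncated coordinate block "
                    f"({j} of {n_lm} landmark lines)"
                )
            landmarks.append(_parse_coord_line(lines[i].strip(), k, record_idx, i + 1))
            i += 1

        curves: list[np.ndarray] = []
        specimen_id = ""
        scale = None
        while i < len(lines):
            line = lines[i].strip()
            if not line:
                i += 1
                continue
            m = _KEYWORD.match(line)
            if m is None:
                raise TpsParseError(f"record {record_idx}, line {i + 1}: unexpected line {line!r}")
            key = m.group(1).upper()
            if key in ("LM", "LM3"):
                break  # next record
            val = m.group(2)
            i += 1
            if key == "CURVES":
                n_curves = int(val)
                for _ in range(n_curves):
                    if i >= len(lines):
                        raise TpsParseError(f"record {record_idx}, line {i}: missing POINTS= block")
                    pm = _KEYWORD.match(lines[i].strip())
                    if pm is None or pm.group(1).upper() != "POINTS":
                        raise TpsParseError(
                            f"record {record_idx}, line {i + 1}: expected POINTS=, got {lines[i].strip()!r}"
                        )
                    n_pts = int(pm.group(2))
                    i += 1
                    pts = []
                    for j in range(n_pts):
                        if i >= len(lines) or _KEYWORD.match(lines[i].strip()):
                            raise TpsParseError(
                                f"record {record_idx}, line {i + 1}: truncated curve "
                                f"({j} of {n_pts} points)"
                            )
                        pts.append(_parse_coord_line(lines[i].strip(), k, record_idx, i + 1))
                        i += 1
                    curves.append(np.stack(pts))
            elif key == "ID":
                specimen_id = val.strip()
            elif key == "SCALE":
                scale = float(val)
            # IMAGE= / COMMENT= are opaque

        pts = np.stack(landmarks)
        if scale is not None:
            pts = pts * scale
            curves = [c * scale for c in curves]
        if flip_y:
            pts = pts.copy()
            pts[:, 1] = -pts[:, 1]
            curves = [np.column_stack([c[:, 0], -c[:, 1], *([c[:, 2]] if k == 3 else [])]) for c in curves]
        if not specimen_id:
            specimen_id = f"record_{record_idx}"
        entries.append((specimen_id, LandmarkConfiguration(pts), curves))
        record_idx += 1

    return entries


def write_tps(
    entries: Iterable[tuple[str, LandmarkConfiguration, Sequence[np.ndarray]]],
    path: str | Path,
) -> Path:
    """Write entries as a TPS file (6-decimal coordinates); inverse of :func:`read_tps`."""
    path = Path(path)
    out: list[str] = []
    for specimen_id, config, curves in entries:
        pts = config.points
        if not np.all(np.isfinite(pts)):
            raise DatasetError(f"{specimen_id!r}: refusing to write non-finite coordinates")
        header = "LM3" if config.dimension == 3 else "LM"
        out.append(f"{header}={config.p}")
        out.extend(" ".join(f"{v:.6f}" for v in row) for row in pts)
        curves = list(curves)
        if curves:
            out.append(f"CURVES={len(curves)}")
            for c in curves:
                c = np.asarray(c, dtype=float)
                if not np.all(np.isfinite(c)):
                    raise DatasetError(f"{specimen_id!r}: non-finite curve point")
                out.append(f"POINTS={c.shape[0]}")
                out.extend(" ".join(f"{v:.6f}" for v in row) for row in c)
        out.append(f"ID={specimen_id}")
    path.write_text("\n".join(out) + ("\n" if out else ""))
    return path


# ---------------------------------------------------------------------------
# Metadata and 3D coordinate tables
# ---------------------------------------------------------------------------


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a specimen metadata CSV keyed by ``specimen_id``.

    Mandatory columns: ``specimen_id``, ``group``.  Missing optional columns
    are filled: ``status`` -> "unknown", ``period`` -> "", ``element`` ->
    "other".  Duplicate ids are an error.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    for col in ("specimen_id", "group"):
        if col not in df.columns:
            raise DatasetError(f"metadata missing mandatory column {col!r}")
    dupes = df["specimen_id"][df["specimen_id"].duplicated()].tolist()
    if dupes:
        raise DatasetError(f"duplicate specimen_id in metadata: {', '.join(sorted(set(dupes)))}")
    if "status" not in df.columns:
        df["status"] = "unknown"
    df.loc[df["status"] == "", "status"] = "unknown"
    if "period" not in df.columns:
        df["period"] = ""
    if "element" not in df.columns:
        df["element"] = "other"
    df.loc[df["element"] == "", "element"] = "other"
    return df.set_index("specimen_id", drop=False)


def read_xyz_table(path: str | Path) -> tuple[str, LandmarkConfiguration]:
    """Read one specimen's 3D landmarks from a CSV with columns x, y, z
    (optional ``role``); row order defines landmark order; the file stem is
    the specimen id."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise DatasetError(f"{path.name}: empty coordinate table")
    for col in ("x", "y", "z"):
        if col not in df.columns:
            raise DatasetError(f"{path.name}: missing column {col!r}")
    pts = df[["x", "y", "z"]].to_numpy(dtype=float)
    roles: tuple[str, ...] = ()
    if "role" in df.columns:
        roles = tuple(str(r) for r in df["role"])
    return path.stem, LandmarkConfiguration(pts, roles)


def assemble_dataset(
    configs: Sequence[tuple[str, LandmarkConfiguration]] | Mapping[str, LandmarkConfiguration],
    metadata: pd.DataFrame,
    element: str,
) -> MorphometricDataset:
    """Join configurations with metadata into a validated dataset.

    Every configuration id must appear in the metadata; all selected records
    must share the landmark count and dimension of the first.  Offending
    specimens are named, never dropped.
    """
    if isinstance(configs, Mapping):
        items = list(configs.items())
    else:
        items = list(configs)
    if not items:
        raise DatasetError("no configurations to assemble")
    missing = [sid for sid, _ in items if sid not in metadata.index]
    if missing:
        raise DatasetError(f"specimen ids absent from metadata: {', '.join(missing)}")
    records = []
    for sid, config in items:
        row = metadata.loc[sid]
        records.append(
            SpecimenRecord(
                specimen_id=sid,
                group=str(row["group"]),
                period=str(row.get("period", "")),
                status=str(row.get("status", "unknown")),
                element=element,
                configuration=config,
            )
        )
    return MorphometricDataset(records=tuple(records), element=element)
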