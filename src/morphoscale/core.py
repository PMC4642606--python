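"""Landmark data containers and file input/output.

A *configuration* is one specimen's set of k homologous landmarks in
d = 2 or 3 Cartesian dimensions.  A *shape sample* is an ordered list of
configurations sharing the same landmark scheme.  Files are read and
written in two plain-text conventions: Rohlf-style TPS files (``LM=``
blocks) and flat CSV tables with one specimen per row and columns
``x1, y1[, z1], x2, ...``.
"""

from __future__ import annotations

import csv as _csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Configuration",
    "ShapeSample",
    "read_landmarks",
    "write_landmarks",
    "validate_sample",
    "HomologyError",
    "LandmarkParseError",
    "DegenerateConfigurationError",
]


class HomologyError(ValueError):
    """Specimens in one sample disagree in landmark count or dimension."""


class LandmarkParseError(ValueError):
    """A landmark file could not be parsed; carries the offending line."""


class DegenerateConfigurationError(ValueError):
    """Configuration is unusable for spline work (collinear, coincident...)."""


@dataclass
class Configuration:
    """One specimen: a k x d array of landmark coordinates.

    Parameters
    ----------
    coords
        Array of shape (k, d) with d in {2, 3}.  Coordinates are stored
        exactly as supplied; no axis flips or rescaling are applied.
    labels
        Optional landmark names, length k.
    id
        Optional specimen identifier.
    """

    coords: np.ndarray
    labels: list[str] | None = None
    id: str | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] not in (2, 3):
            raise ValueError(
                f"coords must be (k, 2) or (k, 3); got {self.coords.shape}"
            )
        if self.labels is not None and len(self.labels) != self.coords.shape[0]:
            raise ValueError("labels length must match landmark count")

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    @property
    def dim(self) -> int:
        return self.coords.shape[1]

    def copy(self) -> "Configuration":
        return Configuration(
            self.coords.copy(),
            None if self.labels is None else list(self.labels),
            self.id,
        )

    def centroid_size(self) -> float:
        c = self.coords - self.coords.mean(axis=0)
        return float(np.sqrt((c ** 2).sum()))


@dataclass
class ShapeSample:
    """An ordered sample of configurations with a shared landmark scheme."""

    configurations: list[Configuration]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.configurations) == 0:
            raise ValueError("a ShapeSample needs at least one configuration")
        k0, d0 = self.configurations[0].coords.shape
        for i, c in enumerate(self.configurations):
            if c.coords.shape != (k0, d0):
                raise HomologyError(
                    f"specimen {i} has shape {c.coords.shape}, expected {(k0, d0)}"
                )

    @property
    def n(self) -> int:
        return len(self.configurations)

    @property
    def k(self) -> int:
        return self.configurations[0].k

    @property
    def dim(self) -> int:
        return self.configurations[0].dim

    @property
    def coords(self) -> np.ndarray:
        """All coordinates as an (n, k, d) array (a copy)."""
        return np.stack([c.coords for c in self.configurations])

    @classmethod
    def from_array(
        cls,
        arr: np.ndarray,
        labels: Sequence[str] | None = None,
        ids: Sequence[str] | None = None,
        metadata: dict | None = None,
    ) -> "ShapeSample":
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 3:
            raise ValueError("expected an (n, k, d) array")
        configs = [
            Configuration(
                arr[i],
                None if labels is None else list(labels),
                None if ids is None else str(ids[i]),
            )
            for i in range(arr.shape[0])
        ]
        return cls(configs, metadata or {})


# ---------------------------------------------------------------------------
# TPS-format files


def _parse_tps(lines: Iterable[str], path: str) -> ShapeSample:
    configs: list[Configuration] = []
    pending: list[list[float]] | None = None
    expected_k = 0
    dim = 2
    cur_id: str | None = None
    cur_scale: float | None = None
    skip = 0  # coordinate lines belonging to a CURVES/POINTS block

    def flush(lineno: int) -> None:
        nonlocal pending, cur_id, cur_scale
        if pending is None:
            return
        if len(pending) != expected_k:
            raise LandmarkParseError(
                f"{path}:{lineno}: LM block promised {expected_k} landmarks, "
                f"found {len(pending)}"
            )
        arr = np.asarray(pending, dtype=float)
        if cur_scale is not None:
            arr = arr * cur_scale
        configs.append(Configuration(arr, id=cur_id))
        pending, cur_id, cur_scale = None, None, None

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("LM3=") or upper.startswith("LM="):
            flush(lineno)
            key, _, val = line.partition("=")
            try:
                expected_k = int(val)
            except ValueError as exc:
                raise LandmarkParseError(f"{path}:{lineno}: bad LM count {val!r}") from exc
            dim = 3 if key.upper() == "LM3" else 2
            pending = []
            skip = 0
        elif upper.startswith("CURVES=") or upper.startswith("POINTS="):
            # semilandmark curves are ignored; swallow their coordinate lines
            _, _, val = line.partition("=")
            if upper.startswith("POINTS="):
                try:
                    skip = int(val)
                except ValueError:
                    skip = 0
        elif upper.startswith("ID="):
            cur_id = line.partition("=")[2].strip()
        elif upper.startswith("SCALE="):
            try:
                cur_scale = float(line.partition("=")[2])
            except ValueError as exc:
                raise LandmarkParseError(f"{path}:{lineno}: bad SCALE value") from exc
        elif upper.startswith("IMAGE=") or upper.startswith("COMMENT="):
            continue
        elif skip > 0:
            skip -= 1
        else:
            if pending is None:
                raise LandmarkParseError(
                    f"{path}:{lineno}: coordinate line outside an LM block"
                )
            parts = line.replace(",", " ").split()
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise LandmarkParseError(
                    f"{path}:{lineno}: non-numeric token in {line!r}"
                ) from exc
            if len(vals) != dim:
                raise LandmarkParseError(
                    f"{path}:{lineno}: expected {dim} coordinates, got {len(vals)}"
                )
            pending.append(vals)
    flush(-1)
    if not configs:
        raise LandmarkParseError(f"{path}: no LM blocks found")
    return ShapeSample(configs)


def _write_tps(sample: ShapeSample, path: Path) -> None:
    key = "LM3" if sample.dim == 3 else "LM"
    with open(path, "w") as fh:
        for i, cfg in enumerate(sample.configurations):
            fh.write(f"{key}={cfg.k}\n")
            for row in cfg.coords:
                fh.write(" ".join(f"{v:.12g}" for v in row) + "\n")
            fh.write(f"ID={cfg.id if cfg.id is not None else i}\n")


# ---------------------------------------------------------------------------
# CSV tables


def _parse_csv(lines: list[str], path: str, dim: int) -> ShapeSample:
    rows = [r for r in _csv.reader(lines) if any(f.strip() for f in r)]
    if not rows:
        raise LandmarkParseError(f"{path}: empty CSV file")

    def numeric(row: list[str]) -> bool:
        try:
            [float(f) for f in row if f.strip()]
            return True
        except ValueError:
            return False

    start = 0
    ids: list[str | None]
    if not numeric(rows[0]):
        start = 1  # header row
    data_rows = rows[start:]
    if not data_rows:
        raise LandmarkParseError(f"{path}: CSV has a header but no data rows")

    # a leading id column is flagged either by the header or by being
    # non-numeric in the first data row
    if start == 1 and rows[0][0].strip().lower() == "id":
        has_id = True
    else:
        has_id = not numeric([data_rows[0][0]])
    parsed: list[list[float]] = []
    ids = []
    for i, row in enumerate(data_rows, start=start + 1):
        fields = [f for f in row if f.strip()]
        ids.append(fields[0] if has_id else None)
        body = fields[1:] if has_id else fields
        try:
            vals = [float(f) for f in body]
        except ValueError as exc:
            raise LandmarkParseError(f"{path}:{i}: non-numeric token") from exc
        parsed.append(vals)
    ncol = len(parsed[0])
    if any(len(p) != ncol for p in parsed):
        raise HomologyError(f"{path}: rows differ in column count")
    if ncol % dim != 0:
        raise LandmarkParseError(
            f"{path}: {ncol} coordinate columns not divisible by dim={dim}"
        )
    arr = np.asarray(parsed).reshape(len(parsed), ncol // dim, dim)
    return ShapeSample.from_array(arr, ids=None if not has_id else ids)


def _write_csv(sample: ShapeSample, path: Path) -> None:
    axes = "xyz"[: sample.dim]
    header = ["id"] + [f"{a}{j + 1}" for j in range(sample.k) for a in axes]
    with open(path, "w", newline="") as fh:
        writer = _csv.writer(fh)
        writer.writerow(header)
        for i, cfg in enumerate(sample.configurations):
            row = [cfg.id if cfg.id is not None else i]
            row += [f"{v:.12g}" for v in cfg.coords.ravel()]
            writer.writerow(row)


def read_landmarks(path, format: str | None = None, dim: int = 2) -> ShapeSample:
    """Read a shape sample from a TPS or CSV file.

    Parameters
    ----------
    path
        File to read.
    format
        ``"tps"`` or ``"csv"``; inferred from the file suffix when None.
    dim
        Coordinate dimension for CSV input (TPS files are self-describing).
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "tps"
    text = path.read_text()
    if format == "tps":
        return _parse_tps(text.splitlines(), str(path))
    if format == "csv":
        return _parse_csv(text.splitlines(), str(path), dim)
    raise ValueError(f"unknown format {format!r}")


def write_landmarks(sample: ShapeSample, path, format: str | None = None) -> None:
    """Write a sample to disk so that :func:`read_landmarks` recovers it."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "tps"
    if format == "tps":
        _write_tps(sample, path)
    elif format == "csv":
        _write_csv(sample, path)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# validation


def _affine_rank(coords: np.ndarray) -> int:
    """Rank of the (1, coordinates) design block of the spline system."""
    q = np.hstack([np.ones((coords.shape[0], 1)), coords])
    return int(np.linalg.matrix_rank(q, tol=1e-9 * max(1.0, np.abs(q).max())))


def validate_sample(sample: ShapeSample) -> list[str]:
    """Report violations that would break downstream spline/Procrustes work.

    Returns a list of human-readable violation strings; an empty list
    means the sample is clean.  Checks: non-finite coordinates, exactly
    coincident landmark pairs, too few landmarks (k < d + 2, below which
    no nonaffine variation exists), and collinear (2D) or coplanar (3D)
    mean configurations, which make the spline system singular.
    """
    report: list[str] = []
    d = sample.dim
    if sample.k < d + 2:
        report.append(
            f"k={sample.k} landmarks in {d}D: need at least {d + 2} "
            "for any nonaffine variation"
        )
    for i, cfg in enumerate(sample.configurations):
        if not np.isfinite(cfg.coords).all():
            report.append(f"specimen {i}: non-finite coordinate")
            continue
        diff = cfg.coords[:, None, :] - cfg.coords[None, :, :]
        dist = np.sqrt((diff ** 2).sum(-1))
        iu = np.triu_indices(cfg.k, 1)
        dup = np.argwhere(dist[iu] == 0.0)
        for (idx,) in dup:
            a, b = iu[0][idx], iu[1][idx]
            report.append(f"specimen {i}: landmarks {a} and {b} coincide")
    mean = sample.coords.mean(axis=0)
    if np.isfinite(mean).all() and _affine_rank(mean) < d + 1:
        report.append(
            "mean configuration is exactly "
            + ("collinear" if d == 2 else "coplanar")
            + ": spline system singular"
        )
    return report
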