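"""Fiber and tractogram data model, resampling, and file I/O.

A *fiber* (streamline) is one white-matter pathway reconstructed by
tractography, represented as an ordered polyline of 3D points in mm.  The
whole pipeline operates on fibers resampled to exactly ``N_POINTS = 21``
equidistant points, so a tractogram is stored compactly as a single
``(n_fibers, 21, 3)`` array.

Supported on-disk formats:

``trk``
    TrackVis TRK via :mod:`nibabel.streamlines`.
``bundles``
    A BrainVISA-style pair: a text header (``.bundles``) recording the fiber
    count, plus a little-endian binary data file (``.bundlesdata``) storing,
    per fiber, an int32 point count followed by that many float32 xyz
    triples.
``array``
    A raw NumPy dump of the ``(n, 21, 3)`` float32 array (``.npy``).
"""

from __future__ import annotations

import os
import struct
from dataclasses import dataclass

import numpy as np

__all__ = [
    "N_POINTS",
    "Tractogram",
    "TractogramFormatError",
    "InvalidFiberError",
    "resample_fiber",
    "flip",
    "read_tractogram",
    "write_tractogram",
]

#: Number of equidistant points every fiber is resampled to.
N_POINTS = 21

FORMATS = ("trk", "bundles", "array")


class InvalidFiberError(ValueError):
    """Raised for degenerate polylines (too few points, zero length)."""


class TractogramFormatError(ValueError):
    """Raised when a tractogram file cannot be parsed."""


def resample_fiber(polyline, n_points: int = N_POINTS) -> np.ndarray:
    """Resample a 3D polyline to ``n_points`` equidistant points.

    Points are placed at equal arc-length intervals along the input
    polyline; the first and last input points are preserved exactly.

    Parameters
    ----------
    polyline : array-like, shape (m, 3)
        At least two points with positive total arc length.
    n_points : int
        Number of output points.

    Returns
    -------
    ndarray, shape (n_points, 3)
    """
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
        raise InvalidFiberError(
            f"polyline must be (m>=2, 3), got shape {pts.shape}"
        )
    if not np.all(np.isfinite(pts)):
        raise InvalidFiberError("polyline contains non-finite coordinates")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = seg.sum()
    if total <= 0.0:
        raise InvalidFiberError("polyline has zero total arc length")
    # cumulative arc length at each input vertex
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, total, n_points)
    out = np.empty((n_points, 3))
    for c in range(3):
        out[:, c] = np.interp(targets, s, pts[:, c])
    out[0] = pts[0]
    out[-1] = pts[-1]
    return out


def flip(f: np.ndarray) -> np.ndarray:
    """Return the fiber with its points stored in reverse order.

    Tractography assigns no canonical orientation to a streamline, so the
    reversed point sequence describes the same curve; point i maps to point
    22 - i (1-based).
    """
    return np.asarray(f)[::-1].copy()


@dataclass
class Tractogram:
    """An ordered collection of 21-point fibers with 0-based integer ids.

    Attributes
    ----------
    points : ndarray, shape (n, 21, 3)
        Fiber coordinates in mm.
    space_note : str
        Free-text tag for the coordinate space (informational only; the
        pipeline is space-agnostic).
    """

    points: np.ndarray
    space_note: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 3 or pts.shape[1] != N_POINTS or pts.shape[2] != 3:
            raise InvalidFiberError(
                f"expected (n, {N_POINTS}, 3) array, got shape {pts.shape}"
            )
        if pts.shape[0] < 1:
            raise InvalidFiberError("tractogram must contain at least one fiber")
        if not np.all(np.isfinite(pts)):
            raise InvalidFiberError("tractogram contains non-finite coordinates")
        self.points = pts

    def __len__(self) -> int:
        return self.points.shape[0]

    def __getitem__(self, i) -> np.ndarray:
        return self.points[i]

    @property
    def ids(self) -> np.ndarray:
        return np.arange(len(self))

    @classmethod
    def from_polylines(cls, polylines, space_note: str = "") -> "Tractogram":
        """Build a tractogram from variable-length polylines, resampling each
        to 21 equidistant points."""
        pts = np.stack([
            p if (np.shape(p) == (N_POINTS, 3)) else resample_fiber(p)
            for p in (np.asarray(p, dtype=float) for p in polylines)
        ])
        return cls(pts, space_note=space_note)


# ---------------------------------------------------------------------------
# File I/O


def _resolve_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in FORMATS:
            raise TractogramFormatError(
                f"unknown format {fmt!r}; expected one of {FORMATS}"
            )
        return fmt
    ext = os.path.splitext(path)[1].lower()
    by_ext = {".trk": "trk", ".bundles": "bundles", ".npy": "array"}
    if ext not in by_ext:
        raise TractogramFormatError(
            f"cannot infer format from extension {ext!r}; pass format="
        )
    return by_ext[ext]


def read_tractogram(path: str, format: str | None = None) -> Tractogram:
    """Read a tractogram; fibers with other than 21 points are resampled.

    Fiber ids follow file order.
    """
    fmt = _resolve_format(path, format)
    if not os.path.exists(path):
        raise TractogramFormatError(f"no such file: {path}")
    if fmt == "trk":
        return _read_trk(path)
    if fmt == "bundles":
        return _read_bundles(path)
    return _read_array(path)


def write_tractogram(t: Tractogram, path: str, format: str | None = None) -> None:
    """Write a tractogram readable back by :func:`read_tractogram`.

    Coordinates are stored as float32, so the round trip is exact at
    float32 precision.
    """
    fmt = _resolve_format(path, format)
    if fmt == "trk":
        _write_trk(t, path)
    elif fmt == "bundles":
        _write_bundles(t, path)
    else:
        _write_array(t, path)


def _read_trk(path: str) -> Tractogram:
    import nibabel as nib

    try:
        trk = nib.streamlines.load(path)
    except Exception as exc:  # nibabel raises assorted error types
        raise TractogramFormatError(f"cannot parse TRK file {path}: {exc}") from exc
    streamlines = list(trk.streamlines)
    if not streamlines:
        raise TractogramFormatError(f"TRK file {path} contains no streamlines")
    return Tractogram.from_polylines(streamlines, space_note="trk/rasmm")


def _write_trk(t: Tractogram, path: str) -> None:
    import nibabel as nib

    sl = nib.streamlines.Tractogram(
        [t.points[i].astype(np.float32) for i in range(len(t))],
        affine_to_rasmm=np.eye(4),
    )
    nib.streamlines.save(sl, path)


def _bundlesdata_path(path: str) -> str:
    return path + "data"


def _read_bundles(path: str) -> Tractogram:
    # minf-style text header: a python-literal dict of attributes
    try:
        with open(path, "r") as fh:
            text = fh.read()
    except OSError as exc:
        raise TractogramFormatError(f"cannot read header {path}: {exc}") from exc
    start = text.find("{")
    end = text.rfind("}")
    if start < 0 or end < 0:
        raise TractogramFormatError(
            f"malformed bundles header {path}: no attribute dict found"
        )
    import ast

    try:
        attrs = ast.literal_eval(text[start : end + 1])
    except Exception as exc:
        raise TractogramFormatError(
            f"malformed bundles header {path}: {exc}"
        ) from exc
    try:
        n_declared = int(attrs["curves_count"])
    except KeyError as exc:
        raise TractogramFormatError(
            f"bundles header {path} lacks 'curves_count'"
        ) from exc

    data_path = _bundlesdata_path(path)
    if not os.path.exists(data_path):
        raise TractogramFormatError(f"missing data file {data_path}")
    polylines = []
    with open(data_path, "rb") as fh:
        while True:
            offset = fh.tell()
            head = fh.read(4)
            if not head:
                break
            if len(head) < 4:
                raise TractogramFormatError(
                    f"truncated fiber header at byte {offset} in {data_path}"
                )
            (npts,) = struct.unpack("<i", head)
            if npts <= 0:
                raise TractogramFormatError(
                    f"invalid point count {npts} at byte {offset} in {data_path}"
                )
            payload = fh.read(12 * npts)
            if len(payload) < 12 * npts:
                raise TractogramFormatError(
                    f"truncated fiber payload at byte {offset + 4} in {data_path}"
                )
            polylines.append(
                np.frombuffer(payload, dtype="<f4").reshape(npts, 3)
            )
    if len(polylines) != n_declared:
        raise TractogramFormatError(
            f"header declares {n_declared} fibers but {data_path} holds "
            f"{len(polylines)}"
        )
    if not polylines:
        raise TractogramFormatError(f"bundles file {path} contains no fibers")
    return Tractogram.from_polylines(polylines, space_note=str(attrs.get("space", "")))


def _write_bundles(t: Tractogram, path: str) -> None:
    attrs = {
        "binary": 1,
        "byte_order": "DCBA",
        "curves_count": len(t),
        "data_file_name": "*.bundlesdata",
        "format": "bundles_1.0",
        "space": t.space_note,
    }
    with open(path, "w") as fh:
        fh.write("attributes = " + repr(attrs) + "\n")
    with open(_bundlesdata_path(path), "wb") as fh:
        for i in range(len(t)):
            fh.write(struct.pack("<i", N_POINTS))
            fh.write(t.points[i].astype("<f4").tobytes())


def _read_array(path: str) -> Tractogram:
    try:
        arr = np.load(path)
    except Exception as exc:
        raise TractogramFormatError(f"cannot parse array file {path}: {exc}") from exc
    if arr.ndim != 3 or arr.shape[1:] != (N_POINTS, 3):
        raise TractogramFormatError(
            f"array file {path} has shape {arr.shape}, expected (n, {N_POINTS}, 3)"
        )
    return Tractogram(arr.astype(float))


def _write_array(t: Tractogram, path: str) -> None:
    np.save(path, t.points.astype(np.float32))
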