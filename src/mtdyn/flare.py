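"""Protofilament-shape metrics for traced microtubule ends.

Operates on ordered 3D polylines (nm), one per protofilament, root (inside
the microtubule wall) to tip. Per protofilament it finds the wall-exit
point (the first point deviating from the axis direction by more than a
straightness tolerance), the flared length (from the last in-wall segment
to the tip) and the mean local curvature of the flare; per microtubule end
it reports the s.d. of flared lengths, the mean curvature and the
raggedness (s.d. of wall-exit axial positions). All metrics are invariant
under rigid motion of the whole end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Default straightness tolerance for the wall-exit search, degrees.
DEFAULT_STRAIGHTNESS_TOL = 10.0


@dataclass
class ProtofilamentTrace:
    """Ordered 3D polyline of one protofilament, root to tip, in nm."""

    points: np.ndarray  # (N, 3)
    mt_id: str = "mt0"
    pf_id: str = "pf0"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (N, 3) array")
        if self.points.shape[0] < 2:
            raise ValueError("a trace needs at least 2 points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValueError("consecutive trace points must be distinct")


@dataclass
class MTEndGeometry:
    """Flare metrics for one microtubule end."""

    mt_id: str
    per_pf: pd.DataFrame  # pf_id, wall_exit_index, wall_exit_axial_nm, flared_length_nm, mean_curvature_deg_per_nm
    length_sd_nm: float
    raggedness_nm: float | None
    mean_curvature_deg_per_nm: float | None
    n_pf: int
    polarity: str = "plus"  # supplied label, not computed
    corked: bool | None = None


# ---------------------------------------------------------------------------
# Contour file format
# ---------------------------------------------------------------------------
# MT <id> <n_pf> <polarity>
# PF <id>
# x_nm y_nm z_nm          (one point per line, root -> tip)

def write_contours(path, ends: list[tuple[str, str, list[ProtofilamentTrace]]]) -> None:
    """Write microtubule ends to the plain-text contour format.

    ``ends`` is a list of ``(mt_id, polarity, traces)`` tuples.
    """
    with open(path, "w") as fh:
        for mt_id, polarity, traces in ends:
            fh.write(f"MT {mt_id} {len(traces)} {polarity}\n")
            for tr in traces:
                fh.write(f"PF {tr.pf_id}\n")
                for p in tr.points:
                    fh.write(f"{p[0]:.4f} {p[1]:.4f} {p[2]:.4f}\n")


def read_contours(path) -> list[tuple[str, str, list[ProtofilamentTrace]]]:
    """Parse a contour file into ``(mt_id, polarity, traces)`` groups.

    Malformed lines raise with the offending line number.
    """
    ends: list[tuple[str, str, list[ProtofilamentTrace]]] = []
    mt_id = polarity = pf_id = None
    declared_n = 0
    traces: list[ProtofilamentTrace] = []
    points: list[list[float]] = []

    def flush_pf(lineno):
        nonlocal points, pf_id
        if pf_id is not None:
            if len(points) < 2:
                raise ValueError(
                    f"line {lineno}: protofilament {pf_id!r} of {mt_id!r} has "
                    f"{len(points)} point(s); need at least 2"
                )
            traces.append(
                ProtofilamentTrace(points=np.array(points), mt_id=mt_id, pf_id=pf_id)
            )
        points = []
        pf_id = None

    def flush_mt(lineno):
        nonlocal traces, mt_id, polarity
        flush_pf(lineno)
        if mt_id is not None:
            if declared_n and len(traces) != declared_n:
                raise ValueError(
                    f"line {lineno}: MT {mt_id!r} declares {declared_n} "
                    f"protofilaments but contains {len(traces)}"
                )
            ends.append((mt_id, polarity, traces))
        traces = []
        mt_id = None

    with open(path) as fh:
        lines = fh.readlines()
    if not any(line.strip() for line in lines):
        raise ValueError(f"{path}: empty contour file")
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if fields[0] == "MT":
            if len(fields) != 4:
                raise ValueError(f"line {lineno}: malformed MT header: {line!r}")
            flush_mt(lineno)
            mt_id, polarity = fields[1], fields[3]
            try:
                declared_n = int(fields[2])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: bad protofilament count") from exc
        elif fields[0] == "PF":
            if mt_id is None:
                raise ValueError(f"line {lineno}: PF before any MT header")
            flush_pf(lineno)
            pf_id = fields[1] if len(fields) > 1 else f"pf{len(traces)}"
        else:
            if pf_id is None:
                raise ValueError(f"line {lineno}: coordinates outside a PF block")
            if len(fields) != 3:
                raise ValueError(f"line {lineno}: expected 'x y z', got {line!r}")
            try:
                points.append([float(v) for v in fields])
            except ValueError as exc:
                raise ValueError(
                    f"line {lineno}: non-numeric coordinate in {line!r}"
                ) from exc
    flush_mt(len(lines))
    return ends


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def estimate_axis(traces: list[ProtofilamentTrace]) -> np.ndarray:
    """Microtubule axis as the principal direction of all trace points.

    The wall segments dominate the point cloud, so the first principal
    component tracks the axis; the sign is oriented root→tip.
    """
    pts = np.vstack([tr.points for tr in traces])
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    # orient toward the tips: tips should project higher than roots
    score = sum(
        float((tr.points[-1] - tr.points[0]) @ axis) for tr in traces
    )
    return axis if score >= 0 else -axis


def find_wall_exit(
    trace: ProtofilamentTrace,
    mt_axis: np.ndarray,
    straightness_tol: float = DEFAULT_STRAIGHTNESS_TOL,
) -> int:
    """Index of the first point where the trace deviates from straight.

    A point deviates when the direction of the segment leaving it makes
    more than ``straightness_tol`` degrees with the microtubule axis. A
    fully straight (blunt) trace returns its last index.
    """
    axis = np.asarray(mt_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    if trace.points.shape[0] < 3:
        return trace.points.shape[0] - 1
    seg = np.diff(trace.points, axis=0)
    seg = seg / np.linalg.norm(seg, axis=1, keepdims=True)
    cosang = np.clip(seg @ axis, -1.0, 1.0)
    angles = np.degrees(np.arccos(cosang))
    off = np.flatnonzero(angles > straightness_tol)
    if off.size == 0:
        return trace.points.shape[0] - 1
    return int(off[0])


def flared_length(trace: ProtofilamentTrace, wall_exit_index: int) -> float:
    """Flared length in nm: from the last in-wall segment to the tip.

    Sums Euclidean segment lengths starting at the segment that ends at
    the wall-exit point (the last segment within the wall) through the
    final point of the trace.
    """
    n = trace.points.shape[0]
    if not 0 <= wall_exit_index < n:
        raise ValueError("wall_exit_index out of range")
    start = max(wall_exit_index - 1, 0)
    seg = np.diff(trace.points[start:], axis=0)
    return float(np.linalg.norm(seg, axis=1).sum())


def local_curvature(
    trace: ProtofilamentTrace, wall_exit_index: int
) -> tuple[np.ndarray, float | None]:
    """Per-vertex local curvature of the flare, deg/nm, and its mean.

    At each interior vertex beyond the wall exit, curvature is the
    turning angle between the adjacent segments divided by their mean
    length. Flares with fewer than 3 points have no curvature (None).
    """
    pts = trace.points[wall_exit_index:]
    if pts.shape[0] < 3:
        return np.array([]), None
    d = np.diff(pts, axis=0)
    lens = np.linalg.norm(d, axis=1)
    u = d / lens[:, None]
    cosang = np.clip(np.einsum("ij,ij->i", u[:-1], u[1:]), -1.0, 1.0)
    turn_deg = np.degrees(np.arccos(cosang))
    mean_len = 0.5 * (lens[:-1] + lens[1:])
    curv = turn_deg / mean_len
    return curv, float(curv.mean())


def raggedness(
    wall_exit_points: np.ndarray, mt_axis: np.ndarray
) -> float | None:
    """S.d. (n−1) of wall-exit axial positions projected on the axis, nm.

    Needs at least 3 protofilaments; otherwise the metric is absent.
    """
    pts = np.asarray(wall_exit_points, dtype=float)
    if pts.shape[0] < 3:
        return None
    axis = np.asarray(mt_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    axial = pts @ axis
    return float(np.std(axial, ddof=1))


def summarize_end(
    traces: list[ProtofilamentTrace],
    mt_axis: np.ndarray | None = None,
    straightness_tol: float = DEFAULT_STRAIGHTNESS_TOL,
    polarity: str = "plus",
    corked: bool | None = None,
) -> MTEndGeometry:
    """Per-protofilament and per-end flare metrics for one microtubule.

    The axis is supplied or estimated from the traces. Per-end curvature
    is the unweighted mean of the per-protofilament means; length s.d.
    and raggedness use the n−1 denominator.
    """
    if len(traces) < 3:
        raise ValueError("need at least 3 protofilament traces per end")
    axis = estimate_axis(traces) if mt_axis is None else np.asarray(mt_axis, float)
    axis = axis / np.linalg.norm(axis)

    rows = []
    exits = []
    for tr in traces:
        k = find_wall_exit(tr, axis, straightness_tol)
        length = flared_length(tr, k)
        _, mean_curv = local_curvature(tr, k)
        exits.append(tr.points[k])
        rows.append(
            {
                "pf_id": tr.pf_id,
                "wall_exit_index": k,
                "wall_exit_axial_nm": float(tr.points[k] @ axis),
                "flared_length_nm": length,
                "mean_curvature_deg_per_nm": mean_curv,
            }
        )
    per_pf = pd.DataFrame(rows)
    lengths = per_pf["flared_length_nm"].to_numpy()
    curvs = per_pf["mean_curvature_deg_per_nm"].dropna().to_numpy()
    mt_id = traces[0].mt_id
    return MTEndGeometry(
        mt_id=mt_id,
        per_pf=per_pf,
        length_sd_nm=float(np.std(lengths, ddof=1)),
        raggedness_nm=raggedness(np.array(exits), axis),
        mean_curvature_deg_per_nm=float(curvs.mean()) if curvs.size else None,
        n_pf=len(traces),
        polarity=polarity,
        corked=corked,
    )


def summarize_ends_table(
    ends: list[tuple[str, str, list[ProtofilamentTrace]]],
    straightness_tol: float = DEFAULT_STRAIGHTNESS_TOL,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-protofilament and per-MT metric tables for a contour dataset."""
    pf_rows, mt_rows = [], []
    for mt_id, polarity, traces in ends:
        geom = summarize_end(traces, straightness_tol=straightness_tol, polarity=polarity)
        df = geom.per_pf.copy()
        df.insert(0, "mt_id", mt_id)
        pf_rows.append(df)
        mt_rows.append(
            {
                "mt_id": mt_id,
                "polarity": polarity,
                "n_pf": geom.n_pf,
                "length_sd_nm": geom.length_sd_nm,
                "raggedness_nm": geom.raggedness_nm,
                "mean_curvature_deg_per_nm": geom.mean_curvature_deg_per_nm,
            }
        )
    return pd.concat(pf_rows, ignore_index=True), pd.DataFrame(mt_rows)
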