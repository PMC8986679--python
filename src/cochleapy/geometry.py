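"""Cochlear-view geometry: A/B diameters, CDL estimation, contact metrics.

This module turns labeled 3D landmarks into the scalar quantities used by
otological planning software:

* the *cochlear view* — the oblique plane containing the basal turn, fitted
  by total least squares to the round window, the modiolus and the
  basal-turn lateral-wall points;
* the **A-value** (cochlear diameter): distance from the round window,
  along a line passing the modiolus, to the farthest point of the opposite
  lateral wall, measured in the cochlear-view plane;
* the **B-value** (cochlear width): wall-to-wall distance perpendicular to
  A, through the modiolus;
* **CDL_OC**, the cochlear duct length along the organ of Corti, from the
  elliptic circular approximation of A and B plus a fixed hook-region
  length;
* electrode **insertion depths** (cumulative polyline length from the
  round window through the contact chain) and **inter-electrode
  distances** (Euclidean distances between consecutive contact centers).

Lengths are millimetres throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import (
    ContactCountError,
    DegenerateGeometryError,
    InsufficientLandmarksError,
    ParameterError,
)
from .landmarks import LandmarkSet

#: Length of the hook region — the most basal portion of the organ of Corti
#: preceding the round-window-centered spiral — added to the elliptic
#: circular approximation.
HOOK_LENGTH_MM = 1.58

EQUATION_MODES = ("as_printed", "grouped")

N_CONTACTS = 12


# ---------------------------------------------------------------------------
# CDL estimation
# ---------------------------------------------------------------------------

def cdl_oc(
    A: float,
    B: float,
    include_hook: bool = True,
    mode: str = "as_printed",
) -> float:
    """Cochlear duct length along the organ of Corti from diameters A and B.

    The elliptic circular approximation combines the cochlear diameter
    ``A`` and width ``B`` (mm) into a duct-length estimate.  Two algebraic
    groupings of the published expression are supported:

    ``as_printed``
        ``1.71 * (1.18*A + 2.69*B) - 0.18*sqrt(0.72*A*B)`` — the literal
        reading, where the 0.18 factor applies only to the root term.
    ``grouped``
        ``1.71 * ((1.18*A + 2.69*B) - sqrt(0.72*A*B))`` — the alternative
        grouping in which the 1.71 factor distributes over both terms.

    When ``include_hook`` is true the fixed hook-region length of
    1.58 mm is added; the hook term is exactly additive in both modes.

    Parameters
    ----------
    A, B : float
        Cochlear diameter and width in mm; must be non-negative.
    include_hook : bool
        Add the 1.58 mm hook-region length.
    mode : {"as_printed", "grouped"}
        Algebraic grouping of the approximation (see above).

    Returns
    -------
    float
        Estimated CDL_OC in mm.
    """
    if mode not in EQUATION_MODES:
        raise ParameterError(f"unknown equation mode {mode!r}; use one of {EQUATION_MODES}")
    A = float(A)
    B = float(B)
    if A < 0 or B < 0:
        raise ParameterError(f"A and B must be non-negative, got A={A}, B={B}")
    linear = 1.18 * A + 2.69 * B
    root = np.sqrt(0.72 * A * B)
    if mode == "as_printed":
        length = 1.71 * linear - 0.18 * root
    else:
        length = 1.71 * (linear - root)
    if include_hook:
        length += HOOK_LENGTH_MM
    return float(length)


# ---------------------------------------------------------------------------
# Cochlear-view plane
# ---------------------------------------------------------------------------

@dataclass
class CochlearViewFrame:
    """Orthonormal frame of the fitted cochlear-view plane.

    ``origin`` is the modiolus projected onto the plane; ``u`` points from
    the origin toward the projected round window; ``v = normal x u``
    completes a right-handed in-plane basis with ``normal = u x v``.
    """

    origin: np.ndarray
    normal: np.ndarray
    u: np.ndarray
    v: np.ndarray

    @property
    def in_plane_axes(self) -> tuple[np.ndarray, np.ndarray]:
        return self.u, self.v

    def project(self, points: np.ndarray) -> np.ndarray:
        """In-plane 2D coordinates (mm) of 3D points."""
        d = np.atleast_2d(points) - self.origin
        return np.column_stack([d @ self.u, d @ self.v])

    def lift(self, xy: np.ndarray) -> np.ndarray:
        """Map in-plane 2D coordinates back to 3D points on the plane."""
        xy = np.atleast_2d(xy)
        return self.origin + np.outer(xy[:, 0], self.u) + np.outer(xy[:, 1], self.v)


def _tls_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares plane: returns (centroid, unit normal)."""
    centroid = points.mean(axis=0)
    centered = points - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] <= 1e-12 * max(s[0], 1.0):
        raise DegenerateGeometryError(
            "landmarks are collinear; the cochlear-view plane is undetermined"
        )
    return centroid, vt[2]


def _first_turn_mask(wall_2d: np.ndarray) -> np.ndarray:
    """Boolean mask of wall points within the first full turn (by order).

    Winding is accumulated around the 2D origin (the projected modiolus)
    starting from the first (most basal) wall point.
    """
    ang = np.unwrap(np.arctan2(wall_2d[:, 1], wall_2d[:, 0]))
    return np.abs(ang - ang[0]) <= 2.0 * np.pi + 1e-9


def fit_cochlear_view(landmarks: LandmarkSet) -> CochlearViewFrame:
    """Fit the cochlear-view plane to one landmark set.

    The plane is the total-least-squares fit through the round window, the
    modiolus, and the lateral-wall points of the first full turn (selected
    by accumulated winding about the modiolus in a provisional all-point
    fit).  The frame origin is the modiolus projection; the first in-plane
    axis points toward the projected round window; the normal is oriented
    so the basal turn winds counter-clockwise.

    Raises
    ------
    DegenerateGeometryError
        If the landmarks are collinear or the round window projects onto
        the modiolus.
    InsufficientLandmarksError
        If fewer than three wall points are present.
    """
    if len(landmarks.wall) < 3:
        raise InsufficientLandmarksError(
            f"need at least 3 wall landmarks to fit the cochlear view, "
            f"got {len(landmarks.wall)}"
        )
    pts_all = np.vstack(
        [landmarks.round_window[None, :], landmarks.modiolus[None, :], landmarks.wall]
    )
    centroid0, normal0 = _tls_plane(pts_all)

    # Provisional frame to select the basal (first) turn by winding order.
    u0 = landmarks.wall[0] - landmarks.modiolus
    u0 = u0 - (u0 @ normal0) * normal0
    if np.linalg.norm(u0) <= 1e-9:
        raise DegenerateGeometryError("first wall point projects onto the modiolus")
    u0 /= np.linalg.norm(u0)
    v0 = np.cross(normal0, u0)
    rel = landmarks.wall - (landmarks.modiolus - ((landmarks.modiolus - centroid0) @ normal0) * normal0)
    wall2 = np.column_stack([rel @ u0, rel @ v0])
    mask = _first_turn_mask(wall2)

    pts = np.vstack(
        [
            landmarks.round_window[None, :],
            landmarks.modiolus[None, :],
            landmarks.wall[mask],
        ]
    )
    centroid, normal = _tls_plane(pts)

    origin = landmarks.modiolus - ((landmarks.modiolus - centroid) @ normal) * normal
    u = landmarks.round_window - origin
    u = u - (u @ normal) * normal
    nu = np.linalg.norm(u)
    if nu <= 1e-9:
        raise DegenerateGeometryError(
            "round window projects onto the modiolus; in-plane axis undefined"
        )
    u /= nu
    v = np.cross(normal, u)

    # Orient the normal so the basal turn winds counter-clockwise in (u, v).
    rel = landmarks.wall[mask] - origin
    w2 = np.column_stack([rel @ u, rel @ v])
    winding = np.sum(np.diff(np.unwrap(np.arctan2(w2[:, 1], w2[:, 0]))))
    if winding < 0:
        normal = -normal
        v = -v
    return CochlearViewFrame(origin=origin, normal=normal, u=u, v=v)


# ---------------------------------------------------------------------------
# A / B measurement
# ---------------------------------------------------------------------------

@dataclass
class ABMeasurement:
    """Measured cochlear diameter (A) and width (B) with their endpoints.

    Endpoints are 3D points lying on the cochlear-view plane.
    """

    A: float
    B: float
    a_endpoints: np.ndarray  # (2, 3): round window, opposite wall point
    b_endpoints: np.ndarray  # (2, 3): wall intersections of the B-line


def _line_polyline_crossings(
    poly: np.ndarray, origin: np.ndarray, direction: np.ndarray
) -> list[tuple[float, int]]:
    """Ordered crossings of a 2D polyline with the line through ``origin``
    along unit ``direction``.

    Returns ``(s, segment_index)`` pairs where ``s`` is the along-line
    coordinate of the crossing (mm, signed), in polyline order.  Crossings
    are linearly interpolated between adjacent vertices.
    """
    perp = np.array([-direction[1], direction[0]])
    off = (poly - origin) @ perp
    along = (poly - origin) @ direction
    hits: list[tuple[float, int]] = []
    for i in range(len(poly) - 1):
        o0, o1 = off[i], off[i + 1]
        if o0 == 0.0:
            hits.append((float(along[i]), i))
        elif o0 * o1 < 0.0:
            f = o0 / (o0 - o1)
            hits.append((float(along[i] + f * (along[i + 1] - along[i])), i))
    if len(poly) and off[-1] == 0.0:
        hits.append((float(along[-1]), len(poly) - 2))
    return hits


def measure_ab(
    landmarks: LandmarkSet,
    frame: CochlearViewFrame | None = None,
) -> ABMeasurement:
    """Measure the cochlear diameter A and width B in the cochlear view.

    All landmarks are projected into the cochlear-view plane.  The A-line
    is the straight line from the projected round window passing through
    the projected modiolus; A is the distance from the round window to the
    farthest crossing of that line with the lateral-wall polyline beyond
    the modiolus (the "furthest point on the opposite wall").

    The B-line is the line through the projected modiolus perpendicular to
    the A-line; B is the distance between its two wall crossings, one on
    each side, taking the basal-most polyline crossing per side.  All
    crossings are linearly interpolated between adjacent wall samples.

    Raises
    ------
    InsufficientLandmarksError
        If fewer than 4 wall points lie on either side of the A-line, or
        a required wall crossing is absent.
    DegenerateGeometryError
        If the round window projects onto the modiolus.
    """
    if frame is None:
        frame = fit_cochlear_view(landmarks)
    rw = frame.project(landmarks.round_window)[0]
    mod = frame.project(landmarks.modiolus)[0]
    wall = frame.project(landmarks.wall)

    s_mod = np.linalg.norm(mod - rw)
    if s_mod <= 1e-9:
        raise DegenerateGeometryError(
            "round window coincides with the modiolus; A-line undefined"
        )
    a_dir = (mod - rw) / s_mod

    crossings = _line_polyline_crossings(wall, rw, a_dir)
    far_s = [s for s, _ in crossings if s > s_mod]
    if not far_s:
        raise InsufficientLandmarksError(
            "wall polyline does not cross the A-line beyond the modiolus"
        )
    A = float(max(far_s))
    far = rw + A * a_dir

    # Side counts relative to the A-line (through rw along a_dir).
    perp = np.array([-a_dir[1], a_dir[0]])
    side = (wall - rw) @ perp
    if (side > 0).sum() < 4 or (side < 0).sum() < 4:
        raise InsufficientLandmarksError(
            "need at least 4 wall points on each side of the A-line, got "
            f"{(side > 0).sum()} / {(side < 0).sum()}"
        )

    # B-line: through the modiolus, perpendicular to A.  Take the first
    # (basal-most) polyline crossing on each side of the modiolus.
    b_hits: dict[int, float] = {}
    for t, _ in _line_polyline_crossings(wall, mod, perp):
        sign = int(np.sign(t))
        if sign != 0 and sign not in b_hits:
            b_hits[sign] = t
        if len(b_hits) == 2:
            break
    if len(b_hits) < 2:
        raise InsufficientLandmarksError(
            "wall polyline does not cross the B-line on both sides of the modiolus"
        )
    B = float(b_hits[1] - b_hits[-1])

    a_end = frame.lift(np.vstack([rw, far]))
    b_end = frame.lift(
        np.vstack([mod + b_hits[1] * perp, mod + b_hits[-1] * perp])
    )
    return ABMeasurement(A=A, B=B, a_endpoints=a_end, b_endpoints=b_end)


# ---------------------------------------------------------------------------
# Electrode contact metrics
# ---------------------------------------------------------------------------

def _require_contacts(landmarks: LandmarkSet) -> np.ndarray:
    n = 0 if landmarks.contacts is None else len(landmarks.contacts)
    if n != N_CONTACTS:
        raise ContactCountError(n, landmarks.subject_id)
    return landmarks.contacts


def insertion_depths(landmarks: LandmarkSet) -> np.ndarray:
    """Cumulative polyline length (mm) from the round window through each
    of the 12 contact centers, basal to apical."""
    contacts = _require_contacts(landmarks)
    chain = np.vstack([landmarks.round_window[None, :], contacts])
    steps = np.linalg.norm(np.diff(chain, axis=0), axis=1)
    return np.cumsum(steps)


def inter_electrode_distances(landmarks: LandmarkSet) -> np.ndarray:
    """Euclidean distances (mm) between the 11 consecutive contact pairs."""
    contacts = _require_contacts(landmarks)
    return np.linalg.norm(np.diff(contacts, axis=0), axis=1)


# ---------------------------------------------------------------------------
# Per-observation measurement record
# ---------------------------------------------------------------------------

@dataclass
class MeasurementRecord:
    """Derived scalar measurements for one observation."""

    subject_id: str
    group: int
    modality: str
    series: int
    A: float
    B: float
    cdl_oc: float
    equation_mode: str
    insertion_depths: np.ndarray | None = None
    ieds: np.ndarray | None = None

    @property
    def mean_ied(self) -> float | None:
        return None if self.ieds is None else float(np.mean(self.ieds))


def measure(
    landmarks: LandmarkSet,
    equation_mode: str = "as_printed",
    include_hook: bool = True,
) -> MeasurementRecord:
    """Full measurement of one landmark set: A, B, CDL_OC and, when contact
    landmarks are present, insertion depths and inter-electrode distances."""
    frame = fit_cochlear_view(landmarks)
    ab = measure_ab(landmarks, frame)
    depths = ieds = None
    if landmarks.has_contacts:
        depths = insertion_depths(landmarks)
        ieds = inter_electrode_distances(landmarks)
    return MeasurementRecord(
        subject_id=landmarks.subject_id,
        group=landmarks.group,
        modality=landmarks.modality,
        series=landmarks.series,
        A=ab.A,
        B=ab.B,
        cdl_oc=cdl_oc(ab.A, ab.B, include_hook=include_hook, mode=equation_mode),
        equation_mode=equation_mode,
        insertion_depths=depths,
        ieds=ieds,
    )
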