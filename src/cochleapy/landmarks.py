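"""Labeled 3D landmark sets and their CSV interchange format.

A :class:`LandmarkSet` holds the points an examiner would place on one scan
of one ear: the round window, the modiolus, an ordered run of lateral-wall
points (basal to apical), and — on post-operative scans — the twelve
electrode-contact centers.  All coordinates are millimetres.

The on-disk format is a flat CSV with one point per row::

    subject_id, group, modality, series, structure, point_index, x_mm, y_mm, z_mm

where ``structure`` is one of ``round_window``, ``modiolus``, ``wall``,
``contact`` and ``point_index`` orders points within a structure
(basal to apical for walls and contacts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STRUCTURES = ("round_window", "modiolus", "wall", "contact")

CSV_COLUMNS = [
    "subject_id",
    "group",
    "modality",
    "series",
    "structure",
    "point_index",
    "x_mm",
    "y_mm",
    "z_mm",
]


@dataclass
class LandmarkSet:
    """Observed landmarks for one subject x modality x test series.

    Parameters
    ----------
    subject_id : str
        Subject identifier.
    group : int
        Study group (1, 2 or 3).
    modality : str
        Imaging modality name, e.g. ``"MSCT"``.
    series : int
        Test-series index (1-based).
    round_window : (3,) ndarray
        Round-window point, mm.
    modiolus : (3,) ndarray
        Modiolus point, mm.
    wall : (n, 3) ndarray
        Lateral-wall points ordered basal to apical, mm.
    contacts : (12, 3) ndarray or None
        Electrode-contact centers ordered basal to apical, mm; ``None``
        for non-implanted ears.
    rigid_transform : (R, t) or None
        The rigid map applied to all points at observation time, recorded
        so that simulation studies remain auditable.  ``R`` is a 3x3
        rotation, ``t`` a translation vector.
    """

    subject_id: str
    group: int
    modality: str
    series: int
    round_window: np.ndarray
    modiolus: np.ndarray
    wall: np.ndarray
    contacts: np.ndarray | None = None
    rigid_transform: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.round_window = np.asarray(self.round_window, dtype=float).reshape(3)
        self.modiolus = np.asarray(self.modiolus, dtype=float).reshape(3)
        self.wall = np.asarray(self.wall, dtype=float).reshape(-1, 3)
        if self.contacts is not None:
            self.contacts = np.asarray(self.contacts, dtype=float).reshape(-1, 3)

    @property
    def has_contacts(self) -> bool:
        return self.contacts is not None and len(self.contacts) > 0

    def key(self) -> tuple[str, int, str, int]:
        return (self.subject_id, self.group, self.modality, self.series)

    def to_frame(self) -> pd.DataFrame:
        """Flatten to the one-point-per-row CSV table."""
        rows: list[tuple] = []

        def emit(structure: str, pts: np.ndarray) -> None:
            for i, p in enumerate(np.atleast_2d(pts)):
                rows.append(
                    (
                        self.subject_id,
                        self.group,
                        self.modality,
                        self.series,
                        structure,
                        i,
                        p[0],
                        p[1],
                        p[2],
                    )
                )

        emit("round_window", self.round_window)
        emit("modiolus", self.modiolus)
        emit("wall", self.wall)
        if self.has_contacts:
            emit("contact", self.contacts)
        return pd.DataFrame(rows, columns=CSV_COLUMNS)


def landmarks_to_frame(landmark_sets: list[LandmarkSet]) -> pd.DataFrame:
    """Concatenate many landmark sets into one CSV table."""
    if not landmark_sets:
        return pd.DataFrame(columns=CSV_COLUMNS)
    return pd.concat([ls.to_frame() for ls in landmark_sets], ignore_index=True)


def write_landmarks_csv(landmark_sets: list[LandmarkSet], path) -> None:
    landmarks_to_frame(landmark_sets).to_csv(path, index=False)


def frame_to_landmarks(df: pd.DataFrame) -> list[LandmarkSet]:
    """Group a flat landmark table back into :class:`LandmarkSet` objects.

    Raises
    ------
    ValueError
        If the header is malformed or a structure label is unknown.
    """
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"landmark table is missing columns: {missing}")
    bad = set(df["structure"].unique()) - set(STRUCTURES)
    if bad:
        raise ValueError(f"unknown landmark structure labels: {sorted(bad)}")

    out: list[LandmarkSet] = []
    for (subj, group, modality, series), sub in df.groupby(
        ["subject_id", "group", "modality", "series"], sort=True
    ):
        def pts(structure: str) -> np.ndarray:
            block = sub[sub["structure"] == structure].sort_values("point_index")
            return block[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)

        rw = pts("round_window")
        mod = pts("modiolus")
        if len(rw) != 1 or len(mod) != 1:
            raise ValueError(
                f"subject {subj!r} {modality}/{series}: need exactly one "
                f"round_window and one modiolus point"
            )
        contacts = pts("contact")
        out.append(
            LandmarkSet(
                subject_id=str(subj),
                group=int(group),
                modality=str(modality),
                series=int(series),
                round_window=rw[0],
                modiolus=mod[0],
                wall=pts("wall"),
                contacts=contacts if len(contacts) else None,
            )
        )
    return out


def read_landmarks_csv(path) -> list[LandmarkSet]:
    return frame_to_landmarks(pd.read_csv(path))
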