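"""Named 2D landmark sets and their CSV/JSON serialization."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Landmark names every template must provide (superset allowed).
REQUIRED_LANDMARKS = frozenset(
    {
        "S", "N", "A", "B", "Pog", "Gn", "Me", "Go", "Ar", "Po", "Or",
        "ANS", "PNS", "U1_tip", "U1_apex", "L1_tip", "L1_apex", "Pt",
    }
)


class MissingLandmarkError(KeyError):
    """A measurement referenced a landmark not present in the set."""


@dataclass
class LandmarkSet:
    """Named 2D points (mm) for one subject. x anterior-positive, y superior-positive."""

    points: dict[str, np.ndarray]
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        self.points = {k: np.asarray(v, dtype=float) for k, v in self.points.items()}

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.points[name]
        except KeyError:
            raise MissingLandmarkError(
                f"landmark {name!r} missing for subject {self.subject_id!r}"
            ) from None

    def names(self) -> set[str]:
        return set(self.points)

    def transformed(self, rotation_deg: float = 0.0, translation=(0.0, 0.0),
                    scale: float = 1.0) -> "LandmarkSet":
        """Return a rigidly moved (and optionally uniformly scaled) copy."""
        th = np.radians(rotation_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        t = np.asarray(translation, dtype=float)
        return LandmarkSet(
            {k: scale * (rot @ v) + t for k, v in self.points.items()},
            subject_id=self.subject_id,
        )


def landmark_sets_to_frame(sets: Iterable[LandmarkSet]) -> pd.DataFrame:
    rows = [
        {"subject_id": s.subject_id, "landmark": name, "x": float(p[0]), "y": float(p[1])}
        for s in sets
        for name, p in s.points.items()
    ]
    return pd.DataFrame(rows, columns=["subject_id", "landmark", "x", "y"])


def write_landmarks_csv(sets: Iterable[LandmarkSet], path) -> None:
    landmark_sets_to_frame(sets).to_csv(path, index=False)


def read_landmarks_csv(path) -> list[LandmarkSet]:
    df = pd.read_csv(path)
    expected = {"subject_id", "landmark", "x", "y"}
    if not expected.issubset(df.columns):
        raise ValueError(f"landmark CSV must have columns {sorted(expected)}")
    out = []
    for sid, grp in df.groupby("subject_id", sort=False):
        pts = {str(r.landmark): np.array([r.x, r.y]) for r in grp.itertuples()}
        out.append(LandmarkSet(pts, subject_id=str(sid)))
    return out


def write_landmarks_json(sets: Iterable[LandmarkSet], path) -> None:
    payload = {
        s.subject_id: {k: [float(v[0]), float(v[1])] for k, v in s.points.items()}
        for s in sets
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_landmarks_json(path) -> list[LandmarkSet]:
    payload = json.loads(Path(path).read_text())
    return [
        LandmarkSet({k: np.asarray(v, float) for k, v in pts.items()}, subject_id=sid)
        for sid, pts in payload.items()
    ]
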