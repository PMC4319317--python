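"""Corallite landmark configurations: reading, validation and scaling.

A corallite is digitized as 28 (optionally 29) X-Y points in pixel
units: odd indices 1..23 are septum/calice-wall junctions (outer ring),
even indices 2..24 the pali / inner septal tips (inner ring), starting
at the dorsal directive and proceeding clockwise; 25-28 are the two
septum-width point pairs. Three discrete characters accompany each
corallite: number of pali (NP), number of radi (NR) and the state of
the ventral triplet (fused / free / trident).

Pixel coordinates are converted to millimetres with a per-image scale
factor obtained from a size reference of known thickness (default
0.16 mm monofilament line).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkSet",
    "calibrate",
    "read_landmarks",
    "TRIPLET_STATES",
    "TRIPLET_CODE",
]

TRIPLET_STATES = ("fused", "trident", "free")
# ordered numeric encoding (increasing separation of the triplet)
TRIPLET_CODE = {"fused": 0, "trident": 1, "free": 2}

REQUIRED_POINTS = tuple(range(1, 29))


@dataclass
class LandmarkSet:
    """One corallite's digitized landmarks plus discrete characters."""

    corallite_id: str
    specimen_id: str
    region: str
    species: str
    points: dict = field(default_factory=dict)  # index -> (x, y) in px
    scale_mm_per_px: float = np.nan
    n_pali: int = 0
    n_radi: int = 0
    triplet_state: str = "fused"

    def __post_init__(self):
        idx = sorted(self.points)
        missing = [i for i in REQUIRED_POINTS if i not in self.points]
        if missing:
            raise ValueError(
                f"corallite {self.corallite_id!r}: missing landmark indices {missing}"
            )
        if len(idx) != len(set(idx)):
            raise ValueError(f"corallite {self.corallite_id!r}: duplicate point index")
        if not (self.scale_mm_per_px > 0):
            raise ValueError(
                f"corallite {self.corallite_id!r}: missing or non-positive scale; "
                "derive one with calibrate(reference_px_length, reference_mm)"
            )
        if self.triplet_state not in TRIPLET_CODE:
            raise ValueError(
                f"corallite {self.corallite_id!r}: triplet_state must be one of "
                f"{TRIPLET_STATES}"
            )

    def point_mm(self, i: int) -> np.ndarray:
        """Landmark ``i`` in millimetres."""
        return np.asarray(self.points[i], dtype=float) * self.scale_mm_per_px

    @property
    def triplet_code(self) -> int:
        return TRIPLET_CODE[self.triplet_state]


def calibrate(reference_px_length: float, reference_mm: float = 0.16) -> float:
    """Scale factor (mm/px) from a size reference of known thickness."""
    if reference_px_length <= 0 or reference_mm <= 0:
        raise ValueError("reference lengths must be positive")
    return reference_mm / reference_px_length


_META_COLS = [
    "corallite_id",
    "specimen_id",
    "region",
    "species",
    "scale_mm_per_px",
    "n_pali",
    "n_radi",
    "triplet_state",
]


def read_landmarks(path) -> list[LandmarkSet]:
    """Read a long-format landmark table (one row per digitized point).

    Required columns: corallite_id, specimen_id, region, species,
    point, x, y, scale_mm_per_px, n_pali, n_radi, triplet_state (the
    per-corallite columns repeated on every row of that corallite).
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    need = set(_META_COLS + ["point", "x", "y"])
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for cid, sub in df.groupby("corallite_id", sort=False):
        if sub["point"].duplicated().any():
            dups = sorted(sub.loc[sub["point"].duplicated(), "point"].unique())
            raise ValueError(f"corallite {cid!r}: duplicate point index {dups}")
        meta = sub.iloc[0]
        if pd.isna(meta["scale_mm_per_px"]):
            raise ValueError(
                f"corallite {cid!r}: missing scale; derive one with "
                "calibrate(reference_px_length, reference_mm)"
            )
        out.append(
            LandmarkSet(
                corallite_id=str(cid),
                specimen_id=str(meta["specimen_id"]),
                region=str(meta["region"]),
                species=str(meta["species"]),
                points={
                    int(r.point): (float(r.x), float(r.y)) for r in sub.itertuples()
                },
                scale_mm_per_px=float(meta["scale_mm_per_px"]),
                n_pali=int(meta["n_pali"]),
                n_radi=int(meta["n_radi"]),
                triplet_state=str(meta["triplet_state"]),
            )
        )
    return out


def landmarks_to_frame(sets: list[LandmarkSet]) -> pd.DataFrame:
    """Inverse of read_landmarks: long-format table for serialization."""
    rows = []
    for lm in sets:
        for i in sorted(lm.points):
            rows.append(
                {
                    "corallite_id": lm.corallite_id,
                    "specimen_id": lm.specimen_id,
                    "region": lm.region,
                    "species": lm.species,
                    "point": i,
                    "x": lm.points[i][0],
                    "y": lm.points[i][1],
                    "scale_mm_per_px": lm.scale_mm_per_px,
                    "n_pali": lm.n_pali,
                    "n_radi": lm.n_radi,
                    "triplet_state": lm.triplet_state,
                }
            )
    return pd.DataFrame(rows)
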