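"""The corallite trait catalogue: 47 measured + 13 derived variables.

Measured per corallite (units mm unless noted):

* 12 septal lengths SL1..SL12 between point pairs (2k-1 : 2k);
* 2 septal widths SW1 (25:26), SW2 (27:28);
* 12 septal distances SD1..SD12 around the outer ring (1:3, 3:5, ...,
  23:1, circular);
* 12 pali distances PD1..PD12 around the inner ring (2:4, ..., 24:2);
* fossa width FL1 (20:8) and length FL2 (2:14); calice width W (7:19)
  and length L (1:13);
* areas: CA, the calice polygon over the outer (odd) ring, and FA, the
  fossa polygon over the inner (even) ring, via the shoelace formula;
* discrete: NP (number of pali), NR (number of radi), TRI (ventral
  triplet state, encoded fused=0, trident=1, free=2).

Derived: FACA = FA/CA; proportions X1..X7 and LAT from chords of the
configuration; averages APD, ASL, ASW; and the septal irregularity
IRR = sum_k |SL_k - SL_{k+1}| over the 12 septa taken circularly.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .landmarks import LandmarkSet

__all__ = [
    "LINEAR_TRAITS",
    "MEASURED_TRAITS",
    "DERIVED_TRAITS",
    "ALL_TRAITS",
    "linear_traits",
    "polygon_area",
    "area_traits",
    "derived_traits",
    "extract_traits",
    "trait_table",
    "specimen_summary",
]

_SL = {f"SL{k}": (2 * k - 1, 2 * k) for k in range(1, 13)}
_ODD = list(range(1, 24, 2))
_EVEN = list(range(2, 25, 2))
_SD = {f"SD{k}": (_ODD[k - 1], _ODD[k % 12]) for k in range(1, 13)}
_PD = {f"PD{k}": (_EVEN[k - 1], _EVEN[k % 12]) for k in range(1, 13)}
_PAIRS = {
    **_SL,
    "SW1": (25, 26),
    "SW2": (27, 28),
    **_SD,
    **_PD,
    "FL1": (20, 8),
    "FL2": (2, 14),
    "W": (7, 19),
    "L": (1, 13),
}

LINEAR_TRAITS = tuple(_PAIRS)  # 42 point-pair distances
MEASURED_TRAITS = LINEAR_TRAITS + ("FA", "CA", "NP", "NR", "TRI")  # the 47
DERIVED_TRAITS = (
    "FACA", "X1", "X2", "X3", "X4", "X5", "X6", "X7", "LAT",
    "APD", "ASL", "ASW", "IRR",
)
ALL_TRAITS = MEASURED_TRAITS + DERIVED_TRAITS


def _dist(lm: LandmarkSet, i: int, j: int) -> float:
    return float(np.linalg.norm(lm.point_mm(i) - lm.point_mm(j)))


def linear_traits(lm: LandmarkSet) -> dict:
    """The 42 linear measurements (mm). Missing points give NaN + warning."""
    out = {}
    for name, (i, j) in _PAIRS.items():
        if i in lm.points and j in lm.points:
            out[name] = _dist(lm, i, j)
        else:
            warnings.warn(
                f"corallite {lm.corallite_id!r}: point {i} or {j} missing, "
                f"{name} reported missing"
            )
            out[name] = np.nan
    return out


def polygon_area(points) -> float:
    """Shoelace area of the polygon through ``points`` in the given order."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise ValueError("a polygon needs at least 3 vertices")
    x, y = pts[:, 0], pts[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def area_traits(lm: LandmarkSet) -> dict:
    """Calice area CA (outer/odd ring) and fossa area FA (inner/even ring)."""
    ca = polygon_area([lm.point_mm(i) for i in _ODD])
    fa = polygon_area([lm.point_mm(i) for i in _EVEN])
    if fa > ca:
        warnings.warn(
            f"corallite {lm.corallite_id!r}: fossa area exceeds calice area "
            "(rings may be mislabelled)"
        )
    return {"FA": fa, "CA": ca}


def derived_traits(tv: dict, lm: LandmarkSet, irr_mode: str = "circular") -> dict:
    """Proportional and averaged variables from the measured traits.

    irr_mode "circular" (default) sums |SL_k - SL_{k+1}| over the ring;
    "all_pairs" sums |SL_i - SL_j| over all unordered septal pairs.
    """

    def safe_div(num, den, name):
        if den == 0 or np.isnan(den):
            warnings.warn(f"corallite {lm.corallite_id!r}: zero length in {name}")
            return np.nan
        return num / den

    d = lambda i, j: _dist(lm, i, j)  # noqa: E731
    sl = np.array([tv[f"SL{k}"] for k in range(1, 13)])
    out = {
        "FACA": safe_div(tv["FA"], tv["CA"], "FACA"),
        "X1": safe_div(d(20, 24) + d(4, 10), d(5, 7) + d(19, 21), "X1"),
        "X2": safe_div(d(24, 4), d(23, 3), "X2"),
        "X3": safe_div(0.5 * (tv["SW1"] + tv["SW2"]), d(1, 2) + d(13, 14), "X3"),
        "X4": safe_div(d(12, 16), d(11, 15), "X4"),
        "X5": safe_div(d(13, 14), tv["L"], "X5"),
        "X6": safe_div(d(1, 2), tv["L"], "X6"),
        "X7": safe_div(d(23, 3), tv["L"], "X7"),
        "LAT": safe_div(d(3, 5) + d(7, 9) + d(17, 19) + d(21, 23), tv["L"], "LAT"),
        "APD": float(np.mean([tv[f"PD{k}"] for k in range(1, 13)])),
        "ASL": float(np.mean(sl)),
        "ASW": float(np.mean([tv["SW1"], tv["SW2"]])),
    }
    if irr_mode == "circular":
        out["IRR"] = float(np.abs(sl - np.roll(sl, -1)).sum())
    elif irr_mode == "all_pairs":
        out["IRR"] = float(sum(abs(a - b) for k, a in enumerate(sl) for b in sl[k + 1:]))
    else:
        raise ValueError(f"unknown irr_mode {irr_mode!r}")
    return out


def extract_traits(lm: LandmarkSet, irr_mode: str = "circular") -> pd.Series:
    """Full trait vector (measured + derived) for one corallite."""
    tv = linear_traits(lm)
    tv.update(area_traits(lm))
    tv.update({"NP": lm.n_pali, "NR": lm.n_radi, "TRI": lm.triplet_code})
    tv.update(derived_traits(tv, lm, irr_mode=irr_mode))
    return pd.Series(tv, name=lm.corallite_id)[list(ALL_TRAITS)]


def trait_table(sets: list[LandmarkSet], irr_mode: str = "circular") -> pd.DataFrame:
    """Corallite-by-trait table with specimen/region/species metadata."""
    rows, meta = [], []
    for lm in sets:
        rows.append(extract_traits(lm, irr_mode=irr_mode))
        meta.append((lm.specimen_id, lm.region, lm.species))
    df = pd.DataFrame(rows)
    md = pd.DataFrame(meta, columns=["specimen_id", "region", "species"], index=df.index)
    return pd.concat([md, df], axis=1)


def specimen_summary(traits: pd.DataFrame) -> pd.DataFrame:
    """Per-specimen trait means/SDs over its corallites.

    Continuous traits get mean and SD (SD missing for a single
    corallite); TRI is summarized as the modal category code with its
    frequency. Output has one row per (specimen, trait).
    """
    if traits.empty:
        return pd.DataFrame(
            columns=["specimen_id", "region", "species", "trait", "mean", "sd", "n_corallites"]
        )
    value_cols = [c for c in traits.columns if c in ALL_TRAITS]
    recs = []
    for sid, sub in traits.groupby("specimen_id", sort=False):
        region, species = sub.iloc[0]["region"], sub.iloc[0]["species"]
        for trait in value_cols:
            vals = sub[trait].dropna()
            if trait == "TRI":
                mode = vals.mode()
                mean = float(mode.iloc[0]) if len(mode) else np.nan
                sd = float((vals == mean).mean()) if len(vals) else np.nan  # modal freq
            else:
                mean = float(vals.mean()) if len(vals) else np.nan
                sd = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
            recs.append(
                {
                    "specimen_id": sid,
                    "region": region,
                    "species": species,
                    "trait": trait,
                    "mean": mean,
                    "sd": sd,
                    "n_corallites": int(len(vals)),
                }
            )
    return pd.DataFrame(recs)
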