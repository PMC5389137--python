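"""Caliper-style cranial indices computed from landmark coordinates.

Five named interlandmark distances (total skull length, viscerocranial
length, alveolar P4-M1 tooth-row length, greatest and minimum palate
width) are measured on the original millimetre coordinates and turned
into four indices, each a ratio of log10 distances.  These indices mix
size into shape and historically fail to separate dogs from wolves; the
module exists to reproduce that negative control, including the index
PCA with fossil projection and bivariate convex-hull exports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, Delaunay, QhullError

from .formspace import FormSpacePCA
from .io import LandmarkConfiguration


@dataclass
class MeasurementScheme:
    """Named landmark pairs defining the caliper measurements."""

    measurements: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        if len(self.measurements) != len(set(self.measurements)):
            raise ValueError("measurement names must be unique")

    @classmethod
    def from_config(cls, cfg: dict) -> "MeasurementScheme":
        raw = cfg.get("measurements", cfg)
        return cls({name: tuple(pair) for name, pair in raw.items()})


#: Measurement names the four indices require.
REQUIRED = (
    "total_skull_length",
    "viscerocranial_length",
    "alveolar_p4_m1",
    "greatest_palate_width",
    "minimum_palate_width",
)

#: index name -> (numerator measurement, denominator measurement)
INDEX_DEFS = {
    "visc_total": ("viscerocranial_length", "total_skull_length"),
    "p4m1_total": ("alveolar_p4_m1", "total_skull_length"),
    "gpw_visc": ("greatest_palate_width", "viscerocranial_length"),
    "mpw_visc": ("minimum_palate_width", "viscerocranial_length"),
}


def interlandmark_distance(
    config: LandmarkConfiguration, pair: tuple[str, str]
) -> float:
    """Euclidean distance between two labelled landmarks (mm, original scale)."""
    a, b = pair
    return float(np.linalg.norm(config.subset([a])[0] - config.subset([b])[0]))


def compute_indices(
    configs: list[LandmarkConfiguration],
    groups: dict[str, str],
    scheme: MeasurementScheme,
    mode: str = "ratio_of_logs",
) -> pd.DataFrame:
    """Per-specimen log10 distances and the four cranial indices.

    ``mode='ratio_of_logs'`` computes log10(a)/log10(b) exactly as the
    indices are defined; ``'log_of_ratio'`` computes log10(a/b) as a
    documented scale-free alternative.  Configurations of the same
    specimen (replicates) are averaged at the distance level.
    """
    if mode not in ("ratio_of_logs", "log_of_ratio"):
        raise ValueError(f"unknown index mode {mode!r}")
    for name in REQUIRED:
        if name not in scheme.measurements:
            raise ValueError(f"measurement scheme lacks {name!r}")

    dists: dict[str, dict[str, list[float]]] = {}
    for c in configs:
        row = dists.setdefault(c.specimen_id, {m: [] for m in scheme.measurements})
        for m, pair in scheme.measurements.items():
            row[m].append(interlandmark_distance(c, pair))

    records = []
    for sid, row in dists.items():
        rec: dict[str, object] = {"specimen": sid, "group": groups.get(sid, "unknown")}
        mm = {m: float(np.mean(v)) for m, v in row.items()}
        for m, d in mm.items():
            if d <= 1.0:
                raise ValueError(
                    f"specimen {sid}: {m} = {d:.3g} mm; log10 would be non-positive"
                )
            rec[f"log10_{m}"] = np.log10(d)
        for idx, (num, den) in INDEX_DEFS.items():
            if mode == "ratio_of_logs":
                rec[idx] = np.log10(mm[num]) / np.log10(mm[den])
            else:
                rec[idx] = np.log10(mm[num] / mm[den])
        records.append(rec)
    return pd.DataFrame(records).set_index("specimen")


def index_pca_project(
    reference: pd.DataFrame, projected: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame | None, FormSpacePCA]:
    """Covariance PCA of the reference indices; unknowns projected afterwards."""
    cols = list(INDEX_DEFS)
    x = reference[cols].to_numpy(dtype=float)
    if np.any(x.std(axis=0) == 0):
        flat = [c for c in cols if reference[c].std() == 0]
        raise ValueError(f"constant index column(s): {flat}")
    pca = FormSpacePCA().fit(x)
    ref_scores = pd.DataFrame(
        pca.scores_, index=reference.index,
        columns=[f"PC{i + 1}" for i in range(pca.scores_.shape[1])],
    )
    proj_scores = None
    if projected is not None:
        proj_scores = pd.DataFrame(
            pca.transform(projected[cols].to_numpy(dtype=float)),
            index=projected.index, columns=ref_scores.columns,
        )
    return ref_scores, proj_scores, pca


def convex_hull_vertices(points: np.ndarray) -> np.ndarray:
    """2D convex-hull vertices in traversal order; degenerate sets pass through."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        return pts
    try:
        hull = ConvexHull(pts)
    except QhullError:  # collinear
        return pts
    return pts[hull.vertices]


def bivariate_export(
    table: pd.DataFrame, var_x: str, var_y: str
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Scatter data plus per-group convex-hull vertex lists for two variables."""
    for v in (var_x, var_y):
        if v not in table.columns:
            raise KeyError(f"variable {v!r} not in table")
    pts = table[[var_x, var_y]].copy()
    pts["group"] = table["group"]
    hulls = {
        g: convex_hull_vertices(sub[[var_x, var_y]].to_numpy(dtype=float))
        for g, sub in pts.groupby("group")
    }
    return pts, hulls


def fraction_inside_hull(points: np.ndarray, hull_points: np.ndarray) -> float:
    """Fraction of ``points`` falling inside the convex hull of ``hull_points``."""
    hull_points = np.asarray(hull_points, dtype=float)
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(hull_points) < 3:
        return 0.0
    try:
        tri = Delaunay(hull_points)
    except QhullError:
        return 0.0
    return float(np.mean(tri.find_simplex(points) >= 0))
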