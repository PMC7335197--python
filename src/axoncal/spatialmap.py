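"""Pixel tuning maps, confidence ellipses and the overlap index.

To quantify how spatially segregated C2- and B2-preferring axons are within
a field of view, every pixel of every merged axon inherits its axon's
windowed condition amplitudes and selectivity index; strongly tuned pixels
(|WSI| beyond a threshold, default 0.75) form two point clouds whose 90%
confidence ellipses (mean + covariance, chi-square scaled) are intersected.
The overlap index is the intersection area divided by the mean ellipse
area: 0 for disjoint domains, 1 for identical ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2
from shapely.geometry import Polygon

from .respstats import AxonResponse
from .segmerge import MergedAxon

__all__ = ["EllipseFit", "OverlapResult", "pixel_tuning_map",
           "fit_confidence_ellipse", "ellipse_polygon",
           "ellipse_overlap_index", "field_overlap"]


def pixel_tuning_map(axons: list[MergedAxon], responses: list[AxonResponse]
                     ) -> pd.DataFrame:
    """Per-pixel condition amplitudes and WSI inherited from the parent axon.

    Pixels claimed by more than one axon are ambiguous and excluded.
    Returns columns: row, col, axon_id, response_c2, response_b2, pixel_wsi
    (NaN where the axon's WSI is undefined).
    """
    by_id = {r.axon_id: r for r in responses}
    rows = []
    for axon in axons:
        resp = by_id.get(axon.axon_id)
        if resp is None:
            continue
        c2 = resp.groups.get(("C2", False))
        b2 = resp.groups.get(("B2", False))
        for r, c in axon.pixel_mask:
            rows.append({
                "row": int(r), "col": int(c), "axon_id": axon.axon_id,
                "response_c2": c2.amplitude_full if c2 else np.nan,
                "response_b2": b2.amplitude_full if b2 else np.nan,
                "pixel_wsi": resp.wsi if resp.wsi is not None else np.nan})
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    counts = table.groupby(["row", "col"])["axon_id"].transform("nunique")
    return table[counts == 1].reset_index(drop=True)


@dataclass
class EllipseFit:
    center: np.ndarray          # 2-vector, pixel coordinates
    covariance: np.ndarray      # 2x2
    confidence_level: float
    semi_axes: np.ndarray       # sqrt(eigval * chi2 quantile), descending
    orientation: np.ndarray     # 2x2, columns are eigenvectors
    area: float                 # pi * s1 * s2


def fit_confidence_ellipse(points: np.ndarray, confidence: float = 0.9
                           ) -> EllipseFit:
    """Confidence ellipse of a 2-D point cloud.

    The ellipse is the level set of the Mahalanobis distance at the
    chi-square(2 df) quantile of *confidence*: semi-axes are
    ``sqrt(lambda_i * q)`` along the covariance eigenvectors.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 two-dimensional points")
    center = pts.mean(axis=0)
    cov = np.cov(pts.T)
    eigval, eigvec = np.linalg.eigh(cov)
    if eigval.min() <= 1e-12 * max(eigval.max(), 1.0):
        raise ValueError("degenerate point cloud (collinear or too small)")
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    q = chi2.ppf(confidence, df=2)
    semi = np.sqrt(eigval * q)
    return EllipseFit(center=center, covariance=cov,
                      confidence_level=confidence, semi_axes=semi,
                      orientation=eigvec, area=float(np.pi * semi[0] * semi[1]))


def ellipse_polygon(e: EllipseFit, n_vertices: int = 512) -> Polygon:
    """Inscribed regular polygonal approximation of the ellipse boundary."""
    theta = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    unit = np.column_stack([np.cos(theta), np.sin(theta)])
    boundary = e.center + (unit * e.semi_axes) @ e.orientation.T
    return Polygon(boundary)


def points_in_ellipse(points: np.ndarray, e: EllipseFit) -> np.ndarray:
    """Boolean mask of points with Mahalanobis distance inside the ellipse."""
    pts = np.asarray(points, dtype=float) - e.center
    inv = np.linalg.inv(e.covariance)
    d2 = np.einsum("ij,jk,ik->i", pts, inv, pts)
    return d2 <= chi2.ppf(e.confidence_level, df=2)


def monte_carlo_intersection_area(e1: EllipseFit, e2: EllipseFit,
                                  n_samples: int = 1_000_000,
                                  rng: np.random.Generator | int | None = None
                                  ) -> tuple[float, float]:
    """Rejection-sampling estimate of the two-ellipse intersection area.

    Samples uniformly over the intersection of the ellipses' bounding boxes
    and counts points inside both Mahalanobis regions — a geometry-free
    cross-check of the polygon-clipping route. Returns (area, standard
    error); (0, 0) when the bounding boxes are disjoint.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    q = chi2.ppf(e1.confidence_level, df=2)
    half1 = np.sqrt(np.diag(e1.covariance) * q)
    half2 = np.sqrt(np.diag(e2.covariance) * chi2.ppf(e2.confidence_level, 2))
    lo = np.maximum(e1.center - half1, e2.center - half2)
    hi = np.minimum(e1.center + half1, e2.center + half2)
    if np.any(hi <= lo):
        return 0.0, 0.0
    pts = rng.uniform(lo, hi, size=(n_samples, 2))
    inside = points_in_ellipse(pts, e1) & points_in_ellipse(pts, e2)
    box = float(np.prod(hi - lo))
    f = inside.mean()
    return f * box, box * float(np.sqrt(f * (1 - f) / n_samples))


@dataclass
class OverlapResult:
    overlap_index: float
    intersection_area: float
    mean_ellipse_area: float


def ellipse_overlap_index(e1: EllipseFit, e2: EllipseFit,
                          n_vertices: int = 512) -> OverlapResult:
    """Intersection area of two ellipses normalized by their mean area.

    Areas are computed on matched inscribed polygons (default 512 vertices),
    so the polygonal shrinkage factor cancels in the index.
    """
    p1, p2 = ellipse_polygon(e1, n_vertices), ellipse_polygon(e2, n_vertices)
    inter = p1.intersection(p2).area
    mean_area = 0.5 * (p1.area + p2.area)
    return OverlapResult(overlap_index=float(inter / mean_area),
                         intersection_area=float(inter),
                         mean_ellipse_area=float(mean_area))


def field_overlap(pixel_map: pd.DataFrame, wsi_threshold: float = 0.75,
                  confidence: float = 0.9) -> dict:
    """Overlap analysis of one field of view.

    Splits the pixel map into C2-tuned (WSI > threshold) and B2-tuned
    (WSI < -threshold) pixels, fits a confidence ellipse to each cloud and
    returns the per-field summary row (counts, areas, overlap index).
    """
    c2 = pixel_map[pixel_map["pixel_wsi"] > wsi_threshold]
    b2 = pixel_map[pixel_map["pixel_wsi"] < -wsi_threshold]
    out = {"n_pixels_c2": len(c2), "n_pixels_b2": len(b2),
           "area_c2": np.nan, "area_b2": np.nan,
           "intersection_area": np.nan, "overlap_index": np.nan}
    if len(c2) < 3 or len(b2) < 3:
        return out
    e_c2 = fit_confidence_ellipse(c2[["row", "col"]].to_numpy(), confidence)
    e_b2 = fit_confidence_ellipse(b2[["row", "col"]].to_numpy(), confidence)
    ov = ellipse_overlap_index(e_c2, e_b2)
    out.update(area_c2=e_c2.area, area_b2=e_b2.area,
               intersection_area=ov.intersection_area,
               overlap_index=ov.overlap_index)
    return out
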