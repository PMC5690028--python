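"""Uniformity metrics and region-of-interest handling.

Conventions: pixel coordinates are 0-based; rectangular extents are
half-open ``[start, stop)``.  The contrast-to-noise ratio implemented here,
``|mean(center) - mean(background)| / sd(background)``, is a package
convention (population standard deviation), documented because no single
standard definition exists.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from emmcup.errors import UndefinedMetricError

__all__ = [
    "Region",
    "ROISpec",
    "MetricsReport",
    "tau_cup",
    "rmsc",
    "cnr",
    "horizontal_profile",
    "default_phantom_rois",
    "compute_report",
]


@dataclass(frozen=True)
class Region:
    """A rectangle, disk, or annulus in 0-based pixel coordinates.

    kind "rect": params (row_start, row_stop, col_start, col_stop), half-open.
    kind "circle": params (row_center, col_center, radius).
    kind "annulus": params (row_center, col_center, r_inner, r_outer);
    pixels with r_inner <= distance < r_outer.
    """

    kind: str
    params: tuple

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        rows, cols = shape
        if self.kind == "rect":
            r0, r1, c0, c1 = self.params
            if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
                raise ValueError(f"rect {self.params} outside image {shape}")
            m = np.zeros(shape, dtype=bool)
            m[int(r0):int(r1), int(c0):int(c1)] = True
            return m
        rr, cc = np.ogrid[:rows, :cols]
        if self.kind == "circle":
            r, c, rad = self.params
            dist2 = (rr - r) ** 2 + (cc - c) ** 2
            m = dist2 <= rad**2
        elif self.kind == "annulus":
            r, c, ri, ro = self.params
            dist2 = (rr - r) ** 2 + (cc - c) ** 2
            m = (dist2 >= ri**2) & (dist2 < ro**2)
        else:
            raise ValueError(f"unknown region kind {self.kind!r}")
        if not m.any():
            raise ValueError(f"{self.kind} region {self.params} is empty")
        return m

    def to_dict(self) -> dict:
        return {"kind": self.kind, "params": list(self.params)}

    @classmethod
    def from_dict(cls, d: dict) -> "Region":
        return cls(kind=d["kind"], params=tuple(d["params"]))


@dataclass(frozen=True)
class ROISpec:
    """Named regions for the uniformity metrics.

    ``center_roi`` and ``edge_roi`` feed the cupping magnitude;
    ``background_roi`` (outside the object) feeds the CNR.
    """

    center_roi: Region
    edge_roi: Region
    background_roi: Region | None = None
    label: str = ""

    def validate(self, shape: tuple[int, int]) -> None:
        center = self.center_roi.to_mask(shape)
        edge = self.edge_roi.to_mask(shape)
        if not center.any() or not edge.any():
            raise ValueError("center/edge ROI is empty")
        if (center & edge).any():
            raise ValueError("center and edge ROIs overlap")
        if self.background_roi is not None:
            self.background_roi.to_mask(shape)

    def to_json(self) -> str:
        d = {
            "label": self.label,
            "center_roi": self.center_roi.to_dict(),
            "edge_roi": self.edge_roi.to_dict(),
        }
        if self.background_roi is not None:
            d["background_roi"] = self.background_roi.to_dict()
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ROISpec":
        d = json.loads(text)
        return cls(
            center_roi=Region.from_dict(d["center_roi"]),
            edge_roi=Region.from_dict(d["edge_roi"]),
            background_roi=(
                Region.from_dict(d["background_roi"])
                if "background_roi" in d
                else None
            ),
            label=d.get("label", ""),
        )


@dataclass(frozen=True)
class MetricsReport:
    tau_cup: float
    rmsc_center: float
    rmsc_edge: float
    cnr: float | None
    roi_means: dict = field(default_factory=dict)


def _roi_values(image: np.ndarray, region: Region) -> np.ndarray:
    return np.asarray(image, dtype=np.float64)[region.to_mask(image.shape)]


def tau_cup(image: np.ndarray, rois: ROISpec) -> float:
    """Cupping magnitude ``100 * (edge_mean - center_mean) / edge_mean`` (%).

    Positive for classic cupping (depressed center).
    """
    center = _roi_values(image, rois.center_roi).mean()
    edge = _roi_values(image, rois.edge_roi).mean()
    if edge == 0:
        raise UndefinedMetricError("edge ROI mean is zero; tau_cup undefined")
    return float(100.0 * (edge - center) / edge)


def rmsc(image: np.ndarray, roi: Region | None = None) -> float:
    """Root-mean-square contrast over a region.

    The whole image is first affinely rescaled to [0, 255]; the result is
    the population standard deviation of the rescaled intensities over the
    region (whole image if ``roi`` is None).  Constant images give 0.
    """
    image = np.asarray(image, dtype=np.float64)
    lo, hi = image.min(), image.max()
    scaled = np.zeros_like(image) if hi == lo else (image - lo) * (255.0 / (hi - lo))
    values = scaled.ravel() if roi is None else scaled[roi.to_mask(image.shape)]
    if values.size == 0:
        raise ValueError("empty region")
    return float(np.sqrt(np.mean((values - values.mean()) ** 2)))


def cnr(image: np.ndarray, rois: ROISpec) -> float:
    """Package-convention CNR: |mean(center) - mean(bg)| / sd(bg)."""
    if rois.background_roi is None:
        raise ValueError("ROISpec has no background ROI; CNR needs one")
    center = _roi_values(image, rois.center_roi)
    bg = _roi_values(image, rois.background_roi)
    sd = float(np.sqrt(np.mean((bg - bg.mean()) ** 2)))
    if sd == 0:
        raise UndefinedMetricError(
            "background ROI standard deviation is zero; CNR undefined"
        )
    return float(abs(center.mean() - bg.mean()) / sd)


def horizontal_profile(image: np.ndarray, row: int | None = None) -> np.ndarray:
    """Intensity values of one row (default: middle row)."""
    image = np.asarray(image)
    if row is None:
        row = image.shape[0] // 2
    if not 0 <= row < image.shape[0]:
        raise ValueError(f"row {row} outside image with {image.shape[0]} rows")
    return image[row].copy()


def default_phantom_rois(
    shape: tuple[int, int],
    center: tuple[float, float] | None = None,
    radius: float | None = None,
    label: str = "default",
) -> ROISpec:
    """Default ROIs for a centred disk phantom of radius R.

    Center ROI: disk of radius 0.1 R at the phantom center.  Edge ROI:
    annulus at 0.8-0.9 R.  Background ROI: a small square in the image
    corner, outside the object.
    """
    rows, cols = shape
    if center is None:
        center = ((rows - 1) / 2.0, (cols - 1) / 2.0)
    if radius is None:
        radius = 0.45 * min(rows, cols)
    r, c = center
    side = max(4, int(round(0.06 * min(rows, cols))))
    return ROISpec(
        center_roi=Region("circle", (r, c, 0.1 * radius)),
        edge_roi=Region("annulus", (r, c, 0.8 * radius, 0.9 * radius)),
        background_roi=Region("rect", (1, 1 + side, 1, 1 + side)),
        label=label,
    )


def compute_report(image: np.ndarray, rois: ROISpec) -> MetricsReport:
    """Evaluate every metric on one image with one ROI set."""
    image = np.asarray(image, dtype=np.float64)
    rois.validate(image.shape)
    roi_means = {}
    named = {"center": rois.center_roi, "edge": rois.edge_roi}
    if rois.background_roi is not None:
        named["background"] = rois.background_roi
    for name, region in named.items():
        vals = _roi_values(image, region)
        roi_means[name] = (
            float(vals.mean()),
            float(np.sqrt(np.mean((vals - vals.mean()) ** 2))),
        )
    cnr_value = None
    if rois.background_roi is not None:
        try:
            cnr_value = cnr(image, rois)
        except UndefinedMetricError:
            cnr_value = None  # constant background (e.g. noiseless synthetic)
    return MetricsReport(
        tau_cup=tau_cup(image, rois),
        rmsc_center=rmsc(image, rois.center_roi),
        rmsc_edge=rmsc(image, rois.edge_roi),
        cnr=cnr_value,
        roi_means=roi_means,
    )
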