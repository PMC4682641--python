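"""Image stack, ROI and trace-table I/O.

Conventions (used throughout the package):

* pixel coordinates are 0-based, (row, col) = (y, x), origin top-left;
* stacks are multi-page TIFF, one page per frame (time series) or per
  plane (z-stacks);
* physical calibration travels in a JSON sidecar (``<stack>.json``) whose
  values override any TIFF tags -- synthetic fixtures always carry
  sidecars;
* trace CSVs have the fixed column order
  ``experiment_id, frame, time_s, raw, normalized, bleach``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

log = logging.getLogger(__name__)

ROLES = ("timeseries", "prestack", "poststack")


@dataclass
class ImageStack:
    """A (time | z, y, x) stack of non-negative intensities."""

    data: np.ndarray
    frame_interval: float
    pixel_size: float
    role: str = "timeseries"
    z_spacing: float | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("stack data must be 3-D (time | z, y, x)")
        if self.data.shape[0] == 0:
            raise ValueError("stack has no pages")
        if not np.all(np.isfinite(self.data)) or np.any(self.data < 0):
            raise ValueError("intensities must be finite and >= 0")
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self):
        return self.data.shape

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class ROISpec:
    """Region of interest in pixel units.

    ``circle``: center=(row, col), radius; ``rectangle``: center and
    extent=(height, width); ``line``: endpoints ((r0, c0), (r1, c1)).
    """

    shape: str
    label: str = "frap"
    center: tuple | None = None
    radius: float | None = None
    extent: tuple | None = None
    endpoints: tuple | None = None

    def __post_init__(self):
        if self.shape not in ("circle", "rectangle", "line"):
            raise ValueError("shape must be circle, rectangle or line")
        if self.label not in ("frap", "flip", "control", "nucleus"):
            raise ValueError("label must be frap, flip, control or nucleus")
        if self.shape == "circle":
            if self.center is None or self.radius is None or self.radius <= 0:
                raise ValueError("circle ROI needs a center and a radius > 0")
            self.center = tuple(float(v) for v in self.center)
        elif self.shape == "rectangle":
            if self.center is None or self.extent is None:
                raise ValueError("rectangle ROI needs center and extent")
        elif self.endpoints is None:
            raise ValueError("line ROI needs endpoints")

    def mask(self, image_shape) -> np.ndarray:
        """Boolean pixel mask; circle membership is pixel-center-in-radius."""
        h, w = image_shape[-2:]
        if self.shape == "circle":
            r0, c0 = self.center
            if not (0 <= r0 < h and 0 <= c0 < w):
                raise ValueError(f"ROI '{self.label}' center outside image bounds")
            rr, cc = np.mgrid[0:h, 0:w]
            return (rr - r0) ** 2 + (cc - c0) ** 2 <= self.radius**2
        if self.shape == "rectangle":
            r0, c0 = self.center
            eh, ew = self.extent
            top, left = r0 - eh / 2, c0 - ew / 2
            if top < -0.5 or left < -0.5 or top + eh > h - 0.5 + 1 or left + ew > w - 0.5 + 1:
                raise ValueError(f"ROI '{self.label}' outside image bounds")
            rr, cc = np.mgrid[0:h, 0:w]
            return (np.abs(rr - r0) <= eh / 2) & (np.abs(cc - c0) <= ew / 2)
        raise ValueError("line ROIs have no pixel mask; use linescan tools")


def write_stack(stack: ImageStack, path) -> None:
    """Write a multi-page TIFF plus its calibration sidecar (lossless for
    integer data)."""
    path = Path(path)
    tifffile.imwrite(path, stack.data, photometric="minisblack")
    sidecar = {
        "frame_interval": stack.frame_interval,
        "pixel_size": stack.pixel_size,
        "role": stack.role,
        "z_spacing": stack.z_spacing,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_stack(path) -> ImageStack:
    """Read a multi-page TIFF; calibration from the JSON sidecar."""
    path = Path(path)
    data = tifffile.imread(path)
    data = np.atleast_2d(np.asarray(data))
    if data.ndim == 2:
        data = data[None]
    if data.size == 0 or data.shape[0] == 0:
        raise ValueError(f"{path} contains no image pages")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise ValueError(
            f"no calibration for {path}: write a sidecar {sidecar_path.name} "
            "with frame_interval and pixel_size"
        )
    meta = json.loads(sidecar_path.read_text())
    return ImageStack(
        data=data,
        frame_interval=float(meta["frame_interval"]),
        pixel_size=float(meta["pixel_size"]),
        role=meta.get("role", "timeseries"),
        z_spacing=meta.get("z_spacing"),
    )


def _roi_to_dict(roi: ROISpec) -> dict:
    d = {"shape": roi.shape, "label": roi.label}
    if roi.center is not None:
        d["center"] = list(roi.center)
    if roi.radius is not None:
        d["radius"] = roi.radius
    if roi.extent is not None:
        d["extent"] = list(roi.extent)
    if roi.endpoints is not None:
        d["endpoints"] = [list(p) for p in roi.endpoints]
    return d


def write_rois(rois, path) -> None:
    Path(path).write_text(json.dumps([_roi_to_dict(r) for r in rois], indent=2))


def read_rois(path, image_shape=None) -> list:
    """Read ROI specs from JSON; optionally validate against image bounds.

    Overlapping frap/flip ROIs are accepted (physically possible) with a
    logged warning.
    """
    entries = json.loads(Path(path).read_text())
    rois = []
    for e in entries:
        kwargs = dict(e)
        if "endpoints" in kwargs:
            kwargs["endpoints"] = tuple(tuple(p) for p in kwargs["endpoints"])
        rois.append(ROISpec(**kwargs))
    if image_shape is not None:
        for roi in rois:
            if roi.shape != "line":
                roi.mask(image_shape)  # raises with the ROI label if out of bounds
        circles = [r for r in rois if r.shape == "circle" and r.label in ("frap", "flip")]
        for i in range(len(circles)):
            for j in range(i + 1, len(circles)):
                a, b = circles[i], circles[j]
                d = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
                if d < a.radius + b.radius:
                    log.warning("ROIs '%s' and '%s' overlap", a.label, b.label)
    return rois


TRACE_COLUMNS = ["experiment_id", "frame", "time_s", "raw", "normalized", "bleach"]


def write_traces(table: pd.DataFrame, path) -> None:
    """Write the trace table CSV with fixed columns and deterministic
    (experiment, frame) row order, full precision, '.' decimal separator."""
    df = table.copy()
    for col in TRACE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[TRACE_COLUMNS].sort_values(["experiment_id", "frame"], kind="stable")
    df.to_csv(path, index=False)


def read_traces(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
    return df
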