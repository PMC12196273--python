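"""Frame processing: chamber cropping, tablet location, ROI geometry,
surface-roughness statistics, and the tabular feature space.

The ROI layout mirrors manual surface-characterisation practice on
dissolution images: a rectangle spanning the full frame width above the
tablet, one below it, and a 1-pixel-wide vertical line through the tablet
centre.  Six deviation-based statistics (Ra, Rq, Rsk, Rku, Min, StdDev)
are computed per ROI; all deviations are taken from the region mean (no
plane levelling).  Kurtosis is non-excess (a Gaussian region gives
Rku = 3), matching surface-metrology convention for Rku; StdDev uses the
sample (n-1) denominator while Rq uses the population (n) denominator, so
the two columns are not redundant.

Feature names follow the grammar ``"<medium> <wavelength><roi> <param>"``
with roi token "top" (top rectangle), "line" (centre line), or blank
(bottom rectangle), e.g. ``"1_2 520top Ra"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MEDIUM_IDS = ("1_2", "Wa", "6_8")
WAVELENGTHS = (255, 520)
ROI_KINDS = ("top_rect", "center_line", "bottom_rect")
ROI_TOKENS = {"top_rect": "top", "center_line": "line", "bottom_rect": ""}
PARAM_NAMES = ("Ra", "Rq", "Rsk", "Kurt", "Min", "StdDev")
AREA_PARAM = "Area"

#: value written into the feature table where a statistic is undefined
#: (skewness/kurtosis of a constant region)
UNDEFINED_FILL = 0.0


@dataclass
class AbsorbanceFrame:
    """One 2-D absorbance map with capture metadata."""

    pixels: np.ndarray  # (H, W), nonnegative
    medium_id: str
    wavelength: int
    time: float  # minutes

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 8:
            raise ValueError("pixels must be a 2-D array with H, W >= 8")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ValueError("pixels must be finite and nonnegative")
        if self.medium_id not in MEDIUM_IDS:
            raise ValueError(f"unknown medium_id {self.medium_id!r}")
        if self.wavelength not in WAVELENGTHS:
            raise ValueError(f"wavelength must be one of {WAVELENGTHS}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class TabletBox:
    """Axis-aligned bounding box, 0-based half-open pixel bounds."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int

    @property
    def is_empty(self) -> bool:
        return self.row_end <= self.row_start or self.col_end <= self.col_start

    @property
    def height(self) -> int:
        return max(0, self.row_end - self.row_start)

    @property
    def width(self) -> int:
        return max(0, self.col_end - self.col_start)


EMPTY_BOX = TabletBox(0, 0, 0, 0)


@dataclass(frozen=True)
class RegionSpec:
    """One ROI: rectangle or 1-px line, half-open bounds, origin top-left.

    ``degenerate`` marks an ROI whose rectangle collapsed to zero rows
    (tablet touching the frame edge); it is reported, never silently
    dropped.
    """

    kind: str
    row_start: int
    row_end: int
    col_start: int
    col_end: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ROI_KINDS:
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        if self.kind == "center_line" and (self.col_end - self.col_start) != 1:
            raise ValueError("center_line must be exactly 1 px wide")

    def extract(self, frame: AbsorbanceFrame) -> np.ndarray:
        """Pixel values of this region, flattened."""
        if self.degenerate:
            raise ValueError(f"cannot extract a degenerate {self.kind} ROI")
        return frame.pixels[self.row_start:self.row_end,
                            self.col_start:self.col_end].ravel()


@dataclass(frozen=True)
class SurfaceStats:
    """Six deviation-from-mean statistics of a pixel region.

    ``rsk``/``rku`` are ``None`` for constant regions (undefined, never a
    silent NaN)."""

    ra: float
    rq: float
    rsk: float | None
    rku: float | None
    min: float
    stddev: float

    def as_dict(self) -> dict[str, float]:
        return {
            "Ra": self.ra,
            "Rq": self.rq,
            "Rsk": UNDEFINED_FILL if self.rsk is None else self.rsk,
            "Kurt": UNDEFINED_FILL if self.rku is None else self.rku,
            "Min": self.min,
            "StdDev": self.stddev,
        }


# ---------------------------------------------------------------------------
# operations


def crop_chamber(frame: AbsorbanceFrame, bounds: TabletBox) -> AbsorbanceFrame:
    """Crop to the dissolution-chamber rectangle, preserving metadata."""
    H, W = frame.shape
    if not (0 <= bounds.row_start < bounds.row_end <= H
            and 0 <= bounds.col_start < bounds.col_end <= W):
        raise ValueError("crop bounds out of range")
    return AbsorbanceFrame(
        pixels=frame.pixels[bounds.row_start:bounds.row_end,
                            bounds.col_start:bounds.col_end].copy(),
        medium_id=frame.medium_id, wavelength=frame.wavelength,
        time=frame.time)


def locate_tablet(frame_520: AbsorbanceFrame,
                  threshold_fraction: float = 0.5) -> TabletBox:
    """Tightest box over pixels above ``threshold_fraction`` x frame max.

    Intended for the visible (520 nm) channel where the tablet body is
    opaque.  An empty box is a valid result once the tablet has fully
    dissolved (or for an all-zero frame).
    """
    px = frame_520.pixels
    vmax = px.max()
    if vmax <= 0:
        return EMPTY_BOX
    mask = px > threshold_fraction * vmax
    if not mask.any():
        return EMPTY_BOX
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return TabletBox(int(rows[0]), int(rows[-1]) + 1,
                     int(cols[0]), int(cols[-1]) + 1)


def define_rois(tablet_box: TabletBox, frame_dims: tuple[int, int],
                margin_px: int = 2) -> dict[str, RegionSpec]:
    """The three ROIs around a located tablet.

    top rectangle: full frame width, frame top to (box top - margin);
    bottom rectangle: (box bottom + margin) to frame bottom;
    centre line: the 1-px column at the box's horizontal midpoint (ties on
    even widths break toward the lower column index), spanning the box rows.
    """
    if tablet_box.is_empty:
        raise ValueError("cannot define ROIs for an empty tablet box")
    H, W = frame_dims
    top_end = max(tablet_box.row_start - margin_px, 0)
    bottom_start = min(tablet_box.row_end + margin_px, H)
    center_col = tablet_box.col_start + (tablet_box.width - 1) // 2
    return {
        "top_rect": RegionSpec("top_rect", 0, top_end, 0, W,
                               degenerate=top_end <= 0),
        "bottom_rect": RegionSpec("bottom_rect", bottom_start, H, 0, W,
                                  degenerate=bottom_start >= H),
        "center_line": RegionSpec("center_line", tablet_box.row_start,
                                  tablet_box.row_end, center_col,
                                  center_col + 1),
    }


def surface_stats(region_pixels: Sequence[float] | np.ndarray) -> SurfaceStats:
    """The six deviation-based statistics of a pixel region.

    With mean z̄ and deviations d_i = z_i − z̄:
    Ra = mean|d|, Rq = sqrt(mean d²), Rsk = mean d³ / Rq³,
    Rku = mean d⁴ / Rq⁴ (non-excess), Min = min d,
    StdDev = sample (n−1) standard deviation.
    """
    z = np.asarray(region_pixels, dtype=float).ravel()
    if z.size < 2:
        raise ValueError("a region needs at least 2 pixels")
    d = z - z.mean()
    rq = float(np.sqrt(np.mean(d * d)))
    if rq == 0.0:
        return SurfaceStats(ra=0.0, rq=0.0, rsk=None, rku=None, min=0.0,
                            stddev=0.0)
    dn = d / rq  # normalised deviations: avoids under/overflow in rq powers
    return SurfaceStats(
        ra=float(np.mean(np.abs(d))),
        rq=rq,
        rsk=float(np.mean(dn ** 3)),
        rku=float(np.mean(dn ** 4)),
        min=float(d.min()),
        stddev=float(np.std(z, ddof=1)),
    )


def tablet_area(frame_520: AbsorbanceFrame,
                threshold_fraction: float = 0.5) -> int:
    """Count of pixels above ``threshold_fraction`` x frame max (px)."""
    vmax = frame_520.pixels.max()
    if vmax <= 0:
        return 0
    return int(np.count_nonzero(frame_520.pixels > threshold_fraction * vmax))


def feature_name(medium_id: str, wavelength: int, roi_kind: str,
                 param_name: str) -> str:
    """Compose a feature name, e.g. ("1_2", 520, "top_rect", "Ra") ->
    "1_2 520top Ra"; the bottom rectangle has a blank roi token."""
    if medium_id not in MEDIUM_IDS:
        raise ValueError(f"unknown medium token {medium_id!r}")
    if wavelength not in WAVELENGTHS:
        raise ValueError(f"unknown wavelength {wavelength!r}")
    if roi_kind not in ROI_TOKENS:
        raise ValueError(f"unknown ROI kind {roi_kind!r}")
    if param_name not in PARAM_NAMES + (AREA_PARAM,):
        raise ValueError(f"unknown parameter {param_name!r}")
    return f"{medium_id} {wavelength}{ROI_TOKENS[roi_kind]} {param_name}"


def parse_feature_name(name: str) -> tuple[str, int, str, str]:
    """Inverse of :func:`feature_name`; area features parse with roi
    "bottom_rect" placeholder replaced by "area"."""
    medium_id, middle, param = name.split(" ")
    for roi_kind, token in ROI_TOKENS.items():
        for wl in WAVELENGTHS:
            if middle == f"{wl}{token}":
                if param == AREA_PARAM and token == "":
                    return medium_id, wl, "area", param
                return medium_id, wl, roi_kind, param
    raise ValueError(f"unparseable feature name {name!r}")


def feature_columns() -> list[str]:
    """The deterministic 114-column order of the feature table: for each
    medium and wavelength, 3 ROIs x 6 statistics (108), then the 6
    per-capture tablet areas."""
    cols = [
        feature_name(m, wl, roi, p)
        for m in MEDIUM_IDS for wl in WAVELENGTHS
        for roi in ROI_KINDS for p in PARAM_NAMES
    ]
    cols += [feature_name(m, wl, "bottom_rect", AREA_PARAM)
             for m in MEDIUM_IDS for wl in WAVELENGTHS]
    return cols


def extract_feature_table(videos: Mapping[tuple[str, int], "object"],
                          sampling_timepoints: Sequence[float],
                          threshold_fraction: float = 0.5,
                          margin_px: int = 2) -> pd.DataFrame:
    """Assemble the per-timepoint feature table from six captures.

    ROI geometry is fixed from each medium's first (t = 0) visible-channel
    frame and applied to both wavelengths of that medium at every
    timepoint; the tablet area is re-thresholded per frame.  A degenerate
    ROI or a statistic undefined on a constant region contributes
    ``UNDEFINED_FILL`` so the assembled table has no missing values.
    """
    required = {(m, wl) for m in MEDIUM_IDS for wl in WAVELENGTHS}
    if set(videos) != required:
        raise ValueError("need exactly the six (medium, wavelength) captures")
    rois_by_medium: dict[str, dict[str, RegionSpec]] = {}
    for m in MEDIUM_IDS:
        v520 = videos[(m, 520)]
        box = locate_tablet(v520.absorbance_frame(0.0), threshold_fraction)
        if box.is_empty:
            raise ValueError(f"no tablet found in the t=0 frame of {m}/520")
        rois_by_medium[m] = define_rois(box, v520.frame_shape, margin_px)
    rows = []
    for t in sampling_timepoints:
        row: dict[str, float] = {}
        for m in MEDIUM_IDS:
            for wl in WAVELENGTHS:
                frame = videos[(m, wl)].absorbance_frame(float(t))
                for roi_kind in ROI_KINDS:
                    roi = rois_by_medium[m][roi_kind]
                    if roi.degenerate:
                        stats = {p: UNDEFINED_FILL for p in PARAM_NAMES}
                    else:
                        stats = surface_stats(roi.extract(frame)).as_dict()
                    for p in PARAM_NAMES:
                        row[feature_name(m, wl, roi_kind, p)] = stats[p]
                row[feature_name(m, wl, "bottom_rect", AREA_PARAM)] = \
                    tablet_area(frame, threshold_fraction)
        rows.append(row)
    table = pd.DataFrame(rows, index=pd.Index([float(t) for t in sampling_timepoints],
                                              name="time_min"))
    return table[feature_columns()]
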