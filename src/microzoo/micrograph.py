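"""Micrograph-to-carbon-biomass quantification.

Converts images of settled, Lugol's-fixed samples into per-sample carbon
biomass by taxon group and 20-um size class: contrast stretch and global
threshold to find regions of interest, moment-based major/minor axis
measurement, a regression-based cilia length correction for ciliates,
prolate-spheroid biovolume, and an allometric carbon:volume conversion.

Axis convention: the ellipse with the same normalized second central moments
as the region mask, axis length = 4 * sqrt(eigenvalue) of the pixel-coordinate
covariance (no +1/12 pixel-area correction), matching the common
``regionprops`` implementations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage import exposure, filters, measure

from .schema import (
    GROUP_COLUMNS,
    SIZE_CLASS_LARGE,
    SIZE_CLASS_SMALL,
    TAXON_CILIATE,
    TAXON_DINO,
    TAXON_TRIPOS,
    ConfigurationError,
    DegenerateShapeError,
    InputError,
    StateError,
    group_column,
)

#: Default minimum ROI area: the settling-chamber method resolves cells down
#: to about 4 um, so anything smaller than a 4-um-diameter disk is noise. The
#: floor is set 15% below that disk's area so a genuine 4-um cell straddling
#: the rasterization boundary is not discarded.
MIN_CELL_DIAMETER_UM = 4.0
DEFAULT_MIN_AREA_UM2 = 0.85 * math.pi * (MIN_CELL_DIAMETER_UM / 2.0) ** 2


@dataclass
class Roi:
    """A connected dark region cropped out of a micrograph."""

    label: int
    bbox: tuple  # (min_row, min_col, max_row, max_col)
    mask: np.ndarray  # boolean, cropped to bbox
    centroid_px: tuple  # (x, y) in full-image coordinates
    image_id: str = ""

    def __post_init__(self) -> None:
        if self.mask.size == 0 or not self.mask.any():
            raise InputError("ROI mask must be non-empty")


@dataclass
class CellMeasurement:
    """One identified cell: axes in um, then biovolume (um^3) and carbon (pg)."""

    sample_id: str
    group: str
    major_axis_um: float
    minor_axis_um: float
    corrected: bool = False
    biovolume_um3: float | None = None
    carbon_pg: float | None = None

    def __post_init__(self) -> None:
        if not (self.major_axis_um >= self.minor_axis_um > 0):
            raise InputError("need major >= minor > 0")


@dataclass
class CarbonModel:
    """Allometric carbon:volume coefficients per group: pg C = scale * V^exp."""

    coefficients: dict  # group -> (c_scale_pg, c_exp)

    def __post_init__(self) -> None:
        for grp, (scale, exp) in self.coefficients.items():
            if scale <= 0 or not (0 < exp <= 1.2):
                raise ConfigurationError(
                    f"invalid coefficients for {grp}: ({scale}, {exp})"
                )


def default_carbon_model() -> CarbonModel:
    """Literature C:V defaults for non-diatom protists (pg C = 0.216 V^0.939).

    A diatom-type entry (0.288 V^0.811) is included for completeness but no
    group maps to it by default.
    """
    return CarbonModel(
        coefficients={
            TAXON_DINO: (0.216, 0.939),
            TAXON_CILIATE: (0.216, 0.939),
            TAXON_TRIPOS: (0.216, 0.939),
            "diatom": (0.288, 0.811),
        }
    )


@dataclass
class CiliaCorrection:
    """Linear map from automated to cilia-free ciliate length."""

    slope: float
    intercept_um: float = 0.0
    n: int = 0
    r_squared: float = float("nan")

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise InputError("correction slope must be positive")


@dataclass
class SampleQuantification:
    """Per-sample biomass (ug C/L) by group x size class, with counts."""

    sample_id: str
    settled_volume_mL: float
    biomass: dict  # group column -> ug C / L
    counts: dict  # group column -> cell count
    tripos_biomass: float = 0.0
    tripos_count: int = 0
    total_biomass: float = 0.0
    low_count: bool = False
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Segmentation and measurement
# ---------------------------------------------------------------------------


def segment_rois(
    image,
    pixel_scale_um_per_px,
    contrast_stretch_percentiles=(0.0, 99.5),
    threshold_method="otsu",
    min_area_um2=DEFAULT_MIN_AREA_UM2,
    image_id="",
):
    """Find connected dark regions larger than ``min_area_um2``.

    The lower stretch percentile defaults to 0 because cells typically cover
    well under 1% of the frame; clipping the dark tail would erase them.

    The image is percentile contrast-stretched, inverted (cells are
    Lugol's-dark on a light background) and globally thresholded; connected
    components above the area floor are returned cropped. Deterministic for
    fixed parameters.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise InputError(f"expected a single-channel 2D image, got {image.ndim}D")
    if pixel_scale_um_per_px <= 0:
        raise InputError("pixel scale must be positive")
    img = image.astype(float)
    p_lo, p_hi = np.percentile(img, contrast_stretch_percentiles)
    if p_hi - p_lo <= 0:
        # sparse field: objects fall outside the percentile window
        p_lo, p_hi = img.min(), img.max()
        if p_hi - p_lo <= 0:
            return []  # flat image: nothing to segment
    stretched = exposure.rescale_intensity(img, in_range=(p_lo, p_hi))
    inverted = 1.0 - stretched
    if threshold_method == "otsu":
        thresh = filters.threshold_otsu(inverted)
    elif threshold_method == "mean":
        thresh = inverted.mean()
    elif isinstance(threshold_method, (int, float)):
        thresh = float(threshold_method)
    else:
        raise InputError(f"unknown threshold method {threshold_method!r}")
    binary = inverted > thresh
    # Otsu splits the background-noise mode when dark objects cover a
    # vanishing fraction of the frame; a real cell/background split has
    # strong class separation, so reject weak ones as object-free.
    if threshold_method == "otsu" and binary.any() and not binary.all():
        if inverted[binary].mean() - inverted[~binary].mean() < 0.35:
            return []
    labels = measure.label(binary, connectivity=2)
    min_area_px = min_area_um2 / pixel_scale_um_per_px**2
    rois = []
    for rp in measure.regionprops(labels):
        if rp.area < min_area_px:
            continue
        r0, c0, r1, c1 = rp.bbox
        rois.append(
            Roi(
                label=rp.label,
                bbox=rp.bbox,
                mask=labels[r0:r1, c0:c1] == rp.label,
                centroid_px=(rp.centroid[1], rp.centroid[0]),
                image_id=image_id,
            )
        )
    return rois


def measure_axes(roi: Roi, pixel_scale_um_per_px: float):
    """Moment-equivalent ellipse axes of the ROI mask, in um.

    Axis length is ``4 * sqrt(eigenvalue)`` of the pixel-coordinate
    covariance of the mask — the ellipse with the same normalized second
    central moments as the region.
    """
    if pixel_scale_um_per_px <= 0:
        raise InputError("pixel scale must be positive")
    if roi.mask.sum() < 2:
        raise DegenerateShapeError("single-pixel mask has no measurable axes")
    rp = measure.regionprops(roi.mask.astype(np.uint8))[0]
    major = rp.axis_major_length * pixel_scale_um_per_px
    minor = rp.axis_minor_length * pixel_scale_um_per_px
    if minor <= 0:
        raise DegenerateShapeError("mask is a line; minor axis is zero")
    return major, minor


def measure_image(
    image,
    pixel_scale_um_per_px,
    image_id="",
    **segment_kwargs,
) -> pd.DataFrame:
    """Segment and measure every ROI in one image.

    Returns a DataFrame with one row per ROI: centroid (px), axes (um), area.
    Group labels are attached later, either from a manual-curation table or,
    for synthetic fixtures, from the generator's ground truth.
    """
    rois = segment_rois(image, pixel_scale_um_per_px, image_id=image_id,
                        **segment_kwargs)
    rows = []
    for roi in rois:
        try:
            major, minor = measure_axes(roi, pixel_scale_um_per_px)
        except DegenerateShapeError:
            continue
        rows.append(
            {
                "image_id": image_id,
                "roi_label": roi.label,
                "center_x_px": roi.centroid_px[0],
                "center_y_px": roi.centroid_px[1],
                "area_px": int(roi.mask.sum()),
                "major_axis_um": major,
                "minor_axis_um": minor,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["image_id", "roi_label", "center_x_px", "center_y_px",
                 "area_px", "major_axis_um", "minor_axis_um"],
    )


def apply_curation(measured: pd.DataFrame, curation: pd.DataFrame) -> pd.DataFrame:
    """Apply a manual include/exclude + group-label table to measured ROIs.

    ``curation`` columns: image_id, roi_label, include (bool), group. ROIs
    absent from the table or marked ``include == False`` are dropped.
    """
    merged = measured.merge(curation, on=["image_id", "roi_label"], how="inner")
    merged = merged[merged["include"].astype(bool)]
    return merged.drop(columns=["include"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Cilia correction
# ---------------------------------------------------------------------------


def fit_cilia_correction(manual_lengths_um, auto_lengths_um, fit_intercept=False):
    """Regress manually measured (cilia-free) on automated ciliate lengths.

    Automated thresholding includes the cilia, so automated major axes
    overestimate ciliate body length; the fitted slope (default
    zero-intercept, a pure correction factor) maps automated lengths back to
    body lengths.
    """
    manual = np.asarray(manual_lengths_um, dtype=float)
    auto = np.asarray(auto_lengths_um, dtype=float)
    if manual.shape != auto.shape or manual.ndim != 1:
        raise InputError("manual and automatic lengths must be paired vectors")
    n = manual.size
    if n < 3:
        raise InputError(f"need at least 3 pairs, got {n}")
    if (manual <= 0).any() or (auto <= 0).any():
        raise InputError("lengths must be positive")
    if fit_intercept:
        slope, intercept = np.polyfit(auto, manual, 1)
    else:
        slope = float(manual @ auto / (auto @ auto))
        intercept = 0.0
    fitted = slope * auto + intercept
    ss_res = float(((manual - fitted) ** 2).sum())
    ss_tot = float(((manual - manual.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return CiliaCorrection(slope=float(slope), intercept_um=float(intercept),
                           n=n, r_squared=r2)


def apply_cilia_correction(measurement: CellMeasurement,
                           correction: CiliaCorrection) -> CellMeasurement:
    """Shrink a ciliate's major axis by the fitted correction.

    Dinoflagellates (and Tripos) pass through unchanged. Applying the
    correction twice is an error. Biovolume, if already computed, is
    recomputed from the corrected axes; carbon is reset (it depends on the
    carbon model and must be recomputed downstream).
    """
    if measurement.group != TAXON_CILIATE:
        return measurement
    if measurement.corrected:
        raise StateError("ciliate measurement already corrected")
    new_major = correction.slope * measurement.major_axis_um + correction.intercept_um
    new_major = max(new_major, measurement.minor_axis_um)
    out = replace(measurement, major_axis_um=new_major, corrected=True)
    if measurement.biovolume_um3 is not None:
        out.biovolume_um3 = biovolume_prolate_spheroid(
            out.major_axis_um, out.minor_axis_um
        )
        out.carbon_pg = None
    return out


# ---------------------------------------------------------------------------
# Biovolume, carbon, size classes
# ---------------------------------------------------------------------------


def biovolume_prolate_spheroid(major_axis_um, minor_axis_um):
    """V = (pi/6) * a * b^2 for a prolate spheroid with axes a >= b (um^3)."""
    a = np.asarray(major_axis_um, dtype=float)
    b = np.asarray(minor_axis_um, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise InputError("axes must be positive")
    if np.any(a < b):
        raise InputError("major axis must be >= minor axis")
    v = (math.pi / 6.0) * a * b * b
    return float(v) if np.isscalar(major_axis_um) else v


def carbon_from_volume(biovolume_um3, group, model: CarbonModel):
    """Allometric carbon content: pg C = c_scale * V^c_exp for the group."""
    v = np.asarray(biovolume_um3, dtype=float)
    if np.any(v <= 0):
        raise InputError("biovolume must be positive")
    if group not in model.coefficients:
        raise ConfigurationError(f"no carbon coefficients for group {group!r}")
    c_scale, c_exp = model.coefficients[group]
    c = c_scale * v**c_exp
    return float(c) if np.isscalar(biovolume_um3) else c


def classify_size_class(major_axis_um, threshold_um=20.0):
    """Two-way size classification on the (corrected) major axis.

    Exactly ``threshold_um`` goes to the large class.
    """
    if major_axis_um <= 0:
        raise InputError("length must be positive")
    return SIZE_CLASS_LARGE if major_axis_um >= threshold_um else SIZE_CLASS_SMALL


# ---------------------------------------------------------------------------
# Sample-level aggregation
# ---------------------------------------------------------------------------

#: pg per mL -> ug per L: 1 pg/mL = 1e-6 ug / 1e-3 L = 1e-3 ug/L
_PG_PER_ML_TO_UG_PER_L = 1e-3


def sample_biomass_table(
    cells,
    settled_volume_mL,
    sample_id="",
    metadata=None,
    size_threshold_um=20.0,
    low_count_floor=80,
) -> SampleQuantification:
    """Aggregate per-cell carbon into per-group, per-size-class biomass.

    Biomass per class is ``sum(carbon_pg) / settled_volume`` converted to
    ug C per litre. Cells labelled Tripos are excluded from the four group
    totals and reported separately (their sporadic occurrence is too
    influential on dinoflagellate totals). Samples with fewer cells than
    ``low_count_floor`` are flagged.
    """
    if not (1.0 <= settled_volume_mL <= 1000.0):
        raise InputError(
            f"settled volume {settled_volume_mL} mL outside plausible 1-1000 mL"
        )
    biomass = {g: 0.0 for g in GROUP_COLUMNS}
    counts = {g: 0 for g in GROUP_COLUMNS}
    tripos_c, tripos_n = 0.0, 0
    for cell in cells:
        if cell.carbon_pg is None:
            raise InputError("all cells must have carbon computed")
        if cell.group == TAXON_CILIATE and not cell.corrected:
            raise StateError(f"uncorrected ciliate in sample {sample_id!r}")
        if cell.group == TAXON_TRIPOS:
            tripos_c += cell.carbon_pg
            tripos_n += 1
            continue
        col = group_column(
            cell.group, classify_size_class(cell.major_axis_um, size_threshold_um)
        )
        biomass[col] += cell.carbon_pg
        counts[col] += 1
    factor = _PG_PER_ML_TO_UG_PER_L / settled_volume_mL
    biomass = {g: v * factor for g, v in biomass.items()}
    n_cells = sum(counts.values()) + tripos_n
    return SampleQuantification(
        sample_id=sample_id,
        settled_volume_mL=settled_volume_mL,
        biomass=biomass,
        counts=counts,
        tripos_biomass=tripos_c * factor,
        tripos_count=tripos_n,
        total_biomass=sum(biomass.values()),
        low_count=n_cells < low_count_floor,
        metadata=dict(metadata or {}),
    )


def cells_from_measurements(
    measured: pd.DataFrame,
    sample_id="",
    correction: CiliaCorrection | None = None,
    model: CarbonModel | None = None,
    group_col="group",
):
    """Build corrected, carbon-bearing :class:`CellMeasurement` objects.

    ``measured`` needs ``major_axis_um``, ``minor_axis_um`` and a group
    column. Ciliates are corrected when a correction is given; biovolume and
    carbon are computed for every cell.
    """
    model = model or default_carbon_model()
    cells = []
    for _, row in measured.iterrows():
        major, minor = float(row["major_axis_um"]), float(row["minor_axis_um"])
        cell = CellMeasurement(
            sample_id=sample_id,
            group=row[group_col],
            major_axis_um=max(major, minor),
            minor_axis_um=min(major, minor),
        )
        if correction is not None:
            cell = apply_cilia_correction(cell, correction)
        elif cell.group == TAXON_CILIATE:
            cell.corrected = True  # explicit no-op correction
        cell.biovolume_um3 = biovolume_prolate_spheroid(
            cell.major_axis_um, cell.minor_axis_um
        )
        cell.carbon_pg = carbon_from_volume(cell.biovolume_um3, cell.group, model)
        cells.append(cell)
    return cells


def quantification_to_frame(quants) -> pd.DataFrame:
    """Stack SampleQuantification results into a biomass table (ug C/L)."""
    rows = []
    for q in quants:
        row = {"sample_id": q.sample_id, **q.metadata}
        row.update(q.biomass)
        row["tripos"] = q.tripos_biomass
        row["total"] = q.total_biomass
        row["n_cells"] = sum(q.counts.values()) + q.tripos_count
        row["low_count"] = q.low_count
        rows.append(row)
    return pd.DataFrame(rows)
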