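"""Synthetic data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here: micrographs
of settled, Lugol's-stained protist cells; seasonal community biomass tables;
two-point dilution experiments; CTD profiles; and grazing-rate columns that
are biomass-dependent in winter only. Each generator is deterministic under a
fixed seed and, at zero noise, inverts exactly through the corresponding
analysis operation, which makes the whole pipeline testable end to end
without any field data.

Cells are rendered as filled dark-on-light ellipses (prolate spheroids seen
in 2D). Ciliates additionally carry a lower-contrast fringe extending the
apparent major axis, emulating cilia that are picked up by automated
thresholding but excluded from manual length measurements.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .micrograph import MIN_CELL_DIAMETER_UM
from .schema import (
    GROUP_COLUMNS,
    META_COLUMNS,
    REGIONS,
    SEASONS,
    TAXON_CILIATE,
    TAXON_DINO,
    InputError,
    PlacementError,
)

# ---------------------------------------------------------------------------
# Micrographs
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCellSpec:
    """One cell to render: position, body axes (um), orientation, taxon.

    ``cilia_fraction`` is the extra apparent length cilia add to the major
    axis (0.12 means the thresholded outline is 12% longer than the body).
    Dinoflagellates must have ``cilia_fraction == 0``.
    """

    center_px: tuple[float, float]
    major_axis_um: float
    minor_axis_um: float
    orientation_rad: float
    group: str
    cilia_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not (self.major_axis_um >= self.minor_axis_um > 0):
            raise InputError(
                f"need major >= minor > 0, got ({self.major_axis_um}, "
                f"{self.minor_axis_um})"
            )
        if self.cilia_fraction < 0:
            raise InputError("cilia_fraction must be >= 0")
        if self.group == TAXON_DINO and self.cilia_fraction != 0:
            raise InputError("dinoflagellates carry no cilia fringe")

    @property
    def apparent_major_um(self) -> float:
        """Major axis including the cilia fringe, as a threshold would see it."""
        return self.major_axis_um * (1.0 + self.cilia_fraction)


def _ellipse_coverage(shape, center, a_px, b_px, theta, supersample=4):
    """Fractional pixel coverage of an ellipse, by supersampling.

    Returns (rows, cols, coverage) for pixels in the ellipse's bounding box.
    Sub-pixel anti-aliasing matters because moment-based axis measurement is
    sensitive to boundary quantization.
    """
    cx, cy = center
    r_max = max(a_px, b_px) / 2.0 + 1.5
    r0 = max(int(math.floor(cy - r_max)), 0)
    r1 = min(int(math.ceil(cy + r_max)) + 1, shape[0])
    c0 = max(int(math.floor(cx - r_max)), 0)
    c1 = min(int(math.ceil(cx + r_max)) + 1, shape[1])
    if r0 >= r1 or c0 >= c1:
        return np.empty(0, int), np.empty(0, int), np.empty(0)

    ss = supersample
    offs = (np.arange(ss) + 0.5) / ss - 0.5
    rows = np.arange(r0, r1)
    cols = np.arange(c0, c1)
    yy = rows[:, None] + offs[None, :]  # (nr, ss)
    xx = cols[:, None] + offs[None, :]
    # subpixel grids relative to center
    dy = (yy.reshape(-1, 1, ss, 1) - cy)
    dx = (xx.reshape(1, -1, 1, ss) - cx)
    ct, st = math.cos(theta), math.sin(theta)
    u = (dx * ct + dy * st) / (a_px / 2.0)
    v = (-dx * st + dy * ct) / (b_px / 2.0)
    inside = (u * u + v * v) <= 1.0
    cov = inside.mean(axis=(2, 3))
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    keep = cov.ravel() > 0
    return rr.ravel()[keep], cc.ravel()[keep], cov.ravel()[keep]


def gen_micrograph(
    specs,
    image_size_px=(512, 512),
    pixel_scale_um_per_px=0.5,
    background_level=200.0,
    noise_sd=0.0,
    seed=None,
    cell_level=60.0,
    fringe_contrast=0.75,
    overlap_margin_px=2.0,
):
    """Render a synthetic micrograph and its ground-truth table.

    Cells are dark ellipses on a light background (Lugol's-like contrast).
    Ciliate specs get an additional fringe ellipse along the major axis only,
    at ``fringe_contrast`` times the cell's contrast, so a global threshold
    will normally absorb it into the ROI and over-measure the major axis by
    ``cilia_fraction`` — the mechanism the downstream cilia correction undoes.

    Returns ``(image, truth)`` where ``image`` is a float array and ``truth``
    a DataFrame with one row per spec (true axes in um, apparent major axis,
    centers in px).
    """
    ny, nx = image_size_px
    scale = float(pixel_scale_um_per_px)
    if scale <= 0:
        raise InputError("pixel scale must be positive")
    rng = np.random.default_rng(seed)
    image = np.full((ny, nx), float(background_level))

    # overlap / bounds rejection on apparent bounding circles
    radii = []
    for s in specs:
        r_px = s.apparent_major_um / scale / 2.0
        cx, cy = s.center_px
        if not (r_px <= cx <= nx - 1 - r_px and r_px <= cy <= ny - 1 - r_px):
            raise PlacementError(
                f"cell at {s.center_px} with apparent radius {r_px:.1f}px "
                "does not fit inside the frame"
            )
        radii.append(r_px)
    for (i, si), (j, sj) in itertools.combinations(enumerate(specs), 2):
        dx = si.center_px[0] - sj.center_px[0]
        dy = si.center_px[1] - sj.center_px[1]
        if math.hypot(dx, dy) < radii[i] + radii[j] + overlap_margin_px:
            raise PlacementError(f"cells {i} and {j} overlap")

    contrast = background_level - cell_level
    rows = []
    for idx, s in enumerate(specs):
        a_px = s.major_axis_um / scale
        b_px = s.minor_axis_um / scale
        if s.cilia_fraction > 0:
            fa_px = s.apparent_major_um / scale
            rr, cc, cov = _ellipse_coverage(
                image.shape, s.center_px, fa_px, b_px, s.orientation_rad
            )
            fringe_level = background_level - fringe_contrast * contrast
            np.minimum.at(
                image, (rr, cc),
                background_level - cov * (background_level - fringe_level),
            )
        rr, cc, cov = _ellipse_coverage(
            image.shape, s.center_px, a_px, b_px, s.orientation_rad
        )
        np.minimum.at(image, (rr, cc), background_level - cov * contrast)
        rows.append(
            {
                "cell_id": idx,
                "group": s.group,
                "center_x_px": s.center_px[0],
                "center_y_px": s.center_px[1],
                "major_axis_um": s.major_axis_um,
                "minor_axis_um": s.minor_axis_um,
                "apparent_major_um": s.apparent_major_um,
                "orientation_rad": s.orientation_rad,
                "cilia_fraction": s.cilia_fraction,
            }
        )
    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd, image.shape)
    truth = pd.DataFrame(
        rows,
        columns=[
            "cell_id", "group", "center_x_px", "center_y_px",
            "major_axis_um", "minor_axis_um", "apparent_major_um",
            "orientation_rad", "cilia_fraction",
        ],
    )
    return image, truth


def random_cell_specs(
    n_cells,
    image_size_px,
    pixel_scale_um_per_px,
    seed=None,
    size_range_um=(4.0, 200.0),
    aspect_range=(1.0, 3.0),
    ciliate_prob=0.35,
    cilia_fraction=0.12,
    max_attempts=20_000,
):
    """Randomly place non-overlapping cells; sizes log-uniform over the range.

    Raises :class:`PlacementError` when the field cannot accommodate the
    requested count within ``max_attempts`` rejections.
    """
    ny, nx = image_size_px
    scale = pixel_scale_um_per_px
    rng = np.random.default_rng(seed)
    lo, hi = size_range_um
    specs: list[SyntheticCellSpec] = []
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    attempts = 0
    while len(specs) < n_cells:
        attempts += 1
        if attempts > max_attempts:
            raise PlacementError(
                f"placed only {len(specs)}/{n_cells} cells after "
                f"{max_attempts} attempts"
            )
        major = math.exp(rng.uniform(math.log(lo), math.log(hi)))
        aspect = rng.uniform(*aspect_range)
        # keep the body area at or above a 4-um disk so every generated cell
        # clears the segmentation size floor
        min_minor = MIN_CELL_DIAMETER_UM**2 / major
        minor = min(max(major / aspect, min_minor), major)
        is_cil = rng.random() < ciliate_prob
        frac = cilia_fraction if is_cil else 0.0
        r_px = major * (1 + frac) / scale / 2.0 + 2.0
        cx = rng.uniform(r_px, nx - 1 - r_px)
        cy = rng.uniform(r_px, ny - 1 - r_px)
        ok = all(
            math.hypot(cx - px, cy - py) >= r_px + pr + 2.0
            for (px, py), pr in zip(centers, radii)
        )
        if not ok:
            continue
        specs.append(
            SyntheticCellSpec(
                center_px=(cx, cy),
                major_axis_um=major,
                minor_axis_um=minor,
                orientation_rad=rng.uniform(0, math.pi),
                group=TAXON_CILIATE if is_cil else TAXON_DINO,
                cilia_fraction=frac,
            )
        )
        centers.append((cx, cy))
        radii.append(r_px)
    return specs


def gen_magnification_batches(
    n_cells=200,
    seed=None,
    ciliate_prob=0.0,
    size_range_um=(4.0, 200.0),
    cut_um=25.0,
    small_scale_um_per_px=0.125,
    large_scale_um_per_px=0.5,
    field_px=2048,
    cells_per_field=40,
    **micrograph_kwargs,
):
    """Render a size-spanning sample as magnification batches.

    Mirrors settling-chamber practice: cells below ``cut_um`` are imaged at
    high magnification (``small_scale_um_per_px``), larger ones at low
    magnification, with however many fields each batch needs. The overall
    major-axis distribution is log-uniform over ``size_range_um``. Returns a
    list of ``(image, truth_table, pixel_scale)`` tuples covering ``n_cells``
    cells in total.
    """
    lo, hi = size_range_um
    if not (lo < cut_um < hi):
        raise InputError("cut_um must fall inside size_range_um")
    n_small = round(n_cells * math.log(cut_um / lo) / math.log(hi / lo))
    batches = []
    rng = np.random.default_rng(seed)
    plan = [
        (n_small, (lo, cut_um), small_scale_um_per_px),
        (n_cells - n_small, (cut_um, hi), large_scale_um_per_px),
    ]
    for n_batch, srange, scale in plan:
        remaining = n_batch
        while remaining > 0:
            n_field = min(cells_per_field, remaining)
            sub_seed = int(rng.integers(0, 2**31 - 1))
            specs = random_cell_specs(
                n_field, (field_px, field_px), scale, seed=sub_seed,
                size_range_um=srange, ciliate_prob=ciliate_prob,
            )
            image, truth = gen_micrograph(
                specs, (field_px, field_px), scale, seed=sub_seed + 1,
                **micrograph_kwargs,
            )
            batches.append((image, truth, scale))
            remaining -= n_field
    return batches


def match_to_truth(measured, truth, max_dist_px=20.0):
    """Join measured ROIs to ground-truth cells by nearest centroid.

    ``measured`` needs columns ``center_x_px``/``center_y_px``; returns the
    measured frame with the truth columns (suffix ``_true``) attached.
    Unmatched ROIs get NaN truth.
    """
    measured = measured.reset_index(drop=True)
    out = measured.copy()
    tx = truth["center_x_px"].to_numpy()
    ty = truth["center_y_px"].to_numpy()
    cols = ["group", "major_axis_um", "minor_axis_um", "apparent_major_um",
            "cilia_fraction"]
    for c in cols:
        out[c + "_true"] = np.nan if c != "group" else None
    for i, row in measured.iterrows():
        d = np.hypot(tx - row["center_x_px"], ty - row["center_y_px"])
        j = int(np.argmin(d))
        if d[j] <= max_dist_px:
            for c in cols:
                out.at[i, c + "_true"] = truth.at[j, c]
    return out


# ---------------------------------------------------------------------------
# Community biomass tables
# ---------------------------------------------------------------------------


@dataclass
class CommunityScenario:
    """Seasonal/regional community design with lognormal sampling noise.

    ``mean_total`` and ``proportions`` are keyed by ``(season, region)``;
    proportions are over the four biomass groups and must sum to 1. The
    default factory (:func:`default_scenario`) encodes the canonical shelf
    pattern: winter communities dominated by large dinoflagellates with
    higher total biomass, a summer shift toward small dinoflagellates, and
    aseasonal ciliates.
    """

    mean_total: dict
    proportions: dict
    sigma: float = 0.45
    n_years: int = 6
    start_year: int = 2018
    seed: int | None = None

    def __post_init__(self) -> None:
        for key in itertools.product(SEASONS, REGIONS):
            if key not in self.mean_total or key not in self.proportions:
                raise InputError(f"scenario missing cell {key}")
            if self.mean_total[key] <= 0:
                raise InputError(f"mean total must be > 0 at {key}")
            p = self.proportions[key]
            tot = sum(p[g] for g in GROUP_COLUMNS)
            if not math.isclose(tot, 1.0, rel_tol=0, abs_tol=1e-9):
                raise InputError(f"proportions at {key} sum to {tot}, not 1")
        if self.sigma < 0:
            raise InputError("sigma must be >= 0")


def default_scenario(sigma: float = 0.45, n_years: int = 6, seed=None):
    """Fig.-1-style community design: means in ug C/L, proportions per cell."""
    mean_total = {
        ("winter", "inner"): 11.0,
        ("winter", "mid"): 13.0,
        ("winter", "outer"): 7.0,
        ("summer", "inner"): 9.0,
        ("summer", "mid"): 4.0,
        ("summer", "outer"): 5.4,
    }
    winter_p = {"dino_small": 0.19, "dino_large": 0.55,
                "cil_small": 0.04, "cil_large": 0.22}
    proportions = {
        ("winter", "inner"): dict(winter_p),
        ("winter", "mid"): dict(winter_p),
        ("winter", "outer"): dict(winter_p),
        ("summer", "inner"): {"dino_small": 0.56, "dino_large": 0.25,
                              "cil_small": 0.03, "cil_large": 0.16},
        ("summer", "mid"): {"dino_small": 0.50, "dino_large": 0.23,
                            "cil_small": 0.05, "cil_large": 0.22},
        ("summer", "outer"): {"dino_small": 0.48, "dino_large": 0.21,
                              "cil_small": 0.05, "cil_large": 0.26},
    }
    return CommunityScenario(
        mean_total=mean_total, proportions=proportions,
        sigma=sigma, n_years=n_years, seed=seed,
    )


def _lognormal_factor(rng, sigma, size):
    """Mean-one multiplicative lognormal noise (exact at sigma = 0)."""
    if sigma == 0:
        return np.ones(size)
    return np.exp(rng.normal(0.0, sigma, size) - sigma**2 / 2.0)


def gen_community_table(scenario: CommunityScenario) -> pd.DataFrame:
    """One sample per (year, season, region); group biomass in ug C/L."""
    rng = np.random.default_rng(scenario.seed)
    rows = []
    for year in range(scenario.start_year, scenario.start_year + scenario.n_years):
        for season in SEASONS:
            for region in REGIONS:
                total = scenario.mean_total[(season, region)]
                props = scenario.proportions[(season, region)]
                noise = _lognormal_factor(rng, scenario.sigma, len(GROUP_COLUMNS))
                row = {"year": year, "season": season, "region": region}
                for g, f in zip(GROUP_COLUMNS, noise):
                    row[g] = total * props[g] * f
                rows.append(row)
    return pd.DataFrame(rows, columns=list(META_COLUMNS) + list(GROUP_COLUMNS))


def plant_composition_outliers(table, scenario, events, total_factor=1.0):
    """Overwrite listed samples with the opposite season's composition.

    ``events`` is a list of (year, season, region). The sample keeps (or
    rescales, via ``total_factor``) its stratum-mean total biomass but takes
    the group proportions of the *other* season — the kind of compositional
    anomaly the RDA-space centroid rule is meant to flag. Returns a copy with
    a boolean ``planted_outlier`` column.
    """
    out = table.copy()
    out["planted_outlier"] = False
    for year, season, region in events:
        mask = (
            (out["year"] == year)
            & (out["season"] == season)
            & (out["region"] == region)
        )
        if not mask.any():
            raise InputError(f"no sample for event {(year, season, region)}")
        opposite = "summer" if season == "winter" else "winter"
        props = scenario.proportions[(opposite, region)]
        total = scenario.mean_total[(season, region)] * total_factor
        for g in GROUP_COLUMNS:
            out.loc[mask, g] = total * props[g]
        out.loc[mask, "planted_outlier"] = True
    return out


def gen_environment_table(table, seed=None, noise_scale=1.0):
    """Season/region-structured environmental covariates per sample.

    Emulates the shelf's light, nutrient and salinity climate: percentage of
    small (<10 um) chlorophyll high in summer (~82%) and low in winter
    (~30%); MLD deep in winter and shallow in summer, deepening offshore;
    nitrate+nitrite high in winter offshore and depleted in summer; salinity
    increasing from coast to shelf break in both seasons.
    """
    rng = np.random.default_rng(seed)
    mld_winter = {"inner": 30.0, "mid": 60.0, "outer": 120.0}
    mld_ratio = {"inner": 3.0, "mid": 6.0, "outer": 8.0}
    no3_winter = {"inner": 0.4, "mid": 2.0, "outer": 4.1}
    salinity = {"inner": 32.0, "mid": 33.0, "outer": 34.0}
    rows = []
    for _, s in table.iterrows():
        season, region = s["season"], s["region"]
        winter = season == "winter"
        pct = 30.0 if winter else 82.0
        pct = float(np.clip(pct + rng.normal(0, 8.0 * noise_scale), 1.0, 99.0))
        mld = mld_winter[region] / (1.0 if winter else mld_ratio[region])
        mld = float(mld * _lognormal_factor(rng, 0.2 * noise_scale, 1)[0])
        no3 = no3_winter[region] if winter else 0.05
        no3 = max(no3 + rng.normal(0, 0.5 * noise_scale * (1.0 if winter else 0.1)), 0.0)
        sal = salinity[region] + rng.normal(0, 0.3 * noise_scale)
        rows.append(
            {"year": s["year"], "season": season, "region": region,
             "pct_chl_small": pct, "mld_m": mld,
             "nitrate_nitrite_umol": no3, "salinity": sal}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Dilution experiments
# ---------------------------------------------------------------------------


@dataclass
class DilutionTruth:
    """Ground truth for a two-point dilution experiment.

    ``mu_true`` is the nutrient-amended phytoplankton growth rate (1/d),
    ``g_true`` the grazing mortality (1/d). ``mu_unamended`` lets nutrient
    limitation be simulated (defaults to ``mu_true``: no limitation).
    ``noise_cv`` is the coefficient of variation of each chlorophyll
    subsample reading (multiplicative lognormal).
    """

    mu_true: float = 0.5
    g_true: float = 0.3
    chl0_wsw: float = 2.0
    dilution_target: float = 0.2
    noise_cv: float = 0.05
    n_bottles: int = 2
    n_subsamples: int = 3
    mu_unamended: float | None = None
    duration_days: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.chl0_wsw <= 0:
            raise InputError("chl0_wsw must be > 0")
        if not (0 < self.dilution_target < 1):
            raise InputError("dilution_target must lie in (0, 1)")
        if self.g_true < 0:
            raise InputError("g_true must be >= 0")
        if self.noise_cv < 0 or self.n_bottles < 2 or self.n_subsamples < 1:
            raise InputError("invalid replication or noise design")


TREATMENTS = ("WSW_amended", "WSW_unamended", "DIL_amended")


def gen_dilution_experiment(truth: DilutionTruth, experiment_id="exp") -> pd.DataFrame:
    """Long-format bottle/subsample chlorophyll table for one experiment.

    Initial (t0) readings are subsample triplicates from the two carboys
    (whole seawater and diluted); 24-h readings are per incubation bottle.
    Apparent growth follows ``chl24 = chl0 * exp((mu - x*g) * t)`` with
    ``x = 1`` for whole seawater and ``x = dilution_target`` for the diluted
    treatment; every reading then gets mean-one lognormal noise.
    """
    rng = np.random.default_rng(truth.seed)
    sigma = math.sqrt(math.log(1.0 + truth.noise_cv**2)) if truth.noise_cv else 0.0
    mu_un = truth.mu_true if truth.mu_unamended is None else truth.mu_unamended
    chl0 = {
        "WSW_amended": truth.chl0_wsw,
        "WSW_unamended": truth.chl0_wsw,
        "DIL_amended": truth.chl0_wsw * truth.dilution_target,
    }
    k = {
        "WSW_amended": truth.mu_true - truth.g_true,
        "WSW_unamended": mu_un - truth.g_true,
        "DIL_amended": truth.mu_true - truth.dilution_target * truth.g_true,
    }
    rows = []

    def emit(treatment, bottle, timepoint, value_true):
        noise = _lognormal_factor(rng, sigma, truth.n_subsamples)
        for sub, f in enumerate(noise, start=1):
            rows.append(
                {"experiment_id": experiment_id, "treatment": treatment,
                 "bottle": bottle, "subsample": sub,
                 "timepoint_h": timepoint,
                 "chl_ug_per_L": value_true * f}
            )

    for trt in TREATMENTS:
        emit(trt, "carboy", 0, chl0[trt])
    for trt in TREATMENTS:
        for b in range(1, truth.n_bottles + 1):
            chl24 = chl0[trt] * math.exp(k[trt] * truth.duration_days)
            emit(trt, f"{trt}_b{b}", 24, chl24)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CTD profiles
# ---------------------------------------------------------------------------


def gen_ctd_profile(
    mld_true_m=25.0,
    kd_true_per_m=0.1,
    surface_temp=12.0,
    temp_drop=4.0,
    surface_par=1000.0,
    beam_atten_mean=0.4,
    n_depths=50,
    max_depth_m=100.0,
    temp_noise_sd=0.0,
    par_noise_cv=0.0,
    beam_noise_sd=0.0,
    thermocline_grad_per_m=0.02,
    day=True,
    seed=None,
) -> pd.DataFrame:
    """Depth profile with a known MLD (step thermocline) and a known Kd.

    Temperature is constant down to ``mld_true_m``, drops by ``temp_drop``
    just below it, then keeps cooling at a slow linear gradient. PAR decays
    as ``surface_par * exp(-kd * z)``. Beam attenuation is constant plus
    optional Gaussian noise. Set ``temp_drop=0`` for an isothermal profile
    (MLD unresolvable).
    """
    if not (0 < mld_true_m < max_depth_m):
        raise InputError("mld_true_m must lie inside the profile depth range")
    rng = np.random.default_rng(seed)
    z = np.linspace(1.0, max_depth_m, n_depths)
    temp = np.full(n_depths, float(surface_temp))
    below = z > mld_true_m
    temp[below] = surface_temp - temp_drop - thermocline_grad_per_m * (
        z[below] - mld_true_m
    )
    if temp_noise_sd > 0:
        temp = temp + rng.normal(0, temp_noise_sd, n_depths)
    par = surface_par * np.exp(-kd_true_per_m * z)
    if par_noise_cv > 0:
        s = math.sqrt(math.log(1 + par_noise_cv**2))
        par = par * np.exp(rng.normal(0, s, n_depths) - s**2 / 2)
    beam = np.full(n_depths, float(beam_atten_mean))
    if beam_noise_sd > 0:
        beam = beam + rng.normal(0, beam_noise_sd, n_depths)
    return pd.DataFrame(
        {
            "depth_m": z,
            "temperature_C": temp,
            "par_umol": par,
            "beam_attenuation_per_m": beam,
            "day_night": "day" if day else "night",
        }
    )


# ---------------------------------------------------------------------------
# Grazing rates
# ---------------------------------------------------------------------------


def gen_grazing_rates(
    biomass_table,
    winter_slope=0.02,
    winter_r_target=0.75,
    summer_mean=0.25,
    summer_sd=0.12,
    winter_intercept=0.10,
    noise_sd=None,
    seed=None,
) -> pd.Series:
    """Grazing-rate column: biomass-dependent in winter, independent in summer.

    Winter rates are ``intercept + slope * total_biomass + eps`` where the
    noise SD is either given (``noise_sd``) or back-computed so the expected
    winter Pearson correlation is ``winter_r_target``. Summer rates are drawn
    independently of biomass. Rates are clipped at zero (grazing mortality is
    non-negative).

    The default target correlation (0.75) is set by power: a six-year,
    two-season, three-region design yields ~18 winter samples, where the
    5%-level detection threshold is r ~ 0.47; 0.75 makes the winter
    dependence detectable in ~95% of realizations while summer independence
    keeps the summer correlation null.
    """
    rng = np.random.default_rng(seed)
    total = biomass_table[list(GROUP_COLUMNS)].sum(axis=1).to_numpy()
    season = biomass_table["season"].to_numpy()
    rates = np.empty(len(biomass_table))

    winter = season == "winter"
    signal = winter_intercept + winter_slope * total[winter]
    if noise_sd is None:
        if not (0 < winter_r_target <= 1):
            raise InputError("winter_r_target must lie in (0, 1]")
        sd_sig = winter_slope * np.std(total[winter], ddof=1) if winter.sum() > 1 else 0.0
        noise_sd = sd_sig * math.sqrt(1.0 / winter_r_target**2 - 1.0)
    rates[winter] = signal + rng.normal(0, noise_sd, winter.sum())
    rates[~winter] = rng.normal(summer_mean, summer_sd, (~winter).sum())
    return pd.Series(np.clip(rates, 0.0, None), index=biomass_table.index,
                     name="grazing_rate")
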