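"""Mixed-layer, light-attenuation, and chlorophyll size-fraction derivations.

Mixed layer depth (MLD) follows a temperature-threshold criterion: the
shallowest sampled depth whose temperature differs from the surface reference
by more than 0.5 degC (absolute difference, so winter inversions count). The
diffuse attenuation coefficient Kd comes from a log-linear fit of daytime PAR
profiles, or from a beam-attenuation calibration for nighttime casts. The
mean mixed-layer light is

    I_m = I0 * (1 - exp(-Kd * MLD)) / (Kd * MLD)

the depth average of exponentially attenuated surface irradiance over the
mixed layer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .schema import InputError


@dataclass
class MldResult:
    mld_m: float  # NaN when unresolved
    resolved: bool
    ref_temp_C: float


@dataclass
class KdFit:
    kd_per_m: float
    r_squared: float
    n: int
    z_min: float
    z_max: float


@dataclass
class BeamKdCalibration:
    """Linear map kd = slope * beam + intercept fitted on daytime casts."""

    slope: float
    intercept: float
    r_squared: float
    n: int
    beam_range: tuple

    def predict(self, beam_value):
        """Apply the calibration; flags extrapolation beyond the fitted range."""
        lo, hi = self.beam_range
        extrapolated = not (lo <= beam_value <= hi)
        return float(self.slope * beam_value + self.intercept), extrapolated


@dataclass
class ChlSizeFractions:
    chl_total: float  # GF/F, ug/L
    chl_large: float  # >10 um, ug/L
    chl_small: float  # difference, clamped at 0
    pct_small: float
    clamped: bool = False


@dataclass
class LightClimate:
    surface_par_I0: float
    kd_per_m: float
    mld_m: float
    im: float


def _validate_profile(profile: pd.DataFrame):
    z = profile["depth_m"].to_numpy(dtype=float)
    if z.size < 2:
        raise InputError("profile needs at least 2 depth levels")
    if not np.all(np.diff(z) > 0):
        raise InputError("depths must be strictly increasing")
    return z


def mixed_layer_depth(profile: pd.DataFrame, delta_T=0.5, ref_depth_m=5.0,
                      interpolate=False) -> MldResult:
    """Shallowest sampled depth whose |T - T_surface| exceeds ``delta_T``.

    The surface reference is the mean temperature over all bins at or above
    ``ref_depth_m``. By default the rule returns a sampled depth (no
    interpolation between bins); ``interpolate=True`` instead interpolates
    linearly to the exact threshold crossing between the bracketing bins.
    Returns an unresolved result when the criterion is never met.
    """
    z = _validate_profile(profile)
    temp = profile["temperature_C"].to_numpy(dtype=float)
    surface = temp[z <= ref_depth_m]
    if surface.size == 0:
        raise InputError(
            f"profile has no levels at or above the {ref_depth_m} m reference"
        )
    ref = float(surface.mean())
    diff = np.abs(temp - ref)
    exceed = np.flatnonzero(diff > delta_T)
    if exceed.size == 0:
        return MldResult(mld_m=float("nan"), resolved=False, ref_temp_C=ref)
    i = int(exceed[0])
    if interpolate and i > 0:
        z0, z1 = z[i - 1], z[i]
        d0, d1 = diff[i - 1], diff[i]
        frac = (delta_T - d0) / (d1 - d0) if d1 != d0 else 1.0
        return MldResult(mld_m=float(z0 + frac * (z1 - z0)), resolved=True,
                         ref_temp_C=ref)
    return MldResult(mld_m=float(z[i]), resolved=True, ref_temp_C=ref)


def kd_from_par(profile: pd.DataFrame, z_min=0.0, z_max=None,
                euphotic_fraction=0.01) -> KdFit:
    """Kd as minus the OLS slope of ln(PAR) on depth over a window.

    The default window runs from the surface to the depth where PAR first
    falls below ``euphotic_fraction`` (1%) of its shallowest value. Depths
    with non-positive PAR are dropped with a warning; at least 3 positive
    readings are required.
    """
    z = _validate_profile(profile)
    par = profile["par_umol"].to_numpy(dtype=float)
    if z_max is None:
        positive = par > 0
        if not positive.any():
            raise InputError("profile has no positive PAR readings")
        surf_par = par[positive][0]
        below = np.flatnonzero(positive & (par < euphotic_fraction * surf_par))
        z_max = float(z[below[0]]) if below.size else float(z[-1])
    window = (z >= z_min) & (z <= z_max)
    zw, pw = z[window], par[window]
    bad = pw <= 0
    if bad.any():
        warnings.warn(
            f"dropping {int(bad.sum())} non-positive PAR readings from the "
            "Kd window",
            stacklevel=2,
        )
        zw, pw = zw[~bad], pw[~bad]
    if zw.size < 3:
        raise InputError(
            f"need at least 3 positive PAR readings in [{z_min}, {z_max}] m"
        )
    ln_par = np.log(pw)
    if np.ptp(ln_par) == 0:  # constant PAR: no attenuation
        return KdFit(kd_per_m=0.0, r_squared=float("nan"), n=zw.size,
                     z_min=float(zw[0]), z_max=float(zw[-1]))
    fit = stats.linregress(zw, ln_par)
    return KdFit(
        kd_per_m=float(-fit.slope),
        r_squared=float(fit.rvalue**2),
        n=zw.size,
        z_min=float(zw[0]),
        z_max=float(zw[-1]),
    )


def fit_kd_beam_calibration(kd_values, beam_values) -> BeamKdCalibration:
    """Calibrate kd against 0-10 m mean beam attenuation (daytime casts)."""
    kd = np.asarray(kd_values, dtype=float)
    beam = np.asarray(beam_values, dtype=float)
    if kd.shape != beam.shape or kd.ndim != 1:
        raise InputError("kd and beam values must be paired vectors")
    if kd.size < 3:
        raise InputError(f"need at least 3 calibration pairs, got {kd.size}")
    fit = stats.linregress(beam, kd)
    return BeamKdCalibration(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=kd.size,
        beam_range=(float(beam.min()), float(beam.max())),
    )


def kd_from_beam(calibration: BeamKdCalibration, beam_value):
    """Predict Kd for a nighttime cast from its mean 0-10 m beam attenuation.

    Returns ``(kd, extrapolated)`` where the flag marks beam values outside
    the calibration range.
    """
    return calibration.predict(beam_value)


def mean_mixed_layer_light(I0, kd_per_m, mld_m):
    """Depth-mean irradiance over the mixed layer.

    I_m = I0 * (1 - exp(-Kd*MLD)) / (Kd*MLD); a series branch covers the
    optically thin limit Kd*MLD -> 0 (where I_m -> I0) to avoid 0/0.
    """
    if I0 <= 0 or kd_per_m <= 0 or mld_m <= 0:
        raise InputError("I0, Kd and MLD must all be positive")
    x = kd_per_m * mld_m
    if x < 1e-6:
        return I0 * (1.0 - x / 2.0 + x * x / 6.0)
    return I0 * (1.0 - math.exp(-x)) / x


def light_climate(I0, kd_per_m, mld_m) -> LightClimate:
    """Bundle surface PAR, Kd, MLD and the derived I_m."""
    return LightClimate(
        surface_par_I0=float(I0),
        kd_per_m=float(kd_per_m),
        mld_m=float(mld_m),
        im=mean_mixed_layer_light(I0, kd_per_m, mld_m),
    )


def chl_size_fractions(chl_gff_reps, chl_10um_reps) -> ChlSizeFractions:
    """Small-fraction chlorophyll from GF/F total and >10 um filter readings.

    chl_small = chl_total - chl_large, clamped at zero (with a flag) when the
    large-fraction reading exceeds the total; pct_small is the small share of
    the total in percent.
    """
    total_reps = np.atleast_1d(np.asarray(chl_gff_reps, dtype=float))
    large_reps = np.atleast_1d(np.asarray(chl_10um_reps, dtype=float))
    if total_reps.size == 0 or large_reps.size == 0:
        raise InputError("need at least one reading per filter type")
    if np.any(total_reps <= 0) or np.any(large_reps < 0):
        raise InputError("chlorophyll readings must be positive")
    total = float(total_reps.mean())
    large = float(large_reps.mean())
    small = total - large
    clamped = small < 0
    if clamped:
        small = 0.0
    return ChlSizeFractions(
        chl_total=total,
        chl_large=large,
        chl_small=small,
        pct_small=100.0 * small / total,
        clamped=clamped,
    )
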