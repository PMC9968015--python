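"""Gas-concentration arithmetic and dose-response calibration with LOD.

Headspace concentrations from liquid injection
----------------------------------------------
Injecting V1 microlitres of a pure volatile liquid (purity p, density d g/mL,
molecular weight M g/mol) into a sealed container of V2 litres gives a vapour
concentration, in ppm, of

    c = 22.4 * p * d * V1 / (M * V2)

(22.4 L/mol is the molar volume of an ideal gas at STP). The formula is
implemented exactly in this printed form. Note that strict dimensional
analysis of microlitre/(g/mol * L) would carry an extra factor of 10^3 to land
on a volume-ppm scale; ``physical_units=True`` applies that factor for users
who want the dimensionally consistent variant, while the default reproduces
the printed convention.

Dose-response calibration
-------------------------
Paper-sensor colour responses saturate at low ppm, so the calibration curve is
fit with a rectangular-hyperbola (Langmuir) form

    r(c) = baseline + r_max * c / (K + c)

by least squares. The linear range is detected as the widest window of
consecutive concentrations, anchored at the lowest one, whose ordinary linear
fit reaches R^2 >= 0.98 (configurable); the limit of detection follows the
ICH-style convention LOD = 3.3 * sigma / slope with sigma the residual sd of
that linear fit. Concentration estimates for unknown samples invert the
Langmuir form analytically and are flagged when they exceed the linear range
(saturated, qualitative only).
"""

from __future__ import annotations

import json
import math
import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "GasSpec",
    "CalibrationModel",
    "InversionResult",
    "TRANS_2_HEXENAL",
    "gas_ppm",
    "injection_volume_for_ppm",
    "fit_calibration",
    "invert_concentration",
]

MOLAR_VOLUME_STP = 22.4  # L/mol


@dataclass(frozen=True)
class GasSpec:
    """Physical constants of a volatile analyte used in Eq.-of-state arithmetic."""

    name: str
    molecular_weight: float  # g/mol
    density: float  # g/mL of the injected liquid
    purity: float = 1.0  # mass fraction in (0, 1]

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError(f"molecular_weight must be > 0, got {self.molecular_weight}")
        if self.density <= 0:
            raise ValueError(f"density must be > 0, got {self.density}")
        if not 0 < self.purity <= 1:
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")


#: trans-2-hexenal, the green-leaf-volatile target analyte (liquid density
#: ~0.85 g/mL, M = 98.14 g/mol).
TRANS_2_HEXENAL = GasSpec("trans-2-hexen-1-al", molecular_weight=98.14, density=0.85)


def gas_ppm(
    injected_volume: float,
    gas: GasSpec,
    container_volume: float,
    physical_units: bool = False,
) -> float:
    """Headspace concentration (ppm) from an injected liquid volume (uL).

    ``container_volume`` is in litres. ``physical_units=True`` applies the
    10^3 factor required for dimensional consistency on a volume-ppm scale
    (see module docstring); the default follows the printed convention.
    """
    if injected_volume < 0:
        raise ValueError(f"injected volume must be >= 0, got {injected_volume}")
    if container_volume <= 0:
        raise ValueError(f"container volume must be > 0, got {container_volume}")
    c = (
        MOLAR_VOLUME_STP
        * gas.purity
        * gas.density
        * injected_volume
        / (gas.molecular_weight * container_volume)
    )
    if physical_units:
        c *= 1e3
    return c


def injection_volume_for_ppm(
    target: float,
    gas: GasSpec,
    container_volume: float,
    physical_units: bool = False,
) -> float:
    """Liquid volume (uL) to inject for a target headspace concentration (ppm).

    Exact algebraic inverse of :func:`gas_ppm`.
    """
    if target < 0:
        raise ValueError(f"target concentration must be >= 0, got {target}")
    if container_volume <= 0:
        raise ValueError(f"container volume must be > 0, got {container_volume}")
    v = (
        target
        * gas.molecular_weight
        * container_volume
        / (MOLAR_VOLUME_STP * gas.purity * gas.density)
    )
    if physical_units:
        v /= 1e3
    return v


@dataclass
class CalibrationModel:
    """Fitted saturating dose-response curve with linear range and LOD."""

    response_max: float  # Langmuir plateau above baseline (distance units)
    half_saturation: float  # ppm at half the plateau
    baseline: float  # response at zero concentration
    linear_range: tuple[float, float]  # (low ppm, high ppm)
    linear_slope: float  # response per ppm on the linear window
    linear_intercept: float
    residual_sd: float  # sd of linear-window residuals, response units
    lod: float  # ppm
    concentrations_used: list[float]
    lod_k: float = 3.3
    r_squared_linear: float = float("nan")
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.response_max <= 0 or self.half_saturation <= 0:
            raise ValueError("response_max and half_saturation must be > 0")
        if not self.linear_range[0] < self.linear_range[1]:
            raise ValueError(f"degenerate linear range {self.linear_range}")

    def predict(self, concentration) -> np.ndarray | float:
        """Langmuir prediction; strictly increasing in concentration."""
        c = np.asarray(concentration, dtype=float)
        r = self.baseline + self.response_max * c / (self.half_saturation + c)
        return float(r) if np.isscalar(concentration) else r

    def to_json(self, path) -> None:
        doc = {
            "response_max": self.response_max,
            "half_saturation_ppm": self.half_saturation,
            "baseline": self.baseline,
            "linear_range_ppm": list(self.linear_range),
            "linear_slope_per_ppm": self.linear_slope,
            "linear_intercept": self.linear_intercept,
            "residual_sd": self.residual_sd,
            "lod_ppm": self.lod,
            "lod_k": self.lod_k,
            "r_squared_linear": self.r_squared_linear,
            "concentrations_used_ppm": self.concentrations_used,
            "warnings": self.warnings,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _linear_fit(c: np.ndarray, r: np.ndarray) -> tuple[float, float, float, float]:
    """OLS fit r = a*c + b; returns (slope, intercept, r_squared, residual_sd)."""
    slope, intercept = np.polyfit(c, r, 1)
    pred = slope * c + intercept
    ss_res = float(np.sum((r - pred) ** 2))
    ss_tot = float(np.sum((r - r.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    dof = max(len(c) - 2, 1)
    return float(slope), float(intercept), r2, math.sqrt(ss_res / dof)


def fit_calibration(
    concentrations,
    responses,
    lod_k: float = 3.3,
    r2_threshold: float = 0.98,
    min_window: int = 3,
) -> CalibrationModel:
    """Fit the Langmuir dose-response and derive linear range, slope and LOD.

    ``concentrations`` and ``responses`` are parallel arrays; replicates are
    simply repeated concentration values. Requires at least four distinct
    concentrations and non-negative responses. The linear window always starts
    at the lowest concentration and must span at least ``min_window`` distinct
    concentrations; if even the smallest window misses ``r2_threshold`` it is
    used anyway and a warning is recorded.
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    if c.shape != r.shape or c.ndim != 1:
        raise ValueError("concentrations and responses must be parallel 1-D arrays")
    unique = np.unique(c)
    if unique.size < 4:
        raise ValueError(f"need >= 4 distinct concentrations, got {unique.size}")
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")
    if np.any(r < 0):
        raise ValueError("responses must be >= 0")

    fit_warnings: list[str] = []

    # replicate means per concentration, for monotonicity diagnostics
    means = np.array([r[c == u].mean() for u in unique])
    pooled_sd = float(np.mean([r[c == u].std(ddof=0) for u in unique]))
    drops = np.diff(means) < -max(pooled_sd, 1e-12)
    if np.any(drops):
        at = unique[1:][drops]
        fit_warnings.append(
            f"mean response decreases beyond noise tolerance at concentration(s) {at.tolist()}"
        )

    # Langmuir least squares
    r_span = max(r.max() - r.min(), 1e-9)
    p0 = (max(r.min(), 1e-6), r_span, float(np.median(unique[unique > 0])) or 1.0)
    bounds = ([0.0, 1e-9, 1e-9], [max(r.max(), 1e-6), 1e4 * r_span, 1e4 * max(unique.max(), 1.0)])
    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                lambda x, b, rmax, k: b + rmax * x / (k + x),
                c,
                r,
                p0=p0,
                bounds=bounds,
                maxfev=20000,
            )
    except RuntimeError as exc:
        raise RuntimeError(
            f"Langmuir fit did not converge: {exc}; concentrations={unique.tolist()}"
        ) from exc
    baseline, response_max, half_saturation = (float(v) for v in popt)

    # linear range: widest low-anchored window of distinct concentrations with
    # an acceptable ordinary linear fit
    window = None
    for end in range(unique.size, min_window - 1, -1):
        sel = np.isin(c, unique[:end])
        slope, intercept, r2, resid_sd = _linear_fit(c[sel], r[sel])
        if r2 >= r2_threshold:
            window = (end, slope, intercept, r2, resid_sd)
            break
    if window is None:
        end = min_window
        sel = np.isin(c, unique[:end])
        slope, intercept, r2, resid_sd = _linear_fit(c[sel], r[sel])
        window = (end, slope, intercept, r2, resid_sd)
        fit_warnings.append(
            f"no low-anchored window reached R^2 >= {r2_threshold}; "
            f"using the minimal {min_window}-point window (R^2 = {r2:.4f})"
        )
    end, slope, intercept, r2, resid_sd = window
    if slope <= 0:
        fit_warnings.append("non-positive linear slope; LOD undefined")
        lod = float("inf")
    else:
        lod = lod_k * resid_sd / slope

    return CalibrationModel(
        response_max=response_max,
        half_saturation=half_saturation,
        baseline=baseline,
        linear_range=(float(unique[0]), float(unique[end - 1])),
        linear_slope=slope,
        linear_intercept=intercept,
        residual_sd=resid_sd,
        lod=lod,
        concentrations_used=unique.tolist(),
        lod_k=lod_k,
        r_squared_linear=r2,
        warnings=fit_warnings,
    )


@dataclass(frozen=True)
class InversionResult:
    """Concentration estimate with a validity flag.

    flag is one of ``"ok"``, ``"saturated"`` (estimate above the linear range:
    qualitative only) or ``"out-of-range"`` (response at or above the Langmuir
    plateau; no finite estimate exists and ``ppm`` is None).
    """

    ppm: float | None
    flag: str


def invert_concentration(model: CalibrationModel, response: float) -> InversionResult:
    """Analytic inverse of the Langmuir curve: c = K (r-b) / (r_max - (r-b)).

    A response at/above the plateau is flagged out-of-range rather than
    extrapolated; a response below baseline maps to 0 ppm.
    """
    if response < 0:
        raise ValueError(f"response must be >= 0, got {response}")
    excess = response - model.baseline
    if excess >= model.response_max:
        return InversionResult(ppm=None, flag="out-of-range")
    if excess <= 0:
        return InversionResult(ppm=0.0, flag="ok")
    c = model.half_saturation * excess / (model.response_max - excess)
    flag = "saturated" if c > model.linear_range[1] else "ok"
    return InversionResult(ppm=float(c), flag=flag)
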