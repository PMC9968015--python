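"""Forward simulator for colorimetric sensor-array experiments.

Generates every input the analysis pipeline consumes — dye x gas screening
exposures, dose-response calibration series, and multi-day plant-stress time
courses — from a planted, fully known ground truth, so that every downstream
estimator can be checked against the values it should recover.

Response model
--------------
Each (dye, gas) pair has a planted maximal response magnitude (``affinity``),
a half-saturation concentration (ppm) and a fixed unit direction in RGB
space. Exposure to a gas mixture moves a dye spot's colour from its control
baseline by the vector sum of per-gas Langmuir magnitudes

    magnitude(c) = affinity * c / (half_saturation + c)

along the per-gas directions. Directions have non-positive components: dye
spots on pale paper darken on exposure, which also keeps default responses
inside the sensor range (clipping events are counted, never silent).
Measurement noise has two planted parts: independent Gaussian strip noise
(``noise_sd`` per channel, applied to test and control strips alike — strip
manufacturing variability dominates) and small instrument read noise
(``read_noise_sd``) on each of the 10 raw sensor reads per spot.

Each dye is assigned one "preferred" gas whose affinity exceeds all others by
the ``selectivity_contrast`` factor; among dyes sharing a preferred gas, the
planted affinities are strictly rank-ordered so "the best dye for gas g" is
well defined in the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arraydata import (
    READINGS_COLUMNS,
    DyeFormulation,
    ExposureRecord,
    RGBReading,
    SensorPanel,
)

__all__ = [
    "DEFAULT_GASES",
    "SyntheticGroundTruth",
    "EmissionProfile",
    "generate_ground_truth",
    "panel_from_truth",
    "expected_magnitude",
    "simulate_exposure",
    "simulate_mixture",
    "simulate_screen",
    "simulate_calibration_series",
    "simulate_plant_timecourse",
    "default_stress_profiles",
]

#: Screening gas set: the target green-leaf volatile first, then the humidity
#: interferent, simple organics, and the two indole biomarkers.
DEFAULT_GASES = [
    "trans-2-hexen-1-al",
    "water",
    "ethanol",
    "acetone",
    "acetic acid",
    "auxin",
    "tryptophol",
]

N_RAW_READS = 10  # raw colour-sensor reads per spot per measurement


@dataclass
class SyntheticGroundTruth:
    """Planted parameters fully determining the simulated sensor behaviour."""

    dyes: list[str]
    gases: list[str]
    affinity: np.ndarray  # (dyes, gases) maximal response magnitudes
    half_saturation: np.ndarray  # (dyes, gases) ppm
    direction: np.ndarray  # (dyes, gases, 3) unit vectors in RGB space
    noise_sd: float  # per-channel strip noise sd, counts
    read_noise_sd: float  # per-channel raw-read noise sd, counts
    humidity_affinity: np.ndarray  # (dyes,) response magnitude to water vapour
    control_rgb: np.ndarray  # (dyes, 3) unexposed baseline colour
    seed: int
    preferred_gas: list[str] = field(default_factory=list)
    sensor_max: float = 255.0
    clip_events: int = 0  # incremented whenever a simulated channel is clipped

    def gas_index(self, gas: str) -> int:
        try:
            return self.gases.index(gas)
        except ValueError:
            raise ValueError(f"unknown gas {gas!r}; truth knows {self.gases}") from None

    def dye_indices(self, dye_ids: list[str]) -> np.ndarray:
        return np.array([self.dyes.index(d) for d in dye_ids])


def generate_ground_truth(
    n_dyes: int,
    gases: list[str] | None = None,
    seed: int = 0,
    selectivity_contrast: float = 4.0,
    base_affinity: float = 40.0,
    noise_sd: float = 1.0,
    read_noise_sd: float = 0.3,
    sensor_max: float = 255.0,
) -> SyntheticGroundTruth:
    """Plant a reproducible dye x gas affinity structure.

    Dye ``i`` prefers ``gases[i % n_gases]``; its affinity for that gas is
    ``selectivity_contrast * base_affinity`` (shrunk by 1.3 for each further
    dye sharing the same preferred gas, so per-gas rankings are strict), with
    half-saturation near 5 ppm. Off-target affinities are a sub-unit fraction
    of ``base_affinity``, capped at 0.7x the preferred affinity so the
    preferred gas always dominates. ``selectivity_contrast`` must exceed 1.
    """
    if n_dyes < 1:
        raise ValueError("need at least one dye")
    if gases is None:
        gases = list(DEFAULT_GASES)
    if not gases:
        raise ValueError("gases must be non-empty")
    if selectivity_contrast <= 1:
        raise ValueError(
            f"selectivity_contrast must be > 1 to plant selectivity, got {selectivity_contrast}"
        )
    rng = np.random.default_rng(seed)
    D, G = n_dyes, len(gases)
    affinity = base_affinity * rng.uniform(0.3, 0.9, size=(D, G))
    half_sat = rng.uniform(2.0, 8.0, size=(D, G))
    preferred = []
    for i in range(D):
        j = i % G
        rank = i // G  # how many earlier dyes share this preferred gas
        preferred.append(gases[j])
        pref_aff = (
            selectivity_contrast
            * base_affinity
            * 1.3**-rank
            * rng.uniform(0.97, 1.03)
        )
        affinity[i, j] = pref_aff
        half_sat[i, j] = rng.uniform(4.5, 5.5)
        off = np.arange(G) != j
        affinity[i, off] = np.minimum(affinity[i, off], 0.7 * pref_aff)
    # darkening hue shifts: non-positive components keep responses in range
    raw = -np.abs(rng.normal(size=(D, G, 3)))
    direction = raw / np.linalg.norm(raw, axis=2, keepdims=True)
    control_rgb = np.array([200.0, 200.0, 180.0]) + rng.uniform(-8, 8, size=(D, 3))
    if "water" in gases:
        humidity_affinity = affinity[:, gases.index("water")].copy()
    else:
        humidity_affinity = base_affinity * rng.uniform(0.1, 0.3, size=D)
    return SyntheticGroundTruth(
        dyes=[f"dye{i:02d}" for i in range(D)],
        gases=list(gases),
        affinity=affinity,
        half_saturation=half_sat,
        direction=direction,
        noise_sd=noise_sd,
        read_noise_sd=read_noise_sd,
        humidity_affinity=humidity_affinity,
        control_rgb=control_rgb,
        seed=seed,
        preferred_gas=preferred,
        sensor_max=sensor_max,
    )


def panel_from_truth(
    truth: SyntheticGroundTruth,
    dye_ids: list[str] | None = None,
    panel_id: str = "synthetic",
) -> SensorPanel:
    """A panel whose spots are (a subset of) the truth's dyes, in order."""
    ids = dye_ids if dye_ids is not None else list(truth.dyes)
    spots = tuple(
        DyeFormulation(dye_id=d, base_dye=d, solvent="ethanol") for d in ids
    )
    return SensorPanel(panel_id=panel_id, spots=spots)


def expected_magnitude(
    truth: SyntheticGroundTruth, gas: str, concentration: float
) -> np.ndarray:
    """Noiseless per-dye Langmuir response magnitude at a concentration."""
    j = truth.gas_index(gas)
    return truth.affinity[:, j] * concentration / (truth.half_saturation[:, j] + concentration)


def _clip(truth: SyntheticGroundTruth, rgb: np.ndarray) -> np.ndarray:
    clipped = np.clip(rgb, 0.0, truth.sensor_max)
    truth.clip_events += int(np.sum(clipped != rgb))
    return clipped


def simulate_mixture(
    truth: SyntheticGroundTruth,
    concentrations: dict[str, float],
    seed: int | np.random.Generator | None = None,
    panel: SensorPanel | None = None,
    replicate: int = 0,
    day: int | None = None,
    condition: str | None = None,
    record_concentration: float | None = None,
) -> ExposureRecord:
    """Simulate one exposure of a panel to a gas mixture.

    ``concentrations`` maps gas name -> ppm; unknown gases raise. Test and
    control strips each receive independent Gaussian strip noise.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if panel is None:
        panel = panel_from_truth(truth)
    idx = truth.dye_indices(list(panel.dye_ids))
    base = truth.control_rgb[idx]  # (spots, 3)
    shift = np.zeros_like(base)
    for gas, ppm in concentrations.items():
        if ppm < 0:
            raise ValueError(f"concentration for {gas!r} must be >= 0, got {ppm}")
        j = truth.gas_index(gas)
        mag = truth.affinity[idx, j] * ppm / (truth.half_saturation[idx, j] + ppm)
        shift += mag[:, None] * truth.direction[idx, j]
    test = base + shift
    if truth.noise_sd > 0:
        test = test + rng.normal(0, truth.noise_sd, size=base.shape)
        control = base + rng.normal(0, truth.noise_sd, size=base.shape)
    else:
        control = base.copy()
    test = _clip(truth, test)
    control = _clip(truth, control)
    return ExposureRecord(
        panel_id=panel.panel_id,
        gas_id="|".join(sorted(concentrations)) if len(concentrations) != 1 else next(iter(concentrations)),
        concentration=record_concentration
        if record_concentration is not None
        else (next(iter(concentrations.values())) if len(concentrations) == 1 else None),
        replicate=replicate,
        test=tuple(RGBReading(*row) for row in test),
        control=tuple(RGBReading(*row) for row in control),
        day=day,
        condition=condition,
    )


def simulate_exposure(
    truth: SyntheticGroundTruth,
    gas: str,
    concentration: float,
    seed: int | np.random.Generator | None = None,
    panel: SensorPanel | None = None,
    replicate: int = 0,
    humidity_ppm: float = 0.0,
    day: int | None = None,
    condition: str | None = None,
) -> ExposureRecord:
    """Single-gas exposure; ``humidity_ppm`` adds water-vapour cross-talk."""
    mixture = {gas: concentration}
    if humidity_ppm > 0:
        if "water" not in truth.gases:
            raise ValueError("humidity co-exposure requires 'water' among the truth's gases")
        mixture["water"] = mixture.get("water", 0.0) + humidity_ppm
    rec = simulate_mixture(
        truth,
        mixture,
        seed=seed,
        panel=panel,
        replicate=replicate,
        day=day,
        condition=condition,
        record_concentration=concentration,
    )
    rec.gas_id = gas
    return rec


def _records_to_table(
    records: list[ExposureRecord],
    panel: SensorPanel,
    truth: SyntheticGroundTruth,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Expand aggregated records into raw readings-table rows (10 reads/spot)."""
    rows = []
    for rec in records:
        for is_control, side in ((0, rec.test), (1, rec.control)):
            for spot, reading in enumerate(side):
                meas = np.array(reading.as_tuple())
                raws = meas[None, :] + rng.normal(
                    0, truth.read_noise_sd, size=(N_RAW_READS, 3)
                )
                raws = _clip(truth, raws)
                for raw in raws:
                    rows.append(
                        (
                            rec.panel_id,
                            spot,
                            panel.spots[spot].dye_id,
                            rec.gas_id,
                            rec.concentration,
                            rec.replicate,
                            is_control,
                            rec.day,
                            rec.condition,
                            raw[0],
                            raw[1],
                            raw[2],
                        )
                    )
    return pd.DataFrame(rows, columns=READINGS_COLUMNS)


def simulate_screen(
    truth: SyntheticGroundTruth,
    concentration: float = 10.0,
    replicates: int = 3,
    seed: int = 0,
    as_records: bool = False,
    panel_id: str = "screen",
):
    """Screening experiment: every gas at one concentration, in replicate.

    Returns a readings-table DataFrame, or (records, panel) when
    ``as_records`` is set.
    """
    rng = np.random.default_rng(seed)
    panel = panel_from_truth(truth, panel_id=panel_id)
    records = [
        simulate_exposure(truth, gas, concentration, seed=rng, panel=panel, replicate=rep)
        for gas in truth.gases
        for rep in range(replicates)
    ]
    if as_records:
        return records, panel
    return _records_to_table(records, panel, truth, rng)


def simulate_calibration_series(
    truth: SyntheticGroundTruth,
    gas: str,
    concentrations=(0.5, 1.0, 2.5, 5.0, 10.0, 25.0),
    replicates: int = 3,
    seed: int = 0,
    dye_ids: list[str] | None = None,
    as_records: bool = False,
    panel_id: str = "calibration",
):
    """Dose-response series at the standard six screening concentrations.

    Returns a full readings table (10 raw reads per spot plus paired
    controls) suitable for ``read_exposures`` -> ``fit_calibration``
    end-to-end, or (records, panel) when ``as_records`` is set.
    """
    concs = list(concentrations)
    if len(set(concs)) != len(concs) or any(c < 0 for c in concs):
        raise ValueError("concentrations must be distinct and >= 0")
    rng = np.random.default_rng(seed)
    panel = panel_from_truth(truth, dye_ids=dye_ids, panel_id=panel_id)
    records = [
        simulate_exposure(truth, gas, c, seed=rng, panel=panel, replicate=rep)
        for c in concs
        for rep in range(replicates)
    ]
    if as_records:
        return records, panel
    return _records_to_table(records, panel, truth, rng)


@dataclass(frozen=True)
class EmissionProfile:
    """Per-day emitted concentration (ppm) of each gas under one condition."""

    condition: str
    emissions: dict[str, tuple[float, ...]]  # gas -> per-day ppm

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.emissions.values()}
        if len(lengths) > 1:
            raise ValueError("all gases must cover the same day set")
        for gas, series in self.emissions.items():
            if any(c < 0 for c in series):
                raise ValueError(f"negative emission for {gas!r}: {series}")

    @property
    def n_days(self) -> int:
        return len(next(iter(self.emissions.values()))) if self.emissions else 0

    def day_mixture(self, day_index: int) -> dict[str, float]:
        return {gas: series[day_index] for gas, series in self.emissions.items()}


def _per_day(series: list[float], days: int) -> tuple[float, ...]:
    if days <= len(series):
        return tuple(series[:days])
    return tuple(series) + (series[-1],) * (days - len(series))


def default_stress_profiles(
    gases: list[str] | None = None, days: int = 5
) -> list[EmissionProfile]:
    """Built-in 5-day emission profiles for control / salinity / starvation.

    The target green-leaf aldehyde declines over days in all conditions, runs
    higher under salinity than control on days 1-3 and under starvation than
    control on days 1-2, with salinity above starvation throughout — but the
    day-1 differences are small against measurement noise, so conditions are
    indistinguishable on day 1. From day 2 each stress additionally shifts a
    condition-specific auxiliary volatile (metabolic signature), so the
    multi-dye fingerprints stay separable on later days even after the
    aldehyde trajectories converge.
    """
    gases = gases if gases is not None else list(DEFAULT_GASES)
    target = "trans-2-hexen-1-al"
    if target not in gases:
        raise ValueError(f"default profiles need {target!r} among the gases")
    aux = [g for g in gases if g not in (target, "water")]
    if len(aux) < 2:
        raise ValueError("default profiles need two non-water auxiliary gases")
    aux_starvation, aux_salinity = aux[0], aux[1]
    flat = [0.5, 0.5, 0.5, 0.5, 0.5]
    up = [0.5, 2.0, 2.0, 1.8, 1.6]
    profiles = [
        EmissionProfile(
            "control",
            {
                target: _per_day([3.0, 1.2, 0.8, 0.55, 0.4], days),
                aux_starvation: _per_day(flat, days),
                aux_salinity: _per_day(flat, days),
            },
        ),
        EmissionProfile(
            "starvation",
            {
                target: _per_day([3.02, 2.0, 0.9, 0.6, 0.45], days),
                aux_starvation: _per_day(up, days),
                aux_salinity: _per_day(flat, days),
            },
        ),
        EmissionProfile(
            "salinity",
            {
                target: _per_day([3.05, 2.6, 1.6, 0.65, 0.5], days),
                aux_starvation: _per_day(flat, days),
                aux_salinity: _per_day(up, days),
            },
        ),
    ]
    return profiles


def simulate_plant_timecourse(
    truth: SyntheticGroundTruth,
    profiles: list[EmissionProfile] | None = None,
    days: int = 5,
    replicates: int = 3,
    seed: int = 0,
    dye_ids: list[str] | None = None,
    as_records: bool = False,
    panel_id: str = "invivo",
):
    """Multi-day in vivo experiment: one exposure per (condition, day,
    replicate) to that condition's emitted gas mixture.

    Days are numbered 1..days. Records carry unknown concentration (mixtures)
    plus day and condition labels. Returns a readings table, or
    (records, panel) when ``as_records`` is set.
    """
    if days < 1:
        raise ValueError(f"days must be >= 1, got {days}")
    if profiles is None:
        profiles = default_stress_profiles(truth.gases, days=days)
    for p in profiles:
        if p.n_days < days:
            raise ValueError(f"profile {p.condition!r} covers {p.n_days} days, need {days}")
    rng = np.random.default_rng(seed)
    panel = panel_from_truth(truth, dye_ids=dye_ids, panel_id=panel_id)
    records = []
    for day in range(1, days + 1):
        for profile in profiles:
            for rep in range(replicates):
                rec = simulate_mixture(
                    truth,
                    profile.day_mixture(day - 1),
                    seed=rng,
                    panel=panel,
                    replicate=rep,
                    day=day,
                    condition=profile.condition,
                )
                rec.gas_id = "headspace"
                rec.concentration = None
                records.append(rec)
    if as_records:
        return records, panel
    return _records_to_table(records, panel, truth, rng)
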