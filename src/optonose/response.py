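"""Euclidean-distance response scoring and the dye x gas sensitivity matrix.

The scalar response of one dye spot to an exposure is the Euclidean distance
in (R, G, B) space between the exposed spot's aggregated reading and the
paired unexposed control:

    d = sqrt((x1-x0)^2 + (y1-y0)^2 + (z1-z0)^2)

Distances are computed on raw aggregated channel counts with no normalisation
or white balance; the metric is scale-equivariant, so channel gain cancels out
of every ranking built on it. Averaging responses over replicates per
(dye, gas) yields the sensitivity matrix used for dye screening.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .arraydata import ExposureRecord, RGBReading, SensorPanel

__all__ = [
    "ResponseVector",
    "SensitivityMatrix",
    "euclidean_distance",
    "response_vector",
    "sensitivity_matrix",
]


def euclidean_distance(test: RGBReading, control: RGBReading) -> float:
    """Colour-change magnitude between a test spot and its control, in counts."""
    return math.sqrt(
        (test.red - control.red) ** 2
        + (test.green - control.green) ** 2
        + (test.blue - control.blue) ** 2
    )


@dataclass
class ResponseVector:
    """Per-dye distance fingerprint of a single exposure event."""

    panel_id: str
    gas_id: str
    concentration: float | None
    replicate: int
    distances: np.ndarray
    day: int | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if np.any(self.distances < 0):
            raise ValueError("response distances must be non-negative")


def response_vector(exposure: ExposureRecord) -> ResponseVector:
    """Position-wise Euclidean distance of every spot from its control."""
    distances = np.array(
        [euclidean_distance(t, c) for t, c in zip(exposure.test, exposure.control)]
    )
    return ResponseVector(
        panel_id=exposure.panel_id,
        gas_id=exposure.gas_id,
        concentration=exposure.concentration,
        replicate=exposure.replicate,
        distances=distances,
        day=exposure.day,
        condition=exposure.condition,
    )


@dataclass
class SensitivityMatrix:
    """Mean Euclidean response of each dye to each gas, over replicates.

    ``values[i, j]`` is the mean distance of dye ``dyes[i]`` to gas
    ``gases[j]``; cells with ``replicate_counts == 0`` are missing (NaN), never
    silently zero. ``std`` holds the replicate standard deviation (ddof=1; NaN
    for fewer than two replicates) for error bars.
    """

    dyes: list[str]
    gases: list[str]
    values: np.ndarray
    replicate_counts: np.ndarray
    std: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.replicate_counts = np.asarray(self.replicate_counts, dtype=int)
        if self.std is None:
            self.std = np.full_like(self.values, np.nan)
        if self.values.shape != (len(self.dyes), len(self.gases)):
            raise ValueError("values shape does not match dye/gas labels")

    @property
    def missing_cells(self) -> list[tuple[str, str]]:
        out = []
        for i, dye in enumerate(self.dyes):
            for j, gas in enumerate(self.gases):
                if self.replicate_counts[i, j] == 0:
                    out.append((dye, gas))
        return out

    def to_csv(self, path) -> None:
        """Dyes as rows, gases as columns."""
        import csv

        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["dye_id", *self.gases])
            for i, dye in enumerate(self.dyes):
                writer.writerow([dye, *(repr(float(v)) for v in self.values[i])])

    def to_json(self, path) -> None:
        doc = {
            "dyes": self.dyes,
            "gases": self.gases,
            "mean_distance": [[None if np.isnan(v) else v for v in row] for row in self.values],
            "replicate_counts": self.replicate_counts.tolist(),
            "std": [[None if np.isnan(v) else v for v in row] for row in self.std],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")


def sensitivity_matrix(
    responses: list[ResponseVector], panel: SensorPanel
) -> SensitivityMatrix:
    """Group responses by gas and average per dye.

    Gases are ordered by first appearance in ``responses``; dyes follow the
    panel's spot order. Every response must carry a known gas label and belong
    to the given panel.
    """
    if not responses:
        raise ValueError("no responses given")
    gases: list[str] = []
    per_gas: dict[str, list[np.ndarray]] = {}
    for rv in responses:
        if rv.panel_id != panel.panel_id:
            raise ValueError(
                f"response for panel {rv.panel_id!r} does not match panel {panel.panel_id!r}"
            )
        if not rv.gas_id:
            raise ValueError("response with unknown gas_id cannot enter the sensitivity matrix")
        if rv.distances.shape[0] != panel.n_spots:
            raise ValueError(
                f"response has {rv.distances.shape[0]} distances for a "
                f"{panel.n_spots}-spot panel"
            )
        if rv.gas_id not in per_gas:
            per_gas[rv.gas_id] = []
            gases.append(rv.gas_id)
        per_gas[rv.gas_id].append(rv.distances)

    dyes = list(panel.dye_ids)
    values = np.full((len(dyes), len(gases)), np.nan)
    counts = np.zeros((len(dyes), len(gases)), dtype=int)
    std = np.full((len(dyes), len(gases)), np.nan)
    for j, gas in enumerate(gases):
        stack = np.vstack(per_gas[gas])  # replicates x dyes
        values[:, j] = stack.mean(axis=0)
        counts[:, j] = stack.shape[0]
        if stack.shape[0] > 1:
            std[:, j] = stack.std(axis=0, ddof=1)
    return SensitivityMatrix(dyes=dyes, gases=gases, values=values, replicate_counts=counts, std=std)
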