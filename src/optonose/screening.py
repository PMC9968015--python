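"""Dye screening: selectivity scores, dye-dye correlation, and panel selection.

Screening compares each dye's mean response to one gas against its mean
response across all screened gases (the "average-subtraction" score): a large
positive deviation marks a dye that responds selectively. Redundant dyes —
pairs whose response profiles across exposures are almost perfectly Pearson
correlated — add little information, and dyes that respond most strongly to
water vapour would inject humidity cross-talk. The selection procedure picks
the three most target-selective dyes plus the best dye for each other gas,
skipping water-sensitive and highly correlated candidates, up to eight spots.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .arraydata import SensorPanel
from .response import ResponseVector, SensitivityMatrix

__all__ = [
    "SelectivityScores",
    "CorrelationResult",
    "PanelSelection",
    "selectivity_scores",
    "dye_correlation_matrix",
    "select_panel",
]


@dataclass
class SelectivityScores:
    """Signed deviations of each (dye, gas) mean response from the dye's own
    mean across all gases. Rows sum to zero by construction."""

    dyes: list[str]
    gases: list[str]
    deviations: np.ndarray

    def __post_init__(self) -> None:
        self.deviations = np.asarray(self.deviations, dtype=float)

    def deviation(self, dye: str, gas: str) -> float:
        return float(self.deviations[self.dyes.index(dye), self.gases.index(gas)])

    def to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["dye_id", *self.gases])
            for i, dye in enumerate(self.dyes):
                writer.writerow([dye, *(repr(float(v)) for v in self.deviations[i])])


def selectivity_scores(S: SensitivityMatrix) -> SelectivityScores:
    """Average-subtraction selectivity: cell = mean response to the gas minus
    the dye's mean response over all gases in ``S``.

    Requires at least two gases and no missing cells.
    """
    if len(S.gases) < 2:
        raise ValueError("selectivity scores need at least 2 gases")
    missing = S.missing_cells
    if missing:
        raise ValueError(f"sensitivity matrix has missing cells: {missing}")
    row_means = S.values.mean(axis=1, keepdims=True)
    return SelectivityScores(dyes=list(S.dyes), gases=list(S.gases), deviations=S.values - row_means)


@dataclass
class CorrelationResult:
    """Pearson correlation of per-dye responses across shared exposures.

    ``undefined_dyes`` lists dyes with zero variance across exposures; their
    off-diagonal correlations are NaN and explicitly flagged rather than
    silently propagated.
    """

    dyes: list[str]
    matrix: np.ndarray
    undefined_dyes: list[str] = field(default_factory=list)

    def correlation(self, dye_a: str, dye_b: str) -> float:
        return float(self.matrix[self.dyes.index(dye_a), self.dyes.index(dye_b)])


def dye_correlation_matrix(
    responses: list[ResponseVector], panel: SensorPanel | None = None
) -> CorrelationResult:
    """Symmetric Pearson correlation between dyes over all shared exposures.

    Needs at least three exposures. Dye labels come from ``panel`` when given,
    otherwise spots are labelled ``spot0..spotN-1``.
    """
    if len(responses) < 3:
        raise ValueError("need at least 3 paired observations per dye pair")
    X = np.vstack([rv.distances for rv in responses])  # exposures x dyes
    n_dyes = X.shape[1]
    if panel is not None:
        if panel.n_spots != n_dyes:
            raise ValueError("panel spot count does not match response length")
        dyes = list(panel.dye_ids)
    else:
        dyes = [f"spot{i}" for i in range(n_dyes)]

    sd = X.std(axis=0)
    undefined = [dyes[i] for i in range(n_dyes) if sd[i] == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.asarray(corr, dtype=float)
    # zero-variance dyes: flag, keep a unit diagonal, NaN elsewhere
    for i in range(n_dyes):
        if sd[i] == 0:
            corr[i, :] = np.nan
            corr[:, i] = np.nan
        corr[i, i] = 1.0
    corr = np.clip(corr, -1.0, 1.0, out=corr, where=~np.isnan(corr))
    return CorrelationResult(dyes=dyes, matrix=corr, undefined_dyes=undefined)


@dataclass
class PanelSelection:
    """Outcome of the screening procedure, with a full audit trail."""

    target_analyte: str
    selected: list[tuple[str, str]]  # (dye_id, justification gas)
    excluded_water_sensitive: list[str]
    excluded_correlated: list[tuple[str, str, float]]  # (dye, partner, correlation)
    warning: str | None = None
    audit: dict = field(default_factory=dict)

    @property
    def selected_dyes(self) -> list[str]:
        return [d for d, _ in self.selected]

    def to_json(self, path) -> None:
        doc = {
            "target_analyte": self.target_analyte,
            "selected": [{"dye_id": d, "justification_gas": g} for d, g in self.selected],
            "excluded_water_sensitive": self.excluded_water_sensitive,
            "excluded_correlated": [
                {"dye_id": d, "partner": p, "correlation": c}
                for d, p, c in self.excluded_correlated
            ],
            "warning": self.warning,
            "audit": self.audit,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _ranked(scores: SelectivityScores, gas: str) -> list[str]:
    """Dyes ranked by deviation for ``gas``, descending; ties broken
    lexicographically by dye_id for determinism."""
    j = scores.gases.index(gas)
    return [
        d
        for d, _ in sorted(
            zip(scores.dyes, scores.deviations[:, j]), key=lambda t: (-t[1], t[0])
        )
    ]


def select_panel(
    scores: SelectivityScores,
    corr: CorrelationResult,
    target_analyte: str,
    water_gas_label: str,
    panel_size: int = 8,
    corr_threshold: float = 0.95,
    n_target_dyes: int = 3,
) -> PanelSelection:
    """Deterministic dye-panel selection.

    1. Discard dyes whose largest deviation is for water vapour.
    2. Rank the rest by deviation for the target analyte; pick the top
       ``n_target_dyes``.
    3. For each other non-water gas, pick the top-deviating unselected dye.
    4. During the per-gas picks, a candidate whose Pearson correlation with an
       already-selected dye exceeds ``corr_threshold`` is skipped (recorded)
       in favour of the next ranked candidate. The target trio of step 2 is
       exempt: dyes tuned to the same analyte co-respond by design, and the
       procedure deliberately stacks three of them for target sensitivity —
       redundancy filtering there would contradict the three-dye requirement.
       Undefined (zero-variance) correlations never trigger a skip.
    5. Stop at ``panel_size``; if fewer eligible dyes exist, return a partial
       panel with a warning — never silent padding.
    """
    if target_analyte not in scores.gases:
        raise ValueError(f"target analyte {target_analyte!r} not among gases {scores.gases}")
    if water_gas_label not in scores.gases:
        raise ValueError(f"water label {water_gas_label!r} not among gases {scores.gases}")

    water_j = scores.gases.index(water_gas_label)
    argmax_gas = np.argmax(scores.deviations, axis=1)
    water_sensitive = [d for i, d in enumerate(scores.dyes) if argmax_gas[i] == water_j]
    eligible = [d for d in scores.dyes if d not in water_sensitive]

    selected: list[tuple[str, str]] = []
    selected_dyes: list[str] = []
    excluded_correlated: list[tuple[str, str, float]] = []
    excluded_set: set[str] = set()

    def correlation_block(candidate: str) -> tuple[str, float] | None:
        for chosen in selected_dyes:
            r = corr.correlation(candidate, chosen)
            if not np.isnan(r) and r > corr_threshold:
                return chosen, r
        return None

    def take(gas: str, how_many: int, check_corr: bool = True) -> None:
        for candidate in _ranked(scores, gas):
            if how_many == 0 or len(selected) >= panel_size:
                return
            if candidate not in eligible or candidate in selected_dyes or candidate in excluded_set:
                continue
            block = correlation_block(candidate) if check_corr else None
            if block is not None:
                partner, r = block
                excluded_correlated.append((candidate, partner, float(r)))
                excluded_set.add(candidate)
                continue
            selected.append((candidate, gas))
            selected_dyes.append(candidate)
            how_many -= 1

    take(target_analyte, n_target_dyes, check_corr=False)
    other_gases = [g for g in scores.gases if g not in (target_analyte, water_gas_label)]
    for gas in other_gases:
        if len(selected) >= panel_size:
            break
        take(gas, 1)

    wanted = min(panel_size, n_target_dyes + len(other_gases))
    warning = None
    if len(selected) < wanted:
        warning = (
            f"only {len(selected)} of {wanted} panel slots could be filled from "
            f"{len(eligible)} eligible dyes"
        )

    audit = {"ranking_by_gas": {g: _ranked(scores, g) for g in scores.gases}}
    return PanelSelection(
        target_analyte=target_analyte,
        selected=selected,
        excluded_water_sensitive=water_sensitive,
        excluded_correlated=excluded_correlated,
        warning=warning,
        audit=audit,
    )


def percentage_gains(S: SensitivityMatrix) -> dict[str, np.ndarray]:
    """Two conventions for "x% higher than the average" sensitivity reports.

    ``above_average`` = (d - mean)/mean x 100; ``of_average`` = d/mean x 100,
    where ``mean`` is the dye's mean response across gases. Both are emitted in
    audit output because published phrasing is ambiguous between them.
    """
    row_means = S.values.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        above = (S.values - row_means) / row_means * 100.0
        of = S.values / row_means * 100.0
    return {"above_average": above, "of_average": of}
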