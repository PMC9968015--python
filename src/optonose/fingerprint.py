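"""Multivariate identification of volatiles and plant growth conditions.

Each exposure of an optimised sensor paper yields an up-to-8-dimensional
fingerprint (one Euclidean-distance response per dye). Principal component
analysis projects these fingerprints to a few axes for visualisation and
variance accounting; a k-nearest-neighbour classifier assigns gas or
growth-condition labels; and a per-day leave-one-out analysis decides from
which day of a stress time course the conditions become separable.

PCA is deterministic up to sign; loadings are sign-fixed so that each
component's largest-magnitude entry is positive, making outputs reproducible
across linear-algebra backends. KNN tie-breaks are fixed: vote ties fall back
to the single nearest neighbour's label, distance ties to training order.
"""

from __future__ import annotations

import csv
import json
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA as _SkPCA
from sklearn.metrics import silhouette_score

from .response import ResponseVector

__all__ = [
    "FingerprintDataset",
    "PCAModel",
    "DayReport",
    "SeparabilityReport",
    "fingerprints_from_responses",
    "read_fingerprints_csv",
    "write_fingerprints_csv",
    "fit_pca",
    "project",
    "classify_knn",
    "condition_separability",
]

MAX_DYES = 8


@dataclass
class FingerprintDataset:
    """Labelled dye-response fingerprints (observations x dyes)."""

    observations: np.ndarray
    labels: list[str]
    dyes: list[str] | None = None
    days: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.observations = np.asarray(self.observations, dtype=float)
        if self.observations.ndim != 2:
            raise ValueError("observations must be a 2-D matrix")
        n, d = self.observations.shape
        if d > MAX_DYES:
            raise ValueError(f"at most {MAX_DYES} dye columns supported, got {d}")
        if not np.all(np.isfinite(self.observations)):
            raise ValueError("observations contain missing/non-finite entries")
        if len(self.labels) != n:
            raise ValueError("labels length does not match observation count")
        if any(not lab for lab in self.labels):
            raise ValueError("labels must be non-empty")
        if self.dyes is None:
            self.dyes = [f"spot{i}" for i in range(d)]
        if len(self.dyes) != d:
            raise ValueError("dye labels do not match column count")
        if self.days is not None:
            self.days = np.asarray(self.days, dtype=int)
            if self.days.shape[0] != n:
                raise ValueError("days length does not match observation count")

    @property
    def n_observations(self) -> int:
        return self.observations.shape[0]


def fingerprints_from_responses(
    responses: list[ResponseVector],
    label_by: str = "gas",
    dyes: list[str] | None = None,
) -> FingerprintDataset:
    """Stack response vectors into a dataset, labelling by ``"gas"`` or
    ``"condition"``. Day indices are carried along when present."""
    if not responses:
        raise ValueError("no responses given")
    X = np.vstack([rv.distances for rv in responses])
    if label_by == "gas":
        labels = [rv.gas_id for rv in responses]
    elif label_by == "condition":
        labels = [rv.condition or "" for rv in responses]
    else:
        raise ValueError(f"label_by must be 'gas' or 'condition', got {label_by!r}")
    days = None
    if all(rv.day is not None for rv in responses):
        days = np.array([rv.day for rv in responses], dtype=int)
    return FingerprintDataset(observations=X, labels=labels, dyes=dyes, days=days)


def write_fingerprints_csv(data: FingerprintDataset, path) -> None:
    """CSV with columns label, day (blank when absent), then one per dye."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "day", *data.dyes])
        for i in range(data.n_observations):
            day = "" if data.days is None else int(data.days[i])
            writer.writerow(
                [data.labels[i], day, *(repr(float(v)) for v in data.observations[i])]
            )


def read_fingerprints_csv(path) -> FingerprintDataset:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header[:2] != ["label", "day"]:
            raise ValueError("fingerprint CSV must start with columns label, day")
        dyes = header[2:]
        labels: list[str] = []
        days: list[int | None] = []
        rows: list[list[float]] = []
        for row in reader:
            labels.append(row[0])
            days.append(int(row[1]) if row[1] != "" else None)
            rows.append([float(v) for v in row[2:]])
    day_arr = None
    if days and all(d is not None for d in days):
        day_arr = np.array(days, dtype=int)
    return FingerprintDataset(
        observations=np.array(rows), labels=labels, dyes=dyes, days=day_arr
    )


@dataclass
class PCAModel:
    """Principal axes of a fingerprint dataset.

    ``loadings`` has one orthonormal column per component (features x
    components); ``explained_variance_fractions`` are non-increasing and sum
    to 1 over all components.
    """

    loadings: np.ndarray
    explained_variance_fractions: np.ndarray
    column_centers: np.ndarray
    column_scales: np.ndarray
    dyes: list[str] = field(default_factory=list)


def fit_pca(
    data: FingerprintDataset, standardize: bool = False, n_components: int | None = None
) -> PCAModel:
    """Centre (and optionally scale to unit variance) columns, then
    eigen-decompose the covariance.

    A zero-variance dye column under standardization is an error naming the
    dye. Needs at least 3 observations and 2 dyes.
    """
    X = data.observations
    n, d = X.shape
    if n < 3:
        raise ValueError(f"PCA needs >= 3 observations, got {n}")
    if d < 2:
        raise ValueError(f"PCA needs >= 2 dyes, got {d}")
    centers = X.mean(axis=0)
    if standardize:
        scales = X.std(axis=0, ddof=1)
        dead = np.flatnonzero(scales <= 1e-12 * (np.abs(centers) + 1.0))
        if dead.size:
            names = [data.dyes[i] for i in dead]
            raise ValueError(f"zero-variance dye column(s) under standardization: {names}")
    else:
        scales = np.ones(d)
    Z = (X - centers) / scales

    pca = _SkPCA(n_components=None, svd_solver="full")
    pca.fit(Z)
    loadings = pca.components_.T.copy()  # features x components
    fractions = pca.explained_variance_ratio_.copy()
    # sign convention: largest-|entry| of each loading is positive
    for k in range(loadings.shape[1]):
        col = loadings[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, k] = -col
    if n_components is not None:
        loadings = loadings[:, :n_components]
        fractions = fractions[:n_components]
    return PCAModel(
        loadings=loadings,
        explained_variance_fractions=fractions,
        column_centers=centers,
        column_scales=scales,
        dyes=list(data.dyes or []),
    )


def project(model: PCAModel, observations: np.ndarray) -> np.ndarray:
    """Score matrix: centred/scaled observations times the loadings."""
    X = np.asarray(observations, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.loadings.shape[0]:
        raise ValueError(
            f"observations have {X.shape[1]} columns but the model expects "
            f"{model.loadings.shape[0]}"
        )
    return (X - model.column_centers) / model.column_scales @ model.loadings


def classify_knn(
    train: FingerprintDataset, queries: np.ndarray, k: int = 3
) -> list[str]:
    """Majority label among the k nearest training fingerprints (Euclidean).

    Vote ties are broken by the single nearest neighbour's label; distance
    ties by training order (stable sort).
    """
    if train.n_observations == 0:
        raise ValueError("empty training set")
    if not 1 <= k <= train.n_observations:
        raise ValueError(f"k must be in 1..{train.n_observations}, got {k}")
    Q = np.asarray(queries, dtype=float)
    if Q.ndim == 1:
        Q = Q[None, :]
    if Q.shape[1] != train.observations.shape[1]:
        raise ValueError("query dimensionality does not match training data")
    dists = cdist(Q, train.observations)
    out: list[str] = []
    for row in dists:
        order = np.argsort(row, kind="stable")
        neighbours = [train.labels[i] for i in order[:k]]
        counts = Counter(neighbours)
        best = max(counts.values())
        winners = {lab for lab, c in counts.items() if c == best}
        if len(winners) == 1:
            out.append(next(iter(winners)))
        else:
            out.append(train.labels[order[0]])
    return out


@dataclass
class DayReport:
    day: int
    n_observations: int
    n_conditions: int
    loo_accuracy: float
    silhouette: float
    separable: bool


@dataclass
class SeparabilityReport:
    """Per-day leave-one-out separability of growth conditions."""

    days: list[DayReport]
    notes: list[str] = field(default_factory=list)
    threshold: float = 0.9
    k: int = 3

    @property
    def separable_days(self) -> list[int]:
        return [d.day for d in self.days if d.separable]

    @property
    def earliest_separable_day(self) -> int | None:
        sep = self.separable_days
        return min(sep) if sep else None

    def to_json(self, path) -> None:
        doc = {
            "threshold": self.threshold,
            "k": self.k,
            "days": [
                {
                    "day": d.day,
                    "n_observations": d.n_observations,
                    "n_conditions": d.n_conditions,
                    "loo_accuracy": d.loo_accuracy,
                    "silhouette": d.silhouette,
                    "separable": d.separable,
                }
                for d in self.days
            ],
            "notes": self.notes,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _loo_accuracy(X: np.ndarray, labels: list[str], k: int) -> float:
    n = X.shape[0]
    correct = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        train = FingerprintDataset(observations=X[mask], labels=[labels[j] for j in range(n) if j != i])
        kk = min(k, n - 1)
        pred = classify_knn(train, X[i], k=kk)[0]
        correct += pred == labels[i]
    return correct / n


def condition_separability(
    timecourse: FingerprintDataset,
    k: int = 3,
    threshold: float = 0.9,
    standardize: bool = True,
) -> SeparabilityReport:
    """For each day: leave-one-out KNN accuracy over that day's fingerprints
    plus the mean silhouette of condition groups in the first-two-PC plane.

    A day is flagged separable when LOO accuracy >= ``threshold``. Days with a
    single condition are skipped with a note. Standardization is on by default
    because dyes differ widely in response magnitude.
    """
    if timecourse.days is None:
        raise ValueError("time-course dataset must carry day indices")
    reports: list[DayReport] = []
    notes: list[str] = []
    for day in sorted(set(int(d) for d in timecourse.days)):
        sel = timecourse.days == day
        X = timecourse.observations[sel]
        labels = [lab for lab, s in zip(timecourse.labels, sel) if s]
        conditions = sorted(set(labels))
        if len(conditions) < 2:
            notes.append(f"day {day}: only one condition present; skipped")
            continue
        accuracy = _loo_accuracy(X, labels, k)
        sil = float("nan")
        try:
            model = fit_pca(
                FingerprintDataset(observations=X, labels=labels, dyes=timecourse.dyes),
                standardize=standardize,
            )
            scores = project(model, X)[:, : min(2, model.loadings.shape[1])]
            if len(conditions) <= X.shape[0] - 1:
                sil = float(silhouette_score(scores, labels))
        except ValueError as exc:
            notes.append(f"day {day}: silhouette unavailable ({exc})")
        reports.append(
            DayReport(
                day=day,
                n_observations=X.shape[0],
                n_conditions=len(conditions),
                loo_accuracy=accuracy,
                silhouette=sil,
                separable=accuracy >= threshold,
            )
        )
    return SeparabilityReport(days=reports, notes=notes, threshold=threshold, k=k)
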