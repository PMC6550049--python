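"""Containers and dataset-level operations for 3D anatomical landmark data.

A *landmark* is a biologically homologous point digitized on a specimen
(here in millimetres, typically from µCT isosurfaces). A specimen is
represented by a :class:`LandmarkConfiguration`; a study sample (one or
more groups of specimens sharing a landmark protocol) by a
:class:`LandmarkDataset`.

All downstream indexing is by landmark *label*, never raw position, so
subsets and bilateral matching are unambiguous.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

__all__ = [
    "ValidationError",
    "LandmarkDefinition",
    "LandmarkConfiguration",
    "LandmarkDataset",
    "SubsetDefinition",
    "TrialQCReport",
    "average_digitization_trials",
    "extract_subset",
    "match_bilateral",
    "COINCIDENT_TOL",
    "MAX_PLACEMENT_ERROR_MM",
]

#: Distances below this (mm) are treated as coincident landmarks (an error).
COINCIDENT_TOL = 1e-9

#: Maximum accepted inter-trial landmark placement error (mm) used for QC
#: of replicate digitization.
MAX_PLACEMENT_ERROR_MM = 0.05


class ValidationError(ValueError):
    """Raised when landmark data violate a structural invariant."""


@dataclass(frozen=True)
class LandmarkDefinition:
    """A named landmark with optional anatomical side assignment."""

    label: str
    description: str = ""
    side: str = "none"  # one of {left, right, midline, none}

    def __post_init__(self) -> None:
        if self.side not in ("left", "right", "midline", "none"):
            raise ValidationError(
                f"invalid side {self.side!r} for landmark {self.label!r}"
            )


@dataclass
class LandmarkConfiguration:
    """One specimen's 3D landmark coordinates (mm).

    Parameters
    ----------
    specimen_id : str
        Unique specimen identifier.
    landmark_labels : sequence of str
        Ordered landmark labels, one per coordinate row.
    coordinates : (K, 3) array
        x/y/z coordinates in mm, rows matching ``landmark_labels``.
    """

    specimen_id: str
    landmark_labels: tuple[str, ...]
    coordinates: np.ndarray

    def __post_init__(self) -> None:
        self.landmark_labels = tuple(str(x) for x in self.landmark_labels)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValidationError(
                f"specimen {self.specimen_id!r}: coordinates must be (K, 3), "
                f"got {self.coordinates.shape}"
            )
        k = self.coordinates.shape[0]
        if k != len(self.landmark_labels):
            raise ValidationError(
                f"specimen {self.specimen_id!r}: {len(self.landmark_labels)} "
                f"labels but {k} coordinate rows"
            )
        if k < 3:
            raise ValidationError(
                f"specimen {self.specimen_id!r}: need at least 3 landmarks, got {k}"
            )
        if len(set(self.landmark_labels)) != k:
            raise ValidationError(
                f"specimen {self.specimen_id!r}: duplicate landmark labels"
            )
        if not np.all(np.isfinite(self.coordinates)):
            bad = int(np.flatnonzero(~np.isfinite(self.coordinates).all(axis=1))[0])
            raise ValidationError(
                f"specimen {self.specimen_id!r}: non-finite coordinate at "
                f"landmark {self.landmark_labels[bad]!r}"
            )
        d = pdist(self.coordinates)
        if d.size and d.min() < COINCIDENT_TOL:
            i, j = _pair_of_condensed_index(int(np.argmin(d)), k)
            raise ValidationError(
                f"specimen {self.specimen_id!r}: coincident landmarks "
                f"{self.landmark_labels[i]!r} and {self.landmark_labels[j]!r}"
            )

    @property
    def n_landmarks(self) -> int:
        return len(self.landmark_labels)

    def reorder(self, labels: Sequence[str]) -> "LandmarkConfiguration":
        """Return a copy with landmarks reordered/subset to ``labels``."""
        idx = [self._index(lbl) for lbl in labels]
        return LandmarkConfiguration(
            self.specimen_id, tuple(labels), self.coordinates[idx]
        )

    def _index(self, label: str) -> int:
        try:
            return self.landmark_labels.index(label)
        except ValueError:
            raise ValidationError(
                f"specimen {self.specimen_id!r}: unknown landmark {label!r}"
            ) from None


def _pair_of_condensed_index(m: int, k: int) -> tuple[int, int]:
    # invert the condensed (pdist) index m -> (i, j), i < j
    i = 0
    while m >= k - i - 1:
        m -= k - i - 1
        i += 1
    return i, i + 1 + m


@dataclass
class LandmarkDataset:
    """A sample of landmark configurations with per-specimen group labels.

    All configurations must share the same landmark labels in the same
    order; every specimen must have a group label and a unique id.
    """

    configurations: list[LandmarkConfiguration]
    group_labels: dict[str, str]
    landmark_definitions: list[LandmarkDefinition] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.configurations:
            raise ValidationError("dataset has no configurations")
        ids = [c.specimen_id for c in self.configurations]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate specimen ids in dataset")
        ref = self.configurations[0].landmark_labels
        for c in self.configurations[1:]:
            if c.landmark_labels != ref:
                missing = set(ref) - set(c.landmark_labels)
                extra = set(c.landmark_labels) - set(ref)
                raise ValidationError(
                    f"specimen {c.specimen_id!r}: landmark set differs from "
                    f"{self.configurations[0].specimen_id!r} "
                    f"(missing {sorted(missing)}, extra {sorted(extra)})"
                )
        for sid in ids:
            if sid not in self.group_labels:
                raise ValidationError(f"specimen {sid!r} has no group label")
        if self.landmark_definitions:
            def_labels = {d.label for d in self.landmark_definitions}
            unknown = [lbl for lbl in ref if lbl not in def_labels]
            if unknown:
                raise ValidationError(
                    f"landmarks without definitions: {unknown}"
                )

    # -- basic accessors -------------------------------------------------

    @property
    def landmark_labels(self) -> tuple[str, ...]:
        return self.configurations[0].landmark_labels

    @property
    def specimen_ids(self) -> tuple[str, ...]:
        return tuple(c.specimen_id for c in self.configurations)

    @property
    def n_specimens(self) -> int:
        return len(self.configurations)

    @property
    def n_landmarks(self) -> int:
        return self.configurations[0].n_landmarks

    def coords_array(self) -> np.ndarray:
        """Stacked coordinates, shape ``(n_specimens, K, 3)``."""
        return np.stack([c.coordinates for c in self.configurations])

    def groups(self) -> tuple[str, ...]:
        """Distinct group labels in order of first appearance."""
        seen: dict[str, None] = {}
        for sid in self.specimen_ids:
            seen.setdefault(self.group_labels[sid], None)
        return tuple(seen)

    def select_group(self, group: str) -> "LandmarkDataset":
        """Return the single-group sub-dataset for ``group``."""
        keep = [c for c in self.configurations
                if self.group_labels[c.specimen_id] == group]
        if not keep:
            raise ValidationError(f"no specimens in group {group!r}")
        return LandmarkDataset(
            keep,
            {c.specimen_id: group for c in keep},
            list(self.landmark_definitions),
        )

    def with_specimens(self, configs: list[LandmarkConfiguration]) -> "LandmarkDataset":
        return LandmarkDataset(
            configs,
            {c.specimen_id: self.group_labels[c.specimen_id] for c in configs},
            list(self.landmark_definitions),
        )


@dataclass(frozen=True)
class SubsetDefinition:
    """A named subset of landmark labels (e.g. ramus, anterior body)."""

    name: str
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        if len(self.labels) < 3:
            raise ValidationError(
                f"subset {self.name!r} needs at least 3 landmarks, "
                f"got {len(self.labels)}"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError(f"subset {self.name!r} has duplicate labels")


@dataclass
class TrialQCReport:
    """Quality control of replicate digitization trials.

    ``displacements`` has one row per (specimen, landmark) with the
    Euclidean inter-trial displacement in mm; ``flagged`` lists exactly
    those pairs whose displacement exceeds ``threshold``.
    """

    displacements: pd.DataFrame  # columns: specimen, landmark, displacement_mm
    threshold: float
    max_displacement: float
    flagged: list[tuple[str, str]]

    def to_dict(self) -> dict:
        return {
            "threshold_mm": self.threshold,
            "max_displacement_mm": self.max_displacement,
            "n_flagged": len(self.flagged),
            "flagged": [list(f) for f in self.flagged],
        }


def average_digitization_trials(
    trial_a: LandmarkDataset,
    trial_b: LandmarkDataset,
    max_error: float = MAX_PLACEMENT_ERROR_MM,
) -> tuple[LandmarkDataset, TrialQCReport]:
    """Average two digitization trials and QC inter-trial placement error.

    Replicate digitization controls observer error: each specimen is
    digitized twice and the trials are averaged coordinate-wise. Landmarks
    whose inter-trial Euclidean displacement exceeds ``max_error`` (default
    0.05 mm) are flagged — advisorily; averaging is still performed, and
    exclusion or re-digitization is left to the user.

    Returns
    -------
    (averaged, report)
        ``averaged`` has the per-axis arithmetic mean coordinates;
        ``report`` is a :class:`TrialQCReport`.
    """
    if set(trial_a.specimen_ids) != set(trial_b.specimen_ids):
        raise ValidationError("trials have different specimen ids")
    if trial_a.landmark_labels != trial_b.landmark_labels:
        raise ValidationError("trials have different landmark labels")
    b_by_id = {c.specimen_id: c for c in trial_b.configurations}

    rows = []
    flagged: list[tuple[str, str]] = []
    averaged: list[LandmarkConfiguration] = []
    labels = trial_a.landmark_labels
    for ca in trial_a.configurations:
        cb = b_by_id[ca.specimen_id]
        disp = np.linalg.norm(ca.coordinates - cb.coordinates, axis=1)
        for lbl, d in zip(labels, disp):
            rows.append((ca.specimen_id, lbl, float(d)))
            if d > max_error:
                flagged.append((ca.specimen_id, lbl))
        averaged.append(
            LandmarkConfiguration(
                ca.specimen_id, labels, (ca.coordinates + cb.coordinates) / 2.0
            )
        )
    table = pd.DataFrame(rows, columns=["specimen", "landmark", "displacement_mm"])
    report = TrialQCReport(
        displacements=table,
        threshold=float(max_error),
        max_displacement=float(table["displacement_mm"].max()),
        flagged=flagged,
    )
    out = LandmarkDataset(
        averaged, dict(trial_a.group_labels), list(trial_a.landmark_definitions)
    )
    return out, report


def extract_subset(dataset: LandmarkDataset, subset: SubsetDefinition) -> LandmarkDataset:
    """Restrict a dataset to a landmark subset, in subset order."""
    known = set(dataset.landmark_labels)
    for lbl in subset.labels:
        if lbl not in known:
            raise ValidationError(
                f"subset {subset.name!r}: unknown landmark {lbl!r}"
            )
    configs = [c.reorder(subset.labels) for c in dataset.configurations]
    defs = [d for d in dataset.landmark_definitions if d.label in subset.labels]
    return LandmarkDataset(configs, dict(dataset.group_labels), defs)


def match_bilateral(
    dataset: LandmarkDataset,
    pairing: Iterable[tuple[str, str]],
) -> tuple[LandmarkDataset, LandmarkDataset]:
    """Split a bilateral dataset into left and right sides for comparison.

    ``pairing`` lists ``(left_label, right_label)`` homolog pairs. The
    right-side landmarks are relabeled to their left homologs in matching
    order, so the two returned datasets can be compared directly with
    EDMA — which is invariant to reflection, making mirrored sides
    commensurable without any alignment step.
    """
    pairing = [(str(l), str(r)) for l, r in pairing]
    lefts = [l for l, _ in pairing]
    rights = [r for _, r in pairing]
    if len(set(lefts)) != len(lefts) or len(set(rights)) != len(rights):
        raise ValidationError("duplicate labels in bilateral pairing")
    if set(lefts) & set(rights):
        raise ValidationError("a label appears on both sides of the pairing")
    known = set(dataset.landmark_labels)
    for lbl in lefts + rights:
        if lbl not in known:
            raise ValidationError(f"pairing label {lbl!r} not in dataset")
    if len(pairing) < 3:
        raise ValidationError("bilateral pairing needs at least 3 pairs")

    left_configs = [c.reorder(lefts) for c in dataset.configurations]
    right_configs = []
    for c in dataset.configurations:
        rc = c.reorder(rights)
        right_configs.append(
            LandmarkConfiguration(rc.specimen_id, tuple(lefts), rc.coordinates)
        )
    groups = dict(dataset.group_labels)
    left = LandmarkDataset(left_configs, dict(groups))
    right = LandmarkDataset(right_configs, dict(groups))
    return left, right
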