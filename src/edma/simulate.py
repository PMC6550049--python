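"""Synthetic two-group landmark data with known ground truth.

Emulates the sampling structure of a µCT landmark study of newborn
mouse mandibles: two groups (a mutant line and unaffected littermates,
n ≈ 20–40 per group) of 3D configurations observed as a true group mean
form plus independent isotropic Gaussian landmark perturbation — the
classical EDMA perturbation model — with optional localized group
effects on a landmark subset and replicate-digitization noise.

Defaults follow that study design: 25 specimens per group and a
perturbation SD of 1–2% of the mean inter-landmark distance, so
within-group dispersion is small relative to the group effects being
detected. Every generator is a pure function of its arguments and seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .landmarks import LandmarkConfiguration, LandmarkDataset, ValidationError

__all__ = [
    "SyntheticDesign",
    "make_template_form",
    "apply_regional_effect",
    "simulate_group",
    "simulate_digitization_pair",
    "simulate_two_group_study",
]

_TOY_TRIANGLE = {
    "labels": ("A", "B", "C"),
    "coords": np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0], [0.0, 4.0, 0.0]]),
}

# corners of the unit cube scaled anisotropically to a 10 x 4 x 3 mm box
_BOX_SCALE = np.array([10.0, 4.0, 3.0])
_BOX_CORNERS = np.array(
    [[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)], dtype=float
)


def make_template_form(kind: str, seed: int = 0) -> LandmarkConfiguration:
    """Deterministic template mean forms.

    ``toy_triangle``: the 3-4-5 right triangle (3 landmarks).
    ``box_8``: the 8 corners of a 10×4×3 mm box.
    ``mandible_16``: 16 reproducible pseudo-random landmarks in a
    10×4×3 mm box (hemimandible-scale), min pairwise separation 0.5 mm,
    drawn from ``seed``.
    """
    if kind == "toy_triangle":
        return LandmarkConfiguration(
            "template", _TOY_TRIANGLE["labels"], _TOY_TRIANGLE["coords"].copy()
        )
    if kind == "box_8":
        labels = tuple(f"c{i + 1}" for i in range(8))
        return LandmarkConfiguration("template", labels, _BOX_CORNERS * _BOX_SCALE)
    if kind == "mandible_16":
        rng = np.random.default_rng(seed)
        pts = np.empty((16, 3))
        n = 0
        while n < 16:
            cand = rng.uniform(0.0, 1.0, size=3) * _BOX_SCALE
            if n == 0 or np.linalg.norm(pts[:n] - cand, axis=1).min() > 0.5:
                pts[n] = cand
                n += 1
        labels = tuple(f"md{i + 1:02d}" for i in range(16))
        return LandmarkConfiguration("template", labels, pts)
    raise ValidationError(
        f"unknown template kind {kind!r} "
        "(expected toy_triangle, box_8, or mandible_16)"
    )


def apply_regional_effect(
    template: LandmarkConfiguration,
    labels: Sequence[str],
    mode: str = "radial_scale",
    magnitude: float | Sequence[float] = 0.1,
) -> LandmarkConfiguration:
    """Apply a localized true effect to a subset of template landmarks.

    ``radial_scale`` moves each affected landmark away from the centroid
    of the affected set by factor (1 + magnitude), so distances *within*
    the affected set scale by exactly (1 + magnitude) while distances
    among unaffected landmarks are untouched. ``displacement`` adds the
    given 3-vector to each affected landmark.
    """
    labels = [str(x) for x in labels]
    idx = [template._index(lbl) for lbl in labels]
    coords = template.coordinates.copy()
    if mode == "radial_scale":
        centroid = coords[idx].mean(axis=0)
        coords[idx] = centroid + (1.0 + float(magnitude)) * (coords[idx] - centroid)
    elif mode == "displacement":
        vec = np.asarray(magnitude, dtype=float)
        if vec.shape != (3,):
            raise ValidationError("displacement magnitude must be a 3-vector")
        coords[idx] = coords[idx] + vec
    else:
        raise ValidationError(
            f"unknown effect mode {mode!r} (expected radial_scale or displacement)"
        )
    return LandmarkConfiguration(
        template.specimen_id, template.landmark_labels, coords
    )


def simulate_group(
    template: LandmarkConfiguration,
    n: int,
    sigma: float | Sequence[float],
    group_label: str,
    seed: int = 0,
) -> LandmarkDataset:
    """Simulate a group under the Gaussian perturbation model.

    Each specimen is the template plus independent N(0, sigma²) noise on
    every coordinate of every landmark. ``sigma`` may be a scalar (mm)
    or a per-landmark vector for heteroscedastic digitization error.
    """
    if n < 1:
        raise ValidationError("n must be at least 1")
    sig = np.asarray(sigma, dtype=float)
    if np.any(sig < 0):
        raise ValidationError("sigma must be non-negative")
    if sig.ndim == 1:
        if sig.shape[0] != template.n_landmarks:
            raise ValidationError("per-landmark sigma length mismatch")
        sig = sig[:, None]  # broadcast over x/y/z
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, 1.0, size=(n, template.n_landmarks, 3)) * sig
    configs = [
        LandmarkConfiguration(
            f"{group_label}_{i + 1:03d}",
            template.landmark_labels,
            template.coordinates + noise[i],
        )
        for i in range(n)
    ]
    groups = {c.specimen_id: group_label for c in configs}
    return LandmarkDataset(configs, groups)


def simulate_digitization_pair(
    dataset: LandmarkDataset, digitization_sd: float, seed: int = 0
) -> tuple[LandmarkDataset, LandmarkDataset]:
    """Two independent noisy digitization trials of each specimen.

    Each trial adds independent N(0, digitization_sd²) noise per
    coordinate, so averaging the trials recovers the latent coordinates
    with the error variance halved.
    """
    if digitization_sd < 0:
        raise ValidationError("digitization_sd must be non-negative")
    rng = np.random.default_rng(seed)
    trials = []
    for _ in range(2):
        configs = [
            LandmarkConfiguration(
                c.specimen_id,
                c.landmark_labels,
                c.coordinates
                + rng.normal(0.0, digitization_sd, size=c.coordinates.shape),
            )
            for c in dataset.configurations
        ]
        trials.append(
            LandmarkDataset(
                configs, dict(dataset.group_labels), list(dataset.landmark_definitions)
            )
        )
    return trials[0], trials[1]


@dataclass
class SyntheticDesign:
    """A serializable two-group study design.

    The reference group is sampled around ``template``; the test group
    around the template with the regional effect applied (if any).
    """

    template_kind: str = "mandible_16"
    n_per_group: tuple[int, int] = (25, 25)
    sigma: float = 0.05  # mm; ~1% of the mean inter-landmark distance
    effect_labels: tuple[str, ...] = ()
    effect_mode: str = "radial_scale"
    effect_magnitude: float = 0.0
    digitization_sd: float = 0.0
    group_names: tuple[str, str] = ("unaffected", "mutant")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticDesign":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown design fields: {sorted(unknown)}")
        for key in ("n_per_group", "effect_labels", "group_names"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "template_kind": self.template_kind,
            "n_per_group": list(self.n_per_group),
            "sigma": self.sigma,
            "effect_labels": list(self.effect_labels),
            "effect_mode": self.effect_mode,
            "effect_magnitude": self.effect_magnitude,
            "digitization_sd": self.digitization_sd,
            "group_names": list(self.group_names),
            "seed": self.seed,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def simulate_two_group_study(
    design: SyntheticDesign, seed: int | None = None
) -> tuple[LandmarkDataset, LandmarkDataset]:
    """Simulate (reference, test) datasets from a design.

    Returns the reference (unaffected) group first and the test (mutant)
    group — with the design's regional effect applied to its mean form —
    second. If ``digitization_sd`` > 0, each group is the average of two
    simulated digitization trials, mirroring the acquisition protocol.
    """
    base_seed = design.seed if seed is None else seed
    # independent substreams for template, the two groups, and digitization
    ss = np.random.SeedSequence(base_seed).spawn(5)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss]

    template = make_template_form(design.template_kind, seed=seeds[0])
    ref_name, test_name = design.group_names
    test_template = template
    if design.effect_labels and design.effect_magnitude:
        test_template = apply_regional_effect(
            template, design.effect_labels, design.effect_mode,
            design.effect_magnitude,
        )
    ref = simulate_group(template, design.n_per_group[0], design.sigma,
                         ref_name, seed=seeds[1])
    test = simulate_group(test_template, design.n_per_group[1], design.sigma,
                          test_name, seed=seeds[2])
    if design.digitization_sd > 0:
        from .landmarks import average_digitization_trials

        a1, a2 = simulate_digitization_pair(ref, design.digitization_sd, seeds[3])
        ref, _ = average_digitization_trials(a1, a2)
        b1, b2 = simulate_digitization_pair(test, design.digitization_sd, seeds[4])
        test, _ = average_digitization_trials(b1, b2)
    return ref, test
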