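"""End-to-end analysis workflow and machine-readable reports.

Ties the stages together the way a two-group landmark study is run:
for the whole landmark set and each regional subset, estimate mean
forms, run the bootstrap mean-form test, compute FDM confidence
intervals, classify significant distances into effect bands, and run a
ln-distance PCA with a group-separation summary. A bilateral variant
compares left vs right sides within each group to assess asymmetry.

Reports are JSON (per-unit summary + provenance) with per-distance CSV
tables; rerunning with the same config and seed reproduces every number
bit-identically.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .inference import (
    bootstrap_fdm_intervals,
    classify_fdm_effects,
    test_mean_form_difference,
)
from .io import read_bilateral_pairing, read_landmark_table, read_subset_definitions
from .landmarks import (
    LandmarkDataset,
    SubsetDefinition,
    ValidationError,
    extract_subset,
    match_bilateral,
)
from .pca import group_separation, ln_distance_table, run_pca

__all__ = ["AnalysisConfig", "AnalysisReport", "run_full_analysis",
           "run_asymmetry_analysis"]

log = logging.getLogger("edma")


@dataclass
class AnalysisConfig:
    """Run configuration for a two-group EDMA + PCA analysis.

    ``group_a`` is the test group (FDM numerator, e.g. mutant) and
    ``group_b`` the reference group (denominator, e.g. unaffected
    littermates).
    """

    group_a: str  # path to landmark CSV, test group
    group_b: str  # path to landmark CSV, reference group
    subsets: dict[str, list[str]] = field(default_factory=dict)
    subset_file: str | None = None
    pairing: list[tuple[str, str]] = field(default_factory=list)
    pairing_file: str | None = None
    n_boot: int = 10_000
    confidence_level: float = 0.90
    bands: tuple[float, float] = (0.05, 0.10)
    estimator: str = "arithmetic"
    pca_scale_free: bool = True
    pca_components: int = 2
    seed: int = 0
    output_dir: str | None = None
    dialect: str = "long"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        if not path.exists():
            raise ValidationError(f"no such config file: {path}")
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config fields: {sorted(unknown)}")
        missing = [k for k in ("group_a", "group_b") if k not in data]
        if missing:
            raise ValidationError(f"config lacks required fields: {missing}")
        if "bands" in data:
            data["bands"] = tuple(data["bands"])
        if "pairing" in data:
            data["pairing"] = [tuple(p) for p in data["pairing"]]
        cfg = cls(**data)
        # resolve relative paths against the config file location
        base = path.parent
        for attr in ("group_a", "group_b", "subset_file", "pairing_file",
                     "output_dir"):
            val = getattr(cfg, attr)
            if val is not None and not Path(val).is_absolute():
                setattr(cfg, attr, str(base / val))
        return cfg

    def content_hash(self) -> str:
        payload = {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """Per-unit analysis results plus provenance."""

    units: dict[str, dict[str, Any]]
    provenance: dict[str, Any]

    def to_dict(self) -> dict[str, Any]:
        return {"units": self.units, "provenance": self.provenance}

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _load_groups(config: AnalysisConfig) -> tuple[LandmarkDataset, LandmarkDataset]:
    for p in (config.group_a, config.group_b):
        if not Path(p).exists():
            raise ValidationError(f"input file does not exist: {p}")
    a = read_landmark_table(config.group_a, config.dialect)
    b = read_landmark_table(config.group_b, config.dialect)
    return a, b


def _resolve_subsets(config: AnalysisConfig) -> list[SubsetDefinition]:
    subsets = [SubsetDefinition(name, tuple(labels))
               for name, labels in config.subsets.items()]
    if config.subset_file:
        subsets.extend(read_subset_definitions(config.subset_file))
    return subsets


def _resolve_pairing(config: AnalysisConfig) -> list[tuple[str, str]]:
    pairing = list(config.pairing)
    if config.pairing_file:
        pairing.extend(read_bilateral_pairing(config.pairing_file))
    return pairing


def _analyze_unit(
    name: str,
    group_a: LandmarkDataset,
    group_b: LandmarkDataset,
    config: AnalysisConfig,
    outdir: Path | None,
) -> dict[str, Any]:
    """One analysis unit: test + CIs + banding + PCA."""
    test = test_mean_form_difference(
        group_a, group_b, n_boot=config.n_boot, seed=config.seed,
        estimator=config.estimator,
    )
    ci = bootstrap_fdm_intervals(
        group_a, group_b, n_boot=config.n_boot,
        confidence_level=config.confidence_level, seed=config.seed,
        estimator=config.estimator,
    )
    effects = classify_fdm_effects(ci, bands=config.bands)

    combined = LandmarkDataset(
        group_a.configurations + group_b.configurations,
        {**group_a.group_labels, **group_b.group_labels},
    )
    table = ln_distance_table(combined, scale_free=config.pca_scale_free)
    max_comp = min(combined.n_specimens - 1, len(table.pair_index))
    n_comp = min(config.pca_components, max_comp)
    pca = run_pca(table, n_components=n_comp)
    sep = group_separation(pca, components=range(1, n_comp + 1))

    if outdir is not None:
        fdm_table = ci.to_frame()
        fdm_table["category"] = effects.categories
        fdm_table.to_csv(outdir / f"fdm_{name}.csv", index=False)
        pca.scores_frame().to_csv(outdir / f"pca_scores_{name}.csv")

    counts = effects.counts()
    return {
        "n_landmarks": group_a.n_landmarks,
        "n_pairs": len(ci.pair_index),
        "n_specimens": [group_a.n_specimens, group_b.n_specimens],
        "mean_form_test": {
            "statistic": test.statistic_observed,
            "p_value": test.p_value,
            "n_boot": test.n_boot,
        },
        "n_significant": int(ci.significant.sum()),
        "effect_counts": counts,
        "pca": {
            "explained_variance_fraction":
                [float(f) for f in pca.explained_variance_fraction],
            "separation_ratio": sep.ratio,
            "centroid_distance": sep.centroid_distance,
            "pooled_dispersion": sep.pooled_dispersion,
        },
    }


def _provenance(config: AnalysisConfig) -> dict[str, Any]:
    return {
        "package_version": __version__,
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "n_boot": config.n_boot,
        "confidence_level": config.confidence_level,
        "estimator": config.estimator,
    }


def run_full_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Full-set + per-subset two-group analysis.

    Analyzes the whole landmark set and every configured subset with
    the bootstrap mean-form test, FDM confidence intervals, effect
    banding, and ln-distance PCA. Writes per-distance CSVs and a JSON
    report to ``config.output_dir`` if set. Idempotent given seed.
    """
    group_a, group_b = _load_groups(config)
    subsets = _resolve_subsets(config)
    outdir = None
    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)

    units: dict[str, dict[str, Any]] = {}
    stages = [("whole", None)] + [(s.name, s) for s in subsets]
    for name, subset in stages:
        log.info("analyzing unit %r (n_boot=%d, seed=%d, estimator=%s, "
                 "confidence=%.2f)", name, config.n_boot, config.seed,
                 config.estimator, config.confidence_level)
        try:
            ga = extract_subset(group_a, subset) if subset else group_a
            gb = extract_subset(group_b, subset) if subset else group_b
            units[name] = _analyze_unit(name, ga, gb, config, outdir)
        except Exception as exc:
            raise type(exc)(f"unit {name!r}: {exc}") from exc

    report = AnalysisReport(units=units, provenance=_provenance(config))
    if outdir is not None:
        report.to_json(outdir / "report.json")
    return report


def _relabel_side(ds: LandmarkDataset, side: str) -> LandmarkDataset:
    from .landmarks import LandmarkConfiguration

    suffix = "_L" if side == "left" else "_R"
    configs = [
        LandmarkConfiguration(c.specimen_id + suffix, c.landmark_labels,
                              c.coordinates)
        for c in ds.configurations
    ]
    return LandmarkDataset(configs, {c.specimen_id: side for c in configs})


def run_asymmetry_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Left-vs-right comparison within each group.

    Bilateral landmarks are matched via the configured pairing (right
    side relabeled to left homologs); EDMA then compares the two sides
    of each group directly, exploiting its invariance to reflection. A
    pairing that covers only part of the landmark set restricts the
    analysis to the paired labels, which is recorded in the report.
    """
    pairing = _resolve_pairing(config)
    if not pairing:
        raise ValidationError("asymmetry analysis requires a bilateral pairing")
    group_a, group_b = _load_groups(config)
    outdir = None
    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)

    units: dict[str, dict[str, Any]] = {}
    for ds in (group_a, group_b):
        for grp in ds.groups():
            sub = ds.select_group(grp)
            left, right = match_bilateral(sub, pairing)
            # disambiguate sides so they can be treated as two samples
            left = _relabel_side(left, "left")
            right = _relabel_side(right, "right")
            name = f"asymmetry_{grp}"
            log.info("analyzing unit %r (left vs right, %d paired landmarks)",
                     name, len(pairing))
            unit = _analyze_unit(name, left, right, config, outdir)
            unit["paired_landmarks"] = len(pairing)
            unit["all_landmarks"] = sub.n_landmarks
            unit["restricted_to_pairing"] = len(pairing) * 2 < sub.n_landmarks
            units[name] = unit

    report = AnalysisReport(units=units, provenance=_provenance(config))
    if outdir is not None:
        report.to_json(outdir / "asymmetry_report.json")
    return report
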