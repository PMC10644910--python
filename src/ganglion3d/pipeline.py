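"""Folder-level orchestration: manifest in, annotated spreadsheet out.

For every raw stack in the input folder the pipeline runs
segment_target → segment_instances → (region + classification when a
region source is configured) → quantification, writes the per-stack
label maps (overall and per class) and finally combines every cell from
every stack into one annotated CSV plus a per-stack summary table.  A
failing file is logged and reported without aborting the batch (lab
folders contain stray files); strict mode aborts on the first error.

The effective configuration is persisted alongside the outputs so a run
can be reproduced exactly: identical folder + manifest + config + seed
give byte-identical CSVs and label maps.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import classify as _classify
from . import imgio, quantify, segmentation
from .classify import ClassificationParams
from .imgio import Manifest
from .instances import InstanceParams, segment_instances

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every tunable of a run, serializable to the manifest's text dialect."""

    prob_cutoff: float = 0.5
    resample: bool = False
    otsu_per_plane: bool = False
    instance: InstanceParams = field(default_factory=InstanceParams)
    classification: ClassificationParams = field(default_factory=ClassificationParams)
    denominator_mode: str = "stack"
    shape_feature: str = "elongation"
    strict: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "instance" in d:
            d["instance"] = InstanceParams(**d["instance"])
        if "classification" in d:
            d["classification"] = ClassificationParams(**d["classification"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


@dataclass
class StackResult:
    stack_name: str
    label_map: imgio.InstanceLabelMap
    per_class_maps: dict[str, imgio.InstanceLabelMap]
    cell_table: pd.DataFrame
    summary: pd.DataFrame


@dataclass
class RunResult:
    stacks: list[StackResult]
    cell_table: pd.DataFrame
    summaries: pd.DataFrame
    failures: dict[str, str]

    @property
    def ok(self) -> bool:
        return not self.failures


def _load_region(stack_path: Path, manifest: Manifest, spacing) -> imgio.RegionMap | None:
    if manifest.region_source == "none":
        return None
    companion = imgio.find_companion(stack_path, manifest.region_pattern)
    if manifest.region_source == "labelmap":
        return imgio.read_region_map(companion)
    probs = imgio.read_probmap(companion)
    return _classify.region_from_probmap(probs, spacing=spacing)


def process_stack(
    stack_path: Path,
    manifest: Manifest,
    config: PipelineConfig,
    out_dir: Path | None = None,
) -> StackResult:
    """Run every stage on one stack; optionally write its artifacts."""
    t0 = time.perf_counter()
    stack = imgio.read_stack(stack_path, manifest)
    mask = segmentation.segment_target(
        stack,
        manifest,
        prob_cutoff=config.prob_cutoff,
        resample=config.resample,
        otsu_per_plane=config.otsu_per_plane,
        stack_path=stack_path,
    )
    labels = segment_instances(mask, config.instance)

    region = _load_region(stack_path, manifest, stack.spacing)
    if region is not None:
        if region.regions.shape != labels.labels.shape:
            raise ValueError(
                f"region map shape {region.regions.shape} != stack shape {labels.labels.shape}"
            )
        classification = _classify.classify_objects(labels, region, config.classification)
    else:
        classification = _classify.ObjectClassification(
            classes={int(i): _classify.CLASS_UNCLASSIFIED for i in labels.object_ids},
            fractions={},
        )
    per_class = _classify.split_by_class(
        labels, classification, policy=config.classification.unclassified_policy
    )

    table = quantify.quantify_objects(labels, stack, classification)
    summary = quantify.summarize_stack(
        labels, table, denominator_mode=config.denominator_mode, region=region
    )
    summary["source_name"] = stack.source_name

    if out_dir is not None:
        stem = stack_path.stem
        imgio.write_label_map(labels, out_dir / f"{stem}_labels.tif")
        for cls, cmap in per_class.items():
            imgio.write_label_map(cmap, out_dir / f"{stem}_labels_{cls}.tif")
    logger.info("%s: %d objects in %.2fs", stack_path.name, labels.n_objects, time.perf_counter() - t0)
    return StackResult(
        stack_name=stack.source_name,
        label_map=labels,
        per_class_maps=per_class,
        cell_table=table,
        summary=summary,
    )


def run_pipeline(
    input_dir: str | Path,
    manifest: str | Path | Manifest,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> RunResult:
    """Process every stack in a folder per the manifest.

    Returns the combined cell table (one row per cell across all stacks,
    annotated with class and source file), the per-stack summaries and a
    map of per-file failures.  Artifacts (label maps, CSVs, effective
    config) are written when ``out_dir`` is given.
    """
    input_dir = Path(input_dir)
    config = config or PipelineConfig()
    if not isinstance(manifest, Manifest):
        manifest = imgio.parse_manifest(manifest)
    stack_paths = sorted(input_dir.glob(manifest.input_pattern))
    if not stack_paths:
        raise FileNotFoundError(
            f"no files matching {manifest.input_pattern!r} in {input_dir}"
        )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        config.save(out_dir / "effective_config.yaml")

    results: list[StackResult] = []
    failures: dict[str, str] = {}
    for path in stack_paths:
        try:
            results.append(process_stack(path, manifest, config, out_dir))
        except Exception as exc:
            if config.strict:
                raise
            logger.error("failed on %s: %s", path.name, exc)
            failures[path.name] = str(exc)

    if results:
        combined = pd.concat([r.cell_table for r in results], ignore_index=True)
        summaries = pd.concat([r.summary for r in results], ignore_index=True)
    else:
        combined = pd.DataFrame(columns=quantify.BASE_COLUMNS)
        summaries = pd.DataFrame()

    if out_dir is not None:
        imgio.write_cell_table(combined, out_dir / "cells.csv")
        summaries.to_csv(out_dir / "summaries.csv", index=False)
        if failures:
            (out_dir / "failures.txt").write_text(
                "\n".join(f"{k}\t{v}" for k, v in failures.items()) + "\n"
            )
    return RunResult(stacks=results, cell_table=combined, summaries=summaries, failures=failures)
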