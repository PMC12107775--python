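"""End-to-end orchestration: simulate/ingest -> build -> select -> evaluate -> analyze.

Each run writes its outputs plus a single ``manifest.json`` capturing the
config snapshot, the per-stage seeds, input file digests, package version and
per-stage wall-clock, so deterministic stages can be reproduced bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biome import class_ratio_table, contrast_groups
from .core import build_method_matrix, filter_uniform
from .errors import ConfigError
from .evaluation import evaluate_variants
from .formats_io import read_study, write_matrix, write_study
from .selection import select_features
from .simulate import FIXTURES, StudyConfig, SubgroupSpec, generate_study
from .types import DEFAULT_MZ_RANGE, METHOD_TAGS, MassGroupScheme

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {"study", "inputs", "methods", "threshold", "mz_range",
               "mass_group_edges", "selection", "evaluation", "analyze", "seed"}


def stage_seed(seed: int, stage: str) -> int:
    """Named substream: one global seed fans out deterministically per stage."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    seeds: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    version: str = __version__
    timings_s: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    status: str = "running"

    def write(self, out_dir: Path) -> None:
        with open(Path(out_dir) / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def validate_config(config: dict) -> dict:
    """Schema check with field-level messages; returns the config unchanged."""
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}; "
                          f"allowed: {sorted(_KNOWN_KEYS)}")
    if ("study" in config) == ("inputs" in config):
        raise ConfigError("config needs exactly one of 'study' (simulate) "
                          "or 'inputs' (ingest existing files)")
    methods = config.get("methods", "all")
    if methods != "all":
        bad = [m for m in methods if m not in METHOD_TAGS]
        if bad:
            raise ConfigError(f"methods: unknown tag(s) {bad}; "
                              f"allowed: {list(METHOD_TAGS)}")
    thr = config.get("threshold", 0.5)
    if not 0.0 < thr < 1.0:
        raise ConfigError("threshold: must be in (0, 1)")
    if "mz_range" in config and len(config["mz_range"]) != 2:
        raise ConfigError("mz_range: must be [lo, hi]")
    return config


def _study_config(spec: dict, seed: int) -> StudyConfig:
    spec = dict(spec)
    preset = spec.pop("preset", None)
    if preset is not None:
        if preset not in FIXTURES:
            raise ConfigError(f"study.preset: unknown preset {preset!r}; "
                              f"allowed: {sorted(FIXTURES)}")
        base = asdict(FIXTURES[preset])
    else:
        base = {}
    base.update(spec)
    base["seed"] = stage_seed(seed, "simulate")
    if isinstance(base.get("subgroup"), dict):
        base["subgroup"] = SubgroupSpec(**base["subgroup"])
    try:
        return StudyConfig(**base)
    except TypeError as exc:
        raise ConfigError(f"study: {exc}") from exc


def run_pipeline(config: dict, out_dir) -> Path:
    """Run the full workflow; returns the output directory."""
    config = validate_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest = RunManifest(config=config)
    try:
        _run_stages(config, out_dir, seed, manifest)
        manifest.status = "ok"
    except Exception:
        manifest.status = "failed"
        manifest.write(out_dir)
        raise
    manifest.write(out_dir)
    return out_dir


def _run_stages(config: dict, out_dir: Path, seed: int, manifest: RunManifest) -> None:
    mz_range = tuple(config.get("mz_range", DEFAULT_MZ_RANGE))
    scheme = MassGroupScheme(tuple(config.get("mass_group_edges",
                                              MassGroupScheme().edges)))
    threshold = float(config.get("threshold", 0.5))
    methods = config.get("methods", "all")
    if methods == "all":
        methods = list(METHOD_TAGS)

    # --- stage: inputs --------------------------------------------------
    t0 = time.perf_counter()
    if "study" in config:
        study_cfg = _study_config(config["study"], seed)
        manifest.seeds["simulate"] = study_cfg.seed
        table, preds, meta, truth = generate_study(study_cfg)
        input_dir = out_dir / "inputs"
        paths = write_study(table, preds, meta, input_dir)
        with open(input_dir / "truth.json", "w", encoding="utf-8") as fh:
            json.dump(truth, fh, indent=2)
        manifest.input_digests = {k: _sha256(p) for k, p in paths.items()}
    else:
        in_dir = Path(config["inputs"]["dir"])
        table, preds, meta = read_study(in_dir)
        manifest.input_digests = {p.name: _sha256(p)
                                  for p in sorted(in_dir.iterdir()) if p.is_file()}
    manifest.timings_s["inputs"] = round(time.perf_counter() - t0, 3)
    n_in_range = int(((table.peaks["mz"] >= mz_range[0])
                      & (table.peaks["mz"] <= mz_range[1])).sum())
    manifest.counts["peaks_total"] = table.n_peaks
    manifest.counts["peaks_dropped_mz_filter"] = table.n_peaks - n_in_range
    if preds.n_records:
        detected_pairs = int((table.intensities.to_numpy() > 0).sum())
        manifest.counts["msms_records"] = preds.n_records
        manifest.counts["msms_coverage_pct"] = round(
            100.0 * preds.n_records / max(detected_pairs, 1), 2)

    # --- stage: build ---------------------------------------------------
    t0 = time.perf_counter()
    matrices = {}
    mat_dir = out_dir / "matrices"
    mat_dir.mkdir(exist_ok=True)
    for tag in methods:
        built = build_method_matrix(tag, table, preds, scheme=scheme,
                                    mz_range=mz_range, threshold=threshold)
        filtered = filter_uniform(built)
        manifest.counts[f"{tag}_features_before_filter"] = built.n_features
        manifest.counts[f"{tag}_features_after_filter"] = filtered.n_features
        if built.meta.get("skipped_samples"):
            manifest.counts[f"{tag}_samples_excluded_no_msms"] = len(
                built.meta["skipped_samples"])
        matrices[tag] = filtered
        write_matrix(filtered, mat_dir / f"{tag}.tsv")
    manifest.timings_s["build"] = round(time.perf_counter() - t0, 3)

    # --- stage: select --------------------------------------------------
    t0 = time.perf_counter()
    sel_cfg = config.get("selection", {})
    sel_seed = stage_seed(seed, "select")
    manifest.seeds["select"] = sel_seed
    sel_dir = out_dir / "selection"
    sel_dir.mkdir(exist_ok=True)
    selections = {}
    for tag, matrix in matrices.items():
        labels = meta.labels_for(matrix.samples)
        result = select_features(
            matrix, labels,
            n_target=sel_cfg.get("n_target"),
            k=int(sel_cfg.get("k", 10)), seed=sel_seed,
            n_estimators=int(sel_cfg.get("n_estimators", 100)))
        selections[tag] = result
        with open(sel_dir / f"{tag}.json", "w", encoding="utf-8") as fh:
            json.dump({
                "n_target": result.n_target,
                "fold_sets": [sorted(s) for s in result.fold_sets],
                "rfe1": sorted(result.rfe1),
                "rfe2": sorted(result.rfe2),
            }, fh, indent=2)
        for name in ("rfe1", "rfe2"):
            (sel_dir / f"{tag}.{name}.txt").write_text(
                "\n".join(sorted(getattr(result, name))) + "\n", encoding="utf-8")
    manifest.timings_s["select"] = round(time.perf_counter() - t0, 3)

    # --- stage: evaluate ------------------------------------------------
    t0 = time.perf_counter()
    eval_cfg = config.get("evaluation", {})
    eval_seed = stage_seed(seed, "evaluate")
    manifest.seeds["evaluate"] = eval_seed
    labels_by_sample = meta.table["biome"]
    report = evaluate_variants(matrices, selections, labels_by_sample,
                               k=int(eval_cfg.get("k", 10)), seed=eval_seed)
    eval_dir = out_dir / "evaluation"
    eval_dir.mkdir(exist_ok=True)
    report.table.to_csv(eval_dir / "report.tsv", sep="\t")
    with open(eval_dir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(json.loads(report.table.reset_index().to_json(orient="records")),
                  fh, indent=2)
    manifest.counts["evaluation_variants"] = report.n_variants
    manifest.timings_s["evaluate"] = round(time.perf_counter() - t0, 3)

    # --- stage: analyze -------------------------------------------------
    t0 = time.perf_counter()
    ana_cfg = config.get("analyze", {})
    ana_dir = out_dir / "analysis"
    ana_dir.mkdir(exist_ok=True)
    if "cc_avg" in matrices:
        cc = matrices["cc_avg"]
        classes = ana_cfg.get("classes")
        if classes is None:  # default: the most variable classes
            variances = cc.values.var(axis=0).sort_values(ascending=False)
            classes = list(variances.index[:10])
        ratios = class_ratio_table(cc, meta, classes)
        ratios.per_sample.to_csv(ana_dir / "class_ratios_per_sample.tsv", sep="\t")
        ratios.summary.to_csv(ana_dir / "class_ratios_summary.tsv", sep="\t")
    contrast = ana_cfg.get("contrast")
    if contrast and "cc_avg" in matrices:
        result = contrast_groups(matrices["cc_avg"], meta,
                                 biome=contrast["biome"],
                                 groupby=contrast.get("groupby", "contributor"))
        result.to_csv(ana_dir / "contrast.tsv", sep="\t")
    manifest.timings_s["analyze"] = round(time.perf_counter() - t0, 3)
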