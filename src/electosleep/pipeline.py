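"""End-to-end workflow orchestration with hash-based idempotence.

Stages (dependency order): simulate -> features -> label -> train -> predict
-> smooth -> architecture [-> compare].  Each stage records the SHA-256 of
its inputs and its config section in a run manifest; a re-run with unchanged
hashes is skipped.  A single global seed fans out to per-stage seeds (stage
name hashed in) so stages re-run independently yet deterministically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as esio
from .features import (
    average_regions,
    detect_outliers,
    flatten,
    median_normalize,
    screen_saturation,
    welch_feature_tensor,
)
from .hypnogram import Hypnogram, estimate_transitions, architecture_stats, smooth as smooth_hypnogram
from .sae import TrainingConfig, fit, nested_cv, predict as sae_predict
from .statemap import assign_by_polygons, auto_polygons, statemap_features
from .states import DEFAULT_REGIONS, names_to_labels
from .synthetic import SyntheticCohortSpec, write_fixture_cohort
from .groupstats import compare_conditions, state_mean_features

log = logging.getLogger("electosleep")

STAGE_ORDER = (
    "simulate", "features", "label", "train", "predict", "smooth",
    "architecture", "compare",
)


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (usually loaded from YAML)."""

    out_dir: Path
    seed: int = 0
    regions: tuple[str, ...] = DEFAULT_REGIONS
    cohort: dict = field(default_factory=dict)
    feature_params: dict = field(default_factory=dict)
    reference_region: str = "CxPrL"
    sae: dict = field(default_factory=dict)
    smoothing: dict = field(default_factory=lambda: {"k": 10, "smoothing": 1.0})
    compare: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        cfg = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            out_dir=Path(cfg.get("out_dir", "runs/default")),
            seed=int(cfg.get("seed", 0)),
            regions=tuple(cfg.get("regions", DEFAULT_REGIONS)),
            cohort=cfg.get("cohort", {}),
            feature_params=cfg.get("features", {}),
            reference_region=cfg.get("reference_region", "CxPrL"),
            sae=cfg.get("sae", {}),
            smoothing=cfg.get("smoothing", {"k": 10, "smoothing": 1.0}),
            compare=cfg.get("compare", {}),
        )

    def stage_seed(self, stage: str) -> int:
        return (self.seed + zlib.crc32(stage.encode())) % (2**31)

    def training_config(self) -> TrainingConfig:
        kw = {k: v for k, v in self.sae.items() if k != "mu"}
        kw.setdefault("seed", self.stage_seed("train"))
        if "mu_grid" in kw:
            kw["mu_grid"] = tuple(kw["mu_grid"])
        return TrainingConfig(**kw)


def _file_hash(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _config_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


class RunManifest:
    """Per-stage input/output hash record, persisted as JSON."""

    def __init__(self, path: Path):
        self.path = Path(path)
        self.data = (
            json.loads(self.path.read_text()) if self.path.exists() else {"stages": {}}
        )

    def up_to_date(self, stage: str, signature: str) -> bool:
        entry = self.data["stages"].get(stage)
        if entry is None or entry["signature"] != signature:
            return False
        return all(Path(p).exists() and _file_hash(Path(p)) == h
                   for p, h in entry["outputs"].items())

    def record(self, stage: str, signature: str, outputs: list[Path]) -> None:
        self.data["stages"][stage] = {
            "signature": signature,
            "outputs": {str(p): _file_hash(Path(p)) for p in outputs},
        }
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


def _mice(config: PipelineConfig) -> list[int]:
    n = int(config.cohort.get("n_mice", 9))
    return list(range(n))


def compute_features(recording, config: PipelineConfig):
    """Recording -> normalized FeatureTensor (outlier mask + averaging + Welch)."""
    fp = config.feature_params
    mask = detect_outliers(recording, mad_multiplier=fp.get("mad_multiplier", 20.0))
    traces, order = average_regions(recording, mask, region_order=list(config.regions))
    tensor = welch_feature_tensor(
        traces, fs=recording.fs, regions=order,
        segment_samples=fp.get("segment_samples", 512),
        f_max=fp.get("f_max", 54.7),
        valid_windows=~mask.window_invalid,
        subject_id=recording.subject_id, session_id=recording.session_id,
    )
    return median_normalize(tensor)


def run_pipeline(config: PipelineConfig, stages=None) -> RunManifest:
    """Execute requested stages in dependency order, skipping up-to-date ones."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(out / "run_manifest.json")
    todo = [s for s in STAGE_ORDER if stages is None or s in stages]
    if "compare" in todo and not config.compare:
        todo.remove("compare")

    for stage in todo:
        try:
            _run_stage(stage, config, out, manifest)
        except Exception as e:
            raise RuntimeError(
                f"stage {stage!r} failed: {e}; inputs and earlier outputs are "
                f"recorded in {manifest.path} — fix the cause and re-run (completed "
                "stages will be skipped)"
            ) from e
    return manifest


def _run_stage(stage: str, config: PipelineConfig, out: Path, manifest: RunManifest) -> None:
    mice = _mice(config)
    rec_paths = [out / f"mouse{m:02d}.h5" for m in mice]
    feat_paths = [out / f"mouse{m:02d}_features.h5" for m in mice]
    label_paths = [out / f"mouse{m:02d}_labels.csv" for m in mice]
    pred_paths = [out / f"mouse{m:02d}_pred.csv" for m in mice]
    smooth_paths = [out / f"mouse{m:02d}_smoothed.csv" for m in mice]
    model_path = out / "model.h5"

    def signature(section, inputs: list[Path]) -> str:
        return _config_hash(
            {
                "section": section,
                "seed": config.seed,
                "inputs": {str(p): _file_hash(p) for p in inputs if Path(p).exists()},
            }
        )

    if stage == "simulate":
        sig = signature(config.cohort, [])
        if manifest.up_to_date(stage, sig):
            log.info("simulate: up to date")
            return
        spec = SyntheticCohortSpec(
            region_names=tuple(config.regions),
            seed=config.stage_seed("simulate"),
            **config.cohort,
        )
        write_fixture_cohort(spec, out)
        manifest.record(stage, sig, rec_paths)

    elif stage == "features":
        sig = signature(config.feature_params, rec_paths)
        if manifest.up_to_date(stage, sig):
            log.info("features: up to date")
            return
        for rp, fp_ in zip(rec_paths, feat_paths):
            rec = esio.read_recording(rp)
            tensor = compute_features(rec, config)
            esio.write_features(fp_, tensor)
            log.info(
                "features %s: %d windows, %d excluded",
                rp.name, tensor.n_windows, int((~tensor.valid_mask).sum()),
            )
        manifest.record(stage, sig, feat_paths)

    elif stage == "label":
        sig = signature({"ref": config.reference_region}, rec_paths)
        if manifest.up_to_date(stage, sig):
            log.info("label: up to date")
            return
        for rp, lp in zip(rec_paths, label_paths):
            rec = esio.read_recording(rp)
            pts = statemap_features(rec, config.reference_region)
            polys = auto_polygons(pts, seed=config.stage_seed("label"))
            hyp = assign_by_polygons(pts, polys)
            hyp.to_csv(lp)
        manifest.record(stage, sig, label_paths)

    elif stage == "train":
        sig = signature(config.sae, feat_paths + label_paths)
        if manifest.up_to_date(stage, sig):
            log.info("train: up to date")
            return
        feats, labels, meta = [], [], None
        for fp_, lp in zip(feat_paths, label_paths):
            tensor = esio.read_features(fp_)
            hyp = Hypnogram.from_csv(lp)
            n = min(tensor.n_windows, len(hyp))
            X = flatten(tensor)[:n]
            y = hyp.labels[:n].copy()
            y[~tensor.valid_mask[:n]] = -1
            feats.append(X)
            labels.append(y)
            meta = tensor
        model = fit(feats, labels, config.training_config(), mu=config.sae.get("mu"))
        model.regions = meta.regions
        model.freqs = meta.freqs
        esio.write_model(model_path, model)
        manifest.record(stage, sig, [model_path])

    elif stage == "predict":
        sig = signature({}, feat_paths + [model_path])
        if manifest.up_to_date(stage, sig):
            log.info("predict: up to date")
            return
        model = esio.read_model(model_path)
        for fp_, pp in zip(feat_paths, pred_paths):
            tensor = esio.read_features(fp_)
            sae_predict(model, tensor).to_csv(pp)
        manifest.record(stage, sig, pred_paths)

    elif stage == "smooth":
        sig = signature(config.smoothing, pred_paths + label_paths)
        if manifest.up_to_date(stage, sig):
            log.info("smooth: up to date")
            return
        label_seqs = [Hypnogram.from_csv(lp).labels for lp in label_paths]
        tm = estimate_transitions(label_seqs, smoothing=config.smoothing.get("smoothing", 1.0))
        esio.write_transitions(out / "transitions.json", tm)
        for pp, sp in zip(pred_paths, smooth_paths):
            hyp = Hypnogram.from_csv(pp)
            smooth_hypnogram(hyp, tm, k=int(config.smoothing.get("k", 10))).to_csv(sp)
        manifest.record(stage, sig, smooth_paths + [out / "transitions.json"])

    elif stage == "architecture":
        sig = signature({}, smooth_paths)
        if manifest.up_to_date(stage, sig):
            log.info("architecture: up to date")
            return
        stats = {
            sp.stem: architecture_stats(Hypnogram.from_csv(sp)) for sp in smooth_paths
        }
        stats_path = out / "architecture.json"
        stats_path.write_text(json.dumps(stats, indent=2, sort_keys=True))
        manifest.record(stage, sig, [stats_path])

    elif stage == "compare":
        sig = signature(config.compare, feat_paths + smooth_paths)
        if manifest.up_to_date(stage, sig):
            log.info("compare: up to date")
            return
        groups = config.compare.get("groups", {})
        summaries: dict[str, list] = {}
        for m, (fp_, sp) in enumerate(zip(feat_paths, smooth_paths)):
            cond = groups.get(f"mouse{m:02d}")
            if cond is None:
                continue
            tensor = esio.read_features(fp_)
            hyp = Hypnogram.from_csv(sp)
            summaries.setdefault(cond, []).append(
                state_mean_features(tensor, hyp, condition=cond)
            )
        conds = sorted(summaries)
        if len(conds) != 2:
            raise ValueError(f"compare needs exactly 2 conditions, got {conds}")
        cmp = compare_conditions(
            summaries[conds[0]], summaries[conds[1]],
            alpha_display=config.compare.get("alpha_display", 0.01),
        )
        payload = {
            st: {"hmp": c.hmp, "headline_p": c.headline_p,
                 "n_significant_features": int(c.display_mask.sum())}
            for st, c in cmp.items()
        }
        cmp_path = out / "comparison.json"
        cmp_path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        manifest.record(stage, sig, [cmp_path])

    else:
        raise ValueError(f"unknown stage {stage!r}")


def validate_inputs(paths, regions=DEFAULT_REGIONS) -> dict:
    """Per-file format/coverage/rate/saturation report (never raises)."""
    report: dict = {"files": {}, "ok": True}
    for p in map(Path, paths):
        entry: dict = {"exists": p.exists(), "problems": []}
        if not p.exists():
            entry["problems"].append("missing file")
        else:
            try:
                rec = esio.read_recording(p)
                entry["fs"] = rec.fs
                if rec.fs != 1000.0:
                    entry["problems"].append(f"sampling rate {rec.fs} != 1000 Hz")
                missing = [r for r in regions if r not in rec.regions]
                if missing:
                    entry["problems"].append(f"regions missing from channel map: {missing}")
                saturated = [
                    ch for ch in sorted(rec.channel_region_map)
                    if screen_saturation(rec.signals[ch])
                ]
                if rec.emg_channel is not None and screen_saturation(rec.emg):
                    saturated.append(rec.emg_channel)
                if saturated:
                    entry["problems"].append(f"saturated channels: {saturated}")
            except Exception as e:
                entry["problems"].append(f"unreadable: {e}")
        report["files"][str(p)] = entry
        report["ok"] &= not entry["problems"]
    return report
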