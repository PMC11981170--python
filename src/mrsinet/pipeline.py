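"""End-to-end pipeline: simulate -> transform -> classify -> evaluate -> saliency.

Each stage writes one artifact carrying a hash of the configuration it
was produced from (plus its upstream hashes); re-running an unchanged
configuration skips completed stages.
"""

from __future__ import annotations

import csv
import json
import logging
import os
from typing import Dict, Optional

import h5py
import numpy as np

from . import classifier_net as cnet
from . import io as io_mod
from . import metrics as metrics_mod
from . import saliency as saliency_mod
from . import simulate as sim_mod
from . import transform_net as tnet
from .config import ExperimentConfig
from .errors import MrsiNetError

log = logging.getLogger("mrsinet.pipeline")


def _stage_paths(cfg: ExperimentConfig) -> Dict[str, str]:
    out = cfg.out_dir
    return {
        "paired_data": os.path.join(out, "data", "paired"),
        "labeled_data": os.path.join(out, "data", "labeled"),
        "transform_ckpt": os.path.join(out, "ckpt", "transform.npz"),
        "classifier_ckpt": os.path.join(out, "ckpt", "classifier.npz"),
        "report": os.path.join(out, "report.json"),
        "saliency_maps": os.path.join(out, "saliency", "maps.h5"),
        "saliency_regions": os.path.join(out, "saliency", "regions.csv"),
    }


def _dataset_hash_matches(path: str, stage_hash: str) -> bool:
    try:
        ds = io_mod.read_dataset(path)
    except (MrsiNetError, OSError):
        return False
    return ds.train.provenance.get("stage_hash") == stage_hash


def _ckpt_hash_matches(path: str, stage_hash: str) -> bool:
    if not os.path.exists(path):
        return False
    try:
        _, header = io_mod.load_checkpoint(path)
    except MrsiNetError:
        return False
    return header.get("stage_hash") == stage_hash


def simulate_stage(cfg: ExperimentConfig, labeled: bool) -> str:
    paths = _stage_paths(cfg)
    key = "labeled_data" if labeled else "paired_data"
    sim = cfg.simulator
    stage_hash = io_mod.config_hash({"sim": cfg.section_dict("simulator"),
                                     "labeled": labeled})
    if _dataset_hash_matches(paths[key], stage_hash):
        log.info("stage=simulate labeled=%s status=skipped hash=%s",
                 labeled, stage_hash)
        return paths[key]
    aug = sim.augment_params()
    if labeled:
        ds = sim_mod.generate_labeled_dataset(
            n_per_class=sim.n_per_class, aug=aug,
            split_fractions=tuple(sim.split_fractions),
            master_seed=sim.master_seed + 1,
            field_range=tuple(sim.field_range),
            discrete_fields=sim.discrete_fields)
    else:
        metabolites = None
        if sim.phantom:
            metabolites, ranges = sim_mod.phantom_preset()
            ds = sim_mod.generate_dataset(
                n=sim.n, ranges=ranges, aug=aug,
                split_fractions=tuple(sim.split_fractions),
                master_seed=sim.master_seed,
                field_range=tuple(sim.field_range),
                discrete_fields=sim.discrete_fields,
                metabolites=metabolites)
        else:
            ds = sim_mod.generate_dataset(
                n=sim.n, aug=aug,
                split_fractions=tuple(sim.split_fractions),
                master_seed=sim.master_seed,
                field_range=tuple(sim.field_range),
                discrete_fields=sim.discrete_fields)
    io_mod.write_dataset(ds, paths[key],
                         extra_provenance={"stage_hash": stage_hash,
                                           "split_fractions": list(sim.split_fractions)})
    log.info("stage=simulate labeled=%s status=done n_train=%d", labeled,
             len(ds.train))
    return paths[key]


def train_transform_stage(cfg: ExperimentConfig) -> str:
    paths = _stage_paths(cfg)
    stage_hash = io_mod.config_hash({
        "sim": cfg.section_dict("simulator"),
        "transform": cfg.section_dict("transform"),
        "seed": cfg.seeds.transform})
    if _ckpt_hash_matches(paths["transform_ckpt"], stage_hash):
        log.info("stage=train-transform status=skipped hash=%s", stage_hash)
        return paths["transform_ckpt"]
    data = io_mod.read_dataset(simulate_stage(cfg, labeled=False))
    model = tnet.build_transform_net(cfg.transform, seed=cfg.seeds.transform)
    state, history = tnet.train_transform(model, data.train, data.validation,
                                          cfg.transform,
                                          seed=cfg.seeds.transform)
    io_mod.save_checkpoint(state, paths["transform_ckpt"], header={
        "stage_hash": stage_hash, "kind": "transform",
        "config": cfg.section_dict("transform"),
        "seed": cfg.seeds.transform,
        "best_epoch": history.best_epoch,
        "val_mse": history.val_loss[history.best_epoch],
        "epochs_run": len(history.val_loss)})
    log.info("stage=train-transform status=done best_epoch=%d val_mse=%.3e",
             history.best_epoch, history.val_loss[history.best_epoch])
    return paths["transform_ckpt"]


def train_classifier_stage(cfg: ExperimentConfig) -> str:
    paths = _stage_paths(cfg)
    stage_hash = io_mod.config_hash({
        "sim": cfg.section_dict("simulator"),
        "transform": cfg.section_dict("transform"),
        "classifier": cfg.section_dict("classifier"),
        "seeds": cfg.section_dict("seeds")})
    if _ckpt_hash_matches(paths["classifier_ckpt"], stage_hash):
        log.info("stage=train-classifier status=skipped hash=%s", stage_hash)
        return paths["classifier_ckpt"]
    t_state, _ = io_mod.load_checkpoint(train_transform_stage(cfg))
    data = io_mod.read_dataset(simulate_stage(cfg, labeled=True))
    model = cnet.build_combined(t_state, cfg.classifier,
                                transform_config=cfg.transform,
                                seed=cfg.seeds.classifier)
    state, history = cnet.train_classifier(model, data.train, data.validation,
                                           cfg.classifier,
                                           seed=cfg.seeds.classifier)
    io_mod.save_checkpoint(state, paths["classifier_ckpt"], header={
        "stage_hash": stage_hash, "kind": "combined",
        "config": cfg.section_dict("classifier"),
        "transform_config": cfg.section_dict("transform"),
        "seed": cfg.seeds.classifier,
        "best_epoch": history.best_epoch,
        "val_bce": history.val_loss[history.best_epoch]})
    log.info("stage=train-classifier status=done best_epoch=%d val_bce=%.4f",
             history.best_epoch, history.val_loss[history.best_epoch])
    return paths["classifier_ckpt"]


def _load_models(cfg: ExperimentConfig):
    t_state, _ = io_mod.load_checkpoint(_stage_paths(cfg)["transform_ckpt"])
    c_state, _ = io_mod.load_checkpoint(_stage_paths(cfg)["classifier_ckpt"])
    transform = tnet.build_transform_net(cfg.transform, seed=cfg.seeds.transform)
    transform.load_state_dict(t_state)
    combined = cnet.build_combined(transform, cfg.classifier,
                                   seed=cfg.seeds.classifier)
    combined.load_state_dict(c_state)
    return transform, combined


def evaluate_stage(cfg: ExperimentConfig) -> Dict:
    paths = _stage_paths(cfg)
    train_classifier_stage(cfg)
    transform, combined = _load_models(cfg)
    paired = io_mod.read_dataset(paths["paired_data"])
    labeled = io_mod.read_dataset(paths["labeled_data"])
    pred = tnet.transform(transform, paired.test.fids)
    recon = metrics_mod.recon_report(paired.test.targets, pred,
                                     ppm_axis=paired.test.ppm_axis)
    probs = cnet.predict(combined, labeled.test.fids)
    roc = metrics_mod.roc_auc(labeled.test.labels, probs)
    conf = metrics_mod.confusion(labeled.test.labels, probs,
                                 threshold=cfg.evaluation.threshold)
    report = {
        "reconstruction": recon.to_dict(),
        "classification": {"auc": roc.auc, "confusion": conf.to_dict(),
                           "threshold": cfg.evaluation.threshold,
                           "n_test": int(len(labeled.test))},
        "config_hash": io_mod.config_hash(cfg.to_dict()),
    }
    os.makedirs(os.path.dirname(paths["report"]) or ".", exist_ok=True)
    with open(paths["report"], "w") as fh:
        json.dump(report, fh, indent=2)
    log.info("stage=evaluate status=done auc=%.3f mse=%.3e", roc.auc,
             recon.mse[0])
    return report


def saliency_stage(cfg: ExperimentConfig) -> Dict:
    paths = _stage_paths(cfg)
    train_classifier_stage(cfg)
    _, combined = _load_models(cfg)
    labeled = io_mod.read_dataset(paths["labeled_data"])
    test = labeled.test
    os.makedirs(os.path.dirname(paths["saliency_maps"]), exist_ok=True)
    reports = {}
    with h5py.File(paths["saliency_maps"], "w") as f:
        f.create_dataset("ppm_axis", data=test.ppm_axis)
        for cls_name, label_val in (("glioma", 1), ("healthy", 0)):
            idx = np.nonzero(test.labels == label_val)[0]
            idx = idx[:cfg.evaluation.n_saliency_maps]
            maps = [saliency_mod.grad_cam(combined, test.fids[i],
                                          target_class=cls_name,
                                          ppm_axis=test.ppm_axis)
                    for i in idx]
            if not maps:
                continue
            arr = np.stack([m.importance for m in maps])
            f.create_dataset(f"importance_{cls_name}", data=arr)
            reports[cls_name] = saliency_mod.region_report(
                maps, windows=cfg.evaluation.windows)
    with open(paths["saliency_regions"], "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=[
            "target_class", "window_name", "ppm_lo", "ppm_hi",
            "mean_importance", "rank"])
        writer.writeheader()
        for cls_name, rep in reports.items():
            for row in rep.to_rows():
                writer.writerow(dict(row, target_class=cls_name))
    log.info("stage=saliency status=done classes=%s", list(reports))
    return reports


def run_pipeline(cfg: Optional[ExperimentConfig] = None) -> Dict:
    """Execute all stages; returns the report bundle (paths + metrics)."""
    cfg = cfg or ExperimentConfig()
    paths = _stage_paths(cfg)
    try:
        simulate_stage(cfg, labeled=False)
        simulate_stage(cfg, labeled=True)
        train_transform_stage(cfg)
        train_classifier_stage(cfg)
        report = evaluate_stage(cfg)
        sal = saliency_stage(cfg)
    except MrsiNetError as exc:
        raise MrsiNetError(
            f"pipeline aborted: {exc} — fix the offending stage "
            "configuration and re-run (completed stages are kept)") from exc
    bundle = {"paths": paths, "report": report,
              "saliency": {k: v.to_rows() for k, v in sal.items()}}
    return bundle
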