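"""End-to-end pipeline driver: synth → preprocess → tfr → cluster → outcome.

The driver runs the full analysis for one channel of interest: simulate
(or load) a cohort, band-pass filter, epoch, reject, apply the
min-epoch inclusion rule, compute baseline-corrected TFR maps per
condition, run the cluster permutation test, derive the per-participant
discrimination measure from the most significant cluster (or a
configured fallback band/window mask), and fit the longitudinal path
models.  Every attrition point — epochs rejected per stage, participants
excluded, per-model n — is recorded in a run manifest.
"""

from __future__ import annotations

import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import cluster as clustermod
from . import io as iomod
from . import outcome as outcomemod
from . import preprocess as prep
from . import synth as synthmod
from . import tfr as tfrmod
from .containers import KEPT

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved configuration for a full pipeline run."""

    sim: synthmod.SimConfig = field(default_factory=synthmod.SimConfig)
    seed: int = 0
    channel: str = "F4"
    filter_low: float = 1.0
    filter_high: float = 8.0
    filter_order: int = 4
    p2p_threshold: float = 150.0
    sd_hi_factor: float = 3.0
    sd_lo_factor: float = 1.0 / 3.0
    sd_iterative: bool = True
    min_epochs: int = 20
    freqs: tuple = tfrmod.DEFAULT_FREQS
    n_cycles: float = 3.5
    trim_ms: float = 200.0
    baseline: tuple = (-200.0, 0.0)
    n_perm: int = 1000
    cluster_alpha: float = 0.05
    connectivity: int = 4
    alpha: float = 0.05
    m_comparisons: int = 2
    fallback_band: tuple = (4.0, 5.0)
    fallback_window: tuple = (0.0, 1080.0)
    input_recordings: list = None  # optional: paths instead of simulation
    vocab_table: str = None        # optional: CSV path instead of simulation

    def to_dict(self):
        d = asdict(self)
        d["sim"] = self.sim.to_dict()
        for key in ("freqs", "baseline", "fallback_band", "fallback_window"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        if "sim" in d and not isinstance(d["sim"], synthmod.SimConfig):
            d["sim"] = synthmod.SimConfig.from_dict(d["sim"])
        for key in ("freqs", "baseline", "fallback_band", "fallback_window"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class PipelineResult:
    manifest: dict
    cluster_result: object
    group: object
    discrimination: pd.DataFrame
    outcome_table: pd.DataFrame
    path_report: object


def preprocess_participant(rec, cfg: PipelineConfig):
    """Filter → epoch → three-stage rejection for one recording."""
    filtered = prep.bandpass_filter(rec, cfg.filter_low, cfg.filter_high,
                                    cfg.filter_order)
    eps = prep.segment_epochs(filtered, cfg.sim.epoch_pre_ms,
                              cfg.sim.epoch_post_ms)
    if eps.n_epochs == 0:
        return eps
    eps = prep.reject_epochs(eps, cfg.p2p_threshold, cfg.sd_hi_factor,
                             cfg.sd_lo_factor, iterative=cfg.sd_iterative)
    return eps


def _participant_maps(eps, cfg: PipelineConfig, pid):
    maps = {}
    for cond in (cfg.sim.condition_a, cfg.sim.condition_b):
        maps[cond] = tfrmod.epochs_to_tfr(
            eps, cfg.channel, cond, freqs=cfg.freqs, n_cycles=cfg.n_cycles,
            trim_ms=cfg.trim_ms, baseline=cfg.baseline, participant_id=pid)
    return maps


def _load_recordings(cfg: PipelineConfig):
    for path in cfg.input_recordings:
        pid = os.path.splitext(os.path.basename(path))[0]
        yield pid, iomod.read_eeg(path), None


def simulate_group(sim_cfg, seed, cfg: PipelineConfig = None):
    """Simulate a cohort and run it to a group TFR stack.

    Convenience for calibration/recovery studies that stop before the
    outcome stage: returns ``(GroupTFR, GroundTruth)`` for the included
    participants on the configured channel.
    """
    pcfg = _with_sim(cfg or PipelineConfig(), sim_cfg)
    conds = (sim_cfg.condition_a, sim_cfg.condition_b)
    truth = synthmod.draw_ground_truth(sim_cfg, seed)
    maps_a, maps_b = [], []
    for pid, rec, _ in synthmod.iter_recordings(sim_cfg, truth):
        eps = preprocess_participant(rec, pcfg)
        if not prep.check_inclusion(eps, conds, pcfg.min_epochs).included:
            continue
        maps = _participant_maps(eps, pcfg, pid)
        maps_a.append(maps[conds[0]])
        maps_b.append(maps[conds[1]])
    return clustermod.group_from_maps(maps_a, maps_b), truth


def _with_sim(cfg: PipelineConfig, sim_cfg):
    if cfg.sim is sim_cfg:
        return cfg
    out = PipelineConfig.from_dict(cfg.to_dict())
    out.sim = sim_cfg
    return out


def run_pipeline(cfg: PipelineConfig, out_dir=None) -> PipelineResult:
    """Execute the full pipeline; idempotent for a fixed config and seed."""
    conds = (cfg.sim.condition_a, cfg.sim.condition_b)
    manifest = {"seed": cfg.seed, "channel": cfg.channel,
                "participants": {}, "config": cfg.to_dict()}

    if cfg.input_recordings:
        source = _load_recordings(cfg)
        truth = None
    else:
        truth = synthmod.draw_ground_truth(cfg.sim, cfg.seed)
        source = synthmod.iter_recordings(cfg.sim, truth)

    maps_a, maps_b, included_ids = [], [], []
    for pid, rec, info in source:
        eps = preprocess_participant(rec, cfg)
        decision = prep.check_inclusion(eps, conds, cfg.min_epochs)
        entry = {"kept": decision.counts,
                 "status_counts": eps.status_counts() if eps.n_epochs else {},
                 "included": decision.included, "reason": decision.reason}
        if info is not None:
            entry["n_artifact_epochs"] = len(info["artifact_epochs"])
        manifest["participants"][pid] = entry
        if not decision.included:
            logger.info("participant %s excluded: %s", pid, decision.reason)
            continue
        maps = _participant_maps(eps, cfg, pid)
        maps_a.append(maps[conds[0]])
        maps_b.append(maps[conds[1]])
        included_ids.append(pid)

    manifest["n_included"] = len(included_ids)
    manifest["n_excluded"] = len(manifest["participants"]) - len(included_ids)
    if len(included_ids) < 2:
        raise RuntimeError("fewer than 2 included participants; "
                           "cannot run group statistics")

    group = clustermod.group_from_maps(maps_a, maps_b)
    result = clustermod.permutation_cluster_test(
        group, n_perm=cfg.n_perm, seed=cfg.seed, alpha=cfg.cluster_alpha,
        connectivity=cfg.connectivity)

    significant = result.significant_clusters()
    if significant:
        mask = significant[0].mask
        mask_source = "most_significant_cluster"
    else:
        mask = clustermod.band_window_mask(group.freqs, group.times,
                                           cfg.fallback_band,
                                           cfg.fallback_window)
        mask_source = "fallback_band_window"
        logger.info("no significant cluster; discrimination measured over "
                    "the configured %s Hz / %s ms mask", cfg.fallback_band,
                    cfg.fallback_window)
    disc = clustermod.discrimination_measure(group, mask)
    discrimination = pd.DataFrame({"participant_id": included_ids,
                                   "discrimination_0m": disc})
    manifest["cluster"] = {
        "mask_source": mask_source,
        "n_clusters": len(result.clusters),
        "min_p": result.min_p(),
        "threshold": result.threshold,
        "df": result.df,
    }

    if cfg.vocab_table:
        vocab = iomod.read_vocab_csv(cfg.vocab_table)
    elif truth is not None:
        vocab = synthmod.simulate_vocabulary(truth, cfg.sim)
    else:
        raise RuntimeError("no vocabulary source: set vocab_table or simulate")

    table = discrimination.merge(vocab, on="participant_id", how="left")
    report = outcomemod.run_path_analysis(table, alpha=cfg.alpha,
                                          m_comparisons=cfg.m_comparisons)
    manifest["models"] = {mid: {"n": rep.n, "beta": rep.beta,
                                "p": rep.p_model}
                          for mid, rep in report.all_models().items()}
    manifest["adjusted_alpha"] = report.adjusted_alpha
    manifest["removed_outliers"] = report.removed_outliers
    manifest["influential_ids"] = report.influential_ids

    if out_dir:
        _write_outputs(out_dir, cfg, manifest, result, discrimination,
                       table, report)
    return PipelineResult(manifest, result, group, discrimination, table,
                          report)


def _write_outputs(out_dir, cfg, manifest, result, discrimination, table,
                   report):
    os.makedirs(out_dir, exist_ok=True)
    cfg.to_yaml(os.path.join(out_dir, "config.yaml"))
    iomod.write_manifest(manifest, os.path.join(out_dir, "manifest.json"))
    pd.DataFrame(clustermod.cluster_table(result)).to_csv(
        os.path.join(out_dir, "clusters.csv"), index=False)
    discrimination.to_csv(os.path.join(out_dir, "discrimination.csv"),
                          index=False)
    table.to_csv(os.path.join(out_dir, "outcome_table.csv"), index=False)
    report.table().to_csv(os.path.join(out_dir, "regression_table.tsv"),
                          sep="\t", index=False)
    pd.DataFrame(report.edges()).to_csv(os.path.join(out_dir, "edges.csv"),
                                        index=False)
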