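"""End-to-end orchestration: synthetic cohort -> preprocessing ->
microstates / ERP / connectivity -> graph metrics -> statistics.

One YAML config drives every stage; all outputs are pure functions of
(config, seed).  Subjects are processed one at a time so full-length raw
recordings never accumulate in memory; downstream stages work from pooled
epoch summaries and per-block adjacency matrices.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectivity, erp, io, microstate, network, preprocess, stats, synth
from .containers import EpochSet
from .montage import is_midline

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    synth: synth.SynthConfig = field(default_factory=synth.SynthConfig)
    # preprocess
    lo_hz: float = 1.0
    hi_hz: float = 40.0
    tmin: float = 0.0
    tmax: float = 3.5
    peak_to_peak_max: float = 200.0
    # microstate
    k_min: int = 2
    k_max: int = 8
    polarity: str = "sensitive"
    min_peak_separation_ms: float = 10.0
    # erp
    electrodes: tuple[str, ...] = ("Fp1", "Fpz", "Fp2", "AF3", "AF4")
    alpha: float = 0.05
    min_run_ms: float = 20.0
    # connectivity / network
    seg_len_s: float = 1.0
    bands: tuple[str, ...] = ("delta", "theta", "alpha", "beta", "gamma")
    # stats
    split_k: int = 16
    behavior_band: str = "theta"
    behavior_measure: str = "cc_midline"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth_kwargs = raw.pop("synth", {})
        for key in ("condition_labels", "channel_labels"):
            if key in synth_kwargs:
                synth_kwargs[key] = (
                    tuple(synth_kwargs[key]) if key == "condition_labels"
                    else list(synth_kwargs[key]))
        cfg = cls(synth=synth.SynthConfig(**synth_kwargs))
        for key, val in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            default = getattr(cfg, key)
            setattr(cfg, key, tuple(val) if isinstance(default, tuple) else val)
        return cfg

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    outputs: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    versions: dict = field(default_factory=dict)

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=1, default=str))
        return path


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name, timings, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        out = fn(*args, **kwargs)
    except Exception as exc:
        raise StageError(f"stage {name!r} failed: {exc}") from exc
    timings[name] = round(time.perf_counter() - t0, 3)
    logger.info("stage %s done in %.2fs", name, timings[name])
    return out


def run_all(config: PipelineConfig | str | Path, out_dir, *,
            seed: int | None = None) -> RunManifest:
    """Execute every stage and write outputs + a manifest to *out_dir*.

    *seed* overrides ``config.synth.seed``; with both fixed the metric and
    statistics tables are bit-identical across runs.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    scfg = config.synth if seed is None else replace(config.synth, seed=seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.hash(), seed=scfg.seed,
                           versions={"numpy": np.__version__,
                                     "pandas": pd.__version__})
    timings = manifest.timings

    cohort = _stage("acquire+preprocess", timings, _cohort_pass, config, scfg)
    (cond_sums, cond_counts, pooled_trials, pooled_conds, adjacency,
     labels, positions, n_rejected) = cohort
    manifest.counts["epochs_rejected"] = n_rejected
    manifest.counts["blocks"] = len(adjacency) // max(1, len(config.bands))

    ms_out = _stage("microstate", timings, _microstate_stage,
                    config, scfg, cond_sums, cond_counts)
    erp_out = _stage("erp", timings, _erp_stage,
                     config, scfg, pooled_trials, pooled_conds, labels)
    whole, nodal = _stage("network", timings, _network_stage,
                          config, adjacency, labels)
    behavior = _stage("behavior", timings, _behavior_stage,
                      config, scfg, whole, nodal)
    valence = synth.generate_valence(scfg)
    stat_out = _stage("stats", timings, _stats_stage,
                      config, whole, nodal, behavior, valence, positions)

    outputs = manifest.outputs
    outputs["behavior"] = str(io.write_table(behavior, out_dir / "behavior.tsv"))
    outputs["valence"] = str(io.write_table(valence, out_dir / "valence.tsv"))
    outputs["metrics"] = str(io.write_table(whole, out_dir / "metrics.tsv"))
    outputs["nodal_metrics"] = str(io.write_table(nodal, out_dir / "nodal_metrics.tsv"))
    outputs["erp_components"] = str(io.write_table(
        erp_out["components"], out_dir / "erp_components.tsv"))
    outputs["erp_anova"] = str(io.write_table(
        erp_out["anova"], out_dir / "erp_anova_intervals.tsv"))
    for cond, sol in ms_out["solutions"].items():
        tpath = out_dir / f"microstate_templates_{cond}.tsv"
        pd.DataFrame(sol.templates.T, index=labels).to_csv(
            tpath, sep="\t", index_label="channel")
        outputs[f"microstate_templates_{cond}"] = str(tpath)
        spath = out_dir / f"microstate_segments_{cond}.tsv"
        io.write_table(sol.segment_table, spath)
        outputs[f"microstate_segments_{cond}"] = str(spath)
    if ms_out["matching"] is not None:
        outputs["microstate_matching"] = str(io.write_table(
            ms_out["matching"], out_dir / "microstate_matching.tsv"))
    outputs["stats"] = str(io.write_table(stat_out, out_dir / "stats_results.tsv"))
    manifest.counts["selected_k"] = {c: int(s.K)
                                     for c, s in ms_out["solutions"].items()}
    manifest.save(out_dir / "manifest.json")
    outputs["manifest"] = str(out_dir / "manifest.json")

    missing = [p for p in outputs.values() if not Path(p).exists()]
    if missing:  # pragma: no cover - invariant check
        raise StageError(f"stage 'manifest' failed: missing outputs {missing}")
    return manifest


# --------------------------------------------------------------------------
# stage implementations

def _cohort_pass(config: PipelineConfig, scfg: synth.SynthConfig):
    """Generate and preprocess every subject; pool what later stages need."""
    cond_sums: dict[str, np.ndarray] = {}
    cond_counts: dict[str, int] = {}
    pooled_trials, pooled_conds = [], []
    adjacency: dict[tuple, np.ndarray] = {}
    labels = positions = None
    n_rejected = 0
    el_idx = None
    bands = {b: connectivity.BANDS[b] for b in config.bands}

    for subj in range(1, scfg.n_subjects + 1):
        rec, events, _truth = synth.generate_recording(
            scfg, seed=[scfg.seed, subj])
        rec = preprocess.bandpass(rec, config.lo_hz, config.hi_hz)
        rec = preprocess.average_reference(rec)
        eps = preprocess.epoch(rec, events, config.tmin, config.tmax)
        eps = preprocess.reject_epochs(eps, config.peak_to_peak_max)
        n_rejected += int((~eps.kept_mask).sum())
        if labels is None:
            labels, positions = list(eps.labels), eps.positions
            el_idx = [eps.channel_index(e) for e in config.electrodes]

        for cond in scfg.condition_labels:
            kept = eps.kept(cond)
            if kept.shape[0] == 0:
                continue
            cond_sums[cond] = cond_sums.get(cond, 0) + kept.sum(axis=0)
            cond_counts[cond] = cond_counts.get(cond, 0) + kept.shape[0]
            pooled_trials.append(kept[:, el_idx, :])
            pooled_conds.append(np.repeat(cond, kept.shape[0]))

        block_of_trial = events["block"].to_numpy()
        for b in np.unique(block_of_trial):
            sel = (block_of_trial == b) & eps.kept_mask
            block_eps = EpochSet(
                data=eps.data[sel], tmin=eps.tmin, tmax=eps.tmax, fs=eps.fs,
                condition=eps.condition[sel], labels=labels,
                positions=positions)
            adj = connectivity.band_adjacencies(
                block_eps, seg_len_s=config.seg_len_s, bands=bands)
            for band, W in adj.items():
                adjacency[(subj, int(b), band)] = W
    return (cond_sums, cond_counts, pooled_trials, pooled_conds, adjacency,
            labels, positions, n_rejected)


def _microstate_stage(config: PipelineConfig, scfg, cond_sums, cond_counts):
    solutions, templates_by_cond = {}, {}
    for cond, total in cond_sums.items():
        grand = total / cond_counts[cond]
        grand = grand - grand.mean(axis=0, keepdims=True)
        series = microstate.gfp(grand, fs=scfg.fs)
        peaks = microstate.gfp_peaks(series, config.min_peak_separation_ms)
        if peaks.size < 2:
            logger.warning("condition %s: too few GFP peaks for clustering",
                           cond)
            continue
        maps = grand[:, peaks].T
        k_max = min(config.k_max, maps.shape[0])
        k_min = min(config.k_min, k_max)
        sols = microstate.taahc(maps, k_min=k_min, k_max=k_max,
                                polarity=config.polarity)
        k_star = microstate.select_k(sols, maps)
        sol = sols[k_star]
        _, segments = microstate.backfit(grand, sol.templates, fs=scfg.fs,
                                         polarity=config.polarity,
                                         tmin=config.tmin)
        sol.segment_table = segments
        solutions[cond] = sol
        templates_by_cond[cond] = sol.templates
    matching = (microstate.match_across_conditions(templates_by_cond)
                if len(templates_by_cond) >= 2 else None)
    return {"solutions": solutions, "matching": matching}


def _erp_stage(config: PipelineConfig, scfg, pooled_trials, pooled_conds,
               labels):
    data = np.concatenate(pooled_trials, axis=0)
    conds = np.concatenate(pooled_conds)
    eps = EpochSet(data=data, tmin=config.tmin, tmax=config.tmax, fs=scfg.fs,
                   condition=conds, labels=list(config.electrodes))
    components = erp.component_table(eps, list(config.electrodes))
    rows = []
    for el in config.electrodes:
        for start, end in erp.pointwise_anova(eps, el, alpha=config.alpha,
                                              min_run_ms=config.min_run_ms):
            rows.append((el, start, end))
    anova = pd.DataFrame(rows, columns=["electrode", "start_ms", "end_ms"])
    return {"components": components, "anova": anova}


def _network_stage(config: PipelineConfig, adjacency, labels):
    return network.summarize(adjacency, labels=labels)


def _behavior_stage(config: PipelineConfig, scfg, whole, nodal):
    metric = _behavior_metric_series(config, whole, nodal)
    behavior = synth.generate_behavior(scfg, metric.to_numpy(),
                                       seed=scfg.seed)
    keys = metric.index.to_frame(index=False)
    behavior = behavior.drop(columns=["block", "condition"])
    behavior.insert(0, "subject", keys["subject"].to_numpy())
    behavior.insert(1, "block", keys["block"].to_numpy())
    n_cond = len(scfg.condition_labels)
    behavior.insert(2, "condition", [
        scfg.condition_labels[(b - 1) % n_cond] for b in behavior["block"]])
    return behavior


def _behavior_metric_series(config: PipelineConfig, whole, nodal) -> pd.Series:
    """Per-(subject, block) metric that accuracy is planted against."""
    band = config.behavior_band
    measure = config.behavior_measure
    if measure.endswith("_midline"):
        col = measure[:-len("_midline")]
        sub = nodal[(nodal["band"] == band)
                    & nodal["electrode"].map(is_midline)]
        series = sub.groupby(["subject", "block"])[col].mean()
    else:
        sub = whole[whole["band"] == band]
        series = sub.set_index(["subject", "block"])[measure]
    return series.sort_index()


def _stats_stage(config: PipelineConfig, whole, nodal, behavior, valence,
                 positions):
    rows = []

    def add(result: stats.StatResult, band="", metric="", extra=""):
        rows.append((result.test, band, metric, result.statistic, result.p,
                     result.r if result.r is not None else np.nan,
                     sum(result.group_sizes), extra))

    # valence pre/post per stimulated condition (paired t needs n >= 3)
    for cond, sub in valence.groupby("condition"):
        if len(sub) >= 3:
            add(stats.paired_ttest(sub["pre"], sub["post"]),
                metric="valence", extra=str(cond))
    # behavior across conditions
    for col in ("correct", "rt_ms"):
        groups = [g[col].to_numpy()
                  for _, g in behavior.groupby("condition")]
        add(stats.oneway_anova(groups), metric=col)
    # global measures vs accuracy
    merged = whole.merge(behavior[["subject", "block", "correct"]],
                         on=["subject", "block"])
    for band, sub in merged.groupby("band"):
        for metric in ("cpl", "ge"):
            vals = sub[metric].to_numpy()
            ok = np.isfinite(vals)
            if ok.sum() >= 3 and np.std(vals[ok]) > 0:
                add(stats.pearson(vals[ok], sub["correct"].to_numpy()[ok]),
                    band=band, metric=metric)
    # local measures: top/bottom split + Welch t
    k = min(config.split_k, len(behavior) // 2)
    g1, g2 = stats.split_by_accuracy(behavior, k)
    keys1 = set(zip(g1["subject"], g1["block"]))
    keys2 = set(zip(g2["subject"], g2["block"]))
    wkey = list(zip(whole["subject"], whole["block"]))
    for band, sub in whole.assign(_key=wkey).groupby("band"):
        for metric in ("cc_mean", "le_mean"):
            v1 = sub[sub["_key"].isin(keys1)][metric].to_numpy()
            v2 = sub[sub["_key"].isin(keys2)][metric].to_numpy()
            if len(v1) >= 2 and len(v2) >= 2:
                add(stats.independent_ttest(v1, v2), band=band, metric=metric,
                    extra="group1-group2")
    # local measures vs accuracy (whole-brain and midline means)
    mid = nodal[nodal["electrode"].map(is_midline)]
    for band, sub in mid.groupby("band"):
        series = sub.groupby(["subject", "block"])[["cc", "le"]].mean()
        joined = series.join(
            behavior.set_index(["subject", "block"])["correct"])
        for metric in ("cc", "le"):
            if joined[metric].std() > 0:
                add(stats.pearson(joined[metric], joined["correct"]),
                    band=band, metric=f"{metric}_midline")
    return pd.DataFrame(rows, columns=["test", "band", "metric", "statistic",
                                       "p", "r", "n", "detail"])
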