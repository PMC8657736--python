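"""End-to-end orchestration: simulate -> features -> scalograms -> statistics.

A run is described by a flat sectioned key-value config (``stage.key = value``).
Unknown keys are hard errors so a typo cannot silently fall back to a default.
All randomness derives from ``run.seed``; rerunning an identical config
reproduces every numeric output exactly, and each output file records the
SHA-256 hash of the resolved configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import platform
import time
from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError
from .features import features_table, group_summary
from .preprocess import FilterSpec, subject_trace
from .simulate import CONDITION_FS, CohortConfig, generate_cohort, preset
from .stats import (ClusterResult, cluster_extent, cluster_permutation_test,
                    compare_wave_features, mass_fraction)
from .timefreq import WaveletSpec, group_mean_scalogram, stack_maps, subject_scalogram
from .trace_io import CohortManifest, read_manifest

logger = logging.getLogger(__name__)

#: every default is the protocol value where one exists
DEFAULTS: dict[str, object] = {
    "run.seed": 0,
    "run.out_dir": "ergop_run",
    "run.conditions": "DA3",
    "run.manifest": "",            # empty: simulate a cohort instead
    "simulate.n_control": 10,
    "simulate.n_achm": 10,
    "simulate.cv": 0.2,
    "filter.low_hz": 0.3,
    "filter.high_hz": 300.0,
    "filter.order": 4,
    "features.b_amp_ref": "trough",
    "wavelet.f_min": 10.0,
    "wavelet.f_max": 300.0,
    "wavelet.f_step": 2.0,
    "wavelet.cycles_min": 3.0,
    "wavelet.cycles_max": 7.0,
    "tfr.baseline_min_ms": -20.0,
    "tfr.baseline_max_ms": 0.0,
    "tfr.window_min_ms": -20.0,
    "tfr.window_max_ms": 100.0,
    "stats.n_perm": 1000,
    "stats.alpha": 0.05,
    "stats.tail": "pos",
}


@dataclass
class RunConfig:
    values: dict[str, object]

    def __getitem__(self, key: str):
        return self.values[key]

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.values, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def parse_config(path: str | None = None, overrides: dict | None = None) -> RunConfig:
    """Resolve defaults, an optional config file, and explicit overrides."""
    values = dict(DEFAULTS)
    items: list[tuple[str, str]] = []
    if path:
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
                key, _, val = line.partition("=")
                items.append((key.strip(), val.strip()))
    for key, val in list((overrides or {}).items()):
        items.append((key, val))
    for key, val in items:
        if key not in DEFAULTS:
            raise ConfigError(f"unknown configuration key {key!r}")
        default = DEFAULTS[key]
        try:
            if isinstance(default, bool):
                values[key] = str(val).lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                values[key] = int(val)
            elif isinstance(default, float):
                values[key] = float(val)
            else:
                values[key] = str(val)
        except ValueError:
            raise ConfigError(f"cannot parse value {val!r} for key {key!r}")
    return RunConfig(values)


def _write_tsv(df: pd.DataFrame, path: str, config_hash: str) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(f"# config_sha256={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n", float_format="%.6g")


def run_all(config: RunConfig) -> dict:
    """Execute every stage for every configured condition; returns artifact paths."""
    out_dir = str(config["run.out_dir"])
    os.makedirs(out_dir, exist_ok=True)
    chash = config.config_hash
    seed = int(config["run.seed"])
    conditions = [c.strip() for c in str(config["run.conditions"]).split(",") if c.strip()]
    fspec = FilterSpec(float(config["filter.low_hz"]), float(config["filter.high_hz"]),
                       int(config["filter.order"]))
    report: dict = {"config": config.values, "config_sha256": chash,
                    "versions": {"ergop": __version__, "numpy": np.__version__,
                                 "python": platform.python_version()},
                    "stages": {}}
    artifacts: dict = {"report": os.path.join(out_dir, "run_report.json")}
    h5_path = os.path.join(out_dir, "scalograms.h5")
    artifacts["scalograms"] = h5_path
    all_features = []
    with h5py.File(h5_path, "w") as h5:
        h5.attrs["config_sha256"] = chash
        for cond in conditions:
            t0 = time.perf_counter()
            stage = f"simulate[{cond}]"
            try:
                if config["run.manifest"]:
                    manifest = read_manifest(str(config["run.manifest"]))
                else:
                    cohort_dir = os.path.join(out_dir, f"cohort_{cond}")
                    cc = CohortConfig(int(config["simulate.n_control"]),
                                      int(config["simulate.n_achm"]), cond,
                                      CONDITION_FS[cond], preset("control", cond),
                                      preset("achm", cond),
                                      between_subject_cv=float(config["simulate.cv"]),
                                      seed=seed)
                    manifest = generate_cohort(cc, cohort_dir)
                report["stages"][stage] = {"seconds": time.perf_counter() - t0}

                stage = f"features[{cond}]"
                t0 = time.perf_counter()
                feats = features_table(manifest, cond, fspec,
                                       b_amp_ref=str(config["features.b_amp_ref"]))
                all_features.append(feats)
                report["stages"][stage] = {"seconds": time.perf_counter() - t0}

                stage = f"tfr[{cond}]"
                t0 = time.perf_counter()
                wspec = WaveletSpec.default(
                    CONDITION_FS[cond], float(config["wavelet.f_min"]),
                    float(config["wavelet.f_max"]), float(config["wavelet.f_step"]),
                    n_range=(float(config["wavelet.cycles_min"]),
                             float(config["wavelet.cycles_max"])))
                baseline = (float(config["tfr.baseline_min_ms"]),
                            float(config["tfr.baseline_max_ms"]))
                window = (float(config["tfr.window_min_ms"]),
                          float(config["tfr.window_max_ms"]))
                scals = {"control": [], "achm": []}
                for subject in manifest.subjects():
                    tr = subject_trace(manifest, subject, cond, fspec)
                    scal = subject_scalogram(tr, wspec, baseline, window)
                    scals[scal.group].append(scal)
                    _save_scalogram(h5, f"{cond}/subjects/{subject}", scal)
                for grp, group_scals in scals.items():
                    _save_scalogram(h5, f"{cond}/group_mean/{grp}",
                                    group_mean_scalogram(group_scals))
                report["stages"][stage] = {"seconds": time.perf_counter() - t0}

                stage = f"compare[{cond}]"
                t0 = time.perf_counter()
                ctrl_feats = feats[feats["group"] == "control"]
                achm_feats = feats[feats["group"] == "achm"]
                tests = compare_wave_features(ctrl_feats, achm_feats)
                maps_c, mask_c = stack_maps(scals["control"])
                maps_a, mask_a = stack_maps(scals["achm"])
                result = cluster_permutation_test(
                    maps_c, maps_a, n_permutations=int(config["stats.n_perm"]),
                    alpha=float(config["stats.alpha"]), tail=str(config["stats.tail"]),
                    seed=seed, valid_mask=mask_c & mask_a)
                ref = scals["control"][0]
                _write_cluster_outputs(result, ref.time_ms, ref.freqs_hz, tests,
                                       out_dir, cond, chash, h5)
                report["stages"][stage] = {"seconds": time.perf_counter() - t0}
            except Exception as exc:
                raise RuntimeError(f"stage {stage} failed: {exc}") from exc
    features_df = pd.concat(all_features, ignore_index=True)
    artifacts["features"] = os.path.join(out_dir, "features.tsv")
    _write_tsv(features_df, artifacts["features"], chash)
    artifacts["group_summary"] = os.path.join(out_dir, "group_summary.tsv")
    _write_tsv(group_summary(features_df), artifacts["group_summary"], chash)
    report["run_seed"] = seed
    with open(artifacts["report"], "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
    return artifacts


def _save_scalogram(h5: h5py.File, group: str, scal) -> None:
    g = h5.create_group(group)
    g.create_dataset("power_db", data=scal.power_db)
    g.create_dataset("time_ms", data=scal.time_ms)
    g.create_dataset("freqs_hz", data=scal.freqs_hz)
    g.create_dataset("valid_mask", data=scal.valid_mask)
    g.attrs["baseline_window_ms"] = scal.baseline_window_ms
    for key in ("subject_id", "group", "condition"):
        val = getattr(scal, key)
        if val is not None:
            g.attrs[key] = val


def _write_cluster_outputs(result: ClusterResult, time_ms, freqs_hz, tests,
                           out_dir: str, condition: str, chash: str, h5: h5py.File) -> None:
    test_rows = [{"condition": condition, "feature": t.feature,
                  "shapiro_p_control": t.shapiro_p["control"],
                  "shapiro_p_achm": t.shapiro_p["achm"], "test": t.test_name,
                  "statistic": t.statistic, "p_value": t.p_value,
                  "control_mean": t.group_stats["control"][0],
                  "control_sd": t.group_stats["control"][1],
                  "achm_mean": t.group_stats["achm"][0],
                  "achm_sd": t.group_stats["achm"][1]} for t in tests]
    _write_tsv(pd.DataFrame(test_rows),
               os.path.join(out_dir, f"feature_tests_{condition}.tsv"), chash)
    cluster_rows = []
    for rank, c in enumerate(result.clusters, start=1):
        row = {"condition": condition, "rank": rank, "mass": c.mass, "p_value": c.p_value}
        row.update(cluster_extent(c, time_ms, freqs_hz))
        cluster_rows.append(row)
    _write_tsv(pd.DataFrame(cluster_rows),
               os.path.join(out_dir, f"clusters_{condition}.tsv"), chash)
    g = h5.create_group(f"{condition}/cluster_test")
    g.create_dataset("t_map", data=result.t_map)
    g.create_dataset("threshold_mask", data=result.threshold_mask)
    sig = np.zeros_like(result.threshold_mask)
    for c in result.clusters:
        if c.p_value is not None and c.p_value < result.alpha:
            sig[c.indices[:, 0], c.indices[:, 1]] = True
    g.create_dataset("significant_mask", data=sig)
    g.create_dataset("null_max_mass", data=result.null_max_mass)
    g.attrs.update({"n_permutations": result.n_permutations, "alpha": result.alpha,
                    "tail": result.tail, "seed": result.seed, "config_sha256": chash})
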