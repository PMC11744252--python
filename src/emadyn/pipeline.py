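"""End-to-end orchestration: simulate/read → QC → metrics → regression;
impute → diurnal fits → prediction surfaces.

``run_all`` drives every stage from one YAML/dict config and emits a run
manifest (config hash, seed, input checksums, stage timings, output paths,
package version).  All randomness flows from the single root seed, so the
result files (data, profiles, tables, surfaces) are byte-identical across
re-runs with the same config + seed; the manifest's timing fields are the
only non-deterministic output.  Progress is logged to stderr, results never
are.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import run_table
from .diurnal import fit_diurnal, predict_surface
from .imputation import ImputationConfig, knn_impute, missingness_summary
from .metrics import apply_outlier_rule, compute_profiles
from .qc import apply_qc
from .synthetic import SimulationConfig, read_long_csv, simulate_dataset, write_long_csv

logger = logging.getLogger("emadyn")
if not logger.handlers:  # stderr stage-progress logging, configured once
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config, "r", encoding="utf-8") as fh:
            return yaml.safe_load(fh)
    return dict(config)


def run_all(config, output_dir=None, seed: int | None = None) -> dict:
    """Execute the full analysis; returns the run manifest (also written).

    ``config`` is a dict or YAML path with optional sections ``simulation``
    (or ``input``: a long CSV path), ``checks`` (CSV path), ``qc``,
    ``metrics``, ``imputation`` and ``diurnal``; ``output_dir`` and ``seed``
    override the config's values.
    """
    cfg = load_config(config)
    out_dir = Path(output_dir or cfg.get("output_dir", "emadyn_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    root_seed = int(seed if seed is not None else cfg.get("seed", 0))

    manifest: dict = {
        "package_version": __version__,
        "seed": root_seed,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "input_checksums": {},
        "stage_timings": {},
        "outputs": {},
    }

    def stage(name):
        class _Timer:
            def __enter__(self):
                logger.info("stage %s: start", name)
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                manifest["stage_timings"][name] = time.perf_counter() - self.t0
                if exc is not None:
                    logger.error("stage %s failed: %s", name, exc)
                else:
                    logger.info("stage %s: done", name)
                return False

        return _Timer()

    # -- data -----------------------------------------------------------------
    with stage("data"):
        if "input" in cfg:
            in_path = Path(cfg["input"])
            records = read_long_csv(in_path)
            manifest["input_checksums"]["input"] = _sha256(in_path)
        else:
            sim_cfg = SimulationConfig.from_dict(
                {**cfg.get("simulation", {}), "seed": root_seed}
            )
            records, _truth = simulate_dataset(sim_cfg)
        data_path = out_dir / "data.csv"
        write_long_csv(records, data_path)
        manifest["outputs"]["data"] = str(data_path)

    # -- qc -------------------------------------------------------------------
    with stage("qc"):
        checks = None
        if cfg.get("checks"):
            checks_path = Path(cfg["checks"])
            checks = pd.read_csv(checks_path)
            manifest["input_checksums"]["checks"] = _sha256(checks_path)
        qc_opts = cfg.get("qc", {})
        clean, report = apply_qc(
            records,
            checks,
            min_required=qc_opts.get("min_required", 3),
            total=qc_opts.get("total", 6),
            max_failures=qc_opts.get("max_failures", 1),
        )
        clean_path = out_dir / "clean.csv"
        write_long_csv(clean, clean_path)
        with open(out_dir / "qc.json", "w", encoding="utf-8") as fh:
            json.dump(report.to_dict(), fh, indent=2, default=str)
        manifest["outputs"]["clean"] = str(clean_path)
        manifest["outputs"]["qc_report"] = str(out_dir / "qc.json")

    # -- metrics + regression -------------------------------------------------
    with stage("metrics"):
        m_opts = cfg.get("metrics", {})
        profiles = compute_profiles(
            clean, pair_policy=m_opts.get("pair_policy", "skip_gaps")
        )
        profiles, rule = apply_outlier_rule(
            profiles, threshold=m_opts.get("outlier_sd", 4.0)
        )
        profiles_path = out_dir / "profiles.csv"
        profiles.to_csv(profiles_path, index=False)
        with open(out_dir / "outliers.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "threshold_sd": rule.threshold_sd,
                    "removed": [list(map(str, r[:3])) + list(r[3:]) for r in rule.removed],
                },
                fh,
                indent=2,
            )
        manifest["outputs"]["profiles"] = str(profiles_path)

    with stage("regression"):
        isi_map = clean.drop_duplicates("participant_id").set_index(
            "participant_id"
        )["isi"]
        table = run_table(profiles, isi_map)
        table_path = out_dir / "table1.csv"
        table.to_csv(table_path, index=False)
        manifest["outputs"]["regression_table"] = str(table_path)

    # -- imputation -----------------------------------------------------------
    with stage("imputation"):
        i_opts = cfg.get("imputation", {})
        imp_cfg = ImputationConfig(
            k=i_opts.get("k", 4),
            time_weight=i_opts.get("time_weight", 4.0),
            round_to_scale=i_opts.get("round_to_scale", True),
        )
        n_missing, n_total, rate = missingness_summary(clean)
        logger.info("missingness: %d of %d (%.1f%%)", n_missing, n_total, 100 * rate)
        imputed, imp_log = knn_impute(clean, imp_cfg)
        imputed_path = out_dir / "imputed.csv"
        write_long_csv(imputed, imputed_path)
        with open(out_dir / "impute_log.json", "w", encoding="utf-8") as fh:
            json.dump(
                {"n_missing": n_missing, "n_total": n_total, "rate": rate,
                 "cells": imp_log},
                fh, default=str,
            )
        manifest["outputs"]["imputed"] = str(imputed_path)

    # -- diurnal GAMs ---------------------------------------------------------
    with stage("diurnal"):
        d_opts = cfg.get("diurnal", {})
        items = d_opts.get("items") or list(pd.unique(imputed["item"]))
        for item in items:
            best, aic_table = fit_diurnal(
                imputed,
                item,
                family=d_opts.get("family", "gaussian"),
                interaction=d_opts.get("interaction", "both"),
                basis_dim=d_opts.get("basis_dim", 10),
            )
            grid = predict_surface(best, n_grid=d_opts.get("grid", 12))
            surface_path = out_dir / f"surface_{item}.csv"
            grid.to_frame().to_csv(surface_path, index=False)
            fit_path = out_dir / f"fit_{item}.json"
            with open(fit_path, "w", encoding="utf-8") as fh:
                json.dump(
                    {
                        "best": best.summary(),
                        "candidates": aic_table.to_dict(orient="records"),
                    },
                    fh,
                    indent=2,
                )
            manifest["outputs"][f"surface_{item}"] = str(surface_path)
            manifest["outputs"][f"fit_{item}"] = str(fit_path)

    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    manifest["outputs"]["manifest"] = str(manifest_path)
    return manifest
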