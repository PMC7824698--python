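"""File formats, run configuration, and the end-to-end pipeline.

Interchange formats are plain text: trajectories travel as CSV
(``time_h, depth_m[, stage]``), ranked-pair datasets as CSV with a JSON
header line carrying the feature basis, and trained separators as JSON.
``run_pipeline`` chains generation -> training -> evaluation -> optimum
derivation and writes a manifest with a config hash so identical configs
reproduce identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .environment import EnvironmentModel, default_env, load_env
from .feature_space import RankedPair, multi_indices
from .fitness_optima import (LinearFitnessCoeffs, closed_form_optimum,
                             cosine_macro_params, study_coefficients)
from .ranking_classifier import evaluate, extract_coefficients, train_separator
from .sample_generator import RankedDataset, default_dataset
from .trajectories import StagePair, Trajectory, cosine_trajectory

logger = logging.getLogger("dvmrank")

__all__ = [
    "read_trajectory_csv",
    "write_trajectory_csv",
    "write_pairs_csv",
    "read_pairs_csv",
    "run_pipeline",
]


def read_trajectory_csv(path) -> Trajectory | StagePair:
    """Read a daily trajectory (or a juvenile/adult pair) from CSV.

    Expects columns ``time_h`` (equispaced, starting at 0) and ``depth_m``
    (signed, <= 0), optionally ``stage`` with values juvenile/adult.
    """
    df = pd.read_csv(path)
    missing = {"time_h", "depth_m"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    if (df["depth_m"] > 0).any():
        row = int(df.index[df["depth_m"] > 0][0]) + 2  # 1-based incl. header
        raise ValueError(f"{path}:{row}: positive depth; depths are signed (<= 0)")

    def build(sub: pd.DataFrame, stage: str) -> Trajectory:
        sub = sub.sort_values("time_h")
        times = sub["time_h"].to_numpy(dtype=float)
        dt = np.diff(times)
        if times.size >= 2 and not np.allclose(dt, dt[0]):
            raise ValueError(f"{path}: time_h samples are not equispaced")
        return Trajectory(sub["depth_m"].to_numpy(dtype=float), stage=stage)

    if "stage" in df.columns and df["stage"].notna().any():
        stages = set(df["stage"].dropna().unique())
        if stages == {"juvenile", "adult"}:
            return StagePair(
                juvenile=build(df[df["stage"] == "juvenile"], "juvenile"),
                adult=build(df[df["stage"] == "adult"], "adult"),
            )
        if len(stages) == 1:
            return build(df, stages.pop())
        raise ValueError(f"{path}: unsupported stage labels {sorted(stages)}")
    return build(df, "unstaged")


def write_trajectory_csv(traj: Trajectory | StagePair, path) -> None:
    """Write a trajectory in the same CSV dialect ``read_trajectory_csv`` reads."""
    frames = []
    parts = ([traj.juvenile, traj.adult] if isinstance(traj, StagePair)
             else [traj])
    for part in parts:
        frames.append(pd.DataFrame({
            "time_h": part.times * 24.0,
            "depth_m": part.samples,
            "stage": part.stage,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_pairs_csv(dataset: RankedDataset, path) -> None:
    """Pair dataset CSV: a ``#`` JSON header line, then one row per pair."""
    basis = multi_indices(dataset.n, dataset.k)
    header = {"n": dataset.n, "k": dataset.k, "seed": dataset.seed,
              "basis": [list(b) for b in basis]}
    n_feat = len(basis)
    cols = [f"diff_{i + 1}" for i in range(n_feat)]
    rows = []
    for idx, p in enumerate(dataset.pairs):
        row = dict(zip(cols, p.diff))
        row.update(label=p.label, direction=p.direction,
                   eps_v=p.eps_v, eps_w=p.eps_w,
                   split="train" if idx in set(dataset.train_idx) else "test")
        rows.append(row)
    with open(path, "w") as fh:
        fh.write("#" + json.dumps(header, sort_keys=True) + "\n")
        pd.DataFrame(rows).to_csv(fh, index=False)


def read_pairs_csv(path) -> RankedDataset:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError(f"{path}: missing JSON header line")
        header = json.loads(first[1:])
        df = pd.read_csv(fh)
    n_feat = len(header["basis"])
    cols = [f"diff_{i + 1}" for i in range(n_feat)]
    pairs = [
        RankedPair(row[cols].to_numpy(dtype=float), int(row["label"]),
                   direction=int(row["direction"]),
                   eps_v=float(row["eps_v"]), eps_w=float(row["eps_w"]))
        for _, row in df.iterrows()
    ]
    train_idx = np.flatnonzero((df["split"] == "train").to_numpy())
    test_idx = np.flatnonzero((df["split"] == "test").to_numpy())
    return RankedDataset([], pairs, train_idx, test_idx,
                         n=header["n"], k=header["k"], seed=header["seed"])


DEFAULT_CONFIG = {
    "env": {"family": "lin-quad"},
    # "study-optimum": cosine optimum of the reported coefficients at the
    # discrete L-point cadence; or give {"A": ..., "B": ...} explicitly
    "base": "study-optimum",
    "L": 8,
    "k": 1,
    "generator": {"n_dirs": 3, "max_mode": 3, "eps_max": 20.0,
                  "n_eps": 67, "n_pairs": 2031, "train_frac": 0.7},
    "classifier": {"lr": 0.1, "epochs": 2000, "l2": 1e-6},
    "seed": 0,
}


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            loaded = yaml.safe_load(fh)
    else:
        loaded = dict(config or {})
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in loaded.items():
        if isinstance(value, dict) and isinstance(merged.get(key), dict):
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


def run_pipeline(config=None, out_dir="dvmrank_run") -> dict:
    """Run generate -> train -> evaluate -> optimum and write artifacts.

    ``config`` is a dict or a YAML/JSON path layered over DEFAULT_CONFIG.
    Writes ``pairs.csv``, ``model.json``, ``optimum.json`` and
    ``manifest.json`` into ``out_dir`` and returns the manifest.
    """
    cfg = _load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    env_cfg = cfg["env"]
    if isinstance(env_cfg, str):
        env = load_env(env_cfg)
    elif set(env_cfg) == {"family"}:
        env = default_env(env_cfg["family"])
    else:
        fam = env_cfg["family"]
        params = {k: v for k, v in env_cfg.items() if k != "family"}
        from .environment import _FAMILIES
        env = EnvironmentModel(fam, _FAMILIES[fam](**params))
    logger.info("environment: %s", env.family)

    if cfg["base"] == "study-optimum":
        opt = closed_form_optimum(study_coefficients(env.family), env,
                                  cadence=int(cfg["L"]))
        base = cosine_trajectory(opt.A, opt.B, L=int(cfg["L"]), C=env.C)
    else:
        base = cosine_trajectory(cfg["base"]["A"], cfg["base"]["B"],
                                 L=int(cfg["L"]), C=env.C)
    gen = cfg["generator"]
    dataset = default_dataset(env, base, seed=seed, k=int(cfg["k"]),
                              n_dirs=int(gen["n_dirs"]),
                              max_mode=int(gen["max_mode"]),
                              eps_max=float(gen["eps_max"]),
                              n_eps=int(gen["n_eps"]),
                              n_pairs=int(gen["n_pairs"]),
                              train_frac=float(gen["train_frac"]))
    logger.info("generated %d strategies, %d pairs",
                len(dataset.strategies), len(dataset.pairs))
    write_pairs_csv(dataset, out / "pairs.csv")

    hyper = dict(cfg["classifier"], seed=seed)
    model = train_separator(dataset, hyper)
    report = evaluate(model, dataset.test_pairs, cv_pairs=dataset.pairs,
                      seed=seed, hyper=hyper)
    (out / "model.json").write_text(model.to_json())
    logger.info("test accuracy %.4f, logloss %.5f, cv %.4f",
                report.accuracy, report.logloss, report.cv_accuracy)

    coeffs_unit = extract_coefficients(model, "unit")
    optimum_obj: dict = {"recovered_lambda_unit": coeffs_unit.lambdas.tolist()}
    if env.family == "lin-quad" and cfg["k"] == 1:
        lam = coeffs_unit.lambdas
        if np.all(lam[:4] > 0):
            lin = LinearFitnessCoeffs(alpha=lam[0], gamma=lam[1],
                                      beta=lam[2], delta=lam[3])
            opt = closed_form_optimum(lin, env)
            M = cosine_macro_params(opt, env)
            optimum_obj.update(A=opt.A, B=opt.B, M=M.values.tolist())
    (out / "optimum.json").write_text(json.dumps(optimum_obj, sort_keys=True))

    manifest = {
        "version": __version__,
        "config": cfg,
        "config_hash": _config_hash(cfg),
        "seed": seed,
        "n_strategies": len(dataset.strategies),
        "n_pairs": len(dataset.pairs),
        "metrics": {
            "test_accuracy": report.accuracy,
            "test_logloss": report.logloss,
            "cv_accuracy": report.cv_accuracy,
        },
        "recovered_lambda_unit": coeffs_unit.lambdas.tolist(),
        "optimum": {k: v for k, v in optimum_obj.items()
                    if k in ("A", "B")},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True,
                                                  indent=1))
    return manifest
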