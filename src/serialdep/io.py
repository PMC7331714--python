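"""Trial-table I/O, schema validation and the end-to-end pipeline.

File convention: comma-delimited UTF-8 text with a header; angles in
degrees on [0, 360) (``target_deg``, ``report_deg``).  In memory angles
are radians (columns ``target``, ``report``).  Out-of-range input angles
are wrapped with a warning; structural problems (missing columns,
duplicate trial keys, unparsable values) are hard errors that name the
offending rows.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from .circular import wrap_angle
from .derive import GROUP_KEYS, derive_trials, exclude_guesses
from .kernel import DoGParams
from .resampling import ResamplingPlan
from .simulate import SimConfig, simulate_experiment

logger = logging.getLogger(__name__)

__all__ = [
    "DatasetSchema",
    "read_trials",
    "write_trials",
    "run_pipeline",
    "PipelineError",
]


@dataclass
class DatasetSchema:
    """Expected columns of a trial-table file."""

    required: List[str] = field(
        default_factory=lambda: [
            "experiment", "subject", "session", "trial_index",
            "target_deg", "report_deg",
        ]
    )
    optional: List[str] = field(default_factory=lambda: ["set_size", "delay_s"])
    angle_unit: str = "deg"


DEFAULT_SCHEMA = DatasetSchema()


def read_trials(path, schema: DatasetSchema = DEFAULT_SCHEMA) -> pd.DataFrame:
    """Read, validate and canonicalise a trial table.

    Returns a DataFrame sorted by (experiment, subject, session,
    trial_index) with radian ``target``/``report`` columns.
    """
    df = pd.read_csv(path)
    missing = [c for c in schema.required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")

    bad_lines = []
    for col in ("target_deg", "report_deg", "trial_index"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            # +2: header line plus 1-based numbering
            bad_lines += [(int(i) + 2, col) for i in df.index[bad]]
        df[col] = vals
    if bad_lines:
        listing = ", ".join(f"line {ln} ({col})" for ln, col in bad_lines[:10])
        raise ValueError(f"{path}: malformed numeric values at {listing}")

    for col in ("target_deg", "report_deg"):
        out_of_range = (df[col] < 0) | (df[col] >= 360)
        if out_of_range.any():
            warnings.warn(
                f"{path}: {int(out_of_range.sum())} {col} value(s) outside [0, 360)"
                " were wrapped",
                stacklevel=2,
            )
            df[col] = np.degrees(wrap_angle(np.radians(df[col].to_numpy())))

    for col in GROUP_KEYS:
        df[col] = df[col].astype(str)
    df["trial_index"] = df["trial_index"].astype(int)

    dup = df.duplicated(subset=GROUP_KEYS + ["trial_index"])
    if dup.any():
        keys = df.loc[dup, GROUP_KEYS + ["trial_index"]].head(5)
        raise ValueError(
            f"{path}: duplicate trial keys:\n{keys.to_string(index=False)}"
        )

    df["target"] = np.radians(df["target_deg"].to_numpy())
    df["report"] = np.radians(df["report_deg"].to_numpy())
    keep = GROUP_KEYS + ["trial_index", "target", "report"]
    keep += [c for c in schema.optional if c in df.columns]
    out = df[keep].sort_values(GROUP_KEYS + ["trial_index"], kind="stable")
    return out.reset_index(drop=True)


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table (radians in memory -> degrees on disk)."""
    out = trials[GROUP_KEYS + ["trial_index"]].copy()
    out["target_deg"] = np.degrees(wrap_angle(trials["target"].to_numpy()))
    out["report_deg"] = np.degrees(wrap_angle(trials["report"].to_numpy()))
    if "set_size" in trials.columns:
        out["set_size"] = trials["set_size"]
    out.to_csv(path, index=False)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _load_config(config) -> dict:
    if isinstance(config, dict):
        return dict(config)
    text = Path(config).read_text()
    if str(config).endswith((".yaml", ".yml")):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)


def _sim_from_config(cfg: dict, seed: Optional[int]):
    sim_cfg = dict(cfg)
    dog_cfg = sim_cfg.pop("dog", {})
    if seed is not None:
        sim_cfg["seed"] = seed
    return SimConfig(**sim_cfg), DoGParams(**dog_cfg)


def run_pipeline(config, out_dir=None, seed: Optional[int] = None) -> dict:
    """Run simulate/load -> derive -> analyze -> report and persist outputs.

    ``config`` is a dict or a path to a YAML/JSON file with keys:

    * ``input`` (path) or ``simulate`` (SimConfig fields, nested ``dog``) —
      exactly one is required;
    * ``analyze``: reference, folded, max_distance_deg, guess_threshold_deg,
      n_boot;
    * ``buildup``: enabled flag plus options;
    * ``out_dir``, ``seed`` (overridable by the function arguments).

    Writes ``trials.csv``, ``curve.csv``, ``subject_slopes.csv``,
    ``stats.json`` and ``run_log.json`` to the output directory and
    returns the result bundle.  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    from . import __version__
    from .serialbias import SerialBiasModel
    from .buildup import BuildUpModel

    cfg = _load_config(config)
    seed = cfg.get("seed") if seed is None else seed
    out_dir = Path(out_dir or cfg.get("out_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)

    # -- stage: acquire trials ------------------------------------------
    try:
        if "input" in cfg:
            trials = read_trials(cfg["input"])
        elif "simulate" in cfg:
            sim_config, dog = _sim_from_config(cfg["simulate"], seed)
            trials = simulate_experiment(sim_config, dog)
        else:
            raise ValueError("config must provide either 'input' or 'simulate'")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("acquire", exc) from exc
    write_trials(trials, out_dir / "trials.csv")

    an = cfg.get("analyze", {})
    plan = ResamplingPlan(
        n_boot=int(an.get("n_boot", 2000)),
        n_perm=int(an.get("n_perm", 2000)),
        alpha=float(an.get("alpha", 0.05)),
        seed=seed,
    )
    stats: dict = {"seed": seed}

    # -- stage: serial-bias analysis ------------------------------------
    try:
        model = SerialBiasModel(
            trials,
            reference=an.get("reference", "target"),
            folded=bool(an.get("folded", True)),
            guess_threshold=np.radians(float(an.get("guess_threshold_deg", 90.0))),
            max_distance=np.radians(float(an.get("max_distance_deg", 90.0))),
        )
        res = model.fit(plan)
    except Exception as exc:
        raise PipelineError("analyze", exc) from exc
    res.curve.to_frame().to_csv(out_dir / "curve.csv", index=False)
    stats["serial_bias"] = res.to_dict()

    # -- stage: build-up ------------------------------------------------
    bu_cfg = cfg.get("buildup", {})
    bu_res = None
    if bu_cfg.get("enabled", True):
        try:
            bu_model = BuildUpModel(
                trials,
                reference=bu_cfg.get("reference", an.get("reference", "target")),
            )
            bu_res = bu_model.fit(plan)
        except Exception as exc:
            raise PipelineError("buildup", exc) from exc
        bu_res.subject_slopes_.to_csv(out_dir / "subject_slopes.csv", index=False)
        stats["buildup"] = bu_res.to_dict()

    # -- stage: report ---------------------------------------------------
    try:
        (out_dir / "stats.json").write_text(json.dumps(stats, indent=2))
        cfg_hash = hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest()
        log = {
            "seed": seed,
            "config_sha256": cfg_hash,
            "serialdep_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "python_version": platform.python_version(),
        }
        (out_dir / "run_log.json").write_text(json.dumps(log, indent=2))
    except Exception as exc:
        raise PipelineError("report", exc) from exc
    logger.info("pipeline finished; outputs in %s", out_dir)

    return {
        "trials": trials,
        "serial_bias": res,
        "buildup": bu_res,
        "stats": stats,
        "out_dir": out_dir,
    }
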