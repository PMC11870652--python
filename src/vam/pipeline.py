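"""Reproducible run driver: config, serialization, end-to-end pipeline.

A run is fully determined by a YAML config plus a global seed.  The driver
generates stimuli and ground-truth behavior, fits the generative model (and
optionally the task-optimized twin), simulates holdout behavior, computes
the behavioral and representation-geometry metrics, and writes everything
into a run directory together with a manifest (config hash, seeds, package
version) so a re-run can be checked artifact-by-artifact.

Two built-in scales:

* ``full``: 128x128 stimuli and the full encoder widths
  (64, 64, 128, 128, 128, 256, 1024);
* ``desk``: 32x32 stimuli with a (16, 16, 32, 64) encoder, sized so the
  whole pipeline runs in minutes on one CPU.

Every random draw flows from the global seed through named substreams
(stimuli, behavior, fitting, simulation, analysis); there is no hidden
global RNG state.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import shutil
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import behavior as bhv
from . import repgeom as rg
from .encoder import EncoderConfig
from .lba import LBAParams
from .model import TaskOptimizedModel, VisualAccumulatorModel
from .stimuli import (
    DIRECTIONS,
    GroundTruthConfig,
    RenderConfig,
    records_to_frame,
    render_batch,
    sample_trial_specs,
    simulate_participant,
)
from .variational import FitConfig

__all__ = [
    "RunConfig",
    "run_pipeline",
    "write_trial_table",
    "read_trial_table",
    "write_metrics",
    "read_metrics",
    "write_checkpoint",
    "read_checkpoint",
]

TRIAL_COLUMNS = ["trial_id", "target_dir", "flanker_dir", "layout",
                 "center_x", "center_y", "congruent", "rt", "choice",
                 "correct"]

_SCALES = {
    "full": {
        "render": dict(out_hw=(128, 128), canvas_scale=1.0),
        "encoder": dict(input_hw=(128, 128),
                        conv_channels=(64, 64, 128, 128, 128, 256),
                        fc_width=1024),
    },
    "desk": {
        "render": dict(out_hw=(32, 32), canvas_scale=0.25),
        "encoder": dict(input_hw=(32, 32), conv_channels=(16, 16, 32),
                        fc_width=64),
    },
}


@dataclasses.dataclass
class RunConfig:
    """Everything needed to reproduce a run.

    ``stimuli``/``fit``/``analysis`` blocks mirror the underlying
    dataclasses; ``scale`` selects the full or desk geometry unless
    explicit overrides are given.
    """

    n_trials: int = 1500
    congruent_frac: float = 0.5
    scale: str = "desk"
    seed: int = 0
    out_dir: str = "vam_run"
    split: tuple = (0.65, 0.15, 0.20)
    #: overrides applied on top of the scale's RenderConfig
    #: (glyph_size, spacing, background, glyph_color, supersample)
    stimuli: dict = dataclasses.field(default_factory=dict)
    fit: FitConfig = dataclasses.field(
        default_factory=lambda: FitConfig(epochs=25, batch_size=64,
                                          augment=False))
    ground_truth: GroundTruthConfig = dataclasses.field(
        default_factory=GroundTruthConfig)
    fit_task_optimized: bool = False
    analysis_layers: tuple = (1, 2, 3)
    analysis_features: tuple = ("target", "flanker")

    def __post_init__(self):
        if self.scale not in _SCALES:
            raise ValueError(f"scale must be one of {sorted(_SCALES)}")

    @property
    def render_config(self) -> RenderConfig:
        kw = dict(_SCALES[self.scale]["render"])
        extra = dict(self.stimuli)
        for key in ("background", "glyph_color", "out_hw"):
            if key in extra and isinstance(extra[key], list):
                extra[key] = tuple(extra[key])
        kw.update(extra)
        return RenderConfig(**kw)

    @property
    def encoder_config(self) -> EncoderConfig:
        return EncoderConfig(**_SCALES[self.scale]["encoder"])

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fit"]["init_params"] = self.fit.init_params.to_dict()
        d["fit"]["augment_cfg"] = dataclasses.asdict(self.fit.augment_cfg)
        d["ground_truth"]["params"] = self.ground_truth.params.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        if "fit" in d and isinstance(d["fit"], dict):
            fd = dict(d["fit"])
            if "init_params" in fd and isinstance(fd["init_params"], dict):
                fd["init_params"] = LBAParams.from_dict(fd["init_params"])
            if "augment_cfg" in fd and isinstance(fd["augment_cfg"], dict):
                from .encoder import AugmentConfig
                fd["augment_cfg"] = AugmentConfig(**fd["augment_cfg"])
            d["fit"] = FitConfig(**fd)
        if "ground_truth" in d and isinstance(d["ground_truth"], dict):
            gd = dict(d["ground_truth"])
            if "params" in gd and isinstance(gd["params"], dict):
                gd["params"] = LBAParams.from_dict(gd["params"])
            d["ground_truth"] = GroundTruthConfig(**gd)
        for key in ("split", "analysis_layers", "analysis_features"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# --------------------------------------------------------------------------
# serialization helpers
# --------------------------------------------------------------------------

def write_trial_table(df: pd.DataFrame, path):
    """CSV trial table at full double precision."""
    df.to_csv(path, index=False, float_format="%.17g")


def read_trial_table(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as e:  # surface the offending line for malformed rows
        raise ValueError(f"malformed trial table {path}: {e}") from e
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table {path} missing columns {sorted(missing)}")
    return df


def write_metrics(metrics: dict, path):
    with open(path, "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True, default=float)


def read_metrics(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_checkpoint(params: dict, path, meta=None):
    """Flat array container (.npz) plus a JSON manifest with shape/hash info."""
    path = Path(path)
    np.savez(path, **params)
    file = path if path.suffix == ".npz" else path.with_suffix(".npz")
    manifest = {
        "arrays": {k: list(np.asarray(v).shape) for k, v in params.items()},
        "sha256": _sha256(file),
        "meta": meta or {},
    }
    with open(file.with_suffix(".json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return file


def read_checkpoint(path) -> dict:
    path = Path(path)
    file = path if path.suffix == ".npz" else path.with_suffix(".npz")
    with open(file.with_suffix(".json")) as fh:
        manifest = json.load(fh)
    if _sha256(file) != manifest["sha256"]:
        raise ValueError(f"checkpoint {file} is corrupt (hash mismatch)")
    with np.load(file) as data:
        return {k: data[k] for k in data.files}


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

def _analysis_metrics(res, cfg: RunConfig, rng) -> dict:
    """Representation metrics on incongruent holdout stimuli."""
    trials = res.model.trials.iloc[res.model.holdout_idx].reset_index(drop=True)
    incong = ~trials["congruent"].to_numpy(bool)
    images = res.model.images[res.model.holdout_idx][incong]
    tgt = trials.loc[incong, "target_dir"].map(
        {d: i for i, d in enumerate(DIRECTIONS)}).to_numpy()
    flk = trials.loc[incong, "flanker_dir"].map(
        {d: i for i, d in enumerate(DIRECTIONS)}).to_numpy()
    out = {}
    seed = int(rng.integers(2 ** 31 - 1))
    for layer in cfg.analysis_layers:
        acts = res.activations(layer, images=images)
        X = acts.values
        if X.shape[1] < 4 or min(np.bincount(tgt)) < 4:
            warnings.warn(f"layer {layer}: too few active units/trials")
            continue
        m = {}
        acc_t, basis_t = rg.decode_feature(X, tgt, seed=seed,
                                           feature="target", layer=layer)
        acc_f, basis_f = rg.decode_feature(X, flk, seed=seed,
                                           feature="flanker", layer=layer)
        m["target_decoding_accuracy"] = acc_t
        m["flanker_decoding_accuracy"] = acc_f
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m["subspace_alignment"] = rg.subspace_alignment(basis_t, basis_f)
        m["participation_ratio"] = rg.participation_ratio(X, tgt)
        m["n_active_units"] = int(X.shape[1])
        nmi = [rg.normalized_mutual_info(X[:, j], tgt)
               for j in range(min(X.shape[1], 64))]
        m["median_target_nmi"] = float(np.nanmedian(nmi))
        out[f"layer_{layer}"] = m
    return out


def run_pipeline(cfg: RunConfig) -> Path:
    """Generate -> fit -> simulate -> analyze, all into a run directory.

    Partial outputs of a previously crashed run are quarantined (renamed),
    never silently overwritten.  Returns the run directory path.
    """
    out = Path(cfg.out_dir)
    if out.exists():
        if (out / "manifest.json").exists():
            raise FileExistsError(f"run directory {out} already complete; "
                                  "choose a new out_dir")
        quarantine = out.with_name(out.name + f".quarantine-{int(time.time())}")
        shutil.move(str(out), str(quarantine))
        warnings.warn(f"quarantined partial run to {quarantine}")
    work = out.with_name(out.name + ".partial")
    if work.exists():
        shutil.rmtree(work)
    work.mkdir(parents=True)

    ss = np.random.SeedSequence(cfg.seed)
    r_stim, r_beh, r_sim, r_analysis = (np.random.default_rng(s)
                                        for s in ss.spawn(4))
    specs = sample_trial_specs(cfg.n_trials, cfg.congruent_frac, rng=r_stim,
                               cfg=cfg.render_config)
    records = simulate_participant(specs, cfg.ground_truth, rng=r_beh)
    trials = records_to_frame(records)
    write_trial_table(trials, work / "trials.csv")
    images = render_batch([r.spec for r in records], cfg.render_config)
    np.savez(work / "stimuli.npz", images=images,
             trial_id=trials["trial_id"].to_numpy())

    model = VisualAccumulatorModel(trials, images, cfg.encoder_config,
                                   split=cfg.split, split_seed=cfg.seed)
    res = model.fit(cfg.fit)
    res.training_log.to_csv(work / "training_log.csv")
    write_metrics(res.posterior.to_dict(), work / "posterior.json")
    write_checkpoint(res.encoder_params, work / "encoder",
                     meta={"seed": cfg.fit.seed,
                           "config": str(cfg.encoder_config)})

    sim = res.simulate(seed=int(r_sim.integers(2 ** 31 - 1)))
    write_trial_table(sim, work / "simulated_trials.csv")
    metrics = {
        "behavior_ground_truth": bhv.behavior_summary(
            model.trials.iloc[model.holdout_idx]),
        "behavior_simulated": bhv.behavior_summary(sim),
        "excluded_fraction": sim.attrs["excluded_fraction"],
        "map_params": res.map_params.to_dict(),
        "diagnostics": res.diagnostics,
        "representation": _analysis_metrics(res, cfg, r_analysis),
    }
    if cfg.fit_task_optimized:
        tom = TaskOptimizedModel(trials, images, cfg.encoder_config,
                                 split=cfg.split, split_seed=cfg.seed)
        tor = tom.fit(cfg.fit)
        tor.training_log.to_csv(work / "task_optimized_log.csv")
        write_checkpoint(tor.encoder_params, work / "task_optimized_encoder")
        metrics["task_optimized_holdout_accuracy"] = tor.accuracy()
    write_metrics(metrics, work / "metrics.json")

    cfg.to_yaml(work / "config.yaml")
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config_sha256": _sha256(work / "config.yaml"),
        "artifacts": {p.name: _sha256(p) for p in sorted(work.iterdir())
                      if p.is_file()},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(work / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    shutil.move(str(work), str(out))
    return out
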