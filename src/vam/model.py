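"""Model and results objects for the visual accumulator.

The public face of the package follows the model/results idiom: build a
:class:`VisualAccumulatorModel` from a trial table and the matching stimulus
images, call :meth:`~VisualAccumulatorModel.fit`, and work with the returned
:class:`VAMResults` (posterior summaries, simulation, behavioral metrics,
activation probes).  :class:`TaskOptimizedModel` trains the same encoder
discriminatively on true target labels and returns
:class:`TaskOptimizedResults` for the confidence analyses.

>>> specs = sample_trial_specs(800, seed=0)
>>> records = simulate_participant(specs, seed=1)
>>> model = VisualAccumulatorModel.from_records(records, images, enc_cfg)
>>> res = model.fit(FitConfig(epochs=10, batch_size=64, seed=0))
>>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import behavior as bhv
from . import encoder as enc
from . import variational as vi
from .lba import LBAParams
from .stimuli import (
    DIRECTIONS,
    RenderConfig,
    records_to_frame,
    render_batch,
    split_dataset,
)

__all__ = [
    "VisualAccumulatorModel",
    "VAMResults",
    "TaskOptimizedModel",
    "TaskOptimizedResults",
]


def _target_labels(trials: pd.DataFrame) -> np.ndarray:
    return trials["target_dir"].map(
        {d: i for i, d in enumerate(DIRECTIONS)}).to_numpy()


class VisualAccumulatorModel:
    """Image-computable accumulator model bound to one participant's data.

    Parameters
    ----------
    trials : DataFrame
        Canonical trial table (``rt`` seconds, ``choice`` 1..4, stimulus
        metadata columns).
    images : (N, H, W, 3) array
        Stimulus raster aligned row-for-row with ``trials``.
    encoder_config : EncoderConfig
        Architecture of the drift-rate encoder.
    split : (train, val, holdout) fractions, default (0.65, 0.15, 0.20)
    split_seed : int
        Seed of the shuffled partition.
    """

    def __init__(self, trials, images, encoder_config,
                 split=(0.65, 0.15, 0.20), split_seed=0):
        trials = trials.reset_index(drop=True)
        images = np.asarray(images, dtype=float)
        if len(trials) != images.shape[0]:
            raise ValueError("trials and images must be aligned")
        self.trials = trials
        self.images = images
        self.encoder_config = encoder_config
        self.train_idx, self.val_idx, self.holdout_idx = split_dataset(
            len(trials), split, seed=split_seed)

    @classmethod
    def from_records(cls, records, images, encoder_config, **kw):
        """Build from a list of TrialRecord plus aligned images."""
        return cls(records_to_frame(records), images, encoder_config, **kw)

    @classmethod
    def from_specs(cls, records, encoder_config,
                   render_cfg: RenderConfig = RenderConfig(), **kw):
        """Build from records alone, rendering the stimuli on the fly."""
        frame = records_to_frame(records)
        images = render_batch([r.spec for r in records], render_cfg)
        return cls(frame, images, encoder_config, **kw)

    @property
    def endog(self):
        """(rt, choice) outcomes, statsmodels-style accessor."""
        return self.trials[["rt", "choice"]].to_numpy()

    def fit(self, fit_config: vi.FitConfig = vi.FitConfig(),
            encoder_kind="cnn", callback=None) -> "VAMResults":
        """Fit by stochastic ELBO ascent; returns a results object."""
        post, zeta, log, diag = vi.fit_vam(
            self.images, self.trials["rt"].to_numpy(float),
            self.trials["choice"].to_numpy(int),
            self.train_idx, self.val_idx,
            encoder_cfg=self.encoder_config, cfg=fit_config,
            encoder_kind=encoder_kind, callback=callback)
        return VAMResults(self, fit_config, post, zeta, log, diag,
                          encoder_kind)


@dataclass
class VAMResults:
    """Fitted visual accumulator: posterior, encoder weights, diagnostics."""

    model: VisualAccumulatorModel
    fit_config: vi.FitConfig
    posterior: vi.PosteriorGaussian
    encoder_params: dict
    training_log: vi.TrainingLog
    diagnostics: dict
    encoder_kind: str = "cnn"

    @property
    def map_params(self) -> LBAParams:
        """Inverse-transformed posterior mean (the point estimate)."""
        return vi.map_estimate(self.posterior)

    def posterior_sd(self, n_draws=100_000, seed=0) -> dict:
        """Posterior SDs of (b, A, t0) by pushing draws through T^-1."""
        rng = np.random.default_rng(seed)
        eps = rng.standard_normal((n_draws, 3))
        ts = vi.reparameterize(self.posterior.mu, self.posterior.L_chol, eps)
        A = np.exp(ts[:, 1])
        draws = np.column_stack([np.exp(ts[:, 0]) + A, A, np.exp(ts[:, 2])])
        return dict(zip(("b", "A", "t0"), draws.std(axis=0)))

    def drift_means(self, images=None) -> np.ndarray:
        """Eval-mode encoder outputs for probe images (default: holdout)."""
        if images is None:
            images = self.model.images[self.model.holdout_idx]
        if self.encoder_kind == "bias":
            return vi._BiasEncoder.forward(np.asarray(images).shape[0],
                                           self.encoder_params)
        return enc.forward(images, self.encoder_params,
                           self.model.encoder_config, mode="eval")

    def simulate(self, images=None, trials=None, seed=0) -> pd.DataFrame:
        """Simulate behavior on probe stimuli at the fitted parameters.

        Returns a trial table with model RTs/choices; undefined trials
        (all sampled drifts non-positive) are dropped and their fraction
        stored in ``attrs["excluded_fraction"]``.
        """
        if images is None:
            images = self.model.images[self.model.holdout_idx]
            trials = self.model.trials.iloc[self.model.holdout_idx]
        elif trials is None:
            raise ValueError("pass trials metadata along with custom images")
        rts, choices, valid, excl, v = vi.sample_model_behavior(
            self.posterior, self.encoder_params, self.model.encoder_config,
            images, seed=seed)
        out = trials.reset_index(drop=True).copy()
        out["rt"] = rts
        out["choice"] = choices
        out["correct"] = [
            c >= 1 and DIRECTIONS[c - 1] == t
            for c, t in zip(choices, out["target_dir"])]
        out = out[valid].reset_index(drop=True)
        out.attrs["excluded_fraction"] = excl
        return out

    def behavior_summary(self, seed=0) -> dict:
        """Congruency effects etc. of holdout-simulated behavior."""
        return bhv.behavior_summary(self.simulate(seed=seed))

    def activations(self, layer, images=None) -> enc.ActivationMatrix:
        """Probe unit activity at one encoder layer (holdout by default)."""
        if self.encoder_kind != "cnn":
            raise ValueError("activations require the CNN encoder")
        if images is None:
            images = self.model.images[self.model.holdout_idx]
        return enc.extract_activations(images, self.encoder_params,
                                       self.model.encoder_config, layer)

    def summary(self) -> str:
        """Human-readable fit summary table."""
        p = self.map_params
        sd = self.posterior_sd()
        log = self.training_log.frame
        lines = [
            "      Visual Accumulator Model Results",
            "=" * 46,
            f"Trials (train/val/holdout): {len(self.model.train_idx)}/"
            f"{len(self.model.val_idx)}/{len(self.model.holdout_idx)}",
            f"Encoder: {self.encoder_kind}, epochs: {len(log)}",
            f"Final train ELBO: {log['train_elbo'].iloc[-1]: .4f}",
            f"Final val ELBO:   {log['val_elbo'].iloc[-1]: .4f}",
            "-" * 46,
            "LBA posterior (MAP = T^-1(mu), SD via pushforward)",
            f"  threshold b       {p.b: .4f}  (sd {sd['b']:.4f})",
            f"  start range A     {p.A: .4f}  (sd {sd['A']:.4f})",
            f"  non-decision t0   {p.t0: .4f}  (sd {sd['t0']:.4f})",
            f"  gap b - A         {p.b - p.A: .4f}",
            "-" * 46,
            f"Diagnostics: choice agreement "
            f"{self.diagnostics['sim_choice_agreement']:.3f}; "
            f"negative-drift fraction "
            f"{self.diagnostics['negative_drift_fraction']:.4f}",
        ]
        if self.diagnostics["chance_accuracy_flag"] or \
                self.diagnostics["negative_drift_flag"]:
            lines.append("WARNING: failed-run diagnostics tripped")
        return "\n".join(lines)


class TaskOptimizedModel:
    """Discriminative twin of the accumulator model (cross-entropy loss).

    Same encoder architecture, optimizer, initialization and augmentation;
    the 4 outputs are class logits for the true target direction.
    """

    def __init__(self, trials, images, encoder_config,
                 split=(0.65, 0.15, 0.20), split_seed=0):
        encoder_config = replace(encoder_config, head="logits")
        self.trials = trials.reset_index(drop=True)
        self.images = np.asarray(images, dtype=float)
        self.encoder_config = encoder_config
        self.labels = _target_labels(self.trials)
        self.train_idx, self.val_idx, self.holdout_idx = split_dataset(
            len(self.trials), split, seed=split_seed)

    def fit(self, fit_config: vi.FitConfig = vi.FitConfig(),
            callback=None) -> "TaskOptimizedResults":
        zeta, log = vi.fit_task_optimized(
            self.images, self.labels, self.train_idx, self.val_idx,
            encoder_cfg=self.encoder_config, cfg=fit_config,
            callback=callback)
        return TaskOptimizedResults(self, fit_config, zeta, log)


@dataclass
class TaskOptimizedResults:
    model: TaskOptimizedModel
    fit_config: vi.FitConfig
    encoder_params: dict
    training_log: vi.TrainingLog

    def logits(self, images=None) -> np.ndarray:
        if images is None:
            images = self.model.images[self.model.holdout_idx]
        return enc.forward(images, self.encoder_params,
                           self.model.encoder_config, mode="eval")

    def accuracy(self, images=None, labels=None) -> float:
        if labels is None:
            labels = self.model.labels[self.model.holdout_idx]
        return float(np.mean(np.argmax(self.logits(images), axis=1)
                             == np.asarray(labels)))

    def confidence_congruency(self, n_groups=10) -> bhv.ConfidenceComparison:
        """Holdout confidence split by congruency, paired over trial blocks."""
        idx = self.model.holdout_idx
        logits = self.logits()
        congruent = self.model.trials["congruent"].to_numpy(bool)[idx]
        groups = np.arange(len(idx)) % n_groups
        return bhv.confidence_congruency(logits, congruent, groups)

    def activations(self, layer, images=None) -> enc.ActivationMatrix:
        if images is None:
            images = self.model.images[self.model.holdout_idx]
        return enc.extract_activations(images, self.encoder_params,
                                       self.model.encoder_config, layer)

    def summary(self) -> str:
        log = self.training_log.frame
        return "\n".join([
            "      Task-Optimized Model Results",
            "=" * 42,
            f"Epochs: {len(log)}",
            f"Final train loss: {log['train_loss'].iloc[-1]:.4f}",
            f"Final train acc:  {log['train_accuracy'].iloc[-1]:.4f}",
            f"Holdout accuracy: {self.accuracy():.4f}",
        ])
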