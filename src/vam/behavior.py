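"""Behavioral summary statistics for flanker-task trial tables.

Operates on the canonical trial table (columns ``target_dir, flanker_dir,
layout, center_x, center_y, congruent, rt, choice, correct``) for either
human-style or model-simulated data.  Conventions follow standard conflict
task analyses:

* RT congruency effect = mean incongruent RT - mean congruent RT, correct
  trials only; accuracy congruency effect = congruent - incongruent accuracy.
* Delta plots: per-decile (0.1..0.9) RT congruency effect against the
  decile-average RT, correct trials only, linear-interpolation quantiles.
* Conditional accuracy functions: accuracy and mean RT within RT quintile
  bins per congruency class.
* Stimulus-feature modulation: one-way ANOVA on RTs (and a chi-squared test
  of accuracy proportions) across layout/position bins.  Horizontal position
  uses 50-px bins with wider outer bins, vertical 25-px bins, in the
  640x480 window space.

Outlier filtering drops RTs at or below 250 ms and then RTs deviating from
the median by more than 10 times the (unscaled) median absolute deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .stimuli import LAYOUTS, WINDOW_H, WINDOW_W

__all__ = [
    "filter_trials",
    "congruency_effects",
    "delta_plot",
    "conditional_accuracy",
    "feature_bins",
    "feature_rt_modulation",
    "feature_acc_modulation",
    "confidence_congruency",
    "behavior_summary",
]

#: horizontal bins: 60-px leftmost, 50-px interior, remainder (80 px) rightmost
X_BIN_EDGES = np.array([0.0, 60.0] + list(np.arange(110.0, 561.0, 50.0))
                       + [float(WINDOW_W)])
#: vertical bins: 25 px, last bin absorbs the 5-px remainder
Y_BIN_EDGES = np.array(list(np.arange(0.0, 476.0, 25.0)) + [float(WINDOW_H)])


@dataclass(frozen=True)
class FilterResult:
    keep: np.ndarray          # boolean mask over the input trials
    n_fast: int               # removed by the 250 ms floor
    n_outlier: int            # removed by the MAD criterion
    all_removed: bool         # warning flag


def filter_trials(rts, min_rt=0.250, mad_k=10.0) -> FilterResult:
    """RT exclusion mask: the 250 ms floor, then the 10-MAD outlier rule.

    The floor removes ``rt <= min_rt``; the median and MAD (raw median
    absolute deviation, unscaled) are computed on the surviving trials and
    trials with ``|rt - median| > mad_k * MAD`` are removed.  When the MAD is
    zero only exact ties with the median survive the strict inequality, so
    identical RTs are never excluded.  Idempotent for ``mad_k >= 1``.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size == 0:
        raise ValueError("empty RT list")
    keep = rts > min_rt
    n_fast = int((~keep).sum())
    n_outlier = 0
    if keep.any():
        med = np.median(rts[keep])
        mad = np.median(np.abs(rts[keep] - med))
        out = keep & (np.abs(rts - med) > mad_k * mad)
        n_outlier = int(out.sum())
        keep = keep & ~out
    all_removed = not keep.any()
    if all_removed:
        warnings.warn("all trials removed by RT filtering")
    return FilterResult(keep, n_fast, n_outlier, all_removed)


@dataclass(frozen=True)
class CongruencyEffects:
    rt_effect: float          # seconds, incongruent - congruent (correct only)
    acc_effect: float         # congruent - incongruent accuracy
    defined: bool


def congruency_effects(trials: pd.DataFrame) -> CongruencyEffects:
    """RT and accuracy congruency effects of a trial table."""
    con = trials[trials["congruent"].astype(bool)]
    inc = trials[~trials["congruent"].astype(bool)]
    if len(con) == 0 or len(inc) == 0:
        warnings.warn("missing congruency class; effects undefined")
        return CongruencyEffects(np.nan, np.nan, False)
    rt_c = con.loc[con["correct"].astype(bool), "rt"]
    rt_i = inc.loc[inc["correct"].astype(bool), "rt"]
    rt_eff = float(rt_i.mean() - rt_c.mean()) if len(rt_c) and len(rt_i) \
        else np.nan
    acc_eff = float(con["correct"].mean() - inc["correct"].mean())
    return CongruencyEffects(rt_eff, acc_eff, True)


def delta_plot(trials: pd.DataFrame, quantiles=None, method="quantile"):
    """Per-decile RT congruency effect vs. decile mean RT (correct trials).

    Column 0 is the average of the congruent and incongruent decile
    statistics, column 1 their difference.  Quantiles use linear
    interpolation.  ``method="quantile"`` differences the RT quantiles
    themselves (one row per quantile, 9 by default); ``method="bin_mean"``
    differences the mean RT within each between-decile bin (one row per
    bin, 10 by default).  Both conventions appear in the conflict-task
    literature and agree to first order.  Requires >= 10 correct trials
    per congruency class.
    """
    if quantiles is None:
        quantiles = np.arange(0.1, 0.91, 0.1)
    if method not in ("quantile", "bin_mean"):
        raise ValueError("method must be 'quantile' or 'bin_mean'")
    ok = trials[trials["correct"].astype(bool)]
    rt_c = ok.loc[ok["congruent"].astype(bool), "rt"].to_numpy()
    rt_i = ok.loc[~ok["congruent"].astype(bool), "rt"].to_numpy()
    if len(rt_c) < 10 or len(rt_i) < 10:
        warnings.warn("too few correct trials per class for a delta plot")
        return np.full((len(quantiles), 2), np.nan)
    if method == "quantile":
        qc = np.quantile(rt_c, quantiles)
        qi = np.quantile(rt_i, quantiles)
        return np.column_stack([(qc + qi) / 2.0, qi - qc])
    edges = np.r_[0.0, quantiles, 1.0]

    def bin_means(rts):
        cuts = np.quantile(rts, edges)
        bins = np.clip(np.searchsorted(cuts[1:-1], rts, side="right"),
                       0, len(edges) - 2)
        return np.array([rts[bins == k].mean() for k in range(len(edges) - 1)])

    mc, mi = bin_means(rt_c), bin_means(rt_i)
    return np.column_stack([(mc + mi) / 2.0, mi - mc])


def conditional_accuracy(trials: pd.DataFrame, quantiles=(0.2, 0.4, 0.6, 0.8)):
    """Conditional accuracy function per congruency class.

    Trials of each class are cut at the class's own RT quantiles into 5
    bins; each bin reports (mean RT, accuracy).  Returns a dict
    ``{"congruent": (5, 2) array, "incongruent": ...}``.
    """
    out = {}
    for name, mask in (("congruent", trials["congruent"].astype(bool)),
                       ("incongruent", ~trials["congruent"].astype(bool))):
        sub = trials[mask]
        if len(sub) < 5:
            warnings.warn(f"too few {name} trials for conditional accuracy")
            out[name] = np.full((len(quantiles) + 1, 2), np.nan)
            continue
        rts = sub["rt"].to_numpy()
        cuts = np.quantile(rts, quantiles)
        bins = np.searchsorted(cuts, rts, side="right")
        rows = []
        for k in range(len(quantiles) + 1):
            sel = bins == k
            rows.append([rts[sel].mean() if sel.any() else np.nan,
                         sub["correct"].to_numpy()[sel].mean()
                         if sel.any() else np.nan])
        out[name] = np.asarray(rows)
    return out


def feature_bins(trials: pd.DataFrame, feature: str) -> np.ndarray:
    """Assign each trial to a stimulus-feature bin (integer labels).

    ``layout`` uses its 7 categories; ``x_position`` / ``y_position`` use
    the window-space pixel bins defined at module level.
    """
    if feature == "layout":
        return trials["layout"].map({l: i for i, l in enumerate(LAYOUTS)}
                                    ).to_numpy()
    if feature == "x_position":
        vals, edges = trials["center_x"].to_numpy(float), X_BIN_EDGES
    elif feature == "y_position":
        vals, edges = trials["center_y"].to_numpy(float), Y_BIN_EDGES
    else:
        raise ValueError("feature must be layout, x_position or y_position")
    if np.any((vals < edges[0]) | (vals > edges[-1])):
        raise ValueError(f"{feature} values outside the stimulus window")
    return np.clip(np.searchsorted(edges, vals, side="right") - 1,
                   0, len(edges) - 2)


def _grouped(values, bins, min_count=1):
    groups = []
    ids = []
    for k in np.unique(bins):
        sel = values[bins == k]
        if len(sel) >= min_count:
            groups.append(sel)
            ids.append(int(k))
        else:
            warnings.warn(f"dropping empty/underpopulated feature bin {k}")
    return ids, groups


@dataclass(frozen=True)
class ModulationResult:
    p_value: float
    statistic: float
    bin_ids: tuple
    bin_values: tuple         # per-bin mean RT (or accuracy)
    defined: bool


def feature_rt_modulation(trials: pd.DataFrame, feature: str,
                          min_per_bin=2) -> ModulationResult:
    """One-way ANOVA of RT across stimulus-feature bins (threshold p < .05)."""
    bins = feature_bins(trials, feature)
    ids, groups = _grouped(trials["rt"].to_numpy(float), bins, min_per_bin)
    if len(groups) < 2:
        warnings.warn("fewer than two populated bins; modulation undefined")
        return ModulationResult(np.nan, np.nan, tuple(ids),
                                tuple(float(g.mean()) for g in groups), False)
    stat, p = stats.f_oneway(*groups)
    return ModulationResult(float(p), float(stat), tuple(ids),
                            tuple(float(g.mean()) for g in groups), True)


def feature_acc_modulation(trials: pd.DataFrame, feature: str,
                           min_per_bin=2) -> ModulationResult:
    """Chi-squared test of accuracy proportions across feature bins."""
    bins = feature_bins(trials, feature)
    ids, groups = _grouped(trials["correct"].to_numpy(bool), bins, min_per_bin)
    if len(groups) < 2:
        warnings.warn("fewer than two populated bins; modulation undefined")
        return ModulationResult(np.nan, np.nan, tuple(ids),
                                tuple(float(g.mean()) for g in groups), False)
    table = np.array([[g.sum(), len(g) - g.sum()] for g in groups], dtype=float)
    merged = []
    acc = None
    for row in table:  # merge bins forward until expected counts are positive
        if acc is None:
            acc = row.copy()
        else:
            acc += row
        if (acc > 0).all():
            merged.append(acc)
            acc = None
    if acc is not None:
        if merged:
            merged[-1] += acc
        else:
            merged.append(acc)
    table = np.asarray(merged)
    if len(table) < len(groups):
        warnings.warn("merged feature bins with zero correct/error counts")
    if len(table) < 2 or np.allclose(table.sum(axis=0).min(), 0):
        return ModulationResult(1.0, 0.0, tuple(ids),
                                tuple(float(g.mean()) for g in groups), True)
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return ModulationResult(float(p), float(stat), tuple(ids),
                            tuple(float(g.mean()) for g in groups), True)


@dataclass(frozen=True)
class ConfidenceComparison:
    mean_congruent: float
    mean_incongruent: float
    wilcoxon_w: float
    p_value: float
    cohens_d: float
    n_pairs: int


def confidence_congruency(logits, congruent, groups) -> ConfidenceComparison:
    """Compare classifier confidence on congruent vs. incongruent trials.

    Confidence is the maximum softmax probability of the 4 logits.  Trials
    are aggregated into paired units of analysis by ``groups`` (e.g. one
    pair of class means per session or per model); the paired congruent /
    incongruent means are compared with a Wilcoxon signed-rank test, and
    Cohen's d is the mean paired difference over its SD.
    """
    logits = np.asarray(logits, dtype=float)
    congruent = np.asarray(congruent, dtype=bool)
    groups = np.asarray(groups)
    z = logits - logits.max(axis=1, keepdims=True)
    pmax = np.exp(z).max(axis=1) / np.exp(z).sum(axis=1)
    pairs = []
    for g in np.unique(groups):
        sel = groups == g
        if congruent[sel].any() and (~congruent[sel]).any():
            pairs.append((pmax[sel & congruent].mean(),
                          pmax[sel & ~congruent].mean()))
    if len(pairs) < 2:
        raise ValueError("need at least 2 groups with both congruency classes")
    pairs = np.asarray(pairs)
    diff = pairs[:, 0] - pairs[:, 1]
    if np.allclose(diff, 0):
        w, p = 0.0, 1.0
    else:
        w, p = stats.wilcoxon(pairs[:, 0], pairs[:, 1])
    sd = diff.std(ddof=1)
    d = float(diff.mean() / sd) if sd > 0 else (np.inf if diff.mean() > 0
                                                else 0.0)
    return ConfidenceComparison(float(pairs[:, 0].mean()),
                                float(pairs[:, 1].mean()),
                                float(w), float(p), d, len(pairs))


def behavior_summary(trials: pd.DataFrame) -> dict:
    """One-stop summary used by the pipeline and results objects."""
    eff = congruency_effects(trials)
    return {
        "n_trials": int(len(trials)),
        "mean_rt": float(trials["rt"].mean()),
        "accuracy": float(trials["correct"].mean()),
        "rt_congruency_effect": eff.rt_effect,
        "acc_congruency_effect": eff.acc_effect,
    }
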