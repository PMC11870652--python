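"""Representation geometry of encoder unit activity.

Analyses operate on an N x K activation matrix (probe stimuli x active
units) and per-stimulus feature labels.  When target and flanker features
are both in play, only incongruent trials are informative (on congruent
trials the two features coincide and would cross-contaminate decoders); the
pipeline driver enforces that restriction.

Provided metrics:

* linear decoding of a stimulus feature with one-vs-rest squared-hinge
  linear SVMs (standardized features, C = 1), returning held-out accuracy
  and the stacked hyperplane-normal "decoding vectors";
* tolerance / cross-context generalization: train the target decoder inside
  one context value, test on all others, average over contexts;
* subspace alignment: mean cosine of the principal angles between the
  row spaces of two decoding-vector matrices (1 parallel, 0 orthogonal);
* participation ratio (sum lambda)^2 / sum lambda^2 of the class-centered
  activation covariance - the effective dimensionality in [1, K];
* normalized mutual information between a single unit's 10-bin discretized
  activity and a discrete stimulus feature, normalized by feature entropy;
* a single-unit selectivity taxonomy (none / selective+ / selective- /
  complex) based on ANOVA, Tukey HSD and a rank-sum magnitude comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "SubspaceBasis",
    "decode_feature",
    "generalization_accuracy",
    "subspace_alignment",
    "participation_ratio",
    "normalized_mutual_info",
    "classify_unit_selectivity",
]


@dataclass(frozen=True)
class SubspaceBasis:
    """Stacked one-vs-rest decoding vectors (n_classes x K) for one feature."""

    X: np.ndarray
    feature: str = ""
    layer: int = -1

    def __post_init__(self):
        if np.asarray(self.X).ndim != 2:
            raise ValueError("X must be 2-D (classes x units)")


def _fit_ovr_svm(X_train, y_train, C=1.0, seed=0):
    scaler = StandardScaler().fit(X_train)
    clf = LinearSVC(C=C, loss="squared_hinge", penalty="l2", dual=True,
                    random_state=seed, max_iter=5000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # occasional convergence chatter
        clf.fit(scaler.transform(X_train), y_train)
    return scaler, clf


def decode_feature(acts, labels, test_size=0.2, seed=0, C=1.0,
                   feature="", layer=-1):
    """Linear decoding of a stimulus feature from unit activity.

    Columns are standardized on the training split (the training mean and
    variance are reused on the test split); one binary squared-hinge linear
    SVM is trained per class value and the multiclass decision goes to the
    most confident sub-classifier.  Returns ``(test_accuracy,
    SubspaceBasis)`` where the basis rows are the hyperplane normals in the
    standardized feature space.
    """
    acts = np.asarray(acts, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least 2 classes to decode")
    X_tr, X_te, y_tr, y_te = train_test_split(
        acts, labels, test_size=test_size, random_state=seed,
        stratify=labels)
    if np.unique(y_tr).size < classes.size:
        raise ValueError("a class is absent from the training split")
    scaler, clf = _fit_ovr_svm(X_tr, y_tr, C=C, seed=seed)
    acc = float(np.mean(clf.predict(scaler.transform(X_te)) == y_te))
    coef = clf.coef_
    if classes.size == 2 and coef.shape[0] == 1:
        coef = np.vstack([-coef[0], coef[0]])  # one hyperplane, both signs
    return acc, SubspaceBasis(coef.copy(), feature=feature, layer=layer)


def generalization_accuracy(acts, target_labels, context_labels, C=1.0,
                            seed=0):
    """Cross-context generalization (tolerance) of target decoding.

    For each context value, a target-direction SVM is trained on the trials
    of that context alone and evaluated on all other contexts; the mean
    accuracy across usable contexts is returned.  Contexts missing a target
    class are skipped with a warning; fewer than two context values is an
    error.
    """
    acts = np.asarray(acts, dtype=float)
    target_labels = np.asarray(target_labels)
    context_labels = np.asarray(context_labels)
    contexts = np.unique(context_labels)
    if contexts.size < 2:
        raise ValueError("need at least 2 context values")
    n_classes = np.unique(target_labels).size
    accs = []
    for ctx in contexts:
        tr = context_labels == ctx
        if np.unique(target_labels[tr]).size < n_classes:
            warnings.warn(f"context {ctx!r} lacks a target class; skipped")
            continue
        scaler, clf = _fit_ovr_svm(acts[tr], target_labels[tr], C=C,
                                   seed=seed)
        pred = clf.predict(scaler.transform(acts[~tr]))
        accs.append(np.mean(pred == target_labels[~tr]))
    if not accs:
        raise ValueError("no usable training context")
    return float(np.mean(accs))


def _orthonormal_rows(X, rtol=1e-10):
    """Orthonormal basis of the row space via reduced SVD; rank-truncated."""
    _, s, Vt = np.linalg.svd(np.asarray(X, dtype=float), full_matrices=False)
    rank = int((s > rtol * s[0]).sum()) if s.size and s[0] > 0 else 0
    return Vt[:rank], rank


def subspace_alignment(X_a, X_b, return_rank=False):
    """Mean cosine of the principal angles between two decoding subspaces.

    Bases come from the reduced SVD of each (classes x K) matrix; the
    singular values of ``V_a V_b'`` are the principal-angle cosines and
    their mean is returned, clamped to [0, 1].  Row rescaling and any
    rotation applied jointly to both matrices leave the metric unchanged.
    Rank-deficient inputs use their actual rank (reported via
    ``return_rank``).
    """
    Xa = X_a.X if isinstance(X_a, SubspaceBasis) else np.asarray(X_a)
    Xb = X_b.X if isinstance(X_b, SubspaceBasis) else np.asarray(X_b)
    if Xa.shape[1] != Xb.shape[1]:
        raise ValueError("bases must live in the same unit space")
    Va, ra = _orthonormal_rows(Xa)
    Vb, rb = _orthonormal_rows(Xb)
    if ra == 0 or rb == 0:
        raise ValueError("zero-rank subspace")
    if min(ra, rb) < min(Xa.shape[0], Xa.shape[1]):
        warnings.warn(f"rank-deficient decoding basis (ranks {ra}, {rb})")
    cos = np.linalg.svd(Va @ Vb.T, compute_uv=False)
    val = float(np.clip(cos.mean(), 0.0, 1.0))
    return (val, (ra, rb)) if return_rank else val


def participation_ratio(acts, labels=None):
    """Effective dimensionality (sum lambda)^2 / sum lambda^2.

    ``lambda`` are the eigenvalues of the covariance of the activations
    after subtracting each class centroid (``labels``; global centering if
    omitted).  Bounded by 1 (all variance on one axis) and K (isotropic).
    Constant activations have no defined dimensionality -> NaN with a
    warning.
    """
    X = np.asarray(acts, dtype=float)
    if labels is None:
        centered = X - X.mean(axis=0)
    else:
        labels = np.asarray(labels)
        centered = X.astype(float).copy()
        for c in np.unique(labels):
            sel = labels == c
            if sel.sum() < 2:
                raise ValueError("need >= 2 samples per class")
            centered[sel] -= X[sel].mean(axis=0)
    # eigenvalues of the covariance via the singular values of the data
    s = np.linalg.svd(centered, compute_uv=False)
    lam = s ** 2 / max(centered.shape[0] - 1, 1)
    tot = lam.sum()
    if tot <= 0:
        warnings.warn("zero-variance activations; participation ratio undefined")
        return np.nan
    return float(tot ** 2 / (lam ** 2).sum())


def normalized_mutual_info(unit_acts, labels, n_bins=10, binning="width"):
    """Plug-in mutual information of one unit with a discrete feature,
    normalized by the feature entropy (range [0, 1], nats internally).

    The unit's activity is discretized into ``n_bins`` equal-width bins over
    its observed range (``binning="count"`` switches to equal-count
    quantile bins); zero-probability cells contribute nothing.  A constant
    feature has zero entropy -> NaN with a warning.
    """
    x = np.asarray(unit_acts, dtype=float)
    y = np.asarray(labels)
    _, y_codes = np.unique(y, return_inverse=True)
    n_y = y_codes.max() + 1
    if n_y < 2:
        warnings.warn("single-valued feature; normalized MI undefined")
        return np.nan
    if binning == "width":
        lo, hi = x.min(), x.max()
        if hi <= lo:
            return 0.0
        edges = np.linspace(lo, hi, n_bins + 1)
    elif binning == "count":
        edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)))
        if edges.size < 2:
            return 0.0
    else:
        raise ValueError("binning must be 'width' or 'count'")
    x_codes = np.clip(np.searchsorted(edges, x, side="right") - 1,
                      0, len(edges) - 2)
    joint = np.zeros((len(edges) - 1, n_y))
    np.add.at(joint, (x_codes, y_codes), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    mi = float((joint[nz] * np.log(joint[nz] / (px @ py)[nz])).sum())
    h_y = float(-(py[py > 0] * np.log(py[py > 0])).sum())
    return float(np.clip(mi / h_y, 0.0, 1.0))


def _tukey_extreme(z, labels, classes, alpha=0.05):
    """Directions with uniformly higher/lower activity than the other three.

    Returns (positive winner or None, negative winner or None) based on
    Tukey's HSD over the class groups.
    """
    res = pairwise_tukeyhsd(z, labels, alpha=alpha)
    pairs = [(classes[i], classes[j])
             for i in range(len(classes)) for j in range(i + 1, len(classes))]
    means = {c: z[labels == c].mean() for c in classes}
    reject = res.reject
    sig_pairs = {frozenset(p) for p, r in zip(pairs, reject) if r}
    pos = [c for c in classes
           if all(frozenset((c, o)) in sig_pairs and means[c] > means[o]
                  for o in classes if o != c)]
    neg = [c for c in classes
           if all(frozenset((c, o)) in sig_pairs and means[c] < means[o]
                  for o in classes if o != c)]
    return (pos[0] if pos else None), (neg[0] if neg else None)


def classify_unit_selectivity(acts, target_labels, anova_alpha=1e-3,
                              tukey_alpha=0.05, ranksum_alpha=0.05):
    """Categorize each unit's target-direction tuning.

    Per unit (z-scored across stimuli): (1) one-way ANOVA across the four
    target directions gates at p < 1e-3 (zero-variance units are "none");
    (2) Tukey's HSD finds a direction with uniformly higher (positive
    winner) and/or uniformly lower (negative winner) activity than the other
    three; a single winner gives "selective+" / "selective-"; (3) with both
    winners, a rank-sum test compares |z| on the positive-direction trials
    against |z| on the negative-direction trials - significance hands the
    label to the larger side, otherwise "complex"; (4) significant units
    matching no pattern are "complex".

    Returns a list of category strings, one per column of ``acts``.
    """
    X = np.atleast_2d(np.asarray(acts, dtype=float))
    labels = np.asarray(target_labels)
    classes = np.unique(labels)
    for c in classes:
        if (labels == c).sum() < 2:
            raise ValueError("need >= 2 samples per direction")
    cats = []
    for j in range(X.shape[1]):
        x = X[:, j]
        sd = x.std()
        if sd == 0:
            cats.append("none")
            continue
        z = (x - x.mean()) / sd
        groups = [z[labels == c] for c in classes]
        _, p = stats.f_oneway(*groups)
        if not (np.isfinite(p) and p < anova_alpha):
            cats.append("none")
            continue
        pos, neg = _tukey_extreme(z, labels, classes, alpha=tukey_alpha)
        if pos is not None and neg is None:
            cats.append("selective+")
        elif neg is not None and pos is None:
            cats.append("selective-")
        elif pos is not None and neg is not None:
            zp = np.abs(z[labels == pos])
            zn = np.abs(z[labels == neg])
            stat, pr = stats.ranksums(zp, zn)
            if pr < ranksum_alpha:
                cats.append("selective+" if np.median(zp) > np.median(zn)
                            else "selective-")
            else:
                cats.append("complex")
        else:
            cats.append("complex")
    return cats
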