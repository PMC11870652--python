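"""Flanker-task stimulus synthesis and ground-truth behavior simulation.

Generates arrowhead ("bird") stimuli in the style of a four-alternative
flanker task: a central target glyph pointing left/right/up/down, surrounded
by four flanker glyphs that share a single direction, arranged in one of
seven layouts (four V formations, horizontal line, vertical line, cross).
Stimuli are composed on a 640x480 virtual window at a random position subject
to edge constraints, anti-aliased, and bilinearly resized to the encoder's
input resolution (128x128 by default).

Behavior is simulated from a ground-truth LBA whose drift-rate means depend
on target/flanker agreement: the target's response accumulates at ``v_t``
(reduced by a conflict decrement on incongruent trials), the flanker's
response (incongruent trials only) at ``v_f``, every other response at
``v_o``, with ``v_t > v_f > v_o``.  Defaults ``(v_t, v_f, v_o) = (3, 1, -1)``
with decrement 0.6 give target-dominant, weakly attractive flankers and the
classic positive RT and accuracy congruency effects (see
:class:`GroundTruthConfig` for why the decrement is needed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.transform import resize

from .lba import LBAParams, sample_trials

__all__ = [
    "DIRECTIONS",
    "LAYOUTS",
    "TrialSpec",
    "TrialRecord",
    "RenderConfig",
    "GroundTruthConfig",
    "sample_trial_specs",
    "render_stimulus",
    "render_canvas",
    "render_batch",
    "simulate_participant",
    "split_dataset",
    "records_to_frame",
    "frame_to_records",
]

DIRECTIONS = ("left", "right", "up", "down")
LAYOUTS = (
    "v_left",
    "v_right",
    "v_up",
    "v_down",
    "line_horizontal",
    "line_vertical",
    "cross",
)

WINDOW_W, WINDOW_H = 640, 480


@dataclass(frozen=True)
class TrialSpec:
    """One stimulus description."""

    target_dir: str
    flanker_dir: str
    layout: str
    center_xy: tuple
    congruent: bool = field(init=False)

    def __post_init__(self):
        if self.target_dir not in DIRECTIONS or self.flanker_dir not in DIRECTIONS:
            raise ValueError("directions must be one of " + ", ".join(DIRECTIONS))
        if self.layout not in LAYOUTS:
            raise ValueError(f"unknown layout {self.layout!r}")
        object.__setattr__(self, "congruent", self.target_dir == self.flanker_dir)


@dataclass(frozen=True)
class TrialRecord:
    """One stimulus plus its behavioral outcome."""

    spec: TrialSpec
    rt: float
    choice: int
    correct: bool = field(init=False)

    def __post_init__(self):
        if self.rt <= 0:
            raise ValueError("rt must be positive")
        if self.choice not in (1, 2, 3, 4):
            raise ValueError("choice must be in 1..4")
        object.__setattr__(
            self, "correct", DIRECTIONS[self.choice - 1] == self.spec.target_dir
        )


@dataclass(frozen=True)
class RenderConfig:
    """Stimulus rendering configuration.

    The glyph is a filled isoceles arrowhead ~``glyph_size`` px long in
    window space; ``spacing`` separates neighboring glyph centers.  The exact
    art is a convention: direction is the only shape cue.  ``out_hw`` sets
    the post-resize raster; ``canvas_scale`` < 1 rasterizes the window on a
    proportionally coarser grid (used by the reduced desk-scale pipeline).
    """

    glyph_size: float = 40.0
    spacing: float = 55.0
    background: tuple = (0.30, 0.45, 0.72)   # uniform blue-ish
    glyph_color: tuple = (0.95, 0.82, 0.20)  # bird color, constant
    out_hw: tuple = (128, 128)
    canvas_scale: float = 1.0
    supersample: int = 2

    def layout_offsets(self, layout: str) -> np.ndarray:
        d = self.spacing
        if layout == "line_horizontal":
            off = [(-2 * d, 0), (-d, 0), (d, 0), (2 * d, 0)]
        elif layout == "line_vertical":
            off = [(0, -2 * d), (0, -d), (0, d), (0, 2 * d)]
        elif layout == "cross":
            off = [(-d, 0), (d, 0), (0, -d), (0, d)]
        elif layout == "v_up":      # apex at target, arms extending down
            off = [(-d, d), (-2 * d, 2 * d), (d, d), (2 * d, 2 * d)]
        elif layout == "v_down":
            off = [(-d, -d), (-2 * d, -2 * d), (d, -d), (2 * d, -2 * d)]
        elif layout == "v_left":    # arms extending right
            off = [(d, -d), (2 * d, -2 * d), (d, d), (2 * d, 2 * d)]
        elif layout == "v_right":
            off = [(-d, -d), (-2 * d, -2 * d), (-d, d), (-2 * d, 2 * d)]
        else:
            raise ValueError(f"unknown layout {layout!r}")
        return np.asarray(off, dtype=float)

    def half_extent(self, layout: str) -> tuple:
        """(hx, hy): half-size of the layout bounding box incl. glyph."""
        off = self.layout_offsets(layout)
        g = self.glyph_size / 2 + 2  # glyph half-extent + anti-alias margin
        return (float(np.abs(off[:, 0]).max() + g), float(np.abs(off[:, 1]).max() + g))


def _glyph_vertices(direction: str, size: float) -> np.ndarray:
    h = size / 2.0
    w = 0.7 * h
    tri = np.array([(-h, -w), (-h, w), (h, 0.0)])  # points right
    if direction == "right":
        rot = np.eye(2)
    elif direction == "left":
        rot = np.array([(-1.0, 0.0), (0.0, -1.0)])
    elif direction == "down":
        rot = np.array([(0.0, -1.0), (1.0, 0.0)])  # +y is down in image coords
    else:  # up
        rot = np.array([(0.0, 1.0), (-1.0, 0.0)])
    return tri @ rot.T


def _rasterize_triangle(alpha: np.ndarray, verts: np.ndarray, scale: float, ss: int):
    """Accumulate anti-aliased coverage of one triangle into ``alpha``.

    ``verts`` are in window coordinates; the raster grid is the window scaled
    by ``scale`` with ``ss``x``ss`` supersampling per pixel.
    """
    H, W = alpha.shape
    v = verts * scale
    x0 = max(int(np.floor(v[:, 0].min())) - 1, 0)
    x1 = min(int(np.ceil(v[:, 0].max())) + 1, W - 1)
    y0 = max(int(np.floor(v[:, 1].min())) - 1, 0)
    y1 = min(int(np.ceil(v[:, 1].max())) + 1, H - 1)
    if x1 < x0 or y1 < y0:
        return
    sub = (np.arange(ss) + 0.5) / ss
    xs = (x0 + np.add.outer(np.arange(x1 - x0 + 1), sub - 0.5).ravel())[None, :]
    ys = (y0 + np.add.outer(np.arange(y1 - y0 + 1), sub - 0.5).ravel())[:, None]
    inside = np.ones((ys.size, xs.size), dtype=bool)
    for i in range(3):
        ax, ay = v[i]
        bx, by = v[(i + 1) % 3]
        inside &= (bx - ax) * (ys - ay) - (by - ay) * (xs - ax) <= 0
    cov = inside.reshape(y1 - y0 + 1, ss, x1 - x0 + 1, ss).mean(axis=(1, 3))
    np.maximum(alpha[y0:y1 + 1, x0:x1 + 1], cov, out=alpha[y0:y1 + 1, x0:x1 + 1])


def render_canvas(spec: TrialSpec, cfg: RenderConfig = RenderConfig(),
                  flankers_only: bool = False) -> np.ndarray:
    """Render the full-resolution window raster (H, W, 3) in [0, 1].

    Deterministic.  Raises if the layout bounding box would be clipped by the
    window edge.  ``flankers_only`` suppresses the target glyph (used by the
    pixel-provenance test surface).
    """
    hx, hy = cfg.half_extent(spec.layout)
    cx, cy = spec.center_xy
    if not (hx <= cx <= WINDOW_W - hx and hy <= cy <= WINDOW_H - hy):
        raise ValueError(
            f"center {spec.center_xy} too close to the edge for layout "
            f"{spec.layout} (half extent {(hx, hy)})"
        )
    sc = cfg.canvas_scale
    H, W = int(round(WINDOW_H * sc)), int(round(WINDOW_W * sc))
    alpha = np.zeros((H, W))
    if not flankers_only:
        verts = _glyph_vertices(spec.target_dir, cfg.glyph_size) + (cx, cy)
        _rasterize_triangle(alpha, verts, sc, cfg.supersample)
    fl = _glyph_vertices(spec.flanker_dir, cfg.glyph_size)
    for off in cfg.layout_offsets(spec.layout):
        _rasterize_triangle(alpha, fl + (cx + off[0], cy + off[1]), sc, cfg.supersample)
    bg = np.asarray(cfg.background)
    fg = np.asarray(cfg.glyph_color)
    return bg + alpha[:, :, None] * (fg - bg)


def render_stimulus(spec: TrialSpec, cfg: RenderConfig = RenderConfig()) -> np.ndarray:
    """Render one stimulus and resize to ``cfg.out_hw`` (bilinear, AA).

    Returns an (H, W, 3) float array in [0, 1]; deterministic given
    (spec, cfg).
    """
    canvas = render_canvas(spec, cfg)
    img = resize(canvas, cfg.out_hw + (3,), order=1, anti_aliasing=True,
                 preserve_range=True)
    return np.clip(img, 0.0, 1.0)


def render_batch(specs, cfg: RenderConfig = RenderConfig()) -> np.ndarray:
    """Render a list of specs into an (N, H, W, 3) array."""
    return np.stack([render_stimulus(s, cfg) for s in specs])


def sample_trial_specs(n, congruent_frac=0.5, seed=None, rng=None,
                       cfg: RenderConfig = RenderConfig()):
    """Sample ``n`` trial specifications.

    Congruency is Bernoulli(``congruent_frac``); target direction, flanker
    direction (conditional on congruency), layout and position are uniform
    over their valid ranges.  Positions are integer pixel centers constrained
    so no glyph is clipped.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= congruent_frac <= 1.0:
        raise ValueError("congruent_frac must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    specs = []
    for _ in range(int(n)):
        congruent = rng.random() < congruent_frac
        tgt = DIRECTIONS[rng.integers(4)]
        if congruent:
            fl = tgt
        else:
            others = [d for d in DIRECTIONS if d != tgt]
            fl = others[rng.integers(3)]
        layout = LAYOUTS[rng.integers(7)]
        hx, hy = cfg.half_extent(layout)
        cx = int(rng.integers(int(np.ceil(hx)), int(np.floor(WINDOW_W - hx)) + 1))
        cy = int(rng.integers(int(np.ceil(hy)), int(np.floor(WINDOW_H - hy)) + 1))
        specs.append(TrialSpec(tgt, fl, layout, (cx, cy)))
    return specs


@dataclass(frozen=True)
class GroundTruthConfig:
    """Ground-truth generator: LBA parameters plus the drift-rate rule.

    The target response accumulates at ``v_target``; on incongruent trials
    the flanker's response accumulates at ``v_flanker``, all remaining
    responses at ``v_other``, and the target drift is reduced by
    ``conflict_decrement``.  The decrement models the degradation of target
    evidence under response conflict; in an independent race a boosted
    flanker accumulator alone lowers incongruent accuracy but *speeds* mean
    correct RTs (selection among independent finishers), so without the
    decrement no positive RT congruency effect is possible.  ``invalid``
    selects how trials on which all four sampled drifts are non-positive are
    handled: ``"resample"`` redraws them, ``"drop"`` removes them.
    """

    params: LBAParams = field(default_factory=lambda: LBAParams(b=1.0, A=0.5, t0=0.25))
    v_target: float = 3.0
    v_flanker: float = 1.0
    v_other: float = -1.0
    conflict_decrement: float = 0.6
    invalid: str = "resample"

    def __post_init__(self):
        if not np.all(np.isfinite([self.v_target, self.v_flanker, self.v_other,
                                   self.conflict_decrement])):
            raise ValueError("ground-truth drift rates must be finite")
        if self.invalid not in ("resample", "drop"):
            raise ValueError("invalid must be 'resample' or 'drop'")

    def drift_means(self, specs) -> np.ndarray:
        """(n, 4) drift-mean matrix implied by the rule."""
        v = np.full((len(specs), 4), self.v_other)
        for i, s in enumerate(specs):
            if s.congruent:
                v[i, DIRECTIONS.index(s.target_dir)] = self.v_target
            else:
                v[i, DIRECTIONS.index(s.target_dir)] = (
                    self.v_target - self.conflict_decrement
                )
                v[i, DIRECTIONS.index(s.flanker_dir)] = self.v_flanker
        return v


def simulate_participant(specs, gt: GroundTruthConfig = GroundTruthConfig(),
                         seed=None, rng=None, max_resample=100):
    """Simulate RTs and choices for a list of trial specs.

    Draws each trial from the ground-truth LBA.  Returns a list of
    :class:`TrialRecord` aligned with ``specs`` (shorter if
    ``gt.invalid == "drop"`` removed undefined trials).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    v = gt.drift_means(specs)
    rts, choices, valid = sample_trials(v, gt.params, rng=rng)
    if gt.invalid == "resample":
        tries = 0
        while not valid.all() and tries < max_resample:
            bad = ~valid
            r2, c2, v2 = sample_trials(v[bad], gt.params, rng=rng)
            rts[bad], choices[bad] = r2, c2
            valid[bad] = v2
            tries += 1
        if not valid.all():
            warnings.warn("some trials remained invalid after resampling; dropped")
    keep = np.flatnonzero(valid)
    return [TrialRecord(specs[i], float(rts[i]), int(choices[i])) for i in keep]


def split_dataset(n, fractions=(0.65, 0.15, 0.20), seed=None, rng=None):
    """Partition ``range(n)`` into shuffled train/validation/holdout index sets.

    Sizes are ``round(n * fraction)`` for validation and holdout with the
    remainder assigned to train, so the three sets are disjoint and
    exhaustive.  Deterministic given ``seed``.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise ValueError("fractions must be three non-negative numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = int(n)
    n_val = int(round(n * fractions[1]))
    n_hold = int(round(n * fractions[2]))
    n_train = n - n_val - n_hold
    perm = rng.permutation(n)
    return (perm[:n_train], perm[n_train:n_train + n_val], perm[n_train + n_val:])


def records_to_frame(records) -> pd.DataFrame:
    """Serialize trial records to the canonical trial-table frame."""
    rows = []
    for i, r in enumerate(records):
        s = r.spec
        rows.append(dict(
            trial_id=i, target_dir=s.target_dir, flanker_dir=s.flanker_dir,
            layout=s.layout, center_x=s.center_xy[0], center_y=s.center_xy[1],
            congruent=s.congruent, rt=r.rt, choice=r.choice, correct=r.correct,
        ))
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame):
    """Inverse of :func:`records_to_frame` (derived fields revalidated)."""
    out = []
    for _, row in df.iterrows():
        spec = TrialSpec(row["target_dir"], row["flanker_dir"], row["layout"],
                         (int(row["center_x"]), int(row["center_y"])))
        out.append(TrialRecord(spec, float(row["rt"]), int(row["choice"])))
    return out
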