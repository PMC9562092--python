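"""Statistics layer: paired t-tests on valence, ANOVA on behavior,
accuracy-based block splitting, Welch t-tests on local network measures,
Pearson correlations of graph metrics with accuracy, and per-electrode
topographic summaries.

All tests are thin, validated wrappers over ``scipy.stats`` returning a
uniform :class:`StatResult`; p-values are reported uncorrected (a
Benjamini–Hochberg helper is available for users who want correction
across bands/metrics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .montage import is_midline


@dataclass
class StatResult:
    test: str
    statistic: float
    p: float
    effect_direction: int = 0          # sign of the effect (post-pre, g1-g2, r)
    group_sizes: tuple = ()
    r: float | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if not (np.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")


def paired_ttest(pre, post) -> StatResult:
    """Two-sided matched-samples t-test on post - pre differences."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    diff = post - pre
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff.mean(), 0.0):
            return StatResult("paired_t", 0.0, 1.0, 0, (pre.size,),
                              note="zero differences")
        return StatResult("paired_t", np.inf * np.sign(diff.mean()), 0.0,
                          int(np.sign(diff.mean())), (pre.size,),
                          note="zero variance, nonzero mean difference")
    res = sstats.ttest_rel(post, pre)
    return StatResult("paired_t", float(res.statistic), float(res.pvalue),
                      int(np.sign(diff.mean())), (pre.size,))


def oneway_anova(groups: list) -> StatResult:
    """One-way ANOVA across groups (F from between/within sums of squares)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    means = [g.mean() for g in groups]
    ssw = sum(((g - m) ** 2).sum() for g, m in zip(groups, means))
    sizes = tuple(g.size for g in groups)
    if np.allclose(ssw, 0.0):
        if np.allclose(means, means[0]):
            return StatResult("anova", 0.0, 1.0, 0, sizes,
                              note="degenerate: all values equal")
        return StatResult("anova", np.inf, 0.0, 0, sizes,
                          note="degenerate: zero within-group variance")
    res = sstats.f_oneway(*groups)
    return StatResult("anova", float(res.statistic), float(res.pvalue),
                      0, sizes)


def split_by_accuracy(blocks: pd.DataFrame, k: int = 16
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k / bottom-k blocks by correct count.

    *blocks* needs columns ``correct`` and, for the deterministic
    tie-break, ``subject`` and ``block`` (lexicographic order).  Returns
    ``(group1, group2)`` = (highest, lowest accuracy).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if 2 * k > len(blocks):
        raise ValueError(f"2k={2 * k} exceeds the {len(blocks)} blocks")
    tie_cols = [c for c in ("subject", "block") if c in blocks.columns]
    ordered = blocks.sort_values(["correct", *tie_cols],
                                 ascending=[False] + [True] * len(tie_cols),
                                 kind="mergesort")
    group1 = ordered.iloc[:k]
    group2 = ordered.iloc[len(ordered) - k:]
    return group1, group2


def independent_ttest(g1, g2) -> StatResult:
    """Two-sided Welch (unequal-variance) t-test."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs >= 2 values")
    delta = g1.mean() - g2.mean()
    if np.allclose(g1.std(ddof=1), 0.0) and np.allclose(g2.std(ddof=1), 0.0):
        if np.allclose(delta, 0.0):
            return StatResult("welch_t", 0.0, 1.0, 0, (g1.size, g2.size),
                              note="degenerate: both groups constant")
        return StatResult("welch_t", np.inf * np.sign(delta), 0.0,
                          int(np.sign(delta)), (g1.size, g2.size),
                          note="zero variance, nonzero mean difference")
    res = sstats.ttest_ind(g1, g2, equal_var=False)
    return StatResult("welch_t", float(res.statistic), float(res.pvalue),
                      int(np.sign(delta)), (g1.size, g2.size))


def pearson(x, y) -> StatResult:
    """Pearson correlation with a two-sided p from the t transform
    (n - 2 degrees of freedom)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.allclose(x.std(), 0.0) or np.allclose(y.std(), 0.0):
        raise ValueError("zero variance input")
    res = sstats.pearsonr(x, y)
    r = float(res.statistic)
    return StatResult("pearson", r, float(res.pvalue), int(np.sign(r)),
                      (x.size,), r=r)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values."""
    return sstats.false_discovery_control(np.asarray(pvalues, dtype=float),
                                          method="bh")


@dataclass
class TopographicSummary:
    table: pd.DataFrame                 # group x electrode means
    midline: pd.DataFrame               # midline electrodes only
    figure: object | None = field(default=None, repr=False)


def topographic_summary(nodal: pd.DataFrame, value: str,
                        group_assignments: dict,
                        positions: dict | None = None, *,
                        render: bool = False) -> TopographicSummary:
    """Per-group, per-electrode mean of a local measure.

    *nodal* needs columns (subject, block, electrode, *value*);
    *group_assignments* maps a group name to a set of (subject, block)
    keys.  Electrodes without a known position are excluded (with a
    warning) when *positions* is given.  With ``render=True`` an
    inverse-distance-interpolated scalp map per group is drawn.
    """
    rows = []
    for gname, keys in group_assignments.items():
        keyset = {tuple(k) for k in keys}
        sel = nodal[[tuple(t) in keyset
                     for t in zip(nodal["subject"], nodal["block"])]]
        for el, sub in sel.groupby("electrode"):
            if positions is not None and el not in positions:
                warnings.warn(f"no position for electrode {el}; excluded")
                continue
            rows.append((gname, el, sub[value].mean(), len(sub)))
    table = pd.DataFrame(rows, columns=["group", "electrode",
                                        f"mean_{value}", "n"])
    midline = table[table["electrode"].map(is_midline)].reset_index(drop=True)
    fig = None
    if render and positions is not None:
        fig = _render_scalp_maps(table, f"mean_{value}", positions)
    return TopographicSummary(table=table, midline=midline, figure=fig)


def _render_scalp_maps(table: pd.DataFrame, col: str, positions: dict):
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    groups = table["group"].unique()
    fig, axes = plt.subplots(1, len(groups), figsize=(4 * len(groups), 4),
                             squeeze=False)
    gx, gy = np.meshgrid(np.linspace(-1.1, 1.1, 80),
                         np.linspace(-1.1, 1.1, 80))
    for ax, gname in zip(axes[0], groups):
        sub = table[table["group"] == gname]
        pts = np.array([positions[e] for e in sub["electrode"]])
        vals = sub[col].to_numpy()
        d = np.sqrt((gx[..., None] - pts[:, 0]) ** 2
                    + (gy[..., None] - pts[:, 1]) ** 2)
        wgt = 1.0 / np.maximum(d, 1e-6) ** 2
        img = (wgt * vals).sum(axis=-1) / wgt.sum(axis=-1)
        img[np.hypot(gx, gy) > 1.05] = np.nan
        ax.imshow(img, origin="lower", extent=(-1.1, 1.1, -1.1, 1.1))
        ax.scatter(pts[:, 0], pts[:, 1], s=8, c="k")
        ax.set_title(str(gname))
        ax.set_axis_off()
    fig.tight_layout()
    return fig
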