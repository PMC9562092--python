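"""ERP microstate analysis.

A microstate is a quasi-stable scalp topography.  The stages implemented
here: global field power (GFP) and its peaks, Topographic
Atomize & Agglomerate Hierarchical Clustering (T-AAHC) of the GFP-peak
maps, predictive-residual-variance (CV) model selection of the number of
classes, back-fitting of templates onto the ERP time course, and matching
of template sets across experimental conditions.

Conventions
-----------
* Maps are average-referenced before anything else; spatial correlation is
  the cosine between average-referenced maps.
* Polarity is *sensitive* by default: evoked (ERP) topographies carry a
  meaningful sign, unlike spontaneous-EEG microstates.  ``polarity=
  "invariant"`` switches every comparison to absolute correlation and
  template extraction to the first principal component.
* GEV (global explained variance) weights each timepoint/map by its
  squared GFP: GEV = sum_t GFP(t)^2 corr(u_t, T_label(t))^2 / sum_t GFP(t)^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


# --------------------------------------------------------------------------
# GFP

@dataclass
class GFPSeries:
    values: np.ndarray  # µV, one per timepoint
    fs: float


def _rereference_maps(maps: np.ndarray, axis: int = -1) -> np.ndarray:
    return maps - maps.mean(axis=axis, keepdims=True)


def gfp(erp: np.ndarray, fs: float = 1.0, *, tol: float = 1e-6) -> GFPSeries:
    """Global field power: the RMS across average-referenced electrodes at
    each instant, GFP(t) = sqrt(mean_i u_i(t)^2).

    *erp* is (n_channels, n_timepoints).  Input that is not average-
    referenced is re-referenced with a warning.
    """
    erp = np.atleast_2d(np.asarray(erp, dtype=float))
    col_means = erp.mean(axis=0)
    if np.abs(col_means).max() > tol * max(1.0, np.abs(erp).max()):
        warnings.warn("input not average-referenced; re-referencing")
        erp = erp - col_means
    return GFPSeries(values=np.sqrt((erp**2).mean(axis=0)), fs=fs)


def gfp_peaks(series: GFPSeries, min_separation_ms: float = 0.0) -> np.ndarray:
    """Strict local maxima of the GFP, thinned to *min_separation_ms*.

    When two peaks fall closer than the separation, the larger is kept.
    Flat or monotone series yield an empty index array.
    """
    if min_separation_ms < 0:
        raise ValueError("min_separation_ms must be >= 0")
    v = series.values
    if v.size < 3:
        return np.array([], dtype=int)
    cand = np.where((v[1:-1] > v[:-2]) & (v[1:-1] > v[2:]))[0] + 1
    if cand.size == 0 or min_separation_ms == 0:
        return cand
    min_sep = min_separation_ms * series.fs / 1000.0
    kept: list[int] = []
    for idx in cand[np.argsort(v[cand])[::-1]]:  # largest first
        if all(abs(idx - k) >= min_sep for k in kept):
            kept.append(idx)
    return np.array(sorted(kept), dtype=int)


# --------------------------------------------------------------------------
# spatial correlation and GEV

def spatial_correlation(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity between two average-referenced maps."""
    u = u - u.mean()
    v = v - v.mean()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(u @ v / (nu * nv))


def _corr_matrix(maps: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """(n_maps, n_templates) cosine correlations; zero-norm rows give 0."""
    m = _rereference_maps(maps)
    t = _rereference_maps(templates)
    mn = np.linalg.norm(m, axis=1, keepdims=True)
    tn = np.linalg.norm(t, axis=1, keepdims=True)
    mn[mn == 0] = 1.0
    tn[tn == 0] = 1.0
    return (m / mn) @ (t / tn).T


def gev(maps: np.ndarray, templates: np.ndarray, labels: np.ndarray) -> float:
    """GFP²-weighted fraction of topographic variance explained."""
    g2 = (_rereference_maps(maps) ** 2).mean(axis=1)  # GFP² per map
    total = g2.sum()
    if total == 0:
        return 1.0
    c = _corr_matrix(maps, templates)
    r = c[np.arange(maps.shape[0]), labels]
    return float((g2 * r**2).sum() / total)


# --------------------------------------------------------------------------
# T-AAHC

@dataclass
class MicrostateSolution:
    """One clustering solution: K unit-norm templates, per-map (or per-
    timepoint) labels, explained variance, and the CV criterion value."""

    K: int
    templates: np.ndarray  # (K, n_channels), unit L2 norm
    labels: np.ndarray
    gev: float
    cv: float | None = None
    segment_table: pd.DataFrame | None = None


class TAAHC:
    """Topographic Atomize & Agglomerate Hierarchical Clustering.

    Bottom-up clustering of topographic maps: every map starts as its own
    cluster; at each step the cluster contributing least GEV is dissolved
    ("atomized") and its members are re-assigned individually to the
    surviving cluster with the highest spatial correlation.  A solution is
    recorded at every K in ``[k_min, k_max]``.

    Follows the scikit-learn estimator protocol: ``fit`` on an
    (n_maps, n_channels) array, then ``predict`` labels for new maps;
    fitted attributes carry a trailing underscore.

    Parameters
    ----------
    k_min, k_max : int
        Range of cluster counts to record.
    polarity : {"sensitive", "invariant"}
        Whether a map and its sign-flip are distinct ("sensitive", the ERP
        default) or identified ("invariant", the spontaneous-EEG default).

    Attributes
    ----------
    solutions_ : dict[int, MicrostateSolution]
        One recorded solution per K.
    templates_ : ndarray
        Templates of the smallest-K (final) solution.
    labels_ : ndarray
        Labels of the final solution.
    """

    def __init__(self, k_min: int = 2, k_max: int = 10,
                 polarity: str = "sensitive"):
        self.k_min = k_min
        self.k_max = k_max
        self.polarity = polarity

    # -- sklearn plumbing ---------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"k_min": self.k_min, "k_max": self.k_max,
                "polarity": self.polarity}

    def set_params(self, **params) -> "TAAHC":
        for key, val in params.items():
            if key not in ("k_min", "k_max", "polarity"):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, val)
        return self

    # -- core ---------------------------------------------------------------
    def _template_of(self, member_maps: np.ndarray) -> np.ndarray:
        if self.polarity == "sensitive":
            t = member_maps.mean(axis=0)
        else:
            # first principal component of the member maps
            _, _, vt = np.linalg.svd(member_maps, full_matrices=False)
            t = vt[0]
            j = np.argmax(np.abs(t))
            if t[j] < 0:
                t = -t
        t = t - t.mean()
        norm = np.linalg.norm(t)
        return t / norm if norm > 0 else t

    def fit(self, maps: np.ndarray, y=None) -> "TAAHC":
        maps = _rereference_maps(np.asarray(maps, dtype=float))
        n_maps = maps.shape[0]
        if self.polarity not in ("sensitive", "invariant"):
            raise ValueError("polarity must be 'sensitive' or 'invariant'")
        if not 1 <= self.k_min <= self.k_max:
            raise ValueError("need 1 <= k_min <= k_max")
        if self.k_max > n_maps:
            raise ValueError(f"k_max={self.k_max} exceeds number of maps {n_maps}")

        g2 = (maps**2).mean(axis=1)  # GFP² weights
        clusters: list[list[int]] = [[i] for i in range(n_maps)]
        templates = [self._template_of(maps[c]) for c in clusters]
        self.solutions_: dict[int, MicrostateSolution] = {}

        while True:
            K = len(clusters)
            if self.k_min <= K <= self.k_max:
                self._record(maps, clusters, templates, K)
            if K <= self.k_min:
                break
            # GEV contribution of each cluster
            contrib = np.empty(K)
            for k, members in enumerate(clusters):
                c = _corr_matrix(maps[members], templates[k][None, :])[:, 0]
                contrib[k] = (g2[members] * c**2).sum()
            worst = int(np.argmin(contrib))
            orphans = clusters.pop(worst)
            templates.pop(worst)
            tmat = np.vstack(templates)
            c = _corr_matrix(maps[orphans], tmat)
            score = c if self.polarity == "sensitive" else np.abs(c)
            dest = np.argmax(score, axis=1)
            touched = set()
            for m, d in zip(orphans, dest):
                clusters[d].append(m)
                touched.add(int(d))
            for d in touched:
                templates[d] = self._template_of(maps[clusters[d]])

        final = self.solutions_[min(self.solutions_)]
        self.templates_ = final.templates
        self.labels_ = final.labels
        self.n_features_in_ = maps.shape[1]
        return self

    def _record(self, maps, clusters, templates, K) -> None:
        labels = np.empty(maps.shape[0], dtype=int)
        for k, members in enumerate(clusters):
            labels[members] = k
        tmat = np.vstack(templates)
        self.solutions_[K] = MicrostateSolution(
            K=K, templates=tmat.copy(), labels=labels,
            gev=gev(maps, tmat, labels))

    def predict(self, maps: np.ndarray) -> np.ndarray:
        """Assign each map to the best-matching final template."""
        c = _corr_matrix(np.asarray(maps, dtype=float), self.templates_)
        score = c if self.polarity == "sensitive" else np.abs(c)
        return np.argmax(score, axis=1)

    def fit_predict(self, maps: np.ndarray, y=None) -> np.ndarray:
        return self.fit(maps).labels_


def taahc(maps: np.ndarray, k_min: int = 2, k_max: int = 10,
          polarity: str = "sensitive") -> dict[int, MicrostateSolution]:
    """Functional wrapper: run :class:`TAAHC` and return its solutions."""
    est = TAAHC(k_min=k_min, k_max=k_max, polarity=polarity).fit(maps)
    return est.solutions_


# --------------------------------------------------------------------------
# CV criterion and model selection

def cv_criterion(residual_var: float, n_channels: int, K: int) -> float:
    """Predictive residual variance criterion:
    CV = sigma2 * ((n-1)/(n-1-K))^2, minimized over K."""
    if n_channels <= K + 1:
        raise ValueError("need n_channels > K + 1")
    n = n_channels
    return float(residual_var) * ((n - 1) / (n - 1 - K)) ** 2


def residual_variance(maps: np.ndarray, templates: np.ndarray,
                      labels: np.ndarray) -> float:
    """Mean variance left unexplained by the assigned unit-norm templates:
    sigma2 = sum_t (u_t'u_t - (T_l(t)'u_t)^2) / (T (n-1))."""
    maps = _rereference_maps(np.asarray(maps, dtype=float))
    t = _rereference_maps(templates)
    tn = np.linalg.norm(t, axis=1, keepdims=True)
    tn[tn == 0] = 1.0
    t = t / tn
    a = np.einsum("mc,mc->m", maps, t[labels])
    resid = (maps**2).sum(axis=1) - a**2
    n = maps.shape[1]
    return float(resid.sum() / (maps.shape[0] * (n - 1)))


def select_k(solutions: dict[int, MicrostateSolution],
             maps: np.ndarray) -> int:
    """Choose K minimizing the CV criterion; annotates each solution's
    ``cv`` field.  The smallest K wins ties."""
    if not solutions:
        raise ValueError("no solutions to select from")
    n_channels = np.asarray(maps).shape[1]
    best_k, best_cv = None, np.inf
    for K in sorted(solutions):
        sol = solutions[K]
        sig2 = residual_variance(maps, sol.templates, sol.labels)
        sol.cv = cv_criterion(sig2, n_channels, K)
        if sol.cv < best_cv:
            best_k, best_cv = K, sol.cv
    return best_k


# --------------------------------------------------------------------------
# back-fitting and cross-condition matching

def backfit(erp: np.ndarray, templates: np.ndarray, fs: float,
            polarity: str = "sensitive", tmin: float = 0.0):
    """Label every timepoint of *erp* (channels x time) with the template
    of maximal spatial correlation and merge runs into segments.

    Returns ``(labels, segment_table)`` where the table rows are
    (start_ms, end_ms, template) and tile the analyzed window.  Ties go to
    the lowest template index, which also absorbs zero-field timepoints.
    """
    erp = np.asarray(erp, dtype=float)
    c = _corr_matrix(erp.T, templates)
    score = c if polarity == "sensitive" else np.abs(c)
    labels = np.argmax(score, axis=1)
    rows = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            rows.append((
                (tmin + start / fs) * 1000.0,
                (tmin + i / fs) * 1000.0,
                int(labels[start]),
            ))
            start = i
    table = pd.DataFrame(rows, columns=["start_ms", "end_ms", "template"])
    return labels, table


def match_across_conditions(templates_by_condition: dict[str, np.ndarray]
                            ) -> pd.DataFrame:
    """Greedy one-to-one pairing of each condition's templates with the
    first (reference) condition's, by descending absolute spatial
    correlation.

    Returns rows (condition, template, ref_template, abs_corr), one per
    matched pair.
    """
    if len(templates_by_condition) < 2:
        raise ValueError("need at least two conditions to match")
    conds = list(templates_by_condition)
    ref_name, ref = conds[0], np.asarray(templates_by_condition[conds[0]])
    rows = []
    for cond in conds[1:]:
        t = np.asarray(templates_by_condition[cond])
        c = np.abs(_corr_matrix(ref, t))  # (K_ref, K_cond)
        order = np.dstack(np.unravel_index(np.argsort(c, axis=None)[::-1],
                                           c.shape))[0]
        used_ref: set[int] = set()
        used: set[int] = set()
        for i, j in order:
            if i in used_ref or j in used:
                continue
            used_ref.add(int(i))
            used.add(int(j))
            rows.append((cond, int(j), int(i), float(c[i, j])))
            if len(used) == min(c.shape):
                break
    df = pd.DataFrame(rows, columns=["condition", "template",
                                     "ref_template", "abs_corr"])
    df.attrs["reference"] = ref_name
    return df
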