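"""Live-imaging morphometry of the developing epidermal basement membrane.

Quantifies three things from annotated time-lapse data:

* the hair-follicle / interfollicular-epidermis (IFE) intensity ratio per
  timepoint, with developmental-stage binning (placode vs hair germ) by a
  median split on follicle depth;
* the IFE/IFE background ratio (each IFE measurement over its movie's mean);
* basement-membrane deformation angles around dividing basal cells, from
  five annotated points per cell and phase, normalized per cell to its
  interphase angle.

Group comparisons use the nonparametric chain (Mann-Whitney U for two
groups; Kruskal-Wallis followed by Dunn's pairwise tests for several), with
a parametric one-way ANOVA omnibus as an option.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .errors import ArgumentError, DegenerateGeometryError
from .types import DivisionGeometry, FollicleSeries

__all__ = [
    "follicle_ratio",
    "bin_stages",
    "ife_background_ratio",
    "division_angles",
    "normalize_angles",
    "group_compare",
    "dunn_test",
]


def follicle_ratio(series: FollicleSeries) -> np.ndarray:
    """Per-timepoint hair-follicle / mean-IFE intensity ratio."""
    ife_means = np.array([np.mean(v) for v in series.ife_intensities])
    if np.any(ife_means == 0):
        i = int(np.nonzero(ife_means == 0)[0][0])
        raise ArgumentError(f"zero IFE mean at timepoint {i}")
    return series.hf_intensity / ife_means


def bin_stages(depths):
    """Median-split follicle depths into developmental stages.

    The shallower half of all measurements is labeled ``"placode"``, the
    deeper half ``"hair_germ"``; group sizes differ by at most 1 (for odd
    n the extra member goes to placode).  Ties are broken by stable input
    order.  Returns an array of labels aligned with the input.
    """
    depths = np.asarray(depths, dtype=float)
    n = len(depths)
    if n < 2:
        raise ArgumentError("need >= 2 depth values to bin")
    order = np.argsort(depths, kind="stable")
    n_placode = (n + 1) // 2
    labels = np.empty(n, dtype=object)
    labels[order[:n_placode]] = "placode"
    labels[order[n_placode:]] = "hair_germ"
    return labels


def ife_background_ratio(series_list):
    """Each individual IFE measurement over its movie's mean IFE value.

    Within each movie the mean of the returned ratios is exactly 1.
    Returns ``(movie_ids, ratios)`` flat arrays over all measurements.
    """
    movie_ids, values = [], []
    for s in series_list:
        for vals in s.ife_intensities:
            for v in vals:
                movie_ids.append(s.movie_id)
                values.append(float(v))
    movie_ids = np.asarray(movie_ids, dtype=object)
    values = np.asarray(values, dtype=float)
    ratios = np.empty_like(values)
    for movie in np.unique(movie_ids):
        sel = movie_ids == movie
        m = values[sel].mean()
        if m == 0:
            raise ArgumentError(f"zero mean IFE value in movie {movie!r}")
        ratios[sel] = values[sel] / m
    return movie_ids, ratios


def _vertex_angle(v, a, b):
    """Interior angle at vertex v between rays v->a and v->b, degrees."""
    u1 = np.asarray(a, float) - np.asarray(v, float)
    u2 = np.asarray(b, float) - np.asarray(v, float)
    n1, n2 = np.linalg.norm(u1), np.linalg.norm(u2)
    if n1 == 0 or n2 == 0:
        raise DegenerateGeometryError("coincident points: vertex angle undefined")
    c = np.clip(np.dot(u1, u2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def division_angles(geom: DivisionGeometry):
    """Mean basement-membrane angle under a dividing cell at one phase.

    Measures, at each basal vertex V_i, the interior angle between the ray
    toward the dividing cell's basal center A and the ray toward the
    neighbor's basal center B_i, and returns the mean of the two angles
    (plus the pair), in degrees within [0, 180].
    """
    a1 = _vertex_angle(geom.V1, geom.A, geom.B1)
    a2 = _vertex_angle(geom.V2, geom.A, geom.B2)
    return (a1 + a2) / 2.0, (a1, a2)


def normalize_angles(angles_by_cell, dialect="difference"):
    """Normalize per-cell phase angles to the cell's interphase angle.

    ``angles_by_cell`` maps cell id -> {phase: mean angle in degrees}.
    The default ``"difference"`` dialect reports ``angle(phase) -
    angle(interphase)`` (metaphase deformation is negative when the BM
    pinches inward); the ``"ratio"`` dialect reports
    ``angle(phase)/angle(interphase)``.  Cells without an interphase
    measurement are skipped with a warning.
    """
    if dialect not in ("difference", "ratio"):
        raise ArgumentError(f"unknown angle dialect {dialect!r}")
    import logging

    out = {}
    for cell, phases in angles_by_cell.items():
        if "interphase" not in phases:
            logging.getLogger(__name__).warning(
                "cell %s has no interphase angle; skipped", cell
            )
            continue
        ref = phases["interphase"]
        if dialect == "difference":
            out[cell] = {ph: ang - ref for ph, ang in phases.items()}
        else:
            out[cell] = {ph: ang / ref for ph, ang in phases.items()}
    return out


def dunn_test(groups, labels=None, adjust="bonferroni"):
    """Dunn's pairwise post-hoc test after Kruskal-Wallis.

    Standard z statistic on mean ranks of the pooled sample with the
    pooled tie correction::

        z_ij = (Rbar_i - Rbar_j) /
               sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))

    where ``T = sum(t^3 - t)`` over tied groups.  Two-sided normal
    p-values, adjusted by Bonferroni (default) or Holm.

    Returns a list of ``(label_i, label_j, z, p_unadjusted, p_adjusted)``.
    """
    if adjust not in ("bonferroni", "holm"):
        raise ArgumentError(f"unknown adjustment {adjust!r}")
    k = len(groups)
    if k < 2:
        raise ArgumentError("need >= 2 groups")
    if labels is None:
        labels = [str(i) for i in range(k)]
    sizes = [len(g) for g in groups]
    if min(sizes) < 1:
        raise ArgumentError("empty group")
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks, start = [], 0
    for n in sizes:
        mean_ranks.append(ranks[start:start + n].mean())
        start += n
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append([labels[i], labels[j], float(z), float(min(p, 1.0))])

    pvals = np.array([r[3] for r in rows])
    m = len(pvals)
    if adjust == "bonferroni":
        padj = np.minimum(pvals * m, 1.0)
    else:  # holm step-down
        order = np.argsort(pvals)
        padj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * pvals[idx])
            padj[idx] = min(running, 1.0)
    return [tuple(r) + (float(p),) for r, p in zip(rows, padj)]


def group_compare(groups, labels=None, design="two_sample",
                  adjust="bonferroni", parametric=False):
    """Compare labeled samples: Mann-Whitney U or Kruskal-Wallis + Dunn.

    ``design="two_sample"`` runs a two-sided Mann-Whitney U test, exact
    when both groups have n <= 8 and no ties, otherwise the normal
    approximation with tie correction.  ``design="multi_group"`` runs the
    Kruskal-Wallis omnibus followed by Dunn's pairwise tests (or a
    parametric one-way ANOVA omnibus when ``parametric=True``).

    Returns a dict with the omnibus statistic/p-value and, for the
    multi-group design, the pairwise Dunn rows.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 1 for g in groups):
        raise ArgumentError("empty group")
    if design == "two_sample":
        if len(groups) != 2:
            raise ArgumentError("two_sample design needs exactly 2 groups")
        pooled = np.concatenate(groups)
        has_ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (max(map(len, groups)) <= 8 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided",
                                 method=method)
        return {"test": f"mann-whitney ({method})",
                "statistic": float(res.statistic), "p_value": float(res.pvalue)}
    if design != "multi_group":
        raise ArgumentError(f"unknown design {design!r}")
    if len(groups) < 2:
        raise ArgumentError("multi_group design needs >= 2 groups")
    if parametric:
        stat, p = stats.f_oneway(*groups)
        omnibus = "one-way ANOVA"
    else:
        stat, p = stats.kruskal(*groups)
        omnibus = "kruskal-wallis"
    return {
        "test": f"{omnibus} + dunn ({adjust})",
        "statistic": float(stat),
        "p_value": float(p),
        "pairwise": dunn_test(groups, labels=labels, adjust=adjust),
    }
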