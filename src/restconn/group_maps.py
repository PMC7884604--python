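"""Group-level contrasts on Fisher-z maps with permutation cluster inference.

The 2x2 (group x time) factorial is realized as the planned voxel-wise
two-sample contrasts the analysis actually interprets: obese vs lean at
each session, and the interaction as an unpaired contrast on per-subject
change maps (T8 - T0).  Clusters of supra-threshold voxels (one-sided
t > t_crit at an uncorrected voxel p) are assigned permutation p-values
from the distribution of the maximum supra-threshold cluster extent
under group-label exchange, then corrected across clusters with
Benjamini-Hochberg FDR.  A nonparametric extent null replaces
random-field theory: it is assumption-free and exact at desk scale.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Cluster",
    "ContrastResult",
    "RoiMask",
    "two_sample_t_grid",
    "fit_group_time_model",
    "cluster_threshold",
    "permutation_null_extents",
    "cluster_fdr",
    "select_obesity_sensitive_rois",
    "select_interaction_roi",
]


@dataclasses.dataclass
class Cluster:
    """A connected supra-threshold component of a stat map."""

    peak_index: tuple[int, int, int]
    peak_value: float
    extent: int
    mask: np.ndarray
    p_value: float | None = None
    q_value: float | None = None


@dataclasses.dataclass
class ContrastResult:
    """Voxel-wise t grid for one planned contrast."""

    stat_grid: np.ndarray
    contrast: str
    df: int
    clusters: list[Cluster] | None = None


@dataclasses.dataclass
class RoiMask:
    """A surviving cluster promoted to a region of interest."""

    mask: np.ndarray
    sign: str  # "positive" (obese > lean) or "negative" (obese < lean)
    cluster: Cluster


def _connectivity_structure(connectivity: int) -> np.ndarray:
    ranks = {6: 1, 18: 2, 26: 3}
    if connectivity not in ranks:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, ranks[connectivity])


def two_sample_t_grid(a_maps: np.ndarray,
                      b_maps: np.ndarray) -> tuple[np.ndarray, int]:
    """Pooled-variance two-sample t (a minus b) per voxel."""
    a_maps = np.asarray(a_maps, dtype=float)
    b_maps = np.asarray(b_maps, dtype=float)
    na, nb = a_maps.shape[0], b_maps.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 maps per group")
    df = na + nb - 2
    ma, mb = a_maps.mean(axis=0), b_maps.mean(axis=0)
    ssa = ((a_maps - ma) ** 2).sum(axis=0)
    ssb = ((b_maps - mb) ** 2).sum(axis=0)
    pooled = (ssa + ssb) / df
    denom = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (ma - mb) / denom, 0.0)
    return t, df


def fit_group_time_model(zmaps: np.ndarray, groups: np.ndarray,
                         sessions: np.ndarray) -> dict[str, ContrastResult]:
    """Planned contrasts of the group x time factorial.

    ``zmaps`` is (n_maps, X, Y, Z) with aligned ``groups`` ("lean"/"obese")
    and ``sessions`` ("T0"/"T8") labels.  Returns obese-vs-lean t grids at
    each session with at least 2 maps per cell, plus the interaction
    contrast (obese minus lean on T8 - T0 change maps) when both sessions
    are present for both groups; participants are assumed ordered
    identically within each session.
    """
    zmaps = np.asarray(zmaps, dtype=float)
    groups = np.asarray(groups)
    sessions = np.asarray(sessions)
    if not (zmaps.shape[0] == groups.size == sessions.size):
        raise ValueError("maps, groups and sessions must align")
    out: dict[str, ContrastResult] = {}
    for sess in ("T0", "T8"):
        ob = zmaps[(groups == "obese") & (sessions == sess)]
        ln = zmaps[(groups == "lean") & (sessions == sess)]
        if sess == "T0" and (len(ob) < 2 or len(ln) < 2):
            raise ValueError("baseline contrast requires >= 2 maps per group")
        if len(ob) >= 2 and len(ln) >= 2:
            t, df = two_sample_t_grid(ob, ln)
            out[f"group_{sess}"] = ContrastResult(t, f"obese_vs_lean_{sess}", df)
    for grp in ("obese", "lean"):
        n0 = ((groups == grp) & (sessions == "T0")).sum()
        n8 = ((groups == grp) & (sessions == "T8")).sum()
        if n8 and n0 != n8:
            raise ValueError(f"{grp}: unpaired session counts {n0} vs {n8}")
    if (sessions == "T8").any():
        ob_ch = (zmaps[(groups == "obese") & (sessions == "T8")]
                 - zmaps[(groups == "obese") & (sessions == "T0")])
        ln_ch = (zmaps[(groups == "lean") & (sessions == "T8")]
                 - zmaps[(groups == "lean") & (sessions == "T0")])
        if len(ob_ch) >= 2 and len(ln_ch) >= 2:
            t, df = two_sample_t_grid(ob_ch, ln_ch)
            out["interaction"] = ContrastResult(
                t, "interaction_change_obese_vs_lean", df)
    return out


def cluster_threshold(stat_grid: np.ndarray, df: int, voxel_p: float = 0.001,
                      connectivity: int = 6) -> list[Cluster]:
    """Connected components of voxels with t above the one-sided threshold.

    Clusters are returned sorted by extent, largest first.  Negate the
    grid to test the opposite direction.
    """
    stat_grid = np.asarray(stat_grid, dtype=float)
    if not np.all(np.isfinite(stat_grid)):
        raise ValueError("stat grid contains non-finite values")
    t_crit = stats.t.isf(voxel_p, df)
    supra = stat_grid > t_crit
    labels, n = ndimage.label(supra, structure=_connectivity_structure(connectivity))
    clusters = []
    for lab in range(1, n + 1):
        mask = labels == lab
        vals = np.where(mask, stat_grid, -np.inf)
        peak = np.unravel_index(np.argmax(vals), stat_grid.shape)
        clusters.append(Cluster(peak_index=tuple(int(i) for i in peak),
                                peak_value=float(stat_grid[peak]),
                                extent=int(mask.sum()), mask=mask))
    clusters.sort(key=lambda c: c.extent, reverse=True)
    return clusters


def permutation_null_extents(zmaps: np.ndarray, groups: np.ndarray,
                             n_perm: int = 1000, voxel_p: float = 0.001,
                             connectivity: int = 6,
                             rng: np.random.Generator | int | None = 0
                             ) -> np.ndarray:
    """Null distribution of the maximum cluster extent under label exchange.

    For each permutation of the group labels the two-sample t grid is
    recomputed and the largest supra-threshold extent over *both*
    one-sided directions is recorded, giving a family null valid for the
    pair of directional contrasts.
    """
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(rng)
    zmaps = np.asarray(zmaps, dtype=float)
    groups = np.asarray(groups)
    flat = zmaps.reshape(zmaps.shape[0], -1)
    shape = zmaps.shape[1:]
    is_a = groups == groups[0]
    na = int(is_a.sum())
    structure = _connectivity_structure(connectivity)
    extents = np.empty(n_perm, dtype=int)
    n = len(groups)
    for b in range(n_perm):
        perm = rng.permutation(n)
        sel = np.zeros(n, dtype=bool)
        sel[perm[:na]] = True
        t, df = two_sample_t_grid(flat[sel], flat[~sel])
        t_crit = stats.t.isf(voxel_p, df)
        supra = (np.abs(t) > t_crit).reshape(shape)
        if not supra.any():
            extents[b] = 0
            continue
        # label positive and negative excursions separately
        best = 0
        tgrid = t.reshape(shape)
        for sgn in (1.0, -1.0):
            part = (sgn * tgrid > t_crit)
            if part.any():
                labels, nlab = ndimage.label(part, structure=structure)
                if nlab:
                    best = max(best, int(np.bincount(labels.ravel())[1:].max()))
        extents[b] = best
    return extents


def cluster_fdr(clusters: list[Cluster], null_extents: np.ndarray,
                q: float = 0.05) -> list[Cluster]:
    """Permutation cluster p-values with Benjamini-Hochberg correction.

    p = (1 + #{null maxima >= extent}) / (B + 1); the +1 smoothing keeps
    p-values valid and strictly positive.
    """
    null_extents = np.asarray(null_extents)
    if null_extents.size == 0:
        raise ValueError("no permutation null extents supplied")
    if not clusters:
        return []
    B = null_extents.size
    for c in clusters:
        c.p_value = float((1 + (null_extents >= c.extent).sum()) / (B + 1))
    pvals = [c.p_value for c in clusters]
    _, qvals, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    for c, qv in zip(clusters, qvals):
        c.q_value = float(qv)
    return clusters


def select_obesity_sensitive_rois(stat_grid: np.ndarray, df: int,
                                  null_extents: np.ndarray,
                                  voxel_p: float = 0.001, q: float = 0.05,
                                  connectivity: int = 6) -> list[RoiMask]:
    """ROIs from clusters surviving cluster-level FDR, in both directions.

    ``stat_grid`` is the baseline obese-vs-lean t map; positive-sign ROIs
    are hyper-connected in the obese group, negative-sign hypo-connected.
    """
    rois = []
    for sign, grid in (("positive", stat_grid), ("negative", -stat_grid)):
        clusters = cluster_threshold(grid, df, voxel_p, connectivity)
        for c in cluster_fdr(clusters, null_extents, q):
            if c.q_value is not None and c.q_value < q:
                rois.append(RoiMask(mask=c.mask, sign=sign, cluster=c))
    return rois


def select_interaction_roi(stat_grid: np.ndarray, df: int,
                           voxel_p: float = 0.001, min_extent: int = 50,
                           connectivity: int = 6) -> RoiMask | None:
    """Largest interaction cluster at an uncorrected p with an extent gate.

    Used to define the change-specific ROI for the hormone analysis;
    returns ``None`` when no cluster reaches ``min_extent``.
    """
    clusters = cluster_threshold(stat_grid, df, voxel_p, connectivity)
    clusters = [c for c in clusters if c.extent >= min_extent]
    if not clusters:
        return None
    return RoiMask(mask=clusters[0].mask, sign="positive", cluster=clusters[0])
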