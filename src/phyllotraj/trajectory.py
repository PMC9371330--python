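"""Community trajectory analysis in ordination space.

A community sampled repeatedly over a season traces a path through
ordination space. Succession shows up as long, directional, rarely-reversing
paths; host-group differences show up as diverging mean paths. This module
builds per-subject trajectories from an ordination, computes their geometry
(path length, net displacement, directionality, turning angles, reversals),
compares paths with a symmetrized mean point-to-segment distance, tests group
differences in length and direction by one-way ANOVA with Tukey HSD, and
scores every OTU's influence on the mean group trajectories by a
leave-one-OTU-out recomputation of the whole ordination pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import orthogonal_procrustes
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .ordination import Ordination, pcoa
from .table import DistanceMatrix, OtuTable, TableError, bray_curtis, css_normalize, hellinger_transform

__all__ = [
    "TrajectorySet",
    "TrajectoryMetrics",
    "InfluenceResult",
    "build_trajectories",
    "trajectory_metrics",
    "mean_trajectory",
    "trajectory_distance",
    "trajectory_group_tests",
    "otu_removal_influence",
]


@dataclass
class TrajectorySet:
    """Per-subject time-ordered coordinate paths sharing one space."""

    paths: dict[str, np.ndarray]          # subject -> (T_s x k) coordinates
    timepoints: dict[str, list]           # subject -> ordered timepoint labels
    groups: pd.Series                     # subject -> grouping label
    n_axes: int
    gaps: list[tuple[str, object]] | None = None  # (subject, missing timepoint)

    @property
    def subjects(self) -> list[str]:
        return list(self.paths)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for s, x in self.paths.items():
            for t, row in zip(self.timepoints[s], x):
                rows.append({"subject": s, "timepoint": t,
                             **{f"axis{i + 1}": v for i, v in enumerate(row)}})
        return pd.DataFrame(rows)


def build_trajectories(
    ordination: Ordination,
    meta: pd.DataFrame,
    subject: str = "genotype",
    time: str = "timepoint",
    group: str = "subpopulation",
) -> TrajectorySet:
    """Assemble per-subject time-ordered paths from ordination coordinates.

    Subjects with fewer than two timepoints are dropped with a warning;
    duplicate subject x timepoint combinations are an error. A missing
    middle timepoint is bridged by a direct segment and recorded in ``gaps``.
    """
    shared = [i for i in ordination.ids if i in meta.index]
    if not shared:
        raise TableError("metadata shares no sample ids with the ordination")
    meta = meta.loc[shared]
    ordination = Ordination(ordination.coordinates.loc[shared],
                            ordination.method)
    coords = ordination.coordinates.to_numpy()
    k = coords.shape[1]
    paths, times, glabels = {}, {}, {}
    gaps: list[tuple[str, object]] = []
    all_times = sorted(meta[time].unique())
    dropped = []
    for subj, idx in meta.groupby(subject, sort=True).groups.items():
        sub = meta.loc[idx]
        if sub[time].duplicated().any():
            raise TableError(f"duplicate timepoints for subject {subj!r}")
        if len(sub) < 2:
            dropped.append(subj)
            continue
        sub = sub.sort_values(time)
        pos = [ordination.ids.index(i) for i in sub.index]
        paths[str(subj)] = coords[pos]
        times[str(subj)] = sub[time].tolist()
        missing = [t for t in all_times
                   if sub[time].min() < t < sub[time].max()
                   and t not in set(sub[time])]
        gaps.extend((str(subj), t) for t in missing)
        glabels[str(subj)] = sub[group].iloc[0]
    if dropped:
        warnings.warn(f"dropping subjects with <2 timepoints: {dropped}")
    if not paths:
        raise TableError("no subject has two or more timepoints")
    return TrajectorySet(paths, times, pd.Series(glabels, name=group), k, gaps)


@dataclass
class TrajectoryMetrics:
    """Per-subject trajectory geometry."""

    table: pd.DataFrame  # length, net_displacement, directionality,
    #                      direction_angle (deg, axes 1-2), n_reversals
    turning_angles: dict[str, np.ndarray]  # per-step angles, degrees
    groups: pd.Series


def _segments(x: np.ndarray) -> np.ndarray:
    return np.diff(x, axis=0)


def trajectory_metrics(ts: TrajectorySet) -> TrajectoryMetrics:
    """Path length, net displacement, directionality, angles, reversals.

    A step is a reversal iff its segment vector projects negatively on the
    subject's net-displacement vector. The direction angle is the planar
    angle of the net displacement in the first two axes; it is undefined
    (NaN) for zero net displacement.
    """
    rows, angles = [], {}
    for s, x in ts.paths.items():
        seg = _segments(x)
        seglen = np.linalg.norm(seg, axis=1)
        length = float(seglen.sum())
        net = x[-1] - x[0]
        netlen = float(np.linalg.norm(net))
        directionality = netlen / length if length > 0 else np.nan
        if netlen > 0:
            reversals = int((seg @ net < 0).sum())
            if ts.n_axes >= 2:
                direction = float(np.degrees(np.arctan2(net[1], net[0])))
            else:
                direction = 0.0 if net[0] >= 0 else 180.0
        else:
            reversals = int(np.ceil(len(seg) / 2)) if length > 0 else 0
            direction = np.nan
        # there-and-back paths: count alternating direction flips directly
        if netlen == 0 and length > 0:
            flips = 0
            for i in range(1, len(seg)):
                if float(seg[i] @ seg[i - 1]) < 0:
                    flips += 1
            reversals = flips
        turn = []
        for i in range(1, len(seg)):
            a, b = seg[i - 1], seg[i]
            na, nb = np.linalg.norm(a), np.linalg.norm(b)
            if na == 0 or nb == 0:
                turn.append(np.nan)
            else:
                c = np.clip(float(a @ b) / (na * nb), -1.0, 1.0)
                turn.append(float(np.degrees(np.arccos(c))))
        angles[s] = np.array(turn)
        rows.append({"subject": s, "length": length,
                     "net_displacement": netlen,
                     "directionality": directionality,
                     "direction_angle": direction,
                     "n_reversals": reversals})
    tab = pd.DataFrame(rows).set_index("subject")
    return TrajectoryMetrics(tab, angles, ts.groups)


def mean_trajectory(ts: TrajectorySet, grouping: pd.Series | None = None) -> TrajectorySet:
    """Per-timepoint centroid paths for each group."""
    grouping = ts.groups if grouping is None else grouping
    out_paths, out_times, out_groups = {}, {}, {}
    for grp in sorted(grouping.unique(), key=str):
        members = [s for s in ts.subjects if grouping[s] == grp]
        times = sorted({t for s in members for t in ts.timepoints[s]})
        centroids = []
        for t in times:
            pts = [ts.paths[s][ts.timepoints[s].index(t)]
                   for s in members if t in ts.timepoints[s]]
            if not pts:
                raise TableError(f"empty group x timepoint cell: ({grp!r}, {t!r})")
            centroids.append(np.mean(pts, axis=0))
        out_paths[str(grp)] = np.array(centroids)
        out_times[str(grp)] = times
        out_groups[str(grp)] = grp
    return TrajectorySet(out_paths, out_times, pd.Series(out_groups), ts.n_axes)


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return float(np.linalg.norm(p - a))
    t = np.clip(float((p - a) @ ab) / denom, 0.0, 1.0)
    return float(np.linalg.norm(p - (a + t * ab)))


def _directed_mean_dist(a: np.ndarray, b: np.ndarray) -> float:
    if len(b) == 1:
        return float(np.mean(np.linalg.norm(a - b[0], axis=1)))
    vals = []
    for p in a:
        vals.append(min(_point_segment_distance(p, b[i], b[i + 1])
                        for i in range(len(b) - 1)))
    return float(np.mean(vals))


def trajectory_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetrized mean point-to-path distance between two paths.

    For each vertex of one path the distance to the nearest continuous
    segment of the other is taken; the two directed means are averaged.
    Single-point paths act as degenerate segments.
    """
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    if a.shape[1] != b.shape[1]:
        raise TableError("paths live in different spaces")
    return 0.5 * (_directed_mean_dist(a, b) + _directed_mean_dist(b, a))


@dataclass
class GroupTestResult:
    anova: pd.DataFrame            # rows: length, direction; df, F, p
    tukey: dict[str, pd.DataFrame]
    excluded_groups: list[str]


def trajectory_group_tests(metrics: TrajectoryMetrics,
                           grouping: pd.Series | None = None) -> GroupTestResult:
    """One-way ANOVA (+ Tukey HSD) on path length and on direction angle.

    Direction is measured as the angle between each subject's net
    displacement (first two axes) and the grand-mean displacement direction,
    folded to [0, 180] degrees, so the test asks whether groups deviate from
    the common successional direction by different amounts.
    """
    grouping = metrics.groups if grouping is None else grouping
    tab = metrics.table.join(grouping.rename("group"))
    sizes = tab.groupby("group").size()
    excluded = sizes.index[sizes < 2].tolist()
    if excluded:
        warnings.warn(f"excluding groups with <2 subjects: {excluded}")
        tab = tab[~tab["group"].isin(excluded)]
    if tab["group"].nunique() < 2:
        raise TableError("need >= 2 groups with >= 2 subjects")

    # fold per-subject direction onto the grand-mean direction
    ang = np.radians(tab["direction_angle"].to_numpy(dtype=float))
    ok = ~np.isnan(ang)
    mean_dir = np.arctan2(np.nanmean(np.sin(ang)), np.nanmean(np.cos(ang)))
    rel = np.degrees(np.abs(np.angle(np.exp(1j * (ang - mean_dir)))))
    tab = tab.assign(direction_rel=rel)

    rows, tukey = [], {}
    for name, col in (("length", "length"), ("direction", "direction_rel")):
        sub = tab.dropna(subset=[col])
        groups = [g[col].to_numpy() for _, g in sub.groupby("group")]
        if np.ptp(np.concatenate(groups)) == 0:
            f, p = 0.0, 1.0
        else:
            within = sum(((g_ - g_.mean()) ** 2).sum() for g_ in groups)
            if within <= 1e-12 * np.ptp(np.concatenate(groups)) ** 2:
                f, p = np.inf, 0.0  # perfectly separated groups
            else:
                f, p = stats.f_oneway(*groups)
                if np.isnan(f):
                    f, p = 0.0, 1.0
        rows.append({"response": name, "df": sub["group"].nunique() - 1,
                     "F": float(f), "p": float(p)})
        try:
            th = pairwise_tukeyhsd(sub[col].to_numpy(), sub["group"].to_numpy())
            tukey[name] = pd.DataFrame(th.summary().data[1:],
                                       columns=th.summary().data[0])
        except Exception:  # zero within-group variance etc.
            tukey[name] = pd.DataFrame()
    return GroupTestResult(pd.DataFrame(rows), tukey, excluded)


# ---------------------------------------------------------------------------
# leave-one-OTU-out influence
# ---------------------------------------------------------------------------

@dataclass
class InfluenceResult:
    """Per-OTU trajectory-influence scores from leave-one-out recomputation."""

    table: pd.DataFrame  # influence, z, significant
    z_cut: float
    protocol: str

    @property
    def significant_otus(self) -> list[str]:
        return self.table.index[self.table["significant"]].tolist()


def _pipeline_coords(table: OtuTable, k: int) -> tuple[pd.DataFrame, DistanceMatrix]:
    norm = css_normalize(table)
    hel = hellinger_transform(norm)
    dist = bray_curtis(hel)
    ordn = pcoa(dist, k)
    return ordn.coordinates, dist


def _mean_paths(coords: pd.DataFrame, meta: pd.DataFrame, subject, time, group):
    ordn = Ordination(coords, "pcoa")
    ts = build_trajectories(ordn, meta.loc[coords.index], subject, time, group)
    return mean_trajectory(ts)


def otu_removal_influence(
    table: OtuTable,
    subject: str = "genotype",
    time: str = "timepoint",
    group: str = "subpopulation",
    n_axes: int = 2,
    z_cut: float = 2.0,
) -> InfluenceResult:
    """Score each OTU by how much its removal shifts mean group trajectories.

    Protocol (fixed): CSS -> Hellinger -> Bray-Curtis -> PCoA(n_axes) ->
    per-group mean trajectories. For each OTU the pipeline is recomputed
    without it, the recomputed coordinates are aligned to the originals by
    orthogonal Procrustes (PCoA axes are defined only up to rotation and
    reflection), and the influence is the mean over groups of
    :func:`trajectory_distance` between original and recomputed mean paths.
    Significance is the z-score of each influence against the mean/SD of all
    OTUs' influences, flagged at ``z > z_cut``.
    """
    table = table.real_samples()
    # one sample per subject x timepoint: drop paired infected replicates
    key = table.sample_meta[[subject, time]].astype(str).agg("|".join, axis=1)
    table = table.subset_samples(table.sample_meta.index[~key.duplicated()])
    coords0, _ = _pipeline_coords(table, n_axes)
    meta = table.sample_meta
    base = _mean_paths(coords0, meta, subject, time, group)
    x0 = coords0.to_numpy()

    influences = {}
    zero_otus = table.counts.columns[(table.counts == 0).all(axis=0)]
    dropped_samples: dict[str, list[str]] = {}
    for otu in table.otu_ids:
        if otu in set(zero_otus):
            influences[otu] = 0.0
            continue
        sub = table.counts.drop(columns=[otu])
        nonzero = sub.sum(axis=1) > 0
        if not nonzero.all():
            dropped_samples[otu] = sub.index[~nonzero].tolist()
        reduced = OtuTable(sub.loc[nonzero], meta.loc[sub.index[nonzero]],
                           table.otu_meta)
        coords, _ = _pipeline_coords(reduced, n_axes)
        shared = coords.index.intersection(coords0.index)
        a = coords.loc[shared].to_numpy()
        b = coords0.loc[shared].to_numpy()
        r, _ = orthogonal_procrustes(a - a.mean(0), b - b.mean(0))
        aligned = pd.DataFrame((coords.to_numpy() - a.mean(0)) @ r + b.mean(0),
                               index=coords.index, columns=coords0.columns)
        paths = _mean_paths(aligned, meta, subject, time, group)
        vals = [trajectory_distance(base.paths[gname], paths.paths[gname])
                for gname in base.paths if gname in paths.paths]
        influences[otu] = float(np.mean(vals))

    ser = pd.Series(influences, name="influence").loc[table.otu_ids]
    mu, sd = ser.mean(), ser.std(ddof=0)
    z = (ser - mu) / sd if sd > 0 else ser * 0.0
    out = pd.DataFrame({"influence": ser, "z": z, "significant": z > z_cut})
    return InfluenceResult(out, z_cut,
                           protocol=f"css->hellinger->braycurtis->pcoa{n_axes}->mean_trajectories")
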