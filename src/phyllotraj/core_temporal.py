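"""Core-taxon selection, time-explainability models, and indicator species.

The "core" microbiome is picked by occupancy ranking: OTUs are ordered by
the fraction of samples they occupy (ties broken by mean relative abundance)
and included while each added OTU still contributes at least a fixed
fraction (default 2%) of the full between-group Bray-Curtis dissimilarity.

Time explainability (TE) asks, per OTU, how much of its abundance at later
timepoints is explained by the whole community's composition one step
earlier. It is the variance share of a random effect whose covariance is a
"community kinship" built from the previous timepoint's standardized
composition — an order-1 sequential linear mixed model fitted by REML, with
a likelihood-ratio test against TE = 0 on the boundary-corrected
(1/2 chi2_0 + 1/2 chi2_1) reference.

Indicator species analysis (IndVal) combines group specificity A with
within-group occupancy B as sqrt(A*B), tested by permuting group labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .genetics import _reml_loglik, spectral_reml
from .table import OtuTable, TableError

__all__ = [
    "CoreSet",
    "TimeExplainability",
    "IndValResult",
    "rank_occupancy_abundance",
    "select_core",
    "core_intersection",
    "time_explainability",
    "indval",
]


def rank_occupancy_abundance(table: OtuTable) -> pd.DataFrame:
    """Rank OTUs by occupancy, ties broken by mean relative abundance, then id."""
    present = table.counts > 0
    occupancy = present.mean(axis=0)
    rel = table.relative_abundance().mean(axis=0)
    df = pd.DataFrame({"occupancy": occupancy, "mean_rel_abundance": rel})
    df = df.sort_values(["occupancy", "mean_rel_abundance"],
                        ascending=[False, False], kind="mergesort")
    # deterministic final tie-break on OTU id
    df["_id"] = df.index
    df = df.sort_values(["occupancy", "mean_rel_abundance", "_id"],
                        ascending=[False, False, True], kind="mergesort")
    return df.drop(columns="_id").rename_axis("otu_id")


@dataclass
class CoreSet:
    """Occupancy-ordered core OTUs with per-rank beta-diversity contributions."""

    otu_ids: list[str]
    contributions: pd.Series  # per-rank marginal contribution (full ranking)
    factor: str
    stopping_rank: int

    def __len__(self) -> int:
        return len(self.otu_ids)

    def to_frame(self, table: OtuTable | None = None) -> pd.DataFrame:
        df = pd.DataFrame(index=pd.Index(self.otu_ids, name="otu_id"))
        df["rank"] = np.arange(1, len(df) + 1)
        df["contribution"] = self.contributions.loc[self.otu_ids].to_numpy()
        if table is not None:
            ranking = rank_occupancy_abundance(table)
            df = df.join(ranking)
            if table.otu_meta is not None:
                df = df.join(table.otu_meta)
        return df


def _mean_between_bc(rel: np.ndarray, level_idx: list[np.ndarray]) -> float:
    """Mean cumulative Bray-Curtis over all cross-level sample pairs.

    Rows are relative abundances on the *full* table, so sum(x + y) = 2 for
    every pair and the subset statistic 0.5 * sum_topk |x - y| accumulates
    monotonically toward the full Bray-Curtis as columns are added.
    """
    total, count = 0.0, 0
    for i in range(len(level_idx)):
        for j in range(i + 1, len(level_idx)):
            a, b = rel[level_idx[i]], rel[level_idx[j]]
            d = 0.5 * cdist(a, b, metric="cityblock")
            total += d.sum()
            count += d.size
    return total / count if count else 0.0


def select_core(table: OtuTable, factor: str, increment: float = 0.02) -> CoreSet:
    """Walk the occupancy ranking, keeping OTUs that add between-group signal.

    At rank k, the mean between-level Bray-Curtis of the full-table relative
    abundances restricted to the top-k OTU columns is computed; the marginal
    contribution of rank k is (BC_k - BC_{k-1}) / BC_full. The core runs
    through the last rank whose contribution is at least ``increment``.
    """
    levels = table.sample_meta[factor]
    if levels.nunique() < 2:
        raise TableError(f"factor {factor!r} must have >= 2 levels")
    ranking = rank_occupancy_abundance(table)
    order = ranking.index.tolist()
    rel_full = table.relative_abundance().to_numpy()
    cols = {o: i for i, o in enumerate(table.otu_ids)}
    idx_order = np.array([cols[o] for o in order])
    level_idx = [np.where((levels == u).to_numpy())[0] for u in levels.unique()]

    bc_full = _mean_between_bc(rel_full, level_idx)
    if bc_full == 0:
        raise TableError("no between-level dissimilarity; core undefined")

    contribs = np.zeros(len(order))
    prev = 0.0
    for k in range(1, len(order) + 1):
        relk = rel_full[:, idx_order[:k]]
        bck = _mean_between_bc(relk, level_idx)
        contribs[k - 1] = (bck - prev) / bc_full
        prev = bck
    ser = pd.Series(contribs, index=order, name="contribution")
    # increment 0 means "every OTU with a strictly positive contribution"
    above = np.nonzero(contribs >= increment if increment > 0
                       else contribs > 0)[0]
    stop = int(above.max()) + 1 if above.size else 0
    return CoreSet(order[:stop], ser, factor, stop)


def core_intersection(a: CoreSet, b: CoreSet) -> CoreSet:
    """Set intersection preserving the first core's order."""
    bset = set(b.otu_ids)
    ids = [o for o in a.otu_ids if o in bset]
    return CoreSet(ids, a.contributions, f"{a.factor}&{b.factor}",
                   stopping_rank=len(ids))


# ---------------------------------------------------------------------------
# time explainability (sequential linear mixed model)
# ---------------------------------------------------------------------------

@dataclass
class TimeExplainability:
    """Per-OTU variance share explained by the previous community state."""

    table: pd.DataFrame  # te, lrt, p, significant (Bonferroni)
    order: int
    skipped: list[str]

    @property
    def significant_otus(self) -> list[str]:
        return self.table.index[self.table["significant"]].tolist()


def time_explainability(
    table: OtuTable,
    subject: str = "genotype",
    time: str = "timepoint",
    order: int = 1,
    alpha: float = 0.05,
    otus: list[str] | None = None,
) -> TimeExplainability:
    """Fit the order-``order`` sequential mixed model for each OTU.

    The response stacks each subject's standardized relative abundance at
    timepoints order+1..T; the random-effect covariance is W W'/q where W
    rows are the per-OTU z-scored community composition at the ``order``
    preceding timepoints (standardization uses only the earlier data, so no
    information leaks backward). Fixed effects are one intercept per
    response timepoint, so the season-wide mean trend does not masquerade as
    contingency. TE = s2_b / (s2_b + s2_e); the LRT against
    s2_b = 0 is referred to 1/2 chi2_0 + 1/2 chi2_1 and Bonferroni-corrected
    over tested OTUs.
    """
    sub_table = table.real_samples()
    meta = sub_table.sample_meta
    # only unreplicated subject x timepoint cells enter (drop infected dupes)
    key = meta[[subject, time]].astype(str).agg("|".join, axis=1)
    first = ~key.duplicated()
    sub_table = sub_table.subset_samples(meta.index[first])
    meta = sub_table.sample_meta
    rel = sub_table.relative_abundance()
    times = sorted(meta[time].unique())
    if len(times) < order + 1:
        raise TableError("need at least order+1 timepoints")

    # subjects observed at all timepoints (consecutive design)
    wide = meta.copy()
    wide["_sid"] = wide.index
    piv = wide.pivot_table(index=subject, columns=time, values="_sid",
                           aggfunc="first")
    piv = piv.dropna()
    subjects = piv.index.tolist()
    if not subjects:
        raise TableError("no subject observed at every timepoint")

    otu_list = otus if otus is not None else sub_table.otu_ids
    # build the stacked design once: rows = subject x later-timepoint
    # per-OTU standardization uses the pooled earlier-timepoint samples only,
    # so temporal trends remain visible to the random effect and nothing
    # leaks backward from the response timepoints
    early_pool = [piv.loc[s, t] for s in subjects for t in times[:-1]]
    pool = rel.loc[early_pool].to_numpy()
    mu, sd = pool.mean(axis=0), pool.std(axis=0)
    sd[sd == 0] = 1.0

    resp_samples, prev_blocks = [], []
    for t_i in range(order, len(times)):
        later = [piv.loc[s, times[t_i]] for s in subjects]
        resp_samples.append(later)
        block = []
        for lag in range(1, order + 1):
            ids = [piv.loc[s, times[t_i - lag]] for s in subjects]
            block.append((rel.loc[ids].to_numpy() - mu) / sd)
        prev_blocks.append(np.hstack(block))
    W = np.vstack(prev_blocks)
    K = W @ W.T / W.shape[1]
    s_eig, u_eig = np.linalg.eigh((K + K.T) / 2.0)

    n_obs = K.shape[0]
    n_sub = len(subjects)
    # per-timepoint fixed intercepts absorb the season-wide mean trend, so
    # the random effect measures cross-subject temporal contingency
    n_blocks = len(resp_samples)
    X = np.zeros((n_obs, n_blocks))
    for b in range(n_blocks):
        X[b * n_sub:(b + 1) * n_sub, b] = 1.0
    xt = u_eig.T @ X

    rows, skipped = [], []
    for otu in otu_list:
        y_parts = []
        absent_early = True
        for t_i, later in enumerate(resp_samples):
            y_parts.append(rel.loc[later, otu].to_numpy())
        # skip OTUs absent at every early timepoint (K carries no signal)
        early_ids = [piv.loc[s, t] for s in subjects for t in times[:-1]]
        if (rel.loc[early_ids, otu] > 0).any():
            absent_early = False
        y = np.concatenate(y_parts)
        if absent_early or np.ptp(y) == 0:
            skipped.append(otu)
            continue
        y = (y - y.mean()) / y.std()
        est = spectral_reml(y, K)
        yt = u_eig.T @ y
        ll_null = _reml_loglik(0.0, s_eig, yt, xt)
        lrt = max(2.0 * (est.loglik - ll_null), 0.0)
        p = 0.5 * stats.chi2.sf(lrt, df=1) if lrt > 0 else 1.0
        rows.append({"otu_id": otu, "te": est.h2, "lrt": lrt, "p": p})
    if not rows:
        raise TableError("no OTU could be tested")
    df = pd.DataFrame(rows).set_index("otu_id")
    df["significant"] = df["p"] < alpha / len(df)
    return TimeExplainability(df, order, skipped)


# ---------------------------------------------------------------------------
# indicator species analysis
# ---------------------------------------------------------------------------

@dataclass
class IndValResult:
    table: pd.DataFrame  # group, A, B, indval, z, p
    n_perm: int
    seed: int

    @property
    def significant_otus(self) -> list[str]:
        return self.table.index[self.table["p"] < 0.05].tolist()


def _indval_components(rel: np.ndarray, present: np.ndarray,
                       group_idx: list[np.ndarray]):
    """Per-OTU per-group specificity A, fidelity B, and IndVal."""
    g = len(group_idx)
    means = np.stack([rel[idx].mean(axis=0) for idx in group_idx])  # g x k
    denom = means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(denom > 0, means / denom, 0.0)
    B = np.stack([present[idx].mean(axis=0) for idx in group_idx])
    return A, B, np.sqrt(A * B)


def indval(
    table: OtuTable, groups: pd.Series | str, n_perm: int = 999, seed: int = 0
) -> IndValResult:
    """Dufrene-Legendre indicator values with a permutation test.

    For each OTU the best group's IndVal = sqrt(A * B) is compared with its
    distribution under group-label permutation; z is the permutation z-score
    and p = (b + 1) / (n_perm + 1). All-zero OTUs are skipped.
    """
    if isinstance(groups, str):
        groups = table.sample_meta[groups]
    groups = groups.loc[table.counts.index]
    labels = groups.to_numpy()
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise TableError("need >= 2 groups")
    rel = table.relative_abundance().to_numpy()
    present = table.counts.to_numpy() > 0
    nonzero = present.any(axis=0)
    otus = np.array(table.otu_ids)[nonzero]
    rel = rel[:, nonzero]
    present = present[:, nonzero]

    def group_indices(lab):
        return [np.where(lab == u)[0] for u in uniq]

    A, B, iv = _indval_components(rel, present, group_indices(labels))
    best_g = iv.argmax(axis=0)
    obs = iv.max(axis=0)

    rng = np.random.default_rng(seed)
    perm_stats = np.empty((n_perm, obs.size))
    for b in range(n_perm):
        lp = labels[rng.permutation(labels.size)]
        _, _, ivp = _indval_components(rel, present, group_indices(lp))
        perm_stats[b] = ivp.max(axis=0)
    exceed = (perm_stats >= obs[None, :] - 1e-12).sum(axis=0)
    p = (exceed + 1) / (n_perm + 1)
    mu = perm_stats.mean(axis=0)
    sd = perm_stats.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (obs - mu) / sd, 0.0)

    df = pd.DataFrame({
        "group": uniq[best_g],
        "A": A[best_g, np.arange(obs.size)],
        "B": B[best_g, np.arange(obs.size)],
        "indval": obs, "z": z, "p": p,
    }, index=pd.Index(otus, name="otu_id"))
    return IndValResult(df, n_perm, seed)
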