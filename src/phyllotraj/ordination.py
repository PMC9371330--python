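"""Ordination and permutational inference on distance matrices.

Implements classical PCoA (eigendecomposition of the Gower-centered matrix),
non-metric multidimensional scaling minimizing Kruskal stress-1 by
alternating monotone regression and Guttman (majorization) updates,
sequential-SS PERMANOVA in the McArdle-Anderson hat-matrix formulation with
optional restricted (within-strata) permutations, a homogeneity-of-dispersion
test (distances to group centroids in principal-coordinate space, keeping the
imaginary contribution of negative eigenvalues), and the Mantel test.

Permutation p-values are always reported as (b + 1) / (n_perm + 1) where b is
the number of permutation statistics at least as extreme as the observed one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression

from .table import DistanceMatrix, TableError

__all__ = [
    "Ordination",
    "PermanovaResult",
    "MantelResult",
    "pcoa",
    "nmds",
    "shepard",
    "permanova",
    "dispersion_homogeneity",
    "mantel",
]


@dataclass
class Ordination:
    """Low-dimensional sample coordinates with fit diagnostics."""

    coordinates: pd.DataFrame  # samples x axes
    method: str  # "pcoa" | "nmds"
    stress: float | None = None
    eigenvalues: np.ndarray | None = None
    variance_explained: np.ndarray | None = None
    n_restarts: int | None = None
    seed: int | None = None
    converged: bool = True

    @property
    def ids(self) -> list[str]:
        return self.coordinates.index.tolist()


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def pcoa(dist: DistanceMatrix, k: int = 2) -> Ordination:
    """Classical metric scaling of a distance matrix.

    Eigendecomposes the Gower-centered matrix -1/2 J D^2 J; axes are scaled
    eigenvectors for positive eigenvalues only (negative eigenvalues are
    dropped and reported through ``eigenvalues``), ordered by nonincreasing
    eigenvalue. Variance explained is relative to the positive spectrum.
    """
    g = _gower_center(dist.values)
    w, v = np.linalg.eigh(g)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    pos = w > max(w.max(), 0) * 1e-10
    n_pos = int(pos.sum())
    if k > n_pos:
        warnings.warn(f"only {n_pos} positive eigenvalues; truncating k={k}")
        k = n_pos
    coords = v[:, :k] * np.sqrt(w[:k])
    coords -= coords.mean(axis=0)
    var_exp = w[:n_pos] / w[:n_pos].sum() if n_pos else np.array([])
    df = pd.DataFrame(coords, index=dist.ids,
                      columns=[f"PCo{i + 1}" for i in range(k)])
    return Ordination(df, "pcoa", eigenvalues=w, variance_explained=var_exp)


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

def _tri(d: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(d.shape[0], 1)
    return d[iu]


def _config_dist(x: np.ndarray) -> np.ndarray:
    diff = x[:, None, :] - x[None, :, :]
    return _tri(np.sqrt((diff ** 2).sum(-1)))


def _stress1(d: np.ndarray, dhat: np.ndarray) -> float:
    denom = float((d ** 2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d - dhat) ** 2).sum() / denom))


def _monotone_fit(delta: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Primary (weak, tie-averaged) monotone regression of d onto delta."""
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    return iso.fit_transform(delta, d)


def _nmds_single(delta, n, k, x0, max_iter, tol):
    iu = np.triu_indices(n, 1)
    x = x0.copy()
    best_x, best_stress = x.copy(), np.inf
    prev = np.inf
    for _ in range(max_iter):
        d = _config_dist(x)
        if d.max() <= 1e-12:          # collapsed configuration: dead end
            break
        dhat = _monotone_fit(delta, d)
        s = _stress1(d, dhat)
        if s < best_stress - 1e-15:
            best_stress, best_x = s, x.copy()
        if s < 1e-12 or abs(prev - s) < tol * max(prev, 1e-12):
            break
        prev = s
        # rescale disparities to the configuration (Kruskal normalization);
        # without it the Guttman iteration shrinks the layout toward zero
        dh2 = (dhat ** 2).sum()
        if dh2 > 0:
            dhat = dhat * np.sqrt((d ** 2).sum() / dh2)
        # Guttman transform with disparities dhat
        ratio = np.zeros_like(d)
        nz = d > 1e-12
        ratio[nz] = dhat[nz] / d[nz]
        b = np.zeros((n, n))
        b[iu] = -ratio
        b = b + b.T
        np.fill_diagonal(b, -b.sum(axis=1))
        x = b @ x / n
    return best_x, best_stress


def nmds(
    dist: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
) -> Ordination:
    """Non-metric MDS minimizing Kruskal stress-1.

    Runs ``n_restarts`` random starts plus one PCoA-seeded start and keeps
    the lowest-stress configuration; each run alternates weak monotone
    regression of configuration distances on the dissimilarity ranks with a
    Guttman majorization update. The reported stress is recomputed from the
    returned (centered) coordinates with one final monotone regression, so
    ``shepard`` reproduces it exactly.
    """
    n = dist.n
    if n < k + 1:
        raise TableError(f"need at least {k + 1} samples for {k}-axis NMDS")
    delta = _tri(dist.values)
    rng = np.random.default_rng(seed)
    starts = [pcoa(dist, min(k, n - 1)).coordinates.to_numpy()]
    if starts[0].shape[1] < k:  # pad degenerate PCoA starts
        pad = np.zeros((n, k - starts[0].shape[1]))
        starts[0] = np.hstack([starts[0], pad])
    scale = max(np.median(delta), 1e-6)
    for _ in range(n_restarts):
        starts.append(rng.normal(0.0, scale, size=(n, k)))
    best_x, best_s = None, np.inf
    for x0 in starts:
        x, s = _nmds_single(delta, n, k, np.asarray(x0, float), max_iter, tol)
        if s < best_s:
            best_x, best_s = x, s
    best_x = best_x - best_x.mean(axis=0)
    # canonical orientation: principal axes of the configuration
    _, _, vt = np.linalg.svd(best_x, full_matrices=False)
    best_x = best_x @ vt.T
    d = _config_dist(best_x)
    if d.max() <= 1e-12 and delta.max() > 0:
        final_stress = np.inf  # every start collapsed; flag, don't raise
    else:
        final_stress = _stress1(d, _monotone_fit(delta, d))
    converged = final_stress < 0.3  # flag, never an exception
    df = pd.DataFrame(best_x, index=dist.ids,
                      columns=[f"NMDS{i + 1}" for i in range(k)])
    return Ordination(df, "nmds", stress=final_stress, n_restarts=n_restarts,
                      seed=seed, converged=converged)


def shepard(dist: DistanceMatrix, ordination: Ordination) -> pd.DataFrame:
    """Paired (dissimilarity, ordination distance, monotone fit) triples.

    The stress recomputed from these triples equals the ordination's
    reported stress.
    """
    delta = _tri(dist.values)
    d = _config_dist(ordination.coordinates.to_numpy())
    dhat = _monotone_fit(delta, d)
    out = pd.DataFrame({"dissimilarity": delta, "distance": d, "fitted": dhat})
    return out.sort_values("dissimilarity").reset_index(drop=True)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    """Sequential (Type-I) PERMANOVA table."""

    table: pd.DataFrame  # term, Df, SumOfSqs, R2, F, p
    n_perm: int
    strata: str | None = None
    seed: int | None = None

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _encode_component(values: pd.Series) -> np.ndarray:
    if pd.api.types.is_numeric_dtype(values) and not isinstance(
        values.dtype, pd.CategoricalDtype
    ):
        v = values.to_numpy(dtype=float)[:, None]
        return v - v.mean(axis=0)
    dummies = pd.get_dummies(values.astype(str), drop_first=True).to_numpy(float)
    return dummies - dummies.mean(axis=0)


def _term_design(meta: pd.DataFrame, term: str) -> np.ndarray:
    parts = [p.strip() for p in term.split(":")]
    mats = []
    for p in parts:
        if p not in meta.columns:
            raise TableError(f"unknown term component {p!r}")
        if meta[p].nunique() <= 1 and not pd.api.types.is_numeric_dtype(meta[p]):
            raise TableError(f"term {p!r} is constant")
        enc = _encode_component(meta[p])
        if enc.shape[1] == 0:
            raise TableError(f"term {p!r} is constant")
        mats.append(enc)
    out = mats[0]
    for m in mats[1:]:
        out = np.einsum("ij,ik->ijk", out, m).reshape(out.shape[0], -1)
    return out


def _hat(m: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(m)
    keep = np.abs(np.diag(r)) > 1e-10 * max(np.abs(np.diag(r)).max(), 1e-300)
    q = q[:, keep]
    return q @ q.T


def _strata_permutation(rng, strata_codes: np.ndarray) -> np.ndarray:
    perm = np.arange(strata_codes.size)
    for s in np.unique(strata_codes):
        idx = np.where(strata_codes == s)[0]
        perm[idx] = idx[rng.permutation(idx.size)]
    return perm


def permanova(
    dist: DistanceMatrix,
    meta: pd.DataFrame,
    terms: list[str],
    n_perm: int = 999,
    strata: str | None = None,
    seed: int = 0,
) -> PermanovaResult:
    """Sequential-SS PERMANOVA via the McArdle-Anderson partition.

    Terms are fitted in the given order on the Gower-centered inner-product
    matrix; each term's sum of squares is tr((H_j - H_{j-1}) G). p-values
    permute sample identities (rows/columns of the distance matrix), freely
    or within ``strata`` blocks, recomputing the full sequential table each
    permutation.
    """
    meta = meta.loc[dist.ids]
    n = dist.n
    g = _gower_center(dist.values)
    designs = [_term_design(meta, t) for t in terms]
    dfs, hats = [], []
    m_prev = np.ones((n, 1))
    h_prev = _hat(m_prev)
    rank_prev = 1
    for x in designs:
        m_cur = np.hstack([m_prev, x])
        h_cur = _hat(m_cur)
        rank_cur = int(np.linalg.matrix_rank(m_cur))
        df = rank_cur - rank_prev
        if df == 0:
            raise TableError("term adds no degrees of freedom (collinear or constant)")
        dfs.append(df)
        hats.append((h_cur, h_prev))
        m_prev, h_prev, rank_prev = m_cur, h_cur, rank_cur
    df_resid = n - rank_prev
    if df_resid <= 0:
        raise TableError("no residual degrees of freedom (degenerate grouping)")
    h_full = h_prev
    resid_proj = np.eye(n) - h_full

    diffs = [hj - hjm1 for hj, hjm1 in hats]

    def sequential_stats(g_mat):
        ss = np.array([float((d * g_mat).sum()) for d in diffs])
        ss_res = float((resid_proj * g_mat).sum())
        f = (ss / np.array(dfs)) / (ss_res / df_resid)
        return ss, ss_res, f

    ss_obs, ss_res_obs, f_obs = sequential_stats(g)
    ss_total = float(np.trace(g))

    rng = np.random.default_rng(seed)
    if strata is not None:
        codes = pd.factorize(meta[strata])[0]
        sizes = np.bincount(codes)
        if (sizes < 2).any():
            raise TableError("strata contain singleton blocks; paired test undefined")
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        perm = (_strata_permutation(rng, codes) if strata is not None
                else rng.permutation(n))
        gp = g[np.ix_(perm, perm)]
        _, _, f_p = sequential_stats(gp)
        exceed += f_p >= f_obs - 1e-12
    pvals = (exceed + 1) / (n_perm + 1)

    rows = []
    for t, df, ss, f, p in zip(terms, dfs, ss_obs, f_obs, pvals):
        rows.append((t, df, ss, ss / ss_total, f, p))
    rows.append(("Residual", df_resid, ss_res_obs, ss_res_obs / ss_total,
                 np.nan, np.nan))
    rows.append(("Total", n - 1, ss_total, 1.0, np.nan, np.nan))
    tab = pd.DataFrame(rows, columns=["term", "Df", "SumOfSqs", "R2", "F", "p"])
    return PermanovaResult(tab, n_perm=n_perm, strata=strata, seed=seed)


# ---------------------------------------------------------------------------
# dispersion homogeneity (betadisper-style)
# ---------------------------------------------------------------------------

@dataclass
class DispersionResult:
    dispersions: pd.Series          # per-sample distance to group centroid
    group_means: pd.Series
    f_statistic: float
    p_value: float
    n_perm: int
    excluded_groups: list[str] = field(default_factory=list)


def dispersion_homogeneity(
    dist: DistanceMatrix,
    groups: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> DispersionResult:
    """Permutation test of multivariate homogeneity of group dispersions.

    Samples are embedded by PCoA keeping all axes; squared distance to the
    group centroid subtracts the contribution of negative-eigenvalue
    (imaginary) axes, as in the standard treatment of semimetric distances.
    A one-way F statistic on the centroid distances is compared with its
    permutation distribution under group-label shuffling.
    """
    groups = groups.loc[dist.ids]
    sizes = groups.value_counts()
    excluded = sizes.index[sizes < 2].tolist()
    if excluded:
        warnings.warn(f"excluding singleton groups: {excluded}")
        keep = ~groups.isin(excluded)
        dist = dist.subset(list(np.array(dist.ids)[keep.to_numpy()]))
        groups = groups[keep]
    if groups.nunique() < 2:
        raise TableError("need at least two groups of size >= 2")

    g = _gower_center(dist.values)
    w, v = np.linalg.eigh(g)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    eps = np.abs(w).max() * 1e-10
    pos, neg = w > eps, w < -eps
    x_pos = v[:, pos] * np.sqrt(w[pos])
    x_neg = v[:, neg] * np.sqrt(-w[neg])

    def centroid_dists(labels: np.ndarray) -> np.ndarray:
        out = np.zeros(len(labels))
        for lab in np.unique(labels):
            m = labels == lab
            cp = x_pos[m].mean(axis=0)
            cn = x_neg[m].mean(axis=0) if x_neg.size else np.zeros(0)
            d2 = ((x_pos[m] - cp) ** 2).sum(axis=1)
            if x_neg.size:
                d2 = d2 - ((x_neg[m] - cn) ** 2).sum(axis=1)
            out[m] = np.sqrt(np.clip(d2, 0.0, None))
        return out

    labels = groups.to_numpy()
    z = centroid_dists(labels)

    def anova_f(y, labels):
        grand = y.mean()
        ss_b = sum(m.sum() * (y[m].mean() - grand) ** 2
                   for m in (labels == u for u in np.unique(labels)))
        ss_w = sum(((y[m] - y[m].mean()) ** 2).sum()
                   for m in (labels == u for u in np.unique(labels)))
        k = len(np.unique(labels))
        df1, df2 = k - 1, len(y) - k
        return (ss_b / df1) / (ss_w / df2) if ss_w > 0 else np.inf

    f_obs = anova_f(z, labels)
    rng = np.random.default_rng(seed)
    # permute group labels over samples; recompute centroid distances + F
    b = 0
    for _ in range(n_perm):
        lp = labels[rng.permutation(len(labels))]
        zp = centroid_dists(lp)
        if anova_f(zp, lp) >= f_obs - 1e-12:
            b += 1
    p = (b + 1) / (n_perm + 1)
    disp = pd.Series(z, index=dist.ids, name="dispersion")
    means = disp.groupby(groups).mean()
    return DispersionResult(disp, means, float(f_obs), float(p), n_perm)


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    p_value: float
    n_perm: int
    seed: int


def mantel(
    d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 999, seed: int = 0
) -> MantelResult:
    """Mantel test: Pearson r between lower triangles, one-sided permutation p.

    The second matrix's rows/columns are permuted jointly; p counts
    permutation correlations >= the observed one.
    """
    if d1.ids != d2.ids:
        if set(d1.ids) != set(d2.ids):
            raise TableError("distance matrices must share sample labels")
        d2 = d2.subset(d1.ids)
    a = _tri(d1.values)
    b = _tri(d2.values)
    if a.std() == 0 or b.std() == 0:
        raise TableError("zero-variance distance triangle; Mantel r undefined")
    r_obs = float(stats.pearsonr(a, b)[0])
    rng = np.random.default_rng(seed)
    n = d1.n
    az = (a - a.mean()) / a.std()
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        bp = _tri(d2.values[np.ix_(perm, perm)])
        r_p = float(np.mean(az * (bp - bp.mean()) / bp.std()))
        if r_p >= r_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return MantelResult(r_obs, p, n_perm, seed)
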