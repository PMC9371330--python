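"""Host-genetic association: genetic distance, kinship, REML heritability,
a single-marker GWAS scan with SVD covariates, and multiple-testing control.

The heritability model is the standard single-random-effect animal model
y = Xb + g + e with g ~ N(0, s2_g K) and e ~ N(0, s2_e I). REML is profiled
over h2 = s2_g / (s2_g + s2_e) using the spectral decomposition of K, which
makes each likelihood evaluation O(n) after one eigendecomposition; the
standard error comes from the observed information at the optimum. The GWAS
is an ordinary least-squares scan (one SNP at a time with fixed covariates),
matching fast univariate association pipelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .table import DistanceMatrix, TableError

__all__ = [
    "GenotypeMatrix",
    "KinshipMatrix",
    "HeritabilityEstimate",
    "GwasResult",
    "load_genotypes",
    "nei_pi_distance",
    "kinship_matrix",
    "pseudo_heritability",
    "svd_covariates",
    "gwas_scan",
    "multiple_testing",
]


@dataclass
class GenotypeMatrix:
    """Biallelic dosages in {0,1,2} (NaN = missing) with SNP coordinates."""

    dosages: pd.DataFrame        # samples x SNPs, float with NaN for missing
    snp_pos: pd.DataFrame        # snp -> chrom, pos

    def __post_init__(self) -> None:
        vals = self.dosages.to_numpy(dtype=float)
        obs = vals[~np.isnan(vals)]
        if not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise TableError("dosages must be 0, 1, 2 or missing")

    @property
    def sample_ids(self) -> list[str]:
        return self.dosages.index.tolist()

    @property
    def snp_ids(self) -> list[str]:
        return self.dosages.columns.tolist()

    def allele_freq(self) -> np.ndarray:
        return np.nanmean(self.dosages.to_numpy(), axis=0) / 2.0

    def filtered(self, maf: float = 0.05, max_missing: float = 0.1) -> "GenotypeMatrix":
        vals = self.dosages.to_numpy(dtype=float)
        p = np.nanmean(vals, axis=0) / 2.0
        m = np.isnan(vals).mean(axis=0)
        keep = (np.minimum(p, 1 - p) >= maf) & (m <= max_missing)
        return GenotypeMatrix(self.dosages.loc[:, keep],
                              self.snp_pos.loc[self.dosages.columns[keep]])


def load_genotypes(path, maf: float = 0.05, max_missing: float = 0.1) -> GenotypeMatrix:
    """Read dosages from TSV (samples x SNPs) or a minimal biallelic VCF.

    Files ending in ``.vcf`` are parsed with cyvcf2 (GT field; ``./.`` is
    missing). The MAF and missingness filters are applied on load.
    """
    if str(path).endswith(".vcf"):
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        ids, chroms, poss, cols = [], [], [], []
        for var in vcf:
            ids.append(var.ID or f"{var.CHROM}_{var.POS}")
            chroms.append(var.CHROM)
            poss.append(var.POS)
            g = np.asarray(var.genotypes, dtype=object)
            dos = np.array([a + b if (a >= 0 and b >= 0) else np.nan
                            for a, b, *_ in var.genotypes], dtype=float)
            cols.append(dos)
        dosages = pd.DataFrame(np.column_stack(cols), index=samples, columns=ids)
        snp_pos = pd.DataFrame({"chrom": chroms, "pos": poss}, index=ids)
    else:
        dosages = pd.read_csv(path, sep="\t", index_col=0).astype(float)
        snp_pos = pd.DataFrame({"chrom": "NA", "pos": range(1, dosages.shape[1] + 1)},
                               index=dosages.columns)
    return GenotypeMatrix(dosages, snp_pos).filtered(maf, max_missing)


def nei_pi_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """Average pairwise allele mismatch probability (Nei's pi).

    For one locus with dosages gi, gj the probability that one random allele
    from each individual differs is (gi (2 - gj) + gj (2 - gi)) / 4; the
    distance is the mean over loci where both individuals are genotyped.
    """
    x = g.dosages.to_numpy(dtype=float)
    n = x.shape[0]
    obs = ~np.isnan(x)
    xf = np.nan_to_num(x)
    # per-pair sums of gi(2-gj) + gj(2-gi) over shared loci, vectorized
    a = xf * obs
    b = (2.0 - xf) * obs
    num = a @ b.T + b @ a.T  # sum over loci of gi(2-gj)+gj(2-gi)
    shared = obs.astype(float) @ obs.astype(float).T
    if (shared == 0).any() and n > 1:
        off = shared.copy()
        np.fill_diagonal(off, 1)
        if (off == 0).any():
            raise TableError("sample pair with zero shared genotyped loci")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = num / (4.0 * shared)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, g.sample_ids, "nei_pi")


@dataclass
class KinshipMatrix:
    """Genomic relatedness from standardized dosages (VanRaden K = ZZ'/m)."""

    values: np.ndarray
    ids: list[str]
    convention: str = "vanraden-standardized"
    n_loci: int = 0

    def aligned(self, ids) -> np.ndarray:
        idx = [self.ids.index(i) for i in ids]
        return self.values[np.ix_(idx, idx)]


def kinship_matrix(g: GenotypeMatrix) -> KinshipMatrix:
    """Standardized-dosage kinship; missing dosages imputed to 2p."""
    x = g.dosages.to_numpy(dtype=float)
    p = np.nanmean(x, axis=0) / 2.0
    mono = (p <= 0) | (p >= 1)
    if mono.any():
        warnings.warn(f"dropping {int(mono.sum())} monomorphic loci")
    x = x[:, ~mono]
    p = p[~mono]
    x = np.where(np.isnan(x), 2 * p, x)
    z = (x - 2 * p) / np.sqrt(2 * p * (1 - p))
    k = z @ z.T / z.shape[1]
    return KinshipMatrix(k, g.sample_ids, n_loci=z.shape[1])


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------

@dataclass
class HeritabilityEstimate:
    h2: float
    se: float
    loglik: float
    converged: bool
    boundary: bool = False
    sigma2_g: float = np.nan
    sigma2_e: float = np.nan


def _reml_loglik(h: float, s: np.ndarray, yt: np.ndarray, xt: np.ndarray) -> float:
    """Profiled REML log-likelihood at variance share h (eigenbasis)."""
    w = h * s + (1.0 - h)
    w = np.maximum(w, 1e-12)
    xw = xt / w[:, None]
    xtx = xt.T @ xw
    try:
        beta = np.linalg.solve(xtx, xw.T @ yt)
    except np.linalg.LinAlgError:
        return -np.inf
    r = yt - xt @ beta
    npar = yt.size - xt.shape[1]
    rss = float(r @ (r / w))
    if rss <= 0:
        return -np.inf
    sign, logdet_xtx = np.linalg.slogdet(xtx)
    if sign <= 0:
        return -np.inf
    return -0.5 * (npar * np.log(rss / npar) + np.log(w).sum()
                   + logdet_xtx + npar)


def spectral_reml(
    y: np.ndarray, K: np.ndarray, X: np.ndarray | None = None
) -> HeritabilityEstimate:
    """Single-random-effect REML by 1-D optimization over h2 on K's spectrum."""
    y = np.asarray(y, dtype=float)
    n = y.size
    if X is None:
        X = np.ones((n, 1))
    s, u = np.linalg.eigh((K + K.T) / 2.0)
    yt, xt = u.T @ y, u.T @ X

    def neg(h):
        return -_reml_loglik(h, s, yt, xt)

    # coarse grid then local refinement keeps the optimizer off bad shoulders
    grid = np.linspace(1e-4, 1 - 1e-4, 41)
    vals = np.array([neg(h) for h in grid])
    h0 = grid[int(np.argmin(vals))]
    lo = max(h0 - 0.05, 1e-6)
    hi = min(h0 + 0.05, 1 - 1e-6)
    res = optimize.minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-8})
    h = float(res.x)
    ll = -float(res.fun)
    converged = bool(res.success) and np.isfinite(ll)
    boundary = h < 1e-3 or h > 1 - 1e-3

    # observed information for the SE (numerical second derivative)
    eps = 1e-4
    hc = min(max(h, eps * 2), 1 - eps * 2)
    d2 = (_reml_loglik(hc + eps, s, yt, xt) - 2 * _reml_loglik(hc, s, yt, xt)
          + _reml_loglik(hc - eps, s, yt, xt)) / eps ** 2
    se = float(1.0 / np.sqrt(-d2)) if d2 < 0 else np.nan

    # implied variance components at the optimum
    w = np.maximum(h * s + (1 - h), 1e-12)
    xw = xt / w[:, None]
    beta = np.linalg.solve(xt.T @ xw, xw.T @ yt)
    r = yt - xt @ beta
    sp2 = float(r @ (r / w)) / (n - xt.shape[1])
    return HeritabilityEstimate(h2=h, se=se, loglik=ll, converged=converged,
                                boundary=boundary, sigma2_g=h * sp2,
                                sigma2_e=(1 - h) * sp2)


def pseudo_heritability(
    y, K: KinshipMatrix, X: np.ndarray | None = None
) -> HeritabilityEstimate:
    """REML pseudo-heritability of a phenotype given a kinship matrix.

    ``y`` may be a pandas Series aligned by index with ``K.ids`` or a plain
    array in K's order; optional fixed covariates ``X`` (without intercept).
    """
    if isinstance(y, pd.Series):
        y = y.loc[K.ids].to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if y.size != len(K.ids):
        raise TableError("phenotype length does not match kinship")
    if not np.isfinite(y).all():
        raise TableError("phenotype contains non-finite values")
    n = y.size
    design = np.ones((n, 1))
    if X is not None:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != n:
            X = X.T
        design = np.hstack([design, X])
    return spectral_reml(y, K.values, design)


# ---------------------------------------------------------------------------
# population-structure covariates and the GWAS scan
# ---------------------------------------------------------------------------

def svd_covariates(g_or_distance, n_pc: int = 10):
    """Top principal axes of the centered genotype (or distance) matrix.

    Returns (covariates, variance_shares); columns are orthonormal left
    singular vectors.
    """
    if isinstance(g_or_distance, GenotypeMatrix):
        x = g_or_distance.dosages.to_numpy(dtype=float)
        p = np.nanmean(x, axis=0) / 2.0
        x = np.where(np.isnan(x), 2 * p, x)
        ids = g_or_distance.sample_ids
    elif isinstance(g_or_distance, DistanceMatrix):
        x = g_or_distance.values
        ids = g_or_distance.ids
    else:
        x = np.asarray(g_or_distance, dtype=float)
        ids = list(range(x.shape[0]))
    xc = x - x.mean(axis=0)
    u, sv, _ = np.linalg.svd(xc, full_matrices=False)
    rank = int((sv > sv[0] * 1e-10).sum()) if sv.size else 0
    if n_pc > rank:
        warnings.warn(f"requested {n_pc} PCs but rank is {rank}; truncating")
        n_pc = rank
    shares = sv ** 2 / (sv ** 2).sum()
    cov = pd.DataFrame(u[:, :n_pc], index=ids,
                       columns=[f"PC{i + 1}" for i in range(n_pc)])
    return cov, shares[:n_pc]


@dataclass
class GwasResult:
    table: pd.DataFrame  # snp, chrom, pos, beta, se, t, p, fdr_flag, bonf_flag
    bonferroni_cutoff: float
    fdr_cutoff: float | None
    n_dropped: int
    covariates: str

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @property
    def lambda_gc(self) -> float:
        p = self.table["p"].dropna().to_numpy()
        chi2 = stats.chi2.isf(p, df=1)
        return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


def gwas_scan(
    y, g: GenotypeMatrix, covariates: pd.DataFrame | np.ndarray | None = None,
    alpha: float = 0.05,
) -> GwasResult:
    """Per-SNP OLS of the phenotype on [intercept, covariates, dosage].

    Two-sided t-test on the dosage coefficient. SNPs collinear with the
    covariates get a missing p-value and are counted in ``n_dropped``.
    """
    if isinstance(y, pd.Series):
        y = y.loc[g.sample_ids].to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if np.ptp(y) == 0:
        raise TableError("constant phenotype; association tests degenerate")
    C = np.ones((n, 1))
    cov_desc = "intercept"
    if covariates is not None:
        cv = (covariates.loc[g.sample_ids].to_numpy(dtype=float)
              if isinstance(covariates, pd.DataFrame)
              else np.atleast_2d(np.asarray(covariates, float)))
        if cv.shape[0] != n:
            cv = cv.T
        C = np.hstack([C, cv])
        cov_desc = f"intercept + {cv.shape[1]} covariates"
    x = g.dosages.to_numpy(dtype=float)
    p_freq = np.nanmean(x, axis=0) / 2.0
    x = np.where(np.isnan(x), 2 * p_freq, x)

    # residualize phenotype and dosages on the covariate space
    q, _ = np.linalg.qr(C)
    yr = y - q @ (q.T @ y)
    xr = x - q @ (q.T @ x)
    gg = (xr ** 2).sum(axis=0)
    gy = xr.T @ yr
    df = n - C.shape[1] - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = gy / gg
        rss = float(yr @ yr) - beta * gy
        sigma2 = rss / df
        se = np.sqrt(sigma2 / gg)
        t = beta / se
    bad = gg <= max(gg.max(), 1.0) * 1e-12
    t[bad] = np.nan
    pvals = 2.0 * stats.t.sf(np.abs(t), df)

    m = int((~np.isnan(pvals)).sum())
    bonf_cut = alpha / m if m else np.nan
    valid = ~np.isnan(pvals)
    fdr_flag = np.zeros(pvals.size, dtype=bool)
    if valid.any():
        fdr_flag[valid] = multipletests(pvals[valid], alpha=alpha, method="fdr_bh")[0]
    ps = np.sort(pvals[valid])
    passed = ps <= alpha * (np.arange(1, ps.size + 1)) / ps.size
    fdr_cut = float(ps[np.nonzero(passed)[0].max()]) if passed.any() else None
    tab = pd.DataFrame({
        "snp": g.snp_ids,
        "chrom": g.snp_pos["chrom"].to_numpy(),
        "pos": g.snp_pos["pos"].to_numpy(),
        "beta": beta, "se": se, "t": t, "p": pvals,
        "fdr_flag": fdr_flag,
        "bonf_flag": np.where(np.isnan(pvals), False, pvals < bonf_cut),
    })
    return GwasResult(tab, bonf_cut, fdr_cut, int(bad.sum()), cov_desc)


def multiple_testing(pvalues, alpha: float = 0.05) -> dict:
    """Benjamini-Hochberg step-up and Bonferroni flags at level ``alpha``."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise TableError("empty p-value vector")
    if ((p <= 0) | (p > 1)).any():
        raise TableError("p-values must lie in (0, 1]")
    bh = multipletests(p, alpha=alpha, method="fdr_bh")[0]
    bonf = p < alpha / p.size
    ps = np.sort(p)
    passed = ps <= alpha * np.arange(1, p.size + 1) / p.size
    fdr_cut = float(ps[np.nonzero(passed)[0].max()]) if passed.any() else None
    return {
        "bh_flags": bh,
        "bonferroni_flags": bonf,
        "bonferroni_cutoff": alpha / p.size,
        "fdr_cutoff": fdr_cut,
        "n_bh": int(bh.sum()),
        "n_bonferroni": int(bonf.sum()),
    }
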