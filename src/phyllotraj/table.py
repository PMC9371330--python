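"""Community table data model, I/O, decontamination, normalization, distances.

The central object is :class:`OtuTable`: an integer sample x OTU count matrix
with per-sample metadata (genotype, subpopulation, site, timepoint, infection
status, negative-control flag) and optional per-OTU annotations (taxonomic
Class, functional guild). Downstream stages consume either the table itself
or an :class:`AbundanceMatrix` produced by one of the transforms here.

The preprocessing order used throughout the package is fixed:
decontaminate -> CSS depth normalization -> Hellinger -> Bray-Curtis.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import fisher_exact

__all__ = [
    "OtuTable",
    "ContaminantReport",
    "AbundanceMatrix",
    "DistanceMatrix",
    "load_table",
    "flag_contaminants",
    "css_normalize",
    "hellinger_transform",
    "bray_curtis",
]

#: metadata columns every sample record must carry
META_COLUMNS = (
    "genotype",
    "subpopulation",
    "site",
    "timepoint",
    "doy",
    "infected",
    "is_control",
)


class TableError(ValueError):
    """Structured input error for malformed tables."""


@dataclass
class OtuTable:
    """Sample x OTU counts plus sample metadata and OTU annotations.

    Parameters
    ----------
    counts : pandas.DataFrame
        Nonnegative integer counts, rows = samples, columns = OTU ids.
    sample_meta : pandas.DataFrame
        Indexed by sample id; must contain :data:`META_COLUMNS`.
    otu_meta : pandas.DataFrame, optional
        Indexed by OTU id; typically columns ``Class`` and ``guild``.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    otu_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dup = c.index[c.index.duplicated()].tolist()
            raise TableError(f"duplicate sample ids: {dup}")
        if c.columns.duplicated().any():
            dup = c.columns[c.columns.duplicated()].tolist()
            raise TableError(f"duplicate OTU ids: {dup}")
        vals = c.to_numpy()
        if (vals < 0).any():
            bad = c.index[(vals < 0).any(axis=1)].tolist()
            raise TableError(f"negative counts in samples: {bad}")
        missing = c.index.difference(self.sample_meta.index)
        if len(missing):
            raise TableError(f"metadata missing sample ids: {missing.tolist()}")
        extra = self.sample_meta.index.difference(c.index)
        if len(extra):
            raise TableError(f"metadata has unknown sample ids: {extra.tolist()}")
        for col in META_COLUMNS:
            if col not in self.sample_meta.columns:
                raise TableError(f"sample metadata lacks column {col!r}")
        # canonical axis names; align metadata row order with counts
        self.counts = c.rename_axis(index="sample_id", columns=None)
        self.sample_meta = self.sample_meta.loc[c.index].rename_axis("sample_id")
        if self.otu_meta is not None:
            self.otu_meta = self.otu_meta.reindex(c.columns)

    # -- convenience -----------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def otu_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def controls(self) -> "OtuTable":
        return self.subset_samples(self.sample_meta["is_control"].astype(bool))

    def real_samples(self) -> "OtuTable":
        return self.subset_samples(~self.sample_meta["is_control"].astype(bool))

    def subset_samples(self, mask_or_ids) -> "OtuTable":
        sub = self.counts.loc[mask_or_ids]
        return OtuTable(sub, self.sample_meta.loc[sub.index], self.otu_meta)

    def drop_otus(self, otu_ids) -> "OtuTable":
        keep = [o for o in self.counts.columns if o not in set(otu_ids)]
        om = self.otu_meta.loc[keep] if self.otu_meta is not None else None
        return OtuTable(self.counts[keep], self.sample_meta, om)

    def relative_abundance(self) -> pd.DataFrame:
        tot = self.counts.sum(axis=1).replace(0, np.nan)
        return self.counts.div(tot, axis=0).fillna(0.0)

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, counts_path, metadata_path, otu_meta_path=None) -> None:
        self.counts.rename_axis("sample_id").to_csv(counts_path, sep="\t")
        self.sample_meta.rename_axis("sample_id").to_csv(metadata_path, sep="\t")
        if otu_meta_path is not None and self.otu_meta is not None:
            self.otu_meta.rename_axis("otu_id").to_csv(otu_meta_path, sep="\t")

    def to_biom(self, path) -> None:
        """Write a minimal BIOM v1 (JSON) document."""
        mat = self.counts.to_numpy()
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "phyllotraj",
            "matrix_type": "dense",
            "matrix_element_type": "int",
            "shape": [int(mat.shape[1]), int(mat.shape[0])],
            # BIOM rows are observations (OTUs), columns are samples
            "rows": [{"id": o, "metadata": None} for o in self.otu_ids],
            "columns": [{"id": s, "metadata": None} for s in self.sample_ids],
            "data": mat.T.astype(int).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)


def _read_biom_counts(path) -> pd.DataFrame:
    with open(path) as fh:
        doc = json.load(fh)
    otus = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    if doc.get("matrix_type") == "sparse":
        mat = np.zeros((len(otus), len(samples)))
        for i, j, v in doc["data"]:
            mat[i, j] = v
    else:
        mat = np.asarray(doc["data"], dtype=float)
    return pd.DataFrame(mat.T, index=samples, columns=otus)


def load_table(counts_path, metadata_path, otu_meta_path=None) -> OtuTable:
    """Load an :class:`OtuTable` from TSV (or BIOM JSON) counts + metadata TSV.

    Counts files ending in ``.biom`` or ``.json`` are parsed as BIOM v1
    documents; anything else as TSV with samples in rows.
    """
    cp = str(counts_path)
    if cp.endswith((".biom", ".json")):
        counts = _read_biom_counts(counts_path)
    else:
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    frac = counts.to_numpy(dtype=float)
    if not np.allclose(frac, np.round(frac)):
        raise TableError("count table contains non-integer values")
    counts = counts.round().astype(int)
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    for col in ("infected", "is_control"):
        if col in meta.columns:
            meta[col] = meta[col].astype(bool)
    otu_meta = None
    if otu_meta_path is not None:
        otu_meta = pd.read_csv(otu_meta_path, sep="\t", index_col=0)
    return OtuTable(counts, meta, otu_meta)


# ---------------------------------------------------------------------------
# decontamination
# ---------------------------------------------------------------------------

@dataclass
class ContaminantReport:
    """Per-OTU prevalence-based contaminant screen against negative controls."""

    table: pd.DataFrame  # columns: prev_control, prev_sample, score, flagged
    threshold: float

    @property
    def flagged_otus(self) -> list[str]:
        return self.table.index[self.table["flagged"]].tolist()

    def pruned(self, table: OtuTable) -> OtuTable:
        return table.drop_otus(self.flagged_otus)


def flag_contaminants(table: OtuTable, threshold: float = 0.1) -> ContaminantReport:
    """Flag OTUs over-represented in negative controls.

    For each OTU a 2x2 presence table (control vs real sample, present vs
    absent) is scored with a one-sided Fisher exact test for
    over-representation in controls. An OTU is flagged iff the p-value is
    below ``threshold`` and its control prevalence exceeds its prevalence in
    real samples.
    """
    ctrl_mask = table.sample_meta["is_control"].astype(bool).to_numpy()
    n_ctrl = int(ctrl_mask.sum())
    n_samp = int((~ctrl_mask).sum())
    if n_ctrl == 0 or n_samp == 0:
        raise TableError("need at least one control and one non-control sample")
    present = table.counts.to_numpy() > 0
    rows = []
    for j, otu in enumerate(table.otu_ids):
        a = int(present[ctrl_mask, j].sum())        # present in controls
        c = int(present[~ctrl_mask, j].sum())       # present in samples
        prev_c = a / n_ctrl
        prev_s = c / n_samp
        _, p = fisher_exact([[a, n_ctrl - a], [c, n_samp - c]], alternative="greater")
        rows.append((otu, prev_c, prev_s, p, bool(p < threshold and prev_c > prev_s)))
    df = pd.DataFrame(
        rows, columns=["otu_id", "prev_control", "prev_sample", "score", "flagged"]
    ).set_index("otu_id")
    return ContaminantReport(df, threshold)


# ---------------------------------------------------------------------------
# normalization and distances
# ---------------------------------------------------------------------------

@dataclass
class AbundanceMatrix:
    """Real-valued sample x OTU matrix tagged with the transform applied."""

    values: pd.DataFrame
    transform: str  # css | hellinger | clr | relative
    dropped_samples: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return self.values.index.tolist()


def _as_frame(table_or_matrix) -> pd.DataFrame:
    if isinstance(table_or_matrix, OtuTable):
        return table_or_matrix.counts.astype(float)
    if isinstance(table_or_matrix, AbundanceMatrix):
        return table_or_matrix.values
    return pd.DataFrame(table_or_matrix).astype(float)


def css_normalize(table: OtuTable, quantile: float = 0.5) -> AbundanceMatrix:
    """Cumulative sum scaling depth normalization.

    Each sample's scaling factor is the sum of its counts at or below the
    ``quantile`` level of its *nonzero* count distribution; normalized values
    are counts divided by this factor and rescaled by the median factor so
    magnitudes stay comparable to raw counts.
    """
    counts = table.counts.astype(float)
    mat = counts.to_numpy()
    factors = np.full(mat.shape[0], np.nan)
    dropped = []
    for i in range(mat.shape[0]):
        nz = mat[i][mat[i] > 0]
        if nz.size == 0:
            dropped.append(counts.index[i])
            continue
        q = np.quantile(nz, quantile)
        factors[i] = mat[i][mat[i] <= q].sum()
    if dropped:
        warnings.warn(f"dropping all-zero samples: {dropped}")
    keep = ~np.isnan(factors)
    med = np.median(factors[keep])
    out = counts.loc[keep].div(factors[keep], axis=0) * med
    return AbundanceMatrix(out, "css", dropped_samples=[str(s) for s in dropped])


def hellinger_transform(table_or_matrix) -> AbundanceMatrix:
    """Hellinger transform: sqrt of relative abundance per sample row."""
    df = _as_frame(table_or_matrix)
    vals = df.to_numpy(dtype=float)
    if (vals < 0).any():
        raise TableError("Hellinger transform requires nonnegative input")
    tot = vals.sum(axis=1)
    zero = tot == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero rows map to zeros")
    safe = np.where(zero, 1.0, tot)
    out = np.sqrt(vals / safe[:, None])
    return AbundanceMatrix(pd.DataFrame(out, index=df.index, columns=df.columns), "hellinger")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with sample labels and a metric tag."""

    values: np.ndarray
    ids: list[str]
    metric: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise TableError("distance matrix must be square")
        if v.shape[0] != len(self.ids):
            raise TableError("labels do not match matrix size")
        if not np.allclose(v, v.T, atol=1e-10):
            raise TableError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-10):
            raise TableError("distance matrix diagonal must be zero")
        if (v < -1e-12).any():
            raise TableError("distances must be nonnegative")
        self.values = (v + v.T) / 2.0
        np.fill_diagonal(self.values, 0.0)
        self.ids = list(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def subset(self, ids) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(self.values[np.ix_(idx, idx)], list(ids), self.metric)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).rename_axis(
            "sample_id"
        ).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, metric: str = "") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(), df.index.tolist(), metric)


def bray_curtis(matrix) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(x, y) = sum|x-y| / sum(x+y) between rows."""
    df = _as_frame(matrix)
    vals = df.to_numpy(dtype=float)
    if (vals < 0).any():
        raise TableError("Bray-Curtis requires nonnegative input")
    tot = vals.sum(axis=1)
    if (tot == 0).any():
        warnings.warn("all-zero rows present; pairwise distance with them set to 0")
    with np.errstate(invalid="ignore"):
        d = squareform(pdist(vals, metric="braycurtis"))
    d = np.nan_to_num(d, nan=0.0)  # both-zero pairs
    return DistanceMatrix(d, df.index.tolist(), "braycurtis")
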