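"""Synthetic successional phyllosphere data with known ground truth.

Emulates the study design the package's analyses assume: a panel of host
genotypes drawn from a few deeply diverged genetic subpopulations (plus some
admixed individuals), each sampled repeatedly over a growing season; paired
infected/symptomless leaves for a subset of plants; one negative-control
sample per collection date; a biallelic SNP panel with one causal variant
shifting a handful of target OTUs; and guild-structured covariance among
OTUs, with the pathogen guild carrying the dominant temporal loadings so
that succession has planted "driver" taxa.

Community counts are drawn multinomially from softmax-closed latent
log-abundances, at a Poisson-distributed sequencing depth per sample, which
reproduces the compositional sparsity of amplicon data without extra
zero-inflation. The subpopulation displacement grows linearly with timepoint
so the host-genetic signal peaks late in the season.

Every planted signal is recorded in :class:`GroundTruth` so recovery can be
scored exactly.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .table import OtuTable

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_genotypes",
    "simulate_succession",
    "simulate",
    "truth_report",
    "load_truth",
    "GenotypePanel",
]

#: collection days mirroring a single-season five-date design
DEFAULT_DOYS = (158, 212, 233, 260, 286)

GUILDS = ("pathogen", "yeast", "mycoparasite", "saprotroph")
GUILD_CLASSES = {
    "pathogen": "Dothideomycetes",
    "yeast": "Tremellomycetes",
    "mycoparasite": "Sordariomycetes",
    "saprotroph": "Leotiomycetes",
}

#: loading of each guild's OTUs on the shared per-sample "pathogen load"
#: factor; yeasts are deliberately uncoupled (modular commensals)
PATHOGEN_LOAD_WEIGHT = {"pathogen": 0.72, "mycoparasite": 0.6,
                        "saprotroph": 0.5}

#: number of OTUs per fine-scale covarying sub-block within a guild
SUBBLOCK_SIZE = 5


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and effect-size parameters for the generator.

    Defaults describe a single-site season: 60 genotypes from 3
    subpopulations (10% admixed), 5 collection dates, 100 real OTUs in 4
    guilds plus 5 control-exclusive contaminants, 200 SNPs at Fst 0.3 with
    one causal variant, mean depth 5000 reads, a strong directional temporal
    shift and a weaker late-season subpopulation displacement.
    """

    n_genotypes: int = 60
    n_timepoints: int = 5
    n_subpops: int = 3
    admix_fraction: float = 0.1
    n_otus: int = 100
    n_snps: int = 200
    fst: float = 0.3
    depth_mean: float = 5000.0
    time_shift: float = 1.0
    subpop_effect: float = 1.5
    causal_snp_effect: float = 1.0
    n_target_otus: int = 5
    guild_block_corr: float = 0.6
    contam_n: int = 5
    noise_sd: float = 0.6
    n_drivers: int = 10
    priority_effect_sd: float = 0.8
    infected_fraction: float = 0.3
    infection_effect: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genotypes", "n_timepoints", "n_subpops", "n_otus", "n_snps"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        if self.n_subpops < 2:
            raise ParameterError("n_subpops must be >= 2")
        if not 0.0 < self.fst < 1.0:
            raise ParameterError("fst must lie in (0, 1)")
        for name in ("admix_fraction", "infected_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]")
        if not -1.0 <= self.guild_block_corr <= 1.0:
            raise ParameterError("guild_block_corr must lie in [-1, 1]")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """Record of every signal planted by the generator."""

    causal_snp_index: int
    target_otu_ids: list[str]
    contaminant_otu_ids: list[str]
    driver_otu_ids: list[str]
    subpop_centroids: dict[str, list[list[float]]]  # subpop -> timepoint x OTU latent means
    true_h2: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "causal_snp_index": int(self.causal_snp_index),
            "target_otu_ids": list(self.target_otu_ids),
            "contaminant_otu_ids": list(self.contaminant_otu_ids),
            "driver_otu_ids": list(self.driver_otu_ids),
            "subpop_centroids": {k: [list(map(float, r)) for r in v]
                                 for k, v in self.subpop_centroids.items()},
            "true_h2": float(self.true_h2),
            "seed": int(self.seed),
        }


@dataclass
class GenotypePanel:
    """Dosage matrix in {0,1,2} with subpopulation assignments."""

    dosages: pd.DataFrame  # genotypes x SNPs
    subpop: pd.Series      # per-genotype label ("pop1".. or "admixed")
    snp_pos: pd.DataFrame  # snp -> chrom, pos
    allele_freq: np.ndarray

    @property
    def genotype_ids(self) -> list[str]:
        return self.dosages.index.tolist()

    def to_tsv(self, path) -> None:
        self.dosages.rename_axis("genotype").to_csv(path, sep="\t")

    def to_vcf(self, path) -> None:
        """Write a minimal diploid biallelic VCF (GT field only)."""
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("##contig=<ID=Chr01>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(self.genotype_ids) + "\n")
            mat = self.dosages.to_numpy()
            for j, snp in enumerate(self.dosages.columns):
                chrom = self.snp_pos.loc[snp, "chrom"]
                pos = self.snp_pos.loc[snp, "pos"]
                gts = "\t".join(gt_map[int(g)] for g in mat[:, j])
                fh.write(f"{chrom}\t{pos}\t{snp}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng((zlib.crc32(stream.encode()) ^ seed) % (2**31))


def simulate_genotypes(config: SimulationConfig) -> GenotypePanel:
    """Simulate a structured SNP panel under the Balding-Nichols model.

    Subpopulation allele frequencies are Beta-distributed around a shared
    ancestral frequency with variance set by ``fst``; admixed individuals mix
    two subpopulation frequency vectors. SNPs whose realized panel-wide minor
    allele frequency falls below 0.05 are rejection-resampled.
    """
    rng = _rng(config.seed, "genotypes")
    n, m, P = config.n_genotypes, config.n_snps, config.n_subpops
    # subpopulation membership: round-robin, tail fraction admixed
    n_admix = int(round(config.admix_fraction * n))
    labels = [f"pop{(i % P) + 1}" for i in range(n - n_admix)] + ["admixed"] * n_admix
    labels = list(rng.permutation(labels))
    # per-individual mixing weights over subpopulations
    W = np.zeros((n, P))
    for i, lab in enumerate(labels):
        if lab == "admixed":
            a, b = rng.choice(P, size=2, replace=False)
            w = rng.uniform(0.3, 0.7)
            W[i, a], W[i, b] = w, 1 - w
        else:
            W[i, int(lab[3:]) - 1] = 1.0

    F = config.fst
    shape = (1 - F) / F
    dosage = np.zeros((n, m), dtype=int)
    freqs = np.zeros(m)
    filled = 0
    while filled < m:
        batch = max(m - filled, 16)
        anc = rng.uniform(0.1, 0.9, size=batch)
        sub = rng.beta(anc[None, :] * shape, (1 - anc[None, :]) * shape, size=(P, batch))
        p_ind = W @ sub  # n x batch individual allele frequencies
        d = rng.binomial(2, p_ind)
        maf = d.mean(axis=0) / 2.0
        maf = np.minimum(maf, 1 - maf)
        ok = np.where(maf >= 0.05)[0]
        take = ok[: m - filled]
        dosage[:, filled:filled + take.size] = d[:, take]
        freqs[filled:filled + take.size] = d[:, take].mean(axis=0) / 2.0
        filled += take.size

    snp_ids = [f"snp{j + 1:05d}" for j in range(m)]
    dosages = pd.DataFrame(dosage, index=[f"G{i + 1:03d}" for i in range(n)],
                           columns=snp_ids)
    snp_pos = pd.DataFrame(
        {"chrom": "Chr01", "pos": np.arange(1, m + 1) * 1000}, index=snp_ids
    )
    return GenotypePanel(dosages, pd.Series(labels, index=dosages.index, name="subpop"),
                         snp_pos, freqs)


def _guild_assignments(config: SimulationConfig, rng) -> pd.DataFrame:
    """Split real OTUs into guild blocks; pathogens first (largest block share)."""
    k = config.n_otus
    props = np.array([0.3, 0.4, 0.1, 0.2])  # pathogen, yeast, mycoparasite, saprotroph
    sizes = np.floor(props * k).astype(int)
    sizes[0] += k - sizes.sum()
    guilds = np.repeat(GUILDS, sizes)
    otu_ids = [f"OTU_{j + 1:04d}" for j in range(k)]
    return pd.DataFrame(
        {"guild": guilds, "Class": [GUILD_CLASSES[g] for g in guilds]}, index=otu_ids
    )


def simulate_succession(
    config: SimulationConfig, genotypes: GenotypePanel
) -> tuple[OtuTable, GroundTruth]:
    """Draw a full season of community samples from the latent model.

    Latent log-abundance of OTU *o* in sample *s* (genotype g, subpop p,
    timepoint t in 0..T-1):

        eta = baseline_o + timeload_o * time_shift * t
              + subpop_disp[p, o] * subpop_effect * t / (T - 1)
              + dosage_g(causal) * causal_snp_effect * [o in targets]
              + persistent per-genotype pathogen load * [o in drivers]
              + infected * infection_effect * [o in pathogen guild]
              + guild-correlated Gaussian noise

    Counts are Multinomial(depth ~ Poisson(depth_mean), softmax(eta)).
    Negative controls (one per timepoint) contain only contaminant OTUs plus
    sparse low-level carryover of common real OTUs.
    """
    if genotypes.dosages.shape != (config.n_genotypes, config.n_snps):
        raise ParameterError("genotype panel does not match configuration")
    rng = _rng(config.seed, "succession")
    T, k = config.n_timepoints, config.n_otus
    otu_meta = _guild_assignments(config, rng)
    otu_ids = otu_meta.index.tolist()
    guilds = otu_meta["guild"].to_numpy()
    # fine-scale covarying sub-blocks within each guild
    subblocks = []
    counters: dict[str, int] = {}
    for g in guilds:
        i = counters.get(g, 0)
        subblocks.append(f"{g}{i // SUBBLOCK_SIZE}")
        counters[g] = i + 1
    # stable draw order for block factors (set order is hash-dependent)
    unique_blocks = sorted(set(subblocks))
    # endemic (non-driver) pathogens carry the shared load factor that
    # mycoparasites and saprotrophs track; the epidemic drivers keep their
    # own boom-bust dynamics (trend + per-host priority effects) so their
    # individual removal is not redundant with the rest of the guild
    load_weights = np.array([PATHOGEN_LOAD_WEIGHT.get(g, 0.0) for g in guilds])

    baseline = rng.normal(0.0, 1.0, size=k)
    # temporal loadings: small everywhere, dominant on the driver OTUs
    timeload = rng.normal(0.0, 0.05, size=k)
    pathogen_idx = np.where(guilds == "pathogen")[0]
    n_drivers = min(config.n_drivers, pathogen_idx.size)
    driver_idx = pathogen_idx[:n_drivers]
    timeload[driver_idx] = rng.uniform(0.4, 0.8, size=n_drivers) * rng.choice(
        [-1.0, 1.0], size=n_drivers
    )
    load_weights[driver_idx] = 0.0

    # per-subpopulation late-season displacement directions, carried by the
    # epidemic driver OTUs: host genetic groups diverge because they differ
    # in susceptibility to the dominant pathogens, so host-genetic community
    # differences act through relatively few taxa
    subpops = sorted({s for s in genotypes.subpop if s != "admixed"})
    disp = {}
    for p in subpops:
        v = np.zeros(k)
        v[driver_idx] = rng.normal(0.0, 1.0, size=driver_idx.size)
        v /= np.linalg.norm(v) / np.sqrt(driver_idx.size)
        disp[p] = v

    # per-genotype persistent pathogen load on driver OTUs: early colonists
    # persist through the season (priority effects), the temporal
    # contingency that sequential mixed models are meant to detect
    priority = rng.normal(0.0, config.priority_effect_sd,
                          size=(config.n_genotypes, n_drivers))

    # causal SNP: pick a common SNP; targets drawn from pathogen+yeast OTUs
    freqs = np.minimum(genotypes.allele_freq, 1 - genotypes.allele_freq)
    causal = int(np.argmax(freqs))
    target_idx = rng.choice(k, size=min(config.n_target_otus, k), replace=False)
    dos = genotypes.dosages.to_numpy()[:, causal].astype(float)

    # guild-block correlated noise via shared guild factors
    rho = config.guild_block_corr
    shared = np.sqrt(abs(rho)) * np.sign(rho)

    infected_genos = set()
    n_inf = int(round(config.infected_fraction * config.n_genotypes))
    if n_inf:
        infected_genos = set(rng.choice(genotypes.genotype_ids, size=n_inf, replace=False))

    geno_ids = genotypes.genotype_ids
    geno_sub = genotypes.subpop
    doys = (list(DEFAULT_DOYS[:T]) if T <= len(DEFAULT_DOYS)
            else list(np.linspace(150, 290, T).astype(int)))

    records, count_rows, sample_ids = [], [], []
    latent_by_sample = {}

    def latent_for(g_i: int, t: int, infected: bool) -> np.ndarray:
        gid = geno_ids[g_i]
        lab = geno_sub.iloc[g_i]
        eta = baseline + timeload * config.time_shift * t
        frac = t / (T - 1) if T > 1 else 0.0
        if lab in disp:
            eta = eta + disp[lab] * config.subpop_effect * frac
        elif subpops:  # admixed: average displacement
            eta = eta + np.mean([disp[p] for p in subpops], axis=0) * config.subpop_effect * frac
        eta = eta.copy()
        eta[driver_idx] += priority[g_i]
        eta[target_idx] += dos[g_i] * config.causal_snp_effect
        if infected:
            eta[guilds == "pathogen"] += config.infection_effect
        # guild covariance: OTUs covary tightly within small sub-blocks
        # (fine-scale ecological clusters), and the pathogen, mycoparasite
        # and saprotroph guilds additionally track one "pathogen load"
        # factor — mycoparasites prey on pathogens and saprotrophs follow
        # the necrotic tissue they create — while yeasts stay fully modular
        # (commensals of the leaf surface)
        f_path = rng.normal(0.0, 1.0)
        block_noise = {b: rng.normal(0.0, 1.0) for b in unique_blocks}
        idio = rng.normal(0.0, 1.0, size=k)
        load = load_weights
        blk = np.array([block_noise[subblocks[j]] for j in range(k)])
        noise = (load * f_path
                 + shared * np.sqrt(np.maximum(1 - load ** 2, 0.0)) * blk
                 + np.sqrt(np.maximum((1 - abs(rho)) * (1 - load ** 2), 0.0))
                 * idio) * config.noise_sd
        return eta + noise

    contam_ids = [f"OTU_C{j + 1:03d}" for j in range(config.contam_n)]
    all_otu_ids = otu_ids + contam_ids
    carryover_pool = np.argsort(baseline)[-10:]  # most abundant real OTUs

    for t in range(T):
        for g_i, gid in enumerate(geno_ids):
            for infected in ([False, True] if gid in infected_genos else [False]):
                sid = f"{gid}_T{t + 1}" + ("_inf" if infected else "")
                eta = latent_for(g_i, t, infected)
                prop = np.exp(eta - eta.max())
                prop /= prop.sum()
                depth = rng.poisson(config.depth_mean)
                counts = rng.multinomial(max(depth, 1), prop)
                row = np.concatenate([counts, np.zeros(config.contam_n, dtype=int)])
                count_rows.append(row)
                sample_ids.append(sid)
                latent_by_sample[sid] = eta
                records.append({
                    "sample_id": sid, "genotype": gid,
                    "subpopulation": geno_sub.iloc[g_i], "site": "site1",
                    "timepoint": t + 1, "doy": doys[t],
                    "infected": infected, "is_control": False,
                })
        # one negative control per collection date
        sid = f"CTRL_T{t + 1}"
        ctrl = np.zeros(k + config.contam_n, dtype=int)
        if config.contam_n:
            depth = max(rng.poisson(config.depth_mean / 50.0), config.contam_n)
            w = rng.dirichlet(np.ones(config.contam_n) * 5.0)
            ctrl[k:] = rng.multinomial(depth, w) + 1  # every contaminant present
        n_carry = min(3, k)
        carry = rng.choice(carryover_pool, size=n_carry, replace=False)
        ctrl[carry] += rng.poisson(2.0, size=n_carry)
        count_rows.append(ctrl)
        sample_ids.append(sid)
        records.append({
            "sample_id": sid, "genotype": "none", "subpopulation": "none",
            "site": "site1", "timepoint": t + 1, "doy": doys[t],
            "infected": False, "is_control": True,
        })

    counts = pd.DataFrame(np.array(count_rows), index=sample_ids, columns=all_otu_ids)
    meta = pd.DataFrame(records).set_index("sample_id")
    contam_meta = pd.DataFrame(
        {"guild": "contaminant", "Class": "Unknown"}, index=contam_ids
    )
    table = OtuTable(counts, meta, pd.concat([otu_meta, contam_meta]))

    # ground-truth latent centroids per subpopulation per timepoint
    centroids: dict[str, list[list[float]]] = {}
    for p in subpops:
        rows = []
        for t in range(T):
            frac = t / (T - 1) if T > 1 else 0.0
            rows.append(list(baseline + timeload * config.time_shift * t
                             + disp[p] * config.subpop_effect * frac))
        centroids[p] = rows

    # variance of the latent host axis (final timepoint) split into the
    # genetic part (subpop displacement + causal effect) vs noise
    axis = disp[subpops[0]] - np.mean([disp[p] for p in subpops], axis=0) \
        if len(subpops) > 1 else disp[subpops[0]]
    axis = axis / (np.linalg.norm(axis) or 1.0)
    gen_scores, tot_scores = [], []
    for g_i, gid in enumerate(geno_ids):
        lab = geno_sub.iloc[g_i]
        d_vec = disp.get(lab, np.mean([disp[p] for p in subpops], axis=0))
        gen = config.subpop_effect * float(d_vec @ axis)
        gen += config.causal_snp_effect * dos[g_i] * float(
            np.sum(axis[target_idx]))
        gen_scores.append(gen)
        sid = f"{gid}_T{T}"
        tot_scores.append(float(latent_by_sample[sid] @ axis))
    vg = float(np.var(gen_scores))
    vt = float(np.var(tot_scores))
    true_h2 = min(max(vg / vt, 0.0), 1.0) if vt > 0 else 0.0

    truth = GroundTruth(
        causal_snp_index=causal,
        target_otu_ids=[otu_ids[j] for j in sorted(target_idx)],
        contaminant_otu_ids=contam_ids,
        driver_otu_ids=[otu_ids[j] for j in sorted(driver_idx)],
        subpop_centroids=centroids,
        true_h2=true_h2,
        seed=config.seed,
    )
    return table, truth


def simulate(config: SimulationConfig) -> tuple[OtuTable, GenotypePanel, GroundTruth]:
    """Convenience: genotypes + succession in one call."""
    panel = simulate_genotypes(config)
    table, truth = simulate_succession(config, panel)
    return table, panel, truth


def truth_report(truth: GroundTruth, path) -> None:
    """Write the ground-truth record as JSON."""
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)


def load_truth(path) -> GroundTruth:
    with open(path) as fh:
        d = json.load(fh)
    return GroundTruth(**d)
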