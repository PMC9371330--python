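"""End-to-end orchestration of the succession analysis.

Stages: simulate (or load) -> decontaminate -> normalize -> distances ->
ordination -> PERMANOVA / dispersion / Mantel -> trajectories (+ influence)
-> core / time-explainability / indicator species -> networks -> host
genetics (heritability, GWAS). Each stage's seed is derived from the global
seed by stable hashing of the stage name, so toggling one stage never shifts
another stage's random stream. Outputs are TSV/GraphML files plus a JSON run
report summarizing every stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core_temporal import core_intersection, indval, select_core, time_explainability
from .genetics import gwas_scan, kinship_matrix, nei_pi_distance, pseudo_heritability, svd_covariates
from .networks import clr_transform, compare_networks, detect_modules, guild_summary, infer_network, zi_pi
from .ordination import dispersion_homogeneity, mantel, nmds, pcoa, permanova
from .simulate import SimulationConfig, simulate, truth_report
from .table import OtuTable, bray_curtis, css_normalize, flag_contaminants, hellinger_transform, load_table
from .trajectory import build_trajectories, mean_trajectory, otu_removal_influence, trajectory_group_tests, trajectory_metrics

__all__ = ["PipelineConfig", "run", "stage_seed", "REPORT_SCHEMA", "validate_report"]

STAGES = ("simulate", "decontaminate", "ordination", "permanova", "mantel",
          "trajectories", "influence", "core", "te", "indval", "networks",
          "genetics")

STAGE_DEPS = {
    "permanova": ("ordination",),
    "mantel": ("ordination",),
    "trajectories": ("ordination",),
    "influence": ("trajectories",),
}

REPORT_SCHEMA = {
    "type": "object",
    "required": ["version", "seed", "parameters", "stages"],
    "properties": {
        "version": {"type": "string"},
        "seed": {"type": "integer"},
        "parameters": {"type": "object"},
        "stages": {"type": "object"},
    },
}

_TYPES = {"object": dict, "string": str, "integer": int, "number": (int, float)}


def validate_report(report: dict, schema: dict = REPORT_SCHEMA) -> bool:
    """Minimal structural validation of a run report against a JSON schema."""
    if schema.get("type") == "object":
        if not isinstance(report, dict):
            return False
        for key in schema.get("required", []):
            if key not in report:
                return False
        for key, sub in schema.get("properties", {}).items():
            if key in report:
                expect = _TYPES.get(sub.get("type"))
                if expect is not None and not isinstance(report[key], expect):
                    return False
    return True


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    h = hashlib.sha256(f"{stage}".encode()).digest()
    return (int.from_bytes(h[:4], "big") ^ int(global_seed)) % (2**31)


@dataclass
class PipelineConfig:
    """What to run, on what input, with what parameters."""

    outdir: str = "phyllotraj_out"
    seed: int = 0
    # either a simulation block or input paths
    simulation: SimulationConfig | None = None
    counts_path: str | None = None
    metadata_path: str | None = None
    otu_meta_path: str | None = None
    stages: tuple[str, ...] = STAGES
    n_perm: int = 199
    contaminant_threshold: float = 0.1
    nmds_axes: int = 2
    n_core: float = 0.02
    network_kw: dict = field(default_factory=dict)

    def validate(self) -> None:
        enabled = set(self.stages)
        unknown = enabled - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for s in enabled:
            for dep in STAGE_DEPS.get(s, ()):
                if dep not in enabled:
                    raise ValueError(f"stage {s!r} requires {dep!r}")
        if self.simulation is None and self.counts_path is None:
            raise ValueError("either a simulation block or input paths required")


def run(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns (and writes) the JSON run report."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": int(config.seed),
                    "parameters": {"n_perm": config.n_perm,
                                   "stages": list(config.stages)},
                    "stages": {}}
    t0 = time.time()
    enabled = set(config.stages)
    panel = truth = None

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")

        if "simulate" in enabled and config.simulation is not None:
            sim = dataclasses.replace(config.simulation,
                                      seed=stage_seed(config.seed, "simulate"))
            table, panel, truth = simulate(sim)
            table.to_tsv(out / "counts.tsv", out / "metadata.tsv",
                         out / "otu_meta.tsv")
            panel.to_tsv(out / "genotypes.tsv")
            truth_report(truth, out / "truth.json")
            report["stages"]["simulate"] = {
                "n_samples": table.n_samples, "n_otus": table.n_otus,
                "seed": sim.seed,
            }
        else:
            table = load_table(config.counts_path, config.metadata_path,
                               config.otu_meta_path)
            report["stages"]["load"] = {"n_samples": table.n_samples,
                                        "n_otus": table.n_otus}

        if "decontaminate" in enabled:
            rep = flag_contaminants(table, config.contaminant_threshold)
            table = rep.pruned(table).real_samples()
            rep.table.to_csv(out / "contaminants.tsv", sep="\t")
            report["stages"]["decontaminate"] = {
                "n_flagged": len(rep.flagged_otus),
                "flagged": rep.flagged_otus,
            }
        else:
            table = table.real_samples()

        needs_dist = enabled & {"ordination", "permanova", "mantel",
                                "trajectories", "genetics"}
        dist = meta = None
        if needs_dist:
            norm = css_normalize(table)
            hel = hellinger_transform(norm)
            dist = bray_curtis(hel)
            dist.to_tsv(out / "braycurtis.tsv")
            meta = table.sample_meta.loc[dist.ids]
        elif enabled - {"simulate"}:
            meta = table.sample_meta

        ordn = pco = None
        if "ordination" in enabled:
            s = stage_seed(config.seed, "ordination")
            ordn = nmds(dist, k=config.nmds_axes, seed=s, n_restarts=4)
            pco = pcoa(dist, k=config.nmds_axes)
            ordn.coordinates.to_csv(out / "nmds.tsv", sep="\t")
            pco.coordinates.to_csv(out / "pcoa.tsv", sep="\t")
            report["stages"]["ordination"] = {
                "stress": ordn.stress,
                "pcoa_var_explained": [float(v) for v in
                                       pco.variance_explained[:config.nmds_axes]],
            }

        if "permanova" in enabled:
            s = stage_seed(config.seed, "permanova")
            terms = ["doy", "subpopulation", "doy:subpopulation"]
            res = permanova(dist, meta, terms, n_perm=config.n_perm, seed=s)
            res.to_tsv(out / "permanova.tsv")
            disp = dispersion_homogeneity(dist, meta["timepoint"],
                                          n_perm=config.n_perm, seed=s + 1)
            report["stages"]["permanova"] = {
                "table": res.table.to_dict("records"),
                "dispersion_p": disp.p_value,
            }
            # paired infection test within plants having both leaf states
            inf_meta = meta[meta["genotype"].isin(
                meta.groupby("genotype")["infected"].nunique()
                .pipe(lambda s2: s2[s2 > 1]).index)]
            if len(inf_meta) and inf_meta["infected"].nunique() > 1:
                sub = dist.subset(inf_meta.index.tolist())
                paired = permanova(sub, inf_meta, ["infected"],
                                   n_perm=config.n_perm,
                                   strata="genotype", seed=s + 2)
                paired.to_tsv(out / "permanova_infection.tsv")
                report["stages"]["permanova"]["infection_R2"] = float(
                    paired.table.loc[0, "R2"])
                report["stages"]["permanova"]["infection_p"] = float(
                    paired.table.loc[0, "p"])

        if "genetics" in enabled or "mantel" in enabled:
            if panel is None and "simulate" in enabled:
                raise ValueError("genetics stages need simulated or loaded genotypes")

        if "mantel" in enabled and panel is not None:
            s = stage_seed(config.seed, "mantel")
            gdist = nei_pi_distance_from_panel(panel)
            series = {}
            for t in sorted(meta["timepoint"].unique()):
                ids = meta.index[(meta["timepoint"] == t) & ~meta["infected"]]
                sub = dist.subset(ids.tolist())
                glabels = meta.loc[ids, "genotype"].tolist()
                gsub = gdist.subset(glabels)
                gsub = type(gsub)(gsub.values, ids.tolist(), gsub.metric)
                r = mantel(sub, gsub, n_perm=config.n_perm, seed=s + int(t))
                series[int(t)] = {"r": r.r, "p": r.p_value}
            pd.DataFrame(series).T.rename_axis("timepoint").to_csv(
                out / "mantel_series.tsv", sep="\t")
            report["stages"]["mantel"] = series

        ts = None
        if "trajectories" in enabled:
            base = pcoa(dist, k=config.nmds_axes)
            uninf = meta.index[~meta["infected"]]
            base_sub = type(base)(base.coordinates.loc[uninf], "pcoa")
            ts = build_trajectories(base_sub, meta.loc[uninf])
            mts = trajectory_metrics(ts)
            tests = trajectory_group_tests(mts)
            mts.table.to_csv(out / "trajectory_metrics.tsv", sep="\t")
            tests.anova.to_csv(out / "trajectory_anova.tsv", sep="\t",
                               index=False)
            mean_trajectory(ts).to_long().to_csv(out / "mean_trajectories.tsv",
                                                 sep="\t", index=False)
            report["stages"]["trajectories"] = {
                "n_subjects": len(ts.subjects),
                "mean_directionality": float(
                    mts.table["directionality"].mean()),
                "total_reversals": int(mts.table["n_reversals"].sum()),
                "anova": tests.anova.to_dict("records"),
            }

        if "influence" in enabled:
            infl = otu_removal_influence(table, n_axes=config.nmds_axes)
            infl.table.to_csv(out / "otu_influence.tsv", sep="\t")
            report["stages"]["influence"] = {
                "n_significant": len(infl.significant_otus),
                "top": infl.table["influence"].idxmax(),
            }

        core_sub = None
        if "core" in enabled:
            core_sub = select_core(table, "subpopulation", config.n_core)
            core_time = select_core(table, "timepoint", config.n_core)
            core = core_intersection(core_sub, core_time)
            core.to_frame(table).to_csv(out / "core_otus.tsv", sep="\t")
            report["stages"]["core"] = {
                "n_subpop": len(core_sub), "n_time": len(core_time),
                "n_intersection": len(core),
            }

        if "te" in enabled:
            te = time_explainability(table)
            te.table.to_csv(out / "time_explainability.tsv", sep="\t")
            report["stages"]["te"] = {
                "n_tested": len(te.table),
                "n_significant": len(te.significant_otus),
                "mean_te": float(te.table["te"].mean()),
            }

        if "indval" in enabled:
            s = stage_seed(config.seed, "indval")
            iv = indval(table, "infected", n_perm=config.n_perm, seed=s)
            iv.table.to_csv(out / "indval.tsv", sep="\t")
            report["stages"]["indval"] = {
                "n_significant": len(iv.significant_otus),
            }

        if "networks" in enabled:
            s = stage_seed(config.seed, "networks")
            net_report = {}
            for t in sorted(meta["timepoint"].unique()):
                sub = table.subset_samples(
                    meta.index[meta["timepoint"] == t].tolist())
                if sub.n_samples < 10:
                    continue
                clr = clr_transform(sub)
                net = infer_network(clr, seed=s + int(t), timepoint=int(t),
                                    **config.network_kw)
                detect_modules(net)
                roles = zi_pi(net)
                net.to_edge_tsv(out / f"network_t{t}.tsv")
                net.to_graphml(out / f"network_t{t}.graphml")
                roles.table.to_csv(out / f"node_roles_t{t}.tsv", sep="\t")
                entry = {"n_edges": net.n_edges,
                         "n_modules": len(set(net.modules.values())),
                         "roles": roles.table["role"].value_counts().to_dict()}
                if table.otu_meta is not None:
                    gs = guild_summary(net, table.otu_meta)
                    gs.table.to_csv(out / f"guild_summary_t{t}.tsv", sep="\t")
                    cls = class_edge_prop_safe(net, table.otu_meta)
                    if cls is not None:
                        cls.to_csv(out / f"class_edges_t{t}.tsv", sep="\t",
                                   index=False)
                net_report[int(t)] = entry
            report["stages"]["networks"] = net_report

        if "genetics" in enabled and panel is not None:
            s = stage_seed(config.seed, "genetics")
            from .genetics import GenotypeMatrix

            gm = GenotypeMatrix(panel.dosages.astype(float), panel.snp_pos)
            K = kinship_matrix(gm)
            # phenotype: per-genotype score at the final timepoint on
            # whichever of the first two ordination axes clusters more with
            # subpopulation (one-way ANOVA F)
            from scipy import stats as _sps

            tmax = meta["timepoint"].max()
            ids = meta.index[(meta["timepoint"] == tmax) & ~meta["infected"]]
            src = (ordn or pcoa(dist, 2)).coordinates
            lab = meta.loc[ids, "subpopulation"]

            def _subpop_f(col):
                v = src.loc[ids, col].to_numpy()
                groups = [v[(lab == u).to_numpy()] for u in lab.unique()]
                f, _ = _sps.f_oneway(*groups)
                return f if np.isfinite(f) else 0.0

            axis = max(src.columns[:2], key=_subpop_f)
            pheno = src.loc[ids, axis]
            pheno.index = meta.loc[ids, "genotype"]
            pheno = pheno.groupby(level=0).mean().loc[
                [g for g in K.ids if g in set(meta.loc[ids, "genotype"])]]
            Ksub = K.aligned(pheno.index.tolist())
            from .genetics import KinshipMatrix as KM

            h2 = pseudo_heritability(pheno.to_numpy(),
                                     KM(Ksub, pheno.index.tolist()))
            gdist = nei_pi_distance(gm).subset(pheno.index.tolist())
            cov, shares = svd_covariates(gdist, n_pc=min(10, len(pheno) - 2))
            gm_sub = GenotypeMatrix(gm.dosages.loc[pheno.index],
                                    gm.snp_pos)
            gw = gwas_scan(pheno.to_numpy(), gm_sub, cov)
            gw.to_tsv(out / "gwas.tsv")
            report["stages"]["genetics"] = {
                "h2": h2.h2, "h2_se": h2.se,
                "lambda_gc": gw.lambda_gc,
                "top_snp": gw.table.loc[gw.table["p"].idxmin(), "snp"]
                if gw.table["p"].notna().any() else None,
                "n_bonferroni": int(gw.table["bonf_flag"].sum()),
                "svd_var_shares": [float(v) for v in shares[:3]],
            }

    report["runtime_s"] = round(time.time() - t0, 2)
    assert validate_report(report)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report


def nei_pi_distance_from_panel(panel):
    from .genetics import GenotypeMatrix, nei_pi_distance as npi

    gm = GenotypeMatrix(panel.dosages.astype(float), panel.snp_pos)
    return npi(gm)


def class_edge_prop_safe(net, otu_meta):
    from .networks import class_edge_proportions

    try:
        return class_edge_proportions(net, otu_meta)
    except Exception:
        return None
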