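"""End-to-end orchestration: load -> summary stats -> ABC -> model check ->
per-gene nulls -> rank tests -> HKA/ML-HKA -> pathway correlation -> dN/dS.

Every stage writes a TSV into the output directory and the run manifest
records every setting and seed needed to reproduce any number in them.
p-values are reported raw, one per gene and test, as is standard for
gene-by-gene selection scans; a Benjamini–Hochberg column can be requested.
"""

from __future__ import annotations

import glob
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abcfit, dnds, hka, io as cio, neutrality, orient, pathway, sumstats
from .divsim import BundleTemplate
from .types import SimConfig, StudyBundle

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    fasta_paths: list[str]
    genotype_table_path: str
    metadata_path: str
    registry_path: str
    outdir: str
    seed: int
    ortholog_fasta_paths: list[str] = field(default_factory=list)
    abc_sims: int = 100_000
    abc_tolerance: float = 1e-2
    abc_n_pred: int = 500
    null_sims: int = 10_000
    theta_window: float = 1.5
    pathway_overrides: dict = field(default_factory=dict)
    mlhka_selected: list = field(default_factory=lambda: [["PDS"], ["CRTISO", "LCYB1", "LCYE"]])
    fdr_column: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if isinstance(raw.get("fasta_paths"), str):
            raw["fasta_paths"] = sorted(glob.glob(raw["fasta_paths"]))
        if isinstance(raw.get("ortholog_fasta_paths"), str):
            raw["ortholog_fasta_paths"] = sorted(glob.glob(raw["ortholog_fasta_paths"]))
        return cls(**raw)


def _stage(name):
    logger.info("stage: %s", name)


# ------------------------------------------------------------ stages

def prepare_candidates(bundle: StudyBundle):
    """Gap-exclude candidate alignments; orient and estimate misorientation
    where an outgroup is present."""
    prepared = {}
    for gene in bundle.loci_of_kind("candidate"):
        aln = orient.exclude_gap_sites(bundle.alignments[gene])
        oriented = est = None
        if aln.outgroup is not None:
            oriented = orient.orient_alleles(aln)
            est = orient.estimate_misorientation_rate(aln)
        prepared[gene] = (aln, oriented, est)
    return prepared


def observed_stats_table(bundle: StudyBundle, prepared) -> pd.DataFrame:
    grouping = bundle.group_of()
    rows = []
    for gene, (aln, oriented, _est) in prepared.items():
        st = sumstats.basic_seq_stats(aln)
        h = sumstats.faywu_H_norm(oriented) if oriented is not None else float("nan")
        fst = sumstats.hudson_fst(aln, grouping).value
        rows.append((gene, st.n, st.L, st.S, st.theta_w, st.pi, st.pi_site, st.K,
                     st.D, h, fst))
    return pd.DataFrame(rows, columns=["gene", "n", "L", "S", "theta_w", "pi",
                                       "pi_per_site", "K", "D", "H", "FST"])


def fit_abc(bundle: StudyBundle, cfg: PipelineConfig, rng: np.random.Generator):
    priors = abcfit.default_priors()
    template = BundleTemplate.from_bundle(bundle)
    observed = sumstats.abc_summary_vector(bundle)
    draws = priors.sample(cfg.abc_sims, rng)
    table = abcfit.simulate_reference_table(draws, template, rng, priors=priors)
    support = {name: priors.support(name) for name in abcfit.PARAM_NAMES}
    posterior = abcfit.abc_loclinear_fit(observed, table, cfg.abc_tolerance,
                                         support=support)
    return priors, template, observed, table, posterior


def run_neutrality_tests(bundle: StudyBundle, prepared, posterior,
                         cfg: PipelineConfig, rng: np.random.Generator):
    """Rank tests for D, H and FST on pooled / geographic / color sample sets."""
    grouping = bundle.group_of()
    west_ids = bundle.ids_in_group("West")
    east_ids = bundle.ids_in_group("East")
    composition = bundle.color_composition()
    results = []
    for gene, (aln, oriented, est) in prepared.items():
        info = bundle.registry[gene]
        m = est.m if est is not None else 0.0
        sim_cfg = SimConfig(n_west=len(west_ids), n_east=len(east_ids),
                            length=info.length, ploidy=1)
        draws = neutrality.resample_posterior(posterior, cfg.null_sims, rng)
        nulls = neutrality.gene_null_distribution(info, draws, m, sim_cfg, rng,
                                                  keep_sims=True)
        st = sumstats.basic_seq_stats(aln)
        # pooled / West / East D
        for sample_set, ids, key in (("pooled", None, "D_pooled"),
                                     ("West", west_ids, "D_west"),
                                     ("East", east_ids, "D_east")):
            sub = aln if ids is None else aln.subset([i for i in ids if i in aln.sequences])
            d_obs = sumstats.tajima_D(sub)
            if np.isfinite(d_obs):
                r = neutrality.rank_test(d_obs, nulls[key], "two_tailed", sample_set)
                results.append(("D", sample_set, gene, r.observed, r.p, r.n_sims_used))
        # pooled / West / East H (orientation done once on the full alignment)
        if oriented is not None:
            ids_order = list(aln.sequences)
            for sample_set, ids, key in (("pooled", None, "H_pooled"),
                                         ("West", west_ids, "H_west"),
                                         ("East", east_ids, "H_east")):
                if ids is None:
                    h_obs = sumstats.faywu_H_norm(oriented)
                else:
                    sub_aln = aln.subset([i for i in ids if i in aln.sequences])
                    sub_or = orient.orient_alleles(sub_aln, aln.outgroup)
                    h_obs = sumstats.faywu_H_norm(sub_or)
                if np.isfinite(h_obs):
                    r = neutrality.rank_test(h_obs, nulls[key], "one_tailed_low", sample_set)
                    results.append(("H", sample_set, gene, r.observed, r.p, r.n_sims_used))
        # geographic FST, theta_w-matched
        fst_obs = sumstats.hudson_fst(aln, grouping).value
        if np.isfinite(fst_obs):
            try:
                r = neutrality.fst_theta_matched_test(fst_obs, st.theta_w, nulls["FST"],
                                                      window=cfg.theta_window)
                results.append(("FST", "geographic", gene, r.observed, r.p, r.n_sims_used))
            except ValueError as exc:
                logger.warning("FST test skipped for %s: %s", gene, exc)
        # color-group tests
        sims = nulls["FST"].sims
        theta_sims = nulls["FST"].theta_w
        for color, comp in composition.items():
            if comp["West"] + comp["East"] < 4:
                continue
            ids = [i for i in bundle.ids_in_color(color) if i in aln.sequences]
            sub_aln = aln.subset(ids)
            d_obs = sumstats.tajima_D(sub_aln)
            if np.isfinite(d_obs):
                r = neutrality.colorgroup_test(d_obs, sims, comp, "D", gene, rng,
                                               "two_tailed", f"color:{color}")
                results.append(("D", f"color:{color}", gene, r.observed, r.p, r.n_sims_used))
            if aln.outgroup is not None:
                h_obs = sumstats.faywu_H_norm(orient.orient_alleles(sub_aln, aln.outgroup))
                if np.isfinite(h_obs):
                    r = neutrality.colorgroup_test(h_obs, sims, comp, "H", gene, rng,
                                                   "one_tailed_low", f"color:{color}")
                    results.append(("H", f"color:{color}", gene, r.observed, r.p,
                                    r.n_sims_used))
        # color-group FST across all color groups, theta_w-matched
        color_of = bundle.color_of()
        cg = {i: color_of[i] for i in aln.sequences}
        usable = {c for c, n in pd.Series(list(cg.values())).value_counts().items() if n >= 2}
        if len(usable) >= 2:
            cfst_obs = sumstats.hudson_fst(
                aln.subset([i for i in aln.sequences if cg[i] in usable]),
                cg).value
            comp_usable = {c: composition[c] for c in composition if c in usable}
            if np.isfinite(cfst_obs):
                try:
                    r = neutrality.colorgroup_test(
                        cfst_obs, sims, comp_usable, "FST", gene, rng, "two_tailed",
                        "color", theta_w=theta_sims, observed_theta_w=st.theta_w,
                        window=cfg.theta_window)
                    results.append(("FST", "color", gene, r.observed, r.p, r.n_sims_used))
                except ValueError as exc:
                    logger.warning("color FST test skipped for %s: %s", gene, exc)
    return pd.DataFrame(results, columns=["statistic", "sample_set", "gene",
                                          "observed", "p", "n_sims"])


def run_hka(bundle: StudyBundle, prepared) -> tuple[pd.DataFrame, pd.DataFrame]:
    counts = {}
    for gene, (aln, _o, _e) in prepared.items():
        if aln.outgroup is None:
            continue
        counts[gene] = hka.hka_counts_from_alignment(aln)
    genes = sorted(counts)
    pair_rows = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            try:
                chi2, p = hka.pairwise_hka(counts[genes[i]], counts[genes[j]])
            except ValueError as exc:
                logger.warning("pairwise HKA %s-%s skipped: %s", genes[i], genes[j], exc)
                continue
            pair_rows.append((genes[i], genes[j], chi2, p))
    pair_df = pd.DataFrame(pair_rows, columns=["locusA", "locusB", "chi2", "p"])
    return pair_df, pd.DataFrame(
        [(c.name, c.n, c.S, c.D_div, c.L) for c in counts.values()],
        columns=["locus", "n", "S", "D_div", "L"])


def run_mlhka(bundle: StudyBundle, prepared, selected_sets) -> pd.DataFrame:
    counts = [hka.hka_counts_from_alignment(aln)
              for _g, (aln, _o, _e) in prepared.items() if aln.outgroup is not None]
    rows = []
    for sel in selected_sets:
        fit = hka.ml_hka(counts, set(sel))
        for name, k in fit.k.items():
            rows.append(("+".join(sel), name, k, fit.theta[name], fit.T,
                         fit.lrt, fit.df, fit.p_value))
    return pd.DataFrame(rows, columns=["model", "locus", "k", "theta_per_site",
                                       "T", "LRT", "df", "p"])


def run_pathway(neut_df: pd.DataFrame, registry, overrides) -> dict:
    genes = sorted(neut_df["gene"].unique())
    assign = pathway.pathway_positions(genes, overrides)
    pvals = neut_df["p"].to_numpy()
    pos = np.array([assign[g] for g in neut_df["gene"]])
    tau_all, p_all = pathway.kendall_tau(pos, pvals)
    per_stat = {}
    for stat in neut_df["statistic"].unique():
        sub = neut_df[neut_df["statistic"] == stat]
        if len(sub) >= 3:
            per_stat[stat] = pathway.kendall_tau(
                np.array([assign[g] for g in sub["gene"]]), sub["p"].to_numpy())
    by_gene = {g: neut_df.loc[neut_df["gene"] == g, "p"].to_numpy() for g in genes}
    (kw_stat, kw_p), (w_stat, w_p) = pathway.group_location_tests(by_gene)
    return {"positions": assign.positions, "tau_all": tau_all, "tau_all_p": p_all,
            "tau_per_stat": per_stat, "kruskal": (kw_stat, kw_p),
            "wilcoxon_updown": (w_stat, w_p)}


def run_dnds(fasta_paths, positions: dict[str, int]):
    alns = []
    for path in fasta_paths:
        la = cio.read_locus_fasta(path)
        seqs = dict(la.sequences)
        if la.outgroup is not None:
            seqs["outgroup"] = la.outgroup
        alns.append(dnds.CodonAlignment(gene=la.name, sequences=seqs))
    table = dnds.pairwise_table(alns)
    out = {"table": table}
    known = table["gene"].isin(positions)
    sub = table[known].dropna(subset=["omega"])
    if len(sub) >= 3 and sub["gene"].nunique() >= 2:
        pos = np.array([positions[g] for g in sub["gene"]])
        out["tau_omega"] = pathway.kendall_tau(pos, sub["omega"].to_numpy())
        sub_n = table[known].dropna(subset=["dN"])
        out["tau_dn"] = pathway.kendall_tau(
            np.array([positions[g] for g in sub_n["gene"]]), sub_n["dN"].to_numpy())
        sub_s = table[known].dropna(subset=["dS"])
        out["tau_ds"] = pathway.kendall_tau(
            np.array([positions[g] for g in sub_s["gene"]]), sub_s["dS"].to_numpy())
    return out


# ------------------------------------------------------------ run-all

def run_full_study(cfg: PipelineConfig) -> dict:
    t0 = time.time()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    _stage("load")
    bundle = cio.read_study_bundle(cfg.fasta_paths, cfg.genotype_table_path,
                                   cfg.metadata_path, cfg.registry_path)
    prepared = prepare_candidates(bundle)

    _stage("summary statistics")
    stats_df = observed_stats_table(bundle, prepared)
    stats_df.to_csv(outdir / "observed_stats.tsv", sep="\t", index=False)

    _stage("abc fit")
    _priors, template, observed, table, posterior = fit_abc(bundle, cfg, rng)
    table.to_csv(outdir / "reference_table.tsv", sep="\t", index=False)
    post_df = posterior.adjusted.copy()
    post_df["weight"] = posterior.weights
    post_df.to_csv(outdir / "posterior.tsv", sep="\t", index=False)

    _stage("model check")
    check = abcfit.posterior_predictive_check(posterior, template, observed,
                                              max(100, cfg.abc_n_pred), rng,
                                              prior_table=table)
    check.rank_pvalues.rename("p").to_csv(outdir / "model_check_ranks.tsv", sep="\t")
    if check.pca_coords is not None:
        check.pca_coords.to_csv(outdir / "model_check_pca.tsv", sep="\t", index=False)

    _stage("neutrality tests")
    neut_df = run_neutrality_tests(bundle, prepared, posterior, cfg, rng)
    if cfg.fdr_column and len(neut_df):
        from scipy.stats import false_discovery_control
        neut_df["p_bh"] = false_discovery_control(neut_df["p"], method="bh")
    neut_df.to_csv(outdir / "neutrality_tests.tsv", sep="\t", index=False)
    _write_table2_like(neut_df, outdir / "table_D_H.tsv")
    _write_table3_like(neut_df, stats_df, outdir / "table_FST.tsv")

    _stage("hka")
    hka_ok = any(aln.outgroup is not None for aln, _o, _e in prepared.values())
    if hka_ok:
        pair_df, counts_df = run_hka(bundle, prepared)
        pair_df.to_csv(outdir / "hka_pairwise.tsv", sep="\t", index=False)
        counts_df.to_csv(outdir / "hka_counts.tsv", sep="\t", index=False)
        mlhka_df = run_mlhka(bundle, prepared, cfg.mlhka_selected)
        mlhka_df.to_csv(outdir / "mlhka.tsv", sep="\t", index=False)
    else:
        logger.warning("no outgroup sequences: HKA and ML-HKA skipped")

    _stage("pathway correlation")
    path_report = run_pathway(neut_df, bundle.registry, cfg.pathway_overrides)
    with open(outdir / "pathway_correlation.json", "w") as fh:
        json.dump(path_report, fh, indent=2, default=float)

    dnds_report = None
    if cfg.ortholog_fasta_paths:
        _stage("dnds")
        dnds_report = run_dnds(cfg.ortholog_fasta_paths, path_report["positions"])
        dnds_report["table"].to_csv(outdir / "dnds_pairwise.tsv", sep="\t", index=False)

    manifest = {
        "seed": cfg.seed,
        "abc": {"sims": cfg.abc_sims, "tolerance": cfg.abc_tolerance,
                "n_pred": cfg.abc_n_pred},
        "nulls": {"sims": cfg.null_sims, "theta_window": cfg.theta_window},
        "mlhka_selected": cfg.mlhka_selected,
        "pathway_overrides": cfg.pathway_overrides,
        "inputs": {"fasta": cfg.fasta_paths, "genotypes": cfg.genotype_table_path,
                   "metadata": cfg.metadata_path, "registry": cfg.registry_path,
                   "orthologs": cfg.ortholog_fasta_paths},
        "runtime_s": round(time.time() - t0, 1),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return {"bundle": bundle, "stats": stats_df, "posterior": posterior,
            "neutrality": neut_df, "pathway": path_report, "dnds": dnds_report,
            "check": check}


def _write_table2_like(neut_df: pd.DataFrame, path) -> None:
    """Gene x {D, p, H, p} x {pooled, West, East} wide table."""
    rows = {}
    for r in neut_df.itertuples(index=False):
        if r.statistic in ("D", "H") and r.sample_set in ("pooled", "West", "East"):
            rows.setdefault(r.gene, {})[f"{r.statistic}_{r.sample_set}"] = r.observed
            rows.setdefault(r.gene, {})[f"{r.statistic}_{r.sample_set}_p"] = r.p
    cols = [f"{s}_{g}{suf}" for g in ("pooled", "West", "East")
            for s in ("D", "H") for suf in ("", "_p")]
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=cols)
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def _write_table3_like(neut_df: pd.DataFrame, stats_df: pd.DataFrame, path) -> None:
    """Gene x {theta_w, FST, p, n} for geographic and color groupings."""
    theta = stats_df.set_index("gene")["theta_w"]
    rows = {}
    for r in neut_df.itertuples(index=False):
        if r.statistic == "FST" and r.sample_set in ("geographic", "color"):
            d = rows.setdefault(r.gene, {})
            d[f"FST_{r.sample_set}"] = r.observed
            d[f"FST_{r.sample_set}_p"] = r.p
            d[f"FST_{r.sample_set}_n"] = r.n_sims
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.insert(0, "theta_w", theta.reindex(df.index))
    df.index.name = "gene"
    df.to_csv(path, sep="\t")
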