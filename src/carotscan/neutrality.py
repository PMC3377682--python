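"""Simulation-based neutrality tests for the candidate genes.

Each candidate gene is compared with its own null distribution: parameter
combinations (N_W, N_E, N_A, T_d, mu_seq) resampled from the ABC posterior,
one infinite-sites simulation per draw at the gene's own fragment length and
sample configuration, misorientation injected at the gene's estimated rate.
The observed statistic is then ranked within the simulated distribution with
a pseudo-count, p = (#{sim <= obs} + 1)/(n + 1): two-tailed for Tajima's D
and FST, one-tailed (low) for normalised Fay–Wu H.

FST is additionally tested against the theta_w-matched subset of simulations
(|theta_w_sim - theta_w_obs| <= 1.5, per-locus units), since FST rank tests
are sensitive to the mutation rate. Color-group tests subsample, from every
simulated dataset, as many sequences from the simulated Western and Eastern
samples as that color group contains in the observed metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .divsim import (
    SeqSimResult,
    apply_misorientation_result,
    simulate_sequence_tables,
)
from .sumstats import (
    faywu_h_from_derived,
    harmonic,
    hudson_fst_from_site_counts,
    tajima_d_from_derived,
)
from .types import DivergenceModelParams, LocusInfo, SimConfig

logger = logging.getLogger(__name__)

STAT_NAMES = ("D_pooled", "D_west", "D_east", "H_pooled", "H_west", "H_east",
              "FST", "theta_w")


@dataclass
class NullDistribution:
    """Simulated values of one statistic for one gene, with companion theta_w."""

    gene: str
    statistic: str
    values: np.ndarray
    theta_w: np.ndarray
    config: SimConfig
    sims: list[SeqSimResult] | None = None   # retained when subsampling tests need them

    def __post_init__(self):
        keep = np.isfinite(self.values)
        dropped = int((~keep).sum())
        if dropped:
            logger.info("null for %s/%s: dropped %d undefined simulated values",
                        self.gene, self.statistic, dropped)
        self._finite_values = self.values[keep]
        self._finite_theta = self.theta_w[keep]

    @property
    def n_sims(self) -> int:
        return int(self._finite_values.size)


@dataclass(frozen=True)
class NeutralityResult:
    gene: str
    statistic: str
    sample_set: str
    observed: float
    p: float
    tail: str                  # two_tailed | one_tailed_low
    n_sims_used: int


# ---------------------------------------------------------- resampling

def resample_posterior(posterior, n: int, seed) -> pd.DataFrame:
    """n joint (N_W, N_E, N_A, T_d, mu_seq) draws from the weighted posterior."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = posterior.resample(n, rng)
    cols = [c for c in ("N_W", "N_E", "N_A", "T_d", "mu_seq") if c in draws.columns]
    return draws[cols]


# ------------------------------------------------------ null building

def _sim_statistics(sim: SeqSimResult) -> dict[str, float]:
    idx_w = np.where(sim.west)[0]
    idx_e = np.where(~sim.west)[0]
    out: dict[str, float] = {}
    dc_pool, n_pool = sim.derived_counts()
    dc_w, n_w = sim.derived_counts(idx_w)
    dc_e, n_e = sim.derived_counts(idx_e)
    out["D_pooled"] = tajima_d_from_derived(dc_pool, n_pool)
    out["D_west"] = tajima_d_from_derived(dc_w, n_w)
    out["D_east"] = tajima_d_from_derived(dc_e, n_e)
    out["H_pooled"] = faywu_h_from_derived(dc_pool, n_pool)
    out["H_west"] = faywu_h_from_derived(dc_w, n_w)
    out["H_east"] = faywu_h_from_derived(dc_e, n_e)
    # FST from unoriented truth counts (orientation-invariant)
    cw = sim.genotypes[:, idx_w].sum(axis=1)
    ce = sim.genotypes[:, idx_e].sum(axis=1)
    poly = ((cw + ce) > 0) & ((cw + ce) < sim.n)
    out["FST"] = hudson_fst_from_site_counts(cw[poly], ce[poly], len(idx_w), len(idx_e))
    out["theta_w"] = dc_pool.size / harmonic(n_pool)
    return out


def gene_null_distribution(gene: LocusInfo, draws: pd.DataFrame, m: float,
                           config: SimConfig, seed,
                           keep_sims: bool = False) -> dict[str, NullDistribution]:
    """One null distribution per statistic for one gene.

    For every posterior draw: simulate the locus (infinite sites, the gene's
    length), flip site polarities at misorientation rate ``m``, and compute
    D, normalised H (pooled/West/East), West–East Hudson FST and per-locus
    theta_w. Simulator failures are logged and the row skipped.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = {name: [] for name in STAT_NAMES}
    sims: list[SeqSimResult] = []
    for row in draws.itertuples(index=False):
        params = DivergenceModelParams(
            N_W=row.N_W, N_E=row.N_E, N_A=row.N_A, T_d=row.T_d, mu_seq=row.mu_seq)
        try:
            sim = simulate_sequence_tables(params, config, rng)
            sim = apply_misorientation_result(sim, m, rng)
            stats = _sim_statistics(sim)
        except Exception:   # propagate nothing; log and skip the row
            logger.exception("null simulation failed for gene %s; row skipped", gene.name)
            continue
        for name in STAT_NAMES:
            values[name].append(stats[name])
        if keep_sims:
            sims.append(sim)
    theta = np.asarray(values["theta_w"], dtype=float)
    return {
        name: NullDistribution(
            gene=gene.name, statistic=name,
            values=np.asarray(values[name], dtype=float),
            theta_w=theta, config=config,
            sims=sims if keep_sims else None)
        for name in STAT_NAMES
    }


# ------------------------------------------------------------ rank tests

def rank_p_value(observed: float, sims: np.ndarray, tail: str) -> float:
    """Monte-Carlo rank p with a pseudo-count and midrank tie handling.

    r_low = (#{sim < obs} + 0.5 #{sim = obs} + 1)/(n + 1) and symmetrically
    r_high; one_tailed_low p = r_low, two_tailed p = min(1, 2 min(r_low,
    r_high)). Both tails carry the +1 pseudo-count, so p is never 0.
    """
    n = sims.size
    less = np.sum(sims < observed)
    ties = np.sum(sims == observed)
    r_low = (less + 0.5 * ties + 1) / (n + 1)
    r_high = (n - less - 0.5 * ties + 1) / (n + 1)
    if tail == "one_tailed_low":
        return float(min(1.0, r_low))
    if tail == "two_tailed":
        return float(min(1.0, 2.0 * min(r_low, r_high)))
    raise ValueError(f"unknown tail {tail!r}")


def rank_test(observed: float, null: NullDistribution, tail: str = "two_tailed",
              sample_set: str = "pooled") -> NeutralityResult:
    """Rank the observed statistic within its simulated null."""
    if not np.isfinite(observed):
        raise ValueError(f"observed {null.statistic} for {null.gene} is undefined")
    sims = null._finite_values
    if sims.size == 0:
        raise ValueError("empty null distribution")
    p = rank_p_value(observed, sims, tail)
    return NeutralityResult(gene=null.gene, statistic=null.statistic,
                            sample_set=sample_set, observed=float(observed),
                            p=p, tail=tail, n_sims_used=int(sims.size))


def fst_theta_matched_test(observed_fst: float, observed_theta_w: float,
                           null: NullDistribution, window: float = 1.5,
                           sample_set: str = "geographic") -> NeutralityResult:
    """Two-tailed FST rank test on theta_w-matched simulations.

    Only simulations with |theta_w_sim - theta_w_obs| <= window (per-locus
    units) enter the null; the count retained is reported as n_sims_used.
    """
    if not np.isfinite(observed_fst):
        raise ValueError("observed FST is undefined")
    sims = null._finite_values
    theta = null._finite_theta
    mask = np.abs(theta - observed_theta_w) <= window
    matched = sims[mask]
    if matched.size == 0:
        raise ValueError("no matched simulations within the theta_w window")
    p = rank_p_value(observed_fst, matched, "two_tailed")
    return NeutralityResult(gene=null.gene, statistic=null.statistic,
                            sample_set=sample_set, observed=float(observed_fst),
                            p=p, tail="two_tailed", n_sims_used=int(matched.size))


# -------------------------------------------------- color-group tests

def _pooled_fst_binary(genotypes: np.ndarray, groups: list[np.ndarray]) -> float:
    """Hudson-style pooled FST over >= 2 groups from a boolean site matrix."""
    wd = 0.0
    wp = 0.0
    for idx in groups:
        ng = len(idx)
        c = genotypes[:, idx].sum(axis=1)
        wd += float(np.sum(c * (ng - c)))
        wp += ng * (ng - 1) / 2.0
    bd = 0.0
    bp = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            ci = genotypes[:, groups[i]].sum(axis=1)
            cj = genotypes[:, groups[j]].sum(axis=1)
            ni, nj = len(groups[i]), len(groups[j])
            bd += float(np.sum(ci * (nj - cj) + cj * (ni - ci)))
            bp += ni * nj
    if bp == 0 or bd == 0:
        return float("nan")
    return 1.0 - (wd / wp) / (bd / bp)


def _subsample_indices(sim: SeqSimResult, n_from_west: int, n_from_east: int,
                       rng: np.random.Generator) -> np.ndarray:
    idx_w = np.where(sim.west)[0]
    idx_e = np.where(~sim.west)[0]
    if n_from_west > len(idx_w) or n_from_east > len(idx_e):
        raise ValueError("requested color-group counts exceed simulated sample sizes")
    take_w = rng.choice(idx_w, size=n_from_west, replace=False)
    take_e = rng.choice(idx_e, size=n_from_east, replace=False)
    return np.concatenate([take_w, take_e])


def colorgroup_null_stats(sims: list[SeqSimResult], composition, statistic: str,
                          rng: np.random.Generator) -> np.ndarray:
    """Simulated null values of a statistic under color-group subsampling.

    For D and H, ``composition`` is {"West": k_w, "East": k_e} for a single
    color group; for FST it is the full color -> {West, East} table and every
    simulated dataset is partitioned into color-group subsamples whose pooled
    multi-group FST is computed.
    """
    out = np.empty(len(sims))
    for s, sim in enumerate(sims):
        if statistic in ("D", "H"):
            subset = _subsample_indices(sim, composition["West"], composition["East"], rng)
            dc, n_sub = sim.derived_counts(subset)
            out[s] = (tajima_d_from_derived(dc, n_sub) if statistic == "D"
                      else faywu_h_from_derived(dc, n_sub))
        elif statistic == "FST":
            idx_w = list(rng.permutation(np.where(sim.west)[0]))
            idx_e = list(rng.permutation(np.where(~sim.west)[0]))
            groups = []
            for _color, comp in composition.items():
                take = [idx_w.pop() for _ in range(comp["West"])] + \
                       [idx_e.pop() for _ in range(comp["East"])]
                if len(take) >= 2:
                    groups.append(np.array(take, dtype=int))
            out[s] = _pooled_fst_binary(sim.genotypes, groups) if len(groups) >= 2 \
                else float("nan")
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
    return out


def colorgroup_test(observed: float, sims: list[SeqSimResult], composition,
                    statistic: str, gene: str, seed, tail: str = "two_tailed",
                    sample_set: str = "color",
                    theta_w: np.ndarray | None = None,
                    observed_theta_w: float | None = None,
                    window: float | None = None) -> NeutralityResult:
    """Rank test against color-group-subsampled nulls.

    When ``theta_w``/``observed_theta_w``/``window`` are given (FST test),
    the null is restricted to theta_w-matched simulations first.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = colorgroup_null_stats(sims, composition, statistic, rng)
    keep = np.isfinite(values)
    if window is not None and theta_w is not None and observed_theta_w is not None:
        keep &= np.abs(np.asarray(theta_w) - observed_theta_w) <= window
    values = values[keep]
    if values.size == 0:
        raise ValueError("no usable color-group simulations")
    p = rank_p_value(observed, values, tail)
    return NeutralityResult(gene=gene, statistic=statistic, sample_set=sample_set,
                            observed=float(observed), p=p, tail=tail,
                            n_sims_used=int(values.size))
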