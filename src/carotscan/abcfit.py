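"""Rejection ABC with local linear-regression adjustment (Beaumont-style).

The divergence-model parameters are drawn from their priors, datasets shaped
like the observed one are simulated per draw, and the draws whose summary
statistics fall nearest the observed vector (a fixed acceptance proportion,
default 10^-2) are kept. Accepted draws are weighted with an Epanechnikov
kernel in standardized Euclidean distance and adjusted by a weighted linear
regression of each (transformed) parameter on the centred statistics.

Priors: the divergence time T_d is Normal(500, 100) truncated to [350, 750]
generations (the study's documented cultivation-history prior). The remaining
priors are weakly informative, spanning plant-typical ranges: log-uniform
effective sizes in [1e2, 1e5], log-uniform mu_seq in [1e-9, 1e-7], log-uniform
mu_ssr in [1e-5, 1e-3], uniform P_SSR in [0, 0.9]; all configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .divsim import BundleTemplate, simulate_summary_stats
from .sumstats import SUMMARY_STAT_NAMES
from .types import DivergenceModelParams

logger = logging.getLogger(__name__)

PARAM_NAMES = ("N_W", "N_E", "N_A", "T_d", "mu_seq", "mu_ssr", "p_ssr")
LOG_PARAMS = frozenset({"N_W", "N_E", "N_A", "mu_seq", "mu_ssr"})


# ----------------------------------------------------------------- priors

@dataclass(frozen=True)
class Marginal:
    """One prior marginal: a frozen scipy distribution plus its support."""

    dist: object
    lo: float
    hi: float
    log_scale: bool = False     # regress/adjust on log10 scale

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        x = self.dist.rvs(size=n, random_state=rng)
        return np.clip(x, self.lo, self.hi)


def point_mass(value: float) -> Marginal:
    return Marginal(dist=stats.uniform(loc=value, scale=0.0), lo=value, hi=value)


@dataclass(frozen=True)
class PriorSpec:
    marginals: dict[str, Marginal]

    def sample(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        if n < 1:
            raise ValueError("n must be >= 1")
        return pd.DataFrame({name: m.sample(n, rng) for name, m in self.marginals.items()})

    def support(self, name: str) -> tuple[float, float]:
        m = self.marginals[name]
        return m.lo, m.hi


def default_priors(
    N_bounds=(1e2, 1e5),
    mu_seq_bounds=(1e-9, 1e-7),
    mu_ssr_bounds=(1e-5, 1e-3),
    td_mean=500.0, td_sd=100.0, td_bounds=(350.0, 750.0),
    p_ssr_max=0.9,
) -> PriorSpec:
    a = (td_bounds[0] - td_mean) / td_sd
    b = (td_bounds[1] - td_mean) / td_sd
    marg = {
        "N_W": Marginal(stats.loguniform(*N_bounds), *N_bounds, log_scale=True),
        "N_E": Marginal(stats.loguniform(*N_bounds), *N_bounds, log_scale=True),
        "N_A": Marginal(stats.loguniform(*N_bounds), *N_bounds, log_scale=True),
        "T_d": Marginal(stats.truncnorm(a, b, loc=td_mean, scale=td_sd), *td_bounds),
        "mu_seq": Marginal(stats.loguniform(*mu_seq_bounds), *mu_seq_bounds, log_scale=True),
        "mu_ssr": Marginal(stats.loguniform(*mu_ssr_bounds), *mu_ssr_bounds, log_scale=True),
        "p_ssr": Marginal(stats.uniform(0.0, p_ssr_max), 0.0, p_ssr_max),
    }
    return PriorSpec(marginals=marg)


def sample_prior(priors: PriorSpec, n: int, seed) -> pd.DataFrame:
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return priors.sample(n, rng)


def params_from_row(row) -> DivergenceModelParams:
    return DivergenceModelParams(
        N_W=float(row["N_W"]), N_E=float(row["N_E"]), N_A=float(row["N_A"]),
        T_d=float(row["T_d"]), mu_seq=float(row["mu_seq"]),
        mu_ssr=float(row.get("mu_ssr", 0.0)) if hasattr(row, "get") else float(row["mu_ssr"]),
        p_ssr=float(row.get("p_ssr", 0.0)) if hasattr(row, "get") else float(row["p_ssr"]),
    )


# -------------------------------------------------------- reference table

def simulate_reference_table(draws: pd.DataFrame, template: BundleTemplate, seed,
                             max_retries: int = 3,
                             priors: "PriorSpec | None" = None) -> pd.DataFrame:
    """One summary-statistic vector per parameter draw.

    Rows whose statistics come out undefined (zero between-population
    diversity under an extreme low-rate draw) are first retried with fresh
    simulator noise; if a draw persistently yields undefined statistics it is
    replaced by a fresh prior draw when ``priors`` is given (keeping the
    configured row count), otherwise dropped with a warning.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stats_rows = np.empty((len(draws), len(SUMMARY_STAT_NAMES)))
    draws = draws.reset_index(drop=True).copy()
    values = draws[list(PARAM_NAMES)].to_numpy()
    for i in range(len(draws)):
        params = DivergenceModelParams(*values[i])
        vec = simulate_summary_stats(params, template, rng)
        retries = 0
        while np.isnan(vec).any() and retries < max_retries:
            retries += 1
            logger.debug("reference-table row %d: undefined statistics, retry %d",
                         i, retries)
            vec = simulate_summary_stats(params, template, rng)
        while np.isnan(vec).any() and priors is not None:
            replacement = priors.sample(1, rng)
            values[i] = replacement[list(PARAM_NAMES)].to_numpy()[0]
            draws.iloc[i] = replacement.iloc[0]
            params = DivergenceModelParams(*values[i])
            vec = simulate_summary_stats(params, template, rng)
        stats_rows[i] = vec
    table = pd.concat(
        [draws, pd.DataFrame(stats_rows, columns=list(SUMMARY_STAT_NAMES))], axis=1)
    bad = table[list(SUMMARY_STAT_NAMES)].isna().any(axis=1)
    if bad.any():
        logger.warning("dropping %d reference-table rows with undefined statistics",
                       int(bad.sum()))
        table = table[~bad].reset_index(drop=True)
    return table


# ------------------------------------------------------------- posterior

@dataclass
class Posterior:
    """Accepted ABC particles, raw and regression-adjusted, with weights."""

    raw: pd.DataFrame
    adjusted: pd.DataFrame
    weights: np.ndarray
    tolerance: float
    distances: np.ndarray = field(default=None)  # type: ignore[assignment]
    regression_ok: bool = True

    def resample(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        """n joint draws from the adjusted particles, proportional to weights."""
        w = np.asarray(self.weights, dtype=float)
        if w.sum() <= 0:
            raise ValueError("all-zero posterior weights")
        idx = rng.choice(len(self.adjusted), size=n, replace=True, p=w / w.sum())
        return self.adjusted.iloc[idx].reset_index(drop=True)


def _standardize_scales(stat_mat: np.ndarray) -> np.ndarray:
    """Per-statistic MAD scale (falling back to SD, then 1, when degenerate)."""
    med = np.median(stat_mat, axis=0)
    mad = np.median(np.abs(stat_mat - med), axis=0)
    sd = stat_mat.std(axis=0)
    scale = np.where(mad > 0, mad, sd)
    return np.where(scale > 0, scale, 1.0)


def abc_loclinear_fit(observed: np.ndarray, table: pd.DataFrame,
                      tolerance: float = 1e-2,
                      param_cols=None, stat_cols=None,
                      log_params=None, support: dict | None = None) -> Posterior:
    """Rejection + local-linear-regression ABC fit.

    ``observed`` is the summary vector in the order of ``stat_cols``. The
    ceil(tolerance * rows) draws nearest in MAD-standardized Euclidean
    distance are accepted with Epanechnikov weights w_i = 1 - (d_i/delta)^2,
    delta the largest accepted distance (that boundary particle gets weight
    0 — the open-kernel convention). Each parameter (log10 scale for
    positive-rate/size parameters) is regressed on the centred statistics by
    weighted least squares and adjusted as theta_i - (s_i - s_obs) @ beta;
    adjusted particles are clamped back to the prior support.
    """
    if not (0.0 < tolerance <= 1.0):
        raise ValueError("tolerance must be in (0, 1]")
    param_cols = list(param_cols) if param_cols is not None else \
        [c for c in PARAM_NAMES if c in table.columns]
    stat_cols = list(stat_cols) if stat_cols is not None else \
        [c for c in SUMMARY_STAT_NAMES if c in table.columns]
    log_params = set(log_params) if log_params is not None else \
        {c for c in param_cols if c in LOG_PARAMS}
    n_rows = len(table)
    n_accept = int(np.ceil(tolerance * n_rows))
    if n_rows < 1 or n_accept < 1:
        raise ValueError("reference table too small for the requested tolerance")
    stat_mat = table[stat_cols].to_numpy(dtype=float)
    observed = np.asarray(observed, dtype=float)
    scale = _standardize_scales(stat_mat)
    z = (stat_mat - observed) / scale
    dist = np.sqrt((z ** 2).sum(axis=1))
    order = np.argsort(dist, kind="stable")[:n_accept]
    accepted = table.iloc[order].reset_index(drop=True)
    d_acc = dist[order]
    delta = d_acc.max()
    if delta > 0:
        weights = 1.0 - (d_acc / delta) ** 2
    else:
        weights = np.ones_like(d_acc)
    if weights.sum() <= 0:
        weights = np.ones_like(d_acc)
    weights = weights / weights.sum()

    raw = accepted[param_cols].copy()
    # transformed parameter matrix
    theta = raw.to_numpy(dtype=float).copy()
    for j, c in enumerate(param_cols):
        if c in log_params:
            theta[:, j] = np.log10(theta[:, j])
    X = (stat_mat[order] - observed) / scale          # centred at observed
    Xd = np.hstack([np.ones((n_accept, 1)), X])
    W = np.sqrt(weights)[:, None]
    regression_ok = True
    try:
        beta, _res, rank, _sv = np.linalg.lstsq(Xd * W, theta * W, rcond=None)
        if rank < Xd.shape[1]:
            raise np.linalg.LinAlgError("rank-deficient local regression design")
        adj = theta - X @ beta[1:, :]
    except np.linalg.LinAlgError:
        logger.warning("singular local-linear design; falling back to rejection only")
        regression_ok = False
        adj = theta
    adjusted = pd.DataFrame(adj, columns=param_cols)
    for c in param_cols:
        if c in log_params:
            adjusted[c] = 10.0 ** adjusted[c]
    if support:
        for c in param_cols:
            if c in support:
                lo, hi = support[c]
                adjusted[c] = adjusted[c].clip(lo, hi)
    return Posterior(raw=raw, adjusted=adjusted, weights=weights,
                     tolerance=tolerance, distances=d_acc, regression_ok=regression_ok)


# --------------------------------------------------------- model checking

@dataclass
class ModelCheckReport:
    pca_coords: pd.DataFrame | None       # columns: set, PC1, PC2
    rank_pvalues: pd.Series               # per statistic, two-tailed
    pca_skipped: bool = False


def posterior_predictive_check(posterior: Posterior, template: BundleTemplate,
                               observed: np.ndarray, n_pred: int, seed,
                               prior_table: pd.DataFrame | None = None) -> ModelCheckReport:
    """Model check: PCA of summary statistics and per-statistic rank p-values.

    Posterior-predictive datasets are simulated from ``n_pred`` resampled
    particles. The PCA is fitted on the prior-simulated statistics (the
    reference table, if given) and the prior, posterior-predictive and
    observed clouds are projected onto PC1-PC2. Each observed statistic also
    gets a two-tailed rank p-value within its posterior-predictive
    distribution.
    """
    if n_pred < 100:
        raise ValueError("n_pred must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = posterior.resample(n_pred, rng)
    pred = np.empty((n_pred, len(SUMMARY_STAT_NAMES)))
    for i, row in enumerate(draws.itertuples(index=False)):
        params = DivergenceModelParams(**{k: getattr(row, k) for k in PARAM_NAMES})
        pred[i] = simulate_summary_stats(params, template, rng)
    pred_df = pd.DataFrame(pred, columns=list(SUMMARY_STAT_NAMES)).dropna()

    observed = np.asarray(observed, dtype=float)
    ranks = {}
    for j, name in enumerate(SUMMARY_STAT_NAMES):
        sims = pred_df[name].to_numpy()
        r = (np.sum(sims <= observed[j]) + 1) / (len(sims) + 1)
        ranks[name] = min(1.0, 2.0 * min(r, 1.0 - r))
    rank_p = pd.Series(ranks)

    pca_coords = None
    pca_skipped = False
    if prior_table is not None and len(prior_table) >= 3:
        prior_stats = prior_table[list(SUMMARY_STAT_NAMES)].to_numpy(dtype=float)
        mu = prior_stats.mean(axis=0)
        sd = prior_stats.std(axis=0)
        if (sd == 0).all():
            pca_skipped = True
        else:
            sd = np.where(sd > 0, sd, 1.0)
            zp = (prior_stats - mu) / sd
            try:
                _u, _s, vt = np.linalg.svd(zp, full_matrices=False)
                comps = vt[:2].T
                frames = []
                for label, mat in (("prior", prior_stats),
                                   ("posterior_predictive", pred_df.to_numpy()),
                                   ("observed", observed[None, :])):
                    proj = ((mat - mu) / sd) @ comps
                    frames.append(pd.DataFrame(
                        {"set": label, "PC1": proj[:, 0], "PC2": proj[:, 1]}))
                pca_coords = pd.concat(frames, ignore_index=True)
            except np.linalg.LinAlgError:
                pca_skipped = True
    else:
        pca_skipped = True
    return ModelCheckReport(pca_coords=pca_coords, rank_pvalues=rank_p,
                            pca_skipped=pca_skipped)
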