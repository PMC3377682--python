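"""HKA tests: the classic pairwise chi-square form and a maximum-likelihood
extension with per-locus selection parameters.

Model, with a single outgroup sequence and theta_i = 4 N mu_i per site:
the expected number of segregating sites at locus i among n_i sampled copies
is E[S_i] = theta_i L_i a_i, a_i = sum_{j<n_i} 1/j, and the expected
ingroup-outgroup divergence count is E[D_i] = theta_i L_i (T + 1), where T is
the species split in 2N-generation units and the +1 (= (1+f)/2 with equal
ancestral and ingroup sizes, f = 1) absorbs ancestral polymorphism at the
split. The ML extension multiplies the polymorphism rate by a selection
parameter k_i (k < 1: diversity deficit, sweep-like; k > 1: excess,
balancing-like) and lets k_i enter the ancestral half of the divergence:
S_i ~ Poisson(k_i theta_i L_i a_i), D_i ~ Poisson(theta_i L_i (T + (1+k_i)/2)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .orient import BASES
from .sumstats import harmonic
from .types import LocusAlignment


@dataclass(frozen=True)
class HKACounts:
    """Polymorphism/divergence counts for one locus."""

    name: str
    n: int          # ingroup sample size
    S: int          # segregating sites in the ingroup
    D_div: int      # fixed differences ingroup vs outgroup
    L: int          # comparable sites

    def __post_init__(self):
        if self.S < 0 or self.D_div < 0:
            raise ValueError("counts must be >= 0")
        if self.L <= 0:
            raise ValueError("L must be > 0")
        if self.n < 2:
            raise ValueError("need n >= 2")


def hka_counts_from_alignment(aln: LocusAlignment, exons_only: bool = False) -> HKACounts:
    """S, fixed-difference and comparable-site counts from a gap-excluded
    alignment with outgroup. A fixed difference is a site where every ingroup
    copy carries one base and the outgroup another."""
    if aln.outgroup is None:
        raise ValueError(f"locus {aln.name!r}: HKA needs an outgroup")
    mat = aln.matrix()
    out = np.array(list(aln.outgroup.upper()))
    if exons_only:
        if aln.exon_mask is None:
            raise ValueError(f"locus {aln.name!r}: no exon annotation")
        mat = mat[:, aln.exon_mask]
        out = out[aln.exon_mask]
    s = 0
    d = 0
    L = 0
    for j in range(mat.shape[1]):
        col = mat[:, j]
        alleles = np.unique(col[np.isin(col, BASES)])
        if len(alleles) == 0 or out[j] not in BASES:
            continue
        L += 1
        if len(alleles) > 1:
            s += 1
        elif alleles[0] != out[j]:
            d += 1
    if L == 0:
        raise ValueError(f"locus {aln.name!r}: zero comparable sites")
    return HKACounts(name=aln.name, n=mat.shape[0], S=s, D_div=d, L=L)


# ----------------------------------------------------------- pairwise HKA

def _solve_hka_moments(counts: list[HKACounts]):
    """Moment estimates (theta_i * L_i, T) from the classic HKA system:
    S_i + D_i = w_i (a_i + T + 1) per locus and sum(D) = (T + 1) sum(w_i)."""
    a = np.array([harmonic(c.n) for c in counts])
    S = np.array([c.S for c in counts], dtype=float)
    D = np.array([c.D_div for c in counts], dtype=float)
    if S.sum() == 0:
        raise ValueError("no polymorphism: HKA expectations degenerate")
    if D.sum() == 0:
        raise ValueError("no divergence: HKA expectations degenerate")

    def f(T):
        w = (S + D) / (a + T + 1.0)
        return D.sum() - (T + 1.0) * w.sum()

    lo, hi = 1e-9, 10.0
    while f(hi) > 0 and hi < 1e9:
        hi *= 10.0
    T_hat = optimize.brentq(f, lo, hi, xtol=1e-12)
    w = (S + D) / (a + T_hat + 1.0)
    return w, T_hat


def pairwise_hka(countsA: HKACounts, countsB: HKACounts) -> tuple[float, float]:
    """Classic two-locus HKA chi-square and its p-value (df = 1).

    chi2 sums (obs - exp)^2 / Var over the four observations, with
    Var(S_i) = E[S_i] + (w_i)^2 b_i (b_i = sum_{j<n_i} 1/j^2) and
    Var(D_i) = E[D_i] + w_i^2, w_i = theta_i L_i.
    """
    counts = [countsA, countsB]
    w, T_hat = _solve_hka_moments(counts)
    chi2 = 0.0
    for i, c in enumerate(counts):
        a_i = harmonic(c.n)
        b_i = harmonic(c.n, 2)
        es = w[i] * a_i
        ed = w[i] * (T_hat + 1.0)
        var_s = es + (w[i] ** 2) * b_i
        var_d = ed + w[i] ** 2
        if var_s <= 0 or var_d <= 0:
            raise ValueError("zero expected counts in HKA")
        chi2 += (c.S - es) ** 2 / var_s + (c.D_div - ed) ** 2 / var_d
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


# ------------------------------------------------------------- ML-HKA

@dataclass
class MLHKAFit:
    theta: dict[str, float]        # per-locus theta_i (per site)
    T: float                       # divergence, 2N-generation units
    k: dict[str, float]            # selection parameters (1.0 off the selected set)
    loglik: float
    loglik_neutral: float
    lrt: float
    df: int
    converged: bool = True

    @property
    def p_value(self) -> float:
        if self.df == 0:
            return 1.0
        return float(stats.chi2.sf(self.lrt, df=self.df))


def _profile_loglik(counts: list[HKACounts], T: float, k: np.ndarray) -> tuple[float, np.ndarray]:
    """Log-likelihood with theta_i profiled out in closed form.

    d lnL / d theta_i = 0 gives
    theta_i L_i = (S_i + D_i) / (k_i a_i + T + (1 + k_i)/2).
    """
    a = np.array([harmonic(c.n) for c in counts])
    S = np.array([c.S for c in counts], dtype=float)
    D = np.array([c.D_div for c in counts], dtype=float)
    denom = k * a + T + 0.5 * (1.0 + k)
    w = (S + D) / denom
    lam_s = k * w * a
    lam_d = w * (T + 0.5 * (1.0 + k))
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(S > 0, S * np.log(np.maximum(lam_s, 1e-300)), 0.0) - lam_s \
            + np.where(D > 0, D * np.log(np.maximum(lam_d, 1e-300)), 0.0) - lam_d
    return float(ll.sum()), w


def _maximize(counts: list[HKACounts], sel_idx: np.ndarray, tol: float = 1e-8):
    """Multi-start bounded maximisation over (log T, log k_sel)."""
    n_sel = int(sel_idx.sum())

    def neg(x):
        T = np.exp(x[0])
        k = np.ones(len(counts))
        k[sel_idx] = np.exp(x[1:])
        ll, _ = _profile_loglik(counts, T, k)
        return -ll

    try:
        _w0, T0 = _solve_hka_moments(counts)
    except ValueError:
        T0 = 1.0
    starts = []
    for k0 in ((1.0,) if n_sel == 0 else (0.3, 1.0, 3.0)):
        starts.append(np.concatenate([[np.log(max(T0, 1e-3))], np.full(n_sel, np.log(k0))]))
    best = None
    for x0 in starts:
        res = optimize.minimize(neg, x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": tol, "maxiter": 20000})
        if best is None or res.fun < best.fun:
            best = res
    T = float(np.exp(best.x[0]))
    k = np.ones(len(counts))
    k[sel_idx] = np.exp(best.x[1:])
    ll, w = _profile_loglik(counts, T, k)
    return ll, T, k, w, bool(best.success)


def ml_hka(counts: list[HKACounts], selected: set[str] | list[str]) -> MLHKAFit:
    """Maximum-likelihood HKA with free selection parameters on ``selected``.

    The neutral model fixes every k_i = 1; LRT = 2 * delta lnL has
    df = |selected|. An empty selected set returns the neutral fit, LRT = 0.
    """
    if len(counts) < 2:
        raise ValueError("ML-HKA needs >= 2 loci")
    names = [c.name for c in counts]
    selected = set(selected)
    unknown = selected - set(names)
    if unknown:
        raise ValueError(f"selected loci not in counts: {sorted(unknown)}")
    sel_idx = np.array([name in selected for name in names])
    no_sel = np.zeros(len(counts), dtype=bool)

    ll0, T0, _k0, w0, ok0 = _maximize(counts, no_sel)
    if not selected:
        theta = {names[i]: w0[i] / counts[i].L for i in range(len(counts))}
        return MLHKAFit(theta=theta, T=T0, k={name: 1.0 for name in names},
                        loglik=ll0, loglik_neutral=ll0, lrt=0.0, df=0, converged=ok0)
    ll1, T1, k1, w1, ok1 = _maximize(counts, sel_idx)
    lrt = max(0.0, 2.0 * (ll1 - ll0))
    theta = {names[i]: w1[i] / counts[i].L for i in range(len(counts))}
    return MLHKAFit(theta=theta, T=T1, k={names[i]: float(k1[i]) for i in range(len(counts))},
                    loglik=ll1, loglik_neutral=ll0, lrt=lrt, df=len(selected),
                    converged=ok0 and ok1)
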