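"""Per-locus and between-group summary statistics.

Sequence statistics: segregating sites S, Watterson's theta_w = S/a1 with
a1 = sum_{i<n} 1/i, nucleotide diversity pi (mean pairwise differences),
haplotype count K, Tajima's D, and the normalised Fay–Wu H of Zeng et al.
(the (theta_pi - theta_L)/sqrt(Var) form with theta and theta^2 plug-ins).
Microsatellite statistics: mean allele number per population, multi-locus
Weir–Cockerham FST, and the shared-allele distance between populations.

Undefined statistics (e.g. D when S = 0, FST when between-group diversity is
zero) are returned as NaN — an explicit flagged value, never silently zero.
The low-level kernels (``*_from_counts``, ``wc_theta_components``, ...) are
shared with the coalescent simulator so observed and simulated summary
vectors are computed identically.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .types import LocusAlignment, MicrosatLocus, OrientedAlignment, StudyBundle

logger = logging.getLogger(__name__)


# ------------------------------------------------------------- constants

def harmonic(n: int, power: int = 1) -> float:
    return float(sum(1.0 / i ** power for i in range(1, n)))


def tajima_constants(n: int) -> dict[str, float]:
    """The a1..e2 constants of Tajima's variance normalisation."""
    a1 = harmonic(n, 1)
    a2 = harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


# --------------------------------------------------- site-level kernels

def biallelic_site_counts(mat: np.ndarray) -> np.ndarray:
    """Allele counts at biallelic sites of a character matrix.

    Returns the count of one of the two alleles at each biallelic site (which
    one is arbitrary; downstream formulas are symmetric in i and n-i).
    Monomorphic and triallelic sites are excluded, as are symbols outside
    A/C/G/T.
    """
    counts = []
    for j in range(mat.shape[1]):
        col = mat[:, j]
        alleles, cnt = np.unique(col, return_counts=True)
        valid = np.isin(alleles, ("A", "C", "G", "T"))
        alleles, cnt = alleles[valid], cnt[valid]
        if len(alleles) == 2:
            counts.append(int(cnt[0]))
    return np.array(counts, dtype=int)


def pi_from_counts(counts: np.ndarray, n: int) -> float:
    """Mean pairwise differences per locus from biallelic allele counts."""
    if n < 2:
        raise ValueError("pi requires n >= 2")
    i = np.asarray(counts, dtype=float)
    return float(np.sum(2.0 * i * (n - i)) / (n * (n - 1)))


def theta_w_from_s(s: int, n: int) -> float:
    return s / harmonic(n) if n >= 2 else float("nan")


def tajima_d_from_counts(s: int, pi: float, n: int) -> float:
    """Tajima's D from S and pi. NaN when S = 0 (flagged undefined)."""
    if s == 0:
        return float("nan")
    c = tajima_constants(n)
    var = c["e1"] * s + c["e2"] * s * (s - 1)
    if var <= 0:        # n = 3 has identically zero variance constants
        return float("nan")
    return (pi - s / c["a1"]) / math.sqrt(var)


def tajima_d_from_derived(derived: np.ndarray, n: int) -> float:
    derived = np.asarray(derived)
    return tajima_d_from_counts(int(derived.size), pi_from_counts(derived, n), n)


def faywu_h_from_derived(derived: np.ndarray, n: int) -> float:
    """Normalised Fay–Wu H from per-site derived-allele counts (1..n-1).

    H = (theta_pi - theta_L) / sqrt(Var), with
    theta_L = (1/(n-1)) sum_i i*xi_i and the Zeng et al. variance
    Var = theta*(n-2)/(6(n-1))
        + theta2*(18 n^2 (3n+2) b_{n+1} - 88 n^3 - 9 n^2 + 13 n - 6)/(9 n (n-1)^2)
    using plug-ins theta = S/a_n and theta2 = S(S-1)/(a_n^2 + b_n), where
    a_n = sum_{i<n} 1/i, b_n = sum_{i<n} 1/i^2 and b_{n+1} = b_n + 1/n^2.
    """
    i = np.asarray(derived, dtype=float)
    s = float(i.size)
    if s == 0:
        return float("nan")
    theta_pi = float(np.sum(2.0 * i * (n - i)) / (n * (n - 1)))
    theta_l = float(np.sum(i) / (n - 1))
    a_n = harmonic(n, 1)
    b_n = harmonic(n, 2)
    b_n1 = b_n + 1.0 / n ** 2
    theta = s / a_n
    theta2 = s * (s - 1) / (a_n ** 2 + b_n)
    var = (theta * (n - 2) / (6.0 * (n - 1))
           + theta2 * (18.0 * n * n * (3 * n + 2) * b_n1 - 88.0 * n ** 3 - 9.0 * n ** 2
                       + 13.0 * n - 6.0) / (9.0 * n * (n - 1) ** 2))
    if var <= 0:
        return float("nan")
    return (theta_pi - theta_l) / math.sqrt(var)


def faywu_h_from_sfs(xi: np.ndarray, n: int) -> float:
    """Normalised Fay–Wu H from the unfolded SFS xi[1..n-1] (index 0 unused)."""
    xi = np.asarray(xi, dtype=int)
    derived = np.repeat(np.arange(1, n), xi[1:n])
    return faywu_h_from_derived(derived, n)


def hudson_components_from_counts(cw: np.ndarray, ce: np.ndarray,
                                  n_w: int, n_e: int) -> tuple[float, float, float]:
    """(Hw_west, Hw_east, Hb) mean pairwise-difference components from
    per-site derived counts in the two groups (biallelic sites)."""
    cw = np.asarray(cw, dtype=float)
    ce = np.asarray(ce, dtype=float)
    hw_w = float(np.sum(2.0 * cw * (n_w - cw)) / (n_w * (n_w - 1))) if n_w > 1 else float("nan")
    hw_e = float(np.sum(2.0 * ce * (n_e - ce)) / (n_e * (n_e - 1))) if n_e > 1 else float("nan")
    hb = float(np.sum(cw * (n_e - ce) + ce * (n_w - cw)) / (n_w * n_e))
    return hw_w, hw_e, hb


def hudson_fst_from_site_counts(cw, ce, n_w: int, n_e: int) -> float:
    """Hudson FST kernel for two groups: 1 - mean(Hw)/Hb."""
    hw_w, hw_e, hb = hudson_components_from_counts(cw, ce, n_w, n_e)
    if hb <= 0:
        return float("nan")
    return 1.0 - 0.5 * (hw_w + hw_e) / hb


# ----------------------------------------------------------- SeqStats

@dataclass
class SeqStats:
    n: int
    L: int
    S: int
    theta_w: float           # per locus
    theta_w_site: float
    pi: float                # per locus
    pi_site: float
    K: int
    D: float                 # NaN when S == 0
    H: float | None = None   # filled when orientation available


def basic_seq_stats(aln: LocusAlignment) -> SeqStats:
    """S, theta_w, pi, K, D for a gap-excluded alignment."""
    if aln.n < 2:
        raise ValueError(f"locus {aln.name!r}: need >= 2 sequences")
    mat = aln.matrix()
    counts = biallelic_site_counts(mat)
    n, L = mat.shape
    s = int(counts.size)
    pi = pi_from_counts(counts, n)
    tw = theta_w_from_s(s, n)
    k = int(np.unique(mat, axis=0).shape[0])
    d = tajima_d_from_counts(s, pi, n)
    return SeqStats(n=n, L=L, S=s, theta_w=tw, theta_w_site=tw / L, pi=pi,
                    pi_site=pi / L, K=k, D=d)


def tajima_D(aln: LocusAlignment) -> float:
    return basic_seq_stats(aln).D


def faywu_H_norm(oriented: OrientedAlignment) -> float:
    """Normalised Fay–Wu H from outgroup-oriented derived counts."""
    if oriented.num_sites == 0:
        return float("nan")
    return faywu_h_from_derived(oriented.derived_counts, oriented.n)


# ----------------------------------------------------------- Hudson FST

@dataclass(frozen=True)
class FstResult:
    estimator: str
    value: float
    groups: tuple[str, ...]


def _pair_diff_sums(mat: np.ndarray, idx_by_group: dict[str, np.ndarray]):
    """Summed within- and between-group pairwise differences over all sites."""
    groups = list(idx_by_group)
    within_diffs = {g: 0.0 for g in groups}
    within_pairs = {g: len(idx_by_group[g]) * (len(idx_by_group[g]) - 1) / 2.0 for g in groups}
    between_diffs = 0.0
    between_pairs = 0.0
    for gi in range(len(groups)):
        for gj in range(gi + 1, len(groups)):
            between_pairs += len(idx_by_group[groups[gi]]) * len(idx_by_group[groups[gj]])
    for j in range(mat.shape[1]):
        col = mat[:, j]
        alleles = np.unique(col[np.isin(col, ("A", "C", "G", "T"))])
        if len(alleles) < 2:
            continue
        cnt = {g: np.array([(col[idx_by_group[g]] == a).sum() for a in alleles], dtype=float)
               for g in groups}
        for g in groups:
            ng = len(idx_by_group[g])
            within_diffs[g] += ng * (ng - 1) / 2.0 - float((cnt[g] * (cnt[g] - 1) / 2.0).sum())
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                g1, g2 = groups[gi], groups[gj]
                between_diffs += (len(idx_by_group[g1]) * len(idx_by_group[g2])
                                  - float((cnt[g1] * cnt[g2]).sum()))
    return within_diffs, within_pairs, between_diffs, between_pairs


def hudson_fst(aln: LocusAlignment, grouping: dict[str, str]) -> FstResult:
    """Hudson's FST = 1 - Hw/Hb for sequences.

    With two groups Hw is the unweighted average of the two within-group mean
    pairwise differences; with more groups all within-group pairs are pooled,
    as are all between-group pairs. Negative values are legitimate; Hb = 0
    yields NaN (flagged undefined).
    """
    ids = list(aln.sequences)
    groups = sorted({grouping[i] for i in ids})
    if len(groups) < 2:
        raise ValueError("FST needs >= 2 groups")
    idx_by_group = {g: np.array([k for k, i in enumerate(ids) if grouping[i] == g])
                    for g in groups}
    for g, idx in idx_by_group.items():
        if len(idx) < 2:
            raise ValueError(f"group {g!r} has < 2 sequences")
    wd, wp, bd, bp = _pair_diff_sums(aln.matrix(), idx_by_group)
    if len(groups) == 2:
        hw = float(np.mean([wd[g] / wp[g] for g in groups]))
    else:
        hw = sum(wd.values()) / sum(wp.values())
    hb = bd / bp
    value = 1.0 - hw / hb if hb > 0 else float("nan")
    return FstResult(estimator="hudson_seq", value=value, groups=tuple(groups))


def hudson_fst_multilocus(alignments: list[LocusAlignment], grouping: dict[str, str]) -> float:
    """Two-group Hudson FST with Hw and Hb summed over loci before the ratio.

    This ratio-of-sums form stays defined when individual loci are
    monomorphic, which matters when the same statistic is computed on
    simulated datasets with low mutation-rate draws.
    """
    hw_sum = 0.0
    hb_sum = 0.0
    for aln in alignments:
        ids = list(aln.sequences)
        groups = sorted({grouping[i] for i in ids})
        idx_by_group = {g: np.array([k for k, i in enumerate(ids) if grouping[i] == g])
                        for g in groups}
        wd, wp, bd, bp = _pair_diff_sums(aln.matrix(), idx_by_group)
        hw_sum += float(np.mean([wd[g] / wp[g] for g in groups]))
        hb_sum += bd / bp
    if hb_sum <= 0:
        return float("nan")
    return 1.0 - hw_sum / hb_sum


# ----------------------------------------------------- microsatellites

def genotype_count_arrays(mat: np.ndarray, allele_lo: int, allele_hi: int):
    """Per-individual allele-copy counts (n, A) from an (n, 2) genotype matrix."""
    n = mat.shape[0]
    a_size = allele_hi - allele_lo + 1
    counts = np.zeros((n, a_size), dtype=np.int64)
    rows = np.repeat(np.arange(n), 2)
    cols = (mat - allele_lo).ravel()
    np.add.at(counts, (rows, cols), 1)
    return counts


def wc_theta_components(pop_allele_counts: np.ndarray, pop_het_counts: np.ndarray,
                        n_i: np.ndarray) -> tuple[float, float]:
    """Weir–Cockerham (1984) variance components for one locus, all alleles.

    ``pop_allele_counts`` is (r, A) allele-copy counts per population,
    ``pop_het_counts`` is (r, A) counts of heterozygous carriers, ``n_i`` the
    diploid sample sizes. Returns (sum_a a, sum_a (a + b + c)).
    """
    n_i = np.asarray(n_i, dtype=float)
    r = len(n_i)
    nbar = n_i.mean()
    nc = (r * nbar - (n_i ** 2).sum() / (r * nbar)) / (r - 1)
    p_i = pop_allele_counts / (2.0 * n_i[:, None])
    h_i = pop_het_counts / n_i[:, None]
    pbar = (n_i[:, None] * p_i).sum(axis=0) / (r * nbar)
    s2 = (n_i[:, None] * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n_i[:, None] * h_i).sum(axis=0) / (r * nbar)
    a_c = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1))
    b_c = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                 - hbar * (2 * nbar - 1) / (4 * nbar))
    c_c = hbar / 2.0
    return float(a_c.sum()), float((a_c + b_c + c_c).sum())


def weir_cockerham_fst(allele_mats: list[np.ndarray], labels: np.ndarray) -> float:
    """Multi-locus multiallelic Weir–Cockerham theta: sum(a) / sum(a+b+c).

    Loci monomorphic across all groups are excluded with a warning.
    """
    labels = np.asarray(labels)
    pops = np.unique(labels)
    pop_idx = [np.where(labels == p)[0] for p in pops]
    n_i = np.array([len(ix) for ix in pop_idx], dtype=float)
    num = 0.0
    den = 0.0
    for mat in allele_mats:
        lo, hi = int(mat.min()), int(mat.max())
        if lo == hi:
            logger.debug("monomorphic SSR locus excluded from Weir–Cockerham FST")
            continue
        counts = genotype_count_arrays(mat, lo, hi)           # (n, A)
        het = (counts == 1).astype(np.int64)
        pac = np.stack([counts[ix].sum(axis=0) for ix in pop_idx])
        phc = np.stack([het[ix].sum(axis=0) for ix in pop_idx])
        a_sum, abc_sum = wc_theta_components(pac, phc, n_i)
        num += a_sum
        den += abc_sum
    if den == 0:
        return float("nan")
    return num / den


def shared_allele_distance(allele_mats: list[np.ndarray], labels: np.ndarray) -> float:
    """DAS = 1 - mean proportion of shared alleles over cross-group pairs.

    For two diploid genotypes the shared-allele count is
    sum_a min(c1_a, c2_a) = 2 - sum_a |c1_a - c2_a| / 2, in {0, 1, 2};
    the proportion divides by 2 and is averaged over loci and all
    between-population individual pairs.
    """
    labels = np.asarray(labels)
    pops = np.unique(labels)
    if len(pops) != 2:
        raise ValueError("shared-allele distance is defined between two populations")
    idx1 = np.where(labels == pops[0])[0]
    idx2 = np.where(labels == pops[1])[0]
    total = 0.0
    for mat in allele_mats:
        lo, hi = int(mat.min()), int(mat.max())
        counts = genotype_count_arrays(mat, lo, hi)
        c1 = counts[idx1]
        c2 = counts[idx2]
        absdiff = np.abs(c1[:, None, :] - c2[None, :, :]).sum(axis=2)
        shared = 2.0 - absdiff / 2.0
        total += float(shared.mean()) / 2.0
    return 1.0 - total / len(allele_mats)


def microsat_stats(loci: list[MicrosatLocus], grouping: dict[str, str]):
    """(mean allele number per group, Weir–Cockerham FST, shared-allele distance)."""
    if not loci:
        raise ValueError("need >= 1 SSR locus")
    ids = list(loci[0].genotypes)
    labels = np.array([grouping[i] for i in ids])
    mats = [loc.allele_matrix(ids) for loc in loci]
    mean_alleles = {}
    for g in sorted(set(labels)):
        gidx = np.where(labels == g)[0]
        mean_alleles[g] = float(np.mean([len(np.unique(m[gidx])) for m in mats]))
    fst = weir_cockerham_fst(mats, labels)
    das = shared_allele_distance(mats, labels)
    return mean_alleles, fst, das


# --------------------------------------------------------- ABC vector

SUMMARY_STAT_NAMES = (
    "ssr_mean_alleles_west", "ssr_mean_alleles_east", "ssr_wc_fst", "ssr_das",
    "seq_haplotypes_west", "seq_haplotypes_east", "seq_haplotypes_pooled",
    "seq_segsites_pooled", "seq_hudson_fst",
)


def abc_summary_vector(bundle: StudyBundle) -> np.ndarray:
    """The fixed-order summary-statistic vector used for ABC fitting.

    SSR block over the control microsatellites: mean allele number in each
    population, Weir–Cockerham FST, shared-allele distance. Sequence block
    over the control sequence loci: mean haplotype number per population and
    pooled, mean pooled segregating sites, and multi-locus Hudson FST.
    Undefined entries raise — ABC requires complete vectors.
    """
    grouping = bundle.group_of()
    ssr_names = bundle.loci_of_kind("control_ssr")
    seq_names = bundle.loci_of_kind("control_seq")
    if not ssr_names or not seq_names:
        raise ValueError("summary vector needs >= 1 SSR and >= 1 control sequence locus")
    mean_alleles, wc, das = microsat_stats([bundle.microsats[n] for n in ssr_names], grouping)
    alns = [bundle.alignments[n] for n in seq_names]
    hap_w, hap_e, hap_p, segs = [], [], [], []
    for aln in alns:
        ids = list(aln.sequences)
        pos = {i: k for k, i in enumerate(ids)}
        mat = aln.matrix()
        west = [pos[i] for i in ids if grouping[i] == "West"]
        east = [pos[i] for i in ids if grouping[i] == "East"]
        hap_p.append(np.unique(mat, axis=0).shape[0])
        hap_w.append(np.unique(mat[west], axis=0).shape[0])
        hap_e.append(np.unique(mat[east], axis=0).shape[0])
        segs.append(basic_seq_stats(aln).S)
    fst_seq = hudson_fst_multilocus(alns, grouping)
    vec = np.array([
        mean_alleles["West"], mean_alleles["East"], wc, das,
        float(np.mean(hap_w)), float(np.mean(hap_e)), float(np.mean(hap_p)),
        float(np.mean(segs)), fst_seq,
    ])
    if np.isnan(vec).any():
        bad = [SUMMARY_STAT_NAMES[k] for k in np.where(np.isnan(vec))[0]]
        raise ValueError(f"undefined summary statistics {bad}; ABC requires complete vectors")
    return vec
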