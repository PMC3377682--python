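"""Pathway-position indexing and position/selection correlation tests.

Position indexes count enzymes from IPI, the most upstream surveyed gene,
with multi-step enzymes indexed at their most upstream step; LCYB1 and LCYE
act at the same level (both cyclise lycopene) and share an index. The
correlation machinery relates per-gene neutrality-test p-values (or dN/dS
values) to position with Kendall's tau_b, tests between-gene heterogeneity
with Kruskal–Wallis, and contrasts genes upstream of the lycopene node
(IPI, PDS, CRTISO) against downstream genes (LCYB1, LCYE, CHXE, ZEP) with a
Wilcoxon rank-sum test. Ties are handled with midranks throughout — p-value
vectors are tied by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_POSITIONS = {
    "IPI": 1, "PDS": 2, "CRTISO": 3, "LCYB1": 4, "LCYE": 4, "CHXE": 5, "ZEP": 6,
}
# relative order that any assignment must respect (LCYB1 and LCYE tied)
_ORDER_CHAIN = ("IPI", "PDS", "CRTISO", "LCYB1", "CHXE", "ZEP")
UPSTREAM_OF_LYCOPENE = ("IPI", "PDS", "CRTISO")
DOWNSTREAM_OF_LYCOPENE = ("LCYB1", "LCYE", "CHXE", "ZEP")


@dataclass(frozen=True)
class PathwayAssignment:
    positions: dict[str, int]

    def __getitem__(self, gene: str) -> int:
        return self.positions[gene]


def _order_ok(positions: dict[str, int]) -> bool:
    chain = [g for g in _ORDER_CHAIN if g in positions]
    vals = [positions[g] for g in chain]
    if any(b <= a for a, b in zip(vals, vals[1:])):
        return False
    if "LCYB1" in positions and "LCYE" in positions \
            and positions["LCYB1"] != positions["LCYE"]:
        return False
    return True


def pathway_positions(genes, overrides: dict[str, int] | None = None) -> PathwayAssignment:
    """Position index per gene; defaults follow the carotenoid chain order.

    Overrides replace defaults; an override that breaks the canonical relative
    order only warns (the user may be modelling a different pathway). Genes
    outside the default set must be supplied via overrides.
    """
    positions = {}
    overrides = overrides or {}
    for g in genes:
        if g in overrides:
            positions[g] = int(overrides[g])
        elif g in DEFAULT_POSITIONS:
            positions[g] = DEFAULT_POSITIONS[g]
        else:
            raise ValueError(f"no default pathway position for gene {g!r}; supply an override")
    if not _order_ok(positions):
        logger.warning("pathway positions violate the canonical carotenoid-chain order")
    return PathwayAssignment(positions=positions)


def kendall_tau(x, y) -> tuple[float, float]:
    """Tie-corrected Kendall's tau_b with its p-value.

    Exact p for small untied samples, normal approximation otherwise
    (scipy's default switch); undefined (NaN) when either vector is all-tied.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("kendall_tau needs equal-length vectors of size >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return float("nan"), float("nan")
    res = stats.kendalltau(x, y)
    return float(res.statistic), float(res.pvalue)


def group_location_tests(values_by_gene: dict[str, np.ndarray],
                         upstream: tuple = UPSTREAM_OF_LYCOPENE,
                         downstream: tuple = DOWNSTREAM_OF_LYCOPENE):
    """Kruskal–Wallis across genes plus upstream-vs-downstream Wilcoxon.

    ``values_by_gene`` pools, per gene, the p-values from every neutrality
    test performed on it (pooled + geographic + color sets). Returns
    ((kw_stat, kw_p), (wilcoxon_stat, wilcoxon_p)); the Wilcoxon form is the
    rank-sum (Mann–Whitney) test with midrank tie handling, two-sided.
    """
    groups = [np.asarray(v, dtype=float) for v in values_by_gene.values()]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    kw = stats.kruskal(*groups)
    up = np.concatenate([values_by_gene[g] for g in upstream if g in values_by_gene])
    down = np.concatenate([values_by_gene[g] for g in downstream if g in values_by_gene])
    if len(up) == 0 or len(down) == 0:
        raise ValueError("empty upstream or downstream set")
    mw = stats.mannwhitneyu(up, down, alternative="two-sided")
    return (float(kw.statistic), float(kw.pvalue)), (float(mw.statistic), float(mw.pvalue))
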