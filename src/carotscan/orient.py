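"""Gap handling, ancestral-state orientation, and misorientation-rate estimation.

Derived/ancestral states at biallelic ingroup sites are assigned with a single
outgroup sequence (the study's tuberous-rooted chervil). Because the outgroup
lineage itself mutates, a fraction of sites are mis-polarised; that fraction is
estimated from the Jukes–Cantor outgroup divergence and later injected into
null simulations so the Fay–Wu H test is compared against equally-biased nulls.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np

from .types import LocusAlignment, OrientationEstimate, OrientedAlignment

BASES = ("A", "C", "G", "T")


def exclude_gap_sites(aln: LocusAlignment, drop_ambiguous: bool = True) -> LocusAlignment:
    """Drop every column where any ingroup or outgroup row has a gap.

    With ``drop_ambiguous`` (default) columns containing ``N`` are dropped too,
    mirroring complete-deletion handling of missing data.
    """
    mat = aln.matrix()
    rows = [mat]
    if aln.outgroup is not None:
        rows.append(np.array([list(aln.outgroup.upper())]))
    full = np.vstack(rows)
    bad = (full == "-").any(axis=0)
    if drop_ambiguous:
        bad |= (full == "N").any(axis=0)
    keep = ~bad
    if not keep.any():
        raise ValueError(f"locus {aln.name!r}: no sites remain after gap exclusion")
    new_seqs = {sid: "".join(mat[i, keep]) for i, sid in enumerate(aln.sequences)}
    new_out = "".join(np.array(list(aln.outgroup.upper()))[keep]) if aln.outgroup else None
    new_mask = aln.exon_mask[keep] if aln.exon_mask is not None else None
    return replace(aln, sequences=new_seqs, outgroup=new_out, exon_mask=new_mask)


def orient_alleles(aln: LocusAlignment, outgroup: str | None = None) -> OrientedAlignment:
    """Polarise biallelic polymorphic sites against the outgroup.

    A site where the outgroup carries one of the two ingroup alleles gets a
    derived count equal to the number of copies of the *other* allele. Sites
    where the outgroup carries a third state (or N) are recorded unorientable.
    Triallelic ingroup sites are excluded entirely.
    """
    out = outgroup if outgroup is not None else aln.outgroup
    if out is None:
        raise ValueError(f"locus {aln.name!r}: orientation requires an outgroup")
    mat = aln.matrix()
    n = mat.shape[0]
    out_arr = np.array(list(out.upper()))
    derived = []
    unorientable: list[int] = []
    for j in range(mat.shape[1]):
        col = mat[:, j]
        alleles, counts = np.unique(col, return_counts=True)
        valid = np.isin(alleles, BASES)
        alleles, counts = alleles[valid], counts[valid]
        if len(alleles) != 2:
            continue  # monomorphic or triallelic (the latter excluded by design)
        og = out_arr[j]
        if og not in alleles:
            unorientable.append(j)
            continue
        derived_allele = alleles[alleles != og][0]
        i = int(counts[alleles == derived_allele][0])
        derived.append(i)
    return OrientedAlignment(n=n, derived_counts=np.array(derived, dtype=int),
                             unorientable=unorientable)


def jc_outgroup_divergence(aln: LocusAlignment, outgroup: str | None = None) -> float:
    """Jukes–Cantor-corrected mean divergence (subst/site) ingroup vs outgroup."""
    out = outgroup if outgroup is not None else aln.outgroup
    if out is None:
        raise ValueError("divergence requires an outgroup")
    mat = aln.matrix()
    out_arr = np.array(list(out.upper()))
    valid_out = np.isin(out_arr, BASES)
    valid_in = np.isin(mat, BASES)
    comparable = valid_in & valid_out[None, :]
    n_comp = comparable.sum(axis=1)
    if not (n_comp > 0).any():
        raise ValueError("zero comparable sites between ingroup and outgroup")
    diffs = (mat != out_arr[None, :]) & comparable
    with np.errstate(invalid="ignore"):
        p = np.where(n_comp > 0, diffs.sum(axis=1) / np.maximum(n_comp, 1), np.nan)
    p_mean = float(np.nanmean(p))
    if p_mean >= 0.75:
        raise ValueError("outgroup divergence saturated (p >= 3/4), JC correction undefined")
    return -0.75 * math.log1p(-4.0 * p_mean / 3.0)


def misorientation_from_divergence(d: float) -> float:
    """Misorientation rate implied by outgroup divergence d.

    Under Jukes–Cantor the outgroup lineage has changed state at a site with
    probability P_change = (3/4)(1 - exp(-4d/3)); conditional on a change, the
    outgroup matches the ingroup's minor allele (flipping the polarity call)
    one time in three. Ceiling 1/4 at saturation. Monotone, m(0) = 0.
    """
    if d < 0:
        raise ValueError("divergence must be >= 0")
    p_change = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
    return p_change / 3.0


def estimate_misorientation_rate(aln: LocusAlignment, outgroup: str | None = None) -> OrientationEstimate:
    """Estimate misorientation rate from the outgroup's JC divergence."""
    d = jc_outgroup_divergence(aln, outgroup)
    return OrientationEstimate(m=misorientation_from_divergence(d), d=d)
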