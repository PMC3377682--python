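"""Pairwise synonymous/nonsynonymous substitution rates (Nei–Gojobori 1986).

Site counting: each codon position contributes the fraction of its three
possible one-step changes that are synonymous (changes to stop codons count
as nonsynonymous); N + S sites sum to 3 per codon. Difference counting:
codons differing at d positions are resolved by averaging Nd and Sd over all
d! orderings of single-step paths, excluding paths that pass through a stop
codon. Proportions use site counts averaged between the two sequences and
are Jukes–Cantor corrected, d = -(3/4) ln(1 - 4p/3); p >= 3/4 is saturated
and flagged undefined (NaN), as is omega when dS is undefined or zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

CODON_TABLE = dict(standard_dna_table.forward_table)
STOP_CODONS = set(standard_dna_table.stop_codons)
BASES = "ACGT"


@dataclass(frozen=True)
class PairwiseRates:
    dN: float
    dS: float
    omega: float
    N_sites: float
    S_sites: float
    Nd: float
    Sd: float


@dataclass
class CodonAlignment:
    """In-frame, gapless codon alignment for >= 2 taxa."""

    gene: str
    sequences: dict[str, str]

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError(f"{self.gene}: unequal sequence lengths")
        L = lengths.pop()
        if L % 3 != 0:
            raise ValueError(f"{self.gene}: length {L} not divisible by 3")
        for taxon, seq in self.sequences.items():
            seq = seq.upper()
            for i in range(0, L - 3, 3):
                if seq[i:i + 3] in STOP_CODONS:
                    raise ValueError(f"{self.gene}/{taxon}: internal stop codon at {i}")

    @property
    def n_codons(self) -> int:
        return len(next(iter(self.sequences.values()))) // 3


def _codon_sites(codon: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) site fractions of one sense codon."""
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} in sequence")
    aa = CODON_TABLE[codon]
    syn = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt not in STOP_CODONS and CODON_TABLE[alt] == aa:
                syn += 1.0 / 3.0
    return 3.0 - syn, syn


def ng86_site_counts(seq: str) -> tuple[float, float]:
    """Total (N_sites, S_sites) of a coding sequence.

    Codons containing symbols outside A/C/G/T are skipped.
    """
    seq = seq.upper()
    if len(seq) % 3:
        raise ValueError("sequence length not divisible by 3")
    N = S = 0.0
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        if any(b not in BASES for b in codon):
            continue
        n, s = _codon_sites(codon)
        N += n
        S += s
    return N, S


def _codon_path_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(Nd, Sd) between two codons, averaged over stop-free mutation paths."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    paths = []
    for order in permutations(diffs):
        cur = c1
        nd = sd = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            if CODON_TABLE[cur] == CODON_TABLE[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        if ok:
            paths.append((nd, sd))
    if not paths:
        # every ordering passes through a stop; count all changes nonsynonymous
        return float(len(diffs)), 0.0
    nd = float(np.mean([p[0] for p in paths]))
    sd = float(np.mean([p[1] for p in paths]))
    return nd, sd


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        return float("nan")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def pairwise_dnds(seqA: str, seqB: str) -> PairwiseRates:
    """NG86 pairwise dN, dS and omega between two in-frame sequences."""
    seqA, seqB = seqA.upper(), seqB.upper()
    if len(seqA) != len(seqB):
        raise ValueError("sequences must be equal length")
    if len(seqA) % 3:
        raise ValueError("length not divisible by 3")
    NA, SA = ng86_site_counts(seqA)
    NB, SB = ng86_site_counts(seqB)
    N_sites = 0.5 * (NA + NB)
    S_sites = 0.5 * (SA + SB)
    Nd = Sd = 0.0
    for i in range(0, len(seqA), 3):
        ca, cb = seqA[i:i + 3], seqB[i:i + 3]
        if any(b not in BASES for b in ca + cb):
            continue
        nd, sd = _codon_path_diffs(ca, cb)
        Nd += nd
        Sd += sd
    pN = Nd / N_sites if N_sites > 0 else float("nan")
    pS = Sd / S_sites if S_sites > 0 else float("nan")
    dN = _jc_correct(pN) if np.isfinite(pN) else float("nan")
    dS = _jc_correct(pS) if np.isfinite(pS) else float("nan")
    omega = dN / dS if np.isfinite(dN) and np.isfinite(dS) and dS > 0 else float("nan")
    return PairwiseRates(dN=dN, dS=dS, omega=omega, N_sites=N_sites, S_sites=S_sites,
                         Nd=Nd, Sd=Sd)


def pairwise_table(alignments: list[CodonAlignment]) -> pd.DataFrame:
    """All-pairs NG86 rates per gene: columns gene, taxon1, taxon2, dN, dS, omega."""
    rows = []
    for aln in alignments:
        taxa = list(aln.sequences)
        for i in range(len(taxa)):
            for j in range(i + 1, len(taxa)):
                r = pairwise_dnds(aln.sequences[taxa[i]], aln.sequences[taxa[j]])
                rows.append((aln.gene, taxa[i], taxa[j], r.dN, r.dS, r.omega))
    return pd.DataFrame(rows, columns=["gene", "taxon1", "taxon2", "dN", "dS", "omega"])


def validate_frame(seq: str) -> bool:
    """True when a sequence is in frame: length divisible by 3, no internal stops."""
    seq = seq.upper()
    if len(seq) % 3:
        return False
    for i in range(0, len(seq) - 3, 3):
        if seq[i:i + 3] in STOP_CODONS:
            return False
    return True
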