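"""Study-shaped synthetic datasets with known truth.

The generator emulates the study design end to end: 46 individuals split
into Western and Eastern groups and five root-color groups, three anonymous
control sequence loci, 17 diploid control microsatellites and seven candidate
genes — all simulated under the two-population divergence model with a deep
outgroup. Candidate genes can carry selection-like distortions:

``neutral``    plain divergence-model draw;
``sweep``      within-population coalescent times shrunk by 1/c (default
               c = 6, a six-fold diversity reduction);
``balancing``  two ancient allelic classes whose common ancestor is forced
               far beyond T_d, producing the intermediate-frequency excess
               balanced polymorphisms leave.

Everything is seeded and writes the exact FASTA/TSV/YAML formats the readers
consume, so every downstream stage can be exercised without any download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import io as cio
from .divsim import divergence_epochs, simulate_microsat_locus, simulate_sequence_locus
from .types import (
    DivergenceModelParams,
    LocusAlignment,
    LocusInfo,
    OrientedAlignment,
    Sample,
    SimConfig,
    StudyBundle,
)

REGIMES = ("neutral", "sweep", "balancing")

DEFAULT_PARAMS = DivergenceModelParams(
    N_W=600.0, N_E=600.0, N_A=30_000.0, T_d=500.0,
    mu_seq=5e-8, mu_ssr=2e-4, p_ssr=0.22,
)

# candidate fragment lengths (sites); PDS mirrors its 911 comparable sites
CANDIDATE_GENES = {
    "IPI": 800, "PDS": 911, "CRTISO": 1300, "LCYB1": 900,
    "LCYE": 1200, "CHXE": 1100, "ZEP": 900,
}
CANDIDATE_POSITIONS = {"IPI": 1, "PDS": 2, "CRTISO": 3, "LCYB1": 4,
                       "LCYE": 4, "CHXE": 5, "ZEP": 6}
CONTROL_SEQ_LENGTHS = {"B1D": 550, "JW3D": 600, "SB4A": 650}
COLOR_COUNTS = {"white": 8, "yellow": 10, "orange": 16, "red": 6, "purple": 6}


@dataclass
class SyntheticScenario:
    """True parameters and design of one synthetic study."""

    seed: int
    params: DivergenceModelParams = DEFAULT_PARAMS
    regimes: dict[str, str] = field(default_factory=dict)   # candidate gene -> regime
    n_west: int = 23
    n_east: int = 23
    outgroup_time: float = 1e6           # generations to the outgroup split
    sweep_factor: float = 6.0            # 1/c shrink of within-pop sizes
    balancing_depth: float | None = None  # forced class-split age; default 32 * N_A
    color_counts: dict[str, int] = field(default_factory=lambda: dict(COLOR_COUNTS))
    color_class_correlation: float = 0.0  # couples colors to balancing classes

    def __post_init__(self):
        for gene, regime in self.regimes.items():
            if gene not in CANDIDATE_GENES:
                raise ValueError(f"unknown candidate gene {gene!r}")
            if regime not in REGIMES:
                raise ValueError(f"unknown regime {regime!r} for gene {gene!r}")
        if sum(self.color_counts.values()) != self.n_west + self.n_east:
            raise ValueError("color counts must sum to the sample size")

    @property
    def class_depth(self) -> float:
        # default: an ancient balanced polymorphism, maintained an order of
        # magnitude longer than the neutral expected TMRCA (4 N_A)
        return self.balancing_depth if self.balancing_depth is not None \
            else 32.0 * self.params.N_A


def scenario_samples(scenario: SyntheticScenario, rng: np.random.Generator) -> list[Sample]:
    """Deterministic sample metadata: ids, West/East split, shuffled colors."""
    n = scenario.n_west + scenario.n_east
    ids = [f"c{i + 1:02d}" for i in range(n)]
    groups = ["West"] * scenario.n_west + ["East"] * scenario.n_east
    colors = [c for c, k in scenario.color_counts.items() for _ in range(k)]
    colors = list(rng.permutation(colors))
    return [Sample(id=i, group=g, color=c) for i, g, c in zip(ids, groups, colors)]


def candidate_epochs(scenario: SyntheticScenario, regime: str,
                     rng: np.random.Generator):
    """(epochs, pop_assignment, class_of_individual) for a candidate regime.

    ``class_of_individual`` is None except under balancing, where it records
    which ancient allelic class each individual's lineage belongs to.
    """
    p = scenario.params
    n_w, n_e = scenario.n_west, scenario.n_east
    if regime == "neutral":
        return divergence_epochs(p), None, None
    if regime == "sweep":
        return divergence_epochs(p, within_scale=1.0 / scenario.sweep_factor), None, None
    if regime == "balancing":
        if scenario.color_class_correlation > 0:
            # colors later in the palette lean toward class 1
            colors = scenario_samples(scenario, np.random.default_rng(scenario.seed))
            lean = np.array([c.color in ("orange", "red", "purple") for c in colors])
            flip = rng.random(n_w + n_e) >= scenario.color_class_correlation
            classes = np.where(flip, rng.integers(0, 2, size=n_w + n_e), lean.astype(int))
        else:
            classes = rng.integers(0, 2, size=n_w + n_e)
        pops = []
        for i in range(n_w + n_e):
            geo = "W" if i < n_w else "E"
            pops.append(f"{geo}{classes[i]}")
        depth = scenario.class_depth
        epochs = [
            (p.T_d, {"W0": p.N_W, "W1": p.N_W, "E0": p.N_E, "E1": p.N_E}, None),
            (depth, {"A0": p.N_A, "A1": p.N_A},
             {"W0": "A0", "E0": "A0", "W1": "A1", "E1": "A1"}),
            (np.inf, {"R": p.N_A}, {"A0": "R", "A1": "R"}),
        ]
        return epochs, pops, classes
    raise ValueError(f"unknown regime {regime!r}")


def generate_candidate_gene(scenario: SyntheticScenario, gene: str,
                            regime: str | None = None,
                            rng: np.random.Generator | None = None,
                            sample_ids=None) -> tuple[LocusAlignment, OrientedAlignment]:
    """One candidate-gene alignment (with outgroup) plus orientation truth."""
    if gene not in CANDIDATE_GENES:
        raise ValueError(f"unknown candidate gene {gene!r}")
    regime = regime if regime is not None else scenario.regimes.get(gene, "neutral")
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}")
    rng = rng if rng is not None else np.random.default_rng(scenario.seed)
    epochs, pops, _classes = candidate_epochs(scenario, regime, rng)
    cfg = SimConfig(n_west=scenario.n_west, n_east=scenario.n_east,
                    length=CANDIDATE_GENES[gene], ploidy=1,
                    mutation_mode="jukes_cantor")
    aln, truth = simulate_sequence_locus(
        scenario.params, cfg, rng, sample_ids=sample_ids, name=gene,
        outgroup_time=scenario.outgroup_time, epochs=epochs, pop_assignment=pops)
    return aln, truth


def generate_control_loci(scenario: SyntheticScenario,
                          rng: np.random.Generator | None = None) -> StudyBundle:
    """Control-only bundle: 17 SSR + 3 sequence loci + metadata + registry."""
    rng = rng if rng is not None else np.random.default_rng(scenario.seed)
    samples = scenario_samples(scenario, rng)
    ids = [s.id for s in samples]
    p = scenario.params
    alignments = {}
    registry = {}
    for name, length in CONTROL_SEQ_LENGTHS.items():
        cfg = SimConfig(n_west=scenario.n_west, n_east=scenario.n_east,
                        length=length, ploidy=1, mutation_mode="jukes_cantor")
        aln, _truth = simulate_sequence_locus(
            p, cfg, rng, sample_ids=ids, name=name,
            outgroup_time=scenario.outgroup_time)
        alignments[name] = aln
        registry[name] = LocusInfo(name=name, kind="control_seq", length=length)
    microsats = {}
    for k in range(17):
        name = f"SSR{k + 1:02d}"
        motif = 2 if k % 3 else 3
        allele_range = (8 + (k % 4), 28 + 2 * (k % 5))
        cfg = SimConfig(n_west=scenario.n_west, n_east=scenario.n_east,
                        length=1, ploidy=2)
        microsats[name] = simulate_microsat_locus(
            p, cfg, motif, allele_range, rng, sample_ids=ids, name=name)
        registry[name] = LocusInfo(name=name, kind="control_ssr", length=1)
    return StudyBundle(samples=samples, alignments=alignments,
                       microsats=microsats, registry=registry)


def generate_study_bundle(scenario: SyntheticScenario
                          ) -> tuple[StudyBundle, dict[str, OrientedAlignment]]:
    """Full bundle (controls + 7 candidate genes) plus per-gene orientation truth."""
    rng = np.random.default_rng(scenario.seed)
    bundle = generate_control_loci(scenario, rng)
    ids = bundle.sample_ids
    truths = {}
    for gene, length in CANDIDATE_GENES.items():
        aln, truth = generate_candidate_gene(scenario, gene, rng=rng, sample_ids=ids)
        bundle.alignments[gene] = aln
        bundle.registry[gene] = LocusInfo(name=gene, kind="candidate", length=length,
                                          position=CANDIDATE_POSITIONS[gene])
        truths[gene] = truth
    return bundle, truths


def make_fixtures(scenario: SyntheticScenario, outdir) -> dict:
    """Write a complete synthetic study to ``outdir`` in the observed formats."""
    bundle, _truths = generate_study_bundle(scenario)
    return cio.write_study_bundle(bundle, outdir)
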