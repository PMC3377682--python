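"""Domain containers for the carrot selection-scan pipeline.

The study design these containers reflect: 46 cultivated carrot individuals,
one haploid gene sequence each, split into a Western and an Eastern group and
into five root-color groups; a tuberous-rooted chervil sequence as outgroup;
17 diploid microsatellite loci and three anonymous sequence loci as neutral
controls; seven carotenoid biosynthesis genes as selection candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

GROUPS = ("West", "East")
COLORS = ("white", "yellow", "orange", "red", "purple")
LOCUS_KINDS = ("candidate", "control_seq", "control_ssr")

NUCLEOTIDES = frozenset("ACGTN-")


@dataclass(frozen=True)
class Sample:
    id: str
    group: str          # "West" | "East"
    color: str          # white/yellow/orange/red/purple

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"sample {self.id!r}: unknown group {self.group!r}")
        if self.color not in COLORS:
            raise ValueError(f"sample {self.id!r}: unknown color {self.color!r}")


@dataclass(frozen=True)
class LocusInfo:
    """Registry entry for one locus.

    ``position`` is the pathway-position index (candidates only): the number
    of distinct enzymes between IPI, the most upstream gene surveyed, and this
    gene, counting a multi-step enzyme at its most upstream step.
    """

    name: str
    kind: str                      # candidate | control_seq | control_ssr
    length: int                    # sites (sequence) or motif-informed span (SSR)
    position: int | None = None    # pathway position, candidates only

    def __post_init__(self) -> None:
        if self.kind not in LOCUS_KINDS:
            raise ValueError(f"locus {self.name!r}: unknown kind {self.kind!r}")
        if self.length <= 0:
            raise ValueError(f"locus {self.name!r}: length must be > 0")
        if self.kind == "candidate" and self.position is None:
            raise ValueError(f"candidate locus {self.name!r} needs a pathway position")


@dataclass
class LocusAlignment:
    """Equal-length haploid nucleotide sequences, one per sampled individual.

    ``sequences`` maps sample id -> sequence over {A,C,G,T,N,-}; the optional
    outgroup row is stored separately. Internally 0-based half-open.
    """

    name: str
    sequences: dict[str, str]
    outgroup: str | None = None
    exon_mask: np.ndarray | None = None   # optional bool per column, True = exon

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"locus {self.name!r}: ragged alignment, lengths {sorted(lengths)}")
        if self.outgroup is not None and self.sequences and len(self.outgroup) != self.length:
            raise ValueError(f"locus {self.name!r}: outgroup length mismatch")
        for sid, seq in self.sequences.items():
            bad = set(seq.upper()) - NUCLEOTIDES
            if bad:
                raise ValueError(f"locus {self.name!r}, sequence {sid!r}: bad symbols {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    @property
    def n(self) -> int:
        return len(self.sequences)

    def matrix(self) -> np.ndarray:
        """Ingroup alignment as an (n, L) array of single characters."""
        return np.array([list(s.upper()) for s in self.sequences.values()])

    def subset(self, sample_ids) -> "LocusAlignment":
        seqs = {sid: self.sequences[sid] for sid in sample_ids}
        return replace(self, sequences=seqs)


@dataclass
class MicrosatLocus:
    """One diploid microsatellite locus; alleles are repeat counts."""

    name: str
    motif: int
    allele_range: tuple[int, int]
    genotypes: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        lo, hi = self.allele_range
        if hi < lo:
            raise ValueError(f"SSR {self.name!r}: empty allele range")
        for sid, (a1, a2) in self.genotypes.items():
            if not (lo <= a1 <= hi and lo <= a2 <= hi):
                raise ValueError(
                    f"SSR {self.name!r}, individual {sid!r}: alleles ({a1},{a2}) "
                    f"outside range [{lo},{hi}]"
                )

    @property
    def n(self) -> int:
        return len(self.genotypes)

    def allele_matrix(self, sample_ids=None) -> np.ndarray:
        ids = list(self.genotypes) if sample_ids is None else list(sample_ids)
        return np.array([self.genotypes[s] for s in ids], dtype=int)


@dataclass
class StudyBundle:
    """All observed inputs, validated: alignments, genotypes, metadata, registry."""

    samples: list[Sample]
    alignments: dict[str, LocusAlignment]
    microsats: dict[str, MicrosatLocus]
    registry: dict[str, LocusInfo]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.samples]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids: {dup}")
        known = set(ids)
        for aln in self.alignments.values():
            extra = set(aln.sequences) - known
            if extra:
                raise ValueError(f"locus {aln.name!r}: unknown sequence labels {sorted(extra)}")
        for ssr in self.microsats.values():
            extra = set(ssr.genotypes) - known
            if extra:
                raise ValueError(f"SSR {ssr.name!r}: unknown individual ids {sorted(extra)}")
        for name in list(self.alignments) + list(self.microsats):
            if name not in self.registry:
                raise ValueError(f"locus {name!r} missing from registry")

    @property
    def sample_ids(self) -> list[str]:
        return [s.id for s in self.samples]

    def group_of(self) -> dict[str, str]:
        return {s.id: s.group for s in self.samples}

    def color_of(self) -> dict[str, str]:
        return {s.id: s.color for s in self.samples}

    def ids_in_group(self, group: str) -> list[str]:
        return [s.id for s in self.samples if s.group == group]

    def ids_in_color(self, color: str) -> list[str]:
        return [s.id for s in self.samples if s.color == color]

    def loci_of_kind(self, kind: str) -> list[str]:
        return [name for name, info in self.registry.items() if info.kind == kind]

    def color_composition(self) -> dict[str, dict[str, int]]:
        """color -> {group -> count}; drives color-group subsampled null tests."""
        comp: dict[str, dict[str, int]] = {c: {g: 0 for g in GROUPS} for c in COLORS}
        for s in self.samples:
            comp[s.color][s.group] += 1
        return {c: g for c, g in comp.items() if sum(g.values()) > 0}


@dataclass
class OrientedAlignment:
    """Per-site derived-allele counts after outgroup polarisation.

    ``derived_counts[j]`` is the number of ingroup copies carrying the derived
    (non-outgroup) allele at oriented polymorphic site j, 1 <= i <= n-1.
    ``unorientable`` lists 0-based columns where the outgroup carried a third
    state (or a gap/N) — excluded from Fay–Wu H.
    """

    n: int
    derived_counts: np.ndarray
    unorientable: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        dc = np.asarray(self.derived_counts, dtype=int)
        if dc.size and not ((dc >= 1) & (dc <= self.n - 1)).all():
            raise ValueError("derived counts must lie in 1..n-1")
        self.derived_counts = dc

    @property
    def num_sites(self) -> int:
        return int(self.derived_counts.size)

    def sfs(self) -> np.ndarray:
        """Unfolded site-frequency spectrum xi[i], i = 1..n-1 (index 0 unused)."""
        out = np.zeros(self.n, dtype=int)
        for i in self.derived_counts:
            out[i] += 1
        return out


@dataclass(frozen=True)
class OrientationEstimate:
    """Misorientation rate m and outgroup divergence d (subst/site, JC-corrected)."""

    m: float
    d: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.m <= 1.0):
            raise ValueError("misorientation rate must be in [0, 1]")
        if self.d < 0:
            raise ValueError("divergence must be >= 0")


@dataclass(frozen=True)
class DivergenceModelParams:
    """Parameters of the two-population divergence model.

    Western and Eastern populations of constant diploid effective sizes N_W and
    N_E split T_d generations ago from an ancestral population of size N_A.
    Sequence loci mutate at mu_seq substitutions/site/generation; microsatellites
    follow a generalised stepwise model with rate mu_ssr mutations/generation and
    geometric step-size parameter p_ssr.
    """

    N_W: float
    N_E: float
    N_A: float
    T_d: float
    mu_seq: float
    mu_ssr: float = 0.0
    p_ssr: float = 0.0

    def __post_init__(self) -> None:
        if min(self.N_W, self.N_E, self.N_A) < 1:
            raise ValueError("effective sizes must be >= 1")
        if self.T_d < 0:
            raise ValueError("divergence time must be >= 0")
        if min(self.mu_seq, self.mu_ssr) < 0:
            raise ValueError("mutation rates must be >= 0")
        if not (0.0 <= self.p_ssr < 1.0):
            raise ValueError("geometric step parameter must be in [0, 1)")


@dataclass(frozen=True)
class SimConfig:
    """Per-locus simulation configuration."""

    n_west: int
    n_east: int
    length: int
    ploidy: int = 1                     # 1 = sequence locus, 2 = microsatellite
    mutation_mode: str = "infinite_sites"   # or "jukes_cantor"

    def __post_init__(self) -> None:
        if self.n_west + self.n_east < 2:
            raise ValueError("need at least 2 sampled copies")
        if self.length < 1:
            raise ValueError("locus length must be >= 1")
        if self.ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")
        if self.mutation_mode not in ("infinite_sites", "jukes_cantor"):
            raise ValueError(f"unknown mutation mode {self.mutation_mode!r}")
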