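"""Coalescent simulation under the two-population divergence model.

The model: Western and Eastern populations of constant diploid effective
sizes N_W and N_E exchange no migrants and merge, T_d generations back, into
an ancestral population of size N_A. Autosomal loci carry 2N gene copies in a
population of N diploid individuals, so k lineages coalesce at rate
k(k-1)/(2 * 2N) per generation — the single time-scaling convention used for
both haploid-sampled sequence loci and diploid microsatellites.

Sequence loci mutate at mu_seq substitutions/site/generation, either as
infinite sites (each mutation a fresh column; used for candidate-gene null
distributions, with misorientation injected post hoc) or as Jukes–Cantor
(recurrent mutation at uniformly chosen sites; used for the ABC reference
table). Microsatellites follow a generalised stepwise model: mutations of
+-k repeat units, k geometric, reflected into the observed allele range.
No intragenic recombination is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import DivergenceModelParams, LocusAlignment, MicrosatLocus, OrientedAlignment, SimConfig

BASES = np.array(["A", "C", "G", "T"])


# ------------------------------------------------------------ genealogy

@dataclass
class SimTree:
    """A coalescent genealogy: leaves 0..n-1, internal nodes n..2n-2."""

    n: int
    parent: np.ndarray             # node -> parent id, -1 at root
    time: np.ndarray               # node times, generations before present
    leaves_under: list             # node -> np.ndarray of descendant leaves
    root: int

    def branch_lengths(self) -> np.ndarray:
        """Per-node branch length to parent (0 at the root)."""
        lens = np.zeros(2 * self.n - 1)
        has_parent = self.parent >= 0
        lens[has_parent] = self.time[self.parent[has_parent]] - self.time[has_parent]
        return lens

    def total_length(self) -> float:
        return float(self.branch_lengths().sum())


def divergence_epochs(params: DivergenceModelParams, within_scale: float = 1.0):
    """Epoch schedule for the plain divergence model.

    ``within_scale`` < 1 shrinks the within-population sizes (sweep-style
    diversity reduction); the ancestral population is unaffected.
    """
    return [
        (params.T_d, {"W": params.N_W * within_scale, "E": params.N_E * within_scale}, None),
        (np.inf, {"A": params.N_A}, {"W": "A", "E": "A"}),
    ]


def simulate_genealogy(pop_of_sample, epochs, rng: np.random.Generator) -> SimTree:
    """Continuous-time coalescent over a piecewise-constant demography.

    ``pop_of_sample`` assigns each sampled gene copy to a population label;
    ``epochs`` is a list of (end_time, {pop: diploid_N}, remap) applied in
    order, the last with end_time = inf and a single population so the tree
    always roots. Within an epoch populations are independent, so each is
    coalesced on its own clock.
    """
    n = len(pop_of_sample)
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    time = np.zeros(2 * n - 1)
    leaves_under: list = [np.array([i], dtype=np.int64) for i in range(n)] + [None] * (n - 1)
    active: dict = {}
    for i, p in enumerate(pop_of_sample):
        active.setdefault(p, []).append(i)
    next_node = n
    t_start = 0.0
    for t_end, sizes, remap in epochs:
        if remap:
            merged: dict = {}
            for p, nodes in active.items():
                merged.setdefault(remap.get(p, p), []).extend(nodes)
            active = merged
        for p, nodes in active.items():
            if p not in sizes:
                raise ValueError(f"no size for active population {p!r}")
            k = len(nodes)
            if k < 2:
                continue
            two_n = 2.0 * sizes[p]
            # waiting times for k -> k-1 -> ... -> 1 lineages, drawn in a block
            ks = np.arange(k, 1, -1, dtype=float)
            waits = rng.exponential(size=k - 1) * (2.0 * two_n / (ks * (ks - 1)))
            times = t_start + np.cumsum(waits)
            n_events = int(np.searchsorted(times, t_end, side="right"))
            if n_events == 0:
                continue
            u1 = rng.random(n_events)
            u2 = rng.random(n_events)
            for e in range(n_events):
                kk = k - e
                i1 = int(u1[e] * kk)
                i2 = int(u2[e] * (kk - 1))
                if i2 >= i1:
                    i2 += 1
                a, b = nodes[i1], nodes[i2]
                parent[a] = next_node
                parent[b] = next_node
                time[next_node] = times[e]
                leaves_under[next_node] = np.concatenate((leaves_under[a], leaves_under[b]))
                if i1 < i2:
                    nodes.pop(i2)
                    nodes.pop(i1)
                else:
                    nodes.pop(i1)
                    nodes.pop(i2)
                nodes.append(next_node)
                next_node += 1
        t_start = t_end
        if sum(len(v) for v in active.values()) == 1:
            break
    remaining = [v for nodes in active.values() for v in nodes]
    if len(remaining) != 1:
        raise RuntimeError("genealogy did not fully coalesce; check epoch schedule")
    return SimTree(n=n, parent=parent, time=time, leaves_under=leaves_under, root=remaining[0])


def place_mutations(tree: SimTree, rate_per_gen: float, rng: np.random.Generator) -> np.ndarray:
    """Branch index of each mutation; Poisson(rate * total length) mutations
    dropped on branches with probability proportional to branch length."""
    lens = tree.branch_lengths()
    total = lens.sum()
    m = rng.poisson(rate_per_gen * total) if total > 0 else 0
    if m == 0:
        return np.empty(0, dtype=np.int64)
    cum = np.cumsum(lens)
    return np.searchsorted(cum, rng.random(m) * total).astype(np.int64)


# ------------------------------------------------- sequence simulation

@dataclass
class SeqSimResult:
    """Compact result of one sequence-locus simulation.

    ``genotypes`` is an (S, n) boolean matrix of true derived states at
    polymorphic sites (infinite-sites mode). ``west`` marks which sample
    columns are Western. ``flipped`` records post-hoc misorientation flips
    (all False until :func:`apply_misorientation_result`).
    """

    n_west: int
    n_east: int
    genotypes: np.ndarray
    west: np.ndarray
    flipped: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.flipped is None:
            self.flipped = np.zeros(self.genotypes.shape[0], dtype=bool)

    @property
    def n(self) -> int:
        return self.n_west + self.n_east

    def derived_counts(self, subset: np.ndarray | None = None):
        """Oriented derived counts (honouring flips) for a sample subset.

        Returns (counts, n_sub) keeping only sites polymorphic in the subset.
        """
        g = self.genotypes if subset is None else self.genotypes[:, subset]
        n_sub = g.shape[1]
        c = g.sum(axis=1)
        c = np.where(self.flipped, n_sub - c, c)
        keep = (c > 0) & (c < n_sub)
        return c[keep], n_sub


def _pop_assignment(config: SimConfig):
    copies = config.ploidy
    west = ["W"] * (config.n_west * copies)
    east = ["E"] * (config.n_east * copies)
    return west + east


def simulate_sequence_tables(params: DivergenceModelParams, config: SimConfig,
                             rng: np.random.Generator,
                             epochs=None, pop_assignment=None) -> SeqSimResult:
    """Infinite-sites simulation returning the true derived-state matrix."""
    if config.ploidy != 1:
        raise ValueError("sequence loci are haploid-sampled (ploidy 1)")
    pops = pop_assignment if pop_assignment is not None else _pop_assignment(config)
    tree = simulate_genealogy(pops, epochs or divergence_epochs(params), rng)
    branches = place_mutations(tree, params.mu_seq * config.length, rng)
    n = tree.n
    geno = np.zeros((len(branches), n), dtype=bool)
    for row, b in enumerate(branches):
        geno[row, tree.leaves_under[b]] = True
    # drop mutations fixed in the sample (on the root branch there are none,
    # but guard anyway) and keep polymorphic rows only
    counts = geno.sum(axis=1)
    keep = (counts > 0) & (counts < n)
    geno = geno[keep]
    west = np.zeros(n, dtype=bool)
    west[: config.n_west] = True
    return SeqSimResult(n_west=config.n_west, n_east=config.n_east, genotypes=geno, west=west)


def apply_misorientation_result(sim: SeqSimResult, m: float,
                                rng: np.random.Generator) -> SeqSimResult:
    """Independently flip each site's polarity with probability m."""
    if not (0.0 <= m <= 1.0):
        raise ValueError("misorientation rate must be in [0, 1]")
    flips = rng.random(sim.genotypes.shape[0]) < m
    return SeqSimResult(n_west=sim.n_west, n_east=sim.n_east, genotypes=sim.genotypes,
                        west=sim.west, flipped=sim.flipped ^ flips)


def apply_misorientation(oriented: OrientedAlignment, m: float, seed) -> OrientedAlignment:
    """Flip each oriented site's derived count i -> n - i with probability m."""
    if not (0.0 <= m <= 1.0):
        raise ValueError("misorientation rate must be in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    dc = oriented.derived_counts.copy()
    flips = rng.random(dc.size) < m
    dc[flips] = oriented.n - dc[flips]
    return OrientedAlignment(n=oriented.n, derived_counts=dc,
                             unorientable=list(oriented.unorientable))


# ------------------------------------------ Jukes–Cantor site states

def _jc_site_states(tree: SimTree, branches: np.ndarray, length: int,
                    rng: np.random.Generator):
    """Leaf states at mutated sites under Jukes–Cantor recurrent mutation.

    Returns (site_positions, states) with states an (m_sites, n) int8 matrix;
    the ancestral state at every mutated site is coded 0 and recoded to a
    random base only when sequences are materialised.
    """
    if len(branches) == 0:
        return np.empty(0, dtype=np.int64), np.empty((0, tree.n), dtype=np.int8)
    sites = rng.integers(0, length, size=len(branches))
    order = np.argsort(sites, kind="stable")
    sites_sorted = sites[order]
    branches_sorted = branches[order]
    uniq, starts = np.unique(sites_sorted, return_index=True)
    states_rows = []
    n = tree.n
    # nodes in decreasing-time order: parents always precede children
    node_order = np.argsort(-tree.time, kind="stable")
    for k, site in enumerate(uniq):
        lo = starts[k]
        hi = starts[k + 1] if k + 1 < len(uniq) else len(sites_sorted)
        bs = branches_sorted[lo:hi]
        if len(bs) == 1:
            row = np.zeros(n, dtype=np.int8)
            row[tree.leaves_under[bs[0]]] = rng.integers(1, 4)
            states_rows.append(row)
            continue
        # multiple hits: evolve the site down the tree with per-branch
        # mutation times drawn uniformly along each branch
        muts: dict[int, list[float]] = {}
        for b in bs:
            top = tree.time[tree.parent[b]] if tree.parent[b] >= 0 else tree.time[b]
            muts.setdefault(int(b), []).append(
                float(rng.uniform(tree.time[b], max(top, tree.time[b])))
            )
        node_state = np.zeros(2 * n - 1, dtype=np.int8)
        for node in node_order:
            p = tree.parent[node]
            state = node_state[p] if p >= 0 else np.int8(0)
            if int(node) in muts:
                for _t in sorted(muts[int(node)], reverse=True):  # oldest first
                    choices = [s for s in range(4) if s != state]
                    state = np.int8(choices[int(rng.integers(3))])
            node_state[node] = state
        states_rows.append(node_state[:n].copy())
    return uniq, np.array(states_rows, dtype=np.int8)


@dataclass
class JCSimResult:
    """Jukes–Cantor sequence simulation: states at mutated sites only."""

    n_west: int
    n_east: int
    length: int
    site_positions: np.ndarray
    states: np.ndarray            # (m_sites, n) int8, 0 = ancestral
    west: np.ndarray

    @property
    def n(self) -> int:
        return self.n_west + self.n_east


def simulate_sequence_jc(params: DivergenceModelParams, config: SimConfig,
                         rng: np.random.Generator, epochs=None,
                         pop_assignment=None) -> JCSimResult:
    pops = pop_assignment if pop_assignment is not None else _pop_assignment(config)
    tree = simulate_genealogy(pops, epochs or divergence_epochs(params), rng)
    branches = place_mutations(tree, params.mu_seq * config.length, rng)
    positions, states = _jc_site_states(tree, branches, config.length, rng)
    west = np.zeros(tree.n, dtype=bool)
    west[: config.n_west] = True
    return JCSimResult(n_west=config.n_west, n_east=config.n_east, length=config.length,
                       site_positions=positions, states=states, west=west)


# --------------------------------------------------- full alignments

def simulate_sequence_locus(params: DivergenceModelParams, config: SimConfig, seed,
                            sample_ids=None, name: str = "sim_locus",
                            outgroup_time: float | None = None,
                            epochs=None, pop_assignment=None):
    """Simulate one sequence locus as a LocusAlignment plus orientation truth.

    Returns (alignment, truth) where truth is the OrientedAlignment of true
    derived counts. With ``outgroup_time`` set, an outgroup sequence diverging
    that many generations ago (or at the ingroup root, if deeper) is attached;
    its private mutations make naive outgroup polarisation imperfect exactly
    as in real data.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if config.mutation_mode == "infinite_sites":
        sim = simulate_sequence_tables(params, config, rng, epochs=epochs,
                                       pop_assignment=pop_assignment)
        m_sites = sim.genotypes.shape[0]
        if m_sites > config.length:
            raise ValueError("locus too short for the simulated number of mutations")
        positions = np.sort(rng.choice(config.length, size=m_sites, replace=False))
        anc_states = np.zeros(m_sites, dtype=np.int8)
        der_states = rng.integers(1, 4, size=m_sites).astype(np.int8)
        ancestral = rng.integers(0, 4, size=config.length)
        base_codes = {}
        for k, pos in enumerate(positions):
            a = ancestral[pos]
            others = [x for x in range(4) if x != a]
            base_codes[pos] = (a, others)
        n = sim.n
        mat = np.tile(BASES[ancestral], (n, 1))
        truth_counts = []
        for k, pos in enumerate(positions):
            a, others = base_codes[pos]
            derived_base = BASES[others[der_states[k] - 1]]
            carriers = sim.genotypes[k]
            mat[carriers, pos] = derived_base
            truth_counts.append(int(carriers.sum()))
        out_seq = None
        if outgroup_time is not None:
            out_seq, mat = _attach_outgroup_is(mat, ancestral, params, config,
                                               outgroup_time, rng)
        ids = sample_ids or [f"s{i}" for i in range(n)]
        seqs = {sid: "".join(mat[i]) for i, sid in enumerate(ids)}
        aln = LocusAlignment(name=name, sequences=seqs, outgroup=out_seq)
        truth = OrientedAlignment(n=n, derived_counts=np.array(truth_counts, dtype=int))
        return aln, truth
    # Jukes–Cantor mode
    sim = simulate_sequence_jc(params, config, rng, epochs=epochs,
                               pop_assignment=pop_assignment)
    ancestral = rng.integers(0, 4, size=config.length)
    n = sim.n
    mat = np.tile(BASES[ancestral], (n, 1))
    truth_counts = []
    for k, pos in enumerate(sim.site_positions):
        # recode: state 0 is the ancestral base at this site; others permuted
        a = ancestral[pos]
        others = [x for x in range(4) if x != a]
        codes = np.array([a] + others)
        col = codes[sim.states[k]]
        mat[:, pos] = BASES[col]
        dcount = int((sim.states[k] != 0).sum())
        if 0 < dcount < n:
            truth_counts.append(dcount)
    out_seq = None
    if outgroup_time is not None:
        out_seq, mat = _attach_outgroup_is(mat, ancestral, params, config, outgroup_time, rng)
    ids = sample_ids or [f"s{i}" for i in range(n)]
    seqs = {sid: "".join(mat[i]) for i, sid in enumerate(ids)}
    aln = LocusAlignment(name=name, sequences=seqs, outgroup=out_seq)
    truth = OrientedAlignment(n=n, derived_counts=np.array(truth_counts, dtype=int))
    return aln, truth


def _attach_outgroup_is(mat: np.ndarray, ancestral: np.ndarray,
                        params: DivergenceModelParams, config: SimConfig,
                        outgroup_time: float, rng: np.random.Generator):
    """Outgroup sequence: the ancestral sequence with Jukes–Cantor mutations
    accumulated over ~2 * outgroup_time generations of independent evolution
    (outgroup branch plus the ingroup stem)."""
    t = 2.0 * float(outgroup_time)
    out = ancestral.copy()
    n_mut = rng.poisson(params.mu_seq * config.length * t)
    hit = rng.integers(0, config.length, size=n_mut)
    for pos in hit:
        others = [x for x in range(4) if x != out[pos]]
        out[pos] = others[int(rng.integers(3))]
    return "".join(BASES[out]), mat


# ----------------------------------------------------- microsatellites

def reflect_into_range(values: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Fold unbounded repeat counts into [lo, hi] by boundary reflection."""
    if hi - lo < 1:
        raise ValueError("allele range width must be >= 2")
    period = 2 * (hi - lo)
    x = np.mod(values - lo, period)
    folded = np.minimum(x, period - x)
    return (lo + folded).astype(int)


def simulate_microsat_values(params: DivergenceModelParams, config: SimConfig,
                             allele_range: tuple[int, int],
                             rng: np.random.Generator, epochs=None) -> np.ndarray:
    """Per-gene-copy repeat counts under the generalised stepwise model."""
    if config.ploidy != 2:
        raise ValueError("microsatellites are diploid (ploidy 2)")
    lo, hi = allele_range
    pops = _pop_assignment(config)
    tree = simulate_genealogy(pops, epochs or divergence_epochs(params), rng)
    branches = place_mutations(tree, params.mu_ssr, rng)
    values = np.zeros(tree.n, dtype=np.int64)
    if len(branches):
        if params.p_ssr == 0.0:
            steps = np.ones(len(branches), dtype=np.int64)
        else:
            steps = rng.geometric(1.0 - params.p_ssr, size=len(branches))
        steps *= rng.choice((-1, 1), size=len(branches))
        leaf_idx = np.concatenate([tree.leaves_under[b] for b in branches])
        rep = np.repeat(steps, [len(tree.leaves_under[b]) for b in branches])
        np.add.at(values, leaf_idx, rep)
    founder = (lo + hi) // 2
    return reflect_into_range(values + founder, lo, hi)


def simulate_microsat_locus(params: DivergenceModelParams, config: SimConfig,
                            motif: int, allele_range: tuple[int, int], seed,
                            sample_ids=None, name: str = "sim_ssr") -> MicrosatLocus:
    """Simulate one diploid microsatellite locus under the divergence model."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = simulate_microsat_values(params, config, allele_range, rng)
    n_ind = (config.n_west + config.n_east)
    ids = sample_ids or [f"s{i}" for i in range(n_ind)]
    genos = {sid: (int(values[2 * i]), int(values[2 * i + 1])) for i, sid in enumerate(ids)}
    return MicrosatLocus(name=name, motif=motif, allele_range=allele_range, genotypes=genos)


# -------------------------------------------- study-shaped templates

@dataclass(frozen=True)
class BundleTemplate:
    """Shape of the observed dataset the reference table must mirror:
    sample sizes per population, control sequence-locus lengths, and
    microsatellite motif sizes / allele ranges."""

    n_west: int
    n_east: int
    seq_lengths: tuple            # ((name, L), ...)
    ssr_meta: tuple               # ((name, motif, (lo, hi)), ...)

    @classmethod
    def from_bundle(cls, bundle) -> "BundleTemplate":
        n_west = len(bundle.ids_in_group("West"))
        n_east = len(bundle.ids_in_group("East"))
        seq = tuple((name, bundle.registry[name].length)
                    for name in bundle.loci_of_kind("control_seq"))
        ssr = tuple((name, bundle.microsats[name].motif, tuple(bundle.microsats[name].allele_range))
                    for name in bundle.loci_of_kind("control_ssr"))
        return cls(n_west=n_west, n_east=n_east, seq_lengths=seq, ssr_meta=ssr)


def _multiallelic_pair_sums(states: np.ndarray, idx_w: np.ndarray, idx_e: np.ndarray):
    """(sum within-pair diffs W, E, between) over sites of an (m, n) state matrix."""
    n_w, n_e = len(idx_w), len(idx_e)
    dw = de = db = 0.0
    for row in states:
        vals = np.unique(row)
        if len(vals) < 2:
            continue
        cw = np.array([(row[idx_w] == v).sum() for v in vals], dtype=float)
        ce = np.array([(row[idx_e] == v).sum() for v in vals], dtype=float)
        dw += n_w * (n_w - 1) / 2.0 - float((cw * (cw - 1) / 2.0).sum())
        de += n_e * (n_e - 1) / 2.0 - float((ce * (ce - 1) / 2.0).sum())
        db += n_w * n_e - float((cw * ce).sum())
    return dw, de, db


def simulate_summary_stats(params: DivergenceModelParams, template: BundleTemplate,
                           rng: np.random.Generator) -> np.ndarray:
    """One draw of the 9-entry ABC summary vector under the divergence model.

    Sequence loci use Jukes–Cantor mutation; microsatellites the generalised
    stepwise model. Definitions match :func:`carotscan.sumstats.abc_summary_vector`
    exactly (same kernels, multi-locus ratio-of-sums Hudson FST).
    """
    n_w, n_e = template.n_west, template.n_east
    # --- microsatellites
    ssr_mats = []
    for _name, _motif, allele_range in template.ssr_meta:
        cfg = SimConfig(n_west=n_w, n_east=n_e, length=1, ploidy=2)
        vals = simulate_microsat_values(params, cfg, tuple(allele_range), rng)
        ssr_mats.append(vals.reshape(-1, 2))
    labels = np.array(["West"] * n_w + ["East"] * n_e)
    from . import sumstats as ss
    idx_w_ind = np.arange(n_w)
    idx_e_ind = np.arange(n_w, n_w + n_e)
    mean_w = float(np.mean([len(np.unique(m[idx_w_ind])) for m in ssr_mats]))
    mean_e = float(np.mean([len(np.unique(m[idx_e_ind])) for m in ssr_mats]))
    wc = ss.weir_cockerham_fst(ssr_mats, labels)
    das = ss.shared_allele_distance(ssr_mats, labels)
    # --- sequence loci (Jukes–Cantor)
    idx_w = np.arange(n_w)
    idx_e = np.arange(n_w, n_w + n_e)
    hap_w, hap_e, hap_p, segs = [], [], [], []
    hw_sum = hb_sum = 0.0
    pairs_w = n_w * (n_w - 1) / 2.0
    pairs_e = n_e * (n_e - 1) / 2.0
    pairs_b = float(n_w * n_e)
    for _name, length in template.seq_lengths:
        cfg = SimConfig(n_west=n_w, n_east=n_e, length=length, ploidy=1,
                        mutation_mode="jukes_cantor")
        sim = simulate_sequence_jc(params, cfg, rng)
        states = sim.states
        poly = np.array([len(np.unique(r)) > 1 for r in states], dtype=bool) \
            if len(states) else np.zeros(0, dtype=bool)
        spoly = states[poly]
        segs.append(spoly.shape[0])
        if spoly.shape[0] == 0:
            hap_p.append(1)
            hap_w.append(1)
            hap_e.append(1)
        else:
            hap_p.append(np.unique(spoly.T, axis=0).shape[0])
            hap_w.append(np.unique(spoly[:, idx_w].T, axis=0).shape[0])
            hap_e.append(np.unique(spoly[:, idx_e].T, axis=0).shape[0])
        dw, de, db = _multiallelic_pair_sums(spoly, idx_w, idx_e)
        hw_sum += 0.5 * (dw / pairs_w + de / pairs_e)
        hb_sum += db / pairs_b
    fst_seq = 1.0 - hw_sum / hb_sum if hb_sum > 0 else np.nan
    return np.array([mean_w, mean_e, wc, das,
                     float(np.mean(hap_w)), float(np.mean(hap_e)), float(np.mean(hap_p)),
                     float(np.mean(segs)), fst_seq])
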