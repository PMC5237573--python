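"""Forward Wright-Fisher simulation of a single 1-Morgan chromosome.

The demography mimics a cattle-like history: a long phase at effective size
Ne = 600, a log-linear decline to Ne = 100, a short constant phase at
Ne = 100, and a final expansion to a sample of 1500 genotyped individuals.  Mutation follows the infinite-sites model on
a continuous physical axis; recombination is Poisson with expectation equal
to the genetic length (in Morgan) per meiosis, with a linear genetic-physical
map.  All randomness flows from a single seed, so populations are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from numba import njit

__all__ = [
    "DemographyConfig",
    "Population",
    "MarkerPanel",
    "build_ne_schedule",
    "simulate_population",
    "select_marker_panel",
]


@dataclass
class DemographyConfig:
    """Demographic and genomic parameters of the forward simulation.

    Defaults reproduce the study design: 1051 generations, Ne = 600 for
    the first 650 generations, a log-linear decline to 100 by generation
    1000, constant at 100 afterwards, and 1500 individuals sampled as
    offspring of the final breeding population.  ``physical_length``
    defaults to 1.6e8 bp (1 cM = 1.6 Mb): with the 1e-8 per-bp mutation
    rate this is the genome size at which the final sample segregates the
    target ~7k SNPs with MAF > 0.01 and shows a bovine-like LD decay.
    """

    n_generations: int = 1051
    final_sample_n: int = 1500
    mutation_rate: float = 1e-8       # per bp per meiosis
    genetic_length: float = 1.0       # Morgan
    physical_length: float = 1.6e8    # bp
    ne_schedule: Optional[np.ndarray] = None  # per-generation Ne override
    ne_initial: int = 600
    ne_final: int = 100
    decline_start: int = 650          # last generation at ne_initial
    decline_end: int = 1000           # first generation at ne_final
    seed: int = 0
    max_sites: int = 60_000           # capacity of the site buffer
    equilibrium_founders: bool = True # seed founders at coalescent equilibrium
    founder_haplotypes: Optional[np.ndarray] = None   # (2*Ne0, S) override
    founder_positions_bp: Optional[np.ndarray] = None # must be sorted
    drop_monomorphic: bool = True     # keep fixed/lost sites if False

    def resolved_ne_schedule(self) -> np.ndarray:
        if self.ne_schedule is not None:
            sched = np.asarray(self.ne_schedule, dtype=np.int64)
            if sched.shape != (self.n_generations,):
                raise ValueError(
                    f"ne_schedule must have length {self.n_generations}"
                )
            if np.any(sched < 2):
                raise ValueError("effective sizes must be >= 2")
            return sched
        return build_ne_schedule(self)


@dataclass
class Population:
    """Phased final-generation sample.

    ``haplotypes`` is a (2N, S) 0/1 matrix, rows 2i and 2i+1 belonging to
    individual i.  ``freqs`` holds the mutant (derived, 1) allele frequency
    per site; positions are strictly increasing.
    """

    haplotypes: np.ndarray
    positions_bp: np.ndarray
    positions_cm: np.ndarray
    freqs: np.ndarray
    n_individuals: int

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def genotypes(self, sites: Optional[Sequence[int]] = None) -> np.ndarray:
        """0/1/2 mutant-allele dosage matrix (N x S or N x len(sites))."""
        hap = self.haplotypes
        x = hap[0::2].astype(np.int8) + hap[1::2].astype(np.int8)
        if sites is not None:
            x = x[:, np.asarray(sites, dtype=np.int64)]
        return x

    def maf(self) -> np.ndarray:
        return np.minimum(self.freqs, 1.0 - self.freqs)


@dataclass
class MarkerPanel:
    """An ordered subset of population sites used as the SNP panel."""

    snp_indices: np.ndarray
    density_label: str
    maf_min: float
    includes_causals: bool = False

    def __len__(self) -> int:
        return len(self.snp_indices)


def build_ne_schedule(config: DemographyConfig) -> np.ndarray:
    """Per-generation effective sizes, indexed by generation - 1.

    Constant at ``ne_initial`` through ``decline_start``, then log-linear
    (exponential in Ne) down to ``ne_final`` at ``decline_end``, and
    constant afterwards.  Log-linear decay has a constant proportional
    rate, so the absolute decline is steepest while Ne is still large and
    the approach to Ne = 100 happens over the last generations.
    """
    n = config.n_generations
    if n < 1:
        raise ValueError("n_generations must be >= 1")
    if config.ne_initial < 2 or config.ne_final < 2:
        raise ValueError("effective sizes must be >= 2")
    g = np.arange(1, n + 1, dtype=np.float64)
    sched = np.full(n, float(config.ne_initial))
    span = config.decline_end - config.decline_start
    if span > 0:
        frac = np.clip((g - config.decline_start) / span, 0.0, 1.0)
        ratio = config.ne_final / config.ne_initial
        sched = config.ne_initial * ratio ** frac
    sched = np.maximum(np.rint(sched), config.ne_final).astype(np.int64)
    sched[g > config.decline_end] = config.ne_final
    return sched


@njit(cache=False)
def _wf_forward(founder, founder_pos, ne_sched, final_n, mu_gamete,
                genetic_length, physical_length, seed,
                cap, drop_mono):  # pragma: no cover - exercised via wrapper
    """Forward WF reproduction over the Ne schedule plus final expansion.

    Site columns are kept sorted by physical position throughout, so a
    meiosis is a handful of contiguous slice copies between crossover
    breakpoints; new mutation columns are appended during a generation and
    merged into position order by the per-generation compaction sweep that
    also drops sites monomorphic among the children.
    """
    np.random.seed(seed)
    n_gen = ne_sched.shape[0]
    max_n = final_n
    for i in range(n_gen):
        if ne_sched[i] > max_n:
            max_n = ne_sched[i]
    A = np.zeros((2 * max_n, cap), dtype=np.uint8)
    B = np.zeros((2 * max_n, cap), dtype=np.uint8)
    pos_bp = np.empty(cap, dtype=np.float64)
    pos_new = np.empty(cap, dtype=np.float64)
    tmp = np.empty(cap, dtype=np.uint8)
    nsites = founder.shape[1]
    n_par = ne_sched[0]
    A[: 2 * n_par, :nsites] = founder
    pos_bp[:nsites] = founder_pos
    cx = np.empty(64, dtype=np.float64)

    # columns [0, ns_sorted) are in position order; [ns_sorted, nsites) is
    # the unsorted tail of recent mutations, folded in every few generations
    ns_sorted = nsites
    compact_every = 8

    for g in range(1, n_gen + 1):
        n_child = ne_sched[g] if g < n_gen else final_n
        ns_par = nsites
        for k in range(2 * n_child):
            par = np.random.randint(n_par)
            start = np.random.randint(2)
            ncx = np.random.poisson(genetic_length)
            if ncx > 64:
                ncx = 64
            if ncx == 0:
                B[k, :ns_par] = A[2 * par + start, :ns_par]
            else:
                for c in range(ncx):
                    # uniform in genetic distance == uniform in bp here
                    cx[c] = np.random.uniform(0.0, physical_length)
                cx[:ncx].sort()
                # sorted block: contiguous slices between breakpoints
                prev = 0
                src = start
                for c in range(ncx):
                    idx = np.searchsorted(pos_bp[:ns_sorted], cx[c])
                    if idx > prev:
                        B[k, prev:idx] = A[2 * par + src, prev:idx]
                    prev = idx
                    src = 1 - src
                B[k, prev:ns_sorted] = A[2 * par + src, prev:ns_sorted]
                # unsorted tail: per-site crossover parity
                for s in range(ns_sorted, ns_par):
                    cnt = 0
                    p = pos_bp[s]
                    for c in range(ncx):
                        if p > cx[c]:
                            cnt += 1
                    B[k, s] = A[2 * par + ((start + cnt) & 1), s]
            # new mutations on this gamete (infinite sites, appended)
            nmut = np.random.poisson(mu_gamete)
            for _ in range(nmut):
                if nsites >= cap:
                    return A[:0, :0], pos_bp[:0], -1
                col = nsites
                pos_bp[col] = np.random.uniform(0.0, physical_length)
                for r in range(2 * n_child):
                    B[r, col] = 0
                B[k, col] = 1
                nsites += 1
        tot = 2 * n_child
        if g % compact_every == 0 or g == n_gen:
            # drop sites monomorphic among the children and merge the tail
            # into position order with one row-major gather
            sums = np.zeros(nsites, dtype=np.int64)
            for r in range(tot):
                row = B[r]
                for s in range(nsites):
                    sums[s] += row[s]
            perm = np.empty(nsites, dtype=np.int64)
            new_idx = np.empty(nsites - ns_sorted, dtype=np.int64)
            n_new = 0
            for s in range(ns_sorted, nsites):
                if (0 < sums[s] < tot) or drop_mono == 0:
                    new_idx[n_new] = s
                    n_new += 1
            for i in range(1, n_new):
                key = new_idx[i]
                j = i - 1
                while j >= 0 and pos_bp[new_idx[j]] > pos_bp[key]:
                    new_idx[j + 1] = new_idx[j]
                    j -= 1
                new_idx[j + 1] = key
            nkeep = 0
            ptr = 0
            for s in range(ns_sorted):
                if (0 < sums[s] < tot) or drop_mono == 0:
                    while (ptr < n_new
                           and pos_bp[new_idx[ptr]] < pos_bp[s]):
                        perm[nkeep] = new_idx[ptr]
                        nkeep += 1
                        ptr += 1
                    perm[nkeep] = s
                    nkeep += 1
            while ptr < n_new:
                perm[nkeep] = new_idx[ptr]
                nkeep += 1
                ptr += 1
            for r in range(tot):
                row = B[r]
                for w in range(nkeep):
                    tmp[w] = row[perm[w]]
                row[:nkeep] = tmp[:nkeep]
            for w in range(nkeep):
                pos_new[w] = pos_bp[perm[w]]
            pos_bp[:nkeep] = pos_new[:nkeep]
            nsites = nkeep
            ns_sorted = nkeep
        A, B = B, A
        n_par = n_child

    return A[: 2 * final_n, :nsites].copy(), pos_bp[:nsites].copy(), nsites


def _equilibrium_founders(config: DemographyConfig, ne0: int):
    """Founder haplotypes at mutation-drift-recombination equilibrium.

    A neutral coalescent sample of the founder generation (2 * Ne0
    haplotypes) with the same mutation and recombination rates supplies the
    stationary standing variation that an infinitely long forward burn-in
    would produce.  Infinite-sites mutations on a continuous axis match the
    forward model.
    """
    import msprime

    ts = msprime.sim_ancestry(
        samples=ne0,
        population_size=ne0,
        sequence_length=config.physical_length,
        recombination_rate=config.genetic_length / config.physical_length,
        discrete_genome=False,
        random_seed=config.seed % (2**31 - 2) + 1,
    )
    ts = msprime.sim_mutations(
        ts,
        rate=config.mutation_rate,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
        random_seed=(config.seed + 1) % (2**31 - 2) + 1,
    )
    hap = np.ascontiguousarray(ts.genotype_matrix().T.astype(np.uint8))
    pos = ts.tables.sites.position.astype(np.float64)
    return hap, pos


def simulate_population(config: DemographyConfig) -> Population:
    """Run the forward simulation and return the final genotyped sample.

    The final ``final_sample_n`` individuals are generated as one expanded
    offspring generation of the last breeding population, so the sample can
    exceed the final effective size.  Sites monomorphic in the sample are
    dropped; the mutant-allele frequency is computed from the sample itself.
    """
    if config.physical_length is None or config.physical_length <= 0:
        raise ValueError("physical_length must be set and positive")
    if config.genetic_length <= 0:
        raise ValueError("genetic_length must be positive")
    sched = config.resolved_ne_schedule()
    mu_gamete = config.mutation_rate * config.physical_length
    if config.founder_haplotypes is not None:
        founder = np.ascontiguousarray(
            config.founder_haplotypes, dtype=np.uint8
        )
        founder_pos = np.asarray(config.founder_positions_bp, dtype=np.float64)
        if founder.shape != (2 * int(sched[0]), len(founder_pos)):
            raise ValueError(
                "founder haplotypes must be (2*Ne0, len(founder_positions))"
            )
        if np.any(np.diff(founder_pos) <= 0):
            raise ValueError("founder positions must be strictly increasing")
    elif config.equilibrium_founders and config.mutation_rate > 0:
        founder, founder_pos = _equilibrium_founders(config, int(sched[0]))
        if founder.shape[1] > config.max_sites:
            raise RuntimeError(
                "founder variation exceeds max_sites; increase the buffer"
            )
    else:
        founder = np.zeros((2 * int(sched[0]), 0), dtype=np.uint8)
        founder_pos = np.zeros(0, dtype=np.float64)
    hap, pos_bp, nsites = _wf_forward(
        founder,
        founder_pos,
        sched,
        config.final_sample_n,
        mu_gamete,
        config.genetic_length,
        config.physical_length,
        config.seed % (2**31 - 1),
        config.max_sites,
        1 if config.drop_monomorphic else 0,
    )
    if nsites < 0:
        raise RuntimeError(
            "site buffer overflow: increase DemographyConfig.max_sites"
        )
    order = np.argsort(pos_bp, kind="stable")
    hap = np.ascontiguousarray(hap[:, order])
    pos_bp = pos_bp[order]
    freqs = hap.mean(axis=0)
    pos_cm = pos_bp / config.physical_length * config.genetic_length * 100.0
    return Population(
        haplotypes=hap,
        positions_bp=pos_bp,
        positions_cm=pos_cm,
        freqs=freqs,
        n_individuals=config.final_sample_n,
    )


def select_marker_panel(
    pop: Population,
    target_count: Optional[int],
    maf_min: float,
    causal_ids: Optional[Sequence[int]] = None,
    keep_causals: bool = False,
    density_label: str = "",
) -> MarkerPanel:
    """Thin the segregating sites to a marker panel.

    With ``target_count`` set, exactly that many sites with MAF >= maf_min
    are chosen approximately equidistant on the genetic map: target grid
    points are placed uniformly over the map and the nearest eligible,
    not-yet-used SNP is taken for each (ties towards the lower position).
    With ``target_count=None`` all eligible sites are returned unthinned
    (the "full sequence" panel).  Causal sites are excluded unless
    ``keep_causals`` is set.
    """
    maf = pop.maf()
    eligible = maf >= maf_min
    causal = np.zeros(pop.n_sites, dtype=bool)
    if causal_ids is not None:
        causal[np.asarray(causal_ids, dtype=np.int64)] = True
    if not keep_causals:
        eligible &= ~causal
    idx = np.flatnonzero(eligible)
    if target_count is None:
        return MarkerPanel(idx, density_label or "all", maf_min, keep_causals)
    if len(idx) < target_count:
        raise ValueError(
            f"only {len(idx)} eligible sites for a {target_count}-SNP panel"
        )
    pos = pop.positions_cm[idx]
    lo, hi = pos[0], pos[-1]
    if target_count == 1:
        grid = np.array([(lo + hi) / 2.0])
    else:
        grid = np.linspace(lo, hi, target_count)
    used = np.zeros(len(idx), dtype=bool)
    chosen = np.empty(target_count, dtype=np.int64)
    for i, g in enumerate(grid):
        j = int(np.searchsorted(pos, g))
        l = j - 1
        while l >= 0 and used[l]:
            l -= 1
        r = j
        while r < len(idx) and used[r]:
            r += 1
        if l < 0:
            best = r
        elif r >= len(idx):
            best = l
        else:
            # tie resolves towards the lower position
            best = l if abs(pos[l] - g) <= abs(pos[r] - g) else r
        used[best] = True
        chosen[i] = idx[best]
    chosen.sort()
    return MarkerPanel(chosen, density_label, maf_min, keep_causals)
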