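"""Forward-in-time simulation of a single diploid chromosome.

The study design needs a population whose linkage disequilibrium (LD)
structure is controllable: imputation reliability is driven by LD decay,
which in a randomly mating population of effective size ``Ne`` follows
Sved's expectation ``E[r^2] ~ 1/(4*Ne*c + 1)`` for two loci ``c`` Morgan
apart.  A discrete Wright-Fisher simulator with recombination and
symmetric biallelic mutation produces exactly that structure at desk
scale (``Ne`` around 100, a few thousand segregating sites), which is all
the downstream evaluation requires: the analysis depends on LD and the
allele-frequency spectrum, not on any particular real genome.

Variants live on a fixed lattice of candidate sites placed uniformly on
the chromosome; each lattice site stands for the stretch of base pairs
around it, so the per-site mutation probability is the per-base rate
times the bp represented per site.  Monomorphic sites are retained in
the output — downstream filters remove non-segregating sites, mirroring
how called-but-fixed variants are handled in sequence data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MORGAN_PER_BP_DEFAULT",
    "SimulationConfig",
    "MarkerMap",
    "HaplotypeSet",
    "GenotypeMatrix",
    "MISSING",
    "simulate_population",
    "sample_diploids",
    "segregating_mask",
    "ld_decay_bins",
]

#: 1 Mb = 1 cM, the standard livestock map convention.
MORGAN_PER_BP_DEFAULT = 0.01 / 1_000_000

#: Sentinel for a missing genotype.
MISSING = -1


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the Wright-Fisher simulation.

    Parameters
    ----------
    population_size_diploid
        Number of diploid individuals per generation (the effective size
        ``Ne`` of the simulated population).
    n_generations
        Generations of random mating to run.  ``0`` returns founder
        haplotypes with sites drawn independently, i.e. no LD structure.
    chromosome_length_bp
        Physical chromosome length in base pairs.
    mutation_rate
        Per-base, per-generation probability of a symmetric 0<->1 flip.
    recombination_rate_per_bp
        Morgan per base pair.  The default encodes 1 Mb = 1 cM.
    n_sample_individuals
        Diploid individuals drawn from the final generation for study.
    n_candidate_sites
        Size of the site lattice the simulator tracks; each site
        represents ``chromosome_length_bp / n_candidate_sites`` bp.
    seed
        Seed for all randomness; identical config + seed gives
        bit-identical output.
    """

    population_size_diploid: int = 100
    n_generations: int = 400
    chromosome_length_bp: int = 10_000_000
    mutation_rate: float = 1.4e-7
    recombination_rate_per_bp: float = MORGAN_PER_BP_DEFAULT
    n_sample_individuals: int = 60
    n_candidate_sites: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size_diploid < 2:
            raise ValueError("population_size_diploid must be >= 2")
        if self.n_sample_individuals > self.population_size_diploid:
            raise ValueError(
                "n_sample_individuals exceeds population_size_diploid"
            )
        if self.chromosome_length_bp <= 0:
            raise ValueError("chromosome_length_bp must be positive")
        if self.mutation_rate < 0 or self.recombination_rate_per_bp < 0:
            raise ValueError("rates must be non-negative")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        if self.n_candidate_sites < 2:
            raise ValueError("n_candidate_sites must be >= 2")


@dataclass
class MarkerMap:
    """Ordered marker positions on one chromosome.

    ``positions_morgan`` is derived from ``positions_bp`` through a
    linear genetic map (``morgan_per_bp``), the same conversion used by
    the LD-decay model downstream.
    """

    chromosome_id: str
    positions_bp: np.ndarray
    morgan_per_bp: float = MORGAN_PER_BP_DEFAULT
    ref_alleles: np.ndarray | None = None
    alt_alleles: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions_bp = np.asarray(self.positions_bp, dtype=np.int64)
        if self.positions_bp.ndim != 1:
            raise ValueError("positions_bp must be one-dimensional")
        if len(self.positions_bp) and np.any(np.diff(self.positions_bp) <= 0):
            raise ValueError("positions_bp must be strictly increasing")
        if self.ref_alleles is None:
            self.ref_alleles = np.full(len(self.positions_bp), "A", dtype=object)
        if self.alt_alleles is None:
            self.alt_alleles = np.full(len(self.positions_bp), "B", dtype=object)

    @property
    def positions_morgan(self) -> np.ndarray:
        return self.positions_bp * self.morgan_per_bp

    def __len__(self) -> int:
        return len(self.positions_bp)

    def take(self, indices: np.ndarray) -> "MarkerMap":
        """Sub-map at the given (increasing) marker indices."""
        idx = np.asarray(indices)
        return MarkerMap(
            chromosome_id=self.chromosome_id,
            positions_bp=self.positions_bp[idx],
            morgan_per_bp=self.morgan_per_bp,
            ref_alleles=np.asarray(self.ref_alleles, dtype=object)[idx],
            alt_alleles=np.asarray(self.alt_alleles, dtype=object)[idx],
        )

    def same_markers(self, other: "MarkerMap") -> bool:
        return (
            self.chromosome_id == other.chromosome_id
            and len(self) == len(other)
            and bool(np.all(self.positions_bp == other.positions_bp))
        )


@dataclass
class HaplotypeSet:
    """H x L matrix of binary alleles over an ordered marker map."""

    alleles: np.ndarray
    marker_map: MarkerMap
    haplotype_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("haplotype alleles must be binary")
        if self.alleles.shape[1] != len(self.marker_map):
            raise ValueError("marker_map length does not match allele columns")
        if not self.haplotype_ids:
            self.haplotype_ids = [f"hap{i}" for i in range(self.alleles.shape[0])]

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[1]

    def allele_frequency(self) -> np.ndarray:
        """Frequency of the alternate (``1``) allele per site."""
        return self.alleles.mean(axis=0)

    def take_markers(self, indices: np.ndarray) -> "HaplotypeSet":
        idx = np.asarray(indices)
        return HaplotypeSet(
            alleles=self.alleles[:, idx],
            marker_map=self.marker_map.take(idx),
            haplotype_ids=list(self.haplotype_ids),
        )

    def take_haplotypes(self, rows: np.ndarray) -> "HaplotypeSet":
        rows = np.asarray(rows)
        return HaplotypeSet(
            alleles=self.alleles[rows],
            marker_map=self.marker_map,
            haplotype_ids=[self.haplotype_ids[i] for i in rows],
        )


@dataclass
class GenotypeMatrix:
    """N x L genotypes coded 0/1/2 (count of the alternate allele).

    Missing entries carry the sentinel :data:`MISSING`.  When derived
    from a :class:`HaplotypeSet`, ``source_hap_indices`` records the two
    source haplotype rows per individual so truth-based tests can reach
    back to the phased alleles.
    """

    genotypes: np.ndarray
    marker_map: MarkerMap
    individual_ids: list[str] = field(default_factory=list)
    source_hap_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix")
        valid = np.isin(self.genotypes, (MISSING, 0, 1, 2))
        if not valid.all():
            raise ValueError("genotypes must be 0, 1, 2 or missing")
        if self.genotypes.shape[1] != len(self.marker_map):
            raise ValueError("marker_map length does not match genotype columns")
        if not self.individual_ids:
            self.individual_ids = [f"ind{i}" for i in range(self.genotypes.shape[0])]

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def allele_frequency(self) -> np.ndarray:
        """Alternate-allele frequency per site over non-missing calls."""
        g = np.ma.masked_equal(self.genotypes, MISSING)
        return np.asarray(g.mean(axis=0) / 2.0)

    def maf(self) -> np.ndarray:
        p = self.allele_frequency()
        return np.minimum(p, 1.0 - p)

    def take_markers(self, indices: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(indices)
        return GenotypeMatrix(
            genotypes=self.genotypes[:, idx],
            marker_map=self.marker_map.take(idx),
            individual_ids=list(self.individual_ids),
            source_hap_indices=self.source_hap_indices,
        )


def _founder_haplotypes(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Independent-site founders: no LD structure (n_generations = 0)."""
    n_hap = 2 * config.population_size_diploid
    freqs = rng.uniform(size=config.n_candidate_sites)
    return (rng.uniform(size=(n_hap, config.n_candidate_sites)) < freqs).astype(np.int8)


def simulate_population(config: SimulationConfig) -> HaplotypeSet:
    """Run the Wright-Fisher simulation and return the final haplotypes.

    Each generation, every child draws two parents uniformly (selfing
    allowed) and receives one recombinant gamete from each: the crossover
    count is Poisson with mean equal to the map length in Morgan, with
    breakpoints uniform on the genetic map.  Mutation then flips each
    site of each haplotype independently with the per-site probability
    (at most one event per site per generation).  Founders are
    monomorphic for allele 0, so all variation is mutation-derived.

    With ``n_generations = 0`` the founder haplotypes are returned with
    every site drawn independently — a no-LD control population.
    """
    rng = np.random.default_rng(config.seed)
    n_dip = config.population_size_diploid
    n_hap = 2 * n_dip
    n_sites = config.n_candidate_sites

    positions_bp = np.sort(
        rng.choice(config.chromosome_length_bp, size=n_sites, replace=False)
    ).astype(np.int64) + 1
    marker_map = MarkerMap(
        chromosome_id="1",
        positions_bp=positions_bp,
        morgan_per_bp=config.recombination_rate_per_bp,
    )

    if config.n_generations == 0:
        alleles = _founder_haplotypes(config, rng)
        return HaplotypeSet(alleles=alleles, marker_map=marker_map)

    pos_morgan = marker_map.positions_morgan
    map_length = config.chromosome_length_bp * config.recombination_rate_per_bp
    p_site = min(
        1.0, config.mutation_rate * config.chromosome_length_bp / n_sites
    )

    pop = np.zeros((n_hap, n_sites), dtype=np.int8)
    site_idx = np.arange(n_sites)

    for _ in range(config.n_generations):
        parents = rng.integers(0, n_dip, size=(n_dip, 2))
        n_cross = rng.poisson(map_length, size=(n_dip, 2))
        starts = rng.integers(0, 2, size=(n_dip, 2))
        children = np.empty_like(pop)
        for child in range(n_dip):
            for which in range(2):
                p = parents[child, which]
                pair = pop[2 * p : 2 * p + 2]
                k = n_cross[child, which]
                if k == 0:
                    gamete = pair[starts[child, which]]
                else:
                    breaks = np.sort(rng.uniform(0.0, map_length, size=k))
                    seg = np.searchsorted(breaks, pos_morgan)
                    hap_choice = (starts[child, which] + seg) % 2
                    gamete = pair[hap_choice, site_idx]
                children[2 * child + which] = gamete
        # sparse symmetric mutation: expected count is small, so draw
        # event positions instead of a full random matrix
        n_mut = rng.binomial(n_hap * n_sites, p_site)
        if n_mut:
            flat = rng.choice(n_hap * n_sites, size=n_mut, replace=False)
            rows, cols = np.unravel_index(flat, (n_hap, n_sites))
            children[rows, cols] ^= 1
        pop = children

    return HaplotypeSet(alleles=pop, marker_map=marker_map)


def sample_diploids(haps: HaplotypeSet, n: int, seed: int) -> GenotypeMatrix:
    """Pair ``2n`` haplotypes sampled without replacement into diploids.

    The genotype at every site is the sum of the pair's alleles.  The
    returned matrix records which haplotype rows formed each individual.
    """
    if 2 * n > haps.n_haplotypes:
        raise ValueError(
            f"cannot sample {n} diploids from {haps.n_haplotypes} haplotypes"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(haps.n_haplotypes, size=2 * n, replace=False)
    pairs = chosen.reshape(n, 2)
    genotypes = haps.alleles[pairs[:, 0]] + haps.alleles[pairs[:, 1]]
    return GenotypeMatrix(
        genotypes=genotypes.astype(np.int8),
        marker_map=haps.marker_map,
        source_hap_indices=pairs,
    )


def segregating_mask(genos: GenotypeMatrix) -> np.ndarray:
    """Boolean mask of sites that vary among the sampled individuals."""
    maf = genos.maf()
    return maf > 0


def ld_decay_bins(
    haps: HaplotypeSet,
    bin_edges_morgan: np.ndarray,
    maf_min: float = 0.1,
) -> "np.ndarray":
    """Mean pairwise r² in genetic-distance bins.

    Computes squared allele correlation for every pair of sites with
    MAF >= ``maf_min`` (LD-decay curves are conventionally drawn on
    common variants) and averages within the given distance bins.
    Returns an array of shape (n_bins, 3): mean distance, mean r², and
    pair count per bin; bins with no pairs hold NaN means.
    """
    freq = haps.allele_frequency()
    maf = np.minimum(freq, 1 - freq)
    keep = maf >= maf_min
    alleles = haps.alleles[:, keep].astype(np.float64)
    pos = haps.marker_map.positions_morgan[keep]
    if alleles.shape[1] < 2:
        raise ValueError("need at least two segregating common sites")

    corr = np.corrcoef(alleles, rowvar=False)
    r2 = corr**2
    iu = np.triu_indices(alleles.shape[1], k=1)
    r2_pairs = r2[iu]
    dist = np.abs(pos[iu[0]] - pos[iu[1]])

    edges = np.asarray(bin_edges_morgan, dtype=float)
    out = np.full((len(edges) - 1, 3), np.nan)
    which = np.digitize(dist, edges) - 1
    for b in range(len(edges) - 1):
        sel = which == b
        n = int(sel.sum())
        if n:
            out[b] = (dist[sel].mean(), r2_pairs[sel].mean(), n)
        else:
            out[b, 2] = 0
    return out
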