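"""Founder genome simulation: mutation-drift equilibrium, locus panels, base population, meiosis.

Loci are abstract biallelic sites laid out on a genetic map (cM).  A
:class:`HaplotypePool` holds the gametes of one generation as a dense 0/1
matrix; all downstream genotype bookkeeping (allele frequencies, allele-count
matrices) is exactly recomputable from it.  Recombination follows the Haldane
model: crossover count per chromosome ~ Poisson(length/100), positions
uniform, no interference.  Mutation is recurrent (allele flip) at a fixed
per-locus, per-meiosis rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

PANEL_UNUSED = 0
PANEL_MARKER = 1
PANEL_QTL = 2


@dataclass
class GenomeMap:
    """Genetic map: chromosome lengths, locus positions, panel labels, base frequencies.

    Positions are cM within chromosome, strictly increasing per chromosome.
    ``panel`` holds one label per locus (0 unused, 1 marker, 2 QTL); marker
    and QTL sets are disjoint by construction.  ``base_allele_freq`` is the
    frequency of allele "1" per locus, frozen when the base population is
    built and reused for G-matrix centering throughout the breeding scheme.
    """

    chrom_lengths: np.ndarray          # (n_chrom,) cM
    chrom_index: np.ndarray            # (n_loci,) chromosome of each locus
    positions: np.ndarray              # (n_loci,) cM within chromosome
    panel: np.ndarray = None           # (n_loci,) int8 labels
    base_allele_freq: np.ndarray = None

    def __post_init__(self):
        self.chrom_lengths = np.asarray(self.chrom_lengths, dtype=float)
        self.chrom_index = np.asarray(self.chrom_index, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.panel is None:
            self.panel = np.zeros(self.positions.size, dtype=np.int8)
        for c in range(self.n_chromosomes):
            pos = self.positions[self.chrom_index == c]
            if pos.size and (np.any(np.diff(pos) <= 0) or pos[0] < 0
                             or pos[-1] > self.chrom_lengths[c]):
                raise ValueError(f"positions on chromosome {c} not strictly "
                                 "increasing within [0, length]")

    @property
    def n_chromosomes(self) -> int:
        return self.chrom_lengths.size

    @property
    def n_loci(self) -> int:
        return self.positions.size

    @property
    def total_length(self) -> float:
        return float(self.chrom_lengths.sum())

    @property
    def marker_idx(self) -> np.ndarray:
        return np.flatnonzero(self.panel == PANEL_MARKER)

    @property
    def qtl_idx(self) -> np.ndarray:
        return np.flatnonzero(self.panel == PANEL_QTL)

    def chrom_slices(self) -> list[slice]:
        """Contiguous locus slice per chromosome (loci are stored chromosome-major)."""
        out = []
        start = 0
        for c in range(self.n_chromosomes):
            n = int(np.sum(self.chrom_index == c))
            out.append(slice(start, start + n))
            start += n
        return out


def random_genome_map(chrom_lengths, n_loci: int, rng: np.random.Generator) -> GenomeMap:
    """Place ``n_loci`` loci uniformly at random, count per chromosome proportional to length."""
    chrom_lengths = np.asarray(chrom_lengths, dtype=float)
    if np.any(chrom_lengths < 0) or n_loci <= 0:
        raise ValueError("chromosome lengths must be >= 0 and n_loci positive")
    probs = chrom_lengths / chrom_lengths.sum()
    counts = rng.multinomial(n_loci, probs)
    chrom_index = np.repeat(np.arange(chrom_lengths.size), counts)
    positions = np.empty(n_loci)
    start = 0
    for c, k in enumerate(counts):
        pos = np.sort(rng.uniform(0.0, chrom_lengths[c], size=k))
        # de-duplicate pathological ties (measure-zero; nudge keeps strict order)
        while k > 1 and np.any(np.diff(pos) <= 0):
            pos = np.sort(rng.uniform(0.0, chrom_lengths[c], size=k))
        positions[start:start + k] = pos
        start += k
    return GenomeMap(chrom_lengths, chrom_index, positions)


@dataclass
class HaplotypePool:
    """Haplotypes of one generation: rows are gametes (two consecutive rows = one individual)."""

    haplotypes: np.ndarray             # (2*n_individuals, n_loci) uint8
    genome: GenomeMap
    mutation_rate: float = 0.0
    generation_index: int = 0

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0] // 2

    def allele_freq(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def expected_heterozygosity(self) -> np.ndarray:
        p = self.allele_freq()
        return 2.0 * p * (1.0 - p)


@dataclass
class Population:
    """A cohort of diploid individuals with pedigree links and haplotypes.

    ``sex`` is True for males.  ``sire``/``dam`` are ids (-1 unknown).
    ``haplotypes`` has shape (n, 2, n_loci).
    """

    ids: np.ndarray
    sex: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    haplotypes: np.ndarray
    birth_round: np.ndarray = None
    hatch: np.ndarray = None
    genotyped: np.ndarray = None

    def __post_init__(self):
        n = self.ids.size
        if self.birth_round is None:
            self.birth_round = np.zeros(n, dtype=np.int64)
        if self.hatch is None:
            self.hatch = np.zeros(n, dtype=np.int64)
        if self.genotyped is None:
            self.genotyped = np.zeros(n, dtype=bool)

    @property
    def n(self) -> int:
        return self.ids.size

    def allele_counts(self, loci: np.ndarray | None = None) -> np.ndarray:
        """0/1/2 allele-count matrix (individuals x loci)."""
        h = self.haplotypes if loci is None else self.haplotypes[:, :, loci]
        return h.sum(axis=1, dtype=np.int64)


# ---------------------------------------------------------------------------
# meiosis

def _gamete(hap_pair: np.ndarray, genome: GenomeMap, rng: np.random.Generator,
            mutation_rate: float, slices: list[slice]) -> np.ndarray:
    """One recombinant gamete from a (2, n_loci) haplotype pair."""
    out = np.empty(hap_pair.shape[1], dtype=np.uint8)
    for c, sl in enumerate(slices):
        length = genome.chrom_lengths[c]
        pos = genome.positions[sl]
        k = rng.poisson(length / 100.0)
        start = rng.integers(2)
        if k == 0:
            out[sl] = hap_pair[start, sl]
        else:
            xo = np.sort(rng.uniform(0.0, length, size=k))
            parity = (np.searchsorted(xo, pos) + start) % 2
            seg = hap_pair[:, sl]
            out[sl] = np.where(parity == 0, seg[0], seg[1])
    if mutation_rate > 0.0:
        n_mut = rng.binomial(out.size, mutation_rate)
        if n_mut:
            idx = rng.choice(out.size, size=n_mut, replace=False)
            out[idx] ^= 1
    return out


def meiosis(hap_pair: np.ndarray, genome: GenomeMap, rng: np.random.Generator,
            mutation_rate: float = 0.0) -> np.ndarray:
    """Form one gamete from a parent's two haplotypes (Haldane recombination).

    Crossover count per chromosome ~ Poisson(length_cM/100); crossover
    positions uniform; the starting haplotype is chosen with probability 1/2.
    Recurrent mutation flips alleles at ``mutation_rate`` per locus.
    """
    if hap_pair.ndim != 2 or hap_pair.shape[0] != 2:
        raise ValueError("hap_pair must have shape (2, n_loci)")
    return _gamete(hap_pair, genome, rng, mutation_rate, genome.chrom_slices())


# ---------------------------------------------------------------------------
# historical population

def _random_mating_generation(haps: np.ndarray, genome: GenomeMap,
                              n_males: int, n_females: int,
                              rng: np.random.Generator, mutation_rate: float,
                              slices: list[slice]) -> np.ndarray:
    """One Wright-Fisher generation: males are individuals [0, n_males)."""
    n = n_males + n_females
    new = np.empty_like(haps, shape=(2 * n, haps.shape[1]))
    sires = rng.integers(0, n_males, size=n)
    dams = rng.integers(n_males, n_males + n_females, size=n)
    for i in range(n):
        s, d = sires[i], dams[i]
        new[2 * i] = _gamete(haps[2 * s:2 * s + 2], genome, rng, mutation_rate, slices)
        new[2 * i + 1] = _gamete(haps[2 * d:2 * d + 2], genome, rng, mutation_rate, slices)
    return new


def simulate_founder_pool(genome: GenomeMap, n_individuals: int, n_generations: int,
                          mutation_rate: float, seed) -> HaplotypePool:
    """Neutral historical population at mutation-drift equilibrium.

    Generation 0 has both alleles at frequency exactly 0.5 at every locus
    (each locus column is a random permutation of equally many 0s and 1s).
    Thereafter: constant size, equal sex numbers, random mating, no
    selection, no migration.
    """
    if n_individuals <= 0:
        raise ValueError("population size must be positive")
    if n_individuals % 2:
        raise ValueError("population size must be even (equal sex split)")
    if not (0.0 <= mutation_rate < 1.0):
        raise ValueError("mutation_rate must be in [0, 1)")
    if n_generations < 0:
        raise ValueError("n_generations must be >= 0")
    rng = np.random.default_rng(seed)
    n_hap = 2 * n_individuals
    haps = np.zeros((n_hap, genome.n_loci), dtype=np.uint8)
    half = n_hap // 2
    for j in range(genome.n_loci):
        col = np.zeros(n_hap, dtype=np.uint8)
        col[:half] = 1
        haps[:, j] = rng.permutation(col)
    n_males = n_individuals // 2
    slices = genome.chrom_slices()
    for _ in range(n_generations):
        haps = _random_mating_generation(haps, genome, n_males,
                                         n_individuals - n_males, rng,
                                         mutation_rate, slices)
    return HaplotypePool(haps, genome, mutation_rate, n_generations)


def expand_founders(pool: HaplotypePool, n_males: int, n_females: int,
                    n_generations: int, offspring_per_mating: int, seed) -> HaplotypePool:
    """Founder expansion: n_males + n_females parents re-sampled each generation.

    Every generation, n_males males and n_females females are randomly
    selected from the current generation (sexes split 50:50 at birth, males
    first), formed into fresh random monogamous pairs, and each pair
    produces ``offspring_per_mating`` offspring — so each expansion
    generation holds min(n_males, n_females) * offspring_per_mating
    individuals.  With ``n_generations == 0`` the sampled founders are
    returned unchanged.
    """
    if pool.n_individuals == 0:
        raise ValueError("empty haplotype pool")
    if n_males <= 0 or n_females <= 0 or offspring_per_mating <= 0:
        raise ValueError("counts must be positive")
    if n_males + n_females > pool.n_individuals:
        raise ValueError(f"requested {n_males + n_females} founders from pool "
                         f"of {pool.n_individuals}")
    rng = np.random.default_rng(seed)
    genome = pool.genome
    slices = genome.chrom_slices()
    chosen = rng.choice(pool.n_individuals, size=n_males + n_females, replace=False)
    idx = np.repeat(2 * chosen, 2) + np.tile([0, 1], chosen.size)
    haps = pool.haplotypes[idx].copy()
    males, females = n_males, n_females
    n_pairs = min(n_males, n_females)
    for _ in range(n_generations):
        if males < n_males or females < n_females:
            raise ValueError("expansion generation too small to supply parents")
        sires = rng.choice(males, size=n_males, replace=False)[:n_pairs]
        dams = males + rng.choice(females, size=n_females, replace=False)[:n_pairs]
        n_off = n_pairs * offspring_per_mating
        new = np.empty((2 * n_off, haps.shape[1]), dtype=np.uint8)
        i = 0
        for p in range(n_pairs):
            s, d = sires[p], dams[p]
            for _ in range(offspring_per_mating):
                new[2 * i] = _gamete(haps[2 * s:2 * s + 2], genome, rng,
                                     pool.mutation_rate, slices)
                new[2 * i + 1] = _gamete(haps[2 * d:2 * d + 2], genome, rng,
                                         pool.mutation_rate, slices)
                i += 1
        haps = new
        males = n_off // 2
        females = n_off - males
    return HaplotypePool(haps, genome, pool.mutation_rate,
                         pool.generation_index + n_generations)


def select_locus_panels(pool: HaplotypePool, maf_min: float, n_markers: int,
                        n_qtl: int, seed) -> GenomeMap:
    """Assign marker and QTL panels by uniform sampling among loci with MAF >= maf_min.

    Returns a new GenomeMap sharing the pool's layout with ``panel`` filled;
    marker and QTL sets are disjoint.
    """
    if not (0.0 <= maf_min <= 0.5):
        raise ValueError("maf_min must be in [0, 0.5]")
    maf = pool.maf()
    eligible = np.flatnonzero((maf >= maf_min) & (maf > 0.0))
    need = n_markers + n_qtl
    if need > eligible.size:
        raise ValueError(f"need {need} loci but only {eligible.size} segregate "
                         f"at MAF >= {maf_min} (shortfall {need - eligible.size})")
    rng = np.random.default_rng(seed)
    pick = rng.choice(eligible, size=need, replace=False)
    g = pool.genome
    panel = np.zeros(g.n_loci, dtype=np.int8)
    panel[pick[:n_markers]] = PANEL_MARKER
    panel[pick[n_markers:]] = PANEL_QTL
    return GenomeMap(g.chrom_lengths, g.chrom_index, g.positions, panel)


def make_base_population(pool: HaplotypePool, genome: GenomeMap, n_males: int,
                         n_females: int, seed) -> tuple[Population, GenomeMap]:
    """Base population: each individual takes one haplotype from each of two distinct founders.

    Sexes meet the exact requested counts (males first).  The returned map
    carries ``base_allele_freq`` computed from these individuals and frozen
    for later G-matrix centering.
    """
    if n_males <= 0 or n_females <= 0:
        raise ValueError("counts must be positive")
    if pool.n_individuals < 2:
        raise ValueError("need at least two founders")
    rng = np.random.default_rng(seed)
    n = n_males + n_females
    haps = np.empty((n, 2, genome.n_loci), dtype=np.uint8)
    for i in range(n):
        f1, f2 = rng.choice(pool.n_individuals, size=2, replace=False)
        haps[i, 0] = pool.haplotypes[2 * f1 + rng.integers(2)]
        haps[i, 1] = pool.haplotypes[2 * f2 + rng.integers(2)]
    ids = np.arange(n, dtype=np.int64)
    sex = np.zeros(n, dtype=bool)
    sex[:n_males] = True
    pop = Population(ids=ids, sex=sex,
                     sire=np.full(n, -1, dtype=np.int64),
                     dam=np.full(n, -1, dtype=np.int64),
                     haplotypes=haps)
    freq = haps.reshape(2 * n, genome.n_loci).mean(axis=0)
    gmap = GenomeMap(genome.chrom_lengths, genome.chrom_index, genome.positions,
                     genome.panel.copy(), freq)
    return pop, gmap


# ---------------------------------------------------------------------------
# LD summary

def ld_r2_by_distance(pool: HaplotypePool, loci: np.ndarray, bins_cM,
                      max_pairs_per_bin: int = 2000, seed=0) -> np.ndarray:
    """Mean r^2 between locus pairs binned by genetic distance (same chromosome).

    A qualitative diagnostic of the equilibrium LD pattern; returns one mean
    r^2 per distance bin (NaN where a bin is empty).
    """
    rng = np.random.default_rng(seed)
    g = pool.genome
    haps = pool.haplotypes[:, loci].astype(float)
    pos = g.positions[loci]
    chrom = g.chrom_index[loci]
    bins = np.asarray(bins_cM, dtype=float)
    sums = np.zeros(bins.size - 1)
    counts = np.zeros(bins.size - 1, dtype=np.int64)
    m = loci.size
    n_draw = max_pairs_per_bin * (bins.size - 1) * 4
    ii = rng.integers(0, m, size=n_draw)
    jj = rng.integers(0, m, size=n_draw)
    for i, j in zip(ii, jj):
        if i == j or chrom[i] != chrom[j]:
            continue
        d = abs(pos[i] - pos[j])
        b = np.searchsorted(bins, d) - 1
        if b < 0 or b >= bins.size - 1 or counts[b] >= max_pairs_per_bin:
            continue
        x, y = haps[:, i], haps[:, j]
        vx, vy = x.var(), y.var()
        if vx <= 0 or vy <= 0:
            continue
        c = ((x - x.mean()) * (y - y.mean())).mean()
        sums[b] += c * c / (vx * vy)
        counts[b] += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
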