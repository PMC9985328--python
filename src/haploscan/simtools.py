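"""Simulated inputs with known ground truth.

Three generators cover the validation designs: planted-block matrices for
combinatorial unit truth, neutral coalescent samples under constant,
bottleneck, two-deme migration, or Out-of-Africa demographies, and
selective-sweep samples conditioned on the selected-allele frequency at
sampling time.  Sweeps use the structured-coalescent sweep model: the
selected-allele frequency trajectory is generated internally and the local
genealogy is simulated conditional on it, with neutral mutations overlaid
afterwards — the standard hybrid alternative to simulating every
individual forward in time.

Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import msprime
import numpy as np

from .io_formats import GeneticMap, HaplotypeMatrix

__all__ = [
    "SweepSimSpec",
    "DemographySpec",
    "planted_matrix",
    "simulate_neutral",
    "simulate_sweep",
    "downsample_snps",
]


@dataclass
class SweepSimSpec:
    """One simulated chromosome: a 10 Mb design scaled down to 1 Mb by default.

    Rates are per bp per generation; ne counts diploid individuals.  The
    selection coefficient is additive (heterozygote fitness 1 + s/2) and
    the beneficial mutation sits at the center of the region.
    """

    ne: float = 10_000.0
    region_bp: int = 1_000_000
    recomb_rate: float = 1.0e-8
    mut_rate: float = 2.5e-8
    s_true: float = 0.0
    target_freq: float = 0.5
    n_sample_diploid: int = 1_000
    maf_min: float = 0.01
    seed: int = 1

    def __post_init__(self) -> None:
        if min(self.recomb_rate, self.mut_rate) < 0:
            raise ValueError("rates must be non-negative")
        if not 0 <= self.target_freq <= 1:
            raise ValueError("target_freq must lie in [0, 1]")

    @property
    def n_sample_chrom(self) -> int:
        return 2 * self.n_sample_diploid


@dataclass
class DemographySpec:
    """Demographic scenario; parameters are in generations and diploids.

    ``bottleneck``: a population of ``n0_chrom`` chromosomes is reduced to
    ``bottleneck_frac`` of its size for ``bottleneck_generations``, then
    recovers and evolves for ``post_generations`` until sampling.
    ``migration``: an ancestral population of ``n0_chrom`` chromosomes
    splits ``post_generations`` ago into two demes of ``deme_diploid``
    diploids with symmetric migration ``migration_rate``; deme 0 is
    sampled.  ``out_of_africa``: the three-population African/European/
    Asian model with exponential growth after the European-Asian split
    (Gravel-style parameters); the European deme is sampled.
    """

    model: str = "constant"
    n0_chrom: int = 20_000
    bottleneck_frac: float = 0.05
    bottleneck_generations: int = 10
    post_generations: int = 1_120
    deme_diploid: float = 10_000.0
    migration_rate: float = 3.11e-5

    def to_msprime(self, spec: SweepSimSpec) -> tuple[msprime.Demography, str]:
        """Return (demography, name of the sampled population)."""
        if self.model == "constant":
            demog = msprime.Demography()
            demog.add_population(name="pop0", initial_size=spec.ne)
            return demog, "pop0"
        if self.model == "bottleneck":
            n0 = self.n0_chrom / 2  # diploids
            demog = msprime.Demography()
            demog.add_population(name="pop0", initial_size=n0)
            t0 = self.post_generations
            demog.add_population_parameters_change(
                time=t0, initial_size=n0 * self.bottleneck_frac, population="pop0"
            )
            demog.add_population_parameters_change(
                time=t0 + self.bottleneck_generations, initial_size=n0, population="pop0"
            )
            return demog, "pop0"
        if self.model == "migration":
            demog = msprime.Demography()
            demog.add_population(name="deme0", initial_size=self.deme_diploid)
            demog.add_population(name="deme1", initial_size=self.deme_diploid)
            demog.add_population(name="anc", initial_size=self.n0_chrom / 2)
            demog.set_symmetric_migration_rate(["deme0", "deme1"], self.migration_rate)
            demog.add_population_split(
                time=self.post_generations, derived=["deme0", "deme1"], ancestral="anc"
            )
            return demog, "deme0"
        if self.model == "out_of_africa":
            return _gravel_out_of_africa(), "EUR"
        if self.model == "out_of_africa_eur":
            return _european_lineage_history(), "EUR"
        raise ValueError(f"unknown demography model {self.model!r}")


def _gravel_out_of_africa() -> msprime.Demography:
    """Three-population Out-of-Africa demography (Gravel-style parameters).

    Ancestral size 7,310 diploids (14,620 chromosomes); African expansion
    5,920 generations ago; out-of-Africa bottleneck population of 1,861
    splitting off 2,040 generations ago; European-Asian split 920
    generations ago with exponential growth (0.38%/gen in Europeans,
    0.48%/gen in Asians) and the published migration rates.
    """
    n_a, n_af, n_b = 7_310, 14_474, 1_861
    n_eu0, r_eu = 1_032, 0.0038
    n_as0, r_as = 554, 0.0048
    t_af, t_b, t_eu_as = 5_920, 2_040, 920
    m_af_b, m_af_eu, m_af_as, m_eu_as = 15e-5, 2.5e-5, 0.78e-5, 3.11e-5
    d = msprime.Demography()
    # AFR is ancestral in the deeper split but exchanges migrants from the
    # present on, so it must start active
    d.add_population(name="AFR", initial_size=n_af, initially_active=True)
    d.add_population(
        name="EUR", initial_size=n_eu0 * np.exp(r_eu * t_eu_as), growth_rate=r_eu
    )
    d.add_population(
        name="ASN", initial_size=n_as0 * np.exp(r_as * t_eu_as), growth_rate=r_as
    )
    d.add_population(name="B", initial_size=n_b)
    d.set_symmetric_migration_rate(["AFR", "EUR"], m_af_eu)
    d.set_symmetric_migration_rate(["AFR", "ASN"], m_af_as)
    d.set_symmetric_migration_rate(["EUR", "ASN"], m_eu_as)
    d.add_population_split(time=t_eu_as, derived=["EUR", "ASN"], ancestral="B")
    d.add_symmetric_migration_rate_change(time=t_eu_as, populations=["AFR", "B"], rate=m_af_b)
    d.add_population_split(time=t_b, derived=["B"], ancestral="AFR")
    d.add_population_parameters_change(time=t_af, initial_size=n_a, population="AFR")
    d.sort_events()
    return d


def _european_lineage_history() -> msprime.Demography:
    """Single-population piecewise rendering of the European lineage.

    Collapses the Out-of-Africa model onto the ancestry of a European
    sample: geometric-mean size of the growing European deme since the
    European-Asian split, the out-of-Africa bottleneck population before
    that, then the African and ancestral sizes.  Structured sweeps cannot
    run in multi-deme models, so sweep replicates under Out-of-Africa-like
    history use this approximation (migration is ignored).
    """
    n_eu0, r_eu, t_eu_as = 1_032, 0.0038, 920
    n_eu_geo = n_eu0 * np.exp(r_eu * t_eu_as / 2.0)
    d = msprime.Demography()
    d.add_population(name="EUR", initial_size=n_eu_geo)
    d.add_population_parameters_change(time=t_eu_as, initial_size=1_861, population="EUR")
    d.add_population_parameters_change(time=2_040, initial_size=14_474, population="EUR")
    d.add_population_parameters_change(time=5_920, initial_size=7_310, population="EUR")
    return d


# ---------------------------------------------------------------------------
# Planted-block matrices
# ---------------------------------------------------------------------------

def planted_matrix(
    k: int, n: int, planted: list[tuple], seed: int
) -> tuple[HaplotypeMatrix, set]:
    """Random binary matrix with planted identical regions and exact truth.

    ``planted`` is a list of (row iterable, i, j) with 0-based inclusive
    column bounds; the rows of each plan are forced identical over the
    interval.  Plans must agree wherever they overlap.  The returned truth
    is the full maximal-block set computed by the exhaustive oracle, so it
    contains the planted blocks (possibly extended) plus chance blocks of
    the background.
    """
    from .pbwt_blocks import naive_blocks

    rng = np.random.default_rng(seed)
    H = rng.integers(0, 2, size=(k, n)).astype(np.uint8)
    for rows, i, j in planted:
        rows = sorted(rows)
        if not rows or rows[-1] >= k or i < 0 or j >= n or i > j:
            raise ValueError(f"plan out of range: {(rows, i, j)}")
        H[rows[1:], i: j + 1] = H[rows[0], i: j + 1]
    for rows, i, j in planted:
        rows = sorted(rows)
        if not np.all(H[rows, i: j + 1] == H[rows[0], i: j + 1]):
            raise ValueError("inconsistent planted blocks (conflicting overlap)")
    bp = (np.arange(n) + 1) * 1_000
    cm = np.arange(n) * 0.01
    m = HaplotypeMatrix(H, bp, positions_cm=cm, chrom="sim")
    return m, naive_blocks(m)


# ---------------------------------------------------------------------------
# Coalescent simulations
# ---------------------------------------------------------------------------

def _matrix_from_ts(ts, spec: SweepSimSpec, maf_min: float) -> HaplotypeMatrix:
    G = ts.genotype_matrix()  # sites x samples, 0/1 under the binary model
    pos = np.array([int(s.position) for s in ts.sites()], dtype=np.int64) + 1
    keep = np.ones(len(pos), dtype=bool)
    # collisions under the discrete-site binary model: keep first at a position
    keep[1:] &= np.diff(pos) > 0
    # drop non-biallelic leftovers
    keep &= (G.max(axis=1) <= 1)
    if maf_min > 0:
        af = G.mean(axis=1)
        keep &= np.minimum(af, 1.0 - af) >= maf_min
    G = G[keep]
    pos = pos[keep]
    if len(pos) == 0:
        raise ValueError("no segregating sites survive filtering; enlarge the region")
    row_ids = [f"msp{i // 2}_{i % 2}" for i in range(G.shape[1])]
    cm = pos.astype(np.float64) * spec.recomb_rate * 100.0
    return HaplotypeMatrix(G.T.astype(np.uint8), pos, row_ids, cm, chrom="sim")


def _map_from_spec(spec: SweepSimSpec, positions_bp: np.ndarray) -> GeneticMap:
    cm = positions_bp.astype(np.float64) * spec.recomb_rate * 100.0
    ids = np.array([f"v{i}" for i in range(len(positions_bp))], dtype=object)
    chrom = np.array(["sim"] * len(positions_bp), dtype=object)
    return GeneticMap(chrom, ids, cm, positions_bp)


def simulate_neutral(
    spec: SweepSimSpec, demography: DemographySpec | None = None
) -> tuple[HaplotypeMatrix, GeneticMap]:
    """Neutral coalescent sample under the given demography.

    Mutations follow a binary 0/1 model on discrete sites (collisions at a
    site are discarded, so the retained sites behave as under infinite
    sites at these rates); the constant recombination rate yields a linear
    genetic map.  The MAF filter of the analysis settings is applied here
    so fixtures match the scan's preprocessing.
    """
    demography = demography or DemographySpec("constant")
    demog, sample_pop = demography.to_msprime(spec)
    seeds = np.random.SeedSequence(spec.seed).generate_state(2) % (2**31 - 1) + 1
    ts = msprime.sim_ancestry(
        samples={sample_pop: spec.n_sample_diploid},
        demography=demog,
        sequence_length=spec.region_bp,
        recombination_rate=spec.recomb_rate,
        random_seed=int(seeds[0]),
    )
    ts = msprime.sim_mutations(
        ts, rate=spec.mut_rate, random_seed=int(seeds[1]),
        model=msprime.BinaryMutationModel(),
    )
    m = _matrix_from_ts(ts, spec, spec.maf_min)
    return m, _map_from_spec(spec, m.positions_bp)


def simulate_sweep(
    spec: SweepSimSpec, demography: DemographySpec | None = None
) -> tuple[HaplotypeMatrix, GeneticMap, dict]:
    """Sweep sample conditioned on the selected-allele frequency at sampling.

    The sweep phase runs under the structured coalescent against an
    internally simulated frequency trajectory ending at ``target_freq``;
    the pre-sweep phase is standard neutral coalescence.  A spec with
    s_true = 0 or target_freq = 0 denotes a replicate where the allele was
    lost and is simulated neutrally, labelled ``lost``.

    Returns (matrix, map, truth) where truth records s_true, target_freq,
    the focal position, and the realized carrier frequency at the focal
    tree (the largest clade consistent with the sweep).
    """
    demography = demography or DemographySpec("constant")
    if spec.s_true <= 0 or spec.target_freq <= 0:
        m, gmap = simulate_neutral(replace(spec, s_true=0.0), demography)
        return m, gmap, {"s_true": 0.0, "target_freq": 0.0, "lost": True,
                         "focal_bp": spec.region_bp // 2, "sample_freq": 0.0}
    demog, sample_pop = demography.to_msprime(spec)
    if demog.num_populations > 1:
        raise ValueError("sweep simulation supports single-population demographies only")
    focal = spec.region_bp / 2
    # near-fixation targets: stay one chromosome short of 1 in the trajectory
    end_freq = min(spec.target_freq, 1.0 - 1.0 / (2.0 * spec.ne))
    sweep = msprime.SweepGenicSelection(
        position=focal,
        start_frequency=1.0 / (2.0 * spec.ne),
        end_frequency=end_freq,
        s=spec.s_true,
        dt=1e-6,
    )
    seeds = np.random.SeedSequence(spec.seed).generate_state(2) % (2**31 - 1) + 1
    ts = msprime.sim_ancestry(
        samples={sample_pop: spec.n_sample_diploid},
        demography=demog,
        sequence_length=spec.region_bp,
        recombination_rate=spec.recomb_rate,
        model=[sweep, msprime.StandardCoalescent()],
        random_seed=int(seeds[0]),
    )
    ts = msprime.sim_mutations(
        ts, rate=spec.mut_rate, random_seed=int(seeds[1]),
        model=msprime.BinaryMutationModel(),
    )
    m = _matrix_from_ts(ts, spec, spec.maf_min)
    tree = ts.at(focal)
    target_count = end_freq * ts.num_samples
    best = min(
        (abs(tree.num_samples(u) - target_count), tree.num_samples(u))
        for u in tree.nodes()
    )
    truth = {
        "s_true": spec.s_true,
        "target_freq": spec.target_freq,
        "lost": False,
        "focal_bp": int(focal),
        "sample_freq": best[1] / ts.num_samples,
    }
    return m, _map_from_spec(spec, m.positions_bp), truth


def downsample_snps(
    m: HaplotypeMatrix,
    target_n: int,
    afs_weights: np.ndarray | None = None,
    seed: int = 0,
) -> HaplotypeMatrix:
    """Random subset of ``target_n`` SNP columns, order preserved.

    Without weights the subset is uniform.  With ``afs_weights`` — a
    histogram over equal minor-allele-frequency bins on (0, 0.5] — sites
    are drawn per bin to match the target spectrum; unfillable bins are
    redistributed to the remaining ones (best effort, logged).
    """
    import logging

    if target_n > m.n:
        raise ValueError(f"target_n={target_n} exceeds available {m.n} sites")
    if target_n == m.n:
        return m
    rng = np.random.default_rng(seed)
    if afs_weights is None:
        idx = np.sort(rng.choice(m.n, size=target_n, replace=False))
        return m.select_columns(idx)

    w = np.asarray(afs_weights, dtype=np.float64)
    w = w / w.sum()
    nbins = len(w)
    af = m.alleles.mean(axis=0)
    maf = np.minimum(af, 1.0 - af)
    bins = np.minimum((maf * 2 * nbins).astype(int), nbins - 1)
    want = np.round(w * target_n).astype(int)
    # fix rounding drift
    while want.sum() > target_n:
        want[np.argmax(want)] -= 1
    while want.sum() < target_n:
        want[np.argmax(w)] += 1
    chosen: list[np.ndarray] = []
    deficit = 0
    avail = [np.flatnonzero(bins == b) for b in range(nbins)]
    for b in range(nbins):
        take = min(want[b], len(avail[b]))
        deficit += want[b] - take
        if take:
            chosen.append(rng.choice(avail[b], size=take, replace=False))
    if deficit:
        logging.getLogger(__name__).warning(
            "AFS-matched downsampling short by %d sites; filling uniformly", deficit
        )
        used = np.concatenate(chosen) if chosen else np.array([], dtype=int)
        rest = np.setdiff1d(np.arange(m.n), used)
        chosen.append(rng.choice(rest, size=deficit, replace=False))
    idx = np.sort(np.concatenate(chosen))
    return m.select_columns(idx)
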