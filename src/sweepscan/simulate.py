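"""Forward Wright-Fisher simulation of phased multi-population SNP panels.

The generator emulates what the scan pipeline consumes: chip-like marker
panels (a few hundred to a few thousand biallelic sites on one chromosome),
neutral drift with recombination and recurrent mutation, optional additive
selection (viability weights 1, 1+s, 1+2s) at a focal site, population splits
with symmetric migration, and three pseudo-outgroup allele calls for
ancestral-state inference. Because the simulator knows the true ancestral
allele and the true sweep location, every downstream statistic can be tested
against ground truth.

Initial variation comes from a mutation-drift burn-in of 10 Ne generations in
a single ancestral population; the per-site mutation probability defaults to
a value giving chip-like common variation (theta = 4 Ne mu per site of order
0.1-0.5) rather than a sequence-scale rate, since the markers stand in for
ascertained chip SNPs. After the burn-in, mutation is off by default: on the
tens-of-generations timescale of the divergence/selection phase new mutations
contribute nothing to common chip variation, whereas a per-site rate high
enough to matter would spuriously erode long-range haplotype identity — the
very signal the scans measure.

A separate single-locus path (no linkage) serves the classical diffusion
checks: fixation probabilities against Kimura's formula and per-generation
heterozygosity decay.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import AlleleCountMatrix, HaplotypeMatrix, PopulationMap

#: default group labels assigned to populations in creation order: the focal
#: population first, then the reference groups it is contrasted against
_GROUP_ORDER = ("NorthAFT", "AFT", "EUT", "IND")


@dataclass
class SimulationConfig:
    n_e: int = 100  # diploid population size (per population)
    n_generations: int = 28  # length of the post-burn-in phase
    chrom_length_bp: int = 4_000_000
    n_markers: int = 1300
    mu: float = 1e-3  # per marker site per gamete per generation (burn-in)
    r_per_bp: float = 1e-6  # recombination probability per bp per meiosis
    s: float = 0.0  # selection coefficient of the focal derived allele
    selected_pos_bp: Optional[int] = None
    sweep_pops: Optional[tuple] = None  # pops under selection; None = all
    split_spec: tuple = ()  # (generation, parent, child[, migration m])
    sample_sizes: dict = field(default_factory=lambda: {"pop0": 50})
    group_of: Optional[dict] = None  # population -> ancestry-group label
    burn_in_factor: int = 10  # burn-in length in units of Ne generations
    mutation_during_phase: bool = False  # mutation after burn-in (see below)
    hard_sweep: bool = True  # start the sweep from a single new copy
    marker_grid: bool = False  # evenly spaced markers instead of uniform draw
    min_final_freq: float = 0.8  # sweep establishment conditioning level
    max_restarts: int = 50
    seed: int = 0

    def validate(self) -> None:
        if self.s < 0:
            raise ValueError("selection coefficient must be >= 0")
        if self.s > 0 and self.selected_pos_bp is None:
            raise ValueError("selection requires selected_pos_bp")
        if self.n_markers < 1:
            raise ValueError("n_markers must be positive")
        for entry in self.split_spec:
            if len(entry) == 4 and not (0 <= entry[3] <= 0.5):
                raise ValueError("migration rate must lie in [0, 0.5]")
        for pop, n in self.sample_sizes.items():
            if n > self.n_e:
                raise ValueError(f"sample size for {pop} exceeds Ne diploids")


@dataclass
class SweepTruth:
    selected_pos_bp: Optional[int]
    selected_marker_id: Optional[str]
    s: float
    final_freq: dict  # population -> derived frequency at the selected site
    fixation_generation: Optional[int]
    sweep_interval_bp: Optional[tuple]  # (start, end), 0-based half-open
    n_attempts: int = 1


@dataclass
class SimulatedDataset:
    haplotypes: HaplotypeMatrix  # polarized: 0 = true ancestral allele
    truth: SweepTruth
    outgroup_alleles: Optional[pd.DataFrame] = None
    population_map: Optional[PopulationMap] = None

    def unpolarized(self, seed: int = 0) -> HaplotypeMatrix:
        """Random ref/alt recoding, for exercising the polarization stage."""
        rng = np.random.default_rng(seed)
        flip = rng.integers(0, 2, self.haplotypes.n_markers).astype(bool)
        haps = self.haplotypes.haplotypes.copy()
        haps[:, flip] = 1 - haps[:, flip]
        markers = self.haplotypes.markers.copy()
        ref = markers["allele_ref"].to_numpy().copy()
        alt = markers["allele_alt"].to_numpy().copy()
        markers["allele_ref"] = np.where(flip, alt, ref)
        markers["allele_alt"] = np.where(flip, ref, alt)
        markers["ancestral_state"] = "unresolved"
        return HaplotypeMatrix(markers, haps, list(self.haplotypes.sample_ids),
                               list(self.haplotypes.pop_labels))


# ---------------------------------------------------------------------------
# generation update
# ---------------------------------------------------------------------------

def _recombine(hap_a: np.ndarray, hap_b: np.ndarray, positions: np.ndarray,
               length_bp: int, r_per_bp: float, rng: np.random.Generator
               ) -> np.ndarray:
    """One recombinant gamete per row of (hap_a, hap_b) parent pairs.

    Crossover counts are Poisson(r L) per meiosis with breakpoints uniform on
    the chromosome; each marker takes the allele of whichever parental strand
    the running crossover parity selects, starting from a random strand.
    """
    n_gam, n_mark = hap_a.shape
    k = rng.poisson(r_per_bp * length_bp, n_gam)
    start = rng.integers(0, 2, n_gam).astype(np.int64)
    seg = np.repeat(start[:, None], n_mark, axis=1)
    for kk in np.unique(k[k > 0]):
        rows = np.flatnonzero(k == kk)
        xo = rng.uniform(0, length_bp, (len(rows), kk))
        # crossovers at or before each marker flip the strand parity
        seg[rows] += (xo[:, :, None] <= positions[None, None, :]).sum(axis=1)
    return np.where(seg % 2 == 0, hap_a, hap_b)


def _next_generation(pops: dict[str, np.ndarray], positions: np.ndarray,
                     cfg: SimulationConfig, sel_index: Optional[int],
                     selection_on: bool, migration: dict, rng,
                     mu: Optional[float] = None) -> dict:
    """Advance every population by one non-overlapping generation."""
    mu = cfg.mu if mu is None else mu
    names = list(pops)
    out = {}
    for name in names:
        pop = pops[name]
        n = pop.shape[0] // 2
        # migrant source per offspring (island pairs set up by splits)
        sources = np.full(n, names.index(name))
        for partner, m in migration.get(name, ()):  # (partner_name, rate)
            if partner in pops and m > 0:
                mig = rng.random(n) < m
                sources[mig] = names.index(partner)
        parent_idx = np.empty((n, 2), dtype=np.int64)
        for src_i in np.unique(sources):
            src_pop = pops[names[src_i]]
            rows = np.flatnonzero(sources == src_i)
            n_src = src_pop.shape[0] // 2
            if selection_on and sel_index is not None \
                    and (cfg.sweep_pops is None or names[src_i] in cfg.sweep_pops):
                g = (src_pop[0::2, sel_index].astype(np.int64)
                     + src_pop[1::2, sel_index])
                w = 1.0 + cfg.s * g
                probs = w / w.sum()
                parent_idx[rows] = rng.choice(n_src, size=(len(rows), 2), p=probs)
            else:
                parent_idx[rows] = rng.integers(0, n_src, size=(len(rows), 2))
        gam_parent = parent_idx.ravel()
        gam_source = np.repeat(sources, 2)
        hap_a = np.empty((2 * n, len(positions)), dtype=np.uint8)
        hap_b = np.empty_like(hap_a)
        for src_i in np.unique(gam_source):
            src_pop = pops[names[src_i]]
            rows = np.flatnonzero(gam_source == src_i)
            hap_a[rows] = src_pop[2 * gam_parent[rows]]
            hap_b[rows] = src_pop[2 * gam_parent[rows] + 1]
        new = _recombine(hap_a, hap_b, positions, cfg.chrom_length_bp,
                         cfg.r_per_bp, rng)
        # recurrent mutation: flip allele state at random (hap, site) cells
        n_mut = rng.poisson(2 * n * len(positions) * mu) if mu > 0 else 0
        if n_mut:
            hrows = rng.integers(0, 2 * n, n_mut)
            hcols = rng.integers(0, len(positions), n_mut)
            new[hrows, hcols] ^= 1
        out[name] = new
    return out


def _sweep_interval(pop: np.ndarray, positions: np.ndarray, sel_index: int,
                    min_freq: float) -> Optional[tuple]:
    """Maximal interval around the selected site where the modal extended
    haplotype of the derived carriers exceeds ``min_freq`` of the population."""
    total = pop.shape[0]
    carriers = np.flatnonzero(pop[:, sel_index] == 1)
    if len(carriers) / total <= min_freq:
        return None
    haps = pop[carriers]
    bounds = [int(positions[sel_index]), int(positions[sel_index]) + 1]
    for direction, stop in ((-1, -1), (+1, len(positions))):
        codes = np.zeros(len(carriers), dtype=np.int64)
        j = sel_index
        while True:
            nxt = j + direction
            if nxt == stop:
                break
            codes = np.unique(codes * 2 + haps[:, nxt], return_inverse=True)[1]
            modal = np.bincount(codes).max()
            if modal / total <= min_freq:
                break
            j = nxt
        if direction < 0:
            bounds[0] = int(positions[j]) - 1
        else:
            bounds[1] = int(positions[j])
    return tuple(bounds)


def simulate_wright_fisher(config: SimulationConfig) -> SimulatedDataset:
    """Run burn-in plus the configured divergence/selection phase and sample.

    Fully reproducible from config.seed. When s > 0 the run is restarted
    (with fresh random substreams) until the derived allele at the selected
    site reaches min_final_freq in every swept population, so that sweep
    replicates carry a recoverable signal; the number of attempts is recorded
    in the truth record.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    burn_seed, *phase_seeds = root.spawn(1 + max(config.max_restarts, 1))
    rng = np.random.default_rng(burn_seed)

    if config.marker_grid:
        positions = np.linspace(1, config.chrom_length_bp, config.n_markers,
                                dtype=np.int64)
    else:
        positions = np.sort(rng.choice(np.arange(1, config.chrom_length_bp + 1),
                                       size=config.n_markers, replace=False))
    sel_index = (int(np.argmin(np.abs(positions - config.selected_pos_bp)))
                 if config.selected_pos_bp is not None else None)

    # mutation-drift burn-in in the single ancestral population
    pops = {"pop0": np.zeros((2 * config.n_e, config.n_markers), dtype=np.uint8)}
    for _ in range(config.burn_in_factor * config.n_e):
        pops = _next_generation(pops, positions, config, None, False, {}, rng)
    burnt = {k: v.copy() for k, v in pops.items()}

    migration: dict[str, list] = {}
    splits = sorted(config.split_spec, key=lambda e: e[0])

    def run_phase(phase_rng):
        pops = {k: v.copy() for k, v in burnt.items()}
        mig = {}
        fixation_gen = None
        if sel_index is not None and config.s > 0:
            col = pops["pop0"][:, sel_index]
            if config.hard_sweep:
                # single new beneficial copy on one haplotype background
                col[:] = 0
                col[phase_rng.integers(0, len(col))] = 1
            elif col.sum() == 0:
                col[phase_rng.integers(0, len(col))] = 1
        for gen in range(config.n_generations):
            for entry in splits:
                if entry[0] == gen:
                    g0, parent, child = entry[:3]
                    pops[child] = pops[parent].copy()
                    if len(entry) == 4 and entry[3] > 0:
                        mig.setdefault(parent, []).append((child, entry[3]))
                        mig.setdefault(child, []).append((parent, entry[3]))
            pops = _next_generation(
                pops, positions, config, sel_index, config.s > 0, mig,
                phase_rng,
                mu=config.mu if config.mutation_during_phase else 0.0)
            if sel_index is not None and config.s > 0 and fixation_gen is None:
                swept = config.sweep_pops or list(pops)
                if all(pops[p][:, sel_index].all() for p in swept if p in pops):
                    fixation_gen = gen
        return pops, mig, fixation_gen

    attempts = 0
    while True:
        attempts += 1
        phase_rng = np.random.default_rng(phase_seeds[attempts - 1])
        pops, migration, fixation_gen = run_phase(phase_rng)
        if sel_index is None or config.s == 0:
            break
        swept = [p for p in (config.sweep_pops or list(pops)) if p in pops]
        freqs = [pops[p][:, sel_index].mean() for p in swept]
        if min(freqs) >= config.min_final_freq:
            break
        if attempts >= config.max_restarts:
            raise RuntimeError(
                f"sweep failed to establish in {attempts} attempts "
                f"(best final frequency {max(freqs):.2f}); increase s or Ne")

    # sample diploids per population, in stable population order
    sample_rng = phase_rng
    blocks, sample_ids, pop_labels = [], [], []
    for pop in config.sample_sizes:
        if pop not in pops:
            raise ValueError(f"sampled population {pop!r} never created")
        chosen = sample_rng.choice(config.n_e, config.sample_sizes[pop],
                                   replace=False)
        rows = np.sort(np.stack([2 * chosen, 2 * chosen + 1], axis=1).ravel())
        blocks.append(pops[pop][rows])
        sample_ids += [f"{pop}_s{i}" for i in range(config.sample_sizes[pop])]
        pop_labels += [pop] * config.sample_sizes[pop]

    markers = pd.DataFrame({
        "marker_id": [f"m{i}" for i in range(config.n_markers)],
        "chrom": "1", "pos_bp": positions,
        "allele_ref": "A", "allele_alt": "G",
        "ancestral_state": "ref"})  # 0 = ancestral by construction
    matrix = HaplotypeMatrix(markers, np.concatenate(blocks, axis=0),
                             sample_ids, pop_labels)
    matrix.validate()

    swept = [p for p in (config.sweep_pops or list(pops)) if p in pops]
    interval = None
    if sel_index is not None and config.s > 0 and swept:
        interval = _sweep_interval(pops[swept[0]], positions, sel_index,
                                   config.min_final_freq)
    truth = SweepTruth(
        selected_pos_bp=(int(positions[sel_index]) if sel_index is not None else None),
        selected_marker_id=(f"m{sel_index}" if sel_index is not None else None),
        s=config.s,
        final_freq={p: float(pops[p][:, sel_index].mean()) for p in pops}
        if sel_index is not None else {},
        fixation_generation=fixation_gen if config.s > 0 else None,
        sweep_interval_bp=interval, n_attempts=attempts)

    groups = config.group_of or {p: _GROUP_ORDER[i % len(_GROUP_ORDER)]
                                 for i, p in enumerate(pops)}
    pm = PopulationMap(pd.DataFrame({
        "sample_id": sample_ids,
        "population": pop_labels,
        "group": [groups[p] for p in pop_labels],
        "relatedness_class": ["north_african" if groups[p] == "NorthAFT"
                              else "commercial" for p in pop_labels]}))
    return SimulatedDataset(matrix, truth, population_map=pm)


def two_population_study_config(seed: int, sweep: bool = True,
                                s: float = 1.0) -> SimulationConfig:
    """The standard two-population study condition used by the validation
    suites: a focal population and a reference that split at the start of the
    phase with weak symmetric migration (m = 0.01), 1,300 markers on a 4-Mb
    chromosome, 50 diploids sampled per population. With sweep=True a hard
    sweep (default s = 1, so Ne s = 100) runs in the focal population only
    and sampling occurs shortly after fixation — the regime Rsb and XP-EHH
    target. With sweep=False the same demography runs neutrally.
    """
    return SimulationConfig(
        s=s if sweep else 0.0,
        selected_pos_bp=2_000_000 if sweep else None,
        sweep_pops=("pop0",),
        split_spec=((0, "pop0", "pop1", 0.01),),
        sample_sizes={"pop0": 50, "pop1": 50},
        group_of={"pop0": "NorthAFT", "pop1": "EUT"},
        seed=seed)


# ---------------------------------------------------------------------------
# outgroups
# ---------------------------------------------------------------------------

def simulate_outgroups(dataset: SimulatedDataset, concordance: float,
                       missing_rate: float = 0.0, n_outgroups: int = 3,
                       seed: int = 0) -> pd.DataFrame:
    """Per-marker allele calls for pseudo-outgroup species.

    Each call is missing with probability missing_rate, otherwise equals the
    true ancestral allele with probability ``concordance`` and the derived
    allele with probability 1 - concordance, independently per outgroup.
    Concordance must exceed 0.5 or majority-rule polarization carries no
    information.
    """
    if not 0.5 < concordance <= 1.0:
        raise ValueError("concordance must lie in (0.5, 1]")
    rng = np.random.default_rng(seed)
    markers = dataset.haplotypes.markers
    anc = np.where(markers["ancestral_state"] == "alt",
                   markers["allele_alt"], markers["allele_ref"]).astype(object)
    der = np.where(markers["ancestral_state"] == "alt",
                   markers["allele_ref"], markers["allele_alt"]).astype(object)
    out = {"marker_id": markers["marker_id"].to_numpy()}
    for k in range(n_outgroups):
        calls = np.where(rng.random(len(markers)) < concordance, anc, der)
        calls = np.where(rng.random(len(markers)) < missing_rate, ".", calls)
        out[f"outgroup{k + 1}"] = calls
    df = pd.DataFrame(out)
    dataset.outgroup_alleles = df
    return df


# ---------------------------------------------------------------------------
# single-locus diffusion checks
# ---------------------------------------------------------------------------

def single_locus_trajectories(n_e: int, s: float, p0: float,
                              n_generations: int, n_replicates: int,
                              seed: int = 0) -> np.ndarray:
    """Allele-frequency trajectories of independent Wright-Fisher loci.

    Additive viability selection: after selection the expected frequency is
    p* = p (1 + s (1 + p)) / (1 + 2 s p), then binomial sampling of 2 Ne
    gametes. Returns an (n_replicates, n_generations + 1) array.
    """
    rng = np.random.default_rng(seed)
    traj = np.empty((n_replicates, n_generations + 1))
    p = np.full(n_replicates, p0)
    traj[:, 0] = p
    for g in range(1, n_generations + 1):
        p_star = p * (1 + s * (1 + p)) / (1 + 2 * s * p) if s else p
        p = rng.binomial(2 * n_e, p_star) / (2 * n_e)
        traj[:, g] = p
    return traj


def fixation_proportion(n_e: int, s: float, initial_count: int = 1,
                        n_replicates: int = 5000, seed: int = 0,
                        max_generations: Optional[int] = None) -> float:
    """Monte-Carlo fixation proportion of a derived allele starting at
    ``initial_count`` copies, run to absorption."""
    rng = np.random.default_rng(seed)
    max_generations = max_generations or 200 * n_e
    p = np.full(n_replicates, initial_count / (2 * n_e))
    active = (p > 0) & (p < 1)
    for _ in range(max_generations):
        if not active.any():
            break
        pa = p[active]
        p_star = pa * (1 + s * (1 + pa)) / (1 + 2 * s * pa) if s else pa
        p[active] = rng.binomial(2 * n_e, p_star) / (2 * n_e)
        active = (p > 0) & (p < 1)
    return float((p >= 1).mean())


def kimura_fixation_probability(n_e: int, s: float, initial_count: int = 1) -> float:
    """Diffusion approximation for additive selection: with initial frequency
    p0, P_fix = (1 - exp(-4 Ne s p0)) / (1 - exp(-4 Ne s))."""
    p0 = initial_count / (2 * n_e)
    if s == 0:
        return p0
    return float(np.expm1(-4 * n_e * s * p0) / np.expm1(-4 * n_e * s))


# ---------------------------------------------------------------------------
# Dirichlet-multinomial allele counts for the FST outlier arm
# ---------------------------------------------------------------------------

@dataclass
class CountSimConfig:
    n_loci: int = 500
    n_pops: int = 3
    alpha: np.ndarray | float = 0.0  # locus effects (0 = neutral)
    #: population effects; the default gives background FST ~ 0.12, the scale
    #: of differentiation between cattle breed groups
    beta: np.ndarray | float = -2.0
    sample_chromosomes: np.ndarray | int = 100
    p_min: float = 0.05  # ancestral-frequency draw bounds
    p_max: float = 0.95
    #: optional locus -> ancestral frequency pins. A planted selected locus
    #: with an extreme random p is unidentifiable (every population drifts to
    #: the same boundary), so recovery studies pin the planted locus mid-range.
    p_fixed: Optional[dict] = None
    seed: int = 0


def simulate_allele_counts(config: CountSimConfig) -> AlleleCountMatrix:
    """Counts under the logit-linear FST model the outlier test assumes.

    For locus i and population j, FST(i,j) = logistic(alpha_i + beta_j); the
    population frequency is Beta-distributed around an ancestral frequency
    p_i ~ Uniform(p_min, p_max) with theta_ij = (1 - FST)/FST, and the
    derived count is Binomial(sample_chromosomes_j, frequency).
    """
    rng = np.random.default_rng(config.seed)
    alpha = np.broadcast_to(np.asarray(config.alpha, dtype=float),
                            (config.n_loci,)).copy()
    beta = np.broadcast_to(np.asarray(config.beta, dtype=float),
                           (config.n_pops,)).copy()
    n_chrom = np.broadcast_to(np.asarray(config.sample_chromosomes),
                              (config.n_pops,)).astype(int)
    if (n_chrom <= 0).any():
        raise ValueError("sample_chromosomes must be positive")
    logit = alpha[:, None] + beta[None, :]
    fst = 1.0 / (1.0 + np.exp(-logit))
    if ((fst <= 0) | (fst >= 1)).any():
        raise ValueError("alpha + beta give FST outside (0, 1)")
    p = rng.uniform(config.p_min, config.p_max, config.n_loci)
    for locus, value in (config.p_fixed or {}).items():
        p[locus] = value
    theta = (1.0 - fst) / fst
    freq = rng.beta(theta * p[:, None], theta * (1 - p)[:, None])
    freq = np.clip(freq, 1e-12, 1 - 1e-12)
    derived = rng.binomial(n_chrom[None, :], freq)
    return AlleleCountMatrix(derived,
                             np.broadcast_to(n_chrom, derived.shape).copy(),
                             [f"locus{i}" for i in range(config.n_loci)],
                             [f"pop{j}" for j in range(config.n_pops)])


def planted_outlier_counts(seed: int, n_loci: int = 500, n_pops: int = 3,
                           alpha_effect: float = 2.5, beta: float = -2.0,
                           sample_chromosomes: int = 100,
                           planted_index: int = None,
                           min_pooled_maf: float = 0.05,
                           max_redraws: int = 20):
    """One selected locus among null loci, for outlier-recovery studies.

    The planted locus's ancestral frequency is pinned at 0.5 (an extreme
    random draw leaves no locus-specific information to detect) and the
    dataset is redrawn until the planted locus passes the pooled
    minor-allele-frequency filter every chip pipeline applies before an FST
    outlier test — a near-monomorphic locus would never reach the test.
    Returns (AlleleCountMatrix, planted_index).
    """
    planted_index = n_loci // 2 if planted_index is None else planted_index
    alpha = np.zeros(n_loci)
    alpha[planted_index] = alpha_effect
    for attempt in range(max_redraws):
        cfg = CountSimConfig(n_loci=n_loci, n_pops=n_pops, alpha=alpha,
                             beta=beta, sample_chromosomes=sample_chromosomes,
                             p_fixed={planted_index: 0.5},
                             seed=seed * max_redraws + attempt)
        counts = simulate_allele_counts(cfg)
        pooled = counts.derived[planted_index].sum() / counts.total[planted_index].sum()
        if min_pooled_maf <= pooled <= 1 - min_pooled_maf:
            return counts, planted_index
    raise RuntimeError(f"no draw passed the MAF filter in {max_redraws} tries")


# ---------------------------------------------------------------------------
# on-disk emission (simulator convenience used by the CLI)
# ---------------------------------------------------------------------------

def write_dataset(dataset: SimulatedDataset, outdir: str | Path,
                  fmt: str = "vcf") -> dict:
    """Write haplotypes (+ popmap, outgroups, truth sidecars) to a directory."""
    from . import io_formats
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    if fmt == "vcf":
        paths["vcf"] = str(outdir / "haplotypes.vcf")
        io_formats.write_phased_vcf(dataset.haplotypes, paths["vcf"])
    elif fmt == "haps":
        paths["haps"] = str(outdir / "haplotypes.haps")
        paths["sample"] = str(outdir / "haplotypes.sample")
        io_formats.write_haps(dataset.haplotypes, paths["haps"], paths["sample"])
    else:
        raise ValueError(f"unknown output format {fmt!r}")
    if dataset.population_map is not None:
        paths["popmap"] = str(outdir / "popmap.tsv")
        dataset.population_map.table.to_csv(paths["popmap"], sep="\t", index=False)
    if dataset.outgroup_alleles is not None:
        paths["outgroups"] = str(outdir / "outgroups.tsv")
        io_formats.write_outgroup_alleles(dataset.outgroup_alleles, paths["outgroups"])
    truth = dataset.truth
    paths["truth"] = str(outdir / "truth.json")
    with open(paths["truth"], "w") as fh:
        json.dump({"selected_pos_bp": truth.selected_pos_bp,
                   "selected_marker_id": truth.selected_marker_id,
                   "s": truth.s, "final_freq": truth.final_freq,
                   "fixation_generation": truth.fixation_generation,
                   "sweep_interval_bp": truth.sweep_interval_bp,
                   "n_attempts": truth.n_attempts}, fh, indent=1)
    if truth.sweep_interval_bp is not None:
        paths["truth_bed"] = str(outdir / "truth.bed")
        with open(paths["truth_bed"], "w") as fh:
            fh.write(f"1\t{truth.sweep_interval_bp[0]}\t"
                     f"{truth.sweep_interval_bp[1]}\tsweep\n")
    return paths
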