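"""Haploid coalescent simulation of zebu Y-chromosome demographic models.

Three competing domestication scenarios are expressed as event schedules
on haploid (Y-chromosome) populations and simulated with the msprime
coalescent sampler (``ploidy=1``, so a population of haploid size N has
pairwise coalescence time N generations):

* **Model 1** — one domestication bottleneck at ~9,000 B.P.; the single
  domestic population splits into three at 3,500 B.P. (first zebu
  arrival in Africa); two descendants merge at 2,000 B.P.
* **Model 2** — three ancestral populations separated for 250,000 years,
  each independently domesticated (own founder bottleneck) at 9,000
  B.P.; two descendants merge at 2,000 B.P.
* **Model 3** — one domesticated lineage (bottleneck at 9,000 B.P.)
  splitting at 3,500 B.P.; at 3,000 B.P. the domestic lineage receives
  an introgression pulse of proportion 0.79 from a long-separated wild
  population; the two domestic subpopulations merge at 2,000 B.P.

In every model the present-day sample of 180 Y chromosomes is pooled
across the surviving populations (the "admixture at time 0" device that
mirrors analysing a single combined sample). Times in years B.P. are
converted to generations at 4.84 years/generation.

Mutations are dropped on the (single, fully linked — the Y does not
recombine) genealogy: the six microsatellites mutate at 0.008/generation
under a strict stepwise model (±1 repeat, equal probability) and the two
IMM profiles evolve as slow infinite-alleles markers at a rate drawn
from the prior, every mutation creating a novel band profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np

GEN_TIME = 4.84  # years per generation
MSAT_RATE = 0.008  # mutations/generation, strict SMM
N_SAMPLES = 180

# event times, years B.P.
T_DOMESTICATION = 9_000
T_AFRICA_SPLIT = 3_500
T_INTROGRESSION = 3_000
T_MERGE = 2_000
T_ANCIENT = 250_000
ADMIX_PROPORTION = 0.79

# the founder phase: the domestic deme keeps its founder size for this
# many generations behind the domestication event before reverting to a
# wild ancestral size (instantaneous SIMCOAL-style shifts at both ends)
BOTTLENECK_GENERATIONS = 20

MSAT_LOCI = ("INRA189", "UMN0103a", "UMN0103b", "UMN0307", "BM861", "BYM1")
IMM_LOCI = ("UMN2405", "UMN2303")
ALL_LOCI = MSAT_LOCI + IMM_LOCI


def years_to_generations(years: float) -> int:
    return int(round(years / GEN_TIME))


@dataclass
class PriorSpec:
    """Uniform priors of the ABC analysis.

    Current/wild effective sizes ~ U(1e3, 1e5) haploid individuals,
    founder (initial domestic herd) sizes ~ U(1, 200), IMM mutation rate
    ~ U(2e-5, 2e-4) per generation; the microsatellite rate is fixed.
    """

    ne_range: tuple[float, float] = (1e3, 1e5)
    founder_range: tuple[int, int] = (1, 200)
    imm_rate_range: tuple[float, float] = (2e-5, 2e-4)
    msat_rate: float = MSAT_RATE

    def draw(self, rng: np.random.Generator, model: int) -> dict:
        """One parameter draw for the given model id.

        Every deme gets its own Ne draw; each domesticated lineage gets
        its own founder size; each IMM locus its own mutation rate.
        """
        n_demes = {1: 6, 2: 6, 3: 7}[model]
        n_founders = {1: 1, 2: 3, 3: 1}[model]
        return {
            "model": model,
            "ne": rng.uniform(*self.ne_range, size=n_demes),
            "founder": rng.integers(
                self.founder_range[0], self.founder_range[1] + 1, size=n_founders
            ),
            "imm_rate": rng.uniform(*self.imm_rate_range, size=len(IMM_LOCI)),
            "msat_rate": self.msat_rate,
        }


@dataclass
class DemographicModel:
    """One scenario: an msprime demography plus its sampling spec."""

    model_id: int
    demography: msprime.Demography
    sampled_populations: tuple[str, ...]
    draw: dict = field(default_factory=dict)

    def sample_sizes(self, rng: np.random.Generator, n: int = N_SAMPLES) -> dict:
        """Pool ``n`` lineages across the present-day populations with
        equal probabilities (the time-0 admixture of the pooled sample)."""
        k = len(self.sampled_populations)
        counts = rng.multinomial(n, [1.0 / k] * k)
        return dict(zip(self.sampled_populations, counts.tolist()))


def _bottleneck(dem, pop: str, t_gen: int, founder: float, wild_ne: float) -> None:
    dem.add_population_parameters_change(
        time=t_gen, population=pop, initial_size=max(founder, 1)
    )
    dem.add_population_parameters_change(
        time=t_gen + BOTTLENECK_GENERATIONS, population=pop, initial_size=wild_ne
    )


def build_model(which: int, draw: dict) -> DemographicModel:
    """Construct the demographic model for scenario 1, 2 or 3.

    ``draw`` comes from :meth:`PriorSpec.draw` (its ``ne`` vector is
    consumed in a fixed deme order, so draws are reproducible).
    """
    if which not in (1, 2, 3):
        raise ValueError(f"unknown model id {which!r}")
    if draw["model"] != which:
        raise ValueError("parameter draw was made for a different model")
    ne = list(map(float, draw["ne"]))
    founders = list(map(float, draw["founder"]))
    t_merge = years_to_generations(T_MERGE)
    t_split = years_to_generations(T_AFRICA_SPLIT)
    t_intro = years_to_generations(T_INTROGRESSION)
    t_dom = years_to_generations(T_DOMESTICATION)
    t_deep = years_to_generations(T_ANCIENT)

    dem = msprime.Demography()
    if which == 1:
        # demes: M, D3, D1, D2, DOM, ANC
        dem.add_population(name="M", initial_size=ne[0])
        dem.add_population(name="D3", initial_size=ne[1])
        dem.add_population(name="D1", initial_size=ne[2])
        dem.add_population(name="D2", initial_size=ne[3])
        dem.add_population(name="DOM", initial_size=ne[4])
        dem.add_population(name="ANC", initial_size=ne[5])
        dem.add_admixture(
            time=t_merge, derived="M", ancestral=["D1", "D2"], proportions=[0.5, 0.5]
        )
        dem.add_population_split(
            time=t_split, derived=["D1", "D2", "D3"], ancestral="DOM"
        )
        _bottleneck(dem, "DOM", t_dom, founders[0], ne[4])
        dem.add_population_split(
            time=t_dom + BOTTLENECK_GENERATIONS, derived=["DOM"], ancestral="ANC"
        )
        sampled = ("M", "D3")
    elif which == 2:
        # demes: M, D3, D1, D2, (wild phases reuse deme Nes), ANC
        dem.add_population(name="M", initial_size=ne[0])
        dem.add_population(name="D3", initial_size=ne[1])
        dem.add_population(name="D1", initial_size=ne[2])
        dem.add_population(name="D2", initial_size=ne[3])
        dem.add_population(name="ANC", initial_size=ne[5])
        dem.add_admixture(
            time=t_merge, derived="M", ancestral=["D1", "D2"], proportions=[0.5, 0.5]
        )
        wild_sizes = {"D1": ne[2], "D2": ne[3], "D3": ne[1]}
        for pop, f in zip(("D1", "D2", "D3"), founders):
            _bottleneck(dem, pop, t_dom, f, wild_sizes[pop])
        dem.add_population_split(
            time=t_deep, derived=["D1", "D2", "D3"], ancestral="ANC"
        )
        sampled = ("M", "D3")
    else:
        # demes: M, S1, S2, P1 (domestic), P2 (wild source), ANC
        dem.add_population(name="M", initial_size=ne[0])
        dem.add_population(name="S1", initial_size=ne[1])
        dem.add_population(name="S2", initial_size=ne[2])
        dem.add_population(name="P1", initial_size=ne[3])
        dem.add_population(name="P2", initial_size=ne[4])
        dem.add_population(name="ANC", initial_size=ne[5])
        dem.add_admixture(
            time=t_merge, derived="M", ancestral=["S1", "S2"], proportions=[0.5, 0.5]
        )
        for sub in ("S1", "S2"):
            dem.add_mass_migration(
                time=t_intro, source=sub, dest="P2", proportion=ADMIX_PROPORTION
            )
        dem.add_population_split(time=t_split, derived=["S1", "S2"], ancestral="P1")
        _bottleneck(dem, "P1", t_dom, founders[0], ne[6])
        dem.add_population_split(time=t_deep, derived=["P1", "P2"], ancestral="ANC")
        sampled = ("M",)
    dem.sort_events()
    return DemographicModel(which, dem, sampled, draw)


def constant_size_model(ne: float) -> DemographicModel:
    """Single constant-size haploid population (closed-form control)."""
    dem = msprime.Demography()
    dem.add_population(name="P", initial_size=ne)
    return DemographicModel(0, dem, ("P",), {"model": 0, "ne": [ne]})


def simulate_genealogy(
    model: DemographicModel,
    seed: int,
    n_samples: int = N_SAMPLES,
    num_replicates: int | None = None,
):
    """Haploid genealogies of ``n_samples`` pooled present-day lineages.

    Returns a single tree sequence, or an iterator of tree sequences when
    ``num_replicates`` is given. The sample split across present-day
    populations is drawn from ``seed`` as well, so results replay.
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    samples = model.sample_sizes(rng, n_samples)
    msp_seed = int(rng.integers(1, 2**31 - 1))
    return msprime.sim_ancestry(
        samples=samples,
        demography=model.demography,
        ploidy=1,
        random_seed=msp_seed,
        num_replicates=num_replicates,
    )


@dataclass
class SimulatedDataset:
    """Genotypes for one coalescent replicate.

    ``genotypes`` is an (n_samples, 8) integer matrix over the loci
    ``MSAT_LOCI + IMM_LOCI``: microsatellite columns hold repeat-unit
    states (net SMM displacement from the ancestral state), IMM columns
    hold infinite-alleles state labels (whole band profiles).
    """

    genotypes: np.ndarray
    loci: tuple[str, ...]
    model_id: int
    draw: dict
    seed: int


def drop_mutations(ts, draw: dict, seed: int, model_id: int = 0) -> SimulatedDataset:
    """Drop mutations for all 8 loci on one shared genealogy.

    Microsatellites: per branch, Poisson(length * msat_rate) mutations,
    each a ±1 repeat step with equal probability (only the net
    displacement matters, a Binomial thinning of the Poisson count).
    IMMs: per branch, any mutation (Poisson at the locus's slow rate)
    replaces the profile with a novel state.
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    tree = ts.first()
    order = list(tree.nodes(order="preorder"))
    nnod = ts.num_nodes
    parent = np.array([tree.parent(u) for u in range(nnod)], dtype=np.int64)
    time = ts.tables.nodes.time
    blen = np.zeros(nnod)
    has_parent = parent >= 0
    blen[has_parent] = time[parent[has_parent]] - time[has_parent]

    n_msat, n_imm = len(MSAT_LOCI), len(IMM_LOCI)
    rates = np.asarray(draw["imm_rate"], dtype=float)
    if rates.size != n_imm:
        rates = np.full(n_imm, float(np.ravel(rates)[0]))
    k = rng.poisson(blen[:, None] * draw["msat_rate"], size=(nnod, n_msat))
    net = 2 * rng.binomial(k, 0.5) - k  # net SMM displacement per branch
    imm_hit = rng.poisson(blen[:, None] * rates[None, :], size=(nnod, n_imm)) > 0

    msat = np.zeros((nnod, n_msat), dtype=np.int64)
    imm = np.zeros((nnod, n_imm), dtype=np.int64)
    next_state = 1
    for u in order:
        p = parent[u]
        if p < 0:
            continue
        msat[u] = msat[p] + net[u]
        for j in range(n_imm):
            if imm_hit[u, j]:
                imm[u, j] = next_state
                next_state += 1
            else:
                imm[u, j] = imm[p, j]
    samples = ts.samples()
    geno = np.concatenate([msat[samples], imm[samples]], axis=1)
    return SimulatedDataset(geno, ALL_LOCI, model_id, draw, seed)


def simulate_dataset(
    model: DemographicModel,
    seed: int,
    n_samples: int = N_SAMPLES,
    linked: bool = True,
) -> SimulatedDataset:
    """One replicate: genealogy + mutations.

    ``linked=True`` (default) drops all 8 loci on a single shared
    genealogy, as expected for the non-recombining Y chromosome;
    ``linked=False`` simulates an independent genealogy per locus.
    """
    if linked:
        ts = simulate_genealogy(model, seed, n_samples)
        return drop_mutations(ts, model.draw, seed + 1, model.model_id)
    cols = []
    for j in range(len(ALL_LOCI)):
        ts = simulate_genealogy(model, seed + 1000 * j, n_samples)
        ds = drop_mutations(ts, model.draw, seed + 1000 * j + 1, model.model_id)
        cols.append(ds.genotypes[:, j])
    return SimulatedDataset(
        np.stack(cols, axis=1), ALL_LOCI, model.model_id, model.draw, seed
    )


def simulate_batch(
    model_id: int,
    n_reps: int,
    seed: int,
    priors: PriorSpec | None = None,
    n_samples: int = N_SAMPLES,
    linked: bool = True,
):
    """Yield ``n_reps`` (draw, SimulatedDataset) pairs for one scenario,
    each replicate with a fresh prior draw. Fully reproducible from
    ``seed``."""
    priors = priors or PriorSpec()
    master = np.random.Generator(np.random.PCG64(seed))
    for _ in range(n_reps):
        rep_seed = int(master.integers(1, 2**31 - 10))
        rng = np.random.Generator(np.random.PCG64(rep_seed))
        draw = priors.draw(rng, model_id)
        model = build_model(model_id, draw)
        yield simulate_dataset(model, rep_seed + 1, n_samples, linked)
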