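"""Coalescent simulation of competing demographic scenarios.

The study system is two co-occurring columbine duos (an Eastern and a
Western *A. kansuensis* / *A. ecalcarata* species pair) plus an outgroup.
Scenarios are declared as population splits, admixture pulses and
continuous-migration epochs in *forward-time* terms with times in
generations, and compiled to an :mod:`msprime` demography for simulation.
The library below encodes the competing origin hypotheses — single origin,
strict parallel origin, and hybrid parallel origin (the Eastern pair
descending from an admixed ancestor that received 54% of its genome from
the Western spurless lineage) — alongside two-population gene-flow modes
and null/power designs used to calibrate the introgression statistics.

Scale-down convention: simulated scenarios keep each hypothesis's topology
and admixture proportion but run at Ne = 10,000 with 20 diploids per
population and 10–20 chromosomes of 1 Mb, so a full scan completes in
minutes on one CPU.  Mutation rate defaults to 7e-9 /bp/generation with a
2-year generation time; recombination defaults to 1e-8 /bp/generation so
that 5-kb windows and jackknife blocks are quasi-independent.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import msprime
import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, PopulationMap
from .variant_io import write_popmap, write_vcf

DEFAULT_NE = 10_000
DEFAULT_MU = 7e-9
DEFAULT_RECOMB = 1e-8
DEFAULT_GENERATION_TIME = 2.0
DEFAULT_DIPLOIDS = 20


@dataclass(frozen=True)
class Split:
    """Forward-time population split: at ``time`` (generations ago) the
    ``derived`` populations originate from ``ancestral``."""

    time: float
    derived: tuple[str, ...]
    ancestral: str


@dataclass(frozen=True)
class Pulse:
    """Instantaneous admixture: at ``time`` generations ago, a fraction
    ``proportion`` of ``dest``'s ancestry is replaced by migrants from
    ``source`` (forward-time direction)."""

    time: float
    source: str
    dest: str
    proportion: float


@dataclass(frozen=True)
class MigrationEpoch:
    """Continuous migration ``source -> dest`` (forward-time) at per-generation
    fraction ``rate`` over generations ``start`` (recent) to ``end`` (older)."""

    source: str
    dest: str
    rate: float
    start: float = 0.0
    end: float = math.inf


@dataclass
class DemographicScenario:
    """Declarative multi-population demography.

    ``populations`` maps every population label (sampled or ancestral-only)
    to its diploid effective size; ``sample_sizes`` lists diploid sample
    counts for the sampled populations only.  All times are in generations.
    """

    name: str
    populations: dict[str, float]
    splits: list[Split] = field(default_factory=list)
    pulses: list[Pulse] = field(default_factory=list)
    migrations: list[MigrationEpoch] = field(default_factory=list)
    mutation_rate: float = DEFAULT_MU
    recombination_rate: float = DEFAULT_RECOMB
    genome: list[tuple[str, int]] = field(default_factory=lambda: [("chr1", 1_000_000)])
    sample_sizes: dict[str, int] = field(default_factory=dict)
    generation_time: float = DEFAULT_GENERATION_TIME

    def __post_init__(self) -> None:
        known = set(self.populations)
        for sp in self.splits:
            if sp.time <= 0:
                raise ValueError(f"{self.name}: split time must be > 0")
            for p in (*sp.derived, sp.ancestral):
                if p not in known:
                    raise ValueError(f"{self.name}: split references unknown population {p!r}")
        for pu in self.pulses:
            if not 0 <= pu.proportion <= 1:
                raise ValueError(f"{self.name}: pulse proportion must be in [0, 1]")
            if pu.time <= 0:
                raise ValueError(f"{self.name}: pulse time must be > 0")
            if pu.source not in known or pu.dest not in known:
                raise ValueError(f"{self.name}: pulse references unknown population")
        if self.mutation_rate < 0:
            raise ValueError("mutation rate must be >= 0")
        for _, length in self.genome:
            if length < 1:
                raise ValueError("chromosome lengths must be >= 1")
        for p in self.sample_sizes:
            if p not in known:
                raise ValueError(f"{self.name}: sample for unknown population {p!r}")

    # -- msprime compilation -------------------------------------------------
    def to_demography(self) -> msprime.Demography:
        # a population stops existing (looking backwards) once it merges
        deactivation = {}
        for sp in self.splits:
            for d in sp.derived:
                deactivation[d] = min(sp.time, deactivation.get(d, math.inf))
        for pu in self.pulses:
            for p in (pu.source, pu.dest):
                if pu.time >= deactivation.get(p, math.inf):
                    raise ValueError(
                        f"{self.name}: pulse at {pu.time} references population "
                        f"{p!r} which merged at {deactivation[p]}"
                    )
        dem = msprime.Demography()
        for pop, ne in self.populations.items():
            dem.add_population(name=pop, initial_size=ne)
        sampled = set(self.sample_sizes)
        for sp in self.splits:
            if sp.ancestral in sampled:
                # Merge into a population that persists to the present:
                # backwards in time, all lineages move to the ancestral label.
                for d in sp.derived:
                    dem.add_mass_migration(time=sp.time, source=d, dest=sp.ancestral, proportion=1.0)
            else:
                dem.add_population_split(time=sp.time, derived=list(sp.derived), ancestral=sp.ancestral)
        for pu in self.pulses:
            # Forward source->dest pulse == backwards: lineages now in dest
            # trace to source with probability `proportion`.
            dem.add_mass_migration(time=pu.time, source=pu.dest, dest=pu.source, proportion=pu.proportion)
        for mig in self.migrations:
            # Forward flow source->dest == backwards migration dest->source.
            dem.add_migration_rate_change(time=mig.start, rate=mig.rate, source=mig.dest, dest=mig.source)
            if math.isfinite(mig.end):
                dem.add_migration_rate_change(time=mig.end, rate=0.0, source=mig.dest, dest=mig.source)
        dem.sort_events()
        return dem

    def with_genome(self, genome: Sequence[tuple[str, int]]) -> "DemographicScenario":
        return dataclasses.replace(self, genome=list(genome))

    def with_migration(self, *epochs: MigrationEpoch, suffix: str = "_mig") -> "DemographicScenario":
        return dataclasses.replace(
            self, name=self.name + suffix, migrations=self.migrations + list(epochs)
        )

    # -- (de)serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["splits"] = [{"time": s.time, "derived": list(s.derived), "ancestral": s.ancestral} for s in self.splits]
        d["genome"] = [[c, int(l)] for c, l in self.genome]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DemographicScenario":
        return cls(
            name=d["name"],
            populations=dict(d["populations"]),
            splits=[Split(s["time"], tuple(s["derived"]), s["ancestral"]) for s in d.get("splits", [])],
            pulses=[Pulse(**p) for p in d.get("pulses", [])],
            migrations=[MigrationEpoch(**m) for m in d.get("migrations", [])],
            mutation_rate=d.get("mutation_rate", DEFAULT_MU),
            recombination_rate=d.get("recombination_rate", DEFAULT_RECOMB),
            genome=[(c, int(l)) for c, l in d.get("genome", [["chr1", 1_000_000]])],
            sample_sizes=dict(d.get("sample_sizes", {})),
            generation_time=d.get("generation_time", DEFAULT_GENERATION_TIME),
        )

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def load_json(cls, path: str | Path) -> "DemographicScenario":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class TruthRecord:
    """Ground truth carried by a simulation run: the scenario, the seed, and
    realized event times in generations and kya (kya = gen x g / 1000)."""

    scenario: DemographicScenario
    seed: int

    def events(self) -> pd.DataFrame:
        g = self.scenario.generation_time
        rows = []
        for sp in self.scenario.splits:
            rows.append(("split", "+".join(sp.derived) + "<-" + sp.ancestral, sp.time, math.nan))
        for pu in self.scenario.pulses:
            rows.append(("pulse", f"{pu.source}->{pu.dest}", pu.time, pu.proportion))
        for mig in self.scenario.migrations:
            rows.append(("migration", f"{mig.source}->{mig.dest}", mig.start, mig.rate))
        df = pd.DataFrame(rows, columns=["kind", "participants", "time_generations", "value"])
        df["time_kya"] = df["time_generations"] * g / 1000.0
        return df.sort_values("time_generations", kind="stable").reset_index(drop=True)

    def admixture_proportions(self) -> dict[str, float]:
        return {f"{p.source}->{p.dest}": p.proportion for p in self.scenario.pulses}

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario.to_dict(),
            "seed": self.seed,
            "events": self.events().to_dict(orient="records"),
        }


def truth_to_kya(truth: TruthRecord) -> pd.DataFrame:
    """Event times in kya via the scenario's generation time."""
    if truth.scenario.generation_time <= 0:
        raise ValueError("generation time must be > 0")
    return truth.events()[["kind", "participants", "time_generations", "time_kya"]]


@dataclass
class SimOutput:
    genotypes: GenotypeMatrix
    popmap: PopulationMap
    truth: TruthRecord

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / "simulated.vcf",
            "popmap": outdir / "popmap.tsv",
            "truth": outdir / "truth.json",
        }
        write_vcf(self.genotypes, paths["vcf"], contigs=self.truth.scenario.genome)
        write_popmap(self.popmap, paths["popmap"])
        paths["truth"].write_text(json.dumps(self.truth.to_dict(), indent=2, sort_keys=True) + "\n")
        return paths


# ---------------------------------------------------------------------------
# Scenario library
# ---------------------------------------------------------------------------

_PAIR_POPS = ("kan_east", "eca_east", "kan_west", "eca_west")

#: Best-fit hybrid-parallel-origin parameters (times in generations at a
#: 2-year generation time): first West kansuensis/ecalcarata divergence at
#: 2,174 kya; admixture pulse into the Eastern ancestor at ~1,629 kya (CI
#: midpoint) contributing 54% of its ancestry; Eastern pair split at
#: 1,406 kya.  Outgroup divergence is set to 10x the oldest ingroup split
#: so ancestral alleles are near-fixed for polarization.
BESTFIT_SPLIT_WEST_GEN = 2_174_000 / DEFAULT_GENERATION_TIME  # 1,087,000
BESTFIT_PULSE_GEN = 1_629_000 / DEFAULT_GENERATION_TIME  # 814,500
BESTFIT_SPLIT_EAST_GEN = 1_406_000 / DEFAULT_GENERATION_TIME  # 703,000
BESTFIT_ALPHA = 0.54


def _pops(names: Sequence[str], ne: float = DEFAULT_NE) -> dict[str, float]:
    return {n: ne for n in names}


def _genome(n_chrom: int, length: int = 1_000_000) -> list[tuple[str, int]]:
    return [(f"chr{i}", length) for i in range(1, n_chrom + 1)]


def _five_pop_scenario(name: str, splits: list[Split], pulses: list[Pulse] | None = None,
                       migrations: list[MigrationEpoch] | None = None,
                       extra_ancestral: Sequence[str] = (),
                       n_chrom: int = 10) -> DemographicScenario:
    ancestral = sorted({sp.ancestral for sp in splits} - set(_PAIR_POPS) - {"outgroup"})
    return DemographicScenario(
        name=name,
        populations=_pops([*_PAIR_POPS, "outgroup", *ancestral, *extra_ancestral]),
        splits=splits,
        pulses=pulses or [],
        migrations=migrations or [],
        genome=_genome(n_chrom),
        sample_sizes={p: DEFAULT_DIPLOIDS for p in (*_PAIR_POPS, "outgroup")},
    )


def _recent_conspecific_flow(rate: float = 2.5e-5, end: float = 2000.0) -> list[MigrationEpoch]:
    """Mild recent gene flow between conspecifics across East/West, used by
    the origin-topology models which all allow recent contact."""
    out = []
    for a, b in (("eca_east", "eca_west"), ("kan_east", "kan_west")):
        out.append(MigrationEpoch(a, b, rate, 0.0, end))
        out.append(MigrationEpoch(b, a, rate, 0.0, end))
    return out


def scenario_library() -> dict[str, DemographicScenario]:
    """Named demographic scenarios: gene-flow modes, origin topologies,
    the best-fit hybrid model, and null/power/recovery designs."""
    lib: dict[str, DemographicScenario] = {}

    # ---- four pairwise gene-flow modes (two populations + outgroup) ------
    def pair_mode(name: str, migrations: list[MigrationEpoch]) -> DemographicScenario:
        return DemographicScenario(
            name=name,
            populations=_pops(["kansuensis", "ecalcarata", "outgroup", "anc_pair", "anc_all"]),
            splits=[
                Split(8_000, ("kansuensis", "ecalcarata"), "anc_pair"),
                Split(80_000, ("anc_pair", "outgroup"), "anc_all"),
            ],
            migrations=migrations,
            genome=_genome(10),
            sample_sizes={p: DEFAULT_DIPLOIDS for p in ("kansuensis", "ecalcarata", "outgroup")},
        )

    m = 1e-4
    both = lambda s, e: [MigrationEpoch("kansuensis", "ecalcarata", m, s, e),
                         MigrationEpoch("ecalcarata", "kansuensis", m, s, e)]
    lib["pair_no_gene_flow"] = pair_mode("pair_no_gene_flow", [])
    lib["pair_secondary_contact"] = pair_mode("pair_secondary_contact", both(0, 4_000))
    lib["pair_early_gene_flow"] = pair_mode("pair_early_gene_flow", both(4_000, 8_000))
    lib["pair_constant_gene_flow"] = pair_mode("pair_constant_gene_flow", both(0, 8_000))

    # ---- null and power designs (four ingroup populations + outgroup) ----
    null_splits = [
        Split(4_000, ("kan_east", "eca_east"), "anc_east"),
        Split(4_000, ("kan_west", "eca_west"), "anc_west"),
        Split(12_000, ("anc_east", "anc_west"), "root"),
        Split(120_000, ("root", "outgroup"), "anc_all"),
    ]
    lib["null_no_flow"] = _five_pop_scenario("null_no_flow", null_splits)
    lib["power_recent_migration"] = _five_pop_scenario(
        "power_recent_migration",
        null_splits,
        migrations=[MigrationEpoch("eca_west", "eca_east", 1e-3, 0.0, 1_000.0)],
    )

    # ---- six origin topologies -------------------------------------------
    flow = _recent_conspecific_flow()
    lib["single_origin_east_kan_first"] = _five_pop_scenario(
        "single_origin_east_kan_first",
        [
            Split(4_000, ("eca_east", "eca_west"), "anc_eca"),
            Split(8_000, ("kan_west", "anc_eca"), "anc_mid"),
            Split(12_000, ("kan_east", "anc_mid"), "root"),
            Split(120_000, ("root", "outgroup"), "anc_all"),
        ],
        migrations=flow,
    )
    lib["single_origin_west_kan_first"] = _five_pop_scenario(
        "single_origin_west_kan_first",
        [
            Split(4_000, ("eca_east", "eca_west"), "anc_eca"),
            Split(8_000, ("kan_east", "anc_eca"), "anc_mid"),
            Split(12_000, ("kan_west", "anc_mid"), "root"),
            Split(120_000, ("root", "outgroup"), "anc_all"),
        ],
        migrations=flow,
    )
    lib["single_origin_colonization"] = _five_pop_scenario(
        "single_origin_colonization",
        [
            Split(4_000, ("kan_east", "kan_west"), "anc_kan"),
            Split(4_000, ("eca_east", "eca_west"), "anc_eca"),
            Split(12_000, ("anc_kan", "anc_eca"), "root"),
            Split(120_000, ("root", "outgroup"), "anc_all"),
        ],
        migrations=flow,
    )
    lib["parallel_origin"] = _five_pop_scenario(
        "parallel_origin", null_splits, migrations=flow
    )
    lib["hybrid_origin_west"] = _five_pop_scenario(
        "hybrid_origin_west",
        [
            Split(4_000, ("kan_west", "eca_west"), "anc_adm_w"),
            Split(5_001, ("anc_adm_w",), "kan_east"),
            Split(12_000, ("kan_east", "eca_east"), "root"),
            Split(120_000, ("root", "outgroup"), "anc_all"),
        ],
        pulses=[Pulse(5_000, "eca_east", "anc_adm_w", BESTFIT_ALPHA)],
        migrations=flow,
    )
    lib["hybrid_origin_east"] = _five_pop_scenario(
        "hybrid_origin_east",
        [
            Split(4_000, ("kan_east", "eca_east"), "anc_adm_e"),
            Split(5_001, ("anc_adm_e",), "kan_west"),
            Split(12_000, ("kan_west", "eca_west"), "root"),
            Split(120_000, ("root", "outgroup"), "anc_all"),
        ],
        pulses=[Pulse(5_000, "eca_west", "anc_adm_e", BESTFIT_ALPHA)],
        migrations=flow,
    )

    # ---- best-fit hybrid-parallel-origin model, literal event times ------
    lib["bestfit_hybrid_origin"] = _five_pop_scenario(
        "bestfit_hybrid_origin",
        [
            Split(BESTFIT_SPLIT_EAST_GEN, ("kan_east", "eca_east"), "anc_east_adm"),
            Split(BESTFIT_PULSE_GEN + 1, ("anc_east_adm",), "kan_west"),
            Split(BESTFIT_SPLIT_WEST_GEN, ("kan_west", "eca_west"), "root"),
            Split(10 * BESTFIT_SPLIT_WEST_GEN, ("root", "outgroup"), "anc_all"),
        ],
        pulses=[Pulse(BESTFIT_PULSE_GEN, "eca_west", "anc_east_adm", BESTFIT_ALPHA)],
    )

    # ---- f4-ratio recovery design ----------------------------------------
    # Same hybrid-origin topology and admixture proportion as the best-fit
    # model, but with the pulse placed close to the sampling time relative
    # to the donor branch.  The split-half f4-ratio estimates the admixture
    # fraction only up to the drift the donor lineage accrues after the
    # pulse (attenuation ~ (T_root - t_pulse)/T_root); a recent pulse keeps
    # that factor near 1 so the estimator is a consistent check of the
    # encoded 54% donor contribution.
    lib["pulse_recovery"] = _five_pop_scenario(
        "pulse_recovery",
        [
            Split(500, ("kan_east", "eca_east"), "anc_east_adm"),
            Split(801, ("anc_east_adm",), "kan_west"),
            Split(20_000, ("kan_west", "eca_west"), "root"),
            Split(200_000, ("root", "outgroup"), "anc_all"),
        ],
        pulses=[Pulse(800, "eca_west", "anc_east_adm", BESTFIT_ALPHA)],
        n_chrom=20,
    )

    # ---- single population, Watterson calibration ------------------------
    lib["single_pop_calibration"] = DemographicScenario(
        name="single_pop_calibration",
        populations={"pop1": DEFAULT_NE},
        genome=_genome(1),
        sample_sizes={"pop1": 10},
    )
    return lib


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _chromosome_seeds(seed: int, n_chrom: int) -> list[tuple[int, int]]:
    ss = np.random.SeedSequence(seed)
    state = ss.generate_state(2 * n_chrom, dtype=np.uint32)
    # msprime seeds must be in [1, 2^32 - 1]
    return [(int(state[2 * i]) % (2**31 - 1) + 1, int(state[2 * i + 1]) % (2**31 - 1) + 1)
            for i in range(n_chrom)]


def simulate(scenario: DemographicScenario, seed: int) -> SimOutput:
    """Draw a genotype matrix from the neutral coalescent under ``scenario``.

    Mutations follow a nucleotide model with at most one mutation per
    retained site: sites carrying recurrent or back mutations are dropped,
    so every retained site is strictly biallelic with a known ancestral
    (ref) and derived (alt) allele.  Deterministic given ``seed``.
    """
    if not scenario.sample_sizes:
        raise ValueError(f"{scenario.name}: no sampled populations")
    demography = scenario.to_demography()
    pop_order = list(scenario.sample_sizes)
    sample_sets = [
        msprime.SampleSet(scenario.sample_sizes[p], population=p, ploidy=2) for p in pop_order
    ]
    sample_names: list[str] = []
    for p in pop_order:
        sample_names.extend(f"{p}_{k:02d}" for k in range(1, scenario.sample_sizes[p] + 1))
    n_dip = len(sample_names)

    site_rows: list[tuple[str, int, str, str]] = []
    dosage_cols: list[np.ndarray] = []
    for (chrom, length), (seed_anc, seed_mut) in zip(
        scenario.genome, _chromosome_seeds(seed, len(scenario.genome))
    ):
        ts = msprime.sim_ancestry(
            samples=sample_sets,
            demography=demography,
            sequence_length=length,
            recombination_rate=scenario.recombination_rate,
            random_seed=seed_anc,
        )
        if scenario.mutation_rate > 0:
            ts = msprime.sim_mutations(ts, rate=scenario.mutation_rate, random_seed=seed_mut)
        for var in ts.variants():
            site = var.site
            if len(site.mutations) != 1 or len(var.alleles) != 2:
                continue
            g = var.genotypes
            dosage_cols.append((g[0::2] + g[1::2]).astype(np.int8))
            site_rows.append((chrom, int(site.position) + 1, var.alleles[0], var.alleles[1]))

    sites = pd.DataFrame(site_rows, columns=["chrom", "pos", "ref", "alt"])
    dosage = (
        np.stack(dosage_cols, axis=1) if dosage_cols else np.empty((n_dip, 0), dtype=np.int8)
    )
    gm = GenotypeMatrix(sites, sample_names, dosage)
    roles = {"outgroup": "outgroup"} if "outgroup" in pop_order else {}
    popmap = PopulationMap(
        assignment={s: s.rsplit("_", 1)[0] for s in sample_names}, roles=roles
    )
    return SimOutput(genotypes=gm, popmap=popmap, truth=TruthRecord(scenario=scenario, seed=seed))


def watterson_expected_segregating_sites(ne: float, mu: float, length: float, n_diploids: int) -> float:
    """Closed-form neutral expectation 4*Ne*mu*L*a_{2n-1} for one population."""
    a = sum(1.0 / i for i in range(1, 2 * n_diploids))
    return 4.0 * ne * mu * length * a
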