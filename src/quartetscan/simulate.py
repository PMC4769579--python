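"""Truth-labeled synthetic quartet data from coalescent simulation.

Generates genotype matrices for a four-taxon quartet sampled as in the
study design this package targets — three ingroup taxa with four
diploids each on the asymmetric topology ((P1, P2), P3), plus a single
diploid outgroup — under incomplete lineage sorting alone or with
introgression pulses of stated direction, time and proportion. Every
simulated window carries a truth label, so each stage of the scan
pipeline can be tested against known ground truth.

Window-confined pulses are realized by simulating affected and
background segments of the chromosome as independent coalescent runs
(linkage does not cross segment boundaries). The realized donor-ancestry
fraction is measured from a census layer placed just above the pulse
time: the fraction of the recipient samples' genome whose ancestral
lineage sits in the donor population at the census.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd
import tskit

from .genotype_io import MISSING, ConfigError, GenotypeMatrix, QuartetSpec
from .popgen import SiteFrequencies

_POPS = ("P1", "P2", "P3", "O")


@dataclass
class DemographyConfig:
    """Demography of the simulated quartet, in generations and diploid N_e.

    Split times are ordered tips-to-root: P1/P2 diverge most recently,
    their ancestor joins P3, and the outgroup is the deepest split. The
    defaults give roughly one coalescent unit between the two ingroup
    splits — enough incomplete lineage sorting for ABBA/BABA patterns to
    be common without gene flow — and per-sample sizes mirroring the
    4+4+4+1 diploid design.

    Rates are coalescent-scaled: with N_e = 10^4 the default mutation
    rate yields nucleotide diversity θ = 4·N_e·μ ≈ 0.01 per bp, the
    magnitude observed in highly polymorphic butterfly genomes, so a
    5-kb window carries on the order of a hundred SNPs as in the data
    this pipeline is built for. Only the products θ = 4N_e μ and
    ρ = 4N_e r (and split times in units of 2N_e) matter to the
    statistics, not the absolute N_e.
    """

    ne: float = 10_000.0
    split_p1_p2: float = 20_000.0
    split_p12_p3: float = 60_000.0
    split_outgroup: float = 200_000.0
    samples: tuple[int, int, int, int] = (4, 4, 4, 1)
    mutation_rate: float = 2.5e-7
    recombination_rate: float = 1e-7
    chromosomes: dict = field(default_factory=lambda: {"chr1": 1_000_000})

    def __post_init__(self):
        if not (0 < self.split_p1_p2 < self.split_p12_p3 < self.split_outgroup):
            raise ConfigError("split times must be strictly ordered tips-to-root")
        if self.mutation_rate < 0 or self.recombination_rate < 0:
            raise ConfigError("rates must be non-negative")


@dataclass
class IntrogressionEvent:
    """A single admixture pulse.

    ``proportion`` is the fraction of recipient lineages replaced by the
    donor at ``time`` generations ago; ``windows`` restricts the pulse to
    the listed (chrom, start, end) intervals, or the whole genome when
    None.
    """

    donor: str = "P3"
    recipient: str = "P2"
    time: float = 4_000.0
    proportion: float = 0.5
    windows: list | None = None
    event_id: str = "pulse"

    def __post_init__(self):
        if not (0 <= self.proportion <= 1):
            raise ConfigError("pulse proportion must lie in [0, 1]")
        if self.donor not in _POPS or self.recipient not in _POPS:
            raise ConfigError("donor and recipient must be quartet populations")
        if self.donor == self.recipient:
            raise ConfigError("donor and recipient must differ")


def _validate_event_times(demog: DemographyConfig, events) -> None:
    # a population exists (backwards in time) until it merges into its ancestor
    exists_until = {"P1": demog.split_p1_p2, "P2": demog.split_p1_p2,
                    "P3": demog.split_p12_p3, "O": demog.split_outgroup}
    for ev in events:
        limit = min(exists_until[ev.donor], exists_until[ev.recipient])
        if not (0 < ev.time < limit):
            raise ConfigError(
                f"pulse time {ev.time} must be younger than {limit}, when "
                f"{ev.donor} and {ev.recipient} both still exist")


def _build_demography(cfg: DemographyConfig, events=(), census_time=None):
    d = msprime.Demography()
    for name in _POPS + ("A12", "A123", "ROOT"):
        d.add_population(name=name, initial_size=cfg.ne)
    for ev in events:
        # backwards in time: recipient lineages jump into the donor
        d.add_mass_migration(time=ev.time, source=ev.recipient,
                             dest=ev.donor, proportion=ev.proportion)
    if census_time is not None:
        d.add_census(time=census_time)
    d.add_population_split(time=cfg.split_p1_p2, derived=["P1", "P2"], ancestral="A12")
    d.add_population_split(time=cfg.split_p12_p3, derived=["A12", "P3"], ancestral="A123")
    d.add_population_split(time=cfg.split_outgroup, derived=["A123", "O"], ancestral="ROOT")
    d.sort_events()
    return d


def _census_donor_fraction(ts, census_time: float, recipient: str, donor: str) -> float:
    """Fraction of recipient sample genome with a donor-side census ancestor."""
    pop_id = {p.metadata.get("name", str(p.id)): p.id for p in ts.populations()}
    rec_samples = [u for u in ts.samples() if ts.node(u).population == pop_id[recipient]]
    if not rec_samples:
        return float("nan")
    times = ts.tables.nodes.time
    pops = ts.tables.nodes.population
    donor_span = 0.0
    total = 0.0
    for tree in ts.trees():
        span = tree.span
        for u in rec_samples:
            v = u
            while v != tskit.NULL and times[v] < census_time:
                v = tree.parent(v)
            total += span
            if v != tskit.NULL and times[v] == census_time and pops[v] == pop_id[donor]:
                donor_span += span
    return donor_span / total


def _site_alleles(ts, kept_idx: np.ndarray):
    """Ancestral and first derived allele per kept site (vectorized)."""
    st = ts.tables.sites
    anc_all = np.array(tskit.unpack_strings(st.ancestral_state,
                                            st.ancestral_state_offset),
                       dtype=object)
    mt = ts.tables.mutations
    der_all = np.array(tskit.unpack_strings(mt.derived_state,
                                            mt.derived_state_offset),
                       dtype=object)
    # first mutation row per site (mutations are sorted by site)
    _, first = np.unique(mt.site, return_index=True)
    der_per_site = np.full(ts.num_sites, "T", dtype=object)
    der_per_site[np.unique(mt.site)] = der_all[first]
    return anc_all[kept_idx], der_per_site[kept_idx]


def _segments(length: int, chrom: str, events):
    """Split [0, length) into maximal runs with a constant set of active pulses."""
    cuts = {0, length}
    for ev in events:
        if ev.windows is None:
            continue
        for (c, s, e) in ev.windows:
            if c == chrom:
                cuts.add(max(0, int(s)))
                cuts.add(min(length, int(e)))
    edges = sorted(cuts)
    for s, e in zip(edges, edges[1:]):
        active = []
        for ev in events:
            if ev.windows is None:
                active.append(ev)
            else:
                for (c, ws, we) in ev.windows:
                    if c == chrom and ws <= s and e <= we:
                        active.append(ev)
                        break
        yield s, e, active


def simulate_quartet_genotypes(demography: DemographyConfig | None = None,
                               events=(), seed: int = 1,
                               depth_mean: float | None = 20.0,
                               depth_overrides=()):
    """Simulate quartet genotypes with per-segment truth labels.

    Returns ``(matrix, truth, quartet)`` where ``truth`` is a DataFrame
    with one row per simulated segment (chrom, start, end, introgressed,
    event_id, realized_fraction). Deterministic for a fixed seed.

    ``depth_mean`` adds Poisson per-genotype read depths (None to omit);
    ``depth_overrides`` is a list of (chrom, start, end, mean) regions
    with a different depth mean, for planting depth-filter failures.
    """
    cfg = demography or DemographyConfig()
    events = list(events)
    _validate_event_times(cfg, events)
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    sample_names = []
    for pop, n in zip(_POPS, cfg.samples):
        sample_names += [f"{pop}_{i}" for i in range(n)]
    n_samples = len(sample_names)

    chroms_col, pos_col, ref_col, alt_col, dos_rows = [], [], [], [], []
    truth_rows = []
    for chrom, length in cfg.chromosomes.items():
        for seg_start, seg_end, active in _segments(int(length), chrom, events):
            anc_seed = int(rng.integers(1, 2**31 - 1))
            mut_seed = int(rng.integers(1, 2**31 - 1))
            census = max(ev.time for ev in active) + 1.0 if active else None
            demog = _build_demography(cfg, active, census_time=census)
            ts = msprime.sim_ancestry(
                samples={p: n for p, n in zip(_POPS, cfg.samples)},
                demography=demog, sequence_length=seg_end - seg_start,
                recombination_rate=cfg.recombination_rate,
                random_seed=anc_seed)
            ts = msprime.sim_mutations(ts, rate=cfg.mutation_rate,
                                       random_seed=mut_seed)
            realized = 0.0
            if active:
                # attribute the realized fraction to the strongest pulse
                main = max(active, key=lambda ev: ev.proportion)
                realized = _census_donor_fraction(ts, census, main.recipient,
                                                 main.donor)
            truth_rows.append({
                "chrom": chrom, "start": seg_start, "end": seg_end,
                "introgressed": bool(active),
                "event_id": ";".join(ev.event_id for ev in active) or ".",
                "realized_fraction": realized,
            })
            gm = ts.genotype_matrix()  # (sites, haploid samples), allele indices
            positions = ts.tables.sites.position.astype(np.int64)
            biallelic = gm.max(axis=1) == 1
            # drop recurrent hits at the same integer coordinate
            first = np.ones(len(positions), dtype=bool)
            first[1:] = positions[1:] != positions[:-1]
            keep = biallelic & first
            gm = gm[keep]
            dos = (gm[:, 0::2] + gm[:, 1::2]).astype(np.int8)
            anc, der = _site_alleles(ts, np.flatnonzero(keep))
            chroms_col.append(np.full(len(dos), chrom, dtype=object))
            pos_col.append(seg_start + positions[keep])
            ref_col.append(anc)
            alt_col.append(der)
            dos_rows.append(dos)

    empty = not dos_rows or sum(len(d) for d in dos_rows) == 0
    matrix = GenotypeMatrix(
        chroms=(np.concatenate(chroms_col) if not empty
                else np.empty(0, dtype=object)),
        pos=(np.concatenate(pos_col) if not empty
             else np.empty(0, dtype=np.int64)),
        ref=(np.concatenate(ref_col) if not empty
             else np.empty(0, dtype=object)),
        alt=(np.concatenate(alt_col) if not empty
             else np.empty(0, dtype=object)),
        dosages=(np.vstack(dos_rows) if not empty
                 else np.empty((0, n_samples), dtype=np.int8)),
        samples=sample_names,
    )
    matrix.validate()
    if depth_mean is not None:
        depth_seed = int(rng.integers(1, 2**31 - 1))
        matrix.depths = simulate_read_depths(
            matrix, depth_mean, depth_seed, overrides=depth_overrides)

    truth = pd.DataFrame(truth_rows)
    quartet = QuartetSpec(
        tuple(s for s in sample_names if s.startswith("P1")),
        tuple(s for s in sample_names if s.startswith("P2")),
        tuple(s for s in sample_names if s.startswith("P3")),
        tuple(s for s in sample_names if s.startswith("O")),
        labels={"P1": "P1", "P2": "P2", "P3": "P3", "O": "O"},
    )
    return matrix, truth, quartet


def simulate_read_depths(matrix: GenotypeMatrix, mean_depth: float,
                         seed: int, overrides=()) -> np.ndarray:
    """Poisson per-genotype read depths, with optional per-region means.

    ``overrides`` is a list of (chrom, start, end, mean) tuples; sites in
    those intervals draw from the override mean instead.
    """
    if mean_depth <= 0:
        raise ConfigError("mean depth must be positive")
    rng = np.random.default_rng(seed)
    means = np.full(matrix.n_sites, float(mean_depth))
    for (chrom, start, end, m) in overrides:
        hit = (matrix.chroms == chrom) & (matrix.pos >= start) & (matrix.pos < end)
        means[hit] = float(m)
    return rng.poisson(means[:, None],
                       size=(matrix.n_sites, matrix.n_samples)).astype(np.int32)


def make_fixture_frequencies(freq_tuples) -> SiteFrequencies:
    """Deterministic frequency table from explicit (p1, p2, p3, p4) tuples.

    Intended for exact oracle tests of the D, f_d and d_xy formulas.
    """
    arr = np.array(list(freq_tuples), dtype=float).reshape(-1, 4)
    if arr.size and (arr.min() < 0 or arr.max() > 1):
        raise ConfigError("frequencies must lie in [0, 1]")
    n = len(arr)
    return SiteFrequencies(
        pos=np.arange(n, dtype=np.int64),
        freqs=arr,
        n_called=np.full((n, 4), 8, dtype=np.int64),
        derived_is_alt=np.ones(n, dtype=bool),
    )


# ---------------------------------------------------------------------------
# Companion text outputs (same formats genotype_io consumes)
# ---------------------------------------------------------------------------

def write_population_map(quartet: QuartetSpec, path: str) -> None:
    with open(path, "w") as fh:
        for role, samples in quartet.roles.items():
            taxon = quartet.labels.get(role, role)
            for s in samples:
                fh.write(f"{s}\t{taxon}\t{role}\n")


def write_scaffold_map(placements: dict, path: str) -> None:
    with open(path, "w") as fh:
        for scaf, pl in placements.items():
            length = "" if pl.length is None else str(pl.length)
            fh.write(f"{scaf}\t{pl.chrom}\t{pl.offset}\t{pl.strand}\t{length}\n")


def write_truth_table(truth: pd.DataFrame, path: str) -> None:
    truth.to_csv(path, sep="\t", index=False)
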