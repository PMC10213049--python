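"""Synthetic mother-infant cohort generator with ground-truth transmission.

The generator emulates the statistical structure of a bifidobacteria-focused
mother-infant strain-transmission study at desk scale:

* GC-rich genomes (default 59.41% GC, the median for the genus) of 100 kb
  (thresholds downstream are ratio- or count-based, so results carry over
  from full 2.3 Mb genomes; SNP *counts* are preserved, not densities);
* within-host micro-diversity: an individual's isolates of one species are
  siblings of a personal founder, each Poisson(10) substitutions away,
  which yields pairwise distances in the observed 1-121 band;
* transmitted mother-infant strain pairs 3-61 SNPs apart (same lineage),
  non-transmitted infants carrying an independent lineage thousands of SNPs
  away (pairwise ~3000-10000, i.e. ANI around 98.7% at 100 kb scale… the
  count is drawn so the *pairwise* distance falls in the configured range);
* perinatal covariates (delivery mode, membrane rupture, labour onset,
  intrapartum antibiotics) drawn from a consistent joint model, with the
  per-dyad transmission probability optionally conditioned on them;
* per-sample species relative-abundance profiles and a multinomial
  shotgun-read simulator with uniform substitution errors.

All randomness flows from one root seed, hierarchically split per
dyad/genome/read-set, so sub-components are reproducible in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from straindyad.errors import ParameterError

SAMPLE_TYPES = ("maternal_stool", "infant_stool", "breast_milk", "vaginal", "oral")
DELIVERY_MODES = ("vaginal", "caesarean")
MEMBRANE_RUPTURE = ("SROM", "POM", "ARM", "at_LSCS")
LABOUR_ONSET = ("spontaneous", "induced", "pre_labour_CS")
ANTIBIOTICS = ("yes", "no")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def rng_for(seed: int, *keys) -> np.random.Generator:
    """Generator from a root seed plus a hierarchical key path.

    Keys may be ints or strings; strings are hashed with CRC32 so the split
    is stable across runs and platforms.
    """
    spawn = tuple(k if isinstance(k, (int, np.integer)) else zlib.crc32(str(k).encode()) for k in keys)
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(int(seed), spawn_key=spawn)))


def encode_sequence(sequence: str) -> np.ndarray:
    """ACGT string -> uint8 codes 0..3."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    if np.any(codes == 255):
        raise ParameterError("sequence contains characters outside ACGT")
    return codes


def decode_sequence(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


@dataclass(eq=False)
class Genome:
    """A strain's assembled sequence with provenance labels.

    ``lineage_id`` records the ancestral lineage the genome was derived
    from, which is the simulation's ground truth for "same strain".
    """

    genome_id: str
    sequence: str
    individual_id: str
    sample_type: str
    species_label: str
    lineage_id: str
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParameterError("genome sequence must be non-empty")
        if self.sample_type not in SAMPLE_TYPES:
            raise ParameterError(f"unknown sample_type {self.sample_type!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def codes(self) -> np.ndarray:
        """Cached uint8 encoding of the sequence (validates the alphabet)."""
        if self._codes is None:
            self._codes = encode_sequence(self.sequence)
        return self._codes

    def gc_content(self) -> float:
        c = self.codes
        return float(np.mean((c == 1) | (c == 2)))


@dataclass
class ReadSet:
    """Simulated single-end shotgun reads from one sample.

    ``truth_composition`` maps genome_id to the expected read fraction
    (abundance x genome length, normalized); it sums to 1 whenever any
    reads are emitted.
    """

    reads: list[tuple[str, str, str]]  # (read_id, sequence, qualities)
    source_sample: str
    truth_composition: dict[str, float]

    def __len__(self) -> int:
        return len(self.reads)


@dataclass(frozen=True)
class Dyad:
    dyad_id: str
    mother_id: str
    infant_id: str
    covariates: Mapping[str, str]


@dataclass(frozen=True)
class TrueTransmission:
    dyad_id: str
    species: str
    mother_genome_id: str
    infant_genome_id: str
    n_snps: int
    lineage_id: str


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Defaults encode the study conditions: 3-61 SNPs between transmitted
    mother-infant strain pairs, distinct lineages separated by thousands of
    SNPs, Poisson(10) micro-diversity branches, 59.41% GC, 100 kb genomes.
    ``covariate_effects`` maps covariate name -> {level: P(transmit)}; with
    several covariates listed the per-covariate probabilities are averaged;
    without a table the flat ``transmitted_fraction`` applies.
    """

    n_dyads: int = 40
    species: tuple[str, ...] = ("Bifidobacterium_breve", "Bifidobacterium_longum")
    genome_length: int = 100_000
    gc_content: float = 0.5941
    transmitted_fraction: float = 0.5
    transmitted_snp_range: tuple[int, int] = (3, 61)
    distinct_snp_range: tuple[int, int] = (3000, 10000)
    microdiversity_mean_snps: float = 10.0
    strains_per_individual: int = 1
    covariate_effects: dict[str, dict[str, float]] | None = None
    genus_fraction_infant: float = 0.5
    genus_fraction_mother: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        lo_t, hi_t = self.transmitted_snp_range
        lo_d, hi_d = self.distinct_snp_range
        if not (0 < lo_t <= hi_t):
            raise ParameterError("transmitted_snp_range must be positive and ordered")
        if not (0 < lo_d <= hi_d):
            raise ParameterError("distinct_snp_range must be positive and ordered")
        if hi_t >= lo_d:
            raise ParameterError(
                "transmitted_snp_range must lie strictly below distinct_snp_range "
                f"(got {self.transmitted_snp_range} vs {self.distinct_snp_range})"
            )
        if self.n_dyads < 1:
            raise ParameterError("n_dyads must be >= 1")
        if not 0.0 <= self.transmitted_fraction <= 1.0:
            raise ParameterError("transmitted_fraction must be in [0, 1]")
        if self.covariate_effects:
            for cov, table in self.covariate_effects.items():
                for level, p in table.items():
                    if not 0.0 <= p <= 1.0:
                        raise ParameterError(f"P(transmit | {cov}={level}) = {p} outside [0, 1]")


@dataclass
class CohortTruth:
    """Simulated dyads, strains, covariates and ground-truth transmissions."""

    dyads: list[Dyad]
    strains: list[Genome]
    true_transmissions: list[TrueTransmission]
    abundances: dict[str, dict[str, float]]  # sample_id -> species -> rel. abundance
    config: CohortConfig

    def __post_init__(self) -> None:
        ids = [g.genome_id for g in self.strains]
        if len(set(ids)) != len(ids):
            raise ParameterError("genome_id must be unique within a cohort")
        by_id = {g.genome_id: g for g in self.strains}
        for t in self.true_transmissions:
            m, i = by_id[t.mother_genome_id], by_id[t.infant_genome_id]
            if m.lineage_id != i.lineage_id:
                raise ParameterError(
                    f"true transmission {t.dyad_id}/{t.species} links different lineages"
                )
        for sample, profile in self.abundances.items():
            total = sum(profile.values())
            if any(v < 0 for v in profile.values()) or total > 1 + 1e-9:
                raise ParameterError(f"abundances of {sample} outside [0, 1] or sum > 1")

    # -- lookup helpers -------------------------------------------------
    def genome(self, genome_id: str) -> Genome:
        return next(g for g in self.strains if g.genome_id == genome_id)

    def genomes_of(self, individual_id: str | None = None, species: str | None = None) -> list[Genome]:
        out = self.strains
        if individual_id is not None:
            out = [g for g in out if g.individual_id == individual_id]
        if species is not None:
            out = [g for g in out if g.species_label == species]
        return list(out)

    @staticmethod
    def stool_sample(individual_id: str) -> str:
        return f"{individual_id}_stool"

    def is_transmitted(self, dyad_id: str, species: str) -> bool:
        return any(t.dyad_id == dyad_id and t.species == species for t in self.true_transmissions)


# ----------------------------------------------------------------------
# genome-level operations
# ----------------------------------------------------------------------

def generate_ancestral_genome(
    length: int,
    gc_content: float,
    seed: int,
    *,
    genome_id: str = "ancestor",
    individual_id: str = "ancestral",
    sample_type: str = "maternal_stool",
    species_label: str = "species",
    lineage_id: str = "L0",
) -> Genome:
    """Random genome with the exact requested base composition.

    The base multiset is fixed (round(length * gc_content) G+C, split evenly
    between G and C, likewise A/T) and shuffled, so the realized GC fraction
    deviates from the request by less than one base, at any length.
    """
    if length < 1000:
        raise ParameterError(f"length must be >= 1000, got {length}")
    if not 0.0 < gc_content < 1.0:
        raise ParameterError(f"gc_content must be in (0, 1), got {gc_content}")
    rng = rng_for(seed, "ancestral", genome_id)
    n_gc = int(round(length * gc_content))
    n_g, n_c = n_gc // 2, n_gc - n_gc // 2
    n_at = length - n_gc
    n_a, n_t = n_at // 2, n_at - n_at // 2
    codes = np.repeat(np.array([0, 1, 2, 3], dtype=np.uint8), [n_a, n_c, n_g, n_t])
    rng.shuffle(codes)
    return Genome(genome_id, decode_sequence(codes), individual_id, sample_type, species_label, lineage_id)


def derive_strain(
    parent: Genome,
    n_snps: int,
    seed: int,
    *,
    genome_id: str | None = None,
    individual_id: str | None = None,
    sample_type: str | None = None,
) -> tuple[Genome, list[int]]:
    """Child genome exactly ``n_snps`` substitutions from ``parent``.

    Positions are drawn without replacement and each substituted base
    differs from the original, so Hamming(parent, child) == n_snps.
    Returns the child (same lineage_id as the parent) and the sorted
    0-based variant positions.
    """
    length = len(parent)
    if n_snps < 0 or n_snps > length:
        raise ParameterError(f"n_snps must be in [0, {length}], got {n_snps}")
    rng = rng_for(seed, "derive", parent.genome_id)
    codes = parent.codes.copy()
    positions = np.sort(rng.choice(length, size=n_snps, replace=False)).astype(np.int64)
    # shift by 1..3 mod 4 guarantees the new base differs from the old
    shifts = rng.integers(1, 4, size=n_snps).astype(np.uint8)
    codes[positions] = (codes[positions] + shifts) % 4
    child = Genome(
        genome_id if genome_id is not None else f"{parent.genome_id}+{n_snps}snp",
        decode_sequence(codes),
        individual_id if individual_id is not None else parent.individual_id,
        sample_type if sample_type is not None else parent.sample_type,
        parent.species_label,
        parent.lineage_id,
    )
    return child, [int(p) for p in positions]


# ----------------------------------------------------------------------
# cohort simulation
# ----------------------------------------------------------------------

def _draw_covariates(rng: np.random.Generator) -> dict[str, str]:
    """Joint covariate model: delivery mode follows labour onset, membrane
    rupture and antibiotics follow delivery mode; marginals roughly match a
    maternity cohort (about 60% vaginal births)."""
    onset = rng.choice(LABOUR_ONSET, p=[0.55, 0.27, 0.18])
    if onset == "pre_labour_CS":
        mode = "caesarean"
    else:
        mode = rng.choice(DELIVERY_MODES, p=[0.82, 0.18])
    if mode == "caesarean" and onset == "pre_labour_CS":
        rupture = "at_LSCS"
    else:
        rupture = rng.choice(["SROM", "ARM", "POM"], p=[0.55, 0.30, 0.15])
    abx = rng.choice(ANTIBIOTICS, p=[0.85, 0.15] if mode == "caesarean" else [0.25, 0.75])
    return {
        "delivery_mode": str(mode),
        "membrane_rupture": str(rupture),
        "labour_onset": str(onset),
        "antibiotics_in_labour": str(abx),
    }


def transmission_probability(config: CohortConfig, covariates: Mapping[str, str]) -> float:
    """P(transmit | covariates): average of the per-covariate effect-table
    probabilities, falling back to the flat transmitted fraction."""
    if not config.covariate_effects:
        return config.transmitted_fraction
    probs = [
        table[covariates[cov]]
        for cov, table in config.covariate_effects.items()
        if covariates.get(cov) in table
    ]
    return float(np.mean(probs)) if probs else config.transmitted_fraction


def _poisson_branch(rng: np.random.Generator, mean: float, length: int) -> int:
    return int(min(max(1, rng.poisson(mean)), length))


def simulate_cohort(config: CohortConfig | None = None, **overrides) -> CohortTruth:
    """Simulate a dyad cohort with ground-truth transmission labels.

    For each (dyad, species): the mother carries a lineage founded a few
    thousand SNPs from the species ancestor; if transmission occurs
    (Bernoulli with covariate-conditioned probability) the infant's primary
    strain is derived from the mother's primary strain at a uniform draw
    from the transmitted SNP range, otherwise the infant founds an
    independent lineage. Additional per-individual strains (micro-diversity)
    are Poisson-branch siblings of the primary strain. Deterministic given
    ``config.seed``.
    """
    if config is None:
        config = CohortConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    seed = config.seed
    half_lo = max(1, config.distinct_snp_range[0] // 2)
    half_hi = max(half_lo, config.distinct_snp_range[1] // 2)

    # ancestors differ across species because the shuffle RNG is keyed by id
    ancestors: dict[str, Genome] = {
        sp: generate_ancestral_genome(
            config.genome_length,
            config.gc_content,
            seed,
            genome_id=f"{sp}_ancestor",
            species_label=sp,
            lineage_id=f"{sp}_L0000",
        )
        for sp in config.species
    }

    dyads: list[Dyad] = []
    strains: list[Genome] = []
    transmissions: list[TrueTransmission] = []
    abundances: dict[str, dict[str, float]] = {}
    lineage_counter = {sp: 0 for sp in config.species}

    def new_lineage(sp: str) -> str:
        lineage_counter[sp] += 1
        return f"{sp}_L{lineage_counter[sp]:04d}"

    def add_individual_strains(primary: Genome, rng_key: tuple, count: int) -> None:
        strains.append(primary)
        rng = rng_for(seed, *rng_key)
        for k in range(1, count):
            n = _poisson_branch(rng, config.microdiversity_mean_snps, len(primary))
            sib, _ = derive_strain(
                primary, n, int(rng.integers(0, 2**31)),
                genome_id=f"{primary.genome_id[:-1]}{k}",
            )
            strains.append(sib)

    for d in range(config.n_dyads):
        dyad_id = f"D{d:03d}"
        mother_id, infant_id = f"M{d:03d}", f"I{d:03d}"
        cov_rng = rng_for(seed, "covariates", d)
        covariates = _draw_covariates(cov_rng)
        dyads.append(Dyad(dyad_id, mother_id, infant_id, covariates))
        p_transmit = transmission_probability(config, covariates)
        event_rng = rng_for(seed, "events", d)

        for sp in config.species:
            anc = ancestors[sp]
            lin = new_lineage(sp)
            founder_rng = rng_for(seed, "founder", d, sp)
            n_founder = int(founder_rng.integers(half_lo, half_hi + 1))
            mother_primary, _ = derive_strain(
                anc, n_founder, int(founder_rng.integers(0, 2**31)),
                genome_id=f"{mother_id}_{sp}_s0", individual_id=mother_id,
                sample_type="maternal_stool",
            )
            mother_primary.lineage_id = lin
            add_individual_strains(mother_primary, ("micro", d, sp, "M"), config.strains_per_individual)

            transmitted = bool(event_rng.random() < p_transmit)
            if transmitted:
                lo, hi = config.transmitted_snp_range
                n_trans = int(event_rng.integers(lo, hi + 1))
                infant_primary, _ = derive_strain(
                    mother_primary, n_trans, int(event_rng.integers(0, 2**31)),
                    genome_id=f"{infant_id}_{sp}_s0", individual_id=infant_id,
                    sample_type="infant_stool",
                )
                transmissions.append(
                    TrueTransmission(dyad_id, sp, mother_primary.genome_id,
                                     infant_primary.genome_id, n_trans, lin)
                )
            else:
                ilin = new_lineage(sp)
                n_ifounder = int(founder_rng.integers(half_lo, half_hi + 1))
                infant_primary, _ = derive_strain(
                    anc, n_ifounder, int(founder_rng.integers(0, 2**31)),
                    genome_id=f"{infant_id}_{sp}_s0", individual_id=infant_id,
                    sample_type="infant_stool",
                )
                infant_primary.lineage_id = ilin
            add_individual_strains(infant_primary, ("micro", d, sp, "I"), config.strains_per_individual)

        # per-sample genus-level relative abundances (Dirichlet shares of a
        # sample-type-specific genus fraction; remainder is other taxa)
        ab_rng = rng_for(seed, "abundance", d)
        for indiv, genus_frac in ((mother_id, config.genus_fraction_mother),
                                  (infant_id, config.genus_fraction_infant)):
            shares = ab_rng.dirichlet(np.ones(len(config.species)))
            abundances[CohortTruth.stool_sample(indiv)] = {
                sp: float(genus_frac * s) for sp, s in zip(config.species, shares)
            }

    return CohortTruth(dyads, strains, transmissions, abundances, config)


# ----------------------------------------------------------------------
# reads
# ----------------------------------------------------------------------

def simulate_reads(
    composition: Mapping[Genome, float],
    total_reads: int,
    read_length: int = 150,
    error_rate: float = 0.0,
    seed: int = 0,
    *,
    source_sample: str = "sample",
) -> ReadSet:
    """Single-end shotgun reads from a genome mixture.

    Read counts per genome are multinomial with weights abundance x genome
    length; start positions are uniform; substitution errors are i.i.d. per
    base at ``error_rate``. Qualities are flat Phred 40 ('I').
    """
    if total_reads < 0:
        raise ParameterError("total_reads must be >= 0")
    if not 0.0 <= error_rate <= 0.1:
        raise ParameterError("error_rate must be in [0, 0.1]")
    genomes = sorted(composition.keys(), key=lambda g: g.genome_id)
    if any(composition[g] < 0 for g in genomes):
        raise ParameterError("abundances must be >= 0")
    if total_reads == 0:
        return ReadSet([], source_sample, {})
    if not genomes or all(composition[g] == 0 for g in genomes):
        raise ParameterError("empty composition with total_reads > 0")
    for g in genomes:
        if len(g) < read_length:
            raise ParameterError(f"genome {g.genome_id} shorter than read_length")

    rng = rng_for(seed, "reads", source_sample)
    weights = np.array([composition[g] * len(g) for g in genomes], dtype=float)
    probs = weights / weights.sum()
    counts = rng.multinomial(total_reads, probs)
    truth = {g.genome_id: float(p) for g, p in zip(genomes, probs)}

    reads: list[tuple[str, str, str]] = []
    qual = "I" * read_length
    r = 0
    for g, n in zip(genomes, counts):
        if n == 0:
            continue
        codes = g.codes
        starts = rng.integers(0, len(g) - read_length + 1, size=n)
        for s in starts:
            frag = codes[s : s + read_length].copy()
            if error_rate > 0:
                err = rng.random(read_length) < error_rate
                n_err = int(err.sum())
                if n_err:
                    frag[err] = (frag[err] + rng.integers(1, 4, size=n_err).astype(np.uint8)) % 4
            reads.append((f"{source_sample}_r{r:07d}", decode_sequence(frag), qual))
            r += 1
    return ReadSet(reads, source_sample, truth)


# ----------------------------------------------------------------------
# sample QC
# ----------------------------------------------------------------------

def qc_filter_samples(
    sample_read_counts: Mapping[str, int],
    min_reads: int = 100_000,
    dyad_pairs: Iterable[tuple[str, str]] | None = None,
) -> set[str]:
    """Sample QC: drop samples under the read-count floor, then singletons.

    A sample is retained iff its post-filtering read count is >= ``min_reads``
    (default 100,000). If ``dyad_pairs`` (mother_sample, infant_sample) is
    given, samples whose dyad partner was not retained are additionally
    dropped, so no singleton dyad members survive.
    """
    if any(c < 0 for c in sample_read_counts.values()):
        raise ParameterError("read counts must be >= 0")
    retained = {s for s, c in sample_read_counts.items() if c >= min_reads}
    if dyad_pairs is not None:
        paired: set[str] = set()
        for mother, infant in dyad_pairs:
            if mother in retained and infant in retained:
                paired.update((mother, infant))
        retained &= paired
    return retained
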