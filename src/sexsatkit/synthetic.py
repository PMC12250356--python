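"""Synthetic read libraries, satDNA catalogs and genotype matrices.

The generator reproduces the statistical structure the downstream analyses
assume, with a ground-truth ledger for recovery tests:

* satDNA families live as head-to-tail tandem arrays built from a random
  consensus monomer and its substitution variants; per-library copy numbers
  follow a sex-bias multiplier (a Y-accumulated family has, e.g., a 3x
  multiplier in the male library), and designated haplotypes can be made
  exclusive to one library, emulating variants confined to a
  non-recombining sex-chromosome region;
* reads are uniform random substrings of those arrays (random strand), so
  monomer phase in a read is arbitrary, mixed with i.i.d. uniform random
  background sequence — no sequencing-error or quality model;
* genotype matrices hold i.i.d. null loci (each individual heterozygous
  with probability h) plus planted, perfectly sex-linked XY/ZW loci.

All randomness flows from the seeds passed in; fixed seeds give
byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abundance import reverse_complement
from .io import MISSING

BASES = np.array(list("ACGT"))


@dataclass
class SatFamilySpec:
    """Blueprint for one synthetic satDNA family.

    ``sex_bias`` maps each library label to a copy-number multiplier;
    ``exclusive_haplotypes`` maps a library label to the number of
    haplotypes that exist only in that library's arrays. The family's
    share of a library's reads is its share of the genome,
    ``array_copies * multiplier * rul / genome_size`` (genome size is a
    parameter of :func:`simulate_libraries`), as expected under uniform
    low-coverage sequencing.
    """

    family_id: str
    rul: int
    n_variants: int = 1
    mutation_rate: float = 0.05
    array_copies_per_genome: int = 200
    sex_bias: dict[str, float] = field(default_factory=dict)
    exclusive_haplotypes: dict[str, int] = field(default_factory=dict)
    #: ceiling on any haplotype's divergence from the consensus; variants
    #: beyond family-level similarity would not be monomers of this satDNA
    max_divergence: float = 0.15

    def __post_init__(self) -> None:
        if self.rul < 10:
            raise ValueError("repeat unit length must be >= 10 bp")
        if not 0.0 <= self.mutation_rate <= 0.3:
            raise ValueError("mutation_rate must lie in [0, 0.3]")
        if self.n_variants < 1:
            raise ValueError("need at least one variant")
        if not self.sex_bias:
            raise ValueError("sex_bias must name at least one library")
        if any(m <= 0 for m in self.sex_bias.values()):
            raise ValueError("sex-bias multipliers must be positive")
        for lib in self.exclusive_haplotypes:
            if lib not in self.sex_bias:
                raise ValueError(f"exclusive library {lib!r} not in sex_bias")
        if not 0.0 < self.max_divergence <= 0.3:
            raise ValueError("max_divergence must lie in (0, 0.3]")


@dataclass
class GenotypeSimSpec:
    n_loci: int
    n_males: int
    n_females: int
    het_prob: float = 0.5
    n_planted_xy: int = 0
    n_planted_zw: int = 0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.het_prob <= 1.0:
            raise ValueError("het_prob must lie in [0, 1]")
        if self.n_planted_xy + self.n_planted_zw > self.n_loci:
            raise ValueError("cannot plant more sex-linked loci than loci")
        if min(self.n_loci, self.n_males, self.n_females) < 0:
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")


@dataclass
class SatFamilyTruth:
    family_id: str
    consensus: str
    variants: list[str]
    exclusive: dict[str, list[str]]
    array_counts: dict[str, dict[str, int]]  # library -> haplotype -> copies
    sat_read_counts: dict[str, int]  # library -> reads drawn from the array


@dataclass
class SyntheticTruth:
    sat_families: list[SatFamilyTruth] = field(default_factory=list)
    slm_xy_loci: list[str] = field(default_factory=list)
    slm_zw_loci: list[str] = field(default_factory=list)
    slm_xy_indices: list[int] = field(default_factory=list)
    slm_zw_indices: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Sequence helpers


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[rng.integers(0, 3)]
    return "".join(out)


def _distinct_mutants(rng: np.random.Generator, consensus: str, rate: float,
                      count: int, taken: set[str], max_divergence: float) -> list[str]:
    max_subs = max(1, int(max_divergence * len(consensus)))
    out: list[str] = []
    for _ in range(count):
        for _attempt in range(1000):
            cand = _mutate(rng, consensus, max(rate, 1.0 / len(consensus)))
            n_subs = sum(a != b for a, b in zip(cand, consensus))
            if cand not in taken and 1 <= n_subs <= max_subs:
                taken.add(cand)
                out.append(cand)
                break
        else:
            raise RuntimeError("could not generate a distinct haplotype")
    return out


def _family_truth(spec: SatFamilySpec, rng: np.random.Generator) -> SatFamilyTruth:
    """Realize the family's haplotypes and per-library tandem arrays."""
    consensus = random_dna(rng, spec.rul)
    taken = {consensus}
    variants = [consensus] + _distinct_mutants(
        rng, consensus, spec.mutation_rate, spec.n_variants - 1, taken, spec.max_divergence
    )
    exclusive = {
        lib: _distinct_mutants(rng, consensus, spec.mutation_rate, count, taken,
                               spec.max_divergence)
        for lib, count in sorted(spec.exclusive_haplotypes.items())
    }
    array_counts: dict[str, dict[str, int]] = {}
    for lib in sorted(spec.sex_bias):
        units = list(variants) + exclusive.get(lib, [])
        copies_total = max(len(units), round(spec.array_copies_per_genome * spec.sex_bias[lib]))
        base, rem = divmod(copies_total, len(units))
        array_counts[lib] = {
            unit: base + (1 if k < rem else 0) for k, unit in enumerate(units)
        }
    return SatFamilyTruth(
        family_id=spec.family_id,
        consensus=consensus,
        variants=variants,
        exclusive=exclusive,
        array_counts=array_counts,
        sat_read_counts={},
    )


def _build_array(rng: np.random.Generator, counts: dict[str, int], min_length: int) -> str:
    """Lay the haplotypes down as contiguous homogenized blocks.

    Tandem arrays evolve under concerted evolution, so neighboring copies
    are near-identical: each haplotype occupies one contiguous run of
    copies and only the run order is randomized. A 150 bp read therefore
    almost always samples a single haplotype, as in real arrays.
    """
    blocks = [unit * c for unit, c in counts.items() if c > 0]
    rng.shuffle(blocks)
    array = "".join(blocks)
    while len(array) < min_length:  # tiny arrays are tiled to fit a read
        array += array
    return array


# ---------------------------------------------------------------------------
# Read simulation


def simulate_libraries(
    specs: list[SatFamilySpec],
    read_length: int = 150,
    n_reads_per_library: int = 2000,
    seed: int = 0,
    genome_size: int = 100_000,
) -> tuple[dict[str, list[str]], SyntheticTruth]:
    """Simulate per-library read sets holding several satDNA families at once.

    Every spec must address the same set of libraries. Each library
    receives reads from each family's tandem array in proportion to the
    array's share of the genome (``copies * multiplier * rul /
    genome_size``; uniform random start, random strand), and uniform
    random background sequence for the remainder — the sampling model of
    uniform low-coverage whole-genome sequencing.
    """
    if n_reads_per_library <= 0:
        raise ValueError("n_reads_per_library must be positive")
    if not specs:
        raise ValueError("need at least one family spec")
    libraries = sorted(specs[0].sex_bias)
    for spec in specs[1:]:
        if sorted(spec.sex_bias) != libraries:
            raise ValueError("all family specs must address the same libraries")
    for spec in specs:
        if read_length < spec.rul:
            raise ValueError(
                f"read length {read_length} shorter than repeat unit {spec.rul}"
            )
        if read_length < 2 * spec.rul:
            warnings.warn(
                f"read length {read_length} < 2x repeat unit {spec.rul}: "
                "full-monomer capture is not guaranteed for every read"
            )

    rng = np.random.default_rng(seed)
    truths = [_family_truth(spec, rng) for spec in specs]
    reads: dict[str, list[str]] = {}
    for lib in libraries:
        lib_reads: list[str] = []
        n_sat_per_family = []
        for spec in specs:
            genome_share = (
                spec.array_copies_per_genome * spec.sex_bias[lib] * spec.rul / genome_size
            )
            n_sat_per_family.append(round(n_reads_per_library * genome_share))
        total_sat = sum(n_sat_per_family)
        if total_sat > n_reads_per_library:
            warnings.warn(
                f"satDNA read demand ({total_sat}) exceeds library size in {lib}; scaling down"
            )
            n_sat_per_family = [
                int(n * n_reads_per_library / total_sat) for n in n_sat_per_family
            ]
            total_sat = sum(n_sat_per_family)
        for spec, truth, n_sat in zip(specs, truths, n_sat_per_family):
            array = _build_array(rng, truth.array_counts[lib], read_length + spec.rul)
            truth.sat_read_counts[lib] = n_sat
            starts = rng.integers(0, len(array) - read_length + 1, size=n_sat)
            flips = rng.random(n_sat) < 0.5
            for start, flip in zip(starts, flips):
                fragment = array[start:start + read_length]
                lib_reads.append(reverse_complement(fragment) if flip else fragment)
        for _ in range(n_reads_per_library - total_sat):
            lib_reads.append(random_dna(rng, read_length))
        order = rng.permutation(len(lib_reads))
        reads[lib] = [lib_reads[i] for i in order]
    return reads, SyntheticTruth(sat_families=truths)


def simulate_sat_reads(
    spec: SatFamilySpec,
    read_length: int = 150,
    n_reads_per_library: int = 2000,
    seed: int = 0,
    genome_size: int = 100_000,
) -> tuple[dict[str, list[str]], SyntheticTruth]:
    """Single-family convenience wrapper around :func:`simulate_libraries`."""
    return simulate_libraries([spec], read_length, n_reads_per_library, seed, genome_size)


# ---------------------------------------------------------------------------
# Genotype simulation


def simulate_genotypes(
    spec: GenotypeSimSpec,
) -> tuple[pd.DataFrame, dict[str, str], SyntheticTruth]:
    """Simulate a loci x individuals genotype matrix with planted SLMs.

    Null loci are i.i.d.: each individual is heterozygous (code 2) with
    probability ``het_prob``, otherwise homozygous 0 or 1 with equal
    probability. Planted XY loci are heterozygous in every male and
    homozygous in every female (ZW mirrored). Missingness is applied to
    null loci only, so planted loci stay recoverable by construction.
    """
    rng = np.random.default_rng(spec.seed)
    males = [f"M{i + 1:02d}" for i in range(spec.n_males)]
    females = [f"F{i + 1:02d}" for i in range(spec.n_females)]
    individuals = males + females
    L, N = spec.n_loci, len(individuals)
    if N == 0 or L == 0:
        raise ValueError("empty genotype design")

    hom = rng.choice([0, 1], size=(L, N))
    codes = np.where(rng.random((L, N)) < spec.het_prob, 2, hom)

    planted = rng.choice(L, size=spec.n_planted_xy + spec.n_planted_zw, replace=False)
    xy_idx = np.sort(planted[: spec.n_planted_xy])
    zw_idx = np.sort(planted[spec.n_planted_xy:])
    male_cols = np.arange(spec.n_males)
    female_cols = np.arange(spec.n_males, N)
    for i in xy_idx:
        codes[i, male_cols] = 2
        codes[i, female_cols] = rng.choice([0, 1], size=spec.n_females)
    for i in zw_idx:
        codes[i, female_cols] = 2
        codes[i, male_cols] = rng.choice([0, 1], size=spec.n_males)

    if spec.missing_rate > 0:
        null_rows = np.setdiff1d(np.arange(L), planted)
        mask = rng.random((null_rows.size, N)) < spec.missing_rate
        sub = codes[null_rows]
        sub[mask] = MISSING
        codes[null_rows] = sub

    loci = [f"L{i + 1:05d}" for i in range(L)]
    matrix = pd.DataFrame(codes, index=pd.Index(loci, name="locus"), columns=individuals)
    sexes = {ind: ("M" if ind in set(males) else "F") for ind in individuals}
    truth = SyntheticTruth(
        slm_xy_loci=[loci[i] for i in xy_idx],
        slm_zw_loci=[loci[i] for i in zw_idx],
        slm_xy_indices=[int(i) for i in xy_idx],
        slm_zw_indices=[int(i) for i in zw_idx],
    )
    return matrix, sexes, truth
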