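"""Input preparation for LD-based recombination-map inference.

The inference itself (two-locus likelihood optimization over a demographic
model) is an external tool's job; this module prepares its inputs:

* segmental-duplication SNP filtering (shared with the phasing workflow);
* pseudo-diploid construction on the X chromosome, pairing hemizygous male
  genotypes into artificial diploids so that diploid-only inference methods
  can use males;
* scaling of an effective-population-size history by 3/4 for the X (the X
  carries three chromosomes for every four autosomes under an equal sex
  ratio);
* combination of separately inferred pseudoautosomal (PAR) and
  non-pseudoautosomal X maps into one chromosome-wide map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from recmap.genmap import GeneticMap
from recmap.hotspots import IntervalSet
from recmap.phasing import filter_segdup_sites

DEFAULT_MUTATION_RATE = 4e-9  # per bp per generation
X_SCALING = 0.75


@dataclass
class PopSizeHistory:
    """Piecewise-constant effective-population-size trajectory.

    ``times`` are epoch start times in generations (strictly increasing from
    0); ``sizes`` are diploid effective sizes.  ``mutation_rate`` is the
    per-bp per-generation rate assumed alongside the history.
    """

    times: np.ndarray
    sizes: np.ndarray
    mutation_rate: float = DEFAULT_MUTATION_RATE

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.sizes = np.asarray(self.sizes, dtype=float)
        if len(self.times) != len(self.sizes):
            raise ValueError("times and sizes must have equal length")
        if len(self.times) == 0 or self.times[0] != 0:
            raise ValueError("history must start at time 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("epoch times must be strictly increasing")
        if np.any(self.sizes <= 0):
            raise ValueError("population sizes must be positive")

    @classmethod
    def read_tsv(cls, path: str, mutation_rate: float | None = None) -> "PopSizeHistory":
        """Read a two-column (time, size) TSV with a header line; an optional
        JSON sidecar ``<path>.json`` may supply the mutation rate."""
        times, sizes = [], []
        with open(path) as fh:
            next(fh)  # header
            for line in fh:
                if not line.strip():
                    continue
                t, n = line.split()[:2]
                times.append(float(t))
                sizes.append(float(n))
        if mutation_rate is None:
            try:
                with open(path + ".json") as fh:
                    mutation_rate = json.load(fh).get("mutation_rate", DEFAULT_MUTATION_RATE)
            except FileNotFoundError:
                mutation_rate = DEFAULT_MUTATION_RATE
        return cls(np.asarray(times), np.asarray(sizes), mutation_rate)

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("time_generations\tdiploid_size\n")
            for t, n in zip(self.times, self.sizes):
                fh.write(f"{t:.17g}\t{n:.17g}\n")
        with open(path + ".json", "w") as fh:
            json.dump({"mutation_rate": self.mutation_rate}, fh)


def scale_history(history: PopSizeHistory, factor: float = X_SCALING) -> PopSizeHistory:
    """Multiply every epoch's size by ``factor`` (default 0.75 for the X)."""
    if factor <= 0:
        raise ValueError("scaling factor must be positive")
    return PopSizeHistory(history.times.copy(), history.sizes * factor,
                          history.mutation_rate)


@dataclass(frozen=True)
class SamplePlan:
    """Chromosome accounting for one population's inference inputs.

    Autosomal inference uses two chromosomes per individual.  X inference
    uses two per female plus two per *pair* of males (each pseudo-diploid
    contributes two X chromosomes); an unpaired male is dropped.
    """

    population: str
    n_females: int
    n_males: int

    @property
    def n_autosomal_chromosomes(self) -> int:
        return 2 * (self.n_females + self.n_males)

    @property
    def n_x_chromosomes(self) -> int:
        return 2 * self.n_females + 2 * (self.n_males // 2)


def plan_samples(n_females: int, n_males: int, population: str = "") -> SamplePlan:
    """Derive autosomal and X chromosome counts from the sample sex makeup."""
    if n_females < 0 or n_males < 0:
        raise ValueError("sample counts must be non-negative")
    return SamplePlan(population, n_females, n_males)


def make_pseudodiploids(
    male_haplotypes: np.ndarray,
    male_ids: Sequence[str] | None = None,
    pairing_seed: int = 0,
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Pair hemizygous male X genotypes into unphased pseudo-diploids.

    ``male_haplotypes`` is ``(n_males, n_sites)`` with haploid calls 0/1 and
    -1 for missing.  Males are shuffled deterministically by
    ``pairing_seed`` and paired consecutively; an odd male is dropped.  Each
    pair's calls become one unphased diploid genotype per site, missing when
    either member is missing.  Pooled allele counts over the retained males
    are conserved, so frequency-based downstream inference is invariant to
    the pairing.

    Returns the ``(n_pairs, n_sites, 2)`` genotype array and the list of
    paired ids.
    """
    male_haplotypes = np.asarray(male_haplotypes)
    n_males = male_haplotypes.shape[0]
    if n_males < 2:
        raise ValueError("need at least 2 males to build pseudo-diploids")
    if male_ids is None:
        male_ids = [f"male{i}" for i in range(n_males)]
    rng = np.random.default_rng(pairing_seed)
    order = rng.permutation(n_males)
    n_pairs = n_males // 2
    genotypes = np.empty((n_pairs, male_haplotypes.shape[1], 2), dtype=np.int8)
    pairs: list[tuple[str, str]] = []
    for k in range(n_pairs):
        i, j = order[2 * k], order[2 * k + 1]
        a, b = male_haplotypes[i], male_haplotypes[j]
        missing = (a < 0) | (b < 0)
        genotypes[k, :, 0] = np.where(missing, -1, a)
        genotypes[k, :, 1] = np.where(missing, -1, b)
        pairs.append((male_ids[i], male_ids[j]))
    return genotypes, pairs


def combine_par_nonpar(
    map_par: GeneticMap | None, map_nonpar: GeneticMap, par_boundary_bp: int
) -> GeneticMap:
    """Concatenate separately inferred PAR and non-PAR X maps.

    The PAR (before ``par_boundary_bp``, 1-based) recombines in both sexes
    and is inferred like an autosome; the non-PAR map's genetic positions
    are offset by the PAR's total length so the combined cumulative map is
    continuous.  Total genetic length is conserved:
    ``total(combined) = total(PAR) + total(non-PAR)``.
    """
    if map_par is None or map_par.n_markers == 0:
        return map_nonpar
    if np.any(map_par.positions >= par_boundary_bp):
        raise ValueError("PAR map has markers at or beyond the PAR boundary")
    if np.any(map_nonpar.positions < par_boundary_bp):
        raise ValueError("non-PAR map has markers before the PAR boundary")
    par_cm = map_par.genetic_positions - map_par.genetic_positions[0]
    offset = par_cm[-1]
    nonpar_cm = (map_nonpar.genetic_positions - map_nonpar.genetic_positions[0]
                 + offset)
    return GeneticMap(
        map_nonpar.chromosome,
        np.concatenate([map_par.positions, map_nonpar.positions]),
        np.concatenate([par_cm, nonpar_cm]),
        map_nonpar.chromosome_length or map_par.chromosome_length,
    )


def filter_segdup_snps(
    positions: np.ndarray, chromosome: str, segdups: IntervalSet
) -> np.ndarray:
    """Positions (1-based) retained after removing SNPs inside segdups.

    Same half-open overlap rule as the phasing-panel filter; re-exposed here
    for the map-inference input path.
    """
    positions = np.asarray(positions)
    return positions[filter_segdup_sites(positions, chromosome, segdups)]
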