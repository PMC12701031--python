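"""Synthetic inputs with fully recorded ground truth for every pipeline stage.

Each generator is deterministic under a fixed seed and returns, alongside
its output, a :class:`SimTruth` record sufficient to compute the expected
result of the consuming analysis exactly: planted hotspot intervals and
intensities, planted lift perturbations (unmapped markers, cross-chromosome
moves, mirrored chromosomes), planted Mendelian violations, and planted
switch errors by class.

The simulations are deliberately minimal: marker grids are uniform, allele
frequencies are drawn from a flat spectrum, and no linkage disequilibrium is
generated — none of the scored logic depends on those features, only on
marker geometry, rates, het density, and the planted events themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from recmap.convert import UNMAPPED, LiftTable
from recmap.genmap import GeneticMap
from recmap.phasing import PhasedSample


@dataclass
class SimTruth:
    """Ground truth of one synthetic data set.

    Only the fields relevant to the generator that produced it are filled.
    Intervals are 0-based half-open; positions 1-based like marker input.
    """

    seed: int
    params: dict = field(default_factory=dict)
    # sim_map
    hotspot_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    hotspot_rates: list[float] = field(default_factory=list)
    background_rate: float | None = None
    # sim_lift
    unmapped_markers: list[tuple[str, int]] = field(default_factory=list)
    cross_chromosome_markers: list[tuple[str, int]] = field(default_factory=list)
    inverted_chromosomes: list[str] = field(default_factory=list)
    # sim_trio
    planted_missing: list[tuple[str, int]] = field(default_factory=list)
    planted_violations: list[int] = field(default_factory=list)
    # sim_phased_errors
    single_switch_positions: list[int] = field(default_factory=list)
    double_switch_positions: list[int] = field(default_factory=list)


def sim_map(
    chrom_length: int,
    n_markers: int,
    background_rate: float,
    hotspots: Sequence[tuple[int, int, float]] = (),
    seed: int = 0,
    chromosome: str = "chr1",
) -> tuple[GeneticMap, SimTruth]:
    """Simulate a piecewise-constant map with planted hotspots.

    ``hotspots`` is a list of ``(span_bp, n_markers, fold)``: each hotspot
    covers ``span_bp`` with ``n_markers`` evenly spaced markers whose
    internal segments run at ``fold × background_rate``; placements are
    uniform at random, non-overlapping (an unplaceable configuration raises).
    Background markers are drawn uniformly over the chromosome, excluding
    hotspot interiors so planted segment structure is exact, and the
    cumulative cM is built by integrating the segment rates from 0.
    """
    rng = np.random.default_rng(seed)
    for span, m, fold in hotspots:
        if span >= chrom_length:
            raise ValueError("hotspot span must be smaller than the chromosome")
        if m < 2 or fold <= 0:
            raise ValueError("hotspots need >= 2 markers and positive fold")

    # place hotspots without overlap (margin keeps them off the ends and
    # separated from each other so background segments stay at background rate)
    margin = 1000
    placed: list[tuple[int, int, int, float]] = []  # (start 1-based, span, m, fold)
    for span, m, fold in hotspots:
        for _attempt in range(1000):
            start = int(rng.integers(margin + 1, chrom_length - span - margin))
            if all(start + span + margin < s or s + sp + margin < start
                   for s, sp, _, _ in placed):
                placed.append((start, span, m, fold))
                break
        else:
            raise ValueError("could not place hotspots without overlap")

    bg = np.unique(rng.integers(1, chrom_length + 1, size=n_markers))
    for start, span, _, _ in placed:
        bg = bg[(bg < start - margin // 2) | (bg > start + span + margin // 2)]

    positions = list(bg)
    hot_rate_at: dict[int, float] = {}  # left-marker position -> rate
    truth = SimTruth(seed=seed, params={
        "chrom_length": chrom_length, "n_markers": n_markers,
        "background_rate": background_rate, "hotspots": list(hotspots),
    }, background_rate=background_rate)
    for start, span, m, fold in placed:
        marks = np.round(np.linspace(start, start + span, m)).astype(int)
        positions.extend(int(p) for p in marks)
        for p in marks[:-1]:
            hot_rate_at[int(p)] = fold * background_rate
        truth.hotspot_intervals.append((chromosome, start - 1, start + span - 1))
        truth.hotspot_rates.append(fold * background_rate)

    pos = np.unique(np.asarray(positions, dtype=np.int64))
    rates = np.full(len(pos) - 1, background_rate)
    for i, p in enumerate(pos[:-1]):
        if int(p) in hot_rate_at:
            rates[i] = hot_rate_at[int(p)]
    cm = np.concatenate([[0.0], np.cumsum(rates * np.diff(pos) / 1e6)])
    gmap = GeneticMap(chromosome, pos, cm, chromosome_length=chrom_length)
    return gmap, truth


def sim_lift(
    maps: Mapping[str, GeneticMap],
    chrom_lengths: Mapping[str, int],
    shift_bp: int = 0,
    invert_chroms: Sequence[str] = (),
    frac_unmapped: float = 0.0,
    frac_cross: float = 0.0,
    seed: int = 0,
) -> tuple[LiftTable, SimTruth]:
    """Build a coordinate-lift table with planted perturbations.

    Chromosomes in ``invert_chroms`` get mirrored coordinates
    (``L − p + 1``); all others are shifted by ``shift_bp``.  Exactly
    ``round(frac_unmapped · n)`` markers per chromosome are marked unmapped
    and ``round(frac_cross · n)`` moved to a phantom chromosome; all
    perturbations are recorded in the truth.
    """
    if not 0 <= frac_unmapped <= 1 or not 0 <= frac_cross <= 1:
        raise ValueError("fractions must be in [0, 1]")
    rng = np.random.default_rng(seed)
    inverted = {str(c) for c in invert_chroms}
    table = LiftTable()
    truth = SimTruth(seed=seed, params={
        "shift_bp": shift_bp, "frac_unmapped": frac_unmapped,
        "frac_cross": frac_cross,
    }, inverted_chromosomes=sorted(inverted))
    for chrom, gmap in maps.items():
        n = gmap.n_markers
        n_unmapped = round(frac_unmapped * n)
        n_cross = round(frac_cross * n)
        perturbed = rng.choice(n, size=n_unmapped + n_cross, replace=False)
        unmapped_idx = set(perturbed[:n_unmapped].tolist())
        cross_idx = set(perturbed[n_unmapped:].tolist())
        length = int(chrom_lengths[chrom])
        for i, pos in enumerate(map(int, gmap.positions)):
            if i in unmapped_idx:
                table.add(chrom, pos, UNMAPPED, 0)
                truth.unmapped_markers.append((chrom, pos))
                continue
            new_pos = length - pos + 1 if str(chrom) in inverted else pos + shift_bp
            if i in cross_idx:
                table.add(chrom, pos, f"{chrom}_decoy", new_pos)
                truth.cross_chromosome_markers.append((chrom, pos))
            else:
                table.add(chrom, pos, chrom, new_pos)
    return table, truth


@dataclass
class TrioData:
    """Simulated trio genotypes plus the child's true haplotypes."""

    chromosome: str
    positions: np.ndarray
    child: np.ndarray   # (n_sites, 2), column 0 paternal, 1 maternal
    mother: np.ndarray
    father: np.ndarray
    child_paternal: np.ndarray  # true transmitted haplotypes
    child_maternal: np.ndarray


def sim_trio(
    n_sites: int,
    freq_range: tuple[float, float] = (0.05, 0.5),
    missing_rate: float = 0.0,
    mendel_error_rate: float = 0.0,
    seed: int = 0,
    chromosome: str = "chr1",
    spacing_bp: int = 1000,
) -> tuple[TrioData, SimTruth]:
    """Simulate a trio obeying Mendelian transmission, with planted defects.

    Per-site alternate-allele frequencies are uniform on ``freq_range``;
    parental haplotypes are independent Bernoulli draws and the child
    inherits one haplotype from each parent.  ``missing_rate`` knocks out
    individual genotypes at random; ``mendel_error_rate`` plants guaranteed
    non-Mendelian configurations (both parents 0/0, child 0/1).  Sites are
    evenly spaced ``spacing_bp`` apart.
    """
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(*freq_range, size=n_sites)
    haps = (rng.random((4, n_sites)) < freqs).astype(np.int8)  # m1 m2 f1 f2
    m1, m2, f1, f2 = haps
    positions = np.arange(1, n_sites + 1, dtype=np.int64) * spacing_bp

    mother = np.stack([m1, m2], axis=1)
    father = np.stack([f1, f2], axis=1)
    child = np.stack([f1.copy(), m1.copy()], axis=1)  # paternal, maternal
    truth = SimTruth(seed=seed, params={
        "n_sites": n_sites, "missing_rate": missing_rate,
        "mendel_error_rate": mendel_error_rate,
    })

    if mendel_error_rate > 0:
        bad = np.flatnonzero(rng.random(n_sites) < mendel_error_rate)
        for i in bad:
            mother[i] = (0, 0)
            father[i] = (0, 0)
            child[i] = (0, 1)
        truth.planted_violations = [int(positions[i]) for i in bad]

    if missing_rate > 0:
        names = ("child", "mother", "father")
        for name, arr in zip(names, (child, mother, father)):
            miss = np.flatnonzero(rng.random(n_sites) < missing_rate)
            arr[miss] = (-1, -1)
            truth.planted_missing.extend((name, int(positions[i])) for i in miss)

    data = TrioData(chromosome, positions, child, mother, father,
                    child_paternal=f1, child_maternal=m1)
    return data, truth


def sim_phased_errors(
    positions: np.ndarray,
    paternal: np.ndarray,
    maternal: np.ndarray,
    n_single: int = 0,
    n_double: int = 0,
    min_separation: int = 3,
    seed: int = 0,
    chromosome: str = "chr1",
) -> tuple[PhasedSample, SimTruth]:
    """Derive a test phase from true haplotypes with planted switch errors.

    A *single switch* is a crossover of the haplotype labeling at one
    heterozygous site (labeling flips from there onward → one switch
    indicator).  A *double switch* flips the phase of one isolated
    heterozygote (→ two adjacent switch indicators).  Events are placed at
    heterozygous sites separated by at least ``min_separation`` hets, away
    from the ends, so each event produces an isolated indicator run of the
    intended length; raises if the haplotypes carry too few hets to place
    everything.
    """
    rng = np.random.default_rng(seed)
    paternal = np.asarray(paternal, dtype=np.int8)
    maternal = np.asarray(maternal, dtype=np.int8)
    het = np.flatnonzero(paternal != maternal)
    n_het = len(het)
    candidates = [i for i in range(2, n_het - 2)]
    rng.shuffle(candidates)
    chosen: list[int] = []
    for idx in candidates:
        if len(chosen) == n_single + n_double:
            break
        if all(abs(idx - c) >= min_separation for c in chosen):
            chosen.append(idx)
    if len(chosen) < n_single + n_double:
        raise ValueError(
            f"cannot place {n_single + n_double} events on {n_het} hets "
            f"with separation {min_separation}"
        )
    singles = sorted(chosen[:n_single])
    doubles = sorted(chosen[n_single:])

    # orientation of the test labeling at each het: 0 = hap1 carries paternal
    orient = np.zeros(n_het, dtype=np.int8)
    for idx in singles:
        orient[idx:] ^= 1
    for idx in doubles:
        orient[idx] ^= 1

    hap1 = paternal.copy()
    hap2 = maternal.copy()
    flip = het[orient == 1]
    hap1[flip], hap2[flip] = maternal[flip], paternal[flip]

    truth = SimTruth(seed=seed, params={
        "n_single": n_single, "n_double": n_double,
        "min_separation": min_separation,
    },
        single_switch_positions=[int(positions[het[i]]) for i in singles],
        double_switch_positions=[int(positions[het[i]]) for i in doubles],
    )
    sample = PhasedSample(chromosome, np.asarray(positions, dtype=np.int64),
                          hap1, hap2)
    return sample, truth
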