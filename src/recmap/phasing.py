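"""Trio-derived truth phase and switch-error scoring of phased samples.

A child's heterozygous genotypes can often be phased exactly from its
parents: if at least one parent is homozygous, Mendelian segregation forces
which allele is paternal and which maternal.  Such trio-resolved sites form
a truth set against which the output of a statistical phaser is scored with
the switch-error taxonomy: a *switch error* is a flip of the parental
assignment between consecutive truth-phased heterozygotes; isolated flips
are *single switches*; two adjacent switch errors are *paired* and form a
*double switch* — the signature of one mis-phased (or mis-genotyped) site
rather than a true long-range phasing break.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from recmap.hotspots import IntervalSet

logger = logging.getLogger(__name__)

MISSING = -1


class PhaseStatus(str, Enum):
    RESOLVED = "resolved"          # child het, phase forced by Mendelian rules
    UNDETERMINED = "undetermined"  # child het, both parents het
    DISCARDED = "discarded"        # missing data or non-Mendelian configuration
    HOMOZYGOUS = "homozygous"      # child homozygous: carried, never scored


@dataclass(frozen=True)
class TrioSite:
    """One biallelic site of a trio with its phase resolution.

    Genotypes are unordered allele pairs (0/1; -1 for missing).  When
    ``status == RESOLVED``, ``paternal``/``maternal`` give the transmitted
    alleles.
    """

    chromosome: str
    position: int
    child: tuple[int, int]
    mother: tuple[int, int]
    father: tuple[int, int]
    status: PhaseStatus
    paternal: int | None = None
    maternal: int | None = None


def _can_transmit(genotype: tuple[int, int], allele: int) -> bool:
    return allele in genotype


def mendelian_phase(
    chromosome: str,
    positions: Sequence[int],
    child: np.ndarray,
    mother: np.ndarray,
    father: np.ndarray,
) -> list[TrioSite]:
    """Resolve the child's phase at every site from Mendelian segregation.

    ``child``/``mother``/``father`` are ``(n_sites, 2)`` allele arrays.
    A child heterozygote is RESOLVED when exactly one assignment of its two
    alleles to the parents is Mendelian-consistent, UNDETERMINED when both
    are (both parents heterozygous), and DISCARDED when neither is
    (non-Mendelian) or any trio member has missing data.  Child homozygotes
    are carried as HOMOZYGOUS (or DISCARDED on missingness/inconsistency)
    but never scored.
    """
    sites: list[TrioSite] = []
    for i, pos in enumerate(positions):
        c = (int(child[i, 0]), int(child[i, 1]))
        m = (int(mother[i, 0]), int(mother[i, 1]))
        f = (int(father[i, 0]), int(father[i, 1]))
        if MISSING in c or MISSING in m or MISSING in f:
            sites.append(TrioSite(chromosome, pos, c, m, f, PhaseStatus.DISCARDED))
            continue
        if c[0] == c[1]:
            a = c[0]
            status = (PhaseStatus.HOMOZYGOUS
                      if _can_transmit(f, a) and _can_transmit(m, a)
                      else PhaseStatus.DISCARDED)
            sites.append(TrioSite(chromosome, pos, c, m, f, status))
            continue
        # child het: which parental assignments are consistent?
        pat1 = _can_transmit(f, 1) and _can_transmit(m, 0)  # paternal=1, maternal=0
        pat0 = _can_transmit(f, 0) and _can_transmit(m, 1)  # paternal=0, maternal=1
        if pat1 and pat0:
            sites.append(TrioSite(chromosome, pos, c, m, f, PhaseStatus.UNDETERMINED))
        elif pat1:
            sites.append(TrioSite(chromosome, pos, c, m, f, PhaseStatus.RESOLVED,
                                  paternal=1, maternal=0))
        elif pat0:
            sites.append(TrioSite(chromosome, pos, c, m, f, PhaseStatus.RESOLVED,
                                  paternal=0, maternal=1))
        else:
            sites.append(TrioSite(chromosome, pos, c, m, f, PhaseStatus.DISCARDED))
    return sites


def truth_sites_from_haplotypes(
    chromosome: str,
    positions: Sequence[int],
    paternal: np.ndarray,
    maternal: np.ndarray,
) -> list[TrioSite]:
    """Build a fully resolved truth set from known haplotypes.

    Used when the true phase is available directly (simulated children);
    every heterozygote is RESOLVED, homozygotes are carried unscored.
    """
    sites = []
    for pos, p, m in zip(positions, paternal, maternal):
        p, m = int(p), int(m)
        geno = (p, m)
        if p == m:
            sites.append(TrioSite(chromosome, int(pos), geno, (m, m), (p, p),
                                  PhaseStatus.HOMOZYGOUS))
        else:
            sites.append(TrioSite(chromosome, int(pos), geno, (m, m), (p, p),
                                  PhaseStatus.RESOLVED, paternal=p, maternal=m))
    return sites


@dataclass
class PhasedSample:
    """One sample's phased haplotypes at a set of biallelic sites."""

    chromosome: str
    positions: np.ndarray
    hap1: np.ndarray
    hap2: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.hap1 = np.asarray(self.hap1, dtype=np.int8)
        self.hap2 = np.asarray(self.hap2, dtype=np.int8)


@dataclass
class SwitchErrorReport:
    """Switch-error accounting for one phased sample against a trio truth.

    Invariants: ``n_single_switches + n_paired_switches == n_switch_errors``;
    each double switch consumes exactly two paired switch errors;
    ``switch_error_rate = n_switch_errors / n_phased_hets``;
    ``phase_error_rate = (n_single_switches + n_double_switches) /
    n_phased_hets`` — the phase error rate counts each double switch (one
    wrongly phased site) once instead of twice.
    """

    n_phased_hets: int
    n_switch_errors: int
    n_single_switches: int
    n_paired_switches: int
    n_double_switches: int
    n_truth_only: int = 0
    run_length_histogram: dict[int, int] = field(default_factory=dict)
    switch_positions: list[int] = field(default_factory=list)

    @property
    def switch_error_rate(self) -> float:
        return self.n_switch_errors / self.n_phased_hets

    @property
    def phase_error_rate(self) -> float:
        return (self.n_single_switches + self.n_double_switches) / self.n_phased_hets

    def to_dict(self) -> dict:
        return {
            "n_phased_hets": self.n_phased_hets,
            "n_switch_errors": self.n_switch_errors,
            "n_single_switches": self.n_single_switches,
            "n_paired_switches": self.n_paired_switches,
            "n_double_switches": self.n_double_switches,
            "switch_error_rate": self.switch_error_rate,
            "phase_error_rate": self.phase_error_rate,
            "n_truth_only": self.n_truth_only,
            "run_length_histogram": {str(k): v for k, v in
                                     sorted(self.run_length_histogram.items())},
        }


def decompose_switch_runs(indicators: np.ndarray) -> tuple[int, int, int, dict[int, int]]:
    """Decompose a boolean switch-indicator sequence into error classes.

    Maximal runs of consecutive switch indicators are classified: a run of
    length 1 is a single switch; a run of length k ≥ 2 contributes
    ``k // 2`` double switches (each consuming two paired switch errors) and
    ``k % 2`` single switches.  Returns (singles, paired, doubles,
    run-length histogram).
    """
    singles = paired = doubles = 0
    hist: dict[int, int] = {}
    k = 0
    for flag in np.append(indicators, False):
        if flag:
            k += 1
            continue
        if k:
            hist[k] = hist.get(k, 0) + 1
            if k == 1:
                singles += 1
            else:
                doubles += k // 2
                paired += 2 * (k // 2)
                singles += k % 2
            k = 0
    return singles, paired, doubles, hist


def rates_from_counts(n_phased_hets: int, n_switch_errors: int,
                      n_single_plus_double: int) -> tuple[float, float]:
    """Switch-error and phase-error rates from summary counts.

    The denominators are the number of Mendelian-phased heterozygotes.
    """
    if n_phased_hets <= 0:
        raise ValueError("n_phased_hets must be positive")
    return n_switch_errors / n_phased_hets, n_single_plus_double / n_phased_hets


def score_switches(
    truth_sites: Iterable[TrioSite], test: PhasedSample
) -> SwitchErrorReport:
    """Score a phased sample against trio-resolved heterozygotes.

    Only truth sites with RESOLVED status participate; UNDETERMINED and
    child-homozygous sites neither count nor interrupt adjacency.  The test
    sample's haplotype labeling is aligned to truth at the first scored het,
    so no switch is charged at the start.  For each subsequent consecutive
    pair of scored hets a switch indicator records whether the parental
    assignment flips relative to truth; indicator runs are decomposed by
    :func:`decompose_switch_runs`.  Truth hets absent from the test phase
    (or not heterozygous there) are dropped from scoring and counted in
    ``n_truth_only``.
    """
    resolved = [s for s in truth_sites if s.status is PhaseStatus.RESOLVED]
    test_index = {int(p): i for i, p in enumerate(test.positions)}

    orientations: list[int] = []
    scored_pos: list[int] = []
    n_truth_only = 0
    for site in resolved:
        i = test_index.get(site.position)
        if i is None:
            n_truth_only += 1
            continue
        h1, h2 = int(test.hap1[i]), int(test.hap2[i])
        if {h1, h2} != {0, 1}:
            n_truth_only += 1
            continue
        # orientation 0: hap1 carries the paternal allele
        orientations.append(0 if h1 == site.paternal else 1)
        scored_pos.append(site.position)

    n = len(orientations)
    if n < 2:
        raise ValueError(f"only {n} phased heterozygotes; need at least 2 to score")
    o = np.asarray(orientations)
    indicators = o[1:] != o[:-1]
    singles, paired, doubles, hist = decompose_switch_runs(indicators)
    return SwitchErrorReport(
        n_phased_hets=n,
        n_switch_errors=int(indicators.sum()),
        n_single_switches=singles,
        n_paired_switches=paired,
        n_double_switches=doubles,
        n_truth_only=n_truth_only,
        run_length_histogram=hist,
        switch_positions=[p for p, f in zip(scored_pos[1:], indicators) if f],
    )


# ---------------------------------------------------------------------------
# panel merging / site filtering
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Unphased biallelic genotypes for many samples at ordered sites.

    ``genotypes`` has shape ``(n_sites, n_samples, 2)`` with allele codes
    0/1 and -1 for missing.
    """

    chromosome: str
    positions: np.ndarray
    samples: list[str]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)

    @property
    def n_sites(self) -> int:
        return len(self.positions)


def filter_segdup_sites(
    positions: np.ndarray, chromosome: str, segdups: IntervalSet
) -> np.ndarray:
    """Mask of sites (1-based positions) falling *outside* all segdup intervals.

    Overlap is half-open on 0-based coordinates: a SNP at 1-based position p
    is removed when ``start <= p-1 < end`` for some interval — so a SNP at an
    interval's start is removed, one at its end coordinate is kept.
    """
    inside = segdups.contains_points(chromosome, np.asarray(positions) - 1)
    return ~inside


def merge_sample_into_panel(
    sample: GenotypeMatrix,
    panel: GenotypeMatrix,
    segdups: IntervalSet | None = None,
) -> GenotypeMatrix:
    """Merge one sample's genotypes into a reference panel for joint phasing.

    The site universe is the intersection of sample and panel positions,
    further restricted to sites outside segmental-duplication intervals
    (prone to genotyping artifacts).  Raises if no sites survive.
    """
    if sample.chromosome != panel.chromosome:
        raise ValueError("sample and panel are on different chromosomes")
    common, si, pi = np.intersect1d(sample.positions, panel.positions,
                                    return_indices=True)
    if len(common) == 0:
        raise ValueError("sample and panel share no sites")
    keep = np.ones(len(common), dtype=bool)
    if segdups is not None:
        keep = filter_segdup_sites(common, sample.chromosome, segdups)
    logger.info("merge: %d shared sites, %d after segdup filter",
                len(common), int(keep.sum()))
    if not keep.any():
        raise ValueError("no sites left after segmental-duplication filtering")
    genotypes = np.concatenate(
        [sample.genotypes[si][keep], panel.genotypes[pi][keep]], axis=1
    )
    return GenotypeMatrix(sample.chromosome, common[keep],
                          sample.samples + panel.samples, genotypes)
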