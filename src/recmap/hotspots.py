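"""Recombination hotspot detection and interval-overlap enrichment.

Hotspots are detected from a map's inter-SNP segments with a filtering
heuristic: segments whose rate is at least 10× the chromosome average are
flagged and merged, and merged runs bounded by more than two SNPs and
spanning less than 5 kb are called hotspots.  Overlap between interval sets
is quantified as the fraction of query intervals touching any target
interval (≥1 bp, half-open semantics), with significance from a permutation
null that re-places each query interval uniformly at random on its own
chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from recmap.genmap import GeneticMap, to_segments

HOTSPOT_FOLD = 10.0     # flag segments at >= this multiple of the chromosome mean
HOTSPOT_MIN_SNPS = 3    # "more than two SNPs": >= 3 bounding markers
HOTSPOT_MAX_SPAN = 5000  # bp, strict upper bound on merged-run span


@dataclass
class IntervalSet:
    """Genomic intervals with BED semantics (0-based, half-open), per chromosome.

    Intervals are kept sorted by start within each chromosome.
    """

    intervals: dict[str, np.ndarray] = field(default_factory=dict)
    label: str = ""

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, int, int]], label: str = ""
    ) -> "IntervalSet":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in records:
            if end <= start:
                raise ValueError(f"invalid interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((int(start), int(end)))
        ivs = {
            chrom: np.asarray(sorted(pairs), dtype=np.int64).reshape(-1, 2)
            for chrom, pairs in by_chrom.items()
        }
        return cls(ivs, label)

    @classmethod
    def read_bed(cls, path: str, label: str = "") -> "IntervalSet":
        records = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split()
                records.append((fields[0], int(fields[1]), int(fields[2])))
        return cls.from_records(records, label or path)

    def write_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.intervals):
                for start, end in self.intervals[chrom]:
                    fh.write(f"{chrom}\t{start}\t{end}\n")

    def __len__(self) -> int:
        return sum(len(v) for v in self.intervals.values())

    def __iter__(self):
        for chrom in sorted(self.intervals):
            for start, end in self.intervals[chrom]:
                yield chrom, int(start), int(end)

    def restrict(self, chromosomes: Iterable[str]) -> "IntervalSet":
        keep = set(chromosomes)
        return IntervalSet(
            {c: v.copy() for c, v in self.intervals.items() if c in keep}, self.label
        )

    def merged(self) -> "IntervalSet":
        """Union of overlapping or book-ended intervals."""
        out: dict[str, np.ndarray] = {}
        for chrom, iv in self.intervals.items():
            merged: list[list[int]] = []
            for start, end in iv:
                if merged and start <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], end)
                else:
                    merged.append([int(start), int(end)])
            out[chrom] = np.asarray(merged, dtype=np.int64).reshape(-1, 2)
        return IntervalSet(out, self.label)

    def contains_points(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Boolean mask: does each 0-based point fall inside an interval?"""
        positions = np.asarray(positions)
        if chrom not in self.intervals or len(self.intervals[chrom]) == 0:
            return np.zeros(len(positions), dtype=bool)
        iv = self.merged().intervals[chrom]
        idx = np.searchsorted(iv[:, 1], positions, side="right")
        inside = np.zeros(len(positions), dtype=bool)
        ok = idx < len(iv)
        inside[ok] = iv[idx[ok], 0] <= positions[ok]
        return inside


@dataclass
class OverlapResult:
    """Overlap of a query interval set with a target set, with optional null.

    ``fraction`` is the proportion of query intervals overlapping any target
    interval by ≥1 bp.  When a permutation null has been run,
    ``fold_enrichment = fraction / permutation_mean_fraction`` and
    ``empirical_p`` uses the add-one estimator, so it is never exactly 0.
    """

    n_query: int
    n_overlapping: int
    fraction: float
    permutation_mean_fraction: float | None = None
    fold_enrichment: float | None = None
    empirical_p: float | None = None
    n_permutations: int | None = None
    seed: int | None = None


def detect_hotspots(gmap: GeneticMap) -> IntervalSet:
    """Find hotspots in one chromosome's map with the filtering heuristic.

    The chromosome average rate is total cM divided by the physical span
    between first and last marker (the length-weighted mean of segment
    rates).  Segments at ≥10× that average are flagged; runs of consecutive
    flagged segments (sharing a marker) are merged; a merged run is a hotspot
    iff it is bounded by more than two SNPs (≥3 markers, i.e. ≥2 segments)
    and spans less than 5 kb.
    """
    if gmap.n_markers < 2 or gmap.total_cm <= 0:
        return IntervalSet(label=f"hotspots:{gmap.chromosome}")
    segments = to_segments(gmap)
    mean_rate = gmap.total_cm / (gmap.span_bp / 1e6)
    flagged = [s.rate >= HOTSPOT_FOLD * mean_rate for s in segments]

    records: list[tuple[str, int, int]] = []
    i = 0
    while i < len(segments):
        if not flagged[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(segments) and flagged[j + 1]:
            j += 1
        run = segments[i : j + 1]
        n_snps = run[-1].right_marker - run[0].left_marker + 1
        span = run[-1].end - run[0].start
        if n_snps >= HOTSPOT_MIN_SNPS and span < HOTSPOT_MAX_SPAN:
            records.append((gmap.chromosome, run[0].start, run[-1].end))
        i = j + 1
    return IntervalSet.from_records(records, label=f"hotspots:{gmap.chromosome}") \
        if records else IntervalSet(label=f"hotspots:{gmap.chromosome}")


def detect_hotspots_all(maps: Mapping[str, GeneticMap]) -> IntervalSet:
    """Hotspots for a whole map collection, pooled into one interval set."""
    records = [(c, s, e) for m in maps.values() for c, s, e in detect_hotspots(m)]
    return IntervalSet.from_records(records, "hotspots") if records else IntervalSet(label="hotspots")


def _count_overlapping(query: IntervalSet, target_merged: IntervalSet) -> int:
    n = 0
    for chrom, iv in query.intervals.items():
        tgt = target_merged.intervals.get(chrom)
        if tgt is None or len(tgt) == 0:
            continue
        # interval [s, e) overlaps some target iff the first target with
        # end > s exists and starts before e
        idx = np.searchsorted(tgt[:, 1], iv[:, 0], side="right")
        ok = idx < len(tgt)
        n += int(np.sum(ok & (np.where(ok, tgt[np.minimum(idx, len(tgt) - 1), 0], 0) < iv[:, 1])))
    return n


def overlap_fraction(
    query: IntervalSet,
    target: IntervalSet,
    chromosomes: Iterable[str] | None = None,
) -> OverlapResult:
    """Fraction of query intervals overlapping any target interval (≥1 bp).

    ``chromosomes`` optionally restricts both sets (e.g. to autosomes) before
    counting.  The measure is directional: swapping query and target changes
    the denominator and in general the fraction.
    """
    if chromosomes is not None:
        query = query.restrict(chromosomes)
        target = target.restrict(chromosomes)
    n_query = len(query)
    if n_query == 0:
        raise ValueError("empty query set: overlap fraction undefined")
    n_hit = _count_overlapping(query, target.merged())
    return OverlapResult(n_query, n_hit, n_hit / n_query)


def shuffle_null(
    query: IntervalSet,
    target: IntervalSet,
    chrom_sizes: Mapping[str, int],
    n_perm: int = 1000,
    seed: int = 0,
    chromosomes: Iterable[str] | None = None,
) -> OverlapResult:
    """Permutation null for interval overlap, shuffling within chromosomes.

    Each permutation independently re-places every query interval uniformly
    at random on its own chromosome (length preserved; placed intervals may
    overlap each other), mirroring a same-chromosome shuffle.  Reported are
    the observed overlap fraction, the mean fraction across permutations,
    their ratio (fold enrichment), and the add-one empirical p-value
    ``(1 + #{perm ≥ observed}) / (n_perm + 1)``.  Deterministic given seed.
    """
    if chromosomes is not None:
        query = query.restrict(chromosomes)
        target = target.restrict(chromosomes)
    observed = overlap_fraction(query, target)
    target_merged = target.merged()
    rng = np.random.default_rng(seed)

    chroms, lengths, sizes = [], [], []
    for chrom in sorted(query.intervals):
        iv = query.intervals[chrom]
        if chrom not in chrom_sizes:
            raise ValueError(f"no chromosome size for {chrom}")
        size = int(chrom_sizes[chrom])
        ln = (iv[:, 1] - iv[:, 0]).astype(np.int64)
        if np.any(ln > size):
            raise ValueError(f"query interval longer than chromosome {chrom}")
        chroms.append(chrom)
        lengths.append(ln)
        sizes.append(size)

    n_query = len(query)
    perm_fractions = np.empty(n_perm)
    for p in range(n_perm):
        hits = 0
        for chrom, ln, size in zip(chroms, lengths, sizes):
            tgt = target_merged.intervals.get(chrom)
            starts = rng.integers(0, size - ln + 1)  # inclusive high via size-ln
            if tgt is None or len(tgt) == 0:
                continue
            idx = np.searchsorted(tgt[:, 1], starts, side="right")
            ok = idx < len(tgt)
            hits += int(np.sum(ok & (np.where(ok, tgt[np.minimum(idx, len(tgt) - 1), 0], 0)
                                     < starts + ln)))
        perm_fractions[p] = hits / n_query

    mean_frac = float(perm_fractions.mean())
    return OverlapResult(
        n_query=n_query,
        n_overlapping=observed.n_overlapping,
        fraction=observed.fraction,
        permutation_mean_fraction=mean_frac,
        fold_enrichment=observed.fraction / mean_frac if mean_frac > 0 else float("inf"),
        empirical_p=(1 + int(np.sum(perm_fractions >= observed.fraction))) / (n_perm + 1),
        n_permutations=n_perm,
        seed=seed,
    )
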