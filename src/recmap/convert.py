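"""Transfer genetic maps between genome assemblies and repair the result.

Coordinate conversion itself is external (a liftOver run on single-base
records); this module consumes its output as a :class:`LiftTable` and applies
the cleanup a transferred map needs before it is usable:

1. optional inversion of the genetic axis on chromosomes whose orientation
   differs between assemblies (applied *before* the lift);
2. dropping markers that are unmapped or land on a different chromosome,
   then re-sorting by new physical position;
3. a single left-to-right scan that discards markers breaking monotonicity
   or implying a recombination rate above a ceiling (default 50 cM/Mb) —
   such spikes are liftover artifacts, not biology.

Every discard is counted in a :class:`CleanupReport`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from recmap.genmap import GeneticMap

DEFAULT_MAX_RATE = 50.0  # cM/Mb ceiling for the sequential filter
UNMAPPED = "."


@dataclass
class LiftTable:
    """Old-assembly → new-assembly coordinate mapping for point positions.

    ``records`` maps ``(old_chromosome, old_position)`` (1-based) to
    ``(new_chromosome, new_position)``; unmapped positions have
    ``new_chromosome == "."``.  Positions absent from the table are treated
    as unmapped.
    """

    records: dict[tuple[str, int], tuple[str, int]] = field(default_factory=dict)

    def lookup(self, chrom: str, pos: int) -> tuple[str, int]:
        return self.records.get((chrom, pos), (UNMAPPED, 0))

    def add(self, old_chrom: str, old_pos: int, new_chrom: str, new_pos: int) -> None:
        key = (old_chrom, old_pos)
        if key in self.records:
            raise ValueError(f"duplicate lift record for {old_chrom}:{old_pos}")
        self.records[key] = (new_chrom, new_pos)

    @classmethod
    def read_tsv(cls, path: str) -> "LiftTable":
        """Read a 4-column TSV: oldChrom, oldPos (1-based), newChrom ('.' =
        unmapped), newPos.  Lines starting with '#' are skipped."""
        table = cls()
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                old_chrom, old_pos, new_chrom, new_pos = line.split()[:4]
                table.add(old_chrom, int(old_pos),
                          new_chrom, int(new_pos) if new_chrom != UNMAPPED else 0)
        return table

    @classmethod
    def read_bed_pair(cls, lifted_bed: str, unmapped_bed: str | None = None) -> "LiftTable":
        """Build a table from liftOver output on single-base BED records.

        The convention is that each input BED record carries its source
        coordinate in the name column as ``chrom:pos`` (1-based); the lifted
        file's coordinates give the new position (0-based start).  Records in
        the unmapped file (same name convention) become unmapped entries.
        """
        table = cls()

        def parse_name(name: str) -> tuple[str, int]:
            chrom, pos = name.rsplit(":", 1)
            return chrom, int(pos)

        with open(lifted_bed) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.split()
                new_chrom, start, name = fields[0], int(fields[1]), fields[3]
                old_chrom, old_pos = parse_name(name)
                table.add(old_chrom, old_pos, new_chrom, start + 1)
        if unmapped_bed is not None:
            with open(unmapped_bed) as fh:
                for line in fh:
                    if not line.strip() or line.startswith("#"):
                        continue
                    name = line.split()[3]
                    old_chrom, old_pos = parse_name(name)
                    table.add(old_chrom, old_pos, UNMAPPED, 0)
        return table

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            for (oc, op), (nc, np_) in sorted(self.records.items()):
                fh.write(f"{oc}\t{op}\t{nc}\t{np_ if nc != UNMAPPED else 0}\n")


@dataclass
class CleanupReport:
    """Audit of marker fates through the assembly-transfer pipeline.

    ``n_unmapped + n_cross_chromosome + n_dropped_monotonic + n_dropped_rate
    + n_retained == n_input``.
    """

    n_input: int = 0
    n_unmapped: int = 0
    n_cross_chromosome: int = 0
    n_dropped_monotonic: int = 0
    n_dropped_rate: int = 0
    n_retained: int = 0

    def check(self) -> None:
        total = (self.n_unmapped + self.n_cross_chromosome
                 + self.n_dropped_monotonic + self.n_dropped_rate + self.n_retained)
        if total != self.n_input:
            raise AssertionError(f"cleanup counts {total} != n_input {self.n_input}")

    def merged(self, other: "CleanupReport") -> "CleanupReport":
        return CleanupReport(*(getattr(self, f) + getattr(other, f)
                               for f in ("n_input", "n_unmapped", "n_cross_chromosome",
                                         "n_dropped_monotonic", "n_dropped_rate",
                                         "n_retained")))


def invert_chromosome(gmap: GeneticMap) -> GeneticMap:
    """Invert the genetic axis: each marker's cM becomes ``total − cM``.

    Used when a chromosome's orientation is flipped between assemblies: the
    genetic distances must be mirrored so that, once the lift mirrors the
    physical axis and markers are re-sorted, inter-marker rates come out as
    the reverse of the originals.  The returned map has *decreasing* genetic
    positions (physical order unchanged), so it is built unvalidated; the
    subsequent lift-and-sort restores validity.  Applying the inversion twice
    restores the original genetic positions.
    """
    if gmap.n_markers == 0:
        return gmap
    total = gmap.genetic_positions[-1] + gmap.genetic_positions[0]
    # total - cM, anchored so the involution property holds for maps whose
    # first marker is not at 0 cM
    inverted = total - gmap.genetic_positions
    return GeneticMap(gmap.chromosome, gmap.positions.copy(), inverted,
                      gmap.chromosome_length, validate=False)


def apply_lift(
    gmap: GeneticMap, lift: LiftTable
) -> tuple[GeneticMap, CleanupReport]:
    """Move markers to new-assembly coordinates and re-sort.

    Markers that are unmapped, or whose target chromosome differs from the
    *modal* target chromosome of this source chromosome's lifted markers, are
    dropped and counted.  Surviving markers keep their genetic positions and
    are sorted by new physical position; the result may be non-monotone in cM
    (repaired downstream by :func:`clean_monotonic`) and is returned
    unvalidated.  Markers landing on an already-occupied target position are
    dropped and counted under ``n_dropped_monotonic`` (a zero-bp interval has
    no defined rate).
    """
    report = CleanupReport(n_input=gmap.n_markers)
    lifted: list[tuple[int, float, str]] = []
    for pos, cm in zip(gmap.positions, gmap.genetic_positions):
        new_chrom, new_pos = lift.lookup(gmap.chromosome, int(pos))
        if new_chrom == UNMAPPED:
            report.n_unmapped += 1
        else:
            lifted.append((new_pos, float(cm), new_chrom))

    if lifted:
        chroms = [c for _, _, c in lifted]
        modal = max(set(chroms), key=chroms.count)
        kept = [(p, c) for p, c, ch in lifted if ch == modal]
        report.n_cross_chromosome = len(lifted) - len(kept)
    else:
        modal = gmap.chromosome
        kept = []
    kept.sort()
    dedup: list[tuple[int, float]] = []
    for p, c in kept:
        if dedup and p == dedup[-1][0]:
            report.n_dropped_monotonic += 1
            continue
        dedup.append((p, c))
    report.n_retained = len(dedup)
    report.check()
    new_map = GeneticMap(
        gmap.chromosome,
        np.asarray([p for p, _ in dedup], dtype=np.int64),
        np.asarray([c for _, c in dedup]),
        validate=False,
    )
    return new_map, report


def clean_monotonic(
    gmap: GeneticMap, max_rate: float = DEFAULT_MAX_RATE
) -> tuple[GeneticMap, CleanupReport]:
    """Single left-to-right scan enforcing monotone cM and a rate ceiling.

    The first marker is always retained.  Each subsequent marker is dropped
    if its genetic position is smaller than that of the last *retained*
    marker, or if the rate it implies relative to the last retained marker
    exceeds ``max_rate`` (cM/Mb).  Comparing to the last retained marker
    (rather than the previous input marker) guarantees a valid output in one
    pass and makes the operation idempotent.

    Genetic positions are not re-anchored: the first retained marker keeps
    its input cM value, and the total length shrinks by whatever the dropped
    markers contributed.
    """
    report = CleanupReport(n_input=gmap.n_markers)
    if gmap.n_markers == 0:
        report.check()
        return gmap, report
    if np.any(np.diff(gmap.positions) <= 0):
        raise ValueError("clean_monotonic requires markers sorted by physical position")
    keep_pos = [int(gmap.positions[0])]
    keep_cm = [float(gmap.genetic_positions[0])]
    for pos, cm in zip(gmap.positions[1:], gmap.genetic_positions[1:]):
        dcm = float(cm) - keep_cm[-1]
        if dcm < 0:
            report.n_dropped_monotonic += 1
            continue
        rate = dcm / (int(pos) - keep_pos[-1]) * 1e6
        if rate > max_rate:
            report.n_dropped_rate += 1
            continue
        keep_pos.append(int(pos))
        keep_cm.append(float(cm))
    report.n_retained = len(keep_pos)
    report.check()
    cleaned = GeneticMap(gmap.chromosome, np.asarray(keep_pos, dtype=np.int64),
                         np.asarray(keep_cm), gmap.chromosome_length)
    return cleaned, report


def convert_map(
    maps: Mapping[str, GeneticMap],
    lift: LiftTable,
    invert_chroms: Iterable[str] = ("27", "32"),
    max_rate: float = DEFAULT_MAX_RATE,
) -> tuple[dict[str, GeneticMap], dict[str, CleanupReport]]:
    """Full transfer pipeline: invert configured chromosomes, lift, clean.

    Returns the converted maps and a per-chromosome :class:`CleanupReport`.
    Chromosomes left empty after cleanup are omitted from the result.
    """
    invert = {str(c) for c in invert_chroms}
    out: dict[str, GeneticMap] = {}
    reports: dict[str, CleanupReport] = {}
    for chrom, gmap in maps.items():
        m = invert_chromosome(gmap) if str(chrom) in invert else gmap
        m, rep_lift = apply_lift(m, lift)
        m, rep_clean = clean_monotonic(m, max_rate=max_rate)
        rep = CleanupReport(
            n_input=rep_lift.n_input,
            n_unmapped=rep_lift.n_unmapped,
            n_cross_chromosome=rep_lift.n_cross_chromosome,
            n_dropped_monotonic=rep_lift.n_dropped_monotonic + rep_clean.n_dropped_monotonic,
            n_dropped_rate=rep_clean.n_dropped_rate,
            n_retained=rep_clean.n_retained,
        )
        rep.check()
        reports[chrom] = rep
        if m.n_markers:
            out[chrom] = m
    return out, reports
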