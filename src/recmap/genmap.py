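"""Genetic-map data model, I/O, rescaling, windowed rates, and consensus maps.

A genetic map is an ordered set of markers on one chromosome, each with a
physical position (bp, 1-based as in VCF/PLINK) and a cumulative genetic
position (cM).  The recombination rate of the interval between two adjacent
markers, in cM/Mb, is always *derived* from the cumulative positions — it is
never stored as an independent quantity, so the two representations cannot
drift apart.

Internally, interval arithmetic (segments, windows, BED overlap) uses 0-based
half-open coordinates; a marker at 1-based position ``p`` sits at internal
coordinate ``p - 1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HAPMAP_HEADER = ["Chromosome", "Position(bp)", "Rate(cM/Mb)", "Map(cM)"]


@dataclass
class GeneticMap:
    """Ordered markers with physical (bp) and genetic (cM) positions.

    Parameters
    ----------
    chromosome:
        Chromosome identifier (e.g. ``"chr1"`` or ``"1"``).
    positions:
        1-based physical positions, strictly increasing.
    genetic_positions:
        Cumulative genetic positions in cM, non-decreasing.
    chromosome_length:
        Optional total chromosome length in bp.
    validate:
        If True (default) the monotonicity invariants are enforced at
        construction.  Intermediate states of the assembly-transfer pipeline
        (e.g. after orientation inversion, before re-sorting) legitimately
        violate them and are built with ``validate=False``.
    """

    chromosome: str
    positions: np.ndarray
    genetic_positions: np.ndarray
    chromosome_length: int | None = None
    validate: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genetic_positions = np.asarray(self.genetic_positions, dtype=np.float64)
        if self.positions.shape != self.genetic_positions.shape:
            raise ValueError("positions and genetic_positions must have equal length")
        if self.validate:
            self.check_valid()

    def check_valid(self) -> None:
        """Raise ``ValueError`` if the map violates its invariants."""
        if self.n_markers and np.any(np.diff(self.positions) <= 0):
            bad = int(np.argmax(np.diff(self.positions) <= 0)) + 1
            raise ValueError(
                f"{self.chromosome}: physical positions not strictly increasing "
                f"at marker index {bad} (position {self.positions[bad]})"
            )
        if self.n_markers and np.any(np.diff(self.genetic_positions) < 0):
            bad = int(np.argmax(np.diff(self.genetic_positions) < 0)) + 1
            raise ValueError(
                f"{self.chromosome}: genetic positions decrease at marker index {bad}"
            )

    @property
    def n_markers(self) -> int:
        return len(self.positions)

    @property
    def total_cm(self) -> float:
        """Total genetic length, cM(last) - cM(first)."""
        if self.n_markers < 2:
            return 0.0
        return float(self.genetic_positions[-1] - self.genetic_positions[0])

    @property
    def span_bp(self) -> int:
        """Physical span between first and last marker."""
        if self.n_markers < 2:
            return 0
        return int(self.positions[-1] - self.positions[0])

    def rates(self) -> np.ndarray:
        """Per-segment recombination rates in cM/Mb (length ``n_markers - 1``)."""
        if self.n_markers < 2:
            return np.empty(0)
        dcm = np.diff(self.genetic_positions)
        dbp = np.diff(self.positions).astype(float)
        return dcm / dbp * 1e6

    def cm_at(self, coords: np.ndarray | float) -> np.ndarray | float:
        """Cumulative cM at internal (0-based) coordinates, by linear interpolation.

        Outside the marker span the map is clamped to its boundary values.
        """
        return np.interp(coords, self.positions - 1, self.genetic_positions)

    def extent(self) -> tuple[int, int]:
        """Internal-coordinate interval [first marker, last marker]."""
        return int(self.positions[0] - 1), int(self.positions[-1] - 1)


@dataclass(frozen=True)
class RateSegment:
    """Inter-marker interval with a constant recombination rate.

    Coordinates are 0-based half-open; ``left_marker``/``right_marker`` are the
    indices of the bounding markers in the source map, used for SNP counting
    when segments are merged into hotspot candidates.
    """

    chromosome: str
    start: int
    end: int
    rate: float
    left_marker: int
    right_marker: int

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def cm(self) -> float:
        return self.rate * self.length_bp / 1e6


def to_segments(gmap: GeneticMap) -> list[RateSegment]:
    """Decompose a map into its inter-marker constant-rate segments.

    The segments conserve genetic length: the sum of ``rate × length`` equals
    the map's total cM.  Maps with fewer than 2 markers yield an empty list.
    """
    if gmap.n_markers < 2:
        logger.warning("%s: fewer than 2 markers, no segments defined", gmap.chromosome)
        return []
    rates = gmap.rates()
    coords = gmap.positions - 1
    return [
        RateSegment(gmap.chromosome, int(coords[i]), int(coords[i + 1]), float(rates[i]), i, i + 1)
        for i in range(gmap.n_markers - 1)
    ]


def rescale_map(gmap: GeneticMap, target_length_cm: float) -> GeneticMap:
    """Linearly rescale a chromosome's map to a target total genetic length.

    Every genetic position is multiplied by ``target / current_total``, so the
    relative rate profile is unchanged and the new total equals the target
    exactly.  Used to pin LD-inferred maps — whose absolute scale depends on
    the assumed demography — to an externally estimated chromosome length.
    """
    if target_length_cm < 0:
        raise ValueError("target length must be non-negative")
    total = gmap.total_cm
    if target_length_cm == 0:
        return GeneticMap(gmap.chromosome, gmap.positions.copy(),
                          np.zeros(gmap.n_markers), gmap.chromosome_length)
    if total <= 0:
        raise ValueError(
            f"{gmap.chromosome}: cannot rescale a zero-length map to a positive target"
        )
    factor = target_length_cm / total
    return GeneticMap(gmap.chromosome, gmap.positions.copy(),
                      gmap.genetic_positions * factor, gmap.chromosome_length)


def weighted_average_maps(
    maps: Sequence[GeneticMap], weights: Sequence[float]
) -> GeneticMap:
    """Chromosome-weighted consensus of several maps of the same chromosome.

    The marker grid of the result is the sorted union of all input marker
    positions restricted to the interval where *every* input map is defined
    (no extrapolation).  On each union segment the consensus rate is the
    weighted mean ``Σ w_i r_i / Σ w_i`` of the inputs' piecewise-constant
    rates; equivalently, the consensus cumulative cM is the weighted mean of
    the inputs' interpolated cumulative cM, re-anchored to 0 at the first
    union marker.  Weights are typically the number of chromosomes used in
    each map's inference.
    """
    if len(maps) == 0:
        raise ValueError("need at least one map")
    if len(weights) != len(maps):
        raise ValueError("one weight per map required")
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    chrom = maps[0].chromosome
    if any(m.chromosome != chrom for m in maps):
        raise ValueError("all maps must cover the same chromosome")
    if any(m.n_markers < 2 for m in maps):
        raise ValueError("all maps need at least 2 markers")

    lo = max(int(m.positions[0]) for m in maps)
    hi = min(int(m.positions[-1]) for m in maps)
    if hi <= lo:
        raise ValueError(f"{chrom}: input maps have no common physical interval")
    union = np.unique(np.concatenate([m.positions for m in maps]))
    union = union[(union >= lo) & (union <= hi)]
    cm = np.zeros(len(union))
    for m, wi in zip(maps, w):
        cm += wi * m.cm_at(union - 1)
    cm /= w.sum()
    cm -= cm[0]
    length = next((m.chromosome_length for m in maps if m.chromosome_length), None)
    return GeneticMap(chrom, union, cm, length)


def window_rates(
    gmap: GeneticMap,
    window_bp: int,
    step_bp: int | None = None,
    centers_bp: Iterable[int] | None = None,
    end_bp: int | None = None,
) -> pd.DataFrame:
    """Mean recombination rate of a map in physical windows.

    Windows are 0-based half-open ``[start, start + window_bp)``, tiled from 0
    at ``step_bp`` (default: non-overlapping, step = window) up to ``end_bp``
    (default: chromosome length if known, else last marker).  Alternatively an
    explicit grid of window *centers* can be supplied (used for small windows
    placed on a sparse grid to limit autocorrelation).

    The per-window rate is the length-weighted mean of segment rates over the
    part of the window covered by the map (between first and last marker);
    windows with zero covered bp get ``NaN`` — they carry no information and
    must not be conflated with a measured rate of zero.

    Returns a DataFrame with columns ``chromosome, start, end, rate``.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if centers_bp is not None:
        centers = np.asarray(list(centers_bp), dtype=np.int64)
        starts = centers - window_bp // 2
    else:
        if step_bp is None:
            step_bp = window_bp
        if end_bp is None:
            end_bp = gmap.chromosome_length
        if end_bp is None:
            end_bp = int(gmap.positions[-1]) if gmap.n_markers else 0
        starts = np.arange(0, max(end_bp, 0), step_bp, dtype=np.int64)
    ends = starts + window_bp

    if gmap.n_markers < 2:
        rate = np.full(len(starts), np.nan)
    else:
        lo, hi = gmap.extent()
        a = np.clip(starts, lo, hi)
        b = np.clip(ends, lo, hi)
        covered = (b - a).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(
                covered > 0,
                (np.asarray(gmap.cm_at(b)) - np.asarray(gmap.cm_at(a))) / covered * 1e6,
                np.nan,
            )
    return pd.DataFrame(
        {"chromosome": gmap.chromosome, "start": starts, "end": ends, "rate": rate}
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _finalize_chromosome(
    chrom: str,
    pos: list[int],
    cm: list[float],
    rates: list[float],
    has_cm: bool,
    path: str,
) -> GeneticMap:
    positions = np.asarray(pos, dtype=np.int64)
    if has_cm:
        genetic = np.asarray(cm, dtype=float)
    else:
        # reconstruct cumulative cM from 0: rate on a line applies to the
        # interval from that marker to the next; the last line's rate is unused
        genetic = np.zeros(len(pos))
        if len(pos) > 1:
            dbp = np.diff(positions).astype(float)
            genetic[1:] = np.cumsum(np.asarray(rates[:-1]) * dbp / 1e6)
    return GeneticMap(chrom, positions, genetic)


def read_map(path: str, dialect: str = "hapmap_tsv") -> dict[str, GeneticMap]:
    """Read a genetic map file into one :class:`GeneticMap` per chromosome.

    Dialects
    --------
    ``hapmap_tsv``
        Tab-separated with header ``Chromosome  Position(bp)  Rate(cM/Mb)
        Map(cM)``.  If the cM column is absent, cumulative positions are
        reconstructed from the rate column starting at 0; if the rate column
        is absent it is derived on output.
    ``plink_map``
        PLINK ``.map``: chromosome, marker id, cM, bp (whitespace-separated,
        no header).
    """
    if dialect == "hapmap_tsv":
        return _read_hapmap(path)
    if dialect == "plink_map":
        return _read_plink(path)
    raise ValueError(f"unknown dialect: {dialect!r}")


def _read_hapmap(path: str) -> dict[str, GeneticMap]:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        logger.warning("%s: empty map file", path)
        return {}
    header = lines[0].split("\t")
    cols = {name.strip().lower(): i for i, name in enumerate(header)}

    def find(*names: str) -> int | None:
        for n in names:
            if n in cols:
                return cols[n]
        return None

    i_chrom = find("chromosome", "chr", "chrom")
    i_pos = find("position(bp)", "position", "pos")
    i_rate = find("rate(cm/mb)", "rate")
    i_cm = find("map(cm)", "map", "cm", "genetic_map(cm)")
    if i_chrom is None or i_pos is None or (i_rate is None and i_cm is None):
        raise ValueError(f"{path}: unrecognized hapmap header: {header!r}")

    maps: dict[str, GeneticMap] = {}
    cur: str | None = None
    pos: list[int] = []
    cm: list[float] = []
    rates: list[float] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        chrom = fields[i_chrom]
        p = int(fields[i_pos])
        if chrom != cur:
            if cur is not None:
                maps[cur] = _finalize_chromosome(cur, pos, cm, rates, i_cm is not None, path)
            cur, pos, cm, rates = chrom, [], [], []
        if pos and p <= pos[-1]:
            raise ValueError(
                f"{path}:{lineno}: non-monotone position {p} on {chrom} "
                f"(previous {pos[-1]})"
            )
        if i_rate is not None:
            r = float(fields[i_rate])
            if r < 0:
                raise ValueError(f"{path}:{lineno}: negative rate {r}")
            rates.append(r)
        if i_cm is not None:
            cm.append(float(fields[i_cm]))
        pos.append(p)
    if cur is not None:
        maps[cur] = _finalize_chromosome(cur, pos, cm, rates, i_cm is not None, path)
    return maps


def _read_plink(path: str) -> dict[str, GeneticMap]:
    with open(path) as fh:
        lines = [ln.split() for ln in fh if ln.strip()]
    if not lines:
        logger.warning("%s: empty map file", path)
        return {}
    maps: dict[str, GeneticMap] = {}
    cur: str | None = None
    pos: list[int] = []
    cm: list[float] = []
    for lineno, fields in enumerate(lines, start=1):
        if len(fields) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
        chrom, _snp_id, gpos, bp = fields
        p = int(bp)
        if chrom != cur:
            if cur is not None:
                maps[cur] = GeneticMap(cur, np.asarray(pos), np.asarray(cm))
            cur, pos, cm = chrom, [], []
        if pos and p <= pos[-1]:
            raise ValueError(f"{path}:{lineno}: non-monotone position {p} on {chrom}")
        pos.append(p)
        cm.append(float(gpos))
    if cur is not None:
        maps[cur] = GeneticMap(cur, np.asarray(pos), np.asarray(cm))
    return maps


def write_map(
    maps: Mapping[str, GeneticMap] | GeneticMap, path: str, dialect: str = "hapmap_tsv"
) -> None:
    """Write maps to disk; ``read_map(write_map(x))`` round-trips exactly.

    The hapmap dialect recomputes the rate column from cumulative cM (the rate
    on each line is the rate to the next marker; the last line gets 0).
    Values are written with 17 significant digits so the round trip is exact.
    """
    if isinstance(maps, GeneticMap):
        maps = {maps.chromosome: maps}
    with open(path, "w") as fh:
        if dialect == "hapmap_tsv":
            fh.write("\t".join(HAPMAP_HEADER) + "\n")
            for chrom, m in maps.items():
                rates = np.append(m.rates(), 0.0) if m.n_markers > 1 else np.zeros(m.n_markers)
                for p, r, c in zip(m.positions, rates, m.genetic_positions):
                    fh.write(f"{chrom}\t{p}\t{r:.17g}\t{c:.17g}\n")
        elif dialect == "plink_map":
            for chrom, m in maps.items():
                for p, c in zip(m.positions, m.genetic_positions):
                    fh.write(f"{chrom}\t{chrom}:{p}\t{c:.17g}\t{p}\n")
        else:
            raise ValueError(f"unknown dialect: {dialect!r}")
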