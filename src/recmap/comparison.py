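"""Multi-scale comparison of recombination maps.

Two complementary views: rank correlation of windowed rates between pairs of
maps across physical scales (100 bp to 5 Mb), and a Lorenz-style
concentration curve describing how unevenly recombination is distributed
along the genome (e.g. "80% of the genetic distance falls in 30% of the
sequence").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from recmap.genmap import GeneticMap, to_segments, window_rates

# windows of at least this size tile the chromosome end to end; smaller
# windows are placed on a sparse centered grid to limit autocorrelation
TILE_THRESHOLD = 10_000
CENTER_SPACING = 10_000


@dataclass
class CorrelationRow:
    """Spearman correlation between two maps' rates at one window size."""

    map_a: str
    map_b: str
    window_size: int
    n_windows_used: int
    spearman_rho: float


def _window_grid(gmap_a: GeneticMap, gmap_b: GeneticMap, window_size: int,
                 center_phase: int = CENTER_SPACING // 2) -> tuple[np.ndarray, np.ndarray]:
    """Paired window rates for one chromosome covered by both maps."""
    end = max(int(gmap_a.positions[-1]), int(gmap_b.positions[-1]))
    if window_size >= TILE_THRESHOLD:
        rates_a = window_rates(gmap_a, window_size, step_bp=window_size, end_bp=end)
        rates_b = window_rates(gmap_b, window_size, step_bp=window_size, end_bp=end)
    else:
        centers = np.arange(center_phase, end, CENTER_SPACING)
        rates_a = window_rates(gmap_a, window_size, centers_bp=centers)
        rates_b = window_rates(gmap_b, window_size, centers_bp=centers)
    return rates_a["rate"].to_numpy(), rates_b["rate"].to_numpy()


def window_correlation(
    maps_a: Mapping[str, GeneticMap],
    maps_b: Mapping[str, GeneticMap],
    window_size: int,
    chromosomes: Sequence[str] | None = None,
    name_a: str = "A",
    name_b: str = "B",
) -> CorrelationRow:
    """Spearman rho between two maps' windowed rates at one physical scale.

    Windows of ≥10 kb tile each chromosome at step = window size; smaller
    windows (100 bp, 1 kb) are centered every 10 kb.  Windows lacking marker
    coverage in either map are excluded; the remaining paired rates are
    pooled across all shared chromosomes (by default, every chromosome
    present in both collections) and ranked with mid-ranks for ties.
    """
    shared = [c for c in maps_a if c in maps_b]
    if chromosomes is not None:
        wanted = {str(c) for c in chromosomes}
        shared = [c for c in shared if str(c) in wanted]
    if not shared:
        raise ValueError("maps share no chromosome")
    xs, ys = [], []
    for chrom in shared:
        ra, rb = _window_grid(maps_a[chrom], maps_b[chrom], window_size)
        ok = ~(np.isnan(ra) | np.isnan(rb))
        xs.append(ra[ok])
        ys.append(rb[ok])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if len(x) < 3:
        raise ValueError(f"only {len(x)} usable windows; need at least 3")
    rho = stats.spearmanr(x, y).statistic
    return CorrelationRow(name_a, name_b, window_size, len(x), float(rho))


def correlation_table(
    collections: Mapping[str, Mapping[str, GeneticMap]],
    window_sizes: Sequence[int] = (100, 1_000, 10_000, 100_000, 1_000_000, 5_000_000),
    chromosomes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """All-pairs correlation table across window sizes (long format)."""
    names = list(collections)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            for w in window_sizes:
                r = window_correlation(collections[a], collections[b], w,
                                       chromosomes=chromosomes, name_a=a, name_b=b)
                rows.append(vars(r))
    return pd.DataFrame(rows)


@dataclass
class SkewCurve:
    """Concentration (Lorenz-style) curve of recombination along the genome.

    ``sequence_fraction[i]`` is the cumulative fraction of physical sequence
    contributed by the ``i`` highest-rate segments; ``recombination_fraction``
    the corresponding fraction of total genetic distance.  Sorting by rate
    descending makes the curve concave, running from (0, 0) to (1, 1) on or
    above the diagonal.  ``sequence_at(0.8)`` is the standard summary: the
    fraction of sequence needed to account for 80% of recombination.
    """

    sequence_fraction: np.ndarray
    recombination_fraction: np.ndarray

    def sequence_at(self, recombination_fraction: float = 0.8) -> float:
        """Sequence fraction at a given recombination fraction (interpolated)."""
        return float(np.interp(recombination_fraction,
                               self.recombination_fraction, self.sequence_fraction))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sequence_fraction": self.sequence_fraction,
            "recombination_fraction": self.recombination_fraction,
        })


def skew_curve(maps: Mapping[str, GeneticMap] | GeneticMap) -> SkewCurve:
    """Concentration curve of recombination over a map collection.

    All inter-marker segments (pooled across chromosomes) are sorted by rate
    descending and their physical and genetic lengths accumulated.  Segments
    are the map's native resolution, so no windowing choice is imposed.
    """
    if isinstance(maps, GeneticMap):
        maps = {maps.chromosome: maps}
    segs = [s for m in maps.values() for s in to_segments(m)]
    if not segs:
        raise ValueError("no segments: need maps with at least 2 markers")
    phys = np.array([s.length_bp for s in segs], dtype=float)
    gen = np.array([s.cm for s in segs], dtype=float)
    if gen.sum() <= 0:
        raise ValueError("zero total genetic length")
    order = np.argsort(-(gen / phys))
    phys, gen = phys[order], gen[order]
    seq_frac = np.concatenate([[0.0], np.cumsum(phys) / phys.sum()])
    rec_frac = np.concatenate([[0.0], np.cumsum(gen) / gen.sum()])
    return SkewCurve(seq_frac, rec_frac)
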