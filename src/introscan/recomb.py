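"""Recombination-rate landscapes from a linkage map, and weight-rate tests.

Rates are estimated in non-overlapping fixed-size bins (default 1 Mbp,
anchored at coordinate 0 of each chromosome): within a bin, rate = genetic
distance between the two most distal markers divided by their physical
distance in Mbp — exactly the marker-span formula, so sparse bins estimate
their rate over a short span and no correction is applied.  Bins with fewer
than two markers are undefined; bins above a ceiling (default 100 cM/Mbp,
symptomatic of marker mislocalisation) are flagged and excluded downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .io import LinkageMap

logger = logging.getLogger("introscan")

__all__ = [
    "RecombinationBin",
    "RecombinationBins",
    "CorrelationResult",
    "estimate_bin_rates",
    "correlate_weights_with_recombination",
    "classify_recombination_regime",
]


@dataclass
class RecombinationBin:
    chrom: str
    start: int
    end: int
    rate: float          # cM/Mbp; NaN when undefined
    n_markers: int
    filtered: bool = False

    @property
    def defined(self) -> bool:
        return not math.isnan(self.rate)


@dataclass
class RecombinationBins:
    bins: list[RecombinationBin]
    bin_size: int
    max_rate: float

    def __iter__(self):
        return iter(self.bins)

    def __len__(self):
        return len(self.bins)

    def usable(self) -> list[RecombinationBin]:
        return [b for b in self.bins if b.defined and not b.filtered]

    def rate_at(self, chrom: str, position: float) -> float:
        """Rate of the bin containing ``position`` (NaN if undefined/filtered)."""
        for b in self.bins:
            if b.chrom == chrom and b.start <= position < b.end:
                return math.nan if b.filtered else b.rate
        return math.nan

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "chrom": b.chrom, "start": b.start, "end": b.end,
                    "rate_cM_per_Mbp": b.rate, "n_markers": b.n_markers,
                    "filtered": b.filtered,
                }
                for b in self.bins
            ]
        )


def estimate_bin_rates(
    lm: LinkageMap, bin_size: int = 1_000_000, max_rate: float = 100.0
) -> RecombinationBins:
    """Distal-marker-span rates in fixed bins; extreme rates flagged."""
    bins = []
    n_filtered = n_undefined = 0
    for chrom, markers in lm.by_chromosome().items():
        last_bp = markers[-1].bp
        n_bins = last_bp // bin_size + 1
        for i in range(n_bins):
            start, end = i * bin_size, (i + 1) * bin_size
            inside = [m for m in markers if start <= m.bp < end]
            if len(inside) < 2:
                bins.append(RecombinationBin(chrom, start, end, math.nan, len(inside)))
                n_undefined += 1
                continue
            first, last = inside[0], inside[-1]
            if last.bp == first.bp:
                logger.warning(
                    "estimate_bin_rates: %s:%d-%d distal markers coincide", chrom, start, end
                )
                bins.append(RecombinationBin(chrom, start, end, math.nan, len(inside)))
                n_undefined += 1
                continue
            rate = (last.cm - first.cm) / ((last.bp - first.bp) / 1e6)
            filtered = rate > max_rate
            if filtered:
                n_filtered += 1
            bins.append(
                RecombinationBin(chrom, start, end, rate, len(inside), filtered=filtered)
            )
    if n_filtered:
        logger.info("estimate_bin_rates: %d bins above %.0f cM/Mbp flagged", n_filtered, max_rate)
    if n_undefined:
        logger.info("estimate_bin_rates: %d bins undefined (<2 markers)", n_undefined)
    return RecombinationBins(bins=bins, bin_size=bin_size, max_rate=max_rate)


@dataclass
class CorrelationResult:
    rho: float
    p: float
    n: int


def correlate_weights_with_recombination(
    chrom: list[str],
    midpoints: np.ndarray,
    support: np.ndarray,
    bins: RecombinationBins,
) -> CorrelationResult:
    """Spearman correlation of window support with the window's bin rate.

    Each smoothed-weight window is assigned the rate of the bin containing
    its midpoint; windows in undefined or filtered bins are dropped.
    """
    rate_lookup: dict[tuple[str, int], float] = {}
    for b in bins:
        rate_lookup[(b.chrom, b.start // bins.bin_size)] = (
            math.nan if b.filtered else b.rate
        )
    rates = np.asarray(
        [
            rate_lookup.get((c, int(m // bins.bin_size)), math.nan)
            for c, m in zip(chrom, midpoints)
        ]
    )
    ok = ~np.isnan(rates) & ~np.isnan(np.asarray(support, dtype=float))
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info(
            "correlate_weights_with_recombination: %d windows dropped "
            "(undefined or filtered bins)", n_dropped,
        )
    if ok.sum() < 5:
        raise ValueError("fewer than 5 usable (window, bin) pairs")
    rho, p = sps.spearmanr(np.asarray(support)[ok], rates[ok])
    if math.isnan(rho):  # constant input: all ranks tied
        rho, p = 0.0, 1.0
    return CorrelationResult(rho=float(rho), p=float(p), n=int(ok.sum()))


def classify_recombination_regime(
    bins: RecombinationBins, threshold: float = 5.0
) -> dict[tuple[str, int], str]:
    """Label each defined bin 'high' iff rate strictly exceeds ``threshold``."""
    out = {}
    for b in bins.usable():
        out[(b.chrom, b.start)] = "high" if b.rate > threshold else "low"
    return out
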