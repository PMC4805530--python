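"""Closed-form detection framework for bulk vs single-cell sequencing.

A somatic mutation carried by ``k`` of ``n`` pooled cells (mosaicism k/n)
with read depth ``D`` at its locus is seen on average in (k/n)·D/2 reads,
while artifact reads accrue at a rate ``e`` that is a constant fraction of
depth, forcing a detection threshold T = z·e·D (z a confidence factor).
Combining the two gives the depth-independent bound k/n >= 2·z·e on the
minimum mosaicism detectable in bulk sequencing.  In a single cell k/n = 1,
so somatic mutations sit at the same signal level as germline heterozygous
variants.  The closed forms deliberately omit variance terms; a Monte-Carlo
verifier supplies the sampling variability empirically.

The module also carries the Hardy-Weinberg arithmetic used to argue that
germline polymorphic (KNR) insertions are mostly single-copy: for insertion
allele frequency p, the heterozygous fraction among carriers is
2pq/(p² + 2pq).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import ValidationError


@dataclass(frozen=True)
class DetectionParams:
    k: int  # cells carrying the mutation
    n: int  # cells pooled
    D: float  # read depth at the locus
    e: float  # fraction of error reads
    z: float = 2.0  # confidence factor

    def __post_init__(self) -> None:
        if self.n < 1 or not 0 <= self.k <= self.n:
            raise ValidationError("need 0 <= k <= n and n >= 1")
        if self.D < 0:
            raise ValidationError("depth must be >= 0")
        if not 0.0 <= self.e < 1.0:
            raise ValidationError("error fraction must be in [0, 1)")
        if self.z <= 0:
            raise ValidationError("confidence factor must be positive")

    @property
    def T(self) -> float:
        return detection_threshold(self.z, self.e, self.D)


def expected_variant_reads(k: int, n: int, D: float) -> float:
    """Mean variant-supporting reads for mosaicism k/n at depth D: (k/n)·D/2."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValidationError("need 0 <= k <= n")
    return (k / n) * D / 2.0


def detection_threshold(z: float, e: float, D: float) -> float:
    """Read threshold T = z·e·D imposed by the error floor."""
    if z <= 0:
        raise ValidationError("confidence factor must be positive")
    if not 0.0 <= e < 1.0:
        raise ValidationError("error fraction must be in [0, 1)")
    if D < 0:
        raise ValidationError("depth must be >= 0")
    return z * e * D


def min_detectable_mosaicism(z: float, e: float) -> float:
    """Depth-independent detectability bound: k/n >= 2·z·e."""
    if z <= 0:
        raise ValidationError("confidence factor must be positive")
    if not 0.0 <= e < 1.0:
        raise ValidationError("error fraction must be in [0, 1)")
    return 2.0 * z * e


def detection_probability_mc(
    mosaicism: float,
    D: float,
    e: float,
    z: float,
    n_trials: int = 10_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo probability that variant reads clear the threshold.

    Variant-supporting reads are Binomial(D, mosaicism/2); a trial detects
    when they reach T = z·e·D.  At large D the detection probability
    crosses 50% near mosaicism = 2·z·e.
    """
    if not 0.0 <= mosaicism <= 1.0:
        raise ValidationError("mosaicism must be in [0, 1]")
    rng = np.random.default_rng(seed)
    depth = int(round(D))
    reads = rng.binomial(depth, mosaicism / 2.0, size=n_trials)
    return float(np.mean(reads >= detection_threshold(z, e, D)))


def hw_heterozygosity(p: float) -> float:
    """Heterozygous fraction among insertion carriers under Hardy-Weinberg.

    2pq/(p² + 2pq) = (2 - 2p)/(2 - p); strictly decreasing on (0, 1],
    approaching 1 as p -> 0 and 0 at p = 1 (all carriers homozygous).
    """
    if not 0.0 < p <= 1.0:
        raise ValidationError(
            "allele frequency must be in (0, 1]; the carrier-conditional "
            "heterozygosity is undefined at p = 0"
        )
    q = 1.0 - p
    return 2.0 * p * q / (p * p + 2.0 * p * q)


def single_copy_fraction(n_single_copy: int, n_total: int) -> float:
    """Percent of genotyped insertions present in a single copy per cell.

    Counts heterozygous plus hemizygous insertions over all genotyped
    insertions and reports a percentage.
    """
    if n_total < 1 or not 0 <= n_single_copy <= n_total:
        raise ValidationError("need 0 <= n_single_copy <= n_total, n_total >= 1")
    return 100.0 * n_single_copy / n_total
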