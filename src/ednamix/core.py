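"""Core domain types for haplotype-frequency based contributor estimation.

The quantities modelled here follow standard population-genetic notation:
``pi`` (vector of population haplotype frequencies ``p_i`` at one locus),
per-sample read counts ``R_ij`` with within-sample frequencies
``f_ij = R_ij / total_reads``, and per-sample contributor estimates
``N_j`` with profile-likelihood confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PROB_SUM_TOL",
    "PopulationFrequencies",
    "SampleCounts",
    "ContributorEstimate",
]

#: tolerance on "frequencies sum to one" checks
PROB_SUM_TOL = 1e-9


@dataclass(frozen=True)
class PopulationFrequencies:
    """Population haplotype-frequency vector ``pi`` for one locus.

    Parameters
    ----------
    haplotype_ids
        Unique string identifiers, one per haplotype (ASV).
    probs
        Population frequencies ``p_i``; must sum to 1 within ``PROB_SUM_TOL``.
    locus_label
        Free-text locus name.
    ploidy
        1 (haploid), 2 (diploid) or ``None`` when unknown (e.g. heteroplasmic
        loci); ``None`` disables the ploidy-based minimum downstream.
    metadata
        Provenance of the estimate (number of samples averaged, frequency
        floor applied, ...). Not used in any computation.

    Notes
    -----
    Haplotypes with ``p_i == 0`` or ``p_i == 1`` are retained (IDs stay
    stable) but are excluded from all likelihood sums, which divide by
    ``p_i * (1 - p_i)``. Use :attr:`informative` to get the mask of
    haplotypes with ``0 < p_i < 1``.
    """

    haplotype_ids: tuple[str, ...]
    probs: np.ndarray
    locus_label: str = "locus"
    ploidy: int | None = 1
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        ids = tuple(str(h) for h in self.haplotype_ids)
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "haplotype_ids", ids)
        object.__setattr__(self, "probs", probs)
        if probs.ndim != 1:
            raise ValueError("probs must be a 1-D vector")
        if len(ids) != probs.size:
            raise ValueError(
                f"{len(ids)} haplotype ids but {probs.size} frequencies"
            )
        if len(set(ids)) != len(ids):
            raise ValueError("haplotype_ids must be unique")
        if probs.size == 0:
            raise ValueError("at least one haplotype is required")
        if np.any(probs < 0) or np.any(probs > 1):
            raise ValueError("all frequencies must lie in [0, 1]")
        if abs(probs.sum() - 1.0) > PROB_SUM_TOL:
            raise ValueError(
                f"frequencies must sum to 1 (got {probs.sum():.12g})"
            )
        if self.ploidy is not None and self.ploidy < 1:
            raise ValueError("ploidy must be a positive integer or None")
        probs.setflags(write=False)

    @property
    def n_haplotypes(self) -> int:
        """Total number of haplotypes K in the vector."""
        return self.probs.size

    @property
    def informative(self) -> np.ndarray:
        """Boolean mask of haplotypes with ``0 < p_i < 1``."""
        return (self.probs > 0.0) & (self.probs < 1.0)

    @property
    def k_informative(self) -> int:
        """Number of haplotypes entering likelihood sums."""
        return int(self.informative.sum())

    def index_of(self, haplotype_id: str) -> int:
        return self.haplotype_ids.index(haplotype_id)

    def same_index(self, other: "PopulationFrequencies") -> bool:
        return self.haplotype_ids == other.haplotype_ids


@dataclass(frozen=True)
class SampleCounts:
    """Per-sample haplotype read counts ``R_ij`` for one eDNA sample.

    ``read_counts`` is aligned to the haplotype index of the associated
    :class:`PopulationFrequencies`. Samples with ``total_reads == 0`` are
    valid objects (a non-detection) but are excluded from population
    frequency estimation and contributor estimation.
    """

    sample_id: str
    haplotype_ids: tuple[str, ...]
    read_counts: np.ndarray
    replicate_group: str | None = None

    def __post_init__(self):
        ids = tuple(str(h) for h in self.haplotype_ids)
        counts = np.asarray(self.read_counts)
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.allclose(counts, rounded):
                raise ValueError("read counts must be integers")
            counts = rounded.astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        object.__setattr__(self, "haplotype_ids", ids)
        object.__setattr__(self, "read_counts", counts)
        if counts.ndim != 1:
            raise ValueError("read_counts must be a 1-D vector")
        if len(ids) != counts.size:
            raise ValueError("haplotype_ids and read_counts length mismatch")
        if len(set(ids)) != len(ids):
            raise ValueError("haplotype_ids must be unique")
        if np.any(counts < 0):
            raise ValueError("read counts must be nonnegative")
        counts.setflags(write=False)

    @property
    def total_reads(self) -> int:
        return int(self.read_counts.sum())

    @property
    def detected(self) -> bool:
        """True when any target haplotype has at least one read."""
        return self.total_reads > 0

    @property
    def freqs(self) -> np.ndarray:
        """Within-sample frequencies ``f_ij``; requires ``total_reads > 0``."""
        total = self.total_reads
        if total == 0:
            raise ValueError(
                f"sample {self.sample_id!r} has no reads; freqs undefined"
            )
        return self.read_counts / total

    @property
    def k_observed(self) -> int:
        """Number of haplotypes with at least one read."""
        return int((self.read_counts > 0).sum())


@dataclass(frozen=True)
class ContributorEstimate:
    """Contributor-number estimate for one sample (or one site).

    Attributes
    ----------
    n_mle
        Point estimate of the number of contributors (continuous). For
        divergent samples this is the reporting cap, not a finite MLE.
    ci_low, ci_high
        Profile-likelihood confidence bounds; ``ci_high`` may be ``inf``.
    n_min
        Ploidy-based minimum number of contributors.
    k_observed
        Distinct haplotypes observed (union across replicates for sites).
    log_lik_at_mle
        Log-likelihood at the point estimate (``nan`` when divergent).
    xi_used
        Variance-inflation factor assumed during estimation.
    censored_at_min
        True when the raw estimate (or lower bound) was raised to ``n_min``.
    divergent
        True when observed frequencies equal the reference exactly, in
        which case the likelihood increases without bound in N.
    """

    sample_id: str
    n_mle: float
    ci_low: float
    ci_high: float
    n_min: int
    k_observed: int
    log_lik_at_mle: float
    xi_used: float
    alpha: float = 0.05
    censored_at_min: bool = False
    divergent: bool = False

    def __post_init__(self):
        if not self.divergent:
            if not (self.ci_low <= self.n_mle <= self.ci_high):
                raise ValueError(
                    f"CI ({self.ci_low}, {self.ci_high}) does not contain "
                    f"the point estimate {self.n_mle}"
                )
        if self.n_mle <= 0 and not self.divergent:
            raise ValueError("n_mle must be positive")

    def contains(self, n_true: float) -> bool:
        """Whether the confidence interval covers ``n_true``."""
        return self.ci_low <= n_true <= self.ci_high

    @property
    def n_rounded(self) -> int:
        """Integer presentation of the point estimate (reporting only)."""
        if math.isinf(self.n_mle):
            raise ValueError("divergent estimate has no finite rounding")
        return max(int(round(self.n_mle)), 1)


def aligned_frequency_matrix(samples: Sequence[SampleCounts]) -> np.ndarray:
    """Stack within-sample frequency vectors of detected samples (M x K).

    All samples must share one haplotype index; raises otherwise.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("no samples given")
    ids = samples[0].haplotype_ids
    for s in samples[1:]:
        if s.haplotype_ids != ids:
            raise ValueError(
                f"sample {s.sample_id!r} uses a different haplotype index"
            )
    detected = [s for s in samples if s.detected]
    if not detected:
        raise ValueError("no samples with detections")
    return np.vstack([s.freqs for s in detected])
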