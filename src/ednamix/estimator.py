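"""Maximum-likelihood estimation of the number of contributors per sample.

Under panmixia, the haplotypes carried by the ``N_j`` individuals
contributing DNA to sample j are a multinomial draw from the population
frequencies ``pi``, so the contributor-level frequency of haplotype i has
mean ``p_i`` and variance ``p_i (1 - p_i) / N_j``. All downstream noise
(shedding heterogeneity, transport, subsampling, sequencing) is folded
into a single variance-inflation factor ``xi >= 1``, giving the working
model

    f_ij ~ Normal(p_i, xi * p_i * (1 - p_i) / N_j)

for the observed within-sample frequencies. Treating haplotypes as
independent, the log-likelihood in N is

    lnL(N) = (k/2) ln N - (k/2) ln xi - (1/2) sum_i ln(2 pi p_i (1-p_i))
             - (N / 2 xi) * S,    S = sum_i (f_i - p_i)^2 / (p_i (1-p_i))

over the k haplotypes with 0 < p_i < 1 (unobserved haplotypes enter with
f_i = 0; absence is informative). The maximiser is the closed form
``N_MLE = xi * k / S``, and the 100(1-alpha)% profile-likelihood interval
is the set of N whose log-likelihood lies within half the chi-square(1)
quantile of the maximum. Because lnL depends on N only through
``(k/2)(ln N - N/N_MLE)``, the interval bounds are exact multiples of
N_MLE found by one-dimensional root finding in the ratio r = N / N_MLE.
"""

from __future__ import annotations

import math
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import chi2

from .core import ContributorEstimate, PopulationFrequencies, SampleCounts

__all__ = [
    "deviation_statistic",
    "log_likelihood",
    "mle_contributors",
    "profile_ci",
    "ci_ratio_bounds",
    "ploidy_minimum",
    "estimate_sample",
    "estimate_site",
    "mom_contributors",
    "combine_loci",
    "N_CAP",
]

#: displayed point estimate for divergent samples (f identical to pi)
N_CAP = 1e6


def _prepare(freqs, pi: PopulationFrequencies, *, on_novel: str = "error"):
    """Align f with pi, resolve novel haplotypes, return (f, p, mask).

    ``mask`` selects the k informative haplotypes (0 < p_i < 1). A novel
    haplotype is one with reads (f_i > 0) but reference frequency zero;
    by default this is an error because it signals that the reference
    frequencies were estimated without this sample's haplotypes. With
    ``on_novel="drop"`` the offending haplotypes' reads are discarded and
    f is renormalised over the remainder.
    """
    f = np.asarray(freqs, dtype=float)
    p = pi.probs
    if f.shape != p.shape:
        raise ValueError(
            f"frequency vector length {f.size} does not match the "
            f"{p.size}-haplotype reference"
        )
    novel = (f > 0) & (p == 0)
    if novel.any():
        if on_novel == "drop":
            f = np.where(novel, 0.0, f)
            total = f.sum()
            if total == 0:
                raise ValueError(
                    "all observed haplotypes are absent from the reference"
                )
            f = f / total
        else:
            bad = [pi.haplotype_ids[i] for i in np.nonzero(novel)[0]]
            raise ValueError(
                f"haplotypes {bad} observed in the sample but absent from "
                "the reference frequencies; re-estimate the population "
                "frequencies including this sample's haplotypes, or pass "
                "on_novel='drop' to discard their reads"
            )
    return f, p, pi.informative


def deviation_statistic(
    freqs, pi: PopulationFrequencies, *, on_novel: str = "error"
) -> float:
    """Standardised squared deviation ``S = sum (f_i-p_i)^2 / (p_i(1-p_i))``.

    The sum runs over the k informative haplotypes, including those with
    f_i = 0. S carries all the information about N: E[S] ~ xi * k / N.
    """
    f, p, mask = _prepare(freqs, pi, on_novel=on_novel)
    fm, pm = f[mask], p[mask]
    return float(np.sum((fm - pm) ** 2 / (pm * (1.0 - pm))))


def log_likelihood(
    n: float,
    freqs,
    pi: PopulationFrequencies,
    xi: float = 1.0,
    *,
    on_novel: str = "error",
) -> float:
    """Normal-approximation log-likelihood of N contributors.

    Equals the sum over informative haplotypes of the log-density of a
    Normal(p_i, xi p_i (1-p_i) / n) evaluated at f_i.
    """
    if n <= 0:
        raise ValueError("the number of contributors n must be positive")
    if xi < 1:
        raise ValueError("the variance inflation factor xi must be >= 1")
    f, p, mask = _prepare(freqs, pi, on_novel=on_novel)
    fm, pm = f[mask], p[mask]
    k = mask.sum()
    var_unit = pm * (1.0 - pm)
    s = float(np.sum((fm - pm) ** 2 / var_unit))
    return (
        0.5 * k * math.log(n)
        - 0.5 * k * math.log(xi)
        - 0.5 * float(np.sum(np.log(2.0 * math.pi * var_unit)))
        - n * s / (2.0 * xi)
    )


def mle_contributors(
    freqs,
    pi: PopulationFrequencies,
    xi: float = 1.0,
    *,
    on_novel: str = "error",
) -> float:
    """Closed-form MLE ``N = xi * k / S`` of the contributor number.

    Returns ``math.inf`` when the observed frequencies match the reference
    exactly (S = 0): the likelihood then increases without bound and the
    sample is divergent.
    """
    if xi < 1:
        raise ValueError("the variance inflation factor xi must be >= 1")
    f, p, mask = _prepare(freqs, pi, on_novel=on_novel)
    k = int(mask.sum())
    if k == 0:
        raise ValueError("no haplotype with 0 < p_i < 1; N is not estimable")
    fm, pm = f[mask], p[mask]
    s = float(np.sum((fm - pm) ** 2 / (pm * (1.0 - pm))))
    if s == 0.0:
        return math.inf
    return xi * k / s


@lru_cache(maxsize=256)
def ci_ratio_bounds(k: int, alpha: float) -> tuple[float, float]:
    """Profile-CI bounds as multiples of N_MLE, for k informative haplotypes.

    The likelihood-ratio condition lnL(N) >= lnL(N_MLE) - chi2(1, 1-alpha)/2
    reduces, in the ratio r = N / N_MLE, to

        (k/2) (ln r - r + 1) >= -chi2_quantile / 2

    whose boundary has one root in (0, 1) and one in (1, inf).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly between 0 and 1")
    if k < 1:
        raise ValueError("k must be a positive integer")
    target = -chi2.ppf(1.0 - alpha, df=1) / k  # = ln r - r + 1 at the bounds

    def g(r: float) -> float:
        return math.log(r) - r + 1.0 - target

    lo = brentq(g, 1e-12, 1.0 - 1e-12, xtol=1e-12, rtol=1e-12)
    # upper root: expand bracket until g changes sign
    hi_bracket = 2.0
    while g(hi_bracket) > 0:
        hi_bracket *= 2.0
    hi = brentq(g, 1.0 + 1e-12, hi_bracket, xtol=1e-12, rtol=1e-12)
    return float(lo), float(hi)


def profile_ci(
    freqs,
    pi: PopulationFrequencies,
    xi: float = 1.0,
    alpha: float = 0.05,
    *,
    on_novel: str = "error",
) -> tuple[float, float]:
    """Profile-likelihood confidence interval for the contributor number.

    The interval is the set of N whose log-likelihood is within
    ``chi2.ppf(1 - alpha, 1) / 2`` (1.9207 for alpha = 0.05) of the
    maximum; it always contains the point estimate.
    """
    n_mle = mle_contributors(freqs, pi, xi, on_novel=on_novel)
    if math.isinf(n_mle):
        raise ValueError("divergent sample: the likelihood has no maximum")
    k = pi.k_informative
    r_lo, r_hi = ci_ratio_bounds(k, alpha)
    return n_mle * r_lo, n_mle * r_hi


def ploidy_minimum(k_observed: int, ploidy: int | None) -> int:
    """Minimum number of contributors compatible with k observed haplotypes.

    Haploid loci require one individual per observed haplotype; diploid
    loci require half as many, rounded up (four haplotypes can come from
    two heterozygotes). Unknown ploidy (None) disables the constraint.
    """
    if k_observed < 0:
        raise ValueError("k_observed must be nonnegative")
    if ploidy is None:
        return 1
    if ploidy == 1:
        return int(k_observed)
    if ploidy == 2:
        return int(math.ceil(k_observed / 2))
    raise ValueError("ploidy must be 1, 2 or None")


def _assemble_estimate(
    sample_id: str,
    freqs,
    pi: PopulationFrequencies,
    xi: float,
    alpha: float,
    k_observed: int,
    apply_ploidy_min: bool,
    on_novel: str,
) -> ContributorEstimate:
    n_raw = mle_contributors(freqs, pi, xi, on_novel=on_novel)
    n_min = ploidy_minimum(k_observed, pi.ploidy) if apply_ploidy_min else 1
    if math.isinf(n_raw):
        n_point = max(float(N_CAP), float(n_min))
        return ContributorEstimate(
            sample_id=sample_id,
            n_mle=n_point,
            ci_low=float(n_min) if apply_ploidy_min else 0.0,
            ci_high=math.inf,
            n_min=n_min,
            k_observed=k_observed,
            log_lik_at_mle=math.nan,
            xi_used=xi,
            alpha=alpha,
            censored_at_min=False,
            divergent=True,
        )
    ci_low, ci_high = profile_ci(freqs, pi, xi, alpha, on_novel=on_novel)
    censored = False
    if apply_ploidy_min:
        if n_raw < n_min:
            n_raw = float(n_min)
            censored = True
        ci_low = min(max(ci_low, float(n_min)), n_raw)
        ci_high = max(ci_high, n_raw)
    return ContributorEstimate(
        sample_id=sample_id,
        n_mle=float(n_raw),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_min=n_min,
        k_observed=k_observed,
        log_lik_at_mle=log_likelihood(n_raw, freqs, pi, xi, on_novel=on_novel),
        xi_used=xi,
        alpha=alpha,
        censored_at_min=censored,
    )


def estimate_sample(
    sample: SampleCounts,
    pi: PopulationFrequencies,
    xi: float = 1.0,
    alpha: float = 0.05,
    *,
    apply_ploidy_min: bool = True,
    on_novel: str = "error",
) -> ContributorEstimate:
    """Full contributor estimate for a single sample.

    Computes f from the read counts, maximises the likelihood in closed
    form, profiles the confidence interval, and (optionally) raises the
    point estimate and lower bound to the ploidy minimum.
    """
    if not sample.detected:
        raise ValueError(f"empty sample {sample.sample_id!r}: no reads")
    if sample.haplotype_ids != pi.haplotype_ids:
        raise ValueError(
            "sample and reference use different haplotype indices"
        )
    return _assemble_estimate(
        sample.sample_id,
        sample.freqs,
        pi,
        xi,
        alpha,
        sample.k_observed,
        apply_ploidy_min,
        on_novel,
    )


def estimate_site(
    replicates: Sequence[SampleCounts],
    pi: PopulationFrequencies,
    xi: float = 1.0,
    alpha: float = 0.05,
    *,
    apply_ploidy_min: bool = True,
    combine: str = "average",
    on_novel: str = "error",
) -> ContributorEstimate:
    """Contributor estimate for one site from biological replicates.

    Replicate frequency vectors are combined by an equal-weight average
    (``combine="average"``, the default, matching the equal-weight
    treatment of samples in population-frequency estimation) or by pooling
    raw reads (``combine="pool"``). ``k_observed`` is the union of
    haplotypes observed across replicates.
    """
    replicates = [r for r in replicates if r.detected]
    if not replicates:
        raise ValueError("no replicate with detections")
    ids = replicates[0].haplotype_ids
    for r in replicates[1:]:
        if r.haplotype_ids != ids:
            raise ValueError("replicates use mismatched haplotype indices")
    if ids != pi.haplotype_ids:
        raise ValueError("replicates and reference use different indices")
    if combine == "average":
        f = np.mean([r.freqs for r in replicates], axis=0)
    elif combine == "pool":
        pooled = np.sum([r.read_counts for r in replicates], axis=0)
        f = pooled / pooled.sum()
    else:
        raise ValueError("combine must be 'average' or 'pool'")
    k_obs = int(
        np.any([r.read_counts > 0 for r in replicates], axis=0).sum()
    )
    group = replicates[0].replicate_group or replicates[0].sample_id
    return _assemble_estimate(
        group, f, pi, xi, alpha, k_obs, apply_ploidy_min, on_novel
    )


def mom_contributors(
    freqs,
    pi: PopulationFrequencies,
    xi: float = 1.0,
    *,
    on_novel: str = "error",
) -> float:
    """Method-of-moments contributor estimate (this package's variant).

    Matches the aggregate unstandardised moment: since each squared
    deviation has expectation ``xi p_i (1-p_i) / N``,

        N = xi * sum_i p_i (1-p_i) / sum_i (f_i - p_i)^2.

    Provided for comparison; it is generally less efficient than the MLE
    because it does not weight haplotypes by their information content.
    Returns ``math.inf`` when f matches the reference exactly.
    """
    if xi < 1:
        raise ValueError("the variance inflation factor xi must be >= 1")
    f, p, mask = _prepare(freqs, pi, on_novel=on_novel)
    fm, pm = f[mask], p[mask]
    denom = float(np.sum((fm - pm) ** 2))
    if denom == 0.0:
        return math.inf
    return xi * float(np.sum(pm * (1.0 - pm))) / denom


def combine_loci(
    loci: Sequence[tuple],
    alpha: float = 0.05,
    *,
    sample_id: str = "combined",
    apply_ploidy_min: bool = True,
    on_novel: str = "error",
) -> ContributorEstimate:
    """Joint contributor estimate across unlinked loci for one sample.

    Each element of ``loci`` is ``(freqs, pi, xi)`` for one locus. The
    joint log-likelihood is the sum of the per-locus curves over a shared
    N, which stays in the same one-parameter family: with ``k_tot`` the
    total informative haplotypes and ``S_eff = sum_l S_l / xi_l``,

        N_joint = k_tot / S_eff

    and the profile interval again scales N_joint by ratio bounds at
    k_tot. The ploidy minimum is the largest per-locus minimum.
    """
    if not loci:
        raise ValueError("at least one locus is required")
    k_tot = 0
    s_eff = 0.0
    n_min = 1
    const = 0.0
    for freqs, pi, xi in loci:
        if xi < 1:
            raise ValueError("xi must be >= 1 at every locus")
        f, p, mask = _prepare(freqs, pi, on_novel=on_novel)
        fm, pm = f[mask], p[mask]
        k = int(mask.sum())
        k_tot += k
        s_eff += float(np.sum((fm - pm) ** 2 / (pm * (1.0 - pm)))) / xi
        var_unit = pm * (1.0 - pm)
        const += (
            -0.5 * k * math.log(xi)
            - 0.5 * float(np.sum(np.log(2.0 * math.pi * var_unit)))
        )
        if apply_ploidy_min:
            k_obs = int((np.asarray(freqs, dtype=float) > 0).sum())
            n_min = max(n_min, ploidy_minimum(k_obs, pi.ploidy))
    if k_tot == 0:
        raise ValueError("no informative haplotype at any locus")
    if s_eff == 0.0:
        return ContributorEstimate(
            sample_id=sample_id,
            n_mle=max(float(N_CAP), float(n_min)),
            ci_low=float(n_min),
            ci_high=math.inf,
            n_min=n_min,
            k_observed=k_tot,
            log_lik_at_mle=math.nan,
            xi_used=1.0,
            alpha=alpha,
            divergent=True,
        )
    n_joint = k_tot / s_eff
    r_lo, r_hi = ci_ratio_bounds(k_tot, alpha)
    ci_low, ci_high = n_joint * r_lo, n_joint * r_hi
    censored = False
    if apply_ploidy_min and n_joint < n_min:
        n_joint, censored = float(n_min), True
    if apply_ploidy_min:
        ci_low = min(max(ci_low, float(n_min)), n_joint)
        ci_high = max(ci_high, n_joint)
    log_lik = 0.5 * k_tot * math.log(n_joint) + const - n_joint * s_eff / 2.0
    return ContributorEstimate(
        sample_id=sample_id,
        n_mle=float(n_joint),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_min=n_min,
        k_observed=k_tot,
        log_lik_at_mle=log_lik,
        xi_used=1.0,
        alpha=alpha,
        censored_at_min=censored,
    )


# ---------------------------------------------------------------------------
# vectorised batch path used by the Model/Results layer and experiments
# ---------------------------------------------------------------------------

def batch_estimates(
    freq_matrix: np.ndarray,
    ref_matrix: np.ndarray,
    xi: float = 1.0,
    alpha: float = 0.05,
    *,
    k_observed: np.ndarray,
    ploidy: int | None = 1,
    apply_ploidy_min: bool = True,
) -> dict[str, np.ndarray]:
    """Closed-form MLEs and profile CIs for many samples at once.

    ``freq_matrix`` (M x K) holds within-sample frequencies; ``ref_matrix``
    holds the matching reference frequencies per row (rows differ under
    leave-one-out estimation). Haplotypes with reference frequency outside
    (0, 1) are excluded row-wise. Rows where f has mass on a zero-reference
    haplotype are renormalised over the informative set (the batch path
    serves simulation pipelines where the reference is itself estimated
    from the data, so novel haplotypes simply have not been seen elsewhere).
    Returns arrays: n_mle, ci_low, ci_high, n_min, k, divergent, censored.
    """
    f = np.asarray(freq_matrix, dtype=float)
    p = np.asarray(ref_matrix, dtype=float)
    if f.shape != p.shape:
        raise ValueError("frequency and reference matrices differ in shape")
    if xi < 1:
        raise ValueError("xi must be >= 1")
    mask = (p > 0.0) & (p < 1.0)
    f_eff = np.where(mask, f, 0.0)
    row_mass = f_eff.sum(axis=1)
    if np.any(row_mass == 0):
        raise ValueError("a sample has no reads on informative haplotypes")
    f_eff = f_eff / row_mass[:, None]
    denom = np.where(mask, p * (1.0 - p), 1.0)
    dev = np.where(mask, (f_eff - p) ** 2 / denom, 0.0)
    s = dev.sum(axis=1)
    k = mask.sum(axis=1)
    if np.any(k == 0):
        raise ValueError("a sample has no informative haplotype")
    divergent = s == 0.0
    with np.errstate(divide="ignore"):
        n_mle = np.where(divergent, np.inf, xi * k / np.where(s == 0, 1, s))

    r_lo = np.empty_like(n_mle)
    r_hi = np.empty_like(n_mle)
    for kk in np.unique(k):
        lo, hi = ci_ratio_bounds(int(kk), alpha)
        sel = k == kk
        r_lo[sel], r_hi[sel] = lo, hi
    ci_low = n_mle * r_lo
    ci_high = np.where(divergent, np.inf, n_mle * r_hi)
    n_point = np.where(divergent, max(N_CAP, 1.0), n_mle)

    k_obs = np.asarray(k_observed, dtype=int)
    if apply_ploidy_min:
        if ploidy is None:
            n_min = np.ones_like(k_obs)
        elif ploidy == 1:
            n_min = k_obs.copy()
        elif ploidy == 2:
            n_min = np.ceil(k_obs / 2).astype(int)
        else:
            raise ValueError("ploidy must be 1, 2 or None")
        censored = (~divergent) & (n_point < n_min)
        n_point = np.maximum(n_point, n_min)
        ci_low = np.minimum(np.maximum(ci_low, n_min), n_point)
        ci_high = np.maximum(ci_high, n_point)
    else:
        n_min = np.ones_like(k_obs)
        censored = np.zeros_like(divergent)
    ci_low = np.where(divergent, n_min.astype(float), ci_low)
    return {
        "n_mle": n_point,
        "ci_low": ci_low,
        "ci_high": ci_high,
        "n_min": n_min,
        "k_informative": k,
        "deviation_statistic": s,
        "divergent": divergent,
        "censored_at_min": censored,
    }
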