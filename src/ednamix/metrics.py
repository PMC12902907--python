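"""Evaluation metrics and end-to-end simulation experiments.

Two experiment drivers reproduce the package's validation workflow:

* :func:`estimation_experiment` — simulate many independent sites, derive
  leave-one-out population frequencies from the simulated data itself,
  estimate the contributor number per site and score the estimates
  against the recorded truth (Pearson correlation, mean relative error,
  confidence-interval coverage).
* :func:`convergence_experiment` — measure how fast the leave-one-out
  population-frequency estimate approaches the true vector as the number
  of samples grows, across mean-contributor levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ContributorEstimate, PopulationFrequencies
from .estimator import batch_estimates
from .popfreq import loo_frequency_matrix
from .simulate import PRESETS, SimulationConfig, run_scenario

__all__ = [
    "pearson_r",
    "mean_relative_error",
    "ci_coverage",
    "ScenarioMetrics",
    "estimation_experiment",
    "convergence_experiment",
    "samples_needed",
]


def _finite_pairs(true_n, est_n):
    t = np.asarray(true_n, dtype=float)
    e = np.asarray(est_n, dtype=float)
    if t.shape != e.shape:
        raise ValueError("true and estimated vectors differ in length")
    keep = np.isfinite(e)
    return t[keep], e[keep], int((~keep).sum())


def pearson_r(true_n, est_n) -> float:
    """Pearson correlation between true and estimated contributor numbers.

    Divergent (non-finite) estimates are excluded pairwise.
    """
    t, e, _ = _finite_pairs(true_n, est_n)
    if t.size < 2:
        raise ValueError("need at least two finite pairs")
    return float(np.corrcoef(t, e)[0, 1])


def mean_relative_error(true_n, est_n) -> float:
    """Mean relative error in percent: ``100 * mean(|est - true| / true)``.

    The true value sits in the denominator; divergent estimates are
    excluded.
    """
    t, e, _ = _finite_pairs(true_n, est_n)
    if np.any(t <= 0):
        raise ValueError("true contributor numbers must be positive")
    return float(100.0 * np.mean(np.abs(e - t) / t))


def ci_coverage(true_n, estimates) -> float:
    """Percentage of samples whose confidence interval covers the truth.

    ``estimates`` may be a sequence of :class:`ContributorEstimate` or a
    ``(ci_low, ci_high)`` pair of arrays.
    """
    t = np.asarray(true_n, dtype=float)
    if len(estimates) == 2 and not isinstance(
        estimates[0], ContributorEstimate
    ):
        low = np.asarray(estimates[0], dtype=float)
        high = np.asarray(estimates[1], dtype=float)
    else:
        low = np.array([e.ci_low for e in estimates], dtype=float)
        high = np.array([e.ci_high for e in estimates], dtype=float)
    if t.shape != low.shape or t.shape != high.shape:
        raise ValueError("length mismatch between truth and intervals")
    covered = (low <= t) & (t <= high)
    return float(100.0 * covered.mean())


@dataclass
class ScenarioMetrics:
    """Summary of one estimation experiment plus its per-sample table."""

    pearson_r: float
    mre_percent: float
    coverage_percent: float
    n_samples: int
    n_divergent: int
    n_censored: int
    alpha: float
    xi: float
    table: pd.DataFrame = field(repr=False)
    meta: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "mre_percent": self.mre_percent,
            "coverage_percent": self.coverage_percent,
            "n_samples": self.n_samples,
            "n_divergent": self.n_divergent,
            "n_censored": self.n_censored,
            "alpha": self.alpha,
            "xi": self.xi,
            **self.meta,
        }


def estimation_experiment(
    pi_true: PopulationFrequencies,
    preset: str = "ideal",
    n_samples: int = 5000,
    n_bottle_replicates: int = 1,
    xi: float = 1.0,
    alpha: float = 0.05,
    apply_ploidy_min: bool = True,
    use_true_pi: bool = False,
    rng: np.random.Generator | int | None = None,
    **config_overrides,
) -> ScenarioMetrics:
    """Simulate, estimate and score one full scenario.

    Sites are simulated under the named preset with the true contributor
    number drawn uniformly on 1-200. Reference frequencies are the
    leave-one-out average of the per-site frequency vectors (replicates
    averaged first), mirroring the recommended field workflow; pass
    ``use_true_pi=True`` to ablate with the exact generating vector.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    config = PRESETS[preset](
        pi_true,
        n_bottle_replicates=n_bottle_replicates,
        **config_overrides,
    )
    ds = run_scenario(config, n_samples, rng)
    freqs = ds.combined_freqs()
    if use_true_pi:
        refs = np.broadcast_to(pi_true.probs, freqs.shape)
    else:
        refs = loo_frequency_matrix(freqs)
    res = batch_estimates(
        freqs,
        refs,
        xi=xi,
        alpha=alpha,
        k_observed=ds.k_observed(),
        ploidy=pi_true.ploidy,
        apply_ploidy_min=apply_ploidy_min,
    )
    true_n = ds.truth["true_n"].to_numpy()
    est = np.where(res["divergent"], np.inf, res["n_mle"])
    table = pd.DataFrame(
        {
            "sample_id": ds.sample_ids,
            "true_n": true_n,
            "n_mle": res["n_mle"],
            "ci_low": res["ci_low"],
            "ci_high": res["ci_high"],
            "n_min": res["n_min"],
            "k_observed": ds.k_observed(),
            "divergent": res["divergent"],
            "censored_at_min": res["censored_at_min"],
        }
    )
    return ScenarioMetrics(
        pearson_r=pearson_r(true_n, est),
        mre_percent=mean_relative_error(true_n, est),
        coverage_percent=ci_coverage(
            true_n, (res["ci_low"], res["ci_high"])
        ),
        n_samples=n_samples,
        n_divergent=int(res["divergent"].sum()),
        n_censored=int(res["censored_at_min"].sum()),
        alpha=alpha,
        xi=xi,
        table=table,
        meta={
            "preset": preset,
            "n_bottle_replicates": n_bottle_replicates,
            "marker": pi_true.locus_label,
            "reference": "true_pi" if use_true_pi else "loo",
        },
    )


def convergence_experiment(
    pi_true: PopulationFrequencies,
    contributor_levels: Sequence[float] = (1, 2, 5, 10, 25, 50, 100),
    sample_counts: Sequence[int] = (5, 10, 20, 50, 100),
    n_reps: int = 30,
    preset: str = "realistic",
    rng: np.random.Generator | int | None = None,
    **config_overrides,
) -> pd.DataFrame:
    """Mean squared error of LOO frequency estimates vs sampling effort.

    For each mean-contributor level, ``n_reps`` datasets of
    ``max(sample_counts)`` sites are simulated (per-site contributor
    numbers zero-truncated Poisson around the level); each smaller sample
    count reuses the first sites of the same dataset, a nested design that
    reduces Monte-Carlo noise between curve points. The reported cell
    value is the MSE between each site's leave-one-out frequency estimate
    and the true vector, averaged over sites and replicate datasets.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sample_counts = sorted(sample_counts)
    if sample_counts[0] < 2:
        raise ValueError("LOO needs at least two samples per dataset")
    n_max = sample_counts[-1]
    p_true = pi_true.probs
    rows = []
    for level in contributor_levels:
        config = PRESETS[preset](
            pi_true, mean_contributors=float(level), **config_overrides
        )
        mse_sums = {m: 0.0 for m in sample_counts}
        for _ in range(n_reps):
            ds = run_scenario(config, n_max, rng)
            freqs = ds.combined_freqs()
            for m in sample_counts:
                loo = loo_frequency_matrix(freqs[:m])
                mse_sums[m] += float(
                    np.mean((loo - p_true) ** 2, axis=1).mean()
                )
        for m in sample_counts:
            rows.append(
                {
                    "marker": pi_true.locus_label,
                    "mean_contributors": level,
                    "n_samples": m,
                    "mean_mse": mse_sums[m] / n_reps,
                }
            )
    return pd.DataFrame(rows)


def samples_needed(curves: pd.DataFrame, threshold: float) -> int | None:
    """Smallest sample count whose mean MSE is below ``threshold``
    simultaneously for every (marker, contributor-level) curve.

    ``curves`` is the output of :func:`convergence_experiment`
    (concatenate frames to combine markers). Returns ``None`` when no
    tested sample count satisfies all curves.
    """
    pivot = curves.pivot_table(
        index="n_samples",
        columns=["marker", "mean_contributors"],
        values="mean_mse",
    )
    ok = (pivot <= threshold).all(axis=1)
    passing = ok[ok].index
    return int(passing.min()) if len(passing) else None
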