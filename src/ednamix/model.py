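"""Model/Results interface for contributor-number estimation.

`ContributorModel` bundles a haplotype-by-sample read-count table with the
assumptions of the normal-approximation likelihood (reference frequencies,
variance inflation ``xi``, locus ploidy); its :meth:`~ContributorModel.fit`
returns a :class:`ContributorResults` carrying per-site point estimates,
profile-likelihood intervals, diagnostics and a ``summary()`` table, in
the style of statsmodels.

Example
-------
>>> import numpy as np
>>> from ednamix import ContributorModel
>>> from ednamix.markers import HYPERVARIABLE_17
>>> from ednamix.simulate import ideal_config, run_scenario
>>> ds = run_scenario(ideal_config(HYPERVARIABLE_17), 200, rng=7)
>>> res = ContributorModel.from_dataset(ds).fit()
>>> res.frame.columns.tolist()[:3]
['sample_id', 'n_mle', 'ci_low']
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .core import PopulationFrequencies, SampleCounts, aligned_frequency_matrix
from .estimator import batch_estimates
from .popfreq import estimate_pop_frequencies, loo_frequency_matrix

__all__ = ["ContributorModel", "ContributorResults"]


class ContributorModel:
    """Number-of-contributors model for one locus over many eDNA samples.

    Parameters
    ----------
    samples
        :class:`~ednamix.core.SampleCounts` sharing one haplotype index.
        Samples with the same ``replicate_group`` are treated as
        biological replicates of one site and their frequency vectors are
        averaged with equal weight before estimation.
    pop_freqs
        Reference population frequencies. When omitted, leave-one-out
        frequencies are derived from the data themselves (requires at
        least two detected sites).
    xi
        Variance-inflation factor (>= 1) absorbing all noise downstream
        of contributor sampling; 1 assumes none.
    ploidy
        Locus ploidy for the minimum-contributor bound (1, 2 or None to
        disable). Defaults to the reference's ploidy, else haploid.
    """

    def __init__(
        self,
        samples: Sequence[SampleCounts],
        pop_freqs: PopulationFrequencies | None = None,
        *,
        xi: float = 1.0,
        ploidy: int | None = None,
    ):
        samples = [s for s in samples if s.detected]
        if not samples:
            raise ValueError("no samples with detections")
        ids = samples[0].haplotype_ids
        for s in samples[1:]:
            if s.haplotype_ids != ids:
                raise ValueError("samples use mismatched haplotype indices")
        if pop_freqs is not None and pop_freqs.haplotype_ids != ids:
            raise ValueError(
                "reference frequencies use a different haplotype index"
            )
        if xi < 1:
            raise ValueError("xi must be >= 1")
        self.samples = samples
        self.pop_freqs = pop_freqs
        self.xi = float(xi)
        if ploidy is None and pop_freqs is not None:
            ploidy = pop_freqs.ploidy
        self.ploidy = 1 if ploidy is None and pop_freqs is None else ploidy
        self.haplotype_ids = ids
        # group biological replicates into sites, preserving input order
        groups: dict[str, list[SampleCounts]] = {}
        for s in samples:
            key = s.replicate_group or s.sample_id
            groups.setdefault(key, []).append(s)
        self.site_ids = list(groups)
        self._site_samples = groups

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        pop_freqs: PopulationFrequencies | None = None,
        *,
        sample_col: str = "sample_id",
        haplotype_col: str = "haplotype_id",
        reads_col: str = "reads",
        replicate_col: str | None = "replicate",
        **kwargs,
    ) -> "ContributorModel":
        """Build from a long-format count table.

        Expected columns: sample id, haplotype id, read count, and
        optionally a replicate label; (sample, replicate) pairs become
        individual samples grouped per sample id.
        """
        from .io import samples_from_long  # local import to avoid cycle

        samples = samples_from_long(
            df,
            sample_col=sample_col,
            haplotype_col=haplotype_col,
            reads_col=reads_col,
            replicate_col=replicate_col,
            haplotype_ids=None
            if pop_freqs is None
            else pop_freqs.haplotype_ids,
        )
        return cls(samples, pop_freqs, **kwargs)

    @classmethod
    def from_dataset(cls, dataset, pop_freqs=None, **kwargs):
        """Build from a :class:`~ednamix.simulate.SimulatedDataset`."""
        return cls(dataset.to_sample_counts(), pop_freqs, **kwargs)

    # -- fitting -----------------------------------------------------------
    def fit(
        self,
        alpha: float = 0.05,
        *,
        apply_ploidy_min: bool = True,
    ) -> "ContributorResults":
        """Estimate the contributor number for every site.

        Maximises the normal-approximation likelihood in closed form and
        profiles the 100(1-alpha)% confidence interval per site. With no
        user-supplied reference, each site is scored against the
        leave-one-out average of all other sites' frequency vectors.
        """
        site_freqs = []
        k_obs = []
        for sid in self.site_ids:
            reps = self._site_samples[sid]
            site_freqs.append(np.mean([r.freqs for r in reps], axis=0))
            k_obs.append(
                int(np.any([r.read_counts > 0 for r in reps], axis=0).sum())
            )
        freqs = np.vstack(site_freqs)
        if self.pop_freqs is not None:
            refs = np.broadcast_to(self.pop_freqs.probs, freqs.shape)
            reference = "given"
        else:
            if freqs.shape[0] < 2:
                raise ValueError(
                    "leave-one-out reference requires at least two sites; "
                    "supply pop_freqs for a single site"
                )
            refs = loo_frequency_matrix(freqs)
            reference = "loo"
        res = batch_estimates(
            freqs,
            refs,
            xi=self.xi,
            alpha=alpha,
            k_observed=np.array(k_obs),
            ploidy=self.ploidy,
            apply_ploidy_min=apply_ploidy_min,
        )
        frame = pd.DataFrame(
            {
                "sample_id": self.site_ids,
                "n_mle": res["n_mle"],
                "ci_low": res["ci_low"],
                "ci_high": res["ci_high"],
                "n_min": res["n_min"],
                "k_observed": k_obs,
                "k_informative": res["k_informative"],
                "deviation_statistic": res["deviation_statistic"],
                "censored_at_min": res["censored_at_min"],
                "divergent": res["divergent"],
            }
        )
        return ContributorResults(
            model=self,
            frame=frame,
            alpha=alpha,
            reference=reference,
            apply_ploidy_min=apply_ploidy_min,
        )

    def pooled_frequencies(self, **kwargs) -> PopulationFrequencies:
        """Equal-weight population-frequency estimate from all samples."""
        return estimate_pop_frequencies(
            self.samples, ploidy=self.ploidy, **kwargs
        )

    @property
    def frequency_matrix(self) -> np.ndarray:
        return aligned_frequency_matrix(self.samples)


class ContributorResults:
    """Fit results: per-site estimates, intervals and diagnostics."""

    def __init__(self, model, frame, alpha, reference, apply_ploidy_min):
        self.model = model
        self.frame = frame
        self.alpha = alpha
        self.reference = reference
        self.apply_ploidy_min = apply_ploidy_min

    @property
    def n_mle(self) -> np.ndarray:
        return self.frame["n_mle"].to_numpy()

    @property
    def conf_int(self) -> np.ndarray:
        return self.frame[["ci_low", "ci_high"]].to_numpy()

    @property
    def n_divergent(self) -> int:
        return int(self.frame["divergent"].sum())

    def summary(self, max_rows: int = 20) -> str:
        """Human-readable fit summary (statsmodels-style text block)."""
        m = self.model
        head = [
            "Contributor Number Estimation".center(62),
            "=" * 62,
            f"No. sites:         {len(self.frame):>6}"
            f"      Haplotypes (K):    {len(m.haplotype_ids):>6}",
            f"Reference:      {self.reference:>9}"
            f"      xi (inflation):    {m.xi:>6.3g}",
            f"Ploidy:         {str(m.ploidy):>9}"
            f"      Conf. level:       {1 - self.alpha:>6.0%}",
            f"Divergent:      {self.n_divergent:>9}"
            f"      Censored at min:   "
            f"{int(self.frame['censored_at_min'].sum()):>6}",
            "-" * 62,
        ]
        cols = ["sample_id", "n_mle", "ci_low", "ci_high", "n_min",
                "k_observed"]
        body = self.frame[cols].head(max_rows).to_string(
            index=False, float_format=lambda v: f"{v:.2f}"
        )
        tail = []
        if len(self.frame) > max_rows:
            tail.append(f"... {len(self.frame) - max_rows} more sites")
        tail.append("=" * 62)
        return "\n".join(head + [body] + tail)

    def to_csv(self, path, **meta) -> None:
        """Write the per-site table with a metadata comment header."""
        from .io import write_estimates

        write_estimates(
            self.frame,
            path,
            xi=self.model.xi,
            ploidy=self.model.ploidy,
            alpha=self.alpha,
            reference=self.reference,
            **meta,
        )

    def plot_estimates(self, true_n=None, ax=None):
        """Point estimates with CI bars, optionally against true values."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        f = self.frame
        x = np.asarray(true_n) if true_n is not None else np.arange(len(f))
        finite = np.isfinite(f["n_mle"])
        err = np.vstack(
            [
                f["n_mle"] - f["ci_low"],
                np.minimum(f["ci_high"], 10 * f["n_mle"]) - f["n_mle"],
            ]
        )
        ax.errorbar(
            x[finite],
            f["n_mle"][finite],
            yerr=err[:, finite],
            fmt="o",
            ms=3,
            alpha=0.6,
            lw=0.8,
        )
        if true_n is not None:
            lim = [0, max(np.max(x), np.nanmax(f["n_mle"][finite]))]
            ax.plot(lim, lim, "k--", lw=1)
            ax.set_xlabel("true contributors")
        ax.set_ylabel("estimated contributors")
        return ax
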