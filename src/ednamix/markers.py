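"""Example marker frequency vectors used throughout docs and experiments.

Three hypothetical mitochondrial-like (haploid) markers spanning the range
of intraspecific diversity found in practice:

* ``HYPERVARIABLE_17`` — 17 haplotypes with gently decreasing frequencies;
  the best case for frequency-based contributor inference.
* ``VARIABLE_14`` — 14 haplotypes with one common allele (0.40) and a long
  tail of rare ones.
* ``CONSERVED_6`` — 6 haplotypes dominated by a single allele at 0.86,
  typical of conserved metabarcoding loci such as 12S or COI.
"""

from __future__ import annotations

from .core import PopulationFrequencies

__all__ = ["HYPERVARIABLE_17", "VARIABLE_14", "CONSERVED_6", "MARKERS"]


def _marker(label: str, probs) -> PopulationFrequencies:
    ids = tuple(f"hap{i + 1}" for i in range(len(probs)))
    return PopulationFrequencies(
        haplotype_ids=ids, probs=probs, locus_label=label, ploidy=1
    )


HYPERVARIABLE_17 = _marker(
    "hypervariable17",
    (0.140, 0.120, 0.120, 0.100, 0.100, 0.080, 0.080, 0.060, 0.060,
     0.040, 0.040, 0.020, 0.020, 0.005, 0.005, 0.005, 0.005),
)

VARIABLE_14 = _marker(
    "variable14",
    (0.400, 0.170, 0.170, 0.050, 0.050, 0.050, 0.050,
     0.010, 0.010, 0.010, 0.010, 0.010, 0.005, 0.005),
)

CONSERVED_6 = _marker(
    "conserved6", (0.860, 0.120, 0.005, 0.005, 0.005, 0.005)
)

MARKERS = {
    "hypervariable17": HYPERVARIABLE_17,
    "variable14": VARIABLE_14,
    "conserved6": CONSERVED_6,
}
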