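"""Cohorts of LTR retrotransposon 5'/3' LTR pairs with known insertion ages.

At insertion the two long terminal repeats of an element are identical;
each then accumulates substitutions independently at the clock rate, so
the expected pairwise LTR divergence of an element of age T is 2 T r.
Families descend from unrelated templates; within a family, elements
differ by lineage drift proportional to their age.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .. import dna


@dataclass
class LTRPair:
    element_id: str
    family_id: str
    ltr5: str
    ltr3: str
    chrom_class: str = "B"        # "A" or "B"
    true_age_my: float | None = None


def make_ltr_cohort(n: int = 200, median_age_my: float = 0.46,
                    rate: float = 1.3e-8, ltr_len: int = 4000,
                    n_families: int = 6, seed: int = 0,
                    fixed_divergence: float | None = None) -> list[LTRPair]:
    """Draw ``n`` elements with exponential ages (or a fixed LTR divergence).

    ``fixed_divergence`` overrides the age draw: every element gets the age
    T = d / (2 r) whose expected pairwise LTR divergence is exactly ``d``
    (used for estimator-bias checks at a controlled divergence).
    """
    rng = np.random.default_rng(seed)
    templates = [dna.random_dna(rng, ltr_len) for _ in range(n_families)]
    if fixed_divergence is not None:
        ages = np.full(n, fixed_divergence / (2.0 * rate) / 1e6)
    else:
        ages = rng.exponential(median_age_my / np.log(2), n)
    fam_idx = rng.integers(0, n_families, n)
    classes = np.where(rng.random(n) < 0.5, "A", "B")

    cohort = []
    for i in range(n):
        d_branch = ages[i] * 1e6 * rate
        base = dna.jc_mutate(templates[fam_idx[i]], d_branch, rng)
        cohort.append(LTRPair(
            element_id=f"elt{i:04d}",
            family_id=f"FAM{fam_idx[i]:02d}",
            ltr5=dna.jc_mutate(base, d_branch, rng),
            ltr3=dna.jc_mutate(base, d_branch, rng),
            chrom_class=str(classes[i]),
            true_age_my=float(ages[i]),
        ))
    return cohort
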