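"""Repeat monomer and transposable-element template library.

The library holds the four repeat classes the synthetic B chromosome is
built from: a B-specific tandem monomer (the candidate cis drive factor,
restricted to the B), a 180-bp knob monomer shared between A and B
heterochromatin, a centromeric satellite, and a short telomeric filler
unit.  The B-specific monomer is derived from the knob monomer so the two
are related on the sequence level but stay below 80% global identity,
which keeps their separation non-trivial for k-mer classification.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .. import dna

DEFAULT_MONOMER_LENGTHS = {
    "b_specific": 150,
    "knob": 180,
    "centromeric_satellite": 156,
    "telomeric": 21,
}

MIN_MONOMER_LEN = 20
MIN_TE_LTR_LEN = 100


@dataclass
class TETemplate:
    name: str
    internal: str
    ltr: str

    @property
    def length(self) -> int:
        return len(self.internal) + 2 * len(self.ltr)


@dataclass
class RepeatLibrary:
    monomers: dict[str, str]
    te_templates: list[TETemplate] = field(default_factory=list)

    def monomer(self, name: str) -> str:
        return self.monomers[name]


def make_repeat_library(seed: int, monomer_lengths: dict[str, int] | None = None,
                        n_te_templates: int = 24, te_ltr_len: int = 350,
                        te_internal_len: tuple[int, int] = (1200, 2400)
                        ) -> RepeatLibrary:
    """Deterministically generate the repeat library for a given seed."""
    lengths = dict(DEFAULT_MONOMER_LENGTHS)
    if monomer_lengths:
        lengths.update(monomer_lengths)
    for name, L in lengths.items():
        if L < MIN_MONOMER_LEN:
            raise ValueError(f"monomer {name!r} length {L} < {MIN_MONOMER_LEN}")
    if te_ltr_len < MIN_TE_LTR_LEN:
        raise ValueError(f"te LTR length {te_ltr_len} < {MIN_TE_LTR_LEN}")

    rng = np.random.default_rng(seed)
    knob = dna.random_dna(rng, lengths["knob"])

    # derive the B-specific monomer from the knob so they are related but
    # distinguishable; retune the substitution load until global identity
    # lands in [50, 80)
    b_specific = None
    for rate in (0.30, 0.35, 0.25, 0.40, 0.45, 0.20):
        tiled = (knob * (lengths["b_specific"] // len(knob) + 1))[: lengths["b_specific"]]
        candidate = dna.point_mutate(tiled, rate, rng)
        ident = dna.global_identity(candidate, knob)
        if 50.0 <= ident < 80.0:
            b_specific = candidate
            break
    if b_specific is None:  # pragma: no cover - defensive
        raise RuntimeError("could not tune b_specific/knob identity into [50, 80)")

    monomers = {
        "knob": knob,
        "b_specific": b_specific,
        "centromeric_satellite": dna.random_dna(rng, lengths["centromeric_satellite"]),
        "telomeric": dna.random_dna(rng, lengths["telomeric"]),
    }
    templates = []
    for i in range(n_te_templates):
        internal_len = int(rng.integers(te_internal_len[0], te_internal_len[1] + 1))
        templates.append(
            TETemplate(
                name=f"TE{i:02d}",
                internal=dna.random_dna(rng, internal_len),
                ltr=dna.random_dna(rng, te_ltr_len),
            )
        )
    return RepeatLibrary(monomers=monomers, te_templates=templates)
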