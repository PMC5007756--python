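"""Population-level verification statistics for candidate variants.

Genotyped population samples (haploid mitochondrial sequences, one per
individual) are compared with a Pearson chi-square on the 2 x k table of
variant / non-variant counts, without continuity correction. Alignment
columns from multi-species comparisons are scored by the fraction of
non-gap species sharing the reference base, to gauge how conserved the
mutated position is.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

GAP_CHARS = frozenset("-.")


@dataclass(frozen=True)
class GenotypeTable:
    variant_id: str
    n_variant: Mapping[str, int]  # population -> carriers of the variant allele
    n_total: Mapping[str, int]  # population -> haploid individuals genotyped

    def __post_init__(self) -> None:
        if len(self.n_total) < 2:
            raise ValueError("need at least two populations")
        for pop, n in self.n_total.items():
            k = self.n_variant.get(pop)
            if k is None:
                raise ValueError(f"population {pop!r} missing variant count")
            if not 0 <= k <= n:
                raise ValueError(f"population {pop!r}: 0 <= n_variant <= n_total violated")

    def frequencies(self) -> dict[str, float]:
        return {p: self.n_variant[p] / self.n_total[p] for p in self.n_total}


@dataclass(frozen=True)
class AlignmentColumnProfile:
    variant_id: str
    bases: Mapping[str, str]  # species -> base at the homologous column ('-' for gap)


def allele_chisq(table: GenotypeTable) -> tuple[float, int, float]:
    """Pearson chi-square of allele counts across k populations.

    Returns (chi2, df, p) with df = k - 1 and no continuity correction.
    Monomorphic tables (variant count 0 or n in every population jointly,
    i.e. an all-zero expected row) return chi2 = 0, p = 1.
    """
    pops = list(table.n_total)
    if any(table.n_total[p] == 0 for p in pops):
        raise ValueError("every population must have n_total > 0")
    var = np.array([table.n_variant[p] for p in pops], dtype=float)
    non = np.array([table.n_total[p] - table.n_variant[p] for p in pops], dtype=float)
    df = len(pops) - 1
    if var.sum() == 0 or non.sum() == 0:
        return 0.0, df, 1.0
    chi2, p, dof, _ = stats.chi2_contingency(np.vstack([var, non]), correction=False)
    assert dof == df
    return float(chi2), df, float(p)


def column_conservation(
    profile: AlignmentColumnProfile, ref_base: str
) -> tuple[float, dict[str, list[str]]]:
    """Fraction of non-gap species whose base equals ``ref_base``, plus the
    species carrying each observed base."""
    non_gap = {sp: b.upper() for sp, b in profile.bases.items() if b not in GAP_CHARS}
    if len(non_gap) < 2:
        raise ValueError("need at least two non-gap species in the column")
    by_base: dict[str, list[str]] = {}
    for sp, b in sorted(non_gap.items()):
        by_base.setdefault(b, []).append(sp)
    conserved = sum(b == ref_base.upper() for b in non_gap.values())
    return conserved / len(non_gap), by_base
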