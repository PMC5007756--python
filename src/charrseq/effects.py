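"""Functional classification of SNPs within mRNA contigs.

A site is located relative to the explicit CDS interval (5'UTR / coding /
3'UTR, 1-based inclusive) and coding changes are translated with the
standard genetic code into "synonymous" or "X to Y" single-letter
amino-acid consequences ("X to *" for gained stops).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from .data_io import CdsAnnotation
from .variants import FilterTrace

REGIONS = ("5prime", "coding", "3prime")


@dataclass(frozen=True)
class EffectCall:
    region: str
    consequence: str = ""  # "" for UTRs; "synonymous" | "X to Y" | "unknown" for coding
    codon_index: int | None = None  # 1-based codon within CDS
    codon_position: int | None = None  # 1..3

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"invalid region {self.region!r}")
        if (self.region == "coding") != bool(self.consequence):
            raise ValueError("consequence must be nonempty iff region is coding")


class ReferenceMismatchError(ValueError):
    """The annotated sequence disagrees with the site's reference base."""


def locate_region(position: int, cds: CdsAnnotation) -> str:
    if not 1 <= position <= len(cds.sequence):
        raise ValueError(
            f"{cds.contig_id}: position {position} outside 1..{len(cds.sequence)}"
        )
    if position < cds.cds_start:
        return "5prime"
    if position > cds.cds_end:
        return "3prime"
    return "coding"


def classify_coding_change(
    position: int, ref_base: str, alt_base: str, cds: CdsAnnotation
) -> EffectCall:
    """Translate the reference and mutated codon; report the consequence."""
    if locate_region(position, cds) != "coding":
        raise ValueError(f"{cds.contig_id}:{position} is not within the CDS")
    if cds.sequence[position - 1] != ref_base:
        raise ReferenceMismatchError(
            f"{cds.contig_id}:{position}: sequence has "
            f"{cds.sequence[position - 1]!r}, site says {ref_base!r}"
        )
    offset = position - cds.cds_start  # 0-based within CDS
    codon_index = offset // 3
    codon_position = offset % 3
    start = cds.cds_start - 1 + 3 * codon_index
    ref_codon = cds.sequence[start : start + 3]
    alt_codon = ref_codon[:codon_position] + alt_base + ref_codon[codon_position + 1 :]
    if "N" in ref_codon or "N" in alt_codon:
        consequence = "unknown"
    else:
        aa_ref = str(Seq(ref_codon).translate(table=cds.codon_table))
        aa_alt = str(Seq(alt_codon).translate(table=cds.codon_table))
        consequence = "synonymous" if aa_ref == aa_alt else f"{aa_ref} to {aa_alt}"
    return EffectCall(
        region="coding",
        consequence=consequence,
        codon_index=codon_index + 1,
        codon_position=codon_position + 1,
    )


def classify_site(
    position: int, ref_base: str, alt_base: str, cds: CdsAnnotation
) -> EffectCall:
    region = locate_region(position, cds)
    if region != "coding":
        return EffectCall(region=region)
    return classify_coding_change(position, ref_base, alt_base, cds)


EFFECT_CATEGORIES = ("5prime", "synonymous", "non-synonymous", "3prime")


def effect_category(call: EffectCall) -> str:
    if call.region != "coding":
        return call.region
    return "synonymous" if call.consequence == "synonymous" else "non-synonymous"


def effect_table(
    traces: Sequence[FilterTrace], cds_map: Mapping[str, CdsAnnotation]
) -> tuple[pd.DataFrame, dict]:
    """Tally effect categories of retained sites per UNI/REP stratum.

    Returns the category x stratum table (plus a "no annotation" row) and a
    Pearson chi-square (3 df) comparing the category distribution between
    strata; the statistic is NA when a stratum has no classified sites.
    """
    tab = pd.DataFrame(
        0, index=list(EFFECT_CATEGORIES) + ["no annotation"], columns=["UNI", "REP"]
    )
    for t in traces:
        if not t.retained:
            continue
        site = t.site
        cds = cds_map.get(site.contig_id)
        if cds is None:
            tab.loc["no annotation", site.stratum] += 1
            continue
        call = classify_site(site.position, site.ref_base, site.alt_base, cds)
        tab.loc[effect_category(call), site.stratum] += 1
    sub = tab.loc[list(EFFECT_CATEGORIES)]
    test: dict = {"chi2": float("nan"), "df": 3, "p": float("nan")}
    if (sub.sum(axis=0) > 0).all() and (sub.sum(axis=1) > 0).sum() >= 2:
        used = sub.loc[sub.sum(axis=1) > 0]
        chi2, p, df, _ = stats.chi2_contingency(used.T, correction=False)
        test = {"chi2": float(chi2), "df": int(df), "p": float(p)}
    return tab, test
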