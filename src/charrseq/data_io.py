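"""Readers and writers for the tables the pipeline touches.

All files and reports use 1-based inclusive coordinates on the sense strand
of the mRNA contig. Read counts are stored as (ref, alt) integer pairs;
frequencies are always derived downstream, never stored.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

VALID_BASES = frozenset("ACGT")
VALID_STRATA = ("UNI", "REP")


class FormatError(ValueError):
    """A file does not match the expected tabular layout."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


@dataclass(frozen=True)
class SampleMeta:
    """One pooled sample: a morph x timepoint pool of embryos."""

    sample_id: str
    morph: str
    timepoint: float
    pool_size: int = 6
    ploidy: int = 2

    def __post_init__(self) -> None:
        if self.pool_size < 1:
            raise ValidationError(f"sample {self.sample_id}: pool_size must be >= 1")
        if self.ploidy not in (1, 2):
            raise ValidationError(f"sample {self.sample_id}: ploidy must be 1 or 2")
        if self.timepoint <= 0:
            raise ValidationError(f"sample {self.sample_id}: timepoint must be positive")


def validate_samples(samples: Sequence[SampleMeta]) -> None:
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValidationError("sample_ids must be unique")
    if not samples:
        raise ValidationError("at least one sample required")


@dataclass(frozen=True)
class SiteCounts:
    """Per-site (ref, alt) read counts for every registered sample.

    ``stratum`` records whether the candidate came from uniquely (UNI) or
    multiply (REP) mapped reads; the two strata run through the filter
    cascade independently.
    """

    contig_id: str
    position: int
    ref_base: str
    alt_base: str
    stratum: str
    counts: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(
                f"{self.contig_id}:{self.position}: position must be >= 1 (1-based)"
            )
        for b, name in ((self.ref_base, "ref"), (self.alt_base, "alt")):
            if b not in VALID_BASES:
                raise ValidationError(
                    f"{self.contig_id}:{self.position}: invalid {name} base {b!r}"
                )
        if self.ref_base == self.alt_base:
            raise ValidationError(
                f"{self.contig_id}:{self.position}: ref and alt bases are identical"
            )
        if self.stratum not in VALID_STRATA:
            raise ValidationError(
                f"{self.contig_id}:{self.position}: stratum must be UNI or REP"
            )
        for sid, (r, a) in self.counts.items():
            if r < 0 or a < 0:
                raise ValidationError(
                    f"{self.contig_id}:{self.position}: negative count for {sid}"
                )

    def coverage(self, sample_id: str) -> int:
        r, a = self.counts[sample_id]
        return r + a

    def alt_frequency(self, sample_id: str) -> float | None:
        """Alt-allele read frequency, or None for a sample with no coverage."""
        r, a = self.counts[sample_id]
        return a / (r + a) if r + a > 0 else None


@dataclass(frozen=True)
class CdsAnnotation:
    """mRNA sequence with its coding interval (1-based inclusive)."""

    contig_id: str
    cds_start: int
    cds_end: int
    sequence: str
    codon_table: int = 1

    def __post_init__(self) -> None:
        if not 1 <= self.cds_start <= self.cds_end:
            raise ValidationError(f"{self.contig_id}: invalid CDS interval")
        if self.cds_end > len(self.sequence):
            raise ValidationError(f"{self.contig_id}: CDS end beyond sequence")
        if (self.cds_end - self.cds_start + 1) % 3:
            raise ValidationError(
                f"{self.contig_id}: CDS length {self.cds_end - self.cds_start + 1} "
                "not a multiple of 3"
            )
        if set(self.sequence) - set("ACGTN"):
            raise ValidationError(f"{self.contig_id}: sequence alphabet not in ACGTN")


@dataclass
class CountMatrix:
    """Contig x sample integer read counts with a contig -> group annotation."""

    counts: pd.DataFrame
    annotation: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValidationError("count matrix contains negative entries")
        if not all(
            pd.api.types.is_integer_dtype(t) for t in self.counts.dtypes
        ):
            raise ValidationError("count matrix must be integer-valued")
        if self.annotation is None:
            self.annotation = pd.Series(self.counts.index, index=self.counts.index)
        missing = self.counts.index.difference(self.annotation.index)
        if len(missing):
            raise ValidationError(f"contigs without annotation: {list(missing)[:5]}")
        self.annotation = self.annotation.loc[self.counts.index]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


# ---------------------------------------------------------------------------
# sample metadata


def read_samples(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "morph", "timepoint", "pool_size", "ploidy"}
    if not required <= set(df.columns):
        raise FormatError(f"sample table missing columns: {sorted(required - set(df.columns))}")
    samples = [
        SampleMeta(
            sample_id=row.sample_id,
            morph=row.morph,
            timepoint=float(row.timepoint),
            pool_size=int(row.pool_size),
            ploidy=int(row.ploidy),
        )
        for row in df.itertuples()
    ]
    validate_samples(samples)
    return samples


def write_samples(samples: Sequence[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        [
            dict(
                sample_id=s.sample_id,
                morph=s.morph,
                timepoint=s.timepoint,
                pool_size=s.pool_size,
                ploidy=s.ploidy,
            )
            for s in samples
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# site counts

_PAIR_RE = re.compile(r"^(\d+),(\d+)$")


def read_site_counts(path: str | Path, samples: Sequence[SampleMeta]) -> list[SiteCounts]:
    """Read the site-count TSV: contig, pos, ref, alt, stratum, then one
    "ref,alt" column per sample in registration order."""
    validate_samples(samples)
    df = pd.read_csv(path, sep="\t", dtype=str)
    fixed = ["contig", "pos", "ref", "alt", "stratum"]
    if list(df.columns[:5]) != fixed:
        raise FormatError(f"site-count file must start with columns {fixed}")
    for s in samples:
        if s.sample_id not in df.columns:
            raise FormatError(f"site-count file missing sample column {s.sample_id!r}")
    sites: list[SiteCounts] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rec = row._asdict()
        counts: dict[str, tuple[int, int]] = {}
        for s in samples:
            m = _PAIR_RE.match(str(rec[s.sample_id]).strip())
            if not m:
                raise FormatError(
                    f"line {i}: malformed count pair {rec[s.sample_id]!r} "
                    f"for sample {s.sample_id}"
                )
            counts[s.sample_id] = (int(m.group(1)), int(m.group(2)))
        try:
            pos = int(rec["pos"])
        except ValueError as exc:
            raise FormatError(f"line {i}: non-integer position {rec['pos']!r}") from exc
        try:
            sites.append(
                SiteCounts(
                    contig_id=str(rec["contig"]),
                    position=pos,
                    ref_base=str(rec["ref"]),
                    alt_base=str(rec["alt"]),
                    stratum=str(rec["stratum"]),
                    counts=counts,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"line {i}: {exc}") from exc
    return sites


def write_site_counts(
    sites: Iterable[SiteCounts], samples: Sequence[SampleMeta], path: str | Path
) -> None:
    rows = []
    for s in sites:
        row = dict(
            contig=s.contig_id, pos=s.position, ref=s.ref_base, alt=s.alt_base,
            stratum=s.stratum,
        )
        for sm in samples:
            r, a = s.counts[sm.sample_id]
            row[sm.sample_id] = f"{r},{a}"
        rows.append(row)
    cols = ["contig", "pos", "ref", "alt", "stratum"] + [s.sample_id for s in samples]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# count matrices / CDS annotations


def read_count_matrix(path: str | Path, annotation_path: str | Path | None = None) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or (vals % 1 != 0).any():
            raise FormatError(f"non-integer count in sample column {col!r}")
    df = df.astype(int)
    annotation = None
    if annotation_path is not None:
        ann = pd.read_csv(annotation_path, sep="\t", dtype=str)
        if list(ann.columns[:2]) != ["contig", "annotation"]:
            raise FormatError("annotation file must have columns: contig, annotation")
        annotation = ann.set_index("contig")["annotation"]
    return CountMatrix(counts=df, annotation=annotation)


def write_count_matrix(cm: CountMatrix, path: str | Path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="contig")


def read_cds(fasta_path: str | Path, intervals_path: str | Path) -> list[CdsAnnotation]:
    """Read contig sequences (FASTA) plus a TSV of CDS intervals
    (columns: contig, cds_start, cds_end)."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    df = pd.read_csv(intervals_path, sep="\t", dtype=str)
    if not {"contig", "cds_start", "cds_end"} <= set(df.columns):
        raise FormatError("interval file must have columns: contig, cds_start, cds_end")
    out: list[CdsAnnotation] = []
    for row in df.itertuples():
        if row.contig not in seqs:
            raise FormatError(f"contig {row.contig!r} not present in FASTA")
        out.append(
            CdsAnnotation(
                contig_id=row.contig,
                cds_start=int(row.cds_start),
                cds_end=int(row.cds_end),
                sequence=seqs[row.contig],
            )
        )
    return out


# ---------------------------------------------------------------------------
# VCF export of retained sites


def write_vcf(
    records: Iterable[tuple[SiteCounts, "object"]],
    morphs: Sequence[str],
    path: str | Path,
) -> None:
    """Export retained SNPs as a minimal VCF v4.2 with per-morph alt
    frequencies and their absolute difference in INFO.

    ``records`` pairs each site with its MorphAlleleSummary (duck-typed:
    needs .freq mapping and .delta).
    """
    m1, m2 = morphs[0], morphs[1]
    lines = [
        "##fileformat=VCFv4.2",
        f'##INFO=<ID=AF_{m1},Number=1,Type=Float,Description="Alt frequency in {m1} pool">',
        f'##INFO=<ID=AF_{m2},Number=1,Type=Float,Description="Alt frequency in {m2} pool">',
        '##INFO=<ID=DELTA,Number=1,Type=Float,Description="Absolute frequency difference">',
        '##INFO=<ID=STRATUM,Number=1,Type=String,Description="UNI or REP mapping stratum">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for site, summ in records:
        info = (
            f"AF_{m1}={summ.freq[m1]:.4f};AF_{m2}={summ.freq[m2]:.4f};"
            f"DELTA={summ.delta:.4f};STRATUM={site.stratum}"
        )
        lines.append(
            f"{site.contig_id}\t{site.position}\t.\t{site.ref_base}\t"
            f"{site.alt_base}\t.\tPASS\t{info}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
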