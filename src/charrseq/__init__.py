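"""charrseq: pooled RNA-seq SNP filtering and expression analysis for a
genome-duplicated salmonid.

The package separates true segregating SNPs from paralog-divergence
artifacts and interspecific fixed differences in pooled transcriptome data,
quantifies paralog-group differential expression with NB-GLMs, predicts SNP
effects within mRNAs, computes qPCR 2^-ddCt relative expression, and runs
population-level verification statistics. A synthetic-data module generates
every input under the study's sampling design.
"""

from importlib.resources import files

import pandas as pd

from . import data_io, effects, expression, qpcr, synthetic, variants, verification

__version__ = "0.1.0"

__all__ = [
    "data_io",
    "variants",
    "effects",
    "expression",
    "qpcr",
    "verification",
    "synthetic",
    "load_nearly_fixed_snps",
]


def load_nearly_fixed_snps() -> pd.DataFrame:
    """The 60 published nearly-fixed candidate SNPs (per-morph alt-allele
    frequencies from the pooled read counts, with mapping stratum and
    predicted effect), shipped with the package."""
    path = files("charrseq").joinpath("data/nearly_fixed_snps.tsv")
    with path.open() as fh:
        return pd.read_csv(fh, sep="\t")
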