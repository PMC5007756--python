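import pytest

from charrseq.data_io import SampleMeta, SiteCounts

MORPHS = ("AC", "SB")
TIMES = (141.0, 163.0, 200.0, 433.0)


@pytest.fixture
def samples8() -> list[SampleMeta]:
    """The study layout: 2 morphs x 4 timepoints, one pool of 6 diploids each."""
    return [
        SampleMeta(sample_id=f"{m}_{t:g}", morph=m, timepoint=t, pool_size=6, ploidy=2)
        for m in MORPHS
        for t in TIMES
    ]


@pytest.fixture
def make_site(samples8):
    """Build a SiteCounts from 8 (ref, alt) pairs in sample order."""

    def build(pairs, stratum="UNI", contig="c1", pos=100, ref="A", alt="T"):
        assert len(pairs) == len(samples8)
        return SiteCounts(
            contig_id=contig,
            position=pos,
            ref_base=ref,
            alt_base=alt,
            stratum=stratum,
            counts={s.sample_id: tuple(p) for s, p in zip(samples8, pairs)},
        )

    return build
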