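import pytest

from bccluster.assembly_io import Assembly, PaddedContig, ReadPlacement


def make_placement(read_id, gapped_read, padded_start=1, strand="forward", clip=None):
    return ReadPlacement(
        read_id=read_id,
        base_name=read_id.split(".")[0],
        strand=strand,
        padded_start=padded_start,
        gapped_read=gapped_read,
        clip_range=clip or (1, len(gapped_read)),
    )


@pytest.fixture
def mini_assembly():
    """One contig with a padded consensus and two reads (one reverse)."""
    contig = PaddedContig(
        contig_id="contig1",
        padded_consensus="ACGT*ACGTA",
        placements=[
            make_placement("read1", "ACGT*A"),
            make_placement("read2", "GT*ACGTA", padded_start=3, strand="reverse"),
        ],
    )
    return Assembly(contigs=[contig], source="fixture")
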