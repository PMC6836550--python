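import pytest

from cytowgs import GenomeModel, GenomicInterval, Panel


@pytest.fixture
def small_genome() -> GenomeModel:
    """Two-chromosome toy genome with a repeat-flanked (NAHR-prone) region."""
    return GenomeModel(
        contigs={"1": 249_250_621, "2": 243_199_373},
        repeat_regions=[
            GenomicInterval("1", 145_000_000, 145_500_000),
            GenomicInterval("1", 147_800_000, 148_200_000),
        ],
    )


@pytest.fixture
def id_panel() -> Panel:
    return Panel(
        "ID",
        {
            "GENE1": [GenomicInterval("2", 166_000_000, 167_000_000)],
            "GENE2": [GenomicInterval("1", 10_000_000, 10_050_000)],
            "GENE3": [GenomicInterval("1", 80_000_000, 80_120_000)],
        },
    )
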