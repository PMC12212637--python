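import pytest

from hrdbench.genome_segments import ASCNVCallset, GenomeBuild, Segment
from hrdbench.scar_scores import ScarConfig


@pytest.fixture(scope="session")
def toy_genome() -> GenomeBuild:
    """Two 1 Mb autosomes with central centromeres, for per-bp oracles."""
    return GenomeBuild(
        name="toy",
        chromosomes=(("1", 1_000_000), ("2", 1_000_000)),
        centromeres={"1": (450_000, 550_000), "2": (450_000, 550_000)},
    )


@pytest.fixture(scope="session")
def toy_scar_config() -> ScarConfig:
    """Scar thresholds scaled 1:100 to match the 1 Mb toy chromosomes."""
    return ScarConfig(
        loh_min_len=150_000,
        tai_min_len=110_000,
        lst_min_flank=100_000,
        lst_max_gap=30_000,
        lst_smooth_min=30_000,
        whole_chrom_window=10_000,
    )


def make_callset(rows, **meta) -> ASCNVCallset:
    """rows: (chrom, start, end, a_cn, b_cn) tuples."""
    meta.setdefault("sample_id", "test")
    segs = [Segment(c, s, e, None, a, b) for c, s, e, a, b in rows]
    return ASCNVCallset(segments=segs, **meta)
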