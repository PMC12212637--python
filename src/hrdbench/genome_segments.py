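"""Data model, genome constants, and I/O for allele-specific copy-number callsets.

Coordinate conventions
----------------------
Internally every interval is 0-based half-open.  Segment tables on disk are
1-based inclusive (start is shifted by one on read/write; the inclusive end
equals the half-open end).  BED blacklists are 0-based half-open, as usual.

"Mb" throughout the package means exactly 1,000,000 bp, so the scar and
filtering thresholds (15/11/10/3 Mb) are exact integers.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import _intervals

logger = logging.getLogger(__name__)

MB = 1_000_000

SEGMENT_COLUMNS = ["chrom", "start", "end", "total_cn", "A_cn", "B_cn"]


class AlleleStatus(str, enum.Enum):
    """Per-allele copy-number state."""

    LOSS = "loss"
    NEUTRAL = "neutral"
    GAIN = "gain"

    def __str__(self) -> str:  # serialize as bare word
        return self.value


def derive_allele_status(cn: float, loss_max: float = 0.5, gain_min: float = 1.5) -> AlleleStatus:
    """Classify one allele's copy number.

    A copy number <= 0.5 is a loss and >= 1.5 is a gain; the band between is
    neutral (the diploid single-allele expectation is 1).
    """
    if cn < 0:
        raise ValueError(f"negative copy number: {cn}")
    if cn <= loss_max:
        return AlleleStatus.LOSS
    if cn >= gain_min:
        return AlleleStatus.GAIN
    return AlleleStatus.NEUTRAL


def derive_total_status(total_cn: float, loss_max: float = 1.5, gain_min: float = 2.5) -> AlleleStatus:
    """Classify a total copy number against the diploid expectation of 2.

    Mirrors the per-allele rule (neutral band of +/- 0.5 around the diploid
    value): total <= 1.5 is a loss, total >= 2.5 a gain.
    """
    if total_cn < 0:
        raise ValueError(f"negative copy number: {total_cn}")
    if total_cn <= loss_max:
        return AlleleStatus.LOSS
    if total_cn >= gain_min:
        return AlleleStatus.GAIN
    return AlleleStatus.NEUTRAL


# ---------------------------------------------------------------------------
# Genome build
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeBuild:
    """Chromosome coordinate authority: names, lengths, centromere intervals.

    ``chromosomes`` is an ordered list of (name, length) pairs; ``centromeres``
    maps chromosome name to a 0-based half-open (start, end) interval lying
    strictly inside the chromosome.  Only autosomes participate in length
    math (``autosome_total``).
    """

    name: str
    chromosomes: tuple[tuple[str, int], ...]
    centromeres: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        for chrom, (cs, ce) in self.centromeres.items():
            if chrom not in lengths:
                raise ValueError(f"centromere on unknown chromosome {chrom!r}")
            if not (0 < cs < ce < lengths[chrom]):
                raise ValueError(f"centromere {chrom}:{cs}-{ce} not strictly inside chromosome")

    @property
    def autosomes(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.chromosomes if _is_autosome_name(name))

    @property
    def autosome_total(self) -> int:
        lengths = dict(self.chromosomes)
        return sum(lengths[c] for c in self.autosomes)

    def length(self, chrom: str) -> int:
        try:
            return dict(self.chromosomes)[chrom]
        except KeyError:
            raise KeyError(
                f"unknown chromosome {chrom!r}; accepted: {[n for n, _ in self.chromosomes]}"
            ) from None

    def centromere(self, chrom: str) -> tuple[int, int]:
        return self.centromeres[chrom]

    def arms(self, chrom: str) -> list[tuple[str, int, int]]:
        """(arm, start, end) for the p and q arms, excluding the centromere."""
        n = self.length(chrom)
        if chrom not in self.centromeres:
            return [("p", 0, n)]
        cs, ce = self.centromeres[chrom]
        return [("p", 0, cs), ("q", ce, n)]


def _is_autosome_name(name: str) -> bool:
    return name.isdigit() and 1 <= int(name) <= 22


def normalize_chrom(name: str) -> str:
    """Strip a leading 'chr' prefix so mixed-dialect inputs agree."""
    name = str(name).strip()
    return name[3:] if name.lower().startswith("chr") else name


# GRCh37/hs37d5 autosome lengths and centromere intervals (UCSC gap table).
_GRCH37_LENGTHS = {
    "1": 249250621, "2": 243199373, "3": 198022430, "4": 191154276,
    "5": 180915260, "6": 171115067, "7": 159138663, "8": 146364022,
    "9": 141213431, "10": 135534747, "11": 135006516, "12": 133851895,
    "13": 115169878, "14": 107349540, "15": 102531392, "16": 90354753,
    "17": 81195210, "18": 78077248, "19": 59128983, "20": 63025520,
    "21": 48129895, "22": 51304566,
    "X": 155270560, "Y": 59373566,
}
_GRCH37_CENTROMERES = {
    "1": (121535434, 124535434), "2": (92326171, 95326171),
    "3": (90504854, 93504854), "4": (49660117, 52660117),
    "5": (46405641, 49405641), "6": (58830166, 61830166),
    "7": (58054331, 61054331), "8": (43838887, 46838887),
    "9": (47367679, 50367679), "10": (39254935, 42254935),
    "11": (51644205, 54644205), "12": (34856694, 37856694),
    "13": (16000000, 19000000), "14": (16000000, 19000000),
    "15": (17000000, 20000000), "16": (35335801, 38335801),
    "17": (22263006, 25263006), "18": (15460898, 18460898),
    "19": (24681782, 27681782), "20": (26369569, 29369569),
    "21": (11288129, 14288129), "22": (13000000, 16000000),
    "X": (58632012, 61632012), "Y": (10104553, 13104553),
}

GRCH37 = GenomeBuild(
    name="GRCh37",
    chromosomes=tuple(_GRCH37_LENGTHS.items()),
    centromeres=_GRCH37_CENTROMERES,
)
assert GRCH37.autosome_total == 2_881_033_286


def get_genome(name: str) -> GenomeBuild:
    key = name.lower().replace("-", "").replace("_", "")
    if key in {"grch37", "hg19", "hs37d5", "37d5", "b37"}:
        return GRCH37
    raise KeyError(f"unknown genome build {name!r} (available: grch37)")


# ---------------------------------------------------------------------------
# Segments and callsets
# ---------------------------------------------------------------------------


@dataclass
class Segment:
    """One allele-specific copy-number interval (0-based half-open).

    ``a_cn`` is the major and ``b_cn`` the minor allele copy number; the
    constructor swaps them if given in the other order.  A missing
    ``total_cn`` is imputed as ``a_cn + b_cn``.
    """

    chrom: str
    start: int
    end: int
    total_cn: float | None
    a_cn: float
    b_cn: float

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom)
        if self.start >= self.end:
            raise ValueError(f"empty segment {self.chrom}:{self.start}-{self.end}")
        if self.a_cn < 0 or self.b_cn < 0:
            raise ValueError(f"negative allele copy number on {self.chrom}:{self.start}-{self.end}")
        if self.a_cn < self.b_cn:
            self.a_cn, self.b_cn = self.b_cn, self.a_cn
        if self.total_cn is None:
            self.total_cn = self.a_cn + self.b_cn
        elif self.total_cn < 0:
            raise ValueError(f"negative total copy number on {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def cn_state(self) -> tuple[float, float, float]:
        return (self.total_cn, self.a_cn, self.b_cn)

    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class ASCNVCallset:
    """One sample x pipeline allele-specific CNV callset with provenance.

    Segments are kept sorted by (chrom, start) and must not overlap within a
    chromosome.  ``purity`` is the estimated tumor-cell fraction, ``ploidy``
    the estimated genome-wide average total copy number; either may be None
    when the caller did not report it.
    """

    sample_id: str
    segments: list[Segment]
    cell_line: str | None = None
    mass_ratio: float | None = None
    pipeline: str | None = None
    replicate: int | None = None
    purity: float | None = None
    ploidy: float | None = None

    def __post_init__(self) -> None:
        self.segments = sorted(self.segments, key=lambda s: (_chrom_key(s.chrom), s.start))
        prev: Segment | None = None
        for seg in self.segments:
            if prev is not None and prev.chrom == seg.chrom and seg.start < prev.end:
                raise ValueError(
                    f"overlapping segments in {self.sample_id}: "
                    f"{prev.chrom}:{prev.start}-{prev.end} and {seg.chrom}:{seg.start}-{seg.end}"
                )
            prev = seg

    def by_chrom(self) -> dict[str, list[Segment]]:
        out: dict[str, list[Segment]] = {}
        for seg in self.segments:
            out.setdefault(seg.chrom, []).append(seg)
        return out

    def total_length(self) -> int:
        return sum(s.length for s in self.segments)

    def length_weighted_ploidy(self) -> float | None:
        n = self.total_length()
        if n == 0:
            return None
        return sum(s.total_cn * s.length for s in self.segments) / n

    def replace_segments(self, segments: Iterable[Segment]) -> "ASCNVCallset":
        return replace(self, segments=list(segments))


def _chrom_key(chrom: str) -> tuple[int, str]:
    return (int(chrom), "") if chrom.isdigit() else (100, chrom)


def autosomal_coverage_fraction(callset: ASCNVCallset, genome: GenomeBuild) -> float:
    """Fraction of the genome's total autosomal length covered by the callset."""
    covered = sum(s.length for s in callset.segments if _is_autosome_name(s.chrom))
    return covered / genome.autosome_total


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_callset(
    path: str | Path,
    genome: GenomeBuild = GRCH37,
    autosomes_only: bool = True,
    total_cn_tolerance: float = 0.01,
    **metadata,
) -> ASCNVCallset:
    """Read a 1-based inclusive segment table into a validated callset.

    The file must have header columns ``chrom start end total_cn A_cn B_cn``
    (tab-separated); ``total_cn`` may be empty and is then imputed as the
    allele sum.  Rows on non-autosomes are dropped (with a logged count)
    unless ``autosomes_only=False``.  Unknown chromosomes, negative copy
    numbers, and overlapping segments are hard errors.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns and c != "total_cn"]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    known = {name for name, _ in genome.chromosomes}
    segments: list[Segment] = []
    dropped = 0
    for row in df.itertuples(index=False):
        chrom = normalize_chrom(row.chrom)
        if chrom not in known:
            raise ValueError(
                f"{path}: unknown chromosome {row.chrom!r}; accepted: {sorted(known, key=_chrom_key)}"
            )
        if autosomes_only and not _is_autosome_name(chrom):
            dropped += 1
            continue
        total = getattr(row, "total_cn", None)
        total = None if total is None or pd.isna(total) else float(total)
        seg = Segment(
            chrom=chrom,
            start=int(row.start) - 1,  # 1-based inclusive -> 0-based half-open
            end=int(row.end),
            total_cn=total,
            a_cn=float(row.A_cn),
            b_cn=float(row.B_cn),
        )
        if total is not None and abs(seg.total_cn - (seg.a_cn + seg.b_cn)) > total_cn_tolerance:
            raise ValueError(
                f"{path}: total_cn {seg.total_cn} != A_cn+B_cn {seg.a_cn + seg.b_cn} "
                f"at {chrom}:{row.start}-{row.end}"
            )
        if seg.end > genome.length(chrom):
            raise ValueError(f"{path}: segment {chrom}:{row.start}-{row.end} beyond chromosome end")
        segments.append(seg)
    if dropped:
        logger.info("%s: dropped %d non-autosomal rows", path, dropped)
    metadata.setdefault("sample_id", path.stem)
    return ASCNVCallset(segments=segments, **metadata)


def write_callset(callset: ASCNVCallset, path: str | Path) -> None:
    """Write a callset back to the 1-based inclusive segment-table dialect."""
    rows = [
        (s.chrom, s.start + 1, s.end, s.total_cn, s.a_cn, s.b_cn)
        for s in callset.segments
    ]
    pd.DataFrame(rows, columns=SEGMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def write_regions(regions: Iterable[tuple[str, int, int, str]], path: str | Path) -> None:
    """Write classified scar regions as a 4-column 1-based inclusive table."""
    rows = [(chrom, start + 1, end, label) for chrom, start, end, label in regions]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "classification"]).to_csv(
        path, sep="\t", index=False
    )


def read_regions(path: str | Path) -> list[tuple[str, int, int, str]]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        (normalize_chrom(r.chrom), int(r.start) - 1, int(r.end), str(r.classification))
        for r in df.itertuples(index=False)
    ]


def write_reference_regions(
    regions: Iterable[tuple[str, int, int, AlleleStatus, AlleleStatus]], path: str | Path
) -> None:
    """Write high-confidence ASCNV regions as the 5-column status table."""
    rows = [(c, s + 1, e, str(a), str(b)) for c, s, e, a, b in regions]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "A_status", "B_status"]).to_csv(
        path, sep="\t", index=False
    )


def read_blacklist(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Read a BED3 blacklist; returns merged, sorted intervals per chromosome."""
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected at least 3 BED columns")
            try:
                chrom = normalize_chrom(parts[0])
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED line: {exc}") from None
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            per_chrom.setdefault(chrom, []).append((start, end))
    return {chrom: _intervals.merge(ivs) for chrom, ivs in per_chrom.items()}


def blacklist_total_length(blacklist: dict[str, list[tuple[int, int]]]) -> int:
    return sum(_intervals.total_length(ivs) for ivs in blacklist.values())
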