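"""High-confidence ASCNV reference construction from multi-pipeline callsets.

The workflow mirrors how multi-lab benchmarking consortia distill one
trusted callset from many noisy ones:

1. *Reliability filtering* — drop low-mass-ratio gradients, gradients whose
   median estimated purity falls below a floor, callsets whose ploidy sits
   outside a window around the per-cell-line median, and callsets covering
   too little of the autosomes.
2. *Blacklist / minimum length* — subtract blacklisted spans from every
   segment and discard remnants shorter than 10 Mb.
3. *Minimal-node voting* — chop the surviving segments into disjoint
   minimal nodes (interval-tree boundary splitting), tally the
   (total_cn, A_cn, B_cn) combinations observed at each node, keep nodes
   detected at least three times by at least two pipelines, and designate
   the combination whose frequency strictly exceeds 50%.
4. *Merge and trim* — merge abutting nodes with identical designated copy
   numbers and drop merged segments shorter than 3 Mb.

The result carries allele statuses, a scar-region catalog, and reference
HRD scores recomputed from the consensus segments.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from . import _intervals
from .genome_segments import (
    MB,
    ASCNVCallset,
    AlleleStatus,
    GenomeBuild,
    Segment,
    autosomal_coverage_fraction,
    derive_allele_status,
)
from .scar_scores import DEFAULT_CONFIG, HRDScores, ScarConfig, compute_scores, scar_region_catalog

Blacklist = Mapping[str, Sequence[tuple[int, int]]]


@dataclass(frozen=True)
class CallsetFilterCriteria:
    """Thresholds of the reliable-callset selection stage."""

    min_purity: float = 0.30
    ploidy_window: float = 0.15  # fractional window around per-cell-line median
    min_autosome_coverage: float = 0.70
    excluded_mass_ratios: frozenset[float] = frozenset({0.10, 0.20})

    def __post_init__(self) -> None:
        if not (0 < self.min_purity <= 1 and 0 < self.min_autosome_coverage <= 1):
            raise ValueError("purity and coverage thresholds must lie in (0, 1]")
        if self.ploidy_window < 0:
            raise ValueError("ploidy window must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CallsetFilterCriteria":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "excluded_mass_ratios" in data:
            data["excluded_mass_ratios"] = frozenset(float(x) for x in data["excluded_mass_ratios"])
        return cls(**data)


@dataclass
class Node:
    """One minimal disjoint interval with its vote tally."""

    chrom: str
    start: int
    end: int
    votes: Counter  # (total_cn, a_cn, b_cn) -> tally
    pipelines: set[str]

    @property
    def detection_count(self) -> int:
        return sum(self.votes.values())


@dataclass
class ReferenceDataset:
    """High-confidence ASCNV regions plus scar catalog and reference scores."""

    regions: list[Segment]  # consensus segments with designated copy numbers
    statuses: list[tuple[AlleleStatus, AlleleStatus]]  # (A_status, B_status) per region
    scar_regions: list[tuple[str, int, int, str]]
    scores: HRDScores
    provenance: dict = field(default_factory=dict)

    def as_callset(self, sample_id: str = "reference") -> ASCNVCallset:
        return ASCNVCallset(sample_id=sample_id, segments=list(self.regions))

    def status_rows(self) -> list[tuple[str, int, int, AlleleStatus, AlleleStatus]]:
        return [
            (seg.chrom, seg.start, seg.end, a, b)
            for seg, (a, b) in zip(self.regions, self.statuses)
        ]


class EmptyConsensusError(RuntimeError):
    """No callsets (or no nodes) survived filtering; review the criteria."""


# ---------------------------------------------------------------------------
# Stage 1: reliable callsets
# ---------------------------------------------------------------------------


def median_purity_by_ratio(
    callsets: Iterable[ASCNVCallset], min_purity: float = 0.30
) -> dict[tuple[str, float], tuple[float, bool]]:
    """Per (cell line, mass ratio): median estimated purity and retention flag.

    The median across the pipelines/replicates of a dilution gradient is
    adopted as the gradient's actual tumor purity; gradients below
    ``min_purity`` are flagged excluded.
    """
    groups: dict[tuple[str, float], list[float]] = {}
    for cs in callsets:
        key = (cs.cell_line, cs.mass_ratio)
        groups.setdefault(key, [])
        if cs.purity is not None:
            groups[key].append(cs.purity)
    out = {}
    for key, purities in groups.items():
        if not purities:
            raise ValueError(f"no purity estimates available for cell line/ratio group {key}")
        med = statistics.median(purities)
        out[key] = (med, med >= min_purity)
    return out


def select_reliable_callsets(
    callsets: Sequence[ASCNVCallset],
    criteria: CallsetFilterCriteria,
    genome: GenomeBuild,
) -> tuple[list[ASCNVCallset], dict[str, list[str]]]:
    """Apply the four reliability rules; returns (retained, exclusion log)."""
    log: dict[str, list[str]] = {"mass_ratio": [], "purity": [], "ploidy": [], "coverage": []}

    stage = []
    for cs in callsets:
        if any(abs(cs.mass_ratio - r) < 1e-9 for r in criteria.excluded_mass_ratios):
            log["mass_ratio"].append(cs.sample_id)
        else:
            stage.append(cs)

    purity_map = median_purity_by_ratio(stage, criteria.min_purity) if stage else {}
    survivors = []
    for cs in stage:
        _, keep = purity_map[(cs.cell_line, cs.mass_ratio)]
        if keep:
            survivors.append(cs)
        else:
            log["purity"].append(cs.sample_id)

    # per-cell-line median ploidy window
    by_line: dict[str, list[float]] = {}
    for cs in survivors:
        if cs.ploidy is not None:
            by_line.setdefault(cs.cell_line, []).append(cs.ploidy)
    stage2 = []
    for cs in survivors:
        med = statistics.median(by_line.get(cs.cell_line, [cs.ploidy or 0]))
        lo = med * (1 - criteria.ploidy_window)
        hi = med * (1 + criteria.ploidy_window)
        if cs.ploidy is not None and not (lo <= cs.ploidy <= hi):
            log["ploidy"].append(cs.sample_id)
        else:
            stage2.append(cs)

    retained = []
    for cs in stage2:
        if autosomal_coverage_fraction(cs, genome) < criteria.min_autosome_coverage:
            log["coverage"].append(cs.sample_id)
        else:
            retained.append(cs)

    if not retained:
        raise EmptyConsensusError(
            "no callsets survived reliability filtering; review CallsetFilterCriteria "
            f"(exclusions: { {k: len(v) for k, v in log.items()} })"
        )
    return retained, log


# ---------------------------------------------------------------------------
# Stage 2: blacklist and minimum length
# ---------------------------------------------------------------------------


def apply_blacklist_and_min_length(
    callset: ASCNVCallset,
    blacklist: Blacklist | None,
    min_len: int = 10 * MB,
) -> ASCNVCallset:
    """Subtract blacklisted spans, then drop remnants shorter than ``min_len``."""
    blacklist = blacklist or {}
    kept: list[Segment] = []
    for seg in callset.segments:
        cuts = blacklist.get(seg.chrom, [])
        for s, e in _intervals.subtract(seg.interval(), cuts):
            if e - s >= min_len:
                kept.append(
                    Segment(seg.chrom, s, e, seg.total_cn, seg.a_cn, seg.b_cn)
                )
    return callset.replace_segments(kept)


# ---------------------------------------------------------------------------
# Stage 3: minimal nodes and voting
# ---------------------------------------------------------------------------


def build_nodes(
    callsets: Sequence[ASCNVCallset], round_decimals: int | None = None
) -> list[Node]:
    """Chop all segments into disjoint minimal nodes and tally votes.

    Every callset whose segment covers a node contributes one vote for its
    (total_cn, A_cn, B_cn) combination; replicates count separately.
    """
    chroms: dict[str, IntervalTree] = {}
    # the callset index disambiguates otherwise-identical contributions
    # (IntervalTree is a set; replicates must each keep their vote)
    for idx, cs in enumerate(callsets):
        for seg in cs.segments:
            state = seg.cn_state
            if round_decimals is not None:
                state = tuple(round(x, round_decimals) for x in state)
            chroms.setdefault(seg.chrom, IntervalTree()).addi(
                seg.start, seg.end, (state, cs.pipeline, idx)
            )
    nodes: list[Node] = []
    for chrom, tree in sorted(chroms.items()):
        tree.split_overlaps()
        grouped: dict[tuple[int, int], list] = {}
        for iv in tree:
            grouped.setdefault((iv.begin, iv.end), []).append(iv.data)
        for (start, end), data in sorted(grouped.items()):
            votes = Counter(state for state, _pipe, _idx in data)
            pipelines = {pipe for _state, pipe, _idx in data}
            nodes.append(Node(chrom, start, end, votes, pipelines))
    return nodes


def vote_nodes(
    nodes: Iterable[Node],
    min_detections: int = 3,
    min_pipelines: int = 2,
    min_freq: float = 0.5,
) -> list[tuple[str, int, int, tuple[float, float, float]]]:
    """Retain well-supported nodes and designate their consensus copy state.

    A node passes when detected at least ``min_detections`` times by at
    least ``min_pipelines`` distinct pipelines; within a passing node, the
    combination whose frequency strictly exceeds ``min_freq`` of the node's
    detections is designated.  Ties at exactly the threshold discard the
    node.
    """
    designated = []
    for node in nodes:
        if node.detection_count < min_detections or len(node.pipelines) < min_pipelines:
            continue
        state, tally = node.votes.most_common(1)[0]
        if tally / node.detection_count > min_freq:
            designated.append((node.chrom, node.start, node.end, state))
    return designated


# ---------------------------------------------------------------------------
# Stage 4: merge and trim
# ---------------------------------------------------------------------------


def merge_and_trim(
    designated: Iterable[tuple[str, int, int, tuple[float, float, float]]],
    min_final_len: int = 3 * MB,
) -> list[Segment]:
    """Merge abutting nodes with identical copy numbers; drop short remnants."""
    merged: list[tuple[str, int, int, tuple[float, float, float]]] = []
    key = lambda d: ((int(d[0]), "") if d[0].isdigit() else (100, d[0]), d[1])
    for chrom, start, end, state in sorted(designated, key=key):
        if merged and merged[-1][0] == chrom and merged[-1][2] == start and merged[-1][3] == state:
            prev = merged[-1]
            merged[-1] = (chrom, prev[1], end, state)
        else:
            merged.append((chrom, start, end, state))
    return [
        Segment(chrom, start, end, total, a, b)
        for chrom, start, end, (total, a, b) in merged
        if end - start >= min_final_len
    ]


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def build_reference(
    callsets: Sequence[ASCNVCallset],
    blacklist: Blacklist | None,
    criteria: CallsetFilterCriteria,
    genome: GenomeBuild,
    min_segment_len: int = 10 * MB,
    min_final_len: int = 3 * MB,
    min_detections: int = 3,
    min_pipelines: int = 2,
    min_freq: float = 0.5,
    round_decimals: int | None = None,
    scar_config: ScarConfig = DEFAULT_CONFIG,
) -> ReferenceDataset:
    """Run the full consensus workflow for one cell line's callsets."""
    retained, log = select_reliable_callsets(callsets, criteria, genome)
    filtered = [
        apply_blacklist_and_min_length(cs, blacklist, min_segment_len) for cs in retained
    ]
    nodes = build_nodes(filtered, round_decimals=round_decimals)
    designated = vote_nodes(nodes, min_detections, min_pipelines, min_freq)
    segments = merge_and_trim(designated, min_final_len)
    if not segments:
        raise EmptyConsensusError("consensus produced no high-confidence segments")
    ref_callset = ASCNVCallset(sample_id="reference", segments=segments)
    statuses = [
        (derive_allele_status(seg.a_cn), derive_allele_status(seg.b_cn)) for seg in segments
    ]
    scores = compute_scores(ref_callset, genome, scar_config)
    scars = scar_region_catalog(ref_callset, genome, scar_config)
    provenance = {
        "criteria": {
            "min_purity": criteria.min_purity,
            "ploidy_window": criteria.ploidy_window,
            "min_autosome_coverage": criteria.min_autosome_coverage,
            "excluded_mass_ratios": sorted(criteria.excluded_mass_ratios),
        },
        "n_input_callsets": len(callsets),
        "n_retained_callsets": len(retained),
        "exclusions": {k: sorted(v) for k, v in log.items()},
        "voting": {
            "min_detections": min_detections,
            "min_pipelines": min_pipelines,
            "min_freq": min_freq,
        },
    }
    return ReferenceDataset(
        regions=segments,
        statuses=statuses,
        scar_regions=scars,
        scores=scores,
        provenance=provenance,
    )
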