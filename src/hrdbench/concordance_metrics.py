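"""Interval-level agreement metrics between callsets and against a reference.

All metrics are length-weighted (base pairs, not segment counts).  A metric
whose denominator is empty is *undefined* and propagates as ``None`` /
``NaN`` rather than zero — "no data" is not "no agreement".

Comparison levels, from coarsest to strictest:

``detect``  any overlap counts as a match
``cns``     equal total-copy-number status (loss/neutral/gain around 2)
``cn``      equal total copy number
``ascns``   equal (A_status, B_status) pair
``ascn``    equal (a_cn, b_cn) pair
``region:LOH`` / ``region:LST`` / ``region:TAI``
            both profiles annotate the bp with that scar class
"""

from __future__ import annotations

from typing import Callable, Sequence

from . import _intervals
from .genome_segments import (
    ASCNVCallset,
    GenomeBuild,
    Segment,
    derive_allele_status,
    derive_total_status,
)
from .scar_scores import DEFAULT_CONFIG, ScarConfig, annotate_loh, annotate_lst, annotate_tai

LEVELS = ("detect", "cns", "cn", "ascns", "ascn")
REGION_LEVELS = ("region:LOH", "region:LST", "region:TAI")


def _round_state(x: float, decimals: int | None) -> float:
    return x if decimals is None else round(x, decimals)


def _match_predicate(level: str, cn_decimals: int | None = 0) -> Callable[[Segment, Segment], bool]:
    level = level.lower()
    if level == "detect":
        return lambda a, b: True
    if level == "cn":
        return lambda a, b: _round_state(a.total_cn, cn_decimals) == _round_state(b.total_cn, cn_decimals)
    if level == "cns":
        return lambda a, b: derive_total_status(a.total_cn) is derive_total_status(b.total_cn)
    if level == "ascn":
        return lambda a, b: (
            _round_state(a.a_cn, cn_decimals) == _round_state(b.a_cn, cn_decimals)
            and _round_state(a.b_cn, cn_decimals) == _round_state(b.b_cn, cn_decimals)
        )
    if level == "ascns":
        return lambda a, b: (
            derive_allele_status(a.a_cn) is derive_allele_status(b.a_cn)
            and derive_allele_status(a.b_cn) is derive_allele_status(b.b_cn)
        )
    raise ValueError(f"unknown comparison level {level!r}")


def _segment_lookup(callset: ASCNVCallset) -> dict[str, list[Segment]]:
    return callset.by_chrom()


def _elementary(
    per_chrom: Sequence[dict[str, list[Segment]]],
) -> dict[str, list[tuple[int, int, list[Segment | None]]]]:
    """Split all profiles into shared elementary intervals per chromosome.

    Yields, per chromosome, disjoint intervals covering the union of all
    profiles, each with the covering segment (or None) from every profile.
    """
    chroms = sorted({c for look in per_chrom for c in look})
    out: dict[str, list[tuple[int, int, list[Segment | None]]]] = {}
    for chrom in chroms:
        cuts = sorted(
            {s.start for look in per_chrom for s in look.get(chrom, [])}
            | {s.end for look in per_chrom for s in look.get(chrom, [])}
        )
        pieces = []
        pointers = [0] * len(per_chrom)
        for lo, hi in zip(cuts, cuts[1:]):
            covering: list[Segment | None] = []
            for k, look in enumerate(per_chrom):
                segs = look.get(chrom, [])
                i = pointers[k]
                while i < len(segs) and segs[i].end <= lo:
                    i += 1
                pointers[k] = i
                covering.append(segs[i] if i < len(segs) and segs[i].start <= lo else None)
            if any(c is not None for c in covering):
                pieces.append((lo, hi, covering))
        out[chrom] = pieces
    return out


def _scar_regions(
    callset: ASCNVCallset, genome: GenomeBuild, kind: str, config: ScarConfig
) -> dict[str, list[tuple[int, int]]]:
    annot = {"LOH": annotate_loh, "LST": annotate_lst, "TAI": annotate_tai}[kind]
    regions, _ = annot(callset, genome, config)
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in regions:
        per_chrom.setdefault(chrom, []).append((s, e))
    return {c: _intervals.merge(iv) for c, iv in per_chrom.items()}


def jaccard(
    callset_a: ASCNVCallset,
    callset_b: ASCNVCallset,
    level: str = "ascns",
    genome: GenomeBuild | None = None,
    scar_config: ScarConfig = DEFAULT_CONFIG,
    cn_decimals: int | None = 0,
) -> float | None:
    """Length-weighted Jaccard index of two callsets at a comparison level.

    Numerator: bp covered by both with the level's predicate matching.
    Denominator: bp covered by either (for region levels: by either's
    regions of that scar class).  Returns None when the union is empty.
    """
    if level in REGION_LEVELS or level.upper() in {"LOH", "LST", "TAI"}:
        kind = level.split(":")[-1].upper()
        if genome is None:
            raise ValueError("region-level Jaccard requires a genome build")
        ra = _scar_regions(callset_a, genome, kind, scar_config)
        rb = _scar_regions(callset_b, genome, kind, scar_config)
        inter = sum(
            _intervals.intersect_length(ra.get(c, []), rb.get(c, []))
            for c in set(ra) | set(rb)
        )
        union = sum(
            _intervals.total_length(_intervals.merge(list(ra.get(c, [])) + list(rb.get(c, []))))
            for c in set(ra) | set(rb)
        )
        return None if union == 0 else inter / union

    match = _match_predicate(level, cn_decimals)
    inter = union = 0
    pieces = _elementary([_segment_lookup(callset_a), _segment_lookup(callset_b)])
    for chrom_pieces in pieces.values():
        for lo, hi, (sa, sb) in chrom_pieces:
            union += hi - lo
            if sa is not None and sb is not None and match(sa, sb):
                inter += hi - lo
    return None if union == 0 else inter / union


def precision_recall_f1(
    test: ASCNVCallset,
    reference: "ASCNVCallset | object",
    level: str = "ascns",
    cn_decimals: int | None = 0,
) -> tuple[float | None, float | None, float | None]:
    """Length-weighted precision/recall/F1 of a test callset vs a reference.

    ``reference`` may be an ASCNVCallset or a ReferenceDataset (its
    consensus regions are used).  Precision = matched bp / test bp; recall =
    matched bp / reference bp; F1 is their harmonic mean (0 when P+R=0).
    """
    ref_callset = reference.as_callset() if hasattr(reference, "as_callset") else reference
    match = _match_predicate(level, cn_decimals)
    matched = 0
    test_len = test.total_length()
    ref_len = ref_callset.total_length()
    pieces = _elementary([_segment_lookup(test), _segment_lookup(ref_callset)])
    for chrom_pieces in pieces.values():
        for lo, hi, (st, sr) in chrom_pieces:
            if st is not None and sr is not None and match(st, sr):
                matched += hi - lo
    precision = matched / test_len if test_len else None
    recall = matched / ref_len if ref_len else None
    if precision is None or recall is None:
        f1 = None
    else:
        f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def multiinter(
    callsets: Sequence[ASCNVCallset],
) -> list[tuple[str, int, int, int, tuple[int, ...]]]:
    """BEDTools-multiinter-style overlap decomposition.

    Returns disjoint sub-intervals of the union as
    ``(chrom, start, end, count, covering-callset indices)``, 0-based
    half-open, matching ``bedtools multiinter`` semantics at the coverage
    ("detect") level.
    """
    if len(callsets) < 2:
        raise ValueError("multiinter requires at least two callsets")
    pieces = _elementary([_segment_lookup(cs) for cs in callsets])
    out = []
    for chrom in sorted(pieces, key=lambda c: (int(c), "") if c.isdigit() else (100, c)):
        for lo, hi, covering in pieces[chrom]:
            idx = tuple(i for i, seg in enumerate(covering) if seg is not None)
            out.append((chrom, lo, hi, len(idx), idx))
    return out


def reference_concordance(
    callsets: Sequence[ASCNVCallset],
    reference: "ASCNVCallset | object",
    level: str = "ascns",
    cn_decimals: int | None = 0,
) -> dict[int, float]:
    """Fraction of the reference covered by exactly k status-concordant callsets.

    For each k = 1..len(callsets): (bp of reference where exactly k callsets
    carry a matching call) / (total reference bp).  The fractions over k
    partition the concordant span and sum to <= 1.
    """
    ref_callset = reference.as_callset() if hasattr(reference, "as_callset") else reference
    ref_len = ref_callset.total_length()
    if ref_len == 0:
        raise ValueError("empty reference")
    match = _match_predicate(level, cn_decimals)
    lengths = {k: 0 for k in range(1, len(callsets) + 1)}
    pieces = _elementary(
        [_segment_lookup(ref_callset)] + [_segment_lookup(cs) for cs in callsets]
    )
    for chrom_pieces in pieces.values():
        for lo, hi, covering in chrom_pieces:
            sr = covering[0]
            if sr is None:
                continue
            k = sum(
                1 for seg in covering[1:] if seg is not None and match(seg, sr)
            )
            if k:
                lengths[k] += hi - lo
    return {k: v / ref_len for k, v in lengths.items()}
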