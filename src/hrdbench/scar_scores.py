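"""HRD genomic-scar scoring: LOH, TAI, LST counts and their sum, the GIS.

The three scar classes follow the harmonized definitions used in clinical
HRD testing:

* **LOH** — autosomal fragments in which the minor allele is absent, longer
  than 15 Mb (strictly), excluding fragments spanning a whole chromosome.
* **TAI** — allelically imbalanced autosomal segments anchored at a
  chromosome terminus, not extending past the centromere, and at least
  11 Mb long.
* **LST** — breakpoints between adjacent copy-number states on the same
  chromosome arm where both flanking segments are at least 10 Mb long and
  the gap between them is at most 3 Mb, after smoothing away segments
  shorter than 3 Mb.

GIS = LOH + LST + TAI.  Threshold inclusivities are deliberate and are
asserted by the test suite; see the methods note for the rationale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome_segments import MB, ASCNVCallset, GenomeBuild, Segment, derive_allele_status, AlleleStatus

Region = tuple[str, int, int]
State = tuple[float, float, float]  # (total_cn, a_cn, b_cn)


@dataclass(frozen=True)
class ScarConfig:
    """Tunable thresholds of the scar annotators (all lengths in bp).

    Defaults implement the harmonized rules: LOH fragments must exceed
    ``loh_min_len`` strictly; TAI segments must reach ``tai_min_len``
    inclusively; LST flanks must reach ``lst_min_flank`` inclusively with an
    inter-flank gap of at most ``lst_max_gap``; segments shorter than
    ``lst_smooth_min`` are smoothed away before breakpoint counting.
    """

    loh_min_len: int = 15 * MB
    loh_minor_max: float = 0.0  # minor allele cn at or below this is "absent"
    loh_major_min: float = 1.0
    loh_status_mode: bool = False  # if True, qualify on allele status (B=loss, A!=loss)
    whole_chrom_window: int = 1 * MB
    tai_min_len: int = 11 * MB
    imbalance_tol: float = 0.5  # |a_cn - b_cn| must exceed this
    telomere_tol: int = 0
    lst_min_flank: int = 10 * MB
    lst_max_gap: int = 3 * MB
    lst_smooth_min: int = 3 * MB
    cn_tol: float = 0.25  # per-component tolerance when comparing copy states


DEFAULT_CONFIG = ScarConfig()

_EPS = 1e-9


@dataclass
class HRDScores:
    """LOH/TAI/LST counts, their annotated regions, and the GIS sum."""

    loh: int
    tai: int
    lst: int
    loh_regions: list[Region] = field(default_factory=list)
    tai_regions: list[Region] = field(default_factory=list)
    lst_regions: list[Region] = field(default_factory=list)

    @property
    def gis(self) -> int:
        return self.loh + self.lst + self.tai

    def as_dict(self) -> dict[str, int]:
        return {"LOH": self.loh, "TAI": self.tai, "LST": self.lst, "GIS": self.gis}


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _states_equal(a: State, b: State, tol: float) -> bool:
    return all(abs(x - y) <= tol for x, y in zip(a, b))


def _join_equal(pieces: list[tuple[int, int, State]], tol: float) -> list[tuple[int, int, State]]:
    """Re-join abutting pieces with identical copy state (split-invariance)."""
    out: list[tuple[int, int, State]] = []
    for s, e, st in pieces:
        if out and out[-1][1] == s and _states_equal(out[-1][2], st, tol):
            out[-1] = (out[-1][0], e, out[-1][2])
        else:
            out.append((s, e, st))
    return out


def _autosomal_by_chrom(profile: ASCNVCallset, genome: GenomeBuild) -> dict[str, list[Segment]]:
    autosomes = set(genome.autosomes)
    out: dict[str, list[Segment]] = {}
    for seg in profile.segments:
        if seg.chrom in autosomes:
            out.setdefault(seg.chrom, []).append(seg)
    return out


def _is_loh(seg: Segment, cfg: ScarConfig) -> bool:
    if cfg.loh_status_mode:
        return (
            derive_allele_status(seg.b_cn) is AlleleStatus.LOSS
            and derive_allele_status(seg.a_cn) is not AlleleStatus.LOSS
        )
    return seg.b_cn <= cfg.loh_minor_max + _EPS and seg.a_cn >= cfg.loh_major_min - _EPS


def _is_imbalanced(seg: Segment, cfg: ScarConfig) -> bool:
    return abs(seg.a_cn - seg.b_cn) > cfg.imbalance_tol


# ---------------------------------------------------------------------------
# annotators
# ---------------------------------------------------------------------------


def annotate_loh(
    profile: ASCNVCallset, genome: GenomeBuild, config: ScarConfig = DEFAULT_CONFIG
) -> tuple[list[Region], int]:
    """LOH regions: maximal runs of abutting minor-allele-absent segments.

    A run qualifies when strictly longer than ``loh_min_len`` and not
    spanning the whole chromosome (reaching within ``whole_chrom_window`` of
    both chromosome ends).
    """
    regions: list[Region] = []
    for chrom, segs in _autosomal_by_chrom(profile, genome).items():
        chrom_len = genome.length(chrom)
        run: tuple[int, int] | None = None
        runs: list[tuple[int, int]] = []
        for seg in segs:
            if _is_loh(seg, config):
                if run is not None and run[1] == seg.start:
                    run = (run[0], seg.end)
                else:
                    if run is not None:
                        runs.append(run)
                    run = (seg.start, seg.end)
            else:
                if run is not None:
                    runs.append(run)
                    run = None
        if run is not None:
            runs.append(run)
        for s, e in runs:
            if e - s <= config.loh_min_len:
                continue
            whole = s <= config.whole_chrom_window and e >= chrom_len - config.whole_chrom_window
            if whole:
                continue
            regions.append((chrom, s, e))
    return regions, len(regions)


def annotate_tai(
    profile: ASCNVCallset, genome: GenomeBuild, config: ScarConfig = DEFAULT_CONFIG
) -> tuple[list[Region], int]:
    """Telomeric allelic-imbalance segments.

    A segment qualifies when imbalanced (|a_cn - b_cn| beyond tolerance),
    anchored at the profile's covered extent on that chromosome (within
    ``telomere_tol`` of the first or last covered bp — targeted assays never
    reach true telomeres), not extending past the centromere toward the
    opposite arm, and at least ``tai_min_len`` long.
    """
    regions: list[Region] = []
    for chrom, segs in _autosomal_by_chrom(profile, genome).items():
        pieces = _join_equal([(s.start, s.end, s.cn_state) for s in segs], config.cn_tol)
        extent_start = pieces[0][0]
        extent_end = pieces[-1][1]
        cen = genome.centromeres.get(chrom)
        for s, e, (total, a, b) in pieces:
            if abs(a - b) <= config.imbalance_tol:
                continue
            if e - s < config.tai_min_len:
                continue
            p_anchored = s <= extent_start + config.telomere_tol
            q_anchored = e >= extent_end - config.telomere_tol
            ok = False
            if p_anchored and (cen is None or e <= cen[1]):
                ok = True
            if q_anchored and (cen is None or s >= cen[0]):
                ok = True
            if ok:
                regions.append((chrom, s, e))
    return regions, len(regions)


def _smooth_arm(
    pieces: list[tuple[int, int, State]], min_len: int, tol: float
) -> list[tuple[int, int, State]]:
    """Remove pieces shorter than ``min_len``, bridging equal-state neighbors."""
    pieces = _join_equal(pieces, tol)
    while True:
        small = [i for i, (s, e, _) in enumerate(pieces) if e - s < min_len]
        if not small:
            return pieces
        i = min(small, key=lambda i: pieces[i][1] - pieces[i][0])
        victim = pieces.pop(i)
        if 0 < i <= len(pieces) - 1:
            left, right = pieces[i - 1], pieces[i]
            if (
                left[1] == victim[0]
                and right[0] == victim[1]
                and _states_equal(left[2], right[2], tol)
            ):
                pieces[i - 1 : i + 1] = [(left[0], right[1], left[2])]
        pieces = _join_equal(pieces, tol)


def annotate_lst(
    profile: ASCNVCallset, genome: GenomeBuild, config: ScarConfig = DEFAULT_CONFIG
) -> tuple[list[Region], int]:
    """Large-scale state transitions, counted per chromosome arm.

    Segments are clipped to arms at the centromere interval; per arm,
    segments shorter than ``lst_smooth_min`` are smoothed away, then each
    breakpoint with both flanks >= ``lst_min_flank``, a copy-state change,
    and an inter-flank gap <= ``lst_max_gap`` counts one LST.  The reported
    region spans both flanking segments.
    """
    regions: list[Region] = []
    for chrom, segs in _autosomal_by_chrom(profile, genome).items():
        for _arm, arm_start, arm_end in genome.arms(chrom):
            pieces = []
            for seg in segs:
                s = max(seg.start, arm_start)
                e = min(seg.end, arm_end)
                if e > s:
                    pieces.append((s, e, seg.cn_state))
            if len(pieces) < 2:
                continue
            pieces = _smooth_arm(pieces, config.lst_smooth_min, config.cn_tol)
            for (s1, e1, st1), (s2, e2, st2) in zip(pieces, pieces[1:]):
                if (
                    e1 - s1 >= config.lst_min_flank
                    and e2 - s2 >= config.lst_min_flank
                    and s2 - e1 <= config.lst_max_gap
                    and not _states_equal(st1, st2, config.cn_tol)
                ):
                    regions.append((chrom, s1, e2))
    return regions, len(regions)


def compute_scores(
    profile: ASCNVCallset, genome: GenomeBuild, config: ScarConfig = DEFAULT_CONFIG
) -> HRDScores:
    """All three scar counts plus GIS for one allele-specific profile."""
    loh_regions, loh = annotate_loh(profile, genome, config)
    tai_regions, tai = annotate_tai(profile, genome, config)
    lst_regions, lst = annotate_lst(profile, genome, config)
    return HRDScores(
        loh=loh,
        tai=tai,
        lst=lst,
        loh_regions=loh_regions,
        tai_regions=tai_regions,
        lst_regions=lst_regions,
    )


def scar_region_catalog(
    profile: ASCNVCallset, genome: GenomeBuild, config: ScarConfig = DEFAULT_CONFIG
) -> list[tuple[str, int, int, str]]:
    """Classified scar regions; a span fulfilling several definitions is
    emitted once per classification."""
    scores = compute_scores(profile, genome, config)
    catalog = [(c, s, e, "LOH") for c, s, e in scores.loh_regions]
    catalog += [(c, s, e, "LST") for c, s, e in scores.lst_regions]
    catalog += [(c, s, e, "TAI") for c, s, e in scores.tai_regions]
    return sorted(catalog)
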