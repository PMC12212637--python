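"""Seeded synthetic-data generator for tumor-titration ASCNV studies.

This module is the test harness for the rest of the package: it plants
ground-truth allele-specific genomes with known scar counts, mixes them
with normal DNA at graded mass ratios, and emulates multi-pipeline caller
behaviour (breakpoint jitter, missed segments, copy-number errors,
purity-estimation noise, whole-genome-doubling misfits).

Planting layout
---------------
Events are laid out per chromosome arm, walking inward from the telomere,
and are separated by 4 Mb coverage gaps.  The gaps exceed the 3 Mb LST
bridging distance, so event boundaries never create unintended
state-transition breakpoints; interior placement keeps LOH and LST flanks
away from the covered extent so they never count as telomeric imbalance.
Terminal baseline pieces are at least 10.5 Mb so that downstream >=10 Mb
segment filtering cannot move a chromosome's covered extent.  Every planted
profile is verified by scoring it (the counts must equal the targets
exactly); on the rare collision the profile is re-drawn.

Purity model
------------
A tumor titration mixes DNA by *mass*; the tumor-cell fraction therefore
depends on tumor ploidy psi (normal ploidy fixed at 2):

    purity(m, psi) = 2 m / (2 m + psi (1 - m))

so hyperploid genomes yield lower estimated purity at the same mass ratio.
Callers observe contamination-mixed copy numbers and back-correct them with
a (noisy) purity estimate, reporting values rounded to two decimals; with
all noise terms at zero the emulation is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_segments import GRCH37, MB, ASCNVCallset, GenomeBuild, Segment, write_callset
from .scar_scores import DEFAULT_CONFIG, ScarConfig, compute_scores

GAP = 4 * MB  # inter-event coverage gap; > 3 Mb so it never bridges an LST
MIN_TERMINAL_BASE = int(10.5 * MB)  # survives >=10 Mb consensus filtering

# Study-design constants: ten cell lines, seven mass ratios (six tumor
# titrations plus the pure-normal sample), two replicates, six exome
# pipelines (three for the genome-wide arm of the design).
FULL_TITRATION = (0.0, 0.10, 0.20, 0.30, 0.40, 0.50, 1.00)
TUMOR_TITRATIONS = (0.10, 0.20, 0.30, 0.40, 0.50, 1.00)
WES_PIPELINES = ("p1", "p2", "p3", "p4", "p5", "p6")
WGS_PIPELINES = ("w1", "w2", "w3")

# Per-cell-line scar targets (LOH, TAI, LST) and tumor ploidies spanning the
# characterized range of the ten reference lines (GIS 11..96).
DEFAULT_TARGETS: tuple[tuple[int, int, int], ...] = (
    (6, 1, 4), (10, 12, 16), (6, 10, 10), (4, 7, 10), (5, 12, 8),
    (5, 9, 16), (6, 17, 21), (4, 6, 4), (22, 28, 46), (15, 26, 24),
)
DEFAULT_PLOIDIES: tuple[float, ...] = (2.8, 3.6, 2.0, 2.9, 5.1, 2.1, 4.6, 3.1, 2.9, 4.0)


class InfeasibleTargetsError(RuntimeError):
    """The requested scar counts do not fit on the genome's autosomes."""


@dataclass
class TruthProfile:
    """Ground-truth allele-specific genome with a known scar inventory."""

    genome: GenomeBuild
    segments: list[Segment]
    planted: tuple[int, int, int]  # (LOH, TAI, LST)
    ploidy: float  # length-weighted mean total copy number
    seed_entropy: int

    def as_callset(self, sample_id: str = "truth", **metadata) -> ASCNVCallset:
        return ASCNVCallset(
            sample_id=sample_id,
            segments=[replace(s) for s in self.segments],
            **metadata,
        )


@dataclass(frozen=True)
class PipelineBias:
    """Systematic per-pipeline deviations layered on the random noise."""

    purity_shift: float = 0.0
    cn_shift: float = 0.0
    jitter_scale: float = 1.0


@dataclass(frozen=True)
class NoiseModel:
    """Caller-noise parameters; all zeros yield the identity emulation."""

    breakpoint_jitter_sd: float = 0.0  # bp
    miss_prob: float = 0.0  # per-segment dropout
    cn_error_prob: float = 0.0  # per-segment chance of an allele CN error
    cn_error_magnitude: float = 1.0
    purity_noise_sd: float = 0.0
    wgd_misfit_prob: float = 0.0  # chance of a halved/doubled ploidy fit
    pipeline_bias: dict[str, PipelineBias] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for p in (self.miss_prob, self.cn_error_prob, self.wgd_misfit_prob):
            if not 0 <= p <= 1:
                raise ValueError(f"probability out of range: {p}")

    def bias_for(self, pipeline: str | None) -> PipelineBias:
        return self.pipeline_bias.get(pipeline, PipelineBias())


#: Realistic exome-caller noise: ~200 kb breakpoint uncertainty, occasional
#: missed or mis-called segments, a few percent purity-estimation error, and
#: a small chance of a whole-genome-doubling misfit, with mild systematic
#: differences between the six pipelines.
MODERATE_NOISE = NoiseModel(
    breakpoint_jitter_sd=200_000,
    miss_prob=0.02,
    cn_error_prob=0.03,
    cn_error_magnitude=1.0,
    purity_noise_sd=0.03,
    wgd_misfit_prob=0.02,
    pipeline_bias={
        "p1": PipelineBias(purity_shift=0.01, jitter_scale=0.8),
        "p2": PipelineBias(purity_shift=-0.01, jitter_scale=1.2),
        "p3": PipelineBias(cn_shift=0.02),
        "p4": PipelineBias(purity_shift=0.02, jitter_scale=1.0),
        "p5": PipelineBias(purity_shift=-0.02, jitter_scale=0.9),
        "p6": PipelineBias(jitter_scale=1.1),
    },
)


def expected_purity(mass_ratio: float, tumor_ploidy: float) -> float:
    """Tumor-cell fraction whose DNA *mass* fraction equals ``mass_ratio``.

    With normal cells diploid and tumor cells at ploidy psi, a cell
    fraction p contributes DNA mass proportional to p*psi vs (1-p)*2, so
    the cell fraction matching mass fraction m is 2m / (2m + psi(1-m)) —
    strictly decreasing in psi for 0 < m < 1.
    """
    if not 0 <= mass_ratio <= 1:
        raise ValueError("mass_ratio must lie in [0, 1]")
    if tumor_ploidy <= 0:
        raise ValueError("tumor ploidy must be positive")
    m = mass_ratio
    return 2 * m / (2 * m + tumor_ploidy * (1 - m))


# ---------------------------------------------------------------------------
# Truth planting
# ---------------------------------------------------------------------------


def _baseline_copies(rng: np.random.Generator, base_ploidy: float, n_chroms: int) -> list[int]:
    """Per-chromosome balanced baseline allele copies approximating the ploidy."""
    k0 = int(base_ploidy // 2)
    frac = base_ploidy / 2 - k0
    ks = k0 + (rng.random(n_chroms) < frac).astype(int)
    return [int(min(3, max(1, k))) for k in ks]


def _materialize_arm(
    rng: np.random.Generator,
    arm_len: int,
    base_state: tuple[float, float],
    tai: bool,
    queue: list[str],
) -> list[tuple[int, int, tuple[float, float]]]:
    """Lay out events on one arm (coordinates run inward from the telomere).

    Consumes as many interior events from ``queue`` as fit.  Returns pieces
    as (start, end, (a_cn, b_cn)) relative to the telomere.
    """
    pieces: list[tuple[int, int, tuple[float, float]]] = []
    if tai:
        hi = min(13.5 * MB, arm_len - GAP - MB)
        length = int(rng.uniform(11.2 * MB, hi))
        pieces.append((0, length, (2.0, 1.0)))
        pos = length + GAP
    else:
        length = int(rng.uniform(MIN_TERMINAL_BASE, 12 * MB))
        if not queue or length + GAP + 11 * MB > arm_len:
            return [(0, arm_len, base_state)]
        pieces.append((0, length, base_state))
        pos = length + GAP

    while queue:
        kind = queue[-1]
        if kind == "LOH":
            length = int(rng.uniform(15.5 * MB, 18.5 * MB))
            if pos + length > arm_len:
                break
            pieces.append((pos, pos + length, (1.0, 0.0)))
            pos += length + GAP
        else:  # LST: two abutting >=10 Mb flanks with different copy states
            l1 = int(rng.uniform(10.2 * MB, 12.5 * MB))
            l2 = int(rng.uniform(10.2 * MB, 12.5 * MB))
            if pos + l1 + l2 > arm_len:
                break
            pieces.append((pos, pos + l1, (2.0, 2.0)))
            pieces.append((pos + l1, pos + l1 + l2, (1.0, 1.0)))
            pos += l1 + l2 + GAP
        queue.pop()

    if arm_len - pos >= MB:
        pieces.append((pos, arm_len, base_state))
    return pieces


def _plant_once(
    rng: np.random.Generator,
    genome: GenomeBuild,
    targets: tuple[int, int, int],
    base_ploidy: float,
) -> list[Segment] | None:
    n_loh, n_tai, n_lst = targets
    autosomes = list(genome.autosomes)
    copies = dict(zip(autosomes, _baseline_copies(rng, base_ploidy, len(autosomes))))

    arms = []
    for chrom in autosomes:
        for arm, astart, aend in genome.arms(chrom):
            arms.append((chrom, arm, astart, aend))
    order = rng.permutation(len(arms))
    arms = [arms[i] for i in order]

    # assign TAI events to distinct arm termini with enough room
    tai_arms: set[int] = set()
    for i, (_c, _a, astart, aend) in enumerate(arms):
        if len(tai_arms) == n_tai:
            break
        if aend - astart >= 17 * MB:  # room for >=11.2 Mb TAI plus gap
            tai_arms.add(i)
    if len(tai_arms) < n_tai:
        return None

    queue = ["LOH"] * n_loh + ["LST"] * n_lst
    queue = [queue[i] for i in rng.permutation(len(queue))] if queue else []

    segments: list[Segment] = []
    for i, (chrom, arm, astart, aend) in enumerate(arms):
        k = copies[chrom]
        base = (float(k), float(k))
        pieces = _materialize_arm(rng, aend - astart, base, i in tai_arms, queue)
        for s, e, (a, b) in pieces:
            if arm == "p":
                lo, hi = astart + s, astart + e
            else:  # q arm: mirror so coordinate 0 sits at the chromosome end
                lo, hi = aend - e, aend - s
            segments.append(Segment(chrom, lo, hi, None, a, b))
    if queue:  # events left unplaced
        return None
    return segments


def simulate_truth(
    genome: GenomeBuild = GRCH37,
    target_counts: tuple[int, int, int] = (6, 1, 4),
    base_ploidy: float = 2.0,
    seed: int | np.random.SeedSequence = 0,
    max_tries: int = 8,
    config: ScarConfig = DEFAULT_CONFIG,
) -> TruthProfile:
    """Plant a profile whose scar scores equal ``target_counts`` exactly.

    ``target_counts`` is (LOH, TAI, LST).  The planted profile is verified
    through the scoring engine; a draw that does not reproduce the targets
    is rejected and re-drawn (deterministically, from the same seed).
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    entropy = ss.entropy if isinstance(ss.entropy, int) else 0
    for child in ss.spawn(max_tries):
        rng = np.random.default_rng(child)
        segments = _plant_once(rng, genome, target_counts, base_ploidy)
        if segments is None:
            continue
        profile = ASCNVCallset(sample_id="truth", segments=segments)
        scores = compute_scores(profile, genome, config)
        if (scores.loh, scores.tai, scores.lst) == tuple(target_counts):
            total = profile.total_length()
            ploidy = sum(s.total_cn * s.length for s in profile.segments) / total
            return TruthProfile(
                genome=genome,
                segments=profile.segments,
                planted=tuple(target_counts),
                ploidy=ploidy,
                seed_entropy=entropy,
            )
    raise InfeasibleTargetsError(
        f"could not plant scar counts {target_counts} on {genome.name} "
        f"after {max_tries} attempts"
    )


# ---------------------------------------------------------------------------
# Caller emulation
# ---------------------------------------------------------------------------


def _jitter_boundaries(
    rng: np.random.Generator, segs: list[Segment], sd: float, chrom_len: int
) -> list[Segment]:
    bounds = sorted({s.start for s in segs} | {s.end for s in segs})
    delta = rng.normal(0.0, sd, size=len(bounds))
    new = {}
    for i, b in enumerate(bounds):
        lo = 0 if i == 0 else (bounds[i - 1] + b) // 2 + 1
        hi = chrom_len if i == len(bounds) - 1 else (b + bounds[i + 1]) // 2 - 1
        new[b] = int(min(max(b + delta[i], lo), hi))
    out = []
    for s in segs:
        ns, ne = new[s.start], new[s.end]
        if ne > ns:
            out.append(Segment(s.chrom, ns, ne, None, s.a_cn, s.b_cn))
    return out


def emulate_caller(
    truth: TruthProfile,
    mass_ratio: float,
    noise: NoiseModel = NoiseModel(),
    pipeline_id: str = "p1",
    seed: int | np.random.SeedSequence = 0,
    replicate: int = 1,
    cell_line: str | None = None,
    cn_decimals: int = 0,
) -> ASCNVCallset:
    """Emulate one pipeline's callset for one titration sample.

    Tumor copy numbers are mixed with normal diploid signal at the true
    cell fraction, then back-corrected with the pipeline's (noisy) purity
    estimate and rounded to ``cn_decimals`` decimals (default 0: integer
    allele copy numbers, as the established allele-specific callers
    report).  The round trip is exact when all noise terms are zero.
    """
    rng = np.random.default_rng(
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    bias = noise.bias_for(pipeline_id)
    p_true = expected_purity(mass_ratio, truth.ploidy)
    p_est = p_true + bias.purity_shift
    if noise.purity_noise_sd > 0:
        p_est += rng.normal(0.0, noise.purity_noise_sd)
    p_est = min(max(p_est, 0.02), 1.0)

    wgd_factor = 1.0
    if noise.wgd_misfit_prob > 0 and rng.random() < noise.wgd_misfit_prob:
        wgd_factor = 2.0 if rng.random() < 0.5 else 0.5

    segments: list[Segment] = []
    by_chrom: dict[str, list[Segment]] = {}
    for s in truth.segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, segs in by_chrom.items():
        sd = noise.breakpoint_jitter_sd * bias.jitter_scale
        if sd > 0:
            segs = _jitter_boundaries(rng, segs, sd, truth.genome.length(chrom))
        for seg in segs:
            if noise.miss_prob > 0 and rng.random() < noise.miss_prob:
                continue
            alleles = []
            for cn in (seg.a_cn, seg.b_cn):
                observed = p_true * cn + (1 - p_true) * 1.0
                corrected = (observed - (1 - p_est)) / p_est
                alleles.append(corrected + bias.cn_shift / 2)
            if noise.cn_error_prob > 0 and rng.random() < noise.cn_error_prob:
                which = int(rng.random() < 0.5)
                sign = 1 if rng.random() < 0.5 else -1
                alleles[which] += sign * noise.cn_error_magnitude
            a = round(max(alleles[0], 0.0) * wgd_factor, cn_decimals)
            b = round(max(alleles[1], 0.0) * wgd_factor, cn_decimals)
            segments.append(Segment(seg.chrom, seg.start, seg.end, None, a, b))

    sample_id = f"{cell_line or 'truth'}_m{int(round(mass_ratio * 100)):03d}_{pipeline_id}_rep{replicate}"
    callset = ASCNVCallset(
        sample_id=sample_id,
        segments=segments,
        cell_line=cell_line,
        mass_ratio=mass_ratio,
        pipeline=pipeline_id,
        replicate=replicate,
        purity=round(p_est, 4),
        ploidy=None,
    )
    ploidy = callset.length_weighted_ploidy()
    callset.ploidy = None if ploidy is None else round(ploidy, 4)
    return callset


# ---------------------------------------------------------------------------
# Study enumeration
# ---------------------------------------------------------------------------


@dataclass
class StudyResult:
    """All emulated callsets of a titration study plus the truth registry."""

    callsets: list[ASCNVCallset]
    truths: dict[str, TruthProfile]

    def manifest(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": cs.sample_id,
                "cell_line": cs.cell_line,
                "mass_ratio": cs.mass_ratio,
                "pipeline": cs.pipeline,
                "replicate": cs.replicate,
                "purity": cs.purity,
                "ploidy": cs.ploidy,
                "n_segments": len(cs.segments),
            }
            for cs in self.callsets
        ]
        return pd.DataFrame(rows)


def titration_inventory(
    n_cell_lines: int = 10, mass_ratios: Sequence[float] = FULL_TITRATION
) -> pd.DataFrame:
    """Enumerate the physical titration samples (default: 10 x 7 = 70)."""
    rows = [
        {"cell_line": f"{i + 1:02d}", "mass_ratio": m}
        for i in range(n_cell_lines)
        for m in mass_ratios
    ]
    return pd.DataFrame(rows)


def simulate_study(
    n_cell_lines: int = 10,
    mass_ratios: Sequence[float] = TUMOR_TITRATIONS,
    n_replicates: int = 2,
    pipelines: Sequence[str] = WES_PIPELINES,
    noise: NoiseModel = MODERATE_NOISE,
    seed: int = 0,
    genome: GenomeBuild = GRCH37,
    targets: Sequence[tuple[int, int, int]] | None = None,
    ploidies: Sequence[float] | None = None,
) -> StudyResult:
    """Enumerate the full cross-product study design.

    Produces n_cell_lines x |mass_ratios| x n_replicates x |pipelines|
    callsets (720 for the default exome design, 360 with the three
    genome-wide pipelines).  Each callset draws from its own counter-keyed
    substream of ``seed``, so adding callsets never perturbs the others.
    """
    targets = list(targets) if targets is not None else list(DEFAULT_TARGETS)
    ploidies = list(ploidies) if ploidies is not None else list(DEFAULT_PLOIDIES)
    root = np.random.SeedSequence(seed)
    callsets: list[ASCNVCallset] = []
    truths: dict[str, TruthProfile] = {}
    for li in range(n_cell_lines):
        cell_line = f"{li + 1:02d}"
        truth = simulate_truth(
            genome=genome,
            target_counts=targets[li % len(targets)],
            base_ploidy=ploidies[li % len(ploidies)],
            seed=np.random.SeedSequence(seed, spawn_key=(li,)),
        )
        truths[cell_line] = truth
        for ri, ratio in enumerate(mass_ratios):
            for rep in range(1, n_replicates + 1):
                for pi, pipe in enumerate(pipelines):
                    callsets.append(
                        emulate_caller(
                            truth,
                            mass_ratio=ratio,
                            noise=noise,
                            pipeline_id=pipe,
                            replicate=rep,
                            cell_line=cell_line,
                            seed=np.random.SeedSequence(
                                seed, spawn_key=(li, ri + 1, rep, pi)
                            ),
                        )
                    )
    return StudyResult(callsets=callsets, truths=truths)


def write_study(study: StudyResult, outdir: str | Path) -> Path:
    """Write segment files plus a build-ref-compatible manifest.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = study.manifest()
    paths = []
    for cs in study.callsets:
        path = outdir / f"{cs.sample_id}.seg.tsv"
        write_callset(cs, path)
        paths.append(path.name)  # manifest paths are relative to its directory
    manifest.insert(0, "path", paths)
    manifest_path = outdir / "manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False)
    return manifest_path
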