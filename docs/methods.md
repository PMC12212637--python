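# Methods

This note documents the models, rules, and numerical conventions
implemented in `hrdbench`, the choices made where a convention was
genuinely open, and what the synthetic-data tests do and do not
demonstrate about real sequencing data.

## Coordinates and units

Internally every interval is 0-based half-open. Segment tables and the
reference TSV outputs are 1-based inclusive; BED blacklists are 0-based
half-open. "Mb" always means exactly 1,000,000 bp, so the scar and
filtering thresholds (15 / 11 / 10 / 3 Mb) are exact integers. The genome
model embeds the GRCh37 autosome lengths and centromere intervals (UCSC
gap table); the total autosomal length, 2,881,033,286 bp, is the
denominator of every coverage percentage. Chromosome names are normalized
by stripping a leading `chr`.

## Scar scoring

An allele-specific profile is a set of non-overlapping segments per
chromosome with major (*A*) and minor (*B*) allele copy numbers,
*A* ≥ *B* enforced on load. Before annotation, abutting segments with
identical copy state are re-joined, so scores are invariant to how a
caller happens to split a constant region.

**LOH.** A segment qualifies when *B* ≤ 0 and *A* ≥ 1 (a status-based
mode — *B* at loss, *A* not at loss — is available). Abutting qualifying
segments are merged into one fragment, because a fragment "exclusively
composed of LOH" does not stop at an internal copy-number change of the
remaining allele. Fragments count when strictly longer than 15 Mb and not
whole-chromosome; "whole chromosome" means reaching within 1 Mb
(configurable) of both chromosome ends, which is robust to the small
terminal truncations real callers produce.

**TAI.** A segment qualifies when |*A* − *B*| > 0.5 (tolerance
configurable; 0 gives exact inequality), it is at least 11 Mb long
(inclusive), it is anchored at the profile's covered extent on that
chromosome, and it does not extend past the centromere toward the other
arm. Anchoring is tested against the first/last covered base pair rather
than the nominal chromosome ends because targeted assays never reach true
telomeres; a `telomere_tol` parameter (default 0) can relax the anchor.
Segments that also satisfy the LOH definition are not excluded: the
imbalance criterion alone decides. A segment spanning the whole
chromosome fails both arms' centromere conditions and never counts.

**LST.** Computed per chromosome arm (segments are clipped at the
centromere interval), following the convention of the scarHRD family of
tools: a state transition across a centromere is not interpretable as a
chromosomal break. Per arm, segments shorter than 3 Mb are smoothed away
iteratively (shortest first); when the removed piece separated two
abutting neighbours of identical state, the neighbours are bridged into
one segment. A breakpoint then counts when both flanking segments are at
least 10 Mb, their copy states differ, and the gap between them is at
most 3 Mb. The smoothing-filter and gap readings of the 3 Mb rule are
both implemented (they interact: a smoothed-away small segment leaves a
< 3 Mb gap that the gap rule tolerates). The annotated LST region spans
both flanks of the breakpoint.

Copy states are compared with a per-component tolerance of 0.25 by
default, so real-valued caller output behaves like its nearest integer
state without forcing explicit rounding.

**GIS** is the sum of the three counts; the `HRDScores` container exposes
it as a derived property and the test suite verifies the identity and
that each count equals its annotated region list's length on seeded
random profiles.

## Consensus reference construction

Reliability filtering proceeds in order: (1) drop configured mass ratios
(default 10% and 20%); (2) per cell line and mass ratio, take the median
of the callsets' purity estimates as the gradient's actual purity and
drop gradients below 30% — gating is by gradient, not per callset;
(3) drop callsets whose ploidy lies outside ±15% of the per-cell-line
median; (4) drop callsets covering < 70% of the autosomes. All four
thresholds live in `CallsetFilterCriteria` (YAML-loadable).

Blacklist spans are subtracted from each surviving callset's segments
(segments may split), then remnants < 10 Mb are removed — in that order,
before any voting. The filtered segments are organized into an interval
tree and split into minimal disjoint nodes at every segment boundary.
Each covering callset contributes one vote for its
(total_cn, A_cn, B_cn) combination; replicates count separately, and the
vote-frequency denominator is the node's own detection count. Nodes
detected at least 3 times by at least 2 distinct pipelines are retained;
the combination whose frequency strictly exceeds 50% is designated, and a
node whose best combination sits at exactly 50% is discarded. Abutting
designated nodes with identical copy numbers are merged (discarded nodes
leave real gaps that are never bridged), and merged segments < 3 Mb are
dropped. Vote matching is exact on the provided values by default, with
optional rounding (`round_decimals`) for callers that emit fractional
copy numbers.

Allele statuses use the fixed breakpoints: ≤ 0.5 loss, ≥ 1.5 gain,
neutral between (both boundaries inclusive toward their class). For
*total* copy-number status the package mirrors this band around the
diploid value: ≤ 1.5 loss, ≥ 2.5 gain. The per-allele breakpoints are the
harmonized convention; the total-CN band is this package's analogue,
chosen so both scales have a ±0.5 neutral band.

Reference scores are recomputed from the consensus segments through the
same scoring engine, so they are internally consistent by construction
(and asserted, not assumed, in the tests).

## Agreement metrics

All interval metrics are length-weighted in base pairs. Counting matched
*segments* instead of matched length is brittle to arbitrary segment
splits, so segment-count precision/recall is deliberately not the
default. Comparison levels from coarse to strict: detected region, total
CN status, total CN, allele-specific status pair, allele-specific CN pair
(real values compared after rounding to integers by default), and the
three scar-class region levels, whose Jaccard denominator is the union of
the two profiles' regions of that class (not the whole callsets). A
metric with an empty denominator is *undefined* and propagates as
missing, never as zero.

`multiinter` reproduces BEDTools `multiinter` semantics (verified against
the tool itself in the test suite): disjoint sub-intervals of the union,
each labeled with the covering callsets. Per-k reference concordance
reports, for each k, the fraction of reference length covered by exactly
k status-concordant callsets; the fractions partition the concordant span.

Bland–Altman: differences are oriented test − reference; bias is their
mean, LoAs are bias ± 1.96 × sample SD (n − 1 denominator throughout),
the bias CI uses the t distribution with n − 1 df, and the LoA CIs use
the standard error sd·sqrt(1/n + 1.96²/(2(n − 1))). Zero-variance
differences make the one-sample t-test undefined (reported missing). CV
is sample SD over mean × 100. HRD classification treats score ≥ threshold
as positive on both sides of the comparison; the boundary side is
configurable because conventions differ between assays.

## The simulator

The simulator emulates the *output* of allele-specific CNV pipelines on a
tumor titration study — segment tables with purity/ploidy metadata —
never reads, BAFs, or SNPs.

**Truth planting.** Events are laid out per arm, walking inward from the
telomere, separated by 4 Mb coverage gaps (wider than the 3 Mb LST
bridging distance, so event edges cannot create unintended breakpoints).
TAI events (2,1) occupy arm termini; LOH events (1,0) of 15.5–18.5 Mb and
LST pairs (2,2)|(1,1) of ≥ 10.2 Mb flanks are placed interior. Terminal
baseline pieces are at least 10.5 Mb so the ≥ 10 Mb reference filter can
never move a chromosome's covered extent and thereby change TAI
anchoring. Balanced per-chromosome baselines of 1–3 copies per allele
approximate the requested tumor ploidy by randomized rounding. Every
planted profile is verified through the scoring engine — the counts must
equal the targets exactly — and re-drawn on collision; infeasible targets
raise after bounded retries. The default study plants ten component
combinations spanning GIS 11 to 96 with ploidies from 2.0 to 5.1, the
range characterized for the reference cell lines.

**Purity model.** Mixing is by DNA mass, so the tumor-cell fraction at
mass ratio m and tumor ploidy ψ is 2m / (2m + ψ(1 − m)) — strictly
decreasing in ψ, which reproduces the observed bias of hyperploid lines
toward lower estimated purity at the same titration level.

**Caller emulation.** Observed allele copy numbers are the
purity-weighted mix of tumor and diploid normal signal; the emulated
caller back-corrects with its own (noisy, pipeline-biased) purity
estimate and reports integers (rounding decimals configurable), as the
established allele-specific callers do. Noise components: Gaussian
breakpoint jitter (shared boundaries move together; order is preserved by
clamping to neighbour midpoints), per-segment dropout, occasional ±1
allele errors, purity-estimate noise, and a small probability of a
halved/doubled whole-genome-doubling misfit. Setting every component to
zero makes the emulation the identity at any mass ratio. The
`MODERATE_NOISE` preset (200 kb jitter, 2% dropout, 3% CN errors, 3%
purity SD, 2% WGD misfits, mild per-pipeline biases) is the package's
definition of realistic exome-caller behaviour.

**Determinism.** A single study seed fans out to per-callset substreams
keyed by (cell line, ratio, replicate, pipeline) via `SeedSequence` spawn
keys, so enlarging the design never perturbs existing callsets.

**What the simulation does not model.** Probe footprints (coverage is
genome-wide up to the planted gaps), SNP density and BAF noise, germline
CNVs, subclonality, focal amplifications, complex rearrangements, and
correlated errors between pipelines sharing algorithms. Passing the
end-to-end tests therefore demonstrates the correctness of the scoring,
voting, and metric machinery under controlled violations — not the
field accuracy of any particular caller.

## Problem sizes in the test suite

Per-bp oracle comparisons use two 1 Mb toy chromosomes with scar
thresholds scaled 1:100. Consensus-recovery tests run 24–72-callset
zero-noise studies and two seeded 2-cell-line moderate-noise studies at
full genome scale; the GIS identity property runs on 1,000 seeded random
profiles; the Bland–Altman null-rate check uses 10,000 simulated series.
The full suite completes in well under a minute on one CPU.

## Known limitations

* The LST definition is applied per arm; a tool that counts transitions
  across the centromere will differ on profiles with pericentromeric
  state changes.
* Exact-match voting assumes integer (or consistently rounded) caller
  output; fractional callsets should set `round_decimals`.
* The Bland–Altman LoA confidence intervals follow the standard
  approximation above; packages differ in this construction, and exact
  replication of any particular one is not promised.
* `GenomeBuild` ships GRCh37 only; other builds can be constructed but
  no liftover is provided.
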