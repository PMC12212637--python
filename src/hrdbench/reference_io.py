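"""On-disk layout for a reference dataset directory.

A reference directory holds four text files:

* ``ascnv_regions.tsv``   — 5 columns: chrom, start, end, A_status, B_status
* ``ascnv_segments.tsv``  — 6-column segment table with the designated copy
  numbers (what score recomputation and status matching consume)
* ``scar_regions.tsv``    — 4 columns: chrom, start, end, classification
* ``scores.json`` / ``provenance.json``

Coordinates in the TSV files are 1-based inclusive, as in the segment
dialect.
"""

from __future__ import annotations

import json
from pathlib import Path

from .consensus_reference import ReferenceDataset
from .genome_segments import (
    ASCNVCallset,
    derive_allele_status,
    read_callset,
    read_regions,
    write_callset,
    write_regions,
    write_reference_regions,
)
from .scar_scores import HRDScores


def write_reference(ref: ReferenceDataset, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_reference_regions(ref.status_rows(), outdir / "ascnv_regions.tsv")
    write_callset(ref.as_callset(), outdir / "ascnv_segments.tsv")
    write_regions(ref.scar_regions, outdir / "scar_regions.tsv")
    (outdir / "scores.json").write_text(json.dumps(ref.scores.as_dict(), indent=2) + "\n")
    (outdir / "provenance.json").write_text(json.dumps(ref.provenance, indent=2) + "\n")
    return outdir


def load_reference(outdir: str | Path) -> ReferenceDataset:
    outdir = Path(outdir)
    callset = read_callset(outdir / "ascnv_segments.tsv", sample_id="reference")
    scars = read_regions(outdir / "scar_regions.tsv")
    scores_raw = json.loads((outdir / "scores.json").read_text())
    provenance_path = outdir / "provenance.json"
    provenance = json.loads(provenance_path.read_text()) if provenance_path.exists() else {}
    statuses = [
        (derive_allele_status(seg.a_cn), derive_allele_status(seg.b_cn))
        for seg in callset.segments
    ]
    scores = HRDScores(loh=scores_raw["LOH"], tai=scores_raw["TAI"], lst=scores_raw["LST"])
    return ReferenceDataset(
        regions=callset.segments,
        statuses=statuses,
        scar_regions=scars,
        scores=scores,
        provenance=provenance,
    )
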