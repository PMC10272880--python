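"""Site classification and orientation-based target-gene prediction.

Prokaryotic transcription-factor binding sites regulate the genes whose
promoters they sit in, so a peak inside an intergenic spacer is assigned to
each flanking gene whose 5' start faces the spacer: the left neighbour when
it lies on the minus strand, the right neighbour when it lies on the plus
strand.  Divergent flanks thus yield two candidate targets, tandem flanks
one, convergent flanks none, and peaks inside an ORF yield none at all.
A target that heads an operon pulls in the whole transcription unit; a
binding site upstream of an internal operon gene is credited only with the
unit from that gene onward.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .model import AnnotatedGenome, Gene, ValidationError
from .motif import LLDR_BOX, DegenerateConsensus, parse_consensus, scan_region
from .peaks import Peak

SPACER = "spacer"
INTRAGENIC = "intragenic"


@dataclass(frozen=True)
class SiteContext:
    """A peak placed in its genomic context."""

    peak: Peak
    site_class: str  # SPACER or INTRAGENIC
    host_gene: Optional[str]  # set iff intragenic
    left_flank: Optional[tuple[str, str]]  # (gene id, strand), nearest on the left
    right_flank: Optional[tuple[str, str]]


@dataclass(frozen=True)
class TargetCall:
    """A predicted regulatory target with its operon expansion."""

    gene: str
    unit: tuple[str, ...]
    rationale: str


def classify_site(peak: Peak, genome: AnnotatedGenome) -> SiteContext:
    """Classify a peak as intragenic (inside a closed gene interval) or spacer.

    Flanks are the nearest genes strictly to each side of the peak position;
    for an intragenic site the host gene itself is excluded from the flank
    search, so the flanks are its neighbours.
    """
    pos = peak.position
    if not (1 <= pos <= genome.length):
        raise ValidationError(f"peak position {pos} outside genome of length {genome.length}")
    host: Gene | None = None
    for g in genome.genes_by_start():
        if g.contains(pos):
            host = g
            break
    left: Gene | None = None
    right: Gene | None = None
    for g in genome.genes:
        if host is not None and g.id == host.id:
            continue
        if g.end < pos:
            if left is None or g.end > left.end:
                left = g
        elif g.start > pos:
            if right is None or g.start < right.start:
                right = g
    return SiteContext(
        peak=peak,
        site_class=INTRAGENIC if host is not None else SPACER,
        host_gene=host.id if host is not None else None,
        left_flank=(left.id, left.strand) if left is not None else None,
        right_flank=(right.id, right.strand) if right is not None else None,
    )


def expand_operon(gene_id: str, genome: AnnotatedGenome) -> tuple[str, ...]:
    """Transcription unit reported for a binding site upstream of ``gene_id``.

    Returns the operon containing the gene from that gene onward (the whole
    unit when the gene is its first member), or the singleton unit when the
    gene belongs to no operon.
    """
    unit = genome.operon_of(gene_id)
    if unit is None:
        return (gene_id,)
    return unit[unit.index(gene_id):]


def predict_targets(context: SiteContext, genome: AnnotatedGenome,
                    max_distance: Optional[int] = None) -> list[TargetCall]:
    """Orientation rule: a spacer site targets each flank facing it.

    Intragenic sites return an empty list.  ``max_distance`` optionally
    limits how far (bp, peak position to gene 5' start) a flank may be to
    count as a target; default unlimited.
    """
    if context.site_class == INTRAGENIC:
        return []
    calls: list[TargetCall] = []
    pos = context.peak.position
    if context.left_flank is not None:
        gid, strand = context.left_flank
        if strand == "-" and _within(genome.gene(gid).tss, pos, max_distance):
            calls.append(
                TargetCall(gene=gid, unit=expand_operon(gid, genome),
                           rationale="left flank on minus strand; 5' start faces the spacer")
            )
    if context.right_flank is not None:
        gid, strand = context.right_flank
        if strand == "+" and _within(genome.gene(gid).tss, pos, max_distance):
            calls.append(
                TargetCall(gene=gid, unit=expand_operon(gid, genome),
                           rationale="right flank on plus strand; 5' start faces the spacer")
            )
    return calls


def _within(tss: int, pos: int, max_distance: Optional[int]) -> bool:
    return max_distance is None or abs(tss - pos) <= max_distance


def build_target_table(peaks: Sequence[Peak], genome: AnnotatedGenome,
                       regions: Optional[dict[str, str]] = None,
                       consensus: DegenerateConsensus | str = LLDR_BOX,
                       half_width: int = 250) -> pd.DataFrame:
    """One annotated row per peak: context, target calls, and top-2 box matches.

    Region sequences for box scanning come either from ``regions`` (keyed
    ``peak{i}``) or, when the genome carries its sequence, from a window of
    ``half_width`` bp on each side of the peak position.  Without sequence
    the consensus columns are left empty.
    """
    if isinstance(consensus, str):
        consensus = parse_consensus(consensus)
    rows = []
    for i, peak in enumerate(peaks, start=1):
        ctx = classify_site(peak, genome)
        calls = predict_targets(ctx, genome)
        region_id = f"peak{i}"
        seq = None
        if regions is not None:
            seq = regions.get(region_id)
        elif genome.sequence is not None:
            seq = genome.subsequence(peak.position - half_width,
                                     peak.position + half_width)
        boxes = (
            scan_region(seq, consensus, top_k=2, region_id=region_id)
            if seq is not None and len(seq) >= consensus.width
            else []
        )
        row = {
            "peak_id": region_id,
            "position": peak.position,
            "intensity": peak.intensity,
            "site_class": ctx.site_class,
            "host_gene": ctx.host_gene or "",
            "left_gene": ctx.left_flank[0] if ctx.left_flank else "",
            "left_strand": ctx.left_flank[1] if ctx.left_flank else "",
            "right_gene": ctx.right_flank[0] if ctx.right_flank else "",
            "right_strand": ctx.right_flank[1] if ctx.right_flank else "",
            "targets": ",".join(c.gene for c in calls),
            "units": ";".join("-".join(c.unit) for c in calls),
        }
        for k in (1, 2):
            if len(boxes) >= k:
                b = boxes[k - 1]
                row[f"consensus_{k}"] = f"{b.rendered}({b.score}/{b.max_score})"
                row[f"consensus_{k}_offset"] = b.offset
                row[f"consensus_{k}_strand"] = b.strand
            else:
                row[f"consensus_{k}"] = ""
                row[f"consensus_{k}_offset"] = -1
                row[f"consensus_{k}_strand"] = ""
        rows.append(row)
    columns = [
        "peak_id", "position", "intensity", "site_class", "host_gene",
        "left_gene", "left_strand", "right_gene", "right_strand",
        "targets", "units",
        "consensus_1", "consensus_1_offset", "consensus_1_strand",
        "consensus_2", "consensus_2_offset", "consensus_2_strand",
    ]
    return pd.DataFrame(rows, columns=columns)
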