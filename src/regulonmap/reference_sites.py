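"""Curated catalogue of the eight experimentally mapped LldR-binding sites.

Genomic-SELEX-chip screening of the *E. coli* K-12 genome with purified LldR
identified eight binding sites at a ratio cutoff of 6, seven in intergenic
spacers and one inside the *yfbK* ORF.  This module encodes that catalogue —
peak positions, binding intensities, flanking-gene orientations, operon
membership, and the two operator-box sequences reported per region with
their x/14 conservation scores — as an executable fixture: a context genome
and an intensity track that the pipeline's own peak caller, site classifier
and box scorer can be run against and compared with the published calls.

Gene coordinates in the context genome are synthetic (placed to reproduce
each site's spacer/ORF context and flank orientations; real coordinates are
immaterial to the orientation rule); names, strands, order, intensities and
box sequences are the published ones.

One catalogue cell is internally inconsistent: the second box of the
*yfdY*/*lpxP* region is printed with score 9/14, but identity scoring of its
sequence gives 10/14 (its rendering lowercases one matched C).  That cell is
flagged ``score_consistent=False`` and excluded from agreement checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import AnnotatedGenome, Gene, ProbeTrack
from .motif import LLDR_BOX, parse_consensus, render_match, score_match
from .peaks import Peak
from .targets import classify_site, predict_targets

GENOME_LENGTH = 4_641_652  # E. coli K-12 scale


@dataclass(frozen=True)
class ReferenceBox:
    """One reported operator box: printed mixed-case rendering and score."""

    rendered: str  # as catalogued (matched positions uppercase)
    score: int  # catalogued x of x/14
    score_consistent: bool = True  # identity scoring reproduces the catalogued score

    @property
    def sequence(self) -> str:
        return self.rendered.upper()


@dataclass(frozen=True)
class ReferenceSite:
    position: int
    intensity: float
    site_class: str  # "spacer" | "intragenic"
    host_gene: str | None
    left_gene: str
    left_strand: str
    right_gene: str
    right_strand: str
    expected_targets: tuple[str, ...]
    boxes: tuple[ReferenceBox, ReferenceBox]


REFERENCE_SITES: tuple[ReferenceSite, ...] = (
    ReferenceSite(243432, 7.3, "spacer", None, "fadE", "-", "gmhA", "+",
                  ("fadE", "gmhA"),
                  (ReferenceBox("AggaGGTCtGACCAcTT", 12),
                   ReferenceBox("tccTGGTCatAgCAccT", 9))),
    ReferenceSite(2383166, 6.4, "intragenic", "yfbK", "elaD", "+", "yfbL", "+",
                  (),
                  (ReferenceBox("tAtTGGTCaaAgaAcTT", 10),
                   ReferenceBox("tAgaGGcCgGAatAgaT", 8))),
    ReferenceSite(2459264, 6.6, "spacer", None, "yfcZ", "-", "fadL", "+",
                  ("yfcZ", "fadL"),
                  (ReferenceBox("AgcTGGTCcGACCtaTa", 11),
                   ReferenceBox("cAcTGGTCtGAtttcTa", 9))),
    ReferenceSite(2493572, 7.2, "spacer", None, "yfdY", "-", "lpxP", "+",
                  ("yfdY", "lpxP"),
                  (ReferenceBox("tAtaGGTCgGACCAgcT", 11),
                   ReferenceBox("AAtTGGTtgGgcCAtca", 9, score_consistent=False))),
    ReferenceSite(3126270, 13.3, "spacer", None, "glcD", "-", "glcC", "+",
                  ("glcD", "glcC"),
                  (ReferenceBox("AAaTGGTCtGACCggTa", 12),
                   ReferenceBox("cAcaGGTagGACCAaTT", 11))),
    ReferenceSite(3384146, 10.9, "spacer", None, "yhcO", "-", "aaeB", "-",
                  ("yhcO",),
                  (ReferenceBox("cttTcGcCaGACCAaag", 8),
                   ReferenceBox("AAgTGGTagcggCAgga", 8))),
    ReferenceSite(3662638, 13.8, "spacer", None, "gadW", "-", "gadY", "+",
                  ("gadW", "gadY"),
                  (ReferenceBox("tttTGGTCctACCAaaT", 10),
                   ReferenceBox("gAacGGTCaGtgCcgTa", 8))),
    ReferenceSite(3775144, 62.9, "spacer", None, "yibL", "+", "lldP", "+",
                  ("lldP",),
                  (ReferenceBox("AAtTGGcCctACCAaTT", 12),
                   ReferenceBox("AAgTGGcactgCCAaTT", 10))),
)

#: Operon membership of catalogued targets (transcription order).
REFERENCE_OPERONS: tuple[tuple[str, ...], ...] = (
    ("glcD", "glcE", "glcF", "glcG", "glcB", "glcA"),
    ("lldP", "lldR", "lldD"),
)

#: The 12 distinct candidate target genes implied by the catalogue.
EXPECTED_TARGET_GENES = tuple(
    dict.fromkeys(g for site in REFERENCE_SITES for g in site.expected_targets)
)


def reference_genome() -> AnnotatedGenome:
    """Context genome reproducing each catalogued site's flank geometry.

    Flanking genes are placed 100 bp from the peak (span 900 bp); operon
    members extend away from the site in transcription order; the
    intragenic site's host gene straddles its peak position.
    """
    genes: list[Gene] = []

    def left(gid: str, strand: str, p: int, offset: int = 100, span: int = 900) -> None:
        genes.append(Gene(gid, p - offset - span, p - offset, strand))

    def right(gid: str, strand: str, p: int, offset: int = 100, span: int = 900) -> None:
        genes.append(Gene(gid, p + offset, p + offset + span, strand))

    for site in REFERENCE_SITES:
        p = site.position
        if site.site_class == "intragenic":
            genes.append(Gene(site.host_gene, p - 300, p + 300, "+"))
            left(site.left_gene, site.left_strand, p, offset=400)
            right(site.right_gene, site.right_strand, p, offset=400)
        else:
            left(site.left_gene, site.left_strand, p)
            right(site.right_gene, site.right_strand, p)
    # extend operons away from their promoter-proximal first gene
    glcD = next(g for g in genes if g.id == "glcD")
    pos = glcD.start
    for gid in REFERENCE_OPERONS[0][1:]:
        genes.append(Gene(gid, pos - 1000, pos - 100, "-"))
        pos -= 1000
    lldP = next(g for g in genes if g.id == "lldP")
    pos = lldP.end
    for gid in REFERENCE_OPERONS[1][1:]:
        genes.append(Gene(gid, pos + 100, pos + 1000, "+"))
        pos += 1000
    return AnnotatedGenome(
        length=GENOME_LENGTH, genes=tuple(genes), operons=REFERENCE_OPERONS
    )


def reference_track(probe_spacing: int = 100, baseline: float = 1.0) -> ProbeTrack:
    """Probe track carrying the eight catalogued intensities on a flat baseline.

    Each site's intensity is placed on the probe nearest its catalogued
    position; all other probes sit at the baseline ratio.
    """
    from .synthetic import probe_grid

    centres = probe_grid(GENOME_LENGTH, probe_spacing)
    ratios = np.full(centres.size, baseline, dtype=np.float64)
    for site in REFERENCE_SITES:
        idx = int(np.argmin(np.abs(centres - site.position)))
        ratios[idx] = site.intensity
    return ProbeTrack(positions=centres, ratios=ratios, genome_length=GENOME_LENGTH)


def reference_peaks() -> list[Peak]:
    """The eight catalogued sites as Peak objects (catalogued coordinates)."""
    return [
        Peak(position=s.position, intensity=s.intensity,
             span=(s.position, s.position))
        for s in REFERENCE_SITES
    ]


def reproduce_reference() -> dict:
    """Recompute every derivable catalogue cell and report agreement.

    Returns a report dict with per-site target agreement, per-box score and
    rendering agreement (the one internally inconsistent cell excluded), and
    the peak count recovered from the intensity track at cutoff 6.
    """
    from .peaks import call_peaks

    genome = reference_genome()
    consensus = parse_consensus(LLDR_BOX)

    target_rows = []
    predicted_genes: list[str] = []
    for site, peak in zip(REFERENCE_SITES, reference_peaks()):
        ctx = classify_site(peak, genome)
        calls = predict_targets(ctx, genome)
        got = tuple(c.gene for c in calls)
        predicted_genes.extend(got)
        target_rows.append(
            {
                "position": site.position,
                "site_class": (ctx.site_class, site.site_class),
                "targets": (got, site.expected_targets),
                "agree": got == site.expected_targets
                and ctx.site_class == site.site_class,
            }
        )
    distinct = tuple(dict.fromkeys(predicted_genes))

    box_rows = []
    for site in REFERENCE_SITES:
        for k, box in enumerate(site.boxes, start=1):
            score, max_score = score_match(box.sequence, consensus)
            rendered = render_match(box.sequence, consensus)
            box_rows.append(
                {
                    "position": site.position,
                    "box": k,
                    "score": (score, box.score),
                    "rendered": (rendered, box.rendered),
                    "excluded": not box.score_consistent,
                    "agree": (score == box.score and rendered == box.rendered)
                    or not box.score_consistent,
                }
            )

    peaks = call_peaks(reference_track(), cutoff=6.0)
    compared_boxes = [r for r in box_rows if not r["excluded"]]
    report = {
        "sites": target_rows,
        "boxes": box_rows,
        "n_distinct_targets": len(distinct),
        "distinct_targets": distinct,
        "n_peaks_at_cutoff_6": len(peaks),
        "targets_ok": all(r["agree"] for r in target_rows)
        and distinct == EXPECTED_TARGET_GENES,
        "boxes_ok": all(r["agree"] for r in compared_boxes),
        "boxes_compared": len(compared_boxes),
        "peaks_ok": len(peaks) == len(REFERENCE_SITES)
        and all(
            abs(p.intensity - s.intensity) < 1e-9
            for p, s in zip(peaks, REFERENCE_SITES)
        ),
    }
    report["ok"] = report["targets_ok"] and report["boxes_ok"] and report["peaks_ok"]
    return report
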