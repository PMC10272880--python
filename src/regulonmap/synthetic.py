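"""Synthetic genomes, planted operator boxes, and simulated probe tracks.

Desk-scale stand-ins for a genomic-SELEX tiling-array experiment: a random
genome with a user-specified gene/operon plan, operator boxes planted into
intergenic spacers with a controlled number of mismatches, and a probe-ratio
track that emulates the array readout — ~100 bp probe spacing, signal spread
over the 200-300 bp selected-fragment scale, a baseline ratio of 1, and
multiplicative log-normal noise.  Every generator is seeded and the planted
ground truth is returned alongside, so peak calling, target prediction and
motif discovery can all be checked against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import AnnotatedGenome, Gene, ProbeTrack, ValidationError
from .motif import _BASES, DegenerateConsensus

DEFAULT_PROBE_SPACING = 100
DEFAULT_FRAGMENT_LENGTH = 250
DEFAULT_BASELINE = 1.0
DEFAULT_AMPLITUDE = 10.0
DEFAULT_BOX_GAP = 13  # bp between the two boxes of a site (pitch = width + gap)


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------


def generate_genome(seed: int, length: int,
                    gene_plan: Sequence[tuple[str, int, int, str]] = (),
                    operon_plan: Sequence[Sequence[str]] = ()) -> AnnotatedGenome:
    """Random genome (uniform base composition) with the given annotation.

    ``gene_plan`` rows are (id, start, end, strand), 1-based inclusive.
    Overlapping or out-of-bounds genes raise a validation error naming the
    offending gene.  Same seed, same parameters -> identical sequence.
    """
    genes = tuple(Gene(id=g, start=s, end=e, strand=st) for g, s, e, st in gene_plan)
    occupied: list[tuple[int, int, str]] = []
    for g in genes:
        if g.end > length:
            raise ValidationError(f"gene {g.id!r} extends beyond genome length {length}")
        for s, e, other in occupied:
            if g.start <= e and g.end >= s:
                raise ValidationError(f"gene {g.id!r} overlaps gene {other!r}")
        occupied.append((g.start, g.end, g.id))
    rng = np.random.default_rng(seed)
    seq = "".join(np.array(list(_BASES))[rng.integers(0, 4, size=length)])
    return AnnotatedGenome(
        length=length,
        genes=genes,
        operons=tuple(tuple(u) for u in operon_plan),
        sequence=seq,
    )


# ---------------------------------------------------------------------------
# Planting operator boxes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Placement:
    """Where and how to plant one binding site (a set of boxes)."""

    midpoint: int  # 1-based genomic position of the site centre
    n_boxes: int = 2  # operators typically occur as a pair per bound region
    mismatches: int = 0  # substitutions per box, at informative positions
    amplitude: float = DEFAULT_AMPLITUDE  # planted peak apex (ratio units)
    intragenic: bool = False  # allow planting inside an annotated gene


@dataclass(frozen=True)
class PlantedBox:
    start: int  # 1-based genomic start of the 17-mer
    sequence: str
    mismatches: int


@dataclass(frozen=True)
class PlantedSite:
    region_id: str
    position: int  # site centre (the peak's true position)
    amplitude: float
    boxes: tuple[PlantedBox, ...]


@dataclass(frozen=True)
class TruthTable:
    """Ground truth of all planted sites, for recovery tests."""

    sites: tuple[PlantedSite, ...]


def _realise_box(consensus: DegenerateConsensus, mismatches: int,
                 rng: np.random.Generator) -> str:
    informative = consensus.informative_positions
    if mismatches > len(informative):
        raise ValidationError(
            f"requested {mismatches} mismatches but the consensus has only "
            f"{len(informative)} informative positions"
        )
    chars = list(consensus.pattern)
    for i, c in enumerate(chars):
        if c == "n":
            chars[i] = _BASES[rng.integers(0, 4)]
    flip = rng.choice(len(informative), size=mismatches, replace=False)
    for j in np.sort(flip):
        pos = informative[int(j)]
        alternatives = [b for b in _BASES if b != chars[pos]]
        chars[pos] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def plant_sites(genome: AnnotatedGenome, consensus: DegenerateConsensus,
                placements: Sequence[Placement], seed: int,
                box_gap: int = DEFAULT_BOX_GAP) -> tuple[AnnotatedGenome, TruthTable]:
    """Edit the genome sequence to carry operator boxes at each placement.

    Each site gets ``n_boxes`` copies of the consensus (with the requested
    number of informative-position substitutions; 'n' positions filled
    uniformly at random), laid out around the placement midpoint with
    ``box_gap`` bp between consecutive boxes.  Placements must fall in
    intergenic spacers unless flagged ``intragenic``.
    """
    if genome.sequence is None:
        raise ValidationError("cannot plant sites: genome has no sequence")
    rng = np.random.default_rng(seed)
    width = consensus.width
    seq = list(genome.sequence)
    sites: list[PlantedSite] = []
    for idx, pl in enumerate(placements, start=1):
        span = pl.n_boxes * width + (pl.n_boxes - 1) * box_gap
        first_start = pl.midpoint - span // 2  # 1-based
        if first_start < 1 or first_start + span - 1 > genome.length:
            raise ValidationError(
                f"placement at {pl.midpoint} puts boxes outside the genome"
            )
        boxes: list[PlantedBox] = []
        for b in range(pl.n_boxes):
            start = first_start + b * (width + box_gap)
            end = start + width - 1
            if not pl.intragenic:
                for g in genome.genes:
                    if start <= g.end and end >= g.start:
                        raise ValidationError(
                            f"placement at {pl.midpoint} overlaps gene {g.id!r}; "
                            f"flag it intragenic to allow this"
                        )
            box_seq = _realise_box(consensus, pl.mismatches, rng)
            seq[start - 1 : end] = list(box_seq)
            boxes.append(PlantedBox(start=start, sequence=box_seq,
                                    mismatches=pl.mismatches))
        sites.append(
            PlantedSite(region_id=f"site{idx}", position=pl.midpoint,
                        amplitude=pl.amplitude, boxes=tuple(boxes))
        )
    edited = replace(genome, sequence="".join(seq))
    return edited, TruthTable(sites=tuple(sites))


# ---------------------------------------------------------------------------
# Probe-track simulation
# ---------------------------------------------------------------------------


def probe_grid(genome_length: int, probe_spacing: int) -> np.ndarray:
    """Regular probe centres: one per ``probe_spacing`` bp tile."""
    centres = np.arange(0, genome_length - probe_spacing + 1, probe_spacing,
                        dtype=np.int64) + probe_spacing // 2 + 1
    return centres


def simulate_probe_track(genome: AnnotatedGenome, truth: TruthTable,
                         probe_spacing: int = DEFAULT_PROBE_SPACING,
                         fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
                         baseline: float = DEFAULT_BASELINE,
                         noise_sd: float = 0.0, seed: int = 0,
                         jitter: int = 0) -> ProbeTrack:
    """Simulate the array readout for a genome with planted sites.

    Each site contributes a triangular bump of half-width
    ``fragment_length`` centred on its position, apex equal to its
    amplitude; overlapping bumps combine by maximum so a site's apex stays
    at its stated amplitude.  The deterministic value at a probe is
    max(baseline, bump), multiplied by log-normal noise
    exp(N(0, noise_sd^2)).  ``jitter`` (bp) optionally perturbs each probe
    centre uniformly in [-jitter, +jitter] to emulate uneven probe spacing;
    it must stay below half the spacing so order is preserved.
    """
    if probe_spacing <= 0:
        raise ValidationError(f"probe_spacing must be positive, got {probe_spacing}")
    if fragment_length <= 0:
        raise ValidationError(f"fragment_length must be positive, got {fragment_length}")
    if noise_sd < 0:
        raise ValidationError(f"noise_sd must be non-negative, got {noise_sd}")
    if jitter < 0 or 2 * jitter >= probe_spacing:
        if jitter:
            raise ValidationError("jitter must satisfy 0 <= 2*jitter < probe_spacing")
    rng = np.random.default_rng(seed)
    centres = probe_grid(genome.length, probe_spacing)
    if jitter:
        centres = centres + rng.integers(-jitter, jitter + 1, size=centres.size)
        centres = np.clip(centres, 1, genome.length)
    values = np.full(centres.size, baseline, dtype=np.float64)
    for site in truth.sites:
        d = np.abs(centres - site.position)
        bump = site.amplitude * np.clip(1.0 - d / fragment_length, 0.0, None)
        values = np.maximum(values, bump)
    if noise_sd > 0:
        values = values * np.exp(rng.normal(0.0, noise_sd, size=values.size))
    return ProbeTrack(positions=centres, ratios=values, genome_length=genome.length)


# ---------------------------------------------------------------------------
# One-call demo dataset
# ---------------------------------------------------------------------------


def simulate_dataset(seed: int, n_sites: int = 8, site_spacing: int = 5000,
                     consensus: DegenerateConsensus | None = None,
                     mismatches: int = 0, amplitude: float = DEFAULT_AMPLITUDE,
                     noise_sd: float = 0.0, probe_spacing: int = DEFAULT_PROBE_SPACING,
                     fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
                     ) -> tuple[AnnotatedGenome, TruthTable, ProbeTrack]:
    """Complete synthetic experiment: genome + planted sites + probe track.

    Each site sits in the spacer of a divergent gene pair (gL on the minus
    strand to the left, gR on the plus strand to the right), so the
    orientation rule should recover both flanks of every site.
    """
    if consensus is None:
        from .motif import LLDR_BOX, parse_consensus

        consensus = parse_consensus(LLDR_BOX)
    length = (n_sites + 1) * site_spacing
    gene_plan = []
    placements = []
    for i in range(1, n_sites + 1):
        m = i * site_spacing - site_spacing // 2
        # snap the site centre onto a probe centre so the apex is sampled
        m = (m // probe_spacing) * probe_spacing + probe_spacing // 2 + 1
        gene_plan.append((f"g{i}L", m - 1100, m - 200, "-"))
        gene_plan.append((f"g{i}R", m + 200, m + 1100, "+"))
        placements.append(
            Placement(midpoint=m, mismatches=mismatches, amplitude=amplitude)
        )
    genome = generate_genome(seed, length, gene_plan)
    genome, truth = plant_sites(genome, consensus, placements, seed=seed + 1)
    track = simulate_probe_track(
        genome, truth, probe_spacing=probe_spacing,
        fragment_length=fragment_length, noise_sd=noise_sd, seed=seed + 2,
    )
    return genome, truth, track


# ---------------------------------------------------------------------------
# Truth-table TSV round trip
# ---------------------------------------------------------------------------


def write_truth(truth: TruthTable, path: str | Path) -> None:
    rows = []
    for site in truth.sites:
        for box in site.boxes:
            rows.append(
                {
                    "region_id": site.region_id,
                    "site_position": site.position,
                    "amplitude": site.amplitude,
                    "box_start": box.start,
                    "box_sequence": box.sequence,
                    "mismatches": box.mismatches,
                }
            )
    pd.DataFrame(
        rows,
        columns=["region_id", "site_position", "amplitude", "box_start",
                 "box_sequence", "mismatches"],
    ).to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> TruthTable:
    df = pd.read_csv(path, sep="\t", dtype={"box_sequence": str})
    sites: list[PlantedSite] = []
    for (rid, pos, amp), group in df.groupby(
        ["region_id", "site_position", "amplitude"], sort=False
    ):
        boxes = tuple(
            PlantedBox(start=int(r.box_start), sequence=str(r.box_sequence),
                       mismatches=int(r.mismatches))
            for r in group.itertuples()
        )
        sites.append(PlantedSite(region_id=str(rid), position=int(pos),
                                 amplitude=float(amp), boxes=boxes))
    return TruthTable(sites=tuple(sites))
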