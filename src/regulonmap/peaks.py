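"""Peak calling on probe-ratio tracks.

A binding site on a tiling array shows up as a run of probes whose
enrichment ratio clears a fixed cutoff (6.0 by default, on the linear ratio
scale).  Because the selected fragments are longer than the probe spacing,
one site can light up several adjacent probes and a site bound at multiple
nearby operators can split into close runs — runs closer than ``merge_gap``
are therefore merged into a single peak.  No background model or FDR is
involved: the method is a deliberate, reproducible threshold rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ProbeTrack, ValidationError, read_track

__all__ = ["Peak", "call_peaks", "read_track", "write_peaks", "read_peaks"]

DEFAULT_CUTOFF = 6.0
DEFAULT_MERGE_GAP = 300


@dataclass(frozen=True)
class Peak:
    """A called binding site: argmax probe position, its ratio, and the span
    of above-cutoff probes."""

    position: int
    intensity: float
    span: tuple[int, int]

    def __post_init__(self) -> None:
        lo, hi = self.span
        if not (lo <= self.position <= hi):
            raise ValidationError(f"peak position {self.position} outside span {self.span}")


def call_peaks(track: ProbeTrack, cutoff: float = DEFAULT_CUTOFF,
               merge_gap: int = DEFAULT_MERGE_GAP) -> list[Peak]:
    """Call peaks as merged runs of probes with ratio >= cutoff.

    Maximal runs of consecutive above-cutoff probes are found first; runs
    whose nearest above-cutoff probes lie within ``merge_gap`` bp of each
    other are then merged.  Each peak reports the leftmost argmax probe as
    its position and the maximal ratio as its intensity.  An empty track
    yields an empty list.
    """
    if cutoff <= 0:
        raise ValidationError(f"cutoff must be positive, got {cutoff}")
    if merge_gap < 0:
        raise ValidationError(f"merge_gap must be non-negative, got {merge_gap}")
    above = np.flatnonzero(track.ratios >= cutoff)
    if above.size == 0:
        return []
    # group consecutive probe indices into runs
    breaks = np.flatnonzero(np.diff(above) > 1)
    runs = np.split(above, breaks + 1)
    # merge runs whose flanking above-cutoff probes are within merge_gap bp
    merged: list[np.ndarray] = [runs[0]]
    for run in runs[1:]:
        gap = track.positions[run[0]] - track.positions[merged[-1][-1]]
        if gap <= merge_gap:
            merged[-1] = np.concatenate([merged[-1], run])
        else:
            merged.append(run)
    peaks = []
    for run in merged:
        ratios = track.ratios[run]
        best = run[int(np.argmax(ratios))]  # argmax is leftmost on ties
        peaks.append(
            Peak(
                position=int(track.positions[best]),
                intensity=float(track.ratios[best]),
                span=(int(track.positions[run[0]]), int(track.positions[run[-1]])),
            )
        )
    return peaks


def write_peaks(peaks: list[Peak], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "peak_id": [f"peak{i + 1}" for i in range(len(peaks))],
            "position": [p.position for p in peaks],
            "intensity": [p.intensity for p in peaks],
            "span_start": [p.span[0] for p in peaks],
            "span_end": [p.span[1] for p in peaks],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_peaks(path: str | Path) -> list[Peak]:
    df = pd.read_csv(path, sep="\t")
    return [
        Peak(position=int(r.position), intensity=float(r.intensity),
             span=(int(r.span_start), int(r.span_end)))
        for r in df.itertuples()
    ]
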