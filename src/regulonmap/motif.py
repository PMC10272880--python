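"""Degenerate palindromic consensus boxes: parsing, scoring, scanning, discovery.

The operator model is a fixed-width pattern over {A, C, G, T, n} where 'n'
marks an uninformative position (any base).  A candidate site is scored by
counting identities at the informative positions only, so a 17-bp box with
three n's is reported as "x/14".  The canonical example is the LldR operator
of *Escherichia coli* K-12, ``AAnTGGTCnGACCAnTT`` — a 17-bp palindrome whose
two half-sites each bind one protomer of the GntR-family regulator.

Discovery is a deterministic consensus-refinement loop (seeded greedy search
plus majority update over a position frequency matrix), an intentionally
transparent alternative to EM-style motif finders: the objective is exact
recovery of a planted degenerate consensus, not probabilistic modelling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import ValidationError

#: The published LldR operator box (17 bp, palindromic, 14 informative positions).
LLDR_BOX = "AAnTGGTCnGACCAnTT"

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "n": "n"}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (preserving 'n' wildcards)."""
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(seq.upper().replace("N", "n")))
    except KeyError as exc:
        raise ValidationError(f"not a DNA/degenerate character: {exc.args[0]!r}") from None


# ---------------------------------------------------------------------------
# Consensus representation and pairwise scoring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DegenerateConsensus:
    """A degenerate consensus pattern over {A, C, G, T, n}."""

    pattern: str

    @property
    def width(self) -> int:
        return len(self.pattern)

    @property
    def informative_positions(self) -> tuple[int, ...]:
        return tuple(i for i, c in enumerate(self.pattern) if c != "n")

    @property
    def informative_count(self) -> int:
        return sum(1 for c in self.pattern if c != "n")


def parse_consensus(text: str) -> DegenerateConsensus:
    """Parse a consensus string; 'N'/'n' are normalised to lowercase 'n'.

    Raises :class:`ValidationError` naming the (1-based) position of the
    first illegal character.
    """
    if not text:
        raise ValidationError("empty consensus pattern")
    out = []
    for i, ch in enumerate(text):
        up = ch.upper()
        if up == "N":
            out.append("n")
        elif up in _BASE_INDEX:
            out.append(up)
        else:
            raise ValidationError(
                f"illegal character {ch!r} in consensus at position {i + 1}"
            )
    return DegenerateConsensus("".join(out))


def is_palindromic(consensus: DegenerateConsensus) -> bool:
    """True iff the pattern equals its own reverse complement (n pairs with n)."""
    return revcomp(consensus.pattern) == consensus.pattern


def score_match(seq: str, consensus: DegenerateConsensus) -> tuple[int, int]:
    """Count identities at informative positions; returns (score, max score).

    Case-insensitive; only {A,C,G,T} sequences of exactly the consensus width
    are accepted.
    """
    if len(seq) != consensus.width:
        raise ValidationError(
            f"sequence length {len(seq)} != consensus width {consensus.width}"
        )
    up = seq.upper()
    bad = set(up) - set(_BASES)
    if bad:
        raise ValidationError(f"sequence contains non-ACGT characters: {sorted(bad)}")
    score = sum(
        1 for i in consensus.informative_positions if up[i] == consensus.pattern[i]
    )
    return score, consensus.informative_count


def render_match(seq: str, consensus: DegenerateConsensus) -> str:
    """Mixed-case rendering: matched informative positions uppercase, rest lowercase."""
    score_match(seq, consensus)  # validates length and alphabet
    up = seq.upper()
    informative = set(consensus.informative_positions)
    return "".join(
        c if (i in informative and c == consensus.pattern[i]) else c.lower()
        for i, c in enumerate(up)
    )


# ---------------------------------------------------------------------------
# Region scanning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoxMatch:
    """A scored occurrence of a consensus box within a region.

    ``offset`` is the 0-based start of the window on the region's forward
    strand; for a minus-strand match ``raw`` is the reverse complement of
    that window (i.e. the sequence in consensus orientation).
    """

    region_id: str
    offset: int
    strand: str
    raw: str
    score: int
    max_score: int
    rendered: str


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def _window_scores(enc_region: np.ndarray, pattern_enc: np.ndarray,
                   informative: np.ndarray) -> np.ndarray:
    """Identity score of every window of ``enc_region`` against the pattern."""
    w = pattern_enc.size
    if enc_region.size < w:
        return np.zeros(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(enc_region, w)
    if informative.size == 0:
        return np.zeros(windows.shape[0], dtype=np.int64)
    return (windows[:, informative] == pattern_enc[informative]).sum(axis=1)


def scan_region(region: str, consensus: DegenerateConsensus, top_k: int = 2,
                both_strands: bool = True, region_id: str = "region") -> list[BoxMatch]:
    """Score every window of a region and return the top_k non-overlapping hits.

    Windows on both strands are ranked by score (ties: smaller offset, then
    forward strand) and selected greedily so that the reported occupied
    intervals do not overlap on the forward coordinate system.
    """
    region = region.upper()
    w = consensus.width
    if len(region) < w:
        raise ValidationError(
            f"region length {len(region)} shorter than consensus width {w}"
        )
    pattern_enc = _encode(consensus.pattern.replace("n", "A"))
    informative = np.asarray(consensus.informative_positions, dtype=np.int64)
    enc_fwd = _encode(region)
    candidates: list[tuple[int, int, int, str]] = []  # (-score, offset, strand_rank)
    fwd_scores = _window_scores(enc_fwd, pattern_enc, informative)
    for off, sc in enumerate(fwd_scores):
        candidates.append((-int(sc), off, 0, "+"))
    if both_strands:
        enc_rev = _encode(revcomp(region))
        rev_scores = _window_scores(enc_rev, pattern_enc, informative)
        n_win = len(region) - w
        for off_rc, sc in enumerate(rev_scores):
            # window at offset off_rc on the reverse strand covers forward
            # interval starting at n_win - off_rc
            candidates.append((-int(sc), n_win - off_rc, 1, "-"))
    candidates.sort()
    chosen: list[BoxMatch] = []
    occupied: list[tuple[int, int]] = []
    for neg_score, off, _rank, strand in candidates:
        if len(chosen) >= top_k:
            break
        if any(off < e and off + w > s for s, e in occupied):
            continue
        window = region[off : off + w]
        raw = window if strand == "+" else revcomp(window)
        chosen.append(
            BoxMatch(
                region_id=region_id,
                offset=off,
                strand=strand,
                raw=raw,
                score=-neg_score,
                max_score=consensus.informative_count,
                rendered=render_match(raw, consensus),
            )
        )
        occupied.append((off, off + w))
    return chosen


# ---------------------------------------------------------------------------
# Position frequency matrix and information content
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Per-position base counts (columns A, C, G, T) over aligned sites.

    Counts may be fractional after palindromic symmetrisation; every row
    still sums to the site count.
    """

    counts: np.ndarray  # shape (width, 4), float64
    n_sites: float

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.float64)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValidationError("PFM counts must have shape (width, 4)")
        if np.any(counts < 0):
            raise ValidationError("PFM counts must be non-negative")
        if counts.shape[0] and not np.allclose(counts.sum(axis=1), self.n_sites):
            raise ValidationError("PFM column sums must equal the site count")

    @property
    def width(self) -> int:
        return int(self.counts.shape[0])

    def reverse_complement(self) -> "PositionFrequencyMatrix":
        # complement = swap A<->T and C<->G columns; reverse position order
        return PositionFrequencyMatrix(self.counts[::-1, [3, 2, 1, 0]], self.n_sites)


def pfm_from_sites(sites: Sequence[str]) -> PositionFrequencyMatrix:
    if not sites:
        raise ValidationError("cannot build a PFM from zero sites")
    width = len(sites[0])
    counts = np.zeros((width, 4), dtype=np.float64)
    for s in sites:
        if len(s) != width:
            raise ValidationError("aligned sites must share one width")
        for i, c in enumerate(s.upper()):
            counts[i, _BASE_INDEX[c]] += 1
    return PositionFrequencyMatrix(counts, float(len(sites)))


def information_content(pfm: PositionFrequencyMatrix) -> np.ndarray:
    """Per-position information content in bits: 2 + sum_b p_b log2 p_b."""
    if pfm.width == 0 or pfm.n_sites < 1:
        raise ValidationError("empty PFM")
    p = pfm.counts / pfm.n_sites
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    return 2.0 + plogp.sum(axis=1)


# ---------------------------------------------------------------------------
# Consensus discovery
# ---------------------------------------------------------------------------


def _best_site(region_enc_fwd: np.ndarray, region_enc_rev: np.ndarray,
               region: str, pattern_enc: np.ndarray,
               informative: np.ndarray, width: int) -> tuple[int, str, str]:
    """Best-scoring window (both strands) of one region under a consensus.

    Ties resolve to the smaller forward offset, then the forward strand.
    Returns (score, site sequence in consensus orientation, strand).
    """
    fwd = _window_scores(region_enc_fwd, pattern_enc, informative)
    rev = _window_scores(region_enc_rev, pattern_enc, informative)
    n_win = len(region) - width
    best = (-1, 0, 2, "")
    for off, sc in enumerate(fwd):
        cand = (int(sc), -off, 1, region[off : off + width])
        if (cand[0], cand[1], cand[2]) > (best[0], best[1], best[2]):
            best = cand
    for off_rc, sc in enumerate(rev):
        fwd_off = n_win - off_rc
        site = revcomp(region[fwd_off : fwd_off + width])
        cand = (int(sc), -fwd_off, 0, site)
        if (cand[0], cand[1], cand[2]) > (best[0], best[1], best[2]):
            best = cand
    return best[0], best[3], "+" if best[2] == 1 else "-"


def _consensus_from_pfm(pfm: PositionFrequencyMatrix,
                        informative_fraction: float) -> str:
    out = []
    for row in pfm.counts:
        idx = int(np.argmax(row))  # argmax ties resolve to A<C<G<T order
        if row[idx] >= informative_fraction * pfm.n_sites:
            out.append(_BASES[idx])
        else:
            out.append("n")
    return "".join(out)


def discover_consensus(regions: Sequence[str], width: int = 17,
                       informative_fraction: float = 0.5, max_iter: int = 50,
                       seed: int = 0, palindromic: bool = False,
                       ) -> tuple[DegenerateConsensus, PositionFrequencyMatrix]:
    """Discover a shared degenerate consensus across regions.

    The loop: (1) seed with the window of the first region whose exact
    sequence is best conserved across all regions; (2) align each region by
    its best-scoring window under the current consensus (both strands);
    (3) rebuild the position frequency matrix from those sites, symmetrising
    with its reverse complement when ``palindromic``; (4) call each position's
    modal base when its frequency reaches ``informative_fraction``, else 'n';
    iterate to a fixed point or ``max_iter``.  Deterministic for a given
    input order; ``seed`` is accepted for interface stability but the search
    itself is exhaustive, not sampled.
    """
    if len(regions) < 2:
        raise ValidationError("consensus discovery needs at least 2 regions")
    for r in regions:
        if len(r) < width:
            raise ValidationError("every region must be at least the motif width")
    regions = [r.upper() for r in regions]
    enc_fwd = [_encode(r) for r in regions]
    enc_rev = [_encode(revcomp(r)) for r in regions]
    all_informative = np.arange(width, dtype=np.int64)

    # (1) seed: candidate windows from the first region, both strands,
    # ranked by summed best-match identity across all regions.  The top few
    # frames are each refined to a fixed point (a one-bp frame error in the
    # single best candidate is common when the motif has repetitive or
    # palindromic structure), and the refinement with the highest total
    # matched-informative-position count wins.
    ranked: list[tuple[int, int, str]] = []
    r0 = regions[0]
    strands = [r0, revcomp(r0)]
    for strand_rank, strand_seq in enumerate(strands):
        for off in range(len(r0) - width + 1):
            cand = strand_seq[off : off + width]
            cand_enc = _encode(cand)
            total = 0
            for ef, er in zip(enc_fwd, enc_rev):
                fs = _window_scores(ef, cand_enc, all_informative)
                rs = _window_scores(er, cand_enc, all_informative)
                total += max(int(fs.max(initial=0)), int(rs.max(initial=0)))
            ranked.append((-total, strand_rank, cand))
    ranked.sort()
    seeds = list(dict.fromkeys(cand for _, _, cand in ranked[:5]))

    def refine(pattern: str) -> tuple[str, PositionFrequencyMatrix, float]:
        # objective: matched informative positions in excess of the 25%
        # expected by chance, so patterns with different numbers of
        # informative positions compare fairly
        pfm = None
        excess = 0.0
        for _ in range(max_iter):
            cons = DegenerateConsensus(pattern)
            pattern_enc = _encode(cons.pattern.replace("n", "A"))
            informative = np.asarray(cons.informative_positions, dtype=np.int64)
            sites = []
            total = 0
            for region, ef, er in zip(regions, enc_fwd, enc_rev):
                sc, site, _ = _best_site(ef, er, region, pattern_enc,
                                         informative, width)
                sites.append(site)
                total += sc
            excess = total - 0.25 * len(regions) * cons.informative_count
            pfm = pfm_from_sites(sites)
            if palindromic:
                pfm = PositionFrequencyMatrix(
                    (pfm.counts + pfm.reverse_complement().counts) / 2.0,
                    pfm.n_sites,
                )
            new_pattern = _consensus_from_pfm(pfm, informative_fraction)
            if new_pattern == pattern:
                break
            pattern = new_pattern
        return pattern, pfm, excess

    best: tuple[str, PositionFrequencyMatrix, float] | None = None
    for seed_pattern in seeds:
        result = refine(seed_pattern)
        if best is None or result[2] > best[2]:
            best = result

    # (5) frame correction: a fixed point can sit a few bp off the true
    # frame; hill-climb over shifted restarts while the objective improves.
    def shift(pattern: str, k: int) -> str:
        out = ["n"] * width
        for i in range(width):
            j = i - k
            if 0 <= j < width:
                out[i] = pattern[j]
        return "".join(out)

    for _ in range(width):
        improved = False
        shifts = sorted(range(-(width // 2), width // 2 + 1),
                        key=lambda k: (abs(k), k))
        for k in shifts[1:]:  # skip k=0
            cand = shift(best[0], k)
            if set(cand) == {"n"}:
                continue
            result = refine(cand)
            if result[2] > best[2]:
                best = result
                improved = True
                break
        if not improved:
            break
    pattern, pfm, _ = best
    return DegenerateConsensus(pattern), pfm
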