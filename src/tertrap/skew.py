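"""GC-skew profiles, origin/terminus inflection, activity-weighted termination.

On the leading strand of most bacterial chromosomes G outnumbers C, so the
windowed skew (G-C)/(G+C) is positive on one replichore and negative on
the other, switching sign at oriC and at the terminus.  The cumulative sum
of non-overlapping window skews therefore ramps up from origin to terminus
and back down: its global maximum estimates the terminus, its global
minimum the origin (for a conventionally oriented record; an orientation
flag flips the assignment).

The expected termination position weights functional Ter site positions by
their measured fork-arrest activity and takes the circular weighted mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .genome import CircularGenome, GenomeError, reverse_complement


@dataclass
class SkewProfile:
    """Windowed GC-skew over a circular genome.

    ``values[i]`` is (G-C)/(G+C) of the window centered at ``centers[i]``
    (0 where the window has no G or C).  ``cumulative`` is the running sum
    of values, defined for non-overlapping tilings (step == window).
    """

    genome_id: str
    L: int
    window: int
    step: int
    centers: np.ndarray
    values: np.ndarray
    cumulative: Optional[np.ndarray] = None
    origin_estimate: Optional[int] = None
    terminus_estimate: Optional[int] = None
    flat: bool = False

    def to_bedgraph(self, cumulative: bool = False) -> str:
        vals = self.cumulative if cumulative else self.values
        if vals is None:
            raise GenomeError("cumulative curve not computed")
        lines = []
        for c, v in zip(self.centers, vals):
            s0 = int(c - 1 - self.step // 2) % self.L
            lines.append(f"{self.genome_id}\t{max(s0, 0)}\t{min(s0 + self.step, self.L)}\t{v:.6g}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class TerActivity:
    """Fractional replication-arrest activity measured at one Ter site."""

    position: int
    activity: float  # percent of fork-arrest events, >= 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.activity < 0:
            raise GenomeError("activity must be non-negative")


def gc_skew_profile(g: CircularGenome, window: int = 5000, step: Optional[int] = None) -> SkewProfile:
    """Tile the circle with windows and compute (G-C)/(G+C) per window.

    ``step`` defaults to ``window`` (non-overlapping tiling, required for
    the cumulative curve).  Windows wrap the origin.
    """
    L = g.length
    if step is None:
        step = window
    if not 0 < window <= L:
        raise GenomeError(f"window {window} outside 1..{L}")
    if not 0 < step <= window:
        raise GenomeError("step must be in 1..window")
    codes = np.frombuffer(g.sequence.encode("ascii"), dtype=np.uint8)
    is_g = (codes == ord("G")).astype(np.int64)
    is_c = (codes == ord("C")).astype(np.int64)
    # prefix sums over a doubled genome for wrap-around windows
    ext_g = np.concatenate([is_g, is_g])
    ext_c = np.concatenate([is_c, is_c])
    cg = np.concatenate([[0], np.cumsum(ext_g)])
    cc = np.concatenate([[0], np.cumsum(ext_c)])
    starts = np.arange(0, L, step)
    gcounts = cg[starts + window] - cg[starts]
    ccounts = cc[starts + window] - cc[starts]
    denom = gcounts + ccounts
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(denom > 0, (gcounts - ccounts) / np.maximum(denom, 1), 0.0)
    centers = (starts + window // 2) % L + 1
    return SkewProfile(
        genome_id=g.id, L=L, window=window, step=step,
        centers=centers, values=values.astype(float),
    )


def cumulative_skew(p: SkewProfile) -> SkewProfile:
    """Fill the cumulative curve (requires a non-overlapping tiling)."""
    if p.step != p.window:
        raise GenomeError("cumulative skew requires step == window")
    p.cumulative = np.cumsum(p.values)
    return p


def skew_extrema(
    p: SkewProfile, terminus_at_max: bool = True, flat_tol: float = 1e-12
) -> tuple[Optional[int], Optional[int]]:
    """Origin and terminus estimates from the cumulative-skew extrema.

    Returns ``(origin_estimate, terminus_estimate)`` window-center
    positions; resolution is one window.  With ``terminus_at_max`` (the
    conventional record orientation, leading-strand G excess) the terminus
    is the global maximum and the origin the global minimum; flipping the
    flag swaps them.  A flat cumulative curve yields (None, None) and sets
    ``p.flat``.
    """
    if p.cumulative is None:
        cumulative_skew(p)
    cum = p.cumulative
    if float(np.ptp(cum)) <= flat_tol:
        p.flat = True
        p.origin_estimate = p.terminus_estimate = None
        return None, None
    imax = int(np.argmax(cum))
    imin = int(np.argmin(cum))
    if terminus_at_max:
        term, ori = int(p.centers[imax]), int(p.centers[imin])
    else:
        term, ori = int(p.centers[imin]), int(p.centers[imax])
    p.origin_estimate, p.terminus_estimate = ori, term
    return ori, term


def expected_termination_position(
    acts: Sequence[TerActivity], L: int
) -> int:
    """Activity-weighted mean Ter position, on the circle.

    All sites must lie within one semicircle, otherwise the circular mean
    is ambiguous and an error is raised.  The arc containing the sites is
    unrolled around the first site, the weighted mean taken there, and the
    result mapped back to 1..L.  Invariant under coordinate rotation and
    uniform weight scaling.
    """
    acts = list(acts)
    if not acts or all(a.activity == 0 for a in acts):
        raise GenomeError("at least one positive activity required")
    ref = acts[0].position
    unrolled = []
    for a in acts:
        d = (a.position - ref) % L
        if d > L / 2:
            d -= L
        unrolled.append(d)
    if max(unrolled) - min(unrolled) > L / 2:
        raise GenomeError("Ter sites span more than half the chromosome")
    w = np.array([a.activity for a in acts], dtype=float)
    x = np.array(unrolled, dtype=float)
    mean = float(np.sum(w * x) / np.sum(w))
    return int(round(ref - 1 + mean)) % L + 1


@dataclass(frozen=True)
class DifHit:
    """Best dif-motif match; ``ties`` lists equally good alternatives."""

    position: int
    strand: str
    mismatches: int
    ties: tuple[tuple[int, str], ...] = ()

    @property
    def ambiguous(self) -> bool:
        return len(self.ties) > 0


def locate_dif(
    g: CircularGenome, dif_motif: str, max_mismatch: int = 3
) -> Optional[DifHit]:
    """Best-matching window for the dif motif on either strand.

    Returns the window start (forward 1-based) with the fewest mismatches
    within the budget, or None.  Equally good windows are reported as ties
    and flagged ambiguous.
    """
    m = len(dif_motif)
    if m > g.length:
        raise GenomeError("motif longer than genome")
    codes = np.frombuffer(g.sequence.encode("ascii"), dtype=np.uint8)
    L = g.length
    ext = np.concatenate([codes, codes[: m - 1]])
    best_mm = max_mismatch + 1
    hits: list[tuple[int, str]] = []
    for strand, motif in (("+", dif_motif), ("-", reverse_complement(dif_motif))):
        q = np.frombuffer(motif.encode("ascii"), dtype=np.uint8)
        matches = np.zeros(L, dtype=np.int32)
        for k in range(m):
            matches += ext[k : k + L] == q[k]
        mm = m - matches
        cand = int(mm.min())
        if cand < best_mm:
            best_mm = cand
            hits = [(int(i) + 1, strand) for i in np.nonzero(mm == cand)[0]]
        elif cand == best_mm:
            hits += [(int(i) + 1, strand) for i in np.nonzero(mm == cand)[0]]
    if best_mm > max_mismatch or not hits:
        return None
    hits.sort()
    pos, strand = hits[0]
    return DifHit(pos, strand, best_mm, ties=tuple(hits[1:]))
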