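"""Replication fork trap architecture: polarity, innermost sites, width, type.

Two replication forks leave oriC in opposite rotational directions
(clockwise = increasing genome coordinate here) and are confined to the
terminus region by oppositely oriented Tus-Ter clusters.  Each Ter site
arrests the fork approaching its non-permissive face only; the "innermost"
site of a replichore is the first blocking site that fork meets.  The trap
width is the arc between the two innermost sites along the terminus arc
(the arc not containing oriC).  A trap is type I when one of its innermost
sites is the Ter vicinal to the tus gene, type II otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

from .genome import directed_distance
from .motif import TER_LENGTH, TerSite

CW, CCW = "CW", "CCW"


@dataclass(frozen=True)
class PolarityConvention:
    """Maps displayed-strand orientation to the blocked fork direction.

    The constant cannot be derived from the motif alone; it is calibrated
    so that sites planted in the E. coli TerB/TerC/TerG genomic orientation
    (displayed motif on the forward strand of a conventionally oriented
    record) block the clockwise-moving fork.  ``invert=True`` flips every
    assignment, for genomes deposited in the opposite orientation.
    """

    invert: bool = False

    def blocked_direction(self, site: TerSite) -> str:
        primary = CW if site.strand == "+" else CCW
        if self.invert:
            return CCW if primary == CW else CW
        return primary


DEFAULT_CONVENTION = PolarityConvention()


def blocked_direction(
    site: TerSite, convention: PolarityConvention = DEFAULT_CONVENTION
) -> str:
    """Rotational direction of the fork this site arrests (CW or CCW)."""
    return convention.blocked_direction(site)


@dataclass
class ForkTrap:
    """A classified replication fork trap.

    ``innermost_cw`` / ``innermost_ccw`` are the first CW- and CCW-blocking
    sites met by the respective forks; either may be None ("open" trap on
    that replichore).  ``width`` is in bases along the terminus arc;
    ``trap_type`` is 'I', 'II', or None when the trap is open/unclassified.
    """

    genome_id: str
    oriC: int
    L: int
    sites: list[TerSite]
    innermost_cw: Optional[TerSite]
    innermost_ccw: Optional[TerSite]
    width: Optional[int]
    trap_type: Optional[str]
    vicinal: Optional[TerSite]
    midpoint: Optional[int]
    blocked: dict[int, str] = field(default_factory=dict)  # site start -> CW/CCW

    @property
    def width_kb(self) -> Optional[float]:
        return None if self.width is None else self.width / 1000.0

    @property
    def is_open(self) -> bool:
        return self.innermost_cw is None or self.innermost_ccw is None

    def to_dict(self) -> dict:
        def site_d(s: Optional[TerSite]) -> Optional[dict]:
            if s is None:
                return None
            return {
                "label": s.label,
                "start": s.start,
                "strand": s.strand,
                "identity_pct": s.identity_pct,
                "core_ok": s.core_ok,
                "blocked": self.blocked.get(s.start),
                "sequence": s.bases,
            }

        return {
            "genome": self.genome_id,
            "oriC": self.oriC,
            "length": self.L,
            "sites": [site_d(s) for s in self.sites],
            "innermost_cw": site_d(self.innermost_cw),
            "innermost_ccw": site_d(self.innermost_ccw),
            "width_bases": self.width,
            "width_kb": None if self.width is None else round(self.width / 1000),
            "trap_type": self.trap_type,
            "vicinal_label": self.vicinal.label if self.vicinal else None,
            "midpoint": self.midpoint,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def innermost_blocking_sites(
    sites: list[TerSite],
    oriC: int,
    L: int,
    convention: PolarityConvention = DEFAULT_CONVENTION,
) -> tuple[Optional[TerSite], Optional[TerSite]]:
    """First blocking site met by each fork leaving oriC.

    Distances are directed arc lengths from oriC to each site's
    non-permissive face, taken at the lock-base G(6) coordinate (any fixed
    end choice shifts distances by <= 23 bp, below kb reporting
    resolution).  A replichore with no blocking site yields None (open
    trap), not an exception.
    """
    best: dict[str, tuple[int, TerSite]] = {}
    for s in sites:
        d = convention.blocked_direction(s)
        dist = directed_distance(oriC, s.lock_coordinate(L), L, d)
        if d not in best or dist < best[d][0]:
            best[d] = (dist, s)
    return (
        best.get(CW, (None, None))[1],
        best.get(CCW, (None, None))[1],
    )


def _terminus_arc(cw_pos: int, ccw_pos: int, oriC: int, L: int) -> tuple[int, int]:
    """(arc start position, arc length) of the innermost-pair arc avoiding oriC.

    In a non-overlapping trap the CW-blocking site precedes the CCW-blocking
    one on the clockwise path from oriC; in an overlapping trap (the E. coli
    type II arrangement) each fork travels past the other's stop point, the
    order reverses, and the terminus arc runs the other way.  Either way the
    width is the arc between the pair that does not contain oriC.
    """
    fwd = (ccw_pos - cw_pos) % L  # arc cw_pos -> ccw_pos, clockwise
    if (oriC - cw_pos) % L < fwd:  # that arc contains oriC: take the other
        return ccw_pos, L - fwd
    return cw_pos, fwd


def trap_width(cw: TerSite, ccw: TerSite, oriC: int, L: int) -> int:
    """Arc length between the innermost pair along the arc NOT containing oriC."""
    _, width = _terminus_arc(
        cw.lock_coordinate(L), ccw.lock_coordinate(L), oriC, L
    )
    return width


def classify_trap_type(trap: ForkTrap) -> Optional[str]:
    """Type I iff the tus-vicinal site is one of the two innermost sites."""
    if trap.is_open or trap.vicinal is None:
        return None
    vic = (trap.vicinal.start, trap.vicinal.strand)
    for inner in (trap.innermost_cw, trap.innermost_ccw):
        if inner is not None and (inner.start, inner.strand) == vic:
            return "I"
    return "II"


def build_fork_trap(
    genome_id: str,
    sites: list[TerSite],
    oriC: int,
    L: int,
    vicinal: Optional[TerSite] = None,
    convention: PolarityConvention = DEFAULT_CONVENTION,
) -> ForkTrap:
    """Assemble the full trap from an accepted site list.

    Sites failing core verification (pseudo-Ter) are listed in the report
    but excluded from the innermost/width/type computation.
    """
    functional = [s for s in sites if s.core_ok]
    cw, ccw = innermost_blocking_sites(functional, oriC, L, convention)
    width = mid = None
    if cw is not None and ccw is not None:
        arc_start, width = _terminus_arc(
            cw.lock_coordinate(L), ccw.lock_coordinate(L), oriC, L
        )
        mid = (arc_start - 1 + width // 2) % L + 1
    trap = ForkTrap(
        genome_id=genome_id,
        oriC=oriC,
        L=L,
        sites=sites,
        innermost_cw=cw,
        innermost_ccw=ccw,
        width=width,
        trap_type=None,
        vicinal=vicinal,
        midpoint=mid,
        blocked={s.start: convention.blocked_direction(s) for s in sites},
    )
    trap.trap_type = classify_trap_type(trap)
    return trap


def sites_to_gff3(
    sites: list[TerSite],
    L: int,
    convention: PolarityConvention = DEFAULT_CONVENTION,
) -> str:
    """GFF3 of Ter sites with a blocked_direction attribute."""
    lines = ["##gff-version 3"]
    for s in sites:
        end = (s.start + TER_LENGTH - 2) % L + 1
        attrs = (
            f"ID={s.label or 'Ter_' + str(s.start)};identity={s.identity_pct};"
            f"core_ok={str(s.core_ok).lower()};"
            f"blocked_direction={convention.blocked_direction(s)}"
        )
        if end >= s.start:
            lines.append(
                f"{s.genome_id}\ttertrap\tter_site\t{s.start}\t{end}\t"
                f"{s.identity_pct}\t{s.strand}\t.\t{attrs}"
            )
        else:  # wraps the origin: split
            lines.append(
                f"{s.genome_id}\ttertrap\tter_site\t{s.start}\t{L}\t"
                f"{s.identity_pct}\t{s.strand}\t.\t{attrs}"
            )
            lines.append(
                f"{s.genome_id}\ttertrap\tter_site\t1\t{end}\t"
                f"{s.identity_pct}\t{s.strand}\t.\t{attrs}"
            )
    return "\n".join(lines) + "\n"
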