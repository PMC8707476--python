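"""End-to-end fork-trap characterisation of one circular genome.

Wires the stages together: vicinal-Ter extraction from the tus 5'UTR ->
genome-wide Ter scan -> polarity assignment and trap classification ->
GC-skew terminus estimate -> dif location -> distance summary.  Any stage
that yields no result degrades the report to "partial" with a logged
warning instead of aborting, so a genome without a recognisable trap still
produces its site table and skew estimates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .genome import CircularGenome, GenomeFeature, circular_distance
from .motif import (
    MotifError,
    TerSequence,
    TerSite,
    extract_vicinal_ter,
    load_dif_consensus,
    load_reference,
    scan_genome_for_ter,
)
from .skew import (
    TerActivity,
    cumulative_skew,
    expected_termination_position,
    gc_skew_profile,
    locate_dif,
    skew_extrema,
)
from .trap import DEFAULT_CONVENTION, ForkTrap, PolarityConvention, build_fork_trap

logger = logging.getLogger("tertrap")


@dataclass
class TrapReport:
    """Machine-readable summary of one characterisation run.

    ``status`` is "complete" when every stage produced a result, "partial"
    otherwise; ``warnings`` lists what was skipped and why.  All positions
    are 1-based; distances in the summary are kb at 1-decimal precision.
    """

    genome_id: str
    L: int
    oriC: Optional[int] = None
    vicinal: Optional[TerSite] = None
    sites: list[TerSite] = field(default_factory=list)
    trap: Optional[ForkTrap] = None
    terminus_estimate: Optional[int] = None
    origin_estimate: Optional[int] = None
    skew_window: Optional[int] = None
    dif_position: Optional[int] = None
    expected_termination: Optional[int] = None
    warnings: list[str] = field(default_factory=list)

    @property
    def status(self) -> str:
        return "partial" if self.warnings else "complete"

    def landmarks(self) -> dict[str, int]:
        marks: dict[str, int] = {}
        if self.trap is not None and self.trap.midpoint is not None:
            marks["trap_midpoint"] = self.trap.midpoint
        if self.terminus_estimate is not None:
            marks["terminus_estimate"] = self.terminus_estimate
        if self.dif_position is not None:
            marks["dif"] = self.dif_position
        if self.expected_termination is not None:
            marks["expected_termination"] = self.expected_termination
        return marks

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
                "sequence": s.bases,
            }

        return {
            "genome": self.genome_id,
            "length": self.L,
            "oriC": self.oriC,
            "status": self.status,
            "warnings": list(self.warnings),
            "vicinal": site_d(self.vicinal),
            "sites": [site_d(s) for s in self.sites],
            "trap": self.trap.to_dict() if self.trap else None,
            "origin_estimate": self.origin_estimate,
            "terminus_estimate": self.terminus_estimate,
            "skew_window": self.skew_window,
            "dif": self.dif_position,
            "expected_termination": self.expected_termination,
            "distance_summary_kb": distance_summary(self),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_text(self) -> str:
        d = self.to_dict()
        lines = [
            f"Fork trap characterisation: {self.genome_id} ({self.L} bp)",
            f"status: {d['status']}",
        ]
        for w in self.warnings:
            lines.append(f"warning: {w}")
        if self.vicinal:
            lines.append(
                f"vicinal Ter at {self.vicinal.start} ({self.vicinal.strand}), "
                f"identity {self.vicinal.identity_pct}%"
            )
        lines.append(f"accepted Ter sites: {len(self.sites)}")
        for s in self.sites:
            lines.append(
                f"  {s.label or '.':<10} start {s.start:>9}  {s.strand}  "
                f"identity {s.identity_pct}%  core_ok {s.core_ok}"
            )
        if self.trap and not self.trap.is_open:
            t = d["trap"]
            lines.append(
                f"trap: type {t['trap_type']}, width {t['width_kb']} kb, "
                f"midpoint {t['midpoint']}"
            )
        if self.terminus_estimate is not None:
            lines.append(
                f"cumulative GC-skew terminus estimate: {self.terminus_estimate} "
                f"(origin {self.origin_estimate}, window {self.skew_window})"
            )
        if self.dif_position is not None:
            lines.append(f"dif: {self.dif_position}")
        if self.expected_termination is not None:
            lines.append(f"activity-weighted expected termination: {self.expected_termination}")
        for pair, dist in d["distance_summary_kb"].items():
            lines.append(f"distance {pair}: {dist} kb")
        return "\n".join(lines) + "\n"


def distance_summary(report: TrapReport) -> dict[str, float]:
    """Pairwise circular distances (kb, 1 decimal) among report landmarks."""
    marks = report.landmarks()
    names = sorted(marks)
    out: dict[str, float] = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            d = circular_distance(marks[a], marks[b], report.L)
            out[f"{a}--{b}"] = round(d / 1000.0, 1)
    return out


def run_characterisation(
    genome: CircularGenome,
    tus: Optional[GenomeFeature] = None,
    oriC: Optional[int] = None,
    reference: Optional[TerSequence] = None,
    min_identity: float = 70.0,
    require_core: bool = True,
    skew_window: int = 5000,
    cumulative_window: int = 1000,
    dif_motif: Optional[str] = None,
    dif_max_mismatch: int = 3,
    activities: Optional[Sequence[TerActivity]] = None,
    convention: PolarityConvention = DEFAULT_CONVENTION,
) -> TrapReport:
    """Characterise the replication fork trap of one circular genome.

    Mirrors the streamlined workflow used for Enterobacterales genomes:
    the Ter vicinal to tus seeds the genome-wide scan, accepted sites are
    oriented into CW/CCW-blocking clusters, the innermost pair defines the
    trap width and type, and the cumulative GC-skew provides an independent
    terminus estimate.  Fails soft: missing stages produce warnings and a
    partial report.
    """
    if reference is None:
        reference = load_reference("TerB")
    report = TrapReport(genome_id=genome.id, L=genome.length, oriC=oriC)

    query = reference
    if tus is not None:
        try:
            report.vicinal = extract_vicinal_ter(genome, tus, reference, min_identity)
            query = TerSequence(report.vicinal.bases, "vicinal")
            logger.info(
                "vicinal Ter at %d (%s), identity %d%%",
                report.vicinal.start, report.vicinal.strand,
                report.vicinal.identity_pct,
            )
        except MotifError as e:
            report.warnings.append(str(e))
            logger.warning("vicinal stage: %s", e)
    else:
        report.warnings.append("no tus locus supplied; scanned with the reference Ter")

    sites = scan_genome_for_ter(genome, query, min_identity, require_core)
    # label sites in coordinate order; keep the vicinal label where it matches
    labelled = []
    for i, s in enumerate(sites):
        if report.vicinal is not None and (s.start, s.strand) == (
            report.vicinal.start, report.vicinal.strand,
        ):
            labelled.append(s.relabelled("vicinal"))
            report.vicinal = labelled[-1]
        else:
            labelled.append(s.relabelled(f"Ter{i + 1}"))
    report.sites = labelled
    logger.info("scan: %d accepted sites (min identity %s%%)", len(labelled), min_identity)
    if not labelled:
        report.warnings.append("no qualifying Ter sites found")

    if oriC is not None and labelled:
        vic = report.vicinal if report.vicinal in labelled else None
        report.trap = build_fork_trap(
            genome.id, labelled, oriC, genome.length, vicinal=vic, convention=convention
        )
        if report.trap.is_open:
            report.warnings.append(
                "open trap: a replichore has no blocking Ter site"
            )
        elif vic is None:
            report.warnings.append("no vicinal site: trap left unclassified")
    elif oriC is None:
        report.warnings.append("no oriC supplied; trap geometry skipped")

    profile = gc_skew_profile(genome, cumulative_window)
    cumulative_skew(profile)
    ori_est, term_est = skew_extrema(profile)
    if term_est is None:
        report.warnings.append("flat cumulative GC-skew; terminus estimate undefined")
    report.origin_estimate, report.terminus_estimate = ori_est, term_est
    report.skew_window = cumulative_window

    if dif_motif is None:
        dif_motif = load_dif_consensus()
    hit = locate_dif(genome, dif_motif, dif_max_mismatch)
    if hit is None:
        report.warnings.append(
            f"no dif match within {dif_max_mismatch} mismatches"
        )
    else:
        report.dif_position = hit.position
        if hit.ambiguous:
            report.warnings.append(f"dif match ambiguous: ties at {hit.ties}")

    if activities:
        report.expected_termination = expected_termination_position(
            list(activities), genome.length
        )
    return report
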