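"""ChIP coverage quantitation over Ter sites and qPCR enrichment arithmetic.

Coverage side: per-base read-depth tracks are averaged over the 23 bp of
each Ter site; relative enrichment and locus copy number are simple depth
ratios against a reference site or chromosomal baseline.

qPCR side: standard-curve slope gives the amplification efficiency
Eamp = 10^(-1/slope); input Ct values are corrected for the input dilution
(cCt = Ct_input - log_Eamp(dilution)); the immunoprecipitation efficiency
of a specific target relative to a non-specific control region is
Eamp^(cCt_in,sp - Ct_out,sp) / Eamp^(cCt_in,ns - Ct_out,ns).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .motif import TER_LENGTH, TerSite


class QuantError(ValueError):
    """Raised for invalid coverage or qPCR inputs."""


@dataclass
class CoverageTrack:
    """Per-base read depth over a circular genome (length L array, >= 0)."""

    genome_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 1 or self.depth.size == 0:
            raise QuantError("depth must be a non-empty 1-D array")
        if np.any(self.depth < 0):
            raise QuantError("depth values must be non-negative")

    @property
    def L(self) -> int:
        return self.depth.size

    def mean_range(self, start: int, end: int) -> float:
        """Mean depth over a 1-based inclusive range; start > end wraps."""
        L = self.L
        if not (1 <= start <= L and 1 <= end <= L):
            raise QuantError(f"range {start}..{end} outside 1..{L}")
        if start <= end:
            return float(self.depth[start - 1 : end].mean())
        return float(
            np.concatenate([self.depth[start - 1 :], self.depth[:end]]).mean()
        )


def read_depth_track(path: str | Path, genome_id: str = "", L: Optional[int] = None) -> CoverageTrack:
    """Read a per-base depth track from two-column TSV or bedGraph.

    TSV: 1-based ``position<TAB>depth`` rows (any order, missing = 0 when
    ``L`` is given).  bedGraph: ``chrom start end value`` with 0-based
    half-open intervals expanded to per-base depth.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", engine="python")
    if df.shape[1] >= 4:  # bedGraph
        chrom = str(df.iloc[0, 0])
        size = L or int(df.iloc[:, 2].max())
        depth = np.zeros(size)
        for _, row in df.iterrows():
            depth[int(row.iloc[1]) : int(row.iloc[2])] = float(row.iloc[3])
        return CoverageTrack(genome_id or chrom, depth)
    if df.shape[1] != 2:
        raise QuantError(f"{path}: expected 2 (TSV) or 4 (bedGraph) columns")
    pos = df.iloc[:, 0].astype(int).to_numpy()
    val = df.iloc[:, 1].astype(float).to_numpy()
    size = L or int(pos.max())
    depth = np.zeros(size)
    depth[pos - 1] = val
    return CoverageTrack(genome_id or "genome", depth)


def write_depth_tsv(track: CoverageTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, d in enumerate(track.depth, start=1):
            fh.write(f"{i}\t{d:g}\n")


def mean_site_coverage(track: CoverageTrack, site: TerSite) -> float:
    """Arithmetic mean of the 23 per-base depths spanning the site (wraps)."""
    L = track.L
    start = (site.start - 1) % L + 1
    end = (site.start + TER_LENGTH - 2) % L + 1
    return track.mean_range(start, end)


def relative_enrichment(site_mean: float, reference_mean: float) -> float:
    """Site coverage as a percentage of the reference-site coverage."""
    if reference_mean <= 0:
        raise QuantError("reference mean coverage must be positive")
    return 100.0 * site_mean / reference_mean


def locus_copy_number(
    track: CoverageTrack,
    locus: tuple[int, int],
    baseline: Optional[tuple[int, int]] = None,
) -> float:
    """Mean depth over a locus divided by the baseline mean depth.

    ``baseline=None`` uses the global chromosomal mean.  Used e.g. to
    estimate a plasmid copy number per chromosome from input-DNA coverage
    at a plasmid-borne locus.
    """
    locus_mean = track.mean_range(*locus)
    if baseline is None:
        base_mean = float(track.depth.mean())
    else:
        base_mean = track.mean_range(*baseline)
    if base_mean <= 0:
        raise QuantError("baseline mean depth must be positive")
    return locus_mean / base_mean


def amplification_efficiency(slope: float) -> float:
    """Eamp = 10^(-1/slope) from a standard-curve slope (cycles/log10).

    A perfectly doubling reaction has slope -1/log10(2) ~ -3.3219 and
    Eamp = 2.
    """
    if slope >= 0:
        raise QuantError("standard-curve slope must be negative")
    return 10.0 ** (-1.0 / slope)


def corrected_input_ct(ct_input: float, eamp: float, dilution_factor: float) -> float:
    """cCt = Ct_input - log_Eamp(dilution factor).

    Corrects the input-channel Ct for the dilution applied to the input
    sample before qPCR, in units of amplification cycles.
    """
    if eamp <= 1:
        raise QuantError("amplification efficiency must exceed 1")
    if dilution_factor < 1:
        raise QuantError("dilution factor must be >= 1")
    return ct_input - math.log(dilution_factor) / math.log(eamp)


def ip_efficiency(
    sp: tuple[float, float], ns: tuple[float, float], eamp: float
) -> float:
    """IP efficiency of a specific target relative to a non-specific region.

    ``sp`` and ``ns`` are (corrected input Ct, output Ct) pairs; the result
    is Eamp^(cCt_in - Ct_out) for the specific target divided by the same
    quantity for the non-specific control.
    """
    if eamp <= 1:
        raise QuantError("amplification efficiency must exceed 1")
    return eamp ** ((sp[0] - sp[1]) - (ns[0] - ns[1]))


@dataclass
class QPCRTarget:
    """Replicate-averaged Ct data for one amplicon."""

    name: str
    ct_input: float
    ct_output: float
    slope: float
    dilution: float
    sd_input: float = 0.0
    sd_output: float = 0.0

    @property
    def eamp(self) -> float:
        return amplification_efficiency(self.slope)

    @property
    def cct_input(self) -> float:
        return corrected_input_ct(self.ct_input, self.eamp, self.dilution)


@dataclass
class QPCRPanel:
    """A set of qPCR targets sharing an experiment (input/output channels)."""

    targets: dict[str, QPCRTarget] = field(default_factory=dict)

    def ip_efficiencies(self, nonspecific: str) -> dict[str, float]:
        """IP efficiency of every target relative to the named control."""
        if nonspecific not in self.targets:
            raise QuantError(f"no target {nonspecific!r} in panel")
        ns = self.targets[nonspecific]
        out = {}
        for name, t in self.targets.items():
            out[name] = ip_efficiency(
                (t.cct_input, t.ct_output), (ns.cct_input, ns.ct_output), t.eamp
            )
        return out

    def report(self, nonspecific: str) -> pd.DataFrame:
        eff = self.ip_efficiencies(nonspecific)
        rows = []
        for name, t in self.targets.items():
            rows.append(
                {
                    "target": name,
                    "Eamp": round(t.eamp, 4),
                    "Ct_input": round(t.ct_input, 3),
                    "sd_input": round(t.sd_input, 3),
                    "cCt_input": round(t.cct_input, 3),
                    "Ct_output": round(t.ct_output, 3),
                    "sd_output": round(t.sd_output, 3),
                    "ip_efficiency": round(eff[name], 4),
                }
            )
        return pd.DataFrame(rows)


def read_qpcr_csv(path: str | Path) -> QPCRPanel:
    """Load a qPCR Ct table.

    Columns: ``target, channel, Ct, slope, dilution`` with channel in
    {input, output}.  Replicate rows (same target/channel) are averaged;
    their standard deviation is propagated to the report.
    """
    df = pd.read_csv(path)
    required = {"target", "channel", "Ct", "slope", "dilution"}
    missing = required - set(df.columns)
    if missing:
        raise QuantError(f"{path}: missing columns {sorted(missing)}")
    panel = QPCRPanel()
    for name, grp in df.groupby("target", sort=False):
        inp = grp[grp.channel == "input"]
        out = grp[grp.channel == "output"]
        if inp.empty or out.empty:
            raise QuantError(f"target {name!r}: need both input and output rows")
        panel.targets[str(name)] = QPCRTarget(
            name=str(name),
            ct_input=float(inp.Ct.mean()),
            ct_output=float(out.Ct.mean()),
            slope=float(grp.slope.iloc[0]),
            dilution=float(grp.dilution.iloc[0]),
            sd_input=float(inp.Ct.std(ddof=1)) if len(inp) > 1 else 0.0,
            sd_output=float(out.Ct.std(ddof=1)) if len(out) > 1 else 0.0,
        )
    return panel


def site_coverage_report(
    track: CoverageTrack,
    sites: Sequence[TerSite],
    reference_label: Optional[str] = None,
) -> pd.DataFrame:
    """Per-site mean coverage and enrichment relative to a reference site.

    ``reference_label`` names the site whose coverage defines 100%
    (defaults to the highest-coverage site).
    """
    means = {s.label or f"site@{s.start}": mean_site_coverage(track, s) for s in sites}
    if not means:
        raise QuantError("no sites supplied")
    if reference_label is None:
        reference_label = max(means, key=means.get)
    if reference_label not in means:
        raise QuantError(f"no site labelled {reference_label!r}")
    ref = means[reference_label]
    rows = [
        {
            "site": label,
            "mean_coverage": round(m, 2),
            "relative_enrichment_pct": round(relative_enrichment(m, ref), 1),
        }
        for label, m in means.items()
    ]
    return pd.DataFrame(rows)
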