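"""Seeded generators for genomes, coverage tracks, qPCR panels, growth curves.

Every generator emits its ground truth alongside the data (a TruthTable),
so each analysis stage can be validated end to end without external
downloads.  All randomness flows through a single integer seed; re-running
with the same seed reproduces the output byte for byte.

The replichore genome generator emulates the compositional structure of a
real circular chromosome: G is enriched over C on the leading strand, so
bases are drawn with P(G) = 0.25 + delta, P(C) = 0.25 - delta on the arc
running clockwise from oriC to the terminus and with the bias reversed on
the other arc.  Planted elements (a tus start codon with its vicinal Ter
in the 5'UTR, further Ter sites of chosen identity/orientation, a dif
site) are written over the background at known coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .chip import CoverageTrack
from .genome import CircularGenome, reverse_complement
from .growth import GrowthCurve
from .motif import (
    CORE_END,
    CORE_START,
    LOCK_POS,
    NONCORE_INDICES,
    TER_LENGTH,
    TerSequence,
    TerSite,
)

BASES = "ACGT"


class SimulationError(ValueError):
    """Raised for inconsistent generator specifications."""


@dataclass(frozen=True)
class PlantedTer:
    """Specification of one Ter site to plant: where, which way, how diverged."""

    position: int          # forward 1-based start of the 23-bp window
    strand: str            # displayed strand of the motif
    identity: float = 100  # percent identity to the reference
    core_intact: bool = True
    label: str = ""


@dataclass
class GenomeSpec:
    """Parameters of a synthetic replichore genome.

    ``skew_delta`` is the per-base G/C bias (0 <= delta < 0.25);
    ``vicinal_offset`` is the gap in bases between the vicinal Ter and the
    tus start codon (11 by default, matching the E. coli TerB placement).
    """

    L: int
    oriC: int
    terminus: int
    skew_delta: float = 0.04
    tus: Optional[tuple[int, str]] = None  # (start-codon position, strand)
    vicinal_offset: int = 11
    ter_sites: Sequence[PlantedTer] = ()
    dif: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.skew_delta < 0.25:
            raise SimulationError("skew_delta must be in [0, 0.25)")
        for p in (self.oriC, self.terminus):
            if not 1 <= p <= self.L:
                raise SimulationError("oriC/terminus outside genome")


@dataclass
class TruthTable:
    """Ground truth emitted with every generated dataset."""

    L: int = 0
    oriC: Optional[int] = None
    terminus: Optional[int] = None
    tus: Optional[tuple[int, str]] = None
    vicinal: Optional[TerSite] = None
    sites: list[TerSite] = field(default_factory=list)
    dif: Optional[int] = None
    expected_site_means: dict[str, float] = field(default_factory=dict)
    doubling_time: Optional[float] = None
    enrichments: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "L": self.L,
            "oriC": self.oriC,
            "terminus": self.terminus,
            "tus": list(self.tus) if self.tus else None,
            "dif": self.dif,
            "sites": [
                {
                    "label": s.label,
                    "start": s.start,
                    "strand": s.strand,
                    "identity_pct": s.identity_pct,
                    "core_ok": s.core_ok,
                    "sequence": s.bases,
                }
                for s in self.sites
            ],
            "expected_site_means": self.expected_site_means,
            "doubling_time": self.doubling_time,
            "enrichments": self.enrichments,
        }


def mutate_to_identity(
    reference: TerSequence,
    identity: float,
    core_intact: bool = True,
    seed: int = 0,
) -> str:
    """Reference 23-mer with exactly k positions mutated to hit an identity.

    ``identity`` must equal 100*(23-k)/23 for an integer k (within half a
    percent).  With ``core_intact`` the mutations avoid the lock base and
    the 12-bp core (10 eligible positions, so k <= 10); without it the
    mutations are placed inside the lock/core region first, guaranteeing
    the core-verification rule fails.
    """
    k = int(round(TER_LENGTH * (1.0 - identity / 100.0)))
    if abs(100.0 * (TER_LENGTH - k) / TER_LENGTH - identity) > 0.5:
        raise SimulationError(
            f"identity {identity}% is not 100*(23-k)/23 for any integer k"
        )
    rng = np.random.default_rng(seed)
    core_region = [LOCK_POS - 1] + list(range(CORE_START - 1, CORE_END))
    if core_intact:
        if k > len(NONCORE_INDICES):
            raise SimulationError(
                f"cannot place {k} mutations outside the lock/core "
                f"({len(NONCORE_INDICES)} positions available)"
            )
        if k == 0:
            return reference.bases
        positions = rng.choice(NONCORE_INDICES, size=k, replace=False)
    else:
        if k == 0:
            raise SimulationError("core_intact=False requires at least one mutation")
        n_core = min(k, len(core_region))
        positions = list(rng.choice(core_region, size=n_core, replace=False))
        if k > n_core:
            positions += list(
                rng.choice(NONCORE_INDICES, size=k - n_core, replace=False)
            )
        positions = np.asarray(positions)
    seq = list(reference.bases)
    for i in positions:
        alternatives = [b for b in BASES if b != seq[i]]
        seq[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(seq)


def make_replichore_genome(
    spec: GenomeSpec, reference: Optional[TerSequence] = None
) -> tuple[CircularGenome, TruthTable]:
    """Synthetic circular genome with strand-asymmetric G/C composition.

    Background bases are drawn independently with the G/C bias switching
    at oriC and at the terminus; requested elements are then written over
    the background.  Planted intervals must not overlap.  Deterministic
    under ``spec.seed``.
    """
    from .motif import load_reference

    if reference is None:
        reference = load_reference("TerB")
    L, rng = spec.L, np.random.default_rng(spec.seed)
    d = spec.skew_delta
    # clockwise replichore: arc oriC -> terminus in increasing coordinate
    arc_cw = (np.arange(L) - (spec.oriC - 1)) % L < (spec.terminus - spec.oriC) % L
    p_lead = np.array([0.25, 0.25 - d, 0.25 + d, 0.25])  # A, C, G, T
    p_lag = np.array([0.25, 0.25 + d, 0.25 - d, 0.25])
    draws = rng.random(L)
    cum_lead = np.cumsum(p_lead)
    cum_lag = np.cumsum(p_lag)
    idx = np.where(
        arc_cw,
        np.searchsorted(cum_lead, draws, side="right"),
        np.searchsorted(cum_lag, draws, side="right"),
    ).clip(0, 3)
    seq_arr = np.array(list(BASES))[idx]

    truth = TruthTable(L=L, oriC=spec.oriC, terminus=spec.terminus, dif=spec.dif)
    occupied: list[tuple[int, int, str]] = []

    def claim(start: int, length: int, name: str) -> None:
        cells = {(start - 1 + i) % L for i in range(length)}
        for s0, l0, n0 in occupied:
            other = {(s0 - 1 + i) % L for i in range(l0)}
            if cells & other:
                raise SimulationError(f"planted elements overlap: {name} vs {n0}")
        occupied.append((start, length, name))

    def write(start: int, motif: str) -> None:
        for i, b in enumerate(motif):
            seq_arr[(start - 1 + i) % L] = b

    if spec.tus is not None:
        tus_pos, tus_strand = spec.tus
        truth.tus = (tus_pos, tus_strand)
        # start-codon marker in gene orientation
        codon = "ATG" if tus_strand == "+" else reverse_complement("ATG")
        codon_start = tus_pos if tus_strand == "+" else tus_pos - 2
        claim(codon_start, 3, "tus start codon")
        write(codon_start, codon)
        # vicinal Ter: vicinal_offset bases 5' of the start codon
        gap = spec.vicinal_offset
        if tus_strand == "+":
            vic_start = (tus_pos - 1 - gap - TER_LENGTH) % L + 1
            vic_strand, vic_motif = "+", reference.bases
        else:
            vic_start = (tus_pos + gap) % L + 1
            vic_strand, vic_motif = "-", reverse_complement(reference.bases)
        claim(vic_start, TER_LENGTH, "vicinal Ter")
        write(vic_start, vic_motif)
        truth.vicinal = TerSite(
            genome_id="synthetic",
            start=vic_start,
            strand=vic_strand,
            bases=reference.bases,
            identity_frac=1.0,
            core_ok=True,
            label="vicinal",
        )
        truth.sites.append(truth.vicinal)

    for i, p in enumerate(spec.ter_sites):
        displayed = mutate_to_identity(
            reference, p.identity, p.core_intact, seed=spec.seed + 7919 * (i + 1)
        )
        motif = displayed if p.strand == "+" else reverse_complement(displayed)
        label = p.label or f"Ter{i + 1}"
        claim(p.position, TER_LENGTH, label)
        write(p.position, motif)
        truth.sites.append(
            TerSite(
                genome_id="synthetic",
                start=p.position,
                strand=p.strand,
                bases=displayed,
                identity_frac=round(p.identity / 100.0 * TER_LENGTH) / TER_LENGTH,
                core_ok=p.core_intact,
                label=label,
            )
        )

    if spec.dif is not None:
        from .motif import load_dif_consensus

        dif = load_dif_consensus()
        claim(spec.dif, len(dif), "dif")
        write(spec.dif, dif)

    genome = CircularGenome("synthetic", "".join(seq_arr))
    return genome, truth


def simulate_coverage(
    g: CircularGenome,
    oriC: int,
    terminus: int,
    ori_depth: float = 5.0,
    ter_depth: float = 1.0,
    bound_sites: Sequence[tuple[TerSite, float]] = (),
    mean_depth: Optional[float] = None,
    noise: str = "poisson",
    seed: int = 0,
) -> tuple[CoverageTrack, TruthTable]:
    """Coverage track with a fork-progression gradient plus Ter-site peaks.

    Expected depth falls linearly (in arc distance travelled from oriC
    along each replichore) from ``ori_depth`` at oriC to ``ter_depth`` at
    the terminus, emulating the replication gradient of an exponentially
    growing population; ``mean_depth`` optionally rescales the gradient to
    a target genome-wide mean.  Each bound site adds a 23-bp box peak of
    the stated height.  ``noise='poisson'`` draws per-base counts around
    the expectation; ``noise='none'`` returns the exact expectation.
    """
    if not ori_depth >= ter_depth > 0:
        raise SimulationError("need ori_depth >= ter_depth > 0")
    L = g.length
    pos = np.arange(L)
    d_cw_full = (terminus - oriC) % L or L
    d_ccw_full = (oriC - terminus) % L or L
    dist_cw = (pos - (oriC - 1)) % L
    on_cw = dist_cw < d_cw_full
    frac = np.where(on_cw, dist_cw / d_cw_full, ((oriC - 1) - pos) % L / d_ccw_full)
    frac = np.clip(frac, 0.0, 1.0)
    expect = ori_depth + (ter_depth - ori_depth) * frac
    if mean_depth is not None:
        expect *= mean_depth / expect.mean()
    truth = TruthTable(L=L, oriC=oriC, terminus=terminus)
    for site, height in bound_sites:
        sl = [(site.start - 1 + i) % L for i in range(TER_LENGTH)]
        base_mean = float(expect[sl].mean())
        expect[sl] += height
        truth.expected_site_means[site.label or f"site@{site.start}"] = (
            base_mean + height
        )
        truth.sites.append(site)
    if noise == "poisson":
        depth = np.random.default_rng(seed).poisson(expect).astype(float)
    elif noise == "none":
        depth = expect.copy()
    else:
        raise SimulationError(f"unknown noise model {noise!r}")
    return CoverageTrack(g.id, depth), truth


def simulate_growth(
    T_D: float = 25.0,
    lag: float = 40.0,
    plateau_od: float = 1.5,
    noise_sd: float = 0.02,
    cadence: float = 5.0,
    duration: float = 720.0,
    n_replicates: int = 3,
    od0: float = 0.05,
    seed: int = 0,
) -> list[GrowthCurve]:
    """Replicate OD600 trajectories: lag, exponential phase, hard plateau.

    During the exponential phase OD doubles every ``T_D`` minutes exactly,
    so a noiseless trajectory restricted to that phase recovers T_D to
    machine precision; the plateau truncates growth at ``plateau_od``.
    Noise is multiplicative log-normal with fractional SD ``noise_sd``,
    independent per replicate under the seed.
    """
    if T_D <= 0:
        raise SimulationError("doubling time must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + cadence / 2, cadence)
    grown = np.where(t <= lag, od0, od0 * 2.0 ** ((t - lag) / T_D))
    expect = np.minimum(grown, plateau_od)
    curves = []
    for r in range(n_replicates):
        if noise_sd > 0:
            od = expect * np.exp(rng.normal(0.0, noise_sd, size=t.size))
        else:
            od = expect.copy()
        curves.append(GrowthCurve(f"rep{r + 1}", t, od))
    return curves


def simulate_qpcr(
    true_enrichments: dict[str, float],
    eamp: float = 2.0,
    dilution: float = 10000.0,
    ct_noise_sd: float = 0.0,
    nonspecific: str = "ns",
    base_ct: float = 18.0,
    slope: Optional[float] = None,
    seed: int = 0,
):
    """qPCR panel whose Ct values encode the requested IP enrichments.

    Output Ct values are constructed so that the IP-efficiency formula
    recovers each target's enrichment relative to the non-specific control
    in expectation; Gaussian cycle noise with SD ``ct_noise_sd`` is added
    to every Ct.  Returns a QPCRPanel including the control target.
    """
    import math

    from .chip import QPCRPanel, QPCRTarget

    if eamp <= 1:
        raise SimulationError("amplification efficiency must exceed 1")
    if slope is None:
        slope = -1.0 / math.log10(eamp)
    rng = np.random.default_rng(seed)
    log_e = math.log(eamp)
    dil_cycles = math.log(dilution) / log_e
    panel = QPCRPanel()
    targets = dict(true_enrichments)
    targets.setdefault(nonspecific, 1.0)
    for name, enrich in targets.items():
        if enrich <= 0:
            raise SimulationError(f"enrichment for {name!r} must be positive")
        cct_in = base_ct  # corrected input Ct; same template amount everywhere
        ct_in = cct_in + dil_cycles
        # IP pulls down enrich-fold more of this target than the control:
        # output crosses threshold log_eamp(enrich) cycles earlier
        ct_out = cct_in - math.log(enrich) / log_e
        if ct_noise_sd > 0:
            ct_in += rng.normal(0.0, ct_noise_sd)
            ct_out += rng.normal(0.0, ct_noise_sd)
        panel.targets[name] = QPCRTarget(
            name=name, ct_input=ct_in, ct_output=ct_out,
            slope=slope, dilution=dilution,
        )
    return panel
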