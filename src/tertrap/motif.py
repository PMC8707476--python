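"""Ter motif extraction and genome-wide scanning.

A Ter site is a 23-bp Tus-binding sequence.  On the displayed strand the
bases are numbered 1-23, the helicase-triggered "lock" base G(6) sits at
position 6 (its complement C(6) docks into Tus), and a strictly conserved
12-bp core spans positions 8-19 (A(8)..A(19)).  Candidate sites are scored
by ungapped percent identity over the fixed 23-bp frame and verified by the
lock/core rule: position 6 must carry the lock base and positions 8-19 must
match the reference core exactly.

The scan is deterministic: every 23-bp window on both strands (with
circular wrap) is scored, which removes any aligner-parameter dependence
from the site inventory.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from typing import Optional

import numpy as np

from .genome import (
    CircularGenome,
    GenomeFeature,
    circular_subsequence,
    reverse_complement,
)

TER_LENGTH = 23
LOCK_POS = 6          # 1-based, G on the displayed strand
CORE_START, CORE_END = 8, 19  # 1-based inclusive, 12 bases

# indices (0-based) free to mutate without touching lock or core
NONCORE_INDICES = tuple(
    i for i in range(TER_LENGTH)
    if i != LOCK_POS - 1 and not (CORE_START - 1 <= i <= CORE_END - 1)
)

_BASE_CODE = {c: i for i, c in enumerate("ACGTN")}


class MotifError(ValueError):
    """Raised for malformed Ter sequences or failed vicinal-site searches."""


@dataclass(frozen=True)
class TerSequence:
    """A reference Ter 23-mer with its lock base and conserved core."""

    bases: str
    label: str = "TerB"

    def __post_init__(self) -> None:
        if len(self.bases) != TER_LENGTH:
            raise MotifError(
                f"Ter sequence must be {TER_LENGTH} bp, got {len(self.bases)}"
            )
        if set(self.bases) - set("ACGTN"):
            raise MotifError(f"non-DNA characters in Ter sequence {self.bases!r}")

    @property
    def lock_base(self) -> str:
        return self.bases[LOCK_POS - 1]

    @property
    def core(self) -> str:
        return self.bases[CORE_START - 1 : CORE_END]


@dataclass(frozen=True)
class TerSite:
    """A located Ter occurrence.

    ``start``/``end`` are the forward-strand (plus) 1-based inclusive
    bounds of the 23-bp window; ``strand`` says which strand displays the
    motif.  ``bases`` is the displayed-strand 23-mer.  ``identity_frac`` is
    the exact ungapped fraction of identical positions to the query;
    ``identity_pct`` rounds it to integer percent for reporting.
    ``half_life_s`` carries a literature Tus-Ter-lock dissociation
    half-life as annotation only — nothing in the package computes it.
    """

    genome_id: str
    start: int
    strand: str
    bases: str
    identity_frac: float
    core_ok: bool
    label: str = ""
    half_life_s: Optional[float] = None

    @property
    def end(self) -> int:
        return self.start + TER_LENGTH - 1  # caller wraps if needed

    @property
    def identity_pct(self) -> int:
        return int(round(self.identity_frac * 100))

    def pos1(self, L: int) -> int:
        """Forward coordinate of displayed-strand position 1."""
        if self.strand == "+":
            return (self.start - 1) % L + 1
        return (self.start + TER_LENGTH - 2) % L + 1

    def lock_coordinate(self, L: int) -> int:
        """Forward coordinate of the lock base G(6) / non-permissive face."""
        if self.strand == "+":
            off = LOCK_POS - 1
        else:
            off = TER_LENGTH - LOCK_POS
        return (self.start - 1 + off) % L + 1

    def midpoint(self, L: int) -> int:
        return (self.start - 1 + TER_LENGTH // 2) % L + 1

    def relabelled(self, label: str) -> "TerSite":
        return replace(self, label=label)


def load_reference(label: str = "TerB") -> TerSequence:
    """Load a shipped reference Ter sequence (TerB or TerC) by label."""
    text = resources.files("tertrap.data").joinpath("ter_reference.fasta").read_text()
    seqs: dict[str, str] = {}
    name = None
    for line in text.splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            seqs[name] = ""
        elif name:
            seqs[name] += line.strip()
    if label not in seqs:
        raise MotifError(f"no shipped reference {label!r} (have {sorted(seqs)})")
    return TerSequence(seqs[label], label)


def load_dif_consensus() -> str:
    """The 28-bp E. coli dif consensus shipped as replaceable data."""
    text = resources.files("tertrap.data").joinpath("dif_consensus.fasta").read_text()
    return "".join(l.strip() for l in text.splitlines() if not l.startswith(">"))


def percent_identity(a: str, b: str, *, rounded: bool = True) -> float:
    """Ungapped positionwise identity over the fixed 23-bp frame, percent.

    N never matches anything (including N).  ``rounded=False`` returns the
    exact percentage; by default the nearest-integer report value.
    """
    if len(a) != TER_LENGTH or len(b) != TER_LENGTH:
        raise MotifError("percent_identity is defined on 23-mers")
    frac = identity_fraction(a, b)
    pct = frac * 100.0
    return float(round(pct)) if rounded else pct


def identity_fraction(a: str, b: str) -> float:
    """Exact fraction of identical positions; N counts as mismatch."""
    matches = sum(
        1 for x, y in zip(a, b) if x == y and x != "N"
    )
    return matches / TER_LENGTH


def matches_core(candidate: str, reference: TerSequence) -> bool:
    """Core-verification rule for an accepted Ter site.

    True iff the candidate carries the reference lock base at position 6
    (the locking C(6) on the complementary strand) and matches the
    conserved 12-bp core at positions 8-19 exactly.
    """
    if len(candidate) != TER_LENGTH:
        raise MotifError("core check is defined on 23-mers")
    return (
        candidate[LOCK_POS - 1] == reference.lock_base
        and candidate[CORE_START - 1 : CORE_END] == reference.core
    )


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _match_counts(genome_codes: np.ndarray, query: str) -> np.ndarray:
    """Identity match counts for every forward 23-bp window (circular)."""
    L = genome_codes.size
    ext = np.concatenate([genome_codes, genome_codes[: TER_LENGTH - 1]])
    counts = np.zeros(L, dtype=np.int16)
    q = _encode(query)
    n_code = ord("N")
    for k in range(TER_LENGTH):
        if q[k] == n_code:
            continue  # N in the query matches nothing
        counts += (ext[k : k + L] == q[k]) & (ext[k : k + L] != n_code)
    return counts


def scan_genome_for_ter(
    g: CircularGenome,
    query: TerSequence,
    min_identity: float = 70.0,
    require_core: bool = True,
) -> list[TerSite]:
    """Score every 23-bp window on both strands against the query Ter.

    Windows with identity >= ``min_identity`` percent (exact fraction, not
    the rounded report value) and, if ``require_core``, an intact lock/core
    are returned sorted by forward start.  Overlapping hits on the same
    strand are merged keeping the higher-identity frame (leftmost on ties).
    """
    codes = _encode(g.sequence)
    L = g.length
    min_matches = min_identity / 100.0 * TER_LENGTH - 1e-9
    hits: list[TerSite] = []
    for strand, qseq in (("+", query.bases), ("-", reverse_complement(query.bases))):
        counts = _match_counts(codes, qseq)
        for i in np.nonzero(counts >= min_matches)[0]:
            start = int(i) + 1
            window = circular_subsequence(g, start, TER_LENGTH, "+")
            displayed = window if strand == "+" else reverse_complement(window)
            core_ok = matches_core(displayed, query)
            if require_core and not core_ok:
                continue
            hits.append(
                TerSite(
                    genome_id=g.id,
                    start=start,
                    strand=strand,
                    bases=displayed,
                    identity_frac=identity_fraction(displayed, query.bases),
                    core_ok=core_ok,
                )
            )
    return _merge_overlaps(sorted(hits, key=lambda s: (s.start, s.strand)), L)


def _merge_overlaps(hits: list[TerSite], L: int) -> list[TerSite]:
    """Collapse same-strand hits whose 23-bp windows overlap on the circle.

    Keeps the higher-identity frame; ties go to the smallest start.
    """
    out: list[TerSite] = []
    for strand in ("+", "-"):
        strand_hits = [h for h in hits if h.strand == strand]
        if not strand_hits:
            continue
        clusters: list[list[TerSite]] = [[strand_hits[0]]]
        for h in strand_hits[1:]:
            if h.start - clusters[-1][-1].start < TER_LENGTH:
                clusters[-1].append(h)
            else:
                clusters.append([h])
        # circular wrap: the last cluster may overlap the first one
        if len(clusters) > 1 and (clusters[0][0].start - clusters[-1][-1].start) % L < TER_LENGTH:
            clusters[0] = clusters.pop() + clusters[0]
        out.extend(_best(c) for c in clusters)
    return sorted(out, key=lambda s: s.start)


def _best(cluster: list[TerSite]) -> TerSite:
    best = cluster[0]
    for h in cluster[1:]:
        if h.identity_frac > best.identity_frac:
            best = h
    return best


def extract_vicinal_ter(
    g: CircularGenome,
    tus: GenomeFeature,
    reference: TerSequence,
    min_identity: float = 70.0,
) -> TerSite:
    """Find the Ter site in the 50-bp 5'UTR of the tus gene.

    A 23-bp frame slides over the 50 bp immediately upstream (in gene
    orientation) of the tus start codon; both orientations of the frame are
    scored against the reference.  The best window must reach
    ``min_identity`` percent and pass the lock/core check, otherwise no
    vicinal Ter exists and an error is raised.

    For a minus-strand tus the 5'UTR lies downstream in forward genome
    coordinates; ``tus.start``/``tus.end`` follow GFF convention
    (start <= end on the forward strand), so the start codon sits at
    ``tus.start`` for ``+`` genes and ``tus.end`` for ``-`` genes.
    """
    L = g.length
    utr_len = 50
    if tus.strand == "+":
        utr_start = (tus.start - 1 - utr_len) % L + 1
    else:
        utr_start = tus.end % L + 1
    region = circular_subsequence(g, utr_start, utr_len, "+")

    best: Optional[TerSite] = None
    for off in range(utr_len - TER_LENGTH + 1):
        window = region[off : off + TER_LENGTH]
        fwd_start = (utr_start - 1 + off) % L + 1
        for strand, displayed in (("+", window), ("-", reverse_complement(window))):
            frac = identity_fraction(displayed, reference.bases)
            if frac * 100.0 + 1e-9 < min_identity:
                continue
            if not matches_core(displayed, reference):
                continue
            cand = TerSite(
                genome_id=g.id,
                start=fwd_start,
                strand=strand,
                bases=displayed,
                identity_frac=frac,
                core_ok=True,
                label="vicinal",
            )
            if best is None or frac > best.identity_frac:
                best = cand
    if best is None:
        raise MotifError(
            f"no vicinal Ter found in the 50 bp 5'UTR of {tus.id!r} "
            f"(min identity {min_identity}%, core required)"
        )
    return best


def sites_to_tsv(sites: list[TerSite], L: int) -> str:
    """TSV site report (1-based inclusive coordinates)."""
    lines = ["genome_id\tlabel\tstart\tend\tstrand\tidentity_pct\tcore_ok\tsequence"]
    for s in sites:
        end = (s.start + TER_LENGTH - 2) % L + 1
        lines.append(
            f"{s.genome_id}\t{s.label or '.'}\t{s.start}\t{end}\t{s.strand}"
            f"\t{s.identity_pct}\t{str(s.core_ok).lower()}\t{s.bases}"
        )
    return "\n".join(lines) + "\n"
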