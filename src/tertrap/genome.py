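"""Circular-genome representation, coordinate arithmetic and standard-format I/O.

Bacterial chromosomes are circular, so every coordinate operation in this
package wraps modulo the genome length.  Coordinates are 1-based inclusive
internally and in TSV/JSON reports (GenBank/GFF convention); BED output
converts to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FEATURE_KINDS = ("tus", "oriC", "dif", "ter", "gene", "other")


class GenomeError(ValueError):
    """Raised for malformed genomes, features or coordinates."""


@dataclass(frozen=True)
class CircularGenome:
    """A circular DNA sequence over {A,C,G,T,N}, uppercase.

    Position arithmetic is modulo the length ``L``; position 1 is the first
    base of the record as deposited.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise GenomeError(f"genome {self.id!r} has an empty sequence")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise GenomeError(
                f"genome {self.id!r} contains non-DNA characters: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)

    def wrap(self, pos: int) -> int:
        """Map any integer onto the 1..L coordinate circle."""
        return (pos - 1) % self.length + 1

    def subsequence(self, start: int, length: int, strand: str = "+") -> str:
        return circular_subsequence(self, start, length, strand)

    def rotated(self, k: int) -> "CircularGenome":
        """Genome with the coordinate origin moved k bases clockwise.

        The base formerly at position k+1 becomes position 1; all features
        shift by -k mod L.  Used by the rotation-invariance tests.
        """
        k %= self.length
        return CircularGenome(self.id, self.sequence[k:] + self.sequence[:k])


@dataclass(frozen=True)
class GenomeFeature:
    """A located landmark (tus, oriC, dif, ter, gene, ...).

    ``start``/``end`` are 1-based inclusive; ``start > end`` is allowed and
    means the feature wraps the coordinate origin.
    """

    id: str
    start: int
    end: int
    strand: str = "+"
    kind: str = "other"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GenomeError(f"feature {self.id!r}: strand must be + or -")
        if self.kind not in FEATURE_KINDS:
            raise GenomeError(f"feature {self.id!r}: unknown kind {self.kind!r}")
        if self.start < 1 or self.end < 1:
            raise GenomeError(f"feature {self.id!r}: positions are 1-based")


def load_genome(path: str | Path, record_id: Optional[str] = None) -> CircularGenome:
    """Read one record of a FASTA file as a circular genome.

    With more than one record and no ``record_id`` the choice is ambiguous
    and an error listing all record ids is raised.  The sequence is
    uppercased; N bases are preserved.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise GenomeError(f"{path}: no FASTA records found")
    if record_id is None:
        if len(records) > 1:
            ids = ", ".join(r.id for r in records)
            raise GenomeError(
                f"{path}: multiple records ({ids}); pass record_id to choose one"
            )
        rec = records[0]
    else:
        by_id = {r.id: r for r in records}
        if record_id not in by_id:
            ids = ", ".join(by_id)
            raise GenomeError(f"{path}: no record {record_id!r} (have: {ids})")
        rec = by_id[record_id]
    return CircularGenome(rec.id, str(rec.seq).upper())


def write_genome(g: CircularGenome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{g.id}\n")
        for i in range(0, g.length, width):
            fh.write(g.sequence[i : i + width] + "\n")


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N."""
    bad = set(seq) - ALPHABET
    if bad:
        raise GenomeError(f"cannot complement non-DNA characters: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def circular_subsequence(
    g: CircularGenome, start: int, length: int, strand: str = "+"
) -> str:
    """``length`` bases reading clockwise from ``start``, wrapping the origin.

    ``strand == '-'`` returns the reverse complement of the clockwise span.
    """
    L = g.length
    if not 1 <= start <= L:
        raise GenomeError(f"start {start} outside 1..{L}")
    if length <= 0 or length > L:
        raise GenomeError(f"length {length} outside 1..{L}")
    i = start - 1
    end = i + length
    if end <= L:
        s = g.sequence[i:end]
    else:
        s = g.sequence[i:] + g.sequence[: end - L]
    if strand == "-":
        return reverse_complement(s)
    if strand != "+":
        raise GenomeError(f"strand must be + or -, got {strand!r}")
    return s


def circular_distance(a: int, b: int, L: int) -> int:
    """Shortest arc between two positions on a circle of L bases.

    Symmetric; the result is in [0, L/2].
    """
    if not (1 <= a <= L and 1 <= b <= L):
        raise GenomeError(f"positions {a},{b} outside 1..{L}")
    d = abs(a - b)
    return min(d, L - d)


def directed_distance(origin: int, target: int, L: int, direction: str = "CW") -> int:
    """Arc length travelled from origin to target in a fixed rotational sense.

    ``CW`` is the direction of increasing coordinate (wrapping L -> 1),
    ``CCW`` the reverse.  Result is in [0, L).
    """
    if direction == "CW":
        return (target - origin) % L
    if direction == "CCW":
        return (origin - target) % L
    raise GenomeError(f"direction must be CW or CCW, got {direction!r}")


def circular_midpoint(a: int, b: int, L: int) -> int:
    """Midpoint of the *shorter* arc between a and b (1-based, wraps)."""
    d = (b - a) % L
    if d <= L - d:
        m = a + d // 2
    else:
        m = b + (L - d) // 2
    return (m - 1) % L + 1


def load_features_gff3(
    path: str | Path, kind_map: Optional[dict[str, str]] = None
) -> list[GenomeFeature]:
    """Read landmark features from a GFF3 file.

    The feature ``kind`` is inferred from the GFF type column and the
    Name/gene attributes (tus, oriC, dif, Ter* are recognised); ``kind_map``
    overrides the inference per feature id.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    kind_map = kind_map or {}
    feats: list[GenomeFeature] = []
    for f in db.all_features():
        name = f.attributes.get("Name", f.attributes.get("gene", [f.id]))[0]
        fid = f.id or name
        kind = kind_map.get(fid, _infer_kind(f.featuretype, name))
        strand = f.strand if f.strand in ("+", "-") else "+"
        feats.append(GenomeFeature(fid, f.start, f.end, strand, kind))
    return feats


def _infer_kind(featuretype: str, name: str) -> str:
    low = (name or "").lower()
    if low == "tus":
        return "tus"
    if low in ("oric", "ori"):
        return "oriC"
    if low == "dif":
        return "dif"
    if low.startswith("ter") or featuretype.lower() in ("ter_site", "ter"):
        return "ter"
    if featuretype.lower() in ("gene", "cds"):
        return "gene"
    return "other"


def write_bed(
    intervals: Iterable[tuple[str, int, int, str, float, str]],
    path: str | Path,
    L: Optional[int] = None,
) -> None:
    """Write (chrom, start1, end1, name, score, strand) rows as 6-column BED.

    Input coordinates are 1-based inclusive; BED is 0-based half-open.
    An interval with start > end wraps the coordinate origin and is split
    into two BED lines (requires ``L``).
    """
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in intervals:
            if start <= end:
                fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\t{score:g}\t{strand}\n")
            else:
                if L is None:
                    raise GenomeError(
                        f"wrapped interval {name!r} needs the genome length to split"
                    )
                fh.write(f"{chrom}\t{start - 1}\t{L}\t{name}\t{score:g}\t{strand}\n")
                fh.write(f"{chrom}\t0\t{end}\t{name}\t{score:g}\t{strand}\n")
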