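"""Ter identity scoring, lock/core verification, vicinal extraction, scanning."""

import hashlib
from importlib import resources

import pytest

from tertrap.genome import GenomeFeature, reverse_complement
from tertrap.motif import (
    CORE_END,
    CORE_START,
    LOCK_POS,
    TER_LENGTH,
    MotifError,
    extract_vicinal_ter,
    matches_core,
    percent_identity,
    scan_genome_for_ter,
)
from tertrap.simulate import (
    GenomeSpec,
    PlantedTer,
    make_replichore_genome,
    mutate_to_identity,
)

from .conftest import random_genome


def brute_force_scan(genome, query, min_identity, require_core):
    """Independent window enumerator: plain string comparison per frame."""
    L = genome.length
    doubled = genome.sequence + genome.sequence[: TER_LENGTH - 1]
    max_mm = TER_LENGTH - (min_identity / 100.0 * TER_LENGTH - 1e-9)
    hits = []
    queries = {"+": query.bases, "-": reverse_complement(query.bases)}
    for start in range(1, L + 1):
        window = doubled[start - 1 : start - 1 + TER_LENGTH]
        for strand, fwd_query in queries.items():
            mm = 0
            for a, b in zip(window, fwd_query):
                if a != b or a == "N":
                    mm += 1
                    if mm > max_mm:
                        break
            if mm > max_mm:
                continue
            displayed = window if strand == "+" else reverse_complement(window)
            if require_core and not (
                displayed[LOCK_POS - 1] == query.lock_base
                and displayed[CORE_START - 1 : CORE_END] == query.core
            ):
                continue
            hits.append((start, strand, TER_LENGTH - mm))
    return hits


def test_shipped_reference_is_pinned(terb, terc):
    data = resources.files("tertrap.data").joinpath("ter_reference.fasta").read_bytes()
    assert hashlib.md5(data).hexdigest() == "da4d0a5bb9bb8b179d78b58220caca7a"
    assert terb.lock_base == "G" and len(terb.bases) == TER_LENGTH
    # the conserved core runs from A(8) to A(19)
    assert terb.core == "ATGTTGTAACTA"
    assert terc.core == terb.core


class TestPercentIdentity:
    def test_self_identity(self, terb):
        assert percent_identity(terb.bases, terb.bases) == 100

    def test_terc_vs_terb_is_74(self, terb, terc):
        assert percent_identity(terc.bases, terb.bases) == 74

    def test_18_of_23_matches_reports_78(self, terb):
        # same identity fraction as the E. tarda vicinal Ter vs E. coli TerB
        diverged = mutate_to_identity(terb, 100 * 18 / 23, core_intact=True, seed=5)
        assert percent_identity(diverged, terb.bases) == 78

    @pytest.mark.parametrize("k", [0, 1, 4, 9, 23])
    def test_mutation_count_formula(self, terb, k):
        seq = list(terb.bases)
        for i in range(k):
            seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[i]]
        exact = percent_identity("".join(seq), terb.bases, rounded=False)
        assert exact == pytest.approx(100 * (23 - k) / 23)

    def test_symmetry(self, terb, terc):
        assert percent_identity(terb.bases, terc.bases) == percent_identity(
            terc.bases, terb.bases
        )

    def test_n_counts_as_mismatch(self, terb):
        seq = "N" + terb.bases[1:]
        assert percent_identity(seq, terb.bases, rounded=False) == pytest.approx(
            100 * 22 / 23
        )

    def test_length_enforced(self, terb):
        with pytest.raises(MotifError):
            percent_identity(terb.bases[:-1], terb.bases)


class TestMatchesCore:
    def test_reference_matches_itself(self, terb):
        assert matches_core(terb.bases, terb)

    def test_lock_base_mutation_fails(self, terb):
        seq = terb.bases[: LOCK_POS - 1] + "A" + terb.bases[LOCK_POS:]
        assert not matches_core(seq, terb)

    def test_every_single_core_mutation_fails(self, terb):
        for pos in range(CORE_START - 1, CORE_END):  # all 12 core positions
            for alt in "ACGT":
                if alt == terb.bases[pos]:
                    continue
                seq = terb.bases[:pos] + alt + terb.bases[pos + 1 :]
                assert not matches_core(seq, terb)

    def test_non_core_mutations_pass(self, terb):
        seq = "C" + terb.bases[1:]
        assert matches_core(seq, terb)


class TestExtractVicinal:
    def _genome_with_tus(self, strand, offset=11, seed=21):
        L = 100_000
        tus_pos = 50_000
        spec = GenomeSpec(
            L=L, oriC=1, terminus=L // 2 + 10_000, skew_delta=0.0,
            tus=(tus_pos, strand), vicinal_offset=offset, seed=seed,
        )
        genome, truth = make_replichore_genome(spec)
        if strand == "+":
            tus = GenomeFeature("tus", tus_pos, tus_pos + 2, "+", "tus")
        else:
            tus = GenomeFeature("tus", tus_pos - 2, tus_pos, "-", "tus")
        return genome, truth, tus

    def test_planted_11bp_upstream_recovered(self, terb):
        genome, truth, tus = self._genome_with_tus("+")
        site = extract_vicinal_ter(genome, tus, terb)
        assert site.start == truth.vicinal.start
        assert site.strand == "+"
        assert site.identity_pct == 100
        # 11 bases separate the Ter site from the start codon
        assert tus.start - (site.start + TER_LENGTH) == 11

    def test_minus_strand_tus_searches_downstream(self, terb):
        genome, truth, tus = self._genome_with_tus("-")
        site = extract_vicinal_ter(genome, tus, terb)
        assert site.start == truth.vicinal.start
        assert site.strand == "-"
        assert site.bases == terb.bases

    def test_no_planted_site_raises(self, terb):
        genome = random_genome(10_000, seed=33)
        tus = GenomeFeature("tus", 5_000, 5_002, "+", "tus")
        # brute-force confirm no qualifying frame exists in the 50 bp UTR
        utr = genome.sequence[5_000 - 51 : 5_000 - 1]
        ok = []
        for off in range(len(utr) - TER_LENGTH + 1):
            for cand in (utr[off : off + TER_LENGTH],
                         reverse_complement(utr[off : off + TER_LENGTH])):
                frac = sum(a == b for a, b in zip(cand, terb.bases)) / TER_LENGTH
                if frac >= 0.70 and matches_core(cand, terb):
                    ok.append(cand)
        assert not ok
        with pytest.raises(MotifError, match="no vicinal Ter"):
            extract_vicinal_ter(genome, tus, terb)


class TestScan:
    def test_planted_identity_spectrum_recovered(self, terb):
        L = 300_000
        identities = [100.0, 100 * 22 / 23, 100 * 20 / 23, 100 * 19 / 23,
                      100 * 18 / 23]
        strands = ["+", "-", "+", "-", "+"]
        planted = [
            PlantedTer(30_000 + 50_000 * i, strands[i], identities[i], True,
                       f"T{i}")
            for i in range(5)
        ]
        # decoy: ~65% identity with a degenerate core -> must be excluded
        planted.append(PlantedTer(295_000, "+", 100 * 15 / 23, False, "decoy"))
        spec = GenomeSpec(L=L, oriC=1, terminus=150_000, skew_delta=0.0,
                          ter_sites=planted, seed=77)
        genome, truth = make_replichore_genome(spec)
        sites = scan_genome_for_ter(genome, terb, min_identity=65.0,
                                    require_core=True)
        found = {(s.start, s.strand) for s in sites}
        expected = {(p.position, p.strand) for p in planted[:5]}
        assert found == expected
        by_pos = {s.start: s for s in sites}
        for p, ident in zip(planted[:5], identities):
            assert by_pos[p.position].identity_pct == round(ident)

    def test_matches_brute_force_on_seeded_megabase(self, terb):
        genome = random_genome(1_000_000, seed=55)
        fast = scan_genome_for_ter(genome, terb, min_identity=70.0,
                                   require_core=True)
        slow = brute_force_scan(genome, terb, 70.0, True)
        assert {(s.start, s.strand) for s in fast} == {(p, st) for p, st, _ in slow}
        # a random megabase is expected to contain no verified Ter
        assert len(fast) == 0

    def test_scan_rotation_invariance(self, terb):
        spec = GenomeSpec(L=50_000, oriC=1, terminus=25_000, skew_delta=0.0,
                          ter_sites=[PlantedTer(10_000, "+", 100.0, True, "a"),
                                     PlantedTer(40_000, "-", 100 * 20 / 23, True, "b")],
                          seed=3)
        genome, _ = make_replichore_genome(spec)
        base = scan_genome_for_ter(genome, terb, 70.0, True)
        k = 17_345
        rotated = genome.rotated(k)
        rot = scan_genome_for_ter(rotated, terb, 70.0, True)
        L = genome.length
        # rotated position r corresponds to original position r + k (mod L)
        shifted = sorted(((s.start - 1 + k) % L + 1, s.strand) for s in rot)
        assert shifted == sorted((s.start, s.strand) for s in base)

    def test_strand_mirror_under_reverse_complement(self, terb):
        spec = GenomeSpec(L=20_000, oriC=1, terminus=10_000, skew_delta=0.0,
                          ter_sites=[PlantedTer(5_000, "+", 100.0, True, "a")],
                          seed=4)
        genome, _ = make_replichore_genome(spec)
        from tertrap.genome import CircularGenome

        mirrored = CircularGenome(genome.id, reverse_complement(genome.sequence))
        fwd = scan_genome_for_ter(genome, terb, 70.0, True)
        rev = scan_genome_for_ter(mirrored, terb, 70.0, True)
        assert len(fwd) == len(rev) == 1
        L = genome.length
        assert rev[0].strand == "-"
        # window [p, p+22] maps to [L-p-21, L-p+1] on the mirrored genome
        assert rev[0].start == L - fwd[0].start - TER_LENGTH + 2

    def test_k12_stringency(self, terb, k12_like):
        """All ten primary Ter recovered; degenerate-core decoys rejected."""
        genome, truth, spec = k12_like
        sites = scan_genome_for_ter(genome, terb, min_identity=70.0,
                                    require_core=True)
        planted_primary = {
            (p.position, p.strand) for p in spec.ter_sites if p.core_intact
        }
        assert {(s.start, s.strand) for s in sites} == planted_primary
        assert len(sites) == 10
        # without the core rule the degenerate-core decoys reappear
        loose = scan_genome_for_ter(genome, terb, min_identity=70.0,
                                    require_core=False)
        loose_pos = {(s.start, s.strand) for s in loose}
        decoys = {(p.position, p.strand) for p in spec.ter_sites
                  if not p.core_intact}
        assert decoys <= loose_pos
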