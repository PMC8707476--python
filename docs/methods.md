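# Methods

## Scope and model

`tertrap` delineates Tus-dependent replication fork traps on circular
bacterial chromosomes from sequence and simple quantitative inputs.  The
underlying biology: two replication forks leave *oriC* in opposite
rotational senses and are confined to the terminus region by 23-bp Ter
sites bound by the Tus protein.  A Tus–Ter complex arrests only the fork
approaching its non-permissive face; arrest is committed when helicase-
driven strand separation frees the C(6) base, which docks into a
cytosine-specific pocket on Tus (the Tus–Ter "lock").  The package treats
five connected sub-problems: Ter motif discovery, trap architecture,
GC-skew terminus inference, ChIP/qPCR enrichment arithmetic, and
growth-curve kinetics.

## Ter motif model

A Ter site is modelled as a fixed 23-bp frame numbered 1–23 on the
displayed strand, with the lock base G(6) at position 6 and a strictly
conserved 12-bp core at positions 8–19 (A(8)…A(19); `ATGTTGTAACTA` for the
shipped *E. coli* TerB reference).  Candidate sites are scored by ungapped
positionwise percent identity over the full frame; N never matches.  A
candidate is *verified* when position 6 equals the reference lock base and
positions 8–19 equal the reference core exactly.  Sites failing
verification are reported but excluded from trap geometry (pseudo-Ter).

Design choice: identity is defined on the fixed 23-bp frame rather than a
local alignment.  A gapped aligner introduces parameter- and
version-dependent ambiguity for what is ultimately a fixed-length motif
comparison; the frame definition reproduces the published identity
percentages (TerC vs TerB 17/23 = 74%, a vicinal Ter at 18/23 = 78%) and
makes the genome-wide scan exactly enumerable, so it can be checked
against a brute-force window enumerator in the tests.

The scan scores every 23-bp window on both strands with circular wrap
(vectorised per-offset equality counts; ~2L windows).  Defaults:
`min_identity = 70%` — between the weakest accepted vicinal identity (74%)
and the rejected 65% pseudo-site — with the core check on.  Overlapping
same-strand hits merge to the higher-identity frame, leftmost on ties.

The vicinal Ter is searched in the 50 bp immediately 5′ of the *tus* start
codon (strand-aware; both frame orientations).  The fixed 50-bp window is
one reading of "within the 5′UTR"; it covers the canonical placement (site
end 11 bp upstream of the ATG) with room to spare.

## Fork trap geometry

Polarity: the mapping from displayed-strand orientation to blocked fork
direction is a convention constant that cannot be derived from the motif
alone.  It is fixed so that sites in the TerB/TerC/TerG genomic
orientation (motif displayed on the forward strand of a conventionally
oriented record) block the clockwise fork, and shipped as
`PolarityConvention(invert=...)` with a pinning test.  Mirroring a genome
flips strand and rotational sense together, so the same constant applies
to a reverse-complemented record.

The innermost site of a replichore is the first verified site whose
non-permissive face the fork meets, by directed arc distance from *oriC*.
The face coordinate is taken at the lock base G(6); any fixed end choice
moves distances by ≤ 23 bp, below the kb reporting resolution.  Trap width
is the arc between the two innermost sites along the arc *not* containing
*oriC*.  This definition covers both arrangements found in nature: the
non-overlapping dyad (each fork stops before the other's barrier) and the
overlapping type II arrangement, where each fork crosses the terminus and
the two stop points lie past each other.  Width is reported in integer kb;
exact base counts are kept in the JSON.  Type I: the tus-vicinal site is
one of the two innermost sites; type II otherwise; an "open" trap (a
replichore with no blocking site) is a reported outcome, not an error.

## GC-skew analysis

Windowed skew is (G−C)/(G+C) per window, 0 when a window has no G or C
(continuity convention).  "Cumulative skew" means non-overlapping windows
(1000 bp by default) summed from the record origin; 5000-bp windows are
the plotting default.  On a conventionally oriented record leading-strand
G excess makes the cumulative curve rise from origin to terminus, so
terminus = global maximum and origin = global minimum; the assignment is a
flag (`terminus_at_max`) pinned by the synthetic-recovery tests.
Resolution is one window; the synthetic-recovery criterion (≤ 2 kb error
at δ = 0.04, L = 2 Mb) holds in ≥ 19/20 seeds.

The expected termination position is the activity-weighted circular mean
of functional Ter positions (site midpoints; the ≤ 23 bp anchor ambiguity
is immaterial).  Sites must lie within one semicircle — otherwise the
circular mean is genuinely ambiguous and the operation refuses.

The *dif* locus is located by best mismatch-bounded match of a 28-bp
consensus on either strand.  The shipped consensus is the *E. coli* dif
sequence from the general literature (a replaceable data file flagged as
external knowledge); ties are returned and flagged rather than silently
broken.

## ChIP and qPCR quantitation

Site coverage is the arithmetic mean of the 23 per-base depths spanning a
site (wrapping).  Relative enrichment is a simple percentage of a
reference site's mean; locus copy number divides a locus mean by a
baseline mean, defaulting to the global chromosomal mean (a plasmid copy
number per chromosome and the ~5× *oriC* : ~1× terminus replication
gradient are both ratios of this kind; the global mean is the natural
baseline when no reference window is stated).

qPCR arithmetic: Eamp = 10^(−1/slope) from the standard-curve slope;
cCt_input = Ct_input − log_Eamp(dilution factor); IP efficiency =
Eamp^(cCt_in − Ct_out) for the specific target over the same quantity for
a non-specific control region.  Replicate Ct values are averaged before
the formulas and their SD propagated to the report (the combination rule
is not specified upstream; the mean is the conventional choice).
Threshold determination from raw fluorescence and read alignment are out
of scope: the module consumes Ct tables and per-base depth tracks
(two-column TSV or bedGraph).

## Growth kinetics

log2(OD600) vs time.  Each interior point receives the R² of the
least-squares line through the 11 points centered on it (five before,
five after); per-point R² values are averaged across replicates on a
shared time grid, and the longest contiguous run with mean R² ≥ 0.99 is
the linear range (ties → earliest run; determinism).  Per-replicate
slopes over the shared range give growth rates; T_D = 1/mean rate, with
the SE taken over per-replicate doubling times.  Replicates with
mismatched grids are rejected rather than interpolated.  A user-fixed
time window (e.g. 100–210 min) is supported alongside auto-detection.
`GrowthRateModel(curves).fit()` returns a `GrowthFit` results object with
`summary()`.

## Synthetic data

Generators are the test bed; each emits a truth table and is byte-
reproducible under its seed.

* **Genome**: i.i.d. bases with P(G) = 0.25 + δ, P(C) = 0.25 − δ on the
  clockwise *oriC*→terminus arc and the bias reversed on the other arc;
  A/T unbiased, isolating the GC-skew signal.  Default δ = 0.04 gives a
  clean but not caricatural skew at 2–4 Mb scales.  Planted elements
  (tus ATG marker, vicinal Ter 11 bp upstream, diverged Ter sites via
  `mutate_to_identity`, dif) overwrite the background; overlaps error.
  `mutate_to_identity` places exactly k mutations for identity
  100·(23−k)/23, outside the lock/core when the core must stay intact and
  inside it first when it must break.
* **Coverage**: expected depth interpolates linearly in arc distance from
  ~5× at *oriC* to ~1× at the terminus (the replication gradient of an
  exponentially growing population); bound sites add 23-bp box peaks;
  Poisson counts or exact expectation.
* **Growth**: lag → exact exponential (doubling every T_D) → hard plateau,
  with multiplicative log-normal noise.  The mid-phase is truly
  exponential rather than logistic so that the noiseless closed loop
  recovers T_D to machine precision; the smooth shoulder of a logistic
  curve is the main feature of real curves this omits, which the R²
  threshold would simply trim.
* **qPCR**: inverse of the IP-efficiency equations — output Ct values are
  placed log_Eamp(enrichment) cycles early relative to the corrected
  input Ct, plus Gaussian cycle noise.

What passing these tests shows: the analysis operations are correct on
data whose generating process matches their assumptions.  What it does
not show: robustness to real-data pathologies (repeats and mobile
elements producing spurious motif hits, coverage bias, non-stationary
skew from inversions or horizontal transfer, diauxic growth).  The
external-genome benchmarks exercise those only when run on downloaded
assemblies.

## Problem sizes and numerics

Test simulations use 0.2–4 Mb genomes, 20–50 seeds per recovery property,
100 qPCR draws — sizes chosen so the full suite runs in a few minutes
while keeping every recovery criterion at its stated tolerance.
Identity comparisons use exact fractions internally and round to integer
percent only in reports; widths round to integer kb in reports with exact
bases in JSON; landmark distances print at 0.1 kb.  Degenerate inputs are
explicit outcomes, not crashes: flat cumulative skew flags the estimate
undefined, an open trap reports as such, and a missing vicinal Ter
degrades the pipeline report to "partial" (CLI exit code 2).

## Known limitations

* The identity score is ungapped by construction; a Ter variant with an
  indel inside the frame would be missed (none are described in
  Enterobacterales).
* Each FASTA record is analysed separately; multi-replicon architectures
  are not combined.
* The polarity constant must be supplied (or inverted) for records
  deposited in the non-conventional orientation; the cumulative-skew
  orientation flag is the cross-check.
* Tus–Ter binding kinetics are carried as annotation only
  (`TerSite.half_life_s`); nothing is computed from them.
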