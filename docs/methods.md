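# Methods

## Scope and model

`dzmatrix` models the auxiliary-strand-regulated E6 DNAzyme circuit at
*domain resolution*: strands are ordered tuples of named sequence
domains, complexes are sets of strands held by declared Watson–Crick
stems, and dynamics are deterministic mass-action ODEs over a bounded
complex set. There is no thermodynamic folding model, no melting
temperatures and no fluorophore spectral physics; fluorescence is the
concentration of the cleaved fluorophore-bearing fragment (free or still
complexed — backbone scission is what separates it from the quencher),
with arbitrary-unit scaling absorbed by normalization.

### Strand architecture

All sequences are stored 5′→3′; a single lowercase `a` marks the
ribo-adenosine cleavage site of a substrate. The enzyme's catalytic core
is the single conserved 15-nt string `AGCGATCACCCATGT`; the variable
stem-loop of the enzyme is an opaque designed 12-nt hairpin domain. The
buffer area is a separate 2-nt `TA` domain on the substrate and is *not*
counted inside the stated stem lengths.

Stem roles by mode (lengths in bp are the defaults, all configurable
through `StemConfig`):

| mode | enzyme–substrate | aux–enzyme | aux–substrate |
|---|---|---|---|
| three-pronged | S1=7, S2=3 | S3=11 | S4=10 |
| four-pronged | S2=3, S4=3 | S1=11, S5=11 | S3=10, S6=10 |
| weighted | S2=3, S4=3 | S1=11, S5=11 | S3=14, S6=9 |

In matrix libraries the row-specific substrate arm is S3 (shared by all
M-auxiliaries of a row) and the X-side substrate arm S6 is one common
domain on every reporter, so each column element can reach each output
row; enzyme arms S1[j]/S5[j] are column-specific and the 3-bp junctions
are shared. This fixes which half of the row/column domain sharing is
common, a choice the architecture leaves open; it is recorded in the
design report. X-auxiliaries for different output columns k of the same
j are therefore sequence-identical; multi-column products are simulated
as K independent wells (one tube per output column), which is also how
the corresponding bench experiments are run.

### Sequence design

Stems are drawn uniformly at random (seeded `numpy` generator, so a
(constraints, seed) pair is byte-reproducible) and rejected unless they
satisfy: GC fraction in [0.3, 0.7] (for stems ≥ 3 nt), homopolymer runs
≤ 4, and no complementary *or* identical run longer than `crosstalk_k`
(default 5 nt) against any sequence already in the pool, including the
fixed catalytic core and the candidate's own reverse complement. The
retry budget is 1000 redraws per stem; exhausting it raises a design
failure naming the stem. The whole-library `crosstalk_screen` then
verifies the longest unintended complementary run over every ordered
pair of non-partner domain instances. These heuristics replace a
secondary-structure (NUPACK-style) check with a purely combinatorial
one; the conserved core's own 4-nt self-complementary stretch (`GATC`)
is below the default threshold.

One spec-level wrinkle: reverse complementation cannot be an involution
on rA-containing strings (rA→T, T→A), so the involution property holds —
and is tested — on the pure-DNA strands; substrates round-trip to their
deoxy form.

## Kinetic model

Stem dissociation follows `k_off(L) = k_on · exp(−dG_bp · L)` with the
off-rate strictly decreasing in the engaged base pairs L; association is
a single bimolecular rate `k_on`. Defaults: `k_on = 1e5 /M/s`,
`dG_bp = 1.5` per bp, `k_cat = 1e-3 /s`, `k_leak = 0`. No rate constants
are fitted to bench fluorescence (arbitrary units, no deposited numeric
data); the defaults are round-number values in the physically plausible
range, chosen once so that positive and negative wells at the working
concentration (0.3 µM) separate by far more than the readout threshold
within the standard sampling horizon.

The complex set is bounded as drawn in the mechanism: each enzyme arm
binds at most one auxiliary, each auxiliary at most one substrate; there
are no auxiliary·substrate binaries, and no enzyme·substrate binary in
four-pronged mode (two 3-bp junctions alone do not hold a complex). The
three-pronged enzyme·substrate binary *does* exist (S1+S2 = 10 bp) and
is the leak-competent complex of that mode. One-armed substrate
complexes (substrate held by one auxiliary arm plus its junction) exist
in both modes; they cleave only through the `k_leak` channel, so at the
default `k_leak = 0` a well missing any required auxiliary produces
*exactly* zero signal for all time — the clean-separation property the
double-auxiliary design is for. Because the X-side substrate arm is a
shared domain, any reporter row can park on an enzyme·X complex; these
cross-row one-armed complexes are included.

Cleavage is irreversible, at `k_cat · a(pH) · Π_junction (1 − e^{−dG_bp·L})`:
the junction-occupancy factor sends the rate to zero when a junction
stem has zero length (the cleavage site cannot engage the core) and is
≈ 0.98 at the 3-bp default. The pH activity `a(pH)` is 1.0 on the peak
window [8.0, 9.0] with linear falloff to 0 at pH 6.0 and 10.5 — the
simplest shape consistent with the observed activity optimum; it is a
replaceable callable. `mg_present = False` forces all cleavage rates to
zero (the enzyme is Mg²⁺-dependent), with a warning.

After cleavage the two fragments (5′ carries fluorophore and rA, 3′
carries the quencher) are released in one reaction at the off-rate of
the more stably held fragment (supports S3+S2 and S4+S6); fragments do
not rebind. With the default Boolean stoichiometry this makes each
complex effectively single-turnover, which is what makes the weighted
readout quantized: n assembled combinations cleave n substrate
equivalents. Leak cleavage from one-armed complexes collapses cleave and
release into a single reaction (signal-equivalent, keeps the state space
small).

Strand conservation is checked *structurally* at build time (the
multiset of strand atoms — counting a substrate as its two halves — is
identical on both sides of every reaction) and *numerically* along every
trajectory.

## Integration and readout

Networks are integrated with SciPy's LSODA at rtol 1e-8 / atol 1e-12 M
(networks are small; accuracy is cheap), sampled on the grids of the
corresponding bench runs: 4 min × 150 cycles (three-pronged), 4 min ×
300 (Boolean), 7 min × 200 (weighted). Sub-zero integrator noise is
clipped at 0.

Normalization divides every run of a collection by the per-channel
global maximum across the collection ("unified normalization"); the
denominator choice (global max rather than per-run max) is an
assumption, documented here, and an all-zero channel is left at zero.
The Boolean call is endpoint ≥ 0.5 × the positive-control endpoint
(midpoint convention for a by-eye "signal rose" criterion; the demo uses
a dedicated all-ones control well). The weighted call quantizes the
endpoint against a dedicated weight-1 single-combination calibration
well; calls off an integer multiple by more than 25% (fractional) are
flagged `indeterminate`, and endpoints at ≥ 95% of the substrate pool
are flagged `saturated`, meaning the level is a lower bound — a correct
level-2 call with 2× substrate sits exactly at that ceiling, so the flag
marks ceiling contact, not an error.

## Gel prediction

The lane predictor uses greedy maximal assembly at the same structural
abstraction: auxiliaries join enzymes when their enzyme-arm stem meets
`stability_min` (default 6 bp per contact), and the substrate joins only
a complex carrying the *full* auxiliary complement with every anchor
stem above threshold. A pure summed-stem-length criterion cannot
reproduce the observed lanes (it would glue the four-pronged enzyme and
substrate through their 6 summed junction bp, and hold the substrate on
one-armed complexes); requiring the full complement is the same rule
that governs cleavage competence in the kinetic model. Cleavage products
always run as separate bands — the nicked substrate halves dissociate on
the 2-h electrophoresis timescale even where the ODE model's off-rates
are slow. Migration is ordered by total nucleotide count only;
intensities and distances are out of scope. Nucleotide conservation per
lane is asserted on every prediction.

## Demos and problem sizes

The Boolean demo enumerates 4 M matrices × 4 X vectors = 16 independent
wells on the 4 min × 300 grid. The four M matrices are not prescribed
anywhere, so the default set — identity, all-ones, lower-triangular,
anti-diagonal — was chosen to cover all output patterns (both zero, both
one, each mixed case) and is overridable. The weighted demo runs, per
output row, two single-combination wells and the both-combinations well
with substrate at 2×, expecting levels (1, 1, 2).

The exhaustive oracle-equivalence check covers all 64 2×2 instances and
a seeded sample of twelve 3×3 instances; each simulation takes ~10 ms,
so the full acceptance recomputation runs in seconds. The stem-trend
check (S1/S5 from 11 down to 8 bp) compares endpoints at the full
horizon (non-increasing) and at the 60-min pre-saturation sample
(strictly decreasing): with an irreversible cleavage drain and no enzyme
inactivation in the model, *every* variant eventually saturates, so the
discriminating comparison must be made in the kinetic regime — the
standard initial-rate style of activity comparison.

## What the simulations do and do not show

Passing the oracle-equivalence suite shows that the *architecture* —
presence/absence encoding, AND-by-assembly, OR-by-shared-reporter,
weight-by-concentration — computes the intended arithmetic under
idealized mass-action kinetics with designed-in clean separation. It
does not validate real-world rate constants, enzyme turnover limits,
pipetting noise, spectral bleed-through between channels, or sequence
effects beyond exact-complementarity crosstalk; in particular the exact
zero of negative wells is a property of the zero-leak model, whereas
real systems show small nonzero leak (the `k_leak` channel exists to
explore that regime). The generated sequences satisfy the stated
constraints but are not the bench sequences, which are not reproduced
here.

## Known limitations

* Deterministic ODEs only; no stochastic simulation.
* No toehold-mediated strand displacement (deliberately outside the
  mechanism) and no polymeric/aggregated complexes.
* Non-integer weights are accepted by the types but only integer levels
  are calibrated by the quantized readout.
* The SBML export is an SBML-shaped JSON structure (listOfSpecies /
  listOfReactions with mass-action laws), not schema-validated XML.
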