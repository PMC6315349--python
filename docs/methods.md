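# Methods

## Energy model

All predictions derive from a single loop-decomposition nearest-neighbor
model over one to three strands.

**Stacks.** Helical dinucleotide steps carry (ΔH, ΔS) from three shipped,
versioned tables (`src/aptalogic/data/`): a Turner-style RNA/RNA set
(Watson–Crick values of the Xia measurements plus G·U wobble entries of
Mathews-style magnitude), a SantaLucia-unified-style DNA/DNA set, and a
Sugimoto-style RNA/DNA hybrid set.  The tables are labelled
`aptalogic-1.0`; they are the package's own parameterization in the style
of those literature sets, not bit-exact copies, and every hand-summed
expected value in the test suite is recomputed from these same files.

**Loops.** Hairpin, bulge and internal loops carry size-dependent
initiation penalties tabulated at 37 °C and extrapolated beyond the table
with the Jacobson–Stockmayer `1.75·R·T·ln(n/n_max)` term.  Loop penalties
are treated as purely entropic, i.e. scaled linearly in absolute
temperature: `ΔG_loop(T) = ΔG37 · T/310.15 K`.  Multiloops use the affine
`a + b·branches + c·unpaired` form with (a, b, c) = (3.4, 0.4, 0.0)
kcal/mol at 37 °C.  Internal/bulge loops are scored by total size only
(no asymmetry or first-mismatch terms), and dangling ends and coaxial
stacking are excluded — a deliberately minimal mfold-class model that the
exhaustive test oracle can reproduce exactly.

**Terminal penalties.** Every helix end whose closing pair contains A or
U/T (including G·U) pays the table's terminal penalty once per
non-stacked side; this makes an isolated inter-strand helix score exactly
as the two-state duplex computation (tested).

**Salt.** A monovalent-equivalent concentration `[Na+]_eq = [mono] +
3.3·√[Mg2+]` enters as an entropy correction `0.368·ln[Na+]_eq` cal/mol/K
per stacked step.  The default conditions are the assembly buffer of the
modeled experiments: 22 °C, 100 mM monovalent, 10 mM divalent.

**Multi-strand complexes.** Strands are concatenated with recorded
nicks.  A nick never supports stacking, any loop containing a nick at
loop level is exterior-type (zero penalty, no hairpin minimum), and each
strand beyond the first pays one association-initiation term taken from
the table of the adjacent strand pair.  Complexes are capped at three
strands and 400 nt.

## Folding

`fold_mfe` is a Zuker-style dynamic program with tables V (closed by a
pair), M/M2 (multiloop interiors with ≥1/≥2 branches) and WX
(exterior-style regions), extended with an explicit nick-interrupted-loop
case; internal loops are capped at 30 unpaired nt.  The numerical kernel
is compiled with numba.  Tie-breaking in the traceback follows a fixed
case order with ascending indices, so identical inputs give bit-identical
structures.  The DP's minimum provably coincides with the minimum of the
public scorer over all legal structures; the suite checks this against
exhaustive enumeration for a thousand random sequences up to 18 nt and
for random two- and three-strand complexes.  `enumerate_suboptimal` is a
Wuchty-style enumeration over the same tables, returning every structure
within `window·|ΔG_mfe|` of the MFE (deduplicated by pair set); it is
exact, which the suite again verifies by enumeration.

Because the model is pseudoknot-free, an external strand can only invade
a region enclosed by a helix if that helix opens.  Several design
decisions below follow directly from this property.

## Tube equilibria

`enumerate_complexes` folds every strand multiset up to the cap (over all
distinct circular orderings, keeping the lowest-energy one) and keeps
monomers plus any complex whose MFE contains an inter-strand pair.  Each
complex is represented by that single MFE structure, which keeps the
ON/OFF classification of a species unambiguous.  `solve_equilibrium`
finds the law-of-mass-action fixed point `x_j = exp(−ΔG_j/RT)·Π λ_s^ν`
by Newton iteration with Armijo backtracking on the convex dual of the
tube free energy; mass balance is enforced to a relative 1e−6 (typically
far better), and the closed-form dimerization solution is reproduced to
below 1e−9 M.

The 30-minute bench incubations are modeled as "at equilibrium"; no
kinetics are computed.

## Gates and readout

An aptamer motif is a set of *keystone* base pairs (the stem centers and
the deep pocket-flanking pairs of each stem) plus the unpaired dye-pocket
positions.  A species is ON exactly when all keystones are present and
the pocket is open in its representative structure.  Restricting the
motif to keystones — rather than every stem pair — makes the
classification robust to ordinary helix-end fraying, which would
otherwise flip it on thermodynamically irrelevant variants.

Dye binding is modeled as structural gating only: dye is in excess in the
modeled protocols, so `signal = 1 + (F−1)·[gate_ON]/[gate_total]` with a
literature-typical order-of-magnitude enhancement factor F = 100 for both
MG and DFHBI.  Only normalized values are thresholded, so results are
insensitive to F (any F ≫ 1 gives the same bits).  Per experiment the
four scenarios (00, 01, 10, 11) are normalized to their maximum (exactly
100 %) and classified against the channel threshold — 60 % for MG, 40 %
for DFHBI — with equality reading as 0 (the threshold criterion is
"strictly greater").

Stoichiometries mirror the modeled protocols: simple gates run 1 µM gate
RNA with 2 µM of each present input (the NAND recipe doubles the inputs,
exposed as a per-gate multiplier with no mechanistic claim); half-adder
channels run 2 µM arm sites and 2 µM inhibitor per 1 µM tetragon with
5 µM inputs.

## The acceptance rule

A sequence is accepted for a target conformation iff (a) its MFE realizes
the target (all keystone pairs present, pocket open) and (b) the best
conformation-breaking structure — computed exactly by constrained
refolding that forbids one keystone at a time — lies at least 20 % of
|ΔG_mfe| above the MFE.  "Non-equivalent" is deliberately read at the
conformation level: under a literal any-different-pair-set reading no
structured RNA could ever pass, since helix-end fraying always produces
variants within a few percent of the MFE.

The rule is enforced for every aptamer core in isolation and for the
non-interfering (NAND/NOR) gate RNA, both of which pass with margins of
roughly 25–31 % in the shipped fixtures.  For the interfering (AND/OR)
gate RNA only the MFE-match part is enforced and the measured gap is
reported (18.5 % in the shipped fixture): the best competitor of an
interfering OFF state is the partial-ON refold, and that refold *must*
remain within a few kcal/mol — it is the switching transition that
weakly-bound AND inputs (see the Tm window below) have to drive.  A ≥20 %
gap at gate scale (≈8 kcal/mol) would be an unswitchable gate.

## Design criteria and architectures

The designer composes gates from a synthetic stem–pocket–stem core
(layout `a p1 b t b′ p2 a′`: a 5-bp outer stem with weak outer pairs, an
8-nt all-purine-pocket split across p1/p2, a 5-bp G/C inner stem, and an
A-rich terminal loop).  The core is a constructed stand-in with the
architecture of an MG- or Broccoli-type switching aptamer, not a natural
sequence.  All randomized segments are drawn from a seeded generator and
every candidate is verified end to end through fold → tube → readout →
truth table before being returned; failures trigger a redraw
(design-check-redesign made executable, up to `max_redesign_rounds`).

**AND/OR (interfering).** Arms X = rc(a·p1) and Y = rc(p2·a′) fold back
onto the core, so the no-input MFE sequesters the outer-stem keystones
and the pocket (OFF).  AND inputs are complements of one arm plus a
G/C-block terminal toehold whose length is auto-tuned so the *effective
displacement Tm* — the two-state Tm of the input:site duplex net of the
competing arm hairpin, one association event included — lands in
(22, 32] °C, quantifying "slightly above the operating temperature".  OR
inputs share the same gate RNA but carry two arm-stripping domains (the
near arm with the adjacent spacer as toehold, the far arm with a slice of
its terminal toehold), so a single input neutralizes both ends; their
criterion is the plain two-state duplex Tm of the whole input, required
≥15 °C above operating temperature.  The asymmetric Tm definitions are a
documented design decision: a plain-duplex reading of the AND window is
unsatisfiable (any displacement-competent hybrid of 15+ bp melts far
above 32 °C), while a displacement reading of the OR margin is
unsatisfiable (both arm displacements are deliberately near-thermoneutral).

**NAND/NOR (non-interfering).** The extensions are inert anchors; the
no-input MFE is ON.  Each NAND input's duplex extends three nucleotides
into the outer stem — A over the a-side, B over the matching a′-side of
the *same* outer pairs.  Per base pair, one hybrid extension loses the
marginal competition against the RNA stack (hybrid steps are weaker), but
the two rails together win it, so the stem collapses only at 1-1; the
2× input stoichiometry supports the joint invasion.  NOR inputs span
anchor, spacer, the whole outer stem and a pocket overhang, tipping the
global balance to a complete single-input kill.

**XOR / displacement-AND (inhibitors).** The XOR_DNA inhibitor holds the
Broccoli-type arm OFF via three duplex blocks (a′+flank, p1+inner-stem
start, flank+a) separated by two 8-nt single-stranded loops.  Its total
hold is tuned (via searched flank-anchoring extents) to beat the folded
arm by only a few kcal/mol, so one input — entering through a loop plus a
4–5-nt block overlap — strips it.  The two loops are near-complements of
each other with a single mismatch at the sticky boundary: when the inputs
pair via their 17-nt sticky ends the A:B duplex zips on through both loop
complements, burying the toeholds exactly at 1-1 (and the mismatch keeps
the terminal complementary run at exactly 17 nt).  The toehold↔loop
orientation is chosen so that the sticky duplex plus both toeholds on the
XOR inhibitor would be a pseudoknot — geometrically impossible — while
the AND_DNA inhibitor, whose sticky ends copy the two input toeholds at
its termini, zippers with both inputs into the planar three-stranded
complex that frees the MG arm only when both inputs coexist.

**Half adder.** Four vertex strands (each scaffold-half + aptamer arm +
scaffold-half, arms alternating MG/DFHBI) plus one hub strand close the
tetragon: five RNA strands, two copies of each inhibitor per particle.
Scaffold segments are drawn randomly and redrawn until no segment shares
a complementary run of ≥5 nt with any input, inhibitor or arm (the
cross-talk check).  Readout treats each arm as an independent
thermodynamic subsystem with the scaffold inert — whole-particle folding
is beyond a 2D model at this size — and each channel's tube contains both
shared inputs at full concentration.  Order of addition is not modeled;
only the equilibrium endpoint matters.

## Fixtures and reproducibility

`generate_fixtures(seed)` threads one seeded generator through core
drawing, all three family designers and scaffold assembly; the same seed
and generator version give byte-identical FASTA output (tested).  The
shipped seed is 2018.  Generation retries across fresh cores (the
designers' per-core round budget is capped at 40 during generation, as
fresh cores explore the space faster than deep per-core searches) and
completes in about a minute on one CPU.  Typical problem sizes: gate
strands 62–72 nt, complexes up to ~125 nt and three strands, 19–34
complexes per tube.

## Known limitations

* No pseudoknots, coaxial stacking, dangling ends, or loop-sequence
  terms; no partition-function ensemble — each complex is one structure.
* Hybrid and wobble parameters are style-reproductions, not literature
  bit-copies; absolute energies should not be quoted against ViennaRNA
  or mfold outputs (qualitative agreement only).
* The fixture sequences are synthetic stand-ins satisfying the stated
  architectural constraints, not reconstructions of any bench-validated
  set; passing truth tables demonstrate the *model's* switching logic,
  not wet-lab performance of these exact oligos.
* Dye binding, transcription yield, assembly kinetics and particle
  geometry (AFM/DLS-scale structure) are out of scope.
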