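# Methods

This note documents the models implemented in `lanmkit`, the conventions
and defaults they use, and what the synthetic-data generators do and do not
emulate. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Sequence screening (`seq_screen`)

**Motif model.** An EF-hand metal-binding loop is modelled as a 12-residue
window with class constraints at a subset of positions. No published regex
defines the lanmodulin loop, so the default pattern encodes the ligand sets
observed in solved LanM sites — position 1 ∈ {D,N} (the monodentate
Asn/Asp), 3 ∈ {D,N,E}, 5 ∈ {D,N,E,S,T}, 12 ∈ {D,E} (the C-terminal
bidentate carboxylate) — with all other positions unconstrained except that
a proline at position 2 is flagged (`p2`). `X` never satisfies a
constrained position. Every class is caller-overridable, because the
pattern is an explicit approximation of a manually curated screen. The
scan is left-greedy and non-overlapping: a matched loop cannot also serve
as the interior of another match, which is the physically sensible reading
for helix–loop–helix motifs.

**Curation rules.** A candidate passes when (a) it is shorter than 200
residues, (b) it has ≥ 4 hands (a strict-equality toggle exists because
"four EF hands" could be read either way), (c) at least one adjacent hand
pair is separated by ≤ 13 residues, where spacing counts the residues
strictly between loop position 12 of one hand and position 1 of the next,
and (d) at least one hand carries P2. The P2 rule is reported as its own
criterion and can be disabled: it is a hallmark of the family rather than
part of every curation pipeline. Failing verdicts are results with reasons,
never exceptions. Residue indexing is 1-based throughout; signal peptides
are assumed already removed.

**Similarity networks.** Pairwise global (Needleman–Wunsch) alignments use
BLOSUM62 with gap open 11 / extend 1 (Biopython `PairwiseAligner`).
Percent identity uses the alignment length after stripping terminal-gap
columns — internal gaps count against identity, overhangs do not; this
differs subtly from some network-tool conventions and is fixed here for
reproducibility. Database E-values are not reproducible offline (they
depend on database size), so edge admission uses the identity threshold
plus a raw alignment-score floor (default > 0). To make identity exactly
symmetric despite alignment-traceback ties, each pair is aligned in a
canonical sequence order. `rethreshold` raises the threshold of a computed
network without re-aligning, which is how threshold sweeps (40→90%) are
done cheaply.

**Sequence properties.** Average (not monoisotopic) residue masses plus
one water; cross-checked in the tests against Biopython's calculator. The
extinction coefficient uses the Trp/Tyr/cystine increments
(5500/1490/125 M⁻¹cm⁻¹); cysteines are assumed reduced unless a cystine
count is supplied. `X` contributes the mean canonical residue mass and
flags the MW as approximate.

## Binding models (`binding_models`)

**Chelator buffering.** Picomolar affinities are measured with free metal
clamped by a competitive chelator. Speciation uses a single conditional
1:1 stability constant K_cond (L/mol) that folds chelator protonation at
the working pH into one number; K_cond is always user input (an example
table ships clearly marked non-authoritative). The mass balance

K·x² − (K·M_T + K·L_T + 1)·x + K·M_T·L_T = 0,  x = [ML]

is solved with the numerically stable (citardauq) root; closure of both
metal and chelator balances is asserted to 1e-10 relative on every call.
Multi-ligand buffer models are out of scope; if the real buffer deviates
from 1:1 behaviour that error is absorbed into K_cond.

**Hill fits.** The conformational response is
S(x) = S₀ + (S₁−S₀)·xⁿ/(Kⁿ+xⁿ) with x free metal. Fitting is least
squares on a log₁₀(x) axis because titrations span ≥ 4 decades.
Initialization: K from the concentration at the signal midpoint, n = 1;
bounds n ∈ [0.3, 4] and K within [min(x)/100, max(x)·100]. For buffered
datasets the free-metal axis is computed through the speciation solver
before fitting — fits are always on free metal, never totals. Standard
errors come from seeded residual-resampling bootstrap (default 500
resamples). Flat or monotone-decreasing data return a flagged failure
rather than a boundary fit; desorption-shaped data belong in
`fit_desorption` (a 4-parameter logistic on log₁₀ chelator concentration
whose midpoint is [chelator]₁/₂). A replicate-aggregation helper reports
mean ± s.e.m. across independent experiments, the convention used for
benchtop titrations.

## Monomer–dimer equilibrium and dilution ITC (`oligomer_state`)

**Equilibrium.** For D ⇌ 2M, K_dimer = [M]²/[D] (concentration units) and
[P] = [M] + 2[D]; the monomer concentration is the positive root of
2[M]² + K[M] − K[P] = 0, evaluated in a cancellation-safe form and
verified against bisection in the tests. The weight-average MW
M_mono·([M]+4[D])/([M]+2[D]) interprets SEC–MALS apparent masses; it is
exposed as a function of [P] because the on-column concentration is rarely
known precisely.

**ITC forward model.** The cell (volume V₀, initially buffer) receives
injections from a syringe of concentrated protein. Conventions, none of
which the instrument literature fixes unambiguously:

- *Displacement:* instantaneous mixing with overflow at constant V₀:
  P_i = P_{i−1}(1 − v_i/V₀) + P_syr·v_i/V₀, with displaced volume leaving
  at the pre-injection cell concentration.
- *Heat:* q_i = ΔH_diss · (D_mix − D_eq)·V₀ + q_blank, where D_mix is the
  dimer concentration of the hypothetical no-reaction mixture (carryover
  speciation plus injected syringe speciation) and D_eq the equilibrium
  value at P_i. ΔH is **per mole of dimer**; endothermic dissociation
  (positive ΔH) produces positive heats.
- *Standard state:* ΔG = −RT·ln(K_dimer/1 M); ΔS = (ΔH − ΔG)/T; default
  temperature 303.15 K. The default schedule is one 0.2 µl pre-injection
  plus 17 × 2 µl (185 µl cell, 300 µM syringe); the pre-injection is
  excluded from fits by default.

**ITC fitting.** Three parameters (log₁₀K, ΔH, q_blank), K bounded in
[1e-9, 1e-1] M. Residuals are weighted by the observed heat magnitudes by
default ("relative" weighting): heat uncertainty on these instruments
scales with heat size, and matched weighting measurably tightens K
recovery; a floor of 5% of the largest heat prevents near-zero heats from
dominating. These three parameters are mutually sloppy for a single
18-injection series — at 2% noise a single-series K estimate carries
roughly 5–10% uncertainty — which is why the acceptance script averages
three independent simulated series, mirroring the triplicate protocol of
the corresponding benchtop measurement. Identifiability is checked with an
F-test of the dissociation model against a blank-only (flat) model: when
dissociation does not significantly improve the fit (p > 0.01) the result
is flagged `bound_only` and should be read as a bound on K_dimer, not an
estimate. This is the tight-dimer case: a dimer much tighter than the
working concentrations never monomerizes measurably, and its heats sit in
the instrument noise floor.

Linked metal-binding/dimerization equilibria are out of scope; each metal
condition is fitted as a pure dimer-dissociation system.

## Luminescence hydration number (`luminescence`)

Decays are fitted as I(t) = A·exp(−t/τ) + b (baseline on by default,
toggleable); traces arrive on a µs grid and lifetimes are carried in ms
because the q-equation constants assume ms⁻¹ rates. Rates 1/τ are
regressed on D₂O *fraction* (0–1); the CLI accepts percent and converts.
With slope m, intercept τ⁻¹(H₂O) and extrapolation to fraction 1 giving
τ⁻¹(D₂O), the hydration number is

q = 1.11·[τ⁻¹(H₂O) − τ⁻¹(D₂O) − 0.31 + 0.45·n_OH + 0.99·n_NH + 0.075·n_O–CNH]

which for the protein-site default (n_OH = n_NH = 0, n_O–CNH = 1, the
metal-coordinated amide) reduces to q = 1.11·(−m − 0.31 + 0.075). The
oscillator counts are always user input, never inferred from structure.
Sub-zero q values are reported as computed — they indicate a fully
solvent-excluded site within the calibration's uncertainty — and are never
clamped. Multi-exponential deconvolution is out of scope.

## Separation metrics (`separation`)

Batch distribution ratios apply the bead-carryover correction with
generalized volumes, [M]_LanM = (V_de·[M]_de − V_bead·[M]_ad)/V_de, whose
defaults (4 ml strip, 1 ml beads) reproduce the familiar
(4·[M]_de − [M]_ad)/4 form. Negative corrected concentrations (noise near
zero) clamp to 0 with a warning; a metal absent from the liquid phase
reports infinite D with a warning rather than crashing. SF matrices are
reciprocal-consistent with unit diagonal by construction.

Fraction tables carry a strictly increasing bed-volume axis; fraction
volume is Δbed_volume × bed_volume_ml (default 0.7 ml) unless an explicit
volume column is present. Pooled purity generalizes the two-metal form to
C_RE1/ΣC (an extension beyond the printed two-metal definition), and yield
is pooled moles over loaded moles. Pooling windows are always explicit
caller input — published yields depend on which inter-peak fractions were
pooled, so no default pooling is imposed. Window membership tolerates
1e-9 relative floating-point slack on the bed-volume axis. Breakthrough
is the first bed volume where effluent/feed reaches a threshold (default
0.1), linearly interpolated between fractions except when effluent first
appears within a fraction (a rise from exactly zero), which reports that
fraction's bed volume.

## Structure analysis (`structure_sites`)

Structures load through gemmi (PDB or mmCIF). Alternate conformations are
resolved atom-by-atom to the highest-occupancy conformer (ties toward
altloc 'A'); metals below 0.5 occupancy are excluded from site lists.
Donor shells count all O/N atoms (protein or water, excluding the metal's
own residue) within a cutoff, default 3.0 Å — typical Ln–O bonds run
2.3–2.7 Å and no universal cutoff exists, so reports are sorted by
distance and the cutoff is a parameter everywhere. Backbone carbonyl
oxygens count as donors; hydrogens are ignored; waters are counted but
tagged, so solvent-excluded and solvent-containing sites compare
explicitly. A carboxylate (Asp OD1/OD2, Glu OE1/OE2) is bidentate when
both oxygens fall within the cutoff and monodentate when exactly one does;
`site_comparison` flags any between-model denticity change as a
carboxylate shift. Second-sphere hydrogen bonding is assessed as
heavy-atom donor–acceptor distances (≤ 3.5 Å convention; `pair_distance`
reports minima over atom selections, e.g. the arginine guanidinium
nitrogens versus a glutamate's carboxylate oxygens).

Buried surface area uses an in-package Shrake–Rupley sampler with
deterministic golden-spiral points (default 960 per atom, probe 1.4 Å):
BSA = SASA(A) + SASA(B) − SASA(AB), reported as the total over both chains
with the per-chain half alongside, since "buried area" is quoted in both
conventions. The sampler is validated against the analytic two-sphere
cap-overlap formula and for point-count convergence in the tests.
Polyhedron shape classification and crystallographic refinement are out of
scope. `deposited_benchmark` bundles the headline comparisons (modal CN,
carboxylate-shift denticity, Arg–Glu distances, interface BSA) for a
locally supplied La-form/Dy-form structure pair; it downloads nothing.

## Synthetic data (`synthetic_data`)

One master seed fans out through a CRC-label hash into independent
per-generator streams, so adding a generator never changes existing
fixtures and every truth record carries its seed. All outputs are the
standard formats the pipeline reads (FASTA, arrays destined for CSV,
gemmi structures that write valid minimal PDB, marked synthetic).

Defaults are the study conditions: 4 planted hands at 12–13-residue
spacing with P2 in ~110-residue sequences; 12-point titrations at 2%
multiplicative noise (the La condition spans 1 pM–10 nM free metal; other
metals default to 4 decades centred on K_d); the 0.2 µl + 17 × 2 µl
dilution-ITC schedule at 300 µM syringe and 30 °C; decay series at D₂O
fractions 0/0.25/0.50/0.75 over a 2,500 µs window with a 5,000-count
peak; a 95:5 Nd/Dy elution with 0.7 ml bed volumes. The ITC ΔH default
(+25 kJ per mol dimer, endothermic dissociation) is a typical magnitude
for a weak protein dimer, chosen because no printed value is available in
the sources at hand; only K_dimer is compared quantitatively anywhere.
gen_itc's additive instrument-noise floor (off by default; 0.1 µJ is a
typical figure when enabled) exists to emulate the physical insensitivity
of the calorimeter to very tight dimers.

Sequence generators draw backgrounds from an alphabet that cannot satisfy
any loop-position class, so planted loops are provably the only matches —
real proteomes contain near-miss motifs the screen must reject on other
criteria, which these fixtures do not emulate. Similarly, titration noise
is i.i.d. multiplicative (real CD drifts), decays are strictly
single-exponential (real traces can be multi-exponential), elution peaks
are Gaussian with exact mass closure (real columns tail and lose mass),
and idealized metal sites have no second shell or covalent context.
Passing tests therefore demonstrate correctness of the estimators under
the stated models, not robustness to every real-data pathology.

## Problem sizes

Test-suite and acceptance runs use desk-scale sizes chosen to exercise
every code path: ≤ 50-sequence networks (≤ 1,225 alignments), 12-point
titrations, 18-injection ITC series (3 replicates in the acceptance
script), 250-point decay traces, 600-fraction elution tables, 10⁴-draw
property sweeps, and ≤ 4,000-point SASA sampling on small fixtures.
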