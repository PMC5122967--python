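# Methods

This note records the models, conventions and numerical choices behind each
analysis stage, what the synthetic generators do and do not emulate, and the
design decisions taken where more than one defensible convention exists.

## Coordinate model and selections

A structure is a list of atom identities shared by every model plus an
`(n_models, n_atoms, 3)` coordinate array; NMR depositions satisfy the
identical-atom-set invariant by construction and a file violating it is
rejected with the offending atoms named. Hydrogens are retained on reading
(NMR ensembles carry them; the surface module filters them itself).
Alternate locations resolve to the highest-occupancy conformer, ties broken
alphabetically, so reads are deterministic.

Residue numbers in selections are *logical*: file (author) numbering plus a
per-chain offset supplied with the chain map. The deposited chain ids and
numbering of a given entry are configuration, never guessed or hard-coded —
a wrong map produces an empty selection, which is an error rather than an
empty result, precisely because it almost always means a numbering mistake.

The selection grammar is `ENTITY:RANGES:ATOMSPEC` with atom classes
`backbone` ({N, CA, C, O}), `sidechain` (CB outward, side-chain hydrogens
included, amide H excluded), `heavy`, `all`, and `named ...` lists.
Selections are order-stable (chain, residue, atom name) so downstream
results do not depend on file ordering.

## Synthetic generators

All generators are pure functions of their inputs and a seed; noise without a
seed is an error, and no generator touches global random state.

Backbones are grown by NeRF chain extension from one table of ideal bond
lengths and angles (Engh–Huber-like values: N–CA 1.458 Å, CA–C 1.525 Å,
C–N 1.329 Å, C=O 1.231 Å, τ(N–CA–C) 111.2°, …), with φ = −57°, ψ = −47°,
ω = 180° as the α-helix default. Each residue gets N, CA, C, O, CB (except
Gly) and an amide H (except Pro and the N-terminus) placed in the peptide
plane anti to the following CA; the ideal helix then shows the textbook
1.5 Å rise per residue, 3.80 Å CA(i)–CA(i+1) and 2.80 Å HN(i)–HN(i+1). Full
side chains, rotamers and realistic shift prediction are deliberately out of
scope: the generators exist to give every analysis stage an exactly known
answer, not to imitate a force field.

Two-helix complexes place helix A along +z and helix B rotated by the
requested crossing angle and displaced by the requested axis separation
(< 4 Å is rejected as a clash). Because both helices are ideal, the
interhelical-angle analysis recovers the construction angle to well under
the 2° acceptance band; note that with this construction the interface sits
where the axes approach, which for oblique angles is toward one end of the
shorter helix, not its middle.

Shift tables put every residue at 8.30/119.5 ppm (¹H/¹⁵N) and add the
requested perturbations over non-overlapping ranges; Gaussian noise is drawn
independently for both states, 5× wider on ¹⁵N to mimic the wider nitrogen
scale. PRE intensities use the spin-label model below with I_red = 100.
NOE lists contain one restraint per proton pair within the cutoff, bounds
[1.8 Å, d_true + pad], so the generating model violates nothing — the
self-consistency anchor for the violation machinery. RDC sets are
back-calculated from a specified Saupe tensor, making tensor recovery exact
at zero noise.

## Chemical shifts

The combined amide perturbation is √(ΔδH² + (α·ΔδN)²). The ¹⁵N weighting α
defaults to 0.2 (the common ΔδN/5 convention in the calmodulin literature)
and is exposed in the API and CLI because published per-study weightings
vary and are not always recoverable from a paper's text; reported region
averages should therefore be read as α-dependent. Missing observations stay
missing (NaN) through every operation — a residue absent in one state never
contributes a zero.

Titration saturation is the smallest molar ratio after which the mean
absolute per-residue change of the profile to the next point drops below a
tolerance (default 0.005 ppm); a monotonically growing series returns
"not saturated" (None).

The CSI implementation is the simplified Cα-only form: Δ(Cα) against a
built-in random-coil table, ±0.7 ppm dead band, and helix/strand calls only
for runs of at least four consecutive like-signed residues. That is
sufficient for helix/coil segmentation of a binding partner; a
multi-nucleus consensus CSI is out of scope.

Heteronuclear NOE ratios are I_sat/I_nosat with
σ = |ratio|·√((σ_sat/I_sat)² + (σ_nosat/I_nosat)²); the propagation formula
is verified against Monte-Carlo to 5% at 10⁴ draws. Reference peaks within
3× the spectral noise are flagged unreliable and excluded, since their
ratios are arbitrarily wild rather than merely noisy.

## PRE

The intensity model is the two-parameter exponential form standard for
spin-label PRE work: Γ₂ = K/r⁶ and I_ox/I_red = R₂·exp(−Γ₂t)/(R₂+Γ₂).
Defaults K = 1.2×10⁸ Å⁶ s⁻¹, R₂ = 20 s⁻¹, t = 10 ms put the half-broadening
radius near 15 Å, typical for a nitroxide label on a small complex; these
are simulation inputs, not fitted constants.

Published PRE profiles are "normalized" without the factor being stated, so
the default here is explicit and robust: divide raw ratios by the mean of
the top decile of finite raw ratios, which assumes only that a majority of
residues are unaffected by the label. Reference-residue and no-op
normalizations are selectable. Classification thresholds (0.85/0.5/0.2) are
strict upper bounds — a ratio of exactly 0.85 is *no* effect — matching the
"<" phrasing such studies use; a peak broadened beyond detection (I_ox
within 3× noise) is very_strong by definition and carries no numeric ratio.

Difference maps (variant − reference) report positive Δ as increased
label–amide distance. A residue broadened in the reference but measurable
in the variant is flagged `released` (no numeric Δ is meaningful across the
detection edge); the converse is `trapped`.

Back-calculation averages r⁻⁶ over models before converting to Γ₂, the
physically correct ensemble average for relaxation. The spin-label tether
itself is not modelled: the label position is whatever atom the caller
selects (a CB is the usual proxy), a documented approximation that mostly
shifts all distances by a few Å without reordering them — which is why the
consistency statistic is a rank correlation (Spearman, class severity vs
proximity) rather than anything metric.

## Geometry

Superposition is the Kabsch SVD solution with the determinant correction, so
a proper rotation is always returned; collinear point sets are rejected
because their rotation is not unique. The implementation is checked against
an independent Horn quaternion oracle to 10⁻⁸ on random instances.

Ensemble RMSD statistics superpose each unordered model pair *on the scored
selection itself* and report mean ± sd over the C(n,2) pairs — the
convention used by common NMR ensemble-statistics tools, and the one that
published "average pairwise RMSD" tables presume.

Helix axes are the principal direction of the Cα cloud, oriented N→C; a
cloud whose first-to-second singular-value ratio is below 1.5 is flagged as
not helix-like. The interhelical angle is arccos(d₁·d₂) in [0°, 180°] with
both axes N→C. Published EF-hand angle tables depend on the exact axis
definition (often a four-vector construction), which is generally not
recoverable; absolute angles from different conventions are therefore not
comparable, and the conformational-state call takes the closed and open
reference angles as configuration (±15° windows, semi-open in between)
rather than constants.

Hydrogen bonds use a pure distance criterion by default (3.5 Å for
heavy-atom N···O distances; use ~2.5–3.0 Å when the donor selection names
the hydrogens), since that is how such contacts are typically quoted for
NMR ensembles; persistence is the fraction of models containing the
contact. An angular filter is deliberately absent from the default path.

## Surfaces and electrostatics

SASA is Shrake–Rupley quadrature with a deterministic golden-spiral point
set (default 960 points/atom, probe 1.4 Å) over united-atom (Chothia-type)
element radii, hydrogens ignored; a Bondi set with explicit hydrogens is
available. The quadrature is within 0.02% of the closed-form two-sphere
solution at 3840 points and converges to < 1% between 960 and 3840 points on
protein-sized systems; the ±10% tolerance used when comparing buried-surface
areas against published NACCESS-based values absorbs radii-set differences.

BSA is SASA(A) + SASA(B) − SASA(complex), summed over both partners (not
halved) — the convention consistent with published interface sizes of this
magnitude. Burial fractions are 1 − SASA_complex/SASA_free per side chain
with the free state computed within the residue's own entity, group means
area-weighted; a side chain with zero free-state area is skipped with a
warning rather than producing 0/0.

The ESP is a *linearized Debye–Hückel screened Coulomb* sum over formal
pH-7 charges (Asp/Glu −0.5 per carboxylate O, Lys +1 on NZ, Arg +0.5 per
NH, His 0, termini ±1), uniform ε_r = 78.5, κ from the 1:1 ionic strength
(κ⁻¹ ≈ 9.6 Å at 100 mM, 298 K), evaluated on the SASA dot surface and
expressed in kT/e. This is not a Poisson–Boltzmann solver: there is no
dielectric boundary, so magnitudes near the surface are systematically
compressed relative to APBS-style maps. Signs, gradients and the topology
of negative patches — the quantities the steering argument rests on — are
robust to this simplification, and only those are ever asserted.
Evaluation points within 0.5 Å of a charge are clamped and flagged.
Per-atom charges can be supplied explicitly to override the formal model.

Basins are single-linkage connected components (default link distance
2.0 Å, matching the dot-surface point spacing at 960 points/atom) of
surface points below a negative threshold, reported with area, minimum
potential, area-weighted centroid and minimum distance to a target atom
(e.g. a coordinating carboxylate). The dot surface stands in for a
solvent-excluded surface; this changes basin *areas* somewhat but not their
existence or location.

## Restraints and RDCs

Ambiguous (multi-atom) restraint sides use r⁻⁶ summation,
r_eff = (Σ r⁻⁶)^(−1/6), the standard treatment for ambiguous NOEs.
Violation statistics average over *all* restraints within each model and
then report mean ± sd across models — the interpretation consistent with
published "0.0xx ± 0.00x Å" ensemble tables; the alternative (mean over
violated restraints only) is computed alongside. Restraints whose atoms are
absent from the structure are excluded and counted, never silently dropped.

Category counts follow the standard table rules: |i−j| = 0 / 1 / (1,5) /
≥ 5, cross-chain restraints are intermolecular regardless of separation,
and "ambiguous" means a side spanning multiple residues. Because some
tables instead count OR-ambiguous atom selections, the count of restraints
with any multi-atom side is reported as well (`ambiguous_or_groups`), so
both readings are available.

The XPLOR `assign` parser covers the segid/resid/name subset with OR
ambiguity and maps `d dminus dplus` to bounds [d−dminus, d+dplus];
unparseable statements go to a rejection report. The full XPLOR selection
grammar and CYANA dialects are out of scope.

The Saupe fit solves D = bᵀSb by least squares over the five independent
elements of the traceless symmetric order matrix (design matrix
[bx²−bz², by²−bz², 2bxby, 2bxbz, 2bybz]), reporting the condition number;
under five independent vectors, or a rank-deficient design (all vectors
parallel), is an error. Eigenvalues are ordered |S_zz| ≥ |S_yy| ≥ |S_xx|,
giving Da = S_zz/2 and R = ⅔(S_xx−S_yy)/S_zz ∈ [0, ⅔]. Noise-free
fit → back-calculate → fit is a fixed point, and Q = 0 iff exact agreement.

## Pipeline, problem sizes, determinism

A run is configured by one YAML/dict naming inputs and per-stage parameter
blocks; stages with missing optional inputs are skipped, a referenced file
that does not exist fails validation before any computation, and two runs
with identical config and inputs produce byte-identical TSVs and report
(timestamps are excluded from the report for this reason).

The synthetic bundle and the acceptance script use a 20+16-residue two-helix
complex, 5–20 model ensembles, ~100-restraint NOE sets, 34-vector RDC sets
and 100-replicate PRE simulations; these sizes make every property sharp
(recovery errors orders of magnitude below the asserted bands) while keeping
a full run in seconds.

## Known limitations

- No side-chain construction in the generators; charge-bearing atoms for
  ESP tests are supplied as explicit per-atom charges on CB positions.
- The ESP surrogate cannot reproduce Poisson–Boltzmann magnitudes, only
  sign/topology; ESP magnitudes are never asserted anywhere.
- The PROXYL tether is not modelled; PRE back-calculation is anchored at a
  chosen atom.
- Absolute EF-hand angles are convention-dependent; only angle differences
  and synthetic recoveries are asserted.
- Comparisons against the published PEP-19:apo C-CaM statistics require the
  user-fetched deposition files (see README); nothing is downloaded.
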