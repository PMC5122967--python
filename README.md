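# calsteer

Analysis toolkit for NMR ensemble studies of calmodulin–IQ-protein complexes,
built around the question of how an intrinsically disordered, acidic partner
protein tunes Ca²⁺ binding to the C-domain of calmodulin (C-CaM) by
*electrostatic steering*: reshaping the negative electrostatic surface
potential near EF-hand Ca²⁺-binding loop III so that incoming Ca²⁺ is funneled
toward its first coordinating residue (Asp93).

The package covers the complete post-structure analysis of such a study, each
stage usable on its own or through one configured pipeline run:

| stage | what it computes |
|---|---|
| `shift_analysis` | chemical-shift perturbation (CSP) profiles, region means, titration saturation, simplified Cα CSI secondary-structure calls, steady-state ¹⁵N{¹H} NOE ratios with propagated uncertainties |
| `pre` | paramagnetic relaxation enhancement: normalized I_ox/I_red profiles, effect classification, WT-vs-mutant difference maps, ensemble back-calculation, label-site consistency |
| `geometry` | Kabsch superposition, average pairwise ensemble RMSD, helix-axis fits, EF-hand interhelical angles with closed/semi-open/open calls, hydrogen-bond scans |
| `surface` | Shrake–Rupley SASA, buried surface area of an interface, side-chain burial fractions, screened-Coulomb (Debye–Hückel) electrostatic surface potential, negative-ESP basin/channel detection |
| `restraints` | NOE distance-restraint parsing (native TSV and XPLOR `assign`), category counts, r⁻⁶-averaged violation statistics, Saupe-tensor RDC fits with Da, rhombicity and Q factor |
| `synthetic` | ground-truth generators for all of the above: ideal helical backbones, two-state shift tables, spin-label PRE intensities, NOE restraint lists, back-calculated RDC sets |

## The quantities at the core

**CSP** between free and bound states uses the weighted amide norm
Δδ = √(ΔδH² + (α·ΔδN)²), α = 0.2 by default.

**PRE** follows the two-parameter spin-label intensity model
Γ₂ = K/r⁶, I_ox/I_red = R₂·exp(−Γ₂·t)/(R₂+Γ₂); ratios < 0.85 indicate an
effect, < 0.5 a strong one, < 0.2 (or broadening beyond detection) a very
strong one. Ensembles are averaged as ⟨r⁻⁶⟩ before conversion.

**Buried surface** is BSA = SASA(A) + SASA(B) − SASA(AB), summed over both
partners, with NACCESS-like united-atom radii and a 1.4 Å probe.

**ESP** is a linearized Debye–Hückel screened Coulomb sum over formal pH-7
charges, φ(p) = (l_B/ε_r)·Σ qᵢ·exp(−κdᵢ)/dᵢ in kT/e, evaluated on the SASA
dot surface; connected patches with φ below a threshold are reported as
basins with area, depth and distance to a target atom.

**RDC** fits solve D = bᵀS b by linear least squares over the five
independent Saupe elements; Da = S_zz/2, R = ⅔(S_xx−S_yy)/S_zz and
Q = √(Σ(D_obs−D_calc)²/ΣD_obs²).

## Worked example

Generate a fully synthetic study — a two-chain helical complex at a 120°
crossing angle plus shift tables, PRE intensities, NOE restraints and an RDC
set, all with known truth — then analyse it:

```sh
calsteer simulate --out bundle --seed 2
calsteer rmsd bundle/synthetic_complex.pdb "A:*:backbone"
calsteer csp --free bundle/shifts_free.tsv --bound bundle/shifts_bound.tsv --range 5 12 --out prof.tsv
calsteer run --config bundle/config.yaml --out run
```

prints

```
0.328 +/- 0.058 A over 10 model pairs
region 5-12: mean 0.1993 ppm over 8 residues
```

The RMSD line is the average pairwise backbone RMSD over all C(5,2) = 10
model pairs of the bundled 5-model ensemble (the models are the ideal complex
plus 0.15 Å coordinate noise, so ~0.3 Å is the expected spread). The CSP line
recovers the perturbation the generator injected into residues 5–12:
√(0.12² + (0.2·0.8)²) = 0.200 ppm, reproduced to within the 0.004 ppm shift
noise. The `run` report adds, among others, the interhelical angle
(119.9 ± 0.2°, truth 120°) and the RDC fit (Da 7.98 Hz, R 0.309 against the
generating tensor's 8.0 / 0.30).

Python API equivalents live in `calsteer.pipeline.make_synthetic_bundle` /
`run_pipeline`; every CLI subcommand is a thin wrapper over one library
function.

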