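# Methods

This note documents the models, numerical choices, and limitations of
`colorspec`, in the spirit of a package methods section: what is computed,
under which assumptions, and what the synthetic closure tests do and do not
demonstrate.

## Polarizable embedding (FQ / FQFμ)

**Model.** Each MM (solvent) atom carries a fluctuating charge qᵢ; in the
FQFμ variant also an induced point dipole μᵢ. The classical energy is

E(q, μ) = χᵀq + ½qᵀT_qq q + qᵀT_qμ μ + ½μᵀT_μμ μ + qᵀV(D) − μᵀE(D),

minimized under one linear constraint per molecule, Σᵢ∈mol qᵢ = Q_tot
(electronegativity equalization with no intermolecular charge transfer).
Stationarity gives a symmetric bordered (KKT) linear system; the FQ variant
is obtained by deleting all dipole rows/columns. V(D) and E(D) are the
potential and field of the solute source at the MM sites. The solute is
represented classically by point charges (optionally point dipoles) on its
atoms — a surrogate for a quantum density; self-consistent QM↔MM coupling
and response-theory extensions are outside this package's scope, so the
source is held fixed and the MM response to it is exact.

**Kernels.** The published descriptions of these force fields specify the
parameters (χ, η, α) but not always the smearing forms, so the kernels are
explicit configuration here, with defaults chosen from standard practice:

* charge–charge: Ohno kernel J(r) = 1/√(r² + d²), d = 2/(ηᵢ+ηⱼ), which
  interpolates between (ηᵢ+ηⱼ)/2 at contact and Coulomb 1/r at long range
  (leading deviation d²/2r²); a bare 1/r is selectable.
* charge–dipole and dipole–dipole: point-multipole tensors by default;
  optionally Gaussian (Thole-style) damped with pair width
  a = A·(αᵢαⱼ)^{1/6}, using the erf-damped tensor derivatives.
* dipole self-energy: αᵢ⁻¹·I.

**Numerics.** Atomic units internally (1 Å = 1.8897259886 Bohr,
1 Hartree = 27.211386 eV); dense symmetric solve (LAPACK `sysv` via SciPy);
the condition number is estimated for systems up to 600 unknowns and the
solve refused above 10¹²; per-molecule charge sums are verified to 10⁻¹⁰ e
after every solve. Shipped parameter TSVs (`params/*.tsv`) carry
literature-style placeholder values for water and ethanol atom types and
are meant to be replaced by a parametrized set; all tests state their
parameters explicitly.

**Verification.** On small systems the bordered solve is checked against
direct constrained minimization of E(q) (scipy trust-constr), to 10⁻⁸ on
charges. Properties exercised: linearity of the induced response in the
external field, rigid-motion invariance (charges and energies invariant;
dipoles co-rotate), FQFμ→FQ convergence as α→0 with dipole magnitudes
vanishing linearly in α, and faster-than-Coulomb far-field decay of the
embedding potential of neutral molecules.

## Trajectory handling and droplets

Coordinates are Å everywhere; GRO input (nm) is converted on read. Only
orthorhombic boxes are supported. Molecules are made whole by minimum-image
shifts relative to their first atom; a molecule spanning more than half the
box after unwrapping is rejected as ill-defined. Droplets are cut around
the geometric center of the solute: a solvent molecule is retained if and
only if its reference atom (first atom — the oxygen for water-like
solvents) lies within the radius, and retained molecules are kept whole and
shifted to the image nearest the center. Counterions are single-atom
solvent molecules under the same rule (a flag can drop them). Droplet files
round-trip through XYZ at 10⁻⁶ Å and PDB at the format's 10⁻³ Å precision.

## Conformational analysis

Torsions follow the IUPAC convention (cis = 0°, right-hand rule). The Φ
cluster analysis uses four fixed 90° bins; because the strict inequalities
of the usual description leave the bin edges unassigned, bins are half-open
and lower-inclusive ([90°,180°), [0°,90°), [−90°,0°), [−180°,−90°)), and
180° wraps to −180°, making the assignment total and deterministic.
Dihedral distribution functions are periodic histograms normalized to unit
integral (default 1° bins). The central structure of a Φ group minimizes
the mean circular distance to the other members (ties to the lowest frame
index); for RMSD-based clustering the analogous criterion uses
mass-unweighted superposed RMSD on the heavy solute atoms. GROMOS
clustering is the standard neighbor-counting algorithm over the pairwise
superposed-RMSD matrix, with the largest-neighborhood frame (lowest index
on ties) seeding each cluster; the cutoff has no default and must be chosen
per system.

## Solvation analysis

Intermolecular g(r) uses minimum-image distances, shell-volume
normalization 4πr²Δr at bin centers, and ρ_B from the mean B count over the
box volume; an independent cross-check against MDAnalysis `InterRDF` agrees
to the Δr²/(12r²) difference of the two shell-volume conventions.
Intramolecular correlations are shell-volume normalized only (no bulk
density reference). Default grid: 0.02 Å bins to 10 Å — fine enough to
resolve first-peak shifts of a few hundredths of an Å between solvents.
Extremum detection runs on a centered 3-bin moving average (never applied
to the reported g); the first-shell boundary for coordination numbers is
the first minimum after the first peak of that pair's own g(r). RCN is the
trapezoidal shell integral, which for g ≡ 1 reproduces (4/3)πr³ρ to 10⁻³.

## Spectral assembly

Convolution happens on the energy axis (the FWHM is stated in eV; 0.3 eV
default, 0.6 eV appropriate for broader tautomer bands), with unit-area
Gaussians so oscillator strengths set band areas; the default grid spans
the sticks ± max(1 eV, 4·FWHM) at 0.005 eV steps, conserving Σf to 10⁻³.
Averages are taken over raw snapshot spectra and normalized to unit maximum
once at the end, preserving relative snapshot intensities. Convergence
curves resample subsets without replacement (seeded) and report the mean
max-abs distance to a reference (the full average by default). Shifts are
reported in both units from the respective axes — ΔE from the eV peaks and
Δλ from the nm peaks — positive for a red shift, with 1 eV = 23.0605
kcal/mol for energy-error conversions and E[eV]=1239.84193/λ[nm] throughout.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
the physics that produces it:

* **Solute**: a rigid 22-atom two-ring stand-in (one ring oxygen, five
  hydroxyls) with the donor/acceptor labeling H7–H11 / O1–O6 mapped onto
  it, so site-resolved analyses run unchanged. Net charge +1 (the acidic
  flavylium-like state). Φ is drawn from a four-mode von Mises mixture —
  defaults ±160° and ±20° (κ=20) with weights (0.4, 0.1, 0.1, 0.4),
  i.e. quasi-planar conformers dominating — and hydroxyl torsions from a
  bimodal 0°/180° density (κ=10). A 0.02 Å thermal jitter is added.
* **Solvent**: water-like 3-site molecules in a 62 Å periodic box
  (300 by default — a desk-scale density stand-in chosen so RDF tails are
  sampled while generation stays fast). Each donor hydrogen holds, with
  occupancy 0.97, one molecule whose oxygen sits at N(1.82 Å, 0.06 Å)
  along the O–H direction with a small angular jitter; placements that
  would clash with the solute or another shell are retried in a widening
  cone and demoted to bulk if the site is sterically buried (so realized
  occupancy runs ~0.95). Remaining solvent is uniform outside a 3 Å
  excluded-volume radius — bulk structure (solvent–solvent correlation) is
  deliberately absent.
* **Excitations**: one bright state per snapshot,
  E = E₀ + c·d_planar(Φ)² + k·v_emb + ε with defaults E₀ = 2.90 eV,
  c = 0.12 eV/rad² on the angular distance to the nearest planar
  arrangement, k = 5 eV per a.u. of embedding potential, ε ~ N(0, 0.05 eV),
  and strengths f₀ ± 10%. The recorded descriptor v_emb is a per-neighbor
  stabilization (−0.004 a.u. per shell water, ±0.002 jitter); on request it
  is replaced by the FQ solver's actual embedding potential at the solute
  center, coupling the generator to the real embedding stage. This linear
  surrogate reproduces the two qualitative drivers of solvatochromism —
  conformation and solvation — and nothing about real electronic structure:
  passing closure tests shows the *analysis* recovers planted structure,
  not that the surrogate predicts real spectra.

All draws go through one seeded generator; identical seeds give
byte-identical trajectories.

## Problem sizes used in tests and drivers

Closure tests use 10⁴ solvent-free frames for torsion populations, 600
frames with 150 solvent molecules for shell statistics, 200-snapshot
ensembles for band assembly, and 100 seeded replicates (n = 200, σ = 0.05
eV, 300 bootstrap resamples) for parameter-recovery coverage — sizes chosen
to put sampling noise well inside the asserted tolerances.

## Known limitations

* The solute source is classical and fixed: no mutual QM/MM
  self-consistency, no response coupling, no real excitation energies —
  absolute band positions from the surrogate are not comparable to
  experiment; only structural and statistical behavior is.
* No Ewald treatment in the embedding: droplets are finite by construction.
* The background solvent is an ideal gas outside the excluded volume;
  solvent–solvent structure (second shells of the bulk) is not emulated.
* RDF normalization assumes a periodic box; droplet geometries would bias
  the shell-volume convention and are rejected for density-referenced RDFs.
* Triclinic cells and trajectory formats beyond XYZ/GRO/PDB are unsupported.
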