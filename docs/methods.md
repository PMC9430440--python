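# Methods

This note records the models implemented in `hbmap`, the numerical
conventions and defaults, what the synthetic generators do and do not
emulate, and the design choices made where several reasonable options
existed.

## Frequency map

The O–D stretch of dilute HDO is treated as a localized chromophore: each
probe's instantaneous frequency is an affine function of the electrostatic
potential at its three atoms,

    ω = ω₀ + c_D φ(r_D) + c_O φ(r_O) + c_H φ(r_H),

with φ in atomic units (e/Bohr; Bohr = 0.529177 Å, fixed in
`hbmap.frames.BOHR_ANGSTROM`) summed over the partial charges of all other
molecules within a spherical cutoff under the minimum-image convention.
Only D-labelled probes are evaluated — HDO is an isotopic label, so D is
distinguished from H by site label only, never by charge or mass.

**Truncation is by neutral group, not by atom.** A molecule contributes
all of its atoms iff its reference (first, heavy) atom lies within the
cutoff. We verified numerically that an atom-based abrupt cutoff is
pathological for ordered phases: whole coordination shells of a crystal
sit at the cutoff radius, so sub-0.1 Å displacements coherently move bare
±0.4–0.85 e monopoles across the boundary and shift φ by ~0.5 a.u.
(hundreds of cm⁻¹) — a truncation artifact. Group truncation bounds the
error at the much smaller dipole level (~r⁻²). The default cutoff is
7.8 Å with abrupt (group) truncation and no Ewald summation, standard
practice for spectroscopic maps of water. Only the probe's own molecule is
excluded from the sum.

**Coefficients are configuration data, and the shipped set is synthetic.**
`data/synthetic_od_map.csv` carries ω₀ = 2723.6 cm⁻¹ (the gas-phase O–D
fundamental of HDO) and coefficients (c_D, c_O, c_H) =
(+6500, −180, +500) cm⁻¹/a.u. These are *not* transcribed from any
published map; they were calibrated once, before the test suite was
frozen, so that (i) the sign convention is physical — an acceptor oxygen
near D lowers φ_D and red-shifts the mode, giving a monotone frequency
increase along a 2.6–3.4 Å water-dimer stretch; (ii) the ideal-ice fixture
band lands near 2430 cm⁻¹ with a ~40 cm⁻¹ width, in the region observed
for real HDO ice; and (iii) orientational disorder blue-shifts and
broadens the band. Users with a transcribed literature map can supply it
as a CSV with the same keys; every analysis accepts a map file.

## Synthetic configurations

The generators provide configurations whose relevant statistics are known
in closed form, replacing MD trajectories:

- **Ice** — a wurtzite oxygen sublattice in an orthohexagonal supercell
  (8 oxygens per cell; box edges a, √3·a, c). By default a and c follow
  the ideal ratio c/a = √(8/3) derived from the nearest-neighbour O–O
  distance (default 2.75 Å), which makes all four bonds of every oxygen
  exactly equal and the tetrahedral order parameter exactly 1 — the
  analytic crystalline limit. Hydrogens (0.9572 Å along O⋯O axes) are
  assigned by orienting an Eulerian circuit of the 4-regular bond graph,
  which enforces the Bernal–Fowler rules (two covalent H per O, one H per
  link) exactly; `ordered` uses a deterministic circuit, and
  `bernal_fowler_random` seeds the traversal. The ordered scheme is a
  reproducible valid proton assignment, not the crystallographic ice-XI
  ordering — geometry, not proton-disorder statistics, is what the
  analyses consume. Supercells whose box edge falls below 2.5× the O–O
  distance are rejected (minimum image would couple a molecule to its own
  image).
- **Random gas** — uniform single-site particles; ⟨q⟩ → 0, g(r) → 1.
- **Mixtures** — molecule counts solve the mass balance for the requested
  DMSO weight percent (molar masses 18.015/20.028/78.13 g/mol) to within
  one molecule; the heavy-water fraction of the aqueous part (default
  5 wt%) is converted to a mole fraction and realized directly as HDO
  (one D per selected water), since dilute D₂O exchanges to HDO in excess
  H₂O. Cubic box volume realizes the target density (defaults 1.0 g/cm³
  aqueous, 1.1 g/cm³ for 33 wt% DMSO at low temperature; box densities
  are not otherwise constrained and are user-overridable). Placement is
  rejection sampling with random rigid rotations and a 1.5 Å minimum
  intermolecular distance, with a bounded retry budget (default 10⁵) —
  desk-scale boxes only, no Packmol. Charges come from the bundled table:
  SPC/E water, a TIP4P-Ew-style 4-site water for the virtual-site path,
  and the Luzar–Chandler P2 united-atom DMSO model. The analysis itself is
  charge-model-agnostic; the table is data, not code.
- **Disorder** — `perturb_frame` adds i.i.d. Gaussian displacements per
  atom or per rigid molecule, plus optional rigid molecular rotations
  (`rotate_sigma`, radians). The distinction matters: symmetric positional
  noise alone *red*-shifts the mean mapped frequency (1/r is convex, so
  compressed contacts outweigh stretched ones), whereas rotational
  disorder misaligns donor bonds and produces the physical blue shift.
  The package's "liquid-like" reference fixture is therefore
  `perturb_frame(ice, 0.1, rigid=True, rotate_sigma=0.35)`.

What the generators do **not** emulate: thermal equilibrium (no energy
minimization or MD), realistic liquid pair correlations beyond uniformity,
DMSO/water nanoscale segregation, or proton-disorder statistics. Passing
tests therefore demonstrate correctness of the analysis operators and the
qualitative structure–frequency physics, not force-field-level agreement
with experiment. One visible consequence: in a rejection-packed mixture
*all* waters are disordered, so shell-resolved q separates first shell
from bulk only in constructed fixtures, whereas in an equilibrated liquid
the contrast arises physically.

## Structure analysis

- **RDF** — g(r) = ⟨n_pairs(r, r+dr)⟩ / (ρ_b 4πr² dr N_a) with
  minimum-image distances and self-pairs excluded for identical
  selections; uniform bins (default dr = 0.1 Å, r_max = half the smallest
  box edge). Pair searches switch from direct minimum-image evaluation to
  a periodic k-d tree above 500 atoms; both routes are exact and tested
  for equality. A helper locates the first RDF minimum (quadratic
  refinement through the minimum bin) for data-driven shell cutoffs.
- **Tetrahedral order parameter** — q = 1 − ⅜ Σ_{j<k} (cos ψ_jk + ⅓)²
  over the four nearest neighbour centres. Candidate centres are water
  oxygens (and single-site gas particles) by default; DMSO heavy atoms can
  be included via `include_heavy_neighbors=True` since conventions differ
  on whether cosolvent atoms count as neighbours. Ties in the 4-nearest
  selection are broken by stable sort order (deterministic).
- **Shells** — a water is `first_shell` iff the minimum-image distance
  from its D (or, without one, its first hydrogen) to any DMSO sulfur is
  ≤ 3.6 Å, the first minimum of the S–H(water) RDF; the cutoff is
  overridable. Without DMSO the label is `n/a`.
- **P(ω, r)** — values[i, j] = counts in (ω-bin i, r-bin j) / (n_frames ×
  dr): the average number of probes per frame in a shell of thickness dr.
  Summing values × dr over r reproduces the per-frame frequency histogram
  exactly (conservation is asserted at 1e-9 in tests and in the
  acceptance script). Default bins: 2 cm⁻¹ in ω, 0.1 Å in r. The S⋯D
  distance uses the nearest image; ties go to the lowest molecule id.
- **Orientational distribution** — cos θ between a donor O–H(D) bond and
  the O⋯O axis for pairs within 3.5 Å. Mode `bonded` keeps, per unordered
  pair, the best-aligned bond over both molecules (the donating
  hydrogen); `all` keeps both bonds of the ordered pair's first molecule.

## Spectral decomposition

Sum of 3–4 Gaussians A·exp(−4 ln2 (ν−ν₀)²/FWHM²) plus a polynomial
baseline (linear by default; constant/quadratic options), fitted by
trust-region least squares (lmfit) on a 2300–2700 cm⁻¹ window. Bounds:
amplitudes ≥ 0, FWHM ∈ [2, 400] cm⁻¹, centers inside the window —
physical sanity that also prevents component swapping. Default
initialization: dominant peak at the global maximum, sidebands at
±60 cm⁻¹, and (for 4 components) a broad 120 cm⁻¹ band near 2470 cm⁻¹;
up to 5 jittered restarts under a fixed seed keep the best residual, so
fits are deterministic given a seed, and exactly one solver call is made
when the caller supplies `init`. Component areas use the closed form
A·FWHM·√(π/4ln2). An optional 2330–2370 cm⁻¹ exclusion band (off by
default) removes the atmospheric CO₂ artifact region from the residual.
Temperature series are fitted coldest-first with warm starts from the
neighbouring temperature, which keeps component identity stable; a fit
failure at one temperature is recorded and the series continues. The
transition-sharpness score is the largest absolute first difference of a
tracked parameter divided by the median of the remaining differences
(≈1 for a uniform ramp, large for a step); series shorter than 5
temperatures are rejected and flat series return NaN.

## Pipeline and reproducibility

`run_pipeline` executes generate → frequencies → structure → (optional)
spectral fits from one config (YAML or `RunConfig`), writing CSV products
with provenance headers (package version, seed, config hash) and a JSON
manifest. The config hash covers the scientific configuration but not the
output directory. Every random stage derives its generator from the
config seed, so a rerun with the same config is bit-identical. In demo
boxes smaller than twice the map cutoff, the pipeline clamps the
electrostatics cutoff to half the smallest box edge (the minimum-image
limit) and logs it; library functions are strict and raise instead.

Problem sizes used by the test suite and acceptance script — ice
supercells of 96–288 molecules, 4096-particle gases, 150-molecule mixture
boxes over 3–4 frames, and 50-spectrum fitting studies — were chosen as
the smallest systems for which the analytic limits, Monte-Carlo
tolerances and recovery statistics are cleanly resolved.

## Known limitations

- No Ewald electrostatics; the map is short-ranged by construction.
- The shipped map is a calibrated synthetic stand-in (see above), so
  absolute band positions are illustrative; orderings and widths trends
  are the meaningful outputs.
- No lineshape dynamics (spectral diffusion, 2D IR) and no intramolecular
  stretch coupling — the dilute-HDO approximation throughout.
- Orthorhombic boxes only; triclinic inputs are rejected at the reader.
- The mixture builder packs randomly; it does not equilibrate.
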