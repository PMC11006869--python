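# Methods

This note documents the models behind each stage of `ndqkit`, the defaults
and why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical conventions.

## Photocycle simulation (`synthetic_data`)

The photocycle is modeled as a strictly sequential, unidirectional
first-order chain A₁ → A₂ → … → Aₙ → ground with c₁(0) = 1 and rate
constants kᵢ = 1/τᵢ. Populations come from the closed-form Bateman solution;
lifetimes closer than a relative 1e-9 are rejected there (degenerate
denominators) and handled by the matrix-exponential path (`method="expm"`),
which the tests also use as an independent oracle. Mass is conserved
(Σcᵢ + c_ground = 1) and ΔA → 0 as t → ∞ in the noise-free limit.

Each state absorbs as a Gaussian band in **wavelength** (not wavenumber —
a simplicity choice; real retinal bands are asymmetric in λ), and
ΔA(t, λ) = Σᵢ cᵢ(t)·[Sᵢ(λ) − S_g(λ)]. The default five-step scheme places
K1/K2 at 590 nm, M at 400 nm and O1/O2 at 620 nm around a 535.5 nm parent
band, with lifetimes 2 ps, 7 µs, 1 ms, 5 ms and 6 s — the picosecond K
formation, early-microsecond K1 decay, ~1 ms M transition, few-ms O rise
and seconds-scale ground-state recovery characteristic of a sodium-replete
photocycle.

Sampling uses a combined linear/log time base: `time_grid =
(linear_end, points_per_decade, start, end)`, with `points_per_decade`
evenly spaced points up to `linear_end` and the same density per decade
beyond it (one knob controls both densities). Noise is additive i.i.d. Gaussian in ΔA;
heteroscedastic and shot-noise models, instrument-response convolution and
coherent artifacts are out of scope. Whether the real O1/O2 kinetics
require a branched scheme is not established; the generator stays
sequential and branching is deferred.

All generators draw from one `numpy.random.Generator` seeded per call —
identical (config, seed) gives bit-identical output.

## Lifetime distribution analysis (`kinetics_lda`)

The inversion solves, per probe wavelength,

    min_x ‖Ax − y‖² + α²‖x‖²,   A[i,j] = exp(−tᵢ/τⱼ)

on a log-even lifetime grid. Conventions:

* **Grids.** 200 lifetimes by default; the ultrafast grid spans 0.03–5400 ps,
  the ns–s grid starts at 0.0004 ms and ends at 3× the last experimental
  time point. The α path has 200 log-spaced factors in [0.01, 5].
* **Penalty.** Written as α²‖x‖² so the quoted factors act on the amplitude
  norm scale. The regularization operator is the identity (plain ridge):
  no smoothness operator and no non-negativity constraint — the LDM color
  coding implies signed amplitudes, and both constraints are off by default
  as a documented choice.
* **α selection.** L-curve corner: maximum curvature of the parametric
  (log‖Ax−y‖, log‖x‖) curve, estimated by central finite differences with
  the endpoints excluded; ties resolve to the smaller α and a flat curve
  falls back to the median α with a warning. Note that the exponential
  kernel's singular values decay geometrically, so a noise-only input
  produces a gently bending L-curve without a sharp corner; the chosen
  solution still leaves the bulk of the noise in the residual, but the
  corner position itself is not meaningful for pure noise.
* **Implementation.** The α path is computed from one SVD of A (filter
  factors), which makes the 200-α scan cheap and exactly consistent with
  the normal-equation solution; `tikhonov_solve` solves the normal
  equations directly and is cross-checked against the path in tests.
  t ≤ 0 points (pump-probe artifact region) are dropped before inversion.
* **Peak reading.** Intermediate lifetimes are read at local maxima of
  |x(τ)| above a configurable floor (default 10% of the largest
  amplitude at that wavelength), reported with sign. Ridge inversion of
  exponentials produces small ringing side lobes; the floor suppresses
  most but not all of them, which is why peak lists on noisy data carry a
  few low-amplitude entries besides the planted lifetimes.
* **Data reduction.** `reduce_transient` implements forward averaging onto
  the combined linear/log timescale: raw points past the linear segment are
  block-averaged per log bin (mean time, mean value — the bin mean is
  preserved exactly); empty bins are skipped, never interpolated. The exact
  bin schedule of the original instrument software is not published;
  points-per-decade is exposed as a parameter.
* **Normalization.** `normalize_at_time` rescales transients to share the
  first transient's (linearly interpolated) ΔA at a reference time
  (default 0.1 ms), the convention used when comparing sodium titration
  transients.

Global-α mode aggregates the per-wavelength residual/solution norms in
quadrature and picks one corner for the whole surface; per-wavelength mode
is the default since transients at different probe wavelengths are
measured independently.

## Titration and electrophysiology fits (`titration_fits`)

* **Multi-pKa.** y(pH) = baseline + Σ_k A_k/(1 + 10^(pH − pKa_k)); each
  term contributes its full amplitude on the acid side. Initial pKa guesses
  come from an inflection scan of the smoothed |dy/dpH|; amplitudes are
  sign-free (the observed acid-induced red shift corresponds to positive
  A_k when the observable is λ_max). pKa values are reported ascending.
  Whether the original titration was fitted on λ_max, a difference
  spectrum, or absorbance at a fixed wavelength is not stated; the fit
  accepts any observable column, with λ_max as the documented default.
* **Hill.** y = y_max·cⁿ/(Kⁿ + cⁿ) with the Hill coefficient free
  (initialized at 1) — the literature value K½ ≈ 190 mM reports only K.
* **Monoexponential off-kinetics.** I(t) = A·e^(−t/t_off) + C on the
  caller-identified decay segment; non-decaying input is flagged, not
  raised.
* **I–V readout.** Ordinary least squares through the positive-voltage
  points only, evaluated at +60 mV.
* Uncertainties come from the curvature of the least-squares objective
  (lmfit standard errors). Fits are performed with lmfit/least-squares;
  recovery on noise-free fixtures is exact to ≤1e-3 relative and the
  residual RMS tracks the injected noise.
* **Beam radius.** For an isotropic 2-D Gaussian intensity profile the
  enclosed-power fraction is 1 − exp(−r²/2σ²), giving r95 = σ√(2 ln 20).

## Protonation patterns (`protonation_patterns`)

Patterns assign each residue of the ordered triad (default E64, D105, D242)
either the deprotonated state or one of four proton orientations;
enumeration covers proton counts 0…max (default 2, since triple protonation
was not considered in the source analysis), giving Σ_k C(3,k)·4^k = 61
patterns in a canonical order (by proton count, then lexicographic).
Orientations are geometric starting placements and are deliberately **not**
symmetry-deduplicated — the printed counts (1/12/48) imply none. Energy
tables must carry a consistent unit tag; mixed units are rejected. The
selection rule shortlists patterns with |E_exc − E_exp| ≤ 0.3 eV (the
estimated error of the excitation-energy method) and picks the lowest
ground-state energy, reporting all ties; an empty shortlist returns an
explicit "no consistent model" result. A helper converts λ_max to eV
(E = 1239.842/λ). The quantum chemistry itself (geometry optimization,
excitation energies) is out of scope; the module consumes its outputs.

## Structure metrics (`structure_metrics`)

Parsing is delegated to gemmi (PDB and mmCIF); alternate locations resolve
to the highest-occupancy conformer with ties preferring 'A', and author
residue numbering is preserved. Selections use `chain/residue/atoms`
patterns (`A/E64/OE1,OE2`). The Kabsch superposition (SVD with determinant
correction, so reflections are never returned) defaults to Cα atoms paired
by (chain, residue number, atom name) with waters excluded; the atom set is
configurable since published RMSD values rarely state it. The Schiff-base
nitrogen is auto-detected as the lysine NZ within 2.0 Å of retinal C15,
overridable; which atoms define published Schiff-base distances is likewise
an interpretation, documented as min over the selected oxygens to that
nitrogen. The tests validate RMSD against an independent quaternion-method
oracle to 1e-9 and check invariance under proper rigid transforms.

## Motif classification (`motif_classifier`)

Reference residue numbers are 1-based; alignment columns are 0-based
internally and 1-based in user-facing output. The anchor order follows the
conventional listing (109, 112, 116, 123, 251, 216), which spells `RNDQDK`
— ascending order would spell `RNDQKD` and contradict the motif name. The
K216 anchor is kept as conventionally listed even though the retinal
lysine of KR2 is K255; the anchor set is user-configurable for anyone
wanting a different convention. `X` and gaps never satisfy an anchor.
Duplicate removal compares exact ungapped strings case-insensitively,
keeping the first occurrence; the length filter is strictly `> 250`
residues. Pairwise identity is matches/min(ungapped lengths) on a global
alignment (CD-HIT's convention) in unaligned mode, or matched identical
non-gap columns over the shorter sequence's columns in aligned mode.
Identity clustering is greedy and deterministic: length-descending order
with id tie-break, each record joining the first representative at ≥
threshold. The neighbor-joining tree writer (scikit-bio) is plumbing — the
original phylogenetics used an external maximum-likelihood builder, which
is out of scope along with profile-HMM search and MSA construction; the
"full seven transmembrane helices" inspection step is manual and excluded.

## What the synthetic data does and does not show

The generators reproduce the statistical structure each stage assumes:
multiexponential kinetics with Gaussian bands and additive noise, ideal
Henderson–Hasselbalch and Hill responses, alignment families whose motif
columns are never corrupted, and exactly rigid-plus-jitter structure pairs.
Passing tests therefore demonstrate correctness of the algorithms and
their parameter-recovery power under the stated noise models — not
robustness to baseline drift, spectral overlap beyond Gaussian bands,
branched photocycles, alignment errors, or real coordinate uncertainty.
Database-scale sequence counts, quantum-chemical energies, reconstructions
and electrophysiological recordings are inherently not reproducible at
desk scale and are covered only by the bookkeeping and selection logic
around them.

## Problem sizes

Defaults were chosen so every analysis runs in seconds on one core: 200
lifetimes × 200 α per wavelength via one SVD per wavelength; Monte-Carlo
checks use 20–100 seeded replicates; the packaged family has 60 sequences
of 280 residues. All sizes scale up by argument without code changes.
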