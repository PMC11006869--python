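# ndqkit

Analysis toolkit for **NDQ rhodopsins** — the light-driven sodium pumps
recognized by the Asn–Asp–Gln motif on helix C. The package implements, as a
tested and reusable pipeline, the computational stages used to characterize
a member of the recently delineated second subgroup of these pumps (the one
carrying an extra glutamate counterion next to the retinal Schiff base):

* **`motif_classifier`** — reference-anchored motif extraction from a
  multiple sequence alignment (residues aligned to KR2 positions
  109/112/116/123/251/216 spell `RNDQDK` in true sodium pumps), strict
  `>250`-residue and duplicate filtering, greedy CD-HIT-style 90%-identity
  reduction, and Subgroup 1/2 assignment by the residue aligned to KR2 L74
  (Leu/Ile → Subgroup 1, Glu → Subgroup 2), plus a neighbor-joining Newick
  writer.
* **`kinetics_lda`** — model-free lifetime distribution analysis of
  ΔA(t, λ) surfaces: the discretized inverse Laplace transform

  `min_x ‖Ax − y‖² + α²‖x‖²,  A[i,j] = exp(−t_i/τ_j)`

  on a 200-point log-even lifetime grid, with α scanned over 200 log-spaced
  factors in [0.01, 5] and chosen by the L-curve corner (maximum curvature
  of log‖Ax−y‖ vs log‖x‖). Signed amplitudes over all probe wavelengths
  form the lifetime distribution map (LDM); peak lifetimes are read at the
  distribution maxima.
* **`titration_fits`** — multi-pKa Henderson–Hasselbalch fits
  `y(pH) = y₀ + Σ_k A_k/(1 + 10^(pH−pKa_k))`, Hill fits
  `y = y_max·cⁿ/(Kⁿ + cⁿ)` for the sodium dependence of the O state,
  monoexponential photocurrent off-kinetics, the +60 mV linear I–V readout,
  spectrum utilities (sub-grid λ_max, A₂₈₀ normalization) and the Gaussian
  beam 95%-power radius `r95 = σ√(2 ln 20)`.
* **`protonation_patterns`** — enumeration of the protonation microstates
  of the counterion triad (E64, D105, D242; four proton orientations each,
  up to two protons ⇒ 61 patterns: 1 + 12 + 48) and the selection rule
  applied to a quantum-chemistry energy table: shortlist patterns whose
  vertical excitation energy is within the method error (0.3 eV) of the
  measured value, then take the lowest ground-state energy.
* **`structure_metrics`** — PDB/mmCIF loading (via gemmi), atom selections,
  minimum contact distances (e.g. the ~2.1 Å E64–D105 carboxyl-oxygen
  contact diagnostic of a low-barrier hydrogen bond), Kabsch RMSD with
  proper-rotation enforcement, and modeled-residue ranges.
* **`synthetic_data`** — seeded generators for every stage: sequential
  first-order photocycle surfaces (Bateman/matrix-exponential chain with
  Gaussian difference bands on a combined linear/log time base), titration
  and Hill curves, aligned sequence families with planted motifs and
  subgroup letters, and rigid-body-perturbed toy structures. Every stage of
  the pipeline therefore runs offline.

The `analysis/` directory holds numbered narrative drivers
(`01_simulate_photocycle.py` … `06_structure_metrics.py`) that run the
stages end to end and write their tables under `results/`.

## Worked example

Simulate a sodium-replete photocycle, invert it, and read the intermediate
lifetimes:

```bash
python analysis/01_simulate_photocycle.py
python analysis/02_lifetime_maps.py
```

which prints (abridged):

```
ta_noisy: 213 time points x 38 wavelengths, noise sigma 0.002 -> results/ta_noisy.csv
scheme lifetimes (s): K1=2e-12, K2=7e-06, M=0.001, O1=0.005, O2=6
peaks at 400 nm: ... 0.001 s (+0.092) ...
peaks at 620 nm: ... 7.26e-06 s (+0.074), ... 0.00428 s (+0.022), ... 5.46 s (+0.088) ...
planted lifetimes: 2e-12, 7e-06, 0.001, 0.005, 6 s
lifetime grid: 4e-07-90 s, 200 points
```

The blue-shifted M band at 400 nm peaks at the planted 1 ms M decay; the
red-shifted O band at 620 nm shows the 7 µs K1 decay, the O rise near 4–5 ms
and the seconds-scale ground-state recovery — each within one grid step of
the planted lifetime (smaller ringing lobes are the usual side effect of
ridge-regularized exponential inversion). Titration and Hill fits recover
their generator parameters the same way:

```bash
python analysis/04_titration_and_hill.py
# pKa fit: 3.35 +/- 0.01, 5.70 +/- 0.02 (baseline 535.5 nm, residual rms 0.041)
# Hill fit: K_half = 217 +/- 32 mM, n = 0.97
```

The same operations are exposed on the command line, e.g.

```bash
ndqkit patterns --out patterns.csv
# 61 patterns (1 with 0 proton(s), 12 with 1 proton(s), 48 with 2 proton(s)) -> patterns.csv
ndqkit classify --msa family.fasta --ref REF --out report.tsv
ndqkit lda --input ta.csv --out ldm.csv
```

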