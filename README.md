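# thermoshift

Rational thermo-stabilization of membrane proteins by mutations in the
extramembrane regions, as a reusable analysis pipeline.  The package targets
structural biologists and protein engineers who (a) rank candidate single
mutations by predicted folding free-energy differences (ΔΔG), (b) screen the
designs against MD snapshot ensembles, and (c) quantify the experimental
outcome with UV-visible decoloration kinetics and differential scanning
calorimetry (DSC).  The worked system is thermophilic rhodopsin (TR), a
seven-transmembrane retinal proton pump whose crystal model (PDB 5AZD,
chain A, residues 3–253) serves as the reference fold; the published
candidate tables and characterization measurements ship with the package as
inputs (`thermoshift.datasets`).

## What it computes

**Design.** From residue annotations (exposure, membrane region, helix-cap
position, ion pairing) and ΔΔG tables, the selection rules reduce 28
exposed extramembrane residues to 20 scored candidates and then a final set
of 10, greedily by the refined ΔΔG under per-site uniqueness, a
structural-change veto, and N-/C-side balance.

**Ensemble statistics.**  For Cα coordinate sets x, y the optimal
superposition minimizes

    rmsd = min over R, t of sqrt( (1/N) Σ_i | R x_i + t − y_i |² ),

solved by the Kabsch/SVD construction with det(R) = +1.  On top of it:

- *native-state score*: mean r.m.s.d. of 51 snapshots (every 200 ps,
  90–100 ns, endpoints inclusive) versus the crystal, averaged per run,
  mean ± s.e.m. over 3–4 independent runs;
- *random-coil fluctuation*: in a 20-member denatured ensemble, the medoid
  (smallest mean pairwise r.m.s.d.) is the representative and its 19
  r.m.s.d. values form the fluctuation group — an entropy proxy for the
  denatured state;
- per-residue Cα deviation profiles after a single global fit, ion-pair
  occupancy (fraction of frames with pair distance ≤ 5 Å), and the radius
  of gyration R_g = sqrt( Σ m_i |r_i − r_com|² / Σ m_i ) in nm.

**Stability metrics.**  Residual pigment 100·A_after/A_before at 530 nm;
single-exponential decoloration P(t) = P₀ e^(−kt) with τ½ = ln 2 / k; the
DSC chain buffer subtraction → molar normalization → baseline subtraction,
with the apparent T_m at the peak top; and the stabilization rule
ΔT_m ≥ 1 °C versus the wild type.

**Statistics.**  Two-group comparisons run a Kolmogorov–Smirnov normality
screen (Lilliefors-corrected), a two-sided F-test on variances, then
Student's t (equal variances) or Welch's t (unequal), two-tailed — also
available directly on printed mean ± s.e.m. summaries.  On the published
T_m table this reproduces the printed p-values, including the Welch branch
for T114D.

A synthetic-data module generates every input at desk scale (idealized
helical-bundle reference, native and denatured ensembles, decays,
thermograms, distance traces) with per-construct presets carrying the
published parameters; see `docs/methods.md` for what the generators do and
do not emulate.

## Worked example

```python
import numpy as np
import thermoshift as ts

toy = ts.gen_toy_structure()            # synthetic crystal stand-in, 251 Calpha
crystal = ts.select_calpha(toy)
preset = ts.CONSTRUCT_PRESETS["T114D"]  # published per-construct parameters

# native-state ensemble score vs the crystal (3 runs x 51 frames)
runs = ts.gen_native_runs(toy, preset.native_sigma, n_runs=3, seed=5,
                          run_scale_sd=0.05)
score = ts.native_state_score(runs, crystal, (90, 100), 0.2)

# random-coil medoid fluctuation, destabilized mutant vs wild type
ens = {lab: ts.gen_coil_ensemble(toy, ts.CONSTRUCT_PRESETS[lab].coil_scale,
                                 20, seed=s)
       for s, lab in enumerate(["WT", "S8D"])}
medoids, comps = ts.coil_fluctuation_compare(ens, "WT")

# experimental read-outs
fit = ts.fit_decoloration(ts.gen_decoloration(preset.k, np.arange(11.0),
                                              noise_sd=0.5, seed=2))
sample, buffer = ts.gen_dsc(preset.tm, grid=0.01, seed=2)
tm = ts.extract_tm(ts.process_dsc(sample, buffer, molar_conc=1.5e-5))
```

Output (formatted):

```
native-state r.m.s.d.  1.49 +/- 0.04 A  (n = 3 runs)
coil fluctuation WT    19.5 +/- 0.4 A
coil fluctuation S8D   21.6 +/- 0.4 A  p = 0.0007 (student)
decoloration  k = 0.068 min^-1   tau_1/2 = 10.1 min
DSC  Tm = 95.93 C   (wild type 91.78 C -> delta Tm = +4.15 C -> stabilized)
```

Reading it: the T114D native ensemble sits ~1.5 Å from the crystal (a real,
mutation-induced structural shift at this preset); the S8D denatured
ensemble fluctuates significantly more than the wild type's (higher
denatured-state entropy, hence destabilizing); the fitted decoloration rate
0.068 min⁻¹ and the recovered T_m of 95.93 °C match the generator presets,
and the +4.15 °C shift clears the ≥ 1 °C stabilization rule.

A thin CLI mirrors the library (`thermoshift design | native | coil |
ionpair | gyrate | decay | dsc | classify | compare-summary | simulate`);
run `thermoshift --help`.

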