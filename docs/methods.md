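# Methods

`thermoshift` re-implements, as a tested desk-scale pipeline, the analysis
used to engineer thermo-stabilizing mutations in the extramembrane regions
of thermophilic rhodopsin (TR, PDB 5AZD): ΔΔG-based candidate selection,
structural statistics over MD snapshot ensembles, wet-lab stability
metrics, and the branching significance protocol that ties them together.
The cluster-scale inputs (100 ns membrane-embedded MD trajectories, UV-vis
kinetics, DSC scans) are replaced by synthetic generators that reproduce
the statistical structure the analysis assumes, with per-construct presets
carrying the published measurement values.

## Candidate design

Twenty-eight solvent-exposed extramembrane residues feed a predicted
folding free-energy scan (ΔΔG per substitution, kcal/mol, negative =
stabilizing).  The module encodes the selection *rules*, not the geometry:

- **Exposure filter.** A residue qualifies when annotated extramembrane
  with relative solvent exposure ≥ 0.3 (configurable).  Exposure and the
  restricted-dihedral flag are caller-supplied annotations (from a SASA
  program and a Ramachandran check); the original selection was manual, so
  re-deriving them internally would add an algorithm the analysis never
  defined.
- **Exclusion rules.** Restricted main-chain dihedral position; Pro or
  Asp/Glu at a helix N-cap; Lys/Arg/His at a helix C-cap (helix-dipole
  logic: negative charge stabilizes the N-terminus, positive the
  C-terminus, and the capping residue itself must not pre-empt that);
  ion-pair participation; predicted burial in the native-state MD.
- **Ranking.** Candidates sort ascending by position-scan ΔΔG (most
  stabilizing first), deterministic (site, substitution) tie-break.
- **Final selection.** Greedy by the refined build-model ΔΔG, one
  substitution per site, veto on predicted substantial structural change,
  optional bound on the N-side/C-side count imbalance, and a preference for
  unrepresented effect tags on exact score ties.  The published "variety of
  effects and side balance" criterion is qualitative; the bound and the tie
  preference make it explicit and reproducible.

## Ensemble statistics

All superpositions are least-squares optimal rigid-body fits (Kabsch/SVD
with determinant correction, so reflections are never produced) on matched
Cα selections; collinear point sets are flagged degenerate (RMSD still
valid, rotation not unique).  Deviations per residue are measured after a
single global fit — no per-residue refit — so local changes are read in the
frame of the overall fold.

- **Native-state score.** Snapshots sampled every 200 ps over the
  90–100 ns window (51 frames; endpoints inclusive, nearest-frame matching
  with tolerance interval/2) are each fitted to the crystal Cα trace; the
  51 RMSDs average within a run and the 3–4 run averages reduce to
  mean ± s.e.m.  Small values mean the design preserved the native fold.
- **Medoid fluctuation statistic.** For a 20-member denatured-state
  ensemble, all 190 pairwise RMSDs are computed exhaustively; the member
  with the smallest mean RMSD to the rest is the representative (ties break
  to the lowest index), and its 19 RMSDs form the fluctuation group — a
  proxy for denatured-state conformational entropy.  Mutant groups compare
  to the wild type's through the statistical protocol below.
- **Per-residue deviations.** Residue-wise mean Cα deviation per run;
  construct-vs-construct comparison is a per-residue two-tailed Student's t
  across runs at α = 0.05, flagging residues with significantly *larger*
  deviation.  No multiple-testing correction by default (matching the
  reported raw per-residue significance); a Bonferroni option exists.
- **Ion-pair occupancy.** Per-frame atom-pair distance (e.g. Glu6 Cδ –
  Lys79 Nζ); a frame satisfies when distance ≤ cutoff (boundary inclusive,
  default 5 Å).  Occupancy is kept unrounded until reporting, so
  460/501 → 91.82 %, printed as 92 %.
- **Radius of gyration.** Mass-weighted by default about the selection's
  centre of mass, reported in nm (coordinates are Å internally; nm only at
  this reporting boundary).  Exactly homogeneous: scaling coordinates by c
  about the COM scales Rg by c.

## Stability metrics

- **Residual pigment** is the 530 nm absorbance after a 90 °C incubation
  divided by the pre-incubation absorbance, in percent.
- **Decoloration kinetics** fit P(t) = P₀·e^(−kt) by nonlinear least
  squares (both parameters free, k ≥ 0), initialized from a log-linear
  regression; τ½ = ln 2 / k.  No floor term — the pigment decays to zero —
  though a plateau variant is available off by default.  On noiseless
  generator data the fit recovers k to relative error < 1e−4 across
  k ∈ [0.01, 1] min⁻¹.  Internal consistency: 4 minutes at the wild-type
  rate 0.21 min⁻¹ predicts 100·e^(−0.84) = 43.2 %, within one s.e.m. of the
  measured wild-type residual pigment 44.5 ± 3.2 %.
- **DSC processing** follows the instrument-software chain: buffer scan
  interpolated onto the sample grid and subtracted → division by molar
  protein concentration → subtraction of a baseline fitted on the pre- and
  post-transition windows (defaults: first and last 10 °C of the scan;
  linear by default, cubic optional).  A warning fires if the apparent peak
  lies inside a baseline window.  **Tm** is the temperature of the on-grid
  global maximum — "peak top" taken literally, no sub-grid interpolation —
  so the synthetic grid must be ≤ 0.01 °C for two-decimal targets.  No
  scan-rate or irreversibility correction is applied: the transition is
  kinetically controlled and the values are apparent Tm.
- **Stabilization rule.** A mutant is stabilized iff Tm − Tm(WT) ≥ 1 °C
  (boundary inclusive); constructs without a measured Tm are `unmeasured`.
  On the published characterization table this labels exactly V79K, T114D,
  A115P and A116E.

## Statistical protocol

Each comparison runs: (1) a Kolmogorov–Smirnov normality screen per group —
Lilliefors-corrected critical values by default, because the reference
normal's parameters are estimated from the sample and the naive asymptotic
test is anti-conservative (the naive variant remains available); (2) a
two-sided F-test on the variance ratio, p = 2·min(P(F≤f), P(F≥f)); (3)
Student's t (pooled) when variances test equal, Welch's t
(Welch–Satterthwaite df) otherwise, two-tailed.  A normality failure is a
recorded flag, not a hard stop.  A summary-statistics route reconstructs
sd = sem·√n from printed tables and applies the same F/t branch with the
normality screen marked untested; on the published Tm table it reproduces
the printed p-values (0.0014, 0.0060, 0.0017, 0.0029) including the Welch
branch for T114D, whose replicate spread is an order of magnitude tighter
than the wild type's.

**Calibration and a known caveat.** On iid normal groups the protocol's
type-I error is 5 % within Monte-Carlo error at n ∈ {3, 19} (verified over
2000 null replicates per n).  The medoid fluctuation comparison is the
exception: the 19 RMSDs of a group share the estimated representative
structure, are therefore positively correlated, and simulation shows the
nominal-5 % comparison rejects ~10–15 % of null replicates.  This is a
property of the procedure as defined (the group is treated as independent
when it is not), reproduced deliberately; its p-values should be read as
anti-conservative.

## Synthetic generators

The generators claim no physical realism — no force field, membrane, or
temperature semantics — only the statistical contracts the analysis needs,
each bitwise-reproducible under a fixed seed:

- **Reference structure.** An idealized Cα helical bundle, 251 residues
  numbered 3–253 in 7 antiparallel ideal helices (exact 3.8 Å consecutive
  spacing) on a 14.5 Å circle joined by equal-chord arc connectors.  It is
  a synthetic stand-in for the crystal model, with dimensions set from
  seven-helix-bundle geometry so its gyration radius (≈ 2.08 nm computed)
  sits at the real fold's ≈ 2.0 nm.
- **Native-state runs.** Per-run rigid offset (removed by superposition,
  present so fits are exercised) plus per-frame isotropic Gaussian Cα noise
  of scale σ and optional slow AR(1) drift.  Preset σ per construct is the
  published native-state RMSD divided by √3, since the expected post-fit
  RMSD of isotropic noise is ≈ √3·σ.  A run-level scale jitter emulates
  between-run spread.
- **Coil ensembles.** Mean-reverting cumulative backbone displacement: a
  chain-local Ornstein–Uhlenbeck field with 10-residue correlation length
  and stationary per-coordinate scale `coil_scale`.  Expected pairwise RMSD
  is linear in the scale (monotonicity contract) and the member-to-member
  spread lands at the ~10 % relative level seen in the published ensemble
  summaries; a plain unreverted walk was rejected because it concentrates
  variance in the lowest chain mode, roughly doubling that spread and
  destroying the power of the wild-type-vs-mutant comparison at the 1.15×
  scale contrast the analysis must resolve.  Presets: wild type 9 Å
  (placing the medoid statistic in the ~20 Å regime of a denatured
  251-residue chain via E[pair RMSD] ≈ √6·scale), S8D 1.15× the wild type,
  all other constructs equal to the wild type — encoding the published
  qualitative ordering only, with no claim on absolute values.
- **Decoloration / DSC / distance traces.** P(t) = 100·e^(−kt) plus
  Gaussian noise clipped at zero; thermograms as a shared curved buffer
  profile plus linear baseline plus Gaussian endotherm (sd = `width`) on a
  0.01 °C grid; ion-pair traces with an exact count of satisfying frames,
  uniform in [2.5 Å, cutoff] and (cutoff, 12 Å].

What passing tests show — and do not.  Green tests demonstrate that the
rules, estimators and protocol are implemented correctly and recover
generator parameters under the stated noise; they say nothing about
force-field accuracy, real denatured-state physics, instrument artefacts,
or whether the design rules generalize beyond this protein.

## Problem sizes and numerical choices

The default suite runs ensembles of 3 runs × 51 frames × 251 Cα (native),
20 × 251 Cα (coil), 10⁴-replicate Monte-Carlo oracles, 2000-replicate null
calibrations and 50–100-seed power sweeps — sizes chosen so the statistics
are resolvable while the whole suite completes in well under a minute of
CPU for the unit tests and a few minutes including the property sweeps.
Tolerances: superposition oracle agreement 1e−3 Å against a hierarchical
Euler-grid search (0.5° refined to 0.05°) and 1e−9 Å against an independent
rotation-fitting route; frame matching interval/2; Tm equality to the grid
step.  Ties: medoid and ranking tie-breaks are deterministic (lowest index;
lexicographic).  Degenerate inputs (constant groups, zero variance, flat
thermograms, empty selections) raise typed errors rather than propagate
NaNs, except where the comparison has a well-defined limit (identical
constant groups ⇒ p = 1).

## Limitations

ΔΔG values are consumed, never computed; no SASA, secondary-structure
assignment, or side-chain modelling; no mmCIF or binary trajectory formats;
no calorimetric enthalpy integration; no multiple-testing correction across
constructs (matching the source protocol); the medoid-group p-values are
anti-conservative as discussed above.
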