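# Methods

## The model

`cpmgdisp` analyses methyl single-quantum ¹³C CPMG relaxation-dispersion
data under a two-site chemical-exchange model. A methyl ¹³C spin exchanges
between a ground state A and a sparsely populated excited state B,

    A  ⇄  B,   k_ex = k_AB + k_BA,   p_B = k_AB / k_ex,

and its transverse magnetization evolves under the Bloch–McConnell matrix
(ground-state rotating frame, shift difference Δω in rad s⁻¹, the same
exchange-free rate R₂,₀ in both states):

    L = [ −R₂,₀ − k_AB        k_BA          ]
        [   k_AB        −R₂,₀ − k_BA − iΔω ]

A constant-time CPMG experiment applies n 180° refocusing pulses during a
fixed relaxation period T_relax, with ν_CPMG = 1/(2t) and t the inter-pulse
delay; each pulse acts as complex conjugation of the transverse
magnetization. The observable is

    R₂,eff(ν) = −(1/T_relax) ln( |M_A(T_relax)| / |M_A(0)| ),

with the magnetization starting at exchange equilibrium, M(0) = (p_A, p_B).
Varying ν modulates how much of the exchange broadening is refocused,
producing the dispersion profile whose amplitude R_ex is read as the
displacement between low and high ν.

### Numerical propagation

Because R₂,₀ enters L as a multiple of the identity, it separates additively
from the exchange contribution; all propagation is done with R₂,₀ = 0 and
the baseline added afterwards. This also lets the fits profile R₂,₀ out
analytically (see below). Two consecutive echo units (t/2 – 180° – t/2),
with conjugation at each pulse, compose into the *linear* map
U = P·conj(P)·conj(P)·P, where P = exp(K·t/2) is computed from the closed
2×2 eigendecomposition; the even-pulse train is then the matrix power
U^(n/2), evaluated from the eigenvalues of U. The echo count n is rounded to
the nearest even integer ≥ 2, and ν values implying fewer than two pulses
are rejected.

Two independent checks guard this path:

* a brute-force echo-by-echo propagation using `scipy.linalg.expm` (test
  oracle, a deliberately different code path), and
* an exact closed-form solution of the even-pulse train
  (`carver_richards_r2eff`), which evaluates the same echo-pair eigenvalue
  problem in scalar form keeping **both** eigenmodes and the equilibrium
  initial condition. The classic Carver–Richards (CR72) dominant-eigenvalue
  expression is available via `approx=True`; it deviates from the true
  solution by several s⁻¹ at high p_B with large Δω (e.g. ~5 s⁻¹ at
  k_ex = 1600 s⁻¹, p_B = 0.15, Δω = 2 ppm at 18.8 T), which is why the
  exact form is the default cross-check.

A useful analytic anchor is the fast-exchange limit
R_ex → p_A·p_B·Δω²/k_ex (valid for k_ex ≫ Δω), used in property tests at
the 5% level.

**Monotonicity caveat.** R₂,eff(ν) is non-increasing in ν throughout the
intermediate-to-fast regime (verified exactly for k_ex ≥ Δω in rad s⁻¹),
but in slow exchange with large Δω the profile genuinely oscillates by up
to ~1 s⁻¹ between adjacent ν values — a coherence effect of the echo
train, reproduced identically by the independent step-wise oracle. Tests
assert monotonicity only where it holds.

## From intensities to profiles

Constant-time intensities convert as R₂,eff(ν) = −(1/T_relax) ln(I(ν)/I_ref).
Negative rates (I > I_ref) are allowed but flagged. Measurement errors are
estimated from duplicate measurements collected at the reference experiment
and at ν = 200 and 6000 s⁻¹: for a duplicate pair, x₁ − x₂ ~ N(0, 2σ²), so
σ² is the pooled mean of d²/2 per static field, applied uniformly to all
points of that field (duplicates exist at only three schedule positions, so
a per-point estimate is not meaningful) and floored at 0.1 s⁻¹. Duplicated
points enter the profile as the average of their pair.

The dispersion screen computes R_ex as the mean of the two lowest-ν
R₂,eff values minus the mean of the two highest-ν values (two-point means
damp single-point noise; the estimator is a package choice) and passes a
residue when any of its methyls exceeds 5 s⁻¹ at the highest field, where
Δω in rad s⁻¹ — and hence the dispersion amplitude — is largest.

## Fitting

`MethylExchangeModel.fit()` performs weighted least squares over
{k_ex, p_B, |Δω| (ppm), R₂,₀ per field} for one methyl, with both fields
fitted jointly (a single exchange process; Δω in ppm is field-independent).
Numerical choices:

* search variables (log₁₀ k_ex, p_B, dw_ppm) with bounds
  k_ex ∈ [10, 2×10⁴] s⁻¹, p_B ∈ (10⁻⁴, 0.5), |Δω| ∈ (0, 6] ppm,
  R₂,₀ ∈ (0, 200] s⁻¹ — physical ranges for methyl ¹³C;
* the baselines R₂,₀ are linear in the model and are profiled out
  analytically at each step (variable projection), halving the nonlinear
  dimension;
* multi-start initialisation on the grid k_ex ∈ {200, 600, 1600, 4000} s⁻¹
  × p_B ∈ {0.01, 0.05, 0.15} × |Δω| ∈ {0.3, 1, 2} ppm; all starts are
  scored by initial χ² and the best four refined with bounded
  trust-region least squares (`scipy.optimize.least_squares`);
* only |Δω| is fitted — the sign is not identifiable from single-quantum
  CPMG data.

A flat (no-exchange) model fits one constant per field. The exchange model
is kept only if an F-test on the χ² reduction is significant at α = 0.01
**and** the observed R_ex exceeds the screening threshold; otherwise the
profile is reported flat. The exchange model can always shadow a flat
profile at a parameter bound, hence the explicit selection step.

### Clustering and global fits

Converged exchange fits are grouped on log₁₀ k_ex by 1-D single linkage
with a gap cutoff of 0.25 (a factor ≈ 1.8 in rate); each candidate group
with ≥ 2 members is refitted jointly with shared (k_ex, p_B) and per-member
{|Δω|, R₂,₀ per field}. After each joint fit, every member's reduced χ²
under the shared parameters (dof = its points − its 3 member-specific
parameters) is compared with its individually fitted reduced χ²
(dof = points − 5); membership requires

    χ²_cluster / χ²_individual < 2   (strict).

The worst violator is ejected and the fit repeated until stable — one per
round, because a single discordant member can drag the shared parameters
enough to make well-behaved members look discordant. The total objective
decreases across ejection rounds by construction. A rescue pass then offers
each unclustered exchange methyl to every fitted cluster (optimising only
its own |Δω| and baselines under the cluster's shared parameters); if more
than one cluster accepts it, it joins the one giving the lower member χ²,
and the winning cluster is refitted.

Prochiral Leu/Val methyls (a/b, not stereospecifically assigned) are fitted
as separate profiles but may join the same cluster. Note that a residue
whose two prochiral methyls share a process distinct from every other
cluster (the planted "off-cluster" residue L106) can appear as a two-methyl,
one-residue cluster; at residue level this is equivalent to reporting it
unclustered.

### Monte Carlo uncertainties

Parameter errors are estimated by parametric bootstrap: n_reps (default
100) synthetic datasets are drawn as best-fit curve + Gaussian noise at the
per-point σ, refitted starting from the converged solution (cluster
memberships held fixed for cluster fits), and the parameter standard
deviation over converged replicates reported. Runs are deterministic under
the seed; a warning is attached if more than 20% of replicates fail.

## The synthetic-data generator

The generator emulates the acquisition design of a two-field ILV-methyl
CPMG study of the NF-κB p50 RHR homodimer: fields 11.7 T and 18.8 T
(¹³C 125.7 / 201.2 MHz, from the 500/800 MHz ¹H frequencies via
γ_C/γ_H ≈ 0.2515), T_relax = 20 ms, 18 ν values (multiples of 50 s⁻¹,
roughly log-spaced over 100–6000 s⁻¹, so every ν holds an even pulse
count), duplicates at the reference and at ν = 200 and 6000 s⁻¹, and
Gaussian noise of σ = 0.3 s⁻¹ (consistent with tight experimental error
bars; configurable). The exact experimental ν grid is not public; the
chosen grid is recorded in every run summary. The plotted-axis convention
is taken as ν_CPMG = 1/(2t); if the experimental axis were 1/τ_CP = 2ν the
schedule constants would simply rescale by two without affecting any
recovery result.

Preset parameter sets encode the published cluster values — dbd_300K
(1640 s⁻¹ / 4.2% and 420 s⁻¹ / 14.6%; 18 dispersing residues), rhr_300K
(1600 s⁻¹ / 5.1% and 660 s⁻¹ / 14%; 19 residues), dbd_290K (480 s⁻¹ /
2.9%), and rhr_mhc_h2_bound (single field, loop-proximal dispersion
quenched, I104/V233 persistent). The full residue-level membership lists
are not published, so membership tables here are plausible ILV inventories
built around the residues the study names (L67, L97, L106, I139, V147,
V210, L212, I237, I104, V233); they are a modelling choice, not reported
fact. Per-methyl |Δω| is drawn uniformly from [0.4, 1.6] ppm, redrawn until
the noiseless R_ex at 18.8 T exceeds 8 s⁻¹ so that planted "dispersing"
ground truth sits safely above the 5 s⁻¹ screen; non-dispersing methyls are
generated with p_B = 0 exactly, making the flat/exchange ground truth
unambiguous. R₂,₀ is drawn per field from ranges increasing with field and
molecular size.

What the generator does **not** emulate: peak overlap and lineshapes,
intensity-dependent noise, B₁ inhomogeneity, off-resonance effects,
temperature drift, or any deviation from ideal two-site exchange. Passing
tests therefore demonstrate the estimator's correctness and calibration
under the stated noise model, not robustness to every artefact of real
spectra.

Peak-list scenarios place assigned methyl cross peaks on a jittered lattice
(spacing 0.13 ppm ¹H / 0.75 ppm ¹³C per residue type) so nearest neighbours
sit outside the matching tolerance, then apply per-residue bound-state
offsets: single-conformer complexes (MHC_H2, MHC_H2_M1) shift peaks
without splitting; two-conformer complexes (kB_proto, H2_kB, MHC_H2_M2)
split a planted residue set into two components with unequal intensities
(V209 comparable, V112 planted 0.7/0.3), and the M2 components coincide
with the MHC_H2 and M1 positions — the two-orientation binding signature.

## Peak-list analytics

Assignment transfer matches each bound peak to the free-state assignment
minimising the scaled elliptical distance d = √((ΔδH/tol_H)² + (ΔδC/tol_C)²),
accepting d ≤ 1, greedily in order of increasing d; bound peaks are
consumed once but an assignment may acquire several (a split). Defaults
tol_H = 0.05, tol_C = 0.3 ppm — typical methyl linewidths; the combined CSP
uses the conventional ¹³C weight of 0.25. Split-component intensity ratios
estimate conformer populations only under the assumption of equal
relaxation, and are flagged as such. A complex is classified
"multiple_conformations" when ≥ 2 assignments split.

## Problem sizes and defaults

Acceptance-level runs use the full presets (30–31 residues, ~50 methyls,
two fields × 18 points each, n_reps = 100 Monte Carlo replicates); a full
preset pipeline takes a few minutes on one CPU, dominated by the cluster
Monte Carlo. Unit tests use a compact 6-residue spec or reduced n_reps
where the contract under test does not depend on the replicate count.

## CLI

Subcommands: `simulate` (datasets or peak-list scenarios), `fit` (the
dispersion pipeline: screen → fits → clustering → Monte Carlo → TSV report
+ reproducible run summary; clustering and reporting are stages of this one
command rather than separate subcommands), and `peaks compare`. Exit codes:
0 success, 2 validation error, 3 numerical failure. Every run summary
records the seed, schedule, thresholds and σ estimates needed to reproduce
it.

## Known limitations

* Two-site exchange only; no three-site or multi-quantum models, no R₁ρ.
* One shared R₂,₀ per field for both exchange states (standard
  identifiability constraint for CPMG data).
* The 290 K vs 300 K comparison is treated as independent datasets; no
  van 't Hoff/Eyring linking.
* Cluster-membership recovery is exact under the generator's conditions but
  inherently statistical: at much higher noise or smaller |Δω| members can
  be misassigned.
* Conformer populations from intensities ignore differential relaxation.
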