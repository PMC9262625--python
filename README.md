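# cpmgdisp

Analysis of methyl single-quantum ¹³C CPMG relaxation-dispersion data under
two-site chemical exchange, built for studies of sparsely populated protein
conformational states — the motivating system is the NF-κB p50 Rel-homology
-region homodimer, whose DNA-binding domain interconverts on the
millisecond timescale between its ground state and low-populated excited
states, and whose motions are damped by κB DNA binding.

A methyl ¹³C spin exchanging between a ground state A and an excited state
B (rate constant k_ex = k_AB + k_BA, excited-state population
p_B = k_AB/k_ex, shift difference Δω) evolves under the Bloch–McConnell
equations; a constant-time CPMG pulse train of refocusing frequency ν_CPMG
partially quenches the exchange broadening, and the measured dispersion
profile R₂,eff(ν_CPMG) encodes (k_ex, p_B, |Δω|). The package provides:

* **Forward models** — numerical Bloch–McConnell propagation of the echo
  train, an exact closed-form solution used as a cross-check, the classic
  Carver–Richards (CR72) approximation, and the fast-exchange limit
  R_ex = p_A·p_B·Δω²/k_ex.
* **Data handling** — R₂,eff from constant-time peak intensities,
  duplicate-based pooled error estimation, R_ex > 5 s⁻¹ dispersion
  screening, TSV table formats.
* **Fitting** — statsmodels-style model objects: `MethylExchangeModel`
  fits one methyl jointly over both static fields;
  `ClusterExchangeModel` fits a group of methyls with shared (k_ex, p_B)
  and per-methyl |Δω|, enforcing the χ²_cluster/χ²_individual < 2
  membership rule with iterative ejection; both `.fit()` return Results
  objects with Monte Carlo parameter uncertainties, `summary()` and
  `plot()`.
* **Synthetic data** — presets encoding the published exchange parameters
  of the study system (e.g. k_ex = 1640 s⁻¹, p_B = 4.2% for the main
  cluster of the isolated DNA-binding domain), with exact ground truth for
  every pipeline stage.
* **Peak-list analytics** — assignment transfer by elliptical proximity,
  combined ¹H/¹³C chemical-shift perturbations, split-peak detection and
  single- vs multiple-conformation classification of protein–DNA
  complexes.

## Worked example

Simulate the isolated DNA-binding domain dataset at 300 K and run the full
pipeline (screen → per-methyl fits → clustering → global fits → Monte
Carlo):

```
cpmgdisp fit --preset dbd_300K --seed 1 --n-reps 100 --out run/
```

prints (abridged):

```
sigma_11.7T_s = 0.267144
sigma_18.8T_s = 0.291623
screened_residues (18) = 44,67,91,97,106,118,124,134,139,147,156,170,181,196,210,212,224,237
exchange_methyls = 30
cluster_0: n_methyls = 23, n_residues = 14, k_ex = 1638.9 +/- 10.2 s^-1, p_B = 0.0423 +/- 0.0003
cluster_1: n_methyls = 5, n_residues = 3, k_ex = 423.1 +/- 5.0 s^-1, p_B = 0.1447 +/- 0.0012
cluster_2: n_methyls = 2, n_residues = 1, k_ex = 5152.5 +/- 178.3 s^-1, p_B = 0.4760 +/- 0.2037
```

Reading this: the pooled duplicate-based error estimate recovered the
generator's 0.3 s⁻¹ noise; 18 residues pass the R_ex > 5 s⁻¹ screen; the
global fits recover the two planted processes — 14 residues sharing
k_ex ≈ 1640 s⁻¹ with p_B ≈ 4.2%, and the slower three-residue cluster
(I139/V210/L212) at k_ex ≈ 420 s⁻¹ with p_B ≈ 14.5% — with exactly the
planted memberships. The remaining two-methyl "cluster" is the single
planted off-cluster residue (L106), whose prochiral methyls share a third,
faster process; at residue level it is reported unclustered from both main
processes. `run/` contains the per-methyl fit report (TSV), the run
summary, and the config for exact reproduction.

The same machinery is available as a library:

```python
from cpmgdisp import MethylExchangeModel, make_dispersion_dataset, preset

spec = preset("dbd_300K")
profiles, truth = make_dispersion_dataset(spec, seed=1)
key = (67, "a")  # one Leu methyl
model = MethylExchangeModel([p for p in profiles if p.key == key],
                            spec.fields, spec.schedule)
res = model.fit()
res.monte_carlo(n_reps=100, seed=0)
print(res.summary())
```

Peak-list comparison of a free protein with a DNA complex:

```
cpmgdisp simulate --preset kB_proto --seed 1 --out peaks/
cpmgdisp peaks compare --free peaks/free.tsv --bound peaks/kB_proto_bound.tsv \
    --report peaks/report.tsv
```

prints `classification = multiple_conformations` together with the split
assignments — the signature of a DNA complex bound in more than one local
conformation — whereas the `MHC_H2` scenario classifies as a single
conformation.

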