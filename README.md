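# tmcbench

A benchmarking toolkit for machine-learned property prediction of
transition-metal complexes. It contrasts **structure-only** molecular
representations with **electronically informed** models that see total charge
and spin multiplicity — the central failure mode being vertical charge/spin
variants: two inputs with identical coordinates but different charge or spin
state, which structure-only models cannot tell apart.

## What's inside

| Module | Contents |
| --- | --- |
| `tmcbench.chem_core` | Molecular data model (charge, multiplicity, metal center), element tables, extended-XYZ and label-CSV I/O |
| `tmcbench.synthetic` | Octahedral complex generator with LS/HS geometry pairs, vertical charge variants, and a deterministic ligand-field-inspired property oracle (ΔE(HS−LS), HOMO/LUMO/gap, dipole magnitude) |
| `tmcbench.guess_electronic` | One-shot extended-Hückel engine: Slater→Gaussian minimal valence basis, analytic overlaps, Wolfsberg–Helmholz Hamiltonian, per-spin densities, Mulliken spin populations |
| `tmcbench.representations` | Four fixed-length representations, each with global/metal-local variants where defined: bagged many-body spectra (SLATM-style), smooth-density power spectra (SOAP-style), occupied-eigenvalue fingerprints, atomic density-block fingerprints |
| `tmcbench.kernel_models` | Kernel ridge regression (Laplacian/Gaussian), λ = 10^(−n_λ) with n_λ ∈ 0..4 and adaptive σ = 10^(n_σ/2) grid selected by inner 5-fold CV |
| `tmcbench.mpnn` | Invariant continuous-filter message-passing network (numpy, self-contained autodiff) with optional charge/spin embedding tables, global/metal-local scalar readouts, and a latent-charge dipole-magnitude readout; Adam training with plateau LR decay (×0.6 / 60 epochs), early stopping (150) and best-validation checkpointing |
| `tmcbench.harness` | Grouped 10-fold CV plans (LS/HS and vertical pairs never split), cross-model benchmarking with 80/10/10 splits for deep models, charge-subset MAE analyses, sign-error rates, HOMO/LUMO error-correlation, and the 0.9R+0.81K / 0.1R+0.09K KRR timing estimator |

## CLI

```bash
tmcbench synth --n 400 --seed 0 --out data/demo
tmcbench featurize --rep eigen --in data/demo.extxyz --out data/feat
tmcbench train-krr --features data/feat.npy --labels data/demo_labels.csv \
    --property homo --out data/krr
tmcbench train-gnn --train tr.extxyz --val va.extxyz --labels labels.csv \
    --property homo --qs both --out data/gnn
tmcbench benchmark --structures data/demo.extxyz --labels data/demo_labels.csv \
    --models models.yaml --properties homo,gap --k 10 --out data/bench
```

`models.yaml` is a list of model entries, e.g.

```yaml
- name: slatm-global
  kind: krr
  rep: slatm
- name: gnn-qs
  kind: mpnn
  mpnn_config: {use_charge_embedding: true, use_spin_embedding: true}
```

## Notes on fidelity

- The synthetic property oracle is a *test fixture* (crystal-field electron
  counting plus simple charge/electronegativity trends), not a claim about
  any reference electronic-structure method.
- The guess Hamiltonian is standardized on extended Hückel
  (Wolfsberg–Helmholz, K = 1.75) with a versioned parameter CSV
  (`src/tmcbench/data/eh_params.csv`, regenerable via
  `scripts/make_eh_table.py`); spin populations are Mulliken.
- Representation hyperparameter defaults are this artifact's own desk-scale
  choices and are documented in `FeaturizerParams`.
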