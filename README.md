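# excipol

Quantitative structure–function toolkit for amphiphilic copolymer
surfactant excipients.

`excipol` implements the desk-side pipeline for rational excipient design:

* **`excipol.copolymer_sim`** — Monte Carlo generation of per-chain
  copolymer compositions under the terminal (Mayo–Lewis) model, with
  Schulz–Zimm chain-length dispersity, optional finite-pool monomer
  depletion, and fully seeded determinism.
* **`excipol.cdi`** — the compositional dispersity index,
  `CDI = |1/R²|`, where R² measures how well the per-chain
  (major count, minor count) scatter fits the ideal stoichiometric line
  through the origin (slope = minor/major feed ratio; no fitting).
* **`excipol.aggregation`** — T10 aggregation-onset times from turbidity
  (A540) traces: baseline-anchored 10%-of-maximum threshold, linear
  interpolation, censoring, replicate statistics, fold changes.
* **`excipol.surface`** — one-phase exponential-decay fits of dynamic
  surface-tension traces over the first 300 s (rate constant k) and
  tail-of-trace equilibrium tension.
* **`excipol.structure_function`** — the three molecular-weight regimes
  (low ≤ 8 kDa: CDI; high ≥ 12 kDa: equilibrium tension; intermediate
  8–16 kDa: equilibration kinetics), single-predictor OLS per regime,
  and the a-priori design screen (CDI < 3 and k ≥ 4.3 × 10⁻³ s⁻¹).
* **`excipol.polymer_calc`** — Mn from monomer counts plus end-group
  mass, weight↔mole composition conversion, blend molecular-weight
  moments, mean-count allocation for a target Mn.
* **`excipol.synthetic`** — seeded generators for every input the
  pipeline consumes (logistic turbidity curves, exponential tension
  traces) plus the bundled excipient summary table.

## CLI

```bash
excipol simulate --config sim.yaml --out ensemble.csv        # chain ensemble
excipol cdi --ensemble ensemble.csv --out cdi.csv            # CDI of ensemble
excipol t10 --input assay.csv --out t10.csv                  # T10 per replicate
excipol fit-surface --input tension.csv --window-s 300 --out fits.json
excipol regress --out models.json                            # 3 regime fits
excipol screen --cdi 1.64 --k 4.6                            # design screen
excipol synth --kind turbidity --seed 5 --out assay.csv      # synthetic input
```

A simulation config looks like:

```yaml
monomers:
  - {name: Morph, molar_mass: 141.17, feed_fraction: 0.77}
  - {name: Nipam, molar_mass: 113.16, feed_fraction: 0.23}
ratios: {r1: 1.0, r2: 1.0}
length: {mean_dp: 94, dispersity: 1.14, family: schulz_zimm}
n_chains: 20000
pool_mode: infinite_feed
seed: 7
```

Every artifact gets a `.meta.json` sidecar with the producing config,
its hash and the seed; nothing is overwritten without `--force`.

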