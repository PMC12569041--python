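# korbias

Analysis toolkit for biased-signaling studies of the κ-opioid receptor
(KOR), a class-A GPCR whose agonists can preferentially engage G-protein
signaling over β-arrestin recruitment. The package re-implements, as
tested and reusable code, the computational stages such a study combines:

* **MD conformational-state analysis** — each trajectory frame is reduced
  to the distance *d* between Cα(S153³·⁴⁷) and Cζ(Y330⁷·⁵³), the Y330⁷·⁵³
  side-chain dihedral χ (C–CA–CG–CZ) and a flag for whether the R156³·⁵⁰
  side chain faces the intracellular side. Rectangular (d, χ) regions
  define four base states; states 2 and 3 split by the R156 flag into the
  six-state scheme S1, S2A, S2B, S3A, S3B, S4 (S3A is the "alternative"
  conformation thought to favor β-arrestin recruitment). Population tables,
  occupancy histograms and ligand-contact fingerprints (≤ 6 Å heavy-atom
  rule) with wild-type-minus-mutant deltas are built on top.
* **Dose-response pharmacology** — four-parameter logistic fits
  `y = Bottom + (Top − Bottom) / (1 + 10^((log₁₀EC₅₀ − log₁₀c)·h))` with
  |h| ≤ 2, wild-type-normalized activity (E_max, ΔpEC₅₀, RAi) and the
  ligand-bias statistic ΔΔLog(E_max/EC₅₀) between two pathways with a
  two-sided one-sample *t*-test.
* **Radioligand binding** — one-site saturation fits
  `B = B_max·L/(K_d + L)` on total-minus-nonspecific counts, and
  competition fits converted to K_i by Cheng–Prusoff
  `K_i = IC₅₀ / (1 + L/K_d)`.
* **ATR-FTIR difference spectroscopy** — active-minus-inactive absorbance
  spectra with swelling/vapor corrections, band detection with parabolic
  sub-grid refinement, and band-shift reporting in the cysteine S–H
  (2600–2500 cm⁻¹), histidine C–N (1200–1100 cm⁻¹) and amide-I
  (1700–1600 cm⁻¹) windows.
* **Structure comparison** — Kabsch backbone superposition (N, CA, C, O;
  residues matched by author numbering), per-residue ligand contacts and
  named-atom distances.
* **Synthetic data** — seeded generators that emulate each input type
  (trajectories realizing prescribed state geometry, 4PL plate data,
  binding isotherms, additive-band spectra), so the whole pipeline runs
  and is testable offline.

## Worked example

Generate a trajectory with a known state composition, classify it, and fit
a saturation binding isotherm:

```python
import numpy as np
from korbias import GeneratorConfig, StateSpec, classify, featurize, populations
from korbias.synthetic import gen_trajectory, gen_binding
from korbias.pharm import SaturationBinding

spec = StateSpec(counts={"S1": 300, "S2": 200, "S3": 400, "S4": 100},
                 r_down_prob={"S2": 0.3, "S3": 0.7})
traj, truth = gen_trajectory(spec, config=GeneratorConfig(seed=1))
feats = featurize(traj)
labels = classify(feats)
table = populations([labels], [feats])
print("recovered:", (labels == truth).all())
print(table.pooled.round(3).to_string())
print("state-3 R3.50 down:", round(table.r_down[3], 3))

conc = np.array([0.5, 1, 2, 4, 6, 8, 10, 12]) * 1e-9
df, _ = gen_binding("saturation", {"bmax": 5000.0, "kd": 7.79e-9, "ns": 2e10},
                    conc, n_replicates=3, noise_sd=25.0,
                    config=GeneratorConfig(seed=1))
print(SaturationBinding.from_dataframe(df).fit().summary())
```

prints

```
recovered: True
S1            0.300
S2A           0.059
S2B           0.141
S3A           0.272
S3B           0.128
S4            0.100
UNASSIGNED    0.000
state-3 R3.50 down: 0.68

One-site saturation binding fit
  n_obs   : 24
  Bmax    : 4970.46  (95% CI 4664.07 .. 5276.85)
  Kd (nM) : 7.66285  (95% CI 5.76595 .. 9.55976)
```

Every frame's ground-truth label is recovered exactly (the generator places
features strictly inside the state regions), the pooled fractions match the
requested composition, the state-3 R³·⁵⁰-down proportion approximates the
construction probability 0.7, and the one-site fit recovers the generating
K_d of 7.79 nM within its counting noise.

A command-line interface covers the same stages
(`korbias simulate | states | fingerprint | fit | bias | binding | ftir |
structcomp`); every run writes a `provenance.json` with the seed, arguments
and configuration hashes.

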