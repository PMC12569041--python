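# Methods

This note documents the models and procedures the package implements, the
conventions and numerical choices behind them, what the synthetic-data
generators do and do not emulate, and the known limitations.

## Conformational-state classification

**Features.** A trajectory frame is reduced to three quantities: the
Euclidean distance *d* (Å) between Cα of S153³·⁴⁷ and Cζ of Y330⁷·⁵³; the
side-chain torsion χ (degrees) of Y330⁷·⁵³ over the atom chain
C–CA–CG–CZ; and a boolean `r_down` for the R156³·⁵⁰ side-chain
orientation. Torsions use the atan2 form on the plane normals with the
IUPAC sign convention and range (−180°, 180°]; −180° is mapped to +180°.
Under this convention the torsion is invariant under reversing the atom
chain and changes sign under mirror reflection. A collinear atom triple
makes the torsion undefined and is an error, not a NaN.

**Membrane convention.** The membrane normal is +z with +z pointing
extracellular. R156³·⁵⁰ "faces intracellular" when the angle between its
CA→CZ vector and −z is below a threshold (default 90°, i.e. a negative
projection on +z). The threshold is configurable because the geometric
criterion used in the original analysis is not stated; 90° is the simplest
testable reading of "downward".

**State regions.** Base states 1–4 are half-open rectangles [lo, hi) in
(d, χ); χ intervals may wrap across ±180° and are split internally at the
boundary. Regions are validated pairwise disjoint at load time, so no
frame can match two states and there is no runtime tie-break — overlap is
a configuration error. Frames outside every region get the first-class
label UNASSIGNED, which keeps population fractions summing exactly to 1.
Base states 2 and 3 split into A (R156 down) and B (up) sub-states,
giving six labels. The numeric rectangle coordinates are a shipped TOML
configuration (`korbias/data/state_boundaries.toml`), annotated as read
qualitatively from published occupancy-heatmap clusters rather than from
printed values; every population table records the SHA-256 hash of the
boundary file in use.

**Populations.** Fractions are reported two ways, because it is not
specified whether frames were pooled across replicate simulations before
computing percentages or per-replicate fractions were averaged: the pooled
table weights replicates by frame count, and per-replicate fractions are
emitted alongside. Per base state, the proportion of frames with
`r_down` true is reported (from features when available, otherwise from
the A/B sub-label counts of split states).

**Fingerprints.** A residue contacts the ligand in a frame when the
minimum heavy-atom-to-heavy-atom distance is ≤ 6.0 Å; the boundary is
inclusive and the cutoff is recorded in the result. Contact frequency is
contact frames over total frames. The wild-type-minus-mutant delta is
taken over the union of residues (absent residue → frequency 0), positive
values meaning the mutation reduced the interaction. Interaction-type
subclassification (hydrogen bonds, π-stacking) is out of scope; the rule
is distance-only.

## Synthetic trajectory generator

Frame geometry is constructed analytically rather than by physics: the
four torsion atoms of Y330 are placed with fixed bond lengths and angles
and the prescribed torsion (natural-extension-reference-frame placement);
S153 Cα is placed on the sphere of the prescribed distance about Y330 Cζ
with a random direction; R156 Cζ is placed above or below its Cα along
the membrane normal according to the orientation draw, with small lateral
jitter that cannot flip the flag. Sampling ranges default to each state
region shrunk by 20 % per side, so realized features sit strictly inside
the region and classification recovers the generated labels exactly —
this is the oracle-equivalence property the state-classification tests
rely on. Counts may be requested per sub-state (S2A forces `r_down`) or
per base state with a Bernoulli `r_down` probability. Frames are shuffled
deterministically by the seed, and the ground-truth labels are returned in
shuffled order. Optionally a one-atom hetero ligand plus probe residues
with per-residue contact probabilities are added (probe at 4 Å in contact
frames, 12 Å otherwise) for fingerprint testing.

What the generator does **not** emulate: full side-chain chemistry, any
other receptor atoms, lipids or solvent, temporal autocorrelation between
frames, or realistic transition kinetics. Passing tests therefore show
that featurization, classification and bookkeeping are correct — not that
the state scheme itself is a good model of real MD data.

## Dose-response and ligand bias

**4PL model.** `y = Bottom + (Top − Bottom)/(1 + 10^((log₁₀EC₅₀ −
log₁₀c)·h))`, fitted by bounded least squares (trf) in (Bottom, Top,
log₁₀EC₅₀, h) with the Hill slope constrained to |h| ≤ 2 as a closed box
bound (an open bound is not optimizable). The model is invariant under
(Bottom, Top, h) → (Top, Bottom, −h); fits are canonicalized to
Top > Bottom so the Hill sign alone carries the curve direction. The
default fit multi-starts log₁₀EC₅₀ across the tested concentration range
with both Hill signs; `n_starts=1` selects a cheaper data-driven start
(half-height crossing, Hill sign from the response/log-concentration
correlation) used for large simulation sweeps. Convergence tolerances are
1e-12, which recovers noiseless parameters to better than 1e-6 relative.
Flat data (zero response range) is flagged (`flat=True`, Span ≈ 0), not
failed. Uncertainties are asymptotic, from the Jacobian at the optimum.

**Kinetic normalization.** Per well, counts in the response window
(default 5–10 min after compound addition) are averaged and divided by the
pre-addition baseline; the fold change is divided by the vehicle-well fold
change of the same construct and replicate. Missing vehicle wells, empty
windows, and zero baselines are errors.

**Relative activity and bias.** Per replicate, Span, pEC₅₀ and Span/EC₅₀
of a test construct are normalized to the reference fitted in parallel
(matched by experiment index; mismatched replicate counts are an error,
never broadcast). ΔLog = log₁₀(Span/EC₅₀)_test − log₁₀(Span/EC₅₀)_ref
within each pathway, ΔΔLog = ΔLog(A) − ΔLog(B); EC₅₀ is molar and logs
are base 10. The one-sample *t*-test (two-sided) runs on the per-replicate
ΔΔ values — the alternative convention (ΔΔ of per-replicate ΔLog means) is
also exposed, and the two means coincide because the statistic is linear.
Significance classes: * p < 0.05, ** p < 0.01, *** p < 0.001. With fewer
than two replicates, or zero variance across replicates, the statistic is
undefined and reported as absent while the ΔΔ values are still returned.

## Radioligand binding

Specific binding is total minus nonspecific, replicate-matched; negative
specific counts at low radioligand concentration are retained in the fit
(no clipping) and their count is reported. The one-site model
`B = B_max·L/(K_d + L)` is fitted with positivity bounds and
per-parameter scaling (B_max in counts and K_d in molar differ by ~12
orders of magnitude). 95 % confidence intervals are asymptotic
(covariance-based). Competition curves are fitted as a sigmoid in
log(inhibitor) (Hill slope free up to |h| ≤ 5), oriented so Top is the
zero-inhibitor plateau, and K_i = IC₅₀/(1 + L/K_d) is computed exactly
from the fitted IC₅₀ with the user-supplied radioligand concentration and
affinity.

## FTIR difference spectra

Spectra live on a uniform ascending wavenumber grid, default 2 cm⁻¹
step. The difference spectrum is pointwise active minus inactive on a
common grid (regridding is linear interpolation, extrapolation is an
error); positive bands belong to the agonist-bound state, negative to the
antagonist-bound state. Two corrections are provided, both least-squares
scalar fits recorded in provenance: a multiplicative scale against a
reference (film swelling/shrinkage), and subtraction of α × reference
with α minimizing the squared first differences of the corrected spectrum
in 1900–1700 cm⁻¹ (water-vapor rotational lines). The original
correction windows and references are not published; these defaults are
declared choices, not inferences.

Band detection takes the grid extremum of the requested sign in a window
and refines the position by a parabola through the three surrounding
points, reporting to 1 cm⁻¹. On Gaussian bands of FWHM ≥ 8 cm⁻¹ on a
2 cm⁻¹ grid the refined position is within 0.5 cm⁻¹ of the dense-grid
optimum. A flat window or a window with no extremum of the requested sign
reports absence (None) rather than fabricating a peak. With the default
10 cm⁻¹ FWHM, overlapping band pairs separated by ≥ 1.5 × FWHM shift the
difference-spectrum extrema by well under 1 cm⁻¹, so the worked-example
band positions (amide-I 1651 → 1666/1663; S–H 2550 → 2570/2565) are
recovered at the grid's reporting precision.

## Structure comparison

Superposition uses the least-squares rigid transform (Kabsch, via SVD)
over backbone atoms N, CA, C, O of residues matched by chain + author
residue number + insertion code — no sequence alignment. Missing
counterpart atoms are dropped pairwise and counted in the result; fewer
than three pairs or a collinear selection is an error. The receptor-only
selection for cross-model comparisons is a chain filter with optional
residue ranges, recorded in the output provenance, because the atom set
behind published receptor-region RMSD values is not stated. Distances use
heavy atoms only; summaries round to 0.1 Å with full precision retained
in machine output.

## Problem sizes in the verification suite

The acceptance script classifies ~9,000 generated frames over ten state
configurations, runs 200 noisy dose-response simulations (5 % of Span
noise, 3 replicates) for pEC₅₀ recovery and 500 null simulations for the
bias *t*-test's type-I rate, and fits binding isotherms on the 0.5–12 nM
working range with the wild-type K_d (7.79 nM) as the generating value.
These sizes keep the full run under a minute on one CPU while leaving the
statistical checks well-powered.

## Known limitations

* State boundaries are a configuration, not a result: changing the
  rectangles changes every population number. The shipped defaults are
  qualitative.
* The generators draw i.i.d. frames and Gaussian noise; real trajectories
  and plate reads are autocorrelated and heteroscedastic.
* Binding confidence intervals are asymptotic; at small n they can be
  optimistic compared to profile-likelihood or bootstrap intervals.
* No Black–Leff operational-model bias factors, no Markov state models,
  no clustering to discover states, and no amide-I secondary-structure
  deconvolution.
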