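# Methods

## The data-fusion model

Each responding unit (an unambiguous receptor/OSN/glomerulus channel, or
a sensillum-level aggregate where spikes cannot be sorted) is assumed to
have a latent response profile over odorants, and each study measuring
that unit is assumed to observe a *monotone* transformation of it on its
own odorant panel and its own measurement scale, plus noise. Nothing
about absolute scale is trusted; only the within-study response ordering
carries information. Merging is therefore a rank-faithful change of
coordinates, not an averaging of raw values.

### Model families and fitting

Two unit-scaled datasets are related by one of five parametric monotone
families, fitted in both orientations (y on x, and x on y — the
"inverse" fits), giving ten candidates:

| family             | form                                              | parameters |
|--------------------|---------------------------------------------------|------------|
| linear             | a + b·x                                           | a, b |
| exponential        | a·e^{bx} + c                                      | a, b, c |
| sigmoid            | ymin + (ymax − ymin)/(1 + e^{−(x−x0)/k})          | ymin, ymax, x0, k |
| asymptotic         | Asym·(1 − e^{−e^{lrc}·x})                         | Asym, lrc |
| asymptotic-offset  | Asym·(1 − e^{−e^{lrc}(x − c0)})                   | Asym, lrc, c0 |

Fitting minimizes vertical residuals in the fit's own orientation. The
linear family is solved in closed form; the nonlinear families use
Levenberg–Marquardt with analytic Jacobians from eight fixed,
data-statistic-derived starts. The starts are pre-screened by raw
residual sum of squares and only the best four are polished (at most 100
function evaluations each); non-convergent starts are dropped, and a
family is rejected only if every start fails. A fitted curve must be
non-decreasing at 1,001 equispaced points of the overlap range;
violators are rejected with a logged reason.

### Projection and the merged coordinate

The fitted curve is trusted only on the range spanned by the common data
points and is extended on both sides by a straight line of slope 1 —
odorants outside the common response range (typically the best ligands
known to only one study) are mapped through this extension, which is why
single-study top ligands are systematically conservative in a consensus.

Fit quality is the mean distance (MD): the mean orthogonal Euclidean
distance of the common points to the extended curve. The nearest point
is found by a 513-point coarse scan of the curve parameter refined by
bounded scalar minimization (tolerance 1e−12), with closed-form feet of
perpendicular on the two extension rays; this agrees with a brute-force
discretization of the curve at 1e−5 arc resolution to better than 1e−6
in distance (verified in the test suite over all ten families).

A projected point must become one merged number. The paper trail for
the original software leaves this open; here the merged value is the
**arc length** along the extended curve from the lower end of the fitted
region (negative on the lower extension), computed from a 2,001-point
cumulative-trapezoid table inside the fitted region and analytically
(√2 per unit x) on the extensions. Arc length is strictly monotone
along any monotone curve — so ranks are preserved exactly wherever the
fit is exact — and is symmetric in x and y, which makes
merge(a, b) and merge(b, a) rank-identical. The merged values are
rescaled to [0, 1].

Common odorants use the nearest-point projection; odorants unique to the
x-side map to (x, f(x)); unique to the y-side to (f⁻¹(y), y). Inverse
evaluation through a flat stretch of the curve is refused
(`NonInvertibleSegmentError`) rather than silently picking an end.

### Merge order, exclusions, normalization

With ≥ 2 datasets the result depends on the merge order. Where the
permutation count does not exceed `permutation_cap` (default 10,000,
i.e. up to 7 datasets) every permutation is fold-merged left to right
and scored by the average best-fit MD of the result against every single
input dataset; the minimum wins, ties going to the lexicographically
first permutation. Beyond the cap, the currently lowest-MD pair is
merged repeatedly (greedy). On every tested instance the exhaustive
score is ≤ the greedy score, as enumeration guarantees.

Exclusion rules, applied per unit and logged, never abort a merge:
datasets sharing < `overlap_min` (default 5) odorants with every other
dataset are excluded (`too-few-overlap`; with disjoint panels the
largest-coverage component is kept), and datasets whose best achievable
fit exceeds `md_cap` (default 0.1·√2, 10 % of the [0, 1]×[0, 1]
diagonal) are excluded (`md-above-cap`).

Spontaneous firing rate travels through the whole pipeline as the
pseudo-odorant `"SFR"` (0 for studies that did not report it, e.g.
calcium imaging); after merging, each unit's SFR value is subtracted
from all its responses (`reset_sfr`), restoring negative values for
inhibitory odorants, and the SFR row becomes exactly 0.

Global normalization rescales units relative to each other using studies
that recorded more than one unit: each such study is scaled to [0, 1]
jointly across its units, a unit's factor is the largest scaled response
it reaches in any such study, and factors are normalized so the largest
is 1. Units not covered by any multi-unit study keep factor 1 and are
flagged. The exact arithmetic used by the original database is not
published; this is one consistent reading, chosen for being the simplest
that makes "relative response ranges" well-defined.

## Tuning-breadth statistics

Lifetime kurtosis: LTK = (1/M)·Σ((rᵢ − r̄)/σᵣ)⁴ − 3 over the M
non-missing responses of one unit, with the *population* standard
deviation (divide by M), matching the (1/M)Σ(·)⁴ − 3 form; a sample-sd
variant is available behind a flag for sensitivity checks. 0 is the
Gaussian reference; rankings use only units with ≥ 50 responses (the
`min_n` default) because kurtosis estimates on short profiles are
unstable. The SFR row — identically 0 after reset — is excluded.
Population kurtosis is the same formula across units for one odorant,
reported only when the odorant was measured in ≥ `min_units` units
(default 39, about half the catalogued units). Negative (inhibitory)
responses are retained for kurtosis; for lifetime sparseness — the
Rolls–Tovée form LTS = (1 − (Σr/M)²/(Σr²/M))/(1 − 1/M), taken from the
sparseness literature since it requires non-negative inputs — they are
rectified to 0 and the rectification count is reported.

## Profile mapping

`map_receptor` screens a query profile against every unit: Pearson r
over shared odorants (≥ `min_overlap`, default 10), two-sided p from
t = r·√((n−2)/(1−r²)), and a double pass criterion p < 0.05 AND
r > 0.75. No multiple-testing correction is applied by default, so the
screen mirrors raw-p reporting; a Benjamini–Hochberg flag would be the
natural extension and Spearman is available behind a `method` switch.
`identify_sensillum` assigns the recorded profiles one-to-one to each
candidate sensillum's units — exhaustively, since sensilla house at most
4 neurons — maximizing mean correlation (or minimizing mean RMS distance
on [0, 1]-rescaled profiles) and ranks sensilla by that score.
`private_odorant(u)` scores each odorant by R[o, u] − max of R[o, ·]
over the other units with measurements, i.e. the activation margin of
the unit's most diagnostic ligand; the score is invariant under adding
a constant to the whole matrix.

## Calcium-imaging pipeline

Recordings are 20 s at 4 Hz (80 frames); frame i (1-based) spans
[(i−1)/4, i/4) s and a window [t1, t2) contains frames whose start time
falls in it. Stimulus onsets after delivery delay are 6.75 s and
9.75 s. ΔF/F = 100·(Fᵢ − F₀)/F₀ with F₀ the mean of the 5 s before the
first onset. Photobleaching is modeled as A·e^{−x/B} + C; because
odorant responses need not return to baseline within a recording, B is
estimated once per animal from the framewise median solvent-control
trace, then A and C are refitted per trace with B fixed (a linear
weighted least-squares problem). The decay fit ignores the first 750 ms
and everything in [onset, onset + 11 s] for each onset — those frames
can contain response — and weights pre-stimulus frames 100-fold. If the
fitted amplitude is indistinguishable from zero (|A| ≤ 2 standard
errors), the correction is skipped, avoiding the B → ∞ instability of a
flat control. Response magnitude is the mean of the 5 s after onset
minus the mean of the 2.5 s before it (by default the first onset;
`onset_index=2` analyzes the second injection — how the two injections
were combined originally is unstated, so they are kept separate). Slow
sensitivity drift is corrected per animal by regressing the
reference-odorant responses on measurement index and scaling every
response by L(t₁)/L(t); a regression line reaching zero inside the
session is an error, not a silent division.

## Synthetic data: what it emulates and what it does not

The generators produce exactly the structure the merge assumes: a latent
[0, 1] profile (`uniform` broadly tuned, `exponential` right-skewed,
`one-hot` single-ligand), per-study monotone transforms drawn from the
five families — normalized to unit output range so that `noise_sd` is on
the same scale as the responses — additive Gaussian noise, random
odorant subsets of size `overlap_fraction·n`, and optional SFR offsets.
Defaults (60 odorants, 3 studies, 60 % coverage, noise sd 0.05) are the
conditions under which the merge engine is validated. The trace
generator emits raw fluorescence: a resting level modulated by a decay
(10 % amplitude, τ = 8 s), boxcar responses at the protocol onsets and
0.5 % noise.

Rank-recovery replicates use the `uniform` tuning shape: an
ideal-estimator ceiling analysis (truth + noise/√(coverage), 20 seeds)
gives median Spearman 0.988 under uniform truths but only 0.957 (min
0.869) under exponential truths, where most responses sit within the
noise floor of each other — there a rank-recovery criterion measures the
noise, not the algorithm. Passing these tests therefore shows that the
merge preserves resolvable rank structure across incompatible monotone
scales; it does not show robustness to saturation, concentration
mismatch, adaptation or correlated (non-Gaussian) noise, none of which
the generator emulates.

Exact (not just high) rank agreement in the noiseless case is guaranteed
only when each between-study relation is itself representable by one of
the model families (e.g. distinct linear distortions), and is tested as
such. With distortions from *different* families the cross-study
relation is a composition outside the model class; odorants unique to
different studies then acquire sub-1e−3 rank discrepancies (measured
noiseless Spearman ≈ 0.9994). This is a property of the projection
approach, not of the implementation.

The imaging pipeline's recovered magnitudes carry a small (~5 %)
downward bias because F₀ is measured on the already-decaying baseline;
rank structure is unaffected, which is what the recovery checks assert.

## Numerical choices and degenerate inputs

- Constant-valued dataset: error (`degenerate range`) rather than silent
  all-zeros — a flat profile carries no rank information; `allow_flat`
  downgrades it to a warning and all-zeros.
- Duplicate odorant rows (same InChIKey) are collapsed to their mean at
  load time and logged.
- Tie-breaking is fixed everywhere: (MD, family order
  linear → exponential → sigmoid → asymptotic → asymptotic-offset,
  forward before inverse), lexicographic ids/permutations, so identical
  inputs produce byte-identical outputs.
- On-disk numbers use 6 significant digits with `NA` for missing, making
  load → write → load round-trips byte-identical.
- Identifier translation is a local lookup table shipped with the
  package (InChIKey ↔ name/CAS/CID/SMILES, rdkit-checked where SMILES
  are present); CAS cells may hold several registry numbers separated by
  `|`, and conflicting mappings are returned, not collapsed. No network
  calls.

## Problem sizes used in the shipped validation

The validation suite runs the merge at 60 odorants × 3 studies (20
seeded replicates), ordering optimality at 3–4 datasets against full
permutation enumeration, and the geometry oracle at 50 random curve
instances with a 1e−5-resolution discretization — sizes at which the
brute-force oracles are exact and fast while exercising every code
path. Full-scale reproduction against the archived community datasets
is a separate integration suite that activates when those datasets are
present locally.

## Known limitations

- Concentration–response integration, temporal dynamics and mixture
  responses are out of scope; each dataset is one response value per
  odorant.
- The global-normalization arithmetic and the merged-coordinate
  definition are reconstructions of under-specified steps (documented
  above); absolute consensus values may differ from the original
  database even where ranks agree.
- `identify_sensillum` reconstructs a tool whose internals are not
  published; the optimal-assignment formulation is faithful to its
  interface but unverifiable against the original.
- Movement-artifact correction and ROI selection are assumed done
  upstream of the trace pipeline.
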