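# Methods

## The model

A treatment is observed as a sequence of 150-word transcript blocks, each
scored with six bounded frequencies: positive emotional tone, negative
emotional tone and abstraction for each of the two speakers. The analysis
treats each speaker's three-dimensional feature trajectory as a dynamical
system and discretizes it by clustering: the three features are z-scored
(over the data pooled across all subjects of a role, so all subjects share
one state space) and partitioned with K-means into k = 8 states. A state is
a recurring linguistic configuration — a quasi-attractor of the interaction.
States are relabeled 1..k by descending occupancy, which makes a fitted
model deterministic given its seed.

States with an occupancy share below `min_share` (default 1%) are treated as
outliers: their blocks are deleted and the surviving sequence is
re-concatenated, so a transition may span a deletion. This mirrors the
practice of dropping scarcely populated clusters before estimating
transition structure; the deleted-block positions are recorded so the two
roles of a dyad can be re-aligned afterwards.

The symbolic sequence yields a first-order Markov transition matrix (MTM):
`T_ij = P(X_{t+1} = j | X_t = i)` estimated by row-normalized transition
counts. Matrices keep the full pre-pruning size k with *undefined* (NaN)
rows for states never observed as transition sources — undefined is never
imputed as zero, and cross-subject comparisons happen in the one shared
index space. Dyadic dynamics interleave the two speakers: patient-to-
therapist pairs are simultaneous (`pat_t → ther_t`), therapist-to-patient
pairs are lag-1 (`ther_t → pat_{t+1}`); an `interleaved_pairs` variant
treats the alternating sequence as a single chain. The simultaneous/lag-1
split is a documented reading of an interleaved listing that is not fully
explicit in the tradition this follows; both variants are available.

### Direct comparison

Two MTMs are compared by the Pearson correlation of their linearized cells.
Under the default `both_defined` policy only rows defined in *both* matrices
enter, which avoids manufacturing zeros for structurally undefined rows; a
`union_zero` policy (undefined rows as zeros over all k² cells) is provided
for sensitivity analysis. `DeltaCorr` of a pair of dyads is the patient-side
minus the therapist-side correlation; class summaries report mean, sample
SD, range and a normal-approximation 95% CI, `mean ± 1.96·sd/√n`. The
z-based CI (rather than t) is a deliberate convention: it exactly reproduces
the interval arithmetic of the worked example the acceptance checks use.

### Transition-law regression

Each retained matrix cell (i, j) — all pairs of active states, diagonal
included by default since self-transitions are real transitions — becomes
one observation with response `T_ij` and regressors: centroid distance
`d_ij` (Euclidean, standardized space), destination frequency `f_j`, and
composite frequency `f_i·f_j`. Frequencies are computed from the same pruned
sequence that generated the matrix. Four modes are fitted by OLS on z-scored
response and regressors (so coefficients are standardized betas; for a
single regressor the beta equals the Pearson correlation): `distance`,
`freq_j`, `composite`, and `full` = {distance, composite}. Reported per fit:
standardized betas, R, R², adjusted R² by `1 − (1−R²)(N−1)/(N−k−1)` with N
the number of design cells, the overall-F p-value, per-coefficient t-test
p-values, and the ratio |β_composite|/|β_distance|.

Cells of one matrix are treated as independent observations. They are not —
they share rows, and row-normalization couples them — but this inherited
simplification is reproduced deliberately so results remain comparable with
the modeling tradition; the permutation check in the test suite shows the
F-test is calibrated against a y-shuffling null on these designs.

### Drift tests

Non-stationarity is screened per state by comparing occupancy in the first
and last `floor(n/3)` observations (the middle is discarded). The 2×2 table
((a, n1−a), (b, n2−b)) yields `OR = a(n2−b)/(b(n1−a))` with a log-OR normal
95% CI, and a chi-square test with Yates correction by default; uncorrected
and Fisher-exact variants are selectable because printed p-values in this
literature are frequently irreproducible from their own printed counts — the
package standardizes rather than reverse-engineers. A zero cell leaves the
OR undefined (NaN) unless the Haldane–Anscombe +0.5 flag is set; nothing is
corrected silently. Raw p-values are flagged at α = 0.05 (as such screens
are conventionally reported) and a Benjamini–Hochberg column is always
emitted alongside.

## The synthetic generator

Ground truth for every stage comes from a k-state generator whose transition
kernel mixes the two candidate laws additively:

    T_ij ∝ w_freq · f_i·f_j + w_dist · exp(−d_ij / λ)

row-normalized; `f` is a target frequency vector, `d` the centroid distance
matrix. The additive-then-normalize form matches the additive regression the
pipeline fits, keeping recovery interpretable; the exponential kernel is the
simplest monotone choice for "transitions fall off with distance". Each
visited state emits its centroid plus N(0, σ²) noise in standardized units,
mapped to the raw [0, 1] frequency scale by per-feature means/SDs (defaults
0.10/0.10/0.12 and 0.03) and clipped; the clipping rate is reported and a
warning raised above 5%. Dyads are coupled by a per-block coin: with
probability κ the therapist copies a deterministic map of the patient's
current state, otherwise it advances by its own chain. All randomness is
split from one seed via numpy `SeedSequence` spawning (patient chain,
therapist chain, coupling coin, emission noise).

Defaults, chosen once as the study conditions the generator emulates:

| parameter | default | rationale |
|---|---|---|
| k | 8 | the study-scale cluster solution |
| centroids | cube corners {−1,+1}³ | well-separated, pairwise distance ≥ 2 |
| target_freqs | (0.28, 0.19, 0.15, 0.12, 0.10, 0.08, 0.05, 0.03) | occupancy-shaped, descending |
| w_freq, w_dist | 1.0, 0.01 | composite-dominant with a clearly negative distance beta (β_dist ≈ −0.3, ratio ≈ 2.4 on the fitted full model) |
| λ (length_scale) | 1.5 | kernel contrast across cube distances 2–3.46 |
| emission_sd σ | 0.7 | calibrated so 8-cluster K-means explains ≈ 65–75% of variance, the study-scale figure; separation-dependent emulations (label recovery, rare-state isolation) use σ = 0.2 |
| n_blocks | 5000 | within the 10³–10⁴ range of a full brief treatment |
| coupling κ | 0.3 | moderate therapist responsiveness |

`simulate_cohort` builds eight dyads (4 good, 4 poor outcome) sharing one
centroid layout per role. Patients carry a small distance weight
(`pat_w_dist = 0.005`), therapists a pure frequency law; per-subject
heterogeneity enters as multiplicative log-normal jitter of the target
frequencies, with poor-outcome therapists jittered an order of magnitude
more (0.5 vs 0.05) than everyone else — the generator's rendering of the
more variable linguistic behavior of therapists in difficult treatments.
Two patient states and three therapist states are kept rare and their
centroids pushed far out (outlier_scale = 5), so pooled clustering isolates
them and 1% pruning reproduces a 6-active / 5-active structure. The
therapist's coupling response map sends patient state s to therapist state
((s−1) mod 5)+1, keeping responses inside the therapist's frequent
repertoire; an identity map would leak coupling mass into the therapist's
rare states and destroy their rarity.

One structural property of the kernel is worth knowing: because the distance
term contributes `w_dist · exp(0) = w_dist` to every diagonal cell, a state
with a tiny target frequency still has a self-transition weight `w_dist`,
making scarce states sticky. The stationary occupancy of any state is
therefore floored at roughly `w_dist / (k_active · mean row total)` —
about 0.9% at w_dist = 0.01. A generator cannot simultaneously produce a
strong distance beta and arbitrarily rare states; the cohort's patient
weight (0.005, floor ≈ 0.6%) trades some distance-beta magnitude
(β_dist ≈ −0.09 instead of ≈ −0.3) for robustly sub-1% rare states, while
the single-chain default (w_dist = 0.01) demonstrates the stronger regime
where no pruning premise applies.

### What the generator does not emulate

Real transcripts have session boundaries, non-Markov long-range structure,
semantic content, speaker turn-taking inside blocks, and coding-dictionary
idiosyncrasies; the generator has none of these. Emissions are conditionally
independent Gaussian given the state, so cluster shapes are spherical —
kind to K-means in a way real feature clouds may not be. Passing
recovery tests therefore demonstrates the pipeline's correctness and its
statistical behavior under the stated model, not robustness to model
misspecification.

## Numerical choices

- Feature z-scoring uses the population SD (standardized columns have SD
  exactly 1); stored constants are reapplied verbatim to new data.
- K-means: scikit-learn, best of `n_restarts` (default 50) by within-cluster
  sum of squares, seeded; variance explained = 1 − WCSS/TSS.
- Assignment ties (equidistant centroids) break to the lowest state label;
  relabeling is by descending occupancy with stable ties.
- Defined MTM rows sum to 1 within 10⁻⁹ (asserted); generator rows within
  10⁻¹².
- Correlation requires ≥ 3 comparable cells and nonzero variance on both
  sides; degenerate inputs raise instead of returning NaN.
- The regression design requires ≥ 5 cells; exact collinearity of regressors
  and zero-variance responses raise.
- Word-block frequencies use the block size as denominator (not the
  speaker's word count), so a silent speaker scores (0,0,0) — the "silence"
  state whose standardized centroid is negative on all three features.
  Trailing partial blocks are dropped; dictionaries must be pairwise
  disjoint, keeping per-speaker sums provably ≤ 1.

## Problem sizes

The test suite runs at n_blocks between 400 and 5000, 100-seed recovery
loops, and a 500-subject drift calibration; the acceptance script uses an
8-dyad cohort at n_blocks = 3000 (pooled clustering over 24 000 blocks per
role), n_blocks = 1500 for the rare-state emulation, and 100-run recovery
sweeps at n_blocks = 5000. These sizes were chosen as the smallest at which
the sampling error of the checked quantities is comfortably below the
decision margins.

## Known limitations

- Only the occupancy criterion of outlier pruning is operationalized; the
  "very far in the reduced plane" aspect informs the synthetic design but is
  not a pruning rule (no quantitative threshold exists for it).
- Per-subject adjusted R² depends on the cell count N entering the design;
  published per-subject values in this tradition are not always recoverable
  from their printed active-state counts, so N here is always the number of
  design rows, stated per fit.
- The dyad matrix's column space is the target role's own state space; a
  published dyad table showing more populated columns than the target role
  has accepted states is a discrepancy we index around, not reproduce.
- Bounded responses are fitted by OLS, not a beta-type likelihood, for
  comparability with the tradition; R² on probabilities near 0/1 should be
  read accordingly.
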