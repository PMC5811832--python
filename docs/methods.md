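# Methods

This note documents the models, parameter choices and numerical decisions
behind `wavegraph`, and what the synthetic cohorts do and do not emulate.

## Synthetic cohorts

**Signal model.**  ROI *i* of module *m* in a given subject-session is

    x_i = sqrt(rho) f_m  +  sum_e sqrt(delta_e) g_e  +  sqrt(1 - rho - sum_e delta_e) eps_i

where `f_m` is a module-shared latent factor, `g_e` are per-edge factors for
the planted subnetwork's edges incident to *i*, and `eps_i` is white noise.
All latent terms have unit variance, so the population correlation of two
same-module ROIs is exactly `rho` (the within-module coupling for that
group × session) and a planted edge adds exactly `delta` — closed-form
ground truth that makes recovery tests exact.  Factors are produced by
FFT-masking white noise to the carrier band (0.0625–0.125 Hz by default,
matching the scale-2 wavelet band at TR = 2 s) and rescaling to unit sample
variance: this pins band occupancy exactly without filter-design choices.
A coupling combination whose total shared variance reaches 1 at any ROI is
rejected with a per-ROI diagnostic (the target covariance would not be
positive definite).

**Defaults.**  90 ROIs in 6 contiguous modules; 180 timepoints at
TR = 2 s (a 360 s acquisition); groups HV:36, polySD:36, AD:21; sessions
baseline/placebo/naltrexone.  Within-module coupling is 0.12 for HV in all
sessions, 0.45 for polySD in all sessions, and 0.45 for AD except 0.12
under naltrexone — the emulated phenomenon is that both dependent groups
show elevated modular coupling (hence local efficiency) and that
naltrexone normalises it in the alcohol group only, to the control level.
The couplings sit at an operating point chosen (by a seed-replicated
design check) for two properties: the 5 %-density graph is still sensitive
to coupling — at uniformly strong coupling the top-K edge set saturates on
same-module pairs and local efficiency stops discriminating groups — and
the planted drug and group × drug effects are reliably detectable at the
default cohort size, so that the cohort actually instantiates the study
design it stands in for.  The default planted subnetwork is a 20-edge
path alternating between two modules (max degree 2, keeping per-ROI shared
variance well below 1) with extra coupling 0.15 in HV and polySD and 0 in
AD: a dispersed subnetwork of *reduced* connectivity in the alcohol group,
recoverable by the NBS.

**Motion.**  Spikes are single-timepoint offsets (stated amplitude in SD
units) added to all ROIs, giving controllable DVARS exceedances.

**Covariates.**  Age and alcohol/cocaine/opiate exposure (years of use)
are drawn per subject with group-appropriate supports; controls and the
alcohol group are opiate-naive (exposure 0).  An optional injection
regenerates one exposure column with a specified population correlation to
a supplied per-subject metric, for calibrated correlation-recovery tests.

**What is not emulated.**  No image-space physics: no physiological noise
spectra, scanner drift, spatial autocorrelation, registration error or
site effects; ROI signals are stationary Gaussian within a session, real
BOLD is not.  Group differences enter only through modular coupling and
the planted edges, so a passing test shows the *estimators and inference*
behave correctly under the stated data-generating process — not that real
acquisitions satisfy that process.

## Wavelet connectivity

The MODWT is implemented as the standard circular-filter pyramid
(level-j filters upsampled by 2^(j-1), DWT filter pair rescaled by
1/sqrt(2)); filter coefficients come from PyWavelets, the pyramid is local
because PyWavelets offers only the decimated DWT and a length-constrained
SWT.  With periodic boundary the detail/smooth variances partition the
sample variance exactly (the invariant the tests assert at 1e-8); a
reflection boundary is available when wrap-around is a concern.

"Daubechies-4" is ambiguous across communities: the wavelet time-series
literature's D(4) is the 4-tap filter, which PyWavelets (counting
vanishing moments) calls `db2`.  The default is `db2` = D(4); any
orthogonal PyWavelets name is accepted.

Correlations use only non-boundary coefficients: at level j the first
L_j − 1 coefficients, L_j = (2^j − 1)(L − 1) + 1, are circularly
contaminated and are dropped (180 timepoints leave 159 scale-2
coefficients with D(4)).  A zero-variance coefficient vector yields
correlation 0 with a warning rather than NaN.  The nominal dyadic band of
scale 2 at fs = 0.5 Hz is 0.0625–0.125 Hz; the often-printed lower edge
"0.061" is a rounded variant of the same dyadic band, and the exact dyadic
convention is implemented.

## Graphs and efficiency

Edges are ranked by |r| by default (signed ranking by flag), the top
K = ⌊d·R(R−1)/2⌋ kept — `floor`, not `round`, so the count is the
conservative one — and ties broken in ascending (i, j) order so repeated
runs are identical.  Unreachable pairs contribute 0 to efficiency sums,
which keeps all metrics defined on the fragmented graphs a 5 % density can
produce (the reason efficiency is preferred over raw path length there).
Distances are breadth-first via `scipy.sparse.csgraph`; the test suite
verifies all three metrics against a brute-force Floyd–Warshall +
subgraph-enumeration oracle (1e-12) and against networkx.  Because "nodal
efficiency" names two different quantities in the connectomics literature,
both are emitted and labelled: `nodal_local_efficiency` (neighbourhood
subgraph efficiency) and `nodal_global_efficiency` (mean inverse distance).

## Network-based statistic

Edge weights are Fisher z-transformed by default (variance stabilisation
for correlations; toggleable).  Contrasts are one-sided per the configured
direction, matching separate "decreased"/"increased" connectivity tests.
The permutation p-value is (1 + #{perm ≥ obs})/(1 + n_perm), which is a
valid p-value (never 0); when C(n, n_A) ≤ n_perm the test switches to
complete enumeration and p-values are exact.  Permuted t statistics are
computed by blocked matrix products (the one-pass ss − n·mean² form, with
a relative floor of 1e-13·n·max² on the pooled variance to absorb
cancellation residue when observations are near-identical); component
sizes use a union–find over suprathreshold edges.

**Calibration design.**  The max-component-size statistic is
integer-valued, so at stringent primary thresholds its null distribution
is nearly degenerate and the achievable rejection levels sit far below
0.05 — the procedure is strictly conservative there (asserted as such in
the tests).  The two-sided calibration check (realized family-wise error
inside the 95 % binomial band around 0.05 over 200 null replicates) is
therefore run at a primary threshold of t = 0.75 with n = 15/15, where
the null max size has resolution near its 5th percentile and the band
check is informative.

## Group statistics

The split-plot ANOVA is computed directly from the classical sums of
squares (between stratum: group vs subjects-within-groups; within stratum:
drug and group × drug vs drug × subjects-within-groups).  With complete
sessions the weighted main-effect subspaces are orthogonal, so this
weighted-means decomposition coincides with sequential projection even for
unequal group sizes — which is what lets an independent projection-matrix
oracle verify the implementation to 1e-8.  Sums of squares below a
relative floor (1e-20 × data scale² × size) are treated as zero so that
degenerate inputs (all observations equal) yield F = 0, p = 1 rather than
a 0/0 artefact.  No sphericity correction is applied to the two-level
within factor (sphericity holds trivially); the three-session one-way
repeated-measures ANOVA reports Greenhouse–Geisser ε (double-centred
covariance form, clamped to [1/(s−1), 1]) and the ε-corrected p alongside
the uncorrected one.  Correlation p-values are two-sided and t-based;
partial correlations residualize both variables on [intercept |
covariates] and use df = n − 2 − k.  Per-node comparisons report raw p and
Bonferroni p = min(1, p·N_nodes).

Degrees of freedom are reported as computed from the analysed inclusion
set (e.g. F(1, 90) for the drug effect with 93 complete subjects in 3
groups); subjects missing a session are excluded with a logged count, and
the stringent motion filter removes a subject flagged in *any* session
across all sessions, since the repeated-measures design needs complete
subjects.

## Problem sizes and determinism

All simulation-based tests run at reduced sizes (12–20 ROIs, tens of
subjects, 200–1000 permutations) chosen so the full suite completes in a
few minutes while keeping every assertion's Monte-Carlo error well inside
its margin; the acceptance script runs the full default cohort (93
subjects × 3 sessions × 90 ROIs, 10 000 permutations).  Every stochastic
component takes an explicit seed (cohorts via `numpy` SeedSequence
spawning per subject-session), and identical spec + seed reproduces
byte-identical outputs, which the suite asserts end to end.

## Known limitations

Unpaired two-group NBS only (no covariate GLM, paired designs or
threshold-free enhancement); no weighted-graph or minimum-spanning-tree
metrics; no ANCOVA or likelihood-based mixed models; the generator's
stationary Gaussian model understates the heavy tails and autocorrelation
of real BOLD, so empirical error rates on real data may differ from the
calibrated synthetic ones.
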