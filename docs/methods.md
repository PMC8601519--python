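# Methods

## Signed network formation

Regional activity matrices (regions × timepoints) are correlated pairwise
with the sample Pearson coefficient; series are used as provided (no
detrending, standardization, global-signal regression or Fisher
transformation — the correlation's own affine invariance is the only
normalization). Because unequal scan lengths distort the comparability of
correlations across subjects, a cohort is first truncated to the *initial*
timepoints of its shortest series. Links are binarized to the sign of the
correlation; no significance filter is applied. An exact zero correlation
is measure-zero on real data, so it maps to an *absent* link with a logged
warning rather than an arbitrary sign. An optional threshold τ on |r|
produces partially connected networks; raising τ can only remove links.
Matrices are stored dense: at n ≈ 268 regions dense arithmetic is trivially
cheap and simpler to validate.

## Triad census and frustration

A closed triad is any node triple whose three links are all present; open
triples are never counted and never "frustrated". Classifying triads by
negative-link count gives the census (+++, ++−, +−−, −−−); frustration is
n(++−) + n(−−−), the triads with negative sign product. Two implementations
are kept permanently: an O(n³) enumeration (the oracle) and the trace
method on the polarity adjacencies P and N,

    n(+++) = tr(P³)/6,  n(++−) = tr(PPN)/2,  n(+−−) = tr(PNN)/2,  n(−−−) = tr(N³)/6.

All census arithmetic is integer; a non-exact trace division indicates a
corrupted adjacency and raises instead of rounding. A normalized
frustration (fraction of closed triads) is exposed for thresholded networks
whose closed-triad count varies; the raw count remains the primary
statistic for fully connected networks. The switching transformation
(negating all links across a node-subset cut) preserves every triad's sign
product and is used as a test harness for the balance-theoretic invariance.
No balance "energy" or sign-flip dynamics are implemented, and no
minimum-frustration optimization: the frustration count is a descriptive
statistic here.

## Negative-subnetwork topology

TMH = Σd²/Σd over nodal degrees (isolated nodes contribute zero to both
sums; an edgeless subnetwork has no TMH and raises). ASPL is the mean BFS
shortest-path length over connected unordered pairs. A printed form of the
ASPL with a single node-count denominator is dimensionally inconsistent
with a mean over pairs; we use the mean over connected pairs. Rank-based
stage comparisons are invariant to any constant-denominator choice on
connected graphs, so the headline statistics do not depend on this
decision. Disconnected pairs are excluded rather than imputed (with n or
∞), and the excluded-pair count is surfaced per subject so fragmentation —
possible at low negative density — is visible rather than silent.
Transitivity is 3 × triangles / triples with triples Σd(d−1)/2 and
triangles tr(A³)/6.

Degree distributions are pooled across the subjects of a stage and
histogram-normalized to a density; the default bin width is 1 (degrees are
integers) and is configurable since finer binning is what distinguishes a
log-normal from an exponential tail in practice. The log-normal fit is the
closed-form MLE on natural logs: μ is the mean log-degree, σ the 1/n
standard deviation of log-degrees, with asymptotic standard errors σ/√n
and σ/√(2n). Zero-degree nodes are excluded before the fit (log undefined)
and reported as a count; degrees are treated as continuous observations
(no discretization correction). An all-equal sample puts σ on the boundary
and is flagged degenerate rather than fitted.

## Statistical layer

Subjects are binned into Erikson stages by age: [6,12), [12,18), [18,40),
[40,65), [65,∞). A shared boundary age (12, 18, 40, 65) goes to the older
stage — the bins are printed with overlapping edges in common usage, so a
deterministic convention is required; it is configurable via the bounds
constant. Ages below 6 are outside the design and raise.

Normality is screened per stage with Shapiro–Wilk; any rejection at α =
0.05 routes the comparison to rank-based tests (a constant group, for
which W is undefined, counts as a degenerate rejection). Stage comparisons
use the tie-corrected Kruskal–Wallis H (df = k−1, chi-square p), which is
insensitive to the cohort's unequal stage sizes; an all-tied sample yields
H = 0 by convention. Post hoc pairs use Dunn's z with the pooled
tie-corrected rank variance

    var = (N(N+1)/12 − Σ(t³−t)/(12(N−1))) · (1/nᵢ + 1/nⱼ),

two-sided normal p-values, and Benjamini–Hochberg step-up adjustment
*within* each feature's set of stage pairs (not across features). Sex
contrasts use the two-sided Mann–Whitney U; both orientations (U_a,
U_b = n_a·n_b − U_a) are reported since the orientation convention is not
universal. The p-value is exact for tie-free samples of at most 20 and the
tie-corrected normal approximation otherwise. All tests are two-sided at
α = 0.05.

The frustration / negative-density relation is fitted by OLS for
polynomial degrees 1–3. Nested models are compared with the partial F
test, ((RSS_small − RSS_big)/Δdf)/(RSS_big/df_big) — equivalent to the
likelihood-ratio test under Gaussian errors and directly comparable to
published F-values. Selection steps up from linear and stops at the first
non-significant addition. A lower-degree fit whose RSS is at rounding
level (≤ 10⁻¹² of the total sum of squares) is treated as saturated, so
noiseless inputs select the true degree instead of chasing floating-point
noise. The stage × density "ANCOVA" is the partial F test of adding
stage-specific polynomial terms to a model with shared polynomial terms
plus stage intercepts; the polynomial degree defaults to the selected one.
Which polynomial terms interact with stage is an interpretation (the
conventional full-interaction form is used); it is configurable through
the `degree` argument.

## Synthetic cohorts

The generator exists to make every downstream stage testable with known
ground truth; it does not model BOLD hemodynamics, temporal
autocorrelation, scanner noise, site effects, or volumetric data, so
passing tests certify the *pipeline's* correctness and calibration, not
any claim about real brains. Two entry points mirror the pipeline's two
input kinds:

- **factor_timeseries** — region i's series is λᵢ·g(t) + noise with a
  single latent factor g (the factor count is a knob); a stage-controlled
  fraction of loadings is negative, so the expected correlation sign
  between two regions is the product of their loading signs, exact as
  noise → 0. Loading magnitudes are drawn in [0.8, 1.2], bounded away from
  zero so the factor dominates at low noise.
- **direct_network** — fully connected signed networks with each
  subject's negative-link probability drawn from a Beta distribution
  centred on the stage target with concentration κ (default 400, i.e. a
  between-subject density SD of ≈0.015 at density 0.10). Expected
  frustration is monotone in density (C(n,3)·(3p(1−p)² + p³)), so a
  u-shaped density profile plants a u-shaped frustration profile.

Defaults are fixed once: five stages with per-stage sizes 121 / 148 / 265 /
211 / 48 and female fractions matching the pooled study demography,
268 regions, 150 timepoints (a typical eyes-open resting scan at TR = 2 s),
noise SD 1.0, and the u-shaped negative-density profile
(0.14, 0.12, 0.10, 0.12, 0.14) with its minimum at early adulthood —
negative links are a minority of resting-state links. Sex is independent
of all features by default; an additive `sex_effect` density shift for
males is available for power studies. A cohort seed deterministically
spawns per-subject seeds, so identical spec + seed gives bit-identical
cohorts. Frustration injection for balance tests uses `flip_edges`
(sign-negate k present edges; flipping one edge of a balanced complete
K_n frustrates exactly the n−2 triads containing it).

Simulation-based tests and the analysis scripts run scaled-down problem
sizes (typically 30 subjects/stage and 40–60 regions) while keeping the
default effect-size knobs (density profile, dispersion); the planted
effects and calibration properties being tested are size-independent.

## Pipeline and formats

The runner executes truncate → correlate → binarize → split → census →
topology → feature table → statistics, writing a tidy per-subject feature
CSV, a statistics report (JSON + CSV) and a manifest with SHA-256
checksums of every artifact; runs are deterministic for fixed inputs and
config, and benchmark mode (precomputed networks in) touches no random
state. Fragmented negative subnetworks and exact-zero correlations are
warnings, not errors, since both occur on legitimate inputs; missing
subject files and metadata mismatches abort before anything is written.
All on-disk formats are plain text with 0-based node indices documented in
file headers; dense adjacency CSVs carry region labels as header row and
index column, so export → import round trips are exact.

## Known limitations

- The importer validates symmetry, entry domain and shape but cannot know
  a deposited archive's semantics; mapping an external layout onto the
  dense/edge-list formats is the user's step.
- ASPL on a fragmented subnetwork mixes component scales; the excluded-pair
  diagnostic should be checked before comparing fragmented subjects.
- The log-normal fit ignores the discreteness of small degrees; at typical
  negative-subnetwork densities (peak degree ≈ 10) the bias is negligible
  relative to the reported standard errors.
- The parametric (ANOVA) branch after a passing normality gate is
  deliberately absent: the gate only reports, and comparisons always use
  the rank-based route, matching the analysis this package reproduces.
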