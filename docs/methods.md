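# Methods

This note documents the models, numerical choices and limitations behind
`pmenet`.  It is written for users who need to know exactly what the
pipeline computes and what the validation on synthetic data does and does
not demonstrate.

## Preprocessing

Rarefaction draws, for each sample independently, a multivariate
hypergeometric subsample of exactly `depth` reads (subsampling without
replacement, matching the semantics of standard amplicon workflows).
Samples whose total is below the depth are dropped with a warning rather
than failing the run, so partial designs stay usable.  The default depth
is 48,000 reads.

The relative-abundance filter removes ASVs whose *pooled* total (across
all samples, computed after rarefaction) falls strictly below the cut —
default 1e-5, i.e. 0.001%; an ASV exactly at the cut is retained.  The
pooled denominator is a deliberate choice: a per-sample variant is
equally defensible but changes which rare, patchily distributed ASVs
survive; the pooled rule is simpler and is the one all reported numbers
use.

The prevalence filter runs after group selection and keeps ASVs present
(count > 0) in strictly more than `min_prevalence` (default one half) of
the group's samples, with the group's post-rarefaction sample count as
denominator.

## Correlation

Spearman's rho is computed as the Pearson correlation of midranks
(`scipy.stats.rankdata` + `numpy.corrcoef`), which handles ties —
ubiquitous in zero-inflated count data — and reduces to the textbook
1 − 6Σd²/(n(n²−1)) formula when no ties exist.  Because ranks are
invariant under strictly monotone transforms, no log or power transform
of the counts is applied (it would be a no-op).  An ASV with zero
variance across the selected samples has undefined correlations; its row
is set to 0 with a warning, which leaves the node to drop out of the
network as isolated.

## RMT threshold selection

For each candidate threshold, entries with |rho| below it are zeroed,
rows/columns with no surviving off-diagonal entry are removed, and the
eigenvalues of the remaining symmetric submatrix are computed.

**Unfolding.**  Spacing statistics require unit local mean spacing.  The
empirical cumulative spectral distribution (staircase at midrank heights
i + 1/2) is interpolated by a monotone cubic (PCHIP) curve through
quantile-spaced knots — max(5, round(sqrt(m))) knots by default for m
eigenvalues, configurable; fewer knots give a smoother density estimate.
PCHIP through subsampled knots is monotone by construction, so the
mapped eigenvalues are ordered and their consecutive differences are the
unfolded spacings (mean exactly 1 between the first and last knot).  A
fraction of 2.5% of levels is discarded at each spectral edge before
unfolding: the smooth density estimate is unreliable at the edges, and
detached extreme levels — notably the Perron (leading) eigenvalues
contributed by dense modules — do not belong to the bulk ensemble the
spacing statistics describe.  Without this trim, the unfolding across
the bulk-outlier gap systematically distorts a handful of spacings and
biases the Poisson test toward rejection.

**Poisson test.**  The spacing histogram is tested against P(s) = e^(−s)
by chi-square with equal-probability bins under the reference (so every
bin has expected count m/n_bins); n_bins = max(5, ceil(1 + log2 m)),
dof = n_bins − 1, acceptance at p ≥ 0.05.  The same machinery tests
against the Wigner surmise P(s) = (πs/2)e^(−πs²/4) for GOE checks.
Calibration measured during development: i.i.d. exponential spacings are
rejected at ~5–7% as expected; planted decoupled-block spectra at ~3%.

**Selection rule.**  Automatic selection returns the smallest threshold
at which Poisson is accepted *and* remains accepted at the next testable
threshold.  Requiring two consecutive acceptances suppresses single-
threshold flickers of the 5%-level test; the rule is deterministic.
Thresholds whose submatrix has fewer than 20 eigenvalues are recorded as
untestable.  Fixed mode returns the requested threshold verbatim and is
intended for comparing networks under identical conditions (the
conventional fixed value is 0.83).  RMT-thresholding tools differ on
whether they threshold rho or |rho|; `pmenet` thresholds |rho| and
keeps the sign as an edge attribute, since ecological networks at a
single threshold contain both positive and negative links.

## Topology

All summary metrics operate on the unsigned, unweighted skeleton; signs
remain edge attributes.  Average path length is the mean geodesic over
connected ordered pairs only (fragmented networks then report finite
values); average clustering counts nodes of degree < 2 as 0; the degree
power-law R² is the least-squares fit of log10 frequency vs log10 degree
over degrees with nonzero frequency, undefined below three distinct
degrees.  Modules come from Clauset–Newman–Moore greedy modularity
maximization (networkx implementation), with module ids ordered by each
module's smallest node label for reproducibility, and M evaluated by the
direct Newman formula on the final partition.  "Network size" counts
only nodes with at least one surviving link.

## Node roles

Zi uses the *population* standard deviation of within-module degree over
the node's module (Guimerà–Amaral convention); modules whose members all
have equal within-module degree (cliques) get Zi = 0 rather than NaN.
Pi = 1 − Σ_t (k_it/k_i)².  Cutoffs Zi = 2.5 and Pi = 0.62 are boundary-
inclusive on the peripheral side.  Note a structural fact worth keeping
in mind when reading ZP plots: a node linking into only two modules can
never exceed Pi = 0.5, so connectors require participation in at least
three modules.

## Null ensembles

Maslov–Sneppen double-edge swaps (networkx `double_edge_swap`), default
100 swaps per edge and 100 ensemble members, preserve every node's
degree exactly.  Graphs admitting no valid swap (fewer than four nodes)
are returned unchanged with a warning.  Edge weights and signs are
redistributed randomly over the rewired edge set, preserving the global
positive-link count while breaking any sign–topology association.
z = (empirical − ensemble mean)/ensemble sd, with sd undefined (and z
reported missing) below two members.

## Synthetic data generator

The generator emulates the target study design — 2 treatment groups ×
5 sampling weeks × 3 layers × 6 replicates = 180 samples at a fixed
per-sample depth — with planted structure:

- each of `n_modules` modules has one latent N(0,1) factor per sample;
  member ASVs load with ±sqrt(rho_in) (a `neg_fraction` = 0.3 of members
  loads negatively, planting anti-correlated pairs); residual latent
  variance is 1 − rho_in, so pairwise latent correlation is ±rho_in;
- background ASVs load sqrt(rho_out) on one weak global factor;
- one hub per module carries a boosted loading (rho_in + 0.6(1−rho_in))
  and an elevated base abundance, making it the strongest-correlated,
  identifiable member;
- latent log-abundances (base abundance ~ N(0, 1.2²) plus 1.5 × latent,
  natural-log units) are softmax-normalized per sample and counts drawn
  multinomially at the stated depth — reproducing the constant-sum,
  compositional character of rarefied tables.

Compositional closure is a real artifact of this construction: module
factors move the softmax denominator and would induce spurious
cross-module correlations of up to ~0.4 at these design sizes.  The
generator therefore includes a stable core background community
(`core_background_boost` = 3.0 log-units on background base abundances)
that dominates the denominator, restoring cross-module correlations to
≈ rho_out as specified.  Real sediment communities have such cores, but
this also means the generator does *not* probe the regime where a few
correlated taxa dominate the composition; in that regime rank
correlations carry closure-induced dependence that no threshold can
fully remove, and inference quality will be lower than the synthetic
benchmarks suggest.

Other simplifications relative to real data: no overdispersion beyond
the latent lognormal noise (no Dirichlet-multinomial), no phylogenetic
correlation between taxonomy and module membership, no time or depth
trends within the design (labels are exchangeable), and taxonomy strings
are synthetic.  Passing benchmarks therefore demonstrate correctness of
the inference machinery under a known factor model, not performance on
arbitrary real communities.

For threshold-recovery benchmarks the generator also builds correlation
matrices directly (no counts): four dense 50-node blocks with one-factor
entries a_i a_j (a_i ~ U[0.93, 0.97], so |r| ≈ 0.9) and dense
U(−0.3, 0.3) between-block noise.  Two spectral subtleties matter and
are built in deliberately.  First, a literal rank-one-plus-diagonal
block has a spectrally *rigid* bulk (eigenvalues strictly interlace the
diagonal entries), which is not Poisson; each block is instead
synthesized from its spectrum — leading eigenvector along the loading
vector, plus i.i.d. bulk eigenvalues with random eigenvectors — so the
decoupled blocks genuinely carry independent levels.  Second, the unit
diagonal is enforced by Bendel–Mickey/Davies–Higham Givens rotations
(orthogonal similarity: the spectrum is preserved exactly, with bulk
eigenvalues pre-scaled so the trace equals the block size); a naive
congruence rescaling would shift levels by a few mean spacings and
reintroduce repulsion.

## Reduced-size benchmark

The end-to-end benchmark runs the full pipeline (filters → Spearman →
automatic RMT threshold → network → modules → roles) on the complete
180-sample design with 4 modules × 20 ASVs + 80 background ASVs at
10,000 reads/sample, rho_in = 0.85, rho_out = 0.05.  Reported scores:

- **module NMI**: normalized mutual information between inferred modules
  and planted membership, over planted ASVs retained in the network;
- **sign agreement**: fraction of same-module edges whose sign matches
  the product of the planted loading signs;
- **hub recall**: fraction of planted hubs that are the top node of
  their inferred module by within-module strength (sum of |rho| over
  same-module edges).  Strength is used because at the auto-selected
  threshold — which sits *below* the weakest within-module correlation —
  modules are saturated near-cliques and plain degree cannot distinguish
  any member.

Typical results (20 seeds): threshold ≈ 0.2, NMI ≥ 0.9 in 19/20 runs
with median 1.0, sign agreement 1.0, median hub recall 0.75.  The
statistical character of the selection rule means occasional misses are
expected: each plateau threshold is a 5%-level chi-square draw, so a few
percent of seeds select a threshold just outside the planted gap.

## Degenerate inputs and tie-breaking

Duplicate eigenvalues yield zero spacings (handled, and correctly
rejected as non-Poisson when dominant).  Fully degenerate spectra cannot
be unfolded and raise.  Zero-variance ASVs correlate at 0 (see above).
Greedy merges are deterministic given node insertion order; module ids
are relabeled by smallest member.  Empty networks at a threshold raise
rather than return empty objects; empty taxon subnetworks (anchor absent
from a network) return an empty view with a warning, since taxa
genuinely disappear from some group networks.

## Known limitations

- Spearman co-occurrence is not causal and remains sensitive to
  compositional effects; no compositionally-aware estimator (e.g.
  proportionality) is provided.
- The NNSD chi-square has limited power on spectra near the 20-level
  minimum; thresholds accepted on very small submatrices deserve manual
  inspection of the scan table.
- Only unweighted, unsigned modularity is implemented; signed or
  weighted community structure is out of scope.
- Average path length over connected pairs is one of several defensible
  conventions for fragmented graphs; values are not comparable with
  harmonic-mean ("efficiency") definitions.
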