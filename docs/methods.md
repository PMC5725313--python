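# Methods

## The problem

An fMRI statistical map (an SPM{T}, SPM{F} or Z volume from a GLM or ICA
analysis) is conventionally described anatomically — cluster coordinates,
gyri, Brodmann areas. `icnengage` instead describes it *functionally*: how
much does the map engage each of a set of intrinsic connectivity networks
(ICNs, also called resting-state networks)? The ICNs act as a functional
atlas; the output is a small table of engagement metrics per network,
suitable for comparing maps across conditions, sessions, subjects, or
(e.g.) phases of an epileptic seizure.

## Atlas construction

The raw material is a set of K co-registered prototype Z-score volumes
(one per network, e.g. ICA group maps), on a common template grid (shape +
4×4 voxel-to-world affine, typically MNI). With a membership threshold T
(default Z = 3, strict inequality):

* masked maps: `ICN_i(n) = Z_i(n)` if `Z_i(n) > T`, else missing (NaN);
* binary masks: `B_i(n) = 1` iff `Z_i(n) > T`;
* winner-take-all labels: `l(n) = argmax_i ICN_i(n)` over supra-threshold
  components, NaN when none passes. Ties go to the lowest component
  index, deterministically (ties have measure zero on real Z maps; the
  rule exists for reproducibility, not fidelity to any reference
  implementation).

The binary masks may overlap; the label volume is their mutually
exclusive resolution. Artefact components are atlased like any other and
carried with a flag — excluding them is a reporting choice.

Persistence: `labels.nii.gz` (float, NaN = unlabelled), `zmaps.nii.gz`
(4-D masked-Z stack), `meta.json` (schema-versioned: names, T, artefact
flags, provenance). The round trip is bit-exact on labels and metadata
and float32-exact on Z.

## Input handling

Input maps (NIfTI-1, optionally gzipped, or Analyze 7.5) are reconciled
onto the atlas grid — never the reverse — by mapping each atlas voxel
centre through the two affines and interpolating the source volume there:
trilinear for continuous statistics (the default), nearest-neighbour for
masks and labels. NaN is the missing-data sentinel and poisons any
trilinear interpolation that touches it; voxels outside the source field
of view become NaN; disjoint fields of view are an error. The
interpolant for this step is a package choice — there is no canonical
convention to defer to.

Significance thresholding retains `value > threshold` (strict, matching
atlas construction) and optionally removes 26-connected clusters (SPM's
extent convention) smaller than k voxels. Deactivation maps are handled
by an explicit sign flip, never implicitly.

## Engagement metrics

A voxel is *active* when its value is finite and non-zero. Intersections
`|SPM ∩ ICN_i|` are counted against the binary masks `B_i` by default,
since the metric definitions are written in terms of the per-network
masks; a `counting="labels"` switch uses the exclusive labels instead for
strictly additive accounting (both counts are always computed). With
`u_n = clip((v_n − min)/(max − min), 0, 1)` the statistic normalised to
the map's bounds and `U_i = Σ u_n` over active voxels of network i:

| metric | definition | family |
|---|---|---|
| I_i | inter_i / size_i | spatial |
| IR_i | inter_i / Σ_j inter_j | spatial |
| OL_i | inter_i / n_active | spatial |
| SQ_i | 2·inter_i / (n_active + size_i) | spatial (Sørensen–Dice) |
| J_i | inter_i / (n_active + size_i − inter_i) | spatial (Jaccard) |
| MA_i | Σ v_n over active∩B_i / inter_i | activation |
| MA_N,i | U_i / inter_i | activation |
| IR_M,i | MA_N,i / Σ_j MA_N,j | activation |
| RA_N,i | U_i / Σ_j U_j | activation |
| I_M,i | U_i / size_i | density |
| r_i | Pearson r of map with prototype Z | correlation |

Globals: `I_T = Σ inter_i / Σ size_i` (a size-weighted mean of the I_i,
hence always between their min and max), `MA` and `MA_N` (pooled raw and
normalised means over all network-active voxels), `I_T_M = Σ U_i / Σ size_i`.

Identities maintained by construction and asserted in tests:
`SQ = 2J/(1+J)`; `Σ IR_i = 1` and `Σ RA_N,i = 1` whenever defined; all
spatial ratios in [0, 1].

Notes and choices:

* **Per-voxel normalisation.** The normalised numerator is
  `Σ (v_n − min)/(max − min)`, i.e. the minimum is subtracted per voxel,
  not once from the sum. This follows from the two-voxel hand evaluation
  `{min+Δ, max} → (Δ + (max−min))/(max−min)` and keeps MA_N,i in [0, 1].
* **Bounds.** Default (min, max) over the map's active voxels. Passing
  explicit bounds reproduces session-matched normalisation (shared
  bounds make MA_N comparable across maps of one session; spatial
  metrics are unaffected). Non-bracketing bounds clip with a warning; a
  constant map (max = min) is a hard error, since the normalised metrics
  have no defined value.
* **Undefined cells.** Where no voxel of a network is active, MA_i and
  MA_N,i are undefined: reported as NaN plus an explicit `defined` flag,
  never silently zero.
* **Correlation domain.** r_i is computed over voxels belonging to *any*
  network (correlation over the whole grid would be dominated by
  out-of-brain zeros), using the unthresholded input when the pipeline
  has it. Because the atlas persists only masked prototype Z,
  sub-threshold prototype values are treated as 0 in that domain; this
  is a package convention, stated here because the alternative (raw Z)
  is not recoverable from a saved atlas.
* T, F and Z maps share one code path; the sign semantics of the
  statistic are the user's responsibility.

## Test–retest repeatability

ICC flavour: two-way mixed, consistency type (Shrout–Fleiss ICC(3,1)),

    ICC = (MS_subjects − MS_error) / (MS_subjects + (k−1)·MS_error),

chosen because it does not penalise systematic inter-session offsets; an
absolute-agreement ICC(2,1) is available behind a flag for sensitivity
analysis. Estimates can be negative (typically reflecting minimal or null
overlap of a network with the maps); degenerate inputs (zero variance,
fewer than 2 complete rows) return NaN with the dropped-row count
surfaced.

Voxel-wise ICC fields are summarised as the mode over positive values
using 80 equal bins on [0, 1]; the mode is reported as the centre of the
argmax bin (the binning is fixed; the representative point is a package
choice), ties resolved to the lowest bin, ICC = 1 falling in the last bin.

Score sets (tidy: subject, session, ic, basemap, metric, value) are
analysed at three collapsing levels — per item, per base map (pooled
across ICs), global (pooled across ICs and base maps) — for two session
flavours: *within* uses the same-day session pair as the two columns;
*between* stacks the (baseline, later) pairs as row blocks. Each stacked
block's columns are demeaned before stacking (a "mean-free" pairing):
otherwise per-block session offsets masquerade as subject disagreement
and the offset-invariance that motivates the consistency ICC is lost
across blocks. Undefined metric cells are dropped pairwise with the
fraction reported.

Cross-atlas agreement: `topk_agreement` counts base maps shared by the
top-k (default 3) sets of two engagement tables under a declared
base-map correspondence, with rank-k ties broken deterministically by
index order. Under independent random tables its expectation is the
hypergeometric k²/K.

## Metric reduction

The 11 per-network metrics are heavily redundant (five are ratios of the
same intersection count). `MetricReducer` standardises the observation ×
metric matrix (rows with undefined cells dropped and counted), then runs
two stages of principal-axis factoring with 2 factors and a varimax
rotation:

1. stage 1 on all metrics retains 5: the strongest |loading| metrics on
   the two dominant factors (taken alternately) plus the
   highest-uniqueness metric;
2. stage 2 on the survivors selects 3: the top loader on each factor and
   the highest-uniqueness survivor, with rationale codes attached.

Numerical conventions: factors ordered by sum of squared loadings;
loading sign fixed by making each factor's largest-magnitude loading
positive; communalities initialised at squared multiple correlations and
iterated to 1e-6; collinear or constant columns are rejected by name.
Retention counts and factor number are parameters — the mixed
"high loadings / high uniqueness" criterion has no canonical numeric
cut-off, so the rule above is the package's documented default.

## The synthetic world

The fixture generator states one world and keeps it: a 28³ grid of 2 mm
voxels, K = 10 components, blob amplitudes uniform in [5, 9], Gaussian
blob radius 4 voxels with 2-voxel-FWHM smoothing, membership and input
thresholds Z = 3, and 25 subjects × 3 sessions for score sets. Blob
centres are spread by greedy farthest-point sampling so supra-threshold
regions overlap only moderately, as real ICN prototypes do.

* `make_atlas_fixture` returns the Z maps plus ground-truth labels and
  sizes computed by an independent per-voxel loop — the construction
  oracle for the atlas builder.
* `make_activation_fixture` samples `⌊I_i·|ICN_i|⌋` active voxels from
  each component's *exclusive* supra-threshold region, so the achieved
  involvement is exactly the floor-quantised target for every component
  simultaneously; targets exceeding the exclusive capacity are an error.
  Active values are uniform in (threshold, amplitude], so the map passes
  input thresholding unchanged.
* `make_session_scores` draws `y_st = u_s + b_t + d_s·[t≥2] + e_st` with
  independent normal subject (σ_u²), session-offset (σ_b²), between-day
  drift (σ_d², default 0) and residual (σ_e²) effects. The offset term
  exists so the consistency-ICC's insensitivity to systematic
  differences is testable; the drift term (a long-term subject-specific
  change shared by the later same-day pair) is what makes within-session
  ICC genuinely exceed between-session ICC. True consistency ICC of the
  drift-free model: σ_u²/(σ_u² + σ_e²).

All generators are deterministic under a fixed `numpy.random.default_rng`
seed.

What green tests establish — and what they do not: the synthetic maps
have no haemodynamic structure, no spatial autocorrelation in the
activation placement, no inter-subject anatomical variability, and the
score model is additive Gaussian. The tests therefore establish the
*computational* correctness of the metrics, the ICC estimator, and the
reduction procedure on their stated definitions, not the neuroscientific
behaviour of the toolbox on real resting-state or clinical data.

## Known limitations

* Atlases are deterministic winner-take-all; probabilistic (weighted)
  base atlases are out of scope.
* No random-field-theory thresholding and no reading of SPM.mat
  workspaces; thresholds are user-supplied numbers.
* No statistical inference across groups of engagement tables; the
  toolbox is a data summariser.
* The correlation metric's sub-threshold-Z convention (above) makes r_i
  depend mildly on the atlas threshold.
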