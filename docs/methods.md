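# Methods

## Scope and design

The package is an analysis pipeline: synthetic resting-state EEG cohorts →
band-pass preprocessing → pairwise functional connectivity (PLI, MSC,
epoch-based entropy) → group-average weighted graphs → clustering /
shortest-path / modularity analysis → Kruskal–Wallis group statistics. The
clinical data the analysis design targets are not publicly deposited, so the
synthetic generator is a first-class, tested component: it defines the
study conditions under which every downstream claim is validated. Passing
tests therefore demonstrate that the *machinery* recovers known structure
under a controlled generative model — not that any clinical effect exists.

## Synthetic cohort generator

Groups default to SCI n=22, MCI n=52, AD n=28; 30 channels in the standard
10–20 anterior→posterior order; 256 Hz; one 20-s segment per subject
(configurable count — how many clean segments per subject enter the
averages is a free knob of the design).

Per band, each subject receives one band-wide global driver and three
regional sources (anterior / central / posterior), all third-order
Butterworth band-limited unit-variance Gaussian noise. Channels blend the
regional sources with triangular weights centred on their position along
the anterior–posterior axis. With coupling `c = band_coupling[(group,
band)]` the channel variance splits into

    global    G(c) = c^1.8
    local     L(c) = 2.1 · c^0.6 (1 − c)^2
    intrinsic 1 − G − L

These shapes were chosen (and fixed before the validation runs) so that

- `c = 0` gives fully independent channels and `c = 1` an identical
  common source on every channel (the two exact limits the generator must
  honour);
- at low-to-mid coupling the short-range (regional) share dominates, so
  the strongest edges join neighbouring electrodes and long-range shortest
  paths route through relay chains (many hops, weak triangles);
- at high coupling the global share dominates and every pair connects
  directly (hop counts collapse to 1, clustering rises toward 1).

Each channel's shared content is delayed by a fixed fractional lag (uniform
0–6 ms, drawn once per cohort from the master seed), giving consistent
non-zero phase offsets so the PLI is non-degenerate; a zero-lag common
source would pin PLI at 0 by construction.

A second knob, `band_amplitude[(group, band)]`, scales each group's signal
per band and carries the *information-content* contrast (EEG slowing:
cognitive decline shifts power toward slow rhythms). Defaults:

| band  | SCI  | AD   | MCI  |   | coupling SCI/AD/MCI |
|-------|------|------|------|---|---------------------|
| delta | 0.50 | 1.00 | 2.00 |   | 0.25 / 0.45 / 0.70  |
| theta | 1.20 | 1.00 | 0.85 |   | 0.50 / 0.45 / 0.40  |
| alpha | 2.00 | 1.00 | 0.50 |   | 0.75 / 0.50 / 0.25  |
| beta  | 2.00 | 1.00 | 0.50 |   | 0.70 / 0.45 / 0.20  |

Broadband Gaussian noise of scale `noise_sd = 0.3` is added. All
randomness flows from one master seed through `SeedSequence` spawning
(child 0: cohort-level lags; children 1..n: subjects), so cohorts are
bit-identical under identical configs.

What the generator does **not** emulate: 1/f spectra, artifacts, realistic
topographies or volume conduction. Group contrasts enter only through the
two knobs above, so ordering recovery shows sensitivity of the pipeline to
coupling and amplitude structure, nothing more.

## Preprocessing

50 Hz second-order IIR notch (Q = 30) and third-order Butterworth
band-passes into delta 1–4, theta 4–8, alpha 8–12, beta 12–30 Hz, both
applied forward–backward (zero-phase) so phase-based connectivity inherits
no filter delay; the effective magnitude response is the square of the
single-pass response. Whether the original acquisition chain used
zero-phase filtering is unknown; the choice is exposed in the run config.
The first and last second of each filtered segment (1.5 s in the scaled
study, where delta transients are long relative to the segment) are
excluded from connectivity estimation.

## Connectivity

- **PLI**: analytic-signal phases; `|mean sign sin Δφ|`. Constant inputs
  raise a degenerate-signal error.
- **MSC**: Welch windows of 2 s with 50 % overlap by default (≥ 2 Hz
  resolution, 19 windows per 20-s segment; 1-s windows in the scaled
  study); coherence averaged arithmetically over in-band bins. At least
  two windows are required (one window gives identically 1). Under
  independence the estimator sits at its ≈1/M small-sample bias, which the
  tests treat as the null floor.
- **EpEn**: see below. Matrices are symmetric, nonnegative, diagonal
  stored as 0 and excluded everywhere downstream.

## Epoch-based entropy

A continuous left-to-right HMM (self-transitions plus forward skips of at
most one state — Bakis topology) with Gaussian-mixture emissions models the
1-D (single channel) or 2-D (channel pair) observation sequence; full
covariances by default, so the cross term carries the inter-channel
dependence. Defaults at full scale: 10 states × 3 mixtures over 20 s
(≈2-s epochs); the scaled study uses 3 states × 1 mixture over 9 s.

**Fitting.** Baum–Welch is implemented in-package as a MAP-EM:

- deterministic initialisation from a uniform segmentation of the sequence
  into `n_states` contiguous blocks (mixture means from quantile chunks,
  shared block covariance) — identical data give identical fits;
- an inverse-Wishart ridge on every covariance, `Ψ = 10⁻³·v̄·I` with `v̄`
  the mean observation variance (scale-aware, so fits are equivariant
  under amplitude rescaling) and ν = D + 2: the mixture likelihood is
  otherwise unbounded (a component can collapse onto one sample);
- a Dirichlet prior of 5 pseudocounts on self-transitions discouraging
  one-sample states;
- a free, EM-updated entry distribution: the Viterbi path may begin in any
  state and remains non-decreasing; forcing entry at state 1 makes surplus
  states collapse into degenerate "sliver" epochs at the segment start;
- convergence when the relative change of the training objective (the
  penalized log-likelihood, which MAP-EM never decreases) drops below
  `tol` (10⁻⁴ relative by default); non-convergence is flagged, never
  silent.

**Segmentation and entropy.** A custom Viterbi (ties broken toward the
lower state index) yields contiguous epochs, matched across the two
channels but not of equal length. Two epoch-entropy estimators ship:

- `literal` (default of the low-level API): `−Σ_{z∈S_i} P_i(z) log₂ P_i(z)`
  summed over the epoch's observations with the state's mixture *density*
  floored at 10⁻³⁰⁰. Because the density is not a probability mass this
  sum is length-dependent, can exceed usual entropy bounds and goes
  negative wherever `P_i(z) > 1`; it is retained as the printed form of the
  measure.
- `normalized`: the per-sample average negative log₂-density, a plug-in
  estimate of the epoch's differential entropy in bits. This variant is
  stable, scales correctly with signal amplitude (`+log₂ σ_x σ_y`) and is
  what the bundled study configuration and the ordering-validation runs
  use: at desk-scale segment lengths the literal sum is dominated by a few
  peaked epochs and is unusable as a graph weight. Neither variant is
  claimed to be "the" original implementation.

**Degenerate-state pruning.** On data without genuine epoch structure the
left-to-right chain can still collapse a surplus state onto a couple of
samples; since Eq.-style averaging weights every epoch equally, such
slivers poison the measure. `epen_pair` therefore refits with one state
fewer while any Viterbi epoch is shorter than `0.25·T/n_states` (at least
2 samples). `fit_hmm` itself returns the unpruned fit.

Observations are standardized per channel before fitting by default
(prevents scale-driven degeneracy); the study configuration disables
standardization so the amplitude contrast reaches the entropy. Negative
pair values (possible for the literal estimator) are floored at 0 when
assembling adjacency matrices, and recorded in the matrix metadata.

## Graph analysis

Computed on group-average matrices (per-subject computation available).

- **Clustering**: geometric-mean triangle form with weights normalized by
  the maximum off-diagonal weight (keeps C_i ≤ 1; the raw form can exceed
  1 for weights > 1). Nodes with fewer than two nonzero neighbours get 0.
- **Shortest paths**: the default weight-to-distance transform is
  reciprocal, `d = 1/w` — summing raw connectivity weights along a path
  would make strong coupling "long", contradicting the efficiency
  interpretation of short paths; a `literal` mode (`d = w`) is available
  and tested. Dijkstra per source with deterministic tie-breaking (shorter
  distance, then fewer hops, then lexicographic node sequence), so the
  path registry — which records the full node sequence of every pair's
  optimal route — is unique. Per-node outputs: mean distance over the
  n−1 peers and mean hop count. Disconnected pairs yield infinite L,
  flagged rather than hidden.
- **Modularity**: Louvain (networkx) over seeded restarts, scored with the
  standard Newman weighted form `Q = (1/2m) Σ [w_ij − s_i s_j/2m] δ(m_i,m_j)`.
  A variant normalizer (the weighted characteristic path length) is
  available in `modularity_score` for comparison; the package does not
  adopt the convention of reporting Q = 1 for a single-module graph (the
  standard form gives 0 there) — module count and Q are reported
  separately. Resolution is fixed at 1.

## Statistics

Kruskal–Wallis (tie-corrected, chi-squared p) per electrode and band; the
per-subject, per-electrode summary is the node's mean connectivity to the
other n−1 electrodes (node strength/(n−1)), recorded in every output.
Whole-network tests compare the n per-node clustering values across
groups. p < 0.05 is applied only at reporting; no multiple-testing
correction by default (a Benjamini–Hochberg helper exists). The
all-identical degenerate case returns H = 0, p = 1.

## Validation strategy and problem sizes

Unit and property tests check every operation against independent oracles:
DFT amplitudes for the filters, closed forms for PLI/MSC, brute-force
triple loops, Floyd–Warshall with path reconstruction and exhaustive
partition enumeration for the graph metrics, exhaustive monotone-path
search for Viterbi, scipy/hmmlearn/statsmodels cross-checks for densities,
likelihoods and p-value adjustments.

End-to-end ordering recovery runs the full pipeline on scaled cohorts —
6/6/6 subjects, 6 channels spanning the three montage regions, 12-s
segments at 64 Hz, delta/alpha/beta, MSC + EpEn (3 states, 1 mixture,
10 EM iterations) — and checks, over 20 seeded replicates, the expected
orderings: delta connectivity MCI > AD > SCI and alpha/beta connectivity
SCI > AD > MCI for both measures; delta clustering highest in MCI and
lowest in SCI on the entropy graphs; alpha hop counts lowest in SCI on the
coherence graphs (no group below SCI, strictly below MCI — at high
coupling two groups can tie at the fully-direct floor where every hop
count is exactly 1). These sizes are the package's scaled study design;
the full-scale defaults remain available through `CohortConfig()` and
`EpEnParams()`.

## Known limitations

- Hop-count and clustering contrasts on *synthetic entropy* graphs are
  weakly identified: the normalized EpEn carries a large common offset, so
  relative weight contrasts are compressed and shortest paths are almost
  always direct; the topology contrast is therefore carried by the
  coherence graphs in the validation.
- The literal entropy estimator is faithful to its printed form but is not
  a usable connectivity weight at desk scale (sign-indefinite,
  length-dependent); see above.
- PLI on the synthetic cohorts responds to coupling only through the small
  fixed channel lags; in delta the phase offsets are tiny and PLI is close
  to its null level for all groups.
- Whether the HMM should be fit per band or on broadband data is not fully
  determined by the design; the pipeline fits per pair per band,
  consistent with band-specific adjacency matrices.
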