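# Methods

`mibrain` estimates resting-state EEG functional connectivity with histogram
mutual information (MI), reduces each subject's connectivity matrix to binary
networks by proportional thresholding, computes graph-theory metrics on them,
and compares the metrics across four groups (healthy controls and three
post-stroke groups of increasing depression severity: HC, PSND, PSMD, PSD)
with per-threshold one-way ANOVAs and homogeneity-gated post-hoc tests. A
seeded synthetic-data generator with known coupling structure makes every
stage testable end to end.

## Mutual-information connectivity

For two channels within one epoch, MI is the plug-in estimate

    MI(X, Y) = H(X) + H(Y) − H(X, Y)   (natural log; nats)

with entropies from equal-width histograms. Defaults: 11 bins per signal over
each signal's own [min, max] within the epoch — the conventional bin count
for 1,250-sample epochs (5 s at 250 Hz) — with the maximum value assigned to
the last bin. Marginal probabilities are the row/column sums of the joint
histogram, not independent 1-D histograms; this makes the identity exactly
nonnegative and MI(x, x) = H(x) hold to machine precision. Entropy terms sum
probabilities in sorted order so MI(x, y) and MI(y, x) agree bitwise.

Per-epoch MI matrices are averaged over epochs (60 epochs for a 300-s
recording) into the subject's connectivity matrix. No small-sample bias
correction (e.g. Miller–Madow) is applied: the estimator is the plain
plug-in, and its bias floor — approximately (B−1)²/(2·N_eff) nats, which
grows as signal autocorrelation shrinks the effective sample count N_eff per
epoch — is characterised empirically in the test suite rather than corrected.
Bin edges are per-epoch by default; a `global` edge scope (edges from the
whole recording) is exposed for sensitivity analysis, since either reading of
"11 bins" is defensible.

Degenerate inputs: a constant signal occupies one bin and has entropy exactly
0, so its MI with anything is 0 — logged, not an error.

## Preprocessing

Fixed order: per-channel baseline (mean) removal → Hamming-windowed sinc FIR
bandpass (default 0.1–100 Hz) → re-referencing → non-overlapping epoch
segmentation (default 5 s; trailing partial epoch dropped). Baseline removal
and average re-referencing are both linear and commute, so the order between
them is a convention (asserted in tests).

Filter design: transition width at each edge is min(max(0.25·cutoff, 0.5 Hz),
2 Hz), additionally capped at 2·cutoff so a 0.1 Hz high-pass edge still
reaches deep attenuation by DC; the order follows the Hamming approximation
N = 3.3·fs/width, forced odd. The filter is linear-phase and is applied as a
single FFT convolution with its integral group delay compensated —
zero-phase, like forward-backward filtering, but without squaring the
magnitude response. Signals must be longer than three filter lengths.

Re-referencing schemes: `none`, `average` (default), or `linked_pair` (e.g.
mastoid surrogates). A model-based infinity reference (REST) is not
implemented — it requires a volume-conductor lead field — and the average
reference is used as the closest model-free proxy; the reference scheme is
recorded in every output so results from different schemes are never silently
mixed. Artifact handling is a deterministic per-epoch amplitude rejection
(drop any epoch whose absolute amplitude exceeds a configurable threshold);
ICA-based ocular cleaning is out of scope.

## Networks and metrics

Proportional thresholding retains the strongest fraction p of the
n(n−1)/2 unique edges — round-half-up, so p = 0.20 on 16 channels keeps
exactly 24 of 120 edges — equalising edge counts across subjects before any
comparison. Ties at the cut are broken by descending MI then lexicographic
label order, making selection deterministic. The default analysis grid is
p = 0.10–0.30 in 0.01 steps (21 thresholds).

Metrics on the resulting undirected, unweighted graphs:

* clustering coefficient C_i = 2e_i/(k_i(k_i−1)); nodes with degree ≤ 1 get
  C_i = 0; the network summary is the unweighted mean over nodes;
* betweenness centrality: the sum over unordered pairs {j, k} (j ≠ i ≠ k) of
  the fraction of shortest j–k paths through i, unnormalised; pairs with no
  connecting path contribute 0 (0/0 := 0). A normalised variant is exposed
  as an option. The unordered-pair convention was chosen where the summation
  could be read either way; the normalised and ordered variants differ only
  by constant factors;
* interhemispheric edge count under the 10–20 odd/even split (8 left, 8
  right electrodes; up to 64 cross pairs).

Graph algorithms are delegated to networkx; brute-force enumeration oracles
in the test suite pin the exact conventions. Thresholding is applied to each
subject's matrix for statistics; thresholding a group-mean matrix is
meaningful only for visualisation.

## Group statistics

At each threshold, a classical fixed-effects one-way ANOVA from sums of
squares compares the four groups. Post-hoc pairwise tests follow the SPSS
convention the field uses: Levene's test (centre = mean, α = 0.05) gates
between Fisher's LSD (pooled ANOVA error term, unadjusted) when variances
are homogeneous and Tamhane's T2 (Welch t with Satterthwaite df,
Šidák-adjusted over the pairwise family) otherwise. Welch df are never
rounded. All six pairwise comparisons are always reported. No correction is
applied across the 21 thresholds by default — each threshold row stands
alone, matching how such tables are conventionally presented — and a
Bonferroni-across-thresholds option exists but is off.

## Synthetic data

The generator produces multichannel recordings from coupled autoregressive
processes. Every channel follows the same stable AR(2) recursion, default
coefficients (1.1, −0.3) (characteristic roots 0.6 and 0.5), giving a
smooth low-pass signal. Couplings are lagged linear
cross-terms: `target[t] += strength · source[t−lag]`. Stability is enforced
by checking the companion-matrix spectral radius (< 1) before simulation; a
1,000-sample burn-in is discarded; identical inputs and seed give
bit-identical output. Channels are standardised to a common 10 µV scale
(affine per-channel rescaling leaves the min–max-binned MI invariant).
For acyclic coupling graphs the recursion is computed exactly per channel
with `lfilter` in topological order; a generic time-stepping loop covers
cyclic systems. Volume conduction is modelled separately as instantaneous
linear mixing (`apply_mixing`) and is off by default in cohort scenarios so
parameter-recovery results stay interpretable.

The AR coefficients matter twice: a lagged coupling is visible to a zero-lag
dependence measure only through the process autocorrelation at that lag, yet
stronger autocorrelation also shrinks the effective sample count and raises
the plug-in MI bias floor. The defaults sit at the working point where a
single strong coupling (e.g. C3→C4, strength 0.9, lag 2) is reliably the
top-ranked of all 120 edges while independent channels stay at the floor.

### Cohort scenarios

Group-structured cohorts encode known contrasts as generative parameters.
Three dimensionless strength knobs scale fixed coupling templates:

* interhemispheric — the 8 homologous left→right pairs (Fp1→Fp2 … T5→T6),
  each multiplied by a fixed topographic profile (1.6 down to 0.36) so the
  pairs straddle the detection transition and group differences translate
  into graded edge counts rather than all-or-nothing detection;
* fronto-parietal — contralateral anterior→posterior links (F4→P3, Fp2→O1);
* intrahemispheric — left-hemisphere links (C3→T3, P3→T5).

Knob values map to AR coefficients through a gain of 0.2, placing the
default strengths inside the estimator's dynamic range. Two structural rules
keep the contrast clean, both found necessary during design:

1. **One scenario coupling per target.** Two couplings from one source at
   equal lag make the two targets near-duplicates, with spurious MI far
   exceeding genuinely coupled pairs.
2. **Spectral homogeneity.** Each scalp channel also receives a hidden,
   private background source, with coupling-plus-hidden injected power held
   at a constant 0.85 amplitude. Without this, strongly driven channels are
   spectrally slower than pure ones, and pairs of slow channels acquire an
   inflated bias floor that masks or even inverts the designed contrast.

Default group scenarios mirror the qualitative clinical ordering the
analysis is meant to recover: interhemispheric strengths 0.8/0.6/0.4/0.2 and
fronto-parietal 0.7/0.55/0.4/0.25 decreasing from HC to PSD, with
intrahemispheric strength 0.2/0.45/0.6/0.75 increasing correspondingly
(weakened left–right communication with relatively enhanced
hemisphere-internal connections as severity grows). Per-subject seeds derive
deterministically as scenario_seed·10007 + subject_index. Noise SD is 1
(arbitrary units; irrelevant after standardisation).

What the generator does **not** emulate: realistic forward head models,
dipole sources, 1/f spectral shaping beyond the AR dynamics, non-stationary
artifacts, or volume conduction in the default scenarios. Passing the
recovery tests therefore shows that the pipeline detects the designed
coupling structure under these idealised conditions — it does not establish
sensitivity on real patient EEG.

## Built-in studies and problem sizes

* Surrogate coupling detection: 20 seeds, 300-s recordings (60 epochs), one
  C3→C4 coupling at strength 0.9; the coupled edge must be top-ranked and
  survive the sparsest (10%) threshold in ≥ 18/20 seeds.
* Null calibration: 1,000 replicates of four groups of 15 drawn from one
  normal distribution; the gated ANOVA's rejection rate at α = 0.05 must lie
  in [0.035, 0.065].
* Cohort recovery: 20 replicates of four groups × 15 subjects with 90-s
  recordings (18 epochs — the package's study size for this experiment;
  the 300-s default is kept for single-subject analyses). Group means of the
  interhemispheric edge count at the 20% threshold must be strictly
  decreasing HC→PSD, and HC vs PSD post-hoc p < 0.05 at a majority of the 21
  thresholds, in ≥ 80% of replicates (ordering alone in ≥ 90%).

## Known limitations

* The plug-in MI bias is not corrected; comparisons are valid because
  proportional thresholding equalises edge counts and all groups share the
  same estimator, but absolute MI values are biased upward for
  autocorrelated signals.
* MI on simultaneous samples cannot represent directionality, and volume
  conduction (instantaneous mixing) inflates it; the mixing operator exists
  precisely to study that failure mode.
* EDF output is 16-bit; round-trips are exact only to one quantisation step
  of each channel's scaled range.
* The per-threshold tables carry no across-threshold multiplicity
  correction by default (documented above).
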