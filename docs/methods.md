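# Methods

This note documents the models behind `pamscreen`, the parameter defaults
and why they were chosen, the numerical decisions, and what validation on
synthetic data does and does not establish.

## The screen and its generative model

The screen follows a pooled plasmid-loss design: a library of plasmids
carrying a fixed protospacer behind each of the 64 possible trinucleotide
PAMs is grown with (*CRISPR ON*) or without (*CRISPR OFF*) induction of the
*cas* genes, and the PAM-spanning amplicon is sequenced at t = 0, 0.5, 1,
3, 6 and 24 h post-induction in three technical replicate cultures.

The generator models interference as a **lagged single exponential** per
PAM: the unnormalized abundance of PAM *p* at time *t* is

    w_p(t) = f0_p · exp( −λ_p · max(0, t − L) )

with induction lag `L = 1.0 h` (depletion becomes visible between the 1 h
and 3 h samples, matching the observed onset ~1.5 h post-induction).
Observed ON frequencies are `w_p(t) / Σ_q w_q(t)` — the renormalization is
the compositional distortion the pipeline must undo — and OFF frequencies
stay at the initial composition `f0` (Dirichlet-perturbed around uniform,
concentration 100, i.e. ~10% library imbalance; replicates share `f0` since
they split from one transformation pool). This is the simplest model that
reproduces the three observed kinetic classes; it deliberately ignores
cell-to-cell copy-number variance, plasmid fitness effects and culture
bottlenecks.

Default rates, chosen once from the published kinetic shapes:

| group        | rate (1/h)                     | behavior                           |
| ------------ | ------------------------------ | ---------------------------------- |
| stable       | 0                              | no loss                            |
| interfering  | 17 values log-spaced 3.0–6.0   | at the detection floor by 3 h      |
| intermediate | 11 values log-spaced 0.1–0.3   | 10–90% residual at 24 h            |

Per-PAM spreads within the decaying groups reflect the documented
heterogeneity of the intermediate class (its fastest member approaches
interfering-like depletion late in the course). The spread also matters
structurally: with a single intermediate rate, the whole group crosses the
depletion threshold at the same instant, and the threshold-based
compositional correction (below) is maximally biased at whichever sampling
time catches the group mid-transit.

Sequencing is multinomial at `1e5` reads/sample (depth is configurable;
it was chosen so that multinomial noise is far below the group separation)
with uniform per-base substitution errors at `0.001`, constant Q37 quality
strings, and ~50% of reads emitted as reverse complements (a short amplicon
is read from both ends). Errors give depleted PAMs a realistic floor: each
PAM has nine single-mismatch neighbors whose reads mutate into it at rate
`error/3` per differing base, so a fully depleted PAM still collects a few
counts per 1e5 reads — log2fold series therefore saturate near −8 rather
than at the pseudocount bound.

## Counting

Alignment is replaced by direct search for the known protospacer: for a
fixed 98-bp amplicon, locating a 33-nt exact subsequence on either strand
is equivalent to mapping, with ambiguity (two equal-score disjoint hits)
taking the place of a mapping-quality filter. Reads are first 3'-trimmed at
Q < 32 and must then have mean quality ≥ 32 (a per-base interpretation is
available as `quality_mode="per_base"`) and length ≥ 30. Only reads fully
covering the PAM and protospacer — no end gaps — are counted; the PAM is
the three bases immediately 5' of the protospacer on the protospacer-bearing
strand. Reads with a degenerate base in the PAM are tallied as ambiguous.
Every read lands in exactly one QC bin (`retained`, `quality_filtered`,
`length_filtered`, `unmatched`, `ambiguous`), and counting is validated
against an independent brute-force scanner and against planted multinomial
draws. The default mismatch budget is 0; reads with indels in the
protospacer are unmatched, not rescued.

## Depletion correction

For each ON sample, PAMs with frequency below `0.5/64 = 1/128` (strictly)
form the depleted set D. Surviving frequencies are rescaled by the
*multiply* convention, `f_corr = f · (1 − S)`; the reciprocal *divide*
convention is available as `mode="divide"` and the choice is recorded in
the output provenance. Two readings of S exist:

* **Single-row** (the `correct_frequencies` default): S is the summed
  *current* frequency of the depleted PAMs. This matches the formula's
  literal arithmetic and is what the exactness tests pin down, but it is
  nearly a no-op precisely when depletion is strong — what is left of a
  depleted PAM says nothing about what was lost.
* **Control-referenced** (used by the ON/OFF pipeline): S sums the paired
  OFF-control frequencies of the ON-depleted PAMs, i.e. the plasmid mass
  those PAMs *used to hold*. When the depleted PAMs are fully lost this
  equals the survivors' inflation factor exactly, and corrected stable-PAM
  frequencies land back on the ON = OFF diagonal.

The correction has a structural limitation: a PAM in mid-decay that has not
yet crossed 1/128 contributes nothing to S although part of its mass is
already gone, so at time points catching the intermediate group in transit
the stable-group ratio retains a bias of several percent (up to ~8% under
the default scenario — within 3 binomial standard deviations of the
per-PAM counts at 1e5 reads, which is how the diagonal-recovery test is
phrased). No threshold rule can remove this; an estimator based on, e.g.,
the median ON/OFF ratio would, but would depart from the screen's
published procedure.

Count adjustment for diagonal plots matches ON totals to the paired OFF
totals and multiplies each PAM by `f_corr / f_raw` (zero-frequency PAMs
stay zero).

## Ratio series and kinetic features

Ratios `r(t)` are computed per replicate from corrected ON and raw OFF
frequencies, each with a 0.5-read pseudocount (continuity correction; raw
frequency tables report true zeros), and normalized to the t0 ratio so
`r(t0) = 1` exactly. log2fold is averaged across replicates on the log
scale (technical replicates are independent cultures; no pooling rule is
assumed). PAMs unquantifiable at some time (zero OFF frequency, possible
only without pseudocounts) carry the last finite log2fold forward so all
64 leaves stay clusterable.

## Clustering and group naming

The 64 derivative vectors are clustered agglomeratively (average linkage)
with ordinary bootstrap support: the feature dimensions are resampled with
replacement 2000 times and each internal node's support is the fraction of
bootstrap dendrograms containing its exact leaf set (multiscale/AU
corrections are out of scope). Two defaults differ deliberately from a
shape-based clustering of well-separated expression profiles:

* **Euclidean distance**, not correlation. The classifying signal here is
  the *magnitude* of the decay rate; a scale-free distance treats the
  stable group — whose derivatives are zero up to sampling noise — as 64
  random directions that cannot cohere into one cluster, and the
  three-way cut then splits noise instead of kinetics.
  `metric="correlation"` remains available for shape-only questions.
* **Interval-duration weighting**: each derivative component is multiplied
  by its interval length (equivalently, the clustering operates on log2fold
  increments). With sampling intervals spanning 0.5 h to 18 h, raw
  bits/hour vectors let the short early intervals — pure noise before the
  induction lag — dominate the geometry while compressing the late
  intervals where attenuated interference accumulates its signal.
  `interval_weighting="none"` restores unweighted rates.

The three-cluster cut is named by anchors: AAG and ATG (consensus) must
share a cluster (*interfering*), CCG (the repeat trinucleotide) marks
*stable*, the remainder is *intermediate*; anchor conflicts raise an error
with the cluster layout rather than guessing. A threshold fallback
classifier (interfering: log2fold(3 h) ≤ −4; stable: |log2fold(24 h)| ≤ 1;
else intermediate) is provided for robustness checks only; its cutoffs
come from the published kinetic shape description, not from fitted values.

## qPCR model and adaptation scores

Quantification cycles follow `Cq = intercept + slope·log10(percent) +
N(0, sd)` with defaults slope −3.32 (perfect doubling), intercept 24 (Cq at
1% expanded arrays), noise sd 0.15 cycles, reference gene at Cq 16, and
multiplicative per-hotspot assay biases (HS2 ×1.6, HS3 ×0.7) that the
CAA-reference normalization must remove. A zero expanded fraction never
amplifies and is reported censored (NaN), like a water control. Relative
signal is `E^(−ΔCq)` with efficiency `E = 2.0` configurable per assay — the
standard relative-quantification contract, since no quantification model is
otherwise specified. Calibration is fitted by least squares in log–log
space over mixtures spanning 0.1–50% (log-linear Cq behavior is the
standard assumption); the inverse mapping gives the adaptation score, with
sub-range values clamped to zero and flagged, above-range values flagged as
extrapolations, and a delta-method inverse prediction interval available.
Scores are percentages of cells, so negative fits clamp to 0; replicate
averaging is the unweighted mean.

The generator couples planted expanded-array fractions to interference
kinetics (the kinetic model of priming): a PAM's plasmid persists for
`L + ln(200)/λ` hours, and its fraction of adapted cells saturates as
`f_max · (1 − exp(−persist/24 h))` with `f_max = 25%`. Stable PAMs plant
exactly zero. This yields the qualitative headline pattern — intermediate
PAMs out-adapt interfering ones, stable PAMs sit at mock level — and a
strictly ordered truth for rank-recovery tests.

## Spacer acquisition and mapping

The acquisition generator draws spacer start positions from a mixture of a
uniform background and three hotspots (shares 6/7/8%, matching the
observed 5–8% range) on a 3.3-kb synthetic circular plasmid into which the
three printed hotspot spacer sequences are implanted; an optional
`pam_bias` concentrates mass on AAG-adjacent positions. Mapping is exact,
both strands, with circular wrap-around; positions are always reported as
0-based plus-strand starts so both strands share one coordinate axis.
Multi-hit spacers are excluded from profiles, degenerate-base spacers are
tallied separately, and the bookkeeping identity
`mapped + multi_hit + unmapped + excluded = total` always holds. Profile
correlations are Pearson over bins nonzero in at least one profile. The
naive-vs-primed PAM-usage comparison consumes externally supplied spacer
tables; the package ships only synthetic stand-ins.

## Problem sizes and determinism

Full-scale validation simulates 36 samples × 1e5 reads (two conditions,
three replicates, six time points) and runs in ~30–60 s per seed on one
CPU; the test suite runs two such seeds plus reduced-depth (2e4 reads)
scenarios for everything else, chosen so multinomial noise stays well
below the planted group separation. All randomness flows from explicit
seeds through `numpy.random.default_rng`; FASTQ emission is byte-identical
under a fixed seed.

## Known limitations

* The reference 64-PAM grouping ships the published class *sizes* and all
  class memberships stated in text; assignments of unnamed PAMs are a
  plausible synthetic completion (see `pamscreen.pams`), so per-PAM labels
  outside the anchored and text-named members should not be quoted as
  published results.
* Passing recovery tests shows the pipeline inverts its own generative
  model at realistic noise; real libraries add effects the generator
  omits (copy-number variance, fitness differences, PCR bias, adapter
  artifacts), so real-data accuracy is expected to be lower.
* The depletion correction inherits the threshold bias described above.
* Bootstrap support resamples only five feature dimensions; support values
  are correspondingly coarse and should be read qualitatively.
* The qPCR model assumes a common efficiency per assay and independent
  Gaussian Cq noise; inhibition, plateau effects and inter-run drift are
  not modeled.
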