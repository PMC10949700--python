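# Methods

## Generative model

The simulator emulates a SLAM-seq experiment in early zebrafish embryos at
the level of mutation-annotated 3′UTR reads; alignment, trimming and base
quality are out of scope (a real experiment would reach this package after
slamdunk-style processing).

Per gene, expected molecule abundances at `t` hours post injection:

```
m(t) = M0 · exp(−δ_m · max(0, t − t_decay)) · exp(−δ_mir,m · max(0, t − t_mir))
z(t) = (k / δ_z) · (1 − exp(−δ_z · (t − t_on)))        for t ≥ t_on, else 0
```

with the miR-430 components (`δ_mir,m` on the maternal pool, an additive
`δ_mir,z` in `δ_z`) active only for genes carrying an embedded seed site and
only from the miR-430 onset hour; the maternal miR term is written as a
continuous piecewise product rather than a rate switch so `m(t)` has no
jump at onset. Transcription-inhibited (α-amanitin) samples produce no
zygotic molecules at all; 0 mM / non-injected samples produce them but
label them only at the background rate. The miR-430-complementary LNA
scales both miR components by a knockdown fraction (default 1.0 = complete
loss of function; partial knockdown is a config scalar).

Reads are drawn multinomially across genes proportional to `m + z` within
the library size; each read's molecule is zygotic with probability
`z/(m+z)`; fixed-length windows are placed uniformly on the UTR; each
unmasked reference-T converts with probability `conversion_prob` (zygotic
molecule) or `error_prob` (maternal molecule); declared SNP offsets always
read as C. Spike-in counts are Poisson around a fixed 92-row abundance
ladder times a per-sample capture efficiency. Counting noise is therefore
Poisson/multinomial around the kinetic expectations; biological
over-dispersion is not injected by the generator — the statistics module's
calibration and power checks simulate negative-binomial counts directly at
the dispersions of interest.

These kinetic forms (exponential maternal decay, saturating zygotic
accumulation) are the simplest that reproduce stable/up/down
post-activation trajectories and the masked-decay regime; no rate model is
claimed for real embryos.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `conversion_prob(dose)` | `error_prob + 0.004·dose` | per T | strictly increasing; 75 mM → ≈ 0.30, a realistic detected incorporation rate; incorporation efficiencies are otherwise unconstrained placeholders |
| `error_prob` | 3×10⁻⁴ | per T | alkylated SLAM-seq libraries show ~0.01–0.1% background T>C; see the scale note below |
| miR-430 onset | 3 h | h | miR-430 is among the earliest zygotic products |
| read window | 80 nt | nt | 3′-end library read length; coverage detail is irrelevant to the statistics |
| library size | 20 000 | reads/sample | desk-scale depth giving ~50–150 reads per gene per sample |
| cohort | 40–100 genes per class | — | enough for recovery statistics at desk scale |
| UTR length / T fraction | 400 nt / 0.30 | — | typical zebrafish 3′UTR scale and base composition |
| SNP mask | fraction ≥ 0.15, coverage ≥ 7 | — | variant-calling thresholds on pooled controls |
| labeled call | ≥ 2 unmasked conversions | — | the defining read-classification rule |
| expressed / transcribed | > 5 mean CPM; ZCS > 5% or labeled CPM > 1 | — | classification thresholds, evaluated on replicate means over the 4–7 h window |
| trajectories | \|log2FC\| ≥ log2(1.5), padj ≤ 0.2 | — | interval labelling thresholds |
| masked decay | total log2FC(7v2) > −1.5; unlabeled-vs-total padj ≤ 0.05, log2FC < 0 | — | the decay floor is read as a bare log2 value; the alternative reading (−log2(1.5)) is a config switch |
| NB test | pseudocount 0.5 CPM; dispersion prior weight 20 | — | bounded log2FC at zero counts; stable tagwise shrinkage at n = 3 |

## The desk-scale caveat

A real transcriptome spreads a library over ~25 000 genes; the simulated
cohorts use a few hundred, so every gene's read share — and with it the
false-positive sensitivity of *absolute* thresholds like "> 1 labeled CPM"
— is roughly two orders of magnitude higher than in the data those
thresholds were designed for. The background rate default (3×10⁻⁴ per T,
mid-range for alkylated libraries) keeps the per-gene probability of a
spurious labeled read at desk scale comparable to the real setting.
Passing recovery tests therefore demonstrate the pipeline's logic and
calibration, not threshold robustness at genome scale; ratio-based
quantities (ZCS, fold changes, conversion rates per base) are unaffected by
this scale distortion.

## Normalisation

Spike-ins enter through the per-sample ratio of spike-in counts to gene
library size: `factor_s = (spike_s/lib_s) / geomean_j(spike_j/lib_j)`,
re-centred so the median factor is 1, and
`effective library size_s = lib_s · factor_s`. Built on the ratio scale the
resulting CPMs are *exactly* invariant to jointly rescaling one sample's
gene and spike-in counts (a pure sequencing-depth change), while a sample
that captured 2× the spike-ins gets factor 2 and halved CPMs. Labeled and
unlabeled CPMs always use the total fraction's effective sizes, which is
what makes the fraction decomposition exact. Spike-in rows are excluded
from library-size sums and from expression filtering.

The low-expression filter retains a gene iff (≥ 10 reads in ≥ 2 samples)
and, within at least one replicate group, total ≥ 20 reads with > 0 reads
in at least half the group's samples. "Replicate group" means condition ×
timepoint: pooling an entire time course as one condition would filter out
genuinely late-activating genes that are silent at early hours, defeating
the activation analysis. The "some samples" count (2) and all thresholds
are config-exposed. Replicate exclusion is an explicit config list, not
automated outlier detection.

## Differential testing

The two-group negative-binomial test: (1) counts are scaled to the
geometric-mean effective library size and rounded; (2) per-gene dispersions
are moment-estimated from pooled within-group variances; the common
dispersion is the *mean* over informative genes (the per-gene moment
estimate is right-skewed, so a median is biased low and inflates type-I
error), and tagwise values shrink toward it with prior weight 20; (3) the
p-value is the conditional two-sided tail of the observed group split given
the group-sum total, each group sum being NB with size `n/φ` (Poisson at
φ = 0); a normal approximation takes over above 5×10⁵ total counts.
log2 fold changes are computed on mean CPMs with a 0.5-CPM pseudocount, so
they are finite at zero counts. BH adjustment is applied within each
comparison × fraction. At n = 3 vs 3 and dispersion 0.05 the measured
type-I error at α = 0.05 is ~0.045–0.05 and the mean log2FC of true 2×
changes is within 0.01 of 1.

The "unlabeled vs total at 7 h" masked-decay contrast pairs fractions by
sample (both sides use the same libraries and effective sizes); treating
them as independent groups is the exposed alternative. Because unlabeled ≈
total before ZGA, this contrast approximates the difference between the
unlabeled and total 7-vs-2 h fold changes.

## Deterministic conventions and edge cases

* Coordinates are 0-based half-open everywhere internally and on disk.
* Site scanning is sense-strand only; `N` never matches; overlapping sites
  resolve greedily by descending length then position (equal-length
  overlaps keep the leftmost), so a reported 8mer always suppresses the
  6/7mers nested in it. No thermodynamic or context scoring.
* Isoform selection takes the argmax of summed reads over the 2 h and 7 h
  reference timepoints combined (per-timepoint selection is the exposed
  alternative); exact ties go to the lexicographically smaller isoform id
  and are flagged; zero-read genes fall back to the longest isoform,
  flagged low-confidence.
* ZCS is undefined (NaN) when total CPM is below the expression threshold;
  conversion rates are NaN at zero covered T bases; constant inputs to a
  shift test give p = 1 with a warning; "expressed" is strictly `> 5`.
* Conversions at masked offsets are removed *before* the ≥ 2 rule; the SNP
  mask is built from pooled control reads only. A no-mask mode supports
  dose-series-style runs.
* All randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawning; identical inputs and seed give
  byte-identical outputs, and the CLI subcommands call the same stage
  functions as `run_pipeline`, so composed runs are reproducible file for
  file.

## What the simulator does not capture

Alignment and mapping artefacts, sequencing error beyond per-T conversion,
isoform switching (one UTR per gene is simulated; the isoform selector is
exercised on its own inputs), 3′ coverage bias, biological replicate
over-dispersion in the generator, partial LNA dosage series, and
translation. Recovery results on synthetic data bound what the pipeline
can do when its model assumptions hold; they do not certify performance on
real libraries, where mapping and UTR-annotation quality dominate.
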