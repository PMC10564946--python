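# Methods

`m6ascape` re-implements, as a tested pipeline over synthetic data with known
ground truth, the computational procedures of a transcriptome-wide m6A
(MeRIP-seq) analysis of a paired tumor/normal cohort: consensus peak
cataloguing, relative m6A quantification and differential methylation,
m6A-based tumor subtyping, regulator-RBP ranking, CIMS-based single-nucleotide
m6A calling, and GRO-seq elongation-rate estimation. This note records the
models, the parameters that matter, the numerical choices, and what the
synthetic conditions do and do not establish about real data.

## Peak catalogue (`peaks`)

MeRIP-seq marks methylated fragments by antibody immunoprecipitation (IP)
sequenced alongside an input library. Real analyses use two external peak
callers; the funnel implemented here consumes their per-sample calls:

1. **Two-caller consensus** — peaks supported by both callers (>= 1 bp
   overlap, same strand) are merged to the union of each overlapping pair,
   and overlapping unions are collapsed. Union rather than intersection was
   chosen so that neither caller's boundary evidence is discarded; the
   intersection dialect would only shrink coordinates, not change membership.
2. **Recurrence** — a catalogue peak is kept if it is present (>= 1 bp
   overlap by that sample's consensus peaks) in at least `min_samples`
   samples (default 5).
3. **m6Am removal** — m6Am is a cap-adjacent modification that cross-reacts
   with the m6A antibody. A peak is flagged when it overlaps the 5'UTR of its
   gene's canonical transcript, the first transcribed base is A, and that
   adenosine sits in a BCA context (B = C/G/T immediately 5' on the
   transcript strand). The B anchor is placed immediately upstream of the TSS
   adenosine because the chemistry is TSS-anchored.
4. **Annotation** — gene and region come from the canonical transcript only
   (the transcript with the largest overlap when several genes' canonical
   transcripts overlap the peak). Region priority for straddling peaks:
   start/stop-codon vicinity (±100 bp around the codon) > 5'UTR/3'UTR >
   CDS > intron. The vicinity windows reflect the known concentration of m6A
   near start and stop codons; the 100 bp half-width is configurable
   (`peaks.CODON_VICINITY_BP`).

An internal Poisson window caller (`call_enrichment_peaks`) stands in for the
external callers so the pipeline is exercisable end to end: the input track
is scaled to IP depth, non-overlapping windows (default 50 bp) are tested
with a one-sided Poisson tail, and adjacent significant windows are merged.
Because it conditions on the input count instead of modelling its
variance, the scaled comparison is slightly anti-conservative when library
scaling shrinks the expectation; with realistic peak-to-genome fractions the
effect is negligible, and the planted-peak recovery test bounds spurious
calls at 5%.

Descriptive summaries: `motif_fraction` counts peaks containing an IUPAC
motif (default GGACH, the methyltransferase consensus); `metagene_profile`
maps peak midpoints onto a normalised 5'UTR/CDS/3'UTR axis with a fixed
number of bins per region and reports a density summing to one.

## Quantification and differential methylation (`quant`)

The relative m6A level of a peak in a sample is IP RPKM divided by input
RPKM (reads per kilobase of peak per million mapped reads). Peak length
cancels in the ratio; library sizes do not. Values are undefined (missing)
where the input count is zero — no pseudo-count is added by default because
a pseudo-count distorts exactly the low-coverage peaks where the ratio is
least trustworthy.

Paired tumor/normal differential methylation uses the two-sided Wilcoxon
signed-rank test on paired differences with Benjamini–Hochberg correction
(default FDR 0.1) and direction from the median paired difference. The exact
sign-flip null is computed by dynamic programming over the (tie-aware,
doubled) rank sum up to 25 non-zero pairs; above that the normal
approximation with continuity and tie correction is used. Zero differences
are dropped. Peaks with fewer than 5 complete pairs are reported
non-significant with a reason.

The permutation null randomly swaps tumor/normal labels *within* pairs (a
sign flip of each paired difference), preserving the pairing structure the
test assumes, and recounts significant peaks per permutation. At FDR level a
pure-null matrix almost always yields zero counts in both arms, so the
calibration comparison is exposed at the raw p < 0.05 stage
(`adjust=False`); the FDR-level count remains the default for real
contrasts, where the observed count should dwarf the permutation mean.

Two-condition calls (knockdown/overexpression style) use condition means of
relative levels and the symmetric rule |FC| > 1.2. Integration with host-RNA
direction crosses the m6A call with an externally supplied {up, down, ns}
table per gene (RNA differential expression itself is out of scope), giving
hyper-up / hypo-down / hyper-down / hypo-up / non-significant categories;
any peak whose RNA direction is ns (or whose gene is absent) is
non-significant.

## Subtyping (`subtypes`)

Consensus clustering: 1000 resamples draw ceil(0.8 n) tumors without
replacement; each resample is clustered (agglomerative, average linkage,
Euclidean distance over peaks — the classic consensus-clustering inner
family; k-means is available); the consensus matrix entry for a pair is
co-clustered / co-sampled. Peak rows are standardized before clustering by
default (a flag preserves raw levels). Final labels come from average-linkage
hierarchical clustering of 1 − consensus; clusters are named S1..Sk in
increasing order of mean m6A level so the hypermethylated subtype is always
the highest index. k defaults to 2; the proportion of ambiguous clustering
(PAC, consensus entries in (0.1, 0.9)) is reported per k for transparency.

Subtype differential methylation is an unpaired two-sided Wilcoxon rank-sum
(exact for small tie-free samples) with BH correction. Clinical association
uses Fisher's exact test for 2×2 tables and chi-square otherwise (flagged
when an expected cell is below 5; no exact r×c test is attempted). Survival
uses the Kaplan–Meier product-limit estimator with median = smallest t with
S(t) <= 0.5 and the two-group log-rank test; covariate-adjusted hazard
models are deliberately out of scope and the group table is exported for
external modelling.

## Regulator ranking (`regulators`)

For each hypermethylated peak a random-forest regression of its m6A level on
RBP expression (plus encoded clinical covariates) is decomposed along each
decision path: every split attributes the change in node mean to the split
feature, so prediction = root value + sum of contributions holds exactly for
every tree and sample (checked to 1e-9). Forest defaults: 500 trees,
ceil(p/3) candidate features per split, unlimited depth, bootstrap on.

Because the decomposition is centred on the root mean, the *signed* per-
sample contributions of any predictor average to approximately zero over the
fitted cohort — a signed mean cannot rank predictors. The ranking score is
therefore the mean |per-sample contribution| ("magnitude"); the signed mean
is retained for effect-direction inspection (`mode="signed"`). Clinical
covariates participate in the fit but are never ranked as candidate
regulators.

The correlation screen computes Spearman rho per RBP–peak pair (tie-corrected
t approximation) separately for hyper, hypo and unchanged peak strata; a
pair is significant when |rho| > 0.25 and p < 0.05. Per RBP, Fisher's exact
test (one-sided) asks whether significant pairs are over-represented among
hypermethylated peaks versus background, with BH across RBPs. The final
ranking combines the two axes as the product of min-max-standardized
contribution and −log10 FDR — an explicit, swappable rule; both axes are
always emitted raw, and ties order by RBP name.

## CIMS calling and co-localization (`coloc`)

In miCLIP, reverse transcription past the crosslinked antibody adduct
introduces C→T transitions one base 3' of the methylated adenosine. A
mutation record (coverage k, mutations m) is called m6A when it is (i) not a
known SNP (any user-supplied list), (ii) a C→T on the read strand, (iii)
m/k <= 50%, and (iv) immediately 3' of an A in transcript orientation; the
reported residue is that adenosine. The +1 orientation is interpreted on the
transcript strand because the chemistry reads through the RNA 5'→3'.

Distance profiles take, for each A-set anchor midpoint, the signed distance
to the nearest B-set midpoint within ±2 kb, oriented by the anchor's strand;
equidistant candidates resolve to the 3' side for determinism. Midpoint-to-
midpoint is the default convention. Overlap association over a peak universe
marks membership by >= 1 bp same-strand overlap and applies a one-sided
Fisher's exact test.

## Elongation rates (`elongation`)

After release from a DRB transcription block, the front of engaged Pol II
advances from the TSS. Per gene and release time, the per-base coverage of
−10 kb..+120 kb around the TSS (strand-oriented; replicates combined by a
0.01-trimmed mean per base) is averaged into 100-bp bins and fitted with a
cubic smoothing spline; the wave peak is the argmax of the smoothed curve
over the gene body. The smoothing penalty is chosen by generalized
cross-validation by default; `lam` is exposed so a fixed smoothness
(equivalently, a target effective degrees of freedom via the smoother trace)
can be pinned when matching another ecosystem's smoothing-parameter
convention.

Filters: low expression (mean profile depth below a threshold; default the
25th percentile over profiled genes — explicit and data-adaptive since no
absolute cutoff generalises across depths), missing peak at any time,
identical peaks at all times, peaks not strictly increasing with time, and a
25-min peak at or before +1 kb. The rate is the OLS slope of peak position
(kb) on time (min); with two time points this is the two-point slope
exactly. Condition comparisons use the two-sample two-sided KS test. Genes
truncated at chromosome edges are NaN-padded, flagged, and their argmax
restricted to covered bins. A helper exposes the qPCR-style rate arithmetic
(amplicon distance / time of first pre-mRNA reappearance).

## Synthetic data (`simulate`)

The generators define the study conditions; all are deterministic under a
seed and return machine-readable truth.

- **Toy annotation**: non-overlapping two-exon coding genes on both strands
  of one chromosome, each with a planted GGACT window in its CDS;
  even-indexed genes get a BCA-context TSS adenosine.
- **MeRIP coverage**: Poisson background (default mean 2 reads/base) on
  exonic positions in IP and input; IP multiplied by the enrichment fold
  (default 10) inside planted peaks. The expected relative level is the fold
  times the input/IP library-size ratio, not the raw fold — library scaling
  re-normalises the enriched library.
- **Cohort**: mirrors the emulated design scalars — 33 tumor/normal pairs
  plus 32 unpaired tumors (65 tumors), ~2000 peaks with a planted
  differential set split 195 hyper / 93 hypo, two tumor subtypes, 50 RBPs
  with one driver. Log-normal baselines (log-sd 0.5 around level 2);
  multiplicative tumor effect 2 on planted peaks (inverse on hypo);
  S2 tumors get a further ×2 on the hyper set; the driver RBP's standardized
  log-expression replaces a fraction `driver_effect` of the hyper-peak
  log-noise variance (sd 0.3) and its expression is shifted up in S2 — the
  driver is what distinguishes the subtypes. With `driver_effect = 0` the
  driver is exchangeable with every other RBP, which is what makes the
  null-rank uniformity test meaningful. Survival is exponential with
  subtype medians 11.2 / 6.6 months and administrative censoring at 36
  months; clinical features are independent of subtype by default.
- **GRO-seq**: per gene and time, a Gaussian wavefront (width 4 kb,
  amplitude 20) centred at rate × time downstream of the TSS on a decaying
  basal gradient, Poisson-sampled per base; rates default to U(0.5, 4)
  kb/min at release times 10 and 25 min.
- **CIMS**: true sites are C→T records one base 3' of an A with m/k <= 0.5;
  decoys cycle through the four failure modes (SNP-flagged, m/k > 0.5,
  wrong substitution, non-A anchor).

**What the synthetic conditions do not show.** Log-normal levels with
homoscedastic noise lack MeRIP's count-level overdispersion, fragment-length
and GC biases; the driver acts linearly on log levels, so forest ranking is
tested for recovery, not for robustness to non-linear confounding; clinical
features are independent of subtype, so the association tests are exercised
for calibration rather than power; GRO-seq waves are symmetric Gaussians,
ignoring pausing and termination structure. Passing tests therefore
establish the correctness and calibration of the procedures, not their
performance on real libraries.

## Problem sizes used in the checks

The reproduction script and acceptance tests run scaled-down cohorts chosen
as the package's own benchmark conditions: driver recovery on 20 seeded
cohorts (40 tumors, 200 peaks, 15 RBPs, 100-tree forests); its null on 200
cohorts (30 tumors, 60 peaks, 8 RBPs, 50 trees); subtype recovery on 5
cohorts (30 tumors, 1000 resamples at 0.8, the published resampling
parameters); calibration on 20 null cohorts of 33 pairs × 500 peaks;
CIMS equivalence on 10,000 records; elongation recovery on 50 genes over
the full −10/+120 kb span.

## Known limitations

- The internal Poisson caller is a stand-in; real analyses should supply
  external peak calls.
- No exact r×c categorical test; sparse multi-level tables fall back to
  chi-square with a warning note.
- The consensus-clustering inner clusterer sees mean-imputed values where a
  level is missing; with heavy missingness a dedicated imputation step is
  advisable.
- Survival modelling stops at KM/log-rank; hazard ratios require covariate
  adjustment that is explicitly out of scope.
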