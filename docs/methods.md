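# Methods

## The screen being modelled

An E3-ligase substrate screen of this shape compares a ligase-deficient
cell line with the same line after ligase restoration, in three layers:
a diGly-remnant (K-ε-GG) ubiquitome acquired under proteasome inhibition
(MG132), a quantitative proteome, and a transcriptome.  A protein is a
substrate candidate when it is ubiquitinated essentially only in the
restored condition, downregulated at the protein level in that
condition, and — to prioritize clinical relevance — overexpressed in
tumors versus paired normal tissue in an external cohort.  The candidate
signature is then scored on a survival cohort.  `ubinom` implements this
funnel; everything upstream of the peptide tables (spectra, database
search, reporter-ion quantification) is out of scope.

## Digestion and site mapping

Trypsin is modelled as cleaving C-terminal to K or R, suppressed when
the next residue is P and at any blocked position.  A diGly-modified K
is treated as uncleavable, which is why a modified peptide always
carries at least one missed cleavage and why observed diGly peptides
cluster in the 7–31 residue band.  Coordinates are 1-based and
inclusive in protein residue space throughout, so a site prints directly
as `K676`.  Mapping is exact substring search against the supplied FASTA
only; peptides matching more than one locus are flagged ambiguous and
kept (set logic uses all matches but counts each protein once), and no
isoform resolution is attempted.  The modified-peptide parser accepts
the `K[gg]`, `K(gl)` and `K^ub^` dialects through an explicit tag table;
unknown tags raise rather than being ignored.

The packaged `synthetic_tgfbi_nfkb2.fasta` contains **synthetic
stand-in** sequences: random tryptic-realistic backgrounds of the true
TGFBI (683 aa) and NFKB2 (900 aa) lengths with the documented peptides
`LAPVYQKLLER`, `YGCEGPSHGGLPGASSEKGR` and `GHTPLDLTCSTKVK` spliced in so
the modified lysines sit at the documented coordinates K676, K72 and
K741.  They validate coordinate arithmetic, not biology; mapping against
the genuine UniProt entries (Q15582, Q00653) requires supplying those
sequences.

## Set logic and overlap testing

"Unique to a condition" is strict presence/absence of a peptidoform key
(bare sequence plus exact modified positions — site isomers are distinct
events) within one MG132 stratum; the headline analysis uses the treated
stratum and reports the untreated one as QC.  Interactor-list overlap is
tested with the upper-tail hypergeometric probability P(X ≥ k).  The
universe size is a parameter: the pipeline defaults to the number of
proteins in the supplied FASTA, because a detected-proteome universe and
a whole-proteome universe give different p values and neither choice is
canonical.

## Differential contract

Both omics layers use the same generic two-group contract: Welch's
two-sample *t* on log2 values per feature, log2 fold change as the
difference of group means (B − A), Benjamini–Hochberg adjustment across
all tested features, and strict-inequality thresholds on the
linear-scale fold change and the FDR (defaults: transcripts |FC| > 4,
FDR < 0.01; proteins |FC| > 1.5, FDR < 0.05; tumor-vs-normal log2FC > 1,
adjusted p < 0.05).  Missing values are handled pairwise-complete per
feature without imputation; a feature with fewer than two usable samples
in a group is reported with undefined p and excluded from BH (counted
and logged).  A count-model RNA fit is deliberately not reimplemented;
externally computed results can enter through the same TSV schema.

## Nomination

The candidate table is the triple intersection with full provenance
columns (clinical fold change and adjusted p, cell-line fold change and
FDR, ubiquitination sites), sorted by clinical log2 fold change
descending with ties broken lexicographically by protein ID for
determinism.  The intermediate ubiquitinated-and-downregulated set is a
first-class output.  Identifiers are matched as exact gene-symbol
strings; cross-namespace mapping is the caller's responsibility.

The packaged 57-row candidate table transcribes the published screen
outcome.  Its validator enforces unique IDs and adjusted p < 0.05 but
treats the log2FC > 1 bound as documentation: the published table itself
ranks 28 proteins whose printed fold change is ≤ 1 on the log2 scale,
so enforcing the bound would reject the published data.  This
discrepancy is surfaced, not resolved.

## Signature score and stratification

The signature score is the geometric mean of the signature genes'
expression, computed as the arithmetic mean of log2-scale values —
identical quantities, but the log-space form avoids the zero/negative
pathology of a product of linear values, which is why inputs are
required to be nonnegative log2-like values.  Patients are dichotomized
on a Gaussian KDE of the scores with the classic univariate Silverman
bandwidth 0.9·min(sd, IQR/1.34)·n^(−1/5), evaluated on a 512-point grid
over [min − 3h, max + 3h]; with two or more local maxima the threshold
is the density minimum between the two highest peaks ("cut between the
peaks" is an interpretation — cutting *at* a peak would be the other
reading), otherwise the median.  Bandwidth, grid and rule are recorded
in the output for reproducibility.  The procedure is deterministic and
translation-equivariant.

## Survival statistics

Kaplan–Meier curves and the two-group log-rank test are delegated to
lifelines.  The Cox proportional-hazards fit is a hand-authored Newton
maximization of the single-covariate partial likelihood with Breslow
handling of tied event times (the simplest deterministic choice; on
tie-free data it coincides with Efron, which the test suite exploits to
cross-check against lifelines).  Standard errors come from the observed
information; p values are two-sided Wald.  Non-convergence and monotone
likelihood (perfect separation) are flagged in the result rather than
returned silently.  Stratified comparisons report both log-rank and Cox
statistics.  Signature trimming ranks genes by the p value of their
univariate Cox fit and keeps the top k (default 20); the random-forest
trimming route is out of scope because its hyperparameters are not
reproducible.

## Synthetic data generator

`StudyConfig` defaults define the study conditions used throughout the
recovery suite: 300 proteins, 30 substrates, 40 HIF-target-like genes,
4 replicates per condition, protein effect 1.5 log2 with replicate noise
σ = 0.25 (simulated directly in log2 space with Gaussian noise — the
simplest model under which Welch is exact), no substrate mRNA effect
(2.5 log2 for the HIF-target genes, which move at both levels),
per-K-site background diGly detection rate 0.10 plus 0.0125 per-condition
one-sided detection noise, an 8× MG132 detection boost (matching the
order-of-magnitude drop seen in untreated ubiquitome acquisitions),
200 patients with tumor effect 1.5 log2 and unit clinical noise, a 60%
latent copy-loss group that makes the signature score bimodal, survival
hazard exponential in 0.7 per unit centered score, and 20% censoring.
Sequences are built from 6–18 residue cleavage segments (no proline) so
0/1-missed tryptic peptides fall mostly in the 7–31 band.

Randomness uses one global seed with fixed-index substreams per output
file, so adding an output never perturbs existing ones; bundles are
byte-identical for identical configs.

What the generator does *not* emulate: spectra and acquisition effects,
reporter-ion interference, batch effects, sequence homology between
proteins, correlated gene modules, non-proportional hazards, and
informative censoring.  Passing the recovery suite therefore shows the
funnel's logic and statistics are correct under a clean generative
model, not that the thresholds are optimal for any particular real
dataset.

False nominations in the default study arise almost exclusively from
coregulated (HIF-target-like) genes that pick up a one-sided
detection-noise peptide — a realistic failure mode of presence/absence
ubiquitome calling — and their expected number follows analytically from
the per-site noise rate, which is how the recovery suite bounds the
false-discovery proportion.

## Numerical choices and degenerate inputs

Strict inequalities at all threshold boundaries (a log2FC exactly at the
bound is excluded).  BH is the standard step-up transform (statsmodels);
hypergeometric tails come from scipy and are cross-checked against exact
big-integer enumeration in the tests.  The Cox Newton step is clipped to
±5 per iteration with |β| > 20 treated as monotone likelihood.
Degenerate inputs raise early with the offender named: empty sequences,
modifications on non-K residues, contradictory up/down sets, duplicate
clinical IDs, constant covariates, all-identical scores, single-stratum
log-rank.

## Problem sizes

The recovery suite runs the default 300-protein / 200-patient study; the
null-calibration suite uses 1000 replicates for the Welch and log-rank
sizes and the Cox grid uses n = 500.  These sizes give binomial 3σ
calibration bounds of about ±0.02 around the nominal 0.05 while keeping
the whole suite in the tens of seconds on one core.
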