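# Methods

## Simulation model

Source populations drift from a shared ancestral allele-frequency pool
under the Balding–Nichols model: for a branch with drift parameter F,
the child frequency at a marker with parent frequency p is drawn from
Beta(p(1−F)/F, (1−p)(1−F)/F), so E[p_child] = p and
Var[p_child] = F·p(1−p). Branches chain, so both clean multifurcations
and serial splits are expressible. F and a (t generations, Ne diploid)
split are interconvertible through 1 − F = (1 − 1/(2·Ne))^t
(`drift_from_split_time`). Two useful consequences, derived from the
model's moments: two populations whose branches carry drifts F1 and F2
from a common ancestor show pairwise Hudson FST ≈ (F1 + F2)/2, and a
symmetric split therefore has pairwise FST equal to the per-branch
drift — which makes FST-based split dating self-consistent with the
simulator by construction.

Ancestral frequencies are Uniform(0.05, 0.95): the IBS and FST
estimators need segregating sites, and rare-variant dynamics are not the
target of any downstream analysis.

Admixed individuals are recombination mosaics: per haplotype and
chromosome, breakpoints follow a Poisson process of rate g per Morgan
(g = generations since a single admixture pulse), tract ancestries are
i.i.d. Categorical(recipe proportions), and tract alleles are copied
from a randomly chosen source haplotype. This is the standard pulse
approximation: tract lengths are Exponential(mean 100/g cM) and
genome-wide ancestry fractions concentrate on the recipe proportions as
genome length grows. There is no linkage between adjacent tract labels
and no continuous or multi-pulse migration.

Genotyping platforms are modelled as two random marker subsets with a
configurable overlap fraction plus i.i.d. missingness; allele strand
flips are not simulated by default (a marker-map flag injects A/T and C/G
pairs for QC tests). Population metadata places coordinates as a mixture
of a similarity image of the populations' mean ancestry proportions
(strength 1 = exact superposition) and independent noise (strength 0),
so the Procrustes and cross-validation machinery can be calibrated at
both extremes.

## Deconvolution

Windows are half-open [k, k+1) cM intervals tiling each chromosome's
mapped extent (the last window may be shorter; empty windows are
dropped). Per window, PCA is fitted on donor haplotypes only and targets
are projected; K−1 components are kept for K ancestries, since
between-group variation lives in K−1 dimensions. Emissions are Gaussian
per ancestry on the donor scores with a shared diagonal covariance
(pooled within-ancestry variance, floored at 1e-6).

Raw window likelihoods are overconfident: the markers within a window
are in linkage disequilibrium and the Gaussian score model is an
approximation, so the product over windows overstates the evidence. The
emission therefore mixes in a uniform component with weight 0.01
(`emission_floor`), the miscopying/outlier device standard in
local-ancestry HMMs; it caps how much any single window can contribute
and materially improves the calibration of the >0.99 posterior filter.

The HMM transition between adjacent windows at genetic distance d cM
keeps the current ancestry with probability exp(−r·d) and otherwise
draws a state uniformly (r = `switch_rate_per_cm`, default 0.1). This
parameterization has the right limits: r → ∞ gives a uniform transition
matrix and posteriors equal to the per-window likelihoods (no
smoothing), and uniform likelihoods stay uniform. The default r is a
weak prior on ~10 cM fragments; results are insensitive within an order
of magnitude because emissions dominate at array density.

Hard calls are argmax posteriors kept only above the confidence
threshold (default 0.99, strict). Validation against simulator truth
labels a window by the ancestry covering the majority of its span;
exact 50/50 windows count as misassigned for either call, which is the
conservative choice.

At ~50 markers per cM — the density of genome-wide SNP arrays — the
high-confidence filter discards essentially every misassigned window
for donor panels at pairwise FST ≥ 0.15, at the cost of an unassigned
fraction of a few percent. At much sparser density (tens of markers per
window) occasional multi-window stretches of one ancestry genuinely
resemble another, and no calibrated model can assign them correctly;
the filter then trades them for a larger unassigned fraction.

## Masking and distances

Each phased chromosome copy is an independent haploid analysis unit
(relative allele frequencies are unchanged by this, and it doubles the
sample count). Sites outside target-called windows become missing.
Survivor filters: target-ancestry fraction strictly greater than 0.20
(computed from the calls by default; a hook accepts external genome-wide
ancestry estimates instead), and at least 0.10 of the platform-overlap
SNPs retained.

The pairwise distance is 1 − IBS over jointly non-missing markers,
which equals the all-marker-denominator similarity divided by
(1 − joint missing fraction) — the only reading of a "divide by one
minus the missingness" correction that keeps IBS in [0, 1] and removes
the missingness bias. Pairs sharing fewer than 100 markers (about the
minimum seen in real masked array data) are set missing; before MDS,
samples are dropped greedily by missing-pair count, never imputed.
Classical (Torgerson) MDS returns positive-eigenvalue coordinates and
reports negative eigenvalues for diagnostics.

Outlier handling: the default automated rule flags samples whose median
nearest-neighbour distance (first two dimensions, log scale) has a
robust z-score above 6. A coordinate-level median/MAD rule is also
available but is appropriate only for unimodal embeddings — on a
clustered embedding it flags entire clusters, which is exactly the
failure the isolation rule avoids; removing more than 20% of samples is
treated as an error in either case. An explicit exclusion list is always
honoured, mirroring inspection-driven removals.

## Statistics

Hudson's FST is computed as a ratio of averages with the finite-sample
correction p(1−p)/(n−1) in the numerator; a component-FST variant
without sample-size correction serves ancestry frequency vectors from
clustering output. Both are labelled in output because they answer
slightly different questions. Split times invert
1 − FST = (1 − 1/(2·Ne))^t and convert to years at 29 years per
generation (configurable).

f3(target; A, B) is the mean of (t−a)(t−b), with the target
heterozygosity correction t(1−t)/(n_t−1) subtracted per marker when
target allele counts are supplied; f4(A,B;C,D) is the mean of
(a−b)(c−d). Standard errors are delete-one-block jackknives over blocks
of 500 consecutive SNPs (configurable), which is robust to LD at array
marker spacing. The amplitude classification rule takes externally
fitted weighted-LD amplitudes (C, se) per candidate source pair,
computes Z = (C_max − C)/sqrt(se_max² + se²) against the best pair,
retains pairs with Z < 2, and reports macro-group frequencies among
retained pairs. The exponential curve fitting that produces the
amplitudes is out of scope; amplitudes enter through a CSV contract.

## Geography and culture

Clustering is EM for Gaussian mixtures with BIC selection over both the
number of components (1..9 by default) and the covariance family
(spherical/diagonal/tied/full) with 10 seeded restarts. A distance
matrix input is first embedded by classical MDS (default 10
dimensions), since a mixture on raw distances is undefined. The
pipeline clusters the first two MDS dimensions, where the structure
analyses read the embedding.

Kernel utilization regions evaluate a 2-D Gaussian KDE on a grid and
take the smallest density superlevel set holding the stated probability
mass (default 90%); degenerate point sets get a jitter floor. The
Procrustes statistic is the trace correlation after centering, unit
Frobenius scaling and optimal rotation (reflections allowed by
default); significance is a row-permutation test with
p = (1 + #{r_perm ≥ r_obs})/(n_iter + 1).

Cross-validated predictive error fits linear models of each embedding
dimension on geography (lat, lon), one-hot language, and one-hot
subsistence (two alternative schemes), singly and in the standard
combinations, with identical fold partitions across models; the error
metric is mean held-out squared error. Minimum-norm least squares
covers rank-deficient designs, and a category absent from a training
fold falls back to the intercept. Covariates attach to each chromosome
from its population, so population-level covariates are compared
against chromosome-level genetic coordinates.

## Problem sizes

The standard synthetic cohort is 8 populations × 20 diploid individuals
(320 haplotypes), 20,000 markers on 10 chromosomes × 100 cM, with three
Khoesan-like sources at pairwise FST 0.05 under a deeper stem
(donor-group FST ≥ 0.15 against Bantu-like and European-like sources),
Khoesan proportions cycling over 30–80% and a 20-generation pulse. The
deconvolution-fidelity check uses pure-ancestry haplotypes at 50
markers/cM over 5 × 60 cM, matching array density, because single-
ancestry genomes make every window's truth unambiguous. Split-time
recovery uses 50,000 markers and 100 sampled alleles per population.
These sizes give each check comfortable statistical resolution while a
full run of the test suite and the acceptance script stays within a few
minutes on one CPU.

## Limitations

The simulator draws markers in linkage equilibrium within populations;
LD exists only through admixture mosaics. Consequences: block-jackknife
SEs are conservative relative to real arrays, and phasing is taken as
exact (no switch errors), so passing tests demonstrate correctness of
the algorithms under the stated model, not robustness to phasing or
genotyping artefacts. Window truth at tract boundaries is inherently
mixed, so cohort-level misassignment rates include boundary windows
that no windowed method can label uniquely. No coalescent genealogies,
selection, or mutation model; populations are exchangeable samples from
their frequency vectors. Real-data headline quantities that depend on
unpublished inputs (FST tables, donor panels) are outside what the
synthetic cohort can reproduce and are not claimed.
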