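# Methods

## The two-level sign test

The model addresses a specific failure mode of pooled ASE tests: imprinted
genes can be "leaky" (residual expression from the silenced haplotype, from
a biallelic isoform or a biallelic cell minority), so requiring strictly
monoallelic expression misses them, while pooling read counts across
individuals requires an overdispersion model for RNA-seq counts. The
two-level construction sidesteps both. Level one reduces each individual ×
gene to the sign of the binomial Z-score z = (m − n/2)/√(n/4), n = m + p:
does this individual express the maternal or the paternal copy more?
Level two tests whether those signs are symmetric across individuals with
an exact Binomial(n, ½) test. Any within-individual overdispersion affects
the magnitude of z, never its sign, so the second level is calibrated
without a dispersion parameter.

Filters, in order: individuals with m + p below `min_parental` (default 5,
applied to the sum; an each-parent variant is available via
`min_parental_mode="each"`) are dropped, then exact ties (z = 0) are
excluded before n is formed. A gene with no individual left is reported
untestable with a NaN p-value and excluded from the FDR correction rather
than assigned p = 1 — an untestable gene carries no evidence in either
direction.

The two-sided p-value is doubling-the-smaller-tail capped at 1,
min(1, 2·Σ_{i≤min(k,n−k)} C(n,i)/2ⁿ), evaluated via the log-space binomial
CDF. Under p₀ = ½ the distribution is symmetric, so this equals every
standard definition of the two-sided exact test; the log-space route keeps
p-values of order 10⁻⁴⁰ accurate to full double precision (verified in the
suite against big-integer rational arithmetic to 10 significant digits for
all n ≤ 300). Multiple testing uses Benjamini–Hochberg step-up, the field
default where only an FDR level is specified; the procedure sits behind
`bh_fdr` and could be swapped without touching the test.

## Category assignment

Tested genes are classified from two pooled metrics: `single_parent` when
one parent's pooled count is exactly zero (complete silencing at the
resolution of the data), `candidate_imprinted` when q < 0.05 and the
majority parent holds at least `major_share_threshold` (default 0.8) of
pooled parental reads, `asymmetric_only` for the remaining significant
genes. The 0.8 threshold is a package choice, not an estimate: published
category assignments of this kind rely partly on literature curation,
which a program cannot reproduce, so the raw metrics
(`pooled_major_share`, direction counts) are always reported alongside the
category and the threshold is configurable. `asymmetric_only` genes are
deliberately *not* called imprinted — a cis-eQTL in a heterozygous parent
produces exactly this signature (consistent allelic imbalance with
expression from both haplotypes).

## Read-to-parent assignment

A site is informative for an individual iff it is heterozygous and its
alleles have known parental origin. A read is maternal if at least one
informative call matches the maternal allele and none matches the
paternal allele (symmetrically paternal); everything else is unknown.
Two conservative rules where the underlying procedure is underdetermined:
calls matching neither haplotype allele (sequencing error) and conflicting
calls across sites within a read both yield unknown, because a genotype
error should never manufacture a parental call. Reads are linked to genes
by the gene id on the read record; coordinate-based overlap assignment,
alignment, duplicate marking and mapping-bias correction are upstream
concerns and out of scope — the module assumes de-duplicated,
bias-corrected input.

Expression filtering keeps a gene iff log2(CPM) ≥ 1 (CPM from total
counts m+p+u against the individual's library size) in at least 20
individuals, and removes chrX/chrY genes regardless of expression, since
X-inactivation and hemizygosity confound parent-of-origin inference there.
The removal rule is stated in the literature in a form that is ambiguous
about quantifier order; the implemented reading ("keep iff enough
individuals pass") is the only one under which the rule is monotone in
expression.

## The synthetic cohort

The generator emulates the data-generating process the analysis assumes,
with defaults chosen to match the target study design: 306 individuals,
transcript totals negative-binomial (gamma–Poisson, dispersion 0.2 — a
typical bulk RNA-seq value; the totals only set the scale of the unknown
category, so results are insensitive to it), an informative-transcript
probability of 0.018 so that ~98 % of transcripts are of unknown origin,
10 % of phased sites lacking parent-of-origin information, site
heterozygosity 0.5, and a mean informative parental depth of 50 per
individual × gene. Gene classes: fully imprinted (maternal- or
paternal-silenced, leak 0), leaky imprinted (default leak rate 0.05 —
small enough to be invisible to a monoallelic-expression rule, large
enough that every individual shows both alleles at depth ~50), balanced
biallelic, and biallelic with a cis-eQTL (maternal share 0.7 in
regulator-heterozygous individuals, drawn per individual at rate 0.5).
Informative transcripts are maternal with the class probability; m, p, u
arise by binomial thinning, so m + p + u equals the simulated total by
construction.

When a coherent dataset (genotypes + counts + reads) is requested, the
informative-transcript probability is zeroed for individuals without any
informative SNP in a gene, which makes the read-level round trip
(simulate reads → classify → aggregate) an exact identity at zero read
error. Read records are abstract single-end transcript observations
carrying one informative-SNP allele each; isoform structure, mapping bias,
PCR duplicates and base qualities are not modelled. Consequences for
interpretation: passing recovery tests show the statistical machinery is
correct under the assumed sampling model, not that the pipeline is robust
to alignment artefacts — those are removed upstream in any real analysis.

Methylation: ICR CpGs are drawn around beta 0.5, control regions around
0.03 / 0.97, with Gaussian noise (default sd 0.05, clipped to [0, 1]).
This emulates the marginal beta distributions at imprinted vs ordinary
regions, not probe chemistry, cell-composition effects or haplotype-level
methylation (bulk arrays cannot resolve the latter, which is why the
module only ever claims *consistency* with imprinting).

Determinism: every operation draws from `default_rng([seed, stream_tag])`
with a fixed per-operation tag, so operations are reproducible
individually and in any combination; equal configs give byte-identical
serialised outputs.

## Methylation summaries

M-values convert by beta = 2^M/(2^M+1), the inverse of the logit2
definition of the M-value; the pair round-trips to 1e-12 and maps the
partial band endpoints exactly (M = ±log₂3 ↔ beta = 0.25/0.75). Band
endpoints are inclusive — the weaker reading of "between". A region is
consistent with imprinting when it has ≥ `min_cpgs` (3) CpGs and
≥ `min_fraction` (0.5) of its CpG medians fall inside the band; both are
explicit configuration, since no principled count exists and the
literature judges such regions by eye. CpGs are intersected with BED
regions as 0-based half-open vs 1-based positions (start < pos ≤ end).

## Validation concordance

Two result tables agree on a gene when sign(n_mat − n_pat) matches. Genes
untestable in either cohort are reported separately rather than counted
as disagreement. The pipeline's validation cohort reuses the discovery
cohort's gene truth with an independent seed and a smaller sample
(default 99), mimicking replication in a second tissue from different
individuals.

## Problem sizes and numerical notes

The acceptance-level checks run at the sizes their claims are stated for:
10,000 balanced genes × 100 individuals for type-I error, 100 imprinted
among 900 balanced genes for recovery, 1,000 regions for methylation
classification, the full (k, n ≤ 300) grid for the tail oracle. All
complete in well under a minute each on one CPU; the per-gene test is
vectorised (groupby aggregation plus one vectorised binomial-CDF call), so
cohort size is not a practical constraint.

Known limitations: no kinship correction at the second level (individuals
in a pedigree are not independent; the sign test treats them as
exchangeable draws), no isoform-level resolution (a gene with one
imprinted and one biallelic isoform dilutes towards `asymmetric_only`),
and single-parent calls are sensitive to genotyping errors in exactly the
way the conservative read rules try to limit but cannot eliminate.
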