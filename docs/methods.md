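# Methods

## Scope and model of the data

`lnctar` re-implements, as a tested library, the analysis chain used to
characterise lncRNA–mRNA co-regulation in an unreplicated pooled RNA-seq
design: one control and two mutant conditions, each sequenced as a single
pooled library built from three cultures. The chain is

1. FPKM expression from a gene × sample count matrix,
2. pairwise differential expression between pooled libraries with an exact
   conditioned-Poisson test,
3. consensus mRNA/lncRNA classification from multiple coding-potential
   predictors,
4. lncRNA–mRNA target-pair prediction by dual correlation thresholds,
   cis/trans genomic-window classification and a duplex-energy screen,
5. refinement to pairs whose two members are strongly co-regulated, and
6. 2^−ΔΔCt qPCR-style validation.

Read alignment, assembly and quantification from reads are upstream of this
package: its inputs are count matrices, GTF annotation, coding-potential
call tables and Ct tables, all of which the synthetic-data module can also
generate with planted structure.

## Differential expression between unreplicated libraries

With a single library per condition, per-gene counts are modelled as
Poisson: x ~ Poi(r·n1), y ~ Poi(r·n2), where n1, n2 are library sizes.
Conditioning on the total t = x + y removes the nuisance rate r:

    y | t ~ Binomial(t, q),   q = n2 / (n1 + n2).

This is the classic exact test for unreplicated digital expression data
(Audic–Claverie). The upstream tool named for this step in the study this
package models publishes no formulas, so the conditioned-Poisson test is
used as the nearest published equivalent; this substitution is deliberate
and is the package's central statistical choice.

The two-sided p-value uses the minimum-likelihood rule: the summed
probability of all outcomes y′ ∈ {0..t} whose conditional probability does
not exceed that of the observed y. Ties are included, with a relative
tolerance of 1e−7 on the pmf so that exact symmetric ties (q = 1/2) are
never split by floating-point noise; genuinely distinct outcome
probabilities on these totals differ by far more. All pmf evaluations are
done in log space (gammaln) so deeply significant genes keep representable
p-values (~1e−300). Doubling-the-smaller-tail is not offered; the
minimum-likelihood rule is oracle-checkable by direct summation and is what
the tests verify, to 1e−12 relative over the full x, y ≤ 60 grid at library
ratios 0.5, 1, 2.

Fold change is computed on library-normalised counts with a pseudocount
(default 1) in both numerator and denominator:

    log2FC = log2( ((y + c)/n2) / ((x + c)/n1) ),

which is finite for zero counts and antisymmetric under swapping the
samples. Gene length cancels within a gene, so this equals the FPKM fold
change up to the pseudocount.

Significance calling is a conjunctive two-stage filter, each stage
toggleable: a screen (p < 0.05 and |log2FC| ≥ 1.5) and a stringent rule
(fold change ≥ 2.00 and BH-FDR ≤ 0.001). Boundary semantics follow the
operators as written: the p threshold is strict, the others inclusive. FDR
is Benjamini–Hochberg, computed within each pairwise comparison over all
tested genes. The exact test is conservative-to-nominal under its own
model: on a null Poisson simulation with equal rates and equal pooled
libraries (10,000 genes) the fraction of p < 0.05 lands near 0.046.

When replicate columns are pooled, Poisson noise pools to Poisson and the
test is calibrated; with extra-Poisson dispersion the p-values are
anticonservative, which is the known cost of the unreplicated design. The
fold-change screen, not the p-value, is then the effective guard against
null calls — this behaviour is visible in the planted simulations.

## FPKM and library bookkeeping

    fpkm[i, j] = 1e9 · counts[i, j] / (library_sizes[j] · length[i])

Library sizes default to assigned-count column sums and can be overridden
with mapped-read totals (which may exceed assigned counts). Gene length is
the spliced length of the gene's longest transcript — a documented stand-in
for transcript-aware quantification, which is out of scope. Pooling sums
counts and library sizes element-wise per condition.

## Consensus lncRNA identification

Transcripts are classified by intersecting boolean coding calls: lncRNA
only if every required tool calls the transcript non-coding, mRNA only if
every tool calls it coding, otherwise unclassified and excluded downstream.
The number of required tools defaults to all registered tools. The
predictors are pluggable; the shipped baseline is a deterministic
longest-ORF heuristic (coding iff longest ATG→stop ORF ≥ 300 nt, threshold
configurable), which is sufficient for fixtures and is *not* a
re-implementation of any published coding-potential tool. Known/novel
partitioning is a set lookup against a reference ID list standing in for a
database query. Gene-level biotype is "mRNA" if any transcript is coding by
consensus, else "lncRNA" if any is consensus-non-coding.

## Target-pair prediction

**Correlation.** Spearman and Pearson coefficients are computed between
every differentially expressed lncRNA and every mRNA across all
replicate-level expression columns (at least 3 required; the pooled design
alone cannot support correlations, which is why the generator emits
replicate columns). Spearman is Pearson on average ranks — an identity the
tests assert. Pairs require both coefficients ≥ 0.6, boundary inclusive.
Signed correlation is the default; an absolute-value variant exists because
inversely co-regulated pairs (which the refinement stage deliberately
keeps) cannot pass a signed filter.

**cis/trans.** A pair is cis when the lncRNA locus overlaps, by at least
1 bp, the window from 10 kb upstream to 20 kb downstream of the mRNA gene.
Windows are strand-aware with respect to the mRNA by default (for '−'
genes upstream extends beyond the gene end); a strandless mode restores
orientation-agnostic windows. Whole-locus overlap (not TSS distance) is
used, so overlapping loci are trivially cis. Classification is validated
against a per-base membership oracle including ±1 bp probes at both edges.

**Trans energy screen.** Trans candidates must pass a duplex-energy
threshold. The default scorer is a screening proxy, not a thermodynamic
model: the best ungapped antiparallel perfectly-complementary stretch,
scored −2 per G·C and −1 per A·U pair; a mismatch contributes nothing and
terminates a stretch. (Allowing zero-cost mismatches *inside* a window
would let every long random pair accumulate unbounded complementarity,
destroying the screen's discrimination; maximal complementary runs are the
only discriminating reading.) Any adapter producing a (pair, energy) table
— e.g. around a real RNA–RNA hybridization predictor — can replace it. The
default threshold is −25: on the generator's own sequences (mRNA ≈ 2.2 kb,
lncRNA ≈ 0.4 kb spliced) random decoy pairs reach −25 in ≈ 0.05% of cases
while planted complementary windows score ≤ −34; at −20 the decoy rate is
≈ 2.5%, too leaky for a screen. The threshold is configuration, not a
physical quantity.

**Refinement.** Final TAR pairs are those whose lncRNA and mRNA are each
differentially regulated by ≥ 5-fold (|log2FC| ≥ log2 5) in the same
comparison, in either direction — congruent and inverse pairs both
qualify.

## 2^−ΔΔCt validation

Per replicate, ΔCt = Ct(target) − mean Ct over the reference genes
(arithmetic mean in Ct space = geometric mean in expression space);
ΔΔCt = ΔCt − mean ΔCt of the control condition; relative expression =
2^−ΔΔCt. The per-condition headline value is 2^−(mean ΔΔCt), the geometric
mean of replicate values, which makes the control condition exactly 1 by
construction (the arithmetic mean of control replicates exceeds 1 whenever
replicate ΔCt varies, by Jensen's inequality). Significance uses a
two-sided equal-variance Student's t-test on replicate relative-expression
values against the control replicates (Welch available); identical
zero-variance groups return p = 1 by convention. No amplification-
efficiency correction is applied. Adding any constant to every Ct leaves
all outputs unchanged.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study design (three conditions × three
replicates, pooled per condition for DE) with planted structure whose
recovery the acceptance tests measure: DE genes at 8-fold (half up, half
down, in both mutant conditions), ten cis pairs placed inside the partner's
window on either strand, ten trans pairs on different chromosomes with a
20 nt embedded complementary window (≥ −34 proxy score), decoy lncRNAs
placed > 50 kb from every mRNA, mRNA sequences carrying long ORFs and
lncRNA sequences generated ATG-free so the ORF-based calls reproduce the
intended biotypes exactly.

Counts are negative binomial (var = μ + φμ²) around log-normal baseline
means (default mean 200, log-sd 1); φ = 0.01 by default, reflecting the low
biological variability of same-culture triplicates, and φ = 0 recovers the
Poisson assumption under which the exact test is calibrated. Pair members
share a latent per-column log-factor of sd 0.4 whose share of the total
latent variance equals `pair_rho` (default 0.95); the factor is
mean-centered within each condition so it creates cross-column correlation
without perturbing the pooled totals the DE stage sees, and pair-member
baselines are drawn from the expressed stratum (≥ mean/2) so counting noise
cannot dilute the planted correlation. Default problem size is 2,000 mRNAs
and 1,000 lncRNAs on 4 chromosomes — large enough that a ≤ 0.1% null call
rate is a meaningful statement and the whole chain still runs in well under
a minute per seed.

What the generator does **not** emulate: read-level noise and mapping
artefacts, isoform-switching, GC/length biases, batch effects, genuinely
unknown coding potential (its coding calls are internally consistent by
construction), and thermodynamically realistic hybridization. Passing the
planted-recovery suite therefore demonstrates that the chain's logic and
thresholds behave as specified under the stated noise model — not that the
biological discoveries of any particular study are reproducible from raw
data, which would require the original libraries.

## Numerical choices and degenerate inputs

* p-values clipped to [0, 1]; t = 0 gives p = 1; −log10 p capped at the
  smallest positive normal double (≈ 307.65) for volcano tables.
* Zero-variance expression vectors have no defined correlation; such pairs
  are dropped with a logged count rather than propagating NaN.
* Mixed-strand genes are a validation error (the cis window is
  strand-dependent); contradictions between declared and exon-derived
  spans in GTF input log a warning and the exon-derived span wins.
* Clean-read percentages are rounded half-up to 3 decimals.
* All generators are pure functions of (seed, config); pipeline re-runs
  with the same seed produce byte-identical outputs.

## Known limitations

* The exact test's Poisson assumption understates biological variability;
  with pooled single libraries this is a property of the design, not the
  implementation. Replicated-design tests (negative binomial GLMs) are
  deliberately out of scope.
* The duplex-energy proxy ranks complementarity, not free energy; its
  threshold is a calibration against the generator's decoys, and any
  real-data use should swap in a genuine hybridization tool through the
  adapter interface.
* Correlations over 9 replicate columns have wide sampling variability;
  the 0.6 dual threshold admits a few percent of null pairs, which the
  energy and fold-change stages then remove.
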