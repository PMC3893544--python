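# Methods

This note documents the models, the synthetic study design, the numerical
choices, and the known limitations of `hgtkit`.

## The screening statistic

Homology hits for each query ORF are partitioned by whether the recipient's
taxonomic rank name (default `Lamiales`) occurs in the subject lineage, an
ordered name list joined from a subject→lineage TSV. The decision statistic
is the ratio of the best outgroup score to the best ingroup score after
removing self-hits (same id, or 100% identity over the full query span); a
query is a candidate when the ratio strictly exceeds the threshold
(default 1.2). Bit scores are used because they are length- and
database-size-normalised, making the ratio portable across searches; the
score column is whatever the hit table carries, so raw scores work the same
way if supplied consistently. Queries with no ingroup hit at all get ratio
+∞ and are candidates-with-flag (`no_ingroup_hit`) rather than silent
positives: the ratio is undefined there and phylogenetic confirmation is
mandatory. The synthetic screen builds its hit tables from BLOSUM62
Smith–Waterman scores over the simulated reference set — the statistic only
needs a common score scale.

Contamination filtering keeps a transcript when its fragment count summed
over all host-free stages is ≥ 1 (union rule: the evidence is pooled across
host-free samples rather than required in each). Read assignment is a
k-mer-voting substitute for probabilistic multi-mapping: a fragment goes to
every transcript sharing its maximal matching-k-mer count, ties split
1/t; on error-free synthetic reads this reproduces true origins exactly,
which is what the contamination filter needs. Quality trimming truncates at
the first base below the Phred floor (after removing the adapter's first
exact occurrence and everything 3' of it) — a conservative single-pass rule
rather than a sliding window.

ORF prediction scans all six frames for the longest ATG-to-stop segment
(stop excluded), ties broken forward-before-reverse then leftmost; with no
ATG the longest stop-free stretch is returned flagged. Length gates are
inclusive: ≥ 300 nt and ≥ 100 aa.

## Intron mapping and retention

`map_introns` is a spliced alignment implemented as a global affine-gap
alignment in which cDNA-side gaps are cheap to extend (open −6,
extend −0.05) and genomic-side gaps are expensive — so skipped introns
coalesce into contiguous genomic-only blocks — with free end gaps.
Genomic-only runs ≥ 40 nt (configurable) are introns. Junction repeats make
the exact cut ambiguous; within the slide window the GT…AG-conformant
position is preferred, else the leftmost. GT…AG conformity is reported, not
enforced. Intron-position homology across genes is expressed as
(protein-alignment codon column, phase), which is how positions are
compared across species. Retention detection diffs two isoforms by longest
common prefix/suffix: exactly one inserted block whose ambiguity interval
covers a known intron boundary is called partial retention.

## Phylogenetics

Distances are p or Poisson (−ln(1−p)) with pairwise gap deletion. NJ is the
Saitou–Nei algorithm with a deterministic tie-break (lexicographically
smallest cluster-label pair) and negative branch lengths clamped to zero
(deficit logged). Bootstrap resamples columns with replacement; support is
the percentage of replicate NJ trees containing each original bipartition;
replicates that saturate the Poisson correction clamp p just below 1 rather
than abort. The placement test works on unrooted splits: the smallest
query-containing side of any edge that includes a donor member must exclude
all recipient-lineage members at support ≥ 75 (default) for
`hgt_supported`; the mirror-image situation yields `native`, anything else
`unresolved`. ML tree search was deliberately not implemented: the
conclusion in scope rests on clade membership plus support, which NJ
establishes at this scale.

## Type-I functional divergence

Per site, substitution counts (x₁, x₂) are minimum (Fitch) parsimony counts
on each cluster's own topology; all-gap sites in a cluster are excluded and
gapped leaves contribute a full state set. The likelihood is a two-component
mixture: with probability 1−θ₁ both clusters share one rate λ ~ Γ(α, rate α)
and (x₁, x₂) are Poisson(λd₁), Poisson(λd₂) — marginally a bivariate
negative binomial with closed form — and with probability θ₁ the rates are
independent draws. Free parameters (θ₁, α, d₁, d₂) are maximised by L-BFGS-B
from four starts; the null (θ₁ = 0) is refit separately so the LRT is
non-negative by construction. The SE of θ₁ comes from the observed
information (central-difference Hessian), and per-site posteriors from
Bayes' rule at the MLE. The p-value uses the plain χ²₁ convention by
default, with the 50:50 χ²₀/χ²₁ boundary-corrected value reported alongside.

Parsimony counts underestimate true substitution numbers on divergent
trees (multiple hits collapse), which biases θ̂₁ slightly downward. The
recovery study therefore uses 24-taxon clusters with terminal branches of
0.1 and internal branches of 0.04 substitutions/site — enough sequences
that parsimony tracks the true counts — where θ̂₁ at θ = 0.5 lands within
±0.1 in ≥ 90% of replicates at 1,000 sites. With 4-taxon clusters and long
branches the attenuation is substantial and θ̂₁ is conservative; this is a
property of parsimony-count substrates generally, not of this
implementation.

## Codon models

The generator is GY94-style over the 61 sense codons of the universal code:
rate to a codon one nucleotide away is π_j · κ^[transition] ·
ω^[nonsynonymous], zero otherwise, each class matrix scaled to one expected
substitution per codon per time unit. Transition probabilities come from
the symmetrised eigendecomposition (the chain is reversible), cached per
(κ, ω). The likelihood is Felsenstein pruning over pattern-compressed
sites with per-pattern rescaling; mixture models sum class likelihoods at
the root; branch-site models select the foreground matrix per edge. The
foreground is the stem edge above the MRCA of the designated leaves, or the
whole clade with `foreground_clade=True`.

Fitting: branch lengths are estimated jointly with κ and ω under M0 (log
scale, L-BFGS-B) and then held fixed for every other model. This is the
package's main simplification relative to per-model branch-length
re-optimisation; it reduces runtime by an order of magnitude and leaves the
LRT ladder intact (nesting is preserved because all models share the same
fixed lengths), at the cost that absolute lnL values are not comparable to a
full per-model fit. Model parameters are optimised multi-start with bounds
κ, ω ∈ [10⁻⁴, 99]; M7/M8 discretise the beta into K = 10 equal-probability
categories via incomplete-beta category means; alternatives are additionally
started at their null's MLE (`refine_from`), which guarantees lnL_alt ≥
lnL_null up to optimizer tolerance. The M0–M3 test defaults to df = 4
(k = 3 categories: two extra ω's and two proportions); the df is
user-overridable where a different convention is wanted. Site
identification is naive empirical Bayes at the MLEs with the 0.75 posterior
threshold; the full prior-integration (BEB) grid is future work.

## Expression

FPKM = count / (length_kb × total_fragments/10⁶) per stage, with a
conservation identity (Σ FPKM·length_kb·total/10⁶ = Σ counts) holding to
1e-9. Reference-gene stability: geNorm M (mean SD of pairwise log₂
quantity ratios — equivalently of pairwise ΔCt, so the DeltaCT measure
coincides with M up to the same ranking), BestKeeper (raw Ct SD, not
shift-invariant by design), and a composite geometric-mean rank; the
model-based NormFinder decomposition is omitted — the stable-gene
conclusion is reachable from the three implemented measures. ΔΔCt uses
sample-paired ΔCt replicates, plain two-sample Student's t against the
calibrator (no Welch correction, matching the convention of the analysis
this mirrors), and a delta-method SE on the fold (SE_fold = ln2 · fold ·
SE_ΔΔCt); whether the uncertainty is quoted on the fold or on ΔΔCt was an
open choice and the delta-method fold SE is what is reported.

## Synthetic study design

The default taxonomy has a recipient and sister species in one order
("Lamiales"-like, path 0.3 subs/site apart), a two-species donor order
("Brassicales"-like, 1.2 subs/site from the recipient), and an outgroup.
Gene families evolve by Poisson substitution (uniform replacement) with
geometric-length indels (rate 0.02/site/unit, mean 3 aa) tracked through a
site registry so the true alignment is exact. The recipient's own family
members are withheld from the reference database (they are the query
organism). Planted foreign genes are donor copies diverged a further 0.1
subs/site; contaminants are exact host copies; one foreign gene can be
emitted as two isoforms differing by a 21-nt (frame-preserving) partial
retention of its second intron, with the intron's leading codons drawn from
sense codons so the retained block introduces no stop. Reads are uniform
paired 50-mers at Poisson depth (default 8×); contaminants get zero
host-free coverage by construction. The qPCR design spans nine
developmental stages plus a 0–24 h wounding course, five replicates, four
candidate references with increasing drift (0, 0.35, 0.5, 0.7 cycles) and
replicate noise (0.02–0.3), the drift-free gene being the planted stable
reference; planted inductions are 1.3× at 1 h and 3.2× at 24 h with 0.1
cycles of target replicate noise.

Because the deposited sequence records are not bundled, the
accession-anchored structural facts are checked on deterministic synthetic
stand-ins (`synth.ssl_standins`, labelled synthetic throughout): a 1597-bp
cDNA whose longest ORF is 369 aa, a genomic copy with two GT…AG introns,
isoforms differing by one 21-nt block at the first intron's boundary, and a
donor homolog at 88% amino-acid identity. The functions under test are the
production implementations; only the inputs are stand-ins, so these checks
validate the machinery, not the real records.

What the generator does **not** emulate: assembly artifacts (chimeras,
fragmentation), instrument error profiles, codon-usage bias in reverse
translation, rate heterogeneity across protein-family sites, and
amplification-efficiency deviations in qPCR. Passing tests therefore show
the pipeline is correct under its stated models, not that real data meet
those models.

## Problem sizes and determinism

The bundled benchmark is 20 native + 3 foreign + 5 contaminant transcripts
at 8× error-free coverage. Recovery studies use 8 taxa × 500 codons for M0
(20 seeds), 6 taxa × 150 codons × 100 seeds for the M1a–M2a type-I-error
calibration, 24-taxon clusters × 1,000 sites for θ₁ (20 seeds), and 200
seeds for the qPCR band — sizes chosen so the whole suite runs on a single
CPU in minutes while keeping the statistical assertions meaningful. Every
stochastic component takes a seed or `numpy.random.Generator`; identical
configuration gives byte-identical outputs, and the pipeline manifest
records checksums to prove it.
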