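# Methods

## Model and procedure

A gene's allelic expression in one cross direction is summarised by the
pair (m, p) of maternal and paternal read counts summed over the gene's
informative SNPs.  Under biallelic expression the expected maternal
fraction is set by ploidy: f = 1/2 in the diploid embryo and f = 2/3 in the
triploid endosperm (2 maternal : 1 paternal genome copies).  Deviation is
tested with the Pearson χ² statistic on 1 df against expected counts
(nf, n(1−f)), without continuity correction, and the upper-tail p-value of
χ²₁.  Calling then combines significance with effect-size thresholds on
the parental fraction:

| tissue    | null f | MEG requires          | PEG requires          |
|-----------|--------|-----------------------|-----------------------|
| embryo    | 1/2    | p < α and m/n > 2/3   | p < α and p/n > 2/3   |
| endosperm | 2/3    | p < α and m/n > 0.80  | p < α and p/n > 0.50  |

with α = 0.05 (raw p-values; a Benjamini–Hochberg option exists but is off
by default), n ≥ 20 for testability, and all threshold comparisons strict.
">66%" is interpreted as the rational 2/3 (the 2:1 ratio threshold).  The
paternal fraction is computed directly as p/n rather than 1 − m/n so that
exact threshold ties resolve identically for both parents in floating
point.

### Reciprocal combination

Each direction of a reciprocal pair is classified independently and a gene
is MEG (PEG) for the pair only if both directions agree — the conservative
reading of a reciprocal design, and the one that separates imprinting from
founder-allele effects: an allele favoured irrespective of parent shows a
high maternal fraction in one direction and a low one in the other, and
falls through to biallelic.  If either direction is untestable the pair's
call is untestable; a one-direction signal is never reported as imprinted.
The ≥20-read rule likewise applies per direction.  A pooled mode (counts
summed across directions before one test) is provided for sensitivity
analyses; it trades the allele-effect guard for power at low depth.

### Conservation sets

Four reciprocal pairs are compared: the hybrid pairs BM-C/C-BM and
MB-C/C-MB against a two-parent reference, BC/CB for the "Mo17-added" group
(sets I–VI) and MC/CM for the "B73-added" group (sets VII–XII, mirrored
from I–VI since only the reference changes).  Within each comparison a
testable gene is in exactly one of {only-hybrid-imprinted,
only-reference-imprinted, imprinted-in-both}, so I/II (and IV/V, VII/VIII,
X/XI) are mutually exclusive and the "overlap of the four status-differs
sets" is implemented as (I∪II)∩(IV∪V) — the literal four-way intersection
is empty by construction.  Non-conserved = status differs in both
comparisons; conserved = imprinted in all compared pairs (III∩VI resp.
IX∩XII); anything else, including any untestable pair, is unclassified —
absence of evidence is not treated as a status change.  By default
"imprinted" pools tissues (imprinted in either tissue; untestable only if
untestable in both); a per-tissue mode is available.  Whether MEG/PEG
direction must match across pairs is configurable through the status
predicate; the default requires only "imprinted", since the set definitions
speak of imprinting, not of its direction.

### Clusters, motifs, expression subgroups

Imprinted genes are chained per chromosome by single linkage: consecutive
genes (sorted by anchor, default the gene start; midpoint available) join a
cluster when their anchors are ≤ 1 Mb apart, and chains with ≥ 2 members
are reported — a chained cluster may span more than 1 Mb overall, only
consecutive gaps are bounded.

Promoters are the 1.5 kb upstream of the ATG.  Scanning is exact IUPAC
consensus matching, position by position, overlapping hits all reported, on
both strands (reverse complement of the consensus; palindromic consensi can
be deduplicated).  An N in the sequence matches nothing.  The 13 default
element classes (hormone: ABRE, CGTCA-motif, TGACG-motif, ERE, TGA-element,
TCA-element; light: G-box, GT1-motif, TCT-motif, Box-4; stress: ARE, W-box,
LTR) carry PlantCARE-style core consensi chosen by us as reasonable
defaults — motif databases differ on exact cores, so the table is a
configurable TSV and the test suite relies on planted instances, not on any
particular consensus.  No enrichment statistic is attached to group ratio
differences.

Relative expression is FPKM divided by the gene's maximum over samples
(all-zero rows map to zeros, not NaN, so clustering never sees undefined
values); this makes the subgrouping invariant to per-gene uniform scaling.
Subgrouping clusters the relative rows with average linkage and Euclidean
distance and cuts the tree at k = 2 (k configurable; the choice of two
groups — endosperm-primary vs constitutive — is the minimal reading of the
qualitative subgroup description).  The cluster with the largest positive
endosperm margin (mean relative expression in endosperm samples minus mean
elsewhere) is endosperm-primary; with no positive margin (e.g. all-flat
profiles) everything is constitutive.  Genes are sorted by id before
linkage so results do not depend on input order.

## Synthetic data: what it emulates and what it does not

The generator draws per-gene truth statuses i.i.d. (defaults 5% MEG, 5%
PEG, 5% low-coverage, rest biallelic), places genes non-overlapping along
chromosomes with random 20–300 kb gaps, and gives each gene at least one
SNP informative for every default cross (hybrid founders share an allele
differing from the inducer) plus extra SNPs of mixed patterns that exercise
the informativeness filter.  Counts are beta-binomial around the gene's
true maternal fraction with common overdispersion ρ (binomial at ρ = 0,
the default), at Poisson depth (mean 100 by default; 200 for the recovery
analyses, 150 for the `analysis/` narrative — sizes chosen to keep the
suite fast while leaving sampling error well inside the asserted margins).
True fractions default to 0.95/0.05 (embryo MEG/PEG) and 0.95/0.20
(endosperm); biallelic genes sit exactly on the dosage null, so endosperm
biallelic θ = 2/3.  Untestable genes are simulated as low depth (clipped
strictly below the 20-read rule), not missing rows, so the testability
filter is exercised.  Replicates are not modelled: counts represent
replicate-merged totals, consistent with merging biological replicates
before identification.  Per-gene totals are spread multinomially over the
gene's informative SNPs, so aggregation through the counting path recovers
them exactly.

"Swapping parental roles" is implemented as a truth-status swap (MEG↔PEG,
biallelic unchanged, fractions recomputed): in the embryo with the
symmetric default θs this equals mapping θ → 1−θ, and in the endosperm it
re-applies the 2:1 dosage to biallelic genes, which is what a genuine
re-cross would do.

What the generator does **not** emulate: read-level artefacts (mapping
bias, sequencing error beyond the allele-count noise), maternal
contamination of endosperm dissections, founder-specific cis effects
(truth statuses are parent-of-origin only, so on synthetic data the
conservation analysis finds conserved and unclassified genes but no
non-conserved ones unless the user constructs per-pair differing calls),
linked SNP haplotypes, or expression correlation between neighbouring
genes.  Passing tests therefore demonstrate the correctness of the
statistics and plumbing under the stated noise model, not robustness to
alignment-level biases — on real data those must be handled upstream
(e.g. by aligning to both parental genomes, which is outside this
package's scope and documented only as a caveat).

## Numerical and design notes

- χ² is computed closed-form and vectorised; p = 1 exactly on the null and
  underflows to 0 for extreme counts, which only strengthens calls.
- Genes appearing in one direction of a pair but not the other are treated
  as zero-count (hence untestable) in the missing direction.
- Multi-gene SNPs are rejected at genotype load time: one SNP, one gene,
  keeps counts unambiguous.  Third-allele reads are discarded with a tally,
  not errored, tolerating sequencing error.
- Cluster chaining is transitive; input order never matters (stable sort by
  chrom, anchor, gene id).
- All random streams derive from a single seed via named sub-streams, so
  every artefact (including emitted fixture bytes) is reproducible.

## Known limitations

- The endosperm PEG rule (paternal fraction > 0.50 against a null paternal
  fraction of 1/3) is intentionally asymmetric with the MEG rule and makes
  endosperm PEG calls easier than MEG calls at moderate depth; this mirrors
  the stated thresholds rather than a symmetry principle.
- With default thresholds the fraction rule, not α, binds at low depth, so
  realised type-I error is far below α; users lowering `min_reads` should
  re-check error control.
- The strict both-directions rule halves power when one direction is
  marginal; the pooled mode recovers it at the cost of the allele-effect
  guard.
- Interspecies conservation joins depend entirely on the user-supplied
  ortholog/imprinting table; no ortholog inference is performed.
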