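# Methods

This note records the models and procedures implemented in `panfam`, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical choices a maintainer would want
written down.

## Candidate identification

Domain evidence comes from HMMER per-domain tables: the filter applies to
the per-domain *independent* E-value (column 13) and per-domain bit score
(column 14), thresholds E ≤ 1e-5 and score ≥ 20. Homology evidence comes
from 12-column tabular hits with query lengths supplied separately;
coverage is (q_end − q_start + 1)/query_len of the best HSP — no HSP
tiling, the simplest defensible reading. Both evidence types are required
by default (`require_both=True`); an OR mode exists because screening
pipelines differ on this point.

Protein properties: molecular weight from average residue masses minus
one water per bond; GRAVY as mean Kyte–Doolittle hydropathy; aliphatic
index X_Ala + 2.9·X_Val + 3.9·(X_Ile + X_Leu) in mole percent; pI by
bisection of the Bjellqvist net-charge model (ExPASy-compatible pKa set)
to |charge| < 1e-6 within pH 0–14; instability index from the Guruprasad
dipeptide weight table (via Biopython's ProtParam).

## Orthogroup clustering

Greedy incremental clustering in the style of CD-HIT: records sorted by
length descending (ties: gene id ascending); each record joins the first
existing cluster whose **representative** it matches, else founds a new
cluster. The explicit sort makes the partition invariant to input order,
and the founder (longest, then lexicographically smallest) is the
representative.

Pairwise comparison uses a semiglobal alignment (free end gaps; match +1,
mismatch −1, gap open −5, gap extend −1, via Biopython's
PairwiseAligner). Identity is identical residues over the **shorter**
sequence's length (the emulated tool's global-identity convention —
configurable), coverage is the aligned span over the **longer** sequence,
and the alignment length excludes terminal free gaps. Defaults: identity
≥ 0.95, longer-coverage ≥ 0.90, alignment ≥ 100 aa.

An optional 5-mer containment prefilter (skip pairs sharing < 20% of the
smaller sequence's 5-mers) is a pure speed device: sequences related at
≥ 95% identity share far more 5-mers than the cutoff, so it cannot change
results on data near the threshold regime; the test suite asserts
identical partitions with and without it. The pipeline enables it.

## Occupancy classes

For n accessions: core = n; soft-core = ⌈0.9 n⌉ … n−1; cloud = 1 … max(1,
⌊0.1 n⌋); shell is the remainder — a total partition of 1…n. For n = 20
this is 20 / 18–19 / 3–17 / 1–2. Cloud = occupancy 1–2 (rather than
"single accession only") keeps the partition total and matches the
usual description of cloud genes as absent from ~90% of accessions; a
`strict_cloud` flag restricts cloud to occupancy 1. The copy-number
matrix counts members per accession; presence is its indicator.

## Structural variation

All interval arithmetic is 0-based half-open; GFF3 (1-based inclusive) is
converted on read, so touching intervals never overlap. A TE overlapping
the gene body is **genic** regardless of flank overlap (the position
classes must be exclusive; body overlap is the natural priority). Flank
windows default to 2 kb and are strand-aware (upstream = 5′); a
strand-naive mode mirrors to the left flank. TE codes map to order by
their first letter (R = retrotransposon, D = DNA transposon) and to a
superfamily by letters 2–3 (RLC = Ty1-copia, RLG = Ty3-gypsy, DTC =
CACTA, DHH = Helitron, …); malformed codes count as "unknown".

Duplication typing uses gene rank along each chromosome: tandem =
rank-adjacent homolog (0 intervening genes), proximal = within 10
intervening genes (configurable), dispersed otherwise, singleton = no
homolog. Homolog pairs come from shared orthogroup membership.
Whole-genome/segmental duplication is not called (it needs collinearity
blocks, out of scope); such genes fall into "dispersed", and outputs say
so.

## Ka/Ks (Nei–Gojobori 1986)

Synonymous sites per codon: at each position, the fraction of the three
point changes that preserve the amino acid; changes producing a stop
count as nonsynonymous. S averages the two sequences; N = 3·codons − S.
Differences between codons differing at k positions average the
synonymous/nonsynonymous step counts over all k! shortest substitution
pathways, excluding pathways through stop codons (if every ordering is
blocked — possible only for rare codon pairs — all orderings are used
with stop-involving steps counted as nonsynonymous). Jukes–Cantor
correction d = −(3/4)·ln(1 − 4p/3) applies to both proportions;
p ≥ 3/4 makes the correction undefined (NaN), and Ka/Ks is NaN when Ks
= 0, both excluded from downstream tests with counts reported.

Codon alignments are produced by aligning the translated proteins (same
scoring as clustering), back-translating, and dropping codon columns
with a gap in either sequence; terminal stops are trimmed first.

Per orthogroup, the representative is paired with each other member and
the per-orthogroup Ka/Ks is the mean of defined pair values (median and
all-pairs output are available); the unit of observation for the
core-vs-dispensable contrast is the orthogroup. The contrast uses a
two-sided Mann–Whitney U: exact by full enumeration of group assignments
(ties handled by mid-ranks) when both samples have ≤ 8 observations,
otherwise the normal approximation with tie-corrected variance and
continuity correction. The approximation agrees with enumeration to
about 0.01 at the crossover size.

## Codon usage

Counts exclude the terminal stop; internal stops are errors; ambiguous
codons are skipped and counted. RSCU is count over family mean;
single-codon families (Met, Trp) are excluded throughout. ENC is
Wright's estimator with per-family homozygosity F̂ = (nΣp² − 1)/(n − 1)
for families with n > 1, class means over family sizes {2, 3, 4, 6}, the
three-fold mean imputed as the average of the two- and four-fold means
when Ile is unobserved, F̂ = 0 families excluded from class means, and
the result clamped to [20, 61]. Six-fold families are kept whole by
default (codonW convention); a split into 2+4 boxes is available.

The expected-ENC reference curve is Wright's
ENC* = 2 + s + 29/(s² + (1 − s)²) — note 2 + 0.5 + 29/0.5 = 60.5 at
s = 0.5 and limits 31 and 32 at the endpoints.

CAI follows Sharp & Li: pooled reference counts with zeros replaced by
0.5, w = RSCU/RSCU_max per family, CAI = geometric mean of w over the
gene's codons excluding Met/Trp/stops. The pipeline's default reference
set is the lowest-ENC decile of the analyzed genes (the usual
high-expression proxy when no expression-calibrated reference exists);
any reference set can be passed explicitly.

Third-position composition is tallied over synonymously variable codons
only; GC3s, T3s/C3s/A3s/G3s are fractions of that total; PR2 coordinates
are G3/(G3+C3) and A3/(A3+T3). Note the genetic code itself is
asymmetric here (six T-ending vs three A-ending two-fold families), so
only corpora balanced in third-position parity center exactly on
(0.5, 0.5).

Optimal codons: rank genes by ENC, take the lowest and highest deciles
as the high- and low-bias sets, compute RSCU on each set's pooled
counts, and flag codons with RSCU_high > 1, RSCU_low < 1 and ΔRSCU ≥
0.3.

## Expression

Tissue panels: per-gene min–max scaling to [0, 1] across conditions
(constant rows map to zeros — the convention is documented because 0/0
has no natural value); group means are computed on raw FPKM. Time
courses: genes with mean FPKM < 10 are removed (exactly 10 is kept),
replicate columns named `<timepoint>_r<k>` are averaged per time point,
and surviving rows are z-scored (ddof = 1; zero-variance rows are
dropped with a warning).

Fuzzy c-means: Euclidean distance, memberships
u_ij = 1/Σ_l (d_ij/d_lj)^(2/(m−1)), centers the u^m-weighted means,
stopping when the largest center shift < 1e-6 or 200 iterations.
Defaults k = 10, m = 1.25. Initial centers are k distinct rows drawn
from seeded substreams; **5 restarts** are run and the solution with the
lowest final objective kept, because a single random initialization
occasionally merges well-separated planted clusters. Within each run the
objective Σ u^m d² is non-increasing (asserted in tests). Coincident
point/center distances are floored at 1e-12.

## Networks

Pearson r is computed between each focal (family) gene and every other
expressed gene across all provided columns; the two-sided p uses
t = r√((n−2)/(1−r²)) with n−2 df. Edges require r > 0.9 **and** p < 0.01,
both strict. With only 4 time-point means, p < 0.01 needs r > 0.99, so
correlations are usually computed on replicate-level columns; the
generator emits 3 replicates per time point for this reason.

PWM scanning: counts are regularized with a 0.1 pseudocount, scored as
log2 odds against the background (uniform by default, or supplied), and
quantized to 1e-3 bits. The null score distribution is computed exactly
by per-column convolution (dynamic programming) over the quantized
grid, giving the p-value of every achievable score as an upper-tail
sum; tests verify equality with brute-force enumeration over all 4^w
words at the same granularity. Both strands are scanned; reverse-strand
hits report their forward-strand offset. Default hit threshold p ≤
1e-4 (the emulated scanner's default). At that threshold a 2 kb
promoter yields ~0.4 chance hits under the null, so "has a motif hit"
is a permissive criterion by design; stricter thresholds simply pass a
smaller p_max.

Promoters default to 2 kb upstream of the TSS, strand-aware, truncated
at contig edges. GO enrichment is the hypergeometric upper tail per term
over all terms annotated in the background, BH-adjusted; the assembled
network keeps targets that both pass the correlation filter and carry ≥ 1
motif hit.

## The synthetic pan-genome

The generator's defaults encode the emulated study design: 20
accessions; 30/10/10/10 core/soft-core/shell/cloud orthogroups; ~300
codon genes; within-orthogroup protein identity 0.98 (dispensable
classes get 0.02–0.025 more divergence, floored at 0.96, so they remain
clusterable at the 0.95 threshold); between-orthogroup identity 0.30 via
mutation from a shared scaffold; GC3 gradient 0.35–0.90 across
orthogroups; 2-copy duplication rate 0.12 per carrier (copies placed
rank-adjacent, i.e. tandem); 30 TEs per accession planted
upstream/genic/downstream of genes within the 2 kb window with a
DNA-transposon-heavy code mix; PAV deletions covering the reference
copy of each orthogroup absent from an accession, plus intergenic
insertions; 5-tissue gamma-distributed expression; a 4-time-point × 3
replicate salt-stress-style time course with 4 planted temporal clusters
(shape noise sd 0.05, replicate noise sd 2 FPKM) and ~5% planted
low-expression genes; a 10-bp high-information binding-site PWM whose
consensus is planted into the promoters of half the background genes
sharing the focal genes' cluster; and a GO map with one term enriched in
those targets.

Members diverge from their orthogroup ancestor at *half* the configured
divergence so that member-to-member identity realizes the configured
value. Nonsynonymous changes hit the protein-identity target exactly
(count = round((1−identity)·codons)); synonymous changes occur at rate
0.03 (core) or 0.06 (dispensable) per codon, so core orthogroups show
lower Ka, Ks and Ka/Ks — the planted selection contrast.

A single seed drives everything through spawned substreams (one per
generation stage), so bundles are byte-identical across runs and adding
accessions does not perturb earlier ones.

What the generator does **not** emulate: real chromosome structure,
recombination, TE sequence content (coordinates and labels only),
alignment-induced length variation within orthogroups (members differ by
substitutions only), sequencing noise in expression, or motif sites on
the reverse strand. Passing tests therefore demonstrate algorithmic
correctness and pipeline coherence, not robustness to indel-rich
alignments or noisy real annotations.

## Problem sizes and determinism

The shipped tests and the acceptance script run on deliberately compact
instances — 4–5 accession bundles (~170–200 genes), 20-accession bundles
(~1,000 genes) for occupancy recovery, 100-codon pairs for Ka/Ks
oracles, 500-gene corpora for optimal codons — sizes chosen so the whole
validation completes in a few minutes on one core while still exercising
every code path. All randomness flows from explicit seeds
(`numpy.random.SeedSequence` substreams); pipeline reports contain no
timestamps, and plots are written as SVG with fixed hash salts and no
date metadata, so identical configuration and seed reproduce reports
byte for byte.

## Known limitations

- Greedy single-linkage-to-representative clustering inherits the
  emulated tool's order dependence on sequences near the identity
  threshold; the explicit sort makes it deterministic but not
  threshold-free.
- The NG86 estimator is the approximate counting method; likelihood
  methods (GY94-style) are out of scope.
- "WGD or segmental" duplicates are not separated from dispersed ones.
- The ENC imputation for missing six-fold families (use the four-fold
  mean) matters only for very short genes.
- BH adjustment is the only multiple-testing control offered; no
  q-value estimation.
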