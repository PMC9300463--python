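# Methods

## The discovery model

The package operationalizes a common pathway-discovery argument: enzymes of
one biosynthetic pathway are co-regulated, so unknown pathway members should
(1) be expressed where the metabolite is made, (2) track the expression
profile of known pathway genes across tissues and replicates, and (3) come
from protein families able to perform the hypothesized chemistry. Stages:
FPKM quantification → tissue filtering → bait-anchored Pearson co-expression →
family-stratified candidate tables → reciprocal-best-hit orthology between a
producer and a non-producer relative → neighbor-joining clade tests →
Michaelis–Menten characterization of purified candidates.

## Synthetic transcriptomes

The generator emulates a replicated multi-tissue bulk RNA-seq experiment
(default 3 tissues × 2 biological replicates, matching the two-sample-set
design typical of non-model plant studies) containing a planted pathway
module.

**Counts.** Gene counts are negative binomial with Var = μ + μ²/φ, drawn as a
gamma–Poisson mixture. The size parameter φ defaults to 20 (squared
biological CV 0.05, typical of good bulk replicates). Per-gene latent means
are log-normal (σ_log = 1) around `baseline_mean` (default 200 counts), and
per-sample depth factors are uniform on 0.8–1.2× unless an explicit library
size interval is given. Gene lengths are uniform on 500–3000 bp. Background
genes are tissue-independent and mutually uncorrelated.

**The planted module.** Module genes share one latent log2 profile: the
tissue design (mean × `fold_root_enrichment`, default 20, in the pathway
tissue), perturbed by independent per-gene, per-sample Gaussian jitter. The
jitter variance is solved so the *expected* pairwise Pearson correlation of
log2 FPKM within the module equals `module_correlation` (default 0.97):
writing V for the variance of the shared profile across samples and σ² for
the total independent per-gene variance, E[r] ≈ V/(V+σ²), so
σ² = V(1−r)/r; the Gaussian jitter receives σ² minus the NB counting noise on
the log2 scale (delta method: (1/μ + 1/φ)/ln²2, averaged over samples,
floored at zero). Calibration is in expectation, not per draw. Measured over
20 independent simulations at the defaults, the mean within-module pairwise r
is 0.976.

**What a single draw does — and does not — guarantee.** With n = 6 samples a
sample Pearson correlation whose expectation is r fluctuates with standard
deviation ≈ 0.63·(1−r) (the dominant term is the χ²₅ fluctuation of the
per-gene sample noise variance); at r = 0.97 that is ≈ ±0.02. A screen at
r ≥ 0.95 therefore misses ~10–15% of module genes in any one draw, and the
mean recall of the default screen over repeated simulations plateaus near
0.85–0.9 rather than 1.0 — this is a property of sample correlations at
six observations, not of the screen or the calibration. Full recall at this
threshold requires either more samples or a higher target correlation.
False positives are a different matter: a background gene's null correlation
with the bait exceeds 0.95 with probability ~0.2% at n = 6, so the screen's
false-positive rate stays far below 1% at 1000 genes.

**What is not emulated.** Read-level effects (FASTQ, mapping), isoforms,
batch effects, GC bias, and correlated background structure (real
transcriptomes contain other co-regulated modules, which would raise the
false-positive rate above the clean-background figure). Passing tests
demonstrate correctness of the screen's set logic and calibration, not its
precision on real tissue panels.

**Orthologous proteins** are simulated by exact-count substitution: a child
sequence differs from its parent at exactly round((1−t)·len) positions, no
indels, substitutions uniform over the 19 alternative residues. Identity is
therefore exact to within 1/len and independent of aligner gap choices.
**Kinetics data** are v = k_cat·E₀·S/(K_m+S) with multiplicative Gaussian
noise of a given CV. All randomness flows from one seed, split into
independent streams for counts, proteins and kinetics.

## Quantification and screening conventions

- Library size = column sum of the supplied gene-level counts. (Whether a
  given published FPKM used assembly-wide mapped totals instead is often
  unstated; this pipeline documents its own convention and is self-contained.)
- Tissue summary = arithmetic mean over replicate columns; threshold
  comparisons are inclusive (≥), so a gene at exactly the cutoff is retained.
- Correlations are computed on log2(FPKM+1) by default (raw mode available);
  the log transform keeps high-dynamic-range profiles from being dominated by
  the top sample. Which transform published screens used is typically
  unstated; both are exposed.
- Both strict (≥) and open (>) threshold modes exist because published
  screens use both; single-bait screens default to ≥, multi-bait to >.
- Genes with constant profiles have undefined correlation and are excluded
  with a logged warning — never silently assigned r = 0.
- Candidate ranking (min-over-baits r descending, then tissue FPKM, then gene
  id) is a deterministic convention for reproducible tables; published
  candidate picks are manual.
- Family and full-length annotations are inputs (from external domain
  annotation in real use; from the generator in tests) — protein-family
  classification is out of scope.

## Alignment and orthology

Global (Needleman–Wunsch) alignment under BLOSUM62 with affine gap cost
open + k·extend (defaults 11/1, protein-BLAST-style) — global rather than
local because full-length orthologues are being compared; local identities
from heuristic search tools can differ by a couple of percentage points.
`X` is tolerated and scored 0 against everything. The DP engine is
Biopython's `PairwiseAligner`; scores are verified against exhaustive
enumeration of all alignments for short pairs. Percent identity counts
columns where both sequences hold identical residues, divided (by default)
by the alignment columns between the terminal gap overhangs; shorter- and
longer-sequence denominators are switchable. RBH requires a *unique*
top-scoring partner in both directions; ties yield no RBH and are logged.

## Trees and clade claims

Distances are d = 1 − identity/100 from pairwise global alignments — a
deliberate desk-scale simplification that supports topology-level clade
statements (e.g. "the producer's acyltransferase groups with its non-producer
orthologue, apart from the canonical malonyltransferase clade") without an
MSA or model selection. Neighbor joining (Saitou–Nei, via scikit-bio) with
taxa sorted lexicographically for deterministic join order; negative branch
lengths are clamped to zero and logged. Monophyly of a taxon set under an
outgroup rooting is decided on the unrooted tree's splits: the set is a clade
iff some edge bipartitions the leaves into exactly that set versus the rest.
No bootstrap support, no maximum likelihood.

## Kinetics

Unweighted least squares on raw velocities (no error model is assumed;
1/v² weighting is available for constant relative error). Parameters are
fitted as (log k_cat, log K_m), which enforces positivity; starting values
come from the Hanes–Woolf linearization S/v = S/V_max + K_m/V_max, chosen
over Lineweaver–Burk because it amplifies low-S noise far less. Standard
errors derive from the Jacobian at the optimum (Gauss–Newton covariance,
residual variance with n−2 degrees of freedom), mapped to the natural scale
by the delta method; efficiency ratios between two fits get a delta-method
standard error assuming independence. A fitted K_m outside the assayed
substrate range triggers a warning (the data then poorly constrain both
parameters). Substrate inhibition, cooperativity and progress curves are out
of scope.

## Pipeline determinism and problem sizes

`run_discovery` writes every stage artifact plus a summary stamped with a
hash of the configuration and the seed; identical configurations reproduce
identical outputs. The validation script and test suite use desk-scale sizes
chosen to exercise each method well past its asymptotic regime while staying
trivially cheap: 1000-gene transcriptomes with 10-gene modules over 10–20
seeds, 200 random short pairs for the exhaustive alignment oracle, 300-residue
proteins for identity round trips, 50 random 5–8-taxon trees, and 200
noisy kinetics replicates.
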