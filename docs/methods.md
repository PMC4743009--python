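# Methods

## Coordinate conventions

All genomic intervals are 0-based half-open (BED native); an intron is
`[intron_start, intron_end)`. Positions around a splice site are transcript
oriented: +1 is the first exonic base, −1 the last intronic base (the G of
the acceptor AG); there is no position 0. Acceptor distances are signed so
that negative means the alternative acceptor lies upstream (intron-wards)
of the canonical one; on the minus strand this is
`canonical_start − alternative_start`. Minus-strand arithmetic is confined
to `junction_io`; every other module sees transcript-oriented sequence.

## Differential junction usage

Counts for junction *i* in sample *j* are modelled as negative binomial
with mean `mu_i * s_j` and dispersion `alpha_i` (`Var = mu + alpha*mu²`).

* **Size factors** are DESeq-style median-of-ratios over junctions positive
  in all samples, rescaled to geometric mean 1 so the estimator is exactly
  idempotent; when no junction is positive everywhere the code falls back
  to total-count ratios with a warning. A single sample gets factor 1.
* **Dispersion** is per junction by method of moments on normalised counts,
  pooled over the two groups with degree-of-freedom weights, and floored at
  1e−8. This is deliberately simpler than shrinkage estimators: it is
  transparent, adequate at the cohort sizes used here (≥ 16 per group), and
  documented as such — calls on real data will differ in detail from
  DESeq2-based pipelines.
* **Test**: group log-means are fitted by Newton scoring with size-factor
  offsets (the exact NB GLM score equations, vectorised across junctions);
  the Wald statistic uses the expected information. The reported fold
  change is `log2((mean_MUT + 0.5) / (mean_WT + 0.5))` on normalised
  counts. All-zero junctions are untestable (NaN statistics) and excluded
  from the Benjamini–Hochberg denominator, as are junctions below the
  total-count prefilter (default 10). Selection uses padj ≤ 1e−5 and
  |log2FC| ≥ 1; both directions are kept.

Calibration: on effect-free NB cohorts (2,000 junctions, 16 vs 56 samples,
mu = 100–200, alpha = 0.05) the empirical type-I error at nominal 5% is
0.048–0.057 and no junction passes the selection thresholds.

## Event classification

A selected junction is paired against all other junctions in the table
(annotated or expressed) sharing its donor (alt-3′ candidates) or acceptor
(alt-5′ candidates). Exactly one non-empty side fixes the class; both or
neither yield `ambiguous_both` (the two rare cases are not separated). The
canonical partner is the annotated junction with the highest mean count,
preferring annotated over merely expressed partners and breaking ties
toward the smaller absolute distance; this rule is a package choice, since
no standard exists. Novelty means absence from the provided annotation
junction list, a deliberate stand-in for transcript-database membership
that removes any dependence on database versions. The periodicity statistic
is the fraction of acceptor distances in a window (default −50..−1) that
are multiples of 3, with a one-sided exact binomial test against 1/3.

## Sequence context

Windows are `intron_flank + exon_flank` nucleotides (default 50 + 50, the
AG at the centre). Logo matrices use raw per-position frequencies
(probability units) with no pseudocount by default; information content is
`2 − H` bits. Composition contrasts are Pearson χ² on 2×4 tables (2×2 when
collapsed to one base, e.g. G vs not-G at +1), without continuity
correction; a warning is attached when more than 20% of expected cells fall
below 5. Polypyrimidine content is the C/T fraction over a configurable
intronic window (default −20..−3).

## Branchpoint scoring and assignment

Candidates are the adenosines between `min_dist` (default 6, matching the
relaxed minimum the unusually 3′ss-proximal branchpoints in this system
require) and `max_dist` (default 100) upstream of a 3′ss. The heptamer
around the branch A (positions A−5..A+1; branch A at heptamer position 6,
the UACUAAC convention) is scored for antiparallel pairing with the U2
branch-recognition sequence: the six non-bulged positions pair with
A,U,G,A,U,G; Watson–Crick = 1.0, G·U wobble = 0.5 (tunable), else 0, so
scores live on a 0–6 scale with UACUAAC = 6.0. This transparent scheme
stands in for SVM-based branchpoint strength; its values are pairing
counts, not SVM decision values, and are not comparable to them
numerically. Another labelling convention places the branch A at +5 of the
motif; the contrast tables report both indexings.

Assignment searches the canonical-AG side in a window of −44..−16 with a
distance prior at −25, and the AG′ side in −18..−9 with a prior at −12.5
(the 11–14 nt spacing plus a margin for annotation jitter). Ties break by
higher downstream pyrimidine content, then proximity to the prior, then
upstream. On sensitive introns the canonical-side search often lands on the
BP′ when it is the stronger candidate — which is exactly why the predicted
BP-to-AG distances go bimodal for sensitive acceptors while staying
unimodal (~25 nt) for insensitive ones.

Catalogue overlap counts exact genomic coincidence of a catalogued BP
adenosine with the A of the AG′ dinucleotide, plus the mean upstream offset
of the nearest non-coincident catalogue entry within 50 nt.

## The acceptor-choice model

Competing acceptors of one 3′ region are weighted in two regimes:

* wild-type: `exp(u2af/τ)` with `u2af = ppt · (1 + g_bonus·[+1 = G])`
  (U2AF2 reads the polypyrimidine tract, U2AF1 prefers AG-G);
* mutant: `exp(S_best/τ)` where `S_best` is the best branchpoint pairing
  score at mutant-valid spacing (the BP′ window).

Usage at mutant transcript fraction `f` is the linear mixture; the AG′/AG
index follows from the fractions (reported as +∞ when canonical usage is
exactly zero). Defaults: τ = 0.7, g_bonus = 0.5, s_floor = 3.0.

Two usability rules are needed so that "abolished" states exist:

1. **Scanning**: a branchpoint cannot serve an acceptor when a rival
   candidate AG lies between the branch A and that acceptor — the first AG
   downstream of a committed branchpoint wins. This is why destroying the
   canonical branchpoint reroutes all flux to the cryptic site instead of
   letting the (stronger) BP′ serve the canonical AG across the AG′.
2. **Dominance margin**: an acceptor whose best branchpoint pairs more
   than 1.0 (one Watson–Crick pair) worse than the best branchpoint of any
   competitor is outcompeted outright in both regimes. This is what lets a
   perfect-consensus canonical branchpoint extinguish cryptic usage
   regardless of SF3B1 status, while leaving ordinary BP/BP′ gaps (≤ 1.0)
   in soft competition.

Both rules are deterministic, parameter-light renderings of kinetic
commitment; the model makes no free-energy or assembly-kinetics claims.

The built-in mutagenesis construct is **synthetic**: a 60-nt intron + 20-nt
exon laid out with the validated two-branchpoint architecture (cryptic AG′
at −16 with a non-G +1; BP′ serving it at −13 with two adjacent branch-region
adenosines, pairing 4.5; canonical BP at −6, pairing 4.0; one neutral
adenosine; pyrimidine fill elsewhere, chosen with few adenosines exactly as
the validated genes were chosen for their low adenosine content). Its
heptamer scores are model-scale choices satisfying the one documented
ordering (BP′ strictly stronger than BP); the genomic sequences of the real
minigenes are not embedded. Because the canonical BP sits only 6 nt from
its AG, the construct is evaluated with both regime windows relaxed to a
6-nt minimum spacing; defaults elsewhere are unchanged. The truth table
reproduces all seven qualitative outcomes (BP′ or AG′ destruction abolishes
cryptic splicing at every mutant fraction; canonical-BP destruction
abolishes canonical splicing; a neutral adenosine changes nothing; C>G at
the AG′ +1 strengthens it; a perfect canonical BP extinguishes it; swapping
the BP and BP′ heptamers — which exactly exchanges their pairing scores —
reduces it), and the AG′/AG index rises strictly through
f = 0, 0.14, 0.30, 1. An AAG-variant construct demonstrates acceptor
*creation*: mutating the middle adenosine replaces the AG′ with a new
acceptor one base upstream.

## Synthetic cohorts

Each acceptor is a two-exon locus on its own contig (100 + 200 + 100 nt;
strand drawn at random so both orientations are exercised). The last 50
intronic nt are pyrimidine-rich (A/C/G/T = 0.1/0.4/0.1/0.4), the rest of
the background uniform — spurious AG dinucleotides are left in place as
decoys. Planted elements: canonical AG with +1 = G at probability 0.5;
canonical BP heptamer `TGCTGAC` (pairing 5.0, a single adenosine) at −25;
for sensitive acceptors an AG′ at offset *d* drawn from a distribution
supported on −50..−3 with a plateau on −24..−12 and multiples of 3 enriched
3-fold, +1 = G at probability 0.20, and a BP′ heptamer `TACTAAC` (pairing
6.0, strictly stronger) 11–14 nt upstream of the AG′. When the drawn AG′ or
BP′ occupies the canonical BP's position, the canonical BP slides upstream
to the nearest free position rather than resampling the draw — this keeps
the AG′ offset distribution exactly the configured multinomial and mirrors
real sensitive introns, where the cryptic acceptor sits inside the
canonical branchpoint region (and is why the AG-side predicted-BP
distribution goes bimodal).

Counts: each acceptor × sample draws a negative binomial total
(mean 200, dispersion 0.05 — a standard bulk RNA-seq overdispersion; the
source data report none) and redirects a `Binomial(total, leak + ψ·f)`
share to the AG′ junction, with wild-type leak 0.02, effect size ψ = 0.5
and per-sample mutant transcript fraction `f` (0 for wild-type samples).
Cohort defaults: 16 mutant vs 56 wild-type samples; 200 acceptors with 30%
sensitive as the desk-scale stand-in for ~0.5% of a full transcriptome's
~10⁵ junctions (full scale is not desk-runnable and adds nothing to the
properties under test); mutant fractions evenly spaced over 0.2–0.6,
bracketing the 0.14 and 0.30 transcript mutation rates of the reference
mutant cell lines while giving the AG′/AG-vs-f dose response something to
vary over; 12% of AG′ junctions are marked annotated (matching the ~88%
novelty of cryptic acceptors). Every random draw is keyed by
(seed, acceptor index[, sample index]), so identical configurations are
byte-identical and enlarging the cohort never perturbs existing loci.

**What the generator does not emulate** — and therefore what passing tests
do not show about real data: read-level artefacts (mapping bias, soft
clipping, positional coverage), splice-graph complexity beyond two
acceptors per donor, alt-5′ and mixed events (the generator plants only
alt-3′ signal; the alt-5′ code paths are exercised on constructed toy
tables), expression heterogeneity across loci, library-composition effects
beyond global size factors, NMD feedback on transcript abundance, and
motif/GC structure of real introns beyond the planted elements. Sensitivity
and recovery rates on these cohorts are upper bounds, not field estimates.

## Numerical choices and degenerate inputs

Newton fits clamp steps to ±5 and converge to |step| < 1e−12 (≤ 100
iterations); groups with zero totals get a half-count continuity estimate.
BH adjustment delegates to `statsmodels.multipletests` and is checked
against a brute-force step-up oracle in the tests. Binomial and χ² tests
are exact/scipy; χ² tables drop all-zero columns and return (0, 1) when
fewer than two categories remain. Empty candidate sets are results
(unassigned flags, empty histograms), not errors; empty *required* inputs
(no extractable site, an empty contrast group, no acceptor with a usable
branchpoint in either regime) raise. Window extractions never silently
clip: out-of-bounds windows and unknown contig names are errors, and
chromosome-name mismatches (`chr1` vs `1`) are never auto-corrected.

## Problem sizes in the tests and acceptance script

The suite and `scripts/acceptance.py` use the default 200-acceptor cohort
(72 samples, ~260 junctions), a 2,000-junction effect-free cohort for null
calibration, a 2,000-acceptor sequence-level cohort for the +1 composition
check, and 1,000 random instances per oracle-equivalence check. These sizes
give comfortable statistical resolution for every property tested (e.g.
binomial standard error ~0.009 on the +1 G proportion at n = 2,000).

## Known limitations

The NB test is unshrunk and two-group only (no covariates); the paired
canonical junction is chosen by a heuristic; branchpoint strength is a
6-point pairing scale, not a learned model, so absolute strengths should
not be compared with SVM scores; the choice model is qualitative in spirit
— its fractions are softmax conveniences, and τ, g_bonus, s_floor and the
dominance margin are not fitted to any quantitative splice-ratio data.
Multi-branchpoint redundancy is represented only as best-candidate
selection.
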