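# Methods

`crossalign` detects and corrects sample mix-ups in multi-tissue expression
genetics studies (an F2 intercross with genome-wide genotypes and per-tissue
expression arrays).  The central idea: genotype and expression data carry
redundant identity information.  Expression of the same animal in two tissues
is correlated across tissue-shared transcripts; expression of a transcript
with a very strong local eQTL predicts the animal's genotype at that locus.
Either redundancy can be turned into a labeled similarity matrix between two
data dimensions, and a sample whose self-similarity is low while some
off-diagonal entry is high is mislabeled — and, when the evidence is clear,
fixable.

## Aligning expression arrays across tissues

For each tissue pair (s, t), the probes whose expression correlates above
0.75 between the tissues (across animals assayed in both, pairwise-complete
on missing cells) carry the animal-level shared signal; correlating sample
i's vector in s with sample j's in t across those probes gives r_ijst.  The
per-tissue similarity r_ijs is the median of r_ijst over the tissue pairs
containing s.  Diagnosis per row: `correct` when the self cell equals the
row maximum; `relabel` to the argmax when the self cell is observed but
below `self_threshold` (default 0.75), the maximum exceeds `match_threshold`
(0.8), and the maximum clears the second-highest value by `margin` (0.1);
`unfixable` when the self cell is present but no confident target exists;
`unverifiable` when the self cell is missing.  A relabel whose target row is
itself correct is a `duplicate` (one sample assayed twice); duplicates are
merged by per-probe mean.  Within-tissue duplicates are additionally
screened by between-sample correlation above 0.9 across the selected probes.

Two design points deserve emphasis:

* **Rows with missing self-similarity are never auto-relabeled.**  With no
  self cell to contradict the match, a chance near-identity between two
  unrelated animals is indistinguishable from a real mix-up, so such rows go
  to the cannot-be-verified class with their best match recorded as
  evidence.  On a small genome the chance-match distribution has heavy tails
  (see *Limitations*), which makes this conservatism necessary rather than
  cosmetic.
* **Alignment runs in two passes.**  A swap inside tissue t also depresses
  the self-similarity of the affected samples as seen from every other
  tissue; with few tissues the median over pairs cannot absorb that.  The
  pipeline applies confident relabels and duplicate merges first (keeping
  unfixables), re-computes the probe subsets and similarities on the
  corrected data, and only then drops rows that remain unfixable.  Reports
  merge the two passes: acted-on rows keep their first-pass evidence,
  unresolved rows take the second-pass verdict.

With exactly two tissues the method cannot tell which side of a swap is
wrong (the evidence is symmetric); three or more tissues break the tie by
majority.

## Aligning DNA to mRNA via eQTL genotypes

Multipoint genotype probabilities are computed on a marker+pseudomarker grid
(max spacing 0.5 cM) by a scaled forward–backward pass over a three-state
HMM per autosome: Hardy–Weinberg prior (¼, ½, ¼), transitions from the
two-meioses F2 matrix at the interval's recombination fraction (Carter–
Falconer map function by default, which encodes the strong positive
crossover interference of the mouse), and a symmetric genotyping-error
emission (true call with probability 1−ε, each wrong call ε/2, ε = 0.002;
missing calls are uninformative).  The X chromosome is excluded: hemizygous
males are stored as homozygous and all eQTL work is autosomal.

Per tissue, probes with known autosomal location are tested by a single
Haley–Knott regression — phenotype on the genotype probabilities at the
grid position nearest the probe, LOD = (n/2)·log10(RSS₀/RSS₁) — and those
with LOD > 100 are kept, grouped into 1–3-probe units when they share a
position.  The observed eQTL genotype of a DNA sample is its maximal
multipoint probability call, required to strictly exceed 0.99 (else
missing).  Per unit, a k-nearest-neighbor classifier (k = 40, Euclidean
distance on untransformed expression in the unit's 1–3 dimensions) predicts
a query's eQTL genotype; a call needs strictly more than 80% of the
neighbors to agree, otherwise missing.  A sample in the training set never
votes for itself.  After one inference pass, training samples whose own
observed/inferred match proportion is below 0.7 are removed and the
classifiers refitted — exactly two passes, so badly mislabeled samples do
not pollute training.

The DNA-vs-mRNA similarity is the proportion of matching genotypes over
comparable (both non-missing) positions, pooled across all eQTL and all
tissues (pooled counts, not a mean of per-tissue proportions).  A correct
sample matches itself near 1; a mismatched pair matches at about
Σ_g f_g² = 0.375 under F2 frequencies — a wide bimodal separation.  The
diagnosis rule is shared with the expression side, with defaults 0.8 / 0.8 /
0.1 on the match-proportion scale.  Corrections relabel DNA rows
simultaneously (cycles and chains both resolve), drop duplicate rows, and
flag unverifiable ones; an unfixable row whose label is claimed by a
relabel is dropped, since its label is known to be wrong.

## Genotype QC and plate geometry

Independent screens that usually surface mix-ups first: near-duplicate DNA
pairs (genotype identity > 0.98 over ≥ 50 jointly typed markers; unrelated
F2 pairs sit near 0.375); X-vs-recorded-sex concordance (in a cross with a
BTBR dam, females must be RR/BR on the X and males hemizygous — one
discordant call is reported as a probable genotyping error, two or more
flag the sample); and per-sample behavior metrics (missing rate, autosomal
homozygosity, apparent crossovers counted as state changes of the argmax
posterior path at typed markers), flagged beyond median + 5·MAD.

Diagnosed DNA errors are then mapped onto the 96-well genotyping plates:
the signed offset between where a sample was found and where it belonged,
in filling order (column-major by default — down columns, matching
single-channel pipetting), classifies each error as off-by-one, off-by-two,
long-range (same plate) or cross-plate, and maximal runs of consecutive
equal offsets expose systematic pipetting shifts.

## The synthetic-data generator

The simulator emulates the structure such a study presents to the method,
with a complete ground-truth ledger so every detector can be scored
exactly.  Defaults (the package's standard scenario):

| parameter | default | why |
|---|---|---|
| mice | 300 | large enough for LOD ≫ 100 eQTL and k = 40 voting |
| genome | 5 autosomes (100–50 cM, 20 markers each) + X (60 cM, 10 markers) | compressed genome that keeps every stage fast |
| map function | Carter–Falconer | mouse-appropriate interference |
| genotyping error / missing | 0.002 / 0.01 | typical SNP-chip panel rates |
| tissues × probes | 3 × 1000 | smallest tissue count that disambiguates swaps |
| shared-signal probes | 120, loading 3.0 | between-tissue probe correlation λ²/(λ²+1) = 0.9 |
| eQTL per tissue | 60 (2 two-probe units), a = 4, d = 0.5, σ = 1 | single-position LOD ≈ 130–145 at n = 294 |
| sex probes | one Xist-like, one Y-like, effect 2.0 | reproduces the sex-driven similarity structure |
| mice without expression | 6 | exercises the cannot-be-verified class |

Gametes are first-order Markov chains over markers with per-interval
recombination fractions from the map function's inverse; crossover
interference enters only through those interval probabilities (no explicit
crossover-point process).  The X follows the cross design (females RR/BR,
males hemizygous coded homozygous).  Samples are plated in same-sex blocks
of 24 filling-order wells, as real studies do — which is exactly why plate
shifts are barely visible to the sex check.  Expression depends on the
*true* genotypes, so planted DNA errors surface as genotype/expression
mismatches.

Planted errors (defaults): a plate-shift rotation across 9 consecutive
wells (8 off-by-one errors in a run plus one wrap-back, keeping the
corruption a pure permutation so the ledger inverse is exact), one
standalone DNA duplicate (an exact row copy — identity 1.0, trivially above
the 98% screen), one expression swap per tissue, a 3-cycle in the first
tissue, an expression duplicate in the last tissue, and one recorded-sex
swap of a male/female pair chosen so both are detectable from their X
genotypes.  All randomness flows from one seed through spawned child
generators.

### What the generator does not emulate

No array normalization artifacts, batch effects, or probe-level intensity
models; no sample *mixtures* (two animals' tissue pooled into one assay) —
such cases can at best be flagged unfixable, never resolved; no
between-tissue swaps of expression arrays; no clinical-phenotype mix-ups,
which are invisible to this method.  Passing tests therefore demonstrate
the detection logic, not robustness to real-world array pathology.

## Numerical choices

* Forward–backward is scaled per position (no log-space); posteriors are
  renormalized and sum to 1 within 1e−9 at 10⁴ positions.
* The Carter–Falconer inverse is a bracketed Brent root find to 1e−12;
  Haldane and Kosambi invert in closed form.
* Haley–Knott designs use (p_BR, p_RR) contrast coding against the BB
  baseline and least-norm least squares, so rank-deficient (certain
  genotype) designs fit without error; an RSS ratio below 1e−10 is treated
  as a perfect fit (+inf LOD with a warning); a constant phenotype gives
  LOD 0.
* Ranks tie by averaging in the normal-quantile transform.
* `nearest_position` breaks midpoint ties toward the proximal index;
  pseudomarker counts per gap follow ceil(gap/0.5) − 1 with even spacing.
* 2-LOD support intervals take the contiguous run above peak − 2 and extend
  one grid position outward per side.
* The k-NN vote denominator is the number of neighbors actually used (all
  training points, with a warning, when fewer than k exist).

## Limitations

The compressed 5-autosome genome makes the ~180 eQTL strongly linked, so
the mismatched-pair match proportion has SD ≈ 0.13 (vs ≈ 0.03 for a
full-genome panel) and its extreme tail reaches ~0.9 among ~85k pairs.
Consequences: DNA samples without expression data are classed unverifiable
rather than matched (see above), and a correct sample's self-similarity can
dip to ~0.94 when its k-NN misassignments happen to hit linked eQTL.  With
planted mislabels present, single-position LODs are depressed and a few
planted eQTL fall below the LOD > 100 screen (~52–56 of 60 per tissue
survive; all 60 on clean data) — detection is unaffected, which is the
method's own robustness claim.  Thresholds were fixed at the documented
defaults before end-to-end evaluation and are config-exposed, not tuned.
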