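# crossalign

Detection and correction of sample mix-ups in multi-tissue eQTL studies.

## The problem

In an expression genetics study — genome-wide genotypes plus gene expression
on one or more tissues for each animal — sample labels go wrong: tubes get
swapped, a pipette lands one well off and shifts a whole column of DNAs, an
array gets hybridized twice under two names.  Mislabeling silently erodes
QTL mapping power and biases effect estimates, and in a plain genetic study
it is almost undetectable.  Expression genetics data, however, are
self-identifying twice over: a sample's expression is correlated with *its
own* expression in other tissues (across tissue-shared transcripts), and
transcripts with very strong local eQTL predict the sample's *genotype* at
those loci.  `crossalign` turns both redundancies into labeled similarity
matrices, diagnoses which labels are wrong, infers the correct labels where
the evidence is decisive, applies the corrections, and maps inferred DNA
errors back onto the 96-well genotyping plates to reveal their mechanical
origin (off-by-one and off-by-two pipetting runs).

It is written for quantitative geneticists running experimental crosses
(the reference design is an F2 intercross between two inbred mouse strains,
genotypes BB/BR/RR), but every stage operates on plain samples × features
matrices.

## The method

**Expression side.**  For tissues s, t, select probes with between-tissue
correlation r > 0.75; across those probes compute r_ijst, the correlation
of sample i in s with sample j in t, and summarize r_ijs = median_t r_ijst.
Low self-similarity r_iis with a high off-diagonal maximum (clearly above
the second-highest value) identifies — and relabels — a mislabeled array.

**Genotype side.**  Multipoint genotype probabilities come from a 3-state
HMM on a ≤0.5 cM marker/pseudomarker grid (F2 prior (¼,½,¼), genotyping
error rate ε = 0.002, Carter–Falconer map function).  Probes with a local
eQTL at LOD > 100 by single-position Haley–Knott regression,

    LOD = (n/2) · log10(RSS₀ / RSS₁),

define k-nearest-neighbor classifiers (k = 40, call only when >80% of
neighbors agree) that predict each mRNA sample's eQTL genotype from
expression alone.  The observed eQTL genotype of each DNA sample is its
multipoint call (posterior > 0.99).  The proportion of matches, pooled over
all eQTL and tissues, is the DNA-vs-mRNA similarity: correct samples match
themselves near 1, mismatched pairs near Σ_g f_g² = 0.375, and the same
self/max/second rule relabels mislabeled DNAs.  Training is cleaned by one
filter-and-refit pass (samples matching themselves < 0.7 are dropped).

A fully ledgered simulator generates synthetic studies — recombinant F2
genomes, tissue-shared expression factors, large-effect local eQTL,
sex-linked probes — with planted swaps, duplicates, plate-shift runs and
sex swaps, so the entire pipeline is testable with no external data.
See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
from crossalign import SimConfig, simulate_study, run_all

study = simulate_study(SimConfig(seed=1))          # 300 mice, 3 tissues
result = run_all(
    study.expression, study.genotypes, study.genetic_map, study.layout
)

dna = result.geno_result.diagnosis
print("DNA verdicts:", dna.status_counts())
print("DNA relabels:", dna.relabel_map())
runs = result.plate_runs
print(runs[runs.length > 1].to_string(index=False))
```

prints

```
DNA verdicts: {'correct': 284, 'relabel': 9, 'duplicate': 1, 'unfixable': 0, 'unverifiable': 6}
DNA relabels: {'Mouse3003': 'Mouse3011', 'Mouse3004': 'Mouse3003', 'Mouse3005': 'Mouse3004',
 'Mouse3006': 'Mouse3005', 'Mouse3007': 'Mouse3006', 'Mouse3008': 'Mouse3007',
 'Mouse3009': 'Mouse3008', 'Mouse3010': 'Mouse3009', 'Mouse3011': 'Mouse3010'}
 run_id  offset   category  length
      1       1 off-by-one       8
```

Reading this: 284 DNA samples are correctly labeled; 9 wells hold a
neighbor's DNA — wells 4–11 in filling order each contain the sample
intended one well earlier (the length-8 off-by-one run, a classic
single-channel pipetting shift), with the displaced sample found in the
vacated first well; one well is a duplicate of another sample's DNA; and
the 6 mice that were never assayed for expression cannot be verified either
way.  The relabel map reads "the row labeled Mouse3003 is really
Mouse3011", and so on — exactly the permutation the simulator planted
(`study.ledger.expected_dna_relabels()`).  Per-tissue expression verdicts,
the corrected matrices, the sex/X concordance report and the genotype QC
table hang off the same `result` object.

The same pipeline runs from the shell:

```sh
crossalign simulate --out study/ --seed 1
crossalign run-all --data-dir study/ --out reports/
```

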