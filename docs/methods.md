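# Methods

## The methylation decision tree

Bisulfite sequencing of two D4Z4 regions yields per-CpG methylation
fractions: DR1 (29 CpGs, present in every repeat unit on chromosomes 4
and 10) and DUX4-PAS (10 CpGs, amplifiable only from 4qA alleles).
The diagnostic classifier consumes four sites — DUX4-PAS CpG6, DUX4-PAS
CpG3, DR1 CpG1, DR1 CpG22, in that order of relevance — and routes each
subject through a fixed decision tree:

| test (inclusive)            | outcome                  |
|-----------------------------|--------------------------|
| PAS CpG6 ≤ 0.78             | node 3, FSHD             |
| else PAS CpG3 ≤ 0.34, DR1 CpG1 ≤ 0.53 | node 7, FSHD  |
| else PAS CpG3 ≤ 0.34, DR1 CpG1 > 0.53 | node 8, CTRL  |
| else DR1 CpG22 ≤ 0.99       | node 10, CTRL            |
| else                        | node 11, CTRL            |

The node layout is the minimal tree consistent with all 42 labelled
reference subjects under the stated thresholds and feature order; every
labelled row is reproduced and boundary rows (CpG6 exactly 0.78, CpG3
exactly 0.34, CpG22 exactly 1.00) pin the inclusive comparisons.
Thresholds are configuration (`ClassifierConfig`), not constants.

Three deliberate choices where the published description is silent:

* **Unobserved branch.** No labelled subject has PAS CpG3 > 0.34
  together with DR1 CpG1 ≤ 0.53. By default this combination falls
  through to the CpG22 test; `unobserved_branch_policy =
  "report_unclassifiable"` makes the gap explicit instead of guessing a
  label the data never shows.
* **Missing data.** Subjects without DUX4-PAS data (4qB/4qB genotypes)
  take node 10 with label `unclassifiable`, matching how such subjects
  are recorded in the reference tables.
* **Units.** All methylation values are fractions in [0, 1] internally;
  readers accept both percent strings ("57%") and decimals, and integer
  percents round-trip exactly.

Internally, CpG sites are indexed 1-based per region to match the
"CpG 6" naming convention. Decision-node indices other than
{3, 7, 8, 10, 11} never occur in the reference data and carry no
semantics here.

## Threshold recovery

`recover_thresholds` is a parameter-recovery oracle used to validate the
synthetic generator: it re-estimates the four split points from labelled
data via an exhaustive 1-D Gini search over midpoints of adjacent
distinct values (hence invariant to row duplication). Two modes:

* **node-annotated** data (the generator records the sampled leaf):
  each threshold is recovered on exactly the subjects whose decision
  path reaches that test — CpG6 on everyone, CpG3 on non-node-3
  subjects, CpG1 on nodes {7, 8}, CpG22 on nodes {10, 11};
* **label-only** data: the tree is rebuilt greedily in the stated
  feature order. The CpG22 split separates two control-side leaves and
  is therefore unidentifiable from FSHD/CTRL labels; it is returned as
  `None` in this mode rather than a fabricated estimate.

On 1,000 generated subjects all four thresholds are recovered within
±0.05; a scikit-learn decision stump fitted to the same branch subsets
serves as an independent cross-check in the test suite.

## Variant prioritization

Filters run in a fixed order (coverage, panel, consequence type, gnomAD
MAF, internal-reference absence) but *all* failures are recorded, so
retention is order-independent. Key conventions:

* MAF comparison is strict (`< 0.001`); an absent gnomAD frequency
  passes — rarity is never silently coerced to zero.
* Consequence classes come from HGVS nomenclature with precedence
  frameshift > nonsense > splicing > in-frame indel > missense;
  a missense call annotated as lying in a splicing region keeps its
  class but tallies under splicing. Unparseable nomenclature degrades
  to class `other` with a warning, never an exception. The grammar
  subset needed (substitutions, dup/del/ins, intronic offsets,
  frameshift/stop protein changes) is small enough that a dedicated
  parser dependency is not warranted.
* In-silico verdicts do not gate retention (benign-predicted variants
  are legitimately retained when rare); they only feed ACMG evidence.
  Likewise domain localization only feeds PM1.
* The shipped panel is the union of the eight genes in the reference
  inventories (SMCHD1, DNMT3B, LRIF1, CTCF, DNMT1, DNMT3A, EZH2,
  SUV39H1); the full selection list of the original analysis is not
  published, and the panel is user-extensible configuration.
* No zygosity filter is applied (the reference data contain a
  heterozygous *LRIF1* variant retained as relevant).

## ACMG evidence and combination

Computational criteria are assigned from carried annotations only — no
database is queried at run time:

| criterion | rule (defaults) |
|-----------|-----------------|
| PVS1 | frameshift/nonsense or canonical ±1/2 splice, in a gene with LoF Z ≥ 3.09 |
| PS2  | de novo with both parents genotyped negative |
| PM1  | variant lies in an annotated functional domain |
| PM2  | gnomAD frequency absent or < 0.001 |
| PP2  | missense in a gene with missense Z ≥ 3.09 |
| PP3 / BP4 | from the in-silico verdict: strong→PP3 strong, moderate→PP3 moderate, supporting-benign→BP4 |
| BS1  | frequency above the gene's benign cut-off frequency |

The Z threshold 3.09 operationalizes "significant constraint" as the
one-sided 0.1% point of a standard normal; it is configuration, as is
the verdict→strength map. The five-tier combiner implements the 2015
rule-based combination table *as data* (lists of minimal strength-count
profiles per tier), so alternative tables can be swapped in; a set
matching both a pathogenic-side and a benign-side combination is
conflicting and yields VUS. The test suite proves the encoded table
equivalent to an independently hand-written evaluation on every criteria
set of size ≤ 6 and monotone under added evidence.

The published per-variant evidence assignments behind the reference
study's 5/7/7/1 pathogenic/likely-pathogenic/VUS/likely-benign split are
not available, so that split is not a reproduction target; the pipeline's
own computed tally over the 20 reference variants (2/9/8/1) reflects
strictly computational evidence without the curated database assertions
(ClinVar, Varsome, literature) a human assessor would add.

## Segregation and categorization

A carrier's variant origin is `de_novo` only when both parents are in
the pedigree and genotyped negative; a confirmed carrier parent
establishes `inherited_maternal`/`inherited_paternal` even when the
other parent is untested (the transmission is observed); anything else —
missing parents, untested parents, both parents carriers — is
`undetermined`. On the reference families exactly two de novo events
are called.

Permissive-allele reporting follows the convention of the reference
tables: 4qA/4qB genotypes report the single 4qA allele; 4qA/4qA report
the shortest allele, or both when both are ≤ 20 RU (inclusive — the
printed data contain "8 + 20" and "13 + 20"); 4qB/4qB report nothing.
Sizes above 20 RU are a sentinel (`over_20`) that compares greater than
any finite size, because the sizing assay does not resolve them.

Genetic categories are assigned from the shortest permissive allele and
the ACMG outcome: 1–10 RU → FSHD1 (plus-modifier when a
pathogenic/likely-pathogenic panel variant is carried); 11–20 RU with
such a variant → FSHD2; > 20 RU (or no permissive allele) with such a
variant *and* an FSHD methylation call → atypical; otherwise
unexplained. "Modifier variant" means ACMG pathogenic or likely
pathogenic by default; callers may widen to VUS for exploratory use.
The 8–10 RU borderline range is carried in `CategoryRules` but does not
split FSHD1 further.

## The synthetic-data generator

The generator emulates the structure the analysis assumes, not any real
dataset:

* **Cohort strata** default to the reference study's composition — 15
  subjects at 1–3 RU, 80 at 4–7, 7 at 8–10, 2 at 11–20, 6 above 20, and
  16 double-4qA carriers with both alleles drawn uniformly on 3–20 RU
  (126 subjects in all); female fraction 0.45, age ~ N(52.5, 17.7²)
  clipped to 18–95 years. Every generated patient carries at least one
  4qA allele, as in the study cohort; the second, non-contracted allele
  is 4qB with probability 0.5 and always above 20 RU.
* **Methylation** is drawn per decision-tree leaf. Subjects with a
  permissive allele ≤ 20 RU are FSHD-like (leaf mixture 75% node 3,
  25% node 7); the > 20 RU stratum is control-like (30/50/20 over nodes
  8/10/11). Each feature on the leaf's decision path is drawn uniformly
  on the correct side of its threshold, at least `margin` (default
  0.15, shrunk symmetrically near the [0, 1] boundary — the CpG22
  threshold of 0.99 leaves only a sliver above) away, perturbed with
  N(0, 0.03) noise and truncated to stay on its side. Features *off*
  the decision path are uniform on [0, 1], matching the reference data
  where node-3 subjects span both sides of the DR1 CpG1 threshold.
  Background (non-classifier) CpGs are Beta-distributed per class and
  independent across sites; real per-CpG correlation along DR1 is not
  modelled, so passing tests say nothing about spatial methylation
  structure in real data. No distributional parameters for methylation
  are published; these defaults are the generator's own choice, and the
  classifier only ever sees threshold relations.
* **Decoy variants** each violate exactly one named filter (off-panel
  gene, synonymous class, MAF 0.05, coverage < 20), with the violation
  recorded as ground truth.
* **Families** transmit one allele per parent uniformly and a
  heterozygous variant with probability 1/2; a named child can be forced
  de novo. An untyped parent contributes a population-normal (> 20 RU)
  allele.
* **Randomness**: one integer seed; each operation derives a
  deterministic substream via `numpy.random.SeedSequence`, so cohorts,
  variant tables and families are independently reproducible.

Because leaf draws are truncated to the correct threshold side, a
generated cohort is classified back to its true labels essentially
perfectly; the ≥ 99% label-fidelity check in the tests guards the
generator-classifier contract, not real-data performance.

## Numerical and I/O conventions

* Missing markers on input: "—", "-", "", "na", "n/a", "not found"
  (case-insensitive); missing frequencies and methylation values are
  `None`/NaN, never 0.
* Genomic coordinates are 1-based GRCh37 throughout.
* Reports are TSV with a fixed column order; writing then re-reading a
  cohort or variant table reproduces all representable fields
  bit-for-bit. Partial CpG vectors (some sites measured, others not)
  are preserved as-is; downstream stages decide whether the four
  classifier sites are available.
* The reference subject fixture stores only the four classifier CpGs —
  the full 29 + 10 vectors were never published — so its profiles are
  deliberately partial.

## Problem sizes used by the checks

Threshold recovery and label fidelity run on 1,000–2,000 generated
subjects; Mendelian transmission on 10,000 simulated offspring (carrier
fraction within 3 standard errors of 1/2); the combiner equivalence
check enumerates all criteria sets of size ≤ 6 over a 15-code
vocabulary. The whole suite runs in a few seconds on one CPU.

## Known limitations

* The tree reproduces the published thresholds; it cannot assign
  semantics to decision nodes that never occur in the labelled data
  (1, 2, 4, 5, 6, 9, 12, …).
* How chromosome-10 DR1 signal was separated from chromosome 4 is not
  described in the source protocol; methylation profiles are consumed
  as given.
* In-silico predictor scores (REVEL, Missense3D, Varsite, splicing-site
  tools) and population frequencies enter only as input annotations;
  none are recomputed.
* Clinical severity fields (CSS, FCS, MRI patterns) are stored passively
  and never used in computation.
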