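# Methods

## Model and representation

A haploblock is a set of `nmrk` tightly linked bi-allelic markers treated as
one multi-allelic locus; within-block recombination is assumed absent. A
haplotype is encoded as an integer in `[0, 2^nmrk)` whose bit *j* (bit 0 =
first marker in block order) is the allele at marker *j*. An individual of
even ploidy `p` carries a nondecreasing tuple of `p` haplotype codes
(*Ghap*); the observed data per individual and block is the dosage vector
(*Gmrk*), whose entry at marker *j* counts the haplotypes with a 1-bit at
*j*. Dosages are additive over haplotypes, which the solver exploits
heavily: in mixed-radix index space (base `p+1`) the index of an offspring
genotype is the sum of its two gamete indices.

All combinations consistent with a dosage vector come from an exhaustive
table per `(nmrk, p)`: all `C(2^nmrk + p − 1, p)` multisets, generated in
lexicographic order and grouped by dosage index. Lexicographic order is
preserved through every lookup so all downstream tie-breaks are
reproducible. Tables are capped at 8 markers for tetraploids and 6 for
hexaploids (configurable); beyond that the table no longer fits comfortably
in memory and a capacity error is raised per block while other blocks
proceed. Missing dosages are handled at lookup time by a union over the
possible values of the missing entries, so masking an entry can only grow
the solution set. Tables persist to a versioned `.npz` container and
regenerate bit-identically.

## Stage 1 — parsimony inventory

Step (a): a haplotype contained in *every* combination explaining an
individual is certainly present in it; haplotypes forced in at least
`min_frac` (default 10%, rounded up) of the usable individuals are accepted.
Step (b): for each individual not fully explained by the known set, the
solutions introducing the fewest new haplotypes are collected and the
haplotypes required by all of them counted; those required in ≥ `min_frac`
of individuals join the set. Step (b) iterates to a fixpoint; if the sets
cycle, the result of the first execution is kept (anchored in the
near-certain step-(a) haplotypes), with a hard stop at 50 iterations.
Individuals with all dosages missing are excluded from the denominators and
never assigned; a-priori known haplotypes bypass the thresholds. An
individual is assigned only when exactly one of its solutions uses known
haplotypes alone. The stage-1 assignments are discarded when families are
present — only the inventory feeds stage 2.

## Stage 2 — full-sib segregation

Gamete model (one parameter α, fully polysomic): with probability 1 − α a
gamete is a uniform draw of `p/2` distinct homologs; with probability α one
uniformly chosen homolog is transmitted twice, the remaining slots filled
uniformly from the other homologs (for tetraploids the double-reduction
gamete is the duplicated homolog alone; hexaploid gametes duplicate at most
one homolog). Diploid gametes have one homolog, so α is ignored. The
offspring Ghap distribution of a parental pair is the convolution of the two
gamete distributions.

Dosage-error model: independently per marker a true dosage *d* is observed
as *d* with probability 1 − ε and as an adjacent dosage with probability ε,
split equally between *d* ± 1 and folded onto the single neighbour at the
boundaries. Array dosage errors are overwhelmingly off-by-one, which a
single parameter captures.

Scoring: expected offspring genotype-class probabilities are compared with
the observed counts of the fully genotyped offspring by a Pearson χ² test.
Classes with fewer than one expected individual are pooled — together with
observed-but-unexpected classes — into a single category; df = categories −
1 with a floor of 1. If the pooled category has zero expected mass but
non-zero observed count the candidate is impossible (P = 0). Candidate
pairs are enumerated first from inventory-only parental combinations, then,
if none survives, from all dosage-consistent combinations; a family whose
pair count at the stage being enumerated exceeds `max_parent_combs`
(150 000) is demoted, as are families with missing parental dosages or no
fully genotyped offspring. Survivors satisfy P ≥ 0.001·P_best and
P > 10⁻⁸.

Groups of families linked through shared parents are resolved jointly:
repeatedly remove the parental combination that leaves the most offspring
unexplained until the group is compatible (families losing their last
candidate are demoted); then maximize the product of family P values. The
families couple only through shared parents, so the optimum is found by
enumerating shared-parent assignments and maximizing each family's
candidate P given those slots. Under co-optimal ties only assignments
identical across all optima are kept. Offspring of a family with a single
accepted solution get the Ghap whenever their Gmrk maps to a unique
offspring class; offspring with missing dosages are imputed when a single
family-possible Gmrk matches their observed markers, and the family's
imputations are accepted only if fewer than half the family is imputed and
the χ² P including imputed offspring stays above 0.1 of the P without.

### Numerical notes

The inner loop scores every candidate pair against the observed counts in
mixed-radix index space, with the χ² survival function evaluated once per
family over the whole batch. With ε > 0 the expected probability of every
class that could plausibly reach one expected individual is computed
exactly (including channel leakage); classes are screened with an upper
bound `n·(prob + ε·leak₁ + ε²)` at a resolution of 0.25 expected
individuals, and the pooled category uses `n` minus the retained mass, so
truncation does not bias the statistic. The batch kernel is JIT-compiled
(numba) and is verified in the test suite against a pure-numpy reference
and against the straightforward dictionary-based computation. P-value ties
are compared at a relative tolerance of 10⁻⁹ in log space.

## Stage 3 — unrelated material

Unrelated individuals plus all members of demoted families are analyzed
with the stage-1 procedure, seeded with the haplotypes present in the
solved families and any a-priori known codes. If individuals remain
unassigned, one relaxed cycle of step (b) runs with a threshold of 1% of
individuals (minimum 2); its result is accepted only when the number of
uniquely solved individuals strictly increases and no previously unique
individual loses uniqueness. Members of *solved* families that remained
ambiguous are not re-analyzed.

## Pipeline

Blocks are processed independently (no linkage between blocks) and the
whole pipeline is deterministic: identical inputs and parameters give
identical outputs, and block order cannot influence per-block results.
With no families (or `--no-fs`) stages 1–2 are skipped and everything runs
through stage 3 directly. The pedigree, when provided, is used only for
checking: an offspring matches its parents when its Ghap splits into two
gametes each producible (at the configured α) by the respective parent;
with one assigned parent only one gamete is constrained. Replicate samples
can be merged into consensus genotypes beforehand (unique non-missing value
wins; disagreement gives missing).

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.025 | double-reduction frequency of the gamete model |
| `epsilon` | 0.025 | per-marker dosage-error probability |
| `p_ratio` | 0.001 | keep pairs with P ≥ p_ratio · best P |
| `p_min` | 1e-8 | absolute P floor for candidates |
| `max_parent_combs` | 150 000 | parental pair cap before demotion |
| `impute_p_ratio` | 0.1 | imputed-fit tolerance (P_with ≥ ratio·P_without) |
| `impute_max_frac` | 0.5 | reject imputation at ≥ this family fraction |
| `min_frac` | 0.10 | stage-1/3 haplotype presence threshold |
| `relaxed_frac` / min count | 0.01 / 2 | relaxed-cycle threshold |

## The simulator

The generator emulates the two validation designs: (i) a tetraploid
population of 9 FS families of 50 offspring all sharing one parent (10
parents, 460 individuals), founders structured into three clusters of
related individuals; (ii) 2 FS families of 50 sharing a parent plus two
groups of 50 unrelated individuals drawn from two distinct random-mating
source populations (203 individuals). Both use 60 haploblocks whose sizes
cycle over 3–7 markers (the recovery runs in the tests and the acceptance
script use 3–6). Founder haplotypes per block are drawn without replacement
from the `2^nmrk` space to hit a target distinct count of 14–26 (capped by
the space and the founder homolog slots), with geometric frequency decay
0.75 — calibrated so the per-individual SNP heterozygosity of the presets
falls in the 73–85% band characteristic of the intended material — and, in
the cluster design, a shared core of roughly a third of the pool plus
cluster-private haplotypes. Meiosis reuses the solver's gamete model; the
preset double-reduction rate equals the solver default (2.5%). The presets
emit error-free, complete dosage matrices (the validation design);
`epsilon_sim` (±1-adjacent errors) and `missing_rate` are available for
robustness experiments. All randomness flows from a single seed;
identical configurations reproduce identical bytes.

What the simulator does **not** emulate: genotype-calling artifacts beyond
off-by-one errors (e.g. systematically collapsed clusters), linkage decay
within blocks, preferential pairing/partial polysomy, multi-generation
pedigrees, or null alleles. Passing recovery tests therefore demonstrates
the segregation engine and the combinatorial machinery under the stated
inheritance model, not robustness to every artifact of real array data.

## Scoring

`score_against_truth` counts an assignment as correct only when it equals
the true multiset exactly. Percentages are averaged per block and then over
blocks (the summary tables also report pooled-individual percentages, since
the two averaging orders differ when block sizes or assignment rates vary).

## Known limitations

* Haploblocks beyond the table caps are skipped, not approximated.
* The χ² candidate ranking weakens when a cross spreads its offspring over
  many genotype classes (each expected < 1): pooling then absorbs most of
  the signal. This is inherent to the pooling rule, and is the main source
  of wrong family solutions in the validation runs.
* Stage-3 (unrelated-only) calls are parsimony-based and markedly less
  reliable than family-based calls — the design point of the method.
* All individuals must share one even ploidy; odd and mixed ploidies are
  out of scope.
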