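# Methods

This note documents the models and procedures implemented in `funcdiff`,
the assumptions they rest on, the defaults and why they were chosen, and
what the synthetic-data tests do and do not demonstrate about real data.

## Feature matrices

The pipeline treats the KO (KEGG Ortholog) as its atomic feature: an
identifier (`K` + five digits) for a group of orthologous genes with a
shared molecular function. All downstream structure is built from
per-unit KO repertoires (isolate genomes) or per-ORF KO/genus/read-count
tables (metagenome samples).

* **K (KO presence)** — binary, rows = KOs (union over all organisms),
  columns = organisms. Duplicated KOs within an organism count once:
  presence, not copy number.
* **P (pathway coverage)** — for pathway *i* and organism *j*,
  |KOs(j) ∩ members(i)| / |members(i)|. Coverage is monotone under KO-set
  growth and bounded in [0, 1]; dividing by pathway size makes small and
  large pathways comparable. A pathway's member set is its coverage
  denominator, so empty member sets are rejected at parse time.
* **G (genus abundance)** — read counts summed per genus per sample over
  KO-annotated ORFs, then normalized per column to reads-per-million
  (g_ij / g_j × 10⁶). ORFs without a KO are retained by the readers
  under the reserved genus `unclassified` so read totals are conserved,
  but are excluded from KO-indexed matrices and, by default, from the
  per-sample totals g_j (an `include_unannotated` flag adds them back —
  whether the total should include unannotatable reads is a genuine
  modeling choice and both conventions are defensible).
* **Complement adjustment** — with an inoculated focal genus, non-focal
  entries of each column are divided by (1 − f_j), f_j being the focal
  genus' per-million fraction, and the focal rows dropped; column sums
  return to 10⁶. Order of operations: raw sums → per-million →
  complement. Computing f_j on the per-million scale makes the
  complement read as a relative abundance. The adjustment is undefined
  (and an error) when a column consists entirely of the focal genus.
* **A (KO-genus abundance)** — read counts per (KO, genus) row per
  sample; summing its rows per genus reproduces G on KO-annotated reads
  exactly, which the tests assert as a marginalization identity.
* **PM (pathway-genus coverage)** — per (pathway, genus, sample), the
  number of *distinct* KOs of that genus in that sample that are pathway
  members, over pathway size. A count of orthologs, not read-weighted:
  this mirrors the isolate-side P definition and keeps the quantity a
  coverage in [0, 1].

Row and column orders are lexicographic everywhere, and composite row
labels use `"<ko-or-pathway>|<genus>"`; outputs are therefore bit-stable
and round-trip losslessly through the TSV writer/reader pair.

Standard deviations (SD filtering of genus dynamics, discriminative
pathway ranking) use the sample (n−1) denominator throughout; ties break
lexicographically by row id.

## Clustering

Similarity between units is Pearson correlation (default) or Bray-Curtis
similarity (1 − dissimilarity), both exposed because neither is uniquly
right: Pearson compares profile *shape* regardless of scale, Bray-Curtis
compares composition. Pearson is undefined for constant profiles and the
offending unit is reported by name rather than silently patched.

**Affinity propagation** is implemented as damped responsibility/
availability message passing over the similarity matrix with the
diagonal set to a uniform exemplar preference. Defaults: damping 0.9,
max 1000 iterations, convergence declared after 100 iterations of
unchanged exemplar decisions — conservative values in line with common
practice for the algorithm. A tiny symmetric seeded noise (scale 1e-12)
breaks exact-tie degeneracies; results are deterministic given the seed.
Non-convergence returns the current best decision with
`converged=False` instead of failing. The objective the heuristic
pursues — net similarity, the sum of member-to-exemplar similarities
plus exemplar preferences — is recomputed exactly for every result, and
on small separated-structure fixtures the tests verify it against
exhaustive search over exemplar subsets. On unstructured point clouds a
converged affinity propagation solution can sit slightly below the
exhaustive optimum; this is a known property of the heuristic, not a
defect of the implementation, and is why the oracle fixtures are
separated blobs.

**Preference tuning.** The cluster count grows with the preference but
not monotonically: plateaus, local dips, and jumps that skip a count
entirely all occur in practice. `tune_preference` therefore evaluates a
coarse grid across the off-diagonal similarity range (extended downward
when even the minimum over-fragments), then refines between evaluated
preferences whose counts straddle the target, preferring straddles whose
counts bracket the target tightly; the search is capped at 50 affinity
propagation runs. If no preference attains the target exactly — which
genuinely happens when cluster sizes are imbalanced — the clusters of
the closest over-fragmented solution are agglomerated and the merge tree
is cut at the target count. This mirrors the standard workflow of
running affinity propagation at high preference and merging the
resulting clusters under inspection of the dendrogram; the cut replaces
the manual inspection with an explicit target, and the full merge tree
is exported for human review.

**Agglomeration criterion.** Cluster pairs are merged by best joint
exemplar, scored as the maximum over candidate exemplars of the
*minimum* similarity of the other members to that candidate. The
minimum (rather than the mean) makes the score answer "does some member
represent everyone in the union well?"; mean-based scores let a large
tight cluster absorb a stray singleton that a small cluster fits far
better, because one poor member is diluted by many good ones. Merge
heights are negated scores, forced monotone by running maximum.

**Leave-genus-out robustness.** Rows of the named genera are removed
from the G or A matrix, columns re-normalized to per-million, the
samples re-clustered with identical parameters, and the adjusted Rand
index against the full-data clustering reported. ARI 1 means the
partition is unchanged; values ≥ 0.9 indicate the grouping does not
hinge on the removed genera.

## Discriminative analysis

**Coverage-SD ranking** is deliberately simple: across a chosen unit set
(all organisms, cluster exemplars, or a hand-picked comparison), the
pathways with the largest coverage SD are the discriminative ones. A
single planted absence among otherwise-complete pathways is the extreme
case and tops the ranking. Reported tables carry the per-unit coverages
(as percentages for heat-map export) so the SD is recomputable from the
table itself.

**Shadow-feature selection** (`boruta_select`) finds *all relevant*
features for a class response rather than a minimal predictive subset.
Per run: append one shuffled copy (shadow) of every original feature,
fit a random-forest classifier (scikit-learn, 500 trees by default,
class-balanced sampling), and score a hit for every undecided feature
whose importance exceeds the best shadow's. Hits over runs are compared
to Binomial(t, ½) by two-sided tests at significance 1 − confidence
(default confidence 0.99) with Bonferroni correction across the
undecided features; significant excess confirms, significant deficit
rejects. The run cap defaults to 2000; anything undecided at the cap is
reported tentative, never promoted.

Two design points deserve emphasis:

* The shadow pool keeps *full size* every run — one shuffled copy of
  every original feature, decided or not — while rejected features leave
  the design matrix and confirmed ones remain untested. With few
  samples and many features, some pure-noise features are genuinely
  correlated with the realized class labels; against a *shrinking*
  shadow pool such features eventually outrank the best shadow more
  often than not and get falsely confirmed (measured: several spurious
  confirmations per all-noise dataset at n=60 with 200 features). A
  full-size pool keeps the null calibrated — the most chance-correlated
  of m noise features beats the maximum of m fresh shadows only about
  half the time — and the measured null then confirms nothing in ≥95%
  of datasets while planted-signal recall stays at 1.0.
* Importance defaults to permutation importance (decrease in accuracy
  when one feature's values are shuffled), which is scale-free and
  robust for sparse high-dimensional KO-genus matrices; impurity
  importance is available as a much faster option and is what the
  simulation-heavy tests use, since the two agree on which features
  clear the max-shadow bar in these fixtures while differing several
  hundredfold in cost.

Response vectors for the wine system map grape variety → wine color
(Airen → white; Bobal, Tempranillo → red) for the two-class task, or
pass varieties through for the three-class task.

## Synthetic communities

The generator emulates the two data branches the pipeline consumes, with
planted ground truth:

* **Isolates** — an ontology of disjoint KO blocks (20 pathways of 5-15
  KOs by default; an overlap mode exists but the default keeps oracles
  exact). An organism carries every KO of every pathway outside its
  absence set, background KOs from a pool disjoint from the ontology
  (rate 0.02 by default — functional repertoire outside the mapped
  pathways), and unannotated filler genes at 50% of its gene count,
  reflecting that only about half of coding sequences typically map to a
  KO. The default community has 30 organisms in 8 groups with private
  absence pairs — the shape of a kefir-culture isolate panel whose
  KO-content clustering resolves 8 groups, with every absence a planted
  auxotrophy.
* **Metagenome series** — reads are multinomial over (genus, KO) cells:
  genus weights follow planted per-timepoint relative abundances
  (optionally class-dependent), spread uniformly over the genus' KO
  repertoire; 10⁶ reads per sample. The default series has two classes
  of fermentations, treated (inoculated *Lactobacillus*, boost +0.15
  renormalized) and control, three replicate fermentations each over
  four timepoints. The class signal is carried by class-exclusive genera
  (*Pantoea*/*Gluconobacter* with the treatment, *Dyella* against it,
  molds suppressed under treatment) so that it survives complement
  adjustment of the inoculated genus — mirroring how real inoculation
  effects show up as knock-on community shifts, not only as the
  inoculant's own abundance. Shared trends (yeast rising, early
  colonists declining) are mild by comparison. A Dirichlet-multinomial
  option (concentration parameter) adds the overdispersion real
  metagenomes show; the multinomial default keeps the binomial
  error bounds of the tests exact.

What passing tests show — and do not. Recovery of planted structure
shows the pipeline's stages are correct and well-calibrated under the
generator's assumptions: independent reads, uniform within-genus KO
usage, class signal in genus composition. Real metagenomes violate all
three (correlated coverage along assemblies, highly non-uniform KO
abundance within genomes, batch effects), so test results bound
implementation correctness, not field performance.

## Numerical and interface choices

* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; generators derive per-organism/per-sample streams from
  (seed, stream, index) so outputs are byte-stable and insertion-order
  independent.
* Per-million conservation is asserted at 1e-6 relative tolerance;
  similarity symmetry at 1e-9; net-similarity oracle agreement at 1e-9.
* Degenerate inputs error loudly with the offending unit named: empty
  annotations, zero-read samples, constant profiles under Pearson,
  focal-genus fraction 1, dropping every genus.
* Workflow bundles are written without timestamps and fully determined
  by config + seed; rerunning a config reproduces the bundle
  byte-for-byte (asserted in the tests).
* Problem sizes in the test suite and acceptance script (30 organisms,
  24 samples, 10⁶ reads, 20 selection replicates at n=60 with 210
  features, forests of 100-150 trees capped at 50 runs) were chosen as
  the smallest sizes at which every planted effect is unambiguous;
  they keep the full suite in the minutes range on a single CPU.

## Known limitations

* Affinity propagation is a heuristic: no optimality guarantee off the
  separated-structure regime, and `tune_preference` may return a
  neighboring cluster count (flagged, never silent) when no preference
  and no merge-tree cut attains the target.
* The selector's tentative class is a real outcome at the run cap;
  downstream code must not treat it as rejection.
* The KO pattern (`K#####`) is enforced strictly; other ortholog
  vocabularies would need a reader extension.
* Pathway coverage weights every KO equally; a missing hub enzyme and a
  missing accessory gene count the same.
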