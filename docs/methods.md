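# Methods

## The annotation problem

Untargeted LC-MS metabolomics yields thousands of aligned chromatographic
features (m/z, retention time, per-sample abundance), of which only a small
fraction can be identified by matching their MS2 spectra against a library
of authentic standards — libraries cover hundreds of compounds, metabolomes
tens of thousands. `metanno` extends annotation beyond the library by
exploiting the structure of metabolism itself: substrate–product pairs of
enzymatic reactions (reaction pairs, the KEGG RPAIR concept) are
structurally similar and therefore tend to share fragmentation behavior.
An identified metabolite can thus lend its experimental MS2 spectrum to its
reaction-paired neighbors as a *surrogate* reference spectrum, the newly
annotated neighbors lend theirs onward, and annotation propagates
recursively through the metabolic reaction network (MRN) until no new
metabolite is found.

## Model and scores

**Spectral similarity.** All spectrum comparisons use the weighted cosine
("dot product")

    DP = Σ W_S·W_E / sqrt(Σ W_S² · Σ W_E²),    W = I^n (m/z)^m,  n = 1, m = 0,

over a greedy one-to-one fragment alignment (±25 ppm with a 0.01 Th
absolute floor). The forward score spans the union of fragments — unmatched
fragments of either spectrum keep their full weight in their own
denominator, so spurious fragments are penalized; the reverse score
restricts both vectors to the reference spectrum's fragments, the
convention of reverse library search. Scores lie in [0, 1].

**Seed annotation (round 0).** MS1 peaks and MS2 spectra are paired by
precursor m/z (±25 ppm) and RT (±10 s); with several candidate spectra the
most abundant wins (summed intensity of the ten largest fragments; ties
break by smaller |ΔRT|, then |Δm/z|). Pairs are matched against the
standard spectral library within ±25 ppm; an annotation is kept when the
forward *or* the reverse dot product exceeds 0.8 (strictly), and then
filtered by predicted RT (±30%). Surviving metabolites that exist as MRN
nodes become the round-0 seeds.

**Support peaks.** For every annotated metabolite the theoretical
isotopologue envelope [M]..[M+4] is computed from the molecular formula by
exact truncated polynomial expansion of natural isotope abundances (pinned
NIST table; fine structure aggregated by nominal mass shift, m/z spacing
1.00335 Th). Matching MS1 peaks (±25 ppm, co-elution ±3 s, relative
abundance within ±500% of theory) are scored

    Score_iso = 0.45·Score_mz + 0.45·Score_rt + 0.10·Score_int,

each component a linear ramp from 1 at a perfect match to 0 at the
tolerance. Alternative adduct peaks ([M+Na]+ etc., singly charged species
only) are scored with weights 0.8/0.2 on the m/z and RT components, and
each matched adduct receives its own isotope pass. The expected isotope m/z
is anchored on the observed parent peak so a shared calibration offset does
not consume the tolerance.

**Neighbor annotation.** Each seed retrieves its MRN neighbors at one
reaction step (widening to two, then three steps only if it annotates
nothing — per seed, per round). For each neighbor and adduct rule, candidate
peaks must match the theoretical m/z (±25 ppm) and the predicted RT (±30%),
and the candidate's own MS2 spectrum must resemble the precursor-trimmed
surrogate spectrum with DP ≥ 0.5 (fragments heavier than the lighter
precursor are removed before scoring; a trim that empties a spectrum scores
0 and is rejected). Matches are scored

    Score_iden = 0.25·Score_mz + 0.25·Score_rt + 0.50·Score_spec.

Newly annotated metabolites that have not previously served as seeds are
promoted (one seed per metabolite, carrying the best-scoring peak's
spectrum); the loop ends when a round yields no new seeds. Termination is
guaranteed: the cumulative seed set grows strictly while bounded by the
node count. When one (peak, metabolite) hypothesis is re-derived, the best
score is kept but the round stamp records first appearance, so per-round
trajectories stay meaningful. Round-0 annotations are never overwritten.
At output, candidates per peak are ranked by score and truncated to the
top 5 with scores above 0.4.

**Confidence and redundancy.** Peaks sharing a metabolite annotation are
clustered by RT (single linkage, 3 s gap) into peak groups and graded:
1 — contains a library annotation; 2 — else contains isotope support;
3 — else contains a reliable adduct ([M+H]+/[M+Na]+/[M+NH4]+ positive,
[M−H]−/[M+Cl]−/[M+CH3COO]− negative); 4 — otherwise. Redundancy removal
alternates two rules with regrouping until the combined redundancy (mean of
annotations-per-annotated-peak and peak-groups-per-metabolite, computed on
monoisotope-role annotations) stops changing: a metabolite spread over
several groups drops its grade-4 groups unless all are grade 4, and a peak
with several metabolite annotations keeps only the best grade (rules applied
in that order; ties all kept, ranked by score). On pipeline-shaped inputs
this converges within a handful of iterations; for fully adversarial
unstructured inputs the combined metric is not guaranteed monotone (removing
a singleton-group metabolite can raise the groups-per-metabolite mean), a
property of the definitions rather than of the implementation.

**Retention-time prediction (QSRR).** Molecular descriptors arrive as a
numeric table computed externally from structures — the module does no
chemistry. The training set is the library identifications after uniqueness
rules (best dot product per peak, most intense peak per metabolite,
reliable adducts only). Matrix hygiene: columns with more than 50% missing
values dropped, the rest imputed by k-nearest neighbors (k = 10, Euclidean
over standardized columns), constant columns dropped. Descriptor selection
is a stability procedure: 100 random-forest fits on random 68% subsets
(without replacement), recording each fit's top-5 descriptors by impurity
importance; descriptors recorded more than 50 times are kept, with the
published HILIC/RP combinations as fallback when the selection is empty.
Hyperparameters (ntree ∈ {300, 500, 800, 1000} × mtry ∈ {p/3, √p, p/2})
are tuned by out-of-bag MSE and the best point refit on all data.
Everything is seeded and deterministic.

Two degraded modes protect small-library runs. Below 20 training
metabolites, stability selection is skipped (importance cannot be resolved
from ~7-point internal fits, and a chance-correlated noise descriptor can
hijack the model) — the forest keeps every cleaned descriptor — and the RT
filter widens from ±30% to ±50% with a prominent warning. Independently, if
the tuned forest's out-of-bag R² is not positive the model predicts worse
than the training mean; vetoing annotations with it would be unjustified,
so RT predictions are treated as unavailable: library annotations pass
RT-unchecked and neighbor candidates are matched on m/z and spectrum alone
with the RT component scoring 0 (flagged `rt_checked=False`). Both guards
use only training-side information.

**Pathway stage.** Peaks are tested for two-group differences (two-sided
Student's t or Mann-Whitney U, optional Benjamini-Hochberg correction);
the metabolite annotations of dysregulated peaks are tested for pathway
enrichment with the upper-tail hypergeometric law against the universe of
all annotated metabolites (configurable). Quantification Pareto-scales
every peak ((x − mean)/√sd, sample sd), represents each peak group by its
most abundant member and each metabolite by its best-scoring group, and
averages members per pathway. Correlation networks use pairwise Pearson r
with its t-test p (pathway-pathway edges at p < 0.05; gene-metabolite edges
at the stricter p < 0.01 and |r| > 0.7, both exposed as knobs since
published conventions differ).

## The synthetic-data generator

`metanno.fixtures` builds complete, ground-truthed studies:

* **Network**: chain, star, or connected Watts-Strogatz small world
  (k = 4, p = 0.1) over randomly composed organic formulas. Formula
  sampling rejects any candidate whose planted ion species ([M+H]+ and
  [M+Na]+ with their first two isotopologues) would fall within 60 ppm of
  an existing one, so every peak has an unambiguous identity.
* **Spectra**: each node's fragment set is a sliding window over a permuted
  pool of grid-spaced m/z values with intrinsic per-fragment intensities
  (jittered per node). The window step is set so the mean shared-fragment
  proportion across reaction-pair edges equals the inheritance parameter
  (default 0.7); sharing decays with lattice distance and vanishes for
  distant pairs, reproducing the empirical similarity-versus-reaction-step
  decay that propagation relies on, with redundant spectrally valid paths
  into every node. Zero inheritance uses disjoint windows (no propagation
  possible). The star topology instead gives every spoke a random
  inheritance-fraction subset of the hub's fragments.
* **Peaks**: per metabolite a monoisotope peak ([M+H]+, ±5 ppm error,
  log-normal abundance, log-scale noise sd 0.2 across 10 + 10 samples),
  exact [M+1] and [M+2] envelope peaks (intensities from the engine's own
  isotope model — deliberately shared so envelope tests are exact),
  a 30%-intensity [M+Na]+ peak for half the metabolites, and unassigned
  noise peaks kept clear of every match window. Five effect metabolites
  carry a 4-fold change concentrated in one pathway of four.
* **RT**: 100 + 2·d1 + 3·d2 + N(0, 3 s) over two planted descriptors
  d ~ U(0, 60), plus 20 decoy descriptors, missing values in some decoys
  and one constant column to exercise matrix hygiene.
* **Library**: a configurable subset of metabolites (default 20%) with
  intensity-jittered true spectra.

Misannotated-seed experiments replace each library seed with a decoy node
whose mass/RT errors follow the four published corruption classes, attached
to a non-reaction-paired metabolite chosen by measured spectral similarity:
unrelated decoys (types 1-2) attach where everything reachable is below the
0.5 gate, mass-matched decoys (types 3-4) where similarity is marginal
(0.45-0.70). Decoy records carry their defining quantities so tests can
verify the inequalities constructively. Because the generator has no
isomers and no mass collisions, a corrupted run that does bridge back into
the true network re-seeds with correct spectra; the misannotation signature
is therefore measured on the annotations each seed set derives directly.

**What the generator does not emulate**: chromatographic peak shape,
detector noise and saturation, in-source fragmentation, isomers/isobars,
fragmentation chemistry (fragment sets are abstract), missing MS2 coverage
(every monoisotope peak has a spectrum). Passing tests therefore
demonstrate the engine's logic — scoring, gating, propagation, grading,
statistics — under the stated similarity structure, not its accuracy on
real instrument data.

## Problem sizes and numerical choices

The standard test study uses 50 metabolites (≈178 peaks, 20 samples), the
termination sweep 100 random worlds of 4-12 metabolites, the RT recovery
experiment n = 100 metabolites × 22 descriptors over 10-20 replicate
worlds with 50-tree selection forests, and the null-calibration check 2000
simulated peaks. Tolerances: fragment alignment ±25 ppm with a 0.01 Th
floor; score oracles agree to 1e-10; isotope envelopes to 1e-4 relative
against exhaustive isotopologue enumeration. Recursion is capped at 50
rounds and redundancy removal at 20 iterations as guards against
pathological inputs; neither cap is reached in practice. Ties in candidate
ranking break by higher spectral score, then smaller m/z error.

## Known limitations

* Propagated annotations are putative (class-level) identifications;
  grades quantify peak-level evidence, not structural confirmation.
* The organic-structure eligibility rule (non-empty structure string and
  carbon in the formula) is a configurable stand-in for the original
  resource's unpublished curation rule.
* Multiply charged species and in-source fragments are out of scope.
* The intensity-ratio tolerance (±500% normalized by theory) is asymmetric
  in ratio space; it is implemented as defined.
* With very small libraries the engine runs in the degraded RT modes
  described above and neighbor matching loses RT specificity; in real data
  this trades precision for coverage.
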