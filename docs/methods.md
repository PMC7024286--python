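# Methods

This note records the models, parameter choices and numerical conventions
behind each stage, what the synthetic generators do and do not emulate, and
the limitations a user should know before trusting results on real data.

## 1. Distance-based taxonomy

**Model.** Taxon assignment uses uncorrected *p*-distances on a fixed
multiple alignment — no substitution-model correction, no rate variation.
That is deliberate: the species/genus cutoffs in use in cyanobacterial
systematics (99% and 95% 16S identity) are calibrated on raw identity, so
applying a corrected distance would shift strains across the thresholds.
Columns where either sequence has a gap, `N` or an IUPAC ambiguity code are
excluded pair by pair (pairwise deletion); each pair therefore has its own
compared-site count, which the distance matrix retains. A pair with zero
comparable sites is an error, not a zero.

**Clustering.** Species clusters are single-linkage components at
dissimilarity ≤ 0.01, genus clusters at ≤ 0.05 (boundary inclusive:
similarity ≥ 99.0% is conspecific). Single linkage mirrors how pairwise
"x% dissimilarity with y" reasoning is done in practice, but it can chain:
a/b and b/c within the cutoff need not put a and c within it. Chained
clusters that break monophyly on the tree are *flagged*
(`monophyly_ok = False`), never split — the flag is a prompt for human
judgement, which is how such conflicts are resolved in descriptive
taxonomy anyway. Cluster labels are canonicalised by the lexicographically
smallest member id, so the delimitation is invariant to input order.
Because the species cutoff is nested inside the genus cutoff, species
clusters always refine genus clusters, and "new genus" implies
"new species".

**Trees.** The internal tree is neighbor joining (via scikit-bio) on the
p-distance matrix, with negative branch lengths clamped to zero and the
root placed on the branch to a caller-named outgroup. NJ is exact on
additive matrices — the test suite verifies leaf-to-leaf path-length
recovery to < 1e-9 on random additive matrices — which is the property the
monophyly check relies on. Clade support is column bootstrap: resample
alignment columns with replacement, rebuild the NJ tree rooted identically,
and report the percentage of replicates containing each clade of the
full-data tree. 100 replicates by default; a single integer seed makes the
procedure reproducible. A degenerate resample that leaves some pair with
no comparable sites is skipped (it still counts in the denominator).
Users with a maximum-likelihood tree can pass it as Newick and the
delimitation will test monophyly on that tree instead.

**Trimming.** Whether published pairwise dissimilarities were computed on a
full alignment or a trimmed position set is often unclear; the alignment
reader exposes `trim=(start, stop)` so either convention can be
reproduced. Default is the full alignment.

## 2. Feature-based molecular networking

**Preprocessing.** Per spectrum: drop fragments within ±17 Da of the
precursor (they carry no structural signal and would otherwise dominate
every cosine), keep the 100 most intense peaks (bounds the all-pairs cost),
apply square-root intensity scaling (the networking community's convention,
damping base-peak dominance; `none` is selectable), then L2-normalise so
every self-cosine is exactly 1. A spectrum emptied by the window is
excluded from networking with a warning.

**Modified cosine.** Candidate fragment pairs match directly within
0.02 Da or offset by the precursor mass difference Δ within 0.02 Da (the
shifted mode is what lets structural analogs differing by one modification
score highly). The one-to-one assignment is greedy in decreasing
intensity-product order; ties break by smaller m/z residual, then by
smaller m/z sum — the sum (rather than one spectrum's m/z) keeps the rule
symmetric, so f(a,b) = f(b,a) holds exactly. Greedy is not guaranteed
optimal when candidate partners conflict, but it is deterministic, never
exceeds the Hungarian optimum (enforced by test against
`scipy.optimize.linear_sum_assignment`), equals it on conflict-free
instances, and matches the matchms implementation on such instances to
1e-7. With L2-normalised intensities any one-to-one matching is bounded by
Cauchy-Schwarz, so scores stay in [0, 1].

**Edge rules.** An edge requires cosine > 0.7 *and* ≥ 7 matched peaks
("more than six"), then must survive mutual top-K pruning at K = 10: each
endpoint must rank inside the other's 10 best-scoring neighbours
(neighbour-id tie-break, making the filter deterministic). Components with
≥ 2 nodes are the clusters; everything else is a singleton. The library
thresholds differ on purpose: "at least six" matched peaks (≥ 6) for
annotation versus ≥ 7 for network edges — both are configurable, and the
discrepancy is surfaced here rather than silently harmonised. Fragment and
precursor tolerances (0.02 Da) and the analog window (100 Da) are not
dictated by the thresholds above; they are chosen to match common
high-resolution Q-ToF practice and are exposed in `NetworkParams`.
No maximum component size is enforced.

**Annotation.** Strict dereplication requires |Δprecursor| ≤ 0.02 Da and
unshifted matching; analog ("variable") dereplication allows
0.02 < |Δ| ≤ 100 Da with shifted matching and reports Δ as the putative
modification mass. A feature's best hit per mode is kept; a strict match is
never duplicated as an analog hit. The statistical significance model of
peptide-spectrum matching (P-values) is out of scope — analog hits are
similarity statements, not identifications.

**Genus mapping.** For each node, the mean precursor ion intensity over
each genus's samples (features absent from a sample contribute zero, and
the denominator is all samples of the genus), with the argmax as dominant
genus; ties resolve lexicographically and are flagged.

## 3. Growth-inhibition scoring

Per replicate, `% inhibition = 100 − (OD_S − OD_B)/(OD_T − OD_B) × 100`.
A control that did not grow (OD_T ≤ OD_B) invalidates the replicate — it
is excluded with a warning, and the reading errors only if every replicate
failed. Values are *not* clipped: > 100% (sample below blank) and < 0%
(apparent growth stimulation) are preserved and flagged, because they are
evidence about the assay, not noise. Summaries are mean ± SEM with the
n−1 standard deviation (the convention for n = 3 reporting); n = 1 reports
SEM 0 with a flag. Activity is strict: mean > 50%. Inactive cells render
as `n.a.` in the activity table. Positive-control antibiotics are metadata
only; no MIC or dose-response estimation is attempted.

## 4. Synthetic data: what it emulates, and what it does not

**Alignments.** A root sequence uniform over {A,C,G,T} descends through
genus → species → strain ancestors; each branch substitutes a *fixed
count* round(p·L) of randomly chosen sites, each to one of the other three
bases. Branch probabilities are half the target pairwise divergence at each
level (0.4% within species, 3% within genus, 8% between genera, over
L = 1300 sites; a single outgroup at 15%). Fixing counts rather than
flipping per-site coins is a variance-reduction choice: realized pairwise
distances then sit within a few per mille of the planted values even for
the *minimum* over all genus pairs, which per-site Bernoulli mutation does
not guarantee (its binomial tail can push one of the ~21 genus-pair minima
across the 5% genus cutoff). Residual spread comes only from site
collisions between branches, which bias distances down by O(div²). The
default layout — 7 genera holding (2,2,2,2,2,1,1) species and 20 strains —
matches the scale of a small strain-collection survey. Not emulated: gaps,
alignment error, chimeras, rate heterogeneity across sites, GC bias.
Passing tests show cutoff logic and tree topology are recovered under
clean divergence structure, not that the cutoffs themselves are right for
any particular real clade.

**Spectra.** Each family has a base peak set (m/z on a 0.01 Da grid,
≥ 1 Da apart, log-normal intensities); members keep a `shared_fraction`
(default 0.8 of 12 peaks) of it *at family-level intensities*, resample
the rest at ~30% intensity, and — beyond the first member — shift the
precursor and a family-level "modifiable" half of the shared fragments by
a per-member delta in 10–60 Da. Because the modifiable subset is fixed per
family, any two members match on all shared fragments (unmodified ones
directly, modified ones via the precursor-difference shift), which is
exactly the structure modified cosine is designed to exploit. Noise
spectra are fully random and become singletons. Quantification intensities
concentrate each family in one genus's samples. Not emulated: isotope
envelopes, adducts, in-source fragmentation, chimeric MS/MS, retention
time structure, intensity-dependent peak counts.

**Plates.** `OD_S = B + (1 − p/100)(T − B) + N(0, σ)`, truncated at 0,
with noise on the sample wells only, so p is exactly recoverable at σ = 0.
Defaults: B = 0.05, T = 0.65, σ = 0.02, triplicates — OD noise of
0.02 on a 0.6 growth window corresponds to ±3.3% inhibition per replicate.

## 5. Statistical note on inhibition recovery

With triplicates, an interval built from the *reported* SEM
(mean ± 3·sd/√3) is a Student-t interval with 2 degrees of freedom; its
exact coverage is 2·F_t₂(3) − 1 ≈ 90.5%, not the ~99.7% the 3σ intuition
suggests. The acceptance suite therefore checks recovery coverage against
the estimator's *true* standard error (the noise model is known:
100·σ/(T − B)/√n), which is a 3σ normal interval with 99.7% coverage, and
separately verifies that sample-SEM intervals hit their theoretical 90.5%
— a calibration check that the generator's noise really is what the
summary statistics assume.

## 6. Problem sizes and defaults in the checks

The automated checks run at desk scale, chosen so the full suite completes
in well under a minute while still exercising every rule: 20 seeds for the
taxonomy (21 taxa × 1300 sites) and networking (40 spectra) recoveries,
100 random additive matrices of ≤ 8 taxa for the NJ oracle, 200 random
spectrum pairs of ≤ 6 peaks for greedy-vs-optimal, 500 seeded plates for
inhibition coverage. Bootstrap uses 100 replicates in the analysis
drivers and smaller counts in unit tests where only determinism or the
all-or-nothing property is at stake.

## 7. Known limitations

- Single linkage is the only clustering rule; no average/complete-linkage
  comparison is offered, only the monophyly flag as a safeguard.
- NJ is the only internal tree method; for publication-grade phylogenies an
  external ML tree should be supplied.
- The modified cosine caps spectra at 100 peaks; extremely peak-rich
  spectra lose low-intensity information before scoring.
- All-pairs scoring is O(n²) in the number of features; at the scale of
  thousands of features a blocked or indexed implementation would be
  needed.
- Analog deltas are reported unsigned with respect to direction semantics:
  a negative delta means the query is lighter than the library record.
- The activity call is a point-estimate threshold; no uncertainty
  propagation into the active/inactive decision is attempted.
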