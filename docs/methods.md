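# Methods

## Model

A patient is sequenced at T ≥ 2 tumor timepoints (diagnosis = index 0, then
relapses) plus at least one remission control. Somatic SBS mutations private
to a clone are expected to share a VAF trajectory: under the diploid
heterozygous model used throughout,

    E[VAF_t] = purity_t × CCF_t / 2,

where CCF_t is the fraction of tumor cells carrying the mutation at
timepoint t. No copy-number correction is applied — clustering operates on
raw VAFs, and CCF conversion is deliberately out of scope. Observed VAFs
are binomial draws at the local read depth, so a clone of CCF ~0.9 at depth
80 has a per-mutation VAF standard deviation of ~0.055; cluster separability
should be judged against that scale.

## Somatic filter cascade

Seven rules in fixed order (caller PASS status; maximum population allele
frequency < 0.01; total depth ≥ 20 in **every** sample; ≥ 3 variant reads
in ≥ 1 **tumor** sample; VAF ≥ 0.25 in ≥ 1 **tumor** sample; outside
centromere intervals; ≤ 0 variant reads in every control). Removal is
attributed to the first failing rule, making reports reproducible. The
alt-read and VAF rules are restricted to tumor samples: letting a control
qualify a variant would contradict the zero-control-reads somatic rule.
Zero-depth sites fail the depth rule, never the VAF rule (VAF at zero depth
is defined as 0). The population-AF threshold applies to the maximum over
however many population databases are annotated — the most conservative
reading for somatic status.

## Clone tracking

- **Over-segmentation**: K-means (Euclidean, raw VAF space, k-means++
  seeding, best of 25 restarts, fixed seed) with `k_initial` of 10–15,
  intentionally larger than the expected clone count. If `k_initial`
  exceeds the number of *distinct* VAF rows, K is capped there (over-asking
  is harmless intent; the merge step rejoins).
- **Merging**: iteratively merge the pair of clusters with the smallest
  centroid L∞ distance while it is below `merge_distance` = 0.10,
  recomputing the merged centroid as the member mean after each merge. L∞
  reads as "maximum per-timepoint VAF discrepancy"; 0.10 is roughly twice
  the binomial noise scale at depth 80 and separates clones that differ by
  presence of a heterozygous clone. An explicit `manual_map` can replay
  curator merge decisions instead.
- **Small clusters**: clusters below `min_cluster_size` (default 50) are
  dissolved to outliers unless `keep_small_clusters` is set — the flag
  exists because genuinely small clusters can be biologically meaningful
  (a transient clone seen at a single relapse).
- **Outlier pruning**: members farther than `outlier_distance` = 0.20 (L∞)
  from their own centroid become OUTLIER; centroids are recomputed once.
  Outliers are excluded from all downstream profiles.
- **Trajectory labels**: presence at a timepoint means centroid VAF ≥
  `presence_threshold` = 0.05 (≈ the smallest clone reliably visible at
  depth 80). ancestral = present everywhere; falling = present at t=0,
  absent at the end; rising = the reverse; transient = absent at both ends,
  present between; everything else = other.
- **Purity**: reported (never used to rescale) as
  min(1, 2 × median VAF at t of the largest cluster present at t). This is
  only meaningful when a clonal cluster dominates at t; when the largest
  present cluster is subclonal the estimate is biased low, which the run
  report makes visible rather than hiding.

## Profiles and similarity

Each SBS is assigned to one of 96 channels (substitution class × 5' base ×
3' base), reverse-complemented onto the pyrimidine strand; channel order is
the canonical substitution-class-major order, fixed once and reused by
every matrix in the package to prevent silent row misalignment. Mutations
with an N in the trinucleotide context are excluded and counted, not
imputed. Cosine similarity (scale-invariant, in [0,1] for nonnegative
inputs) scores each cluster profile against every catalog signature;
merged entries (e.g. SBS2/13) are equal-weight renormalized means of the
member columns — the neutral reading of a "merged" signature — and the
report view masks values below 0.7.

## De novo extraction and refitting

NMF of the 96×N count matrix uses multiplicative updates minimizing
generalized Kullback–Leibler divergence — the natural objective for count
data (Frobenius is available via `sklearn` if wanted, but the package's own
implementation exposes what the analysis needs: per-iteration objective
trajectories, a monotonicity assertion at every iteration, and seeded
restarts whose best run is kept and reproducible bit-for-bit). W columns
are normalized to sum 1 with the scale absorbed into H, leaving W·H
invariant. ε = 1e-12 guards zero denominators. Extraction is stabilized by
appending background 96-count columns (the simulator generates them;
real analyses would pool external cohort genomes the same way).

Rank selection is diagnostic, not automatic: per rank, the reconstruction
error (non-increasing in rank by nesting) and the mean best-match cosine of
signatures across restart pairs ("reproducibility") are tabulated; the run
rank comes from configuration. For the presets the rank equals the number
of planted processes (3 and 5).

Per-cluster contributions come from a per-profile NNLS refit on the
extracted signatures — not from H — so clusters excluded from extraction
can still be decomposed; H is retained for diagnostics. Relative
contributions are the normalized NNLS coefficients; absolute contributions
are relative × profile total (conserving the mutation count);
reconstruction similarity is the cosine between the observed profile and
its refit, with 0.90 as the reliability threshold. Extracted signatures get
stable letter names (SBSA, SBSB, …) in extraction order.

## Simulator

`simulate_patient` draws each clone mutation's channel from the clone's
signature mixture (a multinomial over the 96 channels), places it at a
uniformly chosen genome site whose trinucleotide context matches the
channel (either strand), without site collisions, and outside the toy
centromere. Context-matched placement makes the planted mixture exactly
the sampling distribution of channels — there is no genome-composition
bias term, which keeps ground truth analytic. Depth is Poisson
(`mean_depth` = 80, matching the study design this emulates; gamma-Poisson
overdispersion behind a flag), alt counts are Binomial(depth, VAF), and
controls receive depth but zero alt reads. Decoy variants engineered to
fail exactly one filter rule each (annotated in the truth table) exercise
the cascade; germline-contaminant decoys carry VAF 0.5 in all samples.

The bundled signature catalog is **synthetic**: deterministic stylized
shapes echoing well-known signature supports (clock-like C>T at NpCpG;
APOBEC C>T/C>G at TpC; a flat signature; UV-like C>T at dipyrimidines; two
distinct C>A patterns). It is not the COSMIC reference and real analyses
should load a real COSMIC v3 TSV.

Preset scenarios scale the two published-style patients ~5× down
(patient-1-like: 3 timepoints, 6 clones, 1800 mutations; patient-2-like:
4 timepoints, 5 clones, 1650 mutations), sizes chosen so every clone
remains resolvable at depth 80 while the full pipeline runs in seconds.
The small transient cluster is kept at 40 mutations (rather than a strict
1/5 of its real-scale counterpart) so it stays recoverable at these sizes,
and preset analyses set `keep_small_clusters`.

### What the simulation does and does not show

Passing tests demonstrate correct bookkeeping, identifiable clustering and
extraction under the stated model: diploid heterozygous VAFs, independent
binomial noise, context-matched placement, coherent per-clone mixtures.
Real data violate several of these — copy-number alterations distort the
VAF↔CCF map, purity varies, signatures overlap more than the synthetic
catalog's, and caller artifacts are not independent of context. Recovery
rates measured here are therefore upper bounds, not expectations for real
genomes.

## Numerical choices and edge cases

- Merge ties: the first minimal-distance pair in sorted-id order is merged;
  deterministic but arbitrary.
- K-means splitting of one clone into halves whose centroids sit just above
  `merge_distance` (~2 × binomial SD) is the known failure mode of the
  threshold merge; it appears occasionally at depth 80 and shows up
  honestly as an extra cluster and a reduced ARI.
- NMF identifiability requires the data cone to reach the signature cone's
  extreme rays; mixtures that never approach purity cannot be recovered
  exactly by *any* method, which is why recovery tests include near-pure
  exposure columns (Dirichlet(1) produces them naturally).
- Zero NNLS coefficient vectors (profile orthogonal to all signatures)
  yield relative = 0, similarity = 0, reliable = false rather than an
  error.
- All stage seeds derive from the single run seed via `SeedSequence`.

## Known limitations

No copy-number-aware CCF, no phylogeny reconstruction, no Bayesian clone
deconvolution, no indel/doublet/extended-context signatures, no
transcriptional strand bias. The merge/outlier thresholds replace what was
manual curation in the study design this follows; `manual_map` exists
precisely so curator decisions can be replayed and audited.
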