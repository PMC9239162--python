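# Methods

## Model and procedure

The pipeline treats developmental gene expression as a continuous character
evolving on a known rooted species phylogeny. Its unit of analysis is the
single-copy ortholog cluster (SCOG): one gene per species, all mutually
orthologous. For each cluster and each adjacent pair of developmental stages
(S_t, S_{t+1}) the log2 fold change X_t = log2 E_{t+1} − log2 E_t is one
character; a six-stage design yields five characters per cluster. Fold
changes rather than absolute RPKM are used because library composition and
annotation differences make absolute expression incomparable across species,
while stage-to-stage ratios are.

**Brownian motion.** Each character evolves independently by BM: the change
along a branch of length ℓ is Normal(0, σ²ℓ). Tip values x then have
covariance σ²V, V_ij = shared root-to-MRCA path length. The ML root state is
the GLS estimate ŷ = (1ᵀV⁻¹1)⁻¹ 1ᵀV⁻¹x — a convex combination of the tips,
so always inside their range — and the ML states of all internal nodes
jointly minimize Σ_edges (x_parent − x_child)²/ℓ with tips fixed. Both are
computed by two-pass Gaussian message passing (pruning up, marginalizing
down), linear in tree size and vectorized across characters; the test suite
checks them against an independently constructed dense GLS solve and a
sparse Laplacian solve to 1e-8. The BM rate is estimated per character from
standardized independent contrasts with the ML (1/n) normalization; it
affects only the reported root variance, never the point estimates. A
uniform rescaling of all branch lengths leaves both the point estimates and
the ML-rate-based root variance unchanged (the geometry factor and the rate
scale cancel).

Characters are reconstructed independently (no cross-transition or
cross-gene covariance). This matches the per-transition input and keeps the
estimator linear; correlated-character models are out of scope.

**Fold-change differential (FCD).** For a focal species with fold changes
X_t and a chosen ancestral node with reconstructed fold changes Y_t,
FCD = max_t (X_t − Y_t); the transition achieving the max is reported
(first index on ties) and clusters are ranked by FCD descending, ties broken
lexically by cluster id. The default ancestral node is the root (the MRCA of
all species); any internal node can be addressed by name or as
`MRCA:leafA,leafB` — unnamed internal nodes receive deterministic post-order
names N1..Nk at parse time. FCD is computed and ranked on the log2 scale;
ranked output also prints the linear equivalent 2^FCD. A configuration
switch (`fcd_scale: linear_difference`) instead differences the linear fold
changes 2^X_t − 2^Y_t; the ranking question is monotone in either choice for
a single transition, but the max across transitions can differ, so the
choice is exposed rather than hidden.

**Activity filter (zRPKM).** Per species and stage, the log2 density of
positive RPKM values is fitted by a Gaussian KDE (Silverman bandwidth); the
mode μ is located on a 512-point grid spanning the data range ± 3
bandwidths (ties take the smallest μ). With U the mean of log2 values above
μ, the half-Gaussian scale is σ = (U − μ)√(π/2), and z = (log2 RPKM − μ)/σ.
Zeros are excluded from the fit — log2(0) is undefined — but re-enter
activity calls as a −∞ sentinel, so an all-zero gene is always inactive.
A gene is active when its mean z across stages is ≥ −3 (boundary
inclusive); an alternative per-stage rule (inactive only if *every* stage is
below the threshold) is exposed as an option because both readings of the
activity criterion occur in practice. A cluster is excluded when one or more
members are inactive. The fit requires ≥ 50 positive values and rejects
degenerate (constant) columns.

**Expression estimates from counts.** When raw counts with replicates are
supplied, per-stage expression is the ML point estimate under
count[g,r] ~ Poisson(a_g·b_r) with Σb_r fixed to the replicate count —
closed form: a_g = rowsum/Σb, b_r = colsum/total·R, the
iterative-proportional-fitting fixed point whose fitted means reproduce the
count margins exactly. A full hierarchical (Bayesian) expression model would
add credible intervals the downstream math never consumes; the pipeline uses
point estimates throughout, so the closed-form estimator is the design
choice. RPKM = count/(length_kb · mapped_reads_millions).

**Divergence.** Per cluster, each species' stage profile is normalized to
sum to 1 (a point on the 5-simplex; requires a positive total, guaranteed
after the activity filter) and divergence is the mean Euclidean distance
over all C(k,2) species pairs — in [0, √2]. Clusters with ≥ 2
domain-annotated members (configurable `functional_min_members`; wordings of
the classification rule differ between "at least two genes" and "more than
two species", so the threshold is explicit) are "functional", the rest
"hypothetical". The two divergence distributions are compared by a
two-sided Mann-Whitney U (exact null when n·m ≤ 1e5 and tie-free, otherwise
normal approximation with continuity correction); sidedness is two-sided by
default since a directional claim should not be baked into the test. Both a
pooled comparison and per-focal-species comparisons (distances restricted to
pairs involving that species) are emitted, since either construction is
defensible.

**Phylostratigraphy.** A gene's age is the oldest stratum of an ordered
taxon hierarchy containing at least one taxon with a detectable homolog;
absences at intermediate strata (losses) never rejuvenate a gene. Genes with
no hits outside the focal species fall into the youngest (orphan) stratum if
the hierarchy provides one, else an "others" bucket. Homology search itself
is upstream: the input is a precomputed presence/absence matrix.

## Synthetic data generator

The generator emulates the study design end to end: a rooted ultrametric
bifurcating tree (coalescent-style random merges, default 5 species, depth
1.0), root fold changes ~ Normal(0, 1) per character, BM evolution at
σ² = 1 log2²/unit depth, stage-0 log2 expression ~ Normal(4, 2²) shared
across species, later stages by accumulating each species' fold changes.
Defaults: 2,000 clusters; 25 planted genes receiving a +4 log2 shift at the
S0→S1 transition on the focal terminal branch (the first leaf unless
configured); 2% silent genes with RPKM ~ Uniform(0, 0.05) everywhere
(exercising the zero/sentinel path); 10% "hypothetical" genes carrying no
domain flags, evolving at `rate_multiplier` × the base rate — 1 by default,
so the class contrast is planted only when asked for (e.g. 4× for
divergence experiments); gene lengths ~ LogNormal(log 1500, 0.4²) bp;
library size 10⁷; counts Poisson(RPKM·length_kb·lib_millions) mapped back
to observed RPKM (a negative-binomial dispersion knob exists, default off —
the downstream math consumes point values and replicate pooling was the
design point). Everything is deterministic given the seed, and a truth
object records planted flags, class labels and the true fold-change vectors
at every node.

What it does *not* emulate: transcript-length biases shared across stages,
composition (TMM-style) effects, correlated expression between genes,
annotation errors in the ortholog map, and non-ultrametric trees (the
estimators do not assume ultrametricity; only the generator's trees are).
Passing tests therefore demonstrate correctness of the estimators and the
pipeline logic under the stated generative model, not robustness to every
artifact of real RNA-seq.

Typical behavior under the defaults: the activity filter retains ~90% of
clusters (the planted silent 2% plus genes whose BM trajectories drift to
very low expression — the per-species inactive fraction lands in the same
8–14% range seen in real perithecium transcriptomes), and planted-shift
recovery puts ≈ 20–22 of the 25 planted genes in the top 50 with median
planted rank well under 50. Recovery depends on the simulated topology:
shifts on a long outgroup branch leak more into the root estimate.

## Numerical choices and edge cases

- Tabular I/O is strict TSV (UTF-8, "." decimal); readers reject rather
  than coerce, and round-trips of canonical files are byte-identical.
- Zero-length branches are floored to ε = 1e-8 (logged); negative lengths
  are errors. Missing branch lengths are an error by default.
- Pseudocount for fold changes: 1.0 RPKM. Post-filter genes are active, so
  it only guards rare stage-level zeros; it does shrink fold changes of
  lowly expressed genes toward 0, which is intentional noise suppression.
- FCD ties across transitions: first transition wins; ranking ties: smaller
  cluster id wins (stable, documented).
- Mann-Whitney exactness threshold n·m ≤ 1e5; with ties the asymptotic
  path with midranks and tie correction is used regardless of size.
- Simplex validation tolerance 1e-6 on profile sums.
- Degenerate inputs (all-equal expression column, all-zero count matrix,
  empty sample, unknown node name) raise informative errors rather than
  propagating NaNs.

## Problem sizes in tests and the acceptance script

Test simulations use 300–2,000 genes, trees of 3–12 taxa, 1,000-replicate
estimator calibrations and 20-seed null controls — sizes at which every
stochastic check is stable under its fixed seed while the whole suite runs
in well under a minute of compute. The acceptance script re-runs the default
2,000-gene pipeline, a 1,000-gene divergence contrast and the calibrations
at the caller's seed.

## Known limitations

- Single-rate BM per character: no Ornstein–Uhlenbeck stabilizing selection,
  rate shifts, or directional trends; a planted shift is *detected* by the
  FCD ranking, not modeled.
- The root estimate borrows from all tips, so a shifted focal tip inflates
  the ancestor toward itself, attenuating its own FCD (visible in the
  worked example: planted +4 shifts score ≈ 3.3–4.4).
- Per-stage density fitting assumes enough expressed genes (≥ 50) per stage
  for a stable KDE; tiny panels need pooled fitting, not provided.
- The divergence metric compares profile *shapes* only; two genes scaled by
  any constant are identical on the simplex.
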