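# Methods

`wmnet` implements a graph-theoretical group analysis of weighted
white-matter brain networks, together with a synthetic cohort
generator that lets every stage be exercised and calibrated without
imaging data.

## The analysis model

**Input.** One symmetric non-negative N x N matrix per subject
(connection probabilities from probabilistic tractography in the
intended application; N = 90 AAL regions by default), plus a phenotype
table (group, MBEA and lexical-tone scores in percent, age, sex, IQ,
brain size).

**Thresholding.** A network at sparsity S keeps the
k = rint(S * N(N-1)/2) strongest edges (round-half-to-even; weight
ties broken by lexicographic node-pair order, so thresholding is
deterministic). Weighted mode keeps the original weights; binary mode
sets them to 1. Analyses sweep an inclusive grid, by default 0.09 to
0.27 in steps of 0.02 (ten sparsities). The grid minimum acts as a
gate: a subject with an isolated node (or a disconnected network)
there is excluded with a logged reason. Because thresholds are
nested, validity at the minimum implies validity along the grid.

**Graph metrics.** Edge length is the reciprocal of weight. Per
thresholded network we compute:

- Cp — mean clustering coefficient. Weighted networks use the Onnela
  geometric-mean triangle formula on weights rescaled by the network
  maximum; it reduces exactly to the binary 2t/k(k-1) form on 0/1
  weights and is invariant under uniform weight rescaling. The
  alternative (Barrat) form can be recomputed downstream since raw
  matrices are preserved; the choice is recorded in the run manifest.
- Lp — mean shortest-path distance over all ordered pairs, exact
  Dijkstra/Floyd-Warshall on the 1/w lengths. Disconnected networks
  raise an error rather than silently switching to harmonic means;
  local and global efficiency are deliberately not offered as global
  summaries.
- Nodal strength (sum of incident weights), nodal efficiency (mean
  inverse distance to all other nodes, unreachable pairs contributing
  zero), and nodal betweenness (Brandes, fractional credit for
  degenerate shortest paths, normalized by (N-1)(N-2)/2).

**Null normalization.** gamma = Cp/C_random and lambda = Lp/L_random,
where C_random, L_random are means over an ensemble (default 1000) of
surrogates built by Maslov-Sneppen double-edge swaps (default 10 x
edge-count successful swaps) followed by a random permutation of the
real network's weight multiset onto the rewired topology. Each
surrogate preserves the degree sequence and the weight multiset
exactly; disconnected surrogates are regenerated. A network is called
small-world when gamma >= 1.5 and lambda is within 1 +/- 0.5 (both
configurable and echoed next to the verdict). Ensemble seeds derive
from SHA-256 of (run seed, subject id, sparsity), so results are
independent of subject ordering and bit-reproducible.

**AUC.** Each metric curve is integrated over the grid by the
trapezoidal rule on the actual spacing (units: metric x sparsity
fraction). Sparsities are fractions, not percent; with a uniform grid
any affine variant of the integral rescales all subjects alike and
leaves group inference unchanged.

**Group inference.** The statistic is the difference of group means
(case minus control) of the AUC. Two-tailed permutation p-values use
label shuffling with the add-one estimator
p = (1 + #{|perm| >= |obs|})/(n_perm + 1) (default n_perm = 10,000),
so p is never zero and has resolution 1/(n_perm + 1). The four global
metrics (Cp, Lp, gamma, lambda) are tested individually without
family correction; each nodal metric forms an N-node family corrected
by Benjamini-Hochberg FDR at alpha = 0.05, with one shared permutation
sequence across nodes to preserve their dependence. Demographics use
the field-standard tests (t for age/IQ/brain size, Pearson chi-square
for sex, Mann-Whitney for the bounded behavioural scores).

**Hubs.** Per group, a node is a hub when its across-subject mean
strength AUC exceeds the across-node mean by more than one across-node
sample SD (ddof = 1, strict inequality). The SD is taken across nodes
of the group-mean profile, not pooled across subjects. The
"normalized AUC" column (division by the group maximum) is display
only.

**Brain-behaviour correlations.** Spearman rank correlations between
the tone score and the lambda AUC (all subjects and within each
group) and the strength AUC of each FDR-significant node, plus
rank-based partial correlations (rank-transform, least-squares
residualization on the covariate, t reference with n - 3 df) both
ways between tone and MBEA.

## The synthetic cohort generator

The generator emulates the statistical shape of a two-group
tractography cohort; it does not emulate brain geometry beyond a 1-D
ring surrogate, tract anatomy, or the unknown real-data weight
distribution (log-normal is an assumption, not a claim about any
study's data).

Per subject: a ring lattice of N nodes with k neighbours (k set by the
raw-sparsity target, default 0.35 > the 0.27 grid maximum) carries
log-normal weights decaying with ring distance (decay scale 4 ring
steps, sigma 0.4), so thresholding retains mostly short-range edges
and the gate at S = 0.09 passes; a fraction beta = 0.10 of edges is
Watts-Strogatz-rewired into long-range shortcuts that keep their
strong weights, which is what holds lambda near 1 while clustering
stays high (gamma >> 1). Per-edge multiplicative log-normal subject
noise (sigma 0.10) individualizes subjects. Subjects are redrawn
(continuing the same stream) in the rare case the gate fails; below
roughly 30 nodes the 9% gate implies mean degree ~2 and generation
becomes unreliable, so scaled runs here use 36 nodes.

Planted case-group effects, each designed to move one report quantity
with minimal leakage into the others:

- **lambda increase** (`delta_lambda`, default 0.5): that fraction of
  the shortcuts is relocated back to local positions, keeping
  weights. Fewer strong long-range links lengthen shortest paths in
  the real network but not in its rewired surrogates, raising lambda.
- **Cp decrease** (`delta_cp`, default 0.30): the top ~0.5% of weights
  is boosted by (1 + delta_cp) and the subject total restored. Rank
  order is unchanged (identical thresholded topologies and binary
  networks); the inflated network maximum suppresses every
  max-rescaled Onnela triangle term, lowering weighted Cp by roughly
  1/(1 + delta_cp). Because surrogates share the weight multiset,
  lambda and gamma are essentially unaffected. An earlier design
  (global log-weight dispersion stretch) was rejected because it
  systematically inflated retained strength at every node.
- **nodal strength increase** (default x1.5 at `Parietal_Inf_R`):
  incident weights of the target node are multiplied, and each
  neighbour's remaining edges are shrunk so neighbour strength totals
  are unchanged — without the compensation the target's fixed ring
  neighbours inherit a spurious group effect. This effect is
  weight-borne: in binary mode it survives only through edge
  retention and is strongly attenuated.

A deliberately accepted divergence: the lambda effect is topological,
so unlike the nodal and Cp effects it remains visible under
binary-mode analysis.

Behavioural scores use the cohort means/SDs (MBEA 88.0 +/- 6.0 vs
64.1 +/- 5.2 with case scores truncated below the 71.7 diagnostic
cutoff; tone 97.5 +/- 2.9 vs 86.1 +/- 14.7, clipped to [0, 100]).
The tone score is coupled to each subject's lambda AUC through a
Gaussian copula on pooled normal scores. The latent correlation is
calibrated by an internal common-random-numbers bisection so that the
*pooled* Spearman correlation matches the target (default -0.3)
despite the per-group locations/scales and the ceiling ties; the
naive latent value under-delivers by ~0.04 through clipping. The
calibration assumes lambda exchangeable across groups; with planted
lambda effects the realized pooled correlation gains a small
between-group component. Table-consistency note: the source cohort
table prints a 10/13 male/female split against a control n of 24; the
generator uses the implied male fraction rounded to the group size.

Effect-size defaults were calibrated once, by simulation, to the
separations a detectably abnormal cohort requires at n = 24 vs 31
(lambda d ~ +2, Cp d ~ -1.3, target-node strength d ~ +2.5, Lp no
difference), satisfying the generator's parameter-recovery contract
(>= 80% power for all three effects); they were not tuned to any
empirical dataset.

## Numerical and scaling choices

- Dense matrices throughout (N <~ 1100); the Maslov-Sneppen swap loop
  is a numba kernel with a pure-Python fallback.
- Node indices are 0-based internally; node labels (AAL names by
  default) are used in all outputs.
- Statistical-calibration runs are scaled down so they complete in
  minutes on one CPU: 36-node cohorts, the three-point grid
  {0.09, 0.18, 0.27}, 4-8 surrogates per ensemble, and 200-3000
  permutations depending on the family tested. The permutation test's
  exchangeability argument — hence its validity — is independent of
  these sizes; surrogate-ensemble Monte-Carlo noise only adds
  exchangeable per-subject noise. The acceptance script's type-I-error
  target uses 500 replicate null cohorts at these sizes (theoretical
  rejection rate at alpha = 0.05 with 200 permutations:
  10/201 = 0.0497).
- The nodal-FDR family needs n_perm well above N/alpha for the BH
  threshold to be reachable at all (p-floor 1/(n_perm + 1)); family
  tests here use 1500-3000 permutations.

## Known limitations

- Surrogate connectivity is enforced by regeneration, which for very
  dense or very sparse degree sequences could bias the ensemble
  slightly toward connected topologies; at the grid densities used
  here regeneration is rare.
- The generator's ring geometry gives all nodes statistically
  identical roles except the planted target, so hub sets on synthetic
  cohorts reflect sampling noise plus the planted node rather than an
  anatomical hub architecture; hub detection is therefore validated
  against its defining rule, not against a known hub set.
- Passing tests on synthetic cohorts demonstrates the statistical
  machinery (calibration, power, FDR control, copula coupling), not
  fidelity to any real tractography cohort.
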