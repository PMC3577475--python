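# Methods

## The problem

At a codon site under negative selection, nonsynonymous substitutions that
would disturb a functionally important physicochemical property (volume,
hydropathy, charge, ...) are removed; at a site under diversifying
selection they are favored. Comparing, per site and property, the *observed*
mean property distance of the substitutions that actually happened against
the *expected* mean distance under neutral single-nucleotide mutation turns
this into a regression problem: a slope near 1 is neutral, well below 1 is
conservation, well above 1 is radical change. Because amino-acid properties
are heavily inter-correlated, `nirmreg` fits all properties jointly and
lets the prior cluster properties with equivalent effects, and — within
each property cluster — cluster sites with similar slopes.

## Distances

For site `i` and property `j` with per-amino-acid scores `s_j`:

* **Observed** `y_ij`: mean of `|s_j(aa_parent) - s_j(aa_child)|` over all
  parent–child node pairs of the rooted phylogeny whose codons at site `i`
  encode different amino acids. Each such pair counts as one substitution
  event regardless of how many nucleotides differ, and `n_i` is the event
  count. Sites with `n_i = 0` are dropped.
* **Expected** `x_ij`: with `F_k` the tip-sequence frequency of codon `k`
  at the site, `N_k` its number of nonsynonymous single-nucleotide
  neighbors (stop codons excluded), and `D_kl` the score distance to the
  l-th such neighbor,

      x_ij = sum_k F_k sum_l D_kl / sum_k F_k N_k .

Both are divided by the property's maximum score distance over all 190
unordered amino-acid pairs, so `y*, x* ∈ [0,1]` and one prior scale serves
all properties. Codon columns containing a gap, ambiguity or stop in any
sequence are removed first. Ancestral sequences are expected from an
external model-based reconstruction; the shipped codon-level Fitch
parsimony fallback (deterministic, lexicographic tie-break) exists so the
pipeline and tests are self-contained, and is not equivalent to a
likelihood-based reconstruction.

## Model

    y*_ij ~ N(b_ij x*_ij, s2_ij)        if b_ij  = 0
    y*_ij ~ N(b_ij x*_ij, s2_ij / n_i)  if b_ij != 0

The matrix of `(b_ij, s2_ij)` gets a nested infinite relational model
prior: property columns are clustered by an outer stick-breaking (DP)
process with concentration `rho`; within column cluster `k`, sites are
clustered by an inner process with concentration `gamma_k`; each
(row-cluster, column-cluster) atom carries `(phi, theta2)` from a
spike-and-slab base measure — with probability `lambda` the spike
`phi = 0`, `theta2 ~ InvGamma(a_kappa, b_kappa)`; otherwise
`phi | theta2 ~ N(alpha_k, theta2 / V0)`, `theta2 ~ InvGamma(a_sigma*,
b_sigma*)`. Hyperpriors: `alpha_k ~ N(m_alpha, C_alpha)`,
`rho ~ Ga(a_rho, b_rho)`, `gamma_k ~ Ga(a_gamma, b_gamma)`,
`lambda ~ Beta(a_lambda, b_lambda)`.

**Inverse-gamma convention.** `InvGamma(a, b)` has mean `1/(b(a-1))`
(scipy scale `1/b`). Only this convention makes the default choices
`(2, 100)` and `(2, 4)` imply prior means 0.01 and 0.25, which is how the
defaults are meant.

**Defaults** (the settings used for the sea-urchin/abalone-type real-data
analysis this model family was built for): `m_alpha = 1`, `C_alpha = 0.25`
(neutrality-centered slopes), `a_rho = b_rho = a_gamma = b_gamma = 1`,
`a_lambda = 2, b_lambda = 8` (about 20% of unique coefficients expected to
be exactly 0 a priori), `a_kappa = 2, b_kappa = 100`, `a_sigma* = 2,
b_sigma* = 10`, `V0 = 10`.

## Posterior computation

Both stick-breaking processes are truncated (K columns, L rows per
cluster; `choose_truncation` gives the smallest K whose expected tail mass
`(rho/(1+rho))^(K-1)` is below a tolerance). One Gibbs sweep updates:
column indicators, column sticks, row indicators (for every cluster,
including empty ones), row sticks, the atoms (spike flag with `phi` and
`theta2` integrated out in closed form, then `theta2`, then `phi`),
`lambda`, `alpha_k`, and the concentrations. All categorical updates are
computed in log space with max-subtraction.

Three computational choices matter and were validated by a Geweke-style
joint-distribution test (alternating data imputation with the sweep
preserves prior-predictive moments) plus prior-recovery chains:

1. **Collapsed column moves (default).** The plain configuration update
   evaluates a candidate cluster at whatever row assignment `xi_{.,k}`
   that cluster currently carries; for empty clusters that assignment is a
   prior draw, so moves that would split a wrongly merged pair of property
   groups essentially never occur and the chain can lock into merged
   states. The default update instead integrates the row indicators out of
   the column move — the weight of cluster `k` is `Pi_k` times the ratio of
   inner-mixture marginal likelihoods of the cluster's columns with and
   without the moving column — and the row indicators are redrawn from
   their exact conditional immediately afterwards, which keeps the scheme
   a valid (partially collapsed) Gibbs sampler. The configuration update
   remains available (`collapsed_columns=False`).
2. **Stick-conditional concentration updates.** With explicit stick
   variables the exact conditional of a concentration is
   `Ga(a + K - 1, b - sum log(1 - v_k))`. The popular auxiliary-variable
   mixture-of-gammas refresh conditions only on the number of distinct
   indicators, which is exact for the marginal (urn) representation but
   measurably biased in the truncated labeled sampler; it is kept as
   `sample_concentrations_escobar_west` and verified against its own
   urn-marginal oracle.
3. **Log-space stick complements.** Conditional Beta draws can have second
   parameter far below float resolution (tiny concentration), making
   `1 - v` round to zero and silently truncating `log(1 - v)` at ~ -36
   where its true magnitude is `O(1/rho)`. Sticks are therefore drawn via
   the two-gamma representation with `log(1 - v)` carried exactly in log
   space; without this the small-concentration regime of the prior is
   unreachable and prior-recovery fails.

Initialization: partitions uniform at random, everything else from the
prior hierarchy; default two chains with seeds derived from the run seed,
pooled after burn-in (draws are tagged by chain). No relabeling is
attempted; every reported summary is label-invariant (pairwise
co-clustering probabilities, per-cell posterior means/quantiles of
`b_ij`, spike probabilities). Convergence is assessed from the exported
trace tables (`rho`, `lambda`, `alpha_k`, occupied-cluster count), as is
conventional for this model class. Atom variances are guarded by a trap
floor of 1e-30 that raises instead of clamping.

## Synthetic data

**Block scenario** (the first simulation study): J=16 properties in four
column clusters (5/5/3/3), I=40 sites with nested row partitions
(3/2/2/1 clusters; eight blocks), block coefficients drawn from
N(1, 0.25), `y* = phi x* + N(0, 0.001)`, `x*` uniform on (0.2, 0.9) when
no real expected-distance matrix is supplied, `n_i = 1`. The fits for this
scenario use variance priors centered on the generating truth —
`theta2 ~ InvGamma(100, 10)` (mean 0.001) and `V0 = 0.004` so the slab
coefficient variance `theta2/V0` has prior mean 0.25
(`sim1_hyperpriors()`); centering these priors on the truth is part of the
study design, and with diffuse variance priors the merged-cluster states
are insufficiently penalized and recovery degrades.

**Sequence scenario** (the second study): 20 sequences of 90 codons
evolved down a balanced tree with uniform branch length 0.1 under a
GY94-style rate matrix (single-nucleotide neighbor moves,
transition/transversion ratio kappa=2, uniform codon frequencies, unit
mean rate). Sites 1–30 are neutral; sites 31–60 multiply each
nonsynonymous rate by `exp(-3 d/max_d)` for molecular volume (conserving
regime); sites 61–90 by `exp(+3 d/max_d)` for hydropathy (radicalizing
regime); rows are renormalized to the baseline leaving rate. The tree,
branch length, tilt form and bias strength 3 are this package's concrete
realization of a qualitatively described design and are recorded in run
manifests. The pipeline then reconstructs ancestors by parsimony and
builds the distance dataset for h, M_v, p, pH_i, V0.

What these generators do **not** emulate: alignment error, ancestral-state
uncertainty (parsimony vs model-based reconstruction), codon usage bias
(equilibrium frequencies are uniform), rate variation within regions, and
indels. Passing tests therefore demonstrate correct inference under the
model's own assumptions, not robustness to real-data violations of them.

### A note on the five-property sequence study

With the published score sets, the pairwise-distance correlation between
hydropathy (KYTJ820101) and Grantham polarity (GRAR740102) is ~0.6–0.7,
and the fitted model co-clusters {h, p} with probability ~1 while
isolating pH_i — both stable across seeds. Partial specific volume
(COHE430101), however, has distance correlation ~0.03 with Grantham
volume (GRAR740103) and ~0.4–0.5 with hydropathy, so a volume-conserving
substitution regime leaves V0 essentially untouched and its column
behaves like a weaker copy of h/p. The model consequently and correctly
places V0 in its own cluster (stable modal partition
{h,p} | {M_v} | {pH_i} | {V0}); an expectation that {M_v, V0} co-cluster
has no generative support under these scores.

## Shipped property table

`data/properties.tsv` carries 15 accession-backed properties (hydropathy,
volume, surrounding hydrophobicity, two polarities, helix/sheet/turn
tendencies, bulkiness, isoelectric point, molecular weight, partial
specific volume, polar requirement, refractive index, composition). Rows
of the 32-property working set whose published score source could not be
verified offline are not shipped; users supply them via the same TSV
schema. All distance computations are invariant to affine rescaling of a
property's scores.

## Classification thresholds

Site labels use posterior-mean cutoffs: strongly conserved below 0.4 (the
only cutoff anchored in the reference analyses), conserved below 0.8,
radical above 1.2. The latter two are package defaults exposed in
configuration and recorded in output metadata; they are reporting
conveniences, not model components.

## Problem sizes

The shipped validation suite runs the block study at J=16, I=40 with
K=L=15 and 3000 iterations (1000 burn-in) and the sequence study at 20
sequences x 90 codons with K=L=10 and the same chain length; the sampler
is vectorized over sites and properties, and these runs complete in about
a minute each. Larger K, L and longer chains (the 25–35 / 15000–20000
range used for real data) scale linearly.

## Known limitations

* Exchangeability across sites ignores spatial/structural dependence.
* One substitution event per branch-site codon change; multi-nucleotide
  codon differences are not decomposed into paths.
* Codon frequencies `F_k` use tip sequences only (configurable upstream of
  the expected-distance call, but ancestral nodes are excluded by
  default).
* The parsimony fallback underestimates change on long branches, biasing
  observed distances downward relative to model-based reconstruction.
* Label-invariant summaries cannot express "cluster 3's" identity across
  runs; anchor properties are used instead.
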