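# Methods

## Timescale and identifiers

Domain ages live on the relative *nd* scale, a [0, 1] ordering of time
events derived from a phylogenomic chronology of SCOP fold families (0 =
origin of proteins, 1 = present). A linear molecular clock converts nd to
geological time: Gy = intercept + slope · nd. The default clock is the
two-anchor line nd = 0 → 3.8 Gy, nd = 1 → 0 Gy; `fit_clock` replaces it by
an ordinary least-squares line through user calibration points and attaches
Pearson and Spearman statistics. Loop prototypes follow the
`METHOD.BRACING.LEN.CLASS.SUBCLASS` grammar with ten admissible bracing
codes (HH, HE, EH, HG, GH, GG, EG, GE, BN, BK); domains follow the SCOP
concise classification string `class.fold.superfamily.family`. Both parsers
are strict and round-trip exactly.

Input tables are tab-separated with a mandatory header and `#` comments.
The mapping reader drops rows failing the strict e-value filter
(`evalue < evalue_max`, matching the < 0.001 convention for reliable
loop–domain associations) and collapses duplicate (loop, domain) pairs to
the minimum e-value, which is conservative with respect to that filter.

## Age transfer and classification

Each loop inherits its age from its linked domains under two schemes:
scheme 1 takes the minimum linked age (the age of the first structural
scaffold); scheme 2 takes the second-smallest age in the multiset of
linked ages (the age at which the loop is first transferred between
scaffolds). Ties between the two smallest ages make the schemes agree.
Because a donor loop cannot postdate its acceptor and no older donor can
exist at the origin, every loop whose minimum linked age equals the global
minimum of the chronology receives its scheme-1 age under scheme 2 as
well. We apply this exception to *all* loops tied at the global minimum
rather than to a single named loop: the justification (absence of any
older donor domain) applies equally to each of them.

Classification is structural: NM ⇔ exactly one linked domain, M′ ⇔ two or
more linked domains all of one age (exact nd equality — events are
discrete chronology values), M ⇔ two or more distinct ages. The domain
Venn groups treat M and M′ both as "modular" when deciding whether a
domain maps to only-modular, only-non-modular or both kinds of loops;
chronology domains without any mapping form the unmapped group.

## Networks

The EF network is the undirected, unweighted bipartite graph of M-loop
records (edges are presence/absence; hit counts never weight them). The
one-mode projections connect two same-side nodes iff they share at least
one bipartite partner, with arc weight equal to the number of shared
partners and direction old → young; contemporaneous pairs are oriented by
a seeded coin flip so runs are reproducible — the seed is an explicit
parameter everywhere. A time-event series contains one cumulative induced
subgraph per distinct node age of the network at hand, so projections can
have fewer events than their parent bipartite graph. Hub subnetworks keep
nodes whose combined weighted degree is strictly above a percentile of all
nodes (99 by default) and drop arcs between surviving contemporaneous
nodes; a percentile of 0 or below is interpreted as "keep every node",
resolving the boundary where "strictly above the 0th percentile" would
otherwise exclude the minimum-degree nodes.

Whole-network descriptors use the standard closed forms: bipartite density
E/(n_loops · n_domains), directed one-mode density arcs/(n(n−1)), and node
average degree 2E/n (E/n per direction for directed graphs).

## Power-law statistics

Degree distributions are assessed on whole distributions: `xmin` defaults
to the smallest positive degree. Two complementary fits are reported per
degree vector:

- γ and R² from the linear regression of log10 P(k) on log10 k over the
  empirical distribution;
- α from the discrete maximum-likelihood fit of P(X = x) ∝ x^−α with
  Hurwitz-zeta normalization, maximized by bounded scalar optimization of
  the log-likelihood −n·log ζ(α, xmin) − α·Σ log x over α ∈ (1.001, 12).

Goodness of fit is the KS statistic between the empirical CDF and the
fitted discrete CDF over x ≥ xmin, evaluated on both sides of each step.
Its p-value is a semi-parametric bootstrap (default 100 replicates):
samples of the observed size are drawn from the fitted model, refitted,
and their KS statistics compared with the observed one; the null is that
the data are power-law, so p ≥ 0.05 supports the fit. Sampling is exact
inverse-CDF: the head of the support is tabulated until the residual tail
mass falls below 1e−6 and rare draws beyond the table are resolved by
bisection on the zeta survival function. Degree vectors with fewer than 10
nonzero entries or all entries equal are rejected as degenerate.

Note that a whole-distribution MLE on a finite preferential-attachment
network is dominated by the head of the distribution (half the nodes are
leaves), so it sits well below the asymptotic tail exponent of 3; tail
fits (xmin ≥ 3) approach 3 from below at n = 2000. Tests pin both
behaviours.

## Reference models

`generate_reference_network` grows graphs node by node with recorded birth
ages. `barabasi` attaches each new node to distinct existing nodes with
probability proportional to current degree (uniform at the degree-0
start); with one edge per node the result is a tree and its average
clustering coefficient is exactly 0, the scale-free control. `barabasi_age`
multiplies the degree kernel by the linear age bonus (t − birth + 1)/t —
the simplest monotone "age and degree" kernel; it is isolated behind the
`kind` switch so other kernels can be added without touching callers.

## Modularity

Six indices are computed per event on the weighted undirected
simplification of the snapshot (opposite arcs merge by summing weights):

- **NG_age / NG_vos** — Newman–Girvan modularity
  Q = (1/2m) Σ_ij (A_ij − k_i k_j/2m) δ(c_i, c_j), with the δ applied to
  the whole bracket (the bounded, standard form), partitioned by time
  event or by detected communities;
- **VQ** — the community quality Σ_c (e_cc − a_c²) of a seeded
  modularity-maximizing clustering (Louvain) standing in for the VOS
  layout clustering, whose exact parameters are not reproducible;
- **FGC** — the quality of the fast-greedy agglomerative partition;
- **C** — the average clustering coefficient over all nodes of the
  simplified graph; nodes of degree < 2 contribute 0 (kept in the average
  so C stays defined on sparse events); bipartite snapshots have no
  triangles and C is reported absent (NaN);
- **C-ratio** — detected communities per non-isolated node.

Pairwise modularity matrices have entries (A_ij − k_i k_j/2m) · M_nd with
M_nd = |log10(|NG_age|)| at that event; when NG_age is 0 the scale is
undefined and falls back to 1 with a warning. The unscaled matrix sums to
zero identically (Σ A = Σ kk/2m = 2m), which the tests verify to 1e−9.
Matrices are hierarchically clustered with Ward's minimum-variance method
(squared-Euclidean dissimilarities between cluster means); dendrograms
export to Newick.

Connectivity accumulation coarse-grains the [0, 1] timeline into equal
age bins (10 by default; age 1.0 falls in the last bin) and tallies each
node's in- and out-arcs by the partner's bin; totals equal the unweighted
degree vectors, and nodes above the 99th combined-degree percentile are
flagged for labeling.

## Waterfall layout and exports

y is the dense age rank (older at the top; equal ages share y). x comes
from a deterministic Kamada-Kawai stress minimization run only within each
community (circularly initialized for determinism), communities tiled left
to right with unit gaps — the qualitative "spread within clusters" is what
matters downstream, not any particular layout engine's energies. Node
glyph sizes are (weighted degree + 10) · scale, the +10 shift keeping
0-degree entities visible; for directed networks the width tracks the
weighted outdegree (donor behaviour) and the height the weighted indegree
(acceptor behaviour). Arc glyphs carry the weight and the destination
node's age as the colour key; palettes are left to plotting code.

Pajek exports write 1-based vertices with x y z coordinates — z carries
the node age so the .net file alone round-trips (nodes, arcs, weights,
ages); the .clu partition holds the 1-based age-event class per node.
GraphML carries all attributes natively.

## Loop stitching

Intermediates are cumulative: at each distinct age, all loops with age ≤
event are concatenated in positional (N → C) order, labels joined with
pipes; age ties enter together. Only the loop regions themselves are
stitched — intervening linker residues are excluded, matching the
pipe-notation convention for loop sequences. Replacement variants
substitute one slot and are kept only if both labels and span starts stay
strictly ascending. Sequences are validated against the 20-letter amino
acid alphabet and written as multi-FASTA with the loop sequence and nd age
in each header.

## Synthetic data

The generator emulates a growing recruitment process, not any real
dataset. Domains are spread evenly over `n_events` discrete events (ages
are event ranks normalized to [0, 1]); every domain births one loop whose
planted label is drawn independently (NM with probability `nm_fraction`,
default 0.55 — the regime where non-modular prototypes form the majority
of loops, as in real loop–domain censuses; M′ at `mprime_rate`, default
0.01, matching the rarity of contemporaneous-modular loops; M otherwise).
M′ loops pair with a second domain of the same event. Each domain after
the first event additionally reuses one strictly older modular loop with
probability 1 − `nm_fraction`, chosen with probability proportional to
current degree^`attach_exponent` (default 1, the linear preferential
attachment that yields MLE exponents in the 2–3.5 range at a few thousand
domains) and biased toward its own planted community block with odds
p_in : p_out. A final pass attaches any modular loop still confined to one
age to a domain of a different age, so planted labels and the structural
M/M′/NM definition coincide exactly and the recovered NM fraction is an
unbiased binomial proportion around `nm_fraction`. Reuse only ever targets
domains younger than the loop's birth event, so the donor/acceptor age
ordering holds by construction.

What the generator does not emulate: the many-to-many multiplicities of
real mapping tables (each synthetic domain recruits at most two loops per
event), e-value noise, the empirical event spacing of the fold-family
chronology, and the specific wave structure of real recruitment. Passing
tests therefore demonstrate correctness of the machinery and statistical
calibration under a controlled model, not agreement with any particular
biological dataset — dataset-dependent headline numbers (prototype counts,
community counts, γ trajectories) are out of reach without the original
mapping data and are deliberately not asserted anywhere.

## Pipeline sizes and determinism

The default pipeline configuration analyzes a 300-domain, 50-event
synthetic dataset with 20 bootstrap replicates per power-law fit — sizes
chosen so a full run completes in about a minute on one core while every
per-event statistic is still exercised; tests use 100-domain runs. A
single global seed fans out to per-stage seeds by fixed offsets (synth +0,
projection +1, stats +2, layout +3, modulo 2³¹), so stages are
independently reproducible and two runs with the same configuration are
bit-identical (the manifest records no timestamps).

## Known limitations

- The VOS clustering of the original Pajek toolchain is approximated by
  any seeded modularity-maximizing clustering; community counts are
  comparable only qualitatively.
- The bootstrap p-value's resolution is 1/`bootstrap_reps`; increase the
  replicate count for publication-grade p-values.
- `fit_power_law` fits whole distributions by default; users probing tail
  behaviour should pass an explicit `xmin`.
- Pajek exports are structurally, not pixel-wise, comparable to layouts
  produced by interactive tools.
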