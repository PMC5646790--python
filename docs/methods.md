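# Methods

## Model and assumptions

The detector treats a protein complex as a *core-attachment* structure:
a stable, densely interconnected core plus peripheral proteins that
associate transiently. Two signals identify cores. Topologically, core
edges close many triangles, captured by the edge clustering coefficient

    ECC_ij = Z_ij / min(k_i − 1, k_j − 1),

where `Z_ij` is the number of common neighbors of the interacting
proteins i and j and the denominator is the largest number of triangles
the edge could participate in given its endpoint degrees. `ECC` lies in
[0, 1]; when an endpoint has degree 1 the denominator is 0 and `ECC` is
defined as 0, since such an edge can close no triangle. Temporally, core
proteins stay active longer, captured by the active time span `AT`
normalized to [0, 1]. The two are combined into a node weight

    W_v = α · Σ_{u ∈ N(v)} ECC_vu + (1 − α) · AT(v),

which is deliberately *not* normalized by degree: with the default
β = 0.55, a degree-1 node (ECC sum 0, weight ≤ 1 − α = 0.4) can never
seed a core, consistent with cores being highly connected. The raw scale
of `W_v` is an open modeling choice; β is exposed for sensitivity
analysis.

Attachments are selected by adhesion — the summed ECC on the edges
joining a candidate to the core. The absolute threshold reading
(`Adh ≥ γ`, default) is used: since every ECC ≤ 1, γ = 1.4 > 1 forces an
attachment to be strongly tied to at least two core members, which
matches the core-attachment intent. A `relative` mode
(`Adh ≥ γ · mean candidate adhesion`) is provided because the comparison
convention is genuinely open.

## Dynamic network construction

Per-gene activity uses the three-sigma rule

    Thresh(g) = μ(g) + k · σ(g) · w(g),    w(g) = 1 / (1 + σ²(g)),

with k = 3, σ the *sample* standard deviation (ddof = 1, hence the
requirement of ≥ 2 time points), and strict `>` comparison so a constant
profile is never active. The damping factor w(g) is the standard
construction in this line of work: it relaxes the threshold toward the
mean for noisy profiles. Both k and the damping are configurable
(`--sigma-k`, `--no-sigma-weighting`) because the exact variant differs
between published uses.

`AT` defaults to **count** mode (number of active time points / T).
Periodic expression over several metabolic cycles produces disjoint
active runs, for which the envelope reading (last − first + 1, provided
as **span** mode) conflates inactivity between cycles with activity;
both modes agree on a single contiguous run (active at points 6–8 with
inactivation at 9 gives 3 either way). `AT` is a global per-protein
quantity computed over all T points after intersecting the network with
the expression matrix; `ECC` and `W_v` are per-snapshot.

## Detection pipeline and determinism

Per snapshot: compute ECC for every edge, `W_v` for every node, seed a
candidate core `{v} ∪ N(v)` for every v with `W_v > β` (strict),
deduplicate identical cores, discard singletons, then attach candidates
in a single order-independent pass against the core alone. Complexes
below `min_complex_size` (default 3, configurable down to 2; average
real complex sizes are considerably larger) are dropped before pooling.
Pooled complexes are ranked by (summed node weight desc, size desc,
lexicographic member tuple asc) and greedily kept only when their
overlap score `OS = |A∩B|²/(|A||B|)` against every kept complex stays
below 0.8. OS at 0.8 is the package's choice of redundancy measure and
cutoff — the original pseudocode does not name either, and OS is the
only set similarity the method otherwise uses. All orderings are
canonical (sorted), so two runs on identical input produce byte-identical
output. No cross-snapshot merging is attempted; the redundancy filter is
the only deduplication.

## Evaluation

Matching is many-to-many at OS ≥ 0.2: a prediction is a true positive if
it matches *any* reference and a reference is covered if *any*
prediction matches it (no one-to-one assignment — one reference complex
may legitimately be matched by several overlapping predictions).
F-measure is the harmonic mean of Sn and Sp, defined as 0 when TP = 0 to
avoid 0/0. Enrichment of a complex of C proteins sharing k members with
a term of F genes out of N background genes is the hypergeometric upper
tail P(X ≥ k), computed through `scipy.stats.hypergeom.sf` (log-gamma
space) and clamped to [0, 1]; the test suite cross-checks it against
exhaustive subset enumeration for all N ≤ 12. Raw p-values are reported
(no multiple-testing correction, matching the conventional 0.01 cutoff
and p-value bin reporting); N defaults to the annotation map's distinct
gene count and is overridable.

## Synthetic benchmark

The generator emulates the stated world the detector assumes: an
Erdős–Rényi background (200 nodes, edge probability 0.01), 5 planted
complexes with near-clique cores (sizes 3–8, intra-core edge probability
0.9, patched to connectivity) and 1–4 attachments each wired to at least
half the core, and periodic expression — 36 time points in 3 identical
cycles of 12, mirroring the yeast metabolic-cycle design. Expression is
Gaussian baseline noise, Normal(5, 0.5) in arbitrary log-scale units,
plus an activation boost of 6 (12 baseline SDs) inside each complex's
6-point active window in every cycle; core genes span the full window,
attachments a random sub-window. The boost magnitude puts activity
calling in the unambiguous regime — the generator tests the detector,
not the robustness of the three-sigma rule to marginal signal.

What the generator does **not** emulate: scale-free degree structure,
false-positive/-negative interaction noise correlated with expression,
overlapping planted complexes, phase drift between cycles, and probe-
level measurement structure. A green recovery test therefore establishes
that the pipeline correctly implements the model and recovers planted
structure under its own assumptions — not that it would attain any
particular accuracy on real interactome data.

## Numerical choices and degenerate inputs

- Strict inequalities where specified: activity (`>` threshold), core
  seeding (`W_v > β`); attachment and matching use `≥`.
- Empty snapshot → no cores; empty candidate set → no attachments;
  all-inactive expression → zero complexes; empty reference set in
  evaluation → error.
- Ties in the redundancy sweep are broken by size then by the sorted
  member tuple, guaranteeing a deterministic ranking.
- Probe aggregation default is per-time-point maximum (conservative
  activity calling when probes disagree); mean is available.
- Identifiers are upper-cased on input by default, since ORF names
  appear in mixed case across common sources; disable with
  `case_fold=False`.

## Known limitations

- The O(N²)-per-snapshot detector is pure Python/networkx; it is sized
  for desk-scale benchmarks and thousand-node interactomes, not
  proteome-scale graphs at interactive speed.
- Headline accuracies on the real DIP/Krogan interactomes with yeast
  metabolic-cycle expression and the CYC2008 reference are not
  reproduced here: they require external downloads, and the original
  redundancy-filter details are under-specified, so the package's
  guarantees are the property-based and planted-recovery results the
  test suite computes.
- Functional annotation is taken as an already-propagated gene→term
  table; no ontology traversal is performed.
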