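# Methods

## Pipeline overview

`tracenet` builds a mesoscale connectome in three stages: (1) per-experiment
import — hemisphere QC, injection identification, normalization; (2) matrix
compilation — replicate averaging onto an N × 2N bilateral matrix; (3) graph
analysis — degree, path, and comparison metrics on the mirror-expanded
2N-node directed graph. This note records the modeling assumptions,
parameter conventions, and numerical choices behind each stage.

## Import and quality control

An experiment is usable only when one hemisphere wins *all three* injection
criteria: more `is_injection` structures, larger total projection-density
sum (over all entries), and possession of the single highest-density entry.
The criteria are applied conjunctively — a tie on any criterion, or
criteria pointing at different hemispheres, rejects the record with a
reason code per failing criterion (`criterion-a`/`-b`/`-c`,
`no-injection`). We read the density sum and the max-density criterion over
*all* entries rather than injection-flagged ones only: tracer signal is
overwhelmingly concentrated around the injection, so the whole-hemisphere
sums are the more robust discriminators, and they remain defined when
injection polygons are missing.

Raw structures are mapped to node-list nodes by climbing the ontology
ancestor path (self first) and taking the first listed member; the
node list's non-overlap invariant (no listed node is an ancestor of
another) makes this unique. Identity-only mapping is available via
`climb=False` for datasets already expressed on the node list.

When several raw structures land on one node, their measures are combined
by a volume-weighted mean using the ontology structure volumes (densities
are fractions of structure volume, so the volume-weighted mean is the
density of the union); if any contributing structure lacks a volume the
mean falls back to unweighted.

Normalization divides every measure by its value at the injection node,
which by construction is the hemisphere-wide density maximum; values that
still exceed 1 (possible after aggregation) are clipped to 1 with a logged
count rather than rescaled or rejected, preserving the [0, 1] reading of
density. A zero injection-site density rejects the experiment; a zero
injection-site value of a secondary measure only marks that measure's map
unavailable.

`auto_threshold` is Otsu's two-class variance-maximizing threshold over a
256-bin histogram of the *nonzero* map values (zeros are absence of signal,
not low signal); a constant nonzero map returns that constant.
`cross_correlate` is the Pearson coefficient over the union of two maps'
keys with zero fill, returning NaN (not an exception) for fewer than two
keys or zero variance.

## Matrix construction

Rows from experiments sharing an injection node are combined by unweighted
element-wise arithmetic mean — replicates are treated as exchangeable
measurements of the same row; no weighting by injection volume is applied.
Structures absent from a record contribute 0 (the segmentation saw no
signal there), not missing data. The ipsilateral self-entry (exactly 1.0
after normalization) is retained in the matrix; all path algorithms drop
self-loops, while degree sums include the diagonal by default with an
`include_diagonal=False` escape hatch.

Mirror expansion assumes left/right homotopy: measured rows are expressed
ipsi/contra, and the unmeasured hemisphere's out-edges are their mirror
image. Every bilateral path statistic inherits this assumption; it is the
price of running whole-brain path algorithms on data acquired in an
injection-relative frame. Row ipsi/contra normalization makes rows from
left- and right-hemisphere injections commensurable before averaging.

## Graph metrics

- Edge weight w = 1/d + s (additive synapse factor, default) or w = s/d
  (multiplicative). s ≥ 0 is unitless; s adds a fixed per-synapse traversal
  cost. d = 0 means *no edge*, never an infinite-weight edge.
- Shortest paths: Dijkstra; ties on total length (within 1e-9) are broken
  by fewer hops, then lexicographic node sequence, so results are
  deterministic. k-shortest paths use Yen's loopless algorithm with the
  same tie-break ordering applied to the collected candidates.
- Betweenness: Brandes accumulation over all co-minimal weighted shortest
  paths, normalized by (n−1)(n−2) ordered pairs, so a star center scores
  exactly 1.
- Binarization thresholds *densities* (entry survives iff d > t, strict;
  `strict=False` gives ≥). Thresholding inverse weights instead would
  invert the semantics of "weak edge"; the density reading is the one under
  which "keep only edges with density > 0.75" makes sense. The diagonal is
  forced to 0 so binary path measures never use self-loops.
- DOS is the BFS hop count on the binarized support; weighted DOS is the
  hop count of the minimum-weighted-distance path (minimum hops among
  co-minimal paths). Unreachable pairs carry an infinity sentinel, and
  averages are reported over finite entries together with the finite-pair
  count.
- Weighted density multiplies each entry by the Euclidean distance (µm)
  between source and target centroids; contralateral columns mirror the
  target centroid across the mediolateral midline plane (default 5700 µm,
  half the 11400 µm mediolateral extent of the reference volume; both the
  midline and the mirror axis are configurable, since acquisition frames
  differ).
- Relative density (A − B)/(A + B) maps 0/0 to 0 by convention; the
  comparative map flags cells whose source node lacks a row in either
  group (flagging is per source row — group membership is a property of
  the injection, not of individual targets).
- Macro-region condensation averages full blocks *including* zero cells by
  default (a block's mean connectivity should reflect absent links);
  `include_zeros=False` is available. Groupings default to ontology
  ancestors at depth 1, with a CSV override.

## GEXF export

Networks are written as GEXF 1.3 with a purpose-built lxml writer: nodes
and edges are emitted in sorted order and floats with full `repr`
precision, so identical graphs yield byte-identical files and the
export/import round trip is the identity on nodes, edges and weights. Edge
weight carries the projection *density* (not the inverse traversal weight),
matching the visualization convention that thickness shows connection
strength. Undirected files are rejected on import; missing edge weights
default to 1.0 with a warning.

## Synthetic generator

The generator emulates the unionize-record shape of real tracer pipelines:
per-structure, per-hemisphere entries with four measures and an
`is_injection` flag, wrapped in JSON with sex/strain/line/volume metadata.

Ground truth: Bernoulli edge support with
p_ipsi = min(1, 2·ed·b) and p_contra = min(1, 2·ed·(1−b)) for edge density
`ed` (default 0.9) and ipsilateral bias `b` (default 0.85) — the defaults
describe a densely connected, ipsilaterally dominated brain. Nonzero
strengths are lognormal(µ = −2, σ = 1) truncated to [0, 1] by resampling
(mesoscale projection strengths are approximately lognormal); resampling
rather than clipping keeps off-diagonal strengths strictly below 1, so the
injection self-entry is always the unique density maximum. Contralateral
strengths are scaled by `contra_strength` (default 0.5) — cross-hemisphere
projections are systematically weaker than same-side ones — and each row's
contralateral mass is forced strictly below its ipsilateral mass (rescaled
on the rare draws violating it), which guarantees uncorrupted simulated
records pass the hemisphere QC by construction.

Noise is additive Gaussian on densities (σ default 0.05), clipped to
[0, 1]; intensity, energy and volume are deterministic scaled copies of
density since density drives all default analyses. The generator does
*not* emulate: spatially correlated segmentation error, partial injection
polygons spanning several nodes, hemisphere-asymmetric truth, or sampling
bias across regions — so passing recovery tests demonstrates correctness
of the pipeline arithmetic, not robustness to every artifact of real
imaging. At nonzero noise the injection can occasionally be attributed to
a neighboring node (the pipeline behaves as designed on ambiguous data);
recovery errors are therefore evaluated on the rows actually recovered.

## Problem sizes and tolerances

Validation runs use graphs of ≤ 8 nodes for exhaustive-enumeration
comparisons (100 seeded graphs; enumeration is the independent oracle),
20-node studies for end-to-end recovery (20 seeds noise-free, 8 seeds for
the replicate-RMSE curve at σ = 0.05, replicates 1–8), and 100 random
graphs for serialization round trips. Noise-free recovery is checked for
*exact* element-wise equality — the pipeline is careful to keep singleton
aggregation and normalization bit-exact. Path-length ties use a 1e-9
absolute tolerance; betweenness comparisons use 1e-9.

## Validating against a full atlas mirror

The same pipeline applies unchanged to a local mirror of the Allen Mouse
Brain Connectivity Atlas: export each experiment's structure unionizes as
one JSON record (`id`, `sex`, `strain`, `transgenic_line`,
`injection_volume`, and `structure_unionizes` with `structure_id`,
`hemisphere_id` 1/2, `is_injection`, and the four `projection_*` fields),
supply the atlas ontology as the JSON/CSV dialect of `load_ontology`, and
a node list of non-overlapping structures. `tracenet import` + `build` then
yield the full bilateral matrix, and the analysis commands reproduce
whole-atlas statistics (ipsilateral mass fraction, edge density, DOS under
thresholding, betweenness outliers). Expect such values to drift with
atlas releases and with the chosen node list; they are properties of the
data snapshot, not of the algorithms.

## Known limitations

- Mirror symmetry is an assumption, not a measurement; genuinely
  lateralized circuits are invisible to the bilateral expansion.
- Sampling bias of the underlying experiments propagates directly: nodes
  never injected simply have no row.
- No clustering/community metrics and no statistical testing of group
  differences are included; matrices export cleanly to dedicated graph
  toolboxes for those analyses.
- The CLI covers the default workflows; programmatic use exposes more
  options (tie-break flags, identity-only mapping, measure selection).
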