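# Methods

This note records the models, procedures and numerical choices behind
`plmfuse`, and what the synthetic benchmark does and does not establish.

## Inputs and conventions

Sequences are uppercase strings over the 20 standard amino acids plus `X`;
nonstandard residues (U, O, B, Z, J, `*`, …) are mapped to `X` at parse
time, matching the preprocessing applied before pLM encoding. All residue
coordinates are 0-based half-open internally. MSAs are read from aligned
FASTA (all columns kept) or A3M (lowercase insertion columns relative to
the query removed before the query-position → column map is built); `.`
gaps normalize to `-`. DSSP secondary structure arrives as a per-residue
8-state string and is reduced H,G,I → H; E,B → E; everything else → O.
Embeddings travel in HDF5, one float32 L×D dataset per record id.

## Similarity and data splitting

PIDE and HVAL follow the formulas in the README. `L` is taken as the
number of match states — columns where both sequences carry a residue —
which is the reading the HVAL formula itself specifies; alignments for
which an aligner emitted no record are treated as dissimilar (HVAL −∞),
the standard convention for sparse all-vs-all searches. One wrinkle worth
recording: the middle branch 480·L^(−0.32·(1+e^(−L/1000))) is not
strictly decreasing — it has a shallow interior minimum near L ≈ 417 and
rises by ≲ 0.01 before the flat 19.5 branch takes over at L = 450 (where
the two branches agree within 0.02). The identity-threshold-vs-length
property is therefore asserted only up to that wiggle.

The splitter is greedy and seeded, mirroring a sequential set
construction: sample the test set (every internal pair HVAL ≤ 0), then
the validation set (HVAL ≤ 0 against test and internally), then admit
training records with HVAL ≤ 0 against both held-out sets and PIDE ≤ 70
against every training record already kept; violators are dropped. No
optimal graph partitioning is attempted — the requested sizes either fill
or the splitter errors with the attainable maximum. Metadata criteria
(deposition date, resolution, CATH topology) are caller-supplied
predicates, not implemented lookups. `verify_no_leakage` independently
re-scans all cross-partition pairs at a fractional-identity threshold
(default 0.3).

## PSSM construction

PSSM generation is deliberately simple and fully specified: for query
position i, with c(i,a) the residue counts over rows carrying a residue in
that column and n_i their number,

    f(i,a) = (c(i,a) + α·q_a) / (n_i + α),   q_a = 1/20 (uniform background)

with pseudocount α = 1 by default; an optional log-odds transform
log2(f/q) is provided. `X` contributes neither counts nor coverage.
Before entering a model, frequencies pass as-is in [0,1] and log-odds are
clipped to [−5,5] and divided by 5, keeping both schemes in a comparable
numeric range. The fusion architectures only require a consistent
20-dim per-residue profile; any external profile in the same layout can
be substituted.

## Models

All predictors are stacks of same-padding 1-D convolutions over the
residue axis with leaky-ReLU activations (slope 0.01) and a per-residue
softmax head (linear head and squared error for continuous targets).
Channel widths are input → 32 → 16 → 8 → K. The `concat` variant widens
the input to D + 20; the `split` variant runs the embedding through
D → 32 → 16 and the PSSM through 20 → 32 → 16, concatenates the two
16-channel feature maps, and finishes with 32 → 8 → K. Merging after each
branch's second layer is a design choice: it gives both inputs equal
learned-feature bandwidth at the merge. Kernel size defaults to 7 —
a local receptive field being the minimal faithful reading of
"convolutional" — so the three-layer base network sees ±9 residues.

Training is Adam (lr 1e-3) over minibatches of whole chains, padded and
masked; activations at padded positions are zeroed after every layer, so
real-residue outputs are provably independent of batch composition.
Early stopping monitors validation Q (accuracy on the declared classes;
negative squared error for regression) with patience 10 and restores the
best weights; without a validation set the training loss is monitored.
Everything is deterministic under the configured seed. Argmax ties break
to the lowest class index. The network is implemented directly in numpy
(forward, backprop, Adam) — at these widths a chain batch is a handful of
small matrix products and needs no framework.

## Workflows

The five strategies share one model contract so that input is the only
variable. MSA-embedding averaging embeds every row on its own ungapped
sequence (never the gapped row) and takes the unweighted column mean over
rows with a residue at the query's column; the query always contributes,
so every position is defined. The consensus workflow (`msacons`) averages
probability vectors, not hard labels, and takes the argmax afterwards —
the information-preserving reading of averaging "predictions" — and
includes the query row. Rows that fail preprocessing are skipped with a
warning rather than aborting the query, since real search outputs contain
fragments. A `max_rows` cap is available for very deep alignments
(default: all rows).

Two exact identities anchor the implementation: for a single-row (or
noise-free identical-copy) alignment, both `msa-emb` and `msacons` reduce
bitwise to `raw`. These are regression-tested.

## Evaluation

Q3 and Q10 are plain accuracies ×100. Per-chain aggregation computes each
chain's metric, then the mean and the population SD over chains, with
SE = SD/√(n−1) and 95% CI half-width 1.96·SE. Spearman's ρ is the Pearson
correlation of mean ranks (ties averaged). F1 uses percent precision and
recall; an empty predicted-positive (or observed-positive) set flags the
affected component as NaN rather than silently zero, with the single
documented convention that F1 = 0 when precision + recall is 0.
Conservation MCC binarizes the nine integer classes at "> 5 conserved" —
the "< 6 not-conserved" phrasing is the same rule on integers — and flags
degenerate 2×2 tables. Segment evaluation extracts maximal runs of a
type; a predicted segment matches an observed one iff both endpoints are
within 5 residues and the intersection covers at least half the union.
A protein counts as correct for Q_ok iff predicted and observed segments
are equal in number and match pairwise in left-to-right order (the
one-to-one matching is order-based and deterministic; no bipartite
search), and the denominator is the set of proteins with at least one
observed segment of the type. Baselines: i.i.d. draws from the class
distribution (closed form 100·Σp²; 33.3 for three uniform states, 10 for
ten) and the constant majority-class prediction.

## Synthetic families

The generator emulates the statistical structure the analysis needs and
nothing more. Labels follow a first-order segment process (state, then a
geometric run length with per-state means H:10, E:5, O:8 — a caricature
of secondary-structure segment statistics). The query is uniform over the
20 amino acids; each of N homologs substitutes each residue with
probability `sub_rate` (replacement uniform over all 20, so expected
identity is 1 − 19/20·sub_rate) and deletes it with probability
`indel_rate`, recorded as a gap. Homologs acquire no insertions, so MSA
columns coincide with query positions and labels attach to columns; the
A3M insertion path is exercised by parser fixtures instead. Embeddings
are μ(label) + N(0, σ²) per coordinate, with the class means placed at
unit mutual distance in D = 16 dimensions (scaled one-hot corners). An
optional per-row label-flip rate emulates low-conservation families where
consensus averaging is expected to hurt. All randomness flows from one
root seed: family k draws from generator seeded (seed, k), and the
provider's noise from (seed, crc32(record id)), so any record regenerates
identically in isolation.

Default study conditions for the headline contrast: 200 training, 30
validation and 50 test families, L = 100, N = 50 homologs, sub_rate 0.3,
indel_rate 0.05, σ ∈ {3, 0.1}, models trained for up to 80 epochs with
patience 10. These sizes make the experiment reproducible on a laptop CPU
in well under a minute per training while leaving the effect enormous
relative to its standard error: at σ = 3 the family average cuts noise SD
from 3 to ≈ 0.42 against a unit class separation, lifting Q3 from ≈ 47 to
≈ 91, while at σ = 0.1 both workflows sit at ≈ 100 and the gap vanishes.

What this does and does not show: the generator reproduces the
*mechanism* by which MSA averaging helps noisy embeddings (conserved
label signal + independent noise) and the regime where it cannot help
(noise already negligible). Real pLM embeddings have correlated,
anisotropic, context-dependent geometry; real families have phylogenetic
structure, insertions and alignment errors; none of that is emulated, so
passing tests demonstrate the pipeline's correctness and the averaging
mechanism, not performance on real proteins. Real embeddings plug in
through the HDF5 adapter (`PrecomputedProvider`) when available.

## Degenerate inputs and numerical details

Frequency-PSSM rows are renormalized against accumulated rounding and
validated to sum to 1 within 1e-9. Softmax is computed with max
subtraction; cross-entropy clips probabilities at 1e-12. A non-finite
training loss aborts with the epoch index. Chains of length 1 are valid
everywhere. Fully-deleted homologs are dropped at simulation time. The
checkpoint is a single `.npz` with the config embedded as JSON.

## Known limitations

- The splitter is greedy; a maximum-cardinality redundancy-free split is
  not attempted.
- PSSMs are profile frequencies, not aligner-weighted profiles
  (no sequence weighting, no gap penalties).
- The consensus workflow re-predicts every row; for very deep alignments
  use the row cap.
- Continuous-target support covers the generic regression head and
  consensus averaging; task-specific disorder models are out of scope.
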