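# Methods

## Problem and model

Linear B-cell epitopes are short contiguous antigen segments recognizable by
antibodies. The classical in-silico selection heuristic holds that a good
epitope peptide is hydrophilic, surface-exposed, conformationally flexible,
and lies in β-turn/random-coil rather than α-helix/β-sheet structure, and
must be at least ~8 residues long to be immunogenically useful. This package
operationalizes that heuristic as five per-residue predictor tracks, a
composite antigenic index, and an ordered rule filter, all parameterized in
one configuration file so that every numeric decision is explicit and echoed
into run manifests.

Coordinates are 1-based inclusive throughout; any BED export converts to
0-based half-open at the serialization boundary only.

## Predictor tracks

**Hydrophilicity.** Hopp–Woods per-residue values, arithmetic mean over an
odd window (default 7) anchored at the center residue. Positions without a
full window are masked by default; a shrinking-window mode exists for
display. Kyte–Doolittle is selectable; because it is a hydropathy scale it
is negated on load so "high = hydrophilic" holds for either choice, and the
run manifest records which scale was active.

**Surface probability.** Emini's hexapeptide statistic: the product of six
fractional surface probabilities divided by 0.37⁶ (0.37 ≈ probability that a
random residue is surface-exposed), so 1.0 is the random expectation. The
even window is anchored at the window's first residue by default; a
center-left anchor (position 3 of 6) is selectable, since the original
tools' anchoring convention is not documented — the convention is config,
not silent behavior.

**Flexibility.** Normalized B-factor flexibility indices (Vihinen et al.
1994 parameterization, the single-table form of Karplus–Schulz-style
profiles), weighted window mean with the center-peaked weight vector
(0.25, 0.4375, 0.625, 1.0, 0.625, 0.4375, 0.25), renormalized to sum 1.
Values above 1.0 indicate above-average backbone mobility.

**Chou–Fasman structure.** Helix nucleates where ≥ 4 of 6 consecutive
residues exceed the helix-former cutoff (P_α > 1.03) and extends while the
running tetrapeptide mean P_α ≥ 1.00; strand nucleates at ≥ 3 of 5 above
P_β > 1.05, extending analogously. A β-turn is called over tetrapeptide
i..i+3 when the bend product f(i)·f(i+1)·f(i+2)·f(i+3) > 7.5·10⁻⁵, mean
P_turn > 1.00, and mean P_turn exceeds both mean P_α and mean P_β there.
Helix/strand overlaps resolve to the larger regional mean propensity; exact
ties soften to E per the global tie-break. Everything else is coil. The
cutoffs are the classical published constants and live in the params file.

**GOR-style structure.** Per residue and state, the score is the sum of
directional information contributed by neighbors at offsets −8..+8, minus a
per-state decision constant (default 0); the argmax state is assigned.
The packaged information table is *synthetic*: generated deterministically
from the Chou–Fasman propensities with a center-peaked offset kernel
(`scripts/make_gor_table.py`, values in centinats), because the original
1978 tables could not be transcribed with confidence. The algorithm follows
the published definition; the table is data and can be replaced by a file
in the same four-column format.

**Tie-breaks and consensus.** All state ties resolve in the fixed order
T > C > E > H (most epitope-permissive first); the two-method consensus
keeps agreements and takes the softer state on disagreement, so a position
counts as rigid only when both methods call it rigid. The downstream filter
consumes only the rigid (H+E) fraction, which makes a reproducible,
epitope-permissive tie-break preferable to an arbitrary one.

## Antigenic index and selection

Each track is discretized onto the bounded score set
{−0.6, −0.3, −0.1, 0, +0.1, +0.3, +0.6} by per-component thresholds (values
equal to a threshold stay in the lower bin); structure states map directly
(T +0.6, C +0.3, E −0.3, H −0.6). The index is the convex combination with
default weights 0.3 / 0.15 / 0.15 / 0.2 / 0.2 (hydrophilicity, surface,
flexibility, CF, GOR), masked wherever any component is masked; it is
therefore bounded by the component score range and monotone in every
component.

Candidates are maximal runs with AI ≥ 0.15 and hydrophilicity ≥ 0.0, runs
separated by ≤ 1 position merged. The rule filter tests, in fixed order:
forbidden-region overlap (off by default; enabled via config for active-site
avoidance), length < 8, rigid fraction > 0.3, mean surface < 1.0, mean
hydrophilicity < 0.0, mean flexibility < 1.0. The first failure is the
reported reason; the full boolean vector is retained. Passed candidates are
ranked by an equal-weight sum of cohort z-scores of the four criterion
means, ties broken by longer length then smaller start.

The minimum length of 8 is the one hard number the selection heuristic
itself supplies. The remaining thresholds quantify qualitative rules
("good", "high", "strong"); they were calibrated once so that the
planted-epitope recovery property of the synthetic benchmark holds
(rank-1 candidate overlapping the planted epitope at Jaccard ≥ 0.5 in
≥ 90% of 200 seeded replicates), and they are echoed into every report.

## Conservation

Per alignment column, identity is the count of the modal non-gap residue
divided by the non-gap count (`exclude`, default) or by the number of rows
(`count-as-mismatch`); modal ties break alphabetically, deterministically.
The variability threshold defaults to 1.0, i.e. any substitution flags the
column. Group contrast reports each group's modal residue per column and
calls a column discordant when group modals differ; groups with no residues
in a column are ignored there. Epitope coordinates project onto alignment
columns through the record's own gap structure; a bundled Needleman–Wunsch
pairwise aligner (match 1, mismatch −1, gap −2) supports projecting onto a
single unaligned homolog, while multiple alignment itself is out of scope.

## Synthetic data

`episcan.synthetic` generates the study conditions. Proteins: background
residues i.i.d. uniform over the 20 amino acids (uniform rather than
database frequencies so tests do not silently depend on an external table; a
Swiss-Prot-like table can be supplied as `background_freqs`); planted
epitope-like segments draw uniformly from {R,K,D,E,N,Q,S,T,G,P} and
buried-helix segments from {A,L,I,V,F,M,W}. The default study protein is
200 residues with one epitope-like segment of 15–25 aa and one buried helix
of 15 aa, non-overlapping, interior. These vocabularies separate the
hydrophilicity, surface and structure tracks by construction — which is
exactly what they are for. Passing the recovery benchmark therefore shows
the pipeline's plumbing and calibration are self-consistent, *not* that the
heuristic finds real epitopes: real antigens have correlated composition,
real epitopes are not compositionally pure, and no structural ground truth
exists here.

Alignments: a uniformly sampled root, rows mutated i.i.d. per column at rate
r (replacement uniform over 20, so it may coincide with the root), then
declared discordant columns fixed to distinct group-specific residues. The
expected pairwise identity is (1−r)² + 2r(1−r)/20 + r²/20, which the tests
check at r = 0.05 within 3 percentage points over 200 replicates. All
generators are pure functions of (spec, seed).

## Numerical and design notes

- Parameter tables ship as plain-text files with citation headers and
  pinned SHA-256 checksums, verified on config load (`verify_checksums`).
- Discretization uses half-open bins with the boundary in the lower bin;
  weights must sum to 1 within 1e-9; all oracle comparisons in the tests
  use 1e-9 tolerances.
- Degenerate inputs fail early with named exceptions: ambiguous residues
  (B/Z/X/U) are rejected rather than imputed because every scale lookup
  needs a canonical residue; sequences shorter than 7 residues are not
  analyzable (7-residue windows, hexapeptide statistic, 6-residue
  Chou–Fasman minimum).
- An empty passed-candidate set is a valid result (exit code 0), since a
  sequence may genuinely offer no acceptable epitope.
- Problem sizes used by the test suite and acceptance script — 200-residue
  proteins, 200-replicate benchmarks, 20×300 alignments — are the package's
  standard benchmark conditions; they run in seconds.

## Known limitations

- No numeric identity with any commercial implementation of these methods
  is claimed; published method definitions with documented constants are
  targeted instead, and the GOR table is an explicitly synthetic stand-in.
- Propensity methods are 1970s–80s statistics: expected secondary-structure
  accuracy is far below modern predictors, and the antigenic index is a
  heuristic, not a probabilistic model.
- Only linear (continuous) epitopes are considered; no conformational
  epitopes, MHC binding, or machine-learned immunogenicity.
- Conservation works on the alignment it is given; alignment quality is the
  caller's responsibility.
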