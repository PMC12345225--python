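# Methods

## The motif model

A PASK motif is defined purely compositionally. For a window length `W`
(default 20), a counted residue class `C` (default {D, E, S, K}), a
fraction threshold `f` (default 3/4) and required residue minima `R`
(default K ≥ 1), a window `s_1 … s_W` qualifies iff

* the number of positions with `s_i ∈ C` is at least `⌈f·W⌉`, and
* every required residue appears at least its minimum number of times.

There is no position weighting, gap model or score — the test is a hard
compositional threshold, which is what makes exact null-model calculations
possible (below). The threshold is converted to an integer count with exact
rational arithmetic (`⌈f·W⌉` computed on `fractions.Fraction`), never by a
floating-point `≥` comparison: 3/4 of 20 must be exactly 15, and 3/5 of 20
exactly 12, independent of binary rounding. Floats supplied by users are
snapped to the nearest small-denominator rational (`limit_denominator(10⁶)`)
so `0.6` means 3/5.

The scanner slides the window one residue at a time, maintaining incremental
counts (add the entering residue, drop the leaving one). This is O(L) per
protein instead of O(L·W) and is required to be outcome-identical to a
per-window recount; that equivalence is asserted against an independent
naive oracle on thousands of random sequences in the test suite and in the
acceptance script.

### Coordinates and region reporting

All coordinates are 1-based and inclusive at both ends, matching the
residue-range convention of protein domain annotation. Overlapping or
abutting qualifying windows (next start ≤ current end + 1) are merged into
maximal regions; `window_support` records how many windows merged. Merged
regions are the default report because a single biological motif typically
produces a run of consecutive qualifying windows; raw windows remain
available (`--windows`) for callers who need the unmerged set. The required
lysine is evaluated per window, not per merged region — a literal reading of
"each 20-residue subsequence must contain a lysine".

### Degenerate inputs

Sequences shorter than the window yield no motifs (not an error): a
proteome scan must not abort on short entries. Sequences are uppercased on
ingest; one trailing stop (`*`) is stripped with a warning and internal
stops are malformed-record errors. Ambiguity codes (X, B, Z, J, U, O) are
retained but never match the counted class or a required residue, so
ambiguity can only suppress a motif, never create one.

## Proteome statistics

The per-proteome statistic is the number of proteins carrying ≥ 1 motif
region, divided by the number of FASTA entries parsed. A protein counts
once however many regions it has. The denominator is a pure function of the
supplied file — whether that file is the reviewed (Swiss-Prot) or
unreviewed subset of a proteome is the caller's choice and is recorded in
the source label. Threshold sweeps scan once per threshold with all other
parameters fixed and assert the nesting invariant (positives at a lower
threshold are a superset of those at a higher one); a violation raises,
since it could only arise from a scanner defect.

GFF3 output uses the protein identifier as `seqid` and feature type
`compositional_bias` in protein coordinate space; no genome mapping is
attempted.

## Region tools

Composition reports are exact per-letter counts over an inclusive residue
range. Substitution schemes apply a source→target residue map uniformly over
a range; the built-in schemes are the classical polyP-binding mutagenesis
panels: K→R (preserves positive charge, removes lysine), S→A (removes
hydroxyls), D→N/E→Q (neutralizes acidic charge, preserves geometry) and
D→A/E→L (removes acidic side chains). All built-in schemes have disjoint
source and target sets, so they are idempotent; length is always preserved.
Because lysine is a required residue of the default motif test, applying
K→R over a full sequence provably eliminates every motif — this is checked
on random lysine-rich sequences.

## Disorder consensus

Per-residue disorder scores in [0, 1] from any number of external
predictors (typically three, e.g. NetSurfP-3.0, Metapredict, IUPred3) are
combined as the per-residue arithmetic mean with a standard-error envelope:
SE = sample standard deviation (n − 1 denominator) / √n. Sample SD is the
conventional reading of "±SE" for a small number of predictors; with a
single track the SE is defined as zero. The disorder call is strictly
`mean > 0.5`, so a residue exactly at 0.5 is not called disordered. Tracks
of unequal length are an error, never truncated, and out-of-range scores
are rejected on ingest rather than clamped. The predictors themselves are
not wrapped: only their exported (position, score) tables are consumed,
keeping the stage offline and deterministic. No smoothing or windowed
averaging is applied — the profile is the raw averaged track.

## Synthetic data

The generator draws i.i.d. residues from a per-letter background
distribution and overwrites specified windows with a seeded random
permutation of an exact residue composition that passes the motif test by
construction. All randomness flows through one `numpy` generator seeded by
a single integer, so fixtures are byte-reproducible. The default test
background for recovery experiments is **D/E/S/K-free** (uniform over
A, L, G, V, P, T), which makes ground truth unambiguous: no window outside
a plant can qualify, so recall and false positives are exact. Plants may
not overlap within a protein.

What the generator does **not** emulate: real proteome composition
(residue frequencies are i.i.d., with no positional or phylogenetic
structure), realistic length distributions, or low-complexity regions
arising from repeat expansion. Passing recovery tests therefore shows that
the scanner implements its definition correctly, not that the definition
has any particular sensitivity/specificity on real proteomes — on real data
the interesting quantity is simply the observed motif-positive fraction.

### Exact null window probability

For an i.i.d. background, the probability that a single window qualifies is
computed exactly by dynamic programming over the joint distribution of
(number of counted-class residues, count of each required residue), with
required-residue counts capped at their minima. For the default
configuration the state space is (W+1) × 2 and the computation is exact up
to float rounding — no Monte Carlo. The DP is cross-checked three ways in
the tests: degenerate backgrounds (all mass on K → 1, no D/E/S/K mass → 0),
a closed-form binomial tail when the required-residue clause is vacuous,
and a 10⁶-window seeded simulation (agreement within 3 binomial standard
errors). Under a uniform background the default motif is rare (≈ 1.8×10⁻⁷
per window), which quantifies why strict-threshold motifs are exceptional
in proteomes whose composition resembles uniform.

### Synthetic stand-ins

`paskscan.standins` constructs, residue by residue, sequences that
reproduce published compositional statistics of real polyP-binding
proteins: a 169-residue GTPase-activating protein stand-in (C-terminal
motif passing 75% with two lysines; an N-terminal region passing only at
50% with exactly seven lysines inside residues 1–45), an 813-residue
exoribonuclease stand-in (27 lysines across residues 644–813; basic domain
passing only at 50%), and a seven-protein screen-hit panel with 1/3/7
positives at 75/60/50%. They are labelled synthetic in identifier,
docstring and FASTA description; they share region-level composition with
their real counterparts but not their residues, so any analysis that
depends on actual sequence content (alignment, conservation, structure)
must use database sequences instead. The alternating counted/non-counted
construction used for the 50%-only regions pins every window at exactly
10/20 counted residues, which is what guarantees they fail at 60%.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `window_length` | 20 residues | size of the sliding window |
| `counted_residues` | D, E, S, K | compositional class |
| `fraction_threshold` | 3/4 (also swept at 3/5, 1/2) | minimum class fraction per window |
| `required_residues` | K ≥ 1 | residues that must appear in each window |
| disorder call | mean > 0.5 (strict) | binary disorder call on the consensus |
| background length | 200 aa | default synthetic protein length |

## Problem sizes in the checks

The test suite and acceptance script use: 1,000 random sequences of length
0–200 for the oracle-equivalence check; 150–200-protein synthetic proteomes
(150–300 aa) for nesting and recovery; 200 motif-positive sequences for the
K→R elimination check; and 10⁶ windows for the Monte-Carlo cross-check of
the exact rate. These sizes give exact (not sampled) answers for the
deterministic checks and sub-percent Monte-Carlo error for the stochastic
one.

## Known limitations

* Proteome-scale validation against UniProt reference proteomes needs
  network access; counts on releases other than the pinned one (2024_06)
  may drift as entries are added or revised.
* The i.i.d. null model ignores window overlap when relating the per-window
  rate to the per-protein positive fraction; the implied expectation is an
  independence approximation, checked only loosely.
* The operational definition of a "PASK-like" N-terminal region — the
  merged 50%-threshold region(s) within a stated truncation — may not match
  a hand-annotated region residue for residue.
* No probabilistic motif models (PWMs, HMMs), gapped motifs, or nucleotide
  scanning.
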