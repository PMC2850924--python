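# Methods

## The model

`acdscan` detects the alpha-crystallin domain (ACD) — the beta-sandwich
hallmark of small heat shock proteins — with a profile hidden Markov model
whose columns carry structural landmarks, and derives every downstream
annotation (zone decomposition, C-terminal anchoring module, hydropathy,
logos) from the column-to-residue map of each hit.

### Profile architecture and estimation

The profile has M match states with 20-symbol emission distributions, insert
states between adjacent columns, and delete states; the allowed moves are
M->M/I/D, I->M/I and D->M/D (no I<->D exchange). It is estimated from a
multiple alignment in which every match column (gap fraction < 0.5) carries a
landmark label in {beta2, L23, beta3, L34, beta4, L45, beta5, L57, beta7,
L78, beta8, L89, beta9}.

* **Emissions** — background-proportional pseudocounts,
  `p(a) = (c(a) + w q(a)) / (n + w)` with total weight `w = 20` (per column);
  insert states emit the background. The background is a packaged Swiss-Prot
  style frequency table (uniform available for tests). The unknown residue X
  is carried but always scores zero log-odds.
* **Transitions** — Dirichlet-style pseudocounts
  (M: 2.0/0.5/0.5, I: 1.6/0.4, D: 1.6/0.4, entry: 1.8/0.2). A flat +1 prior
  is also available, but it was rejected as the default: a delete or insert
  state that is never observed in training then gets 50/50 transitions, which
  prices a gap-extension step at ~1 bit; terminal delete chains and insert
  runs become nearly free, and measured envelope boundaries wandered well
  beyond +-3 residues. The structured prior prices unsupported gap extension
  at ~2.3 bits and restored boundary recovery to 94-100% on the synthetic
  benchmark.
* **Sequence weighting** — none by default; Henikoff position-based weights
  are available (`weighting="henikoff"`).

### Glocal scoring

Alignment is *glocal*: all M columns must be accounted for (match or delete)
against one contiguous subsequence; flanking residues score as background.
This is deliberate — a domain family defined beta2-to-beta9 admits no partial
domain, so fragments cannot qualify. The Viterbi score is
`log2 P(best path) - log2 P(background of the aligned subsequence)`; ties
prefer match over delete over insert, making tracebacks deterministic. The
forward score (log-sum over paths) is available and always dominates Viterbi.
Paths with zero matched columns are excluded. The implementation vectorizes
over columns with a prefix-max (log-sum for forward) trick for the delete
chain, and is verified against exhaustive path enumeration for small models.

### Calibration and E-values

Each profile is calibrated by Viterbi-scoring `n = 200` random sequences of
length 150 drawn i.i.d. from the background, then fitting a Gumbel law by
moments (`lambda = pi / (sigma sqrt 6)`, `mu = mean - gamma / lambda`)
refined by maximum likelihood. E-values use the full extreme-value tail,
`E = N (1 - exp(-exp(-lambda (S - mu))))`, with `N` the number of sequences
scanned. Two caveats are documented rather than hidden: (i) glocal Viterbi
null scores are close to Gaussian (the maximum is over ~L placements, not
L^2), so the fitted Gumbel tail is conservative — reported E-values overstate
the false-positive risk, and thresholds should be read on this calibrated
scale rather than as literal expectations; (ii) calibration length and n are
configurable.

### Iterative enrichment

Starting from the seed profile: scan at threshold `10^s`, drop envelopes
longer than 100 residues, re-express the accepted envelopes on the profile
columns (deletions as gaps, insertions in dedicated columns sized by the
widest insert; insert columns inherit the preceding column's landmark),
re-estimate the profile from that alignment, re-calibrate with a fresh
sub-seed derived from (master seed, iteration), raise the threshold tenfold,
and repeat until `10^e`. Defaults: s = -10, e = -5, final selection at
1e-5, at most 10 iterations. Previously accepted sequences are always
re-evaluated against the current profile. A final curation keeps non-fragment
records with protein-existence level <= 3 and exactly one qualifying envelope
(sequences with a second non-overlapping qualifying envelope are flagged
multi-ACD and excluded).

### Architecture

Zone boundaries on the target are induced by the landmarks: a matched residue
belongs to the zone of its column, an inserted residue to the zone of the
preceding column (so boundary insertions go to the preceding zone and zone
lengths always tile the envelope exactly); deletions contribute nothing. The
C-terminal anchor motif is the *leftmost* `[IVL].[IVL]` match
(`[IV].[IV]` for the strict variant) in the region after the ACD; leftmost is
a deterministic choice that yields the shortest CAM, and the alternative
(occurrence with CAM length closest to the family mode) was considered and
rejected for the default because it presumes the answer. The CAM spans from
the first residue after the ACD to the motif end; the tail is the remainder.
Hydropathy of a zone is the mean Kyte-Doolittle index (X counts 0).

### Group statistics

Lineage keywords map records to animals (Metazoa), plants (Viridiplantae),
fungi, archaea, or other eukaryotes; bacteria are sub-classified class A /
class B / other by the best percent identity of an affine-gap global
alignment (BLOSUM62, gap open 10, extend 1, a length-k gap costing
`10 + (k-1)`) against per-class reference sequences, requiring >= 40%
identity, ties falling to bacOther. The packaged reference sequences are
synthetic stand-ins (the historical class references are not distributed with
the package); users supply their own TSV for real analyses. Logos count, per
profile column, the matched residues plus deletions as an explicit 21st gap
symbol: `I(c) = log2(21) - H(c)`; letter heights are `freq * I(c)` for the 20
amino acids only, so gaps lower the stack without being drawn. No
small-sample correction is applied by default.

## The synthetic generator

The generator emulates the study conditions so that every stage is testable
without downloads:

* A positive record is `N-term + ACD + CAM + tail`: the N-terminal region is
  background sequence of truncated-normal length (mean 53, sd 35, min 0 —
  the family's observed heterogeneity); the ACD is sampled from a profile and
  then point-mutated at 20% of sites; the CAM has truncated-normal length
  (mean 14, sd 3, min 3) and ends with the anchor motif; the tail is
  background (mean 5, sd 5). Decoys are pure background of comparable length.
* The motif's aliphatic flanks are drawn I/V/L with probabilities
  0.70/0.25/0.05 (isoleucine predominates at both extremities in real
  monomers) and the central X from a P/E-enriched distribution; interior CAM
  residues exclude I/V/L entirely so the planted motif is provably the
  leftmost match and the true CAM length is exact by construction.
* Sampling uses a *sharp* generator profile (pseudocount weight 1) while
  scanning uses the deliberately smoothed weight-20 profile: real family
  members are draws from the family distribution itself, not from a
  smoothed estimate of it.
* Metadata (lineage by group mix, fragment flag, existence level) is drawn
  per record; ground truth records every region boundary and zone length.

The packaged seed alignment is a synthetic stand-in for a curated structural
alignment of 11 reference ACDs: 83 columns (zones 38/14/31, the
alpha-crystallin arrangement) with element-wise conservation — ~5%
divergence in strands, ~20% in loops, ~30% in the L57 loop, plus a few L57
deletions. Strands are the structurally constrained core of the sandwich;
the seed's conservation profile mirrors that. What the passing benchmark
shows is therefore that the machinery is correct under a conserved-core
family with independent point noise; it does not certify performance on real
databanks, where phylogenetic correlation, compositional bias and fragments
make detection harder and where HMMER-grade priors and calibration would be
the tool of choice.

## Problem sizes and numerical choices

The benchmark databank is 50 positives + 50 decoys (mutation rate 0.2); the
default run executes 6 scan/re-estimate iterations plus a final pass, with
200 calibration sequences of length 150 per iteration — a few seconds on one
CPU, chosen to keep the full pipeline cheap to rerun while leaving clear
score separation (decoys plateau ~40 bits below the weakest positive).
Emission/transition groups are validated to sum to 1 within 1e-9; traceback
recomputes predecessor identity within 1e-9 bits with the M > D > I tie
order; degenerate cases (empty sequences, all-gap columns, zero-variance
calibration scores, empty reference sets) raise explicit errors.

## Known limitations

* Reported E-values are conservative for the glocal null (see above); they
  order hits correctly but are not literal expected counts.
* One best envelope per sequence: tandem multi-ACD architectures are only
  flagged (via flank re-scanning), not fully decomposed.
* The N-terminal region is not sub-annotated; no relevant profile can be
  built for it.
* Bacterial class assignment quality is bounded by the supplied reference
  sequences; with the synthetic stand-ins it is only a mechanism test.
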