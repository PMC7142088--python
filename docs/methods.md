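# Methods

## The model

Information is stored in the *topology* of a known double-stranded DNA
fragment, not in its sequence. A register of length L (default 450 bp)
carries n designed nick sites; writing a binary block sets each site to
nicked (1) or ground state (0), and writing a 0 costs no reaction. The
readable signal is created by denaturation: each strand melts into ssDNA
fragments that tile [0, L) exactly, split at that strand's cut bonds.
Sequencing the pool and aligning to the known reference turns fragment
boundaries back into nick calls.

All coordinates are 0-based half-open. A nick position is a **bond
coordinate** b ∈ {1..L−1}: the backbone bond between sense positions b−1
and b. Both strands use the sense-frame bond coordinate, which avoids
strand-specific off-by-one arithmetic everywhere downstream.

## Guide design

Guides are 16-nt ssDNAs directing the nickase to one strand; the cut falls
between guide positions 10 and 11. Constraints enforced per register (and
panel): GC fraction in [0.20, 0.60]; no G homopolymer longer than 3;
pairwise Hamming distance ≥ 8 between all guide sequences; consecutive cut
bonds ≥ 25 nt apart (closer nicks would let the inter-nick strand
dissociate spontaneously, which is reserved for deliberate toehold
creation); and each guide's footprint 16-mer occurring exactly once in the
source genome, either strand.

Cut-bond mapping. For a sense-target guide with footprint [f, f+16) the
cut bond is f+10. For an antisense-target guide the guide anneals
antiparallel — its 5′ end sits at the footprint's *right* edge in the
sense frame — so counting 10 guide positions from its 5′ end lands the cut
at bond f+6:

```
sense frame:      f                      f+16
sense  5'  ... N N|N N N N N N N N N ^ N N N N N|N ...   ^ = bond f+10
anti   3'  ... N N|N N N N N v N N N N N N N N N|N ...   v = bond f+6
                   <--- antisense guide 3'....5' (pos 1 at f+15)
```

This genome-frame mapping for antisense guides is a declared convention of
this package (nothing in the scheme pins it); it only has to be applied
consistently by the writer and the decoder, and `validate_register`
re-derives it independently.

The designer is a greedy left-to-right scan: windows of length L are tried
from a seeded offset; within a window, candidate bonds are taken left to
right and accepted as soon as all constraints pass against the sites
already chosen; the first window reaching n sites wins. No backtracking —
the procedure is deterministic per seed, and feasibility is checked up
front by pigeonhole ((n−1)·spacing must fit in the usable bond range).
Site ordinals count by ascending cut bond.

An `end_margin` (default 20 nt) keeps cut bonds at least 20 nt from the
register ends. This is a package choice: it guarantees every denaturation
fragment is at least as long as the aligner's 20-mer seed and the
MINLEN-style read filter, so no fragment class is systematically
invisible to the decoder.

Panels of orthogonal registers additionally require disjoint genome
windows, no shared guide 16-mer, and pairwise similarity < 0.50, where
similarity is the best local-alignment score (unit match, −1
mismatch/gap, Biopython `PairwiseAligner`) normalised by the shorter
length. The threshold metric is a package choice; any monotone
local-similarity would do, and the decoder's ambiguity discard makes the
system robust to the exact value.

## Codecs

Payloads are parsed MSB-first into m-bit blocks (m = the addressed site
count; 10 for the single register, 32 for the default 5-register panel, 50
for ternary), final block zero-padded, padding recorded in the layout
metadata rather than in DNA. Binary blocks map site-wise onto nick
patterns. Ternary blocks are packed as a big-endian integer re-expressed
in base 3, most-significant trit first (any injective 2⁵⁰ → 3³² map works;
base conversion is the declared one); per site 1 = sense nick, 2 =
antisense, 0 = none. The positional-code string ("238") is presentation
only and switches to a canonical comma form whenever an ordinal ≥ 10
exists, because the compact digit string is ambiguous there. Blocks fill a
384-well plate row-major (A1..P24); a multi-register block is split across
the panel in genome order, which is what makes pooled (multi-register)
wells decodable without per-register tags.

## Channel simulation

`apply_pattern` → `denature` produce the exact per-strand fragment tiling;
an optional per-site nicking-failure probability exists (default 0 — the
enzyme protocol is treated as complete). `sim_reads` emulates a
directional ssDNA library on a 250-cycle paired-end run: per fragment
instance, `coverage` read pairs; mate 1 is the fragment 5′ prefix, mate 2
the reverse-complemented 3′ suffix, both truncated to min(read length,
fragment length); substitution errors i.i.d. at `err_rate`; constant
Phred 30 qualities (the decoder never reads qualities). Strand of origin
is preserved by pair orientation — sense fragments yield
mate-1-forward pairs — which is what makes ternary decoding possible.
Not modelled: indels, PCR amplification bias, quality decay, enzyme
kinetics, off-target nicking. Coverage is per fragment, not per base,
matching the decoder's evidence unit ("one read pair = one fragment
observation").

Toehold creation (`make_toehold`) releases the fragment between two
same-strand nicks when their distance is at most the dissociation
threshold, default 20 nt — chosen inside the open interval between the
demonstrated 14-nt release and the ≥ 25 nt stability spacing, and
configurable. The fluorescence reporter readout is modelled as linear with
unit slope in the fraction of toehold-bearing registers; kinetics are out
of scope.

## Decoding

1. **Align**: exact 20-mer seeds from the read, looked up in an index of
   both orientations of every register; candidate placements extended by
   mismatch counting (≤ 10); fewest mismatches wins; equal-score hits on
   different registers → discarded as ambiguous. With ≤ 5 registers of
   450 nt this bespoke aligner is exact, dependency-free and fast; an
   external bwa-style aligner would be interchangeable.
2. **Infer fragments**: concordant pairs (same register, opposite
   orientations) span [min start, max end); strand from mate-1
   orientation. Reads < 20 nt are dropped first.
3. **Size gate**: keep fragments whose template length is within ±1 bp of
   some achievable distance (any inter-cut, cut-to-end, or full length).
4. **Evidence**: each kept fragment adds one boundary count per endpoint
   at any site whose cut bond is within ±1 bp; endpoints at the register
   ends are tallied separately and never support a site.
5. **Call**: binary — site is 1 iff either strand's count ≥ τ (default 1,
   the single-read floor); ternary — 1/2 for sense-/antisense-only
   evidence, 0 for none; evidence on both strands at one site is a
   *conflict*, reported and fatal rather than silently resolved. Sites
   with no evidence are 0, so the all-zero ground state needs no signal
   beyond the full-length strands, and a nick whose own fragment was lost
   is still called through its neighbours' boundaries (hole inference).

The caller uses boundary counts only, never raw coverage depth: depth is
redundant given the size-gated boundary statistic and is harder to
threshold at single-read coverage.

## Same-register mixing

Pooled copies of one register lose their identity to alignment, so the
decoder only sees per-site nick *counts* — an adder channel. The
detecting-matrix codec stores an N-bit selector as the pooled subset of N
fixed row patterns; decodability is exactly the injectivity of subset
sums. `build_detecting_matrix` recurses: a budgeted lexicographic DFS
(sums packed 5 bits/column into integers) finds minimal-M row sets up to
N = 9, and block-diagonal composition of smaller verified matrices covers
larger N; every candidate is verified by exhaustive 2ᴺ enumeration before
use, and the identity matrix (M = N) is the always-valid fallback.
Achieved sizes: (N, M) = (4,3), (5,4), (6,5), (7,5), (8,6), (9,6),
(10,7), (11,8), (12,9) against the asymptotic 2N/log₂N. Count estimation
assumes equimolar pooling at known per-member coverage c: a member's nick
contributes its two flanking fragments, so counts are
round(boundaries / 2c), clamped to [0, N]. Non-integer (noise-robust)
adder decoding and unequal-concentration pools are out of scope.

## Synthetic genome fixture

`make_genome` draws i.i.d. bases at a target GC (default 0.5), seeded.
This emulates the one property of a real bacterial genome the designer
needs — abundant unique 16-mers — and deliberately omits repeats, skewed
composition and mobile elements. Passing designs on the fixture therefore
demonstrate the algorithmic constraints, not that any particular real
genome hosts a given panel; on real genomes the uniqueness scan is the
binding constraint and the same validator applies unchanged.

## Problem sizes and determinism

Tests and the acceptance script run on 4–20 kb fixture genomes, 450 bp
registers with 5–10 sites, payloads of 5–16 bytes, coverages 1–8 and
error rates 0–0.001 — the scale at which every property (exhaustive
1024-pattern write→read identity, 2⁶ mixture selectors, 20-seed design
sweeps) is checked exactly rather than sampled. Every stochastic step
(fixture genome, window offset, read errors, per-well seeds) derives from
explicit integer seeds, so all outputs are byte-reproducible.

## Known limitations

* Nicking completeness is binary (optional failure probability, default
  0); partial nicking efficiencies are not calibrated to enzyme data.
* The decoder requires the layout metadata (well → register map, payload
  length); in-DNA headers are not implemented.
* Detecting-matrix sizes are verified-optimal only up to the search
  budget; above N = 16 the identity construction is used.
* The aligner reports one best placement; it is exact for the intended
  reference scale but not a general-purpose read mapper.
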