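# Methods

## Duplicate model

A *duplicate key* is the tuple a read pair shares with every other copy of the
same original molecule: `(library, ref1, coord1, strand1, ref2, coord2,
strand2, orientation)`, where `coord` is the unclipped 5′ position of each
end. For a forward-strand read that is `POS` minus the summed leading S/H
clip lengths; for a reverse-strand read it is the alignment end (`POS` +
reference-consumed CIGAR length − 1) plus the trailing S/H clips. Soft and
hard clips are interchangeable by construction. Single mapped reads
(unpaired, or with an unmapped mate) use the fragment key `(library, ref,
coord, strand)`.

Ends are canonically ordered by `(ref, coord, strand-rank)` with F < R, so a
pair's key does not depend on which mate is read 1 or on file order.
Orientation (FR/RF/FF/RR) is computed *before* that swap, from the
genomically leftmost end's strand first (coordinate ties: read 1 first), so
FR and RF remain distinct key classes, as in the gold-standard tool.

Within a pair-key group the kept pair maximizes the score: per end, the sum
of base qualities ≥ `qual_floor` (default 15), capped at `score_cap`
(default 32767), summed over both ends. Ties break to the lexicographically
least query name. The qname tie-break (rather than file position) is what
makes verdicts a pure function of record content — the property the block
engine's partition-invariance rests on — and is the single place where a
position-dependent reference tool could legally differ on exact ties.
Fragment groups: any paired end present suppresses every lone fragment at
the site (the paired ends themselves are adjudicated only in their pair
group); otherwise the best lone fragment is kept. Secondary, supplementary
and unmapped records are never flagged and never spawn ends.

## Optical classification

Within an adjudicated duplicate group, members whose query names parse to
(tile, x, y) — colon-split names of 5 or 7 fields, or a user regex with
three capture groups — are linked when they share read group and tile and
lie within `optical_pixel_distance` (default 100) on **both** axes. Linking
is transitive: connected components, not a star around the keeper, so the
result is invariant under member order. In each component every member but
one anchor (the representative if present, else least qname) is relabelled
from PCR to optical duplicate. Only pair duplicates are classified optical;
the representative never is.

## The block engine

**Margin.** One streaming pass records the maximum observed
`|unclipped5 − POS|` over mapped records; the margin is that maximum plus
one. This is measured, not assumed from read length: reverse-strand reads
shift by the reference span, which deletions or splice gaps can push far
beyond read length + clip. Any two records whose keys can collide have
recorded positions within one margin of the shared key coordinate, which is
the fact all settlement decisions rely on.

**Partition.** Blocks of ~`block_records` records (default 100 000), never
splitting a coordinate; a reference change always starts a new block. Block
edges are the neighbouring blocks' first positions, half-open; at reference
boundaries the edge is ±∞ because keys cannot collide across references.

**Speculate.** Each block is processed independently (pure function; thread
pool is a scheduling detail). Pairs are formed by query name within the
block; a pair-key group settles unless (a) its canonical `coord1` lies
within `margin` of a block edge, or (b) `coord1` equals the unclipped 5′
position of some in-block orphan. Clause (b) covers mate-joined pairs formed
later: if a joined pair shares a settled group's key `c`, its genomically
left record has unclipped position `c` and — because `c` is at least a
margin from both edges and positions sit within a margin of `c` — that
record provably lies in this very block, as an orphan. Fragment groups
settle under rule (a) alone (fragment ends are built per record from FLAG
bits, so orphan joining never changes them). Same-key in-block groups from
different blocks always both trip rule (a), even across a run of tiny
blocks, since their records' positions straddle the intervening edges.

**Test overlap.** Orphans are joined *globally* by query name — mate
proximity in sorted files is treated as an optimization hint, not a
correctness assumption, so discordant pairs on other references resolve
correctly. Joined pairs enter the provisional pool at their key; provisional
groups sharing a key are merged across all blocks and adjudicated with the
same group rules. A record adjudicated twice raises — conservation (exactly
one verdict per considered record) is enforced, not hoped for.

A paired record whose mate is absent from the whole file (corrupt input) is
downgraded to a fragment-only end and adjudicated among its fellow
downgraded orphans at its key, with a logged warning count. Its original
FLAG-derived paired fragment end has already suppressed co-located lone
fragments — the same view a global tool gets from FLAG bits — and the
oracle implements the identical rule, so engine/oracle identity holds even
on such input.

**Two passes.** Pass 1 computes the verdict table over the whole file (so
decisions always see complete groups); pass 2 re-reads the input and
rewrites it, clearing then setting FLAG 0x400 (idempotent on re-marked
input), with all other fields byte-preserved and a @PG line appended. The
@PG line carries no command string so that outputs are byte-identical across
block-size and thread settings.

## Metrics

Per library: unpaired reads / read pairs examined, secondary-or-
supplementary and unmapped counts, unpaired / pair / optical-pair duplicate
counts (pairs counted once per pair),
`PERCENT_DUPLICATION = (unpaired_dups + 2·pair_dups) / (unpaired_examined +
2·pairs_examined)`, and the estimated library size: the root `X` of
`U = X·(1 − e^(−N/X))` with `N = pairs examined − optical duplicate pairs`
and `U = pairs examined − duplicate pairs` (the gold-standard convention:
optical duplicates are sequencing artifacts, not resampled molecules).
The root is bracketed by doubling from `X₀ = U` and bisected to relative
tolerance 1e-9 (`expm1` keeps the large-X branch stable); it is absent when
`U = 0` or `U = N`. Note `X` *decreases* in `N` at fixed `U` and tends to
`U` from above. Metrics are tallied from final verdicts only, never from
speculative ones.

## Synthetic fixtures

The generator emulates the coordinate geometry of aligned short-read data:
templates drawn uniformly over references, FR pairs with Gaussian insert
lengths (default mean 300 ± 50 bp, 150 bp reads), ~90 % paired, Gaussian
base qualities (30 ± 5), per-read soft clips (probability and length
configurable) that move recorded positions while preserving unclipped
coordinates, a configurable fraction of cross-reference (discordant) pairs
to force long-range orphan resolution, and 7-field query names encoding
tile/x/y. Duplicate templates copy an earlier template's key but re-draw
clipping and qualities, so best-member selection is exercised; optical
copies land within ±50 px on the original's tile. Every choice flows from
one seed; the same spec yields byte-identical files.

It does **not** model sequence content, base-error profiles, aligner
behaviour, supplementary/secondary alignments, or chimeric artifacts:
passing tests demonstrate correctness of the marking logic on realistic
coordinate/duplicate structure, not robustness to pathological aligner
output. At the default validation density (10⁴ templates on ~1.8 Mb of
reference) a few independent templates collide on a key by chance; such
collisions are genuine duplicates under any key-based definition, and the
truth-derived expectation merges the affected clusters — so the zero-rate
"no duplicates" degenerate check uses a sparse (2 × 50 Mb) configuration
where collisions are absent.

## Validation design

Three independent routes must agree on every fixture: the block engine (at
block sizes from one coordinate to whole-file, threads 1–8), the global-sort
oracle (shared keying/adjudication, none of the block machinery), and the
flags predicted directly from the generator's ground-truth cluster table.
Equality is asserted on flag states, metrics and output bytes. The identity
suite runs ten fixtures of 10⁴ templates spanning duplication rates
{0, 0.1, 0.3}, clip probabilities {0, 0.5}, discordant fractions {0, 0.05}
and 1–3 libraries — sizes chosen so the full grid completes in about a
minute on one CPU while still exercising every reconciliation path
(boundary groups, split pairs, cross-reference orphans, multi-library
keying).

## Limitations

- Coordinate-sorted input only; name-sorted or unsorted files are rejected.
- Whole-file verdict state is held in memory (desk-scale design); no
  spill-to-disk.
- No CRAM, no UMI/barcode-aware keying, no flag propagation to
  secondary/supplementary alignments, no histogram section in the metrics
  file, no patterned-flow-cell distance presets.
- Threading uses a Python thread pool: it demonstrates the independence
  contract (results provably identical at any worker count) rather than
  wall-clock speedup.
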