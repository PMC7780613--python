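# Methods

## The model in brief

A synthetic chromosome arm is represented as an ordered list of loxPsym
units (LUs): the sequence between two adjacent loxPsym sites. Sites are
34 bp in sequence space but are treated as zero-width points for all length
accounting, so LU lengths tile the declared synthetic region exactly and
"deleted bp" is always a sum of reference LU lengths. Both region ends
carry a site, making the terminal LUs recombination-competent (observed
terminal-unit deletions require this); n sites therefore bound n−1 units.
Coordinates are 0-based half-open internally; GFF3 I/O converts to the
1-based closed convention.

A strain's chromosome state is a signed permutation-with-copies of LU
segments plus the list of surviving sites (always one more site than
segments). One Cre event on surviving-site pair (i, j):

* **deletion** — segments strictly between the sites are excised as a
  circle together with the interior sites; the two sites resolve into one
  hybrid site, which keeps the left site's reference identity. Excised
  circles lack a centromere and are discarded (no marker rescue).
* **inversion** — block reversed, every orientation flipped, interior
  sites reversed; an involution.
* **duplication** — tandem duplication of the block with one extra hybrid
  junction site.

Because loxPsym spacers are palindromic, deletion and inversion are both
available to every pair; translocation is out of scope (single-chromosome
model). Per induced cell the event count is Poisson(λ), λ = 2.0 by default
(the induction window is short; two events per cell reproduces the observed
mix of single- and multi-deletion survivors). Event types are drawn from
{deletion 0.45, inversion 0.45, duplication 0.10}: deletions and inversions
dominate observed SCRaMbLE outcomes and duplications are rare on this arm.
Events are applied sequentially and pair weights are recomputed on the
rearranged chromosome after every application.

## Viability and selection

A genotype is viable iff (a) every strictly essential gene is present in at
least one copy, on the chromosome or on the episomal essential-gene array
(eArray) when carried, and (b) the chromosome has exactly one centromere —
zero is acentric loss, two a dicentric; both are treated as lethal (the
source data is silent here; this is standard yeast chromosome biology).
Quasi-essential genes (MMM1, RTT109) do not block deletion; their loss sets
a slow-growth flag. Genes tagged with a condition (PML1 → 37 °C,
SDH2 → glycerol) set a conditional-defect flag only when assessed under
that condition; the default condition (YPD, 30 °C) imposes nothing.
Simultaneous loss of many nonessential genes is always treated as viable —
synthetic lethality among nonessential genes is a known simplification of
this model.

5-FOA selection keeps viable strains whose `URA3`-bearing LU is absent. A
gene replaced by the reporter is physically gone even when its LU remains,
but it still counts among "genes deleted" when the LU is later lost
(deletion statistics are defined on reference LU content); the reporter
itself is never counted as a gene.

The exhaustive single-deletion enumerator (`enumerate_single_deletions`)
tests all O(n²) site pairs and is the oracle against which the stochastic
engine is checked, exhaustively on toy arms and on the full fixture.

## Proximity weights and CIDs

Cre deletion requires a synapse of four recombinase monomers bound at two
sites, so recombination probability tracks 3D proximity. Three weight
models are provided over the current site pairs:

* `power_law`: w = (d + d0)^(−α) with d the current linear separation;
* `hic_contact`: the ICE-balanced contact count of the sites' reference
  bins (meaningful only for an unrearranged strain, i.e. the first round —
  later rounds fall back to the distance-decay model);
* `cid_boost`: power law × β when both sites map into the same chromosomal
  interacting domain (CID) of the reference.

Defaults: α = 0.85, d0 = 5000 bp, β = 6. These were calibrated once, as
the package's stated defaults, so that the default end-to-end simulation
(10⁴ cells, reporter chunk-split into LU-24, eArray present, 5-FOA
selection) reproduces the observed median contiguous deleted-segment span
of 7 kbp; d0 sits at the ~5 kbp half-width of the arm's short-range
interaction structure and β reflects the within-CID contact enrichment of
the synthetic map. They are configurable per round.

ICE balancing uses the square-root variant (rows/columns divided by the
square root of their normalized coverage), tolerance 1e-5, ≤100 iterations,
masking bins with zero coverage or coverage below the 2nd percentile. The
insulation score of bin b is the mean contact in the window×window square
straddling the gap between bins b−1 and b (window 5 bins = 10 kbp at the
2 kbp default bin size, bracketing the 2–10 kbp CID scale), log2-normalized
by its genome-wide mean, which makes it invariant to global scaling.
Boundaries are local minima with prominence ≥ 0.1 (log2 units); domains
tile the bin range between boundaries. Boundaries closer to the matrix
edge than the window cannot be called and are absorbed by terminal domains.

## Synthetic fixtures

The arm fixture emulates a synXIIL-like chromosome: 46 LUs tiling exactly
170,000 bp, lengths 50–16,404 bp, 81 genes of which 16 are strictly
essential and 65 nonessential (two of those quasi-essential), 9 LUs
carrying an essential-class gene, at most 8 genes in one LU, the
centromere in LU-37, and the 10 essential genes before 140 kbp placed so
the locus-grouping rule yields 7 loci including the PRP19/GRC3/RIX7 and
SFI1/ORC3 runs. The essential-LU arithmetic forces a layout the published
numbers only imply: the 9 essential-flag LUs decompose as 5 LUs before
140 kbp (holding the 10 eArray genes), the quasi-essential LU-34, and the
three internal-control LUs 38–40 (6 essential genes after 140 kbp). The
LU-37/LU-38 boundary is placed exactly at 140 kbp so the cutoff cleanly
separates the two groups.

Unpinned LU lengths are a log-normal share of the slack above each LU's
gene-content minimum, rescaled to hit the group totals exactly (rounding
residual absorbed by the largest unpinned unit, everything clamped strictly
inside the pinned global min/max); genes are packed left-to-right with
equal gaps, never across a site. The lengths of LU-23..27 are pinned
(11 kbp total) because that block is also the planted reporter-flanking
CID. Sequence emission joins per-LU random sequences with the real 34 bp
loxPsym sequence. Everything the published record does not pin down — gene
order beyond the named placements, exact coordinates, sequence — is
arbitrary-but-fixed given the seed; generators are pure functions of
(spec, seed) and re-verify every published statistic on their own output.

The contact-matrix fixture is block-CID: power-law decay (d + d0)^(−α)
times a same-domain boost (default 4×) times multiplicative log-normal
noise, symmetric. For the arm, domain boundaries are planted at LU
boundaries (≥ 8 kbp per domain, one domain forced to cover exactly
LU-23..27) so that CID calling, reporter-site ranking and the weight models
can be exercised end-to-end. With zero noise the insulation minimum falls
exactly on each planted boundary; at the default 5% noise recovery is
within one bin.

What the fixtures do **not** emulate: real gene order and intergenic
structure, sequencing error (contigs are exact, so sequence-mode profiling
uses exact matching; the mismatch parameter defaults to 0), restriction-
fragment-level Hi-C artifacts, and translocation with the rest of the
genome. Passing tests therefore demonstrate the correctness of the
bookkeeping, selection logic and inference machinery under the stated
model, not predictions about any particular real strain.

## Iterative rounds and the ledger

One round integrates `URA3` (the chunk-split mode adds two sites and
splits the target LU into -a/-b/-c with the reporter in the middle
sub-unit), simulates a population, selects on 5-FOA, profiles survivors,
and ranks them by deleted bp (ties: fewer non-deletion events, then strain
id). The best strain's rearranged chromosome is linearized into the next
round's reference: surviving segments become the new LU table with their
ids retained (extra copies of a duplicated unit get a `~n` suffix), gene
coordinates and strands are remapped through inversions. If a configured
reporter LU was lost in an earlier round, the round falls back to the
top-ranked retained candidate (no essential/quasi gene, no centromere;
ranked by containing-CID span, else by the span of the surrounding
deletable run).

The ledger counts each round's deleted units with their reference bp and
gene content. Split sub-units accumulate onto their parent, which counts as
deleted only when its full length is gone — so a partially-deleted split LU
is "retained" in the unit count while its lost bp still reduce retained bp.
Retained bp + cumulative deleted bp equals the reference total after every
round. A deleted copy of a duplicated unit can over-count its parent under
the bp-sum rule; with the 0.10 duplication prior and bp-ranked carriers
this is a marginal, documented limitation. "No colonies" stops the
iteration and is reported as a diagnostic (the reporter's neighborhood is
required under the applied selection), mirroring its interpretive role in
the workflow.

## Numerical and testing notes

* All randomness flows through `numpy.random.default_rng` seeded per
  generator/simulation; fixture files embed the seed in their headers, and
  identical seeds give byte-identical outputs.
* Population simulations in the test and acceptance runs use 10⁴ cells
  (3·10³ for the monotonicity experiments), sizes at which the pooled
  deleted-segment median is stable to well under the assertion tolerances.
* Degenerate inputs are rejected loudly: site pairs with i = j, genes
  crossing a site, unsorted sites, all-zero weight matrices, oversized
  insulation windows, negative contact counts. A cell whose arm has fully
  collapsed (a single surviving site) simply stops recombining.
* Sequence-mode profiling tiles a contig greedily left-to-right with exact
  LU matches in both orientations; unit sequences are random 50 bp+ strings,
  so cross-matches are vanishingly unlikely, and any unmatched stretch is a
  hard error rather than a silent skip.
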