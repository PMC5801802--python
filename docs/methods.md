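# Methods

## Coordinate conventions

All internal coordinates are 0-based, half-open, on the forward strand of
a circular genome; an interval `(start, end)` with `end > n` wraps through
the origin. Report output is 1-based inclusive. Canonical presentation
rotates the genome so the LSC starts at position 0 and IRa (the arm
following the LSC) precedes the SSC.

## Inverted-repeat detection

**Sequence route.** An IR pair lies on a single anti-diagonal of the
circular self-vs-reverse-complement comparison: if position `x` pairs with
position `y`, then `x + y` is constant modulo the genome length. The
finder collects candidate anti-diagonals from exact 21-mer matches between
the sequence and its reverse complement, then finds, per candidate
diagonal, the exact maximal window whose mismatch count stays within
`floor(f·L)` (`f` = mismatch fraction, default 0.5% — the arms of real
plastomes are homogenised by gene conversion and are "virtually
identical"). The per-diagonal search is exact: with mismatch positions
`p₁ < p₂ < …`, the maximal window containing exactly the mismatches
`pᵢ₊₁…pᵢ₊ₘ` spans `(pᵢ, pᵢ₊ₘ₊₁)`, so scanning all `(i, m)` with m up to
the budget covers every optimum. Seeding is lossless under the stated
preconditions (`min_len ≥ 50`, `f ≤ 2%`): a qualifying repeat of length L
with `m ≤ 0.02·L` mismatches contains an exact run of at least
`L/(m+1) ≥ 21` bases. Ties on length resolve to the pair whose first
interval starts at the smallest canonical coordinate. A genome with no
qualifying pair returns a distinct "no IR" result — the expected outcome
for IR-loss lineages — rather than an error.

Note one consequence of the mismatch budget: on a genome whose arms are
exactly identical, the maximal window may absorb a few chance matches
beyond the true junction (up to roughly `4/3 ×` the budget, ~17 bp at the
test scale). Downstream quantities are insensitive to this: region
assignment is by majority bp, and expansion bp are measured from gene
anchors, not from the detected junction.

**Coverage route.** The IR is present twice per molecule, so mapped read
depth doubles inside it. Depth is smoothed with a centred circular rolling
median of width `window` (default 200 bp) and divided by the genome-wide
median; maximal runs with ratio in `[low, high]` (defaults 1.7, 2.5 —
"approximately two times" is deliberately a band, not a point) are
reported. Because the IR occupies roughly a third of a plastome, the
genome-wide median sits above the single-copy depth and the doubled ratio
runs near 1.8 rather than 2.0; isolated smoothed positions can flicker
below `low`, so gaps shorter than `window` between qualifying runs are
closed before runs shorter than `window` are discarded.

## Quadripartite partition

The two arcs between the arms become the single-copy regions; the longer
is the LSC. On an exact tie the arc containing coordinate 0 is taken as
the LSC, with a warning (deterministic output on degenerate input). The
composition identity `|LSC| + |SSC| + 2|IR| = genome length` is checked
and *reported* for every genome rather than enforced: published component
tables are known to violate it by a few bp, so a mismatch is a warning,
never an error.

## IR-expansion mapping

Homology is by gene name — plastid gene names are stable across seed
plants and the analysis reasons gene-wise — rather than by whole-genome
alignment. A target gene residing in the IR whose outgroup namesake is
LSC-resident (SSC-resident) counts toward the genes recruited from the
LSC (SSC); genes already duplicated in the outgroup IR contribute nothing
("originally single-copy" is the operative notion).

Basepairs are attributed per arm with a **boundary-anchor midpoint rule**:
each maximal run of same-source recruited genes claims the arm sequence
from the midpoint of the intergenic gap at each end of the run (clipped to
the arm). Nothing in a gene-wise comparison pins junction bp between two
genes more finely; the midpoint is the symmetric, deterministic choice,
and its resolution is half the intergenic gap — which the simulator
records per engineered boundary as `anchor_resolution`. A recruited run
not contiguous with its source region's junction (an internally relocated
block) is flagged `non_contiguous` but its bp are attributed by the same
rule. The raw IR length difference vs the outgroup is reported separately
from the from-LSC + from-SSC total, since the two legitimately differ when
boundaries move on both sides.

## Alignment

Target coding sequences are compared to the functional outgroup copy by
exact global alignment under affine gap costs (match +2, mismatch −3, gap
open −8, gap extend −2; a gap of length g costs `open + g·extend`).
Pairwise alignment against a designated functional reference — rather than
a multiple alignment — keeps "same position" well-defined: every
coordinate is projected onto the reference CDS.

Determinism matters more than speed, because mutation coordinates are read
off the alignment: ties prefer an aligned pair over a gap, a gap in the
target over a gap in the reference, and equal-scoring gaps take their
leftmost placement (the right-to-left traceback prefers the aligned state,
which slides gap runs left). The DP is banded and the band doubled
whenever the traceback touches the band edge or the score fails a
gap-cost ceiling certificate (any path leaving the band carries at least
`|ΔL| + 2(pad+1)` gap bases, bounding its score), so the result is always
the exact full-matrix optimum.

## Pseudogene calling

Walking alignment columns left to right with the cumulative net indel
length `d`: each maximal interior indel run with length ≢ 0 (mod 3) emits
one frameshift (FS) at reference codon `1 + floor(ref_nt/3)`; runs with
length ≡ 0 (mod 3) emit nothing; the frame is restored wherever `d` returns
to 0 (mod 3). Terminal gap runs (a target truncated at either end) are
truncation, not indels — they contribute to coverage only.

Stops are scanned by translating the target in its own running frame: any
TAA/TAG/TGA strictly before the reference's terminal stop emits an SC with
both a reference-projected codon (`aa_ref`) and the target's own codon
count (`aa_target`) — published positions for one event differ between
species, implying species-local numbering, so both are emitted and event
identity uses neither (see below). An SC arising while `d ≢ 0` (mod 3) is
retained but flagged `frameshift_induced`: it is a consequence of the
frameshift, not an independent event, and is excluded from shared-event
matching. A stop at the terminal reference codon is never premature;
target stops beyond the reference terminus are ignored.

Status: `absent` if reference coverage < 0.20; `partial` if some exon's
coverage < 0.20 while another's > 0.80 (missing exons listed); otherwise
`potential_pseudogene` if any FS or SC was found; otherwise `intact`.
The 0.20/0.80 thresholds are configuration defaults — the notion of a
"missing" gene is not quantified in the comparative literature. Loss of
the start codon is recorded as an annotation note, not an inactivating
mutation class. Gene-content tallies count IR-duplicated genes twice in
the total, report the number of IR-resident copies in the duplicated
column, and count `partial` genes among potential pseudogenes (exon loss
inactivates a gene as surely as a frameshift).

## Shared events and Dollo placement

Event identity is the reference-anchored nucleotide position **plus the
exact change descriptor** (`del2@70`, `ins1:T@100`, `TAA@58`) — never the
amino-acid number, which drifts between species downstream of indels.
Groups with identical descriptors in ≥ 2 species are `identical`; groups
at the same reference codon with differing descriptors are
`convergent_same_site` (independent origins at one site). Indel
descriptors are left-normalised: an indel inside a repeat has a position
only up to sliding within the repeat, and the leftmost placement is the
canonical representative on both the alignment side and the simulator
ledger side. An off-by-default codon-window relaxation exists for
near-miss positions; the default is exact identity.

Under Dollo parsimony each event maps to the stem branch of its species
set's MRCA; single-species events go on the terminal branch. If the MRCA
subtree contains species lacking the event, the placement is flagged
inconsistent (homoplasy or undetected loss) and reported under the MRCA —
never silently split into multiple origins. Gene absences and exon losses
are placed the same way. Tree inference itself is out of scope: the
species tree is an input.

## Synthetic data

The simulator is the oracle for every stage. The default world is a
1/10-scale quadripartite genome (LSC 8,000 bp, SSC 1,800 bp, IR 2,600 bp,
matching the real proportions of ~85/18/26 kb) carrying 17 protein genes,
2 tRNAs and 2 rRNAs across all three region classes, including a two-exon
gene (*ndhA*, 180 + 183 nt exons with a 120 nt intron) and two
minus-strand genes. Genes are valid ORFs (start codon, stop-free body,
terminal stop). It evolves depth-first along a rooted 6-leaf tree with
Jukes-Cantor-style substitutions (default 0.01/site per branch) plus
engineered events; the default 5-event scenario plants an IR expansion and
a clade-shared stop gain on the Striga-like stem, a clade-shared
frameshift and a gene deletion on the sister-pair stem, and a terminal
exon loss.

Choices that make the TruthLedger an exact oracle:

* **Arms stay byte-identical** — all change applies to the IRa haplotype
  and IRb is mirrored at assembly, emulating gene-conversion
  homogenisation. Real arms are near-identical but not perfectly so; the
  0.5% mismatch tolerance in detection is exercised by the budget, not by
  simulated arm divergence.
* **Substitutions are rejection-sampled** so they never create or destroy
  a stop/start codon in any protein gene, and genes targeted by
  engineered events are excluded from substitutions entirely. The ledger
  is therefore the complete inventory of inactivating changes, and the
  local sequence context of every planted indel is stable across species,
  so left-normalised positions agree exactly between ledger and pipeline.
* **Junction guard bases**: the four bases flanking the single-copy/IR
  junctions are fixed so that arm extension past a junction meets an
  immediate mismatch; with a zero mismatch budget, detection recovers the
  planted arms exactly.
* **Boundary shifts snap to intergenic midpoints** (regions are laid out
  with 30 bp gene-free margins, so inter-region junctions sit at the
  midpoint of a 60 bp gap), and the recruited span is re-duplicated into
  both arms. The half-gap at the snap point is recorded as the anchor
  resolution; because the mapper uses the same midpoint convention, bp
  recovery is exact in the absence of gene movement.
* Engineered mutations are restricted to plus-strand genes, and event
  combinations that stack a frame-changing edit upstream of a later point
  event on the same gene lineage are not part of the default scenario
  (coordinates are planted in reference-CDS space).

Coverage simulation draws per-base depth from Poisson(d) in single-copy
regions and Poisson(2d) inside the arms (default d = 40×), seeded.

**What a green benchmark does and does not establish.** The simulation
validates detection logic, coordinate bookkeeping and tree logic — not
evolutionary realism. Real data add rate heterogeneity, partially diverged
IR arms, indels outside engineered sites, annotation error, SSC
orientation isomers (reported only relative to the input orientation),
small dispersed repeats, and mapping artefacts in coverage tracks; none of
these are simulated. Pseudogene calls on real data remain "potential"
pseudogenes in the absence of expression evidence.

## Known limitations

* Homology by gene name requires consistent annotation naming between
  target and outgroup; there is no sequence-similarity fallback.
* The IR finder returns the single maximal pair; plastomes with unusual
  large dispersed repeats would need the candidate list inspected.
* bp attribution at expansion boundaries is midpoint-of-gap by
  construction; published totals produced with a different (unstated)
  junction convention can differ by up to one intergenic gap per boundary.
* A gene truncated only at the 3′ end yields reduced coverage but no
  missing-exon signal in single-exon genes; it is called intact if no
  FS/SC exists and coverage stays above the absence threshold.
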