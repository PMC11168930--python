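# Methods

`palindromekit` annotates great-ape sex chromosomes: it discovers
palindromes (long inverted repeats), groups them into homologous clusters
within and across species, partitions a chromosome into sequence classes
(pseudoautosomal, satellite, ampliconic, ancestral), applies the standard
segmental-duplication post-filter, and calls multi-copy and ampliconic
gene families from protein sequences. This note documents the models,
the defaults and why they are what they are, the numerical choices, and
what the synthetic fixtures do and do not demonstrate.

## Palindrome model and detection

A genomic palindrome is a pair of inverted-repeat arms on one chromosome,
optionally separated by a spacer. A candidate is emitted as a palindrome
when all four thresholds hold:

| parameter | default | meaning |
|---|---|---|
| `min_arm_identity_pct` | 98 | arm-vs-arm identity of the inverted alignment |
| `min_arm_len_bp` | 8,000 | each arm must reach this length |
| `max_spacer_bp` | 500,000 | distance arm1.end → arm2.start |
| `max_repeat_fraction` | 0.80 | repetitive content of the candidate footprint (strictly below) |

"Length ≥ 8 kb" is read as *each arm* ≥ 8 kb, matching the field's
definition of palindromes as inverted repeats larger than 8 kb whose
repeated units are the arms. The repetitive-content footprint is the
full span arm1.start → arm2.end (spacer included); a switch
(`include_spacer_in_repeat_fraction`) restricts it to the arms. The
spacer constraint is measured end-of-arm1 to start-of-arm2, and arm
identity comes from a global alignment of arm1 against the reverse
complement of arm2.

Discovery is seed–chain–extend against the chromosome's own reverse
complement: exact k-mer seeds (k = 21) joined on anti-diagonals
(i + j ≈ constant for an inverted pair), chains broken when consecutive
seeds are more than `max_seed_gap` = 5 kb apart along the chromosome or
drift more than `band_width` = 2 kb across diagonals, then exact-match
extension of both arm boundaries. Soft-masked (lowercase) bases never
seed but are aligned through. Candidates shorter than
`min_arm_candidate` = 4 kb per arm are suppressed; the floor sits below
the 8-kb calling threshold on purpose, so that length-failing candidates
are rejected by the documented threshold rather than silently never
proposed. Overlapping candidates are resolved greedily by matched bases
with a leftmost tie-break, which makes detection deterministic.

Pairwise gapped alignment (arm identity, PAR chunks, window
verification) runs on unit-cost edit-distance alignment with an extended
CIGAR; identity = matches / alignment columns and gap fraction = gap
columns / alignment columns, the common lastz identity/continuity
convention. The match/mismatch/gap fields of `AlignParams` parameterize
chaining only. For substitution-dominated divergence — the regime the
thresholds address — unit-cost and scored affine alignment give
identities within a fraction of a percentage point of each other, and
the exact k-mer seeding limits detection to arm pairs above roughly 85%
identity (the probability that a 21-mer survives at divergence d is
(1−d)^21). That floor is far below the 98% calling threshold, so it does
not affect calls; it does mean the raw candidate stream is not a
complete inventory of low-identity inverted repeats.

## Clustering palindromes

Arm-to-arm alignments (internally computed all-pairs, or imported
lastz-style tables) are discarded when identity < 85%, gap fraction
> 5%, matched bases < 500, or either arm is covered < 40% — strict
inequalities, so boundary values survive. A surviving alignment in
either orientation creates an edge between the two palindromes owning
the arms; clusters are connected components (transitive closure:
linked pairs A–B and B–C place A, B, C in one cluster). The same filter
serves orthologous (cross-species) and paralogous (same-chromosome)
links, so clusters may mix the two, and one surviving alignment
suffices — no reciprocity requirement. Cluster ids are the
lexicographically smallest member, which keeps output stable. Sharing
summaries count clusters whose species set contains each named group,
plus exact per-combination counts.

## Sequence classes

The workflow is sequential, mirroring standard sex-chromosome
annotation practice:

1. **PAR**: maximal chromosome-terminal blocks where X and Y align in
   direct orientation. Scanning compares co-linear 10-kb chunks from
   each terminus at ≥ 99% identity, tolerates interruptions up to
   10 kb, refines the boundary at 500-bp resolution, and requires
   ≥ 50 kb to report. The left-terminus block is PAR1, the right PAR2.
   These scan parameters are package choices (the procedure is usually
   described only as "aligning X and Y"); they recover planted
   boundaries within one refinement step.
2. **SAT**: repeat annotation merged when gaps are ≤ 1 kb (inclusive),
   kept when the merged span is strictly > 0.25 Mb.
3. **AMP candidates**: the repeat-masked chromosome is cut into 5-kb
   windows; a window qualifies when a non-self locus (either
   orientation, at least one window-length away) provides ≥ 25 exact
   11-mer seeds in one 250-bp diagonal band *and* the verifying
   alignment reaches ≥ 50% identity. Maximal runs of qualifying windows
   strictly longer than 90 kb are emitted. Terminal partial windows are
   evaluated but flagged and excluded from runs. Windows inside the
   PARs never qualify.
4. **Assignment**: AMP = union of palindrome footprints (spacer
   included by default, switchable) and AMP candidates; precedence
   PAR > SAT > AMP > ANC resolves overlaps into a perfect tiling of
   [0, L) — validated per base. The sequential workflow makes nested
   segments ambiguous; the higher-precedence class wins and each
   resolved overlap is logged. On the Y, leftover ancestral-by-default
   runs that overlap a gene labelled ampliconic are reassigned AMP;
   runs overlapping ancestral genes stay ANC, and the refinement never
   demotes existing AMP.

The seed-count gate in step 3 exists because gapped alignment of two
*unrelated* DNA sequences already yields ~50% identity columns under
unit-cost alignment, so the 50% identity threshold alone cannot separate
homology from noise; requiring concentrated exact-seed support first
makes the step specific (zero qualifying windows on uniform random
chromosomes across seeds) at the cost of a sensitivity floor well above
50% identity for the *detector* (≈ 75–80% with k = 11). Planted
duplications in the fixtures sit at 95% identity, far above the floor.

**Segmental duplications** are not discovered here; externally produced
records are filtered to keep identity > 90%, length > 1 kb and
satellite content < 70%, all strict.

## Gene families

All-vs-all best local protein alignments (BLOSUM62, gap open −11,
extend −1) define homology: identity ≥ 50% over an aligned region
covering ≥ 35% of *both* protein lengths (the plural reading of "35% of
protein lengths"; identity counts matches over all alignment columns,
from the best single local alignment). Families are single-linkage
components with ≥ 2 members, refined by dropping components in which no
within-species pair itself passes the homology criterion. A family is
**ampliconic** when some within-species pair reaches ≥ 97% identity —
cross-species pairs never qualify. Gene density per class assigns each
gene to the class of its midpoint (avoiding double counting at
boundaries) and is tested against class-length proportions with a
Pearson goodness-of-fit chi-squared (df = classes − 1) and Bonferroni
correction.

## Statistical kernel

- Welch (unequal-variance) two-sample t-test; one-sided alternatives;
  the zero-variance-equal-means degenerate case returns p = 0.5 with a
  warning. Welch is used because the compared groups (e.g. arm vs
  spacer GC) have no reason to share a variance.
- Wilcoxon rank-sum: midranks for ties; exact enumeration over all
  labelings for combined n ≤ 20 (tie-safe), a subset-sum counting exact
  null for tie-free samples up to combined n = 40, and otherwise a
  normal approximation with tie-corrected variance and continuity
  correction. Both tests show empirical size 0.05 ± 0.01 at α = 0.05
  over 10⁴ null replicates (n = 30 per group).
- Bonferroni: min(1, p·m).

The statistics are implemented in-package and cross-checked in the test
suite against scipy's independent implementations and against exhaustive
permutation enumeration.

## Synthetic fixtures

The generator plants palindromes (arm2 = mutated reverse complement of
arm1), satellite arrays (tandem units, annotated in the repeat track),
dispersed duplications, terminal PAR blocks shared between an X and a Y,
repeat-track blankets, labelled genes, and protein families. DNA
mutation is independent per-base substitution to a uniformly chosen
different base (optional small indels, geometric mean 2 bp) — the
simplest model that exercises identity thresholds. Protein family
members are mutated from a hidden family reference with an *exact*
substitution count at interior positions (terminal 10 residues spared),
so planted identities realize exactly and cannot be inflated by local
alignment trimming the ends. Identical spec + seed reproduce
byte-identical outputs.

Default fixture conditions: palindrome fixtures are 2-Mb chromosomes
with three qualifying palindromes (10–12-kb arms, 0.5–1% divergence,
20–100-kb spacers) and four decoys each violating exactly one threshold
(96% arms; 6-kb arms; 550-kb spacer; an 85% repeat blanket); window
fixtures plant 120-kb and 60-kb duplications at 95% identity on 1-Mb
chromosomes; protein fixtures plant families whose best within-species
pairs sit at 98%, 96% and ~80% (with a 99% cross-species pair), plus a
family with one copy per species that the refinement must drop. The
acceptance script runs the same constructions at problem sizes (5
palindrome fixtures, 50 tiling fixtures, 3 window fixtures, 5 protein
fixtures, 10⁴ statistical replicates) chosen to keep a complete rerun
comfortably fast on one CPU.

What passing these fixtures does **not** show: sensitivity to
palindromes below ~85% arm identity or to ampliconic copies below the
seed floor; robustness to assembly artefacts, heterochromatic satellite
structure, segmental-duplication mosaicism, or biased base composition;
PAR detection under structural divergence between X and Y termini
(inversions, indel-rich boundaries); protein families with domain-level
(rather than full-length star-topology) homology. Real chromosomes also
carry far denser repeat landscapes than the fixtures emulate.

## Other numerical choices

- Coordinates are 0-based half-open everywhere; parsers reject rather
  than clamp degenerate intervals.
- Interval unions/intersections are computed by sorted merging; the
  per-base mask equivalents exist only in the test oracles.
- Identity decimals are written with full float repr so that
  write→read round-trips are lossless.
- Determinism contract: no operation depends on iteration order of
  unordered containers; ties break on coordinates or lexicographic ids.
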