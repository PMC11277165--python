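# Methods

## The marker and its structural model

The COI-COII intergenic region of *Apis mellifera* mtDNA is modeled as a
regular sequence of structural elements:

```
TRNA_LEU?  (P | P0 | P1)?  Q+  COX2_STUB?
```

where `TRNA_LEU` and `COX2_STUB` are coding-gene stubs carrying the E2 and
(reverse-complemented) H2 primer sites, the P element appears in three
variants, and the Q element occurs in 1–3 tandem copies. The structure
string over tokens `{P, P0, P1, Q}` (e.g. `P0QQ`) is the genotype-level
summary; the maternal lineage is a deterministic function of the leading
element: `P0`/`P1` → A, plain `P` → M, no P element → C. Sub-lineages
(O, Y, Z) are not structurally callable from this marker and are treated as
catalog metadata only.

Samples are haploid drones, so each record carries a single mitotype;
heteroplasmy is out of scope.

## Structure annotation

Tiling is greedy left-to-right. At each cursor position every library unit
is aligned semi-globally (free end gaps on the amplicon side only;
match +1, mismatch −1, gap open −4, gap extend −1, via
`Bio.Align.PairwiseAligner`), identity is defined as matched bases divided
by reference length, and the best unit at or above `min_identity` is
accepted, ties broken by longer reference then lexicographic label.
Defaults and rationale:

- `min_identity = 0.75` — intra-lineage divergence of this region is far
  below 25 %, while unrelated units align well under 0.6; the threshold
  sits comfortably between the two modes. Config-overridable.
- P-variant margin `0.02` — when the top two P-variant identities are
  closer than this, the record is flagged `ambiguous-P` (the winner still
  decides the call). P0 and P1 are deletion/indel derivatives of P, so
  near-ties deserve visibility.
- Inter-unit gaps `< 10 bp` are tolerated and logged; larger unmatched
  stretches produce warnings. A record with no recognizable Q anywhere is
  UNRESOLVED and excluded from haplotyping.

Coordinates are 0-based half-open throughout; sequences are stored on the
E2-first strand after orientation (primer matching allows ≤ 2 mismatches,
no indels — Sanger-grade primer sites).

Quality filtering defaults to `min_length = 300` and
`max_n_fraction = 0.02`. These are declared defaults, not inferred from any
dataset: published analyses of this marker typically discard "bad quality"
reads without stating criteria, so the package makes its criteria explicit
and overridable instead.

## In-silico DraI test

The digestion scans the top strand with a step-1 window for `TTTAAA`
(self-reverse-complementary, so one strand suffices) and cuts after offset
3. All occurrences count, overlapping included, with duplicate cut
coordinates collapsed; `N` never matches; digestion is linear (a PCR
product, not the circular genome). Fragments always sum to the amplicon
length — asserted on every call. Fragment patterns are *not* mapped to
published DraI haplotype names: fragment data alone cannot fully resolve
haplotypes, which is exactly why the sequencing-based pipeline exists.

## Unit-anchored alignment and haplotype collapse

Within one structure class, every unit occurrence is aligned globally to
its library reference with the same scoring as above (fixed scores make the
outputs bit-reproducible; at these divergence levels the alignment is
insensitive to reasonable score changes). Columns are reference positions
plus insertion columns merged across records at the same reference offset,
left-justified; unmatched bases between unit matches travel with the
following block. Each row degaps back to exactly its input sequence —
asserted, so no base is ever dropped.

Haplotypes are groups of byte-identical aligned rows. `N` is never a
wildcard: an N-bearing row merges only with byte-identical rows and the
group is flagged low-confidence, because an N could hide a real difference.

## Nomenclature

Names follow the lineage-series convention of the honey bee COI-COII
literature: lineage letter + integer series + optional lowercase suffix
(`A74`, `A74c`, `M4r`), with underscore aliases (`C2_d`) and prime marks
(`A77′`) accepted in published names; generated names never contain primes.
Rules, applied in deterministic group order (descending size, then
lexicographic representative):

1. exact match → existing name (`known`);
2. nearest same-lineage, same-structure entry at ≤ 2 SNPs with no indel
   difference → that entry's base name + next free suffix in a–z order
   (`renamed_alias`);
3. otherwise → lineage letter + (1 + highest series number in that lineage)
   (`novel`).

The 1–2 SNP suffix threshold and the no-indel condition codify the
renaming conventions used when satellite variants of an established
haplotype are described ("one or two nucleotides" away); both are
config-overridable. Newly named groups enter the catalog with provenance
`this_run`, which makes naming idempotent across reruns.

The packaged catalog ships the 17 published names with lineage, structure
and GenBank accession but no sequences (the sequences live behind the
accessions; the default build is offline). Sequence-less entries
participate in series accounting — they pin the highest occupied number and
the occupied suffixes — but cannot be distance-matched.

## Indel re-coding and median-joining networks

Haplotype network software masks columns exceeding a missing-data
threshold, which on this marker would silently delete the P element and
unshared Q copies. Instead, each gapped column is recoded independently:
gaps become the alphabetically first base of `{A,C,G,T}` absent from the
column (deterministic, and guaranteed distinct from every real state), so
the recoded Hamming distance equals SNP columns + indel columns exactly and
no column is lost. A gapped column already containing all four bases is an
error rather than a silent approximation. Each gap column counts 1 toward
distance (a 2 bp indel counts 2); a block-as-one-event mode is deliberately
not the default because the column-wise scheme is the one that preserves
the Hamming-distance identity. Rows containing N are excluded (no surrogate
is defined for N) and listed in the output.

The median-joining construction is Bandelt-style on the recoded rows of one
structure class (classes are never mixed — their alignments do not share a
column space):

1. feasible links: pairs whose direct distance is within `epsilon`
   (default 0) of their minimax-path distance — at `epsilon = 0` this is
   the union of all minimum spanning trees;
2. quasi-medians of connected triplets: per-column majority where one
   exists, all three states where the triplet is fully heterogeneous
   (candidate expansion capped at 256 per triplet);
3. a median vector is committed whenever it lowers the connection cost of
   the node set (the MST cost over observed + median nodes), best candidate
   first, ties broken lexicographically;
4. medians of degree ≤ 2 whose removal does not raise the cost are pruned,
   to a fixed point.

`total_cost` is the connection cost of the final node set; it never exceeds
the observed-only MST cost, and on tiny instances it is checked against an
exhaustive Steiner-point search. All tie-breaks (MST edge order, candidate
order, median labels `mv1, mv2, …`) are lexicographic, so networks are
bit-reproducible. Exports: GraphML (round-trips through networkx) and a
NEXUS network block.

## Synthetic data: what it emulates and what it does not

The generator emulates the study design of a field survey of this marker:
groups of records per structure class drawn from a planted haplotype
composition, with per-base substitution noise (i.i.d., uniform alternative
base) and at most one short (1–3 bp) indel per record, never inside a
primer site. Founder haplotypes within a group differ by planted SNPs at
disjoint positions, pairwise distance ≥ 3, so the suffix-naming rule cannot
merge them. Haplotype counts are realized by largest-remainder quota rather
than multinomial draws, so a stated composition is reproduced exactly and
no planted haplotype silently vanishes. One seeded generator stream per
call, consumed in a documented order, makes output byte-identical per seed.

The packaged unit library is a synthetic exemplar set: unit lengths
(`P` 67 bp, `P0` = P minus a 15 bp block, `Q` 196 bp, stubs 60–65 bp) are
declared approximations on the field's published length scale, not measured
references. `P1` is derived from P by a single-base indel plus seeded
substitutions applied until all pairwise P-variant identities fall to
≤ 0.9 — a single indel alone would leave P and P1 nearly identical and
the variant call meaningless at realistic noise. For real data, users
supply an exemplar FASTA, or bootstrap one from sequences of known
structure with `derive_unit_library` (Q extracted as the block inserted
between structures differing by one Q copy; the tRNA-leu/P boundary placed
at the longest internal gap of a P-vs-P0 head alignment, with 25 bp of
shared context retained upstream so short post-deletion tails stay
alignable).

Consequently, passing tests demonstrate that the *algorithms* are correct
and closed under the generator's model (annotation inverts composition;
collapse counts equal planted counts; replayed mutation logs reproduce
every record). They do not validate the biological unit definitions against
real amplicons — that requires a user-supplied or bootstrapped library, and
an optional network test that fetches the deposited reference sequences.

## Problem sizes and numerical choices

The shipped tests and the acceptance script use populations of 68–1000
records, 1–30 planted haplotypes per class, 0.5 % substitution noise, and
1000-sequence digestion-oracle sweeps — sizes chosen so the whole suite
reruns in well under a minute per component while keeping every rate
estimate stable across seeds. Degenerate inputs are defined rather than
accidental: a one-haplotype class yields a single-node network; an empty
structure class is skipped with a warning; an empty catalog matches nothing
(distance ∞); suffixes beyond `z` raise rather than wrap.

## Known limitations

- Structure calls assume the grammar `(P|P0|P1)? Q+`; rearranged or
  partial-unit amplicons are flagged UNRESOLVED, not modeled.
- The synthetic mutation model has no transition/transversion bias, no
  rate heterogeneity, and no coalescent genealogy; recovery percentages on
  synthetic data are therefore upper bounds for real Sanger data.
- Nomenclature synonymy across the historical literature (identical
  sequences under different published names) is not resolved automatically.
- Fragment-pattern → published-DraI-haplotype mapping is out of scope by
  design.
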