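# Methods

This note documents the models, conventions and numerical choices behind
`herbdx`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Coordinate and symbol conventions

All column coordinates are 1-based closed intervals, and every formula,
site and primer is tied to a declared frame (a single locus or a named
combined frame); cross-frame use raises an error rather than silently
reinterpreting positions.  Residues are normalized to uppercase on input
and matching is case-insensitive — case in published character formulas is
typographic, not biological.  Each symbol is interpreted through its IUPAC
base set: `N` is "any base" (unknown), a gap is the empty set ("known
absent").  That distinction drives several downstream rules: a missing
locus in a concatenation is filled with `N`, not gaps, because absence of
data is not evidence of a deletion.

## Site profiling

A column is classified from its unambiguous bases only (gaps and ambiguity
codes are missing data, in the pairwise-deletion spirit of the distance
methods): fewer than two unambiguous bases → excluded; one distinct base →
conserved; two or more → variable, subdivided into parsimony-informative
(at least two bases each seen at least twice) and singleton.  Percentages
follow the conventional marker-table layout: variable as a share of
length, informative and singleton as shares of the variable columns.
Haplotypes are counted by complete deletion — distinct residue strings
over the columns clean in *every* record — which is the simplest
deterministic reading; wildcard-compatible merging of ambiguous sequences
was rejected as under-determined (two sequences can each be compatible
with a third yet incompatible with each other).

## Diagnostic formula learning

A diagnostic formula is a conjunction of literals `posN=X` / `posN!=X`
over one frame, attached to one class at one rank.  Semantics on a record:
a positive literal requires the exact unambiguous base (ambiguity or gap
fails it — a probe cannot be assumed to bind an unknown base); a negated
literal is satisfied only when the symbol's base set excludes the state,
so `N` fails it and a gap satisfies it.

The learner works per class against all remaining records:

* **Exact phase** — all conjunctions of 1 to min(`max_literals`, 3)
  literals over candidate literals (those satisfied by at least one
  in-class record and excluding at least one out-of-class record; other
  literals provably cannot occur in an optimal formula).  The objective is
  lexicographic: zero false positives first, then maximal coverage, then
  fewest literals, then lowest positions / positive-before-negative /
  alphabetic state.  The tie-break is a deliberate replacement for the
  unspecified ordering of published rule-learning tools: reproducibility
  is worth more than matching an arbitrary internal order.
* **Greedy phase** — when no zero-false-positive conjunction of at most
  three literals exists, literals that most reduce false positives (ties:
  higher coverage, then position order) are added until false positives
  reach zero or `max_literals` is hit; classes still not separated are
  reported as "no diagnostic pattern".

Formulas with partial coverage are reported rather than discarded — a rule
covering 80 % of a genus is still operationally useful and its false
negatives are stated alongside.  Coverage is computed in-sample on the
training alignment.  The three legacy learner switches accepted for
provenance (`padding`, `percslicing`, `exclusivefs`) are mapped to
single-column literals, no train/test slicing, and the hard
zero-false-positive constraint respectively; other values are rejected
loudly rather than silently approximated.  This mapping reproduces the
*form* of published formulas and is the module's main interpretive risk.

`exhaustive_min_formulas` is a complete enumeration (guarded at k ≤ 3 and
≤ 200 columns for k = 3) used as an exact reference; only formulas
matching at least one in-class record count as diagnostic, otherwise any
unsatisfiable conjunction would trivially qualify.

## ARMS assay design and the binding model

Allele-specific PCR places a primer's 3′-terminal base on a SNP fixed in
the target group; polymerase extension fails on a 3′ mismatch, so only
target templates amplify.  Diagnostic sites are columns where the target
group is fixed for one unambiguous base carried by no unambiguous base of
any other group (an `N` or gap elsewhere does not veto a site — missing
data is not counter-evidence, and the subsequent in-silico screen catches
real conflicts).

Primers are designed on the target-group consensus, default reverse
orientation with the footprint spanning columns `site .. site+len−1` (the
primer is the reverse complement, 3′ end on the site).  A destabilizing
mismatch is substituted at the third base from the 3′ end (configurable):
among the three alternatives the one forming the weakest mispair with the
template is chosen — ranked G·T > G·G > G·A > A·A ≈ T·T > C·T > A·C > C·C
after the usual allele-specific-PCR guidance — excluding substitutions
that would create a perfect match to any non-target template at that
column.  Candidates are annotated with nearest-neighbor Tm (via
Biopython's `Tm_NN`, cross-checked in the tests against an independently
coded unified-parameter calculation), GC fraction, homopolymer and
3′-self-complementarity flags, and ranked by closeness to the target Tm.
A whole-assay designer tries each group's sites in position order and
keeps the first whose primer passes an in-silico screen: binds every
template of its own group, none of the others, and yields a band at least
10 bp from every band already on the gel.

Binding is deliberately coarse: exact 3′-terminal match, no mismatch in
the three 3′-terminal bases (the intentional destabilizing position
excepted), and at most `mismatch_budget` (default 2) mismatches elsewhere;
a template gap or ambiguity under the footprint counts as a mismatch.  No
thermodynamic annealing or amplification-efficiency model is attempted —
the goal is band-pattern prediction, not kinetics.  Fragment size counts
the template columns spanned from the forward primer's 5′ end to the
reverse primer's 5′ end, both footprints included, after removing that
template's gap columns; sizes are therefore invariant under gap-only
alignment columns.  Mixture lanes take the union of their members' bands,
exactly how a multiplex reaction on pooled DNA reads out.

## Distance and parsimony trees, bootstrap, clade support

p-distances use pairwise deletion: each pair is compared over the columns
where both carry an unambiguous base; a pair sharing none is an error
naming the pair.  UPGMA follows the average-linkage recurrence with node
heights at half the merge distance; equidistant merges are broken by the
lexicographically smallest member id so results are reproducible.

Parsimony uses Fitch counting over unique column patterns (ambiguity codes
contribute their base sets; gaps are missing and never cost a change — the
common convention, stated here because alternatives exist).  The
heuristic search runs seeded random-addition starts followed by
first-improvement SPR hill climbing to a local optimum, returning all
distinct equally best trees; determinism from the seed is part of the
contract.  On seven or fewer taxa the tests verify the heuristic against
complete topology enumeration.

The bootstrap resamples columns with replacement; per-replicate RNG
streams derive from the global seed by counter.  Within each replicate the
taxon order is shuffled and UPGMA tie-breaking follows that random order —
without this, deterministic tie-breaks would reproduce identical arbitrary
topologies across replicates and report full support for splits carrying
no signal (the classic tie-breaking artifact; an alignment with zero
variation must collapse to a star).  Support for a named group is the
percentage of replicate trees in which its taxa form one side of a
bipartition after pruning any "ignored" rogue taxa — pruning can only
raise support, which is the point of modified group definitions.  Trees
are exchanged as newick with support as internal labels, so replicate sets
from external programs (e.g. likelihood analyses) can be scored by the
same machinery; likelihood inference itself is intentionally out of scope.

## Synthetic data: what it emulates and what it does not

The generator evolves sequences down the label hierarchy (subfamily →
tribe → genus → record) by uniform single-base replacement at per-branch
per-site rates, then overwrites planted diagnostic sites (forcing the
target class to the planted state and bumping any other record off it),
resets designated conserved windows to the root sequence, and finally
injects `N`/gap noise away from planted and conserved columns.

Defaults mirror the study shape: three deeply diverged groups — a focal
grass subfamily with two tribes and five genera (22 reference records),
a second grass group (the minor tea component), a eudicot group (the
adulterant) — over three loci of 553 / 600 / 618 columns with rate
multipliers 0.6 / 1.0 / 1.6 (slow plastid barcode, second plastid
amplicon, fast nuclear spacer).  Branch divergences (0.10 / 0.04 / 0.015 /
0.004 expected substitutions per site into subfamily / tribe / genus /
record) put within-subfamily single-locus variation in the few-percent
range typical of plastid markers in such groups.  The slow locus carries
conserved universal-primer windows at both ends and conserved assay
windows around three planted group-diagnostic SNPs — the configuration a
designer would seek on a real conserved barcode.  Eight product queries
are exact or one-substitution copies of references (adulterant ×4, focal
genus ×3, related genus ×1), two of them paired with a second-component
sequence, replaying adulteration detection, genus tracing and mixture
bands end to end.

Deliberate simplifications: no transition/transversion or rate
heterogeneity, no indel evolution (gaps only injected), no recombination
or paralogy, and product queries nearly identical to references.  Green
tests on this generator therefore demonstrate the correctness of the
counting, learning, design and support machinery under a known truth —
not the diagnosability of any particular real taxon, which depends on the
actual variation in public sequence data.  `scripts/run_real_data.py`
runs the identical pipeline on locally supplied real alignments for that
purpose.

## Problem sizes and numerical choices

The shipped analyses are desk-scale by design: 22 reference sequences ×
~1,800 combined columns, 100–500 bootstrap replicates, exact formula
search to three literals with combinatorial guards (pair/triple caps) and
a branch-and-bound cut once full coverage is reached.  UPGMA ultrametry is
asserted to 1e−9; support values are percentages in [0, 100]; all RNG
flows through `numpy.random.default_rng` seeded explicitly — there are no
hidden default seeds, and the pipeline config refuses to validate without
one.
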