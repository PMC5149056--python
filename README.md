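# herbdx

**Character-based DNA diagnostics for herbal product authentication.**

Herbal teas and similar products are sold under trivial names ("bamboo
leaves") that map onto hundreds of candidate species — and sometimes onto
none of them, when an adulterant such as carnation (*Dianthus*) leaf
replaces the declared ingredient.  Standard plastid barcodes (*rbcL*,
*matK*) rarely resolve such material to species, but they carry enough
signal to (i) place a product sequence inside a subfamily, tribe or genus,
(ii) diagnose those groups by discrete nucleotide characters, and (iii)
drive a cheap allele-specific PCR that separates the expected ingredient
from its common companions and adulterants on a single gel.

`herbdx` implements that entire dry-lab workflow for food-diagnostics and
molecular-systematics practitioners:

* **Dataset assembly** — labeled multi-locus alignments (FASTA + TSV label
  tables), bi-directional read merging into IUPAC consensus, reference-based
  end trimming, overlap merging of amplicons of one gene, and locus
  concatenation with an exact column → (locus, position) map.
* **Information profiling** — per-dataset length, conserved / variable /
  parsimony-informative / singleton sites and haplotype counts, the
  standard marker-evaluation table.
* **Character-based diagnostics** — per-class conjunctive nucleotide
  formulas (`pos234=T AND pos490=T AND pos878=G`, negation allowed:
  `pos701!=A`).  The learner searches exactly over all 1–3-literal
  conjunctions and greedily beyond, returning for each class the
  zero-false-positive formula of maximal coverage with deterministic
  tie-breaks; queries are classified by the formulas they satisfy.
* **ARMS assay design** — discovery of group-diagnostic SNPs, design of
  destabilized allele-specific reverse primers (3′ terminus on the SNP,
  one extra internal mismatch), nearest-neighbor Tm / GC annotation, and
  in-silico multiplex PCR producing a "virtual gel" of band patterns,
  including mixed-template samples.
* **Phylogenetic support** — p-distances with pairwise deletion, UPGMA,
  Fitch parsimony with seeded random-addition + SPR search, column-resampling
  bootstrap, and per-group monophyly support including "modified" groups
  with rogue taxa ignored.
* **Synthetic data** — a generator that replays the full study shape
  offline: three deeply diverged plant groups, a two-tribe core subfamily,
  planted diagnostic sites, and eight "product" queries (four adulterant,
  four genuine, two of them two-component mixtures).

## Worked example

```python
from herbdx import make_tea_fixture, concatenate_loci, design_assay, simulate_multiplex
from herbdx.rules import LearnerParams, classify_query, learn_rules

fixture = make_tea_fixture(seed=1)
combined = concatenate_loci([fixture.references[l] for l in ("cpA", "cpB", "nuc")])

rules = learn_rules(combined, "genus", LearnerParams(max_literals=4))
for cls, (formula, ev) in rules.items():
    print(f"{cls:22s} {str(formula):12s} coverage={ev.coverage:.0f}% FP={ev.false_positives}")

rulebook = [f for f, _ in rules.values() if f]
query = "".join(fixture.products[l]["P8"].residues for l in ("cpA", "cpB", "nuc"))
print("P8 ->", [cls for cls, _ in classify_query(query, rulebook, combined.length)])
```

prints one diagnostic formula per genus and traces product P8 to its
source genus:

```
Phyllostachys-like     pos203=G     coverage=100% FP=0
Pseudosasa-like        pos170=A     coverage=100% FP=0
Sasa-like              pos48=A      coverage=100% FP=0
Bambusa-like           pos82=C      coverage=100% FP=0
Dendrocalamus-like     pos30=G      coverage=100% FP=0
Cymbopogon-like        pos68=G      coverage=100% FP=0
Dianthus-like          pos37=A      coverage=100% FP=0
P8 -> ['Pseudosasa-like']
```

Each formula is a conjunction of position/state characters in the combined
1,771-column frame with zero false positives over all reference sequences;
coverage is the share of in-class references satisfying it.  Designing the
three-primer multiplex on the slow plastid locus and simulating it on the
eight products:

```python
cpa = fixture.references["cpA"]
groups = {c: [r.id for r in cpa.records if r.label("subfamily") == c]
          for c in cpa.classes("subfamily")}
assay = design_assay(cpa, groups, (1, 26), (534, 20), tm_window=20)
print(simulate_multiplex(assay, fixture.product_lanes("cpA")).to_string(index=False))
```

```
sample          bands control Bambusoideae-like Panicoideae-like Caryophyllaceae-like
    P1 553,552,108,94       +                 -                +                    +
    P2        553,108       +                 -                -                    +
    P3        552,108       +                 -                -                    +
    P4        553,108       +                 -                -                    +
    P5         553,58       +                 +                -                    -
    P6         552,58       +                 +                -                    -
    P7      552,94,58       +                 +                +                    -
    P8         553,58       +                 +                -                    -
```

Every lane shows the ~553 bp universal control band; the shorter
group-specific bands read the sample composition directly: products P1–P4
carry the adulterant (carnation-like) band, P5–P8 the genuine band, and the
two declared mixtures (P1, P7) additionally show the lemongrass-like band.

A `herbdx` command-line entry point wraps the same stages
(`herbdx simulate`, `herbdx run --config run.yaml`, plus per-stage
subcommands); see `herbdx --help`.

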