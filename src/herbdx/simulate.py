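"""Synthetic label-structured alignments with planted diagnostic structure.

Real herbal-product datasets mix deeply diverged plant groups (a grass
subfamily of interest, a second grass used as a minor tea component, and a
eudicot adulterant), a nested tribe/genus structure inside the group of
interest, and "product" query sequences that are identical or
near-identical to one reference class.  The generator reproduces exactly
that shape so every pipeline stage — site profiling, formula learning,
ARMS assay design, bootstrap support — can be exercised offline against a
known truth.

The substitution process is deliberately simple: on each branch of the
label hierarchy every site is replaced, independently with the branch's
per-site probability, by one of the three alternative bases chosen
uniformly (no transition/transversion bias, no indels; gaps and ambiguity
codes are injected afterwards as missing-data noise, never evolved).
Planted diagnostic sites are overwritten after evolution: the target class
is fixed for the planted state and any other record carrying that state is
pushed to an alternative, so planted sites are guaranteed recoverable.

Everything is reproducible from the spec seed; two seeds give the same
label structure with different residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import (
    LabeledAlignment,
    SequenceRecord,
    write_alignment,
    write_label_table,
)

_BASES = np.array(list("ACGT"))


class SpecError(ValueError):
    """The simulation spec is internally inconsistent."""


@dataclass(frozen=True)
class PlantedSite:
    locus: str
    rank: str  # rank whose class is diagnosed
    class_name: str
    position: int  # 1-based within the locus
    state: str


@dataclass
class CladeSpec:
    """Hierarchy and evolutionary knobs for one synthetic dataset.

    ``hierarchy`` maps subfamily -> tribe -> genus -> number of records.
    ``divergence`` gives expected substitutions per site on the branch
    leading *into* each level (keys: subfamily, tribe, genus, record).
    ``locus_rate`` scales those divergences per locus (mimicking slow
    plastid vs fast nuclear markers).  ``conserved_regions`` are column
    ranges reset to the root sequence in every record (universal primer
    landing sites).  ``noise_rate`` is the per-symbol probability of
    replacing a base by N or a gap after evolution (never at planted sites
    or in conserved regions).
    """

    hierarchy: dict[str, dict[str, dict[str, int]]]
    locus_lengths: dict[str, int]
    divergence: dict[str, float] = field(
        default_factory=lambda: {
            "subfamily": 0.10,
            "tribe": 0.04,
            "genus": 0.015,
            "record": 0.004,
        }
    )
    locus_rate: dict[str, float] = field(default_factory=dict)
    planted_sites: list[PlantedSite] = field(default_factory=list)
    conserved_regions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for level, d in self.divergence.items():
            if d < 0:
                raise SpecError(f"negative divergence at level {level!r}")
        if not 0 <= self.noise_rate < 1:
            raise SpecError("noise_rate must be in [0, 1)")
        seen: set[tuple[str, int]] = set()
        for site in self.planted_sites:
            if site.locus not in self.locus_lengths:
                raise SpecError(f"planted site on unknown locus {site.locus!r}")
            if not 1 <= site.position <= self.locus_lengths[site.locus]:
                raise SpecError(
                    f"planted position {site.position} exceeds locus "
                    f"{site.locus!r} length {self.locus_lengths[site.locus]}"
                )
            key = (site.locus, site.position)
            if key in seen:
                raise SpecError(f"duplicate planted position {key}")
            seen.add(key)


@dataclass
class TruthRecord:
    """What the generator actually did, for test harnesses."""

    planted_sites: list[PlantedSite]
    tree_newick: str
    record_classes: dict[str, dict[str, str]]  # id -> rank -> class


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Uniform replacement: each hit site moves to one of 3 alternatives."""
    out = seq.copy()
    hits = np.nonzero(rng.random(seq.size) < rate)[0]
    if hits.size:
        out[hits] = (out[hits] + rng.integers(1, 4, size=hits.size)) % 4
    return out


def simulate_clade_alignment(
    spec: CladeSpec,
) -> tuple[dict[str, LabeledAlignment], TruthRecord]:
    """Evolve sequences down the label hierarchy and plant diagnostic sites.

    Returns one LabeledAlignment per locus (records ordered by hierarchy)
    plus a truth record with the generating tree (newick, branch lengths =
    per-level divergences) and the planted sites.
    """
    rng = np.random.default_rng(spec.seed)
    loci = list(spec.locus_lengths)
    roots = {locus: rng.integers(0, 4, size=length) for locus, length in spec.locus_lengths.items()}

    per_locus_rows: dict[str, list[np.ndarray]] = {locus: [] for locus in loci}
    meta: list[dict] = []
    tree_parts_sf: list[str] = []
    for subfamily, tribes in spec.hierarchy.items():
        sf_seqs = {
            locus: _mutate(
                roots[locus],
                spec.divergence["subfamily"] * spec.locus_rate.get(locus, 1.0),
                rng,
            )
            for locus in loci
        }
        tree_parts_tr: list[str] = []
        for tribe, genera in tribes.items():
            tr_seqs = {
                locus: _mutate(
                    sf_seqs[locus],
                    spec.divergence["tribe"] * spec.locus_rate.get(locus, 1.0),
                    rng,
                )
                for locus in loci
            }
            tree_parts_ge: list[str] = []
            for genus, n_records in genera.items():
                ge_seqs = {
                    locus: _mutate(
                        tr_seqs[locus],
                        spec.divergence["genus"] * spec.locus_rate.get(locus, 1.0),
                        rng,
                    )
                    for locus in loci
                }
                leaf_parts: list[str] = []
                for k in range(n_records):
                    rec_id = f"{genus.replace(' ', '_')}-{k + 1}"
                    species = f"{genus} sp{k // 2 + 1}"
                    for locus in loci:
                        per_locus_rows[locus].append(
                            _mutate(
                                ge_seqs[locus],
                                spec.divergence["record"]
                                * spec.locus_rate.get(locus, 1.0),
                                rng,
                            )
                        )
                    meta.append(
                        {
                            "id": rec_id,
                            "labels": {
                                "subfamily": subfamily,
                                "tribe": tribe,
                                "genus": genus,
                                "species": species,
                            },
                        }
                    )
                    leaf_parts.append(f"{rec_id}:{spec.divergence['record']:g}")
                tree_parts_ge.append(
                    f"({','.join(leaf_parts)}):{spec.divergence['genus']:g}"
                )
            tree_parts_tr.append(
                f"({','.join(tree_parts_ge)}):{spec.divergence['tribe']:g}"
            )
        tree_parts_sf.append(
            f"({','.join(tree_parts_tr)}):{spec.divergence['subfamily']:g}"
        )
    tree_newick = f"({','.join(tree_parts_sf)});"

    # reset conserved regions to the root sequence
    for locus, regions in spec.conserved_regions.items():
        for start, end in regions:
            for row in per_locus_rows[locus]:
                row[start - 1 : end] = roots[locus][start - 1 : end]

    # plant diagnostic sites
    for site in spec.planted_sites:
        state_code = int(np.where(_BASES == site.state)[0][0])
        alt_code = (state_code + 1) % 4
        for row, m in zip(per_locus_rows[site.locus], meta):
            if m["labels"].get(site.rank) == site.class_name:
                row[site.position - 1] = state_code
            elif row[site.position - 1] == state_code:
                row[site.position - 1] = alt_code

    planted_mask: dict[str, set[int]] = {locus: set() for locus in loci}
    for site in spec.planted_sites:
        planted_mask[site.locus].add(site.position)
    for locus, regions in spec.conserved_regions.items():
        for start, end in regions:
            planted_mask[locus].update(range(start, end + 1))

    alignments: dict[str, LabeledAlignment] = {}
    for locus in loci:
        records = []
        for row, m in zip(per_locus_rows[locus], meta):
            residues = list("".join(_BASES[row]))
            if spec.noise_rate:
                hits = np.nonzero(rng.random(len(residues)) < spec.noise_rate)[0]
                for h in hits:
                    if (h + 1) in planted_mask[locus]:
                        continue
                    residues[h] = "N" if rng.random() < 0.5 else "-"
            records.append(
                SequenceRecord(
                    id=m["id"],
                    residues="".join(residues),
                    labels=dict(m["labels"]),
                    source="specimen",
                )
            )
        alignments[locus] = LabeledAlignment(records=records, locus=locus)

    truth = TruthRecord(
        planted_sites=list(spec.planted_sites),
        tree_newick=tree_newick,
        record_classes={m["id"]: dict(m["labels"]) for m in meta},
    )
    return alignments, truth


# ---------------------------------------------------------------------------
# the three-component tea fixture
# ---------------------------------------------------------------------------

GROUP_BAMBOO = "Bambusoideae-like"
GROUP_LEMONGRASS = "Panicoideae-like"
GROUP_CARNATION = "Caryophyllaceae-like"

GENUS_PHYLLOSTACHYS = "Phyllostachys-like"
GENUS_PSEUDOSASA = "Pseudosasa-like"
GENUS_DIANTHUS = "Dianthus-like"
GENUS_CYMBOPOGON = "Cymbopogon-like"

#: cpA mimics a slow plastid barcode region carrying the three-component
#: assay sites; cpB a second plastid amplicon; nuc a fast nuclear spacer.
TEA_LOCI = {"cpA": 553, "cpB": 600, "nuc": 618}

#: conserved windows on cpA: universal primer landing sites at both ends
#: plus the assay windows around the diagnostic SNPs.  Like a real plastid
#: barcode region, the assay rests on stretches conserved across all groups
#: that differ only at the planted diagnostic positions.
CPA_PRIMER_REGIONS = [(1, 26), (223, 292), (407, 446), (534, 553)]

#: the assay's group-diagnostic sites on cpA.
CPA_GROUP_SITES = {
    GROUP_BAMBOO: (407, "T"),
    GROUP_LEMONGRASS: (254, "G"),
    GROUP_CARNATION: (223, "C"),
}


@dataclass
class TeaFixture:
    """Reference alignments, product queries and ground truth."""

    references: dict[str, LabeledAlignment]  # locus -> alignment
    products: dict[str, dict[str, SequenceRecord]]  # locus -> product id -> record
    mixtures: dict[str, list[str]]  # product id -> component groups
    product_origin: dict[str, tuple[str, str]]  # product id -> (group, genus)
    truth: TruthRecord
    seed: int

    @property
    def product_ids(self) -> list[str]:
        first_locus = next(iter(self.products))
        return list(self.products[first_locus])

    def product_lanes(self, locus: str) -> dict[str, list[SequenceRecord]]:
        """Per-product template sets for the multiplex simulation.

        Mixture products contribute their secondary-component record in
        addition to the sequenced primary component.
        """
        lanes: dict[str, list[SequenceRecord]] = {}
        for pid, rec in self.products[locus].items():
            lanes[pid] = [rec]
            mix_rec = self.products[locus].get(f"{pid}-mix")
            if mix_rec is not None:
                lanes[pid].append(mix_rec)
        return {pid: recs for pid, recs in lanes.items() if not pid.endswith("-mix")}

    def write(self, out_dir) -> None:
        """Write the bundle as FASTA + TSV label table + truth TSV."""
        import pathlib

        import pandas as pd

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        by_id = {}
        for locus, aln in self.references.items():
            write_alignment(aln, out / f"{locus}.references.fasta")
            for rec in aln.records:
                by_id.setdefault(rec.id, rec)
        for locus, prods in self.products.items():
            write_alignment(
                LabeledAlignment(records=list(prods.values()), locus=locus),
                out / f"{locus}.products.fasta",
            )
            for rec in prods.values():
                by_id.setdefault(rec.id, rec)
        write_label_table(list(by_id.values()), out / "labels.tsv")
        pd.DataFrame(
            [
                {
                    "locus": s.locus,
                    "rank": s.rank,
                    "class": s.class_name,
                    "position": s.position,
                    "state": s.state,
                }
                for s in self.truth.planted_sites
            ]
        ).to_csv(out / "truth_planted_sites.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "product": pid,
                    "group": group,
                    "genus": genus,
                    "mixture_groups": ";".join(self.mixtures.get(pid, [])),
                }
                for pid, (group, genus) in self.product_origin.items()
            ]
        ).to_csv(out / "truth_products.tsv", sep="\t", index=False)
        with open(out / "truth_tree.nwk", "w") as fh:
            fh.write(self.truth.tree_newick + "\n")


def make_tea_spec(seed: int = 0) -> CladeSpec:
    """The study-shaped default spec: three deeply diverged groups, a
    two-tribe bamboo-like core with several genera, and planted assay and
    genus/species diagnostic sites."""
    hierarchy = {
        GROUP_BAMBOO: {
            "Arundinarieae-like": {
                GENUS_PHYLLOSTACHYS: 4,
                GENUS_PSEUDOSASA: 2,
                "Sasa-like": 3,
            },
            "Bambuseae-like": {
                "Bambusa-like": 2,
                "Dendrocalamus-like": 2,
            },
        },
        GROUP_LEMONGRASS: {
            "Andropogoneae-like": {GENUS_CYMBOPOGON: 3},
        },
        GROUP_CARNATION: {
            "Caryophylleae-like": {GENUS_DIANTHUS: 6},
        },
    }
    planted = [
        PlantedSite("cpA", "subfamily", group, pos, state)
        for group, (pos, state) in CPA_GROUP_SITES.items()
    ]
    # one guaranteed genus-diagnostic site per genus, spread over cpB/nuc
    genus_sites = {
        GENUS_PHYLLOSTACHYS: ("cpB", 112, "T"),
        GENUS_PSEUDOSASA: ("cpB", 278, "G"),
        "Sasa-like": ("cpB", 351, "A"),
        "Bambusa-like": ("cpB", 433, "C"),
        "Dendrocalamus-like": ("cpB", 502, "T"),
        GENUS_CYMBOPOGON: ("cpB", 47, "A"),
        GENUS_DIANTHUS: ("cpB", 555, "G"),
    }
    planted += [
        PlantedSite(locus, "genus", genus, pos, state)
        for genus, (locus, pos, state) in genus_sites.items()
    ]
    # species-diagnostic pair on the nuclear marker for the adulterant
    planted += [
        PlantedSite("nuc", "species", f"{GENUS_DIANTHUS} sp1", 181, "G"),
        PlantedSite("nuc", "species", f"{GENUS_DIANTHUS} sp1", 595, "C"),
    ]
    return CladeSpec(
        hierarchy=hierarchy,
        locus_lengths=dict(TEA_LOCI),
        locus_rate={"cpA": 0.6, "cpB": 1.0, "nuc": 1.6},
        planted_sites=planted,
        conserved_regions={"cpA": list(CPA_PRIMER_REGIONS)},
        noise_rate=0.002,
        seed=seed,
    )


def make_tea_fixture(seed: int = 0) -> TeaFixture:
    """Reference alignments plus eight product queries replaying the study
    narrative: four products are adulterant (carnation-like) copies, three
    trace to one bamboo-like genus and one to another, and two products
    carry an additional lemongrass-like component."""
    spec = make_tea_spec(seed)
    references, truth = simulate_clade_alignment(spec)
    rng = np.random.default_rng((seed, 999))

    by_genus: dict[str, list[str]] = {}
    for rec_id, labels in truth.record_classes.items():
        by_genus.setdefault(labels["genus"], []).append(rec_id)

    origin = {
        "P1": (GROUP_CARNATION, GENUS_DIANTHUS),
        "P2": (GROUP_CARNATION, GENUS_DIANTHUS),
        "P3": (GROUP_CARNATION, GENUS_DIANTHUS),
        "P4": (GROUP_CARNATION, GENUS_DIANTHUS),
        "P5": (GROUP_BAMBOO, GENUS_PHYLLOSTACHYS),
        "P6": (GROUP_BAMBOO, GENUS_PHYLLOSTACHYS),
        "P7": (GROUP_BAMBOO, GENUS_PHYLLOSTACHYS),
        "P8": (GROUP_BAMBOO, GENUS_PSEUDOSASA),
    }
    source_ref = {
        "P1": by_genus[GENUS_DIANTHUS][0],
        "P2": by_genus[GENUS_DIANTHUS][1],
        "P3": by_genus[GENUS_DIANTHUS][0],
        "P4": by_genus[GENUS_DIANTHUS][1],
        "P5": by_genus[GENUS_PHYLLOSTACHYS][0],
        "P6": by_genus[GENUS_PHYLLOSTACHYS][1],
        "P7": by_genus[GENUS_PHYLLOSTACHYS][2],
        "P8": by_genus[GENUS_PSEUDOSASA][0],
    }
    mixtures = {"P1": [GROUP_LEMONGRASS], "P7": [GROUP_LEMONGRASS]}
    mix_source = {
        "P1": by_genus[GENUS_CYMBOPOGON][0],
        "P7": by_genus[GENUS_CYMBOPOGON][1],
    }

    protected: dict[str, set[int]] = {locus: set() for locus in references}
    for site in truth.planted_sites:
        protected[site.locus].add(site.position)
    for locus, regions in spec.conserved_regions.items():
        for start, end in regions:
            protected[locus].update(range(start, end + 1))

    products: dict[str, dict[str, SequenceRecord]] = {
        locus: {} for locus in references
    }
    for pid in origin:
        for locus, aln in references.items():
            ref = aln.record(source_ref[pid])
            residues = list(ref.residues)
            # near-identity: at most one substitution, off the planted sites
            if rng.random() < 0.5:
                pos = int(rng.integers(1, aln.length + 1))
                if pos not in protected[locus] and residues[pos - 1] in "ACGT":
                    current = residues[pos - 1]
                    alts = [b for b in "ACGT" if b != current]
                    residues[pos - 1] = alts[int(rng.integers(0, 3))]
            products[locus][pid] = SequenceRecord(
                id=pid, residues="".join(residues), source="product"
            )
        if pid in mix_source:
            for locus, aln in references.items():
                ref = aln.record(mix_source[pid])
                products[locus][f"{pid}-mix"] = SequenceRecord(
                    id=f"{pid}-mix", residues=ref.residues, source="product"
                )
    return TeaFixture(
        references=references,
        products=products,
        mixtures=mixtures,
        product_origin=origin,
        truth=truth,
        seed=seed,
    )
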