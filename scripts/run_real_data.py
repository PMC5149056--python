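#!/usr/bin/env python
"""Re-run the diagnostic analyses on real marker datasets.

The synthetic bundle exercises every stage offline; this script applies
the identical pipeline to real plant-barcode data (e.g. rbcLa / rbcLb /
matK amplicons of a focal subfamily plus comparison groups, assembled
from public sequence repositories and aligned externally).  It expects,
per marker, an aligned FASTA and one shared tab-separated label table
(columns: id, accession, subfamily, tribe, genus, species, source), e.g.::

    data/
      rbcLa.fasta  rbcLb.fasta  matK.fasta  labels.tsv

Run:
    python scripts/run_real_data.py --data-dir data --rank genus \
        --out results/real_data

It reports the marker information-content table (length, conserved,
variable, parsimony-informative, singleton sites and haplotypes per
dataset), the diagnostic formulas learned per class on each single-locus
and combined frame, and — if a universal primer pair is configured via
--assay-config (YAML with locus, group_rank, universal_forward/reverse)
— the predicted multiplex band patterns.  Sequence retrieval and
alignment are deliberately out of scope: this tool never touches the
network.
"""

from __future__ import annotations

import argparse
from pathlib import Path

import yaml

from herbdx.alignment import concatenate_loci, read_alignment
from herbdx.assay import assay_table, design_assay, simulate_multiplex
from herbdx.profiling import information_table
from herbdx.rules import LearnerParams, learn_rules, write_rulebook


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, required=True)
    parser.add_argument("--labels", type=Path, default=None,
                        help="label table (default: <data-dir>/labels.tsv)")
    parser.add_argument("--rank", default="genus")
    parser.add_argument("--max-literals", type=int, default=5)
    parser.add_argument("--assay-config", type=Path, default=None)
    parser.add_argument("--out", type=Path, required=True)
    args = parser.parse_args()

    labels = args.labels or args.data_dir / "labels.tsv"
    fastas = sorted(args.data_dir.glob("*.fasta"))
    if not fastas:
        raise SystemExit(f"no .fasta files in {args.data_dir}")
    alignments = {p.stem: read_alignment(p, labels, p.stem) for p in fastas}
    datasets = dict(alignments)
    if len(alignments) > 1:
        combined = concatenate_loci(list(alignments.values()), allow_missing=True)
        datasets["combined"] = combined

    args.out.mkdir(parents=True, exist_ok=True)
    info = information_table(datasets)
    info.to_csv(args.out / "information_content.tsv", sep="\t", index=False)
    print(info.to_string(index=False))

    for name, aln in datasets.items():
        labeled = aln.subset([r.id for r in aln.records if r.label(args.rank)])
        if len(labeled.classes(args.rank)) < 2:
            continue
        rules = learn_rules(
            labeled, args.rank, LearnerParams(max_literals=args.max_literals)
        )
        write_rulebook(rules, args.rank, name, args.out / f"rulebook_{name}.tsv")
        n_dx = sum(f is not None for f, _ in rules.values())
        print(f"{name}: {n_dx}/{len(rules)} classes with a diagnostic formula")

    if args.assay_config:
        cfg = yaml.safe_load(args.assay_config.read_text())
        aln = datasets[cfg["locus"]]
        rank = cfg["group_rank"]
        groups = {
            cls: [r.id for r in aln.records if r.label(rank) == cls]
            for cls in aln.classes(rank)
        }
        uf, ur = cfg["universal_forward"], cfg["universal_reverse"]
        assay = design_assay(
            aln,
            groups,
            (int(uf["start"]), int(uf["length"])),
            (int(ur["start"]), int(ur["length"])),
            tm_window=float(cfg.get("tm_window", 15)),
        )
        assay_table(assay).to_csv(args.out / "assay.tsv", sep="\t", index=False)
        gel = simulate_multiplex(assay, {r.id: [r] for r in aln.records})
        gel.to_csv(args.out / "virtual_gel.tsv", sep="\t", index=False)
        print(f"assay designed; expected bands: "
              f"{[assay.expected_fragment(g) for g in assay.diagnostics]}"
              f" + control {assay.control_fragment}")


if __name__ == "__main__":
    main()
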