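"""Shared fixtures: the synthetic tea bundle and random-alignment factories."""

from __future__ import annotations

import numpy as np
import pytest

from herbdx.alignment import LabeledAlignment, SequenceRecord, concatenate_loci
from herbdx.simulate import make_tea_fixture

BASES = np.array(list("ACGT"))


def random_alignment(
    seed: int,
    n_records: int = 6,
    n_cols: int = 40,
    noise: float = 0.0,
    n_classes: int = 0,
    rank: str = "genus",
    locus: str = "rnd",
) -> LabeledAlignment:
    """Random alignment, optionally with class labels and gap/N noise."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_records):
        residues = list(BASES[rng.integers(0, 4, n_cols)])
        if noise:
            for j in np.nonzero(rng.random(n_cols) < noise)[0]:
                residues[j] = "N" if rng.random() < 0.5 else "-"
        labels = {}
        if n_classes:
            labels[rank] = f"class{i % n_classes}"
        records.append(
            SequenceRecord(id=f"r{i}", residues="".join(residues), labels=labels)
        )
    return LabeledAlignment(records=records, locus=locus)


def clustered_alignment(
    seed: int,
    n_classes: int = 4,
    per_class: int = 3,
    n_cols: int = 30,
    class_divergence: float = 0.2,
    within_divergence: float = 0.03,
    rank: str = "genus",
) -> LabeledAlignment:
    """Class-structured alignment: shared ancestor, per-class then
    per-record uniform substitution."""
    rng = np.random.default_rng(seed)
    root = rng.integers(0, 4, n_cols)

    def mutate(seq, rate):
        out = seq.copy()
        hits = np.nonzero(rng.random(n_cols) < rate)[0]
        out[hits] = (out[hits] + rng.integers(1, 4, size=hits.size)) % 4
        return out

    records = []
    for c in range(n_classes):
        anc = mutate(root, class_divergence)
        for k in range(per_class):
            seq = mutate(anc, within_divergence)
            records.append(
                SequenceRecord(
                    id=f"c{c}r{k}",
                    residues="".join(BASES[seq]),
                    labels={rank: f"class{c}"},
                )
            )
    return LabeledAlignment(records=records, locus="clustered")


@pytest.fixture(scope="session")
def tea():
    return make_tea_fixture(1)


@pytest.fixture(scope="session")
def tea_combined(tea):
    combined = concatenate_loci(
        [tea.references["cpA"], tea.references["cpB"], tea.references["nuc"]]
    )
    return combined
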