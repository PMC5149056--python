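"""Per-column information content of an alignment.

For each dataset this computes the classic marker-evaluation summary:
alignment length, conserved / variable columns, the split of variable
columns into parsimony-informative and singleton sites, and the number of
distinct haplotypes.  Gaps and IUPAC ambiguity codes are treated as missing
data for site classification (pairwise-deletion spirit); haplotypes are
counted on the complete-deletion matrix (columns clean in every record).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .alignment import (
    UNAMBIGUOUS,
    DegenerateInputError,
    LabeledAlignment,
)


@dataclass
class SiteProfile:
    """One row of a marker information-content table.

    ``excluded`` counts columns with fewer than two unambiguous bases,
    which cannot be classified; ``conserved + variable + excluded`` equals
    ``length``.  Percentages follow the conventional layout: variable as a
    share of length, parsimony-informative and singleton as shares of the
    variable columns.
    """

    dataset: str
    length: int
    conserved: int
    variable: int
    parsimony_informative: int
    singleton: int
    excluded: int = 0
    haplotypes: int | None = None

    @property
    def variable_pct(self) -> float:
        return round(100.0 * self.variable / self.length, 1) if self.length else 0.0

    @property
    def pai_pct_of_var(self) -> float:
        if not self.variable:
            return 0.0
        return round(100.0 * self.parsimony_informative / self.variable, 1)

    @property
    def sin_pct_of_var(self) -> float:
        if not self.variable:
            return 0.0
        return round(100.0 * self.singleton / self.variable, 1)


def classify_column(column: str) -> str:
    """Classify one column string as conserved/variable/informative/singleton.

    Only unambiguous bases (A, C, G, T) are considered.  Columns with fewer
    than two such bases are 'excluded'; one distinct base is 'conserved';
    two or more distinct bases are variable, and a variable column with at
    least two bases each occurring at least twice is 'informative',
    otherwise 'singleton'.
    """
    counts = Counter(sym for sym in column.upper() if sym in UNAMBIGUOUS)
    n_bases = sum(counts.values())
    if n_bases < 2:
        return "excluded"
    if len(counts) == 1:
        return "conserved"
    if sum(1 for c in counts.values() if c >= 2) >= 2:
        return "informative"
    return "singleton"


def classify_sites(aln: LabeledAlignment, dataset: str | None = None) -> SiteProfile:
    """Count conserved / variable / parsimony-informative / singleton columns."""
    if len(aln.records) < 2:
        raise DegenerateInputError(
            f"site classification needs >= 2 records, got {len(aln.records)}"
        )
    tally = Counter(classify_column(aln.column(pos)) for pos in range(1, aln.length + 1))
    informative = tally["informative"]
    singleton = tally["singleton"]
    return SiteProfile(
        dataset=dataset or aln.locus,
        length=aln.length,
        conserved=tally["conserved"],
        variable=informative + singleton,
        parsimony_informative=informative,
        singleton=singleton,
        excluded=tally["excluded"],
    )


def count_haplotypes(aln: LabeledAlignment) -> int:
    """Number of distinct sequences over columns clean in every record.

    A column is clean when no record shows a gap or ambiguity there
    (complete deletion).  If no column is clean, all records collapse to
    one (empty) haplotype.
    """
    clean_cols = [
        pos
        for pos in range(1, aln.length + 1)
        if all(sym in UNAMBIGUOUS for sym in aln.column(pos))
    ]
    variants = {
        "".join(rec.residues[pos - 1] for pos in clean_cols) for rec in aln.records
    }
    return len(variants)


def profile_dataset(aln: LabeledAlignment, dataset: str | None = None) -> SiteProfile:
    """classify_sites plus the haplotype count."""
    profile = classify_sites(aln, dataset=dataset)
    profile.haplotypes = count_haplotypes(aln)
    return profile


TABLE_COLUMNS = ["Marker", "Len", "Con", "Var", "Var%", "PaI", "PaI%", "Sin", "Sin%", "Hap"]


def information_table(datasets: dict[str, LabeledAlignment]) -> pd.DataFrame:
    """One information-content row per named dataset, percentages to 1 decimal."""
    rows = []
    for name, aln in datasets.items():
        p = profile_dataset(aln, dataset=name)
        rows.append(
            {
                "Marker": name,
                "Len": p.length,
                "Con": p.conserved,
                "Var": p.variable,
                "Var%": p.variable_pct,
                "PaI": p.parsimony_informative,
                "PaI%": p.pai_pct_of_var,
                "Sin": p.singleton,
                "Sin%": p.sin_pct_of_var,
                "Hap": p.haplotypes,
            }
        )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)
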