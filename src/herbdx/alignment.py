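"""Labeled multiple sequence alignments and locus assembly.

This module holds the in-memory containers used across the package — DNA
sequence records carrying taxonomic labels (subfamily / tribe / genus /
species) and a source category (specimen / product / database) — together
with the preprocessing steps that turn per-locus FASTA files into
analysis-ready single- and multi-locus alignment frames:

* merging bi-directional sequencing reads into an IUPAC consensus,
* trimming alignment ends against reference sequences,
* merging two loci that overlap (e.g. two amplicons of one gene), and
* concatenating loci into one combined frame with a coordinate map.

All column coordinates are 1-based, closed intervals, and every report
states which frame (locus or combined) a position refers to.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RANKS = ("subfamily", "tribe", "genus", "species")
SOURCES = frozenset({"specimen", "product", "database"})

#: base -> set of unambiguous bases the symbol can stand for.  Gaps map to
#: the empty set ("known absent"), N to all four ("unknown").
IUPAC_SETS: dict[str, frozenset[str]] = {
    code.upper(): frozenset(bases) for code, bases in ambiguous_dna_values.items()
}
IUPAC_SETS["-"] = frozenset()
IUPAC_SETS["?"] = frozenset()
IUPAC_SETS["U"] = frozenset("T")

#: set of unambiguous bases -> IUPAC code covering exactly that set.
SET_TO_IUPAC: dict[frozenset[str], str] = {
    frozenset(bases): code.upper()
    for code, bases in ambiguous_dna_values.items()
    if code.upper() != "X"
}

UNAMBIGUOUS = frozenset("ACGT")


class AlignmentError(ValueError):
    """Sequences violate an alignment invariant (e.g. unequal lengths)."""


class LabelingError(ValueError):
    """A sequence id is missing from, or inconsistent with, the label table."""


class FrameError(ValueError):
    """A position, primer or formula refers to a different coordinate frame."""


class MergeError(ValueError):
    """Two loci could not be overlap-merged."""


class DegenerateInputError(ValueError):
    """The operation is undefined on this input (too few records/columns)."""


@dataclass
class SequenceRecord:
    """One aligned DNA sequence with taxonomy labels and provenance."""

    id: str
    residues: str
    accession: str = ""
    labels: dict[str, str] = field(default_factory=dict)
    source: str = "specimen"

    def __post_init__(self) -> None:
        if not self.residues:
            raise AlignmentError(f"record {self.id!r} has empty residues")
        self.residues = self.residues.upper()
        if self.source not in SOURCES:
            raise LabelingError(
                f"record {self.id!r}: unknown source {self.source!r} "
                f"(expected one of {sorted(SOURCES)})"
            )
        for rank, name in self.labels.items():
            if rank not in RANKS:
                raise LabelingError(f"record {self.id!r}: unknown rank {rank!r}")
            if name is None:
                self.labels[rank] = ""

    def label(self, rank: str) -> str:
        return self.labels.get(rank, "")

    def base_set(self, position: int) -> frozenset[str]:
        """Unambiguous bases compatible with the symbol at a 1-based position."""
        sym = self.residues[position - 1]
        try:
            return IUPAC_SETS[sym]
        except KeyError:
            raise AlignmentError(
                f"record {self.id!r}: unknown symbol {sym!r} at position {position}"
            ) from None


@dataclass
class LabeledAlignment:
    """Equal-length sequence records under one locus name.

    ``offset`` records how many leading columns were removed by trimming so
    original per-locus coordinates stay recoverable
    (original = trimmed position + offset).
    """

    records: list[SequenceRecord]
    locus: str
    offset: int = 0

    def __post_init__(self) -> None:
        if not self.records:
            raise DegenerateInputError(f"alignment {self.locus!r} has no records")
        length = len(self.records[0].residues)
        seen: set[str] = set()
        for rec in self.records:
            if len(rec.residues) != length:
                raise AlignmentError(
                    f"alignment {self.locus!r}: record {rec.id!r} has length "
                    f"{len(rec.residues)}, expected {length}"
                )
            if rec.id in seen:
                raise AlignmentError(f"alignment {self.locus!r}: duplicate id {rec.id!r}")
            seen.add(rec.id)

    @property
    def length(self) -> int:
        return len(self.records[0].residues)

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    def record(self, rec_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == rec_id:
                return rec
        raise KeyError(rec_id)

    def column(self, position: int) -> str:
        """Residues of one 1-based column, in record order."""
        if not 1 <= position <= self.length:
            raise FrameError(
                f"position {position} outside 1..{self.length} of {self.locus!r}"
            )
        i = position - 1
        return "".join(rec.residues[i] for rec in self.records)

    def classes(self, rank: str) -> list[str]:
        """Distinct non-empty class names at a rank, in first-seen order."""
        out: list[str] = []
        for rec in self.records:
            name = rec.label(rank)
            if name and name not in out:
                out.append(name)
        return out

    def subset(self, ids: list[str]) -> "LabeledAlignment":
        keep = set(ids)
        recs = [rec for rec in self.records if rec.id in keep]
        missing = keep - {r.id for r in recs}
        if missing:
            raise KeyError(f"ids not in alignment {self.locus!r}: {sorted(missing)}")
        return replace(self, records=recs)

    def column_checksum(self, start: int, end: int) -> str:
        """SHA1 of columns start..end (1-based, inclusive), for trim audits."""
        payload = "\n".join(rec.residues[start - 1 : end] for rec in self.records)
        return hashlib.sha1(payload.encode()).hexdigest()


@dataclass(frozen=True)
class Segment:
    """One locus' span inside a combined frame (1-based, closed)."""

    locus: str
    start: int
    end: int


@dataclass
class ConcatenatedAlignment(LabeledAlignment):
    """Combined frame over several loci with a column -> locus map."""

    segments: list[Segment] = field(default_factory=list)
    overlap_log: list[tuple[str, str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.segments:
            pos = 1
            for seg in self.segments:
                if seg.start != pos or seg.end < seg.start:
                    raise FrameError(
                        f"segments do not tile the combined frame at {seg}"
                    )
                pos = seg.end + 1
            if pos != self.length + 1:
                raise FrameError(
                    f"segments cover 1..{pos - 1} but frame has {self.length} columns"
                )

    def map_position(self, position: int) -> tuple[str, int]:
        """Map a combined 1-based column to (primary locus, local position)."""
        if not 1 <= position <= self.length:
            raise FrameError(f"position {position} outside combined frame")
        for seg in self.segments:
            if seg.start <= position <= seg.end:
                return seg.locus, position - seg.start + 1
        raise FrameError(f"position {position} not covered by any segment")


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

LABEL_COLUMNS = ["id", "accession", "subfamily", "tribe", "genus", "species", "source"]


def read_label_table(path) -> pd.DataFrame:
    """Read a tab-separated label table (id/accession/ranks/source)."""
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("id", "source") if c not in table.columns]
    if missing:
        raise LabelingError(f"label table {path} lacks column(s) {missing}")
    if table["id"].duplicated().any():
        dups = table.loc[table["id"].duplicated(), "id"].tolist()
        raise LabelingError(f"label table {path} has duplicate id(s) {dups}")
    return table


def write_label_table(records: list[SequenceRecord], path) -> None:
    rows = [
        {
            "id": rec.id,
            "accession": rec.accession,
            **{rank: rec.label(rank) for rank in RANKS},
            "source": rec.source,
        }
        for rec in records
    ]
    pd.DataFrame(rows, columns=LABEL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_alignment(fasta_path, label_table_path, locus: str) -> LabeledAlignment:
    """Read an aligned FASTA plus its label table into a LabeledAlignment.

    Every FASTA id must appear in the label table; input order is preserved
    and residues are uppercased.  Ranks absent from the table are recorded
    as empty class names.
    """
    table = read_label_table(label_table_path).set_index("id")
    records: list[SequenceRecord] = []
    length: int | None = None
    for seq_rec in SeqIO.parse(str(fasta_path), "fasta"):
        residues = str(seq_rec.seq)
        if length is None:
            length = len(residues)
        elif len(residues) != length:
            raise AlignmentError(
                f"{fasta_path}: record {seq_rec.id!r} has length "
                f"{len(residues)}, expected {length}"
            )
        if seq_rec.id not in table.index:
            raise LabelingError(
                f"{fasta_path}: id {seq_rec.id!r} missing from label table "
                f"{label_table_path}"
            )
        row = table.loc[seq_rec.id]
        labels = {rank: str(row.get(rank, "") or "") for rank in RANKS}
        records.append(
            SequenceRecord(
                id=seq_rec.id,
                residues=residues,
                accession=str(row.get("accession", "") or ""),
                labels=labels,
                source=str(row["source"]),
            )
        )
    if not records:
        raise DegenerateInputError(f"{fasta_path}: no FASTA records")
    return LabeledAlignment(records=records, locus=locus)


def write_alignment(aln: LabeledAlignment, fasta_path, label_table_path=None) -> None:
    """Write an alignment as FASTA (and optionally its label table as TSV)."""
    seqs = [SeqRecord(Seq(rec.residues), id=rec.id, description="") for rec in aln.records]
    SeqIO.write(seqs, str(fasta_path), "fasta")
    if label_table_path is not None:
        write_label_table(aln.records, label_table_path)


def write_segment_map(aln: ConcatenatedAlignment, path) -> None:
    pd.DataFrame(
        [{"locus": s.locus, "start": s.start, "end": s.end} for s in aln.segments]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# read merging
# ---------------------------------------------------------------------------

def merge_bidirectional_reads(
    forward: str, reverse_complemented: str
) -> tuple[str, list[tuple[int, str, str]]]:
    """Merge two reads of one template into an IUPAC consensus.

    Both reads must already sit in the same frame (equal length; pad with N
    before calling).  Per position: agreeing symbols are kept; an N (or gap)
    in one read is recovered from the other; two disagreeing unambiguous
    bases produce the IUPAC code covering both and are listed in the
    conflict report as (1-based position, forward symbol, reverse symbol).
    """
    if len(forward) != len(reverse_complemented):
        raise FrameError(
            f"reads differ in length ({len(forward)} vs {len(reverse_complemented)})"
        )
    fwd = forward.upper()
    rev = reverse_complemented.upper()
    consensus: list[str] = []
    conflicts: list[tuple[int, str, str]] = []
    for i, (a, b) in enumerate(zip(fwd, rev), start=1):
        if a == b:
            consensus.append(a)
            continue
        sa = IUPAC_SETS.get(a, frozenset())
        sb = IUPAC_SETS.get(b, frozenset())
        if sa >= UNAMBIGUOUS or not sa:  # N or gap: take the other read
            consensus.append(b)
        elif sb >= UNAMBIGUOUS or not sb:
            consensus.append(a)
        else:
            union = frozenset(sa | sb)
            consensus.append(SET_TO_IUPAC.get(union, "N"))
            conflicts.append((i, a, b))
    return "".join(consensus), conflicts


# ---------------------------------------------------------------------------
# trimming and locus combination
# ---------------------------------------------------------------------------

def trim_to_reference(
    aln: LabeledAlignment,
    reference_ids: list[str],
    trim_symbols: frozenset[str] = frozenset("-"),
) -> LabeledAlignment:
    """Trim leading/trailing columns where every reference has a gap.

    Mirrors trimming an alignment to the extent actually sequenced in one's
    own specimens: columns at either end in which *all* reference sequences
    show a symbol from ``trim_symbols`` (gap by default; pass ``{'-', 'N'}``
    to also drop primer-masked ends) are removed.  Interior columns are
    never touched.  The returned alignment records the left offset so
    original coordinates remain recoverable.
    """
    if not reference_ids:
        raise DegenerateInputError("reference_ids must be non-empty")
    refs = [aln.record(rid) for rid in reference_ids]

    def all_trimmable(position: int) -> bool:
        return all(rec.residues[position - 1] in trim_symbols for rec in refs)

    start = 1
    while start <= aln.length and all_trimmable(start):
        start += 1
    end = aln.length
    while end >= start and all_trimmable(end):
        end -= 1
    if start > end:
        raise DegenerateInputError(
            f"trimming {aln.locus!r} to references {reference_ids} removes every column"
        )
    records = [
        replace(rec, residues=rec.residues[start - 1 : end], labels=dict(rec.labels))
        for rec in aln.records
    ]
    return LabeledAlignment(records=records, locus=aln.locus, offset=aln.offset + start - 1)


def _merged_labels(a: SequenceRecord, b: SequenceRecord) -> dict[str, str]:
    labels = dict(a.labels)
    for rank, name in b.labels.items():
        if name and not labels.get(rank):
            labels[rank] = name
    return labels


def merge_overlapping_loci(
    aln_a: LabeledAlignment,
    aln_b: LabeledAlignment,
    anchor_ids: list[str],
    min_overlap: int = 20,
) -> ConcatenatedAlignment:
    """Merge two loci whose ends overlap (e.g. two amplicons of one gene).

    The overlap is detected as the longest suffix of ``aln_a`` equal to a
    prefix of ``aln_b`` across *all* anchor sequences (>= ``min_overlap``
    columns).  Shared columns appear once, attributed to ``aln_a``; for
    non-anchor records a disagreement inside the overlap is resolved in
    favour of ``aln_a`` and logged.
    """
    if not anchor_ids:
        raise DegenerateInputError("anchor_ids must be non-empty")
    ids_a, ids_b = set(aln_a.ids), set(aln_b.ids)
    for aid in anchor_ids:
        if aid not in ids_a or aid not in ids_b:
            raise KeyError(f"anchor {aid!r} must be present in both loci")
    if ids_a != ids_b:
        raise MergeError(
            "loci must contain identical record sets for overlap merging; "
            f"only-in-{aln_a.locus}: {sorted(ids_a - ids_b)}, "
            f"only-in-{aln_b.locus}: {sorted(ids_b - ids_a)}"
        )

    max_k = min(aln_a.length, aln_b.length)
    overlap = 0
    for k in range(max_k, min_overlap - 1, -1):
        if all(
            aln_a.record(aid).residues[-k:] == aln_b.record(aid).residues[:k]
            for aid in anchor_ids
        ):
            overlap = k
            break
    if overlap == 0:
        raise MergeError(
            f"no overlap of >= {min_overlap} columns between {aln_a.locus!r} "
            f"and {aln_b.locus!r} on anchors {anchor_ids}"
        )

    records: list[SequenceRecord] = []
    disagreements = 0
    for rec_a in aln_a.records:
        rec_b = aln_b.record(rec_a.id)
        if rec_a.residues[-overlap:] != rec_b.residues[:overlap]:
            if rec_a.id in anchor_ids:
                raise MergeError(
                    f"anchor {rec_a.id!r} disagrees inside the {overlap}-column overlap"
                )
            disagreements += 1  # non-anchor: locus A wins
        records.append(
            SequenceRecord(
                id=rec_a.id,
                residues=rec_a.residues + rec_b.residues[overlap:],
                accession=rec_a.accession or rec_b.accession,
                labels=_merged_labels(rec_a, rec_b),
                source=rec_a.source,
            )
        )
    merged_len = aln_a.length + aln_b.length - overlap
    locus = f"{aln_a.locus}+{aln_b.locus}"
    segments = [
        Segment(aln_a.locus, 1, aln_a.length),
        Segment(aln_b.locus, aln_a.length + 1, merged_len),
    ]
    if segments[1].start > merged_len:  # B entirely inside A's span
        segments = segments[:1]
    merged = ConcatenatedAlignment(
        records=records,
        locus=locus,
        segments=segments,
        overlap_log=[(aln_a.locus, aln_b.locus, overlap)],
    )
    merged.disagreement_count = disagreements  # type: ignore[attr-defined]
    return merged


def concatenate_loci(
    alignments: list[LabeledAlignment],
    allow_missing: bool = False,
    fill: str = "N",
) -> ConcatenatedAlignment:
    """Concatenate loci into one combined frame.

    Record order follows the first alignment (new ids appended in order of
    appearance).  An id absent from a locus is an error unless
    ``allow_missing`` is set, in which case that locus is filled with ``N``
    ("unknown", not gap).
    """
    if not alignments:
        raise DegenerateInputError("no alignments to concatenate")
    order: list[str] = []
    for aln in alignments:
        for rec_id in aln.ids:
            if rec_id not in order:
                order.append(rec_id)

    segments: list[Segment] = []
    pos = 1
    overlap_log: list[tuple[str, str, int]] = []
    for aln in alignments:
        if isinstance(aln, ConcatenatedAlignment) and aln.segments:
            for seg in aln.segments:
                shifted = Segment(seg.locus, seg.start + pos - 1, seg.end + pos - 1)
                segments.append(shifted)
            overlap_log.extend(aln.overlap_log)
        else:
            segments.append(Segment(aln.locus, pos, pos + aln.length - 1))
        pos += aln.length

    records: list[SequenceRecord] = []
    for rec_id in order:
        parts: list[str] = []
        accession = ""
        labels: dict[str, str] = {}
        source = None
        for aln in alignments:
            if rec_id in set(aln.ids):
                rec = aln.record(rec_id)
                parts.append(rec.residues)
                accession = accession or rec.accession
                for rank, name in rec.labels.items():
                    if name and not labels.get(rank):
                        labels[rank] = name
                source = source or rec.source
            elif allow_missing:
                parts.append(fill * aln.length)
            else:
                raise LabelingError(
                    f"record {rec_id!r} missing from locus {aln.locus!r} "
                    "(set allow_missing to fill with N)"
                )
        records.append(
            SequenceRecord(
                id=rec_id,
                residues="".join(parts),
                accession=accession,
                labels=labels,
                source=source or "specimen",
            )
        )
    locus = "+".join(a.locus for a in alignments)
    return ConcatenatedAlignment(
        records=records, locus=locus, segments=segments, overlap_log=overlap_log
    )
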