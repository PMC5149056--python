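"""ARMS assay design and in-silico multiplex PCR.

Allele-specific (ARMS) diagnostics place a primer's 3'-terminal base on a
single nucleotide that is fixed in the target group and absent from all
other groups, so that Taq extension — which tolerates internal mismatches
but not a 3'-terminal one — only proceeds on target templates.  A second,
deliberately destabilizing internal mismatch (by default at the third base
from the 3' end) sharpens that discrimination.  Run in multiplex with a
universal primer pair, every template yields the long control fragment
while only targets add the shorter group-specific band, giving a virtual
gel that separates mixtures by their component groups.

Geometry convention: a reverse primer with its 3' terminus on alignment
column P occupies columns P .. P+len-1 of the template's top strand (its
sequence is the reverse complement of that region); a forward primer with
3' terminus on P occupies P-len+1 .. P.  Fragment size counts template
columns spanned from the forward primer's 5' end to the reverse primer's
5' end, inclusive of both footprints, after removing the template's gap
columns within the span.

The binding model is deliberately coarse — exact 3'-terminal match plus a
small internal mismatch budget — sufficient to predict band patterns but
not PCR efficiency.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp, gc_fraction

from .alignment import (
    UNAMBIGUOUS,
    DegenerateInputError,
    FrameError,
    LabeledAlignment,
    SequenceRecord,
)

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class PartitionError(ValueError):
    """The group partition is invalid (empty or unknown groups)."""


class DesignFailure(RuntimeError):
    """No primer candidate satisfied the design constraints."""

    def __init__(self, violations: list[str]):
        super().__init__("; ".join(violations) or "no candidates")
        self.violations = violations


@dataclass(frozen=True)
class DiagnosticSite:
    """A column fixed for one base in the target group and absent elsewhere."""

    position: int
    target_group: str
    target_state: str
    other_states: frozenset[str]


def find_diagnostic_sites(
    aln: LabeledAlignment, groups: dict[str, list[str]]
) -> dict[str, list[DiagnosticSite]]:
    """Columns where each group is fixed for a base no other group carries.

    The target group must be unambiguous and identical at the column; the
    comparison set is the unambiguous bases observed in all other groups
    (an N or gap elsewhere does not block a site).  Results per group are
    sorted by position.
    """
    if len(groups) < 2:
        raise PartitionError(f"need >= 2 groups, got {list(groups)}")
    members: dict[str, list[SequenceRecord]] = {}
    for name, ids in groups.items():
        if not ids:
            raise PartitionError(f"group {name!r} is empty")
        members[name] = [aln.record(i) for i in ids]

    out: dict[str, list[DiagnosticSite]] = {name: [] for name in groups}
    for pos in range(1, aln.length + 1):
        group_bases = {
            name: {rec.residues[pos - 1] for rec in recs}
            for name, recs in members.items()
        }
        for name, bases in group_bases.items():
            if len(bases) != 1:
                continue
            (state,) = bases
            if state not in UNAMBIGUOUS:
                continue
            others = {
                b
                for other, obases in group_bases.items()
                if other != name
                for b in obases
                if b in UNAMBIGUOUS
            }
            if state not in others:
                out[name].append(
                    DiagnosticSite(
                        position=pos,
                        target_group=name,
                        target_state=state,
                        other_states=frozenset(others),
                    )
                )
    return out


#: mispair stability ranking after the usual ARMS guidance: G.T pairs are
#: near-canonical, purine.purine mispairs intermediate, C.C the weakest.
#: Lower value = weaker pairing = stronger destabilization.
MISPAIR_STABILITY = {
    frozenset("GT"): 5,
    frozenset("GG"): 4,
    frozenset("GA"): 3,
    frozenset("AA"): 2,
    frozenset("TT"): 2,
    frozenset("CT"): 1,
    frozenset("AC"): 1,
    frozenset("CC"): 0,
}


def _pair_stability(primer_base: str, template_base: str) -> int:
    if primer_base == COMPLEMENT.get(template_base):
        return 10  # perfect pair
    return MISPAIR_STABILITY.get(frozenset((primer_base, template_base)), 2)


@dataclass(frozen=True)
class DestabilizationRule:
    """Where and how to place the intentional extra mismatch.

    ``offset`` counts from the 3' end with the terminal base as 1; the
    default (3) mutates the third base from the 3' end.  The substituted
    base is chosen to pair as weakly as possible with the target template
    while avoiding the creation of a perfect match to any non-target
    template at that column.
    """

    offset: int = 3

    def __post_init__(self) -> None:
        if self.offset < 2:
            raise ValueError("destabilizing mismatch may not sit on the 3' terminus")


@dataclass
class PrimerCandidate:
    """A primer written 5'->3' with its alignment anchoring and QC metrics."""

    sequence: str
    orientation: str  # "forward" | "reverse"
    anchor_position: int  # alignment column of the 3'-terminal base
    length: int
    destabilizing_mismatch: tuple[int, str] | None  # (offset from 3' end, base)
    tm: float
    gc: float
    flags: list[str] = field(default_factory=list)

    @property
    def footprint(self) -> tuple[int, int]:
        """Alignment columns covered (1-based, closed), on the top strand."""
        if self.orientation == "forward":
            return self.anchor_position - self.length + 1, self.anchor_position
        return self.anchor_position, self.anchor_position + self.length - 1


def _homopolymer_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _self_dimer_3p(seq: str, probe: int = 4) -> bool:
    """Crude self-complementarity check of the 3' terminus against the primer."""
    tail = seq[-probe:]
    rc_tail = str(Seq(tail).reverse_complement())
    return rc_tail in seq[:-1]


def _group_consensus_base(records: list[SequenceRecord], position: int) -> str | None:
    counts = Counter(
        rec.residues[position - 1]
        for rec in records
        if rec.residues[position - 1] in UNAMBIGUOUS
    )
    if not counts:
        return None
    # majority, deterministic tie-break by base
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]


def design_arms_primer(
    aln: LabeledAlignment,
    site: DiagnosticSite,
    groups: dict[str, list[str]],
    length_range: tuple[int, int] = (18, 30),
    orientation: str = "reverse",
    destabilization: DestabilizationRule | None = DestabilizationRule(),
    tm_target: float = 60.0,
    tm_window: float = 10.0,
    max_homopolymer: int = 5,
) -> list[PrimerCandidate]:
    """Design ranked allele-specific primer candidates for a diagnostic site.

    Candidates are built on the target group's consensus, one per length in
    ``length_range``, with the 3'-terminal base on the site (so it equals
    the target state on the primer's strand) and — unless
    ``destabilization`` is None — one extra internal mismatch at the
    configured offset.  Each candidate is annotated with a nearest-neighbor
    melting temperature, GC fraction, homopolymer and 3'-self-complement
    flags, and the list is ranked by closeness to ``tm_target``.

    Raises DesignFailure, listing the violated constraints, when no length
    yields an acceptable candidate (e.g. insufficient gap-free template or
    every Tm outside ``tm_target`` ± ``tm_window``).
    """
    if orientation not in ("forward", "reverse"):
        raise ValueError(f"unknown orientation {orientation!r}")
    lo, hi = length_range
    if not 15 <= lo <= hi <= 35:
        raise ValueError("primer lengths must lie within 15..35")
    target_records = [aln.record(i) for i in groups[site.target_group]]
    non_target_records = [
        aln.record(i)
        for name, ids in groups.items()
        if name != site.target_group
        for i in ids
    ]

    violations: list[str] = []
    candidates: list[PrimerCandidate] = []
    for length in range(lo, hi + 1):
        if orientation == "forward":
            cols = range(site.position - length + 1, site.position + 1)
        else:
            cols = range(site.position, site.position + length)
        if cols[0] < 1 or cols[-1] > aln.length:
            violations.append(
                f"len={length}: footprint {cols[0]}..{cols[-1]} outside the "
                f"1..{aln.length} frame (insufficient template)"
            )
            continue
        template = []
        gap_col = None
        for col in cols:
            base = _group_consensus_base(target_records, col)
            if base is None:
                gap_col = col
                break
            template.append(base)
        if gap_col is not None:
            violations.append(f"len={length}: no unambiguous target base at column {gap_col}")
            continue
        template_str = "".join(template)  # top strand, 5'->3'
        if orientation == "forward":
            primer = template_str
        else:
            primer = str(Seq(template_str).reverse_complement())
        # by construction the 3' base sits on the site
        expected_3p = (
            site.target_state
            if orientation == "forward"
            else COMPLEMENT[site.target_state]
        )
        assert primer[-1] == expected_3p

        mismatch = None
        if destabilization is not None:
            idx = length - destabilization.offset
            if idx < 0:
                violations.append(
                    f"len={length}: destabilization offset {destabilization.offset} "
                    "exceeds primer length"
                )
                continue
            # alignment column under the mutated primer base
            col = (
                cols[idx]
                if orientation == "forward"
                else cols[length - 1 - idx]
            )
            template_base = template_str[idx if orientation == "forward" else length - 1 - idx]
            original = primer[idx]

            def creates_nontarget_match(base: str) -> bool:
                for rec in non_target_records:
                    tb = rec.residues[col - 1]
                    if tb in UNAMBIGUOUS and base == COMPLEMENT[tb]:
                        return True
                return False

            options = [b for b in "ACGT" if b != original]
            safe = [b for b in options if not creates_nontarget_match(b)] or options
            sub = min(safe, key=lambda b: (_pair_stability(b, template_base), b))
            primer = primer[:idx] + sub + primer[idx + 1 :]
            mismatch = (destabilization.offset, sub)

        tm = MeltingTemp.Tm_NN(Seq(primer))
        flags = []
        if _homopolymer_run(primer) > max_homopolymer:
            flags.append(f"homopolymer>{max_homopolymer}")
        if _self_dimer_3p(primer):
            flags.append("3p-self-complement")
        if abs(tm - tm_target) > tm_window:
            violations.append(
                f"len={length}: Tm {tm:.1f} outside {tm_target}±{tm_window}"
            )
            continue
        if flags:
            violations.append(f"len={length}: {', '.join(flags)}")
            continue
        candidates.append(
            PrimerCandidate(
                sequence=primer,
                orientation=orientation,
                anchor_position=site.position,
                length=length,
                destabilizing_mismatch=mismatch,
                tm=round(tm, 2),
                gc=round(100 * gc_fraction(primer), 1),
                flags=flags,
            )
        )
    if not candidates:
        raise DesignFailure(violations)
    candidates.sort(key=lambda c: (abs(c.tm - tm_target), c.length))
    return candidates


# ---------------------------------------------------------------------------
# assay assembly and in-silico PCR
# ---------------------------------------------------------------------------

@dataclass
class ArmsAssay:
    """Universal primer pair plus per-group diagnostic reverse primers."""

    locus: str
    universal_forward: PrimerCandidate
    universal_reverse: PrimerCandidate
    diagnostics: dict[str, PrimerCandidate]
    mismatch_budget: int = 2

    def expected_fragment(self, group: str) -> int:
        """Diagnostic fragment size on a gap-free template."""
        d = self.diagnostics[group]
        return d.footprint[1] - self.universal_forward.footprint[0] + 1

    @property
    def control_fragment(self) -> int:
        return (
            self.universal_reverse.footprint[1]
            - self.universal_forward.footprint[0]
            + 1
        )


@dataclass
class BandPattern:
    """Predicted bands for one template (or mixture) and their reading."""

    template_id: str
    bands: list[int]
    interpretation: dict[str, bool]
    control: bool


def make_universal_primer(
    aln: LabeledAlignment, start: int, length: int, orientation: str
) -> PrimerCandidate:
    """Build a universal primer from the alignment consensus over all records.

    ``start`` is the leftmost top-strand column of the footprint.
    """
    cols = range(start, start + length)
    if cols[0] < 1 or cols[-1] > aln.length:
        raise FrameError(f"primer footprint {cols[0]}..{cols[-1]} outside frame")
    bases = []
    for col in cols:
        base = _group_consensus_base(aln.records, col)
        if base is None:
            raise DesignFailure([f"no unambiguous consensus at column {col}"])
        bases.append(base)
    template_str = "".join(bases)
    if orientation == "forward":
        primer, anchor = template_str, cols[-1]
    else:
        primer, anchor = str(Seq(template_str).reverse_complement()), cols[0]
    return PrimerCandidate(
        sequence=primer,
        orientation=orientation,
        anchor_position=anchor,
        length=length,
        destabilizing_mismatch=None,
        tm=round(MeltingTemp.Tm_NN(Seq(primer)), 2),
        gc=round(100 * gc_fraction(primer), 1),
    )


def design_assay(
    aln: LabeledAlignment,
    groups: dict[str, list[str]],
    universal_forward: tuple[int, int],
    universal_reverse: tuple[int, int],
    mismatch_budget: int = 2,
    min_band_separation: int = 10,
    **primer_kwargs,
) -> ArmsAssay:
    """Design a complete multiplex assay: universal pair + one diagnostic
    reverse primer per group.

    ``universal_forward`` / ``universal_reverse`` are (leftmost top-strand
    column, length) of the universal footprints.  For each group the
    diagnostic sites are tried in position order; the first site yielding a
    primer whose expected fragment is at least ``min_band_separation`` bp
    away from the control fragment and from every already-chosen band is
    used.  Each accepted primer is additionally verified in silico: it must
    bind every template of its own group and none of the others (zero
    cross-reactivity on the training alignment).  Raises DesignFailure if
    some group cannot be served.
    """
    uf = make_universal_primer(aln, universal_forward[0], universal_forward[1], "forward")
    ur = make_universal_primer(aln, universal_reverse[0], universal_reverse[1], "reverse")
    control = ur.footprint[1] - uf.footprint[0] + 1
    sites = find_diagnostic_sites(aln, groups)
    diagnostics: dict[str, PrimerCandidate] = {}
    taken_sizes = [control]
    failures: list[str] = []
    for group in groups:
        chosen = None
        target_ids = set(groups[group])
        for site in sites[group]:
            try:
                candidates = design_arms_primer(
                    aln, site, groups, orientation="reverse", **primer_kwargs
                )
            except DesignFailure as exc:
                failures.append(f"{group} pos{site.position}: {exc}")
                continue
            primer = candidates[0]
            size = primer.footprint[1] - uf.footprint[0] + 1
            if any(abs(size - s) < min_band_separation for s in taken_sizes):
                failures.append(
                    f"{group} pos{site.position}: fragment {size} too close to "
                    f"existing bands {taken_sizes}"
                )
                continue
            misses = [
                rec.id
                for rec in aln.records
                if rec.id in target_ids
                and not primer_binds(primer, rec, mismatch_budget)
            ]
            cross = [
                rec.id
                for rec in aln.records
                if rec.id not in target_ids and primer_binds(primer, rec, mismatch_budget)
            ]
            if misses or cross:
                failures.append(
                    f"{group} pos{site.position}: in-silico check failed "
                    f"(missed {misses}, cross-reactive {cross})"
                )
                continue
            chosen = primer
            taken_sizes.append(size)
            break
        if chosen is None:
            raise DesignFailure(
                [f"no usable diagnostic site for group {group!r}"] + failures
            )
        diagnostics[group] = chosen
    return ArmsAssay(
        locus=aln.locus,
        universal_forward=uf,
        universal_reverse=ur,
        diagnostics=diagnostics,
        mismatch_budget=mismatch_budget,
    )


def assay_table(assay: ArmsAssay) -> pd.DataFrame:
    """Tabular description of an assay (primers, footprints, expected bands)."""
    rows = [
        {
            "role": "universal_forward",
            "group": "",
            "sequence": assay.universal_forward.sequence,
            "anchor": assay.universal_forward.anchor_position,
            "length": assay.universal_forward.length,
            "tm": assay.universal_forward.tm,
            "gc": assay.universal_forward.gc,
            "expected_fragment": assay.control_fragment,
        },
        {
            "role": "universal_reverse",
            "group": "",
            "sequence": assay.universal_reverse.sequence,
            "anchor": assay.universal_reverse.anchor_position,
            "length": assay.universal_reverse.length,
            "tm": assay.universal_reverse.tm,
            "gc": assay.universal_reverse.gc,
            "expected_fragment": assay.control_fragment,
        },
    ]
    for group, primer in assay.diagnostics.items():
        rows.append(
            {
                "role": "diagnostic",
                "group": group,
                "sequence": primer.sequence,
                "anchor": primer.anchor_position,
                "length": primer.length,
                "tm": primer.tm,
                "gc": primer.gc,
                "expected_fragment": assay.expected_fragment(group),
            }
        )
    return pd.DataFrame(rows)


def primer_binds(
    primer: PrimerCandidate, template: SequenceRecord, mismatch_budget: int = 2
) -> bool:
    """Coarse annealing test of a primer against one aligned template.

    The 3'-terminal base must match exactly; total mismatches over the
    footprint, ignoring the intentional destabilizing mismatch, must stay
    within ``mismatch_budget`` and none may fall on the three 3'-terminal
    bases.  A template gap or ambiguity under the footprint counts as a
    mismatch.
    """
    start, end = primer.footprint
    if start < 1 or end > len(template.residues):
        raise FrameError(
            f"primer footprint {start}..{end} outside template {template.id!r}"
        )
    region = template.residues[start - 1 : end]
    if primer.orientation == "forward":
        expected = primer.sequence  # primer aligns to top strand directly
    else:
        expected = str(Seq(primer.sequence).reverse_complement())
    # index of the primer's 3' terminus within the top-strand footprint
    mismatches = 0
    for i, (p, t) in enumerate(zip(expected, region)):
        if p == t and t in UNAMBIGUOUS:
            continue
        # offset of this footprint column from the primer's 3' end (1 = terminus)
        offset = (len(expected) - i) if primer.orientation == "forward" else (i + 1)
        if offset == 1:
            return False
        if (
            primer.destabilizing_mismatch is not None
            and offset == primer.destabilizing_mismatch[0]
        ):
            continue
        if offset <= 3:
            return False
        mismatches += 1
        if mismatches > mismatch_budget:
            return False
    return True


def _span_size(template: SequenceRecord, start: int, end: int) -> int:
    """Template columns spanned, with that template's gap columns removed."""
    return sum(
        1 for sym in template.residues[start - 1 : end] if sym != "-"
    )


def predict_amplicons(assay: ArmsAssay, template: SequenceRecord) -> BandPattern:
    """Predict the band pattern of one template in the multiplex reaction."""
    bands: list[int] = []
    f_start = assay.universal_forward.footprint[0]
    forward_ok = primer_binds(assay.universal_forward, template, assay.mismatch_budget)
    control = forward_ok and primer_binds(
        assay.universal_reverse, template, assay.mismatch_budget
    )
    if control:
        bands.append(
            _span_size(template, f_start, assay.universal_reverse.footprint[1])
        )
    interpretation: dict[str, bool] = {}
    for group, dprimer in assay.diagnostics.items():
        hit = forward_ok and primer_binds(dprimer, template, assay.mismatch_budget)
        interpretation[group] = hit
        if hit:
            bands.append(_span_size(template, f_start, dprimer.footprint[1]))
    return BandPattern(
        template_id=template.id,
        bands=sorted(bands, reverse=True),
        interpretation=interpretation,
        control=control,
    )


def simulate_multiplex(
    assay: ArmsAssay,
    templates: dict[str, list[SequenceRecord]],
) -> pd.DataFrame:
    """Virtual gel for a set of templates or mixtures.

    ``templates`` maps a lane name to the template records in that sample
    (one for a pure sample, several for a mixture); the lane's bands are
    the union over its members and a group is read as present iff its
    diagnostic band appears.
    """
    if not templates:
        raise DegenerateInputError("no templates to simulate")
    rows = []
    for lane, members in templates.items():
        bands: set[int] = set()
        present = {group: False for group in assay.diagnostics}
        control = False
        for rec in members:
            pattern = predict_amplicons(assay, rec)
            bands.update(pattern.bands)
            control = control or pattern.control
            for group, hit in pattern.interpretation.items():
                present[group] = present[group] or hit
        rows.append(
            {
                "sample": lane,
                "bands": ",".join(str(b) for b in sorted(bands, reverse=True)),
                "control": "+" if control else "-",
                **{group: ("+" if hit else "-") for group, hit in present.items()},
            }
        )
    return pd.DataFrame(rows)
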