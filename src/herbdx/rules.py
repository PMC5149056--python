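"""Character-based diagnostic formulas (logic-rule barcoding).

A taxonomic class is diagnosed not by sequence distance but by a
conjunction of nucleotide-state literals such as::

    pos234=T AND pos490=T AND pos878=G          (positive literals)
    pos12=T AND pos701!=A                       (negated literal allowed)

The learner searches, per class, for the formula with zero false positives
(no out-of-class record satisfies it) and maximal coverage (share of
in-class records satisfying it), preferring fewer literals and breaking
remaining ties deterministically by position, polarity and state.  Search
is exact over all literal conjunctions up to three literals and continues
greedily beyond that, up to ``max_literals``.

Semantics of a literal on a record:

* ``pos=X`` is satisfied iff the record's base at ``pos`` is exactly the
  unambiguous base X — a gap or any ambiguity code fails it;
* ``pos!=X`` is satisfied iff the symbol's IUPAC base set excludes X, so
  an ambiguity covering X (or an N) fails it while a gap satisfies it.

Matching is case-insensitive; states are stored uppercase.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .alignment import (
    IUPAC_SETS,
    DegenerateInputError,
    FrameError,
    LabeledAlignment,
    LabelingError,
    SequenceRecord,
)

STATES = ("A", "C", "G", "T")


class ResourceError(RuntimeError):
    """An exhaustive enumeration would exceed its combinatorial guard."""


@dataclass(frozen=True, order=True)
class DiagnosticLiteral:
    """One position/state test; ``negated`` selects the pos!=X form."""

    position: int
    negated: bool
    state: str

    def satisfied_by(self, residues: str) -> bool:
        base_set = IUPAC_SETS.get(residues[self.position - 1].upper())
        if base_set is None:
            return False
        if self.negated:
            return self.state not in base_set
        return base_set == frozenset((self.state,))

    def __str__(self) -> str:
        op = "!=" if self.negated else "="
        return f"pos{self.position}{op}{self.state}"


@dataclass(frozen=True)
class DiagnosticFormula:
    """Conjunction of literals diagnosing one class within a frame."""

    rank: str
    class_name: str
    literals: tuple[DiagnosticLiteral, ...]
    frame: str = ""

    def __post_init__(self) -> None:
        if not self.literals:
            raise ValueError("a diagnostic formula needs at least one literal")
        positions = [lit.position for lit in self.literals]
        if len(set(positions)) != len(positions):
            raise ValueError(f"duplicate positions in formula {self}")

    def satisfied_by(self, residues: str) -> bool:
        return all(lit.satisfied_by(residues) for lit in self.literals)

    def __str__(self) -> str:
        return " AND ".join(str(lit) for lit in self.literals)


@dataclass
class RuleEvaluation:
    """Coverage / false-negative / false-positive bookkeeping for a formula."""

    coverage: float
    false_negative: float
    false_positives: int
    n_in_class: int
    n_out_class: int


@dataclass
class LearnerParams:
    """Learner knobs.

    ``padding``, ``percslicing`` and ``exclusivefs`` are accepted for
    provenance and mapped onto this implementation's behaviour: padding=1
    means single-column literals (no windows), percslicing=100 means the
    whole dataset is used for training (no held-out slices), and
    exclusivefs=1 enforces the zero-false-positive constraint.  Other
    values are rejected as unsupported rather than silently ignored.
    ``max_literals`` caps formula size (exact search up to three literals,
    greedy extension beyond).
    """

    padding: int = 1
    percslicing: int = 100
    exclusivefs: int = 1
    max_literals: int = 5
    seed: int = 0
    max_exact_pairs: int = 2_000_000
    max_exact_triples: int = 20_000_000

    def __post_init__(self) -> None:
        if self.max_literals < 1:
            raise ValueError("max_literals must be >= 1")
        if (self.padding, self.percslicing, self.exclusivefs) != (1, 100, 1):
            raise ValueError(
                "only padding=1, percslicing=100, exclusivefs=1 are supported"
            )


def evaluate_formula(
    formula: DiagnosticFormula, aln: LabeledAlignment
) -> RuleEvaluation:
    """Coverage over in-class records and false positives over the rest."""
    if formula.frame and formula.frame != aln.locus:
        raise FrameError(
            f"formula frame {formula.frame!r} does not match alignment {aln.locus!r}"
        )
    for lit in formula.literals:
        if not 1 <= lit.position <= aln.length:
            raise FrameError(
                f"literal position {lit.position} outside 1..{aln.length}"
            )
    in_class = [r for r in aln.records if r.label(formula.rank) == formula.class_name]
    out_class = [r for r in aln.records if r.label(formula.rank) != formula.class_name]
    if not in_class:
        raise DegenerateInputError(
            f"no records of {formula.rank}={formula.class_name!r} to evaluate on"
        )
    hits = sum(1 for r in in_class if formula.satisfied_by(r.residues))
    fp = sum(1 for r in out_class if formula.satisfied_by(r.residues))
    coverage = 100.0 * hits / len(in_class)
    return RuleEvaluation(
        coverage=coverage,
        false_negative=100.0 - coverage,
        false_positives=fp,
        n_in_class=len(in_class),
        n_out_class=len(out_class),
    )


# ---------------------------------------------------------------------------
# learning
# ---------------------------------------------------------------------------

def _literal_masks(
    aln: LabeledAlignment, in_idx: list[int], out_idx: list[int]
) -> list[tuple[DiagnosticLiteral, int, int]]:
    """Candidate literals with bitmasks of satisfying in/out records.

    A literal is kept only if it is satisfied by at least one in-class
    record and excludes at least one out-of-class record; any literal
    failing either test can never appear in a minimal zero-false-positive
    formula of maximal coverage.
    """
    candidates: list[tuple[DiagnosticLiteral, int, int]] = []
    residues = [rec.residues for rec in aln.records]
    full_out = (1 << len(out_idx)) - 1
    for pos in range(1, aln.length + 1):
        for negated in (False, True):
            for state in STATES:
                lit = DiagnosticLiteral(position=pos, negated=negated, state=state)
                in_mask = 0
                for j, i in enumerate(in_idx):
                    if lit.satisfied_by(residues[i]):
                        in_mask |= 1 << j
                if not in_mask:
                    continue
                out_mask = 0
                for j, i in enumerate(out_idx):
                    if lit.satisfied_by(residues[i]):
                        out_mask |= 1 << j
                if out_mask == full_out and full_out:
                    continue
                candidates.append((lit, in_mask, out_mask))
    return candidates


def _sort_key(literals: tuple[DiagnosticLiteral, ...]):
    return tuple((lit.position, lit.negated, lit.state) for lit in literals)


def _better(cand, best) -> bool:
    """cand/best = (coverage, -size, tie-key); higher coverage, then fewer
    literals, then the deterministic tie-break order wins."""
    if best is None:
        return True
    if cand[0] != best[0]:
        return cand[0] > best[0]
    if cand[1] != best[1]:
        return cand[1] > best[1]
    return cand[2] < best[2]


def _learn_one_class(
    aln: LabeledAlignment, rank: str, class_name: str, params: LearnerParams
) -> DiagnosticFormula | None:
    in_idx = [i for i, r in enumerate(aln.records) if r.label(rank) == class_name]
    out_idx = [i for i, r in enumerate(aln.records) if r.label(rank) != class_name]
    n_in = len(in_idx)
    candidates = _literal_masks(aln, in_idx, out_idx)
    candidates.sort(key=lambda c: (c[0].position, c[0].negated, c[0].state))

    best: tuple[int, int, tuple] | None = None  # (n covered, -size, tie key)
    best_literals: tuple[DiagnosticLiteral, ...] | None = None

    def consider(lits: tuple[DiagnosticLiteral, ...], in_mask: int) -> None:
        nonlocal best, best_literals
        cand = (bin(in_mask).count("1"), -len(lits), _sort_key(lits))
        if _better(cand, best):
            best = cand
            best_literals = lits

    # exact search, sizes 1..min(max_literals, 3); once full coverage is
    # reached at some size no longer formula can improve on it
    for lit, in_mask, out_mask in candidates:
        if out_mask == 0:
            consider((lit,), in_mask)
    exact_cap = min(params.max_literals, 3)
    if best is not None and best[0] == n_in:
        exact_cap = 1
    if exact_cap >= 2:
        n_pairs = len(candidates) * (len(candidates) - 1) // 2
        if n_pairs <= params.max_exact_pairs:
            for (la, ia, oa), (lb, ib, ob) in combinations(candidates, 2):
                if la.position == lb.position:
                    continue
                im = ia & ib
                if not im:
                    continue
                if best is not None and bin(im).count("1") < best[0]:
                    continue
                if oa & ob == 0:
                    consider((la, lb), im)
    if exact_cap >= 3 and (best is None or best[0] < n_in):
        n_triples = (
            len(candidates) * (len(candidates) - 1) * (len(candidates) - 2) // 6
        )
        if n_triples <= params.max_exact_triples:
            for a, b, c in combinations(range(len(candidates)), 3):
                la, ia, oa = candidates[a]
                lb, ib, ob = candidates[b]
                lc, ic, oc = candidates[c]
                if len({la.position, lb.position, lc.position}) != 3:
                    continue
                im = ia & ib & ic
                if not im:
                    continue
                if best is not None and bin(im).count("1") < best[0]:
                    continue
                if oa & ob & oc == 0:
                    consider((la, lb, lc), im)

    # greedy extension beyond the exact regime
    if best is None and params.max_literals > 0:
        greedy: list[tuple[DiagnosticLiteral, int, int]] = []
        in_mask = (1 << n_in) - 1
        out_mask = (1 << len(out_idx)) - 1
        pool = list(candidates)
        while len(greedy) < params.max_literals and out_mask:
            scored = []
            for lit, im, om in pool:
                if any(lit.position == g[0].position for g in greedy):
                    continue
                nim = in_mask & im
                if not nim:
                    continue
                nom = out_mask & om
                scored.append(
                    (
                        bin(nom).count("1"),
                        -bin(nim).count("1"),
                        (lit.position, lit.negated, lit.state),
                        lit,
                        nim,
                        nom,
                    )
                )
            if not scored:
                break
            scored.sort(key=lambda t: t[:3])
            _, _, _, lit, in_mask, out_mask = scored[0]
            greedy.append((lit, in_mask, out_mask))
        if greedy and out_mask == 0:
            lits = tuple(sorted((g[0] for g in greedy)))
            best_literals = lits

    if best_literals is None:
        return None
    return DiagnosticFormula(
        rank=rank,
        class_name=class_name,
        literals=tuple(sorted(best_literals)),
        frame=aln.locus,
    )


def learn_rules(
    aln: LabeledAlignment, rank: str, params: LearnerParams | None = None
) -> dict[str, tuple[DiagnosticFormula | None, RuleEvaluation | None]]:
    """Learn one diagnostic formula per class at ``rank``.

    Returns a mapping class name -> (formula, evaluation); classes for
    which no zero-false-positive conjunction of up to ``max_literals``
    literals exists map to (None, None) — "no diagnostic pattern".
    """
    params = params or LearnerParams()
    unlabeled = [r.id for r in aln.records if not r.label(rank)]
    if unlabeled:
        raise LabelingError(f"records without a {rank} label: {unlabeled}")
    classes = aln.classes(rank)
    if len(classes) < 2:
        raise DegenerateInputError(
            f"need >= 2 classes at rank {rank!r}, got {classes}"
        )
    out: dict[str, tuple[DiagnosticFormula | None, RuleEvaluation | None]] = {}
    for class_name in classes:
        formula = _learn_one_class(aln, rank, class_name, params)
        if formula is None:
            out[class_name] = (None, None)
        else:
            evaluation = evaluate_formula(formula, aln)
            assert evaluation.false_positives == 0, (
                f"learner returned a formula with false positives for {class_name!r}"
            )
            out[class_name] = (formula, evaluation)
    return out


def exhaustive_min_formulas(
    aln: LabeledAlignment, rank: str, class_name: str, k: int
) -> list[DiagnosticFormula]:
    """All zero-false-positive formulas of <= k literals for one class.

    Complete enumeration over positive and negated literals at distinct
    positions; a formula must match at least one in-class record to count
    as diagnostic.  Guarded (k <= 3; <= 200 columns when k = 3) because the
    search space grows as (8·columns choose k).  Results are sorted by
    (size, positions, polarity, state).  Intended as an exact reference for
    the learner on small inputs.
    """
    if k > 3:
        raise ResourceError(f"exhaustive enumeration capped at k=3, got k={k}")
    if k == 3 and aln.length > 200:
        raise ResourceError(
            f"exhaustive k=3 enumeration capped at 200 columns, got {aln.length}"
        )
    in_records = [r for r in aln.records if r.label(rank) == class_name]
    out_records = [r for r in aln.records if r.label(rank) != class_name]
    if not in_records:
        raise DegenerateInputError(f"no records of {rank}={class_name!r}")

    entries: list[tuple[DiagnosticLiteral, int, int]] = []
    for pos in range(1, aln.length + 1):
        for neg in (False, True):
            for state in STATES:
                lit = DiagnosticLiteral(position=pos, negated=neg, state=state)
                in_mask = 0
                for j, rec in enumerate(in_records):
                    if lit.satisfied_by(rec.residues):
                        in_mask |= 1 << j
                out_mask = 0
                for j, rec in enumerate(out_records):
                    if lit.satisfied_by(rec.residues):
                        out_mask |= 1 << j
                entries.append((lit, in_mask, out_mask))
    found: list[DiagnosticFormula] = []
    for size in range(1, k + 1):
        for combo in combinations(entries, size):
            if len({e[0].position for e in combo}) != size:
                continue
            in_mask = combo[0][1]
            out_mask = combo[0][2]
            for _, im, om in combo[1:]:
                in_mask &= im
                out_mask &= om
            if not in_mask or out_mask:
                continue
            found.append(
                DiagnosticFormula(
                    rank=rank,
                    class_name=class_name,
                    literals=tuple(e[0] for e in combo),
                    frame=aln.locus,
                )
            )
    found.sort(key=lambda f: (len(f.literals), _sort_key(f.literals)))
    return found


def classify_query(
    query: SequenceRecord | str,
    rulebook: list[DiagnosticFormula],
    frame_length: int | None = None,
) -> list[tuple[str, list[DiagnosticFormula]]]:
    """Classes whose formulas a query (aligned into the frame) satisfies.

    Zero or multiple matching classes are allowed and reported as such; no
    single assignment is forced.
    """
    residues = query.residues if isinstance(query, SequenceRecord) else query.upper()
    if frame_length is not None and len(residues) != frame_length:
        raise FrameError(
            f"query length {len(residues)} does not match frame length {frame_length}"
        )
    by_class: dict[str, list[DiagnosticFormula]] = {}
    for formula in rulebook:
        if max(lit.position for lit in formula.literals) > len(residues):
            raise FrameError(
                f"formula {formula} exceeds query length {len(residues)}"
            )
        if formula.satisfied_by(residues):
            by_class.setdefault(formula.class_name, []).append(formula)
    return sorted(by_class.items())


# ---------------------------------------------------------------------------
# textual formula syntax and rulebook TSV
# ---------------------------------------------------------------------------

_LITERAL_RE = re.compile(r"^pos(\d+)\s*(!\s*=|=)\s*([ACGTacgt])$")


def parse_formula(
    text: str, rank: str = "", class_name: str = "", frame: str = ""
) -> DiagnosticFormula:
    """Parse 'posN=X AND posM!=Y' syntax (case-insensitive states)."""
    literals = []
    for chunk in re.split(r"\s+AND\s+", text.strip(), flags=re.IGNORECASE):
        m = _LITERAL_RE.match(chunk.strip())
        if not m:
            raise ValueError(f"cannot parse literal {chunk!r} in {text!r}")
        pos, op, state = m.groups()
        literals.append(
            DiagnosticLiteral(
                position=int(pos),
                negated=("!" in op),
                state=state.upper(),
            )
        )
    return DiagnosticFormula(
        rank=rank, class_name=class_name, literals=tuple(literals), frame=frame
    )


RULEBOOK_COLUMNS = ["rank", "class", "frame", "formula", "coverage", "fn_pct", "fp"]


def write_rulebook(
    rules: dict[str, tuple[DiagnosticFormula | None, RuleEvaluation | None]],
    rank: str,
    frame: str,
    path,
) -> None:
    rows = []
    for class_name, (formula, evaluation) in rules.items():
        rows.append(
            {
                "rank": rank,
                "class": class_name,
                "frame": frame,
                "formula": str(formula) if formula else "no diagnostic pattern",
                "coverage": round(evaluation.coverage, 1) if evaluation else "",
                "fn_pct": round(evaluation.false_negative, 1) if evaluation else "",
                "fp": evaluation.false_positives if evaluation else "",
            }
        )
    pd.DataFrame(rows, columns=RULEBOOK_COLUMNS).to_csv(path, sep="\t", index=False)


def read_rulebook(path) -> list[DiagnosticFormula]:
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    formulas = []
    for _, row in table.iterrows():
        if row["formula"] == "no diagnostic pattern":
            continue
        formulas.append(
            parse_formula(
                row["formula"],
                rank=row["rank"],
                class_name=row["class"],
                frame=row["frame"],
            )
        )
    return formulas
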