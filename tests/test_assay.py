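"""Diagnostic site discovery, ARMS primer design and in-silico PCR."""

import math

import numpy as np
import pytest

from herbdx.alignment import LabeledAlignment, SequenceRecord
from herbdx.assay import (
    ArmsAssay,
    DesignFailure,
    PartitionError,
    design_arms_primer,
    design_assay,
    find_diagnostic_sites,
    make_universal_primer,
    predict_amplicons,
    primer_binds,
    simulate_multiplex,
)

from conftest import random_alignment

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _aln(rows, locus="toy"):
    return LabeledAlignment(
        records=[SequenceRecord(id=i, residues=s) for i, s in rows], locus=locus
    )


def oracle_sites(aln, groups):
    """Naive per-column set comparison, independent of the implementation."""
    out = {g: [] for g in groups}
    for pos in range(1, aln.length + 1):
        for g, ids in groups.items():
            own = {aln.record(i).residues[pos - 1] for i in ids}
            if len(own) != 1 or next(iter(own)) not in "ACGT":
                continue
            others = {
                aln.record(i).residues[pos - 1]
                for og, oids in groups.items()
                if og != g
                for i in oids
            }
            if next(iter(own)) not in {b for b in others if b in "ACGT"}:
                out[g].append(pos)
    return out


class TestFindSites:
    def test_planted_fixed_differences_found_exactly(self):
        base = "ACGTACGTACGTACGTACGT"
        rows = []
        for g, (pos, state) in {"g1": (5, "C"), "g2": (11, "T"), "g3": (17, "G")}.items():
            for k in range(2):
                seq = list(base)
                # give every group a private state at its planted column
                for og, (opos, ostate) in {
                    "g1": (5, "C"),
                    "g2": (11, "T"),
                    "g3": (17, "G"),
                }.items():
                    if og == g:
                        seq[opos - 1] = ostate
                    elif seq[opos - 1] == ostate:
                        seq[opos - 1] = COMP[ostate]
                rows.append((f"{g}r{k}", "".join(seq)))
        aln = _aln(rows)
        groups = {g: [f"{g}r0", f"{g}r1"] for g in ("g1", "g2", "g3")}
        sites = find_diagnostic_sites(aln, groups)
        assert [s.position for s in sites["g1"]] == [5]
        assert [s.position for s in sites["g2"]] == [11]
        assert [s.position for s in sites["g3"]] == [17]
        assert sites["g1"][0].target_state == "C"

    def test_identical_groups_have_no_sites(self):
        aln = _aln([("a", "ACGTACGT"), ("b", "ACGTACGT")])
        sites = find_diagnostic_sites(aln, {"A": ["a"], "B": ["b"]})
        assert sites == {"A": [], "B": []}

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_bruteforce_column_scan(self, seed):
        aln = random_alignment(seed, n_records=9, n_cols=30, noise=0.1)
        groups = {
            "A": [f"r{i}" for i in range(3)],
            "B": [f"r{i}" for i in range(3, 6)],
            "C": [f"r{i}" for i in range(6, 9)],
        }
        got = find_diagnostic_sites(aln, groups)
        expected = oracle_sites(aln, groups)
        for g in groups:
            assert [s.position for s in got[g]] == expected[g]

    def test_empty_group_is_partition_error(self):
        aln = _aln([("a", "ACGT"), ("b", "ACGT")])
        with pytest.raises(PartitionError):
            find_diagnostic_sites(aln, {"A": ["a"], "B": []})


def _planted_assay_alignment(seed=0, n_cols=120, site_pos=80):
    """Two groups identical except one diagnostic SNP with clean flanks."""
    rng = np.random.default_rng(seed)
    base = "".join(np.array(list("ACGT"))[rng.integers(0, 4, n_cols)])
    target = base[: site_pos - 1] + "G" + base[site_pos:]
    other = base[: site_pos - 1] + "A" + base[site_pos:]
    rows = [("t1", target), ("t2", target), ("o1", other), ("o2", other)]
    return _aln(rows), {"T": ["t1", "t2"], "O": ["o1", "o2"]}


class TestPrimerDesign:
    def test_reverse_candidate_ends_on_site_with_one_internal_mismatch(self):
        aln, groups = _planted_assay_alignment()
        sites = find_diagnostic_sites(aln, groups)["T"]
        assert [s.position for s in sites] == [80]
        cands = design_arms_primer(aln, sites[0], groups, tm_target=60, tm_window=30)
        top = cands[0]
        assert top.orientation == "reverse"
        assert top.sequence[-1] == COMP["G"]  # 3' base on the site, primer strand
        # exactly one internal difference vs the perfect-match primer
        start, end = top.footprint
        from Bio.Seq import Seq

        perfect = str(
            Seq(aln.record("t1").residues[start - 1 : end]).reverse_complement()
        )
        diffs = [i for i, (a, b) in enumerate(zip(top.sequence, perfect)) if a != b]
        assert len(diffs) == 1
        offset_from_3p = top.length - diffs[0]
        assert offset_from_3p == top.destabilizing_mismatch[0] == 3

    def test_insufficient_template_is_design_failure(self):
        aln, groups = _planted_assay_alignment(n_cols=60, site_pos=10)
        sites = find_diagnostic_sites(aln, groups)["T"]
        with pytest.raises(DesignFailure, match="insufficient template"):
            design_arms_primer(
                aln, sites[0], groups, orientation="forward", tm_window=30
            )
        # reverse orientation near the right end fails the same way
        aln2, groups2 = _planted_assay_alignment(n_cols=60, site_pos=55)
        sites2 = find_diagnostic_sites(aln2, groups2)["T"]
        with pytest.raises(DesignFailure):
            design_arms_primer(
                aln2, sites2[0], groups2, orientation="reverse", tm_window=30
            )

    def test_destabilized_primer_differs_at_exactly_one_position(self):
        aln, groups = _planted_assay_alignment(seed=4)
        site = find_diagnostic_sites(aln, groups)["T"][0]
        with_mm = design_arms_primer(aln, site, groups, tm_window=30)[0]
        without = design_arms_primer(
            aln, site, groups, destabilization=None, tm_window=30
        )
        same_len = next(c for c in without if c.length == with_mm.length)
        diffs = [
            i for i, (a, b) in enumerate(zip(with_mm.sequence, same_len.sequence)) if a != b
        ]
        assert len(diffs) == 1
        assert with_mm.destabilizing_mismatch is not None
        assert same_len.destabilizing_mismatch is None


# Allawi & SantaLucia (1997) unified nearest-neighbor parameters,
# transcribed independently for the Tm cross-check (kcal/mol, cal/mol/K).
NN_DH = {
    "AA": -7.9, "TT": -7.9, "AT": -7.2, "TA": -7.2, "CA": -8.5, "TG": -8.5,
    "GT": -8.4, "AC": -8.4, "CT": -7.8, "AG": -7.8, "GA": -8.2, "TC": -8.2,
    "CG": -10.6, "GC": -9.8, "GG": -8.0, "CC": -8.0,
}
NN_DS = {
    "AA": -22.2, "TT": -22.2, "AT": -20.4, "TA": -21.3, "CA": -22.7, "TG": -22.7,
    "GT": -22.4, "AC": -22.4, "CT": -21.0, "AG": -21.0, "GA": -22.2, "TC": -22.2,
    "CG": -27.2, "GC": -24.4, "GG": -19.9, "CC": -19.9,
}
INIT_DH = {"A": 2.3, "T": 2.3, "C": 0.1, "G": 0.1}
INIT_DS = {"A": 4.1, "T": 4.1, "C": -2.8, "G": -2.8}


def oracle_tm_nn(seq, dnac1=25.0, dnac2=25.0, na=50.0):
    """Independent nearest-neighbor Tm (unified parameters, SantaLucia 1998
    salt correction on the entropy term)."""
    dh = INIT_DH[seq[0]] + INIT_DH[seq[-1]]
    ds = INIT_DS[seq[0]] + INIT_DS[seq[-1]]
    for i in range(len(seq) - 1):
        pair = seq[i : i + 2]
        dh += NN_DH[pair]
        ds += NN_DS[pair]
    ds += 0.368 * (len(seq) - 1) * math.log(na / 1000.0)
    k = (dnac1 - dnac2 / 2.0) * 1e-9
    return 1000.0 * dh / (ds + 1.987 * math.log(k)) - 273.15


class TestMeltingTemperature:
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_independent_nearest_neighbor_calculation(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, rng.integers(18, 30))])
        from Bio.SeqUtils import MeltingTemp

        assert MeltingTemp.Tm_NN(seq) == pytest.approx(oracle_tm_nn(seq), abs=0.05)


def _toy_assay(n_cols=200, site=120, primer_len=20):
    """Gap-free two-group alignment plus a hand-assembled assay."""
    aln, groups = _planted_assay_alignment(seed=7, n_cols=n_cols, site_pos=site)
    uf = make_universal_primer(aln, 1, primer_len, "forward")
    ur = make_universal_primer(aln, n_cols - primer_len + 1, primer_len, "reverse")
    dp = design_arms_primer(
        aln, find_diagnostic_sites(aln, groups)["T"][0], groups, tm_window=40
    )[0]
    assay = ArmsAssay(
        locus=aln.locus,
        universal_forward=uf,
        universal_reverse=ur,
        diagnostics={"T": dp},
    )
    return aln, groups, assay


class TestAmplicons:
    def test_sizes_follow_anchor_arithmetic_on_gap_free_templates(self):
        aln, groups, assay = _toy_assay()
        pattern = predict_amplicons(assay, aln.record("t1"))
        control = assay.universal_reverse.footprint[1] - assay.universal_forward.footprint[0] + 1
        diag = assay.diagnostics["T"].footprint[1] - assay.universal_forward.footprint[0] + 1
        assert pattern.bands == sorted([control, diag], reverse=True)
        assert pattern.interpretation == {"T": True}
        assert assay.expected_fragment("T") == diag

    def test_non_target_template_shows_control_only(self):
        aln, groups, assay = _toy_assay()
        pattern = predict_amplicons(assay, aln.record("o1"))
        assert pattern.control
        assert pattern.interpretation == {"T": False}
        assert len(pattern.bands) == 1

    def test_fragment_size_invariant_under_gap_only_columns(self):
        aln, groups, assay = _toy_assay()
        before = predict_amplicons(assay, aln.record("t1")).bands
        # widen the alignment with gap columns inside the amplicon
        for rec in aln.records:
            rec.residues = rec.residues[:60] + "-" * 7 + rec.residues[60:]
        uf = make_universal_primer(aln, 1, 20, "forward")
        ur = make_universal_primer(aln, aln.length - 20 + 1, 20, "reverse")
        groups2 = {g: list(ids) for g, ids in groups.items()}
        dp = design_arms_primer(
            aln, find_diagnostic_sites(aln, groups2)["T"][0], groups2, tm_window=40
        )[0]
        assay2 = ArmsAssay(
            locus=aln.locus,
            universal_forward=uf,
            universal_reverse=ur,
            diagnostics={"T": dp},
        )
        assert predict_amplicons(assay2, aln.record("t1")).bands == before

    def test_internal_mismatch_budget(self):
        aln, groups, assay = _toy_assay()
        rec = aln.record("t1")
        # two extra internal mismatches inside the universal-forward footprint
        # are tolerated, a third is not
        res = list(rec.residues)
        for k, pos in enumerate([5, 9, 13]):
            res[pos - 1] = COMP[res[pos - 1]]
            rec2 = SequenceRecord(id="mut", residues="".join(res))
            binds = primer_binds(assay.universal_forward, rec2, mismatch_budget=2)
            assert binds == (k < 2)


class TestMultiplex:
    def test_mixture_shows_both_components(self, tea):
        from herbdx.simulate import (
            GROUP_BAMBOO,
            GROUP_CARNATION,
            GROUP_LEMONGRASS,
        )

        aln = tea.references["cpA"]
        groups = {
            cls: [r.id for r in aln.records if r.label("subfamily") == cls]
            for cls in aln.classes("subfamily")
        }
        assay = design_assay(aln, groups, (1, 26), (534, 20), tm_window=20)
        gel = simulate_multiplex(assay, tea.product_lanes("cpA")).set_index("sample")
        for pid in ("P1", "P7"):
            assert gel.loc[pid, GROUP_LEMONGRASS] == "+"
        assert gel.loc["P1", GROUP_CARNATION] == "+"
        assert gel.loc["P7", GROUP_BAMBOO] == "+"
        # non-mixture products show exactly one component
        assert gel.loc["P2", GROUP_LEMONGRASS] == "-"
        n_bands = len(gel.loc["P1", "bands"].split(","))
        assert n_bands >= 3  # control + two diagnostic fragments

    def test_table_equals_per_template_recomputation(self, tea):
        aln = tea.references["cpA"]
        groups = {
            cls: [r.id for r in aln.records if r.label("subfamily") == cls]
            for cls in aln.classes("subfamily")
        }
        assay = design_assay(aln, groups, (1, 26), (534, 20), tm_window=20)
        lanes = {r.id: [r] for r in aln.records}
        gel = simulate_multiplex(assay, lanes).set_index("sample")
        for rec in aln.records:
            pattern = predict_amplicons(assay, rec)
            row = gel.loc[rec.id]
            assert row["bands"] == ",".join(str(b) for b in pattern.bands)
            for group, hit in pattern.interpretation.items():
                assert row[group] == ("+" if hit else "-")

    def test_zero_cross_reactivity_on_reference_templates(self, tea):
        aln = tea.references["cpA"]
        groups = {
            cls: [r.id for r in aln.records if r.label("subfamily") == cls]
            for cls in aln.classes("subfamily")
        }
        assay = design_assay(aln, groups, (1, 26), (534, 20), tm_window=20)
        gel = simulate_multiplex(assay, {r.id: [r] for r in aln.records}).set_index(
            "sample"
        )
        for rec in aln.records:
            own = rec.label("subfamily")
            for group in groups:
                assert gel.loc[rec.id, group] == ("+" if group == own else "-")

    def test_empty_template_list_is_degenerate(self):
        from herbdx.alignment import DegenerateInputError

        _, _, assay = _toy_assay()
        with pytest.raises(DegenerateInputError):
            simulate_multiplex(assay, {})
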