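"""Triage of bait-versus-control peptide counts."""
import math
from collections import defaultdict

import pytest
from hypothesis import given
from hypothesis import strategies as st

from chptools import datasets
from chptools.triage import (
    CoIPRecord,
    ProteinAnnotation,
    classify,
    consensus,
    cross_structure,
    high_confidence_set,
    mw_from_sequence,
    partner_set,
    rel_delta,
    triage_report,
)


def _rec(o, i, pid="P1", structure="ChP", rep=1):
    return CoIPRecord(pid, structure, rep, o, i)


def _ann(pid="P1", mw=None, seq=None):
    return ProteinAnnotation(pid, mw, seq)


class TestRelDelta:
    @pytest.mark.parametrize(
        "o, i, expected",
        [
            (11, 5, 0.5455),  # just above the 50% selection threshold
            (13, 6, 0.5385),
            (4, 2, 0.5),
            (3, 0, 1.0),  # exclusive detection scores 100%
            (1, 0, 1.0),
            (2, 5, 0.0),  # negative differences clamp to zero
        ],
    )
    def test_bait_mode_values(self, o, i, expected):
        assert rel_delta(o, i) == pytest.approx(expected, abs=1e-4)

    def test_undefined_when_absent_from_bait(self):
        assert rel_delta(0, 5) is None
        assert rel_delta(0, 0) is None

    def test_control_mode(self):
        assert rel_delta(11, 5, mode="control") == pytest.approx(1.2)
        assert rel_delta(3, 0, mode="control") == math.inf

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            rel_delta(-1, 0)

    @given(o=st.integers(1, 200), i=st.integers(0, 200))
    def test_bounded_and_exclusive_is_one(self, o, i):
        rd = rel_delta(o, i)
        assert 0.0 <= rd <= 1.0
        if i == 0:
            assert rd == 1.0


class TestClassify:
    @pytest.mark.parametrize(
        "o, i, mw, expected",
        [
            (3, 0, 151.8, {"unique"}),  # >=3 peptides, bait-exclusive
            (11, 5, None, {"selected"}),  # rel delta 0.545 > 0.5
            (2, 0, 18.0, {"unique_small"}),  # small bait-exclusive, <3 peptides
            (4, 2, 100.0, set()),  # rel delta exactly 0.5: strict inequality
            (3, 0, 20.0, {"unique", "unique_small"}),  # both exclusivity flags
            (2, 0, 100.0, set()),  # exclusive but too few peptides, not small
            (0, 4, 10.0, set()),  # never seen with the bait
            (25, 25, 10.0, set()),  # symmetric background protein
        ],
    )
    def test_rules(self, o, i, mw, expected):
        ann = _ann(mw=mw) if mw is not None else None
        assert set(classify(_rec(o, i), ann).flags) == expected

    def test_is_partner_iff_flagged(self):
        assert classify(_rec(5, 0), None).is_partner
        assert not classify(_rec(2, 2), None).is_partner

    def test_unknown_mass_blocks_small_rule_only(self):
        call = classify(_rec(1, 0), None)
        assert call.flags == frozenset()

    def test_boundary_small_mass_inclusive(self):
        assert "unique_small" in classify(_rec(1, 0), _ann(mw=25.0)).flags
        assert "unique_small" not in classify(_rec(1, 0), _ann(mw=25.01)).flags

    @given(
        o=st.integers(0, 50),
        i=st.integers(0, 50),
        extra=st.integers(1, 20),
        mw=st.one_of(st.none(), st.floats(1.0, 300.0)),
    )
    def test_monotone_in_bait_peptides(self, o, i, extra, mw):
        """More bait evidence can never demote a partner to non-partner."""
        ann = _ann(mw=mw) if mw is not None else None
        before = classify(_rec(o, i), ann).is_partner
        after = classify(_rec(o + extra, i), ann).is_partner
        assert not (before and not after)


class TestPartnerSet:
    def test_hand_worked_three_proteins(self):
        records = [
            _rec(3, 0, "A"),
            _rec(4, 2, "B"),
            _rec(1, 0, "C"),
        ]
        anns = {p: _ann(p, mw) for p, mw in [("A", 100.0), ("B", 100.0), ("C", 20.0)]}
        ps = partner_set(records, anns)
        assert ps.members == frozenset({"A", "C"})
        assert ps.total == 2
        assert ps.category_counts == {"unique": 1, "selected": 0, "unique_small": 1}

    def test_empty_input(self):
        ps = partner_set([])
        assert ps.total == 0 and ps.members == frozenset()

    def test_duplicate_protein_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            partner_set([_rec(3, 0, "A"), _rec(5, 0, "A")])

    def test_mixed_replicates_rejected(self):
        with pytest.raises(ValueError, match="mix"):
            partner_set([_rec(3, 0, "A", rep=1), _rec(3, 0, "B", rep=2)])

    @given(
        st.lists(
            st.tuples(st.integers(0, 10), st.integers(0, 10), st.floats(5.0, 200.0)),
            min_size=0,
            max_size=20,
        )
    )
    def test_agrees_with_exhaustive_rule_oracle(self, triples):
        """partner_set matches independent per-protein rule evaluation."""
        records, anns, oracle_members = [], {}, set()
        oracle_counts = {"unique": 0, "selected": 0, "unique_small": 0}
        for idx, (o, i, mw) in enumerate(triples):
            pid = f"P{idx}"
            records.append(_rec(o, i, pid))
            anns[pid] = _ann(pid, mw)
            # oracle: literal transcription of the three published rules
            uniq = i == 0 and o >= 3
            small = i == 0 and o >= 1 and mw <= 25.0
            sel = i >= 1 and o >= 3 and o > 2 * i  # (O-I)/O > 0.5  <=>  O > 2I
            if uniq or small or sel:
                oracle_members.add(pid)
            oracle_counts["unique"] += uniq
            oracle_counts["unique_small"] += small
            oracle_counts["selected"] += sel
        ps = partner_set(records, anns)
        assert ps.members == frozenset(oracle_members)
        assert dict(ps.category_counts) == oracle_counts

    @given(
        st.lists(
            st.tuples(st.integers(0, 10), st.integers(0, 10), st.floats(5.0, 200.0)),
            min_size=0,
            max_size=20,
        )
    )
    def test_category_algebra(self, triples):
        """total = |unique| + |selected| + |unique_small| - |unique & small|."""
        records = [_rec(o, i, f"P{idx}") for idx, (o, i, _) in enumerate(triples)]
        anns = {
            f"P{idx}": _ann(f"P{idx}", mw) for idx, (_, _, mw) in enumerate(triples)
        }
        ps = partner_set(records, anns)
        both = sum(
            1
            for fl in ps.flags_by_protein.values()
            if {"unique", "unique_small"} <= fl
        )
        c = ps.category_counts
        assert ps.total == c["unique"] + c["selected"] + c["unique_small"] - both


class TestConsensus:
    def _ps(self, members, structure="ChP", rep=1):
        return partner_set(
            [_rec(5, 0, m, structure=structure, rep=rep) for m in members]
        )

    def test_strict_intersection(self):
        sets = [self._ps({"A", "B", "C"}), self._ps({"B", "C"}), self._ps({"C", "B", "D"})]
        assert consensus(sets).members == frozenset({"B", "C"})

    def test_single_set_identity(self):
        ps = self._ps({"A", "B"})
        assert consensus([ps]).members == ps.members

    def test_disjoint_sets_empty(self):
        assert consensus([self._ps({"A"}), self._ps({"B"})]).members == frozenset()

    def test_mixed_structures_rejected(self):
        with pytest.raises(ValueError, match="structures"):
            consensus([self._ps({"A"}, "ChP"), self._ps({"A"}, "SVZ")])

    @given(
        st.lists(
            st.sets(st.sampled_from("ABCDEFGH"), max_size=8), min_size=1, max_size=5
        )
    )
    def test_subset_of_every_input_and_idempotent(self, member_sets):
        sets = [self._ps(m, rep=1) for m in member_sets]
        cons = consensus(sets)
        for s in sets:
            assert cons.members <= s.members
        assert consensus([cons]).members == cons.members
        assert cons.replicate == "consensus"


class TestCrossStructure:
    def test_bundled_candidate_partners(self):
        """All 14 candidates pass the high-confidence filter in SVZ, RMS and
        VCx; exactly 5 of them also pass in the choroid plexus."""
        by_structure = defaultdict(list)
        for r in datasets.load_coip_records():
            by_structure[r.structure].append(r)
        sets = {s: high_confidence_set(v) for s, v in by_structure.items()}
        report = cross_structure(sets, ["SVZ", "RMS", "VCx"], ["ChP"])
        assert len(report.common) == 14
        assert len(report.also_common["ChP"]) == 5
        assert report.also_common["ChP"] == frozenset(
            {"ACOT11", "FIG4", "KCND3", "PIKFYVE", "VAC14"}
        )

    def test_identical_sets(self):
        report = cross_structure({"SVZ": {"A", "B"}, "RMS": {"A", "B"}}, ["SVZ", "RMS"])
        assert report.common == frozenset({"A", "B"})

    def test_exclusive_protein_reported(self):
        report = cross_structure({"SVZ": {"A"}, "RMS": set()}, ["SVZ", "RMS"])
        assert report.common == frozenset()
        assert report.membership.loc["A", "SVZ"]
        assert not report.membership.loc["A", "RMS"]

    def test_unknown_structure_rejected(self):
        with pytest.raises(ValueError, match="unknown structure"):
            cross_structure({"SVZ": {"A"}, "RMS": {"A"}}, ["SVZ", "XXX"])

    def test_needs_two_structures(self):
        with pytest.raises(ValueError):
            cross_structure({"SVZ": {"A"}}, ["SVZ"])


class TestMolecularWeight:
    @pytest.mark.parametrize(
        "seq, kda",
        [
            ("", 0.01802),  # water only
            ("G", 0.07507),
            ("GG", 0.13212),
        ],
    )
    def test_reference_masses(self, seq, kda):
        assert mw_from_sequence(seq) == pytest.approx(kda, abs=1e-4)

    def test_rejects_nonstandard_with_position(self):
        with pytest.raises(ValueError, match="position 2"):
            mw_from_sequence("GGXG")

    def test_annotation_mass_precedence(self):
        ann = ProteinAnnotation("P", mw_kda=10.0, sequence="G" * 100)
        assert ann.mass_kda == 10.0
        assert ProteinAnnotation("P", sequence="G").mass_kda == pytest.approx(
            0.07507, abs=1e-4
        )


def test_report_ordering_and_columns():
    records = [_rec(3, 0, "B"), _rec(10, 1, "A"), _rec(10, 1, "C", rep=2)]
    report = triage_report(records)
    assert list(report["protein_id"]) == ["A", "C", "B"]
    assert set(report.columns) >= {"protein_id", "flags", "rel_delta", "is_partner"}
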