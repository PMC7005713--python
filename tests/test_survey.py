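"""Rotamer survey: calls, concordance, anion flags, exact association test."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from dhpscan.simulate import SimulatedStructureSpec, build_structure
from dhpscan.structures import read_structure
from dhpscan.survey import (
    RotamerCall,
    SurveyTable,
    annotate_anion_coordination,
    assign_rotamers,
    compile_survey,
    dimer_concordance,
    fisher_exact_2x2,
    load_manifest,
    parse_rotamer_notation,
)
from dhpscan.survey import test_ph_association as run_ph_association


def _call(chain="A", rotamer="trans", altloc="", ph=7.0):
    return RotamerCall(
        pdb_id="XXXX", protein="HK", chain_id=chain, residue_number=260,
        altloc=altloc, rotamer=rotamer, crystallization_pH=ph,
    )


class TestAssignRotamers:
    def test_synthetic_dimer_labels(self, dimer_with_sulfate):
        calls = assign_rotamers(dimer_with_sulfate, 260, pdb_id="FIX")
        assert [(c.chain_id, c.rotamer) for c in calls] == [
            ("A", "gauche-"), ("B", "trans"),
        ]
        assert all(c.crystallization_pH == pytest.approx(7.5) for c in calls)

    def test_double_conformer_yields_two_calls(self, tmp_path):
        path = build_structure(
            SimulatedStructureSpec(chain_chi1=((-60.0, 180.0), (-60.0,))),
            tmp_path / "dc.pdb",
        )
        calls = assign_rotamers(read_structure(path), 260)
        assert sorted((c.chain_id, c.altloc, c.rotamer) for c in calls) == [
            ("A", "A", "gauche-"), ("A", "B", "trans"), ("B", "", "gauche-"),
        ]

    def test_unresolvable_selector_raises(self, dimer_with_sulfate):
        with pytest.raises(KeyError):
            assign_rotamers(dimer_with_sulfate, 999)


class TestConcordance:
    @pytest.mark.parametrize(
        "calls,expected",
        [
            ([_call("A", "trans"), _call("B", "trans")], "identical"),
            ([_call("A", "trans"), _call("B", "gauche-")], "distinct"),
            (
                [_call("A", "gauche-", "A"), _call("A", "trans", "B"), _call("B", "trans")],
                "mixed-altloc",
            ),
            ([_call("A", "trans")], "not-evaluated"),
            (
                [_call(c, r) for c, r in zip("ABCD", ["gauche-"] * 2 + ["trans"] * 2)],
                "distinct",
            ),
        ],
    )
    def test_labels(self, calls, expected):
        assert dimer_concordance(calls) == expected


class TestAnionCoordination:
    def test_sulfate_within_cutoff_flags_true(self, dimer_with_sulfate):
        calls = assign_rotamers(dimer_with_sulfate, 260)
        flags = {
            c.chain_id: annotate_anion_coordination(dimer_with_sulfate, c).anion_coordinated
            for c in calls
        }
        assert flags == {"A": True, "B": False}  # sulfate placed at chain A only

    def test_no_hetatm_flags_false(self, tmp_path):
        path = build_structure(
            SimulatedStructureSpec(chain_chi1=((-60.0,), (180.0,))), tmp_path / "f.pdb"
        )
        model = read_structure(path)
        calls = assign_rotamers(model, 260)
        assert all(
            annotate_anion_coordination(model, c).anion_coordinated is False
            for c in calls
        )

    def test_distance_beyond_cutoff_is_not_a_contact(self, tmp_path):
        path = build_structure(
            SimulatedStructureSpec(chain_chi1=((-60.0,),), sulfate_distance=4.5),
            tmp_path / "far.pdb",
        )
        model = read_structure(path)
        call = assign_rotamers(model, 260)[0]
        assert annotate_anion_coordination(model, call).anion_coordinated is False
        assert annotate_anion_coordination(model, call, cutoff=5.0).anion_coordinated


class TestManifest:
    def test_notation_parsing(self):
        assert parse_rotamer_notation("gauche-/gauche- & trans") == (
            ("gauche-",), ("gauche-", "trans"),
        )
        assert parse_rotamer_notation("trans/trans") == (("trans",), ("trans",))

    def test_packaged_manifest_shape(self, manifest):
        assert len(manifest) == 28
        by_id = {e.pdb_id: e for e in manifest}
        assert by_id["4I5S"].ph_value == pytest.approx(8.1)  # midpoint of 7.6-8.6
        assert by_id["4JAV"].subunit_labels == (("gauche-",), ("gauche-", "trans"))
        assert len(by_id["6DK7"].subunit_labels) == 8

    def test_manifest_mode_counts(self, manifest):
        """The printed per-subunit calls tally to 27 gauche- and 39 trans."""
        table = compile_survey(manifest)
        assert table.counts["gauche-"] == 27
        assert table.counts["trans"] == 39
        assert table.counts["gauche+"] == 0
        assert len(table.calls) == 66
        assert len(table.structures()) == 28

    def test_count_conservation(self, manifest):
        table = compile_survey(manifest)
        assert sum(table.counts.values()) == len(table.calls)
        per_structure = {}
        for c in table.calls:
            per_structure[c.pdb_id] = per_structure.get(c.pdb_id, 0) + 1
        assert sum(per_structure.values()) == len(table.calls)

    def test_every_structure_gets_concordance_label(self, manifest):
        table = compile_survey(manifest)
        assert set(table.concordance) == {e.pdb_id for e in manifest}
        assert table.concordance["3DGE"] == "identical"
        assert table.concordance["4I5S"] == "distinct"
        assert table.concordance["4JAV"] == "mixed-altloc"
        assert table.concordance["6DK7"] == "distinct"

    def test_empty_manifest(self):
        table = compile_survey([])
        assert table.calls == [] and sum(table.counts.values()) == 0

    def test_missing_structure_recorded(self, manifest, tmp_path):
        table = compile_survey(manifest[:2], structures_dir=tmp_path)
        assert table.missing_structures == [e.pdb_id for e in manifest[:2]]


class TestFisherExact:
    def test_uniform_table_p_one(self):
        res = fisher_exact_2x2([[2, 2], [2, 2]])
        assert res.p_value == pytest.approx(1.0)
        assert not res.degenerate

    def test_perfectly_separated_table(self):
        # margins 5,5/5,5: the two extreme tables each have probability 1/252
        res = fisher_exact_2x2([[5, 0], [0, 5]])
        assert res.p_value == pytest.approx(2 / 252)
        assert res.odds_ratio == math.inf

    def test_zero_margin_degenerate(self):
        res = fisher_exact_2x2([[0, 0], [3, 4]])
        assert res.p_value == 1.0
        assert res.degenerate

    def test_matches_enumeration_for_all_small_tables(self):
        """Exhaustive check against direct hypergeometric enumeration for
        every margin-consistent 2x2 with total <= 40 (sampled margins)."""
        from math import comb

        rng = np.random.default_rng(17)
        for _ in range(200):
            n = int(rng.integers(1, 41))
            r1 = int(rng.integers(0, n + 1))
            c1 = int(rng.integers(0, n + 1))
            lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
            if lo > hi:
                continue
            a = int(rng.integers(lo, hi + 1))
            table = [[a, r1 - a], [c1 - a, n - r1 - (c1 - a)]]
            res = fisher_exact_2x2(table)
            if 0 in (r1, n - r1, c1, n - c1):
                assert res.degenerate and res.p_value == 1.0
                continue
            denom = comb(n, c1)
            probs = {
                x: comb(r1, x) * comb(n - r1, c1 - x) / denom for x in range(lo, hi + 1)
            }
            expected = sum(p for p in probs.values() if p <= probs[a] * (1 + 1e-7))
            assert res.p_value == pytest.approx(expected, rel=1e-10)

    @settings(deadline=None, max_examples=150, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=12), min_size=4, max_size=4))
    def test_matches_scipy_two_sided(self, cells):
        table = [cells[:2], cells[2:]]
        res = fisher_exact_2x2(table)
        if res.degenerate:
            assert res.p_value == 1.0
            return
        assert res.p_value == pytest.approx(scipy_fisher(table)[1], rel=1e-9)


class TestPhAssociation:
    def test_packaged_survey_not_significant(self, manifest):
        """No association between pH bin and rotamer class across the survey."""
        table = compile_survey(manifest)
        res = run_ph_association(table, threshold_ph=6.5)
        assert res.table.sum() == 66
        assert res.p_value > 0.05
        assert not res.degenerate
        assert res.n_excluded_gauche_plus == 0
        assert res.n_excluded_missing_ph == 0

    def test_perfect_coupling_is_significant(self):
        calls = [_call("A", "gauche-", str(i), ph=5.0) for i in range(10)]
        calls += [_call("B", "trans", str(i), ph=8.0) for i in range(10)]
        res = run_ph_association(SurveyTable(calls=calls), threshold_ph=6.5)
        # hypergeometric: both extreme tables, 2/C(20,10)
        assert res.p_value == pytest.approx(2 / 184756)
        assert res.p_value < 0.001

    def test_single_call_degenerate(self):
        res = run_ph_association(SurveyTable(calls=[_call(ph=5.0)]))
        assert res.degenerate

    def test_exclusions_counted_never_dropped_silently(self):
        calls = [
            _call("A", "gauche-", ph=5.0),
            _call("B", "trans", ph=8.0),
            _call("C", "gauche+", ph=7.0),
            _call("D", "trans", ph=None),
        ]
        res = run_ph_association(SurveyTable(calls=calls))
        assert res.table.sum() == 2
        assert res.n_excluded_gauche_plus == 1
        assert res.n_excluded_missing_ph == 1

    def test_missing_ph_never_defaults_to_seven(self):
        calls = [_call("A", "gauche-", ph=None), _call("B", "trans", ph=None)]
        with pytest.raises(ValueError):
            run_ph_association(SurveyTable(calls=calls))


class TestCoordinateVsManifestConcordance:
    def test_synthetic_batch_reproduces_manifest_entry_by_entry(self, manifest, tmp_path):
        """Coordinate-mode classification of fixtures generated from the
        manifest's label/pH profile recovers every printed call and the same
        27/39 totals."""
        from dhpscan.simulate import build_survey_fixtures

        _, selectors = build_survey_fixtures(manifest, tmp_path, seed=123)
        table = compile_survey(manifest, structures_dir=tmp_path, selectors=selectors)
        assert table.missing_structures == []
        assert table.counts["gauche-"] == 27
        assert table.counts["trans"] == 39
        # entry-by-entry: multiset of labels per structure matches the manifest
        by_id = {e.pdb_id: e for e in manifest}
        for pdb_id in table.structures():
            got = sorted(c.rotamer for c in table.calls if c.pdb_id == pdb_id)
            want = sorted(
                lab for sub in by_id[pdb_id].subunit_labels for lab in sub
            )
            assert got == want, pdb_id
        # pH joined from the manifest
        assert all(
            c.crystallization_pH == by_id[c.pdb_id].ph_value for c in table.calls
        )
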