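import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cysexpose import cys_survey as cs
from cysexpose import peptide_chem as pc
from cysexpose.cys_survey import (
    CysteineRecord,
    SurveyParams,
    classify_detectability,
    classify_exposure_states,
    gamma_s_sasa,
    map_conserved_cysteines,
    shrake_rupley_sasa,
    sphere_points,
    survey_summary,
)


class TestConservation:
    def test_all_conserved(self):
        aln = {"ref": "AAAAC", "s1": "AAAAC", "s2": "GGGGC"}
        recs = map_conserved_cysteines(aln, "ref")
        assert [(r.position, r.conserved) for r in recs] == [(5, True)]

    def test_substitution_breaks_conservation(self):
        aln = {"ref": "AAAAC", "s1": "AAAAS"}
        recs = map_conserved_cysteines(aln, "ref")
        assert recs[0].conserved is False

    def test_gap_arithmetic(self):
        # reference "AC-CG": cysteines at ungapped positions 2 and 3
        aln = {"ref": "AC-CG", "s1": "ACCCG"}
        recs = map_conserved_cysteines(aln, "ref")
        assert [r.position for r in recs] == [2, 3]
        assert all(r.conserved for r in recs)

    def test_reference_absent_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            map_conserved_cysteines({"s1": "AC"}, "ref")

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            map_conserved_cysteines({"ref": "AC", "s1": "ACG"}, "ref")


def oracle_detectability(seq, pos, params=SurveyParams()):
    """Independent brute-force oracle: find the tryptic peptide by scanning
    all 0-missed peptides, then evaluate the four rules directly."""
    peps = []
    start = 0
    for i in range(len(seq)):
        if seq[i] in "KR" and (i + 1 == len(seq) or seq[i + 1] != "P"):
            peps.append((start, i + 1))
            start = i + 1
    if start < len(seq):
        peps.append((start, len(seq)))
    for a, b in peps:
        if a < pos <= b:
            sub = seq[a:b]
            break
    ncys = sub.count("C")
    mass = pc.peptide_mass(sub, {i + 1: "IAM-light" for i, c in enumerate(sub) if c == "C"})
    if len(sub) < params.min_peptide_length:
        return "undetectable:length"
    if (mass + 2 * 1.00728) / 2 < params.min_mh2:
        return "undetectable:mz"
    if mass > params.max_mass:
        return "undetectable:mass"
    if ncys > params.max_cys_per_peptide:
        return "undetectable:cys-count"
    return "detectable:multi-cys" if ncys > 1 else "detectable"


class TestDetectability:
    def test_short_peptide(self):
        assert classify_detectability("ACKGGGGGGK", 2) == "undetectable:length"

    def test_many_cysteines(self):
        seq = "ACCGCGCAAK"
        assert classify_detectability(seq, 2) == "undetectable:cys-count"

    def test_reference_peptide_detectable(self):
        seq = "ANPYECGFDPTSSAR"
        assert classify_detectability(seq, 6) == "detectable"

    def test_low_mz(self):
        # short-ish peptide >=7 residues but below 400 m/z at 2+
        seq = "GGGCGGGK"
        mass = pc.peptide_mass("GGGCGGGK", {4: "IAM-light"})
        assert (mass + 2 * 1.00728) / 2 < 400
        assert classify_detectability(seq, 4) == "undetectable:mz"

    def test_non_cysteine_rejected(self):
        with pytest.raises(ValueError):
            classify_detectability("AAAK", 2)

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_matches_bruteforce_oracle(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 2**32 - 1)))
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=200))
        cys = [i + 1 for i, aa in enumerate(seq) if aa == "C"]
        for pos in cys:
            assert classify_detectability(seq, pos) == oracle_detectability(seq, pos)


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        area = shrake_rupley_sasa(
            np.zeros((1, 3)), np.array([1.80]), probe_radius=1.4, n_points=2000
        )[0]
        closed = 4 * math.pi * (1.80 + 1.40) ** 2
        assert abs(area - closed) / closed < 0.005

    def test_point_density_convergence(self):
        closed = 4 * math.pi * 3.2**2
        errs = []
        for n in (100, 500, 2000):
            a = shrake_rupley_sasa(np.zeros((1, 3)), np.array([1.8]), n_points=n)[0]
            errs.append(abs(a - closed) / closed)
        assert errs[-1] < 0.005

    def test_caged_atom_zero(self, toy_complex, toy_structures):
        active, _ = toy_structures
        sasa = gamma_s_sasa(active)
        buried = {
            (s["subunit"], s["position"])
            for s in toy_complex["truth"]["engineered"]
            if s["buried_active"]
        }
        for key in buried:
            assert sasa[key] == 0.0

    def test_translation_equivalent_atoms_equal(self):
        # two S atoms in identical local environments (same offset occluder)
        coords = np.array(
            [[0.0, 0, 0], [3.0, 0, 0], [100.0, 0, 0], [103.0, 0, 0]]
        )
        radii = np.array([1.8, 1.7, 1.8, 1.7])
        a = shrake_rupley_sasa(coords, radii, [0, 2])
        assert 0 < a[0] < 4 * math.pi * 3.2**2
        assert a[0] == pytest.approx(a[1], rel=1e-12)

    def test_no_cysteine_sulfur_empty(self, tmp_path):
        pdb = tmp_path / "x.pdb"
        pdb.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000"
            "  1.00  0.00           C\nEND\n"
        )
        assert gamma_s_sasa(cs.Structure.from_pdb(pdb)) == {}


class TestExposureStates:
    def test_candidate_pattern(self):
        out = classify_exposure_states(2.0, 30.0, cutoff=5.0)
        assert out == {
            "active": "occluded", "deactive": "exposed", "candidate_pattern": True,
        }

    def test_exposed_in_both(self):
        out = classify_exposure_states(12.0, 14.0)
        assert out["candidate_pattern"] is False

    def test_strict_boundary(self):
        out = classify_exposure_states(4.9, 5.0, cutoff=5.0)
        assert out["active"] == "occluded" and out["deactive"] == "occluded"

    def test_unmodeled_deactive_counts_exposed(self):
        out = classify_exposure_states(2.0, None)
        assert out["deactive"] == "exposed" and out["candidate_pattern"] is True


def make_records(
    total=116, conserved=114, quantified=43, no_data=62,
    fes=19, disulfide=18, undetectable=32, fes_or_ss_candidates=44,
):
    """Construct a record set realizing the requested count cascade."""
    records = []
    partial = conserved - quantified - no_data
    extra_fes_partial = fes_or_ss_candidates - fes - disulfide
    for i in range(total):
        idx = i + 1
        rec = CysteineRecord(subunit="X", position=idx, conserved=i < conserved)
        if not rec.conserved:
            records.append(rec)
            continue
        j = i  # index within conserved block
        if j < quantified:
            rec.exposed_fraction = 0.5
        elif j < quantified + no_data:
            k = j - quantified
            if k < fes:
                rec.annotation = "FeS-ligand"
            elif k < fes + disulfide:
                rec.annotation = "intramolecular-disulfide"
            if k >= no_data - undetectable:
                rec.detectability = "undetectable:length"
        else:
            rec.has_partial_data = True
            if j - quantified - no_data < extra_fes_partial:
                rec.annotation = "FeS-ligand"
        records.append(rec)
    assert partial >= 0
    return records


class TestSurveySummary:
    def test_reference_cascade_counts(self):
        summary = survey_summary(make_records())
        assert summary.total == 116
        assert summary.conserved == 114
        assert summary.quantified == 43
        assert summary.no_data == 62
        assert summary.fes_no_data == 19
        assert summary.disulfide_no_data == 18
        assert summary.undetectable_no_data == 32
        assert summary.candidates == 71
        assert summary.fes_or_disulfide_candidates == 44

    def test_percentages_are_rounded_ratios(self):
        s = survey_summary(make_records())
        assert s.pct_quantified == round(100 * 43 / 114, 1) == 37.7
        assert s.pct_undetectable_no_data == round(100 * 32 / 62, 1) == 51.6
        assert s.pct_candidates == round(100 * 71 / 114, 1) == 62.3
        assert s.pct_disulfide_no_data == round(100 * 18 / 62, 1) == 29.0
        assert s.pct_fes_or_disulfide_candidates == round(100 * 44 / 71, 1) == 62.0
        # 19/62 = 30.645...% -> 30.6 under one-decimal rounding
        assert s.pct_fes_no_data == round(100 * 19 / 62, 1) == 30.6

    def test_empty_records(self):
        s = survey_summary([])
        assert s.total == 0
        assert s.pct_quantified is None

    @given(
        n=st.integers(min_value=1, max_value=50),
        q=st.integers(min_value=0, max_value=50),
    )
    def test_self_consistency(self, n, q):
        q = min(q, n)
        recs = [
            CysteineRecord(
                subunit="A", position=i + 1, conserved=True,
                exposed_fraction=0.5 if i < q else None,
            )
            for i in range(n)
        ]
        s = survey_summary(recs)
        assert s.pct_quantified == round(100 * q / n, 1)


class TestRunSurvey:
    def test_toy_complex_zero_error(self, toy_complex, toy_structures):
        active, deactive = toy_structures
        records = cs.run_survey(
            toy_complex["sequences"],
            toy_complex["alignments"],
            toy_complex["truth"]["reference_species"],
            active_structure=active,
            deactive_structure=deactive,
            annotations=toy_complex["annotations"],
        )
        by_key = {(r.subunit, r.position): r for r in records}
        for site in toy_complex["truth"]["engineered"]:
            rec = by_key[(site["subunit"], site["position"])]
            assert rec.conserved == site["conserved"]
            expected_candidate = site["buried_active"] and not site["buried_deactive"]
            assert rec.exposure_category["candidate_pattern"] == expected_candidate
            assert rec.annotation == site["annotation"]

    def test_unmodeled_deactive_candidate(self, tmp_path):
        from cysexpose import synthetic_data as sd

        out = sd.gen_toy_complex(
            engineered_cys=[
                {"subunit": "A", "position": 20, "conserved": True,
                 "buried_active": True, "buried_deactive": True,
                 "annotation": "none", "modeled_deactive": False},
            ],
            seed=3,
        )
        (tmp_path / "a.pdb").write_text(out["pdb_active"])
        (tmp_path / "d.pdb").write_text(out["pdb_deactive"])
        records = cs.run_survey(
            out["sequences"], out["alignments"], "sp0",
            cs.Structure.from_pdb(tmp_path / "a.pdb"),
            cs.Structure.from_pdb(tmp_path / "d.pdb"),
        )
        rec = records[0]
        assert rec.sasa_deactive is None
        assert rec.exposure_category["candidate_pattern"] is True
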