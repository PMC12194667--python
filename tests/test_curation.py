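"""Curation: parsing, standardization, unit arithmetic, replicate merging."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dpphqsar import curation
from dpphqsar.curation import (
    CurationConfig,
    CuratedCompound,
    Qualifier,
    RawActivityRecord,
    StandardizedStructure,
    coefficient_of_variation,
    curate,
    filter_assay_window,
    filter_quantitative,
    filter_small_molecules,
    merge_duplicates,
    parse_value_cell,
    read_activity_table,
    skewness,
    standardize_structure,
    to_molar,
    to_pic50,
)


def _record(**kw):
    defaults = dict(
        record_id="r", smiles="CCO", ic50_value=10.0, ic50_units="uM",
        qualifier=Qualifier.EXACT, assay_text="DPPH, 30 min", assay_time_min=30.0,
    )
    defaults.update(kw)
    return RawActivityRecord(**defaults)


# ---------------------------------------------------------------- parsing

@pytest.mark.parametrize(
    "cell, value, qualifier",
    [
        ("12.5", 12.5, Qualifier.EXACT),
        ("1e-3", 1e-3, Qualifier.EXACT),
        (" 7 ", 7.0, Qualifier.EXACT),
        (">100", 100.0, Qualifier.GREATER_THAN),
        ("> 100", 100.0, Qualifier.GREATER_THAN),
        (">=50", 50.0, Qualifier.GREATER_THAN),
        ("<0.5", 0.5, Qualifier.LESS_THAN),
        ("<= 2e2", 200.0, Qualifier.LESS_THAN),
        ("1:2", None, Qualifier.RATIO),
        ("n.d.", None, Qualifier.UNKNOWN),
    ],
)
def test_value_cell_parsing(cell, value, qualifier):
    got_value, got_qual = parse_value_cell(cell)
    assert got_qual is qualifier
    if value is None:
        assert math.isnan(got_value)
    else:
        assert got_value == value


def test_read_activity_table_round_trip(tmp_path):
    path = tmp_path / "raw.csv"
    path.write_text(
        "record_id,smiles,inchi,ic50_value,ic50_units,qualifier,assay_text,assay_time_min,doi,chembl_id\n"
        "a,CCO,,12.5,uM,,\"DPPH, 30 min\",30,,\n"
        "b,c1ccccc1O,,>100,uM,,\"DPPH, 30 min\",30,,\n"
        "c,CC(=O)O,,3.2,mg/L,,\"DPPH, 30 min\",,,\n"
    )
    records = read_activity_table(path)
    assert len(records) == 3
    assert records[0].ic50_value == 12.5 and records[0].ic50_units == "uM"
    assert records[0].qualifier is Qualifier.EXACT
    assert records[1].qualifier is Qualifier.GREATER_THAN
    assert records[2].assay_time_min is None


def test_read_activity_table_schema_error(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("smiles,ic50_value\nCCO,1\n")
    with pytest.raises(curation.SchemaError, match="ic50_units"):
        read_activity_table(path)


def test_read_activity_table_empty_file(tmp_path):
    path = tmp_path / "empty.csv"
    path.write_text("")
    with pytest.raises((curation.CurationError, Exception)):
        read_activity_table(path)


# ---------------------------------------------------------------- filters

def test_assay_window_keeps_matching_records():
    records = [
        _record(record_id="keep"),
        _record(record_id="offtime", assay_time_min=60.0),
        _record(record_id="abts", assay_text="ABTS, 30 min"),
        _record(record_id="manual1", assay_time_min=None),
        _record(record_id="manual2", assay_time_min=None),
    ]
    kept, dropped, manual = filter_assay_window(records, "DPPH", 30.0)
    assert [r.record_id for r in kept] == ["keep"]
    assert {r.record_id for r in dropped} == {"offtime", "abts"}
    assert len(manual) == 2


def test_assay_window_requires_keyword():
    with pytest.raises(ValueError):
        filter_assay_window([], "", 30.0)


def test_quantitative_filter_drops_qualified_records():
    records = [
        _record(qualifier=Qualifier.EXACT),
        _record(qualifier=Qualifier.LESS_THAN),
        _record(qualifier=Qualifier.RATIO, ic50_value=math.nan),
    ]
    kept, dropped = filter_quantitative(records)
    assert len(kept) == 1 and len(dropped) == 2
    assert kept[0].qualifier is Qualifier.EXACT
    # degenerate directions
    all_exact = [_record(), _record()]
    assert filter_quantitative(all_exact)[0] == all_exact
    assert filter_quantitative([_record(qualifier=Qualifier.GREATER_THAN)] * 3)[0] == []


# ---------------------------------------------------------------- standardization

def test_standardize_simple_molecule_is_identity():
    s = standardize_structure("CCO")
    assert s.canonical_smiles == "CCO"
    assert s.mol_weight == pytest.approx(46.07, abs=0.01)


def test_standardize_strips_salt_and_neutralizes():
    # sodium acetate -> acetic acid (toolkit-checked expected form)
    s = standardize_structure("CC(=O)[O-].[Na+]")
    assert s.canonical_smiles == "CC(=O)O"


def test_standardize_removes_stereo():
    chiral = standardize_structure("C[C@H](N)C(=O)O")
    flat = standardize_structure("CC(N)C(=O)O")
    assert chiral == flat
    assert "@" not in chiral.canonical_smiles


def test_standardize_is_fixed_point(tiny_fixture):
    library = tiny_fixture[0]
    for smiles in library[:10]:
        once = standardize_structure(smiles)
        twice = standardize_structure(once.canonical_smiles)
        assert once == twice


def test_standardize_error_paths():
    with pytest.raises(curation.StructureParseError) as err:
        standardize_structure("not-a-smiles((", record_id="x1")
    assert err.value.record_id == "x1"
    with pytest.raises(curation.InorganicStructureError):
        standardize_structure("[Na+].[Cl-]")


def test_mw_filter_boundary_is_inclusive():
    def fake(mw):
        return StandardizedStructure("C", "InChI=1S/C", mw)

    kept, dropped = filter_small_molecules([fake(180.2), fake(1000.0), fake(1200.0)], 1000.0)
    assert [s.mol_weight for s in kept] == [180.2, 1000.0]
    assert [s.mol_weight for s in dropped] == [1200.0]


# ---------------------------------------------------------------- unit arithmetic

@pytest.mark.parametrize(
    "value, units, mw, expected",
    [
        (10, "uM", None, 1e-5),
        (1, "M", None, 1.0),
        (2.5, "mM", None, 2.5e-3),
        (50, "nM", None, 5e-8),
        (35.5, "ug/mL", 228.2, 1.5556e-4),
        (35.5, "mg/L", 228.2, 1.5556e-4),
        (0.0355, "g/L", 228.2, 1.5556e-4),
        (10, "µM", None, 1e-5),
    ],
)
def test_to_molar(value, units, mw, expected):
    assert to_molar(value, units, mw) == pytest.approx(expected, abs=1e-8)


def test_to_molar_errors():
    with pytest.raises(curation.UnitError):
        to_molar(1.0, "parsec", None)
    with pytest.raises(curation.UnitError):
        to_molar(1.0, "mg/L", None)  # mass unit without molecular weight
    with pytest.raises(ValueError):
        to_molar(-1.0, "uM", None)


@pytest.mark.parametrize("molar, expected", [(1.0, 0.0), (1e-6, 6.0)])
def test_to_pic50(molar, expected):
    assert to_pic50(molar) == expected


def test_to_pic50_of_case_study_concentration():
    assert to_pic50(to_molar(35.5, "ug/mL", 228.2)) == pytest.approx(3.808, abs=0.001)


@given(st.floats(min_value=1e-9, max_value=1e-1), st.floats(min_value=50, max_value=999))
@settings(deadline=None, max_examples=50)
def test_pic50_round_trips_and_is_decreasing(molar, mw):
    pic50 = to_pic50(molar)
    assert 10.0 ** (-pic50) == pytest.approx(molar, rel=1e-9)
    assert to_pic50(molar * 10) == pytest.approx(pic50 - 1, abs=1e-9)


# ---------------------------------------------------------------- CV and skewness

def test_coefficient_of_variation_examples():
    assert coefficient_of_variation([5, 5, 5]) == 0.0
    assert coefficient_of_variation([1, 2, 3]) == pytest.approx(0.5)
    assert coefficient_of_variation([10, 11]) == pytest.approx(0.0673, abs=1e-3)


def test_coefficient_of_variation_errors():
    with pytest.raises(ValueError):
        coefficient_of_variation([1.0])
    with pytest.raises(ValueError):
        coefficient_of_variation([1.0, -2.0])


@given(st.floats(min_value=0.01, max_value=1e4))
@settings(deadline=None, max_examples=50)
def test_coefficient_of_variation_scale_invariant(c):
    base = [2.0, 3.0, 5.0]
    assert coefficient_of_variation([c * v for v in base]) == pytest.approx(
        coefficient_of_variation(base), rel=1e-9
    )


def test_skewness_sign_and_symmetry():
    assert skewness([1, 2, 3]) == pytest.approx(0.0, abs=1e-12)
    assert skewness([1, 1, 1, 10]) > 0


def test_skewness_matches_textbook_formula():
    # adjusted Fisher-Pearson G1 computed from raw moments, independently
    rng = np.random.default_rng(42)
    x = np.exp(rng.standard_normal(200))
    n = x.size
    m2 = np.mean((x - x.mean()) ** 2)
    m3 = np.mean((x - x.mean()) ** 3)
    g1 = m3 / m2 ** 1.5
    G1 = math.sqrt(n * (n - 1)) / (n - 2) * g1
    assert skewness(x) == pytest.approx(G1, abs=1e-9)


def test_skewness_errors():
    with pytest.raises(ValueError):
        skewness([1, 2])
    with pytest.raises(ValueError):
        skewness([3, 3, 3])


# ---------------------------------------------------------------- merging

def _compound(smiles, molar, rid):
    s = standardize_structure(smiles)
    return CuratedCompound(structure=s, ic50_molar=molar, pic50=to_pic50(molar), source_ids=[rid])


def test_merge_passthrough_without_duplicates():
    comps = [_compound("CCO", 1e-5, "a"), _compound("c1ccccc1O", 2e-5, "b")]
    merged, away, dropped = merge_duplicates(comps)
    assert merged == comps and away == 0 and dropped == 0


def test_merge_collapses_low_cv_pair_to_mean():
    comps = [_compound("CCO", 10e-6, "a"), _compound("CCO", 11e-6, "b")]
    merged, away, dropped = merge_duplicates(comps)
    assert len(merged) == 1 and away == 1 and dropped == 0
    assert merged[0].ic50_molar == pytest.approx(10.5e-6)
    assert merged[0].pic50 == pytest.approx(to_pic50(10.5e-6), abs=1e-12)
    assert merged[0].n_merged == 2 and merged[0].source_ids == ["a", "b"]


def test_merge_removes_high_cv_group():
    comps = [_compound("CCO", 10e-6, "a"), _compound("CCO", 20e-6, "b")]
    merged, away, dropped = merge_duplicates(comps)
    assert merged == [] and dropped == 2 and away == 0


def test_merge_cutoff_limits():
    comps = [_compound("CCO", 10e-6, "a"), _compound("CCO", 20e-6, "b")]
    kept_all, _, _ = merge_duplicates(comps, cv_cutoff=1e9)
    assert len(kept_all) == 1  # infinite cutoff keeps every group, mean-collapsed
    removed, _, dropped = merge_duplicates(comps, cv_cutoff=1e-12)
    assert removed == [] and dropped == 2


# ---------------------------------------------------------------- orchestration

def test_curate_reproduces_fixture_manifest(tmp_path, tiny_fixture):
    _, _, frame, manifest = tiny_fixture
    path = tmp_path / "raw.csv"
    frame.to_csv(path, index=False)
    compounds, report = curate(read_activity_table(path))
    got = {c.structure.canonical_smiles: c for c in compounds}
    expected = {s["canonical_smiles"]: s for s in manifest.expected_survivors}
    assert set(got) == set(expected)
    for key, exp in expected.items():
        assert got[key].pic50 == pytest.approx(exp["pic50"], abs=1e-9)
        assert got[key].n_merged == exp["n_merged"]
    for field, value in manifest.expected_counts.items():
        assert getattr(report, field) == value, field
    assert report.is_conserved()
    # the log transform symmetrizes the skewed concentration scale
    assert report.skewness_ic50 > report.skewness_pic50


def test_curate_empty_input():
    compounds, report = curate([])
    assert compounds == [] and report.n_input == 0 and report.is_conserved()


def test_curate_is_idempotent(tmp_path, tiny_fixture):
    _, _, frame, _ = tiny_fixture
    path = tmp_path / "raw.csv"
    frame.to_csv(path, index=False)
    first, _ = curate(read_activity_table(path))
    again = [
        RawActivityRecord(
            record_id=str(i), smiles=c.structure.canonical_smiles, ic50_value=c.ic50_molar,
            ic50_units="M", qualifier=Qualifier.EXACT, assay_text="DPPH, 30 min", assay_time_min=30.0,
        )
        for i, c in enumerate(first)
    ]
    second, _ = curate(again)
    assert {c.structure.canonical_smiles for c in second} == {c.structure.canonical_smiles for c in first}
    by_key = {c.structure.canonical_smiles: c for c in second}
    for c in first:
        assert by_key[c.structure.canonical_smiles].pic50 == pytest.approx(c.pic50, abs=1e-9)
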