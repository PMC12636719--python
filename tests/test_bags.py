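"""Cohort data model, CSV round-trips, patient-level splits, composition."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import caremil as cm
from caremil.bags import CohortError


def test_save_load_round_trip(tiny_cohort, tmp_path):
    manifest = cm.save_cohort(tiny_cohort, tmp_path)
    loaded = cm.load_cohort(manifest)
    assert len(loaded) == len(tiny_cohort)
    for a, b in zip(tiny_cohort, loaded):
        np.testing.assert_allclose(a.bag.embeddings, b.bag.embeddings, rtol=0, atol=0)
        assert a.bag.cell_types == b.bag.cell_types
        assert a.patient_id == b.patient_id
        assert a.label == b.label
        assert a.blast_fraction == pytest.approx(b.blast_fraction)


def test_save_empty_cohort_rejected(tmp_path):
    with pytest.raises(ValueError):
        cm.save_cohort([], tmp_path)


def test_absent_blast_fraction_round_trips_as_none(tiny_cohort, tmp_path):
    tiny_cohort[0].blast_fraction = None
    manifest = cm.save_cohort(tiny_cohort, tmp_path)
    loaded = cm.load_cohort(manifest)
    assert loaded[0].blast_fraction is None
    assert loaded[1].blast_fraction is not None


def test_percent_string_blast_fraction_rejected(tiny_cohort, tmp_path):
    manifest = cm.save_cohort(tiny_cohort, tmp_path)
    df = pd.read_csv(manifest)
    df["blast_fraction"] = df["blast_fraction"].astype(object)
    df.loc[0, "blast_fraction"] = "20%"
    df.to_csv(manifest, index=False)
    with pytest.raises(CohortError, match="blast_fraction"):
        cm.load_cohort(manifest)


def test_dimension_mismatch_across_slides_is_cohort_error(tiny_cohort, tmp_path):
    manifest = cm.save_cohort(tiny_cohort, tmp_path)
    odd = pd.DataFrame(np.ones((3, 5)), columns=[f"dim_{j}" for j in range(5)])
    odd.to_csv(tmp_path / f"{tiny_cohort[0].bag.slide_id}.csv", index=False)
    with pytest.raises(CohortError, match="dimension"):
        cm.load_cohort(manifest)


def test_missing_embedding_file_names_the_slide(tiny_cohort, tmp_path):
    manifest = cm.save_cohort(tiny_cohort, tmp_path)
    (tmp_path / f"{tiny_cohort[2].bag.slide_id}.csv").unlink()
    with pytest.raises(CohortError, match=tiny_cohort[2].bag.slide_id):
        cm.load_cohort(manifest)


def test_non_finite_embedding_reports_row(tmp_path, tiny_cohort):
    manifest = cm.save_cohort(tiny_cohort, tmp_path)
    path = tmp_path / f"{tiny_cohort[0].bag.slide_id}.csv"
    df = pd.read_csv(path)
    df.iloc[1, 0] = np.inf
    df.to_csv(path, index=False)
    with pytest.raises(CohortError, match="row 1"):
        cm.load_cohort(manifest)


def test_bag_invariants():
    with pytest.raises(ValueError):
        cm.CellBag("x", np.empty((0, 3)))
    with pytest.raises(ValueError):
        cm.CellBag("x", np.ones((3, 2)), cell_types=["a"])
    with pytest.raises(ValueError):
        cm.SlideRecord(bag=cm.CellBag("x", np.ones((1, 2))), patient_id="p",
                       label="not-a-class")
    with pytest.raises(ValueError):
        cm.SlideRecord(bag=cm.CellBag("x", np.ones((1, 2))), patient_id="p",
                       label="AL", blast_fraction=1.5)


# --- splits ----------------------------------------------------------------

def _cohort_of_patients(n_patients, slides_per_patient=1, seed=0):
    rng = np.random.default_rng(seed)
    records = []
    for p in range(n_patients):
        for s in range(slides_per_patient):
            bag = cm.CellBag(f"S{p}-{s}", rng.normal(size=(4, 3)))
            records.append(cm.SlideRecord(bag=bag, patient_id=f"P{p:03d}",
                                          label=["AL", "NL"][p % 2]))
    return records


def test_split_exact_rounding_ten_patients():
    records = _cohort_of_patients(10)
    split = cm.split_by_patient(records, (0.6, 0.2, 0.2), seed=7)
    sizes = [len({r.patient_id for r in part})
             for part in (split.train, split.validation, split.test)]
    assert sizes == [6, 2, 2]


def test_split_keeps_multi_slide_patients_together():
    records = _cohort_of_patients(10, slides_per_patient=5)
    split = cm.split_by_patient(records, (0.6, 0.2, 0.2), seed=3)
    for part in (split.train, split.validation, split.test):
        counts = {}
        for r in part:
            counts[r.patient_id] = counts.get(r.patient_id, 0) + 1
        assert all(c == 5 for c in counts.values())


def test_split_deterministic_and_seed_sensitive():
    records = _cohort_of_patients(20)

    def key(split):
        return tuple(sorted(r.bag.slide_id for r in split.train))

    a = cm.split_by_patient(records, (0.6, 0.2, 0.2), seed=11)
    b = cm.split_by_patient(records, (0.6, 0.2, 0.2), seed=11)
    c = cm.split_by_patient(records, (0.6, 0.2, 0.2), seed=12)
    assert key(a) == key(b)
    assert key(a) != key(c)


def test_split_requires_three_patients():
    with pytest.raises(ValueError):
        cm.split_by_patient(_cohort_of_patients(2), (0.6, 0.2, 0.2), seed=0)


@settings(max_examples=100, deadline=None)
@given(n_patients=st.integers(3, 40), seed=st.integers(0, 2**31 - 1),
       slides=st.integers(1, 3))
def test_split_partitions_are_disjoint_and_exhaustive(n_patients, seed, slides):
    records = _cohort_of_patients(n_patients, slides_per_patient=slides, seed=seed)
    split = cm.split_by_patient(records, (0.5, 0.25, 0.25), seed=seed)
    pid_sets = [{r.patient_id for r in part}
                for part in (split.train, split.validation, split.test)]
    assert not (pid_sets[0] & pid_sets[1] or pid_sets[0] & pid_sets[2]
                or pid_sets[1] & pid_sets[2])
    all_ids = sorted(r.bag.slide_id for r in split.all_records)
    assert all_ids == sorted(r.bag.slide_id for r in records)


# --- composition -----------------------------------------------------------

def test_composition_direct_count():
    bag = cm.CellBag("b", np.ones((3, 2)), cell_types=["A", "A", "B"])
    comp = cm.composition_vector(bag, ["A", "B", "C"])
    assert comp.fractions == {"A": pytest.approx(2 / 3), "B": pytest.approx(1 / 3), "C": 0.0}


def test_composition_single_type_and_unknown_label():
    bag = cm.CellBag("b", np.ones((4, 2)), cell_types=["A"] * 4)
    comp = cm.composition_vector(bag, ["A", "B"])
    assert comp.fractions["A"] == 1.0 and comp.fractions["B"] == 0.0
    bad = cm.CellBag("b", np.ones((1, 2)), cell_types=["D"])
    with pytest.raises(ValueError, match="'D'"):
        cm.composition_vector(bad, ["A", "B"])
    untyped = cm.CellBag("b", np.ones((1, 2)))
    with pytest.raises(ValueError, match="cell_types"):
        cm.composition_vector(untyped, ["A", "B"])


@settings(max_examples=50, deadline=None)
@given(st.lists(st.sampled_from(["A", "B", "C", "D"]), min_size=1, max_size=60))
def test_composition_fractions_sum_to_one_exactly(types):
    bag = cm.CellBag("b", np.ones((len(types), 2)), cell_types=types)
    comp = cm.composition_vector(bag, ["A", "B", "C", "D"])
    counts = {t: types.count(t) for t in "ABCD"}
    # rational-arithmetic ground truth
    assert sum(Fraction(counts[t], len(types)) for t in "ABCD") == 1
    assert all(comp.fractions[t] == pytest.approx(counts[t] / len(types), abs=1e-15)
               for t in "ABCD")
    assert sum(comp.fractions.values()) == pytest.approx(1.0, abs=1e-9)
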