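"""Comorbidity flag assignment, hierarchies, DRG screen, and selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import casemix.elixhauser as ex
from casemix.elixhauser import (
    ComorbidityProfile,
    apply_drg_screen,
    apply_hierarchy,
    assign_flags,
    assign_flags_table,
    condition_keys,
    prevalence_table,
    select_conditions,
)


def true_keys(profile):
    return set(profile.true_keys())


def test_definition_table_has_thirty_conditions(definitions):
    keys = condition_keys(definitions)
    assert len(keys) == 30
    assert keys[0] == "congestive_heart_failure"
    assert "hypertension" in keys  # combined sub-rows
    assert "blood_loss_anemia" in keys


@pytest.mark.parametrize(
    "codes, expected",
    [
        (["4280"], {"congestive_heart_failure"}),
        ([], set()),
        (["25000", "25040"], {"diabetes_uncomplicated", "diabetes_complicated"}),
        (["V45.0"], {"cardiac_arrhythmias"}),
        (["401.9", "402.90"], {"hypertension"}),
        (["2800"], {"blood_loss_anemia"}),
        (["280.1"], {"deficiency_anemias"}),
        (["042"], {"aids_hiv"}),
        (["not-a-code", "4280"], {"congestive_heart_failure"}),  # bad code skipped
    ],
)
def test_assign_flags_matches_definition_patterns(definitions, codes, expected):
    assert true_keys(assign_flags(codes, definitions)) == expected


def test_hierarchy_keeps_only_the_severe_member(definitions):
    both = assign_flags(["25000", "25040", "196.0", "174.0"], definitions)
    assert true_keys(both) >= {
        "diabetes_uncomplicated", "diabetes_complicated",
        "metastatic_cancer", "solid_tumor",
    }
    resolved = apply_hierarchy(both)
    assert true_keys(resolved) == {"diabetes_complicated", "metastatic_cancer"}
    # idempotent, and identity when no pair is present
    assert apply_hierarchy(resolved) == resolved
    single = assign_flags(["4280"], definitions)
    assert apply_hierarchy(single) == single


@given(st.lists(st.sampled_from(
    ["4280", "42731", "V45.0", "25000", "250.40", "196.0", "174.0", "2800",
     "3004", "9999", "480", "V57.1"]), max_size=8))
def test_assign_flags_is_permutation_and_duplication_invariant(definitions_cache, codes):
    definitions = definitions_cache
    base = assign_flags(codes, definitions)
    assert assign_flags(list(reversed(codes)), definitions) == base
    assert assign_flags(codes + codes, definitions) == base
    # profile equals element-wise OR of single-code profiles (pre-hierarchy)
    union: set[str] = set()
    for c in codes:
        union |= true_keys(assign_flags([c], definitions))
    assert true_keys(base) == union


@pytest.fixture(scope="module")
def definitions_cache(definitions):
    return definitions


@given(st.integers(0, 2**30 - 1))
def test_hierarchy_is_idempotent_and_only_clears_flags(definitions_cache, seed):
    keys = condition_keys(definitions_cache)
    rng = np.random.default_rng(seed)
    profile = ComorbidityProfile(dict(zip(keys, rng.random(len(keys)) < 0.4)))
    once = apply_hierarchy(profile)
    assert apply_hierarchy(once) == once
    for k in keys:
        assert once.flags[k] <= profile.flags[k]
    assert not (once.flags["diabetes_uncomplicated"] and once.flags["diabetes_complicated"])
    assert not (once.flags["solid_tumor"] and once.flags["metastatic_cancer"])


def test_drg_screen_clears_flag_for_principal_disease_group(definitions):
    chf = assign_flags(["4280"], definitions)
    screened = apply_drg_screen(chf, 127, definitions)  # cardiac DRG
    assert not screened.flags["congestive_heart_failure"]
    unrelated = apply_drg_screen(chf, 430, definitions)  # psychoses DRG
    assert unrelated.flags["congestive_heart_failure"]


def test_drg_screen_without_drg_warns_once_and_passes_through(definitions):
    chf = assign_flags(["4280"], definitions)
    ex._warned_missing_drg = False
    with pytest.warns(UserWarning, match="DRG missing"):
        assert apply_drg_screen(chf, None, definitions) == chf
    # second call stays silent
    import warnings as w
    with w.catch_warnings():
        w.simplefilter("error")
        apply_drg_screen(chf, None, definitions)


def test_prevalence_table_counts_and_percent(definitions):
    lists = [["4280"], [], [], []]
    table = prevalence_table(assign_flags_table(lists, definitions))
    chf = table.set_index("condition").loc["congestive_heart_failure"]
    assert chf["count"] == 1 and chf["percent"] == 25.0
    assert (table.set_index("condition")["count"].drop("congestive_heart_failure") == 0).all()
    with pytest.raises(ValueError):
        prevalence_table(pd.DataFrame(columns=["congestive_heart_failure"]))


def test_select_conditions_exclusions_and_min_count(definitions):
    lists = [["4280"]] * 20 + [["2800"]] * 6 + [["042"]] * 6
    table = prevalence_table(assign_flags_table(lists, definitions))
    assert len(select_conditions(table)) == 29  # default drops blood-loss anemia
    kept = select_conditions(table, exclusions=(), min_count=0)
    assert len(kept) == 30
    sparse = select_conditions(table, exclusions=(), min_count=10)
    assert "aids_hiv" not in sparse and "congestive_heart_failure" in sparse
    with pytest.raises(ValueError):
        select_conditions(table, exclusions=("no_such_condition",))
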