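import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comorbnet.claims_pdn import (
    EXCLUDED,
    CodeError,
    CategoryProfile,
    EmptyPopulationError,
    PrevalenceCounts,
    StratumFilter,
    UndefinedPhiError,
    assign_category,
    build_pdn,
    canonical_code,
    category_profile,
    classify_dm_type,
    compare_profiles,
    count_prevalences,
    phi_correlation,
    truncate_code,
)
from comorbnet.synthetic_data import generate_cohort


def _claims(rows):
    cols = ["patient_id", "sex", "age", "admission_date", "dx1", "dx2", "dx3", "dx4", "dx5"]
    return pd.DataFrame([dict(zip(cols, r + [""] * (len(cols) - len(r)))) for r in rows])


# --------------------------------------------------------------------------
# phi-correlation


@pytest.mark.parametrize(
    "N, N_i, N_j, N_ij, expected",
    [
        (1000, 100, 50, 5, 0.0),          # N_ij = N_i*N_j/N: independence
        (100, 20, 20, 20, 1.0),           # identical indicator vectors
        (1000, 100, 50, 20, 0.22941573387056177),  # frozen Pearson oracle
        (100, 50, 50, 0, -1.0),           # perfectly disjoint halves
    ],
)
def test_phi_matches_contingency_formula(N, N_i, N_j, N_ij, expected):
    assert phi_correlation(N, N_i, N_j, N_ij) == pytest.approx(expected, abs=1e-12)


def _pearson_on_indicators(N, N_i, N_j, N_ij):
    """Oracle: build the two 0/1 vectors explicitly and correlate them."""
    x = np.zeros(N)
    y = np.zeros(N)
    x[:N_i] = 1
    y[:N_ij] = 1
    y[N_i : N_i + (N_j - N_ij)] = 1
    return float(np.corrcoef(x, y)[0, 1])


@settings(max_examples=1000)
@given(st.data())
def test_phi_equals_pearson_of_indicator_vectors(data):
    N = data.draw(st.integers(4, 400))
    N_i = data.draw(st.integers(1, N - 1))
    N_j = data.draw(st.integers(1, N - 1))
    lo = max(0, N_i + N_j - N)
    N_ij = data.draw(st.integers(lo, min(N_i, N_j)))
    assert phi_correlation(N, N_i, N_j, N_ij) == pytest.approx(
        _pearson_on_indicators(N, N_i, N_j, N_ij), abs=1e-9
    )


def test_phi_undefined_for_absent_or_universal_disease():
    with pytest.raises(UndefinedPhiError):
        phi_correlation(100, 0, 10, 0)
    with pytest.raises(UndefinedPhiError):
        phi_correlation(100, 10, 100, 10)
    with pytest.raises(ValueError):
        phi_correlation(100, 10, 10, 20)  # N_ij above the marginals


# --------------------------------------------------------------------------
# ICD handling


@pytest.mark.parametrize(
    "codes, expected",
    [
        (["25011", "4019"], "T1D"),
        (["250.13"], "T1D"),
        (["25000"], "T2D"),
        (["250.02"], "T2D"),
        (["2504"], "other"),   # 4-digit 250 without conclusive 5th digit
        (["25004"], "other"),  # 5th digit outside 0-3 typing
        (["4019"], "none"),
        (["25000", "25011"], "T1D"),  # T1D precedence over T2D codes
    ],
)
def test_diabetes_typing_from_fifth_digit(codes, expected):
    assert classify_dm_type(codes) == expected


def test_malformed_code_rejected_with_name():
    with pytest.raises(CodeError, match="25x"):
        classify_dm_type(["25x"])
    with pytest.raises(CodeError):
        canonical_code("")
    with pytest.raises(CodeError):
        canonical_code("1234567")


@pytest.mark.parametrize(
    "raw, canon", [("250.01", "25001"), ("25001", "25001"), ("V27", "V27"),
                   ("E950.1", "E9501"), ("401", "401")]
)
def test_code_canonicalization_strips_decimal_point(raw, canon):
    assert canonical_code(raw) == canon


def test_truncation_respects_e_code_roots():
    assert truncate_code("250.01", 3) == "250"
    assert truncate_code("250.01", 4) == "2500"
    assert truncate_code("250.01", 5) == "25001"
    assert truncate_code("E950.1", 3) == "E950"


# --------------------------------------------------------------------------
# prevalence counting


def test_patient_counted_once_despite_repeat_admissions():
    claims = _claims(
        [
            ["p1", "M", 30, "2002-01-01", "401"],
            ["p1", "M", 30, "2003-06-01", "401"],
        ]
    )
    counts = count_prevalences(claims)
    assert counts.N == 1 and counts.N_i["401"] == 1
    assert counts.N_ij == {}


def test_pair_counts_are_patient_level():
    claims = _claims(
        [
            ["p1", "M", 30, "2002-01-01", "401", "250.01"],
            ["p2", "F", 40, "2002-02-01", "401"],
        ]
    )
    counts = count_prevalences(claims)
    assert counts.N == 2
    assert counts.N_i == {"401": 2, "250": 1}
    assert counts.N_ij == {("250", "401"): 1}


def test_empty_stratum_is_an_explicit_error():
    claims = _claims([["p1", "M", 30, "2002-01-01", "401"]])
    with pytest.raises(EmptyPopulationError, match="F"):
        count_prevalences(claims, StratumFilter(sex="F"))


def test_counts_match_generator_ground_truth(small_cohort_spec):
    claims, truth = generate_cohort(small_cohort_spec)
    counts = count_prevalences(claims)
    assert counts.N == truth.N
    for code, n in truth.N_i.items():
        assert counts.N_i[code] == n
    for pair, n in truth.N_ij.items():
        assert counts.N_ij.get(pair, 0) == n


def test_stratum_filters_compose():
    claims, _ = generate_cohort(_spec_for_strata())
    male = count_prevalences(claims, StratumFilter(sex="M"))
    female = count_prevalences(claims, StratumFilter(sex="F"))
    assert male.N + female.N == count_prevalences(claims).N
    t1d = count_prevalences(claims, StratumFilter(dm_type="T1D"))
    assert 0 < t1d.N < male.N + female.N


def _spec_for_strata():
    from comorbnet.synthetic_data import DiseaseSpec, SyntheticCohortSpec

    return SyntheticCohortSpec(
        n_patients=800,
        diseases=[DiseaseSpec("401", 0.2)],
        dm_type_mix={"T1D": 0.4, "T2D": 0.6},
        seed=5,
    )


# --------------------------------------------------------------------------
# PDN thresholding


def _counts_with_ranked_pairs(n_pairs=100):
    """15 diseases, N_ij chosen so candidate phis are strictly ordered."""
    codes = [f"{i:03d}" for i in range(101, 116)]
    n_i = {c: 400 for c in codes}
    pairs = [
        (codes[a], codes[b])
        for a in range(len(codes))
        for b in range(a + 1, len(codes))
    ][:n_pairs]
    n_ij = {p: 1 + k for k, p in enumerate(pairs)}
    return PrevalenceCounts(N=10000, N_i=n_i, N_ij=n_ij)


def test_top_fraction_keeps_ceil_of_candidates():
    counts = _counts_with_ranked_pairs(100)
    pdn = build_pdn(counts, threshold_fraction=0.006)  # ceil(0.6) = 1
    assert len(pdn.links) == 1
    best = max(counts.N_ij, key=counts.N_ij.get)
    assert (pdn.links[0].code_i, pdn.links[0].code_j) == best


def test_equal_phi_ties_are_all_retained():
    n_i = {"401": 100, "402": 100, "403": 100}
    n_ij = {("401", "402"): 10, ("401", "403"): 10, ("402", "403"): 10}
    pdn = build_pdn(PrevalenceCounts(1000, n_i, n_ij), threshold_fraction=0.006)
    assert len(pdn.links) == 3


def test_raising_fraction_never_drops_links():
    counts = _counts_with_ranked_pairs(100)
    kept_small = {
        (l.code_i, l.code_j) for l in build_pdn(counts, 0.05).links
    }
    kept_large = {
        (l.code_i, l.code_j) for l in build_pdn(counts, 0.30).links
    }
    assert kept_small <= kept_large


def test_every_retained_phi_dominates_every_rejected_phi():
    counts = _counts_with_ranked_pairs(100)
    pdn = build_pdn(counts, 0.10)
    kept = {(l.code_i, l.code_j) for l in pdn.links}
    kept_min = min(l.phi for l in pdn.links)
    rejected = [
        counts.phi(a, b) for (a, b) in counts.N_ij if (a, b) not in kept
    ]
    assert kept_min >= max(rejected)


def test_pdn_invariant_to_claim_row_order(small_cohort_spec):
    claims, _ = generate_cohort(small_cohort_spec)
    shuffled = claims.sample(frac=1, random_state=7)
    a = build_pdn(count_prevalences(claims), 0.2)
    b = build_pdn(count_prevalences(shuffled), 0.2)
    assert a.link_table().equals(b.link_table())


def test_planted_pair_survives_thresholding(small_cohort_spec):
    claims, _ = generate_cohort(small_cohort_spec)
    pdn = build_pdn(count_prevalences(claims), threshold_fraction=0.1)
    assert {("401", "585")} <= {(l.code_i, l.code_j) for l in pdn.links}
    # the planted pair has the single highest phi of all candidates
    assert max(pdn.links, key=lambda l: l.phi).code_i in ("401", "585")


def test_no_candidates_warns_and_returns_empty():
    counts = PrevalenceCounts(N=10, N_i={"401": 3}, N_ij={})
    with pytest.warns(UserWarning):
        pdn = build_pdn(counts)
    assert pdn.links == [] and pdn.nodes == {}


# --------------------------------------------------------------------------
# categories and profiles


@pytest.mark.parametrize(
    "code, expected",
    [
        ("401.1", "390-459 circulatory"),
        ("250.01", "240-279 endocrine, nutritional, metabolic, immunity"),
        ("139", "001-139 infectious and parasitic"),
        ("140", "140-239 neoplasms"),
        ("759", "740-759 congenital anomalies"),
        ("850", EXCLUDED),   # injury
        ("650", EXCLUDED),   # pregnancy
        ("760", EXCLUDED),   # perinatal
        ("780", EXCLUDED),   # symptoms
        ("V27", EXCLUDED),
        ("E950", EXCLUDED),
    ],
)
def test_thirteen_chapter_categories(code, expected):
    assert assign_category(code) == expected


def test_profile_counts_non_excluded_nodes():
    pdn = build_pdn(
        PrevalenceCounts(
            1000,
            {"401": 100, "402": 80, "25001": 60, "800": 50},
            {("401", "402"): 30, ("25001", "401"): 20, ("401", "800"): 25},
        ),
        threshold_fraction=1.0,
    )
    prof = category_profile(pdn)
    assert prof.counts["390-459 circulatory"] == 2
    assert prof.counts["240-279 endocrine, nutritional, metabolic, immunity"] == 1
    assert prof.total == 3  # the 800 node is excluded


def test_identical_profiles_compare_as_null():
    p = CategoryProfile({"390-459 circulatory": 5, "140-239 neoplasms": 5}, 10)
    out = compare_profiles(p, p).set_index("category")
    row = out.loc["390-459 circulatory"]
    assert row["z"] == 0 and row["p"] == pytest.approx(1.0)
    assert not out["significant"].any()


def test_proportion_z_matches_pooled_formula_and_statsmodels():
    a = CategoryProfile({"140-239 neoplasms": 30}, 100)
    b = CategoryProfile({"140-239 neoplasms": 10}, 100)
    row = (
        compare_profiles(a, b)
        .set_index("category")
        .loc["140-239 neoplasms"]
    )
    assert row["z"] == pytest.approx(3.5355339, abs=1e-6)
    assert row["p"] == pytest.approx(4.069520e-4, rel=1e-5)
    assert row["significant"] and row["direction"] == "a>b"

    from statsmodels.stats.proportion import proportions_ztest

    z_sm, p_sm = proportions_ztest([30, 10], [100, 100])
    assert row["z"] == pytest.approx(z_sm) and row["p"] == pytest.approx(p_sm)


def test_zero_zero_category_flagged_undefined():
    a = CategoryProfile({"140-239 neoplasms": 10}, 100)
    b = CategoryProfile({"140-239 neoplasms": 12}, 100)
    out = compare_profiles(a, b).set_index("category")
    row = out.loc["390-459 circulatory"]  # 0 vs 0
    assert row["undefined"] and not row["significant"]
    assert math.isnan(row["z"])


def test_bonferroni_divides_the_level():
    a = CategoryProfile({"140-239 neoplasms": 20}, 100)
    b = CategoryProfile({"140-239 neoplasms": 8}, 100)
    plain = compare_profiles(a, b).set_index("category")
    strict = compare_profiles(a, b, bonferroni=True).set_index("category")
    row = "140-239 neoplasms"
    assert plain.loc[row, "significant"]
    assert not strict.loc[row, "significant"]
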