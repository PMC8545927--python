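"""Phenotypic disease networks (PDNs) from inpatient claims.

A PDN is a graph whose nodes are diseases (ICD-9-CM codes) and whose
links are strong pairwise comorbidity correlations measured with the
phi-correlation — the Pearson correlation of the two binary
disease-indicator variables across patients:

    phi_ij = (N*N_ij - N_i*N_j) / sqrt(N_i*N_j*(N - N_i)*(N - N_j))

where ``N`` is the number of patients in the population, ``N_i`` and
``N_j`` the prevalences (patients carrying disease i, resp. j) and
``N_ij`` the number of patients carrying both.  Only the top fraction
of ranked candidate links (default 0.6%) is retained.

Diseases are grouped into 13 ICD-9-CM chapter categories; chapters for
pregnancy, perinatal conditions, symptoms, injuries/poisonings and
E/V supplementary codes are excluded from category profiles.  Two PDNs
are compared category-by-category with a pooled two-sample proportion
z-test.
"""

from __future__ import annotations

import itertools
import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CodeError",
    "EmptyPopulationError",
    "UndefinedPhiError",
    "CATEGORY_LABELS",
    "EXCLUDED",
    "ComorbidityLink",
    "PrevalenceCounts",
    "PDN",
    "CategoryProfile",
    "StratumFilter",
    "canonical_code",
    "truncate_code",
    "classify_dm_type",
    "phi_correlation",
    "claims_to_patients",
    "count_prevalences",
    "build_pdn",
    "assign_category",
    "category_profile",
    "compare_profiles",
]


class CodeError(ValueError):
    """A diagnosis code string is not valid ICD-9-CM syntax."""


class EmptyPopulationError(ValueError):
    """A stratum filter left no patients to analyse."""


class UndefinedPhiError(ValueError):
    """phi is undefined because a disease is absent or universal."""


# Numeric ICD-9-CM with optional 4th/5th digit, or supplementary
# V (2 digits) / E (3 digits) codes; the decimal point is optional.
_CODE_RE = re.compile(
    r"""^(?:
        \d{3}(?:\.?\d{1,2})?     # 001-999 with up to two subdigits
      | V\d{2}(?:\.?\d{1,2})?    # V01-V91
      | E\d{3}(?:\.?\d)?         # E800-E999
    )$""",
    re.IGNORECASE | re.VERBOSE,
)


def canonical_code(code: str) -> str:
    """Validate an ICD-9-CM code and return it without the decimal point.

    Both ``"250.01"`` and ``"25001"`` canonicalize to ``"25001"``.
    Raises :class:`CodeError` for anything else.
    """
    s = str(code).strip()
    if not s or not _CODE_RE.match(s):
        raise CodeError(f"not a valid ICD-9-CM code: {code!r}")
    return s.replace(".", "").upper()


def truncate_code(code: str, node_level: int = 3) -> str:
    """Truncate a canonical code to the 3/4/5-digit node granularity."""
    if node_level not in (3, 4, 5):
        raise ValueError("node_level must be 3, 4 or 5")
    c = canonical_code(code)
    # E codes carry 4 leading characters before subdigits (E + 3 digits)
    root = 4 if c.startswith("E") else 3
    return c[: root + (node_level - 3)]


def classify_dm_type(codes: Iterable[str]) -> str:
    """Classify a patient's diabetes type from their diagnosis codes.

    The 5th digit of a 250.xx code encodes the type: 1 or 3 means
    type 1 (insulin-dependent), 0 or 2 means type 2.  Returns one of
    ``"T1D"``, ``"T2D"``, ``"other"`` (a 250 code without a
    conclusive 5th digit) or ``"none"``.  T1D takes precedence when a
    patient carries codes of both types.
    """
    has_t2d = False
    has_dm = False
    for code in codes:
        c = canonical_code(code)
        if not c.startswith("250"):
            continue
        has_dm = True
        if len(c) == 5:
            fifth = c[4]
            if fifth in "13":
                return "T1D"
            if fifth in "02":
                has_t2d = True
    if has_t2d:
        return "T2D"
    return "other" if has_dm else "none"


def phi_correlation(N: int, N_i: int, N_j: int, N_ij: int) -> float:
    """phi-correlation between two diseases from 2x2 contingency counts.

    Equals the Pearson correlation of the two binary indicator vectors
    of length ``N``.  Raises :class:`UndefinedPhiError` when either
    disease is absent (``N_i == 0``) or universal (``N_i == N``), in
    which case the denominator vanishes.
    """
    if not (0 <= N_ij <= min(N_i, N_j) <= N):
        raise ValueError(
            f"inconsistent counts: N={N}, N_i={N_i}, N_j={N_j}, N_ij={N_ij}"
        )
    if N_i in (0, N) or N_j in (0, N):
        raise UndefinedPhiError(
            f"phi undefined for N_i={N_i}, N_j={N_j} with N={N}"
        )
    num = N * N_ij - N_i * N_j
    den = math.sqrt(N_i * N_j * (N - N_i) * (N - N_j))
    return num / den


# --------------------------------------------------------------------------
# prevalence counting


@dataclass(frozen=True)
class StratumFilter:
    """Patient-level stratum: diabetes type, sex, and/or age range.

    ``age_range`` is inclusive on both ends, on the age at the
    patient's first recorded admission.  ``dm_type`` may be any of
    {"T1D", "T2D", "other", "none"}; ``None`` means no restriction.
    """

    dm_type: str | None = None
    sex: str | None = None
    age_range: tuple[int, int] | None = None

    def describe(self) -> str:
        parts = []
        if self.dm_type:
            parts.append(self.dm_type)
        if self.sex:
            parts.append(self.sex)
        if self.age_range:
            parts.append(f"age {self.age_range[0]}-{self.age_range[1]}")
        return ", ".join(parts) if parts else "all patients"


@dataclass
class PrevalenceCounts:
    """Patient-level disease prevalence tallies for one stratum.

    ``N`` is the number of distinct patients; ``N_i`` maps a disease
    code to the number of patients carrying it; ``N_ij`` maps an
    unordered code pair to the number of patients carrying both.  A
    patient contributes at most once to any count regardless of the
    number of hospitalizations.
    """

    N: int
    N_i: dict[str, int]
    N_ij: dict[tuple[str, str], int]
    stratum: str = "all patients"

    def __post_init__(self) -> None:
        for (a, b), nij in self.N_ij.items():
            if nij > min(self.N_i.get(a, 0), self.N_i.get(b, 0)):
                raise ValueError(f"N_ij for {(a, b)} exceeds a marginal count")
        if any(n > self.N for n in self.N_i.values()):
            raise ValueError("a prevalence count exceeds the population size")

    def phi(self, code_i: str, code_j: str) -> float:
        pair = tuple(sorted((code_i, code_j)))
        return phi_correlation(
            self.N,
            self.N_i[code_i],
            self.N_i[code_j],
            self.N_ij.get(pair, 0),
        )


_DX_COLS = ["dx1", "dx2", "dx3", "dx4", "dx5"]


def claims_to_patients(claims: pd.DataFrame) -> pd.DataFrame:
    """Collapse a claims table to one row per patient.

    Expects columns ``patient_id, sex, age, admission_date, dx1..dx5``
    (dx2..dx5 may be empty/NaN).  Returns a frame indexed by patient
    with ``sex``, ``age`` (at first admission), ``dm_type`` and
    ``codes`` (the deduplicated set of canonical codes across all of
    the patient's claims).
    """
    df = claims.copy()
    dx_cols = [c for c in _DX_COLS if c in df.columns]
    if "dx1" not in dx_cols:
        raise ValueError("claims table must have at least a dx1 column")
    df = df.sort_values(["patient_id", "admission_date"], kind="stable")

    long = df.melt(
        id_vars=["patient_id"], value_vars=dx_cols, value_name="code"
    )[["patient_id", "code"]]
    long = long[long["code"].notna() & (long["code"].astype(str).str.strip() != "")]
    # validate/canonicalize each distinct spelling once
    canon = {c: canonical_code(c) for c in long["code"].unique()}
    long["code"] = long["code"].map(canon)
    code_sets = long.groupby("patient_id", sort=True)["code"].agg(frozenset)

    first = df.drop_duplicates("patient_id", keep="first").set_index("patient_id")
    out = pd.DataFrame(
        {
            "sex": first["sex"],
            "age": first["age"].astype(int),
            "codes": code_sets.reindex(first.index),
        }
    )
    out["dm_type"] = [classify_dm_type(cs) for cs in out["codes"]]
    out.index.name = "patient_id"
    return out[["sex", "age", "dm_type", "codes"]]


def count_prevalences(
    claims: pd.DataFrame,
    stratum: StratumFilter | None = None,
    node_level: int = 3,
) -> PrevalenceCounts:
    """Count patient-level disease prevalences and co-occurrences.

    Codes are truncated to ``node_level`` digits before counting, so a
    patient with 250.01 and 250.13 counts once toward the 3-digit node
    250.  Raises :class:`EmptyPopulationError` if the stratum filter
    leaves no patients.
    """
    patients = (
        claims
        if {"codes", "dm_type"}.issubset(claims.columns)
        else claims_to_patients(claims)
    )
    if stratum is not None:
        mask = pd.Series(True, index=patients.index)
        if stratum.dm_type is not None:
            mask &= patients["dm_type"] == stratum.dm_type
        if stratum.sex is not None:
            mask &= patients["sex"] == stratum.sex
        if stratum.age_range is not None:
            lo, hi = stratum.age_range
            mask &= (patients["age"] >= lo) & (patients["age"] <= hi)
        patients = patients[mask]
    if len(patients) == 0:
        desc = stratum.describe() if stratum else "all patients"
        raise EmptyPopulationError(f"no patients in stratum: {desc}")

    n_i: dict[str, int] = {}
    n_ij: dict[tuple[str, str], int] = {}
    for codes in patients["codes"]:
        nodes = sorted({truncate_code(c, node_level) for c in codes})
        for c in nodes:
            n_i[c] = n_i.get(c, 0) + 1
        for pair in itertools.combinations(nodes, 2):
            n_ij[pair] = n_ij.get(pair, 0) + 1
    return PrevalenceCounts(
        N=len(patients),
        N_i=n_i,
        N_ij=n_ij,
        stratum=stratum.describe() if stratum else "all patients",
    )


# --------------------------------------------------------------------------
# PDN construction


@dataclass(frozen=True)
class ComorbidityLink:
    """One PDN edge: an unordered disease pair with its phi value."""

    code_i: str
    code_j: str
    phi: float
    n_ij: int

    def __post_init__(self) -> None:
        if self.code_i == self.code_j:
            raise ValueError("a comorbidity link needs two distinct diseases")
        if not -1.0 - 1e-12 <= self.phi <= 1.0 + 1e-12:
            raise ValueError(f"phi out of [-1, 1]: {self.phi}")


@dataclass
class PDN:
    """A phenotypic disease network for one patient stratum."""

    nodes: dict[str, str]  # code -> category label (or EXCLUDED)
    links: list[ComorbidityLink]
    stratum: str
    threshold_fraction: float
    prevalence: dict[str, float] = field(default_factory=dict)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(stratum=self.stratum)
        for code, cat in self.nodes.items():
            g.add_node(code, category=cat, prevalence=self.prevalence.get(code))
        for link in self.links:
            g.add_edge(link.code_i, link.code_j, phi=link.phi, n_ij=link.n_ij)
        return g

    def link_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(l.code_i, l.code_j, l.n_ij, l.phi) for l in self.links],
            columns=["code_i", "code_j", "n_ij", "phi"],
        )


def build_pdn(
    counts: PrevalenceCounts,
    threshold_fraction: float = 0.006,
) -> PDN:
    """Threshold the ranked comorbidity links into a PDN.

    Candidate links are all unordered pairs with at least one shared
    patient and a defined phi.  They are ranked by phi descending and
    the top ``ceil(threshold_fraction * n_candidates)`` retained,
    extended through ties at the cutoff value; nodes are the endpoints
    of retained links.
    """
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must be in (0, 1]")
    candidates: list[ComorbidityLink] = []
    for (a, b), nij in counts.N_ij.items():
        if nij < 1:
            continue
        try:
            phi = counts.phi(a, b)
        except UndefinedPhiError:
            continue
        candidates.append(ComorbidityLink(a, b, phi, nij))
    if not candidates:
        warnings.warn(f"no candidate links in stratum {counts.stratum!r}")
        return PDN({}, [], counts.stratum, threshold_fraction)

    candidates.sort(key=lambda l: (-l.phi, l.code_i, l.code_j))
    k = math.ceil(threshold_fraction * len(candidates))
    cutoff = candidates[k - 1].phi
    kept = [l for l in candidates if l.phi >= cutoff]

    nodes = sorted({c for l in kept for c in (l.code_i, l.code_j)})
    return PDN(
        nodes={c: assign_category(c) for c in nodes},
        links=kept,
        stratum=counts.stratum,
        threshold_fraction=threshold_fraction,
        prevalence={c: counts.N_i[c] / counts.N for c in nodes},
    )


# --------------------------------------------------------------------------
# disease categories

EXCLUDED = "EXCLUDED"

# 13 retained ICD-9-CM chapter categories (3-digit root ranges).
# Pregnancy (630-679), perinatal (760-779), symptoms/ill-defined
# (780-799), injury and poisoning (800-999) and the supplementary E/V
# chapters are excluded.
CATEGORY_LABELS: dict[tuple[int, int], str] = {
    (1, 139): "001-139 infectious and parasitic",
    (140, 239): "140-239 neoplasms",
    (240, 279): "240-279 endocrine, nutritional, metabolic, immunity",
    (280, 289): "280-289 blood and blood-forming organs",
    (290, 319): "290-319 mental disorders",
    (320, 389): "320-389 nervous system and sense organs",
    (390, 459): "390-459 circulatory",
    (460, 519): "460-519 respiratory",
    (520, 579): "520-579 digestive",
    (580, 629): "580-629 genitourinary",
    (680, 709): "680-709 skin and subcutaneous tissue",
    (710, 739): "710-739 musculoskeletal and connective tissue",
    (740, 759): "740-759 congenital anomalies",
}


def assign_category(code: str) -> str:
    """Map an ICD-9-CM code to one of the 13 chapter categories.

    Returns :data:`EXCLUDED` for pregnancy, perinatal, symptom,
    injury/poisoning and supplementary (E/V) codes.
    """
    c = canonical_code(code)
    if c.startswith(("E", "V")):
        return EXCLUDED
    root = int(c[:3])
    for (lo, hi), label in CATEGORY_LABELS.items():
        if lo <= root <= hi:
            return label
    return EXCLUDED


@dataclass
class CategoryProfile:
    """Node counts of a PDN over the 13 retained disease categories."""

    counts: dict[str, int]
    total: int

    def proportion(self, label: str) -> float:
        return self.counts.get(label, 0) / self.total if self.total else 0.0


def category_profile(pdn: PDN) -> CategoryProfile:
    """Count a PDN's non-excluded nodes per disease category."""
    counts = {label: 0 for label in CATEGORY_LABELS.values()}
    total = 0
    for code, cat in pdn.nodes.items():
        if cat == EXCLUDED:
            continue
        counts[cat] += 1
        total += 1
    return CategoryProfile(counts=counts, total=total)


def compare_profiles(
    a: CategoryProfile,
    b: CategoryProfile,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Pooled two-sample proportion z-test per disease category.

    For each category with counts ``x_a`` of ``n_a`` versus ``x_b`` of
    ``n_b``, the pooled estimate ``p = (x_a+x_b)/(n_a+n_b)`` gives

        z = (x_a/n_a - x_b/n_b) / sqrt(p*(1-p)*(1/n_a + 1/n_b))

    with a two-sided p-value.  Categories where the pooled proportion
    is 0 or 1 have an undefined z and are flagged non-significant.
    ``direction`` is "a>b", "a<b" or "equal".  With ``bonferroni`` the
    significance level is divided by the number of categories.
    """
    if a.total <= 0 or b.total <= 0:
        raise ValueError("both profiles must have a positive total")
    level = alpha / len(CATEGORY_LABELS) if bonferroni else alpha
    rows = []
    for label in CATEGORY_LABELS.values():
        xa, xb = a.counts.get(label, 0), b.counts.get(label, 0)
        pa, pb = xa / a.total, xb / b.total
        pooled = (xa + xb) / (a.total + b.total)
        se2 = pooled * (1 - pooled) * (1 / a.total + 1 / b.total)
        if se2 == 0:
            z, p, undefined = np.nan, np.nan, True
        else:
            z = (pa - pb) / math.sqrt(se2)
            p = 2 * stats.norm.sf(abs(z))
            undefined = False
        rows.append(
            {
                "category": label,
                "x_a": xa,
                "n_a": a.total,
                "x_b": xb,
                "n_b": b.total,
                "z": z,
                "p": p,
                "significant": (not undefined) and p < level,
                "direction": "a>b" if pa > pb else ("a<b" if pa < pb else "equal"),
                "undefined": undefined,
            }
        )
    return pd.DataFrame(rows)
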