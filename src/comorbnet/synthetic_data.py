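"""Synthetic claims, modular graphs and bipartite networks with ground truth.

The national inpatient-claims databases that comorbidity studies draw
on are access-restricted, and curated interaction databases change
between releases.  This module generates stand-ins with *known* ground
truth so every downstream stage (phi-correlation disease networks,
betweenness backbones, bipartite hub calls) can be tested end to end:

* ``generate_claims`` — a hospitalization-claims table (one main plus
  up to four side ICD-9-CM diagnoses per record) for a cohort with
  prescribed per-disease prevalences, prescribed pairwise
  phi-correlations for selected "planted" disease pairs, and a
  diabetes-type mix planted through the 5th digit of a 250.xx code.
* ``generate_planted_graph`` — a modular graph in which designated
  connector nodes carry all inter-module traffic, i.e. the
  ground-truth high-betweenness backbone is known by construction.
* ``generate_bipartite`` — an Erdős–Rényi bipartite protein-miRNA
  network for degree/hub logic.

Planted pairs are sampled jointly from the 2x2 contingency table
implied by (p_i, p_j, phi); all other diseases are independent
Bernoulli draws.  A single integer seed drives one named random
stream, so equal seeds give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from comorbnet.claims_pdn import canonical_code

__all__ = [
    "InfeasiblePairError",
    "DiseaseSpec",
    "PlantedPair",
    "SyntheticCohortSpec",
    "PlantedGraphSpec",
    "CohortTruth",
    "generate_claims",
    "generate_cohort",
    "generate_planted_graph",
    "generate_bipartite",
]


class InfeasiblePairError(ValueError):
    """A planted pair's target phi is outside the Fréchet-feasible range."""


@dataclass(frozen=True)
class DiseaseSpec:
    """One disease to simulate: its code and population prevalence."""

    code: str
    prevalence: float
    category_hint: str | None = None

    def __post_init__(self) -> None:
        canonical_code(self.code)  # raises CodeError if malformed
        if not 0 < self.prevalence < 1:
            raise ValueError(
                f"prevalence must be in (0, 1), got {self.prevalence} for {self.code}"
            )


def joint_probability(p_i: float, p_j: float, phi: float) -> float:
    """P(both diseases) implied by marginals and a target phi."""
    return p_i * p_j + phi * math.sqrt(p_i * (1 - p_i) * p_j * (1 - p_j))


@dataclass(frozen=True)
class PlantedPair:
    """A disease pair whose sample phi-correlation is controlled."""

    code_i: str
    code_j: str
    target_phi: float

    def __post_init__(self) -> None:
        if self.code_i == self.code_j:
            raise ValueError("planted pair needs two distinct diseases")
        if not -1 <= self.target_phi <= 1:
            raise ValueError(f"target_phi out of [-1, 1]: {self.target_phi}")

    def cell_probabilities(self, p_i: float, p_j: float) -> np.ndarray:
        """2x2 cell probabilities [p11, p10, p01, p00].

        Raises :class:`InfeasiblePairError` when the implied joint
        probability violates the Fréchet bounds
        max(0, p_i + p_j - 1) <= p11 <= min(p_i, p_j).
        """
        p11 = joint_probability(p_i, p_j, self.target_phi)
        lo, hi = max(0.0, p_i + p_j - 1.0), min(p_i, p_j)
        if not lo - 1e-12 <= p11 <= hi + 1e-12:
            raise InfeasiblePairError(
                f"pair ({self.code_i}, {self.code_j}): target phi "
                f"{self.target_phi} implies joint probability {p11:.4g} "
                f"outside the feasible range [{lo:.4g}, {hi:.4g}]"
            )
        p11 = min(max(p11, lo), hi)
        return np.array([p11, p_i - p11, p_j - p11, 1 - p_i - p_j + p11])


_DM_TYPES = ("T1D", "T2D", "other", "none")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Full recipe for a synthetic inpatient cohort.

    ``sex_ratio`` is the fraction of male patients; ``age_distribution``
    lists (age-band, weight) entries whose weights sum to 1;
    ``dm_type_mix`` gives the diabetes-type fractions (keys from
    {"T1D", "T2D", "other", "none"}; "none" patients get no 250 code).
    """

    n_patients: int
    diseases: Sequence[DiseaseSpec]
    planted_pairs: Sequence[PlantedPair] = ()
    sex_ratio: float = 0.5
    age_distribution: Sequence[tuple[tuple[int, int], float]] = (
        ((1, 19), 0.3),
        ((20, 39), 0.2),
        ((40, 59), 0.3),
        ((60, 89), 0.2),
    )
    dm_type_mix: dict[str, float] = field(
        default_factory=lambda: {"T1D": 1.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError("sex_ratio must be in [0, 1]")
        weights = [w for _, w in self.age_distribution]
        if abs(sum(weights) - 1) > 1e-9 or any(w < 0 for w in weights):
            raise ValueError("age_distribution weights must be >= 0 and sum to 1")
        if abs(sum(self.dm_type_mix.values()) - 1) > 1e-9:
            raise ValueError("dm_type_mix fractions must sum to 1")
        unknown = set(self.dm_type_mix) - set(_DM_TYPES)
        if unknown:
            raise ValueError(f"unknown dm types: {sorted(unknown)}")
        prev = self.prevalence_map()
        seen: set[str] = set()
        for pair in self.planted_pairs:
            for c in (pair.code_i, pair.code_j):
                if c not in prev:
                    raise ValueError(f"planted pair references undeclared disease {c}")
                if c in seen:
                    raise ValueError(
                        f"disease {c} appears in more than one planted pair"
                    )
                seen.add(c)
            # raises InfeasiblePairError if the target phi is unreachable
            pair.cell_probabilities(prev[pair.code_i], prev[pair.code_j])

    def prevalence_map(self) -> dict[str, float]:
        codes = [d.code for d in self.diseases]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate disease codes in spec")
        return {d.code: d.prevalence for d in self.diseases}


@dataclass
class CohortTruth:
    """Generator-side tallies for checking downstream counting code."""

    N: int
    N_i: dict[str, int]
    N_ij: dict[tuple[str, str], int]  # planted pairs only
    dm_counts: dict[str, int]

    def sample_phi(self, code_i: str, code_j: str) -> float:
        from comorbnet.claims_pdn import phi_correlation

        pair = tuple(sorted((code_i, code_j)))
        return phi_correlation(
            self.N, self.N_i[code_i], self.N_i[code_j], self.N_ij[pair]
        )


def _sample_disease_matrix(
    spec: SyntheticCohortSpec, rng: np.random.Generator
) -> tuple[list[str], np.ndarray]:
    """Patient x disease boolean matrix honouring prevalences and phi."""
    prev = spec.prevalence_map()
    codes = [d.code for d in spec.diseases]
    col = {c: k for k, c in enumerate(codes)}
    n = spec.n_patients
    have = np.zeros((n, len(codes)), dtype=bool)

    planted = set()
    for pair in spec.planted_pairs:
        cells = pair.cell_probabilities(prev[pair.code_i], prev[pair.code_j])
        draw = rng.choice(4, size=n, p=cells / cells.sum())
        have[:, col[pair.code_i]] = (draw == 0) | (draw == 1)
        have[:, col[pair.code_j]] = (draw == 0) | (draw == 2)
        planted.update((pair.code_i, pair.code_j))
    for c in codes:
        if c not in planted:
            have[:, col[c]] = rng.random(n) < prev[c]
    return codes, have


def _dm_code(dm_type: str, rng: np.random.Generator) -> str | None:
    """A 250.xx code whose 5th digit encodes the requested type."""
    fourth = rng.integers(0, 10)
    if dm_type == "T1D":
        return f"250{fourth}{rng.choice([1, 3])}"
    if dm_type == "T2D":
        return f"250{fourth}{rng.choice([0, 2])}"
    if dm_type == "other":
        return f"250{fourth}"
    return None


def generate_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[pd.DataFrame, CohortTruth]:
    """Generate a claims table plus the generator's own tallies.

    Diseases are assigned once per patient, then split across 1-3
    hospitalization records of at most 5 diagnosis codes each; the
    split is cosmetic, downstream counting deduplicates per patient.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    codes, have = _sample_disease_matrix(spec, rng)

    sexes = np.where(rng.random(n) < spec.sex_ratio, "M", "F")
    bands = [b for b, _ in spec.age_distribution]
    band_idx = rng.choice(
        len(bands), size=n, p=[w for _, w in spec.age_distribution]
    )
    ages = np.array(
        [rng.integers(bands[i][0], bands[i][1] + 1) for i in band_idx]
    )
    dm_types = list(spec.dm_type_mix)
    dm_assign = rng.choice(
        len(dm_types), size=n, p=list(spec.dm_type_mix.values())
    )

    epoch = np.datetime64("2002-01-01")
    n_days = int(
        (np.datetime64("2009-01-01") - epoch) / np.timedelta64(1, "D")
    )

    dm_counts = {t: 0 for t in dm_types}
    n_i = {c: 0 for c in codes}
    n_ij = {
        tuple(sorted((p.code_i, p.code_j))): 0 for p in spec.planted_pairs
    }
    rows = []
    for idx in range(n):
        pid = f"P{idx:07d}"
        patient_codes = [codes[k] for k in np.flatnonzero(have[idx])]
        for c in patient_codes:
            n_i[c] += 1
        for pair in n_ij:
            if have[idx, codes.index(pair[0])] and have[idx, codes.index(pair[1])]:
                n_ij[pair] += 1
        dm_type = dm_types[dm_assign[idx]]
        dm_counts[dm_type] += 1
        dm = _dm_code(dm_type, rng)
        if dm is not None:
            patient_codes.append(dm)
        if not patient_codes:
            continue  # a "none" patient with no sampled disease has no claim
        rng.shuffle(patient_codes)

        n_claims = int(rng.integers(1, 4))
        n_claims = max(min(n_claims, len(patient_codes)), -(-len(patient_codes) // 5))
        dates = sorted(
            str(epoch + rng.integers(0, n_days)) for _ in range(n_claims)
        )
        for j in range(n_claims):
            chunk = patient_codes[j::n_claims][:5]
            rows.append(
                {
                    "patient_id": pid,
                    "sex": sexes[idx],
                    "age": int(ages[idx]),
                    "admission_date": dates[j],
                    **{
                        f"dx{i + 1}": (chunk[i] if i < len(chunk) else "")
                        for i in range(5)
                    },
                }
            )
    claims = pd.DataFrame(rows)
    truth = CohortTruth(N=n, N_i=n_i, N_ij=n_ij, dm_counts=dm_counts)
    return claims, truth


def generate_claims(spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Generate the claims table only (see :func:`generate_cohort`)."""
    return generate_cohort(spec)[0]


# --------------------------------------------------------------------------
# planted-connector graphs


@dataclass(frozen=True)
class PlantedGraphSpec:
    """Recipe for a modular graph with known high-betweenness connectors.

    ``n_modules`` dense modules of ``module_size`` nodes each are built
    as a random spanning tree plus Erdős–Rényi edges at
    ``intra_module_edge_prob``; each of the ``n_connectors`` connector
    nodes is linked to one uniformly chosen node in *every* module, so
    all inter-module shortest paths run through connectors.
    """

    n_modules: int
    module_size: int
    n_connectors: int = 1
    intra_module_edge_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules < 2:
            raise ValueError("need at least 2 modules")
        if self.module_size < 3:
            raise ValueError("module_size must be >= 3")
        if self.n_connectors < 1:
            raise ValueError("need at least 1 connector")
        if not 0 < self.intra_module_edge_prob <= 1:
            raise ValueError("intra_module_edge_prob must be in (0, 1]")


def generate_planted_graph(
    spec: PlantedGraphSpec,
) -> tuple[nx.Graph, list[str]]:
    """Build the modular graph; returns (graph, planted connector ids).

    The graph is connected by construction and each connector bridges
    every module.
    """
    rng = np.random.default_rng(spec.seed)
    g = nx.Graph()
    modules: list[list[str]] = []
    for m in range(spec.n_modules):
        nodes = [f"m{m}n{j}" for j in range(spec.module_size)]
        g.add_nodes_from(nodes)
        # random recursive tree guarantees intra-module connectivity
        for j in range(1, len(nodes)):
            g.add_edge(nodes[j], nodes[int(rng.integers(0, j))])
        for a in range(len(nodes)):
            for b in range(a + 1, len(nodes)):
                if not g.has_edge(nodes[a], nodes[b]) and (
                    rng.random() < spec.intra_module_edge_prob
                ):
                    g.add_edge(nodes[a], nodes[b])
        modules.append(nodes)

    connectors = [f"c{k}" for k in range(spec.n_connectors)]
    for c in connectors:
        g.add_node(c)
        for nodes in modules:
            g.add_edge(c, nodes[int(rng.integers(0, len(nodes)))])
    return g, connectors


# --------------------------------------------------------------------------
# random bipartite networks


def generate_bipartite(
    n_proteins: int, n_mirnas: int, edge_prob: float, seed: int = 0
):
    """Erdős–Rényi bipartite protein-miRNA network, deterministic per seed."""
    from comorbnet.mirna_bipartite import BipartiteNetwork

    if n_proteins <= 0 or n_mirnas <= 0:
        raise ValueError("node counts must be positive")
    if not 0 <= edge_prob <= 1:
        raise ValueError("edge_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    proteins = [f"P{i:03d}" for i in range(n_proteins)]
    mirnas = [f"mir-sim-{j}" for j in range(n_mirnas)]
    mask = rng.random((n_proteins, n_mirnas)) < edge_prob
    edges = {
        (proteins[i], mirnas[j])
        for i, j in zip(*np.nonzero(mask), strict=True)
    }
    return BipartiteNetwork(
        proteins=set(proteins), mirnas=set(mirnas), edges=edges
    )
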