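# comorbnet

Tools for building disease-comorbidity networks from hospital claims data and
for characterising the topology of the disease-associated molecular networks
that sit beneath them. The package covers the full chain used in comorbidity
case studies of type 1 diabetes: typing diabetic inpatients from ICD-9-CM
codes, measuring pairwise disease associations, extracting a high-betweenness
network backbone, classifying hub/bottleneck roles, mapping gene–microRNA
regulation, and annotating results with pathway gene sets. Synthetic-data
generators with planted ground truth make every step testable end to end.

## Scientific background

**Comorbidity strength.** For diseases *i* and *j* observed in a population of
*N* patients, with *N<sub>i</sub>*, *N<sub>j</sub>* patients carrying each
disease and *N<sub>ij</sub>* carrying both, the φ-correlation is

```
φ_ij = (N·N_ij − N_i·N_j) / sqrt(N_i·N_j·(N − N_i)·(N − N_j))
```

which is exactly the Pearson correlation of the two binary disease-indicator
vectors. A phenotypic disease network (PDN) keeps the strongest fraction of
candidate pairs (default: the top 0.6%, extended through ties) as links.
Patients are deduplicated across admissions before counting, and diabetes
mellitus inpatients are typed from the fifth digit of their 250.xx codes
(1 or 3 → type 1; 0 or 2 → type 2), with type 1 taking precedence.

**Network topology.** On a molecular interaction network the package computes
degree, betweenness and closeness centralities, extracts the *backbone* — the
induced subgraph on the top 20% of nodes by betweenness (tie-extended) — and
assigns each node a role: **date-hub** (hub and bottleneck), **party-hub**
(hub only), **nonhub-bottleneck**, or **other**. Hubs and bottlenecks are
defined either by top-fraction cutoffs or by explicit degree/betweenness
values.

**Regulation and pathways.** A bipartite gene–microRNA network yields per-side
degrees and hubs (protein hubs interact with more than 10 miRNAs, miRNA hubs
with more than 12 proteins, by default); miRNA names are canonicalised
(case-folding, `hsa-` prefix removal, alias table). Node sets are annotated
against GMT pathway gene sets by overlap.

## Running the tests

```bash
python -m pytest -q tests/
```

The suite cross-checks the library against independent oracles (brute-force
path enumeration for centralities, Pearson correlation for φ, an external
implementation of the two-proportion z-test) and against the bundled
reference tables.

## Worked example

Simulate a cohort with a planted comorbidity and recover it:

```python
from comorbnet.synthetic_data import (
    SyntheticCohortSpec, DiseaseSpec, PlantedPair, generate_claims,
)
from comorbnet.claims_pdn import count_prevalences

spec = SyntheticCohortSpec(
    n_patients=20000,
    diseases=[DiseaseSpec("401", 0.12), DiseaseSpec("585", 0.06)],
    planted_pairs=[PlantedPair("401", "585", 0.25)],
    seed=42,
)
claims = generate_claims(spec)
counts = count_prevalences(claims)
print("N =", counts.N, " N_401 =", counts.N_i["401"], " N_585 =", counts.N_i["585"])
print("phi =", round(counts.phi("401", "585"), 4))
```

Output:

```
N = 20000  N_401 = 2381  N_585 = 1200
phi = 0.253
```

The planted φ of 0.25 is recovered to within sampling error.

Run the whole pipeline (simulated claims → stratified PDNs → profile
comparison, plus the bundled molecular-network analyses) from the CLI:

```bash
comorbnet demo --seed 1 --outdir demo_out
```

Output:

```
completed stages: simulate, pdn_a, pdn_b, compare_profiles, load_fixture_centralities, classify_roles, mirna_fixture, find_hubs, annotate_pathways
manifest: demo_out/manifest.json
```

`demo_out/hubs.json` then contains the hub sets recomputed from the bundled
gene–miRNA edge list:

```json
{
  "hub_proteins": ["APP", "CTNNB1", "EGFR", "IGF1R", "STAT3", "TGFBR2"],
  "hub_mirnas": ["mir-103a-3p", "mir-155-5p", "mir-181a-5p", "mir-20a-5p",
                 "mir-23b-3p", "mir-24-3p", "mir-34a-5p"]
}
```

Other subcommands (`simulate`, `pdn`, `topology`, `backbone`, `mirna`,
`annotate`) expose the individual stages; see `comorbnet --help`.

## Package layout

| Module | Contents |
| --- | --- |
| `comorbnet.claims_pdn` | claims → patients, φ-correlation, PDN construction, ICD-9 category profiles, two-proportion comparison |
| `comorbnet.graph_metrics` | giant component, centralities, global network metrics |
| `comorbnet.backbone_analysis` | backbone extraction, hub/bottleneck role taxonomy |
| `comorbnet.mirna_bipartite` | miRNA name canonicalisation, bipartite network, hub detection |
| `comorbnet.pathway_overlap` | GMT I/O, overlap annotation |
| `comorbnet.synthetic_data` | cohort, planted-graph and bipartite generators with ground truth |
| `comorbnet.cli_io` / `comorbnet.cli` | fixtures with checksums, file I/O, pipeline runner, CLI |

Methodological details and limitations are documented in
[docs/methods.md](docs/methods.md).
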