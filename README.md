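# msapop

Population (epi)genetics of dominant AFLP and methylation-sensitive AFLP
(MSAP) markers.

## The problem

Anonymous dominant markers remain the workhorse for population-level
surveys of non-model plants: AFLP bands score genetic variation, and
MSAP — the same assay run with the methylation-sensitive isoschizomers
*Hpa*II and *Msp*I — scores cytosine-methylation variation at CCGG sites
in the same individuals. A typical habitat study asks, for tens of
individuals sampled from sites nested in habitats:

* How much genetic and epigenetic diversity is there, and how is it
  structured across habitats and sites?
* Are some loci under selection (Fst outliers), or associated with
  measured soil variables?
* Does epigenetic differentiation track habitat *beyond* what genetic
  structure explains?

`msapop` implements that entire analysis as a tested Python library with
a thin CLI: methylation-state scoring and MSL/NML classification,
POPGENE-style diversity and Nei distances, one- and two-level AMOVA with
Phi statistics and permutation tests, Mantel and partial Mantel tests,
an FDIST-style outlier scan against a Balding–Nichols neutral envelope,
Samβada-style logistic environmental association, PCoA / DistLM / dbRDA /
RDA ordination with Storey q-values, UPGMA with locus bootstrap, and a
synthetic-data generator with known ground truth so every stage is
testable without any data download.

## Core statistics

For an individuals × loci 0/1 band matrix, squared Euclidean distances
d²(i,j) (rescaled for missing scores) feed a hierarchical AMOVA whose
variance components σ²ₐ (among habitats), σ²_b (among sites within
habitats) and σ²_c (within sites) define

    ΦCT = σ²ₐ / σ²ₜ    ΦSC = σ²_b / (σ²_b + σ²_c)    ΦST = (σ²ₐ + σ²_b) / σ²ₜ

with permutation p-values using the add-one rule. For MSAP, each
(HpaII, MspI) score pair maps to a methylation state — (1,1) unmethylated,
(1,0) hemimethylated, (0,1) internal-C methylated, (0,0) uninformative —
and a locus is methylation-susceptible (MSL) when its observed
discordance rate exceeds the duplicate-based error threshold ε. The
partial Mantel test correlates two distance matrices' off-diagonals after
residualizing both on a control matrix, permuting the residualized
matrix.

## Worked example

```python
from msapop.synthetic_data import SimParams, simulate_dataset
from msapop import amova, msap_scoring, matrix_tests

aflp, msap, soil, truth = simulate_dataset(SimParams(seed=1, n_aflp=600, n_msap=600))

m = msap_scoring.score_methylation_states(msap)
classes = msap_scoring.classify_loci(m, epsilon=0.04)
msl, nml = msap_scoring.split_msl_nml(m, classes, msap)
print(f"MSL: {msl.n_loci} of {len(classes)} loci")

d_gen = amova.squared_distance_matrix(aflp)
res = amova.amova(d_gen, aflp.habitat, aflp.site, n_perm=999, seed=1)
print({k: round(float(v), 4) for k, v in res.phi.items()}, res.p_values)

d_epi = amova.squared_distance_matrix(msl)
r = matrix_tests.mantel(d_gen, d_epi, n_perm=9999, seed=1, exact=False)
print(f"Mantel r = {r.r:.3f}, p = {r.p:.4f}")
```

prints

```
MSL: 479 of 600 loci
{'PhiCT': 0.1221, 'PhiSC': 0.0537, 'PhiST': 0.1692} {'PhiCT': 0.001, 'PhiSC': 0.001, 'PhiST': 0.001}
Mantel r = 0.380, p = 0.0001
```

The generator planted habitat-level differentiation θ = 0.10 and
site-level θ = 0.05; the recovered ΦCT = 0.122 and ΦSC = 0.054 estimate
exactly those quantities (all three Phi statistics significant at the
smallest attainable permutation p). About two-thirds of MSAP loci were
planted as methylation-susceptible; 479/600 are recovered at ε = 0.04.
The Mantel r shows the genetic–epigenetic correlation induced by the
obligate and facilitated epiloci.

The same pipeline runs from a YAML config:

```bash
msapop simulate --seed 42 --out demo/
msapop run --config demo/config.yaml
```

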