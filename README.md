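# rhizotrace

Analysis pipeline for rhizosphere cadmium mobility and the microbiome
reassembly that accompanies it — the computational chain behind root-box
studies in which arbuscular mycorrhizal (AM) symbiosis is tested for its
ability to immobilize Cd in the rhizosphere.

It is aimed at microbial ecologists and environmental scientists who have:

* membrane fluorescence **imprints** of Cd²⁺ around roots (plus calibration
  films and a root mask),
* a 16S-style **community table** with a phylogeny,
* a **metabolite** peak-area matrix,
* **soil property** tables,

and want to connect them: how mobile is Cd (hotspot percentage), is the
community assembled by selection or drift (βNTI/RC<sub>bray</sub>), which
taxa are network keystones, which metabolite modules track microbial or
chemical traits, and how much of the Cd-mobility response each data layer
explains (path model + variance partitioning).

## What it computes

* **imprint** — gray→concentration calibration (linear or isotonic),
  per-pixel inversion, the hotspot statistic (pixels > (1 + f)·mean, f =
  0.25 by default), and root–Cd colocalization as a Spearman Mantel test
  over image tiles.
* **commstats** — Shannon/Simpson/Chao1/observed, rarefaction,
  Bray–Curtis, NMDS (Kruskal stress-1 by iterative majorization), ANOSIM,
  SIMPER, Welch-t tables and a simplified LDA-effect-size biomarker scan.
* **assembly** — βMNTD, βNTI against a tip-shuffle null, Raup–Crick on
  Bray–Curtis, and the standard process partition: |βNTI| > 2 ⇒ selection
  (sign separates variable from homogeneous selection), otherwise
  RC<sub>bray</sub> beyond ±0.95 ⇒ dispersal, else drift.
* **netkey** — Spearman co-occurrence networks (|r| > 0.6, p < 0.05 by
  default), topology statistics, and keystone ranking by PageRank and
  eigenvector centrality (both by power iteration).
* **metmod** — weighted metabolite coexpression: ≥5 peak-area filter,
  log₂(x+1), soft-threshold power, adjacency → topological overlap matrix
  (TOM), average-linkage clustering of 1−TOM with minimum module size 28,
  eigenmetabolites with 0.8 merge, Bonferroni module–trait correlation,
  and hub metabolites by kME.
* **integrate** — Spearman screens (r > 0.6 at p < 0.05 or 0.01), Mantel
  tests, Boruta-style all-relevant feature confirmation against ShadowMax,
  a piecewise path model (one standardized regression per endogenous DAG
  node), and variance partitioning by inclusion–exclusion over subset
  fits.
* **synthio** — generators for every input with planted ground truth
  (root imprint geometry, Yule tree + Brownian habitat optima, latent
  metabolite modules, a linear DAG for the integrated block), so each
  stage is testable against what was planted.

## Worked example

```python
from rhizotrace import assembly, imprint, synthio

cfg = synthio.SimulationConfig(seed=1, n_taxa=150, n_groups=2,
                               n_samples_per_group=4,
                               filtering_strength=20.0)

# Cd imprint: hotspot statistic and root colocalization
sim = synthio.simulate_imprint(cfg)
hs = imprint.detect_hotspots(sim.gray)
r, p = imprint.colocalization(sim.root_mask, sim.gray, seed=1)
print(f"hotspot {hs.hotspot_percent:.1f}%  Mantel r={r:.2f} p={p:.3f}")

# community assembly under planted environmental filtering
com = synthio.simulate_community(cfg, regime="filtered")
z = assembly.beta_nti(com.table, com.tree, n_null=99, seed=1)
rc = assembly.raup_crick_bray(com.table, n_null=99, seed=1)
print(assembly.classify_processes(z, rc).process_fractions)
```

prints

```
hotspot 24.3%  Mantel r=0.68 p=0.001
process
heterogeneous-selection    0.607143
homogeneous-selection      0.000000
dispersal-limitation       0.000000
homogenizing-dispersal     0.392857
drift                      0.000000
Name: proportion, dtype: float64
```

i.e. about a quarter of the membrane reads as a Cd accumulation hotspot,
the Cd field is strongly colocalized with the root (Mantel r = 0.68, the
smallest achievable permutation p), and with strong planted filtering
most pairs are classified as deterministic (variable selection), exactly
what |βNTI| > 2 is supposed to detect.

The same chain is available from a shell:

```bash
rhizotrace run --seed 1 --out demo_run     # full demo pipeline + manifest
rhizotrace imprint --image gray.tiff --mask root.png \
    --calibration films.tsv --out out/
```

## Layout

```
src/rhizotrace/   synthio, imprint, commstats, assembly, netkey,
                  metmod, integrate, io, pipeline, cli
tests/            unit + property tests and test_acceptance.py
docs/methods.md   models, assumptions, defaults, limitations
```
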