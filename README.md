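# topodrug

Topological-index driven evaluation and ranking of drug candidates,
demonstrated end to end on ten anti-arrhythmia drugs (metoprolol,
atenolol, bisoprolol, propranolol, sotalol, amiodarone, carvedilol,
flecainide, propafenone, timolol).

A drug molecule is reduced to its hydrogen-suppressed skeleton: a simple
connected graph G = (V, E) of heavy atoms.  For a vertex v, d_v is its
degree and S_v = Σ_{u~v} d_u its neighbor-degree sum.  Classing the edges
by the sorted pair of endpoint values gives the edge partition m_kl, and
with it the generating (NM-)polynomial

    NM(G; s, t) = Σ_{k≤l} m_kl s^k t^l

from which six indices follow, either by operator calculus on the
polynomial or as direct sums over edge classes:

    M1  = Σ (d_u + d_v)          M2  = Σ d_u d_v            (degrees)
    NM1 = Σ (S_u + S_v)          NM2 = Σ S_u S_v            (neighbor sums)
    NH  = Σ 2/(S_u + S_v)        NSS = Σ √(S_u S_v/(S_u+S_v))

The package then

1. fits quadratic QSPR models `P = A + B·TI + C·TI²` of seven
   physicochemical properties (density, boiling point, flash point, BCF,
   KOC, polarizability, molar volume) on each index, with R, R², adjusted
   R², F on (2, n−3) df, its p-value, and RMSE = √(SSE/n);
2. derives entropy-based criterion weights from the vector-normalized
   index decision matrix, `E_j = −(1/ln m) Σ_i n_ij ln n_ij`,
   `w_j ∝ |1 − E_j|`;
3. ranks the drugs with TOPSIS (relative closeness to the ideal point in
   the weighted normalized criterion space) and SAW (weighted sum of
   max-normalized scores).

It is intended for cheminformatics practitioners who want a tested,
reproducible reference implementation of this descriptor/QSPR/MCDM
pipeline, including the published tables it reproduces and the documented
places where those tables are internally inconsistent (see
`docs/methods.md`).

## Worked example

```python
>>> from topodrug import reference, compute_indices
>>> g = reference.drug_graphs()["metoprolol"]
>>> iv = compute_indices(g)
>>> (iv.M1, iv.M2, iv.NM1, iv.NM2, round(iv.NSS, 2), round(iv.NH, 2))
(84.0, 89.0, 178.0, 427.0, 28.77, 4.24)
```

The numbered scripts under `analysis/` run the three stages and narrate
what they find:

```sh
$ python analysis/01_compute_indices.py     # indices of all ten drugs
$ python analysis/02_fit_qspr.py            # 42 quadratic fits + correlations
$ python analysis/03_rank_drugs.py          # entropy weights, TOPSIS, SAW
```

Stage 3 prints (abridged):

```
Entropy weights:
  M1   0.170372
  M2   0.166171
  NM1  0.164530
  NM2  0.155294
  NSS  0.168411
  NH   0.175222

TOPSIS ranking (relative closeness):
             closeness  rank
amiodarone    0.987797     1
carvedilol    0.957530     2
flecainide    0.662413     3
...
atenolol      0.012892    10

Top candidate under both methods: amiodarone
```

Amiodarone attains (or nearly attains) the columnwise ideal in every
criterion, so its closeness approaches 1 and it ranks first under both
methods; atenolol, smallest in every index, ranks last.  The same run
writes every intermediate table (normalized matrix, weighted matrix,
ideals, separations, SAW tables) under `results/mcdm/`.

The command-line interface exposes the same stages:
`topodrug indices`, `topodrug qspr`, `topodrug weights`, `topodrug rank`,
`topodrug generate` (seeded synthetic inputs) and `topodrug reproduce`.

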