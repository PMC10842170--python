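# cofirepy

Analysis toolkit for population coding in hippocampal CA1 ensemble
recordings.  The scientific question it addresses: when an animal moves
between two environments, is the change in neural activity best described as
*remapping* — each cell's place fields rearranging under environmental
control — or as *reregistration* — an internally organized structure of
cell-pair cofiring that is preserved across environments and merely anchored
("registered") differently to each one, chiefly by a minority subpopulation
of anti-cofiring cells?

The package provides, for deconvolved calcium-imaging rasters (cells x
10-Hz frames) with trajectories and soma coordinates:

* **Place tuning** — occupancy-normalized rate maps (~2.5-cm bins),
  linearized 12-degree angular maps, spatial coherence and information
  content `sum_x p(x) (r_x/R) log2(r_x/R)`, circular-shift shuffle
  significance (z > 1.96, both metrics required), and place-map similarity
  with Fisher's z.
* **Coactivity** — cell-pair Kendall tau-b matrices on 1-s bins with the
  standard exclusions (somata < 30 um, cells active in < 2% of bins);
  population coordination (PCo: the Pearson correlation between two
  recordings' tau vectors); position-tuning-independent (PTI) rates;
  network consistency `sum_ij tau_ij r_i(t) r_j(t)` with a pair-identity
  shuffle normalization; anti-cofiring power (fraction of a cell's pairs
  with tau <= -0.05); correlation participation; and the correlation-vs-
  soma-distance profile with its power-law exponent.
* **Decoding** — linear-SVM environment decoding from 1-s activity vectors
  or 60-s windowed PTI coactivity (100 stratified 2/3-1/3 splits, signed
  weights averaged), cross-day transfer, weight-ranked subset decoding
  (the top-quintile "environment-discriminating subset"), property
  enrichment ratios, and pairwise-bin location decoding from activity or
  0/1/2 coincidence codes.
* **Manifold geometry** — PCA/IsoMap embeddings of Gaussian-filtered 1-s
  vectors (5 neighbors, geodesic distances, residual-variance explained
  variance), environment discrimination ratio, Vietoris-Rips Betti
  barcodes, participation ratio `(tr C)^2 / tr(C^2)`, centroid-distance
  skewness and KL divergence under cell removal, 3-D alpha-shape overlap
  between environments, windowed total-least-squares planar fits with
  localness/smoothness dynamics, and the two-sample Kuiper test on planar
  angles.
* **A synthetic ensemble generator** — multi-day, two-environment
  recordings with multimodal place tuning, an internally organized
  assembly/anti-cofiring latent structure in `remap` or `reregister` mode,
  overdispersion, and cross-day cell dropout; ground truth is retained for
  parameter-recovery tests.
* **An STDP ring-network model** — 1000 position-tuned inputs driving a
  recurrent 500 E / 50 I integrate-and-fire network with pair-based STDP on
  the E->E, E->I and I->E pathways, single-track spatial-similarity
  metrics, plasticity knockouts, and the two-track remapping experiment.

See `docs/methods.md` for the models, parameter choices and limitations.

## Worked example

```python
import numpy as np
from cofirepy import synthetic as syn, coactivity as co, decoding as dec, manifold as man

truth = syn.make_ground_truth(n_cells=150, mode="reregister", seed=42)
recs = syn.generate_ensemble_pair(truth, syn.Protocol(days=(1,)), seed=43)

mats = [co.kendall_matrix(co.bin_to_1s(r.raster), coords=r.soma_um) for r in recs]
pco_same = (co.population_coordination(mats[0], mats[2])
            + co.population_coordination(mats[1], mats[3])) / 2
pco_diff = np.mean([co.population_coordination(mats[a], mats[b])
                    for a, b in [(0, 1), (0, 3), (2, 1), (2, 3)]])

binned = [co.bin_to_1s(r.raster).data for r in recs]
X = np.concatenate(binned, axis=1).T
y = np.array([r.environment == "square" for r in recs for _ in range(300)], int)
fs = dec.FeatureSet(X=X, y=y, feature_ids=np.arange(truth.n_cells))
res = dec.train_environment_decoder(fs, reps=100, seed=0)
top = dec.environment_discriminating_subset(res, fraction=0.2)
ratio = dec.proportion_ratio(top, np.arange(truth.n_cells), truth.anti_cell)

emb = man.embed(X, method="isomap", dims=2)
pieces = np.split(emb.points, np.cumsum([b.shape[1] for b in binned])[:-1])
dr = man.discrimination_ratio(pieces, [r.environment for r in recs])
```

Output for this seed:

```
PCo same environment:      0.464
PCo different environment: 0.195
environment decoding accuracy: 0.930
anti-cofiring enrichment in top quintile: 2.10
IsoMap discrimination ratio: 0.251
```

Read: the cofiring structure repeats between visits to the same environment
about 2.4x more strongly than between different environments, yet remains
positively correlated across environments (the preserved backbone); the
current environment is identified from single 1-s activity vectors in 93%
of test bins, and the cells carrying the largest decoder weights are 2.1x
enriched in the planted anti-cofiring subpopulation; in a 2-D IsoMap
embedding the two environments' average projections are well separated
(ratio 0.25; 1 would mean indistinguishable).

A command-line interface mirrors the main stages, e.g.

```sh
cofirepy simulate ensemble --mode reregister --days 2 --seed 1 --out ens.h5
cofirepy analyze decode ens.h5 --reps 100
cofirepy stdp single-track --laps 100 --seeds 10
```

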