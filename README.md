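# healthnet

Analysis of coordinated health development in urban agglomerations —
composite city health indices, an improved inter-city gravity model, and
correlation-network classification of regional collaboration structures,
with a built-in synthetic study-area generator and a cross-validation
harness.

## Who this is for

Researchers in regional health policy and spatial epidemiology who want
to quantify how health development co-evolves across the cities of an
agglomeration (e.g. Beijing–Tianjin–Hebei, the Yangtze or Pearl River
Deltas, Chengdu–Chongqing): which cities act as hubs, how policy waves
and shocks propagate, and whether a region is unipolar, polycentric,
core–periphery, or segmented around two weakly coupled cores.

## The model

1. **Urban Health Index.** City-year indicators (hospitals, physicians,
   beds, per-capita health expenditure, GDP) are min-max standardized
   with declared directions and combined with entropy weights:
   `UHI_i(t) = Σ_j w_j x'_ij(t)`.
2. **Regional collaboration index (HCDI).** The indicator set plus three
   relational indicators (policy support intensity, inverse mean
   distance/travel time to region members) weighted by an AHP judgment
   matrix (geometric-mean method, CR-checked), aggregated over member
   cities with coefficients α.
3. **Policy scoring.** Each policy document scores
   1 × level weight (national 3 / provincial 2 / municipal 1)
   × specificity weight (detailed 2 / general 1); a city-year's Policy
   Support Intensity is the sum over documents covering it.
4. **Gravity model.** For cities i, j of one agglomeration:

   ```
   G_ij(t) = c · UHI_i·UHI_j / d_ij^γ · exp(−Δt_ij/T)
             · (1 − θ·min(UHI_i,UHI_j)/max(UHI_i,UHI_j))
   ```

   with c = 1, γ = 1.8, T = 2 h, θ = 0.3. The last factor suppresses
   gravity between cities with similar health levels (competition).
5. **Collaboration network.** Node strengths `S_i(t) = Σ_j G_ij(t)` are
   correlated over years (Pearson), thresholded at τ = 0.6 into an
   adjacency; degree centrality `C_D(i) = Σ_j g_ij/(n−1)` and Freeman
   centralization feed a rule cascade that labels the structure
   (`unipolar`, `polycentric`, `core_periphery`, `dual_core_segmented`).
6. **Validation.** Leave-one-agglomeration-out cross-validation fits
   (c, γ, θ) by log-space least squares on the other regions and scores
   the held-out region by RMSE and R² on min-max-normalized gravity;
   sensitivity analysis perturbs γ by ±0.1 and T by ±20%.

Because the underlying yearbook data are not machine-readable, the
package ships a first-class synthetic generator
(`healthnet.synthetic`) that reproduces the study design — four
agglomerations of 13/26/9/16 cities over 2005–2023, rising indicator
trends with a 2020 shock, a 2015–2016 policy pulse, core-city elevation,
lognormal distances — and can plant any of the four network archetypes
with known ground truth. See `docs/methods.md` for the full model
account and its limitations.

## Worked example

```python
import healthnet as hn

study = hn.generate_study_area(hn.StudyAreaSpec(seed=1))

std = hn.standardize_panel(study.panel)
weights = hn.entropy_weights(std)
uhi = hn.compute_uhi(std, weights)
print({k: round(v, 3) for k, v in weights.weights.items()})

report = hn.loocv(study)
print(report.summary())

sens = hn.sensitivity_profile(study)
print(sens.attrs["max_pct_by_parameter"])
```

prints

```
{'hospitals': 0.247, 'physicians': 0.244, 'beds': 0.248,
 'health_expenditure_per_capita': 0.02, 'gdp': 0.242}
LOOCV over 4 agglomerations (64 cities, seed 1)
  held out BTH: rmse=0.0030 r2=0.9987 (c=0.993, gamma=1.798, theta=0.299)
  held out YRD: rmse=0.0036 r2=0.9985 (c=0.990, gamma=1.798, theta=0.299)
  held out PRD: rmse=0.0042 r2=0.9990 (c=0.994, gamma=1.799, theta=0.300)
  held out CY: rmse=0.0050 r2=0.9986 (c=0.993, gamma=1.798, theta=0.300)
  worst fold: rmse=0.0050 r2=0.9985
{'T': 4.36, 'gamma': 2.99}
```

Reading the output: the entropy weights spread almost evenly over the
four informative indicators (per-capita expenditure varies little once
standardized, so it carries low weight). Each cross-validation fold
refits the gravity constants on three agglomerations and predicts the
fourth; the fitted values sit at the generating constants
(c = 1, γ = 1.8, θ = 0.3), the normalized prediction error per fold is
below 0.005 and R² above 0.998, i.e. the model generalizes across
regions under the declared 3% multiplicative reference noise. Total
network gravity moves by under 3% when γ is shifted by ±0.1 and by
about 4% when T is shifted by ±20% — the model is insensitive to
moderate mis-specification of its decay constants.

Classifying a planted structure:

```python
planted = hn.plant_structure(
    hn.archetype_spec("dual_core_segmented", seed=0), "dual_core_segmented")
pstd = hn.standardize_panel(planted.panel)
puhi = hn.compute_uhi(pstd, hn.entropy_weights(pstd))
tensor = hn.compute_gravity_study(
    puhi, planted.panel.membership,
    planted.distances, planted.travel_times)["CY"]
net = hn.build_network(tensor)
print(hn.classify_structure(net, puhi.xs(2023, level="year").reindex(net.cities)))
# -> dual_core_segmented
```

## Command line

The same pipeline is available as subcommands writing tidy-CSV/JSON
artifacts plus a manifest (config hash, seed, version):

```bash
healthnet all --out-dir out --seed 1          # simulate → ... → validate
healthnet simulate --config config.yaml
healthnet network --out-dir out               # errors if gravity stage missing
```

Stages: `simulate`, `uhi`, `policy`, `hcdi`, `gravity`, `network`,
`validate`, `all`. Reruns with the same config are byte-identical.

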