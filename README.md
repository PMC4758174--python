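# nestnet

Movement and home-range analysis for gliding forest mammals in fragmented,
partly urban landscapes — built around the Siberian flying squirrel
(*Pteromys volans*), a nocturnal glider that holds several daytime nest
sites inside its home range and switches between them from day to day.
The package is aimed at movement ecologists who want to ask: *does the
choice of the next nest site depend on how far away it is, or on whether
forest connects it to the current one?*

The pipeline covers four stages, each usable on its own:

1. **Landscape & home ranges** (`nestnet.landscape`) — five-class habitat
   rasters at 25 m (H1 suitable forest … H5 water), 100 % minimum-convex-
   polygon home ranges, habitat composition inside polygons and along
   buffered movement paths.
2. **Movement metrics** (`nestnet.movement`) — burst extraction from
   nightly telemetry (stationary periods split bursts), lengths, speeds,
   nightly distances, and a tidy table ready for mixed models.
3. **Connectivity** (`nestnet.connectivity`) — the log-distance matrix
   `D = log(d + 1 m)` and twelve alternative binary connectivity matrices
   C1–C6 / C1g–C6g between an individual's nests (straight vs. free
   routes, suitable vs. suitable+movement forest, within vs. beyond the
   home range, 0 vs. 50 m glidable gaps).
4. **Nest-switching model** (`nestnet.nest_markov`, `nestnet.bayes_fit`) —
   a Markov chain over the nest network with row-softmax transitions

       L = β_I I + (1 − I)(β_D D + β_C C),   P_ij = e^{L_ij} / Σ_j e^{L_ij},
       z(t + Δt) = z(t) P^Δt

   fitted hierarchically (β_l ~ N(α0 + α1·s, Σ), s = ±1 for sex) by
   adaptive Metropolis-within-Gibbs, with DIC comparison across the
   1 + 12 + 12 model family.

Compositional habitat selection (`nestnet.habitat_selection`: log-ratio
analysis, Wilks Λ, sign-randomization tests, ranking matrices) and a
synthetic-data generator (`nestnet.synthetic_data`: patchy landscapes,
nest networks, switching sequences simulated from the model itself,
telemetry tracks) complete the pipeline. See `docs/methods.md` for the
full model description and design choices.

## Worked example

The numbered scripts under `analysis/` run a complete synthetic study.

```bash
python analysis/01_simulate_study.py --seed 7   # landscape + population + data
python analysis/02_movement_metrics.py          # bursts, nightly distances
python analysis/03_connectivity_matrices.py     # D and C1..C6g per individual
python analysis/04_habitat_selection.py         # compositional analysis
python analysis/05_fit_switching_model.py       # hierarchical Bayesian fit
python analysis/06_compare_models.py            # DIC ranking
```

`01` prints the realized landscape and population:

```
landscape 80x80 cells at 25 m: H1 32.0%, H2 20.0%, H3 38.0%, H4 7.0%, H5 3.0%
20 individuals (10 F, 10 M); nests/individual 5.2; 2162 nest observations; 2400 telemetry fixes
```

`05` fits the full model (staying term + distance + C5g connectivity) and
compares the posterior with the hidden generating values:

```
model distance+C5g: 8000 iterations (2000 burn-in), 20 individuals
mean MH acceptance 0.249 (target 0.23)
     parameter   mean     sd   q2.5  q97.5  truth  covered
alpha0[beta_I]  1.433  0.560  0.214  2.534  1.200     True
alpha0[beta_D] -0.289  0.123 -0.544 -0.055 -0.400     True
alpha0[beta_C]  0.513  0.325 -0.095  1.190  0.600     True
alpha1[beta_I]  1.396  0.607  0.278  2.670  0.200    False
alpha1[beta_D]  0.064  0.126 -0.183  0.312 -0.100     True
alpha1[beta_C]  0.391  0.312 -0.220  1.006  0.200     True
DIC = 3839.6 (Dbar 3807.9, pD 31.7)
```

Read: the population mean distance effect `alpha0[beta_D]` is credibly
negative — switching probability falls with inter-nest distance — and five
of the six 95 % intervals cover the generating values (on one simulated
study an occasional miss is expected; calibration across 20 replicates is
checked in the test suite). `06` then ranks models by DIC; the generating
model comes out on top:

```
       model    DIC   Dbar   pD  mean_acceptance  dDIC
distance+C5g 3838.1 3807.1 31.0              0.3   0.0
         C5g 3860.1 3834.6 25.5              0.2  22.1
    distance 3867.4 3841.4 25.9              0.2  29.3
```

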