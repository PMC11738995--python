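# vasckinetics

Quantitative analyses for embryonic vascular imaging: dual-pulse
(EdU/BrdU) cell-cycle kinetics, nucleus–Golgi directional polarity with
circular statistics, and inside/outside-vessel morphometrics — plus a
synthetic-data module that generates labeling experiments and 3D vessel
scenes with known ground truth so every stage can be validated by
parameter recovery.

The package is aimed at researchers quantifying proliferation and
directed migration of endothelial populations (e.g. PROX1⁺ lymphatic
endothelial progenitors around the embryonic cardinal vein) from
segmented 3D microscopy: label masks, detected nuclei and scored marker
flags, not raw fluorescence.

## The estimators

A dual-pulse protocol exposes a scored population of `P_cells` nuclei to
EdU over an injection interval `T_i`, then to BrdU until harvest. At
harvest, EdU⁺BrdU⁺ cells (`S_cells`) are in S-phase; EdU⁺BrdU⁻ cells
(`L_cells`) left S-phase during `T_i`. With the growth fraction GF
estimated from KI67 positivity, the S-phase and total cycle durations of
a steady-state asynchronous population follow from

```
T_S = T_i / (L_cells / S_cells)
T_C = T_S / (S_cells / (P_cells × GF))
GF  = P_cells(KI67⁺) / P_cells
```

Polarity is quantified per cell as the compass angle of the
nucleus→Golgi centroid vector in the x–y plane against the dorsal body
axis, θ = arccos(A·B) signed onto [0°, 360°) (0° dorsal, 90° lateral,
180° ventral, 270° medial), after one-to-one nucleus–Golgi pairing by
closest border–border distance with a 5 µm exclusion. Angular
distributions are summarized by rose histograms, the circular mean,
resultant length R and a Rayleigh uniformity test. Morphometry
classifies cells inside/outside a segmented vessel by centroid distance
to the mask and reports marker-population counts and stage-to-stage
fold changes (ratios of replicate means).

See `docs/methods.md` for model assumptions, validity regimes and
design choices.

## Worked example

Simulate a dual-pulse experiment on 50,000 cells whose true kinetics are
T_C = 26.6 h, T_S = 10 h, GF = 0.8 (the slow, inside-vein regime), then
invert the counts:

```python
import vasckinetics as vk

params = vk.CycleSimParams(t_cycle=26.6, t_s=10.0, growth_fraction=0.8,
                           n_cells=50_000, seed=42)
table, counts, truth = vk.simulate_pulse_labeling(params)  # default schedule:
# EdU available [0, 6] h, BrdU [6, 8] h, T_i = 6 h
est = vk.bootstrap_estimates(table, t_i=6.0, n_boot=1000, seed=0)
```

This prints (via `counts` and the estimate fields):

```
PulseCounts(p_cells=50000, s_cells=14938, l_cells=9109, ki67_pos=40000, t_i=6.0)
T_S = 9.84 h   (truth 10.0)
T_C = 26.35 h  (truth 26.6), 95% CI [25.89, 26.80]
GF  = 0.800    (truth 0.8)
```

`T_S` is `6.0 × 14938 / 9109` — the outflow of the EdU-labeled S cohort
over the 6-h interval sets the S-phase clock — and `T_C` scales it by
the cycling pool's S-phase occupancy `(50000 × 0.8) / 14938`. Both land
within ~1% of the generating truth; the bootstrap interval covers it.

A polarity scene works the same way:

```python
nuclei, golgi, vessel, scene_truth = vk.generate_vessel_scene(
    vk.SceneParams(n_inside=10, n_outside=10, mu_deg=90.0, kappa=4.0, seed=7))
pairing, dist = vk.polarity_pipeline(nuclei, golgi)
```

giving `20` included pairs, circular mean `92.9°` against the generating
`90°`, `R = 0.91`, Rayleigh `p ≈ 0` — a strongly lateralized population,
as simulated.

The same stages are exposed as a CLI (`vasckinetics simulate pulse`,
`simulate scene`, `cellcycle`, `polarity`, `count`, `report`); see
`vasckinetics --help`.

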