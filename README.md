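# figground

Figure-ground statistics of natural scenes at the scale of MT receptive
fields, with a population-coding model of how a fast-speed response bias
prioritizes visual figures.

## The scientific problem

Separating objects, people and animals ("figures") from their
surroundings ("ground") is a core visual computation. Neurons in primate
area MT, when stimulated by two surfaces moving at different speeds
inside one receptive field, respond preferentially to the faster
component; MT populations also over-represent near (crossed) binocular
disparities. These biases would be useful for figure-ground segregation
*if*, in natural scenes, figures reliably move faster and more coherently
than ground regions and sit nearer to the observer — at the spatial scale
of a single receptive field, and after accounting for eye movements.

`figground` implements that analysis end to end as a tested pipeline:

1. **Scene bundles** — co-registered per-pixel rasters of motion speed
   (deg/s), motion direction (deg; 0 = rightward, 90 = upward), radial
   distance (m), and figure/ground/sky labels, plus metadata. Motion below
   the 0.5 deg/s estimation noise floor is censored, and a 5-pixel
   Chebyshev buffer around annotation borders is excluded.
2. **Synthetic scenes** — a generator producing bundles with the documented
   structure of annotated outdoor recordings (mostly-slow censored ground
   motion, fast horizontally biased rigid figure motion, stationary
   figures, a ground-plane distance ramp with figures nearer, sky), so
   everything downstream is testable without data downloads.
3. **Gaze simulation** — fixations drawn from the upper half of a saliency
   median split; smooth pursuit modelled by subtracting the fixated
   point's motion vector (retinal motion, `v - v_fix`); vergence modelled
   geometrically. For a point `P = [x y z]` and fixation `P* = [x* y* z*]`
   with interocular separation `s = 6.2 cm`, eye-frame abscissae are
   `x_R = s/2 - x`, `x_L = -s/2 - x`, horizontal eccentricities
   `θ_{R,L} = atan(x*_{R,L}/z*) - atan(x_{R,L}/z)`, and horizontal
   disparity `d = θ_L - θ_R` (crossed/near positive). Relative disparity
   between two points is provably independent of the fixated point.
4. **Simulated receptive fields (sRFs)** — circular apertures of diameter
   2.5, 5, 10 or 15 deg placed at random, paired with a fixation at an
   eccentricity matching the diameter (±10%), and accepted only if ≤50%
   of aperture pixels are missing and ≥25% are figure and ≥25% ground.
5. **Statistics** — per sRF, figure/ground region summaries: mean log10
   retinal speed (`s_f`, `s_g`), circular variance of direction
   (`v_f`, `v_g`; 1 − mean resultant length), mean disparity (`d_f`,
   `d_g`); differences analyzed with one-sample t-tests (Cohen's D),
   one-way ANOVA across eccentricities (η², Tukey HSD), sign proportions
   with exact binomial CIs, rank-sum/Rayleigh/Kuiper tests for the global
   distributions, and figure/ground probability-ratio curves on 50 linear
   bins with sRF-level bootstrap CIs.
6. **Population model** — 50 neurons with Gaussian tuning over log10
   speed (σ = 1 log unit). For a bi-speed stimulus (figure speed `s_f`,
   ground `s_g = c·s_f`, `c ∈ [0.3, 0.8]`), each neuron combines its two
   single-stimulus rates `r_f`, `r_g` by one of three strategies
   (prioritize faster, average, prioritize slower); speed is decoded as
   the response-weighted average of preferred log speeds. The
   prioritize-faster rule recovers the figure speed; the others read out
   slower speeds.

## Worked example

```python
import figground as fg

params = fg.SceneGenParams()                      # default study conditions
bundles, _ = fg.generate_dataset(10, params, seed=0)
samples, _ = fg.build_srf_set(bundles, n_per_size=50, seed=1)
diff = fg.srf_differences(bundles, samples)
tests = fg.difference_tests(diff)
```

Formatting the three figure-ground differences prints:

```
log-speed: mean +0.465  t(192) = 8.0   p = 8.9e-14  D = 0.58   figure-favored 74% (CI 67-80%)
 circ-var: mean -0.465  t(192) = -11.9 p = 8.6e-25  D = -0.86  figure-favored 74% (CI 67-80%)
disparity: mean +0.494  t(199) = 22.2  p = 1.2e-55  D = 1.57   figure-favored 98% (CI 96-100%)
```

Read: within these simulated receptive fields, figure regions move faster
than ground regions on average (+0.47 log10 deg/s, i.e. ~3× faster), move
more coherently (lower circular variance), and carry more positive
(nearer) disparity (+0.49 deg); the percentages are the share of sRFs in
which the figure side wins, with exact 95% binomial confidence intervals.

The bi-speed decoding experiment is available from the shell:

```bash
figground popmodel --seed 0
```

```
 stimulus    s_f    s_g          strategy  decoded_speed  edge_flagged
        0  1.000  0.618 prioritize_faster          1.035         False
        0  1.000  0.618           average          0.824         False
        0  1.000  0.618 prioritize_slower          0.655         False
        1  1.694  0.737 prioritize_faster          1.724         False
        ...
```

The prioritize-faster strategy decodes essentially the figure speed;
averaging and prioritize-slower fall below it. `figground all --seed 0
--out run/` executes the full pipeline (scenes → gaze → sRFs → statistics
→ population model) and writes CSV/JSON reports.

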