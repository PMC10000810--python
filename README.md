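# helict

Processing chain for **helically acquired propagation-based phase-contrast
micro-CT** (PBI-CT) of low-density samples such as hydrogel tissue
scaffolds, built around one idea: acquiring with a continuously translating
rotation stage and converting the helical frames into *virtual* standard
180° projections spreads fixed-pattern detector errors across the volume,
so ring artifacts largely disappear instead of having to be filtered out.

The package is aimed at synchrotron micro-CT users and method developers.
It contains every stage of the chain plus a synthetic acquisition simulator
with controllable detector defects, so the whole pipeline is testable
without beamline data:

| stage | module | what it does |
|---|---|---|
| simulate | `helict.simulate` | grid-scaffold / bar / blob phantoms, parallel-beam projector, weak-defocus TIE contrast, Poisson + fixed-pattern detector model |
| correct | `helict.preprocess` | flat/dark correction `(I−D)/(F−D)`, vertical beam-profile drop statistic |
| convert | `helict.convert` | helical → virtual standard projections (the core algorithm, below) |
| phr | `helict.phase` | single-distance TIE (Paganin-type) phase retrieval, δ/β = 2000 default |
| dering | `helict.rings` | low-pass Fourier (Raven) and sorting-based stripe filters (comparison baselines) |
| recon | `helict.recon` | parallel-beam FBP (ramp / Shepp-Logan) |
| metrics | `helict.metrics` | SNR, CNR, bar-pattern MTF with 10 % cutoff, FSC + 1/7-threshold resolution (FIRE), ring-residual score |
| dose | `helict.dose` | pitch-aware surface-entry dose `D = Ḋ·Δt·N_eff` |

## The conversion in one paragraph

A helical scan records `N_R·N_p` frames of `M` detector rows while the
stage translates `v = p·M/N_p` rows per projection (`p` = pitch =
stage travel per revolution / detector height). Because a parallel-beam
projection at angle `θ+π` is the horizontal mirror of the one at `θ`,
frame `k` folds onto virtual projection `k′ = k mod (N_p/2)`, flipped when
`⌊k/(N_p/2)⌋` is odd; virtual row `r` receives
`(1−w)·I[i₀] + w·I[i₀+1]` with `i₀ = ⌊r − k·v⌋` and `w` the linear
interpolation weight (`w = 0` when `k·v` is integral). For `p < 2`
redundant rows are discarded (earliest rotation wins); for `p > 2` the
rotations no longer overlap and the unscanned rows are flagged, not
interpolated. The virtual stack has `M′ = M + ⌈v·(N_R·N_p−1)⌉` rows and
feeds any standard 180° reconstruction.

## Worked example

The headline experiment scans one water-equivalent cylinder twice — helical
(32-row detector, `p = 1.5`, 2 rotations, 128 projections/rev) and standard
(full-height detector, 64 projections over 180°) — with *identical*
fixed-pattern defects (1.5 % gain errors, 3 stuck pixels, one 2×7 stuck
patch) at matched surface dose, then scores rings in the reconstructions:

```python
>>> from helict.pipeline import ring_comparison_experiment
>>> r = ring_comparison_experiment(seed=1)
>>> {k: round(v, 3) for k, v in r.items() if isinstance(v, float)}
{'helical': 0.036, 'standard': 0.291, 'standard_raven': 0.101,
 'standard_sorting': 0.148, 'suppression_factor': 8.116}
```

The numbers are the RMS ring power of the reconstructed slices
(attenuation units, mm⁻¹): the raw standard scan shows strong rings
(0.291); the Raven and sorting filters reduce but do not eliminate them
(0.101 / 0.148); helical acquisition plus conversion beats all three
(0.036, an 8× suppression) without any post-hoc filtering.

Dose planning from the shell:

```text
$ helict dose --rate 0.62 --exposure 0.057 --n-proj 3000 --pitch 1.5
effective projections: 2000.00
surface entry dose: 70.68 Gy
```

and the whole chain runs stage by stage
(`helict simulate | correct | convert | phr | dering | recon | metrics`)
or in one shot from a YAML config (`helict run config.yaml outdir/`).

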