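# kermastack

Air-kerma modelling and replacement scheduling for **back-to-back stacked
Co-60 teletherapy sources**.

Cobalt units (single-source teletherapy machines, multisource
stereotactic units like the Leksell Gamma Knife) replace their sources
after about one half-life, discarding half of the purchased activity.
If instead the used source is pushed one capsule position behind a new
one — or two used sources are combined back-to-back in one holder — its
residual output still reaches the focus and offsets the activity that
must be bought. `kermastack` is for medical physicists and source-economy
analysts who want to quantify that trade-off.

## The model

A source behind `n` newer capsules retains the relative air-kerma strength

    S(n) = A(n) * D(n)
    A(n) = exp(-n * (μ_src·h_src + μ_shell·h_shell))   (narrow-beam attenuation)
    D(n) = d² / (d + n·l)²                             (inverse-square, pitch l)

with μ the linear attenuation coefficients at 1.25 MeV, `h` the active
and shell heights, and `d` the source-focus distance. Around this core
the package provides:

* `physics` — correction tables, decay bookkeeping (`2^-age`), stack
  output summation with pluggable per-position transmission factors;
* `scheduling` — the push-back and combine-pairs staged replacement
  schemes with per-epoch activity- and encapsulation-savings accounting;
* `mc` — an independent forced-detection Monte Carlo estimator of the
  same ratio (primary photons, exact ray/cylinder optical depths) used to
  validate the closed form;
* `scenarios` — the packaged Leksell 4C parameter set and randomized
  scenario generation;
* `config` / `reports` / `cli` — a unit-checked YAML schema, CSV/JSON
  report writers and a `kermastack` command-line tool.

## Worked example

```python
import kermastack as ks

bundle = ks.leksell4c_fixture()
rows = ks.correction_table([0, 1, 2, 3], bundle.capsule, bundle.geometry)
```

which tabulates (`kermastack evaluate` prints the same):

```
 n_front  attenuation  distance    total
       0     1.000000  1.000000 1.000000
       1     0.416472  0.876992 0.365242
       2     0.173449  0.775359 0.134485
       3     0.072236  0.690421 0.049874
```

A source one slot back keeps 36.5% of its window output (41.6% survives
attenuation, 87.7% the extra 2.72 cm of distance); three slots back only
5.0% remains, so a holder deeper than three or four positions buys
nothing. The Monte Carlo cross-check agrees with the closed form:

```
$ kermastack mc --n-front 1 --histories 1000000 --seed 1
relative kerma (n_front=1): 0.365213 +- 0.000001 (1000000 histories, seed 1)
```

Feeding the schedule the analytic transmission, the pair-combining scheme
(`kermastack schedule --scheme combine-pairs --epochs 2`):

```
 epoch  residual  new_activity  activity_saving  encapsulation_saving
     1  0.682621      1.317379         0.341311              0.500000
     2  0.682621      1.317379         0.341311              0.500000
```

Two half-life-old sources combined back-to-back deliver 68.3% of one
nominal source (50% from the front one, 50%·36.5% through it), so one
boosted source of 131.7% replaces two full sources: a 34.1% activity
saving and half as many new capsules. With an externally supplied
transmission factor of 0.344 (`--transmission table:<csv>`) the familiar
figures 67.2% / 132.8% / 33.6% come out instead.

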