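# Methods

## Problem

Teletherapy units built around Co-60 (single-source cobalt machines and
multisource stereotactic units such as the Leksell Gamma Knife) replace
their sources after roughly one half-life, discarding half of the
purchased activity. `kermastack` models an alternative: the used source is
kept in the treatment head, pushed one capsule position behind a new
source (or combined back-to-back with another used source), so its
residual output still reaches the focus. The package quantifies how much
of that output survives and what the staged replacement schemes save.

## Closed-form model

A source stacked behind `n` newer capsules is attenuated by the material
in front of it and sits farther from the focus. Its air-kerma strength
relative to the exit-window position is the product of two factors:

* **Narrow-beam attenuation.** Each front capsule interposes its active
  pellet column (height `h_src`, linear attenuation
  `mu_src = (mu/rho)_src * rho_src`) and its steel shell (total height
  `h_shell`, coefficient `mu_shell`), so the primary-photon transmission is

      A(n) = exp(-n * (mu_src*h_src + mu_shell*h_shell)) = A(1)^n

  Scatter build-up is deliberately not modelled; the transmission is a
  primary-photon (narrow-beam) quantity at the 1.25 MeV mean Co-60 photon
  energy, with no spectral treatment of the 1.17/1.33 MeV lines.
  Heterogeneous stacks (capsules of different make per position) are
  supported by summing per-layer optical thicknesses
  (`layered_attenuation`) instead of the power law.

* **Inverse-square distance growth.** The source recedes by one capsule
  pitch `l` per front source:

      D(n) = d^2 / (d + n*l)^2

  The point-source form is adequate because the focus distance exceeds
  five active-column heights (`point_source_validity` checks the ratio
  `d/h_src >= 5`; a violation logs a warning but does not stop the
  calculation, since the model degrades gradually).

The reference parameter set (`leksell4c_fixture`) is the Leksell 4C source:
`(mu/rho)_src = 0.0527 cm^2/g`, effective pellet-column density
`5.88 g/cm^3`, `h_src = 2 cm`; steel shell `(mu/rho) = 0.0535 cm^2/g`,
`rho = 7.85 g/cm^3`, `h_shell = 0.61 cm` (0.12 cm front, 0.49 cm back);
pitch `l = 2.72 cm`; `d = 40.1 cm`. Note the pitch exceeds the summed
layer heights (2.61 cm) by 0.11 cm; the fixture keeps both values and the
transport geometry models the difference as an air gap (treated as
vacuum) behind each capsule. With these constants, `A`, `D` and the total
`A*D` for `n = 1..3` round to 0.416/0.173/0.072, 0.877/0.775/0.690 and
0.365/0.134/0.050 at the 3-decimal precision such correction tables are
quoted at (rounding is numpy's round-half-to-even).

Decay bookkeeping works directly in half-lives (`decay_fraction(age) =
2**-age`), so no half-life constant enters any reproduced number; a Co-60
half-life of 5.2711 y is exported as a labelled constant solely for
converting calendar time to ages.

## Replacement schedules

Both schemes are quantized at one half-life per epoch and governed by the
maintenance condition *residual output + newly purchased activity =
target output*, asserted to machine precision at every epoch. The
transmission provider is pluggable: the analytic total `A(n)*D(n)`, or an
externally supplied per-position table (e.g. factors obtained from an
independent transport calculation), because the savings arithmetic is
conventionally quoted with the simulated one-slot factor 0.344 rather
than the closed-form 0.365.

* **Push-back** (`push_back_schedule`): a single holder with `capacity`
  positions. Each epoch every source ages one half-life and recedes one
  slot; the source pushed past the last slot is withdrawn; a new source
  enters at the window with activity `target - residual` (clamped at zero
  with a warning if the residual ever exceeds the target). By default a
  full-strength source is already installed at epoch 0, so epoch 1 is the
  first replacement: with transmission 0.344 the residual is
  `0.5 * 0.344 = 0.172`, a 17.2% activity saving. The per-epoch new
  activity converges to the geometric-series limit
  `target / (1 + sum_i 2^-i T(i))`, which the tests check against a
  40-epoch run.

  The new-source activity at the first replacement is `1 - 0.172 =
  0.828`. A figure of 81.7% is sometimes quoted for this step; that
  number corresponds to `1 - 0.5*0.365` (the closed-form factor), not to
  the 0.344-based residual. The implementation follows the conservation
  arithmetic throughout.

* **Combine-pairs** (`combine_pairs_schedule`): a bank of an even number
  of window holders. Each epoch the used sources are combined two per
  holder — a pair delivers `0.5 + 0.5*T(1)` of a nominal source (0.672
  with `T(1) = 0.344`) — and one boosted new source of `2*target - pair
  output` (1.328) is bought per pair, i.e. half as many fresh capsules as
  window holders (50% encapsulation saving) and an activity saving of
  `(2 - 1.328)/2 = 0.336`. Epochs beyond the first repeat the same
  nominal per-batch arithmetic; the progressive regrouping of older
  combined holders into larger groups is tracked structurally in the
  inventory timeline but not booked quantitatively, and group sizes above
  two are exposed only as a configuration knob.

Dummy (filler) capsules are zero-activity `SourceRecord`s, so holder
occupancy mirrors the physical loading diagrams literally.

## Monte Carlo transport

`mc_transport` is an independent desk-scale check of the closed form: a
from-scratch forced-detection estimator for primary photons. The geometry
is a coaxial stack of finite cylinders (front shell / active column /
back shell per capsule, air gap behind), with the focal point on the axis
placed a source-focus distance in front of the *reference* capsule's
active-column midpoint — that placement makes the degenerate point-source
limit reproduce the inverse-square factor `d^2/(d+n*l)^2` exactly, which
is the correspondence the estimator is meant to validate.

Each history samples an emission point uniformly in the emitting capsule's
active cylinder and scores `exp(-tau)/r^2` toward the focus, where `tau`
is the exact ray/cylinder-intersection optical depth through every region
except the emitter's own active column (matching the closed form, which
attenuates only by material in front; the emitter's own front shell is
traversed but cancels in normalization). The tally is normalized by the
same estimator on the single-capsule reference geometry, using *common
emission offsets* (paired sampling), and the standard error of the ratio
comes from the delta method including the pairing covariance. Sampling
uses `numpy.random.default_rng`; the seed is mandatory, and a tally is
bit-for-bit reproducible from `(seed, histories, geometry)`.

Numerical choices: the active-column radius is not a vendor-published
number; it defaults to 0.05 cm, is configurable, and is flagged in
comparison reports. Rays parallel to slab faces or to the axis are
handled by interval logic rather than division; zero-height or
zero-radius regions degrade gracefully to points/disks, which the limit
tests exploit. Default runs use 10^6 histories — at the percent level of
agreement being tested, the paired estimator's sampling error is far
below the physical modelling differences, so larger runs buy nothing.

Because both the estimator and the closed form are primary-photon models,
they agree to well under 0.1 percentage points on the reference fixture;
the extended source sits slightly *below* the on-axis closed form
(oblique rays cross more material), and a test asserts that one-sided
inequality. Agreement with a full production transport calculation
(collimator, phantom, scatter, 2x10^9 histories) is *not* claimed: the
published simulated factors (0.344/0.122/0.043) differ from the equation
row by up to 2.4 percentage points, and this package judges its own MC
against that spread, not against sampling error alone. Whether such a
reference tally scores air kerma in vacuo or dose in a phantom is not
recorded in the source material; this package scores in-air kerma ratios
at the focus.

## Scenario generation

`scenarios.random_scenario` draws materials (`mu/rho` in 0.01–0.2 cm^2/g,
density 0.5–12 g/cm^3), layer heights (0.1–5 cm active, 0.1–1 cm shell),
a pitch with up to 20% air gap, and a focus distance of 30–100 cm floored
at `5*h_src` so the point-source validity criterion holds by default; an
option deliberately violates it to exercise the warning path. These
bundles emulate the *structure* of real source inventories, not any
specific commercial unit's values; passing property tests on them shows
the arithmetic and invariants are right, not that any particular unit's
output is predicted. All randomness is seed-deterministic.

## Known limitations

* No scatter, buildup, beam hardening or polyenergetic spectrum; the
  model deliberately stops at narrow-beam primaries.
* No collimator channel material, phantom dose, penumbra or treatment-time
  modelling; no monetary cost model.
* The combine-pairs savings records assume nominal-strength batches each
  epoch; long-horizon group regrowth is structural only.
* The active-column radius default (0.05 cm) is an assumption, flagged in
  every comparison report.
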