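# mitomorph

3-D morphometry and unbiased stereology of cardiac mitochondrial
subpopulations, with a seeded synthetic-EM phantom generator for validating
every estimator against known ground truth.

Cardiomyocyte mitochondria form three spatially defined subpopulations:
**SSM** (subsarcolemmal, immediately under the sarcolemma), **IFM**
(interfibrillar, in rows between myofibrils) and **PNM** (perinuclear,
against the nuclear envelope). Studies of their differential remodelling —
in diabetes, heart failure and ageing — rest on a small set of quantitative
primitives applied to serial block-face SEM label volumes and TEM
micrographs. `mitomorph` implements those primitives as a tested library
for people building or auditing such analyses:

* **Per-organelle 3-D morphometry** on anisotropic label volumes: exact
  voxel volumes, iso-surface mesh surface areas, SA/Vol, spatial subtype
  assignment, an oval/irregular shape classifier, skeleton-based tubular
  projection measurement (length, tip width) and nanotunnel detection
  (thin tubes joining two bodies).
* **Unbiased stereology**: two-lattice point counting for the
  mitochondrial volume fraction of the cardiomyocyte,

      Vv = (N_mito · a_green · n·t) / (N_cm · a_red · n·t) × 100 ,

  with random lattice offsets and a uniform-random start of the systematic
  slice series; and the classical line/point-probe surface density of
  cristae membranes, `Sv = 2·ΣI / (l/p · ΣP)`.
* **Cristae analysis** on 2-D TEM-style images: threshold → grey-level line
  profile → membrane-doublet detection → outer width `W_O`, lumen width
  `W_I` and spacing `S`; plus an ordinal 1/3/5 cristae-order score.
* **Reporting**: animal-first summaries (mean ± SEM over animal means),
  fold changes, and the standard comparison battery (t test, one-way
  ANOVA + Tukey, two-way ANOVA + Sidak).
* **Synthetic data** (`mitomorph.synthetic`): seeded cardiomyocyte label
  volumes with controllable volume fraction, subtype mix, shape mix,
  projections and nanotunnels — plus TEM-style cristae images — every
  object carrying exhaustive ground truth. Defaults reproduce wild-type
  myocardium conditions (30.2% mitochondrial fraction; 15.3/80.1/4.7%
  SSM/IFM/PNM; W_O ≈ 36 nm, W_I ≈ 16 nm).

There is no command-line tool: the package is a library, used from Python.
`examples/` holds one short narrative script per capability.

## Worked example

```
$ python examples/estimate_volume_fraction.py
true voxel fraction:    30.16%
point-count estimate:   29.72% (sd over placements 10.28)
```

The generator placed ~90 mitochondria at the wild-type conditions into a
640 × 640 × 48-voxel volume (13.5 × 13.5 × 50 nm voxels) and recorded the
exact mitochondrial voxel fraction (30.16%). Two-lattice point counting —
a ~3.7 µm red tile for the cardiomyocyte reference, a ~1.6 µm green tile
for mitochondria, every 20th section — recovers it to within half a point
when averaged over 150 random probe placements; the large per-placement sd
is the honest cost of counting a few dozen points per placement, and
shrinks with volume size and placements as 1/√(points).

```
$ python examples/cristae_dimensions.py
15 cristae crossed by the profile line
W_O (outer width):   35.8 nm   truth  35.4 nm
W_I (lumen width):   15.7 nm   truth  15.8 nm
S   (doublet gap):   30.3 nm   truth  28.7 nm
quality score: 1 (ordered coverage 1.00)
cristae surface density Sv: 0.0407 /nm (lamellar truth 0.0396)
```

Here a synthetic mitochondrion rendered with membrane doublets at
W_O = 36 ± 2 nm, W_I = 16 ± 1 nm is re-measured by the threshold →
line-profile → doublet pipeline: widths come back within ~1 nm of the
rendered truth, the image scores "1 = ordered cristae", and the line/point
probes estimate the membrane surface density within ~5% of the analytic
value.

See `docs/methods.md` for the models, estimator derivations, parameter
defaults and known limitations.

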