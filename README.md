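# chiptaxis

Quantification of monocyte recruitment and chemotaxis for vascularized
tumor-on-chip assays.

Microfluidic tumor models perfuse monocytes through a self-assembled
microvascular network that surrounds a central well holding a tumor
spheroid. Two questions define the readout, and this package implements
the computation behind both:

1. **Where are the monocytes?** From a two-channel confocal field
   (vasculature + monocytes), segment the vessel network, locate the
   central well morphologically, detect each cell, and classify it as
   **luminal** (still inside a vessel lumen), **extravasated** (escaped
   into the gel), or **recruited** (migrated into the tumor well).
2. **Why do they move?** From endpoint cell x-positions in a companion
   gel-channel migration assay, estimate the coefficients of the
   Keller–Segel chemotaxis model

   ∂n/∂t = ∂/∂x ( D ∂n/∂x − χ n ∂c/∂x ),

   where *n* is cell density, *c* the normalized chemoattractant
   concentration, *D* (µm²/h) the random-motility coefficient and
   χ (µm²/h per unit *c*) the chemotaxis coefficient. *D* is fit only in
   no-chemoattractant controls, pooled, and then frozen while χ is fit per
   condition — χ ≈ 0 means migration indistinguishable from random
   motility. A three-arm comparison (gradient / uniform stimulus /
   control) separates true chemotaxis from chemokinesis, i.e. uniformly
   elevated motility.

Because raw microscopy for such assays is rarely shareable, a seeded
synthetic-data layer generates vascular-network images with per-cell
ground-truth labels and biased-random-walk migration snapshots with known
(D, χ), making every pipeline stage verifiable end to end.

## Worked example

`examples/03_simulate_and_fit.py` simulates both assay arms with known
coefficients (D = 1000 µm²/h; χ = 13000, i.e. a 10 µm/h drift on the
linear 0→1 gradient across the 1300 µm channel) and runs the estimation
pipeline on the resulting positions:

```
true D   = 1000 um^2/h   fitted D   = 1014
true chi = 13000 um^2/h fitted chi = 12300
migrating percentage: control 0.3% vs gradient 4.2%
```

The fitted coefficients recover the programmed motility within a few
percent, and the migrating percentage (cells beyond the channel midline)
shows the directional response. `examples/01_quantify_synthetic_field.py`
does the same for the imaging pipeline:

```
truth    : {'luminal': 30, 'extravasated': 40, 'recruited': 30}
recovered: {'luminal': 30, 'extravasated': 40, 'recruited': 30, 'total': 100}
recruited fraction: 0.30
```

The other examples demonstrate the forward PDE solver against its closed
form and the chemotaxis-vs-chemokinesis screen.

## Command line

A thin CLI wraps the library for batch use:

```
chiptaxis simulate-image     --out out/            # synthetic field + truth
chiptaxis simulate-migration --out out/ --profile linear_gradient
chiptaxis quantify  --image field.tif --out out/   # or --manifest batch.csv
chiptaxis fit       --positions pos.csv --manifest arms.csv --out out/
chiptaxis demo      --seed 11 --out out/           # seeded end-to-end run
```

Every run writes its fully-resolved flat YAML configuration next to its
outputs; unknown configuration keys are rejected by name.

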