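# fishmfa

Nuclei segmentation and HER2 scoring for dual-color FISH micrographs,
based on inverse multifractal analysis (IMFA) of the blue (DAPI) channel.

## The problem

HER2 status in breast-carcinoma FISH slides is scored from the average
per-nucleus ratio of red (HER2 gene) to green (CEP-17 centromere) signals:
a mean ratio above 2.2 is HER2 positive, below 1.8 negative, in between
equivocal. Everything rests on segmenting the DAPI-stained nuclei first —
and on degraded fields with uneven excitation, no global intensity
threshold works: any cut that excludes bright-side background also loses
the dim-side nuclei.

## The method

From the blue channel, the per-pixel Hölder exponent

    alpha(m, n) = slope of ln mu_k(m, n) vs ln eps_k

is estimated over a ladder of centred windows, where mu is the normalized
sum of intensities in the window ("sum capacity") and eps the normalized
window side. The matrix **A** = {alpha(m, n)} — the *alpha-image* — maps
smooth, locally dense structure (nuclei) to low alpha and rough background
to higher alpha. Initial binarization is a hard threshold

    nucleus candidate  <=>  alpha(m, n) <= alpha_T = 1.1 * alpha_min

(the factor is adjustable, roughly 1.05–1.14; masks are nested in it, so
raising it strictly adds detail). Because a slowly varying illumination
field cancels in the log-log slope, this binarization survives the lateral
ramps that defeat intensity thresholds. Morphological refinement, a
distance-transform/watershed split of touching nuclei, and geometric
rejection of small / non-oval / border regions complete the pipeline. A
classical intensity-thresholding pipeline (sqrt transform, opening, white
top-hat, Otsu) is included as the paired baseline, sharing every stage
after binarization. The global multifractal spectrum f(alpha) and
box-counting dimension estimators round out the analysis module.

No clinical images ship with the package; a synthetic scene generator
reproduces the statistical regime the method exploits (smooth bright
nuclei with windowed contrast ≤ 2:1, dark rough background ≥ 3:1,
optional illumination ramp, red/green dots with known tallies) and serves
as ground truth for all benchmarks. See `docs/methods.md` for the model,
parameter defaults and limitations.

## Worked example

Generate a degraded-illumination scene, segment it, and score HER2:

```sh
$ fishmfa synth -o scenes --n-scenes 1 --regime gradient_illumination \
      --size 508x448 --n-nuclei 20 --seed 1
$ fishmfa segment scenes/scene_000.png -o seg
... INFO fishmfa: segmented 20 nuclei (alpha_min=1.63352, alpha_T=1.79687)
$ fishmfa score scenes/scene_000.png --labels seg/labels.tif -o score
... INFO fishmfa: HER2: {'mean_ratio': 2.7666, 'category': 'positive', 'n_scorable': 20}
```

The segment step writes the alpha-image (`alpha.tif`, 32-bit float), the
initial and refined masks, a 16-bit label map, a contour overlay with
numbered nuclei, a region table (`regions.csv`, with per-region area,
eccentricity and rejection reason), and `report.json`. Here all twenty
generated nuclei were found; Hölder exponents ranged from 1.634 to 3.162
and the threshold landed at 1.1 x 1.63352 = 1.79687. The score step counts
red/green dots per nucleus (e.g. nucleus 1: 5 red, 2 green) and the mean
ratio 2.77 > 2.2 classifies the case HER2 positive — matching the tallies
the generator drew.

If the initial segmentation over- or under-selects, re-run with
`--alpha-factor 1.05 … 1.14`, and drop non-nuclei by id with
`--drop-labels 3,7` — the scriptable form of the interactive
inspect-and-refine loop.

A paired comparison on the same scenes:

```sh
$ fishmfa eval -o ev --n-scenes 4 --seed 1
... INFO fishmfa: mean accuracy: IMFA 1.0000 (sd 0.0000) vs OTHER 1.0000 (sd 0.0000)
```

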