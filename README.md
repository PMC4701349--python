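# lfareader

A desk-scale automated reader for lateral-flow saliva test cards of the kind
used in drugs-of-abuse screening (AMP, KET, COC, MET, OPI, THC panels, with
an optional alcohol reagent strip).

In a lateral-flow immunoassay the sample migrates along a membrane strip by
capillary action. A **control line (C)** confirms that migration happened;
the **test line (T)** works by competitive binding, so its *absence* means
the drug concentration exceeds the cutoff (**positive**), any visible shade
means **negative**, and a missing control line makes the strip **invalid**.
Reading faint lines by eye is notoriously operator-dependent; this package
automates it from a single photograph of the card.

## Method

The reading chain has four stages:

1. **Registration.** ORB features (oriented FAST-9 keypoints + 256-bit
   rotated-BRIEF descriptors) are matched between the photograph and a
   stored template by Hamming distance with a mutual nearest-neighbor
   consistency check; a RANSAC-estimated homography H (template → image)
   rectifies the photograph into the template frame and crops the strip
   region, making everything downstream pose-invariant.
2. **Segmentation.** Per-channel Otsu thresholding finds the colored strip
   labels (union of the R and B dark classes; for alcohol panels the merged
   conjunctions (G∧B) ∪ (G∧R)), followed by a morphological closing, a 10%
   column-occupancy filter, and contour filters by position (centroid must
   be in the upper half of the region) and relative area
   (A_i ≥ 0.5 · A_max). Survivors are matched left-to-right to the declared
   panel, and each label's size and bottom-middle point define the window
   for histogram extraction.
3. **Lateral histogram.** The mean intensity per position along the flow
   axis, x(i) = (1/n) Σ_j s(i, j), is resampled to 100 bins by quadratic
   interpolation, baseline-corrected by subtracting a RANSAC-fitted linear
   illumination model y = a·i + b, and aligned: the minimum of each half is
   found and ±15 bins around each are kept, giving a 62-bin profile with
   the control line centered in bins 1–31 and the test line in bins 32–62.
   Alcohol strips are resampled straight to 62 bins and normalized by
   subtracting the mean of the first 15 bins.
4. **Classification.** Three small all-tansig multilayer perceptrons with a
   reject option: per-bin z-scoring against the training mean/std, an
   affine map of the training range onto [−1, 1], the network
   (62-5-2 for alcohol, 31-1-2 for control lines, 31-7-7-5 for test lines,
   every neuron `tanh(Σ wᵢxᵢ + b)`), a reverse affine map onto the [0, 1]
   class-indicator scale, and a confidence threshold: the argmax class wins
   only if its score reaches the threshold (default 0.9), otherwise the
   answer is **undetermined**. The five test-line classes
   (very_positive … very_negative) collapse to positive / negative, with a
   configurable policy for the doubtful class.

Because no public image set exists for these cards, the package ships a
first-class synthetic generator (`lfareader.synthetic`) that renders test
cards — fiducial texture, colored labels, lines of controlled darkness,
blue alcohol pads, illumination ramps, sensor noise, pose perturbations —
and labeled histogram datasets with the class structure the classifiers
assume. All generators are pure functions of their seed.

## Worked example

```python
from lfareader import (generate_template_image, build_template,
                       generate_card_image, generate_histogram_dataset,
                       read_test)
from lfareader.mlp import train
from lfareader.pipeline import PanelConfig, ReaderModels
from lfareader.synthetic import CardSpec

panel = ("AMP", "KET", "COC", "MET")
image, quad = generate_template_image(panel)
template = build_template(image, quad)

models = ReaderModels(
    control=train(generate_histogram_dataset("control", 2358, seed=12),
                  "control", seed=1)[0],
    testline=train(generate_histogram_dataset("testline", 1955, seed=13),
                   "testline", seed=1)[0],
)

spec = CardSpec(panel=panel,
                control_intensities=(0.8, 0.8, 0.0, 0.8),
                test_classes=("very_negative", "very_positive",
                              "very_negative", "very_negative"),
                pose=(6.0, -4.0, 3.0), seed=42)
card, truth = generate_card_image(spec)
result = read_test(card, template, PanelConfig(panel), models, seed=0)
for strip in result.strips:
    print(f"{strip.strip_id}: {strip.final_result:9s} "
          f"(control={strip.control_status}, test_line={strip.testline_class})")
```

prints

```
AMP: negative  (control=valid, test_line=very_negative)
KET: positive  (control=valid, test_line=very_positive)
COC: invalid   (control=invalid, test_line=very_negative)
MET: negative  (control=valid, test_line=very_negative)
```

AMP carries a dark test line (drug below cutoff → negative); KET has no
test line (drug above cutoff → positive); COC has no control line, so the
strip is invalid regardless of its test region.

The same flow is available from the shell:

```sh
lfa template --panel AMP,KET,COC,MET --out tmpl/
lfa simulate histos --kind control --n 2358 --seed 12 --out control.csv
lfa train --kind control --data control.csv --seed 1 --out models/control.json
lfa simulate card --panel AMP,KET,COC,MET --seed 7 --out cards/
lfa read --image cards/card_00007.png --template tmpl/template.json \
    --panel AMP,KET,COC,MET --models models/ --out result.json
```

Exit codes: 0 ok, 2 registration failure, 3 segmentation mismatch.

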