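# foodpix

Desk-scale tooling for automated dietary assessment from buffet photographs
of replica ("fake") foods: pixel-level label-mask handling with dataset
splitting and training-set augmentation, semantic-segmentation evaluation,
and a food-name standardization chain (StandFood) that links recognized
food classes to FoodEx2-style catalogue codes and on to a food composition
database (FCDB).

## Who this is for

Food-choice researchers run fake-food-buffet (FFB) experiments: participants
serve meals from replica foods, a photograph is taken, and each food is
identified and matched to nutrient data. `foodpix` implements the data
plumbing and measurement half of automating that workflow — everything
around a pixel-level segmentation model, plus the name-matching chain that
turns a recognized food class into nutrient amounts. It does not train a
segmentation network; predictions from any model can be evaluated and
piped through via external masks, and a nearest-palette-colour baseline
segmenter lets the whole pipeline run end to end on synthetic scenes.

## The measures

A prediction is compared with ground truth through the confusion matrix
*n*, where *n*<sub>ij</sub> counts pixels of true class *i* predicted as
class *j*, and *t*<sub>i</sub> = Σ<sub>j</sub> *n*<sub>ij</sub>. With
*n*<sub>cl</sub> classes (background included):

* pixel accuracy: Σ<sub>i</sub> *n*<sub>ii</sub> / Σ<sub>i</sub> *t*<sub>i</sub>
* mean accuracy: (1/*n*<sub>cl</sub>′) Σ<sub>i</sub> *n*<sub>ii</sub> / *t*<sub>i</sub>
* mean IU: (1/*n*<sub>cl</sub>′) Σ<sub>i</sub> *n*<sub>ii</sub> / (*t*<sub>i</sub> + Σ<sub>j</sub> *n*<sub>ji</sub> − *n*<sub>ii</sub>)
* frequency-weighted IU: (Σ<sub>k</sub> *t*<sub>k</sub>)<sup>−1</sup> Σ<sub>i</sub> *t*<sub>i</sub> *n*<sub>ii</sub> / (*t*<sub>i</sub> + Σ<sub>j</sub> *n*<sub>ji</sub> − *n*<sub>ii</sub>)

where *n*<sub>cl</sub>′ counts classes actually present (see
`docs/methods.md` for the empty-class convention). Evaluation over an image
set pools one global confusion matrix.

## The matching chain

StandFood standardizes a food name in three parts: (1) a rule-based
classifier assigns one of the four FoodEx2 food categories (raw,
derivative, simple composite, aggregated composite); (2) the description
part lowercases the name, extracts noun/adjective/verb lemmas by POS
tagging, retrieves catalogue entries sharing a noun lemma and ranks them by
a POS-weighted Jaccard similarity — and when no nouns can be extracted (or
nothing shares one) falls back to Levenshtein distance over whole names;
(3) post-processing lets a strong match's catalogue category override the
classifier. The best match's code keys the FCDB lookup.

## Worked example

```
$ python examples/03_match_food_names.py
query 'pasta'
  best match : 'dried pasta' (code A03DP, noun-index)
  category   : derivative (post-processed)
  top ranked : 'dried pasta' w=0.60, 'fresh pasta' w=0.60, 'pasta salad with tuna and egg' w=0.25
query 'herring'
  best match : 'herrings' (code A02HE, levenshtein)
  category   : raw
  top ranked : 'herrings' w=0.50, 'carrot' w=0.17, 'pear' w=0.17
```

"pasta" is deliberately ambiguous: both pasta entries tie at weight 0.60,
so the chain surfaces both — fresh and dried pasta have different nutrient
profiles and the choice matters for the assessment. "herring" produces no
recognized noun, so the chain switches to edit distance and lands on
"herrings" (one edit away). Similarly:

```
$ python examples/01_split_and_augment.py
split of 121 pairs: training=85 validation=12 testing=24
augmented dataset size: 631
```

A 121-image collection splits 70/10/20 into (85, 12, 24); augmenting each
training pair into seven variants (original, three rotations, horizontal
flip, colour noise, centre zoom) gives 85·7 + 12 + 24 = 631 images.

The other examples evaluate a perturbed mask with the four measures and run
a synthetic scene end to end (segment → standardize → nutrient lookup).
There is also a thin CLI (`foodpix simulate|augment|eval-seg|match|
standardize-names|pipeline|experiment`) over the same functions.

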