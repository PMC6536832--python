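# Methods

This note documents the models, conventions and design decisions behind
`foodpix`: what each stage computes, which parameters matter, what the
synthetic fixtures emulate, and what the tests do and do not demonstrate
about real buffet imagery.

## Data model

Images are 8-bit RGB arrays; ground-truth labels are single-channel masks
of the same width and height holding one class index per pixel, with index
0 reserved for the background. A class registry fixes the ordered mapping
index ↔ food-class name ↔ palette colour (the reference configuration is 56
classes: 55 foods plus background); indices are contiguous, names and
colours unique. Masks are stored as 8-bit single-channel PNGs carrying raw
class indices rather than palette colours: the round trip is bit-exact and
validation against the registry is a range check. Coordinates are
row-major, origin top-left, 0-based.

A "food item" is a 4-connected component of a single non-background class.
4-connectivity is a fixed convention chosen conservatively — diagonal
contact does not merge items — so item counts are deterministic.

## Dataset split

`split_dataset` assigns each image/mask pair to training, validation or
testing with proportions 70 / 10 / 20 and round-half-up counting:
validation = ⌊0.10·N + 0.5⌋, testing = ⌊0.20·N + 0.5⌋, training = the
remainder. For N = 121 this yields (85, 12, 24) — the only triple whose
sevenfold training augmentation gives 85·7 + 12 + 24 = 631. The rule is
applied verbatim even at tiny N (N = 3 gives (2, 0, 1)); only N < 3 is an
error. Assignment is a simple random permutation driven by the seed, with
no stratification by food content.

## Augmentation

Training pairs are expanded into seven variants: the original, rotations by
90°/180°/270°, a horizontal flip, a colour-noise variant and a centre zoom.
Validation and testing pairs are never augmented. Conventions:

* Geometric transforms apply identically to image and mask, so the label
  multiset is preserved exactly and evaluation commutes with them.
* **Noise** (default σ = 10 intensity units) is seeded additive Gaussian
  per pixel and channel, clipped to [0, 255], applied to the image only —
  ground truth does not change in the presence of noise. The Gaussian form
  and magnitude are this package's choices; σ is configurable.
* **Zoom** removes 25 % of each dimension in total (12.5 % per side): the
  retained window spans ⌊(1 − f)·dim⌋ pixels, centred with any odd pixel on
  the trailing side, then is resized back to the original resolution —
  bilinear for the image, nearest-neighbour for the mask so labels stay
  categorical. Food items lying wholly in the removed border disappear.
  Both the border fraction and the resize-back behaviour are explicit,
  configurable conventions.

## Segmentation measures

The confusion matrix pools pixels: entry (i, j) counts pixels of true
class i predicted as j; t_i are row sums. The four measures (pixel
accuracy, mean accuracy, mean IU, frequency-weighted IU) follow the
standard formulas over all classes including the background. Empty-class
convention: a class absent from both truth and prediction is excluded from
the unweighted means; a class predicted but absent from truth contributes
IU 0 to mean IU. This is the convention that never divides by zero.
Evaluation over an image set pools one global matrix (the elementwise sum
of per-image matrices) rather than averaging per-image scores, matching a
"total pixels" reading of the measures; with class distributions varying
strongly between images the two conventions differ.

## The matching chain

**Profiling.** A name is lowercased, tokenized on non-letters, and each
token tagged noun / adjective / verb and lemmatized. The bundled tagger is
deterministic and lexicon-driven (editable word sets in
`foodpix/lexicon.py`), behind a pluggable-tagger contract; precedence is
noun > adjective > verb, one tag per token, and unknown tokens carry no
tag. The lexicon deliberately omits some food-domain words ("dressing",
"herring") from the noun set: statistical taggers fail on exactly such
terms, and the chain must exercise its fallback path for them. The
lemmatizer applies standard English suffix rules plus a small
irregular-form table.

**Description.** Candidate retrieval returns the catalogue entries whose
name shares at least one noun lemma with the query; with no query nouns
the index cannot be searched. Candidates are scored with a POS-weighted
Jaccard over lemma sets, weight = (3|N∩| + 2|A∩| + |V∩|) / (3|N∪| + 2|A∪| +
|V∪|): symmetric, bounded in [0, 1], equal to 1 exactly for identical
non-trivial profiles, with nouns weighted heaviest. The coefficients
(3, 2, 1) are configurable defaults expressing noun primacy. Ties break by
smaller Levenshtein distance between normalized names, then by entry code,
making the ranking total and the chain reproducible. When retrieval is
impossible or empty, the chain ranks the whole catalogue by ascending
Levenshtein distance on normalized names (unit costs, case-insensitive)
and reports fallback weights as 1/(1 + d) so ranked weights remain
non-increasing. The edit-distance routine is the classic two-row dynamic
program; tests verify it against a brute-force recursion and an
independent alignment library, plus the metric axioms.

**Classification.** The category classifier is a transparent rule set, not
a learned model: (1) a recipe-term hit (salad, soup, sandwich, pizza) or
≥ 2 food nouns joined by a connector marks a composite — aggregated when a
recipe term or ≥ 3 food nouns are present, simple otherwise; (2) else any
process-term hit (dried, fried, smoked, juice, sauce, dressing, …) marks a
derivative; (3) else raw. The lexicons are editable configuration. No
claim is made that this rule set matches the accuracy of a trained
classifier on real catalogue data.

**Post-processing.** When the matched entry's catalogue category differs
from the classifier's and the match is strong — noun-index weight ≥ 0.5,
or a Levenshtein match within 2 edits — the match's category wins and the
result is flagged as post-processed. Both thresholds are configurable; the
precedence rule (strong match beats classifier, otherwise classifier
stands) is this package's decision.

## Synthetic fixtures

The generator emulates buffet photographs structurally, not visually:
500×375 frames containing 5–15 layered coloured regions (discs, rectangles,
blobs) — buffet photos average over eleven foods — each painted with its
class's palette colour plus mild per-pixel texture (σ = 3 by default).
Palette colours sit on the 4×4×4 RGB grid, so any two differ by ≥ 85 in
some channel; texture and even σ = 10 colour noise therefore almost never
move a pixel across a nearest-colour boundary. That separation makes the
nearest-palette-colour baseline segmenter exact on noiseless scenes, which
turns the imaging half into an end-to-end identity test. None of this
models real food imagery: no occlusion statistics, no illumination or
texture realism, no class-confusable colours. Passing tests demonstrate
the correctness of the measurement and matching machinery, not
segmentation difficulty.

`perturb_mask` relabels each pixel independently with probability p to a
uniformly chosen *different* class, so expected pixel accuracy against the
original is exactly 1 − p and measured accuracy concentrates within
binomial error — the oracle for the recovery tests.

The toy catalogue (25 entries, all four categories, FoodEx2-style codes)
contains the names the canonical matching walk-throughs need ("salad
dressing", "herrings", "fresh pasta", "dried pasta") plus plain raw foods;
the toy FCDB has one deterministic nutrient row per code, so every
standardized scene class links. Scene class names reuse buffet vocabulary;
names missing from the toy catalogue resolve to their nearest entry, which
is the intended semi-automatic behaviour (the ranked alternates exist for
a human to confirm).

## Problem sizes and determinism

Tests run on small frames (60×45 to 200×150) except where the reference
resolution matters (crop-window arithmetic and perturbation recovery use
500×375); the acceptance script uses 500×375 scenes and an 8-image
end-to-end experiment. Every stochastic component takes an explicit seed
(numpy `default_rng`); per-pair and per-image seeds are derived by affine
hashing from the top-level seed, keeping all derived seeds below 2^31.
Identical configurations produce byte-identical experiment reports.

## Known limitations

* The bundled tagger's lexicons cover buffet vocabulary, not general
  English; unknown food names fall back to edit distance, which favours
  short catalogue names for short queries.
* The rule-based category classifier encodes coarse heuristics; names like
  "apple juice" can be pulled to a strong raw-food match by
  post-processing.
* The four measures are the only evaluation; no boundary-quality metrics.
* No segmentation model is trained here; the baseline segmenter is a
  fixture-scale stand-in and external predictions enter as mask PNGs.
* English names only; the FoodEx2 facet system beyond the four coarse
  categories is out of scope.
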