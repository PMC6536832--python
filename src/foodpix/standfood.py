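"""The StandFood food-name standardization chain.

StandFood assigns a FoodEx2 code and food category to a free-text food name
in three parts:

1. **Classification** — a transparent rule set places the name in one of
   the four FoodEx2 categories (raw, derivative, simple composite,
   aggregated composite) from its food nouns, process terms and recipe
   terms.
2. **Description** — the name is profiled (lowercase, POS tags, lemmas) and
   the catalogue searched for entries sharing at least one noun lemma; each
   candidate is scored with a POS-weighted Jaccard similarity and the
   highest-weight pair returned with its catalogue category. When no nouns
   can be extracted, or no entry shares a noun, the chain falls back to
   ranking the whole catalogue by Levenshtein distance between normalized
   names (the extension handling names the tagger cannot describe).
3. **Post-processing** — when the matched entry's catalogue category
   disagrees with the classifier and the match is strong (weight or edit
   distance within threshold), the match's category overrides the
   classifier's.

The candidate weighting is a POS-weighted Jaccard over lemma sets,

    w = (3 |N_q ∩ N_c| + 2 |A_q ∩ A_c| + |V_q ∩ V_c|)
        / (3 |N_q ∪ N_c| + 2 |A_q ∪ A_c| + |V_q ∪ V_c|),

with nouns weighted heaviest — symmetric, bounded in [0, 1], and equal to 1
exactly when all three lemma sets coincide (non-trivially). The
coefficients are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from foodpix import lexicon
from foodpix.catalogue import Catalogue, CatalogueEntry
from foodpix.textproc import (
    DEFAULT_TAGGER,
    RuleBasedTagger,
    Tagger,
    TextProfile,
    levenshtein,
    profile,
    tokenize,
    noun_lemma,
)

__all__ = [
    "TextProfile",
    "DescriptionResult",
    "StandardizedFood",
    "MatchConfig",
    "profile",
    "retrieve_candidates",
    "score_pair",
    "levenshtein",
    "describe",
    "classify",
    "post_process",
    "standardize",
]


@dataclass(frozen=True)
class MatchConfig:
    """Tunable knobs of the matching chain.

    noun/adjective/verb weights are the POS-Jaccard coefficients;
    weight_threshold and distance_threshold gate the post-processing
    override (a noun-index match must score at least weight_threshold, a
    Levenshtein match must lie within distance_threshold edits).
    """

    noun_weight: float = 3.0
    adjective_weight: float = 2.0
    verb_weight: float = 1.0
    weight_threshold: float = 0.5
    distance_threshold: int = 2


DEFAULT_CONFIG = MatchConfig()


@dataclass(frozen=True)
class DescriptionResult:
    """Outcome of the description part for one query name.

    ``ranked`` lists (entry code, weight) best-first; ``best`` is its head
    or None for an unmatchable query. ``method`` records whether the match
    came through the noun index or the Levenshtein fallback; ``distance``
    is the edit distance of the best match when the fallback was used.
    """

    best: tuple[str, float] | None
    ranked: tuple[tuple[str, float], ...]
    method: str  # "noun-index" | "levenshtein"
    category: str | None
    distance: int | None = None


@dataclass(frozen=True)
class StandardizedFood:
    """A food name resolved to a FoodEx2 code with full provenance."""

    query: str
    code: str
    final_category: str
    classifier_category: str
    description: DescriptionResult
    post_processed: bool


def retrieve_candidates(query: TextProfile, catalogue: Catalogue) -> list[str]:
    """Codes of entries sharing at least one noun lemma with the query.

    Empty when the query has no nouns — the search cannot continue through
    the index and the caller falls back to edit distance. Order follows the
    catalogue for determinism.
    """
    if not query.nouns:
        return []
    hit: set[str] = set()
    for lemma in query.nouns:
        hit |= catalogue.lookup_noun(lemma)
    return [e.code for e in catalogue.entries if e.code in hit]


def score_pair(
    query: TextProfile,
    candidate: TextProfile,
    config: MatchConfig = DEFAULT_CONFIG,
) -> float:
    """POS-weighted Jaccard similarity between two profiles, in [0, 1]."""
    num = (
        config.noun_weight * len(query.nouns & candidate.nouns)
        + config.adjective_weight * len(query.adjectives & candidate.adjectives)
        + config.verb_weight * len(query.verbs & candidate.verbs)
    )
    den = (
        config.noun_weight * len(query.nouns | candidate.nouns)
        + config.adjective_weight * len(query.adjectives | candidate.adjectives)
        + config.verb_weight * len(query.verbs | candidate.verbs)
    )
    if den == 0:
        return 0.0
    return num / den


def describe(
    name: str,
    catalogue: Catalogue,
    tagger: Tagger = DEFAULT_TAGGER,
    config: MatchConfig = DEFAULT_CONFIG,
) -> DescriptionResult:
    """Description part: find the most relevant catalogue entry for a name.

    Noun-index retrieval and POS-weighted scoring when possible; otherwise
    the Levenshtein fallback over the whole catalogue. Ties in weight break
    by smaller edit distance between normalized names, then by entry code,
    so the ranking is total and reproducible. Fallback weights are reported
    as 1 / (1 + distance) so ranked weights stay non-increasing in [0, 1].
    """
    if len(catalogue) == 0:
        raise ValueError("cannot describe against an empty catalogue")
    query = profile(name, tagger)
    candidates = retrieve_candidates(query, catalogue)

    if candidates:
        scored = []
        for code in candidates:
            entry = catalogue[code]
            w = score_pair(query, entry.profile, config)
            d = levenshtein(query.normalized, entry.profile.normalized)
            scored.append((-w, d, code))
        scored.sort()
        ranked = tuple((code, -negw) for negw, _, code in scored)
        best = ranked[0]
        return DescriptionResult(
            best=best,
            ranked=ranked,
            method="noun-index",
            category=catalogue[best[0]].category,
        )

    # Fallback: no nouns extracted, or no entry shares one — rank the whole
    # catalogue by edit distance on normalized names.
    scored_lev = []
    for entry in catalogue.entries:
        d = levenshtein(query.normalized, entry.profile.normalized)
        scored_lev.append((d, entry.code))
    scored_lev.sort()
    ranked = tuple((code, 1.0 / (1.0 + d)) for d, code in scored_lev)
    best_d, best_code = scored_lev[0]
    return DescriptionResult(
        best=ranked[0],
        ranked=ranked,
        method="levenshtein",
        category=catalogue[best_code].category,
        distance=best_d,
    )


def classify(
    name: str,
    tagger: Tagger = DEFAULT_TAGGER,
    food_nouns: frozenset[str] = lexicon.FOOD_NOUNS,
    process_terms: frozenset[str] = lexicon.PROCESS_TERMS,
    recipe_terms: frozenset[str] = lexicon.RECIPE_TERMS,
    connectors: frozenset[str] = lexicon.CONNECTORS,
) -> str:
    """Classification part: assign one of the four FoodEx2 food categories.

    Transparent rule set over the name's tokens:

    1. a recipe-term hit, or >= 2 food nouns joined by a connector ("with",
       "and", or a comma in the raw name), marks a composite dish —
       aggregated when a recipe term is present or >= 3 food nouns are
       named, simple otherwise;
    2. else any process-term hit marks a derivative;
    3. else the food is raw.
    """
    if not name or not name.strip():
        raise ValueError("food name must be non-empty")
    tokens = tokenize(name)
    lemmas = [noun_lemma(t) for t in tokens]
    n_food = len({l for l in lemmas if l in food_nouns})
    has_recipe = any(l in recipe_terms for l in lemmas)
    has_connector = any(t in connectors for t in tokens) or ("," in name)
    if has_recipe or (n_food >= 2 and has_connector):
        if has_recipe or n_food >= 3:
            return "aggregated composite"
        return "simple composite"
    if any(t in process_terms for t in tokens):
        return "derivative"
    return "raw"


def post_process(
    classifier_category: str,
    description: DescriptionResult,
    config: MatchConfig = DEFAULT_CONFIG,
) -> tuple[str, bool]:
    """Post-processing part: reconcile classifier and match categories.

    A strong match — noun-index weight >= weight_threshold, or a Levenshtein
    match within distance_threshold edits — overrides the classifier when
    the two categories disagree; the returned flag records the override.
    """
    if description.best is None or description.category is None:
        return classifier_category, False
    if description.category == classifier_category:
        return classifier_category, False
    _, weight = description.best
    if description.method == "noun-index":
        strong = weight >= config.weight_threshold
    else:
        strong = (
            description.distance is not None
            and description.distance <= config.distance_threshold
        )
    if strong:
        return description.category, True
    return classifier_category, False


def standardize(
    name: str,
    catalogue: Catalogue,
    tagger: Tagger = DEFAULT_TAGGER,
    config: MatchConfig = DEFAULT_CONFIG,
) -> StandardizedFood:
    """Full chain: profile -> classify -> describe -> post-process.

    Returns the best-matching entry's FoodEx2 code, the final food category
    after post-processing, and full provenance (ranked alternates, matching
    method, classifier verdict).
    """
    classifier_category = classify(name, tagger)
    description = describe(name, catalogue, tagger, config)
    final_category, flagged = post_process(classifier_category, description, config)
    assert description.best is not None  # non-empty catalogue guarantees a match
    return StandardizedFood(
        query=name,
        code=description.best[0],
        final_category=final_category,
        classifier_category=classifier_category,
        description=description,
        post_processed=flagged,
    )
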