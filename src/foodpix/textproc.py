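"""Food-name text processing: normalization, POS tagging, lemmas, edit distance.

A food name is profiled by lowercasing it, tokenizing on non-letters,
tagging each token as noun / adjective / verb and lemmatizing the result.
Tagging is rule-based and lexicon-driven (see :mod:`foodpix.lexicon`): one
tag per token with precedence noun > adjective > verb, and tokens the
lexicon does not know carry no tag. Names whose tokens yield no noun at all
cannot enter index-based candidate retrieval and must be matched by
Levenshtein distance instead — the same failure mode statistical taggers
exhibit on domain terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

from foodpix import lexicon

_IRREGULAR_PLURALS = {
    "children": "child",
    "leaves": "leaf",
    "loaves": "loaf",
    "halves": "half",
}

_IRREGULAR_VERBS = {
    "dried": "dry",
    "fried": "fry",
    "baked": "bake",
    "served": "serve",
    "smoked": "smoke",
    "mixed": "mix",
}


def tokenize(text: str) -> list[str]:
    """Lowercase and split on any non-alphabetic character."""
    out: list[str] = []
    word: list[str] = []
    for ch in text.lower():
        if ch.isalpha():
            word.append(ch)
        elif word:
            out.append("".join(word))
            word = []
    if word:
        out.append("".join(word))
    return out


def noun_lemma(token: str) -> str:
    """Singularize a noun token with standard English suffix rules."""
    if token in _IRREGULAR_PLURALS:
        return _IRREGULAR_PLURALS[token]
    if len(token) > 3 and token.endswith("ies"):
        return token[:-3] + "y"
    if len(token) > 3 and token.endswith("oes"):
        return token[:-2]
    if len(token) > 3 and token.endswith(("ches", "shes", "sses", "xes")):
        return token[:-2]
    if len(token) > 2 and token.endswith("s") and not token.endswith(("ss", "us", "is")):
        return token[:-1]
    return token


def verb_lemma(token: str) -> str:
    """Reduce a participle/inflected verb token to its base form."""
    if token in _IRREGULAR_VERBS:
        return _IRREGULAR_VERBS[token]
    if len(token) > 4 and token.endswith("ing"):
        return token[:-3]
    if len(token) > 3 and token.endswith("ed"):
        return token[:-2]
    return token


@dataclass(frozen=True)
class TextProfile:
    """Lowercased food name with POS-tagged, lemmatized word sets."""

    original: str
    normalized: str
    nouns: frozenset[str]
    adjectives: frozenset[str]
    verbs: frozenset[str]


class Tagger(Protocol):
    """Contract for pluggable POS taggers: text in, tagged lemma sets out."""

    def tag(self, tokens: list[str]) -> tuple[set[str], set[str], set[str]]:
        """Return (noun lemmas, adjective lemmas, verb lemmas)."""
        ...


@dataclass(frozen=True)
class RuleBasedTagger:
    """Deterministic lexicon-driven tagger; the bundled default.

    Each token receives at most one tag, with precedence noun > adjective >
    verb; unknown tokens receive none. The lexicons are constructor
    parameters so callers can extend coverage without code changes.
    """

    nouns: frozenset[str] = lexicon.FOOD_NOUNS
    adjectives: frozenset[str] = lexicon.ADJECTIVES
    verbs: frozenset[str] = lexicon.VERBS

    def tag(self, tokens: list[str]) -> tuple[set[str], set[str], set[str]]:
        n: set[str] = set()
        a: set[str] = set()
        v: set[str] = set()
        for tok in tokens:
            nl = noun_lemma(tok)
            if nl in self.nouns:
                n.add(nl)
            elif tok in self.adjectives:
                a.add(tok)
            elif verb_lemma(tok) in self.verbs:
                v.add(verb_lemma(tok))
        return n, a, v


DEFAULT_TAGGER = RuleBasedTagger()


def profile(name: str, tagger: Tagger = DEFAULT_TAGGER) -> TextProfile:
    """Build the text profile of a food name.

    Raises ValueError on empty or whitespace-only input. The lemma sets may
    all be empty when the tagger recognizes none of the tokens.
    """
    if not name or not name.strip():
        raise ValueError("food name must be non-empty")
    normalized = name.lower()
    nouns, adjectives, verbs = tagger.tag(tokenize(name))
    return TextProfile(
        original=name,
        normalized=normalized,
        nouns=frozenset(nouns),
        adjectives=frozenset(adjectives),
        verbs=frozenset(verbs),
    )


def levenshtein(a: str, b: str) -> int:
    """Levenshtein edit distance with unit insert/delete/substitute costs.

    Classic dynamic program over two rows; O(len(a) * len(b)) time,
    O(min(len(a), len(b))) memory.
    """
    if len(a) < len(b):
        a, b = b, a
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        curr = [i] + [0] * len(b)
        for j, cb in enumerate(b, start=1):
            curr[j] = min(
                prev[j] + 1,  # delete
                curr[j - 1] + 1,  # insert
                prev[j - 1] + (ca != cb),  # substitute / match
            )
        prev = curr
    return prev[-1]
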