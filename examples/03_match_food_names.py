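"""Standardizing food names to FoodEx2-style codes with the matching chain.

Three queries exercise the three behaviours of the description part:
"pasta" retrieves both pasta entries through the noun index (the user picks
between nutritionally different foods); "herring" and "French dressing"
yield no recognized nouns, so the Levenshtein fallback finds the nearest
catalogue name. The final category combines the rule-based classifier with
the matched entry's catalogue category via the post-processing rules.
"""

from foodpix.standfood import standardize
from foodpix.synthetic import toy_catalogue

cat = toy_catalogue()
for query in ("pasta", "herring", "French dressing", "dried pasta"):
    food = standardize(query, cat)
    d = food.description
    print(f"query {query!r}")
    print(f"  best match : {cat[food.code].name!r} (code {food.code}, {d.method})")
    print(f"  category   : {food.final_category}"
          + (" (post-processed)" if food.post_processed else ""))
    alternates = [f"{cat[c].name!r} w={w:.2f}" for c, w in d.ranked[:3]]
    print(f"  top ranked : {', '.join(alternates)}")
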