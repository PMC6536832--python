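"""Editable word lists driving the rule-based food-name tagger and classifier.

The tagger is lexicon-driven: a token is extracted as a noun, adjective or
verb only if its lemma appears in the corresponding set below. Tokens whose
lemma appears in no set yield no part-of-speech information at all — this is
deliberate, because real statistical taggers also fail on some food terms
(food-domain words like "dressing" or "herring" are commonly mistagged or
dropped), and the matching chain must handle that case by falling back to
edit-distance search. Consequently those two lemmas are intentionally NOT
in the noun set.

All sets hold lowercase lemmas. They are module-level constants so callers
can pass extended copies to the tagger or classifier without monkeypatching.
"""

# Food nouns the tagger recognizes (lemma form).
FOOD_NOUNS = frozenset(
    {
        "apple",
        "banana",
        "bean",
        "beef",
        "bread",
        "broccoli",
        "butter",
        "carrot",
        "cheese",
        "chicken",
        "chip",
        "chocolate",
        "coffee",
        "cream",
        "croissant",
        "cucumber",
        "egg",
        "fish",
        "grape",
        "ham",
        "jam",
        "juice",
        "lettuce",
        "meat",
        "milk",
        "muesli",
        "mushroom",
        "onion",
        "orange",
        "pasta",
        "pea",
        "pear",
        "pepper",
        "pizza",
        "potato",
        "rice",
        "ring",
        "roll",
        "salad",
        "salmon",
        "sandwich",
        "sauce",
        "sausage",
        "soup",
        "strawberry",
        "tea",
        "toast",
        "tomato",
        "tuna",
        "water",
        "wine",
        "yogurt",
    }
)

# Descriptive adjectives seen in catalogue food names.
ADJECTIVES = frozenset(
    {
        "black",
        "brown",
        "dried",
        "fresh",
        "french",
        "fried",
        "green",
        "grilled",
        "hot",
        "italian",
        "mixed",
        "red",
        "roasted",
        "smoked",
        "sparkling",
        "sweet",
        "white",
        "whole",
        "wholegrain",
    }
)

# Verb lemmas (participles lemmatize to these).
VERBS = frozenset(
    {
        "bake",
        "boil",
        "cook",
        "dry",
        "fry",
        "grill",
        "mix",
        "roast",
        "serve",
        "smoke",
        "steam",
    }
)

# Processing terms: any hit marks a name as a derivative food.
PROCESS_TERMS = frozenset(
    {
        "baked",
        "boiled",
        "cooked",
        "dressing",
        "dried",
        "fried",
        "grilled",
        "juice",
        "roasted",
        "sauce",
        "smoked",
        "toast",
    }
)

# Recipe terms: any hit marks a name as a composite dish.
RECIPE_TERMS = frozenset({"pizza", "salad", "sandwich", "soup"})

# Connectors joining food nouns in composite names.
CONNECTORS = frozenset({"and", "with"})
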