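"""The certainty-of-evidence clauses on four contrasting point sets.

Each scenario lists (implied burden code, weight score) pairs for one
nutrient; the engine reports the certainty level and the clause that fired.
"""

from nutrigap import BurdenCode, RatedPoint, initial_certainty

scenarios = {
    "one excellent survey": [(2, 95)],
    "two strong but discordant": [(3, 60), (1, 55)],
    "three weak but concordant": [(1, 16), (1, 10), (1, 8)],
    "single mid-weight point": [(2, 30)],
}

for name, pairs in scenarios.items():
    pts = [
        RatedPoint(point_id=f"p{i}", code=BurdenCode(c), weight=float(w))
        for i, (c, w) in enumerate(pairs)
    ]
    r = initial_certainty(pts)
    print(f"{name:28s} -> {r.level.label:9s} ({r.triggered_clause})")
print()
print("Disagreements (differing burden codes) above the weight floors block")
print("the high and moderate clauses, so two strong conflicting surveys give")
print("only low certainty, while three concordant weak points reach moderate.")
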