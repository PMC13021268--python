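"""Score individual preference/experience pairs.

Each 4Ps item pairs a preference (1 'unimportant' .. 4 'crucial') with an
experience (1 'not at all' .. 4 'entirely').  The pair maps to a match
category, a signed gap, a rank on the six-graded preference-based
participation scale, and a three-level clinical label.
"""

import fourps as fp

scoring_map = fp.default_scoring_map()

pairs = [
    (4, 4),  # crucial, entirely: perfect match
    (4, 2),  # crucial, to some extent: less than preferred
    (1, 3),  # unimportant, to a large extent: more than preferred
    (2, 2),  # somewhat important, to some extent: perfect match
    (4, 1),  # crucial, not at all: worst mismatch
]

print(f"{'pref':>4} {'exp':>4} {'category':<20} {'gap':>4} {'rank':>4}  level")
for pref, exp in pairs:
    s = fp.score_item(pref, exp, scoring_map)
    print(f"{pref:>4} {exp:>4} {s.category:<20} {s.gap:>4} {s.rank:>4}  {s.level}")

print()
print("Rank 5 = experiences align with preferences; rank 0 = furthest apart.")
print("Levels collapse ranks for clinical dialogue: 0-1 insufficient,")
print("2-3 fair (mismatch to address), 4-5 sufficient (sustain).")
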