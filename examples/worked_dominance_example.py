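"""Survival functions and stochastic dominance on a three-outcome pair.

Lottery A pays 12, 14 or 96 with probabilities 0.05/0.05/0.90; lottery B
pays 12, 90 or 96 with probabilities 0.10/0.05/0.85.  A's survival function
is everywhere at least B's, so A first-order dominates B — every decision
maker who prefers more money should pick A.
"""

from choicebias import Lottery, dominance, p_better, survival

a = Lottery([12, 14, 96], [0.05, 0.05, 0.90])
b = Lottery([12, 90, 96], [0.10, 0.05, 0.85])

print("x      P(A >= x)  P(B >= x)")
for x in (12, 14, 90, 96):
    print(f"{x:<6} {survival(a, x):<10.2f} {survival(b, x):.2f}")

names = {1: "first", 2: "second", 3: "third"}
for order in (1, 2, 3):
    verdict = {1: "A dominates B", 0: "neither", -1: "B dominates A"}[dominance(a, b, order)]
    print(f"{names[order]}-order stochastic dominance: {verdict}")

print(f"EV(A) = {a.ev():.2f}, EV(B) = {b.ev():.2f}")
print(f"P(B pays more) - P(A pays more), independent draws: {p_better(a, b, 0):+.3f}")
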