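"""The three-gene decision-network example, fully deterministic.

Gene A activates gene C, gene B inhibits it; P(A=1)=0.7, P(B=1)=0.2.
Each candidate action clamps one gene and scores the (A, B) outcomes with
the example utility table. The action with the highest expected utility is
the recommended intervention for upregulating gene C.
"""

from wrkybn import run_worked_example

summary = run_worked_example(verbose=True)

# EU(A=1)=90 beats EU(B=0)=85: activating gene A is a better lever on gene C
# than inhibiting its repressor B, given how likely each background state is.
print(f"\nbest action: {summary['recommendation']} "
      f"(EU = {summary['best']['expected_utility']:g})")
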