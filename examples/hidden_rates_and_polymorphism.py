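"""State-space expansions: hidden rate categories and polymorphic conditions.

First prints the design matrices the expansions induce — the umbral
hidden-rates layout for a binary trait, and the ordered vs unordered
polymorphic spaces for three habitat levels — then fits a hidden-rates
model and its one-category special case to show the nesting.
"""

import numpy as np

import pcmkit

hrm = pcmkit.build_hrm_space(["O", "V"], ncat=2, umbral=True)
print("Umbral hidden-rates design (starred = inert category):")
print("states:", hrm.states)
print(hrm.design.matrix)

ordered = pcmkit.build_poly_space(["forest", "fringe", "open"], ordered=True,
                                  order=["forest", "fringe", "open"],
                                  model="ARD")
unordered = pcmkit.build_poly_space(["forest", "fringe", "open"], model="ARD")
print(f"\nOrdered polymorphic space: {len(ordered.states)} states,"
      f" {ordered.design.n_classes} free rates (contiguous runs only)")
print(f"Unordered polymorphic space: {len(unordered.states)} states,"
      f" {unordered.design.n_classes} free rates (all subsets)")

fx = pcmkit.make_fixture(pcmkit.FixtureSpec(n_tips=50, seed=5))
ard = pcmkit.fit_hrm(fx["tree"], fx["discrete"], ncat=1, prior="fitzjohn",
                     nstarts=3, seed=1)
um = pcmkit.fit_hrm(fx["tree"], fx["discrete"], ncat=2, umbral=True,
                    prior="fitzjohn", nstarts=6, seed=2)
print(f"\nARD (ncat=1)  logL = {ard.loglik:.4f}, df = {ard.df}")
print(f"umbral ncat=2 logL = {um.loglik:.4f}, df = {um.df}")
print("The expanded model can only improve the likelihood (nesting); AIC"
      " decides whether the hidden categories are worth their parameters:")
print(pcmkit.compare_models([ard, um], ["ARD", "umbral"]).to_frame().round(3))
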