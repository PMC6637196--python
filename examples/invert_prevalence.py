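"""Estimate a heterozygote advantage from an observed carrier prevalence.

For a variant lethal in homozygotes and at balancing equilibrium, the carrier
fraction 2Q = 2s(1+s)/(1+2s)^2 can be inverted for s without any knowledge of
the variant's mechanism. Instantaneous.
"""

from gridpop import approx_carrier_fraction, fisher_equilibrium, solve_s_for_carrier

print(f"{'observed carriers':>18} {'estimated s':>12} {'check 2Q(s)':>12} {'approx 2s/(1+4s)':>17}")
for carriers in (0.01, 0.04, 0.10, 0.25):
    s = solve_s_for_carrier(carriers)
    back = fisher_equilibrium(s, -1.0).carrier_fraction
    print(f"{carriers:18.3f} {s:12.5f} {back:12.5f} {approx_carrier_fraction(s):17.5f}")

print(
    "\nA 4% carrier frequency (CFTR in Europeans) implies s ~ 2.13% under"
    "\npanmictic mating; with mating restricted to Dunbar-sized communities"
    "\nthe simulator shows the same prevalence requires s ~ 3% (see the"
    "\ncommunity-size sweep example)."
)
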