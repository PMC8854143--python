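"""Rescale the adult reference-diet targets to a child age group.

The reference diet states mass targets for a 2500 kcal adult diet; child
targets are obtained by multiplying by the age group's mean energy intake
over 2500 kcal and rounding to the printed precision.
"""

from dietgap import scale_targets

for label, energy in (("3-4 y", 1311.0), ("5-6 y", 1449.0)):
    scaled = scale_targets(energy, age_group=label)
    print(f"\n{label} (mean energy {energy:.0f} kcal/day):")
    print(scaled.to_frame().to_string(index=False))

# Each row is one food group: the single target in g/day, its range where
# one is defined, and whether the target is a floor (minimum) or a cap
# (maximum).  At 1311 kcal the whole-grain target is 122 g/day, dairy is
# capped at 131 g/day of milk equivalents.
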