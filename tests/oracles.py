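"""Independent oracles used by the tests.

The half-reaction balancer here never calls the package's oxidation-state
machinery: it completes `From -> b To + w H2O + h H+ + e e-` by exact
element/charge closure and reads off the electron count, giving an
independent route to the electron equivalents.
"""

from fractions import Fraction


def half_reaction_electrons(from_name, to_name, element, registry) -> Fraction:
    """Electrons per mole of ``from_name`` released onto the product side.

    Solves, with exact rationals, the closure of

        From -> b To + w H2O + h H+ + e e-

    where b matches the redox-element atoms, w closes oxygen, h closes
    hydrogen and e closes charge.  Positive e means electrons are released
    (oxidation); negative means the transformation consumes electrons.
    """
    sp_f, sp_t = registry[from_name], registry[to_name]
    b = Fraction(sp_f.elements[element], sp_t.elements[element])

    def count(sp, el):
        return Fraction(sp.elements.get(el, 0))

    w = count(sp_f, "O") - b * count(sp_t, "O")
    h = count(sp_f, "H") - b * count(sp_t, "H") - 2 * w
    e = b * sp_t.charge + h - sp_f.charge
    return e
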