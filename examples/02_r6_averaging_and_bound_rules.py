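"""NOE bound-modification rules and r⁻⁶ ensemble averaging.

The NOE signal scales as r⁻⁶, so an ensemble's effective distance is the
inverse sixth root of the mean r⁻⁶ — dominated by the closest conformers.
Bounds are preprocessed with two rules: aliphatic hydrogens are remapped to
their bonded carbon (+1 Å per endpoint), and every bound is padded by 1 Å
for the NOE signal's standard deviation.
"""

import numpy as np

from czbkit import (
    AtomRecord,
    DecoySpec,
    Ensemble,
    NOERestraint,
    Structure,
    derive_true_restraints,
    ensemble_effective_distance,
    make_decoy_ensemble,
    make_toy_complex,
    mean_ensemble_violation,
    pad_restraints,
    remap_aliphatic,
)


def pair(r):
    return Structure(
        [
            AtomRecord("A", 1, "GLY", "CA", "C", (0, 0, 0)),
            AtomRecord("C", 1, "GLY", "CA", "C", (r, 0, 0)),
        ]
    )


# r⁻⁶ averaging: two conformers at 4 and 8 Å look like 4.478 Å, not 6 Å
ens = Ensemble([pair(4.0), pair(8.0)])
restraint = NOERestraint(("A", 1, "CA"), ("C", 1, "CA"), 6.0)
print("effective distance of r = {4, 8}:",
      round(ensemble_effective_distance(ens, restraint), 3),
      "Å  (arithmetic mean would be 6.0)")

# aliphatic remap: a methyl proton restraint moves to its carbon, +1 Å
topo = Structure(
    [
        AtomRecord("C", 70, "LEU", "CD1", "C", (0, 0, 0)),
        AtomRecord("C", 70, "LEU", "HD11", "H", (0.5, 0.5, 0)),
        AtomRecord("B", 40, "TYR", "CZ", "C", (4, 0, 0)),
    ]
)
r = NOERestraint(("C", 70, "HD11"), ("B", 40, "CZ"), 4.0)
rr = remap_aliphatic(r, topo)
print(f"remap: {r.atom_a[2]}–{r.atom_b[2]} {r.upper_bound} Å  ->  "
      f"{rr.atom_a[2]}–{rr.atom_b[2]} {rr.upper_bound} Å")

# padding lowers ensemble violations, never raises them
toy = make_toy_complex()
rset = derive_true_restraints(toy)
decoys, _ = make_decoy_ensemble(
    toy, DecoySpec(sigma_levels=(1.8,), members_per_level=10, seed=1)
)
v0 = mean_ensemble_violation(decoys, rset, "interface")
v1 = mean_ensemble_violation(decoys, pad_restraints(rset, 1.0), "interface")
print(f"decoy ensemble interface violation: {v0:.3f} Å original bounds, "
      f"{v1:.3f} Å after +1 Å padding")
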