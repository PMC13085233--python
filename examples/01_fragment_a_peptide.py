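"""Fragment a small peptide with an ionic cofactor.

Builds a three-residue peptide plus a Zn2+ ion near the first residue's
carbonyl, applies the residue fragmentation protocol (Calpha-C(O) cuts,
hydrogen caps, 2.5 A ion merging), and prints the resulting scheme.
"""

import numpy as np

from mbescreen import AtomRecord, emit_subsystem_geometry, fragment_structure
from mbescreen.graph import SubsystemKey


def tripeptide_with_ion():
    atoms, serial = [], 1
    for i, resname in enumerate(["ALA", "GLY", "GLU"]):
        off = np.array([3.8 * i, 0.0, 0.0])
        for name, element, pos in [
            ("N", "N", (0.0, 0.0, 0.0)),
            ("CA", "C", (1.46, 0.0, 0.0)),
            ("C", "C", (2.46, 1.06, 0.0)),
            ("O", "O", (2.46, 2.26, 0.0)),
        ]:
            atoms.append(AtomRecord(serial=serial, name=name, element=element,
                                    position=np.array(pos) + off, residue_name=resname,
                                    residue_index=i + 1, chain_id="A"))
            serial += 1
    # Zn2+ 2.3 A above the first carbonyl oxygen: inside the merge cutoff
    atoms.append(AtomRecord(serial=serial, name="ZN", element="Zn",
                            position=np.array([2.46, 4.56, 0.0]), residue_name="ZN",
                            residue_index=99, chain_id="A", is_ion=True))
    return atoms


scheme = fragment_structure(tripeptide_with_ion())

print(f"{scheme.N} fragments, total charge {scheme.total_charge:+d} e")
for frag in scheme.fragments:
    print(
        f"  fragment {frag.id}: {frag.role:9s} charge {frag.formal_charge:+d}  "
        f"{len(frag.member_atoms)} atoms, {len(frag.cap_atoms)} cap(s)  [{frag.label}]"
    )

dimer = emit_subsystem_geometry(scheme, SubsystemKey((0, 1)))
print(f"adjacent dimer (0,1): {dimer.n_atoms} atoms, {int(dimer.is_cap.sum())} caps "
      "(the interior cut's caps are dropped and the real bond restored)")

# Each backbone cut produces exactly two hydrogen caps; the ion was merged
# into the residue it coordinates (making an ion_group with its charge),
# and the glutamate residue carries its template charge of -1.
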