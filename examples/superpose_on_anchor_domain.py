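"""Anchored superposition isolates conformational shifts.

Two models that share a rigid core but differ in a mobile region are
compared by superposing on the core only (Kabsch, reflections excluded):
the anchor RMSD reports how well the cores agree, and the per-residue
displacement profile after the transform localizes the moving parts.
Here the second model is the first with its C-terminal half rotated 35°
about a hinge, so the split is known exactly.
"""

import numpy as np
from scipy.spatial.transform import Rotation

from xlstruct import SyntheticSpec, make_structure, superpose_on_anchor
from xlstruct.xl_io import AtomRecord, StructureModel

ref = make_structure(SyntheticSpec(chains=[("A", 40, 1.0)],
                                   inter_chain_offsets={}, seed=0), "reference")
pivot = ref.ca("A", 20)
R = Rotation.from_euler("x", 35, degrees=True).as_matrix()
hinged = StructureModel("hinged", [
    a if a.residue_index <= 20 else
    AtomRecord(a.chain_id, a.residue_index, a.residue_name, a.atom_name,
               tuple(R @ (np.asarray(a.position) - pivot) + pivot), a.element)
    for a in ref.atoms])

result, moved = superpose_on_anchor(ref, hinged, {"A": (1, 20)})
print(f"anchor rmsd over residues 1-20: {result.rmsd:.2e} A")
disp = result.per_residue_displacement
print(f"displacement at residue 10 (anchored) : {disp[('A', 10)]:6.2f} A")
print(f"displacement at residue 30 (mobile)   : {disp[('A', 30)]:6.2f} A")
print(f"displacement at residue 40 (mobile)   : {disp[('A', 40)]:6.2f} A")
# Near-zero anchor rmsd confirms the cores are identical; displacement
# grows with distance from the hinge, mapping the conformational change.
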