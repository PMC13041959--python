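"""Euclidean vs solvent-accessible surface distance.

A crosslinker cannot pass through a protein: when a body of atoms sits
between two lysines, the straight-line (Euclidean) distance understates
the path the reagent must span. This example puts a wall of atoms
between two residues and compares ED with the grid SASD, then shows the
free-space case where the two coincide up to the grid's connectivity
overhead.
"""

from xlstruct import DistanceConfig, ca_distance, sasd
from xlstruct.xl_io import AtomRecord, StructureModel

endpoints = [AtomRecord("A", 1, "LYS", "CA", (0.0, 0.0, 0.0), "C"),
             AtomRecord("A", 2, "LYS", "CA", (10.0, 0.0, 0.0), "C")]
wall = [AtomRecord("W", i + 1, "ALA", "CA", (5.0, float(y), float(z)), "C")
        for i, (y, z) in enumerate((y, z) for y in range(-9, 10, 2)
                                   for z in range(-9, 10, 2))]

blocked_model = StructureModel("walled", endpoints + wall)
cfg = DistanceConfig(grid_spacing=1.0)
ed = ca_distance(blocked_model, ("A", 1), ("A", 2))
s = sasd(blocked_model, ("A", 1), ("A", 2), cfg)
print(f"with a wall in between : ED {ed:5.1f} A   SASD {s:5.1f} A")

free_model = StructureModel("free", endpoints)
free_cfg = DistanceConfig(atom_radii={"C": 0.0}, probe_radius=0.0)
s_free = sasd(free_model, ("A", 1), ("A", 2), free_cfg)
print(f"free space             : ED {ed:5.1f} A   SASD {s_free:5.1f} A")
# SASD exceeds ED whenever the straight line is blocked; in free space it
# matches ED up to voxel discretization (<13% connectivity overhead).
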