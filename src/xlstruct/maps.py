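"""Residue contact maps, lysine distance heatmaps, and difference maps.

Contact maps show every residue pair of two chains within a distance
threshold (default 30 Å, Cα–Cα); lysine heatmaps restrict the same
distance matrix to lysine residues, visualizing crosslinkable-site
geometry.  Difference maps compare the contacts of two assemblies (e.g.
a heterodimer vs the trimer) cell by cell, and hotspots are reported as
4-connected components of the boolean contact matrix.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy.ndimage import label
from scipy.spatial.distance import cdist

from .xl_io import StructureModel


@dataclass
class ContactMap:
    """Inter-chain Cα–Cα distance matrix with a contact threshold."""

    chain_a: str
    chain_b: str
    residues_a: list[int]
    residues_b: list[int]
    distances: np.ndarray  # Å, shape (len(residues_a), len(residues_b))
    threshold: float = 30.0

    @property
    def contacts(self) -> np.ndarray:
        """Boolean contact matrix, derived exactly from distances and threshold."""
        return self.distances <= self.threshold

    @property
    def n_contacts(self) -> int:
        return int(self.contacts.sum())


@dataclass
class LysineHeatmap:
    chain_a: str
    chain_b: str
    lysines_a: list[int]
    lysines_b: list[int]
    distances: np.ndarray


@dataclass
class MapDifference:
    """Contacts exclusive to each map plus the shared set (cell index pairs
    are (residue_index_a, residue_index_b) in author numbering)."""

    only_in_1: list[tuple[int, int]]
    only_in_2: list[tuple[int, int]]
    shared: list[tuple[int, int]]

    @property
    def counts(self) -> dict[str, int]:
        return {"only_in_1": len(self.only_in_1), "only_in_2": len(self.only_in_2),
                "shared": len(self.shared)}


def _residue_min_distances(model: StructureModel, chain_a: str, chain_b: str,
                           res_a: Sequence[int], res_b: Sequence[int]) -> np.ndarray:
    """All-atom minimum distance per residue pair."""
    atoms_a = [(i, np.asarray(a.position)) for a in model.atoms if a.chain_id == chain_a
               for i in [a.residue_index]]
    atoms_b = [(i, np.asarray(a.position)) for a in model.atoms if a.chain_id == chain_b
               for i in [a.residue_index]]
    idx_a = {r: k for k, r in enumerate(res_a)}
    idx_b = {r: k for k, r in enumerate(res_b)}
    pa = np.array([p for _, p in atoms_a])
    pb = np.array([p for _, p in atoms_b])
    d = cdist(pa, pb)
    out = np.full((len(res_a), len(res_b)), np.inf)
    rows = np.array([idx_a[i] for i, _ in atoms_a])
    cols = np.array([idx_b[i] for i, _ in atoms_b])
    np.minimum.at(out, (rows[:, None], cols[None, :]), d)
    return out


def contact_map(model: StructureModel, chain_a: str, chain_b: str,
                threshold: float = 30.0, atom_mode: str = "ca") -> ContactMap:
    """Distance matrix between two chains, thresholded into contacts.

    ``atom_mode="ca"`` (default) measures Cα–Cα; ``"heavy"`` takes the
    all-atom minimum distance per residue pair.  For a chain against
    itself the matrix is symmetric with a zero diagonal.
    """
    res_a = model.residues(chain_a)
    res_b = model.residues(chain_b)
    if atom_mode == "ca":
        d = cdist(model.ca_coords(chain_a), model.ca_coords(chain_b))
    elif atom_mode == "heavy":
        d = _residue_min_distances(model, chain_a, chain_b, res_a, res_b)
    else:
        raise ValueError(f"unknown atom_mode {atom_mode!r}")
    return ContactMap(chain_a=chain_a, chain_b=chain_b,
                      residues_a=res_a, residues_b=res_b,
                      distances=d, threshold=threshold)


def lysine_heatmap(model: StructureModel, chain_a: str, chain_b: str) -> LysineHeatmap:
    """Cα–Cα distance matrix restricted to lysine residues of both chains."""
    lys_a = [r for r in model.residues(chain_a) if model.residue_name(chain_a, r) == "LYS"]
    lys_b = [r for r in model.residues(chain_b) if model.residue_name(chain_b, r) == "LYS"]
    if not lys_a or not lys_b:
        d = np.zeros((len(lys_a), len(lys_b)))
    else:
        d = cdist(model.ca_coords(chain_a, lys_a), model.ca_coords(chain_b, lys_b))
    return LysineHeatmap(chain_a=chain_a, chain_b=chain_b,
                         lysines_a=lys_a, lysines_b=lys_b, distances=d)


def map_difference(map_1: ContactMap, map_2: ContactMap) -> MapDifference:
    """Cell-wise comparison of two contact maps over the same chain pair."""
    if (map_1.chain_a, map_1.chain_b) != (map_2.chain_a, map_2.chain_b):
        raise ValueError("maps cover different chain pairs")
    if map_1.distances.shape != map_2.distances.shape:
        raise ValueError(
            f"axis mismatch: {map_1.distances.shape} vs {map_2.distances.shape}")
    c1, c2 = map_1.contacts, map_2.contacts
    def cells(mask: np.ndarray) -> list[tuple[int, int]]:
        return [(map_1.residues_a[i], map_1.residues_b[j]) for i, j in np.argwhere(mask)]
    return MapDifference(
        only_in_1=cells(c1 & ~c2),
        only_in_2=cells(~c1 & c2),
        shared=cells(c1 & c2),
    )


def hotspots(cmap: ContactMap) -> list[list[tuple[int, int]]]:
    """Contact hotspots as 4-connected components of the contact matrix,
    largest first — an operational stand-in for manual region annotation."""
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    labels, n = label(cmap.contacts, structure=structure)
    comps = []
    for k in range(1, n + 1):
        cells = [(cmap.residues_a[i], cmap.residues_b[j])
                 for i, j in np.argwhere(labels == k)]
        comps.append(cells)
    return sorted(comps, key=len, reverse=True)


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_matrix(distances: np.ndarray, rows: Sequence[int], cols: Sequence[int],
                 path: str | Path) -> None:
    """Distance matrix as TSV with residue indices on both axes."""
    with open(path, "w") as fh:
        fh.write("residue\t" + "\t".join(str(c) for c in cols) + "\n")
        for r, row in zip(rows, distances):
            fh.write(str(r) + "\t" + "\t".join(f"{v:.3f}" for v in row) + "\n")


def write_difference(diff: MapDifference, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("set\tresidue_a\tresidue_b\n")
        for name in ("only_in_1", "only_in_2", "shared"):
            for a, b in getattr(diff, name):
                fh.write(f"{name}\t{a}\t{b}\n")


def plot_contact_map(cmap: ContactMap, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    masked = np.where(cmap.contacts, cmap.distances, np.nan)
    im = ax.imshow(masked, origin="lower", cmap="viridis_r", aspect="auto",
                   extent=(cmap.residues_b[0], cmap.residues_b[-1],
                           cmap.residues_a[0], cmap.residues_a[-1]))
    fig.colorbar(im, ax=ax, label="Cα–Cα distance (Å)")
    ax.set_xlabel(f"chain {cmap.chain_b} residue")
    ax.set_ylabel(f"chain {cmap.chain_a} residue")
    ax.set_title(f"contacts ≤ {cmap.threshold:g} Å")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_lysine_heatmap(hm: LysineHeatmap, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(hm.distances, origin="lower", cmap="magma", aspect="auto")
    ax.set_xticks(range(len(hm.lysines_b)), [str(r) for r in hm.lysines_b],
                  rotation=90, fontsize=6)
    ax.set_yticks(range(len(hm.lysines_a)), [str(r) for r in hm.lysines_a], fontsize=6)
    fig.colorbar(im, ax=ax, label="Cα–Cα distance (Å)")
    ax.set_xlabel(f"chain {hm.chain_b} lysines")
    ax.set_ylabel(f"chain {hm.chain_a} lysines")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
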