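"""Rigid-body superposition (Kabsch) with anchor-domain selection.

Superimposing two models on a common well-ordered region — e.g. the
deacetylase domain shared by alternative predictions of a corepressor
complex — isolates the conformational shifts of the mobile regions: the
anchor RMSD measures how well the rigid cores agree, and the per-residue
displacement profile after the transform localizes the differences.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .xl_io import StructureModel


@dataclass
class SuperpositionResult:
    rotation: np.ndarray           # 3x3, orthonormal, det +1
    translation: np.ndarray        # 3-vector, Å
    rmsd: float                    # over anchor alpha-carbons, Å
    anchor: list[tuple[str, int]] = field(default_factory=list)
    per_residue_displacement: dict[tuple[str, int], float] = field(default_factory=dict)


def kabsch(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Least-squares optimal rigid transform of ``coords_b`` onto ``coords_a``.

    Closed-form solution via SVD of the cross-covariance matrix, with the
    determinant sign corrected so the result is a proper rotation (never
    a mirror).  The transform maps b as ``R @ b + t``.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"coordinate sets differ in shape: {A.shape} vs {B.shape}")
    if A.shape[0] < 3 or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("need two N x 3 arrays with N >= 3")
    ca_, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca_, B - cb
    if np.linalg.matrix_rank(np.vstack([A0, B0])) < 2:
        raise ValueError("degenerate (collinear or coincident) point set")
    H = B0.T @ A0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca_ - R @ cb
    rmsd = float(np.sqrt(np.mean(np.sum((A - (B @ R.T + t)) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def _expand_anchor(anchor, model: StructureModel) -> list[tuple[str, int]]:
    """Normalize an anchor selection to a sorted list of (chain, residue).

    Accepts a list of (chain, residue) pairs or a mapping chain → residue
    iterable / (start, stop) range tuples.
    """
    pairs: set[tuple[str, int]] = set()
    if isinstance(anchor, Mapping):
        for chain, sel in anchor.items():
            if (isinstance(sel, tuple) and len(sel) == 2
                    and all(isinstance(x, int) for x in sel)):
                sel = range(sel[0], sel[1] + 1)
            for r in sel:
                pairs.add((chain, int(r)))
    else:
        pairs.update((c, int(r)) for c, r in anchor)
    return sorted(pairs)


def superpose_on_anchor(model_a: StructureModel, model_b: StructureModel,
                        anchor_selection) -> tuple[SuperpositionResult, StructureModel]:
    """Superpose ``model_b`` onto ``model_a`` using anchor alpha-carbons.

    Anchor residues are paired by identical (chain, residue index) — the
    input order of the selection is irrelevant — and the fitted rigid
    transform is applied to the whole of ``model_b``.  Per-residue Cα
    displacement after the transform is reported for every residue
    present in both models, anchored or not.
    """
    anchor = [
        (c, r) for c, r in _expand_anchor(anchor_selection, model_a)
        if model_a.has_residue(c, r) and model_b.has_residue(c, r)
    ]
    if not anchor:
        raise ValueError("anchor selection has no residues common to both models")
    A = np.array([model_a.ca(c, r) for c, r in anchor])
    B = np.array([model_b.ca(c, r) for c, r in anchor])
    res = kabsch(A, B)
    moved = model_b.transformed(res.rotation, res.translation,
                                model_id=f"{model_b.model_id}_on_{model_a.model_id}")
    disp: dict[tuple[str, int], float] = {}
    for chain in model_a.chains:
        if chain not in moved.chains:
            continue
        for r in model_a.residues(chain):
            if moved.has_residue(chain, r):
                disp[(chain, r)] = float(np.linalg.norm(
                    model_a.ca(chain, r) - moved.ca(chain, r)))
    res.anchor = anchor
    res.per_residue_displacement = disp
    return res, moved


def write_displacements(result: SuperpositionResult, path) -> None:
    """Per-residue displacement profile as TSV."""
    with open(path, "w") as fh:
        fh.write("chain\tresidue\tdisplacement\n")
        for (chain, resi), d in sorted(result.per_residue_displacement.items()):
            fh.write(f"{chain}\t{resi}\t{d:.3f}\n")
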