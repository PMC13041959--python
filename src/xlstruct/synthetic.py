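"""Synthetic test-data generators.

Everything the pipeline consumes can be generated here with known ground
truth: multi-chain Cα-trace models with ideal backbone geometry, decoy
ladders related to a source model by rigid perturbations of known
magnitude plus coordinate noise, crosslink tables with planted
satisfied/violated lysine pairs under the 37 Å criterion, and an
SD3-style benchmark CSM table whose summary statistics are fixed by
construction.

All randomness flows from the spec seed; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import itertools
import math
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np

from .distances import ca_distance
from .xl_io import AtomRecord, CSMRecord, ChainMap, StructureModel

#: helix geometry: 1.5 Å rise and 100° twist per residue (3.6 residues/turn),
#: radius chosen so consecutive Cα atoms sit 3.8 Å apart.
HELIX_RISE = 1.5
HELIX_TWIST = math.radians(100.0)
CA_CA = 3.8
HELIX_RADIUS = math.sqrt(CA_CA**2 - HELIX_RISE**2) / (2.0 * math.sin(HELIX_TWIST / 2.0))

#: lysines are placed at every 7th residue so crosslinkable sites exist.
LYSINE_PERIOD = 7

_NON_K_ALPHABET = "ADEFGHILMNPQRSTVWY"


@dataclass
class SyntheticSpec:
    """Conditions for the synthetic study system.

    Defaults emulate a heterotrimeric complex of mostly-helical subunits
    packed side by side, a decoy ladder spanning sub-Å jitter to
    domain-scale displacement, and planting margins of ±5 Å around the
    37 Å cutoff so labels survive coordinate noise.
    """

    chains: list[tuple[str, int, float]] = field(
        default_factory=lambda: [("A", 60, 0.9), ("B", 50, 0.9), ("C", 40, 0.9)])
    inter_chain_offsets: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {"B": (14.0, 6.0, 0.0), "C": (4.0, 16.0, 10.0)})
    n_planted_satisfied: int = 6
    n_planted_violated: int = 4
    decoy_ladder: list[float] = field(default_factory=lambda: [0.0, 5.0, 15.0, 40.0, 100.0])
    noise_sd: float = 0.5
    seed: int = 0
    cutoff: float = 37.0
    plant_margin: float = 5.0

    def __post_init__(self) -> None:
        if any(length < 5 for _, length, _ in self.chains):
            raise ValueError("chain lengths must be >= 5")
        if any(m < 0 for m in self.decoy_ladder):
            raise ValueError("decoy magnitudes must be >= 0")


def _residue_name(index: int) -> str:
    return "LYS" if index % LYSINE_PERIOD == 0 else "ALA"


def _helix_points(n: int) -> np.ndarray:
    i = np.arange(n)
    return np.column_stack([
        HELIX_RADIUS * np.cos(i * HELIX_TWIST),
        HELIX_RADIUS * np.sin(i * HELIX_TWIST),
        i * HELIX_RISE,
    ])


def _coil_walk(start: np.ndarray, direction: np.ndarray, n: int,
               previous: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Self-avoiding random walk with 3.8 Å steps (clash floor 3.0 Å)."""
    pts = []
    occupied = list(previous)
    pos = start
    heading = direction / np.linalg.norm(direction)
    for _ in range(n):
        placed = None
        for _attempt in range(60):
            jitter = rng.normal(scale=0.6, size=3)
            step = heading + jitter
            step = step / np.linalg.norm(step) * CA_CA
            cand = pos + step
            occ = np.asarray(occupied)
            if np.min(np.linalg.norm(occ - cand, axis=1)) >= 3.0:
                placed = cand
                heading = step / CA_CA
                break
        if placed is None:  # accept the last candidate; realism is a non-goal
            placed = cand
        pts.append(placed)
        occupied.append(placed)
        pos = placed
    return np.asarray(pts)


def make_structure(spec: SyntheticSpec, model_id: str = "synthetic") -> StructureModel:
    """Build a multi-chain Cα-trace model with ideal backbone geometry.

    Each chain starts helical (fraction_helix of its residues: 1.5 Å
    rise, 100° twist, consecutive Cα spacing 3.8 Å) and finishes as a
    self-avoiding coil with the same Cα spacing; chains are translated
    by their inter-chain offsets.  Lysines sit at every 7th residue.
    """
    atoms: list[AtomRecord] = []
    for chain_idx, (chain_id, length, frac_helix) in enumerate(spec.chains):
        rng = np.random.default_rng([spec.seed, 101, chain_idx])
        n_helix = max(2, int(round(length * frac_helix)))
        n_helix = min(n_helix, length)
        pts = _helix_points(n_helix)
        if length > n_helix:
            direction = pts[-1] - pts[-2]
            coil = _coil_walk(pts[-1], direction, length - n_helix, pts, rng)
            pts = np.vstack([pts, coil])
        offset = np.asarray(spec.inter_chain_offsets.get(chain_id, (0.0, 0.0, 0.0)))
        pts = pts + offset
        for i, p in enumerate(pts, start=1):
            atoms.append(AtomRecord(
                chain_id=chain_id, residue_index=i, residue_name=_residue_name(i),
                atom_name="CA", position=tuple(float(x) for x in p), element="C",
            ))
    return StructureModel(model_id, atoms)


def accession_for_chain(chain_id: str) -> str:
    return f"PROT_{chain_id}"


def chain_map_for(model: StructureModel) -> ChainMap:
    """One synthetic accession per chain, offset 0."""
    return ChainMap({accession_for_chain(c): [(c, 0)] for c in model.chains})


def lysine_sites(model: StructureModel) -> list[tuple[str, int]]:
    return [(c, r) for c in model.chains for r in model.residues(c)
            if model.residue_name(c, r) == "LYS"]


def plant_crosslinks(model: StructureModel, spec: SyntheticSpec
                     ) -> tuple[list[CSMRecord], list[dict]]:
    """Plant crosslinks with known satisfaction labels on a model.

    Lysine pairs with ED <= cutoff − margin become planted-satisfied,
    pairs with ED >= cutoff + margin planted-violated; the CSM table
    contains duplicated rows (varying endpoint order and replicate) so
    deduplication is exercised.  Returns the table plus a ground-truth
    row per planted unique crosslink.

    Violated pairs are planted within single chains: a rigid-body
    perturbation of one chain preserves its internal distances, so a
    violated crosslink can never become satisfied on a decoy and the
    ladder's satisfaction signal degrades monotonically by construction.
    """
    rng = np.random.default_rng([spec.seed, 202])
    sites = lysine_sites(model)
    pairs = [(a, b, ca_distance(model, a, b))
             for a, b in itertools.combinations(sites, 2)]
    sat_pool = [p for p in pairs if p[2] <= spec.cutoff - spec.plant_margin]
    vio_pool = [p for p in pairs
                if p[2] >= spec.cutoff + spec.plant_margin and p[0][0] == p[1][0]]
    if len(sat_pool) < spec.n_planted_satisfied or len(vio_pool) < spec.n_planted_violated:
        raise ValueError(
            f"not enough eligible lysine pairs: {len(sat_pool)} satisfiable, "
            f"{len(vio_pool)} violable for request "
            f"({spec.n_planted_satisfied}, {spec.n_planted_violated})")
    chosen = ([sat_pool[i] for i in
               rng.choice(len(sat_pool), spec.n_planted_satisfied, replace=False)]
              + [vio_pool[i] for i in
                 rng.choice(len(vio_pool), spec.n_planted_violated, replace=False)])
    labels = ([True] * spec.n_planted_satisfied) + ([False] * spec.n_planted_violated)
    csms: list[CSMRecord] = []
    truth: list[dict] = []
    n = 0
    for (a, b, ed), satisfied in zip(chosen, labels):
        end_a = (accession_for_chain(a[0]), a[1])
        end_b = (accession_for_chain(b[0]), b[1])
        if end_b < end_a:
            end_a, end_b = end_b, end_a
        support = int(rng.integers(1, 4))
        for k in range(support):
            n += 1
            ea, eb = (end_a, end_b) if rng.random() < 0.5 else (end_b, end_a)
            csms.append(CSMRecord(
                csm_id=f"csm{n:05d}", replicate=f"rep{(k % 3) + 1}",
                protein_a=ea[0], position_a=ea[1],
                protein_b=eb[0], position_b=eb[1],
                score=float(np.round(rng.uniform(10, 200), 2)), passes_fdr=True,
            ))
        truth.append({
            "protein_a": end_a[0], "position_a": end_a[1],
            "protein_b": end_b[0], "position_b": end_b[1],
            "planted_satisfied": satisfied, "true_ed": ed, "csm_support": support,
        })
    return csms, truth


def make_decoys(model: StructureModel, spec: SyntheticSpec) -> list[StructureModel]:
    """Decoy ladder: one randomly chosen chain is rigidly translated along
    a random unit vector — drawn once per ladder so the rungs form a
    coherent perturbation series — by each magnitude in turn, plus
    per-atom Gaussian noise."""
    rng = np.random.default_rng([spec.seed, 303])
    chain = model.chains[int(rng.integers(len(model.chains)))]
    v = rng.normal(size=3)
    v = v / np.linalg.norm(v)
    decoys = []
    for k, mag in enumerate(spec.decoy_ladder):
        shift = v * mag
        atoms = []
        for a in model.atoms:
            p = np.asarray(a.position)
            if a.chain_id == chain:
                p = p + shift
            if spec.noise_sd > 0:
                p = p + rng.normal(scale=spec.noise_sd, size=3)
            atoms.append(AtomRecord(a.chain_id, a.residue_index, a.residue_name,
                                    a.atom_name, tuple(float(x) for x in p), a.element))
        decoys.append(StructureModel(f"decoy{k:02d}_mag{mag:g}", atoms))
    return decoys


# ---------------------------------------------------------------------------
# SD3-style benchmark dataset (synthetic stand-in for the real CSM export)
# ---------------------------------------------------------------------------

def _random_sequence(length: int, k_positions: Sequence[int],
                     rng: np.random.Generator) -> str:
    letters = rng.choice(list(_NON_K_ALPHABET), size=length)
    seq = list("".join(letters))
    for p in k_positions:
        seq[p - 1] = "K"
    return "".join(seq)


def make_benchmark_dataset(seed: int = 0, n_csms: int = 525, n_intra: int = 165,
                           n_inter: int = 52, n_proteins: int = 148,
                           bait_lysines: int = 20, bait_crosslinked: int = 4
                           ) -> tuple[list[CSMRecord], dict[str, str], str]:
    """Synthetic CSM table with summary statistics fixed by construction.

    Builds a crosslink identification table in the style of a search
    engine export over ``n_proteins`` synthetic proteins, planted so the
    deduplicated dataset has exactly ``n_intra`` intra- and ``n_inter``
    inter-molecular unique crosslinks supported by exactly ``n_csms``
    CSM rows, and so the bait protein's sequence carries exactly
    ``bait_lysines`` lysines of which exactly ``bait_crosslinked``
    appear in crosslinks.  Returns (csms, sequences, bait_accession).
    All proteins, sequences and identifiers are synthetic.
    """
    if bait_crosslinked % 2 or bait_crosslinked < 2:
        raise ValueError("bait_crosslinked must be an even count >= 2")
    n_bait_intra = bait_crosslinked // 2
    rng = np.random.default_rng([seed, 404])
    accs = [f"SYN{i:04d}" for i in range(1, n_proteins + 1)]
    bait = accs[0]

    n_group2 = 2 * n_inter
    if n_group2 > n_proteins - 1 - 1:
        raise ValueError("too few proteins to host the requested inter crosslinks")
    group2 = accs[n_proteins - n_group2:]
    group1 = accs[1:n_proteins - n_group2]
    n_intra_rest = n_intra - n_bait_intra
    if len(group1) < 1 or n_intra_rest < len(group1):
        raise ValueError("cannot give every non-bait intra protein a crosslink")

    # sequences: bait has exactly `bait_lysines` K residues; others 10 each.
    sequences: dict[str, str] = {}
    bait_len = 150
    bait_k = sorted(rng.choice(np.arange(1, bait_len + 1), bait_lysines,
                               replace=False).tolist())
    sequences[bait] = _random_sequence(bait_len, bait_k, rng)
    k_sites: dict[str, list[int]] = {bait: bait_k}
    for acc in accs[1:]:
        length = int(rng.integers(80, 220))
        ks = sorted(rng.choice(np.arange(1, length + 1), 10, replace=False).tolist())
        sequences[acc] = _random_sequence(length, ks, rng)
        k_sites[acc] = ks

    uniques: list[tuple[tuple[str, int], tuple[str, int]]] = []

    def canonical(a, b):
        return (a, b) if a <= b else (b, a)

    # bait intra pairs use disjoint lysines → exactly `bait_crosslinked` sites.
    bait_pick = sorted(rng.choice(bait_k, bait_crosslinked, replace=False).tolist())
    for i in range(n_bait_intra):
        uniques.append(canonical((bait, bait_pick[2 * i]), (bait, bait_pick[2 * i + 1])))

    # remaining intra pairs round-robin over group1, distinct position pairs each.
    pair_iters = {acc: itertools.combinations(k_sites[acc], 2) for acc in group1}
    gi = 0
    for _ in range(n_intra_rest):
        acc = group1[gi % len(group1)]
        p, q = next(pair_iters[acc])
        uniques.append(canonical((acc, p), (acc, q)))
        gi += 1

    # inter pairs: disjoint consecutive pairing covers all of group2.
    for j in range(n_inter):
        a, b = group2[2 * j], group2[2 * j + 1]
        uniques.append(canonical((a, k_sites[a][0]), (b, k_sites[b][0])))

    assert len(uniques) == n_intra + n_inter
    assert len(set(uniques)) == len(uniques)

    # distribute CSM support: every unique >= 2, a seeded subset gets 3.
    base = n_csms // len(uniques)
    extra = n_csms - base * len(uniques)
    if base < 1:
        raise ValueError("fewer CSMs than unique crosslinks requested")
    support = np.full(len(uniques), base)
    support[rng.choice(len(uniques), extra, replace=False)] += 1

    csms: list[CSMRecord] = []
    n = 0
    for (end_a, end_b), sup in zip(uniques, support):
        for k in range(int(sup)):
            n += 1
            ea, eb = (end_a, end_b) if rng.random() < 0.5 else (end_b, end_a)
            csms.append(CSMRecord(
                csm_id=f"bcsm{n:05d}", replicate=f"rep{(k % 3) + 1}",
                protein_a=ea[0], position_a=ea[1],
                protein_b=eb[0], position_b=eb[1],
                score=float(np.round(rng.uniform(10, 300), 2)), passes_fdr=True,
            ))
    order = rng.permutation(len(csms))
    csms = [csms[i] for i in order]
    return csms, sequences, bait
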