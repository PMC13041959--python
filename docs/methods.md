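# Methods

## Problem setting

Chemical crosslinking with DSSO covalently bridges lysine side chains that
are close in space; mass spectrometry then identifies the linked peptide
pairs. Each identification (a crosslink spectrum match, CSM) localizes two
sequence positions that, on a correct structural model, must lie within
the reagent's reach. The accepted upper bound for a DSSO-bridged pair,
measured between the two α-carbons, is 37 Å: spacer plus two lysine side
chains plus backbone tolerance. `xlstruct` uses that bound in both
directions — to *validate* candidate models of a complex (how many
crosslinks does a model satisfy?) and to *drive* refinement and docking
(satisfied crosslinks become distance restraints).

## Data model and conventions

* Crosslink positions are 1-based positions in the full-length protein
  sequence. Model residues carry author numbering; a chain map entry
  `(accession → chain, offset)` bridges the two as
  `residue_index = position + offset`. Predicted models typically number
  from 1, so the default offset is 0.
* CSMs are deduplicated on the unordered pair of (accession, position)
  endpoints, ignoring peptide sequence and charge; `csm_support` counts
  the pooled spectra. A crosslink is *intra*-molecular iff both accessions
  are equal (accession level, not chain level, so a homo-oligomer's
  self-links stay intra).
* When an accession maps to several chains, every chain-pair candidate is
  carried and the minimum-ED candidate is used — the standard XL-MS
  convention for copy ambiguity. The complexes this package targets have
  one copy per protein, where the rule is a no-op.
* A crosslink mapped to a non-lysine residue is kept with a warning and a
  flag: CSM site localization can be off by one and discarding silently
  would bias coverage counts.
* CSMs failing the search engine's FDR flag are retained by readers but
  excluded from summaries by default (`fdr_only=True`), matching a 1%
  FDR working set; both modes are exposed because exports differ in
  whether sub-threshold rows are present at all.

## Distances

**Euclidean (ED)** is the Cα–Cα norm. Satisfaction defaults to
`ED ≤ cutoff` with `cutoff = 37 Å`; the α-carbon (not the side-chain
nitrogen) is the stated convention for this criterion.

**Solvent-accessible surface distance (SASD)** answers a stricter
question: can the crosslinker physically span the two sites without
passing through the protein? The model is voxelized on a regular grid
(default spacing 1.0 Å) over its bounding box padded by the cutoff; a
voxel is blocked when its center lies within `vdW + probe` of any atom
(probe 1.4 Å; vdW radii C 1.7, N 1.55, O 1.52, S 1.8 Å — conventional
values). The SASD is the Dijkstra shortest path between the endpoints'
voxels through accessible space, moving between 26-connected neighbors
with Euclidean step costs (1, √2, √3 × spacing). Because an α-carbon
always sits inside the protein volume, each endpoint is first snapped to
its nearest accessible voxel within `max_search_radius` (default 10 Å);
the reported SASD includes both snap segments. A pair is *unreachable*
when an endpoint cannot be rescued or no path exists within the budget
`3 × cutoff` — any longer path is violated regardless, and the budget
bounds runtime.

Numerical properties: SASD ≥ ED − 2·spacing always (triangle inequality
through the snapped voxels); in free space SASD → ED up to the grid's
connectivity overhead, which is at most ≈13% (worst-case oblique
direction for a 26-connected Euclidean-cost grid, found numerically) and
under 8% for near-axis paths. The grid path is checked exactly against an
independent `networkx` Dijkstra oracle in the tests. SASD is the
expensive path and is computed only on request; satisfaction is gated by
ED unless `criterion="sasd"` is set, in which case the same 37 Å default
applies (an interpretation: no separate SASD cutoff is established for
this reagent).

## Scoring and selection

The **XL Score** of a model is the count of mapped crosslinks with
`ED ≤ cutoff`. Unmapped crosslinks (endpoint protein absent from the
chain map, or position outside the modeled range) never penalize a score
but are reported (`n_unmapped`) so coverage differences stay visible.
Ranking is descending by satisfied count with two documented tie-breaks —
ascending mean satisfied ED (a geometrically tighter model wins), then
lexicographic model id — making the order a deterministic total order.

Satisfied crosslinks are exported as unambiguous Cα–Cα restraints with a
permitted band of [0, cutoff], encoded as target = cutoff/2 with
symmetric margins. Two dialects are frozen by golden tests: docking
`assign` statements and a whitespace refinement list. Files are sorted by
(chain, residue) and byte-stable under input permutation. Per-residue
ambiguous restraints were deliberately not emitted: the satisfied set is
already localized to specific α-carbon pairs.

After docking, clusters are shortlisted by the score-window rule: every
cluster whose engine score (lower is better) lies within one standard
deviation *of the best cluster* above the best score survives, and the XL
Score of the shortlisted representatives decides. Which SD defines the
window is an interpretation (the best cluster's), chosen and documented
here.

External engines (fragment assembly, docking) are boundary files only:
restraints out, refined models back in through the same readers. Nothing
is invoked as a subprocess, which keeps the loop testable.

## Structure analysis

Contact maps use Cα–Cα distances at a 30 Å threshold by default — the
same atom convention as the lysine heatmaps — with an all-atom
minimum-distance mode available behind a flag since the convention for
"residue contact" is not universal. The transpose relation, threshold
monotonicity, and agreement with an O(n²) enumeration are tested
properties. Lysine heatmaps are the same matrix restricted to lysine
rows/columns. Assembly differences are reported cell-wise (contacts only
in map 1 / only in map 2 / shared); hotspots are operationalized as
4-connected components of the boolean contact matrix, replacing manual
figure annotation with a reproducible definition.

Superposition is closed-form Kabsch via SVD with determinant sign
correction (proper rotations only — physical structures are never
mirrored). Anchor residues are paired by identical (chain, residue index)
after chain-map normalization; alignment-based pairing is out of scope
because the models compared here share numbering. The anchor RMSD and the
per-residue Cα displacement profile after the transform are reported; the
implementation is cross-checked against `scipy`'s `align_vectors` and a
random-rotation sampling oracle in the tests.

## Synthetic data generator

The generator emulates the study conditions so every operation can be
validated against planted ground truth:

* **Structures** are Cα traces with ideal geometry: helical segments with
  1.5 Å rise and 100° twist per residue (3.6 residues/turn, consecutive
  Cα spacing exactly 3.8 Å), coil tails as self-avoiding 3.8 Å random
  walks, lysines at every 7th residue. Defaults: three mostly-helical
  chains of 60/50/40 residues packed side by side — a trimer-like complex
  at the scale where every pipeline stage is exercised in seconds.
* **Planted crosslinks**: lysine pairs with ED ≤ cutoff − 5 Å are planted
  satisfied, pairs with ED ≥ cutoff + 5 Å violated; the ±5 Å margin keeps
  labels stable under coordinate noise. Violated pairs are planted within
  single chains: a rigid perturbation of one chain preserves intra-chain
  distances, so a violated crosslink can never become satisfied on a
  decoy and the ladder's degradation signal is monotone by construction.
  Emitted CSM tables contain duplicate rows with shuffled endpoint order
  to exercise deduplication.
* **Decoy ladders** perturb one chain — chosen once per ladder, together
  with one random unit direction — by each magnitude in [0, 5, 15, 40,
  100] Å, plus per-atom Gaussian noise (sd 0.5 Å). Drawing the chain and
  direction once makes the rungs a coherent perturbation series: since
  |d + m·v| is convex in m and planted-satisfied pairs start ≤ 32 Å, a
  crosslink that breaks at some magnitude stays broken at larger ones.
* **Benchmark CSM table**: a synthetic search-engine export over 148
  synthetic proteins constructed so the deduplicated dataset has exactly
  525 CSMs, 165 intra- and 52 inter-molecular unique crosslinks, and a
  bait protein with exactly 20 lysines of which exactly 4 are
  crosslinked. All accessions and sequences are synthetic; the table
  exists so the full parse → dedupe → summarize path can be verified
  against counts fixed by construction.
* For SASD exercises the Cα pseudo-atoms stand in for full chains; an
  inflated radius can mimic side-chain volume where needed.

What passing these tests does *not* show: performance on real predicted
models with full side chains, real CSM noise (mis-localization,
decoy matches), or sequence/numbering mismatches beyond the offset model.
The generator makes no claim of physical realism (no Ramachandran
validity, no packing).

## FRET efficiency

Acceptor-photobleaching FRET reports sub-10 nm proximity in cells: if the
acceptor is bleached, a donor that was transferring energy brightens.
Efficiency is implemented as `E = (1 − I_pre/I_post) × 100` percent over
mean donor intensities; the formula's printed precedence is ambiguous in
common write-ups, and this reading (donor dequenching, positive when the
donor brightens) is the physically meaningful one. Intensities must be
positive; negative efficiencies mean no transfer was detected.
Replicate-level statistics on efficiencies are out of scope.

## Problem sizes and determinism

Default test and validation sizes — 150-residue trimers, 10 planted
crosslinks, 50-seed repetitions, ≤20³ voxel oracle fixtures — were chosen
so each property is exercised at a scale where brute-force oracles remain
exact and the whole suite runs in seconds. All generator randomness flows
from a single integer seed through `numpy.random.default_rng`; identical
seeds give byte-identical files. Restraint and manifest outputs carry no
timestamps, so identical inputs give identical bytes.

## Known limitations

* PDB only (no mmCIF); first altloc kept; duplicate residue indices after
  altloc resolution are rejected rather than renumbered.
* SASD treats atoms as hard spheres on a fixed grid; no side-chain
  flexibility, no rotamer sampling, and the reported path includes the
  endpoint rescue segments.
* Anchor pairing requires shared residue numbering; no sequence
  alignment fallback.
* The satisfaction criterion when ED and SASD disagree is ED by default;
  a config flag switches to SASD, with the same cutoff.
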