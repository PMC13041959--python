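"""Crosslink dataset summarization.

Collapses spectrum-level identifications (CSMs) into unique residue-pair
crosslinks, classifies them as intra- or inter-molecular, and computes
dataset-level statistics: CSM counts, unique-crosslink counts, protein
counts and per-protein lysine coverage.  Also provides the
acceptor-photobleaching FRET efficiency used to corroborate proximity in
cells: E = (1 - I_pre / I_post) * 100, in percent, where I is the mean
donor intensity before/after bleaching the acceptor.
"""

from __future__ import annotations

import json
from collections import Counter
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .xl_io import CSMRecord


@dataclass(frozen=True)
class UniqueXL:
    """A deduplicated crosslinked residue pair (unordered endpoints).

    Endpoints are stored in canonical order (accession, then position) so
    A-B and B-A collapse; ``xl_class`` is ``"intra"`` iff the accessions
    match, at the accession level regardless of chain copies.
    """

    endpoint_a: tuple[str, int]
    endpoint_b: tuple[str, int]
    csm_support: int = 1

    def __post_init__(self) -> None:
        if self.endpoint_b < self.endpoint_a:
            raise ValueError("endpoints must be in canonical sorted order")

    @property
    def xl_class(self) -> str:
        return "intra" if self.endpoint_a[0] == self.endpoint_b[0] else "inter"


@dataclass
class DatasetSummary:
    n_csms: int
    n_unique_intra: int
    n_unique_inter: int
    n_proteins: int
    per_protein_lysines: dict[str, tuple[int, int]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_csms": self.n_csms,
            "n_unique_intra": self.n_unique_intra,
            "n_unique_inter": self.n_unique_inter,
            "n_proteins": self.n_proteins,
            "per_protein_lysines": {
                acc: {"n_lysines_in_sequence": a, "n_crosslinked_lysines": b}
                for acc, (a, b) in sorted(self.per_protein_lysines.items())
            },
        }


def dedupe_crosslinks(csms: Sequence[CSMRecord], fdr_only: bool = True) -> list[UniqueXL]:
    """Collapse CSMs into unique residue-pair crosslinks.

    One :class:`UniqueXL` per distinct unordered (accession, position)
    pair; ``csm_support`` counts the contributing CSMs.  With ``fdr_only``
    (the default, matching a 1% FDR-filtered working set) CSMs flagged as
    failing FDR are excluded.  Output order is canonical, independent of
    input row order.
    """
    support: Counter[tuple[tuple[str, int], tuple[str, int]]] = Counter()
    for c in csms:
        if fdr_only and not c.passes_fdr:
            continue
        ends = sorted([(c.protein_a, c.position_a), (c.protein_b, c.position_b)])
        support[(ends[0], ends[1])] += 1
    return [UniqueXL(a, b, n) for (a, b), n in sorted(support.items())]


def expand_uniques(uniques: Sequence[UniqueXL]) -> list[CSMRecord]:
    """Inverse of dedup for round-trip checks: one CSM row per unit of support."""
    out = []
    for u in uniques:
        for k in range(u.csm_support):
            out.append(CSMRecord(
                csm_id=f"{u.endpoint_a}-{u.endpoint_b}-{k}", replicate="r1",
                protein_a=u.endpoint_a[0], position_a=u.endpoint_a[1],
                protein_b=u.endpoint_b[0], position_b=u.endpoint_b[1],
            ))
    return out


def summarize_dataset(csms: Sequence[CSMRecord],
                      uniques: Sequence[UniqueXL],
                      sequences: Mapping[str, str] | None = None) -> DatasetSummary:
    """Dataset-level statistics over CSMs and their unique crosslinks.

    ``n_proteins`` counts distinct accessions appearing at either endpoint
    of any CSM.  For every accession with a sequence provided, lysine
    coverage is reported as (lysines in sequence, distinct crosslinked
    positions that are lysine in that sequence).
    """
    sequences = sequences or {}
    accs = {c.protein_a for c in csms} | {c.protein_b for c in csms}
    xl_positions: dict[str, set[int]] = {}
    for u in uniques:
        for acc, pos in (u.endpoint_a, u.endpoint_b):
            xl_positions.setdefault(acc, set()).add(pos)
    coverage: dict[str, tuple[int, int]] = {}
    for acc, seq in sequences.items():
        n_lys = seq.count("K")
        hit = {p for p in xl_positions.get(acc, ()) if p <= len(seq) and seq[p - 1] == "K"}
        coverage[acc] = (n_lys, len(hit))
    n_intra = sum(1 for u in uniques if u.xl_class == "intra")
    return DatasetSummary(
        n_csms=len(csms),
        n_unique_intra=n_intra,
        n_unique_inter=len(uniques) - n_intra,
        n_proteins=len(accs),
        per_protein_lysines=coverage,
    )


def fret_efficiency(i_pre: float, i_post: float) -> float:
    """Acceptor-photobleaching FRET efficiency in percent.

    Donor dequenching after acceptor bleaching raises donor intensity, so
    i_post > i_pre gives a positive efficiency; a negative value means no
    energy transfer was detected.
    """
    if i_pre <= 0 or i_post <= 0:
        raise ValueError("intensities must be positive")
    return (1.0 - i_pre / i_post) * 100.0


def write_summary(summary: DatasetSummary, out_dir: str | Path,
                  basename: str = "summary") -> None:
    """Emit the summary as a delimited report and a machine-readable JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = [
        ("n_csms", summary.n_csms),
        ("n_unique_intra", summary.n_unique_intra),
        ("n_unique_inter", summary.n_unique_inter),
        ("n_proteins", summary.n_proteins),
    ]
    lines = [f"statistic\tvalue"] + [f"{k}\t{v}" for k, v in rows]
    for acc, (n_k, n_x) in sorted(summary.per_protein_lysines.items()):
        lines.append(f"lysines:{acc}\t{n_k}")
        lines.append(f"crosslinked_lysines:{acc}\t{n_x}")
    (out_dir / f"{basename}.tsv").write_text("\n".join(lines) + "\n")
    (out_dir / f"{basename}.json").write_text(json.dumps(summary.as_dict(), indent=2) + "\n")


def uniques_table(uniques: Sequence[UniqueXL]) -> pd.DataFrame:
    return pd.DataFrame([{
        "protein_a": u.endpoint_a[0], "position_a": u.endpoint_a[1],
        "protein_b": u.endpoint_b[0], "position_b": u.endpoint_b[1],
        "xl_class": u.xl_class, "csm_support": u.csm_support,
    } for u in uniques])
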