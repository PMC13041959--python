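"""Model scoring and selection from crosslink satisfaction.

The XL Score of a candidate model is the number of crosslinks whose
measured Cα–Cα distance falls within the cutoff.  Models are ranked by
that count; satisfied crosslinks are then exported as distance restraints
to drive the next refinement or docking round, and a score-window rule
shortlists docking clusters whose engine score lies within one standard
deviation of the best cluster before the XL Score breaks the tie.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .distances import XLMeasurement
from .xl_io import CA, Restraint, RestraintSet


@dataclass(frozen=True)
class XLScoreResult:
    """Per-model crosslink satisfaction tally used for ranking."""

    model_id: str
    n_satisfied: int
    n_mapped: int
    n_unmapped: int = 0
    mean_satisfied_ed: float | None = None  # defined only when n_satisfied > 0


@dataclass(frozen=True)
class ClusterScore:
    """A docking cluster's engine score (lower is better) and its spread."""

    cluster_id: str
    engine_score: float
    engine_score_sd: float
    representative_model: str


def xl_score(measurements: Sequence[XLMeasurement], n_unmapped: int = 0,
             model_id: str | None = None) -> XLScoreResult:
    """Count satisfied crosslinks for one model.

    All measurements must share one ``model_id`` (supplied explicitly for
    an empty list).  Unmapped crosslinks do not affect the score but are
    carried for coverage reporting.
    """
    ids = {m.model_id for m in measurements}
    if len(ids) > 1:
        raise ValueError(f"measurements span multiple models: {sorted(ids)}")
    if model_id is None:
        model_id = ids.pop() if ids else ""
    sat = [m for m in measurements if m.satisfied]
    mean_ed = sum(m.ed for m in sat) / len(sat) if sat else None
    return XLScoreResult(
        model_id=model_id,
        n_satisfied=len(sat),
        n_mapped=len(measurements),
        n_unmapped=n_unmapped,
        mean_satisfied_ed=mean_ed,
    )


def rank_models(scores: Sequence[XLScoreResult]) -> list[XLScoreResult]:
    """Order models best-first.

    Descending satisfied count; ties broken by ascending mean satisfied
    ED (a tighter model wins), then lexicographic model id so the order
    is a deterministic total order.
    """
    if not scores:
        raise ValueError("no scores to rank")
    def key(s: XLScoreResult):
        mean = s.mean_satisfied_ed if s.mean_satisfied_ed is not None else float("inf")
        return (-s.n_satisfied, mean, s.model_id)
    return sorted(scores, key=key)


def select_constraints(measurements: Sequence[XLMeasurement], cutoff: float = 37.0,
                       dialect: str = "docking-tbl") -> RestraintSet:
    """Turn satisfied crosslinks into Cα–Cα distance restraints.

    Each satisfied crosslink becomes one unambiguous restraint between
    the alpha-carbons of the chain pair actually used, with a permitted
    band of [0, cutoff] encoded as target = cutoff/2 with symmetric
    margins.  An empty result is allowed but warned about.
    """
    restraints = [
        Restraint(
            chain_a=m.chain_pair_used[0], residue_a=m.residue_pair_used[0], atom_a=CA,
            chain_b=m.chain_pair_used[1], residue_b=m.residue_pair_used[1], atom_b=CA,
            target=cutoff / 2.0, lower_margin=cutoff / 2.0, upper_margin=cutoff / 2.0,
        )
        for m in measurements if m.satisfied
    ]
    if not restraints:
        warnings.warn("no satisfied crosslinks: emitting an empty restraint set",
                      stacklevel=2)
    return RestraintSet(restraints=restraints, dialect=dialect)


def cluster_window(clusters: Sequence[ClusterScore]) -> list[ClusterScore]:
    """Shortlist docking clusters within one SD of the best engine score.

    With ``best`` the minimum engine score, every cluster whose score is
    <= best + sd(best cluster) is shortlisted (the best cluster's SD
    defines the window).  Final selection among the shortlist is by the
    XL Score of each representative model via :func:`rank_models`.
    """
    if not clusters:
        raise ValueError("no clusters")
    best = min(clusters, key=lambda c: c.engine_score)
    window = best.engine_score + best.engine_score_sd
    return [c for c in clusters if c.engine_score <= window]


def select_best_cluster(clusters: Sequence[ClusterScore],
                        representative_scores: Mapping[str, XLScoreResult]) -> ClusterScore:
    """Apply the window rule, then pick the shortlisted cluster whose
    representative model ranks best by XL Score."""
    shortlist = cluster_window(clusters)
    ranked = rank_models([representative_scores[c.representative_model] for c in shortlist])
    best_model = ranked[0].model_id
    return next(c for c in shortlist if c.representative_model == best_model)


def ranking_table(scores: Sequence[XLScoreResult]) -> pd.DataFrame:
    ranked = rank_models(scores)
    return pd.DataFrame([{
        "model_id": s.model_id,
        "n_satisfied": s.n_satisfied,
        "n_mapped": s.n_mapped,
        "n_unmapped": s.n_unmapped,
        "mean_satisfied_ed": ("" if s.mean_satisfied_ed is None
                              else round(s.mean_satisfied_ed, 3)),
        "rank": i + 1,
    } for i, s in enumerate(ranked)])


def write_ranking(scores: Sequence[XLScoreResult], path: str | Path) -> None:
    ranking_table(scores).to_csv(path, sep="\t", index=False)
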