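"""GEBV-ranked germplasm screening with lodging-category enrichment.

Candidates carry a 9-level ordinal lodging score (1 = no lodging, 9 = all
plants lodged flat) that maps onto four resistance categories. Screening
ranks candidates by predicted breeding value for a chosen trait, selects
the top N, and compares the category mix of the selection against the base
population — the headline quantity being the combined share of the highly
and moderately lodging-resistant classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ricegs.models import PredictionResult

__all__ = ["LodgingCategoryScheme", "ScreeningResult", "categorize_scores",
           "rank_and_select", "enrichment_report", "CATEGORIES"]

CATEGORIES = ("HLR", "MLR", "Susceptible", "ExtremelySusceptible")


@dataclass(frozen=True)
class LodgingCategoryScheme:
    """Threshold rules mapping an ordinal score x in {1..9} to a category:
    HLR if x <= 2; MLR if 2 < x < 5; Susceptible if 5 <= x < 7;
    ExtremelySusceptible if x >= 7. The four predicates partition {1..9}."""

    def category(self, x: int) -> str:
        if x <= 2:
            return "HLR"
        if x < 5:
            return "MLR"
        if x < 7:
            return "Susceptible"
        return "ExtremelySusceptible"


@dataclass
class ScreeningResult:
    trait: str
    direction: str
    top_n: int
    selected_ids: list[str]
    base_proportions: dict[str, float]
    selected_proportions: dict[str, float]
    enrichment_delta: dict[str, float]

    @property
    def base_resistant_fraction(self) -> float:
        """Combined HLR + MLR share of the base population."""
        return self.base_proportions["HLR"] + self.base_proportions["MLR"]

    @property
    def selected_resistant_fraction(self) -> float:
        """Combined HLR + MLR share of the selected subset."""
        return (self.selected_proportions["HLR"]
                + self.selected_proportions["MLR"])

    def to_json(self, path=None) -> str:
        d = {"trait": self.trait, "direction": self.direction,
             "top_n": self.top_n, "selected_ids": self.selected_ids,
             "base_proportions": self.base_proportions,
             "selected_proportions": self.selected_proportions,
             "enrichment_delta": self.enrichment_delta,
             "base_resistant_fraction": self.base_resistant_fraction,
             "selected_resistant_fraction": self.selected_resistant_fraction}
        text = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def categorize_scores(scores, ids=None,
                      scheme: LodgingCategoryScheme = LodgingCategoryScheme()
                      ) -> tuple[list[str], dict[str, float]]:
    """Map ordinal scores to resistance categories and their proportions.

    Raises on an empty input or any score outside the integers 1..9,
    naming the offending entries.
    """
    scores = np.asarray(scores)
    if scores.size == 0:
        raise ValueError("empty score vector")
    as_int = scores.astype(int)
    bad = (scores != as_int) | (as_int < 1) | (as_int > 9)
    if bad.any():
        where = (np.asarray(ids)[bad].tolist() if ids is not None
                 else np.flatnonzero(bad).tolist())
        raise ValueError(f"scores outside integer range 1..9 at {where[:10]}")
    cats = [scheme.category(int(x)) for x in as_int]
    n = len(cats)
    props = {c: cats.count(c) / n for c in CATEGORIES}
    return cats, props


def rank_and_select(pred: PredictionResult, direction: str,
                    top_n: int = 200) -> list[str]:
    """Select the top-N candidate ids by GEBV.

    ``direction='lower'`` ranks ascending (favourable = smaller, e.g.
    internode length); ``'higher'`` descending (e.g. bending resistance).
    Ties are broken by sample id lexicographically, which keeps selections
    reproducible across runs and platforms.
    """
    if direction not in ("lower", "higher"):
        raise ValueError("direction must be 'lower' or 'higher'")
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    gebv = np.asarray(pred.gebv, dtype=float)
    if top_n > len(gebv):
        import warnings
        warnings.warn(f"top_n={top_n} exceeds {len(gebv)} candidates; "
                      "returning all", RuntimeWarning, stacklevel=2)
        top_n = len(gebv)
    key = gebv if direction == "lower" else -gebv
    order = sorted(range(len(gebv)),
                   key=lambda i: (key[i], pred.sample_ids[i]))
    return [pred.sample_ids[i] for i in order[:top_n]]


def enrichment_report(candidate_scores: pd.DataFrame, selected_ids: list[str],
                      trait: str = "", direction: str = "higher",
                      scheme: LodgingCategoryScheme = LodgingCategoryScheme()
                      ) -> ScreeningResult:
    """Category proportions before and after selection, plus their deltas.

    ``candidate_scores`` needs columns ``accession`` and ``score``;
    ``selected_ids`` must be a subset of the candidates.
    """
    ids = candidate_scores["accession"].tolist()
    missing = set(selected_ids) - set(ids)
    if missing:
        raise KeyError(f"selected ids absent from candidates: "
                       f"{sorted(missing)[:5]}")
    scores = candidate_scores["score"].to_numpy()
    _, base = categorize_scores(scores, ids)
    sel_mask = candidate_scores["accession"].isin(set(selected_ids)).to_numpy()
    _, sel = categorize_scores(scores[sel_mask],
                               [i for i, m in zip(ids, sel_mask) if m])
    delta = {c: sel[c] - base[c] for c in CATEGORIES}
    return ScreeningResult(trait=trait, direction=direction,
                           top_n=len(selected_ids),
                           selected_ids=list(selected_ids),
                           base_proportions=base, selected_proportions=sel,
                           enrichment_delta=delta)
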