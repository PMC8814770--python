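"""Metagenome survey: capsid-architecture frequencies from MCP catalogs.

Given putative major capsid proteins from a metagenome (with external
function scores), the survey filters to confident MCP calls, dereplicates,
featurizes, runs the trained composition classifier, and tallies the
predicted architecture classes.  A cross-check compares genome-length-based
predictions with sequence-based ones where both are available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .g2t import GenomeToTResults
from .library import MCPEntry, dereplicate
from .rf import TClassScheme, featurize_library

logger = logging.getLogger(__name__)

__all__ = ["SurveyReport", "survey_metagenome", "genome_vs_mcp_agreement"]

MCP_CLASS_NAME = "major capsid"


@dataclass
class SurveyReport:
    """Per-class frequency table plus the highlighted top classes."""

    frequencies: pd.DataFrame  # class, count, percent
    n_input: int
    n_filtered: int
    n_dereplicated: int
    top_classes: list[dict]  # {class, percent, genome_range_kbp}

    @property
    def empty(self) -> bool:
        return self.frequencies.empty


def _is_mcp_call(predicted_class: str) -> bool:
    return MCP_CLASS_NAME in str(predicted_class).lower()


def survey_metagenome(
    entries: Sequence[MCPEntry],
    scores: pd.DataFrame | None,
    model,
    scheme: TClassScheme,
    fit: GenomeToTResults,
    score_threshold: float = 2.0,
    top_n: int = 3,
) -> SurveyReport:
    """Predict and tally capsid architectures for a metagenome MCP set.

    ``scores`` is an external function-score table with columns
    ``id, predicted_class, score``; an entry passes when its top-ranked
    class is a major-capsid call AND its score >= threshold (pass ``None``
    to disable filtering).  Survivors are dereplicated at exact sequence
    identity, featurized, and classified; the report lists per-class counts
    and percentages and annotates the most frequent classes with their
    genome-length ranges from the inverse genome-to-T map.
    """
    n_input = len(entries)
    if scores is not None:
        required = {"id", "predicted_class", "score"}
        if not required <= set(scores.columns):
            raise ValueError(f"score table needs columns {sorted(required)}")
        table = scores.drop_duplicates("id").set_index(
            scores.drop_duplicates("id")["id"].astype(str)
        )
        kept = []
        for e in entries:
            if e.id not in table.index:
                logger.warning("no function score for %s; excluded", e.id)
                continue
            row = table.loc[e.id]
            if _is_mcp_call(row["predicted_class"]) and float(row["score"]) >= score_threshold:
                kept.append(e)
    else:
        kept = list(entries)
    n_filtered = len(kept)
    if not kept:
        logger.warning("no entries passed the MCP-call and score filters")
        return SurveyReport(
            frequencies=pd.DataFrame(columns=["class", "count", "percent"]),
            n_input=n_input,
            n_filtered=0,
            n_dereplicated=0,
            top_classes=[],
        )
    kept = dereplicate(kept)
    X = featurize_library(kept)
    pred = model.predict(X)
    counts = pd.Series(pred).value_counts()
    total = int(counts.sum())
    freq = pd.DataFrame(
        {
            "class": counts.index,
            "count": counts.to_numpy(),
            "percent": 100.0 * counts.to_numpy() / total,
        }
    ).reset_index(drop=True)
    top = []
    for _, row in freq.head(top_n).iterrows():
        cls = row["class"]
        members = scheme.members(cls) if cls != scheme.elongated_class else ()
        if members:
            lo = min(fit.genome_range(m, scheme.mre)[0] for m in members)
            hi = max(fit.genome_range(m, scheme.mre)[1] for m in members)
            grange: tuple[float, float] | None = (lo, hi)
        else:
            grange = None
        top.append(
            {"class": cls, "percent": float(row["percent"]), "genome_range_kbp": grange}
        )
    return SurveyReport(
        frequencies=freq,
        n_input=n_input,
        n_filtered=n_filtered,
        n_dereplicated=len(kept),
        top_classes=top,
    )


def genome_vs_mcp_agreement(
    genome_predictions: Mapping[str, str],
    mcp_predictions: Mapping[str, str],
) -> dict:
    """Agreement between the genome-length route and the sequence route.

    Both inputs map entry id -> predicted class label over a shared id set.
    Returns per-class counts of agreeing ids and the overall agreement
    fraction.
    """
    shared = sorted(set(genome_predictions) & set(mcp_predictions))
    if not shared:
        raise ValueError("no shared ids between prediction tables")
    agree_by_class: dict[str, int] = {}
    n_agree = 0
    for i in shared:
        if genome_predictions[i] == mcp_predictions[i]:
            n_agree += 1
            agree_by_class[genome_predictions[i]] = (
                agree_by_class.get(genome_predictions[i], 0) + 1
            )
    return {
        "n_shared": len(shared),
        "n_agree": n_agree,
        "agreement_fraction": n_agree / len(shared),
        "agree_by_class": dict(sorted(agree_by_class.items())),
    }
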