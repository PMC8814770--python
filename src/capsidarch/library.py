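"""MCP/T library construction.

The library associates major capsid protein (MCP) sequences with capsid
architectures (T-numbers).  Candidate MCPs are pulled from annotated phage
genomes by product keyword, filtered by an external structural-function
confidence score, dereplicated at exact sequence identity, and labeled:
phages with a solved capsid structure get the structural T-number, all
others get the genome-to-T prediction (possibly the "elongated" fallback).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .g2t import ELONGATED, CapsidRecord, GenomeToTResults
from .lattice import LatticeArchitecture

logger = logging.getLogger(__name__)

__all__ = [
    "MCPEntry",
    "extract_mcp_candidates",
    "filter_by_function_score",
    "dereplicate",
    "build_library",
    "read_library_tsv",
    "write_library_tsv",
    "read_scores_tsv",
]

#: default product keyword for candidate selection
MCP_KEYWORD = "major capsid"
#: default function-score cutoff (~98% true-positive confidence)
SCORE_THRESHOLD = 2.0


@dataclass(frozen=True)
class MCPEntry:
    """An MCP sequence with its genome context and (eventual) T label."""

    id: str
    phage_name: str
    sequence: str
    genome_kbp: float
    t_label: float | str | None = None  # numeric T, "elongated", or unlabeled
    label_source: str | None = None  # "structure" | "g2t"
    lattice: str | None = None
    alt_labels: tuple[float, ...] = ()
    function_score: float | None = None
    hk97_validated: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")


def extract_mcp_candidates(
    genome_records: Iterable, keyword: str = MCP_KEYWORD
) -> list[MCPEntry]:
    """Select CDS features whose ``/product`` contains ``keyword``
    (case-insensitive substring) from annotated genome records.

    ``genome_records`` are Biopython ``SeqRecord`` objects as parsed from
    GenBank flat files; genome length is the record length in bp / 1000.
    CDS features lacking a ``/translation`` are skipped with a warning.
    """
    kw = keyword.lower()
    out: list[MCPEntry] = []
    for rec in genome_records:
        genome_kbp = len(rec.seq) / 1000.0
        cds = [f for f in rec.features if f.type == "CDS"]
        if not cds:
            logger.warning("record %s has no CDS features", rec.id)
            continue
        hit_index = 0
        for feat in cds:
            products = feat.qualifiers.get("product", [])
            if not any(kw in p.lower() for p in products):
                continue
            translations = feat.qualifiers.get("translation", [])
            if not translations:
                logger.warning(
                    "record %s: CDS %r matches keyword but has no translation; skipped",
                    rec.id,
                    products[0] if products else "?",
                )
                continue
            hit_index += 1
            entry_id = f"{rec.id}_mcp{hit_index}" if hit_index > 1 else f"{rec.id}_mcp"
            out.append(
                MCPEntry(
                    id=entry_id,
                    phage_name=rec.id,
                    sequence=str(translations[0]).rstrip("*"),
                    genome_kbp=genome_kbp,
                )
            )
    return out


def filter_by_function_score(
    entries: Sequence[MCPEntry],
    scores: Mapping[str, float],
    threshold: float = SCORE_THRESHOLD,
) -> list[MCPEntry]:
    """Keep entries with external function score >= ``threshold``
    (boundary inclusive); entries missing from the score table are excluded
    with a warning."""
    kept = []
    for e in entries:
        score = scores.get(e.id)
        if score is None:
            logger.warning("entry %s has no function score; excluded", e.id)
            continue
        if score >= threshold:
            kept.append(replace(e, function_score=float(score)))
    return kept


def dereplicate(entries: Sequence[MCPEntry]) -> list[MCPEntry]:
    """One representative per identical amino-acid sequence, first by
    input order."""
    seen: set[str] = set()
    out = []
    for e in entries:
        if e.sequence in seen:
            continue
        seen.add(e.sequence)
        out.append(e)
    removed = len(entries) - len(out)
    if removed:
        logger.info("dereplication removed %d duplicate sequence(s)", removed)
    return out


def build_library(
    entries: Sequence[MCPEntry],
    high_res_records: Sequence[CapsidRecord],
    fit: GenomeToTResults,
    mre: float,
    architectures: Sequence[LatticeArchitecture] | None = None,
) -> list[MCPEntry]:
    """Attach T labels: structural labels (matched by phage name,
    case-insensitive) take precedence; all other entries are labeled through
    the genome-to-T assignment, recording alternative candidate T-numbers.
    Entries with unknown genome length are rejected."""
    by_name = {r.phage_name.lower(): r for r in high_res_records}
    out = []
    n_structure = n_g2t = 0
    for e in entries:
        if e.genome_kbp is None or not e.genome_kbp > 0:
            raise ValueError(f"entry {e.id}: unknown or non-positive genome length")
        hr = by_name.get(e.phage_name.lower())
        if hr is not None:
            out.append(
                replace(
                    e,
                    t_label=hr.t_value,
                    lattice=hr.lattice,
                    label_source="structure",
                    alt_labels=(),
                )
            )
            n_structure += 1
            continue
        assignment = fit.assign(e.genome_kbp, mre, architectures)
        if assignment.is_elongated:
            label: float | str = ELONGATED
            lattice = None
        else:
            label = assignment.selected.t_float
            lattice = assignment.selected.lattice
        out.append(
            replace(
                e,
                t_label=label,
                lattice=lattice,
                label_source="g2t",
                alt_labels=tuple(a.t_float for a in assignment.alternatives),
            )
        )
        n_g2t += 1
    logger.info(
        "library: %d entries (%d structure-labeled, %d model-labeled)",
        len(out),
        n_structure,
        n_g2t,
    )
    return out


# ---------------------------------------------------------------------------
# TSV I/O


def write_library_tsv(entries: Sequence[MCPEntry], path) -> None:
    rows = []
    for e in entries:
        rows.append(
            {
                "id": e.id,
                "phage": e.phage_name,
                "genome_kbp": e.genome_kbp,
                "sequence": e.sequence,
                "t_label": e.t_label,
                "lattice": e.lattice or "",
                "label_source": e.label_source or "",
                "alt_labels": ",".join(f"{t:g}" for t in e.alt_labels),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_library_tsv(path) -> list[MCPEntry]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for _, row in df.iterrows():
        t_label: float | str | None
        raw = row.get("t_label", "")
        if raw == "" or raw is None:
            t_label = None
        elif raw == ELONGATED:
            t_label = ELONGATED
        else:
            t_label = float(raw)
        alt = tuple(
            float(x) for x in str(row.get("alt_labels", "")).split(",") if x.strip()
        )
        out.append(
            MCPEntry(
                id=row["id"],
                phage_name=row["phage"],
                sequence=row["sequence"],
                genome_kbp=float(row["genome_kbp"]),
                t_label=t_label,
                label_source=row.get("label_source") or None,
                lattice=row.get("lattice") or None,
                alt_labels=alt,
            )
        )
    return out


def read_scores_tsv(path) -> dict[str, float]:
    """Read an external function-score table: ``id  predicted_class  score``.
    Returns scores for entries whose top-ranked class is an MCP call."""
    df = pd.read_csv(path, sep="\t")
    required = {"id", "score"}
    if not required <= set(df.columns):
        raise ValueError(f"score table must have columns {sorted(required)}")
    return dict(zip(df["id"].astype(str), df["score"].astype(float)))
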