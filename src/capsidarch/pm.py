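"""Nearest-neighbour T-number prediction from MCP sequence similarity.

The proximity-matrix (PM) model predicts a query MCP's capsid architecture
as the architecture of its most similar library MCP, subject to a minimum
percent-similarity threshold.  Similarities come either from an external
all-vs-all blastp tabular file (percent identity, symmetrized by maximum)
or from the built-in local aligner, a self-contained approximation of
blastp percent identity (BLOSUM62, affine gaps 11/1, identities over
alignment length).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .g2t import ELONGATED
from .library import MCPEntry

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityMatrix",
    "load_similarity",
    "align_similarity",
    "predict_nearest",
    "evaluate_pm",
    "t_difference_by_bin",
]

EVALUE_THRESHOLD = 1e-3

# Karlin-Altschul parameters for BLOSUM62 with gap costs 11/1 (as reported
# by NCBI blastp); used by the internal aligner to emulate the e-value
# filter so short spurious high-identity islands are not recorded.
KA_LAMBDA = 0.267
KA_K = 0.041

BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


class SimilarityMatrix:
    """Symmetric percent-similarity map over a set of sequence ids.

    Absent pairs are NaN.  When several scores exist for a pair the maximum
    is kept.  ``n_ops`` counts pairwise computations performed to build the
    matrix (used for scaling diagnostics).
    """

    def __init__(self, ids: Sequence[str]):
        self.ids = list(ids)
        self.index = {x: i for i, x in enumerate(self.ids)}
        if len(self.index) != len(self.ids):
            raise ValueError("duplicate ids in similarity matrix")
        n = len(self.ids)
        self.values = np.full((n, n), np.nan)
        self.n_ops = 0

    def record(self, a: str, b: str, similarity: float) -> None:
        """Insert a score, keeping the max and mirroring for symmetry."""
        i, j = self.index[a], self.index[b]
        cur = self.values[i, j]
        if np.isnan(cur) or similarity > cur:
            self.values[i, j] = self.values[j, i] = similarity

    def sim(self, a: str, b: str) -> float:
        return float(self.values[self.index[a], self.index[b]])

    def submatrix_max(
        self, query_idx: np.ndarray, train_idx: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-query best similarity and argmax over a train subset
        (NaN-safe; queries with no scored train pair get -inf)."""
        block = self.values[np.ix_(query_idx, train_idx)]
        filled = np.where(np.isnan(block), -np.inf, block)
        return filled.max(axis=1), filled.argmax(axis=1)


def load_similarity(path) -> SimilarityMatrix:
    """Read a 12-column blast tabular (outfmt 6) file into a similarity
    matrix: rows with evalue > 1e-3 are dropped, pident is the percent
    similarity, and pairs are symmetrized by maximum."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(BLAST_COLUMNS):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(BLAST_COLUMNS)} "
                    f"tab-separated fields, got {len(parts)}"
                )
            try:
                pident = float(parts[2])
                evalue = float(parts[10])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            if evalue > EVALUE_THRESHOLD:
                continue
            rows.append((parts[0], parts[1], pident))
    ids = sorted({r[0] for r in rows} | {r[1] for r in rows})
    matrix = SimilarityMatrix(ids)
    for a, b, pident in rows:
        matrix.record(a, b, pident)
    return matrix


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _percent_identity(alignment) -> float:
    a, b = alignment[0], alignment[1]
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    aln_len = len(a)
    return 100.0 * matches / aln_len if aln_len else 0.0


def align_similarity(
    sequences: Mapping[str, str], evalue: float = EVALUE_THRESHOLD
) -> SimilarityMatrix:
    """All-vs-all local-alignment percent identity over the given sequences.

    An approximation of blastp percent identity: Smith-Waterman with
    BLOSUM62 and affine gap penalties 11 (open) / 1 (extend); identity is
    counted over the alignment length.  Pairs whose best local alignment
    scores <= 0, or whose Karlin-Altschul e-value exceeds ``evalue``
    (default 1e-3, matching the tabular loader), are left absent — this is
    what suppresses short spurious perfect-identity islands between
    unrelated sequences.  Cost is quadratic in the number of sequences
    (tracked in ``n_ops``).
    """
    ids = list(sequences)
    if len(ids) < 2:
        raise ValueError("need at least 2 sequences")
    for name, seq in sequences.items():
        if not seq:
            raise ValueError(f"empty sequence for {name!r}")
    aligner = _make_aligner()
    matrix = SimilarityMatrix(ids)
    for i, a in enumerate(ids):
        matrix.record(a, a, 100.0)
        for b in ids[i + 1 :]:
            matrix.n_ops += 1
            try:
                score = aligner.score(sequences[a], sequences[b])
            except ValueError:  # residues outside the matrix alphabet
                continue
            if score <= 0:
                continue
            e_value = (
                KA_K * len(sequences[a]) * len(sequences[b])
                * np.exp(-KA_LAMBDA * score)
            )
            if e_value > evalue:
                continue
            alignment = aligner.align(sequences[a], sequences[b])[0]
            matrix.record(a, b, _percent_identity(alignment))
    return matrix


def _label_sort_key(label, entry_id: str):
    """Deterministic tie-break: numeric T ascending, then 'elongated',
    then id lexicographically."""
    if isinstance(label, str):
        return (1, 0.0, entry_id)
    return (0, float(label), entry_id)


def predict_nearest(
    matrix: SimilarityMatrix,
    train_labels: Mapping[str, float | str],
    query_id: str,
    min_similarity: float = 0.0,
):
    """Label of the most similar train entry with similarity >=
    ``min_similarity`` percent, or None (no call) when none qualifies.
    Exact ties are broken toward the smaller T label, then the smaller id.
    """
    if query_id in train_labels:
        raise ValueError(f"query {query_id!r} is in the training set")
    best_sim = -np.inf
    best: tuple | None = None
    for train_id, label in train_labels.items():
        s = matrix.values[matrix.index[query_id], matrix.index[train_id]]
        if np.isnan(s) or s < min_similarity:
            continue
        key = _label_sort_key(label, train_id)
        if s > best_sim or (s == best_sim and (best is None or key < best)):
            best_sim = s
            best = key
    if best is None:
        return None
    kind, value, _ = best
    return ELONGATED if kind == 1 else value


def evaluate_pm(
    library: Sequence[MCPEntry],
    matrix: SimilarityMatrix,
    n_splits: int = 1000,
    thresholds: Sequence[float] = tuple(range(0, 101, 10)),
    seed: int | None = None,
    test_fraction: float = 0.2,
) -> pd.DataFrame:
    """Coverage and accuracy of nearest-neighbour prediction over repeated
    random train/test splits, per minimum-similarity threshold.

    coverage = calls / test size; accuracy = correct calls / calls (NaN
    when no calls were made at a threshold — never reported as 0).
    """
    ids = [e.id for e in library]
    labels = {e.id: e.t_label for e in library}
    missing = [i for i in ids if i not in matrix.index]
    if missing:
        raise ValueError(f"library ids absent from similarity matrix: {missing[:5]}")
    idx = np.array([matrix.index[i] for i in ids])
    lab_num = np.array(
        [np.nan if isinstance(labels[i], str) else float(labels[i]) for i in ids]
    )
    lab_is_elong = np.array([isinstance(labels[i], str) for i in ids])

    rng = np.random.default_rng(seed)
    n = len(ids)
    n_test = max(1, int(round(test_fraction * n)))
    calls = {th: 0 for th in thresholds}
    correct = {th: 0 for th in thresholds}
    total_test = 0
    for _ in range(n_splits):
        perm = rng.permutation(n)
        test, train = perm[:n_test], perm[n_test:]
        total_test += test.size
        best_sim, best_arg = matrix.submatrix_max(idx[test], idx[train])
        pred_pos = train[best_arg]
        for th in thresholds:
            called = best_sim >= th
            calls[th] += int(called.sum())
            ok = called & (
                (lab_is_elong[test] & lab_is_elong[pred_pos])
                | (
                    ~lab_is_elong[test]
                    & ~lab_is_elong[pred_pos]
                    & (lab_num[test] == lab_num[pred_pos])
                )
            )
            correct[th] += int(ok.sum())
    rows = []
    for th in thresholds:
        rows.append(
            {
                "threshold": th,
                "fraction_predicted": calls[th] / total_test,
                "accuracy": (correct[th] / calls[th]) if calls[th] else np.nan,
                "n_calls": calls[th],
            }
        )
    return pd.DataFrame(rows)


def t_difference_by_bin(
    library: Sequence[MCPEntry],
    matrix: SimilarityMatrix,
    bin_edges: Sequence[float] = (0, 20, 40, 60, 80, 100),
) -> pd.DataFrame:
    """Relative T-number difference between MCP pairs, summarized per
    similarity bin.

    For a pair (i, j) the relative difference is ``|T_i - T_j| /
    min(T_i, T_j)`` (the smaller T as denominator, so the ratio is
    unbounded above).  Pairs involving an elongated label are skipped.
    Bins are ``[lo, hi)`` except the last, which is ``[lo, hi]``.
    """
    edges = list(bin_edges)
    if edges[0] > 0 or edges[-1] < 100:
        raise ValueError("bin edges must cover [0, 100]")
    numeric = [e for e in library if not isinstance(e.t_label, str)]
    sims, diffs = [], []
    for i, a in enumerate(numeric):
        for b in numeric[i + 1 :]:
            s = matrix.values[matrix.index[a.id], matrix.index[b.id]]
            if np.isnan(s):
                continue
            ta, tb = float(a.t_label), float(b.t_label)
            sims.append(s)
            diffs.append(abs(ta - tb) / min(ta, tb))
    sims_arr, diffs_arr = np.asarray(sims), np.asarray(diffs)
    rows = []
    for lo, hi in zip(edges, edges[1:]):
        if hi == edges[-1]:
            sel = (sims_arr >= lo) & (sims_arr <= hi)
        else:
            sel = (sims_arr >= lo) & (sims_arr < hi)
        d = diffs_arr[sel]
        rows.append(
            {
                "bin_lo": lo,
                "bin_hi": hi,
                "n_pairs": int(sel.sum()),
                "mean": float(d.mean()) if d.size else np.nan,
                "min": float(d.min()) if d.size else np.nan,
                "q25": float(np.quantile(d, 0.25)) if d.size else np.nan,
                "median": float(np.median(d)) if d.size else np.nan,
                "q75": float(np.quantile(d, 0.75)) if d.size else np.nan,
                "max": float(d.max()) if d.size else np.nan,
            }
        )
    return pd.DataFrame(rows)
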