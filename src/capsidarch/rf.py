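"""Random-forest prediction of capsid architecture from MCP composition.

The model maps 22 sequence features — residue count, isoelectric point and
the 20 canonical amino-acid frequencies — to T-number classes.  Classes are
built from the genome-to-T model: T-numbers whose predicted genome-length
ranges overlap are merged into one class (the model cannot tell them apart
from genome length, so the label distinction is not trustworthy), all
T >= 25 architectures form a single "jumbo" class (too few large genomes to
resolve), and "elongated" is its own class.

A prediction is scored correct when the predicted class contains a member T
within the genome-to-T error margin (default 9%) of the entry's library T;
elongated predictions must match exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.ensemble import RandomForestClassifier

from .g2t import ELONGATED, GenomeToTResults
from .lattice import LatticeArchitecture, format_t
from .library import MCPEntry

logger = logging.getLogger(__name__)

__all__ = [
    "AMINO_ACIDS",
    "FEATURE_NAMES",
    "FeatureVector",
    "compute_features",
    "isoelectric_point",
    "load_pka_table",
    "TClass",
    "TClassScheme",
    "build_class_scheme",
    "RFHyperparams",
    "train_classifier",
    "featurize_library",
    "evaluate_classifier",
    "accuracy_vs_size",
    "LogAccuracyModel",
    "LogAccuracyResults",
    "fit_log_accuracy",
    "feature_analysis",
    "clade_feature_profile",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
FEATURE_NAMES = ["length", "pI"] + [f"freq_{aa}" for aa in AMINO_ACIDS]

JUMBO_T_MIN = 25.0


# ---------------------------------------------------------------------------
# features


def load_pka_table() -> dict[str, tuple[float, int]]:
    """The packaged Bjellqvist pKa set: group -> (pKa, charge sign)."""
    path = resources.files("capsidarch.data") / "pka_bjellqvist.tsv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    return {
        str(row["group"]): (float(row["pka"]), int(row["sign"]))
        for _, row in df.iterrows()
    }


def _net_charge(ph: float, counts: Mapping[str, int], pka: Mapping[str, tuple[float, int]]) -> float:
    charge = 0.0
    for group, (pk, sign) in pka.items():
        n = 1 if group in ("Nterm", "Cterm") else counts.get(group, 0)
        if n == 0:
            continue
        if sign > 0:
            charge += n / (1 + 10 ** (ph - pk))
        else:
            charge -= n / (1 + 10 ** (pk - ph))
    return charge


def isoelectric_point(
    sequence: str,
    pka_table: Mapping[str, tuple[float, int]] | None = None,
    tol: float = 1e-4,
) -> float:
    """pH of zero net charge, by bisection on [0, 14].

    The net charge sums the protonated fraction of the positive groups
    (N-terminus, K, R, H), ``1 / (1 + 10**(pH - pKa))``, minus the
    deprotonated fraction of the negative groups (C-terminus, D, E, C, Y),
    ``1 / (1 + 10**(pKa - pH))``; pKa values are the packaged Bjellqvist
    set.  Non-canonical residues contribute no ionizable group.
    """
    if not sequence:
        raise ValueError("empty sequence")
    pka = pka_table if pka_table is not None else load_pka_table()
    counts = {aa: sequence.upper().count(aa) for aa in "KRHDECY"}
    lo, hi = 0.0, 14.0
    # charge is monotone decreasing in pH
    for _ in range(100):
        mid = (lo + hi) / 2
        c = _net_charge(mid, counts, pka)
        if abs(c) < tol:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


@dataclass(frozen=True)
class FeatureVector:
    """The 22-feature representation of one MCP sequence."""

    length: int
    pI: float
    aa_freq: dict

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.length, self.pI] + [self.aa_freq[aa] for aa in AMINO_ACIDS]
        )


def compute_features(sequence: str) -> FeatureVector:
    """Residue count, isoelectric point, and amino-acid frequencies.

    Length and frequencies are computed over canonical residues only;
    ambiguity codes (X, B, Z, ...) are excluded from both numerator and
    denominator, with a logged count.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    counts = {aa: seq.count(aa) for aa in AMINO_ACIDS}
    n_canonical = sum(counts.values())
    n_ambiguous = len(seq) - n_canonical
    if n_ambiguous:
        logger.info("%d non-canonical residue(s) excluded from features", n_ambiguous)
    if n_canonical == 0:
        raise ValueError("sequence has no canonical residues")
    freq = {aa: c / n_canonical for aa, c in counts.items()}
    return FeatureVector(
        length=n_canonical, pI=isoelectric_point(seq), aa_freq=freq
    )


def featurize_library(entries: Sequence[MCPEntry]) -> np.ndarray:
    """Feature matrix (n_entries x 22) in ``FEATURE_NAMES`` order."""
    return np.vstack([compute_features(e.sequence).to_array() for e in entries])


# ---------------------------------------------------------------------------
# class scheme


@dataclass(frozen=True)
class TClass:
    class_id: str
    member_t_values: tuple[float, ...]
    genome_range: tuple[float, float] | None = None


@dataclass
class TClassScheme:
    """Partition of T labels into classifier classes."""

    classes: list[TClass]
    jumbo_class: str
    elongated_class: str
    mre: float

    def class_for(self, t_label: float | str) -> str:
        if isinstance(t_label, str):
            return self.elongated_class
        t = float(t_label)
        if t >= JUMBO_T_MIN:
            return self.jumbo_class
        # labels may be rounded to 2 decimals (9.33 for 28/3): match the
        # nearest member within 0.5% relative tolerance
        best: tuple[float, str] | None = None
        for cls in self.classes:
            for m in cls.member_t_values:
                d = abs(t - m)
                if best is None or d < best[0]:
                    best = (d, cls.class_id)
        if best is not None and best[0] <= 5e-3 * t:
            return best[1]
        raise KeyError(f"T={t} is not covered by the class scheme")

    def members(self, class_id: str) -> tuple[float, ...]:
        for cls in self.classes:
            if cls.class_id == class_id:
                return cls.member_t_values
        raise KeyError(class_id)

    def is_correct(
        self, predicted_class: str, true_label: float | str, margin: float | None = None
    ) -> bool:
        """Correctness rule: elongated must match exactly; otherwise the
        predicted class must contain a member T within ``margin`` (default
        the scheme's MRE) of the entry's library T."""
        margin = self.mre if margin is None else margin
        if isinstance(true_label, str):
            return predicted_class == self.elongated_class
        if predicted_class == self.elongated_class:
            return False
        t = float(true_label)
        return any(
            abs(m - t) <= margin * t for m in self.members(predicted_class)
        )

    def representative_t(self, class_id: str, reference: float | None = None) -> float | str:
        """A display T for the class: the member closest to ``reference``
        (or the smallest member)."""
        if class_id == self.elongated_class:
            return ELONGATED
        ms = self.members(class_id)
        if reference is None:
            return min(ms)
        return min(ms, key=lambda m: abs(m - reference))


def _class_id_for(members: Sequence[float]) -> str:
    labels = sorted(set(members))
    if len(labels) == 1:
        return f"T={format_t(labels[0])}"
    return "T=" + "-".join(format_t(m) for m in labels)


def build_class_scheme(
    architectures: Sequence[LatticeArchitecture],
    fit: GenomeToTResults,
    mre: float,
) -> TClassScheme:
    """Build classifier classes from the genome-to-T model.

    Distinct T-values below the jumbo cutoff whose predicted genome-length
    intervals overlap transitively are merged into one class; all
    T >= 25 values are collapsed into the jumbo class; an elongated class
    is always present.
    """
    t_values = sorted({a.t_float for a in architectures if a.t_float >= 1})
    small = [t for t in t_values if t < JUMBO_T_MIN]
    jumbo = [t for t in t_values if t >= JUMBO_T_MIN]

    ranges = {t: fit.genome_range(t, mre) for t in small}
    classes: list[TClass] = []
    group: list[float] = []
    group_hi = -np.inf
    for t in small:  # ascending T means ascending genome ranges
        lo, hi = ranges[t]
        if group and lo <= group_hi:
            group.append(t)
            group_hi = max(group_hi, hi)
        else:
            if group:
                classes.append(_close_group(group, ranges))
            group = [t]
            group_hi = hi
    if group:
        classes.append(_close_group(group, ranges))

    jumbo_id = f"T>={format_t(JUMBO_T_MIN)}"
    if jumbo:
        jlo = min(fit.genome_range(t, mre)[0] for t in jumbo)
        jhi = max(fit.genome_range(t, mre)[1] for t in jumbo)
        classes.append(TClass(jumbo_id, tuple(jumbo), (jlo, jhi)))
    else:
        classes.append(TClass(jumbo_id, (JUMBO_T_MIN,), None))
    elong_id = ELONGATED
    classes.append(TClass(elong_id, (), None))
    return TClassScheme(
        classes=classes, jumbo_class=jumbo_id, elongated_class=elong_id, mre=mre
    )


def _close_group(group: list[float], ranges: dict) -> TClass:
    lo = min(ranges[t][0] for t in group)
    hi = max(ranges[t][1] for t in group)
    return TClass(_class_id_for(group), tuple(group), (lo, hi))


# ---------------------------------------------------------------------------
# random forest


@dataclass(frozen=True)
class RFHyperparams:
    """Forest settings; defaults are the selected configuration."""

    n_estimators: int = 250
    max_features: int = 4
    max_depth: int = 20
    min_samples_leaf: int = 1
    min_samples_split: int = 46
    bootstrap: bool = True
    class_weight: str = "balanced"

    def to_sklearn(self, seed: int | None) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
            min_samples_split=self.min_samples_split,
            bootstrap=self.bootstrap,
            class_weight=self.class_weight,
            random_state=seed,
        )


def train_classifier(
    features: np.ndarray,
    class_labels: Sequence[str],
    hyperparams: RFHyperparams | None = None,
    seed: int | None = None,
) -> RandomForestClassifier:
    """Fit a seeded random forest over the 22-feature matrix."""
    labels = np.asarray(class_labels)
    if np.unique(labels).size < 2:
        raise ValueError("training set contains a single class")
    X = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    hp = hyperparams or RFHyperparams()
    model = hp.to_sklearn(seed)
    model.fit(X, labels)
    return model


def evaluate_classifier(
    library: Sequence[MCPEntry],
    scheme: TClassScheme,
    hyperparams: RFHyperparams | None = None,
    n_splits: int = 1000,
    seed: int | None = None,
    test_fraction: float = 0.2,
    features: np.ndarray | None = None,
    max_resample: int = 50,
) -> dict:
    """Repeated random-split evaluation of the forest under the class scheme.

    Returns overall accuracy (mean, sd over splits), per-class accuracy,
    and the 2x2 morphology (icosahedral vs elongated) confusion matrix as
    row-normalized percentages (mean and sd).  A split whose training part
    misses a class is resampled (logged).
    """
    X = features if features is not None else featurize_library(library)
    true_labels = [e.t_label for e in library]
    y = np.array([scheme.class_for(t) for t in true_labels])
    is_elong = np.array([isinstance(t, str) for t in true_labels])
    n = len(library)
    n_test = max(1, int(round(test_fraction * n)))
    n_classes_total = np.unique(y).size
    rng = np.random.default_rng(seed)

    overall, morph_rows = [], []
    per_class_hits: dict[str, list] = {}
    for _ in range(n_splits):
        for attempt in range(max_resample):
            perm = rng.permutation(n)
            test, train = perm[:n_test], perm[n_test:]
            if np.unique(y[train]).size == n_classes_total:
                break
            logger.info("split missing a class in training; resampled")
        model = train_classifier(
            X[train], y[train], hyperparams, seed=int(rng.integers(2**31))
        )
        pred = model.predict(X[test])
        correct = np.array(
            [scheme.is_correct(p, true_labels[i]) for p, i in zip(pred, test)]
        )
        overall.append(correct.mean())
        for cls in np.unique(y[test]):
            sel = y[test] == cls
            per_class_hits.setdefault(cls, []).append(float(correct[sel].mean()))
        pred_elong = pred == scheme.elongated_class
        te_elong = is_elong[test]
        row = {}
        for true_e, name in ((False, "icosahedral"), (True, ELONGATED)):
            sel = te_elong == true_e
            if sel.sum():
                row[f"{name}_as_icosahedral"] = 100.0 * float(
                    (~pred_elong[sel]).mean()
                )
                row[f"{name}_as_elongated"] = 100.0 * float(pred_elong[sel].mean())
        morph_rows.append(row)

    morph = pd.DataFrame(morph_rows)
    return {
        "overall_accuracy": float(np.mean(overall)),
        "overall_sd": float(np.std(overall, ddof=1)) if len(overall) > 1 else 0.0,
        "per_class_accuracy": {
            cls: float(np.mean(v)) for cls, v in sorted(per_class_hits.items())
        },
        "morphology_confusion_mean": morph.mean().to_dict(),
        "morphology_confusion_sd": (
            morph.std(ddof=1).to_dict() if len(morph) > 1 else {c: 0.0 for c in morph}
        ),
        "n_splits": n_splits,
    }


def accuracy_vs_size(
    library: Sequence[MCPEntry],
    scheme: TClassScheme,
    hyperparams: RFHyperparams | None = None,
    n_splits_per_size: int = 1000,
    seed: int | None = None,
    sizes: Sequence[int] | None = None,
    features: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean held-out accuracy as a function of training-set size.

    Default sizes are ``n_lib * i/20`` for i = 1..19; for each size the
    library is split into a random training set of that size and the rest
    as test, repeated ``n_splits_per_size`` times.
    """
    n = len(library)
    if n < 40:
        raise ValueError("library too small for a size sweep (need >= 40)")
    X = features if features is not None else featurize_library(library)
    true_labels = [e.t_label for e in library]
    y = np.array([scheme.class_for(t) for t in true_labels])
    if sizes is None:
        sizes = sorted({max(2, int(round(n * i / 20))) for i in range(1, 20)})
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        accs = []
        for _ in range(n_splits_per_size):
            perm = rng.permutation(n)
            train, test = perm[:size], perm[size:]
            if np.unique(y[train]).size < 2:
                continue
            model = train_classifier(
                X[train], y[train], hyperparams, seed=int(rng.integers(2**31))
            )
            pred = model.predict(X[test])
            accs.append(
                float(
                    np.mean(
                        [
                            scheme.is_correct(p, true_labels[i])
                            for p, i in zip(pred, test)
                        ]
                    )
                )
            )
        rows.append(
            {
                "n": size,
                "mean_accuracy": float(np.mean(accs)),
                "sd": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


class LogAccuracyModel:
    """Logarithmic accuracy-scaling model ``ACC(n) = g*log10(n) + h``."""

    def __init__(self, n: Sequence[float], accuracy: Sequence[float]):
        self.n = np.asarray(n, dtype=float)
        self.accuracy = np.asarray(accuracy, dtype=float)
        if self.n.size < 2:
            raise ValueError("need at least 2 points")

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "LogAccuracyModel":
        return cls(table["n"].to_numpy(), table["mean_accuracy"].to_numpy())

    def fit(self, loss: str = "soft_l1") -> "LogAccuracyResults":
        log_n = np.log10(self.n)
        acc = self.accuracy
        slope0, inter0 = np.polyfit(log_n, acc, 1)

        def resid(theta):
            return theta[0] * log_n + theta[1] - acc

        sol = least_squares(resid, np.array([slope0, inter0]), loss=loss)
        if not sol.success:
            raise RuntimeError(f"accuracy-scaling fit failed: {sol.message}")
        g, h = sol.x
        fitted = g * log_n + h
        ss_res = float(np.sum((acc - fitted) ** 2))
        ss_tot = float(np.sum((acc - acc.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return LogAccuracyResults(model=self, g=float(g), h=float(h), r2=r2)


@dataclass
class LogAccuracyResults:
    model: LogAccuracyModel | None
    g: float
    h: float
    r2: float
    ci_g: tuple[float, float] | None = None
    ci_h: tuple[float, float] | None = None

    def predict(self, n) -> float | np.ndarray:
        n_arr = np.asarray(n, dtype=float)
        out = self.g * np.log10(n_arr) + self.h
        return float(out) if np.isscalar(n) else out

    def n_for(self, target_accuracy: float) -> float:
        """Training size at which the fitted curve reaches the target:
        ``n = 10**((A - h) / g)``."""
        return float(10 ** ((target_accuracy - self.h) / self.g))

    def bootstrap_ci(
        self, n_boot: int = 10_000, seed: int | None = None, level: float = 0.95
    ) -> "LogAccuracyResults":
        if self.model is None:
            raise ValueError("bootstrap requires the fitted model's data")
        rng = np.random.default_rng(seed)
        pts = self.model.n.size
        draws = []
        for _ in range(n_boot):
            idx = rng.integers(0, pts, size=pts)
            if np.unique(self.model.n[idx]).size < 2:
                continue
            res = LogAccuracyModel(self.model.n[idx], self.model.accuracy[idx]).fit()
            draws.append((res.g, res.h))
        arr = np.asarray(draws)
        alpha = (1 - level) / 2
        qs = np.quantile(arr, [alpha, 1 - alpha], axis=0)
        self.ci_g = (float(qs[0, 0]), float(qs[1, 0]))
        self.ci_h = (float(qs[0, 1]), float(qs[1, 1]))
        return self


def fit_log_accuracy(table: pd.DataFrame, loss: str = "soft_l1") -> LogAccuracyResults:
    return LogAccuracyModel.from_table(table).fit(loss=loss)


# ---------------------------------------------------------------------------
# feature diagnostics


def feature_analysis(
    model: RandomForestClassifier,
    X_train: np.ndarray,
    y_train: Sequence[str],
    X_test: np.ndarray,
    y_test: Sequence[str],
    mode: str = "permutation",
    hyperparams: RFHyperparams | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-feature accuracy drop under permutation or dropout.

    permutation: shuffle one test-set feature column and re-score;
    dropout: retrain without the feature and re-score.  Positive delta
    means the feature mattered.
    """
    if mode not in ("permutation", "dropout"):
        raise ValueError("mode must be 'permutation' or 'dropout'")
    rng = np.random.default_rng(seed)
    y_test_arr = np.asarray(y_test)
    base = float(np.mean(model.predict(X_test) == y_test_arr))
    rows = []
    for j, name in enumerate(FEATURE_NAMES):
        if mode == "permutation":
            X_perm = X_test.copy()
            X_perm[:, j] = rng.permutation(X_perm[:, j])
            acc = float(np.mean(model.predict(X_perm) == y_test_arr))
        else:
            keep = [c for c in range(X_train.shape[1]) if c != j]
            sub = train_classifier(
                X_train[:, keep], y_train, hyperparams, seed=int(rng.integers(2**31))
            )
            acc = float(np.mean(sub.predict(X_test[:, keep]) == y_test_arr))
        rows.append({"feature": name, "accuracy": acc, "delta": base - acc})
    out = pd.DataFrame(rows)
    out.attrs["baseline_accuracy"] = base
    out.attrs["mode"] = mode
    return out


def clade_feature_profile(
    library: Sequence[MCPEntry],
    clade_member_ids: Sequence[str],
    features: np.ndarray | None = None,
) -> pd.DataFrame:
    """Compare a clade's mean feature values against the whole library.

    A feature is flagged significant when the clade mean departs from the
    library mean by more than one library standard deviation.
    """
    ids = [e.id for e in library]
    clade = set(clade_member_ids)
    if not clade:
        raise ValueError("empty clade")
    unknown = clade - set(ids)
    if unknown:
        raise ValueError(f"clade ids not in library: {sorted(unknown)[:5]}")
    X = features if features is not None else featurize_library(library)
    mask = np.array([i in clade for i in ids])
    lib_mean = X.mean(axis=0)
    lib_sd = X.std(axis=0, ddof=0)
    clade_mean = X[mask].mean(axis=0)
    rows = []
    for j, name in enumerate(FEATURE_NAMES):
        dev = abs(clade_mean[j] - lib_mean[j])
        rows.append(
            {
                "feature": name,
                "clade_mean": float(clade_mean[j]),
                "library_mean": float(lib_mean[j]),
                "library_sd": float(lib_sd[j]),
                "significant": bool(dev > lib_sd[j]),
            }
        )
    return pd.DataFrame(rows)


def prediction_node_visits(model: RandomForestClassifier, X: np.ndarray) -> int:
    """Total decision-tree nodes visited to classify ``X`` — the
    operation-count measure of per-query prediction cost (bounded by
    n_estimators * (max_depth + 1) per query, independent of training size).
    """
    indicator, _ = model.decision_path(np.asarray(X, dtype=float))
    return int(indicator.sum())
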