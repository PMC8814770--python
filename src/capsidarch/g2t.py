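"""Allometric genome-to-T-number (G2T) model.

The triangulation number of a tailed-phage capsid scales with genome length
as a power law, ``T = b * (G / G0)**a`` with ``G0 = 1 kbp``: the genome fills
the capsid volume at near-constant density while each capsid protein covers
a near-constant patch of shell surface, so T (a surface measure) grows like
the 2/3 power of G (a volume measure).  The model is fitted by ordinary
least squares after the natural-log transform

    ln T = a * ln(G / G0) + ln b

:class:`GenomeToTModel` / :class:`GenomeToTResults` follow the familiar
model/results split: the results object carries the fitted parameters, the
T prediction, the architecture-assignment rule (with its "elongated"
fallback) and the inverse genome-range map.  The out-of-sample error of the
fit is summarized by the mean relative error (MRE) of held-out predictions
(:func:`mre_curve`), whose dependence on training size is itself modelled as
an exponential decay ``MRE(n) = p*exp(-q*n) + w`` (:class:`ErrorDecayModel`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .lattice import (
    HEXAGONAL,
    LatticeArchitecture,
    enumerate_architectures,
    format_t,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ELONGATED",
    "CapsidRecord",
    "GenomeToTModel",
    "GenomeToTResults",
    "ErrorDecayModel",
    "ErrorDecayResults",
    "ArchitectureAssignment",
    "fit_g2t",
    "predict_t",
    "assign_architecture",
    "t_to_genome_range",
    "mre_curve",
    "fit_error_decay",
    "compare_alternative_models",
    "theoretical_exponent",
]

#: sentinel label for genomes whose predicted T matches no icosahedral lattice
ELONGATED = "elongated"

G0_KBP = 1.0  # reference genome length, 1 kbp


@dataclass(frozen=True)
class CapsidRecord:
    """One phage's (T-number, genome length) pair with provenance."""

    phage_name: str
    t_value: float
    genome_kbp: float
    lattice: str | None = None
    source: str = "high_resolution"

    def __post_init__(self) -> None:
        if not self.genome_kbp > 0:
            raise ValueError(f"{self.phage_name}: genome_kbp must be > 0")
        if not self.t_value > 0:
            raise ValueError(f"{self.phage_name}: t_value must be > 0")


def records_to_frame(records: Iterable[CapsidRecord]) -> pd.DataFrame:
    recs = list(records)
    return pd.DataFrame(
        {
            "phage": [r.phage_name for r in recs],
            "t_value": [r.t_value for r in recs],
            "lattice": [r.lattice for r in recs],
            "genome_kbp": [r.genome_kbp for r in recs],
        }
    )


@dataclass
class ArchitectureAssignment:
    """A genome length's candidate T-numbers and selected architecture.

    ``candidates`` are the enumerated architectures whose T lies within
    ``t_predicted * (1 +/- mre)``; ``selected`` is the candidate closest to
    the prediction, or the string ``"elongated"`` when no icosahedral T
    falls inside the margin.
    """

    genome_kbp: float
    t_predicted: float
    delta_t: float
    candidates: list[LatticeArchitecture]
    selected: LatticeArchitecture | str
    alternatives: list[LatticeArchitecture] = field(default_factory=list)

    @property
    def is_elongated(self) -> bool:
        return isinstance(self.selected, str)

    @property
    def label(self) -> str:
        if self.is_elongated:
            return ELONGATED
        return self.selected.label

    @property
    def t_label(self) -> float | str:
        """Numeric T of the selection, or ``"elongated"``."""
        if self.is_elongated:
            return ELONGATED
        return self.selected.t_float


class GenomeToTModel:
    """OLS model of ln(T) on ln(G / 1 kbp) over capsid records.

    Parameters
    ----------
    t_values, genome_kbp : array-like
        Strictly positive observed T-numbers and genome lengths (kbp).
    names : sequence of str, optional
        Phage names, for diagnostics.
    """

    def __init__(self, t_values, genome_kbp, names: Sequence[str] | None = None):
        t = np.asarray(t_values, dtype=float)
        g = np.asarray(genome_kbp, dtype=float)
        if t.shape != g.shape or t.ndim != 1:
            raise ValueError("t_values and genome_kbp must be 1-d and equal length")
        if t.size < 3:
            raise ValueError(f"need at least 3 records to fit, got {t.size}")
        if np.any(t <= 0) or np.any(g <= 0):
            raise ValueError("T-numbers and genome lengths must be strictly positive")
        self.t_values = t
        self.genome_kbp = g
        self.names = list(names) if names is not None else None
        self.ln_g = np.log(g / G0_KBP)
        self.ln_t = np.log(t)

    @classmethod
    def from_records(cls, records: Iterable[CapsidRecord]) -> "GenomeToTModel":
        recs = list(records)
        return cls(
            [r.t_value for r in recs],
            [r.genome_kbp for r in recs],
            names=[r.phage_name for r in recs],
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        t_col: str = "t_value",
        genome_col: str = "genome_kbp",
        name_col: str | None = "phage",
    ) -> "GenomeToTModel":
        names = df[name_col].tolist() if name_col and name_col in df else None
        return cls(df[t_col].to_numpy(), df[genome_col].to_numpy(), names=names)

    def fit(self) -> "GenomeToTResults":
        """Ordinary least squares in ln-ln space (deterministic)."""
        x, y = self.ln_g, self.ln_t
        n = x.size
        xm, ym = x.mean(), y.mean()
        sxx = np.sum((x - xm) ** 2)
        if sxx == 0:
            raise ValueError("all genome lengths identical: singular design")
        a = np.sum((x - xm) * (y - ym)) / sxx
        ln_b = ym - a * xm
        resid = y - (a * x + ln_b)
        ss_res = np.sum(resid**2)
        ss_tot = np.sum((y - ym) ** 2)
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        # standard error of the slope, for the +/- on the exponent
        sigma2 = ss_res / (n - 2) if n > 2 else 0.0
        a_se = float(np.sqrt(sigma2 / sxx))
        return GenomeToTResults(
            model=self, a=float(a), ln_b=float(ln_b), r2=float(r2),
            n=int(n), residuals_ln=resid, a_se=a_se,
        )


@dataclass
class GenomeToTResults:
    """Fitted allometric parameters: ``T = b * (G/G0)**a``."""

    model: GenomeToTModel | None
    a: float
    ln_b: float
    r2: float
    n: int
    residuals_ln: np.ndarray
    a_se: float = float("nan")

    @property
    def b(self) -> float:
        return float(np.exp(self.ln_b))

    def predict_t(self, genome_kbp) -> np.ndarray | float:
        """Continuous T prediction ``b * (G/G0)**a`` (direct back-transform,
        no smearing correction)."""
        g = np.asarray(genome_kbp, dtype=float)
        if np.any(g <= 0):
            raise ValueError("genome length must be positive")
        t = self.b * (g / G0_KBP) ** self.a
        return float(t) if np.isscalar(genome_kbp) else t

    def assign(
        self,
        genome_kbp: float,
        mre: float,
        architectures: Sequence[LatticeArchitecture] | None = None,
    ) -> ArchitectureAssignment:
        """Assign an icosahedral architecture (or "elongated") to a genome.

        Candidates are architectures with T in ``[T*(1-mre), T*(1+mre)]``
        where ``T`` is the continuous prediction; the selected one minimizes
        ``|T_arch - T|``.  Ties prefer the hexagonal lattice, then the
        smaller ``t0``.  An empty candidate set yields ``"elongated"``.
        """
        if not 0 < mre < 1:
            raise ValueError(f"mre must be in (0, 1), got {mre}")
        if architectures is None:
            architectures = enumerate_architectures()
        t_pred = self.predict_t(float(genome_kbp))
        lo, hi = t_pred * (1 - mre), t_pred * (1 + mre)
        candidates = [arch for arch in architectures if lo <= arch.t_float <= hi]
        if not candidates:
            selected: LatticeArchitecture | str = ELONGATED
            alternatives: list[LatticeArchitecture] = []
        else:
            selected = min(
                candidates,
                key=lambda arch: (
                    abs(arch.t_float - t_pred),
                    arch.lattice != HEXAGONAL,
                    arch.t0,
                ),
            )
            alternatives = [c for c in candidates if c is not selected]
        return ArchitectureAssignment(
            genome_kbp=float(genome_kbp),
            t_predicted=t_pred,
            delta_t=t_pred * mre,
            candidates=candidates,
            selected=selected,
            alternatives=alternatives,
        )

    def genome_range(self, t_value: float, mre: float) -> tuple[float, float]:
        """Genome interval (kbp) whose assignment margin contains ``t_value``:
        ``G in [(t/(b(1+mre)))**(1/a), (t/(b(1-mre)))**(1/a)] * G0``."""
        if not 0 < mre < 1:
            raise ValueError(f"mre must be in (0, 1), got {mre}")
        t = float(t_value)
        if t < 1:
            raise ValueError("t_value must be >= 1")
        lo = (t / (self.b * (1 + mre))) ** (1 / self.a) * G0_KBP
        hi = (t / (self.b * (1 - mre))) ** (1 / self.a) * G0_KBP
        return lo, hi

    def summary(self) -> str:
        lines = [
            "Genome-to-T allometric model (OLS on ln T vs ln G/G0, G0 = 1 kbp)",
            "=" * 66,
            f"n records          {self.n:>10d}",
            f"exponent a         {self.a:>10.4f}  +/- {self.a_se:.4f} (SE)",
            f"prefactor b        {self.b:>10.4f}  (ln b = {self.ln_b:.4f})",
            f"R^2 (ln-ln space)  {self.r2:>10.4f}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "a": self.a, "ln_b": self.ln_b, "b": self.b,
            "r2": self.r2, "n": self.n, "a_se": self.a_se,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GenomeToTResults":
        return cls(
            model=None, a=d["a"], ln_b=d["ln_b"], r2=d["r2"], n=d["n"],
            residuals_ln=np.asarray(d.get("residuals_ln", [])),
            a_se=d.get("a_se", float("nan")),
        )


# ---------------------------------------------------------------------------
# spec-op style functional facade


def fit_g2t(records: Iterable[CapsidRecord]) -> GenomeToTResults:
    """Fit the allometric model to capsid records (OLS in ln-ln space)."""
    return GenomeToTModel.from_records(records).fit()


def predict_t(fit: GenomeToTResults, genome_kbp) -> float | np.ndarray:
    return fit.predict_t(genome_kbp)


def assign_architecture(
    fit: GenomeToTResults,
    mre: float,
    genome_kbp: float,
    architectures: Sequence[LatticeArchitecture] | None = None,
) -> ArchitectureAssignment:
    return fit.assign(genome_kbp, mre, architectures)


def t_to_genome_range(
    fit: GenomeToTResults, mre: float, t_value: float
) -> tuple[float, float]:
    return fit.genome_range(t_value, mre)


def theoretical_exponent() -> float:
    """Allometric exponent implied by constant packaged-genome density and
    constant exterior surface per capsid protein.

    For a quasi-spherical shell of radius R the T-number counts surface
    patches, ``T ~ R**2``, while the packaged genome fills the volume,
    ``G ~ R**3``.  Eliminating R gives ``T ~ G**(2/3)``.
    """
    import sympy

    R = sympy.symbols("R", positive=True)
    surface_power = sympy.degree(R**2, R)  # T ∝ R^2
    volume_power = sympy.degree(R**3, R)  # G ∝ R^3
    return float(sympy.Rational(surface_power, volume_power))


# ---------------------------------------------------------------------------
# model-accuracy analysis


def _batch_ols_slopes(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise simple OLS: slopes and intercepts for each row of (x, y)."""
    xm = x.mean(axis=1, keepdims=True)
    ym = y.mean(axis=1, keepdims=True)
    sxx = np.sum((x - xm) ** 2, axis=1)
    sxy = np.sum((x - xm) * (y - ym), axis=1)
    a = sxy / sxx
    ln_b = ym[:, 0] - a * xm[:, 0]
    return a, ln_b


def mre_curve(
    records: Iterable[CapsidRecord],
    n_values: Sequence[int],
    reps: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Held-out mean relative error of the fit versus training-set size.

    For each ``n``: draw ``n`` records at random without replacement, fit,
    predict T for the remaining records, and accumulate the per-split mean
    of ``|T_pred - T_emp| / T_emp``.  Returns one row per ``n`` with the
    mean and SD of that quantity over ``reps`` splits.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    recs = list(records)
    n_total = len(recs)
    t_emp = np.array([r.t_value for r in recs])
    ln_g = np.log(np.array([r.genome_kbp for r in recs]) / G0_KBP)
    ln_t = np.log(t_emp)
    rng = np.random.default_rng(seed)
    rows = []
    for n in n_values:
        n = int(n)
        if not 2 <= n < n_total:
            raise ValueError(f"training size n={n} must be in [2, {n_total - 1}]")
        # reps independent permutations; first n columns train, rest test
        order = np.argsort(rng.random((reps, n_total)), axis=1)
        train, test = order[:, :n], order[:, n:]
        a, ln_b = _batch_ols_slopes(ln_g[train], ln_t[train])
        t_pred = np.exp(ln_b[:, None] + a[:, None] * ln_g[test])
        rel_err = np.abs(t_pred - t_emp[test]) / t_emp[test]
        per_split = rel_err.mean(axis=1)
        rows.append(
            {"n": n, "mre": float(per_split.mean()), "sd": float(per_split.std(ddof=1))}
        )
    return pd.DataFrame(rows)


class ErrorDecayModel:
    """Exponential-decay model ``MRE(n) = p*exp(-q*n) + w`` of the error
    curve, fitted by robust (soft-L1) least squares."""

    def __init__(self, n: Sequence[int], mre: Sequence[float]):
        self.n = np.asarray(n, dtype=float)
        self.mre = np.asarray(mre, dtype=float)
        if self.n.size < 4:
            raise ValueError("need at least 4 (n, MRE) points")

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "ErrorDecayModel":
        return cls(table["n"].to_numpy(), table["mre"].to_numpy())

    def fit(self, loss: str = "soft_l1") -> "ErrorDecayResults":
        n, mre = self.n, self.mre
        w0 = float(mre.min())
        p0 = max(float(mre.max() - w0), 1e-3)
        x0 = np.array([p0, 0.1, w0])

        def resid(theta):
            p, q, w = theta
            return p * np.exp(-q * n) + w - mre

        sol = least_squares(
            resid, x0, loss=loss,
            bounds=([0, 1e-8, 0], [np.inf, np.inf, np.inf]),
        )
        if not sol.success:
            raise RuntimeError(
                f"error-decay fit did not converge: {sol.message} "
                f"(status {sol.status}, final cost {sol.cost:.3g})"
            )
        p, q, w = sol.x
        fitted = p * np.exp(-q * n) + w
        ss_res = float(np.sum((mre - fitted) ** 2))
        ss_tot = float(np.sum((mre - mre.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return ErrorDecayResults(model=self, p=float(p), q=float(q), w=float(w), r2=r2)


@dataclass
class ErrorDecayResults:
    """Fitted ``MRE(n) = p*exp(-q*n) + w``; ``w`` is the asymptotic MRE."""

    model: ErrorDecayModel | None
    p: float
    q: float
    w: float
    r2: float
    ci_p: tuple[float, float] | None = None
    ci_q: tuple[float, float] | None = None
    ci_w: tuple[float, float] | None = None

    def predict(self, n) -> np.ndarray | float:
        n_arr = np.asarray(n, dtype=float)
        out = self.p * np.exp(-self.q * n_arr) + self.w
        return float(out) if np.isscalar(n) else out

    def bootstrap_ci(
        self, n_boot: int = 10_000, seed: int | None = None, level: float = 0.95
    ) -> "ErrorDecayResults":
        """Percentile bootstrap CIs for (p, q, w) by resampling the
        (n, MRE) points with replacement and refitting."""
        if self.model is None:
            raise ValueError("bootstrap requires the fitted model's data")
        rng = np.random.default_rng(seed)
        n_pts = self.model.n.size
        draws = []
        for _ in range(n_boot):
            idx = rng.integers(0, n_pts, size=n_pts)
            if np.unique(self.model.n[idx]).size < 4:
                continue
            try:
                res = ErrorDecayModel(self.model.n[idx], self.model.mre[idx]).fit()
            except (RuntimeError, ValueError):  # pragma: no cover - rare
                continue
            draws.append((res.p, res.q, res.w))
        draws_arr = np.asarray(draws)
        alpha = (1 - level) / 2
        qs = np.quantile(draws_arr, [alpha, 1 - alpha], axis=0)
        self.ci_p = (float(qs[0, 0]), float(qs[1, 0]))
        self.ci_q = (float(qs[0, 1]), float(qs[1, 1]))
        self.ci_w = (float(qs[0, 2]), float(qs[1, 2]))
        return self

    def summary(self) -> str:
        lines = [
            "Error-decay model  MRE(n) = p*exp(-q*n) + w  (robust least squares)",
            "=" * 66,
            f"p (initial excess)   {self.p:>10.4f}",
            f"q (decay rate)       {self.q:>10.4f}",
            f"w (asymptotic MRE)   {self.w:>10.4f}",
            f"R^2                  {self.r2:>10.4f}",
        ]
        for name, ci in (("p", self.ci_p), ("q", self.ci_q), ("w", self.ci_w)):
            if ci is not None:
                lines.append(f"95% CI {name}            [{ci[0]:.4f}, {ci[1]:.4f}]")
        return "\n".join(lines)


def fit_error_decay(mre_table: pd.DataFrame, loss: str = "soft_l1") -> ErrorDecayResults:
    """Fit the exponential error-decay model to an ``mre_curve`` table."""
    return ErrorDecayModel.from_table(mre_table).fit(loss=loss)


# ---------------------------------------------------------------------------
# alternative functional forms (quality control)


def compare_alternative_models(records: Iterable[CapsidRecord]) -> pd.DataFrame:
    """Least-squares fits of T vs G under alternative functional forms.

    Each form has two free parameters so the comparison is like-for-like:
    power ``b*G**a``, exponential ``b*exp(a*G)``, quadratic ``c0 + c1*G**2``,
    reciprocal ``c0 + c1/G`` and logarithmic ``c0 + c1*ln(G)``.  R^2 and the
    mean signed residual are reported on the T scale for every form.  The
    power form should attain the maximal R^2 on real capsid data.
    """
    recs = list(records)
    g = np.array([r.genome_kbp for r in recs], dtype=float)
    t = np.array([r.t_value for r in recs], dtype=float)
    if np.unique(g).size < 3:
        raise ValueError("singular design: need at least 3 distinct genome lengths")

    ln_g, ln_t = np.log(g / G0_KBP), np.log(t)

    def lin_fit(x, y):
        coef = np.polyfit(x, y, 1)
        return coef  # slope, intercept

    preds: dict[str, np.ndarray] = {}
    a, c = lin_fit(ln_g, ln_t)
    preds["power"] = np.exp(c) * (g / G0_KBP) ** a
    a, c = lin_fit(g, ln_t)
    preds["exponential"] = np.exp(c) * np.exp(a * g)
    a, c = lin_fit(g**2, t)
    preds["quadratic"] = c + a * g**2
    a, c = lin_fit(1.0 / g, t)
    preds["reciprocal"] = c + a / g
    a, c = lin_fit(ln_g, t)
    preds["logarithmic"] = c + a * ln_g

    ss_tot = float(np.sum((t - t.mean()) ** 2))
    rows = []
    for name, t_hat in preds.items():
        resid = t - t_hat
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
        rows.append(
            {"model": name, "r2": r2, "residual_bias": float(resid.mean())}
        )
    out = pd.DataFrame(rows)
    out["best"] = out["r2"] == out["r2"].max()
    return out


def load_fit_json(path) -> GenomeToTResults:
    import json

    with open(path) as fh:
        return GenomeToTResults.from_dict(json.load(fh))


def assignment_label(assignment: ArchitectureAssignment) -> str:
    """Short display label ("T=7", "T=9.33", "elongated")."""
    if assignment.is_elongated:
        return ELONGATED
    return f"T={format_t(assignment.selected.t_value)}"
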