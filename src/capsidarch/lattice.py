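"""Icosahedral capsid lattice enumeration.

Tailed-phage capsids organize their major capsid proteins (MCPs) on one of
two icosahedral surface lattices.  On the classic *hexagonal* lattice the
triangulation number is the Caspar-Klug index ``T0 = h^2 + h*k + k^2`` and
the shell contains ``60*T0`` MCPs.  The *trihexagonal* lattice additionally
carries ``60*T0`` minor capsid proteins inserted as trimers, which expands
the surface by a factor of 4/3, so its effective triangulation number is
``T = (4/3)*T0`` (e.g. 1.33, 5.33, 9.33 ...).

T-values are held as exact :class:`fractions.Fraction` internally and only
rounded to two decimals for display.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import isqrt
from typing import Iterable, List

__all__ = [
    "HEXAGONAL",
    "TRIHEXAGONAL",
    "LATTICES",
    "LatticeArchitecture",
    "t0_number",
    "t_number",
    "architecture",
    "enumerate_architectures",
    "format_t",
]

HEXAGONAL = "hexagonal"
TRIHEXAGONAL = "trihexagonal"
LATTICES = (HEXAGONAL, TRIHEXAGONAL)

#: surface-expansion factor contributed by the trimer positions of the
#: trihexagonal lattice
TRIHEX_FACTOR = Fraction(4, 3)


def t0_number(h: int, k: int) -> int:
    """Classic Caspar-Klug triangulation number ``T0 = h^2 + h*k + k^2``.

    Parameters
    ----------
    h, k : int
        Lattice steps between neighbouring pentamers; both non-negative,
        not both zero.
    """
    if h < 0 or k < 0:
        raise ValueError(f"lattice steps must be non-negative, got ({h}, {k})")
    if h == 0 and k == 0:
        raise ValueError("(h, k) = (0, 0) does not define a capsid lattice")
    return h * h + h * k + k * k


def t_number(h: int, k: int, lattice: str = HEXAGONAL) -> Fraction:
    """Generalized T-number of the ``(h, k)`` capsid on the given lattice.

    Returns ``T0`` for the hexagonal lattice and exactly ``(4/3)*T0`` for
    the trihexagonal lattice, as an exact rational.
    """
    t0 = t0_number(h, k)
    if lattice == HEXAGONAL:
        return Fraction(t0)
    if lattice == TRIHEXAGONAL:
        return TRIHEX_FACTOR * t0
    raise ValueError(f"unknown lattice {lattice!r}; expected one of {LATTICES}")


def format_t(t: Fraction | float) -> str:
    """Render a T-value the conventional way: integers plain, else 2 decimals
    (``4/3`` -> ``"1.33"``, ``7`` -> ``"7"``)."""
    t = Fraction(t).limit_denominator(10**6)
    if t.denominator == 1:
        return str(t.numerator)
    return f"{float(t):.2f}"


@dataclass(frozen=True, order=True)
class LatticeArchitecture:
    """One icosahedral capsid architecture: an ``(h, k, lattice)`` triple
    with its T-number and protein stoichiometry."""

    t_value: Fraction
    lattice: str
    h: int
    k: int
    t0: int
    mcp_count: int
    minor_count: int

    def __post_init__(self) -> None:
        if self.lattice not in LATTICES:
            raise ValueError(f"unknown lattice {self.lattice!r}")
        if t0_number(self.h, self.k) != self.t0:
            raise ValueError("t0 inconsistent with (h, k)")

    @property
    def t_float(self) -> float:
        return float(self.t_value)

    @property
    def label(self) -> str:
        return f"T={format_t(self.t_value)}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.label} ({self.lattice}, h={self.h}, k={self.k})"


def architecture(h: int, k: int, lattice: str = HEXAGONAL) -> LatticeArchitecture:
    """Build the :class:`LatticeArchitecture` for ``(h, k)`` on ``lattice``."""
    t0 = t0_number(h, k)
    return LatticeArchitecture(
        t_value=t_number(h, k, lattice),
        lattice=lattice,
        h=h,
        k=k,
        t0=t0,
        mcp_count=60 * t0,
        minor_count=60 * t0 if lattice == TRIHEXAGONAL else 0,
    )


def enumerate_architectures(t_max: float | Fraction = 60) -> List[LatticeArchitecture]:
    """All distinct ``(T, lattice)`` architectures with ``T <= t_max``.

    Each distinct (t_value, lattice) pair appears once, represented by its
    canonical ``(h, k)``: the representative with ``h >= k >= 0`` that has
    the smallest ``h`` (then smallest ``k``).  Chiral pairs (h, k)/(k, h)
    are not distinguished.  T-values realizable on both lattices (T = 4,
    T = 12, ...) appear once per lattice.  Sorted by (t_value, lattice).
    """
    t_max = Fraction(t_max).limit_denominator(10**6)
    if t_max < 1:
        raise ValueError(f"t_max must be >= 1, got {t_max}")
    # T0 <= t_max suffices for both lattices since the trihexagonal T is larger.
    h_max = isqrt(int(t_max)) + 1
    best: dict[tuple[Fraction, str], LatticeArchitecture] = {}
    for h in range(h_max + 1):
        for k in range(h + 1):  # canonical h >= k >= 0
            if h == 0 and k == 0:
                continue
            for lattice in LATTICES:
                t = t_number(h, k, lattice)
                if t > t_max:
                    continue
                key = (t, lattice)
                cur = best.get(key)
                if cur is None or (h, k) < (cur.h, cur.k):
                    best[key] = architecture(h, k, lattice)
    return sorted(best.values(), key=lambda a: (a.t_value, a.lattice))


def hexagonal_t_series(t_max: int) -> List[int]:
    """The classic Caspar-Klug T-number series up to ``t_max`` (convenience)."""
    return sorted(
        {a.t0 for a in enumerate_architectures(t_max) if a.lattice == HEXAGONAL}
    )


def architectures_to_rows(archs: Iterable[LatticeArchitecture]) -> list[dict]:
    """Tabular form used by the CLI and TSV writers."""
    return [
        {
            "t_value": format_t(a.t_value),
            "lattice": a.lattice,
            "h": a.h,
            "k": a.k,
            "t0": a.t0,
            "mcp_count": a.mcp_count,
            "minor_count": a.minor_count,
        }
        for a in archs
    ]
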