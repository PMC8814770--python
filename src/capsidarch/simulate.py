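"""Synthetic data generators and the packaged high-resolution fixture.

Every generator is a pure function of its seed.  They emulate the three
data shapes the pipeline consumes: (i) power-law (genome, T) records with
multiplicative lognormal noise, for parameter-recovery tests of the
allometric fit; (ii) multimodal genome-length mixtures, for the density
estimator; and (iii) MCP sequence classes separable by length and
amino-acid composition, a stand-in for a real curated MCP/T library.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .g2t import CapsidRecord, GenomeToTResults
from .library import MCPEntry
from .rf import AMINO_ACIDS

__all__ = [
    "MCPClassProfile",
    "simulate_g2t_records",
    "simulate_genome_mixture",
    "simulate_mcp_classes",
    "default_class_profiles",
    "load_highres_fixture",
    "load_highres_frame",
]

#: genome-length sampling range of the record generator (kbp), matching the
#: span of solved tailed-phage capsid structures.
G_RANGE_KBP = (15.0, 500.0)


def simulate_g2t_records(
    n: int,
    a_true: float = 2 / 3,
    b_true: float = 0.5,
    noise_sd: float = 0.1,
    seed: int | None = None,
) -> list[CapsidRecord]:
    """Power-law (genome, T) records with multiplicative lognormal noise.

    G is log-uniform on [15, 500] kbp and ``T = b * G**a * exp(eps)`` with
    ``eps ~ Normal(0, noise_sd**2)``.  Defaults follow the theoretical 2/3
    exponent and roughly the empirical prefactor and scatter of solved
    capsid structures.
    """
    if n < 3:
        raise ValueError("need n >= 3 records")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    lo, hi = np.log(G_RANGE_KBP)
    g = np.exp(rng.uniform(lo, hi, size=n))
    eps = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    t = b_true * g**a_true * np.exp(eps)
    return [
        CapsidRecord(
            phage_name=f"sim{i:04d}",
            t_value=float(t[i]),
            genome_kbp=float(g[i]),
            source="predicted",
        )
        for i in range(n)
    ]


def simulate_genome_mixture(
    component_means: Sequence[float],
    component_sds: Sequence[float],
    weights: Sequence[float],
    n: int,
    seed: int | None = None,
) -> np.ndarray:
    """Draws from a Gaussian mixture of genome lengths (kbp), truncated to
    positive values by resampling."""
    means = np.asarray(component_means, dtype=float)
    sds = np.asarray(component_sds, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not (means.shape == sds.shape == w.shape):
        raise ValueError("component arrays must have equal length")
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be non-negative and sum to 1")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    comp = rng.choice(means.size, size=n, p=w)
    draws = rng.normal(means[comp], sds[comp])
    while np.any(draws <= 0):  # truncate to > 0
        bad = draws <= 0
        draws[bad] = rng.normal(means[comp[bad]], sds[comp[bad]])
    return draws


@dataclass(frozen=True)
class MCPClassProfile:
    """Generator profile for one synthetic MCP class: a T label, a length
    distribution, and a residue-composition simplex."""

    class_id: str
    t_value: float | str  # numeric T or "elongated"
    length_mean: float
    length_sd: float
    aa_weights: tuple[float, ...]  # over AMINO_ACIDS order

    def __post_init__(self) -> None:
        w = np.asarray(self.aa_weights, dtype=float)
        if w.size != len(AMINO_ACIDS):
            raise ValueError(f"aa_weights must have {len(AMINO_ACIDS)} entries")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("aa_weights must be a valid simplex")
        if not self.length_mean > 0:
            raise ValueError("length_mean must be positive")


def _biased_weights(bias: dict[str, float]) -> tuple[float, ...]:
    """Uniform composition shifted toward the given residues (weights
    renormalized)."""
    w = np.ones(len(AMINO_ACIDS))
    for aa, extra in bias.items():
        w[AMINO_ACIDS.index(aa)] += extra * len(AMINO_ACIDS)
    return tuple(w / w.sum())


def default_class_profiles(separation: float = 0.15) -> list[MCPClassProfile]:
    """Three well-separated MCP classes spanning small, mid and large
    capsids.  ``separation`` scales the composition bias (0 = identical
    compositions; the default gives strongly separable classes)."""
    return [
        MCPClassProfile(
            "T=4", 4.0, length_mean=330, length_sd=15,
            aa_weights=_biased_weights({"A": separation}),
        ),
        MCPClassProfile(
            "T=7", 7.0, length_mean=400, length_sd=15,
            aa_weights=_biased_weights({"G": separation}),
        ),
        MCPClassProfile(
            "T=19", 19.0, length_mean=500, length_sd=15,
            aa_weights=_biased_weights({"F": separation}),
        ),
    ]


def simulate_mcp_classes(
    profiles: Sequence[MCPClassProfile],
    n_per_class: int,
    seed: int | None = None,
    fit: GenomeToTResults | None = None,
    genome_jitter: float = 0.02,
) -> list[MCPEntry]:
    """Labeled synthetic MCP entries drawn from per-class profiles.

    Sequences are i.i.d. per residue from the class's composition, with
    length ``round(Normal(length_mean, length_sd))`` clipped at 30.  When a
    fitted genome-to-T model is given, each entry's genome length is
    back-computed from its class T through the inverse allometric map with
    small multiplicative jitter, so that rebuilding the library from these
    entries round-trips the labels; otherwise a nominal 40 kbp is used.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 class profiles")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    out: list[MCPEntry] = []
    for prof in profiles:
        w = np.asarray(prof.aa_weights)
        for i in range(n_per_class):
            length = max(30, int(round(rng.normal(prof.length_mean, prof.length_sd))))
            seq = "".join(rng.choice(aa, size=length, p=w))
            if fit is not None and not isinstance(prof.t_value, str):
                g_center = (prof.t_value / fit.b) ** (1 / fit.a)
                g = g_center * float(
                    np.exp(rng.uniform(-genome_jitter, genome_jitter))
                )
            else:
                g = 40.0
            out.append(
                MCPEntry(
                    id=f"{prof.class_id}_{i:04d}",
                    phage_name=f"synthetic_{prof.class_id}_{i:04d}",
                    sequence=seq,
                    genome_kbp=g,
                    t_label=prof.t_value,
                    label_source="g2t",
                )
            )
    return out


def simulate_mcp_families(
    profiles: Sequence[MCPClassProfile],
    n_per_class: int,
    mutation_rate: float = 0.1,
    seed: int | None = None,
    fit: GenomeToTResults | None = None,
    genome_jitter: float = 0.02,
) -> list[MCPEntry]:
    """Family-structured synthetic MCP classes: one ancestor per class,
    members derived by point substitution.

    Unlike :func:`simulate_mcp_classes` (i.i.d. residues, separable by
    composition but with label-uninformative pairwise identities), each
    class here is a homologous family: members share ``~(1 - mutation_rate)``
    identity within the class and only chance identity across classes, so
    pairwise similarity correlates with the T label — the structure the
    nearest-neighbour classifier exploits.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 class profiles")
    if not 0 <= mutation_rate < 1:
        raise ValueError("mutation_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    out: list[MCPEntry] = []
    for prof in profiles:
        w = np.asarray(prof.aa_weights)
        length = max(30, int(round(prof.length_mean)))
        ancestor = rng.choice(aa, size=length, p=w)
        for i in range(n_per_class):
            member = ancestor.copy()
            mutate = rng.random(length) < mutation_rate
            member[mutate] = rng.choice(aa, size=int(mutate.sum()), p=w)
            if fit is not None and not isinstance(prof.t_value, str):
                g_center = (prof.t_value / fit.b) ** (1 / fit.a)
                g = g_center * float(np.exp(rng.uniform(-genome_jitter, genome_jitter)))
            else:
                g = 40.0
            out.append(
                MCPEntry(
                    id=f"{prof.class_id}_fam{i:04d}",
                    phage_name=f"synthetic_{prof.class_id}_fam{i:04d}",
                    sequence="".join(member),
                    genome_kbp=g,
                    t_label=prof.t_value,
                    label_source="g2t",
                )
            )
    return out


# ---------------------------------------------------------------------------
# packaged fixture


def load_highres_frame() -> pd.DataFrame:
    """The packaged high-resolution capsid table as a DataFrame."""
    path = resources.files("capsidarch.data") / "highres_capsids.tsv"
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def load_highres_fixture() -> list[CapsidRecord]:
    """The 37 high-resolution capsid records (phage, T, lattice, genome)."""
    df = load_highres_frame()
    return [
        CapsidRecord(
            phage_name=row["phage"],
            t_value=float(row["t_value"]),
            genome_kbp=float(row["genome_kbp"]),
            lattice=None if row["lattice"] == "unspecified" else row["lattice"],
            source="high_resolution",
        )
        for _, row in df.iterrows()
    ]
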