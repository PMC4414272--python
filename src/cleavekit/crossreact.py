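"""Protease x substrate cross-reactivity grids and orthogonality calls.

An orthogonality screen incubates every protease with every substrate under
heavy over-digestion (hundreds- to tens-of-thousands-fold more enzyme than
needed for the cognate pair) and asks which off-target substrates are
touched. Each cell's cleaved fraction maps onto the four-level gel key

    ++  highly efficient cleavage      (>= 0.90 by default)
    +   cleavage                       ([0.10, 0.90))
    -   traces cleaved                 ([0.01, 0.10))
    --  no cleavage                    (< 0.01, i.e. below band detection)

Two cognate protease/substrate pairs (P_i, S_i) and (P_j, S_j) are called
mutually orthogonal iff P_i leaves S_j uncleaved AND P_j leaves S_i
uncleaved under those over-digestion conditions. The maximal sets of
pairwise-orthogonal pairs are the maximal cliques of the resulting graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DataError, DomainError, IncompleteGridError

__all__ = [
    "CategoryThresholds",
    "CrossReactivityGrid",
    "OrthogonalityReport",
    "classify_cell",
    "orthogonality_calls",
]

CATEGORIES = ("++", "+", "-", "--")


@dataclass(frozen=True)
class CategoryThresholds:
    """Cutoffs of the four-level cleavage key (fractions cleaved).

    Defaults reflect gel practice: ~1% is the band detection limit, below
    which a lane reads "no cleavage"; >= 90% reads "highly efficient".
    """

    high: float = 0.90
    cleaved: float = 0.10
    trace: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 < self.trace < self.cleaved < self.high <= 1.0):
            raise DomainError(
                "thresholds must satisfy 0 < trace < cleaved < high <= 1, got "
                f"trace={self.trace}, cleaved={self.cleaved}, high={self.high}"
            )


def classify_cell(fraction: float, thresholds: CategoryThresholds | None = None) -> str:
    """Map a cleaved fraction onto the ++ / + / - / -- key."""
    if not (0.0 <= fraction <= 1.0):
        raise DomainError(f"fraction must lie in [0,1], got {fraction!r}")
    th = thresholds or CategoryThresholds()
    if fraction >= th.high:
        return "++"
    if fraction >= th.cleaved:
        return "+"
    if fraction >= th.trace:
        return "-"
    return "--"


@dataclass(frozen=True)
class CrossReactivityGrid:
    """Protease x substrate matrix of digestion outcomes.

    ``fractions`` holds the cleaved fraction for every (protease, substrate)
    combination at the stated (over-digestion) conditions; ``cognate`` maps
    each substrate to its designated cognate protease. ``conditions`` records
    enzyme concentration, time and temperature for provenance.
    """

    proteases: tuple[str, ...]
    substrates: tuple[str, ...]
    fractions: np.ndarray  # shape (n_proteases, n_substrates)
    cognate: Mapping[str, str] = field(default_factory=dict)
    conditions: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "fractions", f)
        object.__setattr__(self, "proteases", tuple(self.proteases))
        object.__setattr__(self, "substrates", tuple(self.substrates))
        if f.shape != (len(self.proteases), len(self.substrates)):
            raise DataError(
                f"fractions shape {f.shape} does not match "
                f"{len(self.proteases)} proteases x {len(self.substrates)} substrates"
            )
        missing = np.argwhere(~np.isfinite(f))
        if missing.size:
            pairs = ", ".join(
                f"({self.proteases[i]}, {self.substrates[j]})" for i, j in missing
            )
            raise IncompleteGridError(f"grid is missing cells: {pairs}")
        if np.any((f < 0) | (f > 1)):
            raise DomainError("grid fractions must lie in [0,1]")

    @classmethod
    def from_long(cls, df: pd.DataFrame, cognate: Mapping[str, str] | None = None
                  ) -> "CrossReactivityGrid":
        """Build from a long-format table with columns protease, substrate,
        fraction_cleaved (replicate rows are averaged). Missing combinations
        surface later as an incomplete-grid error."""
        proteases = tuple(pd.unique(df["protease"]))
        substrates = tuple(pd.unique(df["substrate"]))
        mat = np.full((len(proteases), len(substrates)), np.nan)
        mean = df.groupby(["protease", "substrate"])["fraction_cleaved"].mean()
        for i, p in enumerate(proteases):
            for j, s in enumerate(substrates):
                if (p, s) in mean.index:
                    mat[i, j] = mean.loc[(p, s)]
        cond_cols = [c for c in ("enzyme_uM", "time_min", "temp_C") if c in df.columns]
        conditions = {c: float(df[c].iloc[0]) for c in cond_cols} if len(df) else {}
        return cls(proteases, substrates, mat, cognate or {}, conditions)

    def fraction(self, protease: str, substrate: str) -> float:
        i = self.proteases.index(protease)
        j = self.substrates.index(substrate)
        return float(self.fractions[i, j])

    def classify(self, thresholds: CategoryThresholds | None = None) -> pd.DataFrame:
        """Categorical ++/+/-/-- matrix as a DataFrame (proteases x substrates)."""
        th = thresholds or CategoryThresholds()
        cats = [
            [classify_cell(self.fractions[i, j], th) for j in range(len(self.substrates))]
            for i in range(len(self.proteases))
        ]
        return pd.DataFrame(cats, index=list(self.proteases),
                            columns=list(self.substrates))


@dataclass(frozen=True)
class OrthogonalityReport:
    """Pairwise orthogonality verdicts and the maximal mutually-orthogonal
    sets of cognate protease/substrate pairs."""

    pairs: tuple[tuple[str, str], ...]  # cognate (protease, substrate) pairs
    verdicts: pd.DataFrame  # boolean, symmetric, indexed by protease label
    maximal_sets: tuple[tuple[str, ...], ...]  # protease labels per clique

    def is_orthogonal(self, protease_i: str, protease_j: str) -> bool:
        return bool(self.verdicts.loc[protease_i, protease_j])

    def summary(self) -> str:
        lines = ["Orthogonality report", "=" * 45,
                 f"cognate pairs: {len(self.pairs)}"]
        for members in self.maximal_sets:
            lines.append("  mutually orthogonal set: {" + ", ".join(members) + "}")
        return "\n".join(lines)


def orthogonality_calls(
    grid: CrossReactivityGrid,
    thresholds: CategoryThresholds | None = None,
    strictness: str = "--",
) -> OrthogonalityReport:
    """Call pairwise orthogonality between cognate protease/substrate pairs.

    (P_i, S_i) and (P_j, S_j) are orthogonal iff P_i's cleavage of S_j and
    P_j's cleavage of S_i both fall at or below the tolerated category:
    ``strictness="--"`` (default) demands no detectable cleavage at the
    grid's over-digestion conditions, ``strictness="-"`` also tolerates
    trace cleavage. Self-pairs are excluded by definition. The maximal
    mutually-orthogonal sets are the maximal cliques of the verdict graph.
    """
    if strictness not in ("--", "-"):
        raise DomainError(f'strictness must be "--" or "-", got {strictness!r}')
    th = thresholds or CategoryThresholds()
    cutoff = th.trace if strictness == "--" else th.cleaved

    if not grid.cognate:
        raise DataError("grid declares no cognate protease for any substrate")
    pairs = []
    for s, p in grid.cognate.items():
        if p not in grid.proteases:
            raise DataError(f"cognate protease {p!r} of {s!r} not in grid")
        if s not in grid.substrates:
            raise DataError(f"substrate {s!r} not in grid")
        pairs.append((p, s))
    pairs.sort(key=lambda ps: grid.proteases.index(ps[0]))

    labels = [p for p, _ in pairs]
    n = len(pairs)
    mat = np.zeros((n, n), dtype=bool)
    for a in range(n):
        for b in range(a + 1, n):
            p_a, s_a = pairs[a]
            p_b, s_b = pairs[b]
            ortho = (
                grid.fraction(p_a, s_b) < cutoff and grid.fraction(p_b, s_a) < cutoff
            )
            mat[a, b] = mat[b, a] = ortho
    verdicts = pd.DataFrame(mat, index=labels, columns=labels)

    g = nx.Graph()
    g.add_nodes_from(labels)
    for a in range(n):
        for b in range(a + 1, n):
            if mat[a, b]:
                g.add_edge(labels[a], labels[b])
    cliques = sorted(
        (tuple(sorted(c, key=labels.index)) for c in nx.find_cliques(g)),
        key=lambda c: (-len(c), [labels.index(m) for m in c]),
    )
    return OrthogonalityReport(tuple(pairs), verdicts, tuple(cliques))
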