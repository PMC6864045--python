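"""Multiplex-panel combinatorics: translocation outcomes and knockout compositions.

Simultaneous double-strand breaks at k loci admit k*(k-1) directed
translocation junctions (each unordered pair contributes both reciprocal
products): 4 cut sites give 12 possible junction outcomes, 10 give 90.
Inversions and large deletions are deliberately not counted.

Knockout-composition analysis decomposes per-cell boolean knockout calls
(rows = cells, columns = genes, as gated flow phenotypes) into the 2^g
combination categories and into fractions grouped by the number of genes
lost, and provides the independence benchmark computed from per-gene
knockout rates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PanelLocus",
    "JunctionOutcome",
    "enumerate_translocations",
    "translocation_count",
    "ko_combination_fractions",
    "expected_combination_fractions",
    "CompositionTable",
    "load_panel",
    "junctions_to_frame",
]


@dataclass(frozen=True)
class PanelLocus:
    """One cut/edit site in a multiplex panel."""

    label: str
    contig: str = ""
    coord: int = 0
    kind: str = "on_target"  # "on_target" | "off_target"


@dataclass(frozen=True)
class JunctionOutcome:
    """One directed translocation junction between two panel loci.

    The two orientations of a pair (A->B and B->A) are distinct outcomes:
    a reciprocal translocation produces both fusion chromosomes.
    """

    partner_a: str
    partner_b: str

    @property
    def orientation(self) -> str:
        return f"{self.partner_a}->{self.partner_b}"


def enumerate_translocations(panel: Sequence[PanelLocus]) -> list[JunctionOutcome]:
    """Every ordered pair of distinct loci; count = k*(k-1)."""
    labels = [p.label if isinstance(p, PanelLocus) else str(p) for p in panel]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate panel labels: {dupes}")
    return [JunctionOutcome(a, b) for a, b in itertools.permutations(labels, 2)]


def translocation_count(k: int) -> int:
    """Closed form k*(k-1) for k cut sites."""
    if k < 0:
        raise ValueError("panel size must be non-negative")
    return k * (k - 1)


@dataclass
class CompositionTable:
    """Knockout-combination composition of a cell population.

    ``combinations`` has one row per boolean category (2^g rows, gene
    columns of 0/1 plus ``fraction``); ``by_count`` groups the same mass
    by the number of genes lost.  Fractions sum to 1 in each table.
    """

    genes: list[str]
    combinations: pd.DataFrame
    by_count: pd.DataFrame

    def marginals(self) -> dict[str, float]:
        """Per-gene knockout fraction implied by the combination table."""
        return {
            g: float((self.combinations[g] * self.combinations["fraction"]).sum())
            for g in self.genes
        }


def _composition_from_probs(genes: list[str], probs: dict[tuple[int, ...], float]) -> CompositionTable:
    rows = []
    for combo in itertools.product((0, 1), repeat=len(genes)):
        rows.append({**dict(zip(genes, combo)), "fraction": probs.get(combo, 0.0)})
    comb = pd.DataFrame(rows, columns=genes + ["fraction"])
    n_ko = comb[genes].sum(axis=1)
    by_count = (
        comb.assign(n_ko=n_ko)
        .groupby("n_ko", as_index=False)["fraction"]
        .sum()
        .reindex(range(len(genes) + 1), fill_value=0)
    )
    by_count["n_ko"] = range(len(genes) + 1)
    return CompositionTable(genes=genes, combinations=comb, by_count=by_count[["n_ko", "fraction"]])


def ko_combination_fractions(m: pd.DataFrame) -> CompositionTable:
    """Observed fractions of each knockout combination in a call matrix.

    ``m`` is a boolean DataFrame, rows = cells, columns = genes.
    """
    if m.shape[0] == 0:
        raise ValueError("knockout-call matrix has no cells")
    genes = list(m.columns)
    arr = m.to_numpy().astype(bool)
    n = arr.shape[0]
    counts: dict[tuple[int, ...], float] = {}
    keys, cnts = np.unique(arr, axis=0, return_counts=True)
    for key, cnt in zip(keys, cnts):
        counts[tuple(int(x) for x in key)] = cnt / n
    return _composition_from_probs(genes, counts)


def expected_combination_fractions(
    rates: dict[str, float] | Sequence[float],
) -> CompositionTable:
    """Combination fractions expected under independent per-gene knockout.

    Category probability is the product of p_i (knockout) or 1-p_i
    (retained) over genes; the benchmark against which observed
    co-occurrence structure is judged.
    """
    if isinstance(rates, dict):
        genes = list(rates)
        ps = [rates[g] for g in genes]
    else:
        ps = list(rates)
        genes = [f"gene{i + 1}" for i in range(len(ps))]
    for p in ps:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"knockout rate {p} outside [0, 1]")
    probs = {}
    for combo in itertools.product((0, 1), repeat=len(genes)):
        prob = 1.0
        for flag, p in zip(combo, ps):
            prob *= p if flag else (1.0 - p)
        probs[combo] = prob
    return _composition_from_probs(genes, probs)


def load_panel(path) -> list[PanelLocus]:
    """Read a panel TSV (columns label, contig, coord, kind)."""
    df = pd.read_csv(path, sep="\t")
    required = {"label"}
    if not required <= set(df.columns):
        raise ValueError(f"panel table must have columns {sorted(required)}")
    loci = [
        PanelLocus(
            label=str(r["label"]),
            contig=str(r.get("contig", "")),
            coord=int(r.get("coord", 0) or 0),
            kind=str(r.get("kind", "on_target")),
        )
        for _, r in df.iterrows()
    ]
    if len({l.label for l in loci}) != len(loci):
        raise ValueError("duplicate panel labels in input table")
    return loci


def junctions_to_frame(junctions: Iterable[JunctionOutcome]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"partner_a": j.partner_a, "partner_b": j.partner_b, "orientation": j.orientation}
            for j in junctions
        ],
        columns=["partner_a", "partner_b", "orientation"],
    )
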