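"""Multi-bait set algebra over filtered interactomes.

The five classical RAD51 paralogs assemble into two heteromeric complexes,
BCDX2 (RAD51B-RAD51C-RAD51D-XRCC2) and CX3 (RAD51C-XRCC3). Complex-level
proximal interactomes are defined by intersection specifications: a prey
belongs to a complex's exclusive interactome when it is seen by every member
bait and by none of the other paralogs. An upset decomposition assigns each
prey to the exact signature of baits that detected it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .ingest import Interactome, normalize_symbol

#: The five classical RAD51 paralog baits.
BAITS = ("RAD51B", "RAD51C", "RAD51D", "XRCC2", "XRCC3")
BCDX2 = frozenset({"RAD51B", "RAD51C", "RAD51D", "XRCC2"})
CX3 = frozenset({"RAD51C", "XRCC3"})


@dataclass(frozen=True)
class IntersectionSpec:
    """Preys required in ALL ``include`` baits and NONE of ``exclude``."""

    include: frozenset[str]
    exclude: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.include:
            raise ValueError("include set must be non-empty")
        if self.include & self.exclude:
            raise ValueError(
                f"include and exclude overlap: {sorted(self.include & self.exclude)}"
            )


#: Exclusive complex-level interactome specifications.
BCDX2_EXCLUSIVE = IntersectionSpec(include=BCDX2, exclude=frozenset({"XRCC3"}))
CX3_EXCLUSIVE = IntersectionSpec(include=CX3, exclude=BCDX2 - CX3)
ALL_COMMON = IntersectionSpec(include=frozenset(BAITS))


def intersect(
    interactomes: Mapping[str, Interactome], spec: IntersectionSpec
) -> list[str]:
    """Preys present in every ``spec.include`` bait and no ``spec.exclude`` bait.

    Returns a sorted list for deterministic downstream output.
    """
    for bait in sorted(spec.include | spec.exclude):
        if bait not in interactomes:
            raise ValueError(
                f"unknown bait {bait!r}; available: {sorted(interactomes)}"
            )
    result: set[str] | None = None
    for bait in spec.include:
        preys = set(interactomes[bait].preys)
        result = preys if result is None else result & preys
    assert result is not None
    for bait in spec.exclude:
        result -= set(interactomes[bait].preys)
    return sorted(result)


def upset_decompose(
    interactomes: Mapping[str, Interactome]
) -> dict[frozenset[str], frozenset[str]]:
    """Partition the prey union by exact bait-membership signature.

    Every prey lands in exactly one cell keyed by the frozenset of baits that
    detected it; empty cells are omitted.
    """
    if not interactomes:
        raise ValueError("at least one interactome is required")
    membership: dict[str, set[str]] = {}
    for bait, inter in interactomes.items():
        for prey in inter.preys:
            membership.setdefault(prey, set()).add(bait)
    cells: dict[frozenset[str], set[str]] = {}
    for prey, baits in membership.items():
        cells.setdefault(frozenset(baits), set()).add(prey)
    return {sig: frozenset(preys) for sig, preys in cells.items()}


def upset_table(cells: Mapping[frozenset[str], frozenset[str]]) -> pd.DataFrame:
    """Cell sizes as a table (signature, n_preys), largest first."""
    rows = [
        {"signature": "&".join(sorted(sig)), "n_preys": len(preys)}
        for sig, preys in cells.items()
    ]
    df = pd.DataFrame(rows).sort_values(
        ["n_preys", "signature"], ascending=[False, True]
    )
    return df.reset_index(drop=True)


@dataclass(frozen=True)
class NoveltyReport:
    """Partition of an interactome's preys by presence in a known catalogue."""

    bait: str
    known: frozenset[str]
    novel: frozenset[str]

    @property
    def fold_over_known(self) -> float:
        """|preys| / max(1, |known|): how many-fold the map exceeds the catalogue."""
        return (len(self.known) + len(self.novel)) / max(1, len(self.known))


def novelty_report(
    interactome: Interactome, known_edges: Iterable[tuple[str, str]]
) -> NoveltyReport:
    """Split preys into those with a catalogued (bait, prey) edge and the rest."""
    bait = interactome.bait
    partners = set()
    # symbols are expected in the ingest namespace already (reader-normalized)
    for a, b in known_edges:
        if a == bait:
            partners.add(b)
        elif b == bait:
            partners.add(a)
    preys = interactome.prey_set
    known = frozenset(preys & partners)
    return NoveltyReport(bait=bait, known=known, novel=frozenset(preys - known))


#: BioGRID TAB3 official-symbol column headers.
_TAB3_COLS = ("Official Symbol Interactor A", "Official Symbol Interactor B")


def read_edge_table(
    path: str | Path,
    column_a: str | int | None = None,
    column_b: str | int | None = None,
) -> list[tuple[str, str]]:
    """Read symbol pairs from a two-column TSV or a BioGRID TAB3-style file.

    Without explicit columns, TAB3 official-symbol headers are auto-detected;
    otherwise the first two columns are used (a header line is tolerated).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if column_a is None and column_b is None:
        if all(c in df.columns for c in _TAB3_COLS):
            column_a, column_b = _TAB3_COLS
        else:
            # generic two-column table; re-read without a header if the first
            # line already looks like data (both cells become column names)
            column_a, column_b = df.columns[0], df.columns[1]
    if isinstance(column_a, int):
        column_a = df.columns[column_a]
    if isinstance(column_b, int):
        column_b = df.columns[column_b]
    edges = [
        (normalize_symbol(a), normalize_symbol(b))
        for a, b in zip(df[column_a], df[column_b])
        if pd.notna(a) and pd.notna(b)
    ]
    return edges


def write_prey_list(
    preys: Sequence[str], signature: str, path: str | Path
) -> None:
    """Write one prey per line with its membership signature."""
    df = pd.DataFrame({"prey": list(preys), "signature": signature})
    df.to_csv(path, sep="\t", index=False)
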