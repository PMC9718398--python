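"""Reading and confidence-filtering of post-search BioID prey tables.

A prey table carries one row per bait x condition x prey: the prey's average
spectral count across biological replicates (AvgSpec), the number of unique
peptides supporting the identification, the iProphet protein-level
probability, and the prey protein length in amino acids (used downstream for
spectral abundance factor normalisation).

The confidence filter keeps identifications with at least ``min_unique``
unique peptides and an iProphet probability of at least ``min_prob`` (both
thresholds inclusive), then discards classical BioID contaminants --
biotin-dependent carboxylases, lysozyme, keratins, ribosomal subunits and a
short list of notorious promiscuous binders.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

CONDITIONS = ("untreated", "HU")

#: Default column names of a prey table on disk.
DEFAULT_DIALECT: dict[str, str] = {
    "bait": "Bait",
    "condition": "Condition",
    "prey": "PreyGene",
    "avg_spec": "AvgSpec",
    "unique_peptides": "UniquePeptides",
    "iprophet_prob": "iProphetProb",
    "protein_length_aa": "LengthAA",
    "n_replicates": "NReps",
}


class PreyTableWarning(UserWarning):
    """Raised (as a warning) when rows of a prey table are rejected."""


def normalize_symbol(symbol: str, isoform_delim: str | None = None) -> str:
    """Upper-case and strip a gene symbol; optionally drop an isoform suffix.

    All tables joined by this package (BioID, screens, gene sets, cohorts)
    are mapped into this single symbol namespace.
    """
    s = str(symbol).strip().upper()
    if isoform_delim and isoform_delim in s:
        s = s.split(isoform_delim, 1)[0]
    return s


@dataclass(frozen=True)
class PreyRecord:
    """One bait-prey observation with its spectral-count evidence."""

    bait: str
    condition: str
    prey: str
    avg_spec: float
    unique_peptides: int
    iprophet_prob: float
    protein_length_aa: int
    n_replicates: int = 2

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if not 0.0 <= self.iprophet_prob <= 1.0:
            raise ValueError(f"iprophet_prob must be in [0, 1], got {self.iprophet_prob}")
        if self.avg_spec < 0:
            raise ValueError(f"avg_spec must be >= 0, got {self.avg_spec}")
        if self.unique_peptides < 0:
            raise ValueError(f"unique_peptides must be >= 0, got {self.unique_peptides}")
        if self.protein_length_aa < 1:
            raise ValueError(
                f"protein_length_aa must be >= 1, got {self.protein_length_aa}"
            )
        if self.n_replicates < 1:
            raise ValueError(f"n_replicates must be >= 1, got {self.n_replicates}")


@dataclass(frozen=True)
class ContaminantList:
    """Symbols and symbol-prefix classes treated as BioID contaminants."""

    symbols: frozenset[str]
    prefixes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.symbols and not self.prefixes:
            raise ValueError("contaminant list must not be empty")
        object.__setattr__(
            self, "symbols", frozenset(normalize_symbol(s) for s in self.symbols)
        )
        object.__setattr__(
            self, "prefixes", tuple(normalize_symbol(p) for p in self.prefixes)
        )

    def __contains__(self, symbol: object) -> bool:
        s = normalize_symbol(str(symbol))
        return s in self.symbols or s.startswith(self.prefixes)

    @classmethod
    def from_file(cls, path: str | Path) -> "ContaminantList":
        """Read a contaminant list: one entry per line, trailing ``*`` marks a prefix."""
        symbols: set[str] = set()
        prefixes: list[str] = []
        for line in Path(path).read_text().splitlines():
            entry = line.strip()
            if not entry or entry.startswith("#"):
                continue
            if entry.endswith("*"):
                prefixes.append(entry[:-1])
            else:
                symbols.add(entry)
        return cls(symbols=frozenset(symbols), prefixes=tuple(prefixes))


#: Classical BioID contaminants: endogenously biotinylated carboxylases,
#: lysozyme, keratins (KRT*), ribosomal subunits (RPL*/RPS*) and a short list
#: of promiscuous binders commonly removed from streptavidin purifications.
DEFAULT_CONTAMINANTS = ContaminantList(
    symbols=frozenset(
        {
            # promiscuous binders
            "AHNAK", "PRKDC", "TOP1", "HLCS", "FLNB", "PRKAA1", "PRKAA2",
            # biotin-dependent carboxylases
            "PC", "PCCA", "PCCB", "MCCC1", "MCCC2", "ACACA", "ACACB",
            # lysozyme
            "LYZ",
        }
    ),
    prefixes=("KRT", "RPL", "RPS"),
)


@dataclass(frozen=True)
class Interactome:
    """A bait's filtered prey set with per-prey average spectral counts."""

    bait: str
    condition: str
    preys: Mapping[str, float]

    @property
    def prey_set(self) -> frozenset[str]:
        return frozenset(self.preys)

    def __len__(self) -> int:
        return len(self.preys)


@dataclass
class FilterReport:
    """Counts removed per confidence/contaminant rule.

    A record violating several rules increments every matching counter;
    ``n_removed`` counts each removed record once.
    """

    n_input: int = 0
    n_kept: int = 0
    removed_low_probability: int = 0
    removed_few_unique_peptides: int = 0
    removed_contaminant: int = 0

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_kept

    def to_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "n_removed": self.n_removed,
            "removed_low_probability": self.removed_low_probability,
            "removed_few_unique_peptides": self.removed_few_unique_peptides,
            "removed_contaminant": self.removed_contaminant,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def read_prey_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    isoform_delim: str | None = None,
) -> list[PreyRecord]:
    """Parse a tab-separated prey table into :class:`PreyRecord` rows.

    Gene symbols are upper-cased and whitespace-stripped. Rows violating a
    field invariant (for example an iProphet probability outside [0, 1] or a
    non-numeric spectral count) are rejected and reported, with their line
    numbers, through a single :class:`PreyTableWarning`. A missing required
    column raises :class:`ValueError` naming the column. Duplicate
    (bait, condition, prey) rows after the first are rejected.
    """
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = [k for k in cols if k != "n_replicates"]
    for key in required:
        if cols[key] not in df.columns:
            raise ValueError(
                f"prey table {path} is missing required column {cols[key]!r}"
            )
    has_nreps = cols["n_replicates"] in df.columns

    records: list[PreyRecord] = []
    errors: list[str] = []
    seen: set[tuple[str, str, str]] = set()
    for idx, row in df.iterrows():
        line_no = int(idx) + 2  # 1-based, after the header line
        try:
            rec = PreyRecord(
                bait=normalize_symbol(row[cols["bait"]], isoform_delim),
                condition=str(row[cols["condition"]]).strip(),
                prey=normalize_symbol(row[cols["prey"]], isoform_delim),
                avg_spec=float(row[cols["avg_spec"]]),
                unique_peptides=int(float(row[cols["unique_peptides"]])),
                iprophet_prob=float(row[cols["iprophet_prob"]]),
                protein_length_aa=int(float(row[cols["protein_length_aa"]])),
                n_replicates=int(float(row[cols["n_replicates"]])) if has_nreps else 2,
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"line {line_no}: {exc}")
            continue
        key = (rec.bait, rec.condition, rec.prey)
        if key in seen:
            errors.append(f"line {line_no}: duplicate (bait, condition, prey) {key}")
            continue
        seen.add(key)
        records.append(rec)
    if errors:
        warnings.warn(
            f"rejected {len(errors)} row(s) of {path}: " + "; ".join(errors),
            PreyTableWarning,
            stacklevel=2,
        )
    return records


def write_prey_table(
    records: Iterable[PreyRecord],
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> None:
    """Write records back to the tab-separated on-disk format."""
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    recs = list(records)
    df = pd.DataFrame(
        {
            cols["bait"]: [r.bait for r in recs],
            cols["condition"]: [r.condition for r in recs],
            cols["prey"]: [r.prey for r in recs],
            cols["avg_spec"]: [r.avg_spec for r in recs],
            cols["unique_peptides"]: [r.unique_peptides for r in recs],
            cols["iprophet_prob"]: [r.iprophet_prob for r in recs],
            cols["protein_length_aa"]: [r.protein_length_aa for r in recs],
            cols["n_replicates"]: [r.n_replicates for r in recs],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def filter_preys(
    records: Sequence[PreyRecord],
    min_prob: float = 0.9,
    min_unique: int = 1,
    contaminants: ContaminantList = DEFAULT_CONTAMINANTS,
) -> tuple[list[PreyRecord], FilterReport]:
    """Apply the confidence and contaminant filters.

    A record is kept iff ``iprophet_prob >= min_prob`` and
    ``unique_peptides >= min_unique`` (both inclusive) and its prey is not a
    contaminant. Input order is preserved. Returns the kept records and a
    :class:`FilterReport` of counts removed per rule.
    """
    if not 0.0 <= min_prob <= 1.0:
        raise ValueError(f"min_prob must be in [0, 1], got {min_prob}")
    if min_unique < 0:
        raise ValueError(f"min_unique must be >= 0, got {min_unique}")
    report = FilterReport(n_input=len(records))
    kept: list[PreyRecord] = []
    for rec in records:
        ok = True
        if rec.iprophet_prob < min_prob:
            report.removed_low_probability += 1
            ok = False
        if rec.unique_peptides < min_unique:
            report.removed_few_unique_peptides += 1
            ok = False
        if rec.prey in contaminants:
            report.removed_contaminant += 1
            ok = False
        if ok:
            kept.append(rec)
    report.n_kept = len(kept)
    return kept, report


def build_interactome(
    records: Sequence[PreyRecord], bait: str, condition: str
) -> Interactome:
    """Collect the (already filtered) records of one bait and condition.

    Raises :class:`ValueError` naming the available baits when the requested
    bait/condition pair has no records.
    """
    bait = normalize_symbol(bait)
    selected = {
        r.prey: r.avg_spec
        for r in records
        if r.bait == bait and r.condition == condition
    }
    if not selected:
        available = sorted({(r.bait, r.condition) for r in records})
        raise ValueError(
            f"no records for bait {bait!r} in condition {condition!r}; "
            f"available (bait, condition) pairs: {available}"
        )
    return Interactome(bait=bait, condition=condition, preys=selected)


def build_interactomes(
    records: Sequence[PreyRecord], condition: str = "untreated"
) -> dict[str, Interactome]:
    """One :class:`Interactome` per bait observed in ``condition``."""
    baits = sorted({r.bait for r in records if r.condition == condition})
    return {b: build_interactome(records, b, condition) for b in baits}
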