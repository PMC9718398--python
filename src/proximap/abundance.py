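"""Spectral-abundance normalisation and differential (replication-stress) scoring.

The spectral abundance factor (SAF) divides a prey's average spectral count
by its protein length in amino acids, correcting the count for protein size.
Heatmap-style matrices carry log2(SAF); preys undetected by a bait are
imputed at an average spectral count of zero, whose log2 is -inf and is
therefore tracked by an explicit mask (and optionally floored for export and
clustering).

The differential score between hydroxyurea (HU) and untreated conditions is
computed on raw average spectral counts:

    log2FC = log2((AvgSpec_HU + 1) / (AvgSpec_untreated + 1))
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ingest import Interactome


def saf(avg_spec: float, protein_length_aa: int) -> float:
    """Spectral abundance factor: average spectral count per amino acid."""
    if protein_length_aa < 1:
        raise ValueError(f"protein_length_aa must be >= 1, got {protein_length_aa}")
    if avg_spec < 0:
        raise ValueError(f"avg_spec must be >= 0, got {avg_spec}")
    return avg_spec / protein_length_aa


@dataclass
class AbundanceMatrix:
    """log2-SAF matrix (preys x bait/condition columns) with an imputation mask.

    ``values`` holds log2(saf(avg_spec + pseudo, length)); with the default
    ``pseudo = 0`` an imputed (undetected) cell is ``-inf``. ``imputed`` marks
    cells where the prey was absent from that bait/condition table.
    """

    values: pd.DataFrame
    imputed: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape != self.imputed.shape:
            raise ValueError("values and imputed mask must share dimensions")

    def floored(self, floor: float | None = None) -> pd.DataFrame:
        """Replace non-finite cells by a floor (default: min finite value - 1)."""
        finite = self.values.values[np.isfinite(self.values.values)]
        if floor is None:
            floor = float(finite.min()) - 1.0 if finite.size else -1.0
        out = self.values.copy()
        return out.where(np.isfinite(out), floor)

    def write_tsv(self, path, floor: float | None = None) -> None:
        df = self.floored(floor)
        df.columns = [f"{b}:{c}" for b, c in df.columns]
        df.to_csv(path, sep="\t", index_label="prey")


def build_abundance_matrix(
    interactomes: Mapping[tuple[str, str], Interactome],
    lengths: Mapping[str, int],
    pseudo: float = 0.0,
    nsaf: bool = False,
) -> AbundanceMatrix:
    """Assemble the log2-SAF matrix over all preys seen anywhere.

    ``interactomes`` maps (bait, condition) -> interactome. A prey absent
    from a column is imputed with an average spectral count of zero. A prey
    with no entry in ``lengths`` raises :class:`ValueError` naming it.
    With ``nsaf=True`` each column's SAF values are renormalised to sum to
    one (NSAF) before the log2 transform.
    """
    all_preys = sorted({p for inter in interactomes.values() for p in inter.preys})
    for prey in all_preys:
        if prey not in lengths:
            raise ValueError(f"no protein length for prey {prey!r}")
    columns = pd.MultiIndex.from_tuples(
        sorted(interactomes), names=["bait", "condition"]
    )
    values = np.empty((len(all_preys), len(columns)))
    mask = np.zeros_like(values, dtype=bool)
    for j, key in enumerate(columns):
        preys = interactomes[key].preys
        safs = np.empty(len(all_preys))
        for i, prey in enumerate(all_preys):
            spec = preys.get(prey)
            if spec is None:
                mask[i, j] = True
                spec = 0.0
            safs[i] = saf(spec + pseudo, lengths[prey])
        if nsaf:
            total = safs.sum()
            if total > 0:
                safs = safs / total
        with np.errstate(divide="ignore"):
            values[:, j] = np.where(safs > 0, np.log2(safs, where=safs > 0),
                                    -np.inf)
    return AbundanceMatrix(
        values=pd.DataFrame(values, index=all_preys, columns=columns),
        imputed=pd.DataFrame(mask, index=all_preys, columns=columns),
    )


@dataclass(frozen=True)
class DifferentialResult:
    """Per-prey HU-vs-untreated log2 fold change on raw average spectral counts."""

    prey: str
    bait: str
    log2fc: float
    avg_spec_untreated: float
    avg_spec_hu: float


def differential_hu(
    untreated: Interactome, hu: Interactome
) -> list[DifferentialResult]:
    """log2((HU + 1) / (untreated + 1)) per prey in the union of both prey sets.

    A prey absent from one condition contributes an average spectral count of
    zero there. Both interactomes must belong to the same bait.
    """
    if untreated.bait != hu.bait:
        raise ValueError(
            f"bait mismatch: {untreated.bait!r} (untreated) vs {hu.bait!r} (HU)"
        )
    results = []
    for prey in sorted(set(untreated.preys) | set(hu.preys)):
        u = float(untreated.preys.get(prey, 0.0))
        h = float(hu.preys.get(prey, 0.0))
        results.append(
            DifferentialResult(
                prey=prey,
                bait=untreated.bait,
                log2fc=math.log2((h + 1.0) / (u + 1.0)),
                avg_spec_untreated=u,
                avg_spec_hu=h,
            )
        )
    return results


def differential_table(results: Sequence[DifferentialResult]) -> pd.DataFrame:
    """Differential results as a table (prey, bait, AvgSpec_U, AvgSpec_HU, log2FC)."""
    return pd.DataFrame(
        {
            "prey": [r.prey for r in results],
            "bait": [r.bait for r in results],
            "AvgSpec_untreated": [r.avg_spec_untreated for r in results],
            "AvgSpec_HU": [r.avg_spec_hu for r in results],
            "log2FC": [r.log2fc for r in results],
        }
    )


def relative_prey_abundance(
    interactome: Interactome, bait_self_spec: float
) -> dict[str, float]:
    """Prey AvgSpec over the bait's own AvgSpec, capped at 1 (dot-plot sizing)."""
    if bait_self_spec <= 0:
        raise ValueError(f"bait_self_spec must be > 0, got {bait_self_spec}")
    return {
        prey: min(1.0, spec / bait_self_spec)
        for prey, spec in interactome.preys.items()
    }
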