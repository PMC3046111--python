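"""Dysregulation and drug-reversal classification of miRNA expression.

The experimental design pools replicates into one log2 expression value per
miRNA per group, with four canonical groups:

``control``       untreated healthy animals,
``disease``       the disease model,
``disease_drug``  disease model receiving the drug,
``drug_only``     healthy animals receiving the drug.

A miRNA is *dysregulated* when its disease value deviates from control by at
least a log2 threshold (default 0.5, boundary inclusive).  A dysregulated
miRNA is *drug-reversed* (a "reversed miRNA", historically PRmiR for a
propranolol study design) when the drug moves its disease expression back
toward control with a linear fold change strictly above a fold threshold
(default 1.5).  Between-group similarity over the dysregulated set is the
Pearson correlation of deviation-from-control vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, ParameterError, UndefinedResultError

#: Canonical group labels, in file-column order.
GROUPS = ("control", "disease", "disease_drug", "drug_only")

DEFAULT_DYSREGULATION_THRESHOLD = 0.5   # log2 units, boundary inclusive
DEFAULT_REVERSAL_FOLD = 1.5             # linear fold, strict inequality


@dataclass(frozen=True)
class ExpressionTable:
    """Per-miRNA log2 expression values, one column per canonical group.

    ``data`` is indexed by miRNA identifier with exactly the columns in
    :data:`GROUPS`.  Values must be finite.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for group in GROUPS:
            if group not in self.data.columns:
                raise InputError(f"expression table is missing group column "
                                 f"{group!r}")
        values = self.data[list(GROUPS)].to_numpy(dtype=float)
        if not np.isfinite(values).all():
            bad = self.data.index[~np.isfinite(values).all(axis=1)]
            raise InputError(f"non-finite expression values for miRNA(s): "
                             f"{', '.join(map(str, bad[:5]))}")

    @property
    def mirnas(self) -> list[str]:
        return list(self.data.index)

    def value(self, mirna_id: str, group: str) -> float:
        if group not in GROUPS:
            raise InputError(f"unknown group label {group!r}; expected one "
                             f"of {GROUPS}")
        return float(self.data.at[mirna_id, group])

    def deviations(self, group: str) -> pd.Series:
        """Deviation-from-control vector ``value(group) - value(control)``."""
        if group not in GROUPS:
            raise InputError(f"unknown group label {group!r}; expected one "
                             f"of {GROUPS}")
        return self.data[group] - self.data["control"]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   group_map: Mapping[str, str] | None = None,
                   id_column: str = "mirna_id") -> "ExpressionTable":
        """Build a table from a DataFrame, optionally remapping group labels.

        ``group_map`` maps file column names to canonical labels, e.g.
        ``{"MI": "disease"}``.
        """
        frame = frame.copy()
        if id_column in frame.columns:
            frame = frame.set_index(id_column)
        if group_map:
            frame = frame.rename(columns=dict(group_map))
        return cls(frame)

    @classmethod
    def read_tsv(cls, path: str | Path,
                 group_map: Mapping[str, str] | None = None) -> "ExpressionTable":
        frame = pd.read_csv(path, sep="\t")
        if frame.columns[0] != "mirna_id":
            frame = frame.rename(columns={frame.columns[0]: "mirna_id"})
        return cls.from_frame(frame, group_map=group_map)

    def write_tsv(self, path: str | Path) -> None:
        self.data[list(GROUPS)].to_csv(path, sep="\t",
                                       index_label="mirna_id",
                                       float_format="%.6g")


@dataclass(frozen=True)
class DysregulationCall:
    """Classification of one miRNA: disease deviation and drug reversal."""

    mirna_id: str
    delta_disease: float          # log2 deviation from control in disease
    direction: str                # 'up' | 'down' | 'none'
    is_dysregulated: bool
    is_prmir: bool = False        # drug-reversed dysregulated miRNA
    reversal_fold: float = 1.0    # linear fold, disease_drug vs disease, >= 1


def detect_dysregulated(table: ExpressionTable,
                        threshold: float = DEFAULT_DYSREGULATION_THRESHOLD,
                        ) -> list[DysregulationCall]:
    """Call dysregulation from the disease deviation from control.

    A miRNA is dysregulated when ``|disease - control| >= threshold`` on the
    log2 scale; the boundary counts as dysregulated.  Returns one call per
    miRNA, in table order.
    """
    if threshold <= 0:
        raise ParameterError(f"dysregulation threshold must be > 0, "
                             f"got {threshold}")
    calls = []
    deltas = table.deviations("disease")
    for mirna_id, delta in deltas.items():
        delta = float(delta)
        if delta >= threshold:
            direction = "up"
        elif delta <= -threshold:
            direction = "down"
        else:
            direction = "none"
        calls.append(DysregulationCall(
            mirna_id=str(mirna_id),
            delta_disease=delta,
            direction=direction,
            is_dysregulated=direction != "none",
        ))
    return calls


def identify_prmirs(calls: Sequence[DysregulationCall],
                    table: ExpressionTable,
                    fold_threshold: float = DEFAULT_REVERSAL_FOLD,
                    ) -> list[DysregulationCall]:
    """Flag drug-reversed miRNAs among the dysregulated calls.

    A call becomes a reversed miRNA when all three hold:

    1. it is dysregulated;
    2. the ``disease_drug`` value moves from the ``disease`` value toward
       the ``control`` value (reversal, not mere change);
    3. the linear fold change ``2**|disease_drug - disease|`` is strictly
       greater than ``fold_threshold``.

    Returns new call records; ``reversal_fold`` is filled for every miRNA.
    """
    if fold_threshold <= 1:
        raise ParameterError(f"reversal fold threshold must be > 1, "
                             f"got {fold_threshold}")
    out = []
    for call in calls:
        control = table.value(call.mirna_id, "control")
        disease = table.value(call.mirna_id, "disease")
        treated = table.value(call.mirna_id, "disease_drug")
        fold = float(2.0 ** abs(treated - disease))
        toward_control = (control - disease) * (treated - disease) > 0
        is_prmir = (call.is_dysregulated and toward_control
                    and fold > fold_threshold)
        out.append(replace(call, is_prmir=is_prmir, reversal_fold=fold))
    return out


def expression_similarity(table: ExpressionTable, group_a: str, group_b: str,
                          dmirs: Iterable[str]) -> float:
    """Pearson correlation of two deviation-from-control vectors.

    Restricted to the dysregulated miRNAs ``dmirs``; symmetric in the two
    groups.  Undefined (raises) for fewer than 3 miRNAs or a zero-variance
    deviation vector.
    """
    dmirs = list(dmirs)
    if len(dmirs) < 3:
        raise UndefinedResultError(
            f"similarity needs at least 3 dysregulated miRNAs, got {len(dmirs)}")
    dev_a = table.deviations(group_a).loc[dmirs].to_numpy(dtype=float)
    dev_b = table.deviations(group_b).loc[dmirs].to_numpy(dtype=float)
    if np.ptp(dev_a) == 0 or np.ptp(dev_b) == 0:
        raise UndefinedResultError(
            f"zero-variance deviation vector for {group_a!r} or {group_b!r}")
    r, _ = stats.pearsonr(dev_a, dev_b)
    return float(r)


def similarity_matrix(table: ExpressionTable, dmirs: Iterable[str],
                      groups: Sequence[str] = ("disease", "disease_drug",
                                               "drug_only")) -> pd.DataFrame:
    """Symmetric between-group similarity matrix over the dysregulated set."""
    dmirs = list(dmirs)
    mat = pd.DataFrame(np.eye(len(groups)), index=groups, columns=groups)
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            r = expression_similarity(table, a, b, dmirs)
            mat.at[a, b] = mat.at[b, a] = r
    return mat


def calls_to_frame(calls: Sequence[DysregulationCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "mirna_id": c.mirna_id,
        "delta_disease": c.delta_disease,
        "direction": c.direction,
        "is_dysregulated": c.is_dysregulated,
        "is_prmir": c.is_prmir,
        "reversal_fold": c.reversal_fold,
    } for c in calls]).set_index("mirna_id")


def write_calls_tsv(calls: Sequence[DysregulationCall],
                    path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", float_format="%.6g")
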