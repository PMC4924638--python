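"""Reading and normalizing absolute proteomics and FPKM transcriptomics tables.

Absolute proteomics arrives as copies per cell; all downstream analysis
works in proteome **mass fractions**: ``m[i,c] = copies[i,c]*mw[i] /
sum_j copies[j,c]*mw[j]``.  Transcriptomes arrive as FPKM with gene
lengths; a gene's transcriptome fraction is FPKM x length normalized over
all genes (proportional to transcript mass).

The evolved-strain analysis reuses the utilized-set ensembles from the
ancestral environment: for each sampled utilized set U, the change in the
utilized transcriptome fraction between an evolved strain and the wild
type is the mass of U in the evolved fractions minus its mass in the
wild-type fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import ModelError
from .solver import DemandProfile
from .utilization import TurnoverTable, turnover_ratios

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "AbundanceTable",
    "TranscriptomeTable",
    "read_abundance_table",
    "write_abundance_table",
    "to_mass_fractions",
    "read_transcriptome_table",
    "write_transcriptome_table",
    "transcriptome_fractions",
    "utilized_transcriptome_change",
    "evolved_turnover_change",
]


class ParseError(ModelError):
    """A table failed validation; messages carry 1-based file line numbers."""


@dataclass
class AbundanceTable:
    """Absolute protein abundances: copies per cell across conditions.

    ``data`` is indexed by protein id with a ``mw`` column (g/mmol)
    followed by one column per condition; ``growth_rates`` maps each
    condition to its measured growth rate (1/h).
    """

    data: pd.DataFrame
    growth_rates: pd.Series

    @property
    def conditions(self) -> list[str]:
        return [c for c in self.data.columns if c != "mw"]

    @property
    def copies(self) -> pd.DataFrame:
        return self.data[self.conditions]


@dataclass
class TranscriptomeTable:
    """FPKM expression with gene lengths (nt) across strains."""

    data: pd.DataFrame
    growth_rates: Optional[pd.Series] = None

    @property
    def strains(self) -> list[str]:
        return [c for c in self.data.columns if c != "length"]


def _read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t")
    except Exception as exc:  # malformed file
        raise ParseError(f"{path}: cannot parse TSV: {exc}") from exc


def _check_duplicates(df: pd.DataFrame, key: str, path) -> None:
    dup = df[key][df[key].duplicated()]
    if not dup.empty:
        lineno = int(dup.index[0]) + 2  # header line + 1-based
        raise ParseError(f"{path}: duplicate {key} {dup.iloc[0]!r} at line {lineno}")


def read_growth_rates(path: str | Path) -> pd.Series:
    """Read the one-row condition -> growth-rate sidecar TSV."""
    df = _read_tsv(path)
    if len(df) != 1:
        raise ParseError(f"{path}: growth-rate sidecar must have exactly one row")
    series = df.iloc[0].astype(float)
    if (series <= 0).any():
        bad = series[series <= 0].index[0]
        raise ParseError(f"{path}: non-positive growth rate for condition {bad!r}")
    return series


def read_abundance_table(
    path: str | Path, growth_rates: str | Path | pd.Series | None = None
) -> AbundanceTable:
    """Read a protein/mw/conditions TSV (plus growth-rate sidecar)."""
    df = _read_tsv(path)
    if "protein" not in df.columns or "mw" not in df.columns:
        raise ParseError(f"{path}: header must contain 'protein' and 'mw' columns")
    _check_duplicates(df, "protein", path)
    conditions = [c for c in df.columns if c not in ("protein", "mw")]
    if not conditions:
        raise ParseError(f"{path}: no condition columns found")
    for col in ["mw", *conditions]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | ((vals <= 0) if col == "mw" else False)
        if bad.any():
            lineno = int(df.index[bad][0]) + 2
            raise ParseError(
                f"{path}: invalid value in column {col!r} at line {lineno}"
            )
        df[col] = vals
    data = df.set_index("protein")
    if isinstance(growth_rates, (str, Path)):
        rates = read_growth_rates(growth_rates)
    elif growth_rates is None:
        rates = pd.Series(dtype=float)
    else:
        rates = growth_rates.astype(float)
    missing = set(conditions) - set(rates.index)
    if len(rates) and missing:
        raise ParseError(f"growth rates missing for conditions: {sorted(missing)}")
    return AbundanceTable(data=data, growth_rates=rates.reindex(conditions))


def write_abundance_table(
    table: AbundanceTable, path: str | Path, growth_rates_path: str | Path | None = None
) -> None:
    out = table.data.reset_index()
    out.to_csv(path, sep="\t", index=False)
    if growth_rates_path is not None:
        table.growth_rates.to_frame().T.to_csv(growth_rates_path, sep="\t", index=False)


def to_mass_fractions(table: AbundanceTable) -> pd.DataFrame:
    """Convert copies per cell to per-condition proteome mass fractions."""
    mass = table.copies.mul(table.data["mw"], axis=0)
    totals = mass.sum(axis=0)
    zero = totals[totals <= 0]
    if not zero.empty:
        raise ParseError(f"condition {zero.index[0]!r} has zero total protein mass")
    return mass.div(totals, axis=1)


def read_transcriptome_table(
    path: str | Path, growth_rates: str | Path | pd.Series | None = None
) -> TranscriptomeTable:
    """Read a gene/length/strain-FPKM TSV."""
    df = _read_tsv(path)
    if "gene" not in df.columns or "length" not in df.columns:
        raise ParseError(f"{path}: header must contain 'gene' and 'length' columns")
    _check_duplicates(df, "gene", path)
    strains = [c for c in df.columns if c not in ("gene", "length")]
    if not strains:
        raise ParseError(f"{path}: no strain columns found")
    for col in ["length", *strains]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | ((vals <= 0) if col == "length" else False)
        if bad.any():
            lineno = int(df.index[bad][0]) + 2
            raise ParseError(f"{path}: invalid value in column {col!r} at line {lineno}")
        df[col] = vals
    rates: Optional[pd.Series]
    if isinstance(growth_rates, (str, Path)):
        rates = read_growth_rates(growth_rates)
    elif growth_rates is None:
        rates = None
    else:
        rates = growth_rates.astype(float)
    return TranscriptomeTable(data=df.set_index("gene"), growth_rates=rates)


def write_transcriptome_table(
    table: TranscriptomeTable,
    path: str | Path,
    growth_rates_path: str | Path | None = None,
) -> None:
    table.data.reset_index().to_csv(path, sep="\t", index=False)
    if growth_rates_path is not None and table.growth_rates is not None:
        table.growth_rates.to_frame().T.to_csv(
            growth_rates_path, sep="\t", index=False
        )


def transcriptome_fractions(table: TranscriptomeTable) -> pd.DataFrame:
    """Per-strain transcriptome fractions: FPKM x length, normalized."""
    mass = table.data[table.strains].mul(table.data["length"], axis=0)
    totals = mass.sum(axis=0)
    zero = totals[totals <= 0]
    if not zero.empty:
        raise ParseError(f"strain {zero.index[0]!r} has all-zero FPKM")
    return mass.div(totals, axis=1)


def utilized_transcriptome_change(
    fractions_wt: pd.Series,
    fractions_evolved: pd.Series,
    sets: Sequence[frozenset[str]],
) -> np.ndarray:
    """Distribution of the change in utilized transcriptome fraction.

    One value per sampled utilized set U:
    ``delta = sum_{i in U} f_evolved[i] - sum_{i in U} f_wt[i]``.
    Genes in U missing from either table contribute zero (warned once).
    """
    universe = set(fractions_wt.index) & set(fractions_evolved.index)
    deltas = np.empty(len(sets))
    warned = False
    for k, uset in enumerate(sets):
        present = sorted(uset & universe)
        if not warned and len(present) < len(uset):
            logger.warning(
                "%d utilized genes missing from the transcriptome table",
                len(uset) - len(present),
            )
            warned = True
        deltas[k] = float(
            fractions_evolved.loc[present].sum() - fractions_wt.loc[present].sum()
        )
    return deltas


def evolved_turnover_change(
    fractions: pd.DataFrame,
    demands: Mapping[str, DemandProfile],
    wild_type: str = "wt",
    scope: Optional[set[str]] = None,
) -> tuple[pd.DataFrame, pd.Series, TurnoverTable]:
    """Per-strain changes in relative in-vivo turnover versus the wild type.

    Transcript fractions stand in for protein mass fractions (assuming
    translated protein per transcript is strain-invariant); demands must be
    computed at each strain's own growth rate.  Returns the per-protein
    change matrix (strains as columns, wild type dropped), the per-strain
    median change, and the underlying turnover table.
    """
    if wild_type not in fractions.columns:
        raise ModelError(f"wild-type column {wild_type!r} absent")
    if wild_type not in demands:
        raise ModelError(f"no demand profile for wild type {wild_type!r}")
    table = turnover_ratios(demands, fractions, scope=scope)
    rel = table.relative
    change = rel.drop(columns=[wild_type]).sub(rel[wild_type], axis=0)
    medians = change.median(axis=0)
    return change, medians, table
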