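"""Methylxanthine positivity and chemistry/aDNA concordance.

Theobromine, theophylline and caffeine amounts (pg/sample) are called
positive above a strict threshold (default 700 pg — values at exactly
the threshold are negative, and sub-threshold values are reported as 0
in output tables). The ambient-contamination background is located as
the largest gap in the sorted log10 values, which on the real data sits
near 200 pg. Concordance between chemical and genetic presence is a
per-analyte 2x2 table with half-up integer-rounded percentages in both
directions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

ANALYTES = ("theobromine", "theophylline", "caffeine")


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def call_positive(records: pd.DataFrame, threshold: float = 700.0) -> pd.DataFrame:
    """Per-item, per-analyte positivity flags (strict ``value > threshold``)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    analytes = [a for a in ANALYTES if a in records.columns]
    if not analytes:
        raise ValueError("no analyte columns present")
    vals = records[analytes]
    if (vals.fillna(0) < 0).any().any():
        raise ValueError("methylxanthine values must be non-negative")
    flags = vals > threshold
    if "item_id" in records.columns:
        flags.index = records["item_id"]
    return flags


def zeroed_table(records: pd.DataFrame, threshold: float = 700.0) -> pd.DataFrame:
    """Reporting convention: sub-threshold values written as 0."""
    out = records.copy()
    for a in ANALYTES:
        if a in out.columns:
            out[a] = out[a].where(out[a] > threshold, 0.0)
    return out


def positivity_rate(flags: Iterable[bool]) -> tuple[int, float]:
    """(integer percent, one-decimal percent) of positive flags."""
    flags = np.asarray(list(flags), dtype=bool)
    if flags.size == 0:
        raise ValueError("no flags")
    pct = 100.0 * flags.sum() / flags.size
    return round_half_up(pct), round(pct, 1)


@dataclass
class BackgroundBreak:
    breakpoint: float | None  # geometric midpoint of the gap; None if no break
    background_upper: float | None  # last value below the gap (the ~200 pg edge)
    positive_lower: float | None  # first value above the gap
    gap_log10: float
    n_values: int


def estimate_background_break(values, min_gap_log10: float = 0.3) -> BackgroundBreak:
    """Locate the background/positive break in a set of measurements.

    On log10-transformed, sorted positive values below the 95th
    percentile, the breakpoint is the geometric midpoint of the largest
    gap between consecutive values; the gap's edges are reported too,
    the lower one being the top of the background (ambient-contamination)
    cluster. A largest gap below ``min_gap_log10`` (a ~2x noise floor)
    means no clear break exists and the breakpoint is undefined.
    """
    v = np.asarray([x for x in values if x > 0], dtype=float)
    if v.size < 20:
        raise ValueError("need at least 20 positive-valued measurements")
    logs = np.sort(np.log10(v))
    logs = logs[logs <= np.quantile(logs, 0.95)]
    gaps = np.diff(logs)
    if gaps.size == 0:
        return BackgroundBreak(None, None, None, 0.0, int(v.size))
    i = int(np.argmax(gaps))
    gap = float(gaps[i])
    if gap < min_gap_log10:
        return BackgroundBreak(None, None, None, gap, int(v.size))
    mid = (logs[i] + logs[i + 1]) / 2.0
    return BackgroundBreak(
        float(10**mid), float(10 ** logs[i]), float(10 ** logs[i + 1]), gap, int(v.size)
    )


@dataclass
class ConcordanceTable:
    """2x2 agreement between a chemical flag and the aDNA presence call."""

    analyte: str
    n_items: int
    chem_pos: int
    adna_pos: int
    both_pos: int
    chem_only: int
    adna_only: int
    neither: int
    pct_chem_to_adna: int  # among chem-positive items, % aDNA-positive
    pct_adna_to_chem: int  # among aDNA-positive items, % chem-positive
    pct_chem_to_adna_1dp: float
    pct_adna_to_chem_1dp: float


def concordance(
    chem_flags: pd.DataFrame,
    adna_calls: Mapping[str, bool] | pd.Series,
) -> dict[str, ConcordanceTable]:
    """Per-analyte concordance between chemistry and aDNA presence.

    ``chem_flags`` is indexed by item id with boolean analyte columns;
    ``adna_calls`` maps item id -> aDNA-positive. Only items present in
    both are counted, and the id sets must coincide — orphans on either
    side raise with the offending ids listed.
    """
    adna = pd.Series(adna_calls).astype(bool)
    chem_ids = set(chem_flags.index)
    adna_ids = set(adna.index)
    if not chem_ids or not adna_ids or not (chem_ids & adna_ids):
        raise ValueError("no items shared between chemistry and aDNA calls")
    orphans = chem_ids ^ adna_ids
    if orphans:
        raise ValueError(f"item ids not analyzed by both methods: {sorted(orphans)}")
    items = chem_flags.index
    out = {}
    for analyte in chem_flags.columns:
        c = chem_flags[analyte].astype(bool)
        a = adna.loc[items]
        both = int((c & a).sum())
        chem_pos = int(c.sum())
        adna_pos = int(a.sum())
        p_ca = 100.0 * both / chem_pos if chem_pos else float("nan")
        p_ac = 100.0 * both / adna_pos if adna_pos else float("nan")
        out[analyte] = ConcordanceTable(
            analyte=analyte,
            n_items=len(items),
            chem_pos=chem_pos,
            adna_pos=adna_pos,
            both_pos=both,
            chem_only=chem_pos - both,
            adna_only=adna_pos - both,
            neither=int((~c & ~a).sum()),
            pct_chem_to_adna=round_half_up(p_ca) if chem_pos else -1,
            pct_adna_to_chem=round_half_up(p_ac) if adna_pos else -1,
            pct_chem_to_adna_1dp=round(p_ca, 1) if chem_pos else float("nan"),
            pct_adna_to_chem_1dp=round(p_ac, 1) if adna_pos else float("nan"),
        )
    return out


def flags_from_counts(n_items: int, n_chem_pos: int, n_both: int, n_adna_pos: int):
    """Construct a consistent per-item flag table from 2x2 margins.

    Convenience for reproducing published concordance arithmetic from
    printed counts: returns (chem flag Series, aDNA flag Series) over
    synthetic item ids.
    """
    if not (n_both <= min(n_chem_pos, n_adna_pos) and n_chem_pos + n_adna_pos - n_both <= n_items):
        raise ValueError("inconsistent 2x2 margins")
    ids = [f"I{i + 1:03d}" for i in range(n_items)]
    chem = pd.Series(False, index=ids)
    adna = pd.Series(False, index=ids)
    chem.iloc[:n_chem_pos] = True
    adna.iloc[:n_both] = True
    adna.iloc[n_chem_pos:n_chem_pos + (n_adna_pos - n_both)] = True
    return chem, adna
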