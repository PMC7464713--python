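"""Differential-expression filtering and summary arithmetic.

Implements the downstream filter applied to per-gene microarray results:
a gene is differentially expressed when its signed fold change exceeds +1.5
or falls below −1.5 (strict inequalities) *and* its LIMMA p-value is below
0.05. Fold changes use the signed convention common in array reports:
−1.95 means 1.95-fold down-regulated; values in (−1, 1) cannot occur and a
fold change of exactly ±1 means "unchanged". Upstream statistics (SST-RMA
summarization, LIMMA model fitting) are out of scope — only the filter and
its summary arithmetic live here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "GeneRecord",
    "DEGFilterCriteria",
    "FilterSummary",
    "WNT_PATHWAY_TABLE",
    "filter_records",
    "summarize_profile",
    "read_gene_table",
    "write_gene_table",
]


@dataclass(frozen=True)
class GeneRecord:
    """One per-gene row: signed fold change, p-value (may be missing), tags."""

    symbol: str
    fold_change: float
    p_value: float | None = None
    pathway_tags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.fold_change == 0:
            raise ValueError(f"{self.symbol}: fold_change must be non-zero (signed ratio)")
        if self.p_value is not None and not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"{self.symbol}: p_value must be in (0, 1], got {self.p_value}")
        object.__setattr__(self, "pathway_tags", frozenset(self.pathway_tags))

    @property
    def up_regulated(self) -> bool:
        return self.fold_change > 0


@dataclass(frozen=True)
class DEGFilterCriteria:
    """Strict cutoffs: fold change > up OR < down, AND p-value < threshold."""

    fc_up_threshold: float = 1.5
    fc_down_threshold: float = -1.5
    p_threshold: float = 0.05

    def __post_init__(self) -> None:
        if not (self.fc_up_threshold > 0 > self.fc_down_threshold):
            raise ValueError("need fc_up_threshold > 0 > fc_down_threshold")
        if not (0.0 < self.p_threshold < 1.0):
            raise ValueError("p_threshold must be in (0, 1)")

    def passes(self, record: GeneRecord) -> bool:
        if record.p_value is None or not record.p_value < self.p_threshold:
            return False
        return (
            record.fold_change > self.fc_up_threshold
            or record.fold_change < self.fc_down_threshold
        )


#: Wnt-pathway-tagged rows of the microarray comparison (P5 vs Ref, 24 h)
#: as printed in the study: signed fold change and LIMMA p-value. CTNNB1
#: (β-catenin itself) was reported as unchanged, without a printed p-value.
WNT_PATHWAY_TABLE: list[GeneRecord] = [
    GeneRecord("WLS", 1.87, 0.0299, frozenset({"Wnt"})),
    GeneRecord("SOST", 1.57, 0.0006, frozenset({"Wnt"})),
    GeneRecord("CTNNBIP1", 1.65, 0.0164, frozenset({"Wnt"})),
    GeneRecord("SOX17", 1.58, 0.0066, frozenset({"Wnt"})),
    GeneRecord("TCF4", 1.55, 0.0397, frozenset({"Wnt"})),
    GeneRecord("SFRP4", -1.95, 0.0062, frozenset({"Wnt"})),
    GeneRecord("AXIN2", -1.82, 0.3533, frozenset({"Wnt"})),
    GeneRecord("DVL3", 1.36, 0.0152, frozenset({"Wnt"})),
    GeneRecord("CTNNB1", 1.08, None, frozenset({"Wnt"})),
]


def filter_records(
    records: Sequence[GeneRecord],
    criteria: DEGFilterCriteria | None = None,
    tag: str | None = None,
) -> list[GeneRecord]:
    """Apply the DEG filter; optionally restrict to one pathway tag.

    Records with a missing p-value are excluded. Input order is preserved,
    so the filter is idempotent.
    """
    if not records:
        raise ValueError("records must be non-empty")
    criteria = criteria or DEGFilterCriteria()
    pool = records if tag is None else [r for r in records if tag in r.pathway_tags]
    return [r for r in pool if criteria.passes(r)]


@dataclass(frozen=True)
class FilterSummary:
    n: int
    percent_of_all: float   # rounded to 2 decimals
    n_up: int
    n_down: int
    percent_up: float       # rounded to 1 decimal
    percent_down: float


def summarize_profile(all_count: int, filtered: Sequence[GeneRecord]) -> FilterSummary:
    """Summary arithmetic over a filtered gene list.

    ``percent_of_all`` is rounded to 2 decimals, direction percentages to
    1 decimal; "up" means a positive signed fold change.
    """
    n = len(filtered)
    if n == 0:
        raise ValueError("filtered list must be non-empty")
    if all_count < n:
        raise ValueError(f"all_count ({all_count}) < number of filtered genes ({n})")
    n_up = sum(1 for r in filtered if r.up_regulated)
    n_down = n - n_up
    return FilterSummary(
        n=n,
        percent_of_all=round(100.0 * n / all_count, 2),
        n_up=n_up,
        n_down=n_down,
        percent_up=round(100.0 * n_up / n, 1),
        percent_down=round(100.0 * n_down / n, 1),
    )


# ---------------------------------------------------------------------------
# CSV dialect: symbol, fold_change, p_value, pathway_tags (semicolon-joined)
# ---------------------------------------------------------------------------

def read_gene_table(path) -> list[GeneRecord]:
    df = pd.read_csv(path)
    records = []
    for row in df.itertuples():
        p = getattr(row, "p_value", None)
        tags = getattr(row, "pathway_tags", "")
        records.append(
            GeneRecord(
                symbol=str(row.symbol),
                fold_change=float(row.fold_change),
                p_value=None if pd.isna(p) else float(p),
                pathway_tags=frozenset(
                    t for t in str(tags or "").split(";") if t and t != "nan"
                ),
            )
        )
    return records


def write_gene_table(path, records: Iterable[GeneRecord]) -> None:
    pd.DataFrame(
        [
            {
                "symbol": r.symbol,
                "fold_change": r.fold_change,
                "p_value": r.p_value,
                "pathway_tags": ";".join(sorted(r.pathway_tags)),
            }
            for r in records
        ]
    ).to_csv(path, index=False)
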