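"""Event-level validation of isoform switching from split-read counts.

Reads spanning exon-exon junctions give a quantification-free check on an
isoform switch called from abundance estimates.  For a skipped exon, reads
supporting the two inclusion flank junctions and the skipping junction are
turned into a per-sample fraction (the share of reads supporting the
skipping isoform); for events distinguished by two alternative junctions
(alternative promoters, terminal exons, mutually exclusive exons) the
fraction is the share supporting one of the two.  Group shifts are tested
with a one-sided Wilcoxon rank-sum test whose direction is fixed in advance
by the expectation from the abundance-based analysis.

Junction coordinates follow the STAR ``SJ.out.tab`` convention: 1-based,
intron-inclusive start/end.  The on-disk table is a long TSV with columns
``chrom  intron_start  intron_end  strand  sample_id  unique_read_count``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .dirtest import rank_sum_pvalue

EVENT_TYPES = ("skipped_exon", "alt_promoter", "mutually_exclusive",
               "alt_terminal")

#: junction roles per event type
_THREE_WAY_ROLES = ("flank_left", "flank_right", "skip")
_TWO_WAY_ROLES = ("junction_a", "junction_b")

Junction = tuple[str, int, int, str]  # chrom, intron start, intron end, strand


@dataclass
class JunctionEvent:
    """A splicing event defined by named junctions.

    ``junctions`` maps role names (``flank_left``/``flank_right``/``skip``
    for skipped exons; ``junction_a``/``junction_b`` for two-way events) to
    1-based intron-inclusive coordinates.  ``favored_direction`` is the
    expected metastatic shift of the event fraction (``greater``/``less``),
    set in advance from the abundance-based call.
    """

    gene_id: str
    event_type: str
    junctions: dict[str, Junction]
    favored_direction: str = "greater"

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        roles = (_THREE_WAY_ROLES if self.event_type == "skipped_exon"
                 else _TWO_WAY_ROLES)
        if set(self.junctions) != set(roles):
            raise ValueError(
                f"{self.event_type} event needs junctions {roles}, "
                f"got {sorted(self.junctions)}"
            )
        for j in self.junctions.values():
            if not j[1] < j[2]:
                raise ValueError(f"junction {j} must have intron start < end")
        if self.favored_direction not in ("greater", "less"):
            raise ValueError("favored_direction must be greater/less")


@dataclass
class JunctionCountTable:
    """Per-sample split-read counts, junctions x samples.

    ``counts`` is indexed by (chrom, intron_start, intron_end, strand);
    values are non-negative integers (missing junctions count as 0 reads).
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("junction read counts must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def sample_counts(self, junction: Junction) -> pd.Series:
        key = tuple(junction)
        if key in self.counts.index:
            return self.counts.loc[key]
        return pd.Series(0, index=self.counts.columns)


def read_junction_counts(path) -> JunctionCountTable:
    long = pd.read_csv(path, sep="\t", dtype={
        "chrom": str, "strand": str, "sample_id": str,
    })
    expected = ["chrom", "intron_start", "intron_end", "strand",
                "sample_id", "unique_read_count"]
    if list(long.columns) != expected:
        raise ValueError(f"junction table must have columns {expected}")
    wide = long.pivot_table(
        index=["chrom", "intron_start", "intron_end", "strand"],
        columns="sample_id", values="unique_read_count",
        aggfunc="sum", fill_value=0,
    ).astype(int)
    wide.columns.name = None
    return JunctionCountTable(wide)


def write_junction_counts(table: JunctionCountTable, path) -> None:
    long = (
        table.counts.stack()
        .rename("unique_read_count")
        .reset_index()
    )
    long.columns = ["chrom", "intron_start", "intron_end", "strand",
                    "sample_id", "unique_read_count"]
    long.to_csv(path, sep="\t", index=False)


def read_events(path) -> list[JunctionEvent]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    events = []
    for (gene, etype, direction), grp in df.groupby(
        ["gene_id", "event_type", "favored_direction"], sort=False
    ):
        junctions = {
            row["role"]: (row["chrom"], int(row["intron_start"]),
                          int(row["intron_end"]), row["strand"])
            for _, row in grp.iterrows()
        }
        events.append(JunctionEvent(gene, etype, junctions, direction))
    return events


def write_events(events: list[JunctionEvent], path) -> None:
    rows = []
    for ev in events:
        for role, (chrom, start, end, strand) in ev.junctions.items():
            rows.append({
                "gene_id": ev.gene_id, "event_type": ev.event_type,
                "role": role, "chrom": chrom, "intron_start": start,
                "intron_end": end, "strand": strand,
                "favored_direction": ev.favored_direction,
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# per-sample fractions
# ---------------------------------------------------------------------------

def fraction_skipped_exon(
    skip_count: float, flank_left: float, flank_right: float
) -> float:
    """Fraction of reads supporting the exon-skipping isoform.

    Inclusion support is the average of the two flank junction counts;
    the fraction is skip / (skip + inclusion).  Returns NaN when no reads
    cover the event (the sample is then excluded from group tests).
    """
    if skip_count < 0 or flank_left < 0 or flank_right < 0:
        raise ValueError("junction counts must be non-negative")
    inclusion = (flank_left + flank_right) / 2.0
    total = skip_count + inclusion
    if total == 0:
        return float("nan")
    return skip_count / total


def fraction_two_way(count_a: float, count_b: float) -> float:
    """Fraction of reads supporting junction A out of the two alternatives;
    NaN when both counts are zero."""
    if count_a < 0 or count_b < 0:
        raise ValueError("junction counts must be non-negative")
    total = count_a + count_b
    if total == 0:
        return float("nan")
    return count_a / total


def event_fractions(
    event: JunctionEvent, table: JunctionCountTable
) -> pd.Series:
    """Per-sample event fraction, NaN for samples with no covering reads."""
    if event.event_type == "skipped_exon":
        skip = table.sample_counts(event.junctions["skip"])
        left = table.sample_counts(event.junctions["flank_left"])
        right = table.sample_counts(event.junctions["flank_right"])
        return pd.Series(
            [fraction_skipped_exon(s, l, r)
             for s, l, r in zip(skip, left, right)],
            index=table.sample_ids,
        )
    a = table.sample_counts(event.junctions["junction_a"])
    b = table.sample_counts(event.junctions["junction_b"])
    return pd.Series(
        [fraction_two_way(x, y) for x, y in zip(a, b)],
        index=table.sample_ids,
    )


def junction_group_test(
    event: JunctionEvent,
    table: JunctionCountTable,
    meta: pd.DataFrame,
    group_col: str = "sample_type",
) -> dict:
    """One-sided rank-sum test of the event fraction, metastatic vs primary.

    The alternative is the event's ``favored_direction`` (the shift
    expected from the abundance-based analysis).  Samples with a missing
    fraction are dropped and counted; a group left without >= 2 usable
    samples makes the event untestable.

    Returns a dict with the group medians/means, usable and dropped sample
    counts, and the one-sided p-value.
    """
    fracs = event_fractions(event, table)
    labels = meta[group_col].reindex(fracs.index)
    out: dict[str, float] = {"gene_id": event.gene_id,
                             "event_type": event.event_type}
    groups = {}
    for name in ("metastatic", "primary"):
        vals = fracs[(labels == name).to_numpy()]
        usable = vals.dropna()
        out[f"n_{name}"] = int(len(usable))
        out[f"n_dropped_{name}"] = int(vals.isna().sum())
        out[f"median_{name}"] = float(usable.median()) if len(usable) else float("nan")
        out[f"mean_{name}"] = float(usable.mean()) if len(usable) else float("nan")
        groups[name] = usable.to_numpy()
    if len(groups["metastatic"]) < 2 or len(groups["primary"]) < 2:
        raise ValueError(f"untestable event for gene {event.gene_id!r}: "
                         "fewer than 2 usable samples in a group")
    out["p"] = rank_sum_pvalue(
        groups["metastatic"], groups["primary"],
        alternative=event.favored_direction,
    )
    return out
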