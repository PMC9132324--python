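"""Percentile-threshold gene-set enrichment with an empirical FDR.

Ranked gene lists (e.g. DIR or DE results ordered by p-value) are cut at
percentile thresholds — the top 5/10/20/40% of genes *with* a p-value,
ceiling-rounded — and each foreground is tested for overrepresentation of
annotation sets (biological processes, kinome phylogenetic groups) with a
one-sided hypergeometric test against the remaining genes as background.
Percentile foregrounds keep differently-powered analyses comparable: a
fixed p cutoff can select half the genes in a large cohort and almost none
in a small one.

P-values are deliberately not multiplicity-adjusted (annotation sets are
strongly dependent and share a constrained universe); the companion
empirical FDR replays the enrichment on random foregrounds of the same
size to show how many annotations pass any alpha by chance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_FRACTIONS = (0.05, 0.10, 0.20, 0.40)


@dataclass
class EnrichmentRecord:
    """One annotation x threshold 2x2 test.

    ``a``: foreground & annotated, ``b``: foreground & not, ``c``:
    background & annotated, ``d``: background & not.  ``odds_ratio`` uses
    0.5 continuity only when some cell is zero (``inf`` when the corrected
    denominator would still be zero cannot occur then).
    """

    annotation_id: str
    threshold_fraction: Optional[float]
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p: float


def percentile_foreground(
    ranked_genes: Sequence[str], fraction: float
) -> list[str]:
    """Top ``ceil(fraction * n)`` genes of a p-value-ascending ranking.

    Only genes that actually received a p-value belong in ``ranked_genes``;
    boundary ties are broken by the stable input order.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    if len(ranked_genes) == 0:
        raise ValueError("ranked gene list is empty")
    k = math.ceil(fraction * len(ranked_genes))
    return list(ranked_genes[:k])


def set_enrichment(
    foreground: Iterable[str],
    universe: Iterable[str],
    annotation_sets: Mapping[str, Iterable[str]],
    threshold_fraction: Optional[float] = None,
) -> list[EnrichmentRecord]:
    """One-sided hypergeometric enrichment of each annotation set.

    The background is ``universe`` minus ``foreground`` (the remaining
    genes, not the whole universe); annotations are intersected with the
    universe first.  P-values are unadjusted by design.
    """
    fg = set(foreground)
    uni = set(universe)
    if not fg <= uni:
        raise ValueError("foreground must be a subset of the universe")
    n_fg = len(fg)
    n_uni = len(uni)
    records = []
    for ann_id, members in annotation_sets.items():
        ann = set(members) & uni
        a = len(fg & ann)
        b = n_fg - a
        c = len(ann) - a
        d = (n_uni - n_fg) - c
        # P(X >= a), X ~ Hypergeom(N=n_uni, K=|ann|, n=n_fg)
        p = float(stats.hypergeom.sf(a - 1, n_uni, len(ann), n_fg))
        if min(a, b, c, d) == 0:
            orat = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            orat = (a * d) / (b * c)
        records.append(EnrichmentRecord(
            ann_id, threshold_fraction, a, b, c, d,
            float(orat), min(p, 1.0)))
    return records


def records_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def kinase_group_enrichment(
    ranked_genes: Sequence[str],
    kinase_groups: pd.Series,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
) -> pd.DataFrame:
    """Kinome phylogenetic-group enrichment at each percentile threshold.

    ``kinase_groups`` maps every ranked gene to its (single) group; the
    annotation sets are the groups themselves and the universe is the
    ranked list.
    """
    missing = [g for g in ranked_genes if g not in kinase_groups.index]
    if missing:
        raise ValueError(f"gene {missing[0]!r} has no kinase group")
    groups = kinase_groups.loc[list(ranked_genes)]
    sets = {grp: set(groups.index[groups == grp])
            for grp in sorted(groups.unique())}
    records: list[EnrichmentRecord] = []
    for fraction in fractions:
        fg = percentile_foreground(ranked_genes, fraction)
        records.extend(
            set_enrichment(fg, ranked_genes, sets, threshold_fraction=fraction)
        )
    return records_frame(records)


def empirical_fdr(
    annotation_sets: Mapping[str, Iterable[str]],
    universe: Sequence[str],
    foreground_size: int,
    n_random: int = 100,
    alpha: float = 0.05,
    seed: Optional[int] = None,
    observed_count: Optional[int] = None,
) -> dict:
    """Expected number of annotations passing ``alpha`` by chance.

    Draws ``n_random`` uniformly random foregrounds of the observed size,
    reruns :func:`set_enrichment` on each, and reports the mean count of
    annotations with p < alpha (and its ratio to an observed count when
    supplied) — an empirical alternative to multiplicity adjustment.
    """
    universe = list(universe)
    if foreground_size > len(universe):
        raise ValueError("foreground_size exceeds the universe")
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    rng = np.random.default_rng(seed)
    counts = np.empty(n_random)
    for i in range(n_random):
        fg = rng.choice(universe, size=foreground_size, replace=False)
        recs = set_enrichment(fg, universe, annotation_sets)
        counts[i] = sum(r.p < alpha for r in recs)
    out = {
        "mean_random_count": float(counts.mean()),
        "alpha": alpha,
        "n_random": n_random,
    }
    if observed_count is not None:
        out["observed_count"] = observed_count
        out["fdr_ratio"] = (float(counts.mean()) / observed_count
                            if observed_count > 0 else float("inf"))
    return out
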