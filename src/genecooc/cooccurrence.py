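"""Enrichment screen: which families track the anchor's phylogenetic profile?

Given a presence/absence matrix and an anchor family, every other family is
crossed against the anchor into a 2x2 contingency table of genome counts and
scored with a two-sided exact hypergeometric (Fisher) test; p-values are
adjusted by Benjamini-Hochberg step-up FDR. The module also produces the
conditional co-occurrence summary for a chosen anchor/partner pair — the
counts behind statements like "89% of anchor-positive genomes also carry the
partner".

The exact test is computed here from first principles (log-factorials via
``gammaln``) so that its two-sided convention — sum the probabilities of all
tables with the same margins whose probability does not exceed the observed
table's — is pinned down and testable against brute-force enumeration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .profiles import PresenceAbsenceMatrix, normalize_family_id

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "FisherResult",
    "EnrichmentResult",
    "CoOccurrenceSummary",
    "StratumCounts",
    "contingency_for_family",
    "fisher_exact",
    "bh_adjust",
    "screen_all_families",
    "cooccurrence_summary",
    "enrichment_to_tsv",
]

Alternative = Literal["two_sided", "greater", "less"]

# Slack, on the log scale, used when deciding whether a table is "as or more
# extreme" than the observed one. Mathematically tied probabilities computed
# through gammaln differ by a few ulps; this absorbs that without admitting
# genuinely less-extreme tables.
_LOG_TIE_EPS = 1e-9


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 cross-tabulation of anchor presence vs. candidate-family presence.

    a: anchor+/family+, b: anchor+/family-, c: anchor-/family+,
    d: anchor-/family-. All entries are genome counts.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            if getattr(self, name) < 0:
                raise ValueError(f"contingency count {name} must be >= 0")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def odds_ratio(self) -> float:
        """Sample odds ratio; inf/nan when zero cells make it undefined."""
        num, den = self.a * self.d, self.b * self.c
        if den == 0:
            return math.nan if num == 0 else math.inf
        return num / den

    @property
    def odds_ratio_corrected(self) -> float:
        """Haldane-Anscombe corrected odds ratio (+0.5 to every cell)."""
        return ((self.a + 0.5) * (self.d + 0.5)) / ((self.b + 0.5) * (self.c + 0.5))


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    odds_ratio: float
    odds_ratio_corrected: float


def _log_binom(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    return gammaln(np.asarray(n) + 1) - gammaln(np.asarray(k) + 1) - gammaln(
        np.asarray(n) - np.asarray(k) + 1
    )


def _hypergeom_support(table: ContingencyTable) -> tuple[np.ndarray, np.ndarray]:
    """Support and log-pmf of cell ``a`` conditional on the table margins."""
    r1, c1, n = table.a + table.b, table.a + table.c, table.n
    k_min, k_max = max(0, r1 + c1 - n), min(r1, c1)
    k = np.arange(k_min, k_max + 1)
    log_pmf = (
        _log_binom(r1, k) + _log_binom(n - r1, c1 - k) - _log_binom(n, c1)
    )
    return k, log_pmf


def fisher_exact(table: ContingencyTable, alternative: Alternative = "two_sided") -> FisherResult:
    """Exact conditional test of independence on a 2x2 table.

    The two-sided p-value sums hypergeometric probabilities, over all tables
    sharing the observed margins, of every table whose probability is at
    most the observed table's (the conventional "as or more extreme" rule).
    One-sided alternatives sum the upper (``greater``) or lower (``less``)
    tail of cell ``a``. Computation is in log-space for stability at large
    genome counts.

    A table with an empty row or column margin admits exactly one
    configuration; p = 1.0 by convention (logged).
    """
    r1, r2 = table.a + table.b, table.c + table.d
    c1, c2 = table.a + table.c, table.b + table.d
    if table.n == 0 or 0 in (r1, r2, c1, c2):
        # A zero margin admits exactly one table with those margins.
        logger.info("degenerate margin in %s: p = 1.0 by convention", table)
        return FisherResult(1.0, table.odds_ratio, table.odds_ratio_corrected)

    k, log_pmf = _hypergeom_support(table)
    observed = int(np.searchsorted(k, table.a))
    if alternative == "two_sided":
        mask = log_pmf <= log_pmf[observed] + _LOG_TIE_EPS
    elif alternative == "greater":
        mask = k >= table.a
    elif alternative == "less":
        mask = k <= table.a
    else:
        raise ValueError(f"unknown alternative: {alternative!r}")
    p = float(min(1.0, np.exp(log_pmf[mask]).sum()))
    # Associations strong enough to underflow double precision are reported
    # at the smallest positive float so p stays in (0, 1].
    p = max(p, 5e-324)
    return FisherResult(p, table.odds_ratio, table.odds_ratio_corrected)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, preserving input order.

    Each input p must lie in (0, 1]. Returns q-values with
    q(i) = min_{j >= i} min(1, p(j) * m / j) on the sorted list.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D collection")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("every p-value must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def contingency_for_family(
    matrix: PresenceAbsenceMatrix, anchor: str, candidate: str
) -> ContingencyTable:
    """Cross the anchor and candidate presence columns into a 2x2 table."""
    if normalize_family_id(anchor) == normalize_family_id(candidate):
        raise ValueError("anchor and candidate must be different families")
    x = matrix.column(anchor)
    y = matrix.column(candidate)
    a = int(np.sum((x == 1) & (y == 1)))
    b = int(np.sum((x == 1) & (y == 0)))
    c = int(np.sum((x == 0) & (y == 1)))
    d = int(np.sum((x == 0) & (y == 0)))
    return ContingencyTable(a, b, c, d)


Direction = Literal["over", "under", "none"]


@dataclass(frozen=True)
class EnrichmentResult:
    family_id: str
    table: ContingencyTable
    odds_ratio: float
    odds_ratio_corrected: float
    p_value: float
    q_value: float
    direction: Direction


def _direction(odds_ratio: float, q_value: float, alpha: float) -> Direction:
    if q_value <= alpha and odds_ratio > 1:
        return "over"
    if q_value <= alpha and odds_ratio < 1:
        return "under"
    return "none"


def screen_all_families(
    matrix: PresenceAbsenceMatrix, anchor: str, alpha: float = 0.05
) -> list[EnrichmentResult]:
    """Test every non-anchor family for over/under-representation in
    anchor-positive genomes.

    Results are ranked by q-value, then by |log corrected odds ratio|
    (largest effect first). Both directions are reported; ``direction`` is
    assigned from the sample odds ratio at FDR level ``alpha``.
    """
    if len(matrix.family_ids) < 2:
        raise ValueError("matrix needs at least 2 families to screen")
    anchor_key = normalize_family_id(anchor)
    x = matrix.column(anchor_key)
    n_pos = int(x.sum())
    if n_pos == 0 or n_pos == len(x):
        raise ValueError(
            "anchor column is constant (all-positive or all-negative); "
            "the comparison is undefined"
        )

    candidates = [f for f in matrix.family_ids if f != anchor_key]
    # Vectorized 2x2 counts: one matrix product per cell.
    data = matrix.data[candidates].to_numpy().astype(np.int64)
    x = x.astype(np.int64)
    a_counts = x @ data
    pos_total = n_pos
    b_counts = pos_total - a_counts
    col_totals = data.sum(axis=0)
    c_counts = col_totals - a_counts
    d_counts = len(x) - pos_total - c_counts

    tables = [
        ContingencyTable(int(a), int(b), int(c), int(d))
        for a, b, c, d in zip(a_counts, b_counts, c_counts, d_counts)
    ]
    fishers = [fisher_exact(t) for t in tables]
    q_values = bh_adjust([f.p_value for f in fishers])

    results = [
        EnrichmentResult(
            family_id=fam,
            table=t,
            odds_ratio=f.odds_ratio,
            odds_ratio_corrected=f.odds_ratio_corrected,
            p_value=f.p_value,
            q_value=float(q),
            direction=_direction(f.odds_ratio, float(q), alpha),
        )
        for fam, t, f, q in zip(candidates, tables, fishers, q_values)
    ]
    results.sort(key=lambda r: (r.q_value, -abs(math.log(r.odds_ratio_corrected))))
    return results


def enrichment_to_tsv(results: Iterable[EnrichmentResult], path: str | Path) -> None:
    rows = [
        {
            "family_id": r.family_id,
            "a": r.table.a,
            "b": r.table.b,
            "c": r.table.c,
            "d": r.table.d,
            "odds_ratio": r.odds_ratio,
            "odds_ratio_corrected": r.odds_ratio_corrected,
            "p": r.p_value,
            "q": r.q_value,
            "direction": r.direction,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class StratumCounts:
    """Co-occurrence counts restricted to one metadata stratum."""

    n_anchor_pos: int
    n_partner_pos: int
    n_both: int

    @property
    def pct_partner_given_anchor(self) -> float | None:
        if self.n_anchor_pos == 0:
            return None
        return 100.0 * self.n_both / self.n_anchor_pos

    @property
    def pct_anchor_given_partner(self) -> float | None:
        if self.n_partner_pos == 0:
            return None
        return 100.0 * self.n_both / self.n_partner_pos


def _round1(x: float | None) -> float | None:
    return None if x is None else round(x, 1)


def _round_int(x: float | None) -> int | None:
    return None if x is None else round(x)


@dataclass(frozen=True)
class CoOccurrenceSummary:
    """Global and per-stratum conditional co-occurrence of two families.

    Exact fractions are stored; one-decimal and integer renderings are
    derived views (the coarser roundings one sees in prose, e.g. "89%").
    """

    anchor: str
    partner: str
    overall: StratumCounts
    by_domain: dict[str, StratumCounts] = field(default_factory=dict)
    by_taxon: dict[str, StratumCounts] = field(default_factory=dict)

    @property
    def n_anchor_pos(self) -> int:
        return self.overall.n_anchor_pos

    @property
    def n_partner_pos(self) -> int:
        return self.overall.n_partner_pos

    @property
    def n_both(self) -> int:
        return self.overall.n_both

    @property
    def pct_partner_given_anchor(self) -> float | None:
        return self.overall.pct_partner_given_anchor

    @property
    def pct_anchor_given_partner(self) -> float | None:
        return self.overall.pct_anchor_given_partner

    def rendered(self) -> dict[str, object]:
        """Counts plus one-decimal and integer-rounded percentage views."""
        return {
            "anchor": self.anchor,
            "partner": self.partner,
            "n_anchor_pos": self.n_anchor_pos,
            "n_partner_pos": self.n_partner_pos,
            "n_both": self.n_both,
            "pct_partner_given_anchor_1dp": _round1(self.pct_partner_given_anchor),
            "pct_partner_given_anchor_int": _round_int(self.pct_partner_given_anchor),
            "pct_anchor_given_partner_1dp": _round1(self.pct_anchor_given_partner),
            "pct_anchor_given_partner_int": _round_int(self.pct_anchor_given_partner),
        }

    def to_tsv(self, path: str | Path) -> None:
        rows = [{"stratum": "all", **_stratum_row(self.overall)}]
        for label, counts in sorted(self.by_domain.items()):
            rows.append({"stratum": f"domain:{label}", **_stratum_row(counts)})
        for label, counts in sorted(self.by_taxon.items()):
            rows.append({"stratum": f"taxon:{label}", **_stratum_row(counts)})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _stratum_row(counts: StratumCounts) -> dict[str, object]:
    return {
        "n_anchor_pos": counts.n_anchor_pos,
        "n_partner_pos": counts.n_partner_pos,
        "n_both": counts.n_both,
        "pct_partner_given_anchor": _round1(counts.pct_partner_given_anchor),
        "pct_anchor_given_partner": _round1(counts.pct_anchor_given_partner),
    }


def _counts(x: np.ndarray, y: np.ndarray) -> StratumCounts:
    return StratumCounts(
        n_anchor_pos=int(x.sum()),
        n_partner_pos=int(y.sum()),
        n_both=int(np.sum((x == 1) & (y == 1))),
    )


def cooccurrence_summary(
    matrix: PresenceAbsenceMatrix,
    anchor: str,
    partner: str,
    taxon_level: int | None = 0,
) -> CoOccurrenceSummary:
    """Conditional co-occurrence counts for an anchor/partner pair,
    globally and per stratum.

    Strata are the domain-of-life labels and, when ``taxon_level`` is given,
    the labels at that index of each genome's taxon path (0 = phylum).
    Stratum labels are taken from the metadata verbatim.
    """
    x = matrix.column(anchor)
    y = matrix.column(partner)
    domains = matrix.domain_labels()

    by_domain = {
        label: _counts(x[domains == label], y[domains == label])
        for label in np.unique(domains)
    }
    by_taxon: dict[str, StratumCounts] = {}
    if taxon_level is not None:
        taxa = np.array(
            [
                (matrix.metadata[g].taxon_path[taxon_level]
                 if g in matrix.metadata
                 and len(matrix.metadata[g].taxon_path) > taxon_level
                 else "unknown")
                for g in matrix.data.index
            ]
        )
        by_taxon = {
            label: _counts(x[taxa == label], y[taxa == label])
            for label in np.unique(taxa)
        }

    return CoOccurrenceSummary(
        anchor=normalize_family_id(anchor),
        partner=normalize_family_id(partner),
        overall=_counts(x, y),
        by_domain=by_domain,
        by_taxon=by_taxon,
    )
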