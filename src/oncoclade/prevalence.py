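"""Neoplasia prevalence with Clopper-Pearson exact confidence intervals.

Necropsy counts from multiple surveys are pooled by taxon or clade, and
point prevalence x/n is reported with the exact (Clopper-Pearson) binomial
interval from Beta quantiles:

    lower = BetaInv(alpha/2;     x,     n - x + 1)   (0 when x = 0)
    upper = BetaInv(1 - alpha/2; x + 1, n - x)       (1 when x = n)

For x = 0 the upper bound has the closed form 1 - (alpha/2)^(1/n). The
exact interval is conservative: its coverage is at least the nominal
level for every true prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

__all__ = [
    "NecropsyCount",
    "PrevalenceEstimate",
    "pool_counts",
    "clopper_pearson",
    "prevalence_table",
]


@dataclass
class NecropsyCount:
    """Necropsy/neoplasia counts for one taxon from one or more sources."""

    taxon: str
    n: int
    x: int
    level: str = "species"  # species | genus-pool | clade
    sources: tuple[str, ...] = ()

    def __post_init__(self):
        if self.n < 1:
            raise ValueError(f"{self.taxon}: need at least one necropsy")
        if not (0 <= self.x <= self.n):
            raise ValueError(f"{self.taxon}: need 0 <= x <= n, got x={self.x}, n={self.n}")


@dataclass
class PrevalenceEstimate:
    taxon: str
    n: int
    x: int
    p_hat: float
    ci_low: float
    ci_high: float
    conf: float = 0.95
    sources: tuple[str, ...] = ()


def pool_counts(
    records: list[NecropsyCount], grouping: dict[str, str] | None = None
) -> list[NecropsyCount]:
    """Sum x and n within groups; order-independent, provenance retained.

    ``grouping`` maps each record's taxon to a group label; with ``None``
    records are grouped by their own taxon. Records whose taxon has no
    group assignment are an error.
    """
    pooled: dict[str, dict] = {}
    for rec in records:
        if grouping is None:
            group = rec.taxon
        elif rec.taxon in grouping:
            group = grouping[rec.taxon]
        else:
            raise ValueError(f"record {rec.taxon!r} has no group assignment")
        slot = pooled.setdefault(group, {"n": 0, "x": 0, "sources": []})
        slot["n"] += rec.n
        slot["x"] += rec.x
        slot["sources"].extend(rec.sources or (rec.taxon,))
    return [
        NecropsyCount(
            taxon=group,
            n=v["n"],
            x=v["x"],
            level="species" if grouping is None else "pooled",
            sources=tuple(sorted(v["sources"])),
        )
        for group, v in sorted(pooled.items())
    ]


def clopper_pearson(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial CI for x successes in n trials."""
    if n < 1 or not (0 <= x <= n):
        raise ValueError(f"invalid counts x={x}, n={n}")
    alpha = 1.0 - conf
    lo = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lo, hi


def prevalence_table(
    records: list[NecropsyCount],
    grouping: dict[str, str] | None = None,
    conf: float = 0.95,
) -> pd.DataFrame:
    """One row per (pooled) group with exact CI; full precision retained.

    The ``display`` column mirrors the conventional 2-3 significant digit
    presentation; the numeric columns keep full precision.
    """
    pooled = pool_counts(records, grouping) if records else []
    rows = []
    for rec in pooled:
        lo, hi = clopper_pearson(rec.x, rec.n, conf)
        p_hat = rec.x / rec.n
        rows.append(
            (
                rec.taxon, rec.n, rec.x, p_hat, lo, hi, conf,
                f"{_sig3(p_hat)} ({_sig3(lo)}–{_sig3(hi)})",
            )
        )
    return pd.DataFrame(
        rows,
        columns=["taxon", "n", "x", "p_hat", "ci_low", "ci_high", "conf", "display"],
    )


def _sig3(v: float) -> str:
    if v == 0:
        return "0"
    return f"{v:.3g}"
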