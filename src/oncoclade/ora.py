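"""Hypergeometric over-representation analysis of gene lists.

Branch-specific duplicate gene lists (foreground) are tested against a
gene-set collection (GMT) within a background universe — by convention the
post-filter query gene set. Each set is intersected with the background
before testing; sets smaller than ``min_set_size`` after intersection are
dropped. P-values are upper-tail hypergeometric, corrected by
Benjamini-Hochberg, and flagged significant at q <= 0.25 by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "hypergeometric_upper_tail",
    "bh_fdr",
    "run_ora",
]


@dataclass
class GeneSetCollection:
    """GMT-style pathway collection: id -> (name, member genes)."""

    sets: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self):
        empty = [k for k, (_, members) in self.sets.items() if not members]
        if empty:
            raise ValueError(f"empty gene sets: {empty}")

    def __len__(self):
        return len(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Parse tab-delimited GMT (id, description, member genes...)."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line {i}: need id, description, >=1 gene")
            pid, desc, genes = parts[0], parts[1], parts[2:]
            if pid in sets:
                raise ValueError(f"GMT line {i}: duplicate pathway id {pid!r}")
            sets[pid] = (desc, frozenset(g for g in genes if g))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for pid, (desc, members) in collection.sets.items():
            fh.write("\t".join([pid, desc, *sorted(members)]) + "\n")


def hypergeometric_upper_tail(k: int, m: int, s: int, N: int) -> float:
    """P(X >= k) with X ~ Hypergeometric(N population, m marked, s drawn)."""
    if not (0 <= k <= min(m, s)) or m > N or s > N:
        raise ValueError(f"impossible counts k={k}, m={m}, s={s}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, m, s))


def bh_fdr(pvalues) -> list[float]:
    """Benjamini-Hochberg step-up adjusted values (capped at 1)."""
    p = list(pvalues)
    if any(v < 0 or v > 1 for v in p):
        raise ValueError("p-values must lie in [0, 1]")
    if not p:
        return []
    return list(multipletests(p, method="fdr_bh")[1])


def run_ora(
    foreground,
    background,
    collection: GeneSetCollection,
    q_max: float = 0.25,
    min_set_size: int = 5,
) -> pd.DataFrame:
    """One hypergeometric test per pathway; results sorted by p.

    ``foreground`` must be a subset of ``background``. Output columns:
    pathway, name, k (overlap), m (set size in background), s (foreground
    size), N (background size), enrichment_ratio = k / (s * m / N), p, q,
    significant (q <= q_max). Output is independent of input ordering.
    """
    fg = frozenset(foreground)
    bg = frozenset(background)
    offenders = sorted(fg - bg)
    if offenders:
        raise ValueError(f"foreground genes absent from background: {offenders}")
    N, s = len(bg), len(fg)

    rows = []
    for pid in sorted(collection.sets):
        name, members = collection.sets[pid]
        m_set = members & bg
        m = len(m_set)
        if m < min_set_size:
            continue
        k = len(m_set & fg)
        p = hypergeometric_upper_tail(k, m, s, N)
        ratio = k / (s * m / N) if s and m else float("nan")
        rows.append((pid, name, k, m, s, N, ratio, p))
    df = pd.DataFrame(
        rows,
        columns=["pathway", "name", "k", "m", "s", "N", "enrichment_ratio", "p"],
    )
    if len(df):
        df["q"] = bh_fdr(df["p"])
        df["significant"] = df["q"] <= q_max
        df = df.sort_values(["p", "pathway"], kind="mergesort").reset_index(drop=True)
    else:
        df["q"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df
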