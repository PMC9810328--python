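"""Intrinsic cancer-risk estimation along a phylogeny.

Lifespan is predicted from body mass by phylogenetic generalised least
squares (PGLS) under a Brownian error covariance:

    ln(lifespan) = b1 + b2 * ln(mass) + eps,  Cov(eps) ~ Brownian(tree)

Intrinsic cancer risk follows the simplified multistage model K = D * t^6
(D maximum body mass in grams, t maximum lifespan in years); only log
ratios of K between nodes are interpreted, so mass units cancel out of
every reported fold change. The per-branch fold change is
log2(K_ancestor / K_node) by default ("literal" convention: a decrease
toward the present is positive); the child/ancestor flip is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .phylo import TimeTree
from .trait_asr import AncestralStates, brownian_structure

__all__ = [
    "PglsFit",
    "pgls_fit",
    "predict_ancestral_lifespans",
    "intrinsic_risk",
    "log2_intrinsic_risk",
    "fold_change_along_tree",
    "risk_table",
]


@dataclass
class PglsFit:
    """GLS coefficients for ln(lifespan) ~ ln(mass) with Brownian errors."""

    intercept: float
    slope: float
    residual_variance: float
    n: int

    def predict_ln_lifespan(self, ln_mass):
        return self.intercept + self.slope * np.asarray(ln_mass, dtype=float)


def pgls_fit(
    tree: TimeTree,
    lifespans: dict[str, float],
    masses: dict[str, float],
) -> PglsFit:
    """Fit ln(lifespan) ~ ln(mass) by GLS under the tree's Brownian covariance.

    ``lifespans`` in years and ``masses`` in grams, both keyed by tip label
    and strictly positive.
    """
    tips = tree.tip_labels()
    for name, table in (("lifespan", lifespans), ("mass", masses)):
        missing = [t for t in tips if t not in table]
        if missing:
            raise ValueError(f"missing {name} for species: {missing}")
        bad = [t for t in tips if table[t] <= 0]
        if bad:
            raise ValueError(f"non-positive {name} for species: {bad}")

    labels, C, _, _ = brownian_structure(tree)
    y = np.log([lifespans[t] for t in labels])
    X = np.column_stack([np.ones(len(labels)), np.log([masses[t] for t in labels])])
    try:
        cho = linalg.cho_factor(C)
    except linalg.LinAlgError as exc:
        raise ValueError(
            "singular Brownian covariance (duplicate zero-distance tips?); "
            "consider an epsilon branch-length fix"
        ) from exc
    CiX = linalg.cho_solve(cho, X)
    Ciy = linalg.cho_solve(cho, y)
    beta = np.linalg.solve(X.T @ CiX, X.T @ Ciy)
    resid = y - X @ beta
    dof = max(len(labels) - 2, 1)
    rv = float(resid @ linalg.cho_solve(cho, resid)) / dof
    return PglsFit(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        residual_variance=max(rv, 0.0),
        n=len(labels),
    )


def predict_ancestral_lifespans(
    fit: PglsFit, ancestral_ln_mass: AncestralStates
) -> dict[str, float]:
    """Per-node lifespan (years): t = exp(b1 + b2 * ln D)."""
    return {
        node: float(np.exp(fit.predict_ln_lifespan(v)))
        for node, v in ancestral_ln_mass.estimate.items()
    }


def intrinsic_risk(D: float, t: float) -> float:
    """Intrinsic cancer risk K = D * t^6 (D grams, t years)."""
    if D <= 0 or t <= 0:
        raise ValueError("body mass and lifespan must be positive")
    return D * t**6


def log2_intrinsic_risk(D: float, t: float) -> float:
    """log2 of K = D * t^6, computed in log space (overflow-safe)."""
    if D <= 0 or t <= 0:
        raise ValueError("body mass and lifespan must be positive")
    return math.log2(D) + 6 * math.log2(t)


def fold_change_along_tree(
    risks: dict[str, float], tree: TimeTree, convention: str = "literal"
) -> pd.DataFrame:
    """Per-branch log2 fold change in intrinsic risk.

    ``convention="literal"`` reports log2(K_ancestor / K_node), so risk
    decreases toward the present are positive; ``"child_over_ancestor"``
    flips the sign. The root has no fold change and is omitted.
    """
    if convention not in ("literal", "child_over_ancestor"):
        raise ValueError(f"unknown sign convention {convention!r}")
    sign = 1.0 if convention == "literal" else -1.0
    rows = []
    for node in tree.preorder():
        if node is tree.root:
            continue
        fc = sign * (math.log2(risks[node.parent.label]) - math.log2(risks[node.label]))
        rows.append((node.parent.label, node.label, fc))
    df = pd.DataFrame(rows, columns=["parent", "child", "log2_fold_change"])
    df.attrs["sign_convention"] = convention
    return df


def risk_table(
    tree: TimeTree,
    masses: dict[str, float],
    lifespans: dict[str, float],
    convention: str = "literal",
) -> pd.DataFrame:
    """Per-node table (node, D, t, K, log2K, fold_change) for a full tree.

    ``masses``/``lifespans`` must cover every node label (tips and
    ancestors, the latter typically from ASR + PGLS prediction).
    """
    risks = {n: intrinsic_risk(masses[n], lifespans[n]) for n in masses}
    fc = fold_change_along_tree(risks, tree, convention=convention)
    fc_map = dict(zip(fc["child"], fc["log2_fold_change"]))
    rows = []
    for node in tree.preorder():
        lab = node.label
        rows.append(
            (
                lab,
                masses[lab],
                lifespans[lab],
                risks[lab],
                log2_intrinsic_risk(masses[lab], lifespans[lab]),
                fc_map.get(lab, float("nan")),
            )
        )
    return pd.DataFrame(rows, columns=["node", "D", "t", "K", "log2K", "fold_change"])
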