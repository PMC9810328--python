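"""Ancestral reconstruction of binary gene copy-number states.

Gene copy number is coded 0 (single copy) / 1 (duplicated) per species and
modelled on the species tree with a two-state reversible Markov chain
(rates q01, q10; for two states any rate pair satisfies detailed balance
against its stationary frequencies). Likelihoods use Felsenstein pruning,
vectorised across genes; ancestral states are empirical-Bayes marginal
posteriors from the standard up-down pass with the stationary frequencies
as root prior. A duplication event is placed on a branch when the parent
is confidently single-copy and the child confidently duplicated, both at
Bayesian posterior probability (BPP) >= 0.80 by default; at most one event
is called per gene per root-to-tip path.

Missing genotypes (species without a scored genome for a gene) are
integrated over both states, not treated as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .phylo import TimeTree

__all__ = [
    "TwoStateModel",
    "matrix_from_long",
    "log_likelihood",
    "likelihood",
    "fit_two_state_model",
    "MarginalReconstruction",
    "marginal_asr",
    "DuplicationEventSet",
    "call_duplications",
    "lineage_duplication_summary",
]

RATE_FLOOR = 1e-8


@dataclass
class TwoStateModel:
    """Reversible two-state model with gain rate q01 and loss rate q10."""

    q01: float
    q10: float
    frequency_mode: str = "optimized"  # or "empirical"

    def __post_init__(self):
        if self.q01 <= 0 or self.q10 <= 0:
            raise ValueError("rates must be positive")

    @property
    def pi(self) -> np.ndarray:
        tot = self.q01 + self.q10
        return np.array([self.q10 / tot, self.q01 / tot])

    def transition_matrix(self, t: float) -> np.ndarray:
        return _pmat(self.q01, self.q10, t)


def _pmat(q01: float, q10: float, t: float) -> np.ndarray:
    tot = q01 + q10
    pi0, pi1 = q10 / tot, q01 / tot
    e = np.exp(-tot * t)
    return np.array([[pi0 + pi1 * e, pi1 * (1 - e)], [pi0 * (1 - e), pi1 + pi0 * e]])


def matrix_from_long(df: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long (gene, species, state) table to genes x species.

    Absent combinations become missing data.
    """
    return df.pivot_table(index="gene", columns="species", values="state",
                          aggfunc="first")


def _states_array(matrix: pd.DataFrame, tree: TimeTree) -> tuple[np.ndarray, list[str]]:
    tips = tree.tip_labels()
    unknown = set(matrix.columns) - set(tips)
    if unknown:
        raise ValueError(f"species not in tree: {sorted(unknown)}")
    arr = np.full((len(matrix), len(tips)), -1, dtype=np.int8)
    for j, tip in enumerate(tips):
        if tip in matrix.columns:
            col = matrix[tip].to_numpy(dtype=float)
            ok = ~np.isnan(col)
            arr[ok, j] = col[ok].astype(np.int8)
    return arr, list(matrix.index)


def _pruning_partials(
    states: np.ndarray, tree: TimeTree, q01: float, q10: float
):
    """Postorder partial likelihoods per node, with per-gene log scaling.

    Returns (partials: dict id(node)->(G,2), logscale: (G,), tip order used).
    """
    tips = tree.tips()
    tip_index = {t.label: j for j, t in enumerate(tips)}
    G = states.shape[0]
    partials: dict[int, np.ndarray] = {}
    logscale = np.zeros(G)
    for node in tree.postorder():
        if node.is_tip:
            s = states[:, tip_index[node.label]]
            F = np.ones((G, 2))
            F[s == 0] = [1.0, 0.0]
            F[s == 1] = [0.0, 1.0]
            partials[id(node)] = F
        else:
            F = np.ones((G, 2))
            for child in node.children:
                P = _pmat(q01, q10, child.branch_length)
                F *= partials[id(child)] @ P.T
            mx = F.max(axis=1)
            mx[mx == 0] = 1.0
            logscale += np.log(mx)
            partials[id(node)] = F / mx[:, None]
    return partials, logscale


def log_likelihood(
    matrix: pd.DataFrame, tree: TimeTree, model: TwoStateModel
) -> np.ndarray:
    """Per-gene pruning log-likelihood; root prior = stationary frequencies."""
    states, _ = _states_array(matrix, tree)
    partials, logscale = _pruning_partials(states, tree, model.q01, model.q10)
    rootF = partials[id(tree.root)]
    return np.log(rootF @ model.pi) + logscale


def likelihood(character: dict[str, int], tree: TimeTree, model: TwoStateModel) -> float:
    """Log-likelihood of a single binary character (dict species -> 0/1)."""
    row = {t: character.get(t, np.nan) for t in tree.tip_labels()}
    matrix = pd.DataFrame([row], index=["g"])
    matrix.columns.name = "species"
    return float(log_likelihood(matrix, tree, model)[0])


def fit_two_state_model(
    matrix: pd.DataFrame,
    tree: TimeTree,
    frequency_mode: str = "empirical",
    per_gene: bool = False,
):
    """Maximise the summed pruning log-likelihood over the rates.

    ``frequency_mode="empirical"`` pins the stationary frequencies at the
    observed state proportions and optimises a single overall rate;
    ``"optimized"`` optimises q01 and q10 freely (bounded below at 1e-8).
    With ``per_gene=True`` a model is fitted independently per gene and a
    dict gene -> model returned.
    """
    if frequency_mode not in ("empirical", "optimized"):
        raise ValueError(f"unknown frequency mode {frequency_mode!r}")
    if per_gene:
        return {
            gene: fit_two_state_model(matrix.loc[[gene]], tree, frequency_mode)
            for gene in matrix.index
        }

    states, _ = _states_array(matrix, tree)

    def total_ll(q01: float, q10: float) -> float:
        partials, logscale = _pruning_partials(states, tree, q01, q10)
        rootF = partials[id(tree.root)]
        tot = q01 + q10
        pi = np.array([q10 / tot, q01 / tot])
        return float(np.sum(np.log(rootF @ pi) + logscale))

    if frequency_mode == "empirical":
        obs = states[states >= 0]
        p1 = float(obs.mean()) if obs.size else 0.5
        p1 = min(max(p1, 1e-6), 1 - 1e-6)

        res = optimize.minimize_scalar(
            lambda logmu: -total_ll(np.exp(logmu) * p1, np.exp(logmu) * (1 - p1)),
            bounds=(np.log(RATE_FLOOR), np.log(1e3)),
            method="bounded",
        )
        mu = float(np.exp(res.x))
        return TwoStateModel(max(mu * p1, RATE_FLOOR), max(mu * (1 - p1), RATE_FLOOR),
                             frequency_mode="empirical")

    res = optimize.minimize(
        lambda v: -total_ll(np.exp(v[0]), np.exp(v[1])),
        x0=np.log([0.1, 0.1]),
        method="L-BFGS-B",
        bounds=[(np.log(RATE_FLOOR), np.log(1e3))] * 2,
    )
    q01, q10 = np.exp(res.x)
    return TwoStateModel(float(q01), float(q10), frequency_mode="optimized")


# ------------------------------------------------------------------ marginals
@dataclass
class MarginalReconstruction:
    """Marginal posterior P(state = 1) per gene per node.

    ``post1`` has shape (n_genes, n_nodes); the BPP of a node's favoured
    state is ``max(p, 1 - p)``.
    """

    genes: list[str]
    node_labels: list[str]
    post1: np.ndarray
    model: TwoStateModel

    def posterior(self, gene: str, node: str) -> float:
        return float(
            self.post1[self.genes.index(gene), self.node_labels.index(node)]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.post1, index=pd.Index(self.genes, name="gene"),
                            columns=self.node_labels)


def marginal_asr(
    matrix: pd.DataFrame, tree: TimeTree, model: TwoStateModel
) -> MarginalReconstruction:
    """Empirical-Bayes marginal ancestral states via the up-down algorithm."""
    states, genes = _states_array(matrix, tree)
    G = states.shape[0]
    partials, _ = _pruning_partials(states, tree, model.q01, model.q10)

    down: dict[int, np.ndarray] = {id(tree.root): np.tile(model.pi, (G, 1))}
    for node in tree.preorder():
        if node.is_tip:
            continue
        child_up = {
            id(c): partials[id(c)] @ _pmat(model.q01, model.q10, c.branch_length).T
            for c in node.children
        }
        for child in node.children:
            M = down[id(node)].copy()
            for sib in node.children:
                if sib is not child:
                    M *= child_up[id(sib)]
            D = M @ _pmat(model.q01, model.q10, child.branch_length)
            norm = D.sum(axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            down[id(child)] = D / norm

    nodes = list(tree.preorder())
    post1 = np.empty((G, len(nodes)))
    for k, node in enumerate(nodes):
        joint = down[id(node)] * partials[id(node)]
        tot = joint.sum(axis=1)
        tot[tot == 0] = 1.0
        post1[:, k] = joint[:, 1] / tot
    return MarginalReconstruction(
        genes=list(genes),
        node_labels=[n.label for n in nodes],
        post1=post1,
        model=model,
    )


# -------------------------------------------------------------- event calling
@dataclass
class DuplicationEventSet:
    """Called duplication branches (child node label) per gene."""

    events: dict[str, list[str]]
    n_genes: int
    bpp_min: float
    diagnostics: dict = field(default_factory=dict)

    @property
    def per_branch_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for branches in self.events.values():
            for b in branches:
                counts[b] = counts.get(b, 0) + 1
        return counts


def call_duplications(
    recon: MarginalReconstruction, tree: TimeTree, bpp_min: float = 0.80
) -> DuplicationEventSet:
    """Place events on branches with a confident 0 -> 1 transition.

    A branch (parent -> child) carries an event for a gene iff the parent
    favours state 0 and the child state 1, both with BPP >= ``bpp_min``.
    Only the rootmost qualifying branch per root-to-tip path is kept, so a
    gene contributes at most one event per lineage. Branches where the
    child is confidently duplicated but the parent is uncertain are tallied
    as unreliable in the diagnostics, not called.
    """
    node_ix = {lab: k for k, lab in enumerate(recon.node_labels)}
    events: dict[str, list[str]] = {}
    unreliable = 0
    nodes = list(tree.preorder())
    for g, gene in enumerate(recon.genes):
        p1 = recon.post1[g]
        called: set[str] = set()
        blocked: set[str] = set()  # node labels below an already-called event
        for node in nodes:
            if node is tree.root:
                continue
            if node.parent.label in blocked or node.parent.label in called:
                blocked.add(node.label)
                continue
            child_p1 = p1[node_ix[node.label]]
            parent_p1 = p1[node_ix[node.parent.label]]
            if child_p1 >= bpp_min:
                if 1 - parent_p1 >= bpp_min:
                    called.add(node.label)
                elif parent_p1 < 0.5:
                    unreliable += 1
        if called:
            events[gene] = sorted(called)
    return DuplicationEventSet(
        events=events,
        n_genes=len(recon.genes),
        bpp_min=bpp_min,
        diagnostics={"unreliable_transitions": unreliable},
    )


def lineage_duplication_summary(
    events: DuplicationEventSet, n_genes: int | None = None
) -> pd.DataFrame:
    """Per-branch event counts, per-gene rates, and gene lists."""
    n = n_genes if n_genes is not None else events.n_genes
    per_branch: dict[str, list[str]] = {}
    for gene, branches in events.events.items():
        for b in branches:
            per_branch.setdefault(b, []).append(gene)
    rows = [
        (branch, len(genes), len(genes) / n, sorted(genes))
        for branch, genes in sorted(per_branch.items())
    ]
    return pd.DataFrame(rows, columns=["branch", "count", "rate", "genes"])
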