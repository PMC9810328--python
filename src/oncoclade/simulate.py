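"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its parameter block and a seed, and
returns the observable data together with the ground truth used to plant
it, so every pipeline stage is testable without external downloads:

* birth-death time trees retaining a fraction of extinct lineages as
  fossil tips;
* log-body-mass evolution as Brownian motion plus compound-Poisson jumps
  (a tractable stand-in for heavy-tailed increment models: exact
  ground-truth ancestral values exist), and lifespans from a log-log
  allometry with phylogenetic noise;
* binary duplication characters evolved under a two-state chain with
  burst branches of elevated gain rate;
* forward/reciprocal PSL hit tables with planted copy numbers and
  scaffold fragmentation;
* GMT gene-set collections with a planted enriched set;
* binomial necropsy counts and clade-shifted lognormal doubling times.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import phylo
from .phylo import Node, TimeTree
from .prevalence import NecropsyCount
from .rbhb import PslAlignment

logger = logging.getLogger(__name__)

__all__ = [
    "TreeParams",
    "TraitParams",
    "DuplicationParams",
    "PslParams",
    "EnrichmentParams",
    "PrevalenceParams",
    "PhenotypeParams",
    "SimulationConfig",
    "simulate_tree",
    "simulate_traits",
    "simulate_duplications",
    "simulate_psl",
    "simulate_gene_sets",
    "simulate_prevalence",
    "simulate_phenotypes",
]


# ---------------------------------------------------------------- parameters
@dataclass
class TreeParams:
    n_tips: int = 50              # extant tips
    birth: float = 0.15           # lineages / My
    death: float = 0.05
    extinct_tip_fraction: float = 0.25  # extinct lineages kept as fossil tips
    max_retries: int = 100


@dataclass
class TraitParams:
    # ln body mass (grams); root near 1 kg, mammal-like BM rate
    root_ln_mass: float = math.log(1000.0)
    sigma2: float = 0.02          # ln-mass variance / My
    jump_rate: float = 0.01       # jumps / My (compound Poisson)
    jump_sd: float = 1.5          # ln-mass units per jump
    # max-lifespan allometry t ~ 4.9 * D^0.15 (years, grams)
    beta1: float = 1.59
    beta2: float = 0.15
    lifespan_noise_sigma2: float = 0.002  # phylogenetic noise on ln lifespan


@dataclass
class DuplicationParams:
    n_genes: int = 2000
    base_gain: float = 0.0003     # events / My on background branches
    burst_gain: float = 0.02      # events / My on burst branches
    loss: float = 0.0001
    n_burst_branches: int = 2
    burst_branches: list[str] | None = None  # default via default_burst_branches
    missing_prob: float = 0.0
    # "zero": genes start single-copy at the root (the duplication-burst
    # scenario); "stationary": root states drawn from the chain's
    # equilibrium (matched conditions for rate-recovery checks)
    root_state: str = "zero"


@dataclass
class PslParams:
    n_genes: int = 60
    min_query_length: int = 100
    max_query_length: int = 900
    copy_number_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.7, 2: 0.2, 3: 0.1}
    )
    fragmentation_prob: float = 0.15
    mismatch_rate: float = 0.02
    reciprocal_error_prob: float = 0.0  # best reciprocal hit points elsewhere


@dataclass
class EnrichmentParams:
    n_pathways: int = 100
    min_set_size: int = 10
    max_set_size: int = 80
    planted_fold: float = 10.0
    foreground_size: int = 150


@dataclass
class PrevalenceParams:
    # (taxon, true prevalence, necropsies) — small-survey structure
    taxa: list[tuple[str, float, int]] = field(
        default_factory=lambda: [
            ("taxon_A", 0.007, 275),
            ("taxon_B", 0.03, 140),
            ("taxon_C", 0.02, 60),
            ("taxon_D", 0.0, 48),
            ("taxon_E", 0.05, 25),
        ]
    )


@dataclass
class PhenotypeParams:
    # clade -> (median doubling time hr, sigma of ln, n cell lines)
    clades: dict[str, tuple[float, float, int]] = field(
        default_factory=lambda: {
            "mammals": (32.0, 0.45, 68),
            "armadillos": (30.0, 0.3, 3),
            "anteaters": (40.0, 0.3, 3),
            "sloths": (100.0, 0.15, 2),
        }
    )


@dataclass
class SimulationConfig:
    seed: int = 0
    tree: TreeParams = field(default_factory=TreeParams)
    traits: TraitParams = field(default_factory=TraitParams)
    duplications: DuplicationParams = field(default_factory=DuplicationParams)
    psl: PslParams = field(default_factory=PslParams)
    enrichment: EnrichmentParams = field(default_factory=EnrichmentParams)
    prevalence: PrevalenceParams = field(default_factory=PrevalenceParams)
    phenotypes: PhenotypeParams = field(default_factory=PhenotypeParams)


# --------------------------------------------------------------------- trees
def simulate_tree(params: TreeParams, seed: int) -> TimeTree:
    """Birth-death time tree; a fraction of extinct lineages become fossil tips."""
    from dendropy.simulate import treesim

    retries = 0
    for attempt in range(params.max_retries):
        rng = random.Random(seed + 7919 * attempt)
        try:
            dtree = treesim.birth_death_tree(
                params.birth,
                params.death,
                num_extant_tips=params.n_tips,
                is_retain_extinct_tips=params.death > 0,
                rng=rng,
            )
            break
        except Exception:  # total extinction; resample
            retries += 1
    else:
        raise RuntimeError(
            f"birth-death simulation failed after {params.max_retries} attempts"
        )
    if retries:
        logger.info("simulate_tree: %d resampling retries after total extinction",
                    retries)

    def convert(dnode) -> Node:
        node = Node(branch_length=dnode.edge.length)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    root.branch_length = None
    for n in phylo._preorder(root):
        if n is not root and (n.branch_length is None or n.branch_length <= 0):
            n.branch_length = phylo.EPSILON_BRANCH
    tree = TimeTree(root)

    # relabel tips: extant E###, fossil (extinct) F###
    ages = tree.node_ages()
    extant, extinct = [], []
    # extancy tolerance must sit above the epsilon used for zero branches
    extancy_tol = 10 * phylo.EPSILON_BRANCH
    for t in tree.tips():
        (extant if ages[t.label] <= extancy_tol else extinct).append(t)
    for i, t in enumerate(extant):
        t.label = f"E{i:03d}"
    for i, t in enumerate(extinct):
        t.label = f"F{i:03d}"

    keep = [t.label for t in extant]
    if extinct:
        k = int(round(params.extinct_tip_fraction * len(extinct)))
        rng2 = random.Random(seed ^ 0x5F5F)
        keep += [t.label for t in rng2.sample(extinct, k)] if k else []
    tree = phylo.prune_to_taxa(tree, keep)
    tree.validate()
    return tree


# -------------------------------------------------------------------- traits
def simulate_traits(
    tree: TimeTree, params: TraitParams, seed: int
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Recursive root-to-tip trait simulation.

    Returns a life-history table (species, mass_g, lifespan_yr) for the
    tips and the ground-truth ln-mass at every node (the jump-inclusive
    path values, so ancestral truth is exact).
    """
    rng = np.random.default_rng(seed)
    truth: dict[str, float] = {tree.root.label: params.root_ln_mass}
    for node in tree.preorder():
        if node is tree.root:
            continue
        t = node.branch_length
        inc = rng.normal(0.0, math.sqrt(params.sigma2 * t)) if params.sigma2 > 0 else 0.0
        n_jumps = rng.poisson(params.jump_rate * t)
        if n_jumps:
            inc += rng.normal(0.0, params.jump_sd, size=n_jumps).sum()
        truth[node.label] = truth[node.parent.label] + inc

    noise: dict[str, float] = {tree.root.label: 0.0}
    for node in tree.preorder():
        if node is tree.root:
            continue
        s2 = params.lifespan_noise_sigma2
        step = rng.normal(0.0, math.sqrt(s2 * node.branch_length)) if s2 > 0 else 0.0
        noise[node.label] = noise[node.parent.label] + step

    rows = []
    for tip in tree.tips():
        ln_mass = truth[tip.label]
        ln_life = params.beta1 + params.beta2 * ln_mass + noise[tip.label]
        rows.append((tip.label, math.exp(ln_mass), math.exp(ln_life)))
    table = pd.DataFrame(rows, columns=["species", "mass_g", "lifespan_yr"])
    return table, truth


# -------------------------------------------------------------- duplications
def default_burst_branches(tree: TimeTree, n: int = 2) -> list[str]:
    """Long-stemmed internal branches subtending mid-sized clades.

    Events on a branch are only placeable when tips exist on both sides of
    it, so clades covering (nearly) all tips are excluded; among branches
    whose clade holds 3 tips to half the tree, the ``n`` longest stems are
    chosen (burst signal scales with stem duration).
    """
    n_tips = len(tree.tips())
    depths = tree.depths()
    candidates = []
    for node in tree.preorder():
        if node is tree.root or node.is_tip:
            continue
        if node.parent is tree.root:
            # a root-child stem has no anchored parent state: a single loss
            # on the sister side can explain the data as well as a gain here
            continue
        if not (3 <= len(tree.clade_tips(node)) <= max(n_tips // 2, 3)):
            continue
        # placement of a gain is sharp when the stem dominates its own
        # root-ward path: score by stem fraction, weighted by stem length
        stem_fraction = node.branch_length / depths[node]
        candidates.append((stem_fraction * node.branch_length, node.label))
    candidates.sort(key=lambda kv: (-kv[0], kv[1]))
    if len(candidates) < n:
        raise ValueError("tree has too few internal branches for burst planting")
    return [label for _, label in candidates[:n]]


def simulate_duplications(
    tree: TimeTree, params: DuplicationParams, seed: int
) -> tuple[pd.DataFrame, dict[str, str | None], list[str]]:
    """Two-state (0 -> 1 gain, 1 -> 0 loss) simulation along branches.

    Burst branches carry the elevated gain rate. Returns the gene x species
    0/1 matrix (NaN where a genotype is masked as missing), the gain
    branches per gene (child node labels in root-to-tip order; a gene may
    gain independently in disjoint clades), and the burst branch list.
    The expected duplicated fraction gained on a burst branch of length T
    is 1 - exp(-gain * T).
    """
    rng = np.random.default_rng(seed)
    bursts = params.burst_branches or default_burst_branches(
        tree, params.n_burst_branches
    )
    unknown = set(bursts) - {n.label for n in tree.preorder()}
    if unknown:
        raise ValueError(f"burst branches not in tree: {sorted(unknown)}")

    tips = tree.tip_labels()
    genes = [f"G{i:04d}" for i in range(params.n_genes)]
    states = np.zeros((params.n_genes, len(tips)), dtype=float)
    gains: dict[str, list[str]] = {g: [] for g in genes}

    if params.root_state == "stationary":
        tot = params.base_gain + params.loss
        pi1 = params.base_gain / tot if tot > 0 else 0.0
        root_states = (rng.uniform(size=params.n_genes) < pi1).astype(np.int8)
    elif params.root_state == "zero":
        root_states = np.zeros(params.n_genes, dtype=np.int8)
    else:
        raise ValueError(f"unknown root_state {params.root_state!r}")
    node_state = {tree.root.label: root_states}
    tip_ix = {t: j for j, t in enumerate(tips)}
    for node in tree.preorder():
        if node is tree.root:
            continue
        gain = params.burst_gain if node.label in bursts else params.base_gain
        t = node.branch_length
        parent = node_state[node.parent.label]
        p01 = _gain_prob(gain, params.loss, t)
        p11 = 1.0 - _loss_prob(gain, params.loss, t)
        u = rng.uniform(size=params.n_genes)
        child = np.where(parent == 0, (u < p01).astype(np.int8),
                         (u < p11).astype(np.int8))
        gained = (parent == 0) & (child == 1)
        for g in np.nonzero(gained)[0]:
            gains[genes[g]].append(node.label)
        node_state[node.label] = child
        if node.is_tip:
            states[:, tip_ix[node.label]] = child

    if params.missing_prob > 0:
        mask = rng.uniform(size=states.shape) < params.missing_prob
        states[mask] = np.nan

    matrix = pd.DataFrame(states, index=pd.Index(genes, name="gene"), columns=tips)
    return matrix, gains, list(bursts)


def _gain_prob(q01: float, q10: float, t: float) -> float:
    tot = q01 + q10
    if tot == 0:
        return 0.0
    return q01 / tot * (1 - math.exp(-tot * t))


def _loss_prob(q01: float, q10: float, t: float) -> float:
    tot = q01 + q10
    if tot == 0:
        return 0.0
    return q10 / tot * (1 - math.exp(-tot * t))


# ----------------------------------------------------------------------- PSL
def simulate_psl(
    params: PslParams,
    seed: int,
    copy_counts: dict[str, int] | None = None,
) -> dict:
    """Forward + reciprocal PSL tables with planted copy numbers.

    One locus is emitted per true gene copy; with ``fragmentation_prob`` a
    locus is split into two partial-coverage hits on distinct scaffolds.
    Reciprocal records map loci back to their source isoform; with
    ``reciprocal_error_prob`` the best reciprocal hit is redirected to a
    different gene (breaking the reciprocal-best criterion for that locus).

    Returns a dict with forward/reciprocal record lists, the isoform->gene
    map, per-isoform query lengths, and the planted truth per gene
    (copy_count, fragmented, duplicated).
    """
    rng = np.random.default_rng(seed)
    if copy_counts is None:
        genes = [f"G{i:04d}" for i in range(params.n_genes)]
        ks = list(params.copy_number_probs)
        ps = np.array([params.copy_number_probs[k] for k in ks], dtype=float)
        ps /= ps.sum()
        counts = rng.choice(ks, size=len(genes), p=ps)
        copy_counts = dict(zip(genes, (int(c) for c in counts)))
    genes = sorted(copy_counts)

    forward: list[PslAlignment] = []
    reciprocal: list[PslAlignment] = []
    isoform_to_gene: dict[str, str] = {}
    query_sizes: dict[str, int] = {}
    truth: dict[str, dict] = {}

    for gene in genes:
        iso = f"{gene}.1"
        isoform_to_gene[iso] = gene
        L = int(rng.integers(params.min_query_length, params.max_query_length + 1))
        query_sizes[iso] = L
        n_copies = copy_counts[gene]
        fragmented = False
        for c in range(n_copies):
            frag = rng.uniform() < params.fragmentation_prob
            fragmented = fragmented or frag
            if frag:
                split = int(L * rng.uniform(0.35, 0.65))
                pieces = [(0, split), (split, L)]
            else:
                pieces = [(0, L)]
            for pi, (qs, qe) in enumerate(pieces):
                scaffold = f"scaf_{gene}_{c}_{pi}"
                span = (qe - qs) * 3 + 2000
                t_start = 500
                fwd = _alignment(
                    rng, iso, L, qs, qe, scaffold, span + 1000, t_start,
                    params.mismatch_rate,
                )
                forward.append(fwd)
                locus_id = f"{scaffold}:{fwd.tStart}-{fwd.tEnd}"
                if rng.uniform() < params.reciprocal_error_prob and len(genes) > 1:
                    other = genes[(genes.index(gene) + 1) % len(genes)]
                    back_target = f"{other}.1"
                else:
                    back_target = iso
                reciprocal.append(
                    _reciprocal_alignment(rng, locus_id, fwd, back_target,
                                          query_sizes.get(back_target, L))
                )
        truth[gene] = {
            "copy_count": n_copies,
            "fragmented": bool(fragmented),
            "duplicated": n_copies >= 2,
        }
    return {
        "forward": forward,
        "reciprocal": reciprocal,
        "isoform_to_gene": isoform_to_gene,
        "query_sizes": query_sizes,
        "truth": truth,
    }


def _alignment(rng, qname, qsize, qstart, qend, tname, tsize, tstart, mismatch_rate):
    size = qend - qstart
    mism = int(rng.binomial(size, mismatch_rate))
    return PslAlignment(
        matches=size - mism, misMatches=mism, repMatches=0, nCount=0,
        qNumInsert=0, qBaseInsert=0, tNumInsert=0, tBaseInsert=0,
        strand="+", qName=qname, qSize=qsize, qStart=qstart, qEnd=qend,
        tName=tname, tSize=tsize, tStart=tstart, tEnd=tstart + size,
        blockCount=1, blockSizes=(size,), qStarts=(qstart,), tStarts=(tstart,),
    )


def _reciprocal_alignment(rng, locus_id, fwd, target_isoform, target_size):
    size = min(fwd.tEnd - fwd.tStart, target_size)
    mism = int(rng.binomial(size, 0.01))
    return PslAlignment(
        matches=size - mism, misMatches=mism, repMatches=0, nCount=0,
        qNumInsert=0, qBaseInsert=0, tNumInsert=0, tBaseInsert=0,
        strand="+", qName=locus_id, qSize=fwd.tEnd - fwd.tStart,
        qStart=0, qEnd=size, tName=target_isoform, tSize=target_size,
        tStart=0, tEnd=size, blockCount=1, blockSizes=(size,),
        qStarts=(0,), tStarts=(0,),
    )


# ------------------------------------------------------------------ gene sets
def simulate_gene_sets(
    background: list[str],
    params: EnrichmentParams,
    seed: int,
    planted_from: list[str] | None = None,
) -> dict:
    """GMT collection with one planted overrepresented set.

    The foreground is drawn so the planted set's overlap is
    ``planted_fold`` times its null expectation (capped by the set size);
    with ``planted_from`` the planted set is built around those genes
    (e.g. genes truly duplicated on a burst branch).
    """
    rng = np.random.default_rng(seed)
    bg = sorted(set(background))
    N = len(bg)
    s = min(params.foreground_size, N)

    sets: dict[str, tuple[str, frozenset[str]]] = {}
    planted_id = "PW0000"
    m = int(rng.integers(params.min_set_size, params.max_set_size + 1))
    if planted_from:
        core = [g for g in planted_from if g in set(bg)][:m]
        extra = rng.choice([g for g in bg if g not in set(core)],
                           size=max(m - len(core), 0), replace=False)
        planted = frozenset(list(core) + list(extra))
    else:
        planted = frozenset(rng.choice(bg, size=m, replace=False))
    sets[planted_id] = ("planted pathway", planted)
    for i in range(1, params.n_pathways):
        mi = int(rng.integers(params.min_set_size, params.max_set_size + 1))
        sets[f"PW{i:04d}"] = (
            f"random pathway {i}",
            frozenset(rng.choice(bg, size=mi, replace=False)),
        )

    k_target = min(len(planted), s, int(round(params.planted_fold * s * len(planted) / N)))
    fg = list(rng.choice(sorted(planted), size=k_target, replace=False))
    rest_pool = [g for g in bg if g not in set(fg)]
    fg += list(rng.choice(rest_pool, size=s - k_target, replace=False))

    from .ora import GeneSetCollection

    return {
        "collection": GeneSetCollection(sets),
        "background": bg,
        "foreground": sorted(fg),
        "planted_id": planted_id,
        "planted_overlap": k_target,
    }


# ----------------------------------------------------------------- prevalence
def simulate_prevalence(params: PrevalenceParams, seed: int) -> tuple[list[NecropsyCount], dict[str, float]]:
    """Binomial necropsy counts per taxon; truth = the true prevalences."""
    rng = np.random.default_rng(seed)
    records, truth = [], {}
    for taxon, p, n in params.taxa:
        x = int(rng.binomial(n, p))
        records.append(NecropsyCount(taxon=taxon, n=n, x=x, sources=("simulated",)))
        truth[taxon] = p
    return records, truth


# ----------------------------------------------------------------- phenotypes
def simulate_phenotypes(params: PhenotypeParams, seed: int) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    """Clade-shifted lognormal doubling-time samples (hours)."""
    rng = np.random.default_rng(seed)
    groups, truth = {}, {}
    for clade, (median, sdlog, n) in params.clades.items():
        groups[clade] = rng.lognormal(math.log(median), sdlog, size=n)
        truth[clade] = median
    return groups, truth
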