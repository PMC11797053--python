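"""Synthetic data with the generative structure the analysis assumes.

The generator mirrors the statistical model underlying the whole pipeline:
a pure-birth (Yule) phylogeny; trophic categories evolving as a
continuous-time Markov chain along the branches; per-family copy numbers
drawn from a Poisson log-normal model

    y_s ~ Poisson(exp(mu + beta * 1[state_s = focal] + u_s + e_s)),
    u ~ MVN(0, sigma2_phylo * C),   e_s ~ N(0, sigma2_resid) iid,

where C is the Brownian-motion covariance of the simulated tree. Because
the generator and the fitted GLMM share this model, parameter recovery is
a fair check of the inference code. Locus tables (for the 5-Mb tandem
rule) and diet compositions (for quantitative trophic levels) are also
emulated.

All generators are deterministic under (seed, parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .trees import PhyloCov, PhyloTree, read_newick, vcv_matrix

__all__ = [
    "CATEGORIES",
    "SimParams",
    "simulate_tree",
    "simulate_trophic_states",
    "simulate_copy_numbers",
    "simulate_locus_table",
    "simulate_diet_composition",
    "write_ortholog_groups",
    "default_rate_matrix",
]

CATEGORIES = ("herbivore", "carnivore", "omnivore")


def default_rate_matrix(rate: float = 0.3) -> np.ndarray:
    """Symmetric 3-state rate matrix with total leave-rate ``2 * rate``."""
    Q = np.full((3, 3), rate)
    np.fill_diagonal(Q, -2 * rate)
    return Q


@dataclass
class SimParams:
    """Study conditions for the synthetic dataset.

    Scalars for ``mu``/``beta``/``sigma2_phylo``/``sigma2_resid`` apply to
    every family; arrays of length ``n_families`` give per-family values.
    ``focal_category`` designates which trophic category carries the
    ``beta`` copy-number effect on the log scale.
    """

    n_species: int = 32
    birth_rate: float = 1.0
    Q: np.ndarray = field(default_factory=default_rate_matrix)
    root_state: str = "omnivore"
    n_families: int = 100
    mu: float | np.ndarray = float(np.log(1.2))
    beta: float | np.ndarray = 0.0
    sigma2_phylo: float | np.ndarray = 0.3
    sigma2_resid: float | np.ndarray = 0.2
    focal_category: str = "herbivore"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 4:
            raise ValueError("n_species must be >= 4")
        if self.birth_rate <= 0:
            raise ValueError("birth rate must be > 0")
        Q = np.asarray(self.Q, dtype=float)
        if Q.shape != (3, 3):
            raise ValueError("Q must be 3x3")
        if np.any(Q - np.diag(np.diag(Q)) < 0):
            raise ValueError("Q off-diagonals must be >= 0")
        if not np.allclose(Q.sum(axis=1), 0, atol=1e-10):
            raise ValueError("Q rows must sum to 0")
        self.Q = Q
        for name in ("sigma2_phylo", "sigma2_resid"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"{name} must be >= 0")
        if self.focal_category not in CATEGORIES:
            raise ValueError(f"unknown focal category {self.focal_category!r}")

    def _per_family(self, name: str) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(getattr(self, name), dtype=float), (self.n_families,)
        ).copy()

    def with_planted(self, n_planted: int, beta: float) -> "SimParams":
        """First ``n_planted`` families get log-effect ``beta``, rest 0."""
        b = np.zeros(self.n_families)
        b[:n_planted] = beta
        return replace(self, beta=b)


def simulate_tree(params: SimParams) -> PhyloTree:
    """Pure-birth (Yule) ultrametric tree with ``n_species`` tips.

    Lineages split at rate ``birth_rate`` each; with k extant lineages the
    waiting time to the next split is Exp(k * birth_rate). Extant branch
    lengths all end at the final simulation time, so the tree is
    ultrametric by construction.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_species
    rate = params.birth_rate
    # each active lineage: (newick subtree string builder via parent merge)
    # represent lineages as (id); record birth time of each lineage
    children: dict[int, tuple[int, int]] = {}
    birth: dict[int, float] = {0: 0.0}
    active = [0]
    next_id = 1
    t = 0.0
    while len(active) < n:
        k = len(active)
        t += rng.exponential(1.0 / (k * rate))
        which = rng.integers(k)
        parent = active[which]
        a, b = next_id, next_id + 1
        next_id += 2
        children[parent] = (a, b)
        birth[a] = birth[b] = t
        active[which] = a
        active.append(b)
    end = t + rng.exponential(1.0 / (n * rate))
    tips = {lin: f"sp{i + 1}" for i, lin in enumerate(sorted(active))}

    def build(node: int) -> str:
        if node in children:
            a, b = children[node]
            length = (birth[a] if a in birth else end) - birth[node]
            return f"({build(a)},{build(b)}):{birth[a] - birth[node]:.10g}"
        return f"{tips[node]}:{end - birth[node]:.10g}"

    if 0 in children:
        a, b = children[0]
        newick = f"({build(a)},{build(b)});"
    else:  # pragma: no cover - n >= 4 always splits
        newick = f"({tips[0]}:{end:.10g});"
    return read_newick(newick)


def simulate_trophic_states(
    tree: PhyloTree,
    Q: np.ndarray,
    root_state: str = "omnivore",
    seed: int = 0,
) -> pd.DataFrame:
    """Evolve trophic categories by a CTMC along the branches.

    Returns a DataFrame with columns ``species`` and ``category``.
    """
    Q = np.asarray(Q, dtype=float)
    if Q.shape != (3, 3) or not np.allclose(Q.sum(axis=1), 0, atol=1e-10) \
            or np.any(Q - np.diag(np.diag(Q)) < 0):
        raise ValueError("invalid rate matrix Q")
    if root_state not in CATEGORIES:
        raise ValueError(f"unknown root state {root_state!r}")
    rng = np.random.default_rng(seed)
    idx = {c: i for i, c in enumerate(CATEGORIES)}
    t = tree._tree
    states: dict[str, str] = {}
    for node in t.preorder_node_iter():
        if node.parent_node is None:
            node._state = idx[root_state]
        else:
            s = node.parent_node._state
            remaining = node.edge.length or 0.0
            while True:
                leave = -Q[s, s]
                if leave <= 0:
                    break
                wait = rng.exponential(1.0 / leave)
                if wait > remaining:
                    break
                remaining -= wait
                probs = Q[s].clip(min=0)
                probs[s] = 0.0
                s = int(rng.choice(3, p=probs / probs.sum()))
            node._state = s
        if node.is_leaf():
            states[node.taxon.label] = CATEGORIES[node._state]
    return pd.DataFrame(
        {"species": list(states), "category": list(states.values())}
    )


def simulate_copy_numbers(
    tree: PhyloTree, states: pd.DataFrame, params: SimParams
) -> pd.DataFrame:
    """Draw the copy-number matrix (species rows, family columns).

    Implements the Poisson log-normal model with a phylogenetically
    correlated random effect (covariance ``sigma2_phylo * C``) and an
    i.i.d. residual ``sigma2_resid`` on the log scale. C is scaled to
    unit root-to-tip depth, so ``sigma2_phylo`` is the marginal
    phylogenetic variance at the tips whatever the tree's time units.
    """
    cov = vcv_matrix(tree)
    cov = PhyloCov(cov.species, cov.C / np.max(np.diag(cov.C)))
    species = cov.species
    missing = set(species) - set(states["species"])
    if missing:
        raise ValueError(f"states missing species: {sorted(missing)}")
    cat = states.set_index("species")["category"].loc[species]
    focal = (cat == params.focal_category).to_numpy(dtype=float)
    n = len(species)
    rng = np.random.default_rng(params.seed + 1)
    mu = params._per_family("mu")
    beta = params._per_family("beta")
    s2p = params._per_family("sigma2_phylo")
    s2e = params._per_family("sigma2_resid")
    # Cholesky of C once; scaled per family
    L = np.linalg.cholesky(cov.C + 1e-12 * np.trace(cov.C) * np.eye(n))
    out = np.empty((n, params.n_families), dtype=int)
    for f in range(params.n_families):
        u = np.sqrt(s2p[f]) * (L @ rng.standard_normal(n))
        e = np.sqrt(s2e[f]) * rng.standard_normal(n)
        eta = mu[f] + beta[f] * focal + u + e
        out[:, f] = rng.poisson(np.exp(eta))
    cols = [f"fam{f + 1}" for f in range(params.n_families)]
    return pd.DataFrame(out, index=pd.Index(species, name="species"),
                        columns=cols)


def simulate_locus_table(
    matrix: pd.DataFrame,
    tandem_fraction: float = 0.5,
    chrom_count: int = 20,
    seed: int = 0,
    window: int = 5_000_000,
    chrom_length: int = 100_000_000,
    gene_length: int = 20_000,
) -> pd.DataFrame:
    """Place gene copies on synthetic chromosomes (BED-like, 0-based).

    For each (family, species) with >= 2 copies the copies are either
    clustered within ``window`` base pairs on a single chromosome (with
    probability ``tandem_fraction``) or scattered on distinct
    chromosomes. Single copies land anywhere.
    """
    if not 0 <= tandem_fraction <= 1:
        raise ValueError("tandem_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for species in matrix.index:
        for family in matrix.columns:
            k = int(matrix.loc[species, family])
            if k == 0:
                continue
            if k == 1:
                chrom = f"chr{rng.integers(chrom_count) + 1}"
                start = int(rng.integers(chrom_length - gene_length))
                rows.append((family, species, chrom, start,
                             start + gene_length))
            elif rng.random() < tandem_fraction:
                chrom = f"chr{rng.integers(chrom_count) + 1}"
                base = int(rng.integers(chrom_length - window - gene_length))
                offs = np.sort(rng.choice(window - gene_length, size=k,
                                          replace=False))
                for o in offs:
                    rows.append((family, species, chrom, base + int(o),
                                 base + int(o) + gene_length))
            else:
                chroms = rng.choice(chrom_count, size=min(k, chrom_count),
                                    replace=False) + 1
                # if k exceeds chrom_count, reuse chromosomes but space the
                # extra copies > window apart so no tandem pair arises
                for i in range(k):
                    chrom = f"chr{chroms[i % len(chroms)]}"
                    lap = i // len(chroms)
                    start = (lap * 2 * (window + gene_length)
                             + int(rng.integers(window)))
                    rows.append((family, species, chrom, start,
                                 start + gene_length))
    return pd.DataFrame(
        rows, columns=["family", "species", "chrom", "start", "end"]
    )


def simulate_diet_composition(
    states: pd.DataFrame, seed: int = 0
) -> pd.DataFrame:
    """Prey proportions per consumer, consistent with the trophic category.

    Herbivores eat primary producers only (prey trophic level 1).
    Carnivores and omnivores receive Dirichlet-distributed proportions over
    herbivorous / omnivorous / carnivorous prey; omnivores additionally eat
    primary producers. Proportions per consumer sum to 1.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for _, rec in states.iterrows():
        sp, cat = rec["species"], rec["category"]
        if cat == "herbivore":
            rows.append((sp, "primary_producer", 1.0))
        elif cat == "carnivore":
            p = rng.dirichlet([4.0, 2.0, 1.0])
            for prey, frac in zip(
                ("herbivorous_prey", "omnivorous_prey", "carnivorous_prey"), p
            ):
                rows.append((sp, prey, float(frac)))
        else:
            p = rng.dirichlet([4.0, 2.0, 1.0, 0.5])
            for prey, frac in zip(
                ("primary_producer", "herbivorous_prey", "omnivorous_prey",
                 "carnivorous_prey"), p,
            ):
                rows.append((sp, prey, float(frac)))
    return pd.DataFrame(rows, columns=["species", "prey_class", "proportion"])


def write_ortholog_groups(matrix: pd.DataFrame, path) -> None:
    """Write an ortholog-group TSV in the dialect `ingest` reads back.

    Header: ``family`` then species names. Each cell holds comma-joined
    synthetic protein IDs (count = matrix entry); zero copies → ``*``.
    """
    with open(path, "w") as fh:
        fh.write("family\t" + "\t".join(matrix.index) + "\n")
        for family in matrix.columns:
            cells = []
            for species in matrix.index:
                k = int(matrix.loc[species, family])
                cells.append(
                    ",".join(f"{species}|{family}|p{i + 1}" for i in range(k))
                    if k else "*"
                )
            fh.write(family + "\t" + "\t".join(cells) + "\n")
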