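"""Synthetic community generator with known assembly regime.

Every downstream stage of the package (diversity, niche breadth, stochasticity
ratio, neutral-model fit, phylogenetic signal, biomarkers) is validated against
tables produced here, because the generator knows the truth: the metacommunity
relative abundances, the immigration rate ``m`` of neutrally assembled local
communities, the per-category selection factors of deterministically assembled
ones, the identities of planted habitat generalists/specialists, and the
Brownian variance of host traits.

Neutral assembly draws each local community's composition from a Dirichlet
with concentration ``N*m*p`` and then reads from a multinomial of size ``N``.
The Dirichlet marginals are Beta(N*m*p_i, N*m*(1-p_i)) -- exactly the
stationary distribution of the Sloan neutral model -- while compositions still
sum to one.  Niche assembly multiplies the metacommunity by fixed per-category
lognormal selection factors, so replicates within a category share a
deterministic signature and differ only by multinomial sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .tables import CountTable, GroupDesign

__all__ = [
    "Metacommunity",
    "SimSpec",
    "make_metacommunity",
    "simulate_neutral",
    "simulate_niche",
    "simulate_community",
    "plant_niche_otus",
    "make_host_tree",
    "tree_vcv",
    "expand_replicates",
    "simulate_host_traits",
]


@dataclass
class Metacommunity:
    """Regional pool: relative abundances over S taxa (sums to one)."""

    p: np.ndarray
    descriptor: str = "lognormal"
    taxon_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if (self.p <= 0).any():
            raise ValueError("metacommunity abundances must be strictly positive")
        if not np.isclose(self.p.sum(), 1.0):
            raise ValueError("metacommunity abundances must sum to 1")
        if not self.taxon_ids:
            width = len(str(self.p.size))
            self.taxon_ids = [f"OTU{i + 1:0{width}d}" for i in range(self.p.size)]

    @property
    def n_taxa(self) -> int:
        return self.p.size


@dataclass
class SimSpec:
    """Parameters of one synthetic experiment (regime + sizes + seed).

    Defaults mirror a rarefied amplicon survey: 5 categories x 5 replicate
    samples, 500 taxa from a lognormal metacommunity, 1,000 reads per sample.
    """

    S: int = 500
    n_categories: int = 5
    n_samples_per_category: int = 5
    depth: int = 1000
    regime: str = "neutral"  # neutral | niche | mixed
    m: float = 0.3
    sigma_sel: float = 3.0
    mix_weight: float = 0.5  # 1 -> fully neutral, 0 -> fully niche
    sigma_meta: float = 2.0
    n_generalist: int = 0
    n_specialist: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.m <= 1:
            raise ValueError("m must lie in (0, 1]")
        if self.regime not in ("neutral", "niche", "mixed"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if min(self.S, self.n_categories, self.n_samples_per_category, self.depth) < 1:
            raise ValueError("all sizes must be >= 1")
        if not 0 <= self.mix_weight <= 1:
            raise ValueError("mix_weight must lie in [0, 1]")

    def design(self) -> GroupDesign:
        labels = {}
        for c in range(self.n_categories):
            cat = f"cat{c + 1}"
            for r in range(self.n_samples_per_category):
                labels[f"{cat}_s{r + 1}"] = cat
        return GroupDesign(labels)


def make_metacommunity(S: int, sigma: float = 2.0, seed: int = 0) -> Metacommunity:
    """Long-tailed (lognormal) metacommunity relative abundance vector."""
    if S < 2:
        raise ValueError("need at least 2 taxa")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    raw = rng.lognormal(mean=0.0, sigma=sigma, size=S)
    p = raw / raw.sum()
    return Metacommunity(p, descriptor=f"lognormal(sigma={sigma})")


def _sample_ids(design: GroupDesign) -> list[str]:
    return list(design.labels)


def simulate_neutral(meta: Metacommunity, n_samples: int, N: int, m: float,
                     seed: int = 0, sample_ids: list[str] | None = None) -> CountTable:
    """Neutrally assembled local communities (Sloan stationary marginals)."""
    if not 0 < m <= 1:
        raise ValueError("m must lie in (0, 1]")
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = np.random.default_rng(seed)
    conc = N * m * meta.p
    counts = np.empty((meta.n_taxa, n_samples), dtype=np.int64)
    for j in range(n_samples):
        q = rng.dirichlet(conc)
        counts[:, j] = rng.multinomial(N, q)
    if sample_ids is None:
        sample_ids = [f"s{j + 1}" for j in range(n_samples)]
    return CountTable(list(meta.taxon_ids), sample_ids, counts)


def _selection_factors(meta: Metacommunity, categories: list[str],
                       sigma_sel: float, rng: np.random.Generator) -> dict[str, np.ndarray]:
    return {
        c: rng.lognormal(mean=0.0, sigma=sigma_sel, size=meta.n_taxa)
        for c in categories
    }


def simulate_niche(meta: Metacommunity, design: GroupDesign, sigma_sel: float,
                   N: int, seed: int = 0) -> CountTable:
    """Deterministically assembled communities under category-specific selection.

    Selection factors ``w[c, i] ~ LogNormal(0, sigma_sel^2)`` are drawn once per
    category; every replicate of a category samples a multinomial around the
    same selected composition ``p * w[c] / sum``.  ``sigma_sel = 0`` reduces
    exactly to multinomial sampling of the metacommunity.
    """
    if sigma_sel < 0:
        raise ValueError("sigma_sel must be >= 0")
    rng = np.random.default_rng(seed)
    w = _selection_factors(meta, design.categories, sigma_sel, rng)
    sample_ids = _sample_ids(design)
    counts = np.empty((meta.n_taxa, len(sample_ids)), dtype=np.int64)
    for j, s in enumerate(sample_ids):
        q = meta.p * w[design.labels[s]]
        q = q / q.sum()
        counts[:, j] = rng.multinomial(N, q)
    return CountTable(list(meta.taxon_ids), sample_ids, counts)


def simulate_community(spec: SimSpec) -> tuple[CountTable, GroupDesign, dict[str, str]]:
    """Run one full experiment from a :class:`SimSpec`.

    Returns ``(table, design, truth)`` where ``truth`` maps planted taxon IDs
    to ``"generalist"``/``"specialist"`` (empty when nothing was planted).
    """
    rng = np.random.default_rng(spec.seed)
    meta = make_metacommunity(spec.S, spec.sigma_meta, seed=int(rng.integers(2**31)))
    design = spec.design()
    sample_ids = _sample_ids(design)
    n = len(sample_ids)
    if spec.regime == "neutral":
        table = simulate_neutral(meta, n, spec.depth, spec.m,
                                 seed=int(rng.integers(2**31)), sample_ids=sample_ids)
    elif spec.regime == "niche":
        table = simulate_niche(meta, design, spec.sigma_sel, spec.depth,
                               seed=int(rng.integers(2**31)))
    else:  # mixed: convex blend of the two compositions before read sampling
        sub = np.random.default_rng(int(rng.integers(2**31)))
        conc = spec.depth * spec.m * meta.p
        w = _selection_factors(meta, design.categories, spec.sigma_sel, sub)
        counts = np.empty((meta.n_taxa, n), dtype=np.int64)
        for j, s in enumerate(sample_ids):
            q_neu = sub.dirichlet(conc)
            q_nic = meta.p * w[design.labels[s]]
            q_nic = q_nic / q_nic.sum()
            q = spec.mix_weight * q_neu + (1 - spec.mix_weight) * q_nic
            counts[:, j] = sub.multinomial(spec.depth, q)
        table = CountTable(list(meta.taxon_ids), sample_ids, counts)
    truth: dict[str, str] = {}
    if spec.n_generalist or spec.n_specialist:
        table, truth = plant_niche_otus(
            table, design, spec.n_generalist, spec.n_specialist,
            seed=int(rng.integers(2**31)),
        )
    return table, design, truth


def plant_niche_otus(table: CountTable, design: GroupDesign, n_generalist: int,
                     n_specialist: int, seed: int = 0,
                     min_total: int | None = None) -> tuple[CountTable, dict[str, str]]:
    """Overwrite rows to plant known habitat generalists and specialists.

    Generalists are spread (near-)uniformly across all samples; each
    specialist is confined to the samples of one randomly chosen category and
    zeroed elsewhere.  Row totals are preserved, so planted taxa keep their
    original abundance and only their distribution changes.  Planting targets
    are picked among taxa with row total >= ``min_total`` (default: twice the
    sample count) so every planted taxon carries enough reads to be
    classifiable at all.
    """
    if n_generalist + n_specialist > table.n_taxa:
        raise ValueError("more planted taxa requested than taxa in the table")
    rng = np.random.default_rng(seed)
    labels = design.for_table(table)
    if min_total is None:
        min_total = 2 * table.n_samples
    eligible = np.flatnonzero(table.taxon_sums >= min_total)
    if eligible.size < n_generalist + n_specialist:
        raise ValueError(
            f"only {eligible.size} taxa have total >= {min_total}; "
            f"cannot plant {n_generalist + n_specialist}"
        )
    chosen = rng.choice(eligible, size=n_generalist + n_specialist, replace=False)
    counts = table.counts.copy()
    truth: dict[str, str] = {}
    n = table.n_samples
    for k, i in enumerate(chosen):
        total = int(counts[i].sum())
        if k < n_generalist:
            base, rem = divmod(total, n)
            row = np.full(n, base, dtype=np.int64)
            row[rng.choice(n, size=rem, replace=False)] += 1
            truth[table.taxon_ids[i]] = "generalist"
        else:
            cat = design.categories[int(rng.integers(len(design.categories)))]
            members = np.flatnonzero(labels == cat)
            row = np.zeros(n, dtype=np.int64)
            row[members] = rng.multinomial(total, np.full(members.size, 1 / members.size))
            truth[table.taxon_ids[i]] = "specialist"
        counts[i] = row
    return CountTable(list(table.taxon_ids), list(table.sample_ids), counts), truth


# ---------------------------------------------------------------------------
# Host trees and traits
# ---------------------------------------------------------------------------

def make_host_tree(n_species: int, seed: int = 0, height: float = 1.0) -> dendropy.Tree:
    """Random ultrametric species tree by sequential random coalescence."""
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace([f"sp{i + 1}" for i in range(n_species)])
    nodes = []
    for t in taxa:
        nd = dendropy.Node(taxon=t)
        nd._height = 0.0
        nodes.append(nd)
    # coalescence times: sorted uniforms scaled to the requested tree height
    times = np.sort(rng.uniform(0.05, 1.0, size=n_species - 1)) * height
    for t in times:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[i], nodes[j]
        parent = dendropy.Node()
        parent._height = float(t)
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = float(t) - a._height
        b.edge.length = float(t) - b._height
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=nodes[0])
    tree.seed_node.edge.length = None
    return tree


def tree_vcv(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Phylogenetic covariance matrix: shared root-to-MRCA branch length."""
    tree = tree.clone(depth=1)
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    idx = {id(lf): k for k, lf in enumerate(leaves)}
    n = len(leaves)
    V = np.zeros((n, n))
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._tipset = [idx[id(node)]]
            V[node._tipset[0], node._tipset[0]] = node.root_distance
        else:
            childsets = [ch._tipset for ch in node.child_nodes()]
            for a in range(len(childsets)):
                for b in range(a + 1, len(childsets)):
                    for i in childsets[a]:
                        for j in childsets[b]:
                            V[i, j] = V[j, i] = node.root_distance or 0.0
            node._tipset = [i for s in childsets for i in s]
    return labels, V


def expand_replicates(tree: dendropy.Tree, reps_per_tip: int) -> dendropy.Tree:
    """Attach ``reps_per_tip`` zero-length replicate tips under each species."""
    tree = tree.clone(depth=1)
    for leaf in list(tree.leaf_node_iter()):
        name = leaf.taxon.label
        leaf.taxon = None
        for r in range(reps_per_tip):
            taxon = dendropy.Taxon(label=f"{name}_r{r + 1}")
            tree.taxon_namespace.add_taxon(taxon)
            child = dendropy.Node(taxon=taxon)
            leaf.add_child(child)
            child.edge.length = 0.0
    return tree


def simulate_host_traits(
    tree: dendropy.Tree, mode: str = "brownian", sigma2: float = 1.0,
    reps_per_tip: int = 1, seed: int = 0, rep_noise_frac: float = 0.01,
) -> tuple[dict[str, float], dendropy.Tree]:
    """Brownian-motion (or label-shuffled) trait values on a host tree.

    Species values are drawn from a multivariate normal with covariance
    ``sigma2 * V`` (V = shared branch length).  With ``reps_per_tip > 1`` each
    species tip is expanded into a zero-length polytomy of replicate tips that
    share the species value plus i.i.d. noise with SD = ``rep_noise_frac``
    times the across-species trait SD (conspecific replicates of one host).
    ``mode="shuffled"`` permutes the Brownian species values across species,
    destroying the phylogenetic signal while keeping the trait distribution.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    if mode not in ("brownian", "shuffled"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    labels, V = tree_vcv(tree)
    vals = rng.multivariate_normal(np.zeros(len(labels)), sigma2 * V,
                                   method="eigh")
    if mode == "shuffled":
        vals = rng.permutation(vals)
    sd = float(np.std(vals)) or 1.0
    if reps_per_tip <= 1:
        return dict(zip(labels, map(float, vals))), tree
    out_tree = expand_replicates(tree, reps_per_tip)
    traits = {}
    for name, v in zip(labels, vals):
        for r in range(reps_per_tip):
            traits[f"{name}_r{r + 1}"] = float(
                v + rng.normal(0.0, rep_noise_frac * sd)
            )
    return traits, out_tree
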