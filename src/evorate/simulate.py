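"""Synthetic multi-locus protein evolution along a time tree.

Ground-truth generator for every downstream stage: K loci of amino-acid
sequences evolve along a given time-calibrated species tree under a 20-state
continuous-time Markov chain with lineage-specific rate multipliers (e.g. a
fast rodent clade and a slow marsupial clade), per-locus rate scalars,
optional discrete-gamma site-rate heterogeneity and optional per-locus taxon
dropout (emulating a subunit that is unannotated in some species).

The branch expected distance (substitutions/site) is

    d_e = mu * (t_e / 100) * branch_rate(e) * locus_scalar * site_rate

with ``mu`` the baseline rate in substitutions per site per 100 MY.  Under
the default equal-rates (Jukes-Cantor-like 20-state) model the transition
probability has the closed form

    P(same | d) = 1/20 + (19/20) * exp(-(20/19) * d)

which also yields the closed-form expected p-distance between two leaves,

    p_exp = (19/20) * (1 - exp(-(20/19) * d_path)),

used as an analytic oracle by the test-suite.  A general model may be
supplied as a 20x20 exchangeability matrix plus equilibrium frequencies, in
which case transition probabilities come from the matrix exponential of the
scaled rate matrix (no closed-form oracle; compare by Monte Carlo).

No indels are simulated: the analysis consumes a fixed alignment, so the
true alignment stays exact; gaps enter only through dropout and the
gap-fill concatenation policy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.stats import gamma as gamma_dist

from .errors import ConfigError, EvorateError
from .seqio import AMINO_ACIDS, CladeMap, LocusAlignment, TimeTree, read_timetree

N_STATES = 20


@dataclass
class LocusSpec:
    """One simulated locus: name, alignment length, relative rate scalar."""

    name: str
    length: int
    scalar: float = 1.0


@dataclass
class SimConfig:
    """Full specification of one simulation run.

    ``branch_rate`` maps a branch (identified by its child-node name;
    unnamed internal nodes are auto-named ``node<k>`` in post-order) to a
    rate multiplier, default 1.0.  ``dropout`` lists (locus, taxon) pairs to
    omit entirely from that locus' alignment.  ``mu`` is the baseline rate
    in substitutions per site per 100 MY.
    """

    tree: TimeTree
    loci: list[LocusSpec]
    mu: float = 0.1
    branch_rate: dict[str, float] = field(default_factory=dict)
    gamma_shape: float | None = None
    gamma_categories: int = 4
    dropout: list[tuple[str, str]] = field(default_factory=list)
    seed: int = 0
    exchangeability: np.ndarray | None = None
    frequencies: np.ndarray | None = None

    def validate(self) -> None:
        if self.mu <= 0:
            raise ConfigError("mu must be positive")
        for name, r in self.branch_rate.items():
            if r <= 0:
                raise ConfigError(f"branch rate for {name!r} must be positive")
        for spec in self.loci:
            if spec.length < 1:
                raise ConfigError(f"locus {spec.name!r} has length < 1")
            if spec.scalar <= 0:
                raise ConfigError(f"locus {spec.name!r} scalar must be positive")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ConfigError("gamma shape must be positive")
        if (self.exchangeability is None) != (self.frequencies is None):
            raise ConfigError(
                "exchangeability matrix and frequencies must be supplied together"
            )
        if self.frequencies is not None:
            freqs = np.asarray(self.frequencies, dtype=float)
            if freqs.shape != (N_STATES,):
                raise ConfigError("frequencies must have 20 entries")
            if abs(freqs.sum() - 1.0) > 1e-9 or (freqs < 0).any():
                raise ConfigError("frequencies must be non-negative and sum to 1")
            ex = np.asarray(self.exchangeability, dtype=float)
            if ex.shape != (N_STATES, N_STATES):
                raise ConfigError("exchangeability matrix must be 20x20")
            if not np.allclose(ex, ex.T):
                raise ConfigError("exchangeability matrix must be symmetric")

    @property
    def is_equal_rates(self) -> bool:
        return self.exchangeability is None

    def manifest(self) -> dict:
        """Parameters sufficient to regenerate the run bit-identically."""
        return {
            "newick": self.tree.dendropy_tree.as_string(schema="newick").strip(),
            "mu": self.mu,
            "loci": [[s.name, s.length, s.scalar] for s in self.loci],
            "branch_rate": dict(self.branch_rate),
            "gamma_shape": self.gamma_shape,
            "gamma_categories": self.gamma_categories,
            "dropout": [list(d) for d in self.dropout],
            "seed": self.seed,
            "model": "equal_rates" if self.is_equal_rates else "custom_matrix",
        }


@dataclass
class SimResult:
    """Simulated per-locus alignments plus ground truth.

    ``branch_distance`` maps (child-node name) -> expected substitutions per
    site on that branch at locus scalar 1 and site rate 1.
    """

    loci: dict[str, LocusAlignment]
    config: SimConfig
    branch_distance: dict[str, float]

    @property
    def locus_order(self) -> list[str]:
        return [spec.name for spec in self.config.loci]


def discrete_gamma_rates(shape: float, n_categories: int) -> np.ndarray:
    """Mean rates of equal-probability discrete gamma categories (mean 1).

    The gamma density with shape=scale⁻¹=a is cut at its quantiles
    i/k; each category's rate is the conditional mean within its slice,
    so the category rates average exactly 1.
    """
    if shape <= 0 or n_categories < 1:
        raise ConfigError("invalid gamma discretization")
    k = n_categories
    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a=shape, scale=1.0 / shape)
    # conditional mean over [lo, hi] via the incomplete-gamma identity
    upper = gamma_dist.cdf(edges[1:], a=shape + 1, scale=1.0 / shape)
    lower = gamma_dist.cdf(edges[:-1], a=shape + 1, scale=1.0 / shape)
    return (upper - lower) * k


def _auto_name_nodes(tree: TimeTree) -> None:
    """Deterministically name unnamed internal nodes in post-order."""
    counter = 0
    for node in tree.dendropy_tree.postorder_node_iter():
        if node.is_leaf():
            continue
        if not node.label:
            node.label = f"node{counter}"
        counter += 1


def _node_name(node) -> str:
    return node.taxon.label if node.is_leaf() else node.label


def _branch_times(tree: TimeTree) -> dict[str, float]:
    """Branch durations in MY, keyed by child-node name."""
    out = {}
    for node in tree.dendropy_tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        out[_node_name(node)] = tree.node_age(parent) - tree.node_age(node)
    return out


def _equal_rates_step(
    states: np.ndarray, d: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Evolve a state vector over one branch under the equal-rates CTMC.

    ``d`` is the per-site expected distance.  P(same) has the closed form
    1/20 + (19/20) exp(-(20/19) d); a changed site moves uniformly to one
    of the 19 other states.
    """
    p_same = 1.0 / N_STATES + (19.0 / 20.0) * np.exp(-(20.0 / 19.0) * d)
    change = rng.random(states.shape) >= p_same
    if not change.any():
        return states.copy()
    new = states.copy()
    # uniform over the 19 states != current
    draw = rng.integers(0, N_STATES - 1, size=int(change.sum()))
    cur = states[change]
    draw = np.where(draw >= cur, draw + 1, draw)
    new[change] = draw
    return new


def _general_step(
    states: np.ndarray,
    d: float,
    rate_matrix: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One branch step under a general reversible model (matrix exponential)."""
    P = expm(rate_matrix * d)
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=1, keepdims=True)
    cum = np.cumsum(P, axis=1)
    u = rng.random(states.shape)
    return (u[:, None] > cum[states]).sum(axis=1).astype(states.dtype)


def _build_rate_matrix(exchangeability: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Reversible rate matrix Q = S diag(pi), scaled to 1 expected sub/site."""
    Q = exchangeability * freqs[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -(freqs * np.diag(Q)).sum()
    return Q / scale


def simulate(config: SimConfig) -> SimResult:
    """Generate per-locus alignments along the configured time tree.

    The root sequence is drawn from the equilibrium frequencies (uniform
    under the equal-rates model); each branch then evolves every site
    independently.  Site-rate categories (if gamma is enabled) are drawn
    once per site and kept fixed along the whole tree.  Identical
    (config, seed) always produce identical output.
    """
    config.validate()
    tree = config.tree
    _auto_name_nodes(tree)
    times = _branch_times(tree)
    rates = {name: config.branch_rate.get(name, 1.0) for name in times}
    branch_distance = {
        name: config.mu * (times[name] / 100.0) * rates[name] for name in times
    }

    if config.is_equal_rates:
        freqs = np.full(N_STATES, 1.0 / N_STATES)
        rate_matrix = None
    else:
        freqs = np.asarray(config.frequencies, dtype=float)
        rate_matrix = _build_rate_matrix(
            np.asarray(config.exchangeability, dtype=float), freqs
        )

    if config.gamma_shape is not None:
        cat_rates = discrete_gamma_rates(config.gamma_shape, config.gamma_categories)
    else:
        cat_rates = np.ones(1)

    dropout = set(config.dropout)
    loci_out: dict[str, LocusAlignment] = {}
    for locus_idx, spec in enumerate(config.loci):
        rng = np.random.default_rng([config.seed, locus_idx])
        site_rates = cat_rates[rng.integers(0, len(cat_rates), size=spec.length)]
        root_states = rng.choice(N_STATES, size=spec.length, p=freqs)

        leaf_states: dict[str, np.ndarray] = {}
        stack = [(tree.dendropy_tree.seed_node, root_states)]
        while stack:
            node, states = stack.pop()
            for child in node.child_nodes():
                d_branch = branch_distance[_node_name(child)] * spec.scalar
                d_sites = d_branch * site_rates
                if rate_matrix is None:
                    child_states = _equal_rates_step(states, d_sites, rng)
                else:
                    if config.gamma_shape is not None:
                        child_states = states.copy()
                        for rate in np.unique(site_rates):
                            mask = site_rates == rate
                            child_states[mask] = _general_step(
                                states[mask], d_branch * rate, rate_matrix, rng
                            )
                    else:
                        child_states = _general_step(
                            states, d_branch, rate_matrix, rng
                        )
                if child.is_leaf():
                    leaf_states[_node_name(child)] = child_states
                else:
                    stack.append((child, child_states))

        members = {
            taxon: "".join(AMINO_ACIDS[s] for s in states)
            for taxon, states in sorted(leaf_states.items())
            if (spec.name, taxon) not in dropout
        }
        loci_out[spec.name] = LocusAlignment(locus=spec.name, members=members)
    return SimResult(loci=loci_out, config=config, branch_distance=branch_distance)


def path_distance(result: SimResult, taxon_a: str, taxon_b: str, locus: str) -> float:
    """Expected substitutions/site on the path between two leaves at a locus."""
    spec = next(s for s in result.config.loci if s.name == locus)
    tree = result.config.tree.dendropy_tree
    nodes = {}
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label in (taxon_a, taxon_b):
            nodes[leaf.taxon.label] = leaf
    if len(nodes) != 2:
        raise EvorateError(f"taxa {taxon_a!r}/{taxon_b!r} not both in the tree")
    mrca = tree.mrca(taxa=[nodes[taxon_a].taxon, nodes[taxon_b].taxon])
    total = 0.0
    for start in (nodes[taxon_a], nodes[taxon_b]):
        node = start
        while node is not mrca:
            total += result.branch_distance[_node_name(node)]
            node = node.parent_node
    return total * spec.scalar


def expected_p(
    result: SimResult, taxon_a: str, taxon_b: str, locus: str
) -> float:
    """Closed-form expected p-distance between two leaves at one locus.

    Equal-rates model only:  p = (19/20)(1 - exp(-(20/19) d_path)); with
    discrete gamma, the equal-probability average over category rates.
    Raises for a custom matrix model (use Monte-Carlo comparison there).
    """
    config = result.config
    if not config.is_equal_rates:
        raise EvorateError(
            "closed-form expected p-distance is defined for the equal-rates "
            "model only"
        )
    d_path = path_distance(result, taxon_a, taxon_b, locus)
    if config.gamma_shape is not None:
        cat = discrete_gamma_rates(config.gamma_shape, config.gamma_categories)
        return float(
            np.mean((19.0 / 20.0) * (1.0 - np.exp(-(20.0 / 19.0) * d_path * cat)))
        )
    return (19.0 / 20.0) * (1.0 - math.exp(-(20.0 / 19.0) * d_path))


# --- the study-condition dataset -------------------------------------------

#: Fixed 15-taxon ultrametric species tree (ages in MYA).  Clade depths
#: follow the canonical mammal timescale: eutherian/marsupial split 160,
#: Boreoeutheria/Atlantogenata 105, Euarchontoglires/Laurasiatheria 96,
#: primate/rodent split 90, marsupial crown split 82.
STUDY_TREE_NEWICK = (
    "((((((primate1:25,primate2:25):35,(primate3:40,primate4:40):20):30,"
    "((rodent1:30,rodent2:30):40,(rodent3:45,rodent4:45):25):20):6,"
    "((laurasiatherian1:55,laurasiatherian2:55):25,laurasiatherian3:80):16):9,"
    "(afrotherian1:60,afrotherian2:60):45):55,"
    "(marsupial1:82,marsupial2:82):78);"
)

STUDY_CLADES = {
    "primate1": "primates",
    "primate2": "primates",
    "primate3": "primates",
    "primate4": "primates",
    "rodent1": "rodents",
    "rodent2": "rodents",
    "rodent3": "rodents",
    "rodent4": "rodents",
    "laurasiatherian1": "Laurasiatherians",
    "laurasiatherian2": "Laurasiatherians",
    "laurasiatherian3": "Laurasiatherians",
    "afrotherian1": "Afrotherians",
    "afrotherian2": "Afrotherians",
    "marsupial1": "marsupials",
    "marsupial2": "marsupials",
}

#: Ten loci named after the channel complex subunits they emulate, with
#: heterogeneous lengths (roughly proportional to the real subunit sizes)
#: and mild per-locus rate variation.  Total 2,330 columns.
STUDY_LOCI = [
    LocusSpec("CatSper1", 350, 1.2),
    LocusSpec("CatSper2", 300, 1.0),
    LocusSpec("CatSper3", 200, 0.9),
    LocusSpec("CatSper4", 220, 1.0),
    LocusSpec("CatSperB", 330, 1.1),
    LocusSpec("CatSperG", 290, 1.0),
    LocusSpec("CatSperD", 260, 0.8),
    LocusSpec("CatSperE", 180, 1.0),
    LocusSpec("CatSperZ", 100, 1.5),
    LocusSpec("EFCAB9", 100, 0.9),
]

#: Baseline rate: substitutions per site per 100 MY.  Chosen so that raw
#: interclade p-distances land in the 0.2-0.35 band typical of
#: fast-evolving reproductive proteins on a 0-0.6 heatmap scale.
STUDY_MU = 0.12

#: Lineage multipliers: the whole rodent clade (stem + crown) evolves 2x
#: faster, the marsupial clade 2x slower.
STUDY_BRANCH_RATES = {
    "rodent1": 2.0,
    "rodent2": 2.0,
    "rodent3": 2.0,
    "rodent4": 2.0,
    "rodents_crown1": 2.0,
    "rodents_crown2": 2.0,
    "rodents_stem": 2.0,
    "marsupial1": 0.5,
    "marsupial2": 0.5,
    "marsupials_stem": 0.5,
}


def _study_tree() -> TimeTree:
    tree = read_timetree(STUDY_TREE_NEWICK)
    # name the rate-bearing internal nodes so multipliers can address them
    dtree = tree.dendropy_tree
    taxa = dtree.taxon_namespace

    def mrca_of(labels):
        return dtree.mrca(taxa=[t for t in taxa if t.label in labels])

    mrca_of(["rodent1", "rodent2"]).label = "rodents_crown1"
    mrca_of(["rodent3", "rodent4"]).label = "rodents_crown2"
    mrca_of(["rodent1", "rodent4"]).label = "rodents_stem"
    mrca_of(["marsupial1", "marsupial2"]).label = "marsupials_stem"
    return tree


def study_clade_map() -> CladeMap:
    """Clade labels for the fixed study tree."""
    return CladeMap(dict(STUDY_CLADES))


def make_paper_like_dataset(seed: int = 0) -> SimResult:
    """Simulate the study conditions: 15 therian-like taxa, 10 loci.

    Rodent branches (stem and crown) carry rate multiplier 2.0 and
    marsupial branches 0.5 on the fixed tree (marsupial split from the
    eutherians at 160 MYA, marsupial crown at 82 MYA).  One marsupial taxon
    lacks the ninth locus, emulating a subunit unannotated in that genome.
    The slow-but-ancient marsupial lineage yields large raw distances yet
    small time-normalized distances — the qualitative reversal the
    downstream rate comparison is designed to expose.
    """
    config = SimConfig(
        tree=_study_tree(),
        loci=list(STUDY_LOCI),
        mu=STUDY_MU,
        branch_rate=dict(STUDY_BRANCH_RATES),
        dropout=[("CatSperZ", "marsupial2")],
        seed=seed,
    )
    return simulate(config)
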