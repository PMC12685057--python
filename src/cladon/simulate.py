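"""Synthetic data with the statistical structure the analysis assumes.

Three generators, one seeded RNG per run:

* a Kingman-coalescent sampler with finite-sites mutation, for checking
  the diversity statistics (E[S] = theta * a1, E[pi] = theta),
* a continuous-time codon-substitution simulator on a fixed tree.  Rates
  follow an MG94-flavored parameterization: a single-nucleotide change
  i -> j has rate proportional to pi(target nucleotide) * kappa^[transition]
  * omega^[nonsynonymous], optionally times a per-codon fitness weight.
  The matrix is rescaled to one expected substitution per codon site per
  unit branch length, so branch lengths read directly as divergence.
  The target-nucleotide parameterization makes ``gc_bias`` interpretable
  at the mutation level: pi_G = pi_C = gc_bias/2,
* a gene-family scenario builder that lays clade-specific rate scales,
  omega, compositional bias and codon preferences over a two-order species
  tree, together with a slowly evolving mitochondrial-like reference — a
  full, runnable analysis input with known ground truth.

No simulated sequence ever contains an in-frame stop codon: the coalescent
mutation kernel redraws hits that would create one, and the codon simulator
moves only between sense codons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

from .codes import NUCLEOTIDES, get_code, is_transition
from .io import CladeMap, CodonAlignment, GeneRecord, PhyloTree, ValidationError


@dataclass
class SimulationParams:
    """Knobs of the generative model; defaults are neutral and symmetric."""

    seed: int = 0
    n: int = 10
    L_codons: int = 300
    theta: float = 5.0
    omega: float = 1.0
    kappa: float = 1.0
    gc_bias: float = 0.5
    clade_rate_scales: dict[str, float] = field(default_factory=dict)
    reference_rate_scale: float = 1.0

    def __post_init__(self):
        if self.theta <= 0 or self.kappa <= 0 or self.omega < 0:
            raise ValidationError("rates must be positive (omega >= 0)")
        if not 0.0 < self.gc_bias < 1.0:
            raise ValidationError("gc_bias must be in (0, 1)")


# ---------------------------------------------------------------------------
# coalescent with finite-sites mutation


class _Node:
    __slots__ = ("children", "length", "label")

    def __init__(self, label=None):
        self.children = []
        self.length = 0.0
        self.label = label


def _kingman_genealogy(n: int, rng) -> tuple[_Node, list[_Node]]:
    """Sample a Kingman genealogy; branch lengths in scaled coalescent time."""
    tips = [_Node(f"seq{i + 1}") for i in range(n)]
    active = list(tips)
    heights = {id(node): 0.0 for node in active}
    t = 0.0
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[int(i)], active[int(j)]
        parent = _Node()
        parent.children = [a, b]
        a.length = t - heights[id(a)]
        b.length = t - heights[id(b)]
        heights[id(parent)] = t
        active = [x for x in active if x is not a and x is not b]
        active.append(parent)
    return active[0], tips


def _genealogy_newick(node: _Node) -> str:
    if not node.children:
        return f"{node.label}:{node.length:.8f}"
    inner = ",".join(_genealogy_newick(c) for c in node.children)
    return f"({inner}):{node.length:.8f}"


def _apply_mutation(seq: np.ndarray, rng, code) -> None:
    """One finite-sites mutation: uniform site, JC change kernel, redrawn
    if the resulting codon would be a stop."""
    while True:
        site = int(rng.integers(seq.size))
        cur = int(seq[site])
        target = int(rng.integers(3))
        new = (cur + 1 + target) % 4
        codon_start = (site // 3) * 3
        codon = seq[codon_start : codon_start + 3].copy()
        codon[site % 3] = new
        text = "".join(NUCLEOTIDES[b] for b in codon)
        if not code.is_stop(text):
            seq[site] = new
            return


def simulate_coalescent_alignment(
    params: SimulationParams, rng=None
) -> tuple[CodonAlignment, PhyloTree]:
    """Sample n sequences of L = 3 * L_codons sites under the neutral
    constant-size coalescent with Poisson(theta * T / 2) mutations placed
    uniformly on branches and assigned to uniformly chosen sites."""
    if params.n < 2:
        raise ValidationError("need n >= 2")
    rng = np.random.default_rng(params.seed) if rng is None else rng
    code = get_code(1)
    root, tips = _kingman_genealogy(params.n, rng)

    edges = []

    def collect(node):
        for child in node.children:
            edges.append(child)
            collect(child)

    collect(root)
    total = sum(e.length for e in edges)
    n_mut = rng.poisson(params.theta * total / 2.0)
    weights = np.array([e.length for e in edges]) / total
    counts = rng.multinomial(n_mut, weights)

    L = 3 * params.L_codons
    sense = np.array(
        [[NUCLEOTIDES.index(b) for b in c] for c in code.sense_codons]
    )
    root_codons = rng.integers(len(code.sense_codons), size=params.L_codons)
    root_seq = sense[root_codons].reshape(-1).astype(np.int8)

    mut_of = {id(e): int(c) for e, c in zip(edges, counts)}
    records = []

    def descend(node, seq):
        for child in node.children:
            s = seq.copy()
            for _ in range(mut_of[id(child)]):
                _apply_mutation(s, rng, code)
            if child.children:
                descend(child, s)
            else:
                records.append(
                    GeneRecord(
                        gene_id=child.label,
                        sequence="".join(NUCLEOTIDES[b] for b in s),
                    )
                )

    descend(root, root_seq)
    records.sort(key=lambda r: int(r.gene_id[3:]))
    tree = PhyloTree.from_newick(_genealogy_newick(root) + ";")
    return CodonAlignment(tuple(records), 1), tree


# ---------------------------------------------------------------------------
# codon substitution model


class CodonModel:
    """MG94-flavored rate matrix on the 61 sense codons, unit-scaled."""

    def __init__(
        self,
        omega: float = 1.0,
        kappa: float = 1.0,
        gc_bias: float = 0.5,
        codon_weights: dict[str, float] | None = None,
        code_id: int = 1,
    ):
        code = get_code(code_id)
        self.code = code
        nt_pi = {
            "G": gc_bias / 2.0,
            "C": gc_bias / 2.0,
            "A": (1.0 - gc_bias) / 2.0,
            "T": (1.0 - gc_bias) / 2.0,
        }
        codons = code.sense_codons
        k = len(codons)
        weights = np.ones(k)
        for c, w in (codon_weights or {}).items():
            c = c.upper().replace("U", "T")
            if c not in code.codon_index:
                raise ValidationError(f"codon weight for non-sense codon {c!r}")
            if w <= 0:
                raise ValidationError("codon weights must be positive")
            weights[code.codon_index[c]] = w

        q = np.zeros((k, k))
        for i, ci in enumerate(codons):
            for pos in range(3):
                for nt in NUCLEOTIDES:
                    if nt == ci[pos]:
                        continue
                    cj = ci[:pos] + nt + ci[pos + 1 :]
                    if not code.is_sense(cj):
                        continue
                    j = code.codon_index[cj]
                    rate = nt_pi[nt] * weights[j]
                    if is_transition(ci[pos], nt):
                        rate *= kappa
                    if code.translate(ci) != code.translate(cj):
                        rate *= omega
                    q[i, j] = rate

        # stationary distribution: product of target frequencies times the
        # codon weight, restricted to sense codons (detailed balance holds)
        pi = np.array(
            [nt_pi[c[0]] * nt_pi[c[1]] * nt_pi[c[2]] for c in codons]
        ) * weights
        pi /= pi.sum()
        mu = float(np.dot(pi, q.sum(axis=1)))
        q /= mu
        self.pi = pi
        self.rates = q
        self.total_rate = q.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            self.cum = np.cumsum(q, axis=1) / self.total_rate[:, None]

    def sample_stationary(self, n_codons: int, rng) -> np.ndarray:
        return rng.choice(len(self.pi), size=n_codons, p=self.pi)

    def evolve(self, seq: np.ndarray, t: float, rng) -> np.ndarray:
        """Evolve codon-index array ``seq`` for time ``t`` by exponential
        waiting times, vectorized over sites."""
        if t < 0:
            raise ValidationError("branch length must be >= 0")
        seq = seq.copy()
        remaining = np.full(seq.size, float(t))
        # sites whose current codon cannot move (e.g. ATG/TGG at omega=0)
        # simply wait out the branch
        active = np.flatnonzero(self.total_rate[seq] > 0)
        while active.size:
            rates = self.total_rate[seq[active]]
            waits = rng.exponential(1.0 / rates)
            still = waits < remaining[active]
            hit = active[still]
            remaining[hit] -= waits[still]
            if hit.size:
                u = rng.random(hit.size)
                rows = self.cum[seq[hit]]
                # first column whose cumulative mass exceeds u = target codon
                seq[hit] = (rows > u[:, None]).argmax(axis=1)
            active = hit[self.total_rate[seq[hit]] > 0]
        return seq

    def to_string(self, seq: np.ndarray) -> str:
        codons = self.code.sense_codons
        return "".join(codons[int(i)] for i in seq)

    def from_string(self, text: str) -> np.ndarray:
        text = text.upper().replace("U", "T")
        if len(text) % 3:
            raise ValidationError("root sequence length not divisible by 3")
        out = []
        for i in range(0, len(text), 3):
            codon = text[i : i + 3]
            if codon not in self.code.codon_index:
                raise ValidationError(
                    f"root sequence contains non-sense codon {codon!r}"
                )
            out.append(self.code.codon_index[codon])
        return np.array(out, dtype=int)


def simulate_codon_evolution(
    tree: PhyloTree,
    root: str | np.ndarray | None,
    params: SimulationParams,
    rate_scale: float = 1.0,
    codon_weights: dict[str, float] | None = None,
    rng=None,
) -> CodonAlignment:
    """Simulate codon sequences down ``tree``; returns the tip alignment.

    ``root`` is a codon sequence (string over sense codons), a codon-index
    array, or ``None``/"stationary" to sample the root from the model's
    stationary distribution.  Branch lengths are multiplied by
    ``rate_scale`` (the per-clade rate knob).
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    model = CodonModel(
        omega=params.omega,
        kappa=params.kappa,
        gc_bias=params.gc_bias,
        codon_weights=codon_weights,
    )
    if root is None or (isinstance(root, str) and root == "stationary"):
        root_seq = model.sample_stationary(params.L_codons, rng)
    elif isinstance(root, str):
        root_seq = model.from_string(root)
    else:
        root_seq = np.asarray(root, dtype=int)

    seqs: dict[int, np.ndarray] = {id(tree.tree.seed_node): root_seq}
    records = []
    for node in tree.tree.preorder_node_iter():
        if node is tree.tree.seed_node:
            continue
        if node.edge.length is None:
            raise ValidationError("missing branch length in simulation tree")
        parent = seqs[id(node.parent_node)]
        seq = model.evolve(parent, node.edge.length * rate_scale, rng)
        seqs[id(node)] = seq
        if node.is_leaf():
            records.append(
                GeneRecord(
                    gene_id=node.taxon.label, sequence=model.to_string(seq)
                )
            )
    if not records:  # single-node tree: the root is the only "tip"
        records.append(
            GeneRecord(gene_id="root", sequence=model.to_string(root_seq))
        )
    return CodonAlignment(tuple(records), 1)


def simulate_gene_set(
    n_genes: int,
    t: float,
    params: SimulationParams,
    codon_weights: dict[str, float] | None = None,
    rng=None,
    prefix: str = "gene",
) -> CodonAlignment:
    """n independent genes, each a stationary root evolved for time ``t``.

    The workhorse for composition checks (PR2, GC3s, Nc): each gene is an
    independent draw whose composition sits at the model's stationary
    distribution.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    model = CodonModel(
        omega=params.omega,
        kappa=params.kappa,
        gc_bias=params.gc_bias,
        codon_weights=codon_weights,
    )
    records = []
    for i in range(n_genes):
        seq = model.sample_stationary(params.L_codons, rng)
        seq = model.evolve(seq, t, rng)
        records.append(
            GeneRecord(gene_id=f"{prefix}{i + 1}", sequence=model.to_string(seq))
        )
    return CodonAlignment(tuple(records), 1)


# ---------------------------------------------------------------------------
# gene-family scenario


@dataclass
class CladeSpec:
    """One gene-family clade: size, taxonomic span, and evolutionary knobs."""

    label: str
    n_genes: int
    orders: tuple[str, ...]
    rate_scale: float = 1.0
    omega: float = 0.2
    kappa: float = 2.0
    gc_bias: float = 0.5
    codon_weights: dict[str, float] = field(default_factory=dict)


@dataclass
class ScenarioConfig:
    seed: int = 0
    L_codons: int = 300
    n_species_per_order: int = 5
    order_labels: tuple[str, str] = ("Malacalcyonacea", "Scleralcyonacea")
    tree_depth: float = 0.05
    reference_rate_scale: float = 1.0
    reference_omega: float = 0.1
    reference_kappa: float = 2.0
    reference_gc_bias: float = 0.4
    clades: tuple[CladeSpec, ...] = ()

    def validate(self) -> None:
        problems = []
        if len(self.clades) < 2:
            problems.append("clades: need >= 2")
        if self.n_species_per_order < 2:
            problems.append("n_species_per_order: need >= 2 per order")
        if self.tree_depth <= 0:
            problems.append("tree_depth: must be > 0")
        for spec in self.clades:
            if not set(spec.orders) <= set(self.order_labels):
                problems.append(f"clade {spec.label}: unknown order in {spec.orders}")
            eligible = self.n_species_per_order * len(spec.orders)
            if spec.n_genes > eligible:
                problems.append(
                    f"clade {spec.label}: n_genes={spec.n_genes} exceeds "
                    f"{eligible} eligible species"
                )
            if spec.n_genes < 2:
                problems.append(f"clade {spec.label}: n_genes must be >= 2")
        if problems:
            raise ValidationError("; ".join(problems))


def default_scenario(seed: int = 0, L_codons: int = 300) -> ScenarioConfig:
    """A gene-family scenario shaped like the octocoral terpene-cyclase
    family: five conserved-to-fast subclades spanning both orders plus
    three order-restricted clades, over a slow mitochondrial-like
    reference.  Rate scales place the fast clades three- to four-fold
    above the reference; conserved subclades carry low omega."""
    both = ("Malacalcyonacea", "Scleralcyonacea")
    mala = ("Malacalcyonacea",)
    scle = ("Scleralcyonacea",)
    clades = (
        CladeSpec("1-I", 6, both, rate_scale=1.5, omega=0.15),
        CladeSpec("1-II", 6, both, rate_scale=1.0, omega=0.1),
        CladeSpec("1-III", 4, mala, rate_scale=3.5, omega=0.3),
        CladeSpec("1-IV", 6, both, rate_scale=1.0, omega=0.15),
        CladeSpec("1-V", 4, scle, rate_scale=3.0, omega=0.3),
        CladeSpec("2", 4, scle, rate_scale=3.5, omega=0.4),
        CladeSpec("3", 6, both, rate_scale=2.5, omega=0.4),
        CladeSpec("4", 4, mala, rate_scale=3.5, omega=0.4),
    )
    return ScenarioConfig(seed=seed, L_codons=L_codons, clades=clades)


@dataclass
class ScenarioBundle:
    clade_alignments: dict[str, CodonAlignment]
    reference: CodonAlignment
    tree: PhyloTree
    clade_map: CladeMap
    config: ScenarioConfig


def _balanced_newick(labels: list[str], depth: float) -> str:
    """Ultrametric balanced-as-possible subtree over ``labels`` with
    root-to-tip path ``depth``."""
    if len(labels) == 1:
        return f"{labels[0]}:{depth:.8f}"
    mid = (len(labels) + 1) // 2
    left = _balanced_newick(labels[:mid], depth / 2.0)
    right = _balanced_newick(labels[mid:], depth / 2.0)
    return f"({left},{right}):{depth / 2.0:.8f}"


def build_species_tree(config: ScenarioConfig) -> tuple[PhyloTree, dict[str, str]]:
    """Two order-level balanced subtrees joined at the root; returns the
    tree and species -> order map."""
    species_order = {}
    subtrees = []
    for order in config.order_labels:
        labels = [
            f"{order[:4]}_sp{i + 1}" for i in range(config.n_species_per_order)
        ]
        for s in labels:
            species_order[s] = order
        subtrees.append(_balanced_newick(labels, config.tree_depth / 2.0))
    newick = f"({subtrees[0]},{subtrees[1]});"
    return PhyloTree.from_newick(newick), species_order


def _gene_tree(species_tree: PhyloTree, species: list[str], gene_ids: list[str],
               rate_scale: float) -> PhyloTree:
    clone = species_tree.tree.clone(depth=1)
    clone.retain_taxa_with_labels(species)
    for edge in clone.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= rate_scale
    # fresh taxa: clone(depth=1) shares the namespace with the species tree
    rename = dict(zip(species, gene_ids))
    ns = dendropy.TaxonNamespace()
    for leaf in clone.leaf_node_iter():
        leaf.taxon = dendropy.Taxon(label=rename[leaf.taxon.label])
        ns.add_taxon(leaf.taxon)
    clone.taxon_namespace = ns
    return PhyloTree(clone)


def generate_gene_family_scenario(config: ScenarioConfig) -> ScenarioBundle:
    """Simulate a full clade-structured gene family plus reference.

    Each clade gets a gene tree: the species tree restricted to a
    deterministic-but-shuffled draw of its eligible species (alternating
    between orders for two-order clades), branch lengths multiplied by the
    clade's rate scale.  Genes evolve under the clade's codon model; the
    reference evolves on the full species tree under the reference model.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    species_tree, species_order = build_species_tree(config)

    clade_alignments = {}
    all_records = []
    for spec in sorted(config.clades, key=lambda s: s.label):
        pools = []
        for order in spec.orders:
            pool = [s for s, o in species_order.items() if o == order]
            pool = [pool[i] for i in rng.permutation(len(pool))]
            pools.append(pool)
        chosen: list[str] = []
        i = 0
        while len(chosen) < spec.n_genes:
            pool = pools[i % len(pools)]
            if pool:
                chosen.append(pool.pop(0))
            i += 1
        gene_ids = [f"{spec.label}.g{j + 1}" for j in range(len(chosen))]
        gtree = _gene_tree(species_tree, chosen, gene_ids, spec.rate_scale)
        params = SimulationParams(
            seed=config.seed,
            L_codons=config.L_codons,
            omega=spec.omega,
            kappa=spec.kappa,
            gc_bias=spec.gc_bias,
        )
        aln = simulate_codon_evolution(
            gtree, "stationary", params,
            codon_weights=spec.codon_weights, rng=rng,
        )
        recs = []
        by_id = {r.gene_id: r for r in aln}
        for gid, sp in zip(gene_ids, chosen):
            r = by_id[gid]
            recs.append(
                replace(
                    r,
                    species=sp,
                    order_label=species_order[sp],
                    clade_label=spec.label,
                )
            )
        clade_aln = CodonAlignment(tuple(recs), 1)
        clade_alignments[spec.label] = clade_aln
        all_records.extend(recs)

    ref_params = SimulationParams(
        seed=config.seed,
        L_codons=config.L_codons,
        omega=config.reference_omega,
        kappa=config.reference_kappa,
        gc_bias=config.reference_gc_bias,
    )
    ref_aln = simulate_codon_evolution(
        species_tree, "stationary", ref_params,
        rate_scale=config.reference_rate_scale, rng=rng,
    )
    ref_records = []
    for r in ref_aln:
        ref_records.append(
            replace(
                r,
                gene_id=f"mt_{r.gene_id}",
                species=r.gene_id,
                order_label=species_order[r.gene_id],
                clade_label="reference",
            )
        )
    reference = CodonAlignment(tuple(ref_records), 1)

    clade_map = CladeMap(
        clade_of={r.gene_id: r.clade_label for r in all_records},
        order_of={r.gene_id: r.order_label for r in all_records},
    )
    return ScenarioBundle(
        clade_alignments=clade_alignments,
        reference=reference,
        tree=species_tree,
        clade_map=clade_map,
        config=config,
    )


def write_scenario(bundle: ScenarioBundle, outdir) -> dict[str, str]:
    """Write the bundle as FASTA/Newick/TSV files consumable by the
    analysis stages; returns a name -> path map."""
    import os

    from .io import write_codon_alignment, write_table

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for label, aln in bundle.clade_alignments.items():
        safe = label.replace("/", "_")
        p = os.path.join(outdir, f"clade_{safe}.fasta")
        write_codon_alignment(aln, p)
        paths[f"clade_{label}"] = p
    p = os.path.join(outdir, "reference.fasta")
    write_codon_alignment(bundle.reference, p)
    paths["reference"] = p
    p = os.path.join(outdir, "species_tree.nwk")
    bundle.tree.write(p)
    paths["tree"] = p

    rows = []
    for aln in list(bundle.clade_alignments.values()) + [bundle.reference]:
        for r in aln:
            rows.append(
                {
                    "gene_id": r.gene_id,
                    "species": r.species,
                    "order": r.order_label,
                    "clade": r.clade_label,
                }
            )
    p = os.path.join(outdir, "meta.tsv")
    write_table(rows, p, header_comment=f"seed={bundle.config.seed}")
    paths["meta"] = p
    return paths
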