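"""Marginal ancestral sequence reconstruction on a fixed tree.

The model is a time-reversible continuous-time Markov chain on nucleotides
or amino acids, with the rate matrix scaled so that one unit of branch
length equals one expected substitution per site.  Likelihoods come from
Felsenstein's pruning algorithm; marginal posteriors at every internal node
come from the standard two-pass scheme (post-order "inside" partials and a
pre-order "outside" message), which for a reversible model is equivalent to
rerooting the tree at each node in turn.

Branch lengths are taken as given — nothing is optimized.  Gaps and ``N``
(``X`` for amino acids) are missing data: an all-ones partial likelihood.
MAP sequences break posterior ties by alphabet order, deterministically.

JC (nucleotides) and Poisson (amino acids) models ship built in; any
reversible rate matrix can be supplied with :meth:`SubstitutionModel.custom`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CodonAlignment, PhyloTree, ValidationError

NT_ALPHABET = tuple("ACGT")
AA_ALPHABET = tuple("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class SubstitutionModel:
    """A reversible substitution model with unit expected rate."""

    alphabet: tuple[str, ...]
    rate_matrix: np.ndarray
    stationary_freqs: np.ndarray
    name: str = "custom"
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        q = np.asarray(self.rate_matrix, dtype=float)
        pi = np.asarray(self.stationary_freqs, dtype=float)
        k = len(self.alphabet)
        if q.shape != (k, k):
            raise ValidationError("rate matrix shape does not match alphabet")
        if not np.allclose(q.sum(axis=1), 0, atol=1e-8):
            raise ValidationError("rate matrix rows must sum to 0")
        off = q - np.diag(np.diag(q))
        if (off < -1e-12).any():
            raise ValidationError("off-diagonal rates must be >= 0")
        if not np.isclose(pi.sum(), 1, atol=1e-8) or (pi <= 0).any():
            raise ValidationError("stationary frequencies must be positive and sum to 1")
        flux = pi[:, None] * q
        if not np.allclose(flux, flux.T, atol=1e-8):
            raise ValidationError("detailed balance violated (model not reversible)")
        # normalize to one expected substitution per site per unit length
        mu = -float(np.dot(pi, np.diag(q)))
        if mu <= 0:
            raise ValidationError("degenerate rate matrix (zero total rate)")
        self.rate_matrix = q / mu
        self.stationary_freqs = pi

    @property
    def k(self) -> int:
        return len(self.alphabet)

    @classmethod
    def jc(cls) -> "SubstitutionModel":
        """Jukes–Cantor: equal rates among the four nucleotides."""
        k = 4
        q = np.full((k, k), 1.0 / 3.0)
        np.fill_diagonal(q, -1.0)
        return cls(NT_ALPHABET, q, np.full(k, 0.25), name="JC")

    @classmethod
    def poisson(cls) -> "SubstitutionModel":
        """Poisson model: equal rates among the 20 amino acids."""
        k = 20
        q = np.full((k, k), 1.0 / (k - 1))
        np.fill_diagonal(q, -1.0)
        return cls(AA_ALPHABET, q, np.full(k, 1.0 / k), name="Poisson")

    @classmethod
    def custom(cls, alphabet, rate_matrix, stationary_freqs) -> "SubstitutionModel":
        return cls(tuple(alphabet), rate_matrix, stationary_freqs)

    def _eigendecomposition(self):
        # symmetrize: B = diag(sqrt(pi)) Q diag(1/sqrt(pi)) is symmetric for
        # reversible Q; P(t) = D^-1 U exp(L t) U' D with D = diag(sqrt(pi))
        if self._eig is None:
            d = np.sqrt(self.stationary_freqs)
            b = (d[:, None] * self.rate_matrix) / d[None, :]
            w, u = np.linalg.eigh((b + b.T) / 2.0)
            self._eig = (w, u, d)
        return self._eig

    def transition_probability(self, t: float) -> np.ndarray:
        """P(t) = exp(Q t), a row-stochastic matrix."""
        if t < 0:
            raise ValidationError(f"branch length must be >= 0, got {t}")
        w, u, d = self._eigendecomposition()
        p = (u * np.exp(w * t)) @ u.T
        p = p / d[:, None] * d[None, :]
        p = np.clip(p, 0.0, None)
        return p / p.sum(axis=1, keepdims=True)


def transition_probability(model: SubstitutionModel, t: float) -> np.ndarray:
    return model.transition_probability(t)


@dataclass
class AncestralReconstruction:
    """Marginal posteriors and MAP sequences at every internal node."""

    node_posteriors: dict[str, np.ndarray]  # node label -> (n_sites, k)
    map_sequences: dict[str, str]
    total_log_likelihood: float
    alphabet: tuple[str, ...]
    node_order: list[str] = field(default_factory=list)


_MISSING = {"-", "N", "?", "X", "."}


def _encode(seq: str, alphabet: tuple[str, ...]) -> np.ndarray:
    """(L, k) tip partial-likelihood matrix; missing symbols -> all ones."""
    k = len(alphabet)
    index = {s: i for i, s in enumerate(alphabet)}
    out = np.zeros((len(seq), k))
    for j, sym in enumerate(seq):
        if sym in index:
            out[j, index[sym]] = 1.0
        elif sym in _MISSING:
            out[j, :] = 1.0
        else:
            raise ValidationError(f"symbol {sym!r} not in model alphabet")
    return out


def _as_sequence_dict(alignment) -> dict[str, str]:
    if isinstance(alignment, CodonAlignment):
        return {r.gene_id: r.sequence for r in alignment}
    if isinstance(alignment, dict):
        return dict(alignment)
    return {gid: seq for gid, seq in alignment}


def _label_nodes(tree: PhyloTree) -> dict:
    """Deterministic labels: tips keep taxon labels; unlabeled internal
    nodes get node1, node2, ... in preorder."""
    labels = {}
    counter = 0
    for node in tree.tree.preorder_node_iter():
        if node.is_leaf():
            labels[node] = node.taxon.label
        elif node.label:
            labels[node] = node.label
        else:
            counter += 1
            labels[node] = f"node{counter}"
    return labels


def _prepare(tree: PhyloTree, seqs: dict[str, str], model: SubstitutionModel):
    tips = set(tree.tip_labels)
    have = set(seqs)
    if tips - have:
        raise ValidationError(f"tips without sequences: {sorted(tips - have)}")
    if have - tips:
        raise ValidationError(f"sequences without tips: {sorted(have - tips)}")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValidationError("sequences differ in length")
    for node in tree.tree.preorder_node_iter():
        if node is tree.tree.seed_node:
            continue
        if node.edge.length is None:
            raise ValidationError("missing branch length on an edge")
    return lengths.pop()


def _inside_pass(tree, labels, tip_partials, model):
    """Post-order partials with per-site log scaling.

    Returns (partials, logscale): for each node, an (L, k) array and an
    (L,) log-scale vector such that the true partial is
    partials * exp(logscale).
    """
    partials, logscale = {}, {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            partials[node] = tip_partials[labels[node]]
            logscale[node] = np.zeros(partials[node].shape[0])
            continue
        prod = None
        scale = None
        for child in node.child_nodes():
            p = model.transition_probability(child.edge.length)
            msg = partials[child] @ p.T
            prod = msg if prod is None else prod * msg
            scale = (
                logscale[child]
                if scale is None
                else scale + logscale[child]
            )
        m = prod.max(axis=1)
        m = np.where(m > 0, m, 1.0)
        partials[node] = prod / m[:, None]
        logscale[node] = scale + np.log(m)
    return partials, logscale


def site_log_likelihood(tree: PhyloTree, model: SubstitutionModel, site_pattern: dict) -> float:
    """Pruning log-likelihood of a single site pattern (tip -> symbol)."""
    seqs = {tip: sym for tip, sym in site_pattern.items()}
    _prepare(tree, seqs, model)
    labels = _label_nodes(tree)
    tip_partials = {t: _encode(s, model.alphabet) for t, s in seqs.items()}
    partials, logscale = _inside_pass(tree, labels, tip_partials, model)
    root = tree.tree.seed_node
    lik = partials[root] @ model.stationary_freqs
    return float(np.log(lik[0]) + logscale[root][0])


def marginal_asr(
    tree: PhyloTree, alignment, model: SubstitutionModel
) -> AncestralReconstruction:
    """Marginal ML reconstruction at every internal node of ``tree``.

    ``alignment`` may be a :class:`CodonAlignment` (sites = nucleotide
    columns), a dict of id -> sequence, or (id, sequence) pairs.  Returns
    per-node per-site posterior vectors, MAP sequences, and the total
    log-likelihood (identical at every valid rooting of a reversible
    model).
    """
    seqs = _as_sequence_dict(alignment)
    _prepare(tree, seqs, model)
    labels = _label_nodes(tree)
    tip_partials = {t: _encode(s, model.alphabet) for t, s in seqs.items()}
    partials, logscale = _inside_pass(tree, labels, tip_partials, model)

    root = tree.tree.seed_node
    pi = model.stationary_freqs
    root_lik = partials[root] @ pi
    total_ll = float(np.sum(np.log(root_lik) + logscale[root]))

    # outside pass: above[v][x] carries P(data outside v's subtree, state
    # at v = x), scaled per site; posterior(v) ∝ inside(v) * above(v)
    above = {root: np.broadcast_to(pi, partials[root].shape).copy()}
    for node in tree.tree.preorder_node_iter():
        if node.is_leaf():
            continue
        children = node.child_nodes()
        msgs = []
        for child in children:
            p = model.transition_probability(child.edge.length)
            msgs.append(partials[child] @ p.T)
        for i, child in enumerate(children):
            sib = above[node].copy()
            for j, msg in enumerate(msgs):
                if j != i:
                    sib = sib * msg
            p = model.transition_probability(child.edge.length)
            a = sib @ p
            m = a.max(axis=1)
            m = np.where(m > 0, m, 1.0)
            above[child] = a / m[:, None]

    node_posteriors: dict[str, np.ndarray] = {}
    map_sequences: dict[str, str] = {}
    node_order: list[str] = []
    symbols = np.array(model.alphabet)
    for node in tree.tree.preorder_node_iter():
        if node.is_leaf():
            continue
        post = partials[node] * above[node]
        post = post / post.sum(axis=1, keepdims=True)
        label = labels[node]
        node_order.append(label)
        node_posteriors[label] = post
        map_sequences[label] = "".join(symbols[np.argmax(post, axis=1)])
    return AncestralReconstruction(
        node_posteriors=node_posteriors,
        map_sequences=map_sequences,
        total_log_likelihood=total_ll,
        alphabet=model.alphabet,
        node_order=node_order,
    )
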