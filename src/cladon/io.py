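"""Shared data model and readers/writers for the formats the pipeline touches.

Sequences travel as FASTA (Biopython), trees as Newick (DendroPy), gene
metadata as TSV.  Per-gene metadata may ride in FASTA headers as
``>gene_id key=value ...`` (keys: species, order, clade) and/or in a sidecar
TSV with columns gene_id/species/order/clade; the sidecar wins on conflict.

Ingest normalizes sequences to uppercase DNA (U→T).  The gap character is
``-`` only; ``N`` is permitted.  Codons containing ``-`` or ``N`` are left in
place and excluded codon-wise by the downstream statistics.  A terminal stop
codon is masked to ``---`` with a logged warning; an internal in-frame stop
is an error.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import dendropy
from Bio import SeqIO

from .codes import GAP, get_code

log = logging.getLogger(__name__)

_ALLOWED = set("ACGTN-")


class ValidationError(ValueError):
    """A dataset violates a structural contract."""


class FrameError(ValidationError):
    """A coding sequence is not a clean in-frame CDS."""


# ---------------------------------------------------------------------------
# sequences


@dataclass(frozen=True)
class GeneRecord:
    """One aligned in-frame coding sequence with its identity labels."""

    gene_id: str
    sequence: str
    species: str = ""
    order_label: str = ""
    clade_label: str = ""

    def __post_init__(self):
        seq = self.sequence.upper().replace("U", "T")
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - _ALLOWED
        if bad:
            raise ValidationError(
                f"record {self.gene_id!r}: disallowed characters {sorted(bad)!r}"
            )
        if len(seq) % 3 != 0:
            raise FrameError(
                f"record {self.gene_id!r}: length {len(seq)} not divisible by 3"
            )

    def codons(self) -> list[str]:
        s = self.sequence
        return [s[i : i + 3] for i in range(0, len(s), 3)]


@dataclass(frozen=True)
class CodonAlignment:
    """An in-frame codon alignment over a set of gene records."""

    records: tuple[GeneRecord, ...]
    genetic_code_id: int = 1

    def __post_init__(self):
        if not self.records:
            raise ValidationError("alignment has no records")
        object.__setattr__(self, "records", tuple(self.records))
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) != 1:
            raise ValidationError(f"records differ in length: {sorted(lengths)}")
        ids = [r.gene_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate gene ids: {dupes}")
        code = get_code(self.genetic_code_id)
        n_codons = self.length // 3
        for r in self.records:
            for i, codon in enumerate(r.codons()):
                if code.is_stop(codon) and i < n_codons - 1:
                    raise FrameError(
                        f"record {r.gene_id!r}: internal stop codon {codon} "
                        f"at codon {i + 1}"
                    )

    @property
    def length(self) -> int:
        return len(self.records[0].sequence)

    @property
    def n_codons(self) -> int:
        return self.length // 3

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, gene_id: str) -> GeneRecord:
        for r in self.records:
            if r.gene_id == gene_id:
                return r
        raise KeyError(gene_id)

    def ids(self) -> list[str]:
        return [r.gene_id for r in self.records]

    def subset(self, gene_ids) -> "CodonAlignment":
        wanted = list(gene_ids)
        missing = set(wanted) - set(self.ids())
        if missing:
            raise ValidationError(f"unknown gene ids: {sorted(missing)}")
        keep = [r for r in self.records if r.gene_id in set(wanted)]
        return CodonAlignment(tuple(keep), self.genetic_code_id)


def _parse_header(description: str) -> tuple[str, dict[str, str]]:
    parts = description.split()
    gene_id = parts[0]
    meta = {}
    for tok in parts[1:]:
        if "=" in tok:
            k, v = tok.split("=", 1)
            meta[k.lower()] = v
    return gene_id, meta


def read_metadata_tsv(path) -> dict[str, dict[str, str]]:
    """Read a gene metadata sidecar (gene_id, species, order, clade)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    if "gene_id" not in df.columns:
        raise ValidationError(f"{path}: metadata TSV needs a gene_id column")
    out = {}
    for _, row in df.iterrows():
        out[row["gene_id"]] = {
            k: row[k] for k in ("species", "order", "clade") if k in df.columns
        }
    return out


def read_codon_alignment(path, code_id: int = 1, metadata=None) -> CodonAlignment:
    """Read an aligned in-frame FASTA into a validated :class:`CodonAlignment`.

    ``metadata`` may be a path to a sidecar TSV or a pre-parsed dict as
    returned by :func:`read_metadata_tsv`; sidecar values override header
    ``key=value`` tokens.  Terminal stop codons are masked to gaps with a
    warning so that downstream codon statistics skip them.
    """
    if metadata is not None and not isinstance(metadata, dict):
        metadata = read_metadata_tsv(metadata)
    metadata = metadata or {}
    code = get_code(code_id)

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id, meta = _parse_header(rec.description)
        meta.update({k: v for k, v in metadata.get(gene_id, {}).items() if v})
        seq = str(rec.seq).upper().replace("U", "T")
        if len(seq) % 3 != 0:
            raise FrameError(
                f"record {gene_id!r}: length {len(seq)} not divisible by 3"
            )
        last = seq[-3:]
        if code.is_stop(last):
            log.warning("record %r: terminal stop codon %s masked", gene_id, last)
            seq = seq[:-3] + GAP * 3
        records.append(
            GeneRecord(
                gene_id=gene_id,
                sequence=seq,
                species=meta.get("species", ""),
                order_label=meta.get("order", ""),
                clade_label=meta.get("clade", ""),
            )
        )
    if not records:
        raise ValidationError(f"{path}: no FASTA records found")
    return CodonAlignment(tuple(records), code_id)


def write_codon_alignment(alignment: CodonAlignment, path) -> None:
    with open(path, "w") as fh:
        for r in alignment:
            meta = []
            if r.species:
                meta.append(f"species={r.species}")
            if r.order_label:
                meta.append(f"order={r.order_label}")
            if r.clade_label:
                meta.append(f"clade={r.clade_label}")
            header = " ".join([r.gene_id] + meta)
            fh.write(f">{header}\n{r.sequence}\n")


# ---------------------------------------------------------------------------
# trees


class PhyloTree:
    """A phylogeny with branch lengths, thin wrapper over a DendroPy tree.

    The tree is treated as rooted when its seed node is a bifurcation and
    as unrooted (degree-3 root) otherwise.  Absent branch lengths stay
    ``None`` — they are "missing", never coerced to zero.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            dupes = sorted({t for t in labels if labels.count(t) > 1})
            raise ValidationError(f"duplicate tip labels: {dupes}")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValidationError(f"negative branch length: {edge.length}")

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            t = dendropy.Tree.get(
                data=text, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise ValidationError(f"Newick parse error: {exc}") from exc
        return cls(t)

    @classmethod
    def from_file(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    @property
    def tip_labels(self) -> list[str]:
        return [
            leaf.taxon.label for leaf in self.tree.leaf_node_iter() if leaf.taxon
        ]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def is_rooted(self) -> bool:
        return len(self.tree.seed_node.child_nodes()) == 2

    def clone(self) -> "PhyloTree":
        return PhyloTree(self.tree.clone(depth=1))

    def branch_lengths(self) -> list[float | None]:
        return [
            e.length
            for e in self.tree.preorder_edge_iter()
            if e.head_node is not self.tree.seed_node
        ]


def read_newick(path) -> PhyloTree:
    return PhyloTree.from_file(path)


# ---------------------------------------------------------------------------
# clade / order assignment


@dataclass
class CladeMap:
    """gene_id → clade label and gene_id → taxonomic order label."""

    clade_of: dict[str, str] = field(default_factory=dict)
    order_of: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path) -> "CladeMap":
        meta = read_metadata_tsv(path)
        return cls(
            clade_of={g: m.get("clade", "") for g, m in meta.items()},
            order_of={g: m.get("order", "") for g, m in meta.items()},
        )

    @classmethod
    def from_alignment(cls, alignment: CodonAlignment) -> "CladeMap":
        return cls(
            clade_of={r.gene_id: r.clade_label for r in alignment},
            order_of={r.gene_id: r.order_label for r in alignment},
        )

    def validate_against(self, alignment: CodonAlignment) -> None:
        known = set(alignment.ids())
        unknown = (set(self.clade_of) | set(self.order_of)) - known
        if unknown:
            raise ValidationError(
                f"clade map refers to unknown gene ids: {sorted(unknown)}"
            )

    def merge(self, other: "CladeMap") -> "CladeMap":
        clade = dict(self.clade_of)
        clade.update({k: v for k, v in other.clade_of.items() if v})
        order = dict(self.order_of)
        order.update({k: v for k, v in other.order_of.items() if v})
        return CladeMap(clade, order)


def annotate(alignment: CodonAlignment, clades: CladeMap) -> CodonAlignment:
    """Return a copy of ``alignment`` with clade/order labels filled in."""
    recs = []
    for r in alignment:
        recs.append(
            replace(
                r,
                clade_label=clades.clade_of.get(r.gene_id, r.clade_label),
                order_label=clades.order_of.get(r.gene_id, r.order_label),
            )
        )
    return CodonAlignment(tuple(recs), alignment.genetic_code_id)


# ---------------------------------------------------------------------------
# tables


def _format_cell(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        if math.isnan(value):
            return "NA"
        return repr(value)
    text = str(value)
    if "\t" in text or "\n" in text:
        raise ValidationError(f"tab/newline in table value: {text!r}")
    return text


def write_table(rows, path, header_comment: str | None = None, keys=None) -> None:
    """Write keyed records as a TSV with an ``NA`` missing-value convention.

    All rows must share one key set (order taken from the first row, or from
    ``keys`` for an empty row list).  No quoting dialect is offered: a value
    containing a tab or newline is an error.  ``header_comment`` lines
    (without leading ``#``) are emitted as ``#``-prefixed lines before the
    header.
    """
    rows = list(rows)
    if rows:
        keys = list(rows[0].keys()) if keys is None else list(keys)
        for row in rows:
            if list(row.keys()) != keys:
                raise ValidationError(
                    f"heterogeneous row keys: {list(row.keys())} vs {keys}"
                )
    else:
        keys = list(keys) if keys is not None else []
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("\t".join(keys) + "\n")
        for row in rows:
            fh.write("\t".join(_format_cell(row[k]) for k in keys) + "\n")
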