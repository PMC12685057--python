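"""Genetic-code tables shared by all statistics.

Everything here is derived programmatically from Biopython's codon tables
(standard code, NCBI table 1, by default).  The derived structures are:

* the 61 sense codons and their amino acids,
* amino-acid synonym families and their degeneracy classes (the partition
  Wright's Nc averages over: nine 2-fold, one 3-fold, five 4-fold and three
  6-fold families, with Met and Trp excluded),
* the fourfold-degenerate codon blocks whose third positions carry the
  PR2 (parity rule 2) signal.

Only the standard code is exercised by the shipped tests; other NCBI table
ids are accepted and the same derivations are applied to them.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
GAP = "-"

#: purine/pyrimidine classes; a substitution within a class is a transition
_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change ``a``→``b`` is a transition."""
    if a == b:
        raise ValueError("not a change: %r -> %r" % (a, b))
    return (a in _PURINES and b in _PURINES) or (
        a in _PYRIMIDINES and b in _PYRIMIDINES
    )


class GeneticCode:
    """Sense/stop codon structure of one NCBI translation table."""

    def __init__(self, code_id: int = 1):
        try:
            table = CodonTable.unambiguous_dna_by_id[code_id]
        except KeyError as exc:
            raise ValueError(f"unknown NCBI codon table id: {code_id}") from exc
        self.code_id = code_id
        self.stop_codons = frozenset(c.replace("U", "T") for c in table.stop_codons)
        self.codon_to_aa = {
            codon.replace("U", "T"): aa for codon, aa in table.forward_table.items()
        }
        self.sense_codons = tuple(sorted(self.codon_to_aa))
        self.codon_index = {c: i for i, c in enumerate(self.sense_codons)}

        # amino acid -> sorted tuple of synonymous codons
        fam: dict[str, list[str]] = {}
        for codon, aa in self.codon_to_aa.items():
            fam.setdefault(aa, []).append(codon)
        self.families = {aa: tuple(sorted(cs)) for aa, cs in fam.items()}
        self.family_size = {aa: len(cs) for aa, cs in self.families.items()}

        # fourfold-degenerate blocks: a leading dinucleotide whose four
        # completions are all sense and all synonymous
        ff = []
        for codon in self.sense_codons:
            prefix = codon[:2]
            block = [prefix + nt for nt in NUCLEOTIDES]
            if all(b in self.codon_to_aa for b in block) and (
                len({self.codon_to_aa[b] for b in block}) == 1
            ):
                ff.append(codon)
        self.fourfold_codons = frozenset(ff)

    def is_sense(self, codon: str) -> bool:
        return codon in self.codon_to_aa

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def translate(self, codon: str) -> str:
        return self.codon_to_aa[codon]

    @property
    def single_codon_aas(self) -> frozenset[str]:
        """Amino acids with one codon (Met/Trp in the standard code)."""
        return frozenset(aa for aa, k in self.family_size.items() if k == 1)

    @property
    def nondegenerate_codons(self) -> frozenset[str]:
        """Codons with no synonym (ATG/TGG in the standard code)."""
        return frozenset(
            c for aa in self.single_codon_aas for c in self.families[aa]
        )

    def degeneracy_classes(self) -> dict[int, tuple[str, ...]]:
        """Map family size k (>=2) -> amino acids in that degeneracy class."""
        out: dict[int, list[str]] = {}
        for aa, k in self.family_size.items():
            if k >= 2:
                out.setdefault(k, []).append(aa)
        return {k: tuple(sorted(v)) for k, v in out.items()}


@lru_cache(maxsize=None)
def get_code(code_id: int = 1) -> GeneticCode:
    return GeneticCode(code_id)


#: the standard code, used throughout unless a caller asks otherwise
STANDARD = get_code(1)
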