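"""Per-gene codon-usage statistics.

The statistics here summarize synonymous-site composition of one coding
sequence at a time:

* raw sense-codon counts (gap/``N``/stop codons excluded codon-wise),
* RSCU — observed codon count over its uniform-usage expectation within the
  synonym family, so a family of size k sums to k,
* Wright's effective number of codons Nc (20 = one codon per amino acid,
  61 = perfectly even usage) and the neutral Nc-vs-GC3s expectation curve,
* GC and GC3s content (GC3s over synonymous third positions only, i.e.
  excluding ATG and TGG in the standard code),
* PR2 asymmetries A3/(A3+T3) and G3/(G3+C3) over third positions of
  fourfold-degenerate codon blocks, which sit at 0.5 under strand- and
  mutation-symmetric synonymous evolution.

All functions return ``None`` for statistics that are undefined on the
given input (empty synonym families, no fourfold codons, ...), never 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .codes import GeneticCode, get_code
from .io import GeneRecord


@dataclass
class CodonCounts:
    """Sense-codon counts for one gene."""

    counts: dict[str, int]
    n_codons_typed: int
    n_codons_excluded: int
    code_id: int = 1

    def __post_init__(self):
        assert sum(self.counts.values()) == self.n_codons_typed


@dataclass
class CodonUsageProfile:
    gene_id: str
    gc: float | None
    gc3s: float | None
    nc: float | None
    pr2_at: float | None
    pr2_gc: float | None
    rscu: dict[str, float | None] = field(default_factory=dict)


def count_codons(record: GeneRecord, code_id: int = 1) -> CodonCounts:
    """Count sense codons; gap/N-containing and stop codons are excluded."""
    code = get_code(code_id)
    counts = {c: 0 for c in code.sense_codons}
    typed = excluded = 0
    for codon in record.codons():
        if code.is_sense(codon):
            counts[codon] += 1
            typed += 1
        else:
            excluded += 1
    return CodonCounts(counts, typed, excluded, code_id)


def rscu(counts: CodonCounts) -> dict[str, float | None]:
    """Relative synonymous codon usage per sense codon.

    RSCU_c = x_c * k / sum(family), for families with any usage; families
    with zero usage map to ``None``.  Single-codon amino acids (Met, Trp)
    report RSCU 1.0 when observed — they carry no synonymous signal and
    are excluded from screens downstream.
    """
    code = get_code(counts.code_id)
    out: dict[str, float | None] = {}
    for aa, codons in code.families.items():
        total = sum(counts.counts[c] for c in codons)
        k = len(codons)
        for c in codons:
            out[c] = counts.counts[c] * k / total if total > 0 else None
    return out


def effective_number_of_codons(counts: CodonCounts) -> float | None:
    """Wright's Nc from family-wise codon homozygosities.

    For each synonym family with n >= 2 observations, the homozygosity is
    F = (n * sum(p_j^2) - 1) / (n - 1).  F is averaged within degeneracy
    classes; the standard code gives Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6.
    A missing 3-fold mean (Ile unobserved) is imputed as (F2 + F4) / 2;
    any other missing or non-positive class mean yields ``None``.  The
    result is clamped to [20, 61].
    """
    code = get_code(counts.code_id)
    class_F: dict[int, list[float]] = {}
    for aa, codons in code.families.items():
        k = len(codons)
        if k < 2:
            continue
        xs = [counts.counts[c] for c in codons]
        n = sum(xs)
        if n < 2:
            continue
        sum_p2 = sum((x / n) ** 2 for x in xs)
        f = (n * sum_p2 - 1) / (n - 1)
        class_F.setdefault(k, []).append(f)

    classes = code.degeneracy_classes()
    mean_F: dict[int, float | None] = {}
    for k in classes:
        fs = class_F.get(k)
        mean_F[k] = sum(fs) / len(fs) if fs else None

    # standard-code special case: the lone 3-fold family (Ile) may be absent
    # or degenerate (F = 0 from a 1:1 split of two observations); its class
    # mean rests on a single family, so impute it from the flanking classes
    if 3 in classes and (mean_F.get(3) is None or mean_F[3] <= 0):
        f2, f4 = mean_F.get(2), mean_F.get(4)
        if f2 is not None and f4 is not None:
            mean_F[3] = (f2 + f4) / 2

    nc = float(len(code.single_codon_aas))
    for k, aas in classes.items():
        fbar = mean_F.get(k)
        if fbar is None or fbar <= 0:
            return None
        nc += len(aas) / fbar
    return min(max(nc, 20.0), 61.0)


def wright_expected_nc(gc3s: float) -> float:
    """Neutral-expectation Nc at synonymous third-position GC content s:
    Nc(s) = 2 + s + 29 / (s^2 + (1-s)^2)."""
    if not 0.0 <= gc3s <= 1.0:
        raise ValueError(f"gc3s must be in [0, 1], got {gc3s}")
    return 2.0 + gc3s + 29.0 / (gc3s**2 + (1.0 - gc3s) ** 2)


def gc_contents(
    record: GeneRecord, code_id: int = 1
) -> tuple[float | None, float | None]:
    """(gc, gc3s): overall GC over typed bases, and GC at synonymous third
    positions of typed sense codons (ATG/TGG excluded)."""
    code = get_code(code_id)
    typed = [b for b in record.sequence if b in "ACGT"]
    gc = sum(b in "GC" for b in typed) / len(typed) if typed else None

    thirds = [
        codon[2]
        for codon in record.codons()
        if code.is_sense(codon) and codon not in code.nondegenerate_codons
    ]
    gc3s = sum(b in "GC" for b in thirds) / len(thirds) if thirds else None
    return gc, gc3s


def pr2_bias(
    record: GeneRecord, code_id: int = 1
) -> tuple[float | None, float | None]:
    """Parity-rule-2 asymmetries on fourfold-degenerate third positions.

    Returns (A3/(A3+T3), G3/(G3+C3)); each is ``None`` when its denominator
    is zero.  Restricting to fourfold blocks removes amino-acid-level
    constraint from the signal (Sueoka's convention).
    """
    code = get_code(code_id)
    a3 = t3 = g3 = c3 = 0
    for codon in record.codons():
        if codon in code.fourfold_codons:
            b = codon[2]
            a3 += b == "A"
            t3 += b == "T"
            g3 += b == "G"
            c3 += b == "C"
    pr2_at = a3 / (a3 + t3) if (a3 + t3) > 0 else None
    pr2_gc = g3 / (g3 + c3) if (g3 + c3) > 0 else None
    return pr2_at, pr2_gc


def profile(record: GeneRecord, code_id: int = 1) -> CodonUsageProfile:
    """Full codon-usage profile for one gene."""
    counts = count_codons(record, code_id)
    gc, gc3s = gc_contents(record, code_id)
    at, gcb = pr2_bias(record, code_id)
    return CodonUsageProfile(
        gene_id=record.gene_id,
        gc=gc,
        gc3s=gc3s,
        nc=effective_number_of_codons(counts),
        pr2_at=at,
        pr2_gc=gcb,
        rscu=rscu(counts),
    )


def usage_table(alignment, code_id: int | None = None) -> list[dict]:
    """One row per gene: gc, gc3s, nc, pr2_at, pr2_gc plus one RSCU column
    per synonymous sense codon (ATG/TGG carry no signal and are omitted)."""
    code_id = alignment.genetic_code_id if code_id is None else code_id
    code = get_code(code_id)
    screen_codons = [
        c for c in code.sense_codons if c not in code.nondegenerate_codons
    ]
    rows = []
    for rec in alignment:
        p = profile(rec, code_id)
        row = {
            "gene_id": p.gene_id,
            "species": rec.species,
            "order": rec.order_label,
            "clade": rec.clade_label,
            "gc": p.gc,
            "gc3s": p.gc3s,
            "nc": p.nc,
            "pr2_at": p.pr2_at,
            "pr2_gc": p.pr2_gc,
        }
        for c in screen_codons:
            row[f"rscu_{c}"] = p.rscu[c]
        rows.append(row)
    return rows
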