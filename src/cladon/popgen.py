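"""Population-genetic and selection statistics.

Within-group diversity follows the classical summaries: segregating sites
S, nucleotide diversity pi (mean pairwise differences, per locus and per
site), Watterson's theta S/a1, and Tajima's (1989) D.  Sites with a gap or
``N`` in any member of the group are excluded before anything is counted
(complete deletion).

Between-sequence selection pressure uses the Nei–Gojobori (1986) counting
estimator: per-codon synonymous/nonsynonymous site fractions, pathway-
averaged synonymous/nonsynonymous differences, Jukes–Cantor correction of
the proportions, and omega = dN/dS.  Codon pairs are dropped pairwise when
either codon is untyped.  By default, mutational pathways passing through a
stop codon are excluded from the averaging; pairs whose every pathway hits
a stop are excluded from the totals and counted.  Setting
``include_stop_paths=True`` restores the equal-weight variant in which stop
steps are classified like any other amino-acid change.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .codes import NUCLEOTIDES, get_code
from .io import CladeMap, CodonAlignment, GeneRecord, ValidationError


@dataclass
class PopGenSummary:
    group_id: str
    n: int
    L: int
    S: int
    pi_total: float
    pi_site: float
    theta_w: float
    tajima_d: float | None
    tajima_d_reason: str = ""


@dataclass
class NG86Result:
    gene_pair: tuple[str, str]
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    pS: float | None
    pN: float | None
    dS: float | None
    dN: float | None
    omega: float | None
    n_codons_compared: int
    n_codons_excluded: int
    reason: str = ""


# ---------------------------------------------------------------------------
# diversity


def _typed_columns(seqs: list[str]) -> np.ndarray:
    """Character matrix restricted to columns typed (ACGT) in every row."""
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(
        len(seqs), -1
    )
    typed = np.isin(arr, np.frombuffer(b"ACGT", dtype="S1"))
    return arr[:, typed.all(axis=0)]


def segregating_sites_and_pi(group, group_id: str = "") -> PopGenSummary:
    """S, pi and Watterson's theta for one group of aligned sequences.

    ``group`` is a :class:`CodonAlignment` (or any iterable of records).
    Complete deletion: only columns typed in every sequence are compared.
    ``tajima_d`` is filled in here when computable (n >= 4, S >= 1).
    """
    records = list(group)
    n = len(records)
    if n < 2:
        raise ValidationError("need at least 2 sequences for diversity")
    arr = _typed_columns([r.sequence for r in records])
    L = arr.shape[1]
    if L == 0:
        raise ValidationError("no compared sites left after complete deletion")

    S = int((arr != arr[0]).any(axis=0).sum())
    diffs = [
        int((arr[i] != arr[j]).sum())
        for i, j in itertools.combinations(range(n), 2)
    ]
    pi_total = float(np.mean(diffs))
    a1 = sum(1.0 / i for i in range(1, n))
    d, reason = tajimas_d(n, S, pi_total)
    return PopGenSummary(
        group_id=group_id,
        n=n,
        L=L,
        S=S,
        pi_total=pi_total,
        pi_site=pi_total / L,
        theta_w=S / a1,
        tajima_d=d,
        tajima_d_reason=reason,
    )


def tajimas_d(n: int, S: int, pi_total: float) -> tuple[float | None, str]:
    """Tajima's (1989) D from (n, S, pi_total).

    Returns (D, reason): D is ``None`` with a reason code when undefined —
    ``"S=0"`` for monomorphic samples and ``"n<4"`` for samples too small
    for the variance constants to be stable.
    """
    if n < 4:
        return None, "n<4"
    if S == 0:
        return None, "S=0"
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return (pi_total - S / a1) / math.sqrt(var), ""


def group_popgen(
    alignment: CodonAlignment, clades: CladeMap, grouping: str = "clade"
) -> list[PopGenSummary]:
    """One :class:`PopGenSummary` per group of genes.

    ``grouping`` is ``"clade"``, ``"order"`` or ``"clade×order"`` (also
    accepted spelled ``"clade_x_order"``).  Groups with fewer than 2 members
    are skipped; n < 4 groups carry a missing Tajima's D.
    """
    annotated = []
    for r in alignment:
        clade = clades.clade_of.get(r.gene_id, r.clade_label)
        order = clades.order_of.get(r.gene_id, r.order_label)
        if grouping == "clade":
            key = clade
        elif grouping == "order":
            key = order
        elif grouping in ("clade×order", "clade_x_order", "cladexorder"):
            key = f"{clade}×{order}"
        else:
            raise ValidationError(f"unknown grouping: {grouping!r}")
        annotated.append((key, r))

    groups: dict[str, list[GeneRecord]] = {}
    for key, r in annotated:
        groups.setdefault(key, []).append(r)
    usable = {k: v for k, v in groups.items() if len(v) >= 2 and k != ""}
    if not usable:
        raise ValidationError("no group has >= 2 members")
    return [
        segregating_sites_and_pi(members, group_id=key)
        for key, members in sorted(usable.items())
    ]


# ---------------------------------------------------------------------------
# Nei–Gojobori 1986


@lru_cache(maxsize=None)
def ng86_site_counts(codon: str, code_id: int = 1) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    Each position contributes the fraction of its 3 single-nucleotide
    changes that are synonymous; changes to a stop codon count in the
    denominator but never as synonymous.  s + n = 3 by construction.
    """
    code = get_code(code_id)
    if not code.is_sense(codon):
        raise ValidationError(f"not a sense codon: {codon!r}")
    aa = code.translate(codon)
    s = 0.0
    for pos in range(3):
        syn = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1 :]
            if code.is_sense(mutant) and code.translate(mutant) == aa:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


@lru_cache(maxsize=None)
def ng86_pathway_diffs(
    codon_a: str, codon_b: str, code_id: int = 1, include_stop_paths: bool = False
) -> tuple[float, float, bool]:
    """Pathway-averaged (Sd, Nd, excluded) between two sense codons.

    Multi-step differences are averaged over all orderings of the changes.
    With the default stop-excluding variant, orderings whose intermediate
    codons include a stop are dropped; if none survive, the pair is flagged
    ``excluded=True`` (Sd = Nd = 0).  With ``include_stop_paths=True`` every
    ordering counts and a step into/out of a stop codon is nonsynonymous.
    """
    code = get_code(code_id)
    for c in (codon_a, codon_b):
        if not code.is_sense(c):
            raise ValidationError(f"not a sense codon: {c!r}")
    positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not positions:
        return 0.0, 0.0, False

    def classify(x: str, y: str) -> tuple[float, float]:
        # one step x -> y, both sense
        return (1.0, 0.0) if code.translate(x) == code.translate(y) else (0.0, 1.0)

    paths = []
    for order in itertools.permutations(positions):
        cur = codon_a
        sd = nd = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            cur_stop = code.is_stop(cur)
            nxt_stop = code.is_stop(nxt)
            if nxt_stop or cur_stop:
                if not include_stop_paths:
                    ok = False
                    break
                nd += 1.0  # stop-involving step treated as nonsynonymous
            else:
                ds, dn = classify(cur, nxt)
                sd += ds
                nd += dn
            cur = nxt
        if ok:
            paths.append((sd, nd))
    if not paths:
        return 0.0, 0.0, True
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd, False


def jukes_cantor(p: float) -> float | None:
    """JC69 distance -(3/4) ln(1 - 4p/3); ``None`` once saturated (p >= 3/4)."""
    if p < 0:
        raise ValueError("proportion must be nonnegative")
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        return None
    return -0.75 * math.log(arg)


def ng86_pair(
    a: GeneRecord, b: GeneRecord, code_id: int = 1, include_stop_paths: bool = False
) -> NG86Result:
    """Nei–Gojobori dN/dS between two aligned in-frame sequences."""
    if len(a.sequence) != len(b.sequence):
        raise ValidationError("sequences differ in length")
    code = get_code(code_id)
    S_sites = N_sites = Sd = Nd = 0.0
    compared = excluded = 0
    for ca, cb in zip(a.codons(), b.codons()):
        if not (code.is_sense(ca) and code.is_sense(cb)):
            excluded += 1
            continue
        sd, nd, skip = ng86_pathway_diffs(ca, cb, code_id, include_stop_paths)
        if skip:
            excluded += 1
            continue
        sa, na = ng86_site_counts(ca, code_id)
        sb, nb = ng86_site_counts(cb, code_id)
        S_sites += (sa + sb) / 2.0
        N_sites += (na + nb) / 2.0
        Sd += sd
        Nd += nd
        compared += 1
    if compared == 0:
        raise ValidationError(
            f"no comparable codons between {a.gene_id!r} and {b.gene_id!r}"
        )
    pS = Sd / S_sites if S_sites > 0 else None
    pN = Nd / N_sites if N_sites > 0 else None
    dS = jukes_cantor(pS) if pS is not None else None
    dN = jukes_cantor(pN) if pN is not None else None
    reason = ""
    if pS is not None and dS is None:
        reason = "pS>=3/4"
    if pN is not None and dN is None:
        reason = (reason + ";" if reason else "") + "pN>=3/4"
    omega = None
    if dS is not None and dN is not None and dS > 0:
        omega = dN / dS
    elif dS == 0 or dS is None:
        reason = (reason + ";" if reason else "") + "dS undefined or 0"
    return NG86Result(
        gene_pair=(a.gene_id, b.gene_id),
        S_sites=S_sites,
        N_sites=N_sites,
        Sd=Sd,
        Nd=Nd,
        pS=pS,
        pN=pN,
        dS=dS,
        dN=dN,
        omega=omega,
        n_codons_compared=compared,
        n_codons_excluded=excluded,
        reason=reason,
    )


def pairwise_ng86(
    alignment: CodonAlignment,
    clades: CladeMap | None = None,
    pairs: str = "all",
    include_stop_paths: bool = False,
) -> list[NG86Result]:
    """NG86 over gene pairs: all pairs, or within-clade pairs only."""
    records = list(alignment)
    out = []
    for a, b in itertools.combinations(records, 2):
        if pairs == "within-clade":
            ca = clades.clade_of.get(a.gene_id, a.clade_label) if clades else a.clade_label
            cb = clades.clade_of.get(b.gene_id, b.clade_label) if clades else b.clade_label
            if ca != cb or ca == "":
                continue
        out.append(
            ng86_pair(a, b, alignment.genetic_code_id, include_stop_paths)
        )
    return out
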