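"""Group-comparison statistics and the RSCU interclade screen.

Two-group contrasts use the Mann–Whitney U test, multi-group contrasts the
Kruskal–Wallis H test — distribution-free choices suited to the small,
non-normal per-clade samples a gene-family analysis produces.  Multiple
testing over codons is controlled with Benjamini–Hochberg FDR.

The interclade RSCU screen mirrors the gene-family analysis: for each of
the 59 synonymous sense codons, per-gene RSCU values are compared across
clades (Kruskal–Wallis), p-values are BH-adjusted across codons, and a
codon "passes" when its adjusted p is below ``alpha`` *and* the spread of
clade-mean RSCU exceeds ``range_min`` (defaults 0.05 and 0.7) — the effect-
size filter keeps statistically significant but tiny differences out.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .codes import get_code
from .io import CladeMap, ValidationError


@dataclass
class GroupTestResult:
    feature: str
    groups: list[tuple[str, int]]
    statistic: float
    p_value: float
    method: str
    n_dropped: int = 0


@dataclass
class RSCUScreenResult:
    codon: str
    amino_acid: str
    p_value: float | None
    q_value: float | None
    rscu_range: float | None
    clade_means: dict[str, float]
    passes: bool


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def _u_statistic(pooled_ranks: np.ndarray, x_mask: np.ndarray) -> float:
    nx = int(x_mask.sum())
    return float(pooled_ranks[x_mask].sum() - nx * (nx + 1) / 2)


def mann_whitney_u(
    x, y, mode: str = "auto", feature: str = ""
) -> GroupTestResult:
    """Two-sided Mann–Whitney U test.

    ``mode="exact"`` enumerates all C(nx+ny, nx) group labelings of the
    pooled sample (midranks, so ties are handled) and reports
    P(|U - nx·ny/2| >= |U_obs - nx·ny/2|).  ``mode="normal"`` uses the
    normal approximation with tie and continuity corrections.  ``"auto"``
    picks exact for nx+ny <= 12 without ties, normal otherwise.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be nonempty")
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if mode == "auto":
        mode = "exact" if (nx + ny <= 12 and not has_ties) else "normal"

    if mode == "exact":
        ranks = _midranks(pooled)
        obs_mask = np.zeros(nx + ny, dtype=bool)
        obs_mask[:nx] = True
        u_obs = _u_statistic(ranks, obs_mask)
        center = nx * ny / 2.0
        dev = abs(u_obs - center)
        total = hits = 0
        for combo in itertools.combinations(range(nx + ny), nx):
            mask = np.zeros(nx + ny, dtype=bool)
            mask[list(combo)] = True
            u = _u_statistic(ranks, mask)
            total += 1
            if abs(u - center) >= dev - 1e-9:
                hits += 1
        p = hits / total
        method = "mann-whitney-exact"
        stat = u_obs
    elif mode == "normal":
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        stat, p = float(res.statistic), float(res.pvalue)
        method = "mann-whitney-normal"
    else:
        raise ValidationError(f"unknown mode: {mode!r}")
    return GroupTestResult(
        feature=feature,
        groups=[("x", nx), ("y", ny)],
        statistic=stat,
        p_value=min(p, 1.0),
        method=method,
    )


def kruskal_wallis(groups, labels=None, feature: str = "") -> GroupTestResult:
    """Kruskal–Wallis H with tie correction; chi-square p on k-1 df.

    A degenerate input where every pooled value is identical returns H = 0,
    p = 1 by convention.
    """
    groups = [np.asarray(list(g), dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValidationError("need >= 2 nonempty groups")
    labels = labels or [f"g{i + 1}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*groups)
    return GroupTestResult(
        feature=feature,
        groups=[(lab, len(g)) for lab, g in zip(labels, groups)],
        statistic=float(h),
        p_value=float(min(p, 1.0)),
        method="kruskal-wallis",
    )


def bh_fdr(p_values) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must be in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def permutation_test(
    x, y, n_perm: int = 10000, seed: int = 0, feature: str = ""
) -> GroupTestResult:
    """Two-sided permutation test on the difference of group means —
    a sensitivity check alongside the rank tests."""
    rng = np.random.default_rng(seed)
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    obs = abs(x.mean() - y.mean())
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        d = abs(pooled[: len(x)].mean() - pooled[len(x) :].mean())
        if d >= obs - 1e-12:
            hits += 1
    return GroupTestResult(
        feature=feature,
        groups=[("x", len(x)), ("y", len(y))],
        statistic=float(obs),
        p_value=(hits + 1) / (n_perm + 1),
        method=f"permutation-{n_perm}",
    )


def rscu_interclade_screen(
    profiles,
    clades: CladeMap,
    alpha: float = 0.05,
    range_min: float = 0.7,
    code_id: int = 1,
) -> list[RSCUScreenResult]:
    """Per-codon Kruskal–Wallis across clades on per-gene RSCU, BH-FDR
    across codons, and an effect-size filter on the clade-mean RSCU range.

    ``profiles`` is a list of :class:`~cladon.codon_usage.CodonUsageProfile`.
    Genes with missing RSCU for a codon are dropped for that codon; a clade
    is usable for a codon when >= 2 of its genes have a value, and a codon
    is testable when >= 2 clades are usable.
    """
    code = get_code(code_id)
    screen_codons = [
        c for c in code.sense_codons if c not in code.nondegenerate_codons
    ]
    by_clade: dict[str, list] = {}
    for p in profiles:
        clade = clades.clade_of.get(p.gene_id, "")
        if clade:
            by_clade.setdefault(clade, []).append(p)
    by_clade = {k: v for k, v in by_clade.items() if len(v) >= 2}
    if len(by_clade) < 2:
        raise ValidationError("need >= 2 clades with >= 2 genes each")

    results = []
    for codon in screen_codons:
        values, labels, means = [], [], {}
        for clade in sorted(by_clade):
            vals = [
                p.rscu[codon]
                for p in by_clade[clade]
                if p.rscu.get(codon) is not None
            ]
            if len(vals) >= 2:
                values.append(vals)
                labels.append(clade)
                means[clade] = float(np.mean(vals))
        if len(values) >= 2:
            test = kruskal_wallis(values, labels, feature=codon)
            p_value = test.p_value
            rng = max(means.values()) - min(means.values())
        else:
            p_value, rng = None, None
        results.append(
            RSCUScreenResult(
                codon=codon,
                amino_acid=code.translate(codon),
                p_value=p_value,
                q_value=None,
                rscu_range=rng,
                clade_means=means,
                passes=False,
            )
        )

    testable = [r for r in results if r.p_value is not None]
    qs = bh_fdr([r.p_value for r in testable])
    for r, q in zip(testable, qs):
        r.q_value = float(q)
        r.passes = bool(
            q < alpha and r.rscu_range is not None and r.rscu_range > range_min
        )
    return results


def compare_orders(
    values_by_gene: dict[str, float],
    orders: CladeMap,
    metric: str = "",
    mode: str = "auto",
) -> GroupTestResult:
    """Two-sided Mann–Whitney on a per-gene (or per-group) metric between
    the two taxonomic orders.  Missing values (None/NaN) are dropped and
    counted."""
    by_order: dict[str, list[float]] = {}
    dropped = 0
    for gid, val in values_by_gene.items():
        order = orders.order_of.get(gid, "")
        if not order:
            continue
        if val is None or (isinstance(val, float) and math.isnan(val)):
            dropped += 1
            continue
        by_order.setdefault(order, []).append(float(val))
    present = sorted(by_order)
    if len(present) != 2:
        raise ValidationError(
            f"need exactly 2 orders with data, found {present}"
        )
    a, b = present
    res = mann_whitney_u(by_order[a], by_order[b], mode=mode, feature=metric)
    res.groups = [(a, len(by_order[a])), (b, len(by_order[b]))]
    res.n_dropped = dropped
    return res
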