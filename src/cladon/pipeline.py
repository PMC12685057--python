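"""End-to-end analysis: wire the stages into one reproducible run.

Given per-clade codon alignments, a reference alignment, and gene metadata,
``run_full_analysis`` emits plain TSV tables (the test surface — no binary
caches): per-gene codon usage, per-group diversity summaries, within-clade
NG86 dN/dS pairs, clade fold-divergence against the reference, the RSCU
interclade screen, and order-level comparisons.  Every table carries a
header comment with the seed, a config hash, and the package version, and a
rerun with the same config and seed reproduces the tables byte for byte.
"""

from __future__ import annotations

import glob
import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import yaml

from . import __version__
from .codon_usage import profile, usage_table
from .divergence import clade_fold_divergence
from .io import (
    CladeMap,
    CodonAlignment,
    ValidationError,
    annotate,
    read_codon_alignment,
    read_newick,
    write_table,
)
from .popgen import group_popgen, pairwise_ng86
from .stats import compare_orders, rscu_interclade_screen

log = logging.getLogger(__name__)

#: per-gene metrics compared between orders (from the usage profiles)
GENE_METRICS = ("pr2_at", "pr2_gc", "nc", "gc3s")
#: per-group metrics compared between orders (from the popgen summaries)
GROUP_METRICS = ("pi_site", "tajima_d")


@dataclass
class AnalysisConfig:
    alignments: dict[str, str] = field(default_factory=dict)  # clade -> fasta
    alignments_dir: str | None = None  # or: directory of clade_*.fasta
    reference: str = ""
    metadata: str | None = None
    tree: str | None = None
    asr_alignment: str | None = None  # ids must match tree tips
    asr_model: str = "JC"
    grouping: str = "clade_x_order"
    sites: str = "all"
    alpha: float = 0.05
    range_min: float = 0.7
    seed: int = 0
    outdir: str = "cladon_out"

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must be in (0, 1)")
        if self.range_min < 0:
            raise ValidationError("range_min must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _load_clade_alignments(config: AnalysisConfig, clades: CladeMap):
    found: dict[str, CodonAlignment] = {}
    if config.alignments:
        for label, path in config.alignments.items():
            found[label] = annotate(read_codon_alignment(path), clades)
    elif config.alignments_dir:
        pattern = os.path.join(config.alignments_dir, "clade_*.fasta")
        for path in sorted(glob.glob(pattern)):
            label = os.path.basename(path)[len("clade_") : -len(".fasta")]
            found[label] = annotate(read_codon_alignment(path), clades)
    if not found:
        raise ValidationError("no clade alignments configured")
    return found


def run_full_analysis(config: AnalysisConfig) -> str:
    """Run every stage; returns the output directory."""
    os.makedirs(config.outdir, exist_ok=True)
    stamp = (
        f"cladon {__version__}\nseed={config.seed}\nconfig_sha={config.hash()}"
    )
    log_lines = [stamp.replace("\n", " ")]

    def _stage(name):
        log_lines.append(f"stage: {name}")
        log.info("stage: %s", name)

    clades = CladeMap.from_tsv(config.metadata) if config.metadata else CladeMap()

    _stage("load")
    clade_alignments = _load_clade_alignments(config, clades)
    reference = annotate(read_codon_alignment(config.reference), clades)
    for aln in clade_alignments.values():
        full_map = CladeMap.from_alignment(aln)
        clades = clades.merge(full_map)
    clades = clades.merge(CladeMap.from_alignment(reference))

    _stage("usage")
    usage_rows = []
    profiles = []
    for label in sorted(clade_alignments):
        aln = clade_alignments[label]
        usage_rows.extend(usage_table(aln))
        profiles.extend(profile(r) for r in aln)
    ref_profiles = [profile(r) for r in reference]
    usage_rows.extend(usage_table(reference))
    write_table(usage_rows, os.path.join(config.outdir, "usage.tsv"), stamp)

    _stage("popgen")
    popgen_rows = []
    summaries = []
    for label in sorted(clade_alignments):
        for s in group_popgen(clade_alignments[label], clades, config.grouping):
            summaries.append(s)
            popgen_rows.append(
                {
                    "group": s.group_id,
                    "n": s.n,
                    "L": s.L,
                    "S": s.S,
                    "pi_total": s.pi_total,
                    "pi_site": s.pi_site,
                    "theta_w": s.theta_w,
                    "tajima_d": s.tajima_d,
                    "reason": s.tajima_d_reason,
                }
            )
    ref_summaries = group_popgen(reference, clades, "order")
    for s in ref_summaries:
        popgen_rows.append(
            {
                "group": f"reference×{s.group_id}",
                "n": s.n,
                "L": s.L,
                "S": s.S,
                "pi_total": s.pi_total,
                "pi_site": s.pi_site,
                "theta_w": s.theta_w,
                "tajima_d": s.tajima_d,
                "reason": s.tajima_d_reason,
            }
        )
    write_table(popgen_rows, os.path.join(config.outdir, "popgen.tsv"), stamp)

    _stage("dnds")
    dnds_rows = []
    for label in sorted(clade_alignments):
        for r in pairwise_ng86(clade_alignments[label], clades, pairs="all"):
            dnds_rows.append(
                {
                    "clade": label,
                    "gene_a": r.gene_pair[0],
                    "gene_b": r.gene_pair[1],
                    "S_sites": r.S_sites,
                    "N_sites": r.N_sites,
                    "Sd": r.Sd,
                    "Nd": r.Nd,
                    "dS": r.dS,
                    "dN": r.dN,
                    "omega": r.omega,
                    "codons": r.n_codons_compared,
                    "excluded": r.n_codons_excluded,
                }
            )
    write_table(dnds_rows, os.path.join(config.outdir, "dnds.tsv"), stamp)

    _stage("divergence")
    reports = clade_fold_divergence(
        clade_alignments, reference, sites=config.sites
    )
    div_rows = [
        {
            "clade": r.clade_label,
            "n_genes": r.n_genes,
            "mean_pairwise_jc": r.mean_pairwise_jc,
            "reference_mean_jc": r.reference_mean_jc,
            "fold": r.fold,
            "matched_species": r.reference_matched_species,
            "reason": r.reason,
        }
        for r in reports
    ]
    write_table(div_rows, os.path.join(config.outdir, "divergence.tsv"), stamp)

    _stage("screen")
    screen = rscu_interclade_screen(
        profiles, clades, alpha=config.alpha, range_min=config.range_min
    )
    screen_rows = [
        {
            "codon": r.codon,
            "amino_acid": r.amino_acid,
            "p_value": r.p_value,
            "q_value": r.q_value,
            "rscu_range": r.rscu_range,
            "passes": r.passes,
        }
        for r in screen
    ]
    write_table(screen_rows, os.path.join(config.outdir, "screen.tsv"), stamp)

    _stage("orders")
    order_rows = []
    for metric in GENE_METRICS:
        for name, profs in (("tc", profiles), ("reference", ref_profiles)):
            values = {p.gene_id: getattr(p, metric) for p in profs}
            try:
                res = compare_orders(values, clades, metric=metric)
            except ValidationError as exc:
                log_lines.append(f"orders: skipped {name}/{metric}: {exc}")
                continue
            order_rows.append(
                {
                    "gene_set": name,
                    "metric": metric,
                    "level": "gene",
                    "group_a": res.groups[0][0],
                    "n_a": res.groups[0][1],
                    "group_b": res.groups[1][0],
                    "n_b": res.groups[1][1],
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "method": res.method,
                }
            )
    for metric in GROUP_METRICS:
        values = {}
        order_of = {}
        for s in summaries:
            if "×" in s.group_id:
                order_of[s.group_id] = s.group_id.split("×", 1)[1]
                values[s.group_id] = getattr(s, metric)
        if len(set(order_of.values())) == 2 and len(values) >= 4:
            try:
                res = compare_orders(
                    values, CladeMap(order_of=order_of), metric=metric
                )
            except ValidationError as exc:
                log_lines.append(f"orders: skipped group-level {metric}: {exc}")
                continue
            order_rows.append(
                {
                    "gene_set": "tc",
                    "metric": metric,
                    "level": "group",
                    "group_a": res.groups[0][0],
                    "n_a": res.groups[0][1],
                    "group_b": res.groups[1][0],
                    "n_b": res.groups[1][1],
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "method": res.method,
                }
            )
        else:
            log_lines.append(f"orders: skipped group-level {metric}")
    write_table(
        order_rows,
        os.path.join(config.outdir, "orders.tsv"),
        stamp,
        keys=[
            "gene_set", "metric", "level", "group_a", "n_a",
            "group_b", "n_b", "statistic", "p_value", "method",
        ],
    )

    if config.tree and config.asr_alignment:
        _stage("asr")
        from .asr import SubstitutionModel, marginal_asr

        tree = read_newick(config.tree)
        aln = read_codon_alignment(config.asr_alignment)
        model = (
            SubstitutionModel.jc()
            if config.asr_model.upper() == "JC"
            else SubstitutionModel.poisson()
        )
        rec = marginal_asr(tree, aln, model)
        asr_dir = os.path.join(config.outdir, "asr")
        os.makedirs(asr_dir, exist_ok=True)
        with open(os.path.join(asr_dir, "ancestors.fasta"), "w") as fh:
            for node in rec.node_order:
                fh.write(f">{node}\n{rec.map_sequences[node]}\n")
        rows = []
        for node in rec.node_order:
            post = rec.node_posteriors[node]
            for site in range(post.shape[0]):
                row = {"node": node, "site": site + 1}
                for k, sym in enumerate(rec.alphabet):
                    row[f"p_{sym}"] = float(post[site, k])
                rows.append(row)
        write_table(rows, os.path.join(asr_dir, "posteriors.tsv"), stamp)
        log_lines.append(f"asr: log-likelihood {rec.total_log_likelihood:.6f}")

    with open(os.path.join(config.outdir, "run.log"), "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return config.outdir
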