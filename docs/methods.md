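# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Data model and ingest

Sequences are in-frame aligned CDS over `{A,C,G,T,N,-}`; ingest uppercases
and maps U→T. The gap character is `-` only. Codons containing `-` or `N`
are "untyped": they stay in the alignment but are excluded codon-wise by
every statistic. A terminal stop codon is masked to `---` with a logged
warning (CDS deposits commonly retain stops); an internal in-frame stop is
an error that names the record and 1-based codon index. Gene metadata
(species, taxonomic order, clade) travels in FASTA headers as `key=value`
tokens and/or a sidecar TSV; the sidecar wins. Only the standard genetic
code (NCBI table 1) is exercised by the shipped tests; other table ids are
accepted and all derived structures (synonym families, degeneracy classes,
fourfold blocks) are recomputed for them.

## Codon usage

*RSCU* is the observed codon count over its uniform-usage expectation
within the synonym family (family sums equal family size). Families with
zero usage are reported missing, never 0. Met and Trp carry no synonymous
signal; they report RSCU 1 when present and are excluded from screens.

*Nc* follows Wright (1990): per family with n ≥ 2 the homozygosity is
F = (n·Σp² − 1)/(n − 1); F is averaged within degeneracy classes (standard
code: nine 2-fold, one 3-fold, five 4-fold, three 6-fold with Leu/Ser/Arg
as single 6-fold families) and Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆,
clamped to [20, 61]. The 3-fold class rests on the single Ile family, so a
missing *or non-positive* F̄₃ is imputed as (F̄₂ + F̄₄)/2 — the non-positive
case (e.g. a 1:1 split of two Ile codons gives F = 0) extends Wright's
missing-data rule to an equally degenerate estimate. Any other class mean
missing or ≤ 0 yields a missing Nc.

*GC3s* is computed over synonymous third positions only (ATG and TGG
excluded); whether a given study's "GC₃" includes nondegenerate thirds is
often unstated, so the synonymous variant is used and documented here.

*PR2* asymmetries are restricted to third positions of fourfold-degenerate
codon blocks (Sueoka's convention, eight blocks in the standard code):
within those blocks every third-position state is synonymous, so the
asymmetry isolates mutational/repair bias from amino-acid-level selection.
Each ratio is missing when its denominator is zero.

## Diversity and selection

π, S and θ_W use complete deletion: only columns typed in every member of
the group are compared. π is reported per locus (mean pairwise differences)
and per site. Tajima's D follows the 1989 constants and requires n ≥ 4 and
S ≥ 1; for n ∈ {2,3} the variance constants are unstable, so D is missing
with a reason code, never 0.

NG86 dN/dS uses pairwise deletion (codon pairs dropped when either codon is
untyped), pathway averaging over all orderings of multi-step codon changes,
and the Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3). Synonymous site
counts exclude changes to stop codons from the numerator but keep the
denominator at 3 per position. By default, pathways through stop codons are
excluded entirely; pairs with no stop-free pathway are dropped from the
totals and counted. An `include_stop_paths` flag restores the equal-weight
variant in which stop-involving steps count as nonsynonymous. ω is missing
when dS is 0 or undefined (saturation, p ≥ 3/4). The complete-deletion /
pairwise-deletion split follows the most common convention for each
statistic. No κ-aware counting or ML codon model is offered; dN/dS here is
a counting estimator and is labelled as such in outputs.

## Clade divergence

The fold statistic is mean within-clade pairwise JC distance divided by the
mean pairwise JC distance among reference sequences of the species present
in that clade. Species matching prevents taxon-sampling differences from
distorting the denominator; when fewer than two reference sequences match,
all reference pairs are used and the fallback is logged and flagged in the
report. Distances default to all typed sites (`--sites all`); `--sites ff3`
restricts to third positions fourfold-degenerate in both sequences as a
synonymous-site proxy. Aggregation is mean-of-pairs; saturated pairs
(p ≥ 3/4) are dropped and counted. JC on all sites is the minimal
correction consistent with plain "nucleotide divergence"; it is a
documented choice, validated on synthetic data with known rate scalings,
not a reimplementation of any particular published protocol.

## Ancestral reconstruction

Reconstruction is marginal (per node, per site), not joint: the posterior
at each internal node is computed from inside (post-order) partial
likelihoods and an outside (pre-order) message, equivalent under
reversibility to rerooting at that node. Branch lengths are taken as given;
nothing is optimized. The rate matrix is validated for detailed balance and
rescaled to one expected substitution per site per unit branch length, and
P(t) comes from the symmetrized eigendecomposition (cached per model).
Per-site scaling keeps partials in range on deep trees. Gaps/`N`/`X` are
missing data (all-ones partials). MAP ties break by alphabet order,
deterministically. JC and Poisson ship built in; empirical amino-acid
matrices are not bundled, but any reversible matrix is accepted. The total
log-likelihood is root-invariant (pulley principle) and is tested as such.

## Group comparisons and the RSCU screen

Two-group contrasts use two-sided Mann–Whitney U; multi-group contrasts
use Kruskal–Wallis with tie correction (χ² p on k−1 df; all-identical
input returns H = 0, p = 1 by convention). Exact Mann–Whitney p-values are
computed by full enumeration of the C(nx+ny, nx) group labelings on
midranks — this handles ties and gives p = 1 for identical multisets — and
are used automatically for nx+ny ≤ 12 without ties; otherwise the normal
approximation with tie and continuity corrections applies. A permutation
test on the mean difference is available as a sensitivity check. FDR is
Benjamini–Hochberg step-up exactly.

The RSCU interclade screen tests each of the 59 synonymous sense codons:
Kruskal–Wallis across clades on per-gene RSCU (genes missing that codon's
RSCU dropped; a clade is usable with ≥ 2 values; a codon is testable with
≥ 2 usable clades), BH adjustment across testable codons, and an
effect-size filter on the range of clade-*mean* RSCU. Defaults α = 0.05
and range > 0.7. Both thresholds are exposed.

## Synthetic data

The generator produces the structures the analysis assumes, with ground
truth recorded:

- **Coalescent sampler** — neutral constant-size Kingman genealogy
  (coalescence rate C(k,2) in scaled time), Poisson(θT/2) mutations placed
  on branches proportionally to length and assigned to uniform sites with
  a JC change kernel. Finite sites keep outputs valid DNA and let π
  saturate realistically; expectations E[S] = θa₁ and E[π] = θ hold to
  within Monte-Carlo error at the tested θ/L. A mutation that would create
  an in-frame stop is redrawn (site and target), preserving the no-stop
  invariant with negligible effect on S at the simulated densities.
- **Codon simulator** — continuous-time Markov chain on the 61 sense
  codons; a single-nucleotide change has rate ∝ π(target nt) ·
  κ^[transition] · ω^[nonsynonymous] · w(target codon), the MG94-style
  target-nucleotide parameterization, so `gc_bias` acts at mutation level
  (π_G = π_C = gc_bias/2) and the optional per-codon weights w impose
  codon-level preference while preserving detailed balance (stationary
  distribution ∝ product of nucleotide frequencies × w over sense codons).
  The matrix is rescaled to one expected substitution per codon site per
  unit branch length; simulation is by exponential waiting times,
  vectorized over sites. Branch lengths therefore read directly as
  expected substitutions per codon.
- **Scenario builder** — a balanced ultrametric species tree with two
  order-level subtrees; each clade draws its genes' species from its
  permitted orders (alternating between orders for two-order clades),
  restricts the species tree to them, scales branch lengths by the clade's
  rate factor, and simulates under the clade's codon model. A
  mitochondrial-like reference (slow, low ω, AT-shifted by default)
  evolves on the full species tree. `default_scenario` mirrors a TC-like
  family: conserved two-order subclades at the reference rate with ω
  0.1–0.15, fast clades at 3–3.5× with ω 0.3–0.4, two order-restricted
  clades, 4–6 genes per clade over 5 species per order, 300-codon genes.
  One seeded generator drives a run; the seed is recorded in every output.

What the generator does **not** emulate: recombination, indels,
demographic change, rate variation among sites, empirical amino-acid
exchangeabilities, and — most importantly — it *does* imprint shared
phylogenetic history on genes within a clade. Passing recovery tests
therefore show the estimators track their targets under the stated model,
not that real TC data meet those assumptions.

## Problem sizes and tolerances

Recovery checks use problem sizes chosen to put Monte-Carlo error well
inside the stated bands: PR2 equilibrium on 200 genes × 300 codons
(±0.02); NG86 ω on 200 replicate 400-codon gene pairs at divergence 0.05
(400 codons is a typical class-I terpene-cyclase CDS length); Watterson/
Tajima on 2000 coalescent replicates (n = 10, θ = 5, 300 codons); fold
divergence as the median over 20 seeded scenarios with 600-codon genes
(single-seed folds are ratios of small means and are noisy). Posterior and
oracle equivalences are exact to 1e-10/1e-9; closed forms to the printed
precision.

## Known limitations

- No phylogenetically corrected comparisons (PGLS, phylogenetic ANOVA):
  genes within a clade share history, so clade/order contrasts overstate
  independence — visible even on synthetic scenarios, where the RSCU
  screen responds to clade-level ancestry as well as to imposed bias.
- dN/dS is the NG86 counting estimator only; no branch/site ML models.
- The fold-divergence metric is a defined, documented statistic of this
  package; published "fold faster" figures computed under other distance
  or normalization choices are comparable only qualitatively.
- BH-adjusted q-values are monotone and dominate their p-values but BH is
  not idempotent; q-values are reported once and never re-adjusted.
- Branch lengths are inputs everywhere; no tree or branch-length
  estimation is performed.
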