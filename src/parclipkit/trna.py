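"""tRNA cross-linking signature: positional profiles, cloverleaf conversion
maps, and background-normalized enrichment testing.

Enrichment compares gene-unique (and isoacceptor-family-unique) read counts
between the cross-linked library and a total-cellular tRNA background.
Counts are scaled between libraries with trimmed-mean-of-M-values (TMM)
normalization; per-feature significance comes from a two-sided Fisher exact
test on the raw integer counts with library totals as margins, adjusted by
Benjamini-Hochberg at a 5% false discovery rate.  TMM enters only the
reported fold-change — Fisher requires integers, so the two are composed
rather than fused.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .align import AlignedRead, TransitionClass
from .annotate import AnnotatedRead
from .metagene import bin_mass
from .references import ReferenceSet

# ---------------------------------------------------------------------------
# positional profile (Fig. 2c analogue)
# ---------------------------------------------------------------------------

def positional_profile(
    reads: Sequence[AnnotatedRead],
    refset: ReferenceSet,
    n_bins: int = 10,
    use_copies: bool = True,
) -> np.ndarray:
    """Bin-normalized read density over the normalized [0, 1] tRNA length.

    Each read's footprint contributes to bins by fractional overlap (as in
    the metagene); the output sums to 1.
    """
    if not reads:
        raise ValueError("no tRNA reads")
    by_gene: dict[str, list[AnnotatedRead]] = {}
    for r in reads:
        if r.category == "tRNA":
            by_gene.setdefault(r.ref_id, []).append(r)
    if not by_gene:
        raise ValueError("no tRNA reads")
    density = np.zeros(n_bins)
    for gid, rs in by_gene.items():
        L = refset.sequences[gid].length
        cov = np.zeros(L)
        for r in rs:
            w = r.copies if use_copies else 1
            cov[r.start - 1 : r.end] += w
        mass, _ = bin_mass(cov, n_bins)
        density += mass
    return density / density.sum()


# ---------------------------------------------------------------------------
# conversion map (Fig. 2d analogue)
# ---------------------------------------------------------------------------

@dataclass
class ConversionProfile:
    """Per-position coverage/conversion tallies mapped onto cloverleaf elements.

    ``table`` has one row per (tRNA, position); ``ratio`` is conversions /
    coverage, NA where coverage is zero.  ``element_means`` averages the
    ratio over reference-T positions with coverage — only uridines can carry
    the 4SU cross-link diagnostic, so non-T positions are structurally
    uninformative and excluded from the element summary.

    The coverage denominator counts d0 and d1TC reads only.  A sequencing
    error removes a converted read from the numerator's class (it becomes
    d2), so retaining errored unconverted reads (d1other) in the denominator
    would bias the ratio downward; excluding both error classes keeps the
    ratio an unbiased estimate of the per-site conversion probability.
    """

    table: pd.DataFrame
    element_means: pd.Series
    argmax_element: str | None


_PROFILE_CLASSES = {TransitionClass.D0, TransitionClass.D1TC}


def conversion_map(
    reads: Sequence[AnnotatedRead],
    refset: ReferenceSet,
    use_copies: bool = True,
) -> ConversionProfile:
    """Per-position conversion ratios for tRNA reads.

    Coverage counts clean reads (d0 and d1TC); conversions count d1TC reads
    at their recorded conversion position.  See :class:`ConversionProfile`
    for why error-carrying classes are excluded from the denominator.
    """
    cov: dict[str, np.ndarray] = {}
    conv: dict[str, np.ndarray] = {}
    for r in reads:
        if r.category != "tRNA" or r.ambiguous or r.transition_class not in _PROFILE_CLASSES:
            continue
        gid = r.ref_id
        if gid not in cov:
            L = refset.sequences[gid].length
            cov[gid] = np.zeros(L)
            conv[gid] = np.zeros(L)
        w = r.copies if use_copies else 1
        cov[gid][r.start - 1 : r.end] += w
        if r.transition_class == TransitionClass.D1TC and r.conversion_pos is not None:
            ann = refset.trna_annotations[gid]
            if not 1 <= r.conversion_pos <= len(ann.element_map):
                raise ValueError(
                    f"conversion position {r.conversion_pos} outside annotation of {gid!r}"
                )
            conv[gid][r.conversion_pos - 1] += w

    rows = []
    for gid in cov:
        ann = refset.trna_annotations[gid]
        seq = refset.sequences[gid].sequence
        for p in range(1, len(seq) + 1):
            c = cov[gid][p - 1]
            rows.append(
                {
                    "trna": gid,
                    "position": p,
                    "element": ann.element_at(p),
                    "ref_base": seq[p - 1],
                    "coverage": c,
                    "conversions": conv[gid][p - 1],
                    "ratio": conv[gid][p - 1] / c if c > 0 else np.nan,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=["trna", "position", "element", "ref_base", "coverage", "conversions", "ratio"],
    )
    informative = table[(table["ref_base"] == "T") & (table["coverage"] > 0)]
    if len(informative):
        element_means = informative.groupby("element")["ratio"].mean()
        argmax = str(element_means.idxmax())
    else:
        element_means = pd.Series(dtype=float)
        argmax = None
    return ConversionProfile(table=table, element_means=element_means, argmax_element=argmax)


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------

@dataclass
class CountTable:
    """Gene- and family-level unique-read counts for the two libraries."""

    genes: pd.DataFrame  # index: gene, columns parclip/background (+family)
    families: pd.DataFrame  # index: family, columns parclip/background

    @property
    def gene_totals(self) -> pd.Series:
        return self.genes[["parclip", "background"]].sum()

    @property
    def family_totals(self) -> pd.Series:
        return self.families[["parclip", "background"]].sum()


def count_unique(
    parclip_reads: Sequence[AlignedRead],
    background_reads: Sequence[AlignedRead],
    refset: ReferenceSet,
    use_copies: bool = True,
) -> CountTable:
    """Count reads unique to one tRNA gene (and unique to one family).

    A read counts for gene g iff every best placement lies in g; the family
    rollup additionally counts reads whose placements stay within a single
    anticodon family.  Reads touching two genes of one family therefore
    count at the family level only; reads spanning families count nowhere.
    """
    genes = [s.id for s in refset.by_category("tRNA")]
    fams = {g: refset.trna_annotations[g].family for g in genes}
    fam_index = sorted(set(fams.values()))

    gene_counts = {g: [0.0, 0.0] for g in genes}
    fam_counts = {f: [0.0, 0.0] for f in fam_index}

    for col, lib in ((0, parclip_reads), (1, background_reads)):
        for ar in lib:
            if not ar.mapped:
                continue
            hit_genes = {h.ref_id for h in ar.hits}
            if not hit_genes <= set(genes):
                continue
            w = ar.copies if use_copies else 1
            hit_fams = {fams[g] for g in hit_genes}
            if len(hit_fams) == 1:
                fam_counts[next(iter(hit_fams))][col] += w
                if len(hit_genes) == 1:
                    gene_counts[next(iter(hit_genes))][col] += w

    gdf = pd.DataFrame.from_dict(gene_counts, orient="index", columns=["parclip", "background"])
    gdf.index.name = "gene"
    gdf["family"] = [fams[g] for g in gdf.index]
    fdf = pd.DataFrame.from_dict(fam_counts, orient="index", columns=["parclip", "background"])
    fdf.index.name = "family"
    return CountTable(genes=gdf, families=fdf)


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    logratio_trim: float,
    sum_trim: float,
) -> float:
    n_obs, n_ref = obs.sum(), ref.sum()
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        raise ValueError("no genes with positive counts in both libraries")
    o, r = obs[pos], ref[pos]
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    # inverse asymptotic (delta-method) variance of M
    w = 1.0 / ((n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r))
    n = len(m)
    lo_m = int(np.floor(n * logratio_trim)) + 1
    hi_m = n + 1 - lo_m
    lo_a = int(np.floor(n * sum_trim)) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
    return float(f) if np.isfinite(f) else 1.0


def tmm_factors(
    counts,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> np.ndarray:
    """Trimmed-mean-of-M-values scaling factors, one per library (column).

    Per-gene M (log2 ratio of library proportions) and A (average log2
    proportion) are computed on genes positive in both libraries; 30% of M
    extremes and 5% of A extremes are trimmed from each tail; the factor is
    2**(precision-weighted mean of the remaining M) against the first
    library as reference, and factors are rescaled to geometric mean 1.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("counts must be a genes x libraries matrix with >= 2 libraries")
    n_lib = x.shape[1]
    f = np.ones(n_lib)
    for j in range(1, n_lib):
        f[j] = _tmm_pair_factor(x[:, j], x[:, 0], logratio_trim, sum_trim)
    return f / np.exp(np.mean(np.log(f)))


# ---------------------------------------------------------------------------
# exact testing and FDR
# ---------------------------------------------------------------------------

def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Sums hypergeometric probabilities of all tables with the same margins
    whose probability does not exceed the observed one.  Returns NaN when
    the feature is absent from both libraries (a + c = 0).
    """
    cells = (a, b, c, d)
    if any(int(v) != v or v < 0 for v in cells):
        raise ValueError("table cells must be nonnegative integers")
    if sum(cells) == 0:
        raise ValueError("all-zero table")
    if a + c == 0:
        return float("nan")
    p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
    return float(min(max(p, np.nextafter(0, 1)), 1.0))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaNs propagate and are excluded
    from the test count m."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


# ---------------------------------------------------------------------------
# enrichment (Fig. 2e analogue)
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    genes: pd.DataFrame
    families: pd.DataFrame
    factors: dict  # TMM factors per library, geometric mean 1


def _enrich_level(
    counts: pd.DataFrame, fdr: float, top_fraction: float
) -> pd.DataFrame:
    c_par = counts["parclip"].to_numpy(dtype=float)
    c_bg = counts["background"].to_numpy(dtype=float)
    n_par, n_bg = c_par.sum(), c_bg.sum()
    # background is the abundance baseline, hence the TMM reference
    factors = tmm_factors(np.column_stack([c_bg, c_par]))
    f_bg, f_par = factors

    pvals = np.array(
        [
            fisher_exact_2x2(int(a), int(n_par - a), int(b), int(n_bg - b))
            if a + b > 0
            else np.nan
            for a, b in zip(c_par, c_bg)
        ]
    )
    qvals = bh_fdr(pvals)
    # 0.5 continuity pseudocount on zero counts, only for the fold-change
    a_fc = np.where(c_par > 0, c_par, 0.5)
    b_fc = np.where(c_bg > 0, c_bg, 0.5)
    log2fc = np.log2((a_fc / (n_par * f_par)) / (b_fc / (n_bg * f_bg)))
    log2fc = np.where(np.isnan(pvals), np.nan, log2fc)

    order = np.argsort(-c_bg, kind="stable")
    cum = np.cumsum(c_bg[order])
    in_top = np.zeros(len(c_bg), dtype=bool)
    # a feature is in the top stratum while the cumulative background
    # abundance before it is still below the threshold
    before = cum - c_bg[order]
    in_top[order] = before < top_fraction * n_bg
    stratum = np.where(in_top, "top85", "residual")

    out = counts.copy()
    out["log2fc"] = log2fc
    out["p"] = pvals
    out["q"] = qvals
    out["significant"] = (qvals < fdr) & (log2fc > 0)
    out["stratum"] = stratum
    return out


def enrichment(
    table: CountTable, fdr: float = 0.05, top_fraction: float = 0.85
) -> EnrichmentResult:
    """TMM-adjusted fold-changes with Fisher/BH significance at both levels."""
    genes = _enrich_level(table.genes, fdr, top_fraction)
    families = _enrich_level(table.families, fdr, top_fraction)
    c_bg = table.genes["background"].to_numpy(dtype=float)
    c_par = table.genes["parclip"].to_numpy(dtype=float)
    f_bg, f_par = tmm_factors(np.column_stack([c_bg, c_par]))
    return EnrichmentResult(
        genes=genes, families=families, factors={"background": f_bg, "parclip": f_par}
    )


def common_dispersion(count_matrix) -> float:
    """Method-of-moments common overdispersion across replicate libraries.

    Diagnostic only — it does not gate significance.  For each feature with
    positive mean the quasi-dispersion ((s^2 - mu) / mu^2) is computed on
    library-size-scaled counts and averaged.
    """
    x = np.asarray(count_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a features x replicates matrix")
    scaled = x / x.sum(axis=0, keepdims=True) * x.sum(axis=0).mean()
    mu = scaled.mean(axis=1)
    var = scaled.var(axis=1, ddof=1)
    ok = mu > 0
    if not ok.any():
        return 0.0
    phi = (var[ok] - mu[ok]) / mu[ok] ** 2
    return float(max(np.mean(phi), 0.0))
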