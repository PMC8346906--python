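"""Reciprocal allele-specific-expression analysis across two F1 crosses.

Two F1 families share a marine mother; one has a Long-allele and one a
Short-allele freshwater father.  At heterozygous SNPs the ratio of
reference to alternate reads in each RNA-seq library measures
cis-regulatory divergence between the parental alleles.  A gene whose
freshwater allele is up-regulated in one cross and down-regulated in the
other (reciprocal ASE) is a candidate target of a triallelic regulatory
element.

Per SNP and tissue two cross-vs-cross tests are run: Fisher's exact test
on read counts pooled within each cross (after binomial down-sampling of
deep libraries to the group median depth), and a Mann-Whitney U test on
per-library log2 allelic ratios.  ``diff_ase`` is the difference of
cross-mean log2 ratios (Long cross minus Short cross).  Filter cascades
then call spine candidates and reciprocally expressed genes, and a
permutation test measures enrichment of called genes near triallelic
regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenomicInterval

SPINE_TISSUES = ("DS", "PS")
CONTROL_TISSUES = ("PF", "H")


# ------------------------------------------------------------------ filters

def filter_eligible_snps(table: pd.DataFrame,
                         min_frac_individuals: float = 20 / 24,
                         min_reads: int = 3,
                         min_allele_frac: float = 0.05) -> list[str]:
    """SNPs informative in enough fish for differential ASE analysis.

    Libraries are summed per individual (a fish may contribute several
    libraries); an individual is informative at a SNP if both alleles
    have >= ``min_reads`` reads and each allele is >= ``min_allele_frac``
    of the individual's total there.  A SNP is eligible if at least
    ``ceil(min_frac_individuals * n_individuals)`` individuals are
    informative, where n_individuals counts distinct fish across both
    crosses (the study's 20-of-24 rule).
    """
    if table["individual_id"].isna().any():
        raise ValueError("individual_id missing; provide an explicit "
                         "library-to-individual map")
    n_indiv = table["individual_id"].nunique()
    need = math.ceil(min_frac_individuals * n_indiv)
    per_ind = (table.groupby(["snp_id", "individual_id"], sort=False)
               [["ref_count", "alt_count"]].sum())
    total = per_ind["ref_count"] + per_ind["alt_count"]
    with np.errstate(invalid="ignore", divide="ignore"):
        ok = ((per_ind["ref_count"] >= min_reads)
              & (per_ind["alt_count"] >= min_reads)
              & (per_ind["ref_count"] >= min_allele_frac * total)
              & (per_ind["alt_count"] >= min_allele_frac * total))
    informative = ok.groupby(level="snp_id").sum()
    return sorted(informative.index[informative >= need])


def downsample_to_median(table: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Binomially thin deep libraries to the median depth of their group.

    Within each (cross, tissue) group the median total read count over
    SNP x library entries is taken; entries above it have each read kept
    independently with probability median/total, preserving the expected
    allelic ratio.  Entries at or below the median are unchanged.
    """
    rng = np.random.default_rng(seed)
    table = table.copy()
    total = table["ref_count"] + table["alt_count"]
    for (_, _), idx in table.groupby(["cross", "tissue"], sort=False).groups.items():
        med = float(np.median(total.loc[idx]))
        deep = idx[total.loc[idx] > med]
        if len(deep) == 0:
            continue
        p = med / total.loc[deep]
        table.loc[deep, "ref_count"] = rng.binomial(
            table.loc[deep, "ref_count"], p)
        table.loc[deep, "alt_count"] = rng.binomial(
            table.loc[deep, "alt_count"], p)
    return table


# ------------------------------------------------------------------ tests

def pooled_fisher(ref_a: int, alt_a: int, ref_b: int, alt_b: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table of per-cross pooled counts."""
    if ref_a + alt_a == 0 or ref_b + alt_b == 0:
        raise ValueError("a cross has zero total reads")
    return float(stats.fisher_exact(
        [[ref_a, alt_a], [ref_b, alt_b]], alternative="two-sided")[1])


def log_ratio(ref: int, alt: int, pseudocount: float = 0.5) -> float:
    """log2 reference/alternate ratio of one library.

    The Haldane-Anscombe pseudocount is applied only when one count is
    zero, keeping the ratio finite without biasing the nonzero cases.
    Both counts zero is undefined (the library carries no information).
    """
    if ref < 0 or alt < 0:
        raise ValueError("negative read count")
    if ref == 0 and alt == 0:
        raise ValueError("both counts zero; exclude this library")
    if ref == 0 or alt == 0:
        return math.log2((ref + pseudocount) / (alt + pseudocount))
    return math.log2(ref / alt)


def _log_ratios(ref: np.ndarray, alt: np.ndarray) -> np.ndarray:
    keep = (ref + alt) > 0
    return np.array([log_ratio(int(r), int(a))
                     for r, a in zip(ref[keep], alt[keep])])


def mwu_reciprocal_test(long_ratios, short_ratios) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparing per-library log ratios by cross.

    Returns (p, diff_ase) with diff_ase = mean(long) - mean(short).
    Exact p when the pooled sample is small (<= 20) and tie-free; the
    tie-corrected normal approximation with continuity correction
    otherwise.
    """
    x = np.asarray(long_ratios, dtype=float)
    y = np.asarray(short_ratios, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty group in Mann-Whitney test")
    diff = float(x.mean() - y.mean())
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if len(x) + len(y) <= 20 and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    p = float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method=method).pvalue)
    return p, diff


def binomial_allele_test(ref: int, alt: int) -> float:
    """Exact two-sided binomial test of ref reads against a 0.5 ratio.

    Two-sidedness by summing the probabilities of all outcomes no more
    likely than the observed one.
    """
    n = ref + alt
    if n < 1:
        raise ValueError("need at least one read")
    return float(stats.binomtest(ref, n, 0.5).pvalue)


# ------------------------------------------------------------------ per-SNP stats

@dataclass
class AseStats:
    """Per-SNP, per-tissue cross-comparison statistics (long DataFrame)."""

    table: pd.DataFrame  # snp_id, tissue, fisher_p, mwu_p, diff_ase, ...


def compute_snp_stats(counts: pd.DataFrame, seed: int = 0,
                      downsample: bool = True) -> pd.DataFrame:
    """All per-SNP x tissue statistics for the filter cascades.

    Returns one row per (snp_id, tissue) with:
    fisher_p (cross-pooled counts, down-sampled), mwu_p and diff_ase
    (per-library log2 ratios, raw counts), per-cross pooled counts and
    binomial p-values, mean log2 ratio per cross, and the SNP's total
    read count over all libraries and tissues (for the depth-outlier
    filter).
    """
    ds = downsample_to_median(counts, seed=seed) if downsample else counts
    pooled = (ds.groupby(["snp_id", "tissue", "cross"], sort=False)
              [["ref_count", "alt_count"]].sum())
    total_per_snp = (counts.assign(t=counts["ref_count"] + counts["alt_count"])
                     .groupby("snp_id", sort=False)["t"].sum())
    meta = counts.drop_duplicates("snp_id").set_index("snp_id")

    rows = []
    grouped = counts.groupby(["snp_id", "tissue"], sort=False)
    for (snp, tissue), grp in grouped:
        row = {"snp_id": snp, "tissue": tissue,
               "chrom": meta.loc[snp, "chrom"], "pos": meta.loc[snp, "pos"],
               "gene_id": meta.loc[snp, "gene_id"],
               "exonic": bool(meta.loc[snp, "exonic"]),
               "total_reads": int(total_per_snp.loc[snp])}
        ratios = {}
        for cross in ("MarineXLong", "MarineXShort"):
            sub = grp[grp["cross"] == cross]
            ratios[cross] = _log_ratios(sub["ref_count"].to_numpy(),
                                        sub["alt_count"].to_numpy())
            try:
                pr, pa = pooled.loc[(snp, tissue, cross)]
            except KeyError:
                pr = pa = 0
            row[f"ref_{cross}"] = int(pr)
            row[f"alt_{cross}"] = int(pa)
            row[f"binom_p_{cross}"] = (binomial_allele_test(int(pr), int(pa))
                                       if pr + pa >= 1 else np.nan)
        lr, sr = ratios["MarineXLong"], ratios["MarineXShort"]
        if len(lr) and len(sr):
            row["mwu_p"], row["diff_ase"] = mwu_reciprocal_test(lr, sr)
            row["mean_lr_long"] = float(lr.mean())
            row["mean_lr_short"] = float(sr.mean())
        else:
            row["mwu_p"] = row["diff_ase"] = np.nan
            row["mean_lr_long"] = row["mean_lr_short"] = np.nan
        tot_l = row["ref_MarineXLong"] + row["alt_MarineXLong"]
        tot_s = row["ref_MarineXShort"] + row["alt_MarineXShort"]
        row["fisher_p"] = (pooled_fisher(
            row["ref_MarineXLong"], row["alt_MarineXLong"],
            row["ref_MarineXShort"], row["alt_MarineXShort"])
            if tot_l > 0 and tot_s > 0 else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ cascades

def spine_candidate_filter(stats_df: pd.DataFrame, alpha: float = 0.05,
                           max_reads: int = 5000,
                           control_diff_bound: float = 1.0) -> list[str]:
    """SNPs behaving as expected for a spine-length regulator.

    Keep a SNP iff it is exonic, its total depth is below ``max_reads``,
    both spine tissues (DS, PS) show differential ASE at unadjusted
    p < alpha with the same sign of diff_ase, and neither control tissue
    (PF, H) shows differential ASE (p > alpha and |diff_ase| < bound).
    SNPs missing any of the four tissues are excluded.
    """
    keep = []
    for snp, grp in stats_df.groupby("snp_id", sort=False):
        by_tissue = grp.set_index("tissue")
        if not set(SPINE_TISSUES + CONTROL_TISSUES).issubset(by_tissue.index):
            continue
        if not bool(by_tissue["exonic"].iloc[0]):
            continue
        if int(by_tissue["total_reads"].iloc[0]) >= max_reads:
            continue
        ds, ps = by_tissue.loc["DS"], by_tissue.loc["PS"]
        if not (ds["mwu_p"] < alpha and ps["mwu_p"] < alpha):
            continue
        if np.sign(ds["diff_ase"]) != np.sign(ps["diff_ase"]):
            continue
        ctrl_ok = all(
            by_tissue.loc[t, "mwu_p"] > alpha
            and -control_diff_bound < by_tissue.loc[t, "diff_ase"]
            < control_diff_bound
            for t in CONTROL_TISSUES)
        if ctrl_ok:
            keep.append(snp)
    return keep


@dataclass
class GeneReciprocityCall:
    gene_id: str
    n_snps: int
    direction_long: int  # sign of the Long-cross mean log ratio
    direction_short: int
    passes_1snp: bool
    passes_2snp: bool


def reciprocal_snp_pass(row: pd.Series, alpha: float = 0.05,
                        fold_min: float = 2.0) -> bool:
    """Does one (snp, tissue) row show reciprocal freshwater expression?

    Requires: each cross's pooled allelic ratio differs from 0.5
    (binomial p < alpha), the crosses differ from each other (both
    Mann-Whitney and Fisher p < alpha), and the between-cross change is
    at least ``fold_min``-fold (|diff_ase| >= log2 fold_min).
    """
    return bool(
        row["binom_p_MarineXLong"] < alpha
        and row["binom_p_MarineXShort"] < alpha
        and row["mwu_p"] < alpha and row["fisher_p"] < alpha
        and abs(row["diff_ase"]) >= math.log2(fold_min))


def reciprocal_gene_filter(stats_df: pd.DataFrame, alpha: float = 0.05,
                           fold_min: float = 2.0, max_reads: int = 5000
                           ) -> tuple[list[GeneReciprocityCall], list[str]]:
    """Call genes with reciprocal expression at 1-SNP and 2-SNP stringency.

    A SNP supports a gene if it is exonic, below the depth-outlier bound
    and passes :func:`reciprocal_snp_pass` in at least one tissue.
    Returns (gene calls, supporting SNP ids).
    """
    eligible = stats_df[(stats_df["exonic"])
                        & (stats_df["total_reads"] < max_reads)
                        & stats_df["gene_id"].notna()]
    passing_snps = []
    for snp, grp in eligible.groupby("snp_id", sort=False):
        if any(reciprocal_snp_pass(row, alpha, fold_min)
               for _, row in grp.iterrows()):
            passing_snps.append(snp)
    sub = eligible[eligible["snp_id"].isin(passing_snps)]
    calls = []
    for gene, grp in sub.groupby("gene_id", sort=False):
        n = grp["snp_id"].nunique()
        calls.append(GeneReciprocityCall(
            gene_id=gene, n_snps=n,
            direction_long=int(np.sign(np.nanmean(grp["mean_lr_long"]))),
            direction_short=int(np.sign(np.nanmean(grp["mean_lr_short"]))),
            passes_1snp=True, passes_2snp=n >= 2))
    calls.sort(key=lambda c: c.gene_id)
    return calls, sorted(passing_snps)


# ------------------------------------------------------------------ enrichment

def _near_any(gene_ivs: list[GenomicInterval],
              regions: list[GenomicInterval], window_bp: int) -> np.ndarray:
    near = np.zeros(len(gene_ivs), dtype=bool)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for i, g in enumerate(gene_ivs):
        for r in by_chrom.get(g.chrom, ()):
            if g.start < r.end + window_bp and r.start < g.end + window_bp:
                near[i] = True
                break
    return near


def proximity_enrichment(called_genes: list[str],
                         gene_intervals: dict[str, GenomicInterval],
                         regions: list[GenomicInterval],
                         window_bp: int = 50_000, n_perm: int = 10_000,
                         seed: int = 0) -> tuple[int, float, float]:
    """Permutation enrichment of called genes near genomic regions.

    observed = number of called genes whose interval lies within
    ``window_bp`` of any region; the null distribution is the same count
    for ``n_perm`` equal-size gene sets drawn uniformly without
    replacement from the universe.  Returns (observed, expected, p) with
    the add-one permutation p-value (1 + #{null >= obs}) / (n_perm + 1).
    """
    universe = sorted(gene_intervals)
    called = sorted(set(called_genes))
    if len(called) > len(universe):
        raise ValueError("called gene set larger than the gene universe")
    missing = set(called) - set(universe)
    if missing:
        raise ValueError(f"called genes missing from universe: {sorted(missing)}")
    ivs = [gene_intervals[g] for g in universe]
    near = _near_any(ivs, regions, window_bp)
    gene_pos = {g: i for i, g in enumerate(universe)}
    observed = int(near[[gene_pos[g] for g in called]].sum())
    rng = np.random.default_rng(seed)
    n = len(called)
    null = np.array([near[rng.choice(len(universe), n, replace=False)].sum()
                     for _ in range(n_perm)])
    p = float((1 + np.sum(null >= observed)) / (n_perm + 1))
    return observed, float(null.mean()), p
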