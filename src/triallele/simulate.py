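"""Seeded generators for synthetic inputs with known ground truth.

Three generators mirror the three data layers the pipeline analyses:

* a population allele-frequency landscape with planted windows in which
  populations fall into 1, 2 or 3 haplotype clusters (marine vs. one or
  two freshwater classes),
* F1-cross allele-specific-expression count tables with tissue-specific
  reciprocal allelic imbalance planted in a subset of genes,
* spine-length phenotypes depending linearly on body length, sex and a
  triallelic genotype class.

Every generator is deterministic given its spec (which carries the seed)
and returns a truth table alongside the data, so downstream recovery is
directly measurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GenomicInterval, GenotypeTable, ValidationError, validate_ase_counts

# library plan of the expression study: per cross, 12 dorsal-spine and
# 12 pelvic-spine libraries (one per fish), 6 pectoral-fin and 6 heart
DEFAULT_LIBRARY_PLAN = {"DS": 12, "PS": 12, "PF": 6, "H": 6}


@dataclass
class LandscapeSpec:
    """Plan for a synthetic population allele-frequency landscape.

    ``windows`` lists planted intervals as (interval, n_clusters,
    divergence).  SNPs are biallelic, so at any one SNP the cluster mean
    frequencies can only take two levels; a planted SNP therefore
    separates a bipartition of the clusters, with the two sides'
    frequencies ``divergence`` apart.  For 2-cluster (marine vs.
    freshwater) windows the bipartition is fixed by ecotype; for
    3-cluster windows each SNP distinguishes one randomly chosen cluster
    from the other two, so any cluster pair differs by ``divergence`` at
    ~2/3 of the planted SNPs and the three clusters sit in general
    position (variance along two axes, not one).  Background regions
    share a single mean frequency per SNP.
    """

    n_marine: int = 5
    n_freshwater: int = 10
    chrom: str = "chrI"
    chrom_length: int = 100_000
    snp_density: float = 0.01
    windows: Sequence[tuple[GenomicInterval, int, float]] = ()
    noise_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_marine + self.n_freshwater < 2:
            raise ValidationError("need at least 2 samples")
        if self.snp_density <= 0:
            raise ValidationError("snp_density must be > 0")
        ivs = sorted((iv for iv, _, _ in self.windows),
                     key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            if a.overlaps(b):
                raise ValidationError(f"planted windows overlap: {a} / {b}")
        for iv, k, d in self.windows:
            if k not in (1, 2, 3):
                raise ValidationError(f"n_clusters must be 1, 2 or 3, got {k}")
            if not 0 <= d <= 1:
                raise ValidationError(f"divergence {d} outside [0, 1]")


def _cluster_assignment(n_marine: int, n_freshwater: int, k: int) -> np.ndarray:
    """Partition samples into k clusters aligned with ecotype labels.

    k=2 separates marine from freshwater; k=3 additionally splits the
    freshwater samples into two classes.
    """
    labels = np.zeros(n_marine + n_freshwater, dtype=int)
    if k >= 2:
        labels[n_marine:] = 1
    if k == 3:
        half = n_freshwater // 2
        labels[n_marine + half:] = 2
    return labels


def generate_genotype_landscape(
    spec: LandscapeSpec,
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Simulate the landscape; returns (table, truth table of planted windows)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_marine + spec.n_freshwater
    n_snps = max(1, int(round(spec.snp_density * spec.chrom_length)))
    positions = np.sort(rng.choice(spec.chrom_length, size=min(
        n_snps, spec.chrom_length), replace=False))
    n_snps = len(positions)

    freqs = np.empty((n_snps, n))
    # background: one shared mean per SNP
    base = rng.uniform(0.05, 0.95, size=n_snps)
    freqs[:] = base[:, None]

    for iv, k, div in spec.windows:
        in_win = (positions >= iv.start) & (positions < iv.end)
        if k == 1 or not in_win.any():
            continue
        labels = _cluster_assignment(spec.n_marine, spec.n_freshwater, k)
        idx = np.where(in_win)[0]
        lo = rng.uniform(0.0, 1.0 - div, size=len(idx))
        for row, p0 in zip(idx, lo):
            levels = np.full(k, p0)
            if k == 2:
                levels[1] = p0 + div
            else:  # one cluster vs. the other two, random side up
                levels[rng.integers(k)] = p0 + div
            if rng.integers(2):
                levels = (2 * p0 + div) - levels  # flip which side is high
            freqs[row] = levels[labels]

    if spec.noise_sd > 0:
        freqs = freqs + rng.normal(0.0, spec.noise_sd, size=freqs.shape)
    freqs = np.clip(freqs, 0.0, 1.0)

    samples = ([f"marine{i}" for i in range(spec.n_marine)]
               + [f"fresh{i}" for i in range(spec.n_freshwater)])
    ecotypes = ["marine"] * spec.n_marine + ["freshwater"] * spec.n_freshwater
    sites = pd.DataFrame({
        "chrom": spec.chrom, "pos": positions,
        "ref": "A", "alt": "T",
    })
    table = GenotypeTable(sites, samples, freqs, ecotypes)
    truth = pd.DataFrame(
        [(iv.chrom, iv.start, iv.end, k, d) for iv, k, d in spec.windows],
        columns=["chrom", "start", "end", "n_clusters", "divergence"])
    return table, truth


# ------------------------------------------------------------------ ASE

@dataclass
class AseEffectSpec:
    """Plan for F1-cross allele-specific read counts.

    ``p_short`` / ``p_long`` are the expected freshwater-allele read
    fractions in the spine tissues (DS, PS) of the Marine x Short and
    Marine x Long crosses for genes carrying the planted reciprocal
    effect; control tissues (PF, H) and unplanted genes sit at 0.5.
    Defaults 0.73 / 0.36 reproduce the observed ~2.7-fold up- and
    ~1.8-fold down-regulation of the two freshwater alleles relative to
    marine (0.73/0.27 = 2.7, 0.64/0.36 = 1.78).
    """

    n_genes: int = 50
    n_snps_per_gene: int = 3
    frac_reciprocal: float = 0.2
    p_short: float = 0.73
    p_long: float = 0.36
    depth_mean: float = 60.0
    depth_dispersion: float = 10.0
    library_plan: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_LIBRARY_PLAN))
    seed: int = 0

    def validate(self) -> None:
        for p in (self.p_short, self.p_long):
            if not 0 < p < 1:
                raise ValidationError(f"allelic fraction {p} outside (0, 1)")
        if self.depth_mean < 0:
            raise ValidationError("depth_mean must be >= 0")
        if not 0 <= self.frac_reciprocal <= 1:
            raise ValidationError("frac_reciprocal outside [0, 1]")


def _draw_depth(rng: np.random.Generator, mean: float, dispersion: float,
                size: int) -> np.ndarray:
    if mean <= 0:
        return np.zeros(size, dtype=int)
    # negative binomial with mean `mean` and shape `dispersion`
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def generate_ase_counts(spec: AseEffectSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate ASE count tables; returns (counts, truth table of genes).

    The freshwater allele is written as the reference allele at every SNP
    (``fw_allele == 'ref'``), so the reference-read fraction equals the
    freshwater-allele fraction.  Per library, ref ~ Binomial(depth, p)
    with depth negative-binomially distributed.

    Each cross has 12 fish: fish 1-12 contribute one DS and one PS
    library each, fish 1-6 a PF library and fish 7-12 a heart library,
    mirroring the study's 72-library design.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_recip = int(round(spec.frac_reciprocal * spec.n_genes))
    reciprocal = np.zeros(spec.n_genes, dtype=bool)
    reciprocal[:n_recip] = True

    rows = []
    snp_counter = 0
    for g in range(spec.n_genes):
        gene = f"gene{g:04d}"
        for s in range(spec.n_snps_per_gene):
            snp_id = f"snp{snp_counter:05d}"
            pos = 1000 * snp_counter + 500
            snp_counter += 1
            for cross, p_fw in (("MarineXShort", spec.p_short),
                                ("MarineXLong", spec.p_long)):
                for tissue, n_lib in spec.library_plan.items():
                    p = 0.5
                    if reciprocal[g] and tissue in ("DS", "PS"):
                        p = p_fw
                    depths = _draw_depth(rng, spec.depth_mean,
                                         spec.depth_dispersion, n_lib)
                    refs = rng.binomial(depths, p)
                    for i in range(n_lib):
                        if tissue in ("DS", "PS"):
                            indiv = i + 1
                        elif tissue == "PF":
                            indiv = i + 1
                        else:  # heart libraries come from the other 6 fish
                            indiv = i + 7
                        rows.append((
                            snp_id, "chrI", pos, gene, True, cross, tissue,
                            f"{cross}_{tissue}{i}", f"{cross}_fish{indiv}",
                            int(refs[i]), int(depths[i] - refs[i]), "ref"))
    counts = pd.DataFrame(rows, columns=[
        "snp_id", "chrom", "pos", "gene_id", "exonic", "cross", "tissue",
        "library_id", "individual_id", "ref_count", "alt_count", "fw_allele"])
    counts = validate_ase_counts(counts)
    truth = pd.DataFrame({
        "gene_id": [f"gene{g:04d}" for g in range(spec.n_genes)],
        "reciprocal": reciprocal,
    })
    return counts, truth


# ------------------------------------------------------------------ phenotypes

@dataclass
class PhenotypeSpec:
    """Plan for spine-length phenotypes on a triallelic genotype.

    Spine length = intercept + beta_sl * standard_length + beta_sex * I(male)
    + gamma[genotype] + Normal(0, resid_sd), with genotype classes SS, SL,
    LL drawn at Hardy-Weinberg proportions for Long-allele frequency
    ``long_freq``.  Units are mm; the default body-length distribution
    (52 +/- 7 mm) matches adult wild-caught fish.
    """

    n_fish: int = 300
    intercept: float = 1.0
    beta_sl: float = 0.08
    beta_sex: float = 0.3
    gamma: tuple[float, float, float] = (0.0, 0.5, 1.0)  # SS, SL, LL
    resid_sd: float = 0.5
    long_freq: float = 0.5
    sl_mean: float = 52.0
    sl_sd: float = 7.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_fish <= 0:
            raise ValidationError("n_fish must be > 0")
        if self.resid_sd < 0:
            raise ValidationError("resid_sd must be >= 0")
        if not 0 < self.long_freq < 1:
            raise ValidationError("long_freq outside (0, 1)")


GENOTYPE_CLASSES = ("SS", "SL", "LL")


def gamma_for_target_pve(target_pve: float, resid_sd: float,
                         long_freq: float = 0.5) -> tuple[float, float, float]:
    """Additive genotype effects (0, d, 2d) giving an expected PVE.

    With Hardy-Weinberg genotype dosage X ~ Binomial(2, q), the additive
    effect d*X contributes variance 2 q (1-q) d^2, so
    PVE = 2q(1-q)d^2 / (2q(1-q)d^2 + resid_sd^2).
    """
    if not 0 < target_pve < 100:
        raise ValidationError("target_pve must be in (0, 100)")
    f = target_pve / 100.0
    var_g = f / (1 - f) * resid_sd**2
    d = float(np.sqrt(var_g / (2 * long_freq * (1 - long_freq))))
    return (0.0, d, 2 * d)


def generate_phenotypes(spec: PhenotypeSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate phenotypes; returns (phenotype table, genotype dosage vector).

    The table holds fish_id, sex, standard_length and identically
    generated DS1 / DS2 / PS spine lengths (one draw shared across the
    three columns would hide per-trait residualization, so each trait
    gets independent residual noise around the same genetic effect).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    dosage = rng.binomial(2, spec.long_freq, size=spec.n_fish)
    sex = rng.integers(0, 2, size=spec.n_fish)  # 1 = male
    sl = rng.normal(spec.sl_mean, spec.sl_sd, size=spec.n_fish)
    gamma = np.asarray(spec.gamma)
    mean = (spec.intercept + spec.beta_sl * sl + spec.beta_sex * sex
            + gamma[dosage])
    table = pd.DataFrame({
        "fish_id": [f"fish{i:04d}" for i in range(spec.n_fish)],
        "population": "simulated",
        "sex": np.where(sex == 1, "M", "F"),
        "standard_length": sl,
    })
    for trait in ("DS1", "DS2", "PS"):
        noise = (rng.normal(0.0, spec.resid_sd, size=spec.n_fish)
                 if spec.resid_sd > 0 else 0.0)
        table[trait] = mean + noise
    table["genotype"] = [GENOTYPE_CLASSES[d] for d in dosage]
    return table, dosage
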