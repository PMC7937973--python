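"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates, at desk scale, everything the pipeline consumes:

* a mirror-symmetric face-like landmark template (half-ellipsoid lattice)
  with an explicit left-right pairing map;
* cohorts of landmark configurations built from smooth latent shape fields
  (so nearby landmarks covary, which is what the RV segmentation exploits),
  linear covariate effects with fixed documented coefficients, an optional
  localized group mean shift (the parent-vs-control contrast), and isotropic
  noise;
* genotype panels with Hardy-Weinberg sampling at given MAFs and AR(1)
  block LD generated through a latent Gaussian copula, with optional
  X-chromosome hemizygous male coding;
* discovery summary statistics from a simulated liability, for use as a
  polygenic-score base.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gwas import GenotypeTable

__all__ = [
    "SyntheticTemplate",
    "CohortSpec",
    "GenoSpec",
    "DEFAULT_COVARIATE_EFFECTS",
    "make_template",
    "smooth_field",
    "localized_direction",
    "simulate_cohort",
    "simulate_genotypes",
    "genetic_trait_scores",
    "simulate_trait_scores",
    "make_discovery_sumstats",
]


@dataclass
class SyntheticTemplate:
    """Symmetric landmark template: ``coords`` (p, 3) with midline on x=0 and
    ``pair_map`` an involution pairing left/right homologues."""

    coords: np.ndarray
    pair_map: np.ndarray

    @property
    def p(self) -> int:
        return self.coords.shape[0]


@dataclass
class CohortSpec:
    """Parameters of one simulated cohort.

    ``effect_size`` is the norm of the group mean shift along the unit
    ``effect_direction`` (3p-vector); with the default latent scales this is
    roughly in Mahalanobis units of the latent shape variation.  ``covariates``
    may be supplied; otherwise sex/age/height/weight are drawn internally.
    """

    n_individuals: int
    n_group1: int = 0  # e.g. number of "parents"; rest are unselected
    latent_rank: int = 10
    latent_sd: float = 0.5
    latent_decay: float = 0.9
    effect_direction: np.ndarray | None = None
    effect_size: float = 0.0
    noise_sd: float = 0.01
    covariates: pd.DataFrame | None = None
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.n_group1 <= self.n_individuals):
            raise ValueError("n_group1 must lie in [0, n_individuals]")
        if self.noise_sd <= 0 or self.latent_sd <= 0:
            raise ValueError("all standard deviations must be positive")
        if self.effect_direction is not None:
            d = np.asarray(self.effect_direction, dtype=float)
            if not np.isclose(np.linalg.norm(d), 1.0, atol=1e-6):
                raise ValueError("effect_direction must have unit norm")
            self.effect_direction = d


@dataclass
class GenoSpec:
    """Parameters of one simulated genotype panel.

    SNPs are laid out in LD blocks of ``block_size`` adjacent SNPs; within a
    block adjacent genotype dosages correlate at ~``ld_block_rho`` via an
    AR(1) latent Gaussian copula.  Blocks are split evenly across ``n_chrom``
    chromosomes, positions spaced ``spacing_bp`` apart.  ``causal_snps`` (with
    optional ``causal_weights``) define a genetic score whose population
    variance share in a unit-variance trait is ``h2_target``.
    """

    n_snps: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_rho: float = 0.0
    block_size: int = 10
    n_chrom: int = 2
    spacing_bp: int = 20_000
    include_x: bool = False
    causal_snps: np.ndarray | None = None
    causal_weights: np.ndarray | None = None
    h2_target: float = 0.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.ld_block_rho < 1.0):
            raise ValueError("ld_block_rho must lie in [0, 1)")
        if not (0.0 <= self.h2_target < 1.0):
            raise ValueError("h2_target must lie in [0, 1)")
        if self.causal_snps is not None:
            self.causal_snps = np.asarray(self.causal_snps, dtype=int)
            if self.causal_weights is not None:
                self.causal_weights = np.asarray(self.causal_weights, dtype=float)
                if not np.all(np.isfinite(self.causal_weights)):
                    raise ValueError("causal weights must be finite")


# Fixed, documented linear covariate effects (coefficient per unit of the
# centred covariate, applied along a covariate-specific smooth unit field).
DEFAULT_COVARIATE_EFFECTS = {
    "sex": 0.15,  # per sex class (0/1)
    "age": 0.008,  # per year
    "height": 0.006,  # per cm
    "weight": 0.004,  # per kg
}


def make_template(p: int = 250, seed: int = 0) -> SyntheticTemplate:
    """Mirror-symmetric half-ellipsoid landmark lattice.

    The lattice has ``r`` rows by ``c`` columns with ``c`` odd (the middle
    column sits on the x=0 midline), so ``p`` must have an odd divisor >= 3;
    the odd divisor closest to sqrt(p) is used.  A seeded smooth, symmetric
    jitter makes the grid irregular while preserving exact mirror symmetry.
    """
    if p < 20:
        raise ValueError("p must be >= 20 to form the lattice")
    odd_divisors = [c for c in range(3, p + 1, 2) if p % c == 0 and p // c >= 3]
    if not odd_divisors:
        raise ValueError(
            f"p={p} has no odd divisor >= 3 with >= 3 rows; pick e.g. a multiple of 3 or 5"
        )
    # pick the odd column count giving the squarest lattice
    c = min(odd_divisors, key=lambda d: abs(np.log(d * d / p)))
    r = p // c
    rng = np.random.default_rng(seed)

    theta = np.linspace(0.3 * np.pi, 0.85 * np.pi, r)  # polar: forehead to chin
    phi = np.linspace(-0.45 * np.pi, 0.45 * np.pi, c)  # azimuth: left to right
    theta = theta + rng.normal(0, 0.01, size=r)  # row jitter (shared per row)
    dphi = rng.normal(0, 0.01, size=c // 2)
    jitter = np.concatenate([dphi, [0.0], -dphi[::-1]])  # antisymmetric in phi
    phi = phi + jitter

    ax, ay, az = 1.0, 1.3, 0.75
    T, P = np.meshgrid(theta, phi, indexing="ij")
    x = ax * np.sin(T) * np.sin(P)
    y = ay * np.cos(T)
    z = az * np.sin(T) * np.cos(P)
    coords = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)

    pair_map = np.empty(p, dtype=int)
    for i in range(r):
        for j in range(c):
            pair_map[i * c + j] = i * c + (c - 1 - j)
    # enforce exact mirror symmetry against floating error
    mirrored = coords[pair_map].copy()
    mirrored[:, 0] *= -1
    coords = 0.5 * (coords + mirrored)
    return SyntheticTemplate(coords=coords, pair_map=pair_map)


def _distance_kernel(coords: np.ndarray, length_scale: float) -> np.ndarray:
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=2)
    return np.exp(-d2 / (2.0 * length_scale**2))


def smooth_field(
    template: SyntheticTemplate, rng: np.random.Generator, length_scale: float = 0.35
) -> np.ndarray:
    """Unit-norm smooth random displacement field over the lattice (3p,)."""
    K = _distance_kernel(template.coords, length_scale)
    g = rng.normal(size=(template.p, 3))
    f = K @ g
    return (f / np.linalg.norm(f)).ravel()


def localized_direction(
    template: SyntheticTemplate,
    center: int | None = None,
    length_scale: float = 0.25,
    seed: int = 0,
) -> np.ndarray:
    """Unit-norm displacement field concentrated around one landmark.

    Emulates a localized mean-shape shift (e.g. midfacial or philtrum
    differences): a smooth random field windowed by a Gaussian bump at the
    ``center`` landmark, symmetrized so it respects the template's mirror
    pairing.
    """
    rng = np.random.default_rng(seed)
    if center is None:
        center = int(rng.integers(template.p))
    K = _distance_kernel(template.coords, length_scale)
    g = K @ rng.normal(size=(template.p, 3))
    d2 = np.sum((template.coords - template.coords[center]) ** 2, axis=1)
    bump = np.exp(-d2 / (2.0 * length_scale**2))
    f = g * bump[:, None]
    # mirror-symmetrize: average with the reflected, re-paired field
    fm = f[template.pair_map].copy()
    fm[:, 0] *= -1
    f = 0.5 * (f + fm)
    return (f / np.linalg.norm(f)).ravel()


def _default_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    sex = rng.integers(0, 2, size=n)
    age = rng.normal(35.0, 10.0, size=n)
    height = rng.normal(163.0, 8.0, size=n) + 12.0 * sex
    weight = rng.normal(62.0, 10.0, size=n) + 10.0 * sex
    return pd.DataFrame({"sex": sex, "age": age, "height": height, "weight": weight})


def simulate_cohort(template: SyntheticTemplate, spec: CohortSpec):
    """Simulate landmark configurations for one cohort.

    configuration_i = template + sum_k z_ik b_k + covariate effects
                      + group_i * effect_size * effect_direction + noise,
    with smooth latent bases b_k (scaled latent_sd * latent_decay^k) fixed by
    the spec seed.  Returns (configs (n, p, 3), covariates DataFrame with a
    trailing truth-free copy of what was used, group_labels (n,) in {0, 1}).
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_individuals, template.p

    # multi-scale smooth fields: length scales span global-to-local structure
    # so nearby landmarks covary at every scale, as real facial variation does
    scales = 0.9 * 0.8 ** np.arange(spec.latent_rank)
    scales = np.maximum(scales, 0.12)
    bases = np.stack(
        [smooth_field(template, rng, length_scale=s) for s in scales]
    )  # (rank, 3p)
    sds = spec.latent_sd * spec.latent_decay ** np.arange(spec.latent_rank)

    covs = spec.covariates
    if covs is None:
        covs = _default_covariates(n, rng)
    else:
        covs = covs.reset_index(drop=True)
        if len(covs) != n:
            raise ValueError("covariates length does not match n_individuals")
    cov_fields = {
        name: smooth_field(template, rng, length_scale=0.5)
        for name in covs.columns
        if name in DEFAULT_COVARIATE_EFFECTS
    }

    direction = spec.effect_direction
    if direction is None and spec.effect_size != 0.0:
        direction = localized_direction(template, seed=spec.seed + 1)

    group = np.zeros(n, dtype=int)
    group[: spec.n_group1] = 1

    z = rng.normal(size=(n, spec.latent_rank)) * sds
    flat = np.tile(template.coords.ravel(), (n, 1))
    flat += z @ bases
    for name, fld in cov_fields.items():
        x = covs[name].to_numpy(dtype=float)
        flat += np.outer(x - x.mean(), DEFAULT_COVARIATE_EFFECTS[name] * fld)
    if direction is not None and spec.effect_size != 0.0:
        flat += np.outer(group.astype(float), spec.effect_size * direction)
    flat += rng.normal(scale=spec.noise_sd, size=flat.shape)
    return flat.reshape(n, p, 3), covs, group


def _block_layout(spec: GenoSpec):
    """(chrom, pos) per SNP and block boundaries."""
    m = spec.n_snps
    n_chrom = max(1, spec.n_chrom)
    per = int(np.ceil(m / n_chrom))
    chroms, pos = [], []
    for j in range(m):
        ci = j // per
        name = "X" if (spec.include_x and ci == n_chrom - 1) else str(ci + 1)
        chroms.append(name)
        pos.append((j % per + 1) * spec.spacing_bp)
    starts = list(range(0, m, spec.block_size))
    blocks = [np.arange(s, min(s + spec.block_size, m)) for s in starts]
    # blocks never straddle a chromosome boundary
    fixed = []
    for b in blocks:
        cuts = np.flatnonzero(np.diff([ord(c[0]) if c == "X" else int(c) for c in np.asarray(chroms)[b]]))
        if cuts.size:
            last = 0
            for cpos in list(cuts + 1) + [b.size]:
                fixed.append(b[last:cpos])
                last = cpos
        else:
            fixed.append(b)
    return np.asarray(chroms), np.asarray(pos), [b for b in fixed if b.size]


def simulate_genotypes(
    n: int, spec: GenoSpec, sex: np.ndarray | None = None
) -> GenotypeTable:
    """Hard-call genotype dosages with AR(1) block LD.

    Per block, haplotype alleles are thresholded latent Gaussians with AR(1)
    correlation rho_z = sin(pi * ld_block_rho / 2) (the inverse of the
    Gaussian-copula attenuation at MAF 0.5), giving adjacent-genotype
    correlation ~ ld_block_rho.  Autosomal dosages are in {0, 1, 2}; on an X
    chromosome males carry one haplotype coded {0, 2}.  Dosages count the
    MAJOR allele; a VCF written from this table has REF=major, ALT=minor.
    """
    if n < 2:
        raise ValueError("need n >= 2 individuals")
    rng = np.random.default_rng(spec.seed)
    m = spec.n_snps
    lo, hi = spec.maf_range
    mafs = rng.uniform(lo, hi, size=m)
    chroms, pos, blocks = _block_layout(spec)
    if sex is None:
        sex = rng.integers(0, 2, size=n)
    sex = np.asarray(sex, dtype=int)

    rho_z = np.sin(np.pi * spec.ld_block_rho / 2.0)
    minor = np.zeros((n, m))
    from scipy.stats import norm

    thresh = norm.ppf(mafs)
    for b in blocks:
        k = b.size
        if rho_z > 0 and k > 1:
            L = np.linalg.cholesky(rho_z ** np.abs(np.subtract.outer(range(k), range(k))))
        else:
            L = np.eye(k)
        is_x = chroms[b[0]] == "X"
        for hap in range(2):
            z = rng.normal(size=(n, k)) @ L.T
            alleles = (z < thresh[b]).astype(float)
            if is_x:
                if hap == 0:
                    minor[:, b] += alleles * np.where(sex[:, None] == 1, 2.0, 1.0)
                else:
                    minor[:, b] += np.where(sex[:, None] == 1, 0.0, alleles)
            else:
                minor[:, b] += alleles

    major_dosage = 2.0 - minor
    bases = np.array(["A", "C", "G", "T"])
    a_major = bases[rng.integers(0, 4, size=m)]
    shift = rng.integers(1, 4, size=m)
    a_minor = bases[(np.searchsorted(bases, a_major) + shift) % 4]
    meta = pd.DataFrame(
        {
            "snp": [f"rs{j + 1}" for j in range(m)],
            "chrom": chroms,
            "pos": pos,
            "allele_major": a_major,
            "allele_minor": a_minor,
            "maf": mafs,
        }
    )
    return GenotypeTable(dosages=major_dosage, snp_meta=meta, sex=sex)


def genetic_trait_scores(genotypes: GenotypeTable, spec: GenoSpec) -> np.ndarray:
    """Standardised genetic score of the causal set, scaled to variance h2_target."""
    if spec.causal_snps is None or spec.causal_snps.size == 0:
        return np.zeros(genotypes.n)
    G = genotypes.dosages[:, spec.causal_snps]
    sd = G.std(axis=0)
    sd[sd < 1e-12] = 1.0
    Gs = (G - G.mean(axis=0)) / sd
    w = (
        spec.causal_weights
        if spec.causal_weights is not None
        else np.ones(spec.causal_snps.size)
    )
    raw = Gs @ w
    s = raw.std()
    if s < 1e-12:
        return np.zeros(genotypes.n)
    return raw / s * np.sqrt(spec.h2_target)


def simulate_trait_scores(
    genotypes: GenotypeTable, spec: GenoSpec, seed: int | None = None
) -> np.ndarray:
    """Unit-variance trait: genetic score (variance h2_target) plus noise."""
    rng = np.random.default_rng(spec.seed + 7919 if seed is None else seed)
    g = genetic_trait_scores(genotypes, spec)
    return g + rng.normal(scale=np.sqrt(1.0 - spec.h2_target), size=genotypes.n)


def make_discovery_sumstats(
    genotypes: GenotypeTable, liability: np.ndarray
) -> pd.DataFrame:
    """Per-SNP regression summary statistics of a simulated discovery liability.

    Linear score regression of the liability on each SNP dosage; the effect
    allele A1 is the counted (major) allele.  Output columns are exactly
    SNP, CHR, BP, A1, A2, BETA, SE, P.
    """
    y = np.asarray(liability, dtype=float)
    if y.std() < 1e-12:
        raise ValueError("degenerate liability (no variance)")
    if y.size != genotypes.n:
        raise ValueError("liability length mismatch")
    from scipy import stats as sps

    G = genotypes.dosages
    n = y.size
    Gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", Gc, Gc)
    sxx_safe = np.where(sxx > 1e-12, sxx, np.nan)
    beta = (yc @ Gc) / sxx_safe
    rss = np.maximum(yc @ yc - beta**2 * sxx_safe, 0.0)
    se = np.sqrt(rss / (n - 2) / sxx_safe)
    t = beta / se
    p = np.maximum(2.0 * sps.t.sf(np.abs(t), df=n - 2), np.finfo(float).tiny)
    meta = genotypes.snp_meta
    out = pd.DataFrame(
        {
            "SNP": meta["snp"],
            "CHR": meta["chrom"],
            "BP": meta["pos"],
            "A1": meta["allele_major"],
            "A2": meta["allele_minor"],
            "BETA": beta,
            "SE": se,
            "P": p,
        }
    )
    return out.dropna().reset_index(drop=True)
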