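"""Synthetic reference panels and GWAS summary statistics with known truth.

The generator emulates the three data layers the basis method consumes:

* a reference panel with contiguous LD blocks, AR(1) within-block
  correlation (r between SNPs i and j is rho^|i-j|) and uniform alt-allele
  frequencies;
* multiple case-control traits whose true per-SNP effects are linear
  combinations of a few sparse latent components (at most one causal SNP
  per block per component, matching the fine-mapping assumption), observed
  with LD-correlated sampling noise scaled by sample size plus optional
  per-study technical noise;
* null studies (all true effects zero), the finite-sample analogue of the
  basis' synthetic control.

Reported standard errors use the exact case-control approximation
se = sigma_MAF(f) / sqrt(N_eff) with N_eff = 4 / (1/N_cases + 1/N_controls),
and sampling noise is drawn from exactly that covariance, so closed-form
variance calculations are exact oracles for these data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from gwasbasis.harmonise import ReferencePanel, SummaryStats, variant_ids
from gwasbasis.shrinkage import sigma_maf

# non-complementary allele pairs only, so no simulated SNP is palindromic
_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"),
                 ("C", "A"), ("C", "T"), ("G", "A"), ("G", "T")]


@dataclass
class SimulationScenario:
    """Parameters of one synthetic study system.

    Defaults describe a generic basis-building setting: 13 traits sharing 3
    latent components over 20,000 SNPs in 200 blocks of 100, moderate local
    LD (rho = 0.9 between adjacent SNPs), common variants only, causal log
    odds ratios of SD 0.15 (odds ratios mostly 0.9-1.2) in 10% of blocks
    per component, and 10,000 cases / 10,000 controls per study.
    """

    n_snps: int = 20_000
    n_blocks: int = 200
    within_block_ld: float = 0.9
    maf_low: float = 0.05
    n_traits: int = 13
    n_components_true: int = 3
    component_loadings: np.ndarray | None = None
    causal_density: float = 0.1
    effect_sd: float = 0.15
    n_cases: int | Sequence[int] = 10_000
    n_controls: int | Sequence[int] = 10_000
    technical_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps <= 0 or self.n_blocks <= 0 or self.n_traits <= 0:
            raise ValueError("counts must be positive")
        if self.n_snps % self.n_blocks:
            raise ValueError("n_snps must be a multiple of n_blocks")
        if not 0 <= self.within_block_ld < 1:
            raise ValueError("within_block_ld must lie in [0, 1)")
        if not 0.01 <= self.maf_low < 0.5:
            raise ValueError("maf_low must lie in [0.01, 0.5)")
        if not 0 < self.causal_density <= 1:
            raise ValueError("causal_density must lie in (0, 1]")

    def per_trait(self, value) -> np.ndarray:
        out = np.broadcast_to(np.asarray(value, int), (self.n_traits,))
        return np.array(out)


def _effective_n(n_cases, n_controls) -> float:
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)


def _ar1_matrix(size: int, rho: float) -> np.ndarray:
    idx = np.arange(size)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def simulate_panel(scenario: SimulationScenario,
                   rng: np.random.Generator | None = None) -> ReferencePanel:
    """Block-structured reference panel, deterministic given the seed."""
    rng = np.random.default_rng(scenario.seed) if rng is None else rng
    p = scenario.n_snps
    block_size = p // scenario.n_blocks
    block = np.repeat([f"B{i:04d}" for i in range(scenario.n_blocks)],
                      block_size)
    within = np.tile(np.arange(block_size), scenario.n_blocks)
    pos = (np.repeat(np.arange(scenario.n_blocks), block_size) * 1_000_000
           + within * 5_000 + 1)
    pairs = rng.integers(0, len(_ALLELE_PAIRS), size=p)
    ref = np.array([_ALLELE_PAIRS[i][0] for i in pairs])
    alt = np.array([_ALLELE_PAIRS[i][1] for i in pairs])
    f = rng.uniform(scenario.maf_low, 1.0 - scenario.maf_low, size=p)
    variants = pd.DataFrame(
        {"chrom": "1", "pos": pos, "ref": ref, "alt": alt,
         "alt_freq": f, "block": block})
    variants.index = variant_ids(variants)
    r = _ar1_matrix(block_size, scenario.within_block_ld)
    ld = {b: r for b in pd.unique(block)}
    return ReferencePanel(variants=variants, ld=ld)


def _block_chol(panel: ReferencePanel) -> dict:
    chol = {}
    cache: dict[int, np.ndarray] = {}
    for blk, rows in panel.block_slices().items():
        r = panel.ld_for(blk)
        key = id(panel.ld[blk]) if panel.ld and blk in panel.ld else -len(rows)
        if key not in cache:
            cache[key] = np.linalg.cholesky(r + 1e-12 * np.eye(len(rows)))
        chol[blk] = (rows, cache[key])
    return chol


def draw_study(
    panel: ReferencePanel,
    beta_true: np.ndarray,
    n_cases: int,
    n_controls: int,
    rng: np.random.Generator,
    trait_id: str = "study",
    technical_noise_sd: float = 0.0,
    extra_beta_noise: np.ndarray | None = None,
) -> SummaryStats:
    """One case-control GWAS observing ``beta_true`` with LD-aware noise.

    ``extra_beta_noise`` is added verbatim to beta_hat (e.g. a cohort-shared
    error component); it is not reflected in the reported standard errors,
    like real technical noise.
    """
    f = panel.variants["alt_freq"].to_numpy(float)
    se = sigma_maf(f) / np.sqrt(_effective_n(n_cases, n_controls))
    noise = np.empty(panel.n_variants)
    for blk, (rows, chol) in _block_chol(panel).items():
        noise[rows] = chol @ rng.standard_normal(len(rows))
    beta_hat = np.asarray(beta_true, float) + se * noise
    if technical_noise_sd > 0:
        beta_hat = beta_hat + rng.normal(0.0, technical_noise_sd,
                                         panel.n_variants)
    if extra_beta_noise is not None:
        beta_hat = beta_hat + np.asarray(extra_beta_noise, float)
    data = panel.variants[["chrom", "pos", "ref", "alt"]].copy()
    data["beta"] = beta_hat
    data["se"] = se
    return SummaryStats(trait_id=trait_id, data=data, n_cases=n_cases,
                        n_controls=n_controls, provenance="simulated",
                        aligned=True)


def simulate_traits(
    scenario: SimulationScenario,
    panel: ReferencePanel,
    rng: np.random.Generator | None = None,
) -> tuple[list[SummaryStats], dict]:
    """Multi-trait GWAS sharing latent components, plus the ground truth.

    True effects are ``loadings @ components`` where each latent component
    is a sparse p-vector with at most one causal SNP per block (causal
    blocks chosen at ``causal_density``, per-SNP effects N(0, effect_sd^2))
    and loadings default to standard normal trait-by-component draws.

    Returns the studies and a dict with ``loadings`` (traits x K),
    ``components`` (K x p), ``beta_true`` (traits x p) and ``causal`` (per
    component, the causal variant ids).
    """
    rng = np.random.default_rng(scenario.seed) if rng is None else rng
    p = panel.n_variants
    k = scenario.n_components_true
    blocks = panel.block_slices()
    block_names = list(blocks)
    n_causal_blocks = max(1, round(scenario.causal_density * len(block_names)))
    components = np.zeros((k, p))
    causal: list[pd.Index] = []
    for c in range(k):
        chosen = rng.choice(len(block_names), size=n_causal_blocks,
                            replace=False)
        snps = np.array([rng.choice(blocks[block_names[b]]) for b in chosen])
        components[c, snps] = rng.normal(0.0, scenario.effect_sd,
                                         size=snps.size)
        causal.append(panel.index[np.sort(snps)])
    if scenario.component_loadings is None:
        loadings = rng.standard_normal((scenario.n_traits, k))
    else:
        loadings = np.asarray(scenario.component_loadings, float)
        if loadings.shape != (scenario.n_traits, k):
            raise ValueError("component_loadings must be n_traits x K")
    beta_true = loadings @ components
    ncase = scenario.per_trait(scenario.n_cases)
    nctrl = scenario.per_trait(scenario.n_controls)
    studies = [
        draw_study(panel, beta_true[t], int(ncase[t]), int(nctrl[t]), rng,
                   trait_id=f"trait{t + 1:02d}",
                   technical_noise_sd=scenario.technical_noise_sd)
        for t in range(scenario.n_traits)
    ]
    truth = {"loadings": loadings, "components": components,
             "beta_true": beta_true, "causal": causal}
    return studies, truth


def simulate_null_study(
    panel: ReferencePanel,
    n_cases: int,
    n_controls: int,
    seed: int | np.random.Generator,
    trait_id: str = "null",
) -> SummaryStats:
    """A study with every true effect zero (finite-sample null control)."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    return draw_study(panel, np.zeros(panel.n_variants), n_cases, n_controls,
                      rng, trait_id=trait_id)


def simulate_null_betas(
    panel: ReferencePanel,
    n_studies: int,
    n_cases: int,
    n_controls: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised null draws: (n_studies x p) beta_hat matrix and shared se.

    Equivalent to stacking :func:`simulate_null_study` outputs with one
    shared sample size, but drawn in one pass for calibration experiments.
    """
    f = panel.variants["alt_freq"].to_numpy(float)
    se = sigma_maf(f) / np.sqrt(_effective_n(n_cases, n_controls))
    betas = np.empty((n_studies, panel.n_variants))
    for blk, (rows, chol) in _block_chol(panel).items():
        z = rng.standard_normal((n_studies, len(rows)))
        betas[:, rows] = z @ chol.T
    return betas * se, se


def latent_recovery_scenario(n_traits: int = 10, seed: int = 0,
                             n_snps: int = 20_000, n_blocks: int = 200,
                             strengths=(1.8, 1.0, 0.55)) -> SimulationScenario:
    """Scenario with K = 3 identifiable latent components.

    Loadings are orthogonalised trait-by-component draws scaled to distinct
    per-component strengths, reflecting distinct latent risk processes of
    differing overall contribution — the setting in which PCA axes are
    expected to line up with the generating factors rather than an
    arbitrary rotation of them.
    """
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((n_traits, len(strengths)))
    q, _ = np.linalg.qr(raw)
    loadings = q * np.sqrt(n_traits) @ np.diag(strengths)
    return SimulationScenario(
        n_snps=n_snps, n_blocks=n_blocks, n_traits=n_traits,
        n_components_true=len(strengths), component_loadings=loadings,
        causal_density=0.2, seed=seed)


@dataclass
class PairedCohortScenario:
    """Paired large/small study design probing shrinkage vs naive bases.

    Each disease has its own sparse causal architecture, one moderately
    sized GWAS used to build the basis, and one small biobank replicate
    that is only projected. All small replicates come from a single cohort
    with shared controls, modelled as an error component drawn once and
    added to every small study, scaled relative to the small-study sampling
    error (``shared_noise_scale``). Basis-study sampling noise is chosen
    comparable in total magnitude to the disease signal, as in real GWAS
    where most SNPs are null: a naive (unshrunk) basis then spends its
    components partly on study noise, so projected replicates land near the
    origin and cluster with each other, while continuous shrinkage
    suppresses null-SNP noise and the replicates land beside their disease.
    """

    n_diseases: int = 4
    n_snps: int = 6_000
    n_blocks: int = 60
    within_block_ld: float = 0.9
    maf_low: float = 0.05
    causal_blocks_per_disease: int = 25
    effect_size: float = 0.12
    n_large: int = 5_000
    n_small: int = 1_000
    shared_noise_scale: float = 1.5
    technical_noise_sd: float = 0.005
    seed: int = 0


def simulate_paired_cohorts(
    scenario: PairedCohortScenario,
) -> tuple[ReferencePanel, list[SummaryStats], list[SummaryStats], dict]:
    """Simulate the paired large/small cohort design.

    Returns the panel, the basis (large) studies, the small replicates to
    project, and a truth dict mapping each small study id to its disease's
    large study id.
    """
    rng = np.random.default_rng(scenario.seed)
    panel_sc = SimulationScenario(
        n_snps=scenario.n_snps, n_blocks=scenario.n_blocks,
        within_block_ld=scenario.within_block_ld, maf_low=scenario.maf_low,
        n_traits=scenario.n_diseases, seed=scenario.seed)
    panel = simulate_panel(panel_sc, rng)
    blocks = panel.block_slices()
    block_names = list(blocks)

    beta_true = {}
    for d in range(scenario.n_diseases):
        chosen = rng.choice(len(block_names),
                            size=scenario.causal_blocks_per_disease,
                            replace=False)
        snps = np.array([rng.choice(blocks[block_names[b]]) for b in chosen])
        b = np.zeros(panel.n_variants)
        b[snps] = rng.choice([-1.0, 1.0], size=snps.size) * scenario.effect_size
        beta_true[f"disease{d + 1}"] = b

    f = panel.variants["alt_freq"].to_numpy(float)
    se_small = sigma_maf(f) / np.sqrt(_effective_n(scenario.n_small,
                                                   scenario.n_small))
    cohort_noise = (scenario.shared_noise_scale * se_small
                    * rng.standard_normal(panel.n_variants))

    larges, smalls = [], []
    pairs = {}
    for name, b in beta_true.items():
        larges.append(draw_study(
            panel, b, scenario.n_large, scenario.n_large, rng,
            trait_id=f"{name}_large",
            technical_noise_sd=scenario.technical_noise_sd))
    for name, b in beta_true.items():
        smalls.append(draw_study(
            panel, b, scenario.n_small, scenario.n_small, rng,
            trait_id=f"{name}_small",
            technical_noise_sd=scenario.technical_noise_sd,
            extra_beta_noise=cohort_noise))
        pairs[f"{name}_small"] = f"{name}_large"
    truth = {"pairs": pairs, "beta_true": beta_true}
    return panel, larges, smalls, truth


def replicate_pairing(basis, larges, smalls, pairs) -> int:
    """Count small replicates whose nearest trait in basis space is their
    disease's basis study (nearest neighbour over projected delta vectors).
    """
    from gwasbasis.projection import project

    deltas = {ss.trait_id: project(basis, ss).delta for ss in larges + smalls}
    ids = list(deltas)
    x = np.array([deltas[i] for i in ids])
    good = 0
    for small, large in pairs.items():
        i = ids.index(small)
        dist = np.linalg.norm(x - x[i], axis=1)
        dist[i] = np.inf
        good += ids[int(np.argmin(dist))] == large
    return good
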