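"""Project independent GWAS into a fitted basis and test for association.

A projected trait is summarised by delta_hat, the difference between its
projected (shrunk) effects and the projected all-zero synthetic control.
Because centring cancels in the difference, delta_hat is simply
gamma_hat' Q_s, a fixed linear score of the study's effect estimates with
weights learnt from independent data. Its sampling covariance therefore
follows from the per-SNP standard errors and the reference-panel LD:

    Var(delta)_kl = sum_blocks sum_{i,j in block} a_ik a_jl r_ij se_i se_j,

with a_ik = Qs_ik * w_i / sigma_MAF_i and cross-block correlation zero.
The global null delta = 0 is tested with T = delta' V^+ delta ~ chi-square
with df = rank(V); each component additionally gets a two-sided normal test,
and Benjamini-Hochberg FDR is applied within user-defined trait categories.

Basis variants missing from a projected study have gamma set to 0, which
biases delta toward 0 (conservative; large missingness costs power, so a
warning is emitted above 5% by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm
from statsmodels.stats.multitest import multipletests

from gwasbasis.basis import Basis
from gwasbasis.harmonise import ReferencePanel, SummaryStats
from gwasbasis.shrinkage import ShrinkageWeights, shrink

logger = logging.getLogger(__name__)

MISSING_WARN_FRACTION = 0.05


@dataclass
class Projection:
    """One projected trait: delta, covariance and test results."""

    trait_id: str
    delta: np.ndarray
    var_delta: np.ndarray | None = None
    z: np.ndarray | None = None
    p_component: np.ndarray | None = None
    chi2_stat: float | None = None
    df: int | None = None
    p_overall: float | None = None
    fdr_component: np.ndarray | None = None
    fdr_overall: float | None = None
    missing_fraction: float = 0.0
    category: str = "default"

    @property
    def m(self) -> int:
        return self.delta.size

    def table(self) -> pd.DataFrame:
        """Per-component long-format table (Table-S10-like layout)."""
        m = self.m
        d = {
            "trait": self.trait_id,
            "PC": [f"PC{k + 1}" for k in range(m)],
            "delta": self.delta,
        }
        if self.var_delta is not None:
            d["var.delta"] = np.diag(self.var_delta)
        if self.z is not None:
            d["z"] = self.z
        if self.p_component is not None:
            d["p.delta"] = self.p_component
        if self.fdr_component is not None:
            d["fdr.delta"] = self.fdr_component
        if self.p_overall is not None:
            d["p.overall"] = self.p_overall
        if self.fdr_overall is not None:
            d["fdr.overall"] = self.fdr_overall
        return pd.DataFrame(d)


def _shrunk_for_projection(basis: Basis, ss: SummaryStats,
                           weights: ShrinkageWeights | None):
    if weights is None:
        weights = ShrinkageWeights(
            index=basis.variant_index, sigma_maf=basis.sigma_maf, w=basis.w,
            prior=basis.prior)
    gamma = shrink(ss, weights, basis.mode).to_numpy(float)
    missing = ~np.isfinite(gamma)
    frac = float(missing.mean())
    if frac > MISSING_WARN_FRACTION:
        logger.warning("%s: %.1f%% of basis variants missing; their effects "
                       "are set to 0, biasing delta toward the null",
                       ss.trait_id, 100 * frac)
    gamma[missing] = 0.0
    return gamma, frac


def project(basis: Basis, ss: SummaryStats,
            weights: ShrinkageWeights | None = None) -> Projection:
    """Project one harmonised study; returns delta only.

    The study must already be aligned to the basis variant index (see
    :func:`gwasbasis.harmonise.align_to_panel`). Shrinkage reuses the w and
    sigma_MAF frozen in the basis unless ``weights`` overrides them.
    """
    if not ss.index.equals(basis.variant_index):
        raise ValueError(
            f"{ss.trait_id}: study is not aligned to the basis variant index")
    gamma, frac = _shrunk_for_projection(basis, ss, weights)
    delta = gamma @ basis.projection_rotation()
    return Projection(trait_id=ss.trait_id, delta=delta, missing_fraction=frac)


def delta_covariance(
    basis: Basis,
    ss: SummaryStats,
    panel: ReferencePanel,
    weights: ShrinkageWeights | None = None,
    diagonal_ld: bool = False,
) -> np.ndarray:
    """Delta-method covariance of delta under block-diagonal panel LD.

    Missing variants contribute zero (they enter the score with gamma fixed
    at 0, not as random quantities). ``diagonal_ld=True`` ignores LD and
    uses independent SNPs; otherwise blocks containing SNPs with nonzero
    projection weight but no LD matrix raise.
    """
    if weights is None:
        sig, w = basis.sigma_maf, basis.w
    else:
        wa = weights.reindex(basis.variant_index)
        sig, w = wa.sigma_maf, wa.w
    qs = basis.projection_rotation()
    if basis.mode == "continuous":
        a = qs * (w / sig)[:, None]
    elif basis.mode == "naive":
        a = qs
    else:  # z_threshold: projected score is sum Q_ik z_i over kept SNPs
        a = qs  # d(z)/d(beta) = 1/se, folded into se below
    se = ss.data["se"].reindex(basis.variant_index).to_numpy(float)
    observed = np.isfinite(se) & np.isfinite(
        ss.data["beta"].reindex(basis.variant_index).to_numpy(float))
    se = np.where(observed, se, 0.0)
    if basis.mode == "z_threshold":
        se = np.where(observed, 1.0, 0.0)  # Var(z) = 1

    sub = panel.subset(basis.variant_index)
    if len(sub.variants) != basis.n_variants:
        raise ValueError("panel does not cover the basis variant index")
    m = a.shape[1]
    v = np.zeros((m, m))
    active = np.any(a != 0, axis=1) & (se > 0)
    missing_ld = []
    for blk, rows in sub.block_slices().items():
        if not active[rows].any():
            continue
        ab = a[rows]
        sb = se[rows]
        if diagonal_ld:
            v += (ab * (sb**2)[:, None]).T @ ab
            continue
        if sub.ld is None or blk not in sub.ld:
            missing_ld.append(blk)
            continue
        r = sub.ld_for(blk)
        cov = r * np.outer(sb, sb)
        v += ab.T @ cov @ ab
    if missing_ld:
        raise ValueError(
            f"no LD available for blocks containing driver SNPs: "
            f"{missing_ld[:10]}")
    return 0.5 * (v + v.T)


def test_overall(delta: np.ndarray, var_delta: np.ndarray,
                 rcond: float = 1e-10) -> tuple[float, int, float]:
    """Chi-square test of the global null delta = 0.

    Uses the Moore-Penrose pseudo-inverse with rank detection, so a
    degenerate covariance simply reduces the degrees of freedom. Returns
    (statistic, df, p).
    """
    v = np.asarray(var_delta, float)
    evals, evecs = np.linalg.eigh(0.5 * (v + v.T))
    cut = rcond * max(evals.max(), 0.0)
    keep = evals > cut
    rank = int(keep.sum())
    if rank == 0:
        return 0.0, 0, 1.0
    proj = evecs[:, keep].T @ np.asarray(delta, float)
    t = float(proj @ (proj / evals[keep]))
    return t, rank, float(chi2.sf(t, rank))


def test_components(delta: np.ndarray, var_delta: np.ndarray):
    """Per-component z = delta_k / sqrt(V_kk) and two-sided normal p."""
    var = np.diag(np.asarray(var_delta, float))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.asarray(delta, float) / np.sqrt(var)
    z = np.where(np.isfinite(z), z, 0.0)
    p = 2.0 * norm.sf(np.abs(z))
    return z, p


def project_study(
    basis: Basis,
    ss: SummaryStats,
    panel: ReferencePanel,
    weights: ShrinkageWeights | None = None,
    category: str = "default",
    diagonal_ld: bool = False,
) -> Projection:
    """Full single-study projection: delta, covariance and raw tests."""
    pr = project(basis, ss, weights)
    v = delta_covariance(basis, ss, panel, weights, diagonal_ld=diagonal_ld)
    t, df, p_overall = test_overall(pr.delta, v)
    z, p_comp = test_components(pr.delta, v)
    pr.var_delta = v
    pr.chi2_stat, pr.df, pr.p_overall = t, df, p_overall
    pr.z, pr.p_component = z, p_comp
    pr.category = category
    return pr


def fdr_adjust(pvals, grouping=None) -> np.ndarray:
    """Benjamini-Hochberg step-up, run independently within each group."""
    p = np.asarray(pvals, float)
    out = np.empty_like(p)
    if grouping is None:
        grouping = np.zeros(p.size)
    groups = np.asarray(grouping)
    for g in pd.unique(groups):
        mask = groups == g
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def flag_significant(
    projections: Sequence[Projection],
    overall_fdr_threshold: float = 0.01,
    component_fdr_threshold: float = 0.01,
) -> pd.DataFrame:
    """Annotate projections with FDR and significance flags.

    Overall FDR is computed across traits within each projection's category;
    per-component FDR likewise, independently per component. A trait is
    overall-significant when fdr_overall < threshold (strict), and
    component-significant when additionally that component's FDR < threshold
    — the conjunction rule, so nothing is component-significant for a trait
    that is not significant overall. Mutates the projections in place and
    returns the combined long-format table.
    """
    cats = np.array([pr.category for pr in projections])
    p_overall = np.array([pr.p_overall for pr in projections], float)
    if np.any(~np.isfinite(p_overall)):
        raise ValueError("all projections need p_overall; run project_study")
    fdr_overall = fdr_adjust(p_overall, cats)
    m = projections[0].m
    p_comp = np.vstack([pr.p_component for pr in projections])
    fdr_comp = np.empty_like(p_comp)
    for k in range(m):
        fdr_comp[:, k] = fdr_adjust(p_comp[:, k], cats)
    rows = []
    for i, pr in enumerate(projections):
        pr.fdr_overall = float(fdr_overall[i])
        pr.fdr_component = fdr_comp[i]
        tab = pr.table()
        tab["category"] = pr.category
        tab["significant.overall"] = pr.fdr_overall < overall_fdr_threshold
        tab["significant.component"] = (
            tab["significant.overall"]
            & (tab["fdr.delta"] < component_fdr_threshold)
        )
        rows.append(tab)
    return pd.concat(rows, ignore_index=True)
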