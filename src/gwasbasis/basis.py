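"""Fit the shared-risk basis: PCA of shrunk effects, rank choice, driver SNPs.

The basis is a plain mean-centred PCA of the traits-by-SNPs matrix of shrunk
effects, with one synthetic "control" trait whose effects are all zero (the
limit of a null GWAS with infinite sample size). Trailing components carry
noise, so the retained rank m is the smallest truncation rank minimising the
mean squared reconstruction error; for generic data this is n - 1 because
column centring removes exactly one dimension.

Each retained rotation column Q_k is then hard-thresholded at the largest
alpha_k for which the distortion D_k(alpha) = 1 - cor(Mc Q_k, Mc Q_k(alpha))
stays below a tolerance (default 1e-3), where Mc is the centred training
matrix. Variants surviving the threshold are the component's "driver SNPs";
the sparsified rotation is what projection uses.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from gwasbasis.harmonise import SummaryStats
from gwasbasis.shrinkage import ShrinkagePrior, ShrinkageWeights, shrink

CONTROL_LABEL = "control"

_FORMAT_VERSION = "gwasbasis-basis-1"

#: default sparsification tolerance for D_k(alpha)
DEFAULT_TOL = 1e-3

_RANK_TIE_TOL = 1e-12


@dataclass
class EffectMatrix:
    """Traits x SNPs matrix of (shrunk) effects, last row the zero control."""

    values: pd.DataFrame
    mode: str = "continuous"

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("effect matrix must have no missing entries")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate trait labels in effect matrix")

    @property
    def traits(self) -> list:
        return list(self.values.index)

    @property
    def variant_index(self) -> pd.Index:
        return self.values.columns

    def centred(self) -> tuple[np.ndarray, np.ndarray]:
        x = self.values.to_numpy(float)
        mu = x.mean(axis=0)
        return x - mu, mu


def assemble(
    studies: Sequence[SummaryStats],
    weights: ShrinkageWeights,
    mode: str = "continuous",
    control_label: str = CONTROL_LABEL,
) -> EffectMatrix:
    """Stack shrunk studies into a trait x SNP matrix plus the zero control."""
    rows = {}
    for ss in studies:
        if ss.trait_id in rows:
            raise ValueError(f"duplicate trait id {ss.trait_id!r}")
        g = shrink(ss, weights, mode)
        if g.isna().any():
            raise ValueError(
                f"{ss.trait_id}: missing effects on the shared index; "
                "intersect studies before assembling")
        rows[ss.trait_id] = g.to_numpy()
    if control_label in rows:
        raise ValueError(f"trait id collides with control label {control_label!r}")
    rows[control_label] = np.zeros(len(weights.index))
    values = pd.DataFrame.from_dict(rows, orient="index", columns=weights.index)
    return EffectMatrix(values=values, mode=mode)


@dataclass
class Basis:
    """A fitted (and optionally sparsified) PCA basis.

    ``rotation`` is p x m with orthonormal columns; ``scores`` are the
    centred training traits projected through it (n x m). ``sigma_maf`` and
    ``w`` freeze the training shrinkage so projected studies are shrunk
    identically. After :func:`sparsify`, ``sparse_rotation`` holds the
    hard-thresholded rotation and ``alpha`` the per-component thresholds.
    """

    traits: list
    variant_index: pd.Index
    col_means: np.ndarray
    rotation: np.ndarray
    scores: np.ndarray
    singular_values: np.ndarray
    mode: str
    sigma_maf: np.ndarray
    w: np.ndarray
    prior: ShrinkagePrior = field(default_factory=ShrinkagePrior)
    tol: float = DEFAULT_TOL
    alpha: np.ndarray | None = None
    sparse_rotation: np.ndarray | None = None
    control_label: str = CONTROL_LABEL

    @property
    def m(self) -> int:
        """Number of retained components."""
        return self.rotation.shape[1]

    @property
    def n_variants(self) -> int:
        return len(self.variant_index)

    def driver_snps(self, k: int) -> pd.Index:
        """Variants with a nonzero entry in sparsified component k."""
        if self.sparse_rotation is None:
            raise ValueError("basis has not been sparsified")
        return self.variant_index[self.sparse_rotation[:, k] != 0]

    def projection_rotation(self) -> np.ndarray:
        """Rotation used for projection: sparse if available, else full."""
        return (self.sparse_rotation
                if self.sparse_rotation is not None else self.rotation)

    def truncate(self, m: int) -> "Basis":
        if not 1 <= m <= self.m:
            raise ValueError(f"cannot truncate rank-{self.m} basis to m={m}")
        return replace(
            self,
            rotation=self.rotation[:, :m],
            scores=self.scores[:, :m],
            singular_values=self.singular_values[:m],
            alpha=None if self.alpha is None else self.alpha[:m],
            sparse_rotation=(None if self.sparse_rotation is None
                             else self.sparse_rotation[:, :m]),
        )


def fit_basis(
    M: EffectMatrix,
    weights: ShrinkageWeights | None = None,
    n_components: int | None = None,
) -> Basis:
    """Mean-centre columns and decompose by thin SVD.

    Component signs are fixed so each rotation column's largest-magnitude
    entry is positive (PCA signs are otherwise arbitrary and would break
    serialisation and regression tests). Columns are centred but not
    variance-scaled.
    """
    n = len(M.traits)
    if n < 3:
        raise ValueError("need at least 3 trait rows (including the control)")
    xc, mu = M.centred()
    if not np.any(xc):
        raise ValueError("degenerate all-zero effect matrix")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    ncomp = min(n, xc.shape[1]) if n_components is None else n_components
    u, s, vt = u[:, :ncomp], s[:ncomp], vt[:ncomp]
    q = vt.T
    # deterministic sign: largest-|.| entry of each column positive
    flip = np.sign(q[np.argmax(np.abs(q), axis=0), np.arange(q.shape[1])])
    flip[flip == 0] = 1.0
    q = q * flip
    scores = xc @ q
    if weights is not None:
        w_aligned = weights.reindex(M.variant_index)
        sig, w = w_aligned.sigma_maf, w_aligned.w
        prior = weights.prior
    else:
        sig = np.ones(xc.shape[1])
        w = np.ones(xc.shape[1])
        prior = ShrinkagePrior()
    return Basis(
        traits=M.traits,
        variant_index=M.variant_index,
        col_means=mu,
        rotation=q,
        scores=scores,
        singular_values=s,
        mode=M.mode,
        sigma_maf=np.asarray(sig, float),
        w=np.asarray(w, float),
        prior=prior,
    )


def reconstruction_mse(M: EffectMatrix, basis: Basis) -> np.ndarray:
    """Mean squared error of the rank-m' reconstruction, m' = 1..ncomp.

    The rank-m' reconstruction keeps the leading m' components; by the
    Eckart-Young theorem the MSE equals the mean of the squared discarded
    singular values. Computed explicitly against the centred matrix so the
    result is an honest reconstruction error, not a formula shortcut.
    """
    xc, _ = M.centred()
    q = basis.rotation
    scores = xc @ q
    mse = np.empty(q.shape[1])
    recon = np.zeros_like(xc)
    for k in range(q.shape[1]):
        recon += np.outer(scores[:, k], q[:, k])
        mse[k] = np.mean((xc - recon) ** 2)
    return mse


def select_rank(M: EffectMatrix, basis: Basis) -> int:
    """Smallest truncation rank minimising the reconstruction MSE.

    Ties within an absolute tolerance of 1e-12 (relative to the leading
    error) are broken toward the smaller rank. For generic centred data
    this returns n - 1: centring removes one dimension, so the last
    component adds nothing.
    """
    mse = reconstruction_mse(M, basis)
    tol = _RANK_TIE_TOL * max(1.0, float(mse[0]))
    best = float(mse.min())
    return int(np.flatnonzero(mse <= best + tol)[0]) + 1


def _distortion_scan(xc: np.ndarray, q_k: np.ndarray):
    """D_k over the grid of distinct |Q_ik| thresholds (exhaustive scan).

    Returns (grid, D) where grid are candidate alpha values in increasing
    order and D[j] = 1 - cor(xc @ q_k, xc @ mask(q_k, grid[j])). Thresholds
    that zero the whole column give D = +inf (correlation undefined).
    """
    full = xc @ q_k
    fc = full - full.mean()
    denom_full = float(fc @ fc)
    if denom_full <= 0:
        raise ValueError("component score has zero variance on training data")
    absq = np.abs(q_k)
    order = np.argsort(absq, kind="stable")
    # cumulative per-trait score removed when all entries with |q| <= alpha go
    contrib = xc[:, order] * q_k[order]
    removed = np.cumsum(contrib, axis=1)
    sorted_abs = absq[order]
    # last occurrence of each distinct value
    last = np.flatnonzero(np.r_[sorted_abs[1:] != sorted_abs[:-1], True])
    grid = sorted_abs[last]
    thresholded = full[:, None] - removed[:, last]
    tc = thresholded - thresholded.mean(axis=0)
    num = fc @ tc
    denom = np.sqrt(denom_full * np.einsum("ij,ij->j", tc, tc))
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - num / denom
    d[~np.isfinite(d)] = np.inf
    return grid, d


def sparsify(basis: Basis, M: EffectMatrix, tol: float | None = None) -> Basis:
    """Hard-threshold each rotation column at its largest admissible alpha.

    For each retained component k the candidate thresholds are the sorted
    distinct values of |Q_ik| (an exact finite grid); alpha_k is the largest
    candidate with D_k(alpha) < tol, or 0 if none qualifies (keeping every
    nonzero entry, for which D is exactly 0). The scan is exhaustive, so no
    monotonicity of D along the grid is assumed.
    """
    tol = basis.tol if tol is None else float(tol)
    if not 0 < tol < 1:
        raise ValueError(f"tol must lie in (0, 1), got {tol}")
    if not M.variant_index.equals(basis.variant_index):
        raise ValueError("effect matrix does not match the basis variant index")
    xc, _ = M.centred()
    q = basis.rotation
    alpha = np.zeros(q.shape[1])
    sparse = np.array(q, copy=True)
    for k in range(q.shape[1]):
        grid, d = _distortion_scan(xc, q[:, k])
        ok = np.flatnonzero(d < tol)
        a_k = float(grid[ok[-1]]) if ok.size else 0.0
        alpha[k] = a_k
        sparse[:, k] = np.where(np.abs(q[:, k]) > a_k, q[:, k], 0.0)
    return replace(basis, tol=tol, alpha=alpha, sparse_rotation=sparse)


def build_basis(
    studies: Sequence[SummaryStats],
    weights: ShrinkageWeights,
    mode: str = "continuous",
    tol: float = DEFAULT_TOL,
    control_label: str = CONTROL_LABEL,
) -> Basis:
    """assemble -> fit -> select rank -> truncate -> sparsify, in one call."""
    M = assemble(studies, weights, mode, control_label=control_label)
    basis = fit_basis(M, weights)
    m = select_rank(M, basis)
    basis = basis.truncate(m)
    return sparsify(basis, M, tol=tol)


# ---------------------------------------------------------------------------
# serialisation: a directory of TSVs plus a JSON manifest with checksums

def _float_frame_bytes(df: pd.DataFrame) -> bytes:
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", float_format="%.17g", index=True)
    return buf.getvalue().encode()


def save_basis(basis: Basis, path: str | Path) -> Path:
    """Write a basis to ``path`` (a directory; created if needed).

    Floats are written with 17 significant digits, so save -> load -> save
    is byte-identical and projections through a reloaded basis match the
    in-memory one exactly. The sparse rotation is reconstructed from the
    full rotation and alpha on load rather than stored.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    variants = pd.DataFrame(
        {
            "col_mean": basis.col_means,
            "sigma_maf": basis.sigma_maf,
            "w": basis.w,
        },
        index=basis.variant_index,
    )
    pcs = [f"PC{k + 1}" for k in range(basis.m)]
    rotation = pd.DataFrame(basis.rotation, index=basis.variant_index,
                            columns=pcs)
    scores = pd.DataFrame(basis.scores, index=pd.Index(basis.traits,
                                                       name="trait"),
                          columns=pcs)
    files = {
        "variants.tsv": _float_frame_bytes(variants),
        "rotation.tsv": _float_frame_bytes(rotation),
        "scores.tsv": _float_frame_bytes(scores),
    }
    manifest = {
        "format": _FORMAT_VERSION,
        "mode": basis.mode,
        "control_label": basis.control_label,
        "tol": basis.tol,
        "prior_W": basis.prior.W,
        "prior_null_odds": basis.prior.null_prior_odds,
        "m": basis.m,
        "traits": basis.traits,
        "singular_values": [float(f"{s:.17g}") for s in basis.singular_values],
        "alpha": (None if basis.alpha is None
                  else [float(f"{a:.17g}") for a in basis.alpha]),
        "checksums": {
            name: hashlib.sha256(blob).hexdigest() for name, blob in files.items()
        },
    }
    for name, blob in files.items():
        (path / name).write_bytes(blob)
    (path / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return path


def load_basis(path: str | Path) -> Basis:
    """Load a basis saved by :func:`save_basis`, verifying checksums."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    if manifest.get("format") != _FORMAT_VERSION:
        raise ValueError(
            f"unsupported basis format {manifest.get('format')!r}; "
            f"expected {_FORMAT_VERSION!r}")
    for name, digest in manifest["checksums"].items():
        actual = hashlib.sha256((path / name).read_bytes()).hexdigest()
        if actual != digest:
            raise ValueError(f"checksum mismatch for {name} in {path}")
    variants = pd.read_csv(path / "variants.tsv", sep="\t", index_col=0,
                           float_precision="round_trip")
    rotation = pd.read_csv(path / "rotation.tsv", sep="\t", index_col=0,
                           float_precision="round_trip")
    scores = pd.read_csv(path / "scores.tsv", sep="\t", index_col=0,
                         float_precision="round_trip")
    idx = pd.Index(variants.index.astype(str), name="variant")
    alpha = manifest["alpha"]
    q = rotation.to_numpy(float)
    basis = Basis(
        traits=list(manifest["traits"]),
        variant_index=idx,
        col_means=variants["col_mean"].to_numpy(float),
        rotation=q,
        scores=scores.to_numpy(float),
        singular_values=np.asarray(manifest["singular_values"], float),
        mode=manifest["mode"],
        sigma_maf=variants["sigma_maf"].to_numpy(float),
        w=variants["w"].to_numpy(float),
        prior=ShrinkagePrior(W=manifest["prior_W"],
                             null_prior_odds=manifest["prior_null_odds"]),
        tol=manifest["tol"],
        control_label=manifest["control_label"],
    )
    if alpha is not None:
        a = np.asarray(alpha, float)
        basis = replace(
            basis, alpha=a,
            sparse_rotation=np.where(np.abs(q) > a[None, :], q, 0.0))
    return basis
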