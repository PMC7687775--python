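"""Read, validate and align GWAS summary statistics onto a reference panel.

All downstream computation assumes a single shared variant index with effect
estimates oriented to the panel's alternative allele. Variants are keyed by
``chrom:pos:ref:alt`` with 1-based inclusive positions (GRCh37 convention by
default); exclusion masks are read as BED (0-based, half-open) and converted
internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_BASES = {"A", "C", "G", "T"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default MHC exclusion interval, GRCh37, 1-based inclusive
MHC_GRCH37 = ("6", 20_000_000, 40_000_000)

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt"]


def variant_ids(df: pd.DataFrame) -> pd.Index:
    """Canonical ``chrom:pos:ref:alt`` identifiers for a variant table."""
    return pd.Index(
        df["chrom"].astype(str)
        + ":"
        + df["pos"].astype(int).astype(str)
        + ":"
        + df["ref"].astype(str)
        + ":"
        + df["alt"].astype(str),
        name="variant",
    )


def is_palindromic(ref: pd.Series, alt: pd.Series) -> pd.Series:
    """Strand-ambiguous A/T and C/G pairs, which cannot be oriented safely."""
    return alt == ref.map(_COMPLEMENT)


def _is_snp(allele: pd.Series) -> pd.Series:
    return allele.isin(_BASES)


@dataclass
class ReferencePanel:
    """Shared variant index with allele frequencies, LD blocks and LD.

    Parameters
    ----------
    variants
        Table indexed by variant id with columns ``chrom``, ``pos``, ``ref``,
        ``alt``, ``alt_freq`` and ``block``. Order defines the canonical
        variant order for everything built on top of the panel.
    ld
        Mapping from block label to the within-block correlation matrix
        (unit diagonal, rows/cols in the panel's within-block variant
        order). Cross-block correlation is treated as exactly zero. ``None``
        means no LD information (identity assumed where needed).
    """

    variants: pd.DataFrame
    ld: dict | None = None

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "ref", "alt", "alt_freq", "block"}
        missing = required - set(self.variants.columns)
        if missing:
            raise ValueError(f"panel variants missing columns: {sorted(missing)}")
        if self.variants.index.has_duplicates:
            dups = self.variants.index[self.variants.index.duplicated()][:5]
            raise ValueError(f"duplicate variants in panel: {list(dups)}")
        f = self.variants["alt_freq"].to_numpy(float)
        if np.any(~np.isfinite(f)) or np.any(f <= 0) or np.any(f >= 1):
            raise ValueError("panel alt_freq must lie strictly in (0, 1)")
        if self.ld is not None:
            for blk, r in self.ld.items():
                n_blk = int((self.variants["block"] == blk).sum())
                r = np.asarray(r, float)
                if r.shape != (n_blk, n_blk):
                    raise ValueError(f"LD matrix for block {blk!r} has shape "
                                     f"{r.shape}, expected ({n_blk}, {n_blk})")
                if np.any(np.abs(r) > 1 + 1e-9):
                    raise ValueError(f"LD matrix for block {blk!r} has |r| > 1")

    @property
    def index(self) -> pd.Index:
        return self.variants.index

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def block_slices(self) -> dict:
        """Integer positions of each block's variants, in panel order."""
        codes, uniques = pd.factorize(self.variants["block"], sort=False)
        out: dict = {}
        for i, blk in enumerate(uniques):
            out[blk] = np.flatnonzero(codes == i)
        return out

    def ld_for(self, block) -> np.ndarray:
        """Within-block correlation matrix, identity if no LD was supplied."""
        n_blk = int((self.variants["block"] == block).sum())
        if self.ld is None or block not in self.ld:
            return np.eye(n_blk)
        return np.asarray(self.ld[block], float)

    def subset(self, ids: pd.Index) -> "ReferencePanel":
        """Restrict the panel to ``ids`` (kept in current panel order)."""
        keep = self.index.isin(ids)
        variants = self.variants.loc[keep]
        ld = None
        if self.ld is not None:
            ld = {}
            for blk, pos in self.block_slices().items():
                sub = keep[pos]
                if sub.any() and blk in self.ld:
                    r = np.asarray(self.ld[blk], float)
                    ld[blk] = r[np.ix_(sub, sub)]
        return ReferencePanel(variants=variants, ld=ld)


@dataclass
class SummaryStats:
    """One trait's per-SNP effect estimates and standard errors.

    ``data`` is indexed by variant id with columns ``chrom``, ``pos``,
    ``ref``, ``alt``, ``beta``, ``se``. Effects are on the log-odds (or
    standardised linear) scale for the alternative allele. After
    :func:`align_to_panel`, the index equals the panel index and variants
    absent from the study carry ``beta = NaN``.
    """

    trait_id: str
    data: pd.DataFrame
    n_cases: int | None = None
    n_controls: int | None = None
    provenance: str = ""
    aligned: bool = False

    @property
    def index(self) -> pd.Index:
        return self.data.index

    @property
    def beta(self) -> pd.Series:
        return self.data["beta"]

    @property
    def se(self) -> pd.Series:
        return self.data["se"]

    def observed(self) -> pd.Index:
        """Variants with a non-missing effect estimate."""
        return self.data.index[self.data["beta"].notna()]


_DEFAULT_COLUMNS = {
    "chrom": "chrom",
    "pos": "pos",
    "ref": "ref",
    "alt": "alt",
    "beta": "beta",
    "se": "se",
}


def load_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_id: str | None = None,
    sep: str | None = None,
    n_cases: int | None = None,
    n_controls: int | None = None,
) -> SummaryStats:
    """Parse a tab- or comma-separated summary statistics file.

    Rows with missing or non-finite ``beta``/``se``, or ``se <= 0``, are
    dropped with a logged count. Duplicate variant keys raise.
    """
    path = Path(path)
    colmap = dict(_DEFAULT_COLUMNS)
    if column_map:
        colmap.update(column_map)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep)
    missing = [v for v in colmap.values() if v not in raw.columns]
    if missing:
        raise ValueError(f"{path}: required columns absent: {missing}")
    df = pd.DataFrame(
        {
            "chrom": raw[colmap["chrom"]].astype(str),
            "pos": pd.to_numeric(raw[colmap["pos"]]).astype(int),
            "ref": raw[colmap["ref"]].astype(str).str.upper(),
            "alt": raw[colmap["alt"]].astype(str).str.upper(),
            "beta": pd.to_numeric(raw[colmap["beta"]], errors="coerce"),
            "se": pd.to_numeric(raw[colmap["se"]], errors="coerce"),
        }
    )
    ok = (
        df["beta"].notna()
        & df["se"].notna()
        & np.isfinite(df["beta"])
        & np.isfinite(df["se"])
        & (df["se"] > 0)
    )
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("%s: dropped %d rows with missing/invalid beta or se",
                       path, n_dropped)
    df = df.loc[ok].copy()
    ids = variant_ids(df)
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique()[:5]
        raise ValueError(f"{path}: duplicated variant keys: {list(dups)}")
    df.index = ids
    return SummaryStats(
        trait_id=trait_id or path.stem,
        data=df,
        n_cases=n_cases,
        n_controls=n_controls,
        provenance=str(path),
    )


def align_to_panel(ss: SummaryStats, panel: ReferencePanel,
                   keep_indels: bool = False) -> SummaryStats:
    """Orient a study's effect estimates to the panel's alternative allele.

    Matching is by chromosome and position. Exact allele matches keep the
    sign of beta; swapped (study effect allele equals the panel reference
    allele) flip it. Strand-ambiguous palindromic SNPs and variants whose
    alleles cannot be matched unambiguously are dropped; no strand flipping
    is attempted. Panel variants absent from the study are retained with
    ``beta = NaN`` (resolution is deferred to projection).
    """
    df = ss.data.copy()
    if not keep_indels:
        df = df.loc[_is_snp(df["ref"]) & _is_snp(df["alt"])]
    df = df.loc[~is_palindromic(df["ref"], df["alt"])]
    # multi-allelic positions in the study are ambiguous -> dropped
    poskey = df["chrom"].astype(str) + ":" + df["pos"].astype(str)
    df = df.loc[~poskey.duplicated(keep=False)]

    pv = panel.variants
    panel_pos = pd.Index(pv["chrom"].astype(str) + ":" + pv["pos"].astype(str))
    study_pos = pd.Index(df["chrom"].astype(str) + ":" + df["pos"].astype(str))
    pos_to_row = pd.Series(np.arange(len(pv)), index=panel_pos)
    hit = study_pos.isin(panel_pos)
    df = df.loc[hit]
    rows = pos_to_row.loc[study_pos[hit]].to_numpy()

    p_ref = pv["ref"].to_numpy()[rows]
    p_alt = pv["alt"].to_numpy()[rows]
    exact = (df["ref"].to_numpy() == p_ref) & (df["alt"].to_numpy() == p_alt)
    swapped = (df["ref"].to_numpy() == p_alt) & (df["alt"].to_numpy() == p_ref)

    beta = np.full(len(pv), np.nan)
    se = np.full(len(pv), np.nan)
    beta[rows[exact]] = df["beta"].to_numpy()[exact]
    se[rows[exact]] = df["se"].to_numpy()[exact]
    beta[rows[swapped]] = -df["beta"].to_numpy()[swapped]
    se[rows[swapped]] = df["se"].to_numpy()[swapped]

    n_unmatched = int((~(exact | swapped)).sum())
    if n_unmatched:
        logger.info("%s: %d variants dropped (allele mismatch with panel)",
                    ss.trait_id, n_unmatched)
    if not np.isfinite(beta).any():
        raise ValueError(f"{ss.trait_id}: no variants align to the panel")

    out = pv[VARIANT_COLUMNS].copy()
    out["beta"] = beta
    out["se"] = se
    return replace(ss, data=out, aligned=True)


def read_bed_mask(path: str | Path) -> list[tuple[str, int, int]]:
    """Read BED intervals and convert to 1-based inclusive coordinates."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#",
                      usecols=[0, 1, 2], names=["chrom", "start", "end"])
    return [
        (str(c).removeprefix("chr"), int(s) + 1, int(e))
        for c, s, e in bed.itertuples(index=False)
    ]


def filter_panel(
    panel: ReferencePanel,
    maf_min: float = 0.01,
    exclude: Iterable[tuple[str, int, int]] | None = None,
) -> ReferencePanel:
    """Restrict a panel by minor allele frequency and exclusion intervals.

    ``exclude`` intervals are 1-based inclusive ``(chrom, start, end)``
    tuples (use :func:`read_bed_mask` to convert from BED). The default MHC
    mask used throughout is :data:`MHC_GRCH37`.
    """
    if not (0 <= maf_min < 0.5):
        raise ValueError(f"maf_min must lie in [0, 0.5), got {maf_min}")
    f = panel.variants["alt_freq"].to_numpy(float)
    keep = np.minimum(f, 1.0 - f) > maf_min
    if exclude:
        chrom = panel.variants["chrom"].astype(str).str.removeprefix("chr")
        pos = panel.variants["pos"].to_numpy(int)
        for c, start, end in exclude:
            c = str(c).removeprefix("chr")
            keep &= ~((chrom == c).to_numpy() & (pos >= start) & (pos <= end))
    return panel.subset(panel.index[keep])


def save_panel(panel: ReferencePanel, path: str | Path,
               write_ld: bool = False) -> Path:
    """Write a panel as TSVs: variant table, BED block file, optional LD.

    The LD table is long-format (``block``, ``i``, ``j``, ``r``) over
    within-block variant offsets with i <= j; it can be large, so it is
    only written on request.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    panel.variants.to_csv(path / "variants.tsv", sep="\t",
                          index_label="variant")
    rows = []
    for blk, pos in panel.block_slices().items():
        sub = panel.variants.iloc[pos]
        rows.append((sub["chrom"].iloc[0], int(sub["pos"].min()) - 1,
                     int(sub["pos"].max()), blk))
    pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]).to_csv(
        path / "blocks.bed", sep="\t", header=False, index=False)
    if write_ld and panel.ld is not None:
        recs = []
        for blk, r in panel.ld.items():
            r = np.asarray(r, float)
            iu = np.triu_indices(r.shape[0])
            for i, j in zip(*iu):
                if r[i, j] != 0:
                    recs.append((blk, i, j, r[i, j]))
        pd.DataFrame(recs, columns=["block", "i", "j", "r"]).to_csv(
            path / "ld.tsv", sep="\t", index=False, float_format="%.10g")
    return path


def load_panel(path: str | Path) -> ReferencePanel:
    """Load a panel directory written by :func:`save_panel`."""
    path = Path(path)
    variants = pd.read_csv(path / "variants.tsv", sep="\t", index_col=0,
                           dtype={"chrom": str})
    variants.index = variants.index.astype(str)
    variants.index.name = "variant"
    ld = None
    ld_path = path / "ld.tsv"
    if ld_path.exists():
        long = pd.read_csv(ld_path, sep="\t")
        ld = {}
        sizes = variants["block"].value_counts()
        for blk, grp in long.groupby("block"):
            n_blk = int(sizes[blk])
            r = np.zeros((n_blk, n_blk))
            r[grp["i"], grp["j"]] = grp["r"]
            r[grp["j"], grp["i"]] = grp["r"]
            ld[blk] = r
    return ReferencePanel(variants=variants, ld=ld)


def intersect_studies(studies: Sequence[SummaryStats]) -> pd.Index:
    """Variants with a non-missing effect estimate in every aligned study."""
    if len(studies) < 2:
        raise ValueError("need at least two studies to intersect")
    idx = studies[0].index
    present = studies[0].data["beta"].notna().to_numpy()
    for ss in studies[1:]:
        obs = ss.observed()
        present &= idx.isin(obs)
    shared = idx[present]
    if len(shared) == 0:
        raise ValueError("no variants shared by all studies")
    return shared
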