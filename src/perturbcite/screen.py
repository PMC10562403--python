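"""Pooled-screen statistics: guide fold changes, gene ranking, enrichment.

A sorting-based CRISPR screen compares gRNA abundance between a high and a
low bin of a FACS-sorted marker (e.g. CD86-high vs CD86-low).  This module
computes per-guide normalized log2 fold changes, combines guides into
gene-level z-scores against the non-targeting (NT) guide distribution, and
provides the two enrichment statistics used downstream: the exact
hypergeometric overlap test between two gene lists and chi-squared adjusted
standardized residuals for perturbation x cluster contingency tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    EmptyBinError,
    InvalidInputError,
    NoNTGuidesError,
    ZeroMarginError,
)

DEFAULT_UNIVERSE = 19674  # genes in the reference transcriptome of the screen library


def _to_cpm(counts: np.ndarray) -> np.ndarray:
    total = counts.sum()
    if total <= 0:
        raise EmptyBinError("sorting bin has zero total counts")
    return counts / total * 1e6


def guide_log2fc(
    table: pd.DataFrame,
    pseudocount: float = 1.0,
    normalization: str = "cpm",
) -> pd.DataFrame:
    """Per-guide log2 fold change between the high and low sorting bins.

    ``table`` needs columns gRNA, gene, is_nt, count_high, count_low.
    Counts are scaled to counts-per-million per bin (or median-ratio
    normalized with ``normalization='median_ratio'``), then
    lfc = log2((cpm_high + pc) / (cpm_low + pc)) and
    mean_abundance = (cpm_high + cpm_low) / 2.
    """
    high = table["count_high"].to_numpy(dtype=float)
    low = table["count_low"].to_numpy(dtype=float)
    if normalization == "cpm":
        nh, nl = _to_cpm(high), _to_cpm(low)
    elif normalization == "median_ratio":
        if high.sum() <= 0 or low.sum() <= 0:
            raise EmptyBinError("sorting bin has zero total counts")
        ref = np.sqrt((high + pseudocount) * (low + pseudocount))
        sh = np.median((high + pseudocount) / ref)
        sl = np.median((low + pseudocount) / ref)
        nh, nl = high / sh, low / sl
    else:
        raise ValueError("normalization must be 'cpm' or 'median_ratio'")
    lfc = np.log2((nh + pseudocount) / (nl + pseudocount))
    out = table[["gRNA", "gene", "is_nt"]].copy()
    out["lfc"] = lfc
    out["mean_abundance"] = (nh + nl) / 2
    return out


def gene_zscore_rank(effects: pd.DataFrame) -> pd.DataFrame:
    """Gene ranking by z-scores of guide fold changes against NT guides.

    Each guide's lfc is standardized against the non-targeting guides,
    z = (lfc - mean(NT)) / sd(NT), and a gene with m guides gets the
    Stouffer combination z_gene = sum(z_i) / sqrt(m).  Two-sided normal
    p-values are BH-adjusted across genes; rank 1 is the largest signed z.
    Requires >= 2 NT guides.  Adding a constant to every guide's lfc leaves
    the z-scores unchanged.
    """
    nt = effects.loc[effects["is_nt"].astype(bool), "lfc"].to_numpy(dtype=float)
    if nt.size < 2:
        raise NoNTGuidesError("need >= 2 non-targeting guides")
    mu, sd = nt.mean(), nt.std(ddof=1)
    if sd == 0:
        raise NoNTGuidesError("non-targeting guide fold changes are constant")
    df = effects.loc[~effects["is_nt"].astype(bool)].copy()
    df["z_guide"] = (df["lfc"] - mu) / sd
    gene = df.groupby("gene")["z_guide"].agg(["sum", "size"])
    z = gene["sum"] / np.sqrt(gene["size"])
    p = 2 * stats.norm.sf(np.abs(z))
    q = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame({"n_guides": gene["size"], "z": z, "p": p, "q": q})
    out.index.name = "gene"
    # ties in z break lexicographically by gene (stable sort after sort_index)
    out = out.sort_index().sort_values("z", ascending=False, kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    return out


@dataclass(frozen=True)
class OverlapTestInput:
    """Overlap of two gene lists of sizes K and n drawn from N genes; x observed."""

    N: int
    K: int
    n: int
    x: int

    def __post_init__(self) -> None:
        if not (0 <= self.x <= min(self.K, self.n) and self.K <= self.N and self.n <= self.N):
            raise InvalidInputError(f"inconsistent overlap inputs {self}")


def hypergeometric_overlap(inp: OverlapTestInput) -> float:
    """Exact upper-tail hypergeometric probability P(X >= x).

    X is the overlap of a random n-subset with a fixed K-subset of an
    N-gene universe.  Computed through log-gamma factorials (scipy's
    survival function), so it is stable for genome-scale N.
    """
    return float(stats.hypergeom.sf(inp.x - 1, inp.N, inp.K, inp.n))


def chisq_residuals(
    table: pd.DataFrame | np.ndarray,
) -> tuple[float, int, float, pd.DataFrame | np.ndarray]:
    """Chi-squared test of independence with adjusted standardized residuals.

    For an observed perturbations x clusters table O with margins r_i, c_j
    and total N: E_ij = r_i c_j / N, chi2 = sum (O - E)^2 / E on
    (r-1)(c-1) degrees of freedom, and the adjusted standardized residual

        res_ij = (O_ij - E_ij) / sqrt(E_ij (1 - r_i/N) (1 - c_j/N))

    which is approximately standard normal under independence (the "stdres"
    convention).  Requires all-positive margins.
    """
    O = np.asarray(table, dtype=float)
    row = O.sum(axis=1)
    col = O.sum(axis=0)
    if (row <= 0).any() or (col <= 0).any():
        raise ZeroMarginError("contingency table has a zero margin")
    total = O.sum()
    E = np.outer(row, col) / total
    chi2 = float(((O - E) ** 2 / E).sum())
    df = (O.shape[0] - 1) * (O.shape[1] - 1)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    denom = np.sqrt(E * (1 - row[:, None] / total) * (1 - col[None, :] / total))
    res = (O - E) / denom
    if isinstance(table, pd.DataFrame):
        res = pd.DataFrame(res, index=table.index, columns=table.columns)
    return chi2, df, p, res


def perturbation_cluster_table(
    labels: Mapping[str, object], clusters: Mapping[str, object]
) -> pd.DataFrame:
    """Cross-tabulate singlet perturbation labels against expression clusters."""
    lab = pd.Series({c: str(l) for c, l in labels.items()})
    clu = pd.Series({c: str(v) for c, v in clusters.items()})
    cells = lab.index.intersection(clu.index)
    return pd.crosstab(lab.loc[cells], clu.loc[cells])


def read_screen_table(path) -> pd.DataFrame:
    """Read a screen count TSV: gRNA, gene, is_nt, count_high, count_low."""
    df = pd.read_csv(path, sep="\t")
    needed = {"gRNA", "gene", "is_nt", "count_high", "count_low"}
    missing = needed - set(df.columns)
    if missing:
        raise InvalidInputError(f"screen table missing columns {sorted(missing)}")
    return df
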