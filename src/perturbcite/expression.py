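"""Expression-level analyses: signature scores, cell states, DE and clustering.

Covers the transcriptome side of the pipeline:

* depth normalization ln(1 + count / cell_total * 1e4);
* a rank-based (Mann-Whitney U style) gene-signature score per cell, used
  both for scoring annotated programs (e.g. antigen processing and
  presentation, T-cell co-stimulation) and for assigning cells to states;
* two-group Wilcoxon rank-sum differential expression with BH correction;
* fold-change-vs-control matrices over perturbation labels, including the
  cross-regulation view restricted to the targeted genes themselves;
* the baseMean-dependent selection rule applied to external DE tables; and
* row z-scoring + k-means clustering for heatmap displays.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .errors import (
    EmptySignatureError,
    GroupTooSmallError,
    KTooLargeError,
    MissingReferenceError,
)

NORM_TARGET = 1e4


def normalize_expression(counts: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Log-normalized layer: ln(1 + count / cell_total * 1e4) per cell."""
    x = np.asarray(counts, dtype=float)
    totals = x.sum(axis=1, keepdims=True)
    scaled = np.where(totals > 0, x / np.where(totals > 0, totals, 1.0) * NORM_TARGET, 0.0)
    y = np.log1p(scaled)
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(y, index=counts.index, columns=counts.columns)
    return y


def depth_normalize(counts: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Depth-normalized (not logged) layer: count / cell_total * 1e4."""
    x = np.asarray(counts, dtype=float)
    totals = x.sum(axis=1, keepdims=True)
    y = np.where(totals > 0, x / np.where(totals > 0, totals, 1.0) * NORM_TARGET, 0.0)
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(y, index=counts.index, columns=counts.columns)
    return y


def _capped_ranks(cell_counts: np.ndarray, r_max: int) -> np.ndarray:
    """Ranks by decreasing count (average ranks for ties), capped at r_max + 1."""
    ranks = stats.rankdata(-np.asarray(cell_counts, dtype=float), method="average")
    return np.minimum(ranks, r_max + 1)


def rank_signature_score(
    cell_counts: pd.Series | np.ndarray,
    signature: Sequence[str],
    gene_ids: Optional[Sequence[str]] = None,
    r_max: int = 1500,
) -> float:
    """Rank-based signature score in [0, 1] for one cell.

    Genes are ranked per cell by decreasing count with average ranks for
    ties; ranks beyond ``r_max`` are clipped to ``r_max + 1``.  With the
    signature's n (capped) ranks r_i,

        U = sum_i r_i - n (n + 1) / 2,    score = 1 - U / (n * r_max)

    clipped to [0, 1].  The score is 1 when the signature occupies the top
    n untied positions and 0 when every signature gene ranks past r_max.
    Invariant under any strictly monotone transform of the cell's counts.
    """
    if isinstance(cell_counts, pd.Series):
        gene_ids = list(cell_counts.index)
        values = cell_counts.to_numpy(dtype=float)
    else:
        values = np.asarray(cell_counts, dtype=float)
        if gene_ids is None:
            raise ValueError("gene_ids required with array input")
    idx = {g: i for i, g in enumerate(gene_ids)}
    sig_idx = [idx[g] for g in signature if g in idx]
    if not sig_idx:
        raise EmptySignatureError("no signature genes present in the gene universe")
    ranks = _capped_ranks(values, r_max)
    n = len(sig_idx)
    u = float(ranks[sig_idx].sum() - n * (n + 1) / 2)
    return float(np.clip(1.0 - u / (n * r_max), 0.0, 1.0))


def score_signatures(
    counts: pd.DataFrame, signatures: Mapping[str, Sequence[str]], r_max: int = 1500
) -> pd.DataFrame:
    """Signature scores for every cell (rows) and signature (columns)."""
    genes = list(counts.columns)
    idx = {g: i for i, g in enumerate(genes)}
    sig_cols = {}
    values = counts.to_numpy(dtype=float)
    ranks = np.apply_along_axis(_capped_ranks, 1, values, r_max)
    for name, sig in signatures.items():
        sig_idx = [idx[g] for g in sig if g in idx]
        if not sig_idx:
            raise EmptySignatureError(f"signature {name!r} absent from gene universe")
        n = len(sig_idx)
        u = ranks[:, sig_idx].sum(axis=1) - n * (n + 1) / 2
        sig_cols[name] = np.clip(1.0 - u / (n * r_max), 0.0, 1.0)
    return pd.DataFrame(sig_cols, index=counts.index)


def assign_cell_state(
    counts: pd.DataFrame, signatures: Mapping[str, Sequence[str]], r_max: int = 1500
) -> pd.Series:
    """Assign each cell to the signature with the highest rank score.

    Exact ties leave the cell "unassigned".  Requires >= 2 signatures.
    """
    if len(signatures) < 2:
        raise ValueError("need >= 2 signatures for state assignment")
    scores = score_signatures(counts, signatures, r_max=r_max)
    arr = scores.to_numpy()
    best = arr.max(axis=1)
    n_best = (arr == best[:, None]).sum(axis=1)
    names = np.array(list(scores.columns))
    states = names[arr.argmax(axis=1)].astype(object)
    states[n_best > 1] = "unassigned"
    return pd.Series(states, index=counts.index, name="state")


def wilcoxon_de(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    min_cells: int = 3,
    lfc_base: str = "natural",
) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum test between two cell groups.

    Tests are run on the depth-normalized (counts / total * 1e4) layer.
    The p-value uses the exact rank-sum distribution when both groups have
    <= 25 cells and the gene has no tied values (mirroring the behaviour of
    the conventional R test), and otherwise the normal approximation with
    tie correction and continuity correction.  The reported z statistic is
    always the (continuity-corrected) normal deviate; its sign is positive
    when group A tends larger.  lfc = log((mean_A + 1) / (mean_B + 1)) on
    depth-normalized means, natural log by default.  q is the BH-adjusted
    p across all tested genes.
    """
    if len(counts_a) < min_cells or len(counts_b) < min_cells:
        raise GroupTooSmallError(f"both groups need >= {min_cells} cells")
    genes = list(counts_a.columns)
    if list(counts_b.columns) != genes:
        counts_b = counts_b[genes]
    xa = np.asarray(depth_normalize(counts_a), dtype=float)
    xb = np.asarray(depth_normalize(counts_b), dtype=float)
    na, nb = xa.shape[0], xb.shape[0]
    small = na <= 25 and nb <= 25

    zs = np.empty(len(genes))
    ps = np.empty(len(genes))
    for j in range(len(genes)):
        a, b = xa[:, j], xb[:, j]
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        w = ranks[:na].sum()
        u = w - na * (na + 1) / 2
        mean_u = na * nb / 2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum()
        ntot = na + nb
        var_u = na * nb / 12 * ((ntot + 1) - tie_term / (ntot * (ntot - 1)))
        if var_u == 0:
            zs[j] = 0.0
            ps[j] = 1.0
            continue
        cc = 0.5 if u != mean_u else 0.0
        zs[j] = (u - mean_u - np.sign(u - mean_u) * cc) / np.sqrt(var_u)
        if small and tie_term == 0:
            ps[j] = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        else:
            ps[j] = min(1.0, 2.0 * stats.norm.sf(abs(zs[j])))
    qs = multipletests(ps, method="fdr_bh")[1]
    mean_a, mean_b = xa.mean(axis=0), xb.mean(axis=0)
    log = np.log if lfc_base == "natural" else np.log2
    lfc = log((mean_a + 1.0) / (mean_b + 1.0))
    return pd.DataFrame(
        {"lfc": lfc, "statistic": zs, "p": ps, "q": qs}, index=pd.Index(genes, name="gene")
    )


def fold_change_matrix(
    counts: pd.DataFrame,
    labels: Mapping[str, object],
    gene_list: Optional[Sequence[str]] = None,
    reference: str = "NT",
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-label fold change of mean depth-normalized expression vs reference.

    entry[label, gene] = (mean depth-normalized expr in label + pc)
                       / (mean in reference + pc)

    The reference row is identically 1 and genes absent everywhere give 1.
    Restricting ``gene_list`` to the targeted genes yields the
    cross-regulation (genetic interaction) view.
    """
    lab = pd.Series({c: str(l) for c, l in labels.items()})
    cells = counts.index.intersection(lab.index)
    lab = lab.loc[cells]
    if reference not in set(lab):
        raise MissingReferenceError(f"reference label {reference!r} has no cells")
    norm = depth_normalize(counts.loc[cells])
    if gene_list is not None:
        norm = norm[[g for g in gene_list if g in norm.columns]]
    means = norm.groupby(lab).mean()
    ref = means.loc[reference]
    return (means + pseudocount).div(ref + pseudocount, axis=1)


@dataclass
class DESelectionRule:
    """Selection rule for external DE tables (gene, baseMean, log2FC, padj).

    In ``basemean_dependent`` mode a gene is selected iff
    padj < padj_max, baseMean > basemean_min and
    |log2FC| > lfc_coef / sqrt(baseMean) + lfc_offset — lowly expressed
    genes must clear a larger fold change.  ``fixed`` mode uses a flat
    |log2FC| > fixed_lfc cut.
    """

    padj_max: float = 0.1
    basemean_min: float = 5.0
    lfc_offset: float = 0.3
    lfc_coef: float = 5.0
    mode: str = "basemean_dependent"
    fixed_lfc: float = 1.0

    def __post_init__(self) -> None:
        if self.lfc_offset < 0 or self.lfc_coef < 0:
            raise ValueError("lfc_offset and lfc_coef must be >= 0")
        if self.mode not in ("basemean_dependent", "fixed"):
            raise ValueError("mode must be 'basemean_dependent' or 'fixed'")

    def lfc_threshold(self, base_mean: float) -> float:
        if self.mode == "fixed":
            return self.fixed_lfc
        return self.lfc_coef / np.sqrt(base_mean) + self.lfc_offset


def select_de_genes(records: pd.DataFrame, rule: DESelectionRule | None = None) -> list[str]:
    """Apply the selection rule to a DE table.

    ``records`` needs columns gene, baseMean, log2FoldChange, padj; rows
    with missing padj are never selected.
    """
    rule = rule or DESelectionRule()
    df = records.copy()
    padj = pd.to_numeric(df["padj"], errors="coerce")
    base = pd.to_numeric(df["baseMean"], errors="coerce")
    lfc = pd.to_numeric(df["log2FoldChange"], errors="coerce")
    with np.errstate(divide="ignore", invalid="ignore"):
        thr = np.where(base > 0, rule.lfc_coef / np.sqrt(np.maximum(base, 1e-300)) + rule.lfc_offset, np.inf)
    if rule.mode == "fixed":
        thr = np.full(len(df), rule.fixed_lfc)
    keep = (padj < rule.padj_max) & (base > rule.basemean_min) & (lfc.abs() > thr)
    keep = keep.fillna(False)
    return df.loc[keep.to_numpy(), "gene"].astype(str).tolist()


def cluster_zscore_kmeans(
    matrix: pd.DataFrame, k: int, seed: int = 0, n_init: int = 25
) -> tuple[pd.Series, pd.DataFrame]:
    """Row z-scoring followed by k-means clustering (heatmap preparation).

    Rows are standardized to mean 0 / sd 1 (population sd; constant rows
    map to zeros) and clustered with k-means using ``n_init`` restarts and
    a fixed seed.  Returns (per-row cluster ids, z-scored matrix).
    """
    if k > len(matrix):
        raise KTooLargeError(f"k={k} exceeds {len(matrix)} rows")
    x = matrix.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    clusters = km.fit_predict(z)
    zdf = pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
    return pd.Series(clusters, index=matrix.index, name="cluster"), zdf


def read_signatures(path) -> dict[str, list[str]]:
    """Read signatures from GMT (name<TAB>desc<TAB>genes...) or two-column TSV."""
    sigs: dict[str, list[str]] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if all(len(ln.split("\t")) == 2 for ln in lines):
        for ln in lines:
            name, gene = ln.split("\t")
            sigs.setdefault(name, []).append(gene)
    else:
        for ln in lines:
            parts = ln.split("\t")
            sigs[parts[0]] = [g for g in parts[2:] if g]
    return sigs
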