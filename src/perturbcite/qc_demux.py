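"""Per-cell QC filters, CLR normalization and hashtag demultiplexing.

Hashtag oligos (HTOs) mark sample groups; a droplet containing two cells
from different hashtag groups shows two positive HTOs and is discarded as a
doublet.  This is what lets a high-MOI design tell genuinely double-infected
cells (one cell, two guides, one hashtag) apart from droplet doublets (two
cells, one guide each, two hashtags).

Demultiplexing here is a deterministic stand-in for quantile-sweep
demultiplexers: per HTO, the CLR-transformed values are split by 1-D
two-means clustering with min/max initialization, and a cell is positive
when its CLR lies strictly above the midpoint of the two final centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import EmptyInputError


@dataclass
class QCParams:
    """Cell-level QC thresholds.

    Cells in the top ``1 - gdo_total_quantile`` tail of total guide-tag
    UMIs are removed (suspected multiplets / ambient sinks), as are cells
    with fewer than ``min_cdna_umis`` transcriptome UMIs or fewer than
    ``min_genes`` detected genes.
    """

    gdo_total_quantile: float = 0.95
    min_cdna_umis: int = 5000
    min_genes: int = 200

    def __post_init__(self) -> None:
        if not 0.0 < self.gdo_total_quantile < 1.0:
            raise ValueError("gdo_total_quantile must be in (0, 1)")
        if self.min_cdna_umis < 0 or self.min_genes < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass(frozen=True)
class CellQCProfile:
    cell_id: str
    total_gdo_umis: int
    total_cdna_umis: int
    n_genes_detected: int


@dataclass(frozen=True)
class HTOCall:
    cell_id: str
    status: str  # negative | singlet | doublet
    hashtag: Optional[str] = None
    positive_set: tuple[str, ...] = ()


def apply_qc_filters(
    profiles: list[CellQCProfile], params: QCParams | None = None
) -> tuple[set[str], dict[str, int]]:
    """Return the retained cell-id set and per-filter removal tallies.

    The three filters are evaluated independently on the full input set and
    the retained set is their intersection, so the result does not depend
    on filter order.  The GDO quantile is the linear-interpolation quantile;
    cells strictly above it are removed.
    """
    params = params or QCParams()
    if not profiles:
        raise EmptyInputError("no QC profiles")
    gdo_totals = np.array([p.total_gdo_umis for p in profiles], dtype=float)
    cutoff = float(np.quantile(gdo_totals, params.gdo_total_quantile))
    pass_gdo = {p.cell_id for p in profiles if p.total_gdo_umis <= cutoff}
    pass_umis = {p.cell_id for p in profiles if p.total_cdna_umis >= params.min_cdna_umis}
    pass_genes = {p.cell_id for p in profiles if p.n_genes_detected >= params.min_genes}
    retained = pass_gdo & pass_umis & pass_genes
    n = len(profiles)
    report = {
        "n_input": n,
        "removed_gdo_total": n - len(pass_gdo),
        "removed_low_cdna_umis": n - len(pass_umis),
        "removed_low_genes": n - len(pass_genes),
        "n_retained": len(retained),
        "gdo_total_cutoff": cutoff,
    }
    return retained, report


def clr_normalize(counts: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Centered log-ratio transform per cell across features (margin=1).

    y[c, f] = ln(counts[c, f] + pseudocount) - mean_f ln(counts[c, .] + pseudocount)

    Each output row has mean zero to machine precision.
    """
    x = np.log(np.asarray(counts, dtype=float) + pseudocount)
    return x - x.mean(axis=1, keepdims=True)


def clr_normalize_across_cells(counts: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """CLR per feature across cells (the alternative margin), for comparison."""
    x = np.log(np.asarray(counts, dtype=float) + pseudocount)
    return x - x.mean(axis=0, keepdims=True)


def _two_means_threshold(values: np.ndarray, max_iter: int = 200) -> Optional[float]:
    """1-D two-means with deterministic (min, max) init; midpoint threshold.

    Returns None when the values are constant (degenerate distribution).
    """
    v = np.asarray(values, dtype=float)
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        return None
    c0, c1 = lo, hi
    for _ in range(max_iter):
        mid = 0.5 * (c0 + c1)
        left = v[v <= mid]
        right = v[v > mid]
        if left.size == 0 or right.size == 0:
            break
        n0, n1 = float(left.mean()), float(right.mean())
        if n0 == c0 and n1 == c1:
            break
        c0, c1 = n0, n1
    return 0.5 * (c0 + c1)


def classify_hashtags(
    clr: np.ndarray | pd.DataFrame,
    cell_ids: Optional[list[str]] = None,
    hto_ids: Optional[list[str]] = None,
) -> list[HTOCall]:
    """Classify each cell as negative, hashtag singlet, or doublet.

    Per HTO feature, a positive/negative threshold is derived from that
    feature's CLR values across all cells (two-means split).  A cell is a
    singlet when exactly one HTO is positive, a doublet when two or more
    are, and negative otherwise.  A constant HTO column yields no positives.
    Deterministic given the input.
    """
    if isinstance(clr, pd.DataFrame):
        cell_ids = list(clr.index) if cell_ids is None else cell_ids
        hto_ids = list(clr.columns) if hto_ids is None else hto_ids
        clr = clr.to_numpy(dtype=float)
    clr = np.asarray(clr, dtype=float)
    n_cells, n_htos = clr.shape
    if cell_ids is None:
        cell_ids = [f"cell{i}" for i in range(n_cells)]
    if hto_ids is None:
        hto_ids = [f"HTO{j}" for j in range(n_htos)]
    if n_cells < 2 or n_htos < 2:
        raise EmptyInputError("need >= 2 cells and >= 2 HTO features")

    positive = np.zeros((n_cells, n_htos), dtype=bool)
    for j in range(n_htos):
        thr = _two_means_threshold(clr[:, j])
        if thr is None:
            continue
        positive[:, j] = clr[:, j] > thr

    calls: list[HTOCall] = []
    for i, cid in enumerate(cell_ids):
        pos = [hto_ids[j] for j in np.flatnonzero(positive[i])]
        if len(pos) == 1:
            calls.append(HTOCall(cid, "singlet", hashtag=pos[0]))
        elif len(pos) >= 2:
            calls.append(HTOCall(cid, "doublet", positive_set=tuple(pos)))
        else:
            calls.append(HTOCall(cid, "negative"))
    return calls


def calls_to_frame(calls: list[HTOCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.cell_id, c.status, c.hashtag or "", ",".join(c.positive_set))
            for c in calls
        ],
        columns=["cell_id", "status", "hashtag", "positive_set"],
    )


def read_qc_profiles_tsv(path) -> list[CellQCProfile]:
    """Read per-cell QC covariates: cell_id, total_gdo_umis, total_cdna_umis, n_genes."""
    df = pd.read_csv(path, sep="\t")
    return [
        CellQCProfile(str(r.cell_id), int(r.total_gdo_umis), int(r.total_cdna_umis), int(r.n_genes))
        for r in df.itertuples()
    ]
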