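"""Protein-level scoring and ranking of perturbation combinations.

The combined per-cell protein score summarizes the co-stimulatory surface
phenotype of a dendritic cell:

    S = RC(CD86) + HTO-Max - RC(PD-L1)

where RC is the relative-count normalization of the ADT panel (per cell
across the panel's features) and HTO-Max is the cell's dominant hashtag
count normalized within its hashtag group (the hashtag antibody targets
MHC-I/CD45, so HTO-Max tracks MHC-I abundance once per-antibody staining
efficiency is removed by the group normalization).  Higher S means more
CD86/MHC-I and less PD-L1.  Perturbation combinations are ranked by the
median S of their cells relative to the non-targeting (NT) median.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errors import MissingModalityError, MissingReferenceError
from .qc_demux import HTOCall


@dataclass
class NormalizationParams:
    adt_scale_factor: float = 1.0
    hto_group_center: str = "mean"  # or "median"

    def __post_init__(self) -> None:
        if self.adt_scale_factor <= 0:
            raise ValueError("adt_scale_factor must be positive")
        if self.hto_group_center not in ("mean", "median"):
            raise ValueError("hto_group_center must be 'mean' or 'median'")


def rc_normalize(
    counts: pd.DataFrame | np.ndarray, params: NormalizationParams | None = None
) -> pd.DataFrame | np.ndarray:
    """Relative-count normalization per cell across features.

    value = count / cell total * adt_scale_factor; all-zero cells map to
    zeros.  Invariant to per-cell scaling of the raw counts.
    """
    params = params or NormalizationParams()
    x = np.asarray(counts, dtype=float)
    totals = x.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rc = np.where(totals > 0, x / np.where(totals > 0, totals, 1.0), 0.0)
    rc = rc * params.adt_scale_factor
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(rc, index=counts.index, columns=counts.columns)
    return rc


def compute_hto_max(
    hto_counts: pd.DataFrame,
    calls: list[HTOCall],
    params: NormalizationParams | None = None,
) -> pd.Series:
    """Per-cell normalized dominant-hashtag value (HTO-Max).

    Singlet cells are grouped by their called hashtag; within each group the
    dominant hashtag's raw count is divided by the group center (mean by
    default), so each group's mean HTO-Max is 1 and per-antibody staining
    efficiency differences cancel.  Empty groups are skipped.
    """
    params = params or NormalizationParams()
    singlets = [c for c in calls if c.status == "singlet"]
    if not singlets:
        return pd.Series(dtype=float, name="hto_max")
    values: dict[str, float] = {}
    by_tag: dict[str, list[HTOCall]] = {}
    for c in singlets:
        by_tag.setdefault(c.hashtag, []).append(c)
    for tag, members in by_tag.items():
        cells = [c.cell_id for c in members if c.cell_id in hto_counts.index]
        if not cells:
            continue
        dominant = hto_counts.loc[cells, tag].astype(float)
        center = dominant.mean() if params.hto_group_center == "mean" else dominant.median()
        if center == 0:
            center = 1.0
        for cid, v in (dominant / center).items():
            values[cid] = float(v)
    return pd.Series(values, name="hto_max")


def protein_score(
    rc_adt: pd.DataFrame,
    hto_max: pd.Series,
    cd86: str = "CD86",
    pdl1: str = "PD-L1",
) -> pd.DataFrame:
    """Combined score S = RC(CD86) + HTO-Max - RC(PD-L1) per cell.

    Only cells present in both inputs are scored; a missing ADT column
    raises MissingModalityError.
    """
    for col in (cd86, pdl1):
        if col not in rc_adt.columns:
            raise MissingModalityError(f"ADT feature {col!r} missing")
    cells = rc_adt.index.intersection(hto_max.index)
    if len(cells) == 0:
        raise MissingModalityError("no cells with both ADT and HTO-Max values")
    out = pd.DataFrame(
        {
            "rc_cd86": rc_adt.loc[cells, cd86].astype(float),
            "rc_pdl1": rc_adt.loc[cells, pdl1].astype(float),
            "hto_max": hto_max.loc[cells].astype(float),
        }
    )
    out["score"] = out["rc_cd86"] + out["hto_max"] - out["rc_pdl1"]
    return out


def summarize_and_rank(
    scores: pd.Series | pd.DataFrame,
    labels: Mapping[str, object],
    reference_label: str = "NT",
) -> pd.DataFrame:
    """Median score per perturbation label, relative to the reference.

    relative_score = median(label) - median(reference); the table is sorted
    descending by relative_score with ties broken by n_cells (larger first)
    then label (lexicographic); rank 1 is the top row.
    """
    if isinstance(scores, pd.DataFrame):
        scores = scores["score"]
    lab = pd.Series({c: str(l) for c, l in labels.items()})
    cells = scores.index.intersection(lab.index)
    df = pd.DataFrame({"score": scores.loc[cells], "label": lab.loc[cells]})
    if reference_label not in set(df["label"]):
        raise MissingReferenceError(f"reference label {reference_label!r} has no cells")
    grouped = df.groupby("label")["score"].agg(["median", "size"])
    grouped.columns = ["median_score", "n_cells"]
    ref_median = grouped.loc[reference_label, "median_score"]
    grouped["relative_score"] = grouped["median_score"] - ref_median
    grouped = grouped.reset_index().sort_values(
        by=["relative_score", "n_cells", "label"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    grouped["rank"] = np.arange(1, len(grouped) + 1)
    return grouped.set_index("label")[["n_cells", "median_score", "relative_score", "rank"]]
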