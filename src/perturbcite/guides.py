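"""Guide calling and gene-level perturbation labels.

A guide is assigned to a cell when it clears two thresholds on the cell's
guide-derived oligo (GDO) UMIs: an absolute floor (default 5 UMIs) and a
relative floor (default 20% of the cell's total GDO UMIs).  Guide sets are
then collapsed to sorted gene-level labels ("Cebpb+Med12", "NT", ...), and
rare combinations — mainly triplets and higher-order sets — are dropped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd

from .errors import UnknownGuideError

NT_LABEL = "NT"


@dataclass
class GuideAssignmentParams:
    min_umis: int = 5
    min_fraction: float = 0.20
    min_cells_per_combo: int = 10
    collapse_nt: bool = True
    collapse_same_gene: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.min_fraction <= 1.0:
            raise ValueError("min_fraction must be in (0, 1]")
        if self.min_umis < 1:
            raise ValueError("min_umis must be >= 1")


@dataclass(frozen=True)
class GuideCall:
    cell_id: str
    guides: tuple[str, ...]
    umis: tuple[int, ...]
    fractions: tuple[float, ...]

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.guides, self.umis))


@dataclass(frozen=True)
class PerturbationLabel:
    """Sorted, deduplicated tuple of targeted genes; "NT" for control-only cells."""

    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("empty perturbation label")
        if tuple(sorted(set(self.genes))) != self.genes:
            raise ValueError("genes must be sorted and deduplicated")

    def __str__(self) -> str:
        return "+".join(self.genes)

    @property
    def order(self) -> int:
        return len(self.genes)

    @classmethod
    def from_genes(cls, genes) -> "PerturbationLabel":
        return cls(tuple(sorted(set(genes))))


def assign_guides(
    gdo_counts: Mapping[str, int],
    params: GuideAssignmentParams | None = None,
    cell_id: str = "",
) -> Optional[GuideCall]:
    """Call the guide set of one cell; None when no guide passes.

    A guide g is included iff UMIs(g) >= min_umis and
    UMIs(g)/total >= min_fraction, both inclusive.  With min_fraction f at
    most floor(1/f) guides can pass.
    """
    params = params or GuideAssignmentParams()
    total = sum(gdo_counts.values())
    if total <= 0:
        return None
    passed = sorted(
        g
        for g, n in gdo_counts.items()
        if n >= params.min_umis and n / total >= params.min_fraction
    )
    if not passed:
        return None
    return GuideCall(
        cell_id,
        tuple(passed),
        tuple(int(gdo_counts[g]) for g in passed),
        tuple(gdo_counts[g] / total for g in passed),
    )


def label_perturbation(
    call: GuideCall,
    guide_to_gene: Mapping[str, str],
    params: GuideAssignmentParams | None = None,
) -> PerturbationLabel:
    """Collapse a guide call to its gene-level label.

    Non-targeting guides (gene "NT") are dropped from mixed sets when
    ``collapse_nt``; cells carrying only non-targeting guides are labelled
    "NT".  Two guides against one gene collapse to the single-gene label
    when ``collapse_same_gene`` (they still do either way, since labels are
    deduplicated gene sets; the flag is kept for dosage-preserving variants).
    """
    params = params or GuideAssignmentParams()
    genes = []
    for g in call.guides:
        if g not in guide_to_gene:
            raise UnknownGuideError(f"guide {g!r} not in guide-to-gene map")
        genes.append(guide_to_gene[g])
    if params.collapse_nt:
        targeting = [g for g in genes if g != NT_LABEL]
        genes = targeting if targeting else [NT_LABEL]
    if not params.collapse_same_gene:
        # dosage-preserving: annotate multiplicity, e.g. Cebpb x2
        counts = Counter(genes)
        genes = [f"{g}x{k}" if k > 1 else g for g, k in counts.items()]
    return PerturbationLabel.from_genes(genes)


def filter_combinations(
    labels: Mapping[str, PerturbationLabel],
    params: GuideAssignmentParams | None = None,
) -> tuple[dict[str, PerturbationLabel], pd.DataFrame]:
    """Drop perturbation labels carried by fewer than min_cells_per_combo cells.

    Returns the retained cell -> label map and a report of dropped labels
    with their cell counts.
    """
    params = params or GuideAssignmentParams()
    sizes = Counter(str(lab) for lab in labels.values())
    dropped = {lab for lab, n in sizes.items() if n < params.min_cells_per_combo}
    retained = {c: lab for c, lab in labels.items() if str(lab) not in dropped}
    report = pd.DataFrame(
        sorted(((lab, sizes[lab]) for lab in dropped), key=lambda t: (-t[1], t[0])),
        columns=["label", "n_cells"],
    )
    return retained, report


def call_guides_matrix(
    gdo: pd.DataFrame,
    guide_to_gene: Mapping[str, str],
    params: GuideAssignmentParams | None = None,
) -> pd.DataFrame:
    """Run guide calling + labelling over a cells x guides count frame.

    Returns a frame indexed by the cells with at least one called guide:
    columns guides ("g1,g2"), umis ("12,7"), label.
    """
    params = params or GuideAssignmentParams()
    rows = []
    for cell_id, counts in gdo.iterrows():
        call = assign_guides(counts.to_dict(), params, cell_id=str(cell_id))
        if call is None:
            continue
        label = label_perturbation(call, guide_to_gene, params)
        rows.append(
            (
                str(cell_id),
                ",".join(call.guides),
                ",".join(str(u) for u in call.umis),
                str(label),
            )
        )
    return pd.DataFrame(rows, columns=["cell_id", "guides", "umis", "label"]).set_index("cell_id")
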