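"""UMI counting for antibody- and guide-derived tag libraries.

Antibody-derived tags (ADT), hashtag oligos (HTO) and guide-derived oligos
(GDO) are sequenced as short feature barcodes attached to a cell barcode
(CBC) and a unique molecular identifier (UMI).  This module turns read-level
evidence into per-modality cells x features UMI count matrices.

Two filters distinguish this counter from a plain tag counter:

* **conflict (purity) filtering** — a (CBC, UMI) pair whose reads split over
  more than one feature is ambiguous (PCR chimera or barcode collision); the
  pair is kept only if its majority feature holds strictly more than a
  purity fraction ``pi`` of the pair's reads, and contributes exactly one
  UMI to that feature.  Anything else is discarded.
* **read-floor filtering** — GDO UMIs backed by fewer than
  ``gdo_min_reads_per_umi`` reads (default 5) are discarded; guide capture
  is noisier than antibody capture and low-read UMIs are dominated by
  ambient molecules.

Feature barcodes (and, when a whitelist is supplied, cell barcodes) are
matched exactly or by a unique Hamming-distance-1 correction; ambiguous
corrections are treated as unmatched.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .errors import DuplicateBarcodeError, FormatError, MalformedRowError

MODALITIES = ("ADT", "HTO", "GDO")


@dataclass(frozen=True)
class FeatureEntry:
    feature_id: str
    display_name: str
    modality: str
    barcode_seq: str
    target_label: str


@dataclass
class FeatureReference:
    """Tag feature reference: id, modality, barcode sequence and target.

    ``target_label`` holds the targeted gene for GDO entries ("NT" marks
    non-targeting control guides) and the protein name for ADT entries.
    """

    entries: list[FeatureEntry]

    def __post_init__(self) -> None:
        ids = [e.feature_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise DuplicateBarcodeError("duplicate feature_id in reference")
        seqs = [e.barcode_seq for e in self.entries]
        if len(set(seqs)) != len(seqs):
            raise DuplicateBarcodeError("duplicate barcode_seq in reference")
        if len({len(s) for s in seqs}) > 1:
            raise MalformedRowError("barcode sequences have unequal lengths")
        for e in self.entries:
            if e.modality not in MODALITIES:
                raise MalformedRowError(f"unknown modality {e.modality!r}")

    @property
    def barcode_length(self) -> int:
        return len(self.entries[0].barcode_seq) if self.entries else 0

    @property
    def modalities(self) -> list[str]:
        present = {e.modality for e in self.entries}
        return [m for m in MODALITIES if m in present]

    def features(self, modality: str) -> list[FeatureEntry]:
        return [e for e in self.entries if e.modality == modality]

    def guide_to_gene(self) -> dict[str, str]:
        """Map of GDO feature id -> targeted gene symbol."""
        return {e.feature_id: e.target_label for e in self.entries if e.modality == "GDO"}

    def modality_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.entries:
            counts[e.modality] = counts.get(e.modality, 0) + 1
        return counts

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                (e.feature_id, e.display_name, e.modality, e.barcode_seq, e.target_label)
                for e in self.entries
            ],
            columns=["feature_id", "display_name", "modality", "barcode_seq", "target_label"],
        ).to_csv(path, index=False)


REQUIRED_REF_COLUMNS = ("feature_id", "display_name", "modality", "barcode_seq", "target_label")


def load_feature_reference(path: str | Path) -> FeatureReference:
    """Read a feature reference CSV.

    Expected columns: feature_id, display_name, modality, barcode_seq,
    target_label.  Raises :class:`MalformedRowError` on missing fields and
    :class:`DuplicateBarcodeError` on repeated barcodes.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in REQUIRED_REF_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedRowError(f"feature reference missing columns: {missing}")
    if df[list(REQUIRED_REF_COLUMNS)].isna().any().any():
        raise MalformedRowError("feature reference has empty fields")
    entries = [
        FeatureEntry(r.feature_id, r.display_name, r.modality, r.barcode_seq, r.target_label)
        for r in df.itertuples()
    ]
    return FeatureReference(entries)


@dataclass(frozen=True)
class TagRead:
    cell_barcode: str
    umi: str
    tag_seq: str
    n_reads: int = 1


@dataclass(frozen=True)
class UMISupport:
    """Read support for one (CBC, UMI, feature) triple."""

    cbc: str
    umi: str
    feature_id: str
    read_count: int


@dataclass
class CountingParams:
    """Knobs of the modified tag counter.

    purity_threshold must exceed 0.5 so at most one feature can win a UMI;
    the read floor applies to GDO UMIs only unless per-modality floors are
    given explicitly.
    """

    purity_threshold: float = 0.75
    gdo_min_reads_per_umi: int = 5
    max_hamming: int = 1
    cbc_whitelist: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        if not 0.5 < self.purity_threshold <= 1.0:
            raise ValueError("purity_threshold must be in (0.5, 1]")
        if self.gdo_min_reads_per_umi < 1:
            raise ValueError("gdo_min_reads_per_umi must be >= 1")

    def read_floor(self, modality: str) -> int:
        return self.gdo_min_reads_per_umi if modality == "GDO" else 1


@dataclass
class TagCountMatrix:
    """Cells x features UMI counts for one tag modality."""

    modality: str
    cell_ids: list[str]
    feature_ids: list[str]
    counts: np.ndarray  # (n_cells, n_features) int64

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.cell_ids), len(self.feature_ids)):
            raise FormatError("count matrix shape inconsistent with ids")
        if (self.counts < 0).any():
            raise FormatError("negative counts")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.cell_ids, columns=self.feature_ids)

    def __eq__(self, other: object) -> bool:  # bit-exact comparison
        if not isinstance(other, TagCountMatrix):
            return NotImplemented
        return (
            self.modality == other.modality
            and self.cell_ids == other.cell_ids
            and self.feature_ids == other.feature_ids
            and np.array_equal(self.counts, other.counts)
        )


def _match_with_hamming(
    query: str, exact: dict[str, str], by_length: Sequence[tuple[str, str]], max_hamming: int
) -> Optional[str]:
    """Return the unique id within Hamming <= max_hamming, else None."""
    hit = exact.get(query)
    if hit is not None:
        return hit
    if max_hamming <= 0:
        return None
    best: Optional[str] = None
    for seq, ident in by_length:
        if len(seq) != len(query):
            continue
        d = sum(a != b for a, b in zip(query, seq))
        if d <= max_hamming:
            if best is not None:
                return None  # ambiguous correction
            best = ident
    return best


def count_tags(
    reads: Iterable[TagRead | UMISupport | tuple],
    ref: FeatureReference,
    params: CountingParams | None = None,
) -> tuple[dict[str, TagCountMatrix], dict]:
    """Count tag UMIs per modality with conflict and read-floor filtering.

    ``reads`` may be :class:`TagRead` objects, ``(cbc, umi, tag_seq)`` or
    ``(cbc, umi, tag_seq, n_reads)`` tuples, or pre-aggregated
    :class:`UMISupport` records (tag already resolved to a feature id).

    Every distinct (CBC, UMI) pair falls into exactly one of three bins:

    * *retained* — its top feature holds strictly more than
      ``purity_threshold`` of its reads and the pair's total reads meet the
      modality read floor; contributes +1 UMI to (cell, top feature);
    * *discarded* — matched at least one feature but failed purity or floor;
    * *unmatched* — none of its reads matched a feature barcode (or its CBC
      failed whitelist correction).

    Returns ``(matrices, log)`` where ``matrices`` maps modality ->
    :class:`TagCountMatrix` (features in reference order, cells sorted) and
    ``log`` carries ``retained_umis``, ``discarded_umis``,
    ``unmatched_umi_groups``, ``unmatched_reads`` and the parameter echo.
    """
    params = params or CountingParams()
    L = ref.barcode_length
    feat_exact = {e.barcode_seq: e.feature_id for e in ref.entries}
    feat_list = [(e.barcode_seq, e.feature_id) for e in ref.entries]
    modality_of = {e.feature_id: e.modality for e in ref.entries}
    feat_cache: dict[str, Optional[str]] = {fid: fid for fid in modality_of}

    wl_exact = wl_list = None
    wl_cache: dict[str, Optional[str]] = {}
    if params.cbc_whitelist is not None:
        wl_exact = {b: b for b in params.cbc_whitelist}
        wl_list = [(b, b) for b in sorted(params.cbc_whitelist)]

    # (cbc, umi) -> {feature_id or None: reads}
    groups: dict[tuple[str, str], dict[Optional[str], int]] = defaultdict(
        lambda: defaultdict(int)
    )
    unmatched_reads = 0
    for r in reads:
        if isinstance(r, TagRead):
            cbc, umi, tag, n = r.cell_barcode, r.umi, r.tag_seq, r.n_reads
        elif isinstance(r, UMISupport):
            cbc, umi, tag, n = r.cbc, r.umi, r.feature_id, r.read_count
        else:
            cbc, umi, tag = r[0], r[1], r[2]
            n = int(r[3]) if len(r) > 3 else 1
        if wl_exact is not None:
            if cbc not in wl_cache:
                wl_cache[cbc] = _match_with_hamming(cbc, wl_exact, wl_list, params.max_hamming)
            corrected = wl_cache[cbc]
            if corrected is None:
                unmatched_reads += n
                groups[(cbc, umi)][None] += n
                continue
            cbc = corrected
        if tag not in feat_cache:
            query = tag[:L] if len(tag) > L else tag
            feat_cache[tag] = _match_with_hamming(query, feat_exact, feat_list, params.max_hamming)
        fid = feat_cache[tag]
        if fid is None:
            unmatched_reads += n
        groups[(cbc, umi)][fid] += n

    retained: dict[str, dict[tuple[str, str], int]] = {m: defaultdict(int) for m in MODALITIES}
    discarded = 0
    unmatched_groups = 0
    for (cbc, _umi), by_feat in groups.items():
        total = sum(by_feat.values())
        matched = {f: n for f, n in by_feat.items() if f is not None}
        if not matched:
            unmatched_groups += 1
            continue
        top_feat = max(matched, key=lambda f: (matched[f], f))
        if matched[top_feat] / total <= params.purity_threshold:
            discarded += 1
            continue
        modality = modality_of[top_feat]
        if total < params.read_floor(modality):
            discarded += 1
            continue
        retained[modality][(cbc, top_feat)] += 1

    matrices: dict[str, TagCountMatrix] = {}
    n_retained = 0
    for modality in ref.modalities:
        feats = [e.feature_id for e in ref.features(modality)]
        col = {f: j for j, f in enumerate(feats)}
        cells = sorted({cbc for (cbc, _f) in retained[modality]})
        row = {c: i for i, c in enumerate(cells)}
        counts = np.zeros((len(cells), len(feats)), dtype=np.int64)
        for (cbc, fid), n_umis in retained[modality].items():
            counts[row[cbc], col[fid]] += n_umis
            n_retained += n_umis
        matrices[modality] = TagCountMatrix(modality, cells, feats, counts)

    log = {
        "retained_umis": n_retained,
        "discarded_umis": discarded,
        "unmatched_umi_groups": unmatched_groups,
        "unmatched_reads": unmatched_reads,
        "observed_umi_groups": len(groups),
        "params": {
            "purity_threshold": params.purity_threshold,
            "gdo_min_reads_per_umi": params.gdo_min_reads_per_umi,
            "max_hamming": params.max_hamming,
            "cbc_whitelist_size": len(params.cbc_whitelist) if params.cbc_whitelist else None,
        },
    }
    return matrices, log


def read_tag_reads_tsv(path: str | Path) -> list[TagRead]:
    """Read tag evidence from a TSV with columns cbc, umi, tag_seq[, n_reads]."""
    df = pd.read_csv(path, sep="\t", dtype={"cbc": str, "umi": str, "tag_seq": str})
    n = df["n_reads"].astype(int) if "n_reads" in df.columns else np.ones(len(df), dtype=int)
    return [
        TagRead(c, u, t, int(k))
        for c, u, t, k in zip(df["cbc"], df["umi"], df["tag_seq"], n)
    ]


def write_tag_reads_tsv(reads: Iterable[UMISupport], path: str | Path) -> None:
    pd.DataFrame(
        [(r.cbc, r.umi, r.feature_id, r.read_count) for r in reads],
        columns=["cbc", "umi", "tag_seq", "n_reads"],
    ).to_csv(path, sep="\t", index=False)


def write_count_matrix(m: TagCountMatrix, out_dir: str | Path) -> None:
    """Write the 10x-style triple: matrix.mtx (features x cells) + TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(out / "matrix.mtx", sparse.coo_matrix(m.counts.T), field="integer")
    (out / "barcodes.tsv").write_text("".join(f"{c}\n" for c in m.cell_ids))
    (out / "features.tsv").write_text(
        "".join(f"{f}\t{f}\t{m.modality}\n" for f in m.feature_ids)
    )


def read_count_matrix(in_dir: str | Path) -> TagCountMatrix:
    """Read a matrix written by :func:`write_count_matrix` (round-trip exact)."""
    d = Path(in_dir)
    for name in ("matrix.mtx", "barcodes.tsv", "features.tsv"):
        if not (d / name).exists():
            raise FormatError(f"missing {name} in {d}")
    try:
        mat = spio.mmread(d / "matrix.mtx")
    except ValueError as exc:
        raise FormatError(f"bad matrix.mtx: {exc}") from exc
    counts = np.asarray(sparse.coo_matrix(mat).todense()).T.astype(np.int64)
    cells = (d / "barcodes.tsv").read_text().splitlines()
    feat_rows = [ln.split("\t") for ln in (d / "features.tsv").read_text().splitlines()]
    feats = [r[0] for r in feat_rows]
    modality = feat_rows[0][2] if feat_rows and len(feat_rows[0]) > 2 else "ADT"
    if counts.shape != (len(cells), len(feats)):
        raise FormatError(
            f"matrix is {counts.shape} but found {len(cells)} barcodes / {len(feats)} features"
        )
    return TagCountMatrix(modality, cells, feats, counts)
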