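"""Synthetic high-MOI perturb-CITE-seq datasets with full ground truth.

Emulates the tag side of a high-multiplicity-of-infection CRISPR
perturbation experiment in dendritic cells: cells are infected at MOI
``moi_lambda`` (integrations per cell are zero-truncated Poisson, since
antibiotic selection keeps only infected cells) with guides drawn uniformly
from a pool of 32 targeting gRNAs over 11 genes plus non-targeting (NT)
controls; each cell carries one of 5 hashtag oligos (HTO); droplets merge
two cells at ``doublet_rate``; and ADT (CD86, PD-L1), HTO (MHC-I/CD45
proxy) and GDO counts are negative binomial with perturbation effects
applied multiplicatively in log2 space, including pairwise interaction
terms (the default effect matrix plants Cebpb+Med12 as the strongest
CD86-up / PD-L1-down / MHC-I-up combination).  A small synthetic gene panel
with per-state and per-perturbation expression programs exercises signature
scoring, state assignment and differential expression.

Every random draw flows through one seeded generator, so a config + seed
pair is a complete description of the dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import InvalidConfigError
from .guides import GuideAssignmentParams, GuideCall, label_perturbation
from .tag_counting import (
    FeatureEntry,
    FeatureReference,
    TagCountMatrix,
    UMISupport,
    write_count_matrix,
)

TARGET_GENES = [
    "Cebpb", "Med12", "Nr4a3", "Zeb2", "Stat5b", "Med14",
    "Stat3", "Socs1", "Irf8", "Rela", "Myb",
]

# log2 effects on (CD86 ADT, PD-L1 ADT, MHC-I / hashtag epitope)
DEFAULT_EFFECTS: dict[str, tuple[float, float, float]] = {
    "Cebpb": (0.8, -0.6, 0.3),
    "Med12": (0.6, -0.3, 0.2),
    "Nr4a3": (0.3, -0.1, 0.1),
    "Zeb2": (0.2, -0.2, 0.0),
    "Stat5b": (0.3, 0.0, 0.1),
    "Med14": (0.2, -0.1, 0.0),
    "Stat3": (-0.2, 0.1, 0.0),
    "Socs1": (0.1, 0.2, 0.0),
    "Irf8": (0.0, 0.1, -0.1),
    "Rela": (-0.1, 0.0, 0.1),
    "Myb": (0.1, 0.1, 0.0),
}

DEFAULT_INTERACTIONS: dict[tuple[str, str], tuple[float, float, float]] = {
    ("Cebpb", "Med12"): (0.5, -0.4, 0.3),
}


def default_guide_pool(n_nt: int = 4) -> list[tuple[str, str]]:
    """32 targeting guides over the 11 target genes plus ``n_nt`` NT guides."""
    pool = []
    for gi, gene in enumerate(TARGET_GENES):
        n_guides = 3 if gi < 10 else 2  # 3*10 + 2 = 32
        for k in range(1, n_guides + 1):
            pool.append((f"g{gene}_{k}", gene))
    for k in range(1, n_nt + 1):
        pool.append((f"gNT_{k}", "NT"))
    return pool


@dataclass
class SimulationConfig:
    """Stated world of the synthetic experiment; see module docstring."""

    n_cells: int = 3000
    moi_lambda: float = 1.6
    guide_pool: list[tuple[str, str]] = field(default_factory=default_guide_pool)
    n_htos: int = 5
    doublet_rate: float = 0.05
    truncated_poisson: bool = True
    # tag count model
    hto_mu_pos: float = 200.0
    hto_mu_bg: float = 10.0
    hto_efficiency: Optional[list[float]] = None  # per-HTO staining factors
    gdo_mu: float = 30.0
    gdo_ambient_mu: float = 0.25
    adt_baseline: dict[str, float] = field(
        default_factory=lambda: {"CD86": 150.0, "PD-L1": 150.0}
    )
    nb_dispersion: float = 0.1
    effect_matrix: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    interaction_terms: dict[tuple[str, str], tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_INTERACTIONS)
    )
    # expression model
    simulate_expression: bool = True
    n_genes: int = 500
    expression_mean_total: float = 8000.0
    depth_sigma: float = 0.25
    n_states: int = 4
    state_program_size: int = 25
    state_program_log2fc: float = 2.0
    perturbation_own_log2fc: float = -1.0
    # read-level model
    reads_per_umi: dict[str, tuple[int, float]] = field(
        default_factory=lambda: {"GDO": (2, 5.0), "ADT": (1, 2.0), "HTO": (1, 2.0)}
    )
    chimera_rate: float = 0.005
    chimera_frac: float = 0.25
    barcode_length: int = 16
    feature_barcode_length: int = 15

    def __post_init__(self) -> None:
        if self.moi_lambda <= 0:
            raise InvalidConfigError("moi_lambda must be positive")
        if not 0.0 <= self.doublet_rate <= 1.0:
            raise InvalidConfigError("doublet_rate must be in [0, 1]")
        if not 0.0 <= self.chimera_rate <= 1.0:
            raise InvalidConfigError("chimera_rate must be in [0, 1]")
        if self.nb_dispersion < 0:
            raise InvalidConfigError("nb_dispersion must be >= 0")
        if self.n_htos < 2:
            raise InvalidConfigError("need >= 2 HTOs")

    @property
    def hto_ids(self) -> list[str]:
        return [f"HTO{i + 1}" for i in range(self.n_htos)]

    @property
    def gene_panel(self) -> list[str]:
        named = list(TARGET_GENES)
        fillers = [f"Gene{i:04d}" for i in range(1, self.n_genes - len(named) + 1)]
        return fillers + named

    def state_signatures(self) -> dict[str, list[str]]:
        panel = self.gene_panel
        sigs = {}
        for s in range(self.n_states):
            start = s * self.state_program_size
            sigs[f"state_{chr(65 + s)}"] = panel[start : start + self.state_program_size]
        return sigs


def ztp_multi_fraction(lam: float) -> float:
    """P(K >= 2 | K >= 1) for K ~ Poisson(lam): the multi-guide cell fraction.

    Closed form (1 - e^-lam - lam e^-lam) / (1 - e^-lam); 0.5952 at the
    design MOI of 1.6.  Strictly increasing in lam, -> 0 as lam -> 0+.
    """
    if lam <= 0:
        raise InvalidConfigError("lambda must be positive")
    e = math.exp(-lam)
    return (1.0 - e - lam * e) / (1.0 - e)


def _sample_ztp(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Zero-truncated Poisson via rejection of zeros (exact)."""
    k = rng.poisson(lam, size)
    zero = k == 0
    while zero.any():
        k[zero] = rng.poisson(lam, int(zero.sum()))
        zero = k == 0
    return k


def _nb(rng: np.random.Generator, mu, dispersion: float) -> np.ndarray:
    """Negative binomial with mean mu and var mu + dispersion * mu^2."""
    mu = np.asarray(mu, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    return rng.poisson(rng.gamma(shape, mu * dispersion))


def _random_barcodes(rng: np.random.Generator, n: int, length: int) -> list[str]:
    alphabet = np.array(list("ACGT"))
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        for bc in ["".join(row) for row in alphabet[rng.integers(0, 4, (n - len(out), length))]]:
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
    return out


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    seed: int
    feature_ref: FeatureReference
    tags: dict[str, TagCountMatrix]  # droplets x features per modality
    expression: Optional[pd.DataFrame]  # droplets x genes UMI counts
    truth: pd.DataFrame  # one row per droplet

    @property
    def droplet_ids(self) -> list[str]:
        return list(self.truth["droplet_id"])

    def tag_frame(self, modality: str) -> pd.DataFrame:
        return self.tags[modality].to_frame()

    def write(self, out_dir: str | Path) -> dict[str, str]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {}
        for modality, m in self.tags.items():
            d = out / f"{modality.lower()}_counts"
            write_count_matrix(m, d)
            manifest[modality] = str(d)
        if self.expression is not None:
            d = out / "gex_counts"
            write_count_matrix(
                TagCountMatrix(
                    "GEX",
                    list(self.expression.index),
                    list(self.expression.columns),
                    self.expression.to_numpy(),
                ),
                d,
            )
            manifest["GEX"] = str(d)
        self.feature_ref.to_csv(out / "feature_reference.csv")
        manifest["feature_reference"] = str(out / "feature_reference.csv")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        manifest["truth"] = str(out / "truth.tsv")
        return manifest


def _build_feature_reference(cfg: SimulationConfig, rng: np.random.Generator) -> FeatureReference:
    n_feat = len(cfg.adt_baseline) + cfg.n_htos + len(cfg.guide_pool)
    seqs = _random_barcodes(rng, n_feat, cfg.feature_barcode_length)
    entries = []
    i = 0
    for prot in cfg.adt_baseline:
        entries.append(FeatureEntry(prot, prot, "ADT", seqs[i], prot))
        i += 1
    for hto in cfg.hto_ids:
        entries.append(FeatureEntry(hto, hto, "HTO", seqs[i], "MHC-I/CD45"))
        i += 1
    for guide, gene in cfg.guide_pool:
        entries.append(FeatureEntry(guide, guide, "GDO", seqs[i], gene))
        i += 1
    return FeatureReference(entries)


def _cell_effects(
    genes: set[str], cfg: SimulationConfig
) -> tuple[float, float, float]:
    """Summed log2 tag effects of a cell's targeted gene set (with interactions)."""
    d = np.zeros(3)
    for g in genes:
        if g in cfg.effect_matrix:
            d += np.array(cfg.effect_matrix[g])
    for (a, b), delta in cfg.interaction_terms.items():
        if a in genes and b in genes:
            d += np.array(delta)
    return float(d[0]), float(d[1]), float(d[2])


def simulate_dataset(config: SimulationConfig | None = None, seed: int = 0) -> SimulatedDataset:
    """Generate a droplet-level dataset with ground truth.

    Deterministic given (config, seed): all draws come from one
    ``numpy.random.default_rng(seed)``.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    ref = _build_feature_reference(cfg, rng)
    guide_ids = [g for g, _ in cfg.guide_pool]
    guide_gene = dict(cfg.guide_pool)
    label_params = GuideAssignmentParams()

    n = cfg.n_cells
    if cfg.truncated_poisson:
        n_int = _sample_ztp(rng, cfg.moi_lambda, n)
    else:
        n_int = rng.poisson(cfg.moi_lambda, n)
    cell_guides = [
        tuple(sorted(rng.choice(len(guide_ids), size=int(k), replace=True).tolist()))
        for k in n_int
    ]
    hashtags = rng.integers(0, cfg.n_htos, n)
    states = rng.integers(0, cfg.n_states, n)

    # droplet formation: doublet_rate of droplets hold two cells
    n_doublets = int(round(cfg.doublet_rate * n / (1.0 + cfg.doublet_rate)))
    order = rng.permutation(n)
    droplets: list[tuple[int, ...]] = [
        (int(order[2 * i]), int(order[2 * i + 1])) for i in range(n_doublets)
    ]
    droplets += [(int(c),) for c in order[2 * n_doublets :]]
    # deterministic order independent of the pairing permutation
    droplets.sort()
    n_drop = len(droplets)
    barcodes = _random_barcodes(rng, n_drop, cfg.barcode_length)

    hto_eff = np.asarray(cfg.hto_efficiency if cfg.hto_efficiency is not None else np.ones(cfg.n_htos))
    adt_names = list(cfg.adt_baseline)
    adt_base = np.array([cfg.adt_baseline[a] for a in adt_names])

    # per-cell log2 tag effect triples
    cell_gene_sets = [
        {guide_gene[guide_ids[g]] for g in gs if guide_gene[guide_ids[g]] != "NT"}
        for gs in cell_guides
    ]
    eff = np.array([_cell_effects(gs, cfg) for gs in cell_gene_sets])

    # expected counts per droplet
    adt_mu = np.zeros((n_drop, len(adt_names)))
    hto_mu = np.zeros((n_drop, cfg.n_htos))
    gdo_mu = np.full((n_drop, len(guide_ids)), cfg.gdo_ambient_mu)
    rows = []
    for di, members in enumerate(droplets):
        tags = set()
        guides_all: list[int] = []
        genes_all: set[str] = set()
        for c in members:
            adt_mu[di] += adt_base * 2.0 ** np.array([eff[c, 0], eff[c, 1]])
            hto_mu[di] += cfg.hto_mu_bg * hto_eff
            hto_mu[di, hashtags[c]] += (
                (cfg.hto_mu_pos - cfg.hto_mu_bg) * hto_eff[hashtags[c]] * 2.0 ** eff[c, 2]
            )
            for g in cell_guides[c]:
                gdo_mu[di, g] += cfg.gdo_mu
                guides_all.append(g)
            tags.add(cfg.hto_ids[hashtags[c]])
            genes_all |= cell_gene_sets[c]
        guide_names = tuple(guide_ids[g] for g in sorted(guides_all))
        if guide_names:
            call = GuideCall("", guide_names, tuple(1 for _ in guide_names), tuple(0.0 for _ in guide_names))
            label = str(label_perturbation(call, guide_gene, label_params))
        else:
            label = "none"
        rows.append(
            {
                "droplet_id": barcodes[di],
                "n_cells": len(members),
                "is_doublet": len(members) == 2,
                "hashtags": ",".join(sorted(tags)),
                "n_integrations": len(guides_all),
                "guides": ",".join(guide_names),
                "true_label": label,
                "true_state": ",".join(f"state_{chr(65 + states[c])}" for c in members),
            }
        )
    truth = pd.DataFrame(rows)

    tags_out = {
        "ADT": TagCountMatrix("ADT", barcodes, adt_names, _nb(rng, adt_mu, cfg.nb_dispersion)),
        "HTO": TagCountMatrix("HTO", barcodes, cfg.hto_ids, _nb(rng, hto_mu, cfg.nb_dispersion)),
        "GDO": TagCountMatrix("GDO", barcodes, guide_ids, _nb(rng, gdo_mu, cfg.nb_dispersion)),
    }

    expression = None
    if cfg.simulate_expression:
        panel = cfg.gene_panel
        gidx = {g: i for i, g in enumerate(panel)}
        base = rng.gamma(2.0, 1.0, cfg.n_genes)
        base = base / base.sum()  # relative expression profile
        sigs = cfg.state_signatures()
        state_delta = np.zeros((cfg.n_states, cfg.n_genes))
        for s in range(cfg.n_states):
            for g in sigs[f"state_{chr(65 + s)}"]:
                state_delta[s, gidx[g]] = cfg.state_program_log2fc
        pert_delta = np.zeros((len(TARGET_GENES), cfg.n_genes))
        for ti, tg in enumerate(TARGET_GENES):
            pert_delta[ti, gidx[tg]] = cfg.perturbation_own_log2fc
        tidx = {g: i for i, g in enumerate(TARGET_GENES)}

        expr_mu = np.zeros((n_drop, cfg.n_genes))
        for di, members in enumerate(droplets):
            for c in members:
                delta = state_delta[states[c]].copy()
                for g in cell_gene_sets[c]:
                    delta += pert_delta[tidx[g]]
                prof = base * 2.0**delta
                depth = cfg.expression_mean_total * rng.lognormal(0.0, cfg.depth_sigma)
                expr_mu[di] += depth * prof / prof.sum()
        expression = pd.DataFrame(
            _nb(rng, expr_mu, cfg.nb_dispersion), index=barcodes, columns=panel
        )

    return SimulatedDataset(cfg, seed, ref, tags_out, expression, truth)


_BASES = "ACGT"


def _encode_umi(index: int, length: int = 10) -> str:
    chars = []
    for _ in range(length):
        chars.append(_BASES[index % 4])
        index //= 4
    return "".join(chars)


def simulate_tag_reads(
    dataset: SimulatedDataset, seed: int = 0, modalities: tuple[str, ...] = ("ADT", "HTO", "GDO")
) -> list[UMISupport]:
    """Explode the dataset's tag matrices into read-level UMI evidence.

    Each true UMI becomes one record with reads drawn from the modality's
    shifted-Poisson ``reads_per_umi`` law; with probability ``chimera_rate``
    a UMI also receives minority reads (``chimera_frac`` of its primary
    reads, rounded, at least 1) on a second random feature of the same
    modality, emulating PCR chimeras.  UMI sequences are unique within each
    cell barcode by construction.  With chimera_rate 0 and all read counts
    at or above the modality floor, re-counting these records reproduces
    the true matrices exactly.
    """
    cfg = dataset.config
    rng = np.random.default_rng(seed)
    records: list[UMISupport] = []
    umi_counter: dict[str, int] = {}
    for modality in modalities:
        m = dataset.tags[modality]
        shift, lam = cfg.reads_per_umi[modality]
        feats = m.feature_ids
        nz_cells, nz_feats = np.nonzero(m.counts)
        for ci, fj in zip(nz_cells, nz_feats):
            cbc = m.cell_ids[ci]
            for _ in range(int(m.counts[ci, fj])):
                idx = umi_counter.get(cbc, 0)
                umi_counter[cbc] = idx + 1
                umi = _encode_umi(idx)
                n_reads = int(shift + (rng.poisson(lam) if lam > 0 else 0))
                records.append(UMISupport(cbc, umi, feats[fj], n_reads))
                if len(feats) > 1 and cfg.chimera_rate > 0 and rng.random() < cfg.chimera_rate:
                    other = int(rng.integers(0, len(feats) - 1))
                    if other >= fj:
                        other += 1
                    minor = max(1, int(round(n_reads * cfg.chimera_frac)))
                    records.append(UMISupport(cbc, umi, feats[other], minor))
    return records
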