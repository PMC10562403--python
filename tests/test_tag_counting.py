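"""Tag counting: purity/read-floor rules, barcode correction, MTX round trips."""

from collections import defaultdict

import numpy as np
import pytest

from perturbcite import (
    CountingParams,
    FeatureReference,
    SimulationConfig,
    TagCountMatrix,
    count_tags,
    load_feature_reference,
    read_count_matrix,
    simulate_dataset,
    simulate_tag_reads,
    write_count_matrix,
)
from perturbcite.errors import DuplicateBarcodeError, FormatError, MalformedRowError
from perturbcite.simulate import _build_feature_reference, _random_barcodes
from perturbcite.tag_counting import FeatureEntry


def small_ref():
    return FeatureReference(
        [
            FeatureEntry("CD86", "CD86", "ADT", "AAAAACCC", "CD86"),
            FeatureEntry("PD-L1", "PD-L1", "ADT", "CCCCCGGG", "PD-L1"),
            FeatureEntry("HTO1", "HTO1", "HTO", "GGGGGTTT", "MHC"),
            FeatureEntry("HTO2", "HTO2", "HTO", "TTTTTAAA", "MHC"),
            FeatureEntry("gA_1", "gA_1", "GDO", "ACACACAC", "A"),
            FeatureEntry("gB_1", "gB_1", "GDO", "GTGTGTGT", "B"),
        ]
    )


def brute_force_count(reads, ref, params):
    """Literal re-statement of the counting rules, independent of count_tags.

    Groups reads by (cbc, umi), matches tags by exact/unique-Hamming-1
    lookup, and applies the purity and modality read-floor rules one group
    at a time with plain python loops.
    """
    def match(seq, barcodes):
        seq = seq[: len(next(iter(barcodes)))]
        if seq in barcodes:
            return barcodes[seq]
        hits = [
            fid
            for bc, fid in barcodes.items()
            if len(bc) == len(seq)
            and sum(x != y for x, y in zip(bc, seq)) <= params.max_hamming
        ]
        return hits[0] if len(hits) == 1 else None

    barcodes = {e.barcode_seq: e.feature_id for e in ref.entries}
    modality = {e.feature_id: e.modality for e in ref.entries}
    groups = defaultdict(lambda: defaultdict(int))
    for cbc, umi, tag, n in reads:
        fid = tag if tag in modality else match(tag, barcodes)
        groups[(cbc, umi)][fid] += n
    tallies = {m: defaultdict(int) for m in ("ADT", "HTO", "GDO")}
    discarded = 0
    for (cbc, _umi), by_feat in groups.items():
        total = sum(by_feat.values())
        matched = {f: n for f, n in by_feat.items() if f is not None}
        if not matched:
            continue
        top = max(matched, key=lambda f: (matched[f], f))
        if matched[top] / total <= params.purity_threshold:
            discarded += 1
            continue
        floor = params.gdo_min_reads_per_umi if modality[top] == "GDO" else 1
        if total < floor:
            discarded += 1
            continue
        tallies[modality[top]][(cbc, top)] += 1
    return tallies, discarded


def as_frames(matrices):
    return {m: mat.to_frame() for m, mat in matrices.items()}


class TestFeatureReference:
    def test_modality_counts_from_csv(self, tmp_path):
        """A 2 ADT + 5 HTO + 32 GDO reference parses with those counts."""
        cfg = SimulationConfig()
        ref = _build_feature_reference(cfg, np.random.default_rng(0))
        path = tmp_path / "ref.csv"
        ref.to_csv(path)
        loaded = load_feature_reference(path)
        counts = loaded.modality_counts()
        assert counts["ADT"] == 2 and counts["HTO"] == 5 and counts["GDO"] == 36
        assert sum(1 for e in loaded.entries if e.modality == "GDO" and e.target_label != "NT") == 32

    def test_duplicate_barcode_rejected(self, tmp_path):
        path = tmp_path / "ref.csv"
        path.write_text(
            "feature_id,display_name,modality,barcode_seq,target_label\n"
            "f1,f1,ADT,ACGTACGT,X\nf2,f2,ADT,ACGTACGT,Y\n"
        )
        with pytest.raises(DuplicateBarcodeError):
            load_feature_reference(path)

    def test_empty_reference_is_valid(self, tmp_path):
        path = tmp_path / "ref.csv"
        path.write_text("feature_id,display_name,modality,barcode_seq,target_label\n")
        assert load_feature_reference(path).entries == []

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "ref.csv"
        path.write_text("feature_id,modality\nf1,ADT\n")
        with pytest.raises(MalformedRowError):
            load_feature_reference(path)


class TestCountingRules:
    def test_purity_rule(self):
        """9:1 read split passes pi=0.75; 6:4 is discarded."""
        ref = small_ref()
        reads = [
            ("cbc1", "umi1", "AAAAACCC", 9),
            ("cbc1", "umi1", "CCCCCGGG", 1),
            ("cbc1", "umi2", "AAAAACCC", 6),
            ("cbc1", "umi2", "CCCCCGGG", 4),
        ]
        mats, log = count_tags(reads, ref, CountingParams(purity_threshold=0.75))
        assert as_frames(mats)["ADT"].loc["cbc1", "CD86"] == 1
        assert log["discarded_umis"] == 1
        assert log["retained_umis"] == 1

    def test_gdo_read_floor_applies_to_gdo_only(self):
        """A 4-read GDO UMI is dropped; a 1-read ADT UMI is kept."""
        ref = small_ref()
        reads = [("cbc2", "umi3", "ACACACAC", 4), ("cbc2", "umi4", "AAAAACCC", 1)]
        mats, log = count_tags(reads, ref, CountingParams(gdo_min_reads_per_umi=5))
        assert mats["GDO"].counts.sum() == 0
        assert as_frames(mats)["ADT"].loc["cbc2", "CD86"] == 1
        assert log["discarded_umis"] == 1

    def test_hamming_correction_and_ambiguity(self):
        ref = FeatureReference(
            [
                FeatureEntry("f1", "f1", "ADT", "AAAAAAAA", "x"),
                FeatureEntry("f2", "f2", "ADT", "AAAAAATT", "y"),
            ]
        )
        # one mismatch from f1 only -> corrected; equidistant from both -> dropped
        reads = [("c", "u1", "AAAAAAAC", 3), ("c", "u2", "AAAAAAAT", 3)]
        mats, log = count_tags(reads, ref)
        frame = as_frames(mats)["ADT"]
        assert frame.loc["c", "f1"] == 1 and frame.loc["c", "f2"] == 0
        assert log["unmatched_umi_groups"] == 1

    def test_tag_longer_than_reference_is_trimmed(self):
        ref = small_ref()
        mats, _ = count_tags([("c", "u", "AAAAACCC" + "TTTTTTTTTTTT", 2)], ref)
        assert as_frames(mats)["ADT"].loc["c", "CD86"] == 1

    def test_cbc_whitelist_correction(self):
        ref = small_ref()
        params = CountingParams(cbc_whitelist=frozenset({"AAAATTTT"}))
        reads = [("AAAATTTA", "u1", "AAAAACCC", 2), ("CCCCCCCC", "u2", "AAAAACCC", 2)]
        mats, log = count_tags(reads, ref, params)
        assert mats["ADT"].cell_ids == ["AAAATTTT"]
        assert log["unmatched_umi_groups"] == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle(self, seed):
        """count_tags equals the literal brute-force counter bit-exactly."""
        reads, ref, params = random_instance(np.random.default_rng(seed), max_reads=2000)
        mats, log = count_tags(reads, ref, params)
        expected, discarded = brute_force_count(reads, ref, params)
        assert log["discarded_umis"] == discarded
        for modality, mat in mats.items():
            frame = mat.to_frame()
            assert frame.to_numpy().sum() == sum(expected[modality].values())
            for (cbc, fid), n in expected[modality].items():
                assert frame.loc[cbc, fid] == n

    def test_monotonicity_in_thresholds(self, rng):
        """Raising purity or the GDO floor never increases any entry."""
        reads, ref, _ = random_instance(rng, max_reads=3000)
        base, _ = count_tags(reads, ref, CountingParams(0.6, 2))
        for params in (CountingParams(0.9, 2), CountingParams(0.6, 8)):
            tighter, _ = count_tags(reads, ref, params)
            for m in base:
                a = base[m].to_frame()
                b = tighter[m].to_frame().reindex(index=a.index, columns=a.columns, fill_value=0)
                assert (b.to_numpy() <= a.to_numpy()).all()

    def test_conservation(self, rng):
        """retained + discarded + unmatched groups == distinct (cbc, umi) pairs."""
        reads, ref, params = random_instance(rng, max_reads=3000)
        _, log = count_tags(reads, ref, params)
        assert (
            log["retained_umis"] + log["discarded_umis"] + log["unmatched_umi_groups"]
            == log["observed_umi_groups"]
        )


def random_instance(rng, max_reads=2000):
    """Random reads over a random small reference, with noise and junk tags."""
    n_feat = int(rng.integers(3, 10))
    seqs = _random_barcodes(rng, n_feat, 12)
    modalities = ["ADT", "HTO", "GDO"]
    ref = FeatureReference(
        [
            FeatureEntry(f"f{i}", f"f{i}", modalities[int(rng.integers(0, 3))], seqs[i], "x")
            for i in range(n_feat)
        ]
    )
    cells = _random_barcodes(rng, 20, 8)
    n_groups = int(rng.integers(20, max(21, max_reads // 8)))
    reads = []
    for gi in range(n_groups):
        cbc = cells[int(rng.integers(0, len(cells)))]
        umi = f"U{gi % 97:03d}"
        for _ in range(int(rng.integers(1, 4))):
            if rng.random() < 0.1:
                tag = "".join(rng.choice(list("ACGT"), 12))  # junk
            else:
                tag = list(seqs[int(rng.integers(0, n_feat))])
                if rng.random() < 0.3:  # sequencing error
                    pos = int(rng.integers(0, 12))
                    tag[pos] = rng.choice(list("ACGT"))
                tag = "".join(tag)
            reads.append((cbc, umi, tag, int(rng.integers(1, 12))))
    params = CountingParams(
        purity_threshold=float(rng.uniform(0.55, 0.95)),
        gdo_min_reads_per_umi=int(rng.integers(1, 8)),
    )
    return reads, ref, params


class TestMatrixIO:
    def test_round_trip_identity(self, tmp_path):
        m = TagCountMatrix("ADT", ["c1", "c2", "c3"], ["f1", "f2"], np.arange(6).reshape(3, 2))
        write_count_matrix(m, tmp_path / "m")
        assert read_count_matrix(tmp_path / "m") == m

    def test_empty_matrix_round_trip(self, tmp_path):
        m = TagCountMatrix("HTO", [], ["f1", "f2"], np.zeros((0, 2), dtype=int))
        write_count_matrix(m, tmp_path / "m")
        assert read_count_matrix(tmp_path / "m") == m

    def test_missing_or_corrupt_mtx(self, tmp_path):
        with pytest.raises(FormatError):
            read_count_matrix(tmp_path)
        m = TagCountMatrix("ADT", ["c1"], ["f1"], np.ones((1, 1), dtype=int))
        write_count_matrix(m, tmp_path / "m")
        (tmp_path / "m" / "matrix.mtx").write_text("1 1 1\n")  # header stripped
        with pytest.raises(FormatError):
            read_count_matrix(tmp_path / "m")


def test_noise_free_read_round_trip():
    """Counting zero-noise simulated reads reproduces the true UMI matrices."""
    cfg = SimulationConfig(
        n_cells=120,
        simulate_expression=False,
        chimera_rate=0.0,
        reads_per_umi={"GDO": (6, 0.0), "ADT": (2, 0.0), "HTO": (2, 0.0)},
    )
    ds = simulate_dataset(cfg, seed=3)
    reads = simulate_tag_reads(ds, seed=4)
    mats, log = count_tags(reads, ds.feature_ref, CountingParams())
    assert log["discarded_umis"] == 0
    for modality in ("ADT", "HTO", "GDO"):
        truth = ds.tag_frame(modality)
        truth = truth.loc[truth.sum(axis=1) > 0]  # cells with no UMIs emit no reads
        got = mats[modality].to_frame()
        assert got.shape == truth.shape
        assert (got.loc[truth.index, truth.columns] == truth).all().all()
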