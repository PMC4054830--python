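"""Window extraction, site enumeration, benchmark curation, partitioning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylsite.curation import (
    AMINO_ACIDS,
    BenchmarkDataset,
    CurationError,
    InvalidResidueError,
    ProteinRecord,
    build_benchmark,
    count_peptide_space,
    enumerate_sites,
    extract_window,
    load_records,
    partition_negatives,
    read_benchmark,
    write_annotations,
    write_benchmark,
    write_fasta,
)


class TestExtractWindow:
    @pytest.mark.parametrize(
        "sequence,center,xi,expected",
        [
            ("ACDEFRGHIKL", 6, 5, "ACDEFRGHIKL"),  # window covers exactly
            ("RACDEF", 1, 5, "RRRRRRACDEF"),  # N-terminal fill
            ("ACDEFK", 6, 5, "ACDEFKKKKKK"),  # C-terminal fill
            ("ARK", 2, 0, "R"),  # xi = 0 degenerate window
            ("ARK", 2, 1, "ARK"),
        ],
    )
    def test_examples(self, sequence, center, xi, expected):
        assert extract_window(sequence, center, xi) == expected

    def test_center_out_of_range(self):
        with pytest.raises(CurationError):
            extract_window("ACDEF", 0, 2)
        with pytest.raises(CurationError):
            extract_window("ACDEF", 6, 2)

    def test_non_standard_residue_in_span(self):
        with pytest.raises(InvalidResidueError):
            extract_window("ACXEFRGHIKL", 6, 5)

    @given(
        seq=st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=40),
        xi=st.integers(min_value=0, max_value=8),
        data=st.data(),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_length_and_center_invariant(self, seq, xi, data):
        pos = data.draw(st.integers(min_value=1, max_value=len(seq)))
        window = extract_window(seq, pos, xi)
        assert len(window) == 2 * xi + 1
        assert window[xi] == seq[pos - 1]


class TestEnumerateSites:
    @pytest.mark.parametrize(
        "sequence,residue_type,expected",
        [
            ("ARKRA", "R", [2, 4]),
            ("ARKRA", "K", [3]),
            ("AAAA", "R", []),
        ],
    )
    def test_examples(self, sequence, residue_type, expected):
        assert enumerate_sites(sequence, residue_type) == expected

    def test_positions_strictly_increasing(self, rng):
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=200))
        sites = enumerate_sites(seq, "K")
        assert all(a < b for a, b in zip(sites, sites[1:]))
        assert all(seq[p - 1] == "K" for p in sites)


class TestBuildBenchmark:
    def test_toy_counts(self, toy_records):
        ds = build_benchmark(toy_records, "R", xi=5)
        assert len(ds.positives) == 2
        assert len(ds.negatives) == 5

    def test_duplicate_negatives_kept_once(self):
        # identical 11-mer negative context in two different proteins
        shared = "ACDEFRGHIKL"
        records = [
            ProteinRecord("A1", "WWWWW" + shared + "WWWWW", {"R": set()}),
            ProteinRecord("A2", "YYYYY" + shared + "YYYYY", {"R": set()}),
        ]
        ds = build_benchmark(records, "R", xi=5)
        peptides = [s.peptide for s in ds.negatives]
        assert peptides.count(shared) == 1
        # first occurrence (input order) is the survivor
        assert next(s for s in ds.negatives if s.peptide == shared).source_accession == "A1"

    def test_self_conflict_removed_from_both(self):
        shared = "ACDEFRGHIKL"
        records = [
            ProteinRecord("B1", "WWWWW" + shared + "WWWWW", {"R": {11}}),
            ProteinRecord("B2", "YYYYY" + shared + "YYYYY", {"R": set()}),
        ]
        ds = build_benchmark(records, "R", xi=5)
        assert shared not in {s.peptide for s in ds.positives}
        assert shared not in {s.peptide for s in ds.negatives}

    def test_label_sets_disjoint_property(self, rng):
        seqs = ["".join(rng.choice(list(AMINO_ACIDS), size=150)) for _ in range(10)]
        records = []
        for i, seq in enumerate(seqs):
            sites = enumerate_sites(seq, "K")
            annotated = set(sites[::3])
            records.append(ProteinRecord(f"S{i}", seq, {"K": annotated}))
        ds = build_benchmark(records, "K", xi=5)
        assert {s.peptide for s in ds.positives}.isdisjoint(
            {s.peptide for s in ds.negatives}
        )

    def test_invalid_annotation_raises_with_accession(self):
        rec = ProteinRecord("BAD1", "ACDEFRGHIKL", {"R": {3}})  # position 3 is D
        with pytest.raises(CurationError, match="BAD1"):
            build_benchmark([rec], "R")

    def test_nonstandard_window_skipped(self, caplog):
        rec = ProteinRecord("U1", "XXXXXRYYYYYACDEFRGHIKL", {"R": set()})
        with caplog.at_level("WARNING"):
            ds = build_benchmark([rec], "R", xi=5)
        assert len(ds.negatives) == 1  # only the clean window survives


class TestPartitionNegatives:
    @pytest.mark.parametrize(
        "n,n_subsets,expected_sizes",
        [
            (1296, 7, {185: 6, 186: 1}),  # Arg-benchmark negative split
            (1518, 7, {217: 6, 216: 1}),  # Lys-benchmark negative split
            (6, 3, {2: 3}),
        ],
    )
    def test_subset_sizes(self, n, n_subsets, expected_sizes):
        partition = partition_negatives(list(range(n)), n_subsets, seed=1)
        sizes = partition.sizes
        assert {s: sizes.count(s) for s in set(sizes)} == expected_sizes

    def test_union_and_disjointness(self):
        items = list(range(100))
        partition = partition_negatives(items, 7, seed=3)
        combined = [x for subset in partition.subsets for x in subset]
        assert sorted(combined) == items
        assert len(set(combined)) == len(items)

    def test_deterministic_per_seed_and_seed_sensitive(self):
        items = list(range(100))
        a = partition_negatives(items, 4, seed=11)
        b = partition_negatives(items, 4, seed=11)
        c = partition_negatives(items, 4, seed=12)
        assert a.subsets == b.subsets
        assert a.subsets != c.subsets

    def test_out_of_range_subsets(self):
        with pytest.raises(CurationError):
            partition_negatives(list(range(5)), 0)
        with pytest.raises(CurationError):
            partition_negatives(list(range(5)), 6)

    def test_accepts_dataset(self, toy_records):
        ds = build_benchmark(toy_records, "R")
        partition = partition_negatives(ds, 2, seed=0)
        assert sum(partition.sizes) == len(ds.negatives)


class TestPeptideSpace:
    def test_exact_powers(self):
        for xi in range(8):
            assert count_peptide_space(xi) == 20 ** (2 * xi)

    def test_published_counts(self):
        assert count_peptide_space(5) == 10_240_000_000_000  # 1.0240e13
        assert count_peptide_space(6) == 4_096_000_000_000_000  # 4.0960e15
        assert count_peptide_space(0) == 1

    def test_negative_xi(self):
        with pytest.raises(CurationError):
            count_peptide_space(-1)


class TestIO:
    def test_fasta_annotation_benchmark_roundtrip(self, toy_records, tmp_path):
        fasta = tmp_path / "seqs.fasta"
        anno = tmp_path / "sites.tsv"
        bench = tmp_path / "benchmark.tsv"
        write_fasta({r.accession: r.sequence for r in toy_records}, fasta)
        write_annotations(toy_records, anno)
        records = load_records(fasta, anno)
        assert {r.accession: r.sequence for r in records} == {
            r.accession: r.sequence for r in toy_records
        }
        ds = build_benchmark(records, "R")
        write_benchmark(ds, bench)
        ds2 = read_benchmark(bench)
        assert isinstance(ds2, BenchmarkDataset)
        assert [s.peptide for s in ds2.positives] == [s.peptide for s in ds.positives]
        assert [s.label for s in ds2.negatives] == [-1] * len(ds.negatives)
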