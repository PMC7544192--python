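"""Synthetic-data generator: plasmids, variants, read simulation, spiking."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from plasmidqc.seqcore import Contig, circular_match, revcomp
from plasmidqc.simdata import (
    ErrorModel,
    VariantSpec,
    apply_variant,
    coverage,
    generate_plasmid,
    mix_reads,
    pairs_for_coverage,
    simulate_reads,
    write_truth_tsv,
)


class TestGeneratePlasmid:
    def test_length_and_alphabet(self):
        p = generate_plasmid(2521, 0.5, seed=1)
        assert len(p.seq) == 2521
        assert set(p.seq) <= set("ACGT")
        assert p.circular

    def test_deterministic_and_seed_sensitive(self):
        a = generate_plasmid(2521, 0.5, seed=1)
        b = generate_plasmid(2521, 0.5, seed=1)
        c = generate_plasmid(2521, 0.5, seed=2)
        assert a.seq == b.seq
        assert a.seq != c.seq

    def test_gc_content_controlled(self):
        p = generate_plasmid(10000, 0.7, seed=3)
        gc = (p.seq.count("G") + p.seq.count("C")) / len(p.seq)
        assert abs(gc - 0.7) < 0.03

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            generate_plasmid(199, 0.5, seed=1)


class TestApplyVariant:
    def test_snp_hamming_distance(self):
        p = generate_plasmid(1000, 0.5, seed=4)
        for n in (1, 4):
            q = apply_variant(p, VariantSpec(kind="snp", n_snps=n, seed=7))
            assert len(q.seq) == len(p.seq)
            dist = sum(a != b for a, b in zip(p.seq, q.seq))
            assert dist == n

    def test_deletion_length(self):
        p = generate_plasmid(3000, 0.5, seed=4)
        q = apply_variant(p, VariantSpec(kind="deletion", length=608, seed=7))
        assert len(q.seq) == len(p.seq) - 608

    def test_insertion_length(self):
        p = generate_plasmid(1000, 0.5, seed=4)
        q = apply_variant(p, VariantSpec(kind="insertion", length=608, seed=7))
        assert len(q.seq) == len(p.seq) + 608

    def test_unrelated_same_length(self):
        p = generate_plasmid(1000, 0.5, seed=4)
        q = apply_variant(p, VariantSpec(kind="unrelated", seed=7))
        assert len(q.seq) == len(p.seq)
        assert q.seq != p.seq

    def test_deterministic(self):
        p = generate_plasmid(1000, 0.5, seed=4)
        v = VariantSpec(kind="snp", n_snps=1, seed=9)
        assert apply_variant(p, v).seq == apply_variant(p, v).seq

    def test_deletion_too_long_rejected(self):
        p = generate_plasmid(500, 0.5, seed=4)
        with pytest.raises(ValueError):
            apply_variant(p, VariantSpec(kind="deletion", length=500, seed=1))


ERROR_FREE = ErrorModel(base_error_rate=0.0, frac_bad_reads=0.0, qual_mean_good=41)


class TestSimulateReads:
    def test_error_free_reads_all_match_source(self):
        p = generate_plasmid(600, 0.5, seed=5)
        rs = simulate_reads(p, 300, ERROR_FREE, seed=6)
        contig = Contig(seq=p.seq, circular=True)
        for pair in rs:
            assert circular_match(pair.r1_seq, contig)
            assert circular_match(pair.r2_seq, contig)

    def test_origin_spanning_fragments_produced(self):
        # a read that matches circularly but not linearly must exist
        p = generate_plasmid(600, 0.5, seed=5)
        rs = simulate_reads(p, 300, ERROR_FREE, seed=6)
        linear = Contig(seq=p.seq, circular=False)
        spanning = [
            pair
            for pair in rs
            if not circular_match(pair.r1_seq, linear)
            or not circular_match(pair.r2_seq, linear)
        ]
        assert spanning, "no origin-spanning fragments in 300 pairs"

    def test_fr_orientation(self):
        # with insert length pinned to the read length, R2 == revcomp(R1)
        p = generate_plasmid(500, 0.5, seed=5)
        m = ErrorModel(read_len=150, insert_mean=150, insert_sd=0.0,
                       base_error_rate=0.0, frac_bad_reads=0.0, qual_mean_good=41)
        rs = simulate_reads(p, 20, m, seed=6)
        for pair in rs:
            assert pair.r2_seq == revcomp(pair.r1_seq)

    def test_deterministic(self):
        p = generate_plasmid(500, 0.5, seed=5)
        a = simulate_reads(p, 50, ErrorModel(), seed=7)
        b = simulate_reads(p, 50, ErrorModel(), seed=7)
        assert [x.r1_seq for x in a] == [x.r1_seq for x in b]
        assert all(
            np.array_equal(x.r1_qual, y.r1_qual) for x, y in zip(a, b)
        )

    def test_empirical_error_rate(self):
        # count substitutions by aligning each R1 to its best-matching
        # circular offset of the source plasmid (errors are sparse, so the
        # true offset is the unambiguous minimum-distance one)
        rate = 0.02
        p = generate_plasmid(400, 0.5, seed=5)
        m = ErrorModel(read_len=50, insert_mean=100, base_error_rate=rate,
                       frac_bad_reads=0.0, qual_mean_good=41)
        rs = simulate_reads(p, 300, m, seed=8)
        doubled = np.frombuffer((p.seq + p.seq).encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(doubled, 50)[:400]
        n_bases = n_errors = 0
        for pair in rs:
            read = np.frombuffer(pair.r1_seq.encode(), dtype=np.uint8)
            n_errors += int((windows != read).sum(axis=1).min())
            n_bases += read.size
        observed = n_errors / n_bases
        se = (rate * (1 - rate) / n_bases) ** 0.5
        assert abs(observed - rate) < 3 * se

    def test_quality_classes(self):
        m = ErrorModel(frac_bad_reads=0.5)
        p = generate_plasmid(500, 0.5, seed=5)
        rs = simulate_reads(p, 400, m, seed=9)
        means = np.array([pair.r1_qual.mean() for pair in rs])
        n_bad = int((means < 30).sum())
        assert 140 < n_bad < 260  # binomial(400, .5) within ~3 sd
        # mates share the class
        means2 = np.array([pair.r2_qual.mean() for pair in rs])
        assert ((means < 30) == (means2 < 30)).all()

    def test_read_longer_than_plasmid_rejected(self):
        p = generate_plasmid(200, 0.5, seed=5)
        with pytest.raises(ValueError):
            simulate_reads(p, 10, ErrorModel(read_len=201, insert_mean=300), seed=1)

    def test_coverage_arithmetic(self):
        assert coverage(5000, 150, 3000) == 500.0
        assert pairs_for_coverage(500, 150, 3000) == 5000


@pytest.fixture(scope="module")
def libraries():
    p = generate_plasmid(400, 0.5, seed=10)
    q = generate_plasmid(400, 0.5, seed=11)
    m = ErrorModel(read_len=50, insert_mean=100)
    return (
        simulate_reads(p, 1200, m, seed=12),
        simulate_reads(q, 700, m, seed=13),
    )


class TestMixReads:
    def test_exact_counts(self, libraries):
        prim, cont = libraries
        mixed = mix_reads(prim, cont, 0.2, 1000, seed=1)
        provs = [pair.provenance for pair in mixed]
        assert len(mixed) == 1000
        assert provs.count("contaminant") == 200
        assert provs.count("primary") == 800

    def test_zero_fraction_all_primary(self, libraries):
        prim, cont = libraries
        mixed = mix_reads(prim, cont, 0.0, 500, seed=1)
        assert all(pair.provenance == "primary" for pair in mixed)

    def test_round_half_even(self, libraries):
        prim, cont = libraries
        mixed = mix_reads(prim, cont, 0.5, 1001, seed=1)
        n_contam = sum(pair.provenance == "contaminant" for pair in mixed)
        assert n_contam == 500  # round-half-even of 500.5

    def test_fraction_above_half_rejected(self, libraries):
        prim, cont = libraries
        with pytest.raises(ValueError):
            mix_reads(prim, cont, 0.6, 100, seed=1)

    def test_insufficient_input_rejected(self, libraries):
        prim, cont = libraries
        with pytest.raises(ValueError):
            mix_reads(prim, cont, 0.5, 2000, seed=1)

    @given(
        fraction=st.floats(min_value=0.0, max_value=0.5),
        total=st.integers(min_value=1, max_value=600),
    )
    def test_count_conservation(self, libraries, fraction, total):
        prim, cont = libraries
        mixed = mix_reads(prim, cont, fraction, total, seed=2)
        n_c = sum(p.provenance == "contaminant" for p in mixed)
        n_p = sum(p.provenance == "primary" for p in mixed)
        assert n_c + n_p == total == len(mixed)
        assert abs(n_c / total - fraction) <= 1 / total

    def test_deterministic(self, libraries):
        prim, cont = libraries
        a = mix_reads(prim, cont, 0.3, 500, seed=3)
        b = mix_reads(prim, cont, 0.3, 500, seed=3)
        assert [p.id for p in a] == [p.id for p in b]


def test_truth_tsv(tmp_path):
    p = generate_plasmid(400, 0.5, seed=10)
    rs = simulate_reads(p, 5, ErrorModel(read_len=50, insert_mean=100), seed=1)
    path = tmp_path / "truth.tsv"
    write_truth_tsv(rs, path)
    lines = path.read_text().splitlines()
    assert lines[0] == "read_id\tprovenance"
    assert len(lines) == 6
    assert all(l.endswith("primary") for l in lines[1:])
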