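import numpy as np
import pytest

from divergescan.snp_filter import (
    SnpFilterParams,
    call_snps,
    parse_pileup,
    snp_density,
    write_vcf,
)


def make_pileup(columns):
    """Render (contig, pos, ref, [(base, qual), ...]) tuples as pileup text,
    tracking read starts/ends so every read spans a contiguous run of
    columns (one synthetic read per column slot index)."""
    # reads are vertical: slot i of consecutive columns belongs to one read
    # as long as the slot exists; simpler: emit ^/$ on every column (1-bp reads)
    lines = []
    for contig, pos, ref, obs in columns:
        bases = "".join(f"^~{b}$" for b, _ in obs)
        quals = "".join(chr(q + 33) for _, q in obs)
        lines.append(f"{contig}\t{pos}\t{ref}\t{len(obs)}\t{bases}\t{quals}")
    return lines


def tiled_pileup(rng, n_cols=40, depth_range=(5, 60), contig="c1", ref="A", qual_range=(10, 40)):
    """Pileup of multi-column reads (length 8) with random bases/quals."""
    read_len = 8
    starts = sorted(
        int(s) for s in rng.integers(1 - read_len, n_cols, size=int(rng.integers(40, 200)))
    )
    reads = []
    for s in starts:
        a, b = max(1, s + 1), min(n_cols, s + read_len)  # 1-based inclusive
        if b < a:
            continue
        length = b - a + 1
        bases = rng.choice(["."] * 12 + ["C", "G", "T", "*"], size=length)
        quals = rng.integers(*qual_range, size=length)
        reads.append((a, b, list(bases), list(quals)))
    lines = []
    for pos in range(1, n_cols + 1):
        cover = [r for r in reads if r[0] <= pos <= r[1]]
        if not cover:
            continue
        bs, qs = [], []
        for a, b, bases, quals in cover:
            ch = bases[pos - a]
            if a == pos:
                ch = "^~" + ch
            if b == pos:
                ch = ch + "$"
            bs.append(ch)
            qs.append(chr(int(quals[pos - a]) + 33))
        lines.append(f"{contig}\t{pos}\t{ref}\t{len(cover)}\t{''.join(bs)}\t{''.join(qs)}")
    return lines


def brute_force_calls(lines, params):
    """Independent literal reimplementation of every rule."""
    cols = list(parse_pileup(lines))
    half = (params.window - 1) // 2
    # rebuild read tracks the slow way
    obs_by_read = {}
    col_lookup = {}
    for ci, col in enumerate(cols):
        col_lookup[(col.contig_id, col.pos)] = col
        for ob in col.observations:
            obs_by_read.setdefault((col.contig_id, ob.read_id), []).append((col.pos, ob))
    calls = []
    for col in cols:
        if col.ref_base == "N" or col.ref_base.islower():
            continue
        passing = []
        for ob in col.observations:
            track = obs_by_read[(col.contig_id, ob.read_id)]
            center_idx = [k for k, (p, o) in enumerate(track) if o is ob][0]
            window = track[max(0, center_idx - half) : center_idx + half + 1]
            if ob.qual < params.min_central_qual:
                continue
            if sum(o.qual for _, o in window) / len(window) < params.min_avg_qual:
                continue
            bad = sum(
                1
                for _, o in window
                if o is not ob and (o.base in "ACGT" or o.base == "*")
            )
            if bad > params.max_gap_mismatch:
                continue
            passing.append(ob)
        non_gap = [o for o in passing if o.base != "*"]
        if not (params.min_coverage <= len(non_gap) <= params.max_coverage):
            continue
        ref = col.ref_base.upper()
        alleles = {ref if o.base == "." else o.base for o in non_gap}
        if len(alleles) != 2 or ref not in alleles:
            continue
        (alt,) = alleles - {ref}
        n_alt = sum(1 for o in non_gap if (ref if o.base == "." else o.base) == alt)
        if n_alt / len(non_gap) < params.min_variant_freq:
            continue
        calls.append((col.contig_id, col.pos, ref, alt, len(non_gap), n_alt / len(non_gap)))
    return calls


def as_tuples(calls):
    return [(c.contig_id, c.pos, c.ref, c.alt, c.depth, c.alt_fraction) for c in calls]


class TestParams:
    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            SnpFilterParams(window=10)

    def test_inverted_coverage_rejected(self):
        with pytest.raises(ValueError):
            SnpFilterParams(min_coverage=20, max_coverage=10)


class TestParsePileup:
    def test_read_tracking_across_columns(self):
        lines = [
            "c1\t1\tA\t2\t^~.^~.\tII",
            "c1\t2\tA\t2\t.C\tII",
            "c1\t3\tA\t2\t.$C$\tII",
        ]
        cols = list(parse_pileup(lines))
        assert [ob.read_id for ob in cols[0].observations] == [0, 1]
        assert [ob.read_id for ob in cols[2].observations] == [0, 1]
        assert cols[1].observations[1].base == "C"

    def test_depth_mismatch_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            list(parse_pileup(["c1\t1\tA\t3\t^~.\tI"]))

    def test_unsorted_rejected(self):
        lines = ["c1\t5\tA\t1\t^~.$\tI", "c1\t3\tA\t1\t^~.$\tI"]
        with pytest.raises(ValueError, match="unsorted"):
            list(parse_pileup(lines))

    def test_wrong_field_count_rejected(self):
        with pytest.raises(ValueError, match="line 1"):
            list(parse_pileup(["c1\t1\tA\t1"]))


class TestCallSnps:
    def test_below_min_coverage_no_call(self):
        lines = make_pileup([("c1", 1, "A", [(".", 40)] * 4 + [("C", 40)] * 4)])
        assert call_snps(lines) == []

    def test_above_max_coverage_no_call(self):
        lines = make_pileup([("c1", 1, "A", [(".", 40)] * 35 + [("C", 40)] * 35)])
        assert call_snps(lines) == []

    def test_clean_het_called(self):
        lines = make_pileup([("c1", 1, "A", [(".", 30)] * 10 + [("C", 30)] * 10)])
        calls = call_snps(lines)
        assert len(calls) == 1
        call = calls[0]
        assert (call.ref, call.alt, call.depth) == ("A", "C", 20)
        assert call.alt_fraction == pytest.approx(0.5)

    def test_low_variant_freq_no_call(self):
        lines = make_pileup([("c1", 1, "A", [(".", 30)] * 17 + [("C", 30)] * 3)])
        assert call_snps(lines) == []

    def test_triallelic_no_call(self):
        lines = make_pileup(
            [("c1", 1, "A", [(".", 30)] * 8 + [("C", 30)] * 6 + [("G", 30)] * 6)]
        )
        assert call_snps(lines) == []

    def test_masked_reference_skipped(self):
        for ref in ("N", "a"):
            lines = make_pileup([("c1", 1, ref, [(".", 30)] * 10 + [("C", 30)] * 10)])
            assert call_snps(lines) == []

    def test_low_central_quality_reads_excluded(self):
        # 10 high-qual ref + 10 low-central-qual alt: alt reads fail NQS,
        # passing depth 10, single allele -> no call
        lines = make_pileup([("c1", 1, "A", [(".", 30)] * 10 + [("C", 10)] * 10)])
        assert call_snps(lines) == []

    def test_window_mismatch_excess_excluded(self):
        # one read with 3 mismatches around the center fails max_gap_mismatch=2
        lines = [
            "c1\t1\tA\t1\t^~C\tI",
            "c1\t2\tA\t1\tC\tI",
            "c1\t3\tA\t1\tC\tI",
            "c1\t4\tA\t1\tC$\tI",
        ]
        cols = list(parse_pileup(lines))
        calls = call_snps(cols, SnpFilterParams(min_coverage=1, max_coverage=60))
        assert calls == []

    def test_brute_force_equivalence_random(self, rng):
        params = SnpFilterParams()
        for trial in range(8):
            lines = tiled_pileup(rng, n_cols=45)
            assert as_tuples(call_snps(lines, params)) == brute_force_calls(lines, params)

    def test_monotone_in_every_threshold(self, rng):
        # tightened parameter grids; raw depth kept <= max_coverage so the
        # qualified-depth gate cannot pull columns into range from above
        base = SnpFilterParams()
        tighter = [
            SnpFilterParams(min_central_qual=30),
            SnpFilterParams(min_avg_qual=30),
            SnpFilterParams(max_gap_mismatch=1),
            SnpFilterParams(min_coverage=15),
            SnpFilterParams(max_coverage=40),
            SnpFilterParams(min_variant_freq=0.45),
        ]
        for trial in range(6):
            lines = tiled_pileup(
                rng, n_cols=40, qual_range=(25, 41)
            )
            n_base = len(call_snps(lines, base))
            for params in tighter:
                assert len(call_snps(lines, params)) <= n_base

    def test_planted_variant_recovery(self, small_params):
        from divergescan.synthetic_data import simulate_contigs, simulate_pileup

        fasta, _, _ = simulate_contigs(small_params)
        seqs = {}
        name = None
        for line in fasta.splitlines():
            if line.startswith(">"):
                name = line[1:]
                seqs[name] = []
            else:
                seqs[name].append(line)
        seqs = {k: "".join(v) for k, v in seqs.items()}
        pileup, truth = simulate_pileup(small_params, seqs)
        calls = call_snps(pileup.splitlines())
        called = {(c.contig_id, c.pos) for c in calls}
        recoverable = truth[truth.recoverable]
        assert len(recoverable) >= 10
        hits = sum(
            1 for r in recoverable.itertuples() if (r.contig_id, r.pos) in called
        )
        assert hits / len(recoverable) >= 0.95


class TestDensity:
    def call(self, contig, pos):
        from divergescan.snp_filter import SnpCall

        return SnpCall(contig, pos, "A", "C", 20, 0.5, 20)

    def test_one_per_kb(self):
        calls = [self.call("c1", i + 1) for i in range(1000)]
        out = snp_density(calls, {"c1": 1_000_000}, {"c1": "chr1"})
        assert out["autosomal_per_kb"] == pytest.approx(1.0)

    def test_zero_calls(self):
        out = snp_density([], {"c1": 1000}, {"c1": "chr1"})
        assert out["autosomal_per_kb"] == 0.0

    def test_sex_chromosome_excluded(self):
        calls = [self.call("c1", 1), self.call("cz", 1)]
        out = snp_density(
            calls, {"c1": 1000, "cz": 1000}, {"c1": "chr1", "cz": "chrZ"}
        )
        assert out["autosomal_per_kb"] == pytest.approx(1.0)
        assert out["excluded_calls"] == 1

    def test_unknown_contig_rejected(self):
        with pytest.raises(ValueError, match="unknown contig"):
            snp_density([self.call("nope", 1)], {"c1": 1000})


class TestVcf:
    def test_minimal_vcf(self, tmp_path):
        from divergescan.snp_filter import SnpCall

        path = tmp_path / "out.vcf"
        write_vcf([SnpCall("c1", 7, "A", "G", 25, 0.4, 25)], str(path))
        lines = path.read_text().splitlines()
        assert lines[0] == "##fileformat=VCFv4.2"
        body = [l for l in lines if not l.startswith("#")]
        assert body == ["c1\t7\t.\tA\tG\t.\tPASS\tDP=25;AF=0.4000\tGT\t0/1"]
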