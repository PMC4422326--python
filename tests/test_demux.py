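"""Barcode assignment, trimming and the minimum-length filter."""

import numpy as np
import pytest

from oracles import prefix_edit_distance
from smrtbs.amplicon import reverse_complement
from smrtbs.demux import (
    BarcodeManifest,
    DemuxedRead,
    ManifestEntry,
    assign_barcode,
    demux_reads,
    length_filter,
    trim_read,
)
from conftest import random_dna


def _build_read(entry, insert):
    return (
        entry.bc_fwd + entry.primer_fwd + insert
        + reverse_complement(entry.primer_rev) + reverse_complement(entry.bc_rev)
    )


class TestAssignBarcode:
    def test_exact_barcode_assigns_with_zero_edits(self, manifest, rng):
        read = manifest.entries[0].bc_fwd + random_dna(rng, 60)
        assert assign_barcode(read, manifest) == ("s1", 0, "forward")

    def test_one_substitution_plus_one_deletion_counts_two_edits(self, manifest, rng):
        bc = manifest.entries[1].bc_fwd
        mutated = "T" + bc[1:10] + bc[11:]  # substitution at 0, deletion at 10
        read = mutated + random_dna(rng, 60)
        sample, edits, orientation = assign_barcode(read, manifest)
        assert (sample, edits) == ("s2", 2)
        # independent full edit-distance confirmation
        window = read[: len(bc) + 2]
        assert prefix_edit_distance(bc, window) == 2

    def test_distance_three_from_every_barcode_unassigned(self, manifest, rng):
        bc = manifest.entries[0].bc_fwd
        mutated = "TT" + bc[3:12] + "A" + bc[12:]  # 2 subs + 1 insertion
        read = mutated + random_dna(rng, 60)
        window = read[: len(bc) + 2]
        assert prefix_edit_distance(bc, window) >= 3
        sample, edits, _ = assign_barcode(read, manifest)
        assert sample is None

    def test_reverse_complement_reads_assigned(self, manifest, rng):
        read = manifest.entries[0].bc_fwd + random_dna(rng, 60)
        sample, edits, orientation = assign_barcode(reverse_complement(read), manifest)
        assert (sample, edits, orientation) == ("s1", 0, "reverse-complement")

    def test_tie_between_samples_is_unassigned(self, rng):
        m = BarcodeManifest([
            ManifestEntry("a", "AAAAAAAAAAAAAAAAAA", "GGTTCCAAGGTTCCAAGG", "ACGT", "ACGT"),
            ManifestEntry("b", "AAAAAAAAAAAAAAAAAT", "CCAATTGGCCAATTGGCC", "ACGT", "ACGT"),
        ])
        read = "AAAAAAAAAAAAAAAAAC" + random_dna(rng, 40)  # distance 1 to both
        sample, edits, _ = assign_barcode(read, m)
        assert sample is None and edits == 1

    def test_empty_manifest_is_configuration_error(self):
        with pytest.raises(ValueError, match="empty"):
            BarcodeManifest([])

    def test_assignments_match_full_edit_distance_oracle(self, manifest, rng):
        """500 constructed prefixes: decision equals an independent DP oracle."""
        max_edits = 2
        bc_len = manifest.barcode_length
        reads = []
        for i in range(500):
            entry = manifest.entries[int(rng.integers(2))]
            bc = list(entry.bc_fwd)
            for _ in range(int(rng.integers(0, 4))):  # 0-3 random edits
                op = rng.integers(3)
                pos = int(rng.integers(len(bc)))
                if op == 0:
                    bc[pos] = str(rng.choice(list("ACGT")))
                elif op == 1 and len(bc) > 1:
                    del bc[pos]
                else:
                    bc.insert(pos, str(rng.choice(list("ACGT"))))
            reads.append("".join(bc) + random_dna(rng, 50))
        for read in reads:
            got, got_edits, _ = assign_barcode(read, manifest, max_edits)
            # oracle: min prefix edit distance per sample over both orientations
            dists = {}
            for e in manifest.entries:
                d = min(
                    prefix_edit_distance(e.bc_fwd, read[: bc_len + max_edits]),
                    prefix_edit_distance(
                        e.bc_fwd, reverse_complement(read)[: bc_len + max_edits]
                    ),
                )
                dists[e.sample_id] = d
            best = min(dists.values())
            winners = [s for s, d in dists.items() if d == best]
            expected = winners[0] if best <= max_edits and len(winners) == 1 else None
            assert got == expected
            if expected is not None:
                assert got_edits == best


class TestTrim:
    def test_constructed_read_recovers_insert_verbatim(self, manifest, rng):
        insert = random_dna(rng, 120)
        entry = manifest.entries[0]
        read = DemuxedRead("r1", "s1", _build_read(entry, insert))
        trimmed = trim_read(read, manifest)
        assert trimmed.sequence == insert
        assert trimmed.flags == ()

    def test_insert_alone_flagged_and_unchanged(self, manifest, rng):
        insert = random_dna(rng, 120)
        read = DemuxedRead("r1", "s1", insert)
        trimmed = trim_read(read, manifest)
        assert trimmed.sequence == insert
        assert "barcode_fwd_missing" in trimmed.flags

    def test_quals_trimmed_in_register_with_sequence(self, manifest, rng):
        insert = random_dna(rng, 60)
        entry = manifest.entries[0]
        seq = _build_read(entry, insert)
        quals = "".join(chr(33 + (i % 60)) for i in range(len(seq)))
        read = DemuxedRead("r1", "s1", seq, quals=quals)
        trimmed = trim_read(read, manifest)
        start = len(entry.bc_fwd) + len(entry.primer_fwd)
        assert trimmed.quals == quals[start : start + len(trimmed.sequence)]

    def test_inserts_recovered_under_barcode_errors(self, manifest):
        """100 constructed reads with 0-2 simulated barcode errors."""
        rng = np.random.default_rng(11)
        for i in range(100):
            entry = manifest.entries[int(rng.integers(2))]
            insert = random_dna(rng, int(rng.integers(80, 200)))
            bc = list(entry.bc_fwd)
            for _ in range(int(rng.integers(0, 3))):
                op = rng.integers(3)
                pos = int(rng.integers(len(bc)))
                if op == 0:
                    bc[pos] = str(rng.choice(list("ACGT")))
                elif op == 1 and len(bc) > 1:
                    del bc[pos]
                else:
                    bc.insert(pos, str(rng.choice(list("ACGT"))))
            seq = (
                "".join(bc) + entry.primer_fwd + insert
                + reverse_complement(entry.primer_rev)
                + reverse_complement(entry.bc_rev)
            )
            read = DemuxedRead(f"r{i}", entry.sample_id, seq)
            assert trim_read(read, manifest).sequence == insert


class TestLengthFilter:
    def test_strictly_greater_than_boundary(self):
        reads = [DemuxedRead(f"r{n}", "s", "A" * n) for n in (49, 50, 51)]
        kept = length_filter(reads, min_len=50)
        assert [len(r) for r in kept] == [51]
        kept_inc = length_filter(reads, min_len=50, inclusive=True)
        assert [len(r) for r in kept_inc] == [50, 51]

    def test_empty_input(self):
        assert length_filter([], min_len=50) == []

    def test_retained_count_matches_recount(self, rng):
        lengths = rng.integers(1, 120, size=1000)
        reads = [DemuxedRead(f"r{i}", "s", "A" * n) for i, n in enumerate(lengths)]
        assert len(length_filter(reads, 50)) == int((lengths > 50).sum())


class TestDemuxProperties:
    def _records(self, manifest, rng, n=60):
        records = []
        for i in range(n):
            entry = manifest.entries[int(rng.integers(2))]
            seq = _build_read(entry, random_dna(rng, 120))
            if rng.random() < 0.5:
                seq = reverse_complement(seq)
            records.append((f"r{i}", seq, None))
        records.append(("junk", random_dna(rng, 150), None))
        return records

    def test_every_read_lands_in_exactly_one_bin(self, manifest, rng):
        records = self._records(manifest, rng)
        by_sample, unassigned, stats = demux_reads(records, manifest, min_len=0)
        total = sum(len(v) for v in by_sample.values()) + len(unassigned)
        n_short = int(stats["n_too_short"].sum())
        assert total + n_short == len(records)

    def test_orientation_symmetry(self, manifest, rng):
        """Reverse-complementing every read and swapping barcode roles must
        reproduce the same sample assignments."""
        records = self._records(manifest, rng)
        swapped = BarcodeManifest([
            ManifestEntry(e.sample_id, e.bc_rev, e.bc_fwd, e.primer_rev, e.primer_fwd)
            for e in manifest.entries
        ])
        rc_records = [(rid, reverse_complement(seq), None) for rid, seq, _ in records]
        a, _, _ = demux_reads(records, manifest, min_len=0)
        b, _, _ = demux_reads(rc_records, swapped, min_len=0)
        assignment_a = {r.read_id: s for s, rs in a.items() for r in rs}
        assignment_b = {r.read_id: s for s, rs in b.items() for r in rs}
        assert assignment_a == assignment_b

    def test_raising_max_edits_never_unassigns(self, manifest, rng):
        records = []
        for i in range(80):
            entry = manifest.entries[int(rng.integers(2))]
            bc = list(entry.bc_fwd)
            for _ in range(int(rng.integers(0, 4))):
                bc[int(rng.integers(len(bc)))] = str(rng.choice(list("ACGT")))
            records.append((f"r{i}", "".join(bc) + random_dna(rng, 80), None))
        counts = []
        for k in (0, 1, 2, 3):
            by_sample, _, _ = demux_reads(records, manifest, max_edits=k, min_len=0)
            counts.append(sum(len(v) for v in by_sample.values()))
        assert counts == sorted(counts)
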