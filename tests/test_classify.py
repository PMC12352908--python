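"""Read alignment and editing-outcome classification."""

import itertools

import numpy as np
import pytest

from crisprselect.classify import (
    AMBIGUOUS,
    DISCARDED,
    INDEL,
    MUT_KI,
    UNEDITED,
    WTSTAR_KI,
    IndelEvent,
    OutcomeTable,
    ReadClassifier,
    align_read,
    classify_read,
    extract_events,
    outcome_tables_from_tsv,
    outcome_tables_to_tsv,
    quantify_sample,
)

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 2, -2, -6, -1


def brute_force_affine_score(ref, read):
    """Exhaustive enumeration of all global alignments (small inputs only).

    Scores with affine gaps: first gap column -6, each further column of
    the same gap -1; matches +2, mismatches -2. Independent of any
    dynamic-programming shortcut.
    """
    best = -np.inf

    def rec(i, j, score, last):
        nonlocal best
        if i == len(ref) and j == len(read):
            best = max(best, score)
            return
        # bound: even all-matches cannot beat best
        remaining = min(len(ref) - i, len(read) - j)
        if score + remaining * MATCH + 0 < best - 20:
            return
        if i < len(ref) and j < len(read):
            s = MATCH if ref[i] == read[j] else MISMATCH
            rec(i + 1, j + 1, score + s, "M")
        if i < len(ref):  # deletion (gap in read)
            gap = GAP_EXTEND if last == "D" else GAP_OPEN
            rec(i + 1, j, score + gap, "D")
        if j < len(read):  # insertion (gap in ref)
            gap = GAP_EXTEND if last == "I" else GAP_OPEN
            rec(i, j + 1, score + gap, "I")

    rec(0, 0, 0.0, None)
    return best


class TestAlignment:
    def test_identity_alignment_scores_two_per_base(self):
        ref = "ACGTACGTACGT"
        aln = align_read(ref, ref)
        assert aln.score == 2 * len(ref)
        assert extract_events(aln) == ()

    def test_one_bp_deletion_left_aligned(self):
        # deletion inside a TT run: leftmost equivalent position is the
        # start of the run
        ref = "ACGGATTTTCAGCA"
        read = ref[:6] + ref[7:]  # delete one T (positions 5-8 equivalent)
        events = extract_events(align_read(read, ref))
        assert events == (IndelEvent(5, -1),)

    def test_empty_and_invalid_reads_rejected(self):
        with pytest.raises(ValueError):
            align_read("", "ACGT")
        with pytest.raises(ValueError, match="non-ACGTN"):
            align_read("ACXT", "ACGT")

    def test_all_n_read_has_zero_matches(self):
        aln = align_read("NNNN", "ACGT")
        assert aln.counts().identities == 0

    @pytest.mark.parametrize("seed", range(6))
    def test_score_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        ref = "".join(rng.choice(list("ACGT"), size=7))
        read = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 9))))
        aln = align_read(read, ref)
        assert aln.score == brute_force_affine_score(ref, read)

    def test_deletion_events_cannot_shift_further_left(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            ref = "".join(rng.choice(list("ACGT"), size=60))
            pos = int(rng.integers(10, 45))
            k = int(rng.integers(1, 4))
            read = ref[:pos] + ref[pos + k:]
            for ev in extract_events(align_read(read, ref)):
                assert ev.net_length < 0
                p, length = ev.position, -ev.net_length
                assert p == 0 or ref[p - 1] != ref[p + length - 1]


class TestClassification:
    def test_reference_read_is_unedited(self, exon_design):
        aln = align_read(exon_design.reference, exon_design.reference)
        assert classify_read(aln, exon_design).category == UNEDITED

    def test_full_templates_called_knockin(self, exon_design):
        for seq, cat in (
            (exon_design.mut_sequence, MUT_KI),
            (exon_design.wtstar_sequence, WTSTAR_KI),
        ):
            assert classify_read(align_read(seq, exon_design.reference),
                                 exon_design).category == cat

    def test_intron_deletion_not_frameshift(self, intron_design):
        ref = intron_design.reference
        pos = intron_design.cut_site + 2  # inside intron
        read = ref[:pos] + ref[pos + 2:]
        out = classify_read(align_read(read, ref), intron_design)
        assert out.category == INDEL
        assert out.indel_region == "intronic"
        assert out.frameshift is False

    def test_exon_insertion_is_frameshift(self, exon_design):
        ref = exon_design.reference
        cut = exon_design.cut_site
        read = ref[:cut] + "T" + ref[cut:]
        out = classify_read(align_read(read, ref), exon_design)
        assert out.category == INDEL
        assert out.frameshift is True
        assert out.indel_region == "exonic"

    def test_partial_template_is_ambiguous(self, exon_design):
        # only one of the two Mut substitutions present
        (p1, _, a1), _ = sorted(exon_design.mut_substitutions)
        seq = list(exon_design.reference)
        seq[p1] = a1
        out = classify_read(align_read("".join(seq), exon_design.reference),
                            exon_design)
        assert out.category == AMBIGUOUS

    def test_both_templates_is_ambiguous(self, exon_design):
        seq = list(exon_design.reference)
        for p, _, a in exon_design.mut_substitutions | exon_design.wtstar_substitutions:
            seq[p] = a
        out = classify_read(align_read("".join(seq), exon_design.reference),
                            exon_design)
        assert out.category == AMBIGUOUS

    def test_garbage_read_discarded(self, exon_design):
        rng = np.random.default_rng(0)
        read = "".join(rng.choice(list("ACGT"), size=len(exon_design)))
        out = classify_read(align_read(read, exon_design.reference), exon_design)
        assert out.category == DISCARDED

    def test_splice_site_deletion_flagged(self, two_region_design):
        ref = two_region_design.reference
        read = ref[:99] + ref[103:]  # spans the exon/intron junction at 100
        out = classify_read(align_read(read, ref), two_region_design)
        assert out.category == INDEL
        assert out.splice_disrupting is True
        assert out.indel_region == "splice_site"


class TestFastPathEquivalence:
    def test_fast_paths_agree_with_full_alignment(self, exon_design):
        """The substitution-only and single-InDel shortcuts must call the
        same category as the affine-gap alignment route."""
        rng = np.random.default_rng(5)
        clf = ReadClassifier(exon_design)
        ref = exon_design.reference
        templates = [ref, exon_design.mut_sequence, exon_design.wtstar_sequence]
        reads = []
        for _ in range(120):
            base = list(templates[rng.integers(3)])
            # sprinkle substitution errors
            for _ in range(rng.integers(0, 4)):
                i = int(rng.integers(len(base)))
                base[i] = "ACGT"[rng.integers(4)]
            seq = "".join(base)
            if rng.random() < 0.5:  # add an indel near the cut site
                p = exon_design.cut_site + int(rng.integers(-10, 10))
                k = int(rng.integers(1, 4))
                seq = seq[:p] + seq[p + k:] if rng.random() < 0.5 else (
                    seq[:p] + "ACGT"[rng.integers(4)] * k + seq[p:]
                )
            reads.append(seq)
        for read in reads:
            fast = clf.classify(read).category
            slow = classify_read(align_read(read, ref), exon_design).category
            assert fast == slow, read


class TestQuantify:
    def test_six_read_example(self, tmp_path, exon_design):
        ref = exon_design.reference
        cut = exon_design.cut_site
        reads = [
            exon_design.mut_sequence, exon_design.mut_sequence,
            exon_design.wtstar_sequence, exon_design.wtstar_sequence,
            ref,
            ref[:cut] + ref[cut + 2:],  # 2-bp exonic deletion
        ]
        fq = tmp_path / "sample.fastq"
        fq.write_text("".join(
            f"@r{i}\n{s}\n+\n{'F' * len(s)}\n" for i, s in enumerate(reads)
        ))
        table = quantify_sample(fq, exon_design)
        assert table.counts[MUT_KI] == 2
        assert table.counts[WTSTAR_KI] == 2
        assert table.counts[UNEDITED] == 1
        assert table.counts[INDEL] == 1
        assert table.indel_strata == {("frameshift", "exonic"): 1}
        assert table.frameshift_frequency() == pytest.approx(1 / 6)

    def test_empty_fastq_warns_and_returns_zero_table(self, tmp_path, exon_design):
        fq = tmp_path / "empty.fastq"
        fq.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            table = quantify_sample(fq, exon_design)
        assert table.total == 0

    def test_truncated_record_counted_discarded(self, tmp_path, exon_design):
        fq = tmp_path / "trunc.fastq"
        fq.write_text(f"@ok\n{exon_design.reference}\n+\n{'F'*240}\n@broken\nACGT\n")
        table = quantify_sample(fq, exon_design)
        assert table.counts[DISCARDED] == 1
        assert table.counts[UNEDITED] == 1

    def test_counts_invariant_to_read_order(self, tmp_path, exon_design):
        rng = np.random.default_rng(1)
        ref = exon_design.reference
        reads = [exon_design.mut_sequence] * 3 + [ref] * 3 + [
            ref[:100] + ref[101:]
        ] * 3
        for name, order in (("fwd", reads), ("rev", reads[::-1])):
            fq = tmp_path / f"{name}.fastq"
            fq.write_text("".join(
                f"@r{i}\n{s}\n+\n{'F' * len(s)}\n" for i, s in enumerate(order)
            ))
        t1 = quantify_sample(tmp_path / "fwd.fastq", exon_design)
        t2 = quantify_sample(tmp_path / "rev.fastq", exon_design)
        assert t1.counts == t2.counts

    def test_outcome_table_tsv_round_trip(self, tmp_path):
        t = OutcomeTable(timepoint=12, condition="treated", replicate=2)
        t.counts[MUT_KI] = 5
        t.counts[INDEL] = 3
        t.indel_strata[("frameshift", "exonic")] = 2
        t.indel_strata[("inframe", "intronic")] = 1
        path = tmp_path / "outcomes.tsv"
        outcome_tables_to_tsv([t], path)
        [back] = outcome_tables_from_tsv(path)
        assert back.counts == t.counts
        assert back.indel_strata == t.indel_strata
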