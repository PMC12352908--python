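"""Editing-outcome classification of amplicon reads.

Each read is aligned globally to the amplicon reference and called as one
of six outcome categories:

``MUT_KI``
    full Mut template substitution set present, WT* set absent, no InDel
    in the cut-site window — the mutation of interest was knocked in.
``WTSTAR_KI``
    the synonymous internal-control template, symmetrically.
``INDEL``
    any insertion/deletion inside the cut-site window (imperfect repair).
``UNEDITED``
    matches the reference at all template positions, no window InDel.
``AMBIGUOUS``
    partial template sets, or both templates present (template
    recombination); excluded from Mut:WT* ratio denominators.
``DISCARDED``
    alignment identity below threshold, or unparsable read.

InDel calls carry frameshift status (exonic net length not a multiple of
3), the region of the event, and whether a canonical splice-site
dinucleotide is disrupted.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import Align

from .amplicon import (
    EXONIC,
    INTRONIC,
    SPLICE_SITE,
    AmpliconDesign,
    EXON,
)

logger = logging.getLogger(__name__)

MUT_KI = "MUT_KI"
WTSTAR_KI = "WTSTAR_KI"
UNEDITED = "UNEDITED"
INDEL = "INDEL"
AMBIGUOUS = "AMBIGUOUS"
DISCARDED = "DISCARDED"

CATEGORIES = (MUT_KI, WTSTAR_KI, UNEDITED, INDEL, AMBIGUOUS, DISCARDED)

#: alignment scoring defaults (match, mismatch, gap open, gap extend)
DEFAULT_SCORING = (2, -2, -6, -1)
#: InDels within this many bases of the cut site are editing outcomes
DEFAULT_CUT_WINDOW = 20
#: minimum fraction of matching aligned columns to keep a read
DEFAULT_MIN_IDENTITY = 0.8


def _make_aligner(scoring=DEFAULT_SCORING) -> Align.PairwiseAligner:
    match, mismatch, gap_open, gap_extend = scoring
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


@dataclass(frozen=True)
class IndelEvent:
    """A single insertion (net_length > 0) or deletion (< 0) on the
    reference frame, left-aligned to its leftmost equivalent position."""

    position: int
    net_length: int


@dataclass
class ReadOutcome:
    category: str
    indel_events: tuple[IndelEvent, ...] = ()
    frameshift: bool = False
    indel_region: str | None = None  # exonic | intronic | splice_site
    splice_disrupting: bool = False
    n_mismatches_outside_templates: int = 0
    reason: str | None = None


@dataclass
class OutcomeTable:
    """Per-sample outcome counts for one (timepoint, condition, replicate)."""

    timepoint: int
    condition: str
    replicate: int
    counts: dict[str, int] = field(default_factory=lambda: {c: 0 for c in CATEGORIES})
    # INDEL stratified by (frameshift|inframe) x region
    indel_strata: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def classified(self) -> int:
        return self.total - self.counts[DISCARDED]

    def add(self, outcome: ReadOutcome) -> None:
        self.counts[outcome.category] += 1
        if outcome.category == INDEL:
            key = (
                "frameshift" if outcome.frameshift else "inframe",
                outcome.indel_region or "unknown",
            )
            self.indel_strata[key] = self.indel_strata.get(key, 0) + 1

    def frameshift_frequency(self) -> float:
        """Fraction of classified reads carrying a frameshift InDel."""
        if self.classified == 0:
            return float("nan")
        n_fs = sum(n for (fs, _), n in self.indel_strata.items() if fs == "frameshift")
        return n_fs / self.classified

    def validate(self) -> None:
        assert sum(self.indel_strata.values()) == self.counts[INDEL]


# -- alignment -------------------------------------------------------------


def align_read(
    read: str,
    reference: str,
    scoring=DEFAULT_SCORING,
) -> Align.Alignment:
    """Global affine-gap alignment of one read against the reference.

    Deterministic for fixed inputs (the aligner's first optimal
    traceback); InDel positions are subsequently left-normalized by
    :func:`extract_events`.
    """
    if not read:
        raise ValueError("empty read")
    bad = set(read) - set("ACGTN")
    if bad:
        raise ValueError(f"non-ACGTN characters in read: {sorted(bad)}")
    aligner = _make_aligner(scoring)
    return aligner.align(reference, read)[0]


def _left_shift(position: int, length: int, deleted: bool, reference: str, read: str,
                ref_at_pos: str) -> int:
    """Shift an InDel event to its leftmost equivalent reference position."""
    seq = reference
    pos = position
    if deleted:
        # deletion of seq[pos:pos+length]: can shift left while the base
        # entering the deleted window equals the base leaving it
        while pos > 0 and seq[pos - 1] == seq[pos + length - 1]:
            pos -= 1
    else:
        # insertion before reference position pos of the string ``ref_at_pos``
        ins = ref_at_pos
        while pos > 0 and seq[pos - 1] == ins[-1]:
            ins = seq[pos - 1] + ins[:-1]
            pos -= 1
    return pos


def extract_events(alignment: Align.Alignment) -> tuple[IndelEvent, ...]:
    """InDel events (reference coordinates, left-aligned) from an alignment."""
    ref_blocks, read_blocks = alignment.aligned
    reference = str(alignment.target)
    read = str(alignment.query)
    events: list[IndelEvent] = []
    prev_ref_end: int | None = None
    prev_read_end: int | None = None
    first_ref_start = ref_blocks[0][0] if len(ref_blocks) else 0
    if len(ref_blocks) and first_ref_start > 0 and read_blocks[0][0] == 0:
        # leading deletion of reference bases
        events.append(IndelEvent(0, -int(first_ref_start)))
    for (rs, re), (qs, qe) in zip(ref_blocks, read_blocks):
        if prev_ref_end is not None:
            dref = rs - prev_ref_end
            dread = qs - prev_read_end
            if dref > 0:  # deletion
                pos = _left_shift(prev_ref_end, dref, True, reference, read, "")
                events.append(IndelEvent(int(pos), -int(dref)))
            if dread > 0:  # insertion
                ins = read[prev_read_end:qs]
                pos = _left_shift(prev_ref_end, dread, False, reference, read, ins)
                events.append(IndelEvent(int(pos), int(dread)))
        prev_ref_end, prev_read_end = re, qe
    if prev_ref_end is not None and prev_ref_end < len(reference):
        events.append(IndelEvent(int(prev_ref_end), -(len(reference) - int(prev_ref_end))))
    return tuple(events)


def _aligned_identity(alignment: Align.Alignment) -> float:
    counts = alignment.counts()
    aligned_cols = counts.identities + counts.mismatches
    if aligned_cols == 0:
        return 0.0
    return counts.identities / aligned_cols


def _read_base_at(alignment: Align.Alignment, ref_pos: int) -> str | None:
    """Read base aligned to a reference position, or None if gapped/absent."""
    for (rs, re), (qs, qe) in zip(*alignment.aligned):
        if rs <= ref_pos < re:
            return str(alignment.query)[qs + (ref_pos - rs)]
    return None


# -- classification --------------------------------------------------------


def _exonic_net_length(design: AmpliconDesign, event: IndelEvent) -> int:
    """Signed exonic length change caused by one event."""
    if event.net_length > 0:
        region = design.region_at(min(event.position, len(design) - 1))
        return event.net_length if region.kind == EXON else 0
    # deletion: count deleted exonic bases
    start = event.position
    end = start - event.net_length
    n_exonic = sum(
        1
        for p in range(start, min(end, len(design)))
        if design.region_at(p).kind == EXON
    )
    return -n_exonic


def _splice_disrupting(design: AmpliconDesign, event: IndelEvent) -> bool:
    if event.net_length > 0:
        span = (event.position, event.position)  # insertion point
        return any(s < span[0] < e for s, e in design.splice_sites) or any(
            s <= event.position - 1 and event.position < e
            for s, e in design.splice_sites
        )
    start, end = event.position, event.position - event.net_length
    return any(start < e and s < end for s, e in design.splice_sites)


def _event_region(design: AmpliconDesign, event: IndelEvent) -> str:
    if _splice_disrupting(design, event):
        return SPLICE_SITE
    pos = min(event.position, len(design) - 1)
    return EXONIC if design.region_at(pos).kind == EXON else INTRONIC


def _indel_outcome(
    design: AmpliconDesign, events: Iterable[IndelEvent], n_mm: int
) -> ReadOutcome:
    events = tuple(events)
    exonic_net = sum(_exonic_net_length(design, ev) for ev in events)
    # region label: the event closest to the cut site decides
    lead = min(events, key=lambda ev: abs(ev.position - design.cut_site))
    return ReadOutcome(
        category=INDEL,
        indel_events=events,
        frameshift=bool(exonic_net % 3 != 0),
        indel_region=_event_region(design, lead),
        splice_disrupting=bool(any(_splice_disrupting(design, ev) for ev in events)),
        n_mismatches_outside_templates=n_mm,
    )


def _decide(
    design: AmpliconDesign,
    events: tuple[IndelEvent, ...],
    read_at: dict[int, str | None],
    n_mm: int,
    cut_window: int,
) -> ReadOutcome:
    """Shared decision core over extracted events and template columns."""
    window_events = tuple(
        ev
        for ev in events
        if abs(ev.position - design.cut_site) <= cut_window
        or (ev.net_length < 0 and ev.position <= design.cut_site <= ev.position - ev.net_length)
    )
    if window_events:
        return _indel_outcome(design, window_events, n_mm)

    mut_hits = sum(1 for p, _r, a in design.mut_substitutions if read_at.get(p) == a)
    wts_hits = sum(1 for p, _r, a in design.wtstar_substitutions if read_at.get(p) == a)
    mut_full = mut_hits == len(design.mut_substitutions)
    wts_full = wts_hits == len(design.wtstar_substitutions)

    if mut_full and not wts_hits:
        return ReadOutcome(MUT_KI, indel_events=events, n_mismatches_outside_templates=n_mm)
    if wts_full and not mut_hits:
        return ReadOutcome(WTSTAR_KI, indel_events=events, n_mismatches_outside_templates=n_mm)
    if mut_hits or wts_hits:
        return ReadOutcome(
            AMBIGUOUS,
            indel_events=events,
            n_mismatches_outside_templates=n_mm,
            reason="partial_or_mixed_templates",
        )
    return ReadOutcome(UNEDITED, indel_events=events, n_mismatches_outside_templates=n_mm)


def classify_read(
    alignment: Align.Alignment,
    design: AmpliconDesign,
    cut_window: int = DEFAULT_CUT_WINDOW,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> ReadOutcome:
    """Call the editing outcome of one aligned read.

    Decision order: DISCARDED (low identity / truncated), INDEL (any
    event within ``cut_window`` of the cut site), MUT_KI / WTSTAR_KI
    (full template set, other set absent), AMBIGUOUS (partial or mixed
    template sets), UNEDITED.
    """
    if _aligned_identity(alignment) < min_identity:
        return ReadOutcome(DISCARDED, reason="low_identity")

    events = extract_events(alignment)
    template_positions = {p for p, _, _ in design.mut_substitutions} | {
        p for p, _, _ in design.wtstar_substitutions
    }
    read_at: dict[int, str | None] = {
        p: _read_base_at(alignment, p) for p in template_positions
    }
    if any(
        read_at[p] is None and not any(
            ev.net_length < 0 and ev.position <= p < ev.position - ev.net_length
            for ev in events
        )
        for p in template_positions
    ):
        # truncated before a template position without an explaining deletion
        return ReadOutcome(DISCARDED, reason="truncated_at_template")

    n_mm = _count_nontemplate_mismatches(alignment, design, template_positions)
    return _decide(design, events, read_at, n_mm, cut_window)


def _count_nontemplate_mismatches(
    alignment: Align.Alignment, design: AmpliconDesign, template_positions: set[int]
) -> int:
    ref = design.reference
    n = 0
    for (rs, re), (qs, qe) in zip(*alignment.aligned):
        seg_ref = ref[rs:re]
        seg_read = str(alignment.query)[qs:qe]
        for off, (a, b) in enumerate(zip(seg_ref, seg_read)):
            if a != b and (rs + off) not in template_positions:
                n += 1
    return n


# -- fast per-sample quantification ----------------------------------------


class ReadClassifier:
    """Reusable classifier with closed-form fast paths.

    Two shortcuts sidestep the dynamic-programming aligner for the
    overwhelmingly common read structures while producing the same
    calls as the full alignment route:

    * equal-length reads explained by substitutions alone are compared
      per position;
    * reads whose length differs from the reference are tested against
      every placement of a single contiguous InDel of the observed net
      length via prefix/suffix mismatch cumulative sums (O(L)); the
      leftmost placement with the fewest mismatches is used, matching
      the aligner's left-aligned gap convention.

    Anything else (multiple InDels, heavy damage) falls back to the
    affine-gap aligner.
    """

    #: mismatch fraction allowed on a fast path before falling back
    FAST_PATH_MAX_MISMATCH = 0.10

    def __init__(
        self,
        design: AmpliconDesign,
        cut_window: int = DEFAULT_CUT_WINDOW,
        min_identity: float = DEFAULT_MIN_IDENTITY,
        scoring=DEFAULT_SCORING,
    ):
        self.design = design
        self.cut_window = cut_window
        self.min_identity = min_identity
        self.aligner = _make_aligner(scoring)
        self._ref_arr = np.frombuffer(design.reference.encode(), dtype=np.uint8)
        self._template_positions = {p for p, _, _ in design.mut_substitutions} | {
            p for p, _, _ in design.wtstar_substitutions
        }

    def classify(self, read: str) -> ReadOutcome:
        if not read or set(read) - set("ACGTN"):
            return ReadOutcome(DISCARDED, reason="invalid_sequence")
        ref = self.design.reference
        delta = len(read) - len(ref)
        if delta == 0:
            outcome = self._try_substitution_only(read)
            if outcome is not None:
                return outcome
        elif 0 < abs(delta) <= self.cut_window * 2:
            outcome = self._try_single_indel(read, delta)
            if outcome is not None:
                return outcome
        alignment = self.aligner.align(ref, read)[0]
        return classify_read(
            alignment, self.design, cut_window=self.cut_window, min_identity=self.min_identity
        )

    def _try_substitution_only(self, read: str) -> ReadOutcome | None:
        ref = self.design.reference
        arr = np.frombuffer(read.encode(), dtype=np.uint8)
        mismatches = np.flatnonzero(arr != self._ref_arr)
        if mismatches.size / len(ref) > self.FAST_PATH_MAX_MISMATCH:
            return None
        read_at = {p: read[p] for p in self._template_positions}
        n_mm = int(sum(1 for i in mismatches if int(i) not in self._template_positions))
        return _decide(self.design, (), read_at, n_mm, self.cut_window)

    def _try_single_indel(self, read: str, delta: int) -> ReadOutcome | None:
        """Best placement of one contiguous InDel of net length ``delta``.

        For each placement p the read decomposes into read[:p] matching
        ref[:p] and the remainder matching the reference after the
        event; mismatch counts for all p come from two cumulative sums.
        """
        ref = self.design.reference
        arr = np.frombuffer(read.encode(), dtype=np.uint8)
        k = abs(delta)
        n = min(len(read), len(ref))
        # prefix mismatches: pre[p] = # mismatches of read[:p] vs ref[:p]
        pre = np.concatenate(([0], np.cumsum(arr[:n] != self._ref_arr[:n])))
        if delta < 0:  # deletion of ref[p:p+k]
            diff = arr != self._ref_arr[k:]  # read[p:] vs ref[p+k:]
        else:  # insertion of read[p:p+k] before ref position p
            diff = arr[k:] != self._ref_arr
        # suf[p] = # mismatches from placement p onward
        suf = np.concatenate((np.cumsum(diff[::-1])[::-1], [0]))
        m = pre[: suf.size] + suf
        p_best = int(np.argmin(m))  # leftmost minimum = left-aligned event
        n_mismatch = int(m[p_best])
        if n_mismatch / len(ref) > self.FAST_PATH_MAX_MISMATCH:
            return None
        event = IndelEvent(p_best, delta)
        read_at: dict[int, str | None] = {}
        for t in self._template_positions:
            if t < p_best:
                read_at[t] = read[t]
            elif delta < 0 and t < p_best + k:
                read_at[t] = None  # deleted
            else:
                read_at[t] = read[t + delta] if 0 <= t + delta < len(read) else None
        n_mm = n_mismatch - sum(
            1
            for t, base in read_at.items()
            if base is not None and base != self.design.reference[t]
        )
        return _decide(self.design, (event,), read_at, n_mm, self.cut_window)


def _iter_fastq(path: Path) -> Iterator[tuple[str, str]]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline()
            if not qual:
                yield header.rstrip("\n"), ""  # truncated record
                return
            yield header.rstrip("\n"), seq.upper()


def quantify_sample(
    fastq_path: str | Path,
    design: AmpliconDesign,
    timepoint: int = 0,
    condition: str = "unknown",
    replicate: int = 0,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    cut_window: int = DEFAULT_CUT_WINDOW,
) -> OutcomeTable:
    """Classify every read of one FASTQ sample into an :class:`OutcomeTable`."""
    fastq_path = Path(fastq_path)
    classifier = ReadClassifier(design, cut_window=cut_window, min_identity=min_identity)
    table = OutcomeTable(timepoint=timepoint, condition=condition, replicate=replicate)
    n = 0
    for header, seq in _iter_fastq(fastq_path):
        n += 1
        if not seq or not header.startswith("@"):
            table.add(ReadOutcome(DISCARDED, reason="truncated_record"))
            logger.warning("discarding unparsable record %d in %s", n, fastq_path)
            continue
        table.add(classifier.classify(seq))
    if n == 0:
        warnings.warn(f"empty FASTQ: {fastq_path}", stacklevel=2)
    table.validate()
    return table


def outcome_tables_to_tsv(tables: Iterable[OutcomeTable], path: str | Path) -> None:
    """Write one row per sample with fixed column order."""
    import pandas as pd

    rows = []
    for t in tables:
        row = {
            "timepoint": t.timepoint,
            "condition": t.condition,
            "replicate": t.replicate,
            "total": t.total,
        }
        for c in CATEGORIES:
            row[c] = t.counts[c]
        for fs in ("frameshift", "inframe"):
            for region in (EXONIC, INTRONIC, SPLICE_SITE):
                row[f"indel_{fs}_{region}"] = t.indel_strata.get((fs, region), 0)
        row["frameshift_frequency"] = t.frameshift_frequency()
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def outcome_tables_from_tsv(path: str | Path) -> list[OutcomeTable]:
    """Read back tables written by :func:`outcome_tables_to_tsv`."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    tables = []
    for _, row in df.iterrows():
        t = OutcomeTable(
            timepoint=int(row["timepoint"]),
            condition=str(row["condition"]),
            replicate=int(row["replicate"]),
        )
        for c in CATEGORIES:
            t.counts[c] = int(row[c])
        for fs in ("frameshift", "inframe"):
            for region in (EXONIC, INTRONIC, SPLICE_SITE):
                n = int(row.get(f"indel_{fs}_{region}", 0))
                if n:
                    t.indel_strata[(fs, region)] = n
        tables.append(t)
    return tables
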