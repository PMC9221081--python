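"""Back-splice junction detection and circRNA quantification.

Detects circRNAs from RNA-seq reads by the head-to-tail split-read
procedure: reads that fail to align contiguously are split into local
segments by exact k-mer seeding with ungapped extension; a pair of
segments from one read that maps to the same chromosome, no more than
``max_junction_span_bp`` apart, on the same strand but in reverse
genomic order supports a back-splice junction.  The exact junction is
refined by maximizing splice-site strength under a PWM log-odds scorer
over MaxEntScan-style windows (donor 9-mer: 3 exonic + 6 intronic;
acceptor 23-mer: 20 intronic + 3 exonic).  Candidates are reported when
supported by at least ``min_support_reads`` reads with a total splice
score of at least ``min_splice_score``.  Expression of each circle is
estimated against a pseudo-circular reference (the circle's 3' end
concatenated to its 5' end) by counting reads that cross the junction
with at least ``min_overhang_nt`` matched nucleotides on each side.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .config import PipelineConfig
from .io import ExonAnnotation, GenomeSequence, ReadRecord, revcomp

__all__ = [
    "SegmentAlignment",
    "CircCandidate",
    "CircRNA",
    "SpliceScorer",
    "KmerIndex",
    "PseudoCircularReference",
    "contiguous_align",
    "split_align",
    "find_head_to_tail",
    "score_splice_sites",
    "refine_junction",
    "filter_candidates",
    "build_pseudo_circular_reference",
    "quantify_junction_reads",
    "make_circ_id",
    "parse_circ_id",
    "detect_circrnas",
    "read_sam_linear_ids",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

DONOR_EXONIC = 3     # donor window: 3 exonic + 6 intronic nt
DONOR_INTRONIC = 6
ACCEPTOR_INTRONIC = 20   # acceptor window: 20 intronic + 3 exonic nt
ACCEPTOR_EXONIC = 3


# ---------------------------------------------------------------------------
# Data types


@dataclass(frozen=True)
class SegmentAlignment:
    """A local ungapped placement of part of a read on the reference.

    ``read_interval`` is 0-based half-open on the (possibly reverse-
    complemented) query; ``ref_interval`` is 1-based inclusive on the
    forward reference strand; ``strand`` is the query orientation.
    """

    read_id: str
    read_start: int
    read_end: int
    chrom: str
    strand: str
    ref_start: int
    ref_end: int
    score: int


@dataclass
class CircCandidate:
    """A candidate back-splice junction.

    ``acceptor_pos`` / ``donor_pos`` are the genomic low / high circle
    boundaries (1-based, forward-strand coordinates); on the '-' strand
    the biological donor lies at the low coordinate, which the splice
    scorer accounts for.
    """

    chrom: str
    strand: str
    acceptor_pos: int
    donor_pos: int
    supporting_read_ids: set[str] = field(default_factory=set)
    donor_score: float = 0.0
    acceptor_score: float = 0.0

    def __post_init__(self) -> None:
        if self.donor_pos <= self.acceptor_pos:
            raise ValueError(
                f"donor_pos ({self.donor_pos}) must exceed acceptor_pos "
                f"({self.acceptor_pos})"
            )

    @property
    def splice_score(self) -> float:
        return self.donor_score + self.acceptor_score

    @property
    def span(self) -> int:
        return self.donor_pos - self.acceptor_pos

    @property
    def support(self) -> int:
        return len(self.supporting_read_ids)


@dataclass
class CircRNA:
    """A reported circRNA with its canonical ID and junction expression."""

    id: str
    candidate: CircCandidate
    exonic_sequence: str
    junction_read_count: int = 0


@dataclass(frozen=True)
class PseudoCircularReference:
    """Circle 3' tail concatenated to 5' head; junction at ``junction_offset``."""

    sequence: str
    junction_offset: int


# ---------------------------------------------------------------------------
# Canonical circRNA identifiers


def make_circ_id(chrom: str | int, pos_a: int, pos_b: int) -> str:
    """Canonical circRNA ID: ``chr{c}_{max}_{min}_-{span}``.

    The two junction coordinates are given in either order; the ID lists
    the larger first and appends the negative span.
    """
    if pos_a <= 0 or pos_b <= 0:
        raise ValueError("positions must be positive")
    if pos_a == pos_b:
        raise ValueError("junction coordinates must differ (zero span)")
    chrom_s = str(chrom)
    if not chrom_s.startswith("chr"):
        chrom_s = "chr" + chrom_s
    hi, lo = max(pos_a, pos_b), min(pos_a, pos_b)
    return f"{chrom_s}_{hi}_{lo}_-{hi - lo}"


_CIRC_ID_RE = re.compile(r"^(chr[\w.]+)_(\d+)_(\d+)_-(\d+)$")


def parse_circ_id(circ_id: str) -> tuple[str, int, int, int]:
    """Inverse of :func:`make_circ_id`: returns (chrom, max, min, -span)."""
    m = _CIRC_ID_RE.match(circ_id)
    if not m:
        raise ValueError(f"not a valid circRNA id: {circ_id!r}")
    chrom, hi, lo, span = m.group(1), int(m.group(2)), int(m.group(3)), int(m.group(4))
    if hi <= lo:
        raise ValueError(f"id {circ_id!r}: first coordinate must exceed second")
    if hi - lo != span:
        raise ValueError(f"id {circ_id!r}: span suffix {span} != {hi} - {lo}")
    return chrom, hi, lo, -span


# ---------------------------------------------------------------------------
# Splice-site strength scoring


class SpliceScorer:
    """PWM log-odds scorer over MaxEntScan window conventions.

    Scores a window as sum over positions of log2(p_col(base) /
    p_background(base)).  Default matrices are estimated from the
    canonical GT-AG sites of a supplied exon annotation; any object with
    ``score_donor_window`` / ``score_acceptor_window`` can be plugged in
    instead (e.g. real MaxEntScan tables).
    """

    def __init__(
        self,
        donor_pwm: np.ndarray,
        acceptor_pwm: np.ndarray,
        background: np.ndarray | None = None,
    ) -> None:
        donor_pwm = np.asarray(donor_pwm, dtype=float)
        acceptor_pwm = np.asarray(acceptor_pwm, dtype=float)
        if donor_pwm.shape != (DONOR_EXONIC + DONOR_INTRONIC, 4):
            raise ValueError(f"donor PWM must be 9x4, got {donor_pwm.shape}")
        if acceptor_pwm.shape != (ACCEPTOR_INTRONIC + ACCEPTOR_EXONIC, 4):
            raise ValueError(f"acceptor PWM must be 23x4, got {acceptor_pwm.shape}")
        for pwm, name in ((donor_pwm, "donor"), (acceptor_pwm, "acceptor")):
            if not np.allclose(pwm.sum(axis=1), 1.0):
                raise ValueError(f"{name} PWM columns must sum to 1")
        if background is None:
            background = np.full(4, 0.25)
        background = np.asarray(background, dtype=float)
        if background.shape != (4,) or not np.isclose(background.sum(), 1.0):
            raise ValueError("background must be 4 base frequencies summing to 1")
        self.donor_pwm = donor_pwm
        self.acceptor_pwm = acceptor_pwm
        self.background = background
        self._donor_logodds = np.log2(donor_pwm / background)
        self._acceptor_logodds = np.log2(acceptor_pwm / background)

    @staticmethod
    def _window_score(logodds: np.ndarray, window: str) -> float:
        if len(window) != logodds.shape[0]:
            raise ValueError(
                f"window length {len(window)} != PWM length {logodds.shape[0]}"
            )
        total = 0.0
        for i, base in enumerate(window):
            j = _BASE_INDEX.get(base)
            if j is not None:  # N contributes 0 (background odds)
                total += logodds[i, j]
        return float(total)

    def score_donor_window(self, window: str) -> float:
        return self._window_score(self._donor_logodds, window)

    def score_acceptor_window(self, window: str) -> float:
        return self._window_score(self._acceptor_logodds, window)

    def max_donor_score(self) -> float:
        return float(self._donor_logodds.max(axis=1).sum())

    def max_acceptor_score(self) -> float:
        return float(self._acceptor_logodds.max(axis=1).sum())

    @classmethod
    def from_annotation(
        cls,
        genome: Mapping[str, GenomeSequence],
        annotations: Sequence[ExonAnnotation],
        pseudocount: float = 0.5,
    ) -> "SpliceScorer":
        """Estimate PWMs from the annotated introns' donor/acceptor windows."""
        donor_windows: list[str] = []
        acceptor_windows: list[str] = []
        for ann in annotations:
            chrom = genome[ann.chrom]
            for intron_start, intron_end in ann.introns:
                if ann.strand == "+":
                    d = _donor_window_plus(chrom, intron_start - 1)
                    a = _acceptor_window_plus(chrom, intron_end + 1)
                else:
                    d = _donor_window_minus(chrom, intron_end + 1)
                    a = _acceptor_window_minus(chrom, intron_start - 1)
                if d is not None:
                    donor_windows.append(d)
                if a is not None:
                    acceptor_windows.append(a)
        if not donor_windows or not acceptor_windows:
            raise ValueError("annotation provides no scorable introns")
        return cls(
            _pwm_from_windows(donor_windows, DONOR_EXONIC + DONOR_INTRONIC, pseudocount),
            _pwm_from_windows(
                acceptor_windows, ACCEPTOR_INTRONIC + ACCEPTOR_EXONIC, pseudocount
            ),
        )


def _pwm_from_windows(windows: list[str], length: int, pseudocount: float) -> np.ndarray:
    counts = np.full((length, 4), pseudocount)
    for w in windows:
        for i, base in enumerate(w):
            j = _BASE_INDEX.get(base)
            if j is not None:
                counts[i, j] += 1
    return counts / counts.sum(axis=1, keepdims=True)


def _donor_window_plus(chrom: GenomeSequence, exon_end: int) -> str | None:
    """Donor 9-mer for a '+' strand exon ending at ``exon_end``."""
    start, end = exon_end - DONOR_EXONIC + 1, exon_end + DONOR_INTRONIC
    if start < 1 or end > len(chrom):
        return None
    return chrom.slice1(start, end)


def _acceptor_window_plus(chrom: GenomeSequence, exon_start: int) -> str | None:
    """Acceptor 23-mer for a '+' strand exon starting at ``exon_start``."""
    start, end = exon_start - ACCEPTOR_INTRONIC, exon_start + ACCEPTOR_EXONIC - 1
    if start < 1 or end > len(chrom):
        return None
    return chrom.slice1(start, end)


def _donor_window_minus(chrom: GenomeSequence, exon_start: int) -> str | None:
    """Donor 9-mer for a '-' strand exon whose genomic start is ``exon_start``."""
    start, end = exon_start - DONOR_INTRONIC, exon_start + DONOR_EXONIC - 1
    if start < 1 or end > len(chrom):
        return None
    return revcomp(chrom.slice1(start, end))


def _acceptor_window_minus(chrom: GenomeSequence, exon_end: int) -> str | None:
    """Acceptor 23-mer for a '-' strand exon whose genomic end is ``exon_end``."""
    start, end = exon_end - ACCEPTOR_EXONIC + 1, exon_end + ACCEPTOR_INTRONIC
    if start < 1 or end > len(chrom):
        return None
    return revcomp(chrom.slice1(start, end))


def score_splice_sites(
    scorer: SpliceScorer,
    genome: Mapping[str, GenomeSequence],
    chrom: str,
    strand: str,
    donor_pos: int,
    acceptor_pos: int,
) -> tuple[float, float]:
    """Splice-strength scores of a back-splice junction's donor and acceptor.

    ``donor_pos``/``acceptor_pos`` are the genomic high/low circle
    boundaries.  On '+', the donor site is the exon end at ``donor_pos``
    and the acceptor the exon start at ``acceptor_pos``; on '-' the
    roles map to the opposite genomic ends and windows are
    reverse-complemented.
    """
    chrom_seq = genome[chrom]
    if strand == "+":
        d = _donor_window_plus(chrom_seq, donor_pos)
        a = _acceptor_window_plus(chrom_seq, acceptor_pos)
    elif strand == "-":
        d = _donor_window_minus(chrom_seq, acceptor_pos)
        a = _acceptor_window_minus(chrom_seq, donor_pos)
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if d is None or a is None:
        raise ValueError(
            f"splice window out of chromosome bounds at {chrom}:"
            f"{acceptor_pos}-{donor_pos} ({strand})"
        )
    return scorer.score_donor_window(d), scorer.score_acceptor_window(a)


# ---------------------------------------------------------------------------
# k-mer index and alignment


class KmerIndex:
    """Exact k-mer index over a set of sequences (forward strand only)."""

    def __init__(self, sequences: Mapping[str, str], k: int, max_hits: int = 50) -> None:
        self.k = k
        self.max_hits = max_hits
        self.sequences = dict(sequences)
        index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        overfull: set[str] = set()
        for name, seq in self.sequences.items():
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                if kmer in overfull or "N" in kmer:
                    continue
                hits = index[kmer]
                hits.append((name, pos))
                if len(hits) > max_hits:
                    del index[kmer]
                    overfull.add(kmer)
        self.index = dict(index)

    @classmethod
    def from_genome(
        cls, genome: Iterable[GenomeSequence], k: int, max_hits: int = 50
    ) -> "KmerIndex":
        return cls({g.chrom_name: g.sequence for g in genome}, k, max_hits)

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self.index.get(kmer, [])


def _diagonal_hits(query: str, index: KmerIndex) -> dict[tuple[str, int], list[int]]:
    """Group seed hits by (reference name, diagonal = ref_pos0 - query_pos)."""
    k = index.k
    diags: dict[tuple[str, int], list[int]] = defaultdict(list)
    for qpos in range(len(query) - k + 1):
        for name, rpos in index.lookup(query[qpos : qpos + k]):
            diags[(name, rpos - qpos)].append(qpos)
    return diags


def _best_segment_on_diagonal(
    query: str, ref: str, diag: int
) -> tuple[int, int, int] | None:
    """Maximal-scoring ungapped run (match +1 / mismatch -1) on one diagonal.

    Returns (query_start, query_end, score), 0-based half-open, or None.
    """
    q_lo = max(0, -diag)
    q_hi = min(len(query), len(ref) - diag)
    if q_hi <= q_lo:
        return None
    best = (0, 0, 0)
    run_start, run_score = q_lo, 0
    best_start, best_end, best_score = q_lo, q_lo, 0
    for q in range(q_lo, q_hi):
        step = 1 if query[q] == ref[q + diag] else -1
        if run_score <= 0:
            run_start, run_score = q, step
        else:
            run_score += step
        if run_score > best_score:
            best_start, best_end, best_score = run_start, q + 1, run_score
    if best_score <= 0:
        return None
    return best_start, best_end, best_score


def split_align(
    read: ReadRecord,
    index: KmerIndex,
    config: PipelineConfig,
    orientation: str = "+",
) -> list[SegmentAlignment]:
    """Local segment placements of a read by k-mer seeding + ungapped extension.

    ``orientation`` '-' aligns the reverse complement of the read; the
    returned read intervals refer to the oriented query.  Only segments
    scoring >= ``min_segment_score`` are kept, sorted by query position.
    """
    query = read.sequence if orientation == "+" else revcomp(read.sequence)
    if len(query) < index.k:
        return []
    segments: list[SegmentAlignment] = []
    seen: set[tuple[str, int, int, int]] = set()
    for (name, diag), _qpos_list in _diagonal_hits(query, index).items():
        hit = _best_segment_on_diagonal(query, index.sequences[name], diag)
        if hit is None:
            continue
        q_start, q_end, score = hit
        if score < config.min_segment_score:
            continue
        key = (name, diag, q_start, q_end)
        if key in seen:
            continue
        seen.add(key)
        segments.append(
            SegmentAlignment(
                read_id=read.read_id,
                read_start=q_start,
                read_end=q_end,
                chrom=name,
                strand=orientation,
                ref_start=q_start + diag + 1,
                ref_end=q_end + diag,
                score=score,
            )
        )
    segments.sort(key=lambda s: (s.read_start, s.read_end, s.chrom, s.ref_start))
    return segments


def contiguous_align(
    read: ReadRecord,
    genome_index: KmerIndex,
    transcript_index: KmerIndex | None,
    config: PipelineConfig,
) -> SegmentAlignment | None:
    """Full-length placement of a read on the genome or a spliced transcript.

    Returns the placement when one exists with identity >=
    ``min_contiguous_identity`` over the whole read (either orientation);
    reads without one are routed to split alignment.
    """
    n = len(read.sequence)
    min_matches = int(np.ceil(config.min_contiguous_identity * n))
    for index in (genome_index, transcript_index):
        if index is None:
            continue
        for orientation in ("+", "-"):
            query = read.sequence if orientation == "+" else revcomp(read.sequence)
            if len(query) < index.k:
                continue
            for (name, diag), qpos_list in sorted(
                _diagonal_hits(query, index).items(),
                key=lambda kv: -len(kv[1]),
            ):
                if diag < 0 or diag + n > len(index.sequences[name]):
                    continue  # full-length placement impossible on this diagonal
                ref = index.sequences[name]
                matches = sum(
                    1 for q in range(n) if query[q] == ref[q + diag]
                )
                if matches >= min_matches:
                    return SegmentAlignment(
                        read_id=read.read_id,
                        read_start=0,
                        read_end=n,
                        chrom=name,
                        strand=orientation,
                        ref_start=diag + 1,
                        ref_end=diag + n,
                        score=2 * matches - n,
                    )
    return None


# ---------------------------------------------------------------------------
# Head-to-tail geometry


def _optimal_breakpoint(
    query: str, ref: str, a: SegmentAlignment, b: SegmentAlignment
) -> tuple[int, int] | None:
    """(donor, acceptor) maximizing per-base read support for the junction.

    The junction read position r splits the query into a prefix placed
    on segment ``a``'s diagonal and a suffix on ``b``'s; the r with the
    most matching bases is the breakpoint the read itself supports
    best.  Ties go to the leftmost r (splice-score refinement resolves
    the residual micro-homology ambiguity).
    """
    da = (a.ref_start - 1) - a.read_start
    db = (b.ref_start - 1) - b.read_start
    lo = max(b.read_start, a.read_start + 1, -db)
    hi = min(a.read_end, b.read_end - 1, len(ref) - da)
    if hi < lo:
        return None
    # cumulative matches along each diagonal over [lo-1, hi]
    best_r, best_score = None, -1
    prefix = 0
    for q in range(a.read_start, lo):
        prefix += query[q] == ref[q + da]
    suffix = 0
    for q in range(lo, b.read_end):
        suffix += query[q] == ref[q + db]
    r = lo
    while True:
        if prefix + suffix > best_score:
            best_score, best_r = prefix + suffix, r
        if r >= hi:
            break
        prefix += query[r] == ref[r + da]
        suffix -= query[r] == ref[r + db]
        r += 1
    donor = best_r + da        # 1-based ref position of the last prefix base
    acceptor = best_r + db + 1  # 1-based ref position of the first suffix base
    return donor, acceptor


def find_head_to_tail(
    segments: Sequence[SegmentAlignment],
    config: PipelineConfig,
    query: str | None = None,
    ref_seqs: Mapping[str, str] | None = None,
) -> CircCandidate | None:
    """Back-splice candidate from one read's segments, or None.

    A pair qualifies iff both segments are on the same chromosome, no
    more than ``max_junction_span_bp`` apart, on the same strand, and in
    reverse order: the segment earlier on the read maps strictly
    downstream of the later segment.  The junction donor is the high
    genomic end of the earlier segment, the acceptor the low genomic
    start of the later one.  A gap between the two segments on the read
    may not exceed ``max_read_gap_nt``; an overlap (both segments
    claiming the same read bases, the signature of micro-homology
    around the junction — canonical splice motifs alone create 4-6 nt
    of it) is tolerated up to ``max_junction_overlap_nt``.  When the
    oriented query and reference sequences are supplied, the boundary
    is placed at the read's optimal breakpoint between the two
    diagonals; otherwise the earlier segment is trimmed by the overlap.
    With several qualifying pairs the highest-scoring one wins.
    """
    best: tuple[int, CircCandidate] | None = None
    for i in range(len(segments)):
        for j in range(i + 1, len(segments)):
            a, b = segments[i], segments[j]
            if a.chrom != b.chrom or a.strand != b.strand:
                continue
            if a.ref_start <= b.ref_end:  # forward order: linear splice
                continue
            overlap = a.read_end - b.read_start
            if overlap > config.max_junction_overlap_nt:
                continue
            if -overlap > config.max_read_gap_nt:
                continue
            if query is not None and ref_seqs is not None and a.chrom in ref_seqs:
                bp = _optimal_breakpoint(query, ref_seqs[a.chrom], a, b)
                if bp is None:
                    continue
                donor, acceptor = bp
            else:
                donor = a.ref_end - max(overlap, 0)
                acceptor = b.ref_start
            if donor <= acceptor:
                continue
            if donor - acceptor > config.max_junction_span_bp:
                continue
            total = a.score + b.score
            cand = CircCandidate(
                chrom=a.chrom,
                strand=a.strand,
                acceptor_pos=acceptor,
                donor_pos=donor,
                supporting_read_ids={a.read_id},
            )
            if best is None or total > best[0]:
                best = (total, cand)
    return None if best is None else best[1]


def refine_junction(
    raw: CircCandidate,
    scorer: SpliceScorer,
    genome: Mapping[str, GenomeSequence],
    window_radius: int = 5,
) -> CircCandidate:
    """Shift the junction within +/-``window_radius`` to maximize splice score.

    Alignment can misplace a back-splice boundary within a stretch of
    micro-homology between the donor and acceptor flanks; all shifts
    that leave the junction-spanning sequence unchanged are equivalent
    explanations of the read evidence.  Among those, the shift with the
    highest donor+acceptor score wins; ties break to the smallest
    absolute shift, then the leftmost position.
    """
    chrom = genome[raw.chrom]

    def shift_consistent(delta: int) -> bool:
        """A shift is read-consistent iff the bases crossing the junction are
        micro-homologous: for delta > 0 the delta bases after the donor must
        (near-)equal the delta bases starting at the acceptor (mirrored for
        < 0).  Up to (|delta|-1)//2 mismatches are allowed — the budget a
        net-positive ungapped extension could have absorbed when it overran
        the junction."""
        d, a = raw.donor_pos, raw.acceptor_pos
        try:
            if delta > 0:
                x = chrom.slice1(d + 1, d + delta)
                y = chrom.slice1(a, a + delta - 1)
            elif delta < 0:
                x = chrom.slice1(d + delta + 1, d)
                y = chrom.slice1(a + delta, a - 1)
            else:
                return True
        except IndexError:
            return False
        mismatches = sum(1 for u, v in zip(x, y) if u != v)
        return mismatches <= (abs(delta) - 1) // 2

    best_shift: int | None = None
    best_score = -np.inf
    for shift in sorted(range(-window_radius, window_radius + 1), key=lambda s: (abs(s), s)):
        donor, acceptor = raw.donor_pos + shift, raw.acceptor_pos + shift
        if donor <= acceptor:
            continue
        if not shift_consistent(shift):
            continue
        try:
            d_score, a_score = score_splice_sites(
                scorer, genome, raw.chrom, raw.strand, donor, acceptor
            )
        except ValueError:
            continue
        total = d_score + a_score
        if total > best_score:  # sorted order encodes the tie-break
            best_score = total
            best_shift = shift
    if best_shift is None:
        best_shift = 0
    donor, acceptor = raw.donor_pos + best_shift, raw.acceptor_pos + best_shift
    try:
        d_score, a_score = score_splice_sites(
            scorer, genome, raw.chrom, raw.strand, donor, acceptor
        )
    except ValueError:
        d_score = a_score = -np.inf
    return replace(
        raw,
        donor_pos=donor,
        acceptor_pos=acceptor,
        donor_score=d_score,
        acceptor_score=a_score,
        supporting_read_ids=set(raw.supporting_read_ids),
    )


def merge_candidates(candidates: Iterable[CircCandidate]) -> list[CircCandidate]:
    """Merge candidates with identical (chrom, strand, donor, acceptor)."""
    merged: dict[tuple[str, str, int, int], CircCandidate] = {}
    for cand in candidates:
        key = (cand.chrom, cand.strand, cand.donor_pos, cand.acceptor_pos)
        if key in merged:
            merged[key].supporting_read_ids |= cand.supporting_read_ids
        else:
            merged[key] = replace(
                cand, supporting_read_ids=set(cand.supporting_read_ids)
            )
    return sorted(
        merged.values(),
        key=lambda c: (c.chrom, c.acceptor_pos, c.donor_pos, c.strand),
    )


def filter_candidates(
    candidates: Iterable[CircCandidate], config: PipelineConfig
) -> list[CircCandidate]:
    """Keep candidates with enough read support and splice strength.

    A candidate passes iff it has at least ``min_support_reads``
    distinct supporting reads and donor+acceptor splice score >=
    ``min_splice_score``; both bounds are inclusive.
    """
    return [
        c
        for c in merge_candidates(candidates)
        if c.support >= config.min_support_reads
        and c.splice_score >= config.min_splice_score
        and c.span <= config.max_junction_span_bp
    ]


# ---------------------------------------------------------------------------
# Pseudo-circular reference and quantification


def _circle_exons(
    candidate: CircCandidate, annotations: Sequence[ExonAnnotation]
) -> ExonAnnotation | None:
    """Transcript whose exon boundaries match both junction ends, if any.

    Preference: both boundaries on annotated exon edges; ties broken by
    the longest (spliced) transcript.
    """
    best: tuple[int, ExonAnnotation] | None = None
    for ann in annotations:
        if ann.chrom != candidate.chrom or ann.strand != candidate.strand:
            continue
        starts = {s for s, _ in ann.exons}
        ends = {e for _, e in ann.exons}
        if candidate.acceptor_pos in starts and candidate.donor_pos in ends:
            length = sum(e - s + 1 for s, e in ann.exons)
            if best is None or length > best[0]:
                best = (length, ann)
    return None if best is None else best[1]


def circle_sequence(
    candidate: CircCandidate,
    annotations: Sequence[ExonAnnotation],
    genome: Mapping[str, GenomeSequence],
) -> str:
    """Exonic sequence of the circle, 5'->3' in transcript orientation.

    Uses the exon structure of a matching annotated transcript when one
    exists (introns spliced out); otherwise falls back to the genomic
    sequence of the whole interval.
    """
    chrom = genome[candidate.chrom]
    ann = _circle_exons(candidate, annotations)
    if ann is not None:
        inside = [
            (s, e)
            for s, e in ann.exons
            if s >= candidate.acceptor_pos and e <= candidate.donor_pos
        ]
        seq = "".join(chrom.slice1(s, e) for s, e in inside)
    else:
        seq = chrom.slice1(candidate.acceptor_pos, candidate.donor_pos)
    return revcomp(seq) if candidate.strand == "-" else seq


def build_pseudo_circular_reference(
    candidate: CircCandidate,
    annotations: Sequence[ExonAnnotation],
    genome: Mapping[str, GenomeSequence],
    flank_len: int,
) -> PseudoCircularReference:
    """Junction-spanning reference: circle 3' tail + circle 5' head.

    Each flank is ``flank_len`` nt when the circle is long enough; a
    circle shorter than twice the flank is simply rotated so the
    junction is interior, with no sequence duplicated.
    """
    circle = circle_sequence(candidate, annotations, genome)
    L = len(circle)
    if L >= 2 * flank_len:
        a = b = flank_len
    elif L > flank_len:
        a, b = flank_len, L - flank_len
    else:
        a, b = (L + 1) // 2, L // 2
    return PseudoCircularReference(circle[L - a :] + circle[:b], a)


def quantify_junction_reads(
    reads: Iterable[ReadRecord],
    pseudo_ref: str | PseudoCircularReference,
    junction_offset: int | None,
    config: PipelineConfig,
) -> int:
    """Count reads crossing the back-splice junction in a pseudo reference.

    A read counts when it has an ungapped placement (either orientation)
    on ``pseudo_ref`` with >= 90% identity that crosses
    ``junction_offset`` with the ``min_overhang_nt`` bases immediately
    flanking the junction all matching on both sides — a mismatch right
    at the junction leaves the back-splice unsupported no matter how
    long the rest of the alignment is.  Each read is counted at most
    once.
    """
    if isinstance(pseudo_ref, PseudoCircularReference):
        ref, junction = pseudo_ref.sequence, pseudo_ref.junction_offset
    else:
        ref, junction = pseudo_ref, junction_offset
        if junction is None:
            raise ValueError("junction_offset required with a plain string reference")
    index = KmerIndex({"ref": ref}, config.seed_kmer, max_hits=len(ref))
    count = 0
    for read in reads:
        if _read_crosses_junction(read, ref, index, junction, config):
            count += 1
    return count


def _read_crosses_junction(
    read: ReadRecord,
    ref: str,
    index: KmerIndex,
    junction: int,
    config: PipelineConfig,
) -> bool:
    for orientation in ("+", "-"):
        query = read.sequence if orientation == "+" else revcomp(read.sequence)
        if len(query) < index.k:
            continue
        for (_name, diag) in _diagonal_hits(query, index):
            q_lo = max(0, -diag)
            q_hi = min(len(query), len(ref) - diag)
            if q_hi <= q_lo:
                continue
            matched = [query[q] == ref[q + diag] for q in range(q_lo, q_hi)]
            if sum(matched) < 0.9 * (q_hi - q_lo):
                continue
            # the placement must cover min_overhang_nt bases on each side of
            # the junction, and those junction-adjacent bases must all match
            k = config.min_overhang_nt
            lo_ref, hi_ref = junction - k, junction + k
            if q_lo + diag > lo_ref or q_hi + diag < hi_ref:
                continue
            window = range(lo_ref - diag, hi_ref - diag)
            if all(matched[q - q_lo] for q in window):
                return True
    return False


# ---------------------------------------------------------------------------
# SAM ingest and the full detection pass


def read_sam_linear_ids(path: str) -> set[str]:
    """Read ids of linearly mapped reads from a precomputed SAM file.

    Reads flagged unmapped are the ones routed to split alignment; all
    others are treated as contiguously placed.
    """
    import pysam

    mapped: set[str] = set()
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if not rec.is_unmapped:
                mapped.add(rec.query_name)
    return mapped


def detect_circrnas(
    reads: Sequence[ReadRecord],
    genome: Sequence[GenomeSequence],
    annotations: Sequence[ExonAnnotation],
    config: PipelineConfig,
    scorer: SpliceScorer | None = None,
    linear_read_ids: set[str] | None = None,
    read_len: int | None = None,
) -> list[CircRNA]:
    """Full back-splice detection pass: route, split, refine, filter, quantify.

    Reads that align contiguously to the genome or a spliced transcript
    are set aside; the remainder are split-aligned in both orientations
    and screened for head-to-tail geometry.  Junctions are refined and
    strand-assigned by splice-site strength, merged, and filtered on
    read support and splice score; each surviving circle is quantified
    against its pseudo-circular reference.
    """
    genome_map = {g.chrom_name: g for g in genome}
    if scorer is None:
        scorer = SpliceScorer.from_annotation(genome_map, annotations)
    genome_index = KmerIndex.from_genome(genome, config.seed_kmer, config.max_seed_hits)
    transcript_seqs = {
        ann.transcript_id: ann.spliced_sequence(genome_map) for ann in annotations
    }
    transcript_index = (
        KmerIndex(transcript_seqs, config.seed_kmer, config.max_seed_hits)
        if transcript_seqs
        else None
    )

    unmapped: list[ReadRecord] = []
    for read in reads:
        if linear_read_ids is not None:
            if read.read_id in linear_read_ids:
                continue
        elif contiguous_align(read, genome_index, transcript_index, config) is not None:
            continue
        unmapped.append(read)

    ref_seqs = {g.chrom_name: g.sequence for g in genome}
    raw: list[CircCandidate] = []
    for read in unmapped:
        best: CircCandidate | None = None
        for orientation in ("+", "-"):
            query = read.sequence if orientation == "+" else revcomp(read.sequence)
            segments = split_align(read, genome_index, config, orientation)
            cand = find_head_to_tail(segments, config, query=query, ref_seqs=ref_seqs)
            if cand is not None and (best is None):
                best = cand
        if best is not None:
            raw.append(best)

    # Merge on geometry alone first, then refine once per junction and pick
    # the strand with the stronger splice signal.
    by_geometry: dict[tuple[str, int, int], CircCandidate] = {}
    for cand in raw:
        key = (cand.chrom, cand.donor_pos, cand.acceptor_pos)
        if key in by_geometry:
            by_geometry[key].supporting_read_ids |= cand.supporting_read_ids
        else:
            by_geometry[key] = replace(
                cand, supporting_read_ids=set(cand.supporting_read_ids)
            )
    refined: list[CircCandidate] = []
    for cand in by_geometry.values():
        variants = []
        for strand in ("+", "-"):
            variants.append(
                refine_junction(
                    replace(cand, strand=strand,
                            supporting_read_ids=set(cand.supporting_read_ids)),
                    scorer,
                    genome_map,
                    config.refine_radius_nt,
                )
            )
        refined.append(max(variants, key=lambda c: c.splice_score))

    kept = filter_candidates(refined, config)

    if read_len is None:
        read_len = max((len(r.sequence) for r in reads), default=0)
    flank = max(read_len - config.min_overhang_nt, config.min_overhang_nt)
    circrnas: list[CircRNA] = []
    for cand in kept:
        pseudo = build_pseudo_circular_reference(cand, annotations, genome_map, flank)
        count = quantify_junction_reads(unmapped, pseudo, None, config)
        circrnas.append(
            CircRNA(
                id=make_circ_id(cand.chrom, cand.donor_pos, cand.acceptor_pos),
                candidate=cand,
                exonic_sequence=circle_sequence(cand, annotations, genome_map),
                junction_read_count=count,
            )
        )
    return circrnas
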