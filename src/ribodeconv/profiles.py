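"""Length-stratified observed 5'-end read profiles.

All per-transcript vectors live on a shared coordinate window anchored at the
first base of the start codon: position ``p`` is a 0-based nt offset relative
to ``cds_start`` and maps to array index ``p + l_up``.  The window spans
``[-l_up, l_down)`` with ``l_up`` upstream cells (default 24, enough to hold
the 5' ends of reads up to 40 nt whose periodicity starts at ``-l + 16``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pysam

logger = logging.getLogger(__name__)

#: default number of representable positions upstream of the start codon
L_UP_DEFAULT = 24

#: default inclusive read-length range for profile construction
LENGTH_RANGE_DEFAULT = (18, 33)

#: anchor read length: the typical yeast footprint size
ANCHOR_LENGTH = 28


@dataclass(frozen=True)
class TranscriptAnnotation:
    """CDS coordinates of one transcript, in transcript-local coordinates.

    ``cds_start`` is the 0-based offset of the first start-codon base;
    ``cds_end`` is the 0-based exclusive end of the stop codon.
    """

    transcript_id: str
    cds_start: int
    cds_end: int
    length: int

    def __post_init__(self) -> None:
        if not (0 <= self.cds_start < self.cds_end <= self.length):
            raise ValueError(
                f"{self.transcript_id}: invalid CDS bounds "
                f"[{self.cds_start}, {self.cds_end}) for length {self.length}"
            )
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS span not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start


def window_bounds(annot: TranscriptAnnotation, l_up: int = L_UP_DEFAULT) -> tuple[int, int]:
    """Return ``(l_up, l_down)`` of the shared profile window for a transcript.

    ``l_down = min(length - cds_start, cds_length + l_up)``, so the window
    always covers the full CDS plus a downstream margin when the transcript
    extends that far.
    """
    l_down = min(annot.length - annot.cds_start, annot.cds_length + l_up)
    return l_up, l_down


@dataclass
class LengthProfile:
    """Per-transcript, per-read-length vector of 5'-end counts.

    ``counts[i]`` holds the (possibly normalized) count of reads whose 5'-most
    aligned base is at position ``i - l_up`` relative to ``cds_start``.
    ``alpha`` is the raw total read count and is never rescaled.
    """

    transcript_id: str
    read_length: int
    counts: np.ndarray
    alpha: float
    l_up: int = L_UP_DEFAULT

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1:
            raise ValueError("counts must be 1-D")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.counts.size

    @property
    def positions(self) -> np.ndarray:
        """Positions (nt relative to ``cds_start``) of each cell."""
        return np.arange(self.n_cells) - self.l_up

    def index_of(self, position: int) -> int:
        idx = position + self.l_up
        if not 0 <= idx < self.n_cells:
            raise IndexError(f"position {position} outside window")
        return idx


@dataclass
class ProfileSet:
    """All retained length profiles of one transcript plus its frame call."""

    transcript_id: str
    profiles: dict[int, LengthProfile]
    in_frame: int
    annotation: TranscriptAnnotation | None = None

    @property
    def read_lengths(self) -> list[int]:
        return sorted(self.profiles)

    @property
    def total_alpha(self) -> float:
        return float(sum(p.alpha for p in self.profiles.values()))


def _frame_totals(profiles: list[LengthProfile]) -> np.ndarray:
    totals = np.zeros(3)
    for p in profiles:
        frames = np.mod(p.positions, 3)
        for f in range(3):
            totals[f] += p.counts[frames == f].sum()
    return totals


def in_frame_of(profile_set: ProfileSet | list[LengthProfile]) -> int:
    """Frame (0, 1, or 2) with the highest total read count across lengths.

    Ties are broken toward the smallest frame index.  Raises ``ValueError``
    when every profile is all-zero.
    """
    if isinstance(profile_set, ProfileSet):
        profiles = list(profile_set.profiles.values())
    else:
        profiles = list(profile_set)
    totals = _frame_totals(profiles)
    if totals.sum() <= 0:
        raise ValueError("no reads: cannot determine the dominant frame")
    return int(np.argmax(totals))  # argmax takes the first maximum


def build_length_profiles(
    alignments,
    annotations: dict[str, TranscriptAnnotation],
    length_range: tuple[int, int] = LENGTH_RANGE_DEFAULT,
    l_up: int = L_UP_DEFAULT,
) -> list[LengthProfile]:
    """Count 5' ends of uniquely mapped reads per transcript and read length.

    Parameters
    ----------
    alignments : str or pysam.AlignmentFile
        Transcriptome-coordinate SAM/BAM file (or an open handle).
    annotations : dict
        Map from transcript id to :class:`TranscriptAnnotation`; every aligned
        reference must be present (unknown references are skipped with a
        warning).
    length_range : (int, int)
        Inclusive range of retained read lengths; the read length is the
        aligned reference span, so 5' soft-clipped bases are ignored and the
        5' end is the first aligned base.

    Returns
    -------
    list of LengthProfile sorted by (transcript_id, read_length).
    """
    l_min, l_max = length_range
    if l_min > l_max:
        raise ValueError("empty length range")
    own_handle = False
    if isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__"):
        alignments = pysam.AlignmentFile(str(alignments), check_sq=False)
        own_handle = True
    counts: dict[tuple[str, int], np.ndarray] = {}
    try:
        for rec_index, rec in enumerate(alignments.fetch(until_eof=True)):
            try:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                if rec.is_reverse:
                    continue  # transcriptome alignments are sense-strand
                if rec.has_tag("NH") and rec.get_tag("NH") > 1:
                    continue  # multimapper
                ref = rec.reference_name
                read_len = rec.reference_end - rec.reference_start
                five_prime = rec.reference_start
            except (TypeError, ValueError) as exc:
                raise ValueError(f"malformed alignment record {rec_index}") from exc
            annot = annotations.get(ref)
            if annot is None:
                logger.warning("read aligned to unknown reference %r; skipped", ref)
                continue
            if not l_min <= read_len <= l_max:
                continue
            key = (annot.transcript_id, read_len)
            if key not in counts:
                _, l_down = window_bounds(annot, l_up)
                counts[key] = np.zeros(l_up + l_down)
            pos = five_prime - annot.cds_start
            idx = pos + l_up
            if 0 <= idx < counts[key].size:
                counts[key][idx] += 1
    finally:
        if own_handle:
            alignments.close()
    out = [
        LengthProfile(tid, l, c, alpha=float(c.sum()), l_up=l_up)
        for (tid, l), c in sorted(counts.items())
    ]
    return out


def group_by_transcript(profiles: list[LengthProfile]) -> dict[str, list[LengthProfile]]:
    grouped: dict[str, list[LengthProfile]] = {}
    for p in profiles:
        grouped.setdefault(p.transcript_id, []).append(p)
    return grouped


def filter_profiles(
    profiles: list[LengthProfile],
    annotations: dict[str, TranscriptAnnotation],
    min_coverage: float = 0.5,
    min_lengths: int = 2,
) -> list[ProfileSet]:
    """Apply the coverage and multiplicity filters and assemble ProfileSets.

    A length profile is retained iff strictly more than ``min_coverage`` of
    the in-frame codon loci within the CDS carry nonzero counts, where the
    in-frame frame is the per-transcript dominant frame over all lengths.  A
    transcript is retained iff at least ``min_lengths`` profiles survive.
    """
    out: list[ProfileSet] = []
    for tid, plist in sorted(group_by_transcript(profiles).items()):
        annot = annotations[tid]
        try:
            frame = in_frame_of(plist)
        except ValueError:
            continue
        loci = np.arange(frame, annot.cds_length, 3)  # in-frame nt loci in CDS
        if loci.size == 0:
            continue
        kept: dict[int, LengthProfile] = {}
        for p in plist:
            idx = loci + p.l_up
            nonzero = np.count_nonzero(p.counts[idx])
            if nonzero > min_coverage * loci.size:
                kept[p.read_length] = p
        if len(kept) >= min_lengths:
            out.append(ProfileSet(tid, kept, in_frame=frame, annotation=annot))
    return out


def normalize_profile(p: LengthProfile) -> LengthProfile:
    """Return a copy whose counts sum to 1; ``alpha`` is unchanged."""
    total = p.counts.sum()
    if total <= 0:
        raise ValueError(f"{p.transcript_id} length {p.read_length}: zero total count")
    return replace(p, counts=p.counts / total)
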