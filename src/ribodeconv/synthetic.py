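"""Ground-truth simulator for every stage of the deconvolution pipeline.

Generates per-transcript sparse frame-0 position signals (optionally scaled
and shaped by per-codon dwell multipliers), per-length signals with small
multiplicative perturbations, unimodal blur kernels, and multinomially
sampled length-stratified read profiles, with optional SAM emission and
single-insertion frameshifts.  Everything derives from one integer seed.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

from ribodeconv.asite import A_SITE_OFFSET, _shift_counts_after
from ribodeconv.cdt import SENSE_CODONS
from ribodeconv.metablur import BLUR_HALF_WIDTH, BlurVector
from ribodeconv.profiles import (
    ANCHOR_LENGTH,
    L_UP_DEFAULT,
    LengthProfile,
    TranscriptAnnotation,
    window_bounds,
)

_RNA_TO_DNA = str.maketrans("U", "T")


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    ``blur_modes`` / ``blur_spreads`` give the per-length centre offset and
    Gaussian spread of the digestion kernels (scalars broadcast to every
    length; spread 0 yields a delta kernel).  ``dwell`` maps codons to dwell
    multipliers: a position holding codon ``c`` draws its signal value from
    ``LogNormal(ln d_c, signal_sigma * d_c)``, so larger multipliers raise
    both the level and the heavy-tailedness of that codon's counts.
    """

    n_transcripts: int = 50
    cds_codons: int | tuple[int, ...] = 150
    read_lengths: tuple[int, ...] = (26, 27, 28, 29, 30)
    mixture_weights: tuple[float, ...] | None = None
    depth: int = 10000
    blur_modes: dict[int, int] | int = 0
    blur_spreads: dict[int, float] | float = 1.0
    dwell: dict[str, float] | None = None
    signal_sigma: float = 0.5
    perturb_sigma: float = 0.05
    frameshift: bool = False
    seed: int = 0
    utr5: int = 30
    utr3: int = 60
    l_up: int = L_UP_DEFAULT

    def __post_init__(self) -> None:
        if self.mixture_weights is None:
            k = len(self.read_lengths)
            self.mixture_weights = tuple(1.0 / k for _ in range(k))
        self.validate()

    def validate(self) -> None:
        problems = []
        if self.n_transcripts < 1:
            problems.append("n_transcripts must be >= 1")
        if len(self.mixture_weights) != len(self.read_lengths):
            problems.append("mixture_weights and read_lengths differ in length")
        if any(w < 0 for w in self.mixture_weights):
            problems.append("mixture weights must be non-negative")
        if self.mixture_weights and not np.isclose(sum(self.mixture_weights), 1.0):
            problems.append("mixture weights must sum to 1")
        if self.depth <= 0:
            problems.append("depth must be positive")
        lengths = self.codon_lengths()
        if any(n < 40 for n in lengths):
            problems.append("cds_codons must be >= 40")
        for l in self.read_lengths:
            if abs(self.blur_mode(l)) > BLUR_HALF_WIDTH:
                problems.append(f"blur mode for length {l} outside kernel range")
            if self.blur_spread(l) < 0:
                problems.append(f"blur spread for length {l} is negative")
        if self.dwell is not None and any(d <= 0 for d in self.dwell.values()):
            problems.append("dwell multipliers must be positive")
        if problems:
            raise ValueError("invalid synthetic spec: " + "; ".join(problems))

    def codon_lengths(self) -> list[int]:
        if isinstance(self.cds_codons, int):
            return [self.cds_codons] * self.n_transcripts
        if len(self.cds_codons) != self.n_transcripts:
            raise ValueError("cds_codons list must match n_transcripts")
        return list(self.cds_codons)

    def blur_mode(self, read_length: int) -> int:
        if isinstance(self.blur_modes, dict):
            return int(self.blur_modes.get(read_length, 0))
        return int(self.blur_modes)

    def blur_spread(self, read_length: int) -> float:
        if isinstance(self.blur_spreads, dict):
            return float(self.blur_spreads.get(read_length, 1.0))
        return float(self.blur_spreads)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        for key in ("blur_modes", "blur_spreads"):
            if isinstance(d[key], dict):
                d[key] = {str(k): v for k, v in d[key].items()}
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticSpec":
        d = json.loads(text)
        for key in ("blur_modes", "blur_spreads"):
            if isinstance(d.get(key), dict):
                d[key] = {int(k): v for k, v in d[key].items()}
        for key in ("cds_codons", "read_lengths", "mixture_weights"):
            if isinstance(d.get(key), list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticTranscript:
    annotation: TranscriptAnnotation
    transcript_seq: str
    cds_seq: str
    consensus: np.ndarray
    signals: dict[int, np.ndarray]
    frameshift_position: int | None = None


@dataclass
class SyntheticTruth:
    spec: SyntheticSpec
    transcripts: list[SyntheticTranscript]
    blurs: dict[int, BlurVector]
    dwell: dict[str, float] = field(default_factory=dict)


def _gaussian_blur(read_length: int, mode: int, spread: float) -> BlurVector:
    offsets = np.arange(-BLUR_HALF_WIDTH, BLUR_HALF_WIDTH + 1)
    if spread == 0:
        weights = (offsets == mode).astype(float)
    else:
        weights = np.exp(-0.5 * ((offsets - mode) / spread) ** 2)
    return BlurVector(read_length, weights / weights.sum())


def generate_truth(spec: SyntheticSpec) -> SyntheticTruth:
    """Draw ground-truth signals, sequences and blur kernels for a spec."""
    spec.validate()
    rng = np.random.default_rng([spec.seed, 0])
    dwell = dict(spec.dwell) if spec.dwell else {c: 1.0 for c in SENSE_CODONS}
    blurs = {
        l: _gaussian_blur(l, spec.blur_mode(l), spec.blur_spread(l))
        for l in spec.read_lengths
    }
    bases = np.array(list("ACGT"))
    codon_pool = np.array([c.translate(_RNA_TO_DNA) for c in SENSE_CODONS])
    transcripts: list[SyntheticTranscript] = []
    for t, n_codons in enumerate(spec.codon_lengths()):
        codons = rng.choice(codon_pool, size=n_codons)
        cds_seq = "".join(codons) + "TAA"
        utr5 = "".join(rng.choice(bases, size=spec.utr5))
        utr3 = "".join(rng.choice(bases, size=spec.utr3))
        seq = utr5 + cds_seq + utr3
        annot = TranscriptAnnotation(
            transcript_id=f"synth{t:04d}",
            cds_start=spec.utr5,
            cds_end=spec.utr5 + len(cds_seq),
            length=len(seq),
        )
        l_up, l_down = window_bounds(annot, spec.l_up)
        consensus = np.zeros(l_up + l_down)
        for c in range(n_codons):
            d = dwell[str(codons[c]).replace("T", "U")]
            sigma = spec.signal_sigma * d
            value = float(np.exp(rng.normal(np.log(d), sigma)))
            consensus[3 * c - A_SITE_OFFSET + l_up] = value
        consensus /= consensus.sum()
        signals = {}
        for l in spec.read_lengths:
            perturbed = consensus * np.exp(
                rng.normal(0.0, spec.perturb_sigma, consensus.size)
            )
            signals[l] = perturbed / perturbed.sum()
        shift_pos: int | None = None
        if spec.frameshift:
            lo, hi = 30, 3 * n_codons - 30
            candidates = np.arange(lo + (-lo) % 3, hi, 3)
            shift_pos = int(rng.choice(candidates))
        transcripts.append(
            SyntheticTranscript(
                annotation=annot,
                transcript_seq=seq,
                cds_seq=cds_seq,
                consensus=consensus,
                signals=signals,
                frameshift_position=shift_pos,
            )
        )
    return SyntheticTruth(spec=spec, transcripts=transcripts, blurs=blurs, dwell=dwell)


def expected_profile(
    truth: SyntheticTruth, transcript: SyntheticTranscript, read_length: int
) -> np.ndarray:
    """Noise-free observed profile: blur applied to the native-frame signal."""
    from ribodeconv.deblur import convolve, shift_for_length, shift_profile

    signal = shift_profile(
        transcript.signals[read_length], -shift_for_length(read_length)
    )
    expected = np.clip(convolve(signal, truth.blurs[read_length]), 0.0, None)
    if transcript.frameshift_position is not None:
        idx = transcript.frameshift_position + truth.spec.l_up
        expected = _shift_counts_after(expected, idx)
    return expected


def sample_reads(
    truth: SyntheticTruth, spec: SyntheticSpec | None = None, exact: bool = False
) -> list[LengthProfile]:
    """Multinomially sample length-stratified profiles from the truth.

    With ``exact=True`` the expected (infinite-depth) profiles scaled to the
    per-length read totals are returned instead of random draws.  Lengths
    with zero mixture weight yield no profile.
    """
    spec = spec or truth.spec
    rng = np.random.default_rng([spec.seed, 1])
    out: list[LengthProfile] = []
    for transcript in truth.transcripts:
        for l, w in zip(spec.read_lengths, spec.mixture_weights):
            if w == 0:
                continue
            n_reads = int(round(spec.depth * w))
            if n_reads == 0:
                continue
            expected = expected_profile(truth, transcript, l)
            total = expected.sum()
            if total <= 0:
                continue
            if exact:
                counts = expected / total * n_reads
            else:
                counts = rng.multinomial(n_reads, expected / total).astype(float)
            out.append(
                LengthProfile(
                    transcript.annotation.transcript_id,
                    l,
                    counts,
                    alpha=float(counts.sum()),
                    l_up=spec.l_up,
                )
            )
    return out


def annotations_of(truth: SyntheticTruth) -> dict[str, TranscriptAnnotation]:
    return {t.annotation.transcript_id: t.annotation for t in truth.transcripts}


def cds_sequences_of(truth: SyntheticTruth) -> dict[str, str]:
    return {t.annotation.transcript_id: t.cds_seq for t in truth.transcripts}


def write_sam(
    truth: SyntheticTruth, profiles: list[LengthProfile], path: str
) -> None:
    """Emit sampled reads as an uncompressed SAM file (one record per read)."""
    annots = annotations_of(truth)
    seqs = {t.annotation.transcript_id: t.transcript_seq for t in truth.transcripts}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for tid in sorted(annots):
            fh.write(f"@SQ\tSN:{tid}\tLN:{annots[tid].length}\n")
        read_id = 0
        for p in profiles:
            annot = annots[p.transcript_id]
            seq = seqs[p.transcript_id]
            for idx in np.flatnonzero(p.counts):
                start = int(idx) - p.l_up + annot.cds_start
                end = start + p.read_length
                if start < 0 or end > annot.length:
                    continue  # read would overhang the transcript
                read_seq = seq[start:end]
                for _ in range(int(round(p.counts[idx]))):
                    fh.write(
                        f"r{read_id}\t0\t{p.transcript_id}\t{start + 1}\t255\t"
                        f"{p.read_length}M\t*\t0\t0\t{read_seq}\t*\tNH:i:1\n"
                    )
                    read_id += 1


def make_fixture(spec: SyntheticSpec, outdir: str, sam: bool = False) -> dict[str, str]:
    """Write a self-describing bundle sufficient to run every CLI command.

    Returns a map from artifact name to file path.
    """
    from ribodeconv import io as rio

    os.makedirs(outdir, exist_ok=True)
    truth = generate_truth(spec)
    profiles = sample_reads(truth)
    paths = {
        "spec": os.path.join(outdir, "spec.json"),
        "annotations": os.path.join(outdir, "annotations.tsv"),
        "cds_fasta": os.path.join(outdir, "cds.fasta"),
        "profiles": os.path.join(outdir, "profiles.tsv"),
        "blur": os.path.join(outdir, "true_blur.tsv"),
        "truth": os.path.join(outdir, "true_consensus.tsv"),
    }
    with open(paths["spec"], "w") as fh:
        fh.write(spec.to_json() + "\n")
    rio.write_annotations(annotations_of(truth), paths["annotations"])
    rio.write_fasta(cds_sequences_of(truth), paths["cds_fasta"])
    rio.write_profiles(profiles, paths["profiles"])
    rio.write_blurs({l: b for l, b in truth.blurs.items()}, paths["blur"])
    truth_rows = {
        t.annotation.transcript_id: (t.consensus, t.frameshift_position)
        for t in truth.transcripts
    }
    rio.write_truth(truth_rows, paths["truth"], l_up=spec.l_up)
    if sam:
        paths["sam"] = os.path.join(outdir, "reads.sam")
        write_sam(truth, profiles, paths["sam"])
    return paths
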