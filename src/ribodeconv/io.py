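"""Plain-text readers and writers for the pipeline's tabular interchange files.

All tables are tab-separated with a header row.  Profile-like tables store
positions as nt offsets relative to the start codon; windows are
reconstructed from the annotation table on read.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ribodeconv.asite import ASiteProfile
from ribodeconv.metablur import BLUR_HALF_WIDTH, BLUR_WIDTH, BlurVector
from ribodeconv.profiles import (
    L_UP_DEFAULT,
    LengthProfile,
    TranscriptAnnotation,
    window_bounds,
)


def read_annotations(path: str) -> dict[str, TranscriptAnnotation]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out = {}
    for row in df.itertuples(index=False):
        out[str(row.transcript_id)] = TranscriptAnnotation(
            transcript_id=str(row.transcript_id),
            cds_start=int(row.cds_start),
            cds_end=int(row.cds_end),
            length=int(row.length),
        )
    return out


def write_annotations(annotations: dict[str, TranscriptAnnotation], path: str) -> None:
    rows = [
        {"transcript_id": a.transcript_id, "cds_start": a.cds_start,
         "cds_end": a.cds_end, "length": a.length}
        for a in sorted(annotations.values(), key=lambda a: a.transcript_id)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_fasta(sequences: dict[str, str], path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=tid, description="")
        for tid, seq in sorted(sequences.items())
    ]
    SeqIO.write(records, path, "fasta")


def write_profiles(profiles: list[LengthProfile], path: str) -> None:
    """One row per nonzero cell: transcript_id, read_length, position, count."""
    rows = []
    for p in profiles:
        for idx in np.flatnonzero(p.counts):
            rows.append(
                (p.transcript_id, p.read_length, int(idx) - p.l_up, p.counts[idx])
            )
    pd.DataFrame(
        rows, columns=["transcript_id", "read_length", "position", "count"]
    ).to_csv(path, sep="\t", index=False)


def read_profiles(
    path: str,
    annotations: dict[str, TranscriptAnnotation],
    l_up: int = L_UP_DEFAULT,
) -> list[LengthProfile]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out: list[LengthProfile] = []
    for (tid, l), group in df.groupby(["transcript_id", "read_length"], sort=True):
        annot = annotations[str(tid)]
        up, down = window_bounds(annot, l_up)
        counts = np.zeros(up + down)
        idx = group["position"].to_numpy(dtype=int) + up
        valid = (idx >= 0) & (idx < counts.size)
        counts[idx[valid]] = group["count"].to_numpy(dtype=float)[valid]
        out.append(
            LengthProfile(str(tid), int(l), counts, alpha=float(counts.sum()), l_up=l_up)
        )
    return out


def write_blurs(blurs: dict[int, BlurVector], path: str) -> None:
    rows = []
    for l in sorted(blurs):
        for offset, weight in zip(blurs[l].offsets, blurs[l].weights):
            rows.append((l, int(offset), weight))
    pd.DataFrame(rows, columns=["read_length", "offset", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def read_blurs(path: str) -> dict[int, BlurVector]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out: dict[int, BlurVector] = {}
    for l, group in df.groupby("read_length", sort=True):
        weights = np.zeros(BLUR_WIDTH)
        for row in group.itertuples(index=False):
            weights[int(row.offset) + BLUR_HALF_WIDTH] = float(row.weight)
        out[int(l)] = BlurVector(int(l), weights)
    return out


def write_meta_profiles(meta: dict[int, "MetaProfile"], path: str) -> None:
    rows = []
    for l in sorted(meta):
        m = meta[l]
        for pos, value, masked in zip(m.positions, m.values, m.outlier_mask):
            rows.append((l, int(pos), value, bool(masked)))
    pd.DataFrame(
        rows, columns=["read_length", "position", "value", "masked"]
    ).to_csv(path, sep="\t", index=False)


def write_deblur_results(results: list["DeblurResult"], path: str) -> None:
    """Full-window rows: transcript_id, read_length|'consensus', position, value, alpha."""
    from ribodeconv.profiles import L_UP_DEFAULT as up

    frames = []
    for res in results:
        n = res.consensus.values.size
        positions = np.arange(n) - up
        frames.append(
            pd.DataFrame(
                {
                    "transcript_id": res.transcript_id,
                    "read_length": "consensus",
                    "position": positions,
                    "value": res.consensus.values,
                    "alpha": np.nan,
                }
            )
        )
        for l, (p_true, _k, alpha) in sorted(res.per_length.items()):
            frames.append(
                pd.DataFrame(
                    {
                        "transcript_id": res.transcript_id,
                        "read_length": str(l),
                        "position": positions,
                        "value": p_true,
                        "alpha": alpha,
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_deblur_results(path: str) -> list["DeblurResult"]:
    from ribodeconv.deblur import ConsensusSignal, DeblurResult, shift_for_length

    df = pd.read_csv(path, sep="\t", comment="#", dtype={"read_length": str})
    results = []
    for tid, group in df.groupby("transcript_id", sort=True):
        consensus = None
        per_length = {}
        for rl, sub in group.groupby("read_length"):
            sub = sub.sort_values("position")
            values = sub["value"].to_numpy(dtype=float)
            if rl == "consensus":
                consensus = ConsensusSignal(str(tid), values / max(values.sum(), 1e-300))
            else:
                l = int(rl)
                alpha = float(sub["alpha"].iloc[0])
                per_length[l] = (values, shift_for_length(l), alpha)
        results.append(
            DeblurResult(
                transcript_id=str(tid),
                consensus=consensus,
                per_length=per_length,
                deviations={},
                objective_trace=[],
                converged=True,
            )
        )
    return results


def write_asite_profiles(asites: dict[str, ASiteProfile], path: str) -> None:
    rows = []
    for tid in sorted(asites):
        a = asites[tid]
        for idx in np.flatnonzero(a.values):
            rows.append((tid, int(idx) - a.l_up, a.values[idx]))
    pd.DataFrame(rows, columns=["transcript_id", "position", "value"]).to_csv(
        path, sep="\t", index=False
    )


def read_asite_profiles(path: str, l_up: int = L_UP_DEFAULT) -> dict[str, ASiteProfile]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out: dict[str, ASiteProfile] = {}
    for tid, group in df.groupby("transcript_id", sort=True):
        max_pos = int(group["position"].max())
        values = np.zeros(l_up + max_pos + 1)
        idx = group["position"].to_numpy(dtype=int) + l_up
        values[idx] = group["value"].to_numpy(dtype=float)
        out[str(tid)] = ASiteProfile(str(tid), values, l_up=l_up)
    return out


def write_truth(
    truth: dict[str, tuple[np.ndarray, int | None]], path: str, l_up: int = L_UP_DEFAULT
) -> None:
    rows = []
    for tid in sorted(truth):
        consensus, shift_pos = truth[tid]
        for idx in np.flatnonzero(consensus):
            rows.append((tid, int(idx) - l_up, consensus[idx],
                         "" if shift_pos is None else shift_pos))
    pd.DataFrame(
        rows, columns=["transcript_id", "position", "value", "frameshift_position"]
    ).to_csv(path, sep="\t", index=False)


def read_codon_values(path: str) -> dict[str, float]:
    """Two-column TSV (codon, value), e.g. a tAI or codon-frequency table."""
    df = pd.read_csv(path, sep="\t", comment="#")
    codon_col, value_col = df.columns[0], df.columns[1]
    return {
        str(row[0]).upper().replace("T", "U"): float(row[1])
        for row in df[[codon_col, value_col]].itertuples(index=False)
    }
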