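"""Per-codon decoding-time estimation from merged A-site profiles.

Frame-0 A-site counts are normalized per transcript, pooled by codon, and
each codon's distribution is fit with a lognormal; its skewness,
``(exp(sigma^2) + 2) * sqrt(exp(sigma^2) - 1)``, serves as the decoding-time
estimate.  Wobble comparisons contrast codons decoded by the same tRNA.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from ribodeconv.asite import ASiteProfile

logger = logging.getLogger(__name__)

STOP_CODONS = {"UAA", "UAG", "UGA"}
SENSE_CODONS = tuple(
    a + b + c
    for a in "UCAG"
    for b in "UCAG"
    for c in "UCAG"
    if a + b + c not in STOP_CODONS
)

#: default minimum pooled observations for a per-codon fit
N_MIN_DEFAULT = 20

#: codon positions trimmed at each CDS end
EDGE_EXCLUDE = 20


@dataclass(frozen=True)
class CodonObservation:
    """One normalized A-site count attributed to a codon type."""

    codon: str
    normalized_count: float

    def __post_init__(self) -> None:
        if self.codon not in SENSE_CODONS:
            raise ValueError(f"{self.codon!r} is not a sense codon")
        if self.normalized_count < 0:
            raise ValueError("normalized count must be non-negative")


@dataclass(frozen=True)
class CodonTimeEntry:
    mu: float
    sigma: float
    skewness: float
    n_obs: int


@dataclass
class CodonTimeTable:
    """Lognormal fit parameters and skewness per codon."""

    entries: dict[str, CodonTimeEntry]
    n_min: int = N_MIN_DEFAULT

    def skewness(self, codon: str) -> float:
        return self.entries[codon].skewness

    def __contains__(self, codon: str) -> bool:
        return codon in self.entries

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"codon": c, "n_obs": e.n_obs, "mu": e.mu, "sigma": e.sigma,
             "skewness": e.skewness}
            for c, e in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["codon", "n_obs", "mu", "sigma", "skewness"])


@dataclass(frozen=True)
class WobblePair:
    """Two codons read by one tRNA, differing only at the third base.

    ``codon_wc`` is the Watson-Crick-paired codon (or the stronger-wobble
    I:C codon for inosine anticodons); ``codon_wb`` is the wobble codon.
    """

    anticodon_first_base: str
    codon_wc: str
    codon_wb: str
    pair_class: str

    def __post_init__(self) -> None:
        if self.anticodon_first_base not in {"U", "G", "I"}:
            raise ValueError("anticodon first base must be U, G, or I")
        if self.codon_wc[:2] != self.codon_wb[:2] or self.codon_wc == self.codon_wb:
            raise ValueError("paired codons must share their first two bases and differ at the third")


def _rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def codon_counts(
    asite: ASiteProfile,
    cds_seq: str,
    edge_exclude: int = EDGE_EXCLUDE,
    min_count: float = 1.0,
) -> list[CodonObservation]:
    """Normalized per-codon-position counts for one transcript.

    The raw count of codon position ``c`` is the frame-0 A-site value at nt
    ``3c``.  The first and last ``edge_exclude`` codon positions and
    positions with raw count below ``min_count`` are excluded; the survivors
    are divided by their own mean.  Transcripts too short to retain any
    position are skipped with a warning.
    """
    seq = _rna(cds_seq)
    n_codons = len(seq) // 3
    if n_codons < 2 * edge_exclude + 1:
        logger.warning(
            "%s: CDS of %d codons too short for decoding-time analysis; skipped",
            asite.transcript_id, n_codons,
        )
        return []
    raw: list[tuple[str, float]] = []
    for c in range(edge_exclude, n_codons - edge_exclude):
        codon = seq[3 * c : 3 * c + 3]
        if codon not in SENSE_CODONS:
            continue
        try:
            value = float(asite.values[asite.index_of(3 * c)])
        except IndexError:
            continue
        if value >= min_count:
            raw.append((codon, value))
    if not raw:
        return []
    mean = sum(v for _, v in raw) / len(raw)
    return [CodonObservation(codon, v / mean) for codon, v in raw]


def lognormal_skewness(sigma: float) -> float:
    """Closed-form skewness of a lognormal with log-scale ``sigma``."""
    e = math.exp(sigma**2)
    return (e + 2.0) * math.sqrt(e - 1.0)


def fit_lognormal_skewness(
    observations: np.ndarray | list[float], n_min: int = N_MIN_DEFAULT
) -> tuple[float, float, float] | None:
    """Maximum-likelihood lognormal fit; returns ``(mu, sigma, skewness)``.

    ``mu`` and ``sigma`` are the mean and (population) standard deviation of
    the natural-log observations.  Returns ``None`` with fewer than ``n_min``
    strictly positive observations.
    """
    x = np.asarray(observations, dtype=float)
    x = x[x > 0]
    if x.size < n_min:
        return None
    logs = np.log(x)
    mu = float(logs.mean())
    sigma = float(logs.std(ddof=0))
    return mu, sigma, lognormal_skewness(sigma)


def build_cdt_table(
    asites: dict[str, ASiteProfile],
    cds_sequences: dict[str, str],
    n_min: int = N_MIN_DEFAULT,
    edge_exclude: int = EDGE_EXCLUDE,
    min_count: float = 1.0,
) -> CodonTimeTable:
    """Pool codon observations across transcripts and fit each codon.

    Stop codons are excluded; codons with fewer than ``n_min`` pooled
    observations are reported as missing.
    """
    pooled: dict[str, list[float]] = {}
    for tid in sorted(asites):
        if tid not in cds_sequences:
            logger.warning("%s: no CDS sequence; skipped", tid)
            continue
        for obs in codon_counts(
            asites[tid], cds_sequences[tid], edge_exclude=edge_exclude,
            min_count=min_count,
        ):
            pooled.setdefault(obs.codon, []).append(obs.normalized_count)
    entries: dict[str, CodonTimeEntry] = {}
    for codon, values in pooled.items():
        fit = fit_lognormal_skewness(values, n_min=n_min)
        if fit is None:
            continue
        mu, sigma, skew = fit
        entries[codon] = CodonTimeEntry(mu=mu, sigma=sigma, skewness=skew, n_obs=len(values))
    return CodonTimeTable(entries=entries, n_min=n_min)


def wobble_delta(table: CodonTimeTable, pair: WobblePair) -> float:
    """Relative decoding-time difference ``(t_wb - t_wc) / t_wc``.

    Returns ``nan`` when the reference skewness is zero.
    """
    t_wc = table.skewness(pair.codon_wc)
    t_wb = table.skewness(pair.codon_wb)
    if t_wc == 0:
        return float("nan")
    return (t_wb - t_wc) / t_wc


def rank_correlation(
    table: CodonTimeTable, covariate: dict[str, float], min_codons: int = 10
) -> tuple[float, float]:
    """Spearman correlation between estimated decoding times and a covariate.

    The covariate (e.g. a tRNA adaptation index or codon usage frequency) is
    keyed by codon; only codons present in both inputs are used.
    """
    covariate = {_rna(c): v for c, v in covariate.items()}
    common = sorted(set(table.entries) & set(covariate))
    if len(common) < min_codons:
        raise ValueError(f"only {len(common)} codons in common (need {min_codons})")
    skews = [table.skewness(c) for c in common]
    covs = [covariate[c] for c in common]
    if len(set(skews)) == 1 or len(set(covs)) == 1:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(skews, covs)
    return float(rho), float(p)


def load_wobble_pairs(path: str | None = None) -> list[WobblePair]:
    """Load wobble codon pairs from a TSV (class, codon_wc, codon_wb).

    Without a path, the bundled yeast table is used.  Class labels start with
    the anticodon first base (U, G, or I).
    """
    if path is None:
        source = resources.files("ribodeconv.data").joinpath("wobble_pairs_yeast.tsv")
        with resources.as_file(source) as fh:
            df = pd.read_csv(fh, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    pairs = []
    for row in df.itertuples(index=False):
        pairs.append(
            WobblePair(
                anticodon_first_base=str(row.pair_class)[0],
                codon_wc=_rna(row.codon_wc),
                codon_wb=_rna(row.codon_wb),
                pair_class=str(row.pair_class),
            )
        )
    return pairs
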